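"""Sparse barcodes x genes UMI count matrix with biotype annotation."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse


class UmiCountMatrix:
    """Non-negative integer UMI counts, barcodes in rows, genes in columns."""

    def __init__(
        self,
        barcodes: Sequence[str],
        genes: Sequence[str],
        biotypes: Sequence[str],
        counts: scipy.sparse.spmatrix,
    ) -> None:
        counts = scipy.sparse.csr_matrix(counts)
        if counts.shape != (len(barcodes), len(genes)):
            raise ValueError(
                f"counts shape {counts.shape} != ({len(barcodes)}, {len(genes)})"
            )
        if len(biotypes) != len(genes):
            raise ValueError("one biotype per gene required")
        if counts.nnz and counts.data.min() < 0:
            raise ValueError("negative counts")
        self.barcodes = list(barcodes)
        self.genes = list(genes)
        self.biotypes = list(biotypes)
        self.counts = counts.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[tuple[str, str], int],
        gene_biotypes: Mapping[str, str],
        barcodes: Sequence[str] | None = None,
        genes: Sequence[str] | None = None,
    ) -> "UmiCountMatrix":
        """Build from a {(barcode, gene): count} mapping.

        Row/column order defaults to sorted barcodes/genes so two matrices
        built from the same counts compare equal.
        """
        if barcodes is None:
            barcodes = sorted({bc for bc, _ in counts})
        if genes is None:
            genes = sorted({g for _, g in counts})
        bc_idx = {b: i for i, b in enumerate(barcodes)}
        g_idx = {g: j for j, g in enumerate(genes)}
        rows, cols, vals = [], [], []
        for (bc, gene), v in counts.items():
            rows.append(bc_idx[bc])
            cols.append(g_idx[gene])
            vals.append(v)
        mat = scipy.sparse.coo_matrix(
            (vals, (rows, cols)), shape=(len(barcodes), len(genes)), dtype=np.int64
        )
        biotypes = [gene_biotypes.get(g, "mRNA") for g in genes]
        return cls(barcodes, genes, biotypes, mat)

    def umis_per_barcode(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def genes_per_barcode(self) -> np.ndarray:
        """Detected genes per barcode (genes with count > 0)."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def gene_totals(self) -> pd.Series:
        return pd.Series(
            np.asarray(self.counts.sum(axis=0)).ravel(), index=self.genes
        )

    def barcode_summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": self.barcodes,
                "umis": self.umis_per_barcode(),
                "genes": self.genes_per_barcode(),
            }
        )

    def subset_barcodes(self, keep: Sequence[str]) -> "UmiCountMatrix":
        keep_set = set(keep)
        idx = [i for i, b in enumerate(self.barcodes) if b in keep_set]
        return UmiCountMatrix(
            [self.barcodes[i] for i in idx],
            self.genes,
            self.biotypes,
            self.counts[idx],
        )

    def equals(self, other: "UmiCountMatrix") -> bool:
        """Order-insensitive equality of the labelled count tensors."""
        if set(self.barcodes) != set(other.barcodes):
            return False
        if set(self.genes) != set(other.genes):
            return False
        a = self.to_frame()
        b = other.to_frame().reindex(index=a.index, columns=a.columns, fill_value=0)
        return bool((a.values == b.values).all())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.toarray(), index=self.barcodes, columns=self.genes
        ).sort_index(axis=0).sort_index(axis=1)
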