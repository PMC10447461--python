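"""Read-to-gene assignment, UMI deduplication, and biotype accounting.

Only uniquely mapped reads are consumed.  A read is assigned to a gene iff
its interval overlaps exactly one gene by >= 1 nt (multi-overlap reads are
dropped, featureCounts-style); assignment is unstranded by default because
random priming leaves cDNA read strand uninformative in bacteria.  UMI counts
collapse identical (barcode, gene, UMI) triples; an optional directional mode
additionally merges Hamming-1 UMI children into parents when
parent_count >= 2 * child_count - 1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import GeneModel
from .matrix import UmiCountMatrix

ALIGNMENT_COLUMNS = ["read_id", "contig", "start", "end", "strand", "unique"]


def read_alignment_tsv(path: str) -> pd.DataFrame:
    """Read the canonical alignment interchange TSV
    (read_id, contig, start, end, strand, unique{0,1}; 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ALIGNMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"alignment TSV missing columns: {missing}")
    return df


def read_alignment_sam(path: str, unique_mapq: int = 30) -> pd.DataFrame:
    """Thin SAM adapter: mapped primary records, MAPQ > threshold => unique."""
    import pysam

    rows = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            rows.append(
                (
                    rec.query_name,
                    rec.reference_name,
                    rec.reference_start + 1,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+",
                    int(rec.mapping_quality > unique_mapq),
                )
            )
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


def assign_reads(
    alignments: pd.DataFrame,
    genes: list[GeneModel],
    stranded: bool = False,
) -> pd.DataFrame:
    """Assign unique-mapped reads to genes by interval overlap.

    Returns a frame with ``read_id``, ``gene_id`` (empty when unassigned) and
    ``reason`` in {assigned, not_unique, unknown_contig, no_feature,
    ambiguous}.  Assigned + unassigned reasons partition the input.
    """
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        # GTF 1-based inclusive -> 0-based half-open
        trees.setdefault(gene.contig, IntervalTree()).addi(
            gene.start - 1, gene.end, (gene.gene_id, gene.strand)
        )
    read_ids = alignments["read_id"].to_numpy()
    contigs = alignments["contig"].to_numpy()
    starts = alignments["start"].to_numpy()
    ends = alignments["end"].to_numpy()
    strands = alignments["strand"].to_numpy()
    uniques = alignments["unique"].to_numpy()
    gene_out = np.empty(len(alignments), dtype=object)
    reason_out = np.empty(len(alignments), dtype=object)
    for i in range(len(alignments)):
        if not uniques[i]:
            gene_out[i], reason_out[i] = "", "not_unique"
            continue
        tree = trees.get(contigs[i])
        if tree is None:
            gene_out[i], reason_out[i] = "", "unknown_contig"
            continue
        hits = tree.overlap(starts[i] - 1, ends[i])
        if stranded:
            hits = {h for h in hits if h.data[1] == strands[i]}
        if len(hits) == 0:
            gene_out[i], reason_out[i] = "", "no_feature"
        elif len(hits) > 1:
            gene_out[i], reason_out[i] = "", "ambiguous"
        else:
            gene_out[i] = next(iter(hits)).data[0]
            reason_out[i] = "assigned"
    return pd.DataFrame(
        {"read_id": read_ids, "gene_id": gene_out, "reason": reason_out}
    )


def _directional_count(umi_counts: Counter) -> int:
    """Directional-network UMI collapse for one (barcode, gene) group.

    Builds directed edges parent->child between Hamming-1 UMIs where
    count(parent) >= 2*count(child) - 1, then counts clusters by visiting
    UMIs in descending count order and absorbing everything reachable.
    """
    umis = sorted(umi_counts, key=lambda u: (-umi_counts[u], u))
    if len(umis) == 1:
        return 1
    by_len = umis  # all same length; pairwise scan (groups are small)
    adj: dict[str, list[str]] = {u: [] for u in umis}
    for i, u in enumerate(by_len):
        cu = umi_counts[u]
        for v in by_len[i + 1 :]:
            if sum(a != b for a, b in zip(u, v)) == 1:
                cv = umi_counts[v]
                if cu >= 2 * cv - 1:
                    adj[u].append(v)
                if cv >= 2 * cu - 1:
                    adj[v].append(u)
    visited: set[str] = set()
    clusters = 0
    for u in umis:  # descending count: parents claim children first
        if u in visited:
            continue
        clusters += 1
        stack = [u]
        visited.add(u)
        while stack:
            cur = stack.pop()
            for nxt in adj[cur]:
                if nxt not in visited:
                    visited.add(nxt)
                    stack.append(nxt)
    return clusters


@dataclass
class CountResult:
    matrix: UmiCountMatrix
    rejected_umis: int = 0


def count_umis(
    tagged: pd.DataFrame,
    gene_biotypes: dict[str, str],
    collapse: str = "exact",
    umi_length: int = 8,
) -> CountResult:
    """Deduplicate UMIs per (barcode, gene) and build the count matrix.

    ``tagged`` needs columns barcode, umi, gene_id (already gene-assigned
    reads).  ``collapse`` is "exact" (identical UMIs count once) or
    "directional".  Records whose UMI length differs from ``umi_length`` are
    rejected and counted.
    """
    if collapse not in ("exact", "directional"):
        raise ValueError(f"unknown collapse mode {collapse!r}")
    if len(tagged) == 0:
        return CountResult(
            UmiCountMatrix.from_counts({}, gene_biotypes, barcodes=[], genes=[])
        )
    ok = tagged["umi"].str.len() == umi_length
    rejected = int((~ok).sum())
    tagged = tagged[ok]
    counts: dict[tuple[str, str], int] = {}
    if collapse == "exact":
        dedup = tagged.drop_duplicates(["barcode", "gene_id", "umi"])
        grouped = dedup.groupby(["barcode", "gene_id"]).size()
        counts = {(bc, g): int(v) for (bc, g), v in grouped.items()}
    else:
        for (bc, g), grp in tagged.groupby(["barcode", "gene_id"]):
            counts[(bc, g)] = _directional_count(Counter(grp["umi"]))
    return CountResult(UmiCountMatrix.from_counts(counts, gene_biotypes), rejected)


def biotype_report(
    reads: pd.DataFrame,
    gene_biotypes: dict[str, str] | None = None,
) -> dict[str, float]:
    """Proportions of reads per RNA class.

    ``reads`` is an assignment frame (read_id, gene_id, reason); unassigned
    reads fall in the ``unassigned`` bucket.  Proportions sum to 1; an empty
    input yields explicit zeros.
    """
    categories = ["mRNA", "rRNA", "tRNA", "ncRNA", "unassigned"]
    totals = dict.fromkeys(categories, 0)
    if len(reads):
        assigned = (
            reads["reason"] == "assigned"
            if "reason" in reads.columns
            else reads["gene_id"].astype(bool)
        )
        assigned &= reads["gene_id"].astype(bool)
        labels = (
            reads.loc[assigned, "gene_id"]
            .map(gene_biotypes or {})
            .fillna("mRNA")
        )
        for biotype, v in labels.value_counts().items():
            totals[biotype] += int(v)
        totals["unassigned"] = int((~assigned).sum())
    n = sum(totals.values())
    report = {k: (v / n if n else 0.0) for k, v in totals.items()}
    report["total_reads"] = n
    return report
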