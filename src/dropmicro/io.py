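"""Readers and writers for the standard formats the toolkit touches.

Sequence reads are held in a minimal :class:`SeqRead`; gene annotation is
parsed from GTF/GFF3 into :class:`GeneModel` records (1-based inclusive
coordinates, as in the source files).  Count matrices round-trip through the
MatrixMarket trio (``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv``).
Gzip is detected by magic bytes, never by file extension.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import gffutils
import scipy.io
import scipy.sparse

from .errors import ParseError

logger = logging.getLogger("dropmicro")

BIOTYPES = ("mRNA", "rRNA", "tRNA", "ncRNA")

# common annotation spellings mapped onto the four reported RNA classes
_BIOTYPE_ALIASES = {
    "protein_coding": "mRNA",
    "mrna": "mRNA",
    "rrna": "rRNA",
    "trna": "tRNA",
    "ncrna": "ncRNA",
    "misc_rna": "ncRNA",
}


@dataclass
class SeqRead:
    """One sequencing read (or any named sequence)."""

    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"{self.id}: quality length != sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A gene as a single genomic interval with an RNA-class label.

    Coordinates are 1-based inclusive (GTF convention).  ``sequence``, when
    set, is the transcript sequence written 5'->3'.
    """

    gene_id: str
    biotype: str
    contig: str
    start: int
    end: int
    strand: str = "+"
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ParseError(
                f"gene {self.gene_id}: end ({self.end}) < start ({self.start})"
            )
        if self.biotype not in BIOTYPES:
            raise ParseError(f"gene {self.gene_id}: unknown biotype {self.biotype!r}")
        if self.strand not in "+-":
            raise ParseError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _open_maybe_gzip(path: str | os.PathLike, mode: str = "rt") -> IO:
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, mode)
        return open(path, mode)
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | os.PathLike) -> Iterator[SeqRead]:
    """Stream 4-line FASTQ records, uppercasing sequences.

    Raises :class:`ParseError` naming the (1-based) record index on a
    truncated quartet or a sequence/quality length mismatch.
    """
    with _open_maybe_gzip(path) as fh:
        record_index = 0
        while True:
            header = fh.readline()
            if not header:
                return
            record_index += 1
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ParseError(f"record {record_index}: malformed FASTQ quartet")
            if not qual and not plus:
                raise ParseError(f"record {record_index}: truncated FASTQ quartet")
            if len(qual) != len(seq):
                raise ParseError(
                    f"record {record_index}: quality length {len(qual)} != "
                    f"sequence length {len(seq)}"
                )
            yield SeqRead(header[1:].split()[0], seq.upper(), qual)


def write_fastq(records: Iterable[SeqRead], path: str | os.PathLike) -> int:
    n = 0
    with _open_maybe_gzip(path, "wt") as fh:
        for rec in records:
            qual = rec.quality or "I" * len(rec.sequence)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")
            n += 1
    return n


def read_fasta(path: str | os.PathLike) -> list[SeqRead]:
    from Bio import SeqIO

    with _open_maybe_gzip(path) as fh:
        return [SeqRead(r.id, str(r.seq).upper()) for r in SeqIO.parse(fh, "fasta")]


def write_fasta(records: Iterable[SeqRead], path: str | os.PathLike) -> int:
    n = 0
    with _open_maybe_gzip(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")
            n += 1
    return n


def _normalise_biotype(raw: str | None, gene_id: str) -> str:
    if raw is None:
        logger.info("gene %s has no biotype attribute; defaulting to mRNA", gene_id)
        return "mRNA"
    canon = _BIOTYPE_ALIASES.get(raw.lower())
    if canon is None:
        if raw in BIOTYPES:
            return raw
        logger.info("gene %s: unrecognised biotype %r treated as ncRNA", gene_id, raw)
        return "ncRNA"
    return canon


def read_gtf(path: str | os.PathLike) -> list[GeneModel]:
    """Parse gene features from a GTF or GFF3 file into :class:`GeneModel`s.

    Accepts either dialect (``gene_id "x"`` or ``ID=x``).  Genes without a
    biotype attribute default to mRNA (logged); a gene feature with no
    identifier at all is a :class:`ParseError`.
    """
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted internal errors
        raise ParseError(f"could not parse annotation {path}: {exc}") from exc

    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        gid = None
        for key in ("gene_id", "ID", "Name"):
            if key in feat.attributes:
                gid = feat.attributes[key][0]
                break
        if gid is None:
            raise ParseError(
                f"gene feature at {feat.seqid}:{feat.start}-{feat.end} "
                "has no gene_id/ID attribute"
            )
        raw_biotype = None
        for key in ("gene_biotype", "biotype", "gene_type"):
            if key in feat.attributes:
                raw_biotype = feat.attributes[key][0]
                break
        genes.append(
            GeneModel(
                gene_id=gid,
                biotype=_normalise_biotype(raw_biotype, gid),
                contig=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
            )
        )
    return genes


def write_mtx(matrix, outdir: str | os.PathLike) -> None:
    """Write the MatrixMarket trio: ``matrix.mtx``, ``barcodes.tsv`` and
    ``features.tsv`` (gene_id <tab> biotype)."""
    os.makedirs(outdir, exist_ok=True)
    scipy.io.mmwrite(
        os.path.join(outdir, "matrix.mtx"),
        scipy.sparse.coo_matrix(matrix.counts),
        field="integer",
    )
    with open(os.path.join(outdir, "barcodes.tsv"), "w") as fh:
        for bc in matrix.barcodes:
            fh.write(bc + "\n")
    with open(os.path.join(outdir, "features.tsv"), "w") as fh:
        for gid, biotype in zip(matrix.genes, matrix.biotypes):
            fh.write(f"{gid}\t{biotype}\n")


def read_mtx(indir: str | os.PathLike):
    from .matrix import UmiCountMatrix

    counts = scipy.sparse.csr_matrix(
        scipy.io.mmread(os.path.join(indir, "matrix.mtx"))
    ).astype(int)
    with open(os.path.join(indir, "barcodes.tsv")) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    genes, biotypes = [], []
    with open(os.path.join(indir, "features.tsv")) as fh:
        for line in fh:
            if line.strip():
                gid, biotype = line.rstrip("\n").split("\t")
                genes.append(gid)
                biotypes.append(biotype)
    return UmiCountMatrix(barcodes=barcodes, genes=genes, biotypes=biotypes, counts=counts)
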