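"""Read1 parsing, whitelist barcode correction, and Read2 pre-trimming.

Read1 carries the 8-nt UMI followed by the 30-nt cell barcode (then residual
poly(T), ignored).  An observed barcode is kept iff it can be *uniquely*
assigned to a whitelist member at Hamming distance <= 2; zero or multiple
candidates discard the read.  Read2 loses its capture-primer handle and the
trailing dA-tail homopolymer before alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import numpy as np
import pandas as pd

from ._util import DNA, encode_seq
from .barcodes import BarcodeWhitelist, BeadPrimerDesign
from .io import SeqRead

# whitelists up to this size are corrected by a vectorised scan over all
# members; larger ones by enumerating the <=2-substitution neighbourhood
# (1 + 90 + 35,235 variants for a 30-mer) against the hash index
_SCAN_LIMIT = 200_000


@dataclass
class ParsedRead:
    read_id: str
    umi: str
    raw_barcode: str
    corrected_barcode: str | None = None
    r2_trimmed: SeqRead | None = None


@dataclass
class DemuxResult:
    """Tagged reads that survived demultiplexing plus per-reason rejection
    counts."""

    tagged: pd.DataFrame  # read_id, barcode, umi
    trimmed_r2: list[SeqRead]
    rejections: dict[str, int] = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return len(self.tagged)


def parse_read1(r1: SeqRead, design: BeadPrimerDesign) -> tuple[str, str]:
    """Fixed-offset extraction of (UMI, raw barcode) from Read1.

    Raises ValueError("too_short") when the read cannot hold UMI + barcode.
    """
    need = design.umi_length + design.barcode_length
    if len(r1.sequence) < need:
        raise ValueError("too_short")
    umi = r1.sequence[: design.umi_length]
    barcode = r1.sequence[design.umi_length : need]
    return umi, barcode


def correct_barcode(
    raw: str, whitelist: BarcodeWhitelist, max_distance: int = 2
) -> str | None:
    """Return the unique whitelist member within Hamming <= ``max_distance``
    of ``raw``, or None when there are zero or several candidates.

    Exact hits return immediately only when the whitelist's verified minimum
    pairwise distance rules out a second member within range; otherwise the
    whole <=max_distance ball is checked so ambiguity is never missed.
    """
    if len(raw) != whitelist.barcode_length:
        return None
    exact = raw in whitelist
    if exact and whitelist.min_distance is not None and (
        whitelist.min_distance > max_distance
    ):
        return raw
    if len(whitelist) <= _SCAN_LIMIT:
        enc = whitelist.encoded()
        dists = (enc != encode_seq(raw)).sum(axis=1)
        hits = np.flatnonzero(dists <= max_distance)
        return whitelist.barcodes[hits[0]] if len(hits) == 1 else None
    return _correct_by_neighbourhood(raw, whitelist, max_distance, exact)


def _correct_by_neighbourhood(
    raw: str, whitelist: BarcodeWhitelist, max_distance: int, exact: bool
) -> str | None:
    hits: set[str] = {raw} if exact else set()
    n = len(raw)
    if max_distance >= 1:
        for i in range(n):
            prefix, suffix = raw[:i], raw[i + 1 :]
            for b in DNA:
                if b == raw[i]:
                    continue
                cand = prefix + b + suffix
                if cand in whitelist:
                    hits.add(cand)
                    if len(hits) > 1:
                        return None
    if max_distance >= 2:
        for i, j in combinations(range(n), 2):
            for bi in DNA:
                if bi == raw[i]:
                    continue
                part = raw[:i] + bi + raw[i + 1 : j]
                for bj in DNA:
                    if bj == raw[j]:
                        continue
                    cand = part + bj + raw[j + 1 :]
                    if cand in whitelist:
                        hits.add(cand)
                        if len(hits) > 1:
                            return None
    if len(hits) == 1:
        return next(iter(hits))
    return None


def trim_read2(
    r2: SeqRead, handle: str = "", min_tail: int = 6
) -> SeqRead | None:
    """Strip a leading capture-primer handle (exact prefix match) and a
    trailing dA-tail homopolymer of length >= ``min_tail``.

    Returns None (reject reason "empty_after_trim") when nothing remains.
    """
    seq = r2.sequence
    offset = 0
    if handle and seq.startswith(handle):
        seq = seq[len(handle) :]
        offset = len(handle)
    tail = len(seq) - len(seq.rstrip("A"))
    if tail >= min_tail:
        seq = seq[: len(seq) - tail]
    if not seq:
        return None
    qual = r2.quality[offset : offset + len(seq)] if r2.quality else None
    return SeqRead(r2.id, seq, qual)


def demux_reads(
    r1_reads: Iterable[SeqRead],
    r2_reads: Iterable[SeqRead],
    whitelist: BarcodeWhitelist,
    design: BeadPrimerDesign,
    r2_handle: str = "",
    min_tail: int = 6,
) -> DemuxResult:
    """Run the full Read1/Read2 demultiplexing loop.

    Rejection reasons: ``too_short`` (R1 shorter than UMI+barcode),
    ``barcode_unassigned`` (zero or ambiguous whitelist candidates),
    ``empty_after_trim`` (R2 fully consumed by trimming).
    """
    rejections = {"too_short": 0, "barcode_unassigned": 0, "empty_after_trim": 0}
    read_ids: list[str] = []
    barcodes: list[str] = []
    umis: list[str] = []
    trimmed: list[SeqRead] = []
    for r1, r2 in zip(r1_reads, r2_reads):
        try:
            umi, raw = parse_read1(r1, design)
        except ValueError:
            rejections["too_short"] += 1
            continue
        corrected = correct_barcode(raw, whitelist)
        if corrected is None:
            rejections["barcode_unassigned"] += 1
            continue
        r2_out = trim_read2(r2, handle=r2_handle, min_tail=min_tail)
        if r2_out is None:
            rejections["empty_after_trim"] += 1
            continue
        read_ids.append(r1.id)
        barcodes.append(corrected)
        umis.append(umi)
        trimmed.append(r2_out)
    tagged = pd.DataFrame({"read_id": read_ids, "barcode": barcodes, "umi": umis})
    return DemuxResult(tagged=tagged, trimmed_r2=trimmed, rejections=rejections)
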