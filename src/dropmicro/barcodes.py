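"""Split-pool bead-primer model and combinatorial barcode whitelist.

The bead primer is synthesised in three ligation rounds on top of an initial
PCR handle; each round draws one segment from a round-specific well plate, so
the cell barcode is the concatenation of three segments.  With the default
plate sizes (96, 96, 48) the whitelist holds 442,368 distinct 30-nt barcodes.
Segments generated by this module are kept at pairwise Hamming distance >= 3
within a round, which makes correction of up to two sequencing errors over the
whole barcode unambiguous (two whitelist members always differ at >= 3
positions when per-round segment lengths are fixed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._util import encode_seq, encode_seqs, random_dna
from .errors import CapacityError, DesignError

DEFAULT_CARDINALITIES = (96, 96, 48)
DEFAULT_SEGMENT_LENGTHS = (10, 10, 10)
DEFAULT_MIN_INTRA_ROUND_DISTANCE = 3

# placeholder constant sequences; real bead manifests override these
DEFAULT_PCR_HANDLE = "CAGACGTGTGCTCTTCCGATCTUGACT"  # 27 nt, U = cleavage site
DEFAULT_LINKERS = ("GTGGCCG", "ATCA")  # 7 nt after round 1, 4 nt after round 2


@dataclass
class SegmentSet:
    """The segments available in one ligation round."""

    round_index: int
    segments: list[str]

    def __post_init__(self) -> None:
        if self.round_index not in (1, 2, 3):
            raise DesignError("round_index must be 1, 2 or 3")
        if not self.segments:
            raise DesignError(f"round {self.round_index}: empty segment set")
        lengths = {len(s) for s in self.segments}
        if len(lengths) != 1:
            raise DesignError(
                f"round {self.round_index}: segments must all have equal length"
            )
        if len(set(self.segments)) != len(self.segments):
            raise DesignError(f"round {self.round_index}: duplicate segments")

    @property
    def segment_length(self) -> int:
        return len(self.segments[0])

    def min_pairwise_distance(self) -> int:
        """Brute-force minimum Hamming distance between any two segments."""
        enc = encode_seqs(self.segments)
        best = self.segment_length
        for i in range(len(self.segments) - 1):
            d = (enc[i + 1 :] != enc[i]).sum(axis=1).min()
            best = min(best, int(d))
            if best == 0:
                break
        return best

    def __len__(self) -> int:
        return len(self.segments)


def generate_segment_sets(
    seed: int,
    cardinalities: Sequence[int] = DEFAULT_CARDINALITIES,
    lengths: Sequence[int] = DEFAULT_SEGMENT_LENGTHS,
    min_intra_round_distance: int = DEFAULT_MIN_INTRA_ROUND_DISTANCE,
) -> list[SegmentSet]:
    """Draw three segment sets by seeded rejection sampling.

    Each accepted segment must be at Hamming distance
    >= ``min_intra_round_distance`` from every segment already accepted in its
    round.  Infeasible demands (e.g. 96 segments of length 3 at distance 3)
    raise :class:`CapacityError`.
    """
    if len(cardinalities) != 3 or len(lengths) != 3:
        raise DesignError("exactly three rounds are modelled")
    rng = np.random.default_rng(seed)
    sets: list[SegmentSet] = []
    for round_index, (card, length) in enumerate(zip(cardinalities, lengths), start=1):
        if min_intra_round_distance > length or card > 4**length:
            raise CapacityError(
                f"round {round_index}: cannot fit {card} segments of length "
                f"{length} at distance {min_intra_round_distance}"
            )
        accepted: list[str] = []
        enc = np.empty((card, length), dtype=np.uint8)
        attempts = 0
        max_attempts = 500 * card
        while len(accepted) < card:
            attempts += 1
            if attempts > max_attempts:
                raise CapacityError(
                    f"round {round_index}: gave up after {max_attempts} draws; "
                    f"{card} segments of length {length} at distance "
                    f"{min_intra_round_distance} appear infeasible"
                )
            cand = random_dna(rng, length)
            cenc = encode_seq(cand)
            n = len(accepted)
            if n and int((enc[:n] != cenc).sum(axis=1).min()) < min_intra_round_distance:
                continue
            enc[n] = cenc
            accepted.append(cand)
        sets.append(SegmentSet(round_index=round_index, segments=accepted))
    return sets


@dataclass
class BeadPrimerDesign:
    """Full bead-primer architecture.

    5'->3': PCR handle (carrying the enzymatic cleavage site), then per
    ligation round a barcode segment (rounds 1 and 2 followed by a linker),
    then the UMI and the poly(T) capture tail.  ``stage_lengths`` are the
    primer lengths after initial synthesis and after each ligation round;
    the defaults (27, 44, 58, 96) reproduce the synthesis intermediates and
    the 96-nt full-length primer.
    """

    segment_sets: list[SegmentSet]
    pcr_handle: str = DEFAULT_PCR_HANDLE
    cleavage_site_position: int = DEFAULT_PCR_HANDLE.index("U")
    linkers: tuple[str, str] = DEFAULT_LINKERS
    umi_length: int = 8
    polyt_length: int = 20
    stage_lengths: tuple[int, int, int, int] = (27, 44, 58, 96)
    barcode_length: int = 30
    min_intra_round_distance: int | None = None

    def __post_init__(self) -> None:
        seg_lens = [s.segment_length for s in self.segment_sets]
        if len(seg_lens) != 3:
            raise DesignError("a design needs exactly three segment sets")
        if sum(seg_lens) != self.barcode_length:
            raise DesignError(
                f"segment lengths {seg_lens} do not sum to the "
                f"{self.barcode_length}-nt cell barcode"
            )
        expected = (
            len(self.pcr_handle),
            len(self.pcr_handle) + seg_lens[0] + len(self.linkers[0]),
            len(self.pcr_handle)
            + seg_lens[0]
            + len(self.linkers[0])
            + seg_lens[1]
            + len(self.linkers[1]),
        )
        expected = expected + (
            expected[2] + seg_lens[2] + self.umi_length + self.polyt_length,
        )
        if tuple(self.stage_lengths) != expected:
            raise DesignError(
                f"stage_lengths {tuple(self.stage_lengths)} inconsistent with "
                f"components (expected {expected})"
            )
        if not 0 <= self.cleavage_site_position < len(self.pcr_handle):
            raise DesignError("cleavage site must lie inside the PCR handle")

    @property
    def cardinalities(self) -> tuple[int, int, int]:
        return tuple(len(s) for s in self.segment_sets)  # type: ignore[return-value]

    @classmethod
    def default(cls, seed: int = 20230) -> "BeadPrimerDesign":
        sets = generate_segment_sets(seed)
        return cls(
            segment_sets=sets,
            min_intra_round_distance=DEFAULT_MIN_INTRA_ROUND_DISTANCE,
        )

    @classmethod
    def toy(
        cls,
        seed: int = 0,
        cardinalities: Sequence[int] = (4, 4, 2),
        min_intra_round_distance: int = DEFAULT_MIN_INTRA_ROUND_DISTANCE,
    ) -> "BeadPrimerDesign":
        """A small design (same primer architecture, fewer wells per round)
        for tests and examples."""
        sets = generate_segment_sets(
            seed, cardinalities, DEFAULT_SEGMENT_LENGTHS, min_intra_round_distance
        )
        return cls(
            segment_sets=sets, min_intra_round_distance=min_intra_round_distance
        )


def assemble_full_primer(
    design: BeadPrimerDesign,
    segment_indices: tuple[int, int, int],
    umi: str,
    polyt_length: int | None = None,
) -> str:
    """Assemble the full-length primer for one well combination.

    Returns handle + seg1 + linker1 + seg2 + linker2 + seg3 + UMI + poly(T),
    of length ``stage_lengths[3]`` with the design's poly(T) tail.
    """
    if len(umi) != design.umi_length:
        raise DesignError(
            f"UMI length {len(umi)} != design umi_length {design.umi_length}"
        )
    segs = [
        design.segment_sets[r].segments[i] for r, i in enumerate(segment_indices)
    ]
    tail = design.polyt_length if polyt_length is None else polyt_length
    primer = (
        design.pcr_handle
        + segs[0]
        + design.linkers[0]
        + segs[1]
        + design.linkers[1]
        + segs[2]
        + umi
        + "T" * tail
    )
    expected = design.stage_lengths[3] - design.polyt_length + tail
    if len(primer) != expected:
        raise DesignError(
            f"assembled primer length {len(primer)} != expected {expected}"
        )
    return primer


def intermediate_lengths(design: BeadPrimerDesign) -> tuple[int, int, int]:
    """Primer lengths after initial synthesis and the first two ligation
    rounds (the synthesis intermediates seen on an electropherogram)."""
    return design.stage_lengths[:3]


class BarcodeWhitelist:
    """The set of valid cell barcodes with an exact-sequence lookup index.

    ``min_distance``, when not None, is a verified lower bound on the pairwise
    Hamming distance between any two members; correction uses it to shortcut
    exact hits safely.
    """

    def __init__(
        self,
        barcodes: list[str],
        segment_sets: list[SegmentSet] | None = None,
        min_distance: int | None = None,
    ) -> None:
        if not barcodes:
            raise DesignError("empty whitelist")
        lengths = {len(b) for b in barcodes}
        if len(lengths) != 1:
            raise DesignError("whitelist barcodes must all have equal length")
        self.barcodes = barcodes
        self.segment_sets = segment_sets
        self.min_distance = min_distance
        self._index = {b: i for i, b in enumerate(barcodes)}
        if len(self._index) != len(barcodes):
            dup = next(b for b in barcodes if barcodes.count(b) > 1)
            raise DesignError(f"duplicate barcode in whitelist: {dup}")
        self._encoded: np.ndarray | None = None

    @property
    def barcode_length(self) -> int:
        return len(self.barcodes[0])

    def __len__(self) -> int:
        return len(self.barcodes)

    def __contains__(self, barcode: str) -> bool:
        return barcode in self._index

    def __iter__(self):
        return iter(self.barcodes)

    def index_of(self, barcode: str) -> int:
        return self._index[barcode]

    def encoded(self) -> np.ndarray:
        if self._encoded is None:
            self._encoded = encode_seqs(self.barcodes)
        return self._encoded

    def sample(self, rng: np.random.Generator, n: int) -> list[str]:
        """Draw n distinct barcodes (e.g. one bead per droplet)."""
        if n > len(self):
            raise CapacityError(
                f"requested {n} barcodes from a whitelist of {len(self)}"
            )
        idx = rng.choice(len(self), size=n, replace=False)
        return [self.barcodes[i] for i in idx]

    def verify_min_distance(self, limit: int = 20_000) -> int | None:
        """Brute-force the true minimum pairwise distance (sets
        ``min_distance``); skipped (returns None) above ``limit`` members."""
        if len(self) > limit:
            return None
        enc = self.encoded()
        best = self.barcode_length
        for i in range(len(self) - 1):
            d = (enc[i + 1 :] != enc[i]).sum(axis=1).min()
            best = min(best, int(d))
            if best == 0:
                break
        self.min_distance = best
        return best


def build_whitelist(design: BeadPrimerDesign) -> BarcodeWhitelist:
    """Concatenate one segment per round over all well combinations.

    The whitelist size is exactly the product of the round cardinalities;
    any collision between concatenated barcodes raises :class:`DesignError`
    (unreachable for equal-length unique segments, but checked regardless).
    """
    s1, s2, s3 = (s.segments for s in design.segment_sets)
    barcodes = [a + b + c for a in s1 for b in s2 for c in s3]
    expected = len(s1) * len(s2) * len(s3)
    if len(set(barcodes)) != expected:
        seen: set[str] = set()
        collision = next(b for b in barcodes if b in seen or seen.add(b))
        raise DesignError(f"segment sets collide on concatenation: {collision}")
    min_distance = design.min_intra_round_distance
    if min_distance is None:
        min_distance = min(s.min_pairwise_distance() for s in design.segment_sets)
    return BarcodeWhitelist(
        barcodes, segment_sets=design.segment_sets, min_distance=min_distance
    )


def segment_sets_to_tsv(sets: Sequence[SegmentSet], path: str) -> None:
    """Serialize as (round, index, sequence) rows so real bead manifests can
    be dropped in."""
    with open(path, "w") as fh:
        fh.write("round\tindex\tsequence\n")
        for s in sets:
            for i, seq in enumerate(s.segments):
                fh.write(f"{s.round_index}\t{i}\t{seq}\n")


def segment_sets_from_tsv(path: str) -> list[SegmentSet]:
    rounds: dict[int, list[tuple[int, str]]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("round"):
            raise DesignError("segment table must start with a round/index/sequence header")
        for line in fh:
            if not line.strip():
                continue
            r, i, seq = line.rstrip("\n").split("\t")
            rounds.setdefault(int(r), []).append((int(i), seq.upper()))
    return [
        SegmentSet(round_index=r, segments=[s for _, s in sorted(rows)])
        for r, rows in sorted(rounds.items())
    ]


def write_whitelist(whitelist: BarcodeWhitelist, path: str) -> None:
    from .io import _open_maybe_gzip

    with _open_maybe_gzip(path, "wt") as fh:
        for bc in whitelist.barcodes:
            fh.write(bc + "\n")


def read_whitelist(path: str) -> BarcodeWhitelist:
    from .io import _open_maybe_gzip

    with _open_maybe_gzip(path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    return BarcodeWhitelist(barcodes)
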