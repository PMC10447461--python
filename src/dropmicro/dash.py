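"""Cas9 sgRNA pool design against rRNA-derived cDNA and in-silico digestion.

Guides are enumerated as every N20-NGG protospacer window on either strand of
the target cDNA duplex, with the canonical blunt cut 3 bp 5' of the PAM
(between protospacer positions 17 and 18).  Filtering removes extreme GC,
long homopolymers (including TTTT, which terminates T7 transcription), and
spacers whose 12-nt PAM-proximal seed + NGG occurs in the non-rRNA off-target
index.  Selected guides tile each target greedily so consecutive cut sites
stay within ``max_gap`` wherever candidates permit.  Digestion is binary: any
full protospacer+PAM match between a molecule's adapters abolishes
re-amplification, so for an initial rRNA fraction r and a depleted fraction d
of rRNA molecules the post-depletion composition is
r(1-d) / (r(1-d) + (1-r)).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from ._util import gc_fraction, max_homopolymer_run, revcomp
from .io import SeqRead

SPACER_LENGTH = 20
PAM = re.compile(r"[ACGT]GG")
SEED_LENGTH = 12  # PAM-proximal seed used for off-target screening
CUT_OFFSET = 17  # blunt cut after protospacer position 17 (3 bp 5' of PAM)

DEFAULT_T7_PROMOTER = "TAATACGACTCACTATAG"
# synthetic stand-in for an sgRNA scaffold; real pools supply their own
DEFAULT_SCAFFOLD = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTG"
    "GCACCGAGTCGGTGCTTTTTTT"
)


@dataclass
class GuideCandidate:
    spacer: str
    pam: str
    target_gene: str
    strand: str  # strand of the cDNA duplex carrying the protospacer
    cut_position: int  # 1-based target coordinate of the base 5' of the cut
    gc_fraction: float
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.spacer) != SPACER_LENGTH:
            raise ValueError("spacer must be 20 nt")
        if not PAM.fullmatch(self.pam):
            raise ValueError("PAM must match NGG")

    @property
    def seed(self) -> str:
        return self.spacer[-SEED_LENGTH:]


@dataclass
class GuideSet:
    selected: list[GuideCandidate]
    max_gap: int
    uncovered: list[tuple[str, int, int]] = field(default_factory=list)

    def per_gene(self) -> dict[str, list[GuideCandidate]]:
        out: dict[str, list[GuideCandidate]] = {}
        for g in self.selected:
            out.setdefault(g.target_gene, []).append(g)
        for guides in out.values():
            guides.sort(key=lambda g: g.cut_position)
        return out

    def protospacer_patterns(self) -> set[str]:
        """Full protospacer+PAM 23-mers (both orientations) for digestion."""
        pats = set()
        for g in self.selected:
            site = g.spacer + g.pam
            pats.add(site)
            pats.add(revcomp(site))
        return pats


def enumerate_guides(targets: dict[str, str]) -> list[GuideCandidate]:
    """Every N20-NGG window on either strand of each target sequence.

    Targets shorter than 23 nt yield nothing.  Cut positions are reported in
    forward-strand coordinates of the target and always lie inside it.
    """
    candidates: list[GuideCandidate] = []
    for gene, seq in targets.items():
        seq = seq.upper()
        n = len(seq)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for i in range(n - SPACER_LENGTH - 3 + 1):
                pam = s[i + SPACER_LENGTH : i + SPACER_LENGTH + 3]
                if not PAM.fullmatch(pam):
                    continue
                spacer = s[i : i + SPACER_LENGTH]
                if set(spacer + pam) - set("ACGT"):
                    continue
                cut_local = i + CUT_OFFSET  # 1-based on the scanned strand
                cut = cut_local if strand == "+" else n - cut_local
                if not 1 <= cut < n:
                    continue
                candidates.append(
                    GuideCandidate(
                        spacer=spacer,
                        pam=pam,
                        target_gene=gene,
                        strand=strand,
                        cut_position=cut,
                        gc_fraction=gc_fraction(spacer),
                    )
                )
    return candidates


def build_offtarget_index(sequences: dict[str, str] | list[str]) -> set[str]:
    """12-nt seeds adjacent to an NGG in the off-target (non-rRNA) sequence
    set, both strands.  A guide whose seed is in this set is discarded."""
    if isinstance(sequences, dict):
        sequences = list(sequences.values())
    index: set[str] = set()
    for seq in sequences:
        seq = seq.upper()
        for s in (seq, revcomp(seq)):
            for m in re.finditer(r"(?=([ACGT]GG))", s):
                i = m.start()
                if i >= SEED_LENGTH:
                    index.add(s[i - SEED_LENGTH : i])
    return index


def filter_guides(
    candidates: list[GuideCandidate],
    gc_range: tuple[float, float] = (0.30, 0.70),
    max_homopolymer: int = 4,
    offtarget_index: set[str] | None = None,
) -> list[GuideCandidate]:
    """Flag and drop candidates with extreme GC, long homopolymers (TTTT is
    always excluded: it terminates T7 transcription), or off-target seeds."""
    kept: list[GuideCandidate] = []
    for cand in candidates:
        flags = set()
        if not gc_range[0] <= cand.gc_fraction <= gc_range[1]:
            flags.add("gc")
        if max_homopolymer_run(cand.spacer) > max_homopolymer or "TTTT" in cand.spacer:
            flags.add("homopolymer")
        if offtarget_index is not None and cand.seed in offtarget_index:
            flags.add("off_target")
        cand.flags = flags
        if not flags:
            kept.append(cand)
    return kept


def tile_guides(
    candidates: list[GuideCandidate],
    max_gap: int = 50,
    target_lengths: dict[str, int] | None = None,
) -> GuideSet:
    """Greedy left-to-right interval cover per target gene.

    From the last covered position, always select the rightmost candidate
    whose cut site is within ``max_gap`` (the standard greedy argument makes
    this selection minimal among feasible covers); where no candidate falls
    in the window, the gap is recorded as an uncovered interval and tiling
    resumes at the next candidate.
    """
    selected: list[GuideCandidate] = []
    uncovered: list[tuple[str, int, int]] = []
    by_gene: dict[str, list[GuideCandidate]] = {}
    for cand in candidates:
        by_gene.setdefault(cand.target_gene, []).append(cand)
    genes = sorted(set(by_gene) | set(target_lengths or {}))
    for gene in genes:
        cands = sorted(
            by_gene.get(gene, []), key=lambda g: (g.cut_position, g.strand, g.spacer)
        )
        if not cands:
            length = (target_lengths or {}).get(gene)
            if length is not None:
                uncovered.append((gene, 1, length))
            continue
        cuts = [g.cut_position for g in cands]
        covered = 0
        i = 0
        taken_cuts: set[int] = set()
        while i < len(cands):
            # rightmost candidate with cut <= covered + max_gap
            j = i
            best = None
            while j < len(cands) and cuts[j] <= covered + max_gap:
                if cuts[j] not in taken_cuts and cuts[j] > covered:
                    best = j
                j += 1
            if best is None:
                # gap: no candidate in the window; jump to the next cut
                nxt = next((k for k in range(i, len(cands)) if cuts[k] > covered), None)
                if nxt is None:
                    break
                uncovered.append((gene, covered + 1, cuts[nxt] - 1))
                covered = cuts[nxt] - max_gap  # allow the next pick
                continue
            selected.append(cands[best])
            taken_cuts.add(cuts[best])
            covered = cuts[best]
            i = best + 1
        length = (target_lengths or {}).get(gene)
        if length is not None and covered + max_gap < length:
            uncovered.append((gene, covered + 1, length))
    return GuideSet(selected=selected, max_gap=max_gap, uncovered=uncovered)


@dataclass
class Amplicon:
    """A library molecule: adapter + insert + adapter."""

    molecule_id: str
    sequence: str
    is_rrna: bool
    adapter5_len: int = 0
    adapter3_len: int = 0

    @property
    def insert(self) -> str:
        end = len(self.sequence) - self.adapter3_len
        return self.sequence[self.adapter5_len : end]


@dataclass
class DigestReport:
    cut_counts: list[int]
    depleted_fraction_rrna: float
    depleted_fraction_overall: float
    initial_rrna_fraction: float
    observed_post_rrna_fraction: float
    predicted_post_rrna_fraction: float
    surviving_rrna: int
    surviving_non_rrna: int


def predict_post_rrna_fraction(r: float, d: float) -> float:
    """Composition after removing a fraction d of rRNA molecules:
    r(1-d) / (r(1-d) + (1-r)).  Conserves non-rRNA molecules exactly."""
    if not (0.0 <= r <= 1.0 and 0.0 <= d <= 1.0):
        raise ValueError("r and d must be fractions")
    num = r * (1.0 - d)
    denom = num + (1.0 - r)
    return num / denom if denom > 0 else 0.0


def digest_in_silico(
    molecules: list[Amplicon],
    guide_set: GuideSet,
    cutting_efficiency: float = 1.0,
    seed: int = 0,
) -> DigestReport:
    """Predict depletion of a molecule pool by the selected guide pool.

    A molecule is depleted iff at least one selected guide's full
    protospacer+PAM matches between its adapters (any cut separates the two
    primer sites, so the fragment cannot re-amplify).  With
    ``cutting_efficiency`` < 1 each site cuts independently with that
    probability (seeded).
    """
    patterns = guide_set.protospacer_patterns()
    rng = np.random.default_rng(seed)
    cut_counts: list[int] = []
    depleted_flags: list[bool] = []
    for mol in molecules:
        insert = mol.insert
        n_sites = 0
        for pat in patterns:
            pos = insert.find(pat)
            while pos != -1:
                n_sites += 1
                pos = insert.find(pat, pos + 1)
        cut_counts.append(n_sites)
        if cutting_efficiency >= 1.0:
            depleted_flags.append(n_sites > 0)
        else:
            depleted_flags.append(
                bool(n_sites) and rng.random() < 1 - (1 - cutting_efficiency) ** n_sites
            )
    depleted = np.array(depleted_flags)
    is_rrna = np.array([m.is_rrna for m in molecules])
    n = len(molecules)
    n_rrna = int(is_rrna.sum())
    r = n_rrna / n if n else 0.0
    d_rrna = float(depleted[is_rrna].mean()) if n_rrna else 0.0
    surviving_rrna = int((is_rrna & ~depleted).sum())
    surviving_non = int((~is_rrna & ~depleted).sum())
    surviving = surviving_rrna + surviving_non
    return DigestReport(
        cut_counts=cut_counts,
        depleted_fraction_rrna=d_rrna,
        depleted_fraction_overall=float(depleted.mean()) if n else 0.0,
        initial_rrna_fraction=r,
        observed_post_rrna_fraction=surviving_rrna / surviving if surviving else 0.0,
        predicted_post_rrna_fraction=predict_post_rrna_fraction(r, d_rrna),
        surviving_rrna=surviving_rrna,
        surviving_non_rrna=surviving_non,
    )


def emit_templates(
    guide_set: GuideSet,
    t7_promoter: str = DEFAULT_T7_PROMOTER,
    scaffold: str = DEFAULT_SCAFFOLD,
) -> list[SeqRead]:
    """In-vitro-transcription DNA templates: promoter + spacer + scaffold,
    with a 5' G prepended when the spacer does not start with G (T7
    initiation requirement)."""
    templates = []
    for k, g in enumerate(guide_set.selected):
        spacer = g.spacer if g.spacer.startswith("G") else "G" + g.spacer
        templates.append(
            SeqRead(
                f"sgRNA_{g.target_gene}_{g.cut_position:05d}_{k}",
                t7_promoter + spacer + scaffold,
            )
        )
    return templates


def parse_templates(
    records: list[SeqRead],
    t7_promoter: str = DEFAULT_T7_PROMOTER,
    scaffold: str = DEFAULT_SCAFFOLD,
) -> list[str]:
    """Recover spacers from emitted templates (inverse of emit_templates,
    up to the prepended initiation G)."""
    spacers = []
    for rec in records:
        seq = rec.sequence
        if not (seq.startswith(t7_promoter) and seq.endswith(scaffold)):
            raise ValueError(f"{rec.id}: not a promoter+spacer+scaffold template")
        core = seq[len(t7_promoter) : len(seq) - len(scaffold)]
        if len(core) == SPACER_LENGTH + 1 and core.startswith("G"):
            core = core[1:]
        spacers.append(core)
    return spacers
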