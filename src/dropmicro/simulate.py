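"""Read-level simulator for the droplet single-microbe library chemistry.

The generator emulates what the wet protocol produces: random-primer capture
of total RNA (rRNA-dominated, ~83% of captured molecules by default), in-situ
cDNA synthesis with a 5'->3' positional bias, dA tailing, droplet barcoding
against a split-pool whitelist with Poisson co-encapsulation (doublets),
PCR duplication of UMIs, and uniform substitution errors on the sequenced
barcode.  Every emitted read carries ground truth (cell, species, gene, UMI,
capture position) plus a "perfect aligner" record, so each downstream stage
can be verified exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import DNA, random_dna
from .barcodes import BarcodeWhitelist, BeadPrimerDesign, build_whitelist
from .errors import CapacityError
from .io import BIOTYPES, GeneModel, SeqRead, write_fastq

# share of captured non-rRNA molecules per class, roughly what bacterial
# total-RNA libraries show once rRNA is accounted separately
DEFAULT_NON_RRNA_WEIGHTS = {"mRNA": 0.80, "tRNA": 0.15, "ncRNA": 0.05}


@dataclass
class SpeciesProfile:
    """One species' transcriptome as seen by the capture chemistry.

    ``gene_abundance`` is normalised *within* each biotype class;
    ``rrna_read_fraction`` sets the share of captured molecules that are
    rRNA-derived (0.83 by default, the pre-depletion regime), and the
    remaining mass is split across mRNA/tRNA/ncRNA by
    ``non_rrna_biotype_weights``.
    """

    name: str
    genes: list[GeneModel]
    gene_abundance: np.ndarray
    rrna_read_fraction: float = 0.83
    non_rrna_biotype_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NON_RRNA_WEIGHTS)
    )

    def __post_init__(self) -> None:
        self.gene_abundance = np.asarray(self.gene_abundance, dtype=float)
        if len(self.gene_abundance) != len(self.genes):
            raise ValueError("one abundance per gene required")
        if (self.gene_abundance < 0).any():
            raise ValueError("abundances must be non-negative")
        if not 0.0 <= self.rrna_read_fraction <= 1.0:
            raise ValueError("rrna_read_fraction must be in [0, 1]")
        for gene in self.genes:
            if gene.sequence is None or len(gene.sequence) != gene.length:
                raise ValueError(
                    f"gene {gene.gene_id}: simulator needs a transcript "
                    "sequence matching the annotated length"
                )
        # normalise within biotype classes
        for biotype in BIOTYPES:
            idx = [i for i, g in enumerate(self.genes) if g.biotype == biotype]
            total = self.gene_abundance[idx].sum()
            if total > 0:
                self.gene_abundance[idx] /= total

    def molecule_gene_probs(self) -> np.ndarray:
        """Per-gene molecule capture probabilities (biotype mass times
        within-class abundance)."""
        probs = np.zeros(len(self.genes))
        biotypes = np.array([g.biotype for g in self.genes])
        present_non_rrna = [
            b for b in BIOTYPES if b != "rRNA" and (biotypes == b).any()
        ]
        has_rrna = (biotypes == "rRNA").any()
        rrna_mass = self.rrna_read_fraction if has_rrna else 0.0
        non_rrna_mass = 1.0 - rrna_mass
        weights = {
            b: self.non_rrna_biotype_weights.get(b, 0.0) for b in present_non_rrna
        }
        wsum = sum(weights.values())
        for biotype in BIOTYPES:
            mask = biotypes == biotype
            if not mask.any():
                continue
            if biotype == "rRNA":
                mass = rrna_mass
            else:
                mass = non_rrna_mass * (weights[biotype] / wsum if wsum else 0.0)
            probs[mask] = mass * self.gene_abundance[mask]
        total = probs.sum()
        if total <= 0:
            raise ValueError(f"species {self.name}: no capturable molecules")
        return probs / total


def make_species_profile(
    name: str,
    seed: int,
    n_mrna: int = 60,
    n_rrna: int = 3,
    n_trna: int = 8,
    n_ncrna: int = 4,
    mrna_length: tuple[int, int] = (400, 1500),
    rrna_length: tuple[int, int] = (1200, 2900),
    small_rna_length: tuple[int, int] = (80, 300),
    rrna_read_fraction: float = 0.83,
    contig: str | None = None,
) -> SpeciesProfile:
    """Generate a synthetic bacterial transcriptome (random sequences laid
    head-to-tail on one contig, log-normal expression within each class)."""
    rng = np.random.default_rng(seed)
    contig = contig or f"{name}_genome"
    genes: list[GeneModel] = []
    pos = 1
    counts = {"mRNA": n_mrna, "rRNA": n_rrna, "tRNA": n_trna, "ncRNA": n_ncrna}
    ranges = {
        "mRNA": mrna_length,
        "rRNA": rrna_length,
        "tRNA": small_rna_length,
        "ncRNA": small_rna_length,
    }
    for biotype in BIOTYPES:
        for i in range(counts[biotype]):
            lo, hi = ranges[biotype]
            length = int(rng.integers(lo, hi + 1))
            seq = random_dna(rng, length)
            genes.append(
                GeneModel(
                    gene_id=f"{name}_{biotype}_{i:03d}",
                    biotype=biotype,
                    contig=contig,
                    start=pos,
                    end=pos + length - 1,
                    strand="+",
                    sequence=seq,
                )
            )
            pos += length + 100  # intergenic gap
    abundance = rng.lognormal(0.0, 1.0, size=len(genes))
    return SpeciesProfile(
        name=name,
        genes=genes,
        gene_abundance=abundance,
        rrna_read_fraction=rrna_read_fraction,
    )


@dataclass
class SimConfig:
    """Study conditions for one simulated library."""

    species: list[SpeciesProfile]
    cells_per_species: list[int]
    loading_lambda: float = 0.1
    umi_per_cell_log_mean: float = math.log(300.0)
    umi_per_cell_log_sigma: float = 0.5
    reads_per_umi_mean: float = 1.5
    insert_length_range: tuple[int, int] = (100, 400)
    coverage_decay: float = 0.003  # geometric rate per nt from the 5' end
    barcode_error_rate: float = 0.0
    r2_handle: str = ""
    r2_polya_tail: int = 8
    r1_length: int = 42
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loading_lambda <= 0:
            raise ValueError("loading_lambda must be > 0")
        if len(self.species) != len(self.cells_per_species):
            raise ValueError("one cell count per species required")
        lo, hi = self.insert_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid insert_length_range")
        if self.r1_length < 38:
            raise ValueError("r1_length must hold UMI (8) + barcode (30)")


def loading_stats(loading_lambda: float) -> dict[str, float]:
    """Poisson droplet-loading fractions.

    empty = e^-lam; singlet = lam e^-lam; multiplet among occupied droplets
    = (1 - e^-lam - lam e^-lam) / (1 - e^-lam).
    """
    lam = loading_lambda
    if lam <= 0:
        raise ValueError("loading rate must be > 0")
    empty = math.exp(-lam)
    singlet = lam * math.exp(-lam)
    occupied = 1.0 - empty
    return {
        "empty_fraction": empty,
        "singlet_fraction": singlet,
        "multiplet_fraction_among_occupied": (occupied - singlet) / occupied,
    }


@dataclass
class SimulatedLibrary:
    """Paired reads plus per-read ground truth and perfect-aligner records."""

    r1: list[SeqRead]
    r2: list[SeqRead]
    truth: pd.DataFrame
    alignments: pd.DataFrame
    barcode_truth: pd.DataFrame
    config: SimConfig
    whitelist: BarcodeWhitelist
    design: BeadPrimerDesign

    @property
    def n_reads(self) -> int:
        return len(self.r1)

    def genes(self) -> list[GeneModel]:
        out: list[GeneModel] = []
        for profile in self.config.species:
            out.extend(profile.genes)
        return out

    def gene_biotypes(self) -> dict[str, str]:
        return {g.gene_id: g.biotype for g in self.genes()}

    def truth_umi_matrix(self):
        """The UMI count matrix implied by ground truth (exact dedup of
        (true barcode, gene, UMI) triples)."""
        from .matrix import UmiCountMatrix

        dedup = self.truth.drop_duplicates(["barcode_true", "gene_id", "umi"])
        counts = dedup.groupby(["barcode_true", "gene_id"]).size()
        return UmiCountMatrix.from_counts(
            {(bc, g): int(v) for (bc, g), v in counts.items()},
            self.gene_biotypes(),
        )

    def write(self, outdir: str, compress: bool = False) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        ext = ".fastq.gz" if compress else ".fastq"
        write_fastq(self.r1, os.path.join(outdir, "R1" + ext))
        write_fastq(self.r2, os.path.join(outdir, "R2" + ext))
        self.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
        self.alignments.to_csv(
            os.path.join(outdir, "alignments.tsv"), sep="\t", index=False
        )
        self.barcode_truth.to_csv(
            os.path.join(outdir, "barcode_truth.tsv"), sep="\t", index=False
        )


def _umi_strings(rng: np.random.Generator, n: int, length: int) -> list[str]:
    idx = rng.integers(0, 4, size=(n, length))
    lut = np.array(list(DNA))
    return ["".join(row) for row in lut[idx]]


def _inject_substitutions(
    rng: np.random.Generator, seq: str, rate: float
) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [b for b in DNA if b != out[i]]
            out[i] = choices[rng.integers(0, 3)]
    return "".join(out)


def simulate_library(
    config: SimConfig,
    design: BeadPrimerDesign | None = None,
    whitelist: BarcodeWhitelist | None = None,
) -> SimulatedLibrary:
    """Generate a full paired library with ground truth.

    Deterministic given ``config.seed``.  Raises :class:`CapacityError` when
    the requested cells outnumber whitelist barcodes.
    """
    rng = np.random.default_rng(config.seed)
    if design is None:
        design = BeadPrimerDesign.toy(seed=config.seed, cardinalities=(24, 24, 12))
    if whitelist is None:
        whitelist = build_whitelist(design)

    # cells, shuffled so doublets mix species at random
    cells: list[tuple[str, int]] = []
    for s_idx, (profile, n_cells) in enumerate(
        zip(config.species, config.cells_per_species)
    ):
        cells.extend((f"{profile.name}_cell{i:05d}", s_idx) for i in range(n_cells))
    order = rng.permutation(len(cells))
    cells = [cells[i] for i in order]

    # droplet occupancy: zero-truncated Poisson, k >= 3 collapsed to 2
    droplets: list[list[tuple[str, int]]] = []
    pos = 0
    while pos < len(cells):
        k = 0
        while k == 0:
            k = int(rng.poisson(config.loading_lambda))
        k = min(k, 2, len(cells) - pos)
        droplets.append(cells[pos : pos + k])
        pos += k
    if len(droplets) > len(whitelist):
        raise CapacityError(
            f"{len(droplets)} occupied droplets exceed the whitelist "
            f"({len(whitelist)} barcodes)"
        )
    droplet_barcodes = whitelist.sample(rng, len(droplets))

    gene_probs = [p.molecule_gene_probs() for p in config.species]
    gene_lengths = [
        np.array([g.length for g in p.genes]) for p in config.species
    ]

    rows: list[tuple] = []  # per-read truth
    r1_list: list[SeqRead] = []
    r2_list: list[SeqRead] = []
    aln_rows: list[tuple] = []
    bc_rows: list[tuple] = []
    read_no = 0
    lo, hi = config.insert_length_range

    for barcode, members in zip(droplet_barcodes, droplets):
        species_names = sorted({config.species[s].name for _, s in members})
        bc_rows.append(
            (
                barcode,
                ";".join(cid for cid, _ in members),
                ";".join(species_names),
                len(members),
                len(members) > 1,
            )
        )
        for cell_id, s_idx in members:
            profile = config.species[s_idx]
            n_umis = max(
                1,
                int(
                    round(
                        rng.lognormal(
                            config.umi_per_cell_log_mean,
                            config.umi_per_cell_log_sigma,
                        )
                    )
                ),
            )
            gidx = rng.choice(len(profile.genes), size=n_umis, p=gene_probs[s_idx])
            lengths = gene_lengths[s_idx][gidx]
            if config.coverage_decay > 0:
                starts = rng.geometric(config.coverage_decay, size=n_umis) - 1
                starts = np.minimum(starts, lengths - 1)
            else:
                starts = (rng.random(n_umis) * lengths).astype(int)
            ilens = rng.integers(lo, hi + 1, size=n_umis)
            # clamp so the full insert fits whenever the transcript allows it
            # (fragments below the library's size selection are not captured)
            starts = np.minimum(starts, np.maximum(lengths - ilens, 0))
            ends = np.minimum(starts + ilens, lengths)
            umis = _umi_strings(rng, n_umis, design.umi_length)
            if config.reads_per_umi_mean > 1.0:
                n_copies = 1 + rng.poisson(
                    config.reads_per_umi_mean - 1.0, size=n_umis
                )
            else:
                n_copies = np.ones(n_umis, dtype=int)
            for m in range(n_umis):
                gene = profile.genes[gidx[m]]
                s, e = int(starts[m]), int(ends[m])
                fragment = gene.sequence[s:e]
                if gene.strand == "+":
                    g_start = gene.start + s
                    g_end = gene.start + e - 1
                else:
                    g_start = gene.end - (e - 1)
                    g_end = gene.end - s
                for _ in range(int(n_copies[m])):
                    read_id = f"read{read_no:08d}"
                    read_no += 1
                    bc_seq = barcode
                    if config.barcode_error_rate > 0:
                        bc_seq = _inject_substitutions(
                            rng, barcode, config.barcode_error_rate
                        )
                    r1_seq = (umis[m] + bc_seq).ljust(config.r1_length, "T")
                    r2_seq = (
                        config.r2_handle + fragment + "A" * config.r2_polya_tail
                    )
                    r1_list.append(SeqRead(read_id, r1_seq, "I" * len(r1_seq)))
                    r2_list.append(SeqRead(read_id, r2_seq, "I" * len(r2_seq)))
                    rows.append(
                        (
                            read_id,
                            barcode,
                            cell_id,
                            profile.name,
                            gene.gene_id,
                            gene.biotype,
                            s,
                            umis[m],
                            False,
                        )
                    )
                    aln_rows.append(
                        (read_id, gene.contig, g_start, g_end, gene.strand, 1)
                    )

    truth = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "barcode_true",
            "cell_id",
            "species",
            "gene_id",
            "biotype",
            "capture_pos",
            "umi",
            "ambient",
        ],
    )
    alignments = pd.DataFrame(
        aln_rows, columns=["read_id", "contig", "start", "end", "strand", "unique"]
    )
    barcode_truth = pd.DataFrame(
        bc_rows, columns=["barcode", "cell_ids", "species_set", "n_cells", "is_doublet"]
    )
    return SimulatedLibrary(
        r1=r1_list,
        r2=r2_list,
        truth=truth,
        alignments=alignments,
        barcode_truth=barcode_truth,
        config=config,
        whitelist=whitelist,
        design=design,
    )


def inject_ambient(
    library: SimulatedLibrary, ambient_rate: float, seed: int = 0
) -> SimulatedLibrary:
    """Re-draw a fraction of each barcode's reads from the pooled cross-cell
    molecule pool (free-floating cDNA picked up by the wrong droplet).

    Replaced reads keep their barcode but take the donor molecule's gene,
    species, UMI, capture position and cDNA sequence; truth is updated and
    the read is flagged ``ambient``.
    """
    if not 0.0 <= ambient_rate < 1.0:
        raise ValueError("ambient_rate must be in [0, 1)")
    if ambient_rate == 0.0 or library.n_reads == 0:
        return library
    rng = np.random.default_rng(seed)
    n = library.n_reads
    swap = np.flatnonzero(rng.random(n) < ambient_rate)
    donors = rng.integers(0, n, size=len(swap))

    truth = library.truth.copy()
    alignments = library.alignments.copy()
    r1 = list(library.r1)
    r2 = list(library.r2)
    design = library.design
    mol_cols = ["cell_id", "species", "gene_id", "biotype", "capture_pos", "umi"]
    aln_cols = ["contig", "start", "end", "strand", "unique"]
    truth_idx = {c: truth.columns.get_loc(c) for c in truth.columns}
    for i, d in zip(swap, donors):
        for c in mol_cols:
            truth.iat[i, truth_idx[c]] = library.truth.iat[d, truth_idx[c]]
        truth.iat[i, truth_idx["ambient"]] = True
        for c in aln_cols:
            alignments.iat[i, alignments.columns.get_loc(c)] = (
                library.alignments.iat[d, alignments.columns.get_loc(c)]
            )
        old_r1 = r1[i]
        raw_barcode = old_r1.sequence[
            design.umi_length : design.umi_length + design.barcode_length
        ]
        donor_umi = library.truth.iat[d, truth_idx["umi"]]
        new_seq = (donor_umi + raw_barcode).ljust(len(old_r1.sequence), "T")
        r1[i] = SeqRead(old_r1.id, new_seq, old_r1.quality)
        r2[i] = SeqRead(r2[i].id, library.r2[d].sequence, library.r2[d].quality)
    return SimulatedLibrary(
        r1=r1,
        r2=r2,
        truth=truth,
        alignments=alignments,
        barcode_truth=library.barcode_truth,
        config=library.config,
        whitelist=library.whitelist,
        design=library.design,
    )
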