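"""Library-quality metrics: species mixing (barnyard), sequencing saturation,
gene-body coverage, and pseudo-bulk correlation.

These are the read-out side of the validation experiments: a two-species mix
exposes droplet doublets and ambient contamination; subsampling reads maps
detected genes against depth; transcript-percentile coverage shows the 5'->3'
capture decay of random-primed cDNA synthesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .errors import InsufficientDataError
from .io import GeneModel
from .matrix import UmiCountMatrix

# subsampling depths (reads per cell) used for the saturation curve
DEFAULT_SATURATION_DEPTHS = (1000, 2000, 4000, 9000, 13000, 18000, 22000)


@dataclass
class BarnyardReport:
    per_barcode: pd.DataFrame  # barcode, per-species UMIs, major, minor_fraction, label
    species_counts: dict[str, int]
    mixed_count: int
    doublet_rate: float
    specificity: dict[str, float]

    @property
    def total_labelled(self) -> int:
        return int(len(self.per_barcode))


def barnyard(
    matrix: UmiCountMatrix,
    species_of_gene: dict[str, str],
    min_umis: int = 10,
    mixed_threshold: float = 0.2,
) -> BarnyardReport:
    """Label each called-cell barcode by species and measure doublets.

    A barcode is "mixed" iff its minor-species UMI fraction is
    >= ``mixed_threshold`` *and* its two top species both have
    >= ``min_umis`` UMIs; otherwise it takes its majority species.
    doublet_rate = mixed / total labelled barcodes.  Specificity per species
    is the median, over that species' singlets, of the fraction of UMIs from
    the assigned species.
    """
    species = sorted(set(species_of_gene.values()))
    if len(species) < 2:
        raise InsufficientDataError("barnyard needs >= 2 species")
    per_species = np.zeros((matrix.shape[0], len(species)))
    s_idx = {s: j for j, s in enumerate(species)}
    gene_species = np.array(
        [s_idx.get(species_of_gene.get(g, ""), -1) for g in matrix.genes]
    )
    dense = matrix.counts.toarray()
    for j, s in enumerate(species):
        per_species[:, j] = dense[:, gene_species == j].sum(axis=1)

    totals = per_species.sum(axis=1)
    order = np.argsort(per_species, axis=1)
    top = order[:, -1]
    second = order[:, -2]
    top_counts = per_species[np.arange(len(totals)), top]
    second_counts = per_species[np.arange(len(totals)), second]
    with np.errstate(invalid="ignore", divide="ignore"):
        minor_fraction = np.where(totals > 0, 1.0 - top_counts / totals, 0.0)
        second_fraction = np.where(totals > 0, second_counts / totals, 0.0)
    mixed = (
        (second_fraction >= mixed_threshold)
        & (top_counts >= min_umis)
        & (second_counts >= min_umis)
    )
    labels = np.where(mixed, "mixed", np.array(species)[top])
    per_barcode = pd.DataFrame(
        {
            "barcode": matrix.barcodes,
            **{f"umis_{s}": per_species[:, j] for j, s in enumerate(species)},
            "total_umis": totals,
            "major_species": np.array(species)[top],
            "minor_fraction": minor_fraction,
            "label": labels,
        }
    )
    mixed_count = int(mixed.sum())
    species_counts = {
        s: int((labels == s).sum()) for s in species
    }
    specificity = {}
    for s in species:
        own = per_barcode.loc[per_barcode["label"] == s]
        frac = own[f"umis_{s}"] / own["total_umis"].replace(0, np.nan)
        specificity[s] = float(frac.median()) if len(own) else float("nan")
    total = len(per_barcode)
    return BarnyardReport(
        per_barcode=per_barcode,
        species_counts=species_counts,
        mixed_count=mixed_count,
        doublet_rate=mixed_count / total if total else 0.0,
        specificity=specificity,
    )


@dataclass
class SaturationCurve:
    depths: list[int]
    median_genes: list[float]  # NaN where the depth is unattainable
    median_umis: list[float] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth": self.depths,
                "median_genes": self.median_genes,
                "median_umis": self.median_umis or np.nan,
            }
        )


def saturation(
    tagged: pd.DataFrame,
    cell_barcodes: list[str],
    depths: tuple[int, ...] = DEFAULT_SATURATION_DEPTHS,
    seed: int = 0,
) -> SaturationCurve:
    """Median detected genes per cell at each subsampled depth.

    ``tagged`` holds gene-assigned reads (barcode, umi, gene_id); at each
    depth d the table is subsampled without replacement to d * n_cells reads
    over the whole library, UMIs are deduplicated exactly, and the median
    distinct-gene count over ``cell_barcodes`` is recorded.  Depths beyond
    the library size are marked unattainable (NaN), not an error.
    """
    depths = tuple(sorted(depths))
    rng = np.random.default_rng(seed)
    n_cells = len(cell_barcodes)
    if n_cells == 0:
        raise InsufficientDataError("no cells for saturation analysis")
    cells = pd.Index(cell_barcodes)
    med_genes: list[float] = []
    med_umis: list[float] = []
    for depth in depths:
        target = depth * n_cells
        if depth == 0:
            med_genes.append(0.0)
            med_umis.append(0.0)
            continue
        if target > len(tagged):
            med_genes.append(float("nan"))
            med_umis.append(float("nan"))
            continue
        idx = rng.choice(len(tagged), size=target, replace=False)
        sub = tagged.iloc[idx]
        sub = sub[sub["barcode"].isin(cells)]
        dedup = sub.drop_duplicates(["barcode", "gene_id", "umi"])
        genes_per_cell = (
            dedup.groupby("barcode")["gene_id"].nunique().reindex(cells, fill_value=0)
        )
        umis_per_cell = (
            dedup.groupby("barcode").size().reindex(cells, fill_value=0)
        )
        med_genes.append(float(genes_per_cell.median()))
        med_umis.append(float(umis_per_cell.median()))
    return SaturationCurve(list(depths), med_genes, med_umis)


def gene_body_coverage(
    alignments: pd.DataFrame,
    genes: list[GeneModel],
    min_length: int = 100,
    n_bins: int = 100,
) -> np.ndarray:
    """Mean transcript coverage across 100 percentile bins, 5'->3'.

    Per qualifying gene (length >= ``min_length``) the per-base coverage from
    overlapping alignments is averaged into ``n_bins`` equal percentile bins,
    oriented 5'->3' by gene strand; bin profiles are summed across genes and
    normalised so the maximum bin equals 1.
    """
    qualifying = [g for g in genes if g.length >= min_length]
    if not qualifying:
        raise InsufficientDataError("no transcripts of sufficient length")
    by_contig: dict[str, pd.DataFrame] = {
        str(c): df for c, df in alignments.groupby("contig")
    }
    profile = np.zeros(n_bins)
    for gene in qualifying:
        reads = by_contig.get(gene.contig)
        cov = np.zeros(gene.length)
        if reads is not None:
            starts = np.maximum(reads["start"].to_numpy(), gene.start) - gene.start
            ends = np.minimum(reads["end"].to_numpy(), gene.end) - gene.start + 1
            keep = starts < ends
            for s, e in zip(starts[keep], ends[keep]):
                cov[s:e] += 1
        if gene.strand == "-":
            cov = cov[::-1]
        bins = (np.arange(gene.length) * n_bins) // gene.length
        binned = np.bincount(bins, weights=cov, minlength=n_bins)
        base_per_bin = np.bincount(bins, minlength=n_bins)
        profile += binned / np.maximum(base_per_bin, 1)
    peak = profile.max()
    if peak <= 0:
        raise InsufficientDataError("no coverage on qualifying transcripts")
    return profile / peak


def pseudobulk_correlation(
    matrix_a: UmiCountMatrix,
    matrix_b: UmiCountMatrix,
    cells_a: list[str] | None = None,
    cells_b: list[str] | None = None,
) -> float:
    """Pearson r of per-gene log10(count + 1) pseudo-bulk profiles.

    Gene universes are outer-joined (missing = 0); counts are summed over
    called cells only when cell lists are given.
    """
    if cells_a is not None:
        matrix_a = matrix_a.subset_barcodes(cells_a)
    if cells_b is not None:
        matrix_b = matrix_b.subset_barcodes(cells_b)
    sums_a = matrix_a.gene_totals()
    sums_b = matrix_b.gene_totals()
    universe = sorted(set(sums_a.index) | set(sums_b.index))
    if len(universe) < 3:
        raise InsufficientDataError("fewer than 3 genes in the shared universe")
    a = np.log10(sums_a.reindex(universe, fill_value=0).to_numpy() + 1.0)
    b = np.log10(sums_b.reindex(universe, fill_value=0).to_numpy() + 1.0)
    r, _ = pearsonr(a, b)
    return float(r)
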