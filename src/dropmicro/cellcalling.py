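"""Putative-cell identification: barcode rank plot, simple knee, and an
EmptyDrops-like Monte-Carlo rescue of genuine small cells.

The primary call thresholds the barcode rank plot: the knee threshold is the
``maxPercentile`` quantile of the top ``nExpectedCells`` barcodes divided by
``maxMinRatio``.  Barcodes below the knee but with enough UMIs are then tested
against an ambient profile (pooled counts of barcodes ranked in
``(indMin, indMax]``): each candidate's multinomial log-likelihood under the
ambient profile is compared with ``simN`` simulated draws of the same total,
the Monte-Carlo p-value gets a +1 correction (never exactly 0), and
Benjamini-Hochberg q-values <= FDR rescue the barcode.  The ten parameters and
their defaults follow the published pipeline configuration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError
from .matrix import UmiCountMatrix

logger = logging.getLogger("dropmicro")


@dataclass
class KneeParams:
    """The ten numeric cell-calling parameters (published defaults)."""

    n_expected_cells: int = 1500
    max_percentile: float = 0.99
    max_min_ratio: float = 10.0
    ind_min: int = 45000
    ind_max: int = 90000
    umi_min: int = 300
    umi_min_frac_median: float = 0.01
    cand_max_n: int = 20000
    fdr: float = 0.01
    sim_n: int = 10000

    def __post_init__(self) -> None:
        if self.ind_min >= self.ind_max:
            raise ValueError("ind_min must be < ind_max")
        if not 0.0 < self.max_percentile <= 1.0:
            raise ValueError("max_percentile must be in (0, 1]")
        for name in ("n_expected_cells", "max_min_ratio", "umi_min",
                     "cand_max_n", "sim_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CellCallResult:
    """Labels partition all barcodes into cell / rescued_cell / background."""

    table: pd.DataFrame  # barcode, rank, genes, umis, label, pvalue, qvalue
    knee_threshold: float
    knee_index: int
    params: KneeParams
    ambient_profile: np.ndarray | None = None

    def cells(self) -> list[str]:
        keep = self.table["label"].isin(["cell", "rescued_cell"])
        return self.table.loc[keep, "barcode"].tolist()


def rank_plot(matrix: UmiCountMatrix, metric: str = "genes") -> pd.DataFrame:
    """Order barcodes by the calling metric, descending.

    ``metric`` is "genes" (total detected genes per barcode, the published
    ranking) or "umis".  Ties break by the other metric then lexicographic
    barcode, so the ordering is deterministic.
    """
    if metric not in ("genes", "umis"):
        raise ValueError("metric must be 'genes' or 'umis'")
    if matrix.shape[0] == 0:
        raise InsufficientDataError("empty matrix")
    df = matrix.barcode_summary()
    secondary = "umis" if metric == "genes" else "genes"
    df = df.sort_values(
        [metric, secondary, "barcode"], ascending=[False, False, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["metric"] = df[metric]
    return df[["rank", "barcode", "genes", "umis", "metric"]]


def simple_knee(
    series: pd.DataFrame, params: KneeParams
) -> tuple[float, list[str]]:
    """Knee threshold = quantile(maxPercentile) of the top nExpectedCells
    metrics, divided by maxMinRatio; returns (threshold, barcodes >= it)."""
    if len(series) < 10:
        raise InsufficientDataError("insufficient_barcodes")
    top = series["metric"].to_numpy()[: params.n_expected_cells]
    threshold = float(np.quantile(top, params.max_percentile)) / params.max_min_ratio
    above = series.loc[series["metric"] >= threshold, "barcode"].tolist()
    return threshold, above


def _multinomial_loglik(counts: np.ndarray, log_p: np.ndarray) -> float:
    n = counts.sum()
    return float(
        gammaln(n + 1) - gammaln(counts + 1).sum() + (counts * log_p).sum()
    )


def empty_drops_rescue(
    matrix: UmiCountMatrix,
    series: pd.DataFrame,
    params: KneeParams,
    seed: int = 0,
    metric: str = "genes",
) -> CellCallResult:
    """Full calling: simple knee plus Monte-Carlo ambient-profile rescue.

    Deterministic given (matrix, params, seed).  With fewer than 100 barcodes
    in the ambient rank window the rescue is skipped (knee-only calling, with
    a warning), matching the degenerate-input contract.
    """
    threshold, knee_cells = simple_knee(series, params)
    knee_set = set(knee_cells)
    knee_index = len(knee_cells)
    table = series.copy()
    table["label"] = np.where(
        table["barcode"].isin(knee_set), "cell", "background"
    )
    table["pvalue"] = np.nan
    table["qvalue"] = np.nan

    window = table[(table["rank"] > params.ind_min) & (table["rank"] <= params.ind_max)]
    if len(window) < 100:
        warnings.warn(
            f"only {len(window)} barcodes in the ambient rank window "
            f"({params.ind_min}, {params.ind_max}]; falling back to knee-only "
            "calling",
            stacklevel=2,
        )
        return CellCallResult(table, threshold, knee_index, params)

    bc_row = {b: i for i, b in enumerate(matrix.barcodes)}
    ambient_rows = [bc_row[b] for b in window["barcode"]]
    ambient = np.asarray(matrix.counts[ambient_rows].sum(axis=0)).ravel().astype(float)
    ambient += 1e-8  # pseudocount: no -inf on genes unseen in ambient
    ambient_p = ambient / ambient.sum()
    log_p = np.log(ambient_p)

    umis = matrix.umis_per_barcode()
    knee_umis = np.array([umis[bc_row[b]] for b in knee_cells]) if knee_cells else np.array([0.0])
    umi_floor = max(params.umi_min, params.umi_min_frac_median * float(np.median(knee_umis)))
    cand_mask = (~table["barcode"].isin(knee_set)) & (
        table["barcode"].map(lambda b: umis[bc_row[b]]) >= umi_floor
    )
    candidates = table.loc[cand_mask].nsmallest(params.cand_max_n, "rank")

    rng = np.random.default_rng(seed)
    sim_cache: dict[int, np.ndarray] = {}
    pvals = np.empty(len(candidates))
    for k, (_, row) in enumerate(candidates.iterrows()):
        obs = np.asarray(matrix.counts[bc_row[row["barcode"]]].todense()).ravel()
        total = int(obs.sum())
        ll_obs = _multinomial_loglik(obs, log_p)
        if total not in sim_cache:
            draws = rng.multinomial(total, ambient_p, size=params.sim_n)
            ll = (
                gammaln(total + 1)
                - gammaln(draws + 1).sum(axis=1)
                + draws @ log_p
            )
            sim_cache[total] = ll
        ll_sim = sim_cache[total]
        pvals[k] = (1 + int((ll_sim <= ll_obs).sum())) / (params.sim_n + 1)

    if len(candidates):
        rejected, qvals, _, _ = multipletests(pvals, alpha=params.fdr, method="fdr_bh")
        idx = candidates.index
        table.loc[idx, "pvalue"] = pvals
        table.loc[idx, "qvalue"] = qvals
        table.loc[idx[rejected & (qvals <= params.fdr)], "label"] = "rescued_cell"
    logger.info(
        "cell calling: %d knee cells, %d candidates, %d rescued",
        knee_index,
        len(candidates),
        int((table["label"] == "rescued_cell").sum()),
    )
    return CellCallResult(table, threshold, knee_index, params, ambient_p)


def plot_rank(result: CellCallResult, path: str) -> None:
    """log10 metric vs log10 rank with the knee threshold as a dashed line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = result.table
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(np.log10(t["rank"]), np.log10(t["metric"].clip(lower=1)), lw=1)
    ax.axhline(np.log10(max(result.knee_threshold, 1)), color="red", ls="--", lw=1)
    ax.set_xlabel("log10 barcode rank")
    ax.set_ylabel("log10 metric")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
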