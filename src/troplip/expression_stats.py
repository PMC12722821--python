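"""Per-cluster CPM summaries and the percentile-based expression comparisons.

For every cluster × condition stratum we report, per gene, the fraction of
cells with detectable expression (raw count > 0), the median CPM and the
95th-percentile CPM, with zeros included.  High-expressor comparisons pick
the cells of a cluster whose CPM lies strictly above the gene's *global*
(conditions pooled) 95th percentile and compare conditions by one-way
ANOVA.  The dot-plot matrix is the log2 ratio of case over control
95th-percentile CPM per gene × cluster.

Percentiles use linear interpolation between closest ranks (the numpy
default); the convention is configurable via ``method``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .errors import DataError
from .io_formats import CellDataset


def compute_cpm(dataset: CellDataset) -> np.ndarray:
    """Counts-per-million per cell: each column rescaled to sum to 1e6.

    Returns a dense gene × cell float array.  Cells with zero total counts
    make CPM undefined and raise :class:`DataError` listing the cell ids.
    """
    totals = np.asarray(dataset.counts.sum(axis=0)).ravel().astype(float)
    zero = totals == 0
    if zero.any():
        ids = list(dataset.cell_meta.loc[zero, "cell_id"])
        raise DataError(f"cells with zero total counts: {ids}")
    return dataset.counts.toarray() / totals[None, :] * 1e6


@dataclass
class ClusterGroupSummary:
    """Long-format per (gene, cluster, condition) summary table."""

    table: pd.DataFrame   # gene, cluster, condition, n_cells,
                          # detect_frac, median_cpm, p95_cpm


def summarize_cluster_groups(
    dataset: CellDataset,
    cpm: np.ndarray,
    percentile: float = 95.0,
    method: str = "linear",
) -> ClusterGroupSummary:
    """Detection fraction, median and upper-percentile CPM per stratum."""
    meta = dataset.cell_meta
    rows = []
    for (cluster, condition), idx in meta.groupby(
        ["cluster", "condition"], sort=True
    ).groups.items():
        cols = np.asarray(idx)
        if cols.size == 0:
            raise DataError(f"empty stratum ({cluster}, {condition})")
        sub = cpm[:, cols]
        raw = dataset.counts[:, cols]
        detect = np.asarray((raw > 0).sum(axis=1)).ravel() / cols.size
        med = np.median(sub, axis=1)
        p95 = np.percentile(sub, percentile, axis=1, method=method)
        rows.append(pd.DataFrame({
            "gene": dataset.gene_ids,
            "cluster": cluster,
            "condition": condition,
            "n_cells": cols.size,
            "detect_frac": detect,
            "median_cpm": med,
            "p95_cpm": p95,
        }))
    return ClusterGroupSummary(pd.concat(rows, ignore_index=True))


def select_high_expressors(
    dataset: CellDataset,
    cpm: np.ndarray,
    gene: str,
    cluster: str,
    percentile: float = 95.0,
    method: str = "linear",
    pooled: bool = True,
) -> tuple[float, pd.DataFrame]:
    """Cells of ``cluster`` with CPM strictly above the gene's percentile.

    The threshold is the 95th percentile over all cells of the cluster with
    conditions pooled ("global"); with ``pooled=False`` it is computed on
    control cells only (first condition in sorted order) as an alternative
    reading.  Returns ``(threshold, subset)`` where ``subset`` carries the
    cell metadata plus a ``cpm`` column; it may be empty.
    """
    if gene not in dataset.gene_ids:
        raise DataError(f"unknown gene {gene!r}")
    gi = dataset.gene_ids.index(gene)
    mask = (dataset.cell_meta["cluster"] == cluster).to_numpy()
    if not mask.any():
        raise DataError(f"cluster {cluster!r} has no cells")
    values = cpm[gi, mask]
    if pooled:
        threshold = float(np.percentile(values, percentile, method=method))
    else:
        conds = sorted(dataset.cell_meta.loc[mask, "condition"].unique())
        ref = (dataset.cell_meta["condition"] == conds[0]).to_numpy() & mask
        threshold = float(np.percentile(cpm[gi, ref], percentile, method=method))
    sel = mask & (cpm[gi] > threshold)
    subset = dataset.cell_meta[sel].copy()
    subset["cpm"] = cpm[gi, sel]
    return threshold, subset


def anova_high_expressors(
    values: np.ndarray,
    condition: np.ndarray,
    log1p: bool = False,
) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of CPM values across condition groups.

    Returns ``(F, p)``; ``(nan, nan)`` flags an untestable stratum (fewer
    than two conditions, or any condition with fewer than two cells).
    All-constant input yields ``F = 0, p = 1``.
    """
    values = np.asarray(values, dtype=float)
    if log1p:
        values = np.log1p(values)
    condition = np.asarray(condition)
    groups = [values[condition == c] for c in pd.unique(condition)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        return float("nan"), float("nan")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    f, p = scipy.stats.f_oneway(*groups)
    return float(f), float(p)


def high_expressor_anova_table(
    dataset: CellDataset,
    cpm: np.ndarray,
    genes: list[str] | None = None,
    percentile: float = 95.0,
    log1p: bool = False,
) -> pd.DataFrame:
    """Run the high-expressor ANOVA for each (gene, cluster) pair."""
    genes = genes if genes is not None else dataset.gene_ids
    rows = []
    for cluster in sorted(dataset.cell_meta["cluster"].unique()):
        for gene in genes:
            threshold, subset = select_high_expressors(
                dataset, cpm, gene, cluster, percentile=percentile
            )
            f, p = anova_high_expressors(
                subset["cpm"].to_numpy(), subset["condition"].to_numpy(),
                log1p=log1p,
            )
            counts = subset["condition"].value_counts().to_dict()
            rows.append({
                "gene": gene, "cluster": cluster,
                "threshold_cpm": threshold,
                "n_selected": len(subset),
                "n_per_condition": ";".join(
                    f"{c}={counts.get(c, 0)}"
                    for c in sorted(dataset.cell_meta["condition"].unique())
                ),
                "F": f, "p": p,
            })
    return pd.DataFrame(rows)


@dataclass
class DotplotMatrix:
    """log2 p95-CPM ratios (case/control) with the control level as dot size."""

    log2fc: pd.DataFrame        # genes × clusters; NaN where undefined
    control_p95: pd.DataFrame   # genes × clusters


def dotplot_log2fc(
    summary: ClusterGroupSummary, case: str, control: str
) -> DotplotMatrix:
    """Per gene × cluster log2(p95 case / p95 control); NaN when either is 0."""
    tab = summary.table
    for cond in (case, control):
        if cond not in set(tab["condition"]):
            raise DataError(f"condition {cond!r} not present in summary")
    case_p = tab[tab["condition"] == case].pivot(
        index="gene", columns="cluster", values="p95_cpm")
    ctrl_p = tab[tab["condition"] == control].pivot(
        index="gene", columns="cluster", values="p95_cpm")
    case_p, ctrl_p = case_p.align(ctrl_p, join="outer")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(case_p.to_numpy() / ctrl_p.to_numpy())
    ratio[(case_p.to_numpy() <= 0) | (ctrl_p.to_numpy() <= 0)] = np.nan
    log2fc = pd.DataFrame(ratio, index=case_p.index, columns=case_p.columns)
    return DotplotMatrix(log2fc, ctrl_p)
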