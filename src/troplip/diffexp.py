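"""Differential expression at two granularities, plus bulk normalization.

Per-cell DE uses the Mann–Whitney U test on CPM values within a cluster
(exact enumeration for tiny groups, tie-corrected normal approximation with
continuity correction otherwise) with Benjamini–Hochberg correction across
genes.

Replicate-level DE — for pseudobulk aggregates of the single-cell data and
for bulk counts — fits, per gene, a negative-binomial GLM with log link,
median-of-ratios size factors as offsets and a single condition coefficient,
and reports the Wald statistic of that coefficient.  This is a deliberately
lean NB-Wald stage: gene-wise method-of-moments dispersions shrunk toward a
mean–dispersion trend, no outlier replacement, no independent filtering, no
fold-change shrinkage.  The Wald z doubles as the GSEA ranking metric.

Bulk normalization follows the trimmed-mean-of-M-values (TMM) recipe:
double-trimmed (30% on M, 5% on A, each tail), precision-weighted mean of
log ratios against an upper-quartile-matched reference, factors rescaled to
geometric mean 1.  FPKM uses TMM-effective library sizes, and the
low-expression filter drops genes whose median FPKM sits in the bottom
quartile of every experimental group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .errors import DataError
from .io_formats import BulkDataset, CellDataset

LN2 = float(np.log(2.0))

DEFAULT_LFC_THRESHOLD = 0.6
DEFAULT_FDR_THRESHOLD = 0.05
DEFAULT_BASEMEAN_THRESHOLD = 1.0


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values, returned in input order.

    NaN entries propagate and are not counted in the number of tests.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    vals = p[ok]
    if ((vals < 0) | (vals > 1)).any():
        raise DataError("p-values must lie in [0, 1]")
    m = vals.size
    if m == 0:
        return out
    order = np.argsort(vals, kind="stable")
    ranked = vals[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def classify_direction(
    de: pd.DataFrame,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    basemean_threshold: float | None = None,
) -> pd.Series:
    """Label genes up/down/ns under strict |log2FC| and FDR thresholds."""
    sig = de["padj"] < fdr_threshold
    if basemean_threshold is not None and "base_mean" in de.columns:
        sig &= de["base_mean"] > basemean_threshold
    lab = np.where(sig & (de["log2fc"] > lfc_threshold), "up",
                   np.where(sig & (de["log2fc"] < -lfc_threshold), "down", "ns"))
    return pd.Series(lab, index=de.index, name="direction")


# ---------------------------------------------------------------------------
# Per-cell Mann–Whitney DE
# ---------------------------------------------------------------------------

def mannwhitney_de(
    dataset: CellDataset,
    cpm: np.ndarray,
    cluster: str,
    case: str,
    control: str,
    pseudocount: float = 1.0,
    exact_max_n: int = 8,
) -> pd.DataFrame:
    """Per-gene Mann–Whitney U test of case vs control CPM in one cluster."""
    meta = dataset.cell_meta
    in_cluster = (meta["cluster"] == cluster).to_numpy()
    case_mask = in_cluster & (meta["condition"] == case).to_numpy()
    ctrl_mask = in_cluster & (meta["condition"] == control).to_numpy()
    n1, n2 = int(case_mask.sum()), int(ctrl_mask.sum())
    if n1 == 0 or n2 == 0:
        raise DataError(
            f"cluster {cluster!r} needs cells in both {case!r} and {control!r}"
        )
    x = cpm[:, case_mask]
    y = cpm[:, ctrl_mask]
    method = "exact" if (n1 <= exact_max_n and n2 <= exact_max_n) else "asymptotic"
    res = scipy.stats.mannwhitneyu(
        x, y, axis=-1, alternative="two-sided", method=method
    )
    u = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # all-tied genes carry no ordering information
    flat = np.ptp(np.hstack([x, y]), axis=1) == 0
    p[flat] = 1.0
    u[flat] = n1 * n2 / 2.0
    log2fc = np.log2((x.mean(axis=1) + pseudocount)
                     / (y.mean(axis=1) + pseudocount))
    base_mean = np.hstack([x, y]).mean(axis=1)
    out = pd.DataFrame({
        "gene": dataset.gene_ids,
        "log2fc": log2fc,
        "base_mean": base_mean,
        "stat": u,
        "p": p,
    }).set_index("gene")
    out["padj"] = benjamini_hochberg(out["p"].to_numpy())
    out["direction"] = classify_direction(out)
    return out


# ---------------------------------------------------------------------------
# Pseudobulk aggregation
# ---------------------------------------------------------------------------

@dataclass
class PseudobulkMatrix:
    """Gene × (sample, cluster) integer sums of single-cell counts."""

    counts: pd.DataFrame       # genes × columns "sample|cluster"
    col_meta: pd.DataFrame     # sample_id, cluster, condition, n_cells


def aggregate_pseudobulk(dataset: CellDataset) -> PseudobulkMatrix:
    """Sum raw counts within each (biological sample, cluster) pair."""
    meta = dataset.cell_meta
    csc = dataset.counts.tocsc()
    cols, col_rows = [], []
    for (sample, cluster), idx in meta.groupby(
        ["sample_id", "cluster"], sort=True
    ).groups.items():
        cells = np.asarray(idx)
        if cells.size == 0:
            continue
        sums = np.asarray(csc[:, cells].sum(axis=1)).ravel()
        cond = meta.loc[cells[0], "condition"]
        cols.append(pd.Series(sums, name=f"{sample}|{cluster}"))
        col_rows.append({
            "column": f"{sample}|{cluster}", "sample_id": sample,
            "cluster": cluster, "condition": cond, "n_cells": cells.size,
        })
    counts = pd.concat(cols, axis=1)
    counts.index = dataset.gene_ids
    return PseudobulkMatrix(counts.astype(np.int64), pd.DataFrame(col_rows))


# ---------------------------------------------------------------------------
# NB-Wald replicate-level DE
# ---------------------------------------------------------------------------

def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against the geometric-mean pseudo-sample."""
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise DataError(
            "no gene has positive counts in every sample; filter first"
        )
    logs = np.log(mat[positive])
    ref = logs.mean(axis=1)
    factors = np.exp(np.median(logs - ref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _dispersion_estimates(
    norm: np.ndarray, groups: np.ndarray, trend_weight: float = 0.25
) -> np.ndarray:
    """Gene-wise MoM dispersions shrunk (log scale) toward a 1/mu trend."""
    n = norm.shape[1]
    fitted = np.zeros_like(norm)
    k = 0
    for g in np.unique(groups):
        cols = groups == g
        fitted[:, cols] = norm[:, cols].mean(axis=1, keepdims=True)
        k += 1
    resid_var = ((norm - fitted) ** 2).sum(axis=1) / max(n - k, 1)
    mean = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (resid_var - mean) / mean**2
    # trend phi(mu) = a1/mu + a0, least squares on informative genes
    ok = np.isfinite(raw) & (raw > 0) & (mean > 0)
    if ok.sum() >= 10:
        design = np.column_stack([1.0 / mean[ok], np.ones(ok.sum())])
        coef, *_ = np.linalg.lstsq(design, raw[ok], rcond=None)
        a1, a0 = max(coef[0], 0.0), max(coef[1], 1e-4)
    else:
        a1, a0 = 0.0, max(np.nanmedian(raw[ok]) if ok.any() else 0.05, 1e-4)
    trend = a1 / np.maximum(mean, 1e-8) + a0
    gene_wise = np.where(ok, np.maximum(raw, 1e-8), trend)
    phi = np.exp((1 - trend_weight) * np.log(gene_wise)
                 + trend_weight * np.log(trend))
    return np.clip(phi, 1e-8, 100.0)


def _nb_irls(
    y: np.ndarray, x: np.ndarray, offset: np.ndarray, phi: np.ndarray,
    n_iter: int = 50, tol: float = 1e-8,
):
    """Vectorised IRLS for per-gene NB GLMs with design [1, condition].

    ``y`` is genes × samples, ``x`` the 0/1 condition indicator, ``offset``
    the log effective library sizes, ``phi`` per-gene dispersions.  Returns
    (coef, se) for the condition coefficient on the natural-log scale.
    """
    n_genes, n_samp = y.shape
    mean0 = np.maximum((y / np.exp(offset)[None, :]).mean(axis=1), 1e-8)
    b0 = np.log(mean0)
    b1 = np.zeros(n_genes)
    for _ in range(n_iter):
        eta = offset[None, :] + b0[:, None] + b1[:, None] * x[None, :]
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + phi[:, None] * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        a11 = w.sum(axis=1)
        a12 = (w * x[None, :]).sum(axis=1)
        a22 = (w * x[None, :] ** 2).sum(axis=1)
        c1 = (w * z).sum(axis=1)
        c2 = (w * z * x[None, :]).sum(axis=1)
        det = a11 * a22 - a12**2
        det = np.where(np.abs(det) < 1e-12, np.nan, det)
        nb0 = (a22 * c1 - a12 * c2) / det
        nb1 = (a11 * c2 - a12 * c1) / det
        shift = np.nanmax(np.abs(nb0 - b0) + np.abs(nb1 - b1))
        b0 = np.where(np.isfinite(nb0), nb0, b0)
        b1 = np.where(np.isfinite(nb1), nb1, b1)
        if shift < tol:
            break
    eta = offset[None, :] + b0[:, None] + b1[:, None] * x[None, :]
    mu = np.exp(np.clip(eta, -30, 30))
    w = mu / (1.0 + phi[:, None] * mu)
    a11 = w.sum(axis=1)
    a12 = (w * x[None, :]).sum(axis=1)
    a22 = (w * x[None, :] ** 2).sum(axis=1)
    det = a11 * a22 - a12**2
    with np.errstate(divide="ignore", invalid="ignore"):
        se1 = np.sqrt(a11 / det)
    return b1, se1


def fit_nb_wald_de(
    counts: pd.DataFrame,
    condition: pd.Series | np.ndarray,
    case: str,
    control: str,
    size_factors: pd.Series | None = None,
    trend_weight: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB GLM Wald test per gene; returns (DE table, ranked list).

    The ranked list orders genes by descending Wald z (ties broken by gene
    id) for use as a preranked-GSEA metric.  All-zero genes are excluded
    from testing and listed with NaN statistics.
    """
    condition = pd.Series(np.asarray(condition), index=counts.columns)
    levels = set(condition)
    if case not in levels or control not in levels:
        raise DataError(f"conditions {case!r}/{control!r} not found in labels")
    keep = condition.isin([case, control])
    counts = counts.loc[:, keep.to_numpy()]
    condition = condition[keep]
    if (condition == case).sum() < 2 or (condition == control).sum() < 2:
        raise DataError("need >= 2 samples per condition for NB-Wald DE")

    tested = counts.index[(counts.sum(axis=1) > 0).to_numpy()]
    dropped = counts.index.difference(tested)
    y = counts.loc[tested].to_numpy(dtype=float)
    if size_factors is None:
        size_factors = estimate_size_factors(counts.loc[tested])
    s = size_factors.reindex(counts.columns).to_numpy(dtype=float)
    x = (condition == case).to_numpy(dtype=float)

    norm = y / s[None, :]
    phi = _dispersion_estimates(norm, x, trend_weight=trend_weight)
    coef, se = _nb_irls(y, x, np.log(s), phi)
    z = coef / se
    p = 2.0 * scipy.stats.norm.sf(np.abs(z))
    de = pd.DataFrame({
        "log2fc": coef / LN2,
        "base_mean": norm.mean(axis=1),
        "stat": z,
        "p": p,
        "dispersion": phi,
    }, index=tested)
    de.index.name = "gene"
    de["padj"] = benjamini_hochberg(de["p"].to_numpy())
    de["direction"] = classify_direction(
        de, basemean_threshold=DEFAULT_BASEMEAN_THRESHOLD
    )
    if len(dropped):
        pad = pd.DataFrame(
            {c: np.nan for c in de.columns}, index=dropped
        )
        pad["direction"] = "ns"
        de = pd.concat([de, pad])
    de = de.loc[counts.index]
    de.index.name = "gene"

    ranked = de.loc[tested, ["stat"]].reset_index()
    ranked = ranked.sort_values(
        ["stat", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    ranked.columns = ["gene", "score"]
    return de, ranked


def pseudobulk_de(
    pseudobulk: PseudobulkMatrix, cluster: str, case: str, control: str,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB-Wald DE restricted to one cluster's pseudobulk columns."""
    meta = pseudobulk.col_meta
    cols = meta[meta["cluster"] == cluster]
    if cols.empty:
        raise DataError(f"no pseudobulk columns for cluster {cluster!r}")
    sub = pseudobulk.counts[cols["column"].tolist()]
    cond = cols.set_index("column")["condition"]
    return fit_nb_wald_de(sub, cond, case, control, **kwargs)


# ---------------------------------------------------------------------------
# TMM / FPKM / low-expression filtering
# ---------------------------------------------------------------------------

def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
) -> pd.Series:
    """TMM scaling factors, geometric mean 1.

    Reference sample = the one whose upper-quartile count proportion is
    closest to the mean upper quartile.  Per sample, the factor is the
    precision-weighted mean of M-values over genes positive in both sample
    and reference, after trimming ``logratio_trim`` from each M tail and
    ``abs_trim`` from each A tail.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.shape[1] < 2:
        raise DataError("TMM needs at least two samples")
    lib = mat.sum(axis=0)
    if (lib == 0).any():
        raise DataError("sample with zero total counts")
    props = mat / lib[None, :]
    uq = np.array([np.percentile(c[c > 0] / t, 75) if (c > 0).any() else 0.0
                   for c, t in zip(mat.T, lib)])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref, ref_lib = mat[:, ref_idx], lib[ref_idx]

    log_factors = np.zeros(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref_idx:
            continue
        obs, obs_lib = mat[:, j], lib[j]
        both = (obs > 0) & (ref > 0)
        if not both.any():
            raise DataError(
                f"sample {counts.columns[j]!r} shares no expressed gene "
                f"with the reference"
            )
        po, pr = obs[both] / obs_lib, ref[both] / ref_lib
        m = np.log2(po / pr)
        a = 0.5 * np.log2(po * pr)
        w = (obs_lib - obs[both]) / (obs_lib * obs[both]) \
            + (ref_lib - ref[both]) / (ref_lib * ref[both])
        n = m.size
        lo_m, hi_m = np.quantile(m, [logratio_trim, 1 - logratio_trim])
        lo_a, hi_a = np.quantile(a, [abs_trim, 1 - abs_trim])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any():
            keep = np.ones(n, dtype=bool)
        log_factors[j] = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])

    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def compute_fpkm(
    dataset: BulkDataset, factors: pd.Series | None = None
) -> pd.DataFrame:
    """FPKM with TMM-effective library sizes."""
    counts = dataset.counts
    if factors is None:
        factors = tmm_factors(counts)
    eff_lib = counts.sum(axis=0).to_numpy() * factors.reindex(counts.columns).to_numpy()
    length_kb = dataset.gene_lengths.to_numpy() / 1e3
    fpkm = counts.to_numpy(dtype=float) / length_kb[:, None] / (eff_lib / 1e6)[None, :]
    return pd.DataFrame(fpkm, index=counts.index, columns=counts.columns)


def filter_low_expressed(
    fpkm: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    quantile: float = 0.25,
    require_all_groups: bool = True,
) -> pd.Index:
    """Retain genes unless their median FPKM is bottom-quartile in every group.

    ``require_all_groups=False`` switches to the stricter reading where a
    single bottom-quartile group suffices for exclusion.
    """
    groups = pd.Series(np.asarray(groups), index=fpkm.columns)
    n_bottom = int(np.floor(quantile * fpkm.shape[0]))
    in_bottom = []
    for g in pd.unique(groups):
        med = fpkm.loc[:, (groups == g).to_numpy()].median(axis=1)
        order = med.rank(method="first").to_numpy()  # ties by row order
        in_bottom.append(order <= n_bottom)
    in_bottom = np.column_stack(in_bottom)
    drop = in_bottom.all(axis=1) if require_all_groups else in_bottom.any(axis=1)
    return fpkm.index[~drop]
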