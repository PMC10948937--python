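"""Matrix construction, k-means model selection and group-difference
statistics shared across the pipeline.

The workhorse statistics are the two-sided Wilcoxon rank-sum test,
Cliff's delta effect size and Benjamini-Hochberg adjustment; cluster
structure is chosen by minimising a k-means AIC, defined here as
``WSS(k) + 2 * k * d`` with ``d`` the number of feature columns.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning
from statsmodels.stats.multitest import multipletests

from .containers import BetaMatrix
from .genomic_core import IntervalSet


def aggregate_probes_to_tiles(probe_beta: BetaMatrix, tiles: IntervalSet) -> pd.DataFrame:
    """Mean beta of the probes *fully contained* in each tile.

    A probe straddling a tile boundary contributes to neither tile; tiles
    with no contained probe get NaN.  Rows are indexed by the tile's
    ``name`` meta (falling back to ``chrom:start-end``).
    """
    coords = probe_beta.coords
    pchrom = coords["chrom"].to_numpy()
    pstart = coords["start"].to_numpy()
    pend = coords["end"].to_numpy()
    beta = probe_beta.beta.to_numpy(dtype=float)

    order = {}
    for c in np.unique(pchrom):
        mask = pchrom == c
        idx = np.nonzero(mask)[0]
        srt = np.argsort(pstart[idx], kind="stable")
        order[c] = idx[srt]

    rows, names = [], []
    for tile in tiles:
        names.append(tile.meta.get("name", f"{tile.chrom}:{tile.start}-{tile.end}"))
        idx = order.get(tile.chrom)
        if idx is None:
            rows.append(np.full(beta.shape[1], np.nan))
            continue
        starts = pstart[idx]
        lo = np.searchsorted(starts, tile.start, side="left")
        hi = np.searchsorted(starts, tile.end, side="left")
        sel = idx[lo:hi]
        sel = sel[pend[sel] <= tile.end]
        if sel.size == 0:
            rows.append(np.full(beta.shape[1], np.nan))
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                rows.append(np.nanmean(beta[sel], axis=0))
    return pd.DataFrame(rows, index=names, columns=probe_beta.beta.columns)


def select_most_variable(matrix: pd.DataFrame, n: int = 10000) -> list:
    """Indices of the ``n`` rows with the highest variance across samples
    (NaN ignored pairwise).  Ties broken by row (genomic) order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(matrix):
        warnings.warn(f"n={n} exceeds {len(matrix)} rows; returning all rows")
        n = len(matrix)
    var = matrix.var(axis=1, ddof=1, skipna=True).fillna(-np.inf).to_numpy()
    # stable sort on descending variance keeps genomic order among ties
    order = np.argsort(-var, kind="stable")[:n]
    return list(matrix.index[np.sort(order)])


def kmeans_with_aic(
    matrix: pd.DataFrame,
    k_range: range = range(1, 26),
    iters: int = 25,
    starts: int = 50,
    seed: int = 0,
) -> dict:
    """Best-of-starts Lloyd k-means over ``k_range`` with AIC model choice.

    AIC(k) = WSS(k) + 2*k*d, d = number of columns.  Missing values are
    row-mean imputed before clustering.  Returns ``labels`` for the AIC-
    minimising k, the ``chosen_k`` and the full ``aic_curve`` frame.
    """
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        row_means = np.nanmean(X, axis=1, keepdims=True)
        if np.isnan(row_means).any():
            raise ValueError("rows with all values missing cannot be clustered")
        X = np.where(np.isnan(X), row_means, X)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in clustering matrix")
    if len(X) < max(k_range):
        raise ValueError("fewer rows than the largest k requested")

    d = X.shape[1]
    rng = np.random.default_rng(seed)
    records, fits = [], {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for k in k_range:
            km = KMeans(
                n_clusters=k,
                init="random",
                n_init=starts,
                max_iter=iters,
                algorithm="lloyd",
                random_state=int(rng.integers(0, 2**31 - 1)),
            ).fit(X)
            wss = float(km.inertia_)
            records.append({"k": k, "wss": wss, "aic": wss + 2.0 * k * d})
            fits[k] = km.labels_
    curve = pd.DataFrame(records)
    chosen_k = int(curve.loc[curve["aic"].idxmin(), "k"])
    return {
        "labels": pd.Series(fits[chosen_k], index=matrix.index, name="cluster"),
        "chosen_k": chosen_k,
        "aic_curve": curve,
    }


def cliffs_delta(x, y) -> float:
    """Cliff's delta: (#{x_i > y_j} - #{x_i < y_j}) / (n*m)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("cliffs_delta requires nonempty samples")
    diff = x[:, None] - y[None, :]
    return float((np.sign(diff)).sum() / (x.size * y.size))


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution when min(n, m) <= 8 and there are no ties,
    otherwise the normal approximation with tie and continuity
    corrections.  ``mode`` may force 'exact' or 'asymptotic'.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wilcoxon_rank_sum requires nonempty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    elif mode in ("exact", "asymptotic"):
        method = mode
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(min(res.pvalue, 1.0))


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cluster_group_medians(
    matrix: pd.DataFrame, labels: pd.Series, groups: pd.Series
) -> pd.DataFrame:
    """Per-cluster, per-group median methylation summary.

    Within each cluster, samples are summarised by the median over member
    rows; the per-sample medians are then summarised by the median within
    each sample group.  Missing values are ignored.
    """
    if not labels.index.equals(matrix.index):
        labels = labels.reindex(matrix.index)
        if labels.isna().any():
            raise ValueError("labels do not align with matrix rows")
    out = {}
    for cluster in sorted(labels.unique()):
        rows = matrix.loc[labels == cluster]
        if rows.empty:
            warnings.warn(f"cluster {cluster} is empty")
            continue
        per_sample = rows.median(axis=0, skipna=True)
        out[cluster] = per_sample.groupby(groups.reindex(per_sample.index)).median()
    return pd.DataFrame(out).T.rename_axis("cluster")
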