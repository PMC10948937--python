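"""Two-platform DMR calling, control filtering, and cancer-specific
region extraction.

Two simplified but honestly calibrated region callers are provided:

* :func:`call_dmrs_tiles` — per-tile two-group test on bisulfite
  methylation proportions.  Pooled counts are compared with a
  two-proportion statistic whose variance is inflated by a
  method-of-moments overdispersion factor
  ``phi = max(1, Pearson chi^2 / df)`` estimated across samples; the
  statistic is referred to a t distribution with ``n1 + n2 - 2``
  degrees of freedom to reflect the estimated phi.
* :func:`call_dmrs_probes` — probe-wise Welch t-test on array beta
  values, with significant probes merged into regions.

Both are deliberately replaceable stand-ins for heavier external
machinery (beta-binomial GLMs, kernel-smoothing region callers); the
surrounding filtering logic — control-comparison intersection, the
600-bp cross-comparison overlap rule, exact tile identity on the
sequencing platform — is the substance of this module.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DMR_COLS, BetaMatrix, DMRSet, TileCounts
from .genomic_core import (
    GenomicInterval,
    IntervalSet,
    extend_intervals,
    intersect_spans,
    is_canonical,
    merge_intervals,
    overlap_width,
)
from .methylation_stats import adjust_bh


def _welch_t_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t-test p-values and mean differences (a - b)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
    p = np.asarray(p, dtype=float)
    delta = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
    p[~np.isfinite(p)] = 1.0  # zero-variance / degenerate rows
    return p, delta


def tile_test_statistics(
    counts: TileCounts, group1: str, group2: str
) -> pd.DataFrame:
    """Per-tile two-proportion test with overdispersion-robust variance.

    Returns a frame with pooled proportions, the mean per-sample beta
    difference (group1 - group2), the overdispersion factor phi, and the
    two-sided p-value.
    """
    s1 = counts.samples_of(group1)
    s2 = counts.samples_of(group2)
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError(f"need >=2 samples per group ({group1}: {len(s1)}, {group2}: {len(s2)})")
    m1 = counts.meth[s1].to_numpy(dtype=float)
    n1 = counts.total[s1].to_numpy(dtype=float)
    m2 = counts.meth[s2].to_numpy(dtype=float)
    n2 = counts.total[s2].to_numpy(dtype=float)

    N1, N2 = n1.sum(axis=1), n2.sum(axis=1)
    p1, p2 = m1.sum(axis=1) / N1, m2.sum(axis=1) / N2
    pooled = (m1.sum(axis=1) + m2.sum(axis=1)) / (N1 + N2)

    # method-of-moments overdispersion across samples, per tile
    with np.errstate(invalid="ignore", divide="ignore"):
        mu1 = n1 * p1[:, None]
        mu2 = n2 * p2[:, None]
        chi2 = np.nansum((m1 - mu1) ** 2 / (mu1 * (1 - p1[:, None])), axis=1) + np.nansum(
            (m2 - mu2) ** 2 / (mu2 * (1 - p2[:, None])), axis=1
        )
    df_phi = (len(s1) + len(s2)) - 2
    phi = np.maximum(1.0, chi2 / df_phi)

    with np.errstate(invalid="ignore", divide="ignore"):
        var = phi * pooled * (1 - pooled) * (1 / N1 + 1 / N2)
        z = (p1 - p2) / np.sqrt(var)
    p = 2 * stats.t.sf(np.abs(z), df=len(s1) + len(s2) - 2)
    p = np.where(np.isfinite(p), p, 1.0)

    with np.errstate(invalid="ignore"):
        beta1 = np.nanmean(m1 / n1, axis=1)
        beta2 = np.nanmean(m2 / n2, axis=1)
    return pd.DataFrame(
        {
            "p": p,
            "delta_beta": beta1 - beta2,
            "phi": phi,
            "pooled_p1": p1,
            "pooled_p2": p2,
        },
        index=counts.meth.index,
    )


def call_dmrs_tiles(
    counts: TileCounts,
    group1: str,
    group2: str,
    min_coverage: int = 10,
    min_delta: float = 0.25,
    max_q: float = 0.05,
) -> DMRSet:
    """Call single-tile DMRs between two groups of bisulfite samples.

    Tiles with any sample (in either group) below ``min_coverage`` reads,
    or lying on non-canonical contigs (scaffolds, sex chromosomes,
    mitochondrial DNA), are removed before testing.  BH correction runs
    across the surviving tiles; tiles with q < ``max_q`` and
    |delta-beta| >= ``min_delta`` are returned as 1-tile regions.
    """
    used = counts.samples_of(group1) + counts.samples_of(group2)
    keep = (counts.total[used] >= min_coverage).all(axis=1)
    keep &= counts.coords["chrom"].map(is_canonical)
    if not keep.any():
        return DMRSet(pd.DataFrame(columns=DMR_COLS))
    sub = TileCounts(
        counts.meth.loc[keep], counts.total.loc[keep], counts.coords.loc[keep], counts.groups
    )
    res = tile_test_statistics(sub, group1, group2)
    res["q"] = adjust_bh(res["p"].to_numpy())
    hits = res[(res["q"] < max_q) & (res["delta_beta"].abs() >= min_delta)]
    coords = sub.coords.loc[hits.index]
    df = pd.DataFrame(
        {
            "chrom": coords["chrom"],
            "start": coords["start"],
            "end": coords["end"],
            "delta_beta": hits["delta_beta"],
            "q": hits["q"],
            "direction": np.where(hits["delta_beta"] > 0, "hyper", "hypo"),
            "n_units": 1,
            "platform": "tiles",
            "comparison": f"{group1}_vs_{group2}",
        }
    ).reset_index(drop=True)
    return DMRSet(df if len(df) else pd.DataFrame(columns=DMR_COLS))


def residualize_covariate(
    beta: pd.DataFrame, covariate: pd.Series, groups: pd.Series
) -> pd.DataFrame:
    """Remove per-probe covariate-level means (categorical covariate such
    as tumor location), preserving the grand mean.  If the covariate
    partition coincides with the group partition the adjustment is
    skipped with a warning (fully confounded)."""
    cov = covariate.reindex(beta.columns)
    grp = groups.reindex(beta.columns)
    part_cov = {tuple(sorted(beta.columns[cov == lv])) for lv in cov.unique()}
    part_grp = {tuple(sorted(beta.columns[grp == lv])) for lv in grp.unique()}
    if part_cov == part_grp:
        warnings.warn("covariate is confounded with group labels; skipping adjustment")
        return beta
    grand = beta.mean(axis=1)
    adj = beta.copy()
    for lv in cov.unique():
        cols = beta.columns[cov == lv]
        adj[cols] = beta[cols].sub(beta[cols].mean(axis=1), axis=0).add(grand, axis=0)
    return adj.clip(0.0, 1.0)


def call_dmrs_probes(
    beta_matrix: BetaMatrix,
    group1: str,
    group2: str,
    covariate: pd.Series | None = None,
    betacutoff: float = 0.05,
    final_delta: float = 0.20,
    max_fdr: float = 0.05,
    merge_gap: int = 1000,
) -> DMRSet:
    """Call array DMRs: probe-wise Welch t-test, BH correction, merge of
    significant probes into regions.

    Probes with q < ``max_fdr`` and |delta-beta| >= ``betacutoff`` are
    merged into a region when the gap between consecutive probes is
    <= ``merge_gap`` bp (a strictly larger gap splits).  Region
    delta-beta is the mean of member-probe deltas; regions are kept when
    the region |delta-beta| >= ``final_delta`` and q < ``max_fdr``.
    """
    s1 = beta_matrix.samples_of(group1)
    s2 = beta_matrix.samples_of(group2)
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError(f"need >=2 samples per group ({group1}: {len(s1)}, {group2}: {len(s2)})")
    beta = beta_matrix.beta[s1 + s2]
    if covariate is not None:
        beta = residualize_covariate(beta, covariate, beta_matrix.groups.reindex(s1 + s2))
    p, delta = _welch_t_rows(beta[s1].to_numpy(dtype=float), beta[s2].to_numpy(dtype=float))
    q = adjust_bh(p)

    probes = beta_matrix.coords.copy()
    probes["delta"] = delta
    probes["q"] = q
    sig = probes[(probes["q"] < max_fdr) & (probes["delta"].abs() >= betacutoff)]
    sig = sig.sort_values(["chrom", "start", "end"], kind="stable")

    rows = []
    cur: list[pd.Series] = []

    def flush() -> None:
        if not cur:
            return
        d = float(np.mean([r["delta"] for r in cur]))
        rows.append(
            {
                "chrom": cur[0]["chrom"],
                "start": int(min(r["start"] for r in cur)),
                "end": int(max(r["end"] for r in cur)),
                "delta_beta": d,
                "q": float(min(r["q"] for r in cur)),
                "direction": "hyper" if d > 0 else "hypo",
                "n_units": len(cur),
            }
        )

    for _, r in sig.iterrows():
        if cur and (r["chrom"] != cur[-1]["chrom"] or r["start"] - cur[-1]["end"] > merge_gap):
            flush()
            cur = []
        cur.append(r)
    flush()

    df = pd.DataFrame(rows)
    if len(df):
        df = df[(df["delta_beta"].abs() >= final_delta) & (df["q"] < max_fdr)]
        df["platform"] = "array"
        df["comparison"] = f"{group1}_vs_{group2}"
        df = df.reset_index(drop=True)
    return DMRSet(df[DMR_COLS] if len(df) else pd.DataFrame(columns=DMR_COLS))


def filter_by_controls(main: DMRSet, controls: list[DMRSet]) -> DMRSet:
    """Intersect the main-comparison DMRs with the union of the control
    comparisons, keeping only the intersecting sub-regions.

    Each output span inherits its main DMR's delta-beta/q/direction; a
    main DMR with no control overlap is dropped.  No direction matching
    between main and control is applied.
    """
    controls = [c for c in controls if len(c)]
    if not controls:
        warnings.warn("empty controls list: returning main DMRs unchanged")
        return main
    platforms = {main.platform} | {c.platform for c in controls}
    platforms.discard(None)
    if len(platforms) > 1:
        raise ValueError(f"mixed platforms in control filtering: {platforms}")
    control_union = IntervalSet(
        iv for c in controls for iv in c.intervals()
    )
    pieces = intersect_spans(main.intervals(), control_union)
    rows = []
    for iv in pieces:
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "delta_beta": iv.meta["delta_beta"],
                "q": iv.meta["q"],
                "direction": iv.meta["direction"],
                "n_units": 1,
                "platform": main.platform,
                "comparison": main.comparison,
            }
        )
    return DMRSet(pd.DataFrame(rows, columns=DMR_COLS) if rows else pd.DataFrame(columns=DMR_COLS))


def dmr_member_probes(dmrs: DMRSet, probes: IntervalSet, pad: int = 500) -> IntervalSet:
    """Probes overlapping any DMR (>=1 bp), each extended by ``pad`` bp on
    both sides and carrying its DMR's delta-beta/direction in meta."""
    out = []
    dmr_ivs = dmrs.intervals()
    pidx = probes._chrom_index()
    for dmr in dmr_ivs:
        ci = pidx.get(dmr.chrom)
        if ci is None:
            continue
        starts, ends, ivs = ci["starts"], ci["ends"], ci["ivs"]
        hi = int(np.searchsorted(starts, dmr.end, side="left"))
        for j in range(hi):
            if ends[j] > dmr.start:
                p = ivs[j]
                meta = dict(p.meta)
                meta.update(
                    delta_beta=dmr.meta["delta_beta"],
                    direction=dmr.meta["direction"],
                    source_dmr=dmr.meta.get("name"),
                )
                out.append(
                    GenomicInterval(p.chrom, max(0, p.start - pad), p.end + pad, p.strand, meta)
                )
    return IntervalSet(out)


def extract_cancer_specific(
    dmrs_ab: DMRSet,
    dmrs_ac: DMRSet,
    platform: str,
    probes: IntervalSet | None = None,
    probe_pad: int = 500,
    min_overlap: int = 600,
    min_delta: float = 0.25,
) -> dict[str, IntervalSet]:
    """Extract regions with cancer-specific methylation from the two
    comparisons sharing a focal cancer (A-vs-B and A-vs-C).

    Only DMRs with |delta-beta| >= ``min_delta`` enter.  On the array
    platform, member probes are extended by ``probe_pad`` bp (each
    carrying its DMR's delta-beta); same-direction extended probes from
    the two comparisons qualify when a pair overlaps by at least
    ``min_overlap`` bp, and the merged pairwise intersections are
    returned.  On the tile platform exact tile identity is required.
    """
    focal_ab = dmrs_ab.comparison.split("_vs_")[0] if dmrs_ab.comparison else None
    focal_ac = dmrs_ac.comparison.split("_vs_")[0] if dmrs_ac.comparison else None
    if focal_ab is not None and focal_ac is not None and focal_ab != focal_ac:
        raise ValueError(f"comparisons do not share a focal cancer: {focal_ab} vs {focal_ac}")

    ab = dmrs_ab.subset(dmrs_ab.df["delta_beta"].abs() >= min_delta)
    ac = dmrs_ac.subset(dmrs_ac.df["delta_beta"].abs() >= min_delta)

    out: dict[str, IntervalSet] = {}
    for direction in ("hyper", "hypo"):
        ab_d = ab.subset(ab.df["direction"] == direction)
        ac_d = ac.subset(ac.df["direction"] == direction)
        if platform == "tiles":
            keys_ac = {(r["chrom"], r["start"], r["end"]) for _, r in ac_d.df.iterrows()}
            ivs = [
                iv
                for iv in ab_d.intervals()
                if (iv.chrom, iv.start, iv.end) in keys_ac
            ]
            out[direction] = IntervalSet(ivs)
        elif platform == "array":
            if probes is None:
                raise ValueError("array platform requires the probe IntervalSet")
            ext_ab = dmr_member_probes(ab_d, probes, pad=probe_pad)
            ext_ac = dmr_member_probes(ac_d, probes, pad=probe_pad)
            pieces = []
            ac_idx = ext_ac._chrom_index()
            for a_iv in ext_ab:
                ci = ac_idx.get(a_iv.chrom)
                if ci is None:
                    continue
                starts, ends, ivs = ci["starts"], ci["ends"], ci["ivs"]
                hi = int(np.searchsorted(starts, a_iv.end, side="left"))
                for j in range(hi):
                    w = min(int(ends[j]), a_iv.end) - max(int(starts[j]), a_iv.start)
                    if w >= min_overlap:
                        s = max(a_iv.start, int(starts[j]))
                        e = min(a_iv.end, int(ends[j]))
                        meta = {
                            "delta_beta": a_iv.meta["delta_beta"],
                            "direction": direction,
                        }
                        pieces.append(GenomicInterval(a_iv.chrom, s, e, meta=meta))
            merged = merge_intervals(IntervalSet(pieces), 0) if pieces else IntervalSet()
            for iv in merged:
                iv.meta["direction"] = direction
            out[direction] = merged
        else:
            raise ValueError(f"unknown platform {platform!r}")
    return out


def count_direction_fourfield(
    specific: dict[tuple[str, str], dict[str, IntervalSet]]
) -> pd.DataFrame:
    """Hyper/hypo counts (and percentages) per (cancer, platform) from the
    cancer-specific region sets."""
    rows = []
    for (cancer, platform), sets in specific.items():
        n_hyper = len(sets.get("hyper", ()))
        n_hypo = len(sets.get("hypo", ()))
        total = n_hyper + n_hypo
        for direction, n in (("hyper", n_hyper), ("hypo", n_hypo)):
            rows.append(
                {
                    "cancer": cancer,
                    "platform": platform,
                    "direction": direction,
                    "count": n,
                    "pct": 100.0 * n / total if total else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["cancer", "platform", "direction", "count", "pct"])
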