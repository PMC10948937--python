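"""Fisher-based TF binding-site enrichment over unit backgrounds.

The contingency unit is a methylation measurement unit (an extended
array probe or a sequencing tile).  For a target set T inside a
background B and a transcription factor F:

    a = |units in T bound by F|        b = |T| - a
    c = |units in B \\ T bound by F|    d = |B \\ T| - c

"bound" means >= 1 bp overlap between the unit interval and any site of
F.  One-sided (enrichment) Fisher's exact p-values are BH-adjusted
across the TFs of a single run.  Variants: category-restricted runs
over an 11-group sample-type vocabulary, cross-platform validation,
pairwise co-localization, per-cluster enrichment, and binding-site
methylation summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BetaMatrix
from .genomic_core import GenomicInterval, IntervalSet, merge_intervals
from .methylation_stats import adjust_bh

#: the closed sample-category vocabulary for categorized binding catalogs
SAMPLE_CATEGORIES: tuple[str, ...] = (
    "analyzed_tumors",
    "other_brain_tumors",
    "neural_progenitors",
    "differentiated_neural",
    "other_brain_neural",
    "psc",
    "rhabdoid",
    "blood",
    "other_cancers",
    "fibroblast",
    "other",
)

ALL_CATEGORIES = "All*"


@dataclass
class BindingSiteCatalog:
    """TF binding sites: frame with columns (tf, chrom, start, end,
    category, source).  Category labels come from a closed vocabulary."""

    df: pd.DataFrame
    vocabulary: tuple[str, ...] = SAMPLE_CATEGORIES

    def __post_init__(self) -> None:
        needed = {"tf", "chrom", "start", "end", "category"}
        if not needed.issubset(self.df.columns):
            raise ValueError(f"catalog requires columns {needed}")
        bad = set(self.df["category"].unique()) - set(self.vocabulary)
        if bad:
            raise ValueError(f"unknown category labels: {sorted(bad)}")
        self.df = self.df.reset_index(drop=True)

    def tfs(self) -> list[str]:
        return sorted(self.df["tf"].unique())

    def sites_of(self, tf: str, category: str | None = None) -> IntervalSet:
        sub = self.df[self.df["tf"] == tf]
        if category is not None and category != ALL_CATEGORIES:
            sub = sub[sub["category"] == category]
        return IntervalSet(
            GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]), meta={"tf": tf})
            for _, r in sub.iterrows()
        )

    def measured(self, tf: str, category: str) -> bool:
        if category == ALL_CATEGORIES:
            return bool((self.df["tf"] == tf).any())
        return bool(((self.df["tf"] == tf) & (self.df["category"] == category)).any())

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tcategory\tsource\n")
            for _, r in self.df.iterrows():
                fh.write(
                    f"{r['chrom']}\t{int(r['start'])}\t{int(r['end'])}\t{r['tf']}\t0\t.\t"
                    f"{r['category']}\t{r.get('source', '.')}\n"
                )

    @classmethod
    def read_bed(cls, path, vocabulary: tuple[str, ...] = SAMPLE_CATEGORIES) -> "BindingSiteCatalog":
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                p = line.rstrip("\n").split("\t")
                rows.append(
                    {
                        "tf": p[3],
                        "chrom": p[0],
                        "start": int(p[1]),
                        "end": int(p[2]),
                        "category": p[6],
                        "source": p[7] if len(p) > 7 else ".",
                    }
                )
        return cls(pd.DataFrame(rows), vocabulary)


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher's exact test: P(X >= a) under the
    hypergeometric law with the table's margins fixed."""
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError(f"counts must be nonnegative integers, got {(a, b, c, d)}")
    N = a + b + c + d
    return float(stats.hypergeom.sf(a - 1, N, a + c, a + b))


def units_bound(units: IntervalSet, sites: IntervalSet) -> np.ndarray:
    """Boolean array (in ``units`` iteration order): unit overlaps (>=1 bp)
    any site.  Vectorized per chromosome against the merged site spans."""
    merged = merge_intervals(sites, 0) if len(sites) else IntervalSet()
    sidx = merged._chrom_index()
    uidx = units._chrom_index()
    out = np.zeros(len(units), dtype=bool)
    for chrom, ui in uidx.items():
        ci = sidx.get(chrom)
        if ci is None:
            continue
        # first merged site ending after the unit start; overlap iff it
        # also starts before the unit end (merged spans are disjoint)
        j = np.searchsorted(ci["ends"], ui["starts"], side="right")
        valid = j < len(ci["starts"])
        hit = np.zeros(len(ui["starts"]), dtype=bool)
        hit[valid] = ci["starts"][j[valid]] < ui["ends"][valid]
        out[ui["order"]] = hit
    return out


def _unit_names(units: IntervalSet) -> list[str]:
    names = [iv.meta.get("name", f"{iv.chrom}:{iv.start}-{iv.end}") for iv in units]
    return names


def enrich_tf_sets(
    target_units: IntervalSet,
    background_units: IntervalSet,
    catalog: BindingSiteCatalog,
    category: str | None = None,
    tfs: list[str] | None = None,
) -> pd.DataFrame:
    """Per-TF enrichment of binding sites in target vs background units.

    ``target_units`` must be an identity subset of ``background_units``.
    TFs with zero sites in the requested category are omitted with a
    warning.  Returns a frame (tf, category, a, b, c, d, p, adj_p,
    significant) BH-adjusted across the run's TFs.
    """
    bg_names = _unit_names(background_units)
    tnames = set(_unit_names(target_units))
    if not tnames.issubset(set(bg_names)):
        raise ValueError("target units are not a subset of the background units")
    in_target = np.array([n in tnames for n in bg_names])

    rows = []
    for tf in tfs if tfs is not None else catalog.tfs():
        sites = catalog.sites_of(tf, category)
        if len(sites) == 0:
            warnings.warn(f"TF {tf} has no sites in category {category or ALL_CATEGORIES}; omitted")
            continue
        bound = units_bound(background_units, sites)
        a = int((bound & in_target).sum())
        b = int((~bound & in_target).sum())
        c = int((bound & ~in_target).sum())
        d = int((~bound & ~in_target).sum())
        rows.append(
            {
                "tf": tf,
                "category": category or ALL_CATEGORIES,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "p": fisher_one_sided(a, b, c, d),
            }
        )
    res = pd.DataFrame(rows, columns=["tf", "category", "a", "b", "c", "d", "p"])
    if len(res):
        res["adj_p"] = adjust_bh(res["p"].to_numpy())
        res["significant"] = res["adj_p"] < 0.05
    else:
        res["adj_p"] = []
        res["significant"] = []
    return res


def validate_across_platforms(
    results_array: dict[tuple[str, str], pd.DataFrame],
    results_tiles: dict[tuple[str, str], pd.DataFrame],
    alpha: float = 0.05,
) -> dict[tuple[str, str], set[str]]:
    """TFs significant (adj_p < alpha) in the analogous DMR set on *both*
    platforms, per (cancer, direction) key."""
    out: dict[tuple[str, str], set[str]] = {}
    for key in set(results_array) & set(results_tiles):
        ra, rt = results_array[key], results_tiles[key]
        sa = set(ra.loc[ra["adj_p"] < alpha, "tf"]) if len(ra) else set()
        st = set(rt.loc[rt["adj_p"] < alpha, "tf"]) if len(rt) else set()
        out[key] = sa & st
    return out


def categorized_enrichment(
    target_units: IntervalSet,
    background_units: IntervalSet,
    catalog: BindingSiteCatalog,
    categories: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Run :func:`enrich_tf_sets` once per sample-category subset (plus
    the full-catalog ``All*`` run).  (TF, category) pairs with no
    measured sites are flagged ``measured=False`` with NaN statistics."""
    cats = (ALL_CATEGORIES,) + (categories if categories is not None else catalog.vocabulary)
    frames = []
    all_tfs = catalog.tfs()
    for cat in cats:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = enrich_tf_sets(target_units, background_units, catalog, category=cat)
        res["measured"] = True
        missing = [tf for tf in all_tfs if not catalog.measured(tf, cat)]
        if missing:
            miss = pd.DataFrame({"tf": missing, "category": cat, "measured": False})
            for col in res.columns:
                if col not in miss.columns:
                    miss[col] = np.full(len(miss), np.nan)
            res = miss[res.columns] if res.empty else pd.concat(
                [res, miss[res.columns]], ignore_index=True
            )
        frames.append(res)
    frames = [f for f in frames if len(f)]
    return pd.concat(frames, ignore_index=True)


def colocalization_matrix(
    tf_names: list[str],
    target_regions: IntervalSet,
    catalog: BindingSiteCatalog,
) -> pd.DataFrame:
    """Pairwise TF co-localization over target regions.

    For each unordered TF pair, regions are counted as (both bound, only
    first, only second, neither); the one-sided Fisher p for
    co-occurrence is BH-adjusted over the upper triangle and mirrored
    into a symmetric matrix (diagonal 0 by convention).
    """
    if len(tf_names) < 2:
        raise ValueError("co-localization requires >= 2 TFs")
    bound = {
        tf: units_bound(target_regions, catalog.sites_of(tf)) for tf in tf_names
    }
    n = len(tf_names)
    raw = np.ones((n, n))
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    pvals = []
    for i, j in pairs:
        bi, bj = bound[tf_names[i]], bound[tf_names[j]]
        a = int((bi & bj).sum())
        b = int((bi & ~bj).sum())
        c = int((~bi & bj).sum())
        d = int((~bi & ~bj).sum())
        pvals.append(fisher_one_sided(a, b, c, d))
    adj = adjust_bh(np.array(pvals)) if pvals else np.array([])
    for (i, j), q in zip(pairs, adj):
        raw[i, j] = raw[j, i] = q
    np.fill_diagonal(raw, 0.0)
    return pd.DataFrame(raw, index=tf_names, columns=tf_names)


def binding_site_methylation(
    probe_beta: BetaMatrix,
    catalog: BindingSiteCatalog,
    tf: str,
    max_gap: int = 500,
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """Per-group mean beta of the probes lying within ``max_gap`` bp of
    any binding site of ``tf`` (inclusive boundary: a probe exactly
    ``max_gap`` bp from a site edge is included).

    Returns a probes x groups frame of per-probe group means, suitable
    for violin-style summaries.
    """
    if tf not in set(catalog.df["tf"]):
        raise ValueError(f"TF {tf!r} not in catalog")
    sites = merge_intervals(catalog.sites_of(tf), 0)
    sidx = sites._chrom_index()
    keep = []
    for unit, row in probe_beta.coords.iterrows():
        ci = sidx.get(row["chrom"])
        if ci is None:
            continue
        gaps = np.maximum(
            0, np.maximum(ci["starts"], row["start"]) - np.minimum(ci["ends"], row["end"])
        )
        if gaps.min() <= max_gap:
            keep.append(unit)
    if not keep:
        warnings.warn(f"no probes within {max_gap} bp of {tf} sites")
        return pd.DataFrame()
    sub = probe_beta.beta.loc[keep]
    glabels = groups if groups is not None else sorted(probe_beta.groups.unique())
    out = {}
    for g in glabels:
        cols = probe_beta.samples_of(g)
        out[g] = sub[cols].mean(axis=1)
    return pd.DataFrame(out)


def clusterwise_enrichment(
    cluster_labels: pd.Series,
    dmr_units: dict[str, IntervalSet],
    catalog: BindingSiteCatalog,
    background_units: IntervalSet,
) -> pd.DataFrame:
    """Per-cluster TF enrichment.  ``cluster_labels`` maps unit names to
    cluster ids; ``dmr_units`` maps a (cancer, direction)-style key to
    the unit IntervalSet of that DMR class.  Each (key, cluster) subset
    is tested against the shared background, BH per run."""
    frames = []
    for key, units in dmr_units.items():
        names = _unit_names(units)
        labels = cluster_labels.reindex(names)
        for cluster in sorted(labels.dropna().unique()):
            member = {n for n, lv in labels.items() if lv == cluster}
            subset = IntervalSet(iv for iv in units if iv.meta.get("name") in member)
            if len(subset) == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = enrich_tf_sets(subset, background_units, catalog)
            res["cluster"] = cluster
            res["dmr_class"] = [key] * len(res)
            frames.append(res)
    if not frames:
        return pd.DataFrame(
            columns=["tf", "category", "a", "b", "c", "d", "p", "adj_p", "significant", "cluster", "dmr_class"]
        )
    return pd.concat(frames, ignore_index=True)
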