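"""Situating cancer-specific DMRs relative to pluripotent stem cell (PSC)
and fetal brain (FB) methylomes.

Seven reference comparisons are called (each tumor type vs PSC, each
tumor type vs FB, and PSC vs FB), cancer-specific regions are atomized
against them into non-overlapping segments carrying membership flags,
and each segment is assigned a developmental category on two axes:

* similarity — decided purely from the *presence/absence* pattern of
  called DMR overlaps: no tumor-vs-PSC DMR but a tumor-vs-FB DMR means
  the tumor resembles PSCs (``PSC_like``); the mirror image is
  ``FB_like``; DMRs in both (or in neither — a zero-evidence fallback)
  mean the methylation level is ``unique`` to the tumor.
* differentiation — from the PSC-vs-FB flag, whose direction is stated
  w.r.t. PSC: a PSC-hyper overlap means methylation is lost from PSC to
  FB (``demethylated_in_differentiation``), PSC-hypo means it is gained
  (``methylated_in_differentiation``), no overlap means ``unchanged``.

A comparison showing overlaps in both directions makes the region
``ambiguous``.  The mapping is total and deterministic over the flag
space; the full truth table is generated by :func:`category_truth_table`.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .containers import BetaMatrix, DMRSet
from .dmr_pipeline import call_dmrs_probes
from .genomic_core import GenomicInterval, IntervalSet

TUMOR_GROUPS = ("ATRT", "MB", "PLEX")
REFERENCE_COMPARISONS = tuple(
    [f"{t}_vs_PSC" for t in TUMOR_GROUPS]
    + [f"{t}_vs_FB" for t in TUMOR_GROUPS]
    + ["PSC_vs_FB"]
)

FLAGS = ("none", "hyper", "hypo", "both")

SIMILARITY_LABELS = ("PSC_like", "FB_like", "unique")
DIFFERENTIATION_LABELS = (
    "demethylated_in_differentiation",
    "methylated_in_differentiation",
    "unchanged",
)


def call_reference_dmrs(
    tumor_beta: BetaMatrix,
    psc_beta: BetaMatrix,
    fb_beta: BetaMatrix,
    tumor_groups: tuple[str, ...] = TUMOR_GROUPS,
    max_q: float = 0.05,
    min_delta: float = 0.25,
    min_len: int = 100,
    max_len: int = 5000,
    **caller_kwargs,
) -> dict[str, DMRSet]:
    """Call the seven reference DMR sets (tumors vs PSC/FB, PSC vs FB) on
    the array platform and post-filter by region length (inclusive
    bounds)."""
    beta = pd.concat([tumor_beta.beta, psc_beta.beta, fb_beta.beta], axis=1)
    groups = pd.concat([tumor_beta.groups, psc_beta.groups, fb_beta.groups])
    groups = groups[~groups.index.duplicated()]
    merged = BetaMatrix(beta, tumor_beta.coords, groups)

    out: dict[str, DMRSet] = {}
    pairs = [(t, "PSC") for t in tumor_groups] + [(t, "FB") for t in tumor_groups] + [("PSC", "FB")]
    for g1, g2 in pairs:
        dmrs = call_dmrs_probes(
            merged, g1, g2, max_fdr=max_q, final_delta=min_delta, **caller_kwargs
        )
        if len(dmrs):
            length = dmrs.df["end"] - dmrs.df["start"]
            dmrs = dmrs.subset((length >= min_len) & (length <= max_len))
        out[f"{g1}_vs_{g2}"] = dmrs
    return out


def _flag_for_atom(
    chrom: str, start: int, end: int, ref: DMRSet
) -> str:
    sub = ref.df[(ref.df["chrom"] == chrom) & (ref.df["start"] < end) & (ref.df["end"] > start)]
    dirs = set(sub["direction"])
    if not dirs:
        return "none"
    if dirs == {"hyper"}:
        return "hyper"
    if dirs == {"hypo"}:
        return "hypo"
    return "both"


def build_developmental_matrix(
    cancer_specific: dict[tuple[str, str], IntervalSet],
    reference_dmrs: dict[str, DMRSet],
) -> pd.DataFrame:
    """Overlap cancer-specific regions with each reference DMR set (>=1 bp)
    and atomize into non-overlapping segments carrying membership flags.

    ``cancer_specific`` maps (cancer, direction) to the region set.
    Returns one row per atom: coordinates, focal cancer, region
    direction, and a flag column per reference comparison with values in
    ``{none, hyper, hypo, both}``.  Atoms are pairwise disjoint within a
    (cancer, direction) class and cover the input footprint.
    """
    rows = []
    for (cancer, direction), regions in cancer_specific.items():
        for region in regions:
            cuts = {region.start, region.end}
            for comp, ref in reference_dmrs.items():
                sub = ref.df[
                    (ref.df["chrom"] == region.chrom)
                    & (ref.df["start"] < region.end)
                    & (ref.df["end"] > region.start)
                ]
                for _, r in sub.iterrows():
                    cuts.add(int(np.clip(r["start"], region.start, region.end)))
                    cuts.add(int(np.clip(r["end"], region.start, region.end)))
            edges = sorted(cuts)
            for s, e in zip(edges[:-1], edges[1:]):
                if e <= s:
                    continue
                row = {
                    "chrom": region.chrom,
                    "start": s,
                    "end": e,
                    "cancer": cancer,
                    "direction": direction,
                }
                for comp in REFERENCE_COMPARISONS:
                    ref = reference_dmrs.get(comp)
                    row[comp] = _flag_for_atom(region.chrom, s, e, ref) if ref is not None else "none"
                rows.append(row)
    cols = ["chrom", "start", "end", "cancer", "direction"] + list(REFERENCE_COMPARISONS)
    return pd.DataFrame(rows, columns=cols)


def categorize_flags(vs_psc: str, vs_fb: str, psc_vs_fb: str) -> str:
    """Map a (tumor-vs-PSC, tumor-vs-FB, PSC-vs-FB) flag triple to a
    category label 'similarity|differentiation' (or 'ambiguous')."""
    for f in (vs_psc, vs_fb, psc_vs_fb):
        if f not in FLAGS:
            raise ValueError(f"unknown flag {f!r}")
    if "both" in (vs_psc, vs_fb, psc_vs_fb):
        return "ambiguous"
    if vs_psc == "none" and vs_fb != "none":
        similarity = "PSC_like"
    elif vs_fb == "none" and vs_psc != "none":
        similarity = "FB_like"
    else:
        # DMRs against both references, or zero evidence: unique to the tumor
        similarity = "unique"
    if psc_vs_fb == "hyper":  # PSC higher than FB
        differentiation = "demethylated_in_differentiation"
    elif psc_vs_fb == "hypo":
        differentiation = "methylated_in_differentiation"
    else:
        differentiation = "unchanged"
    return f"{similarity}|{differentiation}"


def category_truth_table() -> pd.DataFrame:
    """Exhaustive flag-triple -> category mapping (the normative
    definition of the developmental taxonomy)."""
    rows = [
        {
            "vs_psc": p,
            "vs_fb": f,
            "psc_vs_fb": d,
            "category": categorize_flags(p, f, d),
        }
        for p, f, d in itertools.product(FLAGS, FLAGS, FLAGS)
    ]
    return pd.DataFrame(rows)


def categorize_regions(assignments: pd.DataFrame) -> pd.Series:
    """Assign a developmental category to every atom of a developmental
    matrix (output of :func:`build_developmental_matrix`), using the
    focal cancer's own reference comparisons."""
    labels = []
    for _, row in assignments.iterrows():
        cancer = row["cancer"]
        labels.append(
            categorize_flags(
                row[f"{cancer}_vs_PSC"], row[f"{cancer}_vs_FB"], row["PSC_vs_FB"]
            )
        )
    return pd.Series(labels, index=assignments.index, name="category")


def category_counts(assignments: pd.DataFrame, categories: pd.Series) -> pd.DataFrame:
    """Per-(cancer, direction, category) atom counts (bar-plot style
    summary of the developmental matrix)."""
    df = assignments[["cancer", "direction"]].copy()
    df["category"] = categories
    out = df.value_counts(["cancer", "direction", "category"]).rename("n").reset_index()
    return out.sort_values(["cancer", "direction", "category"], kind="stable").reset_index(drop=True)
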