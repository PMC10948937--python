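"""Integration of differential methylation with differential expression.

Differentially expressed (DE) genes are called with a Welch t-test on
log-scale expression (a deliberately simple stand-in for moderated
linear models and count GLMs), DMRs are linked to genes through three
regulatory modes (transcript promoter, linked enhancer, +-200 kb TSS
neighborhood), links are validated across platforms (same-direction DMR
within 5 kb on the other platform) and screened against TAD boundaries,
and the surviving genes are classified as DM-DE (opposite-direction
methylation) or parallel.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DMRSet
from .genomic_core import GenomicInterval, IntervalSet
from .methylation_stats import adjust_bh

REGULATORY_MODES = ("promoter", "enhancer", "neighborhood")


def log_cpm(counts: pd.DataFrame, prior: float = 0.5) -> pd.DataFrame:
    """Library-size normalized log2 counts-per-million."""
    lib = counts.sum(axis=0)
    return np.log2((counts + prior) / (lib + 2 * prior) * 1e6)


def call_de_genes(
    expr: pd.DataFrame,
    groups: pd.Series,
    group1: str,
    group2: str,
    platform: str,
    max_adj_p: float = 0.05,
    min_abs_lfc: float = 1.0,
    is_counts: bool = False,
) -> pd.DataFrame:
    """Per-gene Welch t-test on log-scale expression.

    ``expr`` is genes x samples: raw counts (``is_counts=True``,
    converted to log-CPM) or already log-scaled array intensities.
    Multi-probe inputs must be collapsed to genes by the caller (mean
    over probes of the same gene).  Returns all genes with log2FC
    (group1 - group2), p, adj_p and a ``significant`` flag
    (adj_p < ``max_adj_p`` and |log2FC| >= ``min_abs_lfc``).
    """
    s1 = [s for s in expr.columns if groups[s] == group1]
    s2 = [s for s in expr.columns if groups[s] == group2]
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("need >=2 samples per group")
    x = log_cpm(expr) if is_counts else expr
    a = x[s1].to_numpy(dtype=float)
    b = x[s2].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    zero_var = ~np.isfinite(p)
    p[zero_var] = 1.0
    lfc = a.mean(axis=1) - b.mean(axis=1)
    res = pd.DataFrame(
        {
            "gene": expr.index,
            "log2FC": lfc,
            "p": p,
            "adj_p": adjust_bh(p),
            "platform": platform,
            "comparison": f"{group1}_vs_{group2}",
        }
    )
    res["significant"] = (res["adj_p"] < max_adj_p) & (res["log2FC"].abs() >= min_abs_lfc)
    return res


def collapse_probes_to_genes(expr: pd.DataFrame, probe_to_gene: pd.Series) -> pd.DataFrame:
    """Mean of all probes mapped to the same symbolic gene name."""
    genes = probe_to_gene.reindex(expr.index)
    return expr.groupby(genes).mean()


def build_promoters(gene_models: pd.DataFrame, up: int = 2000, down: int = 500) -> IntervalSet:
    """Transcript promoters: [TSS-up, TSS+down) on '+', mirrored on '-',
    clipped at 0.  ``gene_models`` needs columns (gene, transcript,
    chrom, tss, strand); unknown strands are treated as '+' with a
    warning."""
    ivs = []
    unknown = 0
    for _, r in gene_models.iterrows():
        strand = r["strand"]
        if strand not in ("+", "-"):
            unknown += 1
            strand = "+"
        tss = int(r["tss"])
        if strand == "+":
            s, e = tss - up, tss + down
        else:
            s, e = tss - down, tss + up
        ivs.append(
            GenomicInterval(
                r["chrom"], max(0, s), e, strand,
                {"gene": r["gene"], "transcript": r["transcript"], "tss": tss},
            )
        )
    if unknown:
        warnings.warn(f"{unknown} transcripts with unknown strand treated as '+'")
    return IntervalSet(ivs)


def filter_enhancer_links(enhancers: pd.DataFrame, min_confidence: float = 5.0) -> pd.DataFrame:
    """Keep curated-catalog enhancer links with confidence >= the cutoff;
    links from correlation-based catalogs (source 'fantom-like') carry no
    score and always pass."""
    genehancer_like = enhancers["source"].eq("genehancer-like")
    keep = ~genehancer_like | (enhancers["confidence"] >= min_confidence)
    return enhancers[keep].reset_index(drop=True)


def link_dmrs_to_genes(
    dmrs: DMRSet,
    gene_models: pd.DataFrame,
    enhancers: pd.DataFrame | None,
    mode: str,
    neighborhood: int = 200_000,
    min_confidence: float = 5.0,
) -> pd.DataFrame:
    """Link DMRs to genes through one regulatory mode.

    promoter: DMR overlaps (>=1 bp) any transcript promoter;
    enhancer: DMR overlaps an enhancer linked to the gene (curated links
    pre-filtered to confidence >= ``min_confidence``);
    neighborhood: DMR within +-``neighborhood`` bp of any TSS.
    Returns one row per (gene, transcript, DMR) link with the DMR's
    coordinates, delta-beta and direction.
    """
    if mode not in REGULATORY_MODES:
        raise ValueError(f"mode must be one of {REGULATORY_MODES}, got {mode!r}")
    rows = []
    if mode == "promoter":
        promoters = build_promoters(gene_models)
        for i, r in dmrs.df.iterrows():
            for prom in promoters:
                if (
                    prom.chrom == r["chrom"]
                    and prom.start < r["end"]
                    and prom.end > r["start"]
                ):
                    rows.append(_link_row(r, i, prom.meta["gene"], prom.meta["transcript"],
                                          prom.meta["tss"], mode))
    elif mode == "neighborhood":
        for i, r in dmrs.df.iterrows():
            sub = gene_models[gene_models["chrom"] == r["chrom"]]
            for _, g in sub.iterrows():
                tss = int(g["tss"])
                # distance from the TSS point to the DMR interval
                dist = max(0, max(r["start"] - tss, tss - (r["end"] - 1)))
                if dist <= neighborhood:
                    rows.append(_link_row(r, i, g["gene"], g["transcript"], tss, mode))
    else:  # enhancer
        if enhancers is None:
            raise ValueError("enhancer mode requires an enhancer link table")
        links = filter_enhancer_links(enhancers, min_confidence)
        tss_lookup = gene_models.groupby("gene").first()
        for i, r in dmrs.df.iterrows():
            sub = links[
                (links["chrom"] == r["chrom"])
                & (links["start"] < r["end"])
                & (links["end"] > r["start"])
            ]
            for _, e in sub.iterrows():
                gene = e["gene"]
                tss = int(tss_lookup.loc[gene, "tss"]) if gene in tss_lookup.index else -1
                tx = tss_lookup.loc[gene, "transcript"] if gene in tss_lookup.index else "."
                rows.append(_link_row(r, i, gene, tx, tss, mode))
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "transcript", "tss", "mode", "dmr_id", "chrom", "start", "end",
            "delta_beta", "direction", "platform", "comparison",
        ],
    )


def _link_row(r: pd.Series, dmr_id, gene, transcript, tss, mode) -> dict:
    return {
        "gene": gene,
        "transcript": transcript,
        "tss": tss,
        "mode": mode,
        "dmr_id": dmr_id,
        "chrom": r["chrom"],
        "start": int(r["start"]),
        "end": int(r["end"]),
        "delta_beta": float(r["delta_beta"]),
        "direction": r["direction"],
        "platform": r["platform"],
        "comparison": r["comparison"],
    }


def cross_platform_validate(
    pairs_array: pd.DataFrame, pairs_tiles: pd.DataFrame, max_gap: int = 5000
) -> pd.DataFrame:
    """Keep (gene, DMR) pairs for which the other platform links a
    same-direction DMR to the same gene within ``max_gap`` bp (inclusive
    boundary: exactly 5,000 bp validates, 5,001 does not)."""

    def validated(rows: pd.DataFrame, other: pd.DataFrame) -> pd.DataFrame:
        keep = []
        for idx, r in rows.iterrows():
            cand = other[
                (other["gene"] == r["gene"])
                & (other["direction"] == r["direction"])
                & (other["chrom"] == r["chrom"])
            ]
            if len(cand):
                gaps = np.maximum(
                    0,
                    np.maximum(cand["start"].to_numpy(), r["start"])
                    - np.minimum(cand["end"].to_numpy(), r["end"]),
                )
                if gaps.min() <= max_gap:
                    keep.append(idx)
        return rows.loc[keep]

    va = validated(pairs_array, pairs_tiles)
    vt = validated(pairs_tiles, pairs_array)
    return pd.concat([va, vt], ignore_index=True)


def count_tad_boundaries(span_start: int, span_end: int, chrom: str, tads: IntervalSet) -> int:
    """Number of TAD edges (starts or ends) strictly inside the open span
    (touching an endpoint does not count)."""
    idx = tads._chrom_index().get(chrom)
    if idx is None:
        return 0
    edges = np.concatenate([idx["starts"], idx["ends"]])
    return int(((edges > span_start) & (edges < span_end)).sum())


def tad_boundary_filter(
    pairs: pd.DataFrame,
    tad_sets: dict[str, IntervalSet],
    mode: str = "literal",
) -> pd.DataFrame:
    """Screen (transcript TSS, DMR) spans against TAD boundaries.

    The span runs from the TSS to the DMR edge closest to it.  In
    ``literal`` mode a gene is retained only when *none* of its pairs
    contains a boundary in *any* TAD set; ``any_clean`` retains a gene
    when at least one pair is boundary-free in every set.  Returns the
    retained pairs.
    """
    if not tad_sets:
        raise ValueError("tad_sets must be non-empty")
    if mode not in ("literal", "any_clean"):
        raise ValueError(f"unknown mode {mode!r}")
    crossing = []
    for idx, r in pairs.iterrows():
        tss = int(r["tss"])
        if r["start"] <= tss < r["end"]:
            span = None  # TSS inside the DMR: no span to screen
        else:
            edge = r["start"] if tss < r["start"] else r["end"]
            span = (min(tss, edge), max(tss, edge))
        n_cross = 0
        if span is not None and span[1] > span[0]:
            for tads in tad_sets.values():
                n_cross += count_tad_boundaries(span[0], span[1], r["chrom"], tads)
        crossing.append(n_cross)
    pairs = pairs.assign(n_boundaries=crossing)
    if mode == "literal":
        bad_genes = set(pairs.loc[pairs["n_boundaries"] > 0, "gene"])
        return pairs[~pairs["gene"].isin(bad_genes)].reset_index(drop=True)
    clean_genes = set(pairs.loc[pairs["n_boundaries"] == 0, "gene"])
    return pairs[pairs["gene"].isin(clean_genes)].reset_index(drop=True)


def classify_dm_de(
    validated_pairs: pd.DataFrame,
    de_array: pd.DataFrame,
    de_seq: pd.DataFrame,
) -> pd.DataFrame:
    """Classify genes by the relation between methylation and expression.

    A gene qualifies when DE-significant with the same log2FC sign on
    both expression platforms for the pair's comparison.  Relation is
    ``opposite`` (DM-DE) when sign(delta-beta) == -sign(log2FC) for all
    supporting DMR links, ``parallel`` when the signs agree for all
    links, and ``mixed`` (excluded from both lists) otherwise.  Returns
    one row per (gene, comparison) with the modes of the supporting
    links.
    """
    rows = []
    if not len(validated_pairs):
        return pd.DataFrame(
            columns=["gene", "comparison", "relation", "log2FC", "modes", "n_links"]
        )
    for (gene, comparison), links in validated_pairs.groupby(["gene", "comparison"]):
        ea = de_array[
            (de_array["gene"] == gene)
            & (de_array["comparison"] == comparison)
            & de_array["significant"]
        ]
        es = de_seq[
            (de_seq["gene"] == gene)
            & (de_seq["comparison"] == comparison)
            & de_seq["significant"]
        ]
        if ea.empty or es.empty:
            continue
        lfc_a = float(ea["log2FC"].iloc[0])
        lfc_s = float(es["log2FC"].iloc[0])
        if np.sign(lfc_a) != np.sign(lfc_s):
            continue
        sign_expr = np.sign(lfc_a)
        signs_dm = set(np.sign(links["delta_beta"]))
        if signs_dm == {-sign_expr}:
            relation = "opposite"
        elif signs_dm == {sign_expr}:
            relation = "parallel"
        else:
            relation = "mixed"
        rows.append(
            {
                "gene": gene,
                "comparison": comparison,
                "relation": relation,
                "log2FC": lfc_a,
                "modes": ",".join(sorted(links["mode"].unique())),
                "n_links": len(links),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene", "comparison", "relation", "log2FC", "modes", "n_links"]
    )
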