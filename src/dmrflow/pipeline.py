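"""End-to-end orchestration of the analysis stages over a synthetic
study, plus recovery metrics against the planted truth.

The stages mirror the analytical flow of a two-platform brain tumor
methylome study: DMR calling on both platforms -> control filtering and
cancer-specific extraction -> TF binding-site enrichment with
cross-platform validation -> TAD-scale shift detection -> developmental
categorization against PSC/FB references -> methylation-expression
integration -> CUT&RUN peak filtering.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import dmr_pipeline, dmde_integration, tad_analysis
from .containers import DMRSet, BetaMatrix
from .cutrun_filter import filter_peaks, peak_high_methylation_fraction, retain_by_evidence, scan_motif
from .developmental_context import (
    build_developmental_matrix,
    call_reference_dmrs,
    categorize_regions,
)
from .genomic_core import IntervalSet, extend_intervals
from .synthetic_data import TUMORS, SyntheticStudy
from .tfbs_enrichment import enrich_tf_sets, validate_across_platforms

TUMOR_COMPARISONS = [("ATRT", "MB"), ("ATRT", "PLEX"), ("MB", "PLEX")]


def flip_dmrset(dmrs: DMRSet) -> DMRSet:
    """The same DMRs stated w.r.t. the second group of the comparison."""
    if not len(dmrs):
        return dmrs
    df = dmrs.df.copy()
    g1, g2 = df["comparison"].iloc[0].split("_vs_")
    df["delta_beta"] = -df["delta_beta"]
    df["direction"] = np.where(df["delta_beta"] > 0, "hyper", "hypo")
    df["comparison"] = f"{g2}_vs_{g1}"
    return DMRSet(df)


def run_dmr_stage(study: SyntheticStudy, probe_pad: int = 500) -> dict:
    """Call DMRs on both platforms, filter array DMRs by the control
    comparisons, and extract cancer-specific hyper/hypo region sets."""
    probes, tiles = study.probes, study.tiles

    array_dmrs: dict[str, DMRSet] = {}
    for g1, g2 in TUMOR_COMPARISONS:
        array_dmrs[f"{g1}_vs_{g2}"] = dmr_pipeline.call_dmrs_probes(probes, g1, g2)
    controls = {
        t: dmr_pipeline.call_dmrs_probes(probes, t, "CONTR") for t in TUMORS
    }
    filtered: dict[str, DMRSet] = {}
    for g1, g2 in TUMOR_COMPARISONS:
        key = f"{g1}_vs_{g2}"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            filtered[key] = dmr_pipeline.filter_by_controls(
                array_dmrs[key], [controls[g1], controls[g2]]
            )

    tile_dmrs: dict[str, DMRSet] = {}
    for g1, g2 in TUMOR_COMPARISONS:
        tile_dmrs[f"{g1}_vs_{g2}"] = dmr_pipeline.call_dmrs_tiles(tiles, g1, g2)

    def comparisons_for(focal: str, sets: dict[str, DMRSet]) -> tuple[DMRSet, DMRSet]:
        pair = []
        for g1, g2 in TUMOR_COMPARISONS:
            key = f"{g1}_vs_{g2}"
            if g1 == focal:
                pair.append(sets[key])
            elif g2 == focal:
                pair.append(flip_dmrset(sets[key]))
        return pair[0], pair[1]

    probe_ivs = probes.intervals()
    specific: dict[tuple[str, str], dict[str, IntervalSet]] = {}
    for focal in TUMORS:
        ab, ac = comparisons_for(focal, filtered)
        specific[(focal, "array")] = dmr_pipeline.extract_cancer_specific(
            ab, ac, "array", probes=probe_ivs, probe_pad=probe_pad
        )
        tb, tc = comparisons_for(focal, tile_dmrs)
        specific[(focal, "tiles")] = dmr_pipeline.extract_cancer_specific(tb, tc, "tiles")

    return {
        "array_dmrs": array_dmrs,
        "array_filtered": filtered,
        "tile_dmrs": tile_dmrs,
        "controls": controls,
        "specific": specific,
        "fourfield": dmr_pipeline.count_direction_fourfield(specific),
    }


def _array_background(study: SyntheticStudy, pad: int = 500) -> IntervalSet:
    return extend_intervals(study.probes.intervals(), pad)


def _tile_background(study: SyntheticStudy) -> IntervalSet:
    from .genomic_core import filter_canonical

    return filter_canonical(study.tiles.intervals())


def _target_subset(background: IntervalSet, regions: IntervalSet) -> IntervalSet:
    """Background units overlapping (>=1 bp) any region, by identity."""
    from .tfbs_enrichment import units_bound

    if len(regions) == 0:
        return IntervalSet()
    mask = units_bound(background, regions)
    return IntervalSet(iv for iv, m in zip(background, mask) if m)


def run_enrichment_stage(study: SyntheticStudy, dmr_results: dict) -> dict:
    """TF enrichment per (cancer, direction) on both platforms, plus
    cross-platform validation."""
    catalog = study.regulatory["catalog"]
    bg_array = _array_background(study)
    bg_tiles = _tile_background(study)
    results_array: dict[tuple[str, str], pd.DataFrame] = {}
    results_tiles: dict[tuple[str, str], pd.DataFrame] = {}
    targets_array: dict[tuple[str, str], IntervalSet] = {}
    targets_tiles: dict[tuple[str, str], IntervalSet] = {}
    for (cancer, platform), sets in dmr_results["specific"].items():
        for direction, regions in sets.items():
            key = (cancer, direction)
            bg = bg_array if platform == "array" else bg_tiles
            target = _target_subset(bg, regions)
            store_r = results_array if platform == "array" else results_tiles
            store_t = targets_array if platform == "array" else targets_tiles
            store_t[key] = target
            if len(target) == 0:
                store_r[key] = pd.DataFrame(
                    columns=["tf", "category", "a", "b", "c", "d", "p", "adj_p", "significant"]
                )
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                store_r[key] = enrich_tf_sets(target, bg, catalog)
    validated = validate_across_platforms(results_array, results_tiles)
    return {
        "array": results_array,
        "tiles": results_tiles,
        "validated": validated,
        "targets_array": targets_array,
        "targets_tiles": targets_tiles,
        "background_array": bg_array,
        "background_tiles": bg_tiles,
    }


def run_tad_stage(study: SyntheticStudy, dmr_results: dict, probe_pad: int = 500) -> pd.DataFrame:
    """Large-scale TAD detection for every tumor comparison."""
    probe_ivs = study.probes.intervals()
    frames = []
    for g1, g2 in TUMOR_COMPARISONS:
        key = f"{g1}_vs_{g2}"
        units_array = dmr_pipeline.dmr_member_probes(
            dmr_results["array_filtered"][key], probe_ivs, pad=probe_pad
        )
        units_tiles = dmr_results["tile_dmrs"][key].intervals()
        for iv in units_tiles:
            iv.meta["delta_beta"] = iv.meta.get("delta_beta", 0.0)
        frames.append(
            tad_analysis.detect_largescale_tads(
                units_array, units_tiles, study.regulatory["tad_sets"], comparison=key
            )
        )
    return pd.concat(frames, ignore_index=True)


def run_developmental_stage(study: SyntheticStudy, dmr_results: dict) -> dict:
    """Reference DMRs vs PSC/FB, the developmental matrix, and category
    assignment for the array cancer-specific regions."""
    probes = study.probes
    reference = call_reference_dmrs(
        probes.subset_groups(list(TUMORS)),
        probes.subset_groups(["PSC"]),
        probes.subset_groups(["FB"]),
    )
    cancer_specific = {
        (cancer, direction): sets[direction]
        for (cancer, platform), sets in dmr_results["specific"].items()
        if platform == "array"
        for direction in ("hyper", "hypo")
    }
    matrix = build_developmental_matrix(cancer_specific, reference)
    categories = categorize_regions(matrix) if len(matrix) else pd.Series(dtype=object)
    return {"reference": reference, "matrix": matrix, "categories": categories}


def run_dmde_stage(study: SyntheticStudy, dmr_results: dict, max_adj_p: float = 0.05) -> dict:
    """DE calling on both expression platforms, DMR-gene linking through
    promoters and enhancers, cross-platform validation, TAD-boundary
    screening, and DM-DE classification."""
    expr = study.expression
    gene_models = study.regulatory["gene_models"]
    enhancers = study.regulatory["enhancers"]
    tad_sets = study.regulatory["tad_sets"]

    de_array, de_seq = [], []
    for g1, g2 in TUMOR_COMPARISONS:
        de_array.append(
            dmde_integration.call_de_genes(
                expr["array"], expr["groups"], g1, g2, "array", max_adj_p=max_adj_p
            )
        )
        de_seq.append(
            dmde_integration.call_de_genes(
                expr["counts"], expr["groups"], g1, g2, "rnaseq",
                max_adj_p=max_adj_p, is_counts=True,
            )
        )
    de_array = pd.concat(de_array, ignore_index=True)
    de_seq = pd.concat(de_seq, ignore_index=True)

    classified = []
    for g1, g2 in TUMOR_COMPARISONS:
        key = f"{g1}_vs_{g2}"
        pairs_by_platform = {}
        for platform, dmrs in (
            ("array", dmr_results["array_filtered"][key]),
            ("tiles", dmr_results["tile_dmrs"][key]),
        ):
            frames = [
                dmde_integration.link_dmrs_to_genes(dmrs, gene_models, enhancers, mode)
                for mode in ("promoter", "enhancer")
            ]
            pairs_by_platform[platform] = pd.concat(frames, ignore_index=True)
        validated = dmde_integration.cross_platform_validate(
            pairs_by_platform["array"], pairs_by_platform["tiles"]
        )
        if len(validated):
            validated = dmde_integration.tad_boundary_filter(validated, tad_sets, mode="literal")
        classified.append(dmde_integration.classify_dm_de(validated, de_array, de_seq))
    classified = pd.concat(classified, ignore_index=True)
    return {"de_array": de_array, "de_seq": de_seq, "classified": classified}


def run_cutrun_stage(study: SyntheticStudy, dmr_results: dict) -> dict:
    """Filter the CUT&RUN peak sets, retain by catalog/motif evidence, and
    summarize retained peaks against the DMR classes."""
    cr = study.cutrun
    out = {}
    dmr_classes = {
        f"{cancer}_{direction}_{platform}": sets[direction]
        for (cancer, platform), sets in dmr_results["specific"].items()
        for direction in ("hyper", "hypo")
    }
    for sample, parts in cr["samples"].items():
        peaks = filter_peaks(parts["replicates"], cr["control_peaks"])
        flags = scan_motif(cr["sequences"][sample], cr["pwm"])
        retained = retain_by_evidence(peaks, cr["gtrd_sites"], flags)
        from .cutrun_filter import peaks_vs_dmr_classes

        class_counts = peaks_vs_dmr_classes(retained, dmr_classes, sample=sample)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            high_frac = peak_high_methylation_fraction(retained, study.probes, "ATRT")
        out[sample] = {
            "peaks": peaks,
            "retained": retained,
            "class_counts": class_counts,
            "high_meth_fraction_ATRT": high_frac,
        }
    return out


# ---------------------------------------------------------------------------
# recovery metrics vs the planted truth
# ---------------------------------------------------------------------------

def tile_dmr_recovery(study: SyntheticStudy, tile_dmrs: dict[str, DMRSet]) -> dict:
    """Sensitivity and observed FDR of the tile caller against the planted
    truth, pooled over the tumor comparisons that carry each planted
    region."""
    planted = study.truth_dmrs
    truth_keys = set()
    for _, r in planted.iterrows():
        n_tiles = (r["end"] - r["start"]) // study.config.genome.tile_size
        for i in range(int(n_tiles)):
            s = int(r["start"]) + i * study.config.genome.tile_size
            for g1, g2 in TUMOR_COMPARISONS:
                if r["tumor"] in (g1, g2):
                    truth_keys.add((f"{g1}_vs_{g2}", r["chrom"], s))
    called = set()
    for key, dmrs in tile_dmrs.items():
        for _, r in dmrs.df.iterrows():
            called.add((key, r["chrom"], int(r["start"])))
    tp = len(called & truth_keys)
    fp = len(called - truth_keys)
    fn = len(truth_keys - called)
    return {
        "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
        "fdr": fp / (tp + fp) if (tp + fp) else 0.0,
        "n_true": len(truth_keys),
        "n_called": len(called),
    }


def probe_dmr_recovery(study: SyntheticStudy, array_dmrs: dict[str, DMRSet]) -> dict:
    """Fraction of planted regions recovered by the array caller (>=1 bp
    overlap, matching direction) in each comparison carrying them, and the
    mean |delta-beta error| of the recovered regions."""
    planted = study.truth_dmrs
    n_true, n_found, errs = 0, 0, []
    for _, r in planted.iterrows():
        for g1, g2 in TUMOR_COMPARISONS:
            if r["tumor"] not in (g1, g2):
                continue
            n_true += 1
            sign = 1.0 if r["tumor"] == g1 else -1.0
            want_dir = r["direction"] if sign > 0 else ("hypo" if r["direction"] == "hyper" else "hyper")
            dmrs = array_dmrs[f"{g1}_vs_{g2}"].df
            hit = dmrs[
                (dmrs["chrom"] == r["chrom"])
                & (dmrs["start"] < r["end"])
                & (dmrs["end"] > r["start"])
                & (dmrs["direction"] == want_dir)
            ]
            if len(hit):
                n_found += 1
                errs.append(abs(abs(hit["delta_beta"]).max() - r["delta"]))
    return {
        "sensitivity": n_found / n_true if n_true else float("nan"),
        "mean_abs_delta_error": float(np.mean(errs)) if errs else float("nan"),
        "n_true": n_true,
    }


def category_recovery(study: SyntheticStudy, dev: dict) -> dict:
    """Exact-label agreement between planted developmental categories and
    the bp-majority category of the atoms covering each planted region."""
    planted = study.truth_dmrs
    planted = planted[~planted["largescale"] & (planted["cluster_id"] == "")]
    matrix, categories = dev["matrix"], dev["categories"]
    if not len(matrix):
        return {"agreement": float("nan"), "n": 0}
    n, agree = 0, 0
    for _, r in planted.iterrows():
        sub = matrix[
            (matrix["cancer"] == r["tumor"])
            & (matrix["direction"] == r["direction"])
            & (matrix["chrom"] == r["chrom"])
            & (matrix["start"] < r["end"])
            & (matrix["end"] > r["start"])
        ]
        if sub.empty:
            continue
        n += 1
        weights = (
            np.minimum(sub["end"], r["end"]) - np.maximum(sub["start"], r["start"])
        ).astype(float)
        label_bp: dict[str, float] = {}
        for idx, w in zip(sub.index, weights):
            label_bp[categories[idx]] = label_bp.get(categories[idx], 0.0) + w
        best = max(label_bp, key=label_bp.get)
        if best == r["category"]:
            agree += 1
    return {"agreement": agree / n if n else float("nan"), "n": n}


def dmde_recovery(study: SyntheticStudy, classified: pd.DataFrame) -> dict:
    """Planted opposite-gene recovery and parallel-gene mislabel count."""
    truth = study.regulatory["dmde_truth"]
    opp = truth[truth["relation"] == "opposite"]
    par = truth[truth["relation"] == "parallel"]
    recovered = 0
    for _, r in opp.iterrows():
        hits = classified[
            (classified["gene"] == r["gene"])
            & (classified["relation"] == "opposite")
            & classified["comparison"].str.contains(r["tumor"])
        ]
        if len(hits):
            recovered += 1
    mislabeled = int(
        classified[
            classified["gene"].isin(par["gene"]) & (classified["relation"] == "opposite")
        ]["gene"].nunique()
    )
    return {
        "opposite_recovery": recovered / len(opp) if len(opp) else float("nan"),
        "n_opposite_planted": len(opp),
        "parallel_mislabeled_opposite": mislabeled,
        "n_parallel_planted": len(par),
    }


def tad_recovery(study: SyntheticStudy, largescale: pd.DataFrame) -> dict:
    """Detected large-scale TADs vs the planted clusters (>= 5 units)."""
    truth = study.truth_dmrs
    clusters = truth[truth["largescale"]].groupby("cluster_id")
    n_expected, n_found = 0, 0
    for _, sub in clusters:
        tumor = sub["tumor"].iloc[0]
        direction = sub["direction"].iloc[0]
        chrom = sub["chrom"].iloc[0]
        lo, hi = sub["start"].min(), sub["end"].max()
        for g1, g2 in TUMOR_COMPARISONS:
            if tumor not in (g1, g2):
                continue
            n_expected += 1
            want_dir = direction if tumor == g1 else ("hypo" if direction == "hyper" else "hyper")
            hit = largescale[
                (largescale["comparison"] == f"{g1}_vs_{g2}")
                & (largescale["chrom"] == chrom)
                & (largescale["direction"] == want_dir)
                & (largescale["start"] < hi)
                & (largescale["end"] > lo)
            ]
            if len(hit):
                n_found += 1
    return {
        "expected": n_expected,
        "found": n_found,
        "n_flagged_total": len(largescale),
    }


def enrichment_recovery(study: SyntheticStudy, enrich: dict) -> dict:
    """Rank and adjusted p of the planted TF in its target class on both
    platforms, and whether it survives cross-platform validation."""
    tf = study.config.tfs.planted_tf
    cancer, direction = study.config.tfs.planted_target
    key = (cancer, direction)
    out = {"tf": tf, "validated": tf in enrich["validated"].get(key, set())}
    for platform in ("array", "tiles"):
        res = enrich[platform].get(key, pd.DataFrame())
        if len(res):
            res = res.sort_values("p").reset_index(drop=True)
            row = res[res["tf"] == tf]
            out[f"{platform}_rank"] = int(row.index[0]) + 1 if len(row) else None
            out[f"{platform}_adj_p"] = float(row["adj_p"].iloc[0]) if len(row) else None
        else:
            out[f"{platform}_rank"] = None
            out[f"{platform}_adj_p"] = None
    return out


def null_calibration(study: SyntheticStudy, comparison: tuple[str, str] = ("ATRT", "MB"),
                     max_tiles: int = 5000) -> dict:
    """Uniformity of the tile-test p-values over the study's *non-planted*
    tiles (which carry no group difference): KS statistic/p against
    Uniform(0,1) and the raw fraction below 0.05."""
    from scipy import stats as sps

    from .containers import TileCounts
    from .dmr_pipeline import tile_test_statistics
    from .genomic_core import is_canonical

    tiles = study.tiles
    g1, g2 = comparison
    used = tiles.samples_of(g1) + tiles.samples_of(g2)
    keep = (tiles.total[used] >= 10).all(axis=1)
    keep &= tiles.coords["chrom"].map(is_canonical)
    planted = study.truth_dmrs
    if len(planted):
        planted_mask = pd.Series(False, index=tiles.coords.index)
        for _, r in planted.iterrows():
            planted_mask |= (
                (tiles.coords["chrom"] == r["chrom"])
                & (tiles.coords["start"] >= r["start"])
                & (tiles.coords["end"] <= r["end"])
            )
        keep &= ~planted_mask
    sub = TileCounts(
        tiles.meth.loc[keep].iloc[:max_tiles],
        tiles.total.loc[keep].iloc[:max_tiles],
        tiles.coords.loc[keep].iloc[:max_tiles],
        tiles.groups,
    )
    res = tile_test_statistics(sub, g1, g2)
    ks = sps.kstest(res["p"].to_numpy(), "uniform")
    return {
        "n_tiles": len(res),
        "ks_stat": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "frac_p_below_0.05": float((res["p"] < 0.05).mean()),
    }


def run_all(study: SyntheticStudy) -> dict:
    """Run every stage and attach the recovery report."""
    dmr_results = run_dmr_stage(study)
    enrich = run_enrichment_stage(study, dmr_results)
    largescale = run_tad_stage(study, dmr_results)
    dev = run_developmental_stage(study, dmr_results)
    dmde = run_dmde_stage(study, dmr_results)
    cutrun = run_cutrun_stage(study, dmr_results)
    report = {
        "null_calibration": null_calibration(study),
        "tile_dmr": tile_dmr_recovery(study, dmr_results["tile_dmrs"]),
        "probe_dmr": probe_dmr_recovery(study, dmr_results["array_dmrs"]),
        "enrichment": enrichment_recovery(study, enrich),
        "tads": tad_recovery(study, largescale),
        "developmental": category_recovery(study, dev),
        "dmde": dmde_recovery(study, dmde["classified"]),
    }
    return {
        "dmr": dmr_results,
        "enrichment": enrich,
        "largescale": largescale,
        "developmental": dev,
        "dmde": dmde,
        "cutrun": cutrun,
        "report": report,
    }
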