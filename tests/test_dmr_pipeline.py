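"""DMR calling, control filtering and cancer-specific extraction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dmrflow.containers import DMR_COLS, BetaMatrix, DMRSet, TileCounts
from dmrflow.dmr_pipeline import (
    call_dmrs_probes,
    call_dmrs_tiles,
    count_direction_fourfield,
    extract_cancer_specific,
    filter_by_controls,
    residualize_covariate,
    tile_test_statistics,
)
from dmrflow.genomic_core import GenomicInterval, IntervalSet
from dmrflow.synthetic_data import StudyConfig, design_study, generate_methylomes, null_config


def tile_counts_from_beta(beta_true, depth, rng, groups):
    n_tiles, n_samples = beta_true.shape
    total = rng.poisson(depth, size=(n_tiles, n_samples)) + 1
    meth = rng.binomial(total, beta_true)
    samples = list(groups.index)
    coords = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n_tiles) * 1000,
            "end": (np.arange(n_tiles) + 1) * 1000,
        },
        index=[f"t{i}" for i in range(n_tiles)],
    )
    return TileCounts(
        pd.DataFrame(meth, index=coords.index, columns=samples),
        pd.DataFrame(total, index=coords.index, columns=samples),
        coords,
        groups,
    )


def two_groups(n1=10, n2=10):
    labels = {f"a{i}": "G1" for i in range(n1)}
    labels.update({f"b{i}": "G2" for i in range(n2)})
    return pd.Series(labels)


class TestTileCaller:
    def test_low_coverage_tile_excluded(self):
        rng = np.random.default_rng(0)
        groups = two_groups(3, 3)
        counts = tile_counts_from_beta(np.full((5, 6), 0.5), 30, rng, groups)
        counts.total.iloc[2, 0] = 9  # one sample at coverage 9
        counts.meth.iloc[2, 0] = min(counts.meth.iloc[2, 0], 9)
        dmrs = call_dmrs_tiles(counts, "G1", "G2", min_delta=0.0, max_q=1.01)
        assert "t2" not in set(
            counts.coords.index[counts.coords["start"].isin(dmrs.df["start"] // 1)]
        ) or len(dmrs.df[dmrs.df["start"] == 2000]) == 0

    def test_noncanonical_tiles_removed(self):
        rng = np.random.default_rng(1)
        groups = two_groups(3, 3)
        counts = tile_counts_from_beta(
            np.tile([[0.1] * 3 + [0.9] * 3], (4, 1)), 50, rng, groups
        )
        counts.coords.loc[counts.coords.index[0], "chrom"] = "chrX"
        counts.coords.loc[counts.coords.index[1], "chrom"] = "chrUn_scaffold1"
        dmrs = call_dmrs_tiles(counts, "G1", "G2")
        assert set(dmrs.df["chrom"]) <= {"chr1"}
        assert len(dmrs) == 2

    def test_null_significant_fraction_bounded(self):
        rng = np.random.default_rng(23)
        groups = two_groups()
        mu = rng.uniform(0.2, 0.8, size=2000)
        beta_true = np.clip(
            rng.beta(mu[:, None] * 60, (1 - mu[:, None]) * 60, size=(2000, 20)), 1e-4, 1
        )
        counts = tile_counts_from_beta(beta_true, 30, rng, groups)
        res = tile_test_statistics(counts, "G1", "G2")
        frac = (res["p"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(res))
        assert frac <= 0.05 + 3 * se

    def test_planted_recovery(self):
        rng = np.random.default_rng(31)
        groups = two_groups()
        mu = rng.uniform(0.2, 0.5, size=500)
        beta_true = np.clip(
            rng.beta(mu[:, None] * 60, (1 - mu[:, None]) * 60, size=(500, 20)), 1e-4, 1
        )
        planted = np.arange(0, 50)
        mu_shift = np.clip(mu[planted] + 0.4, None, 0.97)
        beta_true[np.ix_(planted, np.arange(10))] = np.clip(
            rng.beta(mu_shift[:, None] * 60, (1 - mu_shift[:, None]) * 60, size=(50, 10)),
            1e-4, 1,
        )
        counts = tile_counts_from_beta(beta_true, 30, rng, groups)
        dmrs = call_dmrs_tiles(counts, "G1", "G2")
        called = set(dmrs.df["start"] // 1000)
        tp = len(called & set(planted))
        fp = len(called - set(planted))
        assert tp / len(planted) >= 0.9
        assert fp / max(1, len(called)) <= 0.1

    def test_group_too_small_rejected(self):
        rng = np.random.default_rng(2)
        groups = pd.Series({"a0": "G1", "b0": "G2", "b1": "G2"})
        counts = tile_counts_from_beta(np.full((3, 3), 0.5), 30, rng, groups)
        with pytest.raises(ValueError):
            call_dmrs_tiles(counts, "G1", "G2")


def probe_matrix(deltas, groups, rng, spacing=200, start=1000, sd_conc=60):
    """Probes on chr1 with per-probe group-mean difference ``deltas``."""
    n = len(deltas)
    base = rng.uniform(0.3, 0.5, size=n)
    rows, coords = [], []
    for i, d in enumerate(deltas):
        mu1, mu2 = np.clip(base[i] + d, 0.02, 0.98), base[i]
        v1 = rng.beta(mu1 * sd_conc, (1 - mu1) * sd_conc, size=(groups == "G1").sum())
        v2 = rng.beta(mu2 * sd_conc, (1 - mu2) * sd_conc, size=(groups == "G2").sum())
        rows.append(np.concatenate([v1, v2]))
        s = start + i * spacing
        coords.append((f"p{i}", "chr1", s, s + 50))
    beta = pd.DataFrame(rows, index=[c[0] for c in coords], columns=groups.index)
    cdf = pd.DataFrame([c[1:] for c in coords], index=beta.index,
                       columns=["chrom", "start", "end"])
    return BetaMatrix(np.clip(beta, 1e-4, 1 - 1e-4), cdf, groups)


class TestProbeCaller:
    def test_region_below_final_delta_excluded(self):
        rng = np.random.default_rng(41)
        groups = two_groups(12, 12)
        bm = probe_matrix([0.19] * 6, groups, rng, sd_conc=8000)
        dmrs = call_dmrs_probes(bm, "G1", "G2", betacutoff=0.05, final_delta=0.20)
        assert len(dmrs) == 0
        dmrs_low = call_dmrs_probes(bm, "G1", "G2", betacutoff=0.05, final_delta=0.15)
        assert len(dmrs_low) == 1

    def test_merge_gap_boundary_splits(self):
        rng = np.random.default_rng(43)
        groups = two_groups(10, 10)
        # two probes 1,001 bp apart (gap from end of first to start of second)
        bm = probe_matrix([0.4, 0.4], groups, rng, spacing=1051, sd_conc=4000)
        gap = bm.coords.iloc[1]["start"] - bm.coords.iloc[0]["end"]
        assert gap == 1001
        dmrs = call_dmrs_probes(bm, "G1", "G2", merge_gap=1000)
        assert len(dmrs) == 2
        dmrs_wide = call_dmrs_probes(bm, "G1", "G2", merge_gap=1001)
        assert len(dmrs_wide) == 1

    def test_planted_region_recovered_with_delta(self):
        rng = np.random.default_rng(47)
        groups = two_groups(10, 10)
        bm = probe_matrix([0.0] * 4 + [0.4] * 8 + [0.0] * 4, groups, rng, spacing=150)
        dmrs = call_dmrs_probes(bm, "G1", "G2")
        assert len(dmrs) == 1
        assert dmrs.df.loc[0, "n_units"] == 8
        assert dmrs.df.loc[0, "delta_beta"] == pytest.approx(0.4, abs=0.05)
        assert dmrs.df.loc[0, "direction"] == "hyper"

    def test_confounded_covariate_skipped_with_warning(self):
        groups = two_groups(4, 4)
        beta = pd.DataFrame(np.random.default_rng(0).uniform(size=(5, 8)),
                            columns=groups.index)
        with pytest.warns(UserWarning):
            adj = residualize_covariate(beta, groups.copy(), groups)
        pd.testing.assert_frame_equal(adj, beta)

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(53)
        groups = two_groups(8, 8)
        bm = probe_matrix(rng.uniform(-0.4, 0.4, size=60), groups, rng, spacing=400)
        n_loose = len(call_dmrs_probes(bm, "G1", "G2", final_delta=0.1, max_fdr=0.1))
        n_tight = len(call_dmrs_probes(bm, "G1", "G2", final_delta=0.3, max_fdr=0.01))
        assert n_tight <= n_loose


def dmr_from_tuples(rows, platform="array", comparison="A_vs_B"):
    df = pd.DataFrame(
        [
            {
                "chrom": c, "start": s, "end": e, "delta_beta": d,
                "q": 0.01, "direction": "hyper" if d > 0 else "hypo",
                "n_units": 1, "platform": platform, "comparison": comparison,
            }
            for (c, s, e, d) in rows
        ],
        columns=DMR_COLS,
    )
    return DMRSet(df)


class TestControlFilter:
    def test_intersection_example(self):
        main = dmr_from_tuples([("chr1", 1000, 2000, 0.3)])
        ctrl = dmr_from_tuples([("chr1", 1500, 3000, 0.3)], comparison="A_vs_CONTR")
        out = filter_by_controls(main, [ctrl])
        assert [(r["start"], r["end"]) for _, r in out.df.iterrows()] == [(1500, 2000)]
        assert out.df.loc[0, "delta_beta"] == pytest.approx(0.3)

    def test_no_overlap_dropped_and_two_spans(self):
        main = dmr_from_tuples([("chr1", 1000, 2000, 0.3), ("chr2", 0, 500, 0.3)])
        ctrl = dmr_from_tuples(
            [("chr1", 1100, 1300, 0.2), ("chr1", 1600, 1900, 0.2)],
            comparison="A_vs_CONTR",
        )
        out = filter_by_controls(main, [ctrl])
        spans = [(r["chrom"], r["start"], r["end"]) for _, r in out.df.iterrows()]
        assert spans == [("chr1", 1100, 1300), ("chr1", 1600, 1900)]

    def test_empty_controls_warns_and_passes_through(self):
        main = dmr_from_tuples([("chr1", 0, 100, 0.3)])
        with pytest.warns(UserWarning):
            out = filter_by_controls(main, [])
        assert len(out) == 1


class TestCancerSpecific:
    def make_probes(self, positions):
        return IntervalSet(
            [GenomicInterval("chr1", p, p + 50, meta={"name": f"p{i}"})
             for i, p in enumerate(positions)]
        )

    def test_array_overlap_boundary_600(self):
        # one probe per comparison; extended probes (1,050 bp each) overlap
        # by exactly 600 bp when probe starts differ by 450
        probes = self.make_probes([10_000, 10_450])
        ab = dmr_from_tuples([("chr1", 9_990, 10_060, 0.3)], comparison="A_vs_B")
        ac = dmr_from_tuples([("chr1", 10_440, 10_510, 0.3)], comparison="A_vs_C")
        out = extract_cancer_specific(ab, ac, "array", probes=probes)
        assert len(out["hyper"]) == 1 and len(out["hypo"]) == 0
        # one bp further apart -> 599 bp overlap -> excluded
        probes2 = self.make_probes([10_000, 10_451])
        ac2 = dmr_from_tuples([("chr1", 10_441, 10_511, 0.3)], comparison="A_vs_C")
        out2 = extract_cancer_specific(ab, ac2, "array", probes=probes2)
        assert len(out2["hyper"]) == 0

    def test_direction_conflict_excluded(self):
        probes = self.make_probes([10_000, 10_100])
        ab = dmr_from_tuples([("chr1", 9_990, 10_060, 0.3)], comparison="A_vs_B")
        ac = dmr_from_tuples([("chr1", 10_090, 10_160, -0.3)], comparison="A_vs_C")
        out = extract_cancer_specific(ab, ac, "array", probes=probes)
        assert len(out["hyper"]) == 0 and len(out["hypo"]) == 0

    def test_tiles_require_exact_identity(self):
        ab = dmr_from_tuples([("chr1", 1000, 2000, 0.3), ("chr1", 3000, 4000, 0.3)],
                             platform="tiles", comparison="A_vs_B")
        ac = dmr_from_tuples([("chr1", 1000, 2000, 0.3), ("chr1", 3500, 4500, 0.3)],
                             platform="tiles", comparison="A_vs_C")
        out = extract_cancer_specific(ab, ac, "tiles")
        assert [(iv.start, iv.end) for iv in out["hyper"]] == [(1000, 2000)]

    def test_low_delta_inputs_ignored(self):
        ab = dmr_from_tuples([("chr1", 1000, 2000, 0.2)], platform="tiles")
        ac = dmr_from_tuples([("chr1", 1000, 2000, 0.2)], platform="tiles",
                             comparison="A_vs_C")
        out = extract_cancer_specific(ab, ac, "tiles")
        assert len(out["hyper"]) == 0

    def test_mismatched_focal_group_rejected(self):
        ab = dmr_from_tuples([("chr1", 0, 100, 0.3)], comparison="A_vs_B")
        cb = dmr_from_tuples([("chr1", 0, 100, 0.3)], comparison="C_vs_B")
        with pytest.raises(ValueError):
            extract_cancer_specific(ab, cb, "tiles")


class TestFourField:
    def test_empty_and_arithmetic(self):
        empty = count_direction_fourfield({})
        assert len(empty) == 0
        sets = {
            ("A", "array"): {
                "hyper": IntervalSet(
                    [GenomicInterval("chr1", i * 100, i * 100 + 50) for i in range(99)]
                ),
                "hypo": IntervalSet([GenomicInterval("chr1", 0, 50)]),
            }
        }
        out = count_direction_fourfield(sets).set_index("direction")
        assert out.loc["hyper", "count"] == 99
        assert out.loc["hyper", "pct"] == pytest.approx(99.0)
        assert out.loc["hypo", "pct"] == pytest.approx(1.0)

    def test_planted_hyper_bias_recovered(self, results):
        ff = results["dmr"]["fourfield"].set_index(["cancer", "platform", "direction"])
        for platform in ("array", "tiles"):
            assert ff.loc[("ATRT", platform, "hyper"), "pct"] > 50.0
            assert ff.loc[("MB", platform, "hypo"), "pct"] > 50.0


def test_null_pvalues_uniform_ks():
    """With no planted effects the tile-test p-values are ~Uniform(0,1)."""
    cfg = null_config()
    plan = design_study(cfg, 1)
    _, tiles, _ = generate_methylomes(cfg, 1, plan)
    used = tiles.samples_of("ATRT") + tiles.samples_of("MB")
    keep = (tiles.total[used] >= 10).all(axis=1) & tiles.coords["chrom"].map(
        lambda c: c.startswith("chr") and c[3:].isdigit()
    )
    sub = TileCounts(
        tiles.meth.loc[keep].iloc[:5000], tiles.total.loc[keep].iloc[:5000],
        tiles.coords.loc[keep].iloc[:5000], tiles.groups,
    )
    res = tile_test_statistics(sub, "ATRT", "MB")
    assert stats.kstest(res["p"], "uniform").pvalue > 0.01
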