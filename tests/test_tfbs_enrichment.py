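"""TF binding-site enrichment, co-localization and methylation summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln, logsumexp

from dmrflow.containers import BetaMatrix
from dmrflow.genomic_core import GenomicInterval, IntervalSet
from dmrflow.tfbs_enrichment import (
    ALL_CATEGORIES,
    SAMPLE_CATEGORIES,
    BindingSiteCatalog,
    binding_site_methylation,
    categorized_enrichment,
    clusterwise_enrichment,
    colocalization_matrix,
    enrich_tf_sets,
    fisher_one_sided,
    units_bound,
    validate_across_platforms,
)


def fisher_oracle(a, b, c, d):
    """Hypergeometric upper-tail sum via log-gamma — independent oracle."""
    N, r, k = a + b + c + d, a + b, a + c

    def log_comb(n, x):
        return gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)

    hi = min(r, k)
    xs = np.arange(a, hi + 1)
    if len(xs) == 0:
        return 1.0
    terms = log_comb(k, xs) + log_comb(N - k, r - xs) - log_comb(N, r)
    return float(np.exp(logsumexp(terms)))


class TestFisher:
    def test_extreme_tables(self):
        import math

        assert fisher_one_sided(10, 0, 0, 10) == pytest.approx(
            1 / math.comb(20, 10), rel=1e-12
        )
        assert fisher_one_sided(0, 10, 10, 0) == pytest.approx(1.0)

    def test_random_tables_match_log_gamma_oracle(self):
        rng = np.random.default_rng(29)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 60, size=4)
            got = fisher_one_sided(int(a), int(b), int(c), int(d))
            want = fisher_oracle(int(a), int(b), int(c), int(d))
            assert got == pytest.approx(want, rel=1e-12, abs=1e-300)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fisher_one_sided(-1, 0, 0, 0)


def unit_grid(n, chrom="chr1", width=1000):
    return IntervalSet(
        [GenomicInterval(chrom, i * width, i * width + width, meta={"name": f"u{i}"})
         for i in range(n)]
    )


def catalog_from_sites(site_map):
    rows = []
    for tf, ivs in site_map.items():
        for (chrom, s, e) in ivs:
            rows.append({"tf": tf, "chrom": chrom, "start": s, "end": e,
                         "category": "psc", "source": "test"})
    return BindingSiteCatalog(pd.DataFrame(rows))


class TestEnrich:
    def test_tf_covering_every_unit_p_one(self):
        bg = unit_grid(20)
        target = IntervalSet(list(bg)[:5])
        cat = catalog_from_sites({"T": [("chr1", 0, 20_000)]})
        res = enrich_tf_sets(target, bg, cat)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_counts_sum_to_background(self):
        rng = np.random.default_rng(5)
        bg = unit_grid(50)
        target = IntervalSet([iv for iv in bg if rng.random() < 0.3])
        cat = catalog_from_sites(
            {"T": [("chr1", int(s), int(s) + 100) for s in rng.integers(0, 49_000, 10)]}
        )
        res = enrich_tf_sets(target, bg, cat)
        assert (res[["a", "b", "c", "d"]].sum(axis=1) == 50).all()

    def test_planted_enrichment_recovered(self):
        rng = np.random.default_rng(77)
        bg = unit_grid(500)
        target_units = list(bg)[:50]
        target = IntervalSet(target_units)
        sites_hot = [("chr1", iv.start + 100, iv.start + 300) for iv in target_units[:30]]
        sites_cold = [("chr1", int(s), int(s) + 200)
                      for s in rng.integers(50_000, 499_000, 30)]
        cat = catalog_from_sites({"HOT": sites_hot, "COLD": sites_cold})
        res = enrich_tf_sets(target, bg, cat).set_index("tf")
        assert res.loc["HOT", "adj_p"] < 0.05
        assert res.loc["COLD", "adj_p"] > 0.05

    def test_zero_site_tf_omitted_with_warning(self):
        bg = unit_grid(10)
        cat = catalog_from_sites({"T": [("chr2", 0, 100)], "E": [("chr1", 0, 100)]})
        cat.df = cat.df[cat.df["tf"] == "E"]  # T has no rows at all now
        with pytest.warns(UserWarning):
            res = enrich_tf_sets(IntervalSet(list(bg)[:2]), bg, cat, tfs=["T", "E"])
        assert list(res["tf"]) == ["E"]

    def test_target_not_subset_rejected(self):
        bg = unit_grid(10)
        stranger = IntervalSet([GenomicInterval("chr9", 0, 10, meta={"name": "zz"})])
        cat = catalog_from_sites({"T": [("chr1", 0, 100)]})
        with pytest.raises(ValueError):
            enrich_tf_sets(stranger, bg, cat)

    def test_null_false_significance_rate(self):
        """Uniformly placed sites: raw p < 0.05 in about 5% of TFs."""
        rng = np.random.default_rng(101)
        bg = unit_grid(2000)
        target = IntervalSet(list(bg)[:200])
        site_map = {
            f"T{k}": [("chr1", int(s), int(s) + 150)
                      for s in rng.integers(0, 1_999_000, 40)]
            for k in range(200)
        }
        res = enrich_tf_sets(target, bg, catalog_from_sites(site_map))
        frac = (res["p"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(res))
        assert frac <= 0.05 + 3 * se


class TestCategorized:
    def test_all_category_reproduces_plain_run(self):
        rng = np.random.default_rng(55)
        bg = unit_grid(100)
        target = IntervalSet(list(bg)[:20])
        rows = []
        for tf in ("A", "B"):
            for s in rng.integers(0, 99_000, 15):
                rows.append({"tf": tf, "chrom": "chr1", "start": int(s),
                             "end": int(s) + 120,
                             "category": SAMPLE_CATEGORIES[int(rng.integers(11))],
                             "source": "t"})
        cat = BindingSiteCatalog(pd.DataFrame(rows))
        plain = enrich_tf_sets(target, bg, cat)
        full = categorized_enrichment(target, bg, cat)
        sub = full[(full["category"] == ALL_CATEGORIES) & full["measured"]]
        merged = sub.merge(plain, on="tf", suffixes=("_cat", "_plain"))
        assert np.allclose(merged["p_cat"], merged["p_plain"])

    def test_unmeasured_categories_flagged(self):
        cat = catalog_from_sites({"T": [("chr1", 0, 100)]})  # only category 'psc'
        bg = unit_grid(10)
        full = categorized_enrichment(IntervalSet(list(bg)[:2]), bg, cat)
        t_rows = full[full["tf"] == "T"].set_index("category")
        assert bool(t_rows.loc["psc", "measured"])
        assert not bool(t_rows.loc["blood", "measured"])
        assert t_rows["measured"].sum() == 2  # 'psc' and the All* run


class TestValidation:
    def test_platform_intersection(self):
        res_a = {("A", "hyper"): pd.DataFrame({"tf": ["X", "Y"], "adj_p": [0.01, 0.2]})}
        res_t = {("A", "hyper"): pd.DataFrame({"tf": ["X", "Y"], "adj_p": [0.04, 0.01]})}
        out = validate_across_platforms(res_a, res_t)
        assert out[("A", "hyper")] == {"X"}

    def test_empty_side_gives_empty(self):
        res_a = {("A", "hyper"): pd.DataFrame({"tf": [], "adj_p": []})}
        res_t = {("A", "hyper"): pd.DataFrame({"tf": ["X"], "adj_p": [0.01]})}
        assert validate_across_platforms(res_a, res_t)[("A", "hyper")] == set()


class TestColocalization:
    def test_identical_sets_minimal_p(self):
        regions = unit_grid(40)
        shared = [("chr1", i * 1000 + 100, i * 1000 + 300) for i in range(20)]
        rng = np.random.default_rng(3)
        cat = catalog_from_sites({
            "A": shared, "B": shared,
            "C": [("chr1", int(s), int(s) + 100) for s in rng.integers(0, 39_000, 8)],
        })
        m = colocalization_matrix(["A", "B", "C"], regions, cat)
        off = [m.loc["A", "B"], m.loc["A", "C"], m.loc["B", "C"]]
        assert m.loc["A", "B"] == min(off)
        assert np.allclose(m.values, m.values.T)
        assert (np.diag(m.values) == 0).all()

    def test_never_cooccurring_pair_p_one(self):
        regions = unit_grid(20)
        cat = catalog_from_sites({
            "A": [("chr1", i * 1000 + 10, i * 1000 + 60) for i in range(10)],
            "B": [("chr1", i * 1000 + 10, i * 1000 + 60) for i in range(10, 20)],
        })
        m = colocalization_matrix(["A", "B"], regions, cat)
        assert m.loc["A", "B"] == pytest.approx(1.0)

    def test_null_calibration(self):
        rng = np.random.default_rng(63)
        regions = unit_grid(300)
        cat = catalog_from_sites({
            f"T{k}": [("chr1", int(s), int(s) + 200)
                      for s in rng.integers(0, 299_000, 30)]
            for k in range(30)
        })
        tfs = [f"T{k}" for k in range(30)]
        bound = {tf: units_bound(regions, cat.sites_of(tf)) for tf in tfs}
        raw = []
        for i in range(30):
            for j in range(i + 1, 30):
                bi, bj = bound[tfs[i]], bound[tfs[j]]
                a = int((bi & bj).sum()); b = int((bi & ~bj).sum())
                c = int((~bi & bj).sum()); d = int((~bi & ~bj).sum())
                raw.append(fisher_one_sided(a, b, c, d))
        frac = np.mean(np.array(raw) < 0.05)
        se = np.sqrt(0.05 * 0.95 / len(raw))
        assert frac <= 0.05 + 3 * se


class TestBindingSiteMethylation:
    def make_beta(self):
        coords = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "start": [1000, 2550, 2551],
             "end": [1050, 2600, 2601]},
            index=["near", "edge500", "edge501"],
        )
        beta = pd.DataFrame(
            np.array([[0.1, 0.9], [0.2, 0.8], [0.3, 0.7]]),
            index=coords.index, columns=["s1", "s2"],
        )
        groups = pd.Series({"s1": "A", "s2": "B"})
        return BetaMatrix(beta, coords, groups)

    def test_max_gap_boundary(self):
        bm = self.make_beta()
        # site [950, 2050): probe 'edge500' starts 500 bp after the site end
        cat = catalog_from_sites({"T": [("chr1", 950, 2050)]})
        out = binding_site_methylation(bm, cat, "T", max_gap=500)
        assert set(out.index) == {"near", "edge500"}

    def test_absent_tf_rejected_and_empty_warns(self):
        bm = self.make_beta()
        cat = catalog_from_sites({"T": [("chr2", 0, 100)]})
        with pytest.raises(ValueError):
            binding_site_methylation(bm, cat, "MISSING")
        with pytest.warns(UserWarning):
            out = binding_site_methylation(bm, cat, "T")
        assert out.empty


def test_clusterwise_counts_consistent_with_pooled():
    rng = np.random.default_rng(85)
    bg = unit_grid(200)
    units = list(bg)[:40]
    labels = pd.Series(
        {iv.meta["name"]: ("c1" if i < 20 else "c2") for i, iv in enumerate(units)}
    )
    cat = catalog_from_sites(
        {"T": [("chr1", int(s), int(s) + 150) for s in rng.integers(0, 199_000, 25)]}
    )
    res = clusterwise_enrichment(
        labels, {("A", "hyper"): IntervalSet(units)}, cat, bg
    )
    pooled = enrich_tf_sets(IntervalSet(units), bg, cat)
    assert res["a"].sum() == pooled.loc[0, "a"]


def test_planted_tf_top_hit_in_study(results, study):
    rec = results["report"]["enrichment"]
    assert rec["array_rank"] == 1 and rec["tiles_rank"] == 1
    assert rec["array_adj_p"] < 0.05 and rec["tiles_adj_p"] < 0.05
    assert rec["validated"]
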