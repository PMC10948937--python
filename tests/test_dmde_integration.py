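"""Methylation-expression integration: DE calling, regulatory linking,
cross-platform validation, TAD-boundary screening, classification."""

import numpy as np
import pandas as pd
import pytest

from dmrflow.containers import DMR_COLS, DMRSet
from dmrflow.dmde_integration import (
    build_promoters,
    call_de_genes,
    classify_dm_de,
    collapse_probes_to_genes,
    cross_platform_validate,
    filter_enhancer_links,
    link_dmrs_to_genes,
    tad_boundary_filter,
)
from dmrflow.genomic_core import GenomicInterval, IntervalSet


def dmrs_of(rows, platform="array", comparison="A_vs_B"):
    df = pd.DataFrame(
        [
            {"chrom": c, "start": s, "end": e, "delta_beta": d, "q": 0.01,
             "direction": "hyper" if d > 0 else "hypo", "n_units": 1,
             "platform": platform, "comparison": comparison}
            for (c, s, e, d) in rows
        ],
        columns=DMR_COLS,
    )
    return DMRSet(df)


GENES = pd.DataFrame(
    [
        {"gene": "G1", "transcript": "G1.t1", "chrom": "chr1", "tss": 10_000, "strand": "+"},
        {"gene": "G2", "transcript": "G2.t1", "chrom": "chr1", "tss": 10_000, "strand": "-"},
        {"gene": "G3", "transcript": "G3.t1", "chrom": "chr1", "tss": 100, "strand": "+"},
        {"gene": "G4", "transcript": "G4.t1", "chrom": "chr1", "tss": 500_000, "strand": "+"},
    ]
)


class TestDECalling:
    def make_expr(self, lfc, n=8, sd=0.2, seed=0):
        rng = np.random.default_rng(seed)
        samples = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        groups = pd.Series({s: ("A" if s.startswith("a") else "B") for s in samples})
        base = rng.normal(8, 1, size=len(lfc))
        vals = np.empty((len(lfc), 2 * n))
        for j, s in enumerate(samples):
            shift = np.array(lfc) if groups[s] == "A" else 0.0
            vals[:, j] = base + shift + rng.normal(0, sd, size=len(lfc))
        return pd.DataFrame(vals, index=[f"g{i}" for i in range(len(lfc))],
                            columns=samples), groups

    def test_effect_below_one_logfc_not_significant(self):
        expr, groups = self.make_expr([0.99] + [0.0] * 20, sd=0.01)
        res = call_de_genes(expr, groups, "A", "B", "array").set_index("gene")
        assert res.loc["g0", "adj_p"] < 1e-6          # tiny p ...
        assert not bool(res.loc["g0", "significant"])  # ... but |lfc| < 1

    def test_null_false_positive_rate(self):
        expr, groups = self.make_expr([0.0] * 400, sd=0.5, seed=3)
        res = call_de_genes(expr, groups, "A", "B", "array")
        frac = (res["p"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 400)
        assert frac <= 0.05 + 3 * se

    def test_planted_two_fold_genes_recovered(self):
        lfc = [2.0] * 10 + [0.0] * 90
        expr, groups = self.make_expr(lfc, seed=9)
        res = call_de_genes(expr, groups, "A", "B", "array")
        sig = set(res.loc[res["significant"], "gene"])
        assert {f"g{i}" for i in range(10)} <= sig

    def test_zero_variance_gene_p_one(self):
        expr, groups = self.make_expr([0.0, 0.0], sd=0.2)
        expr.iloc[0] = 5.0
        res = call_de_genes(expr, groups, "A", "B", "array").set_index("gene")
        assert res.loc["g0", "p"] == 1.0

    def test_probe_collapse_mean(self):
        expr = pd.DataFrame([[1.0, 2.0], [3.0, 4.0], [10.0, 20.0]],
                            index=["p1", "p2", "p3"], columns=["s1", "s2"])
        mapping = pd.Series({"p1": "G", "p2": "G", "p3": "H"})
        out = collapse_probes_to_genes(expr, mapping)
        assert out.loc["G"].tolist() == [2.0, 3.0]


class TestPromoters:
    def test_plus_minus_and_clip(self):
        promoters = {iv.meta["transcript"]: iv for iv in build_promoters(GENES)}
        assert (promoters["G1.t1"].start, promoters["G1.t1"].end) == (8000, 10_500)
        assert (promoters["G2.t1"].start, promoters["G2.t1"].end) == (9500, 12_000)
        assert (promoters["G3.t1"].start, promoters["G3.t1"].end) == (0, 600)

    def test_unknown_strand_treated_plus_with_warning(self):
        g = GENES.copy()
        g.loc[0, "strand"] = "?"
        with pytest.warns(UserWarning):
            promoters = build_promoters(g)
        iv = [p for p in promoters if p.meta["gene"] == "G1"][0]
        assert (iv.start, iv.end) == (8000, 10_500)


class TestLinking:
    def test_promoter_mode(self):
        dmrs = dmrs_of([("chr1", 8500, 8600, 0.4)])
        out = link_dmrs_to_genes(dmrs, GENES, None, "promoter")
        assert set(out["gene"]) == {"G1"}

    def test_neighborhood_boundary_200kb(self):
        near = dmrs_of([("chr1", 209_999, 210_050, 0.4)])   # TSS 10,000 + 199,999
        out = link_dmrs_to_genes(near, GENES, None, "neighborhood")
        assert "G1" in set(out["gene"])
        far = dmrs_of([("chr1", 210_001, 210_051, 0.4)])    # 200,001 away
        out_far = link_dmrs_to_genes(far, GENES, None, "neighborhood")
        assert "G1" not in set(out_far["gene"])

    def test_enhancer_confidence_cutoff(self):
        enh = pd.DataFrame(
            [
                {"chrom": "chr1", "start": 50_000, "end": 50_500, "gene": "G1",
                 "source": "genehancer-like", "confidence": 4.9},
                {"chrom": "chr1", "start": 60_000, "end": 60_500, "gene": "G2",
                 "source": "genehancer-like", "confidence": 5.0},
            ]
        )
        assert set(filter_enhancer_links(enh)["gene"]) == {"G2"}
        dmrs = dmrs_of([("chr1", 50_100, 50_200, 0.4), ("chr1", 60_100, 60_200, 0.4)])
        out = link_dmrs_to_genes(dmrs, GENES, enh, "enhancer")
        assert set(out["gene"]) == {"G2"}

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            link_dmrs_to_genes(dmrs_of([]), GENES, None, "nonsense")


def pair_row(gene, start, end, direction, platform, tss=10_000, comparison="A_vs_B"):
    return {
        "gene": gene, "transcript": f"{gene}.t1", "tss": tss, "mode": "promoter",
        "dmr_id": 0, "chrom": "chr1", "start": start, "end": end,
        "delta_beta": 0.4 if direction == "hyper" else -0.4,
        "direction": direction, "platform": platform, "comparison": comparison,
    }


class TestCrossPlatformValidation:
    def test_gap_boundary_5kb(self):
        arr = pd.DataFrame([pair_row("G1", 10_000, 11_000, "hyper", "array")])
        til = pd.DataFrame([pair_row("G1", 16_000, 17_000, "hyper", "tiles")])
        assert len(cross_platform_validate(arr, til)) == 2  # both directions validate
        til_far = pd.DataFrame([pair_row("G1", 16_001, 17_001, "hyper", "tiles")])
        assert len(cross_platform_validate(arr, til_far)) == 0

    def test_opposite_direction_never_validates(self):
        arr = pd.DataFrame([pair_row("G1", 10_000, 11_000, "hyper", "array")])
        til = pd.DataFrame([pair_row("G1", 10_000, 11_000, "hypo", "tiles")])
        assert len(cross_platform_validate(arr, til)) == 0


class TestTADBoundaryFilter:
    def tads(self, edges):
        ivs = [GenomicInterval("chr1", s, e) for s, e in zip(edges[:-1], edges[1:])]
        return {"set1": IntervalSet(ivs)}

    def test_same_tad_retained(self):
        pairs = pd.DataFrame([pair_row("G1", 50_000, 51_000, "hyper", "array")])
        out = tad_boundary_filter(pairs, self.tads([0, 100_000, 200_000]))
        assert len(out) == 1

    def test_crossing_pair_drops_gene_in_literal_mode(self):
        pairs = pd.DataFrame(
            [
                pair_row("G1", 50_000, 51_000, "hyper", "array"),
                pair_row("G1", 150_000, 151_000, "hyper", "array"),  # crosses 100k edge
            ]
        )
        tads = self.tads([0, 100_000, 200_000])
        assert len(tad_boundary_filter(pairs, tads, mode="literal")) == 0
        out_any = tad_boundary_filter(pairs, tads, mode="any_clean")
        assert set(out_any["gene"]) == {"G1"}

    def test_empty_chromosome_vacuous(self):
        pairs = pd.DataFrame([pair_row("G1", 400_000, 401_000, "hyper", "array")])
        tads = {"set1": IntervalSet([GenomicInterval("chr2", 0, 1_000_000)])}
        assert len(tad_boundary_filter(pairs, tads)) == 1

    def test_touching_boundary_does_not_count(self):
        # span runs [10_000, 100_000); the edge at exactly 100_000 is outside
        pairs = pd.DataFrame([pair_row("G1", 100_000, 101_000, "hyper", "array")])
        assert len(tad_boundary_filter(pairs, self.tads([0, 100_000, 200_000]))) == 1


class TestClassification:
    def de(self, gene, lfc, platform, sig=True, comparison="A_vs_B"):
        return {"gene": gene, "log2FC": lfc, "p": 1e-8, "adj_p": 1e-6,
                "platform": platform, "comparison": comparison, "significant": sig}

    def test_opposite_and_parallel(self):
        pairs = pd.DataFrame(
            [pair_row("G1", 8500, 8600, "hypo", "array"),
             pair_row("G2", 9600, 9700, "hyper", "array")]
        )
        de_a = pd.DataFrame([self.de("G1", 2.0, "array"), self.de("G2", 2.0, "array")])
        de_s = pd.DataFrame([self.de("G1", 2.2, "rnaseq"), self.de("G2", 1.8, "rnaseq")])
        out = classify_dm_de(pairs, de_a, de_s).set_index("gene")
        assert out.loc["G1", "relation"] == "opposite"
        assert out.loc["G2", "relation"] == "parallel"

    def test_platform_disagreement_excluded(self):
        pairs = pd.DataFrame([pair_row("G1", 8500, 8600, "hypo", "array")])
        de_a = pd.DataFrame([self.de("G1", 2.0, "array")])
        de_s = pd.DataFrame([self.de("G1", -2.0, "rnaseq")])
        assert len(classify_dm_de(pairs, de_a, de_s)) == 0
        de_s_ns = pd.DataFrame([self.de("G1", 2.0, "rnaseq", sig=False)])
        assert len(classify_dm_de(pairs, de_a, de_s_ns)) == 0

    def test_mixed_directions_flagged(self):
        pairs = pd.DataFrame(
            [pair_row("G1", 8500, 8600, "hypo", "array"),
             pair_row("G1", 9600, 9700, "hyper", "array")]
        )
        de_a = pd.DataFrame([self.de("G1", 2.0, "array")])
        de_s = pd.DataFrame([self.de("G1", 2.0, "rnaseq")])
        out = classify_dm_de(pairs, de_a, de_s)
        assert out.loc[0, "relation"] == "mixed"

    def test_opposite_parallel_disjoint(self, results):
        cls = results["dmde"]["classified"]
        opp = set(map(tuple, cls[cls["relation"] == "opposite"][["gene", "comparison"]].values))
        par = set(map(tuple, cls[cls["relation"] == "parallel"][["gene", "comparison"]].values))
        assert not (opp & par)


def test_planted_dmde_recovery(results):
    rec = results["report"]["dmde"]
    assert rec["opposite_recovery"] >= 0.9
    assert rec["parallel_mislabeled_opposite"] == 0
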