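"""Synthetic two-platform methylation study with planted ground truth.

The generator emulates the statistical structure of a multi-cohort brain
tumor methylation study: three tumor groups (ATRT-like, MB-like,
PLEX-like) plus normal controls and PSC/FB reference methylomes,
measured both as array-style probe beta values and as bisulfite tile
counts over a shared synthetic genome; a regulatory genome (genes,
enhancer links, TAD sets, a TF binding-site catalog, a PWM); expression
matrices on two platforms; and CUT&RUN peak calls.

Planted signals, all recorded in machine-readable truth tables:

* cancer-specific DMRs — units shifted by a configured delta-beta in one
  tumor group against every other group, so they surface in both tumor
  comparisons and survive control filtering;
* a developmental category per planted DMR, realised by setting the
  PSC/FB group means to the category's defining pattern;
* TAD-scale shift clusters — several single-tile DMRs spread over >50 kb
  inside one TAD (plus a below-threshold near-miss cluster);
* TF binding-site enrichments — one TF with excess sites inside a target
  DMR class, one TF enriched only through a single sample category;
* DM-DE genes — expression shifted opposite (or, for parallel controls,
  along) the methylation direction of a linked DMR, on both expression
  platforms, linked via promoter or enhancer;
* CUT&RUN peaks with known replicate/control/evidence structure.

Beta values are drawn from Beta(mu*c, (1-mu)*c) with concentration c;
tile methylated counts are Binomial(total, beta) with Poisson totals.
A fixed seed makes every output byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import BetaMatrix, TileCounts
from .cutrun_filter import PWM, scan_motif
from .genomic_core import GenomicInterval, IntervalSet, subset_by_overlap, write_bed
from .tfbs_enrichment import SAMPLE_CATEGORIES, BindingSiteCatalog

TUMORS = ("ATRT", "MB", "PLEX")
ALL_GROUPS = TUMORS + ("CONTR", "PSC", "FB")

#: planted developmental categories, cycled over the planted DMRs.
#: Offsets are added to the baseline b (sign-flipped for hypo regions):
#: (tumor, PSC, FB) methylation relative to the other tumor groups.
#: Keys state the category realised by a *hyper* region; the sign flip of
#: a hypo region also flips the PSC-vs-FB contrast, hence the
#: differentiation half of the label (see :func:`realized_category`).
CATEGORY_OFFSETS = {
    "PSC_like|demethylated_in_differentiation": (1.0, 1.0, 0.0),
    "FB_like|methylated_in_differentiation": (1.0, 0.0, 1.0),
    "unique|unchanged": (1.0, 0.0, 0.0),
    "unique|demethylated_in_differentiation": (1.0, 0.125, -0.625),
}

_DIFF_FLIP = {
    "demethylated_in_differentiation": "methylated_in_differentiation",
    "methylated_in_differentiation": "demethylated_in_differentiation",
    "unchanged": "unchanged",
}


def realized_category(offset_key: str, direction: str) -> str:
    """Category actually planted by an offset pattern for a region of the
    given direction (hypo regions invert the differentiation axis)."""
    similarity, diff = offset_key.split("|")
    if direction == "hypo":
        diff = _DIFF_FLIP[diff]
    return f"{similarity}|{diff}"


@dataclass
class GenomeSpec:
    """Synthetic genome: four 5-Mb autosomes plus a sex chromosome and a
    scaffold that exercise the canonical-chromosome filters."""

    chrom_lengths: dict = field(
        default_factory=lambda: {
            **{f"chr{i}": 5_000_000 for i in range(1, 5)},
            "chrX": 1_000_000,
            "chrUn_scaffold1": 200_000,
        }
    )
    tiles_per_chrom: dict = field(
        default_factory=lambda: {
            **{f"chr{i}": 5000 for i in range(1, 5)},
            "chrX": 60,
            "chrUn_scaffold1": 30,
        }
    )
    tile_size: int = 1000
    probe_size: int = 50
    probe_density: float = 0.7  # fraction of autosomal tiles with a probe


@dataclass
class DMRPlantSpec:
    """Planted cancer-specific DMRs: counts per (tumor, direction), the
    shared effect size, and region geometry."""

    n_hyper: dict = field(default_factory=lambda: {"ATRT": 12, "MB": 3, "PLEX": 2})
    n_hypo: dict = field(default_factory=lambda: {"ATRT": 2, "MB": 12, "PLEX": 8})
    tiles_per_dmr: int = 2
    probes_per_tile: int = 4
    delta: float = 0.4


@dataclass
class TADPlantSpec:
    """TAD layout and planted large-scale shift clusters."""

    tad_size: int = 400_000
    set_names: tuple = ("cortex", "neural_progenitor", "hippocampus", "esc", "neuroblast")
    jitter: int = 20_000
    # (tumor, direction, chrom, tad index, n units); 7 units qualify,
    # 4 units are a deliberate near-miss below the 5-hit rule
    clusters: tuple = (
        ("ATRT", "hyper", "chr3", 1, 7),
        ("ATRT", "hyper", "chr3", 4, 7),
        ("MB", "hypo", "chr4", 2, 7),
        ("PLEX", "hypo", "chr2", 6, 4),
    )


@dataclass
class TFPlantSpec:
    n_tfs: int = 15
    sites_per_tf: int = 300
    site_len: int = 200
    planted_tf: str = "TF01"
    planted_target: tuple = ("ATRT", "hyper")
    planted_fraction: float = 0.5  # fraction of sites inside the target class
    category_tf: str = "TF02"
    category_label: str = "psc"
    category_target: tuple = ("MB", "hypo")


@dataclass
class ExpressionPlantSpec:
    n_genes: int = 160
    n_dmde: int = 12           # opposite-direction planted genes
    n_dmde_enhancer: int = 4   # of which linked via an enhancer, not promoter
    n_parallel: int = 6        # same-direction controls
    log2fc: float = 2.0
    n_per_group: int = 8
    count_mean: float = 300.0
    count_dispersion: float = 0.08
    array_sd: float = 0.35


@dataclass
class CutRunPlantSpec:
    peak_len: int = 300
    rep_shift: int = 40
    # sample -> (kept peaks, n both, n gtrd_only, n motif_only, n in ATRT-hyper DMRs)
    samples: dict = field(
        default_factory=lambda: {
            "MB_like": (40, 20, 8, 8, 15),
            "ATRT_like_1": (4, 0, 0, 3, 0),
            "ATRT_like_2": (2, 0, 0, 1, 0),
            "ATRT_like_3": (3, 0, 0, 2, 0),
        }
    )
    n_rep_only: int = 5      # peaks private to one replicate (dropped)
    n_sex_chrom: int = 3     # peaks on chrX (dropped)
    n_control_hit: int = 3   # peaks overlapping the control set (dropped)
    consensus: str = "GCAGCTGG"


@dataclass
class StudyConfig:
    """Complete configuration of the synthetic study."""

    genome: GenomeSpec = field(default_factory=GenomeSpec)
    dmrs: DMRPlantSpec = field(default_factory=DMRPlantSpec)
    tads: TADPlantSpec = field(default_factory=TADPlantSpec)
    tfs: TFPlantSpec = field(default_factory=TFPlantSpec)
    expression: ExpressionPlantSpec = field(default_factory=ExpressionPlantSpec)
    cutrun: CutRunPlantSpec = field(default_factory=CutRunPlantSpec)
    n_samples: dict = field(
        default_factory=lambda: {"ATRT": 10, "MB": 10, "PLEX": 10, "CONTR": 8, "PSC": 6, "FB": 6}
    )
    concentration: float = 60.0   # Beta-distribution concentration c
    depth_mean: float = 30.0      # Poisson mean of tile read totals
    n_low_coverage_tiles: int = 25
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.n_samples.items():
            if n < 2:
                raise ValueError(f"group {g} needs >= 2 samples")
        if not (0 < self.dmrs.delta <= 1):
            raise ValueError("planted delta must lie in (0, 1]")

    def to_yaml(self, path) -> None:
        # round-trip through JSON turns tuples into YAML-safe lists
        plain = json.loads(json.dumps(asdict(self)))
        with open(path, "w") as fh:
            yaml.safe_dump(plain, fh, sort_keys=False)


def null_config(**overrides) -> StudyConfig:
    """A study with no planted effects of any kind (pure noise)."""
    cfg = StudyConfig(**overrides)
    cfg.dmrs = DMRPlantSpec(
        n_hyper={t: 0 for t in TUMORS}, n_hypo={t: 0 for t in TUMORS}
    )
    cfg.tads = TADPlantSpec(clusters=())
    cfg.expression = ExpressionPlantSpec(n_dmde=0, n_dmde_enhancer=0, n_parallel=0)
    return cfg


# ---------------------------------------------------------------------------
# study plan: deterministic layout of units and planted signals
# ---------------------------------------------------------------------------

@dataclass
class StudyPlan:
    tile_coords: pd.DataFrame          # unit -> chrom/start/end
    probe_coords: pd.DataFrame
    mu: pd.DataFrame                   # unit (tile) x group mean methylation
    probe_tile: pd.Series              # probe -> parent tile
    planted: pd.DataFrame              # planted DMR truth table
    tad_sets: dict                     # set name -> IntervalSet


def _autosomes(genome: GenomeSpec) -> list[str]:
    return [c for c in genome.chrom_lengths if c.startswith("chr") and c[3:].isdigit()]


def design_study(config: StudyConfig, seed: int) -> StudyPlan:
    """Lay out tiles, probes, per-group unit means and the planted-DMR
    truth table.  Deterministic in (config, seed)."""
    config.validate()
    rng = np.random.default_rng(seed)
    genome, dmrspec = config.genome, config.dmrs

    # ---- tiles ----
    tiles = []
    for chrom, n in genome.tiles_per_chrom.items():
        for i in range(n):
            s = i * genome.tile_size
            tiles.append((f"tile_{chrom}_{i:05d}", chrom, s, s + genome.tile_size))
    tile_coords = pd.DataFrame(
        tiles, columns=["unit", "chrom", "start", "end"]
    ).set_index("unit")

    autosomes = _autosomes(genome)
    tad_size, jitter = config.tads.tad_size, config.tads.jitter

    # ---- TAD sets (first set on the exact grid, others jittered) ----
    tad_sets: dict[str, IntervalSet] = {}
    for si, name in enumerate(config.tads.set_names):
        ivs = []
        for chrom in autosomes:
            length = genome.chrom_lengths[chrom]
            edges = [0]
            pos = tad_size
            while pos < length:
                off = 0 if si == 0 else int(rng.integers(-jitter, jitter + 1))
                edges.append(min(length, pos + off))
                pos += tad_size
            edges.append(length)
            edges = sorted(set(edges))
            for s, e in zip(edges[:-1], edges[1:]):
                if e > s:
                    ivs.append(GenomicInterval(chrom, s, e, meta={"name": f"{name}_{chrom}_{s}"}))
        tad_sets[name] = IntervalSet(ivs)

    # ---- planted DMRs: one TAD grid slot per region so that ordinary
    # regions never combine into an accidental large-scale cluster ----
    tiled_span = {c: genome.tiles_per_chrom[c] * genome.tile_size for c in autosomes}
    slots = []  # (chrom, grid tad index) fully inside the tiled span
    for chrom in autosomes:
        for k in range(tiled_span[chrom] // tad_size):
            slots.append((chrom, k))
    reserved = {(cl[2], cl[3]) for cl in config.tads.clusters}
    free_slots = [s for s in slots if s not in reserved]
    rng.shuffle(free_slots)

    categories = list(CATEGORY_OFFSETS)
    planted_rows = []
    slot_iter = iter(free_slots)

    def next_slot():
        try:
            return next(slot_iter)
        except StopIteration as exc:  # pragma: no cover - config error
            raise ValueError("not enough TAD slots for the planted DMRs") from exc

    ci = 0
    for direction, counts in (("hyper", dmrspec.n_hyper), ("hypo", dmrspec.n_hypo)):
        for tumor in TUMORS:
            for _ in range(counts.get(tumor, 0)):
                chrom, k = next_slot()
                base_tile = k * (tad_size // genome.tile_size)
                n_tiles_in_slot = tad_size // genome.tile_size
                # keep every region >= jitter away from the slot edges and
                # leave room for a 50-kb enhancer link inside the same TAD
                lo_tile = jitter // genome.tile_size + 2
                hi_tile = min(
                    n_tiles_in_slot - dmrspec.tiles_per_dmr - jitter // genome.tile_size - 2,
                    n_tiles_in_slot - (jitter + 80_000) // genome.tile_size,
                )
                first = base_tile + int(rng.integers(lo_tile, hi_tile))
                offset_key = categories[ci % len(categories)]
                ci += 1
                planted_rows.append(
                    {
                        "chrom": chrom,
                        "start": first * genome.tile_size,
                        "end": (first + dmrspec.tiles_per_dmr) * genome.tile_size,
                        "tumor": tumor,
                        "direction": direction,
                        "delta": dmrspec.delta,
                        "offset_key": offset_key,
                        "category": realized_category(offset_key, direction),
                        "largescale": False,
                        "cluster_id": "",
                    }
                )

    # ---- large-scale clusters: single-tile DMRs spread over the TAD ----
    for cid, (tumor, direction, chrom, k, n_units) in enumerate(config.tads.clusters):
        lo = k * tad_size + 30_000
        hi = (k + 1) * tad_size - 30_000
        positions = np.linspace(lo, hi - genome.tile_size, n_units).astype(int)
        tile_idx = sorted({int(p // genome.tile_size) for p in positions})
        for t in tile_idx:
            planted_rows.append(
                {
                    "chrom": chrom,
                    "start": t * genome.tile_size,
                    "end": (t + 1) * genome.tile_size,
                    "tumor": tumor,
                    "direction": direction,
                    "delta": dmrspec.delta,
                    "offset_key": "unique|unchanged",
                    "category": "unique|unchanged",
                    "largescale": n_units >= 5,
                    "cluster_id": f"cluster_{cid}",
                }
            )
    planted = pd.DataFrame(
        planted_rows,
        columns=["chrom", "start", "end", "tumor", "direction", "delta",
                 "offset_key", "category", "largescale", "cluster_id"],
    )

    # ---- per-unit, per-group means ----
    mu = pd.DataFrame(
        np.tile(rng.uniform(0.15, 0.85, size=len(tile_coords))[:, None], (1, len(ALL_GROUPS))),
        index=tile_coords.index,
        columns=list(ALL_GROUPS),
    )
    for _, r in planted.iterrows():
        sign = 1.0 if r["direction"] == "hyper" else -1.0
        t_off, p_off, f_off = CATEGORY_OFFSETS[r["offset_key"]]
        # baseline chosen so that every offset stays inside [0.03, 0.97]
        offs = np.array([0.0, t_off, p_off, f_off]) * sign * r["delta"]
        lo_b = 0.03 - offs.min()
        hi_b = 0.97 - offs.max()
        b = rng.uniform(lo_b + 0.02, hi_b - 0.02)
        tiles_hit = tile_coords[
            (tile_coords["chrom"] == r["chrom"])
            & (tile_coords["start"] >= r["start"])
            & (tile_coords["end"] <= r["end"])
        ].index
        mu.loc[tiles_hit, :] = b
        mu.loc[tiles_hit, r["tumor"]] = b + sign * t_off * r["delta"]
        mu.loc[tiles_hit, "PSC"] = b + sign * p_off * r["delta"]
        mu.loc[tiles_hit, "FB"] = b + sign * f_off * r["delta"]

    # ---- probes ----
    probe_rows = []
    planted_tiles = set()
    for _, r in planted.iterrows():
        hit = tile_coords[
            (tile_coords["chrom"] == r["chrom"])
            & (tile_coords["start"] >= r["start"])
            & (tile_coords["end"] <= r["end"])
        ].index
        planted_tiles.update(hit)
    offsets = np.linspace(100, 800, dmrspec.probes_per_tile).astype(int)
    pi = 0
    for unit, row in tile_coords.iterrows():
        if row["chrom"] not in autosomes:
            continue  # the array platform carries no sex/scaffold probes
        if unit in planted_tiles:
            for off in offsets:
                probe_rows.append(
                    (f"probe_{pi:06d}", row["chrom"], row["start"] + off,
                     row["start"] + off + genome.probe_size, unit)
                )
                pi += 1
        elif rng.random() < genome.probe_density:
            off = int(rng.integers(100, genome.tile_size - genome.probe_size - 100))
            probe_rows.append(
                (f"probe_{pi:06d}", row["chrom"], row["start"] + off,
                 row["start"] + off + genome.probe_size, unit)
            )
            pi += 1
    probe_coords = pd.DataFrame(
        probe_rows, columns=["unit", "chrom", "start", "end", "tile"]
    ).set_index("unit")
    probe_tile = probe_coords.pop("tile")

    return StudyPlan(tile_coords, probe_coords, mu, probe_tile, planted, tad_sets)


# ---------------------------------------------------------------------------
# methylomes
# ---------------------------------------------------------------------------

def _sample_names(config: StudyConfig) -> pd.Series:
    labels = {}
    for g in ALL_GROUPS:
        for i in range(config.n_samples[g]):
            labels[f"{g}_{i + 1:02d}"] = g
    return pd.Series(labels, name="group")


def _draw_beta(mu: np.ndarray, c: float, rng: np.random.Generator) -> np.ndarray:
    mu = np.clip(mu, 1e-3, 1 - 1e-3)
    return np.clip(rng.beta(mu * c, (1 - mu) * c), 1e-4, 1 - 1e-4)


def generate_methylomes(
    config: StudyConfig, seed: int, plan: StudyPlan | None = None
) -> tuple[BetaMatrix, TileCounts, pd.DataFrame]:
    """Draw the probe beta matrix and the tile count matrix.

    Probe betas cover all groups (array platform); tile counts cover the
    tumor groups only (sequencing platform).  Returns (probes, tiles,
    planted-DMR truth table).
    """
    if plan is None:
        plan = design_study(config, seed)
    rng = np.random.default_rng(np.random.default_rng(seed).integers(2**31))
    groups = _sample_names(config)

    # probe betas for every group
    probe_mu = plan.mu.loc[plan.probe_tile.values].to_numpy()
    beta = np.empty((len(plan.probe_coords), len(groups)))
    for j, s in enumerate(groups.index):
        g = groups[s]
        beta[:, j] = _draw_beta(probe_mu[:, list(ALL_GROUPS).index(g)], config.concentration, rng)
    probes = BetaMatrix(
        pd.DataFrame(beta, index=plan.probe_coords.index, columns=groups.index),
        plan.probe_coords,
        groups,
    )

    # tile counts for the tumor groups
    tumor_samples = [s for s in groups.index if groups[s] in TUMORS]
    n_tiles = len(plan.tile_coords)
    total = rng.poisson(config.depth_mean, size=(n_tiles, len(tumor_samples))) + 1
    meth = np.empty_like(total)
    for j, s in enumerate(tumor_samples):
        g = groups[s]
        bvals = _draw_beta(
            plan.mu[g].to_numpy(), config.concentration, rng
        )
        meth[:, j] = rng.binomial(total[:, j], bvals)
    # force a few non-planted tiles below the coverage threshold
    nonplanted = plan.mu.index[(plan.mu.nunique(axis=1) == 1)]
    low = rng.choice(
        np.nonzero(plan.tile_coords.index.isin(nonplanted))[0],
        size=min(config.n_low_coverage_tiles, len(nonplanted)),
        replace=False,
    )
    for t in low:
        j = int(rng.integers(len(tumor_samples)))
        total[t, j] = int(rng.integers(0, 10))
        meth[t, j] = min(meth[t, j], total[t, j])
    tiles = TileCounts(
        pd.DataFrame(meth, index=plan.tile_coords.index, columns=tumor_samples),
        pd.DataFrame(total, index=plan.tile_coords.index, columns=tumor_samples),
        plan.tile_coords,
        groups,
    )
    return probes, tiles, plan.planted


# ---------------------------------------------------------------------------
# regulatory genome
# ---------------------------------------------------------------------------

def generate_regulatory_genome(
    config: StudyConfig, seed: int, plan: StudyPlan | None = None
) -> dict:
    """TF binding catalog, gene models, enhancer links, TAD sets and PWM.

    Sites of the planted TF are placed inside its target DMR class at the
    configured excess fraction; all other sites are uniform over the
    tiled autosomal genome.
    """
    if plan is None:
        plan = design_study(config, seed)
    rng = np.random.default_rng(np.random.default_rng(seed).integers(2**31, size=2)[1])
    genome, tfspec, espec = config.genome, config.tfs, config.expression
    autosomes = _autosomes(genome)
    tiled_span = {c: genome.tiles_per_chrom[c] * genome.tile_size for c in autosomes}

    def uniform_site() -> tuple[str, int, int]:
        chrom = autosomes[int(rng.integers(len(autosomes)))]
        s = int(rng.integers(0, tiled_span[chrom] - tfspec.site_len))
        return chrom, s, s + tfspec.site_len

    def site_in(regions: pd.DataFrame) -> tuple[str, int, int]:
        r = regions.iloc[int(rng.integers(len(regions)))]
        span = int(r["end"] - r["start"] - tfspec.site_len)
        s = int(r["start"]) + int(rng.integers(0, max(1, span)))
        return r["chrom"], s, s + tfspec.site_len

    planted = plan.planted
    target_tumor, target_dir = tfspec.planted_target
    target_regions = planted[(planted["tumor"] == target_tumor) & (planted["direction"] == target_dir)]
    cat_tumor, cat_dir = tfspec.category_target
    cat_regions = planted[(planted["tumor"] == cat_tumor) & (planted["direction"] == cat_dir)]

    rows = []
    for ti in range(tfspec.n_tfs):
        tf = f"TF{ti + 1:02d}"
        for _ in range(tfspec.sites_per_tf):
            category = SAMPLE_CATEGORIES[int(rng.integers(len(SAMPLE_CATEGORIES)))]
            if tf == tfspec.planted_tf and len(target_regions) and rng.random() < tfspec.planted_fraction:
                chrom, s, e = site_in(target_regions)
                category = "neural_progenitors"
            elif tf == tfspec.category_tf and len(cat_regions) and rng.random() < tfspec.planted_fraction:
                chrom, s, e = site_in(cat_regions)
                category = tfspec.category_label
            else:
                chrom, s, e = uniform_site()
            rows.append({"tf": tf, "chrom": chrom, "start": s, "end": e,
                         "category": category, "source": "synthetic"})
    catalog = BindingSiteCatalog(pd.DataFrame(rows))

    # ---- gene models and enhancer links ----
    dmde, parallel = _plan_expression_genes(config, plan, rng)
    gene_rows, enh_rows = [], []
    used_spans = []
    for _, g in pd.concat([dmde, parallel]).iterrows():
        gene_rows.append(
            {"gene": g["gene"], "transcript": f"{g['gene']}.t1", "chrom": g["chrom"],
             "tss": int(g["tss"]), "strand": g["strand"]}
        )
        if g["mode"] == "enhancer":
            enh_rows.append(
                {"chrom": g["chrom"], "start": int(g["dmr_start"]), "end": int(g["dmr_end"]),
                 "gene": g["gene"], "source": "genehancer-like", "confidence": 7.0}
            )
    n_rest = espec.n_genes - len(gene_rows)
    planted_iv = IntervalSet(
        GenomicInterval(r["chrom"], max(0, r["start"] - 3000), r["end"] + 3000)
        for _, r in planted.iterrows()
    ) if len(planted) else IntervalSet()
    gi = 0
    while gi < n_rest:
        chrom = autosomes[int(rng.integers(len(autosomes)))]
        tss = int(rng.integers(5000, tiled_span[chrom] - 5000))
        probe = GenomicInterval(chrom, max(0, tss - 2000), tss + 2000)
        if len(planted_iv) and len(subset_by_overlap(IntervalSet([probe]), planted_iv, 1)):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        gene = f"GENE{gi + 1 + len(gene_rows):04d}"
        gene_rows.append({"gene": gene, "transcript": f"{gene}.t1", "chrom": chrom,
                          "tss": tss, "strand": strand})
        gi += 1
    gene_models = pd.DataFrame(gene_rows, columns=["gene", "transcript", "chrom", "tss", "strand"])

    # background enhancer links, including the 4.9 / 5.0 confidence pair
    bg_genes = gene_models["gene"].sample(n=min(30, len(gene_models)), random_state=int(rng.integers(2**31))).tolist()
    for i, gene in enumerate(bg_genes):
        chrom = autosomes[int(rng.integers(len(autosomes)))]
        s = int(rng.integers(0, tiled_span[chrom] - 500))
        conf = float(np.round(rng.uniform(0, 10), 1))
        if i == 0:
            conf = 4.9
        elif i == 1:
            conf = 5.0
        source = "genehancer-like" if rng.random() < 0.7 else "fantom-like"
        enh_rows.append({"chrom": chrom, "start": s, "end": s + 500, "gene": gene,
                         "source": source, "confidence": conf})
    enhancers = pd.DataFrame(
        enh_rows, columns=["chrom", "start", "end", "gene", "source", "confidence"]
    )

    pwm = _build_pwm(config.cutrun.consensus)
    return {
        "catalog": catalog,
        "gene_models": gene_models,
        "enhancers": enhancers,
        "tad_sets": plan.tad_sets,
        "pwm": pwm,
        "dmde_truth": pd.concat([dmde, parallel], ignore_index=True),
    }


def _plan_expression_genes(
    config: StudyConfig, plan: StudyPlan, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Choose planted DMRs to anchor DM-DE (opposite) and parallel genes.

    Promoter-linked genes sit with their TSS 1 kb downstream of the DMR
    (plus strand), so the 2-kb upstream promoter overlaps it; enhancer-
    linked genes sit 50 kb away with the DMR itself annotated as their
    enhancer.
    """
    espec = config.expression
    planted = plan.planted[~plan.planted["largescale"]].reset_index(drop=True)
    n_need = espec.n_dmde + espec.n_parallel
    rows_d, rows_p = [], []
    if n_need == 0 or len(planted) == 0:
        cols = ["gene", "chrom", "tss", "strand", "mode", "dmr_start", "dmr_end",
                "tumor", "direction", "log2fc", "relation"]
        return pd.DataFrame(columns=cols), pd.DataFrame(columns=cols)
    picks = rng.choice(len(planted), size=min(n_need, len(planted)), replace=False)
    for idx, pick in enumerate(picks):
        r = planted.iloc[pick]
        opposite = idx < espec.n_dmde
        enhancer_mode = opposite and idx < espec.n_dmde_enhancer
        sign = 1.0 if r["direction"] == "hyper" else -1.0
        lfc = (-sign if opposite else sign) * espec.log2fc
        gene = f"{'DMDE' if opposite else 'PARA'}{idx + 1:03d}"
        if enhancer_mode:
            tss = int(r["end"]) + 50_000
            mode = "enhancer"
        else:
            tss = int(r["end"]) + 1000
            mode = "promoter"
        row = {
            "gene": gene, "chrom": r["chrom"], "tss": tss, "strand": "+",
            "mode": mode, "dmr_start": int(r["start"]), "dmr_end": int(r["end"]),
            "tumor": r["tumor"], "direction": r["direction"], "log2fc": lfc,
            "relation": "opposite" if opposite else "parallel",
        }
        (rows_d if opposite else rows_p).append(row)
    cols = ["gene", "chrom", "tss", "strand", "mode", "dmr_start", "dmr_end",
            "tumor", "direction", "log2fc", "relation"]
    return pd.DataFrame(rows_d, columns=cols), pd.DataFrame(rows_p, columns=cols)


def _build_pwm(consensus: str, strength: float = 0.85) -> PWM:
    counts = np.full((len(consensus), 4), (1 - strength) / 3 * 100)
    for i, b in enumerate(consensus):
        counts[i, "ACGT".index(b)] = strength * 100
    return PWM.from_counts(counts, pseudocount=0.01, name="NEUROD1_like")


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(
    config: StudyConfig, seed: int, plan: StudyPlan | None = None,
    dmde_truth: pd.DataFrame | None = None, gene_models: pd.DataFrame | None = None,
) -> dict:
    """Two expression matrices (RNA-seq-like counts, array-like log
    intensities) over the tumor groups, with the planted genes shifted by
    the configured log2 fold change in their target group on both
    platforms (independent noise)."""
    if plan is None:
        plan = design_study(config, seed)
    rng = np.random.default_rng(np.random.default_rng(seed).integers(2**31, size=3)[2])
    espec = config.expression
    if dmde_truth is None or gene_models is None:
        reg = generate_regulatory_genome(config, seed, plan)
        dmde_truth, gene_models = reg["dmde_truth"], reg["gene_models"]

    samples, labels = [], {}
    for g in TUMORS:
        for i in range(espec.n_per_group):
            s = f"expr_{g}_{i + 1:02d}"
            samples.append(s)
            labels[s] = g
    groups = pd.Series(labels, name="group")

    genes = gene_models["gene"].tolist()
    lfc = pd.DataFrame(0.0, index=genes, columns=list(TUMORS))
    for _, r in dmde_truth.iterrows():
        lfc.loc[r["gene"], r["tumor"]] = r["log2fc"]

    base_mean = np.exp(rng.normal(np.log(espec.count_mean), 0.6, size=len(genes)))
    base_arr = rng.normal(8.0, 1.0, size=len(genes))

    counts = np.empty((len(genes), len(samples)), dtype=int)
    arr = np.empty((len(genes), len(samples)))
    disp = espec.count_dispersion
    for j, s in enumerate(samples):
        g = groups[s]
        mean_j = base_mean * np.power(2.0, lfc[g].to_numpy())
        lam = rng.gamma(shape=1.0 / disp, scale=mean_j * disp)
        counts[:, j] = rng.poisson(lam)
        arr[:, j] = base_arr + lfc[g].to_numpy() + rng.normal(0, espec.array_sd, size=len(genes))
    return {
        "counts": pd.DataFrame(counts, index=genes, columns=samples),
        "array": pd.DataFrame(arr, index=genes, columns=samples),
        "groups": groups,
        "truth": dmde_truth,
    }


# ---------------------------------------------------------------------------
# CUT&RUN
# ---------------------------------------------------------------------------

def generate_cutrun(
    config: StudyConfig, seed: int, plan: StudyPlan | None = None, pwm: PWM | None = None
) -> dict:
    """Replicate peak sets, control peaks, a NEUROD1-like site catalog,
    per-peak sequences, and the evidence-class truth table.

    Peaks kept after filtering are the bp-intersections of the two
    replicates; sequences carry the planted consensus for motif-class
    peaks and are rejection-sampled motif-free otherwise.
    """
    if plan is None:
        plan = design_study(config, seed)
    rng = np.random.default_rng(np.random.default_rng(seed).integers(2**31, size=4)[3])
    spec = config.cutrun
    genome = config.genome
    if pwm is None:
        pwm = _build_pwm(spec.consensus)
    autosomes = _autosomes(genome)
    tiled_span = {c: genome.tiles_per_chrom[c] * genome.tile_size for c in autosomes}

    atrt_hyper = plan.planted[
        (plan.planted["tumor"] == "ATRT") & (plan.planted["direction"] == "hyper")
    ]
    occupied: list[tuple[str, int, int]] = []

    def fresh_interval(length: int, inside: pd.DataFrame | None = None) -> tuple[str, int, int]:
        for _ in range(1000):
            if inside is not None and len(inside):
                r = inside.iloc[int(rng.integers(len(inside)))]
                chrom = r["chrom"]
                s = int(rng.integers(r["start"], max(r["start"] + 1, r["end"] - length)))
            else:
                chrom = autosomes[int(rng.integers(len(autosomes)))]
                s = int(rng.integers(0, tiled_span[chrom] - length))
            e = s + length
            if all(not (chrom == c and s < oe + 1000 and e > os - 1000) for c, os, oe in occupied):
                occupied.append((chrom, s, e))
                return chrom, s, e
        raise RuntimeError("could not place a peak")

    def random_seq(n: int) -> str:
        return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))

    def clean_seq(n: int) -> str:
        while True:
            s = random_seq(n)
            if not scan_motif({"x": s}, pwm).iloc[0]:
                return s

    out_samples = {}
    control_ivs = []
    gtrd_ivs = [
        GenomicInterval(*fresh_interval(spec.peak_len)) for _ in range(20)
    ]  # background catalog sites not tied to any peak
    truth_rows = []
    sequences: dict[str, dict[str, str]] = {}

    for sample, (n_kept, n_both, n_gtrd, n_motif, n_in_dmr) in spec.samples.items():
        kept = []
        for i in range(n_kept):
            inside = atrt_hyper if (i < n_in_dmr and len(atrt_hyper)) else None
            chrom, s, e = fresh_interval(spec.peak_len + spec.rep_shift, inside)
            kept.append(GenomicInterval(chrom, s, e))
        rep1 = [GenomicInterval(iv.chrom, iv.start, iv.end - spec.rep_shift) for iv in kept]
        rep2 = [GenomicInterval(iv.chrom, iv.start + spec.rep_shift, iv.end) for iv in kept]
        # intersections (what survives replicate unification)
        inter = [GenomicInterval(iv.chrom, iv.start + spec.rep_shift, iv.end - spec.rep_shift)
                 for iv in kept]

        for _ in range(spec.n_rep_only):
            rep1.append(GenomicInterval(*fresh_interval(spec.peak_len)))
            rep2.append(GenomicInterval(*fresh_interval(spec.peak_len)))
        for _ in range(spec.n_sex_chrom):
            s = int(rng.integers(0, genome.chrom_lengths["chrX"] - spec.peak_len))
            iv = GenomicInterval("chrX", s, s + spec.peak_len)
            rep1.append(iv)
            rep2.append(iv)
        for _ in range(spec.n_control_hit):
            chrom, s, e = fresh_interval(spec.peak_len)
            rep1.append(GenomicInterval(chrom, s, e))
            rep2.append(GenomicInterval(chrom, s, e))
            control_ivs.append(GenomicInterval(chrom, s - 50, e + 50))

        # evidence classes in deterministic (chrom, start) order, matching
        # the names filter_peaks will assign
        inter_sorted = sorted(inter, key=lambda iv: (iv.chrom, iv.start, iv.end))
        classes = (["both"] * n_both + ["gtrd_only"] * n_gtrd + ["motif_only"] * n_motif
                   + ["none"] * (n_kept - n_both - n_gtrd - n_motif))
        rng.shuffle(classes)
        seqs = {}
        for i, (iv, cls) in enumerate(zip(inter_sorted, classes)):
            name = f"peak_{i}"
            if cls in ("both", "gtrd_only"):
                gtrd_ivs.append(GenomicInterval(iv.chrom, max(0, iv.start - 50), iv.end + 50))
            if cls in ("both", "motif_only"):
                seq = clean_seq(iv.length)
                pos = int(rng.integers(0, iv.length - len(spec.consensus)))
                seq = seq[:pos] + spec.consensus + seq[pos + len(spec.consensus):]
            else:
                seq = clean_seq(iv.length)
            seqs[name] = seq
            truth_rows.append({"sample": sample, "name": name, "chrom": iv.chrom,
                               "start": iv.start, "end": iv.end, "class": cls})
        sequences[sample] = seqs
        out_samples[sample] = {"replicates": [IntervalSet(rep1), IntervalSet(rep2)]}

    return {
        "samples": out_samples,
        "control_peaks": IntervalSet(control_ivs),
        "gtrd_sites": IntervalSet(gtrd_ivs),
        "sequences": sequences,
        "pwm": pwm,
        "truth": pd.DataFrame(truth_rows,
                              columns=["sample", "name", "chrom", "start", "end", "class"]),
    }


# ---------------------------------------------------------------------------
# whole study
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    config: StudyConfig
    plan: StudyPlan
    probes: BetaMatrix
    tiles: TileCounts
    regulatory: dict
    expression: dict
    cutrun: dict

    @property
    def truth_dmrs(self) -> pd.DataFrame:
        return self.plan.planted


def generate_study(config: StudyConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate the full synthetic study with one shared layout."""
    config = config or StudyConfig()
    plan = design_study(config, seed)
    probes, tiles, _ = generate_methylomes(config, seed, plan)
    regulatory = generate_regulatory_genome(config, seed, plan)
    expression = generate_expression(
        config, seed, plan, regulatory["dmde_truth"], regulatory["gene_models"]
    )
    cutrun = generate_cutrun(config, seed, plan, regulatory["pwm"])
    return SyntheticStudy(config, plan, probes, tiles, regulatory, expression, cutrun)


def write_study(study: SyntheticStudy, outdir) -> None:
    """Serialize every component of the study as plain-text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study.config.to_yaml(out / "config.yaml")
    study.probes.write_tsv(out / "probe_beta.tsv")
    study.tiles.write_tsv(out / "tile_counts.tsv")
    study.probes.groups.to_csv(out / "sample_groups.tsv", sep="\t", header=["group"])
    study.regulatory["catalog"].write_bed(out / "tf_sites.bed")
    for name, tads in study.regulatory["tad_sets"].items():
        write_bed(tads, out / f"tads_{name}.bed")
    study.regulatory["gene_models"].to_csv(out / "gene_models.tsv", sep="\t", index=False)
    study.regulatory["enhancers"].to_csv(out / "enhancers.tsv", sep="\t", index=False)
    study.regulatory["pwm"].write_jaspar(out / "motif.jaspar")
    study.expression["counts"].to_csv(out / "expression_counts.tsv", sep="\t", index_label="gene")
    study.expression["array"].to_csv(out / "expression_array.tsv", sep="\t", index_label="gene")
    study.expression["groups"].to_csv(out / "expression_groups.tsv", sep="\t", header=["group"])
    for sample, parts in study.cutrun["samples"].items():
        for ri, rep in enumerate(parts["replicates"]):
            write_bed(rep, out / f"cutrun_{sample}_rep{ri + 1}.bed")
    write_bed(study.cutrun["control_peaks"], out / "cutrun_control.bed")
    write_bed(study.cutrun["gtrd_sites"], out / "cutrun_gtrd_sites.bed")
    with open(out / "cutrun_sequences.fasta", "w") as fh:
        for sample, seqs in study.cutrun["sequences"].items():
            for name, seq in seqs.items():
                fh.write(f">{sample}|{name}\n{seq}\n")
    truth = {
        "planted_dmrs": study.plan.planted.to_dict("records"),
        "dmde_genes": study.regulatory["dmde_truth"].to_dict("records"),
        "cutrun": study.cutrun["truth"].to_dict("records"),
        "planted_tf": study.config.tfs.planted_tf,
        "category_tf": study.config.tfs.category_tf,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
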