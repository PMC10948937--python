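"""Detection of TADs carrying concordant large-scale methylation shifts.

A topologically associating domain is flagged for a comparison when, on
*each* platform independently, the units (extended probes or tiles)
falling in it satisfy all of:

* at least ``min_hits`` units shifted in the majority direction with
  |delta-beta| >= ``min_delta``;
* strictly fewer than ``max_opposite`` of the qualifying hits shifted in
  the opposite direction (1/10 exactly fails);
* the span from the first to the last qualifying unit strictly exceeds
  ``min_span`` bp (exactly 50 kb fails);

and the two platforms agree on the majority direction.  Flagged TADs
from all cell-type TAD sets are pooled and merged to single coordinates
per (comparison, direction).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genomic_core import GenomicInterval, IntervalSet, merge_intervals


def _tad_platform_call(
    tad: GenomicInterval,
    units: IntervalSet,
    min_hits: int,
    min_delta: float,
    max_opposite: float,
    min_span: int,
) -> str | None:
    """Direction ('hyper'/'hypo') if this platform's units qualify the TAD,
    else None.  Ties in majority direction never qualify."""
    idx = units._chrom_index().get(tad.chrom)
    if idx is None:
        return None
    starts, ends, ivs = idx["starts"], idx["ends"], idx["ivs"]
    hi = int(np.searchsorted(starts, tad.end, side="left"))
    hits = [
        ivs[j]
        for j in range(hi)
        if ends[j] > tad.start and abs(ivs[j].meta["delta_beta"]) >= min_delta
    ]
    if not hits:
        return None
    n_up = sum(1 for h in hits if h.meta["delta_beta"] > 0)
    n_down = len(hits) - n_up
    if n_up == n_down:
        return None
    direction = "hyper" if n_up > n_down else "hypo"
    n_maj, n_opp = max(n_up, n_down), min(n_up, n_down)
    if n_maj < min_hits:
        return None
    if not (n_opp / (n_maj + n_opp) < max_opposite):
        return None
    span = max(h.end for h in hits) - min(h.start for h in hits)
    if not (span > min_span):
        return None
    return direction


def detect_largescale_tads(
    units_array: IntervalSet,
    units_tiles: IntervalSet,
    tad_sets: dict[str, IntervalSet],
    comparison: str,
    min_hits: int = 5,
    min_delta: float = 0.25,
    max_opposite: float = 1 / 10,
    min_span: int = 50_000,
) -> pd.DataFrame:
    """Flag TADs with concordant large-scale methylation shifts.

    ``units_array``/``units_tiles`` carry signed ``delta_beta`` in meta.
    A TAD is reported when it passes on both platforms with the same
    majority direction; flagged TADs from all TAD sets are pooled and
    merged per direction.  Returns a frame (chrom, start, end,
    comparison, direction, n_source_tads).
    """
    if min_hits < 1:
        raise ValueError("min_hits must be >= 1")
    if not tad_sets:
        raise ValueError("at least one TAD set is required")
    flagged: dict[str, list[GenomicInterval]] = {"hyper": [], "hypo": []}
    for set_name, tads in tad_sets.items():
        for tad in tads:
            d_arr = _tad_platform_call(tad, units_array, min_hits, min_delta, max_opposite, min_span)
            if d_arr is None:
                continue
            d_til = _tad_platform_call(tad, units_tiles, min_hits, min_delta, max_opposite, min_span)
            if d_til == d_arr:
                flagged[d_arr].append(
                    GenomicInterval(tad.chrom, tad.start, tad.end, meta={"tad_set": set_name})
                )
    rows = []
    for direction, ivs in flagged.items():
        if not ivs:
            continue
        for merged in merge_intervals(IntervalSet(ivs), 0):
            rows.append(
                {
                    "chrom": merged.chrom,
                    "start": merged.start,
                    "end": merged.end,
                    "comparison": comparison,
                    "direction": direction,
                    "n_source_tads": merged.meta["n_merged"],
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "comparison", "direction", "n_source_tads"]
    ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def largescale_fraction_by_category(
    dmr_categories: pd.DataFrame,
    largescale: pd.DataFrame,
) -> pd.DataFrame:
    """Fraction of regions per category overlapping (>=1 bp) any flagged
    large-scale TAD of the matching comparison.

    ``dmr_categories`` needs columns (chrom, start, end, comparison,
    category); ``largescale`` is the output of
    :func:`detect_largescale_tads` (possibly concatenated over
    comparisons).
    """
    ls_by_comp: dict[str, IntervalSet] = {}
    for comp, sub in largescale.groupby("comparison") if len(largescale) else ():
        ls_by_comp[comp] = IntervalSet(
            GenomicInterval(r["chrom"], int(r["start"]), int(r["end"])) for _, r in sub.iterrows()
        )
    rows = []
    for category, sub in dmr_categories.groupby("category"):
        n = len(sub)
        hit = 0
        for _, r in sub.iterrows():
            ls = ls_by_comp.get(r["comparison"])
            if ls is None:
                continue
            idx = ls._chrom_index().get(r["chrom"])
            if idx is None:
                continue
            if np.any((idx["starts"] < r["end"]) & (idx["ends"] > r["start"])):
                hit += 1
        rows.append({"category": category, "n_regions": n, "n_largescale": hit,
                     "fraction": hit / n if n else 0.0})
    return pd.DataFrame(rows, columns=["category", "n_regions", "n_largescale", "fraction"])
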