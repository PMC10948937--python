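"""Genomic interval data model and coordinate algebra.

All coordinates are 0-based, half-open (BED convention): an interval
``[start, end)`` covers base pairs ``start .. end-1`` and has length
``end - start``.  Any 1-based input dialect must be converted at the
reader boundary.  Chromosome names are kept verbatim; a canonical
autosome filter (``chr1``..``chr22``) is provided as a reusable
predicate because sex chromosomes and scaffolds are repeatedly dropped
throughout the pipeline.

Iteration order of an :class:`IntervalSet` is deterministic:
chromosome (lexicographic), then start, then end, then insertion index.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

CANONICAL_AUTOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))

_STRANDS = {"+", "-", "."}


@dataclass
class GenomicInterval:
    """A half-open genomic interval with free-form metadata.

    ``meta`` is an open key->value mapping used throughout the pipeline to
    carry region attributes (delta-beta, q-value, TF name, category, ...).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: [{self.start}, {self.end})")
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        return overlap_width(self, other)

    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def __repr__(self) -> str:  # compact, meta elided
        s = f"{self.chrom}:[{self.start},{self.end})"
        return s if self.strand == "." else s + self.strand


def overlap_width(a: GenomicInterval, b: GenomicInterval) -> int:
    """Width in bp of the intersection of two intervals (0 if disjoint or
    on different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def interval_gap(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Number of bases strictly between two intervals; 0 when they touch or
    overlap; None when on different chromosomes."""
    if a.chrom != b.chrom:
        return None
    return max(0, max(a.start, b.start) - min(a.end, b.end))


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`, grouped per
    chromosome and sorted by (start, end, insertion index)."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        ivs = list(intervals)
        order = sorted(
            range(len(ivs)),
            key=lambda i: (ivs[i].chrom, ivs[i].start, ivs[i].end, i),
        )
        self._intervals: list[GenomicInterval] = [ivs[i] for i in order]
        self._index: dict[str, dict[str, np.ndarray]] | None = None

    # -- container protocol -------------------------------------------------
    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __len__(self) -> int:
        return len(self._intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self._intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return [iv.key() for iv in self] == [iv.key() for iv in other]

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals)"

    # -- helpers ------------------------------------------------------------
    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self._intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self._intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def _chrom_index(self) -> dict[str, dict[str, np.ndarray]]:
        if self._index is None:
            idx: dict[str, dict[str, np.ndarray]] = {}
            pos = 0
            for chrom, ivs in self.by_chrom().items():
                idx[chrom] = {
                    "starts": np.array([iv.start for iv in ivs], dtype=np.int64),
                    "ends": np.array([iv.end for iv in ivs], dtype=np.int64),
                    "ivs": np.array(ivs, dtype=object),
                    "order": np.arange(pos, pos + len(ivs)),
                }
                pos += len(ivs)
            self._index = idx
        return self._index

    def total_bp(self) -> int:
        """Total bp covered (union; overlapping intervals counted once)."""
        return sum(iv.length for iv in merge_intervals(self, 0))

    def filter(self, predicate) -> "IntervalSet":
        return IntervalSet(iv for iv in self if predicate(iv))


def is_canonical(chrom: str, include_sex: bool = False) -> bool:
    """Canonical-chromosome predicate: autosomes chr1..chr22, optionally
    chrX/chrY. Scaffolds and mitochondrial contigs are never canonical."""
    if chrom in CANONICAL_AUTOSOMES:
        return True
    return include_sex and chrom in ("chrX", "chrY")


def filter_canonical(ivset: IntervalSet, include_sex: bool = False) -> IntervalSet:
    return ivset.filter(lambda iv: is_canonical(iv.chrom, include_sex=include_sex))


# ---------------------------------------------------------------------------
# coordinate algebra
# ---------------------------------------------------------------------------

def merge_intervals(ivset: IntervalSet, max_gap: int = 0) -> IntervalSet:
    """Merge intervals whose gap is <= ``max_gap`` bp into single runs.

    Output intervals are pairwise disjoint per chromosome; with
    ``max_gap=0`` the union of covered bp equals the input's union.
    Each output interval's meta records ``n_merged``.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    out: list[GenomicInterval] = []
    for chrom, ivs in ivset.by_chrom().items():
        cur_start, cur_end, n = ivs[0].start, ivs[0].end, 1
        for iv in ivs[1:]:
            if iv.start <= cur_end + max_gap:
                cur_end = max(cur_end, iv.end)
                n += 1
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end, meta={"n_merged": n}))
                cur_start, cur_end, n = iv.start, iv.end, 1
        out.append(GenomicInterval(chrom, cur_start, cur_end, meta={"n_merged": n}))
    return IntervalSet(out)


def extend_intervals(ivset: IntervalSet, pad: int) -> IntervalSet:
    """Pad every interval by ``pad`` bp on both sides (clipped at 0).
    Metadata and strand are preserved; no merging is performed."""
    if pad < 0:
        raise ValueError(f"pad must be >= 0, got {pad}")
    return IntervalSet(
        GenomicInterval(iv.chrom, max(0, iv.start - pad), iv.end + pad, iv.strand, dict(iv.meta))
        for iv in ivset
    )


def _max_single_overlap(q: GenomicInterval, starts: np.ndarray, ends: np.ndarray) -> int:
    """Largest overlap of ``q`` with any single interval in (starts, ends)
    (sorted by start)."""
    if len(starts) == 0:
        return 0
    hi = int(np.searchsorted(starts, q.end, side="left"))
    if hi == 0:
        return 0
    ov = np.minimum(ends[:hi], q.end) - np.maximum(starts[:hi], q.start)
    m = int(ov.max()) if hi else 0
    return max(0, m)


def subset_by_overlap(
    query: IntervalSet,
    subject: IntervalSet,
    min_overlap: int = 1,
    invert: bool = False,
) -> IntervalSet:
    """Keep query intervals whose overlap with any *single* subject interval
    is >= ``min_overlap`` bp; ``invert=True`` returns the complement.
    Query metadata is preserved."""
    if min_overlap < 1:
        raise ValueError(f"min_overlap must be >= 1, got {min_overlap}")
    sindex = subject._chrom_index()
    kept: list[GenomicInterval] = []
    for q in query:
        ci = sindex.get(q.chrom)
        hit = ci is not None and _max_single_overlap(q, ci["starts"], ci["ends"]) >= min_overlap
        if hit != invert:
            kept.append(q)
    return IntervalSet(kept)


def intersect_spans(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Per-bp intersection of two interval sets, returned as maximal runs.

    Each output interval carries the metadata (and strand) of its
    contributing ``a``-interval; ``b`` only gates which base pairs survive.
    """
    bm = merge_intervals(b, 0) if len(b) else IntervalSet()
    bidx = bm._chrom_index()
    out: list[GenomicInterval] = []
    for iv in a:
        ci = bidx.get(iv.chrom)
        if ci is None:
            continue
        starts, ends = ci["starts"], ci["ends"]
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        for j in range(hi):
            s = max(iv.start, int(starts[j]))
            e = min(iv.end, int(ends[j]))
            if e > s:
                out.append(GenomicInterval(iv.chrom, s, e, iv.strand, dict(iv.meta)))
    return IntervalSet(out)


def distance_to_nearest(q: GenomicInterval, subject: IntervalSet) -> int | None:
    """Gap in bp to the nearest subject interval on the same chromosome
    (0 when overlapping/touching); None when the chromosome is absent."""
    ci = subject._chrom_index().get(q.chrom)
    if ci is None:
        return None
    starts, ends = ci["starts"], ci["ends"]
    gaps = np.maximum(0, np.maximum(starts, q.start) - np.minimum(ends, q.end))
    return int(gaps.min())


# ---------------------------------------------------------------------------
# BED dialect I/O
# ---------------------------------------------------------------------------

def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def write_bed(ivset: IntervalSet, path, meta_cols: list[str] | None = None) -> None:
    """Write BED3/BED6 (tab-separated, half-open).  When ``meta_cols`` is
    given, a commented header line is emitted and each listed meta key is
    appended as an extra column (missing values as '.')."""
    with _open_text(path, "wt") as fh:
        if meta_cols:
            fh.write("#chrom\tstart\tend\tname\tscore\tstrand\t" + "\t".join(meta_cols) + "\n")
        for iv in ivset:
            name = str(iv.meta.get("name", "."))
            score = str(iv.meta.get("score", 0))
            row = [iv.chrom, str(iv.start), str(iv.end), name, score, iv.strand]
            if meta_cols:
                row += [str(iv.meta.get(c, ".")) for c in meta_cols]
            fh.write("\t".join(row) + "\n")


def read_bed(path) -> IntervalSet:
    """Read BED3/BED6 plus extended meta columns written by
    :func:`write_bed`.  Numeric meta values are parsed back to float."""
    ivs: list[GenomicInterval] = []
    meta_cols: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser")):
                continue
            if line.startswith("#"):
                cols = line[1:].split("\t")
                meta_cols = cols[6:]
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            meta: dict = {}
            strand = "."
            if len(parts) > 3 and parts[3] != ".":
                meta["name"] = parts[3]
            if len(parts) > 4 and parts[4] != ".":
                try:
                    sc = float(parts[4])
                    meta["score"] = int(sc) if sc == int(sc) else sc
                except ValueError:
                    meta["score"] = parts[4]
            if len(parts) > 5 and parts[5] in _STRANDS:
                strand = parts[5]
            for i, col in enumerate(meta_cols):
                j = 6 + i
                if j < len(parts) and parts[j] != ".":
                    try:
                        meta[col] = float(parts[j])
                    except ValueError:
                        meta[col] = parts[j]
            ivs.append(GenomicInterval(chrom, start, end, strand, meta))
    return IntervalSet(ivs)
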