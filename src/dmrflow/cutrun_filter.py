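"""CUT&RUN peak post-processing.

Peak-level filtering (replicate bp-intersection, control subtraction,
canonical-chromosome filter), motif scanning with an exact score-
distribution p-value threshold, retention by binding-catalog overlap or
motif presence, and DMR/methylation summaries of the retained peaks.

The motif scanner follows the FIMO convention: a log-odds position
weight matrix is scored over every window on both strands, and the hit
threshold ``s*`` is the smallest score whose tail probability under a
zero-order background, computed by exact dynamic programming over the
discretized per-position score distributions, falls below ``p_max``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .containers import BetaMatrix
from .genomic_core import (
    GenomicInterval,
    IntervalSet,
    intersect_spans,
    is_canonical,
    merge_intervals,
    subset_by_overlap,
)

BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class PWM:
    """Position weight matrix over {A,C,G,T} with a log-odds view.

    ``probs`` has shape (width, 4); each row sums to 1 (built from counts
    with a pseudocount).  ``background`` is the zero-order base
    distribution used both for the log-odds and for the score-
    distribution p-value.
    """

    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    name: str = "motif"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must have shape (width, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")
        if not np.allclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / self.background[None, :])

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        pseudocount: float = 0.1,
        background: np.ndarray | None = None,
        name: str = "motif",
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
        adj = counts + pseudocount * bg[None, :] * 4  # pseudocount split by background
        probs = adj / adj.sum(axis=1, keepdims=True)
        return cls(probs, bg, name)

    @classmethod
    def from_jaspar(cls, path, pseudocount: float = 0.1,
                    background: np.ndarray | None = None) -> "PWM":
        """Read a JASPAR-format position frequency matrix."""
        with open(path) as fh:
            motif = bio_motifs.read(fh, "jaspar")
        counts = np.array([[motif.counts[b][i] for b in BASES] for i in range(motif.length)])
        return cls.from_counts(counts, pseudocount, background, name=motif.name or "motif")

    def write_jaspar(self, path, scale: int = 100) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name} {self.name}\n")
            for bi, b in enumerate(BASES):
                vals = " ".join(str(int(round(p * scale))) for p in self.probs[:, bi])
                fh.write(f"{b} [ {vals} ]\n")


def discretized_log_odds(pwm: PWM, bin_width: float = 1e-3) -> np.ndarray:
    """Integer per-position log-odds scores, ``floor(log_odds/bin_width)``.

    Both the threshold DP and the scanner work on this shared discretized
    matrix, so hit decisions are exact with respect to it; the
    discretization error is at most ``width * bin_width`` log2-units.
    """
    return np.floor(pwm.log_odds / bin_width).astype(np.int64)


def score_threshold(pwm: PWM, p_max: float = 0.001, bin_width: float = 1e-3) -> float:
    """Smallest achievable score ``s*`` (on the discretized scale, in
    log2-units) with P(window score >= s* | background) < p_max, computed
    by exact dynamic programming over the per-position score
    distributions.  Returns +inf when no score is rare enough."""
    if not (0 < p_max < 1):
        raise ValueError("p_max must lie in (0, 1)")
    scaled = discretized_log_odds(pwm, bin_width)
    dist = {0: 1.0}
    for i in range(pwm.width):
        new: dict[int, float] = {}
        for s, p in dist.items():
            for bi in range(4):
                key = s + int(scaled[i, bi])
                new[key] = new.get(key, 0.0) + p * pwm.background[bi]
        dist = new
    keys = sorted(dist)
    tail = 0.0
    k_star = None
    for k in reversed(keys):  # accumulate the upper tail
        tail += dist[k]
        if tail < p_max:
            k_star = k
        else:
            break
    if k_star is None:
        return float("inf")
    return float(k_star * bin_width)


def _window_scores(seq: str, scaled: np.ndarray) -> np.ndarray:
    """All window scores on one strand using the discretized matrix.
    N positions contribute 0 (the log-odds of background vs background)."""
    w = scaled.shape[0]
    n = len(seq) - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    base_idx = np.full(len(seq), -1, dtype=np.int8)
    for bi, b in enumerate(BASES):
        base_idx[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = bi
    scores = np.zeros(n, dtype=np.int64)
    for i in range(w):
        col = base_idx[i : i + n]
        scores += np.where(col >= 0, scaled[i, np.clip(col, 0, 3)], 0)
    return scores


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq))


def scan_motif(
    sequences: dict[str, str],
    pwm: PWM,
    p_max: float = 0.001,
    bin_width: float = 1e-3,
) -> pd.Series:
    """Flag each sequence as a motif hit.

    A record is a hit iff any window on either strand scores at or above
    the exact-DP threshold for ``p_max``.  Sequences shorter than the
    motif width are never hits; N positions score as background (0).
    """
    thr = score_threshold(pwm, p_max, bin_width)
    thr_int = np.inf if np.isinf(thr) else int(round(thr / bin_width))
    scaled = discretized_log_odds(pwm, bin_width)
    flags = {}
    for name, seq in sequences.items():
        seq = seq.upper()
        hit = False
        if len(seq) >= pwm.width and not np.isinf(thr_int):
            for s in (seq, reverse_complement(seq)):
                sc = _window_scores(s, scaled)
                if sc.size and sc.max() >= thr_int:
                    hit = True
                    break
        flags[name] = hit
    return pd.Series(flags, name="motif_hit")


def filter_peaks(
    replicate_peaks: list[IntervalSet],
    control_peaks: IntervalSet,
    include_sex: bool = False,
) -> IntervalSet:
    """Peak-level filtering for one sample.

    Drops peaks on non-canonical chromosomes (and chrX/chrY), drops
    peaks overlapping (>=1 bp) any control peak, then unifies replicates
    by per-bp intersection, re-extracted as maximal regions.  Peak names
    are reassigned as ``peak_<i>`` after unification.
    """
    if not replicate_peaks:
        raise ValueError("at least one replicate is required")

    def clean(peaks: IntervalSet) -> IntervalSet:
        kept = peaks.filter(lambda iv: is_canonical(iv.chrom, include_sex=include_sex))
        if len(control_peaks):
            kept = subset_by_overlap(kept, control_peaks, min_overlap=1, invert=True)
        return kept

    cleaned = [clean(p) for p in replicate_peaks]
    result = merge_intervals(cleaned[0], 0) if len(cleaned[0]) else IntervalSet()
    for rep in cleaned[1:]:
        if len(result) == 0 or len(rep) == 0:
            result = IntervalSet()
            break
        result = merge_intervals(intersect_spans(result, rep), 0)
    out = [
        GenomicInterval(iv.chrom, iv.start, iv.end, meta={"name": f"peak_{i}"})
        for i, iv in enumerate(result)
    ]
    return IntervalSet(out)


def retain_by_evidence(
    peaks: IntervalSet,
    gtrd_sites: IntervalSet,
    motif_flags: pd.Series,
) -> pd.DataFrame:
    """Retain peaks supported by catalog overlap or motif presence.

    Returns a frame (name, chrom, start, end, gtrd_overlap, motif_hit,
    evidence_class) where evidence_class is one of gtrd_only /
    motif_only / both; unsupported peaks are dropped.
    """
    rows = []
    for iv in peaks:
        name = iv.meta.get("name", f"{iv.chrom}:{iv.start}-{iv.end}")
        gtrd = len(subset_by_overlap(IntervalSet([iv]), gtrd_sites, 1)) > 0 if len(gtrd_sites) else False
        motif = bool(motif_flags.get(name, False))
        if not (gtrd or motif):
            continue
        cls = "both" if (gtrd and motif) else ("gtrd_only" if gtrd else "motif_only")
        rows.append(
            {
                "name": name,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "gtrd_overlap": gtrd,
                "motif_hit": motif,
                "evidence_class": cls,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["name", "chrom", "start", "end", "gtrd_overlap", "motif_hit", "evidence_class"],
    )


def peaks_vs_dmr_classes(
    retained: pd.DataFrame,
    dmr_classes: dict[str, IntervalSet],
    sample: str = "sample",
) -> pd.DataFrame:
    """Count retained peaks overlapping (>=1 bp) each DMR class."""
    rows = []
    for cls_name, regions in dmr_classes.items():
        idx = regions._chrom_index()
        n = 0
        for _, r in retained.iterrows():
            ci = idx.get(r["chrom"])
            if ci is not None and np.any(
                (ci["starts"] < r["end"]) & (ci["ends"] > r["start"])
            ):
                n += 1
        rows.append({"sample": sample, "dmr_class": cls_name, "n_peaks": n})
    return pd.DataFrame(rows, columns=["sample", "dmr_class", "n_peaks"])


def peak_high_methylation_fraction(
    retained: pd.DataFrame,
    beta_matrix: BetaMatrix,
    group: str,
    cutoff: float = 0.5,
) -> float:
    """Fraction of peaks whose methylation exceeds ``cutoff`` in *every*
    sample of ``group`` (strict inequality).

    Peak methylation per sample is the mean beta of the units overlapping
    the peak; peaks overlapping no unit are excluded from the
    denominator.
    """
    samples = beta_matrix.samples_of(group)
    coords = beta_matrix.coords
    n_eval, n_high = 0, 0
    for _, r in retained.iterrows():
        mask = (
            (coords["chrom"] == r["chrom"])
            & (coords["start"] < r["end"])
            & (coords["end"] > r["start"])
        )
        if not mask.any():
            continue
        n_eval += 1
        peak_beta = beta_matrix.beta.loc[mask, samples].mean(axis=0)
        if (peak_beta > cutoff).all():
            n_high += 1
    if n_eval == 0:
        warnings.warn("no retained peak overlaps any methylation unit")
        return float("nan")
    return n_high / n_eval
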