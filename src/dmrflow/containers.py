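"""Shared in-memory containers: methylation matrices, tile counts, DMR sets.

These are thin wrappers over pandas objects so that every stage of the
pipeline exchanges the same structures:

* :class:`BetaMatrix` — per-unit (probe or tile) methylation level beta
  in [0, 1] across samples, with a group label per sample and genomic
  coordinates per unit.
* :class:`TileCounts` — (methylated, total) read-count pairs per 1-kb
  tile and sample, as produced by bisulfite sequencing.
* :class:`DMRSet` — differentially methylated regions carrying
  delta-beta, BH q-value, direction, supporting-unit count, platform and
  comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_core import GenomicInterval, IntervalSet

COORD_COLS = ["chrom", "start", "end"]
DMR_COLS = COORD_COLS + ["delta_beta", "q", "direction", "n_units", "platform", "comparison"]


def coords_to_intervals(coords: pd.DataFrame, extra: pd.DataFrame | None = None) -> IntervalSet:
    """Convert a (chrom, start, end)-indexed frame to an IntervalSet; the
    index goes into meta['name'] and any ``extra`` columns into meta."""
    ivs = []
    extra_records = extra.to_dict("index") if extra is not None else {}
    for unit, row in coords.iterrows():
        meta = {"name": unit}
        meta.update(extra_records.get(unit, {}))
        ivs.append(GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]), meta=meta))
    return IntervalSet(ivs)


@dataclass
class BetaMatrix:
    """Methylation levels: ``beta`` (units x samples), ``coords``
    (chrom/start/end per unit), ``groups`` (group label per sample)."""

    beta: pd.DataFrame
    coords: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.beta.index.equals(self.coords.index):
            self.coords = self.coords.loc[self.beta.index]
        missing = [s for s in self.beta.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group label: {missing[:5]}")
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def samples(self) -> list[str]:
        return list(self.beta.columns)

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.beta.columns if self.groups[s] == group]

    def subset_groups(self, groups: list[str]) -> "BetaMatrix":
        cols = [s for s in self.beta.columns if self.groups[s] in groups]
        return BetaMatrix(self.beta[cols], self.coords, self.groups[cols])

    def intervals(self) -> IntervalSet:
        return coords_to_intervals(self.coords)

    def write_tsv(self, path) -> None:
        out = pd.concat([self.coords, self.beta], axis=1)
        out.to_csv(path, sep="\t", index_label="unit")

    @classmethod
    def read_tsv(cls, path, groups: pd.Series) -> "BetaMatrix":
        df = pd.read_csv(path, sep="\t", index_col="unit")
        coords = df[COORD_COLS]
        beta = df.drop(columns=COORD_COLS)
        return cls(beta, coords, groups)


@dataclass
class TileCounts:
    """Bisulfite tile counts: ``meth`` and ``total`` (tiles x samples),
    plus coordinates and sample groups.  ``meth <= total`` everywhere."""

    meth: pd.DataFrame
    total: pd.DataFrame
    coords: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.meth.index.equals(self.total.index):
            raise ValueError("meth/total tile indices differ")
        if (self.meth.to_numpy() > self.total.to_numpy()).any():
            raise ValueError("methylated count exceeds total count")

    def beta(self) -> pd.DataFrame:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.meth / self.total

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.meth.columns if self.groups[s] == group]

    def intervals(self) -> IntervalSet:
        return coords_to_intervals(self.coords)

    def write_tsv(self, path) -> None:
        meth = self.meth.add_suffix(".meth")
        total = self.total.add_suffix(".total")
        out = pd.concat([self.coords, meth, total], axis=1)
        out.to_csv(path, sep="\t", index_label="unit")

    @classmethod
    def read_tsv(cls, path, groups: pd.Series) -> "TileCounts":
        df = pd.read_csv(path, sep="\t", index_col="unit")
        coords = df[COORD_COLS]
        meth = df[[c for c in df.columns if c.endswith(".meth")]]
        meth.columns = [c[: -len(".meth")] for c in meth.columns]
        total = df[[c for c in df.columns if c.endswith(".total")]]
        total.columns = [c[: -len(".total")] for c in total.columns]
        return cls(meth, total, coords, groups)


@dataclass
class DMRSet:
    """A set of differentially methylated regions for one comparison on
    one platform.  ``direction`` is hyper/hypo w.r.t. the first group of
    the comparison and always agrees with the sign of ``delta_beta``."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=DMR_COLS))

    def __post_init__(self) -> None:
        for col in DMR_COLS:
            if col not in self.df.columns:
                raise ValueError(f"DMRSet missing column {col!r}")
        if len(self.df):
            d = self.df
            if (d["q"].lt(0) | d["q"].gt(1)).any():
                raise ValueError("q must lie in [0, 1]")
            if d["delta_beta"].abs().gt(1 + 1e-9).any():
                raise ValueError("|delta_beta| must be <= 1")
            want = np.where(d["delta_beta"].to_numpy() > 0, "hyper", "hypo")
            if (d["direction"].to_numpy() != want).any():
                raise ValueError("direction must equal sign(delta_beta)")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def platform(self) -> str | None:
        return self.df["platform"].iloc[0] if len(self.df) else None

    @property
    def comparison(self) -> str | None:
        return self.df["comparison"].iloc[0] if len(self.df) else None

    def subset(self, mask) -> "DMRSet":
        return DMRSet(self.df[mask].reset_index(drop=True))

    def intervals(self) -> IntervalSet:
        ivs = []
        for i, row in self.df.iterrows():
            meta = {
                "name": f"{row['comparison']}_{i}",
                "delta_beta": float(row["delta_beta"]),
                "q": float(row["q"]),
                "direction": row["direction"],
            }
            ivs.append(GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]), meta=meta))
        return IntervalSet(ivs)

    def write_bed(self, path) -> None:
        """Extended BED: name=comparison, score=round(delta_beta*1000),
        plus q and direction columns."""
        with open(Path(path), "w") as fh:
            fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tq\tdirection\tn_units\tplatform\n")
            for _, row in self.df.iterrows():
                fh.write(
                    "\t".join(
                        [
                            row["chrom"],
                            str(int(row["start"])),
                            str(int(row["end"])),
                            str(row["comparison"]),
                            str(int(round(row["delta_beta"] * 1000))),
                            ".",
                            f"{row['q']:.6g}",
                            row["direction"],
                            str(int(row["n_units"])),
                            row["platform"],
                        ]
                    )
                    + "\n"
                )

    @classmethod
    def read_bed(cls, path) -> "DMRSet":
        rows = []
        with open(Path(path)) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                p = line.rstrip("\n").split("\t")
                rows.append(
                    {
                        "chrom": p[0],
                        "start": int(p[1]),
                        "end": int(p[2]),
                        "comparison": p[3],
                        "delta_beta": int(p[4]) / 1000.0,
                        "q": float(p[6]),
                        "direction": p[7],
                        "n_units": int(p[8]),
                        "platform": p[9],
                    }
                )
        return cls(pd.DataFrame(rows)[DMR_COLS] if rows else pd.DataFrame(columns=DMR_COLS))


def empty_dmrset(platform: str = "array", comparison: str = "") -> DMRSet:
    return DMRSet(pd.DataFrame(columns=DMR_COLS))
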