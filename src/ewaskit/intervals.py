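"""Tissue-labelled genomic interval collections (open-chromatin hotspots).

Intervals are 0-based half-open ``[start, end)``, the BED convention.  A CpG
probe interrogates a single 1-based base ``pos``; it overlaps an interval iff
``start < pos <= end``, i.e. the 0-based coordinate ``pos - 1`` lies inside
the half-open interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_BED_COLUMNS = ["chrom", "start", "end"]


def _normalize_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Sort and merge overlapping/adjacent intervals per chromosome."""
    if df.empty:
        return pd.DataFrame(columns=_BED_COLUMNS)
    if (df["start"] >= df["end"]).any():
        raise ValueError("intervals must satisfy start < end")
    out = []
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end"])
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        merged_s = [int(starts[0])]
        merged_e = [int(ends[0])]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= merged_e[-1]:
                merged_e[-1] = max(merged_e[-1], int(e))
            else:
                merged_s.append(int(s))
                merged_e.append(int(e))
        out.append(pd.DataFrame({"chrom": chrom, "start": merged_s, "end": merged_e}))
    return pd.concat(out, ignore_index=True)


@dataclass
class IntervalCollection:
    """Per-tissue sets of genomic intervals, normalized to merged-disjoint form."""

    data: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = {t: _normalize_intervals(df) for t, df in self.data.items()}

    @property
    def tissues(self) -> list[str]:
        return sorted(self.data)

    def intervals(self, tissue: str) -> pd.DataFrame:
        if tissue not in self.data:
            raise KeyError(f"no intervals for tissue {tissue!r}")
        return self.data[tissue]

    def contains_positions(self, tissue: str, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Boolean overlap of 1-based single-base positions with a tissue's intervals.

        A position overlaps iff ``start < pos <= end`` for some interval.
        """
        chrom = np.asarray(chrom)
        pos0 = np.asarray(pos, dtype=np.int64) - 1  # to 0-based
        hit = np.zeros(pos0.shape, dtype=bool)
        df = self.intervals(tissue)
        for c, sub in df.groupby("chrom"):
            mask = chrom == c
            if not mask.any():
                continue
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            idx = np.searchsorted(starts, pos0[mask], side="right") - 1
            ok = idx >= 0
            inside = np.zeros(ok.shape, dtype=bool)
            inside[ok] = pos0[mask][ok] < ends[idx[ok]]
            hit[mask] = inside
        return hit

    def to_bed_dir(self, directory: str | Path) -> None:
        """Write one BED3 file per tissue (``<tissue>.bed``)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for tissue, df in self.data.items():
            df[_BED_COLUMNS].to_csv(directory / f"{tissue}.bed", sep="\t", header=False, index=False)

    @classmethod
    def from_bed_dir(cls, directory: str | Path) -> "IntervalCollection":
        """Read one BED file per tissue; the tissue label is the file stem."""
        directory = Path(directory)
        data = {}
        for path in sorted(directory.glob("*.bed")):
            df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2], names=_BED_COLUMNS)
            data[path.stem] = df
        if not data:
            logger.warning("no .bed files found in %s", directory)
        return cls(data)
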