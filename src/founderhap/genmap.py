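"""Physical <-> genetic coordinate conversion.

A :class:`GeneticMap` is a monotone map from basepair position to
cumulative genetic position (cM). With knots it interpolates linearly and
refuses to extrapolate (silent extrapolation corrupts dating); without
knots it falls back to a uniform rate, 1 cM/Mb by default — the standard
genome-wide average, and the rate under which an 800 kb interval measures
0.8 cM.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

__all__ = ["GeneticMap", "physical_to_genetic", "read_genetic_map"]


@dataclass
class GeneticMap:
    """Physical-to-genetic position function for one chromosome."""

    chrom: str = ""
    positions_bp: Optional[np.ndarray] = None
    cumulative_cm: Optional[np.ndarray] = None
    rate_cm_per_mb: float = 1.0

    def __post_init__(self) -> None:
        if (self.positions_bp is None) != (self.cumulative_cm is None):
            raise ValueError("knot positions and cM values must be given together")
        if self.positions_bp is not None:
            self.positions_bp = np.asarray(self.positions_bp, dtype=np.float64)
            self.cumulative_cm = np.asarray(self.cumulative_cm, dtype=np.float64)
            if len(self.positions_bp) != len(self.cumulative_cm):
                raise ValueError("knot arrays must have equal length")
            if len(self.positions_bp) < 2:
                raise ValueError("a knotted map needs at least two knots")
            if not np.all(np.diff(self.positions_bp) > 0):
                raise ValueError("knot positions must be strictly increasing")
            if np.any(np.diff(self.cumulative_cm) < 0):
                raise ValueError("cumulative cM must be non-decreasing")
        if self.rate_cm_per_mb <= 0:
            raise ValueError("uniform rate must be positive")

    @property
    def has_knots(self) -> bool:
        return self.positions_bp is not None

    def cm_at(self, pos_bp: float) -> float:
        """Cumulative genetic position (cM) at a physical position."""
        if self.has_knots:
            if pos_bp < self.positions_bp[0] or pos_bp > self.positions_bp[-1]:
                raise ValueError(
                    f"position {pos_bp:.0f} outside map range "
                    f"[{self.positions_bp[0]:.0f}, {self.positions_bp[-1]:.0f}] "
                    f"on {self.chrom or '?'}; extrapolation is refused"
                )
            return float(np.interp(pos_bp, self.positions_bp, self.cumulative_cm))
        return pos_bp / 1e6 * self.rate_cm_per_mb

    def bp_at_cm(self, cm: float) -> float:
        """Inverse map: physical position at a cumulative genetic position.

        On a knotted map with zero-recombination plateaus the inverse is
        set-valued; the leftmost physical position is returned.
        """
        if self.has_knots:
            if cm < self.cumulative_cm[0] or cm > self.cumulative_cm[-1]:
                raise ValueError("genetic position outside map range")
            return float(np.interp(cm, self.cumulative_cm, self.positions_bp))
        return cm / self.rate_cm_per_mb * 1e6

    def genetic_length_cm(self, interval: GenomicInterval) -> float:
        return self.cm_at(interval.end) - self.cm_at(interval.start)


def physical_to_genetic(interval: GenomicInterval, gmap: GeneticMap) -> float:
    """Genetic length of an interval in cM (interpolated, or uniform-rate)."""
    return gmap.genetic_length_cm(interval)


def read_genetic_map(path: str | os.PathLike, chrom: str = "") -> GeneticMap:
    """Read a tab-separated recombination map.

    Accepts a two-column ``position(bp)<TAB>cM`` table (with or without a
    header) or HapMap-style columns where the physical position column
    contains "pos" and the cumulative column contains "cm"/"map"
    (case-insensitive); otherwise the first and last numeric columns are
    taken as position and cumulative cM.
    """
    path = os.fspath(path)
    try:
        df = pd.read_csv(path, sep=r"\s+", engine="python")
    except Exception as exc:
        raise IOError(f"could not read genetic map {path}: {exc}") from exc
    # A headerless two-column file parses with its first row as the header;
    # detect by checking whether the column labels themselves are numeric.
    try:
        float(str(df.columns[0]))
        df = pd.read_csv(path, sep=r"\s+", engine="python", header=None)
    except ValueError:
        pass

    num = df.select_dtypes(include=[np.number])
    if num.shape[1] < 2:
        raise ValueError(f"genetic map {path} needs at least two numeric columns")
    pos_col: Optional[str] = None
    cm_col: Optional[str] = None
    for c in num.columns:
        name = str(c).lower()
        if pos_col is None and ("pos" in name or name.endswith("(bp)") or name == "bp"):
            pos_col = c
        if ("map" in name and "cm" in name) or name in ("cm", "geneticmap", "genetic_map"):
            cm_col = c
    if pos_col is None:
        pos_col = num.columns[0]
    if cm_col is None:
        cm_col = num.columns[-1]
    return GeneticMap(
        chrom=chrom,
        positions_bp=num[pos_col].to_numpy(dtype=np.float64),
        cumulative_cm=num[cm_col].to_numpy(dtype=np.float64),
    )
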