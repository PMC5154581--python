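"""Core genomic containers shared by every stage of the pipeline.

Coordinates are 0-based, half-open (BED convention) throughout. Bins and
segments are kept as parallel numpy arrays inside lightweight dataclasses
rather than raw DataFrames so that invariants (sorted, non-overlapping,
matching grids) can be validated once at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BinProfile",
    "SegmentSet",
    "DilutionSeries",
    "AMP",
    "DEL",
    "NEUTRAL",
]

AMP = "AMP"
DEL = "DEL"
NEUTRAL = "NEUTRAL"


def _as_str_array(x: Iterable) -> np.ndarray:
    return np.asarray(list(x) if not isinstance(x, np.ndarray) else x, dtype=object)


def _check_intervals(chrom: np.ndarray, start: np.ndarray, end: np.ndarray,
                     what: str) -> None:
    if not (len(chrom) == len(start) == len(end)):
        raise ValueError(f"{what}: chrom/start/end lengths differ")
    if len(chrom) == 0:
        raise ValueError(f"{what}: empty interval set")
    if np.any(end <= start):
        i = int(np.argmax(end <= start))
        raise ValueError(f"{what}: interval {i} has end <= start "
                         f"({chrom[i]}:{start[i]}-{end[i]})")
    # sorted & non-overlapping within each chromosome, chromosome blocks contiguous
    seen: set = set()
    prev_chrom = None
    prev_end = -1
    for i in range(len(chrom)):
        c = chrom[i]
        if c != prev_chrom:
            if c in seen:
                raise ValueError(f"{what}: chromosome {c} appears in "
                                 f"non-contiguous blocks (line {i + 1})")
            seen.add(c)
            prev_chrom = c
            prev_end = -1
        if start[i] < prev_end:
            raise ValueError(f"{what}: unsorted or overlapping intervals at "
                             f"line {i + 1} ({c}:{start[i]} < previous end {prev_end})")
        prev_end = end[i]


@dataclass
class BinProfile:
    """Ordered autosomal bins with read counts and derived ratios.

    ``count`` may be float in deterministic (expectation) mixing mode.
    ``ratio``/``log2_ratio`` are populated by :func:`ctdna_stability.profiles.normalize`.
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    count: np.ndarray
    ratio: np.ndarray | None = None
    log2_ratio: np.ndarray | None = None
    floored: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.chrom = _as_str_array(self.chrom)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.count = np.asarray(self.count, dtype=float)
        _check_intervals(self.chrom, self.start, self.end, "BinProfile")
        if len(self.count) != len(self.chrom):
            raise ValueError("BinProfile: count length mismatch")
        if np.any(self.count < 0):
            raise ValueError("BinProfile: negative counts")

    @property
    def n_bins(self) -> int:
        return len(self.chrom)

    def same_grid(self, other: "BinProfile") -> bool:
        return (self.n_bins == other.n_bins
                and bool(np.all(self.chrom == other.chrom))
                and bool(np.all(self.start == other.start))
                and bool(np.all(self.end == other.end)))

    def require_same_grid(self, other: "BinProfile") -> None:
        if self.n_bins != other.n_bins:
            raise ValueError(f"bin grids differ: {self.n_bins} vs {other.n_bins} bins")
        bad = (self.chrom != other.chrom) | (self.start != other.start) \
            | (self.end != other.end)
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(
                f"bin grids differ at bin {i}: "
                f"{self.chrom[i]}:{self.start[i]}-{self.end[i]} vs "
                f"{other.chrom[i]}:{other.start[i]}-{other.end[i]}")

    def with_counts(self, count: np.ndarray) -> "BinProfile":
        return BinProfile(self.chrom.copy(), self.start.copy(),
                          self.end.copy(), np.asarray(count, dtype=float))

    def copy(self) -> "BinProfile":
        return replace(
            self,
            chrom=self.chrom.copy(), start=self.start.copy(),
            end=self.end.copy(), count=self.count.copy(),
            ratio=None if self.ratio is None else self.ratio.copy(),
            log2_ratio=None if self.log2_ratio is None else self.log2_ratio.copy(),
            floored=None if self.floored is None else self.floored.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        d = {"chrom": self.chrom, "start": self.start, "end": self.end,
             "count": self.count}
        if self.ratio is not None:
            d["ratio"] = self.ratio
        if self.log2_ratio is not None:
            d["log2_ratio"] = self.log2_ratio
        return pd.DataFrame(d)


@dataclass
class SegmentSet:
    """Fixed genomic segments with optional copy number, class and median log2."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    copy_number: np.ndarray | None = None
    seg_class: np.ndarray | None = None
    median_log2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = _as_str_array(self.chrom)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        _check_intervals(self.chrom, self.start, self.end, "SegmentSet")
        if self.copy_number is not None:
            self.copy_number = np.asarray(self.copy_number, dtype=np.int64)
            if np.any(self.copy_number < 0):
                raise ValueError("SegmentSet: negative copy number")
        if self.seg_class is not None:
            self.seg_class = _as_str_array(self.seg_class)
            bad = set(self.seg_class) - {AMP, DEL, NEUTRAL}
            if bad:
                raise ValueError(f"SegmentSet: unknown class labels {sorted(bad)}")
        if self.median_log2 is not None:
            self.median_log2 = np.asarray(self.median_log2, dtype=float)

    @property
    def n_segments(self) -> int:
        return len(self.chrom)

    def label(self, i: int) -> str:
        return f"{self.chrom[i]}:{self.start[i]}-{self.end[i]}"

    def classes_from_copy_number(self, normal_copy_number: int = 2) -> "SegmentSet":
        """Assign AMP/DEL/NEUTRAL from integer truth copy numbers."""
        if self.copy_number is None:
            raise ValueError("no copy numbers on this SegmentSet")
        cls = np.where(self.copy_number > normal_copy_number, AMP,
                       np.where(self.copy_number < normal_copy_number, DEL, NEUTRAL))
        return replace(self, seg_class=cls.astype(object))

    def to_frame(self) -> pd.DataFrame:
        d = {"chrom": self.chrom, "start": self.start, "end": self.end}
        if self.copy_number is not None:
            d["copy_number"] = self.copy_number
        if self.seg_class is not None:
            d["class"] = self.seg_class
        if self.median_log2 is not None:
            d["median_log2"] = self.median_log2
        return pd.DataFrame(d)


@dataclass
class DilutionSeries:
    """Ordered cfDNA fractions with one mixed profile per fraction.

    Fractions are strictly decreasing from 1.0 — the x-axis of the in silico
    degradation experiment.
    """

    fractions: Sequence[float]
    profiles: Sequence[BinProfile]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if len(f) == 0:
            raise ValueError("DilutionSeries: empty")
        if len(f) != len(self.profiles):
            raise ValueError("DilutionSeries: fractions/profiles length mismatch")
        if f[0] != 1.0:
            raise ValueError("DilutionSeries: fractions must start at 1.0")
        if np.any(np.diff(f) >= 0):
            raise ValueError("DilutionSeries: fractions must be strictly decreasing")
        if np.any(f <= 0) or np.any(f > 1):
            raise ValueError("DilutionSeries: fractions must lie in (0, 1]")
        self.fractions = f

    def __len__(self) -> int:
        return len(self.fractions)

    def __iter__(self):
        return iter(zip(self.fractions, self.profiles))
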