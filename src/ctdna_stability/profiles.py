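"""Bin counts -> normalised, outlier-smoothed log2 ratios -> segment medians.

Mirrors the downstream of a shallow-WGS copy-number caller: counts are
normalised to the genome-wide median, winsorised per chromosome to tame
outlier bins, log2-transformed, and summarised as per-segment medians over a
fixed segment set. Segmentation itself is out of scope — segments are inputs
(typically the generator's truth, standing in for the time-zero segmentation
of a real library).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .containers import AMP, DEL, NEUTRAL, BinProfile, SegmentSet

__all__ = [
    "normalize",
    "smooth_outliers",
    "segment_medians",
    "classify_segments",
    "segment_bin_indices",
    "process_profile",
    "DEFAULT_AMP_THRESHOLD",
    "DEFAULT_DEL_THRESHOLD",
]

DEFAULT_AMP_THRESHOLD = 0.15
DEFAULT_DEL_THRESHOLD = -0.15


def normalize(profile: BinProfile) -> BinProfile:
    """Divide counts by the genome-wide median count so the median ratio is 1.

    Zero-count bins would give log2 = -inf; their log2 ratio is floored at
    log2(0.5 / median count) (half a fragment) and flagged in ``floored``.
    """
    counts = profile.count
    med = float(np.median(counts))
    if med <= 0:
        raise ValueError("cannot normalize: median bin count is zero")
    ratio = counts / med
    floor = np.log2(0.5 / med)
    with np.errstate(divide="ignore"):
        log2 = np.where(ratio > 0, np.log2(np.maximum(ratio, 1e-300)), floor)
    floored = ratio <= 0
    log2 = np.maximum(log2, floor)
    out = profile.copy()
    out.ratio = ratio
    out.log2_ratio = log2
    out.floored = floored
    return out


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    s = pd.Series(x)
    return s.rolling(window, center=True, min_periods=1).median().to_numpy()


def smooth_outliers(profile: BinProfile, k: float = 4.0,
                    window: int = 9) -> BinProfile:
    """Winsorise single-bin outliers against a local running median.

    Per chromosome, each ratio is clamped to [rm_b - k*MAD, rm_b + k*MAD]
    where rm_b is the centred running median (``window`` bins, shrinking at
    chromosome ends) and MAD is the raw median absolute deviation of the
    residuals ratio - rm over the chromosome. Smoothing local residuals
    rather than whole-chromosome deviations keeps genuine copy-number
    segments intact on chromosomes that carry both gains and losses, however
    deep the sequencing. A chromosome with MAD 0 (noise-free) is left
    untouched. Clamping is idempotent; log2 ratios are recomputed from the
    clamped linear ratios.
    """
    if profile.ratio is None:
        raise ValueError("profile has no ratios; call normalize first")
    if k <= 0:
        raise ValueError(f"MAD multiplier must be > 0, got {k}")
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    ratio = profile.ratio.copy()
    for c in dict.fromkeys(profile.chrom):  # preserves order
        m = profile.chrom == c
        rm = _running_median(ratio[m], window)
        resid = ratio[m] - rm
        mad = np.median(np.abs(resid))
        if mad == 0:
            continue
        ratio[m] = rm + np.clip(resid, -k * mad, k * mad)
    out = profile.copy()
    out.ratio = ratio
    has_floored = profile.floored is not None and np.any(profile.floored)
    floor = profile.log2_ratio[profile.floored].min() if has_floored else -np.inf
    with np.errstate(divide="ignore"):
        out.log2_ratio = np.where(ratio > 0, np.log2(np.maximum(ratio, 1e-300)),
                                  floor)
    out.floored = ratio <= 0
    return out


def segment_bin_indices(profile: BinProfile, segments: SegmentSet) -> list[np.ndarray]:
    """Indices of the bins in each segment.

    A bin belongs to the segment containing its *start* (half-open
    intervals), so boundary bins are never double-counted.
    """
    out = []
    for i in range(segments.n_segments):
        mask = (profile.chrom == segments.chrom[i]) \
            & (profile.start >= segments.start[i]) \
            & (profile.start < segments.end[i])
        out.append(np.flatnonzero(mask))
    return out


def segment_medians(profile: BinProfile, segments: SegmentSet) -> SegmentSet:
    """Per-segment median of bin log2 ratios.

    The per-segment summary of the stability analysis is reported on the
    log2 scale; a segment overlapping no bin is an error naming the segment.
    """
    if profile.log2_ratio is None:
        raise ValueError("profile has no log2 ratios; call normalize first")
    medians = np.empty(segments.n_segments)
    for i, idx in enumerate(segment_bin_indices(profile, segments)):
        if len(idx) == 0:
            raise ValueError(f"segment {segments.label(i)} overlaps no bin")
        medians[i] = np.median(profile.log2_ratio[idx])
    return replace(segments, median_log2=medians)


def classify_segments(segments: SegmentSet,
                      amp_threshold: float = DEFAULT_AMP_THRESHOLD,
                      del_threshold: float = DEFAULT_DEL_THRESHOLD) -> SegmentSet:
    """Label segments AMP / DEL / NEUTRAL by their median log2 ratio."""
    if not (amp_threshold > 0 > del_threshold):
        raise ValueError(f"need amp_threshold > 0 > del_threshold, got "
                         f"({amp_threshold}, {del_threshold})")
    if segments.median_log2 is None:
        raise ValueError("segments have no median log2; call segment_medians first")
    m = segments.median_log2
    cls = np.where(m >= amp_threshold, AMP,
                   np.where(m <= del_threshold, DEL, NEUTRAL))
    return replace(segments, seg_class=cls.astype(object))


def process_profile(profile: BinProfile, smooth: bool = True,
                    k: float = 4.0) -> BinProfile:
    """Convenience: normalize and (optionally) winsorise in one call."""
    out = normalize(profile)
    if smooth:
        out = smooth_outliers(out, k=k)
    return out
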