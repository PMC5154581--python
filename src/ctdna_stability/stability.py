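"""Paired stability testing of copy-number log2 ratios.

The battery a tube/storage time-series experiment needs: a paired Wilcoxon
signed-rank test of bin-level log2 ratios between two libraries (within
amplification or deletion segments), ordinary least squares of log2 ratios
against cfDNA fraction or time with t-tests on both coefficients, Bonferroni
correction, and a contamination-sensitivity scan that measures the smallest
white-blood-cell DNA admixture the signed-rank test detects.

The signed-rank test is implemented here in full: zero differences are
dropped (Wilcoxon's original procedure), |d| is midranked, W is the sum of
ranks of positive differences; the null distribution is exact (dynamic
programme over rank sums) for n <= 25 without ties, and a normal
approximation with tie-corrected variance and continuity correction
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import AMP, DEL, BinProfile, SegmentSet
from .profiles import process_profile, segment_bin_indices
from .synthetic import (CnaTruth, GenomeModel, expected_bin_ratio,
                        simulate_bin_counts, simulate_wbc_counts)
from .dilution import mix_profiles

__all__ = [
    "WilcoxonResult",
    "StabilityResult",
    "RegressionResult",
    "wilcoxon_signed_rank",
    "compare_profiles",
    "ols_fit",
    "bonferroni",
    "sensitivity_scan",
    "EXACT_N_MAX",
]

EXACT_N_MAX = 25

_ALTERNATIVES = ("two-sided", "greater", "less")


@dataclass
class WilcoxonResult:
    statistic: float          # W = sum of ranks of positive differences
    pvalue: float
    n_pairs: int              # pairs used after dropping zero differences
    n_zero: int               # zero differences dropped
    method: str               # 'exact' or 'normal'
    has_ties: bool
    all_zero: bool = False    # every difference was zero: p defined as 1


def _exact_sf_cdf(n: int, w: float) -> tuple[float, float]:
    """P(W >= w) and P(W <= w) for the tie-free signed-rank null via a
    dynamic programme over achievable rank sums (counts are exact in float
    for n <= 25 since 2^25 << 2^53)."""
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    total = counts.sum()  # == 2**n
    wi = int(round(w))
    sf = counts[wi:].sum() / total
    cdf = counts[:wi + 1].sum() / total
    return sf, cdf


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float] | None = None,
                         alternative: str = "two-sided") -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test of x vs y (or of differences x if
    y is None). ``alternative='greater'`` tests for x shifted above y."""
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    x = np.asarray(x, dtype=float)
    if y is None:
        d = x
    else:
        y = np.asarray(y, dtype=float)
        if len(x) != len(y):
            raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
        d = x - y
    if len(d) < 1:
        raise ValueError("need at least one pair")
    n_zero = int(np.sum(d == 0))
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, n_zero, "exact", False, all_zero=True)
    ranks = sps.rankdata(np.abs(d))  # midranks
    w_pos = float(ranks[d > 0].sum())
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if n <= EXACT_N_MAX and not has_ties:
        sf, cdf = _exact_sf_cdf(n, w_pos)
        if alternative == "greater":
            p = sf
        elif alternative == "less":
            p = cdf
        else:
            p = min(1.0, 2.0 * min(sf, cdf))
        return WilcoxonResult(w_pos, float(p), n, n_zero, "exact", False)

    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    var -= float(np.sum(tie_counts ** 3 - tie_counts)) / 48.0
    sd = np.sqrt(var)
    if sd == 0:  # all |d| identical and tied into one block of zeros-after-drop
        p = 1.0
        return WilcoxonResult(w_pos, p, n, n_zero, "normal", has_ties)
    if alternative == "greater":
        z = (w_pos - mu - 0.5) / sd
        p = sps.norm.sf(z)
    elif alternative == "less":
        z = (w_pos - mu + 0.5) / sd
        p = sps.norm.cdf(z)
    else:
        z = (abs(w_pos - mu) - 0.5) / sd
        p = 2.0 * sps.norm.sf(max(z, 0.0))
    return WilcoxonResult(w_pos, float(min(p, 1.0)), n, n_zero, "normal",
                          has_ties)


@dataclass
class StabilityResult:
    """One row of the paired-comparison table."""
    PVAL: float
    TYPE: str                 # 'amplifications' or 'deletions'
    statistic: float
    n_pairs: int
    method: str
    ID: str = ""
    TUBE: str = ""
    STORAGE: str = ""
    TIMEPOINT_1: float = np.nan
    TIMEPOINT_2: float = np.nan
    BONFERRONI: float = np.nan


_CLASS_TYPE = {AMP: "amplifications", DEL: "deletions"}


def compare_profiles(reference: BinProfile, segments: SegmentSet,
                     other: BinProfile, seg_class: str = AMP,
                     alternative: str = "two-sided",
                     smooth: bool = True,
                     depth_align: bool = True,
                     metadata: dict | None = None) -> StabilityResult:
    """Paired signed-rank comparison of bin-level log2 ratios between two
    libraries, restricted to segments of one class (AMP or DEL).

    Both profiles are (re)normalised — and winsorised unless ``smooth`` is
    off — on the reference bin grid, then paired bin-by-bin inside the
    segments of the requested class.

    With ``depth_align`` (default), the paired differences are formed as if
    both libraries were normalised by their total fragment count rather than
    by their median bin count: the per-library median of integer counts is
    quantised (a +-1 count jump at typical low-pass depth shifts every
    difference by more than a sub-percent contamination effect), whereas the
    total is continuous. Medians still define the reported ratio scale.
    """
    if seg_class not in _CLASS_TYPE:
        raise ValueError(f"class must be AMP or DEL, got {seg_class!r}")
    if segments.seg_class is None:
        raise ValueError("segments carry no class labels")
    reference.require_same_grid(other)
    ref = process_profile(reference, smooth=smooth)
    oth = process_profile(other, smooth=smooth)
    sel = segments.seg_class == seg_class
    if not np.any(sel):
        raise ValueError(f"no segment of class {seg_class}")
    idx_lists = segment_bin_indices(ref, segments)
    idx = np.concatenate([idx_lists[i] for i in np.flatnonzero(sel)])
    if len(idx) == 0:
        raise ValueError(f"segments of class {seg_class} overlap no bin")
    x, y = ref.log2_ratio[idx], oth.log2_ratio[idx]
    if depth_align:
        # shift 'other' so its effective normaliser is total-count based:
        # log2 ratio_med + log2(median/total) == log2(count/total), applied
        # relative to the reference's identical re-expression.
        med_ref = float(np.median(reference.count))
        med_oth = float(np.median(other.count))
        offset = (np.log2(med_oth) - np.log2(other.count.sum())) \
            - (np.log2(med_ref) - np.log2(reference.count.sum()))
        y = y + offset
    res = wilcoxon_signed_rank(x, y, alternative=alternative)
    meta = metadata or {}
    return StabilityResult(PVAL=res.pvalue, TYPE=_CLASS_TYPE[seg_class],
                           statistic=res.statistic, n_pairs=res.n_pairs,
                           method=res.method, **meta)


@dataclass
class RegressionResult:
    """One row of the regression table."""
    ALPHA: float
    BETA: float
    ALPHA_PVALUE: float
    BETA_PVALUE: float
    n: int
    df: int
    alpha_se: float
    beta_se: float
    TYPE: str = ""
    ID: str = ""
    TUBE: str = ""
    STORAGE: str = ""
    BONFERRONI_ALPHA: float = np.nan
    BONFERRONI_BETA: float = np.nan


def ols_fit(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Simple linear regression y = alpha + beta*x with two-sided t-tests
    on both coefficients (n - 2 residual df), in closed form.

    Degenerate exact fits: if the residual sum of squares is zero the
    standard errors vanish — a zero coefficient then gets p = 1 (constant
    response carries no evidence) and a non-zero one p = 0 (perfect fit).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    n = len(x)
    if n < 3:
        raise ValueError(f"need n >= 3 observations, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("constant predictor: slope is unidentifiable")
    beta = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    alpha = float(y.mean() - beta * x.mean())
    resid = y - (alpha + beta * x)
    df = n - 2
    s2 = float(np.sum(resid ** 2)) / df
    beta_se = np.sqrt(s2 / sxx)
    alpha_se = np.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx))

    def _pval(coef: float, se: float) -> float:
        if se == 0:
            return 1.0 if coef == 0 else 0.0
        return float(2.0 * sps.t.sf(abs(coef / se), df))

    return RegressionResult(ALPHA=alpha, BETA=beta,
                            ALPHA_PVALUE=_pval(alpha, alpha_se),
                            BETA_PVALUE=_pval(beta, beta_se),
                            n=n, df=df, alpha_se=float(alpha_se),
                            beta_se=float(beta_se))


def bonferroni(pvals: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni correction: p -> min(1, m*p); m defaults to len(pvals)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < 1:
        raise ValueError(f"family size must be >= 1, got {m}")
    return np.minimum(1.0, m * p)


def sensitivity_scan(truth: CnaTruth, genome: GenomeModel,
                     contamination_grid: Sequence[float],
                     depth: float = 7e6, dispersion: float = 0.02,
                     reps: int = 20, alpha: float = 0.05,
                     seed: int | np.random.SeedSequence = 0,
                     power_target: float = 0.9,
                     stop_at_first_detected: bool = False) -> pd.DataFrame:
    """Smallest WBC contamination the paired signed-rank test detects.

    For each contamination w on the grid: simulate a cfDNA profile from the
    truth and a flat WBC profile, mix at cfDNA fraction 1-w in sampled mode,
    and run the two-sided paired test of mixed vs unmixed bin log2 ratios for
    amplification and deletion segments separately, over ``reps`` seeded
    replicates. Returns a table (contamination, rejection_rate_amp,
    rejection_rate_del, detected); ``.attrs['smallest_detected']`` holds the
    smallest w whose rejection rate reaches ``power_target`` for both
    classes (NaN if none does).
    """
    grid = np.asarray(contamination_grid, dtype=float)
    if len(grid) == 0 or np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("contamination grid values must lie in (0, 1)")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    segments = truth.classified_segments()
    if not (np.any(segments.seg_class == AMP) or np.any(segments.seg_class == DEL)):
        raise ValueError("truth has no non-neutral segment")
    ratio = expected_bin_ratio(truth, genome)
    root = np.random.SeedSequence(seed)
    rows = []
    smallest = np.nan
    for w in grid:
        ss = root.spawn(reps)
        rej = {AMP: 0, DEL: 0}
        for rep_seed in ss:
            s_cf, s_wbc, s_mix = rep_seed.spawn(3)
            cf = simulate_bin_counts(genome, ratio, depth, dispersion, s_cf)
            wbc = simulate_wbc_counts(genome, depth, dispersion, s_wbc)
            # target the cfDNA source's own total: keep-probabilities stay
            # valid at any depth and the paired design is depth-matched
            mixed = mix_profiles(cf, wbc, f=1.0 - w, mode="sampled",
                                 total_fragments=None, seed=s_mix)
            for cls in (AMP, DEL):
                if not np.any(segments.seg_class == cls):
                    continue
                res = compare_profiles(cf, segments, mixed, seg_class=cls,
                                       alternative="two-sided")
                rej[cls] += int(res.PVAL < alpha)
        rate_amp = rej[AMP] / reps
        rate_del = rej[DEL] / reps
        detected = rate_amp >= power_target and rate_del >= power_target
        rows.append({"contamination": w, "rejection_rate_amp": rate_amp,
                     "rejection_rate_del": rate_del, "detected": detected})
        if detected and np.isnan(smallest):
            smallest = w
            if stop_at_first_detected:
                break
    out = pd.DataFrame(rows)
    out.attrs["smallest_detected"] = smallest
    out.attrs["reps"] = reps
    out.attrs["alpha"] = alpha
    return out
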