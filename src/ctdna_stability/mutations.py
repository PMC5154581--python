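"""Allelic-fraction time-series analysis of individual somatic mutations.

For each mutation, timepoint and condition: the allelic fraction (variant
reads over total depth), its normal-approximation binomial standard error
and 95% confidence interval, and a one-sided two-sample proportion test of
whether the fraction at an earlier timepoint exceeds the one at the last
timepoint (24 h or 48 h) — a drop in ctDNA would make early fractions
larger. Background (non-reference, non-variant) reads count toward total
depth but not toward the variant proportion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stability import bonferroni

__all__ = [
    "allelic_fraction",
    "af_confidence_interval",
    "af_trend_test",
    "af_stability_report",
    "AF_COLUMNS",
]

# canonical column order for allele-count tables
AF_COLUMNS = ("CHROM", "POS", "REF", "ALT", "NBR_REF_READS",
              "NBR_VARIANT_READS", "NBR_BACKGROUND_READS", "TOT_COUNT")


def allelic_fraction(variant_reads, tot_count):
    """Allelic fraction and its binomial standard error.

    p_hat = variant/total; SE = sqrt(p_hat (1 - p_hat) / total) — the normal
    approximation of the binomial.
    """
    v = np.asarray(variant_reads, dtype=float)
    n = np.asarray(tot_count, dtype=float)
    if np.any(n < 1):
        raise ValueError("tot_count must be >= 1")
    if np.any((v < 0) | (v > n)):
        raise ValueError("variant reads must lie in [0, tot_count]")
    p = v / n
    se = np.sqrt(p * (1.0 - p) / n)
    if np.isscalar(variant_reads) and np.isscalar(tot_count):
        return float(p), float(se)
    return p, se


def af_confidence_interval(p_hat, tot_count, level: float = 0.95,
                           method: str = "wald"):
    """Confidence interval for an allelic fraction, clipped to [0, 1].

    Default is the Wald interval p_hat +/- z*SE matching the normal
    approximation (degenerate at p_hat of exactly 0 or 1 — callers should
    flag those); ``method='wilson'`` gives the better-behaved Wilson score
    interval.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    p = np.asarray(p_hat, dtype=float)
    n = np.asarray(tot_count, dtype=float)
    if np.any(n < 1):
        raise ValueError("tot_count must be >= 1")
    z = sps.norm.ppf(0.5 + level / 2.0)
    if method == "wald":
        se = np.sqrt(p * (1.0 - p) / n)
        low, high = p - z * se, p + z * se
    elif method == "wilson":
        denom = 1.0 + z ** 2 / n
        centre = (p + z ** 2 / (2 * n)) / denom
        half = z * np.sqrt(p * (1 - p) / n + z ** 2 / (4 * n ** 2)) / denom
        low, high = centre - half, centre + half
    else:
        raise ValueError(f"unknown method {method!r}; use 'wald' or 'wilson'")
    low = np.clip(low, 0.0, 1.0)
    high = np.clip(high, 0.0, 1.0)
    if np.isscalar(p_hat):
        return float(low), float(high)
    return low, high


def _two_proportion_greater(v1: float, n1: float, v2: float, n2: float,
                            pooled: bool = True,
                            continuity: bool = False) -> float:
    """One-sided z-test of H0: p1 = p2 vs H1: p1 > p2."""
    p1, p2 = v1 / n1, v2 / n2
    if pooled:
        pp = (v1 + v2) / (n1 + n2)
        var = pp * (1.0 - pp) * (1.0 / n1 + 1.0 / n2)
    else:
        var = p1 * (1.0 - p1) / n1 + p2 * (1.0 - p2) / n2
    if var == 0:
        return 0.5 if p1 == p2 else (0.0 if p1 > p2 else 1.0)
    diff = p1 - p2
    if continuity:
        cc = 0.5 * (1.0 / n1 + 1.0 / n2)
        diff = diff - cc if diff > 0 else (diff + cc if diff < 0 else 0.0)
    z = diff / np.sqrt(var)
    return float(sps.norm.sf(z))


def af_trend_test(series: pd.DataFrame, pooled: bool = True,
                  continuity: bool = False) -> pd.DataFrame:
    """Test each earlier timepoint of one mutation/condition series against
    the last.

    ``series`` needs NBR_VARIANT_READS, TOT_COUNT and TIMEPOINT for a single
    mutation under a single condition. The last timepoint (max hours) is the
    comparator; every earlier timepoint gets a one-sided p-value for
    H1: p_earlier > p_last. The comparator's own row carries PVAL = NaN.
    """
    for col in ("NBR_VARIANT_READS", "TOT_COUNT", "TIMEPOINT"):
        if col not in series.columns:
            raise ValueError(f"missing column {col}")
    if series["TIMEPOINT"].nunique() < 2:
        raise ValueError("need at least two timepoints")
    if (series["TOT_COUNT"] < 1).any():
        raise ValueError("zero total count in series")
    out = series.copy()
    h_last = out["TIMEPOINT"].max()
    last = out[out["TIMEPOINT"] == h_last].iloc[0]
    v2, n2 = float(last["NBR_VARIANT_READS"]), float(last["TOT_COUNT"])
    pvals = np.full(len(out), np.nan)
    for i, (_, row) in enumerate(out.iterrows()):
        if row["TIMEPOINT"] == h_last:
            continue
        pvals[i] = _two_proportion_greater(
            float(row["NBR_VARIANT_READS"]), float(row["TOT_COUNT"]),
            v2, n2, pooled=pooled, continuity=continuity)
    out["PVAL"] = pvals
    return out


def af_stability_report(table: pd.DataFrame, alpha: float = 0.05,
                        level: float = 0.95, pooled: bool = True,
                        ci_method: str = "wald") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Populate all derived columns of an allele-count table and judge
    stability per condition.

    Series are grouped by mutation (CHROM, POS) and condition (ID, TUBE,
    STORAGE where present); each group is trend-tested against its last
    timepoint. Bonferroni correction spans every test in the table. The
    verdict table marks a condition 'stable' iff none of its adjusted
    p-values falls below ``alpha``.
    """
    df = table.copy()
    needed = {"CHROM", "POS", "NBR_VARIANT_READS", "TOT_COUNT", "TIMEPOINT"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    group_cols = ["CHROM", "POS"] + [c for c in ("ID", "TUBE", "STORAGE")
                                     if c in df.columns]
    p, se = allelic_fraction(df["NBR_VARIANT_READS"].to_numpy(),
                             df["TOT_COUNT"].to_numpy())
    df["ALLELIC_FRACTION"] = p
    df["SE"] = se
    low, high = af_confidence_interval(p, df["TOT_COUNT"].to_numpy(),
                                       level=level, method=ci_method)
    df["CI_LOW"] = low
    df["CI_HIGH"] = high
    pieces = []
    for _, grp in df.groupby(group_cols, sort=False):
        pieces.append(af_trend_test(grp, pooled=pooled))
    df = pd.concat(pieces).loc[df.index]
    tested = df["PVAL"].notna()
    if not tested.any():
        raise ValueError("no testable timepoint (only last-timepoint rows)")
    df["BONFERRONI"] = np.nan
    df.loc[tested, "BONFERRONI"] = bonferroni(df.loc[tested, "PVAL"].to_numpy())
    cond_cols = [c for c in ("ID", "TUBE", "STORAGE") if c in df.columns]
    verdict_key = cond_cols if cond_cols else ["CHROM", "POS"]
    verdicts = (df[tested.values]
                .groupby(verdict_key, sort=False)["BONFERRONI"]
                .min()
                .reset_index()
                .rename(columns={"BONFERRONI": "min_bonferroni"}))
    verdicts["verdict"] = np.where(verdicts["min_bonferroni"] < alpha,
                                   "unstable", "stable")
    return df, verdicts
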