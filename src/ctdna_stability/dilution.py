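"""In silico contamination engine: mix cfDNA and WBC bin counts.

White-blood-cell DNA released by in vitro cell lysis dilutes the tumour
signal: a bin with cfDNA linear ratio r, mixed at cfDNA fraction f with flat
germline DNA, has expected ratio f*r + (1-f), i.e. log2 ratio
log2(f*2^r' + (1-f)) for r' on the log2 scale — the "truncation" of the
copy-number profile toward 0 as f falls.

Both sources are rescaled to their own totals before mixing (equal effective
depth), so a depth imbalance cannot masquerade as contamination. Mixing is
defined on bin counts; a deterministic expectation mode serves exact tests
and a sampled mode (binomial thinning of each source) gives realistic noise.
"""

from __future__ import annotations

import numpy as np

from .containers import BinProfile, DilutionSeries

__all__ = [
    "mix_profiles",
    "degradation_series",
    "degradation_fractions",
    "expected_mixture_log2",
    "DEFAULT_RETAIN_PER_STEP",
    "DEFAULT_FLOOR",
]

DEFAULT_RETAIN_PER_STEP = 0.95
DEFAULT_FLOOR = 0.19


def expected_mixture_log2(log2_ratio, f: float):
    """Closed-form log2 ratio after diluting to cfDNA fraction ``f``:
    log2(f * 2**r + (1 - f)). Identity at f=1; 0 is a fixed point."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"f must be in [0, 1], got {f}")
    r = np.asarray(log2_ratio, dtype=float)
    out = np.log2(f * np.exp2(r) + (1.0 - f))
    return float(out) if np.isscalar(log2_ratio) else out


def mix_profiles(cf: BinProfile, wbc: BinProfile, f: float,
                 mode: str = "deterministic",
                 total_fragments: float | None = None,
                 seed: int | np.random.SeedSequence | None = None) -> BinProfile:
    """Mix a cfDNA profile with a WBC profile at cfDNA fraction ``f``.

    deterministic mode: mixed count_b = total * (f*cf_b/sum(cf) +
    (1-f)*wbc_b/sum(wbc)) — the expectation, with float counts.

    sampled mode: each source is binomially thinned to its target proportion
    of ``total_fragments`` and the thinned counts summed; requires a seed.
    """
    cf.require_same_grid(wbc)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"f must be in [0, 1], got {f}")
    cf_sum, wbc_sum = float(cf.count.sum()), float(wbc.count.sum())
    if cf_sum <= 0 or wbc_sum <= 0:
        raise ValueError("source profiles must have positive total counts")
    if total_fragments is None:
        total_fragments = cf_sum
    if mode == "deterministic":
        mixed = total_fragments * (f * cf.count / cf_sum
                                   + (1.0 - f) * wbc.count / wbc_sum)
    elif mode == "sampled":
        if seed is None:
            raise ValueError("sampled mode requires a seed")
        p_cf = f * total_fragments / cf_sum
        p_wbc = (1.0 - f) * total_fragments / wbc_sum
        if p_cf > 1.0 or p_wbc > 1.0:
            raise ValueError(
                f"cannot thin to target: required keep-probabilities "
                f"({p_cf:.3f}, {p_wbc:.3f}) exceed 1; lower total_fragments")
        rng = np.random.default_rng(seed)
        mixed = (rng.binomial(cf.count.astype(np.int64), p_cf)
                 + rng.binomial(wbc.count.astype(np.int64), p_wbc)).astype(float)
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'deterministic' or 'sampled'")
    return cf.with_counts(mixed)


def degradation_fractions(retain_per_step: float = DEFAULT_RETAIN_PER_STEP,
                          floor: float = DEFAULT_FLOOR) -> np.ndarray:
    """cfDNA fractions f_i = retain^i for i = 0, 1, ... while f_i >= floor.

    The defaults (retain 0.95 — five percent degradation per iteration with
    replacement by contaminating WBC DNA — and floor 0.19) give 33 fractions
    spanning 100% down to 0.95^32 ~ 19.4%.
    """
    if not 0.0 < retain_per_step < 1.0:
        raise ValueError(f"retain_per_step must be in (0, 1), got {retain_per_step}")
    if not 0.0 < floor < 1.0:
        raise ValueError(f"floor must be in (0, 1), got {floor}")
    # i_max = largest i with retain^i >= floor
    i_max = int(np.floor(np.log(floor) / np.log(retain_per_step) + 1e-12))
    while retain_per_step ** i_max < floor:
        i_max -= 1
    while retain_per_step ** (i_max + 1) >= floor:
        i_max += 1
    return retain_per_step ** np.arange(i_max + 1)


def degradation_series(cf: BinProfile, wbc: BinProfile,
                       retain_per_step: float = DEFAULT_RETAIN_PER_STEP,
                       floor: float = DEFAULT_FLOOR,
                       mode: str = "deterministic",
                       seed: int | np.random.SeedSequence | None = None,
                       total_fragments: float | None = None) -> DilutionSeries:
    """Iterative degradation series: one mixed profile per fraction
    f_i = retain^i, down to the floor."""
    fractions = degradation_fractions(retain_per_step, floor)
    if mode == "sampled":
        if seed is None:
            raise ValueError("sampled mode requires a seed")
        seeds = np.random.SeedSequence(seed).spawn(len(fractions))
    else:
        seeds = [None] * len(fractions)
    profiles = [mix_profiles(cf, wbc, float(f), mode=mode,
                             total_fragments=total_fragments, seed=s)
                for f, s in zip(fractions, seeds)]
    return DilutionSeries(fractions, profiles,
                          provenance={"mode": mode, "seed": seed,
                                      "retain_per_step": retain_per_step,
                                      "floor": floor})
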