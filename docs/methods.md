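# Methods

## Problem and model

Circulating tumour DNA (ctDNA) is the tumour-derived subset of plasma
cell-free DNA (cfDNA); its proportion is the tumour fraction *t*. In vitro,
lysing white blood cells (WBC) release long germline DNA that can dilute
the ctDNA signal before plasma is separated. The package quantifies how
such dilution shows up in shallow whole-genome copy-number profiles and in
mutation allelic fractions, and how reliably statistical tests detect it.

A genomic bin with tumour copy number *c* in a plasma mixture of tumour
fraction *t* carries expected DNA mass `(t·c + 2(1 − t)) / 2` relative to
diploid. Per-bin expected ratios are rescaled so the genome-wide median is
exactly 1, matching how observed profiles are normalised. Mixing a cfDNA
profile (linear ratio *r*) with flat WBC DNA at cfDNA fraction *f* gives
expected ratio `f·r + (1 − f)`, i.e. log2 ratio `log2(f·2^r + (1 − f))` —
monotone in *f*, attenuating every alteration toward 0 and never flipping
its sign. Because per-bin mixing is a monotone map, segment medians obey
the same closed form; this is verified against the full 33-step
degradation series in the tests.

The closed form is exact when mixing proportions are expressed on the
median-normalised ratio scale. Mixing on raw fragment counts coincides
with it only insofar as a library's total equals bins × median count; for
the ONK6-like preset the gain and loss mass nearly cancel (≈1.4%
imbalance), and the discrepancy stays well inside the 0.01-log2 tolerance
used in the tests.

## Synthetic data generator

The generator emulates the study conditions of a tube/storage stability
experiment on metastatic prostate cancer plasma:

- **Genome**: hg19 autosomes (the build is a declared default, not an
  inference), tiled in fixed bins; default 100 kb (≈28,800 bins),
  configurable. Coordinates 0-based, half-open everywhere.
- **Copy-number truth**: the ONK6-like preset carries a gain of 8q (c=3)
  and losses of 8p, 13q, 16q and chromosome 18 (c=1) — the minimal integer
  events consistent with "amplification"/"loss" — at tumour fraction 0.5;
  arm boundaries follow hg19 centromeres rounded to 0.1 Mb.
- **Counts**: negative binomial via gamma–Poisson mixing, mean
  proportional to the expected ratio and normalised to 7×10⁶ fragments per
  library in expectation, with a single dispersion parameter
  (var = μ + d·μ², default d = 0.02) capturing the overdispersion of
  low-pass WGS without modelling GC or mappability (their correction is
  out of scope; segments are inputs, not called). Dispersion 0 degenerates
  to Poisson. WBC libraries use expected ratio 1 everywhere.
- **Mutations**: at timepoint *h* hours, variant reads are
  Binomial(coverage, p_true·(1 − decay)^h) at default coverage 617;
  background (non-ref/non-alt) reads arrive at a fixed per-base error rate
  (default 10⁻³) and count toward total depth but never toward the variant
  proportion. Decay 0 is the stable-ctDNA scenario; the decay knob exists
  for power studies.
- **Fragment lengths**: a two-component normal mixture — nucleosomal
  cfDNA N(167, 10) bp truncated positive, WBC contaminant N(2000, 500) bp —
  with a monotone non-increasing observation weight modelling PCR and
  flow-cell cluster competition. The default weight is a hard step at
  350 bp (fragments longer than 350 bp are never observed); a smooth
  logistic variant is provided. This reproduces the diagnostic signature
  of a contaminated but sequencing-clean sample: substantial input mass
  above 350 bp, zero observed reads above it.
- **Design sheet**: patients × (tube, storage) conditions × timepoints,
  with the same patients profiled in every condition; vocabulary
  EDTA/STRECK and RT/COLD; the default design (5 patients, 3 conditions,
  4 timepoints) yields 60 samples, and the follow-up design (3 patients,
  2 conditions, 0/48 h) yields 12.

Every stochastic operation is a pure function of (arguments, seed); seeds
are numpy `SeedSequence`s spawned hierarchically so replicates are
independent and replayable.

What the generator does **not** emulate: GC/mappability bias and its
correction, segmentation uncertainty (segments are fixed truth),
sub-clonal copy-number heterogeneity, fixative chemistry (tube type is a
label), or read-level artefacts (no FASTQ/BAM). Passing tests therefore
demonstrate the statistical machinery under idealised library noise, not
robustness to alignment- or capture-level artefacts.

## Ratio processing

Counts are normalised by the genome-wide median bin count (median ratio
exactly 1); zero-count bins get a floored log2 ratio of
`log2(0.5/median)` and are flagged. Outlier smoothing winsorises
residuals from a per-chromosome centred running median (window 9 bins,
shrinking at chromosome ends) at 4 raw MADs of those residuals.
Winsorising against a *local* reference rather than the chromosome-wide
median is deliberate: on a chromosome carrying both a gain and a loss
(chr8 here), chromosome-wide bounds tighten with depth until they clamp
genuine segments, whereas local residuals only ever clamp single-bin
spikes. A chromosome whose residual MAD is 0 (noise-free input) is left
untouched. Segment medians are medians of bin log2 ratios, a bin
belonging to the segment containing its start; classification defaults to
AMP at ≥ +0.15 and DEL at ≤ −0.15 in log2, liberal enough to catch c=3/c=1
events at t ≈ 0.2.

## Statistical tests

**Paired Wilcoxon signed-rank** (authored in full): differences are taken
bin-by-bin within segments of one class; zeros are dropped (Wilcoxon's
original procedure, recorded in the result), |d| midranked, W = sum of
ranks of positive differences. The null distribution is exact — a dynamic
programme over achievable rank sums — for n ≤ 25 without ties; otherwise a
normal approximation with tie-corrected variance and a 0.5 continuity
correction. Exact two-sided p is `min(1, 2·min(P(W≤w), P(W≥w)))`. The
implementation is validated against brute-force sign-flip enumeration and
against an independent reference implementation.

**Depth alignment in paired comparisons.** Each library's ratio scale is
set by its median bin count, an integer-quantised statistic: at 7×10⁶
fragments and 100 kb bins (median ≈ 243 counts) a ±1 jump between two
libraries' medians shifts *every* paired difference by ≈0.006 in log2 —
larger than the effect of a 1% WBC admixture (0.003–0.005). The paired
test therefore forms differences as if both libraries were normalised by
their total fragment count (a continuous statistic that, in a paired
mix-versus-source design, is almost perfectly shared); medians still
define the reported ratio scale. Without this, detection of sub-percent
contamination flips between classes depending on which side of an integer
boundary the medians fall.

**Regression**: simple OLS of bin-level log2 ratios on cfDNA fraction (or
hours), closed form, with two-sided t-tests (n − 2 df) on intercept and
slope. Degenerate exact fits: a zero coefficient with zero residuals gets
p = 1 (a constant response is no evidence), a non-zero one p = 0.
Statistical tests consume bin-level log2 ratios grouped by segment class
rather than the ~5 per-segment medians: paired-rank significance at the
magnitudes reported for percent-level dilutions is unattainable from a
handful of segment pairs, while medians remain the reporting/plotting
summary. Both granularities are exposed.

**Multiple testing**: Bonferroni, `p → min(1, m·p)`, with m defaulting to
the number of tests in the emitted table, overridable.

**Sensitivity scan**: for each contamination w on a grid, simulate
cfDNA + WBC libraries, mix at f = 1 − w in sampled (binomial-thinning)
mode, run the two-sided paired test mixed-vs-unmixed for each class, and
report rejection rates at α = 0.05 across seeded replicates plus the
smallest w detected in ≥ 90% of them. With the default conditions the scan
detects 1% contamination in 20/20 replicates.

**Allelic fractions**: p̂ = variant/total with Wald SE √(p̂(1−p̂)/n) and
Wald 95% CI, matching the normal approximation of the binomial (degenerate
at p̂ = 0 or 1; boundary cases are returned as-is rather than silently
switched — a Wilson option exists). The trend test is a one-sided
two-sample proportion z-test of each earlier timepoint against the last
(H1: earlier fraction greater), pooled variance under H0 by default
(unpooled by flag), no continuity correction by default (negligible at
coverage ≈600). The comparator timepoint carries no p-value. A condition
is judged "stable" iff no Bonferroni-adjusted p falls below α.

## Numerical and design choices

- Sidedness of the paired CNA test defaults to two-sided; the one-sided
  attenuation alternative is available.
- Degradation series: fractions 0.95^i down to a floor of 0.19 — 33 steps,
  ending at 0.95³² ≈ 0.1937 (a 19.4%→100% span); both knobs configurable.
- Deterministic mixing produces float expectation counts; sampled mixing
  binomially thins integer counts and requires a seed. Both sources are
  rescaled to their own totals before mixing so depth imbalance cannot
  masquerade as contamination.
- Exact/approximate switch for the signed-rank test is recorded in every
  result object.
- Problem sizes in the test suite: the contamination scan uses 20
  replicates at one grid point; null-calibration checks use 400 seeded
  replicates; convergence checks run at 10⁸ fragments with Poisson noise
  (the depth-dependent noise component — overdispersion is
  depth-independent and exercised by the calibration tests instead).

## Known limitations

- The Wald CI collapses to a point at p̂ ∈ {0, 1}; use the Wilson option
  near boundaries.
- Type-I error of the paired comparison between *independent* libraries is
  mildly inflated above nominal (measured ≈0.03–0.05 at α = 0.05, within
  the accepted band) by genuine between-library normalisation uncertainty
  that no per-library normaliser can remove.
- The binomial AF model ignores overlapping-mate double counting and
  UMI/duplicate structure; coverage is treated as independent reads.
- Copy numbers are clonal integers; fractional (sub-clonal) events enter
  only through the tumour fraction.
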