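# ctdna-stability

Tools for studying the **in vitro stability of circulating tumour DNA
(ctDNA)** with shallow whole-genome copy-number profiles and targeted
mutation allele counts — aimed at groups validating pre-analytical blood
handling (tube type, storage temperature, time to plasma) for liquid-biopsy
pipelines.

When blood sits in a tube, white blood cells (WBC) lyse and release
germline DNA that dilutes the tumour-derived fraction of cell-free DNA
(cfDNA). A bin with copy-number log2 ratio *r* diluted to cfDNA fraction
*f* has expected log2 ratio

```
r(f) = log2( f · 2^r + (1 − f) )
```

so every amplification and deletion is attenuated toward 0 as *f* falls.
The package provides:

- **synthetic data** — a generator for everything the analysis consumes:
  overdispersed bin-level read counts on hg19 autosomes from an
  integer-copy-number truth (tumour fraction *t*, expected bin ratio
  `(t·c + 2(1−t))/2`, median-rescaled), binomial mutation allele-count
  time series, bimodal cfDNA/WBC fragment-length mixtures, and the
  tube × storage × timepoint sample sheet;
- **ratios** — count normalisation, running-median outlier winsorisation,
  and per-segment median log2 ratios over fixed segments;
- **dilution** — an in silico contamination engine mixing cfDNA and WBC
  counts at any cfDNA fraction (deterministic or binomially sampled), and
  the iterative 5%-degradation series f_i = 0.95^i spanning 100% → 19.4%;
- **stability statistics** — a paired Wilcoxon signed-rank test on
  bin-level log2 ratios (exact null distribution for n ≤ 25 without ties,
  tie- and continuity-corrected normal approximation otherwise), OLS of
  log2 ratios against cfDNA fraction or time with t-tests on intercept and
  slope, Bonferroni correction, and a contamination-sensitivity scan;
- **mutation AF** — allelic fractions with binomial (Wald) standard errors
  and 95% CIs, and a one-sided two-proportion z-test of each timepoint
  against the last.

## Worked example

```python
import ctdna_stability as cs

genome = cs.make_genome(100_000)              # hg19 autosomes, 100 kb bins
truth = cs.onk6_truth(tumour_fraction=0.5)    # gain 8q; losses 8p/13q/16q/18
ratio = cs.expected_bin_ratio(truth, genome)

cf = cs.simulate_bin_counts(genome, ratio, total_fragments=7e6,
                            dispersion=0.02, seed=1)
wbc = cs.simulate_wbc_counts(genome, total_fragments=7e6,
                             dispersion=0.02, seed=2)

prof = cs.process_profile(cf)                 # normalise + smooth outliers
seg = cs.segment_medians(prof, truth.segments)
print(seg.to_frame().to_string(index=False))
print("tumour fraction estimate:",
      round(cs.estimate_tumour_fraction(seg), 3))

mixed = cs.mix_profiles(cf, wbc, f=0.99, mode="sampled", seed=3)
segments = truth.classified_segments()
for cls in ("AMP", "DEL"):
    res = cs.compare_profiles(cf, segments, mixed, seg_class=cls)
    print(f"{res.TYPE}: W={res.statistic:.0f}, n={res.n_pairs}, "
          f"p={res.PVAL:.3g}")
```

prints

```
chrom    start       end  copy_number  median_log2
    8        0  43800000            1    -0.397189
    8 47000000 146364022            3     0.330285
   13 19000000 115169878            1    -0.397189
   16 46500000  90354753            1    -0.405095
   18        0  78077248            1    -0.389327
tumour fraction estimate: 0.488
amplifications: W=303815, n=994, p=4.08e-10
deletions: W=1136131, n=2620, p=6.55e-51
```

The segment medians sit near their theoretical values (log2 1.25 ≈ 0.32
for the 8q gain at t = 0.5, log2 0.75 ≈ −0.42 for the losses), inverting
the ratio model recovers the simulated tumour fraction 0.5, and a **1%**
WBC admixture is already detected by the paired signed-rank test with
p ≈ 4e-10 (amplifications) and 7e-51 (deletions).

## Command line

`ctdna-stability` exposes the pipeline as subcommands — `simulate`,
`dilute`, `ratios`, `test-cna`, `regress-cna`, `test-af`, `sensitivity`,
`report` — reading one YAML run configuration and writing tab-separated
tables whose columns mirror the supplementary-table conventions of
tube/storage stability studies (ID, TUBE, STORAGE, TIMEPOINT_1/2, PVAL,
TYPE, BONFERRONI; ALPHA/BETA and their p-values; CHROM … TOT_COUNT,
ALLELIC_FRACTION). Every run echoes its resolved configuration and a log
with seed and input hashes next to its outputs. Exit codes: 0 success,
2 validation error, 64 unknown subcommand.

```sh
ctdna-stability simulate --preset onk6 --seed 1 --out run/
ctdna-stability dilute --cf run/bins_cf.tsv --wbc run/bins_wbc.tsv --out run/dil/
ctdna-stability regress-cna --manifest run/dil/manifest.tsv \
    --segments run/truth_segments.bed --out run/s3.tsv
```

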