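"""Synthetic-data generator: every input the stability pipeline consumes.

Emulates low-pass whole-genome sequencing of plasma cell-free DNA (cfDNA)
from a cancer patient: a mostly-diploid autosomal genome carrying a handful
of integer-copy-number alterations, overdispersed bin-level read counts at
~7 million fragments per library, binomial mutation allele counts at ~600x
target coverage, bimodal fragment-length mixtures (nucleosomal cfDNA vs long
white-blood-cell fragments), and the blood-collection design sheet of a
tube/storage/timepoint experiment.

Defaults are the study conditions of the emulated experiment: 100 kb bins on
hg19 autosomes, tumour fraction 0.5 on the ONK6-like copy-number pattern
(gain of 8q; losses of 8p, 13q, 16q and 18), 7e6 total fragments with
negative-binomial dispersion 0.02, coverage 617 for mutation loci.

Every stochastic operation is a pure function of (arguments, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import BinProfile, SegmentSet

__all__ = [
    "HG19_AUTOSOMES",
    "GenomeModel",
    "CnaTruth",
    "MutationTruth",
    "FragmentModel",
    "make_genome",
    "onk6_truth",
    "expected_bin_ratio",
    "estimate_tumour_fraction",
    "simulate_bin_counts",
    "simulate_wbc_counts",
    "simulate_af_series",
    "simulate_fragment_lengths",
    "expand_design",
    "TUBES",
    "STORAGES",
    "DESIGN_COLUMNS",
]

# hg19 autosome lengths, chromosomes in karyotype order.
HG19_AUTOSOMES: dict[str, int] = {
    "1": 249250621, "2": 243199373, "3": 198022430, "4": 191154276,
    "5": 180915260, "6": 171115067, "7": 159138663, "8": 146364022,
    "9": 141213431, "10": 135534747, "11": 135006516, "12": 133851895,
    "13": 115169878, "14": 107349540, "15": 102531392, "16": 90354753,
    "17": 81195210, "18": 78077248, "19": 59128983, "20": 63025520,
    "21": 48129895, "22": 51304566,
}

TUBES = ("EDTA", "STRECK")
STORAGES = ("RT", "COLD")
DESIGN_COLUMNS = ("ID", "TUBE", "STORAGE", "TIMEPOINT")


@dataclass(frozen=True)
class GenomeModel:
    """Autosomal genome tiled into fixed-width bins (last bin truncated)."""

    chrom_lengths: Mapping[str, int]
    bin_size: int

    def __post_init__(self) -> None:
        if self.bin_size < 1000:
            raise ValueError(f"bin_size must be >= 1000 bp, got {self.bin_size}")
        if not self.chrom_lengths:
            raise ValueError("empty genome: no chromosomes")
        for c, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {c} has non-positive length {length}")

    @property
    def n_bins(self) -> int:
        return sum(-(-length // self.bin_size)
                   for length in self.chrom_lengths.values())

    def bins(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Bin coordinates (chrom, start, end), 0-based half-open."""
        chroms, starts, ends = [], [], []
        for c, length in self.chrom_lengths.items():
            s = np.arange(0, length, self.bin_size, dtype=np.int64)
            e = np.minimum(s + self.bin_size, length)
            chroms.append(np.full(len(s), c, dtype=object))
            starts.append(s)
            ends.append(e)
        return (np.concatenate(chroms), np.concatenate(starts),
                np.concatenate(ends))

    def empty_profile(self) -> BinProfile:
        c, s, e = self.bins()
        return BinProfile(c, s, e, np.zeros(len(c)))


def make_genome(bin_size: int = 100_000,
                chrom_lengths: Mapping[str, int] | None = None) -> GenomeModel:
    """Tile a genome into bins; defaults to hg19 autosomes at 100 kb."""
    if chrom_lengths is None:
        chrom_lengths = HG19_AUTOSOMES
    return GenomeModel(dict(chrom_lengths), int(bin_size))


@dataclass
class CnaTruth:
    """Ground-truth copy-number alterations and tumour fraction.

    ``segments`` lists only the altered regions (chrom, start, end, tumour
    copy number); everything unlisted is diploid. ``tumour_fraction`` is the
    proportion t of plasma DNA that is tumour-derived.
    """

    segments: SegmentSet
    tumour_fraction: float = 0.5
    normal_copy_number: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumour_fraction <= 1.0:
            raise ValueError(f"tumour_fraction must be in [0, 1], "
                             f"got {self.tumour_fraction}")
        if self.segments.copy_number is None:
            raise ValueError("CnaTruth segments need copy numbers")

    def classified_segments(self) -> SegmentSet:
        return self.segments.classes_from_copy_number(self.normal_copy_number)


def onk6_truth(tumour_fraction: float = 0.5) -> CnaTruth:
    """The ONK6-like prostate-cancer preset: gain of 8q; losses of 8p, 13q,
    16q and chromosome 18.

    Copy numbers are the minimal integer events (3 for the gain, 1 for the
    losses); arm boundaries follow hg19 centromeres, rounded to 0.1 Mb.
    """
    seg = SegmentSet(
        chrom=np.array(["8", "8", "13", "16", "18"], dtype=object),
        start=np.array([0, 47_000_000, 19_000_000, 46_500_000, 0]),
        end=np.array([43_800_000, 146_364_022, 115_169_878, 90_354_753,
                      78_077_248]),
        copy_number=np.array([1, 3, 1, 1, 1]),
    )
    return CnaTruth(segments=seg, tumour_fraction=tumour_fraction)


def _bin_copy_numbers(truth: CnaTruth, genome: GenomeModel) -> np.ndarray:
    """Tumour copy number per bin; a bin belongs to the segment containing
    its start (half-open)."""
    chrom, start, _ = genome.bins()
    c = np.full(len(chrom), truth.normal_copy_number, dtype=float)
    seg = truth.segments
    for i in range(seg.n_segments):
        mask = (chrom == seg.chrom[i]) & (start >= seg.start[i]) \
            & (start < seg.end[i])
        c[mask] = seg.copy_number[i]
    return c


def expected_bin_ratio(truth: CnaTruth, genome: GenomeModel) -> np.ndarray:
    """Noise-free per-bin linear copy-number ratio.

    The raw value per bin is (t*c_b + (1-t)*2) / 2 — the expected DNA mass of
    a tumour/normal mixture relative to diploid — rescaled so the genome-wide
    median ratio is exactly 1, matching how observed profiles are normalised.
    """
    t = truth.tumour_fraction
    c = _bin_copy_numbers(truth, genome)
    raw = (t * c + (1.0 - t) * truth.normal_copy_number) / 2.0
    med = float(np.median(raw))
    if med <= 0:
        raise ValueError("degenerate truth: median expected ratio is zero")
    return raw / med


def estimate_tumour_fraction(segments: SegmentSet,
                             bins_per_segment: np.ndarray | None = None,
                             normal_copy_number: int = 2) -> float:
    """Invert the expected-ratio model on observed segment medians.

    For a segment with tumour copy number c and observed median linear ratio
    m (genome median normalised to 1), m = (t*c + (1-t)*2)/2, hence
    t = 2(m - 1)/(c - 2). Estimates are combined across non-neutral segments,
    weighted by segment bin counts when given.
    """
    if segments.copy_number is None or segments.median_log2 is None:
        raise ValueError("need copy numbers and median log2 ratios")
    c = segments.copy_number.astype(float)
    informative = c != normal_copy_number
    if not np.any(informative):
        raise ValueError("no non-neutral segment to invert")
    m = 2.0 ** segments.median_log2[informative]
    t_hat = 2.0 * (m - 1.0) / (c[informative] - normal_copy_number)
    if bins_per_segment is None:
        w = np.ones(informative.sum())
    else:
        w = np.asarray(bins_per_segment, dtype=float)[informative]
    return float(np.clip(np.average(t_hat, weights=w), 0.0, 1.0))


def _draw_counts(rng: np.random.Generator, mean: np.ndarray,
                 dispersion: float) -> np.ndarray:
    """Negative-binomial counts via gamma-Poisson mixing; dispersion 0
    degenerates to Poisson. Var = mu + dispersion * mu^2."""
    if dispersion < 0:
        raise ValueError(f"dispersion must be >= 0, got {dispersion}")
    if dispersion == 0:
        return rng.poisson(mean)
    lam = np.where(mean > 0,
                   rng.gamma(1.0 / dispersion, dispersion * np.maximum(mean, 1e-300)),
                   0.0)
    return rng.poisson(lam)


def simulate_bin_counts(genome: GenomeModel, expected_ratio: np.ndarray,
                        total_fragments: float = 7e6,
                        dispersion: float = 0.02,
                        seed: int | np.random.SeedSequence = 0) -> BinProfile:
    """Draw per-bin fragment counts with mean proportional to the expected
    ratio, normalised to ``total_fragments`` in expectation."""
    expected_ratio = np.asarray(expected_ratio, dtype=float)
    if len(expected_ratio) != genome.n_bins:
        raise ValueError(f"expected_ratio has {len(expected_ratio)} entries "
                         f"for {genome.n_bins} bins")
    if total_fragments <= 0:
        raise ValueError(f"total_fragments must be > 0, got {total_fragments}")
    if np.any(expected_ratio < 0):
        raise ValueError("expected ratios must be non-negative")
    s = float(expected_ratio.sum())
    if s == 0:
        raise ValueError("all expected ratios are zero")
    rng = np.random.default_rng(seed)
    mean = total_fragments * expected_ratio / s
    counts = _draw_counts(rng, mean, dispersion)
    chrom, start, end = genome.bins()
    return BinProfile(chrom, start, end, counts)


def simulate_wbc_counts(genome: GenomeModel, total_fragments: float = 7e6,
                        dispersion: float = 0.02,
                        seed: int | np.random.SeedSequence = 0) -> BinProfile:
    """Flat (copy-neutral) white-blood-cell DNA profile: expected ratio 1
    everywhere."""
    return simulate_bin_counts(genome, np.ones(genome.n_bins),
                               total_fragments, dispersion, seed)


@dataclass
class MutationTruth:
    """Ground-truth somatic mutations: loci with true allelic fractions and
    a per-locus target coverage."""

    loci: Sequence[tuple[str, int, str, str, float]]
    coverage: int | Sequence[int] = 617

    def __post_init__(self) -> None:
        keys = [(c, p) for c, p, *_ in self.loci]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chrom, pos) in mutation loci")
        for c, p, ref, alt, af in self.loci:
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"p_true must be in [0, 1] at {c}:{p}, got {af}")
        cov = np.broadcast_to(np.asarray(self.coverage, dtype=np.int64),
                              (len(self.loci),))
        if np.any(cov < 1):
            raise ValueError("coverage must be >= 1")
        object.__setattr__(self, "_cov", cov)

    @property
    def coverages(self) -> np.ndarray:
        return self._cov


def simulate_af_series(mut: MutationTruth, timepoints: Sequence[float],
                       decay_per_hour: float = 0.0,
                       error_rate: float = 1e-3,
                       seed: int | np.random.SeedSequence = 0) -> pd.DataFrame:
    """Binomial allele-count time series for each mutation locus.

    At time h the expected allelic fraction is p_true * (1 - decay)^h;
    variant reads are Binomial(coverage, p_h), background (non ref/non alt)
    reads come at a small fixed per-base error rate, and reference reads make
    up the remainder so TOT_COUNT = ref + variant + background. Decay 0 is
    the stable-ctDNA scenario.
    """
    if len(timepoints) == 0:
        raise ValueError("timepoints must be non-empty")
    if not 0.0 <= decay_per_hour < 1.0:
        raise ValueError(f"decay_per_hour must be in [0, 1), got {decay_per_hour}")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError(f"error_rate must be in [0, 1), got {error_rate}")
    rng = np.random.default_rng(seed)
    rows = []
    for (chrom, pos, ref, alt, p_true), cov in zip(mut.loci, mut.coverages):
        for h in timepoints:
            p_h = p_true * (1.0 - decay_per_hour) ** h
            n_var = int(rng.binomial(cov, p_h))
            n_bg = int(rng.binomial(cov - n_var, error_rate)) if cov > n_var else 0
            rows.append({
                "CHROM": chrom, "POS": pos, "REF": ref, "ALT": alt,
                "NBR_REF_READS": int(cov) - n_var - n_bg,
                "NBR_VARIANT_READS": n_var,
                "NBR_BACKGROUND_READS": n_bg,
                "TOT_COUNT": int(cov),
                "TIMEPOINT": float(h),
            })
    return pd.DataFrame(rows)


def hard_length_weight(threshold: float = 350.0) -> Callable[[np.ndarray], np.ndarray]:
    """Step observation weight: fragments up to ``threshold`` bp are observed,
    longer ones never are — PCR/cluster competition at its starkest."""
    def w(length: np.ndarray) -> np.ndarray:
        return (np.asarray(length, dtype=float) <= threshold).astype(float)
    return w


def logistic_length_weight(midpoint: float = 350.0,
                           scale: float = 25.0) -> Callable[[np.ndarray], np.ndarray]:
    """Smooth monotone-decreasing observation weight (logistic in length)."""
    def w(length: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp((np.asarray(length, dtype=float) - midpoint)
                                   / scale))
    return w


@dataclass
class FragmentModel:
    """Bimodal fragment-length mixture: nucleosomal cfDNA vs long
    white-blood-cell contaminant, with a length-dependent observation weight
    modelling PCR and flow-cell cluster competition."""

    cfdna_mean: float = 167.0
    cfdna_sd: float = 10.0
    contaminant_mean: float = 2000.0
    contaminant_sd: float = 500.0
    contaminant_mass: float = 0.0
    observation_weight: Callable[[np.ndarray], np.ndarray] = field(
        default_factory=hard_length_weight)

    def __post_init__(self) -> None:
        if self.cfdna_mean <= 0 or self.contaminant_mean <= 0:
            raise ValueError("fragment length means must be > 0")
        if self.cfdna_sd <= 0 or self.contaminant_sd <= 0:
            raise ValueError("fragment length sds must be > 0")
        if not 0.0 <= self.contaminant_mass <= 1.0:
            raise ValueError(f"contaminant_mass must be in [0, 1], "
                             f"got {self.contaminant_mass}")


def simulate_fragment_lengths(model: FragmentModel, n: int,
                              apply_observation_weight: bool = False,
                              seed: int | np.random.SeedSequence = 0) -> np.ndarray:
    """Sample ``n`` fragment lengths from the cfDNA/contaminant mixture.

    With weighting off, the sample reflects the input DNA mass (contaminant
    included); with weighting on, draws are rejection-sampled with acceptance
    probability ``observation_weight(length)``, emulating what the sequencer
    actually reads. Lengths are truncated positive.
    """
    if n <= 0:
        raise ValueError(f"n must be > 0, got {n}")
    rng = np.random.default_rng(seed)
    out = np.empty(0)
    # rejection-sample in chunks until n accepted draws
    while len(out) < n:
        m = max(2 * (n - len(out)), 256)
        is_cont = rng.random(m) < model.contaminant_mass
        lengths = np.where(
            is_cont,
            rng.normal(model.contaminant_mean, model.contaminant_sd, m),
            rng.normal(model.cfdna_mean, model.cfdna_sd, m),
        )
        lengths = lengths[lengths > 0]
        if apply_observation_weight:
            w = np.asarray(model.observation_weight(lengths), dtype=float)
            if np.any((w < 0) | (w > 1)):
                raise ValueError("observation weights must lie in [0, 1]")
            if w.sum() == 0 and len(out) == 0 and model.contaminant_mass == 1.0:
                raise ValueError("degenerate model: nothing is observable")
            lengths = lengths[rng.random(len(lengths)) < w]
        out = np.concatenate([out, lengths])
    return out[:n]


DEFAULT_TIMEPOINT_LADDER = (0.0, 2.0, 4.0, 24.0, 48.0)


def expand_design(patients_per_condition: int,
                  conditions: Sequence[tuple[str, str]],
                  timepoints: int | Sequence[float] = 4) -> pd.DataFrame:
    """Expand the blood-collection design into one row per sample.

    ``conditions`` is a list of (tube, storage) pairs; the same patients are
    profiled in every condition, mirroring a within-patient tube/storage
    comparison. ``timepoints`` may be a count (taking the leading hours of
    the 0/2/4/24/48 h ladder) or an explicit list of hours. Row count is
    patients_per_condition x len(conditions) x n_timepoints.
    """
    if patients_per_condition < 1:
        raise ValueError("patients_per_condition must be >= 1")
    if len(conditions) == 0:
        raise ValueError("conditions must be non-empty")
    if isinstance(timepoints, (int, np.integer)):
        if timepoints < 1:
            raise ValueError("timepoints count must be >= 1")
        if timepoints > len(DEFAULT_TIMEPOINT_LADDER):
            raise ValueError(f"at most {len(DEFAULT_TIMEPOINT_LADDER)} default "
                             "timepoints; pass explicit hours instead")
        hours: Sequence[float] = DEFAULT_TIMEPOINT_LADDER[:timepoints]
    else:
        hours = list(timepoints)
        if len(hours) == 0:
            raise ValueError("timepoints must be non-empty")
    rows = []
    for tube, storage in conditions:
        if tube not in TUBES:
            raise ValueError(f"unknown tube {tube!r}; allowed: {TUBES}")
        if storage not in STORAGES:
            raise ValueError(f"unknown storage {storage!r}; allowed: {STORAGES}")
        for p in range(1, patients_per_condition + 1):
            for h in hours:
                rows.append({"ID": f"ONK{p}", "TUBE": tube, "STORAGE": storage,
                             "TIMEPOINT": float(h)})
    df = pd.DataFrame(rows, columns=list(DESIGN_COLUMNS))
    if df.duplicated().any():
        raise ValueError("duplicate design rows")
    return df
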