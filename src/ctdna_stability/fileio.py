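"""Readers, writers and run configuration.

All tables are plain tab-separated text with '.' decimals and '\\n' newlines;
coordinates are 0-based half-open and stated as such in every header. Column
names of the sample-sheet and allele-count tables follow the supplementary
conventions of tube/storage stability experiments verbatim (ID, TUBE,
STORAGE, TIMEPOINT; CHROM, POS, REF, ALT, NBR_REF_READS, NBR_VARIANT_READS,
NBR_BACKGROUND_READS, TOT_COUNT).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import BinProfile, SegmentSet
from .mutations import AF_COLUMNS
from .synthetic import DESIGN_COLUMNS, STORAGES, TUBES

__all__ = [
    "read_bin_tsv", "write_bin_tsv",
    "read_segments_bed", "write_segments_bed",
    "read_sample_sheet", "write_sample_sheet",
    "read_af_tsv", "write_af_tsv",
    "write_segment_table",
    "RunConfig",
]

_COORD_NOTE = "# coordinates: 0-based, half-open"


def write_bin_tsv(profile: BinProfile, path) -> None:
    """Bin-count TSV: chrom, start, end, count (+ derived columns if set)."""
    df = profile.to_frame()
    counts = df["count"]
    if np.allclose(counts, np.round(counts)):
        df["count"] = counts.round().astype(np.int64)
    with open(path, "w", newline="\n") as fh:
        fh.write(_COORD_NOTE + "\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n",
                  float_format="%.10g")


def read_bin_tsv(path) -> BinProfile:
    """Parse and validate a bin-count TSV (sorted, non-overlapping bins)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("chrom", "start", "end", "count"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    try:
        return BinProfile(df["chrom"].astype(str).to_numpy(dtype=object),
                          df["start"].to_numpy(), df["end"].to_numpy(),
                          df["count"].to_numpy())
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from e


def write_segments_bed(segments: SegmentSet, path) -> None:
    """BED-like segment table: chrom, start, end[, copy_number]."""
    df = segments.to_frame()
    with open(path, "w", newline="\n") as fh:
        fh.write(_COORD_NOTE + "\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n",
                  float_format="%.10g")


def read_segments_bed(path) -> SegmentSet:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    kw = {}
    if "copy_number" in df.columns:
        kw["copy_number"] = df["copy_number"].to_numpy()
    if "class" in df.columns:
        kw["seg_class"] = df["class"].astype(str).to_numpy(dtype=object)
    if "median_log2" in df.columns:
        kw["median_log2"] = df["median_log2"].to_numpy()
    try:
        return SegmentSet(df["chrom"].astype(str).to_numpy(dtype=object),
                          df["start"].to_numpy(), df["end"].to_numpy(), **kw)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from e


def write_segment_table(segments: SegmentSet, path) -> None:
    """Per-segment report: chrom, start, end, class, median_log2."""
    write_segments_bed(segments, path)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    _validate_sheet(sheet, path)
    sheet.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _validate_sheet(df: pd.DataFrame, path) -> None:
    for col in DESIGN_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    bad_tube = set(df["TUBE"].astype(str)) - set(TUBES)
    if bad_tube:
        raise ValueError(f"{path}: bad TUBE value(s) {sorted(bad_tube)}; "
                         f"allowed: {list(TUBES)}")
    bad_storage = set(df["STORAGE"].astype(str)) - set(STORAGES)
    if bad_storage:
        raise ValueError(f"{path}: bad STORAGE value(s) {sorted(bad_storage)}; "
                         f"allowed: {list(STORAGES)}")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    _validate_sheet(df, path)
    return df[list(DESIGN_COLUMNS)].assign(
        TIMEPOINT=lambda d: d["TIMEPOINT"].astype(float))


def write_af_tsv(table: pd.DataFrame, path) -> None:
    for col in AF_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    lead = [c for c in (*AF_COLUMNS, "ID", "STORAGE", "TUBE", "TIMEPOINT",
                        "ALLELIC_FRACTION", "SE", "CI_LOW", "CI_HIGH",
                        "PVAL", "BONFERRONI") if c in table.columns]
    rest = [c for c in table.columns if c not in lead]
    table[lead + rest].to_csv(path, sep="\t", index=False,
                              lineterminator="\n", float_format="%.10g")


def read_af_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in AF_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    counts = df[["NBR_REF_READS", "NBR_VARIANT_READS", "NBR_BACKGROUND_READS"]]
    if not (counts.sum(axis=1) == df["TOT_COUNT"]).all():
        bad = int((counts.sum(axis=1) != df["TOT_COUNT"]).idxmax())
        raise ValueError(f"{path}: TOT_COUNT != ref+variant+background "
                         f"at row {bad}")
    if "TUBE" in df.columns:
        bad_tube = set(df["TUBE"].astype(str)) - set(TUBES)
        if bad_tube:
            raise ValueError(f"{path}: bad TUBE value(s) {sorted(bad_tube)}; "
                             f"allowed: {list(TUBES)}")
    return df


# ---------------------------------------------------------------------------
# Run configuration

@dataclass
class GenomeConfig:
    bin_size: int = 100_000
    chrom_lengths: dict | None = None


@dataclass
class TruthConfig:
    preset: str = "onk6"
    tumour_fraction: float = 0.5


@dataclass
class DepthConfig:
    total_fragments: float = 7e6
    dispersion: float = 0.02


@dataclass
class DesignConfig:
    patients_per_condition: int = 5
    conditions: list = field(default_factory=lambda: [
        ["EDTA", "RT"], ["EDTA", "COLD"], ["STRECK", "RT"]])
    timepoints: list = field(default_factory=lambda: [0.0, 2.0, 4.0, 24.0])


@dataclass
class DilutionConfig:
    retain: float = 0.95
    floor: float = 0.19
    mode: str = "deterministic"


@dataclass
class TestConfig:
    alpha: float = 0.05
    alternative: str = "two-sided"
    granularity: str = "bin"
    amp_threshold: float = 0.15
    del_threshold: float = -0.15


_SECTIONS = {
    "genome": GenomeConfig, "truth": TruthConfig, "depth": DepthConfig,
    "design": DesignConfig, "dilution": DilutionConfig, "test": TestConfig,
}


@dataclass
class RunConfig:
    """Fully-defaulted, strictly-validated run configuration.

    Unknown keys (top-level or within a section) are rejected; the resolved
    config is echoed into every output directory for replayability.
    """

    genome: GenomeConfig = field(default_factory=GenomeConfig)
    truth: TruthConfig = field(default_factory=TruthConfig)
    depth: DepthConfig = field(default_factory=DepthConfig)
    design: DesignConfig = field(default_factory=DesignConfig)
    dilution: DilutionConfig = field(default_factory=DilutionConfig)
    test: TestConfig = field(default_factory=TestConfig)
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        kwargs = {}
        for name, section_cls in _SECTIONS.items():
            section = data.pop(name, {}) or {}
            allowed = {f.name for f in fields(section_cls)}
            unknown = set(section) - allowed
            if unknown:
                raise ValueError(f"unknown key(s) in section {name!r}: "
                                 f"{sorted(unknown)}")
            kwargs[name] = section_cls(**section)
        kwargs["seed"] = int(data.pop("seed", 0))
        if data:
            raise ValueError(f"unknown top-level config key(s): {sorted(data)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)

    def echo(self, out_dir) -> Path:
        """Write the resolved config (plus its hash) into an output directory."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        path = out_dir / "run_config.yaml"
        path.write_text(text)
        return path

    def digest(self) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]
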