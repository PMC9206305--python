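"""Reading, writing and validating count matrices and sample metadata.

Counts are gene x sample integer tables (TSV, gene identifiers in the first
column); metadata is one CSV row per sample with the design variables and the
physical denominators used by the per-sample-size and per-total-RNA
normalization modes. Time is treated as an unordered factor with an explicit
baseline (week 0), so downstream dummy coding always contrasts against the
pre-intervention state regardless of row order in the input files.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from math import e as _E
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("trinorm")
if not logger.handlers:  # all logging to stderr, configured once at import
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

#: canonical time levels, baseline first
TIME_LEVELS = ("week0", "week2", "week12")
BASELINE_TIME = TIME_LEVELS[0]
CONDITION_LEVELS = ("low", "moderate")

REQUIRED_METADATA_COLUMNS = (
    "sample_id",
    "participant",
    "time",
    "condition",
    "tissue_mass_mg",
)


class FormatError(ValueError):
    """Malformed input table (bad value, missing column, duplicate id)."""


class StructuralError(ValueError):
    """Inconsistent objects (mismatched samples/genes between tables)."""


@dataclass
class PipelineConfig:
    """Thresholds and model options for the full three-mode analysis.

    Defaults follow the published workflow: robust-expression filter at a
    minimum count of 30 per sample, |t| < 1.5 screen, top-10 stable genes,
    DE universe at minimum count 1, BH-FDR at 0.05.
    """

    min_count_stable: int = 30
    t_threshold: float = 1.5
    top_k: int = 10
    min_count_de: int = 1
    fdr_alpha: float = 0.05
    tmm_trim_m: float = 0.30
    tmm_trim_a: float = 0.05
    tmm_min_count: int = 1
    log_base: float = _E
    # screening design: time + volume and their interactions (all five
    # non-intercept coefficients feed the max-|t| screen)
    screen_include_volume: bool = True
    screen_include_interactions: bool = True
    # DE design: legs pooled as biological replicates by default
    de_include_volume: bool = False
    n_quadrature: int = 5
    # paper-literal per-total-RNA mode uses a constant denominator; switch to
    # additionally rescale by sequencing depth (default off)
    total_rna_depth_correction: bool = False

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise FormatError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# count matrix


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample TSV of non-negative integer counts.

    The first column holds gene identifiers, the header holds sample
    identifiers. Raises :class:`FormatError` with the offending location for
    negative or non-integral values and for duplicated identifiers.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return validate_counts(df)


def validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene identifiers: {dup[:5]}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample identifiers: {dup[:5]}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError("count matrix contains non-numeric values")
    bad = ~np.isfinite(values) | (values < 0) | (values != np.floor(values))
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise FormatError(
            f"invalid count {values[g, s]!r} at gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r} (counts must be non-negative integers)"
        )
    return df.astype(np.int64)


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# sample metadata


def read_metadata(path: str | Path, rna_input_ng: float = 1000.0) -> pd.DataFrame:
    """Read per-sample metadata CSV.

    Required columns: sample_id, participant, time, condition, tissue_mass_mg.
    An rna_input_ng column is optional (the study design fixes it at 1000 ng).
    ``time`` is coerced to a categorical with baseline ``week0`` first.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata is missing required column(s): {missing}")
    if "rna_input_ng" not in df.columns:
        df["rna_input_ng"] = rna_input_ng
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata is missing required column(s): {missing}")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample_id in metadata: {dup[:5]}")
    unknown = set(df["time"].astype(str)) - set(TIME_LEVELS)
    if unknown:
        raise FormatError(
            f"unknown time label(s) {sorted(unknown)}; expected {TIME_LEVELS}"
        )
    df["time"] = pd.Categorical(df["time"].astype(str), categories=TIME_LEVELS)
    unknown = set(df["condition"].astype(str)) - set(CONDITION_LEVELS)
    if unknown:
        raise FormatError(
            f"unknown condition label(s) {sorted(unknown)}; expected {CONDITION_LEVELS}"
        )
    df["condition"] = pd.Categorical(
        df["condition"].astype(str), categories=CONDITION_LEVELS
    )
    mass = pd.to_numeric(df["tissue_mass_mg"], errors="coerce")
    if mass.isna().any() or (mass <= 0).any():
        bad = df.loc[~(mass > 0), "sample_id"].tolist()
        raise FormatError(f"tissue_mass_mg must be positive; bad samples: {bad[:5]}")
    df["tissue_mass_mg"] = mass.astype(float)
    df["participant"] = df["participant"].astype(str)
    counts_per_part = df.groupby("participant", observed=True).size()
    solo = counts_per_part[counts_per_part < 2].index.tolist()
    if solo:
        raise FormatError(
            f"each participant needs >= 2 samples; offending: {solo[:5]}"
        )
    return df.set_index("sample_id", drop=False)


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def validate_design(
    counts: pd.DataFrame, meta: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Check counts/metadata alignment and return the pair with metadata
    reordered to match count columns.

    Samples present in the counts but absent from metadata are a hard error;
    unused metadata rows and participants with incomplete time series only
    produce warnings (legs are biological replicates, so partial series are
    usable).
    """
    absent = [s for s in counts.columns if s not in meta.index]
    if absent:
        raise StructuralError(
            f"samples present in counts but missing from metadata: {absent[:5]}"
        )
    unused = [s for s in meta.index if s not in counts.columns]
    if unused:
        logger.warning("metadata rows without count columns (ignored): %s", unused[:10])
    meta = meta.loc[list(counts.columns)]
    expected = len(TIME_LEVELS)
    times_per_part = meta.groupby("participant", observed=True)["time"].nunique()
    incomplete = times_per_part[times_per_part < expected].index.tolist()
    if incomplete:
        logger.warning(
            "participants with incomplete time series: %s", incomplete[:10]
        )
    return counts, meta


def write_manifest(path: str | Path, **entries) -> None:
    """Write a JSON run manifest (parameters, seeds, file list) next to outputs."""
    payload = {k: v for k, v in entries.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
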