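"""Readers and writers for the TSV dialects used throughout the pipeline.

Expression profiles travel as TSV with the on-disk header
``gene  mel  RPE  irid  embryo  [p_mel_RPE  p_mel_irid  p_RPE_irid ...]``;
in memory the canonical column names are spelled out (``melanocyte``,
``rpe``, ``iridophore``, ``embryo``, ``p_mel_rpe`` ...).  Unknown columns
round-trip untouched.  Scientific notation (``1.30E-03``) is accepted
case-insensitively; gene ids are carried verbatim, including colons and
dots.  All tables are TSV, never CSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import TextIO

import numpy as np
import pandas as pd

from .quantify import CountMatrix

__all__ = [
    "read_profile",
    "write_profile",
    "read_counts",
    "write_counts",
    "read_config",
    "PipelineConfig",
]

# on-disk dialect name -> canonical in-memory name
_DIALECT = {
    "gene": "gene",
    "mel": "melanocyte",
    "RPE": "rpe",
    "irid": "iridophore",
    "embryo": "embryo",
    "p_mel_RPE": "p_mel_rpe",
    "p_mel_irid": "p_mel_irid",
    "p_RPE_irid": "p_rpe_irid",
}
_MANDATORY = ("gene", "mel", "RPE", "irid", "embryo")
_NUMERIC_CANONICAL = [v for k, v in _DIALECT.items() if v != "gene"]


class ProfileFormatError(ValueError):
    """Malformed profile TSV (missing column, bad cell, empty file)."""


def read_profile(path: str | Path | TextIO) -> pd.DataFrame:
    """Read a profile TSV in the on-disk dialect into canonical columns."""
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ProfileFormatError(f"empty profile file: {path}") from None
    if raw.empty and raw.columns.empty:
        raise ProfileFormatError(f"empty profile file: {path}")
    missing = [c for c in _MANDATORY if c not in raw.columns]
    if missing:
        raise ProfileFormatError(f"missing mandatory column(s): {missing}")
    df = raw.rename(columns=_DIALECT)
    for col in df.columns:
        if col == "gene":
            continue
        if col in _NUMERIC_CANONICAL:
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ProfileFormatError(
                    f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, row {row + 2}"
                )
            df[col] = converted
        else:
            # unknown columns preserved as opaque annotations
            df[col] = raw[col]
    return df


def write_profile(profile: pd.DataFrame, path: str | Path | TextIO) -> None:
    """Write a canonical profile to the on-disk dialect, preserving extras."""
    inverse = {v: k for k, v in _DIALECT.items()}
    out = profile.rename(columns=inverse)
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_counts(counts_path: str | Path, meta_path: str | Path) -> tuple[CountMatrix, pd.DataFrame]:
    """Read a count matrix TSV (gene_id, length_bp, one column per library)
    and its library metadata TSV (library_id, cell_type, timepoint_hpf,
    total_reads)."""
    counts = pd.read_csv(counts_path, sep="\t")
    for col in ("gene_id", "length_bp"):
        if col not in counts.columns:
            raise ValueError(f"counts file missing column {col!r}")
    counts = counts.set_index("gene_id")
    lengths = counts.pop("length_bp")
    meta = pd.read_csv(meta_path, sep="\t")
    for col in ("library_id", "cell_type", "total_reads"):
        if col not in meta.columns:
            raise ValueError(f"metadata file missing column {col!r}")
    meta = meta.set_index("library_id")
    unknown = [lib for lib in counts.columns if lib not in meta.index]
    if unknown:
        raise ValueError(f"libraries without metadata: {unknown}")
    totals = meta["total_reads"].reindex(counts.columns)
    return CountMatrix(counts, lengths, totals), meta


def write_counts(
    cm: CountMatrix, meta: pd.DataFrame, counts_path: str | Path, meta_path: str | Path
) -> None:
    out = cm.counts.copy()
    out.insert(0, "length_bp", cm.lengths)
    out.index.name = "gene_id"
    out.to_csv(counts_path, sep="\t")
    meta.to_csv(meta_path, sep="\t", index=True, index_label="library_id")


_CONFIG_FIELDS: dict[str, tuple[type, object]] = {
    # name: (type, default)
    "seed": (int, 1),
    "n_genes": (int, 25102),
    "total_reads": (int, 3_000_000),
    "replicates_melanocyte": (int, 11),
    "replicates_iridophore": (int, 5),
    "replicates_rpe": (int, 5),
    "replicates_embryo": (int, 3),
    "theta": (float, 1.0),
    "window": (int, 1000),
    "identity_min": (float, 94.0),
    "coverage_min": (float, 0.70),
    "fold_margin": (float, 2.0),
    "dispersion": (float, 0.2),
    "p_max": (float, 0.05),
    "embryo_rule": (str, "min"),
}


class PipelineConfig:
    """Flat key-value configuration with range validation at load time."""

    def __init__(self, **kwargs):
        for name, (typ, default) in _CONFIG_FIELDS.items():
            value = kwargs.pop(name, default)
            try:
                value = typ(value)
            except (TypeError, ValueError):
                raise ValueError(f"config field {name!r}: cannot parse {value!r} as {typ.__name__}")
            setattr(self, name, value)
        if kwargs:
            raise ValueError(f"unknown config keys: {sorted(kwargs)}")
        self._validate()

    def _validate(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if not 0.0 < self.p_max <= 1.0:
            raise ValueError("p_max must lie in (0, 1]")
        if not 0.0 <= self.coverage_min <= 1.0:
            raise ValueError("coverage_min must lie in [0, 1]")
        if not 0.0 <= self.identity_min <= 100.0:
            raise ValueError("identity_min must lie in [0, 100]")
        if self.window < 3:
            raise ValueError("window must be >= 3")
        if self.fold_margin < 1:
            raise ValueError("fold_margin must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.embryo_rule not in ("min", "max", "any"):
            raise ValueError("embryo_rule must be min, max, or any")
        for name in ("n_genes", "total_reads", "replicates_melanocyte",
                     "replicates_iridophore", "replicates_rpe", "replicates_embryo"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in _CONFIG_FIELDS}


def read_config(path: str | Path) -> PipelineConfig:
    """Parse a flat ``key = value`` config file ('#' starts a comment)."""
    values: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        values[key.strip()] = value.strip()
    return PipelineConfig(**values)
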