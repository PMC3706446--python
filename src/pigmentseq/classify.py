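"""Multi-criteria enrichment classification of pigment-cell expression.

Every published gene list in this analysis is the pass set of a declarative
conjunction of fold-change, absolute-expression, and significance criteria
evaluated per gene on the averaged expression profile.  Three shapes exist:

``shared_all``
    All three pigment cell types within ``within_fold`` of each other
    (max/min), each at least ``min_rpkm``, and every cell type at least
    ``fold_vs_embryo`` above the whole-embryo mean.
``pairwise_shared``
    Two target cell types each at least ``fold_vs_others`` above the third
    (optionally with t-test p < ``p_max`` for each comparison), each target
    at least ``fold_vs_embryo`` above embryo and at least ``min_rpkm``.
``specific``
    One target cell type at least ``fold_vs_others`` above each of the
    other two (optionally p < ``p_max`` for both), at least
    ``fold_vs_embryo`` above embryo, and at least ``min_rpkm``.

Fold thresholds are inclusive (>= k); p thresholds strict (< p_max).  A
fold with zero denominator and positive numerator is +inf and passes any
threshold; 0/0 is undefined and fails.  The embryo criterion has no p-value
component anywhere — the pooled whole-embryo libraries carry no replicate
structure.  By default the embryo-fold criterion must hold for every target
cell type (``embryo_rule="min"``, the strictest reading); ``"max"`` and
``"any"`` relax it to the strongest target only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffstats import fold_ratio

__all__ = [
    "FilterSpec",
    "PathwayReport",
    "apply_filter",
    "preset",
    "preset_names",
    "pathway_report",
]

_CELLS = ("melanocyte", "rpe", "iridophore")

_P_COLUMN = {
    frozenset(("melanocyte", "rpe")): "p_mel_rpe",
    frozenset(("melanocyte", "iridophore")): "p_mel_irid",
    frozenset(("rpe", "iridophore")): "p_rpe_irid",
}


@dataclass(frozen=True)
class FilterSpec:
    """A declarative enrichment filter (one conjunction of criteria)."""

    mode: str  # shared_all | pairwise_shared | specific
    targets: tuple[str, ...] = _CELLS
    fold_vs_others: float = 1.0
    fold_vs_embryo: float = 1.0
    min_rpkm: float = 0.0
    p_max: float | None = None
    within_fold: float | None = None
    embryo_rule: str = "min"

    def __post_init__(self) -> None:
        if self.mode not in ("shared_all", "pairwise_shared", "specific"):
            raise ValueError(f"unknown filter mode {self.mode!r}")
        for t in self.targets:
            if t not in _CELLS:
                raise ValueError(f"unknown cell type {t!r}")
        expected = {"shared_all": 3, "pairwise_shared": 2, "specific": 1}[self.mode]
        if len(set(self.targets)) != expected:
            raise ValueError(
                f"{self.mode} names {expected} distinct target(s), got {self.targets}"
            )
        if self.mode == "shared_all" and self.within_fold is None:
            raise ValueError("shared_all requires within_fold")
        if self.fold_vs_others < 1 or self.fold_vs_embryo < 1:
            raise ValueError("fold thresholds must be >= 1")
        if self.min_rpkm < 0:
            raise ValueError("min_rpkm must be >= 0")
        if self.p_max is not None and not 0.0 < self.p_max <= 1.0:
            raise ValueError("p_max must lie in (0, 1]")
        if self.embryo_rule not in ("min", "max", "any"):
            raise ValueError(f"unknown embryo_rule {self.embryo_rule!r}")

    @property
    def others(self) -> tuple[str, ...]:
        return tuple(c for c in _CELLS if c not in self.targets)


# Preset filters behind each published gene list.  The stringent table
# presets use the same pairwise/specific shapes with the p criterion
# disabled and table-specific folds.
_PRESETS: dict[str, FilterSpec] = {
    # all three cell types within 2-fold, >= 4 RPKM, >= 100-fold over embryo
    "shared_identity": FilterSpec(
        mode="shared_all", targets=_CELLS, within_fold=2.0,
        min_rpkm=4.0, fold_vs_embryo=100.0,
    ),
    # pairwise co-enrichment: 2-fold over the third type (p < 0.05),
    # 8-fold over embryo
    "mel_rpe_shared": FilterSpec(
        mode="pairwise_shared", targets=("melanocyte", "rpe"),
        fold_vs_others=2.0, fold_vs_embryo=8.0, p_max=0.05,
    ),
    "mel_irid_shared": FilterSpec(
        mode="pairwise_shared", targets=("melanocyte", "iridophore"),
        fold_vs_others=2.0, fold_vs_embryo=8.0, p_max=0.05,
    ),
    "rpe_irid_shared": FilterSpec(
        mode="pairwise_shared", targets=("rpe", "iridophore"),
        fold_vs_others=2.0, fold_vs_embryo=8.0, p_max=0.05,
    ),
    # cell-type specific: 2-fold over both other types (p < 0.05),
    # 8-fold over embryo
    "mel_specific": FilterSpec(
        mode="specific", targets=("melanocyte",),
        fold_vs_others=2.0, fold_vs_embryo=8.0, p_max=0.05,
    ),
    "irid_specific": FilterSpec(
        mode="specific", targets=("iridophore",),
        fold_vs_others=2.0, fold_vs_embryo=8.0, p_max=0.05,
    ),
    "rpe_specific": FilterSpec(
        mode="specific", targets=("rpe",),
        fold_vs_others=2.0, fold_vs_embryo=8.0, p_max=0.05,
    ),
    # high-stringency table presets (no p criterion)
    "mel_rpe_stringent": FilterSpec(
        mode="pairwise_shared", targets=("melanocyte", "rpe"),
        fold_vs_others=10.0, fold_vs_embryo=10.0, min_rpkm=10.0,
    ),
    "mel_irid_stringent": FilterSpec(
        mode="pairwise_shared", targets=("melanocyte", "iridophore"),
        fold_vs_others=5.0, fold_vs_embryo=10.0,
    ),
    "irid_stringent": FilterSpec(
        mode="specific", targets=("iridophore",),
        fold_vs_others=30.0, fold_vs_embryo=100.0,
    ),
}


def preset(name: str, **overrides) -> FilterSpec:
    """Return a named preset filter, optionally with field overrides."""
    try:
        spec = _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(_PRESETS))}"
        ) from None
    return replace(spec, **overrides) if overrides else spec


def preset_names() -> list[str]:
    return list(_PRESETS)


def _fold_array(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Vectorised fold ratio: +inf for x/0 with x>0, nan (undefined) for 0/0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        return num / den


def _fold_passes(ratio: np.ndarray, k: float) -> np.ndarray:
    return ~np.isnan(ratio) & (ratio >= k)


def apply_filter(profile: pd.DataFrame, spec: FilterSpec) -> pd.DataFrame:
    """Evaluate a filter per gene; returns one enrichment call per row.

    The result has a ``gene`` column, a boolean ``verdict`` (the conjunction
    of all criteria), one boolean column per criterion, and the fold changes
    and p-values the criteria consumed.
    """
    needed = set(_CELLS) | {"embryo"}
    missing = needed - set(profile.columns)
    if missing:
        raise ValueError(f"profile lacks required columns: {sorted(missing)}")
    if spec.p_max is not None:
        for t in spec.targets:
            for o in spec.others:
                col = _P_COLUMN[frozenset((t, o))]
                if col not in profile.columns:
                    raise ValueError(
                        f"filter needs p-value column {col!r} absent from profile"
                    )

    vals = {c: profile[c].to_numpy(dtype=float) for c in _CELLS}
    emb = profile["embryo"].to_numpy(dtype=float)
    crit: dict[str, np.ndarray] = {}
    extra: dict[str, np.ndarray] = {}

    if spec.mode == "shared_all":
        stacked = np.stack([vals[c] for c in _CELLS])
        lo, hi = stacked.min(axis=0), stacked.max(axis=0)
        within = _fold_array(hi, lo)
        crit["within_fold"] = ~np.isnan(within) & (within <= spec.within_fold)
        crit["min_rpkm"] = lo >= spec.min_rpkm
        extra["within_ratio"] = within
        embryo_folds = []
        for cell in _CELLS:
            f = _fold_array(vals[cell], emb)
            extra[f"fold_{cell}_vs_embryo"] = f
            embryo_folds.append(_fold_passes(f, spec.fold_vs_embryo))
        agg = np.logical_and if spec.embryo_rule == "min" else np.logical_or
        crit["embryo"] = agg.reduce(embryo_folds)
    else:
        if spec.min_rpkm > 0:
            crit["min_rpkm"] = np.logical_and.reduce(
                [vals[t] >= spec.min_rpkm for t in spec.targets]
            )
        for t in spec.targets:
            for o in spec.others:
                f = _fold_array(vals[t], vals[o])
                extra[f"fold_{t}_vs_{o}"] = f
                crit[f"fold_{t}_vs_{o}"] = _fold_passes(f, spec.fold_vs_others)
                if spec.p_max is not None:
                    p = profile[_P_COLUMN[frozenset((t, o))]].to_numpy(dtype=float)
                    extra[f"p_{t}_vs_{o}"] = p
                    crit[f"p_{t}_vs_{o}"] = ~np.isnan(p) & (p < spec.p_max)
        embryo_folds = []
        for t in spec.targets:
            f = _fold_array(vals[t], emb)
            extra[f"fold_{t}_vs_embryo"] = f
            embryo_folds.append(_fold_passes(f, spec.fold_vs_embryo))
        agg = np.logical_and if spec.embryo_rule == "min" else np.logical_or
        crit["embryo"] = agg.reduce(embryo_folds)

    out = pd.DataFrame({"gene": profile["gene"].to_numpy()})
    out["verdict"] = np.logical_and.reduce(list(crit.values()))
    for name, arr in crit.items():
        out[name] = arr
    for name, arr in extra.items():
        out[name] = arr
    return out


@dataclass
class PathwayReport:
    """Fold-change report for curated gene groups (pathway -> genes)."""

    table: pd.DataFrame  # pathway, gene, RPKMs, folds, significance flags
    missing: list[str]  # group members absent from the profile
    alpha: float


def pathway_report(
    profile: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    *,
    alpha: float = 0.01,
) -> PathwayReport:
    """Per-gene enrichment report for curated pathway groups.

    For every gene of every group found in the profile, emits the cell-type
    RPKMs, the iridophore fold change versus melanocyte, RPE, and whole
    embryo, and significance flags (p < ``alpha``) for the iridophore
    comparisons against melanocyte and RPE when the profile provides those
    p-values (columns ``p_irid_mel`` / ``p_irid_rpe``, falling back to the
    canonical pairwise columns).  Genes referenced by a group but absent
    from the profile are listed, never silently dropped.
    """
    if not groups:
        raise ValueError("empty pathway groups")
    idx = profile.set_index("gene")
    p_mel = "p_irid_mel" if "p_irid_mel" in profile.columns else "p_mel_irid"
    p_rpe = "p_irid_rpe" if "p_irid_rpe" in profile.columns else "p_rpe_irid"
    rows = []
    missing: list[str] = []
    for pathway, genes in groups.items():
        for gene in genes:
            if gene not in idx.index:
                missing.append(gene)
                continue
            g = idx.loc[gene]
            row = {
                "pathway": pathway,
                "gene": gene,
                "iridophore": float(g["iridophore"]),
                "melanocyte": float(g["melanocyte"]),
                "rpe": float(g["rpe"]),
                "embryo": float(g["embryo"]) if "embryo" in idx.columns else math.nan,
                "fold_vs_melanocyte": fold_ratio(float(g["iridophore"]), float(g["melanocyte"])),
                "fold_vs_rpe": fold_ratio(float(g["iridophore"]), float(g["rpe"])),
            }
            row["fold_vs_embryo"] = (
                fold_ratio(float(g["iridophore"]), float(g["embryo"]))
                if "embryo" in idx.columns
                else math.nan
            )
            for flag, col in (("sig_vs_melanocyte", p_mel), ("sig_vs_rpe", p_rpe)):
                if col in idx.columns:
                    p = float(g[col])
                    row[col] = p
                    row[flag] = (not math.isnan(p)) and p < alpha
                else:
                    row[flag] = False
            rows.append(row)
    if not rows:
        raise ValueError("no group member present in profile")
    return PathwayReport(table=pd.DataFrame(rows), missing=missing, alpha=alpha)
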