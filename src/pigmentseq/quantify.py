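"""Tag-count quantification: RPKM, cell-type averages, detection, saturation.

Expression is measured in RPKM — reads per kilobase of cDNA per million
uniquely mapped reads:

    rpkm = count / (length_bp / 1000) / (library_total / 1e6)

Cell-type profiles are unweighted arithmetic means of per-library RPKM.
Detection applies a fixed RPKM threshold (default 1, inclusive).  Saturation
curves rarefy each library's aligned tags without replacement to a series of
depths and re-apply the detection threshold at the subsampled total; for a
given seed the subsamples are nested by construction, realised through a
single random permutation of the library's tags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SaturationCurve",
    "compute_rpkm",
    "average_by_celltype",
    "detect_expressed",
    "subsample_counts",
    "saturation_curve",
]

CELL_TYPES = ("melanocyte", "iridophore", "rpe")


@dataclass
class CountMatrix:
    """Integer tag counts per gene per library, with lengths and totals.

    ``counts`` is genes x libraries; ``lengths`` (bp) is indexed by gene;
    ``totals`` (uniquely mapped reads) is indexed by library.  Column sums
    may not exceed the declared totals (tags that did not map uniquely are
    simply absent).
    """

    counts: pd.DataFrame
    lengths: pd.Series
    totals: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        self.counts.index.name = "gene_id"
        self.counts.columns.name = None
        self.lengths = self.lengths.reindex(self.counts.index)
        self.totals = self.totals.reindex(self.counts.columns)
        if self.lengths.isna().any():
            missing = list(self.lengths.index[self.lengths.isna()])[:5]
            raise ValueError(f"genes without length: {missing}")
        if (self.lengths < 1).any():
            bad = list(self.lengths.index[self.lengths < 1])[:5]
            raise ValueError(f"gene lengths < 1 bp: {bad}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        colsums = self.counts.sum(axis=0)
        over = colsums > self.totals
        if over.any():
            raise ValueError(
                f"column sums exceed declared totals for {list(self.totals.index[over])}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def library_ids(self) -> pd.Index:
        return self.counts.columns


@dataclass
class SaturationCurve:
    """Genes detected above ``theta`` RPKM per subsampled depth and seed."""

    theta: float
    table: pd.DataFrame  # columns: library_id, seed, depth, n_detected

    def per_seed_monotone(self) -> bool:
        """True iff detected counts are nondecreasing in depth for every
        (library, seed) series."""
        for _, grp in self.table.groupby(["library_id", "seed"]):
            counts = grp.sort_values("depth")["n_detected"].to_numpy()
            if (np.diff(counts) < 0).any():
                return False
        return True


def compute_rpkm(cm: CountMatrix) -> pd.DataFrame:
    """Exact RPKM matrix with the same axes as the count matrix."""
    if (cm.totals <= 0).any():
        bad = list(cm.totals.index[cm.totals <= 0])
        raise ValueError(f"non-positive library totals: {bad}")
    len_kb = cm.lengths.to_numpy(dtype=float) / 1000.0
    per_million = cm.totals.to_numpy(dtype=float) / 1e6
    values = cm.counts.to_numpy(dtype=float) / len_kb[:, None] / per_million[None, :]
    return pd.DataFrame(values, index=cm.gene_ids, columns=cm.library_ids)


def average_by_celltype(
    rpkm: pd.DataFrame,
    annotations: Mapping[str, str] | pd.Series | pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene unweighted mean RPKM per cell type.

    ``annotations`` maps every library id to exactly one cell-type label
    (a mapping/Series, or a metadata DataFrame with a ``cell_type`` column
    indexed by library id).
    """
    if isinstance(annotations, pd.DataFrame):
        annotations = annotations["cell_type"]
    ann = pd.Series(annotations)
    missing = [lib for lib in rpkm.columns if lib not in ann.index]
    if missing:
        raise ValueError(f"libraries without cell-type annotation: {missing}")
    ann = ann.reindex(rpkm.columns)
    means = {}
    for cell_type, libs in ann.groupby(ann).groups.items():
        if len(libs) == 0:
            raise ValueError(f"cell type {cell_type!r} has no libraries")
        means[cell_type] = rpkm[list(libs)].mean(axis=1)
    return pd.DataFrame(means, index=rpkm.index)


def detect_expressed(
    profile: pd.DataFrame,
    theta: float = 1.0,
    *,
    inclusive: bool = True,
) -> dict[str, pd.Index]:
    """Gene sets detected per cell type at the RPKM threshold ``theta``.

    The boundary is inclusive by default (a gene at exactly ``theta`` RPKM
    counts as expressed).
    """
    if theta <= 0:
        raise ValueError("detection threshold must be > 0")
    out: dict[str, pd.Index] = {}
    for col in profile.columns:
        vals = profile[col]
        mask = vals >= theta if inclusive else vals > theta
        out[col] = profile.index[mask]
    return out


def _library_rng(seed: int, lib_position: int) -> np.random.Generator:
    # per-library stream derived from the root seed, so separate calls with
    # the same seed share the same tag permutation (nested subsamples)
    return np.random.default_rng(np.random.SeedSequence([int(seed), lib_position]))


def _shuffled_tags(column: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    tags = np.repeat(np.arange(len(column), dtype=np.int64), column)
    rng.shuffle(tags)
    return tags


def subsample_counts(cm: CountMatrix, depth: int, seed: int) -> CountMatrix:
    """Rarefy every library to ``depth`` tags without replacement.

    Each library's gene-count vector is treated as a population of aligned
    tags; ``depth`` of them are drawn without replacement (a multivariate
    hypergeometric draw).  For a fixed seed the draws are nested: the
    depth-d subsample is a subset of the depth-d' subsample for d <= d'.
    The returned matrix declares ``depth`` as each library's total.
    """
    if depth <= 0:
        raise ValueError("subsample depth must be > 0")
    arr = cm.counts.to_numpy()
    colsums = arr.sum(axis=0)
    if (depth > colsums).any():
        bad = list(cm.library_ids[depth > colsums])
        raise ValueError(f"depth {depth} exceeds aligned tags for {bad}")
    out = np.empty_like(arr)
    n_genes = arr.shape[0]
    for j in range(arr.shape[1]):
        tags = _shuffled_tags(arr[:, j], _library_rng(seed, j))
        out[:, j] = np.bincount(tags[:depth], minlength=n_genes)
    counts = pd.DataFrame(out, index=cm.gene_ids, columns=cm.library_ids)
    totals = pd.Series(depth, index=cm.library_ids)
    return CountMatrix(counts, cm.lengths.copy(), totals)


def saturation_curve(
    cm: CountMatrix,
    depths: Sequence[int],
    theta: float = 1.0,
    seeds: Sequence[int] = (1,),
    *,
    inclusive: bool = True,
) -> SaturationCurve:
    """Detected-gene counts across nested rarefaction depths.

    For each seed and depth, every library is subsampled and a gene counts
    as detected when its RPKM — recomputed against the subsampled total —
    meets ``theta``.
    """
    depths = list(depths)
    if depths != sorted(depths):
        raise ValueError("depths must be sorted ascending")
    arr = cm.counts.to_numpy()
    len_kb = cm.lengths.to_numpy(dtype=float) / 1000.0
    rows = []
    for j, lib in enumerate(cm.library_ids):
        colsum = int(arr[:, j].sum())
        for seed in seeds:
            tags = _shuffled_tags(arr[:, j], _library_rng(seed, j))
            for depth in depths:
                if depth > colsum:
                    raise ValueError(
                        f"depth {depth} exceeds aligned tags ({colsum}) for {lib!r}"
                    )
                sub = np.bincount(tags[:depth], minlength=arr.shape[0])
                rpkm = sub / len_kb / (depth / 1e6)
                detected = rpkm >= theta if inclusive else rpkm > theta
                rows.append(
                    {
                        "library_id": lib,
                        "seed": seed,
                        "depth": depth,
                        "n_detected": int(detected.sum()),
                    }
                )
    return SaturationCurve(theta=theta, table=pd.DataFrame(rows))
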