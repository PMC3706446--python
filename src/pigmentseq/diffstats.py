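"""Per-gene statistics: Student's t-tests, fold changes, windowed correlation.

Differential calls between pigment cell types use the equal-variance
(pooled) two-sample Student's t-test on linear RPKM across replicate
libraries, with no multiple-testing correction — downstream filters gate on
raw p < 0.05.  Fold changes carry explicit zero semantics: num/0 with num >
0 is +inf (passes any fold threshold), 0/0 is undefined (fails every
threshold).  Whole-embryo comparisons are fold-only; the pooled embryo
libraries carry no replicate structure suitable for a t-test.

Transcriptome-wide similarity between two cell types is summarised by the
average Pearson correlation over all overlapping windows of ``w`` genes
after sorting genes by increasing whole-embryo expression.  Windowing keeps
a handful of extreme outliers from dominating a single global correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quantify import average_by_celltype

__all__ = [
    "FoldChange",
    "WindowProfile",
    "gene_ttest",
    "ttest_matrix",
    "fold_change",
    "fold_ratio",
    "quote_fold",
    "all_pair_stats",
    "windowed_correlation",
    "PAIRS",
]

# canonical cell-type pairs, in profile column order
PAIRS: tuple[tuple[str, str], ...] = (
    ("melanocyte", "rpe"),
    ("melanocyte", "iridophore"),
    ("rpe", "iridophore"),
)

_P_COLUMN = {
    ("melanocyte", "rpe"): "p_mel_rpe",
    ("melanocyte", "iridophore"): "p_mel_irid",
    ("rpe", "iridophore"): "p_rpe_irid",
}


def gene_ttest(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, int, float]:
    """Pooled-variance two-sample Student's t-test, two-sided.

    Returns ``(t, df, p)`` with ``df = nA + nB - 2``.  Degenerate inputs
    follow a fixed contract: both groups constant and equal means gives
    ``t = 0, p = 1``; both constant with unequal means gives an infinite t
    and ``p = 0`` with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 replicates")
    df = a.size + b.size - 2
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0, df, 1.0
        warnings.warn(
            "zero variance in both groups with unequal means; p reported as 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.copysign(math.inf, diff), df, 0.0
    t = diff / math.sqrt(pooled * (1.0 / a.size + 1.0 / b.size))
    p = 2.0 * sps.t.sf(abs(t), df)
    return t, df, p


def ttest_matrix(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised pooled t-test over rows (genes) of two replicate blocks.

    ``a`` is genes x nA, ``b`` genes x nB.  Returns ``(t, p)`` arrays with
    the same degenerate-row contract as :func:`gene_ttest`.
    """
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 replicates")
    df = na + nb - 2
    pooled = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / df
    diff = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    degenerate = pooled == 0.0
    t[degenerate & (diff == 0.0)] = 0.0
    t[degenerate & (diff != 0.0)] = np.sign(diff[degenerate & (diff != 0.0)]) * np.inf
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return t, p


@dataclass(frozen=True)
class FoldChange:
    """A ratio of mean RPKMs with explicit zero semantics."""

    numerator: float
    denominator: float

    @property
    def ratio(self) -> float:
        """num/den; +inf when den = 0 < num; nan (undefined) when both 0."""
        return fold_ratio(self.numerator, self.denominator)

    def at_least(self, k: float) -> bool:
        """Whether the fold passes a >= k threshold; undefined never passes."""
        r = self.ratio
        return (not math.isnan(r)) and r >= k


def fold_change(num: float, den: float) -> FoldChange:
    if num < 0 or den < 0:
        raise ValueError("mean RPKM values must be non-negative")
    return FoldChange(num, den)


def fold_ratio(num: float, den: float) -> float:
    """Scalar fold ratio: num/den, +inf for num>0/0, nan for 0/0."""
    if num < 0 or den < 0:
        raise ValueError("mean RPKM values must be non-negative")
    if den > 0:
        return num / den
    return math.inf if num > 0 else math.nan


def quote_fold(ratio: float) -> float:
    """Render a fold ratio the way the source tables quote them.

    Ratios of at least 1 are truncated to whole folds (71.28 -> 71,
    198.64 -> 198); ratios below 1 are rounded to one decimal (0.70 -> 0.7).
    """
    if math.isnan(ratio):
        return math.nan
    if math.isinf(ratio):
        return math.inf
    return float(math.floor(ratio)) if ratio >= 1.0 else round(ratio, 1)


def all_pair_stats(
    rpkm: pd.DataFrame,
    annotations: Mapping[str, str] | pd.Series | pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the full expression profile: means plus pairwise p-values.

    Returns a DataFrame with a ``gene`` column, mean RPKM per annotated cell
    type (``melanocyte``, ``rpe``, ``iridophore`` and, when libraries carry
    that label, ``embryo``) and the three cell-type pairwise p-value columns
    ``p_mel_rpe``, ``p_mel_irid``, ``p_rpe_irid``.
    """
    if isinstance(annotations, pd.DataFrame):
        annotations = annotations["cell_type"]
    ann = pd.Series(annotations).reindex(rpkm.columns)
    means = average_by_celltype(rpkm, ann)
    profile = pd.DataFrame({"gene": rpkm.index})
    order = [c for c in ("melanocyte", "rpe", "iridophore", "embryo") if c in means]
    for col in order:
        profile[col] = means[col].to_numpy()
    blocks = {
        ct: rpkm[[lib for lib in rpkm.columns if ann[lib] == ct]].to_numpy()
        for ct in ("melanocyte", "rpe", "iridophore")
        if (ann == ct).any()
    }
    for pair in PAIRS:
        x, y = pair
        if x in blocks and y in blocks:
            _, p = ttest_matrix(blocks[x], blocks[y])
            profile[_P_COLUMN[pair]] = p
    return profile


@dataclass
class WindowProfile:
    """Sliding-window Pearson correlations along the embryo-expression order."""

    window: int
    order: pd.Index  # gene order used (ascending embryo expression)
    correlations: pd.DataFrame  # one column per "x_vs_y" pair, row per window start
    averages: dict[str, float]  # unweighted mean r over valid windows
    n_flagged: dict[str, int]  # zero-variance windows excluded per pair


def _sliding_r(x: np.ndarray, y: np.ndarray, w: int) -> np.ndarray:
    """Pearson r for every window of length w starting at 0..n-w-1."""
    # global centering keeps window sums small so the textbook sum formula
    # stays accurate; Pearson r is shift-invariant
    x = x - x.mean()
    y = y - y.mean()
    n = x.size
    win_x = np.lib.stride_tricks.sliding_window_view(x, w)[: n - w]
    win_y = np.lib.stride_tricks.sliding_window_view(y, w)[: n - w]
    sx = win_x.sum(axis=1)
    sy = win_y.sum(axis=1)
    sxx = np.einsum("ij,ij->i", win_x, win_x)
    syy = np.einsum("ij,ij->i", win_y, win_y)
    sxy = np.einsum("ij,ij->i", win_x, win_y)
    var_x = sxx - sx * sx / w
    var_y = syy - sy * sy / w
    cov = sxy - sx * sy / w
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / np.sqrt(var_x * var_y)
    r[(var_x <= 0) | (var_y <= 0)] = np.nan
    return r


def windowed_correlation(
    profile: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] | None = None,
    w: int = 1000,
) -> WindowProfile:
    """Average windowed Pearson correlation between cell-type profiles.

    Genes are sorted by ascending whole-embryo mean RPKM (stable, ties
    broken by gene id); windows cover starts ``0 .. n_genes - w - 1``, i.e.
    exactly ``n_genes - w`` overlapping windows of ``w`` genes.  Windows
    where either vector has zero variance yield a flagged NaN and are
    excluded from the unweighted average.
    """
    if w < 3:
        raise ValueError("window size must be >= 3")
    n = len(profile)
    if n <= w:
        raise ValueError(f"need more than w={w} genes, got {n}")
    if pairs is None:
        pairs = [p for p in PAIRS if p[0] in profile.columns and p[1] in profile.columns]
    ordered = profile.sort_values(["embryo", "gene"], kind="stable")
    order = pd.Index(ordered["gene"])
    correlations = {}
    averages: dict[str, float] = {}
    flagged: dict[str, int] = {}
    for x, y in pairs:
        name = f"{x}_vs_{y}"
        r = _sliding_r(
            ordered[x].to_numpy(dtype=float), ordered[y].to_numpy(dtype=float), w
        )
        correlations[name] = r
        valid = ~np.isnan(r)
        flagged[name] = int((~valid).sum())
        averages[name] = float(r[valid].mean()) if valid.any() else math.nan
    table = pd.DataFrame(correlations)
    table.insert(0, "window_start", np.arange(n - w))
    return WindowProfile(
        window=w, order=order, correlations=table, averages=averages, n_flagged=flagged
    )
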