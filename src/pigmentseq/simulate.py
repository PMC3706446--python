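"""Synthetic pigment-cell study generator with known ground truth.

Emulates the statistical structure of the study design this package
analyses: 11 melanocyte, 5 iridophore, and 5 RPE libraries plus pooled
whole-embryo libraries over a ~25,102-gene universe, heavy-tailed
(log-normal) expression with roughly a third of genes detectably expressed
(>= 1 RPKM) per cell type, and planted enrichment classes that encode the
downstream filter definitions as generative truth.  Tag counts are drawn
per gene x library from a negative binomial on the RPKM-implied mean;
whole-embryo libraries are mixtures in which pigment-cell transcripts are
diluted a few hundred-fold by the bulk of the embryo.

All randomness flows from a single integer seed through one root
``numpy`` generator, so identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .nrdb import Transcript, TranscriptSet
from .quantify import CountMatrix

__all__ = [
    "StudyDesign",
    "SyntheticTruth",
    "CLASS_LABELS",
    "DEFAULT_PROPORTIONS",
    "generate_truth",
    "simulate_counts",
    "generate_redundant_transcripts",
]

CELLS = ("melanocyte", "iridophore", "rpe")

CLASS_LABELS = (
    "background",
    "housekeeping",
    "unexpressed",
    "shared_all",
    "pairwise_mel_rpe",
    "pairwise_mel_irid",
    "pairwise_rpe_irid",
    "specific_melanocyte",
    "specific_iridophore",
    "specific_rpe",
)

_PAIR_TARGETS = {
    "pairwise_mel_rpe": ("melanocyte", "rpe"),
    "pairwise_mel_irid": ("melanocyte", "iridophore"),
    "pairwise_rpe_irid": ("rpe", "iridophore"),
}
_SPECIFIC_TARGETS = {
    "specific_melanocyte": "melanocyte",
    "specific_iridophore": "iridophore",
    "specific_rpe": "rpe",
}

DEFAULT_PROPORTIONS: dict[str, float] = {
    "background": 0.57,
    "housekeeping": 0.20,
    "unexpressed": 0.13,
    "shared_all": 0.01,
    "pairwise_mel_rpe": 0.01,
    "pairwise_mel_irid": 0.01,
    "pairwise_rpe_irid": 0.01,
    "specific_melanocyte": 0.02,
    "specific_iridophore": 0.02,
    "specific_rpe": 0.02,
}


@dataclass(frozen=True)
class StudyDesign:
    """Library layout of the study: replicates per condition and depth."""

    replicates: Mapping[str, int] = field(
        default_factory=lambda: {
            "melanocyte": 11, "iridophore": 5, "rpe": 5, "embryo": 3,
        }
    )
    n_genes: int = 25102
    total_reads_per_library: int = 3_000_000

    def __post_init__(self) -> None:
        for cell, n in self.replicates.items():
            if n < 1:
                raise ValueError(f"replicate count for {cell!r} must be >= 1")
        if self.n_genes < 100:
            raise ValueError("n_genes must be >= 100")
        if self.total_reads_per_library < 10**5:
            raise ValueError("total reads per library must be >= 1e5")

    @property
    def cell_types(self) -> tuple[str, ...]:
        return tuple(self.replicates)

    def library_ids(self) -> list[str]:
        return [
            f"{cell}_{i:02d}"
            for cell in self.replicates
            for i in range(1, self.replicates[cell] + 1)
        ]


@dataclass
class SyntheticTruth:
    """Planted per-gene class labels, baselines, and fold multipliers.

    ``table`` columns: gene, label, baseline (RPKM-scale), one multiplier
    per condition (``mult_melanocyte`` etc. including ``mult_embryo``), and
    ``dispersion``.  Expected RPKM of gene g in condition c is
    ``baseline * mult_c``.
    """

    table: pd.DataFrame
    fold_margin: float
    frac_expressed: float
    pigment_fraction: float

    def expected_rpkm(self, cell: str) -> pd.Series:
        return self.table["baseline"] * self.table[f"mult_{cell}"]

    def labels(self) -> pd.Series:
        return self.table.set_index("gene")["label"]


def _validate_proportions(proportions: Mapping[str, float]) -> None:
    for label, p in proportions.items():
        if label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {label!r}")
        if p < 0:
            raise ValueError(f"negative proportion for class {label!r}")
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(
            f"class proportions sum to {total!r}, not 1 (labels: {sorted(proportions)})"
        )


def generate_truth(
    design: StudyDesign,
    class_proportions: Mapping[str, float] | None = None,
    fold_margin: float = 2.0,
    seed: int = 0,
    *,
    frac_expressed: float = 0.35,
    log_sigma: float = 2.0,
    dispersion: float = 0.2,
    pigment_fraction: float = 0.005,
    jitter: float = 1.35,
) -> SyntheticTruth:
    """Draw planted class labels, baselines, and fold multipliers.

    Baselines are log-normal with scale ``log_sigma``; the location is
    calibrated so the expected fraction of genes at >= 1 RPKM per cell type
    hits ``frac_expressed``.  Enriched classes draw their baseline from the
    same distribution truncated at ``4 * fold_margin`` RPKM (tied to the
    shared-identity filter's 4-RPKM floor) and their enrichment multiplier
    as ``threshold * fold_margin * exp(Exponential(ln 2))`` — a heavy tail
    of enrichment strengths matching the span seen in real enriched-gene
    lists.  Whole-embryo means mix ``pigment_fraction`` of the pigment-cell
    signal with a bulk component that is the baseline itself for
    background/housekeeping genes and zero for planted pigment genes.
    """
    if fold_margin < 1:
        raise ValueError("fold_margin must be >= 1")
    props = dict(class_proportions) if class_proportions is not None else dict(DEFAULT_PROPORTIONS)
    _validate_proportions(props)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    n = design.n_genes
    labels_pool = list(props)
    counts = rng.multinomial(n, [props[l] for l in labels_pool])
    labels = np.repeat(labels_pool, counts)
    rng.shuffle(labels)

    enriched = np.isin(
        labels,
        ["shared_all", *_PAIR_TARGETS, *_SPECIFIC_TARGETS],
    )
    hk = labels == "housekeeping"
    bg = labels == "background"
    off = labels == "unexpressed"

    # location calibration: enriched and housekeeping genes are all
    # expressed by construction; the background stratum supplies the rest
    p_enr = enriched.mean()
    p_hk = hk.mean()
    p_bg = max(bg.mean(), 1e-12)
    p_needed = float(np.clip((frac_expressed - p_enr - p_hk) / p_bg, 1e-4, 1 - 1e-4))
    mu = log_sigma * float(ndtri(p_needed))

    baseline = np.zeros(n)
    baseline[bg] = np.exp(mu + log_sigma * rng.standard_normal(bg.sum()))
    # housekeeping: expressed everywhere; truncated at 1 RPKM
    baseline[hk] = _truncated_lognormal(rng, hk.sum(), mu, log_sigma, lower=1.0)
    floor = 4.0 * fold_margin
    baseline[enriched] = _truncated_lognormal(rng, enriched.sum(), mu, log_sigma, lower=floor)

    mult = {c: np.ones(n) for c in CELLS}
    bulk = np.where(off, 0.0, baseline).copy()
    log_j = math.log(jitter)

    idx_shared = np.flatnonzero(labels == "shared_all")
    for c in CELLS:
        mult[c][idx_shared] = np.exp(rng.uniform(-log_j, log_j, idx_shared.size))
    excess = lambda size: np.exp(rng.exponential(math.log(2.0), size))
    for label, targets in _PAIR_TARGETS.items():
        idx = np.flatnonzero(labels == label)
        f = 2.0 * fold_margin * excess(idx.size)
        for t in targets:
            mult[t][idx] = f * np.exp(rng.uniform(-log_j / 2, log_j / 2, idx.size))
    for label, target in _SPECIFIC_TARGETS.items():
        idx = np.flatnonzero(labels == label)
        mult[target][idx] = 2.0 * fold_margin * excess(idx.size)
    for c in CELLS:
        mult[c][off] = 0.0

    # planted pigment genes contribute only through the pigment-cell share
    bulk[enriched] = 0.0
    cell_mean = np.mean([mult[c] for c in CELLS], axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mult_embryo = np.where(
            baseline > 0,
            (pigment_fraction * cell_mean * baseline + (1 - pigment_fraction) * bulk)
            / np.where(baseline > 0, baseline, 1.0),
            0.0,
        )

    table = pd.DataFrame(
        {
            "gene": [f"g{i:05d}" for i in range(n)],
            "label": labels,
            "baseline": baseline,
            "mult_melanocyte": mult["melanocyte"],
            "mult_iridophore": mult["iridophore"],
            "mult_rpe": mult["rpe"],
            "mult_embryo": mult_embryo,
            "dispersion": np.full(n, float(dispersion)),
        }
    )
    return SyntheticTruth(
        table=table,
        fold_margin=fold_margin,
        frac_expressed=frac_expressed,
        pigment_fraction=pigment_fraction,
    )


def _truncated_lognormal(
    rng: np.random.Generator, size: int, mu: float, sigma: float, lower: float
) -> np.ndarray:
    """Log-normal(mu, sigma) conditioned on being >= lower (inverse CDF)."""
    a = float(ndtr((math.log(lower) - mu) / sigma))
    u = rng.uniform(a, 1.0, size)
    return np.exp(mu + sigma * ndtri(u))


def simulate_counts(
    truth: SyntheticTruth,
    design: StudyDesign,
    seed: int = 0,
    *,
    length_median_bp: float = 2000.0,
    length_log_sigma: float = 0.6,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a tag-count matrix and library metadata from planted truth.

    Counts for gene g in a library of condition c are negative binomial with
    mean ``baseline_g * mult_{c,g} * length_kb_g * total/1e6`` and the
    planted dispersion (variance ``m + dispersion * m**2``); dispersion 0
    falls back to Poisson.  Gene lengths are log-normal with the stated
    median, drawn once per run and carried explicitly so RPKM is exact.
    """
    n = len(truth.table)
    if n != design.n_genes:
        raise ValueError(
            f"truth has {n} genes but design declares {design.n_genes}"
        )
    disp = truth.table["dispersion"].to_numpy()
    if (disp < 0).any():
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    lengths = np.exp(
        math.log(length_median_bp) + length_log_sigma * rng.standard_normal(n)
    )
    lengths = np.clip(np.round(lengths), 200, 50_000).astype(np.int64)
    len_kb = lengths / 1000.0

    total = design.total_reads_per_library
    lib_ids = design.library_ids()
    cell_of = {lib: lib.rsplit("_", 1)[0] for lib in lib_ids}
    baseline = truth.table["baseline"].to_numpy()

    cols = {}
    for lib in lib_ids:
        cell = cell_of[lib]
        m = baseline * truth.table[f"mult_{cell}"].to_numpy() * len_kb * (total / 1e6)
        cols[lib] = _nb_draw(rng, m, disp)
    counts = pd.DataFrame(cols, index=truth.table["gene"])
    totals = pd.Series(total, index=lib_ids)
    over = counts.sum(axis=0) > totals
    if over.any():  # vanishingly rare under the default scale; keep the invariant
        for lib in totals.index[over]:
            col = counts[lib].to_numpy()
            keep = np.random.default_rng(np.random.SeedSequence([int(seed), 2])).multivariate_hypergeometric(
                col, total
            )
            counts[lib] = keep
    meta = pd.DataFrame(
        {
            "library_id": lib_ids,
            "cell_type": [cell_of[lib] for lib in lib_ids],
            "timepoint_hpf": 77,
            "total_reads": total,
        }
    ).set_index("library_id")
    cm = CountMatrix(counts, pd.Series(lengths, index=counts.index), totals)
    return cm, meta


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray) -> np.ndarray:
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    nb = pos & (dispersion > 0)
    po = pos & (dispersion == 0)
    if nb.any():
        size = 1.0 / dispersion[nb]
        p = size / (size + mean[nb])
        out[nb] = rng.negative_binomial(size, p)
    if po.any():
        out[po] = rng.poisson(mean[po])
    return out


def generate_redundant_transcripts(
    n_clusters: int,
    duplicates_per_cluster: int | Sequence[int] | Callable[[np.random.Generator], int] = 2,
    mutation_rate: float = 0.01,
    length_range: tuple[int, int] = (500, 1500),
    seed: int = 0,
    *,
    truncation_range: tuple[float, float] = (0.75, 0.97),
) -> tuple[TranscriptSet, pd.DataFrame]:
    """Build a redundant transcript set with known cluster structure.

    Each cluster has one full-length root sequence and ``duplicates``
    truncated, point-mutated copies; the root (the longest member) is the
    planted representative.  With mutation rates below ~6% the within-
    cluster pairs exceed 94% identity over more than 70% of the shorter
    sequence and should collapse to the representative; between-cluster
    identity is that of unrelated random sequence.
    """
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    if not 0.0 <= mutation_rate < 1.0:
        raise ValueError("mutation_rate must lie in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    bases = np.array(list("ACGT"))

    def n_dups(k: int) -> int:
        if callable(duplicates_per_cluster):
            return int(duplicates_per_cluster(rng))
        if isinstance(duplicates_per_cluster, int):
            return duplicates_per_cluster
        return int(duplicates_per_cluster[k % len(duplicates_per_cluster)])

    transcripts: list[Transcript] = []
    truth_rows = []
    for k in range(n_clusters):
        dups = n_dups(k)
        if dups < 1:
            raise ValueError(f"cluster {k} has no duplicates specified")
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        root = bases[rng.integers(0, 4, length)]
        root_id = f"c{k:03d}_t0"
        transcripts.append(Transcript(root_id, "".join(root)))
        truth_rows.append(
            {
                "transcript_id": root_id, "cluster": k, "representative": True,
                "mutation_rate": mutation_rate, "length_bp": length,
            }
        )
        for j in range(1, dups + 1):
            frac = rng.uniform(*truncation_range)
            sub_len = max(1, int(round(frac * length)))
            seq = root[:sub_len].copy()
            if mutation_rate > 0:
                hit = rng.random(sub_len) < mutation_rate
                if hit.any():
                    shift = rng.integers(1, 4, hit.sum())
                    idx = np.searchsorted(bases, seq[hit])
                    seq[hit] = bases[(idx + shift) % 4]
            tid = f"c{k:03d}_t{j}"
            transcripts.append(Transcript(tid, "".join(seq)))
            truth_rows.append(
                {
                    "transcript_id": tid, "cluster": k, "representative": False,
                    "mutation_rate": mutation_rate, "length_bp": sub_len,
                }
            )
    return TranscriptSet(transcripts), pd.DataFrame(truth_rows)
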