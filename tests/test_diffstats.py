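"""t-tests, fold-change semantics, and windowed Pearson correlation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pigmentseq.diffstats import (
    all_pair_stats,
    fold_change,
    fold_ratio,
    gene_ttest,
    quote_fold,
    ttest_matrix,
    windowed_correlation,
)
from conftest import make_random_profile


class TestGeneTtest:
    def test_closed_form_example(self):
        t, df, p = gene_ttest([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.6742, abs=1e-4)
        assert df == 4
        assert p == pytest.approx(0.0213, abs=1e-4)

    def test_identical_constant_groups(self):
        t, df, p = gene_ttest([5, 5, 5], [5, 5, 5])
        assert (t, p) == (0.0, 1.0)
        assert gene_ttest([0, 0], [0, 0])[2] == 1.0

    def test_constant_unequal_groups_warn_p_zero(self):
        with pytest.warns(RuntimeWarning):
            t, _, p = gene_ttest([1, 1], [2, 2])
        assert p == 0.0 and t == -math.inf

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            gene_ttest([1], [2, 3])

    @pytest.mark.parametrize("seed", range(5))
    def test_antisymmetric_in_group_order(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.random(6), rng.random(4)
        t1, df1, p1 = gene_ttest(a, b)
        t2, df2, p2 = gene_ttest(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)
        assert df1 == df2

    def test_matches_scipy_pooled(self):
        rng = np.random.default_rng(3)
        a, b = rng.random(8), rng.random(5) + 0.3
        t, _, p = gene_ttest(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_matrix_agrees_with_scalar(self):
        rng = np.random.default_rng(4)
        a = rng.random((30, 6))
        b = rng.random((30, 4)) + 0.2
        t, p = ttest_matrix(a, b)
        for i in (0, 13, 29):
            ts, _, ps = gene_ttest(a[i], b[i])
            assert t[i] == pytest.approx(ts)
            assert p[i] == pytest.approx(ps)


class TestFoldChange:
    def test_published_ratio(self):
        fc = fold_change(816.19, 11.45)
        assert fc.ratio == pytest.approx(71.28, abs=0.01)
        assert fc.at_least(71)

    def test_zero_denominator_is_infinite(self):
        fc = fold_change(5.0, 0.0)
        assert math.isinf(fc.ratio)
        assert fc.at_least(1e9)

    def test_zero_over_zero_undefined_fails_everything(self):
        fc = fold_change(0.0, 0.0)
        assert math.isnan(fc.ratio)
        assert not fc.at_least(0.0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            fold_ratio(-1.0, 2.0)

    @pytest.mark.parametrize(
        "ratio,quoted",
        [(71.283, 71.0), (198.641, 198.0), (0.7019, 0.7), (1.0, 1.0), (0.04, 0.0)],
    )
    def test_quote_convention(self, ratio, quoted):
        assert quote_fold(ratio) == quoted


class TestAllPairStats:
    def _rpkm(self, blocks, seed=0):
        cols = {}
        ann = {}
        for cell, block in blocks.items():
            for i, col in enumerate(np.atleast_2d(block).T):
                lib = f"{cell}_{i}"
                cols[lib] = col
                ann[lib] = cell
        return pd.DataFrame(cols, index=[f"g{i}" for i in range(len(next(iter(cols.values()))))]), ann

    def test_identical_groups_give_p_one(self):
        rpkm, ann = self._rpkm(
            {"melanocyte": [[5, 5], [1, 1]], "rpe": [[5, 5], [1, 1]],
             "iridophore": [[5, 5], [1, 1]]}
        )
        profile = all_pair_stats(rpkm, ann)
        assert (profile[["p_mel_rpe", "p_mel_irid", "p_rpe_irid"]] == 1.0).all().all()

    def test_means_and_p_columns_assembled(self):
        rng = np.random.default_rng(1)
        rpkm, ann = self._rpkm(
            {"melanocyte": rng.random((10, 3)), "rpe": rng.random((10, 3)),
             "iridophore": rng.random((10, 2)), "embryo": rng.random((10, 2))}
        )
        profile = all_pair_stats(rpkm, ann)
        assert list(profile.columns[:5]) == [
            "gene", "melanocyte", "rpe", "iridophore", "embryo",
        ]
        mel_libs = [c for c in rpkm.columns if c.startswith("melanocyte")]
        np.testing.assert_allclose(profile["melanocyte"], rpkm[mel_libs].mean(axis=1))
        assert profile["p_mel_rpe"].between(0, 1).all()

    def test_planted_fold_detected_with_high_power(self):
        """A 16-fold planted difference between 5 and 11 replicate libraries
        reaches p < 0.05 in at least 90% of simulations."""
        rng = np.random.default_rng(42)
        hits = 0
        n_trials = 100
        for _ in range(n_trials):
            a = rng.gamma(5.0, 16.0 / 5.0, size=5)  # mean 16, CV ~0.45
            b = rng.gamma(5.0, 1.0 / 5.0, size=11)  # mean 1
            _, _, p = gene_ttest(a, b)
            hits += p < 0.05
        assert hits >= 90


class TestWindowedCorrelation:
    def test_identical_profiles_give_unit_correlation(self):
        profile = make_random_profile(200, seed=1)
        profile["rpe"] = profile["melanocyte"]
        wp = windowed_correlation(profile, pairs=[("melanocyte", "rpe")], w=50)
        r = wp.correlations["melanocyte_vs_rpe"].dropna()
        np.testing.assert_allclose(r, 1.0, atol=1e-12)
        assert wp.averages["melanocyte_vs_rpe"] == pytest.approx(1.0)

    def test_negated_profile_gives_minus_one(self):
        profile = make_random_profile(200, seed=2)
        profile["melanocyte"] += 0.01  # keep windows non-constant
        profile["rpe"] = profile["melanocyte"].max() - profile["melanocyte"]
        wp = windowed_correlation(profile, pairs=[("melanocyte", "rpe")], w=50)
        np.testing.assert_allclose(
            wp.correlations["melanocyte_vs_rpe"].dropna(), -1.0, atol=1e-12
        )

    def test_window_count_is_n_minus_w(self):
        profile = make_random_profile(500, seed=3)
        wp = windowed_correlation(profile, w=100)
        assert len(wp.correlations) == 400

    def test_matches_bruteforce_loop(self):
        profile = make_random_profile(600, seed=4)
        w = 50
        wp = windowed_correlation(profile, pairs=[("melanocyte", "iridophore")], w=w)
        ordered = profile.sort_values(["embryo", "gene"], kind="stable")
        x = ordered["melanocyte"].to_numpy()
        y = ordered["iridophore"].to_numpy()
        brute = np.array(
            [sps.pearsonr(x[i : i + w], y[i : i + w])[0] for i in range(len(x) - w)]
        )
        np.testing.assert_allclose(
            wp.correlations["melanocyte_vs_iridophore"], brute, atol=1e-12
        )

    def test_invariant_to_gene_relabeling(self):
        """Renaming genes without perturbing the embryo ordering leaves the
        average windowed correlation unchanged."""
        profile = make_random_profile(300, seed=5)
        # unique embryo values so the id tiebreak never engages
        profile["embryo"] = np.arange(300, dtype=float)
        renamed = profile.copy()
        renamed["gene"] = [f"x{i:05d}" for i in range(300)]
        w1 = windowed_correlation(profile, w=60)
        w2 = windowed_correlation(renamed, w=60)
        for pair in w1.averages:
            assert w1.averages[pair] == pytest.approx(w2.averages[pair], abs=1e-12)

    def test_average_increases_with_shared_component(self):
        """A common housekeeping component of growing weight drives the
        average windowed correlation up monotonically."""
        rng = np.random.default_rng(6)
        n = 1500
        shared = rng.normal(0, 1, n)
        averages = []
        for rho in (0.0, 0.3, 0.6, 0.9):
            x = rho * shared + (1 - rho) * rng.normal(0, 1, n)
            y = rho * shared + (1 - rho) * rng.normal(0, 1, n)
            profile = pd.DataFrame(
                {
                    "gene": [f"g{i:05d}" for i in range(n)],
                    "melanocyte": np.exp(x),
                    "rpe": np.exp(y),
                    "iridophore": 1.0,
                    "embryo": rng.random(n),
                }
            )
            wp = windowed_correlation(profile, pairs=[("melanocyte", "rpe")], w=200)
            averages.append(wp.averages["melanocyte_vs_rpe"])
        assert averages == sorted(averages)

    def test_small_window_rejected(self):
        with pytest.raises(ValueError):
            windowed_correlation(make_random_profile(100, seed=7), w=2)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            windowed_correlation(make_random_profile(50, seed=8), w=50)
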