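import itertools

import numpy as np
import pandas as pd
import pytest

from clampdecay.decayfit import (AnalysisConfig, CohortDecayModel,
                                 DecayFitError, compare_groups,
                                 enumerate_subsamples, fit_exponential,
                                 group_series_matrix, participant_ec_series,
                                 permutation_test, subsample_fits)

X30 = np.arange(1, 31, dtype=float)


def exp_series(a, b, c, x=X30):
    return a * np.exp(b * x) + c


def brute_force_subsets(n, k):
    """Independent recursive enumeration oracle."""
    def rec(start, need):
        if need == 0:
            return [()]
        return [(i,) + rest
                for i in range(start, n - need + 1)
                for rest in rec(i + 1, need - 1)]
    return rec(0, k)


class TestFitExponential:
    @pytest.mark.parametrize("a, b, c", [
        (2.0, -0.3, 1.0), (-5.0, -0.26, 1.0), (1.0, -0.05, -3.0),
    ])
    def test_noiseless_recovery(self, a, b, c):
        fit = fit_exponential(exp_series(a, b, c))
        assert fit.a == pytest.approx(a, rel=1e-6)
        assert fit.b == pytest.approx(b, rel=1e-6)
        assert fit.c == pytest.approx(c, rel=1e-6, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.initial_state == fit.a + fit.c

    def test_constant_series_degenerates_gracefully(self):
        fit = fit_exponential(np.full(30, 4.0))
        assert fit.a == pytest.approx(0.0, abs=1e-9)
        assert fit.c == pytest.approx(4.0)

    def test_custom_x_grid(self):
        x = np.arange(0, 30, dtype=float)
        fit = fit_exponential(exp_series(2, -0.3, 1, x), x=x)
        assert fit.b == pytest.approx(-0.3, rel=1e-6)

    def test_too_few_points_raises(self):
        with pytest.raises(DecayFitError):
            fit_exponential(np.array([1.0, 2.0, 3.0]))

    def test_fit_is_deterministic(self):
        y = exp_series(-4, -0.2, -1) + np.sin(X30)  # fixed pseudo-noise
        f1, f2 = fit_exponential(y), fit_exponential(y)
        assert (f1.a, f1.b, f1.c) == (f2.a, f2.b, f2.c)


class TestEnumeration:
    @pytest.mark.parametrize("n, k, count", [(4, 3, 4), (15, 12, 455), (5, 5, 1)])
    def test_counts(self, n, k, count):
        subsets = enumerate_subsamples(n, k)
        assert len(subsets) == count
        assert len(set(subsets)) == count

    def test_matches_brute_force_oracle_small_n(self):
        for n in range(1, 9):
            for k in range(1, n + 1):
                assert set(enumerate_subsamples(n, k)) == set(brute_force_subsets(n, k))

    def test_lexicographic_order(self):
        subsets = enumerate_subsamples(5, 3)
        assert subsets == sorted(subsets)

    def test_invalid_k_raises(self):
        with pytest.raises(DecayFitError):
            enumerate_subsamples(4, 5)


def records_from_blocks(block_values, participant="p1", group="g"):
    """Build a trial table in which EC block j holds block_values[j]."""
    rows = []
    gi = 1
    for j, values in enumerate(block_values, start=1):
        for pos, v in enumerate(values, start=1):
            rows.append({"group": group, "participant": participant,
                         "global_index": gi, "phase": "EC",
                         "block_label": f"EC{j}", "within_block_index": pos,
                         "force_at_pv": v, "failure_flag": False})
            gi += 1
    return pd.DataFrame(rows)


class TestParticipantSeries:
    def test_mean_of_identical_blocks_is_identity(self):
        base = np.arange(1.0, 31.0)
        rec = records_from_blocks([base] * 9)
        series = participant_ec_series(rec, "p1")
        np.testing.assert_allclose(series.values, base)

    def test_cancelling_blocks_average_to_zero(self):
        base = np.arange(1.0, 31.0)
        blocks = [base if j % 2 == 0 else -base for j in range(8)] + [np.zeros(30)]
        series = participant_ec_series(rec := records_from_blocks(blocks), "p1")
        np.testing.assert_allclose(series.values, np.zeros(30), atol=1e-12)

    def test_matches_direct_positionwise_mean(self):
        rng = np.random.default_rng(5)
        blocks = [rng.normal(size=30) for _ in range(9)]
        series = participant_ec_series(records_from_blocks(blocks), "p1")
        np.testing.assert_allclose(series.values, np.mean(blocks, axis=0))

    def test_missing_block_raises_with_names(self):
        rec = records_from_blocks([np.arange(30.0)] * 8)  # EC9 absent
        with pytest.raises(DecayFitError, match="p1.*EC9"):
            participant_ec_series(rec, "p1")

    def test_failed_trial_imputed_from_other_blocks(self):
        # block j holds the constant value j, j = 0..8
        blocks = [np.full(30, float(j)) for j in range(9)]
        rec = records_from_blocks(blocks)
        mask = (rec.block_label == "EC5") & (rec.within_block_index == 10)
        rec.loc[mask, "force_at_pv"] = np.nan
        series = participant_ec_series(rec, "p1")
        assert series.n_imputed == 1
        # imputed cell = mean over remaining blocks at position 10
        others = [float(j) for j in range(9) if j != 4]
        imputed = np.mean(others)
        expected = (sum(others) + imputed) / 9
        assert series.values[9] == pytest.approx(expected, abs=1e-12)


class TestSubsampleFits:
    def test_identical_series_give_identical_generating_fits(self):
        series = np.tile(exp_series(-3, -0.2, -1), (15, 1))
        fits = subsample_fits(series, k=12)
        assert len(fits) == 455
        bs = {round(f.b, 9) for f in fits}
        assert bs == {-0.2}

    def test_k_equals_n_reduces_to_grand_average_fit(self):
        rng = np.random.default_rng(2)
        series = exp_series(-3, -0.2, -1) + rng.normal(0, 0.2, (15, 30))
        fits = subsample_fits(series, k=15)
        assert len(fits) == 1
        grand = fit_exponential(series.mean(axis=0))
        assert fits[0].b == pytest.approx(grand.b)

    def test_mean_subset_rate_close_to_grand_fit_on_mild_noise(self):
        rng = np.random.default_rng(3)
        series = exp_series(-3, -0.25, -1) + rng.normal(0, 0.3, (15, 30))
        fits = subsample_fits(series, k=12)
        grand = fit_exponential(series.mean(axis=0))
        assert np.mean([f.b for f in fits]) == pytest.approx(grand.b, abs=0.02)


class TestPermutationAndComparison:
    def test_identical_pooled_series_give_zero_difference(self):
        series = np.tile(exp_series(-3, -0.2, -1), (12, 1))
        diff = permutation_test(series, series.copy(),
                                np.random.default_rng(0))
        np.testing.assert_allclose(diff, 0.0, atol=1e-9)

    def test_same_seed_same_relabeling(self):
        rng_series = np.random.default_rng(4)
        a = exp_series(-3, -0.2, -1) + rng_series.normal(0, 0.3, (12, 30))
        b = exp_series(-3, -0.2, -1) + rng_series.normal(0, 0.3, (12, 30))
        d1 = permutation_test(a, b, np.random.default_rng(11))
        d2 = permutation_test(a, b, np.random.default_rng(11))
        np.testing.assert_array_equal(d1, d2)

    def test_null_permutation_rate_differences_center_at_zero(self):
        rng = np.random.default_rng(6)
        a = exp_series(-3, -0.2, -1) + rng.normal(0, 0.3, (15, 30))
        b = exp_series(-3, -0.2, -1) + rng.normal(0, 0.3, (15, 30))
        comp = compare_groups(a, b, seed=6)
        mean_perm_b = comp.perm_diffs[:, 1].mean()
        sd_perm_b = comp.perm_diffs[:, 1].std()
        assert abs(mean_perm_b) < 3 * sd_perm_b / np.sqrt(455) + 0.01

    def test_copied_group_yields_null_mean_and_high_p(self):
        rng = np.random.default_rng(8)
        a = exp_series(-3, -0.2, -1) + rng.normal(0, 0.3, (15, 30))
        comp = compare_groups(a, a.copy(), seed=8)
        np.testing.assert_allclose(comp.mean_diff, 0.0, atol=1e-9)
        assert (comp.p > 0.9).all()

    def test_p_values_are_multiples_of_reciprocal_subset_count(self):
        rng = np.random.default_rng(9)
        a = exp_series(-3, -0.2, -1) + rng.normal(0, 0.3, (15, 30))
        b = exp_series(-3, -0.1, -1) + rng.normal(0, 0.3, (15, 30))
        comp = compare_groups(a, b, seed=9)
        assert comp.n_subsets == 455
        assert np.all((comp.p >= 0) & (comp.p <= 1))
        np.testing.assert_allclose(comp.p * 455, np.round(comp.p * 455), atol=1e-9)

    def test_one_sided_rule_option(self):
        rng = np.random.default_rng(10)
        a = exp_series(-3, -0.2, -1) + rng.normal(0, 0.3, (15, 30))
        b = exp_series(-3, -0.1, -1) + rng.normal(0, 0.3, (15, 30))
        cfg = AnalysisConfig(permutation_rule="one-sided")
        comp = compare_groups(a, b, seed=10, config=cfg)
        assert comp.permutation_rule == "one-sided"
        assert np.all((comp.p >= 0) & (comp.p <= 1))

    def test_max_subsets_thins_deterministically(self):
        rng = np.random.default_rng(12)
        a = exp_series(-3, -0.2, -1) + rng.normal(0, 0.3, (15, 30))
        b = exp_series(-3, -0.1, -1) + rng.normal(0, 0.3, (15, 30))
        c1 = compare_groups(a, b, seed=12, max_subsets=50)
        c2 = compare_groups(a, b, seed=12, max_subsets=50)
        assert c1.n_subsets == 50
        np.testing.assert_array_equal(c1.boot_diffs, c2.boot_diffs)


class TestCohortModel:
    def test_model_from_series_and_summary(self):
        rng = np.random.default_rng(13)
        series = {
            "arc": exp_series(-3, -0.08, -2) + rng.normal(0, 0.3, (15, 30)),
            "cursor": exp_series(-2.5, -0.26, -0.9) + rng.normal(0, 0.3, (15, 30)),
        }
        model = CohortDecayModel.from_series(series)
        res = model.fit(seed=13)
        assert set(res.group_fits) == {"arc", "cursor"}
        assert res.group_fits["arc"].n_subsets == 455
        assert res.group_fits["arc"].params_mean[1] > res.group_fits["cursor"].params_mean[1]
        text = res.summary()
        assert "arc" in text and "cursor" in text and "p(b)" in text
        d = res.to_dict()
        assert len(d["comparisons"]) == 1

    def test_results_plot_smoke(self):
        import matplotlib
        matplotlib.use("Agg")
        rng = np.random.default_rng(14)
        series = {"arc": exp_series(-3, -0.08, -2) + rng.normal(0, 0.3, (15, 30)),
                  "cursor": exp_series(-2.5, -0.26, -0.9) + rng.normal(0, 0.3, (15, 30))}
        res = CohortDecayModel.from_series(series).fit(seed=14)
        ax = res.plot()
        assert len(ax.lines) == 4

    def test_group_series_matrix_shape(self, default_cohort):
        matrix = group_series_matrix(default_cohort, "arc")
        assert matrix.shape == (15, 30)
        assert np.isfinite(matrix).all()
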