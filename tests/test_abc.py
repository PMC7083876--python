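"""Rejection-ABC machinery: priors, reference tables, rejection, CV, PPC, GoF."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from demosat.abc_inference import (MODEL_BOTTLENECK, MODEL_CONSTANT, PriorSet,
                                   ReferenceTable, abc_reject,
                                   build_reference_table, cv_model_selection,
                                   cv_parameter_estimation, goodness_of_fit,
                                   model_posterior, posterior_predictive_check,
                                   sample_priors, simulate_summaries)
from demosat.sumstats import SummaryVector


def synthetic_table(stats_arr, models=None, params=None, n_ind=50, n_loci=10):
    """Reference table with hand-made statistics (no simulation)."""
    df = pd.DataFrame(stats_arr, columns=["k_mean", "prop_low_freq", "m_ratio"])
    df["model"] = models if models is not None else MODEL_BOTTLENECK
    for col in ("ne_cur", "ne_hist", "ne_bot", "t_bot_start", "t_bot_end",
                "t_hist", "mu", "gsm_par"):
        df[col] = params[col] if params and col in params else 1.0
    return ReferenceTable(df=df, n_ind=n_ind, n_loci=n_loci)


class TestPriors:
    def test_uniform_bottleneck_size_moments(self):
        df = sample_priors(PriorSet(), MODEL_BOTTLENECK, 100000, seed=1)
        x = df["ne_bot"]
        se = (600 - 1) / np.sqrt(12 * x.size)
        assert abs(x.mean() - 300.5) < 3 * se
        assert x.min() >= 1 and x.max() <= 600

    def test_bottleneck_time_ordering_enforced(self):
        df = sample_priors(PriorSet(), MODEL_BOTTLENECK, 20000, seed=2)
        assert (df["t_bot_start"] > df["t_bot_end"]).all()

    def test_lognormal_ne_parameters(self):
        df = sample_priors(PriorSet(), MODEL_CONSTANT, 100000, seed=3)
        logs = np.log(df["ne_cur"])
        assert logs.mean() == pytest.approx(10.5, abs=0.02)
        assert logs.std() == pytest.approx(1.0, abs=0.02)

    def test_constant_model_columns(self):
        df = sample_priors(PriorSet(), MODEL_CONSTANT, 10, seed=4)
        assert df["ne_bot"].isna().all()
        assert df["t_hist"].between(10, 40).all()

    def test_verbal_prior_median(self):
        df = sample_priors(PriorSet.verbal(), MODEL_CONSTANT, 50000, seed=5)
        assert np.median(df["ne_hist"]) == pytest.approx(6708, rel=0.05)


class TestReferenceTable:
    def test_shape_and_determinism(self):
        t1 = build_reference_table(PriorSet(), 100, seed=10, n_ind=20, n_loci=4)
        t2 = build_reference_table(PriorSet(), 100, seed=10, n_ind=20, n_loci=4)
        assert t1.df.shape[0] == 200
        assert set(t1.df["model"]) == {MODEL_BOTTLENECK, MODEL_CONSTANT}
        pd.testing.assert_frame_equal(t1.df, t2.df)

    def test_csv_round_trip(self, tmp_path):
        t = build_reference_table(PriorSet(), 30, seed=11, n_ind=10, n_loci=3)
        path = tmp_path / "table.csv"
        t.save_csv(path)
        back = ReferenceTable.load_csv(path)
        assert back.n_ind == 10 and back.n_loci == 3
        assert np.allclose(back.stats, t.stats)

    def test_bottleneck_rows_have_lower_m_ratio(self):
        t = build_reference_table(PriorSet(), 800, seed=12, n_ind=40, n_loci=12)
        mb = t.model_rows(MODEL_BOTTLENECK)["m_ratio"]
        mc = t.model_rows(MODEL_CONSTANT)["m_ratio"]
        assert stats.mannwhitneyu(mb, mc, alternative="less").pvalue < 1e-3


class TestRejection:
    def test_tolerance_one_returns_prior(self):
        rng = np.random.default_rng(0)
        t = synthetic_table(rng.normal(size=(500, 3)))
        post = abc_reject(SummaryVector(0, 0, 0), t, tolerance=1.0)
        assert post.accepted.shape[0] == 500

    def test_zero_distance_row_retained(self):
        rng = np.random.default_rng(1)
        arr = rng.normal(size=(200, 3))
        t = synthetic_table(arr)
        post = abc_reject(arr[17], t, tolerance=1 / 200)
        assert post.accepted.shape[0] == 1
        assert np.allclose(post.accepted[["k_mean", "prop_low_freq", "m_ratio"]].iloc[0],
                           arr[17])

    def test_zero_mad_falls_back_to_sd(self):
        rng = np.random.default_rng(2)
        arr = rng.normal(size=(100, 3))
        arr[:, 1] = 0.0  # degenerate statistic
        arr[0, 1] = 1.0
        t = synthetic_table(arr)
        with pytest.warns(UserWarning, match="MAD"):
            post = abc_reject(arr[5], t, tolerance=0.1)
        assert np.isfinite(post.distances).all()

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        arr = rng.normal(size=(300, 3))
        params = {"ne_bot": rng.uniform(1, 600, 300)}
        t = synthetic_table(arr, params=params)
        shuffled_idx = rng.permutation(300)
        t2 = ReferenceTable(df=t.df.iloc[shuffled_idx].reset_index(drop=True),
                            n_ind=50, n_loci=10)
        target = arr.mean(axis=0)
        p1 = abc_reject(target, t, 0.05)
        p2 = abc_reject(target, t2, 0.05)
        assert sorted(p1.accepted["ne_bot"]) == pytest.approx(
            sorted(p2.accepted["ne_bot"]))

    def test_invalid_tolerance(self):
        t = synthetic_table(np.zeros((10, 3)))
        with pytest.raises(ValueError):
            abc_reject(SummaryVector(0, 0, 0), t, tolerance=0.0)


class TestModelPosterior:
    def test_identical_models_near_half(self):
        rng = np.random.default_rng(4)
        arr = np.vstack([rng.normal(size=(400, 3))] * 2)
        t = synthetic_table(arr, models=[MODEL_BOTTLENECK] * 400 + [MODEL_CONSTANT] * 400)
        probs = model_posterior(rng.normal(size=3), t, tolerance=0.2)
        assert probs.sum() == pytest.approx(1.0)
        assert abs(probs[MODEL_BOTTLENECK] - 0.5) < 0.15


class TestCrossValidation:
    def test_disjoint_models_classified_perfectly(self):
        rng = np.random.default_rng(5)
        arr = np.vstack([rng.normal(0, 0.1, size=(300, 3)),
                         rng.normal(10, 0.1, size=(300, 3))])
        t = synthetic_table(arr, models=[MODEL_BOTTLENECK] * 300 + [MODEL_CONSTANT] * 300)
        res = cv_model_selection(t, n_pseudo=60, tolerance=0.05, seed=6)
        assert (res.correct_rate == 1.0).all()
        assert res.confusion.to_numpy().sum() == 60

    def test_identically_distributed_models_near_chance(self):
        rng = np.random.default_rng(7)
        arr = rng.normal(size=(1000, 3))  # both models drawn from one distribution
        t = synthetic_table(arr, models=[MODEL_BOTTLENECK] * 500 + [MODEL_CONSTANT] * 500)
        res = cv_model_selection(t, n_pseudo=200, tolerance=0.1, seed=8)
        assert abs(res.correct_rate.mean() - 0.5) < 0.12

    def test_perfect_estimator_zero_error(self):
        # statistics are a bijective function of the parameter -> nearest
        # neighbours share (nearly) the same parameter value
        theta = np.linspace(0, 1, 2000)
        arr = np.column_stack([theta, theta**2, np.cos(theta)])
        t = synthetic_table(arr, params={"ne_bot": theta})
        res = cv_parameter_estimation(t, n_pseudo=100, tolerance=2e-3, seed=9,
                                      params=["ne_bot"])
        assert res.prediction_error["ne_bot"] < 0.01

    def test_uninformative_estimator_near_one(self):
        rng = np.random.default_rng(10)
        arr = rng.normal(size=(4000, 3))              # noise, unrelated to theta
        theta = rng.uniform(0, 1, size=4000)
        t = synthetic_table(arr, params={"ne_bot": theta})
        res = cv_parameter_estimation(t, n_pseudo=150, tolerance=0.2, seed=11,
                                      params=["ne_bot"])
        assert res.prediction_error["ne_bot"] == pytest.approx(1.0, abs=0.25)

    def test_mixed_model_table_rejected(self):
        t = build_reference_table(PriorSet(), 20, seed=13, n_ind=10, n_loci=3)
        with pytest.raises(ValueError):
            cv_parameter_estimation(t, n_pseudo=5, tolerance=0.5, seed=14)


class TestPosteriorPredictive:
    def test_single_draw_shape(self):
        t = build_reference_table(PriorSet(), 50, seed=15, n_ind=15, n_loci=4,
                                  models=(MODEL_BOTTLENECK,))
        target = t.stats.mean(axis=0)
        post = abc_reject(target, t, tolerance=0.2)
        ppc = posterior_predictive_check(post, n_ind=15, n_loci=4, n_draws=1,
                                         seed=16)
        assert ppc.simulated.shape == (1, 3)

    def test_self_consistent_target_not_extreme(self):
        t = build_reference_table(PriorSet(), 400, seed=17, n_ind=30, n_loci=8,
                                  models=(MODEL_BOTTLENECK,))
        target = np.median(t.stats, axis=0)
        post = abc_reject(target, t, tolerance=0.1)
        ppc = posterior_predictive_check(post, n_ind=30, n_loci=8, n_draws=150,
                                         seed=18)
        assert ((ppc.tail_prob > 0.01) & (ppc.tail_prob < 0.99)).all()


class TestGoodnessOfFit:
    def test_p_value_bounds_and_far_target(self):
        rng = np.random.default_rng(19)
        t = synthetic_table(rng.normal(size=(500, 3)))
        p_far = goodness_of_fit(np.array([100.0, 100.0, 100.0]), t, 0.05,
                                n_null=99, seed=20)
        assert p_far == pytest.approx(1 / 100)
        p_in = goodness_of_fit(np.zeros(3), t, 0.05, n_null=99, seed=21)
        assert 0 < p_in <= 1

    def test_null_calibration_uniform(self):
        rng = np.random.default_rng(22)
        t = synthetic_table(rng.normal(size=(600, 3)))
        # targets drawn from the table's own generating distribution
        ps = [goodness_of_fit(t.stats[i], t, 0.05, n_null=60, seed=100 + i)
              for i in range(80)]
        # roughly uniform: rejection rate at 0.1 within binomial band
        rej = sum(p < 0.1 for p in ps)
        lo, hi = stats.binom.interval(0.99, 80, 0.1)
        assert lo <= rej <= hi
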