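"""Statistical-similarity metrics, TSTR utility and the subset t-test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from synthehr.data import train_test_split
from synthehr.fidelity import (fidelity_pvalue, flatten_features, ks_statistic,
                               subset_utility_test, summary_table, tstr_utility)
from synthehr.toygen import generate_cohort

from conftest import tiny_config


def brute_force_ks(x, y):
    """Double-loop ECDF sup-distance oracle for small samples."""
    points = np.concatenate([x, y])
    best = 0.0
    for p in points:
        fx = np.mean(x <= p)
        fy = np.mean(y <= p)
        best = max(best, abs(fx - fy))
    return best


class TestKS:
    def test_identical_samples_give_zero(self):
        x = np.array([1.0, 2.0, 5.0])
        assert ks_statistic(x, x) == 0.0

    def test_disjoint_supports_give_one(self):
        assert ks_statistic(np.array([1.0, 2.0]), np.array([10.0, 11.0])) == 1.0

    def test_hand_enumerated_example(self):
        assert ks_statistic(np.array([1.0, 2.0, 3.0]),
                            np.array([1.0, 2.0, 2.0])) == pytest.approx(1 / 3)

    def test_missing_entries_ignored(self):
        x = np.array([1.0, np.nan, 2.0, 3.0])
        y = np.array([1.0, 2.0, 3.0, np.nan])
        assert ks_statistic(x, y) == 0.0

    def test_empty_observed_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ks_statistic(np.array([np.nan]), np.array([1.0]))

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.integers(min_value=1, max_value=50), st.integers(min_value=1, max_value=50),
           st.integers(min_value=0, max_value=2**31 - 1))
    def test_agrees_with_brute_force_oracle(self, nx, ny, seed):
        rng = np.random.default_rng(seed)
        x = np.round(rng.normal(size=nx), 1)
        y = np.round(rng.normal(size=ny), 1)
        assert ks_statistic(x, y) == pytest.approx(brute_force_ks(x, y), abs=1e-12)


@pytest.fixture(scope="module")
def cohort_pair():
    dataset, masks, gt = generate_cohort(tiny_config(seed=21, n=300))
    return dataset, masks, gt["schema"]


class TestSummaryTable:
    def test_self_comparison_is_exact(self, cohort_pair):
        dataset, masks, schema = cohort_pair
        tab = summary_table((dataset, masks), (dataset, masks), schema)
        num = tab[tab.kind.str.endswith("numeric")]
        assert (num.ks.dropna() == 0).all()
        assert np.allclose(num.real_mean.astype(float), num.synth_mean.astype(float))
        assert np.allclose(num.real_missing_rate, num.synth_missing_rate)

    def test_feature_unobserved_in_synth_flagged(self, cohort_pair):
        dataset, masks, schema = cohort_pair
        synth, synth_masks = dataset.copy(), masks.copy()
        synth.temp_num[:, :, 0] = np.nan
        synth_masks.temp_num[:, :, 0] = 0
        tab = summary_table((dataset, masks), (synth, synth_masks), schema)
        row = tab[tab.feature == schema.temporal_numeric[0]].iloc[0]
        assert row.synth_missing_rate == 1.0
        assert row.ks is None or np.isnan(row.ks)

    def test_missing_rate_excludes_padding(self, cohort_pair):
        dataset, masks, schema = cohort_pair
        tab = summary_table((dataset, masks), (dataset, masks), schema)
        j = 0
        row = tab[tab.feature == schema.temporal_numeric[j]].iloc[0]
        sp = masks.step_present.astype(bool)
        expected = 1.0 - masks.temp_num[:, :, j][sp].mean()
        assert row.real_missing_rate == pytest.approx(expected)

    def test_two_independent_draws_have_small_ks(self):
        a = generate_cohort(tiny_config(seed=31, n=1000))
        b = generate_cohort(tiny_config(seed=32, n=1000))
        tab = summary_table(a[:2], b[:2], a[2]["schema"])
        ks = tab.ks.dropna().astype(float)
        assert (ks < 0.08).all()


@pytest.fixture(scope="module")
def tstr_setup():
    dataset, masks, gt = generate_cohort(tiny_config(seed=41, n=600))
    (tr, trm), (te, tem) = train_test_split(dataset, masks, seed=2)
    return (tr, trm), (te, tem), gt["schema"]


class TestTSTR:
    def test_identical_training_sources_give_identical_metrics(self, tstr_setup):
        train, test, schema = tstr_setup
        res = tstr_utility(train, train, test, schema, "mortality", "rf", seed=0)
        assert res["real"] == res["synthetic"]

    def test_lr_and_rf_run(self, tstr_setup):
        train, test, schema = tstr_setup
        for kind in ("rf", "lr"):
            res = tstr_utility(train, train, test, schema, "mortality", kind, seed=0)
            assert 0 <= res["real"][0] <= 1

    def test_gru_model_runs_and_scores(self, tstr_setup):
        train, test, schema = tstr_setup
        res = tstr_utility(train, train, test, schema, "mortality", "gru", seed=0)
        assert 0 <= res["real"][0] <= 1 and 0 <= res["real"][1] <= 1

    def test_no_signal_target_scores_near_chance(self):
        config = tiny_config(seed=51, n=600, outcome_coef_severity=0.0,
                             outcome_coef_age=0.0)
        dataset, masks, gt = generate_cohort(config)
        (tr, trm), (te, tem) = train_test_split(dataset, masks, seed=3)
        res = tstr_utility((tr, trm), (tr, trm), (te, tem), gt["schema"],
                           "mortality", "rf", seed=0)
        n1 = int(te.static_num[:, list(gt["schema"].static_numeric).index("mortality")].sum())
        n0 = te.n_patients - n1
        null_sd = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(res["real"][0] - 0.5) < 4 * null_sd

    def test_planted_signal_detected_above_permutation_null(self):
        """Real-trained RF AUC beats 0.5 by > 5 null standard deviations
        (Mann-Whitney null sd) when the outcome depends on two features."""
        config = tiny_config(seed=41, n=1200, outcome_prevalence=0.3,
                             outcome_coef_severity=2.0, outcome_coef_age=1.5,
                             missing_rates={"heart_rate": 0.2, "spo2": 0.3,
                                            "resp_pressure": 0.4, "glucose": 0.5,
                                            "o2_device": 0.4})
        dataset, masks, gt = generate_cohort(config)
        schema = gt["schema"]
        train, test = train_test_split(dataset, masks, test_fraction=0.4, seed=2)
        res = tstr_utility(train, train, test, schema, "mortality", "rf", seed=0)
        y = test[0].static_num[:, list(schema.static_numeric).index("mortality")]
        n1, n0 = int(y.sum()), int(len(y) - y.sum())
        null_sd = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert res["real"][0] > 0.5 + 5 * null_sd

    def test_single_class_training_target_rejected(self, tstr_setup):
        train, test, schema = tstr_setup
        broken = train[0].copy()
        broken.static_num[:, list(schema.static_numeric).index("mortality")] = 0.0
        with pytest.raises(ValueError, match="binary|single-class"):
            tstr_utility((broken, train[1]), train, test, schema, "mortality", "rf")


class TestSubsetTest:
    def test_identical_sources_reject_strongly(self, tstr_setup):
        train, test, schema = tstr_setup
        out = subset_utility_test(train, train, test, schema, ["mortality"],
                                  n_features=5, n_trials=10, seed=0)
        assert (out.mean_abs_diff == 0).all()
        assert (out.p_value < 0.001).all()

    def test_pvalue_matches_hand_computed_t_statistic(self):
        """p = P(T_{n-1} <= (mean - X) / (s/sqrt(n))) for hand-set differences."""
        diffs = [0.05, 0.06, 0.04]
        n = len(diffs)
        t_stat = (np.mean(diffs) - 0.04) / (np.std(diffs, ddof=1) / np.sqrt(n))
        expected = stats.t.cdf(t_stat, df=n - 1)
        assert fidelity_pvalue(diffs, 0.04) == pytest.approx(expected, rel=1e-12)
        assert fidelity_pvalue(diffs, 0.04) > 0.5  # mean above X: cannot reject

    def test_single_trial_rejected(self, tstr_setup):
        train, test, schema = tstr_setup
        with pytest.raises(ValueError, match="at least 2"):
            subset_utility_test(train, train, test, schema, ["mortality"],
                                n_features=5, n_trials=1)

    def test_too_few_candidate_features_rejected(self, tstr_setup):
        train, test, schema = tstr_setup
        with pytest.raises(ValueError, match="candidate"):
            subset_utility_test(train, train, test, schema, ["mortality"],
                                n_features=30, n_trials=2)


class TestFlatten:
    def test_summaries_and_counts(self, cohort_pair):
        dataset, masks, schema = cohort_pair
        flat = flatten_features(dataset, masks, schema)
        name = schema.temporal_numeric[0]
        i = 0
        m = masks.temp_num[i, :, 0].astype(bool)
        obs = dataset.temp_num[i, :, 0][m]
        assert flat.frame.loc[i, f"{name}__count"] == m.sum()
        if m.any():
            assert flat.frame.loc[i, f"{name}__mean"] == pytest.approx(obs.mean())
            assert flat.frame.loc[i, f"{name}__last"] == obs[-1]
        assert flat.frame.loc[i, "seq_len"] == dataset.lengths[i]
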