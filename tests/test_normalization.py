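"""Frequency-proportional normalization: interval fitting, the uniform
forward map, and the exact inverse."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from synthehr.normalization import (CohortNormalizer, IntervalMap, fit_interval_map,
                                    renormalize, stochastic_normalize)


def sample_with_ratios():
    """Sample of size 10 with uniques (1,2,3) at ratios (0.1, 0.7, 0.2)."""
    return np.array([1.0] + [2.0] * 7 + [3.0] * 2)


class TestFitIntervals:
    def test_worked_example_intervals(self):
        m = fit_interval_map(sample_with_ratios())
        assert m.values.tolist() == [1.0, 2.0, 3.0]
        assert m.lowers.tolist() == [0.0, 0.1, 0.8]
        assert m.uppers.tolist() == [0.1, 0.8, 1.0]

    def test_single_unique_value_spans_unit_interval(self):
        m = fit_interval_map(np.full(5, 4.2))
        assert m.lowers.tolist() == [0.0] and m.uppers.tolist() == [1.0]

    def test_equal_counts_split_at_half(self):
        m = fit_interval_map(np.array([1.0, 5.0, 1.0, 5.0]))
        assert m.uppers.tolist() == [0.5, 1.0]

    def test_widths_equal_frequencies(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 7, size=500).astype(float)
        m = fit_interval_map(x)
        _, counts = np.unique(x, return_counts=True)
        assert np.allclose(m.uppers - m.lowers, counts / x.size, atol=1e-15)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_interval_map(np.array([np.nan, np.nan]))


class TestNormalize:
    def test_value_lands_in_its_interval(self):
        m = fit_interval_map(sample_with_ratios())
        rng = np.random.default_rng(1)
        out = stochastic_normalize(np.full(1000, 2.0), m, rng)
        assert np.all((out >= 0.1) & (out < 0.8))

    def test_unknown_value_errors_or_snaps_to_nearest(self):
        m = fit_interval_map(sample_with_ratios())
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="not present"):
            stochastic_normalize(np.array([2.6]), m, rng)
        out = stochastic_normalize(np.array([2.4, 2.6]), m, rng, on_unknown="nearest")
        assert 0.1 <= out[0] < 0.8 and 0.8 <= out[1] <= 1.0

    def test_nan_passes_through(self):
        m = fit_interval_map(sample_with_ratios())
        out = stochastic_normalize(np.array([np.nan, 2.0]), m, np.random.default_rng(0))
        assert np.isnan(out[0]) and not np.isnan(out[1])

    def test_normalized_marginal_is_uniform(self):
        """KS distance to Uniform(0,1) < 0.01 on 1e5 draws from the example law."""
        rng = np.random.default_rng(3)
        x = rng.choice([1.0, 2.0, 3.0], p=[0.1, 0.7, 0.2], size=100_000)
        m = fit_interval_map(sample_with_ratios())
        out = stochastic_normalize(x, m, rng)
        d = stats.kstest(out, "uniform").statistic
        assert d < 0.01


class TestRenormalize:
    def test_midpoint_maps_to_owner(self):
        m = fit_interval_map(sample_with_ratios())
        assert renormalize(np.array([0.5]), m)[0] == 2.0

    def test_out_of_range_clipped(self):
        m = fit_interval_map(sample_with_ratios())
        assert renormalize(np.array([1.37]), m)[0] == 3.0
        assert renormalize(np.array([-0.2]), m)[0] == 1.0

    def test_boundary_belongs_to_right_interval(self):
        m = fit_interval_map(sample_with_ratios())
        assert renormalize(np.array([0.1]), m)[0] == 2.0
        assert renormalize(np.array([0.8]), m)[0] == 3.0
        assert renormalize(np.array([1.0]), m)[0] == 3.0

    def test_inverse_of_uniform_reproduces_empirical_law(self):
        """Chi-square check: renormalized U(0,1) draws match fitted frequencies."""
        rng = np.random.default_rng(4)
        x = rng.choice([10.0, 20.0, 30.0, 40.0], p=[0.5, 0.3, 0.15, 0.05], size=2000)
        m = fit_interval_map(x)
        back = renormalize(rng.uniform(size=20_000), m)
        counts = np.array([(back == v).sum() for v in m.values])
        expected = (m.uppers - m.lowers) * back.size
        p = stats.chisquare(counts, expected).pvalue
        assert p > 1e-3


@st.composite
def observed_samples(draw):
    kind = draw(st.sampled_from(["grid", "skewed", "unique", "mixed"]))
    n = draw(st.integers(min_value=1, max_value=120))
    seed = draw(st.integers(min_value=0, max_value=2**31 - 1))
    rng = np.random.default_rng(seed)
    if kind == "grid":
        return rng.choice(np.arange(35, 80, 5.0), size=n)
    if kind == "skewed":
        return np.round(rng.lognormal(1.0, 1.2, size=n), 2)
    if kind == "unique":
        return rng.normal(size=n) + np.arange(n) * 10  # all distinct
    return np.concatenate([rng.choice([1.0, 2.0], size=n), rng.normal(size=n)])


class TestRoundTrip:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(observed_samples(), st.integers(min_value=0, max_value=2**31 - 1))
    def test_renormalize_normalize_is_identity(self, x, seed):
        m = fit_interval_map(x)
        out = renormalize(stochastic_normalize(x, m, np.random.default_rng(seed)), m)
        assert np.array_equal(out, x)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(observed_samples())
    def test_normalization_is_monotone_in_distribution(self, x):
        """Every draw for a smaller value is below every draw for a larger one."""
        m = fit_interval_map(x)
        rng = np.random.default_rng(0)
        out = stochastic_normalize(x, m, rng)
        order = np.argsort(x, kind="stable")
        xs, os = x[order], out[order]
        boundaries = np.flatnonzero(np.diff(xs) > 0)
        for b in boundaries:
            assert os[: b + 1].max() < os[b + 1:].min()


class TestCohortNormalizer:
    def test_serialization_is_bit_exact(self, tiny_cohort, tmp_path):
        dataset, masks, gt = tiny_cohort
        norm = CohortNormalizer.fit(dataset, masks, gt["schema"], seed=5)
        norm.to_json(tmp_path / "norm.json")
        back = CohortNormalizer.from_json(tmp_path / "norm.json")
        assert set(back.maps) == set(norm.maps)
        for name in norm.maps:
            for f in ("values", "lowers", "uppers"):
                a, b = getattr(norm.maps[name], f), getattr(back.maps[name], f)
                assert np.array_equal(a, b)

    def test_feature_substreams_are_order_independent(self, tiny_cohort):
        dataset, masks, gt = tiny_cohort
        norm = CohortNormalizer.fit(dataset, masks, gt["schema"], seed=5)
        a = norm.normalize_temporal(dataset.temp_num, gt["schema"])
        b = norm.normalize_temporal(dataset.temp_num, gt["schema"])
        assert np.array_equal(a, b, equal_nan=True)
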