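"""Wiener first-passage core: density, hit probability, sampler, likelihood."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import chisquare

from prioddm import _wfpt
from prioddm.errors import ConfigurationError, ParameterError
from prioddm.wiener import (
    DDMParams,
    fpt_density,
    loglik_dataset,
    sample_trial,
    sample_trials,
    upper_hit_probability,
)

PARAM_GRID = [
    DDMParams(v=1.0, a=1.5, t0=0.3),
    DDMParams(v=-0.8, a=1.0, t0=0.2),
    DDMParams(v=3.5, a=2.0, t0=0.4),
    DDMParams(v=0.0, a=0.8, t0=0.0),
]


def _total_mass(params, upper_only=False):
    hi = params.t0 + 60.0 / (params.v**2 / 2 + math.pi**2 / (2 * params.a**2)) + 1.0
    total = quad(lambda t: fpt_density(t, "upper", params), params.t0, hi, limit=300)[0]
    if upper_only:
        return total
    total += quad(lambda t: fpt_density(t, "lower", params), params.t0, hi, limit=300)[0]
    return total


class TestDensity:
    @pytest.mark.parametrize("params", PARAM_GRID)
    def test_zero_at_or_before_nondecision(self, params):
        for t in (params.t0 - 0.5, params.t0, 0.0):
            assert fpt_density(t, "upper", params) == 0.0
            assert fpt_density(t, "lower", params) == 0.0

    def test_driftless_symmetry(self):
        p = DDMParams(v=0.0, a=1.2, t0=0.3)
        for t in np.linspace(0.35, 3.0, 17):
            assert fpt_density(t, "upper", p) == pytest.approx(
                fpt_density(t, "lower", p), abs=1e-12
            )

    @pytest.mark.parametrize("params", PARAM_GRID)
    def test_normalizes_to_one(self, params):
        assert _total_mass(params) == pytest.approx(1.0, abs=1e-4)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(
        v=st.floats(-4, 4),
        a=st.floats(0.6, 3.0),
        t0=st.floats(0.0, 0.5),
    )
    def test_normalization_property(self, v, a, t0):
        assert _total_mass(DDMParams(v=v, a=a, t0=t0)) == pytest.approx(1.0, abs=1e-3)

    def test_series_agree_across_regimes(self):
        """Small- and large-time expansions agree wherever both are usable."""
        worst = 0.0
        for v in (-5.0, -1.0, 0.0, 2.0, 5.0):
            for a in (0.5, 1.5, 4.0):
                for tau in np.geomspace(0.01, 5.0, 12):
                    small = _wfpt.wfpt_pdf(tau, 1, v, a, 0.5, 0.0, 1e-7, _wfpt.MODE_SMALL)
                    large = _wfpt.wfpt_pdf(tau, 1, v, a, 0.5, 0.0, 1e-7, _wfpt.MODE_LARGE)
                    worst = max(worst, abs(small - large))
        assert worst < 1e-6

    def test_rejects_nonfinite_time(self):
        with pytest.raises(ParameterError):
            fpt_density(float("nan"), "upper", PARAM_GRID[0])

    def test_rejects_unknown_boundary(self):
        with pytest.raises(ParameterError):
            fpt_density(1.0, "top", PARAM_GRID[0])


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"v": 1.0, "a": -1.0, "t0": 0.3},
            {"v": 1.0, "a": 0.0, "t0": 0.3},
            {"v": 1.0, "a": 1.0, "t0": -0.1},
            {"v": 1.0, "a": 1.0, "t0": 0.3, "w": 0.0},
            {"v": 1.0, "a": 1.0, "t0": 0.3, "s": 0.1},
            {"v": float("inf"), "a": 1.0, "t0": 0.3},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            DDMParams(**kwargs)


class TestHitProbability:
    def test_driftless_is_half(self):
        assert upper_hit_probability(DDMParams(v=0.0, a=1.5, t0=0.3)) == 0.5

    def test_strong_drift_limit(self):
        assert upper_hit_probability(DDMParams(v=50.0, a=1.5, t0=0.3)) == pytest.approx(
            1.0, abs=1e-6
        )

    @pytest.mark.parametrize("params", PARAM_GRID[:3])
    def test_matches_density_quadrature(self, params):
        assert upper_hit_probability(params) == pytest.approx(
            _total_mass(params, upper_only=True), abs=1e-4
        )

    def test_strictly_increasing_in_drift(self):
        probs = [
            upper_hit_probability(DDMParams(v=v, a=1.5, t0=0.3))
            for v in np.linspace(-3, 3, 25)
        ]
        assert np.all(np.diff(probs) > 0)


class TestSampler:
    def test_deterministic_under_seed(self):
        p = PARAM_GRID[0]
        c1, r1 = sample_trials(p, 200, np.random.default_rng(5))
        c2, r2 = sample_trials(p, 200, np.random.default_rng(5))
        assert np.array_equal(c1, c2) and np.array_equal(r1, r2)
        out1 = sample_trial(p, np.random.default_rng(5))
        out2 = sample_trial(p, np.random.default_rng(5))
        assert out1 == out2
        assert out1.boundary in ("upper", "lower")

    def test_driftless_hit_rate(self):
        p = DDMParams(v=0.0, a=1.0, t0=0.3)
        corr, _ = sample_trials(p, 50_000, np.random.default_rng(8))
        se = math.sqrt(0.25 / 50_000)
        assert abs(corr.mean() - 0.5) < 3 * se

    def test_hit_rate_matches_closed_form(self):
        p = DDMParams(v=1.0, a=1.5, t0=0.3)
        corr, _ = sample_trials(p, 50_000, np.random.default_rng(9))
        pu = upper_hit_probability(p)
        se = math.sqrt(pu * (1 - pu) / 50_000)
        assert abs(corr.mean() - pu) < 3 * se

    def test_mean_rt_matches_quadrature(self):
        p = DDMParams(v=2.0, a=1.2, t0=0.35)
        corr, rt = sample_trials(p, 50_000, np.random.default_rng(10))
        x = rt[corr]
        mass = quad(lambda t: fpt_density(t, "upper", p), p.t0, 30, limit=300)[0]
        mean = quad(lambda t: t * fpt_density(t, "upper", p), p.t0, 30, limit=300)[0] / mass
        assert abs(x.mean() - mean) < 3 * x.std(ddof=1) / math.sqrt(x.size)

    def test_rt_distribution_ks_and_chisquare(self):
        """Sampled RTs match the analytic conditional law (KS and GOF)."""
        p = DDMParams(v=1.0, a=1.5, t0=0.3)
        corr, rt = sample_trials(p, 50_000, np.random.default_rng(11))
        x = np.sort(rt[corr])
        ts = np.linspace(p.t0, 40.0, 200_001)
        pdf = _wfpt.pdf_grid(ts - p.t0, 1, p.v, p.a, p.w)
        cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) * np.diff(ts) / 2)])
        cdf /= cdf[-1]
        F = np.interp(x, ts, cdf)
        n = x.size
        ks = max(
            np.max(np.abs(F - np.arange(1, n + 1) / n)),
            np.max(np.abs(F - np.arange(n) / n)),
        )
        assert ks < 0.01
        # 20 equal-probability bins from the analytic CDF
        edges = np.interp(np.linspace(0, 1, 21), cdf, ts)
        counts, _ = np.histogram(x, bins=edges)
        stat, pval = chisquare(counts)
        assert pval > 0.01


class TestLoglik:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["prioritization", "probe_position", "correct", "rt_s"]
        )

    def test_empty_is_zero(self):
        table = self._table([])
        assert loglik_dataset(table, {}) == 0.0

    def test_single_trial_matches_density(self):
        p = DDMParams(v=1.0, a=1.5, t0=0.3)
        table = self._table([("control", 1, 1, 0.8)])
        expected = math.log(fpt_density(0.8, "upper", p))
        assert loglik_dataset(table, {("control", 1): p}) == pytest.approx(expected, rel=1e-12)

    def test_sum_over_trials_matches_per_trial_oracle(self):
        rng = np.random.default_rng(2)
        mapping = {
            ("control", 1): DDMParams(v=0.8, a=1.4, t0=0.25),
            ("first", 2): DDMParams(v=2.0, a=1.1, t0=0.35),
        }
        rows = []
        expected = 0.0
        for _ in range(10):
            cond = ("control", 1) if rng.random() < 0.5 else ("first", 2)
            correct = int(rng.random() < 0.7)
            rt = float(rng.uniform(0.4, 1.8))
            rows.append((cond[0], cond[1], correct, rt))
            expected += math.log(
                fpt_density(rt, "upper" if correct else "lower", mapping[cond])
            )
        assert loglik_dataset(self._table(rows), mapping) == pytest.approx(expected, rel=1e-12)

    def test_unmapped_condition_raises(self):
        table = self._table([("middle", 3, 1, 0.9)])
        with pytest.raises(ConfigurationError):
            loglik_dataset(table, {("control", 1): PARAM_GRID[0]})

    def test_rt_below_nondecision_is_floored(self):
        p = DDMParams(v=1.0, a=1.5, t0=0.5)
        table = self._table([("control", 1, 1, 0.4)])
        assert loglik_dataset(table, {("control", 1): p}) == pytest.approx(-700.0)
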