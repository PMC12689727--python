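"""BPIC arithmetic, model ranking, posterior predictive checks."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from prioddm import _mcmc
from prioddm.design import DesignConfig, generate_design
from prioddm.errors import ConfigurationError, ParameterError
from prioddm.hfit import ChainConfig, Posterior, PriorSpec, build_trial_arrays
from prioddm.models import build_spec
from prioddm.selection import (
    FitResult,
    PPCResult,
    bpic,
    bpic_from_deviance,
    compare_models,
    dic,
    evaluate_fit,
    observed_cell_summaries,
    ppc_simulate,
)


class TestBPICArithmetic:
    def test_conjugate_normal_toy_model(self):
        """Closed-form moments of a normal-mean posterior reproduce BPIC exactly.

        For y_i ~ N(theta, 1) the deviance is D(theta) = C + sum (y_i - theta)^2,
        so over any draw set {theta_d}: Dbar = D(theta_bar) + n * var(theta_d),
        hence pD = n var and BPIC = D(theta_bar) + 3 n var.
        """
        rng = np.random.default_rng(0)
        y = rng.normal(1.0, 1.0, 12)
        n = y.size
        draws = rng.normal(y.mean(), 1 / np.sqrt(n), 4000)
        const = n * np.log(2 * np.pi)
        dev = np.array([const + np.sum((y - th) ** 2) for th in draws])
        th_bar = draws.mean()
        d_hat = const + np.sum((y - th_bar) ** 2)
        got_bpic, got_dic, got_pd = bpic_from_deviance(dev, d_hat)
        var = draws.var()
        assert got_pd == pytest.approx(n * var, abs=1e-6)
        assert got_bpic == pytest.approx(d_hat + 3 * n * var, abs=1e-6)
        assert got_dic == pytest.approx(d_hat + 2 * n * var, abs=1e-6)

    def test_point_mass_posterior_has_zero_complexity(self, small_data):
        """A degenerate posterior gives pD = 0 and BPIC = D(theta_bar)."""
        spec = build_spec(4)
        subjects, rt, up, sidx, vix, aix, tix, _, _ = build_trial_arrays(small_data, spec)
        S, P = len(subjects), spec.n_params
        theta0 = np.zeros((S, P))
        theta0[:, : spec.n_v] = 1.0
        theta0[:, spec.n_v :] = np.log(0.4)
        theta0[:, spec.n_v : spec.n_v + spec.n_a] = np.log(1.5)
        d0 = float(_mcmc.deviance_per_draw(rt, up, sidx, vix, aix, tix, theta0[None])[0])
        K = 50
        post = Posterior(
            spec=spec,
            subjects=subjects,
            mu=np.zeros((2, K, P)),
            sigma=np.full((2, K, P), 0.1),
            theta=np.broadcast_to(theta0, (2, K, S, P)).copy(),
            deviance=np.full((2, K), d0),
            config=ChainConfig(n_chains=2, n_iter=K + 1, burn_in=1),
            priors=PriorSpec(),
            data_hash="x",
        )
        assert bpic(post, small_data) == pytest.approx(d0, abs=1e-8)
        assert dic(post, small_data) == pytest.approx(d0, abs=1e-8)

    def test_bpic_penalty_dominates_dic(self, small_fit, small_data):
        result = evaluate_fit(small_fit, small_data)
        assert result.p_d > 0
        assert result.bpic >= result.dic


def _stub_fit(model_id, bpic_value, data_hash="h"):
    spec = build_spec(model_id)
    return FitResult(
        spec=spec,
        posterior=SimpleNamespace(data_hash=data_hash, spec=spec),
        deviance_trace=np.array([bpic_value]),
        bpic=bpic_value,
        dic=bpic_value - 1,
        p_d=1.0,
        d_bar=bpic_value - 2,
        summaries=pd.DataFrame(),
    )


class TestCompareModels:
    def test_differences_from_best(self):
        fits = [_stub_fit(1, 100.0), _stub_fit(3, 95.0), _stub_fit(7, 97.0)]
        out = compare_models(fits)
        assert out["model_id"].tolist() == [3, 7, 1]
        assert out["bpic_diff"].tolist() == [0.0, 2.0, 5.0]
        assert bool(out["winner"].iloc[0]) and not out["winner"].iloc[1:].any()

    def test_permutation_invariant(self):
        fits = [_stub_fit(1, 100.0), _stub_fit(3, 95.0), _stub_fit(7, 97.0)]
        a = compare_models(fits)
        b = compare_models(fits[::-1])
        pd.testing.assert_frame_equal(a, b)

    def test_tie_broken_by_fewer_parameters_and_flagged(self):
        fits = [_stub_fit(7, 100.0), _stub_fit(4, 100.0)]  # 19 vs 11 params
        out = compare_models(fits)
        assert out["model_id"].iloc[0] == 4
        assert out["tie"].sum() == 2

    def test_mismatched_data_rejected(self):
        fits = [_stub_fit(1, 100.0, "h1"), _stub_fit(3, 95.0, "h2")]
        with pytest.raises(ConfigurationError):
            compare_models(fits)

    def test_needs_two_fits(self):
        with pytest.raises(ConfigurationError):
            compare_models([_stub_fit(1, 100.0)])


@pytest.fixture(scope="module")
def small_design():
    cfg = DesignConfig(n_subjects=3, n_sessions=1, trials_per_session=120, seed=7)
    return generate_design(cfg)


class TestPPC:
    def test_single_draw_deterministic(self, small_fit, small_design):
        a = ppc_simulate(small_fit, small_design, n_draws=1, seed=9)
        b = ppc_simulate(small_fit, small_design, n_draws=1, seed=9)
        pd.testing.assert_frame_equal(a.draws, b.draws)
        assert isinstance(a, PPCResult)
        assert len(a.draws) == 12  # one summary row per design cell

    def test_draw_count_validated(self, small_fit, small_design):
        with pytest.raises(ParameterError):
            ppc_simulate(small_fit, small_design, n_draws=10**9)

    def test_unknown_subject_rejected(self, small_fit, small_design):
        bad = small_design.assign(subject_id="zz")
        with pytest.raises(ConfigurationError):
            ppc_simulate(small_fit, bad, n_draws=1)

    def test_intervals_widen_with_posterior_dispersion(self, small_fit, small_design):
        base = ppc_simulate(small_fit, small_design, n_draws=20, seed=1)
        th = small_fit.theta
        inflated = Posterior(
            spec=small_fit.spec,
            subjects=small_fit.subjects,
            mu=small_fit.mu,
            sigma=small_fit.sigma,
            theta=th.mean(axis=(0, 1), keepdims=True) + 3.0 * (th - th.mean(axis=(0, 1), keepdims=True)),
            deviance=small_fit.deviance,
            config=small_fit.config,
            priors=small_fit.priors,
            data_hash=small_fit.data_hash,
        )
        wide = ppc_simulate(inflated, small_design, n_draws=20, seed=1)
        width = lambda r: (r.intervals["accuracy_hi"] - r.intervals["accuracy_lo"]).mean()
        assert width(wide) > width(base)

    def test_self_consistency_coverage(self, small_fit, small_data):
        """Data from the fitted model itself sit inside the predictive intervals."""
        # larger design so per-cell sampling noise is small next to parameter noise
        cfg = DesignConfig(n_subjects=3, n_sessions=1, trials_per_session=408, seed=13)
        design = generate_design(cfg)
        sid_map = dict(zip(sorted(design["subject_id"].unique()), small_fit.subjects))
        design = design.assign(subject_id=design["subject_id"].map(sid_map))
        # "observed" data: one dataset simulated at the posterior mean
        at_mean = Posterior(
            spec=small_fit.spec,
            subjects=small_fit.subjects,
            mu=small_fit.mu,
            sigma=small_fit.sigma,
            theta=small_fit.theta.mean(axis=(0, 1), keepdims=True).repeat(2, 0),
            deviance=small_fit.deviance,
            config=small_fit.config,
            priors=small_fit.priors,
            data_hash=small_fit.data_hash,
        )
        obs = ppc_simulate(at_mean, design, n_draws=1, seed=99).draws.drop(columns="draw")
        ppc = ppc_simulate(small_fit, design, n_draws=60, seed=2)
        merged = obs.merge(ppc.intervals, on=["prioritization", "probe_position"])
        checks, inside = 0, 0
        for stat in ("accuracy", "mean_rt_correct"):
            ok = (merged[stat] >= merged[f"{stat}_lo"]) & (merged[stat] <= merged[f"{stat}_hi"])
            checks += len(ok)
            inside += ok.sum()
        assert inside / checks >= 0.95

    def test_empty_error_cells_marked_unavailable(self, small_fit, small_design):
        """Cells that produce no errors get NaN error quantiles, not imputed values."""
        boosted = Posterior(
            spec=small_fit.spec,
            subjects=small_fit.subjects,
            mu=small_fit.mu,
            sigma=small_fit.sigma,
            theta=small_fit.theta + np.where(np.arange(small_fit.spec.n_params) < small_fit.spec.n_v, 8.0, 0.0),
            deviance=small_fit.deviance,
            config=small_fit.config,
            priors=small_fit.priors,
            data_hash=small_fit.data_hash,
        )
        out = ppc_simulate(boosted, small_design, n_draws=1, seed=0)
        assert out.draws["q50_error"].isna().all()
        assert out.draws["accuracy"].min() > 0.99
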