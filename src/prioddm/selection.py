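"""Model comparison by BPIC and posterior predictive checking.

With D(theta) = -2 log p(data | theta) evaluated at the subject-level
parameters of each retained draw, the criteria are

    Dbar = E[D(theta)]           (posterior mean deviance)
    pD   = Dbar - D(theta_bar)   (effective number of parameters)
    DIC  = Dbar + pD
    BPIC = Dbar + 2 pD

i.e. BPIC doubles DIC's complexity penalty; lower is better.
``theta_bar`` is the posterior mean of each parameter on its sampling
scale (log scale for boundary and non-decision time), transformed back
before evaluating the likelihood.  The deviance includes the
subject-level Wiener likelihood only; group-level densities are
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _mcmc
from .design import simulate_dataset, GroundTruth
from .errors import ConfigurationError, DiagnosticError, ParameterError
from .hfit import Posterior, build_trial_arrays, posterior_summary
from .models import ALL_CONDITIONS, ModelSpec
from .wiener import DDMParams, sample_trials

__all__ = [
    "FitResult",
    "bpic",
    "dic",
    "bpic_from_deviance",
    "evaluate_fit",
    "compare_models",
    "ppc_simulate",
    "PPCResult",
]

RT_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass
class FitResult:
    """A fitted model bundled with its deviance trace and criteria."""

    spec: ModelSpec
    posterior: Posterior
    deviance_trace: np.ndarray
    bpic: float
    dic: float
    p_d: float
    d_bar: float
    summaries: pd.DataFrame = field(repr=False)


def bpic_from_deviance(dev_trace: np.ndarray, dev_at_mean: float) -> tuple[float, float, float]:
    """(BPIC, DIC, pD) from a deviance trace and D at the posterior mean."""
    dev_trace = np.asarray(dev_trace, dtype=float)
    d_bar = float(dev_trace.mean())
    p_d = d_bar - float(dev_at_mean)
    return d_bar + 2.0 * p_d, d_bar + p_d, p_d


def _deviance_at_theta_bar(posterior: Posterior, table: pd.DataFrame) -> float:
    _, rt, up, sidx, vix, aix, tix, _, _ = build_trial_arrays(table, posterior.spec)
    theta_bar = posterior.theta_bar()[None, :, :]
    return float(_mcmc.deviance_per_draw(rt, up, sidx, vix, aix, tix, theta_bar)[0])


def bpic(posterior: Posterior, table: pd.DataFrame, spec: ModelSpec | None = None) -> float:
    """Bayesian Predictive Information Criterion of one fit."""
    return _criteria(posterior, table)[0]


def dic(posterior: Posterior, table: pd.DataFrame) -> float:
    """Deviance Information Criterion of one fit."""
    return _criteria(posterior, table)[1]


def _criteria(posterior: Posterior, table: pd.DataFrame) -> tuple[float, float, float, float]:
    dev = posterior.deviance.reshape(-1)
    if not np.isfinite(dev).all():
        bad = (~np.isfinite(dev)).mean()
        if bad > 0.01:
            raise DiagnosticError(f"{bad:.1%} of deviance draws are non-finite")
        dev = dev[np.isfinite(dev)]
    d_hat = _deviance_at_theta_bar(posterior, table)
    b, d, p_d = bpic_from_deviance(dev, d_hat)
    return b, d, p_d, float(dev.mean())


def evaluate_fit(posterior: Posterior, table: pd.DataFrame) -> FitResult:
    """Package a posterior with its deviance-based criteria and summaries."""
    b, d, p_d, d_bar = _criteria(posterior, table)
    return FitResult(
        spec=posterior.spec,
        posterior=posterior,
        deviance_trace=posterior.deviance.reshape(-1),
        bpic=b,
        dic=d,
        p_d=p_d,
        d_bar=d_bar,
        summaries=posterior_summary(posterior),
    )


def compare_models(fits: list[FitResult]) -> pd.DataFrame:
    """Rank fitted models by BPIC (ascending); ties favour fewer parameters.

    All fits must be on the same data (checked via the posterior's data
    hash).  The returned table mirrors the published comparison layout:
    model id, description, free-parameter counts, BPIC and the
    difference from the best model.
    """
    if len(fits) < 2:
        raise ConfigurationError("model comparison needs at least 2 fits")
    hashes = {f.posterior.data_hash for f in fits}
    if len(hashes) > 1:
        raise ConfigurationError("fits were computed on different datasets")
    rows = [
        {
            "model_id": f.spec.model_id,
            "description": f.spec.description,
            "n_v": f.spec.n_v,
            "n_a": f.spec.n_a,
            "n_t": f.spec.n_t,
            "n_params": f.spec.n_params,
            "bpic": f.bpic,
            "dic": f.dic,
            "p_d": f.p_d,
        }
        for f in fits
    ]
    out = pd.DataFrame(rows).sort_values(
        ["bpic", "n_params", "model_id"], kind="stable"
    ).reset_index(drop=True)
    best = out["bpic"].iloc[0]
    out["bpic_diff"] = out["bpic"] - best
    out["winner"] = False
    out.loc[0, "winner"] = True
    out["tie"] = out["bpic"] == best
    return out


@dataclass
class PPCResult:
    """Draw-wise posterior predictive summaries plus central intervals."""

    draws: pd.DataFrame
    intervals: pd.DataFrame


def _cell_summaries(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell accuracy, mean RT by correctness, and RT quantiles."""
    rows = []
    for (prio, probe), g in table.groupby(["prioritization", "probe_position"], observed=True):
        corr = g[g["correct"] == 1]["rt_s"].to_numpy()
        err = g[g["correct"] == 0]["rt_s"].to_numpy()
        row = {
            "prioritization": prio,
            "probe_position": probe,
            "accuracy": g["correct"].mean(),
            "mean_rt_correct": corr.mean() if corr.size else np.nan,
            "mean_rt_error": err.mean() if err.size else np.nan,
        }
        for q in RT_QUANTILES:
            row[f"q{int(q * 100)}_correct"] = np.quantile(corr, q) if corr.size else np.nan
            # cells with no simulated errors: quantiles left unavailable
            row[f"q{int(q * 100)}_error"] = np.quantile(err, q) if err.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def ppc_simulate(
    fit: FitResult | Posterior,
    design: pd.DataFrame,
    n_draws: int = 100,
    seed: int = 0,
    response_window: float | None = None,
) -> PPCResult:
    """Simulate datasets from posterior draws and summarize them per cell.

    For each of ``n_draws`` evenly spaced retained draws, the
    subject-level parameters simulate a complete dataset on ``design``
    (no guessing process), and per-cell accuracy, mean correct/error RT
    and RT quantiles are recorded.  ``intervals`` holds the central 95%
    predictive interval of every statistic.  Set ``response_window`` to
    truncate simulated RTs the way the task's response deadline does.
    """
    posterior = fit.posterior if isinstance(fit, FitResult) else fit
    total = posterior.n_draws
    if not 1 <= n_draws <= total:
        raise ParameterError(f"n_draws must be in 1..{total}, got {n_draws}")
    subj_draws = posterior.subject_draws_natural()
    idx = np.linspace(0, total - 1, n_draws).astype(int)
    subjects = posterior.subjects
    design_subjects = list(dict.fromkeys(design["subject_id"]))
    if set(design_subjects) - set(subjects):
        raise ConfigurationError("design contains subjects absent from the fit")
    rng = np.random.default_rng(seed)
    spec = posterior.spec
    all_rows = []
    for d_i, draw in enumerate(idx):
        theta = subj_draws[draw]
        sim = design.copy()
        sim["correct"] = 0
        sim["rt_s"] = 0.0
        c_col = sim.columns.get_loc("correct")
        r_col = sim.columns.get_loc("rt_s")
        for sid in design_subjects:
            si = subjects.index(sid)
            smask = (design["subject_id"] == sid).to_numpy()
            for cond in ALL_CONDITIONS:
                cmask = (
                    smask
                    & (design["prioritization"] == cond.prioritization).to_numpy()
                    & (design["probe_position"] == cond.probe_position).to_numpy()
                )
                n = int(cmask.sum())
                if n == 0:
                    continue
                params = spec.resolve(cond, theta[si])
                corr, rt = sample_trials(params, n, rng)
                if response_window is not None:
                    for _ in range(1000):
                        over = rt > response_window
                        if not over.any():
                            break
                        c2, r2 = sample_trials(params, int(over.sum()), rng)
                        corr[over], rt[over] = c2, r2
                pos = np.flatnonzero(cmask)
                sim.iloc[pos, c_col] = corr.astype(int)
                sim.iloc[pos, r_col] = rt
        cs = _cell_summaries(sim)
        cs.insert(0, "draw", d_i)
        all_rows.append(cs)
    draws = pd.concat(all_rows, ignore_index=True)
    stats = [c for c in draws.columns if c not in ("draw", "prioritization", "probe_position")]
    intervals = (
        draws.groupby(["prioritization", "probe_position"], observed=True)[stats]
        .agg(["mean", lambda x: x.quantile(0.025), lambda x: x.quantile(0.975)])
        .reset_index()
    )
    intervals.columns = [
        c[0] if c[1] == "" else f"{c[0]}_{ {'mean': 'mean', '<lambda_0>': 'lo', '<lambda_1>': 'hi'}[c[1]] }"
        for c in intervals.columns
    ]
    return PPCResult(draws=draws, intervals=intervals)


def observed_cell_summaries(table: pd.DataFrame) -> pd.DataFrame:
    """Observed-data counterpart of the PPC per-cell summaries."""
    return _cell_summaries(table)
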