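"""Two-boundary Wiener diffusion core.

This module provides the exact first-passage machinery for the plain
drift-diffusion model (DDM) used throughout the package: the defective
first-passage-time (FPT) density for either boundary, the closed-form
probability of absorption at the upper boundary, an exact sampler, and
the trial-table log-likelihood.

Conventions
-----------
* **Accuracy coding**: the upper boundary is the *correct* response and
  the lower boundary the *error*, everywhere.  There is no stimulus-side
  (left/right) coding and no start-point bias: the relative start point
  ``w`` is fixed at 0.5.
* **Diffusion scale**: the within-trial noise scale ``s`` is fixed at
  1.0.  Drift rates and boundary separations are only identified up to
  this convention — divide published values estimated under ``s = 0.1``
  by 10 before comparing.
* Inter-trial variability parameters (sv, st, sz) are not part of the
  model: each trial is an i.i.d. draw from the same diffusion given its
  condition's parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from . import _wfpt
from .errors import ConfigurationError, ParameterError

__all__ = [
    "DDMParams",
    "TrialOutcome",
    "fpt_density",
    "upper_hit_probability",
    "sample_trial",
    "sample_trials",
    "loglik_dataset",
]


@dataclass(frozen=True)
class DDMParams:
    """Parameters of one plain diffusion process.

    v : drift rate (evidence units / s, signed; positive drifts toward
        the correct boundary)
    a : boundary separation (evidence units, > 0)
    t0 : non-decision time (s, >= 0)
    w : relative start point as a fraction of ``a``; fixed at 0.5 and
        never estimated
    s : diffusion scale; fixed at 1.0
    """

    v: float
    a: float
    t0: float
    w: float = 0.5
    s: float = 1.0

    def __post_init__(self) -> None:
        for name in ("v", "a", "t0", "w", "s"):
            x = getattr(self, name)
            if not math.isfinite(x):
                raise ParameterError(f"{name} must be finite, got {x!r}")
        if self.a <= 0:
            raise ParameterError(f"boundary separation a must be > 0, got {self.a}")
        if self.t0 < 0:
            raise ParameterError(f"non-decision time t0 must be >= 0, got {self.t0}")
        if not 0 < self.w < 1:
            raise ParameterError(f"start point w must lie in (0, 1), got {self.w}")
        if self.s != 1.0:
            raise ParameterError("diffusion scale s is fixed at 1.0 in this package")


class TrialOutcome(NamedTuple):
    """Outcome of one simulated trial under accuracy coding."""

    correct: bool
    rt: float

    @property
    def boundary(self) -> str:
        return "upper" if self.correct else "lower"


def _check_boundary(boundary: str) -> int:
    if boundary == "upper":
        return 1
    if boundary == "lower":
        return 0
    raise ParameterError(f"boundary must be 'upper' or 'lower', got {boundary!r}")


def fpt_density(t: float, boundary: str, params: DDMParams) -> float:
    """Defective first-passage density of hitting ``boundary`` at time ``t``.

    Evaluated with small-time and large-time series expansions, switching
    automatically to whichever needs fewer terms, truncated for an
    absolute error below 1e-7.  Returns 0 for any ``t <= t0``.
    """
    if not math.isfinite(t):
        raise ParameterError(f"t must be finite, got {t!r}")
    up = _check_boundary(boundary)
    return float(
        _wfpt.wfpt_pdf(t, up, params.v, params.a, params.w, params.t0, 1e-7, _wfpt.MODE_AUTO)
    )


def upper_hit_probability(params: DDMParams) -> float:
    """Probability of absorption at the upper (correct) boundary.

    P(upper) = (1 - exp(-2 v a w)) / (1 - exp(-2 v a)), with the
    driftless limit handled analytically as ``w``.
    """
    v, a, w = params.v, params.a, params.w
    x = 2.0 * v * a
    if abs(x) < 1e-10:
        return float(w)
    return float(np.expm1(-x * w) / np.expm1(-x))


def _decision_time_grid(params: DDMParams, n_grid: int) -> np.ndarray:
    # slowest spectral decay rate sets the usable horizon
    lam1 = params.v**2 / 2.0 + math.pi**2 / (2.0 * params.a**2)
    t_max = 32.0 / lam1
    frac = np.linspace(0.0, 1.0, n_grid)
    return t_max * frac**2  # dense near zero where the density rises steeply


def _conditional_cdf(params: DDMParams, upper: int, n_grid: int):
    taus = _decision_time_grid(params, n_grid)
    pdf = _wfpt.pdf_grid(taus, upper, params.v, params.a, params.w)
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) * np.diff(taus) / 2.0)])
    total = cdf[-1]
    if total <= 0:
        raise ParameterError(
            "degenerate first-passage distribution; check DDM parameters"
        )
    cdf = cdf / total
    # strictly-increasing ramp so inverse interpolation is well defined
    cdf = cdf + np.linspace(0.0, 1e-12, n_grid)
    return taus, cdf / cdf[-1]


def sample_trials(
    params: DDMParams,
    n: int,
    rng: np.random.Generator,
    n_grid: int = 4096,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` trials from the exact joint FPT law.

    Returns ``(correct, rt)`` arrays.  The boundary is drawn from the
    closed-form hit probability; the conditional decision time by
    inverse transform on a dense tabulated CDF of the series density.
    """
    if n < 0:
        raise ParameterError(f"n must be >= 0, got {n}")
    p_up = upper_hit_probability(params)
    correct = rng.random(n) < p_up
    rt = np.empty(n)
    for up in (1, 0):
        mask = correct == bool(up)
        m = int(mask.sum())
        if m == 0:
            continue
        taus, cdf = _conditional_cdf(params, up, n_grid)
        u = rng.random(m)
        rt[mask] = params.t0 + np.interp(u, cdf, taus)
    return correct, rt


def sample_trial(params: DDMParams, rng: np.random.Generator) -> TrialOutcome:
    """Draw a single trial; see :func:`sample_trials`."""
    correct, rt = sample_trials(params, 1, rng)
    return TrialOutcome(bool(correct[0]), float(rt[0]))


def loglik_dataset(
    trials: pd.DataFrame,
    mapping: Mapping[object, DDMParams],
) -> float:
    """Log-likelihood of a trial table under a condition -> params mapping.

    ``trials`` must carry columns ``prioritization``, ``probe_position``,
    ``correct`` and ``rt_s``; the mapping is keyed by
    :class:`~prioddm.models.TrialCondition` (or any equal tuple).  Trials
    whose density underflows (including rt <= t0) contribute a floored
    log-density of -700 rather than -inf, keeping MCMC proposals
    comparable.
    """
    n = len(trials)
    if n == 0:
        return 0.0
    rts = np.asarray(trials["rt_s"], dtype=np.float64)
    if np.any(rts <= 0):
        raise ParameterError("all RTs must be > 0")
    upper = np.asarray(trials["correct"], dtype=np.uint8)
    v = np.empty(n)
    a = np.empty(n)
    t0 = np.empty(n)
    conds = list(zip(trials["prioritization"], trials["probe_position"]))
    cache: dict[object, DDMParams] = {}
    for i, cond in enumerate(conds):
        p = cache.get(cond)
        if p is None:
            try:
                p = mapping[cond]
            except KeyError as exc:
                raise ConfigurationError(f"no parameters mapped for condition {cond!r}") from exc
            cache[cond] = p
        v[i], a[i], t0[i] = p.v, p.a, p.t0
    return float(_wfpt.loglik_trials(rts, upper, v, a, t0))
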