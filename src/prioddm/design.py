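"""Synthetic-data generator emulating the 2AFC prioritization task.

The design it reproduces: each subject completes 3 sessions of 408
trials of a three-item visual working-memory task.  On 75% of trials one
list position (first / middle / last, equiprobable) is prioritized by a
reward cue; the remaining 25% are control trials.  Each serial position
is equally likely to be probed, independently of the prioritization, and
the 2AFC probe screen allows 2.5 s to respond.  With the defaults this
gives 1,224 trials per subject and 102 trials in each of the 12
(prioritization x probe position) cells.

Data are simulated from a condition-mapped diffusion process: each
subject's parameter vector is drawn around group-level means (drift on
the natural scale, boundary and non-decision time on the log scale to
respect positivity), each trial is an exact draw from the Wiener
first-passage law of its cell's parameters, and an optional guessing
contaminant replaces a trial with a coin-flip response at a
condition-invariant uniform RT — the lapse process the fitted DDM does
not model.  RTs beyond the response window are resampled (truncation),
which keeps cell counts balanced; real omitted trials would simply be
missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .models import (
    ALL_CONDITIONS,
    PRIORITIZATIONS,
    PROBE_POSITIONS,
    ModelSpec,
    TrialCondition,
)
from .wiener import DDMParams, sample_trials

__all__ = [
    "DesignConfig",
    "GroundTruth",
    "generate_design",
    "simulate_dataset",
    "subject_params",
    "write_trials",
    "read_trials",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = ["subject_id", "session", "prioritization", "probe_position", "correct", "rt_s"]


@dataclass(frozen=True)
class DesignConfig:
    """Experimental design settings (defaults mirror the study protocol)."""

    n_subjects: int
    n_sessions: int = 3
    trials_per_session: int = 408
    p_reward_trial: float = 0.75
    response_window: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_sessions < 1 or self.trials_per_session < 1:
            raise ParameterError("counts must be positive")
        if not 0.0 <= self.p_reward_trial <= 1.0:
            raise ParameterError("p_reward_trial must lie in [0, 1]")
        if self.response_window <= 0:
            raise ParameterError("response_window must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """Generating group-level parameters for one model specification.

    ``group_means`` holds natural-scale group means in the spec's flat
    order (v slots, a slots, t slots).  ``group_sds`` are between-subject
    SDs on each parameter's *sampling* scale: natural for drift, log for
    boundary and non-decision time.
    """

    spec: ModelSpec
    group_means: np.ndarray
    group_sds: np.ndarray
    guess_rate: float = 0.0
    guess_rt_range: tuple[float, float] = (0.3, 2.5)

    def __post_init__(self) -> None:
        means = np.asarray(self.group_means, dtype=float)
        sds = np.asarray(self.group_sds, dtype=float)
        object.__setattr__(self, "group_means", means)
        object.__setattr__(self, "group_sds", sds)
        p = self.spec.n_params
        if means.shape != (p,) or sds.shape != (p,):
            raise ParameterError(f"group_means/group_sds must have length {p}")
        if np.any(sds < 0):
            raise ParameterError("group_sds must be >= 0")
        if np.any(means[self.spec.n_v :] <= 0):
            raise ParameterError("boundary and non-decision means must be > 0")
        if not 0.0 <= self.guess_rate <= 1.0:
            raise ParameterError("guess_rate must lie in [0, 1]")
        lo, hi = self.guess_rt_range
        if not 0 < lo < hi:
            raise ParameterError("guess_rt_range must satisfy 0 < lo < hi")


def recovery_truth(guess_rate: float = 0.0) -> GroundTruth:
    """Canonical generating truth for recovery studies (winning model 7).

    The group means encode the resource-tradeoff-with-distinct-recency
    pattern this task elicits: modest drift for early positions (~1.1 at
    baseline, boosted to ~1.5-1.9 when prioritized), a strong recency
    advantage at serial position 3 (3.38 control, 4.01 prioritized) that
    is markedly diminished (2.18) when another item is prioritized, and
    non-decision times around 0.36-0.47 s that are fastest for the
    recent item.  Boundary separation is 1.5 evidence units (typical for
    a 2AFC task under the unit diffusion-scale convention).
    Between-subject SDs: 0.3 on drift, 0.15 / 0.10 on log boundary and
    log non-decision time.
    """
    from .models import build_spec

    spec = build_spec(7)
    v = [1.10, 1.52, 1.05, 1.28, 1.85, 1.15, 3.38, 4.01, 2.18]
    a = [1.5]
    t = [0.45, 0.40, 0.47, 0.43, 0.38, 0.44, 0.36, 0.36, 0.36]
    sds = [0.3] * 9 + [0.15] + [0.10] * 9
    return GroundTruth(
        spec=spec,
        group_means=np.array(v + a + t),
        group_sds=np.array(sds),
        guess_rate=guess_rate,
    )


def _split_balanced(n: int, k: int) -> np.ndarray:
    base, rem = divmod(n, k)
    out = np.full(k, base, dtype=int)
    out[:rem] += 1
    return out


def _session_cells(cfg: DesignConfig) -> list[tuple[str, int]]:
    """Per-session list of (prioritization, probe) cell labels, stratified."""
    t = cfg.trials_per_session
    n_reward = int(round(t * cfg.p_reward_trial))
    prio_counts = dict(zip(("first", "middle", "last"), _split_balanced(n_reward, 3)))
    prio_counts["control"] = t - n_reward
    cells: list[tuple[str, int]] = []
    for prio in PRIORITIZATIONS:
        per_probe = _split_balanced(prio_counts[prio], 3)
        for probe, c in zip(PROBE_POSITIONS, per_probe):
            cells.extend([(prio, probe)] * c)
    return cells


def generate_design(cfg: DesignConfig) -> pd.DataFrame:
    """Trial conditions with subject and session labels.

    Cell counts are exactly stratified (102 per design cell per subject
    at the defaults); trial order is shuffled independently per subject
    and session from ``cfg.seed``.
    """
    if cfg.trials_per_session % 12 != 0:
        warnings.warn(
            f"trials_per_session={cfg.trials_per_session} is not divisible by 12; "
            "using the nearest balanced cell assignment",
            stacklevel=2,
        )
    rng = np.random.default_rng(cfg.seed)
    cells = _session_cells(cfg)
    width = max(2, len(str(cfg.n_subjects)))
    rows = []
    for s in range(cfg.n_subjects):
        sid = f"s{s + 1:0{width}d}"
        for sess in range(1, cfg.n_sessions + 1):
            order = rng.permutation(len(cells))
            for i in order:
                prio, probe = cells[i]
                rows.append((sid, sess, prio, probe))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS[:4])


def subject_params(
    truth: GroundTruth, n_subjects: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-subject natural-scale parameter vectors (n_subjects, n_params)."""
    spec = truth.spec
    n_v = spec.n_v
    p = spec.n_params
    out = np.empty((n_subjects, p))
    # drift: natural scale; boundary & t0: lognormal around the group mean
    out[:, :n_v] = rng.normal(truth.group_means[:n_v], truth.group_sds[:n_v], (n_subjects, n_v))
    log_mu = np.log(truth.group_means[n_v:])
    out[:, n_v:] = np.exp(rng.normal(log_mu, truth.group_sds[n_v:], (n_subjects, p - n_v)))
    return out


def simulate_dataset(
    design: pd.DataFrame,
    truth: GroundTruth,
    rng: np.random.Generator,
    response_window: float = 2.5,
) -> pd.DataFrame:
    """Simulate choices and RTs for every trial of ``design``.

    Subjects are drawn around the group truth, then each trial is an
    exact Wiener FPT draw for its cell (resampled while the RT exceeds
    the response window), or — with probability ``guess_rate`` — a fair
    coin flip at a uniform RT in ``guess_rt_range``.
    """
    if truth.spec is None:
        raise ParameterError("truth must carry a ModelSpec")
    subjects = list(dict.fromkeys(design["subject_id"]))
    theta = subject_params(truth, len(subjects), rng)
    out = design.copy()
    out["correct"] = 0
    out["rt_s"] = 0.0
    correct_col = out.columns.get_loc("correct")
    rt_col = out.columns.get_loc("rt_s")
    for si, sid in enumerate(subjects):
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
            params = truth.spec.resolve(cond, theta[si])
            corr, rt = sample_trials(params, n, rng)
            # truncate at the response window by resampling
            for _ in range(1000):
                over = rt > response_window
                if not over.any():
                    break
                c2, r2 = sample_trials(params, int(over.sum()), rng)
                corr[over], rt[over] = c2, r2
            else:
                raise ParameterError(
                    "response window truncation failed to converge; "
                    "parameters place almost all mass beyond the window"
                )
            if truth.guess_rate > 0:
                guess = rng.random(n) < truth.guess_rate
                ng = int(guess.sum())
                corr[guess] = rng.random(ng) < 0.5
                lo, hi = truth.guess_rt_range
                rt[guess] = rng.uniform(lo, min(hi, response_window), ng)
            idx = np.flatnonzero(cmask)
            out.iloc[idx, correct_col] = corr.astype(int)
            out.iloc[idx, rt_col] = rt
    return out


def _fail(msg: str) -> None:
    raise ValidationError(msg)


def validate_trials(table: pd.DataFrame) -> pd.DataFrame:
    """Validate (and lightly coerce) a trial table against the schema."""
    cols = list(table.columns)
    if cols != TRIAL_COLUMNS:
        missing = [c for c in TRIAL_COLUMNS if c not in cols]
        extra = [c for c in cols if c not in TRIAL_COLUMNS]
        _fail(
            f"trial table columns must be exactly {TRIAL_COLUMNS}; "
            f"missing {missing}, unexpected {extra}"
        )
    t = table.copy()
    rt = pd.to_numeric(t["rt_s"], errors="coerce")
    bad = rt.isna() | (rt <= 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        _fail(f"rt_s must be a positive number; first offending row index {row}")
    t["rt_s"] = rt.astype(float)
    bad = ~t["prioritization"].isin(PRIORITIZATIONS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        _fail(
            f"prioritization must be one of {list(PRIORITIZATIONS)}; "
            f"first offending row index {row}: {t['prioritization'].iloc[row]!r}"
        )
    probe = pd.to_numeric(t["probe_position"], errors="coerce")
    bad = ~probe.isin(PROBE_POSITIONS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        _fail(f"probe_position must be one of {list(PROBE_POSITIONS)}; first offending row index {row}")
    t["probe_position"] = probe.astype(int)
    corr = pd.to_numeric(t["correct"], errors="coerce")
    bad = ~corr.isin((0, 1))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        _fail(f"correct must be 0 or 1; first offending row index {row}")
    t["correct"] = corr.astype(int)
    t["session"] = pd.to_numeric(t["session"], errors="coerce").astype(int)
    t["subject_id"] = t["subject_id"].astype(str)
    return t


def write_trials(table: pd.DataFrame, path: str | Path) -> None:
    """Write a validated trial table as CSV with the canonical header."""
    validate_trials(table).to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-table CSV (round-trips with write_trials)."""
    table = pd.read_csv(path, dtype={"subject_id": str})
    return validate_trials(table)
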