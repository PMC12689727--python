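"""Hierarchical Bayesian estimation of the condition-mapped DDM.

Each subject's free parameters (one drift and one non-decision time per
distinct probe-position x attention-state cell of the chosen model, plus
one or four boundary separations) are constrained by group-level normal
distributions on the sampling scale — natural for drift, logarithmic for
boundary and non-decision time, which keeps both positive without hard
constraints.  Weakly-informative priors sit on the group means and
half-normal priors on the group SDs; the sampler is adaptive
Metropolis-within-Gibbs (see :mod:`prioddm._mcmc`), run as several
independent chains whose post-burn-in draws are collapsed into one
posterior after a Gelman-Rubin convergence check.

The chain protocol defaults to 6 chains of 4,000 iterations with the
first 2,000 discarded, i.e. 12,000 retained draws per parameter.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _mcmc
from .design import validate_trials
from .errors import ConfigurationError, DiagnosticError, ParameterError
from .models import ALL_CONDITIONS, ModelSpec, TrialCondition

__all__ = [
    "ChainConfig",
    "PriorSpec",
    "Posterior",
    "fit_model",
    "gelman_rubin",
    "posterior_summary",
    "summarize_draws",
]

RHAT_THRESHOLD = 1.1


@dataclass(frozen=True)
class ChainConfig:
    """MCMC chain protocol (defaults mirror the study: 6 x 4,000, burn 2,000)."""

    n_chains: int = 6
    n_iter: int = 4000
    burn_in: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ParameterError("n_chains must be >= 1")
        if not 0 <= self.burn_in < self.n_iter:
            raise ParameterError("burn_in must satisfy 0 <= burn_in < n_iter")

    @property
    def retained_draws(self) -> int:
        """Total collapsed draws per parameter across chains."""
        return self.n_chains * (self.n_iter - self.burn_in)


@dataclass(frozen=True)
class PriorSpec:
    """Priors per parameter family, on each family's sampling scale.

    ``*_loc`` / ``*_scale`` parameterize the normal prior on the group
    mean; ``*_sd_scale`` the half-normal prior on the group SD.  Drift
    priors live on the natural scale, boundary and non-decision priors
    on the log scale.
    """

    v_loc: float = 2.0
    v_scale: float = 3.0
    v_sd_scale: float = 1.0
    log_a_loc: float = math.log(1.5)
    log_a_scale: float = 0.6
    log_a_sd_scale: float = 0.5
    log_t0_loc: float = math.log(0.4)
    log_t0_scale: float = 0.5
    log_t0_sd_scale: float = 0.25

    def arrays(self, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(prior_mean, prior_scale, sd_scale) vectors in flat-column order."""
        fam = family_codes(spec)
        locs = np.array([self.v_loc, self.log_a_loc, self.log_t0_loc])
        scales = np.array([self.v_scale, self.log_a_scale, self.log_t0_scale])
        sds = np.array([self.v_sd_scale, self.log_a_sd_scale, self.log_t0_sd_scale])
        return locs[fam], scales[fam], sds[fam]


def family_codes(spec: ModelSpec) -> np.ndarray:
    """0 = drift, 1 = boundary, 2 = non-decision, per flat column."""
    return np.array([0] * spec.n_v + [1] * spec.n_a + [2] * spec.n_t, dtype=np.uint8)


def _data_hash(table: pd.DataFrame) -> str:
    payload = table[["subject_id", "session", "prioritization", "probe_position", "correct", "rt_s"]]
    return hashlib.sha256(payload.to_csv(index=False).encode()).hexdigest()[:16]


def build_trial_arrays(table: pd.DataFrame, spec: ModelSpec):
    """Flatten a trial table into the kernel's arrays.

    Returns (subjects, rt, up, sidx, vix, aix, tix, group_trials,
    group_off): trials sorted stably by subject, parameter-column
    indices per trial, and per-(subject, column) trial index lists used
    for incremental likelihood updates.
    """
    table = table.sort_values("subject_id", kind="stable").reset_index(drop=True)
    subjects = list(dict.fromkeys(table["subject_id"]))
    sub_of = {s: i for i, s in enumerate(subjects)}
    n = len(table)
    P = spec.n_params
    rt = table["rt_s"].to_numpy(dtype=np.float64)
    up = table["correct"].to_numpy(dtype=np.uint8)
    sidx = np.array([sub_of[s] for s in table["subject_id"]], dtype=np.int64)
    vix = np.empty(n, dtype=np.int64)
    aix = np.empty(n, dtype=np.int64)
    tix = np.empty(n, dtype=np.int64)
    flat = {c: spec.flat_indices(c) for c in ALL_CONDITIONS}
    for i, (p, q) in enumerate(zip(table["prioritization"], table["probe_position"])):
        try:
            vix[i], aix[i], tix[i] = flat[TrialCondition(p, int(q))]
        except KeyError as exc:
            raise ConfigurationError(f"unmapped condition ({p!r}, {q!r})") from exc
    S = len(subjects)
    keys = np.concatenate([sidx * P + vix, sidx * P + aix, sidx * P + tix])
    ids = np.tile(np.arange(n, dtype=np.int64), 3)
    order = np.argsort(keys, kind="stable")
    group_trials = ids[order]
    group_off = np.zeros(S * P + 1, dtype=np.int64)
    np.add.at(group_off, keys + 1, 1)
    group_off = np.cumsum(group_off)
    return subjects, rt, up, sidx, vix, aix, tix, group_trials, group_off


class Posterior:
    """Chain-resolved MCMC draws for one fitted model.

    Arrays: ``mu`` and ``sigma`` of shape (chains, kept, P) hold the
    group means and SDs on the sampling scale; ``theta`` of shape
    (chains, kept, S, P) the subject parameters; ``deviance`` of shape
    (chains, kept) the subject-level deviance trace.
    """

    def __init__(
        self,
        spec: ModelSpec,
        subjects: list[str],
        mu: np.ndarray,
        sigma: np.ndarray,
        theta: np.ndarray,
        deviance: np.ndarray,
        config: ChainConfig,
        priors: PriorSpec,
        data_hash: str,
    ):
        self.spec = spec
        self.subjects = list(subjects)
        self.mu = mu
        self.sigma = sigma
        self.theta = theta
        self.deviance = deviance
        self.config = config
        self.priors = priors
        self.data_hash = data_hash
        self.fam = family_codes(spec)

    @property
    def n_draws(self) -> int:
        """Collapsed draws per parameter."""
        return self.mu.shape[0] * self.mu.shape[1]

    @property
    def param_labels(self) -> list[str]:
        return self.spec.param_labels

    def group_mean_draws(self, natural: bool = True) -> np.ndarray:
        """Collapsed group-mean draws, (n_draws, P), optionally back-transformed.

        Log-scale columns (boundary, non-decision) are exponentiated, so
        the natural-scale value reported is the group *median* of the
        lognormal subject distribution — the same location the synthetic
        generator parameterizes.
        """
        flat = self.mu.reshape(-1, self.mu.shape[-1]).copy()
        if natural:
            logcols = self.fam > 0
            flat[:, logcols] = np.exp(flat[:, logcols])
        return flat

    def subject_draws_natural(self) -> np.ndarray:
        """Collapsed subject draws (n_draws, S, P) on the natural scale."""
        flat = self.theta.reshape(-1, *self.theta.shape[2:]).copy()
        logcols = self.fam > 0
        flat[:, :, logcols] = np.exp(flat[:, :, logcols])
        return flat

    def theta_bar(self) -> np.ndarray:
        """Posterior-mean subject parameters on the sampling scale, (S, P)."""
        return self.theta.reshape(-1, *self.theta.shape[2:]).mean(axis=0)

    def rhat(self) -> pd.Series:
        """Gelman-Rubin statistic for every group-level parameter."""
        labels = self.param_labels
        vals = {}
        r_mu = gelman_rubin(self.mu)
        r_sig = gelman_rubin(self.sigma)
        for j, lab in enumerate(labels):
            vals[f"mu[{lab}]"] = r_mu[j]
            vals[f"sigma[{lab}]"] = r_sig[j]
        return pd.Series(vals, name="rhat")

    def converged(self, threshold: float = RHAT_THRESHOLD) -> bool:
        return bool((self.rhat() < threshold).all())

    # -- persistence ------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        C, K, P = self.mu.shape
        S = len(self.subjects)
        group = pd.DataFrame(
            {
                "chain": np.repeat(np.arange(C), K),
                "iteration": np.tile(np.arange(K), C),
                "deviance": self.deviance.reshape(-1),
            }
        )
        labels = self.param_labels
        flat_mu = self.mu.reshape(-1, P)
        flat_sig = self.sigma.reshape(-1, P)
        for j, lab in enumerate(labels):
            group[f"mu[{lab}]"] = flat_mu[:, j]
            group[f"sigma[{lab}]"] = flat_sig[:, j]
        group.to_parquet(d / "group_draws.parquet", index=False)
        np.save(d / "subject_draws.npy", self.theta)
        meta = {
            "model_id": self.spec.model_id,
            "spec": self.spec.to_dict(),
            "subjects": self.subjects,
            "chain_config": {
                "n_chains": self.config.n_chains,
                "n_iter": self.config.n_iter,
                "burn_in": self.config.burn_in,
                "seed": self.config.seed,
            },
            "priors": self.priors.__dict__,
            "data_hash": self.data_hash,
            "package_version": _package_version(),
        }
        (d / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def load(cls, directory: str | Path) -> "Posterior":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        spec = ModelSpec.from_dict(meta["spec"])
        cc = ChainConfig(**meta["chain_config"])
        priors = PriorSpec(**meta["priors"])
        group = pd.read_parquet(d / "group_draws.parquet")
        theta = np.load(d / "subject_draws.npy")
        C = cc.n_chains
        K = cc.n_iter - cc.burn_in
        labels = spec.param_labels
        mu = np.stack([group[f"mu[{lab}]"].to_numpy().reshape(C, K) for lab in labels], axis=-1)
        sigma = np.stack(
            [group[f"sigma[{lab}]"].to_numpy().reshape(C, K) for lab in labels], axis=-1
        )
        dev = group["deviance"].to_numpy().reshape(C, K)
        return cls(spec, meta["subjects"], mu, sigma, theta, dev, cc, priors, meta["data_hash"])


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("prioddm")
    except PackageNotFoundError:
        return "unknown"


def _initial_values(table, spec, subjects, rng):
    """Method-of-moments starting values, jittered per chain."""
    P = spec.n_params
    nv, na = spec.n_v, spec.n_a
    theta0 = np.empty((len(subjects), P))
    by_subj = table.groupby("subject_id")
    acc = by_subj["correct"].mean()
    minrt = by_subj["rt_s"].min()
    for s, sid in enumerate(subjects):
        p_corr = float(np.clip(acc[sid], 0.55, 0.95))
        v0 = math.log(p_corr / (1 - p_corr)) / 1.5
        t00 = 0.9 * float(minrt[sid])
        theta0[s, :nv] = v0 + rng.normal(0, 0.25, nv)
        theta0[s, nv : nv + na] = math.log(1.5) + rng.normal(0, 0.08, na)
        logt = math.log(t00) + rng.normal(0, 0.08, spec.n_t)
        theta0[s, nv + na :] = np.minimum(logt, math.log(0.95 * float(minrt[sid])))
    mu0 = theta0.mean(axis=0)
    fam = family_codes(spec)
    sig0 = np.array([0.3, 0.1, 0.1])[fam]
    return theta0, mu0, sig0


def fit_model(
    table: pd.DataFrame,
    spec: ModelSpec,
    chains: ChainConfig | None = None,
    priors: PriorSpec | None = None,
) -> Posterior:
    """Fit one model specification to a preprocessed trial table.

    Runs ``chains.n_chains`` independent adaptive Metropolis-within-Gibbs
    chains (chain c is seeded with ``chains.seed + c``) and returns the
    chain-resolved posterior with per-parameter Gelman-Rubin statistics
    available via :meth:`Posterior.rhat`.
    """
    chains = chains or ChainConfig()
    priors = priors or PriorSpec()
    table = validate_trials(table)
    subjects, rt, up, sidx, vix, aix, tix, gt, go = build_trial_arrays(table, spec)
    if len(subjects) < 2:
        raise ConfigurationError("hierarchical fitting needs at least 2 subjects")
    cells = table.groupby("subject_id").apply(
        lambda g: len(set(zip(g["prioritization"], g["probe_position"]))), include_groups=False
    )
    if (cells < len(ALL_CONDITIONS)).any():
        missing = cells[cells < len(ALL_CONDITIONS)].index.tolist()
        raise ConfigurationError(f"subjects missing design cells: {missing}")

    fam = family_codes(spec)
    prior_m, prior_s, sd_scale = priors.arrays(spec)
    keep = chains.n_iter - chains.burn_in
    S, P = len(subjects), spec.n_params
    mu = np.empty((chains.n_chains, keep, P))
    sigma = np.empty_like(mu)
    theta = np.empty((chains.n_chains, keep, S, P))
    dev = np.empty((chains.n_chains, keep))
    sorted_table = table.sort_values("subject_id", kind="stable")
    for c in range(chains.n_chains):
        rng = np.random.default_rng(chains.seed + c)
        for attempt in range(100):
            th0, mu0, sig0 = _initial_values(sorted_table, spec, subjects, rng)
            ll0 = _mcmc.dataset_loglik(rt, up, sidx, vix, aix, tix, th0)
            if np.isfinite(ll0):
                break
        else:
            raise DiagnosticError("non-finite likelihood at initialization after 100 retries")
        out = _mcmc.run_chain(
            rt, up, sidx, vix, aix, tix, gt, go, fam,
            prior_m, prior_s, sd_scale,
            th0, mu0.copy(), sig0.copy(),
            chains.n_iter, chains.burn_in, (chains.seed + c) % (2**31 - 1),
        )
        mu[c], sigma[c], theta[c], dev[c] = out
    return Posterior(
        spec, subjects, mu, sigma, theta, dev, chains, priors, _data_hash(table)
    )


def gelman_rubin(draws: np.ndarray) -> np.ndarray | float:
    """Potential scale reduction factor (classic between/within form).

    ``draws`` has shape (chains, iterations) or (chains, iterations,
    parameters).  With W the mean within-chain variance and B/n the
    variance of chain means, returns sqrt(((n-1)/n W + B/n) / W).
    Chains that are all constant and identical give exactly 1.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 2:
        return float(_psrf(draws))
    if draws.ndim != 3:
        raise ParameterError("draws must have shape (chains, iters[, params])")
    return np.array([_psrf(draws[:, :, j]) for j in range(draws.shape[2])])


def _psrf(x: np.ndarray) -> float:
    m, n = x.shape
    if m < 2:
        raise DiagnosticError("Gelman-Rubin diagnostic needs at least 2 chains")
    if n < 2:
        raise DiagnosticError("Gelman-Rubin diagnostic needs at least 2 retained iterations")
    w = x.var(axis=1, ddof=1).mean()
    b_over_n = x.mean(axis=1).var(ddof=1)
    if w == 0.0:
        return 1.0 if b_over_n == 0.0 else float("inf")
    var_plus = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_plus / w))


def summarize_draws(x: np.ndarray, ci: float = 0.95) -> tuple[float, float, float]:
    """(mean, lower, upper) with a central credible interval."""
    x = np.asarray(x, dtype=float)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(x, [alpha, 1.0 - alpha])
    return float(x.mean()), float(lo), float(hi)


def posterior_summary(post: Posterior, ci: float = 0.95) -> pd.DataFrame:
    """Posterior mean and central credible interval per group parameter.

    Group means are reported on the natural scale (log-scale columns
    back-transformed draw-wise); group SDs stay on their sampling scale.
    """
    labels = post.param_labels
    nat = post.group_mean_draws(natural=True)
    sig = post.sigma.reshape(-1, post.sigma.shape[-1])
    rhat = post.rhat()
    rows = []
    for j, lab in enumerate(labels):
        m, lo, hi = summarize_draws(nat[:, j], ci)
        rows.append(
            {
                "parameter": lab,
                "kind": "group_mean",
                "mean": m,
                "ci_lower": lo,
                "ci_upper": hi,
                "rhat": rhat[f"mu[{lab}]"],
            }
        )
    for j, lab in enumerate(labels):
        m, lo, hi = summarize_draws(sig[:, j], ci)
        rows.append(
            {
                "parameter": f"sd({lab})",
                "kind": "group_sd",
                "mean": m,
                "ci_lower": lo,
                "ci_upper": hi,
                "rhat": rhat[f"sigma[{lab}]"],
            }
        )
    return pd.DataFrame(rows)
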