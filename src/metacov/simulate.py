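"""Generative simulator for 2AFC trials with ordinal confidence ratings.

Trials are generated from the same type-II SDT observer that the estimators
in :mod:`metacov.sdt` fit, which is what makes parameter recovery a
well-posed check:

1. the stimulus class (S1/S2) is drawn uniformly;
2. type-1 evidence ``x1 ~ Normal(+-d'/2, 1)`` is compared with the criterion
   ``c`` to produce the response;
3. a second, metacognitive evidence sample is drawn from
   ``Normal(+-meta-d'/2, 1)`` truncated to the response-consistent side of
   the rescaled criterion ``meta-c = (c/d') * meta-d'``, and binned by the
   ordered type-2 cutpoints into K confidence levels.

When meta-d' = d' step 3 is distributionally identical to re-binning the
type-1 evidence itself (an "ideal" metacognitive observer, Mratio = 1);
meta-d' < d' models confidence that is noisier than the decision it rates.

Groups of subjects performing several tasks are generated by drawing each
subject's per-task log Mratio vector from a multivariate Gaussian with task
means ``mu_logM``, spreads ``sigma_logM`` and cross-task correlation matrix
``rho`` — the covariance structure the hierarchical model estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .exceptions import InvalidParameterError
from .sdt import criteria_from_tau, default_tau

_EPS = 1e-12

TRIAL_COLUMNS = [
    "subject",
    "task",
    "trial",
    "stimulus",
    "response",
    "accurate",
    "confidence_level",
    "confidence_pct",
]


def _relative_criterion(dprime: float, criterion: float) -> float:
    # c' = c/d'; at d' = 0 the ratio is undefined and the raw c is carried over
    return criterion / dprime if dprime > 0 else criterion


@dataclass(frozen=True)
class SubjectTaskParams:
    """Generative parameters of one subject on one task.

    ``t2c_s1`` / ``t2c_s2`` are the absolute type-2 cutpoints (each ascending)
    below / above the rescaled criterion meta-c; both sides must have K-1
    cutpoints for a K-level confidence scale.
    """

    dprime: float
    criterion: float
    metad: float
    t2c_s1: np.ndarray
    t2c_s2: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "t2c_s1", np.asarray(self.t2c_s1, dtype=float))
        object.__setattr__(self, "t2c_s2", np.asarray(self.t2c_s2, dtype=float))
        if self.dprime < 0 or self.metad < 0:
            raise InvalidParameterError("dprime and metad must be nonnegative")
        if len(self.t2c_s1) != len(self.t2c_s2):
            raise InvalidParameterError("both cutpoint sets must have K-1 entries")
        mc = self.meta_c
        for name, v in (("t2c_s1", self.t2c_s1), ("t2c_s2", self.t2c_s2)):
            if v.size and np.any(np.diff(v) <= 0):
                raise InvalidParameterError(f"{name} must be strictly increasing: {v}")
        if self.t2c_s1.size and not (self.t2c_s1[-1] < mc < self.t2c_s2[0]):
            raise InvalidParameterError(
                f"type-2 cutpoints must straddle meta-c={mc:.3f}: "
                f"max(t2c_s1)={self.t2c_s1[-1]:.3f}, min(t2c_s2)={self.t2c_s2[0]:.3f}"
            )

    @property
    def n_levels(self) -> int:
        return len(self.t2c_s1) + 1

    @property
    def meta_c(self) -> float:
        return _relative_criterion(self.dprime, self.criterion) * self.metad

    @property
    def mratio(self) -> float:
        return self.metad / self.dprime if self.dprime > 0 else np.nan

    @classmethod
    def with_default_criteria(
        cls, dprime: float, metad: float | None = None, criterion: float = 0.0,
        n_levels: int = 11,
    ) -> "SubjectTaskParams":
        """Quantile-spaced cutpoints giving roughly uniform confidence usage."""
        if metad is None:
            metad = dprime
        cprime = _relative_criterion(dprime, criterion)
        tau = default_tau(max(metad, 0.2), cprime, n_levels)
        cuts = criteria_from_tau(max(metad, 0.2), cprime, tau)
        k = n_levels
        return cls(dprime, criterion, metad, cuts[: k - 1], cuts[k:])


def simulate_subject_task(
    params: SubjectTaskParams,
    n_trials: int,
    seed: int | np.random.Generator | None = None,
    subject=0,
    task=0,
) -> pd.DataFrame:
    """Simulate ``n_trials`` 2AFC-plus-confidence trials for one subject-task.

    Returns a trial table with columns ``subject, task, trial, stimulus,
    response, accurate, confidence_level, confidence_pct``; deterministic for
    a fixed integer seed.
    """
    if n_trials < 1:
        raise InvalidParameterError("n_trials must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    k = params.n_levels

    stim = rng.integers(0, 2, size=n_trials)  # 0=S1, 1=S2
    mu1 = np.where(stim == 1, params.dprime / 2.0, -params.dprime / 2.0)
    x1 = rng.normal(mu1, 1.0)
    resp = (x1 > params.criterion).astype(int)

    # metacognitive evidence: truncated to the response side of meta-c
    mc = params.meta_c
    mu2 = np.where(stim == 1, params.metad / 2.0, -params.metad / 2.0)
    lo = np.where(resp == 1, ndtr(mc - mu2), 0.0)
    hi = np.where(resp == 1, 1.0, ndtr(mc - mu2))
    u = rng.uniform(size=n_trials)
    x2 = mu2 + ndtri(np.clip(lo + u * (hi - lo), _EPS, 1.0 - _EPS))

    conf = np.empty(n_trials, dtype=int)
    is2 = resp == 1
    conf[is2] = np.searchsorted(params.t2c_s2, x2[is2])
    conf[~is2] = (k - 1) - np.searchsorted(params.t2c_s1, x2[~is2])

    return pd.DataFrame(
        {
            "subject": subject,
            "task": task,
            "trial": np.arange(n_trials),
            "stimulus": np.where(stim == 1, "S2", "S1"),
            "response": np.where(resp == 1, "S2", "S1"),
            "accurate": (resp == stim).astype(int),
            "confidence_level": conf,
            "confidence_pct": conf * (100.0 / (k - 1)),
        }
    )


def _as_task_vector(x, n_tasks: int, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim == 0:
        v = np.full(n_tasks, float(v))
    if v.shape != (n_tasks,):
        raise InvalidParameterError(f"{name} must be scalar or length {n_tasks}, got {v.shape}")
    return v


def uniform_correlation(n_tasks: int, rho: float) -> np.ndarray:
    """Correlation matrix with a common off-diagonal value."""
    m = np.full((n_tasks, n_tasks), float(rho))
    np.fill_diagonal(m, 1.0)
    return m


@dataclass(frozen=True)
class GroupConfig:
    """Ground-truth generative parameters for a multi-task group.

    Defaults mirror the study conditions the package targets: 4 tasks of 40
    trials each rated on an 11-level (0-100%) confidence scale, per-subject
    d' heterogeneity spanning the observed task means, group-mean Mratio of
    0.8 with spread 0.5 on the log scale and a common cross-task correlation
    of 0.6.
    """

    n_subjects: int = 100
    n_tasks: int = 4
    n_trials: int = 40
    mu_logM: np.ndarray = field(default=None)
    sigma_logM: np.ndarray = field(default=None)
    rho: np.ndarray = field(default=None)
    dprime_range: tuple = (0.5, 2.5)
    criterion: float = 0.0
    n_levels: int = 11
    seed: int | None = None

    def __post_init__(self):
        t = self.n_tasks
        mu = _as_task_vector(np.log(0.8) if self.mu_logM is None else self.mu_logM, t, "mu_logM")
        sig = _as_task_vector(0.5 if self.sigma_logM is None else self.sigma_logM, t, "sigma_logM")
        rho = uniform_correlation(t, 0.6) if self.rho is None else np.asarray(self.rho, float)
        object.__setattr__(self, "mu_logM", mu)
        object.__setattr__(self, "sigma_logM", sig)
        object.__setattr__(self, "rho", rho)
        if self.n_trials < 1 or self.n_levels < 2 or self.n_subjects < 1:
            raise InvalidParameterError("n_trials, n_subjects >= 1 and n_levels >= 2 required")
        if np.any(sig < 0):
            raise InvalidParameterError("sigma_logM must be nonnegative")
        if not (self.dprime_range[0] <= self.dprime_range[1]) or self.dprime_range[0] < 0:
            raise InvalidParameterError(f"invalid dprime_range {self.dprime_range}")
        validate_correlation(rho)

    @property
    def covariance(self) -> np.ndarray:
        return self.rho * np.outer(self.sigma_logM, self.sigma_logM)


def validate_correlation(rho: np.ndarray, tol: float = 1e-8) -> None:
    """Reject (rather than repair) an invalid correlation matrix."""
    rho = np.asarray(rho, dtype=float)
    if rho.ndim != 2 or rho.shape[0] != rho.shape[1]:
        raise InvalidParameterError(f"rho must be square, got shape {rho.shape}")
    if not np.allclose(rho, rho.T, atol=1e-12):
        raise InvalidParameterError(f"rho is not symmetric:\n{rho}")
    if not np.allclose(np.diag(rho), 1.0, atol=1e-12):
        raise InvalidParameterError(f"rho must have a unit diagonal:\n{rho}")
    if np.any(np.abs(rho) > 1 + 1e-12):
        raise InvalidParameterError(f"rho entries must lie in [-1, 1]:\n{rho}")
    if np.linalg.eigvalsh(rho).min() < -tol:
        raise InvalidParameterError(f"rho is not positive semidefinite:\n{rho}")


def _psd_sqrt(cov: np.ndarray) -> np.ndarray:
    evals, vecs = np.linalg.eigh(cov)
    return vecs * np.sqrt(np.clip(evals, 0.0, None))


def simulate_group(config: GroupConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate a full multi-task group; returns (trial table, ground truth).

    Per subject: log Mratio vector ~ MVN(mu_logM, diag(sigma) rho diag(sigma)),
    per-task d' ~ Uniform(dprime_range), meta-d' = exp(logM) * d'; trials via
    :func:`simulate_subject_task`.  The ground-truth dict records the drawn
    log Mratios and d' values plus the config, for recovery scoring.
    """
    t, n = config.n_tasks, config.n_subjects
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss)

    sqrt_cov = _psd_sqrt(config.covariance)
    z = rng.standard_normal((n, t))
    log_m = config.mu_logM + z @ sqrt_cov.T
    dprime = rng.uniform(config.dprime_range[0], config.dprime_range[1], size=(n, t))

    blocks = []
    child_rngs = [np.random.default_rng(s) for s in ss.spawn(n * t)]
    for i in range(n):
        for j in range(t):
            params = SubjectTaskParams.with_default_criteria(
                dprime=dprime[i, j],
                metad=float(np.exp(log_m[i, j]) * dprime[i, j]),
                criterion=config.criterion,
                n_levels=config.n_levels,
            )
            blocks.append(
                simulate_subject_task(
                    params, config.n_trials, seed=child_rngs[i * t + j], subject=i, task=j
                )
            )
    trials = pd.concat(blocks, ignore_index=True)

    cfg = asdict(config)
    for key in ("mu_logM", "sigma_logM", "rho"):
        cfg[key] = np.asarray(cfg[key]).tolist()
    truth = {
        "log_mratio": log_m.tolist(),
        "dprime": dprime.tolist(),
        "config": cfg,
    }
    return trials, truth
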