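"""Hierarchical Bayesian estimation of cross-task metacognitive efficiency.

The model ("hierarchical meta-d'", multi-task variant): each subject s has a
vector of log metacognitive efficiencies, one per task,

    (log M_s1, ..., log M_sT) ~ MultivariateNormal(mu, Sigma),
    Sigma_ij = rho_ij * sigma_i * sigma_j,

with priors mu_t ~ Normal(0, 1), sigma_t ~ InvSqrtGamma(0.001, 0.001)
(i.e. 1/sigma^2 ~ Gamma(0.001, 0.001)) and rho_ij ~ Uniform(-1, 1)
element-wise, restricted to positive semidefinite matrices by rejection.
The data enter through the single-subject type-II SDT likelihood of
:mod:`metacov.sdt`: per subject-task, meta-d' = exp(log M) * d'hat with the
type-1 d' and criterion fixed at their point estimates, and ordered type-2
cutpoints (log-gap parameterized, weakly informative normal priors centred
on data-derived cutpoints).

Inference is by Metropolis-within-Gibbs: conjugate Gibbs draws for mu,
adaptive random-walk Metropolis for subject-level parameters (vectorized
across subjects, which are conditionally independent given the group level),
for log sigma and for each rho entry (with an occasional independence
proposal from the Uniform(-1,1) prior to aid mixing).  Convergence is
monitored with the Gelman-Rubin potential scale reduction factor over
multiple chains, and posterior uncertainty summarised by highest density
intervals (HDIs).  With the likelihood disabled the model factorizes, so
prior-only "fits" return exact iid draws from the joint prior.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, InvalidParameterError
from .sdt import CountsTable, compute_dprime, empirical_tau, type2_loglik

_LSIG_BOUNDS = (-7.0, 3.0)  # hard truncation of log sigma, numerical guard


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HierarchicalModelSpec:
    """Priors of the multi-task hierarchical model."""

    n_tasks: int
    mu_prior_sd: float = 1.0
    sigma_prior_shape: float = 0.001
    sigma_prior_rate: float = 0.001
    tau_prior_sd: float = 1.0

    def __post_init__(self):
        if self.n_tasks < 1:
            raise InvalidParameterError("n_tasks must be >= 1")
        for name in ("mu_prior_sd", "sigma_prior_shape", "sigma_prior_rate", "tau_prior_sd"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings.

    Defaults (3 chains, 10,000 kept draws after 1,000 burn-in) are sized for
    final analyses; examples and tests pass smaller values explicitly.
    """

    n_chains: int = 3
    n_samples: int = 10_000
    n_burnin: int = 1_000
    seed: int | None = None
    adapt_every: int = 25

    def __post_init__(self):
        if self.n_chains < 2:
            raise InvalidParameterError("n_chains must be >= 2 (R-hat needs multiple chains)")
        if self.n_samples < 1 or self.n_burnin < 0:
            raise InvalidParameterError("n_samples >= 1 and n_burnin >= 0 required")


# ---------------------------------------------------------------------------
# posterior diagnostics
# ---------------------------------------------------------------------------


def compute_hdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval containing ``ceil(mass * n)`` samples.

    Ties between equally narrow windows are broken leftmost.
    """
    if not 0.0 < mass < 1.0:
        raise InvalidParameterError(f"mass must be in (0, 1), got {mass}")
    s = np.asarray(samples, dtype=float).ravel()
    s = s[np.isfinite(s)]
    if s.size < 10:
        raise DegenerateDataError(f"need >= 10 finite samples for an HDI, got {s.size}")
    s.sort()
    n = s.size
    m = min(int(math.ceil(mass * n)), n)
    widths = s[m - 1:] - s[: n - m + 1]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + m - 1])


def compute_rhat(chains) -> float:
    """Gelman-Rubin potential scale reduction factor.

    ``chains`` is (n_chains, n_draws); values near 1 indicate convergence.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise InvalidParameterError("compute_rhat needs >= 2 chains of equal length")
    n = x.shape[1]
    if n < 10:
        raise InvalidParameterError("chains must have length >= 10")
    w = x.var(axis=1, ddof=1).mean()
    b_over_n = x.mean(axis=1).var(ddof=1)
    if w == 0.0:
        return 1.0 if b_over_n == 0.0 else float("inf")
    var_plus = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_plus / w))


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------


@dataclass
class HierarchicalPosterior:
    """MCMC draws of the multi-task hierarchical model plus diagnostics.

    Group-level draw arrays are shaped (n_chains, n_draws, ...); subject-level
    log-Mratio draws are (n_chains, n_draws, n_subjects, n_tasks).
    """

    tasks: list
    subjects: list
    pairs: list
    mu: np.ndarray
    sigma: np.ndarray
    rho: np.ndarray
    log_mratio: np.ndarray
    rhat: dict
    meta: dict = field(default_factory=dict)

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)

    def flat(self, name: str) -> np.ndarray:
        """Draws pooled over chains: mu/sigma -> (D, T); rho -> (D, P)."""
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    def group_mratio(self) -> np.ndarray:
        """Pooled draws of the group-level Mratio exp(mu), shape (D, T)."""
        return np.exp(self.flat("mu"))

    def group_mratio_mean(self) -> np.ndarray:
        return self.group_mratio().mean(axis=0)

    def subject_mratio_means(self) -> np.ndarray:
        """Posterior-mean subject-level Mratios, shape (n_subjects, n_tasks)."""
        return np.exp(self.flat("log_mratio")).mean(axis=0)

    def max_rhat(self, group_only: bool = False) -> float:
        """Largest R-hat; ``group_only`` restricts to mu/sigma/rho parameters."""
        if group_only:
            return max(v for k, v in self.rhat.items() if not k.startswith("logM["))
        return max(self.rhat.values())

    def summary(self, mass: float = 0.95) -> pd.DataFrame:
        rows = []
        for name, labels in (
            ("mu", [f"mu_M[{t}]" for t in self.tasks]),
            ("sigma", [f"sigma_M[{t}]" for t in self.tasks]),
            ("rho", [f"rho[{self.tasks[i]},{self.tasks[j]}]" for i, j in self.pairs]),
        ):
            draws = self.flat(name)
            for col, label in enumerate(labels):
                d = draws[:, col]
                lo, hi = compute_hdi(d, mass)
                rows.append(
                    {
                        "parameter": label,
                        "mean": d.mean(),
                        "median": float(np.median(d)),
                        "hdi_lo": lo,
                        "hdi_hi": hi,
                        "rhat": self.rhat.get(label, np.nan),
                        "excludes_zero": bool(lo > 0 or hi < 0),
                    }
                )
        return pd.DataFrame(rows)

    def to_json(self, path, mass: float = 0.95) -> None:
        import json

        payload = {
            "tasks": [str(t) for t in self.tasks],
            "n_subjects": len(self.subjects),
            "meta": self.meta,
            "summary": self.summary(mass).to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)

    def draws_to_csv(self, path) -> None:
        """Group-level draws as delimited text (one row per chain x draw)."""
        c, d, t = self.mu.shape
        cols = {"chain": np.repeat(np.arange(c), d), "draw": np.tile(np.arange(d), c)}
        for j, task in enumerate(self.tasks):
            cols[f"mu_M[{task}]"] = self.mu[..., j].ravel()
            cols[f"sigma_M[{task}]"] = self.sigma[..., j].ravel()
        for p, (i, j) in enumerate(self.pairs):
            cols[f"rho[{self.tasks[i]},{self.tasks[j]}]"] = self.rho[..., p].ravel()
        pd.DataFrame(cols).to_csv(path, index=False)


def summarize_correlations(posterior: HierarchicalPosterior, mass: float = 0.95) -> dict:
    """Cross-task correlation and group-Mratio-difference report.

    Returns ``{"rho": DataFrame, "mratio_difference": DataFrame}``; each row
    carries posterior mean, HDI bounds and whether the HDI excludes zero.
    The Mratio differences are computed on the exponentiated scale,
    exp(mu_i) - exp(mu_j).
    """
    if not posterior.pairs:
        raise InvalidParameterError("posterior has no task pairs (single-task fit)")
    tasks = posterior.tasks
    rho = posterior.flat("rho")
    gm = posterior.group_mratio()
    rho_rows, diff_rows = [], []
    for p, (i, j) in enumerate(posterior.pairs):
        d = rho[:, p]
        lo, hi = compute_hdi(d, mass)
        rho_rows.append(
            {
                "task_i": tasks[i],
                "task_j": tasks[j],
                "mean": d.mean(),
                "hdi_lo": lo,
                "hdi_hi": hi,
                "excludes_zero": bool(lo > 0 or hi < 0),
            }
        )
        dd = gm[:, i] - gm[:, j]
        lo, hi = compute_hdi(dd, mass)
        diff_rows.append(
            {
                "task_i": tasks[i],
                "task_j": tasks[j],
                "mean": dd.mean(),
                "hdi_lo": lo,
                "hdi_hi": hi,
                "excludes_zero": bool(lo > 0 or hi < 0),
            }
        )
    return {"rho": pd.DataFrame(rho_rows), "mratio_difference": pd.DataFrame(diff_rows)}


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------


def _rho_matrix(rho_v: np.ndarray, pairs, t: int) -> np.ndarray:
    r = np.eye(t)
    for p, (i, j) in enumerate(pairs):
        r[i, j] = r[j, i] = rho_v[p]
    return r


def _is_pd(mat: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(mat)
        return True
    except np.linalg.LinAlgError:
        return False


def _cov_terms(lsig: np.ndarray, rho_v: np.ndarray, pairs, t: int):
    sig = np.exp(lsig)
    cov = _rho_matrix(rho_v, pairs, t) * np.outer(sig, sig)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        return None
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    sinv = np.linalg.inv(cov)
    return cov, sinv, logdet


def _log_prior_lsig(lam: float, shape: float, rate: float) -> float:
    # sigma = exp(lam); 1/sigma^2 ~ Gamma(shape, rate), density on the log scale
    return -2.0 * shape * lam - rate * math.exp(-2.0 * lam)


class _SubjectData:
    """Per-subject-task quantities fixed during sampling."""

    def __init__(self, counts_arr, d1, cprime, tau0, n_levels):
        self.counts = counts_arr  # (N, T, 2, 2K)
        self.d1 = d1  # (N, T)
        self.cprime = cprime
        self.tau0 = tau0  # (N, T, 2K-2)
        self.n_levels = n_levels

    def loglik_col(self, t: int, m_col, tau_col):
        """Data log-likelihood of task ``t`` for all subjects."""
        meta_d = np.exp(m_col) * self.d1[:, t]
        return type2_loglik(self.counts[:, t], meta_d, self.cprime[:, t], tau_col, self.n_levels)


def _run_chain(data: _SubjectData, spec: HierarchicalModelSpec, n_keep, n_burn, rng, adapt_every):
    n, t = data.d1.shape
    j2 = data.tau0.shape[-1]
    pairs = list(combinations(range(t), 2))
    npairs = len(pairs)

    # overdispersed initialisation
    mu = rng.normal(0.0, 0.4, t)
    lsig = np.log(0.4) + rng.normal(0.0, 0.3, t)
    while True:
        rho_v = rng.uniform(-0.4, 0.4, npairs)
        terms = _cov_terms(lsig, rho_v, pairs, t)
        if terms is not None:
            break
    cov, sinv, logdet = terms
    m = mu + rng.normal(0.0, 0.4, (n, t))
    tau = data.tau0 + rng.normal(0.0, 0.15, (n, t, j2))

    ll = np.stack([data.loglik_col(k, m[:, k], tau[:, k]) for k in range(t)], axis=1)

    # per-subject proposal scales: likelihood curvature varies strongly with d'
    s_m = np.full((n, t), 0.3)
    s_tau = np.full((n, t), 0.15)
    s_lsig = np.full(t, 0.4)
    s_lsig_nc = np.full(t, 0.4)
    s_rho = np.full(npairs, 0.15)
    acc = {
        "m": np.zeros((n, t)),
        "tau": np.zeros((n, t)),
        "lsig": np.zeros(t),
        "lsig_nc": np.zeros(t),
        "rho": np.zeros(npairs),
    }
    tau_var = spec.tau_prior_sd**2

    out_mu = np.empty((n_keep, t))
    out_sig = np.empty((n_keep, t))
    out_rho = np.empty((n_keep, npairs))
    out_m = np.empty((n_keep, n, t))

    for it in range(n_burn + n_keep):
        # --- subject log-Mratio, one task column at a time (vectorized over subjects)
        for k in range(t):
            eps = rng.standard_normal(n) * s_m[:, k]
            ll_new = data.loglik_col(k, m[:, k] + eps, tau[:, k])
            d = m - mu
            dquad = 2.0 * eps * (d @ sinv[:, k]) + eps**2 * sinv[k, k]
            logr = (ll_new - ll[:, k]) - 0.5 * dquad
            ok = np.log(rng.uniform(size=n)) < logr
            m[ok, k] += eps[ok]
            ll[ok, k] = ll_new[ok]
            acc["m"][:, k] += ok

        # --- type-2 cutpoint log-gaps
        for k in range(t):
            eps = rng.standard_normal((n, j2)) * s_tau[:, k, None]
            tau_new = tau[:, k] + eps
            ll_new = data.loglik_col(k, m[:, k], tau_new)
            dprior = -0.5 * (
                ((tau_new - data.tau0[:, k]) ** 2).sum(-1)
                - ((tau[:, k] - data.tau0[:, k]) ** 2).sum(-1)
            ) / tau_var
            ok = np.log(rng.uniform(size=n)) < (ll_new - ll[:, k]) + dprior
            tau[ok, k] = tau_new[ok]
            ll[ok, k] = ll_new[ok]
            acc["tau"][:, k] += ok

        # --- independence refresh of whole subject vectors from the MVN prior
        # (prior proposal density cancels: accepted on the likelihood ratio
        # alone; keeps subject draws decorrelated when the likelihood is weak)
        try:
            chol_cov = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            chol_cov = None
        if chol_cov is not None:
            m_prop = mu + rng.standard_normal((n, t)) @ chol_cov.T
            ll_prop = np.stack(
                [data.loglik_col(k, m_prop[:, k], tau[:, k]) for k in range(t)], axis=1
            )
            ok = np.log(rng.uniform(size=n)) < (ll_prop.sum(axis=1) - ll.sum(axis=1))
            m[ok] = m_prop[ok]
            ll[ok] = ll_prop[ok]

        # --- group mean: conjugate Gibbs
        prec = np.eye(t) / spec.mu_prior_sd**2 + n * sinv
        cov_mu = np.linalg.inv(prec)
        mean_mu = cov_mu @ (sinv @ m.sum(axis=0))
        mu = mean_mu + np.linalg.cholesky(cov_mu) @ rng.standard_normal(t)

        # --- group spreads (random walk on log sigma)
        for k in range(t):
            lam_new = lsig[k] + rng.normal(0.0, s_lsig[k])
            if not (_LSIG_BOUNDS[0] <= lam_new <= _LSIG_BOUNDS[1]):
                continue
            lsig_new = lsig.copy()
            lsig_new[k] = lam_new
            terms = _cov_terms(lsig_new, rho_v, pairs, t)
            if terms is None:
                continue
            cov_n, sinv_n, logdet_n = terms
            d = m - mu
            quad_old = np.einsum("nt,ts,ns->", d, sinv, d)
            quad_new = np.einsum("nt,ts,ns->", d, sinv_n, d)
            logr = (
                -0.5 * n * (logdet_n - logdet)
                - 0.5 * (quad_new - quad_old)
                + _log_prior_lsig(lam_new, spec.sigma_prior_shape, spec.sigma_prior_rate)
                - _log_prior_lsig(lsig[k], spec.sigma_prior_shape, spec.sigma_prior_rate)
            )
            if np.log(rng.uniform()) < logr:
                lsig, cov, sinv, logdet = lsig_new, cov_n, sinv_n, logdet_n
                acc["lsig"][k] += 1.0

        # --- non-centered sigma move: rescale subject deviations along with sigma.
        # Under the transformation m' = mu + (sigma'/sigma)(m - mu) the MVN prior
        # term cancels against the Jacobian, leaving prior(sigma) x likelihood —
        # this breaks the sigma-vs-spread funnel when the likelihood is weak.
        for k in range(t):
            lam_new = lsig[k] + rng.normal(0.0, s_lsig_nc[k])
            if not (_LSIG_BOUNDS[0] <= lam_new <= _LSIG_BOUNDS[1]):
                continue
            scale = math.exp(lam_new - lsig[k])
            m_col = mu[k] + scale * (m[:, k] - mu[k])
            ll_new = data.loglik_col(k, m_col, tau[:, k])
            logr = (
                ll_new.sum() - ll[:, k].sum()
                + _log_prior_lsig(lam_new, spec.sigma_prior_shape, spec.sigma_prior_rate)
                - _log_prior_lsig(lsig[k], spec.sigma_prior_shape, spec.sigma_prior_rate)
            )
            if np.log(rng.uniform()) < logr:
                lsig_new = lsig.copy()
                lsig_new[k] = lam_new
                terms = _cov_terms(lsig_new, rho_v, pairs, t)
                if terms is None:
                    continue
                lsig = lsig_new
                cov, sinv, logdet = terms
                m[:, k] = m_col
                ll[:, k] = ll_new
                acc["lsig_nc"][k] += 1.0

        # --- correlations (random walk + occasional independence proposal; PSD by rejection)
        for p in range(npairs):
            if rng.uniform() < 0.1:
                r_new = rng.uniform(-1.0, 1.0)
            else:
                r_new = rho_v[p] + rng.normal(0.0, s_rho[p])
            if not -1.0 < r_new < 1.0:
                continue
            rho_new = rho_v.copy()
            rho_new[p] = r_new
            terms = _cov_terms(lsig, rho_new, pairs, t)
            if terms is None:  # non-PSD proposal rejected
                continue
            cov_n, sinv_n, logdet_n = terms
            d = m - mu
            quad_old = np.einsum("nt,ts,ns->", d, sinv, d)
            quad_new = np.einsum("nt,ts,ns->", d, sinv_n, d)
            logr = -0.5 * n * (logdet_n - logdet) - 0.5 * (quad_new - quad_old)
            if np.log(rng.uniform()) < logr:
                rho_v, cov, sinv, logdet = rho_new, cov_n, sinv_n, logdet_n
                acc["rho"][p] += 1.0

        # --- proposal adaptation, during burn-in only
        if it < n_burn and (it + 1) % adapt_every == 0:
            for key, scales, target in (
                ("m", s_m, 0.44),
                ("tau", s_tau, 0.25),
                ("lsig", s_lsig, 0.44),
                ("lsig_nc", s_lsig_nc, 0.44),
                ("rho", s_rho, 0.44),
            ):
                rate = acc[key] / adapt_every
                scales *= np.exp(np.clip(rate - target, -0.5, 0.5))
                np.clip(scales, 1e-3, 10.0, out=scales)
                acc[key][:] = 0.0

        if it >= n_burn:
            i = it - n_burn
            out_mu[i] = mu
            out_sig[i] = np.exp(lsig)
            out_rho[i] = rho_v
            out_m[i] = m

    return out_mu, out_sig, out_rho, out_m


def _sample_prior(spec: HierarchicalModelSpec, n, n_keep, rng):
    """Exact iid draws from the joint prior (likelihood disabled)."""
    t = spec.n_tasks
    pairs = list(combinations(range(t), 2))
    npairs = len(pairs)
    mu = rng.normal(0.0, spec.mu_prior_sd, (n_keep, t))
    phi = np.clip(
        rng.gamma(spec.sigma_prior_shape, 1.0 / spec.sigma_prior_rate, (n_keep, t)),
        1e-290, None,
    )
    sig = phi**-0.5
    rho = rng.uniform(-1.0, 1.0, (n_keep, npairs))
    if t > 2:  # element-wise uniform prior truncated to PSD matrices
        for i in range(n_keep):
            while not _is_pd(_rho_matrix(rho[i], pairs, t) + 1e-12 * np.eye(t)):
                rho[i] = rng.uniform(-1.0, 1.0, npairs)
    m = np.empty((n_keep, n, t))
    for i in range(n_keep):
        corr = _rho_matrix(rho[i], pairs, t)
        cov = corr * np.outer(sig[i], sig[i])
        evals, vecs = np.linalg.eigh(cov)
        sqrt_cov = vecs * np.sqrt(np.clip(evals, 0.0, None))
        m[i] = mu[i] + rng.standard_normal((n, t)) @ sqrt_cov.T
    return mu, sig, rho, m


# ---------------------------------------------------------------------------
# public fitting interface
# ---------------------------------------------------------------------------


def counts_by_subject_task(trials: pd.DataFrame, n_levels: int, collapse_to: int | None = None):
    """Split a trial table into a ``{(subject, task): CountsTable}`` dict."""
    from .sdt import build_counts

    out = {}
    for (subj, task), block in trials.groupby(["subject", "task"], sort=True):
        out[(subj, task)] = build_counts(block, n_levels, collapse_to)
    return out


def fit_hmetad_multitask(
    counts: dict,
    spec: HierarchicalModelSpec | None = None,
    mcmc: McmcConfig | None = None,
    prior_only: bool = False,
) -> HierarchicalPosterior:
    """Fit the multi-task hierarchical meta-d' model.

    ``counts`` maps ``(subject, task)`` to a :class:`CountsTable`; every
    subject must have counts for every task.  Type-1 d' and criterion are
    fixed per subject-task at their (log-linear corrected where needed) point
    estimates.  Emits a warning if any parameter's R-hat exceeds 1.1.
    With ``prior_only=True`` the data likelihood is disabled and the returned
    draws are exact samples from the joint prior.
    """
    subjects = sorted({s for s, _ in counts})
    tasks = sorted({t for _, t in counts})
    missing = [(s, t) for s in subjects for t in tasks if (s, t) not in counts]
    if missing:
        raise InvalidParameterError(f"missing counts for subject-task pairs: {missing[:5]}")
    n, t = len(subjects), len(tasks)
    spec = spec or HierarchicalModelSpec(n_tasks=t)
    if spec.n_tasks != t:
        raise InvalidParameterError(f"spec.n_tasks={spec.n_tasks} but counts contain {t} tasks")
    mcmc = mcmc or McmcConfig()

    k = counts[(subjects[0], tasks[0])].n_levels
    j2 = 2 * k - 2
    counts_arr = np.empty((n, t, 2, 2 * k))
    d1 = np.empty((n, t))
    cprime = np.empty((n, t))
    tau0 = np.empty((n, t, j2))
    for i, s in enumerate(subjects):
        for j, task in enumerate(tasks):
            ct = counts[(s, task)]
            if ct.n_levels != k:
                raise InvalidParameterError("all counts tables must share n_levels")
            est = compute_dprime(ct, correction="loglinear")
            dd = est.dprime
            if dd < 0.05:
                warnings.warn(
                    f"subject {s}, task {task}: estimated d'={dd:.3f} < 0.05; "
                    "flooring at 0.05 for the hierarchical fit",
                    stacklevel=2,
                )
                dd = 0.05
            counts_arr[i, j] = ct.stacked()
            d1[i, j] = dd
            cprime[i, j] = est.criterion / dd
            tau0[i, j] = empirical_tau(ct, dd, est.criterion / dd)

    pairs = list(combinations(range(t), 2))
    ss = np.random.SeedSequence(mcmc.seed)
    chain_seeds = ss.spawn(mcmc.n_chains)

    chains = []
    for c in range(mcmc.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        if prior_only:
            chains.append(_sample_prior(spec, n, mcmc.n_samples, rng))
        else:
            data = _SubjectData(counts_arr, d1, cprime, tau0, k)
            chains.append(
                _run_chain(data, spec, mcmc.n_samples, mcmc.n_burnin, rng, mcmc.adapt_every)
            )

    mu = np.stack([c[0] for c in chains])
    sigma = np.stack([c[1] for c in chains])
    rho = np.stack([c[2] for c in chains])
    log_m = np.stack([c[3] for c in chains])

    rhat = {}
    for j, task in enumerate(tasks):
        rhat[f"mu_M[{task}]"] = compute_rhat(mu[..., j])
        rhat[f"sigma_M[{task}]"] = compute_rhat(np.log(sigma[..., j]))
    for p, (i, j) in enumerate(pairs):
        rhat[f"rho[{tasks[i]},{tasks[j]}]"] = compute_rhat(rho[..., p])
    for i in range(n):
        for j in range(t):
            rhat[f"logM[{subjects[i]},{tasks[j]}]"] = compute_rhat(log_m[..., i, j])

    posterior = HierarchicalPosterior(
        tasks=tasks,
        subjects=subjects,
        pairs=pairs,
        mu=mu,
        sigma=sigma,
        rho=rho,
        log_mratio=log_m,
        rhat=rhat,
        meta={
            "n_chains": mcmc.n_chains,
            "n_samples": mcmc.n_samples,
            "n_burnin": mcmc.n_burnin,
            "seed": mcmc.seed,
            "prior_only": prior_only,
            "n_levels": k,
        },
    )
    if not prior_only and posterior.max_rhat() > 1.1:
        bad = {k_: v for k_, v in rhat.items() if v > 1.1}
        warnings.warn(
            f"convergence warning: R-hat > 1.1 for {sorted(bad)[:8]} "
            f"(max {posterior.max_rhat():.3f}); consider longer chains",
            stacklevel=2,
        )
    return posterior
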