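"""Independent brute-force oracles used to validate the estimators.

These deliberately avoid the implementation paths they check: d' from direct
rate arithmetic, AUROC2 by explicit enumeration of cumulative ROC points,
meta-d' by exhaustive grid search, the HDI by an exhaustive window scan and
R-hat from the textbook between/within variance formula.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtri

from metacov.sdt import CountsTable, _pad_if_needed, empirical_tau, type2_loglik


def dprime_oracle(counts: CountsTable):
    """d'/criterion by direct computation from hit and false-alarm counts."""
    k = counts.n_levels
    hr = (counts.nR_S2[k:].sum() + 0.5) / (counts.nR_S2.sum() + 1.0)
    fr = (counts.nR_S1[k:].sum() + 0.5) / (counts.nR_S1.sum() + 1.0)
    return ndtri(hr) - ndtri(fr), -0.5 * (ndtri(hr) + ndtri(fr))


def auroc2_oracle(counts: CountsTable):
    """Type-II ROC area by explicit trapezoid enumeration."""
    k = counts.n_levels
    correct = counts.nR_S1[:k][::-1] + counts.nR_S2[k:]
    incorrect = counts.nR_S2[:k][::-1] + counts.nR_S1[k:]
    # cumulative "conf >= level" proportions, highest level first
    h = [0.0]
    f = [0.0]
    for lvl in range(k - 1, -1, -1):
        h.append(h[-1] + correct[lvl] / correct.sum())
        f.append(f[-1] + incorrect[lvl] / incorrect.sum())
    area = 0.0
    for a in range(1, len(h)):
        area += 0.5 * (h[a] + h[a - 1]) * (f[a] - f[a - 1])
    return area


def grid_metad_oracle(counts: CountsTable, step=0.005, hi=5.0):
    """Exhaustive meta-d' grid search with nested cutpoint optimization.

    Evaluates the profile likelihood at every grid point (warm-starting the
    inner cutpoint optimization from the previous point) and returns the
    maximizing meta-d' and its log-likelihood.
    """
    from metacov.sdt import compute_dprime

    k = counts.n_levels
    sdt = compute_dprime(counts, correction="loglinear")
    cprime = sdt.criterion / sdt.dprime if abs(sdt.dprime) > 1e-8 else sdt.criterion
    stacked = _pad_if_needed(counts)
    tau = empirical_tau(counts, max(sdt.dprime, 0.1), cprime)
    grid = np.arange(0.0, hi + step / 2, step)
    best_md, best_ll = None, -np.inf
    bounds = [(-6.0, 3.0)] * (2 * k - 2)
    for md in grid:
        res = minimize(
            lambda ta: -type2_loglik(stacked, md, cprime, ta, k),
            tau,
            method="L-BFGS-B",
            bounds=bounds,
        )
        tau = res.x  # warm start the neighbouring grid point
        if -res.fun > best_ll:
            best_ll, best_md = -res.fun, md
    return best_md, best_ll


def hdi_oracle(samples, mass=0.95):
    """Narrowest interval by exhaustive scan over all sorted windows."""
    s = np.sort(np.asarray(samples, dtype=float))
    n = s.size
    m = int(np.ceil(mass * n))
    best = None
    for i in range(n - m + 1):
        w = s[i + m - 1] - s[i]
        if best is None or w < best[0]:
            best = (w, s[i], s[i + m - 1])
    return best[1], best[2]


def rhat_oracle(chains):
    """Gelman-Rubin from chain means and variances, written out longhand."""
    chains = np.asarray(chains, dtype=float)
    c, n = chains.shape
    means = chains.mean(axis=1)
    w = np.mean([np.var(chains[i], ddof=1) for i in range(c)])
    b_over_n = np.var(means, ddof=1)
    return np.sqrt(((n - 1) / n * w + b_over_n) / w)


def random_counts(rng, n_levels=3, n_trials=60):
    """A random small counts table from generative type-II SDT parameters."""
    from metacov.sdt import build_counts
    from metacov.simulate import SubjectTaskParams, simulate_subject_task

    params = SubjectTaskParams.with_default_criteria(
        dprime=rng.uniform(0.8, 2.5),
        metad=rng.uniform(0.4, 2.5),
        criterion=rng.uniform(-0.3, 0.3),
        n_levels=n_levels,
    )
    trials = simulate_subject_task(params, n_trials, seed=rng)
    return build_counts(trials, n_levels), params
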