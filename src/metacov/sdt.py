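"""Type-I and type-II signal detection estimators for 2AFC confidence data.

The canonical input to every estimator is a :class:`CountsTable`: for each
stimulus class, the counts of every (response, confidence) outcome ordered
from the highest-confidence "S1" response down to confidence 0, then from
confidence 0 up to the highest-confidence "S2" response.  With K confidence
levels each stimulus row has 2K cells; cell ``i`` corresponds to the interval
between consecutive decision-axis cutpoints, so the ordering coincides with
ascending position on the evidence axis.

Type-I sensitivity is ``d' = z(hit rate) - z(false-alarm rate)`` with "S2"
arbitrarily playing the role of signal, and criterion
``c = -(z(hit) + z(fa)) / 2``.  Type-II (metacognitive) sensitivity is
quantified either nonparametrically (area under the type-II ROC, AUROC2) or
model-based as meta-d': the type-I d' that an SDT-ideal rater would need in
order to produce the observed response-conditional confidence distributions.
meta-d'/d' ("Mratio") is the performance-controlled efficiency measure; 1 is
SDT-optimal.

The meta-d' observer model used throughout (also by the hierarchical module):
evidence for the confidence rating is distributed Normal(-meta-d'/2, 1) for
S1 stimuli and Normal(+meta-d'/2, 1) for S2 stimuli; the type-1 criterion is
carried over at its *relative* position, meta-c = (c/d')*meta-d'; confidence
arises by binning the evidence with ordered type-2 cutpoints, K-1 of them
below meta-c (for "S1" responses) and K-1 above (for "S2" responses).  The
likelihood is multinomial over response-conditional confidence cells.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

from .exceptions import DegenerateDataError, EstimationError, InvalidParameterError

_TINY = 1e-300


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountsTable:
    """Confidence-by-response counts per stimulus class.

    ``nR_S1[i]`` / ``nR_S2[i]`` count trials with stimulus S1 / S2 falling in
    canonical cell ``i`` (see module docstring for the ordering).
    """

    nR_S1: np.ndarray
    nR_S2: np.ndarray
    n_levels: int

    def __post_init__(self):
        nr1 = np.asarray(self.nR_S1, dtype=float)
        nr2 = np.asarray(self.nR_S2, dtype=float)
        object.__setattr__(self, "nR_S1", nr1)
        object.__setattr__(self, "nR_S2", nr2)
        k = int(self.n_levels)
        if k < 2:
            raise InvalidParameterError(f"n_levels must be >= 2, got {k}")
        for name, v in (("nR_S1", nr1), ("nR_S2", nr2)):
            if v.ndim != 1 or v.size != 2 * k:
                raise InvalidParameterError(
                    f"{name} must have length 2*n_levels={2 * k}, got shape {v.shape}"
                )
            if np.any(v < 0) or not np.all(np.isfinite(v)):
                raise InvalidParameterError(f"{name} must contain finite nonnegative counts")

    @property
    def n_trials(self) -> float:
        return float(self.nR_S1.sum() + self.nR_S2.sum())

    def stacked(self) -> np.ndarray:
        """(2, 2K) array, rows = stimulus S1, S2."""
        return np.stack([self.nR_S1, self.nR_S2])

    # -- confidence-by-accuracy marginals (used by AUROC2) ------------------

    def accuracy_histograms(self) -> tuple[np.ndarray, np.ndarray]:
        """(correct, incorrect) counts per confidence level 0..K-1."""
        k = self.n_levels
        correct = self.nR_S1[:k][::-1] + self.nR_S2[k:]
        incorrect = self.nR_S2[:k][::-1] + self.nR_S1[k:]
        return correct, incorrect

    # -- serialization ------------------------------------------------------

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# metacov counts; n_levels={self.n_levels}; "
                "cells ordered resp-S1 conf K-1..0 then resp-S2 conf 0..K-1\n"
            )
            pd.DataFrame(
                self.stacked(), index=["S1", "S2"],
                columns=[f"cell{i}" for i in range(2 * self.n_levels)],
            ).to_csv(fh, index_label="stimulus")

    @classmethod
    def from_csv(cls, path) -> "CountsTable":
        with open(path) as fh:
            header = fh.readline()
            if "n_levels=" not in header:
                raise InvalidParameterError(f"{path}: missing counts header with n_levels")
            k = int(header.split("n_levels=")[1].split(";")[0])
            df = pd.read_csv(io.StringIO(fh.read()), index_col="stimulus")
        return cls(df.loc["S1"].to_numpy(), df.loc["S2"].to_numpy(), k)


def collapse_levels(levels: np.ndarray, n_levels: int, collapse_to: int) -> np.ndarray:
    """Merge adjacent confidence levels into ``collapse_to`` equal-width bins."""
    if not 2 <= collapse_to <= n_levels:
        raise InvalidParameterError(
            f"collapse_to must be in [2, n_levels={n_levels}], got {collapse_to}"
        )
    return np.minimum((np.asarray(levels) * collapse_to) // n_levels, collapse_to - 1).astype(int)


def build_counts(trials: pd.DataFrame, n_levels: int, collapse_to: int | None = None) -> CountsTable:
    """Tabulate one subject-task block of trials into a :class:`CountsTable`.

    ``trials`` needs columns ``stimulus``, ``response`` (values "S1"/"S2") and
    ``confidence_level`` (integers < ``n_levels``).  ``collapse_to`` optionally
    merges adjacent levels into fewer, equal-width bins first.
    """
    if len(trials) == 0:
        raise DegenerateDataError("cannot build counts from an empty trial table")
    for col in ("subject", "task"):
        if col in trials.columns and trials[col].nunique() > 1:
            raise InvalidParameterError(
                f"trials mix multiple values of '{col}': {sorted(trials[col].unique())}"
            )
    conf = trials["confidence_level"].to_numpy()
    if np.any(conf < 0) or np.any(conf >= n_levels):
        raise InvalidParameterError(
            f"confidence levels outside [0, {n_levels - 1}] present"
        )
    k = n_levels
    if collapse_to is not None:
        conf = collapse_levels(conf, n_levels, collapse_to)
        k = collapse_to
    resp_s2 = (trials["response"] == "S2").to_numpy()
    stim_s2 = (trials["stimulus"] == "S2").to_numpy()
    # canonical cell index
    cell = np.where(resp_s2, k + conf, k - 1 - conf)
    out = np.zeros((2, 2 * k))
    np.add.at(out, (stim_s2.astype(int), cell), 1.0)
    return CountsTable(out[0], out[1], k)


# ---------------------------------------------------------------------------
# type-I d'
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SDTEstimate:
    dprime: float
    criterion: float
    hit_rate: float
    fa_rate: float


def compute_dprime(counts: CountsTable, correction: str = "loglinear") -> SDTEstimate:
    """Type-I d' and criterion from the response marginals of ``counts``.

    "S2" responses to S2 stimuli are hits, "S2" responses to S1 stimuli false
    alarms.  ``correction`` handles hit/FA rates of exactly 0 or 1:
    ``"loglinear"`` adds 0.5 to both numerators and 1 to both denominators
    (always, the standard log-linear rule); ``"none"`` raises on a 0/1 rate.
    """
    k = counts.n_levels
    n_s1, n_s2 = counts.nR_S1.sum(), counts.nR_S2.sum()
    if n_s1 == 0 or n_s2 == 0:
        raise DegenerateDataError("both stimulus classes must be present to compute d'")
    hits = counts.nR_S2[k:].sum()
    fas = counts.nR_S1[k:].sum()
    if correction == "loglinear":
        hr = (hits + 0.5) / (n_s2 + 1.0)
        fr = (fas + 0.5) / (n_s1 + 1.0)
    elif correction == "none":
        hr = hits / n_s2
        fr = fas / n_s1
        if hr in (0.0, 1.0) or fr in (0.0, 1.0):
            raise EstimationError(
                f"hit rate {hr} / false-alarm rate {fr} give an infinite d'; "
                "use correction='loglinear'"
            )
    else:
        raise InvalidParameterError(f"unknown correction {correction!r}")
    zh, zf = ndtri(hr), ndtri(fr)
    return SDTEstimate(
        dprime=float(zh - zf),
        criterion=float(-0.5 * (zh + zf)),
        hit_rate=float(hr),
        fa_rate=float(fr),
    )


# ---------------------------------------------------------------------------
# AUROC2
# ---------------------------------------------------------------------------


def compute_auroc2(counts: CountsTable) -> float:
    """Nonparametric area under the type-II ROC.

    The ROC is traced by cumulating the confidence distributions of correct
    ("type-II hits") and incorrect ("type-II false alarms") trials from the
    highest confidence level down; the area is the trapezoidal integral.
    0.5 is chance; 1.0 is perfect confidence-accuracy separation.
    """
    correct, incorrect = counts.accuracy_histograms()
    nc, ni = correct.sum(), incorrect.sum()
    if nc == 0 or ni == 0:
        raise DegenerateDataError(
            "AUROC2 requires at least one correct and one incorrect trial"
        )
    tpr = np.concatenate([[0.0], np.cumsum(correct[::-1]) / nc])
    fpr = np.concatenate([[0.0], np.cumsum(incorrect[::-1]) / ni])
    return float(np.trapezoid(tpr, fpr))


# ---------------------------------------------------------------------------
# meta-d' observer model: shared likelihood machinery
# ---------------------------------------------------------------------------


def criteria_from_tau(meta_d, cprime, tau):
    """Absolute type-2 cutpoints from log-gap parameters.

    ``tau`` has length 2(K-1): the first K-1 entries are log gaps walking
    *down* from meta-c (response-"S1" cutpoints), the rest log gaps walking
    *up* (response-"S2" cutpoints).  Returns the 2K-1 inner cutpoints in
    ascending order, with meta-c itself in the middle.  Broadcasts over
    leading dimensions of ``meta_d``/``cprime``/``tau``.
    """
    meta_d = np.asarray(meta_d, dtype=float)
    tau = np.asarray(tau, dtype=float)
    j = tau.shape[-1] // 2
    meta_c = np.asarray(cprime, dtype=float) * meta_d
    below = meta_c[..., None] - np.cumsum(np.exp(tau[..., :j]), axis=-1)[..., ::-1]
    above = meta_c[..., None] + np.cumsum(np.exp(tau[..., j:]), axis=-1)
    return np.concatenate([below, meta_c[..., None], above], axis=-1)


def type2_logprobs(meta_d, cprime, tau, n_levels: int):
    """Log response-conditional confidence-cell probabilities.

    Returns an array of shape ``(..., 2, 2K)``: axis -2 indexes the stimulus
    (S1, S2), axis -1 the canonical cells.  Each cell probability is
    conditioned on its own response region (the type-1 response counts carry
    no information about meta-d').
    """
    k = n_levels
    meta_d = np.asarray(meta_d, dtype=float)
    bounds = criteria_from_tau(meta_d, cprime, tau)  # (..., 2K-1)
    mu = meta_d / 2.0
    # stimulus means -mu (S1) and +mu (S2)
    cdf = ndtr(bounds[..., None, :] - np.stack([-mu, mu], axis=-1)[..., None])
    shape = cdf.shape[:-1]
    pad0 = np.zeros(shape + (1,))
    pad1 = np.ones(shape + (1,))
    cells = np.diff(np.concatenate([pad0, cdf, pad1], axis=-1), axis=-1)  # (...,2,2K)
    mass_s1 = cdf[..., k - 1]  # P(respond "S1" | stim), cutpoint k-1 is meta-c
    mass = np.concatenate(
        [
            np.repeat(mass_s1[..., None], k, axis=-1),
            np.repeat((1.0 - mass_s1)[..., None], k, axis=-1),
        ],
        axis=-1,
    )
    return np.log(np.clip(cells, _TINY, None)) - np.log(np.clip(mass, _TINY, None))


def type2_loglik(counts_stacked, meta_d, cprime, tau, n_levels: int):
    """Multinomial log-likelihood of response-conditional confidence counts.

    ``counts_stacked`` is ``(..., 2, 2K)``; broadcasts with the parameter
    arrays; returns shape ``(...,)``.
    """
    lp = type2_logprobs(meta_d, cprime, tau, n_levels)
    return np.sum(counts_stacked * lp, axis=(-2, -1))


def invert_type2_quantiles(meta_d, meta_c, probs_s1, probs_s2, min_gap=1e-2):
    """Type-2 cutpoints hitting given response-conditional cumulative masses.

    For each response side, places cutpoints so that (under the meta-d'
    observer with an equal stimulus mixture) the conditional cumulative
    probability at cutpoint j equals ``probs_*[j]``.  ``probs_s1`` are masses
    accumulated from meta-c *downwards* (so the cutpoints walk down),
    ``probs_s2`` from meta-c upwards.  Returns ``tau`` log-gap parameters of
    length ``2 * len(probs_s1)``.
    """
    probs_s1 = np.clip(np.asarray(probs_s1, dtype=float), 1e-3, 1 - 1e-3)
    probs_s2 = np.clip(np.asarray(probs_s2, dtype=float), 1e-3, 1 - 1e-3)
    mu = meta_d / 2.0
    span = np.linspace(0.0, 8.0 + abs(meta_c) + meta_d, 400)

    def side(probs, sign):
        x = meta_c + sign * span
        # equal-weight stimulus mixture restricted to the response side
        cdf_mix = 0.5 * (ndtr(x + mu) + ndtr(x - mu))
        at_c = 0.5 * (ndtr(meta_c + mu) + ndtr(meta_c - mu))
        if sign > 0:
            cond = (cdf_mix - at_c) / max(1.0 - at_c, 1e-12)
        else:
            cond = (at_c - cdf_mix) / max(at_c, 1e-12)
        cond = np.clip(cond, 0.0, 1.0)
        offs = np.interp(probs, cond, span)
        gaps = np.maximum(np.diff(np.concatenate([[0.0], offs])), min_gap)
        return np.log(gaps)

    return np.concatenate([side(probs_s1, -1.0), side(probs_s2, +1.0)])


def default_tau(meta_d, cprime, n_levels: int):
    """Log-gap cutpoints giving roughly uniform confidence usage per response."""
    k = n_levels
    q = np.arange(1, k) / k
    return invert_type2_quantiles(meta_d, cprime * meta_d, q, q)


def empirical_tau(counts: CountsTable, meta_d: float, cprime: float) -> np.ndarray:
    """Data-driven cutpoint initialisation / prior centre.

    Inverts the observed response-conditional confidence quantiles (pooled
    over stimuli, with 1/(2K) padding against empty cells) under the observer
    model evaluated at ``meta_d``.
    """
    k = counts.n_levels
    pooled = counts.nR_S1 + counts.nR_S2 + 1.0 / (2 * k)
    resp1 = pooled[:k]  # conf K-1 .. 0, i.e. walking down from meta-c reversed
    resp2 = pooled[k:]  # conf 0 .. K-1 walking up
    # cumulative mass from meta-c outwards, excluding the final (total) point
    p1 = np.cumsum(resp1[::-1])[:-1] / resp1.sum()
    p2 = np.cumsum(resp2)[:-1] / resp2.sum()
    return invert_type2_quantiles(meta_d, cprime * meta_d, p1, p2)


# ---------------------------------------------------------------------------
# single-subject MLE
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetadFit:
    """Single-subject maximum-likelihood type-II fit."""

    metad: float
    mratio: float
    dprime: float
    criterion: float
    type2_criteria: np.ndarray
    loglik: float
    convergence_flag: str
    n_levels: int
    tau: np.ndarray = field(repr=False, default=None)


def _pad_if_needed(counts: CountsTable) -> np.ndarray:
    """Log-linear padding, applied only when a (stimulus, response) family is empty."""
    k = counts.n_levels
    stacked = counts.stacked()
    fam = np.array(
        [stacked[0, :k].sum(), stacked[0, k:].sum(), stacked[1, :k].sum(), stacked[1, k:].sum()]
    )
    if np.any(fam == 0):
        return stacked + 1.0 / (2 * k)
    return stacked


def fit_metad_mle(
    counts: CountsTable,
    correction: str = "loglinear",
    max_metad: float = 8.0,
    n_starts: int = 3,
) -> MetadFit:
    """Maximum-likelihood meta-d' for one subject-task counts table.

    The type-1 criterion is fixed at its empirical relative position
    (c' = c/d', scaled by meta-d'); meta-d' and the ordered type-2 cutpoints
    maximize the response-conditional multinomial likelihood.  Cutpoints are
    parameterized as log gaps so ordering holds by construction.
    """
    k = counts.n_levels
    sdt = compute_dprime(counts, correction=correction)
    if abs(sdt.dprime) < 1e-8:
        cprime = sdt.criterion
    else:
        cprime = sdt.criterion / sdt.dprime

    # degenerate: a single confidence level used -> type-II ROC is the diagonal
    correct, incorrect = counts.accuracy_histograms()
    used = (correct + incorrect) > 0
    if used.sum() <= 1:
        tau = default_tau(max(sdt.dprime, 0.1), cprime, k)
        return MetadFit(
            metad=0.0,
            mratio=0.0,
            dprime=sdt.dprime,
            criterion=sdt.criterion,
            type2_criteria=criteria_from_tau(0.0, cprime, tau),
            loglik=float(type2_loglik(counts.stacked(), 0.0, cprime, tau, k)),
            convergence_flag="degenerate",
            n_levels=k,
            tau=tau,
        )

    stacked = _pad_if_needed(counts)

    def negll(x):
        return -float(type2_loglik(stacked, x[0], cprime, x[1:], k))

    d0 = float(np.clip(sdt.dprime, 0.1, max_metad - 0.5))
    tau0 = empirical_tau(counts, d0, cprime)
    bounds = [(0.0, max_metad)] + [(-6.0, 3.0)] * (2 * k - 2)
    starts = [np.concatenate([[d0], tau0])]
    for frac in (0.5, 1.5)[: max(0, n_starts - 1)]:
        starts.append(np.concatenate([[np.clip(d0 * frac, 0.0, max_metad)], tau0]))

    best = None
    any_success = False
    for x0 in starts:
        res = minimize(negll, x0, method="L-BFGS-B", bounds=bounds)
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    metad = float(best.x[0])
    tau = best.x[1:].copy()
    return MetadFit(
        metad=metad,
        mratio=metad / sdt.dprime if sdt.dprime != 0 else np.nan,
        dprime=sdt.dprime,
        criterion=sdt.criterion,
        type2_criteria=criteria_from_tau(metad, cprime, tau),
        loglik=-float(best.fun),
        convergence_flag="converged" if any_success else "max-iter",
        n_levels=k,
        tau=tau,
    )
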