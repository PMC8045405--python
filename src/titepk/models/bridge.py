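"""Bridging CRM: carry a completed schedule's dose-toxicity estimate into
the CRM skeletons of the next schedule.

From the completed schedule's binomial counts, two per-level DLT-probability
estimates are formed: a parametric probit curve Phi(b0 + b1 * dose) and the
nonparametric isotonic (pooled-adjacent-violators) estimate.  They are
blended level-by-level with weights derived from the likelihood ratio of the
two estimates, giving a mixture estimate that trusts whichever explains the
data better at that level.  The mixture, plus copies shifted one dose level
up and down to admit between-schedule heterogeneity, yields three candidate
skeletons; the next schedule's data are analysed by averaging the three
resulting CRM posteriors with weights proportional to their marginal
likelihoods (equal prior model weights).

Dose levels of the two schedules are matched by rank: skeleton position j of
the new schedule inherits the estimate at dose level j of the completed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import isotonic_regression, minimize
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .crm import CRM

__all__ = [
    "ProbitFit",
    "bridged_mixture",
    "probit_fit",
    "pava_isotonic",
    "mixture_estimate",
    "bridge_skeletons",
    "BridgingCRM",
]

_EPS = 1e-6  # probability clip used before likelihood-ratio evaluation


@dataclass(frozen=True)
class ProbitFit:
    """Maximum-likelihood probit dose-response fit on standardised dose."""

    beta0: float
    beta1: float
    dose_center: float
    dose_scale: float

    def predict(self, doses) -> np.ndarray:
        z = (np.asarray(doses, dtype=float) - self.dose_center) / self.dose_scale
        return norm.cdf(self.beta0 + self.beta1 * z)


def probit_fit(doses, x, m, bound: float = 10.0) -> ProbitFit:
    """Probit MLE of per-dose DLT counts, with bounded coefficients.

    The dose axis is standardised before fitting and both coefficients are
    constrained to ``[-bound, bound]``, which keeps the fit finite for
    separated data (e.g. a dose level with zero events).
    """
    doses = np.asarray(doses, dtype=float)
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    if doses.size == 0:
        raise ValueError("need at least one dose level")
    center = doses.mean()
    scale = doses.std(ddof=1) if doses.size > 1 else 1.0
    if scale == 0:
        scale = 1.0
    z = (doses - center) / scale

    def nll(theta):
        p = np.clip(norm.cdf(theta[0] + theta[1] * z), 1e-12, 1 - 1e-12)
        return -(x * np.log(p) + (m - x) * np.log1p(-p)).sum()

    best = None
    for start in ([0.0, 1.0], [0.0, 0.0], [-1.0, 2.0]):
        res = minimize(nll, start, bounds=[(-bound, bound)] * 2, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    return ProbitFit(float(best.x[0]), float(best.x[1]), float(center), float(scale))


def pava_isotonic(x, m) -> np.ndarray:
    """Weighted isotonic (nondecreasing) MLE of per-level event rates.

    Equivalent to the max-min formula
    ``pi_j = max_{u<=j} min_{v>=j} sum(x[u:v+1]) / sum(m[u:v+1])``,
    computed by pooled adjacent violators.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    if x.shape != m.shape:
        raise ValueError("x and m must have equal length")
    if np.any(m <= 0):
        raise ValueError("every level needs at least one patient")
    return isotonic_regression(x / m, weights=m).x


def mixture_estimate(pi_parametric, pi_isotonic, x, m, eps: float = _EPS):
    """Likelihood-ratio blend of the parametric and isotonic estimates.

    Per level, ``lambda_j`` is the binomial likelihood ratio of the two
    estimates (probabilities clipped to ``[eps, 1-eps]``), the weight is
    ``lambda_j / (lambda_j + 1)`` and the blended estimate is
    ``w * parametric + (1 - w) * isotonic``.  A level with no patients gets
    weight 1/2.

    Returns ``(weights, mixture)``.
    """
    pp = np.clip(np.asarray(pi_parametric, dtype=float), eps, 1 - eps)
    pn = np.clip(np.asarray(pi_isotonic, dtype=float), eps, 1 - eps)
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    log_lam = x * (np.log(pp) - np.log(pn)) + (m - x) * (
        np.log1p(-pp) - np.log1p(-pn)
    )
    w = 1.0 / (1.0 + np.exp(-log_lam))  # lambda / (lambda + 1)
    return w, w * pp + (1 - w) * pn


def bridged_mixture(doses, x, m, probit_bound: float = 10.0):
    """Mixture DLT-probability estimate across a dose grid, tolerating
    untried levels.

    The probit curve is fitted to the levels with patients and evaluated on
    the whole grid; the isotonic estimate is computed on the tried levels
    and carried to untried ones as a step function.  Untried levels get
    blend weight 1/2 (an empty binomial likelihood ratio is 1).

    Returns ``(weights, mixture)`` over the full grid.
    """
    doses = np.asarray(doses, dtype=float)
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    tried = m > 0
    if not tried.any():
        raise ValueError("at least one dose level needs patients")
    fit = probit_fit(doses[tried], x[tried], m[tried], bound=probit_bound)
    pi_p = fit.predict(doses)
    iso = pava_isotonic(x[tried], m[tried])
    # carry the isotonic step function onto untried levels
    idx_tried = np.flatnonzero(tried)
    pos = np.clip(np.searchsorted(idx_tried, np.arange(doses.size), "right") - 1,
                  0, idx_tried.size - 1)
    pi_np = iso[pos]
    w, mix = mixture_estimate(pi_p, pi_np, x, m)
    return w, mix, fit


def _strictly_increasing(p: np.ndarray, eps: float = _EPS) -> np.ndarray:
    """Clip into (0, 1) and nudge ties so the vector strictly increases."""
    p = np.clip(np.asarray(p, dtype=float), eps, 1 - eps).copy()
    for j in range(1, p.size):
        if p[j] <= p[j - 1]:
            p[j] = min(p[j - 1] + eps, 1 - eps)
    return p


def bridge_skeletons(pi_mixture) -> list[np.ndarray]:
    """Three candidate skeletons from a bridged estimate.

    Skeleton 1 is the estimate itself; skeleton 2 shifts the curve one dose
    level up (``p_j = pi_{j+1}``, top level ``(pi_J + 1) / 2``); skeleton 3
    one level down (``p_j = pi_{j-1}``, bottom level ``pi_1 / 2``).
    """
    pi = np.asarray(pi_mixture, dtype=float)
    if pi.size < 2:
        raise ValueError("need at least two dose levels to shift")
    s1 = pi.copy()
    s2 = np.append(pi[1:], (pi[-1] + 1.0) / 2.0)
    s3 = np.concatenate(([pi[0] / 2.0], pi[:-1]))
    return [_strictly_increasing(s) for s in (s1, s2, s3)]


class BridgingCRM(BaseEstimator):
    """Model-averaged CRM over bridged skeletons.

    Build the estimator from the completed schedule's counts with
    :meth:`from_completed_schedule` (or pass precomputed ``skeletons``), then
    :meth:`fit` the new schedule's per-level counts.  Posterior summaries are
    averages of the per-skeleton CRM posteriors, weighted by marginal
    likelihood.
    """

    def __init__(
        self,
        skeletons=None,
        target: float = 0.30,
        prior_sd: float = 2.0,
        n_grid: int = 4001,
        span: float = 10.0,
    ):
        self.skeletons = skeletons
        self.target = target
        self.prior_sd = prior_sd
        self.n_grid = n_grid
        self.span = span

    @classmethod
    def from_completed_schedule(
        cls, doses, x, m, probit_bound: float = 10.0, **kwargs
    ) -> "BridgingCRM":
        """Derive the three skeletons from completed-schedule counts."""
        _, mix, fit = bridged_mixture(doses, x, m, probit_bound=probit_bound)
        est = cls(skeletons=bridge_skeletons(mix), **kwargs)
        est.probit_ = fit
        est.mixture_ = mix
        return est

    def fit(self, x, m=None) -> "BridgingCRM":
        """Fit one CRM per skeleton and average by marginal likelihood."""
        if self.skeletons is None:
            raise ValueError(
                "no skeletons; use from_completed_schedule or pass skeletons"
            )
        self.crms_ = [
            CRM(
                skeleton=s,
                target=self.target,
                prior_sd=self.prior_sd,
                n_grid=self.n_grid,
                span=self.span,
            ).fit(x, m)
            for s in self.skeletons
        ]
        lm = np.array([c.log_marginal_ for c in self.crms_])
        lm -= lm.max()
        w = np.exp(lm)  # equal prior model weights
        self.model_weights_ = w / w.sum()
        self.pi_mean_ = np.einsum(
            "k,kj->j", self.model_weights_, [c.pi_mean_ for c in self.crms_]
        )
        return self

    def exceed_prob(self, level: int, threshold: float) -> float:
        return float(
            sum(
                w * c.exceed_prob(level, threshold)
                for w, c in zip(self.model_weights_, self.crms_)
            )
        )

    def recommend(self, n_levels: int | None = None) -> int:
        means = self.pi_mean_ if n_levels is None else self.pi_mean_[:n_levels]
        return int(np.argmin(np.abs(means - self.target)))

    def safety_stop(self, threshold: float = 0.30, level: float = 0.90) -> bool:
        return self.exceed_prob(0, threshold) > level
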