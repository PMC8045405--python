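"""Continual reassessment method (CRM) with the one-parameter power model.

The working model links a prespecified skeleton ``p_1 < ... < p_J`` of
dose-wise DLT probabilities to the true probabilities through

    pi_j = p_j ** exp(alpha),       alpha ~ Normal(0, prior_sd^2).

The skeleton is calibrated with the indifference-interval method: the value
at the anticipated MTD position equals the target, and adjacent values are
spaced so that the model is indifferent between neighbouring doses exactly
when the current estimate sits a halfwidth ``delta`` away from the target.

The posterior over ``alpha`` is one-dimensional and computed by quadrature.
Escalation recommends the dose whose posterior-mean DLT probability is
closest to the target (ties to the lower dose); the safety rule stops the
trial when the lowest dose is too toxic with high posterior probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.base import BaseEstimator

__all__ = ["Skeleton", "lee_cheung_skeleton", "CRM"]


@dataclass(frozen=True)
class Skeleton:
    """Prior skeleton with its calibration anchors."""

    probs: tuple[float, ...]
    target: float = 0.30
    halfwidth: float = 0.10
    prior_mtd: int = 1  # 1-based index nu with probs[nu-1] == target

    def __post_init__(self) -> None:
        p = np.asarray(self.probs)
        if p.size == 0 or np.any(p <= 0) or np.any(p >= 1):
            raise ValueError("skeleton values must lie strictly in (0, 1)")
        if np.any(np.diff(p) <= 0):
            raise ValueError("skeleton must be strictly increasing")


def lee_cheung_skeleton(
    target: float, halfwidth: float, nu: int, n_levels: int
) -> np.ndarray:
    """Indifference-interval skeleton for the power model.

    Sets ``p_nu = target``.  Going up, the next value is chosen so that at
    the exponent where the current level reads ``target - halfwidth`` (the
    point of indifference for escalating), the next level reads
    ``target + halfwidth``; going down is the mirror image.  With target
    0.30 and halfwidth 0.10 this reproduces the familiar six-level skeleton
    (0.02, 0.12, 0.30, 0.50, 0.68, 0.80) for ``nu=3``.
    """
    if not (0 < target < 1):
        raise ValueError("target must lie in (0, 1)")
    if not (0 < halfwidth < min(target, 1 - target)):
        raise ValueError("halfwidth must lie in (0, min(target, 1-target))")
    if not (1 <= nu <= n_levels):
        raise ValueError("prior MTD index nu must lie in 1..n_levels")
    p = np.empty(n_levels)
    p[nu - 1] = target
    for k in range(nu - 1, n_levels - 1):
        # exponent at which level k reads target - halfwidth
        a = np.log(target - halfwidth) / np.log(p[k])
        p[k + 1] = (target + halfwidth) ** (1.0 / a)
    for k in range(nu - 1, 0, -1):
        # exponent at which level k reads target + halfwidth
        a = np.log(target + halfwidth) / np.log(p[k])
        p[k - 1] = (target - halfwidth) ** (1.0 / a)
    return p


class CRM(BaseEstimator):
    """One-parameter power-model CRM fitted by quadrature.

    ``skeleton`` may be a :class:`Skeleton` or a plain increasing sequence.
    Count data are aligned to skeleton positions by dose level (rank).

    Attributes after :meth:`fit`
    ----------------------------
    alpha_ : ndarray            quadrature nodes for alpha
    weights_ : ndarray          normalised posterior weights
    pi_mean_ : ndarray          posterior-mean DLT probability per level
    log_marginal_ : float       log integrated likelihood (for model averaging)
    """

    def __init__(
        self,
        skeleton=None,
        target: float = 0.30,
        prior_sd: float = 2.0,
        n_grid: int = 4001,
        span: float = 10.0,
    ):
        self.skeleton = skeleton
        self.target = target
        self.prior_sd = prior_sd
        self.n_grid = n_grid
        self.span = span

    def _probs(self) -> np.ndarray:
        sk = self.skeleton
        if sk is None:
            raise ValueError("a skeleton is required")
        if isinstance(sk, Skeleton):
            return np.asarray(sk.probs, dtype=float)
        return np.asarray(sk, dtype=float)

    def fit(self, x, m=None) -> "CRM":
        """Fit to per-level counts.

        ``x``/``m`` are DLT and patient counts aligned to skeleton levels
        (shorter arrays cover the lowest levels).  ``fit(None)`` reproduces
        the prior.
        """
        p = self._probs()
        if x is None:
            x = m = np.zeros(0)
        x = np.asarray(x, dtype=float)
        m = np.asarray(m, dtype=float)
        if x.size > p.size:
            raise ValueError("more data levels than skeleton levels")
        a = np.linspace(-self.span * self.prior_sd, self.span * self.prior_sd, self.n_grid)
        theta = np.exp(a)
        ll = np.zeros_like(a)
        for j in range(x.size):
            pij = np.clip(p[j] ** theta, 1e-300, 1 - 1e-16)
            ll += x[j] * np.log(pij) + (m[j] - x[j]) * np.log1p(-pij)
        lp = ll + norm.logpdf(a, 0.0, self.prior_sd)
        mx = lp.max()
        w = np.exp(lp - mx)
        da = a[1] - a[0]
        self.log_marginal_ = float(mx + np.log(w.sum() * da))
        w /= w.sum()
        self.alpha_ = a
        self.weights_ = w
        self.pi_mean_ = np.array([(p[j] ** theta) @ w for j in range(p.size)])
        return self

    def pi_dist(self, level: int):
        """Posterior (values, weights) of pi at a 0-based dose level."""
        p = self._probs()
        return p[level] ** np.exp(self.alpha_), self.weights_

    def exceed_prob(self, level: int, threshold: float) -> float:
        """Posterior P(pi_level > threshold)."""
        pi, w = self.pi_dist(level)
        return float(w[pi > threshold].sum())

    def recommend(self, n_levels: int | None = None) -> int:
        """0-based level with posterior-mean pi closest to the target.

        Ties are broken toward the lower dose.
        """
        means = self.pi_mean_ if n_levels is None else self.pi_mean_[:n_levels]
        return int(np.argmin(np.abs(means - self.target)))

    def safety_stop(self, threshold: float = 0.30, level: float = 0.90) -> bool:
        """Stop iff P(pi at the lowest dose > threshold) exceeds ``level``
        (strict inequality: exactly at the level the trial continues)."""
        return self.exceed_prob(0, threshold) > level
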