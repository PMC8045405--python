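"""Time-to-event exposure-toxicity model (TITE-PK).

The time to a patient's first dose-limiting toxicity (DLT) in cycle 1 is
modelled as the first event of a nonhomogeneous Poisson process whose hazard
is proportional to the scaled drug exposure,

    h(t) = beta * E(t),        H(t) = beta * AUC_E(t),

so the probability of at least one DLT by the end of cycle 1 under a regimen
(d, f) is ``1 - exp(-beta * AUC_E(t* | d, f))``.  Because the reference
schedule has ``AUC_E(t*) = 1`` by construction, ``cloglog`` of the reference
end-of-cycle DLT probability equals ``log(beta)``, which makes prior
elicitation on ``log(beta)`` as transparent as on a reference-dose DLT
probability: the default prior centres the reference-schedule probability at
0.30 with standard deviation 1.25 on the cloglog scale.

``beta`` is the model's only parameter, so the default posterior backend is
deterministic quadrature on a dense ``log(beta)`` grid; an ensemble-MCMC
backend is available as a cross-check.

Data from any mixture of schedules enter one likelihood — pooling across
sequentially investigated schedules needs no dose rescaling and no prior
machinery, the exposure model does the bridging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm
from sklearn.base import BaseEstimator

from ..pk import (
    PKParams,
    ReferenceSchedule,
    Regimen,
    auc_ceff,
    ceff_profile,
    exposure_scale_factor,
)

__all__ = ["SubjectEvent", "TITEPK", "cloglog", "inv_cloglog"]


def cloglog(p):
    """Complementary log-log link, log(-log(1-p))."""
    return np.log(-np.log1p(-np.asarray(p, dtype=float)))


def inv_cloglog(x):
    """Inverse of :func:`cloglog`: 1 - exp(-exp(x))."""
    return -np.expm1(-np.exp(np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class SubjectEvent:
    """One patient's regimen and cycle-1 follow-up.

    ``time`` is the time of the first DLT (``dlt=1``) or of censoring
    (``dlt=0``), in hours from the first administration.  Patients who finish
    cycle 1 without a DLT are censored at the cycle end; administrative
    censoring before the cycle end is also accepted.
    """

    regimen: Regimen
    time: float
    dlt: int

    def __post_init__(self) -> None:
        if not (0 < self.time <= self.regimen.cycle_length):
            raise ValueError(
                f"event time must lie in (0, {self.regimen.cycle_length}], "
                f"got {self.time}"
            )
        if self.dlt not in (0, 1):
            raise ValueError(f"dlt indicator must be 0 or 1, got {self.dlt}")


class TITEPK(BaseEstimator):
    """Exposure-based time-to-first-DLT model with EWOC dose recommendation.

    Parameters
    ----------
    pk : PKParams
        Known kinetic constants (elimination half-life, effect delay).
    ref : Regimen
        Reference schedule; its cycle-1 exposure AUC is normalised to 1.
    prior_p_ref : float, default 0.30
        Anticipated end-of-cycle-1 DLT probability at the reference schedule;
        the prior for ``log(beta)`` is Normal(cloglog(prior_p_ref), prior_sd^2).
    prior_sd : float, default 1.25
    interval : (float, float), default (0.20, 0.40)
        Targeted-toxicity interval bounds (x, y) for the three-way
        classification underdosing / targeted / overdosing.
    feasibility : float, default 0.25
        EWOC bound: a regimen is admissible iff P(overdosing) < feasibility
        (strict).
    escalation_rule : {"highest_auc", "lowest_auc"}, default "highest_auc"
        Among EWOC-admissible candidates, recommend the one with the highest
        (default) or lowest cycle-1 exposure AUC.
    backend : {"grid", "mcmc"}, default "grid"
    n_grid : int, default 2001
        Quadrature nodes on the log(beta) grid.
    span : float, default 8.0
        Grid half-width in prior standard deviations.

    Attributes
    ----------
    log_beta_ : ndarray
        Posterior support points of log(beta) (grid nodes or MCMC draws).
    weights_ : ndarray
        Normalised posterior weights (uniform for MCMC draws).
    scale_ : float
        Exposure scale factor A of the reference schedule.
    n_events_ : int
    """

    def __init__(
        self,
        pk: PKParams | None = None,
        ref: Regimen | None = None,
        prior_p_ref: float = 0.30,
        prior_sd: float = 1.25,
        interval: tuple[float, float] = (0.20, 0.40),
        feasibility: float = 0.25,
        escalation_rule: str = "highest_auc",
        backend: str = "grid",
        n_grid: int = 2001,
        span: float = 8.0,
        mcmc_draws: int = 4000,
        mcmc_burn: int = 1000,
        random_state: int = 0,
    ):
        self.pk = pk
        self.ref = ref
        self.prior_p_ref = prior_p_ref
        self.prior_sd = prior_sd
        self.interval = interval
        self.feasibility = feasibility
        self.escalation_rule = escalation_rule
        self.backend = backend
        self.n_grid = n_grid
        self.span = span
        self.mcmc_draws = mcmc_draws
        self.mcmc_burn = mcmc_burn
        self.random_state = random_state

    # -- resolution of defaults -------------------------------------------

    def _pk(self) -> PKParams:
        return self.pk if self.pk is not None else PKParams(30.0, 0.37)

    def _ref(self) -> ReferenceSchedule:
        reg = self.ref if self.ref is not None else Regimen(5.0, 24.0, 504.0)
        return ReferenceSchedule(reg)

    def _check(self) -> None:
        x, y = self.interval
        if not (0 < x < y < 1):
            raise ValueError(f"interval bounds must satisfy 0 < x < y < 1: {self.interval}")
        if not (0 < self.feasibility < 1):
            raise ValueError("feasibility bound must lie in (0, 1)")
        if not (self.prior_sd > 0):
            raise ValueError("prior_sd must be positive")
        if self.escalation_rule not in ("highest_auc", "lowest_auc"):
            raise ValueError(f"unknown escalation_rule {self.escalation_rule!r}")

    # -- likelihood --------------------------------------------------------

    def _suff_stats(self, subjects: Sequence[SubjectEvent]):
        """(number of events, sum of log E(T_j) over events, sum of AUC_E)."""
        pk, ref = self._pk(), self._ref()
        A = exposure_scale_factor(ref, pk)
        n_events = 0
        sum_log_e = 0.0
        sum_auc = 0.0
        for s in subjects:
            sum_auc += auc_ceff(s.regimen, pk, s.time) / A
            if s.dlt:
                n_events += 1
                e = ceff_profile(s.regimen, pk, s.time)[0] / A
                if e <= 0:
                    raise ValueError(
                        "a DLT was recorded at a time with zero exposure"
                    )
                sum_log_e += np.log(e)
        return n_events, sum_log_e, sum_auc, A

    def log_likelihood(self, log_beta, subjects: Sequence[SubjectEvent]):
        """Log-likelihood of the pooled subject records at ``log_beta``.

        Censored subjects contribute the survivor term ``-beta * AUC_E(T)``,
        subjects with a DLT additionally the log-hazard ``log(beta * E(T))``.
        """
        n_ev, s_loge, s_auc, _ = self._suff_stats(subjects)
        lb = np.asarray(log_beta, dtype=float)
        return n_ev * lb + s_loge - np.exp(lb) * s_auc

    # -- fitting -----------------------------------------------------------

    def fit(self, subjects: Sequence[SubjectEvent], y=None) -> "TITEPK":
        """Compute the posterior of log(beta) from pooled subject records."""
        self._check()
        subjects = list(subjects)
        prior_mean = float(cloglog(self.prior_p_ref))
        n_ev, s_loge, s_auc, A = self._suff_stats(subjects)
        self.scale_ = A
        self.n_events_ = n_ev
        self.prior_mean_ = prior_mean
        self.subjects_ = subjects

        if self.backend == "grid":
            lb = np.linspace(
                prior_mean - self.span * self.prior_sd,
                prior_mean + self.span * self.prior_sd,
                self.n_grid,
            )
            logpost = (
                n_ev * lb
                - np.exp(lb) * s_auc
                + norm.logpdf(lb, prior_mean, self.prior_sd)
            )
            logpost -= logpost.max()
            w = np.exp(logpost)
            total = w.sum()
            if not np.isfinite(total) or total <= 0:
                raise ValueError("degenerate posterior: likelihood vanished on grid")
            self.log_beta_ = lb
            self.weights_ = w / total
        elif self.backend == "mcmc":
            self.log_beta_ = self._mcmc(prior_mean, n_ev, s_auc)
            self.weights_ = np.full(self.log_beta_.size, 1.0 / self.log_beta_.size)
        else:
            raise ValueError(f"unknown backend {self.backend!r}")
        return self

    def _mcmc(self, prior_mean: float, n_ev: int, s_auc: float) -> np.ndarray:
        import emcee

        def logpost(p):
            lb = p[:, 0]
            return (
                n_ev * lb
                - np.exp(lb) * s_auc
                + norm.logpdf(lb, prior_mean, self.prior_sd)
            )

        rng = np.random.default_rng(self.random_state)
        nw = 16
        p0 = prior_mean + 0.5 * rng.standard_normal((nw, 1))
        sampler = emcee.EnsembleSampler(nw, 1, logpost, vectorize=True)
        steps = self.mcmc_burn + max(1, self.mcmc_draws // nw)
        sampler.run_mcmc(p0, steps, progress=False)
        return sampler.get_chain(discard=self.mcmc_burn, flat=True)[:, 0]

    # -- posterior functionals ----------------------------------------------

    def auc_cycle1(self, regimen: Regimen) -> float:
        """Cycle-1 exposure AUC of a regimen on the reference scale."""
        pk = self._pk()
        return auc_ceff(regimen, pk, regimen.cycle_length) / exposure_scale_factor(
            self._ref(), pk
        )

    def prob_dlt_dist(self, regimen: Regimen):
        """Posterior distribution of the end-of-cycle-1 DLT probability.

        Returns ``(values, weights)``: the pushforward of the log(beta)
        posterior through ``1 - exp(-beta * AUC_E(t*))``.
        """
        auc = self.auc_cycle1(regimen)
        p = -np.expm1(-np.exp(self.log_beta_) * auc)
        return p, self.weights_

    def prob_dlt_quantiles(self, regimen: Regimen, q=(0.025, 0.25, 0.5, 0.75, 0.975)):
        p, w = self.prob_dlt_dist(regimen)
        order = np.argsort(p)
        cdf = np.cumsum(w[order])
        return np.interp(q, cdf, p[order])

    def interval_probs(self, regimen: Regimen) -> tuple[float, float, float]:
        """(P underdosing, P targeted, P overdosing) for a regimen."""
        x, y = self.interval
        p, w = self.prob_dlt_dist(regimen)
        p_ud = float(w[p < x].sum())
        p_od = float(w[p > y].sum())
        return p_ud, 1.0 - p_ud - p_od, p_od

    def overdose_prob(self, regimen: Regimen) -> float:
        return self.interval_probs(regimen)[2]

    def ewoc_ok(self, regimen: Regimen) -> bool:
        """EWOC admissibility: overdosing probability strictly below the bound."""
        return self.overdose_prob(regimen) < self.feasibility

    def recommend(
        self,
        candidates: Sequence[Regimen],
        allowed: Sequence[bool] | None = None,
    ) -> Regimen | None:
        """Next regimen among EWOC-admissible candidates, or None to stop.

        ``allowed`` optionally masks candidates (e.g. to forbid skipping
        untried dose levels); the stop decision — no candidate at all is
        admissible — is taken on the unmasked set.
        """
        candidates = list(candidates)
        if not candidates:
            raise ValueError("candidate set is empty")
        ok = [self.ewoc_ok(r) for r in candidates]
        if not any(ok):
            return None
        if allowed is None:
            allowed = [True] * len(candidates)
        pool = [
            (self.auc_cycle1(r), i)
            for i, r in enumerate(candidates)
            if ok[i] and allowed[i]
        ]
        if not pool:
            return None
        key = max if self.escalation_rule == "highest_auc" else min
        _, idx = key(pool)
        return candidates[idx]
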