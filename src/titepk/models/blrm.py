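"""Two-parameter Bayesian logistic regression model (BLRM) for DLT counts.

DLT counts per dose are binomial with

    logit(pi_d) = log(alpha1) + alpha2 * log(d / d_ref),

``alpha2 > 0`` enforced by working on ``(log alpha1, log alpha2)``.  Priors
are mixtures of bivariate normals on that scale, which covers three cases at
once: a weakly informative prior (single component), a meta-analytic
predictive (MAP) prior derived from a completed schedule (single component,
moment-matched from the hierarchical predictive), and a robust MAP prior
(MAP mixed with the weakly informative component).  The posterior is computed
per component on a tensor-product grid; mixture weights are updated by the
component marginal likelihoods.

Dose-escalation decisions use escalation with overdose control (EWOC): a
dose is admissible iff its posterior probability of overdosing is below the
feasibility bound, and the highest admissible dose is recommended.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm
from sklearn.base import BaseEstimator

__all__ = [
    "DoseToxData",
    "BvnComponent",
    "BvnMixturePrior",
    "BLRM",
    "wip_prior",
    "rescale_doses",
    "map_prior_from_schedule",
    "robustify_prior",
]


@dataclass(frozen=True)
class DoseToxData:
    """Binomial DLT counts per dose level for one schedule."""

    doses: tuple[float, ...]
    n: tuple[int, ...]
    r: tuple[int, ...]
    schedule_id: str = ""

    def __post_init__(self) -> None:
        if not (len(self.doses) == len(self.n) == len(self.r)):
            raise ValueError("doses, n and r must have equal length")
        for d, n_d, r_d in zip(self.doses, self.n, self.r):
            if d <= 0:
                raise ValueError(f"doses must be strictly positive, got {d}")
            if not (0 <= r_d <= n_d):
                raise ValueError(f"need 0 <= r <= n per dose, got r={r_d}, n={n_d}")

    @classmethod
    def from_records(cls, records, schedule_id: str = "") -> "DoseToxData":
        """Aggregate an iterable of (dose, dlt 0/1) pairs."""
        agg: dict[float, list[int]] = {}
        for dose, dlt in records:
            n_r = agg.setdefault(float(dose), [0, 0])
            n_r[0] += 1
            n_r[1] += int(dlt)
        doses = tuple(sorted(agg))
        return cls(
            doses,
            tuple(agg[d][0] for d in doses),
            tuple(agg[d][1] for d in doses),
            schedule_id,
        )


@dataclass(frozen=True)
class BvnComponent:
    """One bivariate-normal prior component on (log alpha1, log alpha2)."""

    weight: float
    mean: tuple[float, float]
    sd: tuple[float, float]
    rho: float = 0.0

    def __post_init__(self) -> None:
        if not (self.weight >= 0):
            raise ValueError("component weight must be nonnegative")
        if not (self.sd[0] > 0 and self.sd[1] > 0):
            raise ValueError("component sds must be positive")
        if not (-1 < self.rho < 1):
            raise ValueError("|rho| must be < 1")

    def logpdf(self, a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
        z1 = (a1 - self.mean[0]) / self.sd[0]
        z2 = (a2 - self.mean[1]) / self.sd[1]
        q = (z1**2 - 2 * self.rho * z1 * z2 + z2**2) / (1 - self.rho**2)
        lognorm = np.log(
            2 * np.pi * self.sd[0] * self.sd[1] * np.sqrt(1 - self.rho**2)
        )
        return -0.5 * q - lognorm


@dataclass(frozen=True)
class BvnMixturePrior:
    """Mixture of bivariate-normal components plus the reference dose."""

    components: tuple[BvnComponent, ...]
    ref_dose: float

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("prior needs at least one component")
        if self.ref_dose <= 0:
            raise ValueError("reference dose must be positive")
        total = sum(c.weight for c in self.components)
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"component weights must sum to 1, got {total}")


def wip_prior(
    ref_dose: float,
    pi_ref: float = 0.30,
    sigmas: tuple[float, float] = (2.0, 1.0),
    rho: float = 0.0,
) -> BvnMixturePrior:
    """Weakly informative prior centred at DLT probability ``pi_ref`` at the
    reference dose, with unit-centred slope (median slope 1)."""
    m1 = float(np.log(pi_ref / (1 - pi_ref)))
    return BvnMixturePrior(
        (BvnComponent(1.0, (m1, 0.0), sigmas, rho),), ref_dose
    )


def blrm_loglik(
    log_a1: np.ndarray, log_a2: np.ndarray, data: DoseToxData, ref_dose: float
) -> np.ndarray:
    """Binomial log-likelihood (without the combinatorial constant)."""
    ll = np.zeros(np.broadcast(log_a1, log_a2).shape)
    for d, n_d, r_d in zip(data.doses, data.n, data.r):
        eta = log_a1 + np.exp(log_a2) * np.log(d / ref_dose)
        ll += r_d * eta - n_d * np.logaddexp(0.0, eta)
    return ll


class BLRM(BaseEstimator):
    """BLRM with mixture priors, grid-quadrature posterior and EWOC decisions.

    Attributes after :meth:`fit`
    ----------------------------
    component_posteriors_ : list of (a1 grid, a2 grid, weight matrix)
    mixture_weights_ : ndarray
        Posterior mixture weights (prior weights updated by component
        marginal likelihoods).
    log_marginal_ : float
        Log marginal likelihood of the full mixture.
    """

    def __init__(
        self,
        prior: BvnMixturePrior | None = None,
        interval: tuple[float, float] = (0.20, 0.40),
        feasibility: float = 0.25,
        backend: str = "grid",
        n_grid: int = 401,
        span: float = 6.0,
        mcmc_draws: int = 8000,
        mcmc_burn: int = 1000,
        random_state: int = 0,
    ):
        self.prior = prior
        self.interval = interval
        self.feasibility = feasibility
        self.backend = backend
        self.n_grid = n_grid
        self.span = span
        self.mcmc_draws = mcmc_draws
        self.mcmc_burn = mcmc_burn
        self.random_state = random_state

    def _prior(self) -> BvnMixturePrior:
        if self.prior is None:
            raise ValueError("a BvnMixturePrior must be supplied")
        return self.prior

    def fit(self, data: DoseToxData | None, y=None) -> "BLRM":
        """Posterior over (log alpha1, log alpha2); ``data=None`` reproduces
        the prior."""
        prior = self._prior()
        if data is None:
            data = DoseToxData((prior.ref_dose,), (0,), (0,))
        self.data_ = data
        if self.backend == "grid":
            self._fit_grid(prior, data)
        elif self.backend == "mcmc":
            self._fit_mcmc(prior, data)
        else:
            raise ValueError(f"unknown backend {self.backend!r}")
        return self

    def _fit_grid(self, prior: BvnMixturePrior, data: DoseToxData) -> None:
        posteriors = []
        log_margs = []
        for comp in prior.components:
            g1 = np.linspace(
                comp.mean[0] - self.span * comp.sd[0],
                comp.mean[0] + self.span * comp.sd[0],
                self.n_grid,
            )
            g2 = np.linspace(
                comp.mean[1] - self.span * comp.sd[1],
                comp.mean[1] + self.span * comp.sd[1],
                self.n_grid,
            )
            A1, A2 = np.meshgrid(g1, g2, indexing="ij")
            lp = comp.logpdf(A1, A2) + blrm_loglik(A1, A2, data, prior.ref_dose)
            mx = lp.max()
            if not np.isfinite(mx):
                raise ValueError("degenerate posterior on quadrature grid")
            w = np.exp(lp - mx)
            cell = (g1[1] - g1[0]) * (g2[1] - g2[0])
            log_margs.append(mx + np.log(w.sum() * cell))
            posteriors.append((A1, A2, w / w.sum()))
        log_margs = np.asarray(log_margs)
        lw = np.log([c.weight for c in prior.components]) + log_margs
        lw -= lw.max()
        mix_w = np.exp(lw)
        mix_w /= mix_w.sum()
        self.component_posteriors_ = posteriors
        self.component_log_marginals_ = log_margs
        self.mixture_weights_ = mix_w
        self.log_marginal_ = float(
            np.logaddexp.reduce(
                np.log([c.weight for c in prior.components]) + log_margs
            )
        )

    def _fit_mcmc(self, prior: BvnMixturePrior, data: DoseToxData) -> None:
        import emcee

        comps = prior.components

        def logpost(p):
            a1, a2 = p[:, 0], p[:, 1]
            lp = np.logaddexp.reduce(
                [np.log(c.weight) + c.logpdf(a1, a2) for c in comps], axis=0
            )
            return lp + blrm_loglik(a1, a2, data, prior.ref_dose)

        rng = np.random.default_rng(self.random_state)
        nw = 32
        c0 = comps[0]
        p0 = np.column_stack(
            [
                c0.mean[0] + 0.5 * rng.standard_normal(nw),
                c0.mean[1] + 0.5 * rng.standard_normal(nw),
            ]
        )
        sampler = emcee.EnsembleSampler(nw, 2, logpost, vectorize=True)
        steps = self.mcmc_burn + max(1, self.mcmc_draws // nw)
        sampler.run_mcmc(p0, steps, progress=False)
        chain = sampler.get_chain(discard=self.mcmc_burn, flat=True)
        w = np.full(chain.shape[0], 1.0 / chain.shape[0])
        self.component_posteriors_ = [(chain[:, 0], chain[:, 1], w)]
        self.mixture_weights_ = np.array([1.0])
        self.log_marginal_ = np.nan

    # -- posterior functionals ----------------------------------------------

    def prob_dlt_dist(self, dose: float):
        """Pooled (values, weights) sample of pi_dose across mixture
        components."""
        ref = self._prior().ref_dose
        vals, wts = [], []
        for mw, (A1, A2, W) in zip(
            self.mixture_weights_, self.component_posteriors_
        ):
            pi = expit(A1 + np.exp(A2) * np.log(dose / ref))
            vals.append(np.ravel(pi))
            wts.append(np.ravel(W) * mw)
        return np.concatenate(vals), np.concatenate(wts)

    def prob_dlt_quantiles(self, dose: float, q=(0.025, 0.25, 0.5, 0.75, 0.975)):
        p, w = self.prob_dlt_dist(dose)
        order = np.argsort(p)
        return np.interp(q, np.cumsum(w[order]), p[order])

    def prob_dlt_mean(self, dose: float) -> float:
        p, w = self.prob_dlt_dist(dose)
        return float(p @ w)

    def interval_probs(self, dose: float) -> tuple[float, float, float]:
        x, y = self.interval
        p, w = self.prob_dlt_dist(dose)
        p_ud = float(w[p < x].sum())
        p_od = float(w[p > y].sum())
        return p_ud, 1.0 - p_ud - p_od, p_od

    def overdose_prob(self, dose: float) -> float:
        return self.interval_probs(dose)[2]

    def ewoc_ok(self, dose: float) -> bool:
        return self.overdose_prob(dose) < self.feasibility

    def recommend(
        self, dose_grid: Sequence[float], allowed: Sequence[bool] | None = None
    ) -> float | None:
        """Highest EWOC-admissible dose, or None if every dose is too toxic."""
        dose_grid = list(dose_grid)
        ok = [self.ewoc_ok(d) for d in dose_grid]
        if not any(ok):
            return None
        if allowed is None:
            allowed = [True] * len(dose_grid)
        pool = [d for d, o, a in zip(dose_grid, ok, allowed) if o and a]
        return max(pool) if pool else None


def rescale_doses(
    data: DoseToxData, from_interval: float, to_interval: float
) -> DoseToxData:
    """Re-express doses from one schedule on another schedule's dose scale so
    that nominal doses match cumulative dose (weekly -> daily divides by 7)."""
    if from_interval <= 0 or to_interval <= 0:
        raise ValueError("dosing intervals must be positive")
    factor = to_interval / from_interval
    return replace(data, doses=tuple(d * factor for d in data.doses))


def map_prior_from_schedule(
    data: DoseToxData,
    wip: BvnMixturePrior,
    tau_scales: tuple[float, float] = (0.25, 0.125),
    n_walkers: int = 32,
    n_steps: int = 3000,
    burn: int = 1000,
    thin: int = 5,
    random_state: int = 0,
) -> BvnComponent:
    """Meta-analytic predictive (MAP) prior from one completed schedule.

    Fits a hierarchical BLRM in which each schedule's ``(log a1, log a2)`` is
    exchangeable around population means ``mu`` with between-schedule
    standard deviations ``tau`` (half-normal priors with the given scales;
    the hyperprior on ``mu`` is the weakly informative prior).  Returns the
    posterior-predictive distribution of a new schedule's parameters,
    moment-matched to a single bivariate normal.

    The completed-schedule doses must already be on the new schedule's dose
    scale (see :func:`rescale_doses`).
    """
    if sum(data.n) == 0:
        raise ValueError("completed-schedule data must be nonempty")
    import emcee

    c = wip.components[0]
    m1, m2 = c.mean
    s1, s2 = c.sd
    t1s, t2s = tau_scales
    ref = wip.ref_dose
    log_dr = np.log(np.asarray(data.doses) / ref)
    x = np.asarray(data.r, dtype=float)
    n = np.asarray(data.n, dtype=float)

    def logpost(p):
        mu1, mu2, lt1, lt2, a1, a2 = p.T
        t1, t2 = np.exp(lt1), np.exp(lt2)
        lp = norm.logpdf(mu1, m1, s1) + norm.logpdf(mu2, m2, s2)
        # half-normal on tau, sampled on the log scale (jacobian included)
        lp += norm.logpdf(t1, 0.0, t1s) + lt1 + norm.logpdf(t2, 0.0, t2s) + lt2
        lp += norm.logpdf(a1, mu1, t1) + norm.logpdf(a2, mu2, t2)
        eta = a1[:, None] + np.exp(a2)[:, None] * log_dr[None, :]
        lp += (x * eta - n * np.logaddexp(0.0, eta)).sum(axis=1)
        return lp

    rng = np.random.default_rng(random_state)
    p0 = np.column_stack(
        [
            m1 + 0.5 * rng.standard_normal(n_walkers),
            m2 + 0.3 * rng.standard_normal(n_walkers),
            np.log(t1s) + 0.5 * rng.standard_normal(n_walkers),
            np.log(t2s) + 0.5 * rng.standard_normal(n_walkers),
            m1 + 0.5 * rng.standard_normal(n_walkers),
            m2 + 0.3 * rng.standard_normal(n_walkers),
        ]
    )
    sampler = emcee.EnsembleSampler(n_walkers, 6, logpost, vectorize=True)
    sampler.run_mcmc(p0, n_steps, progress=False)
    chain = sampler.get_chain(discard=burn, thin=thin, flat=True)
    mu = chain[:, :2]
    tau = np.exp(chain[:, 2:4])
    z = rng.standard_normal(mu.shape)
    theta_new = mu + tau * z  # predictive draws for a new schedule
    mean = theta_new.mean(axis=0)
    cov = np.cov(theta_new.T)
    sd = np.sqrt(np.diag(cov))
    rho = float(cov[0, 1] / (sd[0] * sd[1]))
    return BvnComponent(1.0, (float(mean[0]), float(mean[1])), (float(sd[0]), float(sd[1])), rho)


def robustify_prior(
    map_component: BvnComponent, wip: BvnMixturePrior, w: float = 0.8
) -> BvnMixturePrior:
    """Robust MAP prior: ``w * MAP + (1 - w) * WIP``."""
    if not (0 <= w <= 1):
        raise ValueError("mixture weight must lie in [0, 1]")
    wip_c = wip.components[0]
    comps: list[BvnComponent] = []
    if w > 0:
        comps.append(replace(map_component, weight=w))
    if w < 1:
        comps.append(replace(wip_c, weight=1 - w))
    return BvnMixturePrior(tuple(comps), wip.ref_dose)
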