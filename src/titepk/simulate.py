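"""Cohort-by-cohort trial simulation for all designs.

The engine enrols cohorts, refits the chosen model after each cohort and
applies the design's decision rules:

* TITE-PK and BLRM escalate with overdose control.  The trial stops with no
  MTD when every dose is in the overdosing interval; a dose is declared the
  MTD once the model keeps recommending it (the recommendation equals the
  dose the current cohort was treated at), it carries at least
  ``min_at_mtd`` patients and at least ``min_total`` patients have been
  treated in the schedule's step; at the hard patient cap the highest
  admissible dose is declared.
* CRM-type designs treat a fixed number of patients, recommend the dose with
  posterior-mean DLT probability closest to the target, and stop early only
  for safety at the lowest dose.

Sequential two-schedule trials run the first schedule to completion, then —
only if it declared an MTD — run the second schedule carrying the first
schedule's information as pooled likelihood data (TITE-PK), a robust MAP
prior (BLRM), or bridged skeletons (B-CRM).  The second schedule starts at
the highest dose admissible under the carried-over model (configurable to
the lowest dose); the bridging CRM, which carries no posterior, starts at
the lowest dose.
Reported outcome metrics refer to the second schedule's step; when the first
schedule stops without an MTD the whole programme stops and the patients
counted are those enrolled up to that point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .models.blrm import (
    BLRM,
    BvnMixturePrior,
    DoseToxData,
    map_prior_from_schedule,
    rescale_doses,
    robustify_prior,
    wip_prior,
)
from .models.bridge import BridgingCRM
from .models.crm import CRM, lee_cheung_skeleton
from .models.tite import TITEPK, SubjectEvent
from .pk import PKParams, Regimen
from .scenarios import Scenario, ScheduleArm

__all__ = [
    "TrialConfig",
    "TrialResult",
    "simulate_cohort",
    "run_trial",
    "run_sequential_trial",
    "operating_characteristics",
]

SINGLE_METHODS = ("titepk", "blrm", "crm")
SEQUENTIAL_METHODS = ("titepk", "blrm_map", "bcrm")


@dataclass(frozen=True)
class TrialConfig:
    """Design constants shared by the simulated trials.

    ``dlt_time_rule`` controls when within the cycle a simulated DLT occurs:
    ``"uniform"`` draws the time uniformly on (0, cycle_length]; ``"fixed"``
    places it at ``dlt_time_fraction`` of the cycle (e.g. day 15 of 21).
    """

    cohort_size: int = 3
    max_patients: int = 60  # EWOC designs, per schedule step
    crm_sample_size: int = 21  # CRM designs, per schedule step
    feasibility: float = 0.25
    interval: tuple[float, float] = (0.20, 0.40)
    target: float = 0.30
    min_at_mtd: int = 6
    min_total: int = 21
    cycle_length: float = 504.0
    dlt_time_rule: str = "uniform"
    dlt_time_fraction: float = 15.0 / 21.0
    no_skip: bool = False
    s2_start: str = "informed"  # or "lowest"
    # TITE-PK
    pk: PKParams = field(default_factory=lambda: PKParams(30.0, 0.37))
    ref: Regimen = field(default_factory=lambda: Regimen(7.5, 24.0, 504.0))
    prior_p_ref: float = 0.30
    titepk_prior_sd: float = 1.25
    titepk_n_grid: int = 1001
    # BLRM
    blrm_sigmas: tuple[float, float] = (2.0, 1.0)
    blrm_ref_dose: float = 7.5
    blrm_n_grid: int = 101
    map_weight: float = 0.8
    tau_scales: tuple[float, float] = (0.25, 0.125)
    # CRM
    crm_halfwidth: float = 0.10
    crm_nu: int = 3
    crm_prior_sd: float = 2.0
    crm_safety_threshold: float = 0.30
    crm_safety_level: float = 0.90


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one simulated trial (sequential: of its reported step)."""

    method: str
    scenario_id: int
    mtd_dose: float | None
    mtd_true_prob: float | None
    n_patients: int
    n_dlt: int
    n_overdose_patients: int  # patients treated at doses with true prob > y
    stop_reason: str  # "mtd", "all_toxic", "safety", "max_patients"
    started_second_schedule: bool = False
    total_patients: int = 0  # across all steps


def simulate_cohort(
    rng: np.random.Generator,
    regimen: Regimen,
    true_prob: float,
    size: int,
    config: TrialConfig,
) -> list[SubjectEvent]:
    """Draw one cohort's cycle-1 outcomes under the scenario truth."""
    t_star = regimen.cycle_length
    out = []
    for _ in range(size):
        if rng.random() < true_prob:
            if config.dlt_time_rule == "uniform":
                t = t_star * (1.0 - rng.random())  # uniform on (0, t*]
            elif config.dlt_time_rule == "fixed":
                t = config.dlt_time_fraction * t_star
            else:
                raise ValueError(f"unknown dlt_time_rule {config.dlt_time_rule!r}")
            out.append(SubjectEvent(regimen, t, 1))
        else:
            out.append(SubjectEvent(regimen, t_star, 0))
    return out


class _ArmState:
    """Per-schedule bookkeeping during a simulated trial."""

    def __init__(self, arm: ScheduleArm, config: TrialConfig):
        self.arm = arm
        self.regimens = [
            Regimen(d, arm.interval, config.cycle_length) for d in arm.doses
        ]
        self.n = np.zeros(len(arm.doses), dtype=int)
        self.r = np.zeros(len(arm.doses), dtype=int)
        self.subjects: list[SubjectEvent] = []
        self.max_tried = -1

    def enroll(self, rng, level: int, config: TrialConfig) -> None:
        cohort = simulate_cohort(
            rng, self.regimens[level], self.arm.true_probs[level],
            config.cohort_size, config,
        )
        self.subjects.extend(cohort)
        self.n[level] += len(cohort)
        self.r[level] += sum(s.dlt for s in cohort)
        self.max_tried = max(self.max_tried, level)

    @property
    def n_total(self) -> int:
        return int(self.n.sum())

    @property
    def n_dlt(self) -> int:
        return int(self.r.sum())

    def n_overdosed(self, y: float) -> int:
        mask = np.asarray(self.arm.true_probs) > y
        return int(self.n[mask].sum())

    def allowed(self) -> list[bool]:
        limit = self.max_tried + 1
        return [lev <= limit for lev in range(len(self.regimens))]


def _result(method, scenario, arm_state, mtd_level, reason, config,
            started_second=False, total=None):
    arm = arm_state.arm
    dose = prob = None
    if mtd_level is not None:
        dose = arm.doses[mtd_level]
        prob = arm.true_probs[mtd_level]
    return TrialResult(
        method=method,
        scenario_id=scenario.sid,
        mtd_dose=dose,
        mtd_true_prob=prob,
        n_patients=arm_state.n_total,
        n_dlt=arm_state.n_dlt,
        n_overdose_patients=arm_state.n_overdosed(config.interval[1]),
        stop_reason=reason,
        started_second_schedule=started_second,
        total_patients=arm_state.n_total if total is None else total,
    )


# ---------------------------------------------------------------------------
# per-arm escalation loops


def _run_ewoc_arm(rng, state: _ArmState, config: TrialConfig, recommend,
                  fit, start_level: int = 0):
    """Generic EWOC loop; ``fit(state)`` refits the model on the current
    data and ``recommend(model, state, allowed)`` maps it to a dose level
    (``allowed=False`` lifts the no-skip restriction for the final call at
    the patient cap).  The MTD is declared only for a stable recommendation:
    the recommended dose is the one the current cohort was treated at."""
    level = start_level
    while True:
        state.enroll(rng, level, config)
        model = fit(state)
        rec = recommend(model, state, allowed=True)
        if rec is None:
            return None, "all_toxic"
        if (
            rec == level
            and state.n[rec] >= config.min_at_mtd
            and state.n_total >= config.min_total
        ):
            return rec, "mtd"
        if state.n_total + config.cohort_size > config.max_patients:
            final = recommend(model, state, allowed=False)
            if final is None:
                return None, "all_toxic"
            return final, "max_patients"
        level = rec


def _titepk_arm(rng, arm: ScheduleArm, config: TrialConfig,
                pooled: Sequence[SubjectEvent] = ()):
    state = _ArmState(arm, config)
    model = TITEPK(
        pk=config.pk,
        ref=config.ref,
        prior_p_ref=config.prior_p_ref,
        prior_sd=config.titepk_prior_sd,
        interval=config.interval,
        feasibility=config.feasibility,
        n_grid=config.titepk_n_grid,
    )

    def fit(st):
        return model.fit(list(pooled) + st.subjects)

    def recommend(mod, st, allowed):
        mask = st.allowed() if (allowed and config.no_skip) else None
        reg = mod.recommend(st.regimens, mask)
        return None if reg is None else st.regimens.index(reg)

    start = 0
    if pooled and config.s2_start == "informed":
        reg = model.fit(list(pooled)).recommend(state.regimens)
        if reg is None:
            return None, state, "all_toxic"
        start = state.regimens.index(reg)
    level, reason = _run_ewoc_arm(rng, state, config, recommend, fit, start)
    return level, state, reason


def _blrm_arm(rng, arm: ScheduleArm, config: TrialConfig,
              prior: BvnMixturePrior, informed_start: bool = False):
    state = _ArmState(arm, config)
    model = BLRM(
        prior=prior,
        interval=config.interval,
        feasibility=config.feasibility,
        n_grid=config.blrm_n_grid,
    )

    def fit(st):
        data = DoseToxData(
            tuple(arm.doses), tuple(int(v) for v in st.n),
            tuple(int(v) for v in st.r), arm.label,
        )
        return model.fit(data)

    def recommend(mod, st, allowed):
        mask = st.allowed() if (allowed and config.no_skip) else None
        dose = mod.recommend(arm.doses, mask)
        return None if dose is None else list(arm.doses).index(dose)

    start = 0
    if informed_start and config.s2_start == "informed":
        dose = model.fit(None).recommend(arm.doses)
        if dose is None:
            return None, state, "all_toxic"
        start = list(arm.doses).index(dose)
    level, reason = _run_ewoc_arm(rng, state, config, recommend, fit, start)
    return level, state, reason


def _crm_arm(rng, arm: ScheduleArm, config: TrialConfig, estimator=None):
    """CRM or bridging-CRM loop: fixed sample size with a safety stop."""
    state = _ArmState(arm, config)
    if estimator is None:
        estimator = CRM(
            skeleton=lee_cheung_skeleton(
                config.target, config.crm_halfwidth, config.crm_nu,
                len(arm.doses),
            ),
            target=config.target,
            prior_sd=config.crm_prior_sd,
        )
    level = 0
    while True:
        state.enroll(rng, level, config)
        estimator.fit(state.r, state.n)
        if estimator.safety_stop(
            config.crm_safety_threshold, config.crm_safety_level
        ):
            return None, state, "safety"
        rec = estimator.recommend(n_levels=len(arm.doses))
        if config.no_skip:
            rec = min(rec, state.max_tried + 1)
        if state.n_total >= config.crm_sample_size:
            return rec, state, "mtd"
        level = rec


# ---------------------------------------------------------------------------
# public entry points


def run_trial(method: str, scenario: Scenario, config: TrialConfig,
              seed: int) -> TrialResult:
    """Simulate one single-schedule trial."""
    if method not in SINGLE_METHODS:
        raise ValueError(f"unknown single-schedule method {method!r}")
    if scenario.sequential:
        raise ValueError("scenario has two schedules; use run_sequential_trial")
    rng = np.random.default_rng(seed)
    arm = scenario.arms[0]
    if method == "titepk":
        level, state, reason = _titepk_arm(rng, arm, config)
    elif method == "blrm":
        prior = wip_prior(config.blrm_ref_dose, config.prior_p_ref,
                          config.blrm_sigmas)
        level, state, reason = _blrm_arm(rng, arm, config, prior)
    else:
        level, state, reason = _crm_arm(rng, arm, config)
    return _result(method, scenario, state, level, reason, config)


def run_sequential_trial(method: str, scenario: Scenario, config: TrialConfig,
                         seed: int) -> TrialResult:
    """Simulate one sequential two-schedule trial; metrics refer to the
    second schedule's step (see module docstring for the stopping case)."""
    if method not in SEQUENTIAL_METHODS:
        raise ValueError(f"unknown sequential method {method!r}")
    if not scenario.sequential:
        raise ValueError("scenario has a single schedule; use run_trial")
    rng = np.random.default_rng(seed)
    s1, s2 = scenario.arms

    if method == "titepk":
        lvl1, st1, reason1 = _titepk_arm(rng, s1, config)
        if lvl1 is None:
            return _result(method, scenario, st1, None, reason1, config)
        lvl2, st2, reason2 = _titepk_arm(rng, s2, config, pooled=st1.subjects)
    elif method == "blrm_map":
        wip = wip_prior(config.blrm_ref_dose, config.prior_p_ref,
                        config.blrm_sigmas)
        lvl1, st1, reason1 = _blrm_arm(rng, s1, config, wip)
        if lvl1 is None:
            return _result(method, scenario, st1, None, reason1, config)
        s1_data = DoseToxData(tuple(s1.doses), tuple(int(v) for v in st1.n),
                              tuple(int(v) for v in st1.r), s1.label)
        rescaled = rescale_doses(s1_data, s1.interval, s2.interval)
        map_comp = map_prior_from_schedule(
            rescaled, wip, tau_scales=config.tau_scales,
            random_state=int(rng.integers(2**31)),
        )
        prior = robustify_prior(map_comp, wip, config.map_weight)
        lvl2, st2, reason2 = _blrm_arm(rng, s2, config, prior,
                                       informed_start=True)
    else:  # bcrm
        lvl1, st1, reason1 = _crm_arm(rng, s1, config)
        if lvl1 is None:
            return _result(method, scenario, st1, None, reason1, config)
        bridge = BridgingCRM.from_completed_schedule(
            s1.doses, st1.r, st1.n,
            target=config.target, prior_sd=config.crm_prior_sd,
        )
        lvl2, st2, reason2 = _crm_arm(rng, s2, config, estimator=bridge)

    return _result(method, scenario, st2, lvl2, reason2, config,
                   started_second=True,
                   total=st1.n_total + st2.n_total)


def operating_characteristics(
    results: Sequence[TrialResult],
    interval: tuple[float, float] = (0.20, 0.40),
    dlt_metric: str = "proportion",
) -> dict[str, float]:
    """Aggregate operating characteristics over simulated trials.

    The four MTD-selection outcomes (targeted interval, overdosing,
    underdosing, none) partition the replicates.  ``dlt_metric`` selects
    between the proportion of treated patients with a DLT and the mean
    number of DLTs per trial.  Monte-Carlo standard errors accompany the
    selection probabilities.
    """
    if not results:
        raise ValueError("no trial results supplied")
    x, y = interval
    n_rep = len(results)
    in_target = in_over = in_under = none = 0
    patients = dlts = overdosed = 0
    for res in results:
        if res.mtd_true_prob is None:
            none += 1
        elif res.mtd_true_prob > y:
            in_over += 1
        elif res.mtd_true_prob < x:
            in_under += 1
        else:
            in_target += 1
        patients += res.n_patients
        dlts += res.n_dlt
        overdosed += res.n_overdose_patients

    def rate(k):
        p = k / n_rep
        return p, float(np.sqrt(p * (1 - p) / n_rep))

    p_t, se_t = rate(in_target)
    p_o, se_o = rate(in_over)
    p_u, se_u = rate(in_under)
    p_n, se_n = rate(none)
    out = {
        "n_replicates": n_rep,
        "p_mtd_targeted": p_t,
        "p_mtd_overdose": p_o,
        "p_mtd_underdose": p_u,
        "p_no_mtd": p_n,
        "se_mtd_targeted": se_t,
        "se_mtd_overdose": se_o,
        "se_mtd_underdose": se_u,
        "se_no_mtd": se_n,
        "mean_patients": patients / n_rep,
        "prop_patients_overdosed": overdosed / patients if patients else 0.0,
    }
    if dlt_metric == "proportion":
        out["prop_dlt"] = dlts / patients if patients else 0.0
    elif dlt_metric == "count":
        out["mean_dlt"] = dlts / n_rep
    else:
        raise ValueError(f"unknown dlt_metric {dlt_metric!r}")
    return out
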