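import numpy as np
import pytest

from titepk import (
    Regimen,
    SubjectEvent,
    TITEPK,
    ceff_profile,
    cloglog,
    exposure_scale_factor,
    inv_cloglog,
)


def test_cloglog_round_trip():
    p = np.array([0.01, 0.3, 0.9])
    assert np.allclose(inv_cloglog(cloglog(p)), p)


class TestLikelihood:
    def test_empty_data_is_zero(self):
        assert TITEPK().log_likelihood(0.3, []) == pytest.approx(0.0)

    def test_one_censored_reference_subject(self, ref_regimen):
        """A censored subject on the reference schedule contributes exactly
        -beta, because the reference cycle-1 exposure AUC is one."""
        model = TITEPK()
        subj = SubjectEvent(ref_regimen, 504.0, 0)
        for log_beta in (-1.0, 0.0, 0.7):
            ll = model.log_likelihood(log_beta, [subj])
            assert ll == pytest.approx(-np.exp(log_beta), rel=1e-10)

    def test_everolimus_daily_against_independent_derivation(
        self, pk, ref_schedule, daily_subjects
    ):
        """Term-by-term re-derivation: for each subject the contribution is
        delta * (log beta + log E(T)) - beta * AUC_E(T), with AUC computed
        by dense trapezoid quadrature of the exposure profile."""
        log_beta = float(cloglog(0.30))
        beta = np.exp(log_beta)
        A = exposure_scale_factor(ref_schedule, pk)
        expected = 0.0
        for s in daily_subjects:
            t = np.linspace(0, s.time, 40_000)
            auc = np.trapezoid(ceff_profile(s.regimen, pk, t), t) / A
            if s.dlt:
                e_t = ceff_profile(s.regimen, pk, s.time)[0] / A
                expected += log_beta + np.log(e_t) - beta * auc
            else:
                expected += -beta * auc
        got = TITEPK().log_likelihood(log_beta, daily_subjects)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_event_time_outside_cycle_rejected(self, ref_regimen):
        with pytest.raises(ValueError):
            SubjectEvent(ref_regimen, 505.0, 1)
        with pytest.raises(ValueError):
            SubjectEvent(ref_regimen, 0.0, 0)
        with pytest.raises(ValueError):
            SubjectEvent(ref_regimen, 100.0, 2)


class TestPosterior:
    def test_prior_reproduction_without_data(self, ref_regimen):
        """With no data the reference-schedule DLT probability has median
        equal to the anticipated value 0.30."""
        model = TITEPK().fit([])
        med = model.prob_dlt_quantiles(ref_regimen, q=(0.5,))[0]
        assert med == pytest.approx(0.30, abs=0.003)

    def test_all_censored_shrinks_beta(self, ref_regimen):
        model = TITEPK().fit([])
        prior_med = model.prob_dlt_quantiles(ref_regimen, (0.5,))[0]
        subjects = [SubjectEvent(ref_regimen, 504.0, 0) for _ in range(40)]
        fitted = TITEPK().fit(subjects)
        post_med = fitted.prob_dlt_quantiles(ref_regimen, (0.5,))[0]
        assert post_med < prior_med

    def test_zero_dose_probability_zero(self, daily_subjects):
        model = TITEPK().fit(daily_subjects)
        p, w = model.prob_dlt_dist(Regimen(0.0, 24.0, 504.0))
        assert np.all(p == 0.0)

    def test_interval_probs_sum_to_one(self, daily_subjects):
        model = TITEPK().fit(daily_subjects)
        for dose in (2.5, 5.0, 7.5, 10.0):
            probs = model.interval_probs(Regimen(dose, 24.0, 504.0))
            assert sum(probs) == pytest.approx(1.0, abs=1e-9)
            assert all(p >= 0 for p in probs)

    def test_monotone_in_exposure(self, pooled_subjects):
        """Quantile-wise, a regimen with larger exposure AUC has a
        stochastically larger DLT-probability distribution."""
        model = TITEPK().fit(pooled_subjects)
        qs = np.linspace(0.05, 0.95, 10)
        prev = None
        for dose in (2.5, 5.0, 7.5, 10.0):
            cur = model.prob_dlt_quantiles(Regimen(dose, 24.0, 504.0), qs)
            if prev is not None:
                assert np.all(cur >= prev - 1e-12)
            prev = cur

    def test_degenerate_data_raises(self, ref_regimen):
        # an event at a time of (numerically) zero exposure cannot be scored
        with pytest.raises(ValueError):
            TITEPK().fit(
                [SubjectEvent(Regimen(5.0, 24.0, 504.0, 100.0), 50.0, 1)]
            )


class TestDecisions:
    def test_ewoc_is_strict_inequality(self, daily_subjects):
        model = TITEPK(feasibility=0.25).fit(daily_subjects)
        reg = Regimen(2.5, 24.0, 504.0)
        pod = model.overdose_prob(reg)
        assert model.ewoc_ok(reg) == (pod < 0.25)
        exactly = TITEPK(feasibility=pod).fit(daily_subjects)
        assert not exactly.ewoc_ok(reg)  # P_OD == bound -> not admissible

    def test_everolimus_daily_recommends_lowest_dose(self, daily_subjects):
        model = TITEPK().fit(daily_subjects)
        candidates = [Regimen(d, 24.0, 504.0) for d in (2.5, 5.0, 7.5, 10.0)]
        rec = model.recommend(candidates)
        assert rec is not None and rec.dose == 2.5
        # 2.5 mg is also the only admissible dose
        assert [model.ewoc_ok(r) for r in candidates] == [True, False, False, False]

    def test_all_candidates_failing_gives_stop(self, daily_subjects):
        model = TITEPK().fit(daily_subjects)
        toxic = [Regimen(d, 24.0, 504.0) for d in (20.0, 40.0)]
        assert model.recommend(toxic) is None

    def test_single_passing_candidate_returned(self, daily_subjects):
        model = TITEPK().fit(daily_subjects)
        cands = [Regimen(2.5, 24.0, 504.0), Regimen(40.0, 24.0, 504.0)]
        assert model.recommend(cands).dose == 2.5

    def test_lowest_auc_rule_available(self, daily_subjects):
        model = TITEPK(escalation_rule="lowest_auc").fit(daily_subjects)
        cands = [Regimen(d, 24.0, 504.0) for d in (1.0, 2.5)]
        assert model.recommend(cands).dose == 1.0
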