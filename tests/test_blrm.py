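import numpy as np
import pytest
from scipy.special import logit

from titepk import (
    BLRM,
    BvnComponent,
    DoseToxData,
    map_prior_from_schedule,
    rescale_doses,
    robustify_prior,
    wip_prior,
)
from titepk.models.blrm import blrm_loglik

WIP_EV = wip_prior(5.0, 0.30, (1.25, 1.0))


class TestLikelihood:
    def test_empty_data_is_zero(self):
        data = DoseToxData((2.5, 5.0), (0, 0), (0, 0))
        assert blrm_loglik(0.3, -0.2, data, 5.0) == pytest.approx(0.0)

    def test_slope_vanishes_at_reference_dose(self):
        data = DoseToxData((5.0,), (10,), (4,))
        for slope in (-1.0, 0.0, 2.0):
            ll = blrm_loglik(logit(0.3), slope, data, 5.0)
            p = 0.3
            expected = 4 * np.log(p) + 6 * np.log1p(-p)
            assert ll == pytest.approx(expected, rel=1e-12)

    def test_everolimus_daily_against_binomial_formula(self, daily_counts):
        la1, la2 = float(logit(0.30)), 0.0
        expected = 0.0
        for d, n, r in zip(daily_counts.doses, daily_counts.n, daily_counts.r):
            eta = la1 + np.exp(la2) * np.log(d / 5.0)
            p = 1 / (1 + np.exp(-eta))
            expected += r * np.log(p) + (n - r) * np.log1p(-p)
        got = blrm_loglik(la1, la2, daily_counts, 5.0)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValueError):
            DoseToxData((0.0,), (3,), (1,))
        with pytest.raises(ValueError):
            DoseToxData((5.0,), (3,), (4,))


class TestPosterior:
    def test_prior_reproduction_without_data(self):
        model = BLRM(prior=WIP_EV).fit(None)
        med = model.prob_dlt_quantiles(5.0, (0.5,))[0]
        assert med == pytest.approx(0.30, abs=0.01)

    def test_interval_probs_sum_to_one(self, daily_counts):
        model = BLRM(prior=WIP_EV).fit(daily_counts)
        for d in (2.5, 5.0, 7.5, 10.0):
            probs = model.interval_probs(d)
            assert sum(probs) == pytest.approx(1.0, abs=1e-9)

    def test_everolimus_daily_stops_all_doses(self, daily_counts):
        """With the daily data alone every dose is in the overdosing
        interval, so the EWOC recommendation is a stop signal."""
        model = BLRM(prior=WIP_EV).fit(daily_counts)
        assert model.overdose_prob(2.5) > 0.25
        assert model.recommend((2.5, 5.0, 7.5, 10.0)) is None

    def test_dlt_free_patients_do_not_raise_toxicity(self, daily_counts):
        base = BLRM(prior=WIP_EV).fit(daily_counts)
        augmented = DoseToxData(
            daily_counts.doses,
            (daily_counts.n[0] + 3,) + daily_counts.n[1:],
            daily_counts.r,
        )
        more = BLRM(prior=WIP_EV).fit(augmented)
        for d in daily_counts.doses:
            assert more.prob_dlt_mean(d) <= base.prob_dlt_mean(d) + 1e-9

    def test_point_mass_like_recommendation(self):
        """A tight prior at the target probability admits every dose, so the
        highest one is recommended."""
        prior = wip_prior(5.0, 0.30, (0.05, 0.05))
        model = BLRM(prior=prior).fit(None)
        assert model.recommend((2.5, 5.0)) == 5.0


class TestDoseRescaling:
    def test_weekly_to_daily_divides_by_seven(self):
        data = DoseToxData((30.0,), (13,), (4,))
        out = rescale_doses(data, 168.0, 24.0)
        assert out.doses[0] == pytest.approx(30.0 / 7.0)

    def test_identity_for_equal_intervals(self):
        data = DoseToxData((10.0,), (3,), (1,))
        assert rescale_doses(data, 24.0, 24.0).doses == data.doses

    def test_48h_to_24h_halves(self):
        data = DoseToxData((10.0,), (3,), (1,))
        assert rescale_doses(data, 48.0, 24.0).doses[0] == pytest.approx(5.0)


class TestRobustMixture:
    MAP = BvnComponent(1.0, (-1.0, 0.1), (0.5, 0.4), 0.1)

    def test_weight_one_is_pure_map(self):
        prior = robustify_prior(self.MAP, WIP_EV, 1.0)
        assert len(prior.components) == 1
        assert prior.components[0].mean == self.MAP.mean

    def test_weight_zero_is_pure_wip(self):
        prior = robustify_prior(self.MAP, WIP_EV, 0.0)
        assert len(prior.components) == 1
        assert prior.components[0].sd == WIP_EV.components[0].sd

    def test_default_mixture_weights(self):
        prior = robustify_prior(self.MAP, WIP_EV, 0.8)
        assert [c.weight for c in prior.components] == pytest.approx([0.8, 0.2])

    def test_degenerate_mixture_equals_single_component(self, daily_counts):
        single = BLRM(prior=robustify_prior(self.MAP, WIP_EV, 1.0))
        single.fit(daily_counts)
        mixture_prior = robustify_prior(self.MAP, WIP_EV, 0.8)
        # force all weight onto the MAP component
        from dataclasses import replace

        forced = replace(
            mixture_prior,
            components=(
                replace(mixture_prior.components[0], weight=1.0 - 1e-12),
                replace(mixture_prior.components[1], weight=1e-12),
            ),
        )
        mixed = BLRM(prior=forced).fit(daily_counts)
        for d in (2.5, 5.0):
            assert mixed.overdose_prob(d) == pytest.approx(
                single.overdose_prob(d), abs=1e-6
            )


@pytest.fixture(scope="module")
def weekly_rescaled(weekly_counts):
    return rescale_doses(weekly_counts, 168.0, 24.0)


class TestMapPrior:

    def test_no_heterogeneity_recovers_schedule_posterior(self, weekly_rescaled):
        """With between-schedule sds forced to ~0 the predictive collapses
        onto the completed schedule's parameter posterior."""
        comp = map_prior_from_schedule(
            weekly_rescaled, WIP_EV, tau_scales=(1e-3, 1e-3),
            n_steps=2000, burn=800, random_state=3,
        )
        direct = BLRM(prior=WIP_EV).fit(
            DoseToxData(weekly_rescaled.doses, weekly_rescaled.n,
                        weekly_rescaled.r)
        )
        A1, A2, W = direct.component_posteriors_[0]
        mean_direct = (float((A1 * W).sum()), float((A2 * W).sum()))
        assert comp.mean[0] == pytest.approx(mean_direct[0], abs=0.15)
        assert comp.mean[1] == pytest.approx(mean_direct[1], abs=0.15)

    def test_large_heterogeneity_blocks_borrowing(self, weekly_rescaled):
        comp = map_prior_from_schedule(
            weekly_rescaled, WIP_EV, tau_scales=(10.0, 10.0),
            n_steps=2000, burn=800, random_state=3,
        )
        # predictive spread at least as wide as the WIP's scales
        assert comp.sd[0] >= WIP_EV.components[0].sd[0]
        assert comp.sd[1] >= WIP_EV.components[0].sd[1]

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            map_prior_from_schedule(
                DoseToxData((5.0,), (0,), (0,)), WIP_EV
            )
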