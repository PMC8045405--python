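import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from titepk import (
    BridgingCRM,
    bridge_skeletons,
    mixture_estimate,
    pava_isotonic,
    probit_fit,
)
from titepk.models.bridge import bridged_mixture
from conftest import pava_maxmin_oracle


class TestProbitFit:
    def test_recovers_exact_probit_data(self):
        from scipy.stats import norm

        doses = np.array([10.0, 20.0, 30.0, 40.0])
        b0, b1 = -1.2, 0.9
        z = (doses - doses.mean()) / doses.std(ddof=1)
        p = norm.cdf(b0 + b1 * z)
        m = np.full(4, 1000.0)
        fit = probit_fit(doses, m * p, m)  # expected counts: exact MLE known
        assert fit.beta0 == pytest.approx(b0, abs=1e-3)
        assert fit.beta1 == pytest.approx(b1, abs=1e-3)
        assert np.allclose(fit.predict(doses), p, atol=1e-4)

    def test_flat_data_gives_pooled_rate(self):
        doses = np.array([1.0, 2.0, 3.0])
        fit = probit_fit(doses, [1, 1, 1], [4, 4, 4])
        assert np.allclose(fit.predict(doses), 0.25, atol=1e-4)

    def test_everolimus_weekly_increasing(self, weekly_counts):
        fit = probit_fit(weekly_counts.doses, weekly_counts.r, weekly_counts.n)
        p = fit.predict(weekly_counts.doses)
        assert p[1] > p[0]
        assert p[1] == pytest.approx(4 / 13, abs=0.01)  # saturated fit

    def test_separated_data_stays_bounded(self):
        fit = probit_fit([10.0, 20.0], [0, 5], [5, 5], bound=10.0)
        assert abs(fit.beta0) <= 10.0 and abs(fit.beta1) <= 10.0


class TestIsotonic:
    def test_monotone_input_unchanged(self):
        x, m = np.array([0, 1, 3]), np.array([4, 4, 4])
        assert np.allclose(pava_isotonic(x, m), x / m)

    def test_single_violation_pools(self):
        assert np.allclose(pava_isotonic([1, 0], [2, 2]), [0.25, 0.25])

    def test_zero_patients_rejected(self):
        with pytest.raises(ValueError):
            pava_isotonic([0, 1], [3, 0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.integers(1, 5), st.integers(0, 5)), min_size=2,
            max_size=6,
        )
    )
    def test_equals_maxmin_formula(self, data):
        m = np.array([d[0] for d in data], dtype=float)
        x = np.minimum([d[1] for d in data], m)
        got = pava_isotonic(x, m)
        assert np.allclose(got, pava_maxmin_oracle(x, m), atol=1e-12)
        assert np.all(np.diff(got) >= -1e-12)

    def test_pooled_blocks_preserve_weighted_mean(self):
        x = np.array([2.0, 0.0, 1.0])
        m = np.array([3.0, 3.0, 3.0])
        iso = pava_isotonic(x, m)
        assert (iso * m).sum() == pytest.approx(x.sum())


class TestMixture:
    def test_identical_estimates_give_half_weight(self):
        w, mix = mixture_estimate([0.2, 0.4], [0.2, 0.4], [1, 2], [5, 5])
        assert np.allclose(w, 0.5)
        assert np.allclose(mix, [0.2, 0.4])

    def test_empty_level_gets_half_weight(self):
        w, mix = mixture_estimate([0.1], [0.4], [0], [0])
        assert w[0] == pytest.approx(0.5)
        assert mix[0] == pytest.approx(0.25)

    def test_everolimus_weekly_lambda_hand_computed(self, weekly_counts):
        """The 30 mg level's likelihood-ratio weight matches a direct
        evaluation of the binomial ratio formula."""
        fit = probit_fit(weekly_counts.doses, weekly_counts.r, weekly_counts.n)
        pp = np.clip(fit.predict(weekly_counts.doses), 1e-6, 1 - 1e-6)
        pn = np.clip(
            pava_isotonic(weekly_counts.r, weekly_counts.n), 1e-6, 1 - 1e-6
        )
        x, m = 4, 13
        lam = (pp[1] ** x * (1 - pp[1]) ** (m - x)) / (
            pn[1] ** x * (1 - pn[1]) ** (m - x)
        )
        w, _ = mixture_estimate(
            fit.predict(weekly_counts.doses), pn,
            weekly_counts.r, weekly_counts.n,
        )
        assert w[1] == pytest.approx(lam / (lam + 1), rel=1e-9)

    def test_mixture_within_envelope(self):
        rng = np.random.default_rng(0)
        pp = np.sort(rng.uniform(0.05, 0.9, 5))
        pn = np.sort(rng.uniform(0.05, 0.9, 5))
        x = rng.integers(0, 4, 5)
        m = x + rng.integers(1, 4, 5)
        _, mix = mixture_estimate(pp, pn, x, m)
        assert np.all(mix >= np.minimum(pp, pn) - 1e-12)
        assert np.all(mix <= np.maximum(pp, pn) + 1e-12)


class TestBridgeSkeletons:
    def test_shift_formulas(self):
        s1, s2, s3 = bridge_skeletons([0.1, 0.2, 0.3])
        assert np.allclose(s1, [0.1, 0.2, 0.3])
        assert np.allclose(s2, [0.2, 0.3, 0.65])
        assert np.allclose(s3, [0.05, 0.1, 0.2])

    def test_all_strictly_increasing(self):
        for s in bridge_skeletons([0.05, 0.18, 0.33, 0.5]):
            assert np.all(np.diff(s) > 0)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            bridge_skeletons([0.3])

    def test_untried_levels_tolerated(self):
        w, mix, _ = bridged_mixture(
            [2.5, 5.0, 7.5, 10.0], [1, 2, 0, 0], [3, 6, 0, 0]
        )
        assert w[2] == pytest.approx(0.5)  # empty level
        assert mix.shape == (4,)


class TestModelAveraging:
    def test_no_data_gives_equal_weights(self):
        model = BridgingCRM(skeletons=bridge_skeletons([0.1, 0.25, 0.4]))
        model.fit(None)
        assert np.allclose(model.model_weights_, 1 / 3, atol=1e-9)

    def test_identical_skeletons_reduce_to_single_crm(self, daily_counts):
        from titepk import CRM

        sk = np.array([0.12, 0.30, 0.50, 0.68])
        model = BridgingCRM(skeletons=[sk, sk, sk]).fit(
            daily_counts.r, daily_counts.n
        )
        single = CRM(skeleton=sk).fit(daily_counts.r, daily_counts.n)
        assert np.allclose(model.pi_mean_, single.pi_mean_, atol=1e-12)
        assert model.exceed_prob(0, 0.30) == pytest.approx(
            single.exceed_prob(0, 0.30), abs=1e-12
        )

    def test_average_within_convex_hull(self, weekly_counts, daily_counts):
        model = BridgingCRM.from_completed_schedule(
            weekly_counts.doses, weekly_counts.r, weekly_counts.n
        ).fit(daily_counts.r, daily_counts.n)
        assert np.isclose(model.model_weights_.sum(), 1.0)
        per = np.array([c.pi_mean_ for c in model.crms_])
        assert np.all(model.pi_mean_ <= per.max(axis=0) + 1e-12)
        assert np.all(model.pi_mean_ >= per.min(axis=0) - 1e-12)
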