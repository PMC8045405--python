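import numpy as np
import pytest

from titepk import (
    PKParams,
    Regimen,
    ReferenceSchedule,
    everolimus_counts,
    everolimus_subjects,
)

EVEROLIMUS_PK = PKParams(30.0, 0.37)
EVEROLIMUS_REF = Regimen(5.0, 24.0, 504.0)


@pytest.fixture(scope="session")
def pk():
    return EVEROLIMUS_PK


@pytest.fixture(scope="session")
def ref_regimen():
    return EVEROLIMUS_REF


@pytest.fixture(scope="session")
def ref_schedule():
    return ReferenceSchedule(EVEROLIMUS_REF)


@pytest.fixture(scope="session")
def daily_subjects():
    return everolimus_subjects(("daily",))


@pytest.fixture(scope="session")
def pooled_subjects():
    return everolimus_subjects(("weekly", "daily"))


@pytest.fixture(scope="session")
def daily_counts():
    return everolimus_counts("daily")


@pytest.fixture(scope="session")
def weekly_counts():
    return everolimus_counts("weekly")


def ode_ceff_oracle(regimen, pk, times):
    """Effect-compartment profile by adaptive numerical ODE integration.

    Independent of the closed-form implementation: integrates the pair of
    linear ODEs segment by segment between bolus times with tight
    tolerances.
    """
    from scipy.integrate import solve_ivp

    ke, keff = pk.k_e, pk.k_eff

    def rhs(_t, y):
        c, ceff = y
        return [-ke * c, keff * (c - ceff)]

    times = np.asarray(times, dtype=float)
    dose_times = set(regimen.dose_times().tolist())
    breaks = sorted(dose_times | {0.0, float(regimen.cycle_length)})
    y = np.array([0.0, 0.0])
    out = np.empty_like(times)
    for a, b in zip(breaks[:-1], breaks[1:]):
        if a in dose_times:
            y = y + np.array([regimen.dose, 0.0])
        seg = np.unique(np.append(times[(times > a) & (times <= b)], b))
        sol = solve_ivp(rhs, (a, b), y, t_eval=seg, rtol=1e-11, atol=1e-13)
        for t, val in zip(sol.t, sol.y[1]):
            out[np.isclose(times, t)] = val
        y = sol.y[:, -1]
    out[np.isclose(times, 0.0)] = 0.0
    return out


def pava_maxmin_oracle(x, m):
    """Brute-force evaluation of the isotonic max-min formula."""
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    J = x.size
    out = np.empty(J)
    for j in range(J):
        best = -np.inf
        for u in range(j + 1):
            worst = np.inf
            for v in range(j, J):
                worst = min(worst, x[u : v + 1].sum() / m[u : v + 1].sum())
            best = max(best, worst)
        out[j] = best
    return out
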