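"""Unit and property tests for the survival estimators.

Each estimator is checked against an independent oracle: a brute-force
partial-likelihood scan and lifelines for Cox, hand computation and
lifelines for the Aalen–Johansen CIF, and exhaustive pair enumeration
for the time-dependent AUC.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from comorbindex.survival_core import auc_se, cuminc, fit_cox, km, td_auc

# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------


def brute_force_loglik(beta, x, time, event):
    """Naive one-covariate Cox log partial likelihood (no ties assumed)."""
    ll = 0.0
    for i in range(len(time)):
        if not event[i]:
            continue
        risk = [j for j in range(len(time)) if time[j] >= time[i]]
        ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


def test_cox_matches_brute_force_scan():
    """Six-subject toy: Newton solution equals the 1-D grid maximizer."""
    time = np.array([1.0, 2, 3, 4, 5, 6])
    event = np.array([1, 0, 1, 0, 1, 0], dtype=bool)
    x = np.array([1.0, 0, 1, 0, 0, 1])  # last event subject is unexposed
    grid = np.linspace(-4, 4, 160001)
    ll = np.array([brute_force_loglik(b, x, time, event) for b in grid])
    oracle = grid[np.argmax(ll)]
    fit = fit_cox(x[:, None], time, event)
    assert fit.converged
    assert fit.coef[0] == pytest.approx(oracle, abs=1e-3)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_cox_matches_lifelines_with_ties(seed):
    """Random tied data: Efron fit agrees with lifelines to 1e-4."""
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(seed)
    n = 300
    X = pd.DataFrame(
        {"a": rng.binomial(1, 0.4, n).astype(float), "b": rng.normal(size=n)}
    )
    lin = 0.6 * X["a"] - 0.3 * X["b"]
    t = np.ceil(rng.exponential(np.exp(-lin)) * 5)  # heavy ties
    c = np.ceil(rng.exponential(10, n))
    time = np.minimum(t, c)
    event = t <= c
    ours = fit_cox(X, time, event)
    df = X.assign(T=time, E=event.astype(int))
    ref = lifelines.CoxPHFitter().fit(df, "T", "E")
    assert np.abs(ours.coef - ref.params_.values).max() < 1e-4
    assert np.abs(ours.se - ref.standard_errors_.values).max() < 1e-4


def test_cox_null_covariate_recovers_zero():
    rng = np.random.default_rng(42)
    n = 5000
    x = rng.binomial(1, 0.3, n).astype(float)
    time = rng.exponential(1, n)
    event = rng.random(n) < 0.7
    fit = fit_cox(x[:, None], time, event)
    assert abs(fit.coef[0]) < 3 * fit.se[0]


def test_cox_input_validation():
    t = np.array([1.0, 2, 3])
    with pytest.raises(ValueError, match="no events"):
        fit_cox(np.ones((3, 1)) * [[1], [0], [1]], t, [0, 0, 0])
    with pytest.raises(ValueError, match="constant"):
        fit_cox(np.ones((3, 1)), t, [1, 0, 1])
    X = pd.DataFrame({"a": [1.0, 0, 1], "b": [1.0, 0, 1]})
    with pytest.raises(ValueError, match="duplicate"):
        fit_cox(X, t, [1, 0, 1])


def test_cox_separation_flagged():
    """Perfectly separating covariate: warning raised, coefficient capped."""
    time = np.array([1.0, 2, 3, 4, 5, 6])
    event = np.array([1, 0, 1, 0, 1, 0], dtype=bool)
    x = np.array([1.0, 0, 1, 0, 1, 0])
    with pytest.warns(RuntimeWarning, match="separation"):
        fit = fit_cox(x[:, None], time, event)
    assert any("separation" in w for w in fit.warnings_)


# ---------------------------------------------------------------------------
# Kaplan-Meier and cumulative incidence
# ---------------------------------------------------------------------------


def test_km_closed_forms():
    s = km([1, 2, 3, 4], [0, 0, 0, 0])
    assert s(10) == 1.0
    s = km([1, 2, 3, 4], [1, 1, 1, 1])
    np.testing.assert_allclose([s(1), s(2), s(3), s(4)], [0.75, 0.5, 0.25, 0.0])
    assert s(0.5) == 1.0


def test_cuminc_hand_example():
    """Five subjects, two causes: hand Aalen–Johansen values."""
    est = cuminc([1, 2, 3, 4, 5], ["c1", "c2", "censored", "c1", "censored"])
    assert est.cif["c1"](0.5) == 0.0
    assert est.cif["c1"](4) == pytest.approx(0.5)
    assert est.cif["c2"](4) == pytest.approx(0.2)
    assert est.survival(4) == pytest.approx(0.3)


def test_cuminc_single_cause_equals_km():
    rng = np.random.default_rng(3)
    time = np.ceil(rng.exponential(5, 200))
    event = rng.random(200) < 0.6
    cause = np.where(event, "death", "censored")
    est = cuminc(time, cause)
    s = km(time, event)
    for t in [0.5, 1, 2, 5, 10, 30]:
        assert est.cif["death"](t) == pytest.approx(1 - s(t), abs=1e-12)


def test_cuminc_all_censored():
    est = cuminc([1, 2, 3], ["censored"] * 3, causes=["a"])
    assert est.cif["a"](5) == 0.0
    assert est.survival(5) == 1.0


@given(st.integers(0, 1000))
def test_cuminc_conservation_and_monotone(seed):
    """CIFs are nondecreasing, within [0,1], and sum with survival to 1."""
    rng = np.random.default_rng(seed)
    n = rng.integers(3, 60)
    time = np.ceil(rng.exponential(5, n))
    cause = rng.choice(["a", "b", "censored"], size=n)
    est = cuminc(time, cause, causes=["a", "b"])
    grid = np.unique(np.concatenate([time, [0.1, 100.0]]))
    prev = {"a": -1.0, "b": -1.0}
    for t in grid:
        at = est.at(t)
        assert abs(at["a"] + at["b"] + at["survival"] - 1.0) < 1e-10
        for c in ("a", "b"):
            assert 0.0 <= at[c] <= 1.0
            assert at[c] >= prev[c]
            prev[c] = at[c]


def test_cuminc_matches_lifelines():
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(9)
    n = 400
    time = rng.exponential(5, n)  # continuous: lifelines jitters tied times
    code = rng.choice([0, 1, 2], size=n, p=[0.3, 0.4, 0.3])  # 0 = censored
    est = cuminc(time, np.where(code == 0, "censored", code.astype(str)))
    ajf = lifelines.AalenJohansenFitter(calculate_variance=False)
    ajf.fit(time, code, event_of_interest=1)
    ref = ajf.cumulative_density_
    for t in [1, 2, 5, 10]:
        ref_val = float(ref[ref.index <= t].iloc[-1, 0]) if (ref.index <= t).any() else 0.0
        assert est.cif["1"](t) == pytest.approx(ref_val, abs=1e-10)


# ---------------------------------------------------------------------------
# time-dependent AUC
# ---------------------------------------------------------------------------


def enumerate_incident_auc(marker, time, event, horizon):
    """Exhaustive incident/dynamic AUC with Kaplan–Meier concordance weights."""
    s = km(time, event)
    num = den = 0.0
    for ti in sorted(set(np.asarray(time)[np.asarray(event, dtype=bool)])):
        if ti > horizon:
            continue
        cases = [i for i in range(len(time)) if time[i] == ti and event[i]]
        controls = [i for i in range(len(time)) if time[i] > ti]
        if not controls:
            continue
        conc = sum(
            1.0 if marker[i] > marker[j] else 0.5 if marker[i] == marker[j] else 0.0
            for i in cases
            for j in controls
        )
        auc = conc / (len(cases) * len(controls))
        w = 2.0 * (s.left_limit(ti) - s(ti)) * s(ti)
        num += w * auc
        den += w
    return num / den


def test_td_auc_perfect_marker():
    assert td_auc([4, 3, 2, 1], [1, 2, 3, 4], [1, 1, 1, 1], 4) == 1.0


def test_td_auc_toy_matches_enumeration():
    marker = [4.0, 3.0, 1.0, 2.0]
    time = [1.0, 2.0, 3.0, 4.0]
    event = [1, 1, 1, 1]
    expected = enumerate_incident_auc(marker, time, event, 4)
    assert td_auc(marker, time, event, 4) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(5 / 6)  # AUC(1)=1, AUC(2)=1, AUC(3)=0, weights 3:2:1


@given(st.integers(0, 500))
def test_td_auc_matches_enumeration_random(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 25))
    marker = rng.integers(0, 6, n).astype(float)  # force marker ties
    time = np.ceil(rng.exponential(3, n))
    event = rng.random(n) < 0.7
    if not (event & (time <= 5)).any() or not (time > time[event].min()).any():
        return
    try:
        ours = td_auc(marker, time, event, 5)
    except ValueError:
        return
    assert ours == pytest.approx(enumerate_incident_auc(marker, time, event, 5), abs=1e-12)


def test_td_auc_null_marker_near_half():
    rng = np.random.default_rng(5)
    n = 5000
    marker = rng.normal(size=n)
    time = np.ceil(rng.exponential(5, n))
    event = rng.random(n) < 0.5
    assert td_auc(marker, time, event, 10) == pytest.approx(0.5, abs=0.03)


def test_td_auc_monotone_transform_invariant():
    rng = np.random.default_rng(8)
    n = 200
    marker = rng.normal(size=n)
    time = np.ceil(rng.exponential(3, n))
    event = rng.random(n) < 0.6
    base = td_auc(marker, time, event, 5)
    for f in (lambda m: 3 * m + 7, np.exp, lambda m: m**3):
        assert td_auc(f(marker), time, event, 5) == pytest.approx(base, abs=1e-12)


def test_td_auc_errors_without_events():
    with pytest.raises(ValueError):
        td_auc([1, 2], [5, 6], [0, 0], 3)


def test_auc_se_reasonable():
    se = auc_se(0.7, 100, 1000)
    assert 0.0 < se < 0.1
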