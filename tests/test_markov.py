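"""Markov cohort engine: primitives, invariants and the microsim oracle."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mpes.config import MarkovConfig
from mpes.data import ValidationError
from mpes.markov import (MarkovModel, MarkovSpec, TreatmentCosts, UtilityInputs,
                         apply_hr, discount_factor, microsimulate,
                         solve_pd_death_tp, u_std_weighted, weibull_cycle_tp)
from mpes.survival import WeibullParams


@pytest.mark.parametrize("gamma,lam,t,expected", [
    (1.0, 0.05, 1, 0.048771),
    (1.0, 0.05, 50, 0.048771),   # exponential => memoryless, constant tp
    (2.0, 0.01, 5, 0.086069),
])
def test_weibull_cycle_tp_examples(gamma, lam, t, expected):
    assert weibull_cycle_tp(WeibullParams(gamma, lam), t) == pytest.approx(expected, abs=1e-6)


def test_weibull_cycle_tp_vanishes_with_rate():
    assert weibull_cycle_tp(WeibullParams(1.2, 1e-12), 10) == pytest.approx(0.0, abs=1e-9)


def test_apply_hr_examples():
    assert apply_hr(0.1, 1.0) == pytest.approx(0.1)
    assert apply_hr(0.1, 0.5) == pytest.approx(0.051317, abs=1e-6)
    assert apply_hr(1.0, 0.5) == pytest.approx(1.0)  # tp=1 stays 1


@settings(derandomize=True, max_examples=100)
@given(tp=st.floats(0.001, 0.999), hr=st.floats(0.05, 0.999))
def test_apply_hr_direction(tp, hr):
    """A protective hazard ratio strictly decreases every cycle tp."""
    assert apply_hr(tp, hr) < tp


def test_solve_pd_death_tp_example():
    assert solve_pd_death_tp(18, 6, 1.0) == pytest.approx(0.07996, abs=1e-4)


def test_solve_pd_death_tp_boundaries():
    with pytest.raises(ValidationError, match="infeasible"):
        solve_pd_death_tp(6, 6, 1.0)
    with pytest.raises(ValidationError, match="m_other"):
        solve_pd_death_tp(18, 6, 0.5)
    with pytest.raises(ValidationError):
        solve_pd_death_tp(18, 6, 0.0)
    # with an other-cause mean supplied the general decomposition solves
    tp = solve_pd_death_tp(20, 6, 0.9, m_other=30)
    assert 0 < tp < 1


@pytest.mark.parametrize("t,expected", [(12, 1.0), (13, 0.966184), (25, 0.933511)])
def test_discount_factor_examples(t, expected):
    assert float(discount_factor(t)) == pytest.approx(expected, abs=1e-6)


def test_u_std_weighted_examples():
    u = UtilityInputs()
    assert u_std_weighted(1.0, 0.0, 0.0, u) == pytest.approx(0.770)
    assert u_std_weighted(0.0, 1.0, 0.0, u) == pytest.approx(0.538)
    assert u_std_weighted(0.9, 0.095, 0.005, u) == pytest.approx(0.74693, abs=1e-5)
    with pytest.raises(ValidationError):
        u_std_weighted(0.9, 0.2, 0.005, u)


# ---------------------------------------------------------------------------
# cohort engine
# ---------------------------------------------------------------------------

def _spec(structure="three_state", n_cycles=60, **kw):
    costs = {tr: TreatmentCosts(drug_per_cycle=100, drug_cycles=10,
                                followup_per_cycle=400, terminal=2000)
             for tr in ("A", "B")}
    base = dict(
        structure=structure, baseline="A",
        weibull=WeibullParams(1.1, 0.106) if structure == "three_state"
        else WeibullParams(1.25, 0.0235),
        treatments=["A", "B"], hazard_ratios={"B": 0.7}, costs=costs,
        config=MarkovConfig(n_cycles=n_cycles, cohort=10_000),
        pd_death_tp=0.08 if structure == "three_state" else None,
    )
    base.update(kw)
    return MarkovSpec(**base)


@pytest.mark.parametrize("structure", ["two_state", "three_state"])
def test_matrix_rows_and_absorbing_state(structure):
    model = MarkovModel(_spec(structure))
    for t in (1, 10, 60):
        P = model.build_matrix("A", t)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(P >= 0)
        assert np.allclose(P[-1], np.eye(len(P))[-1])  # Dead absorbing
    if structure == "three_state":
        assert P[0, 2] == pytest.approx(0.005)  # fixed other-cause entry


def test_matrix_infeasible_row_raises():
    spec = _spec(weibull=WeibullParams(1.1, 2.0), other_cause_tp=0.9)
    with pytest.raises(ValidationError, match="infeasible"):
        MarkovModel(spec).build_matrix("A", 5)


@pytest.mark.parametrize("structure", ["two_state", "three_state"])
def test_cohort_conservation_and_monotonicity(structure):
    trace = MarkovModel(_spec(structure)).run("B")
    assert np.allclose(trace.occupancy.sum(axis=1), 10_000, atol=1e-9)
    assert np.all(trace.occupancy >= 0)
    dead = trace.occupancy[:, -1]
    assert np.all(np.diff(dead) >= -1e-12)


def test_certain_death_after_one_cycle():
    spec = _spec("two_state", weibull=WeibullParams(1.0, 50.0))  # tp ~ 1
    trace = MarkovModel(spec).run("A")
    assert trace.occupancy[1, 1] == pytest.approx(10_000, rel=1e-6)


def test_constant_matrix_matches_matrix_power():
    """Exponential transitions are time-constant, so occupancy at cycle t
    equals the initial row times M^t."""
    spec = _spec("three_state", weibull=WeibullParams(1.0, 0.08))
    model = MarkovModel(spec)
    trace = model.run("A")
    M = model.build_matrix("A", 1)
    v0 = np.array([10_000.0, 0.0, 0.0])
    for t in (1, 7, 33, 60):
        assert np.allclose(trace.occupancy[t], v0 @ np.linalg.matrix_power(M, t),
                           rtol=1e-10)


def test_expected_cost_qaly_trivial_cases():
    spec = _spec("three_state", n_cycles=1,
                 costs={tr: TreatmentCosts(0, 0, 0, 0) for tr in ("A", "B")})
    model = MarkovModel(spec)
    trace = model.run("A")
    # zero costs and zero utilities give (0, 0)
    c, q = model.expected_cost_qaly(trace, "A",
                                    utilities={"surviving": 0.0, "pd": 0.0,
                                               "other_causes": 0.0})
    assert (c, q) == (0.0, 0.0)


def test_single_cycle_all_pd_qaly():
    """One cycle with the whole cohort progressing: QALY = U_PD / 12."""
    costs = {"A": TreatmentCosts(0, 0, 0, 0)}
    spec = MarkovSpec(structure="three_state", baseline="A",
                      weibull=WeibullParams(1.0, 50.0),  # certain progression
                      treatments=["A"], hazard_ratios={}, costs=costs,
                      config=MarkovConfig(n_cycles=1, cohort=1000),
                      other_cause_tp=0.0, pd_death_tp=0.0)
    model = MarkovModel(spec)
    trace = model.run("A")
    assert trace.occupancy[1, 1] == pytest.approx(1000, rel=1e-6)
    _, q = model.expected_cost_qaly(trace, "A")
    assert q == pytest.approx(0.538 / 12, rel=1e-4)


def test_discounted_totals_split_run_invariance():
    """Accumulating 60 cycles at once equals the sum of two 30-cycle halves
    chained on the same occupancy path."""
    spec = _spec("three_state", n_cycles=60)
    model = MarkovModel(spec)
    trace = model.run("B")
    c, q = model.expected_cost_qaly(trace, "B")

    def partial(t0, t1):
        cc = qq = 0.0
        tc = spec.costs["B"]
        f_pd = 0.75
        for t in range(t0, t1):
            occ = trace.occupancy[t + 1]
            d = float(discount_factor(t + 1, spec.config.discount_rate,
                                      spec.config.discount_start_cycle))
            tp = float(model.transition_probs("B", t + 1))
            u_std = u_std_weighted(1 - tp - spec.other_cause_tp, tp,
                                   spec.other_cause_tp, spec.utilities)
            qq += (occ[0] * u_std + occ[1] * 0.538) / 12 * d
            drug = tc.drug_per_cycle if t + 1 <= tc.drug_cycles else 0.0
            dead_in = trace.occupancy[t][:2].sum() - occ[:2].sum()
            cc += (occ[0] * (drug + tc.followup_per_cycle * (1 - f_pd))
                   + occ[1] * tc.followup_per_cycle * f_pd
                   + dead_in * tc.terminal) * d
        return cc, qq

    c1, q1 = partial(0, 30)
    c2, q2 = partial(30, 60)
    assert c == pytest.approx((c1 + c2) / spec.config.cohort, rel=1e-12)
    assert q == pytest.approx((q1 + q2) / spec.config.cohort, rel=1e-12)


def test_psa_degenerate_matches_cohort_valuation():
    """With every sampling distribution collapsed, PSA draws equal the
    deterministic cohort valuation."""
    spec = _spec("three_state",
                 utilities=UtilityInputs(surviving_se=0, pd_se=0, other_causes_se=0),
                 costs={tr: TreatmentCosts(100, 10, 400, 2000, se_fraction=0.0)
                        for tr in ("A", "B")},
                 followup_pd_fraction=(0.75, 0.75), alive_utility_se=0.0)
    model = MarkovModel(spec)
    psa = model.psa(n_draws=5, seed=9)
    for tr in ("A", "B"):
        c, q = model.expected_cost_qaly(model.run(tr), tr,
                                        hr=spec.hr(tr))
        assert np.allclose(psa.costs[tr], c, rtol=1e-10)
        assert np.allclose(psa.qalys[tr], q, rtol=1e-10)


def test_cohort_trace_matches_microsimulation(rng):
    """Cohort occupancy agrees with a 100,000-person microsimulation within
    3 binomial standard errors, on 5 randomised specs."""
    n_persons = 100_000
    for rep in range(5):
        gamma = float(rng.uniform(0.8, 1.6))
        lam = float(rng.uniform(0.02, 0.12))
        structure = "three_state" if rep % 2 == 0 else "two_state"
        spec = _spec(structure, n_cycles=24,
                     weibull=WeibullParams(gamma, lam),
                     pd_death_tp=float(rng.uniform(0.03, 0.15))
                     if structure == "three_state" else None)
        model = MarkovModel(spec)
        trace = model.run("A")
        counts = microsimulate(spec, "A", n_persons, rng)
        frac_cohort = trace.occupancy / spec.config.cohort
        frac_micro = counts / n_persons
        se = np.sqrt(np.maximum(frac_cohort * (1 - frac_cohort), 1e-12) / n_persons)
        assert np.all(np.abs(frac_micro - frac_cohort) <= 3 * se + 1e-6)


def test_spec_validation():
    with pytest.raises(ValidationError, match="pd_death_tp"):
        _spec("three_state", pd_death_tp=None)
    with pytest.raises(ValidationError, match="hazard ratio"):
        _spec(hazard_ratios={})
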