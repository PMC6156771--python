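"""Decision metrics: ICER, net benefit, CEAC, EVPI."""

import numpy as np
import pytest

from mpes.cea import (PSAResult, analyse, ceac, effective_population,
                      evpi_per_person, incremental_icer, net_benefit,
                      population_evpi)
from mpes.config import EVPISettings
from mpes.data import ValidationError


def _psa(costs, qalys, seed=0):
    n = len(next(iter(costs.values())))
    return PSAResult(costs={k: np.asarray(v, float) for k, v in costs.items()},
                     qalys={k: np.asarray(v, float) for k, v in qalys.items()},
                     n_draws=n, seed=seed)


def test_icer_published_worked_example(rng):
    """Mean incremental cost 4,624 GBP over 0.154 QALYs: ICER ~ 30,026."""
    n = 20_000
    psa = _psa({"M+P": 11_237 + 4_400 * rng.standard_normal(n),
                "D+P": 15_861 + 4_400 * rng.standard_normal(n)},
               {"M+P": np.abs(0.813 + 0.05 * rng.standard_normal(n)),
                "D+P": np.abs(0.967 + 0.05 * rng.standard_normal(n))})
    # shift draws so the means are exact: the ICER is a ratio of means
    psa.costs["D+P"] += 4_624 - (psa.costs["D+P"].mean() - psa.costs["M+P"].mean())
    psa.qalys["D+P"] += 0.154 - (psa.qalys["D+P"].mean() - psa.qalys["M+P"].mean())
    res = incremental_icer(psa, "M+P", "D+P")
    assert res.icer == pytest.approx(4_624 / 0.154, rel=1e-9)
    assert res.icer == pytest.approx(30_026, abs=1.0)
    assert res.label == "icer"


def test_icer_dominance_labels():
    psa = _psa({"A": [100.0, 100.0], "B": [100.0, 100.0]},
               {"A": [1.0, 1.0], "B": [1.2, 1.2]})
    res = incremental_icer(psa, "A", "B")
    assert res.label == "dominant" and res.icer == 0.0
    res2 = incremental_icer(psa, "B", "A")
    assert res2.label == "dominated"
    same = _psa({"A": [1.0, 2.0], "B": [1.0, 2.0]}, {"A": [1.0, 1.0], "B": [1.0, 1.0]})
    assert incremental_icer(same, "A", "B").label == "undefined"


def test_icer_antisymmetry(rng):
    psa = _psa({"A": rng.uniform(0, 100, 50), "B": rng.uniform(0, 100, 50)},
               {"A": rng.uniform(0, 2, 50), "B": rng.uniform(0, 2, 50)})
    ab = incremental_icer(psa, "A", "B")
    ba = incremental_icer(psa, "B", "A")
    assert ab.delta_cost == pytest.approx(-ba.delta_cost)
    assert ab.delta_qaly == pytest.approx(-ba.delta_qaly)


def test_net_benefit_published_worked_example():
    """D+P 2-state entries (cost 15,862, QALY 0.967) at 30,000/QALY."""
    nb = float(net_benefit(15_862, 0.967, 30_000))
    assert nb == pytest.approx(13_148, abs=1.0)
    assert float(net_benefit(0, 0, 12_345)) == 0.0
    assert float(net_benefit(100, 1, 0)) == -100.0
    with pytest.raises(ValueError):
        net_benefit(1, 1, -5)


def test_ceac_normalisation_and_indicator_limits(rng):
    psa = _psa({"A": rng.uniform(0, 100, 500), "B": rng.uniform(0, 100, 500),
                "C": rng.uniform(0, 100, 500)},
               {"A": rng.uniform(0, 2, 500), "B": rng.uniform(0, 2, 500),
                "C": rng.uniform(0, 2, 500)})
    curves = ceac(psa, [0, 10_000, 30_000, 50_000])
    assert np.allclose(curves.sum(axis=1), 1.0, atol=1e-12)
    # a single draw yields indicator curves
    one = _psa({"A": [10.0], "B": [0.0]}, {"A": [1.0], "B": [1.0]})
    ind = ceac(one, [0.0])
    assert list(ind.iloc[0]) == [0.0, 1.0]


def test_ceac_ties_split_equally():
    psa = _psa({"A": [10.0], "B": [10.0]}, {"A": [1.0], "B": [1.0]})
    curves = ceac(psa, [20_000])
    assert list(curves.iloc[0]) == [0.5, 0.5]


def test_ceac_argmax_vs_mean_nb_can_disagree():
    """The treatment maximising mean net benefit need not top the CEAC: a
    skewed distribution can win on average while rarely winning per draw."""
    n = 9_999
    nb_a = np.zeros(n)
    nb_b = np.full(n, -1.0)
    nb_b[: n // 3] = 10.0  # B wins only 1/3 of draws but wins big
    psa = _psa({"A": -nb_a, "B": -nb_b}, {"A": np.zeros(n), "B": np.zeros(n)})
    curves = ceac(psa, [0.0])
    mean_nb = {tr: net_benefit(psa.costs[tr], psa.qalys[tr], 0.0).mean()
               for tr in ("A", "B")}
    assert mean_nb["B"] > mean_nb["A"]          # B best on expectation
    assert curves.iloc[0]["A"] > curves.iloc[0]["B"]  # yet A tops the CEAC


def test_evpi_point_mass_is_zero():
    psa = _psa({"A": [5.0] * 10, "B": [7.0] * 10}, {"A": [1.0] * 10, "B": [1.1] * 10})
    assert evpi_per_person(psa, 30_000) == 0.0


def test_evpi_centered_normal_closed_form(rng):
    """Two treatments whose NB difference is N(0, sigma^2): per-person EVPI
    approaches sigma/sqrt(2*pi)."""
    n = 400_000
    sigma = 100.0
    diff = sigma * rng.standard_normal(n)
    psa = _psa({"A": np.zeros(n), "B": -diff}, {"A": np.zeros(n), "B": np.zeros(n)})
    expected = sigma / np.sqrt(2 * np.pi)
    assert evpi_per_person(psa, 0.0) == pytest.approx(expected, rel=0.02)


def test_evpi_matches_brute_force(rng):
    trs = ["A", "B", "C"]
    psa = _psa({t: rng.uniform(0, 1000, 1000) for t in trs},
               {t: rng.uniform(0, 2, 1000) for t in trs})
    wtp = 25_000.0
    nb = {t: wtp * psa.qalys[t] - psa.costs[t] for t in trs}
    best_per_draw = np.zeros(1000)
    for d in range(1000):
        best_per_draw[d] = max(nb[t][d] for t in trs)
    brute = best_per_draw.mean() - max(nb[t].mean() for t in trs)
    assert evpi_per_person(psa, wtp) == pytest.approx(brute, abs=1e-9)
    # monotone in the option set
    smaller = _psa({t: psa.costs[t] for t in trs[:2]},
                   {t: psa.qalys[t] for t in trs[:2]})
    assert evpi_per_person(psa, wtp) >= evpi_per_person(smaller, wtp) - 1e-12


def test_population_evpi_multiplier():
    """12 years, 9,000/year, 3.5%: effective population ~ 9000 x 10.0017."""
    settings = EVPISettings()
    assert effective_population(settings) == pytest.approx(9000 * 10.0017, rel=1e-4)
    assert population_evpi(1.0, settings) == pytest.approx(90_015, abs=5.0)
    flat = EVPISettings(discount_rate=0.0)
    assert population_evpi(2.0, flat) == pytest.approx(2.0 * 9000 * 12)
    # discounting every year including the first is the config alternative
    alt = EVPISettings(discount_first_year=True)
    assert effective_population(alt) == pytest.approx(9000 * 10.0017 / 1.035, rel=1e-4)


def test_analyse_bundles_everything(rng):
    psa = _psa({"A": rng.uniform(0, 100, 200), "B": rng.uniform(0, 100, 200)},
               {"A": rng.uniform(0, 2, 200), "B": rng.uniform(0, 2, 200)})
    res = analyse(psa, [0, 10_000, 20_000], EVPISettings())
    assert set(res.ceac.columns) == {"A", "B"}
    assert all(v >= 0 for v in res.evpi_pp.values())
    assert res.mean_table.loc["A", "mean_cost"] == pytest.approx(psa.costs["A"].mean())
    # empty grid yields empty curves, not an error
    res2 = analyse(psa, [], EVPISettings())
    assert res2.ceac.empty


def test_psa_result_validation():
    with pytest.raises(ValidationError, match="negative QALYs"):
        _psa({"A": [1.0], "B": [1.0]}, {"A": [-0.1], "B": [1.0]})
    with pytest.raises(ValidationError, match="mismatch"):
        PSAResult(costs={"A": np.ones(3)}, qalys={"A": np.ones(2)}, n_draws=3)
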