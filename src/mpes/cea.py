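"""Decision metrics from probabilistic sensitivity analysis output.

Given per-draw, per-treatment discounted mean costs and QALYs, this module
computes incremental analysis (ICER as ratio of means, with dominance
labelling), net monetary benefit, cost-effectiveness acceptability curves,
and per-person / population expected value of perfect information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import EVPISettings
from .data import ValidationError


@dataclass
class PSAResult:
    """Per-draw discounted mean cost (GBP) and QALY per treatment."""

    costs: dict[str, np.ndarray]
    qalys: dict[str, np.ndarray]
    n_draws: int
    seed: int = 0

    def __post_init__(self) -> None:
        for d in (self.costs, self.qalys):
            for tr, arr in d.items():
                if len(arr) != self.n_draws:
                    raise ValidationError(f"treatment {tr!r}: draw count mismatch")
        if set(self.costs) != set(self.qalys):
            raise ValidationError("costs and qalys must cover the same treatments")
        for tr, q in self.qalys.items():
            if np.any(np.asarray(q) < 0):
                raise ValidationError(f"treatment {tr!r}: negative QALYs in PSA")

    @property
    def treatments(self) -> list[str]:
        return list(self.costs)

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for tr in self.treatments:
            cols[f"cost[{tr}]"] = self.costs[tr]
            cols[f"qaly[{tr}]"] = self.qalys[tr]
        return pd.DataFrame(cols)


@dataclass
class IncrementalResult:
    comparator: str
    reference: str
    delta_cost: float
    delta_cost_se: float
    delta_qaly: float
    delta_qaly_se: float
    icer: float | None
    label: str  # "icer" | "dominant" | "dominated" | "undefined"


def incremental_icer(psa: PSAResult, ref: str, comp: str) -> IncrementalResult:
    """Incremental analysis of ``comp`` versus ``ref``.

    ICER = mean(delta cost) / mean(delta QALY), the ratio of means.
    Dominance cases are labelled instead of reporting a signed ratio:
    comp cheaper and at least as effective -> "dominant"; comp costlier and
    no more effective -> "dominated"; zero mean QALY difference ->
    "undefined".
    """
    for tr in (ref, comp):
        if tr not in psa.costs:
            raise KeyError(f"treatment {tr!r} not in PSA result")
    dc = psa.costs[comp] - psa.costs[ref]
    dq = psa.qalys[comp] - psa.qalys[ref]
    n = psa.n_draws
    dc_m, dq_m = float(dc.mean()), float(dq.mean())
    dc_se = float(dc.std(ddof=1) / np.sqrt(1.0)) if n > 1 else 0.0
    dq_se = float(dq.std(ddof=1) / np.sqrt(1.0)) if n > 1 else 0.0
    # SEs reported on the scale of the PSA distribution (decision uncertainty),
    # matching how incremental tables report mean (SE)
    if dq_m == 0:
        return IncrementalResult(comp, ref, dc_m, dc_se, dq_m, dq_se, None, "undefined")
    if dc_m <= 0 and dq_m > 0:
        return IncrementalResult(comp, ref, dc_m, dc_se, dq_m, dq_se,
                                 dc_m / dq_m, "dominant")
    if dc_m >= 0 and dq_m < 0:
        return IncrementalResult(comp, ref, dc_m, dc_se, dq_m, dq_se,
                                 dc_m / dq_m, "dominated")
    return IncrementalResult(comp, ref, dc_m, dc_se, dq_m, dq_se, dc_m / dq_m, "icer")


def net_benefit(cost, qaly, wtp: float):
    """Net monetary benefit wtp*qaly - cost (GBP)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * np.asarray(qaly, dtype=float) - np.asarray(cost, dtype=float)


def _nb_matrix(psa: PSAResult, wtp: float) -> np.ndarray:
    return np.column_stack([net_benefit(psa.costs[tr], psa.qalys[tr], wtp)
                            for tr in psa.treatments])


def ceac(psa: PSAResult, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    At each threshold, a treatment's probability is the fraction of draws in
    which it attains the strictly greatest net benefit; exact ties split
    their draw's mass equally.  Columns sum to 1 at every threshold.
    """
    if len(psa.treatments) < 2:
        raise ValidationError("CEAC needs >= 2 treatments")
    rows = []
    for wtp in wtp_grid:
        nb = _nb_matrix(psa, wtp)
        best = nb.max(axis=1, keepdims=True)
        is_max = nb == best
        weights = is_max / is_max.sum(axis=1, keepdims=True)
        rows.append(weights.mean(axis=0))
    return pd.DataFrame(rows, columns=psa.treatments,
                        index=pd.Index(list(wtp_grid), name="wtp"))


def evpi_per_person(psa: PSAResult, wtp: float) -> float:
    """Per-person EVPI: E[max_t NB] - max_t E[NB], always >= 0."""
    if len(psa.treatments) < 2:
        raise ValidationError("EVPI needs >= 2 treatments")
    nb = _nb_matrix(psa, wtp)
    # the difference is >= 0 by Jensen; guard the float round-off case where
    # a single treatment wins every draw
    return max(0.0, float(nb.max(axis=1).mean() - nb.mean(axis=0).max()))


def effective_population(settings: EVPISettings) -> float:
    """Discounted number of incident patients over the decision horizon."""
    t = np.arange(settings.horizon_years, dtype=float)
    offset = 1.0 if settings.discount_first_year else 0.0
    return float(settings.incidence *
                 np.sum((1.0 + settings.discount_rate) ** (-(t + offset))))


def population_evpi(evpi_pp: float, settings: EVPISettings) -> float:
    """Population EVPI = per-person EVPI x discounted incident population."""
    if evpi_pp < 0:
        raise ValueError("per-person EVPI must be >= 0")
    settings.validate()
    return evpi_pp * effective_population(settings)


@dataclass
class CEAResults:
    """Bundle of decision metrics for one PSA."""

    psa: PSAResult
    incrementals: list[IncrementalResult]
    ceac: pd.DataFrame
    evpi_pp: dict[float, float]
    evpi_population: dict[float, float]
    mean_table: pd.DataFrame = field(default=None)

    def summary(self) -> pd.DataFrame:
        return self.mean_table


def analyse(psa: PSAResult, wtp_grid, evpi_settings: EVPISettings,
            icer_pairs: list[tuple[str, str]] | None = None,
            nb_wtps=(20_000.0, 30_000.0)) -> CEAResults:
    """Run the full decision analysis on a PSA result."""
    trs = psa.treatments
    if icer_pairs is None:
        icer_pairs = [(trs[i], trs[i + 1]) for i in range(len(trs) - 1)]
    incr = [incremental_icer(psa, ref, comp) for ref, comp in icer_pairs]
    curves = ceac(psa, wtp_grid) if len(wtp_grid) else pd.DataFrame(columns=trs)
    evpi_pp = {w: evpi_per_person(psa, w) for w in nb_wtps}
    evpi_pop = {w: population_evpi(v, evpi_settings) for w, v in evpi_pp.items()}
    rows = {}
    for tr in trs:
        c, q = psa.costs[tr], psa.qalys[tr]
        row = {"mean_cost": c.mean(), "mean_qaly": q.mean()}
        for w in nb_wtps:
            nb = net_benefit(c, q, w)
            row[f"nb@{int(w)}"] = nb.mean()
            lo, hi = np.quantile(nb, [0.025, 0.975])
            row[f"nb@{int(w)}_lo"], row[f"nb@{int(w)}_hi"] = lo, hi
            full = ceac(psa, [w]) if len(trs) >= 2 else None
            row[f"p_ce@{int(w)}"] = float(full[tr].iloc[0]) if full is not None else 1.0
        rows[tr] = row
    mean_table = pd.DataFrame(rows).T
    return CEAResults(psa, incr, curves, evpi_pp, evpi_pop, mean_table)


def plot_ceac(curves: pd.DataFrame, ax=None):
    """Simple CEAC plot (probability cost-effective vs willingness-to-pay)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for tr in curves.columns:
        ax.plot(curves.index, curves[tr], label=tr)
    ax.set_xlabel("willingness-to-pay (GBP/QALY)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax


def plot_ce_plane(psa: PSAResult, ref: str, comp: str, ax=None):
    """Incremental cost-effectiveness plane scatter of PSA draws."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    dq = psa.qalys[comp] - psa.qalys[ref]
    dc = psa.costs[comp] - psa.costs[ref]
    ax.scatter(dq, dc, s=4, alpha=0.3)
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel(f"incremental QALYs ({comp} vs {ref})")
    ax.set_ylabel(f"incremental cost (GBP)")
    return ax
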