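"""Monthly-cycle Markov cohort models for cost-effectiveness analysis.

Two model structures:

* 2-state (Alive, Dead): alive-to-dead transitions from a Weibull fitted to
  overall survival of the baseline treatment, other treatments via hazard
  ratios.
* 3-state (StD, PD, Dead): stable-disease-to-progression transitions from a
  Weibull fitted to progression-free survival (HRs for PFS applied per
  treatment), a fixed per-cycle other-cause death probability out of StD,
  and a constant PD-to-dead probability derived from the mean-survival
  decomposition (:func:`solve_pd_death_tp`).

Time-dependent transition probabilities come from the Weibull via
``1 - S(t)/S(t-1)``; hazard ratios act on the cycle survival fraction as
``1 - (1 - tp)**hr``.  Costs and utilities accrue per cycle on end-of-cycle
occupancy, discounted annually at 3.5% from cycle 13 (configurable); the
terminal-care cost is charged once on entry to Dead.  No half-cycle
correction by default (flag available).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .config import MarkovConfig
from .data import ValidationError
from .survival import WeibullParams

log = logging.getLogger("mpes.markov")


# ---------------------------------------------------------------------------
# transition-probability primitives
# ---------------------------------------------------------------------------

def weibull_cycle_tp(params: WeibullParams, t, lam=None, gamma=None):
    """Probability of the event during cycle t given event-free at t-1.

    ``1 - S(t)/S(t-1) = 1 - exp(lam*(t-1)**gamma - lam*t**gamma)``.
    Vectorises over t and over (lam, gamma) arrays for PSA use.
    """
    lam = params.lam if lam is None else np.asarray(lam, dtype=float)
    gamma = params.gamma if gamma is None else np.asarray(gamma, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(t < 1):
        raise ValueError("cycle index t must be >= 1")
    return 1.0 - np.exp(lam * (t - 1.0) ** gamma - lam * t ** gamma)


def apply_hr(tp, hr):
    """Proportional hazards on the cycle survival fraction: 1-(1-tp)**hr."""
    tp = np.asarray(tp, dtype=float)
    hr = np.asarray(hr, dtype=float)
    if np.any(hr <= 0):
        raise ValueError("hr must be > 0")
    if np.any((tp < 0) | (tp > 1)):
        raise ValueError("tp must be in [0, 1]")
    return 1.0 - (1.0 - tp) ** hr


def solve_pd_death_tp(os_mean: float, pfs_mean: float, p_pc_death: float = 1.0,
                      cycle_months: float = 1.0, m_other: float | None = None) -> float:
    """Constant monthly PD-to-dead probability from mean-survival balance.

    Solves ``os_mean = p_pc_death*(pfs_mean + d_PD) + (1-p_pc_death)*m_other``
    for the mean progressive-disease duration ``d_PD`` and converts it to a
    per-cycle probability ``1 - exp(-cycle_months/d_PD)`` (exponential
    residence in PD).  ``m_other`` is the mean survival time of patients
    dying of other causes; it is required whenever ``p_pc_death < 1``.
    """
    if not (0 <= p_pc_death <= 1):
        raise ValueError("p_pc_death must be in [0, 1]")
    if p_pc_death == 0:
        raise ValidationError("p_pc_death = 0: PD is never entered via this route; "
                              "the decomposition does not define a PD duration")
    if p_pc_death < 1:
        if m_other is None:
            raise ValidationError("m_other is required when p_pc_death < 1")
        d_pd = (os_mean - (1 - p_pc_death) * m_other) / p_pc_death - pfs_mean
    else:
        d_pd = os_mean - pfs_mean
    if d_pd <= 0:
        raise ValidationError(
            f"mean-survival decomposition infeasible: implied PD duration {d_pd:.4g} "
            "months <= 0 (os_mean too small relative to pfs_mean/m_other)")
    return 1.0 - math.exp(-cycle_months / d_pd)


def discount_factor(t, annual_rate: float = 0.035, start_cycle: int = 13,
                    cycles_per_year: int = 12):
    """Annual-step discount factor for cycle t (1-based).

    1 for t < start_cycle, otherwise (1+rate)**(-floor((t-1)/12)): the whole
    first year is undiscounted and the factor steps down once a year.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 1):
        raise ValueError("cycle index t must be >= 1")
    years = np.floor((t - 1) / cycles_per_year)
    f = (1.0 + annual_rate) ** (-years)
    return np.where(t < start_cycle, 1.0, f)


def u_std_weighted(tp_stay, tp_pd, tp_dead_other, u: "UtilityInputs",
                   u_surv=None, u_pd=None, u_other=None):
    """Stable-disease utility as the transition-probability-weighted average
    of the surviving, progressed and other-cause-death utilities."""
    tp_stay = np.asarray(tp_stay, dtype=float)
    tp_pd = np.asarray(tp_pd, dtype=float)
    tp_dead_other = np.asarray(tp_dead_other, dtype=float)
    total = tp_stay + tp_pd + tp_dead_other
    if np.any(np.abs(total - 1.0) > 1e-9):
        raise ValidationError("StD transition probabilities must sum to 1")
    us = u.surviving if u_surv is None else u_surv
    up = u.pd if u_pd is None else u_pd
    uo = u.other_causes if u_other is None else u_other
    return tp_stay * us + tp_pd * up + tp_dead_other * uo


# ---------------------------------------------------------------------------
# model inputs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UtilityInputs:
    """EQ-5D utilities (mean, SE): surviving 0.770(0.015), progressed
    0.538(0.077), death from other causes 0.564(0.067)."""

    surviving: float = 0.770
    surviving_se: float = 0.015
    pd: float = 0.538
    pd_se: float = 0.077
    other_causes: float = 0.564
    other_causes_se: float = 0.067

    def sample(self, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        """Normal draws truncated to [0, 1] for probabilistic analysis."""
        out = {}
        for name in ("surviving", "pd", "other_causes"):
            m, se = getattr(self, name), getattr(self, name + "_se")
            out[name] = np.clip(m + se * rng.standard_normal(n), 0.0, 1.0)
        return out


@dataclass(frozen=True)
class TreatmentCosts:
    """Three cost components (GBP): drug acquisition+administration (charged
    per cycle on treatment for a limited number of cycles), follow-up
    (per cycle alive; split between StD and PD in the 3-state model) and a
    one-off terminal-care cost on entry to Dead."""

    drug_per_cycle: float
    drug_cycles: int
    followup_per_cycle: float
    terminal: float
    se_fraction: float = 0.2  # SE of uncertain costs as a fraction of the mean

    def __post_init__(self) -> None:
        if min(self.drug_per_cycle, self.followup_per_cycle, self.terminal) < 0:
            raise ValidationError("costs must be >= 0")
        if self.drug_cycles < 0:
            raise ValidationError("drug_cycles must be >= 0")

    def sample(self, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        """Gamma draws moment-matched to (mean, se_fraction*mean); the drug
        acquisition cost is a tariff, held fixed."""
        out = {"drug_per_cycle": np.full(n, self.drug_per_cycle)}
        for name in ("followup_per_cycle", "terminal"):
            m = getattr(self, name)
            if m == 0 or self.se_fraction == 0:
                out[name] = np.full(n, m)
                continue
            se = self.se_fraction * m
            shape = (m / se) ** 2
            out[name] = rng.gamma(shape, m / shape, size=n)
        return out


@dataclass
class MarkovSpec:
    """Definition of the cohort model for one structure (2- or 3-state)."""

    structure: str                      # "two_state" | "three_state"
    baseline: str                       # treatment the Weibull describes
    weibull: WeibullParams              # OS Weibull (2-state) or PFS Weibull (3-state)
    treatments: list[str]
    #: per-treatment HR vs baseline applied to the Weibull transition
    #: (OS HRs for 2-state, PFS HRs for 3-state); baseline maps to 1.0
    hazard_ratios: dict[str, float]
    costs: dict[str, TreatmentCosts]
    utilities: UtilityInputs = field(default_factory=UtilityInputs)
    config: MarkovConfig = field(default_factory=MarkovConfig)
    other_cause_tp: float = 0.005       # StD -> Dead per cycle, no uncertainty
    pd_death_tp: float | None = None    # PD -> Dead per cycle (3-state)
    followup_pd_fraction: tuple[float, float] = (0.70, 0.80)
    #: 2-state alive-state utility (the end-of-life EQ-5D value)
    alive_utility: float = 0.538
    alive_utility_se: float = 0.077
    weibull_cov_log: np.ndarray | None = None  # (ln lam, ln gamma) covariance for PSA

    def __post_init__(self) -> None:
        if self.structure not in ("two_state", "three_state"):
            raise ValidationError("structure must be 'two_state' or 'three_state'")
        if self.structure == "three_state" and self.pd_death_tp is None:
            raise ValidationError("three_state spec requires pd_death_tp "
                                  "(see solve_pd_death_tp)")
        for tr in self.treatments:
            if tr not in self.hazard_ratios and tr != self.baseline:
                raise ValidationError(f"no hazard ratio for treatment {tr!r}")
            if tr not in self.costs:
                raise ValidationError(f"no costs for treatment {tr!r}")
        if not (0 <= self.other_cause_tp <= 1):
            raise ValidationError("other_cause_tp must be in [0, 1]")
        lo, hi = self.followup_pd_fraction
        if not (0 <= lo <= hi <= 1):
            raise ValidationError("followup_pd_fraction must be within [0, 1]")
        self.config.validate()

    @property
    def states(self) -> tuple[str, ...]:
        return (("Alive", "Dead") if self.structure == "two_state"
                else ("StD", "PD", "Dead"))

    def hr(self, treatment: str) -> float:
        return 1.0 if treatment == self.baseline else self.hazard_ratios[treatment]


@dataclass
class StateTrace:
    """Per-cycle occupancy (persons) and transition entry counts."""

    states: tuple[str, ...]
    occupancy: np.ndarray       # (n_cycles+1, n_states); row 0 is the start
    entries: np.ndarray         # (n_cycles, n_states, n_states)

    @property
    def dead_entries(self) -> np.ndarray:
        j = self.states.index("Dead")
        live = [i for i in range(len(self.states)) if i != j]
        return self.entries[:, live, j].sum(axis=1)


# ---------------------------------------------------------------------------
# the cohort engine
# ---------------------------------------------------------------------------

class MarkovModel:
    """Cohort model over a :class:`MarkovSpec`; ``run`` produces a trace,
    ``expected_cost_qaly`` turns a trace into discounted per-patient means,
    and ``psa`` propagates parameter uncertainty."""

    def __init__(self, spec: MarkovSpec):
        self.spec = spec

    # -- matrices ----------------------------------------------------------

    def transition_probs(self, treatment: str, t, hr=None, lam=None, gamma=None):
        """Per-cycle probability of leaving the first living state via the
        Weibull route, with the treatment hazard ratio applied."""
        hr = self.spec.hr(treatment) if hr is None else hr
        base = weibull_cycle_tp(self.spec.weibull, t, lam=lam, gamma=gamma)
        return apply_hr(base, hr)

    def build_matrix(self, treatment: str, t: int, hr=None) -> np.ndarray:
        """Transition matrix for cycle t; rows sum to 1 by construction and
        infeasible inputs (row sum > 1) raise rather than being clipped."""
        s = self.spec
        tp = float(self.transition_probs(treatment, t, hr=hr))
        if s.structure == "two_state":
            return np.array([[1.0 - tp, tp], [0.0, 1.0]])
        oc = s.other_cause_tp
        if tp + oc > 1.0:
            raise ValidationError(
                f"cycle {t}: StD row infeasible (tp_progress {tp:.4f} + other-cause "
                f"{oc:.4f} > 1)")
        pd_tp = s.pd_death_tp
        return np.array([
            [1.0 - tp - oc, tp, oc],
            [0.0, 1.0 - pd_tp, pd_tp],
            [0.0, 0.0, 1.0],
        ])

    def run(self, treatment: str, hr=None) -> StateTrace:
        s = self.spec
        n_states = len(s.states)
        n = s.config.n_cycles
        occ = np.zeros((n + 1, n_states))
        occ[0, 0] = s.config.cohort
        entries = np.zeros((n, n_states, n_states))
        for t in range(1, n + 1):
            P = self.build_matrix(treatment, t, hr=hr)
            entries[t - 1] = occ[t - 1][:, None] * P
            occ[t] = entries[t - 1].sum(axis=0)
        return StateTrace(s.states, occ, entries)

    # -- valuation ---------------------------------------------------------

    def expected_cost_qaly(self, trace: StateTrace, treatment: str,
                           utilities: dict | None = None,
                           costs: dict | None = None,
                           pd_fraction: float | None = None,
                           hr=None) -> tuple[float, float]:
        """Discounted per-patient mean (cost, QALY) from a cohort trace.

        ``utilities``/``costs`` may carry PSA draws; defaults are the spec
        means.  QALYs weight end-of-cycle occupancy by state utilities
        (StD via the transition-probability-weighted average) times the
        cycle length in years.
        """
        s = self.spec
        cfg = s.config
        tc = s.costs[treatment]
        u = utilities or {}
        c = costs or {}
        drug = c.get("drug_per_cycle", tc.drug_per_cycle)
        followup = c.get("followup_per_cycle", tc.followup_per_cycle)
        terminal = c.get("terminal", tc.terminal)
        f_pd = (pd_fraction if pd_fraction is not None
                else 0.5 * (s.followup_pd_fraction[0] + s.followup_pd_fraction[1]))

        t = np.arange(1, cfg.n_cycles + 1)
        disc = discount_factor(t, cfg.discount_rate, cfg.discount_start_cycle)
        year_frac = cfg.cycle_months / 12.0
        occ = trace.occupancy[1:]  # end-of-cycle occupancy
        if cfg.half_cycle_correction:
            occ = 0.5 * (trace.occupancy[:-1] + trace.occupancy[1:])
        dead_in = trace.dead_entries
        on_drug = (t <= tc.drug_cycles).astype(float)

        if s.structure == "two_state":
            alive = occ[:, 0]
            u_alive = u.get("pd", s.alive_utility)  # end-of-life EQ-5D value
            qaly = np.sum(alive * u_alive * year_frac * disc)
            cost = np.sum((alive * (drug * on_drug + followup) + dead_in * terminal) * disc)
        else:
            std, pd_occ = occ[:, 0], occ[:, 1]
            tp_pd = self.transition_probs(treatment, t, hr=hr)
            tp_oc = s.other_cause_tp
            u_std = u_std_weighted(1.0 - tp_pd - tp_oc, tp_pd, tp_oc,
                                   s.utilities,
                                   u_surv=u.get("surviving"),
                                   u_pd=u.get("pd"),
                                   u_other=u.get("other_causes"))
            u_pd = u.get("pd", s.utilities.pd)
            qaly = np.sum((std * u_std + pd_occ * u_pd) * year_frac * disc)
            cost = np.sum((std * (drug * on_drug + followup * (1 - f_pd))
                           + pd_occ * followup * f_pd
                           + dead_in * terminal) * disc)
        cohort = cfg.cohort
        return float(cost / cohort), float(qaly / cohort)

    # -- probabilistic sensitivity analysis --------------------------------

    def psa(self, hr_draws: dict[str, np.ndarray] | None = None,
            n_draws: int | None = None, seed: int = 0) -> "PSAResult":
        """Vectorised PSA over parameter draws.

        ``hr_draws`` supplies per-treatment posterior log-HR-scale hazard
        ratio draws from the evidence synthesis (resampled with replacement
        to ``n_draws``); utilities, costs, the Weibull parameters and the
        follow-up split are drawn from their sampling distributions.
        """
        from .cea import PSAResult  # local import to avoid a cycle

        s = self.spec
        cfg = s.config
        n = n_draws or cfg.psa_draws
        rng = np.random.default_rng(seed)
        u_draws = s.utilities.sample(n, rng)
        alive_u = np.clip(s.alive_utility + s.alive_utility_se * rng.standard_normal(n),
                          0.0, 1.0)
        f_pd = rng.uniform(*s.followup_pd_fraction, size=n)
        if s.weibull_cov_log is not None:
            mean = np.array([math.log(s.weibull.lam), math.log(s.weibull.gamma)])
            wdraws = np.exp(rng.multivariate_normal(mean, s.weibull_cov_log, size=n))
            lam_d, gam_d = wdraws[:, 0], wdraws[:, 1]
        else:
            lam_d = np.full(n, s.weibull.lam)
            gam_d = np.full(n, s.weibull.gamma)

        t = np.arange(1, cfg.n_cycles + 1)
        disc = discount_factor(t, cfg.discount_rate, cfg.discount_start_cycle)
        year_frac = cfg.cycle_months / 12.0
        base_tp = weibull_cycle_tp(s.weibull, t[None, :], lam=lam_d[:, None],
                                   gamma=gam_d[:, None])  # (n, cycles)

        costs_out, qalys_out = {}, {}
        for tr in s.treatments:
            if tr == s.baseline:
                hr = np.ones(n)
            elif hr_draws is not None and tr in hr_draws:
                pool = np.asarray(hr_draws[tr], dtype=float)
                hr = pool[rng.integers(0, len(pool), size=n)]
            else:
                hr = np.full(n, s.hr(tr))
            tp = apply_hr(base_tp, hr[:, None])
            c_draws = s.costs[tr].sample(n, rng)
            drug = c_draws["drug_per_cycle"][:, None] * (t[None, :] <= s.costs[tr].drug_cycles)
            followup = c_draws["followup_per_cycle"][:, None]
            terminal = c_draws["terminal"]

            if s.structure == "two_state":
                # survival S(t) under tp sequence, vectorised over draws
                surv = np.cumprod(1.0 - tp, axis=1)
                prev = np.concatenate([np.ones((n, 1)), surv[:, :-1]], axis=1)
                dead_in = prev - surv
                occ = 0.5 * (prev + surv) if cfg.half_cycle_correction else surv
                qaly = np.sum(occ * alive_u[:, None] * year_frac * disc[None, :], axis=1)
                cost = np.sum((occ * (drug + followup)
                               + dead_in * terminal[:, None]) * disc[None, :], axis=1)
            else:
                oc = s.other_cause_tp
                # stochastic draws from heavy-tailed HR posteriors can hit the
                # feasibility boundary; cap at "progresses with certainty"
                # (tp = 1 - oc) and report the affected fraction loudly
                over = tp + oc > 1.0
                if np.any(over):
                    frac = over.any(axis=1).mean()
                    log.warning("psa(%s): %.2f%% of draws hit the StD-row "
                                "feasibility bound; cycle tp capped at %g",
                                tr, 100 * frac, 1.0 - oc)
                    tp = np.minimum(tp, 1.0 - oc)
                pd_tp = s.pd_death_tp
                std = np.ones(n)
                pd_occ = np.zeros(n)
                qaly = np.zeros(n)
                cost = np.zeros(n)
                u_pd = u_draws["pd"]
                for k in range(cfg.n_cycles):
                    tpk = tp[:, k]
                    std_new = std * (1.0 - tpk - oc)
                    pd_new = pd_occ * (1.0 - pd_tp) + std * tpk
                    dead_in = std * oc + pd_occ * pd_tp
                    if cfg.half_cycle_correction:
                        std_eff = 0.5 * (std + std_new)
                        pd_eff = 0.5 * (pd_occ + pd_new)
                    else:
                        std_eff, pd_eff = std_new, pd_new
                    u_std = ((1.0 - tpk - oc) * u_draws["surviving"]
                             + tpk * u_pd + oc * u_draws["other_causes"])
                    qaly += (std_eff * u_std + pd_eff * u_pd) * year_frac * disc[k]
                    cost += (std_eff * (drug[:, k] + followup[:, 0] * (1 - f_pd))
                             + pd_eff * followup[:, 0] * f_pd
                             + dead_in * terminal) * disc[k]
                    std, pd_occ = std_new, pd_new
            costs_out[tr] = cost
            qalys_out[tr] = qaly
        return PSAResult(costs=costs_out, qalys=qalys_out, n_draws=n, seed=seed)


def run_cohort(spec: MarkovSpec, treatment: str) -> StateTrace:
    return MarkovModel(spec).run(treatment)


def expected_cost_qaly(trace: StateTrace, spec: MarkovSpec, treatment: str,
                       **kwargs) -> tuple[float, float]:
    return MarkovModel(spec).expected_cost_qaly(trace, treatment, **kwargs)


def microsimulate(spec: MarkovSpec, treatment: str, n_persons: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Individual-level validation simulator: per-cycle state counts
    (n_cycles+1, n_states) for ``n_persons`` sampled trajectories.

    Exists to cross-validate the deterministic cohort trace; the package's
    analyses never use it.
    """
    model = MarkovModel(spec)
    n_states = len(spec.states)
    n = spec.config.n_cycles
    state = np.zeros(n_persons, dtype=int)
    counts = np.zeros((n + 1, n_states))
    counts[0, 0] = n_persons
    for t in range(1, n + 1):
        P = model.build_matrix(treatment, t)
        cum = np.cumsum(P, axis=1)
        u = rng.uniform(size=n_persons)
        state = (u[:, None] > cum[state][:, :-1]).sum(axis=1)
        counts[t] = np.bincount(state, minlength=n_states)
    return counts
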