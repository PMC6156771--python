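"""End-to-end orchestration: evidence synthesis -> Markov PSA -> decision metrics.

``run_full_analysis`` executes the full chain on a study table:

1. pairwise meta-analysis (fixed and random effects) of the modal treatment
   contrast, for OS and PFS;
2. bivariate meta-analysis of all studies jointly, predicting every
   unreported study-level effect;
3. network meta-analysis (fixed and random) per outcome, with predicted
   effects substituting missing ones;
4. probabilistic 2-state and 3-state Markov cohort models fed by posterior
   hazard-ratio draws (parameter uncertainty propagates as draws, not
   summaries);
5. incremental analysis, net benefit, CEACs and population EVPI.

Every stage is seeded from the single configured seed, so a rerun with the
same inputs is bit-identical.
"""

from __future__ import annotations

import logging
import zlib
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cea as cea_mod
from .config import AnalysisConfig
from .data import StudyRecord, TreatmentSet, ValidationError
from .fixture import hta_fixture
from .markov import MarkovModel, MarkovSpec, solve_pd_death_tp
from .meta import (BRMAPriors, BRMAResults, BivariateMetaAnalysis, MetaAnalysis,
                   NetworkMetaAnalysis)
from .survival import WeibullFit, WeibullParams, fit_weibull_mle, weibull_mean

log = logging.getLogger("mpes.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class ResultBundle:
    """All intermediate posteriors and final decision tables of one run."""

    config: AnalysisConfig
    ma: dict = field(default_factory=dict)            # (outcome, variant) -> results
    brma: BRMAResults | None = None
    nma: dict = field(default_factory=dict)           # (outcome, variant) -> results
    psa: dict = field(default_factory=dict)           # structure -> PSAResult
    cea: dict = field(default_factory=dict)           # structure -> CEAResults
    hr_table: pd.DataFrame | None = None
    predicted: dict = field(default_factory=dict)     # (study, outcome) -> summary dict


def _modal_pair(studies: list[StudyRecord]) -> tuple[str, str]:
    pairs = Counter((s.reference_treatment, s.comparator_treatment) for s in studies)
    return pairs.most_common(1)[0][0]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                log.info("stage %s: start", name)
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage name attached
                raise PipelineError(name, exc) from exc
        return wrapped
    return deco


@_stage("meta_analysis")
def _run_ma(studies, pair, priors, mcmc_for):
    out = {}
    for outcome in ("os", "pfs"):
        ests = [(getattr(s, f"y_{outcome}"), getattr(s, f"se_{outcome}"))
                for s in studies
                if (s.reference_treatment, s.comparator_treatment) == pair
                and getattr(s, f"y_{outcome}") is not None]
        if not ests:
            continue
        model = MetaAnalysis(*zip(*ests))
        out[(outcome, "fixed")] = model.fit("common", priors=priors,
                                            mcmc=mcmc_for(f"ma_{outcome}_fixed"))
        if len(ests) >= 2:
            out[(outcome, "random")] = model.fit("random", priors=priors,
                                                 mcmc=mcmc_for(f"ma_{outcome}_random"))
    return out


@_stage("brma")
def _run_brma(studies, priors, mcmc):
    n_missing = sum((not s.has_os) + (not s.has_pfs) for s in studies)
    if n_missing == 0:
        log.info("brma: no missing outcomes — nothing to predict")
    return BivariateMetaAnalysis(studies, priors=priors).fit(mcmc=mcmc)


@_stage("nma")
def _run_nma(studies, treatments, brma_res, priors, mcmc_for):
    out = {}
    for outcome in ("os", "pfs"):
        subs = []
        for s in studies:
            if getattr(s, f"y_{outcome}") is None and brma_res is not None:
                key = (s.study_id, outcome)
                if key in brma_res.predictions:
                    p = brma_res.predictions[key]
                    subs.append((s.reference_treatment, s.comparator_treatment,
                                 p["loghr_mean"], p["loghr_sd"]))
        try:
            model = NetworkMetaAnalysis.from_studies(studies, outcome, treatments,
                                                     substitutions=subs, priors=priors)
        except ValidationError as exc:
            log.warning("nma(%s): skipped (%s)", outcome, exc)
            continue
        for variant in ("fixed", "random"):
            out[(outcome, variant)] = model.fit(
                variant, mcmc=mcmc_for(f"nma_{outcome}_{variant}"))
    return out


@_stage("markov_psa")
def _run_psa(structure, mk, config, hr_draws, seed):
    weib = mk["os_weibull"] if structure == "two_state" else mk["pfs_weibull"]
    pd_tp = None
    if structure == "three_state":
        pd_tp = solve_pd_death_tp(weibull_mean(mk["os_weibull"]),
                                  weibull_mean(mk["pfs_weibull"]),
                                  p_pc_death=mk["p_cancer_death"],
                                  cycle_months=config.markov.cycle_months)
    treatments: TreatmentSet = mk["treatments"]
    spec = MarkovSpec(
        structure=structure,
        baseline="M+P" if "M+P" in treatments.codes else treatments.baseline,
        weibull=weib,
        treatments=list(treatments.codes),
        hazard_ratios={tr: 1.0 for tr in treatments.codes},
        costs=mk["costs"],
        utilities=mk["utilities"],
        config=config.markov,
        other_cause_tp=mk["other_cause_tp"],
        pd_death_tp=pd_tp,
        followup_pd_fraction=mk["followup_pd_fraction"],
        alive_utility=mk["alive_utility"],
        alive_utility_se=mk["alive_utility_se"],
        weibull_cov_log=mk.get("weibull_cov_log"),
    )
    return MarkovModel(spec).psa(hr_draws=hr_draws, seed=seed)


def _hr_draw_map(structure, studies, ma, brma_res, baseline, rng):
    """Posterior hazard-ratio draws vs the Markov baseline, per treatment."""
    outcome = "os" if structure == "two_state" else "pfs"
    draws = {}
    # contrast of the modal-pair comparator vs baseline: pooled MA draws
    key = (outcome, "fixed")
    if key in ma:
        # pooled effect is comparator (M+P) vs reference (P): invert for P vs M+P
        draws["P"] = np.exp(-ma[key].pooled)
    # docetaxel contrast vs M+P: direct estimate (OS) or BRMA prediction (PFS)
    dp = next((s for s in studies if s.comparator_treatment == "D+P"), None)
    if dp is not None:
        if outcome == "os" and dp.y_os is not None:
            n = len(next(iter(draws.values()))) if draws else 15_000
            draws["D+P"] = np.exp(dp.y_os + dp.se_os * rng.standard_normal(n))
        elif outcome == "pfs":
            if dp.y_pfs is not None:
                n = len(next(iter(draws.values()))) if draws else 15_000
                draws["D+P"] = np.exp(dp.y_pfs + dp.se_pfs * rng.standard_normal(n))
            elif brma_res is not None and (dp.study_id, "pfs") in brma_res.predictions:
                draws["D+P"] = np.exp(brma_res.predictions[(dp.study_id, "pfs")]["y_draws"])
    return draws


def _hr_summary_table(ma, brma_res, nma, predicted_keys) -> pd.DataFrame:
    rows = []

    def add(label, outcome, draws):
        lo, med, hi = np.quantile(draws, [0.025, 0.5, 0.975])
        rows.append({"analysis": label, "outcome": outcome,
                     "hr": float(np.exp(med)), "lo": float(np.exp(lo)),
                     "hi": float(np.exp(hi))})

    for outcome in ("os", "pfs"):
        if (outcome, "fixed") in ma:
            add("MA fixed", outcome, ma[(outcome, "fixed")].pooled)
        if (outcome, "random") in ma:
            add("MA random", outcome, ma[(outcome, "random")].pooled)
    if brma_res is not None:
        for key in predicted_keys:
            p = brma_res.predictions[key]
            add(f"predicted ({key[0]})", key[1], p["y_draws"])
    for outcome in ("os", "pfs"):
        for variant in ("fixed", "random"):
            if (outcome, variant) in nma:
                res = nma[(outcome, variant)]
                top = [c for c in res.treatments.codes if c == "D+P"]
                a = top[0] if top else res.treatments.codes[-1]
                add(f"NMA {variant}", outcome,
                    res.contrast(a, res.treatments.baseline))
    return pd.DataFrame(rows, columns=["analysis", "outcome", "hr", "lo", "hi"])


def run_full_analysis(studies: list[StudyRecord], ipd=None,
                      config: AnalysisConfig | None = None,
                      markov_inputs: dict | None = None) -> ResultBundle:
    """Execute the full evidence-synthesis and cost-effectiveness pipeline."""
    if not studies:
        raise ValidationError("no studies supplied")
    config = (config or AnalysisConfig()).validate()
    if markov_inputs is None:
        _, markov_inputs = hta_fixture()
    treatments: TreatmentSet = markov_inputs["treatments"]
    treatments.validate_records(studies)
    priors = BRMAPriors.from_config(config.priors)
    base_seed = config.mcmc.seed

    def mcmc_for(stage: str):
        from .config import MCMCConfig
        offset = zlib.crc32(stage.encode()) % 1000
        return MCMCConfig(iterations=config.mcmc.iterations, burnin=config.mcmc.burnin,
                          chains=config.mcmc.chains, seed=base_seed + offset)

    if ipd is not None:
        # refit the transition Weibulls from supplied IPD (baseline arm)
        for outcome, key in (("os", "os_weibull"), ("pfs", "pfs_weibull")):
            tbl = ipd.get(outcome) if isinstance(ipd, dict) else None
            if tbl is not None:
                fit: WeibullFit = fit_weibull_mle(tbl, "M+P")
                markov_inputs[key] = fit.params
                markov_inputs["weibull_cov_log"] = fit.cov_log
                log.info("refit %s from IPD: %s", key, fit.params)

    pair = _modal_pair(studies)
    ma = _run_ma(studies, pair, priors, mcmc_for)
    brma_res = _run_brma(studies, priors, mcmc_for("brma"))
    nma = _run_nma(studies, treatments, brma_res, priors, mcmc_for)

    bundle = ResultBundle(config=config, ma=ma, brma=brma_res, nma=nma)
    bundle.predicted = {k: {kk: vv for kk, vv in v.items() if kk != "y_draws" and kk != "se_draws"}
                        for k, v in brma_res.predictions.items()}

    rng = np.random.default_rng(base_seed + 101)
    for structure in ("two_state", "three_state"):
        hr_draws = _hr_draw_map(structure, studies, ma, brma_res,
                                treatments.baseline, rng)
        psa = _run_psa(structure, markov_inputs, config,
                       hr_draws, seed=base_seed + (11 if structure == "two_state" else 13))
        bundle.psa[structure] = psa
        pairs = []
        if "M+P" in psa.treatments and "D+P" in psa.treatments:
            pairs.append(("M+P", "D+P"))
        try:
            bundle.cea[structure] = cea_mod.analyse(
                psa, config.wtp_grid, config.evpi, icer_pairs=pairs or None)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"cea_{structure}", exc) from exc

    bundle.hr_table = _hr_summary_table(ma, brma_res, nma,
                                        list(brma_res.predictions))
    return bundle


def write_results_tables(bundle: ResultBundle, outdir) -> list[Path]:
    """Write machine-readable result tables; returns the written paths."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {outdir} is not writable: {exc}") from exc
    written = []

    def emit(df: pd.DataFrame, name: str, index=False):
        p = outdir / name
        df.to_csv(p, index=index, float_format="%.6g")
        written.append(p)

    if bundle.hr_table is not None:
        emit(bundle.hr_table, "hazard_ratios.csv")
    for structure, cea_res in bundle.cea.items():
        emit(cea_res.mean_table.rename_axis("treatment"),
             f"cea_summary_{structure}.csv", index=True)
        inc = pd.DataFrame([{
            "comparison": f"{r.comparator} vs {r.reference}",
            "delta_cost": r.delta_cost, "delta_cost_se": r.delta_cost_se,
            "delta_qaly": r.delta_qaly, "delta_qaly_se": r.delta_qaly_se,
            "icer": r.icer, "label": r.label,
        } for r in cea_res.incrementals])
        emit(inc, f"incremental_{structure}.csv")
        emit(cea_res.ceac.reset_index(), f"ceac_{structure}.csv")
        evpi = pd.DataFrame([
            {"wtp": w, "evpi_per_person": cea_res.evpi_pp[w],
             "evpi_population": cea_res.evpi_population[w]}
            for w in cea_res.evpi_pp
        ])
        emit(evpi, f"evpi_{structure}.csv")
    return written
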