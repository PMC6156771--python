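"""Bayesian evidence synthesis on log hazard ratios.

Three model families, all sampled with the shared ensemble-MCMC engine:

* :class:`MetaAnalysis` — common-effect and random-effects univariate
  pooling of (y, se) estimates with vague normal / half-normal priors.

* :class:`BivariateMetaAnalysis` — bivariate random-effects meta-analysis
  (BRMA) of correlated OS/PFS log hazard ratios in the product-normal
  formulation, whose purpose here is the *prediction* of study-level effects
  that a trial did not report.  Within-study correlations get Uniform(-1,1)
  priors (they are weakly identified; they can be fixed from external
  knowledge).  The SE of a missing estimate is predicted under an
  exchangeable model for the observed within-study log-variances.

* :class:`NetworkMetaAnalysis` — contrast-based fixed/random-effects NMA
  with basic parameters relative to a declared baseline treatment,
  combining direct and indirect evidence through common comparators.

The between-study model is the bivariate normal::

    mu_i ~ N2((eta_os, lambda0), T),  T = [[tau_os^2, rho_b tau_os tau_pfs],
                                           [.,         tau_pfs^2         ]]

equivalently (product-normal factorisation) mu_os,i ~ N(eta_os, tau_os^2)
and mu_pfs,i | mu_os,i ~ N(lambda0 + lambda1 (mu_os,i - eta_os), psi_pfs^2)
with slope lambda1 = rho_b tau_pfs / tau_os and conditional variance
psi_pfs^2 = tau_pfs^2 (1 - rho_b^2).  Pooled hazard ratios are
HR_OS = exp(eta_os) and HR_PFS = exp(lambda0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ._mcmc import PosteriorDraws, run_sampler
from .config import MCMCConfig, PriorConfig
from .data import StudyRecord, TreatmentSet, ValidationError, Z975

log = logging.getLogger("mpes.meta")

LOG2PI = math.log(2.0 * math.pi)


@dataclass
class BRMAPriors:
    """Prior hyperparameters, written as variances (not BUGS precisions)."""

    effect_variance: float = 1e3     # Normal(0, .) on eta_os, lambda0, basic NMA params
    sd_scale_variance: float = 1e3   # HalfNormal(0, .) on tau_os, tau_pfs, NMA sigma
    logvar_sd_scale: float = 1.0     # HalfNormal scale of the exchangeable log-variance SD

    @classmethod
    def from_config(cls, cfg: PriorConfig) -> "BRMAPriors":
        return cls(effect_variance=cfg.effect_variance,
                   sd_scale_variance=cfg.sd_scale_variance,
                   logvar_sd_scale=cfg.logvar_sd_scale)


def _summary_table(rows: dict[str, np.ndarray]) -> pd.DataFrame:
    out = {}
    for name, draws in rows.items():
        q = np.quantile(draws, [0.025, 0.5, 0.975])
        out[name] = {"mean": draws.mean(), "sd": draws.std(ddof=1),
                     "q2.5": q[0], "median": q[1], "q97.5": q[2]}
    return pd.DataFrame(out).T


# ---------------------------------------------------------------------------
# univariate meta-analysis
# ---------------------------------------------------------------------------

class MetaAnalysisResults:
    """Posterior of a pooled log hazard ratio (and heterogeneity SD)."""

    def __init__(self, model: str, draws: PosteriorDraws, predictive: np.ndarray | None):
        self.model = model
        self._draws = draws
        self.diagnostics = draws.diagnostics
        self.pooled = draws["pooled"]
        self.tau = draws["tau"] if "tau" in draws.names else None
        #: draws of the effect in a new exchangeable study (random model)
        self.predictive = predictive

    @property
    def hr(self) -> float:
        return float(np.exp(self.pooled).mean())

    def hr_ci(self) -> tuple[float, float]:
        lo, hi = np.quantile(self.pooled, [0.025, 0.975])
        return float(np.exp(lo)), float(np.exp(hi))

    def summary(self) -> pd.DataFrame:
        rows = {"pooled_loghr": self.pooled, "pooled_hr": np.exp(self.pooled)}
        if self.tau is not None:
            rows["tau"] = self.tau
        if self.predictive is not None:
            rows["predictive_loghr"] = self.predictive
        return _summary_table(rows)


class MetaAnalysis:
    """Pairwise meta-analysis of independent (y, se) estimates."""

    def __init__(self, y, se):
        self.y = np.asarray(y, dtype=float)
        self.se = np.asarray(se, dtype=float)
        if self.y.size == 0:
            raise ValidationError("meta-analysis needs at least 1 estimate")
        if np.any(self.se <= 0) or not np.all(np.isfinite(self.se)):
            raise ValidationError("all standard errors must be finite and > 0")

    def fit(self, method: str = "common", priors: BRMAPriors | None = None,
            mcmc: MCMCConfig | None = None) -> MetaAnalysisResults:
        priors = priors or BRMAPriors()
        mcmc = mcmc or MCMCConfig()
        y, v = self.y, self.se ** 2
        v0 = priors.effect_variance
        iv_mean = float(np.sum(y / v) / np.sum(1 / v))
        iv_se = float(np.sum(1 / v) ** -0.5)

        if method == "common":
            def log_prob(theta):
                m = theta[:, 0]
                ll = -0.5 * np.sum((y[None, :] - m[:, None]) ** 2 / v[None, :], axis=1)
                return ll - 0.5 * m ** 2 / v0

            draws = run_sampler(log_prob, 1, ["pooled"], mcmc,
                                np.array([iv_mean]), np.array([max(iv_se, 1e-3)]))
            return MetaAnalysisResults("common", draws, None)

        if method != "random":
            raise ValueError("method must be 'common' or 'random'")
        if len(y) < 2:
            raise ValidationError("random-effects meta-analysis needs >= 2 estimates")
        sv = priors.sd_scale_variance

        def log_prob(theta):
            m, tau = theta[:, 0], theta[:, 1]
            bad = tau < 0
            tot = v[None, :] + tau[:, None] ** 2
            ll = -0.5 * np.sum((y[None, :] - m[:, None]) ** 2 / tot + np.log(tot), axis=1)
            lp = ll - 0.5 * m ** 2 / v0 - 0.5 * tau ** 2 / sv
            lp[bad] = -np.inf
            return lp

        spread = max(float(np.std(y, ddof=1)), 1e-3)
        draws = run_sampler(log_prob, 2, ["pooled", "tau"], mcmc,
                            np.array([iv_mean, spread]),
                            np.array([max(iv_se, 1e-3), spread / 2]))
        rng = np.random.default_rng(mcmc.seed + 1)
        predictive = draws["pooled"] + draws["tau"] * rng.standard_normal(draws.n_draws)
        return MetaAnalysisResults("random", draws, predictive)


def fit_ma_common(estimates, mcmc: MCMCConfig | None = None) -> MetaAnalysisResults:
    y, se = zip(*estimates)
    return MetaAnalysis(y, se).fit("common", mcmc=mcmc)


def fit_ma_random(estimates, priors: BRMAPriors | None = None,
                  mcmc: MCMCConfig | None = None) -> MetaAnalysisResults:
    y, se = zip(*estimates)
    return MetaAnalysis(y, se).fit("random", priors=priors, mcmc=mcmc)


# ---------------------------------------------------------------------------
# bivariate random-effects meta-analysis
# ---------------------------------------------------------------------------

class BRMAResults:
    """Joint posterior of the BRMA, including predicted missing effects.

    ``predictions`` maps (study_id, outcome) of each originally-missing
    entry to a dict with per-draw predicted observed effects (``y_draws``),
    the predicted within-study SE draws (``se_draws``, exchangeable-variance
    model) and HR-scale summaries.
    """

    def __init__(self, draws: dict[str, np.ndarray], study_ids: list[str],
                 predictions: dict, diagnostics):
        self.draws = draws
        self.study_ids = study_ids
        self.predictions = predictions
        self.diagnostics = diagnostics
        self.n_draws = len(draws["eta_os"])

    def predicted(self, study_id: str, outcome: str = "pfs") -> dict:
        key = (study_id, outcome)
        if key not in self.predictions:
            raise KeyError(f"no missing {outcome} entry was predicted for {study_id!r}")
        return self.predictions[key]

    def predicted_hr(self, study_id: str, outcome: str = "pfs") -> tuple[float, float, float]:
        """Posterior-median HR with 95% credible interval for a prediction."""
        y = self.predictions[(study_id, outcome)]["y_draws"]
        lo, med, hi = np.quantile(y, [0.025, 0.5, 0.975])
        return float(np.exp(med)), float(np.exp(lo)), float(np.exp(hi))

    def summary(self) -> pd.DataFrame:
        rows = {k: self.draws[k] for k in
                ("eta_os", "lambda0", "lambda1", "tau_os", "tau_pfs", "rho_b", "psi2_pfs")}
        rows["hr_os"] = np.exp(self.draws["eta_os"])
        rows["hr_pfs"] = np.exp(self.draws["lambda0"])
        for (sid, outcome), p in self.predictions.items():
            rows[f"pred_loghr_{outcome}[{sid}]"] = p["y_draws"]
            rows[f"pred_hr_{outcome}[{sid}]"] = np.exp(p["y_draws"])
        return _summary_table(rows)


class BivariateMetaAnalysis:
    """BRMA of study-level OS/PFS log hazard ratios with missing entries.

    Parameters
    ----------
    studies : list of StudyRecord
    priors : BRMAPriors
    fix_rho_w : float or None
        Fix all within-study correlations at this value instead of giving
        them Uniform(-1, 1) priors (useful when external knowledge exists;
        also what the synthetic-data calibration uses).
    force : bool
        Proceed even when fewer than 2 studies report both outcomes (the
        between-study correlation is then unidentified).
    """

    def __init__(self, studies: list[StudyRecord], priors: BRMAPriors | None = None,
                 fix_rho_w: float | None = None, force: bool = False):
        if len(studies) < 2:
            raise ValidationError("BRMA needs at least 2 studies")
        self.studies = list(studies)
        self.priors = priors or BRMAPriors()
        self.fix_rho_w = fix_rho_w
        for outcome, attr in (("os", "has_os"), ("pfs", "has_pfs")):
            if not any(getattr(s, attr) for s in studies):
                raise ValidationError(
                    f"all studies are missing {outcome}; nothing to identify the "
                    f"{outcome} margin with")
        n_complete = sum(1 for s in studies if s.has_os and s.has_pfs)
        if n_complete < 2:
            msg = ("fewer than 2 studies report both outcomes; "
                   "the between-study correlation is unidentified")
            if not force:
                raise ValidationError(msg + " (pass force=True to proceed)")
            log.warning("brma: %s — proceeding under force=True", msg)

    # parameter vector layout: eta_os, lambda0, tau_os, tau_pfs, rho_b,
    # [rho_w per complete study], then per outcome with missing entries the
    # exchangeable log-variance hypers (m_v, s_v)
    def _layout(self):
        names = ["eta_os", "lambda0", "tau_os", "tau_pfs", "rho_b"]
        complete = [i for i, s in enumerate(self.studies) if s.has_os and s.has_pfs]
        rho_idx = {}
        if self.fix_rho_w is None:
            for i in complete:
                rho_idx[i] = len(names)
                names.append(f"rho_w[{self.studies[i].study_id}]")
        missing = [(i, "os") for i, s in enumerate(self.studies) if not s.has_os]
        missing += [(i, "pfs") for i, s in enumerate(self.studies) if not s.has_pfs]
        hyper_idx = {}
        for outcome in ("os", "pfs"):
            if any(o == outcome for _, o in missing):
                obs_se = [getattr(s, f"se_{outcome}") for s in self.studies
                          if getattr(s, f"y_{outcome}") is not None]
                if len(obs_se) < 2:
                    raise ValidationError(
                        f"need >= 2 observed {outcome} SEs for the exchangeable-"
                        "variance prediction of a missing SE")
                hyper_idx[outcome] = len(names)
                names += [f"logvar_mean_{outcome}", f"logvar_sd_{outcome}"]
        return names, complete, rho_idx, missing, hyper_idx

    def fit(self, mcmc: MCMCConfig | None = None) -> BRMAResults:
        mcmc = mcmc or MCMCConfig()
        names, complete, rho_idx, missing, hyper_idx = self._layout()
        ndim = len(names)
        pr = self.priors
        v0, sv, ls = pr.effect_variance, pr.sd_scale_variance, pr.logvar_sd_scale
        studies = self.studies

        obs_logvar = {o: np.array([math.log(getattr(s, f"se_{o}") ** 2) for s in studies
                                   if getattr(s, f"y_{o}") is not None])
                      for o in hyper_idx}

        def log_prob(theta):
            eta, lam0 = theta[:, 0], theta[:, 1]
            t_os, t_pfs, rho_b = theta[:, 2], theta[:, 3], theta[:, 4]
            lp = -0.5 * (eta ** 2 + lam0 ** 2) / v0
            lp = lp - 0.5 * (t_os ** 2 + t_pfs ** 2) / sv
            bad = (t_os < 0) | (t_pfs < 0) | (np.abs(rho_b) >= 1)
            T11 = t_os ** 2
            T22 = t_pfs ** 2
            T12 = rho_b * t_os * t_pfs
            for i, s in enumerate(studies):
                if s.has_os and s.has_pfs:
                    if self.fix_rho_w is not None:
                        rw = self.fix_rho_w
                    else:
                        rw = theta[:, rho_idx[i]]
                        bad = bad | (np.abs(rw) >= 1)
                    c11 = T11 + s.se_os ** 2
                    c22 = T22 + s.se_pfs ** 2
                    c12 = T12 + rw * s.se_os * s.se_pfs
                    det = c11 * c22 - c12 ** 2
                    r1 = s.y_os - eta
                    r2 = s.y_pfs - lam0
                    with np.errstate(divide="ignore", invalid="ignore"):
                        q = (c22 * r1 ** 2 - 2 * c12 * r1 * r2 + c11 * r2 ** 2) / det
                        lp = lp - LOG2PI - 0.5 * np.log(det) - 0.5 * q
                elif s.has_os:
                    c11 = T11 + s.se_os ** 2
                    lp = lp - 0.5 * (np.log(c11) + (s.y_os - eta) ** 2 / c11)
                else:
                    c22 = T22 + s.se_pfs ** 2
                    lp = lp - 0.5 * (np.log(c22) + (s.y_pfs - lam0) ** 2 / c22)
            for o, j in hyper_idx.items():
                mv, svv = theta[:, j], theta[:, j + 1]
                bad = bad | (svv <= 0)
                with np.errstate(divide="ignore", invalid="ignore"):
                    lv = obs_logvar[o]
                    lp = lp - 0.5 * np.sum(
                        (lv[None, :] - mv[:, None]) ** 2 / svv[:, None] ** 2, axis=1) \
                        - lv.size * np.log(np.abs(svv)) \
                        - 0.5 * mv ** 2 / v0 - 0.5 * svv ** 2 / ls ** 2
            lp = np.where(bad, -np.inf, lp)
            return np.where(np.isfinite(lp), lp, -np.inf)

        y_os_obs = [s.y_os for s in studies if s.has_os]
        y_pfs_obs = [s.y_pfs for s in studies if s.has_pfs]
        center = np.zeros(ndim)
        scale = np.full(ndim, 0.1)
        center[0] = float(np.mean(y_os_obs))
        center[1] = float(np.mean(y_pfs_obs))
        center[2] = max(float(np.std(y_os_obs, ddof=1)) if len(y_os_obs) > 1 else 0.1, 0.05)
        center[3] = max(float(np.std(y_pfs_obs, ddof=1)) if len(y_pfs_obs) > 1 else 0.1, 0.05)
        center[4] = 0.0
        scale[4] = 0.3
        for i, j in rho_idx.items():
            scale[j] = 0.3
        for o, j in hyper_idx.items():
            center[j] = float(np.mean(obs_logvar[o]))
            center[j + 1] = 0.5
            scale[j + 1] = 0.2

        post = run_sampler(log_prob, ndim, names, mcmc, center, scale)
        return self._postprocess(post, names, rho_idx, missing, hyper_idx, mcmc)

    def _postprocess(self, post: PosteriorDraws, names, rho_idx, missing,
                     hyper_idx, mcmc: MCMCConfig) -> BRMAResults:
        studies = self.studies
        rng = np.random.default_rng(mcmc.seed + 7)
        d = {nm: post[nm] for nm in names}
        n = post.n_draws
        eta, lam0 = d["eta_os"], d["lambda0"]
        t_os, t_pfs, rho_b = d["tau_os"], d["tau_pfs"], d["rho_b"]
        safe_tos = np.maximum(t_os, 1e-12)
        draws = {
            "eta_os": eta, "lambda0": lam0, "tau_os": t_os, "tau_pfs": t_pfs,
            "rho_b": rho_b,
            "lambda1": rho_b * t_pfs / safe_tos,
            "psi2_pfs": t_pfs ** 2 * (1.0 - rho_b ** 2),
        }
        T11, T22 = t_os ** 2, t_pfs ** 2
        T12 = rho_b * t_os * t_pfs

        # per-study true effects: exact conditional Gaussian draws given theta
        for i, s in enumerate(studies):
            m1, m2 = eta, lam0
            if s.has_os and s.has_pfs:
                rw = (np.full(n, self.fix_rho_w) if self.fix_rho_w is not None
                      else d[f"rho_w[{s.study_id}]"])
                s11, s22 = s.se_os ** 2, s.se_pfs ** 2
                s12 = rw * s.se_os * s.se_pfs
                # posterior cov = (T^-1 + S^-1)^-1 via 2x2 closed forms
                detT = np.maximum(T11 * T22 - T12 ** 2, 1e-300)
                detS = np.maximum(s11 * s22 - s12 ** 2, 1e-300)
                p11 = T22 / detT + s22 / detS
                p22 = T11 / detT + s11 / detS
                p12 = -T12 / detT - s12 / detS
                detP = p11 * p22 - p12 ** 2
                c11, c22, c12 = p22 / detP, p11 / detP, -p12 / detP
                b1 = (T22 * m1 - T12 * m2) / detT + (s22 * s.y_os - s12 * s.y_pfs) / detS
                b2 = (T11 * m2 - T12 * m1) / detT + (s11 * s.y_pfs - s12 * s.y_os) / detS
                mu1 = c11 * b1 + c12 * b2
                mu2 = c12 * b1 + c22 * b2
            else:
                # single observed outcome: Kalman update of the bivariate prior
                if s.has_os:
                    S = T11 + s.se_os ** 2
                    k1, k2 = T11 / S, T12 / S
                    innov = s.y_os - m1
                    mu1, mu2 = m1 + k1 * innov, m2 + k2 * innov
                    c11 = T11 - k1 * T11
                    c12 = T12 - k1 * T12
                    c22 = T22 - k2 * T12
                else:
                    S = T22 + s.se_pfs ** 2
                    k2, k1 = T22 / S, T12 / S
                    innov = s.y_pfs - m2
                    mu1, mu2 = m1 + k1 * innov, m2 + k2 * innov
                    c22 = T22 - k2 * T22
                    c12 = T12 - k2 * T12
                    c11 = T11 - k1 * T12
            z1 = rng.standard_normal(n)
            z2 = rng.standard_normal(n)
            c11c = np.maximum(c11, 0.0)
            sd1 = np.sqrt(c11c)
            with np.errstate(divide="ignore", invalid="ignore"):
                a = np.where(sd1 > 0, c12 / np.maximum(sd1, 1e-300), 0.0)
            resid = np.sqrt(np.maximum(c22 - a ** 2, 0.0))
            draws[f"mu_os[{s.study_id}]"] = mu1 + sd1 * z1
            draws[f"mu_pfs[{s.study_id}]"] = mu2 + a * z1 + resid * z2

        # predictions for missing observed effects
        predictions = {}
        for i, o in missing:
            s = studies[i]
            j = hyper_idx[o]
            mv, svv = d[names[j]], d[names[j + 1]]
            se_pred = np.exp(0.5 * (mv + svv * rng.standard_normal(n)))
            rw = (np.full(n, self.fix_rho_w) if self.fix_rho_w is not None
                  else rng.uniform(-1.0, 1.0, size=n))
            if o == "pfs":
                y_obs, se_obs = s.y_os, s.se_os
                c11 = T11 + se_obs ** 2
                c22 = T22 + se_pred ** 2
                c12 = T12 + rw * se_obs * se_pred
                cond_mean = lam0 + c12 / c11 * (y_obs - eta)
                cond_var = np.maximum(c22 - c12 ** 2 / c11, 0.0)
            else:
                y_obs, se_obs = s.y_pfs, s.se_pfs
                c22 = T22 + se_obs ** 2
                c11 = T11 + se_pred ** 2
                c12 = T12 + rw * se_obs * se_pred
                cond_mean = eta + c12 / c22 * (y_obs - lam0)
                cond_var = np.maximum(c11 - c12 ** 2 / c22, 0.0)
            y_draws = cond_mean + np.sqrt(cond_var) * rng.standard_normal(n)
            q = np.quantile(y_draws, [0.025, 0.5, 0.975])
            predictions[(s.study_id, o)] = {
                "y_draws": y_draws,
                "se_draws": se_pred,
                "se_pred": float(se_pred.mean()),
                "loghr_mean": float(y_draws.mean()),
                "loghr_sd": float(y_draws.std(ddof=1)),
                "hr_median": float(np.exp(q[1])),
                "hr_ci": (float(np.exp(q[0])), float(np.exp(q[2]))),
            }

        return BRMAResults(draws, [s.study_id for s in studies], predictions,
                           post.diagnostics)


def fit_brma(studies: list[StudyRecord], priors: BRMAPriors | None = None,
             mcmc: MCMCConfig | None = None, **kwargs) -> BRMAResults:
    return BivariateMetaAnalysis(studies, priors=priors, **kwargs).fit(mcmc=mcmc)


# ---------------------------------------------------------------------------
# network meta-analysis
# ---------------------------------------------------------------------------

class NMAResults:
    """Posterior contrasts of a network meta-analysis.

    ``contrast(a, b)`` returns per-draw log HRs of treatment ``a`` versus
    ``b`` (antisymmetric by construction: d(A,B) = -d(B,A) in every draw).
    """

    def __init__(self, treatments: TreatmentSet, variant: str,
                 d_draws: dict[str, np.ndarray], sigma: np.ndarray | None,
                 diagnostics):
        self.treatments = treatments
        self.variant = variant
        self._d = d_draws
        self.sigma = sigma
        self.diagnostics = diagnostics

    def contrast(self, a: str, b: str) -> np.ndarray:
        return self._d[a] - self._d[b]

    def contrast_hr(self, a: str, b: str) -> tuple[float, float, float]:
        c = self.contrast(a, b)
        lo, med, hi = np.quantile(c, [0.025, 0.5, 0.975])
        return float(np.exp(med)), float(np.exp(lo)), float(np.exp(hi))

    def summary(self) -> pd.DataFrame:
        rows = {}
        codes = self.treatments.codes
        for i, a in enumerate(codes):
            for b in codes[i + 1:]:
                rows[f"loghr[{a} vs {b}]"] = self.contrast(a, b)
                rows[f"hr[{a} vs {b}]"] = np.exp(self.contrast(a, b))
        if self.sigma is not None:
            rows["sigma"] = self.sigma
        return _summary_table(rows)


class NetworkMetaAnalysis:
    """Contrast-based NMA on log hazard ratios.

    ``estimates`` are (ref, comp, y, se) tuples, y the log HR of comp vs
    ref.  The network must be connected over the declared treatment set.
    """

    def __init__(self, estimates: list[tuple[str, str, float, float]],
                 treatments: TreatmentSet, priors: BRMAPriors | None = None):
        if not estimates:
            raise ValidationError("NMA needs at least 1 estimate")
        self.estimates = list(estimates)
        self.treatments = treatments
        self.priors = priors or BRMAPriors()
        g = nx.Graph()
        g.add_nodes_from(treatments.codes)
        for ref, comp, y, se in estimates:
            if ref not in treatments.codes or comp not in treatments.codes:
                raise ValidationError(f"undeclared treatment in estimate ({ref}, {comp})")
            if se <= 0:
                raise ValidationError("all SEs must be > 0")
            g.add_edge(ref, comp)
        if not nx.is_connected(g):
            comps = [sorted(c) for c in nx.connected_components(g)]
            raise ValidationError(f"treatment network is disconnected: components {comps}")

    @classmethod
    def from_studies(cls, studies: list[StudyRecord], outcome: str,
                     treatments: TreatmentSet,
                     substitutions: list[tuple[str, str, float, float]] | None = None,
                     priors: BRMAPriors | None = None) -> "NetworkMetaAnalysis":
        """Build from study records for one outcome; missing entries may be
        replaced by externally supplied (e.g. BRMA-predicted) estimates."""
        ests = []
        for s in studies:
            y = getattr(s, f"y_{outcome}")
            se = getattr(s, f"se_{outcome}")
            if y is not None:
                ests.append((s.reference_treatment, s.comparator_treatment, y, se))
        if substitutions:
            ests.extend(substitutions)
            log.info("nma(%s): %d substituted (predicted) estimates flagged",
                     outcome, len(substitutions))
        return cls(ests, treatments, priors=priors)

    def fit(self, variant: str = "fixed", mcmc: MCMCConfig | None = None) -> NMAResults:
        if variant not in ("fixed", "random"):
            raise ValueError("variant must be 'fixed' or 'random'")
        mcmc = mcmc or MCMCConfig()
        codes = list(self.treatments.codes)
        basic = [c for c in codes if c != self.treatments.baseline]
        idx = {c: k for k, c in enumerate(basic)}
        names = [f"d[{c}]" for c in basic]
        y = np.array([e[2] for e in self.estimates])
        v = np.array([e[3] ** 2 for e in self.estimates])
        # design: delta_i = d[comp] - d[ref] with d[baseline] = 0
        X = np.zeros((len(self.estimates), len(basic)))
        for r, (ref, comp, _, _) in enumerate(self.estimates):
            if comp != self.treatments.baseline:
                X[r, idx[comp]] += 1.0
            if ref != self.treatments.baseline:
                X[r, idx[ref]] -= 1.0
        v0 = self.priors.effect_variance
        sv = self.priors.sd_scale_variance
        random = variant == "random"
        if random:
            names = names + ["sigma"]

        def log_prob(theta):
            dmat = theta[:, :len(basic)]
            delta = dmat @ X.T  # (n, n_est)
            if random:
                sig = theta[:, len(basic)]
                bad = sig < 0
                tot = v[None, :] + sig[:, None] ** 2
            else:
                bad = np.zeros(theta.shape[0], dtype=bool)
                tot = np.broadcast_to(v[None, :], delta.shape)
            ll = -0.5 * np.sum((y[None, :] - delta) ** 2 / tot + np.log(tot), axis=1)
            lp = ll - 0.5 * np.sum(dmat ** 2, axis=1) / v0
            if random:
                lp = lp - 0.5 * sig ** 2 / sv
                lp = np.where(bad, -np.inf, lp)
            return lp

        # initialise at the weighted least-squares solution
        W = np.diag(1.0 / v)
        A = X.T @ W @ X + np.eye(len(basic)) / v0
        d0 = np.linalg.solve(A, X.T @ W @ y)
        center = np.concatenate([d0, [0.1]]) if random else d0
        scale = np.full(len(names), 0.1)
        post = run_sampler(log_prob, len(names), names, mcmc, center, scale)
        d_draws = {self.treatments.baseline: np.zeros(post.n_draws)}
        for c in basic:
            d_draws[c] = post[f"d[{c}]"]
        sigma = post["sigma"] if random else None
        return NMAResults(self.treatments, variant, d_draws, sigma, post.diagnostics)


def fit_nma(studies: list[StudyRecord], outcome: str, variant: str,
            treatments: TreatmentSet, priors: BRMAPriors | None = None,
            mcmc: MCMCConfig | None = None,
            substitutions=None) -> NMAResults:
    model = NetworkMetaAnalysis.from_studies(studies, outcome, treatments,
                                             substitutions=substitutions, priors=priors)
    return model.fit(variant=variant, mcmc=mcmc)
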