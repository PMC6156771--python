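"""Survival fitting: Cox log hazard ratios and Weibull models from IPD.

The Weibull is parameterised throughout as ``S(t) = exp(-lam * t**gamma)``
with t in months (hazard ``h(t) = lam*gamma*t**(gamma-1)``).  The Markov
engine's time-dependent transition probabilities depend on this exact
convention, so it is fixed here and conversions from other shape/scale
conventions happen at the I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gamma as gamma_fn


class EstimationError(RuntimeError):
    """Raised when a likelihood cannot be maximised on the given data."""


@dataclass(frozen=True)
class WeibullParams:
    """Shape/scale of a Weibull survival model, S(t) = exp(-lam * t**gamma)."""

    gamma: float
    lam: float

    def __post_init__(self) -> None:
        if not (self.gamma > 0 and self.lam > 0):
            raise ValueError(f"Weibull parameters must be positive, got {self}")

    def survival(self, t):
        t = np.asarray(t, dtype=float)
        return np.exp(-self.lam * t ** self.gamma)


@dataclass(frozen=True)
class WeibullFit:
    """Weibull MLE with asymptotic covariance on the (ln lam, ln gamma) scale."""

    params: WeibullParams
    cov_log: np.ndarray  # 2x2, order (ln lam, ln gamma)
    loglik: float
    n: int
    n_events: int

    def sample_params(self, n_draws: int, rng: np.random.Generator) -> np.ndarray:
        """Draw (lam, gamma) pairs from the bivariate normal on log parameters.

        This is the probabilistic-sensitivity-analysis sampling mechanism for
        transition-probability uncertainty.
        """
        mean = np.array([math.log(self.params.lam), math.log(self.params.gamma)])
        draws = rng.multivariate_normal(mean, self.cov_log, size=n_draws)
        return np.exp(draws)  # columns (lam, gamma)


@dataclass(frozen=True)
class CoxEstimate:
    loghr: float
    se: float
    n_events: int

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be > 0")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")


def _cox_loglik_grad_hess(beta: float, times, events, x, ties: str):
    """Partial log-likelihood and derivatives for a single binary covariate."""
    order = np.argsort(-times, kind="stable")  # decreasing time
    t, d, xv = times[order], events[order], x[order]
    r = math.exp(beta)
    # cumulative risk-set sums walking from largest time down
    s0 = np.cumsum(np.where(xv == 1, r, 1.0))
    s1 = np.cumsum(np.where(xv == 1, r, 0.0))
    ll = g = h = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        # risk set at time t[i] is everything from 0..j (times >= t[i])
        dead = (d[i:j + 1] == 1)
        ndead = int(dead.sum())
        if ndead:
            sx = float(xv[i:j + 1][dead].sum())
            S0, S1 = s0[j], s1[j]
            if ties == "breslow":
                ll += beta * sx - ndead * math.log(S0)
                g += sx - ndead * S1 / S0
                h -= ndead * (S1 / S0) * (1.0 - S1 / S0)
            else:  # efron
                dead_s0 = sx * r + (ndead - sx)  # risk-score sum over deaths
                dead_s1 = sx * r
                for k in range(ndead):
                    f = k / ndead
                    d0 = S0 - f * dead_s0
                    d1 = S1 - f * dead_s1
                    ll += -math.log(d0)
                    g += -d1 / d0
                    h -= (d1 / d0) * (1.0 - d1 / d0)
                ll += beta * sx
                g += sx
        i = j + 1
    return ll, g, h


def fit_cox_loghr(ipd: pd.DataFrame, ref_arm: str, comp_arm: str,
                  ties: str = "breslow", max_iter: int = 50,
                  tol: float = 1e-10) -> CoxEstimate:
    """Cox partial-likelihood log HR of ``comp_arm`` versus ``ref_arm``.

    Newton-Raphson on the single arm-indicator coefficient; Breslow tie
    handling by default (Efron behind ``ties="efron"``).  SE is the inverse
    square-root of the observed information at the MLE.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    sub = ipd[ipd["arm"].isin([ref_arm, comp_arm])]
    arms = set(sub["arm"])
    if arms != {ref_arm, comp_arm}:
        raise EstimationError(f"both arms must be present, found {sorted(arms)}")
    times = np.asarray(sub["time_months"], dtype=float)
    events = np.asarray(sub["event"], dtype=int)
    x = (sub["arm"] == comp_arm).to_numpy().astype(int)
    n_events = int(events.sum())
    if n_events == 0:
        raise EstimationError("no events in the pooled data")
    beta = 0.0
    for _ in range(max_iter):
        _, g, h = _cox_loglik_grad_hess(beta, times, events, x, ties)
        if h >= 0:
            raise EstimationError("degenerate information (all events in one arm?)")
        step = -g / h
        step = max(-2.0, min(2.0, step))  # damp wild early steps
        beta += step
        if abs(step) < tol:
            break
    else:
        raise EstimationError(f"Cox Newton-Raphson did not converge (last step {step:.3g})")
    _, _, h = _cox_loglik_grad_hess(beta, times, events, x, ties)
    return CoxEstimate(loghr=beta, se=1.0 / math.sqrt(-h), n_events=n_events)


class CoxPH:
    """Model-object wrapper around :func:`fit_cox_loghr`."""

    def __init__(self, ipd: pd.DataFrame, ref_arm: str, comp_arm: str, ties: str = "breslow"):
        self.ipd = ipd
        self.ref_arm = ref_arm
        self.comp_arm = comp_arm
        self.ties = ties

    def fit(self) -> CoxEstimate:
        return fit_cox_loghr(self.ipd, self.ref_arm, self.comp_arm, ties=self.ties)


def _weibull_mle(times: np.ndarray, events: np.ndarray, max_iter: int = 200):
    """Newton iterations on (a, b) = (ln lam, ln gamma) for censored data."""
    d = events.astype(float)
    nd = d.sum()
    lt = np.log(times)
    # method-of-moments start: exponential rate, unit shape
    a = math.log(max(nd, 1.0) / times.sum())
    b = 0.0
    for _ in range(max_iter):
        lam, gam = math.exp(a), math.exp(b)
        tg = times ** gam
        tglt = tg * lt
        ga = nd - lam * tg.sum()
        gb = nd + gam * float((d * lt).sum()) - lam * gam * tglt.sum()
        haa = -lam * tg.sum()
        hab = -lam * gam * tglt.sum()
        hbb = (gam * float((d * lt).sum())
               - lam * gam * (tglt.sum() + gam * float((tg * lt * lt).sum())))
        H = np.array([[haa, hab], [hab, hbb]])
        gvec = np.array([ga, gb])
        try:
            step = np.linalg.solve(H, gvec)
        except np.linalg.LinAlgError as exc:
            raise EstimationError("singular Hessian in Weibull MLE") from exc
        step = np.clip(-step, -1.0, 1.0)
        a += step[0]
        b += step[1]
        if float(np.abs(step).max()) < 1e-12:
            break
    else:
        raise EstimationError("Weibull MLE did not converge")
    lam, gam = math.exp(a), math.exp(b)
    ll = (nd * (a + b) + (gam - 1) * float((d * lt).sum()) - lam * float((times ** gam).sum()))
    H = np.array([
        [-lam * (times ** gam).sum(),
         -lam * gam * ((times ** gam) * lt).sum()],
        [-lam * gam * ((times ** gam) * lt).sum(),
         gam * float((d * lt).sum()) - lam * gam * (((times ** gam) * lt).sum()
                                                    + gam * ((times ** gam) * lt * lt).sum())],
    ])
    cov = np.linalg.inv(-H)
    return WeibullParams(gamma=gam, lam=lam), cov, ll


def fit_weibull_mle(ipd: pd.DataFrame, arm: str) -> WeibullFit:
    """Right-censored Weibull MLE for one arm, with log-scale covariance.

    Requires at least 2 events; zero event times are a domain error (the
    log-likelihood is unbounded there).
    """
    sub = ipd[ipd["arm"] == arm]
    if len(sub) == 0:
        raise EstimationError(f"arm {arm!r} not present")
    times = np.asarray(sub["time_months"], dtype=float)
    events = np.asarray(sub["event"], dtype=int)
    n_events = int(events.sum())
    if n_events < 2:
        raise EstimationError(f"arm {arm!r}: need >= 2 events, found {n_events}")
    if np.any(times[events == 1] <= 0):
        raise ValueError("event times must be > 0 for the Weibull likelihood")
    times = np.maximum(times, 1e-12)  # zero censoring times carry no information
    params, cov, ll = _weibull_mle(times, events)
    return WeibullFit(params=params, cov_log=cov, loglik=ll, n=len(sub), n_events=n_events)


class WeibullSurvival:
    """Model-object wrapper around :func:`fit_weibull_mle`."""

    def __init__(self, ipd: pd.DataFrame, arm: str):
        self.ipd = ipd
        self.arm = arm

    def fit(self) -> WeibullFit:
        return fit_weibull_mle(self.ipd, self.arm)


def weibull_mean(params: WeibullParams) -> float:
    """Mean survival time Gamma(1 + 1/gamma) * lam**(-1/gamma), in months."""
    return float(gamma_fn(1.0 + 1.0 / params.gamma) * params.lam ** (-1.0 / params.gamma))
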