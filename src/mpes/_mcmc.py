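"""Shared affine-invariant ensemble MCMC runner with convergence diagnostics.

All Bayesian models in the package express a vectorised log posterior
``f(theta) -> (n,)`` over parameter matrices ``theta (n, ndim)`` and are
sampled with emcee's stretch move.  Run lengths are configured as *total*
draw counts: with W walkers, ``ceil(iterations / W)`` steps are taken and
the first ``ceil(burnin / W)`` discarded, so the retained sample size is
approximately ``iterations - burnin`` regardless of the ensemble size.

Diagnostics: split-Rhat and bulk effective sample size computed by arviz
over the walker chains.  ``converged`` flags max Rhat <= threshold; callers
surface the flag rather than failing silently.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import arviz as az
import emcee
import numpy as np

from .config import MCMCConfig

log = logging.getLogger("mpes.mcmc")

RHAT_THRESHOLD = 1.05


@dataclass
class MCMCDiagnostics:
    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values()) if self.rhat else float("nan")


class PosteriorDraws:
    """Retained draws as a name -> flat array mapping, plus diagnostics."""

    def __init__(self, chain: np.ndarray, names: list[str], diagnostics: MCMCDiagnostics):
        # chain: (walkers, steps, ndim)
        self._chain = chain
        self.names = list(names)
        self.diagnostics = diagnostics
        self.n_draws = chain.shape[0] * chain.shape[1]

    def __getitem__(self, name: str) -> np.ndarray:
        j = self.names.index(name)
        return self._chain[:, :, j].reshape(-1)

    def array(self) -> np.ndarray:
        return self._chain.reshape(-1, self._chain.shape[2])

    def summary_row(self, draws: np.ndarray) -> dict:
        q = np.quantile(draws, [0.025, 0.5, 0.975])
        return {"mean": float(draws.mean()), "sd": float(draws.std(ddof=1)),
                "q2.5": float(q[0]), "median": float(q[1]), "q97.5": float(q[2])}


def run_sampler(log_prob, ndim: int, names: list[str], mcmc: MCMCConfig,
                init_center: np.ndarray, init_scale: np.ndarray,
                min_walkers: int = 32, thin: int | None = None) -> PosteriorDraws:
    """Run the ensemble sampler; deterministic given ``mcmc.seed``.

    Differential-evolution moves handle the correlated, heavy-tailed
    posteriors that vague half-normal scale priors produce.  Chains are
    internally oversampled and thinned (factor ~ndim, capped at 10) so the
    retained draw count stays at ``iterations - burnin`` while integrated
    autocorrelation is kept low.
    """
    mcmc.validate()
    nwalkers = max(2 * ndim + 2, min_walkers)
    nwalkers += nwalkers % 2
    if thin is None:
        thin = max(3, min(10, ndim))
    steps = max(2 * thin, math.ceil(mcmc.iterations * thin / nwalkers))
    discard = min(steps - thin, math.ceil(mcmc.burnin * thin / nwalkers))
    rng = np.random.default_rng(mcmc.seed)

    center = np.asarray(init_center, dtype=float)
    scale = np.asarray(init_scale, dtype=float)
    p0 = np.empty((nwalkers, ndim))
    for w in range(nwalkers):
        for _ in range(200):
            cand = center + scale * rng.standard_normal(ndim)
            if np.isfinite(log_prob(cand[None, :])[0]):
                p0[w] = cand
                break
        else:
            raise RuntimeError("could not initialise walkers in the posterior support")

    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob, vectorize=True,
                                    moves=moves)
    state = emcee.State(p0, random_state=np.random.RandomState(rng.integers(2**31 - 1)).get_state())
    log.info("mcmc: ndim=%d walkers=%d steps=%d discard=%d thin=%d seed=%d",
             ndim, nwalkers, steps, discard, thin, mcmc.seed)
    sampler.run_mcmc(state, steps, progress=False, skip_initial_state_check=True)
    chain = sampler.get_chain(discard=discard, thin=thin)  # (steps, walkers, ndim)
    chain = np.swapaxes(chain, 0, 1)                    # (walkers, steps, ndim)

    data = {nm: chain[:, :, j] for j, nm in enumerate(names)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=data)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    rhat_d = {nm: float(rhat[nm].values) for nm in names}
    ess_d = {nm: float(ess[nm].values) for nm in names}
    diag = MCMCDiagnostics(rhat=rhat_d, ess=ess_d,
                           converged=bool(max(rhat_d.values()) <= RHAT_THRESHOLD))
    if not diag.converged:
        log.warning("mcmc: convergence flag raised, max Rhat=%.4f", diag.max_rhat)
    return PosteriorDraws(chain, names, diag)
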