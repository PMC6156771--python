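"""Analysis configuration: priors, MCMC settings, Markov and EVPI settings.

Defaults reproduce the case-study conditions: 30,000 MCMC iterations with
15,000 burn-in for the evidence synthesis; a 180-cycle monthly Markov model
with a 10,000-patient cohort, 3.5%/year discounting from cycle 13; EVPI over
a 12-year decision horizon with 9,000 incident patients per year.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import yaml

from .data import ValidationError


@dataclass
class PriorConfig:
    """Vague prior hyperparameters for the Bayesian synthesis models.

    ``effect_variance`` is the variance of the Normal(0, .) priors on pooled
    effects and regression intercepts; ``sd_scale_variance`` the variance
    parameter of the half-normal priors on between-study SDs.  Written as
    variances (not BUGS precisions).  ``logvar_sd_scale`` is the half-normal
    scale of the hyper-SD in the exchangeable within-study log-variance
    model used to predict the SE of a missing estimate.
    """

    effect_variance: float = 1e3
    sd_scale_variance: float = 1e3
    logvar_sd_scale: float = 1.0

    def validate(self) -> "PriorConfig":
        if self.effect_variance <= 0 or self.sd_scale_variance <= 0 or self.logvar_sd_scale <= 0:
            raise ValidationError("prior variances/scales must be > 0")
        return self


@dataclass
class MCMCConfig:
    """Sampler run lengths, counted as total draws across the ensemble."""

    iterations: int = 30_000
    burnin: int = 15_000
    chains: int = 2
    seed: int = 0

    def validate(self) -> "MCMCConfig":
        if self.iterations <= self.burnin:
            raise ValidationError("mcmc: iterations must exceed burnin")
        if self.burnin < 0 or self.chains < 1:
            raise ValidationError("mcmc: burnin >= 0 and chains >= 1 required")
        return self


@dataclass
class MarkovConfig:
    n_cycles: int = 180
    cycle_months: float = 1.0
    cohort: int = 10_000
    discount_rate: float = 0.035
    discount_start_cycle: int = 13
    half_cycle_correction: bool = False
    psa_draws: int = 10_000

    def validate(self) -> "MarkovConfig":
        if self.n_cycles < 1:
            raise ValidationError("markov: n_cycles >= 1 required")
        if not (0 <= self.discount_rate < 1):
            raise ValidationError("markov: discount_rate must be in [0, 1)")
        if self.cycle_months <= 0 or self.cohort < 1 or self.psa_draws < 1:
            raise ValidationError("markov: cycle_months > 0, cohort >= 1, psa_draws >= 1")
        return self


@dataclass
class EVPISettings:
    """Population scaling of per-person EVPI over future incident cohorts."""

    horizon_years: int = 12
    incidence: float = 9_000.0
    discount_rate: float = 0.035
    discount_first_year: bool = False

    def validate(self) -> "EVPISettings":
        if self.horizon_years < 1 or self.incidence < 0:
            raise ValidationError("evpi: horizon_years >= 1 and incidence >= 0 required")
        if not (0 <= self.discount_rate < 1):
            raise ValidationError("evpi: discount_rate must be in [0, 1)")
        return self


@dataclass
class AnalysisConfig:
    """Top-level configuration for the end-to-end pipeline."""

    priors: PriorConfig = field(default_factory=PriorConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    markov: MarkovConfig = field(default_factory=MarkovConfig)
    evpi: EVPISettings = field(default_factory=EVPISettings)
    wtp_grid: list[float] = field(default_factory=lambda: [float(w) for w in range(0, 50_001, 2_500)])
    # cost/utility inputs; when None the packaged case-study fixture is used
    costs: dict | None = None
    utilities: dict | None = None

    def validate(self) -> "AnalysisConfig":
        self.priors.validate()
        self.mcmc.validate()
        self.markov.validate()
        self.evpi.validate()
        if any(w < 0 for w in self.wtp_grid):
            raise ValidationError("wtp_grid thresholds must be >= 0")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        kwargs = dict(d)
        for key, sub in (("priors", PriorConfig), ("mcmc", MCMCConfig),
                         ("markov", MarkovConfig), ("evpi", EVPISettings)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs).validate()

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        text = open(path).read()
        d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(d or {})

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            if str(path).endswith(".json"):
                json.dump(self.to_dict(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_dict(), fh)
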