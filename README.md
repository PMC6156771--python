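# mpes — multiparameter evidence synthesis for decision models

`mpes` is a Python package for health-technology-assessment analysts and
biostatisticians who need to populate a Markov cost-effectiveness model when
some of the required treatment-effect estimates were never reported.  Its
core idea: treatment effects on overall survival (OS) and progression-free
survival (PFS) are correlated across trials, so a **bivariate random-effects
meta-analysis (BRMA)** of the log hazard ratios can *predict* a study-level
effect that a trial did not report — and the predicted posterior draws can
then drive a more detailed decision model than the reported data alone would
allow.

The package implements the full chain for the motivating case study
(docetaxel + prednisolone, D+P, versus mitoxantrone + prednisolone, M+P, and
prednisolone alone, P, in metastatic hormone-refractory prostate cancer):

* pairwise Bayesian meta-analysis (common-effect and random-effects) of log
  hazard ratios;
* BRMA with the product-normal formulation, missing-effect prediction and
  an exchangeable model for the missing within-study variance;
* fixed/random-effects network meta-analysis (NMA) for indirect contrasts;
* Cox (Breslow/Efron) and right-censored Weibull fitting from IPD tables;
* probabilistic 2-state (Alive/Dead) and 3-state (stable disease /
  progressive disease / dead) monthly-cycle Markov cohort models with
  time-dependent Weibull transitions;
* ICERs, net monetary benefit, CEACs and population EVPI;
* a synthetic-data module generating study sets and survival IPD with known
  ground truth, plus a packaged approximate case-study fixture.

## The model

Observed log hazard ratios per study $i$ are bivariate normal around true
effects, with known within-study SEs and correlation $\rho_{w,i}$:

$$\begin{pmatrix} Y_{OS,i} \\ Y_{PFS,i} \end{pmatrix} \sim
N\!\left(\begin{pmatrix} \mu_{OS,i} \\ \mu_{PFS,i} \end{pmatrix},
\Sigma_i\right)$$

True effects follow the between-study model in product-normal form,
$\mu_{OS,i} \sim N(\eta_{OS}, \tau_{OS}^2)$ and
$\mu_{PFS,i} \mid \mu_{OS,i} \sim N(\lambda_0 + \lambda_1(\mu_{OS,i} -
\eta_{OS}),\ \psi_{PFS}^2)$, with slope
$\lambda_1 = \rho_b \tau_{PFS}/\tau_{OS}$ and conditional variance
$\psi_{PFS}^2 = \tau_{PFS}^2(1-\rho_b^2)$.  Pooled hazard ratios are
$e^{\eta_{OS}}$ and $e^{\lambda_0}$.  A missing $Y_{PFS,i}$ is predicted
directly from the MCMC simulation, with its SE drawn from an exchangeable
model over the observed within-study log variances.

Downstream, the Markov engine converts a Weibull survival model
$S(t) = e^{-\lambda t^\gamma}$ into time-dependent cycle transition
probabilities $1 - S(t)/S(t-1)$, applies hazard-ratio draws as
$1-(1-tp)^{HR}$, and accrues discounted costs and QALYs per cycle
(3.5%/year from cycle 13; stable-disease utility as the
transition-probability-weighted average of the surviving, progressed and
other-cause-death EQ-5D values).

## Worked example

```python
from mpes import AnalysisConfig, hta_fixture, run_full_analysis

studies, _ = hta_fixture()          # 4 trials; TAX 327 has no PFS estimate
cfg = AnalysisConfig()              # 30,000/15,000 MCMC; 180 cycles; 10,000 cohort
cfg.mcmc.seed = 1
bundle = run_full_analysis(studies, config=cfg)
print(bundle.hr_table.round(3).to_string(index=False))
```

prints the synthesis table (hazard ratios with 95% credible intervals):

```
          analysis outcome    hr    lo    hi
          MA fixed      os 0.903 0.751 1.079
         MA random      os 0.902 0.552 1.530
          MA fixed     pfs 0.641 0.531 0.773
         MA random     pfs 0.612 0.140 2.096
predicted (TAX327)     pfs 0.600 0.111 3.142
         NMA fixed      os 0.687 0.523 0.899
        NMA random      os 0.687 0.359 1.234
         NMA fixed     pfs 0.386 0.075 1.916
        NMA random     pfs 0.356 0.021 4.797
```

Reading it: mitoxantrone adds little OS benefit over prednisolone alone
(pooled HR 0.903) but clearly delays progression (PFS HR 0.641).  The row
`predicted (TAX327)` is the BRMA-predicted effect of D+P versus M+P on PFS
(HR 0.600) — the estimate the TAX 327 trial never reported, obtained by
borrowing strength from the correlated OS evidence.  The NMA rows give the
indirect D+P-versus-P contrasts.  The decision models then report, for this
run:

```
two_state:   dCost £5,888, dQALY 0.196, ICER £29,976,  pop EVPI @£20k £1.06e8
three_state: dCost £3,647, dQALY 0.369, ICER  £9,872,  pop EVPI @£20k £9.54e7
```

The predicted PFS effect is what makes the 3-state model possible at all,
and separating stable from progressed patients raises the incremental QALY
gain, hence the much lower ICER — the case study's central finding.  (The
packaged study table and cost/Weibull inputs are approximate stand-ins for
report-only values; see `docs/methods.md`.  Magnitudes, not third decimals,
are the point of this example.)

A command-line interface mirrors the stages:

```bash
mpes run-all --seed 1 --out tables/
mpes brma --seed 1
mpes simulate --kind studies --n 20 --seed 1 --out synthetic.csv
```

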