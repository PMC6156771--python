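# Decision-model inputs for the mHRPC docetaxel case study.
#
# Provenance, per field:
#   published  — value printed in the source publication
#   synthetic  — stand-in constructed by this package to approximate inputs
#                that live only in the original HTA report / supplementary
#                tables; magnitudes chosen so the fitted pipeline reproduces
#                the published results to order of magnitude only.

treatments:
  codes: [P, M+P, D+P]
  baseline: P
  names:
    P: "prednisolone alone"
    M+P: "mitoxantrone + prednisolone"
    D+P: "docetaxel (3-weekly) + prednisolone"

utilities:            # EQ-5D means and SEs — published (Sandblom et al. values)
  surviving: {mean: 0.770, se: 0.015}
  pd: {mean: 0.538, se: 0.077}
  other_causes: {mean: 0.564, se: 0.067}

transition:
  other_cause_tp: 0.005        # published — StD->dead per cycle, no uncertainty
  p_cancer_death: 1.0          # synthetic — share of deaths via progression used
                               # in the mean-survival decomposition (other-cause
                               # route handled by other_cause_tp separately)
  os_weibull: {shape: 1.25, lam: 0.0235}   # synthetic — approximates the HTA-report
                                           # M+P OS Weibull (median ~15 mo)
  pfs_weibull: {shape: 1.10, lam: 0.106}   # synthetic — approximates the SWOG M+P
                                           # PFS Weibull (median ~5.5 mo)
  weibull_cov_log:             # synthetic — PSA covariance on (ln lam, ln gamma)
    sd_loglam: 0.08
    sd_loggamma: 0.04
    corr: -0.5

costs:                # GBP — synthetic; 3-component structure is published
  P:
    drug_per_cycle: 30.0
    drug_cycles: 10
    followup_per_cycle: 520.0
    terminal: 2500.0
    se_fraction: 0.2
  M+P:
    drug_per_cycle: 250.0
    drug_cycles: 10
    followup_per_cycle: 450.0
    terminal: 2500.0
    se_fraction: 0.2
  D+P:
    drug_per_cycle: 700.0
    drug_cycles: 10
    followup_per_cycle: 450.0
    terminal: 2500.0
    se_fraction: 0.2
followup_pd_fraction: [0.70, 0.80]   # published range — share of follow-up cost
                                     # accruing after progression
alive_utility: {mean: 0.538, se: 0.077}  # published — 2-state alive-state utility

discount:
  rate: 0.035                  # published — annual
  start_cycle: 13              # published — first year undiscounted
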