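"""Packaged case-study fixture: the mHRPC docetaxel evidence base.

The four-trial study table mirrors the HTA evidence base: three trials of
mitoxantrone plus corticosteroid versus corticosteroid alone reporting both
OS and PFS, and TAX 327 (docetaxel + prednisolone vs mitoxantrone +
prednisolone) reporting OS only — its PFS effect is the quantity the
bivariate meta-analysis predicts.

Study-level log HR/SE values for the three M+P trials are *synthetic
stand-ins* (the originals live in supplementary tables not shipped here),
constructed so their inverse-variance pooled results reproduce the
published pooled hazard ratios: OS 0.903 (0.751-1.084) and PFS 0.641
(0.532-0.772).  The TAX 327 OS row is the published 0.76 (0.620-0.936).
Decision-model inputs mix published values (utilities, the 0.005
other-cause transition, discounting, the 70-80% follow-up split) with
synthetic placeholders for HTA-report-only inputs (Weibulls, cost levels);
each field's provenance is recorded in the YAML data file.
"""

from __future__ import annotations

import math
from importlib import resources

import numpy as np
import yaml

from .data import StudyRecord, TreatmentSet, read_study_table
from .markov import TreatmentCosts, UtilityInputs
from .survival import WeibullParams


def _data_path(name: str):
    return resources.files("mpes").joinpath("data", name)


def hta_fixture() -> tuple[list[StudyRecord], dict]:
    """Return (studies, markov_inputs) for the packaged case study.

    ``markov_inputs`` carries everything the Markov engine needs:
    ``treatments`` (:class:`TreatmentSet`), ``utilities``, ``costs`` (per
    treatment code), ``os_weibull``/``pfs_weibull`` with ``weibull_cov_log``,
    ``other_cause_tp``, ``p_cancer_death``, ``followup_pd_fraction``,
    ``alive_utility``/``alive_utility_se`` and ``discount`` settings.
    """
    with resources.as_file(_data_path("hta_studies.csv")) as p:
        studies = read_study_table(p)
    raw = yaml.safe_load(_data_path("hta_model.yaml").read_text())

    tr = raw["treatments"]
    treatments = TreatmentSet(codes=tuple(tr["codes"]), baseline=tr["baseline"],
                              names=tr.get("names", {}))
    u = raw["utilities"]
    utilities = UtilityInputs(
        surviving=u["surviving"]["mean"], surviving_se=u["surviving"]["se"],
        pd=u["pd"]["mean"], pd_se=u["pd"]["se"],
        other_causes=u["other_causes"]["mean"], other_causes_se=u["other_causes"]["se"],
    )
    costs = {code: TreatmentCosts(
        drug_per_cycle=c["drug_per_cycle"], drug_cycles=c["drug_cycles"],
        followup_per_cycle=c["followup_per_cycle"], terminal=c["terminal"],
        se_fraction=c.get("se_fraction", 0.2),
    ) for code, c in raw["costs"].items()}
    t = raw["transition"]
    cov = t["weibull_cov_log"]
    s1, s2, r = cov["sd_loglam"], cov["sd_loggamma"], cov["corr"]
    weibull_cov_log = np.array([[s1 ** 2, r * s1 * s2], [r * s1 * s2, s2 ** 2]])

    markov_inputs = {
        "treatments": treatments,
        "utilities": utilities,
        "costs": costs,
        "os_weibull": WeibullParams(gamma=t["os_weibull"]["shape"],
                                    lam=t["os_weibull"]["lam"]),
        "pfs_weibull": WeibullParams(gamma=t["pfs_weibull"]["shape"],
                                     lam=t["pfs_weibull"]["lam"]),
        "weibull_cov_log": weibull_cov_log,
        "other_cause_tp": t["other_cause_tp"],
        "p_cancer_death": t["p_cancer_death"],
        "followup_pd_fraction": tuple(raw["followup_pd_fraction"]),
        "alive_utility": raw["alive_utility"]["mean"],
        "alive_utility_se": raw["alive_utility"]["se"],
        "discount_rate": raw["discount"]["rate"],
        "discount_start_cycle": raw["discount"]["start_cycle"],
    }
    return studies, markov_inputs
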