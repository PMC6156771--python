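"""Evidence-synthesis models: identities, oracles and posterior constraints."""

import numpy as np
import pytest

from mpes.config import MCMCConfig
from mpes.data import StudyRecord, TreatmentSet, ValidationError
from mpes.meta import (BivariateMetaAnalysis, MetaAnalysis,
                       NetworkMetaAnalysis, fit_ma_common)
from mpes.simulate import EvidenceSimConfig, gen_study_set


def test_ma_single_study_identity(medium_mcmc):
    """One study: posterior reproduces the study (vague prior is negligible)."""
    res = MetaAnalysis([-0.3], [0.1]).fit("common", mcmc=medium_mcmc)
    assert res.pooled.mean() == pytest.approx(-0.3, abs=0.01)
    assert res.pooled.std(ddof=1) == pytest.approx(0.1, rel=0.1)


def test_ma_common_inverse_variance_oracle(medium_mcmc):
    """Pooled posterior matches the closed-form inverse-variance estimate."""
    res = MetaAnalysis([0.2, 0.4], [0.1, 0.2]).fit("common", mcmc=medium_mcmc)
    mcse = 0.08944 / np.sqrt(res.diagnostics.ess["pooled"])
    assert res.pooled.mean() == pytest.approx(0.24, abs=max(3 * mcse, 0.005))
    assert res.pooled.std(ddof=1) == pytest.approx(0.08944, rel=0.05)


def test_ma_random_identical_studies_shrinks_tau(medium_mcmc):
    """Five identical studies: tau concentrates near 0 and the pooled mean
    approaches the common-effect answer."""
    y, se = [0.1] * 5, [0.1] * 5
    res = MetaAnalysis(y, se).fit("random", mcmc=medium_mcmc)
    assert np.median(res.tau) < 0.08
    assert res.pooled.mean() == pytest.approx(0.1, abs=0.03)


def test_ma_fixture_pooled_hrs(fixture_studies, medium_mcmc):
    """The case-study M+P vs P estimates pool to the published fixed-effect
    hazard ratios: OS ~0.903, PFS ~0.641."""
    mp = [s for s in fixture_studies if s.comparator_treatment == "M+P"]
    os_res = MetaAnalysis([s.y_os for s in mp], [s.se_os for s in mp]).fit(
        "common", mcmc=medium_mcmc)
    assert os_res.hr == pytest.approx(0.903, abs=0.01)
    pfs_res = MetaAnalysis([s.y_pfs for s in mp], [s.se_pfs for s in mp]).fit(
        "common", mcmc=medium_mcmc)
    assert pfs_res.hr == pytest.approx(0.641, abs=0.01)


def test_ma_validation():
    with pytest.raises(ValidationError):
        MetaAnalysis([], [])
    with pytest.raises(ValidationError):
        MetaAnalysis([0.1], [0.0])
    with pytest.raises(ValidationError):
        MetaAnalysis([0.1], [0.1]).fit("random")


# ---------------------------------------------------------------------------
# BRMA
# ---------------------------------------------------------------------------

def test_brma_posterior_constraints(fixture_studies, fast_mcmc):
    """Every retained draw satisfies |rho_b|<1, tau>=0 and
    psi2_pfs = tau_pfs^2 (1 - rho_b^2) >= 0."""
    res = BivariateMetaAnalysis(fixture_studies).fit(fast_mcmc)
    d = res.draws
    assert np.all(np.abs(d["rho_b"]) < 1)
    assert np.all(d["tau_os"] >= 0) and np.all(d["tau_pfs"] >= 0)
    assert np.all(d["psi2_pfs"] >= 0)
    assert np.allclose(d["psi2_pfs"], d["tau_pfs"] ** 2 * (1 - d["rho_b"] ** 2))
    # lambda1 = rho_b * tau_pfs / tau_os in every draw
    assert np.allclose(d["lambda1"] * d["tau_os"], d["rho_b"] * d["tau_pfs"])


def test_brma_predicts_exactly_the_missing_entries(fixture_studies, fast_mcmc):
    res = BivariateMetaAnalysis(fixture_studies).fit(fast_mcmc)
    assert set(res.predictions) == {("TAX327", "pfs")}
    hr, lo, hi = res.predicted_hr("TAX327")
    assert 0 < lo < hr < hi


def test_brma_no_heterogeneity_prediction_collapses_to_pooled_mean(fast_mcmc):
    """tau=0 and tiny observed PFS SEs: the predicted missing effect must
    collapse to the pooled PFS effect lambda0."""
    cfg = EvidenceSimConfig(n_studies=10, tau_os=0.0, tau_pfs=0.0, rho_w=0.0,
                            se_range=(0.08, 0.12), seed=21,
                            missing_pattern=[(3, "pfs")])
    recs, _ = gen_study_set(cfg)
    tiny = [
        StudyRecord(s.study_id, s.reference_treatment, s.comparator_treatment,
                    y_os=s.y_os, se_os=s.se_os,
                    y_pfs=None if s.y_pfs is None else cfg.eta_pfs,
                    se_pfs=None if s.y_pfs is None else 1e-3)
        for s in recs
    ]
    res = BivariateMetaAnalysis(tiny, fix_rho_w=0.0).fit(fast_mcmc)
    pred = res.predictions[("SIM003", "pfs")]
    lam0 = res.draws["lambda0"].mean()
    assert pred["loghr_mean"] == pytest.approx(lam0, abs=0.05)
    assert pred["loghr_mean"] == pytest.approx(cfg.eta_pfs, abs=0.1)


def test_brma_rho_zero_complete_matches_univariate_random_effects(medium_mcmc):
    """With rho_w = rho_b = 0 and complete data, the BRMA margins reproduce
    two independent univariate random-effects fits."""
    cfg = EvidenceSimConfig(n_studies=15, rho_b=0.0, rho_w=0.0, seed=31)
    recs, _ = gen_study_set(cfg)
    res = BivariateMetaAnalysis(recs, fix_rho_w=0.0).fit(medium_mcmc)
    uni_os = MetaAnalysis([s.y_os for s in recs], [s.se_os for s in recs]).fit(
        "random", mcmc=medium_mcmc)
    uni_pfs = MetaAnalysis([s.y_pfs for s in recs], [s.se_pfs for s in recs]).fit(
        "random", mcmc=medium_mcmc)
    # note rho_b is still estimated in the BRMA, so agreement is approximate
    assert res.draws["eta_os"].mean() == pytest.approx(uni_os.pooled.mean(), abs=0.03)
    assert res.draws["lambda0"].mean() == pytest.approx(uni_pfs.pooled.mean(), abs=0.03)


def test_brma_identifiability_guards():
    only_os = [StudyRecord(f"s{i}", "A", "B", y_os=-0.1, se_os=0.1)
               for i in range(4)]
    with pytest.raises(ValidationError, match="missing pfs"):
        BivariateMetaAnalysis(only_os)
    mixed = only_os[:3] + [StudyRecord("s3", "A", "B", y_pfs=-0.4, se_pfs=0.2)]
    with pytest.raises(ValidationError, match="unidentified"):
        BivariateMetaAnalysis(mixed)
    # force=True proceeds (flagged, not silent)
    BivariateMetaAnalysis(mixed, force=True)


def test_brma_convergence_diagnostics_attached(fixture_studies, fast_mcmc):
    res = BivariateMetaAnalysis(fixture_studies).fit(fast_mcmc)
    assert res.diagnostics.max_rhat > 0
    assert set(res.diagnostics.rhat) == set(res.diagnostics.ess)


# ---------------------------------------------------------------------------
# NMA
# ---------------------------------------------------------------------------

TS = TreatmentSet(codes=("P", "M+P", "D+P"), baseline="P")


def test_nma_single_edge_equals_pairwise_ma(medium_mcmc):
    """A one-edge network is just the pairwise meta-analysis."""
    ests = [("P", "M+P", -0.2, 0.1), ("P", "M+P", -0.4, 0.2)]
    ts = TreatmentSet(codes=("P", "M+P"), baseline="P")
    nma = NetworkMetaAnalysis(ests, ts).fit("fixed", mcmc=medium_mcmc)
    ma = fit_ma_common([(-0.2, 0.1), (-0.4, 0.2)], mcmc=medium_mcmc)
    c = nma.contrast("M+P", "P")
    assert c.mean() == pytest.approx(ma.pooled.mean(), abs=0.01)
    assert c.std(ddof=1) == pytest.approx(ma.pooled.std(ddof=1), rel=0.1)


def test_nma_tree_composition(medium_mcmc):
    """Fixed-effect indirect contrast on a two-edge tree equals the sum of
    the edge log hazard ratios: 0.641 x 0.619 -> 0.397."""
    ests = [("P", "M+P", np.log(0.641), 0.09501),
            ("M+P", "D+P", np.log(0.619), 0.21805)]
    res = NetworkMetaAnalysis(ests, TS).fit("fixed", mcmc=medium_mcmc)
    c = res.contrast("D+P", "P")
    assert float(np.exp(c.mean())) == pytest.approx(0.397, abs=0.008)


def test_nma_contrast_identities(medium_mcmc):
    ests = [("P", "M+P", -0.1, 0.1), ("M+P", "D+P", -0.3, 0.15),
            ("P", "D+P", -0.35, 0.2)]
    res = NetworkMetaAnalysis(ests, TS).fit("random", mcmc=medium_mcmc)
    # antisymmetry and the three-way consistency identity hold per draw
    assert np.allclose(res.contrast("P", "M+P"), -res.contrast("M+P", "P"))
    loop = (res.contrast("P", "M+P") + res.contrast("M+P", "D+P")
            + res.contrast("D+P", "P"))
    assert np.allclose(loop, 0.0, atol=1e-12)
    assert np.all(res.sigma >= 0)


def test_nma_disconnected_network_errors():
    ests = [("P", "M+P", -0.1, 0.1)]
    with pytest.raises(ValidationError, match="disconnected"):
        NetworkMetaAnalysis(ests, TS)
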