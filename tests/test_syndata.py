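"""Generator tests: analytic oracles, invariants, determinism."""

import numpy as np
import pandas as pd
import pytest

from sharedarch import syndata
from sharedarch.syndata import (CohortConfig, SumStatsConfig,
                                analytic_covariance, generate_cohort,
                                generate_multitrait_sumstats,
                                generate_sumstats,
                                population_canonical_correlations)


# ----------------------------------------------------------------- config

def test_rho_validation():
    with pytest.raises(ValueError, match=r"\[0, 1\)"):
        CohortConfig(canonical_rhos=(1.0,))
    with pytest.raises(ValueError, match="non-increasing"):
        CohortConfig(canonical_rhos=(0.1, 0.2))


def test_missing_rate_validation():
    with pytest.raises(ValueError, match="missing_rate"):
        CohortConfig(missing_rate=0.96)


def test_infeasible_rank_names_index():
    # 31 items but requesting more latents than the 7-measure PA base rank
    with pytest.raises(ValueError, match="infeasible"):
        CohortConfig(canonical_rhos=tuple([0.5] * 9), n_subjects=100)
        generate_cohort(CohortConfig(canonical_rhos=tuple(np.linspace(0.5, 0.1, 9)),
                                     n_subjects=100))


# ------------------------------------------- population CCs (exact oracle)

def test_population_ccs_zero_cross():
    cfg = CohortConfig(canonical_rhos=(), n_latents=0, n_subjects=100)
    ccs = population_canonical_correlations(cfg, ("brain", "pa"))
    assert np.allclose(ccs, 0.0, atol=1e-12)


def test_population_ccs_scalar_rho():
    cfg = CohortConfig(canonical_rhos=(0.4,), n_subjects=100, seed=1)
    for pair in (("brain", "mh"), ("brain", "pa")):
        ccs = population_canonical_correlations(cfg, pair)
        assert ccs[0] == pytest.approx(0.4, abs=1e-10)
        assert np.all(ccs[1:] < 1e-8)


@pytest.mark.parametrize("mode", ["independent", "shared"])
def test_population_ccs_match_request(mode):
    cfg = CohortConfig(canonical_rhos=(0.25, 0.15), cross_block_mode=mode,
                       n_subjects=100, seed=3)
    for pair in (("brain", "mh"), ("brain", "pa")):
        ccs = population_canonical_correlations(cfg, pair)
        assert ccs[0] == pytest.approx(0.25, abs=1e-10)
        assert ccs[1] == pytest.approx(0.15, abs=1e-10)
        assert np.all(ccs[2:] < 1e-8)


def test_population_ccs_monte_carlo_oracle():
    """Analytic values match brute-force CCA on 200k draws within 0.01."""
    cfg = CohortConfig(canonical_rhos=(0.3, 0.2), n_subjects=200_000,
                       item_thresholds=None, seed=9,
                       confound_effects={})
    cohort = generate_cohort(cfg)
    from sharedarch.cca import fit_cca
    model = fit_cca(cohort.brain, cohort.pa)
    expected = population_canonical_correlations(cfg, ("brain", "pa"))
    assert np.allclose(model.correlations[:2], expected[:2], atol=0.01)


def test_empirical_covariance_converges():
    cfg = CohortConfig(n_subjects=60_000, canonical_rhos=(0.3,),
                       n_subnets=3, n_mh_items=4, n_pa_base=2,
                       item_thresholds=None, confound_effects={}, seed=5)
    cohort = generate_cohort(cfg)
    joint = np.hstack([cohort.brain.values(), cohort.mh_items.values(),
                       cohort.pa.values()])
    emp = np.cov(joint, rowvar=False)
    sigma, _ = analytic_covariance(cfg)
    assert np.max(np.abs(emp - sigma)) < 0.05


# ---------------------------------------------------------------- cohorts

def test_independence_case_empirical():
    """Zero cross-loadings: empirical r1 is sampling noise only (< 0.05).

    Block sizes are kept small here; the full 28 x 21 layout adds an
    overfitting offset of about (sqrt(p) + sqrt(q)) / sqrt(n) ~ 0.13 even
    under independence, which is a property of sample CCA, not of the
    generator.
    """
    from sharedarch.cca import fit_cca
    rs = []
    for seed in range(3):
        cfg = CohortConfig(n_subjects=6000, canonical_rhos=(0.0,),
                           n_subnets=2, n_pa_base=1,
                           item_thresholds=None, confound_effects={},
                           seed=seed)
        cohort = generate_cohort(cfg)
        m = fit_cca(cohort.brain, cohort.pa)
        rs.append(m.correlations[0])
    assert np.median(np.abs(rs)) < 0.05


def test_missing_rate_observed():
    cfg = CohortConfig(n_subjects=6000, canonical_rhos=(0.2,),
                       missing_rate={"item01": 0.35}, seed=2)
    cohort = generate_cohort(cfg)
    frac = cohort.mh_items.missing_fraction()
    assert abs(frac["item01"] - 0.35) < 0.03
    assert frac["item02"] == 0.0


def test_mar_missingness_depends_on_age():
    cfg = CohortConfig(n_subjects=8000, canonical_rhos=(0.2,),
                       missing_rate=0.3, missing_mechanism="MAR-on-confound",
                       seed=4)
    cohort = generate_cohort(cfg)
    miss = cohort.mh_items.data["item01"].isna()
    age = cohort.confounds.data["age"]
    assert age[miss].mean() > age[~miss].mean() + 1.0


def test_ordinal_levels_and_mask():
    cfg = CohortConfig(n_subjects=500, canonical_rhos=(0.2,),
                       missing_rate=0.2, seed=6)
    cohort = generate_cohort(cfg)
    vals = cohort.mh_items.data.to_numpy().ravel()
    observed = vals[~np.isnan(vals)]
    assert set(np.unique(observed)) <= {0.0, 1.0, 2.0, 3.0}
    assert cohort.mh_items.missing_mask().to_numpy().any()
    assert all(k == "ordinal" for k in cohort.mh_items.kinds.values())


def test_cohort_determinism():
    cfg = CohortConfig(n_subjects=300, canonical_rhos=(0.25, 0.15),
                       missing_rate=0.1, seed=11)
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    for name in ("brain", "mh_items", "pa", "confounds"):
        pd.testing.assert_frame_equal(a.tables()[name].data,
                                      b.tables()[name].data)


def test_pa_windows_correlated():
    cfg = CohortConfig(n_subjects=5000, canonical_rhos=(),
                       n_latents=0, confound_effects={}, seed=8)
    cohort = generate_cohort(cfg)
    d = cohort.pa.data
    r = np.corrcoef(d["sleep_overall"], d["sleep_weekday"])[0, 1]
    assert r == pytest.approx(0.8, abs=0.05)
    assert cohort.pa.data.shape[1] == 21


def test_block_shapes():
    cfg = CohortConfig(n_subjects=50, canonical_rhos=(0.2,), seed=1)
    cohort = generate_cohort(cfg)
    assert cohort.brain.data.shape[1] == 28   # 21 edges + 7 amplitudes
    assert cohort.mh_items.data.shape[1] == 31
    assert cohort.confounds.data.shape[1] == 8


# --------------------------------------------------------------- sumstats

def test_sumstats_config_validation():
    with pytest.raises(ValueError, match="h2"):
        SumStatsConfig(h2_1=1.2)
    with pytest.raises(ValueError, match="rg"):
        SumStatsConfig(h2_1=0.1, h2_2=0.1, rho_g=0.2)
    with pytest.raises(ValueError, match="M"):
        SumStatsConfig(m_snps=0)


def test_null_gwas_mean_chisq():
    cfg = SumStatsConfig(m_snps=30_000, h2_1=0.0, h2_2=0.0, rho_g=0.0,
                         seed=1)
    (ss1, ss2), _ = generate_sumstats(cfg)
    assert np.mean(ss1["Z"] ** 2) == pytest.approx(1.0, abs=0.03)
    assert np.mean(ss1["Z"] * ss2["Z"]) == pytest.approx(0.0, abs=0.02)


def test_mean_chisq_plugin_expectation():
    """Constant l_j = 1: mean chi2 = 1 + N h2 / M = 1.2."""
    cfg = SumStatsConfig(m_snps=50_000, n1=100_000, h2_1=0.10, h2_2=0.0,
                         rho_g=0.0, ld_shape=1e-12, ld_scale=1e-12, seed=3)
    (ss1, _), ld = generate_sumstats(cfg)
    assert np.allclose(ld["L2"], 1.0)
    assert np.mean(ss1["Z"] ** 2) == pytest.approx(1.2, abs=0.03)


def test_sample_overlap_moves_cross_product():
    cfg = SumStatsConfig(m_snps=40_000, h2_1=0.0, h2_2=0.0, rho_g=0.0,
                         sample_overlap_intercept=0.2, seed=4)
    (ss1, ss2), _ = generate_sumstats(cfg)
    assert np.mean(ss1["Z"] * ss2["Z"]) == pytest.approx(0.2, abs=0.02)


def test_ld_scores_at_least_one():
    (_, _), ld = generate_sumstats(SumStatsConfig(m_snps=5000, seed=5))
    assert (ld["L2"] >= 1.0).all()


def test_sumstats_determinism():
    cfg = SumStatsConfig(m_snps=2000, h2_1=0.1, h2_2=0.1, rho_g=0.05, seed=9)
    (a1, a2), lda = generate_sumstats(cfg)
    (b1, b2), ldb = generate_sumstats(cfg)
    pd.testing.assert_frame_equal(a1, b1)
    pd.testing.assert_frame_equal(a2, b2)
    pd.testing.assert_frame_equal(lda, ldb)


def test_lcv_mode_preserves_ldsc_moments():
    cfg = SumStatsConfig(m_snps=60_000, n1=50_000, n2=50_000, h2_1=0.2,
                         h2_2=0.2, rho_g=0.1, lcv_mode="pleiotropy", seed=6)
    (ss1, ss2), ld = generate_sumstats(cfg)
    x = cfg.n1 * ld["L2"] / cfg.m_snps
    # regression-free check: mean chi2 matches 1 + N h2 mean(l)/M
    assert np.mean(ss1["Z"] ** 2) == pytest.approx(1 + 0.2 * np.mean(x),
                                                   rel=0.05)


def test_multitrait_matches_rg_matrix():
    lam = np.array([0.8, 0.6, 0.4])
    rg = np.outer(lam, lam)
    np.fill_diagonal(rg, 1.0)
    frames, ld = generate_multitrait_sumstats([0.3] * 3, rg, [100_000] * 3,
                                              40_000, seed=2)
    from sharedarch import ldsr
    res = ldsr.estimate_rg(frames[0], frames[1], ld)
    assert res.rg == pytest.approx(0.48, abs=3 * res.se)


def test_sumstats_io_roundtrip(tmp_path):
    cfg = SumStatsConfig(m_snps=500, seed=1)
    (ss1, _), ld = generate_sumstats(cfg)
    syndata.write_sumstats(ss1, tmp_path / "a.sumstats")
    back = syndata.read_sumstats(tmp_path / "a.sumstats")
    pd.testing.assert_frame_equal(back, ss1)
    syndata.write_ld_scores(ld, tmp_path / "ld.tsv")
    ld2 = syndata.read_ld_scores(tmp_path / "ld.tsv", m_total=500)
    assert np.allclose(ld2["L2"], ld["L2"])
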