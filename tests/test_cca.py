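import numpy as np
import pandas as pd
import pytest

from sharedarch import syndata
from sharedarch.cca import (fit_cca, fit_with_inference, loading_significance,
                            match_variates, permute_inference, residualize,
                            unique_model)
from sharedarch.impute import dummy_code
from sharedarch.tables import PhenotypeTable


def cca_oracle(y, x):
    """Brute-force generalized-eigenvalue canonical correlations."""
    yc = y - y.mean(axis=0)
    xc = x - x.mean(axis=0)
    syy = yc.T @ yc
    sxx = xc.T @ xc
    syx = yc.T @ xc

    def inv_sqrt(m):
        vals, vecs = np.linalg.eigh(m)
        return vecs @ np.diag(vals ** -0.5) @ vecs.T

    sv = np.linalg.svd(inv_sqrt(syy) @ syx @ inv_sqrt(sxx),
                       compute_uv=False)
    return np.clip(sv, 0, 1)


# ---------------------------------------------------------- residualize

def test_residualize_removes_confound(rng):
    c = rng.normal(size=(100, 1))
    data = pd.DataFrame({"a": c[:, 0] * 2.0 + 3.0})
    conf = pd.DataFrame({"c": c[:, 0]})
    out = residualize(data, conf)
    assert np.allclose(out["a"], 0.0, atol=1e-10)


def test_residualize_orthogonal_confound_only_centers(rng):
    n = 2000
    data = pd.DataFrame({"a": rng.normal(size=n) + 5.0})
    conf = pd.DataFrame({"c": rng.normal(size=n)})
    out = residualize(data, conf)
    fitted = data["a"] - out["a"]
    assert np.allclose(fitted, fitted.mean(), atol=0.2)
    assert abs(out["a"].mean()) < 1e-10


def test_residualize_hat_matrix_oracle(rng):
    y = rng.normal(size=(5, 2))
    c = rng.normal(size=(5, 2))
    out = residualize(pd.DataFrame(y), pd.DataFrame(c, columns=["u", "v"]))
    design = np.column_stack([np.ones(5), c])
    hat = design @ np.linalg.inv(design.T @ design) @ design.T
    oracle = y - hat @ y
    assert np.allclose(out.to_numpy(), oracle, atol=1e-12)


def test_residualize_huh_jhun_reduces_rows(rng):
    data = pd.DataFrame(rng.normal(size=(50, 3)))
    conf = pd.DataFrame(rng.normal(size=(50, 2)))
    out = residualize(data, conf, huh_jhun=True)
    assert out.shape == (47, 3)     # n - rank([1 | conf])


# -------------------------------------------------------------- fit_cca

def test_identical_single_column_r1():
    rng = np.random.default_rng(0)
    a = rng.normal(size=50)
    m = fit_cca(pd.DataFrame({"y": a}), pd.DataFrame({"x": a}))
    assert m.correlations[0] == pytest.approx(1.0, abs=1e-10)


def test_matches_eigen_oracle(rng):
    y = rng.normal(size=(50, 5))
    x = rng.normal(size=(50, 4))
    m = fit_cca(y, x)
    assert np.allclose(m.correlations, cca_oracle(y, x)[:4], atol=1e-8)


def test_recovery_on_synthetic_truth(small_cohort):
    conf = dummy_code(small_cohort.confounds)
    y = residualize(small_cohort.brain, conf)
    x = residualize(small_cohort.pa, conf)
    m = fit_cca(y, x)
    # n=1500: looser than the n=6000 acceptance bound
    assert m.correlations[0] == pytest.approx(0.25, abs=0.08)


def test_invariance_to_invertible_transform(rng):
    y = rng.normal(size=(120, 4))
    x = rng.normal(size=(120, 3))
    t = rng.normal(size=(4, 4)) + 4 * np.eye(4)
    m1 = fit_cca(y, x)
    m2 = fit_cca(y @ t, x)
    assert np.allclose(m1.correlations, m2.correlations, atol=1e-8)


def test_variates_unit_variance_and_orthogonal(rng):
    y = rng.normal(size=(200, 5))
    x = rng.normal(size=(200, 4))
    m = fit_cca(y, x)
    u = m.variates_y.to_numpy()
    v = m.variates_x.to_numpy()
    assert np.allclose(np.var(u, axis=0, ddof=1), 1.0, atol=1e-8)
    cu = np.corrcoef(u, rowvar=False)
    cv = np.corrcoef(v, rowvar=False)
    assert np.allclose(cu - np.eye(4), 0.0, atol=1e-8)
    assert np.allclose(cv - np.eye(4), 0.0, atol=1e-8)


def test_loadings_match_recomputation(rng):
    y = rng.normal(size=(80, 4))
    x = rng.normal(size=(80, 3))
    m = fit_cca(y, x)
    yc = y - y.mean(0)
    for k in range(3):
        for j in range(4):
            expect = np.corrcoef(yc[:, j], m.variates_y.iloc[:, k])[0, 1]
            assert m.loadings_y.iloc[j, k] == pytest.approx(expect,
                                                            abs=1e-10)
    assert np.all(np.abs(m.loadings_y.to_numpy()) <= 1 + 1e-12)


def test_n_too_small_fails(rng):
    with pytest.raises(ValueError, match="n > p \\+ q"):
        fit_cca(rng.normal(size=(8, 5)), rng.normal(size=(8, 4)))


def test_singular_block_fails(rng):
    a = rng.normal(size=50)
    y = np.column_stack([a, a, rng.normal(size=50)])
    with pytest.raises(np.linalg.LinAlgError, match="singular"):
        fit_cca(y, rng.normal(size=(50, 2)))


def test_correlations_descending_in_unit_interval(rng):
    m = fit_cca(rng.normal(size=(100, 6)), rng.normal(size=(100, 5)))
    r = m.correlations
    assert np.all(np.diff(r) <= 1e-12)
    assert np.all((r >= 0) & (r <= 1))


# ---------------------------------------------------- permutation inference

def test_permutation_determinism(rng):
    y = rng.normal(size=(80, 3))
    x = rng.normal(size=(80, 3))
    p1 = permute_inference(y, x, n_perm=100, seed=5)
    p2 = permute_inference(y, x, n_perm=100, seed=5)
    assert np.array_equal(p1, p2)
    p3 = permute_inference(y, x, n_perm=100, seed=6)
    assert not np.array_equal(p1, p3)


def test_pvalues_monotone_never_zero(rng):
    y = rng.normal(size=(100, 4))
    x = np.column_stack([y[:, 0] + 0.5 * rng.normal(size=100),
                         rng.normal(size=(100, 2)).T.reshape(100, -1)[:, 0],
                         rng.normal(size=100)])
    p = permute_inference(y, x, n_perm=150, seed=1)
    assert np.all(np.diff(p) >= 0)
    assert np.all(p > 0)
    assert p[0] == pytest.approx(1 / 151, abs=1e-12)


def test_signal_detected(small_cohort):
    conf = dummy_code(small_cohort.confounds)
    y = residualize(small_cohort.brain, conf)
    x = residualize(small_cohort.pa, conf)
    p = permute_inference(y, x, n_perm=150, seed=2)
    assert p[0] <= 0.05


# ------------------------------------------------------------ unique model

def test_unique_empty_other_equals_simple(rng):
    y = pd.DataFrame(rng.normal(size=(100, 3)))
    x = pd.DataFrame(rng.normal(size=(100, 3)))
    empty = pd.DataFrame(index=y.index)
    m_u = unique_model(y, x, empty, None, n_perm=100, seed=3)
    m_s = fit_with_inference(y, x, n_perm=100, seed=3)
    assert np.allclose(m_u.correlations, m_s.correlations, atol=1e-10)
    assert np.array_equal(m_u.p_values, m_s.p_values)


def test_unique_collapse_under_full_mediation():
    """Shared-latent cohort: partialling out a block containing the true
    latent collapses the brain-MH canonical correlation to the null level."""
    cfg = syndata.CohortConfig(
        n_subjects=3000, canonical_rhos=(0.4,), cross_block_mode="shared",
        n_subnets=3, n_mh_items=5, n_pa_base=2,
        item_thresholds=None, confound_effects={}, missing_rate=0.0, seed=21)
    cohort = syndata.generate_cohort(cfg)
    latent = pd.DataFrame(cohort.truth["latents"],
                          index=cohort.brain.data.index, columns=["g1"])
    simple = fit_cca(cohort.brain.data, cohort.mh_items.data)
    uniq = unique_model(cohort.brain.data, cohort.mh_items.data,
                        latent, None, n_perm=100, seed=1)
    assert simple.correlations[0] > 0.3
    assert uniq.correlations[0] < 0.15          # null-level
    assert uniq.p_values[0] > 0.05


def test_unique_attenuation(small_cohort):
    conf = dummy_code(small_cohort.confounds)
    y_res = residualize(small_cohort.brain, conf)
    x_res = residualize(small_cohort.pa, conf)
    simple = fit_cca(y_res, x_res)
    scores = PhenotypeTable(small_cohort.mh_items.data)
    uniq = unique_model(small_cohort.brain, small_cohort.pa, scores, conf,
                        n_perm=100, seed=2)
    assert uniq.correlations[0] <= simple.correlations[0] + 0.01


def test_unique_brain_only_variant(small_cohort):
    conf = dummy_code(small_cohort.confounds)
    m = unique_model(small_cohort.brain, small_cohort.pa,
                     small_cohort.mh_items, conf, n_perm=100, seed=4,
                     partial="brain-only")
    assert m.n_components == 21


# ------------------------------------------------------- loading inference

def test_loading_significance_detects_driver(small_cohort):
    conf = dummy_code(small_cohort.confounds)
    y = residualize(small_cohort.brain, conf)
    x = residualize(small_cohort.pa, conf)
    model = fit_with_inference(y, x, n_perm=150, seed=5)
    nulls = loading_significance(model, n_perm=100, seed=6)
    assert set(nulls.p_values.columns) == {
        model.loadings_y.columns[k] for k in nulls.variates}
    # pooled null size = n_perm x n significant variates
    some_var = nulls.p_values.index[0]
    assert len(nulls.null_pool[some_var]) == 100 * len(nulls.variates)
    assert np.all((nulls.p_values.to_numpy() > 0)
                  & (nulls.p_values.to_numpy() <= 1))
    # the top observed loading should be flagged
    top = model.loadings_y.iloc[:, 0].abs().idxmax()
    assert nulls.significant.loc[top].any()


def test_loading_significance_empty_when_no_signal(rng):
    y = rng.normal(size=(100, 3))
    x = rng.normal(size=(100, 3))
    model = fit_with_inference(y, x, n_perm=100, seed=7)
    if not model.significant_variates():
        nulls = loading_significance(model, n_perm=50, seed=8)
        assert nulls.p_values.empty
        assert nulls.variates == []


def test_loading_significance_forced_variates(rng):
    y = rng.normal(size=(100, 3))
    x = rng.normal(size=(100, 3))
    model = fit_with_inference(y, x, n_perm=100, seed=9)
    nulls = loading_significance(model, n_perm=60, seed=10, variates=[0])
    assert nulls.p_values.shape == (3, 1)


# ---------------------------------------------------------- match_variates

def test_match_self_identity(rng):
    y = rng.normal(size=(100, 4))
    x = rng.normal(size=(100, 3))
    m = fit_cca(y, x)
    table = match_variates(m, m)
    assert np.allclose(table["abs_corr"], 1.0, atol=1e-10)
    assert list(table["variate_a"]) == list(table["variate_b"])


def test_match_simple_vs_unique(small_cohort):
    conf = dummy_code(small_cohort.confounds)
    y = residualize(small_cohort.brain, conf)
    x = residualize(small_cohort.pa, conf)
    simple = fit_cca(y, x)
    uniq = unique_model(small_cohort.brain, small_cohort.pa,
                        PhenotypeTable(small_cohort.mh_items.data.iloc[:, :3]),
                        conf, n_perm=100, seed=11)
    table = match_variates(simple, uniq)
    first = table[table["variate_a"] == "CV1"].iloc[0]
    assert first["abs_corr"] > 0.9


def test_match_null_low_corr(rng):
    y1 = rng.normal(size=(500, 3))
    x1 = rng.normal(size=(500, 3))
    y2 = rng.normal(size=(500, 3))
    x2 = rng.normal(size=(500, 3))
    m1, m2 = fit_cca(y1, x1), fit_cca(y2, x2)
    table = match_variates(m1, m2)
    assert table["abs_corr"].max() < 0.3


def test_match_requires_shared_subjects(rng):
    m1 = fit_cca(rng.normal(size=(50, 3)), rng.normal(size=(50, 2)))
    y = pd.DataFrame(rng.normal(size=(40, 3)))
    m2 = fit_cca(y, rng.normal(size=(40, 2)))
    with pytest.raises(ValueError, match="subjects"):
        match_variates(m1, m2)
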