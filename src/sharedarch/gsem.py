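"""One-common-factor structural model on a genetic covariance matrix.

Fits ``S approx lam lam' + diag(psi)`` to the unique elements of an
estimated genetic covariance matrix by diagonally weighted least squares
(weights = inverse diagonal of the jackknife sampling covariance V), with a
sandwich-corrected residual chi-square, CFI against an independence model,
and SRMR on standardized residuals.  A joint variant adds one external
phenotype freely correlated with the factor and reports that correlation
with a sandwich standard error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ldsr import GeneticCovariance

logger = logging.getLogger(__name__)


@dataclass
class FactorModel:
    loadings: pd.Series                 # standardized
    loadings_se: pd.Series
    residual_variances: pd.Series
    chi2: float
    df: int
    p: float
    cfi: float                          # clamped to [0, 1]
    cfi_raw: float
    srmr: float
    heywood: bool = False
    factor_external: dict | None = None  # {'phenotype', 'rg', 'se', 'p'}
    meta: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        pd.DataFrame({"loading": self.loadings,
                      "se": self.loadings_se}).to_csv(
            path, sep="\t", index_label="indicator")


def _vech(mat: np.ndarray) -> np.ndarray:
    return mat[np.tril_indices_from(mat)]


def _vech_index(k: int) -> list[tuple[int, int]]:
    return list(zip(*np.tril_indices(k)))


def _subselect(gc: GeneticCovariance, names: list[str]):
    """Sub-matrix S and the matching rows/cols of V for a phenotype subset."""
    idx = [gc.labels.index(n) for n in names]
    s = gc.S.to_numpy()[np.ix_(idx, idx)]
    full_pairs = {pair: u for u, pair in enumerate(_vech_index(len(gc.labels)))}
    sel = []
    for a, b in _vech_index(len(idx)):
        i, j = idx[a], idx[b]
        key = (i, j) if i >= j else (j, i)
        sel.append(full_pairs[key])
    v = gc.V[np.ix_(sel, sel)]
    return s, v


class _OneFactor:
    """sigma_ij(theta) = lam_i lam_j + delta_ij psi_i"""

    def __init__(self, k: int):
        self.k = k
        self.pairs = _vech_index(k)
        self.n_free = 2 * k

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        lam, psi = theta[: self.k], theta[self.k:]
        full = np.outer(lam, lam) + np.diag(psi)
        return _vech(full)

    def jac(self, theta: np.ndarray) -> np.ndarray:
        lam = theta[: self.k]
        j = np.zeros((len(self.pairs), self.n_free))
        for u, (i, jj) in enumerate(self.pairs):
            j[u, i] += lam[jj]
            j[u, jj] += lam[i]
            if i == jj:
                j[u, self.k + i] = 1.0
        return j

    def starts(self, diag: np.ndarray) -> list[np.ndarray]:
        sd = np.sqrt(np.clip(diag, 1e-4, None))
        out = []
        for f in (0.3, 0.5, 0.7, 0.9, -0.5):
            lam0 = f * sd
            psi0 = np.clip((1 - f ** 2), 0.05, None) * np.clip(diag, 1e-4, None)
            out.append(np.concatenate([lam0, psi0]))
        return out

    def bounds(self):
        lo = np.concatenate([np.full(self.k, -np.inf), np.zeros(self.k)])
        hi = np.full(2 * self.k, np.inf)
        return lo, hi


class _FactorPlusExternal:
    """One factor over k indicators plus a freely correlated external trait.

    theta = [lam (k), psi (k), c (factor-external covariance), v_e].
    """

    def __init__(self, k: int):
        self.k = k
        self.pairs = _vech_index(k + 1)
        self.n_free = 2 * k + 2

    def full_sigma(self, theta: np.ndarray) -> np.ndarray:
        k = self.k
        lam, psi = theta[:k], theta[k: 2 * k]
        c, v_e = theta[2 * k], theta[2 * k + 1]
        full = np.zeros((k + 1, k + 1))
        full[:k, :k] = np.outer(lam, lam) + np.diag(psi)
        full[:k, k] = full[k, :k] = lam * c
        full[k, k] = v_e
        return full

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        return _vech(self.full_sigma(theta))

    def jac(self, theta: np.ndarray) -> np.ndarray:
        k = self.k
        lam = theta[:k]
        c = theta[2 * k]
        j = np.zeros((len(self.pairs), self.n_free))
        for u, (i, jj) in enumerate(self.pairs):
            if i < k and jj < k:
                j[u, i] += lam[jj]
                j[u, jj] += lam[i]
                if i == jj:
                    j[u, k + i] = 1.0
            elif i == k and jj < k:           # cross row (i >= jj in vech)
                j[u, jj] += c
                j[u, 2 * k] = lam[jj]
            elif i == k and jj == k:
                j[u, 2 * k + 1] = 1.0
        return j

    def starts(self, diag: np.ndarray) -> list[np.ndarray]:
        d_ind, d_ext = diag[:-1], diag[-1]
        sd = np.sqrt(np.clip(d_ind, 1e-4, None))
        out = []
        for f in (0.3, 0.5, 0.7, 0.9, -0.5):
            lam0 = f * sd
            psi0 = np.clip(1 - f ** 2, 0.05, None) * np.clip(d_ind, 1e-4, None)
            out.append(np.concatenate([lam0, psi0, [0.0],
                                       [max(d_ext, 1e-4)]]))
        return out

    def bounds(self):
        k = self.k
        lo = np.concatenate([np.full(k, -np.inf), np.zeros(k),
                             [-np.inf], [1e-8]])
        hi = np.full(2 * k + 2, np.inf)
        return lo, hi


def _dwls_fit(s_vech: np.ndarray, weights: np.ndarray, model):
    lo, hi = model.bounds()
    best = None
    trace = []

    def resid(theta):
        return np.sqrt(weights) * (s_vech - model.sigma(theta))

    def jac(theta):
        return -np.sqrt(weights)[:, None] * model.jac(theta)

    diag = s_vech[[u for u, (i, j) in enumerate(model.pairs) if i == j]]
    for x0 in model.starts(diag):
        res = optimize.least_squares(resid, np.clip(x0, lo + 1e-9, hi),
                                     jac=jac, bounds=(lo, hi),
                                     xtol=1e-14, ftol=1e-14, gtol=1e-14)
        trace.append((res.status, float(res.cost)))
        if best is None or res.cost < best.cost:
            best = res
    if best is None or best.status <= 0:
        raise RuntimeError(f"factor model did not converge; trace={trace}")
    return best.x


def _residual_chi2(d: np.ndarray, v: np.ndarray, jac: np.ndarray,
                   weights: np.ndarray, df: int):
    """Residual-based test statistic d' pinv((I-P) V (I-P)') d with rank df."""
    w = np.diag(weights)
    try:
        proj = jac @ np.linalg.solve(jac.T @ w @ jac, jac.T @ w)
    except np.linalg.LinAlgError:
        proj = jac @ np.linalg.pinv(jac.T @ w @ jac) @ jac.T @ w
    resid_op = np.eye(len(d)) - proj
    sig_d = resid_op @ v @ resid_op.T
    u = np.linalg.pinv(sig_d, rcond=1e-10, hermitian=True)
    t = float(d @ u @ d)
    p = float(stats.chi2.sf(t, df)) if df > 0 else float("nan")
    return t, p


def _srmr(s: np.ndarray, implied: np.ndarray) -> float:
    d = np.sqrt(np.clip(np.diag(s), 1e-12, None))
    std_resid = (s - implied) / np.outer(d, d)
    vals = _vech(std_resid)
    return float(np.sqrt(np.mean(vals ** 2)))


def _independence_chi2(s: np.ndarray, v: np.ndarray, weights: np.ndarray):
    k = s.shape[0]
    pairs = _vech_index(k)
    jac0 = np.zeros((len(pairs), k))
    for u, (i, j) in enumerate(pairs):
        if i == j:
            jac0[u, i] = 1.0
    implied0 = np.diag(np.diag(s))
    d0 = _vech(s) - _vech(implied0)
    df0 = len(pairs) - k
    return _residual_chi2(d0, v, jac0, weights, df0)


def _weights_from_v(v: np.ndarray) -> np.ndarray:
    dv = np.clip(np.diag(v), 1e-12, None)
    return 1.0 / dv


def fit_common_factor(gc: GeneticCovariance,
                      indicators: list[str] | None = None) -> FactorModel:
    """DWLS one-factor fit with CFI / SRMR and sandwich chi-square.

    Needs >= 3 indicators; Heywood cases (residual variance at the zero
    bound) are flagged, not hidden.  The sign convention makes the first
    indicator's loading positive.
    """
    names = indicators or gc.labels
    if len(names) < 3:
        raise ValueError("one-factor model needs >= 3 indicators")
    s, v = _subselect(gc, names)
    k = len(names)
    model = _OneFactor(k)
    weights = _weights_from_v(v)
    s_vech = _vech(s)
    theta = _dwls_fit(s_vech, weights, model)
    lam, psi = theta[:k], theta[k:]
    if lam[0] < 0:
        lam = -lam
    heywood = bool(np.any(psi < 1e-8))
    if heywood:
        logger.warning("Heywood case: residual variance bounded at 0")
    implied = np.outer(lam, lam) + np.diag(psi)
    std = lam / np.sqrt(np.clip(np.diag(implied), 1e-12, None))

    df = len(s_vech) - model.n_free
    d = s_vech - _vech(implied)
    jac = model.jac(np.concatenate([lam, psi]))
    chi2, p = _residual_chi2(d, v, jac, weights, df)
    chi2_0, _ = _independence_chi2(s, v, weights)
    df0 = len(s_vech) - k
    cfi_raw = _cfi(chi2, df, chi2_0, df0)
    srmr = _srmr(s, implied)
    se = _loading_se(jac, weights, v, k, np.diag(implied))
    return FactorModel(
        loadings=pd.Series(std, index=names),
        loadings_se=pd.Series(se, index=names),
        residual_variances=pd.Series(psi, index=names),
        chi2=chi2, df=df, p=p,
        cfi=float(np.clip(cfi_raw, 0.0, 1.0)), cfi_raw=cfi_raw,
        srmr=srmr, heywood=heywood,
        meta={"indicators": names, "estimator": "DWLS"},
    )


def _cfi(chi2: float, df: int, chi2_0: float, df0: int) -> float:
    base = chi2_0 - df0
    excess = chi2 - df
    if base <= 0:
        return 1.0
    return 1.0 - excess / base


def _sandwich_cov(jac: np.ndarray, weights: np.ndarray,
                  v: np.ndarray) -> np.ndarray:
    w = np.diag(weights)
    bread = np.linalg.pinv(jac.T @ w @ jac)
    return bread @ jac.T @ w @ v @ w @ jac @ bread


def _loading_se(jac, weights, v, k, implied_diag):
    cov = _sandwich_cov(jac, weights, v)
    raw_se = np.sqrt(np.clip(np.diag(cov)[:k], 0, None))
    return raw_se / np.sqrt(np.clip(implied_diag, 1e-12, None))


def factor_external_rg(gc: GeneticCovariance, indicators: list[str],
                       external: str) -> FactorModel:
    """Joint model: factor over the indicators + freely correlated external
    phenotype.  The factor-external genetic correlation is the estimand;
    its SE comes from the sandwich parameter covariance by the delta method.
    """
    if external not in gc.labels:
        raise ValueError(f"external phenotype {external!r} not in matrix")
    names = list(indicators) + [external]
    s, v = _subselect(gc, names)
    k = len(indicators)
    model = _FactorPlusExternal(k)
    weights = _weights_from_v(v)
    s_vech = _vech(s)
    theta = _dwls_fit(s_vech, weights, model)
    lam, psi = theta[:k], theta[k: 2 * k]
    c, v_e = theta[2 * k], theta[2 * k + 1]
    if lam[0] < 0:
        lam, c = -lam, -c
        theta = np.concatenate([lam, psi, [c], [v_e]])
    heywood = bool(np.any(psi < 1e-8))

    implied = model.full_sigma(theta)
    std = lam / np.sqrt(np.clip(np.diag(implied)[:k], 1e-12, None))
    rg_fe = c / np.sqrt(max(v_e, 1e-12))

    jac = model.jac(theta)
    cov_theta = _sandwich_cov(jac, weights, v)
    grad = np.zeros(model.n_free)
    grad[2 * k] = 1.0 / np.sqrt(max(v_e, 1e-12))
    grad[2 * k + 1] = -c / (2.0 * max(v_e, 1e-12) ** 1.5)
    var_rg = float(grad @ cov_theta @ grad)
    se_rg = float(np.sqrt(max(var_rg, 0.0)))
    p_rg = (2 * stats.norm.sf(abs(rg_fe) / se_rg) if se_rg > 0
            else (0.0 if rg_fe != 0 else 1.0))

    df = len(s_vech) - model.n_free
    d = s_vech - _vech(implied)
    chi2, p = _residual_chi2(d, v, jac, weights, df)
    chi2_0, _ = _independence_chi2(s, v, weights)
    df0 = len(s_vech) - (k + 1)
    cfi_raw = _cfi(chi2, df, chi2_0, df0)
    return FactorModel(
        loadings=pd.Series(std, index=indicators),
        loadings_se=pd.Series(np.sqrt(np.clip(np.diag(cov_theta)[:k], 0,
                                              None)), index=indicators),
        residual_variances=pd.Series(psi, index=indicators),
        chi2=chi2, df=df, p=p,
        cfi=float(np.clip(cfi_raw, 0.0, 1.0)), cfi_raw=cfi_raw,
        srmr=_srmr(s, implied), heywood=heywood,
        factor_external={"phenotype": external, "rg": float(rg_fe),
                         "se": se_rg, "p": float(p_rg)},
        meta={"indicators": list(indicators), "external": external,
              "estimator": "DWLS"},
    )
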