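"""Canonical correlation models with permutation inference.

Implements the phenotypic core: confound residualization, simple and
"unique" CCA models (the other behavioural block added to the confound
set), step-down Wilks-type permutation inference for canonical variates,
per-variable loading permutation tests with pooling across significant
variates, and cross-model variate matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import PhenotypeTable

logger = logging.getLogger(__name__)


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, PhenotypeTable):
        return data.data
    if isinstance(data, pd.DataFrame):
        return data
    arr = np.asarray(data, dtype=float)
    return pd.DataFrame(arr, columns=[f"v{i + 1}" for i in range(arr.shape[1])])


@dataclass
class CCAModel:
    weights_y: pd.DataFrame            # brain-side weights A
    weights_x: pd.DataFrame            # behaviour-side weights B
    variates_y: pd.DataFrame           # U = Yc A
    variates_x: pd.DataFrame           # V = Xc B
    correlations: np.ndarray           # r_k, descending
    loadings_y: pd.DataFrame           # corr(Y, U)
    loadings_x: pd.DataFrame           # corr(X, V)
    p_values: np.ndarray | None = None
    tag: str = "simple"
    confound_names: list[str] = field(default_factory=list)
    # residualized inputs retained for permutation refits
    Y: pd.DataFrame | None = None
    X: pd.DataFrame | None = None

    @property
    def n_components(self) -> int:
        return len(self.correlations)

    def significant_variates(self, alpha: float = 0.05) -> list[int]:
        if self.p_values is None:
            return []
        return [k for k, p in enumerate(self.p_values) if p <= alpha]


@dataclass
class LoadingNulls:
    p_values: pd.DataFrame             # brain variables x significant variates
    significant: pd.DataFrame
    null_pool: dict                    # variable -> pooled |loading| null draws
    signed_nulls: dict                 # retained for audit
    variates: list[int]
    n_perm: int


# ----------------------------------------------------------------------
# residualization
# ----------------------------------------------------------------------

def residualize(data, confounds, huh_jhun: bool = False):
    """Replace each column by its residual from least-squares projection on
    [intercept | confounds].

    With ``huh_jhun=True`` the residuals are additionally rotated onto a
    semi-orthogonal basis of the confound null space (n - rank rows), which
    keeps permutation exchangeability exact after residualization.
    """
    d = _as_frame(data)
    c = _as_frame(confounds)
    if not d.index.equals(c.index):
        raise ValueError("data and confounds must share subjects")
    design = np.column_stack([np.ones(len(c)), c.to_numpy(float)])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        logger.warning("confound matrix rank-deficient (%d < %d); dependent "
                       "columns dropped by least squares", rank,
                       design.shape[1])
    beta, _, _, _ = np.linalg.lstsq(design, d.to_numpy(float), rcond=None)
    resid = d.to_numpy(float) - design @ beta
    if huh_jhun:
        u, s, _ = np.linalg.svd(design, full_matrices=True)
        basis = u[:, rank:]                      # null space of confounds'
        resid = basis.T @ resid
        out = pd.DataFrame(resid, columns=d.columns)
    else:
        out = pd.DataFrame(resid, index=d.index, columns=d.columns)
    if isinstance(data, PhenotypeTable):
        return PhenotypeTable(out, dict(data.kinds), dict(data.meta))
    return out


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------

def _qr_block(x: np.ndarray):
    xc = x - x.mean(axis=0)
    q, r = np.linalg.qr(xc)
    diag = np.abs(np.diag(r))
    if diag.min() < 1e-10 * max(diag.max(), 1.0):
        raise np.linalg.LinAlgError(
            "within-block singularity: reduce the rank of the block")
    return q, r, xc


def fit_cca(Y, X, tag: str = "simple",
            confound_names: list[str] | None = None) -> CCAModel:
    """Canonical weights, variates and correlations via whitened SVD.

    Requires n > p + q.  Variates are scaled to unit sample variance; sign
    convention makes each canonical correlation non-negative with the
    leading brain loading positive.
    """
    yf, xf = _as_frame(Y), _as_frame(X)
    n, p = yf.shape
    q = xf.shape[1]
    if n <= p + q:
        raise ValueError(f"need n > p + q (got n={n}, p={p}, q={q})")
    qy, ry, yc = _qr_block(yf.to_numpy(float))
    qx, rx, xc = _qr_block(xf.to_numpy(float))
    uu, sv, vvt = np.linalg.svd(qy.T @ qx)
    k = min(p, q)
    sv = np.clip(sv[:k], 0.0, 1.0)
    scale = np.sqrt(n - 1)
    a = np.linalg.solve(ry, uu[:, :k]) * scale
    b = np.linalg.solve(rx, vvt.T[:, :k]) * scale
    u = yc @ a
    v = xc @ b

    # sign convention: largest-|loading| brain variable positive per variate
    load_y = _corr_columns(yc, u)
    flip = np.sign(load_y[np.abs(load_y).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    a, b, u, v = a * flip, b * flip, u * flip, v * flip
    load_y = load_y * flip
    load_x = _corr_columns(xc, v)

    names = [f"CV{i + 1}" for i in range(k)]
    return CCAModel(
        weights_y=pd.DataFrame(a, index=yf.columns, columns=names),
        weights_x=pd.DataFrame(b, index=xf.columns, columns=names),
        variates_y=pd.DataFrame(u, index=yf.index, columns=names),
        variates_x=pd.DataFrame(v, index=xf.index, columns=names),
        correlations=sv,
        loadings_y=pd.DataFrame(load_y, index=yf.columns, columns=names),
        loadings_x=pd.DataFrame(load_x, index=xf.columns, columns=names),
        tag=tag,
        confound_names=confound_names or [],
        Y=yf, X=xf,
    )


def _corr_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    num = ac.T @ bc
    den = np.outer(np.sqrt((ac ** 2).sum(axis=0)),
                   np.sqrt((bc ** 2).sum(axis=0)))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, 0.0)


# ----------------------------------------------------------------------
# permutation inference for canonical variates
# ----------------------------------------------------------------------

def _residual_on(data: np.ndarray, basis: np.ndarray) -> np.ndarray:
    if basis.shape[1] == 0:
        return data
    design = np.column_stack([np.ones(len(basis)), basis])
    beta, *_ = np.linalg.lstsq(design, data, rcond=None)
    return data - design @ beta


def _orthonormal_basis(mat: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the centered column space, rank-truncated (the
    deflated blocks are rank-deficient by construction)."""
    mc = mat - mat.mean(axis=0)
    u, s, _ = np.linalg.svd(mc, full_matrices=False)
    keep = s > max(s[0], 1e-300) * 1e-9
    return u[:, keep]


def _wilks_stat(qy: np.ndarray, qx: np.ndarray, perm=None) -> float:
    cross = (qy[perm].T if perm is not None else qy.T) @ qx
    sv = np.clip(np.linalg.svd(cross, compute_uv=False), 0.0, 1.0 - 1e-12)
    return float(-np.sum(np.log1p(-sv ** 2)))


def permute_inference(Y, X, n_perm: int = 1000, seed: int = 0,
                      model: CCAModel | None = None) -> np.ndarray:
    """Step-down permutation p-values for the canonical variates.

    For variate k the statistic is a Wilks-type product over variates k..K
    computed after removing the preceding k-1 estimated variates from both
    sides (closure principle); rows of the X block are permuted relative to
    Y.  P-values use the add-one rule and are made monotone non-decreasing
    by a cumulative maximum.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d gives a p-value resolution floor of %.3f",
                       n_perm, 1.0 / (n_perm + 1))
    yf, xf = _as_frame(Y), _as_frame(X)
    if model is None:
        model = fit_cca(yf, xf)
    y = yf.to_numpy(float)
    x = xf.to_numpy(float)
    u = model.variates_y.to_numpy()
    v = model.variates_x.to_numpy()
    n_comp = model.n_components
    rng = np.random.default_rng(seed)
    n = len(y)

    # deflated orthonormal bases per step (permutation only touches X rows,
    # and a row permutation of an orthonormal basis stays orthonormal)
    qys, qxs = [], []
    for k in range(n_comp):
        yk = _residual_on(y, u[:, :k])
        xk = _residual_on(x, v[:, :k])
        qys.append(_orthonormal_basis(yk))
        qxs.append(_orthonormal_basis(xk))

    observed = np.array([_wilks_stat(qys[k], qxs[k]) for k in range(n_comp)])
    exceed = np.zeros(n_comp)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        for k in range(n_comp):
            if _wilks_stat(qys[k], qxs[k][perm]) >= observed[k]:
                exceed[k] += 1
    pvals = (exceed + 1.0) / (n_perm + 1.0)
    return np.maximum.accumulate(pvals)


def fit_with_inference(Y, X, n_perm: int = 1000, seed: int = 0,
                       tag: str = "simple",
                       confound_names: list[str] | None = None) -> CCAModel:
    model = fit_cca(Y, X, tag=tag, confound_names=confound_names)
    model.p_values = permute_inference(Y, X, n_perm=n_perm, seed=seed,
                                       model=model)
    return model


# ----------------------------------------------------------------------
# unique model
# ----------------------------------------------------------------------

def unique_model(Y, X_target, X_other, confounds=None, n_perm: int = 1000,
                 seed: int = 0, tag: str = "unique",
                 partial: str = "both") -> CCAModel:
    """CCA with the other behavioural block appended to the confound set.

    ``partial='both'`` residualizes both the brain block and the target
    behavioural block on the expanded set; ``partial='brain-only'``
    residualizes only the brain block on the other behavioural set.
    """
    yf = _as_frame(Y)
    xt = _as_frame(X_target)
    xo = _as_frame(X_other)
    conf = _as_frame(confounds) if confounds is not None else pd.DataFrame(
        index=yf.index)
    if xo.shape[1] == 0 and conf.shape[1] == 0:
        return fit_with_inference(yf, xt, n_perm=n_perm, seed=seed, tag=tag)
    expanded = pd.concat([conf, xo], axis=1)
    if expanded.shape[1] > len(yf) / 10:
        logger.warning("expanded confound set has %d columns for %d subjects",
                       expanded.shape[1], len(yf))
    y_res = residualize(yf, expanded)
    if partial == "both":
        x_res = residualize(xt, expanded)
    elif partial == "brain-only":
        x_res = residualize(xt, conf) if conf.shape[1] else xt
    else:
        raise ValueError(f"unknown partial mode {partial!r}")
    names = list(expanded.columns)
    return fit_with_inference(y_res, x_res, n_perm=n_perm, seed=seed, tag=tag,
                              confound_names=names)


# ----------------------------------------------------------------------
# loading significance
# ----------------------------------------------------------------------

def loading_significance(model: CCAModel, n_perm: int = 1000, seed: int = 0,
                         alpha: float = 0.05,
                         variates: list[int] | None = None) -> LoadingNulls:
    """Permutation test of each brain variable's canonical loading.

    Per permutation the CCA is refit on row-shuffled X and each brain
    variable's |loading| on every significant variate is recorded; the
    per-variable null pools these across significant variates (the
    cross-variate correction).  Two-sided on magnitude, add-one rule.
    """
    if model.Y is None or model.X is None:
        raise ValueError("model must retain its residualized inputs")
    kept = variates if variates is not None else model.significant_variates(alpha)
    var_names = list(model.loadings_y.index)
    if not kept:
        logger.info("no significant variates; empty loading test")
        empty = pd.DataFrame(index=var_names)
        return LoadingNulls(empty, empty.astype(bool), {}, {}, [], n_perm)

    y = model.Y.to_numpy(float)
    x = model.X.to_numpy(float)
    rng = np.random.default_rng(seed)
    n = len(y)
    pools = {name: [] for name in var_names}
    signed = {name: [] for name in var_names}
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pm = fit_cca(y, x[perm])
        lo = pm.loadings_y.to_numpy()[:, kept]
        for i, name in enumerate(var_names):
            pools[name].extend(np.abs(lo[i]))
            signed[name].extend(lo[i])

    obs = model.loadings_y.to_numpy()
    cols = [model.loadings_y.columns[k] for k in kept]
    pv = np.empty((len(var_names), len(kept)))
    for i, name in enumerate(var_names):
        pool = np.asarray(pools[name])
        for j, k in enumerate(kept):
            pv[i, j] = (np.sum(pool >= abs(obs[i, k])) + 1.0) / (pool.size + 1.0)
    p_df = pd.DataFrame(pv, index=var_names, columns=cols)
    return LoadingNulls(
        p_values=p_df,
        significant=p_df <= alpha,
        null_pool={k: np.asarray(v) for k, v in pools.items()},
        signed_nulls={k: np.asarray(v) for k, v in signed.items()},
        variates=list(kept),
        n_perm=n_perm,
    )


# ----------------------------------------------------------------------
# variate matching across models
# ----------------------------------------------------------------------

def match_variates(model_a: CCAModel, model_b: CCAModel) -> pd.DataFrame:
    """Greedy matching of brain-side canonical variates across two models.

    Returns one row per matched pair with the absolute correlation and the
    sign alignment; ties in |corr| are broken by variate index.
    """
    ua, ub = model_a.variates_y, model_b.variates_y
    if not ua.index.equals(ub.index):
        raise ValueError("models must share subjects")
    corr = _corr_columns(ua.to_numpy(), ub.to_numpy())
    ac = np.abs(corr.copy())
    rows = []
    for _ in range(min(ac.shape)):
        i, j = np.unravel_index(np.argmax(ac), ac.shape)
        rows.append({
            "variate_a": ua.columns[i], "variate_b": ub.columns[j],
            "abs_corr": float(abs(corr[i, j])),
            "sign": int(np.sign(corr[i, j])) or 1,
        })
        ac[i, :] = -1.0
        ac[:, j] = -1.0
    return pd.DataFrame(rows)
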