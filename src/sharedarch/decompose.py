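"""Questionnaire PCA with cumulative-variance retention, per-subject
standardization of activity summaries, and FDR-corrected block correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables import PhenotypeTable

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    loadings: pd.DataFrame          # variables x components, orthonormal cols
    scores: pd.DataFrame            # subjects x components
    explained_variance: np.ndarray  # fractions, descending
    n_retained: int
    standardized: bool = True

    @property
    def component_names(self) -> list[str]:
        return list(self.loadings.columns)

    def retained_scores(self) -> pd.DataFrame:
        return self.scores.iloc[:, : self.n_retained]


@dataclass
class CorrelationGrid:
    r: pd.DataFrame
    p: pd.DataFrame
    p_adjusted: pd.DataFrame
    significant: pd.DataFrame
    q: float
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        marked = self.r.round(3).astype(str)
        marked = marked.mask(self.significant, marked + "*")
        marked.to_csv(path, sep="\t")


def standardize_pa(means: PhenotypeTable, sds: PhenotypeTable) -> PhenotypeTable:
    """Divide each activity summary by its subject-level SD across recording
    days.  Zero-SD entries become missing (count logged)."""
    if not means.aligned(sds):
        raise ValueError("means and SD tables must share subjects")
    sd = sds.data[means.variables].to_numpy(float)
    zero = sd == 0
    if zero.any():
        logger.info("standardize_pa: %d zero-SD entries set to missing",
                    int(zero.sum()))
    out = means.data.to_numpy(float) / np.where(zero, np.nan, sd)
    df = pd.DataFrame(out, index=means.data.index, columns=means.variables)
    return PhenotypeTable(df, dict(means.kinds), dict(means.meta))


def fit_pca(items: PhenotypeTable, standardize: bool = True) -> PCAResult:
    """PCA of a complete item table (z-scored columns by default).

    Sign convention: each loading column's largest-magnitude entry is made
    positive, so results are reproducible across runs.
    """
    x = items.values()
    if np.isnan(x).any():
        raise ValueError("PCA requires a complete (imputed) table")
    n, p = x.shape
    if p > n:
        raise ValueError("more variables than subjects")
    x = x - x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance item")
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    ev = s ** 2 / (n - 1)
    frac = ev / ev.sum()
    loadings = vt.T
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0),
                            np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = x @ loadings
    names = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=items.variables, columns=names),
        scores=pd.DataFrame(scores, index=items.data.index, columns=names),
        explained_variance=frac,
        n_retained=len(names),
        standardized=standardize,
    )


def retain_components(res: PCAResult, cum_var: float = 0.50) -> PCAResult:
    """Keep the smallest leading component set whose cumulative explained
    variance strictly exceeds ``cum_var`` (at least one component)."""
    cum = np.cumsum(res.explained_variance)
    n_keep = int(np.searchsorted(cum, cum_var, side="right")) + 1
    n_keep = min(max(n_keep, 1), len(res.explained_variance))
    return PCAResult(res.loadings, res.scores, res.explained_variance,
                     n_retained=n_keep, standardized=res.standardized)


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN-safe)."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    flat = p.ravel()
    ok = ~np.isnan(flat)
    pv = flat[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    filled = np.full(flat.shape, np.nan)
    filled[ok] = res
    return filled.reshape(p.shape)


def correlate_blocks(scores: PCAResult | pd.DataFrame, pa: PhenotypeTable,
                     q: float = 0.05) -> CorrelationGrid:
    """Pearson r + two-sided p per (component, activity measure) pair with
    one Benjamini-Hochberg family across the full grid.

    Zero-variance columns yield undefined pairs that are excluded from the
    FDR family (logged).
    """
    left = (scores.retained_scores() if isinstance(scores, PCAResult)
            else scores)
    right = pa.data
    if not left.index.equals(right.index):
        raise ValueError("blocks must share subjects")
    n = len(left)
    lx = left.to_numpy(float)
    rx = right.to_numpy(float)
    r = np.full((rx.shape[1], lx.shape[1]), np.nan)
    p = np.full_like(r, np.nan)
    excluded = []
    for j in range(rx.shape[1]):
        yj = rx[:, j]
        obs = ~np.isnan(yj)
        for i in range(lx.shape[1]):
            xi = lx[obs, i]
            yo = yj[obs]
            if xi.std() == 0 or yo.std() == 0 or obs.sum() < 3:
                excluded.append((right.columns[j], left.columns[i]))
                continue
            rr, pp = stats.pearsonr(xi, yo)
            r[j, i], p[j, i] = rr, pp
    if excluded:
        logger.info("correlate_blocks: %d undefined pairs excluded from the "
                    "FDR family", len(excluded))
    adj = bh_fdr(p)
    rows, cols = list(right.columns), list(left.columns)
    r_df = pd.DataFrame(r, index=rows, columns=cols)
    p_df = pd.DataFrame(p, index=rows, columns=cols)
    adj_df = pd.DataFrame(adj, index=rows, columns=cols)
    sig = (adj_df <= q).fillna(False)
    return CorrelationGrid(r_df, p_df, adj_df, sig, q, excluded)
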