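"""LD score regression: SNP heritability, cross-trait genetic correlation
with block-jackknife standard errors, and the multi-phenotype genetic
covariance matrix (with joint jackknife sampling covariance) that feeds the
factor models.

Regression scheme: chi-square (or Z-product) statistics are regressed on
``N l_j / M`` (or ``sqrt(N1 N2) l_j / M``) with a free intercept.  Weights
are the inverse squared expected outcome evaluated at a first-pass
unweighted fit, with one reweighting pass.  Standard errors come from a
delete-one block jackknife over contiguous SNP blocks; all jackknife
quantities are computed from per-block sufficient statistics so the
resampling is O(blocks), not O(blocks x SNPs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .decompose import bh_fdr

logger = logging.getLogger(__name__)

MIN_SNPS = 200


# ----------------------------------------------------------------------
# merging and allele alignment
# ----------------------------------------------------------------------

def align_sumstats(ss1: pd.DataFrame, ss2: pd.DataFrame) -> pd.DataFrame:
    """Merge two sumstats on SNP id with allele consistency.

    Z of the second trait is negated where A1/A2 are swapped; SNPs whose
    allele pairs do not match either orientation are dropped.
    """
    m = ss1.merge(ss2, on="SNP", suffixes=("_1", "_2"))
    same = (m["A1_1"] == m["A1_2"]) & (m["A2_1"] == m["A2_2"])
    flipped = (m["A1_1"] == m["A2_2"]) & (m["A2_1"] == m["A1_2"])
    keep = same | flipped
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropped %d SNPs with inconsistent alleles", n_drop)
    m = m[keep].copy()
    m.loc[flipped[keep], "Z_2"] = -m.loc[flipped[keep], "Z_2"]
    return m


def _merge_ld(ss: pd.DataFrame, ld: pd.DataFrame) -> pd.DataFrame:
    merged = ss.merge(ld[["SNP", "L2"]], on="SNP")
    if len(merged) < MIN_SNPS:
        raise ValueError(f"only {len(merged)} SNPs after merging (< {MIN_SNPS})")
    return merged


def _m_total(ld: pd.DataFrame) -> int:
    return int(ld.attrs.get("m_total", len(ld)))


# ----------------------------------------------------------------------
# weighted two-parameter regression with block sufficient statistics
# ----------------------------------------------------------------------

def _block_ids(n: int, n_blocks: int) -> np.ndarray:
    return np.minimum((np.arange(n) * n_blocks) // n, n_blocks - 1)


@dataclass
class _BlockWLS:
    """Per-block sufficient statistics of a weighted simple regression."""

    a_blocks: np.ndarray   # (B, 3): sum w, sum w x, sum w x^2
    b_blocks: np.ndarray   # (B, 2): sum w y, sum w x y

    @classmethod
    def build(cls, x, y, w, blocks, n_blocks):
        a = np.zeros((n_blocks, 3))
        b = np.zeros((n_blocks, 2))
        np.add.at(a, blocks, np.column_stack([w, w * x, w * x ** 2]))
        np.add.at(b, blocks, np.column_stack([w * y, w * x * y]))
        return cls(a, b)

    @staticmethod
    def _solve(a_sum, b_sum):
        mat = np.array([[a_sum[0], a_sum[1]], [a_sum[1], a_sum[2]]])
        return np.linalg.solve(mat, b_sum)  # [intercept, slope]

    def full(self) -> np.ndarray:
        return self._solve(self.a_blocks.sum(0), self.b_blocks.sum(0))

    def delete_one(self) -> np.ndarray:
        """(B, 2) array of [intercept, slope] with each block deleted."""
        a_tot = self.a_blocks.sum(0)
        b_tot = self.b_blocks.sum(0)
        out = np.empty((len(self.a_blocks), 2))
        for i in range(len(self.a_blocks)):
            out[i] = self._solve(a_tot - self.a_blocks[i],
                                 b_tot - self.b_blocks[i])
        return out


def jackknife_se(values: np.ndarray) -> float:
    """Delete-one-block jackknife standard error."""
    v = np.asarray(values, float)
    b = len(v)
    return float(np.sqrt((b - 1) / b * np.sum((v - v.mean()) ** 2)))


def jackknife_cov(values: np.ndarray) -> np.ndarray:
    v = np.asarray(values, float)
    b = len(v)
    c = v - v.mean(axis=0)
    return (b - 1) / b * (c.T @ c)


# ----------------------------------------------------------------------
# results
# ----------------------------------------------------------------------

@dataclass
class H2Result:
    h2: float
    h2_se: float
    intercept: float
    intercept_se: float
    n_snps: int
    negative: bool = False


@dataclass
class RgResult:
    rg: float
    se: float
    p: float
    rho_g: float
    cross_intercept: float
    cross_intercept_se: float
    h2_1: float
    h2_2: float
    n_snps: int


@dataclass
class GeneticCovariance:
    """Genetic covariance matrix S plus jackknife sampling covariance V of
    its unique (lower-triangle, row-major, diagonal included) elements."""

    S: pd.DataFrame
    V: np.ndarray
    labels: list[str]
    pair_results: dict[tuple[str, str], RgResult] = field(default_factory=dict)

    def unique_elements(self) -> np.ndarray:
        s = self.S.to_numpy()
        return s[np.tril_indices_from(s)]

    def rg_matrix(self) -> pd.DataFrame:
        s = self.S.to_numpy()
        d = np.sqrt(np.diag(s))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = s / np.outer(d, d)
        np.fill_diagonal(r, 1.0)
        return pd.DataFrame(r, index=self.labels, columns=self.labels)


# ----------------------------------------------------------------------
# estimators
# ----------------------------------------------------------------------

def _h2_design(merged: pd.DataFrame, m_total: int):
    x = merged["N"].to_numpy(float) * merged["L2"].to_numpy(float) / m_total
    y = merged["Z"].to_numpy(float) ** 2
    return x, y


def _reweight(x: np.ndarray, y: np.ndarray):
    """One reweighting pass: w = 1 / max(predicted outcome, 0.1)^2 from an
    unweighted first pass."""
    ones = np.ones_like(x)
    a = _BlockWLS.build(x, y, ones, np.zeros(len(x), int), 1)
    icpt, slope = a.full()
    pred = np.maximum(icpt + slope * x, 0.1)
    return 1.0 / pred ** 2, pred


def estimate_h2(ss: pd.DataFrame, ld: pd.DataFrame,
                n_blocks: int = 200,
                max_chisq: float | None = None) -> H2Result:
    """SNP heritability: weighted regression of chi^2 on N l / M.

    Negative slopes are returned as-is with ``negative=True``.
    ``max_chisq`` optionally drops outlier SNPs (off by default; synthetic
    data has no confounded outliers).
    """
    merged = _merge_ld(ss, ld)
    if max_chisq is not None:
        merged = merged[merged["Z"] ** 2 <= max_chisq]
    m_total = _m_total(ld)
    x, y = _h2_design(merged, m_total)
    w, _ = _reweight(x, y)
    blocks = _block_ids(len(x), n_blocks)
    wls = _BlockWLS.build(x, y, w, blocks, n_blocks)
    icpt, slope = wls.full()
    dele = wls.delete_one()
    h2_se = jackknife_se(dele[:, 1])
    icpt_se = jackknife_se(dele[:, 0])
    neg = slope < 0
    if neg:
        logger.warning("negative heritability estimate %.4g", slope)
    return H2Result(float(slope), h2_se, float(icpt), icpt_se, len(merged), neg)


def _pair_blocks(ss1: pd.DataFrame, ss2: pd.DataFrame, ld: pd.DataFrame,
                 n_blocks: int, max_chisq: float | None = None):
    """Shared-SNP sufficient statistics for (h2_1, h2_2, rho_g) regressions.

    The cross regression is weighted by the product of the two traits'
    first-pass expected chi-squares, so a trait regressed on itself yields
    identical weights/regressions in all three fits and hence rg exactly 1.
    """
    merged = align_sumstats(ss1, ss2)
    merged = merged.merge(ld[["SNP", "L2"]], on="SNP")
    if max_chisq is not None:
        merged = merged[(merged["Z_1"] ** 2 <= max_chisq)
                        & (merged["Z_2"] ** 2 <= max_chisq)]
    if len(merged) < MIN_SNPS:
        raise ValueError(f"only {len(merged)} SNPs after merging (< {MIN_SNPS})")
    m_total = _m_total(ld)
    l2 = merged["L2"].to_numpy(float)
    n1 = merged["N_1"].to_numpy(float)
    n2 = merged["N_2"].to_numpy(float)
    z1 = merged["Z_1"].to_numpy(float)
    z2 = merged["Z_2"].to_numpy(float)

    x1 = n1 * l2 / m_total
    x2 = n2 * l2 / m_total
    xc = np.sqrt(n1 * n2) * l2 / m_total
    w1, pred1 = _reweight(x1, z1 ** 2)
    w2, pred2 = _reweight(x2, z2 ** 2)
    wc = 1.0 / (np.maximum(pred1, 0.1) * np.maximum(pred2, 0.1))

    blocks = _block_ids(len(merged), n_blocks)
    fits = {
        "h2_1": _BlockWLS.build(x1, z1 ** 2, w1, blocks, n_blocks),
        "h2_2": _BlockWLS.build(x2, z2 ** 2, w2, blocks, n_blocks),
        "cov": _BlockWLS.build(xc, z1 * z2, wc, blocks, n_blocks),
    }
    return merged, fits


def estimate_rg(ss1: pd.DataFrame, ss2: pd.DataFrame, ld: pd.DataFrame,
                n_blocks: int = 200,
                max_chisq: float | None = None) -> RgResult:
    """Genetic correlation with jackknife SE on the normalized ratio.

    rg = rho_g / sqrt(h2_1 h2_2); fails explicitly when either
    heritability estimate is non-positive.
    """
    merged, fits = _pair_blocks(ss1, ss2, ld, n_blocks, max_chisq)
    return _rg_from_fits(merged, fits)


def _rg_from_fits(merged: pd.DataFrame, fits: dict) -> RgResult:
    i1, h21 = fits["h2_1"].full()
    i2, h22 = fits["h2_2"].full()
    ic, cov = fits["cov"].full()
    if h21 <= 0 or h22 <= 0:
        raise ValueError("rg undefined: non-positive heritability estimate "
                         f"(h2_1={h21:.4g}, h2_2={h22:.4g})")
    rg = cov / np.sqrt(h21 * h22)

    d1 = fits["h2_1"].delete_one()
    d2 = fits["h2_2"].delete_one()
    dc = fits["cov"].delete_one()
    denom = np.sqrt(np.maximum(d1[:, 1] * d2[:, 1], 1e-12))
    rg_blocks = dc[:, 1] / denom
    se = jackknife_se(rg_blocks)
    ic_se = jackknife_se(dc[:, 0])
    if se == 0:
        p = 0.0 if rg != 0 else 1.0
    else:
        p = 2 * stats.norm.sf(abs(rg) / se)
    return RgResult(float(rg), se, float(p), float(cov), float(ic), ic_se,
                    float(h21), float(h22), len(merged))


def build_genetic_covariance(ss_list: list[pd.DataFrame], ld: pd.DataFrame,
                             labels: list[str] | None = None,
                             n_blocks: int = 200) -> GeneticCovariance:
    """Assemble S (h2 diagonal, genetic covariances off-diagonal) and the
    joint delete-one-block sampling covariance V of its unique elements."""
    p = len(ss_list)
    if p < 2:
        raise ValueError("need at least 2 phenotypes")
    labels = labels or [ss.attrs.get("label", f"trait{i + 1}")
                        for i, ss in enumerate(ss_list)]
    s = np.full((p, p), np.nan)
    tril = list(zip(*np.tril_indices(p)))
    dele_cols = {}
    pair_results: dict[tuple[str, str], RgResult] = {}

    for i, j in tril:
        if i == j:
            merged = _merge_ld(ss_list[i], ld)
            x, y = _h2_design(merged, _m_total(ld))
            w, _ = _reweight(x, y)
            blocks = _block_ids(len(x), n_blocks)
            wls = _BlockWLS.build(x, y, w, blocks, n_blocks)
            s[i, i] = wls.full()[1]
            dele_cols[(i, i)] = wls.delete_one()[:, 1]
            if s[i, i] < 0:
                logger.warning("negative h2 for %s (flagged, not clamped)",
                               labels[i])
        else:
            try:
                merged, fits = _pair_blocks(ss_list[i], ss_list[j], ld,
                                            n_blocks)
                res = _rg_from_fits(merged, fits)
            except ValueError as err:
                logger.warning("pair (%s, %s) failed: %s", labels[i],
                               labels[j], err)
                dele_cols[(i, j)] = np.zeros(n_blocks)
                continue
            s[i, j] = s[j, i] = res.rho_g
            pair_results[(labels[i], labels[j])] = res
            dele_cols[(i, j)] = fits["cov"].delete_one()[:, 1]

    dele = np.column_stack([dele_cols[(i, j)] for i, j in tril])
    v = jackknife_cov(dele)
    s_df = pd.DataFrame(s, index=labels, columns=labels)
    return GeneticCovariance(s_df, v, labels, pair_results)


def fdr_correct_pairs(results: dict, q: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg within an explicitly declared family of pairwise
    tests.  ``results`` maps pair labels to objects with .rg/.se/.p."""
    keys = list(results)
    p_raw = np.array([results[k].p for k in keys])
    adj = bh_fdr(p_raw)
    return pd.DataFrame({
        "pair": ["/".join(map(str, k)) if isinstance(k, tuple) else str(k)
                 for k in keys],
        "rg": [results[k].rg for k in keys],
        "se": [results[k].se for k in keys],
        "p": p_raw,
        "p_fdr": adj,
        "significant": adj <= q,
    })
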