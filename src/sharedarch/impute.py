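"""Missing-data handling: sparse-variable exclusion, chained predictive mean
matching, multinomial imputation of multi-level categoricals, dummy coding.

The PMM scheme follows the classical chained-equations recipe: per
iteration and per incomplete variable, a linear model of that variable on
all others (current completed versions) is fit on the observed rows,
coefficients are drawn from their approximate posterior (normal around the
estimate with a scaled-inverse-chi-squared residual variance draw), and
each missing row copies the observed value of one of the k donors whose
predictions are closest.  The final imputed value for a cell is the mean of
its per-iteration draws, so averaged ordinal items may be non-integer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import PhenotypeTable

logger = logging.getLogger(__name__)


@dataclass
class ImputationSpec:
    n_iterations: int = 20
    n_donors: int = 5
    seed: int = 0
    draw_coefficients: bool = True    # disable for the deterministic oracle mode

    def __post_init__(self) -> None:
        if self.n_donors < 1:
            raise ValueError("need at least one donor")
        if self.n_iterations < 1:
            raise ValueError("need at least one iteration")


def exclude_sparse_variables(
        table: PhenotypeTable, max_missing: float = 0.30,
) -> tuple[PhenotypeTable, list[tuple[str, float]]]:
    """Drop variables whose missing fraction strictly exceeds ``max_missing``.

    Returns the reduced table and a list of (name, missing fraction) for the
    dropped variables.  A variable at exactly the threshold is retained.
    """
    if table.data.empty:
        raise ValueError("empty table")
    frac = table.missing_fraction()
    dropped = [(name, float(f)) for name, f in frac.items() if f > max_missing]
    keep = [c for c in table.variables if frac[c] <= max_missing]
    if not keep:
        raise ValueError("all variables exceed the missingness threshold")
    if dropped:
        logger.info("excluded %d sparse variables: %s", len(dropped),
                    [d[0] for d in dropped])
    return table.subset(keep), dropped


def _design(df: pd.DataFrame, exclude: str) -> np.ndarray:
    cols = [c for c in df.columns if c != exclude]
    x = df[cols].to_numpy(float)
    return np.column_stack([np.ones(len(df)), x])


def _posterior_draw(x: np.ndarray, y: np.ndarray, rng: np.random.Generator,
                    draw: bool) -> tuple[np.ndarray, np.ndarray]:
    """OLS fit plus one posterior coefficient draw.

    Returns (beta_hat, beta_star).  Rank-deficient designs are handled by the
    minimum-norm least-squares solution (equivalent to dropping collinear
    predictors), with a logged warning.
    """
    n, p = x.shape
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < p:
        logger.warning("rank-deficient predictor matrix (rank %d < %d); "
                       "collinear predictors effectively dropped", rank, p)
    if not draw:
        return beta, beta
    resid = y - x @ beta
    df_resid = max(n - rank, 1)
    sigma2 = (resid @ resid) / max(rng.chisquare(df_resid), 1e-12)
    xtx = x.T @ x + 1e-10 * np.eye(p)
    try:
        chol = np.linalg.cholesky(np.linalg.inv(xtx))
    except np.linalg.LinAlgError:
        chol = np.zeros((p, p))
    beta_star = beta + np.sqrt(sigma2) * (chol @ rng.standard_normal(p))
    return beta, beta_star


def _pmm_draw(pred_obs: np.ndarray, pred_mis: np.ndarray, y_obs: np.ndarray,
              k: int, rng: np.random.Generator) -> np.ndarray:
    """For each missing prediction pick one of the k nearest observed donors."""
    out = np.empty(len(pred_mis))
    kk = min(k, len(y_obs))
    for i, pm in enumerate(pred_mis):
        dist = np.abs(pred_obs - pm)
        donors = np.argpartition(dist, kk - 1)[:kk]
        if kk == 1:
            choice = donors[np.argmin(dist[donors])]
        else:
            choice = rng.choice(donors)
        out[i] = y_obs[choice]
    return out


def _initial_fill(df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    filled = df.copy()
    for col in df.columns:
        mask = df[col].isna()
        if mask.any():
            obs = df.loc[~mask, col].to_numpy()
            filled.loc[mask, col] = rng.choice(obs, size=int(mask.sum()))
    return filled


def pmm_impute(table: PhenotypeTable, spec: ImputationSpec) -> PhenotypeTable:
    """Chained predictive-mean-matching imputation, averaged over iterations.

    Visit order is ascending missingness; observed entries are never
    altered.  Every single-iteration draw is an observed value of the
    variable, so the averaged cell lies within the observed min-max range.
    """
    rng = np.random.default_rng(spec.seed)
    df = table.data
    frac = df.isna().mean()
    incomplete = [c for c in df.columns
                  if 0 < frac[c] and table.kinds.get(c) != "categorical"]
    incomplete.sort(key=lambda c: (frac[c], c))
    if not incomplete:
        return table.copy()
    for col in incomplete:
        if (df[col].notna().sum()) < spec.n_donors:
            raise ValueError(f"variable {col!r} has fewer complete rows than "
                             f"the donor count {spec.n_donors}")

    current = _initial_fill(df, rng)
    sums = {c: np.zeros(int(df[c].isna().sum())) for c in incomplete}
    masks = {c: df[c].isna().to_numpy() for c in incomplete}

    for _ in range(spec.n_iterations):
        for col in incomplete:
            mask = masks[col]
            x = _design(current, exclude=col)
            y_obs = df.loc[~mask, col].to_numpy(float)
            beta_hat, beta_star = _posterior_draw(
                x[~mask], y_obs, rng, spec.draw_coefficients)
            pred_obs = x[~mask] @ beta_hat
            pred_mis = x[mask] @ beta_star
            draw = _pmm_draw(pred_obs, pred_mis, y_obs, spec.n_donors, rng)
            current.loc[mask, col] = draw
            sums[col] += draw

    out = df.copy()
    for col in incomplete:
        out.loc[masks[col], col] = sums[col] / spec.n_iterations
    return PhenotypeTable(out, dict(table.kinds), dict(table.meta))


def categorical_impute(table: PhenotypeTable, spec: ImputationSpec) -> PhenotypeTable:
    """Multinomial-logistic imputation of categorical variables.

    Per iteration the imputed level is drawn from the predicted class
    probabilities; the final value is the level with the highest count
    across iterations (ties resolved by fixed level order and logged).
    Continuous predictors must already be complete.
    """
    from sklearn.linear_model import LogisticRegression

    rng = np.random.default_rng(spec.seed + 1)
    df = table.data
    cats = [c for c in df.columns
            if table.kinds.get(c) == "categorical" and df[c].isna().any()]
    if not cats:
        return table.copy()

    current = _initial_fill(df, rng)
    counts: dict[str, dict] = {}
    for col in cats:
        mask = df[col].isna().to_numpy()
        levels = np.sort(df.loc[~mask, col].dropna().unique())
        if len(levels) == 0:
            raise ValueError(f"categorical {col!r} has no observed levels")
        counts[col] = {"mask": mask, "levels": levels,
                       "tally": np.zeros((int(mask.sum()), len(levels)))}

    for it in range(spec.n_iterations):
        for col in cats:
            info = counts[col]
            mask, levels = info["mask"], info["levels"]
            if len(levels) == 1:
                info["tally"][:, 0] += 1
                current.loc[mask, col] = levels[0]
                continue
            x = _design(current, exclude=col)[:, 1:]   # sklearn adds intercept
            sd = x.std(axis=0)
            x = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
            y = df.loc[~mask, col].to_numpy()
            clf = LogisticRegression(max_iter=1000, tol=1e-3,
                                     random_state=spec.seed + it)
            clf.fit(x[~mask], y)
            proba_all = clf.predict_proba(x[mask])
            # a level absent from training rows keeps zero probability
            proba = np.zeros((int(mask.sum()), len(levels)))
            for j, lev in enumerate(clf.classes_):
                proba[:, np.searchsorted(levels, lev)] = proba_all[:, j]
            if set(levels) - set(clf.classes_):
                logger.warning("levels %s of %r absent from training rows",
                               sorted(set(levels) - set(clf.classes_)), col)
            proba /= proba.sum(axis=1, keepdims=True)
            cum = np.cumsum(proba, axis=1)
            u = rng.uniform(size=len(proba))
            drawn = np.array([levels[np.searchsorted(cum[i], u[i])]
                              for i in range(len(proba))])
            info["tally"][np.arange(len(drawn)),
                          np.searchsorted(levels, drawn)] += 1
            current.loc[mask, col] = drawn

    out = df.copy()
    for col in cats:
        info = counts[col]
        tally, levels = info["tally"], info["levels"]
        best = np.argmax(tally, axis=1)   # argmax takes the first = lowest level
        ties = (tally == tally.max(axis=1, keepdims=True)).sum(axis=1) > 1
        if ties.any():
            logger.info("%d ties in %r resolved by fixed level order",
                        int(ties.sum()), col)
        out.loc[info["mask"], col] = levels[best]
    return PhenotypeTable(out, dict(table.kinds), dict(table.meta))


def dummy_code(table: PhenotypeTable,
               reference: dict[str, object] | None = None) -> PhenotypeTable:
    """Expand each m-level categorical into m-1 indicators vs a reference
    level (default: the lowest observed level).  Requires a complete table."""
    if table.data.isna().any().any():
        raise ValueError("dummy coding requires a complete table")
    reference = reference or {}
    out = {}
    kinds = {}
    for col in table.variables:
        if table.kinds.get(col) != "categorical":
            out[col] = table.data[col]
            kinds[col] = table.kinds.get(col, "continuous")
            continue
        levels = np.sort(table.data[col].unique())
        ref = reference.get(col, levels[0])
        for lev in levels:
            if lev == ref:
                continue
            name = f"{col}_{_fmt_level(lev)}"
            out[name] = (table.data[col] == lev).astype(float)
            kinds[name] = "continuous"
    df = pd.DataFrame(out, index=table.data.index)
    return PhenotypeTable(df, kinds, dict(table.meta))


def _fmt_level(lev) -> str:
    if isinstance(lev, float) and lev == int(lev):
        return str(int(lev))
    return str(lev)
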