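"""Resting-state network measures from component timeseries.

Two per-subject summaries: component *amplitudes* (sample standard deviation
of each component's timeseries) and *edges* (L2-regularized partial
correlations between components, partialled over the full component set and
then restricted to a selected subset).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ComponentTimeseries:
    """One subject's timepoints x components signal matrix."""

    subject: str
    data: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("timeseries needs >= 2 timepoints")
        if np.isnan(self.data).any():
            raise ValueError("timeseries must not contain missing values")
        if not self.labels:
            self.labels = [f"comp{i + 1}" for i in range(self.data.shape[1])]

    @classmethod
    def read_tsv(cls, path, subject: str | None = None) -> "ComponentTimeseries":
        df = pd.read_csv(path, sep="\t")
        return cls(subject or str(path), df.to_numpy(float), list(df.columns))


def amplitude(ts: ComponentTimeseries) -> np.ndarray:
    """Per-component sample standard deviation (n-1 denominator).

    A constant component has amplitude 0; scaling a component by c scales
    its amplitude by |c|.
    """
    return np.std(ts.data, axis=0, ddof=1)


def partial_edges(ts: ComponentTimeseries, ridge: float = 0.5,
                  select: list[int] | None = None) -> pd.Series:
    """Regularized partial correlations for the selected components' pairs.

    The ridge is added to the *correlation* matrix of all components before
    inversion (scale-free regularization); partialling is therefore over the
    full component set, and the subset restriction happens afterwards.
    Returns a Series indexed ``labelA-labelB`` over C(k,2) unordered pairs.
    """
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    pc = partial_correlation_matrix(ts.data, ridge)
    k = pc.shape[0]
    sel = list(range(k)) if select is None else list(select)
    idx, vals = [], []
    for i, j in itertools.combinations(sel, 2):
        idx.append(f"{ts.labels[i]}-{ts.labels[j]}")
        vals.append(pc[i, j])
    out = pd.Series(vals, index=idx, name=ts.subject)
    out.attrs["ridge"] = ridge
    out.attrs["regularization"] = "ridge on correlation matrix"
    return out


def partial_correlation_matrix(data: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Partial correlations from the (optionally ridge-loaded) correlation
    matrix: ``-p_ij / sqrt(p_ii p_jj)`` of the normalized precision."""
    corr = np.corrcoef(np.asarray(data, float), rowvar=False)
    if np.isnan(corr).any():
        raise ValueError("constant component: correlation undefined")
    k = corr.shape[0]
    mat = corr + ridge * np.eye(k)
    if np.linalg.cond(mat) > 1e12:
        raise np.linalg.LinAlgError(
            "covariance (near-)singular; use ridge > 0")
    prec = np.linalg.inv(mat)
    d = np.sqrt(np.diag(prec))
    pc = -prec / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return pc


def measures_table(timeseries: list[ComponentTimeseries], ridge: float = 0.5,
                   select: list[int] | None = None) -> pd.DataFrame:
    """Stack amplitudes + selected edges into a subjects x measures frame."""
    rows = []
    for ts in timeseries:
        edges = partial_edges(ts, ridge=ridge, select=select)
        sel = select if select is not None else list(range(ts.data.shape[1]))
        amps = amplitude(ts)[sel]
        amp_s = pd.Series(amps, index=[f"amp_{ts.labels[i]}" for i in sel])
        edge_s = edges.rename(lambda s: f"edge_{s}")
        rows.append(pd.concat([edge_s, amp_s]).rename(ts.subject))
    return pd.DataFrame(rows)
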