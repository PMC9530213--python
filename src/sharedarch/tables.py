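"""Phenotype tables: participants x named variables with explicit missingness.

A :class:`PhenotypeTable` wraps a pandas DataFrame indexed by subject id,
with a declared *kind* per variable (``continuous``, ``ordinal`` or
``categorical``).  Missing entries are ``NaN``; a boolean mask view is
available through :meth:`PhenotypeTable.missing_mask`.  Tables round-trip
through tab-separated text with a JSON sidecar recording variable kinds and
arbitrary metadata (for synthetic tables, the generative ground truth).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALID_KINDS = ("continuous", "ordinal", "categorical")


@dataclass
class PhenotypeTable:
    """Participants x variables with missingness mask and variable kinds."""

    data: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.data.columns:
            self.kinds.setdefault(name, "continuous")
        for name, kind in self.kinds.items():
            if kind not in VALID_KINDS:
                raise ValueError(f"unknown variable kind {kind!r} for {name!r}")

    # ------------------------------------------------------------------ views
    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask, True where an entry is missing."""
        return self.data.isna()

    def missing_fraction(self) -> pd.Series:
        return self.data.isna().mean()

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset(self, columns: list[str]) -> "PhenotypeTable":
        kinds = {c: self.kinds[c] for c in columns}
        return PhenotypeTable(self.data[columns].copy(), kinds, dict(self.meta))

    def copy(self) -> "PhenotypeTable":
        return PhenotypeTable(self.data.copy(), dict(self.kinds), dict(self.meta))

    def aligned(self, other: "PhenotypeTable") -> bool:
        return self.data.index.equals(other.data.index)

    # -------------------------------------------------------------------- I/O
    def to_tsv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write TSV (empty field = missing) plus a JSON kinds/meta sidecar."""
        path = Path(path)
        self.data.to_csv(path, sep="\t", index=True, index_label="subject",
                         na_rep="")
        if sidecar:
            side = {"kinds": self.kinds, "meta": _jsonable(self.meta)}
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps(side, indent=1))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PhenotypeTable":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col="subject")
        kinds: dict[str, str] = {}
        meta: dict = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            side = json.loads(sidecar.read_text())
            kinds = side.get("kinds", {})
            meta = side.get("meta", {})
        return cls(df, kinds, meta)


def _jsonable(obj):
    """Recursively convert numpy containers to JSON-serializable types."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
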