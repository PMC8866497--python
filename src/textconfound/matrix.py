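"""Patients-by-covariates matrix with column provenance.

Every downstream stage (Lasso selection, propensity models, Cox fits)
consumes this container.  Columns carry a provenance prefix: ``struct:``
for structured EMR fields and ``text:`` for note-derived terms, so the
selection stage can tell the two blocks apart.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STRUCT_PREFIX = "struct:"
TEXT_PREFIX = "text:"


@dataclass
class CovariateMatrix:
    """Aligned (patients x covariates) real matrix.

    Parameters
    ----------
    patient_ids : ordered patient identifiers, one per row.
    column_names : ordered covariate names, each prefixed with its
        provenance block (``struct:`` or ``text:``).
    values : float array of shape (n_patients, n_columns); finite.
    """

    patient_ids: list[str]
    column_names: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.patient_ids), len(self.column_names)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.patient_ids)} patients x {len(self.column_names)} columns"
            )
        if len(set(self.column_names)) != len(self.column_names):
            dupes = [c for c in self.column_names if self.column_names.count(c) > 1]
            raise ValueError(f"duplicate column names: {sorted(set(dupes))}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("covariate matrix contains non-finite values")

    # -- basic introspection -------------------------------------------------

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_columns(self) -> int:
        return len(self.column_names)

    def structured_columns(self) -> list[str]:
        return [c for c in self.column_names if c.startswith(STRUCT_PREFIX)]

    def text_columns(self) -> list[str]:
        return [c for c in self.column_names if c.startswith(TEXT_PREFIX)]

    # -- transforms ----------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patient_ids, columns=self.column_names)

    def select_columns(self, names: Sequence[str]) -> "CovariateMatrix":
        missing = [n for n in names if n not in self.column_names]
        if missing:
            raise KeyError(f"columns not present: {missing}")
        idx = [self.column_names.index(n) for n in names]
        return CovariateMatrix(list(self.patient_ids), list(names), self.values[:, idx])

    def select_patients(self, ids: Sequence[str]) -> "CovariateMatrix":
        pos = {p: i for i, p in enumerate(self.patient_ids)}
        missing = [p for p in ids if p not in pos]
        if missing:
            raise KeyError(f"patients not present: {missing[:5]}")
        rows = [pos[p] for p in ids]
        return CovariateMatrix(list(ids), list(self.column_names), self.values[rows])

    def hstack(self, other: "CovariateMatrix") -> "CovariateMatrix":
        """Concatenate covariate blocks for the same, identically ordered patients."""
        if self.patient_ids != other.patient_ids:
            raise ValueError("patient order differs between blocks")
        return CovariateMatrix(
            list(self.patient_ids),
            list(self.column_names) + list(other.column_names),
            np.hstack([self.values, other.values]),
        )

    # -- persistence ---------------------------------------------------------

    def write_tsv(self, path: str | Path) -> None:
        """Write the matrix as TSV plus a JSON column-provenance sidecar."""
        path = Path(path)
        df = self.to_dataframe()
        df.index.name = "patient_id"
        df.to_csv(path, sep="\t")
        provenance = {
            c: ("struct" if c.startswith(STRUCT_PREFIX) else "text")
            for c in self.column_names
        }
        path.with_suffix(path.suffix + ".provenance.json").write_text(
            json.dumps(provenance, indent=1)
        )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CovariateMatrix":
        df = pd.read_csv(path, sep="\t", index_col="patient_id")
        return cls(list(df.index.astype(str)), list(df.columns), df.to_numpy(float))


def concat_blocks(blocks: Iterable[CovariateMatrix]) -> CovariateMatrix:
    blocks = list(blocks)
    if not blocks:
        raise ValueError("no blocks to concatenate")
    out = blocks[0]
    for b in blocks[1:]:
        out = out.hstack(b)
    return out
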