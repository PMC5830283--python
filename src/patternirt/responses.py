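"""Respondent-by-item response matrices.

Responses are integer category codes (``0..m_j`` per item); missing cells
are carried as NaN internally and as blank cells in the delimited-text
round-trip format (comma-separated, one header row of item ids, an optional
leading ``respondent_id`` column).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bank import ItemBank

__all__ = ["ResponseMatrix", "read_response_matrix", "write_response_matrix"]

ID_COLUMN = "respondent_id"


@dataclass(frozen=True)
class ResponseMatrix:
    """n x J matrix of integer category codes with a missing-value mask."""

    values: np.ndarray  # float array, NaN = missing
    item_ids: tuple[str, ...]
    respondent_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("response matrix must be 2-D")
        observed = values[~np.isnan(values)]
        if observed.size and not np.allclose(observed, np.round(observed)):
            raise ValueError("response categories must be integers")
        if observed.size and observed.min() < 0:
            raise ValueError("response categories must be non-negative")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "item_ids", tuple(str(i) for i in self.item_ids))
        object.__setattr__(self, "respondent_ids", tuple(str(r) for r in self.respondent_ids))
        if len(self.item_ids) != values.shape[1]:
            raise ValueError("item_ids length must match column count")
        if len(self.respondent_ids) != values.shape[0]:
            raise ValueError("respondent_ids length must match row count")

    @classmethod
    def from_array(
        cls,
        values: np.ndarray,
        item_ids: Sequence[str] | None = None,
        respondent_ids: Sequence[str] | None = None,
    ) -> "ResponseMatrix":
        values = np.asarray(values, dtype=float)
        if item_ids is None:
            item_ids = [f"item{j + 1}" for j in range(values.shape[1])]
        if respondent_ids is None:
            respondent_ids = [f"r{i + 1}" for i in range(values.shape[0])]
        return cls(values=values, item_ids=tuple(item_ids), respondent_ids=tuple(respondent_ids))

    @property
    def n_respondents(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def complete_cases(self) -> "ResponseMatrix":
        """Rows with no missing cell (listwise deletion)."""
        keep = ~self.missing_mask.any(axis=1)
        return ResponseMatrix(
            values=self.values[keep],
            item_ids=self.item_ids,
            respondent_ids=tuple(np.asarray(self.respondent_ids)[keep]),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.item_ids))
        df.insert(0, ID_COLUMN, list(self.respondent_ids))
        return df

    def validate_against(self, bank: ItemBank) -> None:
        """Raise with cell coordinates if the matrix does not conform to a bank."""
        if list(self.item_ids) != bank.item_ids:
            raise ValueError(
                f"item ids do not match the bank: {list(self.item_ids)} vs {bank.item_ids}"
            )
        problems = []
        for j, item in enumerate(bank.items):
            col = self.values[:, j]
            bad = np.flatnonzero(~np.isnan(col) & ((col < 0) | (col > item.n_boundaries)))
            for i in bad:
                problems.append(
                    f"row {self.respondent_ids[i]!r}, item {item.item_id!r}: "
                    f"value {int(col[i])} outside 0..{item.n_boundaries}"
                )
        if problems:
            raise ValueError("out-of-range responses:\n  " + "\n  ".join(problems))


def read_response_matrix(path: str | Path, bank: ItemBank | None = None) -> ResponseMatrix:
    """Read a delimited-text response matrix; blank cells are missing.

    When ``bank`` is given, item ids and category ranges are validated and
    offending cells are reported with row/column coordinates.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if df.shape[1] == 0 or (df.shape[0] == 0 and df.shape[1] <= 1):
        raise ValueError(f"{path}: empty response file")
    if df.columns[0] == ID_COLUMN:
        respondent_ids = df[ID_COLUMN].astype(str).tolist()
        df = df.drop(columns=[ID_COLUMN])
    else:
        respondent_ids = [f"r{i + 1}" for i in range(df.shape[0])]
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no item columns")
    values = np.full(df.shape, np.nan)
    bad_cells = []
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
                continue
            try:
                values[i, j] = int(str(cell).strip())
            except ValueError:
                bad_cells.append(f"row {respondent_ids[i]!r}, column {col!r}: non-integer {cell!r}")
    if bad_cells:
        raise ValueError("invalid cells:\n  " + "\n  ".join(bad_cells))
    rm = ResponseMatrix(values=values, item_ids=tuple(df.columns), respondent_ids=tuple(respondent_ids))
    if bank is not None:
        rm.validate_against(bank)
    return rm


def write_response_matrix(rm: ResponseMatrix, path: str | Path) -> None:
    df = rm.to_frame()
    for col in rm.item_ids:
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, index=False)
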