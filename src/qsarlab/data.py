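"""The compound-by-descriptor table that every pipeline stage exchanges.

A :class:`DescriptorTable` is a thin, validated wrapper around a pandas
DataFrame of descriptor values (rows = compounds, columns = named
descriptors) plus an optional activity vector (pIC50).  It is the common
currency between the synthetic-data generator, the descriptor calculators,
the model builders, validation, the applicability domain and screening.

On disk the table is a plain CSV whose first column is the compound
identifier and whose last column, when present, is ``pIC50``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import MissingDescriptorError, SpecificationError

ACTIVITY_COLUMN = "pIC50"


class DescriptorTable:
    """Compound × descriptor matrix with an optional pIC50 activity column.

    Parameters
    ----------
    X:
        DataFrame indexed by compound identifier, one column per descriptor.
    activity:
        Optional pIC50 series aligned with ``X`` (screening candidates
        usually have none).
    """

    def __init__(self, X: pd.DataFrame, activity: pd.Series | None = None):
        if X.index.has_duplicates:
            dupes = X.index[X.index.duplicated()].unique().tolist()
            raise SpecificationError(f"duplicate compound IDs: {dupes}")
        if X.columns.has_duplicates:
            dupes = X.columns[X.columns.duplicated()].unique().tolist()
            raise SpecificationError(f"duplicate descriptor names: {dupes}")
        X = X.astype(float).rename_axis("compound")
        if activity is not None:
            activity = pd.Series(np.asarray(activity, dtype=float), index=X.index,
                                 name=ACTIVITY_COLUMN)
            if len(activity) != len(X):
                raise SpecificationError("activity length does not match row count")
        self._X = X
        self._y = activity

    # -- basic accessors ---------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return [str(i) for i in self._X.index]

    @property
    def descriptor_names(self) -> list[str]:
        return [str(c) for c in self._X.columns]

    @property
    def X(self) -> pd.DataFrame:
        return self._X

    @property
    def values(self) -> np.ndarray:
        return self._X.to_numpy(dtype=float)

    @property
    def has_activity(self) -> bool:
        return self._y is not None

    @property
    def activity(self) -> pd.Series:
        if self._y is None:
            raise SpecificationError("table has no activity column")
        return self._y

    @property
    def n_compounds(self) -> int:
        return len(self._X)

    def __len__(self) -> int:
        return len(self._X)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        act = "with pIC50" if self.has_activity else "no activity"
        return (f"DescriptorTable({self.n_compounds} compounds × "
                f"{len(self._X.columns)} descriptors, {act})")

    # -- manipulation ------------------------------------------------------
    def subset(self, names: Sequence[str]) -> "DescriptorTable":
        """Restrict to the given descriptor columns (order preserved)."""
        missing = [n for n in names if n not in self._X.columns]
        if missing:
            raise MissingDescriptorError(missing)
        return DescriptorTable(self._X.loc[:, list(names)], self._y)

    def select_rows(self, ids: Iterable[str]) -> "DescriptorTable":
        ids = list(ids)
        y = self._y.loc[ids] if self._y is not None else None
        return DescriptorTable(self._X.loc[ids], y)

    def with_activity(self, activity: Sequence[float]) -> "DescriptorTable":
        return DescriptorTable(self._X, pd.Series(activity, index=self._X.index))

    def design(self, names: Sequence[str]) -> np.ndarray:
        """Raw value matrix for the requested columns, in that order."""
        return self.subset(names).values

    # -- I/O ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Single DataFrame: descriptors followed by pIC50 when present."""
        df = self._X.copy()
        if self._y is not None:
            df[ACTIVITY_COLUMN] = self._y
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DescriptorTable":
        df = pd.read_csv(path, index_col=0)
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DescriptorTable":
        if ACTIVITY_COLUMN in df.columns:
            y = df[ACTIVITY_COLUMN]
            X = df.drop(columns=[ACTIVITY_COLUMN])
            return cls(X, y)
        return cls(df)

    @classmethod
    def from_arrays(cls, ids, names, values, activity=None) -> "DescriptorTable":
        X = pd.DataFrame(np.asarray(values, dtype=float), index=list(ids),
                         columns=list(names))
        y = None if activity is None else pd.Series(np.asarray(activity, float),
                                                    index=X.index)
        return cls(X, y)
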