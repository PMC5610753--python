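"""Ordinary least squares, stepwise MLR and the published equations.

The central object is :class:`LinearModel`: an ordered list of descriptor
names, coefficients and an intercept — either fitted here or transcribed
from the source study's printed equations.  Estimators follow scikit-learn
conventions (``fit``/``predict``, ``get_params``, trailing-underscore fitted
attributes) so they compose with sklearn model selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .data import DescriptorTable
from .exceptions import (CollinearityError, DegenerateInputError,
                         InsufficientDataError, MissingDescriptorError,
                         SpecificationError, UnknownTemplateError)


@dataclass
class LinearModel:
    """Affine model: prediction = intercept + Σ coef·descriptor."""

    names: tuple[str, ...]
    coef: np.ndarray
    intercept: float
    se: np.ndarray | None = None
    intercept_se: float | None = None
    training_ids: tuple[str, ...] | None = None
    stats: dict = field(default_factory=dict)
    provenance: str = "fitted"

    def __post_init__(self):
        self.coef = np.asarray(self.coef, dtype=float)
        if len(self.names) != len(self.coef):
            raise SpecificationError("coefficient count != descriptor count")

    @property
    def k(self) -> int:
        return len(self.names)

    def _matrix(self, data) -> np.ndarray:
        if isinstance(data, DescriptorTable):
            return data.design(self.names)
        if isinstance(data, pd.DataFrame):
            missing = [n for n in self.names if n not in data.columns]
            if missing:
                raise MissingDescriptorError(missing)
            return data.loc[:, list(self.names)].to_numpy(dtype=float)
        X = np.asarray(data, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != self.k:
            raise MissingDescriptorError(
                [f"expected {self.k} columns, got {X.shape[1]}"])
        return X

    def predict(self, data) -> np.ndarray:
        return self.intercept + self._matrix(data) @ self.coef

    def equation(self, digits: int = 3) -> str:
        terms = [f"{c:+.{digits}f}·{n}" for c, n in zip(self.coef, self.names)]
        return "pIC50 = " + " ".join(terms) + f" {self.intercept:+.{digits}f}"

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "type": "linear",
            "names": list(self.names),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "se": None if self.se is None else np.asarray(self.se).tolist(),
            "intercept_se": self.intercept_se,
            "training_ids": None if self.training_ids is None
            else list(self.training_ids),
            "stats": self.stats,
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        return cls(names=tuple(d["names"]), coef=np.asarray(d["coef"]),
                   intercept=float(d["intercept"]),
                   se=None if d.get("se") is None else np.asarray(d["se"]),
                   intercept_se=d.get("intercept_se"),
                   training_ids=None if d.get("training_ids") is None
                   else tuple(d["training_ids"]),
                   stats=d.get("stats", {}),
                   provenance=d.get("provenance", "fitted"))

    @classmethod
    def from_json(cls, path) -> "LinearModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def selected_correlations(model: LinearModel, data: DescriptorTable) -> pd.DataFrame:
    """Pairwise correlation matrix among a model's selected descriptors.

    Mirrors the routine check that no significant collinearity remains
    among the final predictors.
    """
    return data.subset(model.names).X.corr()


# ---------------------------------------------------------------------------
# OLS core
# ---------------------------------------------------------------------------

def _dependent_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Name columns that do not increase the rank of the running design."""
    dependent, rank = [], 0
    for j in range(X.shape[1]):
        r = np.linalg.matrix_rank(X[:, :j + 1])
        if r == rank:
            dependent.append(names[j])
        rank = r
    return dependent


def _ols(X: np.ndarray, y: np.ndarray, names: Sequence[str]):
    """Intercept-augmented least squares with standard errors.

    Returns (coef, intercept, se, intercept_se, ss_res).
    """
    n, k = X.shape
    A = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(A) < k + 1:
        raise CollinearityError(
            "design matrix is rank deficient",
            columns=_dependent_columns(np.column_stack([np.ones(n), X]),
                                       ["(intercept)"] + list(names))[:k + 1])
    beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    ss_res = float(resid @ resid)
    dof = n - k - 1
    if dof > 0:
        mse = ss_res / dof
        cov = mse * np.linalg.inv(A.T @ A)
        se = np.sqrt(np.diag(cov))
    else:
        se = np.full(k + 1, np.nan)
    return beta[1:], float(beta[0]), se[1:], float(se[0]), ss_res


class OLSRegression(BaseEstimator, RegressorMixin):
    """Ordinary least squares on a fixed descriptor selection.

    Parameters
    ----------
    selected:
        Descriptor names to regress on; ``None`` uses every column.
    """

    def __init__(self, selected: Sequence[str] | None = None):
        self.selected = selected

    def _resolve(self, X, y):
        if isinstance(X, DescriptorTable):
            table = X
            y = table.activity.to_numpy() if y is None else np.asarray(y, float)
            names = list(self.selected) if self.selected is not None \
                else table.descriptor_names
            return table.design(names), y, names
        if isinstance(X, pd.DataFrame):
            names = list(self.selected) if self.selected is not None \
                else [str(c) for c in X.columns]
            missing = [n for n in names if n not in X.columns]
            if missing:
                raise MissingDescriptorError(missing)
            return X.loc[:, names].to_numpy(float), np.asarray(y, float), names
        X = np.asarray(X, dtype=float)
        names = list(self.selected) if self.selected is not None \
            else [f"x{j}" for j in range(X.shape[1])]
        return X, np.asarray(y, float), names

    def fit(self, X, y=None):
        Xm, yv, names = self._resolve(X, y)
        n, k = Xm.shape
        if n <= k + 1:
            raise InsufficientDataError(
                f"need more than k+1={k + 1} rows, got {n}")
        coef, intercept, se, int_se, _ = _ols(Xm, yv, names)
        self.selected_ = tuple(names)
        self.coef_ = coef
        self.intercept_ = intercept
        self.model_ = LinearModel(tuple(names), coef, intercept, se=se,
                                  intercept_se=int_se,
                                  training_ids=tuple(X.ids)
                                  if isinstance(X, DescriptorTable) else None)
        return self

    def predict(self, X):
        return self.model_.predict(X)

    def frozen(self) -> "OLSRegression":
        return OLSRegression(selected=list(self.selected_))


def fit_ols(data: DescriptorTable, selected: Sequence[str]) -> LinearModel:
    """Least squares of pIC50 on the chosen descriptor columns."""
    return OLSRegression(selected=list(selected)).fit(data).model_


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

class StepwiseMLR(BaseEstimator, RegressorMixin):
    """Stepwise multiple linear regression by partial-F probabilities.

    Forward selection with backward elimination: at each step the candidate
    whose partial F-test p-value is smallest enters if p ≤ ``p_enter``
    (default 0.05), then included variables with p ≥ ``p_remove`` (default
    0.10) leave, until no move qualifies or ``max_steps`` is reached.
    Ties in p-value are broken by larger |t| and then lexicographic name so
    reruns are deterministic.
    """

    def __init__(self, p_enter: float = 0.05, p_remove: float = 0.10,
                 max_steps: int = 200):
        self.p_enter = p_enter
        self.p_remove = p_remove
        self.max_steps = max_steps

    # partial F p-value of adding column(s): incremental sum-of-squares test
    @staticmethod
    def _partial_f_p(ss_small: float, ss_big: float, df_big: int) -> float:
        if df_big <= 0:
            return 1.0
        if ss_big <= 0:
            return 0.0
        F = (ss_small - ss_big) / (ss_big / df_big)
        return float(stats.f.sf(F, 1, df_big))

    def fit(self, X, y=None):
        if not (0 < self.p_enter < self.p_remove):
            raise SpecificationError("need 0 < p_enter < p_remove")
        if isinstance(X, DescriptorTable):
            table = X
            yv = table.activity.to_numpy() if y is None else np.asarray(y, float)
        else:
            Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(
                np.asarray(X, float),
                columns=[f"x{j}" for j in range(np.asarray(X).shape[1])])
            table = DescriptorTable(Xdf.reset_index(drop=True))
            yv = np.asarray(y, float)
        n = table.n_compounds
        if n <= 2:
            raise InsufficientDataError("stepwise needs more than 2 rows")
        if np.ptp(yv) == 0:
            raise DegenerateInputError("activity has no variance")

        frame = table.X
        names = table.descriptor_names
        cols = {nm: frame[nm].to_numpy(float) for nm in names}
        usable = [nm for nm in names if np.ptp(cols[nm]) > 0]

        def ss_of(sel: list[str]):
            if not sel:
                return float(np.sum((yv - yv.mean()) ** 2))
            Xm = np.column_stack([cols[nm] for nm in sel])
            A = np.column_stack([np.ones(n), Xm])
            beta, _, rank, _ = np.linalg.lstsq(A, yv, rcond=None)
            if rank < A.shape[1]:
                return None
            r = yv - A @ beta
            return float(r @ r)

        def t_of(sel: list[str], nm: str) -> float:
            Xm = np.column_stack([cols[s] for s in sel])
            try:
                coef, _, se, _, _ = _ols(Xm, yv, sel)
            except CollinearityError:
                return 0.0
            j = sel.index(nm)
            return abs(coef[j] / se[j]) if se[j] > 0 else np.inf

        selected: list[str] = []
        steps: list[dict] = []
        ss_cur = ss_of([])
        for _ in range(self.max_steps):
            moved = False
            # forward step
            candidates = []
            for nm in usable:
                if nm in selected:
                    continue
                ss_new = ss_of(selected + [nm])
                if ss_new is None:      # would be collinear with current set
                    continue
                df_big = n - (len(selected) + 1) - 1
                p = self._partial_f_p(ss_cur, ss_new, df_big)
                candidates.append((p, nm, ss_new))
            if candidates:
                best = min(candidates,
                           key=lambda c: (c[0], -t_of(selected + [c[1]], c[1]), c[1]))
                if best[0] <= self.p_enter:
                    selected.append(best[1])
                    ss_cur = best[2]
                    steps.append({"action": "add", "name": best[1], "p": best[0]})
                    moved = True
            # backward step
            if selected:
                worst = None
                for nm in selected:
                    rest = [s for s in selected if s != nm]
                    ss_small = ss_of(rest)
                    df_big = n - len(selected) - 1
                    p = self._partial_f_p(ss_small, ss_cur, df_big)
                    if worst is None or (p, -t_of(selected, nm), nm) > worst[:3]:
                        worst = (p, -t_of(selected, nm), nm, ss_small)
                if worst is not None and worst[0] >= self.p_remove:
                    selected.remove(worst[2])
                    ss_cur = worst[3]
                    steps.append({"action": "remove", "name": worst[2],
                                  "p": worst[0]})
                    moved = True
            if not moved:
                break

        self.steps_ = steps
        self.selected_ = tuple(selected)
        if selected:
            est = OLSRegression(selected=selected).fit(table, yv)
            self.model_ = est.model_
        else:
            self.model_ = LinearModel((), np.empty(0), float(yv.mean()),
                                      training_ids=tuple(table.ids))
        self.coef_ = self.model_.coef
        self.intercept_ = self.model_.intercept
        return self

    def predict(self, X):
        return self.model_.predict(X)

    def frozen(self) -> OLSRegression:
        return OLSRegression(selected=list(self.selected_))


def stepwise_mlr(data: DescriptorTable, p_enter: float = 0.05,
                 p_remove: float = 0.10, max_steps: int = 200) -> LinearModel:
    """Stepwise MLR on a descriptor table; returns the fitted LinearModel."""
    return StepwiseMLR(p_enter, p_remove, max_steps).fit(data).model_


# ---------------------------------------------------------------------------
# published equations
# ---------------------------------------------------------------------------

# Final equations of the source study's four model classes, transcribed
# verbatim (coefficient, standard error).  No descriptor values were
# published, so these are evaluable on user-supplied descriptor tables but
# their training statistics cannot be recomputed here.
_PUBLISHED = {
    "eq1": {  # stepwise MLR
        "terms": [("G(O..O)", 0.010, 0.003), ("nPhX", -0.376, 0.058),
                  ("DipY", 0.265, 0.072), ("GATS7v", -1.574, 0.258),
                  ("MATS2e", 1.076, 0.362), ("nROR", 0.205, 0.063),
                  ("MATS7e", 0.997, 0.401)],
        "intercept": (7.562, 0.488),
    },
    "eq2": {  # FA-MLR
        "terms": [("MATS7v", 2.152, 0.537), ("DipY", 0.230, 0.083),
                  ("nROR", 0.244, 0.048), ("Ss", 0.020, 0.003)],
        "intercept": (3.538, 0.204),
    },
    "eq3": {  # PCRA on factor scores
        "terms": [("FAC1", 0.240, 0.048), ("FAC2", 0.139, 0.048),
                  ("FAC4", 0.114, 0.048), ("FAC7", 0.117, 0.048),
                  ("FAC9", 0.103, 0.048)],
        "intercept": (4.969, 0.047),
    },
    "eq4": {  # GA-PLS (the best model; 7 descriptors)
        "terms": [("X3A", -20.126, 7.555), ("MATS7v", 3.685, 0.391),
                  ("MATS5p", 2.655, 0.471), ("DipY", 0.319, 0.053),
                  ("H-048", 0.230, 0.036), ("MATS6e", -1.084, 0.304),
                  ("ASP", -0.637, 0.234)],
        "intercept": (8.553, 1.397),
    },
}


def transcribe_published_model(equation_id: str) -> LinearModel:
    """Return one of the study's printed equations as a LinearModel.

    ``equation_id`` is one of ``eq1`` (stepwise MLR), ``eq2`` (FA-MLR),
    ``eq3`` (PCRA, factor-score inputs) or ``eq4`` (GA-PLS).
    """
    try:
        eq = _PUBLISHED[equation_id]
    except KeyError:
        raise UnknownTemplateError(
            f"unknown equation {equation_id!r}; choose from "
            f"{sorted(_PUBLISHED)}") from None
    names = tuple(t[0] for t in eq["terms"])
    coef = np.array([t[1] for t in eq["terms"]])
    se = np.array([t[2] for t in eq["terms"]])
    return LinearModel(names, coef, eq["intercept"][0], se=se,
                       intercept_se=eq["intercept"][1],
                       provenance=f"published:{equation_id}")
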