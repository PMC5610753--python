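"""Principal-component factor analysis with varimax, FA-MLR and PCRA.

Factor extraction is the principal component method: descriptor columns are
standardized, the correlation matrix eigen-decomposed, and the smallest
number of factors whose cumulative explained variance reaches the target
(default 95%) is retained.  Loadings are varimax-rotated (pairwise Jacobi
rotations on Kaiser-normalized loadings).  Factor scores are unit-variance
principal component scores carried through the rotation, named FAC1, FAC2, …

Two model builders sit on top:

* :class:`FAMLR` — factor analysis as a variable *pre-selection*: the pool
  of original descriptors highly loaded (|loading| ≥ threshold) on
  activity-relevant factors is handed to stepwise MLR.
* :class:`PCRA` — stepwise regression directly on the (orthogonal) factor
  scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

from .data import DescriptorTable
from .exceptions import ConfigError, DegenerateInputError, SpecificationError
from .linear import LinearModel, StepwiseMLR

# ---------------------------------------------------------------------------
# varimax rotation
# ---------------------------------------------------------------------------


def varimax_criterion(L: np.ndarray) -> float:
    """Raw varimax criterion: Σ_factors [Σ l⁴ − (Σ l²)²/p]."""
    p = L.shape[0]
    return float(np.sum(np.sum(L ** 4, axis=0) - np.sum(L ** 2, axis=0) ** 2 / p))


def varimax(L: np.ndarray, kaiser: bool = True, tol: float = 1e-10,
            max_iter: int = 500) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation by pairwise Jacobi sweeps.

    Returns ``(L_rotated, R)`` with ``L_rotated = L @ R`` and R orthonormal.
    Kaiser normalization (rows scaled to unit communality during rotation)
    is applied by default.
    """
    L = np.asarray(L, dtype=float).copy()
    p, m = L.shape
    R = np.eye(m)
    if m < 2:
        return L, R
    h = np.sqrt(np.sum(L ** 2, axis=1))
    h_safe = np.where(h > 0, h, 1.0)
    if kaiser:
        L /= h_safe[:, None]
    crit = varimax_criterion(L)
    for _ in range(max_iter):
        for i in range(m - 1):
            for j in range(i + 1, m):
                x, yy = L[:, i], L[:, j]
                u = x ** 2 - yy ** 2
                v = 2 * x * yy
                A, B = u.sum(), v.sum()
                C = (u ** 2 - v ** 2).sum()
                D = (2 * u * v).sum()
                num = D - 2 * A * B / p
                den = C - (A ** 2 - B ** 2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-14:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                rot = np.array([[c, -s], [s, c]])
                L[:, [i, j]] = L[:, [i, j]] @ rot
                R[:, [i, j]] = R[:, [i, j]] @ rot
        new_crit = varimax_criterion(L)
        if new_crit - crit < tol:
            break
        crit = new_crit
    if kaiser:
        L *= h_safe[:, None]
    return L, R


# ---------------------------------------------------------------------------
# factor model
# ---------------------------------------------------------------------------

@dataclass
class FactorModel:
    """Varimax-rotated principal-component factor solution."""

    loadings: pd.DataFrame          # descriptors × factors (rotated)
    rotation: np.ndarray            # orthonormal, unrotated → rotated
    explained_variance: np.ndarray  # per retained factor, pre-rotation
    scores: pd.DataFrame            # compounds × factors (rotated, unit var)
    communalities: pd.Series

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    @property
    def factor_names(self) -> list[str]:
        return [str(c) for c in self.loadings.columns]


class FactorAnalysisVarimax(BaseEstimator, TransformerMixin):
    """Principal-component factor extraction + varimax rotation.

    Parameters
    ----------
    variance_target:
        Retain the smallest factor count whose cumulative explained
        variance is at least this fraction (default 0.95).
    """

    def __init__(self, variance_target: float = 0.95):
        self.variance_target = variance_target

    def fit(self, X, y=None):
        if not (0 < self.variance_target <= 1):
            raise ConfigError("variance_target must lie in (0, 1]")
        frame = X.X if isinstance(X, DescriptorTable) else pd.DataFrame(X)
        sd = frame.std(ddof=1)
        keep = sd[sd > 0].index.tolist()
        if len(keep) < 2:
            raise DegenerateInputError(
                "factor analysis needs ≥ 2 descriptors with nonzero variance")
        Z = (frame[keep] - frame[keep].mean()) / sd[keep]
        corr = np.corrcoef(Z.to_numpy(), rowvar=False)
        eigval, eigvec = np.linalg.eigh(corr)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]
        frac = eigval / len(keep)
        m = int(np.searchsorted(np.cumsum(frac), self.variance_target) + 1)
        m = min(m, int(np.sum(eigval > 1e-10)))  # never beyond numerical rank
        lam, V = eigval[:m], eigvec[:, :m]
        loadings = V * np.sqrt(lam)
        rotated, R = varimax(loadings)
        factor_names = [f"FAC{k + 1}" for k in range(m)]
        with np.errstate(divide="ignore"):
            scores_unrot = Z.to_numpy() @ V / np.sqrt(lam)
        scores = scores_unrot @ R

        index = frame.index if isinstance(X, DescriptorTable) else Z.index
        self.columns_ = keep
        self.mean_ = frame[keep].mean()
        self.sd_ = sd[keep]
        self.eigenvalues_ = eigval
        self.rotation_ = R
        self.loadings_ = pd.DataFrame(rotated, index=keep, columns=factor_names)
        self.explained_variance_ratio_ = frac[:m]
        self.scores_ = pd.DataFrame(scores, index=index, columns=factor_names)
        self.communalities_ = pd.Series((rotated ** 2).sum(axis=1), index=keep)
        self.model_ = FactorModel(self.loadings_, R, frac[:m], self.scores_,
                                  self.communalities_)
        self._projection = (V / np.sqrt(lam)) @ R
        return self

    def transform(self, X) -> pd.DataFrame:
        frame = X.X if isinstance(X, DescriptorTable) else pd.DataFrame(X)
        Z = (frame[self.columns_] - self.mean_) / self.sd_
        return pd.DataFrame(Z.to_numpy() @ self._projection, index=frame.index,
                            columns=self.loadings_.columns)

    def score_table(self, X=None, activity=None) -> DescriptorTable:
        """Factor scores as a DescriptorTable (training scores by default)."""
        if X is None:
            scores = self.scores_
        else:
            scores = self.transform(X)
            if activity is None and isinstance(X, DescriptorTable) \
                    and X.has_activity:
                activity = X.activity
        return DescriptorTable(scores, activity)


def factor_analysis(data: DescriptorTable,
                    variance_target: float = 0.95) -> FactorModel:
    """Principal-component FA with varimax; see FactorAnalysisVarimax."""
    return FactorAnalysisVarimax(variance_target).fit(data).model_


# ---------------------------------------------------------------------------
# FA-MLR
# ---------------------------------------------------------------------------

class FAMLR(BaseEstimator, RegressorMixin):
    """Stepwise MLR restricted to descriptors highly loaded on
    activity-relevant factors.

    Relevant factors are found by running stepwise selection on the factor
    scores (as in PCRA); the candidate pool is every original descriptor
    whose maximum |rotated loading| over those factors reaches
    ``loading_threshold``.
    """

    def __init__(self, variance_target: float = 0.95,
                 loading_threshold: float = 0.6,
                 p_enter: float = 0.05, p_remove: float = 0.10):
        self.variance_target = variance_target
        self.loading_threshold = loading_threshold
        self.p_enter = p_enter
        self.p_remove = p_remove

    def fit(self, X, y=None):
        if not (0 < self.loading_threshold < 1):
            raise ConfigError("loading_threshold must lie in (0, 1)")
        table: DescriptorTable = X
        fa = FactorAnalysisVarimax(self.variance_target).fit(table)
        score_table = fa.score_table(activity=table.activity)
        factor_step = StepwiseMLR(self.p_enter, self.p_remove).fit(score_table)
        relevant = list(factor_step.selected_)
        if not relevant:
            # fall back to the factor whose scores correlate best with activity
            r = score_table.X.corrwith(table.activity).abs()
            relevant = [str(r.idxmax())]
        load = fa.loadings_[relevant].abs().max(axis=1)
        pool = load[load >= self.loading_threshold].index.tolist()
        if not pool:
            raise ConfigError(
                f"loading threshold {self.loading_threshold} leaves an empty "
                f"candidate pool (max loading {load.max():.3f})")
        step = StepwiseMLR(self.p_enter, self.p_remove).fit(
            table.subset(pool).with_activity(table.activity))
        self.factor_model_ = fa.model_
        self.relevant_factors_ = tuple(relevant)
        self.pool_ = tuple(pool)
        self.selected_ = step.selected_
        self.model_ = step.model_
        return self

    def predict(self, X):
        return self.model_.predict(X)

    def frozen(self):
        from .linear import OLSRegression

        return OLSRegression(selected=list(self.selected_))


def fa_mlr(data: DescriptorTable, fm: FactorModel | None = None,
           loading_threshold: float = 0.6, p_enter: float = 0.05,
           p_remove: float = 0.10, variance_target: float = 0.95) -> LinearModel:
    """FA-preselected stepwise MLR; returns the fitted LinearModel.

    When a precomputed :class:`FactorModel` is supplied its loadings and
    scores are reused; otherwise FA is fit on ``data`` first.
    """
    if fm is None:
        return FAMLR(variance_target, loading_threshold,
                     p_enter, p_remove).fit(data).model_
    if not (0 < loading_threshold < 1):
        raise ConfigError("loading_threshold must lie in (0, 1)")
    score_table = DescriptorTable(fm.scores, data.activity)
    relevant = list(StepwiseMLR(p_enter, p_remove).fit(score_table).selected_)
    if not relevant:
        r = fm.scores.corrwith(data.activity).abs()
        relevant = [str(r.idxmax())]
    load = fm.loadings[relevant].abs().max(axis=1)
    pool = load[load >= loading_threshold].index.tolist()
    if not pool:
        raise ConfigError(
            f"loading threshold {loading_threshold} leaves an empty candidate "
            f"pool (max loading {load.max():.3f})")
    return StepwiseMLR(p_enter, p_remove).fit(
        data.subset(pool).with_activity(data.activity)).model_


# ---------------------------------------------------------------------------
# PCRA
# ---------------------------------------------------------------------------

class PCRA(BaseEstimator, RegressorMixin):
    """Principal component regression analysis: stepwise MLR on factor scores.

    The retained predictors are orthogonal, so coefficients are invariant
    to which other factors were in the pool.
    """

    def __init__(self, variance_target: float = 0.95,
                 p_enter: float = 0.05, p_remove: float = 0.10):
        self.variance_target = variance_target
        self.p_enter = p_enter
        self.p_remove = p_remove

    def fit(self, X, y=None):
        table: DescriptorTable = X
        fa = FactorAnalysisVarimax(self.variance_target).fit(table)
        score_table = fa.score_table(activity=table.activity)
        step = StepwiseMLR(self.p_enter, self.p_remove).fit(score_table)
        self.fa_ = fa
        self.factor_model_ = fa.model_
        self.selected_ = step.selected_
        self.model_ = step.model_
        return self

    def predict(self, X):
        """Predict for raw descriptor input (scores are computed internally)."""
        scores = self.fa_.transform(X)
        return self.model_.predict(scores)

    def frozen(self) -> "FrozenPCRA":
        """Refit-only variant: frozen FA projection and factor selection."""
        return FrozenPCRA(columns=list(self.fa_.columns_),
                          mean=self.fa_.mean_.to_numpy(),
                          sd=self.fa_.sd_.to_numpy(),
                          projection=self.fa_._projection,
                          factor_names=list(self.fa_.loadings_.columns),
                          selected=list(self.selected_))


class FrozenPCRA(BaseEstimator, RegressorMixin):
    """PCRA with the factor projection and factor choice held fixed.

    Used for leave-one-out folds in the default (selection-frozen) mode:
    only the regression coefficients on the pre-chosen factor scores are
    refit per fold.
    """

    def __init__(self, columns=None, mean=None, sd=None, projection=None,
                 factor_names=None, selected=None):
        self.columns = columns
        self.mean = mean
        self.sd = sd
        self.projection = projection
        self.factor_names = factor_names
        self.selected = selected

    def _scores(self, X) -> pd.DataFrame:
        frame = X.X if isinstance(X, DescriptorTable) else pd.DataFrame(X)
        Z = (frame[self.columns].to_numpy(float) - self.mean) / self.sd
        return pd.DataFrame(Z @ self.projection, index=frame.index,
                            columns=self.factor_names)

    def fit(self, X, y=None):
        table: DescriptorTable = X
        score_table = DescriptorTable(self._scores(table), table.activity)
        from .linear import OLSRegression

        self._ols_ = OLSRegression(selected=list(self.selected)).fit(score_table)
        self.model_ = self._ols_.model_
        return self

    def predict(self, X):
        return self.model_.predict(self._scores(X))


def pcra(data: DescriptorTable, fm: FactorModel | None = None,
         p_enter: float = 0.05, p_remove: float = 0.10,
         variance_target: float = 0.95) -> LinearModel:
    """Stepwise regression on factor scores; returns the fitted LinearModel."""
    if fm is not None:
        score_table = DescriptorTable(fm.scores, data.activity)
        return StepwiseMLR(p_enter, p_remove).fit(score_table).model_
    return PCRA(variance_target, p_enter, p_remove).fit(data).model_
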