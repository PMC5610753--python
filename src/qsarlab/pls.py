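"""NIPALS partial least squares (PLS1) and latent-variable selection.

The NIPALS algorithm extracts latent variables (X scores) — linear
combinations of the standardized descriptors that maximize covariance with
the activity — by alternating weight/score/loading updates with deflation.
With a single response the weight vector is closed-form per component, so
each component is one pass.  The equivalent affine regression vector in the
original descriptor units is assembled as

    b = W (PᵀW)⁻¹ q,   rescaled by the stored standardization constants.

The latent-variable count is chosen by leave-one-out cross-validation with
the Haaland–Thomas F-ratio rule: the smallest component count whose PRESS
is not significantly worse than the minimum PRESS, at α = 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .data import DescriptorTable
from .exceptions import (ConfigError, DegenerateInputError,
                         InsufficientDataError, MissingDescriptorError)


@dataclass
class PLSModel:
    """Fitted NIPALS PLS1 model with its equivalent regression vector."""

    names: tuple[str, ...]
    x_weights: np.ndarray      # p × a
    x_loadings: np.ndarray     # p × a
    x_scores: np.ndarray       # n × a
    y_loadings: np.ndarray     # a
    n_components: int
    coef: np.ndarray           # original units, length p
    intercept: float
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float

    def predict(self, data) -> np.ndarray:
        if isinstance(data, DescriptorTable):
            X = data.design(self.names)
        elif isinstance(data, pd.DataFrame):
            missing = [n for n in self.names if n not in data.columns]
            if missing:
                raise MissingDescriptorError(missing)
            X = data.loc[:, list(self.names)].to_numpy(float)
        else:
            X = np.atleast_2d(np.asarray(data, dtype=float))
        return self.intercept + X @ self.coef

    def to_dict(self) -> dict:
        return {"type": "pls", "names": list(self.names),
                "coef": self.coef.tolist(), "intercept": self.intercept,
                "n_components": self.n_components}


def _standardize(X: np.ndarray, y: np.ndarray):
    x_mean, y_mean = X.mean(axis=0), float(y.mean())
    x_std = X.std(axis=0, ddof=1)
    x_std = np.where(x_std > 0, x_std, 1.0)
    y_std = float(y.std(ddof=1))
    if y_std == 0:
        raise DegenerateInputError("activity has zero variance")
    return (X - x_mean) / x_std, (y - y_mean) / y_std, x_mean, x_std, y_mean, y_std


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_components: int):
    """Core PLS1 deflation on already-standardized data.

    Returns W, P, T, q with nested sub-models: the first a columns give the
    a-component solution.
    """
    n, p = Xc.shape
    X, y = Xc.copy(), yc.copy()
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    for a in range(n_components):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm < 1e-14:          # X carries no further covariance with y
            W, P, T, q = W[:, :a], P[:, :a], T[:, :a], q[:a]
            break
        w /= norm
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-14:
            W, P, T, q = W[:, :a], P[:, :a], T[:, :a], q[:a]
            break
        p_a = X.T @ t / tt
        q_a = float(y @ t) / tt
        X = X - np.outer(t, p_a)
        y = y - q_a * t
        W[:, a], P[:, a], T[:, a], q[a] = w, p_a, t, q_a
    return W, P, T, q


def _regression_vectors(W, P, q):
    """Standardized-unit regression vector for every nested component count."""
    a = W.shape[1]
    out = []
    for k in range(1, a + 1):
        Wk, Pk, qk = W[:, :k], P[:, :k], q[:k]
        out.append(Wk @ np.linalg.solve(Pk.T @ Wk, qk))
    return out


class PLSNipals(BaseEstimator, RegressorMixin):
    """NIPALS PLS1 regression with internal standardization.

    Parameters
    ----------
    n_components:
        Latent-variable count; ``None`` chooses it by LOO cross-validation
        with the Haaland–Thomas rule (``alpha``, ``max_components``).
    selected:
        Optional descriptor-name subset (for DescriptorTable/DataFrame input).
    """

    def __init__(self, n_components: int | None = None,
                 selected: list[str] | None = None,
                 max_components: int = 15, alpha: float = 0.25):
        self.n_components = n_components
        self.selected = selected
        self.max_components = max_components
        self.alpha = alpha

    def _resolve(self, X, y):
        if isinstance(X, DescriptorTable):
            names = list(self.selected) if self.selected is not None \
                else X.descriptor_names
            yv = X.activity.to_numpy() if y is None else np.asarray(y, float)
            return X.design(names), yv, names
        if isinstance(X, pd.DataFrame):
            names = list(self.selected) if self.selected is not None \
                else [str(c) for c in X.columns]
            return X.loc[:, names].to_numpy(float), np.asarray(y, float), names
        X = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
        return X, np.asarray(y, float), names

    def fit(self, X, y=None):
        Xm, yv, names = self._resolve(X, y)
        n, p = Xm.shape
        cap = min(self.max_components, n - 1, p)
        if self.n_components is None:
            a = select_latent_variables(Xm, yv, max_lv=cap, alpha=self.alpha)
        else:
            a = int(self.n_components)
            if not (1 <= a <= min(n - 1, p)):
                raise ConfigError(
                    f"n_components must lie in [1, min(n-1, p)] = "
                    f"[1, {min(n - 1, p)}], got {a}")
        Xc, yc, x_mean, x_std, y_mean, y_std = _standardize(Xm, yv)
        W, P, T, q = _nipals_pls1(Xc, yc, a)
        a_eff = W.shape[1]
        b_std = _regression_vectors(W, P, q)[-1] if a_eff else np.zeros(p)
        coef = b_std * y_std / x_std
        intercept = y_mean - float(x_mean @ coef)
        self.model_ = PLSModel(tuple(names), W, P, T, q, a_eff, coef,
                               intercept, x_mean, x_std, y_mean, y_std)
        self.coef_ = coef
        self.intercept_ = intercept
        self.n_components_ = a_eff
        return self

    def predict(self, X):
        return self.model_.predict(X)

    def frozen(self) -> "PLSNipals":
        return PLSNipals(n_components=self.n_components_,
                         selected=self.selected)


def fit_pls_nipals(X, y=None, n_lv: int = 1, names=None) -> PLSModel:
    """Fit a PLS1 model with a fixed latent-variable count."""
    est = PLSNipals(n_components=n_lv, selected=names)
    return est.fit(X, y).model_


def loo_press_by_components(X: np.ndarray, y: np.ndarray,
                            max_lv: int) -> np.ndarray:
    """LOO PRESS for 1..max_lv components, one NIPALS fit per fold.

    Nested NIPALS sub-models give all component counts from a single
    max_lv fit per left-out compound.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 3:
        raise InsufficientDataError("LOO needs at least 3 compounds")
    max_lv = min(max_lv, n - 2, p)
    press = np.zeros(max_lv)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xt, yt = X[mask], y[mask]
        Xc, yc, x_mean, x_std, y_mean, y_std = _standardize(Xt, yt)
        W, P, _, q = _nipals_pls1(Xc, yc, max_lv)
        bs = _regression_vectors(W, P, q)
        xi = (X[i] - x_mean) / x_std
        for k in range(max_lv):
            b = bs[min(k, len(bs) - 1)] if bs else np.zeros(p)
            pred = y_mean + y_std * float(xi @ b)
            press[k] += (y[i] - pred) ** 2
    return press


def select_latent_variables(X, y, max_lv: int = 15, alpha: float = 0.25) -> int:
    """Haaland–Thomas choice of the latent-variable count.

    Computes LOO PRESS for 1..max_lv and returns the smallest count k with
    PRESS(k) / min PRESS ≤ F(1−alpha; n, n) — i.e. not significantly worse
    than the best, favouring parsimony.
    """
    if max_lv < 1:
        raise ConfigError("max_lv must be ≥ 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    press = loo_press_by_components(X, y, max_lv)
    f_crit = stats.f.ppf(1 - alpha, n, n)
    best = float(press.min())
    if best == 0:
        return int(np.argmin(press) + 1)
    ratios = press / best
    return int(np.nonzero(ratios <= f_crit)[0][0] + 1)


def loo_q2_pls(X, y, max_lv: int = 15, alpha: float = 0.25):
    """LOO Q² of a PLS model whose LV count is chosen by Haaland–Thomas.

    Returns ``(q2, n_components, press_vector)``; Q² = 1 − PRESS/SStot with
    SStot about the full-sample mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    press = loo_press_by_components(X, y, max_lv)
    n = len(y)
    f_crit = stats.f.ppf(1 - alpha, n, n)
    best = float(press.min())
    if best == 0:
        k = int(np.argmin(press) + 1)
    else:
        k = int(np.nonzero(press / best <= f_crit)[0][0] + 1)
    sstot = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - press[k - 1] / sstot
    return q2, k, press
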