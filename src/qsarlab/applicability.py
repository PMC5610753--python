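"""Leverage-based applicability domain and Williams-plot data.

The applicability domain (AD) of a QSAR model is assessed through the hat
matrix of the training design: a compound's leverage

    h_i = x_i (XᵀX)⁻¹ x_iᵀ

(with X the intercept-augmented, training-standardized design restricted
to the model's descriptors) measures its distance from the training
descriptor centroid.  The warning leverage is fixed at h* = 3(k+1)/n for a
model with k descriptors and n training compounds.  Response outliers are
flagged by internally studentized residuals beyond a configurable limit —
3.0 standard-deviation units by default; 2.5 is also conventional and the
report header records which was used.

Candidate (screening) compounds are projected with the training
standardization and dispersion matrix, so a candidate identical to a
training compound receives that compound's training leverage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DescriptorTable
from .exceptions import CollinearityError, DegenerateInputError
from .linear import LinearModel


def warning_leverage(k: int, n: int) -> float:
    """h* = 3(k+1)/n."""
    return 3.0 * (k + 1) / n


@dataclass
class ADReport:
    """Leverages, residuals and domain flags for training + candidate compounds."""

    ids: list[str]
    is_training: np.ndarray            # bool per row
    leverage: np.ndarray
    h_star: float
    std_residuals: np.ndarray          # NaN for candidates
    residual_limit: float
    k: int
    n: int
    note: str = ""
    flags: pd.DataFrame = field(default=None, repr=False)

    def __post_init__(self):
        high = self.leverage > self.h_star
        outlier = np.abs(self.std_residuals) > self.residual_limit
        outlier &= ~np.isnan(self.std_residuals)
        in_domain = ~high & ~outlier
        self.flags = pd.DataFrame(
            {"in_domain": in_domain, "high_leverage": high,
             "response_outlier": outlier}, index=self.ids)

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"is_training": self.is_training,
                           "leverage": self.leverage,
                           "std_residual": self.std_residuals},
                          index=self.ids)
        return df.join(self.flags)

    def to_json(self, path) -> None:
        payload = {"h_star": self.h_star, "k": self.k, "n": self.n,
                   "residual_limit": self.residual_limit, "note": self.note,
                   "compounds": json.loads(
                       self.frame().to_json(orient="index"))}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def to_csv(self, path) -> None:
        self.frame().rename_axis("compound").to_csv(path)


def _model_names(model):
    if isinstance(model, LinearModel):
        return list(model.names)
    if hasattr(model, "names"):
        return list(model.names)
    return list(model.model_.names)


def leverages(model, training: DescriptorTable,
              candidates: DescriptorTable | None = None,
              residual_limit: float = 3.0) -> ADReport:
    """Leverage AD report for the training set and optional candidates."""
    names = _model_names(model)
    k = len(names)
    n = len(training)
    Xt = training.design(names)
    mean, sd = Xt.mean(axis=0), Xt.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    A = np.column_stack([np.ones(n), (Xt - mean) / sd])
    gram = A.T @ A
    if np.linalg.matrix_rank(gram) < k + 1:
        raise CollinearityError("training design is rank deficient for AD",
                                columns=names)
    Ginv = np.linalg.inv(gram)
    h_train = np.einsum("ij,jk,ik->i", A, Ginv, A)

    sr = standardized_residuals(model, training, leverage=h_train)

    ids = list(training.ids)
    lev = h_train
    is_training = np.ones(n, dtype=bool)
    std_res = sr
    if candidates is not None:
        Xc = (candidates.design(names) - mean) / sd
        Ac = np.column_stack([np.ones(len(candidates)), Xc])
        h_cand = np.einsum("ij,jk,ik->i", Ac, Ginv, Ac)
        ids = ids + list(candidates.ids)
        lev = np.concatenate([h_train, h_cand])
        is_training = np.concatenate([is_training,
                                      np.zeros(len(candidates), dtype=bool)])
        std_res = np.concatenate([sr, np.full(len(candidates), np.nan)])

    note = (f"response-outlier limit {residual_limit} SD"
            + ("" if residual_limit == 3.0 else " (3.0 is the usual default)"))
    return ADReport(ids=ids, is_training=is_training, leverage=lev,
                    h_star=warning_leverage(k, n), std_residuals=std_res,
                    residual_limit=residual_limit, k=k, n=n, note=note)


def standardized_residuals(model, training: DescriptorTable,
                           leverage: np.ndarray | None = None) -> np.ndarray:
    """Internally studentized residuals: r_i / √(MSres · (1 − h_i))."""
    names = _model_names(model)
    k = len(names)
    n = len(training)
    if leverage is None:
        leverage = leverages(model, training).leverage[:n]
    y = training.activity.to_numpy()
    yhat = np.asarray(model.predict(training), dtype=float)
    resid = y - yhat
    dof = n - k - 1
    ss_res = float(resid @ resid)
    ms_res = ss_res / dof if dof > 0 else np.nan
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_res <= 1e-20 * max(1.0, ss_tot):   # numerically perfect fit
        return np.zeros(n)
    at_one = np.isclose(leverage, 1.0)
    if at_one.any():
        bad = [training.ids[i] for i in np.nonzero(at_one)[0]]
        raise DegenerateInputError(
            f"leverage 1 makes the studentized residual undefined for: {bad}")
    return resid / np.sqrt(ms_res * (1.0 - leverage))


def williams_data(adr: ADReport) -> pd.DataFrame:
    """Plottable Williams table: leverage vs standardized residual + limits."""
    df = adr.frame().reset_index(names="compound")
    df["h_star"] = adr.h_star
    df["residual_limit_pos"] = adr.residual_limit
    df["residual_limit_neg"] = -adr.residual_limit
    return df


def williams_plot(adr: ADReport, path=None, ax=None):
    """Render the Williams plot (standardized residual vs leverage)."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    df = adr.frame()
    train = df[df.is_training]
    cand = df[~df.is_training]
    ax.scatter(train.leverage, train.std_residual, label="training",
               edgecolor="k", zorder=3)
    if len(cand):
        ax.scatter(cand.leverage, np.zeros(len(cand)), marker="^",
                   label="candidates", edgecolor="k", zorder=3)
    ax.axvline(adr.h_star, ls="--", c="crimson", label="h*")
    for lim in (adr.residual_limit, -adr.residual_limit):
        ax.axhline(lim, ls=":", c="gray")
    ax.set_xlabel("leverage h")
    ax.set_ylabel("standardized residual")
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
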