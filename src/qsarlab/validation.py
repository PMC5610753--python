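"""Fit, cross-validation and permutation statistics for QSAR models.

Covers the statistics the comparative study tabulates for every model:
calibration R², regression standard error SE and variance ratio F;
leave-one-out Q² = 1 − PRESS/SStot and RMScv = √(PRESS/n); external-set
R²p and SEP; and Y-randomization (activity permutation with full
selection+fit reruns).

LOO convention: by default the descriptor *selection* is frozen (taken
from the fit on the full training set) and only the coefficients are refit
in each fold, matching the workflow sequence in which selection precedes
validation; ``strict=True`` reruns the entire selection per fold, the
unbiased variant.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.base import clone

from .data import DescriptorTable
from .exceptions import (DegenerateInputError, InsufficientDataError,
                         LeakageError, SpecificationError)
from .linear import LinearModel, OLSRegression


def _model_k(model) -> int:
    return len(model.names) if hasattr(model, "names") else len(model.model_.names)


def _predict(model, table: DescriptorTable) -> np.ndarray:
    return np.asarray(model.predict(table), dtype=float)


@dataclass
class ValidationReport:
    """Container mirroring the study's statistics table for one model."""

    r2: float | None = None
    q2: float | None = None
    rmscv: float | None = None
    se: float | None = None
    f_statistic: float | None = None
    f_dof: tuple[int, int] | None = None
    r2p: float | None = None
    sep: float | None = None
    n_train: int | None = None
    n_test: int | None = None
    y_randomization: dict | None = None
    flags: list[str] = field(default_factory=list)

    def finalize(self) -> "ValidationReport":
        if self.r2 is not None and self.q2 is not None and self.q2 > self.r2:
            self.flags.append("Q2 exceeds R2")  # reported, not asserted
        return self

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=float)

    def to_text(self) -> str:
        cells = [("n", self.n_train), ("R2_c", self.r2), ("Q2", self.q2),
                 ("RMScv", self.rmscv), ("F", self.f_statistic),
                 ("SE", self.se), ("R2_p", self.r2p), ("SEP", self.sep)]
        head = "\t".join(c[0] for c in cells)
        row = "\t".join("" if v is None else (str(v) if isinstance(v, int)
                                              else f"{v:.3f}")
                        for _, v in cells)
        lines = [head, row]
        if self.flags:
            lines.append("flags: " + "; ".join(self.flags))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------

def fit_statistics(model, data: DescriptorTable) -> ValidationReport:
    """Calibration R², SE and F for a fitted model on its training table."""
    y = data.activity.to_numpy()
    n = len(y)
    k = _model_k(model)
    if n <= k + 1:
        raise InsufficientDataError(
            f"need n > k+1 = {k + 1} compounds for fit statistics, got {n}")
    yhat = _predict(model, data)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateInputError("activity has zero variance")
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_reg = float(np.sum((yhat - y.mean()) ** 2))
    dof = n - k - 1
    report = ValidationReport(
        r2=1.0 - ss_res / ss_tot,
        se=float(np.sqrt(ss_res / dof)),
        f_statistic=(ss_reg / k) / (ss_res / dof) if ss_res > 0 else np.inf,
        f_dof=(k, dof),
        n_train=n,
    )
    return report.finalize()


# ---------------------------------------------------------------------------
# leave-one-out cross-validation
# ---------------------------------------------------------------------------

def _refittable(model_spec):
    """Coerce a model spec into an unfitted estimator with fit/predict."""
    if isinstance(model_spec, LinearModel):
        return OLSRegression(selected=list(model_spec.names))
    return model_spec


def loo_cross_validate(model_spec, data: DescriptorTable, strict: bool = False):
    """Leave-one-out Q², RMScv and per-compound cross-validated predictions.

    ``model_spec`` is an unfitted estimator (StepwiseMLR, FAMLR, PCRA,
    PLSNipals, GAPLS, OLSRegression) or a fitted LinearModel (its selection
    is reused, coefficients refit per fold).  Default mode freezes the
    selection made on the full table; ``strict=True`` reruns selection in
    every fold.
    """
    y = data.activity.to_numpy()
    n = len(y)
    if n < 3:
        raise InsufficientDataError("LOO needs at least 3 compounds")
    est = _refittable(model_spec)
    if not strict and hasattr(est, "frozen"):
        base = est if _is_fitted(est) else clone(est).fit(data)
        est = base.frozen()
    ids = data.ids
    preds = np.empty(n)
    for i in range(n):
        fold_ids = ids[:i] + ids[i + 1:]
        train = data.select_rows(fold_ids)
        try:
            fitted = clone(est).fit(train)
        except Exception as exc:  # noqa: BLE001 - annotate the failing fold
            raise SpecificationError(
                f"LOO refit failed for left-out compound {ids[i]!r}: {exc}"
            ) from exc
        preds[i] = float(np.asarray(fitted.predict(data.select_rows([ids[i]])))[0])
    press = float(np.sum((y - preds) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - press / ss_tot
    rmscv = float(np.sqrt(press / n))
    return q2, rmscv, dict(zip(ids, preds))


def _is_fitted(est) -> bool:
    return any(k.endswith("_") and not k.endswith("__")
               for k in vars(est))


# ---------------------------------------------------------------------------
# external validation
# ---------------------------------------------------------------------------

def external_validate(model, test: DescriptorTable,
                      training_ids=None) -> tuple[float, float]:
    """R²p and SEP on an external test set.

    R²p uses the test-set mean in SStot; SEP is the root mean squared
    prediction error.  Raises on compound overlap with the training set.
    """
    ids = set(test.ids)
    train_ids = training_ids
    if train_ids is None:
        train_ids = getattr(model, "training_ids", None)
        if train_ids is None and hasattr(model, "model_"):
            train_ids = model.model_.training_ids
    if train_ids:
        overlap = ids & set(train_ids)
        if overlap:
            raise LeakageError(
                f"test set shares compounds with training set: {sorted(overlap)}")
    y = test.activity.to_numpy()
    yhat = _predict(model, test)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateInputError("test activity has zero variance")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot, float(np.sqrt(ss_res / len(y)))


# ---------------------------------------------------------------------------
# Y-randomization
# ---------------------------------------------------------------------------

@dataclass
class YRandomizationResult:
    original: float
    permuted: np.ndarray
    statistic: str
    n_permutations: int
    seed: int

    @property
    def percentile(self) -> float:
        """Empirical percentile of the original statistic (0–100)."""
        return 100.0 * float(np.mean(self.permuted < self.original))

    def summary(self) -> dict:
        return {"statistic": self.statistic, "original": self.original,
                "n_permutations": self.n_permutations, "seed": self.seed,
                "permuted_mean": float(self.permuted.mean()),
                "permuted_max": float(self.permuted.max()),
                "percentile": self.percentile}


def y_randomization(model_spec, data: DescriptorTable, n_perm: int = 100,
                    seed: int = 0, statistic: str = "r2") -> YRandomizationResult:
    """Permute activities and rerun the full selection + fit each time.

    Returns the distribution of the calibration R² (or LOO Q² with
    ``statistic="q2"``) under permutation, plus the original value's
    empirical percentile.  Permutations that fail to fit (e.g. empty
    stepwise selection cannot happen — the mean-only model has R² 0) are
    scored as chance level 0.
    """
    if n_perm < 10:
        raise SpecificationError("n_perm must be ≥ 10")
    if statistic not in ("r2", "q2"):
        raise SpecificationError("statistic must be 'r2' or 'q2'")
    est = _refittable(model_spec)
    rng = np.random.default_rng(seed)
    y = data.activity.to_numpy()

    def stat_for(table):
        fitted = clone(est).fit(table)
        if statistic == "r2":
            yv = table.activity.to_numpy()
            yhat = _predict(fitted, table)
            ss_tot = float(np.sum((yv - yv.mean()) ** 2))
            return 1.0 - float(np.sum((yv - yhat) ** 2)) / ss_tot
        q2, _, _ = loo_cross_validate(fitted, table)
        return q2

    original = stat_for(data)
    permuted = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = y[rng.permutation(len(y))]
        try:
            permuted[b] = stat_for(data.with_activity(y_perm))
        except Exception as exc:  # noqa: BLE001
            warnings.warn(f"permutation {b} failed to fit: {exc}")
            permuted[b] = 0.0
    return YRandomizationResult(original=original, permuted=permuted,
                                statistic=statistic, n_permutations=n_perm,
                                seed=seed)


def validation_report(model_spec, train: DescriptorTable,
                      test: DescriptorTable | None = None,
                      n_perm: int | None = None, seed: int = 0,
                      strict_loo: bool = False) -> ValidationReport:
    """One-stop report: fit statistics, LOO, optional external set and
    Y-randomization, in the layout of the study's comparison table."""
    est = _refittable(model_spec)
    fitted = clone(est).fit(train)
    report = fit_statistics(fitted, train)
    q2, rmscv, _ = loo_cross_validate(fitted, train, strict=strict_loo)
    report.q2, report.rmscv = q2, rmscv
    if test is not None:
        report.r2p, report.sep = external_validate(fitted, test,
                                                   training_ids=train.ids)
        report.n_test = len(test)
    if n_perm:
        yr = y_randomization(est, train, n_perm=n_perm, seed=seed)
        report.y_randomization = yr.summary()
    return report.finalize()
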