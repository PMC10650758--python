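"""Calibration and validation figures of merit.

Internal (cross-validation) statistics: RMSECV, R2cv and RPD, all computed
from the assembled held-out predictions.  External statistics: RMSEP, bias
and SEP on a never-trained validation set.

Conventions: R2 is 1 - SSE/SST against the reference mean, reported as a
percentage (the form chemometrics software prints); the squared Pearson
correlation is reported alongside for transparency.  RPD divides the
reference standard deviation (n-1 denominator) by the RMSECV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._cv import make_folds
from .exceptions import ValidationError
from .pls import fit_pls, predict


@dataclass
class CVResult:
    rmsecv: float
    r2cv_pct: float
    rpd: float
    r_pearson2_pct: float
    y_cv: np.ndarray
    n_components: int
    scheme: str


@dataclass
class ExternalValidationResult:
    rmsep: float
    bias: float  # mean(yhat) - mean(y)
    sep: float   # SD of residuals, n-1 denominator
    residuals: np.ndarray

    def __post_init__(self) -> None:
        # algebraic identity: rmsep^2 = bias^2 + sep^2 (n-1)/n
        n = self.residuals.size
        lhs = self.rmsep**2
        rhs = self.bias**2 + self.sep**2 * (n - 1) / n
        assert abs(lhs - rhs) <= 1e-10 * max(1.0, lhs), "RMSEP decomposition violated"


def r2_pct(y_ref: np.ndarray, y_pred: np.ndarray) -> float:
    """100 * (1 - SSE/SST); can be negative for worse-than-mean predictors."""
    y_ref = np.asarray(y_ref, float)
    y_pred = np.asarray(y_pred, float)
    sst = float(np.sum((y_ref - y_ref.mean()) ** 2))
    if sst == 0:
        raise ValidationError("reference values are constant; R2 undefined")
    sse = float(np.sum((y_pred - y_ref) ** 2))
    return 100.0 * (1.0 - sse / sst)


def rpd(y_ref: np.ndarray, rmsecv: float) -> float:
    """Residual prediction deviation: SD(reference) / RMSECV."""
    y_ref = np.asarray(y_ref, float)
    if y_ref.size < 2:
        raise ValidationError("need at least 2 reference values")
    sd = float(y_ref.std(ddof=1))
    if sd == 0:
        raise ValidationError("reference SD is zero; RPD undefined")
    if rmsecv <= 0:
        raise ValidationError("RMSECV must be positive")
    return sd / rmsecv


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    scheme="loo",
    seed: int | None = None,
) -> CVResult:
    """Cross-validate a PLS calibration; every sample is predicted only by
    models that never saw it."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    folds = make_folds(y, scheme, seed)
    y_cv = np.empty(n)
    for held_out in folds:
        train = np.setdiff1d(np.arange(n), held_out)
        if train.size < 2:
            raise ValidationError("a CV fold leaves fewer than 2 training samples")
        a = min(n_components, train.size - 1, X.shape[1])
        model = fit_pls(X[train], y[train], a)
        y_cv[held_out] = predict(model, X[held_out])
    rmsecv = float(np.sqrt(np.mean((y_cv - y) ** 2)))
    r_p = np.corrcoef(y_cv, y)[0, 1] if np.std(y_cv) > 0 else 0.0
    return CVResult(
        rmsecv=rmsecv,
        r2cv_pct=r2_pct(y, y_cv),
        rpd=rpd(y, rmsecv) if rmsecv > 0 else float("inf"),
        r_pearson2_pct=100.0 * float(r_p) ** 2,
        y_cv=y_cv,
        n_components=n_components,
        scheme="loo" if scheme == "loo" else f"kfold:{scheme[1]}",
    )


def external_validate(y_pred: np.ndarray, y_ref: np.ndarray) -> ExternalValidationResult:
    """RMSEP / bias / SEP on an external validation set."""
    y_pred = np.asarray(y_pred, float).ravel()
    y_ref = np.asarray(y_ref, float).ravel()
    if y_pred.size != y_ref.size:
        raise ValidationError(
            f"prediction/reference length mismatch: {y_pred.size} vs {y_ref.size}"
        )
    if y_pred.size < 2:
        raise ValidationError("need at least 2 samples for external validation")
    residuals = y_pred - y_ref
    rmsep = float(np.sqrt(np.mean(residuals**2)))
    bias = float(residuals.mean())
    sep = float(residuals.std(ddof=1))
    return ExternalValidationResult(rmsep=rmsep, bias=bias, sep=sep, residuals=residuals)
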