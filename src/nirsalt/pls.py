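"""Partial least squares regression (PLS1) by NIPALS with X-block deflation.

The model projects centered spectra onto latent components that maximize
covariance with the response, then regresses on the component scores.  With
as many components as the rank of the centered predictor matrix the fit
coincides with ordinary least squares; with fewer it is a regularized,
chemometrics-standard calibration.

Outlier screening follows the usual practice of measuring each sample's
Mahalanobis distance in the latent-score space and cutting at a chi-square
quantile of the squared distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import solve_triangular
from scipy.stats import chi2

from ._cv import make_folds
from .exceptions import ValidationError

_RANK_TOL = 1e-12  # relative residual-energy floor at which deflation stops

MODEL_FORMAT = "nirsalt-pls/1"


@dataclass
class PLSModel:
    """Fitted calibration: centering/scaling constants, NIPALS factors and
    the equivalent regression vector in the original column space."""

    x_mean: np.ndarray
    y_mean: float
    x_scale: np.ndarray | None
    weights: np.ndarray      # W, (p, A)
    x_loadings: np.ndarray   # P, (p, A)
    y_loadings: np.ndarray   # q, (A,)
    coef: np.ndarray         # b, (p,); yhat = y_mean + (x - x_mean)/scale . b
    n_components: int
    scores: np.ndarray = field(repr=False)  # training scores T, (n, A)
    training_meta: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.x_mean.size


def _prepare(X: np.ndarray, y: np.ndarray, scale: bool):
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    else:
        sd = None
    return Xc, y - y_mean, x_mean, y_mean, sd


def _nipals_path(Xc: np.ndarray, yc: np.ndarray, n_components: int):
    """NIPALS factorization with X deflation.

    Returns (W, P, q, T, B) where B[:, a-1] is the regression vector using
    the first a components.  Stops early (rank exhaustion) when the
    covariance or score energy underflows relative to the initial scale.
    """
    n, p = Xc.shape
    Xa = Xc.copy()
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    B = np.zeros((p, n_components))
    R = np.zeros((p, n_components))  # columns of W (P'W)^-1, built incrementally
    x_energy0 = float(np.sum(Xc * Xc)) or 1.0
    b = np.zeros(p)
    a_used = 0
    for a in range(n_components):
        w = Xa.T @ yc
        wnorm = np.linalg.norm(w)
        if wnorm <= np.sqrt(_RANK_TOL * x_energy0) * max(np.linalg.norm(yc), 1e-300):
            break
        w /= wnorm
        t = Xa @ w
        tt = float(t @ t)
        if tt <= _RANK_TOL * x_energy0:
            break
        pa = Xa.T @ t / tt
        qa = float(yc @ t) / tt
        Xa -= np.outer(t, pa)
        W[:, a], P[:, a], q[a], T[:, a] = w, pa, qa, t
        r = w - R[:, :a] @ (P[:, :a].T @ w)
        R[:, a] = r
        b = b + qa * r
        B[:, a] = b
        a_used = a + 1
    return (
        W[:, :a_used],
        P[:, :a_used],
        q[:a_used],
        T[:, :a_used],
        B[:, :a_used],
    )


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    scale: bool = False,
    sample_ids: Sequence[str] | None = None,
    meta: dict | None = None,
) -> PLSModel:
    """Fit a PLS1 calibration.

    ``n_components`` may not exceed ``min(n_samples - 1, n_features)``;
    should the numerical rank turn out lower (e.g. duplicated columns), the
    factorization simply stops there and the model records the count
    actually extracted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 2:
        raise ValidationError("need at least 2 samples")
    if y.size != n:
        raise ValidationError(f"y length {y.size} does not match {n} samples")
    if np.allclose(y, y[0]):
        raise ValidationError("response has zero variance; nothing to calibrate")
    cap = min(n - 1, p)
    if not 1 <= n_components <= cap:
        raise ValidationError(
            f"n_components must be in [1, {cap}] for a {n}x{p} matrix, "
            f"got {n_components}"
        )
    Xc, yc, x_mean, y_mean, sd = _prepare(X, y, scale)
    W, P, q, T, B = _nipals_path(Xc, yc, n_components)
    if W.shape[1] == 0:
        raise ValidationError("predictors carry no covariance with the response")
    meta = dict(meta or {})
    if sample_ids is not None:
        meta["sample_ids"] = [str(s) for s in sample_ids]
    return PLSModel(
        x_mean=x_mean,
        y_mean=y_mean,
        x_scale=sd,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coef=B[:, -1],
        n_components=W.shape[1],
        scores=T,
        training_meta=meta,
    )


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """yhat = y_mean + (x - x_mean) . b (after the training scaling)."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_features:
        raise ValidationError(
            f"column mismatch: model has {model.n_features} wavenumbers, "
            f"input has {X_new.shape[1]}"
        )
    Xc = X_new - model.x_mean
    if model.x_scale is not None:
        Xc = Xc / model.x_scale
    return model.y_mean + Xc @ model.coef


def transform(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Project new spectra onto the model's latent-score space."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_features:
        raise ValidationError("column mismatch with training data")
    Xc = X_new - model.x_mean
    if model.x_scale is not None:
        Xc = Xc / model.x_scale
    # R = W (P'W)^{-1}; P'W is unit-diagonal upper triangular
    PtW = model.x_loadings.T @ model.weights
    R = solve_triangular(PtW, model.weights.T, lower=False, trans="T").T
    return Xc @ R


def mahalanobis_distances(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Mahalanobis distance of each sample in score space.

    Uses the training-score covariance (n-1 denominator), so the training
    set itself satisfies mean(d^2) = A (n-1)/n exactly.
    """
    T_new = transform(model, X)
    S = np.cov(model.scores, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    try:
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "singular score covariance; refit with fewer components"
        ) from exc
    d2 = np.einsum("ij,jk,ik->i", T_new, Sinv, T_new)
    return np.sqrt(np.maximum(d2, 0.0))


@dataclass
class OutlierReport:
    """Screening record: every sample's distance, the cutoff, the removals."""

    distances: np.ndarray
    threshold: float
    removed_ids: list[str]
    removed_indices: list[int]
    rule: str


def _parse_threshold_rule(rule, n_components: int) -> tuple[float, str]:
    """Distance-scale cutoff from a named policy or an explicit number."""
    if isinstance(rule, str):
        if rule.startswith("chi2:"):
            quantile = float(rule.split(":", 1)[1])
            if not 0 < quantile < 1:
                raise ValidationError(f"chi-square quantile must be in (0,1): {quantile}")
            return float(np.sqrt(chi2.ppf(quantile, df=n_components))), rule
        raise ValidationError(f"unknown threshold rule {rule!r}")
    thr = float(rule)
    if thr <= 0:
        raise ValidationError("explicit distance threshold must be positive")
    return thr, f"fixed:{thr:g}"


def remove_outliers(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    threshold_rule="chi2:0.999",
    sample_ids: Sequence[str] | None = None,
    iterative: bool = False,
    max_removed_fraction: float = 0.5,
):
    """Screen calibration samples by score-space Mahalanobis distance.

    Single pass by default; ``iterative=True`` refits and re-screens until
    no sample exceeds the cutoff.  Returns ``(X_kept, y_kept, report)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    ids = [str(s) for s in sample_ids] if sample_ids is not None else [str(i) for i in range(n)]
    keep = np.arange(n)
    removed: list[int] = []
    while True:
        model = fit_pls(X[keep], y[keep], min(n_components, min(keep.size - 1, X.shape[1])))
        d = mahalanobis_distances(model, X[keep])
        threshold, rule_name = _parse_threshold_rule(threshold_rule, model.n_components)
        over = np.where(d > threshold)[0]
        removed.extend(keep[over].tolist())
        if len(removed) > max_removed_fraction * n:
            raise ValidationError(
                f"outlier rule {rule_name} would remove {len(removed)}/{n} samples "
                f"(> {max_removed_fraction:.0%}); aborting — check the data or the rule"
            )
        keep = np.setdiff1d(keep, keep[over])
        if over.size == 0 or not iterative:
            break
    # distances reported for the full input against the final model
    final_model = fit_pls(X[keep], y[keep], min(n_components, min(keep.size - 1, X.shape[1])))
    d_all = mahalanobis_distances(final_model, X)
    threshold, rule_name = _parse_threshold_rule(threshold_rule, final_model.n_components)
    report = OutlierReport(
        distances=d_all,
        threshold=threshold,
        removed_ids=[ids[i] for i in sorted(removed)],
        removed_indices=sorted(removed),
        rule=rule_name,
    )
    return X[keep], y[keep], report


def select_components(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int,
    cv_scheme="loo",
    seed: int | None = None,
    parsimony_factor: float = 1.02,
):
    """Pick the component count by cross-validated RMSE with a parsimony rule.

    The chosen count is the smallest whose RMSECV is within
    ``parsimony_factor`` of the curve minimum (never 0: one component is the
    floor).  Returns ``(chosen, rmsecv_curve)`` with the full curve for
    reporting.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    cap = min(n - 1, p)
    if not 1 <= max_components <= cap:
        raise ValidationError(f"max_components must be in [1, {cap}]")
    folds = make_folds(y, cv_scheme, seed)
    y_cv = np.full((n, max_components), np.nan)
    for held_out in folds:
        train = np.setdiff1d(np.arange(n), held_out)
        if train.size < 2:
            raise ValidationError("a CV fold leaves fewer than 2 training samples")
        Xc, yc, x_mean, y_mean, _ = _prepare(X[train], y[train], scale=False)
        _, _, _, _, B = _nipals_path(Xc, yc, min(max_components, train.size - 1))
        pred = y_mean + (X[held_out] - x_mean) @ B  # (n_held, A_eff)
        a_eff = B.shape[1]
        y_cv[held_out, :a_eff] = pred
        if a_eff < max_components:  # rank exhausted: constant beyond
            y_cv[held_out, a_eff:] = pred[:, [-1]]
    rmsecv_curve = np.sqrt(np.nanmean((y_cv - y[:, None]) ** 2, axis=0))
    best = float(rmsecv_curve.min())
    chosen = int(np.argmax(rmsecv_curve <= parsimony_factor * best)) + 1
    return chosen, rmsecv_curve


# ---------------------------------------------------------------------------
# Serialization: versioned plain-text container
# ---------------------------------------------------------------------------


def save_model(model: PLSModel, path) -> None:
    """Write a calibration to a versioned plain-text file."""
    payload = {
        "format": MODEL_FORMAT,
        "n_components": model.n_components,
        "y_mean": model.y_mean,
        "x_mean": model.x_mean.tolist(),
        "x_scale": None if model.x_scale is None else model.x_scale.tolist(),
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "coef": model.coef.tolist(),
        "scores": model.scores.tolist(),
        "training_meta": model.training_meta,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> PLSModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != MODEL_FORMAT:
        raise ValidationError(
            f"unsupported model format {payload.get('format')!r}; expected {MODEL_FORMAT}"
        )
    return PLSModel(
        x_mean=np.array(payload["x_mean"]),
        y_mean=float(payload["y_mean"]),
        x_scale=None if payload["x_scale"] is None else np.array(payload["x_scale"]),
        weights=np.array(payload["weights"]),
        x_loadings=np.array(payload["x_loadings"]),
        y_loadings=np.array(payload["y_loadings"]),
        coef=np.array(payload["coef"]),
        n_components=int(payload["n_components"]),
        scores=np.array(payload["scores"]),
        training_meta=payload["training_meta"],
    )
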