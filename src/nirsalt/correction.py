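"""Matrix-shift diagnosis and indirect sodium determination.

A calibration built on NaCl-only cured hams, applied to hams cured with
NaCl/KCl blends, predicts values that track the potassium content rather
than the sodium content (the NIR-active salt signal in those samples is
dominated by K+, which penetrates the muscle more readily than Na+).  The
procedure here quantifies that shift and then converts the K-dominated
prediction into an estimated sodium content through a global correction
factor: the ratio of the group-mean wet-chemistry sodium to the group-mean
predicted value, 0.63 for the published cohort.

Report columns are rounded half-up to two decimals; summaries are always
computed from the unrounded values.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal

import numpy as np

from .exceptions import ValidationError
from .io import ReferenceTable


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), as printed tables use.

    The value is first quantized at 8 decimals (half-even) to shed binary
    floating-point noise, then rounded half-up at the requested precision.
    """
    d = Decimal(repr(float(x))).quantize(Decimal("1e-8"), ROUND_HALF_EVEN)
    return float(d.quantize(Decimal(1).scaleb(-ndigits), ROUND_HALF_UP))


@dataclass
class CorrectionRow:
    """One external-validation record in the published table's shape."""

    sample_id: str
    na_real: float
    k_real: float
    na_plus_k: float
    predicted: float
    cf: float        # per-sample na_real / predicted, rounded
    na_calc: float   # global CF x predicted, rounded


@dataclass
class CorrectionSummary:
    """Group-level record: global correction factor and bias bookkeeping.

    ``mean_na_calc`` and ``mean_bias`` use the *rounded* global factor — the
    published convention; with the raw ratio-of-means factor the bias is
    identically zero.
    """

    global_cf: float       # rounded to 2 decimals (the published convention)
    global_cf_raw: float   # mean(na_real) / mean(predicted), unrounded
    mean_na_real: float
    mean_k_real: float
    mean_predicted: float
    mean_na_calc: float    # global_cf x mean_predicted
    mean_bias: float       # mean_na_real - mean_na_calc
    rmse_vs_na: float
    rmse_vs_k: float
    n: int


@dataclass
class MatrixShiftReport:
    """Diagnosis of a prediction set against both candidate analytes."""

    rmse_vs_na: float
    rmse_vs_k: float
    rmsecv_calibration: float
    threshold_factor: float
    shift_toward_k: bool

    @property
    def verdict(self) -> str:
        return "matrix shift toward K" if self.shift_toward_k else "no matrix shift"


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(a, float) - np.asarray(b, float)) ** 2)))


def global_correction_factor(na_real, predicted) -> tuple[float, float]:
    """Ratio of means mean(na_real)/mean(predicted): ``(raw, rounded)``.

    The ratio of means — not the mean of per-sample ratios — is what the
    published 0.63 reproduces from the cohort means.
    """
    na_real = np.asarray(na_real, float).ravel()
    predicted = np.asarray(predicted, float).ravel()
    if na_real.size != predicted.size:
        raise ValidationError("na_real and predicted must have equal length")
    if np.any(predicted <= 0):
        raise ValidationError("predicted values must be strictly positive")
    raw = float(na_real.mean() / predicted.mean())
    return raw, round_half_up(raw, 2)


def per_sample_cf(na_real: float, predicted: float) -> float:
    """Per-sample correction factor na_real/predicted, rounded to 2 decimals."""
    if predicted <= 0:
        raise ValidationError("predicted value must be strictly positive")
    return round_half_up(na_real / predicted, 2)


def calculated_sodium(predicted: float, global_cf: float) -> float:
    """Indirect sodium estimate: global CF x predicted, rounded to 2 decimals."""
    if predicted < 0 or global_cf < 0:
        raise ValidationError("inputs must be non-negative")
    return round_half_up(predicted * global_cf, 2)


def build_correction_table(
    reference: ReferenceTable,
    predicted,
    global_cf: float | None = None,
) -> tuple[list[CorrectionRow], CorrectionSummary]:
    """Per-sample correction table plus group summary.

    ``reference`` must carry both Na and K for every sample (the low-sodium
    cohort).  ``global_cf`` overrides the factor used in the calculated-
    sodium column (e.g. to force the published 0.63); by default it is the
    rounded ratio of means of this very data.
    """
    predicted = np.asarray(predicted, float).ravel()
    if predicted.size != len(reference):
        raise ValidationError(
            f"{predicted.size} predictions for {len(reference)} reference samples"
        )
    if np.any(~np.isfinite(reference.k_pct)):
        missing = [s for s, k in zip(reference.sample_ids, reference.k_pct) if not np.isfinite(k)]
        raise ValidationError(f"samples lack a potassium value: {missing[:5]}")
    cf_raw, cf_rounded = global_correction_factor(reference.na_pct, predicted)
    cf_used = cf_rounded if global_cf is None else float(global_cf)
    rows = [
        CorrectionRow(
            sample_id=s,
            na_real=round_half_up(na, 2),
            k_real=round_half_up(k, 2),
            na_plus_k=round_half_up(na + k, 2),
            predicted=round_half_up(p, 2),
            cf=per_sample_cf(na, p),
            na_calc=calculated_sodium(p, cf_used),
        )
        for s, na, k, p in zip(
            reference.sample_ids, reference.na_pct, reference.k_pct, predicted
        )
    ]
    mean_pred = float(predicted.mean())
    summary = CorrectionSummary(
        global_cf=cf_used,
        global_cf_raw=cf_raw,
        mean_na_real=float(reference.na_pct.mean()),
        mean_k_real=float(reference.k_pct.mean()),
        mean_predicted=mean_pred,
        mean_na_calc=cf_used * mean_pred,
        mean_bias=float(reference.na_pct.mean()) - cf_used * mean_pred,
        rmse_vs_na=_rmse(predicted, reference.na_pct),
        rmse_vs_k=_rmse(predicted, reference.k_pct),
        n=len(reference),
    )
    return rows, summary


def matrix_shift_report(
    predicted,
    na_real,
    k_real,
    rmsecv_calibration: float,
    threshold_factor: float = 1.5,
) -> MatrixShiftReport:
    """Flag a matrix shift toward potassium.

    The shift is declared when the predictions sit closer to K than to Na
    AND the Na error exceeds ``threshold_factor`` x the calibration RMSECV —
    i.e. the model is doing far worse against its nominal analyte than its
    own cross-validation says it should.
    """
    if rmsecv_calibration <= 0:
        raise ValidationError("rmsecv_calibration must be positive")
    rmse_na = _rmse(predicted, na_real)
    rmse_k = _rmse(predicted, k_real)
    return MatrixShiftReport(
        rmse_vs_na=rmse_na,
        rmse_vs_k=rmse_k,
        rmsecv_calibration=float(rmsecv_calibration),
        threshold_factor=float(threshold_factor),
        shift_toward_k=(rmse_k < rmse_na) and (rmse_na > threshold_factor * rmsecv_calibration),
    )


def correction_table_frame(rows: list[CorrectionRow]):
    """Rows as a DataFrame with the published column layout."""
    import pandas as pd

    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in rows],
            "na_real": [r.na_real for r in rows],
            "k_real": [r.k_real for r in rows],
            "na_plus_k": [r.na_plus_k for r in rows],
            "predicted": [r.predicted for r in rows],
            "cf": [r.cf for r in rows],
            "na_calc": [r.na_calc for r in rows],
        }
    )
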