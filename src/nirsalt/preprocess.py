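"""Spectral preprocessing: replicate averaging, Savitzky-Golay derivatives,
region selection and point lookup.

The derivative is taken with respect to wavenumber on the grid re-expressed
ascending internally, so a band whose absorbance rises with wavenumber has a
positive derivative regardless of the stored (descending) column order.
Units of a first derivative are absorbance per cm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .exceptions import ValidationError
from .io import SpectraMatrix


@dataclass
class PreprocessConfig:
    """Savitzky-Golay settings and optional spectral-region restriction.

    The 17-point window with a quadratic polynomial is a common chemometrics
    default at 16 cm^-1 spacing (a ~260 cm^-1 smoothing support); results
    depend on it, so every report echoes these values.
    """

    sg_window: int = 17
    sg_polyorder: int = 2
    derivative_order: int = 1
    region: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window < self.sg_polyorder + 1:
            raise ValidationError(
                f"sg_window must be odd and >= polyorder+1, got {self.sg_window}"
            )
        if self.derivative_order > self.sg_polyorder:
            raise ValidationError("derivative_order must not exceed sg_polyorder")
        if self.region is not None and self.region[0] >= self.region[1]:
            raise ValidationError("region must satisfy low < high")


def average_replicates(spectra: SpectraMatrix) -> SpectraMatrix:
    """Arithmetic mean of each sample's replicate measurements.

    Sample order follows first occurrence among the measurements.
    """
    if spectra.replicate_of is None:
        raise ValidationError("spectra carry no replicate mapping; nothing to average")
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, m in enumerate(spectra.sample_ids):
        s = spectra.replicate_of[m]
        if s not in groups:
            groups[s] = []
            order.append(s)
        groups[s].append(i)
    for s, idx in groups.items():
        if not idx:
            raise ValidationError(f"sample {s!r} has no measurements")
    mean = np.vstack([spectra.absorbance[groups[s]].mean(axis=0) for s in order])
    return SpectraMatrix(order, spectra.wavenumbers.copy(), mean, None)


def sg_derivative(spectra: SpectraMatrix, config: PreprocessConfig) -> SpectraMatrix:
    """Per-row Savitzky-Golay derivative along the wavenumber axis.

    Edge points are handled by fitting the boundary-window polynomial
    (``mode='interp'``), so the derivative is defined on the full grid.
    """
    if config.sg_window > spectra.wavenumbers.size:
        raise ValidationError(
            f"sg_window {config.sg_window} exceeds the {spectra.wavenumbers.size}-point grid"
        )
    # flip to ascending so d/d(wavenumber) carries the physical sign
    asc = spectra.absorbance[:, ::-1]
    deriv = savgol_filter(
        asc,
        window_length=config.sg_window,
        polyorder=config.sg_polyorder,
        deriv=config.derivative_order,
        delta=spectra.spacing,
        axis=1,
        mode="interp",
    )
    out = spectra.copy_with(absorbance=np.ascontiguousarray(deriv[:, ::-1]))
    return out


def select_region(spectra: SpectraMatrix, low_cm1: float, high_cm1: float) -> SpectraMatrix:
    """Restrict columns to wavenumbers in ``[low, high]`` inclusive."""
    if low_cm1 >= high_cm1:
        raise ValidationError("region bounds must satisfy low < high")
    mask = (spectra.wavenumbers >= low_cm1) & (spectra.wavenumbers <= high_cm1)
    if not mask.any():
        raise ValidationError(
            f"region [{low_cm1:g}, {high_cm1:g}] cm^-1 does not overlap the grid "
            f"[{spectra.wavenumbers[-1]:g}, {spectra.wavenumbers[0]:g}]"
        )
    return spectra.copy_with(
        wavenumbers=spectra.wavenumbers[mask],
        absorbance=spectra.absorbance[:, mask],
    )


def value_at(spectra: SpectraMatrix, wavenumber_cm1: float) -> tuple[np.ndarray, float]:
    """Column at the grid point nearest the requested wavenumber.

    Returns ``(values, grid_wavenumber_used)``.  A tie between two equally
    near grid points is broken toward the higher wavenumber.
    """
    dist = np.abs(spectra.wavenumbers - wavenumber_cm1)
    # grid is descending, so argmin's first-occurrence rule picks the
    # higher wavenumber on an exact tie
    j = int(np.argmin(dist))
    return spectra.absorbance[:, j].copy(), float(spectra.wavenumbers[j])


def apply_pipeline(spectra: SpectraMatrix, config: PreprocessConfig) -> SpectraMatrix:
    """Average replicates (if mapped), differentiate, then restrict region."""
    out = spectra
    if out.replicate_of is not None:
        out = average_replicates(out)
    out = sg_derivative(out, config)
    if config.region is not None:
        out = select_region(out, *config.region)
    return out
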