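"""Synthetic two-cohort NIR datasets for the cured-ham salt problem.

The real spectra are confidential, so this module generates stand-in data
with the structure the analysis relies on:

* two cohorts of samples — G1, cured with NaCl only (Na 1.21-3.10 %, mean
  1.99, SD 0.45, n = 310) and G2, cured with NaCl/KCl blends (Na
  0.77-1.25 %, mean 0.93, SD 0.11; K 1.04-1.80 %, mean 1.47, SD 0.21,
  n = 60) — drawn from truncated normals matching those statistics;
* duplicate spectra per sample with independent scatter and noise;
* a salt-sensitive water band whose first-derivative signature peaks at the
  grid point nearest 5537 cm^-1 and whose magnitude follows an *effective*
  NIR-active salt concentration c_eff = w_na*Na + w_k*K.  The default
  weights encode the surface-penetration asymmetry between the ions: in G1
  the signal is carried by Na (w = (1, 0)), in G2 by K (w = (0, 1)), which
  is the mechanism behind the prediction-tracks-potassium matrix shift.

The forward model is phenomenological (Gaussian absorption bands on a
smooth baseline, multiplicative scatter, white noise), not radiative
transfer; see the methods note for what it does and does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import ReferenceTable, SpectraMatrix, default_grid


@dataclass
class CohortSpec:
    """Truncated-normal concentration model for one cohort.

    ``k_*`` parameters are ``None`` for cohorts cured without potassium.
    ``na_k_correlation`` couples the two truncated normals through the
    underlying bivariate Gaussian (the published low-sodium cohort shows a
    Na-K correlation of about 0.7).
    """

    name: str
    n_samples: int
    na_mean: float
    na_sd: float
    na_min: float
    na_max: float
    k_mean: float | None = None
    k_sd: float | None = None
    k_min: float | None = None
    k_max: float | None = None
    na_k_correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError(f"cohort {self.name}: n_samples must be >= 1")
        if not self.na_min <= self.na_mean <= self.na_max:
            raise ValidationError(f"cohort {self.name}: need na_min <= na_mean <= na_max")
        if self.na_sd < 0:
            raise ValidationError(f"cohort {self.name}: na_sd must be >= 0")
        if self.has_k:
            if not self.k_min <= self.k_mean <= self.k_max:  # type: ignore[operator]
                raise ValidationError(f"cohort {self.name}: need k_min <= k_mean <= k_max")
            if self.k_sd < 0:  # type: ignore[operator]
                raise ValidationError(f"cohort {self.name}: k_sd must be >= 0")
        if not -1.0 <= self.na_k_correlation <= 1.0:
            raise ValidationError("na_k_correlation must lie in [-1, 1]")

    @property
    def has_k(self) -> bool:
        return self.k_mean is not None


def g1_default(n_samples: int = 310) -> CohortSpec:
    """NaCl-only cohort matching the published calibration-set statistics."""
    return CohortSpec("G1", n_samples, na_mean=1.99, na_sd=0.45, na_min=1.21, na_max=3.10)


def g2_default(n_samples: int = 60) -> CohortSpec:
    """Low-sodium NaCl/KCl cohort matching the published validation set."""
    return CohortSpec(
        "G2",
        n_samples,
        na_mean=0.93,
        na_sd=0.11,
        na_min=0.77,
        na_max=1.25,
        k_mean=1.47,
        k_sd=0.21,
        k_min=1.04,
        k_max=1.80,
        na_k_correlation=0.7,
    )


@dataclass
class SpectralForwardConfig:
    """Parameters of the phenomenological spectrum model.

    Spectrum = smooth baseline + fixed Gaussian bands with per-sample
    amplitude jitter + a salt band whose amplitude grows linearly (and whose
    center shifts weakly) with c_eff, all passed through per-replicate
    multiplicative scatter and white noise.

    The salt band (center 5636 cm^-1, width 100 cm^-1) is placed so the
    extremum of its first derivative falls at 5536 cm^-1 — the grid point
    nearest the classic 5537 cm^-1 salt-in-water correlation frequency.
    The fixed bands sketch the water/fat NIR background: water OH bands near
    6900 and 5155 cm^-1, CH features near 8400, 5800 and 4330 cm^-1.
    """

    grid: np.ndarray = field(default_factory=default_grid)
    band_centers: tuple[float, ...] = (6900.0, 5155.0, 8400.0, 5800.0, 4330.0)
    band_widths: tuple[float, ...] = (220.0, 160.0, 350.0, 130.0, 110.0)
    band_amplitudes: tuple[float, ...] = (0.55, 0.85, 0.12, 0.20, 0.30)
    band_jitter_sds: tuple[float, ...] = (0.03, 0.04, 0.015, 0.02, 0.03)
    salt_band_center: float = 5636.0
    salt_band_width: float = 100.0
    salt_band_base_amplitude: float = 0.05
    salt_band_jitter_sd: float = 0.007
    salt_shift_coeff: float = 1.0       # cm^-1 per % effective salt
    salt_intensity_coeff: float = 0.05  # absorbance per % effective salt
    w_na_G1: float = 1.0
    w_k_G1: float = 0.0
    w_na_G2: float = 0.0
    w_k_G2: float = 1.0
    baseline_amplitude: float = 0.10
    scatter_slope_sd: float = 0.01
    scatter_offset_sd: float = 0.005
    noise_sd: float = 2e-3
    replicates_per_sample: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        for w in (self.w_na_G1, self.w_k_G1, self.w_na_G2, self.w_k_G2):
            if w < 0:
                raise ValidationError("cohort signal weights must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if len({len(self.band_centers), len(self.band_widths),
                len(self.band_amplitudes), len(self.band_jitter_sds)}) != 1:
            raise ValidationError("band parameter tuples must have equal length")
        if self.replicates_per_sample < 1:
            raise ValidationError("replicates_per_sample must be >= 1")

    def noiseless(self) -> "SpectralForwardConfig":
        """Copy with every nuisance magnitude set to zero."""
        return replace(
            self,
            band_jitter_sds=tuple(0.0 for _ in self.band_jitter_sds),
            salt_band_jitter_sd=0.0,
            scatter_slope_sd=0.0,
            scatter_offset_sd=0.0,
            noise_sd=0.0,
        )

    def effective_salt(self, na_pct: float, k_pct: float, cohort: str) -> float:
        """c_eff = w_na*Na + w_k*K with the cohort's weights (absent K = 0)."""
        k = 0.0 if k_pct is None or np.isnan(k_pct) else float(k_pct)
        if cohort == "G1":
            return self.w_na_G1 * float(na_pct) + self.w_k_G1 * k
        if cohort == "G2":
            return self.w_na_G2 * float(na_pct) + self.w_k_G2 * k
        raise ValidationError(f"unknown cohort {cohort!r}")


@dataclass
class SyntheticDataset:
    """Spectra + reference chemistry + generator ground truth."""

    spectra: SpectraMatrix
    reference: ReferenceTable
    truth: pd.DataFrame


def _underlying_params(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Gaussian (mu, sigma) whose [lo, hi]-truncation has the given *mean*.

    The cohort statistics are observed sample moments, so the generator must
    reproduce them after truncation, not before: with an asymmetric box a
    plain normal at the printed parameters drifts (e.g. ~0.016 % high in Na
    for the low-sodium cohort).  Only the mean is corrected; sigma stays at
    the printed SD, so the truncated draws run a few percent tighter than
    the printed dispersion — the price of keeping a bell-shaped
    distribution inside the observed range (matching the SD too would
    require a near-uniform shape).
    """
    from scipy.optimize import brentq
    from scipy.stats import truncnorm

    if lo > hi:
        raise ValidationError(f"infeasible truncation: min {lo} > max {hi}")
    if not lo <= mean <= hi:
        raise ValidationError("target mean must lie inside the truncation box")

    def truncated_mean_error(mu):
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return float(truncnorm.mean(a, b, loc=mu, scale=sd)) - mean

    half_width = hi - lo
    mu = brentq(truncated_mean_error, lo - half_width, hi + half_width, xtol=1e-12)
    return float(mu), float(sd)


def sample_concentrations(spec: CohortSpec, rng_seed) -> np.ndarray:
    """Draw ``(n_samples, 2)`` concentrations [Na %, K %] for a cohort.

    Rejection sampling from a (bivariate) normal truncated to the cohort's
    boxes, with the underlying Gaussian chosen so the *truncated* marginals
    reproduce the cohort's mean and SD.  The K column is NaN for cohorts
    without potassium.  ``rng_seed`` may be an integer seed or a
    ``numpy.random.Generator``.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    n = spec.n_samples
    out = np.empty((n, 2))
    if not spec.has_k:
        out[:, 0] = _truncated_normal(rng, n, spec.na_mean, spec.na_sd, spec.na_min, spec.na_max)
        out[:, 1] = np.nan
        return out
    if spec.na_sd == 0 and spec.k_sd == 0:
        out[:, 0], out[:, 1] = spec.na_mean, spec.k_mean
        return out
    # Gaussian copula with exact truncated-normal marginals: correlated
    # standard normals mapped through Phi, then through each marginal's
    # truncated-normal quantile function.  (Joint rejection inside the
    # rectangle would distort the marginal statistics badly at rho ~ 0.7.)
    from scipy.special import ndtr
    from scipy.stats import truncnorm

    rho = spec.na_k_correlation
    z = rng.multivariate_normal(
        [0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n, method="cholesky"
    )
    u = np.clip(ndtr(z), 1e-12, 1 - 1e-12)
    for col, (mean, sd, lo, hi) in enumerate(
        [
            (spec.na_mean, spec.na_sd, spec.na_min, spec.na_max),
            (spec.k_mean, spec.k_sd, spec.k_min, spec.k_max),
        ]
    ):
        if sd == 0:
            out[:, col] = mean
            continue
        mu, s = _underlying_params(mean, sd, lo, hi)
        a, b = (lo - mu) / s, (hi - mu) / s
        out[:, col] = truncnorm.ppf(u[:, col], a, b, loc=mu, scale=s)
    return out


def _truncated_normal(rng, n, mean, sd, lo, hi) -> np.ndarray:
    if sd == 0:
        if lo > hi:
            raise ValidationError(f"infeasible truncation: min {lo} > max {hi}")
        return np.full(n, mean)
    mu, s = _underlying_params(mean, sd, lo, hi)
    out = np.empty(n)
    filled = 0
    for _ in range(10_000):
        draw = rng.normal(mu, s, size=max(4 * n, 64))
        good = draw[(draw >= lo) & (draw <= hi)]
        take = min(good.size, n - filled)
        out[filled : filled + take] = good[:take]
        filled += take
        if filled == n:
            return out
    raise ValidationError("truncation box too improbable; rejection cap reached")


def _gauss(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / width) ** 2)


def _baseline(config: SpectralForwardConfig) -> np.ndarray:
    x = config.grid
    span = x.max() - x.min()
    return config.baseline_amplitude * (0.2 + 0.8 * (x.max() - x) / span)


def clean_spectrum(c_eff: float, config: SpectralForwardConfig,
                   band_jitter: np.ndarray | None = None,
                   salt_jitter: float = 0.0) -> np.ndarray:
    """Noise-free spectrum for a given effective salt concentration."""
    x = config.grid
    y = _baseline(config)
    jit = np.zeros(len(config.band_centers)) if band_jitter is None else band_jitter
    for c, w, a, dj in zip(config.band_centers, config.band_widths,
                           config.band_amplitudes, jit):
        y = y + (a + dj) * _gauss(x, c, w)
    amp = config.salt_band_base_amplitude + config.salt_intensity_coeff * c_eff + salt_jitter
    center = config.salt_band_center + config.salt_shift_coeff * c_eff
    return y + amp * _gauss(x, center, config.salt_band_width)


def simulate_spectrum(na_pct: float, k_pct: float, cohort: str,
                      config: SpectralForwardConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """One measured spectrum row: forward model + scatter + noise.

    Deterministic given the generator state; with all nuisance magnitudes
    zero the output is the pure baseline-plus-bands shape.
    """
    if na_pct < 0 or (k_pct is not None and not np.isnan(k_pct) and k_pct < 0):
        raise ValidationError("concentrations must be >= 0")
    c_eff = config.effective_salt(na_pct, k_pct, cohort)
    band_jitter = rng.normal(0.0, config.band_jitter_sds)
    salt_jitter = rng.normal(0.0, config.salt_band_jitter_sd) if config.salt_band_jitter_sd else 0.0
    y = clean_spectrum(c_eff, config, band_jitter, salt_jitter)
    return _measure(y, config, rng)


def _measure(clean: np.ndarray, config: SpectralForwardConfig,
             rng: np.random.Generator) -> np.ndarray:
    slope = rng.normal(0.0, config.scatter_slope_sd) if config.scatter_slope_sd else 0.0
    offset = rng.normal(0.0, config.scatter_offset_sd) if config.scatter_offset_sd else 0.0
    y = (1.0 + slope) * clean + offset
    if config.noise_sd:
        y = y + rng.normal(0.0, config.noise_sd, size=y.shape)
    return y


def generate_dataset(cohorts: list[CohortSpec],
                     config: SpectralForwardConfig | None = None,
                     seed: int | None = None) -> SyntheticDataset:
    """Full synthetic dataset: replicated spectra, reference table, truth.

    All randomness derives from one master seed (``seed`` overrides
    ``config.seed``); reruns are bit-identical.  Replicates share their
    sample's chemistry and band jitter but get independent scatter and
    noise, mimicking repeated probe placements on one slice.
    """
    if not cohorts:
        raise ValidationError("need at least one cohort")
    config = config or SpectralForwardConfig()
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    streams = ss.spawn(len(cohorts))

    meas_ids: list[str] = []
    replicate_of: dict[str, str] = {}
    rows: list[np.ndarray] = []
    ref_ids: list[str] = []
    ref_cohort: list[str] = []
    ref_na: list[float] = []
    ref_k: list[float] = []
    truth_rows: list[dict] = []

    for spec, stream in zip(cohorts, streams):
        rng = np.random.default_rng(stream)
        conc = sample_concentrations(spec, rng)
        for i in range(spec.n_samples):
            sid = f"{spec.name}-{i + 1:03d}"
            na, k = conc[i]
            c_eff = config.effective_salt(na, k, spec.name)
            band_jitter = rng.normal(0.0, config.band_jitter_sds)
            salt_jitter = (
                rng.normal(0.0, config.salt_band_jitter_sd)
                if config.salt_band_jitter_sd else 0.0
            )
            clean = clean_spectrum(c_eff, config, band_jitter, salt_jitter)
            for r in range(config.replicates_per_sample):
                mid = f"{sid}_r{r + 1}"
                meas_ids.append(mid)
                replicate_of[mid] = sid
                rows.append(_measure(clean, config, rng))
            ref_ids.append(sid)
            ref_cohort.append(spec.name)
            ref_na.append(float(na))
            ref_k.append(float(k))
            truth_rows.append(
                {
                    "sample_id": sid,
                    "cohort": spec.name,
                    "na_pct": float(na),
                    "k_pct": float(k),
                    "c_eff": float(c_eff),
                    "salt_band_jitter": float(salt_jitter),
                    **{f"band_jitter_{j}": float(v) for j, v in enumerate(band_jitter)},
                }
            )

    spectra = SpectraMatrix(meas_ids, config.grid.copy(), np.vstack(rows), replicate_of)
    reference = ReferenceTable(ref_ids, ref_cohort, np.array(ref_na), np.array(ref_k))
    return SyntheticDataset(spectra, reference, pd.DataFrame(truth_rows))
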