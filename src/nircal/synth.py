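"""Synthetic NIR reflectance spectra with the statistical structure the
calibration pipeline assumes.

Mixing is linear in pseudo-absorbance A = -log10(R): each component
contributes Gaussian bands scaled by its mass fraction, on top of a linear
baseline, a per-series random offset, multiplicative scatter and additive
noise.  Reflectance is recovered as 10**(-A), floored away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import REFLECTANCE_FLOOR, META_COLUMNS, SpectrumSet, WavenumberGrid
from .protocol import COMPONENTS, BlendComposition, ProtocolMatrix, composition_for_level

CALIBRATION_REGION = (7500.0, 4000.0)  # analyte must be identifiable here

#: guard band (cm^-1) around the analyte's signature band that excipient
#: bands may not enter, so the analyte stays identifiable
_EXCLUSION_CM1 = 250.0


@dataclass(frozen=True)
class GaussianBand:
    center_cm1: float
    width_cm1: float
    amplitude: float  # absorbance per unit mass fraction

    def evaluate(self, wavenumbers: np.ndarray) -> np.ndarray:
        z = (wavenumbers - self.center_cm1) / self.width_cm1
        return self.amplitude * np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class PureSpectraLibrary:
    """Per-component Gaussian band lists (absorbance per unit mass fraction)."""

    bands: dict[str, tuple[GaussianBand, ...]]

    def pure_spectrum(self, component: str, wavenumbers: np.ndarray) -> np.ndarray:
        out = np.zeros_like(wavenumbers, dtype=float)
        for band in self.bands[component]:
            out += band.evaluate(wavenumbers)
        return out

    def mixture_absorbance(
        self, composition: BlendComposition, wavenumbers: np.ndarray
    ) -> np.ndarray:
        fractions = composition.mass_fractions()
        out = np.zeros_like(wavenumbers, dtype=float)
        for component, w in fractions.items():
            out += w * self.pure_spectrum(component, wavenumbers)
        return out


@dataclass(frozen=True)
class NoiseModel:
    """Noise/variability magnitudes for spectrum simulation.

    sigma_additive      additive absorbance noise sd, i.i.d. per point
    sigma_scatter       sd of the per-spectrum multiplicative factor (around 1)
    sigma_series        sd of the per-series absorbance baseline random effect
    baseline_slope_range  half-range of the per-spectrum linear baseline
                          slope, absorbance per 1e4 cm^-1 (slope ~ U(-r, r))
    baseline_offset     constant absorbance offset shared by all spectra
    """

    # defaults frozen after a one-off simulation study so the downstream
    # validation lands near ~1 % repeatability RSD at the protocol sizes
    sigma_additive: float = 0.007
    sigma_scatter: float = 0.035
    sigma_series: float = 0.0045
    baseline_slope_range: float = 0.03
    baseline_offset: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_additive", "sigma_scatter", "sigma_series",
                     "baseline_slope_range"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def noiseless(cls, baseline_offset: float = 0.30) -> "NoiseModel":
        return cls(sigma_additive=0.0, sigma_scatter=0.0, sigma_series=0.0,
                   baseline_slope_range=0.0, baseline_offset=baseline_offset)


def make_pure_library(seed: int, n_bands_per_component: int = 3) -> PureSpectraLibrary:
    """Draw a random band library; deterministic for a fixed seed.

    The analyte (meloxicam) always receives one signature band inside the
    7500-4000 cm^-1 calibration region, and excipient bands are kept at
    least 250 cm^-1 away from its center so the analyte direction is
    identifiable after mean-centering.
    """
    if n_bands_per_component < 1:
        raise ValueError("n_bands_per_component must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = 4200.0, 10500.0

    signature_center = rng.uniform(4600.0, 7200.0)
    bands: dict[str, tuple[GaussianBand, ...]] = {}
    for component in COMPONENTS:
        comp_bands: list[GaussianBand] = []
        for k in range(n_bands_per_component):
            if component == "meloxicam" and k == 0:
                center = signature_center
            else:
                center = rng.uniform(lo, hi)
                while abs(center - signature_center) < _EXCLUSION_CM1:
                    center = rng.uniform(lo, hi)
            width = rng.uniform(80.0, 220.0)
            amplitude = rng.uniform(0.4, 1.4)
            if component == "meloxicam" and k == 0:
                amplitude = rng.uniform(1.0, 1.8)  # strong signature band
            comp_bands.append(GaussianBand(center, width, amplitude))
        bands[component] = tuple(comp_bands)
    return PureSpectraLibrary(bands=bands)


def simulate_spectrum(
    composition: BlendComposition,
    lib: PureSpectraLibrary,
    noise: NoiseModel,
    rng: np.random.Generator,
    series_delta: float = 0.0,
    grid: WavenumberGrid | None = None,
) -> np.ndarray:
    """One reflectance row on ``grid`` (default instrument grid).

    A = sum_c w_c*eps_c + b0 + b1*(nu/1e4) + delta_series + e,  A' = m*A,
    R = 10**(-A') floored at 1e-6.  ``series_delta`` is the per-series
    random effect, drawn once per series by the caller.
    """
    grid = grid or WavenumberGrid()
    nu = grid.values
    a_det = lib.mixture_absorbance(composition, nu) + noise.baseline_offset
    if np.max(a_det) > -np.log10(REFLECTANCE_FLOOR):
        raise ValueError(
            "composition absorbance would underflow reflectance "
            f"(max A={np.max(a_det):.2f} > {-np.log10(REFLECTANCE_FLOOR):.0f})"
        )
    slope = rng.uniform(-noise.baseline_slope_range, noise.baseline_slope_range) \
        if noise.baseline_slope_range > 0 else 0.0
    e = rng.normal(0.0, noise.sigma_additive, size=nu.shape) \
        if noise.sigma_additive > 0 else 0.0
    m = rng.normal(1.0, noise.sigma_scatter) if noise.sigma_scatter > 0 else 1.0
    a = a_det + slope * (nu / 1e4) + series_delta + e
    reflectance = 10.0 ** (-m * a)
    return np.clip(reflectance, REFLECTANCE_FLOOR, None)


def generate_protocol_dataset(
    protocol: ProtocolMatrix,
    lib: PureSpectraLibrary,
    noise: NoiseModel,
    seed: int,
    grid: WavenumberGrid | None = None,
) -> tuple[SpectrumSet, SpectrumSet]:
    """Simulate one spectrum per protocol entry.

    Series random effects are drawn once per (role, series) and shared by
    all spectra of that series; validation batches are independent of
    calibration batches.  Fully reproducible from ``seed``.
    """
    grid = grid or WavenumberGrid()
    rng = np.random.default_rng(seed)

    deltas: dict[tuple[str, int], float] = {}
    for role in ("cal", "val"):
        for s in range(1, protocol.n_series + 1):
            deltas[(role, s)] = (
                rng.normal(0.0, noise.sigma_series) if noise.sigma_series > 0 else 0.0
            )

    def build(entries) -> SpectrumSet:
        rows, meta = [], []
        for e in entries:
            comp = composition_for_level(e.meloxicam_pct_ww)
            rows.append(
                simulate_spectrum(
                    comp, lib, noise, rng,
                    series_delta=deltas[(e.role, e.series)], grid=grid,
                )
            )
            meta.append({
                "sample_id": e.sample_id,
                "role": e.role,
                "series": e.series,
                "level_index": e.level_index,
                "nominal_pct_ww": e.meloxicam_pct_ww,
            })
        return SpectrumSet(
            grid=grid,
            values=np.vstack(rows),
            meta=pd.DataFrame(meta, columns=META_COLUMNS),
        )

    calibration = build(protocol.calibration_entries())
    validation = build(protocol.validation_entries())
    return calibration, validation
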