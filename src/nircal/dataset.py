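"""Core spectral data containers: wavenumber grid and spectrum sets."""

from __future__ import annotations

import numpy as np
import pandas as pd

META_COLUMNS = ["sample_id", "role", "series", "level_index", "nominal_pct_ww"]

REFLECTANCE_FLOOR = 1e-6  # keeps -log10(R) finite


class WavenumberGrid:
    """Descending wavenumber grid in cm^-1.

    Instrument grids are uniform (default 11000 -> 4000 at 8 cm^-1,
    876 points); derived grids (e.g. after resolution reduction with a
    partial trailing block) may be irregular.
    """

    def __init__(
        self,
        start_cm1: float = 11000.0,
        end_cm1: float = 4000.0,
        step_cm1: float = 8.0,
    ) -> None:
        if step_cm1 <= 0:
            raise ValueError("step_cm1 must be positive")
        if start_cm1 <= end_cm1:
            raise ValueError("grid must be descending: start_cm1 > end_cm1")
        n, rem = divmod(start_cm1 - end_cm1, step_cm1)
        if abs(rem) > 1e-9 and abs(rem - step_cm1) > 1e-9:
            raise ValueError("(start - end) must be divisible by step")
        n = round((start_cm1 - end_cm1) / step_cm1) + 1
        self._values = start_cm1 - step_cm1 * np.arange(n, dtype=float)
        self._values.flags.writeable = False

    @classmethod
    def from_values(cls, values: np.ndarray) -> "WavenumberGrid":
        values = np.asarray(values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("grid needs a 1-D array of at least 2 points")
        if not np.all(np.diff(values) < 0):
            raise ValueError("grid values must be strictly descending")
        obj = cls.__new__(cls)
        obj._values = values.copy()
        obj._values.flags.writeable = False
        return obj

    @property
    def values(self) -> np.ndarray:
        return self._values

    @property
    def n_points(self) -> int:
        return self._values.size

    @property
    def start_cm1(self) -> float:
        return float(self._values[0])

    @property
    def end_cm1(self) -> float:
        return float(self._values[-1])

    @property
    def is_uniform(self) -> bool:
        steps = -np.diff(self._values)
        return bool(np.allclose(steps, steps[0], rtol=0, atol=1e-6))

    @property
    def step_cm1(self) -> float:
        """Spacing in cm^-1; only defined for uniform grids."""
        if not self.is_uniform:
            raise ValueError("grid is not uniform; step is undefined")
        return float(self._values[0] - self._values[1])

    def __len__(self) -> int:
        return self.n_points

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return self._values.shape == other._values.shape and bool(
            np.allclose(self._values, other._values, rtol=0, atol=1e-9)
        )

    def __repr__(self) -> str:
        return (
            f"WavenumberGrid({self.start_cm1:g}..{self.end_cm1:g} cm-1, "
            f"{self.n_points} points)"
        )


class SpectrumSet:
    """A stack of spectra sharing one grid, plus per-sample metadata.

    ``values`` holds reflectance for raw instrument data, but carries
    whatever units a pre-treatment produces (absorbance, derivative, ...)
    downstream; positivity is only enforced for raw reflectance via
    ``check_reflectance``.  ``meta`` has one row per spectrum with columns
    sample_id, role, series, level_index, nominal_pct_ww.
    """

    def __init__(
        self,
        grid: WavenumberGrid,
        values: np.ndarray,
        meta: pd.DataFrame,
        check_reflectance: bool = True,
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (samples x points)")
        if values.shape[1] != grid.n_points:
            raise ValueError(
                f"values have {values.shape[1]} columns, grid has {grid.n_points} points"
            )
        if len(meta) != values.shape[0]:
            raise ValueError("metadata row count does not match spectrum count")
        missing = [c for c in META_COLUMNS if c not in meta.columns]
        if missing:
            raise ValueError(f"metadata missing columns {missing}")
        if meta["sample_id"].duplicated().any():
            dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample_ids: {sorted(set(dupes))}")
        if check_reflectance and np.any(values <= 0):
            raise ValueError("reflectance must be strictly positive")
        self.grid = grid
        self.values = values
        self.meta = meta.reset_index(drop=True)

    # alias used where the raw-instrument meaning is intended
    @property
    def reflectance(self) -> np.ndarray:
        return self.values

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def y(self) -> np.ndarray:
        """Nominal analyte concentrations (% w/w)."""
        return self.meta["nominal_pct_ww"].to_numpy(dtype=float)

    def absorbance(self) -> np.ndarray:
        """Pseudo-absorbance -log10(values)."""
        return -np.log10(self.values)

    def with_values(
        self, values: np.ndarray, grid: WavenumberGrid | None = None
    ) -> "SpectrumSet":
        """New set with replaced spectral values; metadata passes through."""
        return SpectrumSet(
            grid=grid if grid is not None else self.grid,
            values=values,
            meta=self.meta,
            check_reflectance=False,
        )

    def subset(self, mask: np.ndarray) -> "SpectrumSet":
        return SpectrumSet(
            grid=self.grid,
            values=self.values[mask],
            meta=self.meta.loc[mask],
            check_reflectance=False,
        )
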