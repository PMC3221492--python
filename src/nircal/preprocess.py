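"""Spectral pre-treatments and region selection.

All operations are strictly per-spectrum (row-wise) and pass metadata
through untouched.  The fixed pipeline order is:

    -log10(R) transform -> region selection -> pre-treatment

applied by :func:`apply_pipeline`; regression centering happens later
inside the model fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import savgol_filter

from .dataset import SpectrumSet, WavenumberGrid

METHODS = (
    "none",
    "smoothing_moving_average",
    "smoothing_savitzky_golay",
    "unit_vector_normalization",
    "minmax_normalization",
    "snv",
    "norris_gap_first_derivative",
    "norris_gap_second_derivative",
    "deresolve",
)

DEFAULT_REGION = (7500.0, 4000.0)


@dataclass(frozen=True)
class PreprocessSpec:
    """One pre-treatment plus the spectral region it runs on.

    Defaults follow the study conventions: Savitzky-Golay window of 11
    points with a second-order polynomial, Norris gap/segment of 5 points,
    resolution-reduction factor 2, region 7500-4000 cm^-1.
    """

    method: str = "none"
    window_points: int = 11
    poly_order: int = 2
    derivative_order: int = 0
    gap_points: int = 5
    segment_points: int = 5
    deresolve_factor: int = 2
    region: tuple[float, float] = DEFAULT_REGION

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.window_points % 2 == 0 or self.window_points <= self.poly_order:
            raise ValueError("window_points must be odd and > poly_order")
        if self.derivative_order not in (0, 1, 2):
            raise ValueError("derivative_order must be 0, 1 or 2")
        if self.derivative_order > self.poly_order:
            raise ValueError("derivative_order must be <= poly_order")
        if self.gap_points < 1:
            raise ValueError("gap_points must be >= 1")
        if self.segment_points % 2 == 0 or self.segment_points < 1:
            raise ValueError("segment_points must be odd and >= 1")
        if self.deresolve_factor < 2 or int(self.deresolve_factor) != self.deresolve_factor:
            raise ValueError("deresolve_factor must be an integer >= 2")
        high, low = self.region
        if high <= low:
            raise ValueError("region must be (high_cm1, low_cm1) with high > low")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["region"] = list(d["region"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessSpec":
        d = dict(d)
        if "region" in d:
            d["region"] = tuple(d["region"])
        return cls(**d)

    def label(self) -> str:
        return self.method


def select_region(s: SpectrumSet, high_cm1: float, low_cm1: float) -> SpectrumSet:
    """Keep exactly the grid points nu with low <= nu <= high (inclusive)."""
    nu = s.grid.values
    mask = (nu >= low_cm1) & (nu <= high_cm1)
    if not mask.any():
        raise ValueError(
            f"region ({high_cm1}, {low_cm1}) cm^-1 does not overlap grid "
            f"[{s.grid.end_cm1}, {s.grid.start_cm1}]"
        )
    grid = WavenumberGrid.from_values(nu[mask])
    return s.with_values(s.values[:, mask], grid=grid)


def moving_average(s: SpectrumSet, window_points: int = 11) -> SpectrumSet:
    """Centered unweighted moving average; edges use shrunken windows."""
    if window_points % 2 == 0 or window_points < 1:
        raise ValueError("window_points must be odd and >= 1")
    n = s.grid.n_points
    if window_points > n:
        raise ValueError(f"window ({window_points}) larger than spectrum ({n} points)")
    half = window_points // 2
    kernel = np.ones(window_points)
    counts = np.convolve(np.ones(n), kernel, mode="same")
    out = np.empty_like(s.values)
    for i, row in enumerate(s.values):
        out[i] = np.convolve(row, kernel, mode="same") / counts
    return s.with_values(out)


def savitzky_golay(
    s: SpectrumSet,
    window_points: int = 11,
    poly_order: int = 2,
    derivative_order: int = 0,
) -> SpectrumSet:
    """Savitzky-Golay smoothing/derivative.

    Local least-squares polynomial per centered window; derivatives are
    taken along the stored point order and scaled by step^-order, so units
    are absorbance * cm^order.  Edges fit the polynomial on the first/last
    full window and evaluate it at the edge offsets.
    """
    if window_points % 2 == 0 or window_points <= poly_order:
        raise ValueError("window_points must be odd and > poly_order")
    if derivative_order > poly_order:
        raise ValueError("derivative_order must be <= poly_order")
    if window_points > s.grid.n_points:
        raise ValueError("window larger than spectrum")
    h = s.grid.step_cm1  # requires uniform grid
    out = savgol_filter(
        s.values,
        window_length=window_points,
        polyorder=poly_order,
        deriv=derivative_order,
        delta=h,
        axis=1,
        mode="interp",
    )
    return s.with_values(out)


def _segment_means(x: np.ndarray, segment_points: int) -> np.ndarray:
    """Mean over a centered window of segment_points; NaN where incomplete."""
    n = x.shape[-1]
    half = segment_points // 2
    kernel = np.ones(segment_points) / segment_points
    means = np.apply_along_axis(
        lambda r: np.convolve(r, kernel, mode="same"), -1, x
    )
    means[..., :half] = np.nan
    if half > 0:
        means[..., -half:] = np.nan
    return means


def norris_gap_derivative(
    s: SpectrumSet, gap_points: int = 5, segment_points: int = 5, order: int = 1
) -> SpectrumSet:
    """Norris gap derivative on segment-averaged points.

    With segment means xbar_j and gap g (points), step h (cm^-1):
    order 1: (xbar_{i+g} - xbar_{i-g}) / (2 g h)
    order 2: (xbar_{i-g} - 2 xbar_i + xbar_{i+g}) / (g h)^2
    Edge positions replicate the nearest computable value.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if gap_points < 1:
        raise ValueError("gap_points must be >= 1")
    if segment_points % 2 == 0:
        raise ValueError("segment_points must be odd")
    n = s.grid.n_points
    half = segment_points // 2
    reach = gap_points + half
    if 2 * reach >= n:
        raise ValueError(
            f"gap ({gap_points}) + segment ({segment_points}) exceed spectrum length {n}"
        )
    h = s.grid.step_cm1
    xbar = _segment_means(s.values, segment_points)
    g = gap_points
    out = np.full_like(s.values, np.nan)
    lo, hi = reach, n - reach  # interior output indices [lo, hi)
    if order == 1:
        out[:, lo:hi] = (xbar[:, lo + g:hi + g] - xbar[:, lo - g:hi - g]) / (2 * g * h)
    else:
        out[:, lo:hi] = (
            xbar[:, lo - g:hi - g] - 2 * xbar[:, lo:hi] + xbar[:, lo + g:hi + g]
        ) / (g * h) ** 2
    out[:, :lo] = out[:, [lo]]
    out[:, hi:] = out[:, [hi - 1]]
    return s.with_values(out)


def snv(s: SpectrumSet) -> SpectrumSet:
    """Standard normal variate: per-spectrum (x - mean) / sd, sd with n-1."""
    means = s.values.mean(axis=1, keepdims=True)
    sds = s.values.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sds.ravel() == 0)
    if bad.size:
        ids = s.meta["sample_id"].iloc[bad].tolist()
        raise ValueError(f"constant spectrum (sd=0), cannot apply SNV: {ids}")
    return s.with_values((s.values - means) / sds)


def unit_vector_normalize(s: SpectrumSet) -> SpectrumSet:
    """Scale each spectrum to unit Euclidean norm."""
    norms = np.linalg.norm(s.values, axis=1, keepdims=True)
    bad = np.flatnonzero(norms.ravel() == 0)
    if bad.size:
        ids = s.meta["sample_id"].iloc[bad].tolist()
        raise ValueError(f"zero-norm spectrum, cannot normalize: {ids}")
    return s.with_values(s.values / norms)


def minmax_normalize(s: SpectrumSet) -> SpectrumSet:
    """Map each spectrum affinely onto [0, 1]."""
    mins = s.values.min(axis=1, keepdims=True)
    maxs = s.values.max(axis=1, keepdims=True)
    span = maxs - mins
    bad = np.flatnonzero(span.ravel() == 0)
    if bad.size:
        ids = s.meta["sample_id"].iloc[bad].tolist()
        raise ValueError(f"constant spectrum (max=min), cannot min/max normalize: {ids}")
    return s.with_values((s.values - mins) / span)


def deresolve(s: SpectrumSet, factor: int = 2) -> SpectrumSet:
    """Reduce resolution by boxcar-averaging non-overlapping blocks of
    ``factor`` points; a trailing partial block is averaged as-is.  The
    grid becomes the block-center (mean) wavenumbers.
    """
    if int(factor) != factor or factor < 2:
        raise ValueError("factor must be an integer >= 2")
    n = s.grid.n_points
    if factor >= n:
        raise ValueError(f"factor ({factor}) must be smaller than spectrum length ({n})")
    edges = np.arange(0, n, factor)
    sums = np.add.reduceat(s.values, edges, axis=1)
    counts = np.minimum(edges + factor, n) - edges
    out = sums / counts
    new_nu = np.add.reduceat(s.grid.values, edges) / counts
    return s.with_values(out, grid=WavenumberGrid.from_values(new_nu))


def apply_pretreatment(s: SpectrumSet, spec: PreprocessSpec) -> SpectrumSet:
    """Dispatch a single pre-treatment by spec.method."""
    m = spec.method
    if m == "none":
        return s
    if m == "smoothing_moving_average":
        return moving_average(s, spec.window_points)
    if m == "smoothing_savitzky_golay":
        return savitzky_golay(s, spec.window_points, spec.poly_order, spec.derivative_order)
    if m == "unit_vector_normalization":
        return unit_vector_normalize(s)
    if m == "minmax_normalization":
        return minmax_normalize(s)
    if m == "snv":
        return snv(s)
    if m == "norris_gap_first_derivative":
        return norris_gap_derivative(s, spec.gap_points, spec.segment_points, order=1)
    if m == "norris_gap_second_derivative":
        return norris_gap_derivative(s, spec.gap_points, spec.segment_points, order=2)
    if m == "deresolve":
        return deresolve(s, spec.deresolve_factor)
    raise ValueError(f"unknown method {m!r}")


def apply_pipeline(
    s: SpectrumSet, spec: PreprocessSpec, to_absorbance: bool = True
) -> SpectrumSet:
    """Full fixed-order pipeline: absorbance -> region -> pre-treatment."""
    if to_absorbance:
        s = s.with_values(s.absorbance())
    high, low = spec.region
    s = select_region(s, high, low)
    return apply_pretreatment(s, spec)


def standard_specs(region: tuple[float, float] = DEFAULT_REGION) -> list[PreprocessSpec]:
    """The nine scanned pre-treatments (a)-(i), in canonical order."""
    return [PreprocessSpec(method=m, region=region) for m in METHODS]
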