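"""Wide-CSV persistence for spectrum sets.

Layout: optional ``#``-prefixed header comment lines (tool version, config
hash, seed), then a CSV whose first five columns are the sample metadata
(sample_id, role, series, level_index, nominal_pct_ww) followed by one
column per grid wavenumber, labelled with its cm^-1 value and stored in
descending (instrument) order.  Readers accept ascending files and
normalize them, logging the flip.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import META_COLUMNS, SpectrumSet, WavenumberGrid

log = logging.getLogger("nircal")


def _format_wavenumber(v: float) -> str:
    return f"{v:.6g}"


def write_spectrumset(
    s: SpectrumSet,
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    path = Path(path)
    cols = [_format_wavenumber(v) for v in s.grid.values]
    frame = pd.concat(
        [s.meta[META_COLUMNS].reset_index(drop=True),
         pd.DataFrame(s.values, columns=cols)],
        axis=1,
    )
    buf = _io.StringIO()
    buf.write(f"# nircal {__version__}")
    if header_comment:
        buf.write(f" {header_comment}")
    buf.write("\n")
    frame.to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def read_spectrumset(path: str | Path) -> SpectrumSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    try:
        frame = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no data rows") from None
    if frame.empty:
        raise ValueError(f"{path}: no data rows")
    missing = [c for c in META_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")

    spec_cols = [c for c in frame.columns if c not in META_COLUMNS]
    if len(spec_cols) < 2:
        raise ValueError(f"{path}: fewer than 2 wavenumber columns")
    try:
        nu = np.array([float(c) for c in spec_cols])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric wavenumber column label: {exc}") from None

    values = frame[spec_cols].to_numpy(dtype=float)
    diffs = np.diff(nu)
    if np.all(diffs < 0):
        pass  # canonical descending order
    elif np.all(diffs > 0):
        log.info("%s: wavenumber columns ascending; flipping to instrument order", path)
        nu = nu[::-1]
        values = values[:, ::-1]
    else:
        bad = _first_out_of_order(nu)
        raise ValueError(
            f"{path}: wavenumber columns out of order; first offending column "
            f"'{spec_cols[bad]}'"
        )

    grid = WavenumberGrid.from_values(nu)
    if not grid.is_uniform:
        raise ValueError(f"{path}: non-uniform wavenumber grid")
    bad_rows = np.flatnonzero(~np.isfinite(values).all(axis=1))
    if bad_rows.size:
        # +2: one header comment line assumed absent from pandas numbering;
        # report CSV data row numbers (1-based after the column header)
        raise ValueError(
            f"{path}: malformed/missing spectral values in data rows "
            f"{(bad_rows + 1).tolist()}"
        )
    return SpectrumSet(grid=grid, values=values, meta=frame[META_COLUMNS])


def _first_out_of_order(nu: np.ndarray) -> int:
    """Index of the first column breaking monotonicity (given mixed order)."""
    descending = nu[1] < nu[0]
    d = np.diff(nu)
    viol = np.flatnonzero(d >= 0) if descending else np.flatnonzero(d <= 0)
    return int(viol[0]) + 1
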