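"""Latent-variable calibration: PLS1 (NIPALS) and PCR.

X is mean-centered but not variance-scaled (spectroscopy convention);
y is the analyte concentration in % w/w.  A fitted model exposes the
prediction vector b(h) for any factor count h up to the achieved maximum,
so factor-wise figures of merit come from a single fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset import SpectrumSet, WavenumberGrid
from .preprocess import PreprocessSpec, apply_pipeline

_DEFLATION_RTOL = 1e-12  # stop when t't falls below this fraction of factor 1's


@dataclass
class CalibrationModel:
    """Fitted PLS or PCR calibration.

    Predictions with h factors depend only on the first h factor triples;
    ``coef(h)`` reconstructs the regression vector on centered data.
    """

    method: str  # "pls" | "pcr"
    x_mean: np.ndarray
    y_mean: float
    n_factors: int  # achieved maximum
    # PLS: weights W, loadings P (p x H), y-loadings q (H,)
    # PCR: loadings V (p x H), singular values s (H,), score coefs gamma (H,)
    _A: np.ndarray = field(repr=False, default=None)
    _B: np.ndarray = field(repr=False, default=None)
    _c: np.ndarray = field(repr=False, default=None)
    h_selected: int | None = None
    preprocess: PreprocessSpec | None = None
    grid_values: np.ndarray | None = None
    scores: np.ndarray | None = field(repr=False, default=None)  # n x H, not serialized

    def coef(self, h: int | None = None) -> np.ndarray:
        """Regression vector b(h) for centered X (h defaults to h_selected)."""
        h = self._resolve_h(h)
        if h == 0:
            return np.zeros_like(self.x_mean)
        if self.method == "pls":
            W, P, q = self._A[:, :h], self._B[:, :h], self._c[:h]
            return W @ np.linalg.solve(P.T @ W, q)
        V, gamma = self._A[:, :h], self._c[:h]
        return V @ gamma

    def predict(self, X_new: np.ndarray, h: int | None = None) -> np.ndarray:
        """y_hat = y_mean + (x - x_mean) @ b(h) per sample."""
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.x_mean.size:
            raise ValueError(
                f"grid mismatch: model has {self.x_mean.size} points, "
                f"input has {X_new.shape[1]}"
            )
        return self.y_mean + (X_new - self.x_mean) @ self.coef(h)

    def predict_spectra(self, s: SpectrumSet, h: int | None = None) -> np.ndarray:
        """Apply the stored preprocessing to raw spectra, then predict."""
        if self.preprocess is None:
            raise ValueError("model carries no preprocessing spec")
        proc = apply_pipeline(s, self.preprocess)
        if self.grid_values is not None and not np.allclose(
            proc.grid.values, self.grid_values, rtol=0, atol=1e-9
        ):
            raise ValueError("grid mismatch between model and new spectra")
        return self.predict(proc.values, h)

    def _resolve_h(self, h: int | None) -> int:
        if h is None:
            h = self.h_selected if self.h_selected is not None else self.n_factors
        if not 0 <= h <= self.n_factors:
            raise ValueError(f"h={h} outside available factors 0..{self.n_factors}")
        return int(h)

    # -- persistence ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "n_factors": self.n_factors,
            "A": self._A.tolist(),
            "B": self._B.tolist() if self._B is not None else None,
            "c": self._c.tolist(),
            "h_selected": self.h_selected,
            "preprocess": self.preprocess.to_dict() if self.preprocess else None,
            "grid_values": (
                self.grid_values.tolist() if self.grid_values is not None else None
            ),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            method=d["method"],
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            n_factors=int(d["n_factors"]),
            _A=np.asarray(d["A"], dtype=float),
            _B=np.asarray(d["B"], dtype=float) if d.get("B") is not None else None,
            _c=np.asarray(d["c"], dtype=float),
            h_selected=d.get("h_selected"),
            preprocess=(
                PreprocessSpec.from_dict(d["preprocess"]) if d.get("preprocess") else None
            ),
            grid_values=(
                np.asarray(d["grid_values"], dtype=float)
                if d.get("grid_values") is not None
                else None
            ),
        )

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _check_xy(X: np.ndarray, y: np.ndarray, max_factors: int) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D with one row per y entry")
    if X.shape[0] < max_factors + 1:
        raise ValueError(
            f"need n_samples >= max_factors + 1 ({X.shape[0]} < {max_factors + 1})"
        )
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance; nothing to calibrate")
    return X, y


def fit_pls(X: np.ndarray, y: np.ndarray, max_factors: int = 10) -> CalibrationModel:
    """Univariate-response PLS1 via NIPALS with X and y deflation.

    Stops early (reporting the achieved factor count) once the score
    energy t't drops below 1e-12 of the first factor's.
    """
    X, y = _check_xy(X, y, max_factors)
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    p = X.shape[1]
    W = np.zeros((p, max_factors))
    P = np.zeros((p, max_factors))
    q = np.zeros(max_factors)
    T = np.zeros((X.shape[0], max_factors))
    tt1 = None
    achieved = 0
    for h in range(max_factors):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w /= nw
        t = Xc @ w
        tt = float(t @ t)
        if tt1 is None:
            tt1 = tt
        if tt <= _DEFLATION_RTOL * tt1:
            break
        p_h = Xc.T @ t / tt
        q_h = float(yc @ t / tt)
        Xc = Xc - np.outer(t, p_h)
        yc = yc - q_h * t
        W[:, h], P[:, h], q[h], T[:, h] = w, p_h, q_h, t
        achieved = h + 1
    if achieved == 0:
        raise ValueError("no PLS factor could be extracted (X'y is zero)")
    return CalibrationModel(
        method="pls",
        x_mean=x_mean,
        y_mean=y_mean,
        n_factors=achieved,
        _A=W[:, :achieved],
        _B=P[:, :achieved],
        _c=q[:achieved],
        scores=T[:, :achieved],
    )


def fit_pcr(X: np.ndarray, y: np.ndarray, max_factors: int = 10) -> CalibrationModel:
    """Principal component regression: SVD of centered X, components by
    decreasing singular value, y regressed on the leading scores."""
    X, y = _check_xy(X, y, max_factors)
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # drop numerically null directions
    keep = s > s[0] * 1e-12 if s.size and s[0] > 0 else np.zeros(s.size, bool)
    rank = int(keep.sum())
    if rank == 0:
        raise ValueError("X is numerically zero after centering")
    h_max = min(max_factors, rank)
    V = Vt[:h_max].T
    s_h = s[:h_max]
    gamma = (U[:, :h_max].T @ yc) / s_h  # per-component coef on loadings
    return CalibrationModel(
        method="pcr",
        x_mean=x_mean,
        y_mean=y_mean,
        n_factors=h_max,
        _A=V,
        _B=None,
        _c=gamma,
        scores=U[:, :h_max] * s_h,
    )


def fit_method(
    X: np.ndarray, y: np.ndarray, method: str, max_factors: int = 10
) -> CalibrationModel:
    method = method.lower()
    if method == "pls":
        return fit_pls(X, y, max_factors)
    if method == "pcr":
        return fit_pcr(X, y, max_factors)
    raise ValueError(f"unknown method {method!r}; use 'pls' or 'pcr'")


def fit_calibration(
    s: SpectrumSet,
    spec: PreprocessSpec,
    method: str = "pls",
    max_factors: int = 10,
    h_selected: int | None = None,
) -> CalibrationModel:
    """Fit on a raw SpectrumSet: runs the preprocessing pipeline, fits,
    and attaches the spec + retained grid for later prediction."""
    proc = apply_pipeline(s, spec)
    max_factors = min(max_factors, proc.n_samples - 1)
    model = fit_method(proc.values, s.y, method, max_factors)
    model.preprocess = spec
    model.grid_values = proc.grid.values.copy()
    if h_selected is not None:
        model.h_selected = min(h_selected, model.n_factors)
    return model
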