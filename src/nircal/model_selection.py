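"""Cross-validation, figures of merit and the pre-treatment x method scan.

RMSECV drives factor selection: the chosen model is the one with the
smallest number of factors whose RMSECV is not meaningfully above the best
achievable, operationalized as an MSE-ratio threshold (default 1.05), with
a Haaland-Thomas style F-test available as an alternative rule.

R-squared is reported two ways: squared Pearson correlation between
cross-validated predictions and reference values (``r2``), and the classic
1 - SSE/SST (``r2_classic``).  RMSEP and RMSEE are treated as synonyms
(external-set root-mean-square prediction error).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chemometrics import CalibrationModel, fit_calibration, fit_method
from .dataset import SpectrumSet
from .preprocess import PreprocessSpec, apply_pipeline


@dataclass
class CVResult:
    """Per-factor figures of merit from one cross-validation run."""

    method: str
    preprocess: str
    rmsecv: np.ndarray  # index h-1 -> value at h factors
    rmsec: np.ndarray
    bias: np.ndarray
    r2: np.ndarray
    r2_classic: np.ndarray
    h_selected: int
    cv_predictions: np.ndarray = field(repr=False, default=None)  # n x H
    rmsep: float | None = None

    @property
    def max_factors(self) -> int:
        return len(self.rmsecv)

    def at_selected(self) -> dict:
        h = self.h_selected
        return {
            "pretreatment": self.preprocess,
            "model": self.method.upper(),
            "pc_number": h,
            "rmsecv": float(self.rmsecv[h - 1]),
            "rmsep": self.rmsep,
            "r2": float(self.r2[h - 1]),
            "bias": float(self.bias[h - 1]),
        }


def _folds(n: int, scheme: str | tuple[str, int]) -> list[np.ndarray]:
    if scheme == "loo":
        return [np.array([i]) for i in range(n)]
    if isinstance(scheme, tuple) and len(scheme) == 2 and scheme[0] == "lgo":
        k = int(scheme[1])
        if k < 1 or n % k != 0:
            raise ValueError(f"group size {k} incompatible with n={n}")
        return [np.arange(i, i + k) for i in range(0, n, k)]
    raise ValueError(f"unknown CV scheme {scheme!r}; use 'loo' or ('lgo', k)")


def select_n_factors(
    rmsecv_curve: np.ndarray,
    f_thresh: float = 1.05,
    rule: str = "ratio",
    n_obs: int | None = None,
    alpha: float = 0.25,
) -> int:
    """Smallest factor count whose cross-validated MSE is within tolerance
    of the curve minimum.

    ``ratio`` rule (default): h* = min h with RMSECV(h)^2 <= f_thresh *
    min_h' RMSECV(h')^2.  ``ftest`` rule uses an F quantile at probability
    1-alpha with n_obs degrees of freedom on both MSEs instead of the
    fixed threshold.
    """
    curve = np.asarray(rmsecv_curve, dtype=float)
    if curve.size < 1:
        raise ValueError("empty RMSECV curve")
    mse = curve**2
    best = mse.min()
    if rule == "ratio":
        thresh = f_thresh * best
    elif rule == "ftest":
        if n_obs is None:
            raise ValueError("ftest rule needs n_obs")
        thresh = stats.f.ppf(1 - alpha, n_obs, n_obs) * best
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    return int(np.flatnonzero(mse <= thresh)[0]) + 1


def _pearson_r2(yhat: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(yhat) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(np.corrcoef(yhat, y)[0, 1] ** 2)


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    method: str = "pls",
    max_factors: int = 10,
    scheme: str | tuple[str, int] = "loo",
    f_thresh: float = 1.05,
    selection_rule: str = "ratio",
    preprocess_label: str = "",
) -> CVResult:
    """Leave-one-out / leave-group-out CV with per-fold refits.

    Each fold refits from scratch on the remaining samples (centering
    redone inside the fit; pre-treatments are per-spectrum, so applying
    them before the split does not leak).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 samples for cross-validation")
    folds = _folds(n, scheme)
    max_factors = min(max_factors, n - max(len(f) for f in folds) - 1)
    if max_factors < 1:
        raise ValueError("too few samples for even one factor after holding out a fold")

    full = fit_method(X, y, method, max_factors)
    h_avail = full.n_factors

    fold_models = []
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        m = fit_method(X[mask], y[mask], method, max_factors)
        fold_models.append(m)
        h_avail = min(h_avail, m.n_factors)

    cv_pred = np.empty((n, h_avail))
    for fold, m in zip(folds, fold_models):
        for h in range(1, h_avail + 1):
            cv_pred[fold, h - 1] = m.predict(X[fold], h)

    resid = cv_pred - y[:, None]
    rmsecv = np.sqrt(np.mean(resid**2, axis=0))
    bias = resid.mean(axis=0)
    r2 = np.array([_pearson_r2(cv_pred[:, h], y) for h in range(h_avail)])
    sst = float(np.sum((y - y.mean()) ** 2))
    r2_classic = 1.0 - np.sum(resid**2, axis=0) / sst

    rmsec = np.empty(h_avail)
    for h in range(1, h_avail + 1):
        rmsec[h - 1] = float(np.sqrt(np.mean((full.predict(X, h) - y) ** 2)))

    h_sel = select_n_factors(
        rmsecv, f_thresh=f_thresh, rule=selection_rule, n_obs=n
    )
    return CVResult(
        method=method,
        preprocess=preprocess_label,
        rmsecv=rmsecv,
        rmsec=rmsec,
        bias=bias,
        r2=r2,
        r2_classic=r2_classic,
        h_selected=h_sel,
        cv_predictions=cv_pred,
    )


def rmsep(
    model: CalibrationModel, X_val: np.ndarray, y_val: np.ndarray, h: int | None = None
) -> float:
    """Root-mean-square error of prediction on an external set."""
    y_val = np.asarray(y_val, dtype=float).ravel()
    if y_val.size == 0:
        raise ValueError("empty validation set")
    yhat = model.predict(X_val, h)
    return float(np.sqrt(np.mean((yhat - y_val) ** 2)))


GRID_COLUMNS = [
    "pretreatment", "model", "pc_number", "rmsecv", "rmsep", "r2", "bias", "error",
]


def grid_search(
    cal: SpectrumSet,
    val: SpectrumSet | None,
    specs: list[PreprocessSpec],
    methods: tuple[str, ...] = ("pcr", "pls"),
    max_factors: int = 10,
    scheme: str | tuple[str, int] = "loo",
    f_thresh: float = 1.05,
) -> pd.DataFrame:
    """Scan (pre-treatment, method) pairs; one row each at its selected
    factor count, sorted by RMSECV ascending.  A failing combination is
    flagged in the ``error`` column and the scan continues.
    """
    if not specs:
        raise ValueError("no preprocessing specs supplied")
    rows = []
    for spec in specs:
        for method in methods:
            try:
                proc = apply_pipeline(cal, spec)
                cv = cross_validate(
                    proc.values, cal.y, method=method, max_factors=max_factors,
                    scheme=scheme, f_thresh=f_thresh, preprocess_label=spec.label(),
                )
                row = cv.at_selected()
                if val is not None:
                    model = fit_calibration(
                        cal, spec, method, max_factors, h_selected=cv.h_selected
                    )
                    proc_val = apply_pipeline(val, spec)
                    row["rmsep"] = rmsep(model, proc_val.values, val.y, cv.h_selected)
                row["error"] = ""
            except Exception as exc:  # keep scanning; report the failure
                row = {
                    "pretreatment": spec.label(), "model": method.upper(),
                    "pc_number": np.nan, "rmsecv": np.nan, "rmsep": np.nan,
                    "r2": np.nan, "bias": np.nan, "error": str(exc),
                }
            rows.append(row)
    table = pd.DataFrame(rows, columns=GRID_COLUMNS)
    return table.sort_values("rmsecv", na_position="last").reset_index(drop=True)


def best_combination(table: pd.DataFrame) -> dict:
    """Top-ranked non-failing row of a grid-search table."""
    ok = table[table["error"] == ""]
    if ok.empty:
        raise ValueError("all grid-search combinations failed")
    return ok.iloc[0].to_dict()
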