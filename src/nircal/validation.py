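"""External method validation via accuracy profiles.

Per concentration level: trueness (recovery, relative bias), precision from
a one-way random-effects ANOVA (repeatability and intermediate-precision
variance components), beta-expectation tolerance limits with Satterthwaite
degrees of freedom, and a compliance decision against symmetric relative
acceptance limits.  A linearity profile (OLS of predicted on nominal)
completes the report.

Conventions, configurable where noted: beta defaults to 0.95; the relative
acceptance limit defaults to +/-5 %; reported RSDs are normalized by the
grand mean of the level's predictions, while the tolerance-limit formula
uses the nominal concentration as its relative basis (both are emitted).
A negative between-series variance estimate is clipped to zero (the raw
estimate is kept alongside for simulation work).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

_R_CAP = 1e12  # variance ratio cap when the within-series component is zero


def is_compliant(
    tol_lower: float, tol_upper: float, acceptance_lower: float, acceptance_upper: float
) -> bool:
    """Subset rule: the tolerance interval must lie inside the acceptance
    interval for the level to be declared valid."""
    return acceptance_lower <= tol_lower and tol_upper <= acceptance_upper


def trueness(predictions: np.ndarray, nominal: float) -> tuple[float, float, float]:
    """(mean prediction, recovery %, relative bias %) at one level."""
    if nominal <= 0:
        raise ValueError("nominal concentration must be positive")
    predictions = np.asarray(predictions, dtype=float).ravel()
    if predictions.size == 0:
        raise ValueError("no predictions supplied")
    mean_pred = float(predictions.mean())
    recovery = 100.0 * mean_pred / nominal
    relative_bias = 100.0 * (mean_pred - nominal) / nominal
    return mean_pred, recovery, relative_bias


@dataclass(frozen=True)
class VarianceComponents:
    s_w2: float        # within-series (repeatability) variance
    s_b2: float        # between-series variance, clipped at 0
    s_b2_raw: float    # unclipped ANOVA point estimate
    s_ip2: float       # intermediate precision = s_w2 + s_b2
    ms_w: float
    ms_b: float
    df_w: int
    df_b: int
    grand_mean: float
    p: int             # number of series
    n: int             # replicates per series


def variance_components(predictions: np.ndarray) -> VarianceComponents:
    """Balanced one-way random-effects ANOVA on a p x n prediction matrix
    (rows = series, columns = replicates)."""
    M = np.asarray(predictions, dtype=float)
    if M.ndim != 2:
        raise ValueError("predictions must be a p x n matrix (series x replicates)")
    if np.isnan(M).any():
        raise ValueError("unbalanced design (missing replicates) is not supported")
    p, n = M.shape
    if p < 2 or n < 2:
        raise ValueError(f"need p >= 2 series and n >= 2 replicates, got {p} x {n}")
    grand = float(M.mean())
    series_means = M.mean(axis=1)
    ss_b = n * float(np.sum((series_means - grand) ** 2))
    ss_w = float(np.sum((M - series_means[:, None]) ** 2))
    df_b, df_w = p - 1, p * (n - 1)
    ms_b = ss_b / df_b
    ms_w = ss_w / df_w
    s_w2 = ms_w
    s_b2_raw = (ms_b - ms_w) / n
    s_b2 = max(0.0, s_b2_raw)
    return VarianceComponents(
        s_w2=s_w2, s_b2=s_b2, s_b2_raw=s_b2_raw, s_ip2=s_w2 + s_b2,
        ms_w=ms_w, ms_b=ms_b, df_w=df_w, df_b=df_b,
        grand_mean=grand, p=p, n=n,
    )


def tolerance_interval(
    relative_bias: float,
    s_w2: float,
    s_b2: float,
    p: int,
    n: int,
    nominal: float,
    beta: float = 0.95,
) -> tuple[float, float]:
    """Beta-expectation tolerance limits (%) for a future single result,
    expressed relative to the nominal concentration.

    limits = relative_bias +/- t_{nu,(1+beta)/2} * sqrt(1 + 1/(p*n*B^2)) * RSD_IP
    with R = s_b2/s_w2, B^2 = (R+1)/(n*R+1), Satterthwaite
    nu = (R+1)^2 / [ (R + 1/n)^2/(p-1) + (1 - 1/n)/(p*n) ],
    RSD_IP = 100*sqrt(s_w2 + s_b2)/nominal.

    Degenerate case s_w2 = s_b2 = 0 collapses to the point {relative_bias}.
    """
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must be in (0, 1)")
    if s_w2 < 0 or s_b2 < 0:
        raise ValueError("variance components must be >= 0")
    s_ip2 = s_w2 + s_b2
    if s_ip2 == 0:
        return relative_bias, relative_bias
    R = s_b2 / s_w2 if s_w2 > 0 else _R_CAP
    B2 = (R + 1.0) / (n * R + 1.0)
    nu = (R + 1.0) ** 2 / (
        (R + 1.0 / n) ** 2 / (p - 1) + (1.0 - 1.0 / n) / (p * n)
    )
    t = stats.t.ppf((1.0 + beta) / 2.0, nu)
    rsd_ip = 100.0 * np.sqrt(s_ip2) / nominal
    half = t * np.sqrt(1.0 + 1.0 / (p * n * B2)) * rsd_ip
    return float(relative_bias - half), float(relative_bias + half)


@dataclass
class LevelValidation:
    """Full per-level validation record (one accuracy-profile row)."""

    nominal: float
    p: int
    n: int
    mean_pred: float
    recovery: float
    relative_bias: float
    s_w2: float
    s_b2: float
    s_ip2: float
    rsd_repeatability: float       # vs grand mean of predictions
    rsd_intermediate: float        # vs grand mean of predictions
    rel_tol_lower: float
    rel_tol_upper: float
    abs_tol_lower: float
    abs_tol_upper: float
    acceptance_lower: float
    acceptance_upper: float
    compliant: bool
    degenerate: bool = False       # zero total variance, point interval


def _level_validation(
    matrix: np.ndarray, nominal: float, acceptance_rel: float, beta: float
) -> LevelValidation:
    mean_pred, recovery, rel_bias = trueness(matrix, nominal)
    vc = variance_components(matrix)
    lo, hi = tolerance_interval(
        rel_bias, vc.s_w2, vc.s_b2, vc.p, vc.n, nominal, beta=beta
    )
    basis = vc.grand_mean if vc.grand_mean != 0 else nominal
    acc_lo, acc_hi = -acceptance_rel, acceptance_rel
    return LevelValidation(
        nominal=nominal, p=vc.p, n=vc.n,
        mean_pred=mean_pred, recovery=recovery, relative_bias=rel_bias,
        s_w2=vc.s_w2, s_b2=vc.s_b2, s_ip2=vc.s_ip2,
        rsd_repeatability=100.0 * np.sqrt(vc.s_w2) / basis,
        rsd_intermediate=100.0 * np.sqrt(vc.s_ip2) / basis,
        rel_tol_lower=lo, rel_tol_upper=hi,
        abs_tol_lower=nominal * (1.0 + lo / 100.0),
        abs_tol_upper=nominal * (1.0 + hi / 100.0),
        acceptance_lower=acc_lo, acceptance_upper=acc_hi,
        compliant=is_compliant(lo, hi, acc_lo, acc_hi),
        degenerate=(vc.s_ip2 == 0.0),
    )


def accuracy_profile(
    predictions: pd.DataFrame,
    acceptance_rel: float = 5.0,
    beta: float = 0.95,
) -> list[LevelValidation]:
    """One LevelValidation per concentration level.

    ``predictions`` needs columns nominal_pct_ww, series, prediction; the
    design must be balanced within each level (equal replicates per
    series), as in the validation protocol matrix.
    """
    required = {"nominal_pct_ww", "series", "prediction"}
    missing = required - set(predictions.columns)
    if missing:
        raise ValueError(f"predictions frame missing columns {sorted(missing)}")
    out = []
    for nominal, grp in predictions.groupby("nominal_pct_ww", sort=True):
        counts = grp.groupby("series").size()
        if counts.nunique() != 1:
            raise ValueError(
                f"unbalanced design at level {nominal}: replicates per series "
                f"{dict(counts)}"
            )
        n = int(counts.iloc[0])
        matrix = np.vstack([
            g["prediction"].to_numpy(dtype=float)
            for _, g in grp.groupby("series", sort=True)
        ])
        out.append(_level_validation(matrix, float(nominal), acceptance_rel, beta))
    return out


@dataclass
class LinearityFit:
    slope: float
    intercept: float
    r2: float
    levels: list[float]
    abs_tol_lower: list[float]
    abs_tol_upper: list[float]
    acceptance_lower: list[float]
    acceptance_upper: list[float]
    compliant: list[bool]


def linearity_profile(
    predictions: np.ndarray,
    nominals: np.ndarray,
    acceptance_rel: float = 5.0,
    profile: list[LevelValidation] | None = None,
) -> LinearityFit:
    """OLS of predicted on nominal concentration over all validation
    samples, with per-level tolerance limits (from the accuracy profile,
    if given) against acceptance limits nominal*(1 +/- acceptance_rel/100).
    """
    y = np.asarray(predictions, dtype=float).ravel()
    x = np.asarray(nominals, dtype=float).ravel()
    if y.size != x.size:
        raise ValueError("predictions and nominals differ in length")
    levels = sorted(set(x.tolist()))
    if len(levels) < 2:
        raise ValueError("linearity needs at least 2 distinct nominal levels")
    slope, intercept = np.polyfit(x, y, 1)
    r = np.corrcoef(x, y)[0, 1]
    by_level = {lv.nominal: lv for lv in (profile or [])}
    tol_lo, tol_hi, acc_lo, acc_hi, ok = [], [], [], [], []
    for c in levels:
        a_lo = c * (1.0 - acceptance_rel / 100.0)
        a_hi = c * (1.0 + acceptance_rel / 100.0)
        acc_lo.append(a_lo)
        acc_hi.append(a_hi)
        lv = by_level.get(c)
        if lv is not None:
            tol_lo.append(lv.abs_tol_lower)
            tol_hi.append(lv.abs_tol_upper)
            ok.append(is_compliant(lv.abs_tol_lower, lv.abs_tol_upper, a_lo, a_hi))
        else:
            tol_lo.append(np.nan)
            tol_hi.append(np.nan)
            ok.append(False)
    return LinearityFit(
        slope=float(slope), intercept=float(intercept), r2=float(r**2),
        levels=[float(c) for c in levels],
        abs_tol_lower=tol_lo, abs_tol_upper=tol_hi,
        acceptance_lower=acc_lo, acceptance_upper=acc_hi,
        compliant=ok,
    )


@dataclass
class ValidationReport:
    levels: list[LevelValidation]
    linearity: LinearityFit
    acceptance_rel: float
    beta: float

    @property
    def all_compliant(self) -> bool:
        return all(lv.compliant for lv in self.levels)

    def levels_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(lv) for lv in self.levels])

    def linearity_frame(self) -> pd.DataFrame:
        lf = self.linearity
        return pd.DataFrame({
            "nominal": lf.levels,
            "abs_tol_lower": lf.abs_tol_lower,
            "abs_tol_upper": lf.abs_tol_upper,
            "acceptance_lower": lf.acceptance_lower,
            "acceptance_upper": lf.acceptance_upper,
            "compliant": lf.compliant,
        })

    def summary(self) -> str:
        lines = [
            f"beta = {self.beta}, acceptance = +/-{self.acceptance_rel} %",
            f"linearity: slope = {self.linearity.slope:.4f}, "
            f"intercept = {self.linearity.intercept:.4f}, R2 = {self.linearity.r2:.4f}",
        ]
        for lv in self.levels:
            lines.append(
                f"level {lv.nominal:g} % w/w: recovery {lv.recovery:.2f} %, "
                f"RSD(r) {lv.rsd_repeatability:.3f} %, RSD(ip) {lv.rsd_intermediate:.3f} %, "
                f"tol [{lv.rel_tol_lower:.3f}, {lv.rel_tol_upper:.3f}] %, "
                f"{'COMPLIANT' if lv.compliant else 'NON-COMPLIANT'}"
            )
        lines.append(
            "method range: " + ("all levels compliant" if self.all_compliant
                                else "not all levels compliant")
        )
        return "\n".join(lines)


def validate_predictions(
    predictions: pd.DataFrame,
    acceptance_rel: float = 5.0,
    beta: float = 0.95,
) -> ValidationReport:
    """Full report from a tidy predictions frame
    (columns nominal_pct_ww, series, prediction)."""
    profile = accuracy_profile(predictions, acceptance_rel=acceptance_rel, beta=beta)
    lin = linearity_profile(
        predictions["prediction"].to_numpy(dtype=float),
        predictions["nominal_pct_ww"].to_numpy(dtype=float),
        acceptance_rel=acceptance_rel,
        profile=profile,
    )
    return ValidationReport(
        levels=profile, linearity=lin, acceptance_rel=acceptance_rel, beta=beta
    )


def validate_model(model, validation_set, acceptance_rel: float = 5.0,
                   beta: float = 0.95) -> ValidationReport:
    """Predict a validation SpectrumSet with a fitted model and build the
    accuracy/linearity report."""
    preds = model.predict_spectra(validation_set)
    frame = pd.DataFrame({
        "nominal_pct_ww": validation_set.y,
        "series": validation_set.meta["series"].to_numpy(),
        "prediction": preds,
    })
    return validate_predictions(frame, acceptance_rel=acceptance_rel, beta=beta)
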