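"""SUV computation, decay correction, geometric summaries, time-uptake curves, PK.

Standardized uptake value (SUV) normalizes a tissue activity concentration by
the injected activity per gram of body weight (tissue density taken as 1 g/mL),
so SUV = 1 means the tracer is distributed as if uniformly over the body.
Uptake distributions are right-skewed and are summarized geometrically
(geometric mean and geometric coefficient of variation, GCV).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ZR89_HALF_LIFE_H = 78.4  # zirconium-89 physical half-life, hours

__all__ = [
    "ZR89_HALF_LIFE_H",
    "ScanContext",
    "GeometricSummary",
    "CurveFit",
    "compute_suv",
    "decay_correct",
    "summarize_uptake",
    "fit_time_uptake_curve",
    "estimate_terminal_half_life",
]


@dataclass(frozen=True)
class ScanContext:
    """Injection and scan metadata needed to turn activity into SUV."""

    body_weight_kg: float
    injected_dose_MBq: float  # net dose, decay-corrected to injection time
    scan_time_h: float = 48.0  # hours post-injection
    protein_dose_mg: float = 10.0  # total (labeled + cold) antibody protein dose
    isotope_half_life_h: float = ZR89_HALF_LIFE_H

    ALLOWED_PROTEIN_DOSES = (4.0, 10.0)

    def __post_init__(self) -> None:
        if self.body_weight_kg <= 0 or self.injected_dose_MBq <= 0:
            raise ValueError("body weight and injected dose must be positive")
        if self.scan_time_h < 0 or self.isotope_half_life_h <= 0:
            raise ValueError("scan time must be >= 0 and half-life positive")
        if float(self.protein_dose_mg) not in self.ALLOWED_PROTEIN_DOSES:
            raise ValueError(
                f"protein dose must be one of {self.ALLOWED_PROTEIN_DOSES} mg"
            )


@dataclass(frozen=True)
class GeometricSummary:
    geometric_mean: float
    gcv: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class CurveFit:
    """Best time-uptake curve among linear / log-linear / quadratic by AIC."""

    form: Literal["linear", "log-linear", "quadratic"]
    coefficients: dict
    aic: float
    aic_by_form: dict
    projected_curve: pd.DataFrame  # projection at 10 mg protein dose
    categorical_estimates: pd.DataFrame  # per-timepoint estimates (10 mg)
    fits: dict = field(repr=False, default_factory=dict)


def compute_suv(activity_conc_kBq_per_mL: float, ctx: ScanContext) -> float:
    """SUV from an activity concentration within a VOI.

    SUV = concentration / (injected dose / body weight), with body weight in
    grams, dose in kBq and tissue density 1 g/mL, so the result is unitless.
    Zero concentration gives SUV 0; negative concentration is invalid.
    """
    conc = np.asarray(activity_conc_kBq_per_mL, dtype=float)
    if np.any(conc < 0):
        raise ValueError("activity concentration must be >= 0")
    dose_kBq = ctx.injected_dose_MBq * 1000.0
    weight_g = ctx.body_weight_kg * 1000.0
    out = conc / (dose_kBq / weight_g)
    return float(out) if np.isscalar(activity_conc_kBq_per_mL) else out


def decay_correct(
    value,
    elapsed_h: float,
    half_life_h: float = ZR89_HALF_LIFE_H,
    mode: Literal["correct", "decay"] = "correct",
):
    """Rescale a radioactivity measurement to the injection reference time.

    ``mode="correct"`` multiplies by 2**(elapsed/half_life) (undoes physical
    decay of a measurement taken ``elapsed_h`` after injection); ``mode="decay"``
    is the inverse (applies decay forward in time). Negative ``elapsed_h`` is
    allowed and makes the two modes exact inverses.
    """
    if half_life_h <= 0:
        raise ValueError("half-life must be positive")
    if mode not in ("correct", "decay"):
        raise ValueError("mode must be 'correct' or 'decay'")
    factor = 2.0 ** (float(elapsed_h) / half_life_h)
    if mode == "decay":
        factor = 1.0 / factor
    return np.asarray(value, dtype=float) * factor if not np.isscalar(value) else value * factor


def summarize_uptake(values: Sequence[float], conf_level: float = 0.95) -> GeometricSummary:
    """Geometric mean, GCV and a t-based CI computed on the log scale.

    GCV = sqrt(exp(s^2) - 1) with s^2 the unbiased sample variance of the
    logs; for a log-normal distribution this estimates the coefficient of
    variation on the natural scale.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one value")
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("all values must be positive and finite")
    logs = np.log(x)
    n = x.size
    m = float(np.mean(logs))
    gm = math.exp(m)
    if n == 1:
        return GeometricSummary(gm, 0.0, gm, gm, 1)
    s2 = float(np.var(logs, ddof=1))
    gcv = math.sqrt(math.exp(s2) - 1.0)
    se = math.sqrt(s2 / n)
    tq = stats.t.ppf(0.5 + conf_level / 2.0, df=n - 1)
    return GeometricSummary(gm, gcv, math.exp(m - tq * se), math.exp(m + tq * se), n)


def _curve_design(time_d: np.ndarray, form: str) -> np.ndarray:
    """Time columns of the fixed design for one candidate curve form.

    The log-linear form uses log(hours since injection); a 1-hour scan enters
    as 1 h so the axis never hits log(0).
    """
    t = np.asarray(time_d, dtype=float)
    if form == "linear":
        return t[:, None]
    if form == "log-linear":
        hours = np.maximum(t * 24.0, 1.0)
        return np.log(hours)[:, None]
    if form == "quadratic":
        return np.column_stack([t, t**2])
    raise ValueError(f"unknown curve form {form!r}")


def fit_time_uptake_curve(
    data: pd.DataFrame,
    uptake_col: str = "uptake",
    uptake_scale: Literal["mean", "log-max"] = "log-max",
) -> CurveFit:
    """Select the best postinjection time-uptake curve by AIC.

    ``data`` has one row per tissue measurement with columns ``patient_id``,
    ``time_d`` (days post-injection), ``protein_dose_mg`` (4 or 10) and the
    uptake column. Each candidate form (linear, log-linear, quadratic in time)
    is fitted as a linear mixed model with a patient random intercept and
    protein dose as a main effect only, under maximum likelihood; the form
    with the lowest AIC wins, ties broken toward fewer parameters. SUVmax-type
    responses (``uptake_scale="log-max"``) are log-transformed; SUVmean
    (``"mean"``) is analyzed untransformed.

    Returns the winning fit plus the continuous curve and the
    categorical-timepoint estimates, both projected at the 10 mg dose.
    """
    from .mixedmodel import LmmSpec, fit_lmm

    df = data.copy()
    required = {"patient_id", "time_d", "protein_dose_mg", uptake_col}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if df["time_d"].nunique() < 3:
        raise ValueError("need >= 3 distinct timepoints to select a curve form")
    bad_dose = set(df["protein_dose_mg"].unique()) - {4, 10, 4.0, 10.0}
    if bad_dose:
        raise ValueError(f"protein dose must be 4 or 10 mg, got {sorted(bad_dose)}")

    if uptake_scale == "log-max":
        if (df[uptake_col] <= 0).any():
            raise ValueError("log-scale analysis requires positive uptake")
        df["_y"] = np.log(df[uptake_col].astype(float))
    else:
        df["_y"] = df[uptake_col].astype(float)
    df["_dose10"] = (df["protein_dose_mg"].astype(float) == 10.0).astype(float)
    multi_dose = df["_dose10"].nunique() > 1

    forms = ["linear", "log-linear", "quadratic"]
    n_time_cols = {"linear": 1, "log-linear": 1, "quadratic": 2}
    fits, aics = {}, {}
    for form in forms:
        cols = _curve_design(df["time_d"].to_numpy(), form)
        for j in range(cols.shape[1]):
            df[f"_t{j}"] = cols[:, j]
        terms = [f"_t{j}" for j in range(cols.shape[1])]
        if multi_dose:
            terms.append("_dose10")
        spec = LmmSpec(response="_y", fixed="1 + " + " + ".join(terms),
                       random="patient", method="ml")
        fit = fit_lmm(df, spec)
        fits[form] = fit
        aics[form] = fit.aic
    # minimal AIC; near-ties resolved toward the fewer-parameter form, in the
    # order linear < log-linear < quadratic
    aic_min = min(aics.values())
    eligible = [f for f in forms if aics[f] <= aic_min + 1e-6 * max(1.0, abs(aic_min))]
    best = min(eligible, key=lambda f: (n_time_cols[f], forms.index(f)))
    best_fit = fits[best]

    t_grid = np.linspace(float(df["time_d"].min()), float(df["time_d"].max()), 50)
    cols = _curve_design(t_grid, best)
    beta = best_fit.beta
    names = list(best_fit.beta_names)
    pred = np.full(t_grid.shape, beta[names.index("Intercept")])
    for j in range(cols.shape[1]):
        pred += beta[names.index(f"_t{j}")] * cols[:, j]
    if multi_dose:
        pred += beta[names.index("_dose10")] * 1.0  # project at 10 mg
    projected = pd.DataFrame({"time_d": t_grid, "prediction": pred})
    if uptake_scale == "log-max":
        projected["prediction_suv"] = np.exp(projected["prediction"])

    # categorical timepoint model (time as factor), same random structure
    df["_tp"] = df["time_d"].astype(float)
    cat_terms = "C(_tp)" + (" + _dose10" if multi_dose else "")
    cat_fit = fit_lmm(df, LmmSpec(response="_y", fixed="1 + " + cat_terms,
                                  random="patient", method="reml"))
    tps = sorted(df["_tp"].unique())
    rows = []
    for tp in tps:
        c = np.zeros(len(cat_fit.beta))
        c[list(cat_fit.beta_names).index("Intercept")] = 1.0
        name = f"C(_tp)[T.{tp}]"
        if name in cat_fit.beta_names:
            c[list(cat_fit.beta_names).index(name)] = 1.0
        if multi_dose:
            c[list(cat_fit.beta_names).index("_dose10")] = 1.0
        est = float(c @ cat_fit.beta)
        se = float(np.sqrt(c @ cat_fit.vcov_beta @ c))
        lo, hi = est - 1.96 * se, est + 1.96 * se
        if uptake_scale == "log-max":
            est, lo, hi = math.exp(est), math.exp(lo), math.exp(hi)
        rows.append({"time_d": tp, "estimate": est, "ci_low": lo, "ci_high": hi})
    categorical = pd.DataFrame(rows)

    coef = dict(zip(best_fit.beta_names, best_fit.beta))
    return CurveFit(form=best, coefficients=coef, aic=aics[best], aic_by_form=aics,
                    projected_curve=projected, categorical_estimates=categorical,
                    fits=fits)


def estimate_terminal_half_life(pk: pd.DataFrame,
                                time_col: str = "time_d",
                                conc_col: str = "concentration"):
    """Terminal elimination half-life by log-linear regression.

    Standard noncompartmental convention: among candidate windows consisting
    of the last k >= 3 positive post-peak samples, pick the window maximizing
    the adjusted R^2 of the log-concentration vs time regression; the terminal
    rate constant is minus the slope and t1/2 = ln 2 / lambda_z.

    Returns ``(t_half_days, n_points_used, adj_r2)``.
    """
    df = pk[[time_col, conc_col]].dropna().sort_values(time_col)
    df = df[df[conc_col] > 0]
    t = df[time_col].to_numpy(dtype=float)
    c = df[conc_col].to_numpy(dtype=float)
    if t.size < 3:
        raise ValueError("need >= 3 positive concentrations")
    peak = int(np.argmax(c))
    t, c = t[peak:], c[peak:]
    n = t.size
    if n < 3:
        raise ValueError("need >= 3 post-peak samples")
    logc = np.log(c)
    best = None
    for k in range(3, n + 1):
        tt, yy = t[n - k:], logc[n - k:]
        if np.ptp(tt) == 0:
            continue
        slope, intercept = np.polyfit(tt, yy, 1)
        if slope >= 0:
            continue
        resid = yy - (slope * tt + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((yy - yy.mean()) ** 2))
        if ss_tot == 0:
            continue
        r2 = 1.0 - ss_res / ss_tot
        adj_r2 = 1.0 - (1.0 - r2) * (k - 1) / (k - 2)
        # prefer larger adjusted R^2; on ties (noiseless data) prefer more points
        if best is None or adj_r2 > best[0] + 1e-12 or (
            abs(adj_r2 - best[0]) <= 1e-12 and k > best[1]
        ):
            best = (adj_r2, k, slope)
    if best is None:
        raise ValueError("no terminal log-linear phase (concentrations nondecreasing)")
    adj_r2, k, slope = best
    lam = -slope
    return math.log(2.0) / lam, k, adj_r2
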