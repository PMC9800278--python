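"""Response categorization and survival analysis on baseline-uptake strata.

Patients are stratified by their baseline geometric-mean SUVmax (median split,
predefined) or analyzed continuously per population standard deviation.
Kaplan-Meier curves and log-rank tests compare strata; hazard ratios come from
Cox models with Firth's Jeffreys-prior penalization, which keeps estimates
finite and reduces small-sample bias even under monotone likelihood (complete
separation) — essential with ~38 patients.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import optimize, stats

__all__ = [
    "SurvivalRecord",
    "KmCurve",
    "CoxFit",
    "recist_categorize",
    "km_estimate",
    "logrank_test",
    "cox_score_test",
    "firth_cox",
    "patient_exposure",
    "median_split",
]


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time: float  # months
    event: int  # 1 = progression/death (PFS) or death (OS), 0 = censored
    covariate: float

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass
class KmCurve:
    times: np.ndarray  # distinct event times
    survival: np.ndarray  # S(t) at those times
    variance: np.ndarray  # Greenwood variance of S(t)
    median: float  # NaN if never reached
    median_ci: tuple

    def at(self, t: float) -> float:
        """Product-limit estimate S(t) (right-continuous step function)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxFit:
    log_hr: float
    hr: float
    ci: tuple  # on the HR scale
    p: float
    penalized: bool
    se: float
    loglik: float
    n_events: int


def recist_categorize(sld_baseline_mm: float, sld_nadir_mm: float,
                      sld_current_mm: float, new_lesions: bool = False) -> str:
    """Best-response category from sums of longest diameters (RECIST 1.1).

    PD: >=20% increase over nadir AND >=5 mm absolute increase, or new
    lesions; CR: disappearance of all target lesions; PR: >=30% decrease from
    baseline; otherwise SD. PD takes precedence over PR/CR.
    """
    for v in (sld_baseline_mm, sld_nadir_mm, sld_current_mm):
        if v < 0:
            raise ValueError("SLD must be >= 0")
    if sld_nadir_mm > sld_baseline_mm:
        raise ValueError("nadir SLD cannot exceed baseline SLD")
    growth = sld_current_mm - sld_nadir_mm
    if new_lesions or (
        sld_nadir_mm > 0
        and growth >= 0.2 * sld_nadir_mm
        and growth >= 5.0
    ):
        return "PD"
    if sld_current_mm == 0:
        return "CR"
    if sld_baseline_mm > 0 and (sld_baseline_mm - sld_current_mm) >= 0.3 * sld_baseline_mm:
        return "PR"
    return "SD"


def _to_arrays(records):
    if isinstance(records, pd.DataFrame):
        t = records["time"].to_numpy(dtype=float)
        e = records["event"].to_numpy(dtype=int)
        x = (records["covariate"].to_numpy(dtype=float)
             if "covariate" in records.columns else None)
    else:
        recs = list(records)
        t = np.array([r.time for r in recs], dtype=float)
        e = np.array([r.event for r in recs], dtype=int)
        x = np.array([r.covariate for r in recs], dtype=float)
    if t.size == 0:
        raise ValueError("no records")
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    return t, e, x


def km_estimate(records) -> KmCurve:
    """Kaplan-Meier product-limit estimator with Greenwood variance."""
    t, e, _ = _to_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    event_times = np.unique(t[e == 1])
    if event_times.size:
        surv = kmf.survival_function_at_times(event_times).to_numpy()
        # Greenwood: var = S(t)^2 * sum d/(n(n-d)) over event times <= t
        tab = kmf.event_table
        d = tab["observed"].to_numpy(dtype=float)
        n = tab["at_risk"].to_numpy(dtype=float)
        tt = tab.index.to_numpy(dtype=float)
        ok = (d > 0) & (n > d)
        cum = np.cumsum(np.where(ok, d / (n * np.maximum(n - d, 1e-300)), 0.0))
        var = np.array([
            surv[i] ** 2 * cum[np.searchsorted(tt, et, side="right") - 1]
            for i, et in enumerate(event_times)
        ])
    else:
        surv = np.array([])
        var = np.array([])
    med = kmf.median_survival_time_
    med = float(med) if np.isfinite(med) else float("nan")
    try:
        from lifelines.utils import median_survival_times
        ci_df = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(ci_df.iloc[0, 0]), float(ci_df.iloc[0, 1])
    except Exception:  # degenerate curves
        lo = hi = float("nan")
    return KmCurve(times=event_times, survival=surv, variance=var,
                   median=med, median_ci=(lo, hi))


def logrank_test(group_a, group_b):
    """Two-sample log-rank test; returns (chi2, p)."""
    ta, ea, _ = _to_arrays(group_a)
    tb, eb, _ = _to_arrays(group_b)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group; log-rank undefined")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


# --- Cox partial likelihood (Breslow ties) ----------------------------------

def _cox_quantities(beta: float, t: np.ndarray, e: np.ndarray, x: np.ndarray):
    """Breslow log partial likelihood, score and information at scalar beta."""
    order = np.argsort(-t, kind="stable")  # decreasing time: cumulative risk sets
    ts, es, xs = t[order], e[order], x[order]
    eta = beta * xs
    shift = eta.max()
    w = np.exp(eta - shift)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w * xs)
    s2 = np.cumsum(w * xs**2)
    # risk set at event time: all with t >= t_i -> last index of block with same time
    _, inv = np.unique(-ts, return_inverse=True)
    last_idx = np.zeros(inv.max() + 1, dtype=int)
    np.maximum.at(last_idx, inv, np.arange(ts.size))
    ridx = last_idx[inv]
    ev = es == 1
    S0, S1, S2 = s0[ridx][ev], s1[ridx][ev], s2[ridx][ev]
    xb = xs[ev]
    # undo the overflow shift: log S0_true = log S0_shifted + shift
    loglik = float(np.sum(beta * xb - np.log(S0) - shift))
    score = float(np.sum(xb - S1 / S0))
    info = float(np.sum(S2 / S0 - (S1 / S0) ** 2))
    return loglik, score, info


def cox_score_test(records_or_time, event=None, covariate=None):
    """Score test of beta=0 in an unpenalized Cox model; returns (chi2, p).

    With a binary group covariate and untied event times this equals the
    log-rank statistic.
    """
    if event is None:
        t, e, x = _to_arrays(records_or_time)
    else:
        t = np.asarray(records_or_time, dtype=float)
        e = np.asarray(event, dtype=int)
        x = np.asarray(covariate, dtype=float)
    _, u, i = _cox_quantities(0.0, t, e, x)
    if i <= 0:
        raise ValueError("zero information; score test undefined")
    chi2 = u**2 / i
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def firth_cox(records, per_sd: bool = False, decrease: bool = False,
              conf_level: float = 0.95) -> CoxFit:
    """Firth-penalized Cox regression for a single covariate.

    Maximizes l*(b) = l(b) + 0.5*log I(b) (Breslow ties). The penalty is the
    Jeffreys prior of the partial likelihood; it keeps the estimate finite
    under monotone likelihood and counters small-sample bias. Confidence
    limits are profile penalized-likelihood (chi2 cutoff), the p value is the
    penalized likelihood-ratio test against b=0 — Wald statistics misbehave
    exactly in the separated cases the penalty exists for.

    ``per_sd`` rescales the covariate by its population SD; ``decrease`` flips
    its sign so the hazard ratio reads "per SD decrease".
    """
    t, e, x = _to_arrays(records)
    if x is None:
        raise ValueError("records must carry a covariate")
    n_events = int(e.sum())
    if np.unique(t[e == 1]).size < 2:
        raise ValueError("need >= 2 distinct event times")
    if np.std(x) == 0:
        raise ValueError("covariate does not vary")
    z = x.copy()
    if per_sd:
        z = z / np.std(z, ddof=1)
    if decrease:
        z = -z

    def neg_pen(b: float) -> float:
        ll, _, info = _cox_quantities(b, t, e, z)
        if info <= 0:
            return np.inf
        return -(ll + 0.5 * math.log(info))

    br = optimize.minimize_scalar(neg_pen, bounds=(-50, 50), method="bounded",
                                  options={"xatol": 1e-10})
    beta = float(br.x)
    lstar_max = -float(br.fun)
    _, _, info_hat = _cox_quantities(beta, t, e, z)
    se = 1.0 / math.sqrt(info_hat)

    # profile penalized-likelihood CI: l*(b) = l*(beta) - chi2q/2
    chi2q = stats.chi2.ppf(conf_level, 1)
    target = lstar_max - chi2q / 2.0

    def shifted(b):
        return -neg_pen(b) - target

    def find_root(lo, hi):
        try:
            return float(optimize.brentq(shifted, lo, hi, xtol=1e-6))
        except ValueError:
            return float("nan")

    step = max(5 * se, 0.5)
    lo = beta - step
    while shifted(lo) > 0 and lo > -60:
        lo -= step
    hi = beta + step
    while shifted(hi) > 0 and hi < 60:
        hi += step
    ci_lo = find_root(lo, beta)
    ci_hi = find_root(beta, hi)

    lstar_null = -neg_pen(0.0)
    lr = max(2.0 * (lstar_max - lstar_null), 0.0)
    p = float(stats.chi2.sf(lr, 1))
    return CoxFit(log_hr=beta, hr=math.exp(beta),
                  ci=(math.exp(ci_lo), math.exp(ci_hi)), p=p, penalized=True,
                  se=se, loglik=lstar_max, n_events=n_events)


# --- patient-level exposure helpers -----------------------------------------

def patient_exposure(lesions: pd.DataFrame) -> pd.Series:
    """Baseline geometric mean SUVmax per patient over nonirradiated lesions.

    Uses pretreatment scans (timepoint == 0) and excludes irradiated lesions,
    matching how the uptake-survival exposure is defined.
    """
    df = lesions
    mask = (df["timepoint"] == 0)
    if "irradiated" in df.columns:
        mask &= ~df["irradiated"].astype(bool)
    base = df[mask]
    if base.empty:
        raise ValueError("no pretreatment nonirradiated lesions")
    return base.groupby("patient_id")["suv_max"].apply(
        lambda s: float(np.exp(np.mean(np.log(s))))
    )


def median_split(exposure: pd.Series) -> pd.Series:
    """High/low grouping at the predefined median; ties go to the lower group."""
    med = float(exposure.median())
    return (exposure > med).map({True: "high", False: "low"})
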