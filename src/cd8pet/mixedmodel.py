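"""Linear mixed models with patient and lesion-within-patient random intercepts.

Tumor tracer uptake is measured repeatedly: several lesions per patient and,
on repeat imaging, several scans per lesion. Log-scale linear mixed models with
a patient random intercept (and, when lesions are scanned more than once, a
lesion intercept nested within patient) account for this clustering. Fixed
effects are estimated by REML (or ML for likelihood-ratio comparisons), Wald
confidence intervals use Satterthwaite degrees of freedom, and estimates are
back-transformed to geometric means and percent differences.

The covariance of one patient's observations is
``sigma2_patient * J + sigma2_lesion * L + sigma2_resid * I`` where J is
all-ones and L marks scan pairs of the same lesion. Fitting profiles the
residual variance: the criterion is optimized over the log variance *ratios*
(Nelder-Mead, then a Newton polish on the profiled criterion), which keeps the
components nonnegative and gives the residual scale in closed form.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy import optimize, stats

__all__ = [
    "LmmSpec",
    "LmmFit",
    "fit_lmm",
    "percent_effect",
    "lrt",
    "treatment_change_model",
    "compute_icc",
]

_GAMMA_FLOOR = 1e-10  # variance ratio treated as a boundary (zero) estimate
# residual floor relative to y'W^-1 y: above the cancellation noise of the
# quadratic-form subtraction, so perfect fits get a common, comparable loglik
_RSS_FLOOR = 1e-10


@dataclass(frozen=True)
class LmmSpec:
    """What to fit: response column, patsy fixed-effect formula, structure."""

    response: str
    fixed: str = "1"
    random: Literal["patient", "patient+lesion"] = "patient"
    method: Literal["reml", "ml"] = "reml"
    patient_col: str = "patient_id"
    lesion_col: str = "lesion_id"

    def __post_init__(self) -> None:
        if self.random not in ("patient", "patient+lesion"):
            raise ValueError("random structure must be 'patient' or 'patient+lesion'")
        if self.method not in ("reml", "ml"):
            raise ValueError("method must be 'reml' or 'ml'")


@dataclass
class LmmFit:
    beta: np.ndarray
    beta_names: tuple
    vcov_beta: np.ndarray
    sigma2_patient: float
    sigma2_lesion: float  # 0 when structure is patient-only
    sigma2_resid: float
    loglik: float
    method: str
    n_obs: int
    n_params: int  # fixed + variance parameters, for AIC
    spec: LmmSpec
    boundary: bool  # a variance component collapsed to ~0
    _kernel: object = field(repr=False, default=None)
    _theta_names: tuple = field(repr=False, default_factory=tuple)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def df_resid(self) -> int:
        return self.n_obs - len(self.beta)

    def wald_table(self, conf_level: float = 0.95) -> pd.DataFrame:
        """Per-coefficient estimates, Satterthwaite-df t intervals and p values."""
        rows = []
        for i, name in enumerate(self.beta_names):
            c = np.zeros(len(self.beta))
            c[i] = 1.0
            est, se, df, p, lo, hi = self.contrast(c, conf_level)
            rows.append({"term": name, "estimate": est, "se": se, "df": df,
                         "ci_low": lo, "ci_high": hi, "p": p})
        return pd.DataFrame(rows).set_index("term")

    def contrast(self, c: Sequence[float], conf_level: float = 0.95):
        """Wald inference for c'beta with Satterthwaite degrees of freedom."""
        c = np.asarray(c, dtype=float)
        if c.shape != (len(self.beta),):
            raise ValueError(
                f"contrast must have length {len(self.beta)}, got {c.shape}"
            )
        est = float(c @ self.beta)
        var = float(c @ self.vcov_beta @ c)
        se = math.sqrt(max(var, 0.0))
        df = self.satterthwaite_df(c)
        if se == 0.0:
            return est, 0.0, df, (1.0 if est == 0 else 0.0), est, est
        tstat = est / se
        if math.isfinite(df):
            p = 2.0 * stats.t.sf(abs(tstat), df)
            tq = stats.t.ppf(0.5 + conf_level / 2.0, df)
        else:
            p = 2.0 * stats.norm.sf(abs(tstat))
            tq = stats.norm.ppf(0.5 + conf_level / 2.0)
        return est, se, df, p, est - tq * se, est + tq * se

    def influence(self, c: Sequence[float]) -> np.ndarray:
        """Row weights a (original row order) such that c'beta_hat = a'y.

        This is the GLS influence vector c'(X'V^-1 X)^-1 X'V^-1; it lets
        first-stage (plug-in) uncertainty in a transformed response be
        propagated into a contrast by the delta method.
        """
        if self._kernel is None:
            raise ValueError("fit does not retain its kernel")
        c = np.asarray(c, dtype=float)
        k = self._kernel
        gp = self.sigma2_patient / self.sigma2_resid
        gl = self.sigma2_lesion / self.sigma2_resid
        WinvX = k.winv_apply(k.X, gp, gl)
        XtWX = k.X.T @ WinvX
        a_sorted = WinvX @ np.linalg.solve(XtWX, c)
        a = np.empty_like(a_sorted)
        a[k.order] = a_sorted
        return a

    # --- Satterthwaite machinery -------------------------------------------

    def _theta(self) -> np.ndarray:
        vals = {"patient": self.sigma2_patient, "lesion": self.sigma2_lesion,
                "resid": self.sigma2_resid}
        return np.array([vals[k] for k in self._theta_names])

    def satterthwaite_df(self, c: Sequence[float]) -> float:
        """Satterthwaite df for c'beta by the delta method.

        df = 2 (c'Cc)^2 / (g' A g) with C the fixed-effect covariance as a
        function of the variance components, g its gradient at the estimate and
        A the asymptotic covariance of the variance components (inverse REML
        information, computed numerically). Falls back to a normal
        approximation (df = inf) at boundary estimates, where the quadratic
        expansion is not trustworthy.
        """
        if self.boundary or self._kernel is None:
            return math.inf
        c = np.asarray(c, dtype=float)
        theta = self._theta()
        if np.any(theta < 0) or self.sigma2_resid <= 0:
            return math.inf
        try:
            var_c = float(c @ self.vcov_beta @ c)
            steps = np.maximum(theta, np.mean(theta)) * 1e-4
            g = np.zeros(len(theta))
            for i in range(len(theta)):
                tp, tm = theta.copy(), theta.copy()
                tp[i] += steps[i]
                tm[i] = max(tm[i] - steps[i], 1e-12)
                g[i] = (_cvar_at_theta(self._kernel, tp, c)
                        - _cvar_at_theta(self._kernel, tm, c)) / (tp[i] - tm[i])
            H = _numeric_hessian(
                lambda t: _neg2_loglik_at_theta(self._kernel, t, reml=True), theta
            )
            A = 2.0 * np.linalg.inv(H)  # cov(theta_hat)
            denom = float(g @ A @ g)
            if denom <= 0:
                return math.inf
            df = 2.0 * var_c**2 / denom
            return float(np.clip(df, 1.0, 1e7))
        except np.linalg.LinAlgError:
            return math.inf


class _Kernel:
    """Vectorized GLS pieces for W = I + gp*J_patient + gl*L_lesion.

    W has a closed-form inverse: the lesion blocks invert by Sherman-Morrison
    (D = I + gl*L, D^-1 = I - gl/(1+m_l*gl) J_l per lesion) and the patient
    all-ones term is a rank-1 Woodbury update of D. Everything reduces to
    per-lesion and per-patient sums, so one criterion evaluation is a handful
    of numpy reductions regardless of group sizes.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray,
                 patients: np.ndarray, lesions: np.ndarray | None):
        # sort rows so lesions are contiguous within patients
        if lesions is None:
            order = np.argsort(patients, kind="stable")
        else:
            order = np.lexsort((lesions, patients))
        self.order = order  # sorted position -> original row index
        self.X = X[order]
        self.y = y[order]
        self.R = np.column_stack([self.X, self.y])
        pats = patients[order]
        les = lesions[order] if lesions is not None else np.arange(len(pats))
        self.n, self.p = X.shape
        # lesion segmentation (unique within patient by construction)
        key = pd.MultiIndex.from_arrays([pats, les])
        new_lesion = np.ones(self.n, dtype=bool)
        new_lesion[1:] = key[1:] != key[:-1]
        self.les_starts = np.flatnonzero(new_lesion)
        self.m_l = np.diff(np.append(self.les_starts, self.n))
        self.row_lesion = np.cumsum(new_lesion) - 1
        new_patient = np.ones(self.n, dtype=bool)
        new_patient[1:] = pats[1:] != pats[:-1]
        self.pat_starts = np.flatnonzero(new_patient)
        self.row_patient = np.cumsum(new_patient) - 1
        self.lesion_patient = self.row_patient[self.les_starts]
        self.n_patients = len(self.pat_starts)
        self.n_lesions = len(self.les_starts)

    def winv_apply(self, Z: np.ndarray, gp: float, gl: float) -> np.ndarray:
        """W^-1 Z for rows in the kernel's sorted order."""
        Z = np.atleast_2d(Z.T).T if Z.ndim == 1 else Z
        m_l = self.m_l
        if gl != 0.0:
            S_l = np.add.reduceat(Z, self.les_starts, axis=0)
            fac_l = gl / (1.0 + m_l * gl)
            DinvZ = Z - fac_l[self.row_lesion, None] * S_l[self.row_lesion]
            ones_D_Z_l = S_l / (1.0 + m_l * gl)[:, None]
            c_l = m_l / (1.0 + m_l * gl)
            a_row = 1.0 / (1.0 + m_l * gl)[self.row_lesion]
        else:
            DinvZ = Z
            ones_D_Z_l = np.add.reduceat(Z, self.les_starts, axis=0)
            c_l = m_l.astype(float)
            a_row = np.ones(self.n)
        c_g = np.zeros(self.n_patients)
        np.add.at(c_g, self.lesion_patient, c_l)
        u_g = np.zeros((self.n_patients, Z.shape[1]))
        np.add.at(u_g, self.lesion_patient, ones_D_Z_l)
        scale_g = gp / (1.0 + gp * c_g)
        return DinvZ - (scale_g[self.row_patient] * a_row)[:, None] \
            * u_g[self.row_patient]

    def pieces(self, gp: float, gl: float):
        """Return (logdet W, X'W^-1 X, X'W^-1 y, y'W^-1 y)."""
        R, p = self.R, self.p
        m_l = self.m_l
        # D^-1 applied to R (lesion blocks)
        if gl != 0.0:
            S_l = np.add.reduceat(R, self.les_starts, axis=0)
            fac_l = gl / (1.0 + m_l * gl)
            DinvR = R - fac_l[self.row_lesion, None] * S_l[self.row_lesion]
            ones_D_R_l = S_l / (1.0 + m_l * gl)[:, None]  # 1'D^-1 R per lesion
            c_l = m_l / (1.0 + m_l * gl)  # 1'D^-1 1 per lesion
            logdet = float(np.sum(np.log1p(m_l * gl)))
            a_row = 1.0 / (1.0 + m_l * gl)[self.row_lesion]
        else:
            DinvR = R
            S_l = np.add.reduceat(R, self.les_starts, axis=0)
            ones_D_R_l = S_l
            c_l = m_l.astype(float)
            logdet = 0.0
            a_row = np.ones(self.n)
        # rank-1 patient update: W^-1 = D^-1 - gp/(1+gp*c_g) (D^-1 1)(1'D^-1)
        c_g = np.zeros(self.n_patients)
        np.add.at(c_g, self.lesion_patient, c_l)
        u_g = np.zeros((self.n_patients, p + 1))
        np.add.at(u_g, self.lesion_patient, ones_D_R_l)
        denom_g = 1.0 + gp * c_g
        logdet += float(np.sum(np.log(denom_g)))
        scale_g = gp / denom_g
        WinvR = DinvR - (scale_g[self.row_patient] * a_row)[:, None] \
            * u_g[self.row_patient]
        M = R.T @ WinvR
        return logdet, M[:p, :p], M[:p, p], float(M[p, p])


def _assemble_kernel(df: pd.DataFrame, spec: LmmSpec):
    if spec.patient_col not in df.columns:
        raise ValueError(f"data lacks grouping column {spec.patient_col!r}")
    nested = spec.random == "patient+lesion"
    if nested and spec.lesion_col not in df.columns:
        raise ValueError(f"nested structure needs column {spec.lesion_col!r}")
    y_all = np.asarray(df[spec.response], dtype=float)
    if np.any(~np.isfinite(y_all)):
        raise ValueError("response contains non-finite values")
    X_df = dmatrix(spec.fixed, df, return_type="dataframe")
    if len(X_df) != len(df):
        raise ValueError("fixed-effect design dropped rows (missing covariates?)")
    X_all = np.asarray(X_df, dtype=float)
    names = tuple(X_df.design_info.column_names)
    p = X_all.shape[1]
    if np.linalg.matrix_rank(X_all) < p:
        raise ValueError("fixed-effect design matrix is rank deficient")
    patients = df[spec.patient_col].to_numpy()
    uniq = pd.unique(patients)
    if len(uniq) < 2:
        raise ValueError("need >= 2 patients for a random-intercept model")
    if nested:
        counts = df.groupby([spec.patient_col, spec.lesion_col]).size()
        if counts.max() < 2:
            raise ValueError(
                "nested lesion intercepts need repeated scans of the same lesion"
            )
    codes = pd.factorize(patients)[0]
    lesions = (pd.factorize(df[spec.lesion_col])[0] if nested else None)
    kernel = _Kernel(X_all, y_all, codes, lesions)
    return kernel, names, X_all.shape[0], p


def _profiled_pieces(kernel: _Kernel, gammas, nested):
    gp = float(gammas[0])
    gl = float(gammas[1]) if nested else 0.0
    return kernel.pieces(gp, gl)


def _profiled_criterion(log_gammas, kernel, nested, n, p, reml):
    gammas = np.exp(np.clip(log_gammas, -34.0, 34.0))
    logdet, XtWX, XtWy, ytWy = _profiled_pieces(kernel, gammas, nested)
    sign, logdet_xtwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return 1e12
    beta = np.linalg.solve(XtWX, XtWy)
    rss = max(ytWy - float(beta @ XtWy), _RSS_FLOOR * max(ytWy, 1.0))
    if reml:
        return logdet + logdet_xtwx + (n - p) * math.log(rss / (n - p))
    return logdet + n * math.log(rss / n)


def _numeric_hessian(f, x, rel_step=1e-4):
    k = len(x)
    h = np.maximum(np.abs(x), np.mean(np.abs(x))) * rel_step
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            xi, xj = h[i], h[j]
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += xi
                xm[i] -= xi
                H[i, i] = (f(xp) - 2 * f0 + f(xm)) / xi**2
            else:
                xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                xpp[[i, j]] += [xi, xj]
                xpm[i] += xi
                xpm[j] -= xj
                xmp[i] -= xi
                xmp[j] += xj
                xmm[[i, j]] -= [xi, xj]
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * xi * xj)
    return H


def _gls_at_theta(kernel: _Kernel, theta):
    """GLS pieces for raw components V = s2p*J + [s2l*L] + s2e*I.

    V = s2e * W with W = I + (s2p/s2e) J + (s2l/s2e) L, so the profiled kernel
    is reused and rescaled.
    """
    if len(theta) == 3:
        s2p, s2l, s2e = (float(t) for t in theta)
    else:
        s2p, s2e = (float(t) for t in theta)
        s2l = 0.0
    if s2e <= 0:
        raise np.linalg.LinAlgError("residual variance must be positive")
    logdetW, XtWX, XtWy, ytWy = kernel.pieces(s2p / s2e, s2l / s2e)
    n = kernel.n
    return (logdetW + n * math.log(s2e), XtWX / s2e, XtWy / s2e, ytWy / s2e)


def _neg2_loglik_at_theta(kernel, theta, reml):
    n, p = kernel.n, kernel.p
    logdet, XtVX, XtVy, ytVy = _gls_at_theta(kernel, theta)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = ytVy - float(beta @ XtVy)
    out = logdet + rss
    if reml:
        sign, ld2 = np.linalg.slogdet(XtVX)
        out += ld2 + (n - p) * math.log(2 * math.pi)
    else:
        out += n * math.log(2 * math.pi)
    return out


def _cvar_at_theta(kernel, theta, c):
    _, XtVX, _, _ = _gls_at_theta(kernel, theta)
    return float(c @ np.linalg.solve(XtVX, c))


def fit_lmm(df: pd.DataFrame, spec: LmmSpec) -> LmmFit:
    """Fit a random-intercept LMM by profiled REML (or ML).

    The variance-ratio criterion is minimized by Nelder-Mead from a small grid
    of starts and polished by Newton steps on numerical derivatives, so that on
    balanced designs the components agree with closed-form ANOVA estimators to
    high precision. Components that collapse to zero are reported as boundary
    estimates (``fit.boundary``) and downstream Satterthwaite df fall back to
    the normal approximation there.
    """
    kernel, names, n, p = _assemble_kernel(df, spec)
    nested = spec.random == "patient+lesion"
    reml = spec.method == "reml"
    k = 2 if nested else 1

    crit = lambda lg: _profiled_criterion(lg, kernel, nested, n, p, reml)
    best = None
    # coarse Nelder-Mead from a few starts; the Newton polish below supplies
    # the final precision
    starts = [np.zeros(k), np.full(k, -2.0), np.full(k, 2.0)]
    if k == 2:
        starts += [np.array([2.0, -2.0]), np.array([-2.0, 2.0])]
    for x0 in starts:
        res = optimize.minimize(crit, x0, method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-8,
                                         "maxiter": 400})
        if best is None or res.fun < best.fun:
            best = res
    lg = np.asarray(best.x, dtype=float)

    # Newton polish on the smooth profiled criterion (numerical derivatives)
    for _ in range(25):
        h = 1e-6
        grad = np.zeros(k)
        for i in range(k):
            xp, xm = lg.copy(), lg.copy()
            xp[i] += h
            xm[i] -= h
            grad[i] = (crit(xp) - crit(xm)) / (2 * h)
        if np.max(np.abs(grad)) < 1e-11:
            break
        H = _numeric_hessian(crit, lg, rel_step=1e-5)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        step = np.clip(step, -1.0, 1.0)
        cand = lg - step
        if crit(cand) <= crit(lg) + 1e-13 and np.all(cand > -34) and np.all(cand < 34):
            lg = cand
        else:
            break

    gammas = np.exp(np.clip(lg, -34.0, 34.0))
    logdet, XtWX, XtWy, ytWy = _profiled_pieces(kernel, gammas, nested)
    beta = np.linalg.solve(XtWX, XtWy)
    rss = max(ytWy - float(beta @ XtWy), _RSS_FLOOR * max(ytWy, 1.0))
    s2e = rss / (n - p) if reml else rss / n
    s2p = s2e * gammas[0]
    s2l = s2e * gammas[1] if nested else 0.0
    boundary = bool(gammas[0] < _GAMMA_FLOOR or (nested and gammas[1] < _GAMMA_FLOOR))
    if boundary:
        warnings.warn("a variance component hit the zero boundary; "
                      "Satterthwaite df fall back to the normal approximation",
                      stacklevel=2)
    vcov_beta = s2e * np.linalg.inv(XtWX)

    sign, logdet_xtwx = np.linalg.slogdet(XtWX)
    if reml:
        loglik = -0.5 * (logdet + logdet_xtwx + (n - p) * math.log(2 * math.pi * s2e)
                         + (n - p))
    else:
        loglik = -0.5 * (logdet + n * math.log(2 * math.pi * s2e) + n)

    theta_names = ("patient", "lesion", "resid") if nested else ("patient", "resid")
    return LmmFit(beta=beta, beta_names=names, vcov_beta=vcov_beta,
                  sigma2_patient=s2p, sigma2_lesion=s2l, sigma2_resid=s2e,
                  loglik=float(loglik), method=spec.method, n_obs=n,
                  n_params=p + k + 1, spec=spec, boundary=boundary,
                  _kernel=kernel, _theta_names=theta_names)


def percent_effect(fit: LmmFit, contrast: Sequence[float], conf_level: float = 0.95):
    """Back-transform a log-scale contrast to a percent difference.

    Returns ``(percent, (ci_low, ci_high), p)`` with
    percent = 100*(exp(c'beta) - 1) and CI endpoints transformed from the
    log-scale Wald interval (Satterthwaite df).
    """
    est, se, df, p, lo, hi = fit.contrast(contrast, conf_level)
    return (100.0 * (math.exp(est) - 1.0),
            (100.0 * (math.exp(lo) - 1.0), 100.0 * (math.exp(hi) - 1.0)),
            p)


def lrt(fit_full: LmmFit, fit_reduced: LmmFit):
    """Likelihood-ratio test of nested fixed-effect structures (ML fits only)."""
    if fit_full.method != "ml" or fit_reduced.method != "ml":
        raise ValueError("LRT requires ML fits; REML logliks are not comparable "
                         "across fixed-effect structures")
    df = fit_full.n_params - fit_reduced.n_params
    if df < 0:
        raise ValueError("reduced model must be nested in (not larger than) full")
    stat = max(2.0 * (fit_full.loglik - fit_reduced.loglik), 0.0)
    if df == 0:  # identical structures: no evidence either way
        return stat, 0, 1.0
    return stat, df, float(stats.chi2.sf(stat, df))


def compute_icc(fit: LmmFit) -> float:
    """Patient-level fraction of the log-uptake variance.

    With one scan per lesion the lesion and residual variability are
    inseparable, so the baseline model is patient + residual and the residual
    plays the lesion role: ICC = s2_patient / (s2_patient + s2_lesion + s2_resid).
    """
    total = fit.sigma2_patient + fit.sigma2_lesion + fit.sigma2_resid
    if total <= 0:
        raise ValueError("all variance components are zero; ICC undefined")
    return fit.sigma2_patient / total


@dataclass
class TreatmentChangeReport:
    percent_per_week: float
    ci: tuple
    p: float
    percent_per_week_pd: float
    percent_per_week_nonpd: float
    interaction_p: float
    projection_30d_percent: float
    adjusted: bool
    fit_overall: LmmFit = field(repr=False, default=None)
    fit_interaction: LmmFit = field(repr=False, default=None)


def _plugin_contrast(fit: LmmFit, c: np.ndarray, U: np.ndarray | None,
                     cov_theta: np.ndarray | None, conf_level: float = 0.95):
    """Wald inference for c'beta with first-stage plug-in variance added.

    When the response was built by adding U @ theta_hat (estimated spline
    coefficients), c'beta_hat inherits variance a'U cov(theta) U'a with a the
    GLS influence vector; this is propagated by the delta method on top of the
    usual mixed-model variance.
    """
    est, se, df, p, lo, hi = fit.contrast(c, conf_level)
    if U is None or cov_theta is None:
        return est, se, df, p, lo, hi
    a = fit.influence(c)
    w = a @ U
    extra = float(w @ cov_theta @ w)
    se_tot = math.sqrt(se**2 + max(extra, 0.0))
    if se_tot == 0.0:
        return est, se_tot, df, (1.0 if est == 0 else 0.0), est, est
    tstat = est / se_tot
    if math.isfinite(df):
        p = 2.0 * stats.t.sf(abs(tstat), df)
        tq = stats.t.ppf(0.5 + conf_level / 2.0, df)
    else:
        p = 2.0 * stats.norm.sf(abs(tstat))
        tq = stats.norm.ppf(0.5 + conf_level / 2.0)
    return est, se_tot, df, p, est - tq * se_tot, est + tq * se_tot


def treatment_change_model(data: pd.DataFrame, adjusted: bool = False,
                           suv_col: str | None = None,
                           spline=None) -> TreatmentChangeReport:
    """Per-week uptake change during therapy, overall and by PD vs non-PD.

    ``data`` is a lesion table (one row per lesion x scan) with columns
    ``patient_id``, ``lesion_id``, ``timepoint`` (days since therapy start;
    pretreatment coded 0), ``bor`` and the uptake column (``suv_max`` or, when
    ``adjusted``, ``suv_max_adjusted``). Time enters in weeks (days/7, exact).
    The model has nested random intercepts (lesion within patient); the
    response-dependence test is the Wald test (Satterthwaite df) of the
    week x non-PD interaction. The 30-day summary compounds the weekly rate:
    100*((1 + rate)^(30/7) - 1).

    For volume-adjusted analyses, pass the fitted ``spline`` (and have a
    ``volume_at_pet_cm3`` column): the adjusted response is a linear function
    of the estimated spline coefficients, and their sampling covariance is
    propagated into every reported interval and p value. Without it the
    intervals treat the adjustment as known and are anticonservative.
    """
    col = suv_col or ("suv_max_adjusted" if adjusted else "suv_max")
    for c in ("patient_id", "lesion_id", "timepoint", "bor", col):
        if c not in data.columns:
            raise ValueError(f"missing column {c!r}")
    df = data.copy()
    if not (df["timepoint"] > 0).any():
        raise ValueError("no on-treatment rows (timepoint > 0)")
    if (df[col] <= 0).any():
        raise ValueError("uptake must be positive for log-scale analysis")
    df["_y"] = np.log(df[col].astype(float))
    df["_weeks"] = df["timepoint"].astype(float) / 7.0
    df["_nonpd"] = (df["bor"].astype(str) != "PD").astype(float)

    U = cov_theta = None
    if spline is not None:
        if "volume_at_pet_cm3" not in df.columns:
            raise ValueError("plug-in propagation needs a volume_at_pet_cm3 column")
        if spline.cov_coefficients is not None:
            # adjusted log y = log s + (B(anchor) - B(V)) @ theta_hat
            U = (spline.basis(spline.anchor_volume_cm3)
                 - spline.basis(df["volume_at_pet_cm3"].to_numpy()))
            cov_theta = np.asarray(spline.cov_coefficients)

    fit_overall = fit_lmm(df, LmmSpec(response="_y", fixed="1 + _weeks",
                                      random="patient+lesion"))
    i_w = list(fit_overall.beta_names).index("_weeks")
    c = np.zeros(len(fit_overall.beta))
    c[i_w] = 1.0
    est, se, dfree, p, lo, hi = _plugin_contrast(fit_overall, c, U, cov_theta)
    pct = 100.0 * (math.exp(est) - 1.0)
    ci = (100.0 * (math.exp(lo) - 1.0), 100.0 * (math.exp(hi) - 1.0))

    fit_int = fit_lmm(df, LmmSpec(response="_y",
                                  fixed="1 + _weeks + _nonpd + _weeks:_nonpd",
                                  random="patient+lesion"))
    names = list(fit_int.beta_names)
    c_pd = np.zeros(len(fit_int.beta))
    c_pd[names.index("_weeks")] = 1.0
    c_non = c_pd.copy()
    c_non[names.index("_weeks:_nonpd")] = 1.0
    pct_pd = 100.0 * (math.exp(
        _plugin_contrast(fit_int, c_pd, U, cov_theta)[0]) - 1.0)
    pct_non = 100.0 * (math.exp(
        _plugin_contrast(fit_int, c_non, U, cov_theta)[0]) - 1.0)
    c_i = np.zeros(len(fit_int.beta))
    c_i[names.index("_weeks:_nonpd")] = 1.0
    _, _, _, p_int, _, _ = _plugin_contrast(fit_int, c_i, U, cov_theta)

    rate = pct / 100.0
    proj30 = 100.0 * ((1.0 + rate) ** (30.0 / 7.0) - 1.0)
    return TreatmentChangeReport(
        percent_per_week=pct, ci=ci, p=p,
        percent_per_week_pd=pct_pd, percent_per_week_nonpd=pct_non,
        interaction_p=p_int, projection_30d_percent=proj30,
        adjusted=adjusted, fit_overall=fit_overall, fit_interaction=fit_int,
    )
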