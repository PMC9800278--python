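"""Empirical partial-volume adjustment of lesion uptake.

Small lesions read out an artifactually low SUVmax because the PET point
spread function smears their signal over neighboring voxels (the partial
volume effect). Rather than a voxel-level correction, the adjustment here is
data driven: fit the pretreatment relation between CT-derived lesion volume
and log SUVmax with a 5-knot restricted cubic spline, express each observation
as its log-scale difference from the expected uptake of same-volume lesions,
and re-anchor that difference at the expected uptake of a 5 cm^3 lesion (a
volume safely inside the flat region of the curve). Lesion volumes at PET time
are linearly interpolated between the baseline and first response CT.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VolumeTrajectory",
    "SplineModel",
    "oblate_volume",
    "interpolate_volume",
    "rcs_basis",
    "fit_volume_uptake_spline",
    "adjust_uptake",
]

DEFAULT_ANCHOR_CM3 = 5.0
KNOT_QUANTILES = (0.05, 0.275, 0.5, 0.725, 0.95)  # Harrell default, 5 knots


@dataclass(frozen=True)
class VolumeTrajectory:
    """Lesion volume at baseline CT and at the first on-treatment CT."""

    v_baseline_cm3: float
    t_baseline_d: float
    v_followup_cm3: float
    t_followup_d: float

    def __post_init__(self) -> None:
        if self.v_baseline_cm3 < 0 or self.v_followup_cm3 < 0:
            raise ValueError("volumes must be >= 0")
        if self.t_followup_d <= self.t_baseline_d:
            raise ValueError("follow-up CT must be after baseline CT")


def oblate_volume(diam_long_cm, diam_short_cm):
    """Volume of an oblate spheroid from two orthogonal CT diameters.

    The two equal (equatorial) axes take the long measurement:
    V = (pi/6) * L^2 * S, in cm^3. Pass ``long_equatorial=False`` semantics via
    swapped arguments is rejected: the long diameter must come first.
    """
    L = np.asarray(diam_long_cm, dtype=float)
    S = np.asarray(diam_short_cm, dtype=float)
    if np.any(S < 0):
        raise ValueError("diameters must be >= 0")
    if np.any(L < S):
        raise ValueError("diam_long_cm must be >= diam_short_cm (argument order)")
    v = (math.pi / 6.0) * L**2 * S
    return float(v) if v.ndim == 0 else v


def interpolate_volume(traj: VolumeTrajectory, t_query_d: float) -> float:
    """Expected lesion volume at the PET date, linear between the two CTs.

    Queries after the follow-up CT clamp to the follow-up volume (no
    extrapolation below zero); queries before baseline are invalid.
    """
    if t_query_d < traj.t_baseline_d:
        raise ValueError("query time precedes the baseline CT")
    if t_query_d >= traj.t_followup_d:
        return traj.v_followup_cm3
    frac = (t_query_d - traj.t_baseline_d) / (traj.t_followup_d - traj.t_baseline_d)
    return traj.v_baseline_cm3 + frac * (traj.v_followup_cm3 - traj.v_baseline_cm3)


def rcs_basis(x, knots: Sequence[float]) -> np.ndarray:
    """Restricted cubic spline basis (Harrell), linear beyond boundary knots.

    For k knots t_1 < ... < t_k returns k-1 columns: x itself plus k-2
    truncated-cubic terms normalized by (t_k - t_1)^2, matching
    rms::rcspline.eval with norm=2.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = len(t)
    if k < 3 or np.any(np.diff(t) <= 0):
        raise ValueError("knots must be >= 3 strictly increasing values")
    norm = (t[-1] - t[0]) ** 2
    cols = [x]
    for j in range(k - 2):
        term = (
            np.clip(x - t[j], 0, None) ** 3
            - np.clip(x - t[-2], 0, None) ** 3 * (t[-1] - t[j]) / (t[-1] - t[-2])
            + np.clip(x - t[-1], 0, None) ** 3 * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(term / norm)
    return np.column_stack(cols)


@dataclass
class SplineModel:
    """Fitted expected log-uptake as a function of lesion volume."""

    knots: np.ndarray  # on the predictor scale (log volume by default)
    coefficients: np.ndarray  # intercept + k-1 basis coefficients
    predictor_transform: Literal["identity", "log"] = "log"
    anchor_volume_cm3: float = DEFAULT_ANCHOR_CM3
    n_lesions: int = 0
    sigma2_resid: float = float("nan")
    cov_coefficients: np.ndarray | None = None  # sampling cov of coefficients

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.knots) != 5:
            raise ValueError("expected exactly 5 knots")
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")

    def _transform(self, volume_cm3):
        v = np.asarray(volume_cm3, dtype=float)
        if np.any(v <= 0):
            raise ValueError("volumes must be positive")
        return np.log(v) if self.predictor_transform == "log" else v

    def basis(self, volume_cm3) -> np.ndarray:
        """Design rows [1, rcs basis] at the given volume(s)."""
        x = self._transform(volume_cm3)
        B = rcs_basis(np.atleast_1d(x), self.knots)
        return np.column_stack([np.ones(B.shape[0]), B])

    def expected_log_uptake(self, volume_cm3):
        """E(log SUVmax) at the given volume(s); linear tails beyond the knots."""
        out = self.basis(volume_cm3) @ self.coefficients
        return float(out[0]) if np.ndim(volume_cm3) == 0 else out

    @property
    def expected_at_anchor(self) -> float:
        return self.expected_log_uptake(self.anchor_volume_cm3)

    def to_json(self) -> str:
        return json.dumps({
            "knots": self.knots.tolist(),
            "coefficients": self.coefficients.tolist(),
            "predictor_transform": self.predictor_transform,
            "anchor_volume_cm3": self.anchor_volume_cm3,
            "n_lesions": self.n_lesions,
            "sigma2_resid": self.sigma2_resid,
            "cov_coefficients": (None if self.cov_coefficients is None
                                 else np.asarray(self.cov_coefficients).tolist()),
        })

    @classmethod
    def from_json(cls, text: str) -> "SplineModel":
        d = json.loads(text)
        return cls(knots=d["knots"], coefficients=d["coefficients"],
                   predictor_transform=d["predictor_transform"],
                   anchor_volume_cm3=d["anchor_volume_cm3"],
                   n_lesions=d.get("n_lesions", 0),
                   sigma2_resid=d.get("sigma2_resid", float("nan")),
                   cov_coefficients=(None if d.get("cov_coefficients") is None
                                     else np.asarray(d["cov_coefficients"])))


def fit_volume_uptake_spline(
    volumes_cm3: Sequence[float],
    suv_max: Sequence[float],
    patient_ids: Sequence | None = None,
    predictor_transform: Literal["identity", "log"] = "log",
    anchor_volume_cm3: float = DEFAULT_ANCHOR_CM3,
    trim_upper_quantile: float | None = None,
) -> SplineModel:
    """Regress log SUVmax on a 5-knot restricted cubic spline of volume.

    Fit on *pretreatment* lesions only. Knots sit at the (0.05, 0.275, 0.5,
    0.725, 0.95) quantiles of the (log-)volume; ``trim_upper_quantile`` (e.g.
    0.95) optionally drops lesions above that volume quantile before fitting.
    Volumes span three orders of magnitude, hence the default log predictor.

    When ``patient_ids`` are supplied the spline coefficients are fixed
    effects of a mixed model with a patient random intercept, consistent with
    the clustering handling everywhere else in the pipeline: lesions of one
    patient share an uptake level, and ignoring that both wastes efficiency
    and understates the curve's stability. Without ids the fit is OLS.
    """
    v = np.asarray(volumes_cm3, dtype=float)
    s = np.asarray(suv_max, dtype=float)
    if v.shape != s.shape:
        raise ValueError("volumes and SUVs must have the same length")
    pid = None if patient_ids is None else np.asarray(patient_ids)
    if pid is not None and pid.shape != v.shape:
        raise ValueError("patient_ids must match volumes in length")
    mask = np.isfinite(v) & np.isfinite(s)
    v, s = v[mask], s[mask]
    if pid is not None:
        pid = pid[mask]
    if np.any(v <= 0) or np.any(s <= 0):
        raise ValueError("volumes and SUVs must be positive")
    if trim_upper_quantile is not None:
        keep = v <= np.quantile(v, trim_upper_quantile)
        v, s = v[keep], s[keep]
        if pid is not None:
            pid = pid[keep]
    if v.size < 25:
        raise ValueError("need >= 25 lesions to fit the spline")
    x = np.log(v) if predictor_transform == "log" else v
    if len(np.unique(np.round(x, 12))) < 5:
        raise ValueError("degenerate volume spread: < 5 distinct values")
    knots = np.quantile(x, KNOT_QUANTILES)
    if np.any(np.diff(knots) <= 0):
        raise ValueError("degenerate volume spread: knots not distinct")
    y = np.log(s)
    B = rcs_basis(x, knots)
    if pid is not None and len(np.unique(pid)) >= 2:
        from .mixedmodel import LmmSpec, fit_lmm

        df = pd.DataFrame({f"b{j}": B[:, j] for j in range(B.shape[1])})
        df["patient_id"] = pid
        df["_y"] = y
        fixed = "1 + " + " + ".join(f"b{j}" for j in range(B.shape[1]))
        fit = fit_lmm(df, LmmSpec(response="_y", fixed=fixed, random="patient"))
        coef = fit.beta
        sigma2 = fit.sigma2_resid
        cov = fit.vcov_beta
    else:
        Bi = np.column_stack([np.ones(x.size), B])
        coef, _, rank, _ = np.linalg.lstsq(Bi, y, rcond=None)
        if rank < Bi.shape[1]:
            raise ValueError("spline design is rank deficient")
        resid = y - Bi @ coef
        sigma2 = float(resid @ resid / max(x.size - Bi.shape[1], 1))
        cov = sigma2 * np.linalg.inv(Bi.T @ Bi)
    return SplineModel(knots=knots, coefficients=np.asarray(coef),
                       predictor_transform=predictor_transform,
                       anchor_volume_cm3=anchor_volume_cm3,
                       n_lesions=int(x.size),
                       sigma2_resid=float(sigma2),
                       cov_coefficients=np.asarray(cov))


def adjust_uptake(suv_max, volume_at_pet_cm3, spline: SplineModel,
                  scale: Literal["log", "linear"] = "log"):
    """Partial-volume-adjusted uptake, anchored at the spline's anchor volume.

    On the default log scale the observed-minus-expected difference of log
    geometric means is re-anchored: adjusted = exp(log s - E(V) + E(anchor)).
    The ``linear`` mode takes the difference on the SUV scale instead
    (adjusted = s - exp(E(V)) + exp(E(anchor))); the log form keeps the whole
    analysis geometric and is the default.
    """
    s = np.asarray(suv_max, dtype=float)
    if np.any(s <= 0):
        raise ValueError("suv_max must be positive")
    ev = spline.expected_log_uptake(np.atleast_1d(volume_at_pet_cm3))
    e5 = spline.expected_at_anchor
    if scale == "log":
        out = np.exp(np.log(s) - ev + e5)
    elif scale == "linear":
        out = s - np.exp(ev) + np.exp(e5)
    else:
        raise ValueError("scale must be 'log' or 'linear'")
    return float(out[0]) if np.ndim(suv_max) == 0 and out.size == 1 else out


def add_volume_columns(lesions: pd.DataFrame) -> pd.DataFrame:
    """Add ``volume_cm3`` (oblate spheroid at the scan's CT) per row."""
    df = lesions.copy()
    df["volume_cm3"] = oblate_volume(df["diam_long_cm"].to_numpy(),
                                     df["diam_short_cm"].to_numpy())
    return df


def add_pet_volumes(lesions: pd.DataFrame) -> pd.DataFrame:
    """Add ``volume_at_pet_cm3``: CT volume interpolated to the PET date.

    Each row's CT volume (``volume_cm3``) was measured ``ct_date_offset_days``
    away from the PET scan. Baseline rows use their own CT volume; on-treatment
    rows interpolate linearly between the baseline CT (day 0) and the row's
    response CT at day ``timepoint + ct_date_offset_days``, evaluated at the
    PET day.
    """
    df = lesions.copy()
    if "volume_cm3" not in df.columns:
        df = add_volume_columns(df)
    df["volume_at_pet_cm3"] = df["volume_cm3"]
    base = df[df["timepoint"] == 0].set_index("lesion_id")["volume_cm3"]
    on = df["timepoint"] > 0
    for idx in df.index[on]:
        row = df.loc[idx]
        lid = row["lesion_id"]
        if lid not in base.index:
            continue  # no baseline CT: keep the row's own CT volume
        t_ct = float(row["timepoint"] + row["ct_date_offset_days"])
        traj = VolumeTrajectory(float(base[lid]), 0.0,
                                float(row["volume_cm3"]), max(t_ct, 1e-9))
        df.loc[idx, "volume_at_pet_cm3"] = interpolate_volume(
            traj, float(row["timepoint"]))
    return df
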