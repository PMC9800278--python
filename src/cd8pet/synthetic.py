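"""Seeded synthetic cohorts, serum PK series and slide pairs with ground truth.

The clinical trial data behind this pipeline are access restricted, so every
analysis here is exercised on synthetic data that reproduces the trial's
*statistical* structure, with the generating parameters kept as ground truth
for recovery tests:

* hierarchical log-normal lesion SUVmax — grand geometric mean 5.6, geometric
  CV 0.72, patient-level intraclass correlation 0.46, ~38 patients with a
  zero-truncated Poisson(7) number of lesions each (~266 lesions);
* best overall response drawn with the trial's mix (19 PD / 4 SD / 8 PR /
  4 CR of 35 evaluable), response-dependent per-week uptake slopes and
  volume shrinkage on treatment;
* a partial-volume attenuation f(V) = min(1, (V/2)^gamma) multiplying the
  measured SUV of lesions below 2 cm^3 — the analysis must rediscover this
  knee from the data, never read gamma;
* exponential survival whose log-hazard is linked to the patient's baseline
  geometric-mean uptake;
* monoexponential serum decay with a 1.19-day half-life;
* IHC/autoradiography slide pairs with a known affine misalignment and a
  spatially varying CD8 density field per immune phenotype.

SUV statistics are generated at lesion level; there is no voxel-level PET
simulation.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .coreg import AffineTransform, warp_image

__all__ = [
    "GeneratorParams",
    "CohortDataset",
    "SlidePair",
    "generate_cohort",
    "generate_pk_series",
    "generate_slide_pair",
    "PART_A_SCHEDULE_DAYS",
]

BOR_LEVELS = ("PD", "SD", "PR", "CR")
# part-A sampling schedule: before injection and 30 min, 3 h, 1-2 d, 4 d, 7 d
PART_A_SCHEDULE_DAYS = (0.0, 0.5 / 24.0, 3.0 / 24.0, 1.0, 2.0, 4.0, 7.0)

_TOTAL_LOG_VAR = math.log(1.0 + 0.72**2)  # GCV 0.72 -> sigma^2_total


def _default_slopes() -> dict:
    # log-SUV change per week on treatment; deeper decline with better response
    return {"PD": -0.02, "SD": -0.05, "PR": -0.09, "CR": -0.12}


def _default_shrinkage() -> dict:
    # relative volume change per week, as a fraction of the baseline volume
    # (linear in time, like the piecewise-linear course RECIST assessments
    # resolve); responders shrink
    return {"PD": 0.05, "SD": 0.0, "PR": -0.10, "CR": -0.14}


@dataclass
class GeneratorParams:
    """Knobs of the synthetic trial; defaults reproduce the study conditions."""

    n_patients: int = 38
    lesions_per_patient: float = 7.0  # zero-truncated Poisson mean
    mu_log_suv: float = math.log(5.6)
    sd_patient: float = math.sqrt(0.46 * _TOTAL_LOG_VAR)
    sd_lesion: float = math.sqrt(0.54 * _TOTAL_LOG_VAR - 0.01)
    sd_residual: float = 0.1
    icc_target: float = 0.46
    bor_probs: tuple = (19 / 35, 4 / 35, 8 / 35, 4 / 35)  # (PD, SD, PR, CR)
    slope_per_week_by_bor: dict = field(default_factory=_default_slopes)
    lesion_slope_sd: float = 0.01  # interlesional slope heterogeneity (log/week)
    shrinkage_per_week_by_bor: dict = field(default_factory=_default_shrinkage)
    pv_threshold_cm3: float = 2.0
    pv_gamma: float = 0.3  # 0 disables the attenuation entirely
    serum_half_life_days: float = 1.19
    pk_c0: float = 100.0  # arbitrary concentration units at t=0
    hr_per_sd: float = -math.log(1.6)  # log-hazard per +1 SD patient uptake
    censor_rate: float = 0.03  # random censoring hazard, per month
    horizon_months: float = 18.0  # administrative censoring
    ontreatment_fraction: float = 0.5  # patients with repeat imaging (19/38)
    irradiated_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        for name in ("sd_patient", "sd_lesion", "sd_residual", "lesion_slope_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        probs = np.asarray(self.bor_probs, dtype=float)
        if probs.shape != (4,) or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("bor_probs must be 4 nonnegative values summing to 1")
        if self.pv_threshold_cm3 <= 0:
            raise ValueError("pv_threshold_cm3 must be positive")
        if self.serum_half_life_days <= 0:
            raise ValueError("serum half-life must be positive")
        if not 0.0 <= self.icc_target <= 1.0:
            raise ValueError("icc_target must lie in [0, 1]")
        missing = set(BOR_LEVELS) - set(self.slope_per_week_by_bor)
        missing |= set(BOR_LEVELS) - set(self.shrinkage_per_week_by_bor)
        if missing:
            raise ValueError(f"per-BOR maps lack levels: {sorted(missing)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bor_probs"] = list(d["bor_probs"])
        return d


@dataclass
class CohortDataset:
    """Lesion x scan table, patient table, PK table and generator ground truth."""

    lesions: pd.DataFrame
    patients: pd.DataFrame
    pk: pd.DataFrame
    ground_truth: dict

    def validate(self) -> None:
        orphan = set(self.lesions["patient_id"]) - set(self.patients["patient_id"])
        if orphan:
            raise ValueError(f"lesions reference unknown patients: {sorted(orphan)[:3]}")
        per_lesion = self.lesions.groupby("lesion_id")["patient_id"].nunique()
        if (per_lesion > 1).any():
            raise ValueError("a lesion_id maps to more than one patient")
        if not set(self.patients["bor"]).issubset(set(BOR_LEVELS) | {"NE"}):
            raise ValueError("invalid BOR category")


def pv_attenuation(volume_cm3, threshold_cm3: float, gamma: float):
    """Multiplicative partial-volume factor min(1, (V/threshold)^gamma)."""
    v = np.asarray(volume_cm3, dtype=float)
    return np.minimum(1.0, (v / threshold_cm3) ** gamma)


def generate_cohort(params: GeneratorParams) -> CohortDataset:
    """Simulate one trial cohort; deterministic given ``params`` (incl. seed).

    Baseline log SUVmax = mu + u_patient + v_lesion + eps with the configured
    SDs; on-treatment adds (per-BOR slope + lesion slope noise) x weeks.
    Measured SUV is the noisy true SUV times the partial-volume factor at the
    lesion's *current* volume. Lesion volumes follow per-BOR weekly relative
    change; each scan row carries the CT diameters measured at the nearest CT
    (baseline CT at day 0, response CT at ~6 weeks) plus the CT-to-PET offset,
    so downstream code must interpolate volume to PET time itself.
    """
    if params.n_patients == 0:
        raise ValueError("empty cohort: n_patients is 0")
    rng = np.random.default_rng(params.seed)
    lam = params.lesions_per_patient
    sigma_p, sigma_l, sigma_e = params.sd_patient, params.sd_lesion, params.sd_residual

    patient_rows, lesion_rows = [], []
    for i in range(params.n_patients):
        pid = f"P{i+1:03d}"
        bor = BOR_LEVELS[rng.choice(4, p=np.asarray(params.bor_probs))]
        mmr = "dMMR" if rng.random() < 9 / 34 else "pMMR"
        phenotype = ("desert", "stromal", "inflamed")[
            rng.choice(3, p=[15 / 34, 15 / 34, 4 / 34])
        ]
        u_p = rng.normal(0.0, sigma_p)
        # zero-truncated Poisson lesion count
        n_les = 0
        while n_les == 0:
            n_les = int(rng.poisson(lam))
        has_repeat = rng.random() < params.ontreatment_fraction
        t_on = float(rng.uniform(28.0, 36.0)) if has_repeat else np.nan
        t_ct = float(rng.uniform(40.0, 44.0))  # first response CT, ~6 weeks
        slope_pat = params.slope_per_week_by_bor[bor]
        shrink = params.shrinkage_per_week_by_bor[bor]

        true_log_lesions = []
        for j in range(n_les):
            lid = f"{pid}-L{j+1:02d}"
            site = ("lymph_node", "lung", "liver", "bone", "skin")[
                rng.choice(5, p=[99 / 212, 42 / 212, 35 / 212, 17 / 212, 19 / 212])
            ]
            irradiated = bool(rng.random() < params.irradiated_fraction)
            # CT geometry: long diameter lognormal (>= 1 cm), oblate short axis
            L = 0.0
            while L < 1.0:
                L = float(rng.lognormal(math.log(1.8), 0.65))
            rho = float(rng.uniform(0.6, 1.0))
            S = rho * L
            v0 = (math.pi / 6.0) * L**2 * S
            v_ratio = S / L  # preserved while the lesion scales isotropically
            suv_mean_ratio = float(rng.uniform(0.55, 0.85))

            v_l = rng.normal(0.0, sigma_l)
            true0 = params.mu_log_suv + u_p + v_l
            true_log_lesions.append(true0)
            slope_les = slope_pat + rng.normal(0.0, params.lesion_slope_sd)

            def row(timepoint_d, true_log, volume_now, ct_volume, ct_offset_d):
                att = float(pv_attenuation(volume_now, params.pv_threshold_cm3,
                                           params.pv_gamma))
                eps = rng.normal(0.0, sigma_e)
                measured = math.exp(true_log + eps) * att
                # back out CT diameters from the CT-date volume
                Lc = (6.0 * ct_volume / (math.pi * v_ratio)) ** (1.0 / 3.0)
                return {
                    "patient_id": pid, "lesion_id": lid, "organ_site": site,
                    "irradiated": irradiated, "timepoint": timepoint_d,
                    "suv_max": measured, "suv_mean": measured * suv_mean_ratio,
                    "diam_long_cm": Lc, "diam_short_cm": Lc * v_ratio,
                    "ct_date_offset_days": ct_offset_d, "bor": bor,
                    "true_log_suv": true_log, "true_volume_cm3": volume_now,
                }

            lesion_rows.append(row(0.0, true0, v0, v0, 0.0))
            if has_repeat:
                weeks = t_on / 7.0
                # linear-in-time volume course, floored at a minimal
                # CT-measurable volume
                v_on = v0 * max(1.0 + shrink * weeks, 0.01)
                v_ct = v0 * max(1.0 + shrink * (t_ct / 7.0), 0.01)
                lesion_rows.append(row(
                    t_on, true0 + slope_les * weeks, v_on, v_ct, t_ct - t_on))

        patient_rows.append({
            "patient_id": pid, "bor": bor, "mmr_status": mmr,
            "phenotype": phenotype, "n_lesions": n_les,
            "ontreatment_day": t_on, "response_ct_day": t_ct,
            "true_u_patient": u_p, "true_slope_per_week": slope_pat,
            "true_geomean_log_suv": float(np.mean(true_log_lesions)),
        })

    patients = pd.DataFrame(patient_rows)
    lesions = pd.DataFrame(lesion_rows)

    # survival linked to standardized patient-level baseline uptake
    g = patients["true_geomean_log_suv"].to_numpy()
    z = (g - g.mean()) / g.std(ddof=1) if len(g) > 1 and g.std(ddof=1) > 0 \
        else np.zeros(len(g))
    lam_os = math.log(2.0) / 9.0  # baseline hazard: median OS ~9 months
    pfs_median = {"PD": 1.5, "SD": 4.0, "PR": 8.0, "CR": 12.0}
    os_t, os_e, pfs_t, pfs_e = [], [], [], []
    for k, brow in enumerate(patients.itertuples()):
        h_os = lam_os * math.exp(params.hr_per_sd * z[k])
        t_os = rng.exponential(1.0 / h_os)
        h_pfs = math.log(2.0) / pfs_median[brow.bor] * math.exp(params.hr_per_sd * z[k])
        t_pfs = rng.exponential(1.0 / h_pfs)
        c = params.horizon_months
        if params.censor_rate > 0:
            c = min(c, rng.exponential(1.0 / params.censor_rate))
        c = max(c, 0.05)
        os_t.append(min(t_os, c))
        os_e.append(int(t_os <= c))
        t_pfs = min(t_pfs, t_os)  # progression cannot follow death
        pfs_t.append(min(t_pfs, c))
        pfs_e.append(int(t_pfs <= c))
    patients["os_months"] = os_t
    patients["os_event"] = os_e
    patients["pfs_months"] = pfs_t
    patients["pfs_event"] = pfs_e
    patients["z_uptake"] = z

    pk = generate_pk_series(params, n_samples=min(9, params.n_patients),
                            noise_cv=0.1, rng=rng)

    truth = {
        "params": params.to_dict(),
        "u_patient": dict(zip(patients["patient_id"], patients["true_u_patient"])),
        "slope_per_week": dict(zip(patients["patient_id"],
                                   patients["true_slope_per_week"])),
    }
    ds = CohortDataset(lesions=lesions, patients=patients, pk=pk,
                       ground_truth=truth)
    ds.validate()
    return ds


def generate_pk_series(params: GeneratorParams, n_samples: int = 9,
                       noise_cv: float = 0.1,
                       times_d=PART_A_SCHEDULE_DAYS,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Monoexponential serum concentration-time tables.

    C(t) = C0 * 2^(-t / t_half) * (1 + noise), noise ~ N(0, noise_cv),
    sampled at the part-A schedule by default. Concentrations are floored at
    a tiny positive value so log-scale fits stay defined.
    """
    if params.serum_half_life_days <= 0:
        raise ValueError("serum half-life must be positive")
    times = np.asarray(times_d, dtype=float)
    if times.max() < 2.0 * params.serum_half_life_days:
        raise ValueError("sampling times must span >= 2 half-lives")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    rows = []
    for i in range(n_samples):
        clean = params.pk_c0 * 2.0 ** (-times / params.serum_half_life_days)
        noisy = clean * (1.0 + noise_cv * rng.normal(size=times.size))
        noisy = np.maximum(noisy, params.pk_c0 * 1e-9)
        for t, c in zip(times, noisy):
            rows.append({"patient_id": f"PK{i+1:03d}", "time_d": float(t),
                         "concentration": float(c)})
    return pd.DataFrame(rows)


@dataclass
class SlidePair:
    """One registered IHC/autoradiography pair with synthetic ground truth."""

    ihc_positivity: np.ndarray  # bool, IHC frame
    arg_image: np.ndarray  # float >= 0, ARG frame
    roi_mask: np.ndarray  # bool, IHC frame
    background_mask: np.ndarray  # bool, IHC frame (non-tissue)
    landmarks: pd.DataFrame  # columns x_ihc, y_ihc, x_arg, y_arg
    scan_delay_h: float
    true_affine: AffineTransform | None = None  # IHC (row,col) -> ARG (row,col)
    true_density_field: np.ndarray | None = None

    def validate(self) -> None:
        shp = self.ihc_positivity.shape
        for name in ("roi_mask", "background_mask"):
            if getattr(self, name).shape != shp:
                raise ValueError(f"{name} shape differs from IHC image")
        if len(self.landmarks) < 3:
            raise ValueError("need >= 3 landmark pairs")
        if not np.all(np.isfinite(self.arg_image)) or np.any(self.arg_image < 0):
            raise ValueError("ARG image must be finite and nonnegative")


def _roi_ellipse(shape, rng) -> np.ndarray:
    H, W = shape
    rr, cc = np.mgrid[0:H, 0:W]
    cy, cx = H * rng.uniform(0.45, 0.55), W * rng.uniform(0.45, 0.55)
    ay, ax = H * rng.uniform(0.28, 0.36), W * rng.uniform(0.24, 0.32)
    return ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 <= 1.0


def generate_slide_pair(shape=(256, 256), phenotype: str = "stromal",
                        affine: AffineTransform | None = None,
                        noise_sd: float = 0.02, scan_delay_h: float = 24.0,
                        seed: int = 0, background_level: float = 0.05,
                        psf_sigma_px: float = 3.0) -> SlidePair:
    """Synthetic slide pair with known misalignment and CD8 density field.

    The CD8 density is a smoothed random blob field scaled by phenotype:
    *desert* near-zero inside the tumor, *stromal* concentrated in a rim at
    the tumor border, *inflamed* diffusely elevated. IHC positivity is a
    Bernoulli draw per pixel from the density. The ARG is the PSF-blurred
    density, decayed by 2^(-scan_delay_h/78.4), resampled into the ARG frame
    through ``affine`` (IHC->ARG; identity if omitted), plus a uniform
    background and Gaussian noise. Landmarks are exact corresponding points.
    """
    H, W = shape
    if H < 256 or W < 256:
        raise ValueError("shape must be at least 256 x 256")
    if phenotype not in ("desert", "stromal", "inflamed"):
        raise ValueError("phenotype must be desert, stromal or inflamed")
    if affine is None:
        affine = AffineTransform.identity()
    rng = np.random.default_rng(seed)

    roi = _roi_ellipse(shape, rng)
    blobs = ndimage.gaussian_filter(rng.normal(size=shape), sigma=min(H, W) / 16)
    blobs = (blobs - blobs.min()) / (blobs.max() - blobs.min() + 1e-12)
    dist_in = ndimage.distance_transform_edt(roi)
    rim = np.exp(-dist_in / (0.06 * min(H, W))) * roi
    if phenotype == "desert":
        density = 0.015 * blobs * roi
    elif phenotype == "stromal":
        density = (0.55 * rim + 0.06 * blobs) * roi * (0.4 + 0.6 * blobs)
    else:  # inflamed
        density = (0.25 + 0.5 * blobs) * roi
    density = np.clip(density + 0.01 * blobs * ~roi, 0.0, 1.0)

    ihc = rng.random(shape) < density

    signal = ndimage.gaussian_filter(density, sigma=psf_sigma_px)
    signal = signal * 2.0 ** (-scan_delay_h / 78.4)
    # ARG frame: pull the IHC-frame signal through the inverse map
    warped, valid = warp_image(signal, affine.inverse(), shape, "bilinear")
    arg = np.where(valid, warped, 0.0) + background_level
    if noise_sd > 0:
        arg = arg + rng.normal(0.0, noise_sd, shape)
    arg = np.clip(arg, 0.0, None)

    # background: image border strip away from tissue (IHC frame)
    border = np.zeros(shape, dtype=bool)
    b = max(8, min(H, W) // 32)
    border[:b, :] = border[-b:, :] = border[:, :b] = border[:, -b:] = True
    background_mask = border & ~ndimage.binary_dilation(roi, iterations=5)

    pts = np.array([[H * 0.2, W * 0.2], [H * 0.2, W * 0.8],
                    [H * 0.8, W * 0.25], [H * 0.75, W * 0.75],
                    [H * 0.5, W * 0.5]])
    mapped = affine.apply(pts)
    landmarks = pd.DataFrame({
        "x_ihc": pts[:, 1], "y_ihc": pts[:, 0],
        "x_arg": mapped[:, 1], "y_arg": mapped[:, 0],
    })
    pair = SlidePair(ihc_positivity=ihc, arg_image=arg, roi_mask=roi,
                     background_mask=background_mask, landmarks=landmarks,
                     scan_delay_h=scan_delay_h, true_affine=affine,
                     true_density_field=density)
    pair.validate()
    return pair
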