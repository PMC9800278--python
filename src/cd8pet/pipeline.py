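"""End-to-end orchestration: simulate -> quantify -> adjust -> model -> survive -> coreg.

Every run is a pure function of (config, seed): each enabled stage writes its
outputs plus a manifest (stage parameters, seed, output checksums) under the
run directory, and the final report aggregates the headline numbers (geometric
means, percent-per-week raw vs adjusted, KM medians, tau by tile size).
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .coreg import estimate_affine, summarize_slide, warp_image, correlate_slides
from .mixedmodel import LmmSpec, compute_icc, fit_lmm, treatment_change_model
from .petquant import estimate_terminal_half_life, summarize_uptake
from .survival import firth_cox, km_estimate, logrank_test, median_split, patient_exposure
from .synthetic import (GeneratorParams, generate_cohort, generate_slide_pair)
from .volume import (DEFAULT_ANCHOR_CM3, add_pet_volumes, add_volume_columns,
                     adjust_uptake, fit_volume_uptake_spline)

log = logging.getLogger("cd8pet")

ALL_STAGES = ("simulate", "quant", "adjust", "model", "survival", "coreg")


@dataclass
class PipelineConfig:
    out_dir: str = "cd8pet_run"
    seed: int = 0
    stages: tuple = ALL_STAGES
    generator: dict = field(default_factory=dict)
    anchor_volume_cm3: float = DEFAULT_ANCHOR_CM3
    tile_sizes: tuple = (32, 64, 128)  # matched to the synthetic slide size
    stride_frac: float = 0.5
    n_slides: int = 8
    slide_shape: tuple = (256, 256)
    endpoints: tuple = ("pfs", "os")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        bad = set(cfg.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"stages: unknown stage names {sorted(bad)}")
        return cfg

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir), "seed": self.seed,
            "stages": list(self.stages), "generator": dict(self.generator),
            "anchor_volume_cm3": self.anchor_volume_cm3,
            "tile_sizes": list(self.tile_sizes),
            "stride_frac": self.stride_frac, "n_slides": self.n_slides,
            "slide_shape": list(self.slide_shape),
            "endpoints": list(self.endpoints),
        }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order and return the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": list(config.stages)}
    stages = set(config.stages)

    gen_kwargs = dict(config.generator)
    gen_kwargs["seed"] = config.seed
    params = GeneratorParams(**gen_kwargs)

    dataset = None
    if "simulate" in stages:
        dataset = generate_cohort(params)
        files = cio.write_cohort(dataset, out / "data")
        cio.write_manifest(out, "simulate", config.seed, params.to_dict(),
                           files.values())
        report["n_patients"] = int(len(dataset.patients))
        report["n_lesions"] = int(
            dataset.lesions[dataset.lesions.timepoint == 0].shape[0])
    else:
        data_dir = out / "data"
        if not (data_dir / "lesions.csv").exists():
            raise FileNotFoundError(f"no input data under {data_dir}; "
                                    "enable the simulate stage or provide CSVs")
        from .synthetic import CohortDataset
        dataset = CohortDataset(
            lesions=cio.read_lesion_table(data_dir / "lesions.csv"),
            patients=cio.read_table(data_dir / "patients.csv"),
            pk=cio.read_table(data_dir / "pk.csv"),
            ground_truth={},
        )

    lesions = dataset.lesions
    baseline = lesions[(lesions["timepoint"] == 0)
                       & (~lesions["irradiated"].astype(bool))]

    if "quant" in stages:
        summ = summarize_uptake(baseline["suv_max"])
        halves = [estimate_terminal_half_life(g)[0]
                  for _, g in dataset.pk.groupby("patient_id")]
        quant = {
            "baseline_geomean_suvmax": summ.geometric_mean,
            "baseline_gcv": summ.gcv,
            "baseline_ci": [summ.ci_low, summ.ci_high],
            "n_lesions": summ.n,
            "serum_half_life_days": float(np.mean(halves)),
            "serum_half_life_sd": float(np.std(halves, ddof=1)) if len(halves) > 1 else 0.0,
        }
        path = out / "quant.json"
        path.write_text(json.dumps(quant, indent=2))
        cio.write_manifest(out, "quant", config.seed, {}, [path])
        report["quant"] = quant

    adjusted_tbl = None
    spline = None
    if "adjust" in stages:
        tbl = add_pet_volumes(add_volume_columns(lesions))
        pre = tbl[(tbl["timepoint"] == 0) & (~tbl["irradiated"].astype(bool))]
        spline = fit_volume_uptake_spline(pre["volume_cm3"], pre["suv_max"],
                                          patient_ids=pre["patient_id"],
                                          anchor_volume_cm3=config.anchor_volume_cm3)
        tbl["suv_max_adjusted"] = adjust_uptake(
            tbl["suv_max"].to_numpy(), tbl["volume_at_pet_cm3"].to_numpy(), spline)
        adjusted_tbl = tbl
        cio.write_table(tbl, out / "lesions_adjusted.csv")
        (out / "spline.json").write_text(spline.to_json())
        cio.write_manifest(out, "adjust", config.seed,
                           {"anchor_volume_cm3": config.anchor_volume_cm3},
                           [out / "lesions_adjusted.csv", out / "spline.json"])
        report["adjust"] = {
            "expected_log_uptake_at_anchor": spline.expected_at_anchor,
            "n_fit_lesions": spline.n_lesions,
        }

    if "model" in stages:
        base_model = baseline.copy()
        base_model["_y"] = np.log(base_model["suv_max"].astype(float))
        fit0 = fit_lmm(base_model, LmmSpec(response="_y", fixed="1",
                                           random="patient"))
        icc = compute_icc(fit0)
        model_report = {
            "icc": icc,
            "geomean_from_lmm": math.exp(float(fit0.beta[0])),
        }
        has_repeat = (lesions["timepoint"] > 0).any()
        if has_repeat:
            raw = treatment_change_model(lesions, adjusted=False)
            model_report["raw"] = {
                "percent_per_week": raw.percent_per_week, "ci": list(raw.ci),
                "interaction_p": raw.interaction_p,
                "projection_30d_percent": raw.projection_30d_percent,
            }
            if adjusted_tbl is not None:
                adj = treatment_change_model(adjusted_tbl, adjusted=True,
                                             spline=spline)
                model_report["adjusted"] = {
                    "percent_per_week": adj.percent_per_week, "ci": list(adj.ci),
                    "interaction_p": adj.interaction_p,
                    "projection_30d_percent": adj.projection_30d_percent,
                }
        path = out / "model_report.json"
        path.write_text(json.dumps(model_report, indent=2))
        cio.write_manifest(out, "model", config.seed, {}, [path])
        report["model"] = model_report

    if "survival" in stages:
        expo = patient_exposure(lesions)
        groups = median_split(expo)
        pat = dataset.patients.set_index("patient_id")
        surv_report = {"median_exposure": float(expo.median())}
        for ep in config.endpoints:
            tcol, ecol = f"{ep}_months", f"{ep}_event"
            recs = pd.DataFrame({
                "time": pat.loc[expo.index, tcol].astype(float),
                "event": pat.loc[expo.index, ecol].astype(int),
                "covariate": expo.values,
            })
            hi = recs[groups.values == "high"]
            lo = recs[groups.values == "low"]
            km_hi, km_lo = km_estimate(hi), km_estimate(lo)
            chi2, p = logrank_test(hi, lo)
            cox = firth_cox(recs, per_sd=True, decrease=True)
            surv_report[ep] = {
                "median_high": km_hi.median, "median_low": km_lo.median,
                "logrank_chi2": chi2, "logrank_p": p,
                "hr_per_sd_decrease": cox.hr, "hr_ci": list(cox.ci),
                "hr_p": cox.p,
            }
        path = out / "survival.json"
        path.write_text(json.dumps(surv_report, indent=2, default=float))
        cio.write_manifest(out, "survival", config.seed, {}, [path])
        report["survival"] = surv_report

    if "coreg" in stages:
        rng = np.random.default_rng(config.seed + 101)
        summaries = []
        slide_dir = out / "slides"
        outputs = []
        from .coreg import AffineTransform
        for i in range(config.n_slides):
            phen = ("desert", "stromal", "inflamed")[i % 3]
            th = rng.uniform(-0.3, 0.3)
            s = rng.uniform(0.8, 1.25)
            M = s * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            A = AffineTransform(M, rng.uniform(-10, 10, 2))
            pair = generate_slide_pair(config.slide_shape, phen, A,
                                       noise_sd=0.02,
                                       scan_delay_h=float(rng.uniform(24, 96)),
                                       seed=int(rng.integers(0, 2**31 - 1)))
            sid = f"S{i+1:02d}"
            cio.write_slide_pair(pair, slide_dir, sid)
            dst, src = cio.landmarks_to_rc(pair.landmarks)
            est, rmse = estimate_affine(dst, src)
            aligned, _ = warp_image(pair.arg_image, est, pair.ihc_positivity.shape)
            summ = summarize_slide(sid, pair.ihc_positivity, aligned,
                                   pair.roi_mask, pair.background_mask,
                                   pair.scan_delay_h,
                                   tile_sizes=config.tile_sizes,
                                   stride_frac=config.stride_frac)
            summaries.append(summ)
            for size, tbl in summ.tile_tables.items():
                tp = slide_dir / f"{sid}_tiles_{size}.csv"
                cio.write_table(tbl, tp)
                outputs.append(tp)
        coreg_report = {
            "slide_level": correlate_slides(summaries, "slide-level"),
            "pooled_by_size": {},
        }
        for size in config.tile_sizes:
            try:
                res = correlate_slides(summaries, "tile-pooled", tile_size=size)
                coreg_report["pooled_by_size"][str(size)] = {
                    "tau": res["tau"], "p": res["p"], "n_tiles": res["n_tiles"]}
            except ValueError:
                continue
        path = out / "correlation.json"
        path.write_text(json.dumps(coreg_report, indent=2, default=float))
        outputs.append(path)
        cio.write_manifest(out, "coreg", config.seed,
                           {"tile_sizes": list(config.tile_sizes)}, outputs)
        report["coreg"] = coreg_report

    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
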