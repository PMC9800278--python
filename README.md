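# cd8pet

Analysis pipeline for whole-body CD8 immuno-PET trials: SUV quantification,
an empirical spline-based partial-volume adjustment of longitudinal lesion
uptake, geometric-mean mixed-model inference, survival analysis on uptake
strata, and spatial autoradiography–IHC correlation — together with a seeded
synthetic-trial generator that reproduces the statistical structure such
studies produce.

## The problem

A zirconium-89-labeled one-armed anti-CD8 antibody makes CD8⁺ T cells visible
on PET across every lesion of a patient at once. Quantifying what those images
say about immunotherapy is a statistics problem with several traps:

* **Clustered, right-skewed uptake.** SUVmax of lesions is log-normal-ish and
  clusters within patients (several lesions each) and within lesions
  (repeat scans). All inference here uses linear mixed models on
  log SUVmax with a patient random intercept and, for repeat imaging, a
  lesion intercept nested within patient:

  `log SUVmax_ijk = x'β + u_i + v_ij + ε_ijk`,
  `u ~ N(0, σ²_patient), v ~ N(0, σ²_lesion), ε ~ N(0, σ²_resid)`,

  fitted by REML with Satterthwaite degrees of freedom (ML for likelihood
  ratio tests and AIC). Estimates back-transform to geometric means and
  percent differences, e.g. a per-week log slope b reads as
  `100·(e^b − 1)` percent per week.

* **Partial-volume bias masquerading as pharmacodynamics.** Lesions that
  respond shrink; lesions small relative to scanner resolution read out
  artificially low SUV. An on-treatment uptake decline that is stronger in
  responders can therefore be pure physics. The adjustment is empirical:
  regress pretreatment log SUVmax on a 5-knot restricted cubic spline of
  lesion volume (oblate spheroid from two orthogonal CT diameters,
  `V = (π/6)·L²·S`; volume at PET time linearly interpolated between CTs),
  then re-express every observation as
  `log SUV − Ê(V) + Ê(5 cm³)` — the uptake the lesion would show at a
  reference volume on the flat part of the curve. Because the spline is
  estimated, its coefficient covariance is propagated into all downstream
  treatment-effect intervals (delta method).

* **Small-sample survival.** Baseline uptake (patient geometric mean over
  nonirradiated lesions) is related to PFS/OS by Kaplan–Meier/log-rank on a
  predefined median split, and continuously per population SD via Cox
  regression with Firth's penalization `ℓ*(β) = ℓ(β) + ½·log I(β)`, which
  stays finite under monotone likelihood and de-biases small samples.

* **Does the tracer see T cells?** Autoradiographs of biopsied tissue are
  registered to CD8 IHC sections via landmark-estimated affine transforms;
  local agreement is measured in overlapping tiles (≥25 % tumor-ROI overlap)
  as Kendall's τ_b between percent CD8⁺ pixels and decay-corrected,
  background-subtracted tracer intensity.

Real trial data of this kind are access-restricted, so the package ships a
calibrated generator (`cd8pet.synthetic`) producing cohorts, serum PK decay
curves and slide pairs with known ground truth, which the test suite uses for
oracle checks and parameter-recovery experiments.

## Worked example

```python
import numpy as np
from cd8pet import GeneratorParams, generate_cohort, summarize_uptake
from cd8pet.volume import (add_volume_columns, add_pet_volumes,
                           fit_volume_uptake_spline, adjust_uptake)
from cd8pet.mixedmodel import (LmmSpec, fit_lmm, compute_icc,
                               treatment_change_model)

cohort = generate_cohort(GeneratorParams(seed=1))
baseline = cohort.lesions.query("timepoint == 0 and ~irradiated")
summ = summarize_uptake(baseline["suv_max"])
print(f"geometric mean SUVmax {summ.geometric_mean:.2f} "
      f"(GCV {summ.gcv:.2f}, n={summ.n})")

baseline = baseline.assign(_y=np.log(baseline["suv_max"]))
fit = fit_lmm(baseline, LmmSpec(response="_y", fixed="1", random="patient"))
print(f"ICC {compute_icc(fit):.2f}")

tbl = add_pet_volumes(add_volume_columns(cohort.lesions))
pre = tbl.query("timepoint == 0 and ~irradiated")
spline = fit_volume_uptake_spline(pre["volume_cm3"], pre["suv_max"],
                                  pre["patient_id"])
tbl["suv_max_adjusted"] = adjust_uptake(tbl["suv_max"].to_numpy(),
                                        tbl["volume_at_pet_cm3"].to_numpy(),
                                        spline)
raw = treatment_change_model(tbl)
adj = treatment_change_model(tbl, adjusted=True, spline=spline)
print(f"uptake change {raw.percent_per_week:+.1f} %/week raw, "
      f"{adj.percent_per_week:+.1f} %/week volume-adjusted")
```

prints

```
geometric mean SUVmax 5.08 (GCV 0.69, n=239)
ICC 0.47
uptake change -6.3 %/week raw, -5.7 %/week volume-adjusted
```

i.e. this simulated cohort has a baseline geometric mean SUVmax of 5.08 with a
geometric coefficient of variation of 0.69; 47 % of the log-uptake variance
sits between patients; average uptake falls 6.3 % per treatment week before —
and 5.7 % after — removing the shrinkage-driven partial-volume artifact. (The
default generator assigns responders genuinely steeper declines, so a real
response-dependent effect remains after adjustment.)

The same pipeline is scriptable end to end:

```bash
cd8pet all --seed 1 --out run/          # simulate → quant → adjust → model →
                                        # survival → coreg, with manifests
```

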