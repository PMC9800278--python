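"""Typed CSV/image I/O with schema-versioned headers and run manifests."""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

log = logging.getLogger("cd8pet")

SCHEMA_VERSION = "1"

LESION_COLUMNS = {
    "patient_id": str, "lesion_id": str, "organ_site": str, "irradiated": bool,
    "timepoint": float, "suv_max": float, "suv_mean": float,
    "diam_long_cm": float, "diam_short_cm": float, "ct_date_offset_days": float,
}
OPTIONAL_LESION_COLUMNS = {
    "bor": str, "true_log_suv": float, "true_volume_cm3": float,
    "volume_cm3": float, "volume_at_pet_cm3": float, "suv_max_adjusted": float,
}


def write_table(df: pd.DataFrame, path) -> None:
    """CSV with a `# schema_version` comment header (readable with comment='#')."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# schema_version={SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_lesion_table(path, strict: bool = False) -> pd.DataFrame:
    """Read and validate a lesion x scan table.

    Mandatory columns are type-checked; rows violating the value constraints
    (nonpositive SUV, suv_mean > suv_max, short > long diameter, duplicate
    lesion-to-patient mapping) are rejected with a logged line number, or
    raise when ``strict``.
    """
    df = read_table(path)
    missing = set(LESION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"lesion table lacks mandatory columns: {sorted(missing)}")
    for col, typ in LESION_COLUMNS.items():
        if typ is float:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                line = int(df.index[bad][0]) + 3  # header comment + column row
                raise ValueError(f"non-numeric value in column {col!r} at line {line}")
            df[col] = coerced
    ok = (
        (df["suv_max"] > 0)
        & (df["suv_mean"] > 0)
        & (df["suv_max"] >= df["suv_mean"] - 1e-12)
        & (df["diam_short_cm"] >= 0)
        & (df["diam_long_cm"] >= df["diam_short_cm"])
        & df["timepoint"].notna()
    )
    if (~ok).any():
        lines = (df.index[~ok] + 3).tolist()
        msg = f"rejected {int((~ok).sum())} invalid lesion rows (lines {lines[:5]}...)"
        if strict:
            raise ValueError(msg)
        log.warning(msg)
        df = df[ok].reset_index(drop=True)
    per_lesion = df.groupby("lesion_id")["patient_id"].nunique()
    if (per_lesion > 1).any():
        raise ValueError("a lesion_id maps to more than one patient_id")
    return df


def write_cohort(dataset, out_dir) -> dict:
    """Write lesions/patients/pk CSVs plus the ground-truth JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(dataset.lesions, out / "lesions.csv")
    write_table(dataset.patients, out / "patients.csv")
    write_table(dataset.pk, out / "pk.csv")
    (out / "ground_truth.json").write_text(
        json.dumps(dataset.ground_truth, indent=2, sort_keys=True, default=float))
    return {name: str(out / name) for name in
            ("lesions.csv", "patients.csv", "pk.csv", "ground_truth.json")}


def write_slide_pair(pair, out_dir, slide_id: str) -> dict:
    """ARG as 16-bit TIFF (with a stored scale factor), masks/IHC as 8-bit PNG."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arg = np.asarray(pair.arg_image, dtype=float)
    scale = float(arg.max()) if arg.max() > 0 else 1.0
    arg16 = np.round(arg / scale * 65535).astype(np.uint16)
    tifffile.imwrite(out / f"{slide_id}_arg.tif", arg16)
    for name, img in (("ihc", pair.ihc_positivity), ("roi", pair.roi_mask),
                      ("background", pair.background_mask)):
        Image.fromarray((np.asarray(img, bool) * 255).astype(np.uint8)).save(
            out / f"{slide_id}_{name}.png")
    write_table(pair.landmarks, out / f"{slide_id}_landmarks.csv")
    meta = {"slide_id": slide_id, "scan_delay_h": pair.scan_delay_h,
            "arg_scale": scale}
    if pair.true_affine is not None:
        meta["true_affine_params"] = pair.true_affine.params.tolist()
    (out / f"{slide_id}_meta.json").write_text(json.dumps(meta, indent=2))
    return meta


def read_slide_pair(in_dir, slide_id: str):
    """Load a slide pair written by :func:`write_slide_pair`."""
    from .coreg import AffineTransform
    from .synthetic import SlidePair

    p = Path(in_dir)
    meta = json.loads((p / f"{slide_id}_meta.json").read_text())
    arg16 = tifffile.imread(p / f"{slide_id}_arg.tif").astype(float)
    arg = arg16 / 65535.0 * meta["arg_scale"]
    imgs = {}
    for name in ("ihc", "roi", "background"):
        imgs[name] = np.asarray(Image.open(p / f"{slide_id}_{name}.png")) > 127
    lm = read_table(p / f"{slide_id}_landmarks.csv")
    affine = None
    if "true_affine_params" in meta:
        q = np.asarray(meta["true_affine_params"])
        affine = AffineTransform(q[:4].reshape(2, 2), q[4:])
    return SlidePair(ihc_positivity=imgs["ihc"], arg_image=arg,
                     roi_mask=imgs["roi"], background_mask=imgs["background"],
                     landmarks=lm, scan_delay_h=meta["scan_delay_h"],
                     true_affine=affine)


def landmarks_to_rc(landmarks: pd.DataFrame):
    """Landmark CSV columns (x, y) to (row, col) point arrays (IHC, ARG)."""
    dst = landmarks[["y_ihc", "x_ihc"]].to_numpy(dtype=float)
    src = landmarks[["y_arg", "x_arg"]].to_numpy(dtype=float)
    return dst, src


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(out_dir, stage: str, seed: int, params: dict, outputs) -> Path:
    """Stage manifest: inputs, parameters, seed and output checksums."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "seed": seed,
        "schema_version": SCHEMA_VERSION,
        "parameters": params,
        "outputs": {str(Path(f).name): file_checksum(f) for f in outputs},
    }
    path = out / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=float))
    return path
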