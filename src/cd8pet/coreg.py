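"""Autoradiography-to-IHC registration and tile-based spatial correlation.

A phosphor-plate autoradiograph (ARG) of a tissue block records where the
radiolabeled CD8 tracer sits; the CD8 immunohistochemistry (IHC) section of
the same block records where CD8+ T cells actually are. The two images live in
different pixel grids, so the ARG is pulled into the IHC frame through an
affine transform estimated from manually selected control points. Local
agreement is then quantified in overlapping square tiles: per tile, the
percentage of IHC-positive pixels versus the decay-corrected,
background-subtracted mean ARG intensity, correlated by Kendall's tau-b.

Conventions: pixel coordinates are 0-based (row, col) with the origin at the
top-left; tiles are half-open [row0, row0+size) x [col0, col0+size).
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .petquant import ZR89_HALF_LIFE_H, decay_correct

__all__ = [
    "AffineTransform",
    "Tile",
    "TileMeasurement",
    "SlideSummary",
    "estimate_affine",
    "warp_image",
    "compute_tiles",
    "measure_tiles",
    "kendall_tau",
    "correlate_slides",
    "DEFAULT_TILE_SIZES",
    "MIN_ROI_OVERLAP",
    "MIN_TILES_WITHIN",
]

DEFAULT_TILE_SIZES = (100, 400, 1000, 2000, 4000, 8000)
MIN_ROI_OVERLAP = 0.25  # tiles need >= 25% overlap with the tumor ROI
MIN_TILES_WITHIN = 6  # within-slide correlations need >= 6 tiles


@dataclass(frozen=True)
class AffineTransform:
    """Maps destination (IHC-frame) (row, col) to source (ARG-frame) (row, col).

    ``src = matrix @ dst + offset``; the pull direction matches resampling.
    """

    matrix: np.ndarray  # (2, 2)
    offset: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float))
        object.__setattr__(self, "offset", np.asarray(self.offset, dtype=float))
        if self.matrix.shape != (2, 2) or self.offset.shape != (2,):
            raise ValueError("matrix must be 2x2 and offset length 2")
        if abs(np.linalg.det(self.matrix)) <= 1e-12:
            raise ValueError("affine linear part is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(2), np.zeros(2))

    @property
    def params(self) -> np.ndarray:
        """The 6 parameters as a flat array (row-major matrix, then offset)."""
        return np.concatenate([self.matrix.ravel(), self.offset])

    def apply(self, points_rc: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_rc, dtype=float))
        return pts @ self.matrix.T + self.offset

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.offset)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self after other: (self o other)(x) = self(other(x))."""
        return AffineTransform(self.matrix @ other.matrix,
                               self.matrix @ other.offset + self.offset)


@dataclass(frozen=True)
class Tile:
    row0: int
    col0: int
    size_px: int
    roi_overlap_fraction: float


@dataclass(frozen=True)
class TileMeasurement:
    tile: Tile
    ihc_pct_positive: float  # 0..100
    arg_intensity: float  # decay-corrected, background-subtracted (may be < 0)


@dataclass
class SlideSummary:
    slide_id: str
    global_ihc_pct: float
    global_arg_intensity: float
    tile_tables: dict = field(default_factory=dict)  # size -> DataFrame
    within_slide_tau: dict = field(default_factory=dict)  # size -> (tau, p)


def estimate_affine(landmarks_dst_rc, landmarks_src_rc):
    """Least-squares affine from >= 3 control-point pairs.

    ``landmarks_dst_rc`` are IHC-frame (row, col) points, ``landmarks_src_rc``
    the corresponding ARG-frame points. Returns ``(transform, rmse)`` where
    rmse is the residual of the mapped landmarks in source pixels.
    """
    dst = np.atleast_2d(np.asarray(landmarks_dst_rc, dtype=float))
    src = np.atleast_2d(np.asarray(landmarks_src_rc, dtype=float))
    if dst.shape != src.shape or dst.shape[1] != 2:
        raise ValueError("landmark arrays must both be (n, 2)")
    n = dst.shape[0]
    if n < 3:
        raise ValueError("need >= 3 landmark pairs")
    centered = dst - dst.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
        raise ValueError("landmarks are collinear; affine is not identifiable")
    A = np.column_stack([dst, np.ones(n)])  # (n, 3)
    sol, _, _, _ = np.linalg.lstsq(A, src, rcond=None)  # (3, 2)
    matrix = sol[:2].T
    offset = sol[2]
    tfm = AffineTransform(matrix, offset)
    resid = tfm.apply(dst) - src
    rmse = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return tfm, rmse


def warp_image(src_image: np.ndarray, transform: AffineTransform,
               out_shape: tuple, interpolation: str = "bilinear"):
    """Pull-resample a source image into the destination frame.

    Each output pixel (row, col) reads the source at ``transform(row, col)``.
    Out-of-bounds samples are invalid: returns ``(warped, valid_mask)`` with
    invalid pixels set to NaN (float output). Bilinear for intensities,
    nearest for masks.
    """
    order = {"nearest": 0, "bilinear": 1}.get(interpolation)
    if order is None:
        raise ValueError("interpolation must be 'nearest' or 'bilinear'")
    src = np.asarray(src_image, dtype=float)
    warped = ndimage.affine_transform(
        src, transform.matrix, offset=transform.offset, output_shape=out_shape,
        order=order, mode="constant", cval=np.nan)
    valid = np.isfinite(warped)
    return warped, valid


def compute_tiles(roi_mask: np.ndarray, tile_size_px: int,
                  stride_px: int | None = None,
                  min_overlap: float = MIN_ROI_OVERLAP) -> list:
    """Regular overlapping tile grid, filtered by ROI overlap.

    Default stride is half the tile size (50% overlap). A tile is kept when
    the ROI covers at least ``min_overlap`` of its area; the grid only
    contains tiles fully inside the image bounds.
    """
    roi = np.asarray(roi_mask).astype(bool)
    H, W = roi.shape
    size = int(tile_size_px)
    if size <= 0 or size > H or size > W:
        return []
    stride = int(stride_px) if stride_px is not None else max(size // 2, 1)
    if stride <= 0:
        raise ValueError("stride must be positive")
    # summed-area table for O(1) overlap queries
    integ = np.zeros((H + 1, W + 1), dtype=np.int64)
    integ[1:, 1:] = np.cumsum(np.cumsum(roi, axis=0), axis=1)
    area = size * size
    tiles = []
    for r0 in range(0, H - size + 1, stride):
        for c0 in range(0, W - size + 1, stride):
            inside = int(integ[r0 + size, c0 + size] - integ[r0, c0 + size]
                         - integ[r0 + size, c0] + integ[r0, c0])
            frac = inside / area
            if frac >= min_overlap:
                tiles.append(Tile(r0, c0, size, frac))
    return tiles


def measure_tiles(ihc_positivity: np.ndarray, arg_aligned: np.ndarray,
                  tiles: list, background_mask: np.ndarray | None = None,
                  scan_delay_h: float = 0.0,
                  half_life_h: float = ZR89_HALF_LIFE_H) -> list:
    """Per-tile IHC percent positivity and ARG intensity.

    ``arg_aligned`` is the ARG already in the IHC frame (NaN where invalid).
    ihc_pct = 100 * positive / valid pixels in the tile; arg = decay-corrected
    mean over valid pixels minus the decay-corrected slide background (mean ARG
    over ``background_mask``). Background subtraction may yield negative
    intensities, which are kept — clamping would bias rank correlations. Tiles
    with no valid pixel are dropped.
    """
    ihc = np.asarray(ihc_positivity).astype(bool)
    arg = np.asarray(arg_aligned, dtype=float)
    if ihc.shape != arg.shape:
        raise ValueError("IHC and ARG images must be co-registered (same shape)")
    if background_mask is not None:
        bg_px = arg[np.asarray(background_mask).astype(bool)]
        bg_px = bg_px[np.isfinite(bg_px)]
        background = float(np.mean(bg_px)) if bg_px.size else 0.0
    else:
        background = 0.0
    bg_corrected = decay_correct(background, scan_delay_h, half_life_h)
    out = []
    for t in tiles:
        sl = (slice(t.row0, t.row0 + t.size_px), slice(t.col0, t.col0 + t.size_px))
        arg_t = arg[sl]
        valid = np.isfinite(arg_t)
        n_valid = int(valid.sum())
        if n_valid == 0:
            continue  # dropped: warped ARG does not cover this tile
        mean_arg = float(arg_t[valid].mean())
        pct = 100.0 * float(ihc[sl][valid].sum()) / n_valid
        intensity = decay_correct(mean_arg, scan_delay_h, half_life_h) - bg_corrected
        out.append(TileMeasurement(t, pct, float(intensity)))
    return out


def _tau_exact_p(x: np.ndarray, y: np.ndarray, tau_obs: float) -> float:
    """Two-sided p by full permutation enumeration of tau-b (n <= 8)."""
    n = len(x)
    taus = []
    ys = np.asarray(y)
    for perm in itertools.permutations(range(n)):
        t = stats.kendalltau(x, ys[list(perm)]).statistic
        taus.append(t)
    taus = np.asarray(taus)
    return float(np.mean(np.abs(taus) >= abs(tau_obs) - 1e-12))


def kendall_tau(x, y, exact_max_n: int = 8):
    """Kendall's tau-b with tie correction; returns (tau_b, p).

    Two-sided p value by exact permutation enumeration for n <= 8 and the
    normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if x.size < 2:
        raise ValueError("need >= 2 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: correlation undefined")
    res = stats.kendalltau(x, y, method="asymptotic")
    tau = float(res.statistic)
    if x.size <= exact_max_n:
        p = _tau_exact_p(x, y, tau)
    else:
        p = float(res.pvalue)
    return tau, p


def summarize_slide(slide_id: str, ihc_positivity, arg_aligned, roi_mask,
                    background_mask=None, scan_delay_h: float = 0.0,
                    tile_sizes=DEFAULT_TILE_SIZES, stride_frac: float = 0.5,
                    half_life_h: float = ZR89_HALF_LIFE_H) -> SlideSummary:
    """Global and per-tile-size measurements for one registered slide pair.

    Global values use all ROI pixels (not only kept tiles). Within-slide tau
    is reported per tile size only when >= 6 tiles survive the overlap filter,
    since rank correlations on fewer tiles are too unstable to interpret.
    """
    ihc = np.asarray(ihc_positivity).astype(bool)
    arg = np.asarray(arg_aligned, dtype=float)
    roi = np.asarray(roi_mask).astype(bool)
    valid_roi = roi & np.isfinite(arg)
    if not valid_roi.any():
        raise ValueError("ROI has no valid registered ARG pixels")
    if background_mask is not None:
        bg_px = arg[np.asarray(background_mask).astype(bool)]
        bg_px = bg_px[np.isfinite(bg_px)]
        bg = float(bg_px.mean()) if bg_px.size else 0.0
    else:
        bg = 0.0
    global_ihc = 100.0 * float(ihc[valid_roi].sum()) / int(valid_roi.sum())
    global_arg = (decay_correct(float(arg[valid_roi].mean()), scan_delay_h, half_life_h)
                  - decay_correct(bg, scan_delay_h, half_life_h))
    summary = SlideSummary(slide_id, global_ihc, global_arg)
    for size in tile_sizes:
        tiles = compute_tiles(roi, size, stride_px=max(int(size * stride_frac), 1))
        meas = measure_tiles(ihc, arg, tiles, background_mask, scan_delay_h,
                             half_life_h)
        if not meas:
            continue
        tbl = pd.DataFrame({
            "row0": [m.tile.row0 for m in meas],
            "col0": [m.tile.col0 for m in meas],
            "size_px": size,
            "roi_overlap": [m.tile.roi_overlap_fraction for m in meas],
            "ihc_pct_positive": [m.ihc_pct_positive for m in meas],
            "arg_intensity": [m.arg_intensity for m in meas],
        })
        summary.tile_tables[size] = tbl
        if len(tbl) >= MIN_TILES_WITHIN:
            try:
                summary.within_slide_tau[size] = kendall_tau(
                    tbl["ihc_pct_positive"], tbl["arg_intensity"])
            except ValueError:
                pass  # constant tile values: undefined, omitted
    return summary


def correlate_slides(summaries: list, mode: str = "slide-level",
                     tile_size: int | None = None):
    """Kendall correlation report across slides.

    Modes: ``slide-level`` correlates the global per-slide values (needs >= 3
    slides); ``tile-within`` reports each slide's within-slide tau at a tile
    size (slides with < 6 tiles excluded); ``tile-pooled`` pools tiles across
    all slides, including those with < 6 tiles, then correlates once.
    """
    if mode == "slide-level":
        if len(summaries) < 3:
            raise ValueError("slide-level correlation needs >= 3 slides")
        tau, p = kendall_tau([s.global_ihc_pct for s in summaries],
                             [s.global_arg_intensity for s in summaries])
        return {"mode": mode, "n_slides": len(summaries), "tau": tau, "p": p}
    if tile_size is None:
        raise ValueError("tile modes need a tile_size")
    if mode == "tile-within":
        rows = []
        for s in summaries:
            if tile_size in s.within_slide_tau:
                tau, p = s.within_slide_tau[tile_size]
                rows.append({"slide_id": s.slide_id, "tau": tau, "p": p,
                             "n_tiles": len(s.tile_tables[tile_size])})
        if not rows:
            raise ValueError("no slide has >= 6 tiles at this size")
        return {"mode": mode, "tile_size": tile_size,
                "per_slide": pd.DataFrame(rows),
                "median_tau": float(pd.DataFrame(rows)["tau"].median())}
    if mode == "tile-pooled":
        tables = [s.tile_tables[tile_size] for s in summaries
                  if tile_size in s.tile_tables]
        if not tables:
            raise ValueError("no tiles at this size in any slide")
        pooled = pd.concat(tables, ignore_index=True)
        tau, p = kendall_tau(pooled["ihc_pct_positive"], pooled["arg_intensity"])
        return {"mode": mode, "tile_size": tile_size, "n_tiles": len(pooled),
                "tau": tau, "p": p}
    raise ValueError("mode must be slide-level, tile-within or tile-pooled")
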