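"""Pre-processing: intensity normalisation, contrast enhancement, body
masking and centre-of-mass / ICP spatial initialisation.

Intensity statistics are always computed inside the body mask (when one is
supplied) so background noise cannot shift the scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_multiotsu, threshold_otsu

from .containers import AffineTransform, Volume

logger = logging.getLogger(__name__)


@dataclass
class BodyMask:
    """Binary body-support mask with its provenance."""

    volume: Volume
    threshold: float
    n_components_found: int

    @property
    def data(self) -> np.ndarray:
        return self.volume.data > 0.5

    def centroid_mm(self) -> np.ndarray:
        idx = np.argwhere(self.data)
        if idx.size == 0:
            raise ValueError("empty body mask")
        return idx.mean(axis=0) * self.volume.grid.spacing_arr + self.volume.grid.origin_arr


def minmax_normalize(v: Volume, mask: np.ndarray | None = None) -> Volume:
    """Map [min, max] linearly to [0, 1]; statistics restricted to ``mask``."""
    data = np.asarray(v.data, dtype=float)
    sel = data[mask] if mask is not None else data
    lo, hi = float(sel.min()), float(sel.max())
    if hi <= lo:
        raise ValueError("min-max normalisation undefined for a constant volume")
    return v.with_data(np.clip((data - lo) / (hi - lo), 0.0, 1.0))


def enhance_contrast(
    v: Volume, lower_pct: float = 1.0, upper_pct: float = 99.0, mask: np.ndarray | None = None
) -> Volume:
    """Clip intensities at histogram percentiles, then min-max rescale.

    Saturates outliers and expands the bulk dynamic range, accentuating
    tissue boundaries.
    """
    if not (0 <= lower_pct < upper_pct <= 100):
        raise ValueError("require 0 <= lower_pct < upper_pct <= 100")
    data = np.asarray(v.data, dtype=float)
    sel = data[mask] if mask is not None else data
    # discrete percentile methods pick actual sample values, so at least the
    # nominal tail mass saturates and a second application is the identity
    lo = float(np.percentile(sel, lower_pct, method="higher"))
    hi = float(np.percentile(sel, upper_pct, method="lower"))
    if hi <= lo:
        raise ValueError("degenerate percentile window (constant clip range)")
    return v.with_data((np.clip(data, lo, hi) - lo) / (hi - lo))


def body_mask(v: Volume) -> BodyMask:
    """Histogram threshold -> largest connected component -> closing -> hole fill.

    Multi-class Otsu with the lowest threshold separating background; plain
    Otsu's single split can land on the fat-lean boundary and cut away the
    subcutaneous fat shell.
    """
    data = np.asarray(v.data, dtype=float)
    if data.max() <= data.min():
        raise ValueError("empty foreground: volume is constant")
    if (data == 0).mean() > 0.2:
        # an exactly-zero background (already-masked image, or noise confined
        # to the body): the support is the mask; re-masking is then stable
        thr = 0.0
    else:
        thr = None
        for classes in (4, 3):  # background / fat / lean / bright organs
            try:
                thr = float(threshold_multiotsu(data, classes=classes)[0])
                break
            except ValueError:  # fewer distinct modes than classes
                continue
        if thr is None:
            thr = float(threshold_otsu(data))
    fg = data > thr
    if not fg.any():
        raise ValueError("empty foreground after Otsu threshold")
    lab, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        fg = lab == (1 + int(np.argmax(sizes)))
    struct = ndimage.generate_binary_structure(3, 1)
    fg = ndimage.binary_closing(fg, structure=struct, iterations=2)
    fg = ndimage.binary_fill_holes(fg)
    return BodyMask(v.with_data(fg.astype(float)), thr, n)


def apply_mask(v: Volume, mask: BodyMask) -> Volume:
    """Zero out background voxels."""
    return v.with_data(np.where(mask.data, v.data, 0.0))


TISSUE_FLOOR = 0.02
STATS_EROSION = 2


def preprocess_volume(
    v: Volume, lower_pct: float = 1.0, upper_pct: float = 99.0
) -> tuple[Volume, BodyMask]:
    """Full intensity pipeline: mask, then masked min-max + contrast window.

    Intensity statistics are computed on the body mask eroded by
    ``STATS_EROSION`` voxels: partial-volume voxels at the body boundary span
    the whole background-to-tissue range and would otherwise drag the scale
    of resampled images far from that of crisp ones.  In-mask intensities are
    mapped to ``[TISSUE_FLOOR, 1]`` while background stays exactly 0, keeping
    body voxels strictly separated from background.  The combination makes
    the pipeline idempotent (to 1e-6): re-running it reproduces the same mask
    and the percentile window maps the floored range onto itself.
    """
    mask = body_mask(v)
    struct = ndimage.generate_binary_structure(3, 1)
    stats = ndimage.binary_erosion(mask.data, structure=struct, iterations=STATS_EROSION)
    if not stats.any():
        stats = mask.data
    out = minmax_normalize(v, stats)
    out = enhance_contrast(out, lower_pct, upper_pct, stats)
    out = out.with_data(TISSUE_FLOOR + (1.0 - TISSUE_FLOOR) * out.data)
    return apply_mask(out, mask), mask


def _surface_points(mask: BodyMask) -> np.ndarray:
    """Physical coordinates of 6-neighbour surface voxels of the mask."""
    m = mask.data
    struct = ndimage.generate_binary_structure(3, 1)
    surf = m & ~ndimage.binary_erosion(m, structure=struct, border_value=0)
    idx = np.argwhere(surf)
    return idx * mask.volume.grid.spacing_arr + mask.volume.grid.origin_arr


def _procrustes_rigid(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid fit R, t minimising ||R src + t - dst||^2 (Kabsch)."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, cd - R @ cs


def com_align(
    moving_mask: BodyMask,
    fixed_mask: BodyMask,
    mode: str = "com",
    max_iter: int = 100,
    tol: float = 1e-4,
) -> AffineTransform:
    """Spatial initialisation aligning body masks.

    ``com``: translation matching mask centroids.  ``icp``: rigid refinement
    on mask surface points (nearest-neighbour correspondences), started from
    the centroid translation.  The returned transform maps fixed-space points
    into moving space (pull-back convention).  On ICP non-convergence the
    centroid translation is returned with a warning.
    """
    t0 = moving_mask.centroid_mm() - fixed_mask.centroid_mm()
    com = AffineTransform.translation_only(t0)
    if mode == "com":
        return com
    if mode != "icp":
        raise ValueError(f"unknown alignment mode {mode!r}")

    fixed_pts = _surface_points(fixed_mask)
    moving_pts = _surface_points(moving_mask)
    tree_m = cKDTree(moving_pts)
    tree_f = cKDTree(fixed_pts)
    R, t = np.eye(3), t0.copy()
    for it in range(max_iter):
        # symmetric nearest-neighbour correspondences reduce the tangential
        # sliding bias of one-directional matching on voxelised surfaces
        _, nn1 = tree_m.query(fixed_pts @ R.T + t)
        _, nn2 = tree_f.query((moving_pts - t) @ R)
        src = np.vstack([fixed_pts, fixed_pts[nn2]])
        dst = np.vstack([moving_pts[nn1], moving_pts])
        R_new, t_new = _procrustes_rigid(src, dst)
        converged = np.abs(R_new - R).max() < 1e-9 and np.abs(t_new - t).max() < tol
        R, t = R_new, t_new
        if converged:
            return AffineTransform(R, t)
    logger.warning("ICP did not converge in %d iterations; falling back to COM", max_iter)
    return com
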