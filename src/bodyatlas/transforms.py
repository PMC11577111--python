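"""Transform algebra: warping, composition, inversion, velocity integration,
Jacobians and resolution pyramids.

Every operation obeys the global pull-back convention: a displacement field
``u`` on a fixed grid defines ``phi(x) = x + u(x)`` mapping fixed-space points
into moving space, and :func:`warp_volume` produces an image on the fixed grid
by sampling the moving image at ``phi(x)``.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .containers import AffineTransform, DisplacementField, Grid, LabelVolume, Volume


class NonConvergenceError(RuntimeError):
    """Raised when fixed-point field inversion fails to reach tolerance."""


def _sample(data: np.ndarray, index_pts: np.ndarray, order: int, fill: float) -> np.ndarray:
    """Sample ``data`` at fractional index points of shape (..., 3)."""
    coords = np.moveaxis(index_pts, -1, 0)
    return ndimage.map_coordinates(
        np.asarray(data, dtype=float), coords, order=order, mode="constant", cval=fill
    )


def warp_volume(
    moving: Volume,
    fieldv: DisplacementField,
    interpolation: str = "linear",
    fill: float = 0.0,
) -> Volume:
    """Resample ``moving`` through ``phi = id + u`` onto the field's (fixed) grid.

    Out-of-domain samples take ``fill`` (default 0, background).
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    order = 1 if interpolation == "linear" else 0
    pts = fieldv.grid.coordinates() + fieldv.data
    out = _sample(moving.data, moving.grid.to_index(pts), order, fill)
    return Volume(out, fieldv.grid)


def warp_labels(moving: LabelVolume, fieldv: DisplacementField) -> LabelVolume:
    """Warp an integer label map with nearest-neighbour interpolation."""
    pts = fieldv.grid.coordinates() + fieldv.data
    out = _sample(moving.data, moving.grid.to_index(pts), 0, 0.0)
    return LabelVolume(np.rint(out).astype(moving.data.dtype), fieldv.grid, moving.labels)


def sample_field(fieldv: DisplacementField, points: np.ndarray) -> np.ndarray:
    """Linearly interpolate the field's vectors at physical points (..., 3).

    Outside the field domain the displacement extends with its edge values
    (zero-extension would create spurious boundary compression — and hence
    folding — when composing fields whose support reaches the domain edge).
    """
    idx = fieldv.grid.to_index(points)
    coords = np.moveaxis(idx, -1, 0)
    out = np.empty(points.shape, dtype=float)
    for d in range(3):
        out[..., d] = ndimage.map_coordinates(
            fieldv.data[..., d], coords, order=1, mode="nearest"
        )
    return out


def compose_affine_field(
    affine: AffineTransform, inner: DisplacementField
) -> DisplacementField:
    """Exact displacement of ``affine ∘ phi_inner`` (no outer-field sampling)."""
    pts = inner.grid.coordinates() + inner.data
    return DisplacementField(affine.apply(pts) - inner.grid.coordinates(), inner.grid)


def compose(outer: DisplacementField, inner: DisplacementField) -> DisplacementField:
    """Displacement of ``phi_outer ∘ phi_inner`` on the inner field's grid.

    Under the pull-back convention this satisfies
    ``warp(warp(m, outer), inner) == warp(m, compose(outer, inner))``
    up to interpolation error, and ``(outer∘inner)(x) = outer(inner(x))``.
    """
    if not inner.grid.compatible(outer.grid):
        raise ValueError("compose requires fields on compatible grids")
    pts = inner.grid.coordinates() + inner.data
    u = inner.data + sample_field(outer, pts)
    return DisplacementField(u, inner.grid)


def invert(
    fieldv: DisplacementField,
    tol: float = 0.01,
    max_iter: int = 50,
    raise_on_failure: bool = True,
) -> DisplacementField:
    """Invert a (near-)diffeomorphic field by fixed-point iteration.

    Iterates ``u_inv <- -u(x + u_inv(x))`` until the max update falls below
    ``tol`` (mm).  The achieved residual is stored in ``result.meta``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    coords = fieldv.grid.coordinates()
    uinv = np.zeros_like(fieldv.data)
    residual = np.inf
    for _ in range(max_iter):
        new = -sample_field(fieldv, coords + uinv)
        residual = float(np.sqrt(((new - uinv) ** 2).sum(axis=-1)).max())
        uinv = new
        if residual < tol:
            break
    else:
        if raise_on_failure and residual >= tol:
            raise NonConvergenceError(
                f"field inversion residual {residual:.4g} mm after {max_iter} iterations"
            )
    out = DisplacementField(uinv, fieldv.grid)
    out.meta["inversion_residual_mm"] = residual
    return out


def integrate_velocity(velocity: DisplacementField, squaring_steps: int = 6) -> DisplacementField:
    """Unit-time flow of a stationary velocity field via scaling and squaring.

    The velocity is scaled by ``2**-squaring_steps`` and the resulting small
    displacement is self-composed ``squaring_steps`` times.  For velocities
    whose scaled step is well below a voxel the result is diffeomorphic
    (positive Jacobian everywhere).
    """
    if squaring_steps < 0:
        raise ValueError("squaring_steps must be >= 0")
    u = DisplacementField(velocity.data / float(2**squaring_steps), velocity.grid)
    for _ in range(squaring_steps):
        u = compose(u, u)
    return u


def jacobian_determinant(fieldv: DisplacementField) -> Volume:
    """Voxel-wise ``det(I + ∇u)`` via spacing-scaled central differences.

    One-sided differences are used at the boundary; folding statistics should
    exclude the boundary shell.
    """
    if min(fieldv.grid.shape) < 3:
        raise ValueError("jacobian requires at least 3 voxels per axis")
    sp = fieldv.grid.spacing
    J = np.empty(fieldv.grid.shape + (3, 3), dtype=float)
    for comp in range(3):
        grads = np.gradient(fieldv.data[..., comp], *sp)
        for ax in range(3):
            J[..., comp, ax] = grads[ax]
    J += np.eye(3)
    return Volume(np.linalg.det(J), fieldv.grid)


def downsample(volume: Volume, factor: int) -> Volume:
    """Anti-aliased (Gaussian-prefiltered) downsampling by an integer factor.

    Keeps every ``factor``-th voxel starting at the origin, so the origin is
    unchanged and spacing is multiplied by ``factor``.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return volume.copy()
    if any(s < factor for s in volume.grid.shape):
        raise ValueError("downsampling factor exceeds grid size")
    sigma = (factor - 1) / 2.0
    sm = ndimage.gaussian_filter(np.asarray(volume.data, dtype=float), sigma, mode="nearest")
    data = sm[::factor, ::factor, ::factor]
    grid = Grid(data.shape, tuple(volume.spacing * factor), tuple(volume.origin))
    return Volume(data, grid)


def downsample_field(fieldv: DisplacementField, factor: int) -> DisplacementField:
    """Component-wise anti-aliased downsampling of a field (mm preserved)."""
    comps = [downsample(Volume(fieldv.data[..., d], fieldv.grid), factor) for d in range(3)]
    return DisplacementField(np.stack([c.data for c in comps], axis=-1), comps[0].grid)


def upsample_field(fieldv: DisplacementField, target: Grid) -> DisplacementField:
    """Resample a field's vectors onto ``target`` (linear; mm units preserved)."""
    pts = target.coordinates()
    return DisplacementField(sample_field(fieldv, pts), target)


def apply_affine_as_field(affine: AffineTransform, grid: Grid) -> DisplacementField:
    """Densify an affine transform: ``u(x) = (L x + t) - x`` at voxel centres."""
    pts = grid.coordinates()
    return DisplacementField(affine.apply(pts) - pts, grid)
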