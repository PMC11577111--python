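"""Cubic B-spline velocity lattice: the parameters of the deformable
transform.

A stationary velocity field is represented by 3-vector coefficients on a
regular lattice of control points covering the fixed image domain with one
boundary ring.  Because the image grid is axis-aligned and uniformly spaced,
interpolation to the dense grid is a separable tensor product of three small
per-axis basis matrices; the exact adjoint of that linear map projects dense
gradients back onto the lattice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .containers import DisplacementField, Grid


def bspline3(t: np.ndarray) -> np.ndarray:
    """Cubic B-spline basis function (support |t| < 2, unit integral)."""
    t = np.abs(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    m1 = t < 1.0
    out[m1] = 2.0 / 3.0 - t[m1] ** 2 + 0.5 * t[m1] ** 3
    m2 = (t >= 1.0) & (t < 2.0)
    out[m2] = (2.0 - t[m2]) ** 3 / 6.0
    return out


@dataclass
class VelocityLattice:
    """B-spline control-point coefficients of a stationary velocity field."""

    coefficients: np.ndarray  # (nx, ny, nz, 3), mm
    spacing: np.ndarray  # control-point spacing, mm per axis
    origin: np.ndarray  # position of control point (0, 0, 0), mm
    grid: Grid  # the fixed image grid the lattice covers
    degree: int = 3

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.coefficients.ndim != 4 or self.coefficients.shape[-1] != 3:
            raise ValueError("coefficients must have shape (nx, ny, nz, 3)")

    @classmethod
    def for_grid(cls, grid: Grid, control_spacing_mm) -> "VelocityLattice":
        """Zero lattice covering ``grid`` with one boundary ring of controls."""
        delta = np.broadcast_to(np.asarray(control_spacing_mm, dtype=float), (3,)).copy()
        extent = grid.extent
        n = (np.floor(extent / delta + 1e-9) + 4).astype(int)
        origin = grid.origin_arr - delta
        return cls(np.zeros(tuple(n) + (3,)), delta, origin, grid)

    def basis_matrices(self, grid: Grid | None = None) -> list[np.ndarray]:
        """Per-axis dense basis matrices A_d of shape (n_vox_d, n_ctrl_d)."""
        grid = grid or self.grid
        mats = []
        for d in range(3):
            pos = grid.origin[d] + grid.spacing[d] * np.arange(grid.shape[d])
            s = (pos - self.origin[d]) / self.spacing[d]
            idx = np.arange(self.coefficients.shape[d])
            mats.append(bspline3(s[:, None] - idx[None, :]))
        return mats

    def dense_velocity(self, grid: Grid | None = None) -> DisplacementField:
        """Interpolate coefficients to a dense velocity field on ``grid``."""
        grid = grid or self.grid
        Ax, Ay, Az = self.basis_matrices(grid)
        v = np.einsum("ai,bj,ck,ijkd->abcd", Ax, Ay, Az, self.coefficients, optimize=True)
        return DisplacementField(v, grid)

    def project_dense_gradient(self, dense: np.ndarray, grid: Grid | None = None) -> np.ndarray:
        """Exact adjoint of :meth:`dense_velocity`: scatter a dense gradient
        image (shape + (3,)) back to coefficient space."""
        grid = grid or self.grid
        Ax, Ay, Az = self.basis_matrices(grid)
        return np.einsum("ai,bj,ck,abcd->ijkd", Ax, Ay, Az, np.asarray(dense), optimize=True)

    def with_coefficients(self, coef: np.ndarray) -> "VelocityLattice":
        return VelocityLattice(coef, self.spacing.copy(), self.origin.copy(), self.grid, self.degree)

    @classmethod
    def from_dense_samples(
        cls, field: DisplacementField, control_spacing_mm, grid: Grid
    ) -> "VelocityLattice":
        """Fit a lattice whose spline interpolates a smooth field at the
        control points (used to carry a coarse level's velocity to a finer
        lattice)."""
        from .transforms import sample_field

        lat = cls.for_grid(grid, control_spacing_mm)
        n = lat.coefficients.shape[:3]
        axes = [lat.origin[d] + lat.spacing[d] * np.arange(n[d]) for d in range(3)]
        ii, jj, kk = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([ii, jj, kk], axis=-1)
        vals = sample_field(field, pts)
        coef = np.empty_like(vals)
        for d in range(3):
            coef[..., d] = ndimage.spline_filter(vals[..., d], order=3, mode="mirror")
        return lat.with_coefficients(coef)


# ---------------------------------------------------------------------------
# bending energy

_D2 = np.array([1.0, -2.0, 1.0])
_D1 = np.array([-0.5, 0.0, 0.5])


def _second_derivatives(v: np.ndarray, spacing: np.ndarray) -> list[tuple[float, np.ndarray]]:
    """(weight, d2v) pairs for the 6 distinct second derivatives of each
    component; zero-padded stencils so each operator is self-adjoint."""
    out = []
    for comp in range(v.shape[-1]):
        f = v[..., comp]
        for ax in range(3):
            d = ndimage.correlate1d(f, _D2 / spacing[ax] ** 2, axis=ax, mode="constant")
            out.append((1.0, comp, (ax, ax), d))
        for a in range(3):
            for b in range(a + 1, 3):
                d = ndimage.correlate1d(f, _D1 / spacing[a], axis=a, mode="constant")
                d = ndimage.correlate1d(d, _D1 / spacing[b], axis=b, mode="constant")
                out.append((2.0, comp, (a, b), d))
    return out


def bending_energy_dense(v: np.ndarray, spacing) -> tuple[float, np.ndarray]:
    """Mean squared second spatial derivative of a dense vector field.

    Returns the scalar energy and its exact gradient with respect to the
    dense field (the finite-difference operators are self-adjoint under
    zero padding).  Zero for any affine (linear-in-x) field.
    """
    spacing = np.asarray(spacing, dtype=float)
    n = v[..., 0].size
    energy = 0.0
    grad = np.zeros_like(v)
    for w, comp, (a, b), d in _second_derivatives(v, spacing):
        energy += w * float((d**2).sum())
        if a == b:
            g = ndimage.correlate1d(d, _D2 / spacing[a] ** 2, axis=a, mode="constant")
        else:
            g = ndimage.correlate1d(d, _D1 / spacing[a], axis=a, mode="constant")
            g = ndimage.correlate1d(g, _D1 / spacing[b], axis=b, mode="constant")
        grad[..., comp] += 2.0 * w * g
    return energy / n, grad / n


def bending_energy(lattice: VelocityLattice) -> tuple[float, np.ndarray]:
    """FFD bending energy of the lattice's dense velocity field.

    Returns the scalar and its gradient with respect to the lattice
    coefficients (chain rule through the separable interpolation).
    """
    v = lattice.dense_velocity().data
    e, g_dense = bending_energy_dense(v, lattice.grid.spacing_arr)
    return e, lattice.project_dense_gradient(g_dense)
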