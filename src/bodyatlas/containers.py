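"""Grid-aware volume and vector-field containers.

All spatial objects live on an axis-aligned regular grid.  A voxel with
integer index ``(i, j, k)`` sits at physical position
``origin + index * spacing`` (millimetres).  Displacement fields follow the
pull-back convention used throughout the package: a field ``u`` defined on a
*fixed* grid transports fixed-space points into moving space via
``phi(x) = x + u(x)``, and warping resamples the moving image at ``phi(x)``
so the result lives on the fixed grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

PULLBACK = "pullback-mm"


@dataclass(frozen=True)
class Grid:
    """Regular 3D sampling grid in physical (mm) coordinates."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"grid shape must be 3 positive ints, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be strictly positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    @property
    def spacing_arr(self) -> np.ndarray:
        return np.asarray(self.spacing, dtype=float)

    @property
    def origin_arr(self) -> np.ndarray:
        return np.asarray(self.origin, dtype=float)

    @property
    def extent(self) -> np.ndarray:
        """Physical size of the grid (distance between first and last voxel centres)."""
        return (np.asarray(self.shape) - 1) * self.spacing_arr

    @property
    def center(self) -> np.ndarray:
        return self.origin_arr + self.extent / 2.0

    def coordinates(self) -> np.ndarray:
        """Physical coordinates of all voxel centres, shape ``shape + (3,)``.

        Cached (read-only view) — composition and warping hit this repeatedly.
        """
        cached = getattr(self, "_coords", None)
        if cached is None:
            axes = [
                self.origin[d] + self.spacing[d] * np.arange(self.shape[d])
                for d in range(3)
            ]
            ii, jj, kk = np.meshgrid(*axes, indexing="ij")
            cached = np.stack([ii, jj, kk], axis=-1)
            cached.setflags(write=False)
            object.__setattr__(self, "_coords", cached)
        return cached

    def to_index(self, points: np.ndarray) -> np.ndarray:
        """Convert physical points (..., 3) to fractional voxel indices."""
        return (np.asarray(points, dtype=float) - self.origin_arr) / self.spacing_arr

    def compatible(self, other: "Grid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


def _check_grid_data(data: np.ndarray, grid: Grid, ncomp: int | None) -> None:
    expected = grid.shape if ncomp is None else grid.shape + (ncomp,)
    if data.shape != expected:
        raise ValueError(f"data shape {data.shape} does not match grid {expected}")


@dataclass
class Volume:
    """Scalar 3D image on a regular grid (anatomy, masks, probability maps)."""

    data: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("Volume data must be 3D")
        _check_grid_data(self.data, self.grid, None)

    @classmethod
    def from_array(
        cls,
        data: np.ndarray,
        spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
        origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "Volume":
        data = np.asarray(data)
        return cls(data, Grid(data.shape, spacing, origin))

    @property
    def spacing(self) -> np.ndarray:
        return self.grid.spacing_arr

    @property
    def origin(self) -> np.ndarray:
        return self.grid.origin_arr

    def with_data(self, data: np.ndarray) -> "Volume":
        return Volume(np.asarray(data), self.grid)

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.grid)


@dataclass
class LabelVolume:
    """Integer-labelled 3D segmentation with a label dictionary (0 = background)."""

    data: np.ndarray
    grid: Grid
    labels: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("LabelVolume data must be integer-typed")
        if self.data.min() < 0:
            raise ValueError("labels must be non-negative")
        _check_grid_data(self.data, self.grid, None)
        self.labels = dict(self.labels)
        self.labels.setdefault(0, "background")
        present = set(np.unique(self.data).tolist())
        unknown = present - set(self.labels)
        if unknown:
            raise ValueError(f"voxel labels {sorted(unknown)} missing from label dictionary")

    def mask(self, label_id: int) -> Volume:
        return Volume((self.data == label_id).astype(float), self.grid)

    def structure_ids(self) -> list[int]:
        return sorted(k for k in self.labels if k != 0)

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.data.copy(), self.grid, dict(self.labels))


@dataclass
class DisplacementField:
    """Dense displacement field on a fixed grid; components in mm.

    ``data[..., d]`` is the d-th displacement component.  The field maps
    fixed-space points to moving-space points (pull-back convention).
    """

    data: np.ndarray
    grid: Grid
    convention: str = PULLBACK
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValueError("DisplacementField data must have shape (X, Y, Z, 3)")
        _check_grid_data(self.data, self.grid, 3)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("displacement components must be finite")

    @classmethod
    def zeros(cls, grid: Grid) -> "DisplacementField":
        return cls(np.zeros(grid.shape + (3,)), grid)

    @property
    def spacing(self) -> np.ndarray:
        return self.grid.spacing_arr

    def with_data(self, data: np.ndarray) -> "DisplacementField":
        return DisplacementField(np.asarray(data, dtype=float), self.grid, self.convention)

    def copy(self) -> "DisplacementField":
        return DisplacementField(self.data.copy(), self.grid, self.convention, dict(self.meta))

    def max_norm(self) -> float:
        return float(np.sqrt((self.data**2).sum(axis=-1)).max())


@dataclass
class AffineTransform:
    """Affine map ``phi(x) = L x + t`` in physical coordinates (mm)."""

    linear: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.linear)) < 1e-12:
            raise ValueError("affine linear part is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def translation_only(cls, t) -> "AffineTransform":
        return cls(np.eye(3), np.asarray(t, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.linear.T + self.translation

    def compose(self, inner: "AffineTransform") -> "AffineTransform":
        """Return ``self ∘ inner`` (apply ``inner`` first)."""
        return AffineTransform(
            self.linear @ inner.linear,
            self.linear @ inner.translation + self.translation,
        )

    def inverse(self) -> "AffineTransform":
        linv = np.linalg.inv(self.linear)
        return AffineTransform(linv, -linv @ self.translation)

    def is_identity(self, tol: float = 1e-9) -> bool:
        return (
            np.allclose(self.linear, np.eye(3), atol=tol)
            and np.allclose(self.translation, 0.0, atol=tol)
        )
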