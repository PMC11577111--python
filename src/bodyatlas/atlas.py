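"""Atlas construction and unbiasing.

The initial atlas averages the subjects warped into the reference space,
``A_init = (1/n) sum_i I_i ∘ phi_i``.  Label atlases average one-hot encoded,
linearly warped structure masks into per-structure probability maps.  The
initial atlas inherits the reference subject's geometry; the unbiasing step
warps it by the average inverse deformation ``Phi = (1/n) sum_i phi_i^{-1}``
so the result reflects the population's mean geometry instead,
``A_u = A_init ∘ Phi``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import DisplacementField, LabelVolume, Volume
from .transforms import NonConvergenceError, invert, warp_volume

logger = logging.getLogger(__name__)


@dataclass
class Atlas:
    """Anatomical average plus per-structure probability maps."""

    anatomical: Volume
    probabilities: dict  # structure name -> Volume in [0, 1]
    coverage: Volume  # mean in-domain sampling weight per voxel
    n_subjects: int
    reference_id: str = ""
    unbiased: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, vol in self.probabilities.items():
            lo, hi = float(vol.data.min()), float(vol.data.max())
            if lo < -1e-6 or hi > 1 + 1e-6:
                raise ValueError(f"probability map {name} out of [0, 1]: [{lo}, {hi}]")


def build_initial_atlas(
    images: Sequence[Volume], fields: Sequence[DisplacementField]
) -> tuple[Volume, Volume]:
    """Average the subjects warped into the reference space.

    Returns ``(A_init, coverage)``; coverage is the mean in-domain sampling
    weight (0 where every subject sampled outside its domain — those atlas
    voxels are 0 and should be masked downstream).
    """
    if not images:
        raise ValueError("cannot build an atlas from an empty image list")
    if len(images) != len(fields):
        raise ValueError("images and fields must have equal length")
    grid = fields[0].grid
    acc = np.zeros(grid.shape, dtype=float)
    cov = np.zeros(grid.shape, dtype=float)
    for img, f in zip(images, fields):
        if not f.grid.compatible(grid):
            raise ValueError("all fields must live on the reference grid")
        acc += warp_volume(img, f, "linear").data
        cov += warp_volume(Volume(np.ones(img.grid.shape), img.grid), f, "linear").data
    n = len(images)
    return Volume(acc / n, grid), Volume(cov / n, grid)


def build_label_atlas(
    labels: Sequence[LabelVolume], fields: Sequence[DisplacementField]
) -> dict:
    """Per-structure probability maps: one-hot encode, warp linearly, average.

    All subjects must share a label dictionary.  Linear interpolation of the
    indicator functions keeps each map in [0, 1] and smooth.
    """
    if not labels:
        raise ValueError("cannot build a label atlas from an empty list")
    if len(labels) != len(fields):
        raise ValueError("labels and fields must have equal length")
    ref_dict = dict(labels[0].labels)
    for lab in labels[1:]:
        if dict(lab.labels) != ref_dict:
            raise ValueError("inconsistent label dictionaries across subjects")
    grid = fields[0].grid
    out: dict[str, np.ndarray] = {}
    for lid in labels[0].structure_ids():
        name = ref_dict[lid]
        acc = np.zeros(grid.shape, dtype=float)
        for lab, f in zip(labels, fields):
            acc += warp_volume(lab.mask(lid), f, "linear").data
        out[name] = np.clip(acc / len(labels), 0.0, 1.0)
    return {name: Volume(data, grid) for name, data in out.items()}


def average_inverse_field(
    fields: Sequence[DisplacementField],
    tol: float = 0.01,
    max_iter: int = 50,
) -> DisplacementField:
    """Average inverse deformation ``Phi = (1/n) sum_i phi_i^{-1}``.

    Each field is inverted by fixed-point iteration; a non-convergent
    inversion aborts with the offending subject index.
    """
    if not fields:
        raise ValueError("no fields to invert")
    grid = fields[0].grid
    acc = np.zeros(grid.shape + (3,), dtype=float)
    for i, f in enumerate(fields):
        try:
            inv = invert(f, tol=tol, max_iter=max_iter)
        except NonConvergenceError as exc:
            raise NonConvergenceError(f"inversion failed for field {i}: {exc}") from exc
        logger.info(
            "field %d inversion residual %.4g mm", i, inv.meta["inversion_residual_mm"]
        )
        acc += inv.data
    return DisplacementField(acc / len(fields), grid)


def unbias_atlas(atlas: Atlas, fields: Sequence[DisplacementField]) -> Atlas:
    """Warp the initial atlas (anatomy and every probability map) by the
    average inverse field of the deformations that built it."""
    phi_bar = average_inverse_field(fields)
    anatomical = warp_volume(atlas.anatomical, phi_bar, "linear")
    probs = {
        name: Volume(np.clip(warp_volume(vol, phi_bar, "linear").data, 0.0, 1.0), phi_bar.grid)
        for name, vol in atlas.probabilities.items()
    }
    coverage = warp_volume(atlas.coverage, phi_bar, "linear")
    return Atlas(
        anatomical=anatomical,
        probabilities=probs,
        coverage=coverage,
        n_subjects=atlas.n_subjects,
        reference_id=atlas.reference_id,
        unbiased=True,
        provenance={**atlas.provenance, "unbiased_by": "average_inverse_field"},
    )


def build_atlas(
    images: Sequence[Volume],
    labels: Sequence[LabelVolume],
    fields: Sequence[DisplacementField],
    reference_id: str = "",
    unbias: bool = True,
) -> Atlas:
    """Convenience: initial anatomical + label atlases, optionally unbiased."""
    anatomical, coverage = build_initial_atlas(images, fields)
    probs = build_label_atlas(labels, fields)
    atlas = Atlas(
        anatomical=anatomical,
        probabilities=probs,
        coverage=coverage,
        n_subjects=len(images),
        reference_id=reference_id,
    )
    return unbias_atlas(atlas, fields) if unbias else atlas
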