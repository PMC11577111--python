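"""Synthetic 3D body phantoms with organ/fat labels, ground-truth
deformations and matching phenotype tables.

The generator emulates the study conditions of a whole-body water-contrast
MR cohort at desk scale: an elliptical body with a subcutaneous-fat shell,
visceral-fat blobs, and five abdominal "organ" ellipsoids (liver, spleen,
pancreas, left/right kidney), deformed per subject by a random smooth
diffeomorphic field composed with a global scale + translation.  Each subject
carries a phenotype record placed in a requested sex x BMI group, so the
cohort machinery (grouping, healthy filter, reference selection) runs
unchanged on synthetic data.

Every deformation produced here is exact ground truth: registration tests
recover it, atlas tests average it, and the VBM test plants a known extra
visceral-fat region in a "diseased" subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .cohort import BMI_RANGES, GroupAssignment, SubjectRecord, assign_group
from .containers import AffineTransform, DisplacementField, Grid, LabelVolume, Volume
from .evaluation import folding_ratio
from .transforms import (
    compose_affine_field,
    integrate_velocity,
    warp_labels,
    warp_volume,
)

LABEL_NAMES = {
    0: "background",
    1: "subcutaneous_fat",
    2: "visceral_fat",
    3: "liver",
    4: "spleen",
    5: "pancreas",
    6: "kidney_left",
    7: "kidney_right",
}

#: organ ellipsoids as (centre offset from body centre, semi-axes), mm
DEFAULT_ORGANS = {
    "liver": ((26.0, 0.0, 60.0), (26.0, 22.0, 24.0)),
    "spleen": ((-40.0, 0.0, 50.0), (14.0, 12.0, 18.0)),
    "pancreas": ((0.0, -5.0, 26.0), (26.0, 10.0, 7.0)),
    "kidney_left": ((-28.0, 10.0, 15.0), (11.0, 11.0, 20.0)),
    "kidney_right": ((28.0, 10.0, 15.0), (11.0, 11.0, 20.0)),
}

DEFAULT_INTENSITIES = {
    "lean": 0.55,
    "subcutaneous_fat": 0.25,
    "visceral_fat": 0.25,
    "liver": 0.85,
    "spleen": 0.80,
    "pancreas": 0.75,
    "kidney_left": 0.80,
    "kidney_right": 0.80,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity model and seed of the synthetic body template."""

    shape: tuple[int, int, int] = (64, 48, 96)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    body_semi_axes: tuple[float, float, float] = (80.0, 60.0, 135.0)
    shell_thickness: float = 12.0
    n_visceral_blobs: int = 6
    blob_radius_range: tuple[float, float] = (9.0, 14.0)
    organs: dict = field(default_factory=lambda: dict(DEFAULT_ORGANS))
    intensities: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))
    noise_sd: float = 0.02
    seed: int = 0

    @property
    def grid(self) -> Grid:
        return Grid(self.shape, self.spacing)


@dataclass(frozen=True)
class DeformParams:
    """Per-subject random deformation: smooth velocity + global affine."""

    amplitude_mm: float = 8.0
    correlation_mm: float = 30.0
    scale_range: tuple[float, float] = (0.94, 1.06)
    translation_mm: float = 6.0
    squaring_steps: int = 6


@dataclass(frozen=True)
class FatParams:
    """Per-subject visceral-fat variability: fraction of lean abdominal voxels
    converted to visceral fat (independently per subject)."""

    base_fraction: float = 0.05


@dataclass(frozen=True)
class DiseaseEffect:
    """Planted effect: extra visceral fat in a known region of diseased subjects.

    ``delta`` is the extra conversion fraction of lean voxels in the region
    (default +0.30, i.e. a strong planted perirenal-fat increase).
    """

    center_offset: tuple[float, float, float] = (0.0, 8.0, 15.0)
    semi_axes: tuple[float, float, float] = (46.0, 24.0, 26.0)
    delta: float = 0.30


@dataclass
class SyntheticSubject:
    record: SubjectRecord
    anatomy: Volume
    labels: LabelVolume
    phi_true: DisplacementField


# ---------------------------------------------------------------------------
# template construction


def _ellipsoid_mask(grid: Grid, center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    pts = grid.coordinates()
    r2 = (((pts - center) / semi) ** 2).sum(axis=-1)
    return r2 <= 1.0


def disease_region_mask(spec: PhantomSpec, effect: DiseaseEffect) -> np.ndarray:
    """Boolean mask of the planted-effect region on the template grid."""
    center = spec.grid.center + np.asarray(effect.center_offset)
    return _ellipsoid_mask(spec.grid, center, np.asarray(effect.semi_axes))


def build_label_template(spec: PhantomSpec) -> tuple[LabelVolume, Volume]:
    """Deterministic label template and binary body-support volume."""
    grid = spec.grid
    center = grid.center
    body_semi = np.asarray(spec.body_semi_axes)
    if spec.shell_thickness >= body_semi.min():
        raise ValueError("shell thickness must be smaller than the body minor semi-axis")
    body = _ellipsoid_mask(grid, center, body_semi)
    inner = _ellipsoid_mask(grid, center, body_semi - spec.shell_thickness)
    labels = np.zeros(grid.shape, dtype=np.int16)
    labels[body & ~inner] = 1  # subcutaneous fat shell

    organ_ids = {name: i for i, name in enumerate(list(LABEL_NAMES.values())[3:], start=3)}
    organ_masks = {}
    for name, (off, semi) in spec.organs.items():
        m = _ellipsoid_mask(grid, center + np.asarray(off), np.asarray(semi))
        if not (m <= inner).all():
            raise ValueError(f"organ {name} extends outside the body interior")
        organ_masks[name] = m
    names = list(organ_masks)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if (organ_masks[a] & organ_masks[b]).any():
                raise ValueError(f"organs {a} and {b} overlap")
    for name, m in organ_masks.items():
        labels[m] = organ_ids[name]

    # visceral fat blobs: random spheres in the abdominal interior, on lean tissue
    rng = np.random.default_rng(spec.seed)
    abdomen_semi = np.asarray([0.62, 0.62, 0.45]) * body_semi
    abdomen_center = center + np.array([0.0, 0.0, 0.0])
    for _ in range(spec.n_visceral_blobs):
        u = rng.uniform(-1.0, 1.0, size=3) * 0.8
        c = abdomen_center + u * abdomen_semi
        r = rng.uniform(*spec.blob_radius_range)
        blob = _ellipsoid_mask(grid, c, np.full(3, r))
        labels[blob & inner & (labels == 0)] = 2

    return LabelVolume(labels, grid, dict(LABEL_NAMES)), Volume(body.astype(float), grid)


def paint_anatomy(
    labels: LabelVolume, body: Volume, spec: PhantomSpec, rng: np.random.Generator
) -> Volume:
    """Paint intensities from labels: background exactly 0, structures at their
    declared means plus Gaussian noise (inside the body only)."""
    img = np.zeros(labels.grid.shape, dtype=float)
    support = body.data > 0
    img[support] = spec.intensities["lean"]
    for lid, name in LABEL_NAMES.items():
        if lid == 0:
            continue
        img[labels.data == lid] = spec.intensities[name]
    if spec.noise_sd > 0:
        img[support] += rng.normal(0.0, spec.noise_sd, size=int(support.sum()))
        np.clip(img, 0.0, None, out=img)
    return Volume(img, labels.grid)


def make_template(spec: PhantomSpec | None = None) -> tuple[Volume, LabelVolume]:
    """Noise-free-geometry template: anatomy volume and exact label volume."""
    spec = spec or PhantomSpec()
    labels, body = build_label_template(spec)
    rng = np.random.default_rng(spec.seed + 1)
    return paint_anatomy(labels, body, spec, rng), labels


# ---------------------------------------------------------------------------
# per-subject sampling


def random_velocity(
    grid: Grid, amplitude_mm: float, correlation_mm: float, rng: np.random.Generator
) -> DisplacementField:
    """Smooth random stationary velocity: white noise convolved with a Gaussian
    of the given correlation length, rescaled to the target max amplitude."""
    if amplitude_mm == 0:
        return DisplacementField.zeros(grid)
    sigma_vox = correlation_mm / grid.spacing_arr
    v = rng.standard_normal(size=grid.shape + (3,))
    for d in range(3):
        # zero padding tapers the velocity toward the domain boundary, so the
        # amplitude normalisation is set by the interior field
        v[..., d] = ndimage.gaussian_filter(v[..., d], sigma_vox, mode="constant")
    norm = np.sqrt((v**2).sum(axis=-1)).max()
    if norm > 0:
        v *= amplitude_mm / norm
    return DisplacementField(v, grid)


def _sample_phenotypes(
    group: GroupAssignment, subject_id: str, rng: np.random.Generator, diseased: bool
) -> SubjectRecord:
    lo, hi = BMI_RANGES[group.category]
    bmi = rng.uniform(lo, min(hi, 40.0))
    if group.sex == "female":
        height = float(np.clip(rng.normal(163.0, 6.0), 145.0, 185.0))
        body_fat = 25.0 + 0.9 * (bmi - 22.0) + rng.normal(0.0, 2.0)
    else:
        height = float(np.clip(rng.normal(176.0, 7.0), 155.0, 200.0))
        body_fat = 13.0 + 1.0 * (bmi - 22.0) + rng.normal(0.0, 2.0)
    weight = bmi * (height / 100.0) ** 2
    flags = {
        "cancer_record": False,
        "self_reported_disease": bool(diseased),
        "operation_history": False,
    }
    rec = SubjectRecord(
        subject_id=subject_id,
        sex=group.sex,
        age=float(rng.uniform(45.0, 75.0)),
        weight=weight,
        height=height,
        body_fat=float(np.clip(body_fat, 5.0, 60.0)),
        flags=flags,
    )
    assert assign_group(rec.sex, rec.bmi).category == group.category
    return rec


def perturb_visceral_fat(
    labels: LabelVolume,
    region: np.ndarray,
    fraction: float,
    rng: np.random.Generator,
) -> LabelVolume:
    """Convert a random ``fraction`` of lean voxels inside ``region`` to
    visceral fat (label 2); inert when fraction is 0."""
    if fraction <= 0:
        return labels.copy()
    out = labels.data.copy()
    candidates = np.flatnonzero(region.ravel() & (out.ravel() == 0))
    n = int(round(fraction * candidates.size))
    if n > 0:
        chosen = rng.choice(candidates, size=n, replace=False)
        out.ravel()[chosen] = 2
    return LabelVolume(out, labels.grid, dict(labels.labels))


def sample_subject(
    spec: PhantomSpec,
    group: GroupAssignment | str,
    subject_id: str,
    seed: int,
    deform: DeformParams | None = None,
    fat: FatParams | None = None,
    diseased: bool = False,
    disease_effect: DiseaseEffect | None = None,
) -> SyntheticSubject:
    """Draw one synthetic subject: phenotypes, deformed anatomy/labels, and
    the exact ground-truth field ``phi_true`` (template -> subject).

    Fully reproducible: the same (spec, seed, parameters) yield bit-identical
    subjects.  Raises if the requested deformation amplitude produces folding.
    """
    if isinstance(group, str):
        sex, cat = group.split("-")
        group = assign_group(sex, (BMI_RANGES[cat][0] + min(BMI_RANGES[cat][1], 40.0)) / 2.0)
    deform = deform or DeformParams()
    fat = fat or FatParams()
    rng = np.random.default_rng(seed)
    grid = spec.grid

    labels0, body = build_label_template(spec)
    abdomen = _ellipsoid_mask(
        grid, grid.center, np.asarray([0.62, 0.62, 0.45]) * np.asarray(spec.body_semi_axes)
    )
    labels_i = perturb_visceral_fat(labels0, abdomen, fat.base_fraction, rng)
    if diseased:
        effect = disease_effect or DiseaseEffect()
        labels_i = perturb_visceral_fat(labels_i, disease_region_mask(spec, effect), effect.delta, rng)
    # noise-free geometry is deformed; acquisition noise is added afterwards
    # in subject space, so all subjects share the template's noise statistics
    noise_free = replace(spec, noise_sd=0.0)
    anatomy_i = paint_anatomy(labels_i, body, noise_free, rng)

    vel = random_velocity(grid, deform.amplitude_mm, deform.correlation_mm, rng)
    disp = integrate_velocity(vel, deform.squaring_steps)
    s = rng.uniform(*deform.scale_range)
    t = rng.uniform(-deform.translation_mm, deform.translation_mm, size=3)
    c = grid.center
    affine = AffineTransform(np.eye(3) * s, c - s * c + t)
    phi_true = compose_affine_field(affine, disp)

    fr = folding_ratio(phi_true)
    if fr > 0:
        raise ValueError(
            f"deformation amplitude {deform.amplitude_mm} mm produced folding (ratio {fr:.4g})"
        )

    record = _sample_phenotypes(group, subject_id, rng, diseased)
    anatomy_s = warp_volume(anatomy_i, phi_true, "linear")
    if spec.noise_sd > 0:
        support = anatomy_s.data > 0
        noisy = anatomy_s.data.copy()
        noisy[support] += rng.normal(0.0, spec.noise_sd, size=int(support.sum()))
        anatomy_s = Volume(np.clip(noisy, 0.0, None), grid)
    return SyntheticSubject(
        record=record,
        anatomy=anatomy_s,
        labels=warp_labels(labels_i, phi_true),
        phi_true=phi_true,
    )


def generate_group(
    spec: PhantomSpec,
    group: str,
    n: int,
    seed: int,
    deform: DeformParams | None = None,
    fat: FatParams | None = None,
    n_diseased: int = 0,
    disease_effect: DiseaseEffect | None = None,
    id_prefix: str = "sub",
) -> list[SyntheticSubject]:
    """Generate ``n`` healthy (+ ``n_diseased`` diseased) subjects of one group."""
    seeds = np.random.SeedSequence(seed).generate_state(n + n_diseased)
    subjects = []
    for i in range(n + n_diseased):
        diseased = i >= n
        tag = "d" if diseased else "h"
        subjects.append(
            sample_subject(
                spec,
                group,
                f"{id_prefix}-{group}-{tag}{i:03d}",
                int(seeds[i] % (2**31)),
                deform=deform,
                fat=fat,
                diseased=diseased,
                disease_effect=disease_effect,
            )
        )
    return subjects


def make_cohort(
    out_dir,
    groups: Sequence[str],
    n_per_group: int,
    seed: int,
    spec: PhantomSpec | None = None,
    deform: DeformParams | None = None,
    fat: FatParams | None = None,
    n_diseased: int = 0,
    disease_effect: DiseaseEffect | None = None,
) -> Path:
    """Write a synthetic cohort to disk: per-subject NIfTI volumes, a phenotype
    CSV, and a JSON manifest of the ground-truth deformations."""
    import json

    from . import io as bio
    from .cohort import write_phenotypes

    spec = spec or PhantomSpec()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    anatomy_t, labels_t = make_template(spec)
    bio.write_volume(anatomy_t, out / "template_anatomy.nii")
    bio.write_labels(labels_t, out / "template_labels.nii")

    records = []
    manifest = {"seed": seed, "groups": {}, "subjects": {}}
    group_seeds = np.random.SeedSequence(seed).generate_state(len(groups))
    for g, gs in zip(groups, group_seeds):
        subjects = generate_group(
            spec, g, n_per_group, int(gs % (2**31)), deform, fat, n_diseased, disease_effect
        )
        manifest["groups"][g] = [s.record.subject_id for s in subjects]
        for s in subjects:
            sid = s.record.subject_id
            sdir = out / sid
            sdir.mkdir(exist_ok=True)
            bio.write_volume(s.anatomy, sdir / "anatomy.nii")
            bio.write_labels(s.labels, sdir / "labels.nii")
            bio.write_field(s.phi_true, sdir / "phi_true.nii")
            records.append(s.record)
            manifest["subjects"][sid] = {
                "group": g,
                "diseased": bool(s.record.flags["self_reported_disease"]),
            }
    write_phenotypes(records, out / "phenotypes.csv")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
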