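"""Registration-quality metrics: Dice overlap, 95th-percentile Hausdorff
distance, and the folding ratio of a deformation field."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .containers import DisplacementField, LabelVolume, Volume
from .transforms import jacobian_determinant


def dice(a: Volume, b: Volume) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two binary volumes.

    Convention for degenerate inputs: 1.0 when both masks are empty, 0.0 when
    exactly one is empty.
    """
    if not a.grid.compatible(b.grid):
        raise ValueError("dice requires volumes on the same grid")
    am = np.asarray(a.data) > 0.5
    bm = np.asarray(b.data) > 0.5
    sa, sb = int(am.sum()), int(bm.sum())
    if sa == 0 and sb == 0:
        return 1.0
    if sa == 0 or sb == 0:
        return 0.0
    return 2.0 * int((am & bm).sum()) / (sa + sb)


def _boundary(mask: np.ndarray) -> np.ndarray:
    """6-connectivity boundary voxels of a binary mask."""
    struct = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    return mask & ~eroded


def hausdorff95(a: Volume, b: Volume) -> float:
    """Symmetric 95th-percentile Hausdorff distance (mm) between mask surfaces.

    Directed distances are measured between boundary voxels via Euclidean
    distance transforms with physical spacing; the symmetric value is the max
    of the two directed 95th percentiles.
    """
    if not a.grid.compatible(b.grid):
        raise ValueError("hausdorff95 requires volumes on the same grid")
    am = np.asarray(a.data) > 0.5
    bm = np.asarray(b.data) > 0.5
    if am.sum() == 0 or bm.sum() == 0:
        raise ValueError("hausdorff95 is undefined for empty masks")
    sp = a.grid.spacing
    ab_, bb_ = _boundary(am), _boundary(bm)

    def directed(src: np.ndarray, dst: np.ndarray) -> float:
        dt = ndimage.distance_transform_edt(~dst, sampling=sp)
        return float(np.percentile(dt[src], 95))

    return max(directed(ab_, bb_), directed(bb_, ab_))


def folding_ratio(fieldv: DisplacementField, interior_margin: int = 1) -> float:
    """Fraction of interior voxels whose Jacobian determinant is <= 0.

    Boundary voxels (one-sided differences) are excluded from the statistic.
    """
    det = jacobian_determinant(fieldv).data
    m = interior_margin
    if m > 0:
        det = det[m:-m, m:-m, m:-m]
    return float((det <= 0).sum() / det.size)


@dataclass
class MetricReport:
    """Per-stage registration quality summary for one group of subjects."""

    stage: str
    per_label_dice: dict = field(default_factory=dict)  # label name -> (mean, sd)
    mean_dice: float = float("nan")
    mean_hd95: float = float("nan")
    folding: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "per_label_dice": {k: list(v) for k, v in self.per_label_dice.items()},
            "mean_dice": self.mean_dice,
            "mean_hd95": self.mean_hd95,
            "folding_ratio": self.folding,
        }


def evaluate_pair(
    reference_labels: LabelVolume, warped_labels: LabelVolume
) -> tuple[dict, float, float]:
    """Per-structure Dice and HD95 between a reference and a warped label map."""
    per_dice, per_hd = {}, {}
    for lid in reference_labels.structure_ids():
        name = reference_labels.labels[lid]
        ra, wa = reference_labels.mask(lid), warped_labels.mask(lid)
        per_dice[name] = dice(ra, wa)
        if ra.data.sum() > 0 and wa.data.sum() > 0:
            per_hd[name] = hausdorff95(ra, wa)
    mean_d = float(np.mean(list(per_dice.values())))
    mean_h = float(np.mean(list(per_hd.values()))) if per_hd else float("nan")
    return per_dice, mean_d, mean_h


def evaluate_group(
    reference_labels: LabelVolume,
    warped_by_stage: dict[str, list[LabelVolume]],
    fields_by_stage: dict[str, list[DisplacementField]] | None = None,
) -> list[MetricReport]:
    """Mean +/- sd Dice and HD95 per stage across subjects, plus mean folding
    ratio of the stage's deformation fields when provided."""
    reports = []
    for stage, warped_list in warped_by_stage.items():
        all_dice: dict[str, list[float]] = {}
        mean_ds, mean_hs = [], []
        for warped in warped_list:
            per_dice, mean_d, mean_h = evaluate_pair(reference_labels, warped)
            for name, val in per_dice.items():
                all_dice.setdefault(name, []).append(val)
            mean_ds.append(mean_d)
            if np.isfinite(mean_h):
                mean_hs.append(mean_h)
        rep = MetricReport(
            stage=stage,
            per_label_dice={
                k: (float(np.mean(v)), float(np.std(v))) for k, v in all_dice.items()
            },
            mean_dice=float(np.mean(mean_ds)),
            mean_hd95=float(np.mean(mean_hs)) if mean_hs else float("nan"),
        )
        if fields_by_stage and stage in fields_by_stage:
            rep.folding = float(
                np.mean([folding_ratio(f) for f in fields_by_stage[stage]])
            )
        reports.append(rep)
    return reports
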