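"""Voxel-based morphometry: compare atlas-space tissue maps between a healthy
and a pathological group.

Each subject contributes one spatially normalised map (here: visceral-fat
indicator maps warped to atlas space).  Maps are Gaussian-smoothed, a voxel-
wise general linear model with a group indicator is fitted, the two-sided t
statistic is converted to a signed z score (probit transform), and the voxel
p-values are corrected with Benjamini-Hochberg FDR.  The significance mask
keeps voxels that survive BH at level ``q`` *and* have corrected p below the
retention threshold (default 0.001).

Sign convention: positive z means the pathological group mean exceeds the
healthy group mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .containers import Volume

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # approx 2.355


@dataclass
class GroupSample:
    """Atlas-space maps (one Volume per subject) for one group."""

    maps: list
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.maps) < 2:
            raise ValueError(f"group {self.label!r} needs >= 2 subjects")
        grid = self.maps[0].grid
        for m in self.maps[1:]:
            if not m.grid.compatible(grid):
                raise ValueError("all maps in a group must share the atlas grid")

    def stack(self) -> np.ndarray:
        return np.stack([np.asarray(m.data, dtype=float) for m in self.maps])


@dataclass
class ZMap:
    """Voxel-wise z scores with corrected p-values and significance mask."""

    z: Volume
    p_corrected: Volume
    significance: Volume  # binary
    analysis_mask: Volume  # binary
    n_flagged_zero_variance: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sig = self.significance.data > 0.5
        mask = self.analysis_mask.data > 0.5
        if (sig & ~mask).any():
            raise ValueError("significance mask extends outside the analysis mask")


def smooth(v: Volume, fwhm_mm: float) -> Volume:
    """Spacing-aware Gaussian smoothing; ``fwhm_mm = 0`` is the identity."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return v.copy()
    sigma_vox = (fwhm_mm / FWHM_TO_SIGMA) / v.grid.spacing_arr
    return v.with_data(ndimage.gaussian_filter(np.asarray(v.data, dtype=float), sigma_vox))


def glm_group_test(
    healthy: GroupSample,
    diseased: GroupSample,
    mask: np.ndarray | None = None,
    covariates: tuple[np.ndarray | None, np.ndarray | None] = (None, None),
) -> ZMap:
    """Voxel-wise GLM with intercept + group indicator (optional covariates).

    With no covariates this is exactly the pooled two-sample t-test with
    ``n_a + n_b - 2`` degrees of freedom.  The two-sided p-value is mapped to
    a signed z score via the probit transform; positive z means
    diseased > healthy.  Voxels with zero residual variance get z = 0 and are
    counted in ``n_flagged_zero_variance``.
    """
    grid = healthy.maps[0].grid
    A = healthy.stack().reshape(len(healthy.maps), -1)
    B = diseased.stack().reshape(len(diseased.maps), -1)
    na, nb = A.shape[0], B.shape[0]
    Y = np.concatenate([A, B], axis=0)

    cols = [np.ones(na + nb), np.concatenate([np.zeros(na), np.ones(nb)])]
    cov_a, cov_b = covariates
    if cov_a is not None or cov_b is not None:
        ca = np.atleast_2d(np.zeros((na, 0)) if cov_a is None else np.asarray(cov_a, float))
        cb = np.atleast_2d(np.zeros((nb, 0)) if cov_b is None else np.asarray(cov_b, float))
        extra = np.concatenate([ca.reshape(na, -1), cb.reshape(nb, -1)], axis=0)
        cols.extend(extra.T)
    X = np.column_stack(cols)
    k = X.shape[1]
    df = na + nb - k
    if df < 1:
        raise ValueError("not enough subjects for the design")

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    c = np.zeros(k)
    c[1] = 1.0
    var_scale = float(c @ XtX_inv @ c)

    se = np.sqrt(sigma2 * var_scale)
    effect = c @ beta
    zero_var = se < 1e-14
    t = np.zeros_like(effect)
    np.divide(effect, se, out=t, where=~zero_var)

    # two-sided p, then signed probit transform
    p = 2.0 * stats.t.sf(np.abs(t), df)
    z = np.sign(t) * stats.norm.isf(np.clip(p, 1e-300, 1.0) / 2.0)
    z[zero_var] = 0.0
    p[zero_var] = 1.0

    mask_arr = np.ones(grid.shape, bool) if mask is None else np.asarray(mask, bool)
    z_vol = np.where(mask_arr, z.reshape(grid.shape), 0.0)
    p_vol = np.where(mask_arr, p.reshape(grid.shape), 1.0)
    n_flagged = int((zero_var.reshape(grid.shape) & mask_arr).sum())
    if n_flagged:
        logger.info("%d in-mask voxels had zero within-group variance (z set to 0)", n_flagged)
    return ZMap(
        z=Volume(z_vol, grid),
        p_corrected=Volume(p_vol, grid),  # uncorrected until fdr_threshold
        significance=Volume(np.zeros(grid.shape), grid),
        analysis_mask=Volume(mask_arr.astype(float), grid),
        n_flagged_zero_variance=n_flagged,
        params={"df": df, "n_healthy": na, "n_diseased": nb, "corrected": False},
    )


def fdr_threshold(zmap: ZMap, q: float = 0.05, p_retain: float = 0.001) -> ZMap:
    """Benjamini-Hochberg correction over in-mask voxels.

    The significance mask keeps voxels rejected by BH at level ``q`` whose
    corrected p is additionally below ``p_retain``.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    mask = zmap.analysis_mask.data > 0.5
    if not mask.any():
        raise ValueError("empty analysis mask")
    p_in = zmap.p_corrected.data[mask]
    reject, p_adj, _, _ = multipletests(p_in, alpha=q, method="fdr_bh")
    p_corr = np.ones(zmap.z.grid.shape)
    p_corr[mask] = p_adj
    sig = np.zeros(zmap.z.grid.shape, bool)
    sig[mask] = reject & (p_adj < p_retain)
    return ZMap(
        z=zmap.z,
        p_corrected=Volume(p_corr, zmap.z.grid),
        significance=Volume(sig.astype(float), zmap.z.grid),
        analysis_mask=zmap.analysis_mask,
        n_flagged_zero_variance=zmap.n_flagged_zero_variance,
        params={**zmap.params, "corrected": True, "q": q, "p_retain": p_retain},
    )


def run_vbm(
    healthy_maps: Sequence[Volume],
    diseased_maps: Sequence[Volume],
    analysis_mask: np.ndarray | None = None,
    fwhm_mm: float | None = None,
    q: float = 0.05,
    p_retain: float = 0.001,
    seed: int = 0,
) -> ZMap:
    """Full VBM comparison: balance group sizes, smooth, GLM, FDR.

    The larger group is subsampled (seeded, reproducible) to the size of the
    smaller so the cohorts are comparable.  ``fwhm_mm`` defaults to 2 voxels.
    """
    healthy_maps = list(healthy_maps)
    diseased_maps = list(diseased_maps)
    if min(len(healthy_maps), len(diseased_maps)) < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(seed)
    n = min(len(healthy_maps), len(diseased_maps))
    if len(healthy_maps) > n:
        keep = sorted(rng.choice(len(healthy_maps), size=n, replace=False))
        healthy_maps = [healthy_maps[i] for i in keep]
    if len(diseased_maps) > n:
        keep = sorted(rng.choice(len(diseased_maps), size=n, replace=False))
        diseased_maps = [diseased_maps[i] for i in keep]

    grid = healthy_maps[0].grid
    if fwhm_mm is None:
        fwhm_mm = 2.0 * float(min(grid.spacing))
    hs = GroupSample([smooth(m, fwhm_mm) for m in healthy_maps], "healthy")
    ds = GroupSample([smooth(m, fwhm_mm) for m in diseased_maps], "diseased")
    zmap = glm_group_test(hs, ds, mask=analysis_mask)
    zmap = fdr_threshold(zmap, q=q, p_retain=p_retain)
    zmap.params.update({"fwhm_mm": fwhm_mm, "seed": seed, "n_per_group": n})
    return zmap


def save_overlay_figures(zmap: ZMap, background: Volume, out_dir) -> list:
    """Axial and coronal overlay figures of significant z values."""
    from pathlib import Path

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    z = np.where(zmap.significance.data > 0.5, zmap.z.data, np.nan)
    shape = background.grid.shape
    views = {"axial": shape[2] // 2, "coronal": shape[1] // 2}
    paths = []
    for name, idx in views.items():
        fig, ax = plt.subplots(figsize=(5, 5))
        if name == "axial":
            bg, ov = background.data[:, :, idx].T, z[:, :, idx].T
        else:
            bg, ov = background.data[:, idx, :].T, z[:, idx, :].T
        ax.imshow(bg, cmap="gray", origin="lower")
        im = ax.imshow(ov, cmap="hot", origin="lower")
        fig.colorbar(im, ax=ax, label="z score")
        ax.set_title(f"{name} slice {idx}")
        ax.axis("off")
        path = out / f"vbm_overlay_{name}.png"
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths
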