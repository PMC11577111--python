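"""Pairwise registration engine.

Two stages, mirroring standard intensity-based pipelines for whole-body MR:

1. *Affine* (12 dof: translation, rotation, shear, scale) optimised with a
   derivative-free Powell search over a factor-2 multi-resolution pyramid —
   this absorbs global pose, size and field-of-view differences.
2. *Diffeomorphic free-form deformation*: a stationary velocity field on a
   cubic B-spline control lattice, integrated to a displacement by scaling
   and squaring, optimised coarse-to-fine by gradient descent on
   ``metric + lambda * bending_energy`` with a backtracking line search.
   The velocity magnitude is capped so each squaring-scaled step stays well
   below a voxel, a sufficient condition against folding.

Everything is deterministic: no stochastic sampling, fixed iteration
schedules, analytic B-spline gradients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field


import numpy as np
from scipy import ndimage, optimize

from .containers import AffineTransform, DisplacementField, Volume
from .lattice import VelocityLattice, bending_energy_dense
from .preprocess import BodyMask, com_align, preprocess_volume
from .transforms import (
    apply_affine_as_field,
    compose,
    compose_affine_field,
    downsample,
    integrate_velocity,
    warp_volume,
)
from .evaluation import folding_ratio

logger = logging.getLogger(__name__)

N_NMI_BINS = 64


@dataclass(frozen=True)
class RegistrationConfig:
    """Hyperparameters of both registration stages."""

    metric: str = "ncc"  # ssd | ncc | nmi
    lambda_bending: float = 1e-3
    pyramid_levels: int = 3
    control_spacing_mm: tuple[float, ...] = (32.0, 16.0, 8.0)
    max_iterations: tuple[int, ...] = (60, 60, 30)
    step_mm: float = 2.0
    convergence_tol: float = 1e-5
    squaring_steps: int = 6
    velocity_cap_voxels: float = 0.4
    affine_pyramid: tuple[int, ...] = (4, 2)
    affine_maxiter: int = 40
    init_mode: str = "com"  # com | icp

    def __post_init__(self) -> None:
        if self.metric not in ("ssd", "ncc", "nmi"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.lambda_bending < 0:
            raise ValueError("lambda_bending must be >= 0")
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if len(self.control_spacing_mm) < self.pyramid_levels:
            raise ValueError("control spacing schedule shorter than pyramid")
        if any(
            a < b
            for a, b in zip(self.control_spacing_mm, self.control_spacing_mm[1:])
        ) :
            raise ValueError("control-point spacing schedule must be non-increasing")


# ---------------------------------------------------------------------------
# dissimilarity metrics


def dissimilarity(
    fixed: Volume | np.ndarray,
    warped: Volume | np.ndarray,
    metric: str = "ncc",
    mask: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Dissimilarity between a fixed image and a warped moving image.

    Returns ``(value, gradient)`` where the gradient is taken with respect to
    the warped intensities (zero outside the mask).

    * ``ssd``: mean squared difference (0 at a perfect match).
    * ``ncc``: ``1 - normalised cross-correlation`` (0 at a perfect match,
      invariant to positive affine intensity maps of either image).
    * ``nmi``: ``1 - NMI`` with the Studholme normalised mutual information
      ``(H(F)+H(W))/H(F,W)`` from a 64-bin joint histogram with linear
      (partial-volume) binning.  NMI lies in [1, 2], so the value is
      negative and minimised at good alignment.
    """
    f = np.asarray(fixed.data if isinstance(fixed, Volume) else fixed, dtype=float)
    w = np.asarray(warped.data if isinstance(warped, Volume) else warped, dtype=float)
    if f.shape != w.shape:
        raise ValueError("fixed and warped images must share a grid")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty mask")
        fm, wm = f[mask], w[mask]
    else:
        fm, wm = f.ravel(), w.ravel()

    grad_flat = np.zeros(fm.shape, dtype=float)
    n = fm.size
    if metric == "ssd":
        diff = wm - fm
        value = float((diff**2).mean())
        grad_flat = 2.0 * diff / n
    elif metric == "ncc":
        fc = fm - fm.mean()
        wc = wm - wm.mean()
        sf = np.sqrt((fc**2).mean())
        sw = np.sqrt((wc**2).mean())
        if sf < 1e-12 or sw < 1e-12:
            value = 1.0
        else:
            ncc = float((fc * wc).mean() / (sf * sw))
            value = 1.0 - ncc
            grad_flat = -(fc / (sf * sw) - ncc * wc / sw**2) / n
    elif metric == "nmi":
        value, grad_flat = _nmi(fm, wm)
    else:
        raise ValueError(f"unknown metric {metric!r}")

    if mask is not None:
        grad = np.zeros_like(f)
        grad[mask] = grad_flat
    else:
        grad = grad_flat.reshape(f.shape)
    return value, grad


def _nmi(fm: np.ndarray, wm: np.ndarray, bins: int = N_NMI_BINS) -> tuple[float, np.ndarray]:
    """1 - NMI and its analytic gradient w.r.t. warped intensities."""
    eps = 1e-12
    n = fm.size

    def bin_coords(x):
        lo, hi = float(x.min()), float(x.max())
        width = (hi - lo) / (bins - 1) if hi > lo else 1.0
        s = (x - lo) / width
        i0 = np.clip(np.floor(s).astype(int), 0, bins - 2)
        t = np.clip(s - i0, 0.0, 1.0)
        return i0, t, width

    fi0, ft, _ = bin_coords(fm)
    wi0, wt, wwidth = bin_coords(wm)

    joint = np.zeros((bins, bins))
    for df, wf in ((0, 1 - ft), (1, ft)):
        for dw, ww in ((0, 1 - wt), (1, wt)):
            np.add.at(joint, (fi0 + df, wi0 + dw), wf * ww)
    joint /= n
    pf = joint.sum(axis=1)
    pw = joint.sum(axis=0)
    hf = float(-(pf[pf > eps] * np.log(pf[pf > eps])).sum())
    hw = float(-(pw[pw > eps] * np.log(pw[pw > eps])).sum())
    hj = float(-(joint[joint > eps] * np.log(joint[joint > eps])).sum())
    nmi = (hf + hw) / max(hj, eps)

    logj = np.log(np.maximum(joint, eps))
    logw = np.log(np.maximum(pw, eps))
    # moving a sample's w-intensity shifts mass from bin wi0 to wi0+1
    dhw = -(logw[wi0 + 1] - logw[wi0]) / (n * wwidth)
    dlogj = logj[:, wi0 + 1] - logj[:, wi0]  # (bins, n)
    dhj = -((1 - ft) * dlogj[fi0, np.arange(n)] + ft * dlogj[fi0 + 1, np.arange(n)]) / (
        n * wwidth
    )
    dnmi = (dhw * hj - (hf + hw) * dhj) / max(hj, eps) ** 2
    return 1.0 - nmi, -dnmi


# ---------------------------------------------------------------------------
# affine stage

_PARAM_SCALE = np.array([10.0] * 3 + [0.1] * 3 + [0.05] * 3 + [0.05] * 3)


def _params_to_affine(p: np.ndarray, center: np.ndarray) -> AffineTransform:
    """12 parameters -> affine about ``center``: translation(3), euler
    rotation(3, rad), log-scale(3), shear(3)."""
    t, rot, logs, shear = p[:3], p[3:6], p[6:9], p[9:12]
    cx, sx = np.cos(rot[0]), np.sin(rot[0])
    cy, sy = np.cos(rot[1]), np.sin(rot[1])
    cz, sz = np.cos(rot[2]), np.sin(rot[2])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    Sh = np.array([[1, shear[0], shear[1]], [0, 1, shear[2]], [0, 0, 1]])
    L = Rz @ Ry @ Rx @ Sh @ np.diag(np.exp(logs))
    return AffineTransform(L, center - L @ center + t)


def _affine_metric(
    fixed_level: Volume,
    moving: Volume,
    total: AffineTransform,
    metric: str,
    mask: np.ndarray | None,
) -> float:
    pts = total.apply(fixed_level.grid.coordinates())
    idx = moving.grid.to_index(pts)
    w = ndimage.map_coordinates(
        np.asarray(moving.data, dtype=float),
        np.moveaxis(idx, -1, 0),
        order=1,
        mode="constant",
        cval=0.0,
    )
    value, _ = dissimilarity(fixed_level.data, w, metric, mask)
    return value


def register_affine(
    fixed: Volume,
    moving: Volume,
    init: AffineTransform | None = None,
    config: RegistrationConfig | None = None,
    mask: np.ndarray | None = None,
) -> AffineTransform:
    """Optimise a 12-dof affine (translation, rotation, scale, shear).

    The correction is parameterised about the fixed-image centre and composed
    with ``init`` (``total = init ∘ correction``); optimisation runs Powell's
    method over the affine pyramid, coarse to fine.  The best iterate seen is
    returned, so the final metric never exceeds the initial one.
    """
    config = config or RegistrationConfig()
    init = init or AffineTransform.identity()
    center = fixed.grid.center
    p = np.zeros(12)

    for factor in config.affine_pyramid:
        fixed_l = downsample(fixed, factor)
        mask_l = None
        if mask is not None:
            mask_l = downsample(Volume(mask.astype(float), fixed.grid), factor).data > 0.5
        best = {"val": np.inf, "p": p.copy()}

        def objective(q, fixed_l=fixed_l, mask_l=mask_l, best=best):
            total = init.compose(_params_to_affine(q * _PARAM_SCALE, center))
            val = _affine_metric(fixed_l, moving, total, config.metric, mask_l)
            if val < best["val"]:
                best["val"] = val
                best["p"] = q.copy() * _PARAM_SCALE
            return val

        res = optimize.minimize(
            objective,
            p / _PARAM_SCALE,
            method="Powell",
            options={"maxiter": config.affine_maxiter, "xtol": 1e-6, "ftol": 1e-8},
        )
        p = best["p"] if best["val"] <= res.fun else res.x * _PARAM_SCALE
        logger.info("affine level (factor %d): metric %.6g", factor, best["val"])

    return init.compose(_params_to_affine(p, center))


# ---------------------------------------------------------------------------
# deformable stage


@dataclass
class FFDResult:
    """Outcome of the multi-resolution diffeomorphic FFD stage."""

    lattices: list
    field: DisplacementField  # total field (init ∘ deformable)
    deformable_field: DisplacementField
    objective_history: list = dc_field(default_factory=list)
    folding: float = float("nan")


def _cap_velocity(lat: VelocityLattice, config: RegistrationConfig) -> VelocityLattice:
    """Rescale coefficients so the scaled squaring step stays below the cap."""
    vmax = lat.dense_velocity().max_norm()
    limit = config.velocity_cap_voxels * min(lat.grid.spacing) * 2**config.squaring_steps
    if vmax > limit > 0:
        lat = lat.with_coefficients(lat.coefficients * (limit / vmax))
    return lat


def _ffd_objective(
    lat: VelocityLattice,
    fixed_l: Volume,
    moving_l: Volume,
    config: RegistrationConfig,
    mask: np.ndarray | None,
    want_grad: bool,
):
    v = lat.dense_velocity()
    u = integrate_velocity(v, config.squaring_steps)
    warped = warp_volume(moving_l, u, "linear")
    d_val, d_grad = dissimilarity(fixed_l.data, warped.data, config.metric, mask)
    if config.lambda_bending > 0:
        be, be_grad_dense = bending_energy_dense(v.data, lat.grid.spacing_arr)
    else:
        be, be_grad_dense = 0.0, None
    energy = d_val + config.lambda_bending * be
    if not want_grad:
        return energy, None
    # dD/du via chain rule; the gradient through scaling-and-squaring is
    # approximated by its small-deformation limit (the line search evaluates
    # the exact objective, so accepted steps always decrease it).
    grads = np.gradient(warped.data, *fixed_l.grid.spacing)
    g_dense = np.stack([d_grad * g for g in grads], axis=-1)
    if be_grad_dense is not None:
        g_dense = g_dense + config.lambda_bending * be_grad_dense
    return energy, lat.project_dense_gradient(g_dense)


def register_ffd(
    fixed: Volume,
    moving: Volume,
    init_field: DisplacementField | None = None,
    config: RegistrationConfig | None = None,
    mask: np.ndarray | None = None,
    init_affine: AffineTransform | None = None,
) -> FFDResult:
    """Multi-resolution diffeomorphic B-spline FFD registration.

    ``moving`` is first brought into fixed space by the initial transform
    (``init_affine``, composed exactly, or a dense ``init_field``); the
    residual deformation is modelled as a B-spline stationary velocity
    optimised coarse-to-fine.  Each level's velocity initialises the next,
    finer lattice.  Returns the per-level lattices and the total displacement
    field ``init ∘ deformable``.
    """
    config = config or RegistrationConfig()
    if init_affine is not None:
        init_field = apply_affine_as_field(init_affine, fixed.grid)
    m0 = warp_volume(moving, init_field, "linear") if init_field is not None else moving

    levels = config.pyramid_levels
    history: list[float] = []
    lattices: list[VelocityLattice] = []
    prev_velocity: DisplacementField | None = None

    for level in range(levels):
        factor = 2 ** (levels - 1 - level)
        fixed_l = downsample(fixed, factor)
        moving_l = downsample(m0, factor)
        mask_l = None
        if mask is not None:
            mask_l = downsample(Volume(mask.astype(float), fixed.grid), factor).data > 0.5
        spacing_mm = config.control_spacing_mm[level]
        if prev_velocity is None:
            lat = VelocityLattice.for_grid(fixed_l.grid, spacing_mm)
        else:
            lat = VelocityLattice.from_dense_samples(prev_velocity, spacing_mm, fixed_l.grid)
            lat = _cap_velocity(lat, config)

        energy, grad = _ffd_objective(lat, fixed_l, moving_l, config, mask_l, True)
        step = config.step_mm
        max_iter = config.max_iterations[min(level, len(config.max_iterations) - 1)]
        for it in range(max_iter):
            if grad is None or not np.all(np.isfinite(grad)):
                logger.warning("non-finite FFD gradient at level %d; aborting level", level)
                break
            gmax = float(np.abs(grad).max())
            if gmax == 0:
                break
            accepted = False
            for _ in range(10):
                cand = _cap_velocity(
                    lat.with_coefficients(lat.coefficients - (step / gmax) * grad), config
                )
                e_new, g_new = _ffd_objective(cand, fixed_l, moving_l, config, mask_l, True)
                if e_new < energy:
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                break
            rel = (energy - e_new) / max(abs(energy), 1e-12)
            lat, energy, grad = cand, e_new, g_new
            history.append(energy)
            step = min(step * 1.5, 4.0 * config.step_mm)
            if rel < config.convergence_tol:
                break
        logger.info("FFD level %d (factor %d): energy %.6g after %d iters", level, factor, energy, it + 1)
        lattices.append(lat)
        prev_velocity = lat.dense_velocity()

    v_full = lattices[-1].dense_velocity(fixed.grid)
    u_ffd = integrate_velocity(v_full, config.squaring_steps)
    if init_affine is not None:
        total = compose_affine_field(init_affine, u_ffd)
    elif init_field is not None:
        total = compose(init_field, u_ffd)
    else:
        total = u_ffd
    result = FFDResult(
        lattices=lattices,
        field=total,
        deformable_field=u_ffd,
        objective_history=history,
        folding=folding_ratio(total),
    )
    logger.info("FFD total field folding ratio: %.4g", result.folding)
    return result


# ---------------------------------------------------------------------------
# full pairwise chain


@dataclass
class TransformChain:
    """All transform stages of one pairwise registration."""

    com: AffineTransform
    affine: AffineTransform
    affine_field: DisplacementField
    ffd: FFDResult
    total: DisplacementField
    fixed_preprocessed: Volume
    moving_preprocessed: Volume
    fixed_mask: BodyMask
    moving_mask: BodyMask


def register_pair(
    fixed: Volume, moving: Volume, config: RegistrationConfig | None = None
) -> TransformChain:
    """Full pipeline for one pair: preprocess -> COM/ICP init -> affine ->
    diffeomorphic FFD.  Deterministic given inputs and config."""
    config = config or RegistrationConfig()
    fixed_pp, fixed_mask = preprocess_volume(fixed)
    moving_pp, moving_mask = preprocess_volume(moving)
    com = com_align(moving_mask, fixed_mask, mode=config.init_mode)
    affine = register_affine(fixed_pp, moving_pp, init=com, config=config)
    affine_field = apply_affine_as_field(affine, fixed.grid)
    ffd = register_ffd(fixed_pp, moving_pp, config=config, init_affine=affine)
    return TransformChain(
        com=com,
        affine=affine,
        affine_field=affine_field,
        ffd=ffd,
        total=ffd.field,
        fixed_preprocessed=fixed_pp,
        moving_preprocessed=moving_pp,
        fixed_mask=fixed_mask,
        moving_mask=moving_mask,
    )
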