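"""Inter-subject spatial normalization.

Each reconstructed volume is warped onto a smoothed reference template
(FWHM = 3 x voxel size) by a 12-DOF affine registration followed by a cubic
B-spline free-form deformation, both maximizing masked normalized
cross-correlation over a coarse-to-fine multi-resolution schedule.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, optimize

from .core import Volume
from .errors import InvalidGridError, RegistrationError, UndefinedCorrelationError
from .reconstruct import ncc
from .transforms import (
    AffineTransform3D,
    BSplineTransform3D,
    fit_coefficients_to_field,
)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # sigma = FWHM / 2.3548


def smooth_gaussian(volume: Volume, fwhm) -> Volume:
    """Mask-aware Gaussian smoothing with FWHM given in physical units (µm).

    The kernel is separable and anisotropic in voxels when the spacing is
    anisotropic.  Inside the mask a normalized convolution is used so the
    zero background does not bleed inward; outside the mask voxels stay 0.
    With no mask a plain Gaussian filter is applied.
    """
    fwhm = np.broadcast_to(np.asarray(fwhm, dtype=float), (3,))
    if np.any(fwhm < 0):
        raise ValueError("fwhm components must be >= 0")
    sigma_vox = fwhm * FWHM_TO_SIGMA / np.asarray(volume.spacing)
    if np.all(sigma_vox == 0):
        return volume.copy()
    out = volume.copy()
    if volume.mask is None:
        out.voxels = ndimage.gaussian_filter(volume.voxels.astype(float), sigma_vox)
        return out
    m = volume.mask.astype(float)
    num = ndimage.gaussian_filter(volume.voxels * m, sigma_vox)
    den = ndimage.gaussian_filter(m, sigma_vox)
    vox = np.zeros_like(num)
    inside = den > 1e-12
    vox[inside] = num[inside] / den[inside]
    vox[~volume.mask] = 0.0
    out.voxels = vox
    return out


def smooth_template(template: Volume, fwhm_factor: float = 3.0) -> Volume:
    """Smooth the reference template with FWHM = fwhm_factor x voxel size."""
    return smooth_gaussian(
        template, np.asarray(template.spacing) * fwhm_factor
    )


def _downsample_volume(volume: Volume, factor: int) -> Volume:
    """Anti-aliased downsampling by an integer factor (spacing scales up)."""
    if factor == 1:
        return volume
    sm = ndimage.gaussian_filter(volume.voxels.astype(float), 0.5 * factor)
    sl = tuple(slice(None, None, factor) for _ in range(3))
    vox = sm[sl]
    mask = None
    if volume.mask is not None:
        mask = ndimage.gaussian_filter(volume.mask.astype(float), 0.5 * factor)[sl] >= 0.5
    return Volume(vox, tuple(np.asarray(volume.spacing) * factor), mask=mask,
                  origin=volume.origin.copy())


def _warp_affine(moving: Volume, transform: AffineTransform3D, reference: Volume,
                 order: int = 1):
    """Resample ``moving`` on the reference grid (backward mapping)."""
    pts = reference.grid_coordinates().reshape(3, -1).T
    mapped = transform.apply(pts)
    idx = ((mapped - moving.origin) / np.asarray(moving.spacing)).T.reshape(
        (3,) + reference.shape
    )
    vox = ndimage.map_coordinates(moving.voxels.astype(float), idx, order=order,
                                  cval=0.0)
    mask = None
    if moving.mask is not None:
        mask = ndimage.map_coordinates(moving.mask.astype(float), idx, order=1,
                                       cval=0.0) >= 0.5
    return vox, mask


def _masked_ncc(fixed: Volume, warped_vox, warped_mask) -> float:
    joint = warped_mask if fixed.mask is None else (fixed.mask & warped_mask)
    if joint.sum() < max(64, 0.05 * (fixed.mask.sum() if fixed.mask is not None
                                     else fixed.voxels.size)):
        return -1.0
    try:
        return ncc(fixed.voxels, warped_vox, joint)
    except UndefinedCorrelationError:
        return -1.0


def _center_of_mass(volume: Volume) -> np.ndarray:
    w = np.clip(volume.voxels.astype(float), 0, None)
    if volume.mask is not None:
        w = w * volume.mask
    total = w.sum()
    if total <= 0:
        return volume.physical_center()
    idx = np.array(ndimage.center_of_mass(w))
    return volume.origin + idx * np.asarray(volume.spacing)


def _affine_value_and_grad(fixed: Volume, moving: Volume, center,
                           smooth_sigma_vox: float = 0.0):
    """Objective factory for affine registration: negative NCC of the warped
    moving volume over in-field fixed voxels, with its analytic gradient
    w.r.t. the 12 parameters (9 matrix entries + 3 translations in units of
    the mean voxel spacing).

    The zero background is part of the signal -- the brain outline drives
    scale and rotation -- so no tissue mask is applied.  Cubic interpolation
    (coefficients prefiltered once) and *no* extra pre-smoothing: smoothing
    both images before resampling biases the optimum toward contractive
    maps (resampling a smoothed image smooths it again), which measurably
    shrinks the recovered scales; the pyramid's own anti-alias filtering is
    the only blur applied.
    """
    fvox = fixed.voxels.astype(float)
    msm = moving.voxels.astype(float)
    if smooth_sigma_vox > 0:
        fvox = ndimage.gaussian_filter(fvox, smooth_sigma_vox)
        msm = ndimage.gaussian_filter(msm, smooth_sigma_vox)
    mcoef = ndimage.spline_filter(msm, order=3)
    grads = np.gradient(msm, *moving.spacing)
    gcoefs = [ndimage.spline_filter(g, order=3) for g in grads]
    pts = fixed.grid_coordinates().reshape(3, -1)
    fflat = fvox.ravel()
    msp = np.asarray(moving.spacing)[:, None]
    morig = np.asarray(moving.origin)[:, None]
    nm = np.asarray(moving.shape)[:, None] - 1
    n_total = fflat.size
    center = np.asarray(center, dtype=float)
    c = center[:, None]
    rel = pts - c
    tscale = float(np.mean(fixed.spacing))

    def value_and_grad(x):
        M = x[:9].reshape(3, 3)
        t = x[9:] * tscale
        mapped = M @ rel + c + t[:, None]
        idx = (mapped - morig) / msp
        infield = np.all((idx >= 0) & (idx <= nm), axis=0)
        if infield.sum() < max(64, 0.25 * n_total):
            return 1.0, np.zeros(12)
        warped = ndimage.map_coordinates(mcoef, idx, order=3, prefilter=False,
                                         cval=0.0)
        f = fflat[infield]
        w = warped[infield]
        fc = f - f.mean()
        wc = w - w.mean()
        sff = fc @ fc
        sww = wc @ wc
        if sff <= 0 or sww <= 0:
            return 1.0, np.zeros(12)
        sfw = fc @ wc
        denom = np.sqrt(sff * sww)
        score = sfw / denom
        dw = (fc - (sfw / sww) * wc) / denom  # d score / d warped (in-field)
        g = np.zeros((3, n_total))
        for a in range(3):
            ga = ndimage.map_coordinates(gcoefs[a], idx[:, infield], order=3,
                                         prefilter=False, cval=0.0)
            g[a, infield] = dw * ga
        grad_M = g @ rel.T            # d score / d M entries
        grad_t = g.sum(axis=1) * tscale
        grad = -np.concatenate([grad_M.ravel(), grad_t])
        return -float(score), grad

    return value_and_grad


def _crop_to_mask(volume: Volume, margin: int = 8) -> Volume:
    """Crop to the bounding box of the foreground (mask or nonzero voxels)
    plus a margin, adjusting the origin; used to shrink the metric domain."""
    fg = volume.mask if volume.mask is not None else volume.voxels > 0
    if not fg.any():
        return volume
    lo, hi = [], []
    for a in range(3):
        axes = tuple(b for b in range(3) if b != a)
        prof = fg.any(axis=axes)
        nz = np.nonzero(prof)[0]
        lo.append(max(0, nz[0] - margin))
        hi.append(min(volume.shape[a], nz[-1] + 1 + margin))
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    return Volume(
        volume.voxels[sl],
        tuple(volume.spacing),
        mask=None if volume.mask is None else volume.mask[sl],
        origin=volume.origin + np.asarray(lo) * np.asarray(volume.spacing),
    )


def register_affine_3d(
    fixed: Volume,
    moving: Volume,
    levels: tuple[int, ...] = (4, 2, 1),
    maxiter_schedule: tuple[int, ...] = (300, 200, 150),
) -> AffineTransform3D:
    """12-DOF affine registration maximizing NCC, coarse to fine.

    Initialized by center-of-mass alignment, then optimized per pyramid
    level with L-BFGS-B on an analytic NCC gradient (matrix entries and
    preconditioned translations).  The metric domain is the fixed
    foreground bounding box plus a background margin.  Deterministic.  The
    returned transform maps fixed-space physical points into moving space.
    """
    center = fixed.physical_center()
    t0 = _center_of_mass(moving) - _center_of_mass(fixed)
    fixed_c = _crop_to_mask(fixed)
    x = np.concatenate([np.eye(3).ravel(), np.zeros(3)])
    x_t_phys = t0  # carry translation in physical units between levels

    best_fun = None
    for factor, maxiter in zip(levels, maxiter_schedule):
        f = _downsample_volume(fixed_c, factor)
        m = _downsample_volume(moving, factor)
        vg = _affine_value_and_grad(f, m, center)
        tscale = float(np.mean(f.spacing))
        x[9:] = x_t_phys / tscale
        res = optimize.minimize(
            vg, x, jac=True, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-10},
        )
        x = res.x
        x_t_phys = x[9:] * tscale
        best_fun = res.fun
        if factor == levels[0] and best_fun >= 0.999:
            raise RegistrationError("affine optimizer stalled at the coarsest level")
    return AffineTransform3D(x[:9].reshape(3, 3), x_t_phys, center)


# --------------------------------------------------------------------------
# B-spline registration
# --------------------------------------------------------------------------


def _default_grid_spacing(fixed: Volume) -> np.ndarray:
    """Default control spacing: 1/8 of each axis physical extent, but never
    below 2.5 voxels (cubic support needs a few voxels per control cell)."""
    extent = (np.asarray(fixed.shape) - 1) * np.asarray(fixed.spacing)
    return np.maximum(extent / 8.0, 2.5 * np.asarray(fixed.spacing))


def _make_grid(fixed: Volume, grid_spacing) -> BSplineTransform3D:
    sp = np.asarray(grid_spacing, dtype=float)
    if np.any(sp < 2 * np.asarray(fixed.spacing)):
        raise InvalidGridError("control spacing below two voxels on some axis")
    lo = fixed.origin
    hi = fixed.origin + (np.asarray(fixed.shape) - 1) * np.asarray(fixed.spacing)
    grid = BSplineTransform3D.zeros_covering(lo, hi, sp)
    if np.any(np.asarray(grid.coefficients.shape[:3]) < 4):
        raise InvalidGridError("control grid needs >= 4 points of support per axis")
    return grid


def _ncc_and_gradient(fvals, warped, gx, gy, gz, sel):
    """NCC over the selected voxels and its gradient w.r.t. the dense
    displacement (chain rule through the sampled moving-image gradient)."""
    f = fvals[sel]
    w = warped[sel]
    fc = f - f.mean()
    wc = w - w.mean()
    sff = fc @ fc
    sww = wc @ wc
    if sff <= 0 or sww <= 0:
        return -1.0, None
    sfw = fc @ wc
    denom = np.sqrt(sff * sww)
    score = sfw / denom
    dw = (fc - (sfw / sww) * wc) / denom  # d score / d warped values
    grad = np.zeros(fvals.shape + (3,))
    grad[sel, 0] = dw * gx[sel]
    grad[sel, 1] = dw * gy[sel]
    grad[sel, 2] = dw * gz[sel]
    return float(score), grad


def register_bspline_3d(
    fixed: Volume,
    moving: Volume,
    init: AffineTransform3D | None = None,
    grid_spacing=None,
    levels: tuple[int, ...] = (2, 1),
    grid_levels: int = 2,
    maxiter: int = 100,
) -> BSplineTransform3D:
    """Cubic B-spline deformation on top of an affine initialization.

    The total map is ``p -> affine(p) + D(p)`` with ``D`` the spline
    displacement over the fixed (template) domain.  Coefficients maximize
    masked NCC via L-BFGS-B with an analytic gradient; the schedule runs an
    image pyramid (x2 then full resolution) and halves the control spacing
    once between grid levels, initializing the finer grid by a least-squares
    fit to the coarse displacement field.  Grid coarseness is the only
    regularizer.
    """
    init = init or AffineTransform3D.identity(fixed.physical_center())
    if grid_spacing is None:
        fine_sp = _default_grid_spacing(fixed)
    else:
        fine_sp = np.asarray(grid_spacing, dtype=float)
        if np.any(fine_sp < 2.0 * np.asarray(fixed.spacing)):
            raise InvalidGridError("control spacing below two voxels on some axis")
    spacings = [fine_sp * (2 ** (grid_levels - 1 - i)) for i in range(grid_levels)]
    # pair image levels with grid levels (last grid level at full resolution)
    if len(levels) < grid_levels:
        levels = tuple([levels[0]] * (grid_levels - len(levels))) + tuple(levels)
    schedule = list(zip(levels[-grid_levels:], spacings))

    grid = _make_grid(fixed, spacings[0])
    for factor, g_sp in schedule:
        if not np.allclose(g_sp, grid.grid_spacing):
            new_grid = _make_grid(fixed, g_sp)
            axes = [
                fixed.origin[a] + np.arange(fixed.shape[a]) * fixed.spacing[a]
                for a in range(3)
            ]
            dense = grid.displacement_on_grid(fixed.shape, fixed.spacing, fixed.origin)
            new_grid.coefficients = fit_coefficients_to_field(new_grid, dense, axes)
            grid = new_grid

        f = _downsample_volume(fixed, factor)
        m = _downsample_volume(moving, factor)
        axes = [f.origin[a] + np.arange(f.shape[a]) * f.spacing[a] for a in range(3)]
        Bs = grid.basis_matrices(axes)
        pts = f.grid_coordinates().reshape(3, -1).T
        affine_pts = init.apply(pts)

        # moving-image gradient in physical units, for the chain rule
        grads = np.gradient(m.voxels.astype(float), *m.spacing)
        m_mask = m.mask if m.mask is not None else np.ones(m.shape, bool)
        f_mask = f.mask if f.mask is not None else np.ones(f.shape, bool)
        fvals = f.voxels.astype(float)
        n_coef = grid.coefficients.size
        shape_c = grid.coefficients.shape

        def value_and_grad(flat):
            C = flat.reshape(shape_c)
            disp = np.einsum("xi,yj,zk,ijka->xyza", Bs[0], Bs[1], Bs[2], C,
                             optimize=True)
            mapped = affine_pts + disp.reshape(-1, 3)
            idx = ((mapped - m.origin) / np.asarray(m.spacing)).T
            warped = ndimage.map_coordinates(m.voxels.astype(float), idx, order=1,
                                             cval=0.0).reshape(f.shape)
            wmask = ndimage.map_coordinates(m_mask.astype(float), idx, order=1,
                                            cval=0.0).reshape(f.shape) >= 0.5
            sel = f_mask & wmask
            if sel.sum() < 64:
                return 1.0, np.zeros(n_coef)
            gx = ndimage.map_coordinates(grads[0], idx, order=1, cval=0.0).reshape(f.shape)
            gy = ndimage.map_coordinates(grads[1], idx, order=1, cval=0.0).reshape(f.shape)
            gz = ndimage.map_coordinates(grads[2], idx, order=1, cval=0.0).reshape(f.shape)
            score, dgrad = _ncc_and_gradient(fvals, warped, gx, gy, gz, sel)
            if dgrad is None:
                return 1.0, np.zeros(n_coef)
            gc = np.einsum("xi,yj,zk,xyza->ijka", Bs[0], Bs[1], Bs[2], dgrad,
                           optimize=True)
            return -score, -gc.ravel()

        # cap each coefficient at 0.45x the control spacing per axis: cubic
        # B-spline fields within this bound cannot fold, enforcing the
        # grid-coarseness regularization (unbounded coefficients can grow
        # to many voxels by folding tissue onto tissue for a higher NCC)
        cap = np.broadcast_to(0.45 * grid.grid_spacing, shape_c).ravel()
        res = optimize.minimize(
            value_and_grad,
            np.clip(grid.coefficients.ravel(), -cap, cap),
            jac=True,
            method="L-BFGS-B",
            bounds=list(zip(-cap, cap)),
            options={"maxiter": maxiter, "ftol": 1e-9, "gtol": 1e-8},
        )
        grid.coefficients = res.x.reshape(shape_c)
    return grid


def warp(
    volume: Volume,
    affine: AffineTransform3D | None,
    bspline: BSplineTransform3D | None,
    reference: Volume,
    order: int = 1,
) -> Volume:
    """Resample ``volume`` onto the reference grid under affine (+ B-spline).

    Backward mapping ``p -> affine(p) + D(p)``; linear interpolation for
    intensities by default (``order=3`` for cubic), nearest-neighbour
    (majority) for the mask; out-of-field voxels get value 0 and mask 0.
    """
    affine = affine or AffineTransform3D.identity(reference.physical_center())
    pts = reference.grid_coordinates().reshape(3, -1).T
    mapped = affine.apply(pts)
    if bspline is not None:
        mapped = mapped + bspline.displacement_at(pts)
    idx = ((mapped - volume.origin) / np.asarray(volume.spacing)).T.reshape(
        (3,) + reference.shape
    )
    vox = ndimage.map_coordinates(volume.voxels.astype(float), idx, order=order,
                                  cval=0.0)
    mask = None
    if volume.mask is not None:
        mask = ndimage.map_coordinates(volume.mask.astype(float), idx, order=1,
                                       cval=0.0) >= 0.5
    return Volume(vox, tuple(reference.spacing), mask=mask,
                  origin=reference.origin.copy())


def normalize_subject(
    subject: Volume,
    template: Volume,
    fwhm_factor: float = 3.0,
    grid_spacing=None,
    affine_levels: tuple[int, ...] = (4, 2, 1),
    bspline_levels: tuple[int, ...] = (2, 1),
) -> tuple[Volume, AffineTransform3D, BSplineTransform3D]:
    """Full normalization of one subject: smooth the template once, affine
    then B-spline registration, and a final warp onto the template grid."""
    ref = smooth_template(template, fwhm_factor)
    aff = register_affine_3d(ref, subject, levels=affine_levels)
    bsp = register_bspline_3d(ref, subject, init=aff, grid_spacing=grid_spacing,
                              levels=bspline_levels)
    warped = warp(subject, aff, bsp, template)
    return warped, aff, bsp
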