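"""Intra-subject 3D reconstruction.

Calibrated sections are stacked along z and then realigned sequentially:
the two central sections are registered first, then the stack is traversed
outward in both directions, each section rigidly registered (3 DOF:
in-plane translation + rotation) to its already-aligned inner neighbour.
The similarity metric is masked normalized cross-correlation, optimized at
a 4x downsampled resolution and refined at full resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .core import SectionImage, Volume
from .errors import HeterogeneousSectionsError, UndefinedCorrelationError
from .transforms import RigidTransform2D, resample_section, resample_section_mask


def stack_sections(sections: list[SectionImage], dz: float) -> Volume:
    """Stack ordered sections into a volume with inter-section spacing dz."""
    if not sections:
        raise ValueError("no sections to stack")
    shape = sections[0].shape
    spacing2d = tuple(sections[0].spacing)
    for s in sections:
        if s.shape != shape or tuple(s.spacing) != spacing2d:
            raise HeterogeneousSectionsError(
                f"section {s.index} differs in shape or spacing"
            )
    voxels = np.stack([np.asarray(s.pixels, dtype=float) for s in sections], axis=2)
    masks = [s.mask for s in sections]
    mask = (
        np.stack([m.astype(bool) for m in masks], axis=2)
        if all(m is not None for m in masks)
        else None
    )
    return Volume(voxels, (spacing2d[0], spacing2d[1], dz), mask=mask)


def ncc(a: np.ndarray, b: np.ndarray, joint_mask: np.ndarray | None = None) -> float:
    """Masked normalized cross-correlation in [-1, 1].

    Raises :class:`UndefinedCorrelationError` when either image is constant
    inside the mask (zero variance), including an empty mask.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if joint_mask is not None:
        sel = np.asarray(joint_mask, dtype=bool)
        av, bv = a[sel], b[sel]
    else:
        av, bv = a.ravel(), b.ravel()
    if av.size == 0:
        raise UndefinedCorrelationError("empty joint mask")
    ac = av - av.mean()
    bc = bv - bv.mean()
    denom = np.sqrt((ac @ ac) * (bc @ bc))
    if denom <= 0:
        raise UndefinedCorrelationError("zero variance inside the joint mask")
    return float(np.clip((ac @ bc) / denom, -1.0, 1.0))


def _downsample2d(pixels: np.ndarray, mask: np.ndarray | None, factor: int):
    """Block-average downsampling (factor x factor); mask by majority."""
    if factor == 1:
        return pixels.astype(float), mask
    n0 = pixels.shape[0] // factor * factor
    n1 = pixels.shape[1] // factor * factor
    p = pixels[:n0, :n1].reshape(n0 // factor, factor, n1 // factor, factor)
    out = p.mean(axis=(1, 3))
    m = None
    if mask is not None:
        mm = mask[:n0, :n1].reshape(n0 // factor, factor, n1 // factor, factor)
        m = mm.mean(axis=(1, 3)) >= 0.5
    return out, m


def _rigid_cost(fixed_px, moving_px, spacing, center):
    """Objective factory: negative NCC of the moving section warped by a
    rigid transform, evaluated over the whole fixed frame restricted to the
    in-field region of the warped image (cleaned sections have background 0,
    so the tissue outline itself is part of the signal); poor in-field
    coverage scores +1."""
    fixed_px = np.asarray(fixed_px, dtype=float)
    moving_coef = ndimage.spline_filter(np.asarray(moving_px, dtype=float), order=3)
    sp = np.asarray(spacing, dtype=float)
    n0, n1 = fixed_px.shape
    ii, jj = np.meshgrid(np.arange(n0), np.arange(n1), indexing="ij")
    pts = np.stack([ii.ravel() * sp[0], jj.ravel() * sp[1]], axis=1)
    min_infield = max(64, int(0.25 * fixed_px.size))

    def cost(params):
        t = RigidTransform2D(params[0], params[1], params[2], center)
        idx = (t.apply(pts) / sp).T
        infield = (
            (idx[0] >= 0) & (idx[0] <= n0 - 1) & (idx[1] >= 0) & (idx[1] <= n1 - 1)
        ).reshape(n0, n1)
        if infield.sum() < min_infield:
            return 1.0
        warped = ndimage.map_coordinates(
            moving_coef, idx.reshape(2, n0, n1), order=3, prefilter=False, cval=0.0
        )
        try:
            return -ncc(fixed_px, warped, infield)
        except UndefinedCorrelationError:
            return 1.0

    return cost


def _simplex(x0: np.ndarray, step: float) -> np.ndarray:
    """Initial Nelder-Mead simplex: x0 plus one ``step`` offset per axis
    (the default 5%-of-x0 simplex collapses when components start at 0)."""
    x0 = np.asarray(x0, dtype=float)
    simplex = np.tile(x0, (x0.size + 1, 1))
    simplex[1:] += np.eye(x0.size) * step
    return simplex


def register_rigid_2d(
    fixed: SectionImage,
    moving: SectionImage,
    init: RigidTransform2D | None = None,
    downsample: int = 4,
    refine_full: bool = True,
    search_shift: float = 250.0,
    search_angle: float = 8.0,
    smooth_sigma_px: float = 2.0,
) -> tuple[RigidTransform2D, dict]:
    """Register ``moving`` onto ``fixed`` (maximize masked NCC).

    Two stages: (1) at ``downsample``-fold reduced resolution, a
    deterministic coarse grid search over translations and angles around the
    initial transform seeds a Nelder-Mead simplex; (2) optional simplex
    refinement at full resolution.  Both stages run on mildly Gaussian
    pre-smoothed pixels (``smooth_sigma_px``), which widens the NCC basin
    and suppresses edge-pixelation bias between slightly dissimilar
    neighbouring sections.  The best of {init, identity, optimum} by
    full-resolution NCC is returned, so the result never degrades the
    starting alignment.
    """
    center = fixed.physical_center()
    init = init or RigidTransform2D.identity(center)
    spacing = tuple(fixed.spacing)
    f_px = np.asarray(fixed.pixels, dtype=float)
    m_px = np.asarray(moving.pixels, dtype=float)
    if smooth_sigma_px > 0:
        f_px = ndimage.gaussian_filter(f_px, smooth_sigma_px)
        m_px = ndimage.gaussian_filter(m_px, smooth_sigma_px)

    # --- stage 1: coarse level
    f_lo, _ = _downsample2d(f_px, None, downsample)
    m_lo, _ = _downsample2d(m_px, None, downsample)
    sp_lo = (spacing[0] * downsample, spacing[1] * downsample)
    center_lo = SectionImage(f_lo, sp_lo, 0).physical_center()
    cost_lo = _rigid_cost(f_lo, m_lo, sp_lo, center_lo)

    step = sp_lo[0]
    n_steps = int(np.ceil(search_shift / step))
    shifts = np.arange(-n_steps, n_steps + 1) * step
    ang_step = search_angle / 2 if search_angle > 0 else 1.0
    angles = np.arange(-search_angle, search_angle + 1e-9, ang_step)
    p0 = init.parameters
    best = (cost_lo(p0), p0)
    for dtx in shifts:
        for dty in shifts:
            for dth in angles:
                p = p0 + [dtx, dty, dth]
                c = cost_lo(p)
                if c < best[0]:
                    best = (c, p)
    scale = np.array([sp_lo[0], sp_lo[1], 1.0])
    res = optimize.minimize(
        lambda x: cost_lo(x * scale),
        best[1] / scale,
        method="Nelder-Mead",
        options={
            "xatol": 0.05,
            "fatol": 1e-6,
            "maxiter": 300,
            "initial_simplex": _simplex(best[1] / scale, 1.0),
        },
    )
    params = res.x * scale

    # --- stage 2: full-resolution refinement
    if refine_full:
        cost_hi = _rigid_cost(f_px, m_px, spacing, center)
        scale_hi = np.array([spacing[0], spacing[1], 0.5])
        res = optimize.minimize(
            lambda x: cost_hi(x * scale_hi),
            params / scale_hi,
            method="Nelder-Mead",
            options={
                "xatol": 0.02,
                "fatol": 1e-7,
                "maxiter": 300,
                "initial_simplex": _simplex(params / scale_hi, 1.0),
            },
        )
        params = res.x * scale_hi
    else:
        cost_hi = _rigid_cost(f_px, m_px, spacing, center)

    # never return something worse than the initial or identity transform
    candidates = [params, init.parameters, np.zeros(3)]
    costs = [cost_hi(p) for p in candidates]
    k = int(np.argmin(costs))
    best_params = candidates[k]
    report = {
        "ncc": -float(costs[k]),
        "converged": bool(res.success),
        "improved_over_init": costs[k] <= costs[1] + 1e-12,
    }
    return (
        RigidTransform2D(best_params[0], best_params[1], best_params[2], center),
        report,
    )


@dataclass
class AlignmentReport:
    """Per-adjacent-pair QC of the sequential alignment."""

    per_pair_ncc_before: list[float] = field(default_factory=list)
    per_pair_ncc_after: list[float] = field(default_factory=list)
    transforms: list[RigidTransform2D] = field(default_factory=list)
    converged_flags: list[bool] = field(default_factory=list)
    pair_indices: list[tuple[int, int]] = field(default_factory=list)

    def sort_by_section(self):
        """Order report rows by moving-section index."""
        order = np.argsort([m for _, m in self.pair_indices])
        for name in (
            "per_pair_ncc_before",
            "per_pair_ncc_after",
            "transforms",
            "converged_flags",
            "pair_indices",
        ):
            setattr(self, name, [getattr(self, name)[i] for i in order])


def _safe_pair_ncc(fixed: SectionImage, moving_px) -> float:
    try:
        return ncc(fixed.pixels, moving_px, None)
    except UndefinedCorrelationError:
        return 0.0


def align_stack_center_out(
    volume: Volume, downsample: int = 4, refine_full: bool = True,
    search_shift: float = 250.0, search_angle: float = 8.0,
) -> tuple[Volume, AlignmentReport, list[RigidTransform2D]]:
    """Center-out sequential alignment of a section stack.

    With N sections the central pair (c0 = N//2 - 1, c1 = N//2) is aligned
    first, c0 acting as the fixed anchor; the sweep then proceeds outward,
    each section registered to its already-aligned inner neighbour and
    initialized from that neighbour's final transform.  Returns the
    realigned volume, the QC report, and the per-section transforms
    (identity for the anchor).
    """
    nz = volume.shape[2]
    if nz < 2:
        raise ValueError("need at least two sections to align")
    if volume.mask is None:
        raise ValueError("stack must carry section masks")

    sections = [volume.section(k) for k in range(nz)]
    spacing2d = (volume.spacing[0], volume.spacing[1])
    c0 = nz // 2 - 1
    transforms: list[RigidTransform2D | None] = [None] * nz
    aligned: list[SectionImage | None] = [None] * nz
    transforms[c0] = RigidTransform2D.identity(sections[c0].physical_center())
    aligned[c0] = sections[c0]
    report = AlignmentReport()

    def register_to(inner: int, k: int):
        fixed = aligned[inner]
        moving = sections[k]
        before = _safe_pair_ncc(fixed, moving.pixels.astype(float))
        t, info = register_rigid_2d(
            fixed, moving, init=transforms[inner], downsample=downsample,
            refine_full=refine_full, search_shift=search_shift,
            search_angle=search_angle,
        )
        px = resample_section(moving.pixels, spacing2d, t)
        mk = resample_section_mask(moving.mask, spacing2d, t)
        transforms[k] = t
        aligned[k] = SectionImage(px, spacing2d, k, mk)
        report.per_pair_ncc_before.append(before)
        # the identity transform is among the register_rigid_2d candidates,
        # so the reported "after" NCC can never fall below "before"
        report.per_pair_ncc_after.append(info["ncc"])
        report.transforms.append(t)
        report.converged_flags.append(info["converged"])
        report.pair_indices.append((inner, k))

    for k in range(c0 + 1, nz):  # central pair first, then posterior sweep
        register_to(k - 1, k)
    for k in range(c0 - 1, -1, -1):  # anterior sweep
        register_to(k + 1, k)
    report.sort_by_section()

    out = volume.copy()
    for k in range(nz):
        out.voxels[:, :, k] = aligned[k].pixels
        out.mask[:, :, k] = aligned[k].mask
    return out, report, [t for t in transforms]


def mean_adjacent_ncc(volume: Volume) -> float:
    """Mean NCC over all adjacent section pairs (QC summary statistic)."""
    vals = []
    for k in range(volume.shape[2] - 1):
        a, b = volume.section(k), volume.section(k + 1)
        joint = a.mask & b.mask
        try:
            vals.append(ncc(a.pixels, b.pixels, joint))
        except UndefinedCorrelationError:
            continue
    return float(np.mean(vals)) if vals else 0.0
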