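"""Spatial transforms: in-plane rigid, 12-parameter affine, cubic B-spline.

All transforms map *physical* coordinates (µm) and follow the backward
(resampling) convention: warping image ``I`` by transform ``T`` produces the
image ``x -> I(T(x))``, so ``T`` maps output (fixed) space into input
(moving) space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


def _rot2(theta_deg: float) -> np.ndarray:
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s], [s, c]])


@dataclass
class RigidTransform2D:
    """In-plane rigid motion: rotation by ``theta`` about ``center``, then
    translation by ``(tx, ty)``.  ``T(p) = R(theta) (p - c) + c + t``."""

    tx: float = 0.0
    ty: float = 0.0
    theta: float = 0.0  # degrees
    center: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)

    @classmethod
    def identity(cls, center=(0.0, 0.0)) -> "RigidTransform2D":
        return cls(0.0, 0.0, 0.0, np.asarray(center, dtype=float))

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty])

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N, 2) array of physical points."""
        p = np.asarray(points, dtype=float)
        return (p - self.center) @ _rot2(self.theta).T + self.center + self.translation

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        t = _rot2(self.theta) @ other.translation + self.translation
        return RigidTransform2D(t[0], t[1], self.theta + other.theta, self.center)

    def inverse(self) -> "RigidTransform2D":
        t = -(_rot2(-self.theta) @ self.translation)
        return RigidTransform2D(t[0], t[1], -self.theta, self.center)

    @property
    def parameters(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.theta])


def resample_section(
    section_pixels: np.ndarray,
    spacing: tuple[float, float],
    transform: RigidTransform2D,
    order: int = 1,
    cval: float = 0.0,
) -> np.ndarray:
    """Resample a 2D image under a rigid transform (backward mapping).

    Output pixel at index ``i`` (physical ``p = i * spacing``) takes the value
    of the input sampled at ``transform(p)``.  Out-of-field pixels get ``cval``.
    """
    sp = np.asarray(spacing, dtype=float)
    n0, n1 = section_pixels.shape
    ii, jj = np.meshgrid(np.arange(n0), np.arange(n1), indexing="ij")
    pts = np.stack([ii.ravel() * sp[0], jj.ravel() * sp[1]], axis=1)
    mapped = transform.apply(pts) / sp
    coords = mapped.T.reshape(2, n0, n1)
    return ndimage.map_coordinates(
        np.asarray(section_pixels, dtype=float), coords, order=order, cval=cval
    )


def resample_section_mask(
    mask: np.ndarray, spacing, transform: RigidTransform2D
) -> np.ndarray:
    """Resample a binary mask (linear interpolation, threshold at 0.5)."""
    return resample_section(mask.astype(float), spacing, transform, order=1) >= 0.5


# --------------------------------------------------------------------------
# 3D affine
# --------------------------------------------------------------------------


def _euler_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Rotation matrix for extrinsic x-y-z Euler angles in degrees."""
    ax, ay, az = np.deg2rad([rx, ry, rz])
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


@dataclass
class AffineTransform3D:
    """12-DOF affine map ``T(p) = M (p - c) + c + t`` in physical space."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        if abs(np.linalg.det(self.matrix)) <= 1e-12:
            raise ValueError("affine matrix is singular")

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "AffineTransform3D":
        return cls(np.eye(3), np.zeros(3), np.asarray(center, dtype=float))

    @classmethod
    def from_params(cls, params, center) -> "AffineTransform3D":
        """Build from 12 parameters:
        ``[tx, ty, tz, rx, ry, rz (deg), sx, sy, sz, hxy, hxz, hyz]``,
        with ``M = R · H · diag(s)`` (H unit upper-triangular shear)."""
        p = np.asarray(params, dtype=float)
        if p.shape != (12,):
            raise ValueError("expected 12 affine parameters")
        R = _euler_matrix(p[3], p[4], p[5])
        H = np.array([[1, p[9], p[10]], [0, 1, p[11]], [0, 0, 1]])
        S = np.diag(p[6:9])
        return cls(R @ H @ S, p[:3].copy(), np.asarray(center, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return (p - self.center) @ self.matrix.T + self.center + self.translation

    def compose(self, other: "AffineTransform3D") -> "AffineTransform3D":
        """``self ∘ other`` expressed about ``self.center``."""
        c, t = self.center, self.translation
        co, to = other.center, other.translation
        # other(p) = Mo (p - co) + co + to ; feed into self.
        M = self.matrix @ other.matrix
        # T(p) = M (p - c) + T(c); translation = T(c) - c
        at_c = self.matrix @ (other.matrix @ (c - co) + co + to - c) + c + t
        return AffineTransform3D(M, at_c - c, c)

    def inverse(self) -> "AffineTransform3D":
        Minv = np.linalg.inv(self.matrix)
        return AffineTransform3D(Minv, -(Minv @ self.translation), self.center)

    def decompose(self) -> dict:
        """Polar decomposition diagnostics: rotation angle (deg), singular
        values (scales) and the centre displacement, for recovery checks."""
        U, s, Vt = np.linalg.svd(self.matrix)
        R = U @ Vt
        if np.linalg.det(R) < 0:  # reflectionless rotation factor
            U[:, -1] *= -1
            s = s.copy()
            R = U @ Vt
        angle = np.rad2deg(np.arccos(np.clip((np.trace(R) - 1) / 2, -1, 1)))
        return {
            "rotation_deg": float(angle),
            "scales": np.sort(s)[::-1],
            "translation": self.translation.copy(),
        }


# --------------------------------------------------------------------------
# 3D cubic B-spline free-form deformation
# --------------------------------------------------------------------------


def bspline3(u: np.ndarray) -> np.ndarray:
    """The cubic B-spline kernel (support [-2, 2], partition of unity)."""
    a = np.abs(np.asarray(u, dtype=float))
    out = np.zeros_like(a)
    m1 = a < 1
    out[m1] = (4 - 6 * a[m1] ** 2 + 3 * a[m1] ** 3) / 6
    m2 = (a >= 1) & (a < 2)
    out[m2] = (2 - a[m2]) ** 3 / 6
    return out


def basis_matrix(coords: np.ndarray, origin: float, spacing: float, n_ctrl: int) -> np.ndarray:
    """Dense 1D cubic B-spline basis: ``B[v, i] = B3((x_v - p_i)/δ)`` with
    control points ``p_i = origin + i·δ``."""
    x = (np.asarray(coords, dtype=float) - origin) / spacing
    idx = np.arange(n_ctrl)
    return bspline3(x[:, None] - idx[None, :])


@dataclass
class BSplineTransform3D:
    """Cubic B-spline displacement field added after an affine map.

    ``coefficients`` has shape ``(ni, nj, nk, 3)`` (µm displacements); control
    point ``(i, j, k)`` sits at ``control_origin + (i, j, k) * grid_spacing``.
    Zero coefficients give the identity displacement.
    """

    control_origin: np.ndarray
    grid_spacing: np.ndarray
    coefficients: np.ndarray

    def __post_init__(self):
        self.control_origin = np.asarray(self.control_origin, dtype=float)
        self.grid_spacing = np.asarray(self.grid_spacing, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 4 or self.coefficients.shape[-1] != 3:
            raise ValueError("coefficients must have shape (ni, nj, nk, 3)")
        if np.any(self.grid_spacing <= 0):
            raise ValueError("grid spacing must be positive")

    @classmethod
    def zeros_covering(cls, extent_lo, extent_hi, grid_spacing) -> "BSplineTransform3D":
        """Zero-displacement grid whose cubic support covers
        ``[extent_lo, extent_hi]`` in every axis."""
        lo = np.asarray(extent_lo, dtype=float)
        hi = np.asarray(extent_hi, dtype=float)
        sp = np.asarray(grid_spacing, dtype=float)
        # need control indices floor(x/δ)-1 .. floor(x/δ)+2 available
        first = np.floor((lo - lo) / sp).astype(int) - 1  # = -1
        n = np.ceil((hi - lo) / sp).astype(int) + 4
        origin = lo + first * sp
        return cls(origin, sp, np.zeros((n[0], n[1], n[2], 3)))

    def basis_matrices(self, axes_coords) -> list[np.ndarray]:
        """Per-axis dense basis for a separable grid of physical coords."""
        return [
            basis_matrix(axes_coords[a], self.control_origin[a],
                         self.grid_spacing[a], self.coefficients.shape[a])
            for a in range(3)
        ]

    def displacement_on_grid(self, volume_shape, spacing, origin) -> np.ndarray:
        """Dense displacement field on a voxel grid, shape ``shape + (3,)``."""
        axes = [
            np.asarray(origin)[a] + np.arange(volume_shape[a]) * np.asarray(spacing)[a]
            for a in range(3)
        ]
        Bx, By, Bz = self.basis_matrices(axes)
        return np.einsum("xi,yj,zk,ijka->xyza", Bx, By, Bz, self.coefficients,
                         optimize=True)

    def displacement_at(self, points: np.ndarray) -> np.ndarray:
        """Displacement at arbitrary (N, 3) physical points."""
        p = np.asarray(points, dtype=float)
        idx = (p - self.control_origin) / self.grid_spacing
        out = np.empty_like(p)
        for a in range(3):
            out[:, a] = ndimage.map_coordinates(
                self.coefficients[..., a], idx.T, order=3, prefilter=False,
                mode="constant", cval=0.0,
            )
        return out


def fit_coefficients_to_field(
    grid: BSplineTransform3D, field_values: np.ndarray, axes_coords
) -> np.ndarray:
    """Least-squares B-spline coefficients reproducing a dense displacement
    field sampled on a separable grid (used for grid refinement)."""
    Bs = grid.basis_matrices(axes_coords)
    pinvs = [np.linalg.pinv(B) for B in Bs]
    return np.einsum("ix,jy,kz,xyza->ijka", pinvs[0], pinvs[1], pinvs[2],
                     field_values, optimize=True)
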