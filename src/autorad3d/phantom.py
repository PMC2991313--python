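"""Synthetic autoradiography phantoms with known ground truth.

A phantom emulates the objects a real 2DG experiment produces on film: a
brain-shaped activity volume with internal structures of distinct 2DG
uptake, serial coronal sections that were mounted with small rigid
misalignments, film rendering through an invertible gray <-> activity
relation with a co-exposed standards strip, dust and overlapping-section
artifacts, and two-group studies with a regional activation effect.  Every
random draw is recorded as ground truth so each downstream stage can be
validated quantitatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .calibrate import fit_calibration
from .core import SectionImage, Volume
from .errors import InvalidSpecError
from .transforms import RigidTransform2D, resample_section, resample_section_mask

#: Default film-response standards: gray level vs activity (nCi/g).
#: Mildly convex, as ¹⁴C film response is; activity 0 maps to the film
#: background gray (10), not to gray 0.
DEFAULT_CALIBRATION_PAIRS: tuple[tuple[float, float], ...] = (
    (10.0, 0.0),
    (55.0, 35.0),
    (100.0, 75.0),
    (145.0, 125.0),
    (190.0, 190.0),
    (235.0, 280.0),
)


@dataclass
class PhantomSpec:
    """Specification of one synthetic brain.

    ``structure_levels`` lists (label, baseline activity nCi/g); the first
    entry is the surrounding brain tissue, later entries are nested internal
    structures.  Default activities are in the range of cortical 2DG uptake.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 40)
    spacing: tuple[float, float, float] = (10.0, 10.0, 20.0)  # µm
    structure_levels: tuple[tuple[str, float], ...] = (
        ("tissue", 60.0),
        ("dorsal_nucleus", 110.0),
        ("ventral_nucleus", 140.0),
    )
    noise_sd: float = 0.0  # nCi/g
    dust_rate: float = 0.0  # speckle probability per section
    overlap_rate: float = 0.0  # overlap-blob probability per section
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(int(n) < 8 for n in self.grid_shape):
            raise InvalidSpecError("grid_shape components must all be >= 8")
        if any(s <= 0 for s in self.spacing):
            raise InvalidSpecError("spacings must be strictly positive")
        acts = [a for _, a in self.structure_levels]
        if any(a <= 0 for a in acts) or len(set(acts)) != len(acts):
            raise InvalidSpecError(
                "baseline activities must be strictly positive and distinct"
            )
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Everything that was randomly drawn while making a phantom dataset."""

    per_section_transforms: list[RigidTransform2D] = field(default_factory=list)
    activation_mask: np.ndarray | None = None
    effect_size: float = 0.0
    calibration_pairs: np.ndarray = field(
        default_factory=lambda: np.asarray(DEFAULT_CALIBRATION_PAIRS)
    )

    def __post_init__(self):
        pairs = np.asarray(self.calibration_pairs, dtype=float)
        if np.any(np.diff(pairs[:, 0]) <= 0) or np.any(np.diff(pairs[:, 1]) <= 0):
            raise InvalidSpecError("calibration pairs must be strictly monotone")
        self.calibration_pairs = pairs

    def standards_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.calibration_pairs, columns=["gray", "nci_per_g"]
        )


def _template_labels(U: np.ndarray, V: np.ndarray, spec: PhantomSpec,
                     axes_jitter=(1.0, 1.0),
                     struct_scales=(1.0, 1.0)) -> np.ndarray:
    """In-plane label pattern in normalized coordinates (full scale).

    Like a real coronal section the pattern is bilaterally symmetric about
    the midline (V = 0) but dorsoventrally asymmetric: the outline is an
    ellipse broadened on the dorsal side, and the nested structures sit on
    the midline at distinct dorsoventral positions with unequal in-plane
    anisotropy, so in-plane rotation is identifiable from any section.
    """
    ax = 0.30 * axes_jitter[0]
    ay = 0.24 * axes_jitter[1]
    labels = np.zeros(U.shape, dtype=np.int16)
    axx = ax * (1.0 + 0.10 * np.tanh(4 * U))
    labels[(U / axx) ** 2 + (V / ay) ** 2 <= 1.0] = 1
    # structure 2: dorsal midline blob; structure 3: bilateral pair of
    # lateral blobs (hippocampus-like), which pins in-plane rotation
    regions = [
        [((0.10, 0.0), (0.095, 0.080))],
        [((-0.06, 0.105), (0.065, 0.055)), ((-0.06, -0.105), (0.065, 0.055))],
    ]
    for s, blobs in enumerate(regions, start=2):
        if s - 2 >= len(spec.structure_levels) - 1:
            break
        g = np.asarray(struct_scales[s - 2], dtype=float)  # scalar or per-point
        for c, r in blobs:
            inside = (
                ((U - c[0]) / (r[0] * g)) ** 2 + ((V - c[1]) / (r[1] * g)) ** 2
            ) <= 1.0
            labels[inside & (labels >= 1)] = s
    return labels


def _template_centroid(spec: PhantomSpec, axes_jitter=(1.0, 1.0)):
    """Centroid of the full-scale template pattern, in normalized units."""
    nx, ny = spec.grid_shape[:2]
    x = (np.arange(nx) - (nx - 1) / 2) / nx
    y = (np.arange(ny) - (ny - 1) / 2) / ny
    X2, Y2 = np.meshgrid(x, y, indexing="ij")
    base = _template_labels(X2, Y2, spec, axes_jitter)
    m = base > 0
    return float(X2[m].mean()), float(Y2[m].mean())


def _labels_at(spec: PhantomSpec, Xn, Yn, Zn, axes_jitter=(1.0, 1.0)) -> np.ndarray:
    """Continuous label function at normalized coordinates.

    ``Xn, Yn`` are in units of the grid extent, centred on 0; ``Zn`` runs
    over [0, 1] inside the brain (label 0 outside).  Each z-plane is the 2D
    template concentrically scaled (about the template's own centroid) by a
    sinusoidal z-taper — full cross-section in the middle, ~55% linear size
    at both ends.  Scaling about the centroid keeps anatomical change
    between adjacent sections a pure small zoom, so slice-to-slice rigid
    alignment has a well-defined ground truth.  The nested structures wax
    and wane slowly along z (always present, radius varying by +-20%),
    which together with the taper makes the anteroposterior scale
    identifiable for 3D registration.
    """
    Xn = np.asarray(Xn, dtype=float)
    Yn = np.asarray(Yn, dtype=float)
    Zn = np.asarray(Zn, dtype=float)
    cx, cy = _template_centroid(spec, axes_jitter)
    in_z = (Zn >= 0.0) & (Zn <= 1.0)
    zc = np.clip(Zn, 0.0, 1.0)
    taper = 0.55 + 0.45 * np.sin(np.pi * zc)
    s2 = 0.8 + 0.2 * np.sin(np.pi * zc + 0.4)
    s3 = 0.8 + 0.2 * np.cos(np.pi * zc)
    U = cx + (Xn - cx) / taper
    V = cy + (Yn - cy) / taper
    labels = _template_labels(U, V, spec, axes_jitter, struct_scales=(s2, s3))
    labels[~in_z] = 0
    return labels


def _ellipsoid_labels(spec: PhantomSpec, axes_jitter=(1.0, 1.0),
                      affine=None) -> np.ndarray:
    """Label volume on the spec grid: 0 outside, 1 tissue, 2.. nested.

    With ``affine`` given (an :class:`AffineTransform3D` in physical µm
    coordinates), the labels are evaluated analytically at the transformed
    coordinates — an exactly warped brain with no resampling involved.
    """
    nx, ny, nz = spec.grid_shape
    sp = np.asarray(spec.spacing)
    x = np.arange(nx) * sp[0]
    y = np.arange(ny) * sp[1]
    z = np.arange(nz) * sp[2]
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    if affine is not None:
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
        X, Y, Z = (a.reshape(X.shape) for a in affine.apply(pts).T)
    Xn = (X / sp[0] - (nx - 1) / 2) / nx
    Yn = (Y / sp[1] - (ny - 1) / 2) / ny
    Zn = (Z / sp[2] + 0.5) / nz
    return _labels_at(spec, Xn, Yn, Zn, axes_jitter)


def _soft_weights(spec: PhantomSpec, Xn, Yn, Zn, axes_jitter=(1.0, 1.0),
                  edge_um: float = 8.0):
    """Partial-volume weights of the brain and each nested structure at
    normalized coordinates (continuous, rotation-equivariant rendering).

    Each boundary is a logistic profile of approximate signed physical
    distance with half-width ``edge_um``, emulating film blur and the
    partial-volume averaging of digitization; hard thresholding these
    weights at 0.5 reproduces the label geometry of :func:`_labels_at`.
    """
    Xn = np.asarray(Xn, dtype=float)
    Yn = np.asarray(Yn, dtype=float)
    Zn = np.asarray(Zn, dtype=float)
    cx, cy = _template_centroid(spec, axes_jitter)
    in_z = (Zn >= 0.0) & (Zn <= 1.0)
    zc = np.clip(Zn, 0.0, 1.0)
    taper = 0.55 + 0.45 * np.sin(np.pi * zc)
    s2 = 0.8 + 0.2 * np.sin(np.pi * zc + 0.4)
    s3 = 0.8 + 0.2 * np.cos(np.pi * zc)
    U = cx + (Xn - cx) / taper
    V = cy + (Yn - cy) / taper
    extent = spec.grid_shape[0] * spec.spacing[0]  # µm per normalized unit

    def ell(cu, cv, ru, rv):
        e = np.sqrt(((U - cu) / ru) ** 2 + ((V - cv) / rv) ** 2)
        r_phys = taper * np.sqrt(ru * rv) * extent
        d = (1.0 - e) * r_phys  # approximate signed distance, µm
        return 0.5 * (1.0 + np.tanh(d / edge_um))

    ax = 0.30 * axes_jitter[0]
    ay = 0.24 * axes_jitter[1]
    axx = ax * (1.0 + 0.10 * np.tanh(4 * U))
    # soft anteroposterior cap: uptake fades over the first/last sections,
    # giving the brain a real z-boundary (pins the anteroposterior scale in
    # 3D registration; a per-section intensity scale is invisible to the
    # NCC-based slice-to-slice alignment)
    length_z = spec.grid_shape[2] * spec.spacing[2]
    d_end = np.minimum(Zn, 1.0 - Zn) * length_z  # µm to the nearer z-end
    w_cap = 0.5 * (1.0 + np.tanh((d_end - 5.0) / 12.0))
    w_brain = ell(0.0, 0.0, axx, ay) * in_z * w_cap
    weights = []
    n_structs = len(spec.structure_levels) - 1
    if n_structs >= 1:
        weights.append(ell(0.10, 0.0, 0.095 * s2, 0.080 * s2))
    if n_structs >= 2:
        weights.append(np.maximum(ell(-0.06, 0.105, 0.065 * s3, 0.055 * s3),
                                  ell(-0.06, -0.105, 0.065 * s3, 0.055 * s3)))
    return w_brain, weights


def make_phantom_volume(
    spec: PhantomSpec,
    axes_jitter=(1.0, 1.0),
    level_scales: np.ndarray | None = None,
    blend_sigma: float = 8.0,  # boundary half-width, µm
    affine=None,
) -> Volume:
    """Build the activity volume of one synthetic brain.

    All region boundaries are rendered with a smooth partial-volume edge
    profile (half-width ``blend_sigma`` µm, isotropic in physical space),
    so interior voxel values are the baseline activities plus convex blends
    between them and the brain rim rolls off toward the background —
    mimicking film blur at the 10 µm digitization pitch.  With ``affine``
    given, the brain is rendered analytically under that transform (for
    registration ground truth; no resampling).  Deterministic given
    ``spec.seed``.
    """
    nx, ny, nz = spec.grid_shape
    sp = np.asarray(spec.spacing)
    x = np.arange(nx) * sp[0]
    y = np.arange(ny) * sp[1]
    z = np.arange(nz) * sp[2]
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    if affine is not None:
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
        X, Y, Z = (a.reshape(X.shape) for a in affine.apply(pts).T)
    Xn = (X / sp[0] - (nx - 1) / 2) / nx
    Yn = (Y / sp[1] - (ny - 1) / 2) / ny
    Zn = (Z / sp[2] + 0.5) / nz
    w_brain, weights = _soft_weights(spec, Xn, Yn, Zn, axes_jitter,
                                     edge_um=blend_sigma)
    acts = np.array([a for _, a in spec.structure_levels], dtype=float)
    if level_scales is not None:
        acts = acts * np.asarray(level_scales, dtype=float)
    interior = np.full(spec.grid_shape, acts[0], dtype=float)
    for w, a in zip(weights, acts[1:]):
        interior += w * (a - acts[0])
    activity = w_brain * interior
    mask = w_brain > 0.5
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        activity[mask] += rng.normal(0.0, spec.noise_sd, int(mask.sum()))
    return Volume(activity, spec.spacing, mask=mask)


def structure_mask(spec: PhantomSpec, structure: int, axes_jitter=(1.0, 1.0)) -> np.ndarray:
    """Binary mask of one labelled region (1 = tissue, 2.. = nested)."""
    return _ellipsoid_labels(spec, axes_jitter) == structure


def slice_and_perturb(
    volume: Volume,
    max_shift: float,
    max_angle: float,
    seed: int,
    truth: GroundTruth | None = None,
) -> tuple[list[SectionImage], GroundTruth]:
    """Cut the volume into sections and mount each with a random rigid error.

    Each z-plane is resampled under an independent rigid transform with
    tx, ty ~ U(-max_shift, max_shift) µm and theta ~ U(-max_angle,
    max_angle) degrees about the section centre.  The drawn transforms are
    recorded in the returned :class:`GroundTruth`; resampling a section with
    the recorded *inverse* recovers the original plane.
    """
    if max_shift < 0 or max_angle < 0:
        raise ValueError("max_shift and max_angle must be >= 0")
    rng = np.random.default_rng(seed)
    truth = truth or GroundTruth()
    truth.per_section_transforms = []
    sections: list[SectionImage] = []
    spacing2d = (volume.spacing[0], volume.spacing[1])
    nz = volume.shape[2]
    for k in range(nz):
        plane = volume.section(k)
        tx, ty = rng.uniform(-max_shift, max_shift, 2)
        theta = rng.uniform(-max_angle, max_angle)
        if max_shift == 0 and max_angle == 0:
            tx = ty = theta = 0.0
        t = RigidTransform2D(tx, ty, theta, plane.physical_center())
        if tx == 0 and ty == 0 and theta == 0:
            pixels, mask = plane.pixels.astype(float), plane.mask
        else:
            pixels = resample_section(plane.pixels, spacing2d, t, order=3)
            mask = (
                resample_section_mask(plane.mask, spacing2d, t)
                if plane.mask is not None
                else None
            )
        truth.per_section_transforms.append(t)
        sections.append(SectionImage(pixels, spacing2d, k, mask))
    return sections, truth


def _place_disjoint(rng, shape, tissue: np.ndarray, blob: np.ndarray, margin: int):
    """Random top-left corner where ``blob`` fits without touching tissue
    (within ``margin`` pixels); None if no spot is found in 50 tries."""
    grown = ndimage.binary_dilation(tissue, iterations=margin) if margin else tissue
    bh, bw = blob.shape
    for _ in range(50):
        i = int(rng.integers(0, shape[0] - bh + 1))
        j = int(rng.integers(0, shape[1] - bw + 1))
        if not np.any(grown[i : i + bh, j : j + bw] & blob):
            return i, j
    return None


@dataclass
class FilmRender:
    """Output of :func:`render_film`."""

    sections: list[SectionImage]  # 8-bit gray sections
    standards: pd.DataFrame  # columns gray, nci_per_g
    clamp_counts: list[int]  # out-of-calibration-range pixels per section


def render_film(
    sections: list[SectionImage],
    truth: GroundTruth,
    dust_rate: float = 0.0,
    overlap_rate: float = 0.0,
    seed: int = 0,
) -> FilmRender:
    """Render activity sections to 8-bit film scans.

    Activities are pushed through the *inverse* of the ground-truth
    gray->activity spline, quantized round-half-up to 0..255, and clamped at
    the calibration range (film saturation); the number of clamped pixels is
    reported per section.  Dust speckles (small bright blobs disjoint from
    tissue) and overlap blobs (a shifted copy of a tissue patch, disjoint
    from the section) are added at the given per-section probabilities.
    """
    rng = np.random.default_rng(seed)
    curve = fit_calibration(truth.standards_table())
    a_lo, a_hi = curve(np.asarray(curve.valid_range))
    out: list[SectionImage] = []
    clamp_counts: list[int] = []
    for sec in sections:
        act = np.asarray(sec.pixels, dtype=float)
        clamped = int(np.count_nonzero((act < a_lo) | (act > a_hi)))
        gray = curve.inverse(np.clip(act, a_lo, a_hi))
        gray8 = np.clip(np.floor(gray + 0.5), 0, 255).astype(np.uint8)

        tissue = sec.mask if sec.mask is not None else gray8 > curve.valid_range[0]
        if rng.uniform() < dust_rate:
            r = int(rng.integers(1, 3))
            from skimage.morphology import disk

            blob = disk(r).astype(bool)
            spot = _place_disjoint(rng, gray8.shape, tissue, blob, margin=3)
            if spot is not None:
                i, j = spot
                region = gray8[i : i + blob.shape[0], j : j + blob.shape[1]]
                # bright against the film background, but not so extreme
                # that the speckle forms its own Otsu class on dim sections
                region[blob] = 150
        if rng.uniform() < overlap_rate and np.any(tissue):
            ii, jj = np.nonzero(tissue)
            sl = (slice(ii.min(), ii.max() + 1), slice(jj.min(), jj.max() + 1))
            patch_mask = tissue[sl].copy()
            patch_vals = gray8[sl].copy()
            # keep a fragment (~40% of the bounding box) as the stray section
            ph = max(2, patch_mask.shape[0] // 2)
            pw = max(2, patch_mask.shape[1] // 2)
            patch_mask = patch_mask[:ph, :pw]
            patch_vals = patch_vals[:ph, :pw]
            if np.any(patch_mask):
                spot = _place_disjoint(rng, gray8.shape, tissue, patch_mask, margin=2)
                if spot is not None:
                    i, j = spot
                    region = gray8[i : i + ph, j : j + pw]
                    region[patch_mask] = patch_vals[patch_mask]
        out.append(SectionImage(gray8, sec.spacing, sec.index))
        clamp_counts.append(clamped)
    return FilmRender(out, truth.standards_table(), clamp_counts)


@dataclass
class Subject:
    """One synthetic animal of a group study."""

    subject_id: str
    group: str  # "A" or "B"
    volume: Volume  # ground-truth activity volume (common grid)
    sections: list[SectionImage]  # rendered 8-bit film scans
    standards: pd.DataFrame
    truth: GroundTruth


@dataclass
class GroupStudy:
    """A two-group synthetic study with a known regional activation."""

    subjects: list[Subject]
    activation_mask: np.ndarray
    effect_size: float
    spec: PhantomSpec


def default_effect_region(spec: PhantomSpec) -> np.ndarray:
    """Default activation region: the dorsal nucleus (structure label 2)."""
    return structure_mask(spec, 2)


def make_group_study(
    spec: PhantomSpec,
    n_per_group: int,
    effect_region: np.ndarray | None = None,
    effect_size: float = 0.10,
    seed: int = 0,
    max_shift: float = 100.0,
    max_angle: float = 5.0,
    subject_sd: float = 0.03,
) -> GroupStudy:
    """Generate ``2 * n_per_group`` subjects with a group-B activation.

    Each subject is an independently jittered phantom: in-plane axes ~ N(1,
    subject_sd/2) (shape variability) and a smooth multiplicative uptake
    field 1 + f with sd(f) = subject_sd and ~10-voxel correlation length
    (regional biological variability; global film/exposure scale is what
    the co-exposed standards calibration removes, so it is not simulated).
    Subjects are sliced with random mounting errors and rendered to film.
    Group B activity is multiplied by ``1 + effect_size`` inside
    ``effect_region`` before sectioning.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    effect_region = (
        default_effect_region(spec) if effect_region is None else effect_region
    )
    rng = np.random.default_rng(seed)
    subjects: list[Subject] = []
    for g, group in enumerate(["A", "B"]):
        for i in range(n_per_group):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            sub_rng = np.random.default_rng(sub_seed)
            axes_jitter = 1.0 + sub_rng.normal(0, subject_sd / 2, 2)
            sub_spec = PhantomSpec(
                grid_shape=spec.grid_shape,
                spacing=spec.spacing,
                structure_levels=spec.structure_levels,
                noise_sd=spec.noise_sd,
                seed=sub_seed,
            )
            vol = make_phantom_volume(sub_spec, axes_jitter)
            if subject_sd > 0:
                field = ndimage.gaussian_filter(
                    sub_rng.standard_normal(spec.grid_shape), (10.0, 10.0, 5.0)
                )
                field *= subject_sd / field.std()
                vol.voxels *= 1.0 + field
            if group == "B" and effect_size != 0.0:
                vol.voxels[effect_region] *= 1.0 + effect_size
            truth = GroundTruth(
                activation_mask=effect_region, effect_size=effect_size
            )
            secs, truth = slice_and_perturb(
                vol, max_shift, max_angle, seed=sub_seed + 1, truth=truth
            )
            film = render_film(
                secs, truth, spec.dust_rate, spec.overlap_rate, seed=sub_seed + 2
            )
            subjects.append(
                Subject(
                    subject_id=f"{group}{i:02d}",
                    group=group,
                    volume=vol,
                    sections=film.sections,
                    standards=film.standards,
                    truth=truth,
                )
            )
    return GroupStudy(subjects, effect_region, effect_size, spec)
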