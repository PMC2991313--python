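"""Section cleaning: Otsu thresholding, morphological opening, largest
connected component.

The cleaning chain separates brain tissue from film background and removes
the two classic film artifacts — dust speckles and overlapping neighbouring
sections — before calibration and stacking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .core import SectionImage
from .errors import DegenerateHistogramError, EmptyMaskError


@dataclass
class CleaningParams:
    """Parameters of the section-cleaning chain.

    opening_radius
        Radius of the disk structuring element, in µm (default 50 µm,
        i.e. 5 pixels at the 10 µm digitization pitch).
    min_component_pixels
        Components smaller than this never qualify as tissue.
    tissue_bright
        Polarity flag: True when tissue has higher gray values than the
        film background (the default for digitized uptake images).
    """

    opening_radius: float = 50.0
    min_component_pixels: int = 1
    tissue_bright: bool = True

    def __post_init__(self):
        if self.opening_radius < 0:
            raise ValueError("opening_radius must be >= 0")
        if self.min_component_pixels < 1:
            raise ValueError("min_component_pixels must be >= 1")


def otsu_threshold(histogram: np.ndarray) -> int:
    """Otsu's optimal threshold from a 256-bin gray-level histogram.

    Returns the integer ``t`` maximizing the between-class variance
    ``σ²_B(t) = ω0 ω1 (μ0 − μ1)²`` where class 0 is ``gray <= t`` and class 1
    is ``gray > t``.  Ties are broken toward the lowest ``t``.
    """
    h = np.asarray(histogram, dtype=float)
    if h.ndim != 1 or h.size != 256:
        raise ValueError("histogram must be a 256-bin count vector")
    if np.any(h < 0):
        raise ValueError("histogram counts must be non-negative")
    if np.count_nonzero(h) < 2:
        raise DegenerateHistogramError("histogram has fewer than two occupied bins")

    total = h.sum()
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(h)[:-1]                    # mass of class 0 for t = 0..254
    w1 = total - w0
    m0 = np.cumsum(h * levels)[:-1]
    mu_total = (h * levels).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        mean0 = m0 / w0
        mean1 = (mu_total - m0) / w1
        sigma_b = w0 / total * w1 / total * (mean0 - mean1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    return int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximizer


def _binarize(section: SectionImage, params: CleaningParams) -> np.ndarray:
    pixels = np.asarray(section.pixels)
    hist = np.bincount(pixels.astype(np.uint8).ravel(), minlength=256)
    t = otsu_threshold(hist)
    if params.tissue_bright:
        return pixels > t
    return pixels <= t


def clean_section(section: SectionImage, params: CleaningParams | None = None) -> SectionImage:
    """Clean one section: Otsu binarization, disk opening, largest
    8-connected component; background pixels are set to 0 and the tissue
    mask is stored on the returned section."""
    params = params or CleaningParams()
    binary = _binarize(section, params)

    radius_px = int(round(params.opening_radius / min(section.spacing)))
    if radius_px > 0:
        binary = ndimage.binary_opening(binary, structure=morphology.disk(radius_px))

    labels = measure.label(binary, connectivity=2)  # 8-connectivity in 2D
    if labels.max() == 0:
        raise EmptyMaskError(section.index)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    if sizes.max() < params.min_component_pixels:
        raise EmptyMaskError(
            section.index,
            f"largest component below min_component_pixels in section {section.index}",
        )
    mask = labels == np.argmax(sizes)

    cleaned = section.pixels.copy()
    cleaned[~mask] = 0
    return SectionImage(cleaned, section.spacing, section.index, mask)


def clean_subject(
    sections: list[SectionImage], params: CleaningParams | None = None
) -> list[SectionImage]:
    """Clean every section of a subject, preserving order and indices.

    Aborts with a single error listing all failing section indices so a bad
    film region is reported in one pass.
    """
    if not sections:
        raise ValueError("no sections to clean")
    out: list[SectionImage] = []
    failures: list[int] = []
    for sec in sections:
        try:
            out.append(clean_section(sec, params))
        except (EmptyMaskError, DegenerateHistogramError):
            failures.append(sec.index)
    if failures:
        raise EmptyMaskError(
            failures[0], f"cleaning failed for section indices {failures}"
        )
    return out
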