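"""Core in-memory containers: 2D sections and 3D volumes.

Conventions
-----------
* Physical units are micrometres (µm) everywhere inside the package; the
  NIfTI writer converts to millimetres at the file boundary.
* Arrays are indexed ``[i, j]`` (sections) and ``[i, j, k]`` (volumes), with
  the world coordinate of index ``(i, j, k)`` equal to
  ``origin + (i*dx, j*dy, k*dz)``.  Sections are stacked along the last
  axis, ordered anterior -> posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SectionImage:
    """One digitized coronal section.

    ``pixels`` holds either 8-bit gray levels (raw film scan) or calibrated
    activities in nCi/g (after calibration); ``mask`` marks tissue.
    """

    pixels: np.ndarray
    spacing: tuple[float, float]
    index: int
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("section pixels must be 2D")
        if len(self.spacing) != 2 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be two strictly positive values")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape:
                raise ValueError("mask shape must match pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def physical_center(self) -> np.ndarray:
        """Physical coordinates of the image centre (rotation centre)."""
        n = np.asarray(self.pixels.shape, dtype=float)
        return (n - 1.0) / 2.0 * np.asarray(self.spacing, dtype=float)

    def copy(self) -> "SectionImage":
        return SectionImage(
            pixels=self.pixels.copy(),
            spacing=tuple(self.spacing),
            index=self.index,
            mask=None if self.mask is None else self.mask.copy(),
        )


@dataclass
class Volume:
    """A 3D activity volume with anisotropic spacing and a tissue mask."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    mask: np.ndarray | None = None
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("volume voxels must be 3D")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive values")
        self.origin = np.asarray(self.origin, dtype=float)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.voxels.shape:
                raise ValueError("mask shape must match voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def world(self, index) -> np.ndarray:
        """World coordinate of a voxel index (µm)."""
        return self.origin + np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def physical_center(self) -> np.ndarray:
        n = np.asarray(self.voxels.shape, dtype=float)
        return self.origin + (n - 1.0) / 2.0 * np.asarray(self.spacing)

    def grid_coordinates(self) -> np.ndarray:
        """World coordinates of every voxel, shaped ``(3,) + shape``."""
        axes = [
            self.origin[a] + np.arange(self.voxels.shape[a]) * self.spacing[a]
            for a in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=0)

    def section(self, k: int) -> SectionImage:
        """Extract slice ``k`` as a SectionImage (shares no memory)."""
        return SectionImage(
            pixels=self.voxels[:, :, k].copy(),
            spacing=(self.spacing[0], self.spacing[1]),
            index=k,
            mask=None if self.mask is None else self.mask[:, :, k].copy(),
        )

    def copy(self) -> "Volume":
        return Volume(
            voxels=self.voxels.copy(),
            spacing=tuple(self.spacing),
            mask=None if self.mask is None else self.mask.copy(),
            origin=self.origin.copy(),
        )
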