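"""File I/O: section TIFFs, standards CSVs, NIfTI / MetaImage volumes.

Sections are single-page grayscale TIFFs named ``<subject>_s###.tif`` and
ordered by the three-digit index (anterior -> posterior).  Volumes go to
NIfTI-1 (spacing stored in mm per that format's convention) or MetaImage.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile

from .core import SectionImage, Volume
from .errors import ConfigError

_SECTION_RE = re.compile(r"^(?P<subject>.+)_s(?P<index>\d{3})\.tif$")
_MASK_RE = re.compile(r"^(?P<subject>.+)_m(?P<index>\d{3})\.tif$")

UM_PER_MM = 1000.0


def write_sections(
    sections: list[SectionImage], directory, subject: str, write_masks: bool = False
) -> list[Path]:
    """Write sections as ``<subject>_s###.tif`` (and masks as ``_m###``)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for sec in sections:
        px = np.asarray(sec.pixels)
        path = directory / f"{subject}_s{sec.index:03d}.tif"
        # resolution tags: pixels per centimetre
        res = (1e4 / sec.spacing[0], 1e4 / sec.spacing[1])
        tifffile.imwrite(path, px, resolution=res, resolutionunit="CENTIMETER")
        paths.append(path)
        if write_masks and sec.mask is not None:
            tifffile.imwrite(
                directory / f"{subject}_m{sec.index:03d}.tif",
                (sec.mask.astype(np.uint8) * 255),
            )
    return paths


def read_sections(
    directory,
    spacing: tuple[float, float] = (10.0, 10.0),
    subject: str | None = None,
    require_uint8: bool = True,
    with_masks: bool = False,
) -> list[SectionImage]:
    """Read a directory of ``*_s###.tif`` sections, sorted by index.

    Indices must be contiguous from 0 with no duplicates.  When TIFF
    resolution tags are present and disagree with ``spacing`` a warning is
    issued and the configured spacing wins.
    """
    directory = Path(directory)
    found: dict[int, Path] = {}
    for path in sorted(directory.iterdir()):
        m = _SECTION_RE.match(path.name)
        if not m:
            continue
        if subject is not None and m.group("subject") != subject:
            continue
        idx = int(m.group("index"))
        if idx in found:
            raise ConfigError(f"duplicate section index {idx} in {directory}")
        found[idx] = path
    if not found:
        raise ConfigError(f"no section TIFFs found in {directory}")
    indices = sorted(found)
    expected = list(range(len(indices)))
    if indices != expected:
        missing = sorted(set(expected) - set(indices))
        raise ConfigError(f"section indices not contiguous from 0; missing {missing}")

    sections = []
    for idx in indices:
        path = found[idx]
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            arr = page.asarray()
            res = page.tags.get("XResolution")
            if res is not None:
                num, den = res.value
                if num and den and (num, den) != (1, 1):
                    px_um = den / num * 1e4  # resolution tags are per-cm here
                    if abs(px_um - spacing[0]) > 0.5:
                        warnings.warn(
                            f"{path.name}: TIFF resolution tag ({px_um:.1f} µm) "
                            f"disagrees with configured spacing {spacing[0]} µm; "
                            "using the configuration",
                            stacklevel=2,
                        )
        if require_uint8 and (arr.dtype != np.uint8 or arr.ndim != 2):
            raise ConfigError(
                f"{path.name}: expected single-channel 8-bit TIFF, "
                f"got dtype {arr.dtype}, ndim {arr.ndim}"
            )
        mask = None
        if with_masks:
            mpath = path.with_name(path.name.replace("_s", "_m", 1))
            if mpath.exists():
                mask = tifffile.imread(mpath) > 0
        sections.append(SectionImage(arr, spacing, idx, mask))
    return sections


def read_standards(path) -> pd.DataFrame:
    """Read a standards CSV with header ``gray,nci_per_g``."""
    df = pd.read_csv(path)
    if not {"gray", "nci_per_g"}.issubset(df.columns):
        raise ConfigError(f"{path}: standards CSV needs columns gray,nci_per_g")
    return df


def write_standards(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_volume(volume: Volume, path, fmt: str | None = None) -> Path:
    """Write a volume to NIfTI-1 (.nii/.nii.gz) or MetaImage (.mha/.mhd).

    Spacing is converted µm -> mm for both formats.  Voxels are written
    bit-exactly (float64 for activity volumes); the mask, if any, travels in
    a sibling file with suffix ``_mask``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = fmt or ("metaimage" if path.suffix in {".mha", ".mhd"} else "nifti")
    spacing_mm = np.asarray(volume.spacing) / UM_PER_MM
    origin_mm = volume.origin / UM_PER_MM
    if fmt == "nifti":
        affine = np.diag(list(spacing_mm) + [1.0])
        affine[:3, 3] = origin_mm
        img = nib.Nifti1Image(np.asarray(volume.voxels), affine)
        img.header.set_zooms(spacing_mm)
        nib.save(img, path)
    elif fmt == "metaimage":
        img = sitk.GetImageFromArray(np.ascontiguousarray(
            np.transpose(np.asarray(volume.voxels), (2, 1, 0))))
        img.SetSpacing(tuple(spacing_mm))
        img.SetOrigin(tuple(origin_mm))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unknown volume format {fmt!r}")
    if volume.mask is not None:
        mask_path = _mask_path(path)
        mvol = Volume(volume.mask.astype(np.uint8), volume.spacing,
                      origin=volume.origin)
        write_volume(mvol, mask_path, fmt)
    return path


def _mask_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii", ".mha", ".mhd"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + "_mask" + suffix)
    raise ValueError(f"unrecognized volume suffix in {name}")


def read_volume(path, with_mask: bool = True) -> Volume:
    """Read a NIfTI or MetaImage volume written by :func:`write_volume`."""
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(path)
        vox = np.asarray(img.dataobj)
        spacing_mm = img.header.get_zooms()[:3]
        origin_mm = img.affine[:3, 3]
    else:
        img = sitk.ReadImage(str(path))
        vox = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
        spacing_mm = img.GetSpacing()
        origin_mm = np.asarray(img.GetOrigin())
    mask = None
    if with_mask:
        mpath = _mask_path(path)
        if mpath.exists():
            mask = read_volume(mpath, with_mask=False).voxels > 0
    return Volume(
        vox,
        tuple(np.asarray(spacing_mm, dtype=float) * UM_PER_MM),
        mask=mask,
        origin=np.asarray(origin_mm, dtype=float) * UM_PER_MM,
    )


def write_montage(volume: Volume, path, overlay: np.ndarray | None = None) -> None:
    """PNG montage of the three orthogonal mid-slices (QC figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    mids = [s // 2 for s in volume.shape]
    slices = [
        volume.voxels[mids[0], :, :].T,
        volume.voxels[:, mids[1], :].T,
        volume.voxels[:, :, mids[2]].T,
    ]
    over = None
    if overlay is not None:
        over = [
            overlay[mids[0], :, :].T,
            overlay[:, mids[1], :].T,
            overlay[:, :, mids[2]].T,
        ]
    for i, ax in enumerate(axes):
        ax.imshow(slices[i], cmap="gray", origin="lower")
        if over is not None:
            masked = np.ma.masked_where(over[i] == 0, over[i])
            ax.imshow(masked, cmap="autumn", origin="lower", alpha=0.7)
        ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
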