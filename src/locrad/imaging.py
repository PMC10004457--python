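"""Volumes, ROI masks, cohort manifests, and NIfTI round-tripping.

Array convention: volumes are indexed ``(slice, row, col)`` = ``(z, y, x)``
with ``spacing`` given in millimetres in the same order.  Masks share their
volume's grid exactly; no resampling or registration happens here.

On disk the canonical format is NIfTI-1 (via nibabel), stored in the usual
``(x, y, z)`` axis order with the spacing carried in the header zooms, so
that a write-then-read round trip is bit-exact.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import nibabel as nib
from scipy import ndimage

__all__ = [
    "Modality",
    "Group",
    "ImageVolume",
    "RoiMask",
    "ManifestEntry",
    "CohortManifest",
    "ImageFormatError",
    "DimensionError",
    "EmptyRoiError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "suv_threshold_roi",
    "roi_volume_cm3",
]


class ImageFormatError(ValueError):
    """File is not a readable supported image."""


class DimensionError(ValueError):
    """Image payload is not a 3D scalar grid."""


class EmptyRoiError(ValueError):
    """An operation produced or received an empty ROI."""


class Modality(str, Enum):
    CT = "CT"
    PET = "PET"


class Group(str, Enum):
    LRRC = "LRRC"          # biopsy-confirmed local recurrence (positive class)
    NO_LRRC = "NO_LRRC"    # lesion proven non-recurrent (negative class)


#: physical units implied by each modality
UNITS = {Modality.CT: "HU", Modality.PET: "SUV"}


def _check_spacing(spacing) -> tuple[float, float, float]:
    sp = tuple(float(s) for s in spacing)
    if len(sp) != 3 or any(not np.isfinite(s) or s <= 0 for s in sp):
        raise ValueError(f"spacing must be three positive mm values, got {spacing!r}")
    return sp


@dataclass
class ImageVolume:
    """A 3D scalar image with physical voxel spacing.

    ``voxels`` is ``(z, y, x)``; ``spacing`` is (z, y, x) in mm.  CT volumes
    are in Hounsfield units, PET volumes in SUV.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    modality: Modality

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise DimensionError(f"volume must be 3D, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite voxels")
        self.spacing = _check_spacing(self.spacing)
        self.modality = Modality(self.modality)

    @property
    def units(self) -> str:
        return UNITS[self.modality]

    @property
    def in_plane_spacing(self) -> float:
        """Mean of the row/column spacings (mm)."""
        return 0.5 * (self.spacing[1] + self.spacing[2])

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class RoiMask:
    """Binary ROI support co-registered to an :class:`ImageVolume`."""

    support: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.support)
        if arr.ndim != 3:
            raise DimensionError(f"mask must be 3D, got shape {arr.shape}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError("mask values must be strictly binary")
            arr = arr.astype(bool)
        if not arr.any():
            raise EmptyRoiError("mask has no in-ROI voxel")
        self.support = arr
        self.spacing = _check_spacing(self.spacing)

    @property
    def n_voxels(self) -> int:
        return int(self.support.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


def check_paired(volume: ImageVolume, mask: RoiMask) -> None:
    """Raise unless mask and volume share one grid (shape and spacing)."""
    if volume.voxels.shape != mask.support.shape:
        raise ValueError(
            f"mask shape {mask.support.shape} != volume shape {volume.voxels.shape}"
        )
    if not np.allclose(volume.spacing, mask.spacing, rtol=1e-6, atol=0.0):
        raise ValueError(f"mask spacing {mask.spacing} != volume spacing {volume.spacing}")


# ---------------------------------------------------------------------------
# NIfTI I/O


def _load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of error types
        raise ImageFormatError(f"cannot read {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DimensionError(f"{path}: expected 3D payload, got {data.ndim}D")
    zx, zy, zz = img.header.get_zooms()[:3]
    # stored (x, y, z) -> package order (z, y, x)
    return data.T, (float(zz), float(zy), float(zx))


def _save_nifti(data_zyx: np.ndarray, spacing: tuple[float, float, float], path) -> None:
    sz, sy, sx = spacing
    affine = np.diag((sx, sy, sz, 1.0))
    img = nib.Nifti1Image(np.asarray(data_zyx).T, affine)
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, str(path))


def read_volume(path, modality: Modality) -> ImageVolume:
    """Read a 3D NIfTI volume; spacing comes from the header zooms."""
    data, spacing = _load_nifti(path)
    return ImageVolume(data.astype(np.float64), spacing, Modality(modality))


def write_volume(volume: ImageVolume, path) -> None:
    _save_nifti(volume.voxels.astype(np.float64), volume.spacing, path)


def read_mask(path) -> RoiMask:
    data, spacing = _load_nifti(path)
    return RoiMask(data, spacing)


def write_mask(mask: RoiMask, path) -> None:
    _save_nifti(mask.support.astype(np.uint8), mask.spacing, path)


# ---------------------------------------------------------------------------
# ROI proposal and measurement


def suv_threshold_roi(
    volume: ImageVolume,
    seed_box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]],
    fraction: float = 0.4,
) -> RoiMask:
    """Fractional-SUVmax threshold ROI proposal for PET volumes.

    Inside the axis-aligned ``seed_box`` (three ``(start, stop)`` index
    pairs), voxels with value >= ``fraction`` x (max SUV in the box) are
    kept, and of those only the connected component (6-connectivity)
    containing the hottest voxel is returned.  The threshold uses the
    box-local maximum, so the result is invariant to rescaling the whole
    volume by a positive constant.

    Clinical contouring applies expert corrections after this step; those
    are out of scope, and externally supplied masks are always accepted by
    the rest of the pipeline.
    """
    if volume.modality is not Modality.PET:
        raise ValueError("suv_threshold_roi requires a PET volume")
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    slices = tuple(slice(int(a), int(b)) for a, b in seed_box)
    sub = volume.voxels[slices]
    if sub.size == 0:
        raise EmptyRoiError("seed_box selects no voxels")
    vmax = float(sub.max())
    if vmax <= 0:
        raise EmptyRoiError("seed_box contains no positive uptake")
    keep = np.zeros(volume.voxels.shape, dtype=bool)
    keep[slices] = sub >= fraction * vmax
    labels, _ = ndimage.label(keep)
    hot = np.unravel_index(int(np.argmax(np.where(keep, volume.voxels, -np.inf))), keep.shape)
    comp = labels == labels[hot]
    return RoiMask(comp, volume.spacing)


def roi_volume_cm3(mask: RoiMask) -> float:
    """ROI volume: in-mask voxel count x voxel volume, in cm^3."""
    return mask.n_voxels * mask.voxel_volume_mm3 / 1000.0


# ---------------------------------------------------------------------------
# Cohort manifest


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    modality: Modality
    group: Group
    volume_path: str
    mask_path: str


@dataclass
class CohortManifest:
    """Per-sample inventory: id, modality, group label, and file paths."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def subset(self, modality: Modality) -> "CohortManifest":
        modality = Modality(modality)
        return CohortManifest([e for e in self.entries if e.modality is modality])

    def n_per_group(self) -> dict[Group, int]:
        out = {g: 0 for g in Group}
        for e in self.entries:
            out[e.group] += 1
        return out

    COLUMNS = ("id", "modality", "group", "volume_path", "mask_path")

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(self.COLUMNS)
            for e in self.entries:
                w.writerow(
                    (e.sample_id, e.modality.value, e.group.value, e.volume_path, e.mask_path)
                )

    @classmethod
    def from_csv(cls, path) -> "CohortManifest":
        path = Path(path)
        entries = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            missing = set(cls.COLUMNS) - set(reader.fieldnames or ())
            if missing:
                raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
            for row in reader:
                entries.append(
                    ManifestEntry(
                        sample_id=row["id"],
                        modality=Modality(row["modality"]),
                        group=Group(row["group"]),
                        volume_path=row["volume_path"],
                        mask_path=row["mask_path"],
                    )
                )
        return cls(entries)
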