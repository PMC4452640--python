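"""Image containers and NIfTI I/O.

All images in the pipeline are carried as :class:`ImageVolume` (a 3D scalar
field or a 4D stack with voxel dimensions in mm), :class:`ParametricMap`
(a quantified volume tagged with its physical quantity and a per-voxel
validity mask) or :class:`ROIMask` (a labelled binary region on the same
grid). Files are NIfTI-1 only; the unit tag travels in the header
``descrip`` field so maps survive a round trip through disk.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "ParametricMap",
    "ROIMask",
    "read_volume",
    "write_volume",
    "read_mask",
]


@dataclass
class ImageVolume:
    """A 3D scalar field (or 4D stack) with voxel dimensions in mm."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]  # (dx, dy, dz) in mm
    unit: str = "a.u."

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim not in (3, 4):
            raise ValueError(
                f"expected a 3D or 4D array, got {self.data.ndim}D"
            )
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel dimensions must be positive: {self.voxel_size}")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        dx, dy, dz = self.voxel_size
        return dx * dy * dz

    @property
    def n_volumes(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[3]


@dataclass
class ParametricMap(ImageVolume):
    """An ImageVolume tagged with its quantity and a per-voxel validity mask.

    Voxels where the quantification could not be trusted (division guard,
    non-positive diffusion signal, failed bolus fit, ...) are flagged in
    ``valid`` rather than silently zeroed, so ROI statistics can exclude
    and count them.
    """

    quantity: str = "unknown"
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.data.ndim != 3:
            raise ValueError("a ParametricMap is a single 3D volume")
        if self.valid is None:
            self.valid = np.ones(self.data.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.data.shape:
                raise ValueError("validity mask shape does not match data")

    @property
    def n_invalid(self) -> int:
        return int((~self.valid).sum())

    def with_data(self, data: np.ndarray, quantity: str | None = None,
                  unit: str | None = None) -> "ParametricMap":
        """A copy with new voxel data (and optionally a new quantity/unit)."""
        return dataclasses.replace(
            self,
            data=np.asarray(data, dtype=np.float64),
            quantity=self.quantity if quantity is None else quantity,
            unit=self.unit if unit is None else unit,
            valid=self.valid.copy(),
        )


@dataclass
class ROIMask:
    """A labelled binary region on an image grid."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    label: str = "roi"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("an ROI mask is a single 3D volume")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel dimensions must be positive: {self.voxel_size}")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz


def _affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    """Right-handed axial affine from the voxel dimensions (mm)."""
    dx, dy, dz = voxel_size
    return np.diag([dx, dy, dz, 1.0])


def write_volume(vol: ImageVolume, path: str | Path) -> Path:
    """Write a volume (or map) as NIfTI-1; the unit tag goes in ``descrip``."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"output directory does not exist: {path.parent}")
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64),
                          _affine(vol.voxel_size))
    img.header["pixdim"][1:4] = vol.voxel_size
    tag = vol.unit
    if isinstance(vol, ParametricMap):
        tag = f"{vol.quantity} [{vol.unit}]"
    img.header["descrip"] = tag.encode()[:79]
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path, expect_4d: bool | None = None) -> ImageVolume:
    """Read a NIfTI-1 file into an :class:`ImageVolume`.

    ``expect_4d`` asserts dimensionality: True requires a 4D series, False a
    3D volume, None accepts either.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:  # malformed file: re-raise with the filename
        raise IOError(f"could not read NIfTI file {path}: {exc}") from exc
    if data.ndim not in (3, 4):
        raise ValueError(f"{path}: expected a 3D or 4D image, got {data.ndim}D")
    if expect_4d is True and data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D series, got {data.ndim}D")
    if expect_4d is False and data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    unit = img.header["descrip"].tobytes().split(b"\x00", 1)[0].decode(errors="replace")
    return ImageVolume(data=data, voxel_size=tuple(float(z) for z in zooms),
                       unit=unit or "a.u.")


def read_mask(path: str | Path, label: str = "roi") -> ROIMask:
    """Read a NIfTI file as a binary ROI mask (non-zero voxels are in)."""
    vol = read_volume(path, expect_4d=False)
    return ROIMask(data=vol.data != 0, voxel_size=vol.voxel_size, label=label)
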