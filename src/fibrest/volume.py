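"""3D scalar image volumes with isotropic physical voxel size.

The :class:`ImageVolume` is the common currency of the pipeline: a 3D grid of
scalar intensities indexed ``(z, y, x)`` plus the isotropic voxel side length
in nanometres.  Direction vectors and physical coordinates everywhere in this
package use ``(x, y, z)`` component order and micrometres; the conversion
between array indices ``(iz, iy, ix)`` and physical points is centralised
here.

NIfTI files store the voxel size in mm in the header; TIFF stacks carry no
physical metadata, so a small YAML sidecar manifest is required for them.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
import yaml

logger = logging.getLogger(__name__)

NM_PER_MM = 1.0e6
NM_PER_UM = 1.0e3


@dataclasses.dataclass
class ImageVolume:
    """A 3D scalar intensity grid with isotropic voxel size.

    Parameters
    ----------
    data:
        3D array indexed ``(z, y, x)``; finite values.
    voxel_size:
        Isotropic voxel side length in nanometres (> 0).
    provenance:
        Free-text note on where the volume came from.
    """

    data: np.ndarray
    voxel_size: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if self.voxel_size <= 0:
            raise ValueError(f"voxel_size must be > 0 nm, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size_um(self) -> float:
        """Voxel side length in micrometres."""
        return self.voxel_size / NM_PER_UM

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.voxel_size, self.provenance)


def voxel_to_um(index_zyx: np.ndarray, voxel_size_nm: float) -> np.ndarray:
    """Map fractional ``(z, y, x)`` indices to physical ``(x, y, z)`` μm.

    Voxel centres sit at integer indices, so index ``i`` maps to
    ``i * voxel_size_um``.
    """
    idx = np.asarray(index_zyx, dtype=float)
    return idx[..., ::-1] * (voxel_size_nm / NM_PER_UM)


def um_to_voxel(points_xyz_um: np.ndarray, voxel_size_nm: float) -> np.ndarray:
    """Map physical ``(x, y, z)`` μm points to fractional ``(z, y, x)`` indices."""
    pts = np.asarray(points_xyz_um, dtype=float)
    return pts[..., ::-1] / (voxel_size_nm / NM_PER_UM)


def downsample_volume(volume: ImageVolume, factor: int) -> ImageVolume:
    """Downsample by block averaging over ``factor³`` cubes.

    The voxel size is multiplied by ``factor``.  Dimensions that are not
    divisible by ``factor`` are cropped at the trailing end with a warning.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"downsampling factor must be an integer >= 1, got {factor}")
    factor = int(factor)
    if factor == 1:
        return volume.copy()
    data = volume.data
    trimmed = tuple((s // factor) * factor for s in data.shape)
    if trimmed != data.shape:
        logger.warning(
            "downsample factor %d does not divide shape %s; cropping to %s",
            factor, data.shape, trimmed,
        )
        data = data[: trimmed[0], : trimmed[1], : trimmed[2]]
    nz, ny, nx = (s // factor for s in data.shape)
    blocks = data.reshape(nz, factor, ny, factor, nx, factor)
    out = blocks.mean(axis=(1, 3, 5))
    return ImageVolume(out, volume.voxel_size * factor,
                       f"{volume.provenance} [downsampled x{factor}]".strip())


# ---------------------------------------------------------------------------
# File IO
# ---------------------------------------------------------------------------

def write_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or multi-page TIFF (.tif).

    NIfTI encodes the voxel size in the header (mm).  TIFF gets a YAML
    sidecar ``<stem>.manifest.yaml`` recording voxel size and axis order.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        mm = volume.voxel_size / NM_PER_MM
        affine = np.diag([mm, mm, mm, 1.0])
        # nibabel expects (x, y, z) axis order on disk
        img = nib.Nifti1Image(np.ascontiguousarray(volume.data.T), affine)
        img.header.set_zooms((mm, mm, mm))
        nib.save(img, str(path))
    elif suffixes.endswith((".tif", ".tiff")):
        tifffile.imwrite(str(path), np.asarray(volume.data),
                         photometric="minisblack")
        manifest = {
            "voxel_size_nm": float(volume.voxel_size),
            "axis_order": "zyx",
            "provenance": volume.provenance,
        }
        sidecar = path.with_suffix(".manifest.yaml")
        sidecar.write_text(yaml.safe_dump(manifest))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")


def read_volume(path: str | Path, voxel_size: float | None = None) -> ImageVolume:
    """Read a NIfTI or multi-page TIFF volume.

    For TIFF the voxel size comes from the sidecar manifest, or from the
    ``voxel_size`` argument (nm).  Anisotropic NIfTI voxels are rejected.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        if not np.allclose(zooms, zooms[0], rtol=1e-6):
            raise ValueError(f"anisotropic voxels are unsupported: zooms {zooms} mm")
        data = np.asanyarray(img.dataobj).T  # disk (x, y, z) -> memory (z, y, x)
        return ImageVolume(np.ascontiguousarray(data), float(zooms[0]) * NM_PER_MM,
                           provenance=str(path))
    if suffixes.endswith((".tif", ".tiff")):
        data = tifffile.imread(str(path))
        sidecar = path.with_suffix(".manifest.yaml")
        if voxel_size is None:
            if not sidecar.exists():
                raise ValueError(
                    f"TIFF carries no voxel size; provide voxel_size= in nm or a "
                    f"manifest at {sidecar.name}"
                )
            manifest = yaml.safe_load(sidecar.read_text())
            voxel_size = float(manifest["voxel_size_nm"])
        return ImageVolume(data, float(voxel_size), provenance=str(path))
    raise ValueError(f"unsupported volume format: {path.name}")


@dataclasses.dataclass
class ROIMask:
    """Boolean 3D region-of-interest mask on the same grid as a volume."""

    data: np.ndarray
    voxel_size: float
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.data.shape}")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0 nm")
        if not self.data.any():
            warnings.warn(f"ROI mask '{self.label}' is empty", stacklevel=2)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.data.sum())


def write_mask(mask: ROIMask, path: str | Path) -> None:
    write_volume(ImageVolume(mask.data.astype(np.uint8), mask.voxel_size,
                             provenance=mask.label), path)


def read_mask(path: str | Path, label: str = "") -> ROIMask:
    vol = read_volume(path)
    return ROIMask(vol.data > 0, vol.voxel_size, label=label or vol.provenance)
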