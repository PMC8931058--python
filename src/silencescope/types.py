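"""Core containers: 3D image stacks, cell geometry, and spot-table schema.

Coordinate conventions used throughout the package:

* voxel grids are indexed (z, y, x), 0-based;
* the physical center of voxel ``i`` along an axis with voxel size ``v`` nm is
  ``(i + 0.5) * v`` nm, so positions are continuous nm coordinates;
* cell and nucleus outlines are 2D (y, x) — spots are assigned to compartments
  by their lateral position only, matching how projected outlines are combined
  with 3D spot coordinates in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

#: Column schema shared by every spot table in the package, whether it came
#: from the Gaussian-fitting detector or from the synthetic fast path.
SPOT_COLUMNS = [
    "spot_id", "channel", "z_nm", "y_nm", "x_nm",
    "amplitude", "integrated_intensity", "sigma_xy_nm", "sigma_z_nm",
    "background", "residual", "cell_id", "compartment",
]


@dataclass
class ImageStack:
    """One channel's 3D voxel grid with physical voxel sizes.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Non-negative finite intensities.
    voxel_size_xy_nm, voxel_size_z_nm : float
        Physical voxel size; defaults match a 60x widefield setup
        (XY 107.5 nm, Z 200 nm).
    channel_name : str
        One of the pipeline's channel names (mrna, fluc, suntag, ago, dapi,
        background) or any user label.
    """

    voxels: np.ndarray
    voxel_size_xy_nm: float = 107.5
    voxel_size_z_nm: float = 200.0
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D (z, y, x) array, got ndim={self.voxels.ndim}")
        if self.voxel_size_xy_nm <= 0 or self.voxel_size_z_nm <= 0:
            raise ValueError("voxel sizes must be strictly positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("image intensities must be finite")
        if self.voxels.size and self.voxels.min() < 0:
            raise ValueError("image intensities must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_nm3(self) -> float:
        return self.voxel_size_xy_nm ** 2 * self.voxel_size_z_nm

    def voxel_to_nm(self, zyx: np.ndarray) -> np.ndarray:
        """Convert (possibly fractional) voxel indices to nm (voxel-center convention)."""
        zyx = np.atleast_2d(np.asarray(zyx, dtype=float))
        scale = np.array([self.voxel_size_z_nm, self.voxel_size_xy_nm, self.voxel_size_xy_nm])
        return np.squeeze((zyx + 0.5) * scale)

    def nm_to_voxel(self, pos_nm: np.ndarray) -> np.ndarray:
        pos_nm = np.atleast_2d(np.asarray(pos_nm, dtype=float))
        scale = np.array([self.voxel_size_z_nm, self.voxel_size_xy_nm, self.voxel_size_xy_nm])
        return np.squeeze(pos_nm / scale - 0.5)

    def to_tiff(self, path: str | Path) -> None:
        """Write as an ImageJ-style TIFF carrying voxel-size metadata (µm units)."""
        xy_um = self.voxel_size_xy_nm / 1000.0
        tifffile.imwrite(
            str(path),
            self.voxels.astype(np.float32),
            imagej=True,
            resolution=(1.0 / xy_um, 1.0 / xy_um),
            metadata={"spacing": self.voxel_size_z_nm / 1000.0, "unit": "um", "axes": "ZYX"},
        )

    @classmethod
    def from_tiff(cls, path: str | Path, channel_name: str = "") -> "ImageStack":
        with tifffile.TiffFile(str(path)) as tf:
            voxels = tf.asarray().astype(np.float64)
            xy_nm, z_nm = 107.5, 200.0
            try:
                page = tf.pages[0]
                xres = page.tags["XResolution"].value  # pixels per unit, rational
                xy_nm = 1000.0 * xres[1] / xres[0]
                if tf.imagej_metadata and "spacing" in tf.imagej_metadata:
                    z_nm = 1000.0 * float(tf.imagej_metadata["spacing"])
            except (KeyError, TypeError, ZeroDivisionError):
                pass
        if voxels.ndim == 2:
            voxels = voxels[None]
        return cls(voxels, voxel_size_xy_nm=xy_nm, voxel_size_z_nm=z_nm,
                   channel_name=channel_name or Path(path).stem)


def _ellipse_mask(shape_yx: tuple[int, int], center: tuple[float, float],
                  radii: tuple[float, float]) -> np.ndarray:
    yy, xx = np.ogrid[: shape_yx[0], : shape_yx[1]]
    cy, cx = center
    ry, rx = radii
    return ((yy + 0.5 - cy) / ry) ** 2 + ((xx + 0.5 - cx) / rx) ** 2 <= 1.0


@dataclass
class CellGeometry:
    """Per-cell 2D nucleus and cell outline with compartment-containment tests.

    Two backings are supported transparently:

    * *analytic*: axis-aligned ellipses (center + semi-axes in pixels), used by
      the synthetic generator so that 50-cell virtual fields need no rasterized
      masks; masks are rasterized lazily on demand;
    * *mask*: arbitrary boolean masks, as produced by watershed segmentation.
    """

    cell_id: int
    field_shape_yx: tuple[int, int]
    pixel_size_nm: float = 107.5
    center_px: tuple[float, float] | None = None
    cell_radii_px: tuple[float, float] | None = None
    nucleus_radii_px: tuple[float, float] | None = None
    touches_border: bool = False
    _cell_mask: np.ndarray | None = field(default=None, repr=False)
    _nucleus_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.is_analytic:
            cr, nr = self.cell_radii_px, self.nucleus_radii_px
            if nr[0] >= cr[0] or nr[1] >= cr[1]:
                raise ValueError(f"cell {self.cell_id}: nucleus must fit inside the cell")
        elif self._cell_mask is None:
            raise ValueError("CellGeometry needs either ellipse parameters or masks")
        elif self._nucleus_mask is not None and np.any(self._nucleus_mask & ~self._cell_mask):
            # enforce nucleus ⊆ cell for mask-backed geometry
            self._nucleus_mask = self._nucleus_mask & self._cell_mask

    @property
    def is_analytic(self) -> bool:
        return self.center_px is not None and self.cell_radii_px is not None

    @classmethod
    def from_masks(cls, cell_id: int, nucleus_mask: np.ndarray, cell_mask: np.ndarray,
                   pixel_size_nm: float = 107.5, touches_border: bool = False) -> "CellGeometry":
        return cls(cell_id=cell_id, field_shape_yx=cell_mask.shape,
                   pixel_size_nm=pixel_size_nm, touches_border=touches_border,
                   _cell_mask=cell_mask.astype(bool), _nucleus_mask=nucleus_mask.astype(bool))

    # -- containment -------------------------------------------------------
    def _contains(self, y_px, x_px, which: str):
        y_px = np.asarray(y_px, dtype=float)
        x_px = np.asarray(x_px, dtype=float)
        if self.is_analytic:
            cy, cx = self.center_px
            ry, rx = self.cell_radii_px if which == "cell" else self.nucleus_radii_px
            return ((y_px - cy) / ry) ** 2 + ((x_px - cx) / rx) ** 2 <= 1.0
        mask = self._cell_mask if which == "cell" else self._nucleus_mask
        iy = np.clip(np.floor(y_px).astype(int), 0, mask.shape[0] - 1)
        ix = np.clip(np.floor(x_px).astype(int), 0, mask.shape[1] - 1)
        inside = (y_px >= 0) & (y_px < mask.shape[0]) & (x_px >= 0) & (x_px < mask.shape[1])
        return mask[iy, ix] & inside

    def contains_cell(self, y_px, x_px):
        return self._contains(y_px, x_px, "cell")

    def contains_nucleus(self, y_px, x_px):
        return self._contains(y_px, x_px, "nucleus")

    # -- masks and areas ---------------------------------------------------
    @property
    def cell_mask(self) -> np.ndarray:
        if self._cell_mask is None:
            self._cell_mask = _ellipse_mask(self.field_shape_yx, self.center_px, self.cell_radii_px)
        return self._cell_mask

    @property
    def nucleus_mask(self) -> np.ndarray:
        if self._nucleus_mask is None:
            self._nucleus_mask = _ellipse_mask(self.field_shape_yx, self.center_px, self.nucleus_radii_px)
        return self._nucleus_mask

    @property
    def nucleus_area_um2(self) -> float:
        px_um2 = (self.pixel_size_nm / 1000.0) ** 2
        if self._nucleus_mask is not None:
            return float(self._nucleus_mask.sum()) * px_um2
        ry, rx = self.nucleus_radii_px
        return float(np.pi * ry * rx) * px_um2
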