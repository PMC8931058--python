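"""Nucleus/cell outlining and compartment assignment.

Nuclei are segmented from the DAPI channel and cell outlines from the diffuse
probe-background haze, both on maximum-intensity projections (outlines are 2D;
spots are assigned by their lateral position only).  The recipe is the common
smoothing → global threshold → watershed chain; the threshold defaults to Otsu
and is overridable because the original pipeline's exact settings are tool
internals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import watershed

from silencescope.types import CellGeometry, ImageStack


def _projection(stack: ImageStack, smooth_sigma: float) -> np.ndarray:
    mip = stack.voxels.max(axis=0)
    return gaussian(mip, sigma=smooth_sigma, preserve_range=True)


def segment_nuclei(dapi: ImageStack, smooth_sigma: float = 2.0,
                   threshold: float | None = None, min_area_px: int = 200,
                   min_peak_distance_px: int = 15) -> np.ndarray:
    """Label nuclei on the smoothed DAPI projection.

    Touching nuclei are split by a distance-transform watershed.  An all-zero
    image yields zero labels (not an error).
    """
    sm = _projection(dapi, smooth_sigma)
    if sm.max() <= 0:
        return np.zeros(sm.shape, dtype=np.int32)
    thr = threshold_otsu(sm) if threshold is None else threshold
    binary = ndimage.binary_fill_holes(sm > thr)
    if not binary.any():
        return np.zeros(sm.shape, dtype=np.int32)
    dist = ndimage.distance_transform_edt(binary)
    peaks = peak_local_max(dist, min_distance=min_peak_distance_px, labels=binary)
    markers = np.zeros(sm.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist, markers, mask=binary)
    areas = np.bincount(labels.ravel())
    small = np.flatnonzero(areas < min_area_px)
    labels[np.isin(labels, small[small > 0])] = 0
    # relabel consecutively
    _, labels = np.unique(labels, return_inverse=True)
    return labels.reshape(sm.shape).astype(np.int32)


def segment_cells(background: ImageStack | None, nuclei: np.ndarray,
                  smooth_sigma: float = 4.0, threshold: float | None = None) -> np.ndarray:
    """Seeded watershed of cell outlines from the probe-background haze.

    Each cell label grows from its nucleus seed within the above-threshold
    haze region, so touching cells are partitioned by the watershed ridge.
    """
    if background is None:
        raise ValueError(
            "background channel missing: cannot outline cells from images; "
            "use spots-only mode with analytic geometry instead")
    sm = _projection(background, smooth_sigma)
    if nuclei.max() == 0:
        return np.zeros(sm.shape, dtype=np.int32)
    thr = threshold_otsu(sm) if threshold is None else threshold
    mask = (sm > thr) | (nuclei > 0)
    return watershed(-sm, markers=nuclei, mask=mask).astype(np.int32)


def geometry_from_labels(nuclei: np.ndarray, cells: np.ndarray,
                         pixel_size_nm: float = 107.5) -> list[CellGeometry]:
    """Build mask-backed :class:`CellGeometry` objects from label images.

    Cells whose mask touches the field border are flagged (and excluded from
    per-cell metrics downstream).  Nucleus labels are matched to the cell
    label that contains them.
    """
    geoms = []
    for prop in regionprops(cells):
        cell_mask = cells == prop.label
        nucleus_mask = (nuclei == prop.label) & cell_mask
        if not nucleus_mask.any():
            # fall back to any nucleus inside this cell
            inside = np.unique(nuclei[cell_mask])
            inside = inside[inside > 0]
            if inside.size:
                nucleus_mask = np.isin(nuclei, inside) & cell_mask
        border = (prop.bbox[0] == 0 or prop.bbox[1] == 0
                  or prop.bbox[2] == cells.shape[0] or prop.bbox[3] == cells.shape[1])
        geoms.append(CellGeometry.from_masks(
            cell_id=int(prop.label) - 1, nucleus_mask=nucleus_mask, cell_mask=cell_mask,
            pixel_size_nm=pixel_size_nm, touches_border=border))
    return geoms


def geometry_table(geoms: list[CellGeometry]) -> pd.DataFrame:
    return pd.DataFrame({
        "cell_id": [g.cell_id for g in geoms],
        "nucleus_area_um2": [g.nucleus_area_um2 for g in geoms],
        "touches_border": [g.touches_border for g in geoms],
    })


def assign_compartment(spots: pd.DataFrame, geometry: list[CellGeometry],
                       pixel_size_nm: float | None = None) -> pd.DataFrame:
    """Assign each spot a ``cell_id`` and ``compartment`` from its (y, x).

    A spot is *nuclear* if it falls inside a nucleus outline, *cytoplasmic* if
    inside a cell but outside its nucleus, and *unassigned* (cell_id −1)
    outside every cell; unassigned spots are excluded downstream.
    """
    spots = spots.copy()
    n = len(spots)
    cell_id = np.full(n, -1, dtype=int)
    compartment = np.full(n, "unassigned", dtype=object)
    if n == 0:
        spots["cell_id"], spots["compartment"] = cell_id, compartment
        return spots
    px = pixel_size_nm or (geometry[0].pixel_size_nm if geometry else 107.5)
    y_px = spots["y_nm"].to_numpy(dtype=float) / px
    x_px = spots["x_nm"].to_numpy(dtype=float) / px
    unclaimed = np.ones(n, dtype=bool)
    for geom in geometry:
        if not unclaimed.any():
            break
        idx = np.flatnonzero(unclaimed)
        in_cell = geom.contains_cell(y_px[idx], x_px[idx])
        hit = idx[in_cell]
        if hit.size == 0:
            continue
        in_nuc = geom.contains_nucleus(y_px[hit], x_px[hit])
        cell_id[hit] = geom.cell_id
        compartment[hit] = np.where(in_nuc, "nuclear", "cytoplasmic")
        unclaimed[hit] = False
    spots["cell_id"] = cell_id
    spots["compartment"] = compartment
    return spots
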