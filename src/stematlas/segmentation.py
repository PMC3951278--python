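"""Segmentation of stem images into masks and contour polygons.

Two image sources are handled.  Flat-bed scans of stem slabs (RGB,
~35.3 um/px) are segmented by thresholding the HSV value channel at 0.5,
which separates the bright slabs (value around 0.8) from the dark scanner
background (around 0.1).  Grey-level macroscopy images of stem slices
(~3.62 um/px, dark field: cell walls bright, lumens dark) are segmented by
a cell-detecting watershed followed by hole filling and a morphological
closing, and the resulting contour is simplified with Douglas-Peucker.

Image coordinates are converted to the mathematical frame on load:
x = col * resolution, y = (n_rows - 1 - row) * resolution, in mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology, segmentation as skseg
from skimage.measure import label as cc_label

from .geometry import (Polygon, centre_polygon, chain_contour_pixels,
                       orient_ccw, simplify_dp, GeometryError)


class SegmentationError(ValueError):
    """Segmentation produced no usable foreground."""


@dataclass(frozen=True)
class LabelledMask:
    """Binary mask of one object plus its physical resolution (mm/px)."""

    mask: np.ndarray
    resolution: float
    source_id: str = ""

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if not np.asarray(self.mask).any():
            raise ValueError("mask has no foreground pixel")


def rgb_to_value(img: np.ndarray) -> np.ndarray:
    """HSV value channel of an 8-bit RGB image: V = max(R, G, B) / 255."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected a 3-channel RGB image, got shape {img.shape}")
    return img.max(axis=2).astype(float) / 255.0


def segment_slabs(value: np.ndarray, threshold: float = 0.5,
                  min_area_px: int = 1000, resolution: float = 0.0353,
                  source_id: str = "") -> list[LabelledMask]:
    """Segment bright slabs from a dark background in the value channel.

    Connected components of ``value > threshold`` with at least
    ``min_area_px`` pixels are kept (small components are scanner dust);
    holes inside each slab are filled.  Components are returned in
    reading order of their centroids.
    """
    fg = np.asarray(value, float) > threshold
    labels = cc_label(fg, connectivity=2)
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    ids = ids[counts >= min_area_px]
    if len(ids) == 0:
        raise SegmentationError(
            f"no slab component above {min_area_px} px at threshold {threshold}")
    cys = ndi.center_of_mass(fg, labels, ids)
    order = np.lexsort(([c[1] for c in cys], [c[0] for c in cys]))
    out = []
    for k, i in enumerate(order, start=1):
        m = ndi.binary_fill_holes(labels == ids[i])
        sid = f"{source_id}_slab{k:02d}" if source_id else f"slab{k:02d}"
        out.append(LabelledMask(m, resolution, sid))
    return out


def mask_to_contour(m: LabelledMask) -> Polygon:
    """Extract the outer contour of a mask as a centred CCW polygon in mm.

    Boundary pixels (foreground pixels 4-adjacent to background, image
    border counting as background) are thinned to unit width, chained, and
    the chain is scaled by the resolution, centred on its area centroid and
    oriented counter-clockwise.  The original centroid (mm, image frame) is
    recorded in ``meta['centroid_mm']``.
    """
    mask = ndi.binary_fill_holes(np.asarray(m.mask).astype(bool))
    inner = ndi.binary_erosion(mask, structure=ndi.generate_binary_structure(2, 1),
                               border_value=0)
    boundary = mask & ~inner
    poly = chain_contour_pixels(boundary)
    xy = poly.xy * m.resolution
    poly = Polygon(xy)
    poly, centroid = centre_polygon(poly)
    poly = orient_ccw(poly)
    meta = dict(poly.meta)
    meta.update(centroid_mm=centroid, source_id=m.source_id,
                resolution=m.resolution)
    return Polygon(poly.xy, meta=meta)


def _slice_foreground(img: np.ndarray, closing_radius_px: int,
                      sigma_px: float = 2.0, marker_depth: float = 10.0,
                      min_cell_px: int = 20) -> np.ndarray:
    """Foreground mask of a cellular section via a cell-detecting watershed.

    Watershed basins of the Gaussian-smoothed image are seeded at its
    regional minima of depth >= ``marker_depth`` (cell lumens; the depth
    floor suppresses noise minima) plus one marker along the image border,
    from which the background floods.  Basins reached from the border are
    background; the union of cell basins is hole-filled, closed with a disk
    of ``closing_radius_px``, and reduced to its largest component.
    """
    smooth = filters.gaussian(np.asarray(img, float), sigma=sigma_px,
                              preserve_range=True)
    markers = cc_label(morphology.h_minima(smooth, marker_depth),
                       connectivity=2)
    border_label = markers.max() + 1
    edge = np.zeros_like(markers, dtype=bool)
    edge[0], edge[-1], edge[:, 0], edge[:, -1] = True, True, True, True
    markers[edge & (markers == 0)] = border_label
    basins = skseg.watershed(smooth, markers)
    border = np.unique(np.concatenate([basins[0], basins[-1],
                                       basins[:, 0], basins[:, -1]]))
    cells = ~np.isin(basins, border)
    cells = morphology.remove_small_objects(cells, max_size=min_cell_px - 1)
    if not cells.any():
        raise SegmentationError("no cell region detected (blank image?)")
    cells = ndi.binary_fill_holes(cells)
    closed = morphology.closing(
        cells, morphology.disk(closing_radius_px, decomposition="sequence"))
    closed = ndi.binary_fill_holes(closed)
    labels = cc_label(closed, connectivity=2)
    if labels.max() == 0:
        raise SegmentationError("empty foreground after closing")
    largest = 1 + np.argmax(np.bincount(labels.ravel())[1:])
    return labels == largest


def segment_slice_contour(img: np.ndarray, resolution: float,
                          closing_radius_px: int = 30,
                          dp_tol_mm: float = 0.1,
                          source_id: str = "") -> Polygon:
    """Contour polygon of a macroscopy slice image (centred, mm, simplified).

    The foreground is segmented by the cell-detecting watershed chain, its
    outer boundary chained to a polygon, scaled to mm, simplified with
    Douglas-Peucker at ``dp_tol_mm`` (100 um default) and re-centred.
    """
    fg = _slice_foreground(img, closing_radius_px)
    poly = mask_to_contour(LabelledMask(fg, resolution, source_id))
    meta = dict(poly.meta)
    simplified = simplify_dp(poly, dp_tol_mm)
    simplified, shift = centre_polygon(simplified)
    # keep the mask centroid as the reference point for bundle centring
    meta["centroid_mm"] = (meta["centroid_mm"][0] + shift[0],
                           meta["centroid_mm"][1] + shift[1])
    try:
        simplified = orient_ccw(simplified)
    except GeometryError:  # pragma: no cover - simplification kept >=3 vertices
        raise
    return Polygon(simplified.xy, meta=meta)
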