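"""Detection of vascular-bundle centroids in macroscopy section images.

Vascular bundles appear as ~300 um clusters of small thick-walled cells
embedded in parenchyma.  The detection chain removes the parenchyma cell
walls with alternate sequential filters (openings and closings with disks
of radius 1..10 px), detects bundles as extended minima of the filtered
image (depth thresholds 30 for large and 20 for small bundles), separates
touching bundles with a watershed on the complement of the distance map,
and reports region centroids in mm relative to the slice-contour centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology
from skimage.measure import label as cc_label, regionprops
from skimage.draw import polygon2mask
from skimage.segmentation import watershed
import shapely

from .geometry import Polygon


@dataclass(frozen=True)
class BundleSet:
    """Bundle centroids (mm) relative to the slice-contour centroid."""

    centroids: np.ndarray   # (n, 2)
    source_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "centroids",
                           np.asarray(self.centroids, float).reshape(-1, 2))

    @property
    def n(self) -> int:
        return len(self.centroids)


def asf(img: np.ndarray, r_max: int = 10) -> np.ndarray:
    """Alternate sequential filter: opening then closing, disks r = 1..r_max.

    Removes bright and dark structures thinner than the running radius
    (parenchyma cell walls) while larger structures (bundles) persist.
    Borders are handled by reflective padding; the output range is bounded
    by the input range.
    """
    if r_max < 1:
        raise ValueError(f"r_max must be >= 1, got {r_max}")
    out = np.asarray(img, float)
    for r in range(1, r_max + 1):
        fp = morphology.disk(r)
        out = ndi.grey_opening(out, footprint=fp, mode="reflect")
        out = ndi.grey_closing(out, footprint=fp, mode="reflect")
    return out


def extended_minima(img: np.ndarray, h: float) -> np.ndarray:
    """Extended minima: regional minima of the h-minima transform.

    The h-minima transform (greyscale reconstruction by erosion of
    image + h over image) fills every minimum shallower than ``h``; the
    regional minima of the result are plateau regions marking each
    surviving minimum of depth >= h, covering its whole flooded floor.
    """
    if h <= 0:
        raise ValueError(f"h must be > 0, got {h}")
    work = np.asarray(img, float)
    filled = morphology.reconstruction(work + h, work, method="erosion")
    return morphology.local_minima(filled, connectivity=2)


def separate_touching(mask: np.ndarray, marker_depth: float = 2.0) -> np.ndarray:
    """Split touching near-convex blobs with a watershed on -distance.

    Markers are the plateau-merged maxima (h-maxima of depth
    ``marker_depth`` px, suppressing rasterisation ripples) of the
    Euclidean distance map; the watershed of the complement of the
    distance map cuts the mask along distance-map ridges.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(mask)
    peaks = morphology.h_maxima(dist, marker_depth)
    markers = cc_label(peaks, connectivity=2)
    if markers.max() == 0:
        markers = cc_label(mask, connectivity=2)
    return watershed(-dist, markers, mask=mask).astype(np.int32)


def _contour_mask_px(contour: Polygon, shape: tuple, resolution: float) -> np.ndarray:
    """Rasterise a centred contour back into the image pixel frame."""
    cx, cy = contour.meta.get("centroid_mm", (0.0, 0.0))
    xy = contour.xy + np.array([cx, cy])
    rows = (shape[0] - 1) - xy[:, 1] / resolution
    cols = xy[:, 0] / resolution
    return polygon2mask(shape, np.column_stack([rows, cols]))


def detect_bundles(img: np.ndarray, resolution: float,
                   h_large: int = 30, h_small: int = 20,
                   r_max: int = 10, contour: Polygon | None = None,
                   invert: bool = False, min_area_px: int = 9,
                   source_id: str = "") -> BundleSet:
    """Full bundle-detection chain on one macroscopy image.

    ASF -> extended minima at both depth thresholds -> watershed separation
    -> centroids in mm, translated by the slice-contour centroid.  Regions
    detected at both thresholds are merged keeping the deep-threshold
    region.  Detections outside the slice contour (background, bark
    remnants) are discarded.  ``invert`` flips polarity for images where
    bundles are locally bright instead of dark.

    An empty detection returns an empty BundleSet, not an error.
    """
    work = np.asarray(img, float)
    if invert:
        work = work.max() - work
    filtered = asf(work, r_max=r_max)
    large = extended_minima(filtered, h_large)
    small = extended_minima(filtered, h_small)

    # keep deep detections; add shallow components that touch none of them
    small_labels = cc_label(small, connectivity=2)
    overlapping = np.unique(small_labels[large & (small_labels > 0)])
    extra = small & ~np.isin(small_labels, overlapping)
    detect = large | extra

    if contour is not None:
        inside = _contour_mask_px(contour, work.shape, resolution)
        keep_lab = cc_label(detect, connectivity=2)
        frac_in = ndi.mean(inside.astype(float), keep_lab,
                           np.arange(1, keep_lab.max() + 1))
        detect = np.isin(keep_lab, 1 + np.nonzero(np.asarray(frac_in) >= 0.9)[0])

    labels = separate_touching(detect)
    cents = []
    for rp in regionprops(labels):
        if rp.area < min_area_px:
            continue
        r, c = rp.centroid
        cents.append((c * resolution, ((work.shape[0] - 1) - r) * resolution))
    if not cents:
        return BundleSet(np.empty((0, 2)), source_id)
    cents = np.asarray(cents)
    if contour is not None:
        cx, cy = contour.meta.get("centroid_mm", (0.0, 0.0))
        cents = cents - np.array([cx, cy])
        inside = shapely.contains_xy(contour.to_shapely().buffer(1e-9),
                                     cents[:, 0], cents[:, 1])
        if not inside.all():
            warnings.warn(f"{int(np.sum(~inside))} centroid(s) outside the "
                          "slice contour discarded", stacklevel=2)
            cents = cents[inside]
    return BundleSet(cents, source_id)
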