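"""Actin growth-cone detection at neurite tips.

An actin object is a growth cone when it (a) co-localizes with the TUBB3
neurite mask by at least one pixel and (b) sits at the end of a neurite,
i.e. its centroid lies within ``max_tip_distance`` of a skeleton endpoint.
Areas are reported in µm²; per-object footprints are refined at half-peak
so the area does not depend on where the global threshold happened to land
in the histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.segmentation import watershed

from .image import ChannelImage
from .neurites import Skeleton


@dataclass
class GrowthConeParams:
    max_tip_distance: float = 5.0  # µm, "end of neurite" gate
    min_area: float = 2.0  # µm², noise rejection
    median_size: int = 3  # px, pre-threshold median filter
    half_peak_refine: bool = True
    split_min_distance: float = 2.0  # µm between shape maxima when splitting


def _split_touching(fg: np.ndarray, ps: float, min_distance_um: float) -> np.ndarray:
    """Label actin foreground, splitting dumbbell-shaped objects (two cones
    from neighbouring tips fused by blur) at the waist of their distance
    transform."""
    edt = ndi.distance_transform_edt(fg)
    min_px = max(int(round(min_distance_um / ps)), 1)
    peaks = peak_local_max(
        edt, min_distance=min_px, threshold_abs=1.0, labels=cc_label(fg, connectivity=2)
    )
    if len(peaks) == 0:
        return cc_label(fg, connectivity=2)
    markers = np.zeros(fg.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    return watershed(-edt, markers=markers, mask=fg, connectivity=2)


def detect_growth_cones(
    actin: ChannelImage,
    neurite_mask: np.ndarray,
    skeleton: Skeleton,
    params: GrowthConeParams | None = None,
) -> pd.DataFrame:
    """Detect and measure growth cones; one row per retained cone."""
    params = params or GrowthConeParams()
    if actin.shape != neurite_mask.shape:
        raise ValueError("actin image and neurite mask shapes differ")
    ps = actin.pixel_size
    img = actin.as_float()
    med = ndi.median_filter(img, size=params.median_size)
    if med.min() == med.max():
        return _empty_cones()
    th = threshold_otsu(med)
    fg = med > th
    labels = _split_touching(fg, ps, params.split_min_distance)
    if labels.max() == 0:
        return _empty_cones()

    endpoints = skeleton.endpoints
    tree = cKDTree(np.asarray(endpoints, dtype=float)) if endpoints else None
    bg = float(np.median(med))
    rows = []
    for prop in regionprops(labels, intensity_image=med):
        area = prop.area * ps**2
        if area < params.min_area:
            continue
        sl = prop.slice
        obj = labels[sl] == prop.label
        if not (obj & neurite_mask[sl]).any():
            continue  # no TUBB3 co-localization
        cy, cx = prop.centroid  # px
        if tree is None:
            continue
        tip_dist, _ = tree.query([cy, cx])
        tip_dist *= ps
        if tip_dist > params.max_tip_distance:
            continue
        if params.half_peak_refine:
            peak = float(prop.intensity_max)
            half = bg + 0.5 * (peak - bg)
            area = _half_peak_area(med, labels, prop, half) * ps**2
        rows.append(
            {
                "cone_id": len(rows) + 1,
                "area_um2": float(area),
                "centroid_x_um": cx * ps,
                "centroid_y_um": cy * ps,
                "tip_distance_um": float(tip_dist),
            }
        )
    return pd.DataFrame(rows) if rows else _empty_cones()


def _half_peak_area(med, labels, prop, half: float) -> int:
    """Footprint of the object at half of its peak above background.

    Evaluated in a padded bounding box so the footprint may extend slightly
    beyond the detection threshold contour, restricted to pixels connected
    to the object.
    """
    pad = 3
    r0 = max(prop.bbox[0] - pad, 0)
    c0 = max(prop.bbox[1] - pad, 0)
    r1 = min(prop.bbox[2] + pad, med.shape[0])
    c1 = min(prop.bbox[3] + pad, med.shape[1])
    lw = labels[r0:r1, c0:c1]
    window = (med[r0:r1, c0:c1] >= half) & ((lw == prop.label) | (lw == 0))
    wl = cc_label(window, connectivity=2)
    obj_ids = np.unique(wl[(labels[r0:r1, c0:c1] == prop.label) & window])
    obj_ids = obj_ids[obj_ids > 0]
    if obj_ids.size == 0:
        return prop.area
    return int(np.isin(wl, obj_ids).sum())


def _empty_cones() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["cone_id", "area_um2", "centroid_x_um", "centroid_y_um", "tip_distance_um"]
    )


def normalize_to_untreated(
    mean_areas, untreated_control_mean: float
):
    """Express condition means as unitless ratios to the untreated control."""
    if not untreated_control_mean > 0:
        raise ValueError("untreated control mean must be positive")
    if isinstance(mean_areas, dict):
        return {k: v / untreated_control_mean for k, v in mean_areas.items()}
    arr = np.asarray(mean_areas, dtype=float)
    return arr / untreated_control_mean
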