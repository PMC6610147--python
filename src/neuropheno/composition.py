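"""Culture composition by marker/nucleus co-localization.

A nucleus is positive for a marker when at least ``overlap_fraction`` of its
pixels exceed the marker threshold, so stray marker signal that does not
co-localize with any DAPI nucleus contributes to no call. Fractions reported:
TUBB3+ (neurons) among retained nuclei, TBR1/CTIP2 among all nuclei, the
projection fraction (TBR1 or CTIP2) among TUBB3+ cells, and TBR1∧CTIP2
double positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .image import ChannelImage, LabelMask


@dataclass
class MarkerCall:
    nucleus_label: int
    tubb3: bool = False
    tbr1: bool = False
    ctip2: bool = False

    @property
    def double_positive(self) -> bool:
        return self.tbr1 and self.ctip2

    @property
    def projection(self) -> bool:
        return self.tbr1 or self.ctip2


def call_markers(
    nuclei: LabelMask,
    markers: dict[str, ChannelImage],
    thresholds: dict[str, float] | None = None,
    overlap_fraction: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Call per-nucleus marker positivity and summarize culture composition.

    ``markers`` maps channel names (``TUBB3``, ``TBR1``, ``CTIP2``; any subset)
    to images sharing the nuclei geometry. Thresholds default to Otsu computed
    on nucleus-restricted intensities per marker.
    """
    labels = nuclei.labels
    ids = np.unique(labels[labels > 0])
    if ids.size == 0:
        raise ValueError("no nuclei to call markers on")
    thresholds = dict(thresholds or {})
    nucleus_px = labels > 0

    calls = pd.DataFrame({"nucleus_label": ids.astype(int)})
    for name, img in markers.items():
        if img.data.shape != labels.shape:
            raise ValueError(f"marker {name}: geometry mismatch with nuclei")
        vals = img.as_float()
        if name not in thresholds:
            inside = vals[nucleus_px]
            thresholds[name] = (
                float(threshold_otsu(inside)) if inside.min() < inside.max() else np.inf
            )
        above = vals > thresholds[name]
        frac = np.bincount(labels[above], minlength=labels.max() + 1)[ids]
        total = np.bincount(labels[nucleus_px], minlength=labels.max() + 1)[ids]
        calls[name.lower()] = frac / total >= overlap_fraction

    for col in ("tubb3", "tbr1", "ctip2"):
        if col not in calls:
            calls[col] = False
    calls["projection"] = calls["tbr1"] | calls["ctip2"]
    calls["double_positive"] = calls["tbr1"] & calls["ctip2"]

    n = len(calls)
    n_tubb3 = int(calls["tubb3"].sum())
    summary = {
        "n_nuclei": float(n),
        "pct_tubb3": 100.0 * n_tubb3 / n,
        "pct_tbr1": 100.0 * calls["tbr1"].mean(),
        "pct_ctip2": 100.0 * calls["ctip2"].mean(),
        "pct_projection": (
            100.0 * (calls["projection"] & calls["tubb3"]).sum() / n_tubb3
            if n_tubb3
            else float("nan")
        ),
        "pct_double": 100.0 * calls["double_positive"].mean(),
    }
    return calls, summary
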