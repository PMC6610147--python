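"""Calibrated image containers and TIFF I/O.

All spatial quantities in this package are expressed in micrometres (µm);
images carry their pixel size explicitly so that downstream measurements
(areas, arc lengths, diameters) can always be reported in physical units.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class ChannelImage:
    """A single-channel 2D grayscale image with pixel calibration.

    Parameters
    ----------
    data:
        2D array of intensities. Rendered images are uint16; analysis code
        accepts any real dtype.
    pixel_size:
        Edge length of one pixel in µm.
    channel:
        Optional channel name (e.g. ``"DAPI"``, ``"TUBB3"``).
    """

    data: np.ndarray
    pixel_size: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"ChannelImage requires a 2D array, got ndim={self.data.ndim}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def as_float(self) -> np.ndarray:
        return self.data.astype(np.float64, copy=False)


@dataclass
class LabelMask:
    """Integer-labelled segmentation sharing pixel geometry with its image.

    Label 0 is background; positive labels are individual objects, each a
    single 8-connected component.
    """

    labels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("LabelMask requires a 2D label array")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def foreground(self) -> np.ndarray:
        return self.labels > 0

    @property
    def n_labels(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0

    def areas_um2(self) -> dict[int, float]:
        """Pixel area per label, converted to µm²."""
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        px_area = self.pixel_size**2
        return {int(i): float(c) * px_area for i, c in zip(ids, counts)}


def write_channel_tiff(path: str | os.PathLike, image: ChannelImage) -> None:
    """Write a single-plane 16-bit grayscale TIFF with µm/px resolution tags."""
    data = image.data
    if data.dtype != np.uint16:
        data = np.clip(np.round(data), 0, 65535).astype(np.uint16)
    # TIFF resolution is pixels per unit; store pixels per centimetre.
    ppcm = 1.0e4 / image.pixel_size
    tifffile.imwrite(
        path,
        data,
        resolution=(ppcm, ppcm),
        resolutionunit="CENTIMETER",
        metadata={"pixel_size_um": image.pixel_size, "channel": image.channel},
    )


def read_channel_tiff(path: str | os.PathLike, channel: str = "") -> ChannelImage:
    """Read a TIFF written by :func:`write_channel_tiff` (or any calibrated TIFF)."""
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = page.asarray()
        pixel_size = None
        try:
            xres = page.tags["XResolution"].value  # (num, den) pixels per unit
            unit = page.tags["ResolutionUnit"].value
            per_unit = xres[0] / xres[1]
            unit_um = {2: 2.54e4, 3: 1.0e4}.get(int(unit), None)  # inch / cm
            if unit_um and per_unit > 0:
                pixel_size = unit_um / per_unit
        except (KeyError, ZeroDivisionError):
            pixel_size = None
    if pixel_size is None:
        raise ValueError(f"{path}: no pixel-size calibration in TIFF tags")
    return ChannelImage(data=data, pixel_size=float(pixel_size), channel=channel)
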