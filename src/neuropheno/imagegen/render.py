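"""Forward optical model: ground-truth geometry -> noisy 16-bit channel images.

The model is deliberately simple: structures are rasterized at their nominal
amplitudes (axonal intensity scales with local thickness, so bead-like
swellings are bright), a smooth background plane with a mild random gradient
is added, the whole field is blurred with an isotropic Gaussian PSF, and
shot (Poisson) plus Gaussian read noise are applied before clipping to the
bit depth. Disabling noise and blur makes rendering conservative: every
ground-truth object is recoverable by exact thresholding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import line as draw_line
from skimage.morphology import dilation as grey_dilation_op, disk as disk_footprint

from ..image import ChannelImage
from .scene import SceneGroundTruth

ALL_CHANNELS = ("DAPI", "TUBB3", "actin", "TAU1", "MAP2", "TBR1", "CTIP2")

DEFAULT_GAINS = {
    "DAPI": 12000.0,
    "debris": 15000.0,
    "TUBB3_soma": 9000.0,
    "TUBB3_neurite": 6000.0,
    "actin_cone": 8000.0,
    "actin_neurite": 1200.0,
    "TAU1": 6000.0,
    "MAP2": 6000.0,
    "TBR1": 10000.0,
    "CTIP2": 10000.0,
}

DEFAULT_BACKGROUND = {
    "DAPI": 400.0, "TUBB3": 400.0, "actin": 400.0, "TAU1": 400.0,
    "MAP2": 400.0, "TBR1": 300.0, "CTIP2": 300.0,
}


@dataclass
class RenderConfig:
    """Acquisition parameters of the virtual microscope.

    Defaults (0.325 µm/px, 1024², PSF σ 0.4 µm, 16 bit) are chosen so the
    1 µm swelling threshold spans ≥3 px.
    """

    pixel_size: float = 0.325  # µm/px
    shape: tuple[int, int] = (1024, 1024)  # (rows, cols)
    psf_sigma: float = 0.4  # µm; 0 disables blur
    bit_depth: int = 16
    gains: dict = field(default_factory=lambda: dict(DEFAULT_GAINS))
    background: dict = field(default_factory=lambda: dict(DEFAULT_BACKGROUND))
    background_gradient: float = 0.15  # relative amplitude of the bg plane tilt
    photon_scale: float = 0.1  # photons per intensity count (shot noise)
    read_noise_sd: float = 30.0  # counts
    noise: bool = True

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1


def _to_px(points_um: np.ndarray, ps: float) -> np.ndarray:
    """(x, y) µm -> integer (row, col) pixel indices."""
    pts = np.atleast_2d(points_um)
    cols = np.round(pts[:, 0] / ps).astype(int)
    rows = np.round(pts[:, 1] / ps).astype(int)
    return np.stack([rows, cols], axis=1)


def _width_radius_px(width_um: float, ps: float) -> int:
    """Dilation radius giving a ribbon of roughly the requested width."""
    return max(int(round(width_um / (2 * ps) - 0.5)), 0)


def rasterize_polylines(
    shape: tuple[int, int], polylines_um: list[np.ndarray], ps: float, width_um: float
) -> np.ndarray:
    """Boolean ribbon mask of a set of polylines at a common width."""
    canvas = np.zeros(shape, dtype=bool)
    for poly in polylines_um:
        px = _to_px(poly, ps)
        px = np.clip(px, 0, [shape[0] - 1, shape[1] - 1])
        for (r0, c0), (r1, c1) in zip(px[:-1], px[1:]):
            rr, cc = draw_line(r0, c0, r1, c1)
            canvas[rr, cc] = True
    r = _width_radius_px(width_um, ps)
    if r > 0 and canvas.any():
        canvas = grey_dilation_op(canvas, disk_footprint(r))
    return canvas


def rasterize_disk(
    canvas: np.ndarray, center_um: np.ndarray, radius_um: float, ps: float,
    value: float = 1.0, mode: str = "max",
) -> None:
    """Stamp a filled disk onto ``canvas`` (max-composited)."""
    rows, cols = canvas.shape
    r0, c0 = _to_px(center_um, ps)[0]
    rad = radius_um / ps
    lo_r, hi_r = max(int(r0 - rad) - 1, 0), min(int(r0 + rad) + 2, rows)
    lo_c, hi_c = max(int(c0 - rad) - 1, 0), min(int(c0 + rad) + 2, cols)
    if lo_r >= hi_r or lo_c >= hi_c:
        return
    yy, xx = np.mgrid[lo_r:hi_r, lo_c:hi_c]
    mask = (yy - r0) ** 2 + (xx - c0) ** 2 <= rad**2
    patch = canvas[lo_r:hi_r, lo_c:hi_c]
    if mode == "max":
        patch[mask] = np.maximum(patch[mask], value)
    else:
        patch[mask] += value


def _background_plane(shape, level: float, gradient: float, rng) -> np.ndarray:
    rows, cols = shape
    gx = rng.uniform(-gradient, gradient)
    gy = rng.uniform(-gradient, gradient)
    y = (np.arange(rows) / max(rows - 1, 1) - 0.5)[:, None]
    x = (np.arange(cols) / max(cols - 1, 1) - 0.5)[None, :]
    return level * (1.0 + gx * x + gy * y)


def _check_resolvable(gt: SceneGroundTruth, cfg: RenderConfig) -> None:
    if any(n.axon is not None for n in gt.neurons):
        px_across = 1.0 / cfg.pixel_size  # px across the 1 µm swelling threshold
        if px_across < 2.0:
            raise ValueError(
                f"pixel_size {cfg.pixel_size} µm/px too coarse: the 1 µm swelling "
                f"threshold spans {px_across:.2f} px (<2); use finer sampling"
            )


def render_scene(
    gt: SceneGroundTruth,
    cfg: RenderConfig | None = None,
    seed: int = 0,
    channels: tuple[str, ...] | None = None,
) -> dict[str, ChannelImage]:
    """Render the requested channels of one scene.

    Same (scene, config, seed) gives bit-identical images. When ``channels``
    is None, DAPI/TUBB3/actin are rendered, plus TAU1+MAP2 if the scene has
    axons.
    """
    cfg = cfg or RenderConfig()
    _check_resolvable(gt, cfg)
    if channels is None:
        channels = ("DAPI", "TUBB3", "actin")
        if any(n.axon is not None for n in gt.neurons):
            channels = channels + ("TAU1", "MAP2")
    unknown = set(channels) - set(ALL_CHANNELS)
    if unknown:
        raise ValueError(f"unknown channels: {sorted(unknown)}")

    ps = cfg.pixel_size
    shape = cfg.shape
    rng = np.random.default_rng(seed)
    g = cfg.gains
    out: dict[str, ChannelImage] = {}

    for ch in channels:
        signal = np.zeros(shape, dtype=np.float64)
        if ch == "DAPI":
            for n in gt.neurons:
                rasterize_disk(signal, n.soma_center, n.nucleus_radius, ps, g["DAPI"])
            for center, radius in gt.debris:
                rasterize_disk(signal, center, radius, ps, g["debris"])
        elif ch == "TUBB3":
            neurite_polys = [
                b.vertices for n in gt.neurons if n.is_neuron for b in n.neurite_trees
            ]
            widths = {b.width for n in gt.neurons if n.is_neuron for b in n.neurite_trees}
            for w in sorted(widths):
                ribbon = rasterize_polylines(
                    shape,
                    [b.vertices for n in gt.neurons if n.is_neuron
                     for b in n.neurite_trees if b.width == w],
                    ps, w,
                )
                signal[ribbon] = np.maximum(signal[ribbon], g["TUBB3_neurite"])
            for n in gt.neurons:
                if n.is_neuron:
                    rasterize_disk(signal, n.soma_center, n.soma_radius, ps, g["TUBB3_soma"])
        elif ch == "actin":
            ribbon = rasterize_polylines(
                shape,
                [b.vertices for n in gt.neurons if n.is_neuron for b in n.neurite_trees],
                ps, 0.8,
            )
            signal[ribbon] = np.maximum(signal[ribbon], g["actin_neurite"])
            for n in gt.neurons:
                for cone in n.growth_cones:
                    radius = math.sqrt(cone.area / math.pi)
                    rasterize_disk(signal, cone.tip, radius, ps, g["actin_cone"])
        elif ch == "TAU1":
            axons = [n.axon for n in gt.neurons if n.axon is not None]
            if axons:
                widths = {a.width for a in axons}
                for w in sorted(widths):
                    ribbon = rasterize_polylines(
                        shape, [a.vertices for a in axons if a.width == w], ps, w
                    )
                    signal[ribbon] = np.maximum(signal[ribbon], g["TAU1"])
                for a in axons:
                    for s, diam in a.swellings:
                        pos = a.point_at_arc(s)
                        amp = g["TAU1"] * min(diam / a.width, 8.0)
                        rasterize_disk(signal, pos, diam / 2.0, ps, amp)
        elif ch == "MAP2":
            dend = [b.vertices for n in gt.neurons for b in n.dendrites]
            if dend:
                ribbon = rasterize_polylines(shape, dend, ps, 1.2)
                signal[ribbon] = np.maximum(signal[ribbon], g["MAP2"])
        elif ch in ("TBR1", "CTIP2"):
            flag = "tbr1" if ch == "TBR1" else "ctip2"
            for n in gt.neurons:
                if getattr(n, flag):
                    rasterize_disk(signal, n.soma_center, n.nucleus_radius, ps, g[ch])

        img = signal + _background_plane(
            shape, cfg.background.get(ch, 400.0), cfg.background_gradient, rng
        )
        if cfg.psf_sigma > 0:
            img = ndi.gaussian_filter(img, sigma=cfg.psf_sigma / ps)
        if cfg.noise:
            img = rng.poisson(np.clip(img, 0, None) * cfg.photon_scale) / cfg.photon_scale
            img = img + rng.normal(0.0, cfg.read_noise_sd, size=shape)
        img = np.clip(np.round(img), 0, cfg.max_value).astype(np.uint16)
        out[ch] = ChannelImage(data=img, pixel_size=ps, channel=ch)
    return out
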