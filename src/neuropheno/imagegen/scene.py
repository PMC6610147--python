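"""Ground-truth scene sampling.

A scene is one simulated field of view of a sparse post-mitotic neuronal
culture: single-neuron somata with non-overlapping nuclei (except for a
requested fraction of deliberately touching pairs), branching neurite trees
whose total arc length per neuron follows the preset's lognormal law plus a
between-replicate shift, actin-rich growth cones at neurite leaves, optional
sub-micron axons carrying bead-like swellings placed by a homogeneous Poisson
process along the arc, and a contingent of small pyknotic (dead-cell) nuclei.

Default field geometry (332.8 µm square, 25 neurons) reproduces the assay
plating density of ~20,000 cells/cm² used for the 24-hour outgrowth read-out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .presets import Preset, get_preset

DEFAULT_FIELD_UM = 332.8  # 1024 px at 0.325 µm/px
DEFAULT_NEURONS_PER_FIELD = 25  # ≈ 2.2e4 cells/cm² in the default field


@dataclass
class Branch:
    """One neurite branch: an open polyline with a drawing width."""

    vertices: np.ndarray  # (N, 2) float, (x, y) µm
    width: float  # µm
    parent: int = -1  # index of parent branch, -1 for roots

    @property
    def arc_length(self) -> float:
        d = np.diff(self.vertices, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    @property
    def tip(self) -> np.ndarray:
        return self.vertices[-1]


@dataclass
class GrowthConeTruth:
    tip: np.ndarray  # (x, y) µm, coincides with a neurite leaf vertex
    area: float  # µm²


@dataclass
class AxonTruth:
    vertices: np.ndarray  # (N, 2) µm
    width: float  # µm baseline
    swellings: list[tuple[float, float]] = field(default_factory=list)  # (arc µm, diameter µm)

    @property
    def arc_length(self) -> float:
        d = np.diff(self.vertices, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def point_at_arc(self, s: float) -> np.ndarray:
        """Interpolate the (x, y) position at arc position ``s`` µm."""
        d = np.hypot(*np.diff(self.vertices, axis=0).T)
        cum = np.concatenate([[0.0], np.cumsum(d)])
        s = min(max(s, 0.0), cum[-1])
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(i, len(d) - 1)
        t = 0.0 if d[i] == 0 else (s - cum[i]) / d[i]
        return self.vertices[i] * (1 - t) + self.vertices[i + 1] * t


@dataclass
class NeuronTruth:
    id: int
    soma_center: np.ndarray  # (x, y) µm
    nucleus_radius: float  # µm
    soma_radius: float  # µm
    is_neuron: bool  # TUBB3+
    is_projection: bool  # TBR1 or CTIP2 positive
    tbr1: bool
    ctip2: bool
    neurite_trees: list[Branch] = field(default_factory=list)
    total_neurite_length: float = 0.0  # µm, sum of branch arc lengths
    growth_cones: list[GrowthConeTruth] = field(default_factory=list)
    axon: AxonTruth | None = None
    dendrites: list[Branch] = field(default_factory=list)  # MAP2+ processes


@dataclass
class SceneGroundTruth:
    preset_name: str
    seed: int
    field_size: tuple[float, float]  # (width, height) µm
    neurons: list[NeuronTruth]
    debris: list[tuple[np.ndarray, float]]  # dead-cell nuclei: (center µm, radius µm)
    replicate_shift: float = 0.0  # µm added to the neurite-length mean
    growth_cone_shift: float = 0.0  # µm² added to the cone-area mean

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    def total_axon_length(self) -> float:
        return sum(n.axon.arc_length for n in self.neurons if n.axon is not None)

    def n_swellings(self) -> int:
        return sum(len(n.axon.swellings) for n in self.neurons if n.axon is not None)


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size=None):
    """Lognormal with the requested arithmetic mean and coefficient of variation."""
    sigma2 = math.log1p(cv * cv)
    mu = math.log(max(mean, 1e-9)) - sigma2 / 2
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def draw_replicate_shift(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    mean_range: tuple[float, float] | None,
) -> float:
    """Between-replicate additive shift.

    Normal(0, sd), rejected until the shifted mean lies inside ``mean_range``
    (the published range of replicate means) when one is given.
    """
    if sd <= 0:
        return 0.0
    lo, hi = mean_range if mean_range is not None else (mean - 4 * sd, mean + 4 * sd)
    for _ in range(10_000):
        s = float(rng.normal(0.0, sd))
        if lo <= mean + s <= hi:
            return s
    return 0.0  # pragma: no cover - unreachable for sane parameters


def _walk(
    rng: np.random.Generator,
    start: np.ndarray,
    theta: float,
    length: float,
    field_size: tuple[float, float],
    step: float = 2.0,
    turn_sd: float = 0.18,
    margin: float = 2.0,
) -> tuple[np.ndarray, float]:
    """Persistent random walk of exact arc length, reflected at field borders.

    Step and turning noise are kept gentle so the curvature radius stays well
    above the ribbon width and PSF scale; sub-resolution wiggle would be
    erased by rendering and make ground-truth arc length unrecoverable by any
    measurement. Returns the polyline and the final heading.
    """
    w, h = field_size
    pts = [np.asarray(start, dtype=float)]
    remaining = float(length)
    while remaining > 1e-9:
        d = min(step, remaining)
        theta += rng.normal(0.0, turn_sd)
        for _ in range(4):  # reflect until inside (corner needs two flips)
            nxt = pts[-1] + d * np.array([math.cos(theta), math.sin(theta)])
            if nxt[0] < margin or nxt[0] > w - margin:
                theta = math.pi - theta
            elif nxt[1] < margin or nxt[1] > h - margin:
                theta = -theta
            else:
                break
        nxt = np.clip(nxt, margin, [w - margin, h - margin])
        pts.append(nxt)
        remaining -= d
    return np.array(pts), theta


def _grow_tree(
    rng: np.random.Generator,
    origin: np.ndarray,
    theta: float,
    length: float,
    width: float,
    field_size: tuple[float, float],
    branch_prob: float = 0.35,
) -> tuple[list[Branch], list[tuple[np.ndarray, float]]]:
    """Grow one root neurite of exact total arc length ``length``.

    With probability ``branch_prob`` (and enough length) the root bifurcates
    once; leaves are returned as (tip position, heading).
    """
    branches: list[Branch] = []
    leaves: list[tuple[np.ndarray, float]] = []
    if length > 12.0 and rng.random() < branch_prob:
        stem_len = length * rng.uniform(0.35, 0.65)
        stem, theta_end = _walk(rng, origin, theta, stem_len, field_size)
        branches.append(Branch(vertices=stem, width=width))
        rest = length - stem_len
        split = rng.beta(2.0, 2.0)
        for frac, sign in ((split, 1.0), (1.0 - split, -1.0)):
            dtheta = sign * rng.uniform(0.3, 0.9)
            child, th = _walk(rng, stem[-1], theta_end + dtheta, rest * frac, field_size)
            branches.append(Branch(vertices=child, width=width, parent=0))
            leaves.append((child[-1], th))
    else:
        poly, th = _walk(rng, origin, theta, length, field_size)
        branches.append(Branch(vertices=poly, width=width))
        leaves.append((poly[-1], th))
    return branches, leaves


def _place_somata(
    rng: np.random.Generator,
    n: int,
    radii: np.ndarray,
    field_size: tuple[float, float],
    touching_fraction: float,
) -> np.ndarray:
    """Dart-throwing placement; a requested fraction of nuclei placed as
    touching pairs to exercise seed-based splitting downstream."""
    w, h = field_size
    margin = 6.0
    n_pairs = int(round(touching_fraction * n / 2.0))
    centers: list[np.ndarray] = []

    def far_enough(p: np.ndarray, r: float, slack: float = 1.5) -> bool:
        return all(
            np.hypot(*(p - q)) >= r + radii[j] + slack for j, q in enumerate(centers)
        )

    i = 0
    while i < n - n_pairs:
        for _ in range(200):
            p = rng.uniform([margin, margin], [w - margin, h - margin])
            if far_enough(p, radii[i]):
                centers.append(p)
                i += 1
                break
        else:  # crowded field: accept closest-effort placement
            centers.append(rng.uniform([margin, margin], [w - margin, h - margin]))
            i += 1
    for _ in range(n_pairs):
        for _ in range(200):
            j = int(rng.integers(0, len(centers)))
            ang = rng.uniform(0, 2 * math.pi)
            dist = radii[j] + radii[i] - 0.3  # just touching
            p = centers[j] + dist * np.array([math.cos(ang), math.sin(ang)])
            if (
                margin <= p[0] <= w - margin
                and margin <= p[1] <= h - margin
                and all(
                    np.hypot(*(p - q)) >= radii[i] + radii[k] - 0.5
                    for k, q in enumerate(centers)
                    if k != j
                )
            ):
                centers.append(p)
                i += 1
                break
        else:
            centers.append(rng.uniform([margin, margin], [w - margin, h - margin]))
            i += 1
    return np.array(centers) if centers else np.zeros((0, 2))


def sample_scene(
    preset: Preset | str,
    n_neurons: int,
    seed: int,
    field_size: tuple[float, float] = (DEFAULT_FIELD_UM, DEFAULT_FIELD_UM),
    replicate_shift: float | None = None,
    growth_cone_shift: float | None = None,
    touching_fraction: float = 0.08,
    debris_fraction: float = 0.10,
) -> SceneGroundTruth:
    """Sample the full ground truth of one field of view.

    Same (preset, n_neurons, seed, options) gives bit-identical output.
    ``replicate_shift`` / ``growth_cone_shift`` override the per-replicate
    random effects (pass 0.0 to sample the pure cell-level distribution);
    when ``None`` they are drawn from the scene's own generator, i.e. a
    standalone scene is its own replicate.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if n_neurons < 0:
        raise ValueError("n_neurons must be non-negative")
    rng = np.random.default_rng(seed)

    if replicate_shift is None:
        replicate_shift = draw_replicate_shift(
            rng, preset.neurite_length_mean, preset.replicate_effect_sd,
            preset.neurite_length_range,
        )
    if growth_cone_shift is None:
        growth_cone_shift = draw_replicate_shift(
            rng, preset.growth_cone_area_mean, preset.growth_cone_effect_sd,
            preset.growth_cone_area_range,
        )
    len_mean = max(preset.neurite_length_mean + replicate_shift, 5.0)
    cone_mean = max(preset.growth_cone_area_mean + growth_cone_shift, 2.5)

    radii = rng.uniform(3.2, 3.9, size=max(n_neurons, 1))[:n_neurons]
    centers = _place_somata(rng, n_neurons, radii, field_size, touching_fraction)

    neurons: list[NeuronTruth] = []
    for i in range(n_neurons):
        r_n = float(radii[i])
        c = centers[i]
        is_neuron = bool(rng.random() < preset.fraction_neurons)
        is_proj = bool(is_neuron and rng.random() < preset.fraction_projection)
        tbr1 = ctip2 = False
        if is_proj:
            while not (tbr1 or ctip2):
                tbr1 = bool(rng.random() < 0.55)
                ctip2 = bool(rng.random() < 0.65)
        neuron = NeuronTruth(
            id=i + 1,
            soma_center=c,
            nucleus_radius=r_n,
            soma_radius=r_n + 0.5,
            is_neuron=is_neuron,
            is_projection=is_proj,
            tbr1=tbr1,
            ctip2=ctip2,
        )
        if is_neuron:
            total = float(_lognormal(rng, len_mean, preset.neurite_length_cv))
            n_roots = int(rng.choice([1, 2, 3], p=[0.3, 0.5, 0.2]))
            weights = rng.dirichlet(np.full(n_roots, 2.0))
            base_angle = rng.uniform(0, 2 * math.pi)
            offset = 0
            for k in range(n_roots):
                theta = base_angle + k * 2 * math.pi / n_roots + rng.normal(0, 0.3)
                origin = c + (neuron.soma_radius) * np.array(
                    [math.cos(theta), math.sin(theta)]
                )
                origin = np.clip(origin, 2.0, np.array(field_size) - 2.0)
                branches, leaves = _grow_tree(
                    rng, origin, theta, total * weights[k], preset.neurite_width,
                    field_size,
                )
                for b in branches:
                    if b.parent >= 0:
                        b.parent += offset
                neuron.neurite_trees.extend(branches)
                offset = len(neuron.neurite_trees)
                for tip, _ in leaves:
                    if rng.random() < preset.growth_cone_prob:
                        area = float(
                            _lognormal(rng, cone_mean, preset.growth_cone_area_cv)
                        )
                        neuron.growth_cones.append(
                            GrowthConeTruth(tip=tip.copy(), area=area)
                        )
            neuron.total_neurite_length = float(
                sum(b.arc_length for b in neuron.neurite_trees)
            )
            if preset.has_axons:
                ax_len = float(
                    _lognormal(rng, preset.axon_length_mean, preset.axon_length_cv)
                )
                theta = rng.uniform(0, 2 * math.pi)
                poly, _ = _walk(
                    rng, c, theta, ax_len, field_size, step=3.0, turn_sd=0.15
                )
                axon = AxonTruth(vertices=poly, width=preset.axon_baseline_width)
                arc = axon.arc_length
                n_sw = int(rng.poisson(preset.swelling_rate * arc / 1000.0))
                lo, hi = preset.swelling_diameter_range
                # swellings sit mostly distally, clear of the soma-proximal
                # stretch where dendrites fasciculate with the axon
                start = min(max(0.2 * arc, 20.0), 0.5 * arc)
                positions = np.sort(rng.uniform(start, max(arc - 4.0, start), n_sw))
                for s in positions:
                    axon.swellings.append((float(s), float(rng.uniform(lo, hi))))
                neuron.axon = axon
                for _d in range(2):  # MAP2+ dendrites
                    th = rng.uniform(0, 2 * math.pi)
                    dpoly, _ = _walk(
                        rng, c, th, rng.uniform(40.0, 90.0), field_size,
                        step=2.0, turn_sd=0.2,
                    )
                    neuron.dendrites.append(Branch(vertices=dpoly, width=1.2))
        neurons.append(neuron)

    debris: list[tuple[np.ndarray, float]] = []
    n_debris = int(round(debris_fraction * n_neurons))
    w, h = field_size
    for _ in range(n_debris):
        for _ in range(100):
            p = rng.uniform([4.0, 4.0], [w - 4.0, h - 4.0])
            if all(np.hypot(*(p - n.soma_center)) > n.nucleus_radius + 4.0 for n in neurons):
                break
        debris.append((p, float(rng.uniform(1.3, 2.0))))

    return SceneGroundTruth(
        preset_name=preset.name,
        seed=seed,
        field_size=tuple(field_size),
        neurons=neurons,
        debris=debris,
        replicate_shift=float(replicate_shift),
        growth_cone_shift=float(growth_cone_shift),
    )
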