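"""End-to-end orchestration: simulate -> segment -> measure -> aggregate -> compare.

A run is described by a single :class:`RunConfig` (optionally loaded from
YAML). In simulate mode each biological replicate is a set of fields of view
sharing one between-replicate random effect; replicate seeds derive as
``base_seed + replicate_index`` so every number in the output tables is
reproducible from the manifest alone.
"""

from __future__ import annotations

import glob
import math
import os
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .composition import call_markers
from .growthcones import GrowthConeParams, detect_growth_cones
from .image import ChannelImage, read_channel_tiff
from .imagegen import RenderConfig, get_preset, render_scene, sample_scene
from .imagegen.scene import draw_replicate_shift
from .neurites import measure_neurites
from .nuclei import NucleiParams, segment_nuclei
from .stats import (
    GroupComparison,
    aggregate,
    comparisons_table,
    mann_whitney_u,
    t_test_unpaired,
    two_way_anova,
)
from .swellings import AxonSegParams, detect_swellings, segment_axons, swellings_table

REQUIRED_CHANNELS = {
    "outgrowth": ("DAPI", "TUBB3"),
    "growthcone": ("DAPI", "TUBB3", "actin"),
    "swelling": ("TAU1",),
    "composition": ("DAPI", "TUBB3", "TBR1", "CTIP2"),
}

DEFAULT_NEURONS_PER_IMAGE = 25


@dataclass
class Condition:
    name: str
    preset: str = ""
    genotype: str = ""
    treatment: str = "untreated"


@dataclass
class RunConfig:
    assay: str  # outgrowth | growthcone | swelling | composition
    conditions: list[Condition]
    mode: str = "simulate"  # simulate | images
    n_neurons: int = 300  # per replicate (simulate mode)
    replicates: int = 3
    images_per_replicate: int | None = None
    seed: int = 0
    out_dir: str = "out"
    image_dir: str | None = None
    channel_map: dict = dc_field(default_factory=dict)  # channel -> glob pattern
    pixel_size: float = 0.325
    min_cells: int = 100
    min_images: int = 10
    render: RenderConfig = dc_field(default_factory=RenderConfig)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        conds = [Condition(**c) for c in raw.pop("conditions")]
        render = RenderConfig(**raw.pop("render", {}))
        return cls(conditions=conds, render=render, **raw)

    def validate(self) -> None:
        if self.assay not in REQUIRED_CHANNELS:
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.mode == "simulate":
            for c in self.conditions:
                get_preset(c.preset)  # raises on unknown
                if self.assay == "swelling" and not get_preset(c.preset).has_axons:
                    raise ValueError(f"preset {c.preset!r} has no axons for the swelling assay")
        elif self.mode == "images":
            if not self.image_dir:
                raise ValueError("images mode requires image_dir")
            for ch in REQUIRED_CHANNELS[self.assay]:
                pattern = self.channel_map.get(ch, f"*{ch}*.tif")
                if not glob.glob(os.path.join(self.image_dir, "**", pattern), recursive=True):
                    raise ValueError(
                        f"assay {self.assay!r} requires channel {ch!r}: no files match "
                        f"{pattern!r} under {self.image_dir}"
                    )
        else:
            raise ValueError(f"unknown mode {self.mode!r}")


# ---------------------------------------------------------------------------
# simulation of one biological replicate


def simulate_replicate(
    preset_name: str,
    n_neurons: int,
    seed: int,
    render_cfg: RenderConfig | None = None,
    channels: tuple[str, ...] | None = None,
    n_images: int | None = None,
    neurons_per_image: int = DEFAULT_NEURONS_PER_IMAGE,
):
    """Simulate one replicate: several fields sharing one replicate effect.

    Returns a list of (ground_truth, images) pairs.
    """
    preset = get_preset(preset_name)
    cfg = render_cfg or RenderConfig()
    rng = np.random.default_rng(seed)
    shift_len = draw_replicate_shift(
        rng, preset.neurite_length_mean, preset.replicate_effect_sd,
        preset.neurite_length_range,
    )
    shift_gc = draw_replicate_shift(
        rng, preset.growth_cone_area_mean, preset.growth_cone_effect_sd,
        preset.growth_cone_area_range,
    )
    if n_images is None:
        n_images = max(math.ceil(n_neurons / neurons_per_image), 1)
    counts = [n_neurons // n_images] * n_images
    for i in range(n_neurons - sum(counts)):
        counts[i] += 1
    field_um = (cfg.shape[1] * cfg.pixel_size, cfg.shape[0] * cfg.pixel_size)
    out = []
    for c in counts:
        scene_seed = int(rng.integers(2**31))
        render_seed = int(rng.integers(2**31))
        gt = sample_scene(
            preset, c, scene_seed, field_size=field_um,
            replicate_shift=shift_len, growth_cone_shift=shift_gc,
        )
        images = render_scene(gt, cfg, seed=render_seed, channels=channels)
        out.append((gt, images))
    return out


# ---------------------------------------------------------------------------
# per-image analyses


def analyze_outgrowth_image(
    images: dict[str, ChannelImage],
    with_cones: bool = False,
    nuclei_params: NucleiParams | None = None,
    cone_params: GrowthConeParams | None = None,
):
    """Nuclei + neurite stages (and optionally growth cones) on one field."""
    labels, nucleus_records = segment_nuclei(images["DAPI"], nuclei_params)
    cells, skel, mask = measure_neurites(images["TUBB3"], labels)
    cones = None
    if with_cones:
        cones = detect_growth_cones(images["actin"], mask, skel, cone_params)
    n_excluded = sum(r.excluded for r in nucleus_records)
    qc = {"n_nuclei": int(labels.n_labels), "n_excluded_nuclei": int(n_excluded)}
    return cells, cones, qc


def analyze_swelling_image(
    images: dict[str, ChannelImage], params: AxonSegParams | None = None
):
    """Axon segmentation + swelling detection on one field."""
    mask, skel = segment_axons(images["TAU1"], params, map2=images.get("MAP2"))
    length_mm = skel.total_length_um / 1000.0
    if length_mm <= 0:
        return {"length_mm": 0.0, "n_swellings": 0, "records": [], "flagged": True}
    records = detect_swellings(
        mask, skel, images["TAU1"].pixel_size, intensity=images["TAU1"].as_float()
    )
    return {
        "length_mm": length_mm,
        "n_swellings": len(records),
        "records": records,
        "flagged": False,
    }


def analyze_composition_image(
    images: dict[str, ChannelImage], nuclei_params: NucleiParams | None = None
):
    """Nucleus segmentation + marker calling on one field."""
    labels, _ = segment_nuclei(images["DAPI"], nuclei_params)
    if labels.n_labels == 0:
        return None, None
    markers = {k: images[k] for k in ("TUBB3", "TBR1", "CTIP2") if k in images}
    calls, summary = call_markers(labels, markers)
    return calls, summary


# ---------------------------------------------------------------------------
# full runs


def _sim_channels(assay: str) -> tuple[str, ...]:
    return {
        "outgrowth": ("DAPI", "TUBB3"),
        "growthcone": ("DAPI", "TUBB3", "actin"),
        "swelling": ("TAU1", "MAP2"),
        "composition": ("DAPI", "TUBB3", "TBR1", "CTIP2"),
    }[assay]


def run(config: RunConfig) -> dict:
    """Execute a full configured run and write the output bundle.

    Outputs under ``out_dir``: cells/cones/swellings CSVs, replicate
    summaries, group comparisons, a QC report and a run manifest. Fixed
    seed -> byte-identical outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    for sub in ("cells", "cones", "swellings", "summaries", "comparisons", "qc"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    cell_rows: list[pd.DataFrame] = []
    cone_rows: list[pd.DataFrame] = []
    swell_rows: list[pd.DataFrame] = []
    rate_rows: list[dict] = []
    comp_rows: list[dict] = []
    qc_entries: list[dict] = []

    with_cones = config.assay == "growthcone"
    for ci, cond in enumerate(config.conditions):
        for rep in range(config.replicates):
            rep_seed = int(config.seed + 1000 * ci + rep)
            scenes = simulate_replicate(
                cond.preset, config.n_neurons, rep_seed,
                render_cfg=config.render, channels=_sim_channels(config.assay),
                n_images=config.images_per_replicate,
            )
            rep_qc = {
                "condition": cond.name, "replicate": rep, "seed": rep_seed,
                "n_images": len(scenes), "warnings": [],
            }
            if config.assay in ("outgrowth", "growthcone"):
                n_cells = 0
                for img_i, (_, images) in enumerate(scenes):
                    cells, cones, _ = analyze_outgrowth_image(images, with_cones=with_cones)
                    cells = cells.assign(
                        condition=cond.name, genotype=cond.genotype,
                        treatment=cond.treatment, replicate=rep, image=img_i,
                    )
                    n_cells += len(cells)
                    cell_rows.append(cells)
                    if cones is not None and len(cones):
                        cone_rows.append(
                            cones.assign(
                                condition=cond.name, genotype=cond.genotype,
                                treatment=cond.treatment, replicate=rep, image=img_i,
                            )
                        )
                rep_qc["n_cells"] = n_cells
            elif config.assay == "swelling":
                length_mm = 0.0
                n_sw = 0
                for img_i, (_, images) in enumerate(scenes):
                    res = analyze_swelling_image(images)
                    if res["flagged"]:
                        rep_qc["warnings"].append(f"image {img_i}: empty TAU1 channel")
                        continue
                    length_mm += res["length_mm"]
                    n_sw += res["n_swellings"]
                    tab = swellings_table(res["records"])
                    if len(tab):
                        swell_rows.append(
                            tab.assign(condition=cond.name, genotype=cond.genotype,
                                       treatment=cond.treatment, replicate=rep, image=img_i)
                        )
                rate_rows.append(
                    {
                        "condition": cond.name, "genotype": cond.genotype,
                        "treatment": cond.treatment, "replicate": rep,
                        "length_mm": length_mm, "n_swellings": n_sw,
                        "rate_per_mm": (n_sw / length_mm) if length_mm > 0 else float("nan"),
                    }
                )
                rep_qc["length_mm"] = length_mm
            elif config.assay == "composition":
                for img_i, (_, images) in enumerate(scenes):
                    calls, summary = analyze_composition_image(images)
                    if summary is None:
                        rep_qc["warnings"].append(f"image {img_i}: no nuclei")
                        continue
                    comp_rows.append(
                        {"condition": cond.name, "replicate": rep, "image": img_i, **summary}
                    )
            if config.assay in ("outgrowth", "growthcone"):
                if rep_qc.get("n_cells", 0) < config.min_cells:
                    rep_qc["warnings"].append(
                        f"below min_cells gate ({rep_qc.get('n_cells', 0)} < {config.min_cells})"
                    )
            if rep_qc["n_images"] < config.min_images:
                rep_qc["warnings"].append(
                    f"below min_images gate ({rep_qc['n_images']} < {config.min_images})"
                )
            qc_entries.append(rep_qc)

    result: dict = {"qc": qc_entries}
    cells_df = pd.concat(cell_rows, ignore_index=True) if cell_rows else pd.DataFrame()
    cones_df = pd.concat(cone_rows, ignore_index=True) if cone_rows else pd.DataFrame()
    swell_df = pd.concat(swell_rows, ignore_index=True) if swell_rows else pd.DataFrame()
    rates_df = pd.DataFrame(rate_rows)
    comp_df = pd.DataFrame(comp_rows)

    comparisons: list[GroupComparison] = []
    summaries = pd.DataFrame()
    if config.assay == "outgrowth" and len(cells_df):
        summaries = aggregate(
            cells_df, ["condition", "genotype", "treatment", "replicate"],
            "total_neurite_length_um", min_cells=config.min_cells,
        )
        comparisons = _group_tests(summaries, "mean")
    elif config.assay == "growthcone" and len(cones_df):
        summaries = aggregate(
            cones_df, ["condition", "genotype", "treatment", "replicate"],
            "area_um2", min_cells=1,
        )
        comparisons = _group_tests(summaries, "mean")
    elif config.assay == "swelling" and len(rates_df):
        summaries = rates_df
        comparisons = _group_tests(rates_df, "rate_per_mm", test="t")
    elif config.assay == "composition" and len(comp_df):
        summaries = comp_df

    result.update(
        cells=cells_df, cones=cones_df, swellings=swell_df, rates=rates_df,
        composition=comp_df, summaries=summaries, comparisons=comparisons,
    )

    cells_df.to_csv(out / "cells" / "cell_records.csv", index=False)
    cones_df.to_csv(out / "cones" / "growth_cones.csv", index=False)
    swell_df.to_csv(out / "swellings" / "swellings.csv", index=False)
    if len(rates_df):
        rates_df.to_csv(out / "swellings" / "axon_summary.csv", index=False)
    if len(comp_df):
        comp_df.to_csv(out / "summaries" / "composition.csv", index=False)
    summaries.to_csv(out / "summaries" / "replicate_summaries.csv", index=False)
    comparisons_table(comparisons).to_csv(out / "comparisons" / "comparisons.csv", index=False)
    with open(out / "qc" / "qc_report.yaml", "w") as fh:
        yaml.safe_dump({"replicates": qc_entries}, fh, sort_keys=True)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(_manifest(config), fh, sort_keys=True)
    return result


def _group_tests(summaries: pd.DataFrame, value_col: str, test: str = "mw"):
    """Pairwise genotype contrast on replicate values; two-way ANOVA when
    several treatments are present."""
    comparisons: list[GroupComparison] = []
    gated = summaries[summaries["passed_gate"]] if "passed_gate" in summaries else summaries
    genotypes = [g for g in gated["genotype"].unique() if g]
    if len(genotypes) == 2:
        x = gated.loc[gated["genotype"] == genotypes[0], value_col].to_numpy()
        y = gated.loc[gated["genotype"] == genotypes[1], value_col].to_numpy()
        if len(x) and len(y):
            if test == "t" and len(x) > 1 and len(y) > 1:
                comparisons.append(t_test_unpaired(x, y))
            else:
                comparisons.append(mann_whitney_u(x, y))
    if "treatment" in gated and gated["treatment"].nunique() > 1 and len(genotypes) > 1:
        comparisons.extend(two_way_anova(gated, value_col))
    return comparisons


def _manifest(config: RunConfig) -> dict:
    return {
        "assay": config.assay,
        "mode": config.mode,
        "seed": int(config.seed),
        "n_neurons": int(config.n_neurons),
        "replicates": int(config.replicates),
        "images_per_replicate": config.images_per_replicate,
        "min_cells": int(config.min_cells),
        "min_images": int(config.min_images),
        "statistical_unit": "biological replicate",
        "conditions": [
            {"name": c.name, "preset": c.preset, "genotype": c.genotype, "treatment": c.treatment}
            for c in config.conditions
        ],
        "render": {
            "pixel_size": config.render.pixel_size,
            "shape": list(config.render.shape),
            "psf_sigma": config.render.psf_sigma,
            "noise": config.render.noise,
            "photon_scale": config.render.photon_scale,
            "read_noise_sd": config.render.read_noise_sd,
        },
    }


def load_image_set(directory: str | os.PathLike, channel_map: dict | None = None):
    """Read one field's channel TIFFs from a directory (images mode)."""
    channel_map = channel_map or {}
    images = {}
    for ch in ("DAPI", "TUBB3", "actin", "TAU1", "MAP2", "TBR1", "CTIP2"):
        pattern = channel_map.get(ch, f"*{ch}*.tif")
        hits = sorted(glob.glob(os.path.join(str(directory), pattern)))
        if hits:
            images[ch] = read_channel_tiff(hits[0], channel=ch)
    return images
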