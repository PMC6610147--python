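"""On-disk fixtures: rendered channels as TIFF, ground truth as CSV, YAML manifest."""

from __future__ import annotations

import os
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ..image import ChannelImage, write_channel_tiff
from .render import RenderConfig
from .scene import SceneGroundTruth


def ground_truth_tables(gt: SceneGroundTruth) -> dict[str, pd.DataFrame]:
    """Ground truth as flat tables: one row per neuron / growth cone / swelling."""
    neurons = pd.DataFrame(
        [
            {
                "neuron_id": n.id,
                "x_um": n.soma_center[0],
                "y_um": n.soma_center[1],
                "nucleus_radius_um": n.nucleus_radius,
                "is_neuron": n.is_neuron,
                "is_projection": n.is_projection,
                "tbr1": n.tbr1,
                "ctip2": n.ctip2,
                "total_neurite_length_um": n.total_neurite_length,
                "n_branches": len(n.neurite_trees),
                "n_growth_cones": len(n.growth_cones),
                "axon_length_um": n.axon.arc_length if n.axon else 0.0,
                "n_swellings": len(n.axon.swellings) if n.axon else 0,
            }
            for n in gt.neurons
        ]
    )
    cones = pd.DataFrame(
        [
            {
                "neuron_id": n.id,
                "tip_x_um": c.tip[0],
                "tip_y_um": c.tip[1],
                "area_um2": c.area,
            }
            for n in gt.neurons
            for c in n.growth_cones
        ]
    )
    swellings = pd.DataFrame(
        [
            {
                "neuron_id": n.id,
                "arc_position_um": s,
                "diameter_um": d,
                "x_um": n.axon.point_at_arc(s)[0],
                "y_um": n.axon.point_at_arc(s)[1],
            }
            for n in gt.neurons
            if n.axon is not None
            for (s, d) in n.axon.swellings
        ]
    )
    return {"neurons": neurons, "growth_cones": cones, "swellings": swellings}


def write_fixture(
    gt: SceneGroundTruth,
    images: dict[str, ChannelImage],
    out_dir: str | os.PathLike,
    render_config: RenderConfig | None = None,
    render_seed: int | None = None,
) -> dict[str, Path]:
    """Write per-channel 16-bit TIFFs, ground-truth CSVs and a YAML manifest.

    Re-running with identical seeds reproduces identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, img in images.items():
        p = out / f"{name}.tif"
        write_channel_tiff(p, img)
        paths[name] = p
    for table_name, df in ground_truth_tables(gt).items():
        p = out / f"truth_{table_name}.csv"
        df.to_csv(p, index=False, float_format="%.6f")
        paths[table_name] = p

    manifest = {
        "preset": gt.preset_name,
        "scene_seed": int(gt.seed),
        "render_seed": int(render_seed) if render_seed is not None else None,
        "n_neurons": gt.n_neurons,
        "field_size_um": [float(v) for v in gt.field_size],
        "replicate_shift_um": float(gt.replicate_shift),
        "growth_cone_shift_um2": float(gt.growth_cone_shift),
        "channels": sorted(images),
        "render_config": _config_dict(render_config) if render_config else None,
    }
    mpath = out / "manifest.yaml"
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    paths["manifest"] = mpath
    return paths


def _config_dict(cfg: RenderConfig) -> dict:
    d = asdict(cfg)
    d["shape"] = list(d["shape"])
    return d
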