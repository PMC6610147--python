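"""Reference assay protocols at the study's conditions.

These functions wire the simulator and the measurement stages together at
the canonical problem sizes used for parameter-recovery checks: a few
biological replicates of a few hundred neurons for the 24-hour outgrowth
and growth-cone assays, tens of millimetres of axon for the swelling assay,
and about a thousand nuclei for culture composition. Every function is
deterministic given its base seed (replicate seeds derive as base + index).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .imagegen import RenderConfig
from .pipeline import (
    analyze_composition_image,
    analyze_outgrowth_image,
    analyze_swelling_image,
    simulate_replicate,
)


def outgrowth_recovery(
    preset: str,
    n_replicates: int = 3,
    neurons_per_replicate: int = 300,
    base_seed: int = 0,
    with_cones: bool = True,
    render_cfg: RenderConfig | None = None,
) -> pd.DataFrame:
    """Run the full outgrowth (and optionally growth-cone) pipeline.

    Returns one row per biological replicate with the mean per-neuron total
    neurite length and the mean retained growth-cone area.
    """
    channels = ("DAPI", "TUBB3", "actin") if with_cones else ("DAPI", "TUBB3")
    rows = []
    for rep in range(n_replicates):
        scenes = simulate_replicate(
            preset, neurons_per_replicate, base_seed + rep + 1,
            render_cfg=render_cfg, channels=channels,
        )
        lengths: list[float] = []
        areas: list[float] = []
        for _, images in scenes:
            cells, cones, _ = analyze_outgrowth_image(images, with_cones=with_cones)
            lengths.extend(cells["total_neurite_length_um"])
            if cones is not None and len(cones):
                areas.extend(cones["area_um2"])
        rows.append(
            {
                "preset": preset,
                "replicate": rep,
                "n_cells": len(lengths),
                "mean_length_um": float(np.mean(lengths)) if lengths else np.nan,
                "n_cones": len(areas),
                "mean_cone_area_um2": float(np.mean(areas)) if areas else np.nan,
                "sum_length_um": float(np.sum(lengths)),
                "sum_cone_area_um2": float(np.sum(areas)),
            }
        )
    return pd.DataFrame(rows)


def grand_mean(table: pd.DataFrame, sum_col: str, n_col: str) -> float:
    """Cell-weighted grand mean over replicates."""
    return float(table[sum_col].sum() / table[n_col].sum())


def swelling_recovery(
    preset: str,
    n_replicates: int = 5,
    scenes_per_replicate: int = 4,
    axons_per_scene: int = 8,
    base_seed: int = 0,
    render_cfg: RenderConfig | None = None,
) -> pd.DataFrame:
    """Run axon segmentation + swelling detection over several replicates.

    Axon density is kept modest (8 axons per field) so the network stays
    thin and resolvable, as in taxol-primed day-50 cultures.
    """
    rows = []
    for rep in range(n_replicates):
        scenes = simulate_replicate(
            preset, axons_per_scene * scenes_per_replicate, base_seed + rep + 1,
            render_cfg=render_cfg, channels=("TAU1", "MAP2"),
            n_images=scenes_per_replicate,
        )
        length_mm = 0.0
        n_sw = 0
        for _, images in scenes:
            res = analyze_swelling_image(images)
            length_mm += res["length_mm"]
            n_sw += res["n_swellings"]
        rows.append(
            {
                "preset": preset,
                "replicate": rep,
                "length_mm": length_mm,
                "n_swellings": n_sw,
                "rate_per_mm": n_sw / length_mm if length_mm > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def pooled_rate(table: pd.DataFrame) -> float:
    """Total swellings over total axon length (per mm)."""
    return float(table["n_swellings"].sum() / table["length_mm"].sum())


def composition_recovery(
    n_nuclei: int = 1000,
    nuclei_per_scene: int = 125,
    base_seed: int = 0,
    render_cfg: RenderConfig | None = None,
) -> dict[str, float]:
    """Composition preset scenes totalling ``n_nuclei`` nuclei.

    Returns pooled percentages: TUBB3+ among retained nuclei and
    TBR1-or-CTIP2+ among TUBB3+ cells.
    """
    n_scenes = max(int(np.ceil(n_nuclei / nuclei_per_scene)), 1)
    scenes = simulate_replicate(
        "composition", n_nuclei, base_seed + 1,
        render_cfg=render_cfg,
        channels=("DAPI", "TUBB3", "TBR1", "CTIP2"),
        n_images=n_scenes,
    )
    n_total = n_tubb3 = n_proj = 0
    for _, images in scenes:
        calls, _ = analyze_composition_image(images)
        if calls is None:
            continue
        n_total += len(calls)
        n_tubb3 += int(calls["tubb3"].sum())
        n_proj += int((calls["tubb3"] & calls["projection"]).sum())
    return {
        "n_nuclei": float(n_total),
        "pct_tubb3": 100.0 * n_tubb3 / n_total if n_total else np.nan,
        "pct_projection": 100.0 * n_proj / n_tubb3 if n_tubb3 else np.nan,
    }
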