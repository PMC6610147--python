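"""Named simulation presets.

A preset bundles the ground-truth phenotype distributions of one experimental
condition: per-neuron total neurite length at 24 h after replating, growth-cone
area, axonal swelling burden at day 50, and culture composition fractions.
The built-in presets encode the group-level statistics reported for
SPG4-patient versus control iPSC-derived cortical neurons (spastin
haploinsufficiency halves neurite outgrowth, roughly two-and-a-half-folds
growth-cone area, and raises the swelling rate from 0.07 to 1.54 per mm axon),
plus a GABAergic pair that deliberately shares one parameter set to model the
reported absence of a genotype effect in inhibitory neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class Preset:
    """Ground-truth parameter bundle for one condition.

    Length/area distributions are lognormal (right-skewed, positive support)
    with the given mean and coefficient of variation; a per-replicate random
    effect shifts the mean additively, drawn Normal(0, ``replicate_effect_sd``)
    truncated so the shifted mean stays inside ``neurite_length_range`` /
    ``growth_cone_area_range`` (the published between-replicate ranges).
    """

    name: str
    neurite_length_mean: float  # µm
    neurite_length_cv: float = 0.5
    replicate_effect_sd: float = 0.0  # µm, between-replicate random effect
    neurite_length_range: tuple[float, float] | None = None  # µm, replicate means
    growth_cone_area_mean: float = 11.2  # µm²
    growth_cone_area_cv: float = 0.4
    growth_cone_effect_sd: float = 0.0  # µm², between-replicate
    growth_cone_area_range: tuple[float, float] | None = None
    swelling_rate: float = 0.0  # per mm axon
    swelling_diameter_range: tuple[float, float] = (1.0, 7.0)  # µm
    axon_baseline_width: float = 0.6  # µm
    has_axons: bool = False
    axon_length_mean: float = 400.0  # µm per axon
    axon_length_cv: float = 0.3
    fraction_neurons: float = 1.0
    fraction_projection: float = 0.921
    neurite_width: float = 0.8  # µm
    growth_cone_prob: float = 0.8  # one cone per neurite leaf with this prob

    def __post_init__(self) -> None:
        if self.neurite_length_mean < 0 or self.growth_cone_area_mean < 0:
            raise ValueError("means must be non-negative")
        if self.swelling_rate < 0:
            raise ValueError("swelling_rate must be non-negative")
        if not (0 <= self.fraction_neurons <= 1 and 0 <= self.fraction_projection <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.has_axons and self.swelling_diameter_range[0] <= self.axon_baseline_width:
            raise ValueError("swelling diameters must exceed the baseline axon width")


_PRESETS: dict[str, Preset] = {}


def register_preset(preset: Preset, overwrite: bool = False) -> None:
    if preset.name in _PRESETS and not overwrite:
        raise ValueError(f"preset {preset.name!r} already registered")
    _PRESETS[preset.name] = preset


def get_preset(name: str) -> Preset:
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None


def available_presets() -> list[str]:
    return sorted(_PRESETS)


# 24-hour outgrowth / growth-cone assay conditions (replated day-57 neurons,
# fixed after exactly 24 h; only DAPI/TUBB3/actin are meaningful).
register_preset(
    Preset(
        name="control-24h",
        neurite_length_mean=60.6,
        replicate_effect_sd=11.1,
        neurite_length_range=(39.0, 75.0),
        growth_cone_area_mean=11.2,
        growth_cone_effect_sd=0.9,
        growth_cone_area_range=(4.0, 17.0),
    )
)
register_preset(
    Preset(
        name="spg4-24h",
        neurite_length_mean=29.4,
        replicate_effect_sd=5.4,
        neurite_length_range=(17.0, 39.0),
        growth_cone_area_mean=27.9,
        growth_cone_effect_sd=1.0,
        growth_cone_area_range=(20.0, 37.0),
    )
)

# Day-50 taxol-primed cultures: TAU1+ axons with bead-like swellings, MAP2+
# dendrites. Neurite/growth-cone parameters are nominal only.
register_preset(
    Preset(
        name="control-d50",
        neurite_length_mean=45.0,
        swelling_rate=0.07,
        has_axons=True,
    )
)
register_preset(
    Preset(
        name="spg4-d50",
        neurite_length_mean=45.0,
        swelling_rate=1.54,
        has_axons=True,
    )
)

# GABAergic pair: identical parameters by design (the genotype null result).
_gaba = Preset(
    name="gaba-control",
    neurite_length_mean=55.0,
    replicate_effect_sd=8.0,
    growth_cone_area_mean=12.0,
    growth_cone_effect_sd=1.0,
    swelling_rate=0.1,
    has_axons=True,
)
register_preset(_gaba)
register_preset(replace(_gaba, name="gaba-spg4"))

# Differentiation-characterization scenes: mixed culture with a small
# non-neuronal fraction and deep-layer marker identities.
register_preset(
    Preset(
        name="composition",
        neurite_length_mean=35.0,
        fraction_neurons=0.977,
        fraction_projection=0.921,
    )
)
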