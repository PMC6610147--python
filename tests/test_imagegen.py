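"""Simulator: ground-truth sampling, rendering, and on-disk fixtures."""

import math

import numpy as np
import pandas as pd
import pytest
import tifffile

from neuropheno.image import read_channel_tiff
from neuropheno.imagegen import (
    RenderConfig,
    get_preset,
    ground_truth_tables,
    render_scene,
    sample_scene,
    write_fixture,
)
from neuropheno.imagegen.scene import AxonTruth, Branch, NeuronTruth, SceneGroundTruth


def _scene_fingerprint(gt):
    tables = ground_truth_tables(gt)
    return {k: v.round(9) for k, v in tables.items()}


class TestSampling:
    def test_empty_scene(self):
        gt = sample_scene("control-24h", 0, seed=7)
        assert gt.n_neurons == 0
        assert gt.neurons == []

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError, match="unknown preset"):
            sample_scene("no-such-preset", 10, seed=1)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            sample_scene("control-24h", -1, seed=1)

    def test_seeded_determinism(self):
        a = sample_scene("spg4-d50", 200, seed=3)
        b = sample_scene("spg4-d50", 200, seed=3)
        fa, fb = _scene_fingerprint(a), _scene_fingerprint(b)
        for key in fa:
            pd.testing.assert_frame_equal(fa[key], fb[key])
        for na, nb in zip(a.neurons, b.neurons):
            for ba, bb in zip(na.neurite_trees, nb.neurite_trees):
                np.testing.assert_array_equal(ba.vertices, bb.vertices)

    def test_total_length_equals_branch_sum(self):
        gt = sample_scene("control-24h", 60, seed=11)
        for n in gt.neurons:
            if n.is_neuron:
                total = sum(b.arc_length for b in n.neurite_trees)
                assert abs(total - n.total_neurite_length) < 1e-6

    def test_growth_cones_sit_on_leaves(self):
        gt = sample_scene("control-24h", 60, seed=12)
        for n in gt.neurons:
            leaf_tips = {tuple(np.round(b.tip, 9)) for b in n.neurite_trees}
            for cone in n.growth_cones:
                assert tuple(np.round(cone.tip, 9)) in leaf_tips

    def test_swelling_diameters_in_preset_range(self):
        gt = sample_scene("spg4-d50", 40, seed=13)
        lo, hi = get_preset("spg4-d50").swelling_diameter_range
        diams = [d for n in gt.neurons if n.axon for _, d in n.axon.swellings]
        assert diams, "expected some swellings at 1.54/mm"
        assert all(lo <= d <= hi for d in diams)

    def test_nuclei_do_not_overlap_beyond_touching_request(self):
        gt = sample_scene("control-24h", 40, seed=14, touching_fraction=0.0)
        centers = np.array([n.soma_center for n in gt.neurons])
        radii = np.array([n.nucleus_radius for n in gt.neurons])
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                d = np.hypot(*(centers[i] - centers[j]))
                assert d >= radii[i] + radii[j]

    def test_moment_fidelity_mean_and_cv_within_2pct(self):
        # cell-level law at zero replicate shift, pooled over many scenes
        preset = get_preset("control-24h")
        lengths = []
        for s in range(20):
            gt = sample_scene(
                "control-24h", 500, seed=1000 + s,
                replicate_shift=0.0, growth_cone_shift=0.0,
            )
            lengths += [n.total_neurite_length for n in gt.neurons]
        lengths = np.asarray(lengths)
        assert len(lengths) == 10_000
        mean, cv = lengths.mean(), lengths.std() / lengths.mean()
        assert abs(mean / preset.neurite_length_mean - 1) < 0.02
        assert abs(cv / preset.neurite_length_cv - 1) < 0.02

    @pytest.mark.parametrize(
        "preset,lo,hi", [("control-24h", 39.0, 75.0), ("spg4-24h", 17.0, 39.0)]
    )
    def test_replicate_means_fall_in_published_range(self, preset, lo, hi):
        """Per-replicate (n=100) ground-truth means stay in the published
        between-replicate range in at least 95% of 200 replicates."""
        hits = 0
        for rep in range(200):
            gt = sample_scene(preset, 100, seed=20_000 + rep)
            m = np.mean([n.total_neurite_length for n in gt.neurons])
            hits += lo <= m <= hi
        assert hits >= 190


class TestRendering:
    def _single_neurite_scene(self):
        vertices = np.array([[60.0, 100.0], [110.0, 100.0]])  # straight 50 µm
        neuron = NeuronTruth(
            id=1, soma_center=np.array([56.0, 100.0]), nucleus_radius=3.5,
            soma_radius=4.0, is_neuron=True, is_projection=False,
            tbr1=False, ctip2=False,
            neurite_trees=[Branch(vertices=vertices, width=0.8)],
            total_neurite_length=50.0,
        )
        return SceneGroundTruth(
            preset_name="manual", seed=0, field_size=(332.8, 332.8),
            neurons=[neuron], debris=[],
        )

    def test_noise_free_tubb3_matches_rasterized_truth(self, clean_cfg):
        from neuropheno.imagegen import rasterize_polylines

        gt = self._single_neurite_scene()
        imgs = render_scene(gt, clean_cfg, seed=1, channels=("TUBB3",))
        img = imgs["TUBB3"].as_float()
        fg = img > 1000  # background is 400, neurite signal 6400
        expected = rasterize_polylines(
            clean_cfg.shape, [gt.neurons[0].neurite_trees[0].vertices],
            clean_cfg.pixel_size, 0.8,
        )
        # add the soma disk
        yy, xx = np.mgrid[: clean_cfg.shape[0], : clean_cfg.shape[1]]
        c = np.round(gt.neurons[0].soma_center / clean_cfg.pixel_size)
        expected |= (yy - c[1]) ** 2 + (xx - c[0]) ** 2 <= (4.0 / 0.325) ** 2
        assert np.array_equal(fg, expected)

    def test_swelling_renders_at_requested_width(self, clean_cfg):
        axon = AxonTruth(
            vertices=np.array([[20.0, 150.0], [300.0, 150.0]]),
            width=0.6, swellings=[(140.0, 4.0)],
        )
        neuron = NeuronTruth(
            id=1, soma_center=np.array([20.0, 150.0]), nucleus_radius=3.5,
            soma_radius=4.0, is_neuron=True, is_projection=False,
            tbr1=False, ctip2=False, axon=axon,
        )
        gt = SceneGroundTruth(
            preset_name="manual", seed=0, field_size=(332.8, 332.8),
            neurons=[neuron], debris=[],
        )
        imgs = render_scene(gt, clean_cfg, seed=1, channels=("TAU1",))
        img = imgs["TAU1"].as_float()
        col = int(round(160.0 / 0.325))  # bead centre at x = 20 + 140 µm
        profile = img[:, col] > 1000
        width_px = int(profile.sum())
        assert width_px == pytest.approx(4.0 / 0.325, abs=1.0)  # ≈ 12 px

    def test_marker_channel_only_background_for_negative_cells(self, clean_cfg):
        gt = self._single_neurite_scene()  # TBR1-negative neuron
        imgs = render_scene(gt, clean_cfg, seed=1, channels=("TBR1",))
        img = imgs["TBR1"].as_float()
        c = (gt.neurons[0].soma_center / 0.325).astype(int)
        patch = img[c[1] - 10 : c[1] + 10, c[0] - 10 : c[0] + 10]
        assert patch.max() <= 301  # flat background only

    def test_render_determinism(self, default_cfg):
        gt = sample_scene("control-24h", 15, seed=5)
        a = render_scene(gt, default_cfg, seed=9, channels=("DAPI", "TUBB3"))
        b = render_scene(gt, default_cfg, seed=9, channels=("DAPI", "TUBB3"))
        for ch in a:
            np.testing.assert_array_equal(a[ch].data, b[ch].data)

    def test_coarse_pixels_refused_for_axon_scenes(self):
        gt = sample_scene("spg4-d50", 3, seed=2)
        cfg = RenderConfig(pixel_size=0.8, shape=(256, 256))
        with pytest.raises(ValueError, match="too coarse"):
            render_scene(gt, cfg, seed=1, channels=("TAU1",))


class TestFixtures:
    def test_round_trip_and_manifest(self, tmp_path, default_cfg):
        gt = sample_scene("control-24h", 8, seed=21)
        imgs = render_scene(gt, default_cfg, seed=22, channels=("DAPI", "TUBB3"))
        paths = write_fixture(gt, imgs, tmp_path / "scene", default_cfg, render_seed=22)
        for ch in ("DAPI", "TUBB3"):
            back = read_channel_tiff(paths[ch], channel=ch)
            np.testing.assert_array_equal(back.data, imgs[ch].data)
            assert back.pixel_size == pytest.approx(0.325, rel=1e-4)
        neurons = pd.read_csv(paths["neurons"])
        assert len(neurons) == gt.n_neurons
        # re-running with identical seeds reproduces identical files
        gt2 = sample_scene("control-24h", 8, seed=21)
        imgs2 = render_scene(gt2, default_cfg, seed=22, channels=("DAPI", "TUBB3"))
        paths2 = write_fixture(gt2, imgs2, tmp_path / "scene2", default_cfg, render_seed=22)
        for name in ("neurons", "growth_cones", "swellings", "manifest"):
            assert paths[name].read_bytes() == paths2[name].read_bytes()
        for ch in ("DAPI", "TUBB3"):
            np.testing.assert_array_equal(
                tifffile.imread(paths[ch]), tifffile.imread(paths2[ch])
            )
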