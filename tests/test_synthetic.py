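"""Renderer ground truth, acquisition writing and the trait simulator."""
from datetime import datetime

import numpy as np
import pytest

import fruitmorph as fm
from fruitmorph import io as fio

TS = datetime(2021, 9, 15, 10, 30, 0)


def red_spec(**kwargs):
    defaults = dict(
        side_radius_profile=fm.constant_profile(3.0),
        top_radius_profile=fm.constant_profile(3.0),
        peel_hue_mixture=[(0.0, 0.9, 0.8, 1.0)],
        weight_g=163.2, rng_seed=3)
    defaults.update(kwargs)
    return fm.FruitSpec(**defaults)


class TestFruitSpecValidation:
    def test_non_positive_radius_rejected(self):
        profile = fm.constant_profile(3.0)
        profile[17] = -0.1
        with pytest.raises(ValueError, match="positive"):
            red_spec(side_radius_profile=profile)

    def test_mixture_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            red_spec(peel_hue_mixture=[(0.0, 0.9, 0.8, 0.5),
                                       (0.3, 0.9, 0.8, 0.4)])

    def test_oversized_fruit_rejected(self):
        with pytest.raises(ValueError, match="larger than"):
            fm.render_fruit(red_spec(side_radius_profile=fm.constant_profile(8.0),
                                     top_radius_profile=fm.constant_profile(8.0)),
                            0.01)


class TestRenderFruit:
    def test_constant_profile_gives_disks(self):
        sample = fm.render_fruit(red_spec(), 0.01)
        for cam in range(1, 6):
            mask = sample.truth_masks[cam]
            assert mask.sum() > 0
            rows = np.any(mask, axis=1).nonzero()[0]
            cols = np.any(mask, axis=0).nonzero()[0]
            # disk of radius 300 px within 1 px
            assert abs((rows[-1] - rows[0] + 1) - 600) <= 2
            assert abs((cols[-1] - cols[0] + 1) - 600) <= 2
            assert mask.sum() == pytest.approx(np.pi * 300 ** 2, rel=0.01)

    def test_pure_red_hue_after_quantization(self):
        sample = fm.render_fruit(red_spec(), 0.01)
        hist = fm.fruit_histogram([sample.images[1]], [sample.truth_masks[1]])
        # all hue mass in the bin containing hue 0 (bin width 1/64)
        assert hist.hue_bin_mass()[0] == pytest.approx(1.0, abs=1e-9)

    def test_image_equals_background_outside_mask(self):
        sample = fm.render_fruit(red_spec(), 0.01)
        for cam in range(1, 6):
            outside = ~sample.truth_masks[cam]
            assert (sample.images[cam][outside]
                    == sample.backgrounds[cam][outside]).all()

    def test_ellipse_dimensions_recovered(self):
        spec = red_spec(side_radius_profile=fm.ellipse_profile(3.5, 2.8))
        sample = fm.render_fruit(spec, 0.01)
        seg = fm.segment_fruit(sample.images[1], sample.backgrounds[1])
        width, height = fm.dimensions(seg.mask, 0.01)
        assert width == pytest.approx(7.0, rel=0.01)
        assert height == pytest.approx(5.6, rel=0.01)

    def test_hue_mixture_reextraction(self, two_tone_fruit):
        s = two_tone_fruit
        masks = [fm.segment_fruit(s.images[c], s.backgrounds[c]).mask
                 for c in (1, 2, 3, 4)]
        hist = fm.fruit_histogram([s.images[c] for c in (1, 2, 3, 4)], masks)
        mass = hist.hue_bin_mass()
        red_bin = 0
        yellow_bin = np.searchsorted(hist.hue_bin_edges, 0.13) - 1
        assert mass[red_bin] == pytest.approx(0.7, abs=0.03)
        assert mass[yellow_bin] == pytest.approx(0.3, abs=0.03)

    def test_asymmetry_monotone_in_skew(self):
        rng = np.random.default_rng(0)
        indices = []
        for skew in (0.0, 0.05, 0.10, 0.15, 0.20):
            spec = red_spec(side_radius_profile=fm.ellipse_profile(1.6, 1.3),
                            top_radius_profile=fm.constant_profile(1.5),
                            asymmetry_skew=skew)
            sample = fm.render_fruit(spec, 0.01)
            indices.append(fm.asymmetry_index(sample.truth_masks[4]))
        assert indices[0] == pytest.approx(0.0, abs=0.005)
        assert all(b >= a for a, b in zip(indices, indices[1:]))
        assert indices[-1] > 0.01

    def test_render_deterministic_for_seed(self):
        a = fm.render_fruit(red_spec(), 0.01)
        b = fm.render_fruit(red_spec(), 0.01)
        assert (a.images[2] == b.images[2]).all()


class TestWriteSample:
    @pytest.fixture()
    def small_sample(self):
        spec = red_spec(side_radius_profile=fm.constant_profile(1.0),
                        top_radius_profile=fm.constant_profile(1.0))
        return fm.render_fruit(spec, 0.01)

    def test_layout_and_roundtrip(self, small_sample, tmp_path):
        paths = fm.write_sample(small_sample, tmp_path, "T042", 7, TS)
        assert (tmp_path / "images" / "T042" / "cam3"
                / "T042_cam3_0007_20210915_103000.tif") in paths
        image, weight, meta = fio.read_image_with_weight(paths[0])
        assert (image == small_sample.images[1]).all()
        assert weight == 163.2
        assert meta["weight_source"] == "metadata"

    def test_collision_rejected(self, small_sample, tmp_path):
        fm.write_sample(small_sample, tmp_path, "T001", 1, TS)
        with pytest.raises(FileExistsError):
            fm.write_sample(small_sample, tmp_path, "T001", 1, TS)

    def test_spec_file_roundtrip(self, tmp_path):
        from fruitmorph.synthetic import read_spec_file, write_spec_file
        spec = red_spec(asymmetry_skew=0.12)
        path = tmp_path / "fruit.spec"
        write_spec_file(spec, path)
        loaded = read_spec_file(path)
        assert np.allclose(loaded.side_radius_profile, spec.side_radius_profile)
        assert loaded.weight_g == spec.weight_g
        assert loaded.peel_hue_mixture == spec.peel_hue_mixture
        assert loaded.rng_seed == spec.rng_seed


class TestSimulateRecords:
    def test_shapes_and_columns(self):
        df = fm.simulate_records(n_cultivars=3, n_fruit=10, seed=1)
        assert len(df) == 30
        assert df["cultivar"].nunique() == 3
        for column in ("weight_g", "width_mean_cm", "height_mean_cm",
                       "shape_index", "asymmetry"):
            assert (df[column] > 0).all()

    def test_weight_far_more_variable_than_width(self):
        df = fm.simulate_records(n_cultivars=5, n_fruit=200, seed=2)
        cv = df.groupby("cultivar").agg(
            w=("weight_g", lambda x: x.std() / x.mean()),
            d=("width_mean_cm", lambda x: x.std() / x.mean()))
        assert (cv["w"] > 2 * cv["d"]).all()

    def test_deterministic(self):
        a = fm.simulate_records(n_cultivars=2, n_fruit=5, seed=3)
        b = fm.simulate_records(n_cultivars=2, n_fruit=5, seed=3)
        assert a.equals(b)
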