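"""Phantom generation: geometry sampling, rendering, rater simulation."""

import json

import numpy as np
import pytest

from nerveseg.phantom import (NerveGeometry, PhantomSpec, RaterModel,
                              generate_dataset, generate_sample,
                              rasterize_mask, render_phantom,
                              sample_nerve_geometry, save_sample,
                              simulate_tracing)
from nerveseg.preprocess import Tracing, binarize, fill_tracing
from nerveseg.reliability import csa_mm2, icc_2_1


def shoelace(p):
    x, y = p[:, 0], p[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


class TestGeometry:
    def test_degenerate_spec_yields_circle_of_requested_area(self):
        spec = PhantomSpec.default("wrist", nerve_csa_sd=0.0,
                                   nerve_aspect_range=(1.0, 1.0),
                                   boundary_irregularity=0.0)
        geom = sample_nerve_geometry(spec, np.random.default_rng(0))
        area = shoelace(geom.polygon) * spec.pixel_spacing**2
        assert area == pytest.approx(9.8, rel=0.005)
        assert geom.true_area == pytest.approx(area, rel=1e-9)

    def test_area_distribution_recovers_stated_moments(self):
        spec = PhantomSpec.default("wrist", image_height=256, image_width=256)
        rng = np.random.default_rng(7)
        areas = np.array([sample_nerve_geometry(spec, rng).true_area
                          for _ in range(1000)])
        se = 2.4 / np.sqrt(1000)
        assert abs(areas.mean() - 9.8) < 3 * se

    def test_impossible_geometry_errors(self):
        spec = PhantomSpec.default("wrist", nerve_csa_mean=1e6, nerve_csa_sd=0.0)
        with pytest.raises(ValueError, match="could not fit"):
            sample_nerve_geometry(spec, np.random.default_rng(0))

    def test_polygon_needs_12_vertices(self):
        with pytest.raises(ValueError):
            NerveGeometry(center=(0, 0), polygon=np.zeros((5, 2)), true_area=1.0)


class TestRender:
    def test_noise_free_limit_is_piecewise_constant(self):
        spec = PhantomSpec.default("wrist", speckle_contrast=0.0,
                                   background_bands=1)
        rng = np.random.default_rng(1)
        geom = sample_nerve_geometry(spec, rng)
        img = render_phantom(geom, spec, rng)
        levels = np.unique(img.astype(np.float64))
        assert len(levels) <= 3
        for v in levels:
            assert min(abs(v - t) for t in (0.18, 0.45, 0.75)) < 1e-6

    def test_nerve_is_hypoechoic_across_seeds(self, wrist_spec_small):
        inside, outside = [], []
        for seed in range(20):
            s = generate_sample(wrist_spec_small, seed)
            inside.append(s.image[s.mask].mean())
            outside.append(s.image[~s.mask].mean())
        assert np.mean(inside) < np.mean(outside)
        assert all(i < o for i, o in zip(inside, outside))

    def test_same_seed_is_bit_identical(self, wrist_spec_small):
        a = generate_sample(wrist_spec_small, 42)
        b = generate_sample(wrist_spec_small, 42)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)
        np.testing.assert_array_equal(a.tracing.vertices, b.tracing.vertices)


class TestRasterize:
    def test_mask_area_tracks_polygon_area(self):
        spec = PhantomSpec.default("wrist")
        for seed in range(30):
            s = generate_sample(spec, seed)
            if s.geometry.true_area < 4.0:
                continue
            est = csa_mm2(s.mask, spec.pixel_spacing, largest_component_only=False)
            assert est == pytest.approx(s.geometry.true_area, rel=0.02)

    def test_polygon_outside_canvas_errors(self):
        geom = NerveGeometry(center=(100, 100),
                             polygon=np.column_stack([
                                 100 + 10 * np.cos(np.linspace(0, 2 * np.pi, 16, endpoint=False)),
                                 100 + 10 * np.sin(np.linspace(0, 2 * np.pi, 16, endpoint=False))]),
                             true_area=1.0)
        with pytest.raises(ValueError):
            rasterize_mask(geom, 64, 64)


class TestRater:
    def test_perfect_rater_reproduces_polygon(self, wrist_spec_small):
        geom = sample_nerve_geometry(wrist_spec_small, np.random.default_rng(3))
        tr = simulate_tracing(geom, RaterModel(vertex_jitter_sd=0.0, boundary_bias=0.0),
                              np.random.default_rng(0), wrist_spec_small.pixel_spacing)
        np.testing.assert_allclose(tr.vertices, geom.polygon)
        h, w = wrist_spec_small.image_height, wrist_spec_small.image_width
        np.testing.assert_array_equal(fill_tracing(tr, h, w),
                                      rasterize_mask(geom, h, w))

    def test_outward_bias_inflates_area(self, wrist_spec_small):
        rater = RaterModel(vertex_jitter_sd=0.0, boundary_bias=0.1)
        sp = wrist_spec_small.pixel_spacing
        for seed in range(20):
            rng = np.random.default_rng(seed)
            geom = sample_nerve_geometry(wrist_spec_small, rng)
            tr = simulate_tracing(geom, rater, rng, sp)
            assert shoelace(tr.vertices) * sp**2 > geom.true_area

    def test_symmetric_jitter_is_area_unbiased(self, wrist_spec_small):
        # fresh geometry per repetition so rasterization granularity averages
        # out instead of acting as a fixed per-shape offset
        rater = RaterModel(vertex_jitter_sd=0.08, boundary_bias=0.0)
        sp = wrist_spec_small.pixel_spacing
        h, w = wrist_spec_small.image_height, wrist_spec_small.image_width
        diffs = []
        for rep in range(200):
            rng = np.random.default_rng(1000 + rep)
            geom = sample_nerve_geometry(wrist_spec_small, rng)
            tr = simulate_tracing(geom, rater, rng, sp)
            diffs.append(fill_tracing(tr, h, w).sum() * sp**2 - geom.true_area)
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * se

    def test_rater_agreement_improves_as_jitter_shrinks(self, wrist_spec_small):
        sp = wrist_spec_small.pixel_spacing
        h, w = wrist_spec_small.image_height, wrist_spec_small.image_width
        geoms = [sample_nerve_geometry(wrist_spec_small, np.random.default_rng(s))
                 for s in range(30)]
        iccs = []
        for jitter in (0.30, 0.15, 0.05):
            rater = RaterModel(vertex_jitter_sd=jitter)
            cols = []
            for which in (0, 1):
                areas = [
                    fill_tracing(
                        simulate_tracing(g, rater,
                                         np.random.default_rng(9000 + 2 * i + which), sp),
                        h, w).sum() * sp**2
                    for i, g in enumerate(geoms)
                ]
                cols.append(areas)
            iccs.append(icc_2_1(np.column_stack(cols))[0])
        assert iccs[0] < iccs[1] < iccs[2]


class TestSiteContrast:
    def test_wrist_is_shallower_and_larger_than_forearm(
            self, wrist_spec_small, forearm_spec_small):
        wmid = np.mean(wrist_spec_small.nerve_depth_range)
        fmid = np.mean(forearm_spec_small.nerve_depth_range)
        assert wmid < fmid
        rngw = np.random.default_rng(21)
        rngf = np.random.default_rng(22)
        wrist = [sample_nerve_geometry(wrist_spec_small, rngw) for _ in range(100)]
        fore = [sample_nerve_geometry(forearm_spec_small, rngf) for _ in range(100)]
        assert np.mean([g.center[1] for g in wrist]) < np.mean([g.center[1] for g in fore])
        assert np.mean([g.true_area for g in wrist]) > np.mean([g.true_area for g in fore])


def test_save_sample_writes_png_csv_json(tmp_path, wrist_spec_small):
    import imageio.v3 as iio

    s = generate_sample(wrist_spec_small, 5, sample_id="demo")
    save_sample(s, tmp_path)
    img = iio.imread(tmp_path / "demo.png")
    mask = iio.imread(tmp_path / "demo_mask.png")
    assert img.dtype == np.uint8 and img.shape == s.image.shape
    assert set(np.unique(mask)) <= {0, 255}
    np.testing.assert_array_equal(binarize(mask), s.mask)
    sidecar = json.loads((tmp_path / "demo.json").read_text())
    assert sidecar["site"] == "wrist"
    assert sidecar["pixel_spacing"] == wrist_spec_small.pixel_spacing
    assert sidecar["true_area"] == pytest.approx(s.geometry.true_area)
    assert (tmp_path / "demo_trace.csv").exists()


def test_spec_validation():
    with pytest.raises(ValueError):
        PhantomSpec(site="elbow")
    with pytest.raises(ValueError):
        PhantomSpec(site="wrist", nerve_csa_mean=-1.0)
    with pytest.raises(ValueError):
        PhantomSpec(site="wrist", nerve_depth_range=(0.8, 0.2))
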