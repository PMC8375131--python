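"""Otsu cell segmentation, invaded area, polar profiling and metric
extraction, including the seeded synthetic recovery sweep."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spherinv.core_detect import CoreDetection
from spherinv.errors import ProfileError
from spherinv.images import CorrectedImage
from spherinv.invasion import (RadialProfile, extract_metrics,
                               measure_invaded_area, polar_profile,
                               segment_cells_otsu)
from spherinv.model import SpheroidInvasionModel
from spherinv.synthetic import SceneSpec, render_spheroid_image


def make_core(mask_shape, cx, cy, radius):
    yy, xx = np.mgrid[0:mask_shape[0], 0:mask_shape[1]]
    core_mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    return CoreDetection(center=(cx, cy), core_mask=core_mask,
                         core_area=float(core_mask.sum()),
                         core_equiv_radius=radius, threshold=0.0)


class TestOtsuSegmentation:
    def test_two_level_image_split_exactly(self):
        rng = np.random.default_rng(0)
        pixels = np.where(rng.uniform(size=(200, 200)) < 0.4, 0.8, 1.0)
        mask = segment_cells_otsu(CorrectedImage(pixels))
        assert np.array_equal(mask, pixels == 0.8)

    def test_noiseless_scene_mask_equals_drawn_pixels(self, clean_scene):
        spec, (img, _) = clean_scene
        # on a noise-free flat-field render the raw image already is a
        # valid ratio image up to scale; Otsu must cut between the object
        # grays and the background
        mask = segment_cells_otsu(CorrectedImage(img.pixels))
        assert np.array_equal(mask, img.pixels != spec.background_gray)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            segment_cells_otsu(CorrectedImage(np.ones((64, 64))))


class TestInvadedArea:
    def test_zero_without_invaders(self):
        img, _ = render_spheroid_image(
            SceneSpec(n_invading_cells=0, noise_sd=0.0,
                      illumination_gradient_ratio=1.0, seed=1))
        mask = img.pixels < 140.0
        core = make_core(mask.shape, 520.0, 520.0, 150.0)
        assert measure_invaded_area(mask, core, 1.0) == 0.0

    def test_200_sparse_blobs_match_analytic_area(self):
        spec = SceneSpec(n_invading_cells=200, cell_radius=5.0,
                         core_radius_true=100.0, r_outermost_true=480.0,
                         noise_sd=0.0, illumination_gradient_ratio=1.0,
                         seed=9)
        img, truth = render_spheroid_image(spec)
        mask = img.pixels < 140.0
        core = make_core(mask.shape, 520.0, 520.0, 100.0)
        area = measure_invaded_area(mask, core, 1.0)
        assert area == pytest.approx(200 * np.pi * 25.0, rel=0.10)
        assert area == truth.invaded_area_true

    def test_monotone_in_cell_count(self):
        areas = []
        for n in (100, 300):
            img, _ = render_spheroid_image(
                SceneSpec(n_invading_cells=n, noise_sd=0.0,
                          illumination_gradient_ratio=1.0, seed=13))
            mask = img.pixels < 140.0
            core = make_core(mask.shape, 520.0, 520.0, 150.0)
            areas.append(measure_invaded_area(mask, core, 1.0))
        assert areas[1] > areas[0]

    def test_mismatched_shapes_rejected(self):
        core = make_core((64, 64), 32, 32, 10)
        with pytest.raises(ValueError):
            measure_invaded_area(np.zeros((32, 32), bool), core, 1.0)


class TestPolarProfile:
    def test_full_disk_rasterization_band(self, disk_mask):
        prof = polar_profile(disk_mask, (520.0, 520.0), r_limit=519)
        assert np.all(prof.yield_[:149] == 1.0)
        assert np.all(prof.yield_[152:] == 0.0)

    def test_thin_ring(self):
        yy, xx = np.mgrid[0:1040, 0:1040]
        rr = np.sqrt((xx - 520.0) ** 2 + (yy - 520.0) ** 2)
        ring = (rr >= 98.5) & (rr <= 101.5)
        prof = polar_profile(ring, (520.0, 520.0), r_limit=519)
        assert prof.yield_[100] > 0.8
        assert np.all(prof.yield_[:96] == 0.0)
        assert np.all(prof.yield_[105:] == 0.0)

    def test_empty_mask_zero_yield(self):
        prof = polar_profile(np.zeros((200, 200), bool), (100.0, 100.0),
                             r_limit=99)
        assert np.all(prof.yield_ == 0.0)
        assert prof.radii[-1] == 99

    def test_r_limit_clipped_to_border(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="spherinv.invasion"):
            prof = polar_profile(np.zeros((200, 200), bool),
                                 (100.0, 100.0), r_limit=150)
        assert prof.r_limit <= 99
        assert any("clipping" in r.message for r in caplog.records)

    def test_center_outside_rejected(self):
        with pytest.raises(ValueError):
            polar_profile(np.zeros((50, 50), bool), (80.0, 10.0), 20)


class TestExtractMetrics:
    def test_plateau_plus_linear_ramp_recovers_both_radii(self):
        r = np.arange(0, 520)
        y = np.where(r < 150, 1.0, np.clip(0.2 * (410.0 - r) / 260.0,
                                           0.0, None))
        prof = RadialProfile(radii=r, yield_=y, r_limit=519,
                             center=(520.0, 520.0))
        m = extract_metrics(prof)
        assert m.core_radius == 150.0
        assert m.r_max_invasion == pytest.approx(410.0, abs=2.0)
        assert not m.tail_fit.fallback
        assert m.tail_fit.r_squared > 0.999

    def test_disk_only_profile_degenerates_to_rim(self, disk_mask):
        prof = polar_profile(disk_mask, (520.0, 520.0), r_limit=519)
        m = extract_metrics(prof)
        assert 148.0 <= m.core_radius <= 152.0
        assert 148.0 <= m.r_max_invasion <= 152.0

    def test_all_zero_profile_rejected(self):
        prof = RadialProfile(radii=np.arange(100),
                             yield_=np.zeros(100), r_limit=99,
                             center=(0.0, 0.0))
        with pytest.raises(ProfileError):
            extract_metrics(prof)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(core=st.integers(30, 120), extent=st.integers(10, 300),
           peak=st.floats(0.05, 0.45), seed=st.integers(0, 1000))
    def test_ordering_invariant(self, core, extent, peak, seed):
        # random plateau + noisy declining tail: core <= r_max <= r_limit
        rng = np.random.default_rng(seed)
        r = np.arange(0, 520)
        y = np.zeros(520)
        y[:core] = 1.0
        end = min(core + extent, 519)
        ramp = peak * (1 - (r[core:end] - core) / max(end - core, 1))
        y[core:end] = np.clip(
            ramp + 0.02 * rng.standard_normal(end - core), 0.0, 1.0)
        prof = RadialProfile(radii=r, yield_=y, r_limit=519,
                             center=(0.0, 0.0))
        m = extract_metrics(prof)
        assert m.core_radius <= m.r_max_invasion <= 519

    def test_bad_tail_band_rejected(self):
        prof = RadialProfile(radii=np.arange(10), yield_=np.ones(10),
                             r_limit=9, center=(0.0, 0.0))
        with pytest.raises(ValueError):
            extract_metrics(prof, tail_lo=0.3, tail_hi=0.2)


class TestSceneRecovery:
    def test_rotating_scene_90_degrees_changes_metrics_under_2pct(
            self, default_scene):
        img, _ = default_scene
        res0 = SpheroidInvasionModel(img.pixels).fit()
        res90 = SpheroidInvasionModel(
            np.ascontiguousarray(np.rot90(img.pixels))).fit()
        assert abs(res90.core_radius - res0.core_radius) \
            <= 0.02 * res0.core_radius
        assert abs(res90.r_max_invasion - res0.r_max_invasion) \
            <= 0.02 * res0.r_max_invasion

    def test_seeded_sweep_recovers_radii(self):
        # 20 scenes across the supported geometry; medians must recover
        # the outermost-cell radius within 15% and the core radius within
        # 10%
        rng = np.random.default_rng(123)
        core_err, rmax_err = [], []
        for _ in range(20):
            c = rng.uniform(120, 180)
            ro = rng.uniform(max(250.0, c + 30), 480)
            n = int(rng.integers(100, 401))
            spec = SceneSpec(core_radius_true=c, r_outermost_true=ro,
                             n_invading_cells=n,
                             seed=int(rng.integers(0, 2**31)))
            img, truth = render_spheroid_image(spec)
            res = SpheroidInvasionModel(img).fit()
            core_err.append(abs(res.core_radius - c) / c)
            rmax_err.append(abs(res.r_max_invasion - ro) / ro)
        assert np.median(core_err) <= 0.10
        assert np.median(rmax_err) <= 0.15
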