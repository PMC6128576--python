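"""Segmentation, projection, Feret morphometry and parent-artery sizing."""


import numpy as np
import pytest

from fwhmvasc._errors import AnalysisError, ValidationError
from fwhmvasc.fwhmcore import compute_fwhm, sample_profile, window_level_from_fwhm
from fwhmvasc.morphometry import (
    estimate_local_axis,
    max_feret_diameter,
    measure_residual,
    parent_artery_diameter,
    perpendicular_extent,
    project_mask,
    segment_at_level,
)
from fwhmvasc.phantom import PhantomConfig, default_annotations, generate_phantom
from fwhmvasc.volio import AnnotationSet


def brute_force_feret(pixels, pitch):
    """Independent oracle: max pairwise distance over all pixel corners."""
    offs = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    corners = (pixels[:, None, :] + offs[None, :, :]).reshape(-1, 2) * pitch
    best = 0.0
    for i in range(len(corners)):
        d = np.linalg.norm(corners[i + 1:] - corners[i], axis=1)
        if len(d):
            best = max(best, float(d.max()))
    return best


class TestSegmentAtLevel:
    def test_low_level_spans_connected_grid(self):
        vol = np.random.default_rng(0).uniform(1, 2, (8, 8, 8))
        seg = segment_at_level(vol, 0.5, (4, 4, 4))
        assert seg.mask.all()

    def test_seed_below_level_rejected(self):
        vol = np.zeros((8, 8, 8))
        vol[4, 4, 4] = 1.0
        with pytest.raises(AnalysisError, match="seed outside segmentation"):
            segment_at_level(vol, 0.5, (0, 0, 0))
        with pytest.raises(AnalysisError):
            segment_at_level(vol, 2.0, (4, 4, 4))  # level above global max

    def test_blurred_cylinder_half_max_diameter(self):
        """Mask cross-section matches the 2D disk-PSF convolution oracle."""
        cfg = PhantomConfig(seed=3, noise_sigma=0.0, psf_sigma_mm=0.5)
        series, truth = generate_phantom(cfg)
        vol = series.phase(truth.peak_phase_index)
        peak = vol.max()
        level = cfg.background_level + (peak - cfg.background_level) / 2.0
        centre = np.asarray(cfg.parent_center_mm).astype(int)
        seg = segment_at_level(vol, level, centre, series.spacing_mm, series.origin_mm)
        # cross-section through the parent far from the remnant
        x0 = 8
        width = np.count_nonzero(seg.mask[x0, :, centre[2]])
        # oracle: dense 2D convolution of the voxelized disk with the PSF,
        # half-max width along a line through the centre
        h = 0.02
        g = np.arange(-6, 6, h)
        U, V = np.meshgrid(g, g, indexing="ij")
        # voxelized disk: union of unit squares whose centres lie inside
        disk = np.zeros_like(U)
        for cy in range(-3, 4):
            for cz in range(-3, 4):
                if cy**2 + cz**2 <= cfg.parent_radius_mm**2:
                    disk[(np.abs(U - cy) <= 0.5) & (np.abs(V - cz) <= 0.5)] = 1.0
        from scipy import ndimage
        blurred = ndimage.gaussian_filter(disk, sigma=cfg.psf_sigma_mm / h)
        profile = blurred[:, np.argmin(np.abs(g))]
        above = g[profile >= 0.5 * profile.max()]
        oracle_width = above.max() - above.min()
        assert width == pytest.approx(oracle_width, abs=1.0)
        assert width == pytest.approx(2 * cfg.parent_radius_mm, abs=1.0)


class TestProjectMask:
    def test_axis_aligned_box_silhouette(self):
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[2:7, 3:9, 4:6] = True
        proj = project_mask(mask, (0, 0, 1.0))
        assert proj.image.sum() == 5 * 6
        assert sorted(proj.image.shape) == [5, 6]
        assert proj.image.all()

    def test_sphere_any_normal_gives_disk(self):
        g = np.arange(21)
        X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
        mask = (X - 10) ** 2 + (Y - 10) ** 2 + (Z - 10) ** 2 <= 36  # r=6
        n = np.array([1.0, 2.0, 3.0])
        n /= np.linalg.norm(n)
        proj = project_mask(mask, n)
        # silhouette of a 12 mm sphere: a disk of the same diameter +- 1 px
        for axis in (0, 1):
            extent = np.ptp(np.argwhere(proj.image)[:, axis]) + 1
            assert extent == pytest.approx(12, abs=1.5)

    def test_oblique_projection_matches_point_oracle(self, clean_phantom):
        cfg, series, truth = clean_phantom
        mask = truth.lumen_mask
        n = np.array([0.3, -0.8, 0.52])
        n /= np.linalg.norm(n)
        proj = project_mask(mask, n)
        # oracle: project every voxel centre independently and re-rasterize
        from fwhmvasc.morphometry import _plane_basis
        u, v = _plane_basis(n)
        world = np.argwhere(mask).astype(float)
        coords = np.stack([world @ u, world @ v], axis=1)
        lo = coords.min(axis=0)
        pix = np.round((coords - lo) / proj.pitch_mm).astype(int)
        oracle = np.zeros(pix.max(axis=0) + 1, dtype=bool)
        oracle[pix[:, 0], pix[:, 1]] = True
        assert proj.image.shape == oracle.shape
        np.testing.assert_array_equal(proj.image, oracle)

    def test_empty_mask_rejected(self):
        with pytest.raises(AnalysisError):
            project_mask(np.zeros((4, 4, 4), dtype=bool), (0, 0, 1.0))


class TestFeret:
    def test_single_pixel_feret_is_sqrt2(self):
        d, _ = max_feret_diameter(np.array([[0, 0]]), 1.0)
        assert d == pytest.approx(np.sqrt(2))

    def test_rectangle_matches_brute_force(self):
        pix = np.array([[i, j] for i in range(8) for j in range(4)])
        d, axis = max_feret_diameter(pix, 1.0)
        assert d == pytest.approx(brute_force_feret(pix, 1.0), rel=1e-12)
        assert d == pytest.approx(np.sqrt(8**2 + 4**2), rel=1e-12)
        # extent perpendicular to the max-Feret (diagonal) axis
        s = perpendicular_extent(pix, 1.0, axis)
        assert s == pytest.approx(64 / np.sqrt(80), rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_regions_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pix = np.unique(rng.integers(0, 14, (60, 2)), axis=0)
        d, _ = max_feret_diameter(pix, 0.7)
        assert d == pytest.approx(brute_force_feret(pix, 0.7), rel=1e-12)


class TestMeasureResidual:
    def _disk_setup(self, diameter=10):
        g = np.arange(41)
        X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
        r = diameter / 2
        mask = (X - 20) ** 2 + (Z - 20) ** 2 <= r**2
        mask &= np.abs(Y - 20) <= 2
        ann = AnnotationSet(
            profile_line=([10.0, 20.0, 20.0], [30.0, 20.0, 20.0]),
            neck_points=([15.0, 20.0, 15.0], [25.0, 20.0, 15.0]),
            seed_point=[20.0, 20.0, 20.0],
            projection_normal=[0.0, 1.0, 0.0],
        )
        return mask, ann

    def test_disk_largest_equals_smallest(self):
        mask, ann = self._disk_setup(diameter=10)
        m = measure_residual(mask, ann, level=0.0)
        assert m.largest_diameter_mm == pytest.approx(10, abs=1.5)
        assert m.smallest_diameter_mm == pytest.approx(10, abs=1.5)
        assert m.neck_length_mm == pytest.approx(10.0)

    def test_phantom_remnant_ellipse_silhouette(self):
        # remnant semiaxes (4, 3, 2): projected along the 2 mm semiaxis the
        # silhouette is a 8 x 6 ellipse
        cfg = PhantomConfig(seed=11, noise_sigma=0.0,
                            remnant_semiaxes_mm=(4.0, 3.0, 2.0),
                            coil_center_mm=(10.0, 10.0, 10.0))
        series, truth = generate_phantom(cfg)
        rc = np.asarray(cfg.remnant_center_mm)
        semi = np.asarray(cfg.remnant_semiaxes_mm)
        # silhouette plane normal along the 2 mm semiaxis (z): in-plane 8 x 6
        mask = truth.lumen_mask.copy()
        # isolate the remnant: drop everything below the neck junction
        g = np.arange(cfg.grid_shape[2])
        mask[:, :, g < int(rc[2] - semi[2])] = False
        ann = AnnotationSet(
            profile_line=(rc - [6, 0, 0], rc + [6, 0, 0]),
            neck_points=(rc + [-1.0, -3.0, 0.0], rc + [1.0, -3.0, 0.0]),
            seed_point=rc,
            projection_normal=[0.0, 0.0, 1.0],
        )
        m = measure_residual(mask, ann, level=0.0)
        assert m.largest_diameter_mm == pytest.approx(8.0, abs=1.5)
        assert m.smallest_diameter_mm == pytest.approx(6.0, abs=1.5)

    def test_neck_line_off_target_rejected(self):
        mask, ann = self._disk_setup()
        far = AnnotationSet(
            profile_line=ann.profile_line,
            neck_points=([2.0, 20.0, 2.0], [5.0, 20.0, 2.0]),
            seed_point=ann.seed_point,
            projection_normal=ann.projection_normal,
        )
        with pytest.raises(AnalysisError, match="neck line off target"):
            measure_residual(mask, far, level=0.0)

    def test_threshold_monotone_mask_nesting(self, default_phantom):
        cfg, series, truth = default_phantom
        vol = series.phase(truth.peak_phase_index)
        seed = np.asarray(cfg.remnant_center_mm)
        levels = [60.0, 100.0, 140.0]
        masks = [segment_at_level(vol, lv, seed).mask for lv in levels]
        for lo, hi in zip(masks, masks[1:]):
            assert np.all(lo[hi])  # higher level's mask nested in lower's
        vols = [m.sum() for m in masks]
        assert vols == sorted(vols, reverse=True)


class TestParentArteryDiameter:
    def test_phantom_cylinder_low_noise(self, default_phantom, default_ann):
        cfg, series, truth = default_phantom
        vol = series.phase(truth.peak_phase_index)
        prof = sample_profile(vol, default_ann.profile_line, 0.25,
                              series.spacing_mm, series.origin_mm)
        level = window_level_from_fwhm(compute_fwhm(prof))
        d = parent_artery_diameter(series, default_ann, level,
                                   phase=truth.peak_phase_index)
        assert d == pytest.approx(3.0, abs=0.5)

    def test_contrast_amplitude_invariance(self, default_ann):
        # doubling the bolus amplitude leaves the FWHM diameter unchanged
        from fwhmvasc.phantom import BolusParams

        diameters = []
        for amp in (200.0, 400.0):
            cfg = PhantomConfig(seed=9, noise_sigma=0.0,
                                bolus=BolusParams(amplitude=amp))
            series, truth = generate_phantom(cfg)
            ann = default_annotations(cfg)
            vol = series.phase(truth.peak_phase_index)
            prof = sample_profile(vol, ann.profile_line, 0.25,
                                  series.spacing_mm, series.origin_mm)
            level = window_level_from_fwhm(compute_fwhm(prof))
            diameters.append(parent_artery_diameter(series, ann, level,
                                                    phase=truth.peak_phase_index))
        assert diameters[0] == pytest.approx(diameters[1], rel=1e-6)

    def test_axis_estimation_on_straight_cylinder(self):
        g = np.arange(30)
        X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
        mask = (Y - 15) ** 2 + (Z - 15) ** 2 <= 1.5**2
        pts = np.argwhere(mask).astype(float)
        centre = np.array([15.0, 15.0, 15.0])
        local = pts[np.linalg.norm(pts - centre, axis=1) <= 5.0]
        axis = estimate_local_axis(local)
        angle = np.degrees(np.arccos(abs(axis @ np.array([1.0, 0, 0]))))
        assert angle < 5.0

    def test_degenerate_axis_rejected(self):
        g = np.arange(20)
        X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
        ball = (X - 10) ** 2 + (Y - 10) ** 2 + (Z - 10) ** 2 <= 16
        with pytest.raises(AnalysisError, match="degenerate"):
            estimate_local_axis(np.argwhere(ball).astype(float))
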