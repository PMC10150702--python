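"""Preprocessing: compensation, surface handling, patches, scan QC."""

import dataclasses

import numpy as np
import pytest

from octmargin.params import TissueLabel, TissueParams
from octmargin.preprocess import (
    MISSING_SURFACE,
    Patch,
    QCError,
    SurfaceMap,
    compensate_depth,
    detect_surface,
    enface_projection,
    extract_patches,
    extract_subvolume,
    normalize_patch,
    normalize_surface,
    qc_scan,
)
from octmargin.simulate import simulate_ascan, simulate_cohort, simulate_volume
from octmargin.volume import OCTVolume


def step_volume(surface_row=30, n_bscans=2, lateral=20, depth=64,
                floor_db=28.0, signal_db=55.0):
    """Noiseless volume: floor above ``surface_row``, flat signal below."""
    data = np.full((n_bscans, lateral, depth), floor_db)
    data[:, :, surface_row:] = signal_db
    return OCTVolume(data, 6.0, 15.0)


class TestCompensateDepth:
    def test_flat_profiles_are_identity(self, quiet_system):
        vol = step_volume(depth=quiet_system.depth_pixels)
        out = compensate_depth(vol, quiet_system)
        np.testing.assert_allclose(out.data, vol.data, rtol=1e-12)

    def test_inverts_acquisition_sensitivity_exactly(self, system, quiet_system):
        """Noiseless compensated A-scan is pure I*exp(-2 mu z) in linear units."""
        params = TissueParams(
            label=TissueLabel.WM0, mu=4.0, intensity_db=60.0,
            surface_roughness_um=0.0, surface_reflection_db=0.0,
        )
        with_sens = dataclasses.replace(system, noise_floor_db=-300.0)
        ascan = simulate_ascan(params, with_sens, 0, speckle=False)
        vol = OCTVolume(np.tile(ascan, (1, 4, 1)), 6.0, 15.0)
        out = compensate_depth(vol, with_sens)
        z = with_sens.depth_mm()
        expected = 10.0 ** (60.0 / 10.0) * np.exp(-2.0 * 4.0 * z)
        np.testing.assert_allclose(out.linear[0, 0], expected, rtol=1e-9)

    def test_profile_length_mismatch_rejected(self, system):
        vol = step_volume(depth=system.depth_pixels // 2)
        with pytest.raises(ValueError, match="length"):
            compensate_depth(vol, system)


class TestDetectSurface:
    def test_noiseless_step_detected_exactly(self):
        surface = detect_surface(step_volume(surface_row=30), noise_floor_db=28.0)
        assert (surface.indices == 30).all()

    def test_all_floor_column_marked_missing(self):
        vol = step_volume(surface_row=30)
        vol.data[:, 5, :] = 28.0
        surface = detect_surface(vol, noise_floor_db=28.0, smooth_columns=1)
        assert (surface.indices[:, 5] == MISSING_SURFACE).all()
        assert 0 < surface.missing_fraction < 1

    def test_zero_roughness_cohort_has_constant_surface(self, system, tissue_params):
        params = dataclasses.replace(
            tissue_params[TissueLabel.WM0], surface_roughness_um=0.0
        )
        rng = np.random.default_rng(0)
        vol, truth = simulate_volume(params, system, 3, rng)
        surface = detect_surface(vol, noise_floor_db=system.noise_floor_db)
        assert (surface.indices == truth.base_surface_px).all()

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError, match="threshold"):
            detect_surface(step_volume(), threshold_db_above_floor=0.0)


class TestNormalizeSurface:
    def test_flat_surface_at_zero_is_identity(self):
        vol = step_volume(surface_row=0)
        surface = SurfaceMap(np.zeros(vol.data.shape[:2], dtype=int))
        out = normalize_surface(vol, surface, noise_floor_db=28.0)
        np.testing.assert_allclose(out.data, vol.data)

    def test_redetected_surface_is_zero_everywhere(self, system, tissue_params):
        rng = np.random.default_rng(1)
        vol, _ = simulate_volume(tissue_params[TissueLabel.WM0], system, 3, rng)
        surface = detect_surface(vol, noise_floor_db=system.noise_floor_db)
        out = normalize_surface(vol, surface, noise_floor_db=system.noise_floor_db)
        again = detect_surface(out, noise_floor_db=system.noise_floor_db)
        assert (again.indices == 0).all()

    def test_shift_preserves_below_surface_samples(self):
        vol = step_volume(surface_row=10)
        rng = np.random.default_rng(2)
        vol.data[:, :, 10:] += rng.normal(0, 1, vol.data[:, :, 10:].shape)
        vol = OCTVolume(vol.data, 6.0, 15.0)
        surface = SurfaceMap(np.full(vol.data.shape[:2], 10))
        out = normalize_surface(vol, surface, noise_floor_db=28.0)
        n_kept = vol.n_depth - 10
        np.testing.assert_allclose(
            out.data[:, :, :n_kept].sum(axis=2),
            vol.data[:, :, 10:].sum(axis=2),
        )

    def test_too_few_surfaces_is_qc_failure(self):
        vol = step_volume()
        indices = np.full(vol.data.shape[:2], MISSING_SURFACE)
        indices[:, :5] = 30
        with pytest.raises(QCError, match="columns"):
            normalize_surface(vol, SurfaceMap(indices), min_valid_fraction=0.5)


class TestEnface:
    def test_constant_volume_projects_to_constant(self):
        vol = OCTVolume(np.full((3, 8, 32), 50.0), 6.0, 15.0)
        img = enface_projection(vol, band_px=(0, 16))
        np.testing.assert_allclose(img, 50.0)

    def test_single_pixel_band_equals_surface_plane(self):
        rng = np.random.default_rng(3)
        vol = OCTVolume(rng.uniform(40, 60, (3, 8, 32)), 6.0, 15.0)
        img = enface_projection(vol, band_px=(0, 1))
        np.testing.assert_allclose(img, vol.data[:, :, 0])

    def test_brighter_tissue_projects_brighter(self, normalized_volume_factory):
        wm, _ = normalized_volume_factory(TissueLabel.WM0, n_bscans=4, seed=4)
        tumor, _ = normalized_volume_factory(TissueLabel.WM60plus, n_bscans=4, seed=4)
        assert enface_projection(wm, band_px=(3, 40)).mean() > enface_projection(
            tumor, band_px=(3, 40)
        ).mean()

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            enface_projection(step_volume(), band_px=(5, 5))


class TestSubvolume:
    def test_full_roi_is_identity(self):
        vol = step_volume(n_bscans=4)
        out = extract_subvolume(vol, (0, 4))
        np.testing.assert_array_equal(out.data, vol.data)
        assert out.patient_id == vol.patient_id

    def test_default_cohort_subvolumes_span_40_bscans(self):
        from octmargin.params import CohortSpec

        assert CohortSpec().bscans_per_subvolume == 40

    def test_out_of_bounds_or_empty_roi_rejected(self):
        vol = step_volume(n_bscans=4)
        with pytest.raises(ValueError, match="ROI"):
            extract_subvolume(vol, (0, 5))
        with pytest.raises(ValueError, match="ROI"):
            extract_subvolume(vol, (2, 2))


class TestPatches:
    def test_clean_normalized_volume_yields_all_candidates(
        self, normalized_volume_factory, system
    ):
        vol, _ = normalized_volume_factory(TissueLabel.WM0, n_bscans=6, seed=5)
        patches = extract_patches(
            vol, bscan_stride=1, noise_floor_db=system.noise_floor_db
        )
        n_lat_positions = vol.n_lateral // 144
        assert len(patches) == 6 * n_lat_positions
        assert all(p.data.shape == (144, 56) for p in patches)

    def test_invalid_columns_exclude_overlapping_patches(self, system):
        vol = step_volume(surface_row=0, lateral=160, depth=64)
        vol.invalid_columns = np.zeros(vol.data.shape[:2], dtype=bool)
        vol.invalid_columns[0, 70] = True
        patches = extract_patches(
            vol, bscan_stride=1, noise_floor_db=28.0
        )
        assert all(
            not (p.bscan_index == 0 and p.lateral_offset <= 70 < p.lateral_offset + 144)
            for p in patches
        )

    def test_dropout_columns_invalidate_patch(self):
        vol = step_volume(surface_row=0, lateral=160, depth=64, signal_db=55.0)
        vol.data[:, 40:120, :] = 28.0  # dropout block at the floor
        patches = extract_patches(vol, bscan_stride=1, noise_floor_db=28.0)
        assert patches == []

    def test_patch_too_large_for_volume_returns_empty(self):
        vol = step_volume(surface_row=0, lateral=16, depth=16)
        assert extract_patches(vol, noise_floor_db=28.0) == []


class TestNormalizePatch:
    def test_zero_mean_unit_sd_and_idempotent(self):
        rng = np.random.default_rng(6)
        patch = Patch(rng.uniform(40, 60, (12, 8)), 6.0, 15.0)
        z = normalize_patch(patch)
        assert abs(z.data.mean()) < 1e-12
        assert z.data.std() == pytest.approx(1.0)
        zz = normalize_patch(z)
        np.testing.assert_allclose(zz.data, z.data, atol=1e-12)

    def test_constant_patch_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_patch(np.full((4, 4), 50.0))


class TestQC:
    @pytest.mark.parametrize("artifact,expected", [
        ("none", {"ok"}),
        ("fold_over", {"fold_over"}),
        ("dropout", {"dropout"}),
    ])
    def test_injected_artifacts_are_flagged(
        self, system, tissue_params, artifact, expected
    ):
        rng = np.random.default_rng(8)
        vol, _ = simulate_volume(
            tissue_params[TissueLabel.WM60plus], system, 6, rng, artifact=artifact
        )
        assert qc_scan(vol, noise_floor_db=system.noise_floor_db) == expected

    def test_cohort_rejection_tracks_artifact_fraction(self, system):
        """QC rejection on a simulated cohort within the binomial 95% CI."""
        from octmargin.params import CohortSpec

        spec = CohortSpec(
            n_patients=10, scans_per_patient=4, bscans_per_subvolume=4,
            artifact_fraction=0.6, seed=13,
        )
        cohort = simulate_cohort(spec)
        rejected = [
            qc_scan(vol, noise_floor_db=system.noise_floor_db) != {"ok"}
            for vol, _ in cohort.volumes()
        ]
        n = len(rejected)
        ci = 1.96 * np.sqrt(0.6 * 0.4 / n)
        assert abs(np.mean(rejected) - 0.6) <= ci + 1e-9
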