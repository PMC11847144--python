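"""Frame correction, HDR merge, SNR, point detection, patches, calibration."""

import numpy as np
import pytest

from mdoi.montecarlo import (Acquisition, CameraModel, SourceSpec,
                             forward_acquisition, run_mc)
from mdoi.phantoms import OpticalProperties, make_phantom
from mdoi.preprocess import (CalibrationMissingError,
                             auto_roi_size, calibrate_reflectance,
                             correct_frames, extract_patches,
                             find_illumination_points, merge_uhdr, snr)
from mdoi.preprocess import EmptyPatternError, PatchStack
from mdoi.rte import RTEModelConfig, reflectance_semi_infinite


def make_acq(frames, exposures, dark=None, background=None, flatfield=None,
             shape=(16, 16), camera=None):
    camera = camera or CameraModel()
    dark = dark if dark is not None else {
        e: np.full(shape, camera.dark_offset) for e in range(len(exposures))}
    return Acquisition(
        frames=frames,
        exposures_ms=tuple(exposures),
        patterns=[[(4.0, 4.0)]],
        dark_frames=dark,
        background_frame=(background if background is not None
                          else np.zeros(shape)),
        flatfield=flatfield if flatfield is not None else np.ones(shape),
        pixel_pitch_mm=(0.5, 0.5),
        camera=camera,
    )


class TestCorrectFrames:
    def test_raw_equals_dark_plus_background_gives_zero(self):
        shape = (8, 8)
        cam = CameraModel(dark_offset=100.0)
        bg = np.full(shape, 7.0)
        raw = np.full((5, *shape), 107.0, dtype=np.uint16)
        acq = make_acq({(0, 0): raw}, [10.0], background=bg, shape=shape,
                       camera=cam)
        out = correct_frames(acq)
        assert np.all(out.images[(0, 0)] == 0.0)

    def test_flatfield_division(self):
        shape = (8, 8)
        ff = np.ones(shape)
        ff[3, 3] = 2.0
        raw = np.full((2, *shape), 300, dtype=np.uint16)
        acq = make_acq({(0, 0): raw}, [10.0], flatfield=ff, shape=shape)
        out = correct_frames(acq)
        assert out.images[(0, 0)][3, 3] == pytest.approx(
            out.images[(0, 0)][0, 0] / 2.0)

    def test_missing_dark_frame_raises(self):
        raw = np.zeros((2, 8, 8), dtype=np.uint16)
        acq = make_acq({(0, 1): raw}, [10.0], shape=(8, 8))
        with pytest.raises(CalibrationMissingError):
            correct_frames(acq)

    def test_replicate_averaging_reduces_read_noise(self):
        """Averaging 50 replicates shrinks the read-noise std ~ sqrt(50)."""
        rng = np.random.default_rng(11)
        shape = (24, 24)
        cam = CameraModel(dark_offset=100.0, read_noise=2.0)
        signal = 500.0
        raw = (signal + cam.dark_offset
               + rng.normal(0, cam.read_noise, size=(50, *shape)))
        raw = np.round(raw).astype(np.uint16)
        acq = make_acq({(0, 0): raw}, [10.0], shape=shape, camera=cam)
        out = correct_frames(acq)
        single_std = (raw[0].astype(float) - cam.dark_offset - signal).std()
        avg_std = (out.images[(0, 0)] - signal).std()
        # quantization adds ~0.29 counts rms on top of 2/sqrt(50)
        assert avg_std < single_std / np.sqrt(50) * 2.0


def ladder_acq(radiance, exposures, cam=None, full=4095):
    """Noise-free linear-camera frames for a known radiance map."""
    cam = cam or CameraModel(read_noise=0.0)
    shape = radiance.shape
    frames = {}
    for e, t in enumerate(exposures):
        counts = np.clip(np.round(radiance * t + cam.dark_offset), 0, full)
        frames[(0, e)] = counts.astype(np.uint16)[None].repeat(2, axis=0)
    return make_acq(frames, exposures, shape=shape, camera=cam)


class TestMergeUHDR:
    def test_consistent_pixel_recovers_common_radiance(self):
        radiance = np.full((8, 8), 3.25)
        acq = ladder_acq(radiance, [10.0, 20.0, 40.0])
        merged, flagged = merge_uhdr(correct_frames(acq), 0,
                                     exposure_indices=(0, 1, 2))
        assert not flagged.any()
        np.testing.assert_allclose(merged, 3.25, rtol=0.05)

    def test_saturated_long_exposure_excluded(self):
        radiance = np.full((8, 8), 60.0)  # saturates at 80 ms (4800 > 4095)
        acq = ladder_acq(radiance, [10.0, 20.0, 40.0, 80.0])
        corrected = correct_frames(acq)
        assert corrected.saturated[(0, 3)].all()
        merged, flagged = merge_uhdr(corrected, 0,
                                     exposure_indices=(0, 1, 2, 3))
        assert not flagged.any()
        np.testing.assert_allclose(merged, 60.0, rtol=0.05)

    def test_wide_dynamic_range_recovered(self):
        """A 1e4:1 radiance scene is recovered within 2% except where every
        exposure saturates (flagged)."""
        rng = np.random.default_rng(3)
        radiance = 10 ** rng.uniform(-1.0, 3.0, size=(32, 32))
        acq = ladder_acq(radiance, [10.0, 20.0, 40.0, 80.0])
        merged, flagged = merge_uhdr(correct_frames(acq), 0,
                                     exposure_indices=(0, 1, 2, 3))
        ok = ~flagged & (radiance * 10 > 20)  # above quantization floor
        rel = np.abs(merged[ok] - radiance[ok]) / radiance[ok]
        assert np.max(rel) < 0.02
        assert flagged.sum() == (radiance * 10 + 100 > 4095).sum()

    def test_needs_two_exposures(self):
        acq = ladder_acq(np.ones((4, 4)), [10.0])
        with pytest.raises(ValueError):
            merge_uhdr(correct_frames(acq), 0, exposure_indices=(0,))


class TestSNR:
    @pytest.mark.parametrize("ratio,db", [(1, 0.0), (10, 20.0), (100, 40.0)])
    def test_closed_form(self, ratio, db):
        img = np.ones((21, 21))
        rows = np.arange(21)[:, None] - 10
        cols = np.arange(21)[None, :] - 10
        dist = np.hypot(rows * 0.5, cols * 0.5)
        img[np.abs(dist - 3.0) <= 0.25] = float(ratio)
        assert snr(img, (10, 10), 3.0, (0.5, 0.5)) == pytest.approx(db,
                                                                    abs=0.2)

    def test_zero_background_warns_infinite(self):
        img = np.zeros((21, 21))
        rows = np.arange(21)[:, None] - 10
        cols = np.arange(21)[None, :] - 10
        dist = np.hypot(rows * 0.5, cols * 0.5)
        img[np.abs(dist - 3.0) <= 0.25] = 5.0
        with pytest.warns(UserWarning):
            assert snr(img, (10, 10), 3.0, (0.5, 0.5)) == float("inf")

    def test_decreases_with_distance_on_mc_patch(self, small_phantom):
        res = run_mc(small_phantom, SourceSpec((15.0, 15.0)), 30_000, 5)
        img = res.reflectance_map + 1e-9
        vals = [snr(img, (30, 30), rho, (0.5, 0.5))
                for rho in (1.0, 3.0, 6.0)]
        assert vals[0] > vals[1] > vals[2]


def gaussian_spot(shape, center, amp=100.0, sigma=1.5):
    r = np.arange(shape[0])[:, None] - center[0]
    c = np.arange(shape[1])[None, :] - center[1]
    return amp * np.exp(-(r**2 + c**2) / (2 * sigma**2))


class TestFindPoints:
    def test_single_spot(self):
        img = gaussian_spot((31, 31), (14, 17))
        pts = find_illumination_points(img, 5)
        assert pts.tolist() == [[14, 17]]

    def test_grid_of_nine(self):
        img = np.zeros((40, 40))
        nodes = [(8 + 12 * i, 8 + 12 * j) for i in range(3)
                 for j in range(3)]
        for p in nodes:
            img += gaussian_spot((40, 40), p)
        pts = find_illumination_points(img, 6)
        assert sorted(map(tuple, pts)) == sorted(nodes)

    def test_close_spots_brighter_wins(self):
        img = gaussian_spot((31, 31), (15, 15), amp=100.0)
        img += gaussian_spot((31, 31), (15, 18), amp=60.0)
        pts = find_illumination_points(img, 6)
        assert pts.tolist() == [[15, 15]]

    def test_empty_pattern_raises(self):
        with pytest.raises(EmptyPatternError):
            find_illumination_points(np.zeros((10, 10)), 3, threshold=1.0)


class TestPatches:
    def test_centered_patch(self):
        img = gaussian_spot((60, 60), (30, 30))
        stack = extract_patches(img, [(30, 30)], 41, (0.5, 0.5))
        assert stack.patches.shape == (1, 41, 41)
        assert np.unravel_index(stack.patches[0].argmax(),
                                (41, 41)) == (20, 20)
        assert not stack.padded[0]

    def test_corner_patch_padded_and_flagged(self):
        img = np.ones((60, 60))
        stack = extract_patches(img, [(1, 1)], 41, (0.5, 0.5))
        assert stack.padded[0]
        assert stack.patches[0, 0, 0] == 0.0  # zero-padded region

    def test_even_roi_rejected(self):
        with pytest.raises(ValueError):
            extract_patches(np.ones((20, 20)), [(10, 10)], 10, (0.5, 0.5))

    def test_overlap_warns(self):
        img = np.ones((60, 60))
        with pytest.warns(UserWarning, match="cross-talk"):
            extract_patches(img, [(20, 20), (20, 25)], 21, (0.5, 0.5))

    def test_auto_roi_covers_synthetic_halo(self):
        img = np.zeros((61, 61))
        r = np.hypot(np.arange(61)[:, None] - 30,
                     np.arange(61)[None, :] - 30)
        halo_r = 9
        img[r <= halo_r] = 10.0
        assert auto_roi_size(img, (30, 30)) >= 2 * halo_r + 1


def theory_patch(props, size=25, pitch=0.5, cfg=None):
    cfg = cfg or RTEModelConfig()
    c = size // 2
    r = np.arange(size) - c
    rho = np.hypot(r[:, None] * pitch, r[None, :] * pitch)
    out = np.zeros((size, size))
    pos = rho > 0
    out[pos] = reflectance_semi_infinite(rho[pos], props.mua, props.musp,
                                         cfg)
    return out, rho


class TestCalibration:
    def test_linear_relation_recovered_exactly(self, dermis):
        """Normalized intensities built as a*R_theory + b are mapped back
        onto the theory with sub-1e-6 residual (exact linear model)."""
        cfg = RTEModelConfig()
        theory, rho = theory_patch(dermis, cfg=cfg)
        a, n_pix = 5.0, theory.size
        b = (1.0 - a * theory.sum()) / n_pix  # so a*R + b sums to 1
        norm = a * theory + b
        patches = np.stack([norm * k for k in (1.0, 2.0, 0.5)])
        stack = PatchStack(patches=patches,
                           point_px=np.tile([[12, 12]], (3, 1)),
                           roi_size=25, pixel_pitch_mm=(0.5, 0.5))
        out = calibrate_reflectance(stack, dermis, cfg)
        s, o = out.calibration
        assert s == pytest.approx(1.0 / a, rel=1e-6)
        assert o == pytest.approx(-b / a, rel=1e-6)
        sel = (rho >= cfg.effective_rho_min()) & (rho <= cfg.rho_max)
        np.testing.assert_allclose(out.patches[0][sel], theory[sel],
                                   rtol=1e-6)

    def test_identity_when_normalized_input_is_theory(self, dermis):
        """If the normalized patch already equals the reference theory the
        calibrated output equals the normalized input (scale absorbs only
        the patch sum)."""
        cfg = RTEModelConfig()
        theory, _ = theory_patch(dermis, cfg=cfg)
        stack = PatchStack(patches=np.stack([theory, 3.0 * theory]),
                           point_px=np.tile([[12, 12]], (2, 1)),
                           roi_size=25, pixel_pitch_mm=(0.5, 0.5))
        out = calibrate_reflectance(stack, dermis, cfg)
        s, o = out.calibration
        assert s == pytest.approx(theory.sum(), rel=1e-9)
        assert o == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(out.patches, np.stack([theory, theory]),
                                   rtol=1e-9, atol=1e-15)

    def test_mc_roundtrip_residual(self):
        """MC acquisition of a uniform isotropic medium, preprocessed and
        calibrated, matches the dipole reflectance within 5% relative RMS
        (ring-averaged) over the part of the fitting window where the
        diffusion approximation holds (rho >= 1 mm, ~3 transport mean free
        paths)."""
        props = OpticalProperties(0.04, 2.9411, 0.0, 1.4)
        ph = make_phantom((24, 24, 12), (0.25, 0.25, 0.25), props)
        cam = CameraModel()
        with pytest.warns(UserWarning, match="saturated"):
            acq = forward_acquisition(ph, [[(12.125, 12.125)]], cam,
                                      n_photons=100_000, seed=9,
                                      n_replicates=10)
        corrected = correct_frames(acq)
        radiance, _ = merge_uhdr(corrected, 0)
        pts = find_illumination_points(radiance, 5, max_points=1)
        stack = extract_patches(radiance, pts, 41, (0.25, 0.25))
        cfg = RTEModelConfig()
        out = calibrate_reflectance(stack, props, cfg)
        rho = out.rho_grid()
        sel = (rho >= 1.0) & (rho <= cfg.rho_max)
        theory = reflectance_semi_infinite(rho[sel], props.mua, props.musp,
                                           cfg)
        ring = np.round(rho[sel] / 0.25).astype(int)
        resid = [out.patches[0][sel][ring == k].mean()
                 / theory[ring == k].mean() - 1.0
                 for k in np.unique(ring)]
        assert np.sqrt(np.mean(np.square(resid))) < 0.05


def test_noise_free_profile_monotone(small_phantom):
    """Preprocessing a noise-free acquisition of a homogeneous phantom
    leaves radial profiles that fall monotonically with distance."""
    cam = CameraModel(read_noise=0.0, background_level=0.0,
                      flatfield_amplitude=0.0)
    acq = forward_acquisition(small_phantom, [[(15.25, 15.25)]], cam,
                              n_photons=60_000, seed=4, n_replicates=30)
    radiance, _ = merge_uhdr(correct_frames(acq), 0)
    pts = find_illumination_points(radiance, 5, max_points=1)
    stack = extract_patches(radiance, pts, 25, (0.5, 0.5))
    patch = stack.patches[0]
    rho = stack.rho_grid()
    bins = np.arange(0.5, 5.1, 0.5)
    prof = [patch[(rho >= lo) & (rho < lo + 0.5)].mean() for lo in bins]
    assert np.all(np.diff(prof) < 0)
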