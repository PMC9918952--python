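"""Preprocessing chain: demosaic, equalization, demixing, registration."""

import numpy as np
import pytest
from scipy import ndimage

from mishelf.optics import OpticalGeometry
from mishelf.preprocess import (
    RegistrationParams,
    _resample,
    apply_registration,
    calibrate_crosstalk,
    demosaic,
    equalize_background,
    register_channels,
    remove_crosstalk,
)
from mishelf.simulate import (
    CfaPattern,
    CrosstalkMatrix,
    HologramSet,
    MosaicFrame,
    add_noise,
    apply_crosstalk,
    apply_vignette,
    default_crosstalk,
    mosaic,
    vignette_profile,
)

GEOM = OpticalGeometry(d=2.5e-3, z=2.375e-3, pitch=2e-6, nx=256, ny=256)
WL3 = (405e-9, 520e-9, 630e-9)


def random_set(n=3, shape=(64, 64), seed=0, lo=0.1, hi=2.0):
    rng = np.random.default_rng(seed)
    return HologramSet(rng.uniform(lo, hi, (n,) + shape), WL3[:n], GEOM.pitch)


class TestDemosaic:
    def test_constant_mosaic_fills_all_channels(self):
        frame = MosaicFrame(np.full((16, 16), 0.42), CfaPattern.named("rggb"))
        out = demosaic(frame)
        np.testing.assert_allclose(out, 0.42, atol=1e-12)

    def test_cfa_sites_preserved_exactly(self):
        rng = np.random.default_rng(1)
        cfa = CfaPattern.named("rggb")
        data = rng.uniform(0, 1, (32, 32))
        out = demosaic(MosaicFrame(data, cfa))
        for ch in range(3):
            mask = cfa.channel_mask(ch, data.shape)
            np.testing.assert_array_equal(out[ch][mask], data[mask])

    def test_affine_ramp_reproduced_in_interior(self):
        yy, xx = np.indices((64, 64))
        ramp = 1.0 + 0.01 * yy + 0.02 * xx
        cfa = CfaPattern.named("rggb")
        hs = HologramSet(np.stack([ramp] * 3), WL3, GEOM.pitch)
        out = demosaic(mosaic(hs, cfa, bit_depth=None))
        assert np.abs(out - ramp)[:, 3:-3, 3:-3].max() < 1e-10

    def test_four_channel_pattern_supported(self):
        rng = np.random.default_rng(2)
        cfa = CfaPattern.named("rgbw")
        hs = HologramSet(
            rng.uniform(0.5, 1.5, (4, 32, 32)), (405e-9, 450e-9, 520e-9, 630e-9),
            GEOM.pitch,
        )
        out = demosaic(mosaic(hs, cfa, bit_depth=None))
        assert out.shape == (4, 32, 32) and np.all(np.isfinite(out))


class TestEqualizeBackground:
    def test_object_free_frame_becomes_flat(self):
        prof = vignette_profile(GEOM, (64, 64))
        hs = HologramSet(np.stack([prof] * 3), WL3, GEOM.pitch)
        out = equalize_background(hs, prof, mode="subtract")
        for ch in out.images:
            assert ch.std() < 1e-12
            assert ch.mean() == pytest.approx(prof.mean())

    def test_ratiometric_mode_inverts_vignette(self):
        rng = np.random.default_rng(0)
        # odd grid: one pixel sits exactly on the optical axis (profile = 1)
        truth = rng.uniform(0.5, 1.5, (3, 65, 65))
        vignetted = np.stack([apply_vignette(t, GEOM) for t in truth])
        hs = HologramSet(vignetted, WL3, GEOM.pitch)
        out = equalize_background(hs, vignette_profile(GEOM, (65, 65)), mode="ratio")
        assert np.abs(out.images - truth).max() < 1e-10

    def test_corner_background_flat_after_equalization(self):
        # vignetted object-free hologram: corners must come back to the mean
        prof = vignette_profile(GEOM, (256, 256))
        hs = HologramSet(prof[None], (450e-9,), GEOM.pitch)
        out = equalize_background(hs, prof, mode="subtract")
        corner = out.images[0][:32, :32]
        assert corner.std() / corner.mean() < 0.01

    def test_nonpositive_flat_masked_with_warning(self):
        flat = np.ones((16, 16))
        flat[0, 0] = 0.0
        hs = HologramSet(np.ones((1, 16, 16)), (450e-9,), GEOM.pitch)
        with pytest.warns(UserWarning, match="nonpositive"):
            out = equalize_background(hs, flat, mode="ratio")
        assert np.isfinite(out.images).all()

    def test_unknown_mode_rejected(self):
        hs = random_set(1)
        with pytest.raises(ValueError):
            equalize_background(hs, np.ones((64, 64)), mode="divide")


def _calibration_frames(L: CrosstalkMatrix, shape=(64, 64), power=1.3):
    n = L.n
    frames = np.zeros((n, n) + shape)
    for j in range(n):
        single = np.zeros((n,) + shape)
        single[j] = power
        mixed = apply_crosstalk(
            HologramSet(single, WL3[:n] if n <= 3 else (1, 2, 3, 4), GEOM.pitch), L
        )
        frames[j] = mixed.images
    return frames


class TestCalibrateCrosstalk:
    def test_selective_channels_give_identity(self):
        frames = _calibration_frames(CrosstalkMatrix(np.eye(3) * 2.0))
        L = calibrate_crosstalk(frames)
        np.testing.assert_allclose(L.matrix, np.eye(3), atol=1e-12)

    def test_recovers_known_matrix_noiseless(self):
        truth = default_crosstalk(3, leakage=0.1, seed=3)
        L = calibrate_crosstalk(_calibration_frames(truth))
        ref = truth.column_normalized().matrix
        assert np.abs(L.matrix - ref).max() / ref.max() < 1e-6

    def test_recovers_known_matrix_with_sensor_noise(self):
        truth = default_crosstalk(3, leakage=0.1, seed=3)
        frames = _calibration_frames(truth)
        noisy = np.empty_like(frames)
        for j in range(3):
            for i in range(3):
                f = add_noise(frames[j, i], shot=True, read_sigma=0.005, seed=j * 3 + i)
                noisy[j, i] = np.round(np.clip(f, 0, 4) / 4 * 4095) / 4095 * 4
        L = calibrate_crosstalk(noisy)
        ref = truth.column_normalized().matrix
        assert np.abs(L.matrix - ref).max() / ref.max() < 0.02

    def test_invariant_to_global_exposure(self):
        truth = default_crosstalk(3, leakage=0.15, seed=1)
        frames = _calibration_frames(truth)
        a = calibrate_crosstalk(frames)
        b = calibrate_crosstalk(frames * 3.7)
        np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-12)

    def test_inseparable_detectors_rejected(self):
        frames = _calibration_frames(
            CrosstalkMatrix(np.eye(3)), shape=(8, 8)
        )
        flat = frames.mean(axis=1, keepdims=True) * np.ones((1, 3, 1, 1))
        with pytest.raises(ValueError, match="not separable"):
            calibrate_crosstalk(flat)


class TestRemoveCrosstalk:
    def test_identity_matrix_is_noop(self):
        hs = random_set()
        out = remove_crosstalk(hs, CrosstalkMatrix(np.eye(3)))
        np.testing.assert_allclose(out.images, hs.images, atol=1e-14)
        assert out.tag == "true"

    @pytest.mark.parametrize("n, seed", [(3, 0), (4, 1)])
    def test_demix_inverts_mix(self, n, seed):
        wl = (405e-9, 450e-9, 520e-9, 630e-9)[:n]
        rng = np.random.default_rng(seed)
        hs = HologramSet(rng.uniform(0.1, 2.0, (n, 32, 32)), wl, GEOM.pitch)
        L = default_crosstalk(n, leakage=0.1, seed=seed)
        out = remove_crosstalk(apply_crosstalk(hs, L), L)
        assert np.abs(out.images - hs.images).max() < 1e-10

    def test_quantized_leakage_fixture_demixes_within_1pct(self):
        rng = np.random.default_rng(4)
        hs = HologramSet(rng.uniform(0.5, 1.5, (3, 64, 64)), WL3, GEOM.pitch)
        L = default_crosstalk(3, leakage=0.1, seed=4)
        mixed = apply_crosstalk(hs, L)
        quant = HologramSet(
            np.round(mixed.images / 4 * 4095) / 4095 * 4, WL3, GEOM.pitch,
            tag="channel",
        )
        out = remove_crosstalk(quant, L)
        for rec, true in zip(out.images, hs.images):
            assert np.sqrt(np.mean((rec - true) ** 2)) < 0.01 * true.mean()

    def test_clipping_reported(self):
        imgs = np.stack([np.full((8, 8), 0.01), np.full((8, 8), 0.02)])
        hs = HologramSet(imgs, (405e-9, 520e-9), GEOM.pitch)
        L = CrosstalkMatrix(np.array([[1.0, 0.9], [0.0, 1.0]]))
        with pytest.warns(UserWarning, match="below zero"):
            out = remove_crosstalk(hs, L)
        assert out.meta["clipped_fraction"] > 0.01
        assert out.images.min() == 0.0


@pytest.fixture(scope="module")
def textured_image():
    rng = np.random.default_rng(0)
    img = ndimage.gaussian_filter(rng.standard_normal((256, 256)), 4)
    return (img - img.min()) / np.ptp(img)


class TestRegistration:
    def test_identical_images_are_identity(self, textured_image):
        p = register_channels(np.stack([textured_image] * 3), 0)
        np.testing.assert_allclose(p.scales, 1.0, atol=1e-3)
        np.testing.assert_allclose(p.shifts, 0.0, atol=0.05)

    def test_known_shift_recovered(self, textured_image):
        moved = ndimage.shift(textured_image, (3.0, -2.0), order=3, mode="reflect")
        p = register_channels(
            np.stack([textured_image, moved]), 0, estimate_scale=False
        )
        np.testing.assert_allclose(p.shifts[1], [3.0, -2.0], atol=0.1)

    def test_known_scale_recovered(self, textured_image):
        magnified = _resample(textured_image, 1 / 1.01, (0.0, 0.0))
        p = register_channels(np.stack([textured_image, magnified]), 0)
        assert p.scales[1] == pytest.approx(1.01, abs=0.002)

    def test_featureless_images_rejected(self):
        flat = np.ones((64, 64))
        with pytest.raises(ValueError, match="confidence"):
            register_channels(np.stack([flat, flat]), 0, estimate_scale=False)


class TestApplyRegistration:
    def test_identity_params_bit_identical(self, textured_image):
        hs = HologramSet(np.stack([textured_image] * 3), WL3, GEOM.pitch)
        out = apply_registration(hs, RegistrationParams.identity(3))
        np.testing.assert_array_equal(out.images, hs.images)

    def test_round_trip_within_interpolation_error(self, textured_image):
        moved = _resample(
            ndimage.shift(textured_image, (2.0, -1.0), order=3, mode="reflect"),
            1 / 1.01,
            (0.0, 0.0),
        )
        hs = HologramSet(np.stack([textured_image, moved]), WL3[:2], GEOM.pitch)
        p = register_channels(hs.images, 0)
        out = apply_registration(hs, p)
        resid = (out.images[1] - textured_image)[16:-16, 16:-16]
        assert np.sqrt(np.mean(resid**2)) < 1e-3

    def test_registered_channels_correlate_at_origin(self, textured_image):
        moved = ndimage.shift(textured_image, (4.0, 3.0), order=3, mode="reflect")
        hs = HologramSet(np.stack([textured_image, moved]), WL3[:2], GEOM.pitch)
        p = register_channels(hs.images, 0, estimate_scale=False)
        out = apply_registration(hs, p)
        a = out.images[0] - out.images[0].mean()
        b = out.images[1] - out.images[1].mean()
        xc = np.abs(np.fft.ifft2(np.fft.fft2(a) * np.conj(np.fft.fft2(b))))
        peak = np.unravel_index(np.argmax(xc), xc.shape)
        assert peak == (0, 0)

    def test_params_channel_count_checked(self):
        hs = random_set(3)
        with pytest.raises(ValueError):
            apply_registration(hs, RegistrationParams.identity(2))


def test_full_preprocess_recovers_true_holograms():
    """Mosaic -> demosaic -> equalize -> demix round trip on a small fixture."""
    rng = np.random.default_rng(9)
    truth = HologramSet(
        ndimage.gaussian_filter(rng.uniform(0.6, 1.4, (3, 64, 64)), (0, 2, 2)),
        WL3,
        GEOM.pitch,
    )
    prof = vignette_profile(GEOM, (64, 64))
    L = default_crosstalk(3, leakage=0.1, seed=2)
    mixed = apply_crosstalk(
        HologramSet(truth.images * prof, WL3, GEOM.pitch), L
    )
    frame = mosaic(mixed, CfaPattern.named("rggb"), bit_depth=None)
    channels = HologramSet(demosaic(frame), WL3, GEOM.pitch, tag="channel")
    flat_frame = mosaic(
        apply_crosstalk(HologramSet(np.stack([prof] * 3), WL3, GEOM.pitch), L),
        CfaPattern.named("rggb"),
        bit_depth=None,
    )
    flat = demosaic(flat_frame)
    eq = equalize_background(channels, flat, mode="ratio")
    out = remove_crosstalk(eq, L.column_normalized())
    # demosaic interpolation limits the interior accuracy; scale-free compare
    rec, ref = out.images[:, 8:-8, 8:-8], truth.images[:, 8:-8, 8:-8]
    for r, t in zip(rec, ref):
        r = r * t.mean() / r.mean()
        assert np.sqrt(np.mean((r - t) ** 2)) / t.mean() < 0.02
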