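"""Planar quantification: threshold ROIs, geometric means, dead time,
registration, relative-TAC extraction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridose.core import LN2, RegionLabel
from hybridose.planar import (
    PlanarScanPair,
    correct_dead_time,
    dead_time_loss_factor,
    delineate_roi,
    extract_relative_tacs,
    geometric_mean_rate,
    mirror_lateral,
    register_to_first,
)
from hybridose.synthetic import NoiseOptions, build_patient, translate_image

from conftest import make_kinetics

LIVER = RegionLabel.LIVER
TUMOR = RegionLabel.TUMOR


# ---------------------------------------------------------------------------
# ROI delineation
# ---------------------------------------------------------------------------


class TestDelineateRoi:
    def test_brute_force_threshold(self):
        image = np.array([[10.0, 5.0], [4.0, 3.0]])
        mask = delineate_roi(image, np.ones((2, 2), bool), 0.40)
        assert image[mask].sum() == 19.0  # keeps {10, 5, 4}
        assert not mask[1, 1]

    def test_constant_image_keeps_whole_boundary(self):
        boundary = np.zeros((3, 3), bool)
        boundary[1, :] = True
        mask = delineate_roi(np.full((3, 3), 2.0), boundary, 0.40)
        np.testing.assert_array_equal(mask, boundary)

    def test_single_pixel_boundary(self):
        boundary = np.zeros((2, 2), bool)
        boundary[0, 0] = True
        image = np.array([[3.0, 0.0], [0.0, 0.0]])
        assert delineate_roi(image, boundary, 0.4)[0, 0]
        with pytest.raises(ValueError, match="positive maximum"):
            delineate_roi(np.zeros((2, 2)), boundary, 0.4)

    def test_empty_boundary_and_bad_fraction(self):
        with pytest.raises(ValueError):
            delineate_roi(np.ones((2, 2)), np.zeros((2, 2), bool), 0.4)
        with pytest.raises(ValueError):
            delineate_roi(np.ones((2, 2)), np.ones((2, 2), bool), 1.2)


# ---------------------------------------------------------------------------
# geometric mean
# ---------------------------------------------------------------------------


def _pair(ant, post, duration=1.0):
    return PlanarScanPair(
        anterior=np.asarray(ant, float),
        posterior=np.asarray(post, float),
        time_h=3.0,
        duration_s=duration,
    )


class TestGeometricMean:
    def test_known_rates(self):
        # ROI-summed rates 100 and 64 cps -> GM 80 cps
        pair = _pair([[100.0]], [[64.0]])
        rate, sigma = geometric_mean_rate(pair, np.ones((1, 1), bool))
        assert rate == pytest.approx(80.0)
        assert sigma == pytest.approx(0.5 * 80.0 * math.sqrt(1 / 100 + 1 / 64))

    def test_equal_views_identity(self):
        # lateral axis is axis 0: posterior stored mirrored along it
        pair = _pair([[55.0], [5.0]], [[5.0], [55.0]])
        roi = np.array([[True], [False]])
        rate, _ = geometric_mean_rate(pair, roi)
        assert rate == pytest.approx(55.0)

    def test_swap_views_invariance(self):
        ant = np.array([[100.0, 3.0], [7.0, 1.0]])
        post = np.array([[2.0, 60.0], [0.5, 9.0]])
        roi = np.ones((2, 2), bool)
        rate, _ = geometric_mean_rate(_pair(ant, post), roi)
        swapped = _pair(mirror_lateral(post), mirror_lateral(ant))
        rate_swapped, _ = geometric_mean_rate(swapped, roi)
        assert rate_swapped == pytest.approx(rate, rel=1e-12)

    def test_zero_counts_error(self):
        with pytest.raises(ValueError, match="zero counts"):
            geometric_mean_rate(_pair([[0.0]], [[5.0]]), np.ones((1, 1), bool))


# ---------------------------------------------------------------------------
# dead time
# ---------------------------------------------------------------------------


class TestDeadTime:
    def test_tau_zero_identity(self):
        assert correct_dead_time(12345.0, 0.0) == 12345.0

    def test_forward_model_inversion(self):
        # 50,000 cps at tau = 1 us is observed as 47,561.5 cps
        observed = 50000.0 * math.exp(-50000.0 * 1e-6)
        assert observed == pytest.approx(47561.47, abs=0.01)
        assert correct_dead_time(observed, 1e-6) == pytest.approx(50000.0, rel=1e-9)

    def test_low_rate_limit(self):
        assert correct_dead_time(1e-6, 1e-6) == pytest.approx(1e-6, rel=1e-6)
        assert correct_dead_time(0.0, 1e-6) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=0.0, max_value=0.9))
    def test_round_trip_identity(self, fraction):
        tau = 2e-6
        true_rate = fraction / (math.e * tau)
        observed = true_rate * dead_time_loss_factor(true_rate, tau)
        assert correct_dead_time(observed, tau) == pytest.approx(
            true_rate, rel=1e-9, abs=1e-9
        )

    def test_above_paralyzable_maximum_raises(self):
        tau = 1e-6
        with pytest.raises(ValueError, match="paralyzable maximum"):
            correct_dead_time(1.01 / (math.e * tau), tau)


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------


def _blob_image(shape=(48, 48), center=(22, 25), seed=None, scale=4000.0):
    x, z = np.indices(shape)
    img = scale * np.exp(-(((x - center[0]) / 5.0) ** 2 + ((z - center[1]) / 7.0) ** 2))
    if seed is not None:
        img = np.random.default_rng(seed).poisson(img).astype(float)
    return img


class TestRegistration:
    def test_identity(self):
        img = _blob_image()
        fixed = _pair(img, mirror_lateral(img))
        shift, resampled = register_to_first(fixed, fixed)
        assert shift == (0, 0)
        np.testing.assert_array_equal(resampled.anterior, fixed.anterior)

    def test_known_shift_recovered(self):
        img = _blob_image()
        fixed = _pair(img, mirror_lateral(img))
        moving = _pair(
            translate_image(img, (5, -3)),
            mirror_lateral(translate_image(img, (5, -3))),
        )
        shift, resampled = register_to_first(moving, fixed)
        assert shift == (5, -3)
        core = (slice(8, -8), slice(8, -8))
        np.testing.assert_allclose(resampled.anterior[core], fixed.anterior[core])
        np.testing.assert_allclose(resampled.posterior[core], fixed.posterior[core])

    def test_noisy_shift_recovery_rate(self):
        """Poisson noise at high SNR: exact recovery in >= 95/100 trials."""
        clean = _blob_image(scale=400.0)
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            fixed_img = rng.poisson(clean).astype(float)
            moving_img = rng.poisson(translate_image(clean, (4, -2))).astype(float)
            shift, _ = register_to_first(
                _pair(moving_img, mirror_lateral(moving_img)),
                _pair(fixed_img, mirror_lateral(fixed_img)),
            )
            hits += shift == (4, -2)
        assert hits >= 95

    def test_flat_images_raise(self):
        with pytest.raises(ValueError, match="flat"):
            register_to_first(_pair(np.ones((20, 20)), np.ones((20, 20))),
                              _pair(np.ones((20, 20)), np.ones((20, 20))))


# ---------------------------------------------------------------------------
# relative TAC extraction
# ---------------------------------------------------------------------------


class TestExtractRelativeTacs:
    def test_noiseless_ratios_match_ground_truth(self, phantom, noiseless_options):
        kin = make_kinetics(uptakes={LIVER: 0.3}, half_lives={LIVER: 12.6}, tau=2e-6)
        ds = build_patient(phantom, kin, noiseless_options, seed=0)
        tacs, failures = extract_relative_tacs(ds)
        assert not failures or LIVER in tacs
        rates = tacs[LIVER].rates
        for t, r in zip(tacs[LIVER].times[1:], rates[1:]):
            assert r / rates[0] == pytest.approx(
                math.exp(-LN2 * (t - 3.0) / 12.6), rel=1e-6
            )

    def test_couch_shifts_are_compensated(self, phantom):
        kin = make_kinetics(uptakes={LIVER: 0.3}, half_lives={LIVER: 12.6})
        opts = NoiseOptions(poisson=False, spect_blur_fwhm_mm=0.0, couch_shift_px=3)
        ds = build_patient(phantom, kin, opts, seed=5)
        tacs, _ = extract_relative_tacs(ds)
        rates = tacs[LIVER].rates
        for t, r in zip(tacs[LIVER].times[1:], rates[1:]):
            assert r / rates[0] == pytest.approx(
                math.exp(-LN2 * (t - 3.0) / 12.6), rel=5e-3
            )

    def test_two_scan_patient_yields_two_samples(self, phantom, noiseless_options):
        kin = make_kinetics(times=(3.0, 24.0))
        ds = build_patient(phantom, kin, noiseless_options, seed=0)
        tacs, _ = extract_relative_tacs(ds)
        assert len(tacs[LIVER].samples) == 2

    def test_zero_uptake_region_fails_per_region(self, phantom, noiseless_options):
        kin = make_kinetics(uptakes={LIVER: 0.3})  # nothing in the stomach
        ds = build_patient(phantom, kin, noiseless_options, seed=0)
        tacs, failures = extract_relative_tacs(ds)
        assert LIVER in tacs
        assert RegionLabel.STOMACH in failures

    def test_shape_invariant_to_calibration_and_attenuation(self, phantom):
        """Relative TAC ratios do not depend on the calibration factor or
        on (time-constant) attenuation."""
        ratios = []
        for cf, attenuation in [(10.0, True), (20.0, False)]:
            kin = make_kinetics(
                uptakes={LIVER: 0.3},
                half_lives={LIVER: 12.6},
                planar_calibration_cps_per_MBq=cf,
            )
            opts = NoiseOptions(
                poisson=False,
                spect_blur_fwhm_mm=0.0,
                couch_shift_px=0,
                include_attenuation=attenuation,
            )
            ds = build_patient(phantom, kin, opts, seed=0)
            tacs, _ = extract_relative_tacs(ds)
            rates = tacs[LIVER].rates
            ratios.append(rates / rates[0])
        np.testing.assert_allclose(ratios[0], ratios[1], rtol=1e-9)
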