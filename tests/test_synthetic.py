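"""Synthetic cohort generator: sampling, projection physics, counting model."""

import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm

from hybridose.core import LN2, RegionLabel
from hybridose.synthetic import (
    CohortDistributions,
    EllipsoidRegion,
    NoiseOptions,
    PhantomGeometry,
    TruncatedNormal,
    apply_counting_model,
    build_patient,
    expected_counts,
    project_planar,
    sample_cohort,
)

from conftest import make_kinetics

LIVER = RegionLabel.LIVER
TUMOR = RegionLabel.TUMOR


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------


class TestSampleCohort:
    def test_deterministic_under_fixed_seed(self):
        a = sample_cohort(3, seed=7)
        b = sample_cohort(3, seed=7)
        for ka, kb in zip(a, b):
            assert ka == kb
            for t in ka.half_lives_h.values():
                assert 2.0 < t <= 17.0

    def test_truncated_normal_mean_matches_quadrature(self):
        """Sample mean of liver T_eff vs numerical integration of the
        truncated-normal density (independent quadrature oracle)."""
        spec = TruncatedNormal(12.6, 1.7, lower=2.0, upper=17.0)
        cohort = sample_cohort(10000, seed=1)
        sample_mean = np.mean([k.half_lives_h[LIVER] for k in cohort])

        z = norm(loc=spec.mean, scale=spec.sd)
        mass, _ = integrate.quad(z.pdf, spec.lower, spec.upper)
        num, _ = integrate.quad(lambda x: x * z.pdf(x), spec.lower, spec.upper)
        assert abs(sample_mean - num / mass) < 0.1

    def test_zero_sd_returns_mean_exactly(self):
        params = CohortDistributions(
            half_lives={r: TruncatedNormal(12.6, 0.0) for r in (TUMOR, LIVER)},
            uptakes=CohortDistributions().uptakes,
        )
        k = sample_cohort(1, params, seed=0)[0]
        assert k.half_lives_h[TUMOR] == 12.6
        assert k.half_lives_h[LIVER] == 12.6

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            sample_cohort(0, seed=1)
        with pytest.raises(ValueError):
            TruncatedNormal(12.6, 1.7, lower=17.0, upper=2.0)
        with pytest.raises(ValueError):
            TruncatedNormal(12.6, 0.1, lower=100.0, upper=101.0)

    def test_two_scan_fraction(self):
        params = CohortDistributions(two_scan_fraction=1.0)
        assert all(len(k.scan_times_h) == 2 for k in sample_cohort(5, params, seed=3))
        params = CohortDistributions(two_scan_fraction=0.0)
        assert all(len(k.scan_times_h) == 3 for k in sample_cohort(5, params, seed=3))


# ---------------------------------------------------------------------------
# planar projection
# ---------------------------------------------------------------------------


def uniform_slab_phantom(mu=0.15, n=20, voxel=5.0):
    """A slab of attenuator spanning the full grid depth."""
    half = n * voxel  # ellipsoid big enough to cover the grid
    return PhantomGeometry(
        shape=(n, n, n),
        voxel_size_mm=voxel,
        regions=(
            EllipsoidRegion(
                RegionLabel.BACKGROUND, (half / 2,) * 3, (10 * half,) * 3, mu
            ),
        ),
    )


class TestProjectPlanar:
    def test_views_identical_without_attenuation(self, phantom):
        act = np.zeros(phantom.shape)
        act[10, 7, 30] = 5.0
        ant = project_planar(phantom, act, "anterior", include_attenuation=False)
        post = project_planar(phantom, act, "posterior", include_attenuation=False)
        np.testing.assert_array_equal(ant, post)

    def test_total_counts_conserved_without_attenuation(self, phantom):
        rng = np.random.default_rng(0)
        act = rng.uniform(size=phantom.shape)
        img = project_planar(phantom, act, "anterior", False, calibration_cps_per_MBq=3.0)
        assert img.sum() == pytest.approx(3.0 * act.sum(), rel=1e-12)

    @pytest.mark.parametrize("depth_voxel", [2, 9, 16])
    def test_conjugate_view_depth_invariance(self, depth_voxel):
        """sqrt(I_ant * I_post) = I0 exp(-mu T / 2) regardless of depth."""
        mu = 0.15
        ph = uniform_slab_phantom(mu=mu)
        act = np.zeros(ph.shape)
        act[10, depth_voxel, 10] = 7.0
        ant = project_planar(ph, act, "anterior")
        post = project_planar(ph, act, "posterior")
        gm = math.sqrt(ant[10, 10] * post[10, 10])
        thickness_cm = ph.shape[1] * ph.voxel_size_mm / 10.0
        assert gm == pytest.approx(7.0 * math.exp(-mu * thickness_cm / 2.0), rel=1e-6)

    def test_uniform_slab_line_integral(self):
        ph = uniform_slab_phantom(mu=0.0)
        act = np.full(ph.shape, 0.25)
        img = project_planar(ph, act, "anterior", include_attenuation=False,
                             calibration_cps_per_MBq=2.0)
        expected = ph.shape[1] * 0.25 * 2.0
        np.testing.assert_allclose(img, expected, rtol=1e-12)

    def test_mismatched_grid_raises(self, phantom):
        with pytest.raises(ValueError):
            project_planar(phantom, np.zeros((2, 2, 2)), "anterior")


# ---------------------------------------------------------------------------
# counting model
# ---------------------------------------------------------------------------


class TestCountingModel:
    def test_pure_poisson_mean(self):
        rates = np.array([[10.0, 50.0], [0.5, 200.0]])
        duration = 3.0
        totals = np.mean(
            [apply_counting_model(rates, 0.0, duration, seed=s) for s in range(200)],
            axis=0,
        )
        se = np.sqrt(rates * duration / 200.0)
        assert np.all(np.abs(totals - rates * duration) <= 3.0 * se + 1e-9)

    def test_paralyzable_loss_factor(self):
        """Total rate 50 kcps at tau = 1 us loses the factor exp(-0.05)."""
        rates = np.full((100, 100), 5.0)  # sums to 50,000 cps
        counts = expected_counts(rates, 1e-6, duration_s=2.0)
        assert counts.sum() == pytest.approx(
            100000.0 * math.exp(-0.05), rel=1e-12
        )

    def test_zero_rate_zero_counts(self):
        out = apply_counting_model(np.zeros((4, 4)), 1e-6, 10.0, seed=0)
        assert np.all(out == 0)

    def test_negative_rates_raise(self):
        with pytest.raises(ValueError):
            apply_counting_model(np.array([[-1.0]]), 0.0, 1.0)


# ---------------------------------------------------------------------------
# phantom and patient assembly
# ---------------------------------------------------------------------------


class TestPhantom:
    def test_default_phantom_invariants(self, phantom):
        phantom.validate()

    def test_tumor_outside_liver_rejected(self, phantom):
        regions = tuple(
            EllipsoidRegion(TUMOR, (200.0, 80.0, 30.0), r.semiaxes_mm, r.mu_per_cm)
            if r.label == TUMOR
            else r
            for r in phantom.regions
        )
        bad = PhantomGeometry(phantom.shape, phantom.voxel_size_mm, regions)
        with pytest.raises(ValueError, match="inside the liver"):
            bad.validate()

    def test_tumor_takes_precedence_over_liver(self, phantom, phantom_labels):
        tumor = next(r for r in phantom.regions if r.label == TUMOR)
        assert np.all(
            phantom_labels[phantom._membership(tumor)] == int(TUMOR)
        )


class TestBuildPatient:
    def test_activity_conservation_noise_and_blur_off(self, phantom, noiseless_options):
        kin = make_kinetics(
            uptakes={TUMOR: 0.1, LIVER: 0.4}, half_lives={TUMOR: 12.5, LIVER: 12.6}
        )
        ds = build_patient(phantom, kin, noiseless_options, seed=0)
        total = sum(f * kin.injected_activity_MBq for f in kin.uptake_fractions.values())
        assert ds.spect.activity_MBq.sum() == pytest.approx(total, rel=1e-9)
        liver_sum = ds.spect.activity_MBq[ds.spect.labels == int(LIVER)].sum()
        assert liver_sum == pytest.approx(0.4 * 2000.0, rel=1e-9)

    def test_planar_ratios_follow_decay(self, phantom, noiseless_options):
        kin = make_kinetics(uptakes={LIVER: 0.3}, half_lives={LIVER: 12.6})
        ds = build_patient(phantom, kin, noiseless_options, seed=0)
        sums = [p.anterior.sum() for p in ds.planar]
        for t, s in zip(kin.scan_times_h[1:], sums[1:]):
            assert s / sums[0] == pytest.approx(
                math.exp(-LN2 * (t - 3.0) / 12.6), rel=1e-12
            )

    def test_two_scan_times(self, phantom, noiseless_options):
        kin = make_kinetics(times=(3.0, 24.0))
        ds = build_patient(phantom, kin, noiseless_options, seed=0)
        assert len(ds.planar) == 2
        assert ds.spect.time_h == 3.0

    def test_seed_determinism(self, phantom):
        kin = make_kinetics(tau=2e-6)
        a = build_patient(phantom, kin, NoiseOptions(), seed=11)
        b = build_patient(phantom, kin, NoiseOptions(), seed=11)
        for pa, pb in zip(a.planar, b.planar):
            np.testing.assert_array_equal(pa.anterior, pb.anterior)
            np.testing.assert_array_equal(pa.posterior, pb.posterior)
        np.testing.assert_array_equal(a.spect.activity_MBq, b.spect.activity_MBq)

    def test_blur_preserves_total_activity(self, phantom):
        kin = make_kinetics()
        opts = NoiseOptions(poisson=False, spect_blur_fwhm_mm=12.0, couch_shift_px=0)
        ds = build_patient(phantom, kin, opts, seed=0)
        assert ds.spect.activity_MBq.sum() == pytest.approx(0.3 * 2000.0, rel=1e-6)

    def test_invalid_kinetics_rejected(self):
        with pytest.raises(ValueError):
            make_kinetics(uptakes={LIVER: 1.5})
        with pytest.raises(ValueError):
            make_kinetics(half_lives={LIVER: 18.0})
        with pytest.raises(ValueError):
            make_kinetics(times=(3.0,))
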