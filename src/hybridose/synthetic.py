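"""Synthetic patient generator for the hybrid planar/SPECT dosimetry pipeline.

Real input data for this kind of study are serial anterior/posterior
whole-body scans plus one quantitative SPECT/CT, none of which can be
shipped.  This module builds fully specified stand-in patients instead: a
voxelized ellipsoid phantom, organ-wise mono-exponential kinetics sampled
from the population the clinical cohort exhibited, ideal conjugate-view
projections with depth-dependent attenuation, paralyzable dead-time losses
and Poisson counting noise, and a calibrated SPECT activity volume with an
optional Gaussian partial-volume blur.  Ground-truth kinetics are retained
on every dataset so each downstream stage can be tested against the truth.

Conventions: grid axes are (x lateral, y anterior->posterior, z axial);
planar images are (x, z); voxel indices are 0-based and world coordinates
are millimetres at voxel centers.  The posterior view is stored laterally
mirrored (camera frame), exactly as a dual-head acquisition delivers it.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import norm, truncnorm

from .core import LN2, QUANTIFIED_REGIONS, PatientRecord, RegionLabel

# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EllipsoidRegion:
    """Axis-aligned ellipsoid with a region label and attenuation."""

    label: RegionLabel
    center_mm: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]
    mu_per_cm: float = 0.15

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semiaxes_mm):
            raise ValueError("semiaxes must be positive")
        if self.mu_per_cm < 0:
            raise ValueError("attenuation coefficient must be >= 0")

    def analytic_volume_mL(self) -> float:
        a, b, c = self.semiaxes_mm
        return 4.0 / 3.0 * math.pi * a * b * c / 1000.0

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        """Membership of an (N, 3) array of world coordinates."""
        p = (np.asarray(points_mm, dtype=float) - np.asarray(self.center_mm)) / np.asarray(
            self.semiaxes_mm
        )
        return (p**2).sum(axis=-1) <= 1.0

    def surface_points(self, n_theta: int = 24, n_phi: int = 48) -> np.ndarray:
        theta = np.linspace(0.0, math.pi, n_theta)
        phi = np.linspace(0.0, 2.0 * math.pi, n_phi, endpoint=False)
        th, ph = np.meshgrid(theta, phi, indexing="ij")
        a, b, c = self.semiaxes_mm
        cx, cy, cz = self.center_mm
        pts = np.stack(
            [
                cx + a * np.sin(th) * np.cos(ph),
                cy + b * np.sin(th) * np.sin(ph),
                cz + c * np.cos(th),
            ],
            axis=-1,
        )
        return pts.reshape(-1, 3)


@dataclass(frozen=True)
class PhantomGeometry:
    """Voxelized anatomy: a list of ellipsoid regions on a regular grid.

    Labels are mutually exclusive.  Non-tumor regions claim voxels in list
    order; the tumor always takes precedence over the liver (it is required
    to lie fully inside it).  Regions carrying ``RegionLabel.BACKGROUND``
    contribute attenuation only (body outline).
    """

    shape: tuple[int, int, int]
    voxel_size_mm: float
    regions: tuple[EllipsoidRegion, ...]

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        if any(n < 1 for n in self.shape):
            raise ValueError("grid shape must be positive")

    # -- geometry helpers ---------------------------------------------------

    @property
    def voxel_volume_mL(self) -> float:
        return self.voxel_size_mm**3 / 1000.0

    def axis_coordinates_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            (np.arange(n, dtype=float) + 0.5) * self.voxel_size_mm for n in self.shape
        )

    def _membership(self, region: EllipsoidRegion) -> np.ndarray:
        x, y, z = self.axis_coordinates_mm()
        cx, cy, cz = region.center_mm
        ax, ay, az = region.semiaxes_mm
        q = (
            ((x[:, None, None] - cx) / ax) ** 2
            + ((y[None, :, None] - cy) / ay) ** 2
            + ((z[None, None, :] - cz) / az) ** 2
        )
        return q <= 1.0

    def label_volume(self) -> np.ndarray:
        labels = np.zeros(self.shape, dtype=np.int16)
        tumor = None
        for region in self.regions:
            if region.label == RegionLabel.BACKGROUND:
                continue
            if region.label == RegionLabel.TUMOR:
                tumor = region
                continue
            member = self._membership(region)
            labels[member & (labels == 0)] = int(region.label)
        if tumor is not None:
            labels[self._membership(tumor)] = int(RegionLabel.TUMOR)
        return labels

    def attenuation_volume(self) -> np.ndarray:
        mu = np.zeros(self.shape, dtype=float)
        for region in self.regions:
            mu[self._membership(region)] = region.mu_per_cm
        return mu

    def region_volume_mL(self, label: RegionLabel, labels: np.ndarray | None = None) -> float:
        if labels is None:
            labels = self.label_volume()
        return float(np.count_nonzero(labels == int(label))) * self.voxel_volume_mL

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Check the structural invariants of the phantom.

        Raises ``ValueError`` if the tumor is not fully inside the liver,
        if two regions other than the (tumor, liver) pair overlap, or if a
        voxelized region volume deviates from the analytic ellipsoid volume
        by more than one voxel-shell (surface area times voxel size).
        """
        by_label = {r.label: r for r in self.regions}
        tumor = by_label.get(RegionLabel.TUMOR)
        liver = by_label.get(RegionLabel.LIVER)
        if tumor is not None and liver is not None:
            if not np.all(liver.contains(tumor.surface_points())):
                raise ValueError("tumor ellipsoid must lie fully inside the liver")
        organ_regions = [r for r in self.regions if r.label != RegionLabel.BACKGROUND]
        for r1, r2 in itertools.combinations(organ_regions, 2):
            pair = {r1.label, r2.label}
            if pair == {RegionLabel.TUMOR, RegionLabel.LIVER}:
                continue
            overlap = np.count_nonzero(self._membership(r1) & self._membership(r2))
            if overlap:
                raise ValueError(
                    f"regions {r1.label.name} and {r2.label.name} overlap "
                    f"({overlap} voxels)"
                )
        labels = self.label_volume()
        for region in organ_regions:
            analytic = region.analytic_volume_mL()
            if region.label == RegionLabel.LIVER and tumor is not None:
                voxel = self.region_volume_mL(
                    RegionLabel.LIVER, labels
                ) + self.region_volume_mL(RegionLabel.TUMOR, labels)
            else:
                voxel = self.region_volume_mL(region.label, labels)
            a, b, c = (s / 10.0 for s in region.semiaxes_mm)  # cm
            # Knud Thomsen approximation of the ellipsoid surface (cm^2)
            p = 1.6075
            surface = 4.0 * math.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0) ** (
                1.0 / p
            )
            shell = surface * self.voxel_size_mm / 10.0  # mL
            if abs(voxel - analytic) > shell:
                raise ValueError(
                    f"voxelized volume of {region.label.name} ({voxel:.1f} mL) "
                    f"deviates from analytic ({analytic:.1f} mL) by more than "
                    f"one voxel-shell ({shell:.1f} mL)"
                )


def default_phantom(voxel_size_mm: float = 5.0) -> PhantomGeometry:
    """Desk-scale torso phantom: body outline, lungs, liver with an embedded
    spherical tumor, stomach, spleen and kidneys.  Attenuation coefficients
    approximate soft tissue (0.15/cm) and lung (0.04/cm) at 155 keV."""
    n = int(round(240.0 / voxel_size_mm))
    ny = int(round(160.0 / voxel_size_mm))
    regions = (
        EllipsoidRegion(RegionLabel.BACKGROUND, (120, 80, 120), (115, 75, 115), 0.15),
        EllipsoidRegion(RegionLabel.LUNGS, (120, 75, 50), (70, 45, 38), 0.04),
        EllipsoidRegion(RegionLabel.LIVER, (90, 80, 140), (70, 52, 50), 0.15),
        EllipsoidRegion(RegionLabel.TUMOR, (85, 80, 150), (25, 25, 25), 0.15),
        EllipsoidRegion(RegionLabel.STOMACH, (185, 85, 105), (25, 22, 25), 0.15),
        EllipsoidRegion(RegionLabel.SPLEEN, (185, 80, 168), (22, 20, 22), 0.15),
        EllipsoidRegion(RegionLabel.KIDNEYS, (120, 130, 185), (35, 15, 20), 0.15),
    )
    return PhantomGeometry(shape=(n, ny, n), voxel_size_mm=voxel_size_mm, regions=regions)


# ---------------------------------------------------------------------------
# population distributions and ground-truth kinetics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruncatedNormal:
    """Normal distribution truncated to (lower, upper]."""

    mean: float
    sd: float
    lower: float = 2.0
    upper: float = 17.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean) or not np.isfinite(self.sd) or self.sd < 0:
            raise ValueError("mean and sd must be finite, sd >= 0")
        if self.lower >= self.upper:
            raise ValueError("truncation bounds must satisfy lower < upper")
        if self.sd > 0:
            a, b = (self.lower - self.mean) / self.sd, (self.upper - self.mean) / self.sd
            if norm.cdf(b) - norm.cdf(a) <= 0.0:
                raise ValueError("truncation bounds exclude all probability mass")
        elif not (self.lower < self.mean <= self.upper):
            raise ValueError("degenerate distribution: mean outside truncation bounds")

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.sd == 0:
            return self.mean if size is None else np.full(size, self.mean)
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=size, random_state=rng)


@dataclass(frozen=True)
class Uniform:
    low: float
    high: float

    def sample(self, rng: np.random.Generator, size: int | None = None):
        return rng.uniform(self.low, self.high, size=size)


@dataclass(frozen=True)
class LogUniform:
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low <= 0 or self.high <= self.low:
            raise ValueError("log-uniform bounds must satisfy 0 < low < high")

    def sample(self, rng: np.random.Generator, size: int | None = None):
        return np.exp(rng.uniform(math.log(self.low), math.log(self.high), size=size))


def _default_half_life_specs() -> dict[RegionLabel, TruncatedNormal]:
    pop = {
        RegionLabel.TUMOR: (12.5, 1.9),
        RegionLabel.LIVER: (12.6, 1.7),
        RegionLabel.LUNGS: (12.0, 1.9),
        RegionLabel.STOMACH: (10.9, 1.9),
        RegionLabel.SPLEEN: (14.7, 2.3),
        RegionLabel.KIDNEYS: (12.8, 2.5),
    }
    return {r: TruncatedNormal(m, s) for r, (m, s) in pop.items()}


def _default_uptake_specs() -> dict[RegionLabel, LogUniform | Uniform]:
    return {
        RegionLabel.TUMOR: LogUniform(0.01, 0.30),
        RegionLabel.LIVER: Uniform(0.15, 0.40),
        RegionLabel.LUNGS: Uniform(0.005, 0.02),
        RegionLabel.STOMACH: Uniform(0.005, 0.03),
        RegionLabel.SPLEEN: Uniform(0.003, 0.015),
        RegionLabel.KIDNEYS: Uniform(0.003, 0.015),
    }


@dataclass(frozen=True)
class CohortDistributions:
    """Population the cohort is sampled from.

    Effective half-lives are drawn per region from truncated normals
    centered on the clinical population values (tumor 12.5 +- 1.9 h, liver
    12.6 +- 1.7 h, lungs 12.0 +- 1.9 h, ...), truncated to (2 h, 17 h].
    Tumor uptake is log-uniform over 1%-30% of the injected activity; organ
    uptakes are uniform over modest ranges.  Half-lives of different organs
    within a patient are sampled independently (no inter-organ correlation
    is imposed; configurable only by replacing the specs).
    """

    half_lives: dict[RegionLabel, TruncatedNormal] = field(
        default_factory=_default_half_life_specs
    )
    uptakes: dict[RegionLabel, LogUniform | Uniform] = field(
        default_factory=_default_uptake_specs
    )
    injected_activity: Uniform = Uniform(1296.0, 7162.0)
    scan_times_h: tuple[float, ...] = (3.0, 24.0, 48.0)
    time_jitter_h: tuple[float, ...] = (1.0, 1.0, 4.0)
    jitter_times: bool = False
    two_scan_fraction: float = 4.0 / 13.0
    physical_half_life_h: float = 17.0
    dead_time_tau_s: float = 2.0e-6
    planar_calibration_cps_per_MBq: float = 10.0
    biexp_slow_fraction: float = 0.0


@dataclass(frozen=True)
class GroundTruthKinetics:
    """True kinetics of one synthetic patient.

    ``uptake_fractions`` are fractions of the injected activity residing in
    each region at the first scan time; ``half_lives_h`` are the effective
    half-lives governing the mono-exponential washout anchored at t1.  A
    positive ``biexp_slow_fraction`` switches each region to a two-component
    decay: (1 - s) at the region half-life plus s at the physical half-life,
    emulating a fast free-radionuclide phase followed by physical decay of
    the still-bound fraction.
    """

    uptake_fractions: dict[RegionLabel, float]
    half_lives_h: dict[RegionLabel, float]
    injected_activity_MBq: float
    scan_times_h: tuple[float, ...]
    physical_half_life_h: float = 17.0
    dead_time_tau_s: float = 2.0e-6
    planar_calibration_cps_per_MBq: float = 10.0
    biexp_slow_fraction: float = 0.0

    def __post_init__(self) -> None:
        fracs = np.array(list(self.uptake_fractions.values()), dtype=float)
        if np.any(fracs <= 0) or np.any(fracs >= 1) or fracs.sum() > 1.0 + 1e-12:
            raise ValueError("uptake fractions must lie in (0, 1) and sum to <= 1")
        for region, half_life in self.half_lives_h.items():
            if not 0 < half_life <= self.physical_half_life_h + 1e-12:
                raise ValueError(
                    f"effective half-life of {RegionLabel(region).name} must lie in "
                    f"(0, T_phys]"
                )
        if self.injected_activity_MBq <= 0:
            raise ValueError("injected activity must be positive")
        if len(self.scan_times_h) not in (2, 3):
            raise ValueError("2 or 3 scan times required")
        if self.dead_time_tau_s < 0:
            raise ValueError("dead-time constant must be >= 0")
        if not 0 <= self.biexp_slow_fraction < 1:
            raise ValueError("slow fraction must lie in [0, 1)")

    def region_activity_MBq(self, region: RegionLabel, time_h: float) -> float:
        """True activity of a region, anchored at the first scan time."""
        if region not in self.uptake_fractions:
            return 0.0
        t1 = self.scan_times_h[0]
        a1 = self.uptake_fractions[region] * self.injected_activity_MBq
        dt = time_h - t1
        fast = math.exp(-LN2 * dt / self.half_lives_h[region])
        if self.biexp_slow_fraction == 0:
            return a1 * fast
        slow = math.exp(-LN2 * dt / self.physical_half_life_h)
        s = self.biexp_slow_fraction
        return a1 * ((1.0 - s) * fast + s * slow)


def sample_cohort(
    n_patients: int,
    population_params: CohortDistributions | None = None,
    seed: int = 0,
) -> list[GroundTruthKinetics]:
    """Draw a reproducible cohort of ground-truth kinetics.

    Identical ``(population_params, seed)`` yield an identical cohort.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    params = population_params or CohortDistributions()
    rng = np.random.default_rng(seed)
    cohort = []
    for _ in range(n_patients):
        half_lives = {
            region: float(spec.sample(rng)) for region, spec in params.half_lives.items()
        }
        uptakes = {
            region: float(spec.sample(rng)) for region, spec in params.uptakes.items()
        }
        a0 = float(params.injected_activity.sample(rng))
        times = np.asarray(params.scan_times_h, dtype=float)
        if params.jitter_times:
            jitter = np.asarray(params.time_jitter_h, dtype=float)[: times.size]
            times = times + rng.uniform(-jitter, jitter)
        if rng.uniform() < params.two_scan_fraction:
            times = times[:2]
        cohort.append(
            GroundTruthKinetics(
                uptake_fractions=uptakes,
                half_lives_h=half_lives,
                injected_activity_MBq=a0,
                scan_times_h=tuple(float(t) for t in times),
                physical_half_life_h=params.physical_half_life_h,
                dead_time_tau_s=params.dead_time_tau_s,
                planar_calibration_cps_per_MBq=params.planar_calibration_cps_per_MBq,
                biexp_slow_fraction=params.biexp_slow_fraction,
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# planar projection and counting model
# ---------------------------------------------------------------------------


def project_planar(
    phantom: PhantomGeometry,
    activity_map: np.ndarray,
    direction: str = "anterior",
    include_attenuation: bool = True,
    calibration_cps_per_MBq: float = 1.0,
) -> np.ndarray:
    """Expected count-rate image of an ideal planar acquisition.

    Line-integral projection along the anterior-posterior axis (axis 1).
    With attenuation enabled, each voxel is attenuated by exp(-mu-path) from
    its center to the corresponding body surface.  Both views are returned
    in the anterior (unmirrored) frame; with attenuation disabled the two
    views are identical and total counts equal total activity times the
    calibration factor.
    """
    activity_map = np.asarray(activity_map, dtype=float)
    if activity_map.shape != phantom.shape:
        raise ValueError("activity map and phantom must share the same grid")
    if direction not in ("anterior", "posterior"):
        raise ValueError("direction must be 'anterior' or 'posterior'")
    if include_attenuation:
        mu_dl = phantom.attenuation_volume() * (phantom.voxel_size_mm / 10.0)
        if direction == "anterior":
            path = np.cumsum(mu_dl, axis=1) - 0.5 * mu_dl
        else:
            path = np.cumsum(mu_dl[:, ::-1, :], axis=1)[:, ::-1, :] - 0.5 * mu_dl
        weighted = activity_map * np.exp(-path)
    else:
        weighted = activity_map
    return weighted.sum(axis=1) * calibration_cps_per_MBq


def apply_counting_model(
    expected_rates: np.ndarray,
    tau_s: float,
    duration_s: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Observed counts: paralyzable dead-time losses followed by Poisson noise.

    The loss factor exp(-n tau), with n the image-total true rate, is
    applied uniformly to all pixels (the camera loses events globally), then
    each pixel is drawn Poisson with mean duration times the lost rate.
    """
    rates = np.asarray(expected_rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("expected rates must be >= 0")
    if tau_s < 0 or duration_s <= 0:
        raise ValueError("tau must be >= 0 and duration > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    loss = math.exp(-float(rates.sum()) * tau_s)
    return rng.poisson(rates * loss * duration_s).astype(float)


def expected_counts(expected_rates: np.ndarray, tau_s: float, duration_s: float) -> np.ndarray:
    """Noise-free counterpart of :func:`apply_counting_model`."""
    rates = np.asarray(expected_rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("expected rates must be >= 0")
    loss = math.exp(-float(rates.sum()) * tau_s)
    return rates * loss * duration_s


# ---------------------------------------------------------------------------
# patient assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlanarScanPair:
    """One anterior/posterior whole-body pair.

    ``posterior`` is stored in the camera (laterally mirrored) frame.
    """

    anterior: np.ndarray
    posterior: np.ndarray
    time_h: float
    duration_s: float
    dead_time_corrected: bool = False

    def __post_init__(self) -> None:
        if self.anterior.shape != self.posterior.shape:
            raise ValueError("anterior and posterior images must share a shape")
        if np.any(self.anterior < 0) or np.any(self.posterior < 0):
            raise ValueError("counts must be >= 0")
        if self.time_h < 0 or self.duration_s <= 0:
            raise ValueError("time must be >= 0 and duration > 0")


@dataclass(frozen=True)
class SpectStudy:
    """Calibrated SPECT activity volume with its anatomical label volume."""

    activity_MBq: np.ndarray
    labels: np.ndarray
    voxel_volume_mL: float
    time_h: float

    def __post_init__(self) -> None:
        if self.activity_MBq.shape != self.labels.shape:
            raise ValueError("activity and label volumes must be congruent")
        if self.voxel_volume_mL <= 0:
            raise ValueError("voxel volume must be positive")
        if np.any(self.activity_MBq < 0):
            raise ValueError("activities must be >= 0")


@dataclass(frozen=True)
class NoiseOptions:
    """Acquisition emulation switches.

    Defaults are the study conditions: Poisson counting noise on, 12 mm
    FWHM SPECT blur (partial-volume emulation), attenuation on, an
    effective planar dwell of 160 s per pixel (a point stays in a ~40 cm
    detector field of view for 40/15 min at the 15 cm/min bed speed), and
    couch shifts of up to 3 pixels on the later scans.
    """

    poisson: bool = True
    spect_blur_fwhm_mm: float = 12.0
    include_attenuation: bool = True
    planar_duration_s: float = 160.0
    couch_shift_px: int = 3
    spect_calibration_counts_per_MBq: float = 100.0


@dataclass(frozen=True)
class PatientDataset:
    """Everything the pipeline sees for one patient, plus the ground truth."""

    record: PatientRecord
    planar: tuple[PlanarScanPair, ...]
    spect: SpectStudy
    kinetics: GroundTruthKinetics
    planar_boundaries: dict[RegionLabel, np.ndarray]
    lobe_boundary: np.ndarray
    dead_time_tau_s: float

    def __post_init__(self) -> None:
        if len(self.planar) not in (2, 3):
            raise ValueError("2 or 3 planar pairs required")
        if abs(self.planar[0].time_h - self.spect.time_h) > 1e-9:
            raise ValueError("SPECT time must equal the first planar time")


def translate_image(image: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Integer-pixel translation with zero fill: out(x) = in(x - shift)."""
    out = np.zeros_like(image)
    s0, s1 = int(shift[0]), int(shift[1])
    n0, n1 = image.shape
    src0 = slice(max(0, -s0), min(n0, n0 - s0))
    src1 = slice(max(0, -s1), min(n1, n1 - s1))
    dst0 = slice(max(0, s0), min(n0, n0 + s0))
    dst1 = slice(max(0, s1), min(n1, n1 + s1))
    out[dst0, dst1] = image[src0, src1]
    return out


def planar_rough_boundaries(
    phantom: PhantomGeometry, dilate_px: int = 2
) -> dict[RegionLabel, np.ndarray]:
    """Planar rough boundaries per region.

    Stands in for the manual rough-delineation step, whose clinical purpose
    is to separate each organ/tumor from the other regions containing
    activity: each boundary is the region's silhouette along the
    anterior-posterior axis, dilated, minus the (slightly dilated)
    silhouettes of the other quantified regions.  The tumor, which sits
    inside the liver silhouette, excludes only non-hepatic regions; the
    liver in turn excludes the tumor silhouette.
    """
    labels = phantom.label_volume()
    silhouettes = {
        region: (labels == int(region)).any(axis=1) for region in QUANTIFIED_REGIONS
    }
    boundaries = {}
    for region, silhouette in silhouettes.items():
        if not silhouette.any():
            continue
        boundary = (
            ndimage.binary_dilation(silhouette, iterations=dilate_px)
            if dilate_px > 0
            else silhouette
        )
        excluded = np.zeros_like(silhouette)
        for other, other_sil in silhouettes.items():
            if other == region:
                continue
            if region == RegionLabel.TUMOR and other == RegionLabel.LIVER:
                continue
            excluded |= other_sil
        if excluded.any():
            boundary &= ~ndimage.binary_dilation(excluded, iterations=1)
        if boundary.any():
            boundaries[region] = boundary
    return boundaries


def activity_volume_at(
    phantom: PhantomGeometry,
    kinetics: GroundTruthKinetics,
    time_h: float,
    labels: np.ndarray | None = None,
) -> np.ndarray:
    """Voxel activity map (MBq/voxel): each region's activity spread
    uniformly over its voxels."""
    if labels is None:
        labels = phantom.label_volume()
    volume = np.zeros(phantom.shape, dtype=float)
    for region in kinetics.uptake_fractions:
        mask = labels == int(region)
        n = np.count_nonzero(mask)
        if n == 0:
            continue
        volume[mask] = kinetics.region_activity_MBq(region, time_h) / n
    return volume


def build_patient(
    geometry: PhantomGeometry,
    kinetics: GroundTruthKinetics,
    options: NoiseOptions | None = None,
    seed: int = 0,
    patient_id: str = "synthetic",
) -> PatientDataset:
    """Compose a full synthetic patient dataset.

    Planar pairs at each scan time reflect the region activities; the SPECT
    activity volume at t1 equals the voxelized activity map, optionally
    blurred by an isotropic Gaussian.  With noise and blur off, region sums
    of the SPECT volume equal the true uptakes exactly.
    """
    options = options or NoiseOptions()
    rng = np.random.default_rng(seed)
    labels = geometry.label_volume()
    cf = kinetics.planar_calibration_cps_per_MBq
    tau = kinetics.dead_time_tau_s

    pairs = []
    for k, t in enumerate(kinetics.scan_times_h):
        act = activity_volume_at(geometry, kinetics, t, labels)
        ant = project_planar(geometry, act, "anterior", options.include_attenuation, cf)
        post = project_planar(geometry, act, "posterior", options.include_attenuation, cf)
        if k > 0 and options.couch_shift_px > 0:
            shift = tuple(
                int(s)
                for s in rng.integers(
                    -options.couch_shift_px, options.couch_shift_px + 1, size=2
                )
            )
            ant = translate_image(ant, shift)
            post = translate_image(post, shift)
        post = np.flip(post, axis=0)  # camera frame
        if options.poisson:
            ant_counts = apply_counting_model(ant, tau, options.planar_duration_s, rng)
            post_counts = apply_counting_model(post, tau, options.planar_duration_s, rng)
        else:
            ant_counts = expected_counts(ant, tau, options.planar_duration_s)
            post_counts = expected_counts(post, tau, options.planar_duration_s)
        pairs.append(
            PlanarScanPair(ant_counts, post_counts, float(t), options.planar_duration_s)
        )

    spect_act = activity_volume_at(geometry, kinetics, kinetics.scan_times_h[0], labels)
    if options.spect_blur_fwhm_mm > 0:
        sigma_vox = options.spect_blur_fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        sigma_vox /= geometry.voxel_size_mm
        spect_act = ndimage.gaussian_filter(spect_act, sigma_vox)
    if options.poisson:
        cf_spect = options.spect_calibration_counts_per_MBq
        spect_act = rng.poisson(spect_act * cf_spect).astype(float) / cf_spect
    spect = SpectStudy(
        activity_MBq=spect_act,
        labels=labels,
        voxel_volume_mL=geometry.voxel_volume_mL,
        time_h=float(kinetics.scan_times_h[0]),
    )

    vv = geometry.voxel_volume_mL
    tumor_vol = float(np.count_nonzero(labels == int(RegionLabel.TUMOR))) * vv
    liver_vol = (
        float(
            np.count_nonzero(
                np.isin(labels, (int(RegionLabel.LIVER), int(RegionLabel.TUMOR)))
            )
        )
        * vv
    )
    record = PatientRecord(
        patient_id=patient_id,
        injected_activity_MBq=kinetics.injected_activity_MBq,
        scan_times_h=kinetics.scan_times_h,
        tumor_volume_mL=tumor_vol,
        liver_volume_mL=liver_vol,
    )
    lobe = np.isin(labels, (int(RegionLabel.LIVER), int(RegionLabel.TUMOR)))
    return PatientDataset(
        record=record,
        planar=tuple(pairs),
        spect=spect,
        kinetics=kinetics,
        planar_boundaries=planar_rough_boundaries(geometry),
        lobe_boundary=lobe,
        dead_time_tau_s=tau,
    )


def build_cohort(
    n_patients: int,
    geometry: PhantomGeometry | None = None,
    population_params: CohortDistributions | None = None,
    options: NoiseOptions | None = None,
    seed: int = 0,
) -> list[PatientDataset]:
    """Sample a cohort and build the full dataset for every patient."""
    geometry = geometry or default_phantom()
    kin = sample_cohort(n_patients, population_params, seed)
    rng = np.random.default_rng(seed + 1)
    return [
        build_patient(
            geometry, k, options, seed=int(rng.integers(2**31)), patient_id=f"syn{i + 1:02d}"
        )
        for i, k in enumerate(kin)
    ]
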