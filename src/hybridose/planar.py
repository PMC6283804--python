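"""Relative time-activity curves from serial anterior/posterior planar scans.

Processing follows the conjugate-view convention: a 40% threshold ROI
inside a manually supplied rough boundary, the geometric mean of the
anterior and the (mirrored) posterior ROI count rates, a global paralyzable
dead-time correction, and translation registration of the later whole-body
scans to the first.  No attenuation or scatter correction is applied - the
planar data carry only the *shape* of the time-activity curves; absolute
scale comes from the SPECT study.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import lambertw

from .core import RegionLabel
from .synthetic import PatientDataset, PlanarScanPair, translate_image

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RelativeTAC:
    """Per-region geometric-mean count-rate samples over time."""

    region: RegionLabel
    samples: tuple[tuple[float, float, float], ...]  # (time_h, rate_cps, sigma_cps)

    def __post_init__(self) -> None:
        if len(self.samples) not in (2, 3):
            raise ValueError("a relative TAC holds 2 or 3 samples")
        times = self.times
        if np.any(np.diff(times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.rates <= 0):
            raise ValueError("rates must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.array([s[0] for s in self.samples])

    @property
    def rates(self) -> np.ndarray:
        return np.array([s[1] for s in self.samples])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([s[2] for s in self.samples])


def delineate_roi(
    image: np.ndarray, rough_boundary: np.ndarray, threshold_fraction: float = 0.4
) -> np.ndarray:
    """Threshold ROI: pixels inside the rough boundary with value >=
    threshold_fraction times the boundary maximum (inclusive comparison;
    ties at the threshold are kept)."""
    rough_boundary = np.asarray(rough_boundary, dtype=bool)
    if not rough_boundary.any():
        raise ValueError("rough boundary is empty")
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold fraction must lie in (0, 1)")
    vmax = float(np.asarray(image)[rough_boundary].max())
    if vmax <= 0:
        raise ValueError("no positive maximum inside the rough boundary")
    return rough_boundary & (np.asarray(image) >= threshold_fraction * vmax)


def mirror_lateral(image: np.ndarray) -> np.ndarray:
    """Map a posterior camera-frame image into the anterior frame."""
    return np.flip(image, axis=0)


def geometric_mean_rate(
    pair: PlanarScanPair,
    roi: np.ndarray,
    roi_posterior: np.ndarray | None = None,
    rate_correction: float = 1.0,
) -> tuple[float, float]:
    """Conjugate-view geometric mean of the ROI count rate.

    The posterior view is mirrored into the anterior frame before masking.
    ``roi_posterior`` allows a separately delineated posterior-view ROI (the
    threshold is applied per view by default); when omitted the anterior ROI
    is reused.  ``rate_correction`` is the multiplicative dead-time factor
    (true/observed) for this scan.  Returns (rate, sigma) with the Poisson
    uncertainty 0.5 * GM * sqrt(1/N_ant + 1/N_post).
    """
    roi = np.asarray(roi, dtype=bool)
    post = mirror_lateral(pair.posterior)
    n_ant = float(pair.anterior[roi].sum())
    n_post = float(post[roi_posterior if roi_posterior is not None else roi].sum())
    if n_ant <= 0 or n_post <= 0:
        raise ValueError("geometric mean undefined: zero counts in an ROI view")
    r_ant = n_ant / pair.duration_s * rate_correction
    r_post = n_post / pair.duration_s * rate_correction
    rate = math.sqrt(r_ant * r_post)
    sigma = 0.5 * rate * math.sqrt(1.0 / n_ant + 1.0 / n_post)
    return rate, sigma


def correct_dead_time(
    observed_rate: float, tau_s: float, max_relative_correction: float = 0.30
) -> float:
    """Invert the paralyzable forward model m = n exp(-n tau) (low branch).

    Raises for observed rates above the paralyzable maximum 1/(e tau).
    Corrections larger than ``max_relative_correction`` are unusual for
    whole-body scans and are logged as a warning.
    """
    if observed_rate < 0:
        raise ValueError("observed rate must be >= 0")
    if tau_s < 0:
        raise ValueError("dead-time constant must be >= 0")
    if tau_s == 0 or observed_rate == 0:
        return float(observed_rate)
    peak = 1.0 / (math.e * tau_s)
    if observed_rate > peak * (1.0 + 1e-12):
        raise ValueError(
            f"observed rate {observed_rate:.6g} cps exceeds the paralyzable "
            f"maximum {peak:.6g} cps"
        )
    arg = max(-observed_rate * tau_s, -1.0 / math.e)
    true_rate = float(-lambertw(arg, 0).real / tau_s)
    if (true_rate - observed_rate) / observed_rate > max_relative_correction:
        logger.warning(
            "dead-time correction of %.1f%% exceeds the configured %.0f%% cap",
            100.0 * (true_rate / observed_rate - 1.0),
            100.0 * max_relative_correction,
        )
    return true_rate


def dead_time_loss_factor(true_rate: float, tau_s: float) -> float:
    """Forward paralyzable loss factor m/n = exp(-n tau)."""
    if true_rate < 0 or tau_s < 0:
        raise ValueError("rate and tau must be >= 0")
    return math.exp(-true_rate * tau_s)


def register_to_first(
    moving: PlanarScanPair, fixed: PlanarScanPair, search_window: int = 8
) -> tuple[tuple[int, int], PlanarScanPair]:
    """Translation registration of a later scan pair to the first.

    The integer-pixel shift of ``moving`` relative to ``fixed`` is found by
    maximizing the normalized cross-correlation of the anterior views over
    a (2w+1)^2 search window; ties prefer the smallest displacement.  The
    returned pair is resampled into the fixed frame (the posterior view,
    stored mirrored, receives the laterally mirrored translation).
    """
    if moving.anterior.shape != fixed.anterior.shape:
        raise ValueError("images must share a shape")
    ref = np.asarray(fixed.anterior, dtype=float)
    img = np.asarray(moving.anterior, dtype=float)
    if ref.std() == 0 or img.std() == 0:
        raise ValueError("normalized cross-correlation undefined for flat images")
    w = int(search_window)
    core = (slice(w, ref.shape[0] - w), slice(w, ref.shape[1] - w))
    ref_core = ref[core]
    ref_core = ref_core - ref_core.mean()
    ref_norm = math.sqrt(float((ref_core**2).sum()))
    candidates = sorted(
        ((s0, s1) for s0 in range(-w, w + 1) for s1 in range(-w, w + 1)),
        key=lambda s: (s[0] * s[0] + s[1] * s[1], s),
    )
    best, best_score = (0, 0), -np.inf
    for s in candidates:
        aligned = translate_image(img, (-s[0], -s[1]))[core]
        aligned = aligned - aligned.mean()
        denom = ref_norm * math.sqrt(float((aligned**2).sum()))
        if denom == 0:
            continue
        score = float((ref_core * aligned).sum()) / denom
        if score > best_score + 1e-12:
            best, best_score = s, score
    s0, s1 = best
    resampled = PlanarScanPair(
        anterior=translate_image(moving.anterior, (-s0, -s1)),
        posterior=translate_image(moving.posterior, (s0, -s1)),
        time_h=moving.time_h,
        duration_s=moving.duration_s,
        dead_time_corrected=moving.dead_time_corrected,
    )
    return best, resampled


def extract_relative_tacs(
    patient: PatientDataset,
    rough_boundaries: dict[RegionLabel, np.ndarray] | None = None,
    threshold_fraction: float = 0.4,
    tau_s: float | None = None,
    register: bool = True,
    search_window: int = 8,
    threshold_per_view: bool = True,
) -> tuple[dict[RegionLabel, RelativeTAC], dict[RegionLabel, str]]:
    """Full planar procedure: ROIs on the first scan, transfer to the
    registered later scans, dead-time correction, geometric means.

    ROIs are delineated per view (40% of each view's boundary maximum) by
    default; set ``threshold_per_view=False`` to delineate on the anterior
    view only and reuse that ROI for the posterior view.  Failures (e.g. a
    region with no counts) are reported per region, not per patient.
    """
    if len(patient.planar) < 2:
        raise ValueError("at least two planar pairs are required")
    boundaries = rough_boundaries if rough_boundaries is not None else patient.planar_boundaries
    tau = patient.dead_time_tau_s if tau_s is None else tau_s

    first = patient.planar[0]
    pairs = [first]
    for pair in patient.planar[1:]:
        if register:
            _, pair = register_to_first(pair, first, search_window)
        pairs.append(pair)

    corrections = []
    for pair in pairs:
        m_ant = float(pair.anterior.sum()) / pair.duration_s
        m_post = float(pair.posterior.sum()) / pair.duration_s
        corrections.append(
            (
                correct_dead_time(m_ant, tau) / m_ant if m_ant > 0 else 1.0,
                correct_dead_time(m_post, tau) / m_post if m_post > 0 else 1.0,
            )
        )

    tacs: dict[RegionLabel, RelativeTAC] = {}
    failures: dict[RegionLabel, str] = {}
    post_first = mirror_lateral(first.posterior)
    for region, boundary in boundaries.items():
        try:
            roi_ant = delineate_roi(first.anterior, boundary, threshold_fraction)
            roi_post = (
                delineate_roi(post_first, boundary, threshold_fraction)
                if threshold_per_view
                else roi_ant
            )
            samples = []
            for pair, (c_ant, c_post) in zip(pairs, corrections):
                # geometric mean of per-view dead-time-corrected ROI rates
                post = mirror_lateral(pair.posterior)
                n_ant = float(pair.anterior[roi_ant].sum())
                n_post = float(post[roi_post].sum())
                if n_ant <= 0 or n_post <= 0:
                    raise ValueError("zero counts in an ROI view")
                r_ant = n_ant / pair.duration_s * c_ant
                r_post = n_post / pair.duration_s * c_post
                rate = math.sqrt(r_ant * r_post)
                sigma = 0.5 * rate * math.sqrt(1.0 / n_ant + 1.0 / n_post)
                samples.append((pair.time_h, rate, sigma))
            tacs[region] = RelativeTAC(region=region, samples=tuple(samples))
        except ValueError as exc:
            failures[region] = str(exc)
    return tacs, failures
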