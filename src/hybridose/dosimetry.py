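"""Time-integrated activity, TIACs, S-factors and organ/tumor doses.

The absolute time-activity curve of each source region is integrated to
infinity under the standard piecewise assumptions: linear growth from zero
to A(t1) before the first scan, the fitted mono-exponential between the
first and last scans, and physical decay beyond the last scan.  All three
segments are analytic:

    A~ = A(t1) t1 / 2
       + A(t1) (1 - exp(-lambda_eff (t_last - t1))) / lambda_eff
       + A(t_last) T_phys / ln(2)

Dividing by the injected activity gives the time-integrated activity
coefficient (residence time) a~ = A~ / A0, which can never exceed
T_phys/ln(2) for a single region.  Doses follow the organ-level S-factor
formalism; the default S-factors come from a local beta-deposition model
S = Delta_beta / m (gamma cross-dose is negligible for this nuclide
relative to the beta self-dose), with reference values rescaled by 1/mass
for patient-specific organ masses and a log-log interpolated unit-density
sphere series for tumors.  User-supplied S-factor tables override both.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import (
    DECAYS_PER_MBQ_H,
    J_PER_MEV,
    LN2,
    RE188,
    NuclideConstants,
    RegionLabel,
)
from .kinetics import AbsoluteTAC

logger = logging.getLogger(__name__)

#: soft-tissue density used to convert volumes to masses (g/mL)
SOFT_TISSUE_DENSITY_G_PER_ML = 1.03


# ---------------------------------------------------------------------------
# time integration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TIACResult:
    """Time-integrated activity of one region, with its segment breakdown."""

    region: RegionLabel
    tia_MBq_h: float
    segments: tuple[float, float, float]  # (rise, fitted body, tail)
    horizon_h: float = math.inf
    tiac_h: float | None = None

    def __post_init__(self) -> None:
        if not math.isclose(self.tia_MBq_h, sum(self.segments), rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError("segment breakdown must sum to the total")


def piecewise_time_integrated_activity(
    activity_at_t1_MBq: float,
    effective_half_life_h: float,
    t1_h: float,
    last_scan_h: float,
    constants: NuclideConstants = RE188,
    tail_half_life_h: float | None = None,
) -> tuple[float, float, float]:
    """Analytic segments (rise, body, tail) of the piecewise integral.

    ``tail_half_life_h`` defaults to the physical half-life; single-point
    protocols pass ``last_scan_h == t1_h`` together with their assumed
    half-life, so the assumed decay applies from t1 to infinity.
    """
    a1 = float(activity_at_t1_MBq)
    if not np.isfinite(a1) or a1 < 0:
        raise ValueError("activity at t1 must be finite and >= 0")
    if effective_half_life_h <= 0:
        raise ValueError("effective half-life must be positive")
    if t1_h < 0 or last_scan_h < t1_h:
        raise ValueError("need 0 <= t1 <= last scan time")
    lam = LN2 / effective_half_life_h
    rise = a1 * t1_h / 2.0
    if math.isinf(last_scan_h):
        return rise, a1 / lam, 0.0
    dt = last_scan_h - t1_h
    body = a1 / lam * (1.0 - math.exp(-lam * dt))
    a_last = a1 * math.exp(-lam * dt)
    tail_t = constants.physical_half_life_h if tail_half_life_h is None else tail_half_life_h
    if tail_t <= 0:
        raise ValueError("tail half-life must be positive")
    tail = a_last * tail_t / LN2
    return rise, body, tail


def integrate_tia(
    abs_tac: AbsoluteTAC,
    t1_h: float,
    last_scan_h: float,
    constants: NuclideConstants = RE188,
    tail_half_life_h: float | None = None,
) -> TIACResult:
    """Integrate an absolute TAC from 0 to infinity (piecewise analytic)."""
    segments = piecewise_time_integrated_activity(
        float(abs_tac.activity_MBq(t1_h)),
        abs_tac.fit.half_life_h,
        t1_h,
        last_scan_h,
        constants,
        tail_half_life_h,
    )
    return TIACResult(region=abs_tac.region, tia_MBq_h=sum(segments), segments=segments)


def tiac(tia_MBq_h: float, injected_activity_MBq: float) -> float:
    """Time-integrated activity coefficient (residence time, hours)."""
    if injected_activity_MBq <= 0:
        raise ValueError("injected activity must be positive")
    return tia_MBq_h / injected_activity_MBq


def with_tiac(result: TIACResult, injected_activity_MBq: float) -> TIACResult:
    return replace(result, tiac_h=tiac(result.tia_MBq_h, injected_activity_MBq))


# ---------------------------------------------------------------------------
# S-factors
# ---------------------------------------------------------------------------


def local_deposition_s_factor(mass_kg: float, constants: NuclideConstants = RE188) -> float:
    """S-factor (mGy per MBq h) assuming all beta energy deposits locally."""
    if mass_kg <= 0:
        raise ValueError("mass must be positive")
    joule_per_MBq_h = constants.mean_beta_energy_MeV * J_PER_MEV * DECAYS_PER_MBQ_H
    return joule_per_MBq_h / mass_kg * 1000.0


@dataclass(frozen=True)
class OrganSFactor:
    """Reference organ S-value, rescaled as S(m) = S_ref * m_ref / m for
    beta self-dose at a patient-specific organ mass."""

    region: RegionLabel
    reference_mass_kg: float
    s_mGy_per_MBq_h: float

    def at_mass(self, mass_kg: float) -> float:
        if mass_kg <= 0:
            raise ValueError("mass must be positive")
        return self.s_mGy_per_MBq_h * self.reference_mass_kg / mass_kg


@dataclass(frozen=True)
class SphereSFactorTable:
    """Self-dose S-values for unit-density spheres, log-log interpolated."""

    masses_g: np.ndarray
    s_mGy_per_MBq_h: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.masses_g, dtype=float)
        s = np.asarray(self.s_mGy_per_MBq_h, dtype=float)
        if m.size != s.size or m.size < 2:
            raise ValueError("sphere series needs >= 2 (mass, S) nodes")
        if np.any(np.diff(m) <= 0):
            raise ValueError("sphere masses must be strictly increasing")
        if np.any(s <= 0) or np.any(m <= 0):
            raise ValueError("masses and S-values must be positive")

    def interpolate(self, mass_g: float) -> float:
        if mass_g <= 0:
            raise ValueError("mass must be positive")
        logs = np.interp(
            math.log(mass_g), np.log(self.masses_g), np.log(self.s_mGy_per_MBq_h)
        )
        return float(math.exp(logs))


def default_sphere_table(
    constants: NuclideConstants = RE188,
    masses_g: np.ndarray | None = None,
) -> SphereSFactorTable:
    """Local-deposition sphere series over 1 g to 1 kg."""
    m = np.logspace(0, 3, 13) if masses_g is None else np.asarray(masses_g, dtype=float)
    s = np.array([local_deposition_s_factor(mg / 1000.0, constants) for mg in m])
    return SphereSFactorTable(masses_g=m, s_mGy_per_MBq_h=s)


# ---------------------------------------------------------------------------
# doses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseResult:
    region: RegionLabel
    normalized_mGy_per_MBq: float
    absolute_Gy: float
    s_factor_mGy_per_MBq_h: float


def organ_dose(
    tiac_h: float,
    injected_activity_MBq: float,
    region_mass_kg: float,
    region: RegionLabel = RegionLabel.LIVER,
    s_factor: OrganSFactor | None = None,
    constants: NuclideConstants = RE188,
) -> DoseResult:
    """Organ absorbed dose from its TIAC and a mass-scaled S-factor.

    With no reference S-factor supplied, the local-deposition model
    S = Delta_beta / m is used directly at the patient's organ mass.
    """
    if region_mass_kg <= 0:
        raise ValueError("organ mass must be positive")
    if injected_activity_MBq <= 0:
        raise ValueError("injected activity must be positive")
    if s_factor is None:
        s = local_deposition_s_factor(region_mass_kg, constants)
    else:
        s = s_factor.at_mass(region_mass_kg)
    normalized = tiac_h * s
    return DoseResult(
        region=region,
        normalized_mGy_per_MBq=normalized,
        absolute_Gy=normalized * injected_activity_MBq / 1000.0,
        s_factor_mGy_per_MBq_h=s,
    )


def tumor_dose_sphere(
    tiac_h: float,
    injected_activity_MBq: float,
    tumor_volume_mL: float,
    density_g_per_mL: float = SOFT_TISSUE_DENSITY_G_PER_ML,
    sphere_table: SphereSFactorTable | None = None,
    constants: NuclideConstants = RE188,
    small_volume_warning_mL: float = 20.0,
) -> DoseResult:
    """Tumor dose through the spherical self-dose model.

    Tumors smaller than ~20 mL sit in the partial-volume regime of the
    SPECT system, where the measured activity (and hence the dose) is known
    to be biased low; a warning is logged but the dose is still returned.
    """
    if tumor_volume_mL <= 0:
        raise ValueError("tumor volume must be positive")
    if tumor_volume_mL < small_volume_warning_mL:
        logger.warning(
            "tumor volume %.1f mL is in the resolution/partial-volume regime; "
            "the dose estimate is expected to be biased low",
            tumor_volume_mL,
        )
    table = sphere_table or default_sphere_table(constants)
    mass_g = tumor_volume_mL * density_g_per_mL
    s = table.interpolate(mass_g)
    normalized = tiac_h * s
    return DoseResult(
        region=RegionLabel.TUMOR,
        normalized_mGy_per_MBq=normalized,
        absolute_Gy=normalized * injected_activity_MBq / 1000.0,
        s_factor_mGy_per_MBq_h=s,
    )


def administered_activity_uncertainty(components_percent) -> float:
    """Combine independent relative uncertainties in quadrature (%)."""
    c = np.asarray(list(components_percent), dtype=float)
    if np.any(c < 0):
        raise ValueError("uncertainty components must be >= 0")
    return float(np.sqrt((c**2).sum()))


def prescribe_activity(
    tumor_volume_mL: float,
    rate_MBq_per_mL: float = 37.0,
    bounds_MBq_per_mL: tuple[float, float] = (14.8, 92.5),
) -> float:
    """Empirical activity prescription: 37 MBq per mL of tumor, with the
    per-mL rate clamped to the clinically used 14.8-92.5 MBq/mL range."""
    if tumor_volume_mL <= 0:
        raise ValueError("tumor volume must be positive")
    lo, hi = bounds_MBq_per_mL
    return tumor_volume_mL * min(max(rate_MBq_per_mL, lo), hi)


# ---------------------------------------------------------------------------
# dose tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseTable:
    """Per-patient normalized/absolute doses with cohort summary rows."""

    normalized_mGy_per_MBq: pd.DataFrame  # patients x regions
    absolute_Gy: pd.DataFrame
    normalized_summary: pd.DataFrame  # rows: mean, sd, min, max
    absolute_summary: pd.DataFrame


def summarize_dose_table(
    normalized_mGy_per_MBq: pd.DataFrame,
    injected_activities_MBq: pd.Series,
) -> DoseTable:
    """Cohort summary of a per-patient normalized-dose table.

    Absolute doses per patient are normalized dose times A0 / 1000 (Gy).
    Missing entries are excluded from every summary.  The SD uses the
    sample convention (n-1); a single-entry column gets SD 0 by convention
    (logged).
    """
    body = normalized_mGy_per_MBq.astype(float)
    if body.empty:
        raise ValueError("dose table has no rows")
    activities = injected_activities_MBq.astype(float).reindex(body.index)
    if activities.isna().any():
        raise ValueError("every patient row needs an injected activity")
    absolute = body.mul(activities, axis=0) / 1000.0

    def _summary(frame: pd.DataFrame) -> pd.DataFrame:
        if (frame.notna().sum() == 0).any():
            raise ValueError("a region column has no valid entries")
        sd = frame.std(ddof=1)
        singletons = frame.notna().sum() == 1
        if singletons.any():
            logger.info("SD set to 0 for single-entry columns: %s",
                        list(frame.columns[singletons]))
            sd = sd.where(~singletons, 0.0)
        return pd.DataFrame(
            {"mean": frame.mean(), "sd": sd, "min": frame.min(), "max": frame.max()}
        ).T

    return DoseTable(
        normalized_mGy_per_MBq=body,
        absolute_Gy=absolute,
        normalized_summary=_summary(body),
        absolute_summary=_summary(absolute),
    )
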