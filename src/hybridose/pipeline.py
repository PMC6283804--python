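"""End-to-end hybrid planar/SPECT dosimetry for one patient or a cohort.

Per patient the pipeline runs: planar relative TAC extraction (threshold
ROIs, registration, dead-time correction, geometric means), SPECT region
activities (label readout, volume-matched tumor segmentation),
mono-exponential fits, rescaling to absolute TACs, piecewise time
integration to TIACs, and S-factor doses.  A region that fails (e.g. no
counts) is reported in ``failures`` and excluded from the results without
aborting the patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import QUANTIFIED_REGIONS, RE188, NuclideConstants, PatientRecord, RegionLabel
from .dosimetry import (
    SOFT_TISSUE_DENSITY_G_PER_ML,
    DoseResult,
    DoseTable,
    SphereSFactorTable,
    TIACResult,
    integrate_tia,
    organ_dose,
    summarize_dose_table,
    tumor_dose_sphere,
    with_tiac,
)
from .kinetics import AbsoluteTAC, ExpFitResult, fit_tac, rescale_to_absolute
from .planar import RelativeTAC, extract_relative_tacs
from .spect import (
    AbsoluteActivityMeasurement,
    organ_activity,
    tumor_segmentation_volume_matched,
)
from .synthetic import PatientDataset


@dataclass
class PatientAnalysis:
    """All intermediate and final quantities for one patient."""

    record: PatientRecord
    tacs: dict[RegionLabel, RelativeTAC] = field(default_factory=dict)
    fits: dict[RegionLabel, ExpFitResult] = field(default_factory=dict)
    measurements: dict[RegionLabel, AbsoluteActivityMeasurement] = field(default_factory=dict)
    absolute_tacs: dict[RegionLabel, AbsoluteTAC] = field(default_factory=dict)
    tiacs: dict[RegionLabel, TIACResult] = field(default_factory=dict)
    doses: dict[RegionLabel, DoseResult] = field(default_factory=dict)
    failures: dict[RegionLabel, str] = field(default_factory=dict)

    def as_protocol_input(self) -> dict:
        return {
            "id": self.record.patient_id,
            "tacs": self.tacs,
            "measurements": self.measurements,
            "A0": self.record.injected_activity_MBq,
        }


def measure_spect_activities(
    dataset: PatientDataset,
    regions: tuple[RegionLabel, ...] = QUANTIFIED_REGIONS,
) -> tuple[dict[RegionLabel, AbsoluteActivityMeasurement], dict[RegionLabel, str]]:
    """Absolute activities at the SPECT time for every requested region."""
    measurements: dict[RegionLabel, AbsoluteActivityMeasurement] = {}
    failures: dict[RegionLabel, str] = {}
    for region in regions:
        try:
            if region == RegionLabel.TUMOR:
                _, measurements[region] = tumor_segmentation_volume_matched(
                    dataset.spect, dataset.lobe_boundary, dataset.record.tumor_volume_mL
                )
            elif region == RegionLabel.LIVER:
                measurements[region] = organ_activity(
                    dataset.spect,
                    RegionLabel.LIVER,
                    include_labels=(RegionLabel.LIVER, RegionLabel.TUMOR),
                )
            else:
                measurements[region] = organ_activity(dataset.spect, region)
        except ValueError as exc:
            failures[region] = str(exc)
    return measurements, failures


def analyze_patient(
    dataset: PatientDataset,
    regions: tuple[RegionLabel, ...] = QUANTIFIED_REGIONS,
    constants: NuclideConstants = RE188,
    threshold_fraction: float = 0.4,
    register: bool = True,
    weighted_fit: bool = True,
    sphere_table: SphereSFactorTable | None = None,
    tissue_density_g_per_mL: float = SOFT_TISSUE_DENSITY_G_PER_ML,
) -> PatientAnalysis:
    """Run the full dosimetry chain for one patient."""
    analysis = PatientAnalysis(record=dataset.record)
    tacs, tac_failures = extract_relative_tacs(
        dataset, threshold_fraction=threshold_fraction, register=register
    )
    analysis.tacs = {r: t for r, t in tacs.items() if r in regions}
    analysis.failures.update({r: m for r, m in tac_failures.items() if r in regions})

    measurements, spect_failures = measure_spect_activities(dataset, regions)
    analysis.measurements = measurements
    analysis.failures.update(spect_failures)

    a0 = dataset.record.injected_activity_MBq
    for region in regions:
        tac = analysis.tacs.get(region)
        spect = measurements.get(region)
        if tac is None or spect is None:
            continue
        try:
            fit = fit_tac(tac, weighted=weighted_fit)
            abs_tac = rescale_to_absolute(fit, float(fit.predict(spect.time_h)), spect)
            result = integrate_tia(
                abs_tac, spect.time_h, float(tac.times[-1]), constants
            )
            result = with_tiac(result, a0)
            if region == RegionLabel.TUMOR:
                dose = tumor_dose_sphere(
                    result.tiac_h,
                    a0,
                    dataset.record.tumor_volume_mL,
                    density_g_per_mL=tissue_density_g_per_mL,
                    sphere_table=sphere_table,
                    constants=constants,
                )
            else:
                mass_kg = spect.volume_mL * tissue_density_g_per_mL / 1000.0
                dose = organ_dose(result.tiac_h, a0, mass_kg, region, constants=constants)
        except ValueError as exc:
            analysis.failures[region] = str(exc)
            continue
        analysis.fits[region] = fit
        analysis.absolute_tacs[region] = abs_tac
        analysis.tiacs[region] = result
        analysis.doses[region] = dose
    return analysis


def analyze_cohort(
    datasets: list[PatientDataset], **kwargs
) -> tuple[list[PatientAnalysis], DoseTable]:
    """Analyze every patient and assemble the cohort dose table."""
    analyses = [analyze_patient(ds, **kwargs) for ds in datasets]
    rows = {
        a.record.patient_id: {
            r.region_name: d.normalized_mGy_per_MBq for r, d in a.doses.items()
        }
        for a in analyses
    }
    normalized = pd.DataFrame.from_dict(rows, orient="index")
    activities = pd.Series(
        {a.record.patient_id: a.record.injected_activity_MBq for a in analyses}
    )
    return analyses, summarize_dose_table(normalized, activities)


def fit_summary_frame(analyses: list[PatientAnalysis]) -> pd.DataFrame:
    """Tidy per-(patient, region) fit export: amplitude, half-lives, R^2."""
    from .kinetics import effective_to_biological

    rows = []
    for analysis in analyses:
        for region, fit in analysis.fits.items():
            try:
                t_bio = effective_to_biological(min(fit.half_life_h, RE188.physical_half_life_h))
            except ValueError:
                t_bio = np.nan
            rows.append(
                {
                    "patient": analysis.record.patient_id,
                    "region": region.region_name,
                    "a": fit.amplitude,
                    "T_eff_h": fit.half_life_h,
                    "T_bio_h": t_bio,
                    "R2": fit.r_squared,
                    "n_points": fit.n_points,
                }
            )
    return pd.DataFrame(rows)
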