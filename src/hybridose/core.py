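"""Shared domain types and physical constants.

The package quantifies six source regions that are visible in the
thorax/abdomen SPECT field of view of a Re-188 Lipiodol radioembolization
patient: the tumor, the entire liver, the lungs, the stomach, the spleen
and the kidneys.  Label codes are stable across the synthetic phantom, the
planar pipeline and the SPECT pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from importlib import resources

import numpy as np
import pandas as pd

LN2 = float(np.log(2.0))

#: joules per MeV
J_PER_MEV = 1.602176634e-13
#: decays accumulated by 1 MBq in 1 hour
DECAYS_PER_MBQ_H = 3.6e9


class RegionLabel(IntEnum):
    """Integer codes of the quantified source regions (0 = background)."""

    BACKGROUND = 0
    TUMOR = 1
    LIVER = 2
    LUNGS = 3
    STOMACH = 4
    SPLEEN = 5
    KIDNEYS = 6

    @property
    def region_name(self) -> str:
        return self.name.lower()


#: regions for which activities, kinetics and doses are reported
QUANTIFIED_REGIONS = (
    RegionLabel.TUMOR,
    RegionLabel.LIVER,
    RegionLabel.LUNGS,
    RegionLabel.STOMACH,
    RegionLabel.SPLEEN,
    RegionLabel.KIDNEYS,
)


@dataclass(frozen=True)
class NuclideConstants:
    """Decay data needed by the kinetics and dose models.

    Parameters
    ----------
    physical_half_life_h:
        Physical half-life in hours.
    mean_beta_energy_MeV:
        Mean energy per decay deposited locally by the beta spectrum; used
        by the default local-deposition S-factor model.
    """

    physical_half_life_h: float = 17.0
    mean_beta_energy_MeV: float = 0.763

    def __post_init__(self) -> None:
        if self.physical_half_life_h <= 0:
            raise ValueError("physical half-life must be positive")
        if self.mean_beta_energy_MeV <= 0:
            raise ValueError("mean beta energy must be positive")

    @property
    def decay_constant_per_h(self) -> float:
        return LN2 / self.physical_half_life_h


#: Re-188: 17 h half-life, 0.763 MeV mean beta energy per decay
RE188 = NuclideConstants()


@dataclass(frozen=True)
class PatientRecord:
    """Administrative/anatomical data of one treated patient."""

    patient_id: str
    injected_activity_MBq: float
    scan_times_h: tuple[float, ...]
    tumor_volume_mL: float
    liver_volume_mL: float
    sex: str = ""
    age: float | None = None

    def __post_init__(self) -> None:
        if self.injected_activity_MBq <= 0:
            raise ValueError("injected activity must be positive")
        times = np.asarray(self.scan_times_h, dtype=float)
        if times.size < 1 or np.any(np.diff(times) <= 0):
            raise ValueError("scan times must be strictly increasing")
        if self.tumor_volume_mL <= 0 or self.liver_volume_mL <= 0:
            raise ValueError("volumes must be positive")


def load_patient_table() -> pd.DataFrame:
    """Packaged per-patient table: administered activities, scan times and
    tumor/liver volumes of the 14 treatment sessions (13 patients, one
    treated twice).  Missing ``t3_h`` marks the four two-scan sessions."""
    with resources.files("hybridose.data").joinpath("table1_patients.csv").open() as fh:
        return pd.read_csv(fh, dtype={"patient": str})


def load_normalized_dose_table() -> pd.DataFrame:
    """Packaged per-patient normalized absorbed doses (mGy/MBq) by region."""
    with resources.files("hybridose.data").joinpath(
        "table2_normalized_doses.csv"
    ).open() as fh:
        return pd.read_csv(fh, dtype={"patient": str})


def patient_records_from_table(table: pd.DataFrame | None = None) -> list[PatientRecord]:
    """Build :class:`PatientRecord` objects from the packaged patient table."""
    if table is None:
        table = load_patient_table()
    records = []
    for _, row in table.iterrows():
        times = [row["t1_h"], row["t2_h"]]
        if not pd.isna(row.get("t3_h")):
            times.append(row["t3_h"])
        records.append(
            PatientRecord(
                patient_id=str(row["patient"]),
                injected_activity_MBq=float(row["injected_activity_MBq"]),
                scan_times_h=tuple(float(t) for t in times),
                tumor_volume_mL=float(row["tumor_volume_mL"]),
                liver_volume_mL=float(row["liver_volume_mL"]),
                sex=str(row.get("sex", "")),
                age=float(row["age"]) if not pd.isna(row.get("age")) else None,
            )
        )
    return records
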