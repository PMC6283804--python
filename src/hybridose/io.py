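"""Serialization: NIfTI volumes, NPZ planar images, CSV tables, YAML config.

A patient dataset round-trips through a directory layout of small standard
files: ``meta.yaml`` (record, ground-truth kinetics, dead-time constant),
``planar_XX.npz`` per scan pair, ``spect_activity.nii`` / ``spect_labels.nii``
and ``boundaries.npz``.  Round-trips are lossless apart from float
precision in YAML.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import PatientRecord, RegionLabel
from .dosimetry import OrganSFactor, SphereSFactorTable
from .planar import RelativeTAC
from .synthetic import (
    CohortDistributions,
    GroundTruthKinetics,
    LogUniform,
    PatientDataset,
    PlanarScanPair,
    SpectStudy,
    TruncatedNormal,
    Uniform,
)

# ---------------------------------------------------------------------------
# patient datasets
# ---------------------------------------------------------------------------


def _kinetics_to_dict(k: GroundTruthKinetics) -> dict:
    return {
        "uptake_fractions": {r.region_name: float(v) for r, v in k.uptake_fractions.items()},
        "half_lives_h": {r.region_name: float(v) for r, v in k.half_lives_h.items()},
        "injected_activity_MBq": float(k.injected_activity_MBq),
        "scan_times_h": [float(t) for t in k.scan_times_h],
        "physical_half_life_h": float(k.physical_half_life_h),
        "dead_time_tau_s": float(k.dead_time_tau_s),
        "planar_calibration_cps_per_MBq": float(k.planar_calibration_cps_per_MBq),
        "biexp_slow_fraction": float(k.biexp_slow_fraction),
    }


def _kinetics_from_dict(d: dict) -> GroundTruthKinetics:
    return GroundTruthKinetics(
        uptake_fractions={RegionLabel[k.upper()]: v for k, v in d["uptake_fractions"].items()},
        half_lives_h={RegionLabel[k.upper()]: v for k, v in d["half_lives_h"].items()},
        injected_activity_MBq=d["injected_activity_MBq"],
        scan_times_h=tuple(d["scan_times_h"]),
        physical_half_life_h=d["physical_half_life_h"],
        dead_time_tau_s=d["dead_time_tau_s"],
        planar_calibration_cps_per_MBq=d["planar_calibration_cps_per_MBq"],
        biexp_slow_fraction=d["biexp_slow_fraction"],
    )


def save_patient(dataset: PatientDataset, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    record = dataset.record
    meta = {
        "record": {
            "patient_id": record.patient_id,
            "injected_activity_MBq": float(record.injected_activity_MBq),
            "scan_times_h": [float(t) for t in record.scan_times_h],
            "tumor_volume_mL": float(record.tumor_volume_mL),
            "liver_volume_mL": float(record.liver_volume_mL),
            "sex": record.sex,
            "age": record.age,
        },
        "kinetics": _kinetics_to_dict(dataset.kinetics),
        "dead_time_tau_s": float(dataset.dead_time_tau_s),
        "voxel_volume_mL": float(dataset.spect.voxel_volume_mL),
        "spect_time_h": float(dataset.spect.time_h),
        "n_planar": len(dataset.planar),
    }
    (directory / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    for k, pair in enumerate(dataset.planar):
        np.savez(
            directory / f"planar_{k:02d}.npz",
            anterior=pair.anterior,
            posterior=pair.posterior,
            time_h=pair.time_h,
            duration_s=pair.duration_s,
            dead_time_corrected=pair.dead_time_corrected,
        )
    affine = np.diag([*(3 * [meta["voxel_volume_mL"] ** (1 / 3) * 10.0]), 1.0])
    nib.save(
        nib.Nifti1Image(dataset.spect.activity_MBq.astype(np.float32), affine),
        directory / "spect_activity.nii",
    )
    nib.save(
        nib.Nifti1Image(dataset.spect.labels.astype(np.int16), affine),
        directory / "spect_labels.nii",
    )
    np.savez(
        directory / "boundaries.npz",
        lobe=dataset.lobe_boundary,
        **{r.region_name: m for r, m in dataset.planar_boundaries.items()},
    )
    return directory


def load_patient(directory: str | Path) -> PatientDataset:
    directory = Path(directory)
    meta = yaml.safe_load((directory / "meta.yaml").read_text())
    rec = meta["record"]
    record = PatientRecord(
        patient_id=rec["patient_id"],
        injected_activity_MBq=rec["injected_activity_MBq"],
        scan_times_h=tuple(rec["scan_times_h"]),
        tumor_volume_mL=rec["tumor_volume_mL"],
        liver_volume_mL=rec["liver_volume_mL"],
        sex=rec.get("sex", ""),
        age=rec.get("age"),
    )
    pairs = []
    for k in range(meta["n_planar"]):
        with np.load(directory / f"planar_{k:02d}.npz") as data:
            pairs.append(
                PlanarScanPair(
                    anterior=data["anterior"],
                    posterior=data["posterior"],
                    time_h=float(data["time_h"]),
                    duration_s=float(data["duration_s"]),
                    dead_time_corrected=bool(data["dead_time_corrected"]),
                )
            )
    activity = np.asarray(nib.load(directory / "spect_activity.nii").dataobj, dtype=float)
    labels = np.asarray(nib.load(directory / "spect_labels.nii").dataobj, dtype=np.int16)
    spect = SpectStudy(
        activity_MBq=activity,
        labels=labels,
        voxel_volume_mL=meta["voxel_volume_mL"],
        time_h=meta["spect_time_h"],
    )
    with np.load(directory / "boundaries.npz") as data:
        lobe = data["lobe"]
        boundaries = {
            RegionLabel[name.upper()]: data[name] for name in data.files if name != "lobe"
        }
    return PatientDataset(
        record=record,
        planar=tuple(pairs),
        spect=spect,
        kinetics=_kinetics_from_dict(meta["kinetics"]),
        planar_boundaries=boundaries,
        lobe_boundary=lobe,
        dead_time_tau_s=meta["dead_time_tau_s"],
    )


# ---------------------------------------------------------------------------
# cohort configuration
# ---------------------------------------------------------------------------

_DIST_TAGS = {TruncatedNormal: "truncnorm", Uniform: "uniform", LogUniform: "loguniform"}


def _dist_to_dict(dist) -> dict:
    d = {"kind": _DIST_TAGS[type(dist)]}
    d.update({k: float(v) for k, v in vars(dist).items()})
    return d


def _dist_from_dict(d: dict):
    kind = d.pop("kind")
    cls = {v: k for k, v in _DIST_TAGS.items()}[kind]
    return cls(**d)


def save_cohort_config(params: CohortDistributions, path: str | Path) -> None:
    doc = {
        "half_lives": {r.region_name: _dist_to_dict(s) for r, s in params.half_lives.items()},
        "uptakes": {r.region_name: _dist_to_dict(s) for r, s in params.uptakes.items()},
        "injected_activity": _dist_to_dict(params.injected_activity),
        "scan_times_h": list(params.scan_times_h),
        "time_jitter_h": list(params.time_jitter_h),
        "jitter_times": params.jitter_times,
        "two_scan_fraction": params.two_scan_fraction,
        "physical_half_life_h": params.physical_half_life_h,
        "dead_time_tau_s": params.dead_time_tau_s,
        "planar_calibration_cps_per_MBq": params.planar_calibration_cps_per_MBq,
        "biexp_slow_fraction": params.biexp_slow_fraction,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_cohort_config(path: str | Path) -> CohortDistributions:
    doc = yaml.safe_load(Path(path).read_text())
    return CohortDistributions(
        half_lives={
            RegionLabel[k.upper()]: _dist_from_dict(v) for k, v in doc["half_lives"].items()
        },
        uptakes={RegionLabel[k.upper()]: _dist_from_dict(v) for k, v in doc["uptakes"].items()},
        injected_activity=_dist_from_dict(doc["injected_activity"]),
        scan_times_h=tuple(doc["scan_times_h"]),
        time_jitter_h=tuple(doc["time_jitter_h"]),
        jitter_times=doc["jitter_times"],
        two_scan_fraction=doc["two_scan_fraction"],
        physical_half_life_h=doc["physical_half_life_h"],
        dead_time_tau_s=doc["dead_time_tau_s"],
        planar_calibration_cps_per_MBq=doc["planar_calibration_cps_per_MBq"],
        biexp_slow_fraction=doc["biexp_slow_fraction"],
    )


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def write_tac_csv(tacs_by_patient: dict[str, dict[RegionLabel, RelativeTAC]], path) -> None:
    """Tidy relative-TAC export: patient, region, time_h, gm_rate, sigma."""
    rows = [
        {"patient": pid, "region": region.region_name, "time_h": t, "gm_rate": r, "sigma": s}
        for pid, tacs in tacs_by_patient.items()
        for region, tac in tacs.items()
        for t, r, s in tac.samples
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_organ_s_factors(path) -> dict[RegionLabel, OrganSFactor]:
    """Organ S-factor CSV: region, mass_kg, S_mGy_per_MBq_h."""
    frame = pd.read_csv(path)
    return {
        RegionLabel[row["region"].upper()]: OrganSFactor(
            region=RegionLabel[row["region"].upper()],
            reference_mass_kg=float(row["mass_kg"]),
            s_mGy_per_MBq_h=float(row["S_mGy_per_MBq_h"]),
        )
        for _, row in frame.iterrows()
    }


def read_sphere_s_factors(path) -> SphereSFactorTable:
    """Sphere S-factor CSV: mass_g, S_mGy_per_MBq_h (ascending mass)."""
    frame = pd.read_csv(path).sort_values("mass_g")
    return SphereSFactorTable(
        masses_g=frame["mass_g"].to_numpy(dtype=float),
        s_mGy_per_MBq_h=frame["S_mGy_per_MBq_h"].to_numpy(dtype=float),
    )
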