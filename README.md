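# hybridose

Hybrid planar/SPECT organ-level dosimetry for ¹⁸⁸Re-Lipiodol
radioembolization of hepatocellular carcinoma, written for medical
physicists and nuclear-medicine researchers who need reproducible
image-based dose calculations and a way to stress-test the whole chain
without patient data.

¹⁸⁸Re (T_phys = 17 h, E_max ≈ 2.1 MeV) emits both therapeutic betas and
imageable 155 keV photons, so post-treatment imaging can drive
patient-specific dosimetry.  The package implements the hybrid method:

* **Relative kinetics from planar imaging** — serial anterior/posterior
  whole-body scans, 40 %-threshold ROIs inside user-supplied rough
  boundaries, translation registration of later scans, paralyzable
  dead-time correction, and the conjugate-view geometric mean
  √(R_ant·R_post), fit with A_rel(t) = a·e^(−ln2·t/T_eff) by weighted
  least squares (1/T_eff = 1/T_phys + 1/T_bio).
* **Absolute scale from quantitative SPECT** — label-based organ readout
  and volume-matched tumor segmentation (top-k voxels until the reported
  tumor volume is reached); the fitted curve is rescaled so
  A(t₁) equals the SPECT activity.
* **Dose** — analytic time integration (linear rise to t₁, fitted
  exponential to the last scan, physical-decay tail), TIAC ã = Ã/A₀, and
  mass-scaled organ / sphere-model tumor S-factors
  (default: local beta deposition, S = Δ_β/m).
* **Protocol sparsification** — TIACs from two-point subsets
  ({3,24}, {3,48}, {24,48} h) and single-scan rules ({3 h}+T_phys,
  {3 h}+T_eff) compared against the three-scan reference via percent
  differences, box-plot statistics and exact/asymptotic
  Mann–Whitney–Wilcoxon tests.
* **Synthetic cohorts** — a voxel phantom plus population kinetics
  generator (truncated-normal effective half-lives, log-uniform tumor
  uptake spanning 1–30 % of A₀, Poisson noise, dead time, couch shifts,
  partial-volume blur) that makes every stage testable end to end.

The packaged clinical tables (per-patient administered activities, scan
times, volumes, and normalized doses for 14 treatment sessions) let the
cohort dose summaries be regenerated exactly.

## Worked example

```python
import numpy as np
from hybridose import RegionLabel, build_cohort, analyze_patient

cohort = build_cohort(3, seed=42)           # synthetic patients
analyses = [analyze_patient(ds) for ds in cohort]

for ds, a in zip(cohort, analyses):
    liver = a.fits[RegionLabel.LIVER]
    dose = a.doses[RegionLabel.TUMOR]
    print(
        f"{a.record.patient_id}: A0={a.record.injected_activity_MBq:7.1f} MBq  "
        f"liver T_eff={liver.half_life_h:5.2f} h (true "
        f"{ds.kinetics.half_lives_h[RegionLabel.LIVER]:5.2f})  "
        f"tumor dose={dose.absolute_Gy:6.1f} Gy"
    )
```

prints

```
syn01: A0= 5072.9 MBq  liver T_eff=12.33 h (true 12.33)  tumor dose=  74.1 Gy
syn02: A0= 4033.8 MBq  liver T_eff=11.31 h (true 11.32)  tumor dose=  55.5 Gy
syn03: A0= 3860.3 MBq  liver T_eff=13.40 h (true 13.39)  tumor dose=  20.8 Gy
```

Each line is one synthetic patient run through the full chain: the
effective half-life fitted from the planar TACs matches the generator's
ground truth to ~0.01 h at the default noise level, and the tumor dose in
gray follows from the SPECT-anchored TIAC and the sphere-model S-factor
at the patient's tumor volume.  Inter-patient dose variability is driven
almost entirely by the sampled tumor uptake fraction, which is why doses
per injected activity span an order of magnitude while half-lives barely
move.

The clinical cohort summaries come straight from the packaged tables:

```python
from hybridose import load_normalized_dose_table, load_patient_table, summarize_dose_table

doses = load_normalized_dose_table().set_index("patient")
patients = load_patient_table().set_index("patient")
table = summarize_dose_table(doses, patients["injected_activity_MBq"])
print(table.normalized_summary.round(2))   # mean/sd/min/max per region
```

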