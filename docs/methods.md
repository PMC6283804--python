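# Methods

## The dosimetry problem

After trans-arterial radioembolization with a ¹⁸⁸Re-labelled Lipiodol
conjugate, the absorbed dose in the tumor and in the organs at risk (liver,
lungs, and secondarily stomach, spleen, kidneys) must be estimated from
post-treatment imaging.  Whole-body (WB) planar scans are cheap and can be
repeated, but without transmission data they cannot be made quantitative;
a single quantitative SPECT/CT is quantitative but gives only one time
point.  The hybrid method combines them:

1. serial anterior/posterior WB planar pairs (2–3 time points over ~48 h)
   give the *shape* of each region's time–activity curve (TAC);
2. one quantitative SPECT/CT at the first time point t₁ anchors the
   *absolute scale*;
3. the anchored curve is integrated analytically to the time-integrated
   activity (TIA) and divided by the injected activity A₀ to give the
   time-integrated activity coefficient (TIAC, a residence time in hours);
4. TIACs times mass-adjusted S-factors give organ doses, and times
   sphere-model S-factors give tumor doses.

## Planar processing

Each region's rough boundary is an *input* (the clinical step is manual;
its purpose is to separate the region from other activity-containing
structures).  Inside the boundary a 40 % threshold of the boundary maximum
(inclusive ≥, applied per view) defines the ROI on the first scan.  Later
scans are registered to the first by integer-pixel translation maximizing
normalized cross-correlation over a configurable search window; rotation
is not searched — WB misalignment across two days is dominated by couch
offsets, and this is a documented limitation.  ROIs are transferred by the
inverse translation (the posterior view, stored in the mirrored camera
frame, receives the laterally mirrored translation).

The regional signal is the conjugate-view geometric mean
√(R_ant · R_post) of the ROI count rates, whose depth dependence cancels
under uniform attenuation.  Count rates are corrected for paralyzable
dead time: the observed image-total rate m = n·e^(−nτ) is inverted on the
low-rate branch via the Lambert-W function and the resulting factor n/m is
applied uniformly (losses are global to the detector).  No attenuation,
scatter or background correction is applied — any time-constant
multiplicative factor cancels in the relative TAC, which is the only thing
the planar data contribute.

## Kinetics

Relative TACs are fit with A_rel(t) = a·e^(−ln2·t/T_eff) by weighted least
squares, weights 1/σ² with σ propagated from Poisson counts
(σ_GM = ½·GM·√(1/N_ant + 1/N_post)); the fit runs in linear space so the
weights keep their meaning, initialized from the weighted log-linear
closed form.  Two-point data use the exact closed form.  The effective
half-life relates to the biological one through parallel first-order
elimination, 1/T_eff = 1/T_phys + 1/T_bio, with T_phys = 17 h for ¹⁸⁸Re;
fits with T_eff > T_phys are surfaced as errors rather than clipped.

The fitted curve is rescaled so that its value at the SPECT time equals
the SPECT-measured activity: A(t) = a·[A(r,t₁)/A_rel(r,t₁)]·e^(−ln2·t/T_eff),
where A_rel(r,t₁) is the *fitted* value at t₁ (using the raw first sample
instead is available as a sensitivity variant, but the fitted value is the
definition used throughout).

## SPECT quantification

SPECT volumes arrive post-reconstruction, in MBq per voxel after a scalar
camera calibration factor (projection-domain simulation, OSEM, scatter and
attenuation correction are out of scope).  Organs are read out through an
anatomical label volume; "entire liver" includes the tumor voxels, since
the pre-calculated S-values exist only for the whole organ.  The tumor is
segmented by *volume matching*: the k = round(V_tumor/V_voxel)
highest-activity voxels inside the hepatic lobe boundary, with ties broken
by deterministic voxel order.  This realizes "a fixed threshold chosen
such that the recovered volume equals the reported tumor volume" exactly
to one voxel, deterministically, without a threshold search.  No
partial-volume correction is applied; the resulting low bias for small
objects is an expected property, and tumors below ~20 mL trigger a
logged warning.

## Time integration and doses

With the fitted exponential anchored at t₁ and the last scan at t_last,
the TIA over (0, ∞) is analytic in three segments:

    Ã = A(t₁)·t₁/2                                   (linear rise from 0)
      + A(t₁)·(1 − e^(−λ_eff·(t_last−t₁)))/λ_eff     (fitted body)
      + A(t_last)·T_phys/ln2                         (physical-decay tail)

For two-scan patients the tail attaches at t₂ by the same rule.  The TIAC
is ã = Ã/A₀.  For any amplitude compatible with physical decay before t₁
(A(t₁) ≤ A₀·2^(−t₁/T_phys)), ã ≤ T_phys/ln2 = 24.53 h.

Doses use the organ-level S-factor formalism.  The default S-factors come
from a local beta-deposition model S = Δ_β/m with Δ_β = 0.763 MeV per
decay (for ¹⁸⁸Re the photon cross-dose is negligible against the beta
self-dose), i.e. S(0.1 kg) = 4.40 mGy/(MBq·h).  Reference organ S-values,
when supplied as a CSV table, are rescaled by 1/mass to the patient's
organ mass; tumors use a unit-density-sphere series (default density
1.03 g/mL) interpolated log-log in mass.  Normalized dose is ã·S
(mGy/MBq); absolute dose is normalized·A₀/1000 (Gy).

The administered-activity uncertainty combines its components in
quadrature (√Σc²; the canonical component set 0.5 %, 3 %, 10 % combines to
10.5 %).  The empirical prescription is 37 MBq per mL of tumor with the
per-mL rate clamped to 14.8–92.5 MBq/mL.

## Protocol-sparsification study

The three-point schedule {3, 24, 48} h is the reference.  Two-point
subsets refit the exponential on the subset, rescale to the SPECT
activity, and attach the physical-decay tail at the subset's last time.
Single-point protocols use the SPECT activity directly with an assumed
half-life — the physical 17 h ("{3 h}+T_phys") or a population effective
half-life ("{3 h}+T_eff") — applied from t₁ to infinity with no tail
switch (there is no later scan to anchor one; a switch-at-48 h variant
can be emulated by passing an explicit tail half-life).  The linear-rise
segment before t₁ is included by default and is switchable.

Analytically, on a mono-exponential truth with T_eff = 12.6 h,
{3 h}+T_phys overestimates the reference TIAC by +28.8 % and
{3 h}+T_eff(12.6) differs by −2.6 % (only through the reference's
physical tail after 48 h).

Percent differences (100·(ã_X − ã_ref)/ã_ref) are summarized by box-plot
statistics (linear-interpolation quartiles, whiskers at the most extreme
points within 1.5·IQR) and compared with the two-sided
Mann–Whitney–Wilcoxon rank-sum test: U counts pairs with x > y plus half
the ties; for combined n ≤ 12 the p-value is exact by enumerating all
C(n+m, n) group assignments, otherwise a tie-corrected normal
approximation with continuity correction is used.

## The synthetic cohort generator

No real scan can be shipped, so every stage is exercised on synthetic
patients with the statistical structure the analysis assumes:

* **Anatomy** — a desk-scale voxel phantom (240×160×240 mm at 5 mm) of
  axis-aligned ellipsoids: body outline (attenuation only, μ = 0.15/cm at
  155 keV), lungs (μ = 0.04/cm), liver with an embedded 25 mm-radius
  spherical tumor, stomach, spleen, kidneys.  Labels are mutually
  exclusive with tumor precedence over liver; the validator checks that
  the tumor lies inside the liver, that no other pair overlaps, and that
  voxelized volumes match the analytic ellipsoid volumes to one
  voxel-shell.
* **Kinetics** — per-region mono-exponential washout anchored at t₁, with
  effective half-lives drawn from truncated normals on (2 h, 17 h]
  centered at the clinical population values (tumor 12.5 ± 1.9, liver
  12.6 ± 1.7, lungs 12.0 ± 1.9, stomach 10.9 ± 1.9, spleen 14.7 ± 2.3,
  kidneys 12.8 ± 2.5 h).  Tumor uptake is log-uniform over 1–30 % of A₀;
  organ uptakes are uniform over modest ranges (liver 15–40 %, others
  ≤3 %), chosen so the liver dominates and the fraction sum stays below 1.
  Inter-organ half-life correlation within a patient is unknown and is
  *not* imposed (independent draws; replace the distribution specs to
  change this).  A bi-exponential option adds a slow component at T_phys,
  emulating a fast free-radionuclide phase followed by physical decay of
  the still-bound fraction.
* **Acquisition** — line-integral conjugate-view projections with
  depth-dependent attenuation (the half-voxel self-attenuation convention
  makes the geometric-mean identity exact); a global paralyzable dead-time
  loss (τ = 2 µs default, keeping cohort losses below 6 %); Poisson
  counting noise with an effective planar dwell of 160 s per pixel (a
  point stays in a ~40 cm detector field of view at the 15 cm/min bed
  speed — this yields megacount WB images, the regime the threshold-ROI
  procedure needs); integer-pixel couch shifts of up to 3 pixels on the
  later scans; a 12 mm-FWHM Gaussian blur of the SPECT volume as a
  partial-volume emulation, chosen so the known small-object
  underestimation is qualitatively reproducible.
* **Schedule** — scan times default to {3, 24, 48} h with optional jitter
  matching the clinical tolerances (±1, ±1, ±4 h); a patient is a
  two-scan patient with probability 4/13, mirroring the clinical cohort.
* **Injected activity** — uniform over the clinical 1296–7162 MBq range.

Identical (parameters, seed) produce bit-identical datasets.

### What the generator does not emulate

Planar views are ideal line integrals: no collimator blur, no scatter, no
septal penetration, and no inter-scan redistribution of activity between
organs.  ROI boundaries are geometric silhouettes rather than drawn by an
operator, and the anatomy is ellipsoidal.  Passing tests therefore show
that the *processing chain* is correct and unbiased under the stated
physics, not that the method is accurate on clinical data — in particular
the clinical inter-observer ROI variability, which dominates the spread
of real subset-protocol comparisons, has no counterpart here.

One structural consequence matters for interpretation: a planar view is a
superposition along the line of sight, so the ROI of a region whose
silhouette overlaps another active region mixes two exponentials.  Exact
(1e-6) end-to-end half-life recovery is therefore only possible when each
ROI signal is mono-exponential (single-active-region phantoms, or all
regions sharing one half-life); on the full default cohort the liver
cohort mean is recovered to a few hundredths of an hour, which is what
the acceptance checks assert.  Relatedly, with a mono-exponential truth
the {24, 48} subset refits the same half-life as the reference and its
TIAC difference is exactly zero while {3, 24} sits analytically at about
+7 % (its physical tail attaches at 24 h): the clinical observation that
{3, 24} is the *tightest* subset is a property of clinical measurement
noise, not of this generative model, and the test suite asserts instead
the model-implied claims (all subsets within ±20 %, {3 h}+T_phys biased
high by >20 % for most patients).

## Numerical choices

* Threshold comparisons are inclusive (≥); ties at the threshold are kept.
* The volume-matched tumor threshold is implemented as top-k selection
  with stable (C-order voxel index) tie-breaking — deterministic and
  exact to one voxel.
* Registration tie-breaks prefer the smallest displacement; the NCC is
  evaluated on a central core excluding the search margin.
* The dead-time inversion uses the principal Lambert-W branch and is
  exact to better than 1e-9 over rates up to 90 % of the paralyzable
  maximum; corrections above 30 % (configurable) log a warning.
* Quartiles use linear interpolation between order statistics
  (numpy's default percentile convention; configurable convention was
  considered and rejected — the tests pin one convention).
* Sample SD (n−1) for cohort summaries; a single-entry column reports
  SD 0 with a log note.
* Degenerate fits (constant or rising data) raise ``ValueError`` rather
  than returning unphysical half-lives.
* All times are hours post-injection; activities MBq; the serialization
  layer writes NIfTI (volumes), NPZ (planar pairs, masks), CSV (tables)
  and YAML (generator config, metadata).

## Problem sizes

The test suite and the acceptance script run the full pipeline on
20-patient cohorts of 48×32×48-voxel phantoms (with 10 000-draw sampling
checks and 100-point integration grids), sizes at which every stage's
statistical checks are already stable.

## Known limitations

Rotation-free registration; no background subtraction (the clinical
procedure applies none); no bone-marrow or healthy-liver (tumor-excluded)
dose; no voxel-level dosimetry; the default S-factors neglect cross-organ
dose entirely and the sphere model assumes unit-density spheres.  The
packaged clinical tables carry the published rounding; summary statistics
recomputed from them can differ from published summary rows in the last
digit (and the published liver "Max" row excludes its own largest body
entry — body rows are treated as authoritative).
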