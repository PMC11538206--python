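# Methods

`petleskit` evaluates automated lesion segmentations on whole-body
somatostatin-receptor PET/CT (e.g. ⁶⁸Ga-DOTATATE in metastatic
pheochromocytoma/paraganglioma and other neuroendocrine tumors). It covers
the full quantitative chain around a segmentation model without containing
one: SUV conversion and grid geometry, threshold-based candidate
annotation, lesion-level detection scoring, tumor-burden quantification,
agreement statistics, and anatomically resolved failure analysis, all
exercised on synthetic phantoms with known truth.

## Volumes and SUV

All volumes are 3D scalar fields with voxel spacing and origin in mm, in
RAS orientation; oblique affines are rejected rather than silently
mishandled. Two volumes are *aligned* when shape matches and spacing and
origin agree within 1e-3 mm; every cross-volume operation requires
alignment.

PET activity concentration is normalized as body-weight SUV,

    SUV_bw(v) = activity(v) [Bq/mL] × body weight [g] / injected dose [Bq],

with the injected dose assumed decay-corrected to the scan reference time
(DICOM convention) and small negative reconstruction values clipped to
zero. Body-weight SUV is the standard clinical choice and matches the
magnitudes the thresholds below presume (lesion SUVmax roughly 4–40,
hepatic background near 6); lean-body-mass or BSA variants are out of
scope. Resampling of companion volumes onto the PET grid uses trilinear
interpolation for continuous images and nearest-neighbour for masks and
label maps — the only choice that cannot invent fractional mask values.

## Synthetic phantoms

The generator emulates the *structure* of a heavily metastatic
somatostatin-receptor PET cohort, not the physics of a scanner:

- **Anatomy.** A stacked-ellipse body (pelvis–abdomen–thorax–neck–head)
  with ellipsoidal organs at fixed relative positions; a fixed integer
  code set {background 0, brain_skull 1, lung 2, mediastinum 3, liver 4,
  spleen 5, kidney 6, other_abdomen 7, bone 8} replaces an external organ
  segmentation network with a deterministic contract.
- **Background uptake** (SUV): soft tissue 1, liver 6 (the tracer's high
  physiologic hepatic background; configurable), spleen 18, kidney 10,
  bladder 12, lung 0.4, brain 0.2, bone 0.8, with a smooth ~10%
  multiplicative texture field.
- **Lesions.** Non-overlapping spheres (rejection-sampled inside the
  body), radius log-uniform 3–25 mm, nominal peak SUV uniform 4–40;
  per-scan count log-normal with median 30, clipped to [3, 280] — the
  composition of a cohort with 4–277 lesions per scan. Spheres rather than
  realistic shapes: connectivity, volume and uptake logic are what is
  under test, and spheres carry analytic volume oracles.
- **Imaging.** The emission image is blurred with a Gaussian PSF
  (FWHM 5 mm) and given heteroscedastic Gaussian noise
  (sd = 0.15·√intensity). Masks stay crisp: contours are decisions, while
  the image the threshold sees is smeared — which reproduces the realistic
  failure mode of small blurred lesions dropping below threshold. Full
  Poisson sinogram simulation is deliberately not attempted; only relative
  background/contrast behavior matters downstream.
- **Degradation.** A synthetic "AI prediction" drops each lesion
  independently with probability either fixed or logistic in log SUV and
  log volume (defaults c0 = 2.2, c_SUV = −1.2, c_vol = −0.8, so small
  faint lesions are missed preferentially), optionally erodes/dilates kept
  lesions by one voxel (an erosion that would annihilate a lesion keeps a
  core voxel so the kept/missed flags remain an exact oracle), and adds
  Poisson(λ = 3) false-positive blobs placed so they never touch true
  lesions. All randomness flows from one seed; identical spec + seed is
  bit-identical.

What the phantoms do *not* model: realistic lesion morphology, CT texture,
attenuation/scatter, inter-scanner variation, and reader variability in
the ground truth. Passing tests therefore demonstrate the correctness of
the measurement chain under known truth, not clinical performance of any
segmentation model.

## Annotation emulation

Ground-truth curation is modeled as: global voxel threshold (SUV ≥ t, with
t = 6 for PPGL/NET-like settings and 4 for low-uptake cohorts), 26-connected
decomposition into candidates, programmatic rejection rules (e.g. "≥ 50%
of voxels inside spleen/kidney"), and explicit add-back masks for known
sub-threshold tumors. A region's SUVmax exceeds t exactly when it contains
a voxel ≥ t, so voxelwise thresholding realizes the SUVmax-threshold rule.
No minimum-volume filter is applied by default.

## Detection scoring

Scan level: TP/TN/FP/FN from emptiness of ground truth vs prediction;
DSC = 2|GT∩P|/(|GT|+|P|) (defined as 1 for two empty masks). Lesion
level: both masks are decomposed into maximal 26-connected components
(labels deterministic by first voxel in C order; configurable to 6/18
connectivity). A ground-truth lesion is detected iff it shares at least
one voxel with the prediction (overlap fraction configurable); one
predicted component with zero ground-truth overlap is one false positive;
a single predicted component overlapping several ground-truth lesions
credits each. This any-overlap rule is the simplest one under which
TP + FN always equals the ground-truth lesion count. Cohort DSC is the
mean of per-scan DSC over scans with nonempty ground truth (pooled-voxel
DSC is reported alongside); per-scan sensitivity is undefined — and
excluded from medians — for scans without ground-truth lesions.

## Tumor burden

Over a binary mask: SUVmax, SUVmean, TTV = voxel count × Sx·Sy·Sz × 0.001
(cm³), TLU = SUVmean × TTV. TLU is algebraically the voxelwise sum of
SUV × voxel volume, an identity the tests verify to 1e-9. SUVmean for the
scan-level value is computed over the whole mask (not lesionwise-then-
averaged). An empty mask yields TTV = TLU = 0 with SUVmax/SUVmean NaN, so
downstream agreement statistics can exclude rather than absorb a bias
toward zero. TLU's unit is SUV·cm³; exported tables follow the common
convention of printing it as [cm³].

## Agreement statistics

- **Bland–Altman**: mean difference (prediction − reference) with
  ±1.96·SD limits of agreement; pairs outside the limits are flagged
  outliers. Simulation tests confirm ≈95% coverage for Gaussian
  differences.
- **Median RMD**: (pred − ref)/ref per scan, median with range; a
  prediction that finds nothing gives exactly −1, the statistic's floor.
  Pairs with a zero reference are excluded and counted.
- **ICC**: two-way random effects, absolute agreement, single measurement
  (pingouin's ICC(A,1)) as the primary form — absolute agreement is what
  "the prediction reproduces the reference burden" means — with the
  consistency form ICC(C,1) reported alongside. Interpretation bands:
  superior ≥ 0.8, great ≥ 0.61, moderate ≥ 0.41, low ≥ 0.21, else poor
  (half-open bins so every value maps to exactly one category).
- **Cluster-adjusted Wilcoxon rank-sum.** Lesions from one patient are
  correlated, and so are their TP/FN labels (a scan that misses one lesion
  tends to miss others). The test uses the classical rank-sum z statistic
  with its permutation variance inflated by the within-cluster structure:
  with centered midranks s_i,

      Var(W) = n₁n₂/(N(N−1)) · [Σᵢ sᵢ² + ρ̂_g · Σ_c Σ_{i≠j∈c} sᵢsⱼ],

  where ρ̂_g is the one-way-ANOVA intraclass correlation of the 0/1 group
  labels, clamped to [0, 1]. When every cluster is a singleton the
  cross-term vanishes and the test is *exactly* the ordinary large-sample
  rank-sum test; when labels are uncorrelated within clusters it stays
  close to it; when labels and values both cluster, the variance grows.
  Simulation (20 clusters of size 1–10, cluster random effects,
  beta-distributed per-cluster label propensities, 1000 replicates) puts
  the empirical type-I error near 4–5% at α = 0.05, versus ~10% for the
  unadjusted test. Pairwise group comparisons are reported without
  multiplicity correction (raw p < 0.05), with a Holm option available.
  The default clustering unit is the patient (serial scans of one patient
  share a cluster), configurable to scan.

## Failure analysis

Each evaluated lesion (TP/FN over ground-truth components, FP over
predicted components — each status has exactly one natural voxel support)
is assigned the organ code covering the plurality of its voxels, ties
toward the smaller code, background-plurality lesions to "unassigned";
assignment is total and deterministic. Region-by-status frequency tables
have margins equal to cohort totals by construction. For liver lesions,
TBR = lesion SUVmax / normal-liver SUVmean, where "normal liver" is the
liver label minus the union of ground-truth and predicted lesion voxels —
an organ label map includes tumors, and their uptake must not inflate the
background. Scans without a liver label get no TBR rather than a zero.

## Numerical and design choices

- Connected-component labeling uses `scipy.ndimage.label` with a full
  3×3×3 structuring element, relabeled deterministically; an independent
  BFS flood-fill oracle in the test suite verifies equivalence on random
  volumes.
- Mask integrality tolerance on read: 1e-6; alignment tolerance: 1e-3 mm.
- Phantom grids in the tests and the acceptance script use reduced fields
  of view (typically 48–64 voxels in-plane at 3 mm) because lesion counts,
  not voxel counts, drive every statistic; the generator default remains
  96×96×192 at 3 mm.
- Per-scan seeds derive from one root seed via `numpy` seed sequences, so
  cohort runs are reproducible scan-by-scan and re-running a serialized
  config reproduces outputs byte-identically.

## Known limitations

Spherical lesions understate the difficulty of matching irregular,
confluent disease; the any-overlap detection rule is generous for large
merged components; ICC values on small cohorts carry wide confidence
intervals that the package reports only via pingouin's internals; and the
clustered rank test is a large-sample approximation — with very few
clusters a permutation approach would be preferable.
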