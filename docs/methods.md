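# Methods

`lesionquant` implements a regional quantification pipeline for multiple
sclerosis (MS) lesions on conventional multi-contrast MRI, together with a
synthetic phantom generator that makes every stage testable without patient
data.  The scientific setting is a comparison of two relapsing-remitting MS
cohorts — pediatric-onset and adult-onset — scanned under slightly different
protocols, where the quantities of interest are T2-hyperintense lesion volume
(T2LV) and count, T1-hypointense ("black hole") lesion volume (T1LV), their
regional breakdown (supratentorial vs infratentorial; brainstem with
midbrain, pons, medulla; cerebellum; periventricular), lesion incidence
tables, and voxelwise lesion-frequency maps in a common template space.

## Phantom model

Anatomy is a nested-ellipsoid head defined analytically in millimetre
coordinates: a supratentorial ellipsoid with a white-matter (WM) core,
grey-matter (GM) shell and paired ellipsoidal lateral ventricles (CSF), and
an infratentorial compartment made of a cylindrical brainstem column split
axially into midbrain, pons and medulla slabs plus a cerebellar ellipsoid
with its own WM core.  The tentorium is the axial plane z = −14 mm.  The
atlas is rebuilt analytically on any grid, so resampled subjects get an exact
atlas rather than an interpolated one.  Base region labels are mutually
exclusive and exhaust the brain mask by construction; derived masks
(brainstem, infratentorial, periventricular) are unions or distance-based
dilations of base labels.  The periventricular region is the set of brain
voxels within a configurable Euclidean distance (default 3 mm, anisotropic
voxel sampling) of the ventricles.

Two acquisition protocols are modelled: *pediatric* (axial 2 mm contiguous
slices) and *adult* (3 mm slices), both 0.98 mm in-plane.  Tissue classes
carry constant (PD, T2, T1) means; absolute intensities are free parameters,
chosen so that the WM:GM T2 contrast ratio is 1.36 (pediatric) and 1.38
(adult), lesions are PD/T2-hyperintense (T2 at 1.5 × WM), and CSF is
T2-bright/T1-dark.  Noise is additive Gaussian (default σ = 4 intensity
units, i.e. lesion–WM T2 separation of ~17 σ; Rician noise is not modelled —
at this SNR the difference is negligible and the Gaussian is invertible in
tests).  The bias field is the exponential of a sum of 2–3 broad 3-D Gaussian
bumps (widths 30–60 mm), scaled to a configurable log-amplitude (default
0.2 ≈ ±10% modulation) and normalized to mean 1 over the brain; it is smooth
and strictly positive by construction.

Lesions are spheres with jittered radii (default 2.5–6 mm supratentorially,
1.8–4 mm in the narrow infratentorial compartments), placed rejection-wise
so that each sphere lies entirely inside the WM of its target region and is
separated from every other lesion by at least one voxel in the 26-connected
sense (enforced by dilating placed lesions one voxel before testing
overlap).  Placement retries shrink the radius cap in crowded regions and
raise a placement error after a bounded number of attempts.

**T1 black-hole model.**  Each lesion's T1 intensity follows a radial ramp
m(d) relative to the WM T1 mean, rising from the core multiplier (default
0.70) at the centre to 1.0 at the rim, with the exponent chosen so that the
fraction of the lesion volume falling below the 85% reference threshold
equals the requested core fraction.  The ground-truth T1 mask is exactly
that sub-threshold core.  The adult protocol multiplies the lesion T1
profile by 0.83/0.85, which makes an 83% threshold under the adult contrast
select the same voxels as 85% under the pediatric contrast — this is the
constructed truth that the cross-protocol calibration must recover.

**Cohort sampler.**  Each study arm is a distribution over phantom recipes:
per-subject total T2LV is drawn from a normal with the arm's reported
mean/SD (pediatric 12.76 (2.7) cm³, adult 10.03 (3.4) cm³; supratentorial
spheres are added until the ground-truth volume reaches the drawn target),
and infratentorial lesions are present with the arm's reported incidence
(0.759 vs 0.434), with counts near the reported means (4.1 vs 1.45; capped
at 6, at most 3 per narrow brainstem segment with overflow to the
cerebellum) split among pons, midbrain, medulla and cerebellum.  Per-subject
seeds derive deterministically from a master seed; identical spec + seed
yields bit-identical volumes.

What the phantom does **not** emulate: cortical folding, partial-volume
mixing beyond the implicit voxelization, pulse-sequence physics, Rician
noise, registration errors between contrasts (contrasts are generated
aligned), and non-spherical or confluent lesion shapes.  Passing recovery
tests therefore demonstrates correctness of the pipeline's numerics and
rules, not clinical-grade robustness on real scans.

## Preprocessing

Order: resample → bias-correct → register → normalize.

*Resampling.*  All subjects are brought onto the adult sampling
(0.98 × 0.98 × 3 mm) on a center-aligned grid covering the source field of
view, trilinear for intensities, nearest-neighbour for labels; binary masks
are resampled trilinearly and re-thresholded at 0.5.  A single structure
about three voxels across can gain or lose up to ~10% volume depending on
its sub-voxel position (pure discretization; verified identical to
SimpleITK's linear resampler), but the effect has near-zero mean, so total
lesion volume over a realistic multi-lesion mask is conserved to ~2%.

*Bias correction.*  A simplified smooth-field estimator: iterate (default 4
passes) classifying in-mask log-intensities into three clusters
(multi-Otsu), subtracting per-cluster means, smoothing the residual with a
heavy masked Gaussian (default 30 mm), and accumulating into the log-field
estimate.  The field is normalized to mean exactly 1 over the mask and is
strictly positive.  This is not the full N3 histogram-sharpening
deconvolution; it satisfies the same testable contract (null fields
estimated within 2%, WM coefficient-of-variation strictly reduced for bias
amplitudes up to 0.5).

*Rigid registration.*  PD and T1 are registered to T2 by Powell minimization
of the masked mean squared difference over 6 parameters (rotations
parameterized in degrees so Powell's steps are commensurate with the
millimetre translations), with a smoothed, subsampled first level and an
optional full-resolution refinement.  Perturbations of a few mm/deg are
recovered within 0.5 mm / 0.5°.  The pipeline default uses the coarse level
only, because phantom contrasts are generated aligned.

*Intensity normalization.*  A two-piece linear map pins the in-mask 2nd
percentile, median and 98th percentile to the standard scale (0, 100, 200).
Landmarks are order statistics (`np.percentile(..., method="nearest")`): a
monotone map commutes with order statistics exactly, which makes the
normalization idempotent to machine precision (interpolated percentiles
break this at the middle breakpoint).

## Segmentation

*Supratentorial T2 lesions* use a four-class (WM, GM, CSF, lesion)
multivariate-Gaussian Bayesian classifier over the normalized (PD, T2, T1)
vector: a voxel is lesion when the posterior
π_L N(x; μ_L, Σ_L) / Σ_c π_c N(x; μ_c, Σ_c) exceeds a threshold (default
0.5, the MAP rule for a two-way decision).  No spatial regularization is
applied.  In the pipeline the WM/GM/CSF classes are fitted per subject from
the atlas tissue labels (the WM sample is trimmed of its brightest-T2 decile
so lesions do not contaminate it); the lesion class is synthesized from the
WM statistics with configured raw-scale contrast multipliers (1.33, 1.5,
0.80), mapped through each contrast's normalization map, and an inflated WM
covariance with a small prior (0.04).  A brute-force per-voxel posterior
implementation must agree exactly with the vectorized one (tested).

*Infratentorial T2 lesions* — unreliable for the multispectral classifier
under the source protocols and originally delineated by hand — use a
relative threshold: voxels brighter than 1.3 × the infratentorial WM mean,
within the infratentorial mask, intended for review through the manual-edit
importer (add/remove/keep labels on the same grid).

*T1 black holes.*  A voxel is hypointense when (a) it is "confirmed bright
on T2", implemented as containment in the final T2 lesion mask, and (b) its
T1 intensity is below a protocol fraction (pediatric 0.85, adult 0.83) of
the mean T1 of surrounding normal-appearing white matter — WM within a ring
(default 5 mm) of the lesion surface, lesion voxels excluded, falling back
to the global NAWM mean with a logged warning when the ring is empty.  The
T1 mask is a subset of the T2 mask by construction.  Relative thresholds are
invariant under any global intensity gain but *not* under the two-piece
normalization map (its segments have non-zero intercepts), so the pipeline
applies them to the bias-corrected, un-normalized images; this keeps the
threshold exactly protocol-relative and is the more principled reading of a
"percent of NAWM" rule.

*Cross-protocol calibration.*  Given subjects scanned under both protocols,
the adult fraction is the value whose median (over subjects) T1LV matches
the pediatric T1LV at the 85% reference: a 0.005-step grid scan of the
signed median volume difference followed by bisection (valid because each
subject's thresholded volume is non-decreasing in the fraction).  The median
(rather than the mean) is robust to a single outlier pair.  If the volume
curves never cross and the best discrepancy exceeds 5% of the median
reference volume, a calibration error carrying the full diagnostic curve is
raised.

## Quantification

Connected components are labeled at 26-connectivity by default — the
strictest reading of "distinct lesions are separated by at least one voxel"
(6/18 available).  T2 lesions below 3 voxels are discarded from both counts
and volumes; T1 lesions have no minimum (the printed rule covers T2 only).
Note the 3-voxel rule's parenthetical "9 mm³" implies 3 mm³ voxels, while
the working grid's voxel is 0.98 × 0.98 × 3 = 2.8812 mm³; the *count* rule
(3 voxels) is taken as authoritative.  Volumes are voxel counts × voxel
volume (cm³), additive over regions, so supratentorial + infratentorial,
periventricular + non-periventricular, and midbrain + pons + medulla =
brainstem hold at machine precision.  A lesion straddling the tentorium is
counted once, in the compartment holding the voxel majority (ties go
supratentorial); its volume splits by voxel membership.  Frequency maps are
voxelwise means of the binary template-space lesion masks per compartment;
phantoms are generated in a shared grid so the template transform is the
identity (an affine applicator with nearest/trilinear interpolation is
provided and round-trip tested).

## Statistics

Lesion volumes are right-skewed, so volume comparisons use Student's t-test
(pooled variance; Welch by config) on log(volume + c) with c = 1 cm³ — the
transform constant is not specified by the study and 1 cm³ keeps zero-volume
subjects defined.  Non-normalized continuous variables (infratentorial and
periventricular volumes) use the Mann-Whitney U-test: exact enumeration for
combined n ≤ 12 without ties, otherwise the normal approximation with tie
and continuity corrections; all-tied samples return p = 1 by convention.
Incidence uses Fisher's exact test with the point-probability two-sided rule
(sum of all same-margin tables whose probability does not exceed the
observed table's, within a 1e-7 relative tolerance absorbing floating-point
ties).  Significance is declared at raw p < 0.05 with no multiplicity
correction (the comparisons are pre-specified).  Type-I error of both group
tests is verified at 0.045–0.055 under 10⁴ null simulations at n = 29/29.

Per-subject T1:T2 volume ratios are compared with the t-test; subjects with
zero T2 volume in a region are dropped from that region's ratio comparison
(the ratio is undefined), so a ratio row can be absent when fewer than two
subjects per group qualify.

## Problem sizes and numerical choices

Phantom grids are 96 × 96 × 60 (pediatric, 2 mm) and 96 × 96 × 40 (adult,
3 mm), a 94 × 94 × 120 mm field of view.  The demonstration pipeline runs
two cohorts of 10 subjects each; recovery checks use 10 phantom seeds and
10 calibration pairs — sizes chosen so a complete desk run of all stages
finishes in minutes on one CPU while keeping Monte-Carlo errors on the
reported rates near one percentage point.  Covariance fits add a ridge
(1e-6 × mean eigenvalue) only when singular; posteriors are computed via
Cholesky factors in log space and normalized with the log-sum-exp shift.
Degenerate inputs follow explicit conventions: zero variance in both groups
with equal means gives p = 1 (unequal means is an error), empty masks and
non-overlapping fields of view raise typed errors rather than propagating
NaNs.

## Known limitations

The Bayesian classifier's lesion class is synthesized from configured
contrast multipliers rather than trained on labeled lesions; on real data it
would need either training labels or an intensity-prior atlas.  The phantom
grids are center-aligned (no oblique acquisitions), the stereotaxic
transform is supplied rather than estimated (nonlinear registration is out
of scope), skull stripping is assumed done (mask supplied), and interactive
lesion review is replaced by a deterministic edit-mask importer.  Reported
recovery rates (Dice ≈ 0.99, volume error ≈ 1%) reflect the phantom's crisp
tissue model; real-scan performance is outside what these tests can show.
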