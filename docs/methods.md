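# Methods

`tarsalct` re-creates, end to end, the quantitative in vivo µCT workflow
used to monitor arthritis in the mouse tarsus: per-image bone and
soft-tissue volumetry over an anatomically anchored volume of interest
(VOI), plus the longitudinal statistics of a three-arm treatment study.
Because raw scans from such studies are rarely deposited, the package
ships a synthetic-data layer — geometric phantoms with exact ground
truth, and cohort simulators with known effect structure — so every stage
of the pipeline can be validated quantitatively.

## Image model and quantification pipeline

A volume is a 3-D scalar grid of HU-like arbitrary units (AU) with
per-axis voxel spacing in mm (`VoxelVolume`). The protocol's spacing is
18 µm isotropic; the slice axis is the last array axis with +z distal.
Quantification proceeds in four steps (`quantify`):

1. **Reorientation** (`reorient_to_axis`). The above-threshold bone voxel
   cloud is reduced to its second moments; the volume is rigidly rotated
   so the longest principal axis lies along +z, with trilinear
   interpolation into a grid padded so no tissue is clipped. Degenerate
   inputs are rejected: fewer than 10 foreground voxels, or a principal
   SD ratio below 1.05 (no meaningful long axis). The axis sign is fixed
   by bone-mass asymmetry: the heavier (landmark) end of the stack goes
   proximal (−z). If the measured misalignment is under 0.5° the volume
   is returned untouched — resampling an already-aligned image would
   degrade it for no benefit, and this keeps the aligned path bit-exact.
2. **VOI extraction** (`find_voi_start`, `extract_voi`). The VOI is a
   full-slice slab of 100 slices (1.8 mm at 18 µm) starting at the first
   slice containing the landmark bone. Automatic landmark detection (the
   first slice whose above-threshold count rises from zero) is defined
   for phantoms only; real anatomy requires an explicit start slice, as
   in the manual protocol. An optional histogram tool
   (`compute_histogram`, `suggest_threshold`) reproduces the
   threshold-from-histogram inspection step; the Otsu cut is computed
   from the histogram restricted to the soft/bone portion, with the
   midpoint of the optimal plateau returned (well-separated classes leave
   a flat maximum across the empty intensity gap, and the conventional
   first-bin tie-break would sit against the soft peak).
3. **Segmentation** (`segment_bone`, `segment_soft`). Bone is every voxel
   strictly above 3500 AU on raw intensities. Soft tissue is every voxel
   inside [−300, 1500] AU after an isotropic Gaussian of SD 0.1 mm
   (converted to voxels per axis, kernel truncated at 4 SD); smoothing is
   applied to the soft channel only. Bone voxels are excluded from the
   soft mask by default, so the compartments are disjoint.
4. **Volumetrics** (`mask_volume`). Volume is the true-voxel count times
   the voxel volume — nothing else. This makes a brute-force triple-loop
   count an exact oracle, which the tests exploit.

## The phantom

`default_tarsal_spec()` describes a tarsal-like scene at 18 µm: five
ellipsoidal bone bodies — a large navicular analogue, three cuneiform
analogues side by side, and a cuboid analogue — inside an ellipsoidal
soft envelope (transverse semi-axis 1.3 mm) on an air background.
Rasterization is voxel-centre membership, with the scene rotation undone
point-wise, so ground truth is exact by construction. Three geometric
properties are deliberate:

* **The bone stack spans exactly 100 slices.** The extreme bone surfaces
  poke 8 µm (less than half a voxel) past the first and last covered
  slice centres, so the default VOI contains the entire stack and
  noiseless bone recovery can be checked for *exact* equality.
* **In-plane balance.** The cuneiform analogues' lateral offsets cancel
  at every z, so the principal axis of the aligned phantom is exactly +z.
  An unbalanced stack is intrinsically tilted (several degrees) and
  would trigger resampling of an already-aligned image.
* **Midpoint intensities.** Air −900, soft 300, bone 6700 AU, noise SD
  50 AU. Each segmentation boundary sits at the midpoint of the step it
  cuts (3500 = (300+6700)/2; −300 = (−900+300)/2), so neither trilinear
  resampling nor the 0.1 mm Gaussian shifts the implied tissue surfaces
  on average. Off-midpoint intensities bias recovered volumes by
  ~0.2 voxels over the whole surface area — several percent for bodies
  of this size — which is a property of thresholding interpolated data,
  not of any particular scanner.

Residual noiseless STV error (~2.6%) is the smoothing shell at the
soft/bone interface: the soft window's upper bound (1500 AU) is
necessarily below the soft→bone midpoint, so a sub-σ shell of soft
tissue adjacent to bone falls out of the window. It is confined to
within 0.4 mm of interfaces and is the same effect a real scan would
show.

**Disease effects.** `apply_disease` carves erosion pits — spheres of
radius 0.05 mm centred at seeded random points on the bone surfaces —
one at a time against the rasterized bone mask until ground-truth bone
volume has dropped by the requested fraction (stopping within 0.5%).
The calibrated pit centres are stored on the spec, so regeneration is
deterministic and erosion is monotone in the fraction for a fixed seed.
Swelling scales the envelope semi-axes isotropically (volume ratio is
exact up to the enclosed bone, well inside 5%), enlarging the grid if
needed.

## The cohort simulator

`default_cohort_design()` encodes a three-arm longitudinal study: naive
(n=10), untreated (n=6), prednisolone (n=6), measured on days 0, 7, 14,
21 for caliper paw thickness (mm), in vivo BV (mm³) and STV (mm³), with
terminal ordinal histopathology (0–4) for inflammation, pannus and bone
destruction. Each animal is group/day mean + a Gaussian animal-level
random intercept + Gaussian residual; design SDs are totals, and the
residual SD is the quadrature complement of the intercept SD (caliper
0.05, STV 0.6, BV 0.06 in the defaults). Day-21 means and SDs anchor
the printed endpoints of the study the package emulates (STV 10.7 ± 0.8
vs 19.5 ± 2.4 mm³; BV 2.1 ± 0.1 vs 1.4 ± 0.1 mm³; caliper 2.08 ± 0.08 vs
2.6 ± 0.2 mm); intermediate days are synthetic interpolations with the
model's canonical shape (elevated at enrolment, peak at day 7, treatment
response thereafter) — they are plausible, not reported, values. The
histopathology distributions put the naive mass at 0, centre untreated
at 3–4 and prednisolone at 1–2, reproducing the group ordering without
inventing unprinted means.

The terminal ex vivo channel inverts the published agreement line:
`ex = (in − 0.4)/0.7 + ε`, so regressing in vivo on ex vivo recovers
slope 0.7 and intercept 0.4 by construction. The default scatter SD
(0.12 mm³) is set so the simulated 21-pair regression shows R² ≈ 0.98 at
the default between-group spread; recovery tests use a smaller stated
scatter (0.05 mm³) independent of this default.

What the simulators do **not** emulate: reconstruction physics (beam
hardening, ring artifacts, partial-volume blur beyond interpolation),
anatomically realistic bone shapes, observer variability in landmark
placement, missing data and dropout, or any correlation between an
animal's imaging measures and its histopathology scores. Passing tests
therefore demonstrate correctness of the measurement and inference
machinery under known truth, not performance on real scans.

## Statistical layer

Matching the emulated analysis plan: two-way ANOVA (group × day, OLS)
for caliper data — analysed as change from baseline by default, since
that is how paw-swelling trajectories are reported; linear mixed-effects
(random intercept per animal, REML via statsmodels `MixedLM`) for the
µCT measures; one-way ANOVA for terminal ex vivo BV; Kruskal–Wallis with
midranks and tie correction plus Dunn's z (pooled ranks, Bonferroni over
the comparisons performed) for ordinal scores, each treatment group
against the untreated control. Per-day contrasts are estimated on cell
means; mixed-model contrasts use a Wald t with df = n_animals − n_groups,
the between-animal degrees of freedom that dominate a single-day
between-group contrast under a random-intercept model (statsmodels does
not provide Satterthwaite df). The 500-replicate null simulation puts
the day-21 contrast's type-I error at ~0.05, inside the 3–8% calibration
band. Degenerate inputs are handled explicitly: identical groups give
F = 0, p = 1; a zero-variance fit falls back to exact cell means with
p ∈ {0, 1} by sign of the difference.

The agreement regression is a closed-form OLS of in vivo on ex vivo
(that orientation matches the published line; a flag can swap axes for
sensitivity analysis); it is cross-checked against `scipy.stats
.linregress` in the tests.

## Numerical and design choices

* Intensities are stored as float32 in memory and signed 16-bit integers
  on disk (the AU range fits comfortably), fixing round-trip semantics.
  NIfTI spacing is authoritative; TIFF stacks require an explicit
  spacing because their resolution tags are unreliable in practice.
* Segmentation always runs after resampling; masks are never resampled
  (mask interpolation aliases surfaces).
* Strict `>` at the bone threshold and an inclusive soft window, so a
  uniform volume at exactly 3500 AU contains no bone.
* The in vivo VOI is a full-slice slab; a cylindrical in-plane
  restriction (as used for ex vivo analysis in the emulated protocol) is
  a documented open question and can be imposed by masking before
  `mask_volume`.
* The validation suite and acceptance script run at the scale chosen for
  the package's own CI: the study-size phantom (≈6.8 M voxels), 20 noise
  seeds, rotations up to 45°, 500-seed regression recovery, 500-replicate
  type-I calibration.

## Known limitations

* Landmark auto-detection assumes the first above-threshold slice is the
  landmark bone — true for phantoms, not guaranteed on real anatomy
  (the talus must be excluded by the operator's start slice).
* Principal-axis reorientation recovers the axis but not roll about it;
  volumetrics are roll-invariant, renderings are not.
* The mixed-model df approximation is exact only for balanced designs
  with dominant between-animal variance; p-values on heavily unbalanced
  real data may differ in late decimals from other software.
* Erosion pits model surface roughening only; they do not reproduce
  trabecular microarchitecture, and trabecular morphometry (BV/TV,
  Tb.Th, …) is out of scope.
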