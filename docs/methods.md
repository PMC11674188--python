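# Methods

`imfseg` quantifies inter-/intra-muscular fat (IMF) and muscle volume from
axial T1-weighted MR stacks of the calf or thigh. On T1-weighted images fat
is bright and muscle dark, but the separating intensity threshold is
unstable across scanners, coils and slices, so a fixed threshold does not
reproduce across repeated scans. The pipeline addresses this with a
slice-specific fixed-point threshold search plus a set of corrections for
the two failure modes that dominate test-retest error: noise mistaken for
fat, and partial-volumed fat voxels whose signal mixes muscle and fat.

## Pipeline

Stages, in order, for one volume:

1. **CLAHE** (contrast-limited adaptive histogram equalization), per slice,
   flattens receive-coil (B1) intensity falloff before any class or contour
   decision. Output is rescaled to the slice's original dynamic range.
   Defaults: clip limit 2% of tile histogram mass, 8x8 tile grid.
2. **Automated ROI.** A three-class multi-Otsu pre-mask separates void/
   cortical bone (low), muscle-like (mid) and fat-like (high) intensities.
   *Bone*: low-signal objects >= 234 mm^2 that do not touch the image border
   are cortex; marrow is seeded at the maximal cluster of the z-summed
   fat-class mask — marrow fat is the structure most nearly co-aligned
   along the stack — with the cluster *enclosed by cortex* preferred, since
   subcutaneous fat can also be substantially z-aligned; the seed is grown
   into overlapping fat components per slice, and cortex ∪ marrow is
   solidified. *Muscle*: the mid-class mask is closed (1.5 mm disk) to
   bridge thin fat streaks, opened with half that radius to cut soldered
   boundary debris, cleaned of objects < 60 cm^2 and holes < 180 cm^2
   (border-connected complement components are exterior, never holes), and
   the largest object is flood-filled. Its convex hull approximates the
   fascia — a smooth envelope that must also enclose inter-muscular fat —
   and three coarse-to-fine rounds of a morphological geodesic active
   contour settle the hull onto the fascial edge (balloon = contraction
   pressure, morphological smoothing = curvature term, inverse-gradient
   gain = edge attraction). A round changing the area by more than 50% is
   treated as divergent and reverted (flagged). *Overshoot removal*: within
   the contour, an Otsu split separates fat-like candidates; large
   (>= 50 mm^2) candidates touching the primary bone that have connected
   candidates on an adjacent slice are removed as subcutaneous overshoot;
   single-slice candidates are retained (3-D fidelity exception). The split
   is only trusted when the two classes separate by >= 2 pooled SDs —
   on lean muscle an unconditional Otsu would halve the noise and the
   bright half percolates into a spurious candidate. The final ROI is the
   fascia interior minus all bone, multiplied into the **raw** image: all
   intensity statistics (threshold search, partial-volume model, overshoot
   candidates) run on raw intensities; CLAHE output drives only class and
   contour decisions. A config switch (`itsa_on_raw=False`) runs everything
   on CLAHE output instead.
3. **ITSA round 1.** Per slice: seed threshold from Otsu on the ROI
   histogram, then iterate
   `ST_R = (1 + (SF_i - SM_i)/SF_i) * SM_i`,
   where SM_i and SF_i are the mean intensities of the currently segmented
   muscle and fat. Fat islands below 4 mm^2 are pruned before computing the
   class means at each iteration (noise must not steer the threshold);
   convergence when successive thresholds differ by < 0.5 intensity units
   (exact equality is fragile in floating point), max 50 iterations. If
   pruning empties the fat class the slice is declared lean and returns an
   empty mask (flagged). The final mask is taken at the converged threshold
   *without* pruning; island handling is deferred to the 3-D check.
4. **ITSA round 2** repeats the search on the ROI with round-1 fat
   removed, lowering the threshold into the partial-volume band. Round-2
   voxels are disjoint from round 1 by construction.
5. **3-D connectivity check**, applied to each round's mask and then their
   union: per-slice 8-connected islands >= 16 mm^2 are definite fat; smaller
   islands are kept only when connected to fat on an adjacent slice
   (through-plane contact includes in-plane 8-neighbour offsets by default,
   `connectivity.z_mode="face"` restricts to same-position contact);
   everything else is removed as noise. A single-slice volume falls back to
   the area rule alone.
6. **Lean-muscle safeguard**: union-mask fat voxels with intensity within
   2 SD of the round-1 muscle mean are reclassified to muscle. Runs before
   the partial-volume fit so the model never sees voxels about to be
   reclassified.
7. **Partial-volume correction.** Assuming signal scales linearly with the
   fat fraction per voxel, `C = (SV_x - SM_x)/(SF_max - SM_x)`, clamped to
   [0, 1]; SF_max is the mean of the top quartile of round-1 IMF voxel
   intensities (config: the 75th-percentile point, or the mean subcutaneous
   signal as a sensitivity alternative — also the fallback when round 1 is
   empty); SM_x is the whole-volume mean of ROI voxels outside the entire
   IMF segmentation. Voxels at or above SF_max are full fat (NF); the rest
   of the mask carries per-voxel fractions (NV). Negative raw C (noise)
   clamps to 0 rather than erroring.
8. **Metrics.** `IMF_V = (NF + sum C_i) * VoxelVolume`,
   `M_V = (NM + sum(1 - C_i)) * VoxelVolume`,
   `IMF% = IMF_V/(IMF_V + M_V) * 100`; conservation
   IMF_V + M_V = ROI volume holds exactly. Volumes are internal mm^3,
   reported cm^3; per-slice means are reported because calf and thigh
   protocols have different slice counts. Protocol presets select slices
   (calf 1.0 T: centre 8 of 10, end slices suffer signal loss; thigh 3 T:
   all 15). Subcutaneous fat volume is the fat pre-mask outside the fascia
   contour times voxel volume (a pragmatic operational definition).
9. **QC.** Automatic flags from diagnostics: ITSA non-convergence, snake
   divergence/revert, absent bone, and the lean-muscle signature (the 2 SD
   safeguard reclassifying > 5% of candidate fat, or at least half the
   slices finding no fat distribution). Flagged cases are exported as a
   NIfTI label map + JSON code-map sidecar (or a flat one-byte-per-voxel
   `.tag` buffer behind a format flag), edited externally, and re-imported;
   by default the threshold search is re-run inside the corrected ROI
   (corrections fix the ROI, not the thresholds), or metrics alone can be
   recomputed from the imported labels.

### Ablation variants

`variant_metrics` recomputes metrics from a finished case with the
corrections toggled, for attributing precision gains. "3-D off" does not
mean "no island handling": island removal is intrinsic to the method, and
the 3-D check is a *rescue* applied to it. With the check off, only the
in-plane area rule decides (sub-16 mm^2 islands are discarded wholesale,
including genuine streak tips); with it on, z-connected small islands
survive. "CF off" counts every retained fat voxel as a full voxel instead
of its fraction; "round 2 off" uses the round-1 mask alone.

## Precision statistics

Duplicate-measurement conventions (densitometry practice): per pair
SD_i = |a_i - b_i|/sqrt(2), CV_i = 100 SD_i/mean_i; RMSSD and RMSCV are
root-mean-squares over subjects; the least significant change
LSC = 1.96 sqrt(2) RMSSD. ICC(2,1) (two-way random effects, absolute
agreement, single measure) is computed from the ANOVA mean squares with the
McGraw-Wong F-based 95% CI and is verified in tests against pingouin's
independent implementation. Bland-Altman differences are method1 - method2
(convention: fully-automated minus reference); the calibration line is
ordinary least squares. Long-term pairs pair each follow-up with the first
baseline scan.

## Synthetic phantoms

The phantom module renders a leg cross-section — elliptical fascia,
subcutaneous fat ring, one long bone (dark cortex annulus, bright marrow),
and bright fat streaks — on a 4x supersampled in-plane grid, then
block-averages to the voxel grid, so every boundary voxel carries an
analytically known partial-volume fat fraction and the true IMF volume is a
quadrature sum, exact to < 1%. Streaks are rotated rectangles (width
0.8-2.5 mm, length 15-40 mm) that persist over 3-10 contiguous slices and
drift slowly, giving the 3-D connectivity rule true positives; a few
isolated one/two-voxel bright specks with no z-support are true negatives.
The fascia and outer skin boundary wobble (<= 2.5 mm) and taper (6% across
the stack) per slice — legs are not cylinders, and without this the static
subcutaneous ring would be as z-aligned as marrow. Imaging conditions:
tissue means muscle 100, fat/subcutaneous 230, marrow 235, cortex and
background ~4 (T1w contrast ordering); a 5% parabolic multiplicative bias
field; additive Gaussian noise SD 5 (Rician optional). Geometry presets
mirror the two acquisition protocols (calf 1.0 T: 0.312 x 0.312 x 2.0 mm,
10 slices, fascia 44 x 50 mm semi-axes giving a ~66 cm^2 compartment,
comparable to reported mid-calf muscle areas; thigh 3 T:
0.977 x 0.977 x 5.0 mm, 15 slices). A "dystrophy" preset pushes wide
streaks against the fascia to reproduce the hardest failure mode for QC
testing.

Test-retest subjects share one anatomy; each of the two acquisitions gets
an independent small rigid repositioning (<= 2 mm translation, <= 3 deg
rotation, resampled at the supersampled resolution) and independent
noise/bias realizations. Both scans pass through the same resampling path —
a grid-aligned "first" scan would be artificially crisp and bias the pair.
True metrics are computed in the anatomy frame and are identical within a
pair, so measured within-pair differences are pipeline error only.

What the phantom does **not** emulate: MR physics (relaxometry, k-space
artifacts), motion streaks, anatomical texture inside muscle, multiple
muscle compartments, or bilateral fields of view (a splitting utility for
bilateral thigh volumes cuts at the widest background gap along x, but the
battery is unilateral). Passing the phantom batteries therefore shows the
algorithmic chain is correct and stable under noise, bias, partial
voluming and repositioning — not that it handles pathology, motion or
real-tissue texture; those remain the province of the QC workflow.

## Numerical and design choices

- Axis convention: axis 0 through-plane; areas use in-plane spacing,
  volumes add slice thickness. All size rules are stated in physical units
  and converted per-volume, so one configuration serves 0.312 mm and
  0.977 mm pixels.
- Boundary ties: "above 234 mm^2" is >=, "below 60/180 cm^2" is <; islands
  of exactly 16 mm^2 are definite fat.
- Muscle-mask cleanup order (closing before the size rules) bridges
  streak-fragmented muscle before the 60 cm^2 object rule can delete the
  fragments; the largest object always survives as a degraded fallback.
- The in-plane island pruning during ITSA iterations (4 mm^2) exists only
  to stabilize the class means; the final masks are unpruned and judged by
  the 3-D rule, which is strictly more permissive for z-connected fat.
- Primary bone = component with the largest mean cross-sectional area
  (tibia in the calf, femur in the thigh).
- Fixed points of the threshold map need not be unique; the test oracle
  enumerates all of them (the map is piecewise constant between distinct
  intensities) and requires the iterate to land within tolerance of one.
- Degenerate inputs: empty/constant ROI slices return empty fat with a
  flag; SF_max <= SM_x (no fat/muscle contrast) is a hard error; pairs with
  zero mean are excluded from CV; zero between-subject variance returns a
  flagged ICC of 0.
- Problem sizes in the shipped batteries (20 subjects, 10-slice calf
  volumes, 4x supersampling) were chosen so the full acceptance battery
  completes comfortably on a single CPU while keeping >= 30 degrees of
  freedom for precision estimates.

## Known limitations

- INTER- vs INTRA-muscular fat are quantified jointly, not separated.
- The subcutaneous-fat volume definition is operational (pre-mask outside
  the fascia), not anatomically validated.
- The marrow z-summation cue needs either slice-to-slice anatomy variation
  or the cortex-enclosure disambiguation; on a perfectly cylindrical
  phantom with no wobble the subcutaneous ring ties with marrow.
- Contours are found per slice independently; no 3-D contour propagation.
- The Sliceomatic-style `.tag` adapter is a best-effort flat-binary layout;
  the NIfTI + sidecar dialect is the supported contract.
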