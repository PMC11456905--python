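# Methods

This note records the models implemented in `liverspare`, the parameter
defaults and why they were chosen, and what the synthetic phantoms do and
do not establish about real patient data.

## Synthetic phantoms

Each phantom lives on a regular voxel grid, by default 128 × 128 × 24 at
1.1 × 1.1 × 8.0 mm — thin in-plane pixels with thick axial slices, the
geometry of abdominal quantitative-MR stacks. All anatomy is procedurally
simple (ellipsoids and tubes): an elliptical body cylinder, an ellipsoidal
liver displaced toward the patient's right, a spherical tumour (GTV)
strictly inside the liver, two superior lung ellipsoids, a posterior
vertebral column with a spinal-canal tube inside it, and an anterior
bowel-like tube. Realism of organ shape is explicitly a non-goal; what
matters is that every downstream contract (containment, density
partition, beam geometry) can be exercised and checked exactly.

**cT1 field.** Liver fibroinflammation is emulated as a two-component cT1
mixture on top of a spatially correlated Gaussian field (white noise
convolved with a Gaussian of `correlation_length_mm`, default 15 mm, then
standardized). The field is cut at its empirical quantile equal to
`functional_fraction_target` within liver∩FOV; voxels below the cut draw
cT1 from N(700, 40²) ms, voxels above from N(950, 40²) ms, each clipped to
its own side of the 800 ms boundary. The clipping makes the imposed
functional fraction exact — including the degenerate targets 0 and 1 —
at the cost of truncating the component tails by about 0.6 % of draws.
The two-component form and its parameters are this package's stand-in
for within-liver cT1 distributions, which are not characterised in the
literature at voxel level; they are deliberately configurable.

**Field of view.** cT1 acquisitions often do not cover the whole liver.
The FOV mask keeps a fraction (`fov_coverage_fraction`, default 0.75) of
the liver's axial slices, removing whole slices from the superior end,
matching how a fixed axial stack truncates a cranially extended organ.

**Determinism.** A phantom is a pure function of its configuration; the
seed feeds a `SeedSequence` that splits into independent streams for the
correlated field and the mixture draws.

## FLV segmentation

The chain is: in-plane block-mean downsample by 2 (1.1 → 2.2 mm; slice
direction untouched) → crop to the bounding box of liver∩FOV → strict
threshold (`cT1 < 800 ms` functional) → Gaussian smoothing of the binary
mask → keep voxels at or above the median smoothed value. Masks are
downsampled by block vote (block mean ≥ 0.5).

Numerical choices:

- **σ units.** The smoothing sigma is 4 voxels of the downsampled
  in-plane grid by default (configurable to isotropic mm). The filter's
  purpose is to stop the optimiser chasing grid-scale speckle, which is a
  grid-scale notion, so voxel units are the natural default; the slice
  axis is not smoothed in voxel units.
- **ROI-normalized smoothing.** The 0/1 mask and the ROI indicator are
  convolved with the same zero-padded Gaussian (kernel truncated at 6σ)
  and divided inside the ROI. The ratio is a local functional fraction in
  [0, 1] that is immune to boundary attenuation: a fully functional liver
  maps back to exactly the full ROI rather than being eroded at the organ
  edge by zero padding.
- **Median scope.** The median is taken over strictly positive smoothed
  values (within liver∩FOV by default) and the threshold keeps `≥` so the
  all-functional case reproduces the full ROI. A median over all ROI
  voxels would be 0 whenever under half the liver is functional and the
  rule would then keep everything.
- **Known behaviour of the median rule.** Because the 6σ kernel spreads
  positivity widely, in a diffusely heterogeneous liver nearly every ROI
  voxel is strictly positive after smoothing and the rule effectively
  keeps the upper half of the smoothed field. Two consequences, both
  verified against a dense brute-force implementation of the chain:
  isolated speckle is removed when the functional region dominates the
  ROI but can survive on top of the smoothed halo when it does not; and
  the realized FLV/FOV ratio concentrates near ~50 % even when the
  imposed pre-smoothing functional fraction spans 0.2–0.85. The
  pre-smoothing fraction, not the post-median ratio, is the controlled
  covariate of the synthetic study.
- The FLV is resampled to the planning grid by nearest neighbour so it
  stays binary.

## Pseudo-CT

Every body voxel receives exactly one relative electron density by
priority: vertebrae 1.153, lung 0.328, remaining tissue 0.988; outside
the body 0. Priority puts specific structures above the generic
remainder; the assignment partitions the body exactly (tested).

## Dose engine

A linear, density-aware pencil beam intended for *relative* plan
comparison, not absolute dosimetry. Twelve parallel-beamlet beams are
equispaced over the arc 168° → 24° traversed through posterior (the arc
avoiding the anterior-left sector), gantry 0° anterior, increasing
clockwise viewed from the feet. Beamlets form a 5 mm lattice in the plane
perpendicular to each beam covering the PTV projection plus 10 mm.

The influence of beamlet *b* on voxel *v* is
`exp(-μ_eff · d_rad(v, beam)) · exp(-r_vb² / 2σ²)` with μ_eff = 0.005/mm
and σ = 3 mm — toy constants, configurable, chosen to give depth-dose and
penumbra behaviour qualitatively like a MV photon beam at the 2.2–8 mm
grid scale. `d_rad` is the exact line integral of electron density along
the ray (plane-crossing traversal, no sampling error; vectorized over
rays). Entries below 10⁻⁴ of their column maximum are truncated to keep
the matrix sparse. Beamlets are non-divergent: divergence adds nothing to
a same-engine comparison and would complicate the brute-force oracle.

## Optimization

The objective is a weighted sum of one-sided quadratic penalties — PTV
underdose below the prescription (weight 100), PTV overdose above
1.25 × Rx (20), OAR dose above structure levels (50 on each PRV), liver
(minus GTV) mean above the tier limit (2000) — plus, in the sparing arm,
`weight × mean_FLV[x/(1+x)]`, `x = (d/d_ref)^k`, with d_ref = 15 Gy,
k = 3. The per-voxel damage is logistic in log dose, so its gradient is
spread across the dose range rather than concentrated at one DVH level:
the optimiser can trade low dose to a large volume against high dose to a
small volume, the behaviour wanted for a parallel-architecture organ.
The functional form and constants are this package's concrete
instantiation of a commercial "parallel" cost whose formula is not
public; all are configurable.

The solver is projected gradient descent (non-negativity by projection)
with a monotone backtracking line search and a deterministic start
(uniform fluence scaled so the PTV mean equals the prescription), so plan
pairs differing only in the sparing term are exactly comparable and the
objective trace is non-increasing by construction. Default 120
iterations, relative-decrease tolerance 10⁻⁷.

**Prescription tiers.** Plans are tried from the highest tier down
(default 50 Gy with a 13 Gy liver-mean cap, then 40 Gy with 15 Gy); the
first tier whose optimized plan respects its cap on the liver-minus-GTV
mean is selected. These tier values are package defaults standing in for
protocol tables that are not public, and are fully overridable.

**Sparing weight ladder.** Starting at 25 and doubling (7 steps by
default), the parallel weight rises while PTV D95% stays at or above the
optimal tolerance (95 % of prescription); the last compliant plan is
returned, warm-started from the standard fluence for speed. If the first
rung already violates the floor, the standard plan is returned flagged.

**Matched-coverage check.** Standard plans are rescaled (pure linear
factor on fluence and dose) to the sparing plan's PTV D95% before a
second cohort comparison, ruling out coverage loss as the source of the
FLV reduction.

## Metrics and statistics

Dx% and Dycc are computed on sorted voxel doses — no histogram binning —
so worked examples are exact; Dycc interpolates the cumulative-volume
curve linearly between sorted voxels. The binned DVH (0.05 Gy bins) is
for plotting and agrees with sorted-voxel metrics within one bin width.
The functional ratio rounds half away from zero to an integer percent.
V10Gy is emitted in both conventions (volume at/above and volume below
10 Gy) because liver criteria are quoted both ways.

The paired Wilcoxon signed-rank test drops zero differences, uses
midranks for ties, and enumerates all 2^n sign assignments for n ≤ 20
(two-sided p = min(1, 2·min(P(W ≤ w), P(W ≥ w))) — which reproduces the
2/2¹⁰ = 0.0020 floor for a 10-patient cohort with a uniform direction of
effect). For n > 20 a tie-corrected normal approximation is used and
flagged. Zero-drop (rather than Pratt's method) is the classic treatment
and appropriate here because continuous dose metrics make exact zeros
measure-zero events. Quartiles use linear interpolation between order
statistics (the common "type 7" convention).

## Cohort study conditions

The default cohort is 10 phantoms with per-patient seeds
`base_seed + index`, imposed functional fractions spanning 0.2–0.85 and
tumour radii 8–20 mm, planned on a 64 × 64 × 24 grid at 2.2 × 2.2 × 8 mm
(the in-plane-downsampled acquisition grid). These sizes keep a full
cohort run to a few minutes on one CPU while leaving every contract
non-trivial (hundreds of beamlets, ~10⁵ voxels). Acceptance-level tests
assert, per patient: the zero-weight sparing plan is bit-identical to the
standard plan; the sparing plan strictly lowers the FLV mean dose with
D95 at or above tolerance; the ordering and the exact cohort p-value
survive the matched-coverage rescale.

## What passing tests do and do not show

The phantoms establish that the *machinery* is correct: segmentation
matches a dense brute-force oracle voxel-for-voxel, the dose engine is
exactly linear with exact radiological depths, the optimizer is monotone
and deterministic, and the statistics are exact by enumeration. They do
not establish clinical effect sizes: real cT1 maps have anatomy-linked
heterogeneity, real beam models include scatter, divergence and
Monte-Carlo noise, and real livers deform and move. Motion management,
MR acquisition physics, deformable registration and clinical tolerance
tables are out of scope; the departmental criteria used here are
configurable stand-ins.
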