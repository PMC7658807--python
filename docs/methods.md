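# Methods

This note documents the models and procedures implemented in
`rhizoquant`, the assumptions behind them, the parameters that matter,
what the synthetic-data generators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Actin dynamics (`dynamics`)

For a time-lapse stack F₁…F_T of one cell, the per-frame correlation is
the mean over all j ≠ i of the Pearson correlation between frames i and
j over the selected pixels, and the per-frame difference is the mean
over j ≠ i of the mean per-pixel absolute difference |Fᵢ − Fⱼ|.  Stack
summaries are unweighted means over frames.  All-pairs averaging (every
j ≠ i, not consecutive pairs) is the headline statistic; a
correlation-versus-lag decay curve is available as a companion output
(`correlation_by_lag`) for presentations that prefer an interval-resolved
view.

Choices and conventions:

- The difference is the mean **absolute** difference per pixel.  A
  signed mean would cancel symmetric intensity fluctuations and could
  not separate a stabilized network from a remodeling one.  A squared
  variant sits behind the `squared` flag.
- Pearson correlation is invariant under positive affine intensity
  transforms, so no intensity normalization precedes it.  For the
  difference, frames are used raw by default; a per-frame
  mean-normalization flag exists and the chosen mode is recorded in the
  result (`difference_mode`), because the two modes are not comparable
  across instruments.
- A constant frame under the mask makes the correlation undefined; this
  raises `ZeroVarianceError` naming the frame index rather than
  silently emitting 0.
- The cell mask defaults to the whole frame.  Whether background
  (non-cell) pixels are excluded is an acquisition decision; both modes
  are supported and the mask source is recorded in the run manifest.
- Per-cell results are the replicate unit; aggregation across cells
  happens in `reporting`, never here.

## Actin architecture (`architecture`)

Each z-slice is globally thresholded (Otsu by default; any fixed value
can be given and is recorded), objects below `min_object_px` (default
10 px, a speckle suppressor) are removed, the binary is thinned to a
unit-width skeleton, and slice skeletons are combined by union
projection, then re-thinned.  The projected intensity image is the
per-pixel maximum across slices.

- Bundling is the biased Fisher–Pearson skewness g₁ = m₃/m₂^{3/2} of
  projected intensity at skeleton pixels.  Skeleton pixel counts are in
  the thousands, so the small-sample correction (G₁) would change
  nothing measurable; the moment form is used and documented.
- Zero intensity variance on the skeleton is defined as skewness 0 (a
  perfectly uniform network is unbundled); fewer than 3 skeleton pixels
  is an error.
- Occupancy = skeleton pixels inside the cell mask / mask pixels,
  always in [0, 1].
- Skeletonize-then-project is the default order; project-then-skeletonize
  is available behind a flag for sensitivity checks.
- An empty foreground yields a valid empty-skeleton result with a logged
  warning, not an error: blank fields are data.

## FRAP (`frap`)

Traces are normalized by the mean of the pre-bleach scans (pre-bleach
level ≡ 1) and time is re-zeroed to the first post-bleach point.  When a
reference trace from an unbleached region is supplied, acquisition
bleaching is corrected first by pointwise division by the reference
scaled to its own pre-bleach mean.

Recovery is fitted with the single-component model
F(t) = F₀ + A·(1 − e^{−kt}), giving mobile fraction Mf = A/(1 − F₀),
halftime t_half = ln 2/k, and R² over post-bleach points.  One
exponential is the minimal model consistent with summarizing recovery by
a single mobile fraction and halftime; diffusion-profile models
(Soumpasis/Axelrod) and two-component fits are out of scope.

Numerical choices:

- Bounded least squares with k ∈ (0, 10] per time unit and
  A ∈ [0, 1.5]; k is initialized from the time the trace first reaches
  half its observed span, A from the span itself.
- F₀ is fixed to the first post-bleach sample by default — more stable
  at sparse (1-point-per-minute) sampling — with co-fitting behind
  `fix_f0=False`.
- A trace with no observable recovery returns the immobile limit
  (Mf = 0, infinite halftime) with `converged=True`; optimizer failure
  returns `converged=False` with diagnostics, never an exception.
- When the fitted halftime exceeds half the observation window (slow,
  incompletely recovered cells), Mf is still reported from the fitted
  asymptote and the fit carries a wide-confidence-interval warning.

## BFA-body quantification (`compartments`)

Threshold (Otsu default, fixed values recorded), 8-connected component
labeling (4-connectivity behind a flag), components below `min_area`
(default 4 px) discarded, labels renumbered from 1.  Area and mean
intensity are measured per particle, the mean always on the original
image — never on the binary.  Per-cell summaries (mean body area and
intensity) are computed downstream in `reporting`, keeping this module
purely geometric.

## SNP-index mapping (`snp_index`)

- Read QC: a read is discarded iff the fraction of bases with quality
  below Q30 strictly exceeds 10%; a read at exactly 10% is kept.  The
  decision depends only on the multiset of quality scores.  Phred+33 is
  assumed; qualities above 60 are rejected as probable Phred+64 rather
  than guessed.
- Substituted reference: known wild-type SNPs are written into the
  public reference so that, after aligning mutant reads, only
  mutant-specific variants reach SNP-index ≈ 1.  Strict mode errors on
  any reference-base mismatch; lenient mode skips with a warning, which
  makes re-application idempotent.  Lengths are always preserved and
  coordinates are 1-based (VCF convention).
- SNP-index = alt/(ref+alt).  Zero-depth sites are reported as
  undefined (NaN), never coerced to 0, so site totals reconcile.
- Homozygous candidates: depth > 5 AND SNP-index > 0.9, both strict,
  mirroring the mapping pipeline's extraction rule; output sorted by
  (chromosome, position).
- Alignment (BWA), alignment filtering and effect annotation are out of
  scope: counts enter as a VCF with AD fields (biallelic records only;
  multiallelic rows are skipped with a warning) or a 4-column table.

## Expression and statistics (`reporting`)

Relative expression is 2^−ΔCp with ΔCp = Cp_target − Cp_reference;
shift-invariant in Cp and halving per extra target cycle.  Group
comparisons are exactly the tests figure legends name: two-tailed
Student's t for two groups, one-way ANOVA + Tukey HSD, or two-way ANOVA
with interaction + Tukey HSD on factor-combination cells.  An
unbalanced two-way layout is an explicit error rather than a silent
fallback to a different sum-of-squares decomposition.  No
multiple-testing machinery beyond Tukey is applied.  Error bars:
downstream consumers receive per-replicate values, so either SD or SEM
can be drawn; the tests themselves operate on replicates.

## Synthetic data (`synthgen`)

All generators are pure functions of their parameter objects, seed
included; identical parameters give bitwise-identical output.

**Filament time-lapse.**  Filaments are line segments rasterized with
anti-aliasing and blurred with σ = width/2 to mimic optics (sub-pixel
sensitivity for the correlation metric comes from the blur).  The
acquisition default is the emulated protocol: 25 frames at 2.5 s
(60 s course).  Design features, chosen once as a realistic emulation of
a cortical actin array in an elongating root cell:

- *Remodeling* is whole-filament replacement: each filament is
  independently replaced by a fresh random filament with probability p
  per frame.  p = 0 is the actin-stabilized (MBS-like) frozen control —
  the drug's concentration/duration is not modeled, only its effect.
  One rate parameter is all the monotonicity contrasts need.
- *Geometry*: orientations are near-axial (±0.35 rad), as cortical
  arrays in elongating cells are, and initial anchor rows are
  stratified so the array starts evenly spaced.  Both choices keep
  chance collinear overlaps of independent filaments rare; such
  overlaps otherwise masquerade as bundles.
- *Brightness*: per-filament amplitudes are lognormal with CV 0.3,
  emulating variable labeling and focal depth.  Without this, skeleton
  intensities of an unbundled network are nearly degenerate and the
  skewness statistic saturates on rasterization artifacts.
- *Bundling*: a `bundled_fraction` (default 0.3) of filaments share
  paths in groups of `bundling_factor`, so bundled pixels carry ~b-fold
  intensity while the rest run single.  A network with *every* filament
  bundled would merely rescale the intensity distribution, which the
  scale-invariant skewness cannot see; the mixture is what carries the
  signal, as it does in real cells.
- *Field sizes*: the 128-px default frame emulates a time-lapse crop of
  one cell; `whole_cell_params()` (384 px, 135 filaments, same areal
  density) emulates a projected whole-cell image and is the appropriate
  substrate for architecture metrics, which are distribution statistics
  and need on the order of a hundred filaments (a dozen bundles) for
  stable estimates.
- Noise is additive Gaussian (σ = 2 intensity units on ~100-unit
  filaments by default): the simplest model with closed-form
  expectations; Poisson statistics, PSF anisotropy and photobleaching
  are not modeled.

**FRAP traces** follow the closed-form single-exponential recovery with
pre-bleach scans at the pre-bleach level, optional per-frame
acquisition-bleaching attenuation, and additive Gaussian noise.  The
default acquisition matches the emulated protocol: 3 pre-bleach scans,
then 1 frame/min over 40 min.

**BFA-body fields** are non-overlapping uniform disks (≥ 2 px apart, so
bodies stay distinct under 8-connectivity) on a uniform background,
placed by bounded rejection sampling (error if the packing is
infeasible).  The truth table lists each disk's exact rasterized pixel
area and noiseless mean intensity.  Real BFA bodies are neither disk
shaped nor uniform; this generator tests the measurement chain, not the
biology of body formation.

**Allele-count tables** draw per-site depth from a negative binomial
(mean 30, dispersion 10 by default — over-dispersed, as shotgun coverage
is) and alt counts from a binomial at 1 − e, 0.5, or e for truth
homozygous / heterozygous / absent sites (e = sequencing error rate,
default 0.01).  Read-level artifacts (mapping bias, indel spill-over)
are not simulated; counts are taken as the aligner would deliver them.

What passing tests on these generators shows: the measurement chain —
metric definitions, thresholds, fits, filters — is correct on data whose
truth is known, under noise models chosen for analytic tractability.
What it does not show: robustness to optics, drift, uneven
illumination, segmentation failure on real tissue, or aligner behavior.

## Problem sizes in tests and the acceptance script

Ensemble checks use 20 replicate 128×128×25 stacks per remodeling rate
(rates 0/0.1/0.3/0.6), 20 seed-paired whole-cell fields for bundling, a
3×3 FRAP grid (Mf ∈ {0.3, 0.6, 0.9} × t_half ∈ {2, 5, 15} min) with 50
noisy replicates per cell at σ = 0.02 of the pre-bleach level, 12-body
particle fields, and 10,000-site variant panels.  These sizes give
Monte-Carlo error comfortably below the effect sizes being asserted
while keeping a full run in the tens of seconds.

## Known limitations

- The filament simulator renders segment endpoints at integer pixels;
  sub-pixel motion enters only through the optical blur.
- Whole-filament replacement is a caricature of treadmilling and
  severing; it produces the right correlation-decay ordering but not
  realistic kymographs.
- The FRAP module fits one exponential; genuinely two-phase recoveries
  will show reduced R² rather than a second component.
- `bundling_skewness` compares networks only when acquisition settings
  match; it is affine-invariant but not invariant to gamma or clipping.
- Two-way ANOVA requires balanced designs by construction; unbalanced
  data must be analyzed with an explicitly chosen decomposition
  elsewhere.
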