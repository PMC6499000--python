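# Methods

`spheroquant` re-implements, as a tested pipeline, the quantitative analysis
stack of a pancreatic heterocellular-spheroid photodynamic-therapy (PDT) /
radiation-therapy (RT) combination study: bright-field segmentation with
core/halo separation, viability and necrosis readouts, optical redox ratio
(ORR) imaging, combination-additivity analysis, western-blot densitometry and
DNA-content (cell-cycle) profiling.  Because no real microscopy, blot or flow
data are distributed with it, every stage is validated end-to-end against a
seeded synthetic-data generator that carries exact ground truth.

## Spheroid segmentation (`segment`)

A bright-field frame is binarized by an adaptive local-mean threshold: pixel
`I(x)` is foreground iff it deviates from the mean over a square window by
more than `s * (local max - local min)` in the direction of the contrast
polarity (dark spheroid on a light field by default).  The procedure runs
twice:

* **core pass** (stringent, `s_core = 0.35`): binarize, remove objects below
  `min_object_px` (25 px), close with a 4 px disk, fill holes, keep the
  largest connected component (ties broken by centroid proximity to the frame
  centre — one spheroid per U-bottom well);
* **total pass** (permissive, `s_total = 0.15`): binarize, remove small
  objects, keep components whose centroid lies within
  `halo_search_factor = 2.5` core-equivalent radii of the core centroid, and
  union them with the core.

Areas are pixel counts times `pixel_size_um**2`.  A frame in which no
component survives the core pass yields an explicit no-spheroid outcome
(empty masks, zero areas), not an exception.

Numerical and design choices:

* **Window size** defaults to 1/8 of the image width, made odd (65 px at
  512 px).  The window must exceed the halo-cell scale (~16 um) and stay
  below the smallest spheroid diameter (~200 um), and it must be local
  enough that a faint cell 30-60 um off the rim of a large dark core is
  judged against mostly-background statistics.  Quarter-width windows fail
  that last requirement: the core drags the local mean down and faint halo
  cells never clear the offset at any sensitivity.
* **Closing before hole filling** (radius 4 px, configurable): a crowded halo
  locally depresses the rim contrast and can nick the detected boundary
  ring; an unnicked ring is required for the hole fill that recovers the
  optically flat core interior.  Speckle is removed *before* closing so
  noise cannot be welded into pseudo-objects.
* **Threshold epsilon**: the foreground test adds `1e-9 * max|I|` to the
  offset so filter round-off on locally constant regions (zero dynamic
  range) cannot mark pixels foreground.  A constant image maps to an empty
  mask exactly.
* The local statistic (mean over a reflective-border window) is the common
  reading of "adaptive thresholding"; both sensitivities, the window and the
  association radius are exposed in `SegmentationParams` so alternative
  calibrations can be swapped in.

## Per-spheroid readouts and statistics (`quantify`)

The necrosis readout is the propidium-iodide (PI) channel averaged over the
total spheroid mask after subtracting a background level estimated as the
median intensity outside the mask (clamped at zero per pixel); calcein is
quantified identically and reported separately.  Spheroid areas are
normalized to the mean area of the untreated controls of the same model and
day, so the control group has mean normalized area 1 by construction.
Growth curves are fit with the three-parameter logistic
`A(t) = K / (1 + exp(-r (t - t0)))` by least squares
(`scipy.optimize.curve_fit`); constant curves are flagged degenerate with
`K` at the plateau.

Group comparisons follow the study's stated recipe: a d'Agostino-Pearson
normality check per group (reported, not gating; it needs n >= 8), then
Student's t-test for two groups or one-way ANOVA with Bonferroni-adjusted
pairwise post-hoc t-tests for more.  The Bonferroni family is all pairwise
comparisons within one panel (one model, one day, one readout):
`p_adj = min(1, m * p_raw)`, `m = k(k-1)/2`.  Groups with fewer than two
values are excluded with a warning.

## Optical redox ratio (`redox`)

Per pixel, `ORR = FAD / (FAD + NADH)`, defined only where the summed signal
exceeds a noise floor (default: 3x the standard deviation of the summed
signal outside the spheroid mask — division at dark pixels is numerically
meaningless).  Defined values are clipped to [0, 1]; the per-spheroid ORR is
the mean over defined pixels inside the mask, and an all-undefined mask is an
explicit no-signal outcome.  Channel registration is assumed (same
acquisition).  ORR-necrosis coupling is reported per model as Pearson (with
confidence interval) and Spearman coefficients; groups with fewer than three
complete records or zero variance are flagged instead of reported.

## Combination additivity (`combination`)

Each treatment group is summarized by mean +/- SEM in the plane spanned by
normalized area (x) and background-subtracted mean PI (y).  The additive
prediction for a combination is the control point plus the vector sum of the
two single-agent displacements; its uncertainty is the root-sum-square of the
three group SEMs (the control mean enters twice with opposite signs but is
one estimate, so its SEM is counted once).  The observed combination is
classified per axis by comparing it to the prediction within
`z_{1-alpha/2} * sqrt(sigma_pred^2 + SEM_obs^2)` (alpha = 0.05): beyond the
band in the benefit direction (more necrosis; more shrinkage) is
super-additive, beyond it the other way sub-additive, inside it additive.

The source analysis draws the geometric sum as an arrow without a formal
synergy statistic; this confidence-band rule is this package's explicit
construction and its output is labelled as such.  A seeded percentile
bootstrap over spheroids (2000 draws) is available for small or non-normal
groups.  No Bliss/Loewe/Chou-Talalay indices are computed — the construction
is a mean-shift geometric sum, not an isobologram.

## Densitometry (`densitometry`)

Bands are quantified on 8-bit grayscale gels (16-bit input is linearly
rescaled first) with user-supplied fixed-size rectangular ROIs: the
background ROI has the same size and sits directly above the band (falling
back to below when above leaves the image).  The signal is
`(255 - band mean) - (255 - background mean)`, clamped at zero (a band
lighter than its background is not addressed by the source procedure and is
treated as absent).  Expression is normalized lane-wise to the loading
control and across lanes to the no-treatment condition, so the reference lane
is 1.0 for every protein; lanes with zero loading-control signal are flagged
with expression undefined.  Automatic lane/band detection is out of scope —
ROIs mirror the manual ImageJ-style workflow.

## Cell-cycle profiling (`cellcycle`)

Single-parameter DNA-content event lists are decomposed into sub-G1
(apoptotic), G1, S and G2/M fractions by a Dean-Jett-Fox-flavoured
procedure (the acquisition software's algorithm is unnamed in the source, so
this is an explicit stand-in):

1. events below 1% of the G1 mean are discarded as debris;
2. the G1 peak is the mode of a Gaussian-KDE-smoothed histogram, with a
   guard that reassigns to a half-position peak when the highest peak is the
   4N peak of a G2-rich sample;
3. sigma_G1 is a scaled MAD over events within +/-15% of the peak, after
   which the peak is refined as the mean of events within 2 sigma (two
   passes);
4. sub-G1 is gated as events below `g1_mean - k * sigma_G1` (k = 3);
5. the remaining events get an EM fit over Gaussian G1, Gaussian G2/M (mean
   free within 5% of twice the G1 mean, width tied to the G1 coefficient of
   variation) and an S-phase slab (uniform between the peaks convolved with
   a Gaussian of width sigma_G1); component shapes are otherwise fixed, only
   weights and the tied G2/M mean update.

Fractions always form a probability vector.  The gate and fit are
scale-equivariant, so rescaling the DNA-content channel leaves fractions
unchanged.  Zero-variance input is handled as a pure G1 population; an
undetectable G1 peak yields an explicit unfittable outcome.  Doublet
discrimination is out of scope (no scatter or pulse-width channels in the
data model) and is noted in the profile metadata.

## Synthetic-data generator (`phantoms`)

Every generator is a pure function of its spec including the seed
(bit-identical reruns; one `numpy.random.Generator` per call, no global
state).

* **Spheroid phantom**: a disk of depressed intensity (core level 60 on
  background 200, nominal 8-bit scale) at 2 um/px on a 512x512 frame — the
  acquisition geometry of the emulated study — with optional halo cells:
  Gaussian attenuation bumps (FWHM radius 8 um, peak attenuation 60)
  scattered uniformly by area in an annulus from the core rim to a fixed
  120 um migration band (capped by the frame).  Halo attenuation is ~0.43x
  the core contrast because loose single cells are far less optically thick
  than the dense core — which is exactly why the segmentation needs a second,
  permissive pass.  The truth halo mask is the FWHM support of the noiseless
  bump field.  The PI channel is `background + necrotic_fraction * 150`
  inside the spheroid (linear link, the simplest testable model for a mean
  intensity readout); calcein is its live-cell complement.  Additive
  Gaussian noise (sd 2 by default) is clipped to [0, 255].
* **Redox pair**: `FAD = scale * orr_field`, `NADH = scale - FAD`, plus
  optional noise.  The subtraction form makes the noiseless per-pixel ratio
  invert bit-exactly, which the oracle-equivalence tests rely on.
* **DNA events**: sub-G1 is a truncated exponential rising toward
  `g1_mean - 3 sigma_G1` with lower support at 10% of the G1 mean (heavily
  degraded DNA is rarer than mildly degraded DNA, and the distribution stays
  strictly below the 3-sigma gate and above the debris floor); G1 and G2/M
  are normal with a common coefficient of variation (default 5%, G2/M mean
  at twice G1); S is uniform between the peaks.  Labels are retained as
  ground truth.
* **Gel phantom**: rectangular bands (18x36 px) at `background - signal` on a
  uniform background, truth signals and ROI annotations returned alongside.

### The fixture study

`pipeline.generate_fixtures` builds a miniature three-model, three-day
(days 3, 5, 12), seven-group study — control, 2.5 J/cm2 PDT, 2/10/20 Gy RT,
and PDT + 10/20 Gy combinations, four replicates per group on 256x256 px
frames at 4 um/px (a deliberately compact rendering of the same geometry).
The designed response surface encodes the qualitative pattern of the
emulated study: RT stunts growth dose- and time-dependently (down to ~20-25%
of control area for 20 Gy at day 12 in the most responsive model), PDT
drives necrosis with little effect on size, the combination shrinks size at
0.8x the additive deficit (slightly sub-additive) and boosts necrosis by a
designed synergy term (super-additive), and only the glycolytic model couples
its ORR linearly to the necrotic fraction.  DNA fixtures use sub-G1 truths of
24.0 / 31.4 / 30.9 / 40.2% for control / PDT / 10 Gy / combination.
Replicate jitter: 4% sd on radius, 2 points sd on necrotic fraction.

What passing on these fixtures does **not** show: the phantoms have ideal
contrast polarity, a single spheroid per frame, perfectly registered
channels, linear staining, no illumination gradients, no debris or doublets,
and an ORR-necrosis coupling that is exact by construction (the near-unity
correlation recovered for the glycolytic model is a property of the design,
not a performance claim).  Real-data use requires recalibrating the two
sensitivities, the window and the noise floors.

## Pipeline determinism

`run_pipeline` executes segment -> quantify -> redox -> combination, with
densitometry and cell-cycle profiling as independent branches; failures are
recorded per entry without aborting the rest.  Outputs (per-spheroid CSV,
JSON reports, run log with a SHA-256 config hash and the seed) contain no
timestamps, so a rerun with the same manifest and seed is byte-identical.

## Problem sizes used in the shipped validation

Segmentation sweep: 50 phantoms (10 radii in 100-400 um x halo counts
0-300).  Additivity calibration: 500 seeds x 4 groups x 20 spheroids,
summary-level simulation.  Statistics calibration: 10,000 null ANOVA panels
(3 groups, n = 8).  Cell-cycle: 5000 events per sample, 100-seed recovery
sweep spanning sub-G1 0.20-0.45.  Fixture study: 252 image entries, 3 gel
phantoms, 12 DNA samples.

## Known limitations

* The halo-area estimate counts detected halo pixels, not cells; faint cells
  within ~40 um of the rim of a large core remain undetectable by a
  mean-window threshold, so halo areas are lower bounds there.
* The additivity rule assumes approximately normal group means; use the
  bootstrap flag for n < ~10.
* S-phase fractions are the least identifiable part of the DNA mixture
  (errors up to ~3 points on single samples, < 2 points on average).
* FCS binary parsing is out of scope; DNA events are read from single-column
  CSV (`dna_content`), with conversion left to upstream tooling.
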