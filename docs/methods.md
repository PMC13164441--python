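# Methods

## The measurement model

On non-contrast CT (NCCT), acute ischemic edema lowers brain attenuation by
only a few Hounsfield units in the first hours, which is why hyperacute
lesions are hard to call by eye. The package quantifies a lesion ROI not by
its mean HU alone but by the *shape* of its HU distribution, through four
first-order metrics computed per ROI per scan:

* **SD** (HU): sample standard deviation of the raw pixel values, with the
  n−1 denominator. Dispersion = tissue heterogeneity.
* **Skewness**: adjusted Fisher–Pearson G1 (bias-corrected).
* **Excess kurtosis**: bias-corrected G2, so a Gaussian sample → 0.
* **Entropy** (bits): plug-in Shannon entropy −Σ pᵢ log₂ pᵢ of the binned
  histogram. Structural disorganization of the tissue.

The binning contract is 100 half-open bins of exactly 1 HU over the brain
window −40..60 HU (the final bin is closed, so integer HU values are never
double counted). Out-of-range pixels — streak or bone contamination at an
ROI edge — are clipped into the edge bins by default; a drop policy and a
per-sample dynamic range mode exist but are off by default because the
standardized window is what makes entropies comparable across scans.

Two choices here are inferences, recorded in every `MetricSet.metadata`:

* **Log base 2.** The published group entropies (4.34 cortical, 3.99 basal
  ganglia) sit just below the Gaussian values 0.5·log₂(2πeσ²) at the
  published SDs (4.41 and 4.03 bits); natural-log entropies would be ~0.7×
  smaller. Base 2 is the only base numerically consistent with the
  reported pairs.
* **Plug-in estimator.** No small-sample correction by default; the
  Miller–Madow correction is available as an option. At the ≥1 cm² ROI
  floor (≳500 pixels) the plug-in bias is ≲0.05 bits, and at the 10⁵-pixel
  ROIs used for recovery runs it is ≲0.001 bits.

Moment metrics are computed on raw values, entropy on the histogram;
population-moment variants are switchable by argument.

## ROIs and mirrored controls

ROIs are planar boolean masks congruent with an axial HU array, with a
minimum area of 1 cm² (boundary inclusive; at 0.45 mm pixels that is 494
pixels). The within-subject control is the lesion mask reflected
column-wise about the sagittal midline (col′ = round(2·mid − col)); the
reflection preserves pixel count and is an involution for an integer
midline. The midline can be supplied or estimated by minimizing the mean
squared HU difference between the left half and the mirrored right half
over candidate columns in the central third of the image. Registration of
the diffusion-defined infarct core into CT space is out of scope: masks are
assumed to be in CT pixel coordinates already.

## Temporal analysis

Each subject is a time-sorted sequence of (lesion, control) metric pairs
over minutes post-onset.

* **Crossover**: the first time the lesion−control mean-HU gap changes from
  negative to ≥0, linearly interpolated between the bracketing scans; an
  exact zero at a scan time counts at that scan. A lesion that is never
  hypodense is not a crossover. The estimator is defined on mean HU, not on
  the shape metrics.
* **Peak diagnostic window**: windows [t, t+width) slide over the pooled
  time span (defaults: width 12 min, step 1 min). Per window each subject
  contributes the mean of each lesion metric over its in-window scans;
  cortical vs basal-ganglia separation is tested per metric with a pooled
  t, and the window score is the worse of the SD and entropy p-values.
  Windows with fewer than 2 contributing subjects per group are skipped;
  the top-ranked (lowest-score) window is the peak. Because subjects with
  no in-window scan are excluded rather than imputed, neighbouring windows
  can rank above the all-subject window when dropping a borderline subject
  sharpens the contrast; this adds a few hundredths of a bit of spread to
  the "entropy at peak" readout across seeds.
* **Anchored deltas / repeated measures**: scans are matched to anchor
  times by nearest scan within ±15 min (configurable); unmatched subjects
  are excluded with a logged warning for deltas, and make the design
  unbalanced (an error naming the subjects) for the repeated-measures
  ANOVA, which assumes sphericity and applies no Greenhouse–Geisser
  correction.

## Statistics

Pooled-variance (Student) t is the default flavor: from the published
baseline SD summaries (27, 5.16, 1.17) vs (18, 3.94, 0.46) it gives
t = 4.20, consistent with the published 4.171 up to rounding of the
summaries, whereas Welch gives 4.88 — so pooled is what the source analysis
used (Welch remains available). The one-way ANOVA accepts raw vectors or
(n, mean, SD) summaries and satisfies F = t² exactly for two groups.
Cohen's d uses the (n−1)-weighted pooled SD. Bonferroni correction uses
family size m = 4 (the four metrics at one contrast) by default. Bootstrap
CIs are percentile, default 2000 resamples, seed mandatory. The
repeated-measures ANOVA is the standard one-way within-subject (subjects
as blocks) decomposition.

## The synthetic cohort generator

The generator defines the study conditions: 27 cortical and 18
basal-ganglia subjects, on average 5.2 scans each on a jittered anchor grid
{0, 60, 81.5, 94, 120, 180} min (baseline, the 76–87-min peak window and
the 120-min scan are always present; the rest are kept with probability
chosen to hit the 5.2 average, minimum 3 scans), and 10⁵ pixels per ROI by
default (chosen for estimator stability; a few-hundred-pixel "realistic"
mode is a config away).

**Pixel model.** Each ROI is drawn from a probability mass function over
the 100 histogram bins, a symmetric four-component Gaussian mixture:
locations μ±δ crossed with two component widths. At fixed variance the
location split δ lowers entropy (toward bimodality) and the width contrast
raises kurtosis (scale mixing). Calibration is by nested 1-D root finds on
the *discretized* pmf: the inner solve pins the pmf SD exactly (unit
binning inflates a continuous σ by ≈1/12 HU², so solving on the pmf rather
than the continuous parameters keeps achieved SD within 1e-4 of target);
the outer solve drives the pmf entropy to its target; the kurtosis target
enters through the closed-form width contrast and is honoured when the
entropy deficit leaves room, otherwise clipped to the family's feasible
band (flagged in the returned parameters). Sampling maps drawn bin indices
to uniform jitter within each 1-HU bin, so re-binning a sample reproduces
its pmf draws exactly; the jitter adds 1/12 HU² to the sample variance
(≈+0.008 HU at SD 5.16), visible in the recovery numbers.

**Subject structure.** Subject-level SD/entropy targets are the group
target plus between-subject spread (±1.17/±0.46 SD, ±0.30/±0.15 entropy),
realized as stratified normal scores with exact sample mean and SD,
comonotone between SD and entropy, shuffled by seed — so the group
mean ± SD columns are reproduced by construction and cohort-mean recovery
is meaningful at n = 27/18 (an i.i.d. mode exists and is used for null
simulations). Kurtosis targets are drawn per subject from one distribution
common to both regions (N(0.08, 0.30), clipped to feasibility): kurtosis
and skewness are deliberately *null* dimensions, as in the source
comparison, where neither metric separated the groups. A per-subject mean-
HU offset (SD 2 HU) applied equally to lesion and control mimics
between-subject attenuation differences. Temporal evolution rescales the
anchor trajectories to the subject's baseline targets (multiplicatively
for SD, additively for entropy), interpolating linearly between anchors
and extrapolating flat beyond 180 min.

**Feasibility bound and a template inconsistency.** The Gaussian maximizes
entropy at fixed variance, so a joint (SD, entropy) target must satisfy
entropy ≤ 0.5·log₂(2πe·SD²) (up to discretization). The generator clips
every per-scan entropy target to this bound (logged). The baseline group
targets respect the bound (4.34 vs 4.41; 3.99 vs 4.03), but the cortical
*temporal* anchor pairs at 60–120 min do not: at the peak, entropy 4.52 at
SD 5.38 exceeds the bound of 4.47 bits. No pixel distribution can realize
those group means under this binning, so clipping is systematic at the
cortical peak and the recovered in-window cortical entropy lands at
≈4.43–4.47 bits — the information-theoretically feasible optimum — rather
than 4.52. This is a property of the printed anchor pairs, not of the
calibrator: SD recovery is unaffected, and the baseline recoveries are
within ±0.02.

**Crossovers.** Exactly round(27/3) = 9 cortical subjects are planted with
a crossover: the control mean-HU path declines linearly to the 27.89-HU
crossover level by 94 min, while the lesion path rises from baseline to
meet it at t_c ~ U(90, 98) and overtakes it by 1 HU over the next 30 min,
so the post-crossing margin at the guaranteed 120-min scan is ≥0.5 HU even
at small pixel counts. Basal-ganglia subjects keep a constant −3.12 HU gap
and never cross.

**Phantoms.** Optionally each scan is rasterized into a 128×128 symmetric
head phantom (bright skull annulus, homogeneous brain, lesion blob of the
exact ROI pixel count, control blob mirrored about the geometric midline)
— the simplest geometry satisfying the area and mirroring contracts, not
an anatomical simulation.

**What the generator does not emulate:** CT physics (beam hardening,
partial-volume, correlated texture), anatomical geometry, the between-
subject spread of skewness/kurtosis printed for the real cohort (the
symmetric family pins skewness near 0 with only sampling spread), DWI, and
any post-180-min decline beyond flat extrapolation. Passing recovery tests
therefore demonstrates that the pipeline measures what the generator
encodes — binned-intensity statistics and mean-HU trajectories — not that
it would segment or register real scans.

## Numerical notes

* Root finds use Brent's method; achieved SD and entropy are re-evaluated
  on the final pmf and must be within 1e-4 of target or calibration raises.
* Degenerate inputs error loudly: empty ROIs, zero-variance samples for
  skewness/kurtosis, zero baselines, single-scan crossover queries,
  unbalanced repeated-measures designs.
* All randomness flows from a single integer seed through spawned
  per-subject streams; cohort generation, bootstrap CIs and the report
  bundle are bit-reproducible for a fixed config.
* Problem sizes used by the shipped checks: recovery runs use the full
  27/18 × 10⁵-pixel condition; pipeline smoke and null-error simulations
  keep the subject counts and reduce pixels per ROI (256–4000), which
  leaves group-level inference essentially unchanged because pixel-level
  noise is a small fraction of between-subject spread.

## Known limitations

* The peak-window search operationalizes "strongest separation" as the
  worst-case p-value over SD and entropy; other reasonable scores (product
  of p-values, effect sizes) would rank near-tied windows differently.
* The crossover estimator interpolates linearly between scans ~26–30 min
  apart near the crossing, so detected times inherit that granularity.
* Bootstrap CIs are percentile (no BCa); repeated-measures ANOVA assumes
  sphericity.
* Multi-slice ROIs are handled as pooled per-slice samples by the caller;
  whether pooling matches the original single-slice reading is unknown.
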