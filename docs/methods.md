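# Methods

`seqrsa` re-implements, as a reusable pipeline, the analysis of how learned
temporal structure reshapes multi-voxel event representations: changes in
pattern similarity from a pre-learning to a post-learning scan are modeled
as a function of three competing time metrics, with two-level permutation
statistics, mixed-model comparisons, representational geometry via
non-metric MDS, and a searchlight engine with small-volume TFCE
correction. Everything is exercised end to end on synthetic data whose
statistical structure matches the experimental conditions the analyses assume.

## The task model

Participants learn four sequences ("virtual days") of five unique events.
Each event has a time on a hidden virtual clock; the clock's speed differs
between sequences, partially dissociating three metrics of temporal
structure between any two events:

- **virtual time** — absolute difference of the events' times on the hidden
  clock (virtual hours),
- **order** — absolute difference of sequence positions,
- **real time** — absolute difference in elapsed seconds since the first
  event of the respective sequence.

The 190 unordered event pairs split into 40 same-sequence and 150
different-sequence pairs. The central dependent measure is
**pattern-similarity change**: mean Fisher-z-transformed Pearson
correlation between multi-voxel patterns of two events across all ordered
pairs of different mini-blocks (90 correlations at 10 blocks;
same-mini-block comparisons are excluded), computed per scanning phase,
post minus pre.

## Statistical engines

**Subject level.** Similarity change (or a behavioral outcome) is
regressed on z-scored predictors by OLS; the focal coefficient's t-value
is referred to a null distribution from shuffling the outcome vector
(default 10,000 shuffles, one shared permutation per iteration for all
coefficients). The right-tail p with add-one correction,
p_r = (1 + #{t_null ≥ t_obs}) / (1 + n_perm), maps to
Z = Φ⁻¹(1 − p_r). Z is sign-preserving and capped at the resolution of
the permutation scheme (p clipped to [1/(n+1), n/(n+1)]), so perfect
positive and perfect negative effects produce symmetric finite Z.
Predictors are z-scored within the pair subset the model is actually fit
on (same-sequence rows, different-sequence rows, or all rows).

**Group level.** Per-subject Z-values are tested against zero with a
one-sample t whose null comes from random sign-flips (default 10,000),
two-sided with add-one correction. Effect sizes are Cohen's d with the
Hedges small-sample correction J(df) = 1 − 3/(4·df − 1); confidence
intervals invert the noncentral-t distribution (asymptotic normal
approximation beyond |t| > 50, where the exact cdf underflows). For
paired contrasts d uses the pooled SD of the two conditions,
√((s₁² + s₂²)/2), and the CI from the difference-score t is rescaled into
that metric; the construction is documented here rather than claimed to
match any particular other implementation digit for digit.

**Permutation RM-ANOVA.** For the 2×2 within-subject region × membership
design every effect reduces to a per-subject contrast whose squared
paired-t equals the classical F; the permutation null relabels factor
levels within subjects, which for these contrasts is a sign-flip of the
contrast. Generalized η² is reported
(SS_effect / (SS_effect + all subject-involving SS)).

**Mixed models.** Fixed effects of interest (z-scored time metrics,
deviation-coded ±0.5 membership, explicit product columns for
interactions) are tested by likelihood-ratio tests between ML fits
(statsmodels MixedLM) of a full and a nested reduced model with identical
random-effects structure, χ² = 2ΔlogLik, df = 1. On convergence failure or
singular fit the random structure is simplified along a ladder
(default: intercept + focal slope, then focal slope only); every rung
retains the focal random slope. A converged boundary fit (random variance
≈ 0, which is the truth for simulated data whose subjects share one
design) is accepted and flagged in metadata; outright failure is flagged,
never silently replaced.

## Synthetic data

The generator is the package's test bed; its defaults are the
experiment-scale conditions: 28 subjects, 4 × 5 events with virtual times in [6, 24]
virtual hours, 10 mini-blocks per phase, 100-voxel ROIs.

- **Design.** Event times are uniform draws on the virtual day constrained
  to a minimum gap of 2.5 virtual hours; clock speeds alternate between
  0.55 and 0.45 virtual hours per real second. These two constants were
  calibrated so the pooled event-level correlations of virtual time with
  order and with real time land near 0.97 — realistic for monotonically increasing within-day
  time metrics under a moderate clock-speed manipulation — while keeping the metrics separable by
  multiple regression.
- **Patterns.** Similarity structure is planted in the expected
  correlation matrix of the post-phase event means:
  C = C₀ + baseline + a_within·zvd·[same] + b_across·zvd·[different], with
  zvd the virtual distance z-scored within each pair class, C₀ a constant
  baseline correlation (0.1), and defaults a_within = +0.04,
  b_across = −0.04 in correlation units. The matrix is projected to the
  nearest PSD correlation matrix (eigenvalue clipping, diagonal
  re-normalization — a fixed point on PSD inputs), event means are drawn
  with that correlation, and mini-block patterns add independent Gaussian
  noise (sd 1.0). Pre-phase patterns use the unstructured C₀. Measured
  similarity change is therefore the planted structure attenuated by the
  noise-to-signal ratio; with unit signal and unit noise the attenuation
  is ≈ 0.5. An entorhinal-style mode (`uniform_slope`) plants one negative
  slope for all pairs regardless of membership.
- **Behavior.** Remembered times are
  virtual_time + γ·d(e) + ε, ε ~ N(0, 1.0), where d(e) is the deviation of
  the mean time of same-position events in the other sequences; γ defaults
  to 0.5. Responses are clipped to the [6, 24] timeline. **Note:**
  truncation at the timeline bounds pulls boundary events' errors toward
  the interior — that is, toward the other-sequences mean — so clipped
  responses carry a small genuine generalization-like bias even at γ = 0
  (≈7% of responses clip at the default noise, inflating null rejections
  to ≈10%). This is a property of any bounded response scale, not an
  inference artifact; type-I calibration checks therefore disable
  clipping (`clip_responses=False`). Sorting starts correct; with
  probability 0.4 one same-position pair is exchanged between two
  sequences and with probability 0.2 one event moves to a random wrong
  group.
- **Volumes.** The searchlight fixture plants a graded cluster (radius 2,
  effect scaled by 1 − d/(r+1), strongest at the center so the group peak
  localizes there) of strong slopes (±0.3, voxel noise sd 0.35) inside a
  12³ volume whose brain mask is a margin-2 box; the a-priori small-volume
  mask is nested one voxel further in, so that its border voxels are not
  smoothing-boundary voxels (renormalized smoothing at a data edge
  otherwise inflates boundary values by asymmetrically weighting the
  signal side). Cluster effect sizes are deliberately strong: they are
  chosen for desk-scale power of the Monte-Carlo validation runs, not to
  mimic empirical effect magnitudes.

What the generator does **not** emulate: temporal autocorrelation of the
BOLD signal (the paradigm's identical pre/post stimulus orders remove it
from the contrast), motion or scanner physics, anatomical geometry,
spatially correlated noise, and inter-subject variability in the design
(all simulated subjects share one design). Passing tests therefore show
that the pipeline recovers what it assumes — planted linear
distance–similarity structure under independent noise — not that the
assumptions hold for any real dataset.

## Searchlight

Spheres of radius 3 voxels (123 lattice offsets) around every brain-mask
voxel are intersected with the gray-matter mask; spheres with ≤ 25 gray
voxels are discarded. Per sphere, similarity change is computed from the
sphere's voxels and three models are fit (same-sequence slope,
different-sequence slope, membership × virtual-time interaction with
deviation coding); each focal t is stored at the center. Maps are smoothed
(Gaussian, FWHM 3 mm, σ = FWHM/(2√(2 ln 2)) converted by voxel size,
NaN-aware with weight renormalization). Group inference: voxelwise
one-sample t across subjects, TFCE (H = 2, E = 0.5, dh = max/100,
26-connectivity — the common defaults for TFCE in neuroimaging
software), family-wise corrected p within the
small-volume mask from the max-TFCE null over random sign-flips, plus
voxelwise uncorrected permutation p. Enhancement is one-sided (positive);
negative contrasts are tested on negated maps. A follow-up ROI is the
26-connected suprathreshold component containing the peak voxel of the
uncorrected p map inside the small-volume mask (threshold exposed as an
option, default p < 0.01).

## MDS geometry

Fixed-effect-predicted similarities from the membership × virtual-time
mixed model are converted to distances by the max-minus-similarity rule
(linear, order-preserving, and deterministic). Non-metric MDS is SMACOF majorization with
isotonic disparity regression (scipy's PAVA), 1000 random starts by
default, per-start convergence when the stress-1 decrease falls below
1e-6 (300 iterations cap), keeping the lowest-stress configuration,
centered at the origin. Stress-1 = √(Σ(d̂ − d_emb)²/Σd_emb²). The stress
permutation test shuffles the 190 off-diagonal distances as a set,
re-embeds with a reduced 10 starts per iteration (tractability), and
reports z = (observed − null mean)/null
sd and the add-one proportion of null stresses at or below the observed.
Note that non-metric solutions identify distances only up to a monotone
transform: a zero-stress solution can compress distinct input distances
into numerical near-ties, so rank agreement between input and embedded
distances is checked with a tie tolerance.

## Numerical and convention choices

- Fisher z: r clipped to ±(1 − 1e-7) before atanh; identical patterns give
  a large finite z.
- Cross-block averaging uses the 90 ordered block pairs; including both
  directions makes the unordered mean identical, so the ordered/unordered
  reading is moot by construction.
- Median splits (descriptive only): "low" is at-or-below the median.
- Sorting accuracy maximizes group→sequence overlap via the Hungarian
  algorithm (equal to brute force over the 24 mappings); a swap error is a
  *mutual* same-position interchange, one-sided misplacements are plain
  errors. Surrogate sorting errors move uniformly chosen events to
  uniformly chosen wrong groups, matching each subject's error count.
- Separate same-/different-sequence tests use α = 0.025 in reporting;
  brain–behavior Spearman correlations likewise (two tests). The α
  bookkeeping lives in the reporting layer, not the statistics.
- No automatic outlier exclusion anywhere; an explicit subject-exclusion
  list in the run config is the only exclusion mechanism.

## Monte-Carlo problem sizes

Validation simulations are sized for a desktop CPU: type-I calibration of
the two-level pipeline uses 1000 simulated 28-subject experiments with
n_perm = 500 and n_flips = 1000; effect recovery uses 100 experiments;
generalization-bias recovery uses 100 (recovery) and 200 (null) datasets;
searchlight validation uses 100 planted and 30 null runs at the 12³
geometry with 10 subjects and 300 flips. `scripts/acceptance.py` re-runs
the same computations at moderately smaller run counts and records every
quantity with the problem size used.

## Known limitations

- The per-subject permutation shuffles similarity-change values across
  pairs, ignoring that pairs sharing an event are dependent; the group
  sign-flip level is exact regardless, and the type-I calibration covers
  the full two-level chain.
- MixedLM random-effect structures are limited to what statsmodels
  expresses (no crossed random factors); the simplification ladder is a
  documented heuristic.
- The noncentral-t CI for paired d follows the construction above; other
  implementations may differ in the rescaling convention.
- Searchlight volumes assume a shared grid across subjects (registration
  is out of scope).
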