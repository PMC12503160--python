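# Methods

This note documents the models, default parameters, numerical choices, and
known limitations of `groovemap`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Study design emulated by the generator

The synthetic study mirrors a body-sensation-map experiment on musical
groove: 108 participants each hear 12 excerpts (4 funk, 4 jazz funk,
4 rock), rate *wanting to move* and *pleasure* on a 1–5 Likert scale, rate
their familiarity with each excerpt (1–5), and paint each felt component
on a body silhouette. Each excerpt carries a pulse-entropy value; the
defaults span 0.669–0.787 with genre means 0.734 (funk), 0.750 (jazz
funk), 0.722 (rock) — jazz funk highest, matching the ordering such real
stimuli exhibit.

## Rating model (generative and fitted)

Latent rating = intercept + genre effect (treatment contrasts vs funk) +
0.97·familiarity + training terms + standardized-entropy linear/quadratic
terms + by-participant intercept + by-participant genre slope +
by-stimulus intercept + Gaussian residual. The observed rating clamps the
latent to [1, 5] and rounds to the integer grid; familiarity itself is a
discretized Gaussian (mean 2.45/2.28/2.33 by genre, latent SD 0.30).
Training years are zero-inflated exponential (≈55% zeros, mean ≈2 y,
SD ≈4 y). Default coefficients: intercept 1.31, jazz funk −1.21, rock
−0.91, familiarity 0.97 (the headline effect sizes of the emulated
design); random SDs 0.28 (participant intercept), 0.15 (participant genre
slope), 0.15 (stimulus intercept); residual SD 0.50.

**Why these scales.** A parameter-recovery simulation through a
clamp-then-round observation channel is only well posed when the channel
is approximately information-preserving. Two distortions compete:

1. *Boundary censoring.* Latent draws clamped at 1 or 5 attenuate every
   slope. The intercept is therefore placed at the symmetric-tails point
   (equal clamping mass at both ends), keeping censoring at ~2–3% of
   trials.
2. *Grid discretization.* If the conditional latent SD falls much below
   ~0.55, the 1-point Likert grid is under-dithered: E[round(μ+ε)] bends
   around μ with local slope 1 ± ~2πe^(−2π²σ²), which adds real
   replicate-to-replicate variability to slope estimates that no
   model-based SE can report. The residual SD of 0.50 keeps the grid
   dithered.

Both constraints cannot be satisfied perfectly at once; the defaults are a
deliberate compromise, fixed once. A consequence, measured by the
acceptance suite, is that the familiarity slope (whose study-scale SE is
~0.036) retains a censoring attenuation of roughly −0.014 (~0.4 SE) and a
few-percent variance inflation, so its nominal-95% CI coverage sits at
≈92–93% rather than 95%, and the null distribution of the genre
likelihood-ratio statistic is deflated by ~10% (type-I ≈0.03 at nominal
0.05). These are properties of the discretized observation model, not of
the estimator: on continuous latents the same fits are unbiased and
calibrated, and the fitted estimates and standard errors reproduce
`lme4::lmer` on identical data to four decimals. Removing the distortion
would require an ordinal-likelihood (cumulative-link) model, which is
deliberately outside this package's scope.

### Fitting backend

Models are fit with statsmodels `MixedLM`; crossed random effects are
encoded as variance components on a single grouping blob, with random
genre slopes as participant-by-genre (compound-symmetry) components. The
profiled (RE)ML surface can have spurious optima when variance components
approach zero, so every fit runs both L-BFGS and Powell and keeps the
higher likelihood. Singular or non-converging fits descend a fallback
ladder — drop stimulus slopes, then participant slopes, then intercepts
only — and the converged structure plus the full ladder log are recorded
on the returned `ModelFit`. Data with exactly zero residual variance
(noise-free simulations) are returned as the interpolating least-squares
solution, flagged in the ladder log.

Denominator degrees of freedom use a classical between-within assignment:
stimulus-level terms (genre, entropy) get `n_stimuli − 3` df,
participant-level covariates (training) `n_participants − 3`, and
observation-level covariates the residual df. This is an approximation
(labeled `between-within` in every output); Satterthwaite/Kenward–Roger
df are not available from the backend. Likelihood-ratio comparisons
require ML (not REML) fits and are refused otherwise. Pairwise genre
post-hocs take their familywise adjustment from the equicoordinate
multivariate-*t* distribution over the contrast set (QMC integration,
seeded), falling back to a labeled Tukey studentized-range adjustment if
the integration fails; adjusted p-values are floored at the unadjusted
ones. Pulse entropy enters regression models as QR-orthogonalized
polynomials of the standardized value with unit-variance columns and
positive leading coefficients; the basis record is attached to the fit.

## Painting model

Stroke logs are (t, x, y, brush-radius) samples at ~60 Hz, 0-based pixel
coordinates, origin top-left. Per trial, each region named in the truth's
`effect_regions[(component, genre)]` is painted with its listed
probability; a painted region receives an Ornstein–Uhlenbeck-style walk
tethered to the region centroid and confined to the region eroded by
roughly one brush radius, so stamped discs remain essentially within the
targeted body part and planted effects stay crisp against the atlas.
Successive region strokes are separated by a 250 ms pen-up pause; 2% of
samples stray to off-body positions to exercise downstream screening.
Defaults plant the component effect in arms+legs (paint probability 0.65
for wanting-to-move vs 0.05 for pleasure), the genre effect in
hips+shoulders (0.65 funk vs 0.05 others), and a 0.30 baseline in head
and chest; expected within-region coverage is 0.45.

Rasterization stamps a kernel per sample — hard disc (weight 1 within the
radius) or Gaussian (σ = radius/2, truncated at 3σ) — accumulating and
clipping at 1 per pixel (paint saturates; unbounded accumulation is a
flag). Consecutive samples of one drag (inter-sample gap ≤ 50 ms) farther
apart than a brush radius are bridged by stamps every half radius; larger
time gaps are pen-up moves and are never painted across. Off-canvas
sample centers are skipped and counted. The fraction of deposited mass
outside the silhouette is recorded before masking; masking zeroes
out-of-body pixels and is idempotent. Screening flags trials covering
>95% of the silhouette (scribble-everything) and, optionally, trials
exceeding an out-of-body mass threshold; flagged trials are partitioned
out and tabulated, never silently deleted.

## Pixel-wise inference

One-sample and paired *t* maps and 1- or 2-factor within-subject ANOVA
*F* maps are computed vectorized over in-silhouette pixels; each effect is
tested against its effect-by-subject stratum, with no sphericity
correction (the classical univariate partitioning). Zero-variance pixels
— ubiquitous in painting data — receive stat 0 / p 1 when the mean is
also zero, and a signed infinite sentinel with p 0 (counted in
`n_flagged`) otherwise, so empty background cannot generate rejections.
FDR correction is Benjamini–Hochberg per statistical map over in-mask
pixels only; out-of-mask pixels never enter the family, and no
cluster-extent or spatial smoothing is applied. Familiarity groupings use
a median split of stimulus means (ties at the median go low); entropy
groupings use rank tertiles with the remainder assigned to the middle
bin.

## Silhouette atlas

The silhouette is procedural: head and ears from ellipses, torso bands
(neck/throat/mouth, shoulders, upper chest, chest, abdomen, hips), arms
flush against the torso with wrists and hands, legs with ankles and feet
— 14 regions that partition the in-mask pixels exactly, forming a single
connected component. Default canvas 522 rows × 171 columns (the classic
body-map aspect); any size ≥ 64×64 that leaves every region non-empty is
accepted, and an undersized canvas raises rather than returning a partial
partition.

## Pulse entropy

Onset strength is half-wave-rectified spectral flux (Hann STFT, frame
1024, hop 256 at 22,050 Hz → 86.1 frames/s). The envelope is centered,
autocorrelated, normalized to 1 at lag 0, restricted to lags 0.25–2.0 s
(beat periods for 30–240 bpm), and floored at 0. The curve, normalized to
sum 1, is scored by normalized Shannon entropy −Σp log p / log N ∈ [0, 1]:
a one-hot curve gives 0, a uniform curve 1, and an all-zero curve (no
periodicity evidence) is defined as 1 with a degeneracy flag. This is a
re-implementation of the pulse-entropy construct, not a bit-compatible
port of any toolbox: frame sizes, lag window and normalization are
explicit parameters recorded on every result, so absolute values are
comparable within this package but not against other implementations.
Synthetic audio is a click train (3 ms raised-cosine 1.5 kHz bursts) with
the beat period rounded to whole samples, Gaussian timing jitter, and
Poisson distractor onsets; jitter at or above half the period warns that
beat identity is lost.

## Problem sizes in the test suite

The acceptance tests run the spatial analyses on a 132×64 atlas with 50
subjects and 50 replicates, FDR calibration on 24×21 noise grids with 200
replicates, rating-model recovery at full study scale (108×12) with 100
replicates, LRT calibration at 40 participants with 500 replicates, and
inverted-U detection at 54 participants with 100 replicates per scenario
— sizes chosen so the complete suite exercises every claim at meaningful
replication while remaining a routine local run.

## Known limitations

- No ordinal/cumulative-link rating models, no Bayesian fits, no
  pixel-wise mixed models, no spatial smoothing, cluster-extent or
  permutation (maxT) correction, no sphericity correction by default.
- The between-within df assignment is approximate; with only 12 stimuli,
  chi-square references for between-stimulus fixed effects are
  anticonservative when stimulus-level variance is present, which is why
  the type-I calibration is defined under a fully exchangeable-stimuli
  null.
- The stroke simulator is a stand-in for human coloring (no painting
  styles, handedness, erasing, or device artifacts), and the silhouette
  is a procedural stand-in for scanned body templates.
- Passing recovery tests on synthetic data shows the pipeline is
  internally consistent at the stated effect sizes and noise levels; it
  does not certify performance on real paintings, whose spatial
  autocorrelation and idiosyncrasies the generator does not emulate.
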