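# groovemap

Body-sensation-map (BSM) analysis of musical groove — the pleasurable urge
to move to music — as a tested, reusable Python pipeline.

In the BSM paradigm, participants listen to short music excerpts, rate two
groove components (*wanting to move* and *pleasure*) on a 1–5 Likert scale,
and paint on a 2D body silhouette where in the body they feel each
component. `groovemap` covers the full analysis chain for such a study:

- **`synthetic_data`** — generates a complete study with known ground
  truth: 108 participants × 12 excerpts (funk, jazz funk, rock; 4 tracks
  each) × 2 components, with Likert ratings from a latent linear mixed
  model, painting stroke logs from region-targeted random walks, a
  procedural body-silhouette atlas with 14 named regions, and click-train
  audio with controllable beat-timing jitter.
- **`canvas`** — reconstructs per-trial paint-intensity maps from raw mouse
  stroke logs (time, x, y, brush radius), removes paint falling outside the
  silhouette, screens anomalous trials, and aggregates trials into
  per-subject condition maps.
- **`mapstats`** — mass-univariate pixel-wise inference: one-sample *t*
  maps against zero, two-way within-subject (repeated-measures) ANOVA *F*
  maps for component × genre, paired-contrast *t* maps, all corrected with
  Benjamini–Hochberg FDR over the in-silhouette pixels; plus median/tertile
  stimulus groupings for familiarity and rhythmic-complexity analyses and
  per-region summaries.
- **`ratings`** — stimulus similarity matrices (Euclidean distance between
  participant-rating vectors), linear mixed-effects models of ratings on
  genre (funk as treatment reference, familiarity and musical training as
  covariates, crossed by-participant / by-stimulus random effects),
  likelihood-ratio model comparison, multivariate-*t*-adjusted pairwise
  post-hocs, and orthogonal linear + quadratic pulse-entropy models (the
  inverted-U analysis).
- **`audio_features`** — pulse entropy, an entropy-based inverse index of
  pulse clarity: rectified-spectral-flux onset envelope → beat-lag
  autocorrelation (0.25–2 s window) → normalized Shannon entropy of the
  autocorrelation curve, in [0, 1]. Low entropy = clear, certain beat.

## The statistics in brief

For per-subject maps $m_s(x)$ the pixel-wise one-sample statistic is
$t(x) = \bar m(x) / (\hat\sigma(x)/\sqrt n)$ with $n-1$ df; factorial maps
use the classical repeated-measures partitioning, testing each effect
against its effect-by-subject stratum, e.g.
$F_A(x) = \mathrm{MS}_A(x) / \mathrm{MS}_{A\times S}(x)$ on
$(a-1),\,(a-1)(n-1)$ df. Multiplicity is handled per map by
Benjamini–Hochberg: reject all $p \le p_{(k)}$ for the largest $k$ with
$p_{(k)} \le kq/m$, with $m$ the in-silhouette pixel count.

Ratings are modeled as
$y_{ps} = \beta_0 + \beta_g\,\mathrm{genre}_s + \beta_f\,\mathrm{fam}_{ps}
+ \beta_t\,\mathrm{training}_p + u_p + v_s + \varepsilon_{ps}$
fit by REML (ML for likelihood-ratio comparisons), and pulse entropy enters
as orthogonal linear and quadratic polynomials, where a negative quadratic
coefficient is the inverted-U signature of intermediate rhythmic
complexity maximizing groove.

## Worked example

```python
import numpy as np
from groovemap import (default_design, default_truth, make_silhouette,
                       gen_strokes, rasterize, apply_mask, aggregate,
                       rm_anova_map, summarize_regions, dice)
from groovemap.synthetic_data import COMPONENTS, GENRES

atlas = make_silhouette((132, 64))
design = default_design(n_participants=50)
truth = default_truth()   # movement planted in arms+legs, funk in hips+shoulders

logs = gen_strokes(design, truth, atlas, seed=3)
maps = [apply_mask(rasterize(log, atlas), atlas) for log in logs]
cells = aggregate(maps, by=("participant", "component", "genre"),
                  genre_of={s.id: s.genre for s in design.stimuli})
result = rm_anova_map({k: m.grid for k, m in cells.items()},
                      {"component": list(COMPONENTS), "genre": list(GENRES)},
                      atlas, q=0.05)

extremities = atlas.region_mask("arms") | atlas.region_mask("legs")
print("component-effect Dice vs arms+legs:",
      round(dice(result["component"].sig, extremities), 3))
print("interaction pixels:", result["component:genre"].n_sig)
```

prints

```
component-effect Dice vs arms+legs: 0.948
interaction pixels: 0
```

i.e. the pixels where the two groove components differ significantly
coincide almost exactly with the planted extremity regions (Dice 0.95),
and the component × genre interaction map is empty — the planted double
dissociation (movement → extremities, genre → hips/shoulders) is recovered
cleanly from raw stroke logs.

## Command line

A thin CLI wraps the library: `groovemap simulate | rasterize | mapstats |
ratings | entropy` (see `--help` on each subcommand).
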