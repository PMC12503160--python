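"""Synthetic study generator: participants, ratings, paintings, and audio.

The generators emulate a body-sensation-map study of musical groove: every
participant hears each of 12 music excerpts (4 tracks in each of 3 genres:
funk, jazz funk, rock), rates two groove components (wanting to move,
pleasure) on a 1-5 Likert scale, and paints where in the body each component
is felt on a silhouette canvas.  Each excerpt carries a pulse-entropy value
(a rhythm-predictability index in [0, 1]).

Ratings are produced by a linear mixed model on a latent scale -- genre fixed
effects with funk as reference, a familiarity slope, musical-training and
pulse-entropy terms, crossed random effects (by-participant intercept and
genre slope, by-stimulus intercept) -- then clamped to [1, 5] and rounded to
the Likert grid.  Paintings are produced by region-targeted random walks on
the silhouette whose per-cell painting probabilities encode the planted
spatial effects.  All generators are deterministic given a seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .canvas import StrokeLog
from .silhouette import DEFAULT_DIMS, SilhouetteAtlas, make_silhouette

__all__ = [
    "Stimulus",
    "StudyDesign",
    "SimulationTruth",
    "default_design",
    "default_truth",
    "make_silhouette",
    "gen_ratings",
    "gen_strokes",
    "gen_click_audio",
    "gen_null_maps",
]

GENRES = ("funk", "jazz_funk", "rock")
COMPONENTS = ("wanting_to_move", "pleasure")

AUDIO_SAMPLE_RATE = 22_050  # Hz; adequate for onset analysis at half the cost of 44.1 k


@dataclass(frozen=True)
class Stimulus:
    id: str
    genre: str
    pulse_entropy: float  # nominal rhythm-predictability index in [0, 1]

    def __post_init__(self) -> None:
        if self.genre not in GENRES:
            raise ValueError(f"unknown genre {self.genre!r}")
        if not 0.0 <= self.pulse_entropy <= 1.0:
            raise ValueError("pulse_entropy must lie in [0, 1]")


@dataclass(frozen=True)
class StudyDesign:
    """Factorial layout: every participant rates every stimulus on both components."""

    n_participants: int = 108
    stimuli: tuple[Stimulus, ...] = ()
    components: tuple[str, str] = COMPONENTS
    rating_scale: tuple[int, int] = (1, 5)

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")

    @property
    def participant_ids(self) -> list[str]:
        width = len(str(self.n_participants))
        return [f"p{i + 1:0{width}d}" for i in range(self.n_participants)]

    def genre_of(self, stimulus_id: str) -> str:
        for s in self.stimuli:
            if s.id == stimulus_id:
                return s.genre
        raise KeyError(stimulus_id)

    def entropy_of(self, stimulus_id: str) -> float:
        for s in self.stimuli:
            if s.id == stimulus_id:
                return s.pulse_entropy
        raise KeyError(stimulus_id)


def _default_stimuli() -> tuple[Stimulus, ...]:
    # Nominal per-track pulse entropies: genre means 0.734 / 0.750 / 0.722
    # with the jazz-funk tracks highest on average, spanning 0.669-0.787.
    vals = {
        "funk": (0.700, 0.726, 0.742, 0.768),
        "jazz_funk": (0.712, 0.741, 0.760, 0.787),
        "rock": (0.669, 0.712, 0.733, 0.774),
    }
    return tuple(
        Stimulus(id=f"{g}_{i + 1}", genre=g, pulse_entropy=v)
        for g in GENRES
        for i, v in enumerate(vals[g])
    )


def default_design(n_participants: int = 108) -> StudyDesign:
    return StudyDesign(n_participants=n_participants, stimuli=_default_stimuli())


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth generative parameters used by the generators.

    ``fixed_effects`` holds the latent-scale regression coefficients;
    ``genre`` entries are treatment contrasts relative to funk.  The defaults
    for the genre contrasts and the familiarity slope are the headline
    wanting-to-move effects of the emulated study design (-1.21 jazz funk,
    -0.91 rock, +0.97 familiarity).  Remaining scales were chosen once, subject
    to a two-sided identifiability constraint of the clamp-then-round
    observation model: latent draws must rarely hit the 1/5 boundary (the
    intercept sits at the symmetric-tails point, censoring ~2-3%) while the
    conditional latent sd stays >= ~0.55 so the 1-point Likert grid is
    dithered and rounding does not distort slope recovery; see
    docs/methods.md.

    ``effect_regions[(component, genre)]`` maps region names to the
    probability that the region is painted on such a trial;
    ``paint_intensity[region]`` is the expected fraction of the region covered
    when it is painted.
    """

    fixed_effects: dict = field(
        default_factory=lambda: {
            "intercept": 1.31,
            "genre": {"jazz_funk": -1.21, "rock": -0.91},
            "familiarity": 0.97,
            "formal_training_years": 0.0,
            "informal_training_years": 0.0,
            "entropy_linear": 0.0,
            "entropy_quadratic": 0.0,
        }
    )
    random_sd: dict = field(
        default_factory=lambda: {
            "participant_intercept": 0.28,
            "participant_genre_slope": 0.15,
            "stimulus_intercept": 0.15,
        }
    )
    residual_sd: float = 0.50
    # Familiarity is itself a 1-5 Likert response: discretized Gaussian whose
    # mean depends (weakly) on genre, funk most familiar.
    familiarity_mean: dict = field(
        default_factory=lambda: {"funk": 2.45, "jazz_funk": 2.28, "rock": 2.33}
    )
    familiarity_sd: float = 0.30
    # Spatial ground truth: component effect planted in the extremities
    # (arms + legs painted for wanting-to-move only), genre effect in hips +
    # shoulders (funk only), head and chest painted in every condition.
    effect_regions: dict = field(
        default_factory=lambda: {
            (comp, genre): {
                "head": 0.30,
                "chest": 0.30,
                "arms": 0.65 if comp == "wanting_to_move" else 0.05,
                "legs": 0.65 if comp == "wanting_to_move" else 0.05,
                "hips": 0.65 if genre == "funk" else 0.05,
                "shoulders": 0.65 if genre == "funk" else 0.05,
            }
            for comp in COMPONENTS
            for genre in GENRES
        }
    )
    paint_intensity: dict = field(default_factory=lambda: {"default": 0.45})
    stray_fraction: float = 0.02  # fraction of stroke samples landing off-body

    def __post_init__(self) -> None:
        for name, sd in self.random_sd.items():
            if sd < 0:
                raise ValueError(f"random_sd[{name!r}] must be >= 0")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        flat = [
            v
            for k, v in self.fixed_effects.items()
            if k != "genre"
        ] + list(self.fixed_effects.get("genre", {}).values())
        if not np.all(np.isfinite(flat)):
            raise ValueError("fixed_effects must be finite")
        for cell, regions in self.effect_regions.items():
            for region, w in regions.items():
                if w < 0:
                    raise ValueError(f"paint weight for {region} in {cell} is negative")
        for region, c in self.paint_intensity.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"coverage for {region!r} must lie in [0, 1]")

    def coverage_of(self, region: str) -> float:
        return self.paint_intensity.get(region, self.paint_intensity.get("default", 0.45))

    def with_fixed(self, **updates) -> "SimulationTruth":
        """Copy with some fixed-effect entries replaced."""
        fe = dict(self.fixed_effects)
        fe.update(updates)
        return replace(self, fixed_effects=fe)


def default_truth() -> SimulationTruth:
    return SimulationTruth()


# ---------------------------------------------------------------------------
# Ratings
# ---------------------------------------------------------------------------

def _simulate_participants(design: StudyDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Per-participant covariates: years of formal / informal musical training.

    Zero-inflated exponential, rounded to whole years: most online samples
    report no training, a minority several years (population mean ~2 years,
    SD ~4).
    """
    n = design.n_participants
    out = {}
    for col in ("formal_training_years", "informal_training_years"):
        has = rng.random(n) >= 0.55
        years = np.round(rng.exponential(scale=4.4, size=n)) * has
        out[col] = np.clip(years, 0, 25).astype(int)
    return pd.DataFrame(out, index=design.participant_ids)


def _simulate_familiarity(
    design: StudyDesign, truth: SimulationTruth, rng: np.random.Generator
) -> np.ndarray:
    """Familiarity Likert response per (participant, stimulus), genre-shifted."""
    mus = np.array([truth.familiarity_mean[s.genre] for s in design.stimuli])
    latent = rng.normal(mus, truth.familiarity_sd, size=(design.n_participants, len(mus)))
    return np.clip(np.rint(latent), 1, 5).astype(int)


def gen_ratings(
    design: StudyDesign, truth: SimulationTruth, seed: int
) -> pd.DataFrame:
    """Simulate the long-format rating table.

    Returns one row per participant x stimulus x component with columns
    participant_id, stimulus_id, genre, component, rating, familiarity,
    formal_training_years, informal_training_years, pulse_entropy.

    The latent rating is the mixed-model linear predictor (genre, familiarity,
    training, standardized-entropy linear and quadratic terms, crossed random
    effects, Gaussian residual); the observed rating clamps the latent to the
    rating scale and rounds to the Likert grid.  Random effects are drawn
    independently per component, since the two components are analyzed as
    separate models.
    """
    rng = np.random.default_rng(seed)
    fe = truth.fixed_effects
    lo, hi = design.rating_scale
    stimuli = design.stimuli
    n_p, n_s = design.n_participants, len(stimuli)

    training = _simulate_participants(design, rng)
    familiarity = _simulate_familiarity(design, truth, rng)

    ent = np.array([s.pulse_entropy for s in stimuli])
    ent_sd = ent.std()
    z_ent = (ent - ent.mean()) / ent_sd if ent_sd > 0 else np.zeros_like(ent)
    genre_eff = np.array([fe["genre"].get(s.genre, 0.0) for s in stimuli])
    genre_index = {g: i for i, g in enumerate(GENRES)}
    g_idx = np.array([genre_index[s.genre] for s in stimuli])

    frames = []
    for component in design.components:
        u_p = rng.normal(0.0, truth.random_sd["participant_intercept"], n_p)
        u_pg = rng.normal(
            0.0, truth.random_sd["participant_genre_slope"], (n_p, len(GENRES))
        )
        u_s = rng.normal(0.0, truth.random_sd["stimulus_intercept"], n_s)
        eps = rng.normal(0.0, truth.residual_sd, (n_p, n_s))

        latent = (
            fe["intercept"]
            + genre_eff[None, :]
            + fe["familiarity"] * familiarity
            + fe["formal_training_years"] * training["formal_training_years"].to_numpy()[:, None]
            + fe["informal_training_years"] * training["informal_training_years"].to_numpy()[:, None]
            + fe["entropy_linear"] * z_ent[None, :]
            + fe["entropy_quadratic"] * (z_ent**2)[None, :]
            + u_p[:, None]
            + u_pg[:, g_idx]
            + u_s[None, :]
            + eps
        )
        rating = np.clip(np.rint(np.clip(latent, lo, hi)), lo, hi).astype(int)

        frames.append(
            pd.DataFrame(
                {
                    "participant_id": np.repeat(design.participant_ids, n_s),
                    "stimulus_id": np.tile([s.id for s in stimuli], n_p),
                    "genre": np.tile([s.genre for s in stimuli], n_p),
                    "component": component,
                    "rating": rating.ravel(),
                    "familiarity": familiarity.ravel(),
                    "formal_training_years": np.repeat(
                        training["formal_training_years"].to_numpy(), n_s
                    ),
                    "informal_training_years": np.repeat(
                        training["informal_training_years"].to_numpy(), n_s
                    ),
                    "pulse_entropy": np.tile(ent, n_p),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Stroke logs
# ---------------------------------------------------------------------------

def _region_walk(
    region: np.ndarray,
    mask: np.ndarray,
    coverage: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Ornstein-Uhlenbeck-style walk tethered to the region centroid.

    Samples are confined to the region eroded by roughly one brush radius
    (falling back to the full region for thin parts), so the stamped discs
    stay essentially within the targeted body part and planted spatial
    effects remain crisp against the region atlas.
    """
    from scipy import ndimage

    rr, cc = np.nonzero(region)
    area = rr.size
    brush = max(2, int(round(0.16 * math.sqrt(area))))
    eroded = ndimage.binary_erosion(region, iterations=max(1, brush - 1))
    if not eroded.any():
        eroded = region
    err, ecc = np.nonzero(eroded)
    cy, cx = err.mean(), ecc.mean()
    n_samples = max(3, min(400, int(round(3.0 * coverage * area / (math.pi * brush**2)))))

    start = rng.integers(err.size)
    y, x = float(err[start]), float(ecc[start])
    theta, step = 0.15, 1.2 * brush
    pts = np.empty((n_samples, 2))
    H, W = mask.shape
    for i in range(n_samples):
        for _ in range(8):
            ny = y + theta * (cy - y) + rng.normal(0.0, step)
            nx = x + theta * (cx - x) + rng.normal(0.0, step)
            iy, ix = int(round(ny)), int(round(nx))
            if 0 <= iy < H and 0 <= ix < W and eroded[iy, ix]:
                y, x = ny, nx
                break
        pts[i] = (x, y)
    return pts, brush


def gen_strokes(
    design: StudyDesign,
    truth: SimulationTruth,
    atlas: SilhouetteAtlas,
    seed: int,
    participants: list[str] | None = None,
) -> list[StrokeLog]:
    """Simulate painting stroke logs for every trial of the design.

    Per trial, each region named in ``truth.effect_regions[(component,
    genre)]`` is painted with its listed probability; painted regions receive
    a smooth tethered random walk whose rasterization covers roughly the
    region's coverage fraction.  A ``truth.stray_fraction`` of samples is
    displaced to random off-body canvas positions to exercise out-of-body
    screening downstream.  Trials whose condition has no positive region
    weight produce an empty (legal) log.
    """
    for cell, regions in truth.effect_regions.items():
        for region in regions:
            if region not in atlas.names:
                raise ValueError(f"effect region {region!r} not in atlas")

    rng = np.random.default_rng(seed)
    mask = atlas.mask
    off_rr, off_cc = np.nonzero(~mask)
    pids = participants if participants is not None else design.participant_ids
    logs: list[StrokeLog] = []
    for pid in pids:
        for stim in design.stimuli:
            for component in design.components:
                weights = truth.effect_regions.get((component, stim.genre), {})
                xs, ys, brushes = [], [], []
                for region, p in weights.items():
                    if p <= 0 or rng.random() >= p:
                        continue
                    pts, brush = _region_walk(
                        atlas.region_mask(region), mask, truth.coverage_of(region), rng
                    )
                    xs.append(pts[:, 0])
                    ys.append(pts[:, 1])
                    brushes.append(np.full(len(pts), brush, dtype=float))
                if xs:
                    x = np.concatenate(xs)
                    y = np.concatenate(ys)
                    b = np.concatenate(brushes)
                    if truth.stray_fraction > 0 and off_rr.size:
                        stray = rng.random(x.size) < truth.stray_fraction
                        k = int(stray.sum())
                        if k:
                            j = rng.integers(off_rr.size, size=k)
                            x[stray] = off_cc[j].astype(float)
                            y[stray] = off_rr[j].astype(float)
                    # ~60 Hz mouse sampling within a drag; a 250 ms pen-up
                    # pause separates the per-region strokes (and any stray
                    # sample) so downstream interpolation never paints
                    # across the lift.
                    t = 16.0 * np.arange(x.size)
                    lengths = [len(v) for v in xs]
                    pen_up = np.zeros(x.size, dtype=bool)
                    pen_up[np.cumsum(lengths)[:-1]] = True
                    if truth.stray_fraction > 0 and off_rr.size:
                        pen_up[stray] = True
                        pen_up[1:][stray[:-1]] = True
                    t = t + 250.0 * np.cumsum(pen_up)
                    samples = np.column_stack([t, x, y, b])
                else:
                    samples = np.empty((0, 4))
                logs.append(
                    StrokeLog(
                        participant_id=pid,
                        stimulus_id=stim.id,
                        component=component,
                        samples=samples,
                    )
                )
    return logs


# ---------------------------------------------------------------------------
# Null maps (for error-rate calibration)
# ---------------------------------------------------------------------------

def gen_null_maps(
    n_subjects: int,
    cells: list[tuple],
    shape: tuple[int, int],
    seed: int,
    noise_sd: float = 1.0,
) -> dict:
    """Global-null subject-by-cell maps: spatially independent Gaussian noise.

    Used to calibrate false-discovery control of the pixel-wise tests: no
    effect is planted anywhere, so every rejection is a false discovery.
    Returns ``{(subject_index, *cell): grid}``.
    """
    rng = np.random.default_rng(seed)
    return {
        (s, *cell): rng.normal(0.0, noise_sd, shape)
        for s in range(n_subjects)
        for cell in cells
    }


# ---------------------------------------------------------------------------
# Audio
# ---------------------------------------------------------------------------

def gen_click_audio(
    tempo_bpm: float,
    timing_jitter_sd: float = 0.0,
    noise_onset_rate: float = 0.0,
    duration: float = 10.0,
    seed: int = 0,
    sample_rate: int = AUDIO_SAMPLE_RATE,
) -> tuple[np.ndarray, int]:
    """Synthesize a click train with controllable beat-timing uncertainty.

    A proxy for music of varying pulse entropy: clicks at the nominal tempo
    with Gaussian timing jitter (seconds) plus Poisson distractor onsets
    (events/second).  The beat period is rounded to a whole number of samples
    so that at zero jitter the train is exactly isochronous.  Returns
    (mono waveform float in [-1, 1], sample rate).
    """
    if not 40.0 <= tempo_bpm <= 240.0:
        raise ValueError("tempo must lie in [40, 240] bpm")
    if duration < 5.0:
        raise ValueError("duration must be >= 5 s")
    period = int(round(60.0 / tempo_bpm * sample_rate))
    if timing_jitter_sd >= 0.5 * period / sample_rate:
        warnings.warn(
            "timing jitter exceeds half the beat period; beat identity is lost",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    y = np.zeros(n)

    # 3 ms raised-cosine 1.5 kHz burst.
    t = np.arange(int(0.003 * sample_rate)) / sample_rate
    click = np.sin(2 * np.pi * 1500.0 * t) * np.hanning(t.size)

    onsets = np.arange(0, n - click.size, period, dtype=float)
    if timing_jitter_sd > 0:
        onsets = onsets + rng.normal(0.0, timing_jitter_sd * sample_rate, onsets.size)
    for amp, starts in ((1.0, onsets),):
        for s in starts:
            i = int(round(s))
            if 0 <= i <= n - click.size:
                y[i : i + click.size] += amp * click
    if noise_onset_rate > 0:
        k = rng.poisson(noise_onset_rate * duration)
        for s in rng.uniform(0, n - click.size, k):
            i = int(round(s))
            y[i : i + click.size] += 0.7 * click
    peak = np.abs(y).max()
    if peak > 1.0:
        y = y / peak
    return y, sample_rate
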