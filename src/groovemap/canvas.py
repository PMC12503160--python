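"""Reconstruction of painting intensity maps from raw mouse stroke logs.

A trial's stroke log is the sequence of (time, x, y, brush-radius) samples
recorded while the participant colored the body silhouette.  ``rasterize``
replays the log by stamping a brush kernel at every sample, saturating at 1
per pixel (repainting a spot conveys no extra signal); ``apply_mask`` removes
paint falling outside the silhouette; ``screen_anomalies`` flags scribble-
everything and mostly-off-body trials without deleting them; ``aggregate``
averages trial maps into per-subject condition maps for the pixel-wise
statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .silhouette import SilhouetteAtlas

__all__ = [
    "StrokeLog",
    "PaintMap",
    "ScreeningPolicy",
    "brush_kernel",
    "rasterize",
    "apply_mask",
    "screen_anomalies",
    "aggregate",
]


@dataclass(frozen=True)
class StrokeLog:
    """Raw painting events of one trial.

    ``samples`` is an (n, 4) float array of (t_ms, x_px, y_px, brush_px);
    times are non-decreasing, brush radii positive, coordinates 0-based with
    origin top-left (x rightward, y downward).
    """

    participant_id: str
    stimulus_id: str
    component: str
    samples: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2 or s.shape[1] != 4:
            raise ValueError("samples must be an (n, 4) array of (t, x, y, brush)")
        object.__setattr__(self, "samples", s)
        if s.size:
            if not np.all(np.isfinite(s[:, 1:3])):
                raise ValueError("stroke coordinates must be finite")
            if np.any(np.diff(s[:, 0]) < 0):
                raise ValueError("stroke times must be non-decreasing")
            if np.any(s[:, 3] <= 0):
                raise ValueError("brush radii must be positive")

    def __len__(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class PaintMap:
    """Per-trial (or aggregated) non-negative intensity grid.

    ``grid`` values lie in [0, 1] after clipping.  ``out_of_body_fraction``
    is the share of deposited brush mass that fell outside the silhouette
    (before masking); ``deposited_mass`` is the pre-clip total brush mass,
    used for mass-accounting checks; ``n_skipped`` counts samples whose
    center fell entirely off-canvas.
    """

    grid: np.ndarray
    participant_id: str = ""
    stimulus_id: str = ""
    component: str = ""
    out_of_body_fraction: float | None = None
    deposited_mass: float = 0.0
    n_skipped: int = 0
    masked: bool = False
    n_trials: int = 1
    extra: dict = field(default_factory=dict, compare=False)

    @property
    def meta(self) -> tuple[str, str, str]:
        return (self.participant_id, self.stimulus_id, self.component)


_KERNEL_CACHE: dict = {}


def brush_kernel(radius: float, kind: str = "disc") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Brush footprint for a given radius.

    ``disc``: weight 1 on every pixel whose center lies within Euclidean
    distance ``radius`` of the brush center.  ``gaussian``: weights
    exp(-d^2 / (2 sigma^2)) with sigma = radius / 2, truncated at 3 sigma.
    Returns (row offsets, col offsets, weights).
    """
    key = (round(float(radius), 3), kind)
    if key in _KERNEL_CACHE:
        return _KERNEL_CACHE[key]
    if kind == "disc":
        r = float(radius)
        n = int(math.floor(r))
        dy, dx = np.mgrid[-n : n + 1, -n : n + 1]
        inside = dy**2 + dx**2 <= r**2
        out = (dy[inside], dx[inside], np.ones(int(inside.sum())))
    elif kind == "gaussian":
        sigma = float(radius) / 2.0
        n = max(1, int(math.ceil(3.0 * sigma)))
        dy, dx = np.mgrid[-n : n + 1, -n : n + 1]
        d2 = dy**2 + dx**2
        inside = d2 <= (3.0 * sigma) ** 2
        w = np.exp(-d2[inside] / (2.0 * sigma**2))
        out = (dy[inside], dx[inside], w)
    else:
        raise ValueError(f"unknown kernel kind {kind!r}")
    _KERNEL_CACHE[key] = out
    return out


PEN_UP_MS = 50.0  # inter-sample time gap beyond which a new stroke begins


def _interpolated_points(samples: np.ndarray, max_dt_ms: float = PEN_UP_MS) -> np.ndarray:
    """Insert intermediate stamps along within-drag segments.

    Consecutive samples of a continuous mouse drag (inter-sample time gap at
    most ``max_dt_ms``) that are farther apart than one brush radius are
    connected by stamps spaced at most half a radius apart, so sampling gaps
    do not leave dotted strokes.  A larger time gap marks a pen-up move and
    is never painted across.
    """
    if samples.shape[0] < 2:
        return samples
    chunks = [samples[:1]]
    for prev, cur in zip(samples[:-1], samples[1:]):
        d = math.hypot(cur[1] - prev[1], cur[2] - prev[2])
        r = min(prev[3], cur[3])
        if d > r and (cur[0] - prev[0]) <= max_dt_ms:
            k = int(math.ceil(d / (0.5 * r)))
            f = (np.arange(1, k) / k)[:, None]
            chunks.append(prev[None, :] * (1 - f) + cur[None, :] * f)
        chunks.append(cur[None, :])
    return np.concatenate(chunks, axis=0)


def rasterize(
    log: StrokeLog,
    atlas: SilhouetteAtlas,
    kernel: str = "disc",
    interpolate: bool = True,
    clip: bool = True,
) -> PaintMap:
    """Replay a stroke log into a paint intensity grid.

    Each sample deposits its brush kernel at (x, y); mass accumulates across
    samples and is clipped at 1 per pixel (saturating paint; set
    ``clip=False`` for unbounded accumulation).  Samples whose rounded center
    lies off-canvas are skipped and counted.  The fraction of deposited mass
    falling outside the silhouette is recorded before any masking; the
    returned grid itself is *not* masked -- compose with :func:`apply_mask`.
    """
    H, W = atlas.dims
    grid = np.zeros((H, W))
    mask = atlas.mask
    total_mass = 0.0
    outside_mass = 0.0
    n_skipped = 0

    samples = log.samples
    if samples.size:
        centers_ok = (
            (np.rint(samples[:, 1]) >= 0)
            & (np.rint(samples[:, 1]) < W)
            & (np.rint(samples[:, 2]) >= 0)
            & (np.rint(samples[:, 2]) < H)
        )
        n_skipped = int((~centers_ok).sum())
        kept = samples[centers_ok]
        stamps = _interpolated_points(kept) if interpolate else kept
        # stamp all samples sharing a brush radius in one vectorized deposit
        radii = np.round(stamps[:, 3], 3) if stamps.size else np.empty(0)
        for r in np.unique(radii):
            sel = stamps[radii == r]
            dy, dx, w = brush_kernel(r, kernel)
            ry = np.rint(sel[:, 2]).astype(int)[:, None] + dy[None, :]
            rx = np.rint(sel[:, 1]).astype(int)[:, None] + dx[None, :]
            wv = np.broadcast_to(w[None, :], ry.shape)
            ok = (ry >= 0) & (ry < H) & (rx >= 0) & (rx < W)
            ry, rx, wv = ry[ok], rx[ok], wv[ok]
            np.add.at(grid, (ry, rx), wv)
            total_mass += float(wv.sum())
            outside_mass += float(wv[~mask[ry, rx]].sum())

    frac = outside_mass / total_mass if total_mass > 0 else 0.0
    return PaintMap(
        grid=np.clip(grid, 0.0, 1.0) if clip else grid,
        participant_id=log.participant_id,
        stimulus_id=log.stimulus_id,
        component=log.component,
        out_of_body_fraction=frac,
        deposited_mass=total_mass,
        n_skipped=n_skipped,
    )


def apply_mask(pmap: PaintMap, atlas: SilhouetteAtlas) -> PaintMap:
    """Zero all paint outside the silhouette; idempotent.

    If the map carries no out-of-body fraction yet, it is finalized here from
    the (post-clip) grid mass split.
    """
    if pmap.grid.shape != atlas.dims:
        raise ValueError(f"map shape {pmap.grid.shape} != atlas dims {atlas.dims}")
    frac = pmap.out_of_body_fraction
    if frac is None:
        total = float(pmap.grid.sum())
        frac = float(pmap.grid[~atlas.mask].sum()) / total if total > 0 else 0.0
    return replace(
        pmap,
        grid=np.where(atlas.mask, pmap.grid, 0.0),
        out_of_body_fraction=frac,
        masked=True,
    )


@dataclass(frozen=True)
class ScreeningPolicy:
    """Thresholds for anomalous-trial screening.

    ``max_coverage``: flag trials painting more than this fraction of the
    in-silhouette pixels (scribble-everything).  ``max_out_of_body``: if set,
    flag trials whose out-of-body mass fraction exceeds it.  Empty paintings
    are always legal data.
    """

    max_coverage: float = 0.95
    max_out_of_body: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_coverage <= 1.0:
            raise ValueError("max_coverage must lie in [0, 1]")
        if self.max_out_of_body is not None and not 0.0 <= self.max_out_of_body <= 1.0:
            raise ValueError("max_out_of_body must lie in [0, 1]")


def screen_anomalies(
    maps: Sequence[PaintMap],
    atlas: SilhouetteAtlas,
    policy: ScreeningPolicy | None = None,
) -> tuple[list[PaintMap], list[PaintMap], pd.DataFrame]:
    """Partition trial maps into kept and flagged; nothing is deleted.

    Returns (kept, flagged, report) where the report tabulates every trial's
    in-silhouette coverage, out-of-body fraction, and flag reasons.
    """
    policy = policy or ScreeningPolicy()
    n_inmask = int(atlas.mask.sum())
    kept, flagged, rows = [], [], []
    for m in maps:
        coverage = float((m.grid[atlas.mask] > 0).sum()) / n_inmask
        oob = m.out_of_body_fraction or 0.0
        reasons = []
        if coverage > policy.max_coverage:
            reasons.append("coverage")
        if policy.max_out_of_body is not None and oob > policy.max_out_of_body:
            reasons.append("out_of_body")
        (flagged if reasons else kept).append(m)
        rows.append(
            {
                "participant_id": m.participant_id,
                "stimulus_id": m.stimulus_id,
                "component": m.component,
                "coverage": coverage,
                "out_of_body_fraction": oob,
                "flagged": bool(reasons),
                "reasons": ",".join(reasons),
            }
        )
    return kept, flagged, pd.DataFrame(rows)


_GROUP_KEYS = ("participant", "component", "genre", "stimulus", "familiarity_bin", "entropy_bin")


def aggregate(
    maps: Sequence[PaintMap],
    by: Sequence[str],
    genre_of: Mapping[str, str] | None = None,
    stimulus_bins: Mapping[str, Mapping[str, str]] | None = None,
) -> dict[tuple, PaintMap]:
    """Pixel-wise mean of trial maps within each requested grouping cell.

    ``by`` is drawn from {participant, component, genre, stimulus,
    familiarity_bin, entropy_bin}.  ``genre_of`` maps stimulus id to genre
    (needed when grouping by genre); ``stimulus_bins`` maps bin-key name to a
    stimulus-to-label mapping (needed for familiarity/entropy bins).  Returns
    {key tuple -> mean PaintMap with n_trials set}; aggregating one map per
    group is the identity.
    """
    bad = [k for k in by if k not in _GROUP_KEYS]
    if bad:
        raise ValueError(f"unknown grouping keys {bad}; allowed: {_GROUP_KEYS}")

    def key_of(m: PaintMap) -> tuple | None:
        parts = []
        for k in by:
            if k == "participant":
                parts.append(m.participant_id)
            elif k == "component":
                parts.append(m.component)
            elif k == "stimulus":
                parts.append(m.stimulus_id)
            elif k == "genre":
                if genre_of is None:
                    raise ValueError("grouping by genre requires genre_of")
                parts.append(genre_of[m.stimulus_id])
            else:
                if stimulus_bins is None or k not in stimulus_bins:
                    raise ValueError(f"grouping by {k} requires stimulus_bins[{k!r}]")
                parts.append(stimulus_bins[k][m.stimulus_id])
        return tuple(parts)

    groups: dict[tuple, list[PaintMap]] = {}
    for m in maps:
        groups.setdefault(key_of(m), []).append(m)

    out = {}
    for key, members in groups.items():
        grid = np.mean([m.grid for m in members], axis=0)
        first = members[0]
        out[key] = PaintMap(
            grid=grid,
            participant_id=first.participant_id if "participant" in by else "",
            stimulus_id=first.stimulus_id if "stimulus" in by else "",
            component=first.component if "component" in by else "",
            masked=all(m.masked for m in members),
            n_trials=len(members),
            extra={"key": key},
        )
    return out
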