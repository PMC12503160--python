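"""Procedural body-silhouette canvas with a named region partition.

The painting paradigm asks participants to color a 2D human silhouette, and
every downstream statistic is computed over the in-silhouette pixels.  This
module builds a deterministic humanoid mask of arbitrary size together with a
label grid that partitions the in-mask pixels into 14 anatomical regions
(head, ears, neck/throat/mouth, shoulders, upper chest, chest, abdomen, arms,
wrists, hands, hips, legs, ankles, feet).  The partition is exhaustive and
overlap-free by construction, and the silhouette forms a single connected
foreground component.

Coordinates are 0-based with origin at the top-left corner; ``x`` runs
rightward along columns and ``y`` downward along rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

REGION_NAMES: tuple[str, ...] = (
    "head",
    "ears",
    "neck_throat_mouth",
    "shoulders",
    "upper_chest",
    "chest",
    "abdomen",
    "arms",
    "wrists",
    "hands",
    "hips",
    "legs",
    "ankles",
    "feet",
)

#: Default canvas size (rows, cols); 522 x 171 follows the aspect ratio of the
#: classic body-sensation-map silhouette.
DEFAULT_DIMS: tuple[int, int] = (522, 171)


class AtlasSizeError(ValueError):
    """Raised when the requested canvas is too small to draw every region."""


@dataclass(frozen=True)
class SilhouetteAtlas:
    """Body mask plus exhaustive region partition.

    Attributes
    ----------
    labels
        Integer grid; 0 = outside the body, ``i`` >= 1 indexes
        ``names[i - 1]``.
    names
        Region names in label order.
    """

    labels: np.ndarray
    names: tuple[str, ...] = REGION_NAMES
    _region_cache: dict = field(default_factory=dict, compare=False, repr=False)

    @property
    def dims(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def mask(self) -> np.ndarray:
        """Boolean grid, True inside the body."""
        return self.labels > 0

    def region_mask(self, name: str) -> np.ndarray:
        if name not in self._region_cache:
            idx = self.names.index(name) + 1
            self._region_cache[name] = self.labels == idx
        return self._region_cache[name]

    def region_centroid(self, name: str) -> tuple[float, float]:
        """(row, col) centroid of a region."""
        rr, cc = np.nonzero(self.region_mask(name))
        return float(rr.mean()), float(cc.mean())

    def region_counts(self) -> dict[str, int]:
        return {n: int(self.region_mask(n).sum()) for n in self.names}


def _band(frac0: float, frac1: float, rows: int) -> tuple[int, int]:
    """Half-open row range [r0, r1) for a pair of height fractions."""
    return int(round(frac0 * rows)), int(round(frac1 * rows))


def make_silhouette(dims: tuple[int, int] = DEFAULT_DIMS) -> SilhouetteAtlas:
    """Build a deterministic humanoid silhouette atlas.

    Parameters
    ----------
    dims
        (rows, cols) of the canvas; both must be >= 64.

    Raises
    ------
    AtlasSizeError
        If the canvas is too small for every region to receive at least one
        pixel, or the resulting silhouette is not a single connected
        component.  A partial partition is never returned.
    """
    rows, cols = int(dims[0]), int(dims[1])
    if rows < 64 or cols < 64:
        raise AtlasSizeError(f"canvas {rows}x{cols} too small; need at least 64x64")

    labels = np.zeros((rows, cols), dtype=np.int16)
    rr, cc = np.mgrid[0:rows, 0:cols]
    cx = (cols - 1) / 2.0
    dx = np.abs(cc - cx)  # horizontal offset from the body midline, pixels
    W, H = cols, rows

    def assign(name: str, sel: np.ndarray) -> None:
        idx = REGION_NAMES.index(name) + 1
        labels[sel & (labels == 0)] = idx

    # Head: ellipse.  Ears: small discs flanking it (assigned after the head,
    # so only their part outside the ellipse is labeled "ears").
    head_cy, head_ry, head_rx = 0.080 * H, 0.075 * H, 0.14 * W
    head = ((rr - head_cy) / head_ry) ** 2 + ((cc - cx) / head_rx) ** 2 <= 1.0
    assign("head", head)
    ear_r = 0.040 * W
    for sgn in (-1.0, 1.0):
        ear = (rr - head_cy) ** 2 + (cc - (cx + sgn * 0.145 * W)) ** 2 <= ear_r**2
        assign("ears", ear)

    # Torso bands, top to bottom; each half-open in rows so bands tile.
    r0, r1 = _band(0.145, 0.19, H)
    assign("neck_throat_mouth", (rr >= r0) & (rr < r1) & (dx <= 0.06 * W))
    r0, r1 = _band(0.19, 0.23, H)
    assign("shoulders", (rr >= r0) & (rr < r1) & (dx <= 0.20 * W))
    r0, r1 = _band(0.23, 0.29, H)
    assign("upper_chest", (rr >= r0) & (rr < r1) & (dx <= 0.19 * W))
    r0, r1 = _band(0.29, 0.37, H)
    assign("chest", (rr >= r0) & (rr < r1) & (dx <= 0.18 * W))
    r0, r1 = _band(0.37, 0.46, H)
    assign("abdomen", (rr >= r0) & (rr < r1) & (dx <= 0.17 * W))
    r0, r1 = _band(0.46, 0.54, H)
    assign("hips", (rr >= r0) & (rr < r1) & (dx <= 0.19 * W))

    # Arms hang flush against the torso so the silhouette stays connected.
    arm_band = (dx > 0.20 * W) & (dx <= 0.28 * W)
    r0, r1 = _band(0.21, 0.55, H)
    assign("arms", (rr >= r0) & (rr < r1) & arm_band)
    r0, r1 = _band(0.55, 0.585, H)
    assign("wrists", (rr >= r0) & (rr < r1) & arm_band)
    r0, r1 = _band(0.585, 0.66, H)
    assign("hands", (rr >= r0) & (rr < r1) & (dx > 0.195 * W) & (dx <= 0.285 * W))

    # Legs: two columns separated by a midline gap, joined at the hips.
    leg_band = (dx > 0.02 * W) & (dx <= 0.19 * W)
    r0, r1 = _band(0.54, 0.86, H)
    assign("legs", (rr >= r0) & (rr < r1) & leg_band)
    r0, r1 = _band(0.86, 0.90, H)
    assign("ankles", (rr >= r0) & (rr < r1) & (dx > 0.03 * W) & (dx <= 0.17 * W))
    r0, r1 = _band(0.90, 0.985, H)
    assign("feet", (rr >= r0) & (rr < r1) & (dx > 0.03 * W) & (dx <= 0.20 * W))

    atlas = SilhouetteAtlas(labels=labels)
    empty = [n for n, c in atlas.region_counts().items() if c == 0]
    if empty:
        raise AtlasSizeError(f"canvas {rows}x{cols} leaves regions empty: {empty}")
    n_comp = ndimage.label(atlas.mask, structure=np.ones((3, 3)))[1]
    if n_comp != 1:
        raise AtlasSizeError(
            f"canvas {rows}x{cols} yields {n_comp} connected components"
        )
    return atlas


# ---------------------------------------------------------------------------
# PNG round trip: mask.png (nonzero = inside), regions.png (grayscale label
# values) and legend.json mapping pixel value -> region name.
# ---------------------------------------------------------------------------

def save_atlas(atlas: SilhouetteAtlas, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    Image.fromarray((atlas.mask * 255).astype(np.uint8)).save(out / "mask.png")
    Image.fromarray(atlas.labels.astype(np.uint8)).save(out / "regions.png")
    legend = {str(i + 1): name for i, name in enumerate(atlas.names)}
    (out / "legend.json").write_text(json.dumps(legend, indent=2))


def load_atlas(in_dir: str | Path) -> SilhouetteAtlas:
    src = Path(in_dir)
    labels = np.asarray(Image.open(src / "regions.png"), dtype=np.int16)
    legend = json.loads((src / "legend.json").read_text())
    names = tuple(legend[str(i)] for i in sorted(int(k) for k in legend))
    mask = np.asarray(Image.open(src / "mask.png")) > 0
    if not np.array_equal(mask, labels > 0):
        raise ValueError("mask.png and regions.png disagree on the silhouette")
    return SilhouetteAtlas(labels=labels, names=names)
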