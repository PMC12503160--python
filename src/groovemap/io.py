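"""Plain-text interchange formats for the pipeline.

Stroke logs and rating tables travel as CSV, paint maps and statistic maps
as TSV matrices with JSON sidecars, the silhouette atlas as PNG pairs with a
JSON legend (see :mod:`groovemap.silhouette`).  Pixel coordinates are
0-based, origin top-left, x rightward, y downward.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .canvas import PaintMap, StrokeLog
from .mapstats import StatMap

STROKE_COLUMNS = [
    "participant_id", "stimulus_id", "component", "t_ms", "x_px", "y_px", "brush_px",
]
RATING_COLUMNS = [
    "participant_id", "stimulus_id", "genre", "component", "rating", "familiarity",
    "formal_training_years", "informal_training_years", "pulse_entropy",
]


def write_strokes_csv(logs: Iterable[StrokeLog], path: str | Path) -> None:
    frames = []
    for log in logs:
        if len(log) == 0:
            continue
        s = log.samples
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": log.participant_id,
                    "stimulus_id": log.stimulus_id,
                    "component": log.component,
                    "t_ms": s[:, 0],
                    "x_px": s[:, 1],
                    "y_px": s[:, 2],
                    "brush_px": s[:, 3],
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=STROKE_COLUMNS)
    )
    df.to_csv(path, index=False)


def read_strokes_csv(path: str | Path) -> list[StrokeLog]:
    df = pd.read_csv(path)
    missing = [c for c in STROKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"stroke CSV missing columns: {missing}")
    logs = []
    for (pid, stim, comp), grp in df.groupby(
        ["participant_id", "stimulus_id", "component"], sort=True
    ):
        samples = grp[["t_ms", "x_px", "y_px", "brush_px"]].to_numpy(dtype=float)
        logs.append(
            StrokeLog(
                participant_id=str(pid), stimulus_id=str(stim),
                component=str(comp), samples=samples,
            )
        )
    return logs


def write_ratings_csv(table: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in RATING_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"rating table missing columns: {missing}")
    table[RATING_COLUMNS].to_csv(path, index=False)


def read_ratings_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RATING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"rating CSV missing columns: {missing}")
    return df


def write_paintmap_tsv(pmap: PaintMap, path: str | Path) -> None:
    np.savetxt(path, pmap.grid, delimiter="\t", fmt="%.6g")


def read_paintmap_tsv(
    path: str | Path, participant_id: str = "", stimulus_id: str = "", component: str = ""
) -> PaintMap:
    grid = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    return PaintMap(
        grid=grid, participant_id=participant_id,
        stimulus_id=stimulus_id, component=component,
    )


def save_statmap(smap: StatMap, out_dir: str | Path, name: str) -> None:
    """Write stat/p/sig TSV matrices plus a JSON sidecar of the metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / f"{name}_stat.tsv", smap.stat, delimiter="\t", fmt="%.6g")
    np.savetxt(out / f"{name}_p.tsv", smap.p, delimiter="\t", fmt="%.6g")
    np.savetxt(out / f"{name}_sig.tsv", smap.sig.astype(int), delimiter="\t", fmt="%d")
    meta = {
        "contrast": smap.contrast,
        "df": list(smap.df),
        "q": smap.q,
        "critical_p": smap.crit_p,
        "n_subjects": smap.n_subjects,
        "n_significant": smap.n_sig,
        "n_flagged": smap.n_flagged,
    }
    (out / f"{name}_meta.json").write_text(json.dumps(meta, indent=2))


def save_heatmap_png(
    grid: np.ndarray, path: str | Path, mask: np.ndarray | None = None,
    cmap: str = "magma",
) -> None:
    """Optional quick-look rendering of a map grid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = np.array(grid, dtype=float)
    if mask is not None:
        data = np.where(mask, data, np.nan)
    fig, ax = plt.subplots(figsize=(4, 4 * data.shape[0] / max(data.shape[1], 1)))
    im = ax.imshow(data, cmap=cmap, interpolation="nearest")
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_axis_off()
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
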