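"""Mass-univariate pixel-wise inference on subject-level body maps.

Every in-silhouette pixel gets an independent test across subjects -- a
one-sample t against zero, a paired t between matched conditions, or a
within-subject (repeated-measures) ANOVA F for factorial designs -- and the
resulting p-map is corrected with the Benjamini-Hochberg false-discovery-rate
procedure over the in-silhouette pixels of that map only.  Out-of-silhouette
pixels never enter the correction family.

Degenerate pixels are common in painting data (most background pixels are
exactly zero for every subject): zero-variance pixels with zero mean receive
stat 0 / p 1, while zero variance around a nonzero mean receives a signed
infinite-statistic sentinel with p 0 and is counted in ``n_flagged``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .silhouette import SilhouetteAtlas

__all__ = [
    "StatMap",
    "fdr_threshold",
    "one_sample_t_map",
    "paired_t_map",
    "rm_anova_map",
    "split_familiarity",
    "split_entropy",
    "summarize_regions",
    "dice",
]

_VAR_TOL = 1e-24


@dataclass(frozen=True)
class StatMap:
    """Pixel-wise test-statistic map with its FDR-corrected rejection set."""

    stat: np.ndarray  # t or F; signed for t, NaN outside the mask
    p: np.ndarray  # two-sided p, NaN outside the mask
    sig: np.ndarray  # boolean; True only inside the mask
    df: tuple[float, ...]  # (df,) for t, (df1, df2) for F
    q: float  # FDR level
    crit_p: float  # BH critical p (0 when nothing is rejected)
    n_subjects: int
    contrast: str  # human-readable label; for t maps, positive = first-named side
    mask: np.ndarray = field(repr=False)
    n_flagged: int = 0  # zero-variance / nonzero-mean sentinel pixels

    @property
    def n_sig(self) -> int:
        return int(self.sig.sum())


def fdr_threshold(p_values: np.ndarray, q: float) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up over a family of p-values.

    Sort ascending, find the largest k with p_(k) <= k q / m, and reject every
    test with p <= p_(k).  Returns (boolean rejection array aligned with the
    input, critical p), with an all-False set and critical p 0 when no k
    qualifies or the input is empty.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.sort(p)
    ok = order <= np.arange(1, m + 1) * q / m
    if not ok.any():
        return np.zeros(m, dtype=bool), 0.0
    crit = float(order[np.nonzero(ok)[0][-1]])
    return p <= crit, crit


def _finalize(
    stat_in: np.ndarray,
    p_in: np.ndarray,
    mask: np.ndarray,
    df: tuple[float, ...],
    q: float,
    n: int,
    contrast: str,
    n_flagged: int,
) -> StatMap:
    """Embed in-mask vectors into full grids and apply BH over the mask."""
    rej, crit = fdr_threshold(p_in, q)
    stat = np.full(mask.shape, np.nan)
    p = np.full(mask.shape, np.nan)
    sig = np.zeros(mask.shape, dtype=bool)
    stat[mask] = stat_in
    p[mask] = p_in
    sig[mask] = rej
    return StatMap(
        stat=stat, p=p, sig=sig, df=df, q=q, crit_p=crit,
        n_subjects=n, contrast=contrast, mask=mask, n_flagged=n_flagged,
    )


def _t_from_values(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized one-sample t of subject-by-pixel values against zero.

    Returns (t, two-sided p, flagged count) with the degenerate-pixel policy
    described in the module docstring.
    """
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    t = np.zeros(x.shape[1])
    p = np.ones(x.shape[1])
    live = sd**2 > _VAR_TOL
    t[live] = mean[live] / (sd[live] / np.sqrt(n))
    p[live] = 2.0 * stats.t.sf(np.abs(t[live]), n - 1)
    degenerate = ~live & (np.abs(mean) > 1e-12)
    t[degenerate] = np.sign(mean[degenerate]) * np.inf
    p[degenerate] = 0.0
    return t, p, int(degenerate.sum())


def _stack(maps: Sequence) -> np.ndarray:
    grids = [m.grid if hasattr(m, "grid") else np.asarray(m) for m in maps]
    return np.stack(grids, axis=0)


def one_sample_t_map(
    subject_maps: Sequence,
    atlas: SilhouetteAtlas,
    q: float = 0.05,
    contrast: str = "mean > 0",
) -> StatMap:
    """Pixel-wise one-sample t of per-subject maps against zero (df = n - 1)."""
    data = _stack(subject_maps)
    n = data.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if data.shape[1:] != atlas.dims:
        raise ValueError("map dims do not match the atlas")
    mask = atlas.mask
    t, p, flagged = _t_from_values(data[:, mask])
    return _finalize(t, p, mask, (float(n - 1),), q, n, contrast, flagged)


def paired_t_map(
    maps_a: Sequence,
    maps_b: Sequence,
    atlas: SilhouetteAtlas,
    q: float = 0.05,
    contrast: str = "a > b",
    subjects_a: Sequence | None = None,
    subjects_b: Sequence | None = None,
) -> StatMap:
    """Pixel-wise paired t on within-subject differences (positive = a > b)."""
    if len(maps_a) != len(maps_b):
        raise ValueError("paired collections must have equal length")
    if subjects_a is not None or subjects_b is not None:
        if list(subjects_a or []) != list(subjects_b or []):
            raise ValueError("subject identifiers of the two collections do not match")
    diff = _stack(maps_a) - _stack(maps_b)
    n = diff.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if diff.shape[1:] != atlas.dims:
        raise ValueError("map dims do not match the atlas")
    mask = atlas.mask
    t, p, flagged = _t_from_values(diff[:, mask])
    return _finalize(t, p, mask, (float(n - 1),), q, n, contrast, flagged)


def _f_ratio(ss_eff: np.ndarray, df_eff: int, ss_err: np.ndarray, df_err: int):
    """F, p and flag count with the zero-variance policy applied pixel-wise."""
    F = np.zeros_like(ss_eff)
    p = np.ones_like(ss_eff)
    ms_err = ss_err / df_err
    live = ms_err > _VAR_TOL
    F[live] = (ss_eff[live] / df_eff) / ms_err[live]
    p[live] = stats.f.sf(F[live], df_eff, df_err)
    degenerate = ~live & (ss_eff > 1e-12)
    F[degenerate] = np.inf
    p[degenerate] = 0.0
    return F, p, int(degenerate.sum())


def rm_anova_map(
    cell_maps: Mapping[tuple, np.ndarray],
    factors: Mapping[str, Sequence],
    atlas: SilhouetteAtlas,
    q: float = 0.05,
) -> dict[str, StatMap]:
    """Pixel-wise within-subject ANOVA over a full factorial of 1 or 2 factors.

    ``cell_maps`` maps (subject, level_a) or (subject, level_a, level_b) to a
    per-subject cell-mean grid; ``factors`` is an ordered mapping of one or
    two factor names to their level sequences.  Every subject must supply
    every cell (the classical univariate repeated-measures partitioning
    requires a balanced full crossing); missing cells raise a validation
    error naming them.

    Each effect is tested against its own effect-by-subject interaction
    stratum: F_A = MS_A / MS_{AxS}, df (a-1, (a-1)(n-1)); the two-factor form
    adds B and the AxB interaction with error stratum AxBxS.  No sphericity
    correction is applied.  Returns {effect name -> StatMap}; interaction key
    is "A:B".
    """
    names = list(factors)
    if len(names) not in (1, 2):
        raise ValueError("rm_anova_map supports 1 or 2 within-subject factors")
    levels = [list(factors[n]) for n in names]
    subjects = sorted({k[0] for k in cell_maps})
    n = len(subjects)
    if n < 3:
        raise ValueError("need at least 3 subjects")

    expected = [
        (s, *cell)
        for s in subjects
        for cell in (
            [(a,) for a in levels[0]]
            if len(names) == 1
            else [(a, b) for a in levels[0] for b in levels[1]]
        )
    ]
    missing = [k for k in expected if k not in cell_maps]
    if missing:
        raise ValueError(f"unbalanced design; missing cells: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))

    mask = atlas.mask
    a = len(levels[0])
    if len(names) == 1:
        # D[n, a, P]
        D = np.stack(
            [np.stack([cell_maps[(s, la)][mask] for la in levels[0]]) for s in subjects]
        )
        m = D.mean(axis=(0, 1))
        m_s = D.mean(axis=1)
        m_a = D.mean(axis=0)
        ss_a = n * ((m_a - m) ** 2).sum(axis=0)
        resid = D - m_s[:, None, :] - m_a[None, :, :] + m
        ss_as = (resid**2).sum(axis=(0, 1))
        df_a, df_as = a - 1, (a - 1) * (n - 1)
        F, p, fl = _f_ratio(ss_a, df_a, ss_as, df_as)
        return {
            names[0]: _finalize(
                F, p, mask, (float(df_a), float(df_as)), q, n, f"RM F: {names[0]}", fl
            )
        }

    b = len(levels[1])
    # D[n, a, b, P]
    D = np.stack(
        [
            np.stack(
                [
                    np.stack([cell_maps[(s, la, lb)][mask] for lb in levels[1]])
                    for la in levels[0]
                ]
            )
            for s in subjects
        ]
    )
    m = D.mean(axis=(0, 1, 2))
    m_s = D.mean(axis=(1, 2))  # [n, P]
    m_a = D.mean(axis=(0, 2))  # [a, P]
    m_b = D.mean(axis=(0, 1))  # [b, P]
    m_ab = D.mean(axis=0)  # [a, b, P]
    m_sa = D.mean(axis=2)  # [n, a, P]
    m_sb = D.mean(axis=1)  # [n, b, P]

    ss_a = n * b * ((m_a - m) ** 2).sum(axis=0)
    ss_b = n * a * ((m_b - m) ** 2).sum(axis=0)
    ss_ab = n * ((m_ab - m_a[:, None, :] - m_b[None, :, :] + m) ** 2).sum(axis=(0, 1))
    ss_as = b * ((m_sa - m_s[:, None, :] - m_a[None, :, :] + m) ** 2).sum(axis=(0, 1))
    ss_bs = a * ((m_sb - m_s[:, None, :] - m_b[None, :, :] + m) ** 2).sum(axis=(0, 1))
    resid = (
        D
        - m_sa[:, :, None, :]
        - m_sb[:, None, :, :]
        - m_ab[None, :, :, :]
        + m_s[:, None, None, :]
        + m_a[None, :, None, :]
        + m_b[None, None, :, :]
        - m
    )
    ss_abs = (resid**2).sum(axis=(0, 1, 2))

    out = {}
    specs = [
        (names[0], ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        (names[1], ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        (f"{names[0]}:{names[1]}", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
    ]
    for label, ss_eff, df_eff, ss_err, df_err in specs:
        F, p, fl = _f_ratio(ss_eff, df_eff, ss_err, df_err)
        out[label] = _finalize(
            F, p, mask, (float(df_eff), float(df_err)), q, n, f"RM F: {label}", fl
        )
    return out


def split_familiarity(stimulus_means: pd.Series) -> pd.Series:
    """Median split of stimulus-mean familiarity into 'low' / 'high'.

    Ties at the median go low.  With all means equal the high bin is empty
    and a warning is emitted.
    """
    means = pd.Series(stimulus_means, dtype=float)
    if len(means) < 2:
        raise ValueError("need at least 2 stimuli for a familiarity split")
    med = means.median()
    labels = pd.Series(np.where(means <= med, "low", "high"), index=means.index)
    if (labels == "high").sum() == 0:
        warnings.warn("all stimulus familiarity means tied; high bin is empty",
                      stacklevel=2)
    return labels


def split_entropy(stimulus_values: pd.Series) -> pd.Series:
    """Rank-based tertile split into 'low' / 'medium' / 'high'.

    Stimuli are ordered by value (stable for ties); the lowest n//3 go low,
    the highest n//3 go high, and any remainder stays in the middle bin.
    """
    vals = pd.Series(stimulus_values, dtype=float)
    n = len(vals)
    if n < 3:
        raise ValueError("need at least 3 stimuli for an entropy split")
    k = n // 3
    order = vals.sort_values(kind="stable").index
    labels = pd.Series("medium", index=vals.index, dtype=object)
    labels[order[:k]] = "low"
    labels[order[n - k:]] = "high"
    return labels


def summarize_regions(stat_map: StatMap, atlas: SilhouetteAtlas) -> pd.DataFrame:
    """Per-region summary of a significance map, ranked by significant count."""
    if stat_map.sig.shape != atlas.dims:
        raise ValueError("stat map dims do not match the atlas")
    rows = []
    for name in atlas.names:
        region = atlas.region_mask(name)
        sig = stat_map.sig & region
        n_sig = int(sig.sum())
        vals = stat_map.stat[sig]
        finite = vals[np.isfinite(vals)]
        rows.append(
            {
                "region": name,
                "n_pixels": int(region.sum()),
                "n_sig": n_sig,
                "frac_sig": n_sig / int(region.sum()),
                "mean_stat": float(np.abs(finite).mean()) if finite.size else np.nan,
                "peak_stat": float(np.abs(finite).max()) if finite.size else np.nan,
                "dominant_sign": (
                    int(np.sign(np.nansum(np.sign(vals)))) if n_sig else 0
                ),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["n_sig", "region"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )


def dice(set_a: np.ndarray, set_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); 0 when both sets are empty."""
    a = np.asarray(set_a, dtype=bool)
    b = np.asarray(set_b, dtype=bool)
    denom = int(a.sum()) + int(b.sum())
    return 2.0 * int((a & b).sum()) / denom if denom else 0.0
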