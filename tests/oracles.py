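"""Independent brute-force oracles for the pixel-wise statistics.

Deliberately written with explicit loops over cell means and raw
sums-of-squares formulas, sharing no code with the package implementation,
so agreement between the two routes is informative.
"""

from __future__ import annotations

import math

import numpy as np


def one_sample_t(values) -> tuple[float, float]:
    """(t, df) of a list of subject values against zero, from raw formulas."""
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean / math.sqrt(var / n), n - 1


def paired_t(a, b) -> tuple[float, float]:
    diffs = [x - y for x, y in zip(a, b)]
    return one_sample_t(diffs)


def rm_anova_2way(data: np.ndarray) -> dict:
    """Two-way within-subject ANOVA from sums of squares, loop-based.

    ``data`` has shape (n_subjects, a, b) with one observation per cell.
    Returns {effect: (F, df1, df2)} for 'A', 'B' and 'A:B', each tested
    against its effect-by-subject interaction stratum.
    """
    n, a, b = data.shape
    grand = data.sum() / data.size
    m_s = [data[s].sum() / (a * b) for s in range(n)]
    m_a = [data[:, i, :].sum() / (n * b) for i in range(a)]
    m_b = [data[:, :, j].sum() / (n * a) for j in range(b)]
    m_ab = [[data[:, i, j].sum() / n for j in range(b)] for i in range(a)]
    m_sa = [[data[s, i, :].sum() / b for i in range(a)] for s in range(n)]
    m_sb = [[data[s, :, j].sum() / a for j in range(b)] for s in range(n)]

    ss_a = n * b * sum((m - grand) ** 2 for m in m_a)
    ss_b = n * a * sum((m - grand) ** 2 for m in m_b)
    ss_ab = n * sum(
        (m_ab[i][j] - m_a[i] - m_b[j] + grand) ** 2 for i in range(a) for j in range(b)
    )
    ss_as = b * sum(
        (m_sa[s][i] - m_s[s] - m_a[i] + grand) ** 2 for s in range(n) for i in range(a)
    )
    ss_bs = a * sum(
        (m_sb[s][j] - m_s[s] - m_b[j] + grand) ** 2 for s in range(n) for j in range(b)
    )
    ss_abs = sum(
        (
            data[s, i, j]
            - m_sa[s][i]
            - m_sb[s][j]
            - m_ab[i][j]
            + m_s[s]
            + m_a[i]
            + m_b[j]
            - grand
        )
        ** 2
        for s in range(n)
        for i in range(a)
        for j in range(b)
    )

    out = {}
    for name, ss_eff, df_eff, ss_err, df_err in [
        ("A", ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        ("B", ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        ("A:B", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
    ]:
        if df_eff > 0 and df_err > 0:
            out[name] = ((ss_eff / df_eff) / (ss_err / df_err), df_eff, df_err)
    return out


def bh_reject(p_values, q) -> tuple[list, float]:
    """Benjamini-Hochberg by direct enumeration of every threshold."""
    m = len(p_values)
    indexed = sorted(range(m), key=lambda i: p_values[i])
    crit, found = 0.0, False
    for rank, i in enumerate(indexed, start=1):
        if p_values[i] <= rank * q / m:
            crit, found = p_values[i], True
    return [p <= crit if found else False for p in p_values], crit
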