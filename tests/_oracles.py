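"""Independent brute-force oracles used by the test suite.

Everything here recomputes quantities from first principles (grid searches,
exhaustive enumeration, explicit arithmetic) without touching the library's
own code paths, so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import itertools

import numpy as np


def grid_min_residual(target, reference, allow_scale: bool, step: float = 0.001) -> float:
    """Minimum Procrustes residual over a brute-force grid of rotation angles.

    Both shapes are centered (and reduced to unit centroid size in scale
    mode); at each grid angle the residual is evaluated directly, with the
    least-squares size factor applied analytically in scale mode.
    """
    tgt = np.asarray(target, float)
    ref = np.asarray(reference, float)
    tgt = tgt - tgt.mean(axis=0)
    ref = ref - ref.mean(axis=0)
    if allow_scale:
        tgt = tgt / np.sqrt((tgt ** 2).sum())
        ref = ref / np.sqrt((ref ** 2).sum())

    thetas = np.arange(0.0, 2 * np.pi, step)
    cos, sin = np.cos(thetas), np.sin(thetas)
    # rotated target coords for all angles: (n_angles, n_points, 2)
    x, y = tgt[:, 0], tgt[:, 1]
    rx = cos[:, None] * x - sin[:, None] * y
    ry = sin[:, None] * x + cos[:, None] * y
    if allow_scale:
        # optimal beta per angle: beta = sum(ref . R t) (unit-size shapes)
        beta = rx @ ref[:, 0] + ry @ ref[:, 1]
        beta = np.clip(beta, 0.0, None)
        resid = 1.0 - beta ** 2
    else:
        resid = ((rx - ref[:, 0]) ** 2 + (ry - ref[:, 1]) ** 2).sum(axis=1)
    return float(resid.min())


def mw_u_statistic(x, y) -> float:
    """min(U_x, U_y) by direct pair counting."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    u_x = sum(1.0 if xi > yi else (0.5 if xi == yi else 0.0) for xi in x for yi in y)
    return min(u_x, len(x) * len(y) - u_x)


def mw_exact_pvalue(x, y) -> float:
    """Exact two-sided Mann-Whitney p by exhaustive enumeration of all
    C(n+m, n) assignments of the pooled ranks (no ties): doubled min-tail
    probability of U, capped at 1."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, m = len(x), len(y)
    total = n + m
    offset = n * (n + 1) / 2.0

    pooled = np.sort(np.concatenate([x, y]))
    assert np.unique(pooled).size == total, "enumeration oracle assumes no ties"
    ranks_x = np.searchsorted(pooled, np.sort(x)) + 1
    u_obs = ranks_x.sum() - offset
    u_min = min(u_obs, n * m - u_obs)

    count_le = 0
    n_combos = 0
    for combo in itertools.combinations(range(1, total + 1), n):
        u = sum(combo) - offset
        if u <= u_min + 1e-9:
            count_le += 1
        n_combos += 1
    # doubled lower-tail probability of U (symmetric around nm/2), capped
    return min(1.0, 2.0 * count_le / n_combos)


def pearson_chi2(table) -> tuple[float, int]:
    """Pearson chi-square statistic and df via explicit margin arithmetic."""
    t = np.asarray(table, float)
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    expected = row @ col / t.sum()
    stat = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return stat, df


def one_way_anova_f(groups) -> float:
    """One-way ANOVA F by the textbook sum-of-squares decomposition."""
    groups = [np.asarray(g, float) for g in groups]
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = len(all_vals) - len(groups)
    return float((ss_between / df_between) / (ss_within / df_within))
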