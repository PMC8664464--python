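"""Left-right head asymmetry by fold-and-compare Procrustes (object symmetry),
plus side comparison of appendage lengths.

A head is compared with its own mirror image: the configuration is mirrored
across the facial midline, each left landmark label is swapped with its right
partner, and the original and reflected copies are superimposed by an
ordinary Procrustes fit. The residual sum of squared landmark distances
(D_sym) measures fluctuating asymmetry; a perfectly bilaterally symmetric
head scores zero.

D_sym is reported alongside a percent-correlation score,
``100 * sqrt(1 - m^2)`` with ``m^2`` the full-Procrustes residual between
the unit-size original and its reflection (the correlation statistic of the
PROTEST procedure). 100 means perfect symmetry; the score decreases
monotonically as D_sym grows.

Appendages (T1 legs, forewings) have scalar lengths per side; their
|left - right| differences are compared across groups by one-way ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .landmark_io import AppendageLengths, LandmarkConfiguration
from .procrustes import procrustes_distance
from .stats import TestResult

__all__ = [
    "SymmetryResult",
    "AsymmetrySummary",
    "reflect_relabel",
    "symmetry_score",
    "score_cohort",
    "compare_symmetry",
    "appendage_asymmetry",
]


@dataclass
class SymmetryResult:
    specimen_id: str
    d_sym: float
    correlation_pct: float
    group: str | None = None


@dataclass
class AsymmetrySummary:
    group_stats: pd.DataFrame  # group, n, mean/sd of d_sym and correlation_pct
    tests: list[TestResult]


def reflect_relabel(c: LandmarkConfiguration) -> LandmarkConfiguration:
    """Mirror a configuration across its facial midline and swap side labels.

    The midline is the axis through the two unpaired landmarks (median
    ocellus, mandible center): the configuration is rotated so that axis is
    vertical, x is negated about the axis, the rotation is undone, and each
    left label is exchanged with its right partner. An involution, and an
    isometry, so centroid size is preserved exactly; residual misalignment of
    the mirror axis is absorbed downstream by the Procrustes fit.
    """
    scheme = c.scheme
    if not scheme.paired or len(scheme.midline) != 2:
        raise ValueError("scheme lacks left/right pairing information")

    m0 = c.coord(scheme.midline[0])
    m1 = c.coord(scheme.midline[1])
    axis = m1 - m0
    if np.allclose(axis, 0):
        raise ValueError("midline landmarks coincide; reflection axis undefined")

    # Rotate so the midline axis lies along +y.
    phi = np.arctan2(axis[0], axis[1])  # angle of axis from the +y direction
    rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    pivot = (m0 + m1) / 2.0
    local = (c.coords - pivot) @ rot.T  # midline now at x = 0 through origin

    mirrored = local.copy()
    mirrored[:, 0] = -mirrored[:, 0]
    restored = mirrored @ rot + pivot

    out = restored.copy()
    for left, right in scheme.paired:
        i, j = scheme.index(left), scheme.index(right)
        out[i], out[j] = restored[j].copy(), restored[i].copy()

    return c.with_coords(out)


def symmetry_score(c: LandmarkConfiguration, group: str | None = None) -> SymmetryResult:
    """Score one head: D_sym and percent correlation between its sides.

    D_sym is the full-Procrustes residual (scaling enabled) between the
    configuration and its reflected-relabeled copy; because both copies are
    at unit centroid size the residual is already normalized by the shape's
    total landmark variance, so ``correlation_pct = 100 * sqrt(1 - D_sym)``.
    """
    reflected = reflect_relabel(c)
    d_sym = procrustes_distance(c, reflected, allow_scale=True)
    if d_sym < 1e-12:  # snap float dust so symmetric heads score exactly 0 / 100
        d_sym = 0.0
    m2 = min(max(d_sym, 0.0), 1.0)
    corr = 100.0 * float(np.sqrt(1.0 - m2))
    return SymmetryResult(
        specimen_id=c.specimen_id,
        d_sym=d_sym,
        correlation_pct=corr,
        group=group if group is not None else c.group,
    )


def score_cohort(configs: Sequence[LandmarkConfiguration]) -> pd.DataFrame:
    """Per-specimen symmetry table: specimen_id, group, d_sym, correlation_pct."""
    rows = [symmetry_score(c) for c in configs]
    return pd.DataFrame(
        {
            "specimen_id": [r.specimen_id for r in rows],
            "group": [r.group for r in rows],
            "d_sym": [r.d_sym for r in rows],
            "correlation_pct": [r.correlation_pct for r in rows],
        }
    )


def _welch(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Welch t on possibly zero-variance samples.

    Degenerate rule: if both variances vanish, p -> 0 when the means differ
    (t = +/-inf) and (t, p) = (0, 1) when they coincide.
    """
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        return float(np.sign(np.mean(x) - np.mean(y)) * np.inf), 0.0
    t, p = sps.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def compare_symmetry(
    groups: Mapping[str, Sequence[SymmetryResult]],
    pairs: Sequence[tuple[str, str]] | None = None,
) -> AsymmetrySummary:
    """Welch two-sample t-tests on per-specimen D_sym between group pairs.

    ``pairs`` defaults to every unordered pair of groups. Each group needs
    n >= 2.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, rows in groups.items():
        if len(rows) < 2:
            raise ValueError(f"group {g!r} has n < 2")

    names = list(groups)
    if pairs is None:
        pairs = [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]

    stats_rows = []
    for g, rows in groups.items():
        d = np.array([r.d_sym for r in rows])
        corr = np.array([r.correlation_pct for r in rows])
        stats_rows.append(
            {
                "group": g,
                "n": len(rows),
                "d_sym_mean": d.mean(),
                "d_sym_sd": d.std(ddof=1),
                "correlation_mean": corr.mean(),
                "correlation_sd": corr.std(ddof=1),
            }
        )

    tests = []
    for a, b in pairs:
        xa = np.array([r.d_sym for r in groups[a]])
        xb = np.array([r.d_sym for r in groups[b]])
        t, p = _welch(xa, xb)
        tests.append(
            TestResult(
                name=f"{a} vs {b}",
                test="welch-t",
                statistic=t,
                p_raw=p,
                group_sizes=(xa.size, xb.size),
            )
        )
    return AsymmetrySummary(group_stats=pd.DataFrame(stats_rows), tests=tests)


def appendage_asymmetry(
    rows: Sequence[AppendageLengths],
    groups: Mapping[str, str] | None = None,
    use_signed: bool = False,
) -> pd.DataFrame:
    """One-way ANOVA of left-right length differences across groups, per part.

    The response is |left - right| by default (the magnitude of asymmetry;
    signed differences via ``use_signed``). Returns one row per part with the
    F statistic, p-value and group sizes. If every difference is identical
    (zero between-group and within-group variance) the F statistic is
    reported as 0 with p = 1.
    """
    records = []
    for r in rows:
        group = groups.get(r.specimen_id) if groups is not None else r.group
        if group is None:
            raise ValueError(f"no group label for specimen {r.specimen_id!r}")
        diff = r.signed_difference if use_signed else abs(r.signed_difference)
        records.append({"specimen_id": r.specimen_id, "part": r.part, "group": group, "diff": diff})
    df = pd.DataFrame(records)
    if df.empty:
        raise ValueError("no appendage rows")

    out = []
    for part, sub in df.groupby("part", sort=False):
        samples = [g["diff"].to_numpy() for _, g in sub.groupby("group", sort=False)]
        if len(samples) < 2:
            raise ValueError(f"part {part!r}: need at least two groups")
        if np.allclose(np.concatenate(samples), np.concatenate(samples)[0]):
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = sps.f_oneway(*samples)
        out.append(
            {
                "part": part,
                "F": float(f_stat),
                "p": float(p),
                "n_groups": len(samples),
                "n_total": int(sub.shape[0]),
            }
        )
    return pd.DataFrame(out)
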