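"""Procrustes superimposition of 2-D landmark configurations.

Ordinary Procrustes fits translate both shapes to the origin, optionally
rescale to unit centroid size, and rotate by the least-squares optimal
*proper* rotation (reflections are excluded — a silent reflection would
destroy the left/right symmetry analysis; the symmetry module applies its
mirror explicitly). Generalized Procrustes analysis (GPA) iterates the fit
against a consensus to produce a mean shape, as used for the superimposed
wireframe comparison of species mean heads.

The Procrustes distance is the residual sum of squared distances between
corresponding landmarks after the optimal fit. In scale mode the fit also
includes the least-squares size factor (full Procrustes), so the distance
between unit-size shapes is 1 - r^2 with r the Procrustes correlation; this
is the normalization behind the percent-symmetry score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .landmark_io import LandmarkConfiguration, LandmarkScheme, centroid_size

__all__ = [
    "AlignedShape",
    "MeanShape",
    "align_pair",
    "procrustes_distance",
    "gpa",
    "wireframe_export",
    "DEFAULT_WIREFRAME",
]


@dataclass
class AlignedShape:
    """A configuration after centering, (optional) unit scaling and rotation.

    ``centroid_size`` records the size before any rescaling.
    """

    coords: np.ndarray
    centroid_size: float
    specimen_id: str


@dataclass
class MeanShape:
    """GPA consensus: unit centroid size, a fixed point of the alignment step."""

    coords: np.ndarray
    n_specimens: int
    converged: bool
    iterations: int
    scheme: LandmarkScheme | None = None


def _as_coords(shape) -> tuple[np.ndarray, str]:
    if isinstance(shape, LandmarkConfiguration):
        return np.asarray(shape.coords, dtype=float), shape.specimen_id
    if isinstance(shape, (AlignedShape, MeanShape)):
        return np.asarray(shape.coords, dtype=float), getattr(shape, "specimen_id", "mean")
    return np.asarray(shape, dtype=float), "array"


def _center_scale(coords: np.ndarray, allow_scale: bool) -> tuple[np.ndarray, float]:
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centered ** 2).sum()))
    if cs <= 0:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return (centered / cs if allow_scale else centered), cs


def _rotation_terms(reference: np.ndarray, target: np.ndarray) -> tuple[float, float]:
    """P, Q such that sum_i ref_i . R(theta) tgt_i = P cos(theta) + Q sin(theta)."""
    ax, ay = reference[:, 0], reference[:, 1]
    bx, by = target[:, 0], target[:, 1]
    p = float(np.sum(ax * bx + ay * by))
    q = float(np.sum(ay * bx - ax * by))
    return p, q


def _rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def align_pair(target, reference, allow_scale: bool = True):
    """Ordinary Procrustes fit of ``target`` onto ``reference``.

    Returns ``(AlignedShape, rotation_angle, residual)``. The rotation is the
    least-squares optimal proper rotation (no reflection). With
    ``allow_scale`` both shapes are reduced to unit centroid size and the
    residual additionally includes the least-squares size factor beta, giving
    the full Procrustes distance 1 - r^2; the returned coordinates are kept
    at unit centroid size. Without scaling the residual is the plain sum of
    squared landmark distances after centering and rotation.
    """
    tgt, tgt_id = _as_coords(target)
    ref, _ = _as_coords(reference)
    if tgt.shape != ref.shape:
        raise ValueError(f"shape mismatch: {tgt.shape} vs {ref.shape}")

    tgt_c, tgt_cs = _center_scale(tgt, allow_scale)
    ref_c, _ = _center_scale(ref, allow_scale)

    p, q = _rotation_terms(ref_c, tgt_c)
    theta = float(np.arctan2(q, p))
    r = float(np.hypot(p, q))  # max of P cos + Q sin over proper rotations

    rotated = tgt_c @ _rot(theta).T
    if allow_scale:
        # unit-size shapes: ||beta R t - ref||^2 minimized at beta = r
        residual = max(0.0, 1.0 - r * r)
    else:
        residual = float((tgt_c ** 2).sum() + (ref_c ** 2).sum() - 2.0 * r)
        residual = max(0.0, residual)

    return AlignedShape(coords=rotated, centroid_size=tgt_cs, specimen_id=tgt_id), theta, residual


def procrustes_distance(a, b, allow_scale: bool = True) -> float:
    """Residual sum of squared inter-landmark distances after the optimal fit.

    Symmetric in its arguments, zero iff the shapes coincide up to the
    allowed transformations (translation, rotation, and size in scale mode).
    """
    _, _, residual = align_pair(a, b, allow_scale=allow_scale)
    return residual


def gpa(
    shapes: Sequence,
    tol: float = 1e-8,
    max_iter: int = 100,
    allow_scale: bool = True,
):
    """Generalized Procrustes analysis.

    Iteratively rotates every (centered, unit-size) shape onto the current
    consensus and recomputes the consensus as the coordinate-wise mean,
    rescaled to unit centroid size, until the consensus moves less than
    ``tol`` (root summed squared coordinate change) or ``max_iter`` passes.

    Returns ``(MeanShape, list[AlignedShape])``.
    """
    if len(shapes) < 2:
        raise ValueError("GPA requires at least 2 shapes")

    coords, ids, sizes = [], [], []
    scheme = None
    for s in shapes:
        c, sid = _as_coords(s)
        if isinstance(s, LandmarkConfiguration):
            if scheme is None:
                scheme = s.scheme
            elif s.scheme != scheme:
                raise ValueError("all shapes must share one landmark scheme")
        centered, cs = _center_scale(c, allow_scale)
        coords.append(centered)
        ids.append(sid)
        sizes.append(cs)

    consensus = coords[0].copy()
    consensus /= np.sqrt((consensus ** 2).sum())

    aligned = list(coords)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        aligned = []
        for c in coords:
            p, q = _rotation_terms(consensus, c)
            aligned.append(c @ _rot(np.arctan2(q, p)).T)
        new_consensus = np.mean(aligned, axis=0)
        norm = np.sqrt((new_consensus ** 2).sum())
        if norm <= 0:
            raise ValueError("degenerate consensus (shapes cancel)")
        new_consensus /= norm
        change = float(np.sqrt(((new_consensus - consensus) ** 2).sum()))
        consensus = new_consensus
        if change < tol:
            converged = True
            break

    mean = MeanShape(
        coords=consensus,
        n_specimens=len(shapes),
        converged=converged,
        iterations=iterations,
        scheme=scheme,
    )
    aligned_shapes = [
        AlignedShape(coords=a, centroid_size=cs, specimen_id=sid)
        for a, cs, sid in zip(aligned, sizes, ids)
    ]
    return mean, aligned_shapes


#: Edges for the standard head wireframe: ocellar triangle, eye outlines,
#: cheeks and the midline axis.
DEFAULT_WIREFRAME = (
    ("median-ocellus", "lateral-ocellus-L"),
    ("median-ocellus", "lateral-ocellus-R"),
    ("lateral-ocellus-L", "lateral-ocellus-R"),
    ("eye-top-L", "eye-arc-L"),
    ("eye-arc-L", "eye-bottom-L"),
    ("eye-top-R", "eye-arc-R"),
    ("eye-arc-R", "eye-bottom-R"),
    ("eye-bottom-L", "cheek-arc-L"),
    ("eye-bottom-R", "cheek-arc-R"),
    ("cheek-arc-L", "mandible-center"),
    ("cheek-arc-R", "mandible-center"),
    ("mio-L", "mio-R"),
    ("antennal-socket-L", "antennal-socket-R"),
    ("median-ocellus", "mandible-center"),
)


def wireframe_export(
    mean: MeanShape,
    edges: Sequence[tuple[str, str]] = DEFAULT_WIREFRAME,
    scheme: LandmarkScheme | None = None,
) -> list[tuple[str, str, np.ndarray, np.ndarray]]:
    """Segment list ``(label_a, label_b, point_a, point_b)`` in consensus
    coordinates, for overlaying species mean shapes."""
    scheme = scheme or mean.scheme
    if scheme is None:
        raise ValueError("a landmark scheme is required to resolve edge labels")
    segments = []
    for a, b in edges:
        ia, ib = scheme.index(a), scheme.index(b)
        segments.append((a, b, mean.coords[ia].copy(), mean.coords[ib].copy()))
    return segments
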