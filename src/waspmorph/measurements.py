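"""The seven linear head measures and their size-normalized ratios.

Head shape is summarized by five dimensionless ratios: MHW/HL, OIO/HL,
MIO/HL and AIO/HL normalize the width measures against head length, and
FEP/FE normalizes cheek size. Normalization removes natural variation in
overall body size, leaving shape.

Measures
--------
MHW : maximum head width
HL  : head length
OIO : interocular distance through the ocelli
MIO : maximum interocular distance
AIO : interocular distance across the antennal sockets
FE  : distance from the bottom of the eye to the center of the mandible
FEP : farthest point on the cheek, measured perpendicular to the line FE
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .landmark_io import LandmarkConfiguration

__all__ = [
    "HeadMeasurements",
    "NormalizedRatios",
    "RATIO_NAMES",
    "compute_ratios",
    "measures_from_landmarks",
    "fe_fep_per_side",
    "group_ratio_summary",
]

RATIO_NAMES = ("MHW_HL", "OIO_HL", "MIO_HL", "AIO_HL", "FEP_FE")


@dataclass(frozen=True)
class HeadMeasurements:
    specimen_id: str
    MHW: float
    HL: float
    OIO: float
    MIO: float
    AIO: float
    FE: float
    FEP: float
    group: str | None = None
    sex: str | None = None
    oio_is_proxy: bool = False

    def __post_init__(self):
        for name in ("MHW", "HL", "OIO", "MIO", "AIO", "FE", "FEP"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.AIO > self.MIO + 1e-12:
            raise ValueError(
                f"AIO ({self.AIO}) exceeds MIO ({self.MIO}); antennal width cannot "
                "exceed the maximum interocular width"
            )


@dataclass(frozen=True)
class NormalizedRatios:
    specimen_id: str
    MHW_HL: float
    OIO_HL: float
    MIO_HL: float
    AIO_HL: float
    FEP_FE: float
    group: str | None = None
    sex: str | None = None

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in RATIO_NAMES}


def compute_ratios(m: HeadMeasurements) -> NormalizedRatios:
    """Size-normalized shape ratios: four widths over HL, plus FEP over FE."""
    if m.HL == 0 or m.FE == 0:
        raise ZeroDivisionError("HL and FE must be nonzero to form ratios")
    return NormalizedRatios(
        specimen_id=m.specimen_id,
        MHW_HL=m.MHW / m.HL,
        OIO_HL=m.OIO / m.HL,
        MIO_HL=m.MIO / m.HL,
        AIO_HL=m.AIO / m.HL,
        FEP_FE=m.FEP / m.FE,
        group=m.group,
        sex=m.sex,
    )


def _dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def _point_line_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Perpendicular distance from point p to the line through a and b."""
    p, a, b = (np.asarray(v, float) for v in (p, a, b))
    d = b - a
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("degenerate line: endpoints coincide")
    return float(abs(d[0] * (p[1] - a[1]) - d[1] * (p[0] - a[0])) / n)


def fe_fep_per_side(c: LandmarkConfiguration) -> dict[str, tuple[float, float]]:
    """Per-side (FE, FEP): FE from eye bottom to mandible center, FEP the
    perpendicular offset of the cheek arc from that line. Retained per side
    for asymmetry work; ratio reporting averages the sides."""
    mandible = c.coord("mandible-center")
    out = {}
    for side in ("L", "R"):
        eye_bottom = c.coord(f"eye-bottom-{side}")
        cheek = c.coord(f"cheek-arc-{side}")
        fe = _dist(eye_bottom, mandible)
        fep = _point_line_distance(cheek, eye_bottom, mandible)
        out[side] = (fe, fep)
    return out


def measures_from_landmarks(
    c: LandmarkConfiguration,
    aux: Mapping[str, Sequence[float]] | None = None,
) -> HeadMeasurements:
    """Derive the seven measures from a 16-landmark configuration.

    MIO and AIO are inter-landmark distances (MIO endpoints, antennal
    sockets). FE and FEP are computed per side and averaged. MHW and HL
    endpoints are not among the 16 landmarks and must be supplied in ``aux``
    as points ``head_left``/``head_right`` and ``head_top``/``head_bottom``.

    OIO: the true endpoints (eye margins at ocellus height) are outline
    points; when ``aux`` lacks ``oio_left``/``oio_right`` the
    lateral-ocellus-to-lateral-ocellus distance is used and the result is
    flagged ``oio_is_proxy``.
    """
    aux = dict(aux or {})

    missing = []
    for measure, keys in (("MHW", ("head_left", "head_right")), ("HL", ("head_top", "head_bottom"))):
        if any(k not in aux for k in keys):
            missing.append(measure)
    if missing:
        raise ValueError(
            f"aux endpoints required for measure(s): {', '.join(missing)} "
            "(supply head_left/head_right and head_top/head_bottom)"
        )

    mhw = _dist(aux["head_left"], aux["head_right"])
    hl = _dist(aux["head_top"], aux["head_bottom"])

    if "oio_left" in aux and "oio_right" in aux:
        oio = _dist(aux["oio_left"], aux["oio_right"])
        proxy = False
    else:
        oio = _dist(c.coord("lateral-ocellus-L"), c.coord("lateral-ocellus-R"))
        proxy = True

    mio = _dist(c.coord("mio-L"), c.coord("mio-R"))
    aio = _dist(c.coord("antennal-socket-L"), c.coord("antennal-socket-R"))

    per_side = fe_fep_per_side(c)
    fe = float(np.mean([per_side["L"][0], per_side["R"][0]]))
    fep = float(np.mean([per_side["L"][1], per_side["R"][1]]))

    return HeadMeasurements(
        specimen_id=c.specimen_id,
        MHW=mhw, HL=hl, OIO=oio, MIO=mio, AIO=aio, FE=fe, FEP=fep,
        group=c.group, sex=c.sex, oio_is_proxy=proxy,
    )


def group_ratio_summary(rows: Sequence[NormalizedRatios]) -> pd.DataFrame:
    """Per-group mean, unbiased SD (n-1) and n for each ratio.

    Mirrors the supplementary-table layout: one row per (group, sex), columns
    n plus mean/sd per ratio. Groups of size 1 report SD as NaN (undefined).
    """
    if len(rows) == 0:
        raise ValueError("no ratio rows to summarize")
    df = pd.DataFrame(
        [
            {"group": r.group, "sex": r.sex, **r.as_dict()}
            for r in rows
        ]
    )
    grouped = df.groupby(["group", "sex"], dropna=False)
    pieces = {"n": grouped.size()}
    for name in RATIO_NAMES:
        pieces[f"{name}_mean"] = grouped[name].mean()
        pieces[f"{name}_sd"] = grouped[name].std(ddof=1)
    return pd.DataFrame(pieces).reset_index()
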