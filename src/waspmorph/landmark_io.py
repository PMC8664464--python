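"""Landmark and measurement I/O for the 16-landmark *Nasonia* head scheme.

Heads are digitized at 16 named landmarks: one at each ocellus (median plus
two lateral), the top, bottom and maximum arc of each compound eye, the
maximum arc of each cheek (gena), both ends of the maximum interocular
distance (MIO), the two antennal sockets, and the center of the mandible.
Seven of these come in anatomical left/right pairs; the median ocellus and
the mandible center sit on the facial midline.

Landmarks arrive as 2-D coordinates in TPS files (the standard morphometrics
interchange format) or are built programmatically; digitizing replicates of
the same head are averaged landmark-wise before analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkScheme",
    "LandmarkConfiguration",
    "AppendageLengths",
    "DEFAULT_HEAD_SCHEME",
    "SchemeMismatchError",
    "TPSParseError",
    "read_tps",
    "write_tps",
    "average_replicates",
    "read_measurements_csv",
    "read_appendages_csv",
    "centroid_size",
]


class SchemeMismatchError(ValueError):
    """Landmark data does not fit the declared landmark scheme."""


class TPSParseError(ValueError):
    """Malformed TPS file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class LandmarkScheme:
    """Named landmark layout: 7 anatomical (left, right) pairs + 2 midline points.

    Left/right is the specimen's own (anatomical) side, fixed by label — it is
    never inferred from coordinates, which would fail on deformed hybrid heads.
    """

    names: tuple[str, ...]
    paired: tuple[tuple[str, str], ...]
    midline: tuple[str, str]

    def __post_init__(self):
        names = tuple(self.names)
        paired = tuple(tuple(p) for p in self.paired)
        midline = tuple(self.midline)
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "paired", paired)
        object.__setattr__(self, "midline", midline)
        if len(names) != 16:
            raise SchemeMismatchError(f"scheme must have 16 landmarks, got {len(names)}")
        if len(set(names)) != len(names):
            raise SchemeMismatchError("landmark labels must be unique")
        if len(paired) != 7 or len(midline) != 2:
            raise SchemeMismatchError("scheme must have 7 left/right pairs and 2 midline landmarks")
        in_pairs = [lbl for pair in paired for lbl in pair]
        if len(set(in_pairs)) != 14:
            raise SchemeMismatchError("paired labels must be distinct")
        covered = set(in_pairs) | set(midline)
        if covered != set(names) or set(midline) & set(in_pairs):
            raise SchemeMismatchError("pairs + midline must partition the 16 labels")

    @property
    def n_landmarks(self) -> int:
        return len(self.names)

    def index(self, label: str) -> int:
        try:
            return self.names.index(label)
        except ValueError:
            raise KeyError(f"unknown landmark label {label!r}") from None

    def partner(self, label: str) -> str | None:
        """Contralateral partner of a paired label; None for midline labels."""
        for left, right in self.paired:
            if label == left:
                return right
            if label == right:
                return left
        if label in self.midline:
            return None
        raise KeyError(f"unknown landmark label {label!r}")

    @property
    def left_labels(self) -> tuple[str, ...]:
        return tuple(left for left, _ in self.paired)

    @property
    def right_labels(self) -> tuple[str, ...]:
        return tuple(right for _, right in self.paired)


#: Default head scheme. Pair order mirrors the digitizing protocol: lateral
#: ocelli, eye tops/bottoms/arcs, cheek arcs, MIO endpoints, antennal sockets.
DEFAULT_HEAD_SCHEME = LandmarkScheme(
    names=(
        "median-ocellus",
        "lateral-ocellus-L", "lateral-ocellus-R",
        "eye-top-L", "eye-top-R",
        "eye-bottom-L", "eye-bottom-R",
        "eye-arc-L", "eye-arc-R",
        "cheek-arc-L", "cheek-arc-R",
        "mio-L", "mio-R",
        "antennal-socket-L", "antennal-socket-R",
        "mandible-center",
    ),
    paired=(
        ("lateral-ocellus-L", "lateral-ocellus-R"),
        ("eye-top-L", "eye-top-R"),
        ("eye-bottom-L", "eye-bottom-R"),
        ("eye-arc-L", "eye-arc-R"),
        ("cheek-arc-L", "cheek-arc-R"),
        ("mio-L", "mio-R"),
        ("antennal-socket-L", "antennal-socket-R"),
    ),
    midline=("median-ocellus", "mandible-center"),
)


def centroid_size(coords: np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark distances from the centroid."""
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt((centered ** 2).sum()))


@dataclass
class LandmarkConfiguration:
    """One specimen's landmark coordinates (a single replicate, or averaged).

    Coordinates are in image units with arbitrary scale, y-up (mathematical
    convention); rows follow ``scheme.names`` order.
    """

    specimen_id: str
    coords: np.ndarray
    scheme: LandmarkScheme = DEFAULT_HEAD_SCHEME
    replicate_index: int | str = 0
    species: str | None = None
    sex: str | None = None
    ploidy: str | None = None
    group: str | None = None

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (self.scheme.n_landmarks, 2):
            raise SchemeMismatchError(
                f"specimen {self.specimen_id!r}: expected coords of shape "
                f"({self.scheme.n_landmarks}, 2), got {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"specimen {self.specimen_id!r}: non-finite coordinates")
        if centroid_size(coords) <= 0:
            raise ValueError(f"specimen {self.specimen_id!r}: degenerate (zero centroid size)")
        self.coords = coords

    def coord(self, label: str) -> np.ndarray:
        return self.coords[self.scheme.index(label)]

    @property
    def centroid_size(self) -> float:
        return centroid_size(self.coords)

    def with_coords(self, coords: np.ndarray, **changes) -> "LandmarkConfiguration":
        return replace(self, coords=np.asarray(coords, dtype=float), **changes)


@dataclass
class AppendageLengths:
    """Left/right length replicates for one appendage (T1 leg or forewing)."""

    specimen_id: str
    part: str  # "T1-leg" | "forewing"
    left_replicates: tuple[float, ...]
    right_replicates: tuple[float, ...]
    group: str | None = None

    def __post_init__(self):
        self.left_replicates = tuple(float(v) for v in self.left_replicates)
        self.right_replicates = tuple(float(v) for v in self.right_replicates)
        for side, reps in (("left", self.left_replicates), ("right", self.right_replicates)):
            if len(reps) < 1:
                raise ValueError(f"{self.specimen_id}/{self.part}: no {side} replicates")
            if any(v <= 0 for v in reps):
                raise ValueError(f"{self.specimen_id}/{self.part}: non-positive {side} length")

    @property
    def left(self) -> float:
        return float(np.mean(self.left_replicates))

    @property
    def right(self) -> float:
        return float(np.mean(self.right_replicates))

    @property
    def signed_difference(self) -> float:
        return self.left - self.right


# ---------------------------------------------------------------------------
# TPS files
# ---------------------------------------------------------------------------

def read_tps(
    path,
    scheme: LandmarkScheme = DEFAULT_HEAD_SCHEME,
    *,
    flip_y: bool = False,
) -> list[LandmarkConfiguration]:
    """Read a TPS landmark file into one configuration per specimen block.

    Accepts ``LM=``, ``ID=``, ``IMAGE=`` and ``SCALE=`` keys. ``SCALE``
    multiplies the block's coordinates. ``flip_y=True`` negates y for files
    digitized with an image-origin (y-down) convention; the default assumes
    mathematical y-up. A silent mirror-flip would corrupt the left/right
    symmetry analysis, hence the explicit flag.
    """
    text = Path(path).read_text()
    configs: list[LandmarkConfiguration] = []

    block_coords: list[list[float]] | None = None
    block_lm = 0
    block_id: str | None = None
    block_scale = 1.0
    block_start = 0

    def close_block(lineno: int):
        nonlocal block_coords, block_id, block_scale
        if block_coords is None:
            return
        if len(block_coords) != block_lm:
            raise TPSParseError(
                f"block declares LM={block_lm} but has {len(block_coords)} coordinate rows",
                line=block_start,
            )
        if block_lm != scheme.n_landmarks:
            raise SchemeMismatchError(
                f"specimen {block_id or f'#{len(configs) + 1}'}: LM={block_lm}, "
                f"scheme requires {scheme.n_landmarks}"
            )
        coords = np.asarray(block_coords, dtype=float) * block_scale
        if flip_y:
            coords[:, 1] = -coords[:, 1]
        configs.append(
            LandmarkConfiguration(
                specimen_id=block_id or f"specimen-{len(configs) + 1}",
                coords=coords,
                scheme=scheme,
            )
        )
        block_coords, block_id, block_scale = None, None, 1.0

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        key_upper = key.strip().upper()
        if key_upper == "LM" and _ == "=":
            close_block(lineno)
            try:
                block_lm = int(value)
            except ValueError:
                raise TPSParseError(f"bad LM count {value!r}", line=lineno) from None
            block_coords = []
            block_start = lineno
        elif key_upper == "ID" and _ == "=":
            block_id = value.strip()
        elif key_upper == "SCALE" and _ == "=":
            try:
                block_scale = float(value)
            except ValueError:
                raise TPSParseError(f"bad SCALE {value!r}", line=lineno) from None
        elif key_upper == "IMAGE" and _ == "=":
            continue
        else:
            if block_coords is None:
                raise TPSParseError(f"coordinate row before any LM= header: {line!r}", line=lineno)
            parts = line.split()
            if len(parts) != 2:
                raise TPSParseError(f"expected 'x y', got {line!r}", line=lineno)
            try:
                block_coords.append([float(parts[0]), float(parts[1])])
            except ValueError:
                raise TPSParseError(f"non-numeric coordinate in {line!r}", line=lineno) from None

    close_block(lineno=len(text.splitlines()))
    return configs


def write_tps(configs: Iterable[LandmarkConfiguration], path) -> None:
    """Write configurations as consecutive TPS blocks (SCALE omitted, i.e. 1)."""
    lines: list[str] = []
    for c in configs:
        lines.append(f"LM={c.scheme.n_landmarks}")
        for x, y in c.coords:
            lines.append(f"{x:.6f} {y:.6f}")
        lines.append(f"ID={c.specimen_id}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Replicate averaging
# ---------------------------------------------------------------------------

def average_replicates(reps: Sequence[LandmarkConfiguration]) -> LandmarkConfiguration:
    """Landmark-wise arithmetic mean of digitizing replicates of one specimen.

    The study protocol digitized each head three times; any count >= 1 is
    accepted, with a warning below three.
    """
    if len(reps) == 0:
        raise ValueError("cannot average an empty replicate list")
    first = reps[0]
    for r in reps[1:]:
        if r.specimen_id != first.specimen_id:
            raise ValueError(
                f"mixed specimen ids in replicate list: {first.specimen_id!r} vs {r.specimen_id!r}"
            )
        if r.scheme != first.scheme:
            raise SchemeMismatchError("replicates use different landmark schemes")
    if len(reps) < 3:
        warnings.warn(
            f"specimen {first.specimen_id!r}: averaging {len(reps)} replicate(s); protocol uses 3",
            stacklevel=2,
        )
    mean_coords = np.mean([r.coords for r in reps], axis=0)
    return first.with_coords(mean_coords, replicate_index="averaged")


# ---------------------------------------------------------------------------
# Measurement CSVs
# ---------------------------------------------------------------------------

MEASUREMENT_COLUMNS = ("specimen_id", "group", "sex", "MHW", "HL", "OIO", "MIO", "AIO", "FE", "FEP")
APPENDAGE_COLUMNS = ("specimen_id", "part", "side", "replicate", "length")


def read_measurements_csv(path) -> list:
    """Read a head-measurement CSV into validated HeadMeasurements records.

    Expected columns: specimen_id, group, sex, MHW, HL, OIO, MIO, AIO, FE, FEP.
    """
    from .measurements import HeadMeasurements  # deferred: avoids import cycle

    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement CSV missing required column(s): {', '.join(missing)}")
    records = []
    for _, row in df.iterrows():
        sid = str(row["specimen_id"])
        values = {}
        for col in ("MHW", "HL", "OIO", "MIO", "AIO", "FE", "FEP"):
            try:
                values[col] = float(row[col])
            except (TypeError, ValueError):
                raise ValueError(f"specimen {sid!r}: non-numeric {col} value {row[col]!r}") from None
        try:
            records.append(
                HeadMeasurements(
                    specimen_id=sid,
                    group=str(row["group"]),
                    sex=str(row["sex"]),
                    **values,
                )
            )
        except ValueError as exc:
            raise ValueError(f"specimen {sid!r}: {exc}") from None
    return records


def read_appendages_csv(path) -> list[AppendageLengths]:
    """Read long-format appendage CSV (specimen_id, part, side, replicate, length)."""
    df = pd.read_csv(path)
    missing = [c for c in APPENDAGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"appendage CSV missing required column(s): {', '.join(missing)}")
    out: list[AppendageLengths] = []
    for (sid, part), sub in df.groupby(["specimen_id", "part"], sort=False):
        sides = {}
        for side in ("left", "right"):
            reps = sub.loc[sub["side"] == side].sort_values("replicate")["length"]
            sides[side] = tuple(float(v) for v in reps)
        if not sides["left"] or not sides["right"]:
            warnings.warn(f"specimen {sid!r}/{part}: missing a side, skipped", stacklevel=2)
            continue
        group = sub["group"].iloc[0] if "group" in sub.columns else None
        out.append(
            AppendageLengths(
                specimen_id=str(sid),
                part=str(part),
                left_replicates=sides["left"],
                right_replicates=sides["right"],
                group=None if group is None else str(group),
            )
        )
    return out
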