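"""Data model, screen geometry and file IO for fixation and click data.

Coordinate convention: pixel coordinates with the origin at the top-left
corner of the image, x increasing rightward and y increasing downward.
Angular quantities (degrees of visual angle) are converted to pixels through
a :class:`ScreenGeometry`, which is the sole authority for that conversion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScreenGeometry",
    "Fixation",
    "FixationSequence",
    "ClickTable",
    "SchemaError",
    "DEFAULT_GEOMETRY",
    "DIALECTS",
    "deg_to_px",
    "px_to_deg",
    "drop_first_center_fixation",
    "load_fixations",
    "save_fixations",
]


class SchemaError(ValueError):
    """Raised when an input table does not provide the mandatory columns."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display and viewing distance.

    Parameters
    ----------
    width_m, height_m
        Physical size of the display in meters.
    res_x, res_y
        Display resolution in pixels.
    distance_m
        Viewing distance in meters.
    """

    width_m: float
    height_m: float
    res_x: int
    res_y: int
    distance_m: float

    def __post_init__(self) -> None:
        for name in ("width_m", "height_m", "res_x", "res_y", "distance_m"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"ScreenGeometry.{name} must be strictly positive, got {value!r}")

    @property
    def px_per_m(self) -> float:
        """Pixels per meter along the horizontal axis (single scalar, isotropic use)."""
        return self.res_x / self.width_m


#: Geometry of the recording setup used throughout the examples:
#: a 24-inch, 0.52 m x 0.32 m display at 1920 x 1200 px viewed from 0.7 m.
DEFAULT_GEOMETRY = ScreenGeometry(
    width_m=0.52, height_m=0.32, res_x=1920, res_y=1200, distance_m=0.7
)


def deg_to_px(angle_deg, geom: ScreenGeometry):
    """Convert visual angle (degrees) to on-screen pixels.

    Uses the exact relation ``2 * d * tan(angle / 2)`` and the horizontal
    pixel pitch only, so pixels are treated as isotropic.
    Accepts scalars or arrays.
    """
    angle = np.asarray(angle_deg, dtype=float)
    meters = 2.0 * geom.distance_m * np.tan(np.deg2rad(angle) / 2.0)
    out = meters * geom.px_per_m
    return out if out.ndim else float(out)


def px_to_deg(px, geom: ScreenGeometry):
    """Inverse of :func:`deg_to_px` (round-trips to better than 1e-9 relative)."""
    pixels = np.asarray(px, dtype=float)
    meters = pixels / geom.px_per_m
    out = np.rad2deg(2.0 * np.arctan(meters / (2.0 * geom.distance_m)))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class Fixation:
    """A single fixation: position in pixels, duration and onset in ms."""

    x: float
    y: float
    duration: float = 0.0
    onset: float = 0.0
    index: int = 0

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError(f"fixation duration must be >= 0, got {self.duration}")
        if self.onset < 0:
            raise ValueError(f"fixation onset must be >= 0, got {self.onset}")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


PHASES = ("encoding", "recall")


@dataclass(frozen=True)
class FixationSequence:
    """Ordered fixations of one participant on one image in one phase."""

    fixations: tuple[Fixation, ...]
    phase: str
    participant_id: str
    image_id: str
    image_size: tuple[int, int] = (1024, 768)

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixations", tuple(self.fixations))
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        onsets = [f.onset for f in self.fixations]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("fixations must be sorted by onset")
        if not all(np.isfinite(f.x) and np.isfinite(f.y) for f in self.fixations):
            raise ValueError("fixation positions must be finite")
        indices = [f.index for f in self.fixations]
        if len(set(indices)) != len(indices):
            raise ValueError("fixation indices must be unique within a sequence")

    def __len__(self) -> int:
        return len(self.fixations)

    def __iter__(self) -> Iterator[Fixation]:
        return iter(self.fixations)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of x/y positions in pixels."""
        if not self.fixations:
            return np.empty((0, 2), dtype=float)
        return np.array([[f.x, f.y] for f in self.fixations], dtype=float)

    @property
    def durations(self) -> np.ndarray:
        return np.array([f.duration for f in self.fixations], dtype=float)

    def with_fixations(self, fixations: Iterable[Fixation]) -> "FixationSequence":
        return replace(self, fixations=tuple(fixations))


def drop_first_center_fixation(
    seq: FixationSequence,
    geom: ScreenGeometry,
    radius_deg: float = 1.0,
    center: tuple[float, float] | None = None,
) -> FixationSequence:
    """Drop the leading fixation if it sits on the display centre.

    The first fixation is removed only when it lies within ``radius_deg`` of
    the centre (default: centre of ``seq.image_size``); otherwise the sequence
    is returned unchanged. Empty sequences pass through unchanged.
    """
    if len(seq) == 0:
        return seq
    if center is None:
        center = (seq.image_size[0] / 2.0, seq.image_size[1] / 2.0)
    first = seq.fixations[0]
    dist = math.hypot(first.x - center[0], first.y - center[1])
    if dist <= deg_to_px(radius_deg, geom):
        return seq.with_fixations(seq.fixations[1:])
    return seq


# ---------------------------------------------------------------------------
# IO

#: Column-mapping dialects for delimited fixation tables. ``sep=None`` lets
#: pandas sniff the delimiter. The ``eyelink`` profile covers fixation-report
#: exports (tab-separated, CURRENT_FIX_* columns).
DIALECTS: dict[str, dict] = {
    "default": {
        "sep": None,
        "participant": "participant",
        "image": "image",
        "phase": "phase",
        "x": "x",
        "y": "y",
        "duration": "duration",
        "onset": "onset",
    },
    "eyelink": {
        "sep": "\t",
        "participant": "RECORDING_SESSION_LABEL",
        "image": "image",
        "phase": "phase",
        "x": "CURRENT_FIX_X",
        "y": "CURRENT_FIX_Y",
        "duration": "CURRENT_FIX_DURATION",
        "onset": "CURRENT_FIX_START",
    },
}

_MANDATORY = ("participant", "image", "phase", "x", "y", "duration")
_NUMERIC = ("x", "y", "duration", "onset")


def _resolve_dialect(dialect) -> dict:
    if isinstance(dialect, str):
        try:
            return dict(DIALECTS[dialect])
        except KeyError:
            raise ValueError(f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}")
    out = dict(DIALECTS["default"])
    out.update(dialect or {})
    return out


def load_fixations(
    path,
    dialect: str | Mapping[str, str] = "default",
    image_size: tuple[int, int] = (1024, 768),
) -> list[FixationSequence]:
    """Read a delimited fixation table into grouped, onset-sorted sequences.

    Rows are grouped by (participant, image, phase). A missing mandatory
    column raises :class:`SchemaError` naming the column; a non-numeric value
    raises :class:`ValueError` naming the file line; an empty file returns an
    empty list with a warning.
    """
    spec = _resolve_dialect(dialect)
    path = Path(path)
    if path.stat().st_size == 0:
        warnings.warn(f"{path}: empty fixation file", stacklevel=2)
        return []
    try:
        df = pd.read_csv(path, sep=spec["sep"], engine="python")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty fixation file", stacklevel=2)
        return []
    if df.empty:
        warnings.warn(f"{path}: fixation file has a header but no rows", stacklevel=2)
        return []

    for key in _MANDATORY:
        if spec[key] not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {spec[key]!r} (role: {key})")

    has_onset = spec["onset"] in df.columns
    cols = {key: spec[key] for key in _MANDATORY}
    if has_onset:
        cols["onset"] = spec["onset"]
    table = df[[cols[k] for k in cols]].copy()
    table.columns = list(cols)
    if not has_onset:
        # fall back to file order so grouping/sorting stays deterministic
        table["onset"] = np.arange(len(table), dtype=float)

    for key in _NUMERIC:
        coerced = pd.to_numeric(table[key], errors="coerce")
        bad = coerced.isna() & table[key].notna()
        if bad.any():
            # +2: one for the header line, one for 1-based numbering
            line = int(bad.idxmax()) + 2
            raise ValueError(
                f"{path}: non-numeric value {table.loc[bad.idxmax(), key]!r} "
                f"in column {key!r} on row {line}"
            )
        if coerced.isna().any():
            line = int(coerced.isna().idxmax()) + 2
            raise ValueError(f"{path}: missing value in column {key!r} on row {line}")
        table[key] = coerced

    table["phase"] = table["phase"].astype(str).str.strip().str.lower()
    unknown = set(table["phase"]) - set(PHASES)
    if unknown:
        raise SchemaError(f"{path}: unknown phase value(s) {sorted(unknown)}; expected {PHASES}")

    sequences: list[FixationSequence] = []
    for (participant, image, phase), group in table.groupby(
        ["participant", "image", "phase"], sort=True
    ):
        group = group.sort_values("onset", kind="stable")
        fixations = [
            Fixation(
                x=float(row.x),
                y=float(row.y),
                duration=float(row.duration),
                onset=float(row.onset),
                index=i,
            )
            for i, row in enumerate(group.itertuples())
        ]
        sequences.append(
            FixationSequence(
                fixations=tuple(fixations),
                phase=str(phase),
                participant_id=str(participant),
                image_id=str(image),
                image_size=tuple(image_size),
            )
        )
    return sequences


def save_fixations(
    sequences: Sequence[FixationSequence],
    path,
    relocated: Mapping[tuple[str, str], np.ndarray] | None = None,
    matched: Mapping[tuple[str, str], Sequence[int]] | None = None,
) -> pd.DataFrame:
    """Write sequences back to the standard CSV schema.

    ``relocated`` optionally maps (participant, image) to an (n_recall, 2)
    array of relocated positions for that trial's recall sequence; ``matched``
    maps (participant, image) to matched encoding indices. The written frame
    is also returned.
    """
    rows = []
    for seq in sequences:
        key = (seq.participant_id, seq.image_id)
        reloc = relocated.get(key) if relocated and seq.phase == "recall" else None
        matched_ids = set(matched.get(key, ())) if matched and seq.phase == "encoding" else None
        for i, f in enumerate(seq):
            row = {
                "participant": seq.participant_id,
                "image": seq.image_id,
                "phase": seq.phase,
                "x": f.x,
                "y": f.y,
                "duration": f.duration,
                "onset": f.onset,
            }
            if reloc is not None:
                row["relocated_x"] = float(reloc[i][0])
                row["relocated_y"] = float(reloc[i][1])
            if matched_ids is not None:
                row["matched"] = int(f.index in matched_ids)
            rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)
    return frame


@dataclass
class ClickTable:
    """Click positions marking subjectively important scene regions."""

    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["participant", "image", "x", "y", "latency"]
        )
    )

    REQUIRED = ("participant", "image", "x", "y")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise SchemaError(f"click table missing mandatory column {col!r}")
        if "latency" not in self.frame.columns:
            self.frame = self.frame.assign(latency=np.nan)

    @classmethod
    def from_csv(cls, path, sep=None) -> "ClickTable":
        return cls(pd.read_csv(path, sep=sep, engine="python"))

    def filtered(self, image_size: tuple[int, int]) -> "ClickTable":
        """Drop clicks outside the image bounds."""
        f = self.frame
        ok = (f.x >= 0) & (f.x < image_size[0]) & (f.y >= 0) & (f.y < image_size[1])
        return ClickTable(f[ok].reset_index(drop=True))

    def positions_for(self, image_id: str) -> np.ndarray:
        """(n, 2) click positions for one image."""
        sub = self.frame[self.frame.image.astype(str) == str(image_id)]
        return sub[["x", "y"]].to_numpy(dtype=float)

    @property
    def image_ids(self) -> list[str]:
        return sorted(self.frame.image.astype(str).unique())
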