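"""Reading, writing and validating single-particle tracking tables.

Time-lapse trackers (TrackMate and friends) export one row per detected
spot with a track identifier, spatial coordinates and a timestamp.  This
module turns such CSV exports into the in-memory :class:`TrackSet` used by
the motility and proximity analyses, and writes the same dialect back out.

Two header dialects are auto-detected:

* the internal minimal header ``track_id,x,y,z,t`` (``z`` optional), and
* the common uppercase export header ``TRACK_ID, POSITION_X, POSITION_Y,
  POSITION_Z, POSITION_T``.

Coordinates are micrometres and timestamps hours throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Track",
    "TrackSet",
    "TrackFormatError",
    "TrackValidationError",
    "read_tracks",
    "write_tracks",
]


class TrackFormatError(ValueError):
    """A tracking table is structurally malformed (e.g. a missing column)."""


class TrackValidationError(ValueError):
    """A tracking table parsed but violates track semantics."""


@dataclass
class Track:
    """One cell's time-ordered positions.

    Parameters
    ----------
    track_id:
        Identifier, unique within a :class:`TrackSet`.
    t, x, y, z:
        Equal-length arrays; ``t`` in hours (strictly increasing), spatial
        coordinates in µm.  ``z`` defaults to zeros with ``planar=True``
        when the source table had no z column.
    cell_type:
        Optional label (``macrophage`` | ``fibroblast`` | ``tumor``).
    planar:
        True when z was absent in the source and filled with zeros.
    """

    track_id: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray | None = None
    cell_type: str | None = None
    planar: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.z is None:
            self.z = np.zeros_like(self.x)
            self.planar = True
        else:
            self.z = np.asarray(self.z, dtype=float)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise TrackValidationError(
                f"track {self.track_id}: coordinate arrays have unequal lengths"
            )
        for name, arr in (("t", self.t), ("x", self.x), ("y", self.y), ("z", self.z)):
            if not np.all(np.isfinite(arr)):
                raise TrackValidationError(
                    f"track {self.track_id}: non-finite values in column '{name}'"
                )
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise TrackValidationError(
                f"track {self.track_id}: timestamps not strictly increasing "
                "(duplicate or out-of-order spots)"
            )

    @property
    def n_spots(self) -> int:
        return len(self.t)

    @property
    def usable(self) -> bool:
        """Single-spot tracks are retained but unusable for speed/MSD."""
        return self.n_spots >= 2

    def positions(self, use_z: bool = False) -> np.ndarray:
        cols = (self.x, self.y, self.z) if use_z else (self.x, self.y)
        return np.column_stack(cols)


@dataclass
class TrackSet:
    """A collection of tracks sharing a nominal frame interval and units."""

    tracks: list[Track] = field(default_factory=list)
    frame_interval: float = 1.0  # hours
    spatial_units: str = "um"

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def __getitem__(self, i: int) -> Track:
        return self.tracks[i]

    def usable(self) -> list[Track]:
        return [tr for tr in self.tracks if tr.usable]

    def by_type(self, cell_type: str) -> "TrackSet":
        return TrackSet(
            [tr for tr in self.tracks if tr.cell_type == cell_type],
            frame_interval=self.frame_interval,
            spatial_units=self.spatial_units,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tr in sorted(self.tracks, key=lambda tr: tr.track_id):
            for i in range(tr.n_spots):
                rows.append(
                    {
                        "track_id": tr.track_id,
                        "x": tr.x[i],
                        "y": tr.y[i],
                        "z": tr.z[i],
                        "t": tr.t[i],
                        "cell_type": tr.cell_type if tr.cell_type else "",
                    }
                )
        return pd.DataFrame(
            rows, columns=["track_id", "x", "y", "z", "t", "cell_type"]
        )


# header dialects: canonical name -> accepted source column name
_MINIMAL = {"track_id": "track_id", "x": "x", "y": "y", "z": "z", "t": "t"}
_EXPORT = {
    "track_id": "TRACK_ID",
    "x": "POSITION_X",
    "y": "POSITION_Y",
    "z": "POSITION_Z",
    "t": "POSITION_T",
}
_REQUIRED = ("track_id", "x", "y", "t")


def _detect_dialect(columns: Sequence[str]) -> dict[str, str]:
    cols = set(columns)
    if "TRACK_ID" in cols or "POSITION_X" in cols:
        return _EXPORT
    return _MINIMAL


def read_tracks(
    path: str | Path,
    dialect: str = "auto",
    frame_interval: float = 1.0,
) -> TrackSet:
    """Read a tracking CSV into a validated :class:`TrackSet`.

    Parameters
    ----------
    path:
        CSV file with a header row.
    dialect:
        ``"auto"`` (header inspection), ``"minimal"`` or ``"export"``.
    frame_interval:
        Nominal frame interval in hours, recorded on the result.

    Raises
    ------
    TrackFormatError
        If a required column (track id, x, y, t) is absent.
    TrackValidationError
        If a track has duplicate or non-monotone timestamps, or
        non-finite coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if dialect == "auto":
        mapping = _detect_dialect(df.columns)
    elif dialect == "minimal":
        mapping = _MINIMAL
    elif dialect == "export":
        mapping = _EXPORT
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    missing = [mapping[c] for c in _REQUIRED if mapping[c] not in df.columns]
    if missing:
        raise TrackFormatError(
            f"{path.name}: missing required column(s) {', '.join(missing)}"
        )

    has_z = mapping["z"] in df.columns
    has_type = "cell_type" in df.columns

    tracks: list[Track] = []
    for tid, grp in df.groupby(mapping["track_id"], sort=True):
        grp = grp.sort_values(mapping["t"], kind="stable")
        t = grp[mapping["t"]].to_numpy(dtype=float)
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise TrackValidationError(
                f"track {tid}: duplicate or non-monotone timestamps"
            )
        ctype = None
        if has_type:
            vals = grp["cell_type"].astype(str)
            first = vals.iloc[0]
            ctype = first if first and first != "nan" else None
        tracks.append(
            Track(
                track_id=int(tid),
                t=t,
                x=grp[mapping["x"]].to_numpy(dtype=float),
                y=grp[mapping["y"]].to_numpy(dtype=float),
                z=grp[mapping["z"]].to_numpy(dtype=float) if has_z else None,
                cell_type=ctype,
            )
        )
    return TrackSet(tracks, frame_interval=frame_interval)


def write_tracks(trackset: TrackSet, path: str | Path) -> Path:
    """Write a TrackSet as CSV (minimal dialect, deterministic row order).

    Rows are ordered by (track_id, t); coordinates keep 9 significant
    digits so a write→read round trip preserves them beyond 6 digits.
    """
    path = Path(path)
    df = trackset.to_frame()
    df.to_csv(path, index=False, float_format="%.9g")
    return path
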