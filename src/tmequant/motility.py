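"""Motility statistics for cell trajectories: net-displacement speed and MSD.

Two quantities summarise each track:

* **average speed** — the mean of the magnitudes of the net displacement
  over consecutive 1 h intervals (planar x, y by default).  Net
  displacement per interval, not path length: a cell that wiggles within
  an interval but returns to its start has moved 0 µm that hour.

* **time-averaged MSD** — for a track with ``N`` steps (``N + 1``
  positions) the mean squared displacement at lag ``n`` uses all
  overlapping windows::

      MSD(n) = 1/(N - n + 1) * sum_{i=0..N-n} [(x_{i+n} - x_i)^2
                                               + (y_{i+n} - y_i)^2]

  The log–log slope of MSD against lag diagnoses the motility regime:
  2 for ballistic (straight-line) motion, 1 for uncorrelated diffusion.

Tracks are assumed resampled to a uniform grid; :func:`resample_track`
snaps spots to the nominal interval by nearest timestamp and splits the
track into segments across gaps longer than one interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .track_io import Track, TrackSet

__all__ = [
    "SpeedSeries",
    "MsdCurve",
    "average_speed",
    "msd",
    "ensemble_msd",
    "resample_track",
    "msd_loglog_slope",
]


class UndefinedSpeedError(ValueError):
    """Raised for tracks too short to define a speed (fewer than 2 spots)."""


@dataclass
class SpeedSeries:
    """Per-interval net displacement magnitudes and their mean for one track."""

    track_id: int
    displacements: np.ndarray  # µm per interval
    interval: float  # hours

    @property
    def average_speed(self) -> float:
        """Mean net displacement per interval, in µm/h."""
        return float(np.mean(self.displacements) / self.interval)


@dataclass
class MsdCurve:
    """Time-averaged MSD of one track (or an ensemble mean curve)."""

    lags: np.ndarray  # in steps, 1..n_max
    values: np.ndarray  # µm²
    n_contrib: np.ndarray  # windows (per-track) or tracks (ensemble) per lag
    dt: float = 1.0  # hours per step
    sem: np.ndarray | None = None  # ensemble only

    def as_frame(self) -> pd.DataFrame:
        d = {"lag": self.lags, "lag_hours": self.lags * self.dt, "msd": self.values,
             "n": self.n_contrib}
        if self.sem is not None:
            d["sem"] = self.sem
        return pd.DataFrame(d)


def resample_track(track: Track, interval: float = 1.0) -> list[Track]:
    """Snap spots to a uniform grid and split across gaps.

    Each spot is assigned to the nearest multiple of ``interval``; when
    several spots land in one bin the one closest to the grid time wins.
    Consecutive occupied bins form a segment; a gap of more than one bin
    starts a new segment.  Single-spot segments are dropped.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    bins = np.rint(track.t / interval).astype(int)
    # keep the spot nearest to the grid time within each bin
    best: dict[int, int] = {}
    for i, b in enumerate(bins):
        if b not in best or abs(track.t[i] - b * interval) < abs(
            track.t[best[b]] - b * interval
        ):
            best[b] = i
    order = sorted(best)
    segments: list[list[int]] = [[]]
    for j, b in enumerate(order):
        if segments[-1] and b - order[j - 1] > 1:
            segments.append([])
        segments[-1].append(best[b])
    out = []
    for k, seg in enumerate(segments):
        if len(seg) < 2:
            continue
        idx = np.array(seg)
        out.append(
            Track(
                track_id=track.track_id if len(segments) == 1 else track.track_id,
                t=np.array([round(track.t[i] / interval) * interval for i in idx]),
                x=track.x[idx],
                y=track.y[idx],
                z=track.z[idx],
                cell_type=track.cell_type,
                planar=track.planar,
            )
        )
    return out


def average_speed(track: Track, interval: float = 1.0) -> SpeedSeries:
    """Average speed as mean per-interval planar net displacement.

    Raises :class:`UndefinedSpeedError` for single-spot tracks (they are
    retained upstream but carry no speed).
    """
    if track.n_spots < 2:
        raise UndefinedSpeedError(
            f"track {track.track_id}: speed undefined for a single-spot track"
        )
    disps: list[float] = []
    for seg in resample_track(track, interval):
        dx = np.diff(seg.x)
        dy = np.diff(seg.y)
        disps.extend(np.hypot(dx, dy))
    if not disps:
        raise UndefinedSpeedError(
            f"track {track.track_id}: no usable interval after resampling"
        )
    return SpeedSeries(track.track_id, np.asarray(disps), interval)


def msd(track: Track, n_max: int | None = None, use_z: bool = False) -> MsdCurve:
    """Time-averaged MSD of one uniformly sampled track.

    Planar (x, y) by default; ``use_z=True`` adds the axial term.  The
    track must have uniform time spacing (resample first otherwise).
    """
    if track.n_spots < 2:
        raise ValueError(f"track {track.track_id}: MSD needs at least 2 spots")
    dts = np.diff(track.t)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
        raise ValueError(
            f"track {track.track_id}: non-uniform time spacing; resample first"
        )
    pos = track.positions(use_z=use_z)
    N = track.n_spots - 1  # number of steps
    n_max = N if n_max is None else min(n_max, N)
    lags = np.arange(1, n_max + 1)
    values = np.empty(n_max)
    counts = np.empty(n_max, dtype=int)
    for j, n in enumerate(lags):
        d = pos[n:] - pos[:-n]
        sq = np.einsum("ij,ij->i", d, d)
        values[j] = sq.mean()  # N - n + 1 overlapping windows
        counts[j] = len(sq)
    return MsdCurve(lags=lags, values=values, n_contrib=counts, dt=float(dts[0]))


def ensemble_msd(
    trackset: TrackSet,
    n_max: int | None = None,
    min_track_fraction: float = 0.5,
    use_z: bool = False,
) -> MsdCurve:
    """Mean ± SEM MSD across tracks of a condition.

    Per lag, the mean and SEM are taken over the tracks that possess that
    lag; lags reached by fewer than ``min_track_fraction`` of usable
    tracks are dropped so the tail is not dominated by a few long tracks.
    """
    usable = [tr for tr in trackset.usable() if tr.n_spots >= 3]
    if not usable:
        raise ValueError("no usable track (>= 3 spots) in the ensemble")
    curves = [msd(tr, n_max=n_max, use_z=use_z) for tr in usable]
    dt = curves[0].dt
    longest = max(len(c.lags) for c in curves)
    per_lag: list[np.ndarray] = []
    for n in range(1, longest + 1):
        vals = np.array([c.values[n - 1] for c in curves if len(c.lags) >= n])
        per_lag.append(vals)
    keep = [
        n for n in range(1, longest + 1)
        if len(per_lag[n - 1]) >= min_track_fraction * len(curves)
    ]
    lags = np.array(keep, dtype=int)
    means = np.array([per_lag[n - 1].mean() for n in keep])
    sems = np.array(
        [
            per_lag[n - 1].std(ddof=1) / np.sqrt(len(per_lag[n - 1]))
            if len(per_lag[n - 1]) > 1
            else 0.0
            for n in keep
        ]
    )
    counts = np.array([len(per_lag[n - 1]) for n in keep], dtype=int)
    return MsdCurve(lags=lags, values=means, n_contrib=counts, dt=dt, sem=sems)


def msd_loglog_slope(curve: MsdCurve, max_lag: int | None = None) -> float:
    """Least-squares slope of log MSD vs log lag (motility-regime exponent)."""
    mask = curve.values > 0
    lags = curve.lags[mask]
    vals = curve.values[mask]
    if max_lag is not None:
        keep = lags <= max_lag
        lags, vals = lags[keep], vals[keep]
    if len(lags) < 2:
        raise ValueError("need at least two positive MSD values to fit a slope")
    slope, _ = np.polyfit(np.log(lags.astype(float)), np.log(vals), 1)
    return float(slope)


def speed_table(trackset: TrackSet, interval: float = 1.0) -> pd.DataFrame:
    """Per-track speed summary; short tracks are reported, not dropped."""
    rows = []
    for tr in trackset:
        try:
            s = average_speed(tr, interval)
            rows.append(
                {
                    "track_id": tr.track_id,
                    "cell_type": tr.cell_type or "",
                    "n_spots": tr.n_spots,
                    "n_intervals": len(s.displacements),
                    "average_speed": s.average_speed,
                    "usable": True,
                }
            )
        except UndefinedSpeedError:
            rows.append(
                {
                    "track_id": tr.track_id,
                    "cell_type": tr.cell_type or "",
                    "n_spots": tr.n_spots,
                    "n_intervals": 0,
                    "average_speed": np.nan,
                    "usable": False,
                }
            )
    return pd.DataFrame(rows)
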