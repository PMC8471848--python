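"""Persistent-random-walk trajectories with tumor-proximity speed modulation.

Macrophages perform a planar persistent random walk: at each step the
heading is drawn from a wrapped normal centered on the previous heading,
with circular standard deviation σ chosen so the mean resultant length
equals the ``persistence`` parameter p (σ = sqrt(−2·ln p); p = 0 gives
uniform headings, p = 1 a deterministic straight line).  Step lengths are
gamma-distributed with mean ``speed·dt`` and coefficient of variation
``speed_cv`` (cv = 0 collapses to the deterministic ballistic limit).

The per-cell mean speed is set once, from the cell's *initial* 3D
distance to the nearest tumor cell: ``base_speed_close`` within
``proximity_radius`` (default 100 µm), ``base_speed_far`` beyond — the
regime is static ground truth.  Fibroblasts and tumor cells are
quasi-static (Gaussian positional jitter).  The x–y domain is reflecting,
which preserves step lengths and hence speed statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..track_io import Track, TrackSet
from .config import GroundTruth, SimConfig
from .population import CellPopulation

__all__ = ["simulate_trajectories"]


def _heading_sigma(persistence: float) -> float:
    if persistence <= 0.0:
        return np.inf  # uniform headings
    if persistence >= 1.0:
        return 0.0
    return float(np.sqrt(-2.0 * np.log(persistence)))


def _reflect(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates back into [lo, hi] by specular reflection."""
    span = hi - lo
    v = np.mod(v - lo, 2 * span)
    v = np.where(v > span, 2 * span - v, v)
    return v + lo


def simulate_trajectories(
    population: CellPopulation, config: SimConfig
) -> tuple[TrackSet, GroundTruth]:
    """Simulate hourly tracks for every cell of the population.

    Returns the tracks plus a ground-truth table with each cell's regime
    (close/far by initial tumor distance), its distance to the nearest
    tumor cell, and its configured mean speed.
    """
    if len(population) == 0:
        raise ValueError("empty population")
    if config.dt <= 0:
        raise ValueError("dt must be positive")
    cells = population.cells
    tumors = population.of_type("tumor")
    modulated = config.base_speed_close != config.base_speed_far
    if modulated and len(tumors) == 0:
        raise ValueError(
            "proximity-modulated speeds need at least one tumor cell"
        )

    tpos = tumors[["x", "y", "z"]].to_numpy() if len(tumors) else None
    rng = config.rng(stream=2)
    sigma = _heading_sigma(config.persistence)
    Lx, Ly, _ = config.domain_size
    n_steps = config.n_steps
    t_grid = np.arange(n_steps + 1) * config.dt

    tracks: list[Track] = []
    truth_rows = []
    for row in cells.itertuples(index=False):
        p0 = np.array([row.x, row.y, row.z])
        if tpos is not None:
            d = np.sqrt(((tpos - p0) ** 2).sum(axis=1))
            dist = float(d.min())
        else:
            dist = np.inf
        if row.cell_type == "macrophage":
            close = dist <= config.proximity_radius
            mean_speed = config.base_speed_close if close else config.base_speed_far
            regime = "close" if close else "far"
            x, y = _walk(rng, p0[:2], mean_speed, config, sigma, (Lx, Ly))
            z = np.full(n_steps + 1, p0[2])
        else:
            mean_speed = 0.0
            regime = "static"
            jitter = config.jitter_sd
            x = p0[0] + (rng.normal(0, jitter, n_steps + 1) if jitter > 0 else 0.0)
            y = p0[1] + (rng.normal(0, jitter, n_steps + 1) if jitter > 0 else 0.0)
            if jitter > 0:
                x[0], y[0] = p0[0], p0[1]
                x = _reflect(x, 0, Lx)
                y = _reflect(y, 0, Ly)
            else:
                x = np.full(n_steps + 1, p0[0])
                y = np.full(n_steps + 1, p0[1])
            z = np.full(n_steps + 1, p0[2])
        tracks.append(
            Track(
                track_id=int(row.cell_id),
                t=t_grid.copy(),
                x=np.asarray(x, dtype=float),
                y=np.asarray(y, dtype=float),
                z=z,
                cell_type=row.cell_type,
            )
        )
        truth_rows.append(
            {
                "cell_id": int(row.cell_id),
                "cell_type": row.cell_type,
                "regime": regime,
                "distance_to_tumor": dist,
                "true_mean_speed": mean_speed,
            }
        )
    trackset = TrackSet(tracks, frame_interval=config.dt)
    return trackset, GroundTruth(cells=pd.DataFrame(truth_rows))


def _walk(
    rng: np.random.Generator,
    start_xy: np.ndarray,
    mean_speed: float,
    config: SimConfig,
    sigma: float,
    bounds: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    n = config.n_steps
    mean_step = mean_speed * config.dt
    if mean_step == 0:
        x = np.full(n + 1, start_xy[0])
        return x, np.full(n + 1, start_xy[1])
    # gamma step lengths: shape k = 1/cv², scale mean/k; cv=0 → deterministic
    if config.speed_cv > 0:
        k = 1.0 / config.speed_cv**2
        steps = rng.gamma(k, mean_step / k, size=n)
    else:
        steps = np.full(n, mean_step)
    theta0 = rng.uniform(0, 2 * np.pi)
    if np.isinf(sigma):
        headings = rng.uniform(0, 2 * np.pi, size=n)
    elif sigma == 0.0:
        headings = np.full(n, theta0)
    else:
        headings = theta0 + np.cumsum(rng.normal(0.0, sigma, size=n))
    dx = steps * np.cos(headings)
    dy = steps * np.sin(headings)
    x = np.concatenate([[start_xy[0]], start_xy[0] + np.cumsum(dx)])
    y = np.concatenate([[start_xy[1]], start_xy[1] + np.cumsum(dy)])
    x = _reflect(x, 0, bounds[0])
    y = _reflect(y, 0, bounds[1])
    return x, y
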