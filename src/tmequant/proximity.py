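"""Tumor-proximity analysis of macrophage motility.

Each macrophage is paired with its nearest tumor cell using the 3D
Euclidean distance between their positions at the start of imaging
(immediately after gelation); distances are then ranked and the k closest
("close") and k farthest ("far") macrophages are compared with a
one-tailed Welch t-test on their average migration speeds, with the
alternative mean(close) > mean(far).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

__all__ = [
    "ProximityRecord",
    "SpeedComparison",
    "pair_distances",
    "close_far_groups",
    "compare_speeds",
    "records_to_frame",
]


@dataclass
class ProximityRecord:
    macrophage_id: int
    nearest_tumor_id: int
    distance: float  # µm, 3D, at t0
    speed: float | None = None  # µm/h
    regime: str = "middle"  # close | far | middle


@dataclass
class SpeedComparison:
    t_statistic: float
    p_value: float  # one-sided, H1: mean(close) > mean(far)
    mean_close: float
    mean_far: float
    n_close: int
    n_far: int
    degenerate: bool = False


def _positions(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    ids = df["cell_id"].to_numpy()
    cols = ["x", "y", "z"] if "z" in df.columns else ["x", "y"]
    pos = df[cols].to_numpy(dtype=float)
    if pos.shape[1] == 2:
        pos = np.column_stack([pos, np.zeros(len(pos))])
    return ids, pos


def pair_distances(
    macrophages: pd.DataFrame,
    tumors: pd.DataFrame,
    speeds: dict[int, float] | None = None,
) -> list[ProximityRecord]:
    """Pair each macrophage with its nearest tumor cell at t0.

    Both inputs need ``cell_id, x, y[, z]`` columns with positions in µm;
    a missing z is treated as 0 (the slice z is assigned per cell upstream).
    Ties in distance are broken by the lowest tumor-cell id.
    """
    if len(tumors) == 0:
        raise ValueError("no tumor cells: proximity analysis undefined")
    if len(macrophages) == 0:
        return []
    mids, mpos = _positions(macrophages)
    tids, tpos = _positions(tumors)
    order = np.argsort(tids, kind="stable")  # argmin then picks lowest id on ties
    tids, tpos = tids[order], tpos[order]
    d = cdist(mpos, tpos)
    nearest = d.argmin(axis=1)
    records = [
        ProximityRecord(
            macrophage_id=int(mids[i]),
            nearest_tumor_id=int(tids[nearest[i]]),
            distance=float(d[i, nearest[i]]),
            speed=None if speeds is None else speeds.get(int(mids[i])),
        )
        for i in range(len(mids))
    ]
    return records


def close_far_groups(
    records: list[ProximityRecord], k: int = 15
) -> tuple[list[ProximityRecord], list[ProximityRecord]]:
    """Split ranked records into the k closest and k farthest macrophages.

    Records are ranked by distance ascending with ties broken by
    macrophage id; the first k become the close group, the last k the far
    group, everything between keeps regime ``middle`` (kept for the
    speed-vs-distance scatter).
    """
    if len(records) < 2 * k:
        raise ValueError(
            f"need at least {2 * k} macrophages for k={k}; got {len(records)}. "
            "Reduce k."
        )
    ranked = sorted(records, key=lambda r: (r.distance, r.macrophage_id))
    for r in ranked:
        r.regime = "middle"
    close = ranked[:k]
    far = ranked[-k:]
    for r in close:
        r.regime = "close"
    for r in far:
        r.regime = "far"
    return close, far


def compare_speeds(
    close: list[ProximityRecord] | np.ndarray,
    far: list[ProximityRecord] | np.ndarray,
    alternative: str = "greater",
) -> SpeedComparison:
    """One-tailed Welch t-test on average speeds, H1: mean(close) > mean(far).

    Welch's unequal-variance variant; it reduces to Student's t under
    equal variances.  Two degenerate zero-variance groups with equal
    means report t = 0, p = 0.5 with a degenerate flag.
    """
    def _speeds(group):
        if len(group) and isinstance(group[0], ProximityRecord):
            vals = [r.speed for r in group]
            if any(v is None for v in vals):
                raise ValueError("a record has no speed; compute speeds first")
            return np.asarray(vals, dtype=float)
        return np.asarray(group, dtype=float)

    a, b = _speeds(close), _speeds(far)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 members")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return SpeedComparison(0.0, 0.5, float(a.mean()), float(b.mean()),
                                   len(a), len(b), degenerate=True)
        p = 0.0 if ((a.mean() > b.mean()) == (alternative == "greater")) else 1.0
        return SpeedComparison(np.inf if p == 0 else -np.inf, p,
                               float(a.mean()), float(b.mean()),
                               len(a), len(b), degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return SpeedComparison(
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean_close=float(a.mean()),
        mean_far=float(b.mean()),
        n_close=len(a),
        n_far=len(b),
    )


def records_to_frame(records: list[ProximityRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
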