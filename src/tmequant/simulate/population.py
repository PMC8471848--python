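"""Seeding of the synthetic cell population in the collagen domain."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CELL_TYPES, SimConfig

__all__ = ["CellPopulation", "simulate_population", "composition_from_densities"]


@dataclass
class CellPopulation:
    """Initial 3D positions and types of all seeded cells."""

    cells: pd.DataFrame  # cell_id, cell_type, x, y, z

    def __len__(self) -> int:
        return len(self.cells)

    def of_type(self, cell_type: str) -> pd.DataFrame:
        return self.cells[self.cells["cell_type"] == cell_type].reset_index(drop=True)

    @property
    def counts(self) -> dict[str, int]:
        c = self.cells["cell_type"].value_counts()
        return {t: int(c.get(t, 0)) for t in CELL_TYPES}


def composition_from_densities(
    densities: dict[str, float], n_total: int
) -> dict[str, int]:
    """Split ``n_total`` cells across types proportionally to seeding density.

    Largest-remainder apportionment so the counts always sum to
    ``n_total`` and exact ratios (e.g. 2400:600:200 over 320 cells →
    240:60:20) come out exact.
    """
    total_density = sum(densities.values())
    if total_density <= 0 or n_total <= 0:
        raise ValueError("zero total cells requested")
    quotas = {t: n_total * d / total_density for t, d in densities.items()}
    counts = {t: int(np.floor(q)) for t, q in quotas.items()}
    short = n_total - sum(counts.values())
    remainders = sorted(
        densities, key=lambda t: (quotas[t] - counts[t], t), reverse=True
    )
    for t in remainders[:short]:
        counts[t] += 1
    return counts


def simulate_population(config: SimConfig) -> CellPopulation:
    """Place cells uniformly at random in the domain.

    Per-type counts follow the configured seeding densities (or explicit
    per-type counts when ``config.n_cells`` is a dict).  Reproducible for
    a given seed.
    """
    if isinstance(config.n_cells, dict):
        counts = {t: int(n) for t, n in config.n_cells.items() if n > 0}
    else:
        counts = composition_from_densities(config.seeding_densities, config.n_cells)
    if sum(counts.values()) <= 0:
        raise ValueError("zero total cells requested")
    rng = config.rng(stream=1)
    Lx, Ly, Lz = config.domain_size
    rows = []
    cid = 0
    for cell_type in sorted(counts):
        for _ in range(counts[cell_type]):
            x, y, z = rng.uniform((0, 0, 0), (Lx, Ly, Lz))
            rows.append(
                {"cell_id": cid, "cell_type": cell_type, "x": x, "y": y, "z": z}
            )
            cid += 1
    return CellPopulation(pd.DataFrame(rows))
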