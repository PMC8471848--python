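"""Configuration and ground-truth containers for the synthetic co-culture.

The defaults encode the study conditions of the 3D tri-culture this
package quantifies: bone-marrow-derived macrophages, 3T3 fibroblasts and
YUMM melanoma cells seeded in collagen at 2400/600/200 K cells/mL
(a 12:3:1 ratio, 75% macrophages), imaged hourly, with macrophage speed
elevated within 100 µm of the nearest tumor cell, and roughly 40% of
single macrophages actively secreting at least one measured protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ShapeParams", "SecretionParams", "SimConfig", "GroundTruth"]

CELL_TYPES = ("macrophage", "fibroblast", "tumor")


@dataclass
class ShapeParams:
    """Parametric morphologies for the label-image generator.

    Disks emulate round (high-compactness) macrophages, rotated
    rectangles the spindle morphology, and k-armed stars the stellate
    morphology with protrusions.  Sizes in pixels.
    """

    n_disks: int = 6
    n_spindles: int = 6
    n_stars: int = 6
    disk_radius_px: float = 30.0
    spindle_axes_px: tuple[float, float] = (20.0, 60.0)  # (width, length)
    star_arms: int = 5
    star_outer_px: float = 45.0
    star_inner_px: float = 18.0
    size_jitter: float = 0.2  # uniform relative jitter on linear size
    random_orientation: bool = True
    image_shape: tuple[int, int] = (640, 640)
    margin_px: int = 8
    max_retries: int = 500


def _default_log_means() -> dict[str, float]:
    # rough pg/mL scales for a mixed M1/M2 cytokine panel
    return {
        "TNF-a": 5.0, "IL-6": 5.5, "IL-10": 4.0, "CCL2": 6.0,
        "CXCL1": 5.0, "G-CSF": 4.5, "GM-CSF": 3.5, "CX3CL1": 4.0,
        "Chi3l3": 6.5, "TGF-b1": 4.5, "IL-12p70": 3.0, "CCL22": 4.0,
    }


def _default_group_effects() -> dict[str, dict[str, float]]:
    # co-culture roughly doubles the secreted inflammatory/M2 analytes
    up = float(np.log(2.0))
    return {
        "co_culture": {
            "TNF-a": up, "IL-6": up, "CCL2": up, "Chi3l3": up, "IL-10": up,
        }
    }


def _default_clusters() -> dict[str, tuple[str, ...]]:
    return {
        "M1-like": ("TNF-a", "IL-6"),
        "M2-like": ("Chi3l3", "IL-10"),
        "polyfunctional": ("TNF-a", "Chi3l3", "IL-10"),
    }


@dataclass
class SecretionParams:
    """Log-normal plate model with group offsets and below-LOD censoring."""

    log_means: dict[str, float] = field(default_factory=_default_log_means)
    log_sd: float = 0.6
    groups: tuple[str, ...] = ("mono", "co_culture")
    n_per_group: int = 6
    group_log_effects: dict[str, dict[str, float]] = field(
        default_factory=_default_group_effects
    )
    lod: float | dict[str, float] = 15.0  # pg/mL; censors the low-abundance analytes
    # single-cell model
    n_cells: int = 500
    positivity_threshold: float = 1.0  # arbitrary signal units
    cluster_profiles: dict[str, tuple[str, ...]] = field(default_factory=_default_clusters)

    @property
    def analytes(self) -> list[str]:
        return list(self.log_means)

    def lod_of(self, analyte: str) -> float:
        if isinstance(self.lod, dict):
            return float(self.lod.get(analyte, 0.0))
        return float(self.lod)


@dataclass
class SimConfig:
    """Parameters of the synthetic 3D tri-culture.

    Speeds in µm/h, distances in µm, time in hours.  ``persistence`` sets
    the heading correlation of the macrophage persistent random walk
    (0 = uncorrelated, 1 = deterministic straight line).
    """

    domain_size: tuple[float, float, float] = (1000.0, 1000.0, 300.0)
    seeding_densities: dict[str, float] = field(
        default_factory=lambda: {
            "macrophage": 2400.0,  # K cells/mL
            "fibroblast": 600.0,
            "tumor": 200.0,
        }
    )
    n_cells: int | dict[str, int] = 320  # total; split by density ratio
    dt: float = 1.0  # hours
    n_steps: int = 48
    base_speed_far: float = 6.0
    base_speed_close: float = 12.0
    speed_cv: float = 0.3  # per-step speed coefficient of variation
    proximity_radius: float = 100.0
    persistence: float = 0.6
    jitter_sd: float = 0.2  # µm, quasi-static fibroblasts/tumor cells
    shape_params: ShapeParams = field(default_factory=ShapeParams)
    secretion_params: SecretionParams = field(default_factory=SecretionParams)
    secretor_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if min(self.domain_size) <= 0:
            raise ValueError("domain dimensions must be positive")
        if self.base_speed_far < 0 or self.base_speed_close < 0:
            raise ValueError("speeds must be non-negative")
        if not (0.0 <= self.persistence <= 1.0):
            raise ValueError("persistence must lie in [0, 1]")
        if self.proximity_radius <= 0:
            raise ValueError("proximity_radius must be positive")
        if not (0.0 <= self.secretor_fraction <= 1.0):
            raise ValueError("secretor_fraction must lie in [0, 1]")
        if self.n_steps < 1:
            raise ValueError("n_steps must be at least 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.speed_cv < 0 or self.jitter_sd < 0:
            raise ValueError("noise scales must be non-negative")
        if isinstance(self.n_cells, dict):
            if sum(self.n_cells.values()) <= 0:
                raise ValueError("zero total cells requested")
        elif self.n_cells <= 0:
            raise ValueError("zero total cells requested")
        if any(d < 0 for d in self.seeding_densities.values()):
            raise ValueError("seeding densities must be non-negative")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic generator per simulation stage."""
        return np.random.default_rng([int(self.seed) % (2**31), int(stream)])


@dataclass
class GroundTruth:
    """Known truth attached to each synthetic output.

    Only the fields relevant to the generating operation are populated.
    """

    cells: pd.DataFrame | None = None  # regime, distance, true mean speed
    shapes: pd.DataFrame | None = None  # analytic geometry per mask label
    plate_log_means: pd.DataFrame | None = None  # group × analyte true ln-mean
    censored: pd.DataFrame | None = None
    secretor: pd.Series | None = None  # per-cell secretor status
    cluster: pd.Series | None = None  # per-cell planted profile
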