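"""Bulk-assay arithmetic: tumor volume, collagen density, fibroblast density."""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["tumor_volume", "collagen_density", "fibroblast_density"]


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper tumor volume in mm³: 0.52 · L · W².

    Caliper convention is L ≥ W; swapped inputs are corrected with a
    warning rather than rejected.
    """
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("caliper dimensions must be positive")
    if width_mm > length_mm:
        warnings.warn(
            "width > length; swapping to caliper convention L >= W", stacklevel=2
        )
        length_mm, width_mm = width_mm, length_mm
    return 0.52 * length_mm * width_mm**2


def collagen_density(collagen_ug: float, tumor_mass_mg: float) -> float:
    """Soluble collagen per tumor mass, µg collagen / mg tumor."""
    if tumor_mass_mg <= 0:
        raise ValueError("tumor mass must be positive")
    if collagen_ug < 0:
        raise ValueError("collagen amount cannot be negative")
    return collagen_ug / tumor_mass_mg


def fibroblast_density(
    marker_area_px2: float | np.ndarray,
    n_fields: int,
    pixel_size_um: float = 1.0,
) -> float:
    """Marker-positive area per high-power field, in µm² per HPF.

    ``marker_area_px2`` is either the total positive area or a per-field
    array (summed); the result divides by the number of fields.
    """
    if n_fields < 1:
        raise ValueError("need at least one field")
    total_px2 = float(np.sum(marker_area_px2))
    if total_px2 < 0:
        raise ValueError("area cannot be negative")
    return total_px2 * pixel_size_um**2 / n_fields
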