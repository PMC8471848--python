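"""Synthetic multiplex secretion data: bulk plates and single-cell matrices.

Bulk plates are log-normal per analyte with additive group offsets on the
log scale; concentrations that fall below the analyte's limit of
detection are censored (flagged below-range), emulating multiplex
immunoassay exports.  Single-cell matrices plant a known secretor
fraction: non-secretors draw background signal strictly below every
positivity threshold, secretors receive one of the planted cluster
profiles with the profile's analytes pushed above threshold.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ..secretion import SecretionTable, SingleCellSecretionMatrix
from .config import GroundTruth, SimConfig

__all__ = ["simulate_secretion_plate", "simulate_single_cell_secretion"]


def simulate_secretion_plate(config: SimConfig) -> tuple[SecretionTable, GroundTruth]:
    """Log-normal samples × analytes plate with planted groups and censoring."""
    sp = config.secretion_params
    analytes = sp.analytes
    if len(analytes) < 1:
        raise ValueError("need at least one analyte")
    n_samples = sp.n_per_group * len(sp.groups)
    if n_samples < 2:
        raise ValueError("need at least two samples")
    rng = config.rng(stream=4)

    sample_ids, group_of = [], []
    for g in sp.groups:
        for i in range(sp.n_per_group):
            sample_ids.append(f"{g}_{i + 1}")
            group_of.append(g)

    true_log_means = pd.DataFrame(
        {
            a: {
                g: sp.log_means[a] + sp.group_log_effects.get(g, {}).get(a, 0.0)
                for g in sp.groups
            }
            for a in analytes
        }
    )
    vals = np.empty((n_samples, len(analytes)))
    for j, a in enumerate(analytes):
        mus = np.array([true_log_means.loc[g, a] for g in group_of])
        vals[:, j] = np.exp(rng.normal(mus, sp.log_sd))
    values = pd.DataFrame(vals, index=sample_ids, columns=analytes)

    lods = np.array([sp.lod_of(a) for a in analytes])
    censored = pd.DataFrame(
        values.to_numpy() < lods, index=sample_ids, columns=analytes
    )
    fully_censored = [a for a in analytes if censored[a].all()]
    if fully_censored:
        warnings.warn(
            "LOD censors every sample of analyte(s): " + ", ".join(fully_censored),
            stacklevel=2,
        )
    # a real export reports no number below range; blank the censored cells
    values = values.mask(censored, 0.0)
    table = SecretionTable(values, censored, "raw", list(fully_censored))
    truth = GroundTruth(plate_log_means=true_log_means, censored=censored.copy())
    return table, truth


def simulate_single_cell_secretion(
    config: SimConfig,
) -> tuple[SingleCellSecretionMatrix, GroundTruth]:
    """Cells × analytes matrix with a planted secretor fraction.

    Each cell is a secretor with probability ``config.secretor_fraction``;
    secretors are assigned one of the planted cluster profiles uniformly.
    """
    sp = config.secretion_params
    analytes = sp.analytes
    rng = config.rng(stream=5)
    thr = sp.positivity_threshold
    n = sp.n_cells

    is_secretor = rng.random(n) < config.secretor_fraction
    cluster_names = list(sp.cluster_profiles)
    assigned = np.array(
        [rng.choice(cluster_names) if s else "none" for s in is_secretor],
        dtype=object,
    )
    # background strictly below threshold for every analyte
    vals = thr * rng.uniform(0.0, 0.5, size=(n, len(analytes)))
    col_of = {a: j for j, a in enumerate(analytes)}
    for i in np.flatnonzero(is_secretor):
        profile = sp.cluster_profiles[assigned[i]]
        for a in profile:
            # strictly above threshold: 1.5–6× with a log-normal tail
            vals[i, col_of[a]] = thr * (1.5 + rng.lognormal(0.0, 0.5))
    cell_ids = [f"cell_{i:04d}" for i in range(n)]
    values = pd.DataFrame(vals, index=cell_ids, columns=analytes)
    thresholds = pd.Series({a: thr for a in analytes})
    matrix = SingleCellSecretionMatrix(values, thresholds)
    truth = GroundTruth(
        secretor=pd.Series(is_secretor, index=cell_ids, name="secretor"),
        cluster=pd.Series(assigned, index=cell_ids, name="cluster"),
    )
    return matrix, truth
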