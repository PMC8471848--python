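"""Multiplex secretion-profile preprocessing and analysis.

Bulk plates arrive as samples × analytes concentration tables (pg/mL)
with some entries flagged "OOR<" — below the quantifiable range of the
analyte's logistic standard curve.  The preprocessing pipeline is:

1. :func:`impute_oor` — replace each below-range entry with the lowest
   uncensored value observed for that analyte;
2. :func:`transform` — natural-log transform, or per-analyte z-scores;
3. downstream: pairwise Pearson correlation between samples,
   hierarchical clustering of profiles, and PCA.

Single-cell secretion matrices (cells × analytes) are summarised by the
secretor fraction (cells with ≥ 1 analyte above its positivity threshold)
and per-cell polyfunctionality (number of analytes above threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

__all__ = [
    "SecretionTable",
    "SingleCellSecretionMatrix",
    "ClusterResult",
    "impute_oor",
    "transform",
    "correlation_matrix",
    "cluster_profiles",
    "pca_scores",
    "classify_secretors",
    "read_plate_csv",
    "write_plate_csv",
]

OOR_MARKER = "OOR<"


@dataclass
class SecretionTable:
    """Samples × analytes concentrations with a below-range censoring mask.

    ``values`` and ``censored`` share index (sample ids) and columns
    (analyte names).  ``transform_state`` tracks what the numbers mean:
    raw pg/mL, natural-log, or per-analyte z-scores.
    """

    values: pd.DataFrame
    censored: pd.DataFrame
    transform_state: str = "raw"  # raw | ln | z
    all_censored_analytes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.shape != self.censored.shape:
            raise ValueError("values and censoring mask differ in shape")
        if not (self.values.index.equals(self.censored.index)
                and self.values.columns.equals(self.censored.columns)):
            raise ValueError("values and censoring mask are not aligned")
        if self.transform_state == "raw":
            ok = self.values.to_numpy()[~self.censored.to_numpy()]
            if np.any(ok < 0):
                raise ValueError("negative raw concentrations")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def analytes(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SingleCellSecretionMatrix:
    """Cells × analytes signal matrix with per-analyte positivity thresholds."""

    values: pd.DataFrame
    thresholds: pd.Series  # indexed by analyte

    def __post_init__(self) -> None:
        missing = [a for a in self.values.columns if a not in self.thresholds.index]
        if missing:
            raise ValueError(
                f"missing positivity threshold for analyte(s): {', '.join(missing)}"
            )


def impute_oor(table: SecretionTable) -> SecretionTable:
    """Replace below-range entries with the analyte's lowest uncensored value.

    Column-wise: every censored entry of an analyte becomes the minimum of
    that analyte's uncensored entries.  Analytes with *all* entries
    censored cannot be imputed; they stay censored and are listed in
    ``all_censored_analytes``.  Idempotent.
    """
    if table.transform_state != "raw":
        raise ValueError("impute before transforming")
    vals = table.values.copy()
    mask = table.censored.copy()
    flagged = list(table.all_censored_analytes)
    for col in vals.columns:
        cmask = mask[col].to_numpy()
        if not cmask.any():
            continue
        if cmask.all():
            if col not in flagged:
                flagged.append(col)
            continue
        floor = vals.loc[~mask[col], col].min()
        vals.loc[mask[col], col] = floor
        mask[col] = False
    return SecretionTable(vals, mask, "raw", flagged)


def transform(table: SecretionTable, mode: str, pseudo_floor: float | None = None) -> SecretionTable:
    """Natural-log transform or per-analyte z-scores.

    ``ln`` needs strictly positive entries; zeros raise unless a
    ``pseudo_floor`` (added before the log) is declared.  ``zscore``
    standardises each analyte with the sample (n−1) standard deviation.
    """
    vals = table.values.astype(float).copy()
    if mode == "ln":
        if table.transform_state != "raw":
            raise ValueError("ln-transform expects raw concentrations")
        arr = vals.to_numpy()
        if (arr <= 0).any():
            if pseudo_floor is None:
                raise ValueError(
                    "non-positive entries; declare a pseudo_floor for ln"
                )
            arr = arr + pseudo_floor
        out = pd.DataFrame(np.log(arr), index=vals.index, columns=vals.columns)
        return replace(table, values=out, transform_state="ln")
    if mode == "zscore":
        mu = vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=1)
        zero_var = sd == 0
        if zero_var.any():
            warnings.warn(
                f"zero-variance analyte(s) left at 0: "
                f"{', '.join(vals.columns[zero_var])}",
                stacklevel=2,
            )
            sd = sd.replace(0, 1.0)
        out = (vals - mu) / sd
        return replace(table, values=out, transform_state="z")
    raise ValueError(f"unknown transform mode {mode!r}")


def correlation_matrix(table: SecretionTable) -> pd.DataFrame:
    """Pairwise Pearson correlation between sample profiles.

    Symmetric with unit diagonal; a zero-variance sample has undefined
    correlations, reported as NaN with a warning.
    """
    if table.values.shape[1] < 2:
        raise ValueError("need at least 2 analytes to correlate samples")
    arr = table.values.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr)
    corr = np.asarray(corr, dtype=float)
    np.fill_diagonal(corr, 1.0)
    if (sd == 0).any():
        bad = np.flatnonzero(sd == 0)
        warnings.warn(
            f"zero-variance sample(s) {', '.join(str(table.samples[i]) for i in bad)}: "
            "correlation undefined (NaN)",
            stacklevel=2,
        )
        corr[bad, :] = np.nan
        corr[:, bad] = np.nan
        for i in bad:
            corr[i, i] = 1.0
    return pd.DataFrame(corr, index=table.samples, columns=table.samples)


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray
    ids: list  # observation ids in input row order
    leaf_order: list  # ids in dendrogram order
    labels: dict = field(default_factory=dict)  # id -> flat-cluster label

    def cut(self, n_clusters: int) -> dict:
        if len(self.linkage_matrix) == 0:
            return {i: 1 for i in self.ids}
        flat = hierarchy.fcluster(self.linkage_matrix, n_clusters, criterion="maxclust")
        return {i: int(c) for i, c in zip(self.ids, flat)}


def cluster_profiles(
    table: SecretionTable,
    axis: str = "samples",
    method: str = "average",
    n_clusters: int | None = None,
) -> ClusterResult:
    """Agglomerative clustering (Euclidean distance) of rows or columns.

    Expects a z-transformed table (warns otherwise).  Leaf order is
    deterministic: scipy's dendrogram order with observations entered in
    row order, lower id first on ties.
    """
    if table.transform_state == "raw":
        warnings.warn("clustering raw concentrations; z-transform first "
                      "for comparable analyte scales", stacklevel=2)
    mat = table.values if axis == "samples" else table.values.T
    ids = list(mat.index)
    if len(ids) == 1:
        return ClusterResult(np.empty((0, 4)), ids, list(ids), {ids[0]: 1})
    Z = hierarchy.linkage(mat.to_numpy(dtype=float), method=method, metric="euclidean")
    order = hierarchy.leaves_list(Z)
    res = ClusterResult(Z, ids, [ids[i] for i in order])
    if n_clusters is not None:
        res.labels = res.cut(n_clusters)
    return res


def pca_scores(table: SecretionTable, n_components: int = 2):
    """PCA of sample profiles: scores and explained-variance fractions.

    Analytes are centered; components are orthonormal and the explained
    variance fractions are non-increasing.  ``n_components`` beyond the
    data rank is truncated with a warning.
    """
    X = table.values.to_numpy(dtype=float)
    n_samples, n_analytes = X.shape
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    rank = min(n_samples - 1, n_analytes)
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank
    p = PCA(n_components=n_components, svd_solver="full")
    scores = p.fit_transform(X)
    score_df = pd.DataFrame(
        scores,
        index=table.samples,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return score_df, p.explained_variance_ratio_.copy()


def classify_secretors(
    matrix: SingleCellSecretionMatrix, polyfunctional_min: int = 2
) -> pd.DataFrame:
    """Flag secretors and count per-cell polyfunctionality.

    A cell is a secretor iff at least one analyte exceeds its positivity
    threshold; polyfunctionality is the count of analytes above threshold
    (cells at or above ``polyfunctional_min`` get the polyfunctional flag).
    Returns a per-cell frame; the secretor fraction is
    ``out["secretor"].mean()``.
    """
    vals = matrix.values
    thr = matrix.thresholds.reindex(vals.columns)
    above = vals.gt(thr, axis=1)
    n_above = above.sum(axis=1)
    return pd.DataFrame(
        {
            "secretor": n_above >= 1,
            "n_analytes_above": n_above,
            "polyfunctional": n_above >= polyfunctional_min,
        },
        index=vals.index,
    )


def read_plate_csv(path: str | Path) -> SecretionTable:
    """Read a plate CSV whose censored cells carry the ``OOR<`` marker."""
    raw = pd.read_csv(path, index_col=0, dtype=str)
    censored = raw.apply(lambda s: s.str.strip().str.startswith(OOR_MARKER))
    vals = raw.mask(censored, np.nan).apply(pd.to_numeric)
    vals = vals.fillna(0.0)
    return SecretionTable(vals, censored.astype(bool))


def write_plate_csv(table: SecretionTable, path: str | Path) -> Path:
    """Write a raw plate with ``OOR<`` markers for censored cells."""
    if table.transform_state != "raw":
        raise ValueError("only raw plates are written with OOR markers")
    out = table.values.astype(object).copy()
    out = out.where(~table.censored, OOR_MARKER)
    out.to_csv(path, float_format="%.6g")
    return Path(path)
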