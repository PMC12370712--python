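"""Preprocessing and KNN-based per-modality hypergraph construction with fusion.

Raw tabular inputs (mixed numeric/categorical, possibly with missing cells) are
imputed, one-hot encoded and z-scored using statistics from a designated fit
subset of subjects, so train/test separation is respected.  Raw sensor streams
are gap-interpolated, windowed, and reduced to window statistics.  Each
modality then yields one KNN hypergraph: every subject is the centroid of one
hyperedge containing itself plus its Z nearest neighbors in that modality's
feature space.  Modalities are fused by concatenating feature columns and
incidence columns over the shared subject set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hypergraph import Hypergraph

__all__ = [
    "ModalityFeatureTable",
    "MultimodalDataset",
    "PreprocessSpec",
    "read_feature_table",
    "read_labels",
    "preprocess_table",
    "summarize_timeseries",
    "knn_hyperedges",
    "fuse_modalities",
]

TRAIN, TEST, UNLABELED = "train", "test", "unlabeled"


@dataclass(frozen=True)
class ModalityFeatureTable:
    """Numeric node-by-feature matrix for one modality, rows aligned to node_ids."""

    modality_name: str
    node_ids: tuple[str, ...]
    features: np.ndarray
    feature_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=float)
        object.__setattr__(self, "features", X)
        if X.ndim != 2 or X.shape[0] != len(self.node_ids):
            raise ValueError("features must be 2-D with one row per node id")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise KeyError("duplicate node ids")
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite (no missing values after preprocessing)")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def dim(self) -> int:
        return self.features.shape[1]


@dataclass(frozen=True)
class MultimodalDataset:
    """Aligned modality tables + integer class labels + train/test/unlabeled mask."""

    tables: tuple[ModalityFeatureTable, ...]
    labels: np.ndarray
    split_mask: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.tables:
            raise ValueError("need at least one modality table")
        ids = self.tables[0].node_ids
        for t in self.tables[1:]:
            if t.node_ids != ids:
                raise ValueError(f"modality {t.modality_name!r} node ids misaligned")
        y = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", y)
        if y.shape != (len(ids),):
            raise ValueError("labels must have one entry per node")
        if len(self.split_mask) != len(ids):
            raise ValueError("split_mask must have one entry per node")
        for s in self.split_mask:
            if s not in (TRAIN, TEST, UNLABELED):
                raise ValueError(f"bad split flag {s!r}")

    @property
    def node_ids(self) -> tuple[str, ...]:
        return self.tables[0].node_ids

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1

    def mask(self, flag: str) -> np.ndarray:
        return np.array([s == flag for s in self.split_mask])

    def with_split(self, split_mask) -> "MultimodalDataset":
        return replace(self, split_mask=tuple(split_mask))


@dataclass(frozen=True)
class PreprocessSpec:
    """Imputation / normalization / windowing configuration.

    ``gap_interpolation_max`` and ``window_length`` are in seconds; gaps
    shorter than the threshold are linearly interpolated at the native
    sampling rate, longer gaps invalidate every window they touch.
    """

    numeric_impute: str = "mean"
    categorical_impute: str = "mode"  # or "unknown"
    normalize: str = "zscore"  # or "none"
    gap_interpolation_max: float = 5.0
    window_length: float = 30.0

    def __post_init__(self) -> None:
        if self.window_length <= 0:
            raise ValueError("window_length must be > 0")
        if self.gap_interpolation_max < 0:
            raise ValueError("gap_interpolation_max must be >= 0")
        if self.numeric_impute != "mean":
            raise ValueError("numeric_impute must be 'mean'")
        if self.categorical_impute not in ("mode", "unknown"):
            raise ValueError("categorical_impute must be 'mode' or 'unknown'")
        if self.normalize not in ("zscore", "none"):
            raise ValueError("normalize must be 'zscore' or 'none'")


def read_feature_table(path) -> pd.DataFrame:
    """Read a delimited feature table (comma or tab autodetected).

    First column must be ``node_id``; a header row is required.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype={0: str})
    if df.columns[0] != "node_id":
        raise ValueError(f"first column must be 'node_id', got {df.columns[0]!r}")
    df["node_id"] = df["node_id"].astype(str)
    return df


def read_labels(path) -> dict[str, int]:
    """Read a two-column node_id,label file into a mapping."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if list(df.columns[:2]) != ["node_id", "label"]:
        raise ValueError("labels file must have columns node_id,label")
    return {str(r.node_id): int(r.label) for r in df.itertuples()}


def preprocess_table(
    raw_table: pd.DataFrame,
    spec: PreprocessSpec,
    fit_ids: list[str] | tuple[str, ...],
    modality_name: str = "other",
) -> ModalityFeatureTable:
    """Impute, encode and normalize a raw mixed-type table.

    All statistics (column means, modes, z-score location/scale, one-hot
    category sets) come from the ``fit_ids`` rows only; remaining rows are
    transformed with those statistics.  Constant columns get a unit z-score
    divisor.  Population (ddof=0) standard deviation is used.
    """
    if "node_id" not in raw_table.columns:
        raise ValueError("raw table must have a node_id column")
    if len(fit_ids) == 0:
        raise ValueError("fit_ids must be nonempty")
    df = raw_table.copy()
    df["node_id"] = df["node_id"].astype(str)
    node_ids = tuple(df["node_id"])
    fit_set = {str(i) for i in fit_ids}
    fit_rows = df["node_id"].isin(fit_set).to_numpy()
    if not fit_rows.any():
        raise ValueError("no rows match fit_ids")

    blocks: list[np.ndarray] = []
    names: list[str] = []
    for col in df.columns:
        if col == "node_id":
            continue
        series = df[col]
        numeric = pd.to_numeric(series, errors="coerce")
        treat_numeric = pd.api.types.is_numeric_dtype(series) or (
            numeric.notna() | series.isna()).all()
        if treat_numeric:
            vals = numeric.to_numpy(dtype=float)
            fit_vals = vals[fit_rows]
            if np.all(np.isnan(fit_vals)):
                raise ValueError(f"column {col!r} entirely missing on fit rows")
            mean = np.nanmean(fit_vals)
            vals = np.where(np.isnan(vals), mean, vals)
            if spec.normalize == "zscore":
                loc = np.mean(vals[fit_rows])
                scale = np.std(vals[fit_rows])  # population std
                if scale == 0:
                    scale = 1.0
                vals = (vals - loc) / scale
            blocks.append(vals[:, None])
            names.append(col)
        else:
            cat = series.astype("string")
            fit_cat = cat[fit_rows]
            if fit_cat.isna().all():
                raise ValueError(f"column {col!r} entirely missing on fit rows")
            if spec.categorical_impute == "mode":
                mode = fit_cat.mode().iloc[0]
                cat = cat.fillna(mode)
            else:
                cat = cat.fillna("Unknown")
            categories = sorted(cat[fit_rows].dropna().unique())
            if spec.categorical_impute == "unknown" and "Unknown" not in categories:
                categories.append("Unknown")
            for level in categories:
                blocks.append((cat == level).to_numpy(dtype=float)[:, None])
                names.append(f"{col}={level}")
    if not blocks:
        raise ValueError("table has no feature columns")
    X = np.hstack(blocks)
    return ModalityFeatureTable(modality_name, node_ids, X, tuple(names))


def summarize_timeseries(times, values, spec: PreprocessSpec) -> np.ndarray:
    """Reduce a timestamped signal to ``[mean of window means, mean of window variances]``.

    Gaps shorter than ``spec.gap_interpolation_max`` are linearly interpolated
    at the native (median) sampling interval; windows of ``spec.window_length``
    seconds that overlap a longer gap (or fall outside the recorded span) are
    dropped, and the per-window mean and population variance are averaged over
    the retained windows.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != v.shape or t.size < 2:
        raise ValueError("need >= 2 time-sorted samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("samples must be strictly time-sorted")
    dt = float(np.median(np.diff(t)))
    gaps = np.diff(t)
    # long gaps: open intervals (t[i], t[i+1]) that invalidate windows
    long_gaps = [(t[i], t[i + 1]) for i in np.flatnonzero(gaps > spec.gap_interpolation_max)]
    grid = np.arange(t[0], t[-1] + dt / 2, dt)
    sig = np.interp(grid, t, v)

    W = spec.window_length
    means, variances = [], []
    start = t[0]
    while start + W <= t[-1] + dt / 2:
        stop = start + W
        if not any(g0 < stop and g1 > start for g0, g1 in long_gaps):
            sel = (grid >= start) & (grid < stop)
            if sel.any():
                w = sig[sel]
                means.append(float(np.mean(w)))
                variances.append(float(np.var(w)))
        start = stop
    if not means:
        raise ValueError("no retained windows (signal too short or too gappy)")
    return np.array([float(np.mean(means)), float(np.mean(variances))])


def knn_hyperedges(table: ModalityFeatureTable, Z: int, metric: str = "euclidean") -> Hypergraph:
    """One hyperedge per node: the centroid plus its Z nearest neighbors.

    Every hyperedge has exactly ``Z + 1`` members and always contains its
    centroid (guaranteed self-connection).  Distance ties are broken by
    ascending node index; weights are unit.
    """
    if metric != "euclidean":
        raise ValueError("only the euclidean metric is supported")
    n = table.n_nodes
    if not (0 < Z < n):
        raise ValueError(f"Z must satisfy 0 < Z < n_nodes, got Z={Z}, n={n}")
    X = table.features
    sq = np.sum(X ** 2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    B = np.zeros((n, n))
    for x in range(n):
        row = d2[x].copy()
        row[x] = -np.inf  # self excluded from the neighbor ranking
        order = np.argsort(row, kind="stable")  # ties -> ascending index
        B[x, x] = 1.0
        B[order[1:Z + 1], x] = 1.0
    return Hypergraph(B, np.ones(n), table.node_ids,
                      tuple(f"knn:{table.modality_name}:{nid}" for nid in table.node_ids))


def fuse_modalities(
    dataset: MultimodalDataset,
    Z_per_modality: list[int] | tuple[int, ...] | int,
) -> tuple[np.ndarray, Hypergraph]:
    """Concatenate modality features column-wise and KNN incidences edge-wise.

    Returns the fused node-feature matrix of width ``sum_w d(w)`` and the
    fused hypergraph with ``W * |Q|`` hyperedges over the shared node set.
    """
    W = len(dataset.tables)
    if isinstance(Z_per_modality, (int, np.integer)):
        Z_per_modality = [int(Z_per_modality)] * W
    if len(Z_per_modality) != W:
        raise ValueError("need one Z per modality")
    fused_features = np.hstack([t.features for t in dataset.tables])
    subgraphs = [knn_hyperedges(t, Z) for t, Z in zip(dataset.tables, Z_per_modality)]
    B = np.hstack([h.incidence for h in subgraphs])
    m = np.concatenate([h.edge_weights for h in subgraphs])
    eids = tuple(eid for h in subgraphs for eid in h.edge_ids)
    return fused_features, Hypergraph(B, m, dataset.node_ids, eids)
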