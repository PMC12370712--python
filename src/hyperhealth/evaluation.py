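"""Experiment harness: repeated stratified k-fold CV, metrics, ablations, Z grid.

The protocol mirrors a transductive semi-supervised evaluation: within each
fold the KNN hypergraph spans all nodes, but preprocessing statistics
(z-scoring) come from the training fold only, and the loss sees training
labels only.  Each (repeat, fold) cell retrains from scratch with seed
``base_seed + repeat * folds + fold`` so paired comparisons (ablations,
baselines, Z grid) share fold assignments and seeds exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import stats
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import StratifiedKFold

from .construction import MultimodalDataset, TRAIN, TEST
from .model import TrainConfig, train, predict

__all__ = [
    "RunConfig",
    "EvaluationReport",
    "accuracy",
    "macro_f1",
    "paired_t_test",
    "cross_validate",
    "ablate_modalities",
    "ablate_static_weighting",
    "grid_search_Z",
    "run_baseline_gcn",
]


def accuracy(labels_true, labels_pred) -> float:
    """Fraction of correct predictions."""
    yt, yp = np.asarray(labels_true), np.asarray(labels_pred)
    if yt.size == 0 or yt.shape != yp.shape:
        raise ValueError("inputs must be equal-length and nonempty")
    return float(accuracy_score(yt, yp))


def macro_f1(labels_true, labels_pred) -> float:
    """Unweighted mean of per-class F1; classes absent from both are excluded."""
    yt, yp = np.asarray(labels_true), np.asarray(labels_pred)
    if yt.size == 0 or yt.shape != yp.shape:
        raise ValueError("inputs must be equal-length and nonempty")
    return float(f1_score(yt, yp, average="macro", zero_division=0.0))


def paired_t_test(metric_a, metric_b) -> tuple[float, float]:
    """Classical paired t-test on the per-fold differences.

    Degenerate conventions: identical vectors give (0, 1.0); zero-variance
    nonzero-mean differences give (inf-signed t, p = 0.0).
    """
    a, b = np.asarray(metric_a, dtype=float), np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    n = a.size
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    d = a - b
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        return float(np.sign(mean) * np.inf), 0.0
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


@dataclass(frozen=True)
class RunConfig:
    """Cross-validation layout + per-cell training configuration."""

    Z_per_modality: tuple[int, ...] | int = 5
    folds: int = 10
    repeats: int = 10
    base_seed: int = 0
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class EvaluationReport:
    """Per-fold metric vectors (length folds*repeats) with summary statistics."""

    accuracies: np.ndarray
    f1_scores: np.ndarray
    seeds: tuple[int, ...]
    config: dict
    baseline_name: str | None = None
    paired_p_value: float | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.f1_scores))

    @property
    def sd_f1(self) -> float:
        return float(np.std(self.f1_scores, ddof=1)) if len(self.f1_scores) > 1 else 0.0

    def to_dict(self) -> dict:
        d = {
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "mean_f1": self.mean_f1,
            "sd_f1": self.sd_f1,
            "accuracies": [float(a) for a in self.accuracies],
            "f1_scores": [float(f) for f in self.f1_scores],
            "seeds": list(self.seeds),
            "config": self.config,
        }
        if self.baseline_name is not None:
            d["baseline"] = self.baseline_name
            d["paired_p_value"] = self.paired_p_value
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def _fold_cells(dataset: MultimodalDataset, config: RunConfig):
    """Yield (cell_seed, split_mask) for every repeat x fold, repeat-major."""
    y = dataset.labels
    per_class = np.bincount(y)
    if per_class.min() < config.folds:
        raise ValueError(
            f"smallest class has {per_class.min()} members; needs >= folds={config.folds}")
    idx = np.arange(dataset.n_nodes)
    for r in range(config.repeats):
        skf = StratifiedKFold(n_splits=config.folds, shuffle=True,
                              random_state=config.base_seed + r)
        for f, (train_idx, test_idx) in enumerate(skf.split(idx, y)):
            split = np.array([TRAIN] * dataset.n_nodes, dtype=object)
            split[test_idx] = TEST
            yield config.base_seed + r * config.folds + f, tuple(split)


def cross_validate(dataset: MultimodalDataset, config: RunConfig) -> EvaluationReport:
    """Repeated stratified k-fold CV, retraining from scratch per cell."""
    accs, f1s, seeds = [], [], []
    for cell_seed, split in _fold_cells(dataset, config):
        ds = dataset.with_split(split)
        tc = replace(config.train, seed=cell_seed)
        model, _, op, X0 = train(ds, tc, config.Z_per_modality)
        test_idx = np.flatnonzero(ds.mask(TEST))
        pred, _ = predict(model, op, X0, test_idx)
        accs.append(accuracy(ds.labels[test_idx], pred))
        f1s.append(macro_f1(ds.labels[test_idx], pred))
        seeds.append(cell_seed)
    return EvaluationReport(np.array(accs), np.array(f1s), tuple(seeds),
                            _config_snapshot(config))


def _config_snapshot(config: RunConfig) -> dict:
    d = asdict(config)
    if isinstance(d["Z_per_modality"], tuple):
        d["Z_per_modality"] = list(d["Z_per_modality"])
    return d


def _drop_modality(dataset: MultimodalDataset, w: int) -> MultimodalDataset:
    tables = tuple(t for i, t in enumerate(dataset.tables) if i != w)
    return MultimodalDataset(tables, dataset.labels, dataset.split_mask)


def ablate_modalities(dataset: MultimodalDataset, config: RunConfig) -> dict[str, EvaluationReport]:
    """Full model plus one leave-one-modality-out run per modality.

    All runs share fold assignments and seeds; leave-one-out reports carry the
    paired t-test p-value against the full model.
    """
    if len(dataset.tables) < 2:
        raise ValueError("modality ablation needs >= 2 modalities")
    W = len(dataset.tables)
    Z = config.Z_per_modality
    Zs = [Z] * W if isinstance(Z, (int, np.integer)) else list(Z)
    full = cross_validate(dataset, replace(config, Z_per_modality=tuple(Zs)))
    out = {"full": full}
    for w, t in enumerate(dataset.tables):
        sub = _drop_modality(dataset, w)
        sub_Z = tuple(z for i, z in enumerate(Zs) if i != w)
        rep = cross_validate(sub, replace(config, Z_per_modality=sub_Z))
        _, p = paired_t_test(full.accuracies, rep.accuracies)
        rep.baseline_name = "full"
        rep.paired_p_value = p
        out[f"without_{t.modality_name}"] = rep
    return out


def ablate_static_weighting(dataset: MultimodalDataset, config: RunConfig) -> dict[str, EvaluationReport]:
    """Adaptive per-node gate vs a fixed 0.5 gate, under identical folds/seeds."""
    adaptive = cross_validate(
        dataset, replace(config, train=replace(config.train, adaptive_gate=True)))
    static = cross_validate(
        dataset, replace(config, train=replace(config.train, adaptive_gate=False)))
    _, p = paired_t_test(adaptive.accuracies, static.accuracies)
    static.baseline_name = "adaptive"
    static.paired_p_value = p
    return {"adaptive": adaptive, "static": static}


def grid_search_Z(dataset: MultimodalDataset, Z_values, config: RunConfig) -> list[dict]:
    """One CV run per hyperedge-size Z (shared seeds); rows of Z vs accuracy."""
    n = dataset.n_nodes
    for Z in Z_values:
        if not 0 < Z < n:
            raise ValueError(f"Z={Z} must be in (0, n_nodes={n})")
    rows = []
    for Z in Z_values:
        rep = cross_validate(dataset, replace(config, Z_per_modality=int(Z)))
        rows.append({"Z": int(Z), "mean_accuracy": rep.mean_accuracy,
                     "sd_accuracy": rep.sd_accuracy, "mean_f1": rep.mean_f1})
    return rows


def run_baseline_gcn(dataset: MultimodalDataset, config: RunConfig) -> EvaluationReport:
    """Clique-expansion GCN baseline: same folds/seeds, same decoupled head.

    The fused hypergraph is expanded to a simple graph and propagated with the
    symmetric degree-normalized adjacency-with-self-loops operator.
    """
    rep = cross_validate(
        dataset, replace(config, train=replace(config.train, operator_kind="gcn")))
    rep.baseline_name = "gcn"
    return rep
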