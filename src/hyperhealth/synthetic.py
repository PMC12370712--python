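"""Seeded generator of synthetic multimodal elderly-cohort datasets.

Emulates a small monitored cohort: ~50 subjects, three risk classes
(low / moderate / high) and three feature modalities (physiological,
behavioral, environmental).  Class-conditional features are Gaussian with
class means placed at mutually orthogonal random directions separated by
``effect_size * noise_sd`` and isotropic noise ``noise_sd^2`` — the simplest
structure a KNN hypergraph can exploit.  Raw-input generators produce
1 Hz sinusoid-plus-noise vitals streams with sensor gaps, and a cell-blanking
degrader for testing imputation.  Every generator is a pure function of
(spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .construction import ModalityFeatureTable, MultimodalDataset, TRAIN, TEST

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "simulate_cohort",
    "simulate_raw_physiology",
    "degrade_table",
]

MODALITY_NAMES = ("physiological", "behavioral", "environmental")
CLASS_NAMES = ("low", "moderate", "high")


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one simulated cohort.

    ``effect_size`` is the pairwise class-mean separation in within-class
    standard-deviation units; a scalar applies to every modality, a
    per-modality tuple makes some modalities uninformative (0).
    """

    n_subjects: int = 50
    class_proportions: tuple[float, ...] = (0.4, 0.3, 0.3)
    modality_dims: tuple[int, ...] = (8, 6, 4)
    effect_size: float | tuple[float, ...] = 3.0
    noise_sd: float = 1.0
    missing_rate: float = 0.05
    gap_rate: float = 4.0  # expected sensor gaps per hour
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < len(self.class_proportions):
            raise ValueError("need at least one subject per class")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if any(d < 1 for d in self.modality_dims):
            raise ValueError("modality dims must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        es = self.effect_sizes
        if any(e < 0 for e in es):
            raise ValueError("effect_size must be >= 0")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        for c, p in enumerate(self.class_proportions):
            if int(round(p * self.n_subjects)) == 0:
                raise ValueError(f"class {c} has zero expected members at n={self.n_subjects}")

    @property
    def n_classes(self) -> int:
        return len(self.class_proportions)

    @property
    def effect_sizes(self) -> tuple[float, ...]:
        if isinstance(self.effect_size, (int, float)):
            return (float(self.effect_size),) * len(self.modality_dims)
        if len(self.effect_size) != len(self.modality_dims):
            raise ValueError("need one effect size per modality")
        return tuple(float(e) for e in self.effect_size)


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters behind an emitted cohort."""

    labels: np.ndarray
    informative: tuple[bool, ...]  # per modality
    class_means: tuple[np.ndarray, ...]  # per modality: (C, d_w)
    noise_sd: float


def _apportion(n: int, proportions) -> np.ndarray:
    """Largest-remainder class counts summing exactly to n."""
    raw = np.asarray(proportions) * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def _class_means(rng, C: int, d: int, separation: float) -> np.ndarray:
    """C mean vectors, pairwise euclidean distance exactly ``separation``.

    Mutually orthogonal random unit directions scaled by separation/sqrt(2).
    Requires d >= C.
    """
    if d < C:
        raise ValueError("modality dimension must be >= number of classes")
    A = rng.standard_normal((d, C))
    Q, _ = np.linalg.qr(A)
    return (separation / np.sqrt(2.0)) * Q.T  # (C, d)


def simulate_cohort(spec: CohortSpec) -> tuple[MultimodalDataset, GroundTruth]:
    """Draw one cohort: aligned modality tables, labels, stratified 80/20 split.

    Class counts follow ``class_proportions`` exactly (largest-remainder
    rounding) and are shuffled over subjects; the train/test split is
    stratified with ``round(test_fraction * n_c)`` test subjects per class
    (40/10 at the default n=50).
    """
    rng = np.random.default_rng(spec.seed)
    n, C = spec.n_subjects, spec.n_classes
    counts = _apportion(n, spec.class_proportions)
    labels = np.repeat(np.arange(C), counts)
    rng.shuffle(labels)
    node_ids = tuple(f"s{i:03d}" for i in range(n))

    tables = []
    means_per_modality = []
    for w, (name, d, es) in enumerate(zip(MODALITY_NAMES, spec.modality_dims,
                                          spec.effect_sizes)):
        mu = _class_means(rng, C, d, es * spec.noise_sd)
        X = mu[labels] + spec.noise_sd * rng.standard_normal((n, d))
        tables.append(ModalityFeatureTable(
            name, node_ids, X, tuple(f"{name[:4]}_{j}" for j in range(d))))
        means_per_modality.append(mu)

    split = np.array([TRAIN] * n, dtype=object)
    for c in range(C):
        members = np.flatnonzero(labels == c)
        n_test = int(round(spec.test_fraction * len(members)))
        test_members = rng.choice(members, size=n_test, replace=False)
        split[test_members] = TEST

    dataset = MultimodalDataset(tuple(tables), labels, tuple(split))
    truth = GroundTruth(
        labels=labels.copy(),
        informative=tuple(e > 0 for e in spec.effect_sizes),
        class_means=tuple(means_per_modality),
        noise_sd=spec.noise_sd,
    )
    return dataset, truth


def simulate_raw_physiology(
    spec: CohortSpec,
    labels: np.ndarray | None = None,
    duration_s: float = 600.0,
    class_mean_levels: tuple[float, ...] = (60.0, 75.0, 90.0),
    amplitude: float = 5.0,
    period_s: float = 60.0,
    signal_noise_sd: float = 0.0,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-subject 1 Hz heart-rate-like streams with injected sensor gaps.

    Each stream is ``level_c + amplitude * sin(2 pi t / period) + noise``
    where ``level_c`` depends on the subject's risk class.  Gaps (dropped
    samples) occur at ``spec.gap_rate`` per hour with uniform 2–10 s length.
    Returns ``{subject_id: (times, values)}``.
    """
    rng = np.random.default_rng(spec.seed + 1_000_003)
    if labels is None:
        counts = _apportion(spec.n_subjects, spec.class_proportions)
        labels = np.repeat(np.arange(spec.n_classes), counts)
        rng_l = np.random.default_rng(spec.seed)
        rng_l.shuffle(labels)
    out = {}
    t = np.arange(0.0, duration_s, 1.0)
    for i in range(spec.n_subjects):
        level = class_mean_levels[int(labels[i]) % len(class_mean_levels)]
        v = level + amplitude * np.sin(2 * np.pi * t / period_s)
        if signal_noise_sd > 0:
            v = v + signal_noise_sd * rng.standard_normal(t.shape)
        keep = np.ones(t.shape, dtype=bool)
        n_gaps = rng.poisson(spec.gap_rate * duration_s / 3600.0)
        for _ in range(n_gaps):
            g0 = rng.uniform(0, duration_s)
            glen = rng.uniform(2.0, 10.0)
            keep &= ~((t > g0) & (t < g0 + glen))
        out[f"s{i:03d}"] = (t[keep], v[keep])
    return out


def degrade_table(table: pd.DataFrame, missing_rate: float, seed: int) -> pd.DataFrame:
    """Blank each non-id cell independently with probability ``missing_rate``."""
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = table.copy()
    for col in out.columns:
        if col == "node_id":
            continue
        blank = rng.random(len(out)) < missing_rate
        out[col] = out[col].astype(object).where(~blank, other=np.nan)
    return out


def dataset_to_tables(dataset: MultimodalDataset) -> dict[str, pd.DataFrame]:
    """Modality tables as delimited-text-ready DataFrames (node_id first column)."""
    out = {}
    for t in dataset.tables:
        df = pd.DataFrame(t.features,
                          columns=t.feature_names or [f"f{j}" for j in range(t.dim)])
        df.insert(0, "node_id", list(t.node_ids))
        out[t.modality_name] = df
    return out
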