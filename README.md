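# hyperhealth

Multimodal hypergraph convolutional networks for health-risk classification
of small monitored cohorts — e.g. elderly participants wearing physiological
sensors, carrying activity trackers, and living with ambient IoT sensors.

Subjects in such a cohort are related in ways that go beyond pairwise
similarity: a group of participants can share a physiological profile, an
activity pattern, or a living environment. `hyperhealth` models each such
group as a *hyperedge* — an edge joining any number of nodes — and classifies
subjects into risk categories (low / moderate / high) by propagating features
over the resulting hypergraph.

## The model

For a hypergraph with binary incidence matrix **B** (|Q| nodes × |E|
hyperedges), hyperedge weights **M** (unit here), node degrees
**D**<sub>q</sub> and hyperedge degrees **D**<sub>e</sub>, the normalized
hypergraph Laplacian is

&nbsp;&nbsp;&nbsp; L = I − D<sub>q</sub><sup>−1/2</sup> B M D<sub>e</sub><sup>−1</sup> Bᵀ D<sub>q</sub><sup>−1/2</sup>

which is symmetric positive semidefinite. Both the spectral-domain
convolution (filtering in L's eigenbasis with response 1 − λ) and the
spatial node→hyperedge→node message passing collapse to one fixed linear
aggregator **G**:

* spectral: G = D<sub>q</sub><sup>−1/2</sup> B M D<sub>e</sub><sup>−1</sup> Bᵀ D<sub>q</sub><sup>−1/2</sup> = I − L
* spatial: G = D<sub>q</sub><sup>−1</sup> B M D<sub>e</sub><sup>−1</sup> Bᵀ (row-stochastic)

The classifier is *decoupled*: propagation and transformation are separate.
Raw fused features X⁰ are smoothed L times, and a learnable per-node gate
adds back a fraction of each node's raw features to counter oversmoothing:

&nbsp;&nbsp;&nbsp; H = G<sup>L</sup> X⁰ + diag(σ(R)) X⁰

H feeds a two-layer fully connected head (hidden width 128, ReLU, dropout
0.5) producing one score per risk class. Training is transductive and
full-batch: the hypergraph covers all subjects, cross-entropy is evaluated on
the training mask only, and R, the weights and biases are optimized jointly
with Adam (lr 10⁻³, weight decay 5·10⁻⁴, lr × 0.7 every 200 epochs,
600 epochs).

The hypergraph itself is built per modality by KNN: each subject is the
centroid of one hyperedge containing itself and its Z nearest neighbors in
that modality's (z-scored) feature space. Modalities are fused by
concatenating feature columns and incidence columns, so W modalities over |Q|
subjects give W·|Q| hyperedges. A clique-expansion GCN baseline (each
hyperedge replaced by a clique, symmetric normalized adjacency with
self-loops) runs under the identical protocol for comparison.

## Worked example

```python
from hyperhealth import (CohortSpec, RunConfig, simulate_cohort,
                         cross_validate, run_baseline_gcn, ablate_modalities)

# 50 subjects, 3 risk classes; physiological features most informative
spec = CohortSpec(n_subjects=50, effect_size=(2.0, 1.0, 0.5), seed=7)
dataset, truth = simulate_cohort(spec)

cfg = RunConfig(Z_per_modality=5, folds=10, repeats=2, base_seed=7)
rep = cross_validate(dataset, cfg)
gcn = run_baseline_gcn(dataset, cfg)
print(f"HGCN : accuracy {rep.mean_accuracy:.3f} +/- {rep.sd_accuracy:.3f}, "
      f"macro-F1 {rep.mean_f1:.3f}")
print(f"GCN  : accuracy {gcn.mean_accuracy:.3f} +/- {gcn.sd_accuracy:.3f}, "
      f"macro-F1 {gcn.mean_f1:.3f}")
for name, r in ablate_modalities(dataset, cfg).items():
    print(f"{name:25s} accuracy {r.mean_accuracy:.3f}")
```

prints

```
HGCN : accuracy 0.720 +/- 0.209, macro-F1 0.670
GCN  : accuracy 0.720 +/- 0.209, macro-F1 0.678
full                      accuracy 0.720
without_physiological     accuracy 0.510
without_behavioral        accuracy 0.740
without_environmental     accuracy 0.690
```

Accuracy is the mean over 2 × 10 stratified CV folds (each fold retrains
from scratch). Dropping the physiological modality — the one carrying most
of the class signal in this simulation — costs 21 accuracy points, while
dropping the weakly informative modalities changes little; this is the
leave-one-modality-out ablation, and the per-fold pairing (shared folds and
seeds across all runs) makes the deltas directly comparable.

The same experiments are available from a shell:

```bash
hyperhealth --out data --seed 7 simulate
hyperhealth --config run.json --seed 7 --out results evaluate
hyperhealth --config run.json --seed 7 --out results ablate --mode modality
hyperhealth --config run.json --seed 7 --out results gridsearch-z --z-values 3,5,8
```

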