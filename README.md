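# pairpred

Pairwise kernel methods for predicting whether two protein structures
interact.

Docking answers *how* two proteins interact, but is far too expensive to
screen the millions of candidate pairs in an interactome. `pairpred`
addresses the cheaper yes/no question — *do* these two structures
interact? — by casting it as binary classification over pairs of
proteins, using kernel methods that need nothing but a precomputed
all-vs-all similarity (e.g. structural-alignment scores) or the raw
amino-acid sequences.

## What it implements

**Base kernels on proteins.**
An all-vs-all structural similarity matrix `M` is symmetric but
indefinite, so it is not a valid kernel. It is corrected through its
eigendecomposition `M = U D Uᵀ`, replacing each eigenvalue λ by
ψ(λ) = 1 + λ for λ > 0 and 0 otherwise (ψ(λ) = λ² is available as an
option), and then normalized onto the unit sphere,
K′(x, y) = K(x, y)/√(K(x, x)·K(y, y)).
For sequences, the (k, m)-**mismatch kernel** (default k = 6, m = 1)
counts shared k-mers up to m mismatches without ever materializing the
20⁶-dimensional feature space.

**Kernels on pairs.** Two constructions lift a base kernel K to
unordered pairs:

- TPPK (tensor product pairwise kernel):
  `K((p₁,p₂),(q₁,q₂)) = K(p₁,q₁)K(p₂,q₂) + K(p₁,q₂)K(p₂,q₁)`,
  computed after adding 1 to the normalized base kernel so its values
  lie in [0, 2] and products of strong dissimilarities cannot masquerade
  as similarity;
- MLPK (metric learning pairwise kernel):
  `K((p₁,p₂),(q₁,q₂)) = (K(p₁,q₁) − K(p₁,q₂) − K(p₂,q₁) + K(p₂,q₂))²`,
  the squared inner product of within-pair difference features
  (invariant to constant shifts of the base kernel).

**Classifiers.** A kernelized k-nearest-neighbor whose discriminant is
the difference of summed feature-space distances to the k nearest
negatives and k nearest positives, and a soft-margin SVM with
asymmetric per-class costs C⁺, C⁻ for the imbalanced setting, trained
on the precomputed pair-kernel Gram matrix. Platt scaling converts SVM
discriminants to probabilities.

**Evaluation.** 5-fold cross-validation repeated three times (15
splits), internal 5-fold grid search for C⁺ ∈ {10⁻⁸..10⁸},
C⁺/C⁻ ∈ {3, 10, 100} (NN: k ∈ {1, 2, 3, 5, 10, 15}), area under the
precision-recall curve (average precision), extrapolation of measured
precision from the benchmark ratio r = 3 to a realistic ratio
r′ = (v(v−1)/2 − e)/e via p/(p + (r′/r)(1 − p)), and exact Wilcoxon
signed-rank comparison of methods displayed as a transitively reduced
dominance graph.

**Benchmark construction.** Uniform negative sampling (5 negatives per
positive), collapse of redundant pairs linking the same two sequence
clusters, a 50-residue length filter, downsampling of negatives to
3:1, and screening of genome-scale candidate pairs whose BLAST
E-value distance to any training pair is below 0.01.

**Synthetic data.** A planted-signal generator emulates every input
(similarity matrix, FASTA, labeled pairs, clusters, E-values) so the
whole pipeline is testable offline; see `docs/methods.md`.

## Worked example

```python
import numpy as np
from pairpred import (PlantedModel, gen_similarity, gen_benchmark,
                      spectral_correct, unit_normalize, shift_base,
                      mlpk, tppk, cross_validate, compare_methods,
                      transitive_reduction)

model = PlantedModel(seed=0)                 # 120 proteins, 4 families
S = gen_similarity(model)                    # indefinite score matrix
dataset, clusters, evalues, lengths = gen_benchmark(model)
print(f"benchmark: {dataset.n_pos} interacting, "
      f"{dataset.n_neg} non-interacting pairs")

K = unit_normalize(spectral_correct(S))      # psi(lambda) = 1 + lambda
Kb = shift_base(K)                           # entries now in [0, 2]
results = {}
for name, builder in [("SVM+MLPK", mlpk), ("SVM+TPPK", tppk)]:
    Kp = builder(Kb, dataset.pairs)
    res = cross_validate(Kp, dataset.y, classifier="svm", seed=0,
                         c_plus_grid=(1e-4, 1e-2, 1, 1e2, 1e4))
    results[name] = res
    print(f"{name}: mean 3x5cv AUC-PR = {res.mean_auc:.3f}")
prior = dataset.n_pos / len(dataset)
print(f"class prior (random-ranking baseline) = {prior:.2f}")
G = transitive_reduction(compare_methods(
    {m: np.array(r.aucs) for m, r in results.items()}))
print("dominance edges:", list(G.edges) or "none (methods statistically tied)")
```

prints

```
benchmark: 93 interacting, 279 non-interacting pairs
SVM+MLPK: mean 3x5cv AUC-PR = 0.642
SVM+TPPK: mean 3x5cv AUC-PR = 0.623
class prior (random-ranking baseline) = 0.25
dominance edges: none (methods statistically tied)
```

The benchmark is built at the 3:1 negative:positive ratio, so a random
ranking scores ≈ 0.25; both pairwise kernels recover the planted
family-compatibility signal far above that baseline, and on this
synthetic block model the two constructions are statistically tied
(no Wilcoxon edge at p < 0.05 across the 15 splits).

The same pipeline is available from the shell:

```sh
pairpred simulate --n-proteins 120 --seed 0 --out data/
pairpred crossval --kernel mammoth-matrix --matrix data/similarity.tsv \
    --pairs data/pairs.tsv --pairwise mlpk --pairwise tppk \
    --classifier svm --quick-grid --seed 0 --out results/
```

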