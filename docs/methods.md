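# Methods

## Problem setting

Given a set of proteins with either an all-vs-all structural similarity
matrix (scores from a structural aligner such as MAMMOTH, treated as an
arbitrary symmetric score `s(p, q)`) or amino-acid sequences, and a set
of labeled protein pairs (interacting / non-interacting), the package
trains a kernel classifier over *pairs* of proteins and evaluates it
under class imbalance. Every stage is deterministic given its seed.

## Base kernels

**Spectral correction.** A raw score matrix `M` is symmetric but almost
always indefinite, hence unusable as a kernel. We eigendecompose
`M = U diag(λ₁..λₙ) Uᵀ` and rebuild with ψ(λ) = 1 + λ for λ > ε and 0
otherwise (ε = 10⁻¹⁰·max|λ|, guarding against spurious float
eigenvalues of either sign; the score scale is unitless so the absolute
cutoff is relative). For strictly positive spectra this equals
`M + UUᵀ`: the negative eigenspace is discarded and a unit ridge is
added on the retained one. The alternative ψ(λ) = λ², which also yields
a PSD matrix while preserving eigenvector structure, is exposed as
`psi="square"`. Asymmetric input (common in raw aligner output) is
symmetrized as `(S + Sᵀ)/2` with a logged warning rather than rejected.

**Normalization.** Kernels are projected onto the unit sphere,
`K′(x,y) = K(x,y)/√(K(x,x)K(y,y))`, before any pairwise construction.
A zero or negative diagonal entry means the protein has no
feature-space representation after correction; we raise an error naming
the protein rather than dropping it silently, because a silently
shrinking id set corrupts downstream pair lists.

**Mismatch kernel.** A sequence is represented by occurrence counts of
all k-mers, where an observed k-mer also counts toward every k-mer
within Hamming distance m (defaults k = 6, m = 1 over the 20 standard
residues). Rather than materializing the |A|ᵏ feature space, the Gram
entry is computed as Σ over observed k-mer pairs (α, α′) of
|N(α) ∩ N(α′)|, and this intersection size depends only on the Hamming
distance d(α, α′): a k-mer β in both neighborhoods is described by how
many positions match α, match α′, or differ from both, giving a small
combinatorial sum (zero beyond d = 2m). Distances between observed
k-mer sets are computed vectorized, so cost is O(L₁L₂k) per sequence
pair with memory O(L₁L₂). Windows containing nonstandard residues
(X, B, Z, U, ...) are skipped by default (`nonstandard="error"` to
reject instead); only the 20-letter alphabet carries signal here.

## Pairwise kernels

TPPK: `K(p₁,q₁)K(p₂,q₂) + K(p₁,q₂)K(p₂,q₁)` — pairs are similar when
members can be matched one-to-one. Because two strongly *negative* base
values multiply to a large positive value, TPPK requires the base
kernel shifted by +1 (normalized entries then lie in [0, 2]); the
constructor enforces the flag. An optional `half=True` multiplies by ½
(some formulations include the factor); default off, since only the
relative scale matters to both classifiers after hyperparameter search.

MLPK: `(K(p₁,q₁) − K(p₁,q₂) − K(p₂,q₁) + K(p₂,q₂))²` — the squared
inner product of within-pair difference features. The four signs cancel
any constant added to the base kernel, so the +1 shift applied for
consistency with TPPK provably has no numeric effect (a unit test
asserts this). Self-pairs have the zero difference feature and MLPK
value 0.

Both constructions are PSD whenever the base kernel is; pair lists are
canonicalized (lexicographic member order) at parse time so member-swap
symmetry is structural. Large pair-kernel matrices are assembled in
512-row blocks; results are identical to full materialization.

## Classifiers

**Kernel NN.** Feature-space distance
`d(x, y) = √(K(x,x) − 2K(x,y) + K(y,y))` (radicands in [−10⁻⁹, 0) are
clamped to 0; anything lower raises, as it indicates an invalid
kernel). The discriminant is Σ distances to the k nearest negatives
minus Σ distances to the k nearest positives, so positive score =
interacting; ties at equal distance are broken by canonical pair id to
keep results order-independent. k must not exceed the smaller class.

**SVM.** The asymmetric-cost soft-margin dual — box constraints
αᵢ ≤ C⁺ for positives, αᵢ ≤ C⁻ for negatives — is solved by
scikit-learn's SMO on the precomputed Gram matrix with `C=1` and
per-class weights equal to the costs, which makes the box constraints
exactly C⁺/C⁻. Solver tolerance 10⁻⁶; the iteration cap is high
(10⁷) and hitting it logs a warning. The model stores the full dual
coefficient vector αᵢyᵢ and bias, and evaluates
`f(x) = Σ αᵢyᵢ K(x, xᵢ) + b` itself; an independent SLSQP
quadratic-program oracle in the test suite checks the dual objective
to 10⁻⁶.

**Platt scaling.** `P(y=1|f) = 1/(1 + exp(a·f + b))` fitted by Newton
iterations with backtracking on the cross-entropy, using the standard
prior-smoothed targets `t⁺ = (N⁺+1)/(N⁺+2)`, `t⁻ = 1/(N⁻+2)`, which
keep parameters finite on separable calibration data. The `predict`
pipeline trains on 90% of the labeled pairs and calibrates on the held
10%.

## Evaluation protocol

**3×5cv.** Five folds, three independent repeats, stratified by label
at the *pair* level. Proteins may appear on both sides of a split; this
leakage is inherent to pair-level splitting and is documented rather
than "fixed", because the protocol being modeled splits pairs.
Stratification uses a round-robin dealer with the negative stream
offset by (#positives mod folds), so fold sizes differ by at most one
both overall and per class. Per-repeat RNG streams are spawned from the
top-level seed.

**Hyperparameters.** Internal 5-fold CV on each training set maximizes
mean AUC-PR over C⁺ ∈ {10⁻⁸..10⁸} × C⁺/C⁻ ∈ {3, 10, 100} (51
combinations) for the SVM, k ∈ {1, 2, 3, 5, 10, 15} for NN; ties go to
the smaller C⁺ (then smaller ratio) or smaller k, preferring the
stronger-regularized model. Infeasible k values (exceeding the smaller
class of an inner fold) are skipped with a warning.

**PR analysis.** Precision/recall at every distinct score threshold
with ties grouped; AUC-PR is average precision (Σ ΔTP·precision /
#positives, no interpolation), checked exhaustively against a
brute-force oracle on all 2⁸ label arrangements of 8 points and
against scikit-learn. Constant scores give a single-point curve with
AUC equal to prevalence, with a warning. For plotting, per-split
precisions are vertically averaged on a fixed 100-point recall grid;
AUC is always computed per split first.

**Precision extrapolation.** Benchmarks fix negatives:positives at
r = 3, but among v proteins with e interacting pairs the realistic
ratio is r′ = (v(v−1)/2 − e)/e, so measured precision p is reported as
p/(p + (r′/r)(1 − p)) — fixed points at 0 and 1, identity at r′ = r,
strictly increasing in p.

**Method comparison.** Paired Wilcoxon signed-rank over the 15 per-split
AUC values: zero differences dropped, midranks for ties, the exact null
distribution of the positive-rank sum computed by dynamic programming
over doubled (hence integer) ranks, two-sided p by doubling the smaller
tail. An edge A→B requires p < 0.05 with the rank sum favoring A; the
displayed graph is the transitive reduction (a cycle, possible in
principle for paired tests, is reported and the graph returned
unreduced).

## Benchmark construction

Negatives are sampled uniformly without replacement from unordered
non-interacting pairs, five per positive. Redundant pairs linking the
same two sequence clusters are collapsed: all-negative groups keep one
at random; mixed groups keep only positives; multi-positive groups keep
the positive with the fewest positive neighbors (pairs sharing a
protein, counted on the pre-filter positive set), ties seeded-random.
Negatives with a member shorter than 50 residues are removed and the
rest downsampled to ⌊3 × #positives⌋ (if fewer survive, all are kept
with a warning). Candidate pairs for genome-scale prediction are
screened by the E-value distance
`min(max(E(p₁,q₁), E(p₂,q₂)), max(E(p₁,q₂), E(p₂,q₁)))` to each
training pair — members are matched in the closer of the two ways and
the worse E-value within a matching governs, since both members must be
similar for the pairs to be redundant; missing E-values read as +∞ and
candidates whose minimum distance does not exceed 0.01 are dropped.

## Synthetic data

The generator emulates the four inputs without downloads. Proteins
belong to latent structural families (default 120 proteins, 4 equal
families). Similarity is Gaussian around 6 ± 1.5 within a family and
1 ± 1 across (self-similarity 10), drawn asymmetrically and
symmetrized by averaging — the resulting matrix is indefinite, as real
aligner score matrices are, so the correction path is exercised
non-trivially. Interaction is planted through a symmetric family-pair
compatibility table (default: families 0–1 and 2–3 interact); 100
positives are drawn, of which 10% are uniform noise pairs emulating
label noise. Sequences are per-family ancestors (length 60–220)
mutated at 10% per site. Sequence clusters are *finer* than families —
sub-clusters of 2 near-identical members — mimicking high-identity
sequence clustering within a structural fold; were clusters as coarse
as families, the cluster-link filter would collapse every positive
linking one compatible family pair to a single survivor and destroy
the benchmark. E-values are 10⁻⁶⁰–10⁻²⁰ within a cluster,
10⁻⁸–10⁻³ within a family, absent (+∞) across families. The full
pipeline (5× negative sampling → cluster-link filter → length filter
and 3:1 downsampling) yields ≈ 93 positives and exactly three times as
many negatives.

What the generator does *not* emulate: continuous gradation of
structural similarity (scores are flat two-level blocks plus noise),
domain architecture, indels, and homology between families. One
consequence is measurable: with a flat block model the four base-kernel
entries entering TPPK and MLPK are approximately two-valued, so the two
pairwise constructions carry essentially the same information and
perform statistically indistinguishably (SVM+MLPK wins roughly 5–6 of
10 generator seeds, at every grid size tried). The empirically reported
superiority of MLPK+SVM on real benchmarks plausibly rests on metric
structure in real alignment scores that this generator lacks; passing
planted-signal tests therefore demonstrates that the pipeline recovers
a recoverable signal, not that the method ranking on real data is
reproduced.

## Problem sizes and runtime choices

Signal-recovery runs (tests and `scripts/acceptance.py`) use a reduced
SVM grid, C⁺ ∈ {10⁻⁴, 10⁻², 1, 10², 10⁴} × ratio {3, 10, 100}, and the
default 120-protein benchmark; a full 17-value grid changes mean AUC-PR
by < 0.01 on this problem while multiplying runtime several-fold. The
10-seed MLPK-vs-TPPK comparison plus the property suite completes in
about two minutes on one CPU.

## Known limitations

- Pair-level CV leaks protein identity across folds (by design, see
  above); protein-disjoint splitting would measure a harder
  generalization task.
- The NN discriminant's distances depend on whether the base kernel was
  +1-shifted (the shift changes pairwise-kernel geometry); the pair
  kernel records `base_shifted` and the pipeline always shifts before
  TPPK, so reported NN results are under the shifted convention.
- `sample_negatives` enumerates the candidate pool and is intended for
  benchmark-scale inputs (≲ a few thousand proteins), not genome-scale
  enumeration.
- The exact Wilcoxon null is computed by enumeration-equivalent DP and
  is exact for the 15-split protocol; for hundreds of splits a normal
  approximation would be preferable.
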