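"""Synthetic inputs with a planted interaction signal.

The generator emulates the inputs the pipeline consumes in practice --
an all-vs-all structural similarity matrix, protein sequences, labeled
interaction pairs, sequence clusters, and a BLAST-style E-value table
-- without any external data.  Proteins belong to latent structural
families; structural similarity is high within a family and low across
families, and whether two proteins interact is governed by a symmetric
family-pair compatibility table.  A learnable signal therefore exists:
the family memberships are recoverable from similarity, and the
compatibility table maps family pairs to labels.

Raw similarity is drawn with *asymmetric* noise and then symmetrized,
which makes the score matrix indefinite (as real aligner score matrices
are), so the spectral-correction path is exercised non-trivially.

Sequence clusters are finer than structural families: each family is
partitioned into small sub-clusters of near-identical sequences,
mimicking high-identity sequence clustering within a structural fold.
E-values are tiny within a cluster, moderate within a family, and
absent (infinite) across families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pairpred.benchmark import (
    ClusterAssignment,
    EvalueTable,
    finalize_ratio,
    link_cluster_filter,
    sample_negatives,
)
from pairpred.kernels import STANDARD_AA
from pairpred.matrices import SimilarityMatrix
from pairpred.pairs import PairDataset, ProteinPair

_DEFAULT_COMPAT = ((0, 1), (2, 3))


@dataclass(frozen=True)
class PlantedModel:
    """Parameters of the planted-signal generator.

    The defaults give ~120 proteins in 4 equal families with two
    compatible family pairs, ~100 interacting pairs, and the standard
    5x negative oversampling followed by redundancy filtering and 3:1
    downsampling -- small enough that the full repeated-CV protocol
    runs in minutes on one CPU.
    """

    n_proteins: int = 120
    n_families: int = 4
    within_mean: float = 6.0
    within_sd: float = 1.5
    between_mean: float = 1.0
    between_sd: float = 1.0
    self_similarity: float = 10.0
    compatible: tuple[tuple[int, int], ...] = _DEFAULT_COMPAT
    n_positives: int = 100
    positive_rate: float = 0.9
    negative_multiplier: int = 5
    ratio: float = 3.0
    min_length: int = 50
    cluster_size: int = 2
    length_range: tuple[int, int] = (60, 220)
    mutation_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.within_sd < 0 or self.between_sd < 0:
            raise ValueError("similarity standard deviations must be >= 0")
        if self.n_families < 1 or self.n_proteins < self.n_families:
            raise ValueError("need at least one protein per family")
        if not 0.0 <= self.positive_rate <= 1.0:
            raise ValueError("positive_rate must lie in [0, 1]")
        compat = set()
        for a, b in self.compatible:
            if not (0 <= a < self.n_families and 0 <= b < self.n_families):
                raise ValueError(f"family index out of range in {(a, b)}")
            compat.add((min(a, b), max(a, b)))
        object.__setattr__(self, "compatible", tuple(sorted(compat)))

    @property
    def protein_ids(self) -> tuple[str, ...]:
        return tuple(f"P{i:04d}" for i in range(self.n_proteins))

    def families(self) -> dict[str, int]:
        """Deterministic assignment of proteins to families (balanced,
        contiguous blocks)."""
        ids = self.protein_ids
        return {pid: i * self.n_families // self.n_proteins for i, pid in enumerate(ids)}

    def is_compatible(self, fa: int, fb: int) -> bool:
        return (min(fa, fb), max(fa, fb)) in self.compatible


def gen_similarity(model: PlantedModel, seed: int | None = None) -> SimilarityMatrix:
    """Block-structured similarity matrix with asymmetric noise.

    Entries are drawn around ``within_mean`` inside a family and
    ``between_mean`` across families, independently for (i, j) and
    (j, i); the container symmetrizes by averaging.  The resulting
    matrix is indefinite for the default parameters.
    """
    seed = model.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    fam = model.families()
    ids = model.protein_ids
    f = np.array([fam[i] for i in ids])
    same = f[:, None] == f[None, :]
    mean = np.where(same, model.within_mean, model.between_mean)
    sd = np.where(same, model.within_sd, model.between_sd)
    S = mean + sd * rng.standard_normal((model.n_proteins, model.n_proteins))
    # asymmetric draw, symmetrized by averaging: keeps the matrix
    # indefinite while the off-diagonal noise variance halves
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, model.self_similarity)
    return SimilarityMatrix(ids=ids, values=S)


def gen_sequences(
    n: int | None = None,
    length_range: tuple[int, int] | None = None,
    seed: int | None = None,
    families: dict[str, int] | None = None,
    model: PlantedModel | None = None,
    mutation_rate: float | None = None,
) -> dict[str, str]:
    """Family-structured protein sequences.

    Each family has a random ancestor; members are copies mutated at a
    fixed per-site rate (substitutions only, over the 20 standard
    residues).  Returns an id -> sequence mapping in id order.
    """
    if model is None:
        model = PlantedModel()
    if families is None:
        families = model.families()
    if n is not None and n != len(families):
        families = {pid: families[pid] for pid in list(families)[:n]}
    length_range = length_range or model.length_range
    rate = model.mutation_rate if mutation_rate is None else mutation_rate
    rng = np.random.default_rng(model.seed + 1 if seed is None else seed)
    aa = np.frombuffer(STANDARD_AA.encode(), dtype=np.uint8)
    fams = sorted(set(families.values()))
    ancestors = {}
    for fm in fams:
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        ancestors[fm] = rng.choice(aa, size=length)
    out = {}
    for pid in families:
        anc = ancestors[families[pid]]
        seq = anc.copy()
        mut = rng.random(len(seq)) < rate
        seq[mut] = rng.choice(aa, size=int(mut.sum()))
        out[pid] = seq.tobytes().decode("ascii")
    return out


def _planted_positives(model: PlantedModel, rng: np.random.Generator) -> PairDataset:
    fam = model.families()
    ids = list(model.protein_ids)
    compat_pool = []
    all_pool = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            p = ProteinPair(ids[i], ids[j])
            all_pool.append(p)
            if model.is_compatible(fam[ids[i]], fam[ids[j]]):
                compat_pool.append(p)
    if not compat_pool:
        raise ValueError("compatibility table admits no interacting family pair")
    n_signal = int(round(model.positive_rate * model.n_positives))
    n_noise = model.n_positives - n_signal
    if n_signal > len(compat_pool):
        raise ValueError(
            f"cannot draw {n_signal} positives from {len(compat_pool)} "
            "compatible pairs"
        )
    chosen = set(
        compat_pool[i]
        for i in rng.choice(len(compat_pool), size=n_signal, replace=False)
    )
    # uniform noise positives from anywhere (emulating label noise)
    remaining = [p for p in all_pool if p not in chosen]
    for i in rng.choice(len(remaining), size=n_noise, replace=False):
        chosen.add(remaining[i])
    pairs = tuple(sorted(chosen))
    return PairDataset(pairs=pairs, labels=(1,) * len(pairs))


def _cluster_assignment(model: PlantedModel) -> ClusterAssignment:
    fam = model.families()
    by_family: dict[int, list[str]] = {}
    for pid in model.protein_ids:
        by_family.setdefault(fam[pid], []).append(pid)
    mapping = {}
    for fm, members in by_family.items():
        for i, pid in enumerate(members):
            mapping[pid] = f"F{fm}C{i // model.cluster_size:03d}"
    return ClusterAssignment(mapping=mapping)


def _evalue_table(
    model: PlantedModel, clusters: ClusterAssignment, rng: np.random.Generator
) -> EvalueTable:
    fam = model.families()
    ids = list(model.protein_ids)
    values: dict[tuple[str, str], float] = {}
    for i, a in enumerate(ids):
        values[(a, a)] = 0.0
        for b in ids[i + 1 :]:
            if fam[a] != fam[b]:
                continue  # no detectable similarity across families
            if clusters[a] == clusters[b]:
                e = 10.0 ** rng.uniform(-60.0, -20.0)
            else:
                e = 10.0 ** rng.uniform(-8.0, -3.0)
            values[(a, b)] = e
    return EvalueTable(values=values)


def gen_benchmark(
    model: PlantedModel | None = None, seed: int | None = None
) -> tuple[PairDataset, ClusterAssignment, EvalueTable, dict[str, int]]:
    """Full synthetic benchmark.

    Draws planted positives from compatible family pairs (a
    ``1 - positive_rate`` fraction is uniform label noise), samples
    ``negative_multiplier`` negatives per positive, collapses redundant
    cluster links, and applies the length filter plus ``ratio`` : 1
    downsampling.  Returns the final pair dataset together with the
    cluster assignment, E-value table, and protein lengths.
    """
    model = model or PlantedModel()
    seed = model.seed if seed is None else seed
    ss = np.random.SeedSequence(seed).generate_state(4)
    rng = np.random.default_rng(int(ss[0]))
    positives = _planted_positives(model, rng)
    clusters = _cluster_assignment(model)
    evalues = _evalue_table(model, clusters, rng)
    sequences = gen_sequences(model=model, seed=int(ss[1]) % 2**31)
    lengths = {pid: len(s) for pid, s in sequences.items()}
    negatives = sample_negatives(
        list(model.protein_ids),
        positives,
        multiplier=model.negative_multiplier,
        seed=int(ss[2]) % 2**31,
    )
    combined = PairDataset(
        pairs=positives.pairs + negatives.pairs,
        labels=positives.labels + negatives.labels,
    )
    filtered = link_cluster_filter(combined, clusters, seed=int(ss[3]) % 2**31)
    final = finalize_ratio(
        filtered,
        lengths,
        min_length=model.min_length,
        ratio=model.ratio,
        seed=int(ss[0]) % 2**31,
    )
    return final, clusters, evalues, lengths
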