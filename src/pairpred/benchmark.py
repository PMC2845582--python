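"""Benchmark construction: negative sampling, redundancy filtering, and
candidate-pair screening.

A benchmark of interacting (+1) and non-interacting (-1) protein pairs
is assembled in stages: negatives are sampled uniformly at random from
non-interacting pairs (five negatives per positive at first); redundant
pairs linking the same two sequence clusters are collapsed; negatives
involving short proteins are removed and the remainder downsampled to a
3:1 negative:positive ratio.

For genome-scale prediction, candidate pairs that resemble any training
pair are excluded: the distance from a candidate pair to a training
pair is the best (minimum over the two member matchings) of the worse
(maximum) E-value within a matching, and candidates whose minimum
distance to the training set does not exceed a threshold (0.01) are
dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

from pairpred.pairs import PairDataset, ProteinPair

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterAssignment:
    """Total mapping protein-id -> cluster-id (e.g., sequence-identity
    clusters from an external clustering run)."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "mapping", {str(k): str(v) for k, v in self.mapping.items()}
        )

    def __getitem__(self, protein_id: str) -> str:
        return self.mapping[protein_id]

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.mapping

    def cluster_pair(self, pair: ProteinPair) -> tuple[str, str]:
        """Unordered cluster-pair key linking the two members."""
        ca, cb = self.mapping[pair.a], self.mapping[pair.b]
        return (ca, cb) if ca <= cb else (cb, ca)


@dataclass(frozen=True)
class EvalueTable:
    """Sparse (query, target) -> E-value map; a missing entry means no
    detectable similarity and reads as +infinity."""

    values: dict[tuple[str, str], float]
    symmetric: bool = True

    def __post_init__(self) -> None:
        clean = {}
        for (q, t), e in self.values.items():
            e = float(e)
            if e < 0:
                raise ValueError(f"negative E-value {e} for ({q}, {t})")
            clean[(str(q), str(t))] = e
        object.__setattr__(self, "values", clean)

    def get(self, query: str, target: str) -> float:
        e = self.values.get((query, target))
        if e is None and self.symmetric:
            e = self.values.get((target, query))
        return np.inf if e is None else e


def count_candidate_pairs(n_proteins: int, include_self: bool = True) -> int:
    """Number of unordered candidate pairs among ``n_proteins``
    structures; with self-pairs this is n(n+1)/2."""
    if n_proteins < 0:
        raise ValueError("n_proteins must be non-negative")
    n = n_proteins
    return comb(n + 1, 2) if include_self else comb(n, 2)


def sample_negatives(
    proteins: list[str],
    positives: PairDataset,
    multiplier: int = 5,
    seed: int = 0,
) -> PairDataset:
    """Uniform sample (without replacement) of non-interacting pairs.

    Draws ``multiplier * #positives`` unordered pairs of distinct
    proteins not present in ``positives``; reproducible by seed.
    """
    ids = sorted(set(str(p) for p in proteins))
    pos_set = {p for p, y in positives if y == 1}
    n_pos = sum(1 for _, y in positives if y == 1)
    want = multiplier * n_pos
    pool = [
        ProteinPair(a, b)
        for a, b in combinations(ids, 2)
        if ProteinPair(a, b) not in pos_set
    ]
    if want > len(pool):
        raise ValueError(
            f"cannot sample {want} negatives from a pool of {len(pool)} "
            "candidate pairs"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=want, replace=False)
    return PairDataset(
        pairs=tuple(pool[i] for i in sorted(chosen)),
        labels=(-1,) * want,
    )


def _positive_neighbor_counts(positives: list[ProteinPair]) -> dict[ProteinPair, int]:
    """For each positive pair, the number of *other* positive pairs
    sharing a protein with it (computed on the pre-filter positive set)."""
    by_protein: dict[str, int] = {}
    for p in positives:
        by_protein[p.a] = by_protein.get(p.a, 0) + 1
        by_protein[p.b] = by_protein.get(p.b, 0) + 1
    out = {}
    for p in positives:
        # pairs sharing either member, not counting the pair itself
        out[p] = by_protein[p.a] + by_protein[p.b] - 2
    return out


def link_cluster_filter(
    pairs: PairDataset, clusters: ClusterAssignment, seed: int = 0
) -> PairDataset:
    """Collapse redundant pairs linking the same two clusters.

    Pairs are grouped by the unordered pair of clusters they link.
    Within a group: if all pairs are negative, one survives (uniformly
    at random, seeded); if the group mixes labels, the negatives are
    dropped; if two or more positives remain, only the positive with
    the fewest positive neighbors (pairs sharing a protein, counted on
    the pre-filter positive set) survives, ties broken at random.
    """
    missing = sorted(
        {pid for p, _ in pairs for pid in (p.a, p.b) if pid not in clusters}
    )
    if missing:
        raise ValueError(f"unclustered proteins: {missing[:10]}")
    rng = np.random.default_rng(seed)
    groups: dict[tuple[str, str], list[int]] = {}
    for i, (p, _) in enumerate(pairs):
        groups.setdefault(clusters.cluster_pair(p), []).append(i)
    all_positives = [p for p, y in pairs if y == 1]
    neighbor_count = _positive_neighbor_counts(all_positives)
    keep: list[int] = []
    for key in sorted(groups):
        idx = groups[key]
        pos = [i for i in idx if pairs.labels[i] == 1]
        if not pos:
            keep.append(idx[int(rng.integers(len(idx)))])
        elif len(pos) == 1:
            keep.append(pos[0])
        else:
            counts = np.array([neighbor_count[pairs.pairs[i]] for i in pos])
            best = np.where(counts == counts.min())[0]
            keep.append(pos[int(rng.choice(best))])
    keep.sort()
    return pairs.subset(keep)


def finalize_ratio(
    pairs: PairDataset,
    lengths: dict[str, int],
    min_length: int = 50,
    ratio: float = 3.0,
    seed: int = 0,
) -> PairDataset:
    """Length-filter negatives and downsample them to ``ratio`` : 1.

    Negative pairs with any member shorter than ``min_length`` residues
    are removed; the remaining negatives are downsampled (uniformly,
    seeded) to ``floor(ratio * #positives)``.  Positives are untouched.
    If too few negatives survive the length filter, all are kept and a
    warning is logged.
    """
    pos_idx = [i for i, y in enumerate(pairs.labels) if y == 1]
    neg_idx = [i for i, y in enumerate(pairs.labels) if y == -1]
    missing = sorted(
        {
            pid
            for i in neg_idx
            for pid in (pairs.pairs[i].a, pairs.pairs[i].b)
            if pid not in lengths
        }
    )
    if missing:
        raise ValueError(f"lengths missing for proteins: {missing[:10]}")
    eligible = [
        i
        for i in neg_idx
        if lengths[pairs.pairs[i].a] >= min_length
        and lengths[pairs.pairs[i].b] >= min_length
    ]
    want = int(ratio * len(pos_idx))
    if len(eligible) < want:
        logger.warning(
            "only %d negatives survive the length filter (need %d for "
            "%g:1); keeping all", len(eligible), want, ratio,
        )
        chosen = eligible
    else:
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(eligible), size=want, replace=False)
        chosen = [eligible[i] for i in pick]
    keep = sorted(pos_idx + list(chosen))
    return pairs.subset(keep)


def pair_distance(
    candidate: ProteinPair, train: ProteinPair, E: EvalueTable
) -> float:
    """E-value distance from a candidate pair to a training pair.

    Members are matched one-to-one in whichever of the two ways is
    closer; within a matching the *larger* of the two E-values governs
    (both members must be similar for the pairs to be redundant):
    ``min(max(E(p1,q1), E(p2,q2)), max(E(p1,q2), E(p2,q1)))``.
    """
    d1 = max(E.get(candidate.a, train.a), E.get(candidate.b, train.b))
    d2 = max(E.get(candidate.a, train.b), E.get(candidate.b, train.a))
    return min(d1, d2)


def filter_candidates(
    candidates: list[ProteinPair],
    train_pairs: list[ProteinPair],
    E: EvalueTable,
    threshold: float = 0.01,
) -> list[ProteinPair]:
    """Retain candidates whose minimum pair distance to every training
    pair exceeds ``threshold``; with an empty training set everything is
    retained (with a warning)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not train_pairs:
        logger.warning("empty training set: retaining all candidates")
        return list(candidates)
    out = []
    for c in candidates:
        dmin = min(pair_distance(c, t, E) for t in train_pairs)
        if dmin > threshold:
            out.append(c)
    return out
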