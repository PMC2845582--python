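"""Cross-validation protocol and evaluation statistics.

The protocol is 5-fold cross-validation repeated three times (3x5cv,
15 splits), stratified by label at the *pair* level.  Hyperparameters
(``C+`` and the ratio ``C+/C-`` for the SVM, ``k`` for nearest
neighbor) are selected per training set by an internal 5-fold
cross-validation maximizing mean area under the precision-recall
curve.

Because the benchmark fixes the negative:positive ratio at ``r`` (3 by
default) while the realistic ratio ``r'`` is far higher, measured
precisions are extrapolated via ``p / (p + (r'/r) (1 - p))`` with
``r' = (v (v-1)/2 - e) / e`` for ``v`` proteins and ``e`` interacting
pairs.

Methods are compared by Wilcoxon signed-rank tests on per-split
AUC-PR; the dominance relation is displayed after transitive
reduction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from pairpred.classifiers import (
    NNModel,
    nn_decision,
    svm_decision,
    svm_train,
)
from pairpred.pairs import PairKernelMatrix

logger = logging.getLogger(__name__)

#: the hyperparameter grids of the full protocol
DEFAULT_C_PLUS_GRID = tuple(10.0**e for e in range(-8, 9))
DEFAULT_RATIO_GRID = (3.0, 10.0, 100.0)
DEFAULT_K_GRID = (1, 2, 3, 5, 10, 15)


@dataclass(frozen=True)
class CVPlan:
    """Fold assignments for repeated stratified cross-validation.

    ``assignments[rep, i]`` is the fold of pair ``i`` in repeat
    ``rep``; within each repeat the folds partition all pairs.
    """

    folds: int
    repeats: int
    seed: int
    assignments: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.assignments, dtype=int)
        if a.shape[0] != self.repeats:
            raise ValueError("assignments must have one row per repeat")
        if a.min(initial=0) < 0 or a.max(initial=0) >= self.folds:
            raise ValueError("fold index out of range")
        a.flags.writeable = False
        object.__setattr__(self, "assignments", a)

    @property
    def n_pairs(self) -> int:
        return self.assignments.shape[1]

    @property
    def n_splits(self) -> int:
        return self.folds * self.repeats

    def iter_splits(self):
        """Yield ``(repeat, fold, train_idx, test_idx)`` for all splits."""
        for rep in range(self.repeats):
            row = self.assignments[rep]
            for fold in range(self.folds):
                test = np.where(row == fold)[0]
                train = np.where(row != fold)[0]
                yield rep, fold, train, test


def make_cv_plan(
    labels, seed: int, folds: int = 5, repeats: int = 3
) -> CVPlan:
    """Build a 3x5cv plan stratified by label.

    Each repeat shuffles independently (streams derived from ``seed``)
    and deals each class round-robin into folds, with the negative
    stream offset so that total fold sizes stay balanced.
    """
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if n < 10:
        raise ValueError(f"need at least 10 pairs, got {n}")
    pos = np.where(y == 1)[0]
    neg = np.where(y == -1)[0]
    if len(pos) < folds or len(neg) < folds:
        raise ValueError(
            f"too few pairs for {folds}-fold stratification: "
            f"{len(pos)} positives, {len(neg)} negatives"
        )
    streams = np.random.SeedSequence(seed).spawn(repeats)
    assignments = np.empty((repeats, n), dtype=int)
    for rep in range(repeats):
        rng = np.random.default_rng(streams[rep])
        perm_pos = rng.permutation(pos)
        perm_neg = rng.permutation(neg)
        for i, ix in enumerate(perm_pos):
            assignments[rep, ix] = i % folds
        for i, ix in enumerate(perm_neg):
            assignments[rep, ix] = (len(pos) + i) % folds
    return CVPlan(folds=folds, repeats=repeats, seed=seed, assignments=assignments)


def pr_curve(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precision-recall curve with tied scores grouped.

    Returns ``(precision, recall, thresholds)`` over the distinct score
    thresholds in descending order: at threshold t, every example with
    score >= t is predicted positive.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores/labels shape mismatch")
    n_pos = int((y == 1).sum())
    n_neg = int((y == -1).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for a PR curve")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    tp = np.cumsum(y[order] == 1)
    pred = np.arange(1, len(y) + 1)
    # last index of each tied group
    distinct = np.where(np.diff(s_sorted) != 0)[0]
    last = np.append(distinct, len(y) - 1)
    if len(last) == 1:
        logger.warning("constant scores: single-point PR curve")
    precision = tp[last] / pred[last]
    recall = tp[last] / n_pos
    thresholds = s_sorted[last]
    return precision, recall, thresholds


def auc_pr(scores, labels=None) -> float:
    """Area under the PR curve, computed as average precision: the mean
    over positives of the precision at the threshold where each
    positive is first retrieved (no interpolation).

    Accepts either ``(scores, labels)`` or a precomputed
    ``(precision, recall, thresholds)`` tuple.
    """
    if labels is None:
        precision, recall, _ = scores
    else:
        precision, recall, _ = pr_curve(scores, labels)
    recall = np.asarray(recall, dtype=float)
    precision = np.asarray(precision, dtype=float)
    drecall = np.diff(np.concatenate(([0.0], recall)))
    return float(np.sum(drecall * precision))


@dataclass(frozen=True)
class ExtrapolationContext:
    """Class-ratio context for precision extrapolation.

    ``r`` is the benchmark negative:positive ratio, ``v`` the number of
    proteins in the source interaction set and ``e`` its number of
    interacting pairs; the realistic ratio is
    ``r' = (v (v-1)/2 - e) / e``.
    """

    r: float
    v: int
    e: int

    def __post_init__(self) -> None:
        if self.e <= 0:
            raise ValueError("e (number of interacting pairs) must be positive")
        if self.r <= 0:
            raise ValueError("r must be positive")
        if self.r_prime < 0:
            raise ValueError("derived ratio r' is negative: e exceeds v(v-1)/2")

    @property
    def r_prime(self) -> float:
        return (self.v * (self.v - 1) / 2.0 - self.e) / self.e


def extrapolate_precision(p, ctx: ExtrapolationContext):
    """Rescale measured precision from ratio r to the realistic r'.

    ``p_est = p / (p + (r'/r) (1 - p))``; fixed points at 0 and 1,
    identity when r' = r, strictly increasing in p.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("precision must lie in [0, 1]")
    factor = ctx.r_prime / ctx.r
    with np.errstate(invalid="ignore"):
        out = p / (p + factor * (1.0 - p))
    out = np.where((p == 0) & (factor == 0), 0.0, out)
    return float(out) if out.ndim == 0 else out


@dataclass
class EvalResult:
    """Per-split evaluation of one method: 15 AUC-PR values plus the PR
    curves they were computed from."""

    method: str
    aucs: list[float] = field(default_factory=list)
    curves: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    chosen_params: list[dict] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    def averaged_curve(self, grid_points: int = 100):
        """Vertically average per-split precision over a fixed recall
        grid (for plotting only; AUC is computed per split)."""
        grid = np.linspace(0.0, 1.0, grid_points)
        stack = []
        for precision, recall in self.curves:
            idx = np.searchsorted(recall, grid, side="left")
            idx = np.clip(idx, 0, len(precision) - 1)
            stack.append(precision[idx])
        return grid, np.mean(stack, axis=0)


def _inner_auc(
    V: np.ndarray, y: np.ndarray, train: np.ndarray, test: np.ndarray,
    classifier: str, params: dict,
) -> float:
    Ktr = V[np.ix_(train, train)]
    Kte = V[np.ix_(test, train)]
    ytr, yte = y[train], y[test]
    if classifier == "svm":
        model = svm_train(
            Ktr, ytr, params["c_plus"], params["c_plus"] / params["ratio"],
            check_psd=False,
        )
        scores = Kte @ model.dual_coefficients + model.bias
    elif classifier == "nn":
        pkm = PairKernelMatrix(
            rows=params["_pairs_train"], cols=params["_pairs_train"], values=Ktr,
        )
        model = NNModel(train_kernel=pkm, labels=tuple(ytr), k=params["k"])
        scores = nn_decision(model, Kte, np.diag(V)[test])
    else:
        raise ValueError(f"unknown classifier {classifier!r}")
    return auc_pr(scores, yte)


def grid_search(
    K_train: PairKernelMatrix | np.ndarray,
    labels,
    classifier: str = "svm",
    c_plus_grid=DEFAULT_C_PLUS_GRID,
    ratio_grid=DEFAULT_RATIO_GRID,
    k_grid=DEFAULT_K_GRID,
    inner_folds: int = 5,
    seed: int = 0,
) -> dict:
    """Select hyperparameters by internal cross-validation.

    Returns ``{"c_plus": ..., "ratio": ...}`` for the SVM or
    ``{"k": ...}`` for NN, maximizing mean inner-CV AUC-PR; ties are
    broken toward smaller ``c_plus`` (then smaller ratio) or smaller
    ``k``.  NN values of k infeasible on some inner training fold are
    skipped with a warning.
    """
    is_pkm = isinstance(K_train, PairKernelMatrix)
    V = K_train.values if is_pkm else np.asarray(K_train, dtype=float)
    pairs = K_train.rows if is_pkm else tuple(range(len(labels)))
    y = np.asarray(labels, dtype=int)
    if classifier == "svm":
        grid = [
            {"c_plus": c, "ratio": r} for c in sorted(c_plus_grid) for r in sorted(ratio_grid)
        ]
    elif classifier == "nn":
        grid = [{"k": k} for k in sorted(k_grid)]
    else:
        raise ValueError(f"unknown classifier {classifier!r}")
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if len(grid) == 1:
        return dict(grid[0])
    plan = make_cv_plan(y, seed=seed, folds=inner_folds, repeats=1)
    splits = list(plan.iter_splits())
    best_params, best_score = None, -np.inf
    for params in grid:
        aucs = []
        feasible = True
        for _, _, tr, te in splits:
            if classifier == "nn":
                ytr = y[tr]
                k_max = min(int((ytr == 1).sum()), int((ytr == -1).sum()))
                if params["k"] > k_max:
                    logger.warning(
                        "skipping infeasible k = %d (smaller class has %d "
                        "examples in an inner fold)", params["k"], k_max,
                    )
                    feasible = False
                    break
                params = {**params, "_pairs_train": tuple(pairs[i] for i in tr)}
            aucs.append(_inner_auc(V, y, tr, te, classifier, params))
        if not feasible:
            continue
        score = float(np.mean(aucs))
        if score > best_score + 1e-12:  # strict improvement; ties keep smaller
            best_score, best_params = score, params
    if best_params is None:
        raise ValueError("no feasible hyperparameter setting in the grid")
    return {k: v for k, v in best_params.items() if not k.startswith("_")}


def cross_validate(
    Kpair: PairKernelMatrix,
    labels,
    classifier: str = "svm",
    plan: CVPlan | None = None,
    seed: int = 0,
    method_label: str | None = None,
    do_grid_search: bool = True,
    c_plus_grid=DEFAULT_C_PLUS_GRID,
    ratio_grid=DEFAULT_RATIO_GRID,
    k_grid=DEFAULT_K_GRID,
    fixed_params: dict | None = None,
    extrapolation: ExtrapolationContext | None = None,
) -> EvalResult:
    """Run the full repeated-CV protocol for one method.

    ``Kpair`` is the square pair-kernel Gram matrix over all labeled
    pairs.  For each of the 15 splits, hyperparameters are selected on
    the training folds (or taken from ``fixed_params``), the classifier
    is trained, and test-fold AUC-PR recorded.  If ``extrapolation`` is
    given, the stored PR curves carry extrapolated precisions (AUC is
    always computed on the unextrapolated curve).
    """
    if not Kpair.is_square:
        raise ValueError("cross_validate needs a square pair kernel")
    y = np.asarray(labels, dtype=int)
    V = Kpair.values
    if plan is None:
        plan = make_cv_plan(y, seed=seed)
    if method_label is None:
        method_label = f"{classifier}+{Kpair.construction}"
    result = EvalResult(method=method_label)
    diag = np.diag(V)
    for rep, fold, train, test in plan.iter_splits():
        if fixed_params is not None:
            params = dict(fixed_params)
        elif do_grid_search:
            params = grid_search(
                V[np.ix_(train, train)], y[train], classifier=classifier,
                c_plus_grid=c_plus_grid, ratio_grid=ratio_grid, k_grid=k_grid,
                seed=seed * 1000 + rep * plan.folds + fold,
            )
        else:
            params = {"c_plus": 1.0, "ratio": 3.0} if classifier == "svm" else {"k": 3}
        Ktr = V[np.ix_(train, train)]
        Kte = V[np.ix_(test, train)]
        if classifier == "svm":
            model = svm_train(
                Ktr, y[train], params["c_plus"], params["c_plus"] / params["ratio"],
                check_psd=False,
            )
            scores = Kte @ model.dual_coefficients + model.bias
        else:
            pkm = PairKernelMatrix(
                rows=tuple(Kpair.rows[i] for i in train),
                cols=tuple(Kpair.rows[i] for i in train),
                values=Ktr,
                construction=Kpair.construction,
                base_shifted=Kpair.base_shifted,
            )
            model = NNModel(train_kernel=pkm, labels=tuple(y[train]), k=params["k"])
            scores = nn_decision(model, Kte, diag[test])
        precision, recall, thr = pr_curve(scores, y[test])
        result.aucs.append(auc_pr((precision, recall, thr)))
        if extrapolation is not None:
            precision = extrapolate_precision(precision, extrapolation)
        result.curves.append((precision, recall))
        result.chosen_params.append(params)
    return result


def _wilcoxon_exact(diff: np.ndarray) -> tuple[float, float, float]:
    """Exact Wilcoxon signed-rank test.

    Zero differences are dropped; tied absolute differences receive
    midranks.  Returns ``(W_plus, p_greater, p_two_sided)`` where the
    exact null distribution of the positive-rank sum is computed by
    dynamic programming over doubled (integer) ranks and the two-sided
    p doubles the smaller one-sided tail.
    """
    d = np.asarray(diff, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0, 1.0
    absd = np.abs(d)
    order = np.argsort(absd)
    ranks = np.empty(n)
    sorted_abs = absd[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    r2 = np.rint(2.0 * ranks).astype(int)  # doubled midranks are integers
    w_plus2 = int(np.rint(2.0 * float(ranks[d > 0].sum())))
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: total + 1 - r].copy()
    counts /= counts.sum()
    p_ge = float(counts[w_plus2:].sum())
    p_le = float(counts[: w_plus2 + 1].sum())
    p_two = min(1.0, 2.0 * min(p_ge, p_le))
    return w_plus2 / 2.0, p_ge, p_two


def compare_methods(
    auc_table: dict[str, np.ndarray], alpha: float = 0.05
) -> nx.DiGraph:
    """Pairwise Wilcoxon dominance graph over methods.

    An edge A -> B means A's per-split AUC-PR values exceed B's with
    signed-rank two-sided p < ``alpha`` (and in A's favor).  All
    methods must be evaluated on the identical split set.
    """
    methods = list(auc_table)
    lengths = {m: len(np.asarray(auc_table[m])) for m in methods}
    if len(set(lengths.values())) > 1:
        raise ValueError(f"mismatched split counts: {lengths}")
    G = nx.DiGraph()
    G.add_nodes_from(methods)
    for i, a in enumerate(methods):
        for b in methods[i + 1 :]:
            d = np.asarray(auc_table[a], dtype=float) - np.asarray(
                auc_table[b], dtype=float
            )
            w_plus, p_greater, p_two = _wilcoxon_exact(d)
            if p_two < alpha:
                nz = d[d != 0]
                total_rank = len(nz) * (len(nz) + 1) / 2.0
                if w_plus > total_rank / 2.0:
                    G.add_edge(a, b, p=p_two, p_one_sided=p_greater)
                else:
                    G.add_edge(b, a, p=p_two, p_one_sided=1.0 - p_greater)
    return G


def transitive_reduction(G: nx.DiGraph) -> nx.DiGraph:
    """Minimal edge set with the same reachability as ``G``.

    If the dominance relation contains a cycle (possible in principle
    with paired tests), the cycle is reported and the graph returned
    unreduced.
    """
    if not nx.is_directed_acyclic_graph(G):
        cycle = nx.find_cycle(G)
        logger.warning("dominance graph has a cycle %s; returning unreduced", cycle)
        return G.copy()
    R = nx.transitive_reduction(G)
    # transitive_reduction drops node/edge data; restore edge attributes
    for u, v in R.edges:
        R.edges[u, v].update(G.edges[u, v])
    return R
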