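"""Classifiers over precomputed pair-kernel matrices.

Two kernel methods are provided:

* a kernelized k-nearest-neighbor classifier whose real-valued
  discriminant is the difference between the summed feature-space
  distances to the k nearest negative and the k nearest positive
  training examples (positive score = "interacting"), and

* a soft-margin SVM with asymmetric per-class regularization
  (``C+`` for interacting pairs, ``C-`` for non-interacting ones),
  appropriate when negatives outnumber positives.  The quadratic
  program is solved by scikit-learn's SMO implementation on the
  precomputed Gram matrix; this module stores the dual solution and
  evaluates the discriminant ``f(x) = sum_i alpha_i y_i K(x, x_i) + b``
  directly.

Platt scaling converts SVM discriminants into probabilities by fitting
a two-parameter sigmoid on held-out scores by regularized maximum
likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from pairpred.matrices import MatrixValidationError, PSD_TOL
from pairpred.pairs import PairKernelMatrix, ProteinPair

logger = logging.getLogger(__name__)

#: clamp for tiny negative radicands in feature-space distances
DIST_CLAMP = 1e-9


def kernel_distance(K: np.ndarray | PairKernelMatrix, i: int, j: int) -> float:
    """Feature-space Euclidean distance between examples i and j.

    ``d = sqrt(K(i,i) - 2 K(i,j) + K(j,j))``.  Radicands in
    ``[-1e-9, 0)`` (floating-point noise on a valid kernel) are clamped
    to 0; anything more negative indicates an invalid kernel.
    """
    V = K.values if isinstance(K, PairKernelMatrix) else np.asarray(K)
    r = V[i, i] - 2.0 * V[i, j] + V[j, j]
    if r < -DIST_CLAMP:
        raise MatrixValidationError(
            f"negative squared distance {r:.3g} between {i} and {j}: "
            "kernel is not PSD"
        )
    return float(np.sqrt(max(r, 0.0)))


def _distances_from_row(
    row: np.ndarray, self_val: float, train_diag: np.ndarray
) -> np.ndarray:
    r = self_val - 2.0 * row + train_diag
    if np.min(r, initial=0.0) < -DIST_CLAMP:
        raise MatrixValidationError(
            f"negative squared distance {np.min(r):.3g}: kernel is not PSD"
        )
    return np.sqrt(np.clip(r, 0.0, None))


@dataclass(frozen=True)
class NNModel:
    """k-nearest-neighbor model: the stored training Gram matrix, its
    labels, and the neighbor count k (k <= min(#pos, #neg))."""

    train_kernel: PairKernelMatrix
    labels: tuple[int, ...]
    k: int

    def __post_init__(self) -> None:
        labels = tuple(int(y) for y in self.labels)
        object.__setattr__(self, "labels", labels)
        if not self.train_kernel.is_square:
            raise ValueError("training kernel must be square")
        if len(labels) != len(self.train_kernel.rows):
            raise ValueError("labels length != kernel size")
        n_pos = sum(1 for y in labels if y == 1)
        n_neg = sum(1 for y in labels if y == -1)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k > min(n_pos, n_neg):
            raise ValueError(
                f"k = {self.k} exceeds the smaller class "
                f"({n_pos} positives, {n_neg} negatives)"
            )


def nn_discriminant(
    model: NNModel, test_row: np.ndarray, test_self: float
) -> float:
    """NN discriminant for one test example.

    ``score = sum_{x in N_k^-} d(x~, x) - sum_{x in N_k^+} d(x~, x)``
    where ``N_k^+/-`` are the k nearest positive/negative training
    examples in feature space.  Positive score means "interacting"
    (the nearest negatives are far, the nearest positives near); the
    predicted label is the sign.  Ties at equal distance are broken by
    canonical pair id, so the result is order-independent.
    """
    row = np.asarray(test_row, dtype=float)
    n = len(model.labels)
    if row.shape != (n,):
        raise ValueError(f"test row has shape {row.shape}, expected ({n},)")
    diag = np.diag(model.train_kernel.values)
    d = _distances_from_row(row, float(test_self), diag)
    y = np.array(model.labels)
    tie_key = np.array([str(p) for p in model.train_kernel.rows])
    score = 0.0
    for sign, cls in ((+1.0, -1), (-1.0, +1)):
        idx = np.where(y == cls)[0]
        order = idx[np.lexsort((tie_key[idx], d[idx]))][: model.k]
        score += sign * float(d[order].sum())
    return score


def nn_decision(model: NNModel, K_test: PairKernelMatrix | np.ndarray,
                test_diag: np.ndarray) -> np.ndarray:
    """Vector of NN discriminants for a block of test rows."""
    V = K_test.values if isinstance(K_test, PairKernelMatrix) else np.asarray(K_test)
    return np.array(
        [nn_discriminant(model, V[i], float(test_diag[i])) for i in range(V.shape[0])]
    )


@dataclass(frozen=True)
class SVMModel:
    """Dual solution of the asymmetric-cost soft-margin SVM.

    ``dual_coefficients[i] = alpha_i * y_i`` for every training example
    (zero off the support);  ``0 <= alpha_i <= C+`` for positives and
    ``<= C-`` for negatives; ``sum_i alpha_i y_i = 0``.
    """

    dual_coefficients: np.ndarray
    bias: float
    c_plus: float
    c_minus: float
    support_ids: tuple[ProteinPair, ...] = field(default=())

    def __post_init__(self) -> None:
        ay = np.asarray(self.dual_coefficients, dtype=float)
        ay.flags.writeable = False
        object.__setattr__(self, "dual_coefficients", ay)
        if abs(ay.sum()) > 1e-6 * max(1.0, np.abs(ay).max(initial=0.0)):
            raise ValueError(
                f"dual constraint violated: sum alpha_i y_i = {ay.sum():.3g}"
            )


def svm_train(
    K: PairKernelMatrix | np.ndarray,
    labels,
    c_plus: float,
    c_minus: float,
    tol: float = 1e-6,
    max_iter: int = 10_000_000,
    check_psd: bool = True,
) -> SVMModel:
    """Train the asymmetric-cost SVM on a precomputed kernel.

    The per-class box constraints are ``alpha_i <= c_plus`` for
    ``y_i = +1`` and ``alpha_i <= c_minus`` for ``y_i = -1``.
    Deterministic for fixed inputs and solver settings.
    """
    if c_plus <= 0 or c_minus <= 0:
        raise ValueError("c_plus and c_minus must be positive")
    is_pkm = isinstance(K, PairKernelMatrix)
    V = K.values if is_pkm else np.asarray(K, dtype=float)
    y = np.asarray(labels, dtype=int)
    if V.shape != (len(y), len(y)):
        raise ValueError("kernel/labels size mismatch")
    classes = set(y.tolist())
    if classes != {-1, 1}:
        raise ValueError(f"need both classes -1 and +1, got {sorted(classes)}")
    if check_psd:
        w = np.linalg.eigvalsh(V)
        if w[0] < -PSD_TOL * max(w[-1], 1.0):
            raise MatrixValidationError(
                f"kernel not PSD (min eigenvalue {w[0]:.3g}); "
                "apply spectral_correct to the base similarity first"
            )
    # SVC box constraint is C * class_weight[y_i]; with C=1 the weights
    # are exactly the per-class costs
    clf = SVC(
        kernel="precomputed",
        C=1.0,
        class_weight={1: c_plus, -1: c_minus},
        tol=tol,
        max_iter=max_iter,
        shrinking=True,
    )
    clf.fit(V, y)
    if clf.fit_status_ != 0:
        logger.warning("SVM solver hit the iteration cap (%d)", max_iter)
    ay = np.zeros(len(y))
    ay[clf.support_] = clf.dual_coef_[0]
    support_ids = (
        tuple(K.rows[i] for i in clf.support_) if is_pkm else ()
    )
    return SVMModel(
        dual_coefficients=ay,
        bias=float(clf.intercept_[0]),
        c_plus=float(c_plus),
        c_minus=float(c_minus),
        support_ids=support_ids,
    )


def svm_decision(
    model: SVMModel, K_test_rows: PairKernelMatrix | np.ndarray
) -> np.ndarray:
    """SVM discriminants ``f(x) = sum_i alpha_i y_i K(x, x_i) + b`` for a
    block of test rows (one row per test example, columns = training
    examples)."""
    V = (
        K_test_rows.values
        if isinstance(K_test_rows, PairKernelMatrix)
        else np.atleast_2d(np.asarray(K_test_rows, dtype=float))
    )
    n = model.dual_coefficients.shape[0]
    if V.shape[1] != n:
        raise ValueError(f"test rows have {V.shape[1]} columns, expected {n}")
    return V @ model.dual_coefficients + model.bias


@dataclass(frozen=True)
class PlattCalibration:
    """Sigmoid ``P(y=+1 | f) = 1 / (1 + exp(slope * f + intercept))``.

    Fitted slope is negative for a classifier whose scores increase
    with the probability of interaction, so the mapping is increasing
    in the score.
    """

    slope: float
    intercept: float


def platt_fit(scores, labels, max_iter: int = 100) -> PlattCalibration:
    """Fit Platt calibration by regularized maximum likelihood.

    Uses the standard prior-smoothed targets ``t+ = (N+ + 1)/(N+ + 2)``
    and ``t- = 1/(N- + 2)``, which keep the parameters finite even when
    the classes are separable, and a Newton iteration with backtracking
    on the cross-entropy objective.
    """
    f = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if set(y.tolist()) != {-1, 1}:
        raise ValueError("calibration data must contain both classes")
    n_pos = int((y == 1).sum())
    n_neg = int((y == -1).sum())
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def objective(a: float, b: float) -> float:
        z = a * f + b
        # -sum [t * log p + (1-t) log(1-p)], p = sigmoid(-z); stable form
        return float(np.sum(np.where(z >= 0, t * z, (t - 1.0) * z)
                            + np.log1p(np.exp(-np.abs(z)))))

    a, b = 0.0, float(np.log((n_neg + 1.0) / (n_pos + 1.0)))
    obj = objective(a, b)
    sigma = 1e-12  # Hessian regularizer
    for _ in range(max_iter):
        z = a * f + b
        p = 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))  # P(y=+1)
        d1 = t - p
        g_a = float(np.dot(f, d1))
        g_b = float(d1.sum())
        if max(abs(g_a), abs(g_b)) < 1e-10:
            break
        w = p * (1.0 - p)
        h_aa = float(np.dot(f * f, w)) + sigma
        h_bb = float(w.sum()) + sigma
        h_ab = float(np.dot(f, w))
        det = h_aa * h_bb - h_ab * h_ab
        da = -(h_bb * g_a - h_ab * g_b) / det
        db = -(h_aa * g_b - h_ab * g_a) / det
        step = 1.0
        while step >= 1e-10:
            new_obj = objective(a + step * da, b + step * db)
            if new_obj < obj + 1e-4 * step * (g_a * da + g_b * db):
                a, b = a + step * da, b + step * db
                obj = new_obj
                break
            step /= 2.0
        else:
            break
    return PlattCalibration(slope=a, intercept=b)


def platt_apply(cal: PlattCalibration, score) -> np.ndarray | float:
    """Map scores to probabilities; output is strictly inside (0, 1)."""
    z = np.clip(cal.slope * np.asarray(score, dtype=float) + cal.intercept, -500, 500)
    p = 1.0 / (1.0 + np.exp(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0 - np.finfo(float).epsneg)
    return float(p) if p.ndim == 0 else p
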