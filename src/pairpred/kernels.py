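"""Base kernels on proteins: spectral correction of similarity matrices
and the (k, m)-mismatch string kernel on sequences.

Raw structural-alignment scores are symmetric but usually indefinite
(an all-vs-all score matrix has negative eigenvalues), so they cannot be
used as a kernel directly.  ``spectral_correct`` rebuilds the matrix from
its eigendecomposition after mapping each eigenvalue lambda through
``psi(lambda) = 1 + lambda`` for positive lambda and 0 otherwise, which
both removes the negative spectrum and adds a ridge on the retained
eigenspace.  ``unit_normalize`` then projects onto the unit sphere,
``K'(x, y) = K(x, y) / sqrt(K(x, x) K(y, y))``.

The mismatch kernel maps a sequence to the vector of occurrence counts of
every k-mer, where a k-mer occurrence also counts toward all k-mers
within Hamming distance m of it.  The kernel is the inner product of
these feature vectors.  The implementation never materializes the
``A**k``-dimensional feature space: it sums, over every pair of observed
k-mers (alpha, alpha'), the size of the intersection of their mismatch
neighborhoods, which depends only on the Hamming distance between alpha
and alpha' and is computed in closed form.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from math import comb, factorial

import numpy as np

from pairpred.matrices import KernelMatrix, MatrixValidationError, SimilarityMatrix

logger = logging.getLogger(__name__)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: relative threshold below which an eigenvalue counts as zero
EIG_POS_TOL = 1e-10


def spectral_correct(S: SimilarityMatrix, psi: str = "shift") -> KernelMatrix:
    """Convert an indefinite similarity matrix into a PSD kernel.

    Eigendecompose ``S = U diag(lambda) U.T`` and rebuild with
    ``psi(lambda)`` in place of each eigenvalue.

    Parameters
    ----------
    S
        Symmetric similarity matrix (symmetrized on construction).
    psi
        ``"shift"`` (default): ``psi(lambda) = 1 + lambda`` for
        ``lambda > 0``, else 0.  ``"square"``: ``psi(lambda) =
        lambda**2`` (an alternative correction that also discards no
        sign information; kept as a config option).

    Returns
    -------
    KernelMatrix
        PSD kernel with ``corrected=True``.
    """
    w, U = np.linalg.eigh(S.values)
    scale = np.max(np.abs(w), initial=0.0)
    pos = w > EIG_POS_TOL * max(scale, 1.0)
    if psi == "shift":
        psi_w = np.where(pos, 1.0 + w, 0.0)
    elif psi == "square":
        psi_w = w**2
    else:
        raise ValueError(f"unknown psi variant: {psi!r}")
    K = (U * psi_w) @ U.T
    return KernelMatrix(ids=S.ids, values=K, corrected=True)


def unit_normalize(K: KernelMatrix) -> KernelMatrix:
    """Project a kernel onto the unit sphere.

    ``K'(x, y) = K(x, y) / sqrt(K(x, x) K(y, y))``; the result has unit
    diagonal and entries in [-1, 1].

    Raises
    ------
    MatrixValidationError
        If any diagonal entry is zero or negative (the corresponding
        protein has no feature-space representation and must be filtered
        by the caller first); the offending ids are named.
    """
    d = np.diag(K.values)
    bad = np.where(d <= 0)[0]
    if bad.size:
        names = [K.ids[i] for i in bad[:10]]
        raise MatrixValidationError(
            f"cannot normalize: non-positive diagonal for ids {names}"
        )
    inv = 1.0 / np.sqrt(d)
    Kn = K.values * np.outer(inv, inv)
    np.fill_diagonal(Kn, 1.0)
    return KernelMatrix(
        ids=K.ids, values=Kn, corrected=K.corrected, normalized=True
    )


@dataclass(frozen=True)
class MismatchParams:
    """Parameters of the (k, m)-mismatch kernel.

    ``k`` is the k-mer length, ``m`` the maximum number of mismatched
    positions, ``alphabet`` the residue symbol set (defaults to the 20
    standard amino acids).  ``nonstandard`` controls what to do with a
    k-mer window containing a symbol outside the alphabet: ``"skip"``
    (default) drops the window, ``"error"`` raises.
    """

    k: int = 6
    m: int = 1
    alphabet: str = STANDARD_AA
    nonstandard: str = "skip"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if not 0 <= self.m < self.k:
            raise ValueError("m must satisfy 0 <= m < k")
        if not self.alphabet or len(set(self.alphabet)) != len(self.alphabet):
            raise ValueError("alphabet must be non-empty with unique symbols")
        if self.nonstandard not in ("skip", "error"):
            raise ValueError("nonstandard policy must be 'skip' or 'error'")


def kmer_neighborhood(kmer: str, params: MismatchParams) -> set[str]:
    """All k-mers within Hamming distance ``m`` of ``kmer``.

    For ``m = 1`` over an alphabet of size A the neighborhood has size
    ``1 + k (A - 1)``.
    """
    if len(kmer) != params.k:
        raise ValueError(f"k-mer length {len(kmer)} != k = {params.k}")
    outside = set(kmer) - set(params.alphabet)
    if outside:
        raise ValueError(f"symbols outside alphabet: {sorted(outside)}")
    out = {kmer}
    frontier = {kmer}
    for _ in range(params.m):
        nxt = set()
        for w in frontier:
            for i in range(params.k):
                for a in params.alphabet:
                    if a != w[i]:
                        nxt.add(w[:i] + a + w[i + 1 :])
        frontier = nxt - out
        out |= nxt
    return out


@lru_cache(maxsize=None)
def _neighborhood_overlap(d: int, k: int, m: int, A: int) -> int:
    """Size of ``N(alpha) ∩ N(alpha')`` for k-mers at Hamming distance d.

    A k-mer beta in the intersection is described by: at ``j`` of the
    ``k - d`` agreement positions it differs from both alpha and alpha'
    (A - 1 choices each); at the ``d`` disagreement positions, ``a``
    match alpha, ``b`` match alpha', and ``c = d - a - b`` differ from
    both (A - 2 choices each).  Then ``dist(beta, alpha) = b + c + j``
    and ``dist(beta, alpha') = a + c + j``; both must be <= m.
    """
    total = 0
    for j in range(min(m, k - d) + 1):
        agree = comb(k - d, j) * (A - 1) ** j
        for a in range(d + 1):
            for b in range(d - a + 1):
                c = d - a - b
                if b + c + j <= m and a + c + j <= m:
                    ways = factorial(d) // (
                        factorial(a) * factorial(b) * factorial(c)
                    )
                    total += agree * ways * max(A - 2, 0) ** c if c else agree * ways
    return total


def _encode_kmers(
    seq: str, params: MismatchParams, seq_id: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Distinct k-mers of ``seq`` as a (n_distinct, k) uint8 code array
    plus occurrence counts.  Windows containing nonstandard symbols are
    skipped or rejected per policy."""
    k = params.k
    lut = np.full(256, -1, dtype=np.int16)
    for i, a in enumerate(params.alphabet):
        lut[ord(a)] = i
    codes = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if np.any(codes < 0) and params.nonstandard == "error":
        bad = sorted({seq[i] for i in np.where(codes < 0)[0]})
        raise ValueError(
            f"nonstandard symbols {bad} in sequence"
            + (f" {seq_id!r}" if seq_id else "")
        )
    n_win = len(seq) - k + 1
    if n_win <= 0:
        return np.empty((0, k), dtype=np.uint8), np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = windows.min(axis=1) >= 0
    windows = windows[valid].astype(np.uint8)
    if windows.shape[0] == 0:
        return np.empty((0, k), dtype=np.uint8), np.empty(0, dtype=np.int64)
    uniq, counts = np.unique(windows, axis=0, return_counts=True)
    return uniq, counts


def mismatch_kernel(
    sequences: list[str],
    params: MismatchParams | None = None,
    ids: list[str] | None = None,
) -> KernelMatrix:
    """Mismatch kernel Gram matrix over a list of sequences.

    ``K(x, y) = sum_beta Phi_x(beta) Phi_y(beta)`` where ``Phi_x(beta)``
    counts k-mers of x whose mismatch neighborhood contains beta.
    Computed as a weighted sum of neighborhood-overlap sizes over all
    pairs of observed k-mers, so memory is linear in sequence length.

    Raises
    ------
    ValueError
        If the input list is empty or any sequence is shorter than k
        (offending ids listed).
    """
    if params is None:
        params = MismatchParams()
    if not sequences:
        raise ValueError("empty sequence list")
    if ids is None:
        ids = [f"seq{i}" for i in range(len(sequences))]
    if len(ids) != len(sequences):
        raise ValueError("ids/sequences length mismatch")
    short = [i for i, s in zip(ids, sequences) if len(s) < params.k]
    if short:
        raise ValueError(
            f"sequences shorter than k = {params.k}: {short}"
        )
    A = len(params.alphabet)
    # overlap weight by Hamming distance; zero beyond 2m
    weights = np.array(
        [_neighborhood_overlap(d, params.k, params.m, A) for d in range(params.k + 1)],
        dtype=float,
    )
    enc = [_encode_kmers(s, params, i) for s, i in zip(sequences, ids)]
    n = len(sequences)
    K = np.zeros((n, n))
    for i in range(n):
        Xi, ci = enc[i]
        for j in range(i, n):
            Xj, cj = enc[j]
            if Xi.shape[0] == 0 or Xj.shape[0] == 0:
                continue
            dist = (Xi[:, None, :] != Xj[None, :, :]).sum(axis=2)
            K[i, j] = K[j, i] = ci @ weights[dist] @ cj
    # PSD by construction (inner products of explicit feature vectors);
    # skip the eigenvalue check, which is O(n^3)
    return KernelMatrix(ids=tuple(ids), values=K, _validate=False)
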