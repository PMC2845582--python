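"""Kernels on unordered pairs of proteins.

Two constructions lift a base kernel ``K`` on proteins to a kernel on
protein pairs:

* **TPPK** (tensor product pairwise kernel) --
  ``K_TPPK((p1,p2),(q1,q2)) = K(p1,q1) K(p2,q2) + K(p1,q2) K(p2,q1)``.
  Two pairs are similar when their members can be matched one-to-one
  with high base similarity.  Because a product of two strongly
  *negative* base values is positive, the base kernel is shifted by +1
  first so that its (normalized) entries lie in [0, 2].

* **MLPK** (metric learning pairwise kernel) --
  ``K_MLPK((p1,p2),(q1,q2)) = (K(p1,q1) - K(p1,q2) - K(p2,q1) + K(p2,q2))**2``.
  A pair is represented by the difference of its members in feature
  space, squared to be order-invariant.  Adding a constant to every
  base-kernel entry cancels in the four-term difference, so the +1
  shift applied for consistency with TPPK has no numeric effect here.

Both are PSD whenever the base kernel is PSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pairpred.matrices import KernelMatrix, MatrixValidationError

#: row-block size for lazily built pair-kernel matrices
_BLOCK = 512


@dataclass(frozen=True, order=True)
class ProteinPair:
    """Unordered pair of protein ids, stored in canonical (lexicographic)
    order so pair equality and hashing are order-insensitive."""

    a: str
    b: str

    def __post_init__(self) -> None:
        a, b = str(self.a), str(self.b)
        if b < a:
            a, b = b, a
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def is_self(self) -> bool:
        return self.a == self.b

    def __str__(self) -> str:
        return f"{self.a}|{self.b}"


@dataclass(frozen=True)
class PairDataset:
    """Labeled list of protein pairs; labels are +1 (interacting) or -1.

    Pairs are canonicalized on construction; duplicates (after
    canonicalization) and self-pairs are rejected unless explicitly
    allowed.
    """

    pairs: tuple[ProteinPair, ...]
    labels: tuple[int, ...]
    allow_self: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        pairs = tuple(
            p if isinstance(p, ProteinPair) else ProteinPair(*p) for p in self.pairs
        )
        labels = tuple(int(y) for y in self.labels)
        if len(pairs) != len(labels):
            raise ValueError("pairs/labels length mismatch")
        if any(y not in (-1, 1) for y in labels):
            bad = sorted({y for y in labels if y not in (-1, 1)})
            raise ValueError(f"labels must be +1/-1, got {bad}")
        if not self.allow_self:
            selfs = [str(p) for p in pairs if p.is_self]
            if selfs:
                raise ValueError(f"self-pairs not allowed: {selfs[:5]}")
        seen: dict[ProteinPair, int] = {}
        for i, p in enumerate(pairs):
            if p in seen:
                raise ValueError(
                    f"duplicate pair {p} at positions {seen[p]} and {i}"
                )
            seen[p] = i
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(zip(self.pairs, self.labels))

    @property
    def y(self) -> np.ndarray:
        return np.array(self.labels, dtype=int)

    @property
    def n_pos(self) -> int:
        return sum(1 for y in self.labels if y == 1)

    @property
    def n_neg(self) -> int:
        return sum(1 for y in self.labels if y == -1)

    def proteins(self) -> list[str]:
        """Sorted list of distinct protein ids appearing in any pair."""
        out = set()
        for p in self.pairs:
            out.add(p.a)
            out.add(p.b)
        return sorted(out)

    def subset(self, indices) -> "PairDataset":
        idx = list(indices)
        return PairDataset(
            pairs=tuple(self.pairs[i] for i in idx),
            labels=tuple(self.labels[i] for i in idx),
            allow_self=self.allow_self,
        )


@dataclass(frozen=True)
class PairKernelMatrix:
    """Kernel matrix over protein pairs.

    ``rows`` and ``cols`` usually coincide (a square Gram matrix) but a
    rectangular test-vs-train block is allowed.
    """

    rows: tuple[ProteinPair, ...]
    cols: tuple[ProteinPair, ...]
    values: np.ndarray
    construction: str = "TPPK"
    base_shifted: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.rows), len(self.cols)):
            raise ValueError(
                f"values shape {v.shape} != ({len(self.rows)}, {len(self.cols)})"
            )
        if self.rows == self.cols and v.size:
            if np.max(np.abs(v - v.T)) > 1e-8:
                raise MatrixValidationError("square pair kernel not symmetric")
            v = (v + v.T) / 2.0
        v.flags.writeable = False
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "rows", tuple(self.rows))
        object.__setattr__(self, "cols", tuple(self.cols))

    @property
    def is_square(self) -> bool:
        return self.rows == self.cols


def shift_base(K: KernelMatrix) -> KernelMatrix:
    """Add 1 to every entry of a normalized base kernel.

    A normalized kernel has entries in [-1, 1]; after the shift they lie
    in [0, 2].  The all-ones matrix is PSD, and the sum of PSD matrices
    is PSD, so validity is preserved.
    """
    if not K.normalized:
        raise ValueError("shift_base expects a unit-normalized kernel")
    return KernelMatrix(
        ids=K.ids,
        values=K.values + 1.0,
        corrected=K.corrected,
        normalized=K.normalized,
        shifted_by_one=True,
        _validate=False,
    )


def _pair_indices(
    Kb: KernelMatrix, pairs: tuple[ProteinPair, ...]
) -> tuple[np.ndarray, np.ndarray]:
    pos = {pid: i for i, pid in enumerate(Kb.ids)}
    try:
        ia = np.array([pos[p.a] for p in pairs], dtype=int)
        ib = np.array([pos[p.b] for p in pairs], dtype=int)
    except KeyError as exc:
        raise KeyError(
            f"pair references protein {exc.args[0]!r} absent from the base kernel"
        ) from None
    return ia, ib


def _build_blockwise(fn, n_rows: int, n_cols: int) -> np.ndarray:
    """Assemble a pair-kernel matrix row-block by row-block.

    ``fn(start, stop)`` returns rows [start, stop).  Bounds peak memory
    for large pair lists; the result is identical to full
    materialization.
    """
    out = np.empty((n_rows, n_cols))
    for start in range(0, n_rows, _BLOCK):
        stop = min(start + _BLOCK, n_rows)
        out[start:stop] = fn(start, stop)
    return out


def tppk(
    Kb: KernelMatrix,
    rows,
    cols=None,
    half: bool = False,
) -> PairKernelMatrix:
    """Tensor product pairwise kernel matrix.

    Parameters
    ----------
    Kb
        Base kernel; must have ``shifted_by_one=True`` (apply
        :func:`shift_base` first) so that products of base values cannot
        turn two dissimilar pairs into a similar one.
    rows, cols
        Pair lists; ``cols`` defaults to ``rows`` (square Gram matrix).
    half
        Multiply by 1/2 (some formulations include the factor); off by
        default.
    """
    if not Kb.shifted_by_one:
        raise ValueError(
            "TPPK requires the +1-shifted base kernel; apply shift_base first"
        )
    rows = tuple(rows)
    cols = rows if cols is None else tuple(cols)
    ra, rb = _pair_indices(Kb, rows)
    ca, cb = _pair_indices(Kb, cols)
    B = Kb.values

    def block(s, e):
        v = (
            B[np.ix_(ra[s:e], ca)] * B[np.ix_(rb[s:e], cb)]
            + B[np.ix_(ra[s:e], cb)] * B[np.ix_(rb[s:e], ca)]
        )
        return 0.5 * v if half else v

    values = _build_blockwise(block, len(rows), len(cols))
    return PairKernelMatrix(
        rows=rows, cols=cols, values=values, construction="TPPK", base_shifted=True
    )


def mlpk(Kb: KernelMatrix, rows, cols=None) -> PairKernelMatrix:
    """Metric learning pairwise kernel matrix.

    The value is the squared four-term difference
    ``(K(p1,q1) - K(p1,q2) - K(p2,q1) + K(p2,q2))**2``; any constant
    added to every base entry cancels, so shifted and unshifted base
    kernels give identical MLPK values.
    """
    rows = tuple(rows)
    cols = rows if cols is None else tuple(cols)
    ra, rb = _pair_indices(Kb, rows)
    ca, cb = _pair_indices(Kb, cols)
    B = Kb.values

    def block(s, e):
        diff = (
            B[np.ix_(ra[s:e], ca)]
            - B[np.ix_(ra[s:e], cb)]
            - B[np.ix_(rb[s:e], ca)]
            + B[np.ix_(rb[s:e], cb)]
        )
        return diff**2

    values = _build_blockwise(block, len(rows), len(cols))
    return PairKernelMatrix(
        rows=rows,
        cols=cols,
        values=values,
        construction="MLPK",
        base_shifted=Kb.shifted_by_one,
    )
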