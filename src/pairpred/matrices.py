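"""Named square matrix containers for protein similarity and kernel data.

``SimilarityMatrix`` holds raw, possibly indefinite all-vs-all scores such
as those produced by a structural aligner.  ``KernelMatrix`` holds a
symmetric positive-semidefinite matrix together with provenance flags
recording which transformations (spectral correction, unit normalization,
the +1 shift) produced it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-8
#: relative eigenvalue floor: smallest eigenvalue must be >= -PSD_TOL * largest
PSD_TOL = 1e-8


class MatrixValidationError(ValueError):
    """Raised when a similarity/kernel matrix violates its invariants."""


def _check_ids(ids: tuple[str, ...]) -> None:
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if list(ids).count(i) > 1})
        raise MatrixValidationError(f"duplicate ids: {dupes}")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square matrix of raw similarity scores over named proteins.

    Parameters
    ----------
    ids
        Ordered protein identifiers, one per row/column.
    values
        Square array of real scores.  Asymmetric input (common in raw
        aligner output) is symmetrized as ``(S + S.T) / 2`` with a
        warning; asymmetry beyond ``SYMMETRY_TOL`` is reported.
    """

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.ids)
        object.__setattr__(self, "ids", ids)
        _check_ids(ids)
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise MatrixValidationError(f"matrix must be square, got shape {v.shape}")
        if v.shape[0] != len(ids):
            raise MatrixValidationError(
                f"{len(ids)} ids but matrix of shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            bad = np.argwhere(~np.isfinite(v))[:5]
            raise MatrixValidationError(f"non-finite entries at {bad.tolist()}")
        asym = np.max(np.abs(v - v.T)) if v.size else 0.0
        if asym > SYMMETRY_TOL:
            logger.warning(
                "similarity matrix asymmetric (max |S - S.T| = %.3g); "
                "symmetrizing as (S + S.T)/2",
                asym,
            )
            v = (v + v.T) / 2.0
        else:
            v = (v + v.T) / 2.0  # exact symmetry for downstream eigh
        v.flags.writeable = False
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, protein_id: str) -> int:
        try:
            return self.ids.index(protein_id)
        except ValueError:
            raise KeyError(f"unknown protein id: {protein_id!r}") from None


@dataclass(frozen=True)
class KernelMatrix:
    """Symmetric PSD matrix over named proteins with provenance flags.

    Flags record the pipeline stage: ``corrected`` after spectral
    correction, ``normalized`` after projection onto the unit sphere,
    ``shifted_by_one`` after the +1 shift applied before pairwise kernel
    construction.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    corrected: bool = False
    normalized: bool = False
    shifted_by_one: bool = False
    _validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.ids)
        object.__setattr__(self, "ids", ids)
        _check_ids(ids)
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise MatrixValidationError(f"kernel must be square, got shape {v.shape}")
        if v.shape[0] != len(ids):
            raise MatrixValidationError(
                f"{len(ids)} ids but matrix of shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise MatrixValidationError("non-finite kernel entries")
        if np.max(np.abs(v - v.T), initial=0.0) > SYMMETRY_TOL:
            raise MatrixValidationError("kernel matrix not symmetric within 1e-8")
        v = (v + v.T) / 2.0
        if self._validate:
            self._check_psd(v)
            if self.normalized and not self.shifted_by_one:
                d = np.diag(v)
                if np.max(np.abs(d - 1.0), initial=0.0) > SYMMETRY_TOL:
                    raise MatrixValidationError(
                        "normalized kernel must have unit diagonal"
                    )
        v.flags.writeable = False
        object.__setattr__(self, "values", v)

    @staticmethod
    def _check_psd(v: np.ndarray) -> None:
        if v.size == 0:
            return
        w = np.linalg.eigvalsh(v)
        lam_max = max(w[-1], 0.0)
        if w[0] < -PSD_TOL * max(lam_max, 1.0):
            raise MatrixValidationError(
                f"kernel not PSD: smallest eigenvalue {w[0]:.3g} "
                f"(largest {lam_max:.3g}); apply spectral_correct first"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, protein_id: str) -> int:
        try:
            return self.ids.index(protein_id)
        except ValueError:
            raise KeyError(f"unknown protein id: {protein_id!r}") from None

    def with_flags(self, **flags: bool) -> "KernelMatrix":
        return replace(self, **flags)

    def submatrix(self, ids: list[str]) -> "KernelMatrix":
        """Restrict to a subset/reordering of proteins."""
        idx = np.array([self.index_of(i) for i in ids])
        return replace(
            self,
            ids=tuple(ids),
            values=self.values[np.ix_(idx, idx)],
            _validate=False,
        )
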