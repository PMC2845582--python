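"""Readers and writers for the plain-text formats the pipeline consumes.

Matrices travel as TSV with protein ids in the first row and column;
sequences as FASTA (ids up to the first whitespace in the header);
labeled pairs, cluster assignments, E-values and lengths as simple TSV
tables.  A binary matrix cache (NumPy ``.npz`` with an id manifest) is
available for large kernels.  All round-trips are lossless for ids and
preserve values to at least 1e-12 relative.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from pairpred.benchmark import ClusterAssignment, EvalueTable
from pairpred.matrices import KernelMatrix, SimilarityMatrix
from pairpred.pairs import PairDataset, PairKernelMatrix, ProteinPair

logger = logging.getLogger(__name__)

FORMAT_VERSION = "1"


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


def read_similarity_tsv(path) -> SimilarityMatrix:
    """Read a labeled square similarity matrix from TSV."""
    df = _read_matrix_df(path)
    return SimilarityMatrix(ids=tuple(df.index), values=df.to_numpy(dtype=float))


def _read_matrix_df(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(i) for i in df.index]
    cols = [str(c) for c in df.columns]
    _check_unique(ids, "row")
    _check_unique(cols, "column")
    if ids != cols:
        raise ValueError(f"{path}: row ids and column ids differ")
    body = df.to_numpy()
    try:
        body = body.astype(float)
    except (TypeError, ValueError):
        for r, row in enumerate(df.itertuples(index=False)):
            for c, cell in enumerate(row):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric cell at row {ids[r]!r}, "
                        f"column {cols[c]!r}: {cell!r}"
                    ) from None
        raise
    df.index = ids
    df.columns = cols
    return df.astype(float)


def write_similarity_tsv(path, S: SimilarityMatrix | KernelMatrix) -> None:
    df = pd.DataFrame(S.values, index=list(S.ids), columns=list(S.ids))
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_kernel_tsv(path, **flags) -> KernelMatrix:
    df = _read_matrix_df(path)
    return KernelMatrix(
        ids=tuple(df.index), values=df.to_numpy(dtype=float),
        _validate=False, **flags,
    )


def write_matrix_cache(path, M: SimilarityMatrix | KernelMatrix) -> None:
    """Binary cache: ``.npz`` holding the value array and an id manifest."""
    np.savez_compressed(
        path, values=M.values, ids=np.array(list(M.ids), dtype=object),
    )


def read_matrix_cache(path, kind: str = "similarity"):
    with np.load(path, allow_pickle=True) as z:
        ids = tuple(str(i) for i in z["ids"])
        values = z["values"]
    if kind == "similarity":
        return SimilarityMatrix(ids=ids, values=values)
    return KernelMatrix(ids=ids, values=values, _validate=False)


def read_fasta(path) -> dict[str, str]:
    """Sequences keyed by the FASTA header up to the first whitespace."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(s), id=pid, description="") for pid, s in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


_LABEL_TOKENS = {"1": 1, "+1": 1, "-1": -1}


def read_pairs_tsv(path, allow_self: bool = False) -> PairDataset:
    """Labeled pair list: columns id_a, id_b, label (+1/-1), optional
    weight.  Pairs are canonicalized; duplicates are rejected with the
    line numbers of both occurrences."""
    pairs: list[ProteinPair] = []
    labels: list[int] = []
    first_line: dict[ProteinPair, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                )
            a, b, token = fields[0].strip(), fields[1].strip(), fields[2].strip()
            if token not in _LABEL_TOKENS:
                raise ValueError(
                    f"{path}:{lineno}: unknown label token {token!r} "
                    "(expected +1, 1 or -1)"
                )
            p = ProteinPair(a, b)
            if p.is_self and not allow_self:
                raise ValueError(f"{path}:{lineno}: self-pair {p} not allowed")
            if p in first_line:
                raise ValueError(
                    f"{path}: duplicate pair {p} on lines "
                    f"{first_line[p]} and {lineno}"
                )
            first_line[p] = lineno
            pairs.append(p)
            labels.append(_LABEL_TOKENS[token])
    if not pairs:
        logger.warning("%s: empty pair list", path)
    return PairDataset(pairs=tuple(pairs), labels=tuple(labels), allow_self=allow_self)


def write_pairs_tsv(path, dataset: PairDataset) -> None:
    with open(path, "w") as fh:
        for p, y in dataset:
            fh.write(f"{p.a}\t{p.b}\t{y:+d}\n")


def write_pair_kernel_tsv(path, K: PairKernelMatrix) -> None:
    """Pair-kernel matrix TSV with ``id_a|id_b`` composite keys."""
    df = pd.DataFrame(
        K.values,
        index=[str(p) for p in K.rows],
        columns=[str(p) for p in K.cols],
    )
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_clusters_tsv(path) -> ClusterAssignment:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["protein", "cluster"], dtype=str
    )
    _check_unique(df["protein"], "protein")
    return ClusterAssignment(mapping=dict(zip(df["protein"], df["cluster"])))


def write_clusters_tsv(path, clusters: ClusterAssignment) -> None:
    with open(path, "w") as fh:
        for pid, cl in sorted(clusters.mapping.items()):
            fh.write(f"{pid}\t{cl}\n")


def read_evalues_tsv(path) -> EvalueTable:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["query", "target", "evalue"],
        dtype={"query": str, "target": str},
    )
    values = {
        (q, t): float(e)
        for q, t, e in zip(df["query"], df["target"], df["evalue"])
    }
    return EvalueTable(values=values)


def write_evalues_tsv(path, E: EvalueTable) -> None:
    with open(path, "w") as fh:
        for (q, t), e in sorted(E.values.items()):
            fh.write(f"{q}\t{t}\t{e:.6g}\n")


def read_lengths_tsv(path) -> dict[str, int]:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["protein", "length"], dtype={"protein": str}
    )
    _check_unique(df["protein"], "protein")
    return {p: int(n) for p, n in zip(df["protein"], df["length"])}


def write_lengths_tsv(path, lengths: dict[str, int]) -> None:
    with open(path, "w") as fh:
        for pid, n in sorted(lengths.items()):
            fh.write(f"{pid}\t{n}\n")


@dataclass
class RunConfig:
    """Experiment-level configuration.

    Defaults mirror the standard protocol: base kernel from a
    similarity matrix, MLPK pairwise construction, SVM classifier,
    the full hyperparameter grids, benchmark ratio r = 3.
    """

    kernel: str = "matrix"  # "matrix" (structure scores) | "mismatch"
    matrix_file: str | None = None
    fasta_file: str | None = None
    pairs_file: str | None = None
    pairwise: str = "mlpk"  # "tppk" | "mlpk"
    classifier: str = "svm"  # "svm" | "nn"
    mismatch_k: int = 6
    mismatch_m: int = 1
    psi: str = "shift"  # "shift" (1 + lambda) | "square" (lambda^2)
    folds: int = 5
    repeats: int = 3
    ratio: float = 3.0
    c_plus_grid: tuple = tuple(10.0**e for e in range(-8, 9))
    ratio_grid: tuple = (3.0, 10.0, 100.0)
    k_grid: tuple = (1, 2, 3, 5, 10, 15)
    extrapolation_v: int | None = None
    extrapolation_e: int | None = None
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        for attr in ("matrix_file", "fasta_file", "pairs_file"):
            f = getattr(cfg, attr)
            if f is not None and not Path(f).exists():
                raise FileNotFoundError(f"{attr} = {f!r} does not exist")
        if cfg.pairwise not in ("tppk", "mlpk"):
            raise ValueError(f"pairwise must be tppk or mlpk, got {cfg.pairwise!r}")
        if cfg.classifier not in ("svm", "nn"):
            raise ValueError(f"classifier must be svm or nn, got {cfg.classifier!r}")
        if cfg.kernel not in ("matrix", "mismatch"):
            raise ValueError(f"kernel must be matrix or mismatch, got {cfg.kernel!r}")
        return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: dict, seeds: dict, inputs: list) -> Path:
    """Record the run: config echo, seeds, format version, and sha256
    checksums of every input file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": FORMAT_VERSION,
        "config": config,
        "seeds": seeds,
        "inputs": {str(p): _sha256(p) for p in inputs if p and Path(p).exists()},
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
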