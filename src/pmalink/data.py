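"""Core data model and tabular I/O.

The central object is the binary pseudogene x miRNA adjacency matrix built
from experimentally supported associations; side information (a pseudogene
expression table and miRNA target-gene sets) is carried alongside it in a
:class:`DatasetBundle`.  All three tables are plain TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationMatrix",
    "ExpressionTable",
    "TargetSets",
    "DatasetBundle",
    "load_pairs",
    "load_expression",
    "load_targets",
    "count_unlabeled",
    "write_pairs",
    "write_matrix",
    "read_matrix",
]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")
    return ids


@dataclass
class AssociationMatrix:
    """Binary adjacency matrix PM with identifier axes.

    ``values[i, j] == 1`` iff pseudogene ``pseudogene_ids[i]`` is known to be
    associated with miRNA ``mirna_ids[j]``.
    """

    values: np.ndarray
    pseudogene_ids: list[str]
    mirna_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("association matrix must be 2-D")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8)
        self.pseudogene_ids = _check_unique(self.pseudogene_ids, "pseudogene")
        self.mirna_ids = _check_unique(self.mirna_ids, "miRNA")
        n_p, n_m = self.values.shape
        if len(self.pseudogene_ids) != n_p or len(self.mirna_ids) != n_m:
            raise ValueError("identifier lists do not match matrix shape")

    @property
    def n_pseudogenes(self) -> int:
        return self.values.shape[0]

    @property
    def n_mirnas(self) -> int:
        return self.values.shape[1]

    def positive_pairs(self) -> np.ndarray:
        """Indices (i, j) of known associations, row-major order."""
        return np.argwhere(self.values == 1)

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            self.values.copy(), list(self.pseudogene_ids), list(self.mirna_ids)
        )


@dataclass
class ExpressionTable:
    """Real-valued pseudogene x condition expression matrix."""

    values: np.ndarray
    pseudogene_ids: list[str]
    condition_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression table must be 2-D")
        if np.isnan(self.values).any():
            raise ValueError("expression table contains missing values")
        self.pseudogene_ids = _check_unique(self.pseudogene_ids, "pseudogene")
        self.condition_ids = _check_unique(self.condition_ids, "condition")
        if self.values.shape != (len(self.pseudogene_ids), len(self.condition_ids)):
            raise ValueError("identifier lists do not match matrix shape")


class TargetSets(dict):
    """Mapping miRNA id -> frozenset of target-gene identifiers."""

    def __init__(self, mapping: Mapping[str, Sequence[str]] | None = None):
        super().__init__()
        if mapping:
            for k, v in mapping.items():
                self[str(k)] = frozenset(str(g) for g in v)

    def get_set(self, mirna_id: str) -> frozenset:
        return self.get(mirna_id, frozenset())


@dataclass
class DatasetBundle:
    """Associations plus optional side tables, aligned by identifier."""

    associations: AssociationMatrix
    expression: ExpressionTable | None = None
    targets: TargetSets | None = None
    provenance: str = ""
    metadata: dict = field(default_factory=dict)


def count_unlabeled(pm: AssociationMatrix) -> int:
    """Number of unconfirmed (unlabeled) pseudogene-miRNA pairs."""
    return int(pm.values.size - pm.values.sum())


def load_pairs(
    path,
    pseudogene_ids: Sequence[str] | None = None,
    mirna_ids: Sequence[str] | None = None,
    header: bool = False,
) -> AssociationMatrix:
    """Read a two-column (pseudogene_id, mirna_id) TSV into an adjacency matrix.

    Duplicate pairs collapse to a single 1.  Identifier order is
    first-appearance order unless explicit axis lists are given, in which case
    every listed entity appears even with zero associations.
    """
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
            pairs.append((fields[0].strip(), fields[1].strip()))
    if not pairs:
        raise ValueError(f"{path}: no association pairs found")

    if pseudogene_ids is None:
        pseudogene_ids = list(dict.fromkeys(p for p, _ in pairs))
    else:
        pseudogene_ids = [str(x) for x in pseudogene_ids]
    if mirna_ids is None:
        mirna_ids = list(dict.fromkeys(m for _, m in pairs))
    else:
        mirna_ids = [str(x) for x in mirna_ids]

    p_index = {p: i for i, p in enumerate(pseudogene_ids)}
    m_index = {m: j for j, m in enumerate(mirna_ids)}
    values = np.zeros((len(pseudogene_ids), len(mirna_ids)), dtype=np.int8)
    for p, m in pairs:
        if p not in p_index:
            raise ValueError(f"pseudogene {p!r} not in the provided identifier list")
        if m not in m_index:
            raise ValueError(f"miRNA {m!r} not in the provided identifier list")
        values[p_index[p], m_index[m]] = 1
    return AssociationMatrix(values, pseudogene_ids, mirna_ids)


def load_expression(path) -> ExpressionTable:
    """Read a TSV expression table (first column = pseudogene id, one header line).

    Rows containing missing values are dropped and logged.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError("expression table needs at least two condition columns")
    bad = df.index[df.isna().any(axis=1)]
    if len(bad):
        logger.warning("dropping %d expression rows with missing values", len(bad))
        df = df.drop(index=bad)
    return ExpressionTable(
        df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]
    )


def load_targets(path) -> TargetSets:
    """Read a two-column (mirna_id, gene_id) TSV into target sets."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
            mapping.setdefault(fields[0].strip(), set()).add(fields[1].strip())
    return TargetSets(mapping)


def write_pairs(pm: AssociationMatrix, path) -> None:
    """Write the positive pairs of an adjacency matrix as a two-column TSV."""
    with open(path, "w") as fh:
        for i, j in pm.positive_pairs():
            fh.write(f"{pm.pseudogene_ids[i]}\t{pm.mirna_ids[j]}\n")


def write_matrix(values: np.ndarray, row_ids: Sequence[str], col_ids: Sequence[str], path) -> None:
    """Write a labelled matrix as TSV (12 significant digits for reals)."""
    values = np.asarray(values)
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(str(c) for c in col_ids) + "\n")
        for rid, row in zip(row_ids, values):
            if np.issubdtype(values.dtype, np.integer):
                cells = [str(int(v)) for v in row]
            else:
                cells = [format(float(v), ".12g") for v in row]
            fh.write(str(rid) + "\t" + "\t".join(cells) + "\n")


def read_matrix(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a labelled TSV matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]
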