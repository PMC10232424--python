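"""Entity similarity kernels.

Four pseudogene kernels (expression Pearson, Gaussian interaction profile,
Hamming profile, cosine profile) and four miRNA kernels (target-set
functional, GIP, Hamming, cosine).  The GIP/Hamming/cosine kernels are
functions of the interaction profiles, i.e. the rows (pseudogene axis) or
columns (miRNA axis) of the binary adjacency matrix.

Conventions shared by all kernels: output is symmetric, entries lie in
[0, 1], and the diagonal is exactly 1.  Entities whose defining profile is
degenerate (all-zero interaction profile, constant expression row, empty
target set, or an entity absent from a side table) get similarity 0 to every
other entity and self-similarity 1, which keeps each matrix a valid kernel
for the fusion stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .data import AssociationMatrix, ExpressionTable, TargetSets

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityMatrix",
    "expression_similarity",
    "functional_similarity",
    "gip_kernel",
    "hamming_similarity",
    "cosine_similarity",
    "pseudogene_kernel_stack",
    "mirna_kernel_stack",
]

_AXES = ("pseudogene", "mirna")


@dataclass
class SimilarityMatrix:
    """Square symmetric nonnegative similarity kernel with labelled axis."""

    values: np.ndarray
    entity_ids: list[str]
    kernel_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square and match entity_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError(f"{self.kernel_name}: similarity matrix is not symmetric")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError(f"{self.kernel_name}: entries outside [0, 1]")
        np.clip(self.values, 0.0, 1.0, out=self.values)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _profiles(pm: AssociationMatrix, axis: str) -> tuple[np.ndarray, list[str]]:
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {_AXES}")
    if axis == "pseudogene":
        return pm.values.astype(float), list(pm.pseudogene_ids)
    return pm.values.T.astype(float), list(pm.mirna_ids)


def expression_similarity(
    expr: ExpressionTable, pseudogene_ids: Sequence[str] | None = None
) -> SimilarityMatrix:
    """Pearson correlation of expression rows, negatives clipped to 0.

    ``pseudogene_ids`` aligns the kernel to the association axis; entities
    without an expression row get the degenerate-profile convention.
    Constant (zero-variance) rows likewise get 0 off-diagonal.
    """
    if expr.values.shape[1] < 2:
        raise ValueError("expression similarity needs at least two conditions")
    if pseudogene_ids is None:
        pseudogene_ids = list(expr.pseudogene_ids)
    pseudogene_ids = [str(x) for x in pseudogene_ids]
    n = len(pseudogene_ids)
    row_of = {p: i for i, p in enumerate(expr.pseudogene_ids)}

    out = np.zeros((n, n))
    present = [k for k, p in enumerate(pseudogene_ids) if p in row_of]
    missing = n - len(present)
    if missing:
        logger.info("expression table missing %d of %d pseudogenes", missing, n)
    if present:
        sub = expr.values[[row_of[pseudogene_ids[k]] for k in present]]
        sd = sub.std(axis=1)
        nonconst = sd > 0
        if nonconst.sum() >= 2:
            corr = np.corrcoef(sub[nonconst])
            idx = np.array(present)[nonconst]
            out[np.ix_(idx, idx)] = np.clip(corr, 0.0, 1.0)
    np.fill_diagonal(out, 1.0)
    out = (out + out.T) / 2
    return SimilarityMatrix(out, pseudogene_ids, "expression_pearson")


def functional_similarity(
    targets: TargetSets, mirna_ids: Sequence[str]
) -> SimilarityMatrix:
    """Target-set overlap |Gi ∩ Gj| / (sqrt|Gi| · sqrt|Gj|).

    miRNAs absent from the mapping are treated as having an empty target set
    (logged, not an error); empty sets follow the degenerate convention.
    """
    mirna_ids = [str(x) for x in mirna_ids]
    sets = []
    n_missing = 0
    for m in mirna_ids:
        s = targets.get_set(m) if isinstance(targets, TargetSets) else frozenset(
            targets.get(m, ())
        )
        if not s and m not in targets:
            n_missing += 1
        sets.append(s)
    if n_missing:
        logger.info("%d miRNAs absent from target mapping; treated as empty sets", n_missing)
    n = len(mirna_ids)
    out = np.zeros((n, n))
    sizes = np.array([len(s) for s in sets], dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            if sizes[i] and sizes[j]:
                out[i, j] = out[j, i] = len(sets[i] & sets[j]) / (
                    np.sqrt(sizes[i]) * np.sqrt(sizes[j])
                )
    np.fill_diagonal(out, 1.0)
    return SimilarityMatrix(out, mirna_ids, "functional_targets")


def gip_kernel(pm: AssociationMatrix, axis: str) -> SimilarityMatrix:
    """Gaussian interaction profile kernel exp(-γ ||x_i - x_j||²).

    The bandwidth γ is the reciprocal of the mean squared profile norm over
    the chosen axis, so the kernel adapts to the density of the adjacency
    matrix.  Requires at least one known association.
    """
    profiles, ids = _profiles(pm, axis)
    mean_sq_norm = float((profiles**2).sum(axis=1).mean())
    if mean_sq_norm == 0:
        raise ValueError("empty interaction profile: adjacency matrix has no positives")
    gamma = 1.0 / mean_sq_norm
    d2 = cdist(profiles, profiles, "sqeuclidean")
    out = np.exp(-gamma * d2)
    np.fill_diagonal(out, 1.0)
    out = (out + out.T) / 2
    return SimilarityMatrix(out, ids, f"gip_{axis}")


def hamming_similarity(pm: AssociationMatrix, axis: str) -> SimilarityMatrix:
    """1 minus the fraction of profile positions at which two entities differ."""
    profiles, ids = _profiles(pm, axis)
    out = 1.0 - cdist(profiles, profiles, "hamming")
    np.fill_diagonal(out, 1.0)
    out = (out + out.T) / 2
    return SimilarityMatrix(out, ids, f"hamming_{axis}")


def cosine_similarity(pm: AssociationMatrix, axis: str) -> SimilarityMatrix:
    """Cosine of the angle between interaction profiles.

    Zero-norm profiles get 0 off-diagonal and 1 on the diagonal.
    """
    profiles, ids = _profiles(pm, axis)
    norms = np.linalg.norm(profiles, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = profiles / safe[:, None]
    out = unit @ unit.T
    out[norms == 0, :] = 0.0
    out[:, norms == 0] = 0.0
    np.fill_diagonal(out, 1.0)
    out = np.clip((out + out.T) / 2, 0.0, 1.0)
    return SimilarityMatrix(out, ids, f"cosine_{axis}")


def pseudogene_kernel_stack(
    pm: AssociationMatrix, expression: ExpressionTable | None
) -> list[SimilarityMatrix]:
    """The pseudogene kernels: expression (if available), GIP, Hamming, cosine."""
    stack = []
    if expression is not None:
        stack.append(expression_similarity(expression, pm.pseudogene_ids))
    stack += [
        gip_kernel(pm, "pseudogene"),
        hamming_similarity(pm, "pseudogene"),
        cosine_similarity(pm, "pseudogene"),
    ]
    return stack


def mirna_kernel_stack(
    pm: AssociationMatrix, targets: TargetSets | None
) -> list[SimilarityMatrix]:
    """The miRNA kernels: target-set functional (if available), GIP, Hamming, cosine."""
    stack = []
    if targets is not None:
        stack.append(functional_similarity(targets, pm.mirna_ids))
    stack += [
        gip_kernel(pm, "mirna"),
        hamming_similarity(pm, "mirna"),
        cosine_similarity(pm, "mirna"),
    ]
    return stack
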