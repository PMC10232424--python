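"""Similarity kernel fusion (SKF).

Fuses K similarity kernels over the same entities by cross-kernel diffusion:

1. each kernel is column-normalized to give its initial status matrix;
2. a row-stochastic kNN sparsification of each *original* kernel acts as a
   fixed local diffusion operator;
3. each status is repeatedly updated towards the sparsified projection of
   the average of the *other* kernels' statuses, mixed (weight ``alpha``)
   with the average of the other kernels' initial statuses, and
   re-symmetrized;
4. the final statuses are averaged and denoised elementwise by a
   mutual-neighbour weight matrix (1 for mutual kNN pairs, 0 for mutually
   non-neighbouring pairs, 0.5 otherwise).

The update couples every kernel to the consensus of the others, so shared
structure is amplified and kernel-specific noise is averaged out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import SimilarityMatrix

__all__ = [
    "FusionConfig",
    "FusedSimilarity",
    "normalize_kernel",
    "sparsify_kernel",
    "neighbor_mask",
    "skf_fuse",
]


@dataclass
class FusionConfig:
    """Knobs of the diffusion.

    ``alpha`` balances diffusion against the initial statuses and must lie in
    (0, 1); ``n_neighbors`` sets the kNN neighbourhood size (``None`` means
    max(3, round(0.3 n)), resolved at fusion time); ``n_iterations`` caps the
    diffusion steps and ``tol`` stops early once the largest status change
    falls below it.  ``legacy_denominator`` divides the complement sum by 2
    instead of K-1 (see docs/methods.md).
    """

    alpha: float = 0.5
    n_neighbors: int | None = None
    n_iterations: int = 10
    tol: float = 1e-6
    legacy_denominator: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.n_neighbors is not None and self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.tol < 0:
            raise ValueError("tol must be nonnegative")

    def resolve_neighbors(self, n: int) -> int:
        k = self.n_neighbors if self.n_neighbors is not None else max(3, round(0.3 * n))
        if k > n:
            raise ValueError(f"n_neighbors={k} exceeds number of entities {n}")
        return k


@dataclass
class FusedSimilarity:
    """SKF output plus the configuration that produced it."""

    values: SimilarityMatrix
    config: FusionConfig = field(default_factory=FusionConfig)
    iterations_run: int = 0


def normalize_kernel(values: np.ndarray) -> np.ndarray:
    """Column-stochastic normalization; all-zero columns become uniform."""
    values = np.asarray(values, dtype=float)
    if values.min() < 0:
        raise ValueError("kernel has negative entries")
    colsum = values.sum(axis=0)
    n = values.shape[0]
    out = np.empty_like(values)
    zero = colsum == 0
    nz = ~zero
    out[:, nz] = values[:, nz] / colsum[nz]
    out[:, zero] = 1.0 / n
    return out


def neighbor_mask(values: np.ndarray, n_neighbors: int) -> np.ndarray:
    """Boolean mask of each row's kNN set N_i.

    N_i always contains i itself plus the ``n_neighbors - 1`` other entities
    with the largest similarity to i; ties are broken by ascending index.
    """
    if n_neighbors < 1:
        raise ValueError("n_neighbors must be >= 1")
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    mask = np.zeros((n, n), dtype=bool)
    idx = np.arange(n)
    for i in range(n):
        mask[i, i] = True
        if n_neighbors > 1:
            others = idx[idx != i]
            # descending similarity, ascending index on ties
            order = others[np.lexsort((others, -values[i, others]))]
            mask[i, order[: n_neighbors - 1]] = True
    return mask


def sparsify_kernel(values: np.ndarray, n_neighbors: int) -> np.ndarray:
    """Row-stochastic kNN sparsification (local diffusion operator)."""
    values = np.asarray(values, dtype=float)
    if values.min() < 0:
        raise ValueError("kernel has negative entries")
    mask = neighbor_mask(values, n_neighbors)
    out = np.where(mask, values, 0.0)
    rowsum = out.sum(axis=1)
    zero = rowsum == 0
    if zero.any():
        # degenerate all-zero neighbourhood: uniform over N_i
        out[zero] = mask[zero] / mask[zero].sum(axis=1, keepdims=True)
        rowsum = out.sum(axis=1)
    return out / rowsum[:, None]


def skf_fuse(stack: list[SimilarityMatrix], config: FusionConfig | None = None) -> FusedSimilarity:
    """Fuse a stack of K >= 2 similarity kernels over identical entities."""
    if config is None:
        config = FusionConfig()
    if len(stack) < 2:
        raise ValueError("kernel fusion needs at least two kernels")
    ids = stack[0].entity_ids
    for s in stack[1:]:
        if s.entity_ids != ids or s.values.shape != stack[0].values.shape:
            raise ValueError("all kernels in the stack must share entity_ids")
    K = len(stack)
    n = len(ids)
    nn = config.resolve_neighbors(n)
    denom = 2.0 if config.legacy_denominator else float(K - 1)

    initial = [normalize_kernel(s.values) for s in stack]
    operators = [sparsify_kernel(s.values, nn) for s in stack]

    statuses = [m.copy() for m in initial]
    init_total = np.sum(initial, axis=0)
    iterations_run = 0
    for _ in range(config.n_iterations):
        total = np.sum(statuses, axis=0)
        new = []
        for r in range(K):
            comp_t = (total - statuses[r]) / denom
            comp_0 = (init_total - initial[r]) / denom
            m = config.alpha * (operators[r] @ comp_t @ operators[r].T) + (
                1 - config.alpha
            ) * comp_0
            new.append((m + m.T) / 2)
        delta = max(float(np.abs(a - b).max()) for a, b in zip(new, statuses))
        statuses = new
        iterations_run += 1
        if delta < config.tol:
            break

    overall = np.mean(statuses, axis=0)
    mask = neighbor_mask(overall, nn)
    weight = np.where(
        mask & mask.T, 1.0, np.where(~mask & ~mask.T, 0.0, 0.5)
    )
    fused = weight * overall
    fused = (fused + fused.T) / 2
    np.clip(fused, 0.0, None, out=fused)
    return FusedSimilarity(
        values=SimilarityMatrix(fused, list(ids), "skf_fused"),
        config=config,
        iterations_run=iterations_run,
    )
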