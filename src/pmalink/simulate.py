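"""Synthetic dataset generator with planted block structure.

Real pseudogene-miRNA association data pair a sparse bipartite adjacency
matrix with pseudogene expression profiles and miRNA target-gene sets.  All
similarity kernels used downstream reward shared-neighbour / shared-profile
structure, so the generator plants a stochastic block model: pseudogenes and
miRNAs are assigned to latent blocks, associations are dense within a block
and sparse between blocks, expression rows are noisy copies of a block mean,
and target sets are drawn mostly from a block-specific gene pool.  Block
membership is the recoverable ground truth that makes every downstream stage
testable without database downloads.
"""

from __future__ import annotations

import numpy as np

from .data import AssociationMatrix, DatasetBundle, ExpressionTable, TargetSets

__all__ = ["generate_synthetic_dataset", "shuffle_associations"]


def generate_synthetic_dataset(
    n_p: int = 120,
    n_m: int = 100,
    n_blocks: int = 4,
    p_within: float = 0.3,
    p_between: float = 0.02,
    n_conditions: int = 12,
    expr_noise_sd: float = 0.5,
    genes_per_block: int = 60,
    gene_overlap: float = 0.1,
    targets_per_mirna: int = 20,
    seed: int = 0,
) -> DatasetBundle:
    """Generate a planted-block bundle; a pure function of its arguments.

    Parameters
    ----------
    n_p, n_m:
        Numbers of pseudogenes and miRNAs.
    n_blocks:
        Latent blocks; each entity is assigned to one uniformly at random.
    p_within, p_between:
        Association probability for same-block and cross-block pairs;
        requires ``0 <= p_between < p_within <= 1``.
    n_conditions:
        Expression conditions (tissues / cancers).
    expr_noise_sd:
        Standard deviation of the i.i.d. Gaussian noise added to the
        block-specific expression mean (itself standard normal per condition).
    genes_per_block, gene_overlap, targets_per_mirna:
        Each miRNA draws ``targets_per_mirna`` target genes, a
        ``1 - gene_overlap`` fraction from its own block's pool of
        ``genes_per_block`` genes and the rest from the other pools.
    seed:
        Single integer seed; per-component streams are derived from it.
    """
    if not (0 <= p_between < p_within <= 1):
        raise ValueError("require 0 <= p_between < p_within <= 1")
    if n_blocks < 1 or n_blocks > min(n_p, n_m):
        raise ValueError("n_blocks must be in [1, min(n_p, n_m)]")
    if not (0 <= gene_overlap <= 1):
        raise ValueError("gene_overlap must be in [0, 1]")
    if n_conditions < 2:
        raise ValueError("need at least two expression conditions")
    if expr_noise_sd < 0:
        raise ValueError("expr_noise_sd must be nonnegative")
    if genes_per_block < 1 or targets_per_mirna < 1:
        raise ValueError("genes_per_block and targets_per_mirna must be positive")

    rng_blocks = np.random.default_rng([int(seed), 1])
    rng_pm = np.random.default_rng([int(seed), 2])
    rng_expr = np.random.default_rng([int(seed), 3])
    rng_targets = np.random.default_rng([int(seed), 4])

    p_blocks = rng_blocks.integers(0, n_blocks, size=n_p)
    m_blocks = rng_blocks.integers(0, n_blocks, size=n_m)

    same_block = p_blocks[:, None] == m_blocks[None, :]
    prob = np.where(same_block, p_within, p_between)
    values = (rng_pm.random((n_p, n_m)) < prob).astype(np.int8)

    pseudogene_ids = [f"PG{i:04d}" for i in range(n_p)]
    mirna_ids = [f"MIR{j:04d}" for j in range(n_m)]
    pm = AssociationMatrix(values, pseudogene_ids, mirna_ids)

    block_means = rng_expr.standard_normal((n_blocks, n_conditions))
    expr_values = block_means[p_blocks] + expr_noise_sd * rng_expr.standard_normal(
        (n_p, n_conditions)
    )
    expression = ExpressionTable(
        expr_values, list(pseudogene_ids), [f"cond{c:02d}" for c in range(n_conditions)]
    )

    pools = [
        [f"gene_b{b}_{k:03d}" for k in range(genes_per_block)] for b in range(n_blocks)
    ]
    mapping: dict[str, set[str]] = {}
    n_own = int(round(targets_per_mirna * (1 - gene_overlap)))
    n_own = min(n_own, genes_per_block)
    for j, mid in enumerate(mirna_ids):
        b = m_blocks[j]
        own = rng_targets.choice(pools[b], size=n_own, replace=False)
        other_pool = [g for bb in range(n_blocks) if bb != b for g in pools[bb]]
        n_other = min(targets_per_mirna - n_own, len(other_pool))
        other = (
            rng_targets.choice(other_pool, size=n_other, replace=False)
            if n_other > 0
            else []
        )
        mapping[mid] = set(own) | set(other)
    targets = TargetSets(mapping)

    return DatasetBundle(
        associations=pm,
        expression=expression,
        targets=targets,
        provenance=(
            f"synthetic planted-block bundle (n_p={n_p}, n_m={n_m}, "
            f"n_blocks={n_blocks}, p_within={p_within}, p_between={p_between}, "
            f"seed={seed})"
        ),
        metadata={
            "pseudogene_blocks": p_blocks.tolist(),
            "mirna_blocks": m_blocks.tolist(),
            "seed": int(seed),
        },
    )


def shuffle_associations(bundle: DatasetBundle, seed: int) -> DatasetBundle:
    """Null bundle: same number of positives placed uniformly at random.

    Destroys the planted association structure while keeping the side tables,
    giving a permutation null for cross-validation performance.
    """
    pm = bundle.associations
    n = int(pm.values.sum())
    rng = np.random.default_rng([int(seed), 99])
    flat = rng.choice(pm.values.size, size=n, replace=False)
    values = np.zeros(pm.values.size, dtype=np.int8)
    values[flat] = 1
    shuffled = AssociationMatrix(
        values.reshape(pm.values.shape), list(pm.pseudogene_ids), list(pm.mirna_ids)
    )
    return DatasetBundle(
        associations=shuffled,
        expression=bundle.expression,
        targets=bundle.targets,
        provenance=bundle.provenance + f" [associations shuffled, seed={seed}]",
        metadata=dict(bundle.metadata),
    )
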