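"""Partition robustness: Rand Index, adjusted Rand Index, leave-N-out stability.

The stability protocol clusters the full cohort once (the consensus initial
partition, CIP), then repeatedly removes a few subjects, rebuilds the
similarity matrix from the remaining z-score rows, re-runs consensus
clustering at the same gamma and scores the agreement with the CIP on the
retained subjects with the Rand Index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import comb

from .cluster import ClusteringConfig, ConsensusPartition, consensus_cluster, similarity_matrix

__all__ = [
    "StabilityConfig",
    "StabilityReport",
    "rand_index",
    "adjusted_rand_index",
    "loo_stability",
]


@dataclass
class StabilityConfig:
    removal_sizes: Sequence[int] = tuple(range(1, 34))
    reps_per_size: int = 10
    master_seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.removal_sizes):
            raise ValueError("removal sizes must be >= 0")
        if self.reps_per_size < 1:
            raise ValueError("reps_per_size must be >= 1")


@dataclass
class StabilityReport:
    """Rand-Index distributions per removal size."""

    records: pd.DataFrame  # columns: size, rep, ri
    cip: ConsensusPartition = field(repr=False, default=None)

    @property
    def medians(self) -> dict[int, float]:
        return self.records.groupby("size")["ri"].median().to_dict()

    @property
    def overall_median(self) -> float:
        return float(self.records["ri"].median())


def _contingency(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    pi = np.unique(p, return_inverse=True)[1]
    qi = np.unique(q, return_inverse=True)[1]
    table = np.zeros((pi.max() + 1, qi.max() + 1), dtype=np.int64)
    np.add.at(table, (pi, qi), 1)
    return table


def _check_pair(p, q) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p)
    q = np.asarray(q)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("labelings must be 1-D and of equal length")
    if p.size < 2:
        raise ValueError("need at least 2 items")
    return p, q


def rand_index(p, q) -> float:
    """Fraction of item pairs co-clustered in both or separated in both labelings."""
    p, q = _check_pair(p, q)
    n = p.size
    table = _contingency(p, q)
    total = comb(n, 2, exact=True)
    same_both = int(comb(table, 2).sum())
    same_p = int(comb(table.sum(axis=1), 2).sum())
    same_q = int(comb(table.sum(axis=0), 2).sum())
    disagree = (same_p - same_both) + (same_q - same_both)
    return (total - disagree) / total


def adjusted_rand_index(p, q) -> float:
    """Chance-corrected Rand Index via the standard contingency formulation."""
    p, q = _check_pair(p, q)
    n = p.size
    table = _contingency(p, q)
    index = comb(table, 2).sum()
    sum_a = comb(table.sum(axis=1), 2).sum()
    sum_b = comb(table.sum(axis=0), 2).sum()
    total = comb(n, 2, exact=True)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((index - expected) / (max_index - expected))


def loo_stability(z: np.ndarray, gamma: float, stab: StabilityConfig,
                  cluster_config: ClusteringConfig | None = None,
                  cip: ConsensusPartition | None = None) -> StabilityReport:
    """Leave-N-out stability of the consensus partition.

    ``z`` is the ADS subjects x features z-score matrix. The CIP is computed
    on the full matrix (or passed in); each repetition removes ``size``
    subjects uniformly without replacement, recomputes the similarity matrix
    from the remaining rows and re-runs consensus clustering with gamma
    unchanged; the RI is evaluated against the CIP restricted to the retained
    subjects.
    """
    z = np.asarray(z, dtype=float)
    n = z.shape[0]
    if any(s >= n for s in stab.removal_sizes):
        raise ValueError("removal size must be smaller than the number of subjects")
    base_cfg = cluster_config or ClusteringConfig(gamma=gamma)
    if cip is None:
        full_cfg = _with(base_cfg, gamma=gamma, seed=stab.master_seed)
        cip = consensus_cluster(similarity_matrix(z), full_cfg)

    ss = np.random.SeedSequence(stab.master_seed)
    rows = []
    for size in stab.removal_sizes:
        for rep in range(stab.reps_per_size):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            keep = np.sort(rng.permutation(n)[size:])
            sub_seed = int(rng.integers(2 ** 31 - 1))
            cfg = _with(base_cfg, gamma=gamma, seed=sub_seed)
            part = consensus_cluster(similarity_matrix(z[keep]), cfg)
            ri = rand_index(part.labels, cip.labels[keep])
            rows.append({"size": size, "rep": rep, "ri": ri})
    records = pd.DataFrame(rows, columns=["size", "rep", "ri"])
    return StabilityReport(records=records, cip=cip)


def _with(cfg: ClusteringConfig, **kwargs) -> ClusteringConfig:
    params = dict(
        gamma=cfg.gamma, n_iterations=cfg.n_iterations,
        coassignment_threshold=cfg.coassignment_threshold,
        max_consensus_rounds=cfg.max_consensus_rounds,
        negative_weight_policy=cfg.negative_weight_policy, seed=cfg.seed)
    params.update(kwargs)
    return ClusteringConfig(**params)
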