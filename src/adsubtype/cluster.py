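"""Subject-similarity graph construction and weighted-modularity community detection.

The clustering route is: pairwise correlation between subjects' abnormality
z-score vectors -> weighted graph -> Louvain modularity maximization with a
resolution parameter gamma -> consensus over many seeded iterations via a
co-assignment matrix, iterated until the co-assignment matrix is binary-blocked.
A gamma search returns the smallest grid value whose consensus partition has a
requested number of clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ClusteringConfig",
    "PartitionResult",
    "ConsensusPartition",
    "GammaSearchError",
    "ConsensusError",
    "similarity_matrix",
    "modularity",
    "louvain",
    "consensus_cluster",
    "gamma_search",
]

_MOVE_TOL = 1e-12


class GammaSearchError(RuntimeError):
    """No gamma on the grid produced the requested number of clusters."""

    def __init__(self, message: str, k_by_gamma: dict[float, int] | None = None):
        super().__init__(message)
        self.k_by_gamma = k_by_gamma or {}


class ConsensusError(RuntimeError):
    """Consensus iteration failed to reach a binary-blocked co-assignment matrix."""


@dataclass
class ClusteringConfig:
    """Parameters of the consensus community-detection run."""

    gamma: float = 1.2
    n_iterations: int = 1000
    coassignment_threshold: float = 0.5
    max_consensus_rounds: int = 100
    negative_weight_policy: str = "clip_zero"  # or "signed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if not 0 < self.coassignment_threshold < 1:
            raise ValueError("coassignment_threshold must lie in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.max_consensus_rounds < 1:
            raise ValueError("max_consensus_rounds must be >= 1")
        if self.negative_weight_policy not in ("clip_zero", "signed"):
            raise ValueError(
                f"unknown negative_weight_policy {self.negative_weight_policy!r}"
            )


@dataclass
class PartitionResult:
    """A single community-detection outcome."""

    labels: np.ndarray  # contiguous integers from 1, canonical by size
    modularity: float
    gamma: float
    seed: int | None = None


@dataclass
class ConsensusPartition:
    """Final consensus labels plus the first-round co-assignment matrix."""

    labels: np.ndarray
    coassignment: np.ndarray
    gamma: float
    n_iterations: int
    rounds: int
    partitions: list[np.ndarray] | None = None

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())


# ---------------------------------------------------------------------------
# similarity


def similarity_matrix(z: np.ndarray, method: str = "pearson",
                      subject_ids: Sequence[str] | None = None) -> np.ndarray:
    """Pairwise correlation between subjects' z-score vectors.

    Rows are subjects, columns features. Pearson by default; Spearman
    available. Raises on zero-variance rows, naming the offending subject.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 2:
        raise ValueError("z must be a 2-D subjects x features array")
    n, p = z.shape
    if n < 3:
        raise ValueError(f"need >= 3 subjects, got {n}")
    if p < 2:
        raise ValueError(f"need >= 2 features, got {p}")
    sd = z.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = ([str(subject_ids[i]) for i in bad] if subject_ids is not None
                 else [f"row {i}" for i in bad])
        raise ValueError(f"zero-variance subject rows: {', '.join(names)}")
    if method == "pearson":
        S = np.corrcoef(z)
    elif method == "spearman":
        ranks = stats.rankdata(z, axis=1)
        S = np.corrcoef(ranks)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    S = (S + S.T) / 2.0
    np.clip(S, -1.0, 1.0, out=S)
    return S


def _prepare_weights(S: np.ndarray, policy: str) -> tuple[np.ndarray, np.ndarray | None]:
    """Zero the diagonal and apply the negative-weight policy.

    Returns (W_pos, W_neg) where W_neg is None under clip_zero and the
    magnitude of negative weights under the signed policy.
    """
    W = np.array(S, dtype=float, copy=True)
    if W.shape[0] != W.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("similarity matrix must be symmetric")
    np.fill_diagonal(W, 0.0)
    if policy == "clip_zero":
        return np.where(W > 0, W, 0.0), None
    Wp = np.where(W > 0, W, 0.0)
    Wn = np.where(W < 0, -W, 0.0)
    return Wp, (Wn if Wn.any() else None)


def _q_component(W: np.ndarray, labels: np.ndarray, gamma: float) -> float:
    """Raw modularity sum Sum_ij [w_ij - gamma k_i k_j / 2m] delta(c_i, c_j).

    Not normalized by 2m; the caller applies the appropriate normalization.
    """
    two_m = W.sum()
    k = W.sum(axis=1)
    nc = labels.max() + 1
    w_in = 0.0
    comm_k = np.zeros(nc)
    for c in range(nc):
        idx = labels == c
        w_in += W[np.ix_(idx, idx)].sum()
        comm_k[c] = k[idx].sum()
    return w_in - gamma * (comm_k ** 2).sum() / two_m


def modularity(S: np.ndarray, labels: np.ndarray, gamma: float = 1.0,
               negative_weight_policy: str = "clip_zero") -> float:
    """Weighted Newman-Girvan modularity with resolution gamma.

    Q = (1/2m) Sum_ij [w_ij - gamma k_i k_j/(2m)] delta(c_i, c_j) with
    self-weights excluded. Under the signed policy an asymmetric
    positive/negative combination is used (Q+ down-weighted by Q- as in the
    signed-network formulation).
    """
    labels = _as_internal_labels(labels)
    Wp, Wn = _prepare_weights(S, negative_weight_policy)
    vp = Wp.sum()
    if Wn is None:
        if vp <= 0:
            raise ValueError("total edge weight is zero")
        return _q_component(Wp, labels, gamma) / vp
    vn = Wn.sum()
    if vp <= 0:
        raise ValueError("total positive edge weight is zero")
    qp = _q_component(Wp, labels, gamma) / vp
    qn = _q_component(Wn, labels, gamma) / vn
    return qp - vn / (vp + vn) * qn


def _as_internal_labels(labels: np.ndarray) -> np.ndarray:
    """Map arbitrary labels to contiguous 0-based integers."""
    labels = np.asarray(labels)
    _, out = np.unique(labels, return_inverse=True)
    return out.astype(np.int64)


def canonicalize_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters as 1..k by descending size (ties: first occurrence)."""
    labels = _as_internal_labels(labels)
    sizes = np.bincount(labels)
    first = np.zeros(sizes.size, dtype=np.int64)
    for c in range(sizes.size):
        first[c] = np.flatnonzero(labels == c)[0]
    order = sorted(range(sizes.size), key=lambda c: (-sizes[c], first[c]))
    remap = np.empty(sizes.size, dtype=np.int64)
    for new, old in enumerate(order):
        remap[old] = new + 1
    return remap[labels]


# ---------------------------------------------------------------------------
# Louvain core


def _move_nodes(Wp: np.ndarray, Wn: np.ndarray | None, gamma: float,
                rng: np.random.Generator, labels: np.ndarray | None = None
                ) -> tuple[np.ndarray, bool]:
    """Greedy single-node moves until no move improves modularity.

    Works on a (possibly aggregated) graph with self-loops on the diagonal:
    degrees and total weight include the diagonal, link weights to candidate
    communities exclude it (a self-loop is internal wherever the node goes).
    """
    n = Wp.shape[0]
    if labels is None:
        labels = np.arange(n, dtype=np.int64)
    else:
        labels = _as_internal_labels(labels)

    vp = Wp.sum()
    kp = Wp.sum(axis=1)
    Wp_off = Wp.copy()
    np.fill_diagonal(Wp_off, 0.0)
    totp = np.bincount(labels, weights=kp, minlength=n)

    signed = Wn is not None
    if signed:
        vn = Wn.sum()
        kn = Wn.sum(axis=1)
        Wn_off = Wn.copy()
        np.fill_diagonal(Wn_off, 0.0)
        totn = np.bincount(labels, weights=kn, minlength=n)
        alpha_n = 1.0 / (vp + vn) if (vp + vn) > 0 else 0.0
    alpha_p = 1.0 / vp if vp > 0 else 0.0

    any_moved = False
    while True:
        n_moves = 0
        for i in rng.permutation(n):
            ci = labels[i]
            totp[ci] -= kp[i]
            lw = np.bincount(labels, weights=Wp_off[i], minlength=n)
            gain = alpha_p * (lw - gamma * kp[i] * totp / vp)
            if signed:
                totn[ci] -= kn[i]
                lwn = np.bincount(labels, weights=Wn_off[i], minlength=n)
                gain = gain - alpha_n * (lwn - gamma * kn[i] * totn / vn)
            best = int(np.argmax(gain))
            if gain[best] <= gain[ci] + _MOVE_TOL:
                best = ci
            if best != ci:
                n_moves += 1
                any_moved = True
            labels[i] = best
            totp[best] += kp[i]
            if signed:
                totn[best] += kn[i]
        if n_moves == 0:
            break
    return _as_internal_labels(labels), any_moved


def _aggregate(W: np.ndarray, labels: np.ndarray) -> np.ndarray:
    nc = labels.max() + 1
    onehot = np.zeros((W.shape[0], nc))
    onehot[np.arange(W.shape[0]), labels] = 1.0
    return onehot.T @ W @ onehot


def _q_internal(Wp: np.ndarray, Wn: np.ndarray | None, labels: np.ndarray,
                gamma: float) -> float:
    vp = Wp.sum()
    q = _q_component(Wp, labels, gamma) / vp
    if Wn is not None:
        vn = Wn.sum()
        q -= vn / (vp + vn) * _q_component(Wn, labels, gamma) / vn
    return q


_N_PERTURB = 5
_PERTURB_FRAC = 0.1


def _louvain_labels(Wp: np.ndarray, Wn: np.ndarray | None, gamma: float,
                    rng: np.random.Generator) -> np.ndarray:
    n = Wp.shape[0]
    final = np.arange(n, dtype=np.int64)
    Ap, An = Wp, Wn
    while True:
        labels, moved = _move_nodes(Ap, An, gamma, rng)
        final = labels[final]
        if not moved or labels.max() + 1 == Ap.shape[0]:
            break
        Ap = _aggregate(Ap, labels)
        An = _aggregate(An, labels) if An is not None else None
    # polish at the original resolution, then escape shallow local optima by
    # perturbing a few node assignments and re-converging, keeping improvements
    final, _ = _move_nodes(Wp, Wn, gamma, rng, labels=final)
    q = _q_internal(Wp, Wn, final, gamma)
    n_kick = max(1, int(round(_PERTURB_FRAC * n)))
    # local optima are frequent on small dense graphs and rare on large
    # block-structured ones; scale the escape effort accordingly
    n_rounds = _N_PERTURB if n <= 32 else 1
    for _ in range(n_rounds):
        trial = final.copy()
        kicked = rng.choice(n, size=n_kick, replace=False)
        trial[kicked] = rng.integers(0, n, size=n_kick)
        trial, _ = _move_nodes(Wp, Wn, gamma, rng, labels=trial)
        q_trial = _q_internal(Wp, Wn, trial, gamma)
        if q_trial > q + _MOVE_TOL:
            final, q = trial, q_trial
    return final


def louvain(S: np.ndarray, gamma: float = 1.0, seed: int = 0,
            negative_weight_policy: str = "clip_zero") -> PartitionResult:
    """One seeded Louvain run on the similarity graph.

    Greedy local moves in shuffled node order, community aggregation, repeat
    until no move improves Q, then a final node-level refinement sweep.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    Wp, Wn = _prepare_weights(S, negative_weight_policy)
    if Wp.sum() <= 0:
        raise ValueError("total edge weight is zero")
    rng = np.random.default_rng(seed)
    labels = _louvain_labels(Wp, Wn, gamma, rng)
    labels = canonicalize_labels(labels)
    q = modularity(S, labels, gamma, negative_weight_policy)
    return PartitionResult(labels=labels, modularity=q, gamma=gamma, seed=seed)


# ---------------------------------------------------------------------------
# consensus


def _coassignment(partitions: list[np.ndarray]) -> np.ndarray:
    n = partitions[0].size
    D = np.zeros((n, n))
    for lab in partitions:
        D += lab[:, None] == lab[None, :]
    D /= len(partitions)
    return D


def _labels_from_binary(D: np.ndarray) -> np.ndarray:
    """Connected components of a binary-blocked co-assignment matrix."""
    n = D.shape[0]
    labels = -np.ones(n, dtype=np.int64)
    cur = 0
    for i in range(n):
        if labels[i] >= 0:
            continue
        stack = [i]
        labels[i] = cur
        while stack:
            j = stack.pop()
            for k in np.flatnonzero(D[j] > 0.5):
                if labels[k] < 0:
                    labels[k] = cur
                    stack.append(k)
        cur += 1
    return labels


def consensus_cluster(S: np.ndarray, config: ClusteringConfig,
                      keep_partitions: bool = False) -> ConsensusPartition:
    """Consensus community detection over seeded Louvain iterations.

    Runs ``n_iterations`` Louvain passes with distinct seeds, forms the
    co-assignment matrix of same-cluster fractions, thresholds it and
    re-clusters until the co-assignment matrix is binary-blocked.
    """
    Wp, Wn = _prepare_weights(S, config.negative_weight_policy)
    if Wp.sum() <= 0:
        raise ValueError("total edge weight is zero")
    ss = np.random.SeedSequence(config.seed)

    first_coassign = None
    archive: list[np.ndarray] | None = [] if keep_partitions else None
    Ap, An = Wp, Wn
    for rnd in range(1, config.max_consensus_rounds + 1):
        children = ss.spawn(config.n_iterations)
        parts = []
        for child in children:
            rng = np.random.default_rng(child)
            parts.append(_louvain_labels(Ap, An, config.gamma, rng))
        if rnd == 1 and keep_partitions:
            archive = [p.copy() for p in parts]
        D = _coassignment(parts)
        if rnd == 1:
            first_coassign = D.copy()
            np.fill_diagonal(first_coassign, 1.0)
        binary = np.abs(D - np.round(D)).max() < 1e-9
        if binary:
            labels = canonicalize_labels(_labels_from_binary(np.round(D)))
            return ConsensusPartition(
                labels=labels, coassignment=first_coassign, gamma=config.gamma,
                n_iterations=config.n_iterations, rounds=rnd,
                partitions=archive)
        Dt = np.where(D >= config.coassignment_threshold, D, 0.0)
        np.fill_diagonal(Dt, 0.0)
        if Dt.sum() <= 0:
            raise ConsensusError(
                "thresholded co-assignment matrix has no edges; lower the "
                f"threshold (currently {config.coassignment_threshold})")
        Ap, An = Dt, None
    raise ConsensusError(
        f"co-assignment matrix not binary after {config.max_consensus_rounds} "
        "rounds; the partition landscape may be degenerate")


def gamma_search(S: np.ndarray, target_k: int, grid: Sequence[float],
                 config: ClusteringConfig) -> tuple[float, ConsensusPartition]:
    """Smallest grid gamma whose consensus partition has exactly target_k clusters.

    The grid is scanned in ascending order; the scan stops at the first hit
    (community count is non-decreasing in gamma in practice, so the first hit
    is the smallest). Raises :class:`GammaSearchError` listing k(gamma) when
    no grid value achieves the target.
    """
    if target_k < 2:
        raise ValueError("target_k must be >= 2")
    if len(grid) == 0:
        raise ValueError("gamma grid is empty")
    n = S.shape[0]
    if target_k > n:
        raise GammaSearchError(
            f"target_k={target_k} exceeds the number of subjects ({n})")
    grid = sorted(float(g) for g in grid)
    k_by_gamma: dict[float, int] = {}
    for g in grid:
        cfg = ClusteringConfig(
            gamma=g, n_iterations=config.n_iterations,
            coassignment_threshold=config.coassignment_threshold,
            max_consensus_rounds=config.max_consensus_rounds,
            negative_weight_policy=config.negative_weight_policy,
            seed=config.seed)
        try:
            part = consensus_cluster(S, cfg)
        except ConsensusError as exc:
            warnings.warn(f"consensus failed at gamma={g}: {exc}")
            continue
        k_by_gamma[g] = part.n_clusters
        if part.n_clusters == target_k:
            return g, part
    raise GammaSearchError(
        f"no grid gamma produced k={target_k}; observed " +
        ", ".join(f"k({g:g})={k}" for g, k in k_by_gamma.items()),
        k_by_gamma)


def default_gamma_grid(start: float = 0.8, stop: float = 2.0,
                       step: float = 0.02) -> np.ndarray:
    """Ascending gamma grid; step matches the precision of typical reported values."""
    n = int(round((stop - start) / step)) + 1
    return np.round(start + step * np.arange(n), 10)
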