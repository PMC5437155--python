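"""Functional network connectivity (FNC) and graph analysis.

FNC is the Pearson correlation matrix among component time courses.
Community structure is detected with Newman's leading-eigenvector
bisection (with Kernighan-Lin style fine-tuning), generalized to
signed weights with the asymmetric positive/negative null-model
weighting: for total positive weight ``s+`` and negative weight
``s-``,

    Q* = Q+ - (s- / (s+ + s-)) Q-

which reduces to the classical Newman Q for all-positive matrices.
Weighted graph metrics (node strength, clustering coefficient, global
and local efficiency) follow the standard weighted definitions with
path lengths taken as the inverse of the connection weight.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.csgraph import shortest_path
from sklearn.metrics import adjusted_mutual_info_score

__all__ = [
    "fnc",
    "signed_modularity_matrix",
    "modularity_q",
    "modularity_partition",
    "ami",
    "threshold_sparsity",
    "graph_metrics",
]


def export_fnc_csv(F: np.ndarray, path, labels=None) -> None:
    """Write an FNC matrix to CSV (network labels as header/index)."""
    import pandas as pd

    n = F.shape[0]
    labels = list(labels) if labels is not None else list(range(n))
    pd.DataFrame(F, index=labels, columns=labels).to_csv(path)


def export_partition(partition: np.ndarray, path) -> None:
    """Write a community partition as a plain label file, one per line."""
    with open(path, "w") as fh:
        fh.write("\n".join(str(int(x)) for x in partition) + "\n")


def fnc(tcs: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of (T x N) time courses."""
    tcs = np.asarray(tcs, dtype=float)
    if tcs.shape[1] < 2:
        raise ValueError("need at least 2 networks")
    sd = tcs.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"network {bad} has a constant time course")
    return np.corrcoef(tcs.T)


def signed_modularity_matrix(W: np.ndarray) -> np.ndarray:
    """Normalized signed modularity matrix ``B*``.

    ``Q(partition) = sum over within-community (i, j) of B*_ij``
    implements the asymmetric signed extension; the diagonal of ``W``
    is ignored (self-connectivity is undefined for FNC).
    """
    W = np.asarray(W, dtype=float)
    W0 = W.copy()
    np.fill_diagonal(W0, 0.0)
    Wp = np.clip(W0, 0.0, None)
    Wn = -np.clip(W0, None, 0.0)
    sp = Wp.sum()
    sn = Wn.sum()
    B = np.zeros_like(W0)
    if sp > 0:
        kp = Wp.sum(axis=1)
        B += (Wp - np.outer(kp, kp) / sp) / sp
    if sn > 0:
        kn = Wn.sum(axis=1)
        B -= (Wn - np.outer(kn, kn) / sn) / (sp + sn)
    return B


def modularity_q(W: np.ndarray, partition: np.ndarray) -> float:
    """Signed modularity Q of a partition (labels per node)."""
    B = signed_modularity_matrix(W)
    labels = np.asarray(partition)
    same = labels[:, None] == labels[None, :]
    return float(B[same].sum())


def _fine_tune(Bg: np.ndarray, s: np.ndarray) -> np.ndarray:
    # Greedy single-node sign flips while they increase s' Bg s.
    s = s.copy()
    while True:
        gains = -4.0 * s * (Bg @ s) + 4.0 * np.diag(Bg)
        best = int(np.argmax(gains))
        if gains[best] <= 1e-12:
            return s
        s[best] = -s[best]


def modularity_partition(W: np.ndarray) -> tuple[np.ndarray, float]:
    """Newman leading-eigenvector community detection on signed weights.

    Recursive spectral bisection with fine-tuning, stopping when no
    split yields a positive modularity gain.  Returns contiguous
    labels starting at 1 and the signed Q of the final partition.
    Deterministic; an all-zero matrix yields a single community with
    Q = 0.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    B = signed_modularity_matrix(W)
    labels = np.zeros(n, dtype=int)
    next_label = [1]

    def divide(nodes: np.ndarray) -> None:
        if nodes.size == 1:
            labels[nodes] = next_label[0]
            next_label[0] += 1
            return
        Bsub = B[np.ix_(nodes, nodes)]
        Bg = Bsub - np.diag(Bsub.sum(axis=1))
        evals, evecs = np.linalg.eigh(Bg)
        lead = evecs[:, -1]
        s = np.where(lead >= 0, 1.0, -1.0)
        s = _fine_tune(Bg, s)
        dq = 0.5 * s @ Bg @ s
        if dq <= 1e-12 or np.all(s > 0) or np.all(s < 0):
            labels[nodes] = next_label[0]
            next_label[0] += 1
            return
        divide(nodes[s > 0])
        divide(nodes[s < 0])

    divide(np.arange(n))
    q = modularity_q(W, labels)
    return labels, float(q)


def ami(p: np.ndarray, q: np.ndarray) -> float:
    """Adjusted mutual information between two partitions.

    Chance-corrected under the permutation model with max
    normalization; 1 for identical partitions up to relabeling, ~0 in
    expectation for independent partitions.
    """
    p = np.asarray(p)
    q = np.asarray(q)
    if p.shape != q.shape:
        raise ValueError("partitions must cover the same nodes")
    # Symmetrize: the underlying computation is symmetric only up to
    # floating-point association order.
    return float(
        0.5 * adjusted_mutual_info_score(p, q, average_method="max")
        + 0.5 * adjusted_mutual_info_score(q, p, average_method="max")
    )


def threshold_sparsity(W: np.ndarray, sparsity: float = 0.5) -> np.ndarray:
    """Keep the strongest off-diagonal connections by absolute value.

    Absolute values are taken, then the top ``sparsity`` fraction of
    off-diagonal pairs by magnitude is kept and the rest zeroed; ties
    at the cutoff are all kept.  Output is symmetric with zero
    diagonal.
    """
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must be in (0, 1]")
    W = np.abs(np.asarray(W, dtype=float))
    np.fill_diagonal(W, 0.0)
    n = W.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = W[iu]
    keep = int(np.ceil(sparsity * vals.size))
    if keep >= vals.size:
        return W
    cutoff = np.sort(vals)[::-1][keep - 1]
    out = np.where(W >= cutoff, W, 0.0)
    np.fill_diagonal(out, 0.0)
    return out


def _shortest_lengths(W: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / W, np.inf)
    np.fill_diagonal(L, 0.0)
    return shortest_path(L, method="D", directed=False)


def graph_metrics(W: np.ndarray) -> dict:
    """Node-averaged weighted graph metrics of a non-negative matrix.

    ``node_strength``: mean row sum.  ``clustering``: mean weighted
    clustering coefficient (geometric-mean triangle formula on weights
    scaled by the maximum).  ``global_eff``: mean inverse shortest
    path length over node pairs (lengths = 1/weight; unreachable
    pairs contribute 0).  ``local_eff``: mean nodal efficiency of each
    node's neighbor subgraph weighted by the cube root of the
    connecting weights.
    """
    W = np.asarray(W, dtype=float)
    if (W < 0).any():
        raise ValueError("graph_metrics expects non-negative weights")
    n = W.shape[0]
    strength = W.sum(axis=1)

    A = (W > 0).astype(float)
    k = A.sum(axis=1)
    wmax = W.max()
    What = (W / wmax) ** (1.0 / 3.0) if wmax > 0 else W
    tri = np.diag(What @ What @ What)
    denom = k * (k - 1)
    clustering = np.where(denom > 0, tri / np.where(denom > 0, denom, 1), 0.0)

    d = _shortest_lengths(W)
    with np.errstate(divide="ignore"):
        dinv = np.where(d > 0, 1.0 / d, 0.0)
    dinv[~np.isfinite(d)] = 0.0
    np.fill_diagonal(dinv, 0.0)
    global_eff = dinv.sum() / (n * (n - 1)) if n > 1 else 0.0

    local = np.zeros(n)
    for u in range(n):
        nb = np.flatnonzero(W[u] > 0)
        ku = nb.size
        if ku < 2:
            continue
        dsub = _shortest_lengths(W[np.ix_(nb, nb)])
        with np.errstate(divide="ignore"):
            dsub_inv = np.where(dsub > 0, 1.0 / dsub, 0.0)
        dsub_inv[~np.isfinite(dsub)] = 0.0
        np.fill_diagonal(dsub_inv, 0.0)
        w_u = W[u, nb]
        terms = (np.outer(w_u, w_u) * dsub_inv) ** (1.0 / 3.0)
        local[u] = terms.sum() / (ku * (ku - 1))

    return {
        "node_strength": float(strength.mean()),
        "clustering": float(clustering.mean()),
        "global_eff": float(global_eff),
        "local_eff": float(local.mean()),
    }
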