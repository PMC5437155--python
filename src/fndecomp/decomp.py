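"""PCA reduction, whitening, Infomax ICA, and group ICA.

These are the shared linear-algebra stages of both multi-subject
methods: subject-level PCA (for IVA-GL and GIG-ICA) and group-level
PCA + Infomax on temporally concatenated reduced data (for GIG-ICA's
first stage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from fndecomp.datatypes import SubjectDataset

__all__ = [
    "ReducedData",
    "GroupICAResult",
    "pca_reduce",
    "whiten_spatial",
    "infomax",
    "group_ica",
    "zscore_maps",
]


@dataclass
class ReducedData:
    """Whitened PCA reduction of a (time x voxel) data matrix.

    ``reduced`` (k x V) has uncorrelated unit-variance rows;
    ``dewhitening @ reduced`` reconstructs the centered data within the
    retained subspace.
    """

    reduced: np.ndarray
    whitening: np.ndarray
    dewhitening: np.ndarray
    retained_variance: float
    eigenvalues: np.ndarray = field(default=None)


def pca_reduce(data: np.ndarray | SubjectDataset, k: int) -> ReducedData:
    """Reduce a (T x V) matrix to its top-k whitened temporal components.

    Each voxel's temporal mean is removed, the T x T temporal
    covariance is eigendecomposed, and the top-k eigendirections are
    kept and scaled to unit variance (voxels as samples).

    Raises
    ------
    ValueError
        If ``k`` exceeds the numerical rank of the data.
    """
    if isinstance(data, SubjectDataset):
        data = data.data
    data = np.asarray(data, dtype=float)
    T, V = data.shape
    X = data - data.mean(axis=0)
    cov = X @ X.T / V
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(T, V) * np.finfo(float).eps * max(evals.max(), 0.0)
    rank = int(np.sum(evals > tol))
    if k > rank:
        raise ValueError(f"k={k} exceeds the data rank ({rank})")
    lam = evals[:k]
    E = evecs[:, :k]
    whitening = (E / np.sqrt(lam)).T
    dewhitening = E * np.sqrt(lam)
    reduced = whitening @ X
    retained = float(lam.sum() / evals.sum()) if evals.sum() > 0 else 1.0
    return ReducedData(
        reduced=reduced,
        whitening=whitening,
        dewhitening=dewhitening,
        retained_variance=retained,
        eigenvalues=evals,
    )


def whiten_spatial(
    data: np.ndarray | SubjectDataset, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """PCA-reduce and re-whiten with spatially centered rows.

    Returns ``(X, back)`` where ``X`` (k x V) has rows with exactly
    zero mean, unit variance and identity sample covariance over
    voxels, and ``back`` (T x k) maps component space back to the
    centered data space (``back @ X`` reconstructs the retained
    subspace up to the removed row means, which are negligible for
    mean-removed fMRI-like data).

    With this normalization, any unit-norm combination ``w @ X`` is an
    exactly standardized spatial map, which the reference-guided and
    IVA updates rely on.
    """
    rd = pca_reduce(data, k)
    X0 = rd.reduced
    mu = X0.mean(axis=1, keepdims=True)
    Xc = X0 - mu
    V = X0.shape[1]
    cov = Xc @ Xc.T / V
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 1e-12, None)
    Cw = (evecs / np.sqrt(evals)) @ evecs.T  # symmetric whitener
    X = Cw @ Xc
    back = rd.dewhitening @ np.linalg.inv(Cw)
    return X, back


def _infomax_loglik(W: np.ndarray, u: np.ndarray) -> float:
    # Mean log-likelihood under the logistic prior: log|det W| +
    # mean over samples of sum_i log g'(u_i), g'(u) = y(1-y) for the
    # logistic sigmoid; log g'(u) = -u - 2*log(1+exp(-u)).
    sign, logdet = np.linalg.slogdet(W)
    if sign <= 0:
        return -np.inf
    log_gprime = -u - 2.0 * np.logaddexp(0.0, -u)
    return float(logdet + log_gprime.sum(axis=0).mean())


def infomax(
    whitened: np.ndarray,
    seed: int = 0,
    *,
    lrate: float | None = None,
    max_iter: int = 2048,
    tol: float = 1e-6,
    anneal: float = 0.9,
    blowup: float = 1e9,
) -> np.ndarray:
    """Natural-gradient Infomax ICA with a logistic nonlinearity.

    Operates full-batch on whitened data (k x V, unit-variance
    uncorrelated rows) and returns the (k x k) unmixing matrix such
    that ``components = unmixing @ whitened``.  The learning rate
    defaults to ``0.1 / ln(k)`` (the classical per-block rate
    ``0.015 / ln(k)`` scaled for full-batch updates) and is annealed
    (x ``anneal``) on a weight blow-up, restarting from the last
    stable iterate.
    Convergence is declared when the relative weight change drops
    below ``tol``; non-convergence issues a warning and returns the
    best iterate.
    """
    X = np.asarray(whitened, dtype=float)
    k, V = X.shape
    if lrate is None:
        lrate = 0.1 / np.log(k) if k > 1 else 0.05
    rng = np.random.default_rng(seed)
    W, _ = np.linalg.qr(rng.standard_normal((k, k)))
    eye = np.eye(k)
    last_good = W.copy()
    converged = False
    for _ in range(max_iter):
        u = W @ X
        y = 1.0 / (1.0 + np.exp(-u))
        grad = (eye + (1.0 - 2.0 * y) @ u.T / V) @ W
        step = lrate * grad
        change = np.abs(step).max()
        if not np.isfinite(change) or change > blowup:
            lrate *= anneal
            W = last_good.copy()
            continue
        last_good = W.copy()
        W = W + step
        if change / max(np.abs(W).max(), 1e-12) < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            "Infomax did not reach the weight-change tolerance; "
            "returning the final iterate",
            RuntimeWarning,
        )
    return W


def zscore_maps(maps: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Z-score each row over (in-mask) voxels: zero mean, unit SD."""
    maps = np.array(maps, dtype=float)
    sel = slice(None) if mask is None else mask
    sub = maps[:, sel]
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (maps - mu) / sd


@dataclass
class GroupICAResult:
    """Group-level ICs from temporally concatenated reduced data.

    ``group_maps`` (G2 x V) are z-scored over in-mask voxels;
    ``group_mixing`` ((M*G1) x G2) maps the group components back to
    the concatenated reduced space.
    """

    group_maps: np.ndarray
    group_mixing: np.ndarray
    subject_reductions: list[ReducedData] = field(default_factory=list)


def group_ica(
    datasets: list[SubjectDataset] | list[np.ndarray],
    G1: int,
    G2: int,
    seed: int = 0,
    *,
    infomax_kwargs: dict | None = None,
) -> GroupICAResult:
    """Temporal-concatenation group ICA.

    Subject-level PCA to ``G1`` per subject, concatenation along the
    reduced-time dimension, group-level PCA to ``G2``, then Infomax.
    Group maps are sign-aligned so that each map's skewness is
    positive, and z-scored.
    """
    if G2 > G1:
        raise ValueError(f"G2={G2} must not exceed G1={G1}")
    arrays = [d.data if isinstance(d, SubjectDataset) else d for d in datasets]
    V = arrays[0].shape[1]
    for i, a in enumerate(arrays):
        if a.shape[1] != V:
            raise ValueError(
                f"dataset {i} has {a.shape[1]} voxels, expected {V}"
            )
    reductions = [pca_reduce(a, G1) for a in arrays]
    concat = np.vstack([r.reduced for r in reductions])
    Xg, back = whiten_spatial(concat, G2)
    W = infomax(Xg, seed=seed, **(infomax_kwargs or {}))
    maps = W @ Xg
    # Positive-skewness sign convention keeps matching deterministic.
    skew = ((maps - maps.mean(axis=1, keepdims=True)) ** 3).mean(axis=1)
    flip = np.where(skew < 0, -1.0, 1.0)
    maps = maps * flip[:, None]
    mixing = back @ np.linalg.inv(W) * flip[None, :]
    return GroupICAResult(
        group_maps=zscore_maps(maps),
        group_mixing=mixing,
        subject_reductions=reductions,
    )
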