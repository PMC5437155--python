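"""Independent vector analysis: IVA-G, IVA-L and the IVA-GL pipeline.

IVA jointly decomposes M subjects' whitened datasets, maximizing
independence of components within each subject while maximizing the
dependence within each source component vector (SCV) — the set of
corresponding components across subjects.  IVA-G models each SCV as
multivariate Gaussian (its cost depends only on second-order
cross-subject statistics); IVA-L models SCVs as multivariate Laplace
(a super-Gaussian model matched to spatial fMRI sources).  IVA-GL runs
IVA-G to convergence and refines with IVA-L warm-started from it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from fndecomp.datatypes import DecompositionResults, SubjectDataset
from fndecomp.decomp import whiten_spatial, zscore_maps

__all__ = ["IVAState", "iva_g", "iva_l", "iva_gl", "joint_isi", "IVAGL"]

logger = logging.getLogger(__name__)


@dataclass
class IVAState:
    """State of an IVA optimization.

    ``unmixing[m]`` is subject m's (I1 x I1) unmixing matrix;
    ``cost_trace`` the accepted cost values (non-increasing);
    ``converged`` whether the weight-change tolerance was met.
    """

    unmixing: np.ndarray  # (M, I1, I1)
    cost_trace: list[float]
    converged: bool


def _as_stack(reduced: list[np.ndarray]) -> np.ndarray:
    X = np.asarray(reduced, dtype=float)
    if X.ndim != 3:
        raise ValueError("reduced must be a list of (I1 x V) matrices")
    return X


def _scv_covs(W: np.ndarray, R: np.ndarray) -> np.ndarray:
    # S[c] = M x M covariance of component c across subjects.
    # R[m, n] = X_m X_n' / V;  S[c, m, n] = w_mc' R[m,n] w_nc.
    return np.einsum("mci,mnij,ncj->cmn", W, R, W, optimize=True)


def _iva_g_cost(W: np.ndarray, R: np.ndarray, ridge: float = 0.0) -> float:
    M = W.shape[0]
    S = _scv_covs(W, R)
    if ridge:
        S = S + ridge * np.eye(M)[None]
    sign, logdet = np.linalg.slogdet(S)
    if np.any(sign <= 0):
        return np.inf
    cost = 0.5 * logdet.sum()
    for m in range(M):
        s, ld = np.linalg.slogdet(W[m])
        if s == 0:
            return np.inf
        cost -= ld
    return float(cost)


def _polish_permutations(
    W: np.ndarray, cost_fn, cost: float
) -> tuple[np.ndarray, float, bool]:
    """Escape permutation local optima by within-subject row swaps.

    Gradient steps cannot cross the discrete barrier between two
    solutions that differ by swapping a subject's component rows, yet
    such swaps change how components group into SCVs (and hence the
    cost).  Greedily applies the best cost-lowering swap until none
    remains; the overall cost stays monotone.
    """
    M, I1, _ = W.shape
    changed = False
    while True:
        best = None
        for m in range(M):
            for c1 in range(I1):
                for c2 in range(c1 + 1, I1):
                    W_try = W.copy()
                    W_try[m, [c1, c2]] = W_try[m, [c2, c1]]
                    c_try = cost_fn(W_try)
                    if c_try < cost - 1e-10 and (
                        best is None or c_try < best[0]
                    ):
                        best = (c_try, W_try)
        if best is None:
            return W, cost, changed
        cost, W = best
        changed = True


def _realign_scvs(W: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Candidate global permutation realignment of SCV indices.

    Permutes each subject's component rows so that corresponding
    components line up across subjects by spatial-map correlation
    (greedy matching against running centroid maps).  This proposes a
    jump between permutation basins that neither gradient steps nor
    single swaps can cross; callers accept it only when it lowers the
    IVA cost.
    """
    from fndecomp.evaluate import greedy_match

    M, I1, _ = W.shape
    V = X.shape[2]
    maps = []
    for m in range(M):
        Y = W[m] @ X[m]
        Y = Y - Y.mean(axis=1, keepdims=True)
        Y = Y / np.linalg.norm(Y, axis=1, keepdims=True)
        maps.append(Y)
    W_new = W.copy()
    centroid = maps[0].copy()
    count = 1
    for m in range(1, M):
        sim = np.abs(maps[m] @ centroid.T)
        perm = np.empty(I1, dtype=int)
        for e, t, _ in greedy_match(sim).pairs:
            perm[t] = e
        W_new[m] = W[m][perm]
        aligned = maps[m][perm]
        sign = np.sign(np.einsum("ij,ij->i", aligned, centroid))
        sign[sign == 0] = 1.0
        centroid = centroid * count + aligned * sign[:, None]
        centroid /= np.linalg.norm(centroid, axis=1, keepdims=True)
        count += 1
    return W_new


def iva_g(
    reduced: list[np.ndarray],
    seed: int = 0,
    *,
    step: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 1024,
) -> IVAState:
    """IVA with a multivariate-Gaussian SCV model.

    Minimizes ``sum_c 0.5 log det Sigma_c - sum_m log |det W_m|``
    (Sigma_c the cross-subject covariance of component c) by gradient
    descent with step halving on cost increase, starting from identity
    unmixing (the data are whitened).  The cost depends on the data
    only through the pairwise cross-covariance blocks, which are
    precomputed once.  A singular SCV covariance gets a small ridge
    (logged).
    """
    X = _as_stack(reduced)
    M, I1, V = X.shape
    R = np.einsum("miv,njv->mnij", X, X, optimize=True) / V
    W = np.broadcast_to(np.eye(I1), (M, I1, I1)).copy()
    if step is None:
        step = 0.1 / I1
    ridge = 0.0
    cost = _iva_g_cost(W, R)
    if not np.isfinite(cost):
        ridge = 1e-10
        logger.info("iva_g: singular SCV covariance at start; ridge added")
        cost = _iva_g_cost(W, R, ridge)
    trace = [cost]
    converged = False
    eyeM = np.eye(M)
    iters = 0
    while iters < max_iter:
        stalled = False
        while iters < max_iter:
            iters += 1
            S = _scv_covs(W, R)
            if ridge:
                S = S + ridge * eyeM[None]
            try:
                Sinv = np.linalg.inv(S)
            except np.linalg.LinAlgError:
                ridge = max(ridge * 10.0, 1e-10)
                logger.info("iva_g: singular SCV covariance; ridge -> %g", ridge)
                continue
            # grad wrt row c of W_m: sum_n Sinv[c,m,n] R[m,n] w_nc - (W_m^-T)_c
            T1 = np.einsum("mnij,ncj->mnci", R, W, optimize=True)
            grad = np.einsum("cmn,mnci->mci", Sinv, T1, optimize=True)
            grad -= np.transpose(np.linalg.inv(W), (0, 2, 1))
            accepted = False
            s = step
            while s > 1e-14:
                W_new = W - s * grad
                c_new = _iva_g_cost(W_new, R, ridge)
                if c_new <= cost + 1e-12:
                    change = np.abs(W_new - W).max()
                    W = W_new
                    if c_new < cost:
                        trace.append(c_new)
                    cost = c_new
                    accepted = True
                    if change < tol:
                        converged = True
                    break
                s *= 0.5
            if not accepted:
                stalled = True
            if stalled or converged:
                break
        def cost_fn(w, _ridge=ridge):
            return _iva_g_cost(w, R, _ridge)

        moved = False
        W_cand = _realign_scvs(W, X)
        c_cand = cost_fn(W_cand)
        if c_cand < cost - 1e-10:
            W, cost, moved = W_cand, c_cand, True
            trace.append(cost)
        W, cost, swapped = _polish_permutations(W, cost_fn, cost)
        if swapped:
            trace.append(cost)
        if moved or swapped:
            converged = False
        else:
            converged = converged or stalled
            break
    return IVAState(unmixing=W, cost_trace=trace, converged=converged)


def _iva_l_cost(W: np.ndarray, X: np.ndarray) -> float:
    M, I1, V = X.shape
    Y = np.einsum("mij,mjv->miv", W, X, optimize=True)
    norms = np.sqrt((Y**2).sum(axis=0))  # (I1, V)
    cost = norms.mean(axis=1).sum()
    for m in range(M):
        s, ld = np.linalg.slogdet(W[m])
        if s == 0:
            return np.inf
        cost -= ld
    return float(cost)


def iva_l(
    reduced: list[np.ndarray],
    init: IVAState | None = None,
    seed: int = 0,
    *,
    step: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 1024,
) -> IVAState:
    """IVA with a multivariate-Laplace SCV model.

    Natural-gradient updates with the score ``phi(y_m) = y_m /
    ||y_SCV||_2`` (the component's L2 norm taken across subjects),
    step halving on cost increase.  Warm-startable from an
    :class:`IVAState` (typically the IVA-G solution).
    """
    X = _as_stack(reduced)
    M, I1, V = X.shape
    W = (
        init.unmixing.copy()
        if init is not None
        else np.broadcast_to(np.eye(I1), (M, I1, I1)).copy()
    )
    if step is None:
        step = 0.1 / I1
    eps = 1e-12
    eye = np.eye(I1)
    cost = _iva_l_cost(W, X)
    trace = [cost]
    converged = False
    iters = 0
    while iters < max_iter:
        stalled = False
        while iters < max_iter:
            iters += 1
            Y = np.einsum("mij,mjv->miv", W, X, optimize=True)
            norms = np.sqrt((Y**2).sum(axis=0)) + eps
            phi = Y / norms[None]
            G = eye[None] - np.einsum("miv,mjv->mij", phi, Y, optimize=True) / V
            delta = np.einsum("mij,mjk->mik", G, W, optimize=True)
            accepted = False
            s = step
            while s > 1e-14:
                W_new = W + s * delta
                c_new = _iva_l_cost(W_new, X)
                if c_new <= cost + 1e-12:
                    change = np.abs(W_new - W).max()
                    W = W_new
                    if c_new < cost:
                        trace.append(c_new)
                    cost = c_new
                    accepted = True
                    if change < tol:
                        converged = True
                    break
                s *= 0.5
            if not accepted:
                stalled = True
            if stalled or converged:
                break
        def cost_fn(w):
            return _iva_l_cost(w, X)

        moved = False
        W_cand = _realign_scvs(W, X)
        c_cand = cost_fn(W_cand)
        if c_cand < cost - 1e-10:
            W, cost, moved = W_cand, c_cand, True
            trace.append(cost)
        W, cost, swapped = _polish_permutations(W, cost_fn, cost)
        if swapped:
            trace.append(cost)
        if moved or swapped:
            converged = False
        else:
            converged = converged or stalled
            break
    return IVAState(unmixing=W, cost_trace=trace, converged=converged)


def joint_isi(unmixing: np.ndarray, mixing: np.ndarray) -> float:
    """Joint inter-symbol interference of an IVA solution.

    Averages ``|W_m A_m|`` over subjects and measures the distance of
    the result from a scaled permutation; 0 means perfect separation,
    values near 1 mean none.
    """
    W = np.asarray(unmixing, dtype=float)
    A = np.asarray(mixing, dtype=float)
    if W.ndim == 2:
        W, A = W[None], A[None]
    G = np.abs(np.einsum("mij,mjk->mik", W, A)).mean(axis=0)
    N = G.shape[0]
    rows = (G.sum(axis=1) / G.max(axis=1) - 1.0).sum()
    cols = (G.sum(axis=0) / G.max(axis=0) - 1.0).sum()
    return float((rows + cols) / (2.0 * N * (N - 1)))


def iva_gl(
    datasets: list[SubjectDataset] | list[np.ndarray],
    I1: int,
    seed: int = 0,
    *,
    tol: float = 1e-6,
    max_iter_g: int = 16384,
    max_iter_l: int = 1024,
) -> DecompositionResults:
    """Full IVA-GL pipeline on raw multi-subject data.

    Subject-level PCA/whitening to ``I1``, IVA-G to convergence,
    IVA-L warm-started from it; per-subject maps are z-scored and time
    courses recovered through each subject's PCA dewhitening and the
    unmixing inverse, then standardized.  Components are aligned
    across subjects by SCV index.
    """
    arrays = [d.data if isinstance(d, SubjectDataset) else d for d in datasets]
    V = arrays[0].shape[1]
    for i, a in enumerate(arrays):
        if a.shape[1] != V:
            raise ValueError(f"dataset {i} has {a.shape[1]} voxels, expected {V}")
    whitened, backs = [], []
    for a in arrays:
        X, back = whiten_spatial(a, I1)
        whitened.append(X)
        backs.append(back)
    state_g = iva_g(whitened, seed=seed, tol=tol, max_iter=max_iter_g)
    state = iva_l(whitened, init=state_g, seed=seed, tol=tol, max_iter=max_iter_l)
    if not state.converged:
        warnings.warn("IVA-L did not converge within max_iter", RuntimeWarning)
    subject_maps, subject_tcs = [], []
    for m, X in enumerate(whitened):
        W = state.unmixing[m]
        maps = W @ X
        # Positive-skewness sign convention, applied consistently to
        # maps and time courses.
        skew = ((maps - maps.mean(axis=1, keepdims=True)) ** 3).mean(axis=1)
        flip = np.where(skew < 0, -1.0, 1.0)
        maps = zscore_maps(maps * flip[:, None])
        tcs = backs[m] @ np.linalg.inv(W) * flip[None, :]
        tcs = tcs - tcs.mean(axis=0)
        sd = tcs.std(axis=0)
        sd[sd == 0] = 1.0
        subject_maps.append(maps)
        subject_tcs.append(tcs / sd)
    group_maps = np.mean(subject_maps, axis=0)
    return DecompositionResults(
        method="iva_gl",
        n_components=I1,
        subject_maps=subject_maps,
        subject_tcs=subject_tcs,
        group_maps=group_maps,
        diagnostics={
            "converged": bool(state_g.converged and state.converged),
            "n_iterations": len(state_g.cost_trace) + len(state.cost_trace),
            "final_cost": state.cost_trace[-1],
            "iva_g_cost_trace": state_g.cost_trace,
            "iva_l_cost_trace": state.cost_trace,
        },
    )


@dataclass
class IVAGLResults(DecompositionResults):
    """IVA-GL fit results (alias carrying the standard fields)."""


class IVAGL:
    """IVA-GL model for multi-subject data.

    Parameters
    ----------
    datasets : list of SubjectDataset or (T x V) arrays
    n_components : int
        Model order I1 used for the subject-level PCAs.

    ``fit(seed)`` runs a single seeded IVA-G + IVA-L pass and returns
    a :class:`fndecomp.datatypes.DecompositionResults`.
    """

    def __init__(
        self,
        datasets: list,
        n_components: int,
        *,
        tol: float = 1e-6,
        max_iter_g: int = 16384,
        max_iter_l: int = 1024,
    ) -> None:
        if n_components < 2:
            raise ValueError("n_components must be >= 2")
        self.datasets = datasets
        self.n_components = n_components
        self.tol = tol
        self.max_iter_g = max_iter_g
        self.max_iter_l = max_iter_l

    def fit(self, seed: int = 0) -> DecompositionResults:
        return iva_gl(
            self.datasets,
            self.n_components,
            seed=seed,
            tol=self.tol,
            max_iter_g=self.max_iter_g,
            max_iter_l=self.max_iter_l,
        )
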