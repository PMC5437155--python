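"""Test-retest reliability machinery.

One-sample t maps with Benjamini-Hochberg FDR masks, and intraclass
correlation (ICC) from a one-way ANOVA with subjects as groups and
k = 2 repeated observations:

    ICC = sigma_p^2 / (sigma_p^2 + sigma_e^2)

with ``sigma_p^2 = max(0, (MSB - MSW)/2)`` the inter-subject variance
and ``sigma_e^2 = MSW`` the error variance.  Negative variance
components are clamped to zero, so ICC lies in [0, 1].  Short-term
reliability compares scan 2 with scan 3; long-term reliability
compares scan 1 with the average of scans 2 and 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ICCResult",
    "one_sample_t_fdr",
    "icc_oneway",
    "icc_oneway_vec",
    "network_reliability",
    "connectivity_icc",
]

logger = logging.getLogger(__name__)


@dataclass
class ICCResult:
    icc: float
    sigma_p2: float
    sigma_e2: float


def one_sample_t_fdr(
    maps: np.ndarray, q: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-wise right-tailed one-sample t-test with BH-FDR mask.

    ``maps`` is (n_datasets x V).  Returns the t map and the boolean
    mask of voxels surviving Benjamini-Hochberg correction at level
    ``q``.  Zero-variance voxels get p = 1 (logged).
    """
    maps = np.asarray(maps, dtype=float)
    if maps.shape[0] < 2:
        raise ValueError("need at least 2 datasets")
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        logger.info("one_sample_t_fdr: %d zero-variance voxels get p=1", zero.sum())
    sd_safe = np.where(zero, 1.0, sd)
    t = mean / (sd_safe / np.sqrt(n))
    t[zero] = 0.0
    p = stats.t.sf(t, df=n - 1)
    p[zero] = 1.0
    mask = multipletests(p, alpha=q, method="fdr_bh")[0]
    return t, mask


def icc_oneway_vec(
    x1: np.ndarray, x2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized one-way ICC over columns of paired (n x m) arrays.

    Returns ``(icc, sigma_p2, sigma_e2)`` arrays of length m.
    """
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    if x1.shape != x2.shape:
        raise ValueError("x1 and x2 must have the same shape")
    n = x1.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    subj_mean = (x1 + x2) / 2.0
    grand = subj_mean.mean(axis=0)
    # k = 2 observations per subject.
    ssb = 2.0 * ((subj_mean - grand) ** 2).sum(axis=0)
    msb = ssb / (n - 1)
    ssw = ((x1 - subj_mean) ** 2 + (x2 - subj_mean) ** 2).sum(axis=0)
    msw = ssw / n  # df = n*(k-1) = n
    sigma_p2 = np.maximum(0.0, (msb - msw) / 2.0)
    sigma_e2 = msw
    # A column that is exactly constant (same value for every subject
    # and scan) has no inter-subject effect: ICC 0, not 0/0 round-off.
    degenerate = (
        (np.ptp(x1, axis=0) == 0)
        & (np.ptp(x2, axis=0) == 0)
        & (x1[0] == x2[0])
    )
    denom = sigma_p2 + sigma_e2
    safe = (denom > 0) & ~degenerate
    icc = np.where(safe, sigma_p2 / np.where(denom > 0, denom, 1.0), 0.0)
    return icc, sigma_p2, sigma_e2


def icc_oneway(x1: np.ndarray, x2: np.ndarray) -> ICCResult:
    """One-way ANOVA ICC of two paired observation vectors."""
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    icc, sp2, se2 = icc_oneway_vec(x1[:, None], x2[:, None])
    return ICCResult(icc=float(icc[0]), sigma_p2=float(sp2[0]), sigma_e2=float(se2[0]))


def network_reliability(
    maps_by_scan: list[np.ndarray] | dict,
    mask: np.ndarray,
    mode: str = "short",
) -> float:
    """Mean voxel-wise ICC of one network's maps across scans.

    ``maps_by_scan`` holds one (n_subjects x V) stack per scan
    (ordered scan 1, 2, 3; a dict keyed 1..3 is also accepted), with
    subjects aligned across scans.  ``mode='short'`` compares scan 2
    with scan 3; ``mode='long'`` compares scan 1 with the mean of
    scans 2 and 3.  The per-voxel ICCs are averaged inside ``mask``.
    """
    if isinstance(maps_by_scan, dict):
        scans = [np.asarray(maps_by_scan[k], dtype=float) for k in sorted(maps_by_scan)]
    else:
        scans = [np.asarray(s, dtype=float) for s in maps_by_scan]
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if mode == "short":
        a, b = scans[1], scans[2]
    elif mode == "long":
        a, b = scans[0], (scans[1] + scans[2]) / 2.0
    else:
        raise ValueError("mode must be 'short' or 'long'")
    icc, _, _ = icc_oneway_vec(a[:, mask], b[:, mask])
    return float(icc.mean())


def connectivity_icc(
    fnc_by_scan: list[np.ndarray] | dict, mode: str = "short"
) -> np.ndarray:
    """Element-wise ICC of connectivity strengths across scans.

    ``fnc_by_scan`` holds one (n_subjects x E) stack of vectorized
    connectivity values per scan (ordered scan 1, 2, 3).  Returns the
    length-E vector of ICCs, with the same short/long scan pairing as
    :func:`network_reliability`.
    """
    if isinstance(fnc_by_scan, dict):
        scans = [np.asarray(fnc_by_scan[k], dtype=float) for k in sorted(fnc_by_scan)]
    else:
        scans = [np.asarray(s, dtype=float) for s in fnc_by_scan]
    if mode == "short":
        a, b = scans[1], scans[2]
    elif mode == "long":
        a, b = scans[0], (scans[1] + scans[2]) / 2.0
    else:
        raise ValueError("mode must be 'short' or 'long'")
    icc, _, _ = icc_oneway_vec(a, b)
    return icc
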