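"""Component/template matching and simulation accuracy statistics.

Estimated components are matched to ground-truth templates with a
greedy rule: repeatedly pick the globally largest remaining similarity,
record the pair, and delete its row and column (ties broken by the
smallest (row, column) index).  Accuracy is the absolute Pearson
correlation between an estimate and its matched truth; method
comparisons use two-tailed paired t-tests with Bonferroni correction
across the settings of an experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from fndecomp.datatypes import DecompositionResults, GroundTruth

__all__ = [
    "MatchTable",
    "AccuracyTable",
    "greedy_match",
    "accuracy",
    "paired_ttest",
    "bonferroni",
    "build_templates",
    "score_method",
    "score_experiment",
    "ExperimentScore",
]


@dataclass
class MatchTable:
    """Pairing between estimated components and templates.

    ``pairs`` lists (estimated index, template index, similarity)
    in the order chosen by the greedy rule; indices are unique on each
    side.  ``unmatched_estimates`` / ``unmatched_templates`` hold the
    leftover indices of the larger side.
    """

    pairs: list[tuple[int, int, float]]
    unmatched_estimates: list[int]
    unmatched_templates: list[int]

    def estimate_for(self, template: int) -> int | None:
        for e, t, _ in self.pairs:
            if t == template:
                return e
        return None


def greedy_match(similarity: np.ndarray) -> MatchTable:
    """Greedy global-maximum-first matching on a similarity matrix.

    ``similarity`` is (n_estimates x n_templates) of absolute
    correlations.  Note the greedy rule is not the optimal assignment:
    a large entry consumes its row and column even when the optimal
    pairing would split them.
    """
    S = np.asarray(similarity, dtype=float)
    if S.size == 0:
        n_est, n_tmpl = S.shape if S.ndim == 2 else (0, 0)
        return MatchTable([], list(range(n_est)), list(range(n_tmpl)))
    work = S.copy()
    pairs = []
    n_pairs = min(work.shape)
    for _ in range(n_pairs):
        # argmax scans in row-major order, so exact ties resolve to the
        # smallest (row, column).
        i, j = np.unravel_index(np.argmax(work), work.shape)
        pairs.append((int(i), int(j), float(S[i, j])))
        work[i, :] = -np.inf
        work[:, j] = -np.inf
    used_e = {e for e, _, _ in pairs}
    used_t = {t for _, t, _ in pairs}
    return MatchTable(
        pairs=pairs,
        unmatched_estimates=[i for i in range(S.shape[0]) if i not in used_e],
        unmatched_templates=[j for j in range(S.shape[1]) if j not in used_t],
    )


def optimal_match(similarity: np.ndarray) -> MatchTable:
    """Optimal (Hungarian) assignment — diagnostic only.

    The scoring pipeline deliberately uses :func:`greedy_match`; this
    maximum-total-similarity alternative exists solely to quantify how
    far the greedy pairing falls from optimal on a given matrix.
    """
    from scipy.optimize import linear_sum_assignment

    S = np.asarray(similarity, dtype=float)
    if S.size == 0:
        n_est, n_tmpl = S.shape if S.ndim == 2 else (0, 0)
        return MatchTable([], list(range(n_est)), list(range(n_tmpl)))
    rows, cols = linear_sum_assignment(S, maximize=True)
    pairs = [(int(i), int(j), float(S[i, j])) for i, j in zip(rows, cols)]
    return MatchTable(
        pairs=pairs,
        unmatched_estimates=[i for i in range(S.shape[0]) if i not in set(rows)],
        unmatched_templates=[j for j in range(S.shape[1]) if j not in set(cols)],
    )


def accuracy(estimated: np.ndarray, truth: np.ndarray) -> float:
    """Absolute Pearson correlation between an estimate and its truth."""
    estimated = np.asarray(estimated, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimated.shape != truth.shape:
        raise ValueError("estimated and truth must have equal length")
    if estimated.std() == 0 or truth.std() == 0:
        raise ValueError("accuracy is undefined for a constant input")
    r = np.corrcoef(estimated, truth)[0, 1]
    return float(abs(r))


def paired_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-tailed paired t-test of ``a`` versus ``b``.

    Returns ``(t, p)`` with ``t = mean(d) / (SD(d)/sqrt(n))``,
    ``d = a - b``, and p from the t distribution with n-1 df.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length vectors")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: t-test undefined")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def bonferroni(pvals, alpha: float = 0.05) -> list[bool]:
    """Bonferroni significance flags: ``p < alpha / m``."""
    pvals = list(pvals)
    if not pvals:
        return []
    thr = alpha / len(pvals)
    return [p < thr for p in pvals]


# ---------------------------------------------------------------------------
# Experiment scoring


@dataclass
class AccuracyTable:
    """Per-subject, per-source accuracy of one method.

    ``spatial`` and ``temporal`` are (subjects x source) DataFrames of
    absolute correlations; columns are template ids (ints) plus
    ``"unique"`` when subject-unique sources are present.  Entries are
    NaN where a subject lacks the source.
    """

    method: str
    spatial: pd.DataFrame
    temporal: pd.DataFrame
    match: MatchTable = None

    @property
    def per_subject_spatial(self) -> np.ndarray:
        return self.spatial.mean(axis=1, skipna=True).to_numpy()

    @property
    def per_subject_temporal(self) -> np.ndarray:
        return self.temporal.mean(axis=1, skipna=True).to_numpy()


def build_templates(truths: list[GroundTruth]) -> dict[int, np.ndarray]:
    """Mean ground-truth map per template id across the subjects that
    carry it (subject-unique sources are excluded)."""
    acc: dict[int, list[np.ndarray]] = {}
    for gt in truths:
        for row, tid in enumerate(gt.source_ids):
            if tid >= 0:
                acc.setdefault(tid, []).append(gt.maps[row])
    return {tid: np.mean(maps, axis=0) for tid, maps in sorted(acc.items())}


def _abs_corr_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    As = (A - A.mean(axis=1, keepdims=True)) / A.std(axis=1, keepdims=True)
    Bs = (B - B.mean(axis=1, keepdims=True)) / B.std(axis=1, keepdims=True)
    return np.abs(As @ Bs.T / A.shape[1])


def score_method(
    result: DecompositionResults, truths: list[GroundTruth]
) -> AccuracyTable:
    """Match a method's group-level maps to templates and score every
    subject's components and time courses against its ground truth.

    The group-level maps are matched to the mean-GT templates by the
    greedy rule; the pairing then propagates to subject-specific maps
    and TCs (component order is aligned with the group level for both
    methods).  If subject-unique sources exist and exactly as many
    estimated components are left unmatched as needed, each leftover
    component is scored against the subject's unique source.
    """
    templates = build_templates(truths)
    tids = list(templates)
    tmpl = np.array([templates[t] for t in tids])
    match = greedy_match(_abs_corr_matrix(result.group_maps, tmpl))
    has_unique = any("unique" in gt.labels for gt in truths)
    columns: list = list(tids)
    if has_unique:
        columns.append("unique")
    M = result.n_subjects
    spatial = pd.DataFrame(np.nan, index=range(M), columns=columns)
    temporal = pd.DataFrame(np.nan, index=range(M), columns=columns)
    unique_est = (
        match.unmatched_estimates[0]
        if has_unique and len(match.unmatched_estimates) == 1
        else None
    )
    for m, gt in enumerate(truths):
        row_of = {tid: r for r, tid in enumerate(gt.source_ids) if tid >= 0}
        maps, tcs = result.subject_maps[m], result.subject_tcs[m]
        for e, tcol, _ in match.pairs:
            tid = tids[tcol]
            if tid not in row_of:
                continue
            r = row_of[tid]
            spatial.loc[m, tid] = accuracy(maps[e], gt.maps[r])
            temporal.loc[m, tid] = accuracy(tcs[:, e], gt.tcs[:, r])
        if has_unique and "unique" in gt.labels:
            r = gt.labels.index("unique")
            if unique_est is not None:
                spatial.loc[m, "unique"] = accuracy(maps[unique_est], gt.maps[r])
                temporal.loc[m, "unique"] = accuracy(
                    tcs[:, unique_est], gt.tcs[:, r]
                )
    return AccuracyTable(
        method=result.method, spatial=spatial, temporal=temporal, match=match
    )


@dataclass
class ExperimentScore:
    """Accuracy tables for each method plus the paired-test results."""

    tables: dict
    ttests: pd.DataFrame


def score_experiment(
    results: dict[str, DecompositionResults],
    truths: list[GroundTruth],
    *,
    mode: str = "per_subject",
    order: tuple[str, str] = ("iva_gl", "gigica"),
) -> ExperimentScore:
    """Score two methods on identical datasets and compare them.

    ``mode='per_subject'`` compares the per-subject mean accuracies
    (one paired t-test per domain, spatial and temporal);
    ``mode='per_component'`` runs one paired test per source across
    subjects.  Differences are taken ``order[0] - order[1]`` (IVA
    minus GIG-ICA by default), so a negative t favours the second
    method.  Zero-variance differences are reported as "no
    difference" (t = 0, p = 1) rather than an error.
    """
    tables = {name: score_method(res, truths) for name, res in results.items()}
    a, b = (tables[order[0]], tables[order[1]])
    rows = []

    def _safe_ttest(x, y):
        x, y = np.asarray(x), np.asarray(y)
        keep = ~(np.isnan(x) | np.isnan(y))
        x, y = x[keep], y[keep]
        if x.size < 2:
            return np.nan, np.nan
        try:
            return paired_ttest(x, y)
        except ValueError:
            return 0.0, 1.0  # identical accuracies: no difference

    if mode == "per_subject":
        for domain in ("spatial", "temporal"):
            xa = getattr(a, f"per_subject_{domain}")
            xb = getattr(b, f"per_subject_{domain}")
            t, p = _safe_ttest(xa, xb)
            rows.append({"domain": domain, "source": "mean", "t": t, "p": p})
    elif mode == "per_component":
        for domain in ("spatial", "temporal"):
            da = getattr(a, domain)
            for col in da.columns:
                t, p = _safe_ttest(
                    da[col].to_numpy(), getattr(b, domain)[col].to_numpy()
                )
                rows.append({"domain": domain, "source": col, "t": t, "p": p})
    else:
        raise ValueError("mode must be 'per_subject' or 'per_component'")
    return ExperimentScore(tables=tables, ttests=pd.DataFrame(rows))
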