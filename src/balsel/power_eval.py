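"""Windowed ROC protocol for scan power.

The region is tiled by 100-bp nonoverlapping windows from position 1 and
each window is scored by the maximum per-SNP score it contains.  The
true window of a replicate is the window containing a scored SNP within
50 bp of the balanced site (the qualifying SNP closest to the balanced
site; missing when no SNP qualifies, in which case the replicate still
contributes its negative windows).  TPR at a threshold is the fraction
of replicates whose true-window score reaches it; FPR pools negative
windows across replicates.  Normalised-threshold FPR curves (min-max
normalised scores, evenly spaced thresholds) serve the null/structure
scenarios, which have no true windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .genome_model import ChromosomeLayout
from .ihs_scan import ScanResult

__all__ = [
    "ROCResult",
    "WindowScores",
    "window_scores",
    "roc",
    "paired_roc",
    "tpr_at_fpr",
    "roc_auc",
    "rank_auc",
    "normalized_fpr_curve",
    "WINDOW_SIZE",
    "TRUTH_RADIUS",
]

WINDOW_SIZE = 100
TRUTH_RADIUS = 50


@dataclass
class WindowScores:
    """Per-replicate window scores: the true-window score (NaN when the
    replicate has no SNP within the truth radius) and all negative-window
    scores (windows with no scored SNP are omitted)."""

    true_score: float
    negative_scores: np.ndarray


@dataclass
class ROCResult:
    method: str
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    n_replicates: int
    window_size: int = WINDOW_SIZE
    truth_radius: int = TRUTH_RADIUS


def window_scores(
    scan: ScanResult,
    layout: ChromosomeLayout,
    window_size: int = WINDOW_SIZE,
    truth_radius: int = TRUTH_RADIUS,
) -> WindowScores:
    """Tile the region into nonoverlapping windows and score each by its
    maximum per-SNP score."""
    if scan.n_snps == 0:
        return WindowScores(true_score=float("nan"), negative_scores=np.empty(0))
    pos = scan.positions
    scores = scan.scores
    win_idx = (pos - 1) // window_size
    bsite = layout.balanced_site_position
    qualifying = np.flatnonzero(np.abs(pos - bsite) <= truth_radius)
    true_win = -1
    if qualifying.size:
        closest = qualifying[np.argmin(np.abs(pos[qualifying] - bsite))]
        true_win = int(win_idx[closest])
    uniq = {}
    for w, s in zip(win_idx, scores):
        w = int(w)
        if w not in uniq or s > uniq[w]:
            uniq[w] = s
    true_score = uniq.pop(true_win, float("nan")) if true_win >= 0 else float("nan")
    return WindowScores(
        true_score=float(true_score),
        negative_scores=np.asarray(sorted(uniq.values()), dtype=float),
    )


def roc(
    replicate_scores: Sequence[WindowScores],
    thresholds: Optional[int | str] = "all-observed",
    method: str = "",
) -> ROCResult:
    """Build the ROC from per-replicate window scores.

    ``thresholds`` is either "all-observed" (sorted union of every
    observed score) or an integer count of evenly spaced thresholds from
    0 to the global maximum.
    """
    if not replicate_scores:
        raise ValueError("need at least one replicate")
    true_scores = np.asarray([w.true_score for w in replicate_scores])
    negatives = np.concatenate(
        [w.negative_scores for w in replicate_scores]
        + [np.empty(0)]  # guard against an all-empty set
    )
    observed = np.concatenate([true_scores[np.isfinite(true_scores)], negatives])
    if observed.size == 0:
        raise ValueError("no scored windows")
    if thresholds == "all-observed":
        thr = np.unique(np.concatenate([[0.0], observed]))
    else:
        thr = np.linspace(0.0, float(observed.max()), int(thresholds))
    # missing true windows count in the denominator (conservative)
    with np.errstate(invalid="ignore"):
        tpr = (true_scores[None, :] >= thr[:, None]).sum(axis=1) / len(true_scores)
    if negatives.size:
        fpr = (negatives[None, :] >= thr[:, None]).sum(axis=1) / negatives.size
    else:
        fpr = np.zeros_like(thr)
    return ROCResult(
        method=method,
        thresholds=thr,
        tpr=tpr.astype(float),
        fpr=fpr.astype(float),
        n_replicates=len(replicate_scores),
    )


def tpr_at_fpr(result: ROCResult, fpr_level: float) -> float:
    """TPR at the smallest threshold whose FPR does not exceed the level
    (conservative step interpolation, no crossing of the level)."""
    if not 0.0 < fpr_level < 1.0:
        raise ValueError("fpr_level must be in (0, 1)")
    ok = np.flatnonzero(result.fpr <= fpr_level)
    if ok.size == 0:
        return float("nan")
    # thresholds ascend; FPR is non-increasing, so the first qualifying
    # threshold yields the largest attainable TPR
    return float(result.tpr[ok[0]])


def paired_roc(
    selection_scans: Sequence[ScanResult],
    neutral_scans: Sequence[ScanResult],
    layout: ChromosomeLayout,
    method: str = "",
    window_size: int = WINDOW_SIZE,
    truth_radius: int = TRUTH_RADIUS,
) -> ROCResult:
    """ROC with the true window from each selection replicate and the
    negative windows from matched neutral replicates (every window of a
    neutral replicate is a potential false positive).

    Using neutral windows as the FPR reference keeps young-sweep
    scenarios evaluable: immediately after the sweep phase the whole
    simulated region shares the extreme haplotype signal, so windows of
    the selection replicates themselves carry no contrast.
    """
    trues = [
        window_scores(s, layout, window_size, truth_radius)
        for s in selection_scans
    ]
    negs = [
        window_scores(s, layout, window_size, truth_radius=-1)
        for s in neutral_scans
    ]
    if len(trues) == len(negs):
        paired = [
            WindowScores(t.true_score, n.negative_scores)
            for t, n in zip(trues, negs)
        ]
    else:
        pooled_neg = np.concatenate([n.negative_scores for n in negs])
        paired = [WindowScores(t.true_score, np.empty(0)) for t in trues]
        if paired:
            paired[0] = WindowScores(paired[0].true_score, pooled_neg)
    return roc(paired, method=method)


def roc_auc(result: ROCResult) -> float:
    """Trapezoidal area under the (FPR, TPR) curve."""
    order = np.argsort(result.fpr)
    f = np.concatenate([[0.0], result.fpr[order], [1.0]])
    t = np.concatenate([[0.0], result.tpr[order], [1.0]])
    return float(np.trapezoid(t, f))


def rank_auc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    pos = pos[np.isfinite(pos)]
    neg = neg[np.isfinite(neg)]
    if pos.size == 0 or neg.size == 0:
        return float("nan")
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return float((gt + 0.5 * eq) / (pos.size * neg.size))


def normalized_fpr_curve(
    scans: Sequence[ScanResult],
    layout: ChromosomeLayout,
    n_thresholds: int = 100,
    window_size: int = WINDOW_SIZE,
) -> tuple[np.ndarray, np.ndarray]:
    """FPR at evenly spaced min-max-normalised thresholds, pooling all
    windows of all replicates (no truth windows; used for null and
    structure scenarios)."""
    if not scans:
        raise ValueError("need at least one scan")
    all_scores = []
    for scan in scans:
        # truth_radius=-1: no window qualifies as true; every window is a
        # potential false positive
        ws = window_scores(scan, layout, window_size=window_size, truth_radius=-1)
        all_scores.append(ws.negative_scores)
    pooled = np.concatenate(all_scores + [np.empty(0)])
    if pooled.size == 0:
        raise ValueError("no scored windows")
    lo, hi = float(pooled.min()), float(pooled.max())
    if hi <= lo:
        raise ValueError("degenerate (constant) scores: normalisation undefined")
    norm = (pooled - lo) / (hi - lo)
    thr = np.linspace(0.0, 1.0, int(n_thresholds))
    fpr = (norm[None, :] >= thr[:, None]).sum(axis=1) / norm.size
    return thr, fpr.astype(float)
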