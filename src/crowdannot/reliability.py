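"""Crowd-size calibration by rater resampling with ROC/AUC scoring.

How many independent crowd raters does a photo-annotation task need?  Small
crowds reach confident consensus on wrong answers more often than large ones,
so the question is answered empirically: from a pool of raters who all rated
the same gold-standard photo set, draw many random subsets at each candidate
crowd size k, score each photo by the subset's vote fraction, and compare
against the gold labels with an ROC curve.  The spread of the resulting AUC
values at each k gives pointwise confidence bands; the smallest k whose AUC
(mean, or lower confidence bound) clears a target — say 0.90 — is the crowd
size to commission.

The AUC here is the trapezoidal area under the empirical ROC curve with tied
scores grouped into single steps, which makes it identical to the
Mann-Whitney pairwise estimator (#{pos > neg} + half the ties, over all
pos x neg pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata as _rankdata

__all__ = [
    "NOT_REACHED",
    "ResamplingPlan",
    "ROCCurve",
    "AUCEstimate",
    "CrowdSizeCurve",
    "roc_curve",
    "auc",
    "mann_whitney_auc",
    "jackknife_crowd_resample",
    "minimal_crowd_size",
    "stabilization_point",
]

NOT_REACHED = None  # returned when no tested crowd size clears the target


@dataclass(frozen=True)
class ResamplingPlan:
    """Resampling design: which crowd sizes, how many draws per size.

    The reference design draws 50 random samples of 2 raters, then 50 of 3,
    and so on; sampling is without replacement within a draw (a rater appears
    at most once in a crowd) and independent across draws.
    """

    crowd_sizes: tuple = tuple(range(2, 21))
    samples_per_size: int = 50
    seed: int = 0

    def __post_init__(self):
        sizes = tuple(int(k) for k in self.crowd_sizes)
        if not sizes or min(sizes) < 1:
            raise ValueError("crowd sizes must be positive")
        if list(sizes) != sorted(set(sizes)):
            raise ValueError("crowd sizes must be strictly increasing")
        if self.samples_per_size < 1:
            raise ValueError("samples_per_size must be at least 1")
        object.__setattr__(self, "crowd_sizes", sizes)


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC curve: FPF/TPF points plus the thresholds that induce them."""

    fpf: tuple
    tpf: tuple
    thresholds: tuple

    def __post_init__(self):
        f, t = np.asarray(self.fpf), np.asarray(self.tpf)
        if f[0] != 0 or t[0] != 0 or f[-1] != 1 or t[-1] != 1:
            raise ValueError("ROC curve must run from (0,0) to (1,1)")
        if (np.diff(f) < -1e-12).any() or (np.diff(t) < -1e-12).any():
            raise ValueError("ROC coordinates must be nondecreasing")

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.fpf, self.tpf])


@dataclass(frozen=True)
class AUCEstimate:
    auc: float
    n_pos: int
    n_neg: int

    def __post_init__(self):
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC outside [0,1]")


def _validate_scores(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1 or s.size == 0:
        raise ValueError("scores and labels must be matching 1-d arrays")
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("AUC undefined: need at least one positive and one negative")
    return s, y


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    """Empirical ROC from sweeping the threshold over all distinct scores.

    Photos with equal scores enter the curve as a single step (a diagonal
    segment), the convention under which the trapezoidal area equals the
    Mann-Whitney estimator with half-credit for ties.
    """
    s, y = _validate_scores(scores, labels)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    # collapse runs of equal score into single threshold steps
    distinct = np.where(np.diff(s) != 0)[0]
    idx = np.r_[distinct, s.size - 1]
    tp = np.cumsum(y)[idx]
    fp = np.cumsum(1 - y)[idx]
    tpf = np.r_[0.0, tp / n_pos]
    fpf = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s[idx]]
    return ROCCurve(tuple(fpf), tuple(tpf), tuple(thresholds))


def auc(
    scores: Sequence[float] | ROCCurve, labels: Sequence[int] | None = None
) -> AUCEstimate | float:
    """Area under the ROC curve (trapezoidal rule).

    Called with a fitted ``ROCCurve`` it returns the bare area; called with
    raw scores and binary labels it returns an ``AUCEstimate``.  Either way
    the value equals the Mann-Whitney pairwise estimator.
    """
    if isinstance(scores, ROCCurve):
        return float(np.trapezoid(scores.tpf, scores.fpf))
    s, y = _validate_scores(scores, labels)
    curve = roc_curve(s, y)
    area = float(np.trapezoid(curve.tpf, curve.fpf))
    return AUCEstimate(auc=min(1.0, max(0.0, area)), n_pos=int(y.sum()), n_neg=int(y.size - y.sum()))


def mann_whitney_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC: (#{pos > neg} + 0.5 #{ties}) / (n_pos * n_neg).

    Computed via midranks, O(n log n); serves as the identity check for the
    trapezoidal route.
    """
    s, y = _validate_scores(scores, labels)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    ranks = _rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


@dataclass(frozen=True)
class CrowdSizeCurve:
    """Per-crowd-size AUC summaries from the resampling procedure.

    ``table`` has one row per crowd size k with the mean AUC over the M
    draws, percentile confidence bounds, the between-sample SD, and the draw
    count; ``draws`` maps k to the raw AUC values.
    """

    table: pd.DataFrame
    draws: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"k", "mean_auc", "ci_lo", "ci_hi", "sd_auc", "n_samples"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"curve table missing columns {required - set(self.table.columns)}")
        t = self.table
        if ((t["ci_lo"] > t["mean_auc"] + 1e-12) | (t["mean_auc"] > t["ci_hi"] + 1e-12)).any():
            raise ValueError("confidence bounds must bracket the mean")

    @property
    def crowd_sizes(self) -> np.ndarray:
        return self.table["k"].to_numpy()


def jackknife_crowd_resample(
    votes: np.ndarray,
    labels: Sequence[int],
    plan: ResamplingPlan,
    ci_level: float = 0.95,
) -> CrowdSizeCurve:
    """Crowd-size resampling over a complete rater x photo vote matrix.

    ``votes[i, j]`` is rater i's binary vote (1 = target present) on photo j;
    the design must be complete (every rater rated every photo).  For each
    crowd size k in the plan, draw M simple random k-subsets of the rater
    pool without replacement (independently across draws), score each photo
    by the subset's vote fraction, and compute the AUC of those scores
    against ``labels``.  Reports the mean, percentile confidence bounds
    (2.5/97.5 for the default level), and between-sample SD per k.
    Deterministic given ``plan.seed``.
    """
    votes = np.asarray(votes)
    if votes.ndim != 2:
        raise ValueError("votes must be a rater x photo matrix")
    labels = np.asarray(labels, dtype=int)
    n_raters, n_photos = votes.shape
    if labels.shape != (n_photos,):
        raise ValueError("labels length must match the photo axis")
    if max(plan.crowd_sizes) > n_raters:
        raise ValueError(
            f"crowd size {max(plan.crowd_sizes)} exceeds the pool of {n_raters} raters"
        )

    rng = np.random.default_rng(plan.seed)
    alpha = (1.0 - ci_level) / 2.0
    rows = []
    draws: dict[int, np.ndarray] = {}
    for k in plan.crowd_sizes:
        aucs = np.empty(plan.samples_per_size)
        for m in range(plan.samples_per_size):
            # sorted so the draw is a set: summation order cannot perturb scores
            subset = np.sort(rng.choice(n_raters, size=k, replace=False))
            scores = votes[subset].mean(axis=0)
            aucs[m] = mann_whitney_auc(scores, labels)
        draws[k] = aucs
        # identical draws (e.g. k = pool size) have exactly zero spread
        if aucs.max() == aucs.min():
            spread, mean = 0.0, float(aucs[0])
        else:
            spread, mean = float(aucs.std(ddof=1)), float(aucs.mean())
        # percentile bounds can exclude a heavily skewed mean (e.g. one low
        # draw among many perfect ones); widen minimally so they bracket it
        rows.append(
            {
                "k": k,
                "mean_auc": mean,
                "ci_lo": min(mean, float(np.percentile(aucs, 100 * alpha))),
                "ci_hi": max(mean, float(np.percentile(aucs, 100 * (1 - alpha)))),
                "sd_auc": spread if aucs.size > 1 else 0.0,
                "n_samples": plan.samples_per_size,
            }
        )
    return CrowdSizeCurve(table=pd.DataFrame(rows), draws=draws)


def minimal_crowd_size(
    curve: CrowdSizeCurve, target_auc: float, criterion: str = "mean"
) -> int | None:
    """Smallest tested crowd size whose AUC statistic reaches the target.

    ``criterion="mean"`` compares the mean resampled AUC; ``"ci_lower"``
    requires the whole spread of consensus (the lower confidence bound) to
    clear the target.  Returns NOT_REACHED (None) when no tested size does.
    """
    if not (0.5 < target_auc <= 1.0):
        raise ValueError("target AUC must lie in (0.5, 1]")
    if criterion not in ("mean", "ci_lower"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if curve.table.empty:
        raise ValueError("empty crowd-size curve")
    col = "mean_auc" if criterion == "mean" else "ci_lo"
    hits = curve.table.loc[curve.table[col] >= target_auc, "k"]
    return int(hits.iloc[0]) if len(hits) else NOT_REACHED


def stabilization_point(curve: CrowdSizeCurve, epsilon: float = 0.02) -> int | None:
    """Smallest k from which the between-sample AUC SD stays at or below epsilon.

    Identifies where between-sample variation has stabilised: the bound must
    hold for k and every larger tested size.  Returns NOT_REACHED (None) if
    the tail never settles under epsilon.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if curve.table.empty:
        raise ValueError("empty crowd-size curve")
    sd = curve.table["sd_auc"].to_numpy()
    k = curve.table["k"].to_numpy()
    ok = sd <= epsilon
    # suffix scan: first index where all later sizes also satisfy the bound
    for i in range(len(ok)):
        if ok[i:].all():
            return int(k[i])
    return NOT_REACHED
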