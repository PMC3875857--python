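"""Evaluation metrics for classifier and transcript-model predictions.

AUROC (pair-counting), tolerance-aware per-base precision/recall,
transcript-level matching with end offsets, strand cross-correlation with
an offset scan, threshold-based rates, rank-sum dependence tests, and the
random-guessing baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .sequence_io import TranscriptAnnotation

__all__ = [
    "EvaluationReport",
    "auroc",
    "pr_per_base",
    "random_baseline_pr",
    "transcript_match",
    "strand_cross_correlation",
    "threshold_rates",
    "dependence_expression_test",
    "annotations_to_binary",
]


@dataclass
class EvaluationReport:
    """A named metric value with its sample size and settings."""

    metric: str
    value: float
    n: int
    settings: dict = field(default_factory=dict)


def auroc(pos_scores, neg_scores) -> float:
    """Pair-counting AUROC: P(pos > neg) + 0.5 P(pos == neg).

    Computed with the rank (Mann-Whitney U) identity, which equals the
    trapezoidal area under the ROC curve exactly, ties included.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def annotations_to_binary(
    annotations: list[TranscriptAnnotation], chrom_lengths: dict[str, int]
) -> dict[str, dict[str, np.ndarray]]:
    """Per-strand transcribed-base masks from transcript annotations."""
    out = {
        c: {"+": np.zeros(n, dtype=bool), "-": np.zeros(n, dtype=bool)}
        for c, n in chrom_lengths.items()
    }
    for a in annotations:
        out[a.chrom][a.strand][a.interval.start : a.interval.end] = True
    return out


def pr_per_base(
    predicted: dict[str, dict[str, np.ndarray]],
    truth: dict[str, dict[str, np.ndarray]],
    tolerance_bp: int = 0,
    tolerant_recall: bool = False,
) -> tuple[float, float]:
    """Per-base precision and recall with a positional tolerance.

    Recall is the fraction of true transcribed bases that are predicted;
    precision is the fraction of predicted bases lying within
    ``tolerance_bp`` of a true transcribed base on the same strand (the
    tolerance applies to precision only unless ``tolerant_recall``).
    Returns (nan, recall) when nothing is predicted.
    """
    tp_r = n_true = tp_p = n_pred = 0
    for chrom, strands in truth.items():
        for strand, t in strands.items():
            p = predicted[chrom][strand]
            t_dilated = (
                ndimage.maximum_filter1d(t.astype(np.uint8), 2 * tolerance_bp + 1) > 0
                if tolerance_bp > 0
                else t
            )
            p_dilated = (
                ndimage.maximum_filter1d(p.astype(np.uint8), 2 * tolerance_bp + 1) > 0
                if tolerance_bp > 0 and tolerant_recall
                else p
            )
            n_true += int(t.sum())
            tp_r += int((t & p_dilated).sum())
            n_pred += int(p.sum())
            tp_p += int((p & t_dilated).sum())
    recall = tp_r / n_true if n_true else float("nan")
    precision = tp_p / n_pred if n_pred else float("nan")
    return precision, recall


def random_baseline_pr(
    p: float,
    truth_fraction: float,
    n: int,
    rng: np.random.Generator,
    replicates: int = 20,
) -> tuple[float, float]:
    """Expected precision/recall of independent Bernoulli(p) guessing
    against a Bernoulli(truth_fraction) ground truth (zero tolerance).

    With p equal to the transcribed fraction both converge to that
    fraction.  Returns means over replicates.
    """
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    precs, recs = [], []
    for _ in range(replicates):
        truth = rng.random(n) < truth_fraction
        pred = rng.random(n) < p
        tp = int((truth & pred).sum())
        precs.append(tp / max(int(pred.sum()), 1))
        recs.append(tp / max(int(truth.sum()), 1))
    return float(np.mean(precs)), float(np.mean(recs))


def _tx_ends(a: TranscriptAnnotation) -> tuple[int, int]:
    """(TSS, CPA) genomic bases of a transcript (interval endpoints)."""
    if a.strand == "+":
        return a.interval.start, a.interval.end - 1
    return a.interval.end - 1, a.interval.start


def transcript_match(
    predicted: list[TranscriptAnnotation],
    true: list[TranscriptAnnotation],
    end_offset_bp: int = 200,
) -> tuple[float, float, list[tuple[int, int]]]:
    """Greedy one-to-one transcript matching.

    A (predicted, true) pair matches iff same chromosome and strand with
    |dTSS| <= offset and |dCPA| <= offset; pairs are consumed in order of
    increasing summed end distance.  Returns (precision, recall, matching)
    with the matching as (predicted index, true index) pairs.
    """
    pairs = []
    for i, pa in enumerate(predicted):
        p_tss, p_cpa = _tx_ends(pa)
        for j, ta in enumerate(true):
            if pa.chrom != ta.chrom or pa.strand != ta.strand:
                continue
            t_tss, t_cpa = _tx_ends(ta)
            d_tss, d_cpa = abs(p_tss - t_tss), abs(p_cpa - t_cpa)
            if d_tss <= end_offset_bp and d_cpa <= end_offset_bp:
                pairs.append((d_tss + d_cpa, i, j))
    pairs.sort()
    used_p, used_t = set(), set()
    matching = []
    for _, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        matching.append((i, j))
    precision = len(matching) / len(predicted) if predicted else float("nan")
    recall = len(matching) / len(true) if true else float("nan")
    return precision, recall, matching


def strand_cross_correlation(
    track_plus: np.ndarray,
    track_minus: np.ndarray,
    offset_range: tuple[int, int] = (-500, 500),
) -> tuple[int, float, dict[int, float]]:
    """Pearson correlation between strand tracks at every offset.

    At offset k, ``track_plus[i]`` is correlated with ``track_minus[i+k]``
    over the overlapping span; returns (argmax offset, its correlation,
    all correlations).
    """
    a = np.asarray(track_plus, dtype=float)
    b = np.asarray(track_minus, dtype=float)
    if len(a) != len(b):
        raise ValueError("tracks must have equal length")
    lo, hi = offset_range
    corrs: dict[int, float] = {}
    for k in range(lo, hi + 1):
        if k >= 0:
            x, y = a[: len(a) - k] if k else a, b[k:]
        else:
            x, y = a[-k:], b[: len(b) + k]
        if len(x) < 2:
            continue
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            continue
        corrs[k] = float(np.corrcoef(x, y)[0, 1])
    if not corrs:
        raise ValueError("overlap shorter than 2 bases at every offset")
    best = max(corrs, key=lambda k: corrs[k])
    return best, corrs[best], corrs


def threshold_rates(scores, labels, score_threshold: float) -> tuple[float, float]:
    """(TPR, FPR) at a score threshold (predicted positive iff score >= t)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    pred = scores >= score_threshold
    tpr = float((pred & (labels == 1)).sum() / (labels == 1).sum())
    fpr = float((pred & (labels == 0)).sum() / (labels == 0).sum())
    return tpr, fpr


def dependence_expression_test(
    dependent_changes, independent_changes
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum on |expression change| between genes
    whose promoters are predicted to depend on a factor and the rest."""
    dep = np.abs(np.asarray(dependent_changes, dtype=float))
    ind = np.abs(np.asarray(independent_changes, dtype=float))
    if len(dep) == 0 or len(ind) == 0:
        raise ValueError("both sets must be non-empty")
    res = stats.ranksums(dep, ind)
    return float(res.statistic), float(res.pvalue)
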