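"""Evaluation metrics: pixel IOU, energy-ratio SNR, and coordinate-based precision/recall.

IOU compares two binary masks as |A ∩ B| / |A ∪ B|.  SNR compares a noisy
image against its noise-free counterpart as
10 * log10(sum clean^2 / sum (noisy - clean)^2).  Picks are matched to
ground-truth centers greedily in descending score order within a Euclidean
distance threshold; precision = TP / (TP + FP), recall = TP / (TP + FN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, ShapeError
from .formats_io import BinaryLabelMap, Micrograph, Pick, PickSet

__all__ = [
    "MatchResult",
    "EvalReport",
    "iou",
    "snr",
    "snr_linear",
    "match_picks",
    "precision_recall",
    "evaluate",
]


@dataclass(frozen=True)
class MatchResult:
    """TP/FP/FN counts plus the matched (pick, truth) pairs at a distance threshold."""

    tp: int
    fp: int
    fn: int
    pairs: tuple[tuple[Pick, Pick], ...]
    dist_threshold: float


@dataclass
class EvalReport:
    """Summary of one picking run against ground truth."""

    precision: float
    recall: float
    iou_per_particle: list[float] = field(default_factory=list)
    mean_iou: float = float("nan")
    match: MatchResult | None = None


def _mask_data(m) -> np.ndarray:
    return m.data if isinstance(m, BinaryLabelMap) else np.asarray(m)


def iou(a, b) -> float:
    """Pixel intersection-over-union of two binary masks; both empty -> 1.0."""
    da, db = _mask_data(a).astype(bool), _mask_data(b).astype(bool)
    if da.shape != db.shape:
        raise ShapeError(f"mask shapes differ: {da.shape} vs {db.shape}")
    union = np.count_nonzero(da | db)
    if union == 0:
        return 1.0  # perfect agreement on absence
    return np.count_nonzero(da & db) / union


def snr(noisy, clean) -> float:
    """Energy-ratio SNR in dB: 10 * log10(sum clean^2 / sum (noisy - clean)^2)."""
    f = noisy.data if isinstance(noisy, Micrograph) else np.asarray(noisy, dtype=float)
    fh = clean.data if isinstance(clean, Micrograph) else np.asarray(clean, dtype=float)
    if f.shape != fh.shape:
        raise ShapeError(f"image shapes differ: {f.shape} vs {fh.shape}")
    sig = float(np.sum(fh.astype(np.float64) ** 2))
    noise = float(np.sum((f.astype(np.float64) - fh.astype(np.float64)) ** 2))
    if sig == 0.0:
        raise DomainError("SNR undefined: clean image has zero energy")
    if noise == 0.0:
        raise DomainError("SNR undefined: noisy and clean images are identical")
    return 10.0 * np.log10(sig / noise)


def snr_linear(noisy, clean) -> float:
    """The same energy ratio on the linear scale (10^(dB/10))."""
    return 10.0 ** (snr(noisy, clean) / 10.0)


def match_picks(pred: PickSet, truth: PickSet, dist_threshold: float) -> MatchResult:
    """Greedy matching of picks to ground-truth centers.

    Picks are visited in descending score order; each is a true positive if
    some not-yet-matched truth center lies within ``dist_threshold``
    (Euclidean; the nearest such center is consumed).  Unmatched picks are
    FP, unmatched truths FN, so TP + FP = |pred| and TP + FN = |truth|.
    """
    if dist_threshold <= 0:
        raise ValueError("dist_threshold must be > 0")
    truths = list(truth.picks)
    taken = [False] * len(truths)
    pairs: list[tuple[Pick, Pick]] = []
    tsq = dist_threshold * dist_threshold
    for p in sorted(pred.picks, key=lambda q: (-q.score, q.y, q.x)):
        best, best_d = -1, tsq
        for j, t in enumerate(truths):
            if taken[j]:
                continue
            d = (p.x - t.x) ** 2 + (p.y - t.y) ** 2
            if d <= best_d:
                best, best_d = j, d
        if best >= 0:
            taken[best] = True
            pairs.append((p, truths[best]))
    tp = len(pairs)
    return MatchResult(
        tp=tp,
        fp=len(pred.picks) - tp,
        fn=len(truths) - tp,
        pairs=tuple(pairs),
        dist_threshold=float(dist_threshold),
    )


def precision_recall(m: MatchResult) -> tuple[float, float]:
    """precision = TP / (TP + FP), recall = TP / (TP + FN); zero denominators raise."""
    if m.tp + m.fp == 0:
        raise DomainError("precision undefined: no picks (TP + FP = 0)")
    if m.tp + m.fn == 0:
        raise DomainError("recall undefined: no ground-truth particles (TP + FN = 0)")
    return m.tp / (m.tp + m.fp), m.tp / (m.tp + m.fn)


def evaluate(
    pred: PickSet,
    truth: PickSet,
    dist_threshold: float,
    pred_mask: BinaryLabelMap | None = None,
    truth_mask: BinaryLabelMap | None = None,
    box_size: int | None = None,
) -> EvalReport:
    """Full report: coordinate precision/recall plus (optionally) pixel IOU.

    When masks are supplied, a per-particle IOU is computed on the box
    around each ground-truth center, along with the whole-mask mean.
    """
    m = match_picks(pred, truth, dist_threshold)
    precision, recall = precision_recall(m)
    per: list[float] = []
    mean_iou = float("nan")
    if pred_mask is not None and truth_mask is not None:
        pm, tm = _mask_data(pred_mask), _mask_data(truth_mask)
        if pm.shape != tm.shape:
            raise ShapeError("mask shapes differ")
        h, w = tm.shape
        for t in truth.picks:
            s = box_size or t.box_size
            x0 = max(0, int(round(t.x)) - s // 2)
            y0 = max(0, int(round(t.y)) - s // 2)
            x1, y1 = min(w, x0 + s), min(h, y0 + s)
            per.append(iou(pm[y0:y1, x0:x1], tm[y0:y1, x0:x1]))
        mean_iou = float(np.mean(per)) if per else iou(pm, tm)
    return EvalReport(
        precision=precision, recall=recall, iou_per_particle=per,
        mean_iou=mean_iou, match=m,
    )
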