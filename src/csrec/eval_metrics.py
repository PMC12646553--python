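"""Recommendation quality and safety metrics.

All four metrics are computed per visit and macro-averaged over the visits
pooled across the evaluated patients:

* Jaccard — |y ∩ ŷ| / |y ∪ ŷ|; both sets empty counts as 1 (a vacuously
  perfect recommendation).
* PRAUC — step-integrated precision–recall area per visit: medications are
  ranked by descending score (ties broken by ascending index) and the
  average-precision sum Σ_i Precision(i)·ΔRecall(i) is accumulated over the
  full ranking; visits with no true medication are excluded with a warning.
* F1 — harmonic mean of per-visit precision and recall, 0/0 defined as 0.
* DDI rate — fraction of unordered recommended pairs flagged in the
  contraindication matrix; visits recommending fewer than two medications
  contribute 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class EvalBatch:
    """Per-visit (true index-set, predicted index-set, score vector) triples
    plus the DDI adjacency used by the safety metric."""

    pairs: list[tuple[set[int], set[int], np.ndarray]]
    ddi: np.ndarray | None = None

    def __post_init__(self):
        if not self.pairs:
            raise ValueError("EvalBatch needs at least one visit")
        if self.ddi is not None:
            ddi = getattr(self.ddi, "weights", self.ddi)
            self.ddi = np.asarray(ddi, dtype=np.float64)


def jaccard(batch: EvalBatch) -> float:
    vals = []
    for y, yhat, _ in batch.pairs:
        union = y | yhat
        vals.append(1.0 if not union else len(y & yhat) / len(union))
    return float(np.mean(vals))


def _visit_prauc(y: set[int], scores: np.ndarray) -> float:
    order = np.lexsort((np.arange(len(scores)), -np.asarray(scores)))
    hits = np.fromiter((1.0 if int(i) in y else 0.0 for i in order), float,
                       len(order))
    tp = np.cumsum(hits)
    precision = tp / np.arange(1, len(order) + 1)
    recall = tp / len(y)
    delta_recall = np.diff(np.concatenate(([0.0], recall)))
    return float(np.sum(precision * delta_recall))


def prauc(batch: EvalBatch) -> float:
    vals = []
    n_empty = 0
    for y, _, scores in batch.pairs:
        if not y:
            n_empty += 1
            continue
        vals.append(_visit_prauc(y, scores))
    if n_empty:
        logger.debug("%d visit(s) with empty medication truth excluded "
                     "from PRAUC", n_empty)
    if not vals:
        raise ValueError("no visit with a non-empty medication truth")
    return float(np.mean(vals))


def f1(batch: EvalBatch) -> float:
    vals = []
    for y, yhat, _ in batch.pairs:
        inter = len(y & yhat)
        prec = inter / len(yhat) if yhat else 0.0
        rec = inter / len(y) if y else 0.0
        vals.append(0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec))
    return float(np.mean(vals))


def ddi_rate(batch: EvalBatch) -> float:
    if batch.ddi is None:
        raise ValueError("ddi_rate requires the DDI adjacency on the batch")
    vals = []
    for _, yhat, _ in batch.pairs:
        rec = sorted(yhat)
        n_pairs = len(rec) * (len(rec) - 1) // 2
        if n_pairs == 0:
            vals.append(0.0)
            continue
        flagged = sum(1 for a in range(len(rec)) for b in range(a + 1, len(rec))
                      if batch.ddi[rec[a], rec[b]] > 0)
        vals.append(flagged / n_pairs)
    return float(np.mean(vals))


def score_batch(batch: EvalBatch) -> dict[str, float]:
    """All four metrics as a flat dict (DDI omitted when no matrix given)."""
    out = {"jaccard": jaccard(batch), "prauc": prauc(batch), "f1": f1(batch)}
    if batch.ddi is not None:
        out["ddi"] = ddi_rate(batch)
    return out
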