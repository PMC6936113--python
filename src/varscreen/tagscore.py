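"""Tag assignment, weighted v-score, and threshold-sweep evaluation.

The tag rules are the quantitative review standard (one tag per artifact
mode); the v-score is the weighted sum v = sum_i w_i * x_i over the active
metric set with three default weight levels (3 for lcr/vafr/lm/ni/nd, 2 for
lncr/mv/hdr, 1 for the rest). A LOW v-score marks a likely true variant, so
a threshold sweep classifies vscore < t as "retained true".
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Optional, Sequence

from .core import (
    EvaluationResult,
    MetricVector,
    NormalTrackSummary,
    PileupCounts,
    ScoredVariant,
    Tag,
    ThresholdConfig,
    WeightConfig,
)

logger = logging.getLogger(__name__)


def assign_tags(
    metrics: MetricVector,
    counts: PileupCounts,
    cfg: ThresholdConfig,
    normal: Optional[NormalTrackSummary] = None,
) -> frozenset[Tag]:
    """Apply the tag standard to one metric vector.

    Somatic-only tags (NCN/LCN/VN) are emitted only when a normal-track
    summary is present. RI implies RR (a repeat region is its prerequisite).
    """
    tags: set[Tag] = set()
    if metrics.lcr > 0:
        tags.add(Tag.LC)
    if metrics.vafr >= 1 - cfg.thr_vaf:
        tags.add(Tag.LVF)
    if metrics.lm >= 0.2 and counts.d_l >= 2:
        tags.add(Tag.LM)
    if metrics.mm >= 1:
        tags.add(Tag.MM)
    if metrics.hdr >= 1:
        tags.add(Tag.HDR)
    if metrics.nh >= 0.9:
        tags.add(Tag.HE)
    if metrics.ne >= 0.9:
        tags.add(Tag.EN)
    if metrics.ni >= 0.9:
        tags.add(Tag.NI)
    if metrics.nd >= 0.9:
        tags.add(Tag.ND)
    if metrics.dir >= 0.9:
        tags.add(Tag.D)
    if metrics.sse >= 0.9:
        tags.add(Tag.SSE)
    if metrics.mv >= 0.2 and counts.d_mv >= 2:
        tags.add(Tag.MV)
    if metrics.r == 1:
        tags.add(Tag.RR)
    if metrics.ri == 1:
        tags.add(Tag.RI)
        tags.add(Tag.RR)
    if metrics.li == 1:
        tags.add(Tag.AO)
    if metrics.si >= 0.9:
        tags.add(Tag.SI)
    if normal is not None and metrics.lncr is not None:
        if metrics.lncr == 1:
            tags.add(Tag.NCN)
        elif 0 < metrics.lncr < 1:
            tags.add(Tag.LCN)
        nvaf = metrics.nvaf or 0.0
        if cfg.vn_literal:
            if nvaf >= 0.1 * cfg.thr and normal.d_normal >= 2:
                tags.add(Tag.VN)
        elif nvaf >= 0.1 * cfg.thr_vaf and normal.d_n >= 2:
            tags.add(Tag.VN)
    return frozenset(tags)


def vscore(metrics: MetricVector, weights: Optional[WeightConfig] = None) -> float:
    """Weighted sum over the active metric set (16 germline / 18 somatic)."""
    weights = weights or WeightConfig()
    md = metrics.as_dict(somatic=metrics.is_somatic)
    return float(sum(weights.weights[name] * value for name, value in md.items()))


def f_beta(precision: float, recall: float, beta: float = 0.3) -> float:
    """F_beta = (1 + b^2) P R / (b^2 P + R); 0 when P = R = 0."""
    if precision == 0 and recall == 0:
        return 0.0
    b2 = beta * beta
    return (1 + b2) * precision * recall / (b2 * precision + recall)


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def _evaluate_at(scores, labels, threshold: float, beta: float) -> EvaluationResult:
    tp = fp = tn = fn = 0
    for s, y in zip(scores, labels):
        positive = s < threshold
        if positive and y:
            tp += 1
        elif positive:
            fp += 1
        elif y:
            fn += 1
        else:
            tn += 1
    total = tp + fp + tn + fn
    if tp + fp == 0 or tp + fn == 0:
        logger.debug("degenerate confusion at t=%.3g (no predicted or no true positives)",
                     threshold)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return EvaluationResult(
        threshold=threshold, tp=tp, fp=fp, tn=tn, fn=fn,
        precision=precision, recall=recall,
        f_beta=f_beta(precision, recall, beta),
        accuracy=(tp + tn) / total if total else 0.0,
        mcc=mcc(tp, fp, tn, fn),
    )


def sweep_thresholds(
    scored: Sequence[ScoredVariant] | Sequence[float],
    truth: Sequence[int],
    beta: float = 0.3,
    step: float = 0.1,
) -> tuple[list[EvaluationResult], float]:
    """Evaluate v-score cutoffs from 0 to max(vscore) inclusive.

    ``scored`` may be ScoredVariants or raw v-scores aligned with ``truth``
    (1 = true variant). A variant is classified as retained-true when its
    v-score lies strictly below the threshold. Returns the per-threshold
    table and the best threshold (argmax F_beta, smallest on ties).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    scores = [
        sv.vscore if isinstance(sv, ScoredVariant) else float(sv) for sv in scored
    ]
    if len(scores) != len(truth):
        raise ValueError("labels must cover all variants")
    if len(set(truth)) < 2:
        logger.warning("truth labels are all one class; precision or recall degenerate")
    top = max(scores, default=0.0)
    n_steps = int(math.floor(top / step + 1e-9))
    thresholds = [round(i * step, 10) for i in range(n_steps + 1)]
    if thresholds[-1] < top - 1e-9:
        thresholds.append(top)
    table = [_evaluate_at(scores, truth, t, beta) for t in thresholds]
    best = max(table, key=lambda r: (r.f_beta, -r.threshold))
    return table, best.threshold
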