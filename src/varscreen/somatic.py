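"""Two-track somatic scoring.

The normal track is screened for potential germline alleles: every
non-reference allele key at the locus with at least two supporting normal
reads is scored with the germline metric set (using the normal-track
coverage requirement ``thr_n``); alleles whose v-score falls at or below the
cutoff (default 3.5, inside the robust 3-4 threshold band) are treated as
germline. Germline alleles are then excluded from the tumor track's
multiple-variant tally, and the two normal-track metrics are appended:

* ``nvaf = d_n / d_normal`` — candidate allele frequency in the normal
* ``lncr = 1 - min(thr_n, d_normal) / thr_n`` — low normal-coverage risk
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import replace
from typing import Optional

from .core import (
    MetricVector,
    NormalTrackSummary,
    PileupContext,
    PileupCounts,
    ThresholdConfig,
    WeightConfig,
)
from . import metrics as M
from .alignment_io import catalog_mismatches
from .tagscore import vscore

logger = logging.getLogger(__name__)


def detect_germline_in_normal(
    normal_ctx: PileupContext,
    cfg: ThresholdConfig,
    vscore_cutoff: Optional[float] = None,
    weights: Optional[WeightConfig] = None,
) -> NormalTrackSummary:
    """Score every candidate germline allele seen in the normal pileup.

    Returns the normal-track coverage/support tallies for the somatic
    candidate plus the set of alleles judged germline (with their v-scores).
    """
    if vscore_cutoff is None:
        vscore_cutoff = cfg.germline_vscore_cutoff
    weights = weights or WeightConfig()
    ref_key = normal_ctx.ref_base_at(normal_ctx.variant.locus.pos)
    candidate_key = normal_ctx.variant.allele_key

    covering = [r for r in normal_ctx.reads if r.covers]
    d_normal = len(covering)
    d_n = sum(1 for r in covering if r.allele == candidate_key)
    summary = NormalTrackSummary(d_normal=d_normal, d_n=d_n)
    if d_normal == 0:
        return summary

    allele_depth = Counter(r.allele for r in covering if r.allele is not None)
    normal_cfg = replace(cfg, thr=cfg.thr_n)
    for allele, depth in sorted(allele_depth.items()):
        if allele == ref_key or depth < cfg.germline_min_support:
            continue
        counts = M.tally_counts(
            normal_ctx.reads, normal_cfg, candidate_key=allele, ref_base=ref_key)
        ctx_a = PileupContext(
            variant=normal_ctx.variant,
            reads=_with_support(normal_ctx.reads, allele),
            mismatches=catalog_mismatches(normal_ctx.reads, candidate_key=allele),
            window_n=normal_ctx.window_n,
            ref_window=normal_ctx.ref_window,
            ref_window_start=normal_ctx.ref_window_start,
        )
        vec, _ = M.compute_metric_vector(ctx_a, normal_cfg, counts=counts)
        score = vscore(vec, weights)
        if score <= vscore_cutoff:
            summary.germline_alleles[allele] = score
    return summary


def _with_support(reads, allele_key):
    out = []
    for r in reads:
        r2 = replace(r, supports=(r.allele == allele_key))
        out.append(r2)
    return out


def somatic_metrics(summary: NormalTrackSummary, cfg: ThresholdConfig) -> tuple[float, float]:
    """(nvaf, lncr) from the normal-track summary alone."""
    nvaf = summary.d_n / summary.d_normal if summary.d_normal else 0.0
    lncr = 1.0 - min(cfg.thr_n, summary.d_normal) / cfg.thr_n
    return nvaf, lncr


def score_somatic_variant(
    tumor_ctx: PileupContext,
    normal_ctx: PileupContext,
    cfg: ThresholdConfig,
    weights: Optional[WeightConfig] = None,
) -> tuple[MetricVector, PileupCounts, NormalTrackSummary]:
    """18-metric vector for a somatic candidate (tumor + normal track)."""
    summary = detect_germline_in_normal(normal_ctx, cfg, weights=weights)
    germ = set(summary.germline_alleles) - {tumor_ctx.variant.allele_key}
    vec, counts = M.compute_metric_vector(tumor_ctx, cfg, germline_alleles=germ)
    vec.nvaf, vec.lncr = somatic_metrics(summary, cfg)
    return vec, counts, summary
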