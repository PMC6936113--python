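"""Read-level artifact metrics for one candidate variant.

Each public function implements one named metric of the scoring model:

* ``lcr``  low-coverage risk            1 - min(thr, d)/thr
* ``vafr`` allele-frequency risk        1 - d_m/d
* ``nh``/``ne``  near-head / near-end supporter rates
* ``ni``/``nd``  adjacent insertion / deletion rates
* ``sse`` same start/end rate, ``dir`` directional rate
* ``lm``  low-MAPQ supporter rate
* ``mm``  multiple-mismatch score over the +/-10 bp window
* ``mv``  multiple-variant (third allele) rate
* ``hdr`` high-discrepancy score from linked mismatches
* ``si``  short-insert (mate overlap) rate
* ``r``/``ri``/``li``  repeat-context binary flags

A covering read counts toward d; a supporting read carries the candidate
allele and counts toward d_m. All rate denominators are guarded: an empty
pileup scores maximal risk (lcr = vafr = 1) and zero rates, with a warning.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Optional, Sequence

from .core import (
    MetricVector,
    MismatchRecord,
    PileupContext,
    PileupCounts,
    ReadEvidence,
    ThresholdConfig,
    VariantCall,
    VariantClass,
)

logger = logging.getLogger(__name__)


def tally_counts(
    reads: Sequence[ReadEvidence],
    cfg: ThresholdConfig,
    candidate_key: Optional[str] = None,
    germline_alleles: Iterable[str] = (),
    ref_base: Optional[str] = None,
) -> PileupCounts:
    """Aggregate per-read evidence into the named pileup tallies.

    When ``candidate_key`` is given, support is re-derived from each read's
    observed allele key (used to score alternative alleles of the same
    pileup, e.g. germline detection in the normal track); otherwise the
    stored ``supports`` flag is used.
    """
    germ = set(germline_alleles)
    counts = PileupCounts()
    span_groups: Counter = Counter()
    strand_groups: Counter = Counter()
    other_alleles: set[str] = set()
    for read in reads:
        if not read.covers:
            continue
        counts.d += 1
        supports = (read.allele == candidate_key) if candidate_key is not None else read.supports
        allele = read.allele
        if allele is not None and allele != ref_base and not supports and allele not in germ:
            counts.d_mv += 1
            other_alleles.add(allele)
        if not supports:
            continue
        counts.d_m += 1
        if read.dist_head <= cfg.near_dist:
            counts.d_h += 1
        if read.dist_end <= cfg.near_dist:
            counts.d_e += 1
        if read.has_adjacent_insertion:
            counts.d_insert += 1
        if read.has_adjacent_deletion:
            counts.d_del += 1
        if read.mapq < cfg.mapq_thr:
            counts.d_l += 1
        span_groups[(read.aln_start, read.aln_end)] += 1
        strand_groups[read.strand] += 1
        if read.paired:
            counts.d_p += 1
            if read.in_mate_overlap:
                counts.d_si += 1
    counts.d_s_max = max(span_groups.values(), default=0)
    counts.d_d_max = max(strand_groups.values(), default=0)
    counts.n_other_alleles = len(other_alleles)
    return counts


def coverage_metrics(counts: PileupCounts, cfg: ThresholdConfig) -> tuple[float, float]:
    """(lcr, vafr); an uncovered locus carries maximal risk on both."""
    if counts.d == 0:
        logger.warning("no covering reads at locus: lcr=vafr=1")
        return 1.0, 1.0
    lcr = 1.0 - min(cfg.thr, counts.d) / cfg.thr
    vafr = 1.0 - counts.d_m / counts.d
    return lcr, vafr


def positional_rates(counts: PileupCounts) -> tuple[float, float]:
    if counts.d_m == 0:
        logger.warning("no supporting reads: nh=ne=0")
        return 0.0, 0.0
    return counts.d_h / counts.d_m, counts.d_e / counts.d_m


def adjacent_indel_rates(counts: PileupCounts) -> tuple[float, float]:
    if counts.d_m == 0:
        logger.warning("no supporting reads: ni=nd=0")
        return 0.0, 0.0
    return counts.d_insert / counts.d_m, counts.d_del / counts.d_m


def duplication_strand_rates(counts: PileupCounts) -> tuple[float, float]:
    if counts.d_m == 0:
        logger.warning("no supporting reads: sse=dir=0")
        return 0.0, 0.0
    return counts.d_s_max / counts.d_m, counts.d_d_max / counts.d_m


def mapping_quality_rate(counts: PileupCounts, cfg: ThresholdConfig) -> float:
    # d_l tallied with strict mapq < mapq_thr
    if counts.d_m == 0:
        logger.warning("no supporting reads: lm=0")
        return 0.0
    return counts.d_l / counts.d_m


def multiple_mismatch_score(ctx: PileupContext, cfg: ThresholdConfig) -> float:
    """Sum of low-frequency mismatch depths, scaled by 100/n.

    Only mismatches whose pileup frequency depth/d falls strictly below
    ``mm_freq_thr`` enter the sum; recurrent (high-frequency) mismatches are
    the province of hdr instead.
    """
    if ctx.window_n <= 0:
        raise ValueError("window_n must be positive")
    d = sum(1 for r in ctx.reads if r.covers)
    if d == 0:
        return 0.0
    total = sum(m.depth for m in ctx.mismatches if m.depth / d < cfg.mm_freq_thr)
    return total * 100 / ctx.window_n


def multiple_variant_rate(
    ctx: PileupContext,
    germline_alleles: Iterable[str] = (),
    counts: Optional[PileupCounts] = None,
    cfg: Optional[ThresholdConfig] = None,
) -> tuple[float, int]:
    """(mv, d_mv): reads carrying a non-reference allele other than the
    candidate (and, somatic mode, not a known germline allele)."""
    if counts is None:
        counts = tally_counts(
            ctx.reads, cfg or ThresholdConfig(), germline_alleles=germline_alleles,
            ref_base=ctx.ref_base_at(ctx.variant.locus.pos),
        )
    if counts.d_m == 0:
        logger.warning("no supporting reads: mv=0")
        return 0.0, counts.d_mv
    return counts.d_mv / counts.d_m, counts.d_mv


def high_discrepancy_score(ctx: PileupContext, cfg: ThresholdConfig) -> tuple[float, float]:
    """(hdr, HR_max) from mismatches linked to supporting reads.

    HR = 2h/(d_m + d_i) per linked mismatch. When the best-linked mismatch
    reaches ``hr_thr``, hdr is the sum of all HR >= hr_thr (and may exceed 1
    when several mismatches are concordant); otherwise hdr = HR_max.
    """
    d_m = sum(1 for r in ctx.reads if r.supports)
    hrs = []
    for mm in ctx.mismatches:
        if mm.cooccurrence > 0 and d_m + mm.depth > 0:
            hrs.append(2 * mm.cooccurrence / (d_m + mm.depth))
    if not hrs:
        return 0.0, 0.0
    hr_max = max(hrs)
    if hr_max >= cfg.hr_thr:
        return sum(h for h in hrs if h >= cfg.hr_thr), hr_max
    return hr_max, hr_max


def short_insert_rate(counts: PileupCounts) -> float:
    if counts.d_p == 0:
        logger.debug("no paired supporting reads: si=0")
        return 0.0
    return counts.d_si / counts.d_p


# ---------------------------------------------------------------------------
# repeat context


def find_tandem_repeats(seq: str, cfg: ThresholdConfig) -> list[tuple[int, int, str]]:
    """Maximal tandem repeat tracts in ``seq`` as (start, end, unit).

    Half-open 0-based [start, end). Units of length 1 (homopolymers) need
    >= ``homopolymer_min`` copies, longer units >= ``min_copies``. Units are
    reduced to their primitive form before reporting.
    """
    tracts: list[tuple[int, int, str]] = []
    n = len(seq)
    for ulen in range(1, cfg.unit_len_max + 1):
        need = cfg.homopolymer_min if ulen == 1 else cfg.min_copies
        i = 0
        while i + ulen * need <= n:
            unit = seq[i:i + ulen]
            if len(set(unit)) == 0 or _primitive(unit) != unit:
                i += 1
                continue
            copies = 1
            j = i + ulen
            while j + ulen <= n and seq[j:j + ulen] == unit:
                copies += 1
                j += ulen
            if copies >= need:
                tracts.append((i, i + copies * ulen, unit))
                i = j
            else:
                i += 1
    # drop tracts fully contained in another tract of the same primitive unit
    out = []
    for t in tracts:
        if not any(
            o != t and o[0] <= t[0] and t[1] <= o[1] and _same_cycle(o[2], t[2])
            for o in tracts
        ):
            out.append(t)
    return sorted(set(out))


def _primitive(unit: str) -> str:
    for k in range(1, len(unit)):
        if len(unit) % k == 0 and unit == unit[:k] * (len(unit) // k):
            return unit[:k]
    return unit


def _same_cycle(a: str, b: str) -> bool:
    a, b = _primitive(a), _primitive(b)
    return len(a) == len(b) and b in a + a


def repeat_flags(
    variant: VariantCall, ref_window: str, ref_window_start: int, cfg: ThresholdConfig
) -> tuple[int, int, int]:
    """(r, ri, li) binary repeat-context flags.

    r: a tandem repeat tract lies within ``repeat_dist`` bp of the locus.
    ri: the variant is an insertion whose inserted bases are whole copies of
    a nearby tract's primitive unit (cyclic rotations allowed — left
    alignment makes the rotation arbitrary).
    li: the variant is an insertion of >= ``li_len`` bp duplicating the
    reference immediately before or after the locus.
    """
    locus_idx = variant.locus.pos - ref_window_start
    lo = locus_idx - cfg.repeat_dist
    hi = locus_idx + cfg.repeat_dist
    near = [
        t for t in find_tandem_repeats(ref_window, cfg)
        if t[0] <= hi and t[1] - 1 >= lo
    ]
    r = 1 if near else 0
    ri = 0
    li = 0
    if variant.vclass is VariantClass.INS:
        ins = variant.inserted
        if r:
            for _, _, unit in near:
                if len(ins) % len(unit) == 0:
                    for shift in range(len(unit)):
                        rot = unit[shift:] + unit[:shift]
                        if ins == rot * (len(ins) // len(unit)):
                            ri = 1
                            break
                if ri:
                    break
        if len(ins) >= cfg.li_len:
            after = ref_window[locus_idx + 1: locus_idx + 1 + len(ins)]
            before = ref_window[max(0, locus_idx + 1 - len(ins)): locus_idx + 1]
            if ins == after or ins == before:
                li = 1
    return r, ri, li


def compute_metric_vector(
    ctx: PileupContext,
    cfg: ThresholdConfig,
    germline_alleles: Iterable[str] = (),
    counts: Optional[PileupCounts] = None,
) -> tuple[MetricVector, PileupCounts]:
    """All 16 germline metrics for one pileup (somatic extras are appended
    by the somatic module). Deterministic and order-invariant in the reads."""
    if counts is None:
        counts = tally_counts(
            ctx.reads, cfg, germline_alleles=germline_alleles,
            ref_base=_candidate_ref_key(ctx),
        )
    lcr, vafr = coverage_metrics(counts, cfg)
    nh, ne = positional_rates(counts)
    ni, nd = adjacent_indel_rates(counts)
    sse, dir_ = duplication_strand_rates(counts)
    lm = mapping_quality_rate(counts, cfg)
    mm = multiple_mismatch_score(ctx, cfg)
    mv, _ = multiple_variant_rate(ctx, germline_alleles, counts=counts, cfg=cfg)
    hdr, _ = high_discrepancy_score(ctx, cfg)
    si = short_insert_rate(counts)
    r, ri, li = repeat_flags(ctx.variant, ctx.ref_window, ctx.ref_window_start, cfg)
    vec = MetricVector(
        lcr=lcr, vafr=vafr, nh=nh, ne=ne, ni=ni, nd=nd, sse=sse, dir=dir_,
        lm=lm, mm=mm, mv=mv, hdr=hdr, si=si, r=r, ri=ri, li=li,
    )
    return vec, counts


def _candidate_ref_key(ctx: PileupContext) -> str:
    """Reference allele key at the locus (the anchor base)."""
    return ctx.ref_base_at(ctx.variant.locus.pos)
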