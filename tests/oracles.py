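"""Independent brute-force recounts used as test oracles.

Every function here recomputes a quantity with plain loops from first
principles, independent of the implementation's aggregation path.
"""

from collections import Counter


def brute_metrics(ctx, cfg, germline=(), normal=None):
    """Naive per-read recount of every rate metric for a pileup context."""
    ref_base = ctx.ref_window[ctx.variant.locus.pos - ctx.ref_window_start]
    covering = [r for r in ctx.reads if r.covers]
    supporters = [r for r in covering if r.supports]
    d, d_m = len(covering), len(supporters)

    out = {}
    out["lcr"] = 1 - min(cfg.thr, d) / cfg.thr if d else 1.0
    out["vafr"] = 1 - d_m / d if d else 1.0
    out["nh"] = (
        sum(1 for r in supporters if r.dist_head <= cfg.near_dist) / d_m if d_m else 0.0
    )
    out["ne"] = (
        sum(1 for r in supporters if r.dist_end <= cfg.near_dist) / d_m if d_m else 0.0
    )
    out["ni"] = (
        sum(1 for r in supporters if r.has_adjacent_insertion) / d_m if d_m else 0.0
    )
    out["nd"] = (
        sum(1 for r in supporters if r.has_adjacent_deletion) / d_m if d_m else 0.0
    )
    spans = Counter((r.aln_start, r.aln_end) for r in supporters)
    out["sse"] = max(spans.values()) / d_m if d_m else 0.0
    strands = Counter(r.strand for r in supporters)
    out["dir"] = max(strands.values()) / d_m if d_m else 0.0
    out["lm"] = (
        sum(1 for r in supporters if r.mapq < cfg.mapq_thr) / d_m if d_m else 0.0
    )

    # mismatch catalog recomputed from per-read link sets
    depth = Counter()
    cooc = Counter()
    for r in ctx.reads:
        for mid in r.linked_mismatch_ids:
            depth[mid] += 1
            if r.supports:
                cooc[mid] += 1
    total = sum(v for mid, v in depth.items() if d and v / d < cfg.mm_freq_thr)
    out["mm"] = total * 100 / ctx.window_n if d else 0.0

    germ = set(germline)
    d_mv = sum(
        1
        for r in covering
        if r.allele is not None
        and r.allele != ref_base
        and not r.supports
        and r.allele not in germ
    )
    out["mv"] = d_mv / d_m if d_m else 0.0
    out["d_mv"] = d_mv

    hrs = [
        2 * cooc[mid] / (d_m + depth[mid])
        for mid in sorted(depth)
        if cooc[mid] > 0
    ]
    if not hrs:
        out["hdr"] = 0.0
    else:
        hr_max = max(hrs)
        out["hdr"] = (
            sum(h for h in hrs if h >= cfg.hr_thr) if hr_max >= cfg.hr_thr else hr_max
        )

    d_p = sum(1 for r in supporters if r.paired)
    d_si = sum(1 for r in supporters if r.paired and r.in_mate_overlap)
    out["si"] = d_si / d_p if d_p else 0.0

    if normal is not None:
        out["nvaf"] = normal.d_n / normal.d_normal if normal.d_normal else 0.0
        out["lncr"] = 1 - min(cfg.thr_n, normal.d_normal) / cfg.thr_n
    return out


def brute_sweep(scores, labels, beta, thresholds):
    """Exhaustive confusion counting at each threshold (positive = score < t)."""
    rows = []
    for t in thresholds:
        tp = sum(1 for s, y in zip(scores, labels) if s < t and y)
        fp = sum(1 for s, y in zip(scores, labels) if s < t and not y)
        fn = sum(1 for s, y in zip(scores, labels) if s >= t and y)
        tn = sum(1 for s, y in zip(scores, labels) if s >= t and not y)
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        if p == 0 and r == 0:
            fb = 0.0
        else:
            fb = (1 + beta**2) * p * r / (beta**2 * p + r)
        rows.append((t, tp, fp, tn, fn, p, r, fb))
    return rows


def brute_auc(scores, labels):
    """Pairwise Mann-Whitney AUC with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def linear_scan_reads(bam, chrom, start0, end0, exclude_duplicates=True):
    """Names of primary reads whose aligned span intersects [start0, end0)."""
    names = []
    for read in bam.fetch(until_eof=True):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if exclude_duplicates and read.is_duplicate:
            continue
        if read.reference_name != chrom:
            continue
        if read.reference_start < end0 and (read.reference_end or 0) > start0:
            names.append(read.query_name + ("/2" if read.is_read2 else "/1"))
    return sorted(names)
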