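"""Alignment, variant and reference file handling.

Reads coordinate-sorted indexed BAM/SAM through pysam (index-backed
retrieval, logarithmic in track size), classifies per-read support for a
candidate allele from the CIGAR, catalogs nearby substitution mismatches,
and writes scored output (TSV + annotated VCF).

Read filtering matches a default review track: duplicates, secondary,
supplementary and unmapped records are excluded before any counting
(configurable). Head/end distances are measured in aligned-reference space
from the first/last aligned (non-clipped) base; soft-clips are invisible.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pysam

from .core import (
    GenomicLocus,
    MismatchRecord,
    PileupContext,
    ReadEvidence,
    ScoredVariant,
    ThresholdConfig,
    VariantCall,
)

logger = logging.getLogger(__name__)

CIGAR_M, CIGAR_I, CIGAR_D, CIGAR_N, CIGAR_S = 0, 1, 2, 3, 4
CIGAR_EQ, CIGAR_X = 7, 8
_REF_CONSUMING = {CIGAR_M, CIGAR_D, CIGAR_N, CIGAR_EQ, CIGAR_X}
_QUERY_CONSUMING = {CIGAR_M, CIGAR_I, CIGAR_S, CIGAR_EQ, CIGAR_X}


class DataError(RuntimeError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# VCF input


def normalize_variant(chrom: str, pos: int, ref: str, alt: str,
                      ref_seq: Optional[str] = None) -> VariantCall:
    """Minimal left-aligned representation of one (ref, alt) pair.

    Trims the shared suffix, then the shared prefix (keeping one anchor
    base for indels), then shifts indels leftward while the reference
    permits (``ref_seq`` is the full contig sequence; 0-based indexing).
    """
    ref, alt = ref.upper(), alt.upper()
    changed = True
    while changed:
        changed = False
        if ref[-1] == alt[-1]:
            if len(ref) > 1 and len(alt) > 1:
                ref, alt = ref[:-1], alt[:-1]
                changed = True
            elif pos > 1 and ref_seq is not None:
                prev = ref_seq[pos - 2].upper()
                ref, alt = prev + ref[:-1], prev + alt[:-1]
                pos -= 1
                changed = True
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantCall(GenomicLocus(chrom, pos), ref, alt)


def load_variants(
    vcf_path: str,
    region: Optional[tuple[str, int, int]] = None,
    reference: Optional["pysam.FastaFile"] = None,
) -> list[VariantCall]:
    """One VariantCall per (record, alt) pair, multi-allelics split,
    indels left-aligned when a reference is supplied, sorted by locus."""
    calls: list[VariantCall] = []
    try:
        vf = pysam.VariantFile(vcf_path)
    except (ValueError, OSError) as exc:
        raise DataError(f"malformed VCF {vcf_path}: {exc}") from exc
    with vf:
        if reference is not None:
            known = set(reference.references)
        records = vf.fetch(*region) if region else vf
        for rec in records:
            if reference is not None and rec.chrom not in known:
                raise DataError(
                    f"contig {rec.chrom!r} (VCF line at {rec.chrom}:{rec.pos}) "
                    "absent from reference"
                )
            ref_seq = reference.fetch(rec.chrom) if reference is not None else None
            for alt in rec.alts or ():
                if set(alt.upper()) - set("ACGT"):
                    logger.warning("skipping symbolic/non-ACGT alt %s at %s:%d",
                                   alt, rec.chrom, rec.pos)
                    continue
                calls.append(normalize_variant(rec.chrom, rec.pos, rec.ref, alt, ref_seq))
    calls.sort(key=lambda c: (c.locus.chrom, c.locus.pos, c.ref, c.alt))
    return calls


# ---------------------------------------------------------------------------
# read retrieval and support classification


@dataclass
class _Walk:
    """One pass over a read's CIGAR: matched bases and indel events."""

    base_at: dict  # ref_pos0 -> query_pos
    insertions: list  # (ref_boundary0, length, seq)
    deletions: list  # (ref_start0, length)


def _walk_cigar(read: "pysam.AlignedSegment") -> _Walk:
    seq = read.query_sequence
    if seq is None:
        raise DataError(f"read {read.query_name} has no sequence")
    base_at: dict[int, int] = {}
    insertions: list[tuple[int, int, str]] = []
    deletions: list[tuple[int, int]] = []
    qpos, rpos = 0, read.reference_start
    for op, length in read.cigartuples or ():
        if op in (CIGAR_M, CIGAR_EQ, CIGAR_X):
            for k in range(length):
                base_at[rpos + k] = qpos + k
            qpos += length
            rpos += length
        elif op == CIGAR_I:
            insertions.append((rpos, length, seq[qpos:qpos + length]))
            qpos += length
        elif op in (CIGAR_D, CIGAR_N):
            if op == CIGAR_D:
                deletions.append((rpos, length))
            rpos += length
        elif op == CIGAR_S:
            qpos += length
    if qpos != len(seq):
        raise DataError(
            f"read {read.query_name}: CIGAR consumes {qpos} query bases, "
            f"sequence has {len(seq)}"
        )
    return _Walk(base_at, insertions, deletions)


def classify_support(read: "pysam.AlignedSegment", variant: VariantCall) -> str:
    """'supports', 'covers_only' or 'no_cover' for one aligned record."""
    pos0 = variant.locus.pos - 1
    if not (read.reference_start <= pos0 < (read.reference_end or read.reference_start)):
        return "no_cover"
    walk = _walk_cigar(read)
    allele = _observed_allele(walk, read.query_sequence, variant)
    return "supports" if allele == variant.allele_key else "covers_only"


def _observed_allele(walk: _Walk, seq: str, variant: VariantCall) -> Optional[str]:
    """Observed allele key at the candidate locus (see ReadEvidence)."""
    pos0 = variant.locus.pos - 1
    for rstart, length, ins_seq in walk.insertions:
        if rstart == pos0 + 1:
            return "+" + ins_seq
    for rstart, length in walk.deletions:
        if rstart == pos0 + 1:
            return f"-{length}"
        if rstart <= pos0 < rstart + length:
            return "*"
    qpos = walk.base_at.get(pos0)
    if qpos is None:
        return None
    return seq[qpos]


def _mate_span(read: "pysam.AlignedSegment") -> Optional[tuple[int, int]]:
    """Mate's aligned reference span [start0, end0), from the MC tag when
    present, else approximated with this read's query length."""
    if not read.is_paired or read.mate_is_unmapped:
        return None
    if read.next_reference_id != read.reference_id:
        return None
    start = read.next_reference_start
    if read.has_tag("MC"):
        ref_len = _cigar_ref_len(read.get_tag("MC"))
    else:
        ref_len = read.query_length or read.infer_query_length() or 0
    return start, start + ref_len


_CIGAR_OPS = "MIDNSHP=X"


def _cigar_ref_len(cigar: str) -> int:
    total = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if _CIGAR_OPS.index(ch) in _REF_CONSUMING:
                total += int(num)
            num = ""
    return total


def build_read_evidence(
    read: "pysam.AlignedSegment",
    variant: VariantCall,
    cfg: ThresholdConfig,
) -> ReadEvidence:
    """Fully populated per-read evidence for one candidate locus."""
    pos0 = variant.locus.pos - 1
    start0, end0 = read.reference_start, read.reference_end or read.reference_start
    covers = start0 <= pos0 < end0
    walk = _walk_cigar(read)
    allele = _observed_allele(walk, read.query_sequence, variant) if covers else None
    supports = covers and allele == variant.allele_key
    if covers:
        left = pos0 - start0
        right = (end0 - 1) - pos0
        dist_head, dist_end = (right, left) if read.is_reverse else (left, right)
    else:
        dist_head = dist_end = 0

    has_ins = False
    for rstart, length, _seq in walk.insertions:
        if variant.vclass.value == "INS" and rstart == pos0 + 1 and length == len(variant.inserted):
            continue  # the candidate event itself
        if min(abs(rstart - 1 - pos0), abs(rstart - pos0)) <= cfg.near_dist:
            has_ins = True
    has_del = False
    for rstart, length in walk.deletions:
        if variant.vclass.value == "DEL" and rstart == pos0 + 1 and length == variant.deleted_len:
            continue
        dist = 0 if rstart <= pos0 < rstart + length else min(
            abs(rstart - pos0), abs(rstart + length - 1 - pos0))
        if dist <= cfg.near_dist:
            has_del = True

    mate = _mate_span(read)
    in_overlap = bool(covers and mate and mate[0] <= pos0 < mate[1])

    return ReadEvidence(
        read_id=f"{read.query_name}/{2 if read.is_read2 else 1}",
        covers=covers,
        supports=supports,
        allele=allele,
        dist_head=dist_head,
        dist_end=dist_end,
        strand="-" if read.is_reverse else "+",
        mapq=read.mapping_quality,
        aln_start=start0 + 1,
        aln_end=end0,
        has_adjacent_insertion=has_ins,
        has_adjacent_deletion=has_del,
        paired=mate is not None,
        in_mate_overlap=in_overlap,
        linked_mismatch_ids=frozenset(),
    )


def _window_mismatches(
    read: "pysam.AlignedSegment",
    variant: VariantCall,
    ref_window: str,
    ref_window_start: int,
    cfg: ThresholdConfig,
) -> frozenset:
    """(1-based ref pos, base) substitutions this read carries inside the
    +/-window_pad catalog window, the locus itself excluded."""
    pos0 = variant.locus.pos - 1
    walk = _walk_cigar(read)
    seq = read.query_sequence
    ids = []
    for rpos, qpos in walk.base_at.items():
        if rpos == pos0:
            continue
        if abs(rpos - pos0) > cfg.window_pad:
            continue
        idx = rpos + 1 - ref_window_start
        if not 0 <= idx < len(ref_window):
            continue
        ref_base = ref_window[idx].upper()
        base = seq[qpos].upper()
        if base != ref_base and base != "N" and ref_base != "N":
            ids.append((rpos + 1, base))
    return frozenset(ids)


def fetch_reads(
    alignment: "pysam.AlignmentFile | str",
    locus: GenomicLocus,
    pad: int = 0,
    variant: Optional[VariantCall] = None,
    cfg: Optional[ThresholdConfig] = None,
) -> list[ReadEvidence]:
    """Primary, non-duplicate reads whose aligned span intersects
    [pos - pad, pos + pad]; index-backed region query."""
    cfg = cfg or ThresholdConfig()
    force_no_support = variant is None
    if variant is None:
        # locus-only query: distances/flags populated, support left False
        variant = VariantCall(locus, "A", "C")
    own = False
    if isinstance(alignment, str):
        alignment = open_alignment(alignment)
        own = True
    try:
        out = []
        start = max(0, locus.pos - 1 - pad)
        end = locus.pos + pad
        for read in alignment.fetch(locus.chrom, start, end):
            if _filtered(read, cfg):
                continue
            ev = build_read_evidence(read, variant, cfg)
            if force_no_support:
                ev.supports = False
            out.append(ev)
        out.sort(key=lambda r: (r.aln_start, r.aln_end, r.read_id))
        return out
    finally:
        if own:
            alignment.close()


def _filtered(read: "pysam.AlignedSegment", cfg: ThresholdConfig) -> bool:
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return True
    if cfg.exclude_duplicates and read.is_duplicate:
        return True
    return False


def open_alignment(path: str) -> "pysam.AlignmentFile":
    try:
        af = pysam.AlignmentFile(path)
    except (ValueError, OSError) as exc:
        raise DataError(f"cannot open alignment {path}: {exc}") from exc
    if not af.has_index():
        raise DataError(
            f"alignment {path} has no index; create one with 'samtools index'")
    return af


def catalog_mismatches(reads: Sequence[ReadEvidence],
                       candidate_key: Optional[str] = None) -> list[MismatchRecord]:
    """Aggregate per-read linked mismatch ids into MismatchRecords.

    depth = reads carrying the (pos, base) substitution; cooccurrence = those
    that also support the candidate (optionally redefined by allele key).
    """
    depth: dict[tuple[int, str], int] = {}
    cooc: dict[tuple[int, str], int] = {}
    for read in reads:
        supports = (read.allele == candidate_key) if candidate_key is not None else read.supports
        for mid in read.linked_mismatch_ids:
            depth[mid] = depth.get(mid, 0) + 1
            if supports:
                cooc[mid] = cooc.get(mid, 0) + 1
    return [
        MismatchRecord(pos=pos, allele=base, depth=depth[(pos, base)],
                       cooccurrence=cooc.get((pos, base), 0))
        for pos, base in sorted(depth)
    ]


def build_pileup_context(
    alignment: "pysam.AlignmentFile",
    reference: "pysam.FastaFile",
    variant: VariantCall,
    cfg: ThresholdConfig,
) -> PileupContext:
    """Assemble the full scoring context for one candidate on one track."""
    locus = variant.locus
    if locus.chrom not in reference.references:
        raise DataError(f"contig {locus.chrom!r} absent from reference")
    contig_len = reference.get_reference_length(locus.chrom)
    pad = max(cfg.window_pad, cfg.li_len + 5, cfg.repeat_dist + cfg.unit_len_max * 8)
    win_start0 = max(0, locus.pos - 1 - pad)
    win_end0 = min(contig_len, locus.pos + pad)
    ref_window = reference.fetch(locus.chrom, win_start0, win_end0).upper()
    ref_window_start = win_start0 + 1

    pos0 = locus.pos - 1
    lo = max(0, pos0 - cfg.window_pad)
    hi = min(contig_len - 1, pos0 + cfg.window_pad)
    window_n = (hi - lo + 1) - 1  # locus excluded

    evidences = []
    for read in alignment.fetch(locus.chrom, pos0, pos0 + 1):
        if _filtered(read, cfg):
            continue
        ev = build_read_evidence(read, variant, cfg)
        ev.linked_mismatch_ids = _window_mismatches(
            read, variant, ref_window, ref_window_start, cfg)
        evidences.append(ev)
    mismatches = catalog_mismatches(evidences)
    return PileupContext(
        variant=variant,
        reads=evidences,
        mismatches=mismatches,
        window_n=window_n,
        ref_window=ref_window,
        ref_window_start=ref_window_start,
    )


# ---------------------------------------------------------------------------
# scored output

TSV_FIXED = ("chrom", "pos", "ref", "alt", "vclass", "d", "d_m")


def write_scored_output(
    scored: Sequence[ScoredVariant],
    out_prefix: str,
    vcf_in: Optional[str] = None,
    somatic: bool = False,
    header_meta: Optional[dict] = None,
) -> tuple[str, str]:
    """Write ``<prefix>.tsv`` and ``<prefix>.vcf``.

    The TSV has one row per variant with all metric values, the v-score
    (2 decimals) and semicolon-joined tags. The VCF is a copy of the input
    with INFO keys VS (Float, per alt) and VT ('|'-joined tags per alt)
    added; without an input VCF a minimal valid one is generated.
    """
    from .core import GERMLINE_METRICS, SOMATIC_METRICS

    names = SOMATIC_METRICS if somatic else GERMLINE_METRICS
    tsv_path = out_prefix + ".tsv"
    vcf_path = out_prefix + ".vcf"
    with open(tsv_path, "w") as fh:
        for key in sorted(header_meta or {}):
            fh.write(f"# {key}={header_meta[key]}\n")
        fh.write("\t".join(TSV_FIXED + names + ("vscore", "tags")) + "\n")
        for sv in scored:
            md = sv.metrics.as_dict(somatic=somatic)
            row = [
                sv.variant.locus.chrom, str(sv.variant.locus.pos),
                sv.variant.ref, sv.variant.alt, sv.variant.vclass.value,
                str(sv.counts.d), str(sv.counts.d_m),
            ]
            row += [_fmt(md[n]) for n in names]
            row += [f"{sv.vscore:.2f}", sv.tag_string]
            fh.write("\t".join(row) + "\n")

    lookup = {
        sv.variant.key: sv for sv in scored
    }
    _write_annotated_vcf(lookup, scored, vcf_in, vcf_path)
    return tsv_path, vcf_path


def _fmt(x: float) -> str:
    return f"{x:.4f}".rstrip("0").rstrip(".") or "0"


_VS_HEADER = '##INFO=<ID=VS,Number=A,Type=Float,Description="Weighted artifact v-score">'
_VT_HEADER = '##INFO=<ID=VT,Number=A,Type=String,Description="Review tags, |-joined per alt">'


def _write_annotated_vcf(lookup, scored, vcf_in, vcf_path) -> None:
    if vcf_in is not None:
        with open(vcf_in) as fh:
            lines = fh.read().splitlines()
    else:
        contigs = sorted({sv.variant.locus.chrom for sv in scored})
        lines = ["##fileformat=VCFv4.2"]
        lines += [f"##contig=<ID={c}>" for c in contigs]
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
        for sv in scored:
            v = sv.variant
            lines.append("\t".join([
                v.locus.chrom, str(v.locus.pos), ".", v.ref, v.alt, ".", ".", "."]))
    out = []
    for line in lines:
        if line.startswith("##"):
            out.append(line)
            continue
        if line.startswith("#CHROM"):
            out.append(_VS_HEADER)
            out.append(_VT_HEADER)
            out.append(line)
            continue
        f = line.split("\t")
        chrom, pos, ref = f[0], int(f[1]), f[3]
        vs_vals, vt_vals = [], []
        any_hit = False
        for alt in f[4].split(","):
            norm = normalize_variant(chrom, pos, ref, alt) if set(alt) <= set("ACGT") else None
            sv = lookup.get(norm.key) if norm else None
            if sv is None:
                vs_vals.append(".")
                vt_vals.append(".")
            else:
                any_hit = True
                vs_vals.append(f"{sv.vscore:.2f}")
                vt_vals.append("|".join(sorted(t.value for t in sv.tags)) or ".")
        if any_hit:
            extra = f"VS={','.join(vs_vals)};VT={','.join(vt_vals)}"
            f[7] = extra if f[7] in (".", "") else f[7] + ";" + extra
        out.append("\t".join(f))
    with open(vcf_path, "w") as fh:
        fh.write("\n".join(out) + "\n")
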