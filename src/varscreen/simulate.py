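"""Synthetic paired-end pileups with injected artifact signatures.

Every review tag has a corresponding generator signature that plants the
artifact into an otherwise clean pileup (depth 50, VAF 0.5, 100 bp reads,
300 +/- 30 bp fragments, balanced strands, MAPQ 60), so the whole scoring
path is testable offline. Truth convention: a ``none``-signature variant is
a true variant, an artifact-signature variant is a false positive — this is
a simulation convention, not a biological claim.

What this emulates: coverage, allele fraction, strand/placement composition,
MAPQ, adjacent indels, linked and scattered mismatches, mate overlap, repeat
context, and a matched normal track. What it does not: base-quality error
models, alignment ambiguity, GC bias — results on real data can differ where
those dominate.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pysam

from .core import GenomicLocus, Tag, ThresholdConfig, VariantCall

logger = logging.getLogger(__name__)

BASES = "ACGT"
READ_LEN = 100
FRAG_MEAN = 300
FRAG_SD = 30
SHORT_FRAG = 160  # < 2 read lengths so mates overlap at the locus

SIGNATURE_TO_TAG: dict[str, Optional[Tag]] = {
    "none": None,
    "near_head": Tag.HE,
    "near_end": Tag.EN,
    "strand_bias": Tag.D,
    "same_start_end": Tag.SSE,
    "low_mapq": Tag.LM,
    "adjacent_insertion": Tag.NI,
    "adjacent_deletion": Tag.ND,
    "linked_mismatch": Tag.HDR,
    "multi_mismatch": Tag.MM,
    "multi_allele": Tag.MV,
    "low_vaf": Tag.LVF,
    "low_coverage": Tag.LC,
    "short_insert_overlap": Tag.SI,
    "repeat_context": Tag.RR,
    "repeat_unit_insertion": Tag.RI,
    "large_duplicative_insertion": Tag.AO,
    "tumor_in_normal": Tag.VN,
    "no_normal_coverage": Tag.NCN,
    "low_normal_coverage": Tag.LCN,
}
SIGNATURES = tuple(SIGNATURE_TO_TAG)
SOMATIC_SIGNATURES = ("tumor_in_normal", "no_normal_coverage", "low_normal_coverage")


@dataclass
class ArtifactSpec:
    """Conditions for one simulated pileup."""

    signature: str = "none"
    intensity: float = 1.0  # fraction of supporting reads carrying the signature
    depth: int = 50
    vaf: float = 0.5
    normal_depth: int = 40
    normal_vaf: float = 0.0

    def __post_init__(self) -> None:
        if self.signature not in SIGNATURE_TO_TAG:
            raise ValueError(f"unknown signature {self.signature!r}")
        if not 0 <= self.intensity <= 1 or not 0 <= self.vaf <= 1:
            raise ValueError("intensity and vaf must lie in [0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")

    @staticmethod
    def for_signature(signature: str, strong: bool = True) -> "ArtifactSpec":
        """Canonical super-threshold (``strong``) or clearly sub-threshold
        conditions for one signature's target tag."""
        spec = ArtifactSpec(signature=signature)
        if signature == "low_coverage":
            spec = replace(spec, depth=8 if strong else 30)
        elif signature == "low_vaf":
            spec = replace(spec, depth=60, vaf=4 / 60 if strong else 0.5)
        elif signature == "tumor_in_normal":
            spec = replace(spec, normal_vaf=0.3 if strong else 0.0)
        elif signature == "no_normal_coverage":
            spec = replace(spec, normal_depth=0 if strong else 40)
        elif signature == "low_normal_coverage":
            spec = replace(spec, normal_depth=3 if strong else 40)
        elif not strong:
            weak = {"multi_mismatch": 0.0, "multi_allele": 0.0,
                    "low_mapq": 0.1}.get(signature, 0.3)
            spec = replace(spec, intensity=weak)
        return spec


# ---------------------------------------------------------------------------
# reference construction


def make_reference(
    length: int,
    gc: float = 0.45,
    repeat_inserts: Sequence[tuple[int, str, int]] = (),
    seed: int = 0,
) -> tuple[str, list[tuple[int, int, str]]]:
    """Random contig sequence with optional tandem-repeat tracts.

    ``repeat_inserts`` are (start0, unit, copies); the tract overwrites the
    underlying sequence. Returns (sequence, placements) where placements are
    half-open 0-based (start, end, unit). Deterministic for a seed.
    """
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = list(rng.choice(list(BASES), size=length, p=p))
    placed = []
    for start, unit, copies in repeat_inserts:
        tract = unit * copies
        if start < 0 or start + len(tract) > length:
            raise ValueError("repeat tract outside contig")
        seq[start:start + len(tract)] = list(tract)
        placed.append((start, start + len(tract), unit))
    return "".join(seq), placed


def scrub_window(seq: list, locus0: int, cfg: ThresholdConfig,
                 rng: np.random.Generator, radius: int = 40) -> None:
    """Re-randomize bases around ``locus0`` until the window holds no tandem
    repeat tract near the locus (keeps non-repeat signatures tag-clean)."""
    from .metrics import find_tandem_repeats

    lo = max(0, locus0 - radius)
    hi = min(len(seq), locus0 + radius + 1)
    for _ in range(200):
        window = "".join(seq[lo:hi])
        tracts = find_tandem_repeats(window, cfg)
        near = [t for t in tracts
                if t[0] <= (locus0 - lo) + cfg.repeat_dist
                and t[1] - 1 >= (locus0 - lo) - cfg.repeat_dist]
        if not near:
            return
        s, e, _ = near[0]
        for k in range(lo + s, lo + e):
            prev = seq[k - 1] if k > 0 else ""
            choices = [b for b in BASES if b != prev]
            seq[k] = choices[int(rng.integers(len(choices)))]
    raise RuntimeError("could not scrub repeat context near locus")


# ---------------------------------------------------------------------------
# read construction


def _build_read(ref: str, start0: int, read_len: int,
                events: Sequence[tuple[str, int, object]]) -> tuple[str, list, int]:
    """Sequence, cigartuples and reference span of one read.

    ``events``: ('X', pos0, base) substitution; ('I', boundary0, seq)
    insertion between boundary0-1 and boundary0; ('D', start0, length)
    deletion. Events before the read start are ignored.
    """
    subs = {pos: base for kind, pos, base in events if kind == "X"}
    inss = {pos: s for kind, pos, s in events if kind == "I"}
    dels = {pos: ln for kind, pos, ln in events if kind == "D"}
    seq: list[str] = []
    cig: list[list[int]] = []

    def emit(op: int, n: int) -> None:
        if n <= 0:
            return
        if cig and cig[-1][0] == op:
            cig[-1][1] += n
        else:
            cig.append([op, n])

    rpos = start0
    while len(seq) < read_len and rpos < len(ref):
        if rpos in inss and rpos > start0 and seq:
            ins = str(inss[rpos])[: read_len - len(seq)]
            seq.extend(ins)
            emit(1, len(ins))
            if len(seq) >= read_len:
                break
        if rpos in dels and rpos > start0 and seq:
            ln = int(dels[rpos])
            emit(2, ln)
            rpos += ln
            continue
        seq.append(subs.get(rpos, ref[rpos]))
        emit(0, 1)
        rpos += 1
    return "".join(seq), [tuple(c) for c in cig], rpos - start0


def _cigar_str(cig) -> str:
    return "".join(f"{n}{'MIDNSHP=X'[op]}" for op, n in cig)


@dataclass
class SimRead:
    name: str
    start0: int
    seq: str
    cigar: list
    reverse: bool
    first_in_pair: bool
    mapq: int
    mate_start0: int
    mate_cigar: str
    tlen: int

    def to_segment(self, header: pysam.AlignmentHeader, tid: int = 0) -> pysam.AlignedSegment:
        a = pysam.AlignedSegment(header)
        a.query_name = self.name
        a.query_sequence = self.seq
        a.flag = (0x1 | 0x2
                  | (0x10 if self.reverse else 0)
                  | (0x20 if not self.reverse else 0)
                  | (0x40 if self.first_in_pair else 0x80))
        a.reference_id = tid
        a.reference_start = self.start0
        a.mapping_quality = self.mapq
        a.cigartuples = self.cigar
        a.next_reference_id = tid
        a.next_reference_start = self.mate_start0
        a.template_length = self.tlen
        a.query_qualities = pysam.qualitystring_to_array("I" * len(self.seq))
        a.set_tag("MC", self.mate_cigar)
        return a


def _make_pair(ref: str, name: str, fs: int, frag_len: int,
               events1=(), events2=(), mapq1: int = 60, mapq2: int = 60,
               read_len: int = READ_LEN) -> list[SimRead]:
    """An FR pair: forward mate at fragment start, reverse mate at its end."""
    s2 = fs + frag_len - read_len
    seq1, cig1, span1 = _build_read(ref, fs, read_len, events1)
    seq2, cig2, span2 = _build_read(ref, s2, read_len, events2)
    tlen = (s2 + span2) - fs
    r1 = SimRead(name, fs, seq1, cig1, False, True, mapq1, s2, _cigar_str(cig2), tlen)
    r2 = SimRead(name, s2, seq2, cig2, True, False, mapq2, fs, _cigar_str(cig1), -tlen)
    return [r1, r2]


def _alt_events(variant: VariantCall) -> list[tuple[str, int, object]]:
    pos0 = variant.locus.pos - 1
    vc = variant.vclass.value
    if vc == "SNV":
        return [("X", pos0, variant.alt)]
    if vc == "INS":
        return [("I", pos0 + 1, variant.inserted)]
    return [("D", pos0 + 1, variant.deleted_len)]


def simulate_variant_pileup(
    ref: str,
    variant: VariantCall,
    spec: ArtifactSpec,
    rng: np.random.Generator,
    name_prefix: str = "r",
) -> list[SimRead]:
    """Read pairs realizing ``spec`` around one candidate variant.

    Exactly ``spec.depth`` reads cover the locus (each pair contributes one
    covering mate, except the short-insert signature where both mates
    overlap the locus); VAF is realized within one read of depth * vaf.
    """
    pos0 = variant.locus.pos - 1
    sig = spec.signature
    n_alt = int(round(spec.depth * spec.vaf))
    n_ref = spec.depth - n_alt
    n_sig = int(round(spec.intensity * n_alt))
    alt_events = _alt_events(variant)
    reads: list[SimRead] = []
    serial = 0

    def frag() -> int:
        return int(np.clip(rng.normal(FRAG_MEAN, FRAG_SD), 220, 380))

    def add_covering(events, mapq=60, offset=None, forward=None, fl=None) -> None:
        nonlocal serial
        if forward is None:
            forward = serial % 2 == 0
        if offset is None:
            offset = int(rng.integers(10, READ_LEN - 10))
        fl = fl or frag()
        name = f"{name_prefix}{serial:05d}"
        serial += 1
        if forward:
            fs = pos0 - offset
            reads.extend(_make_pair(ref, name, fs, fl, events1=events, mapq1=mapq))
        else:
            # covering read is the reverse (right) mate
            fs = pos0 - offset + READ_LEN - fl
            reads.extend(_make_pair(ref, name, fs, fl, events2=events, mapq2=mapq))

    # supporting reads -------------------------------------------------------
    extra = len(variant.inserted) if variant.vclass.value == "INS" else 0
    if sig == "short_insert_overlap" and n_sig > 0:
        n_pairs = (n_sig + 1) // 2
        for i in range(n_pairs):
            shift = int(rng.integers(65, 76))
            fs = pos0 - shift
            name = f"{name_prefix}{serial:05d}"
            serial += 1
            reads.extend(_make_pair(ref, name, fs, SHORT_FRAG,
                                    events1=alt_events, events2=alt_events))
        rest = max(0, n_alt - 2 * n_pairs)
        for i in range(rest):
            add_covering(list(alt_events), offset=int(rng.integers(10, 90)),
                         forward=i % 2 == 0)
    else:
        alt_offsets = _distinct_offsets(rng, n_alt, hi=READ_LEN - 10 - extra)
        for i in range(n_alt):
            events = list(alt_events)
            mapq = 60
            offset = alt_offsets[i]
            forward = i % 2 == 0
            in_sig = i < n_sig
            if sig == "near_head" and in_sig:
                o = int(rng.integers(0, 6))
                offset = o if forward else READ_LEN - 1 - o
            elif sig == "near_end" and in_sig:
                o = int(rng.integers(0, 6))
                offset = READ_LEN - 1 - o if forward else o
            elif sig == "strand_bias" and in_sig:
                forward = True
            elif sig == "same_start_end" and in_sig:
                offset = 30
            elif sig == "low_mapq" and in_sig:
                mapq = 0
            elif sig == "adjacent_insertion" and in_sig:
                events.append(("I", pos0 + 3, ref[pos0 + 2]))
            elif sig == "adjacent_deletion" and in_sig:
                events.append(("D", pos0 + 3, 1))
            elif sig == "linked_mismatch" and in_sig:
                events.append(("X", pos0 + 3, _other_base(ref[pos0 + 3])))
            add_covering(events, mapq=mapq, offset=offset, forward=forward)

    # non-supporting (reference) reads --------------------------------------
    n_third = 0
    if sig == "multi_allele":
        n_third = min(n_ref, max(2, int(round(spec.intensity * n_alt))))
        if spec.intensity == 0:
            n_third = 0
    third_base = _other_base(ref[pos0], variant.alt if variant.vclass.value == "SNV" else None)
    n_scatter = int(round(spec.intensity * 8)) if sig == "multi_mismatch" else 0
    scatter_pos = [pos0 + off for off in (-10, -8, -6, -4, 4, 6, 8, 10)][:n_scatter]
    for j in range(n_ref):
        events: list = []
        if j < n_third:
            events.append(("X", pos0, third_base))
        elif scatter_pos:
            sp = scatter_pos.pop()
            events.append(("X", sp, _other_base(ref[sp])))
        add_covering(events)
    return reads


def _distinct_offsets(rng: np.random.Generator, n: int,
                      hi: int = READ_LEN - 10) -> list[int]:
    pool = np.arange(10, hi)
    if n <= len(pool):
        return [int(x) for x in rng.choice(pool, size=n, replace=False)]
    return [int(x) for x in rng.choice(pool, size=n, replace=True)]


def _other_base(base: str, *exclude: Optional[str]) -> str:
    for b in BASES:
        if b != base and b not in exclude:
            return b
    raise ValueError("no alternative base")


# ---------------------------------------------------------------------------
# site preparation (variant + local reference context per signature)


def prepare_site(seq: list, locus0: int, signature: str, chrom: str,
                 cfg: ThresholdConfig, rng: np.random.Generator) -> VariantCall:
    """Choose the candidate variant at ``locus0`` and shape the local
    reference so the signature's repeat context (or its absence) holds."""
    if signature in ("repeat_context", "repeat_unit_insertion"):
        scrub_window(seq, locus0, cfg, rng)
        if signature == "repeat_context":
            anchor = "C"
            seq[locus0] = anchor
            for k in range(locus0 + 2, locus0 + 9):
                seq[k] = "T"
            # keep the tract bounded
            seq[locus0 + 1] = "G"
            seq[locus0 + 9] = "G" if seq[locus0 + 9] == "T" else seq[locus0 + 9]
            return VariantCall(GenomicLocus(chrom, locus0 + 1), anchor, "A")
        seq[locus0] = "C"
        for k in range(locus0 + 1, locus0 + 8):
            seq[k] = "T"
        seq[locus0 + 8] = "G" if seq[locus0 + 8] == "T" else seq[locus0 + 8]
        if locus0 > 0 and seq[locus0 - 1] == "C":
            seq[locus0 - 1] = "A"
        return VariantCall(GenomicLocus(chrom, locus0 + 1), "C", "CT")
    scrub_window(seq, locus0, cfg, rng)
    if signature == "large_duplicative_insertion":
        ins = "".join(seq[locus0 + 1: locus0 + 26])
        if ins[-1] == seq[locus0]:
            seq[locus0] = _other_base(ins[-1])
        return VariantCall(GenomicLocus(chrom, locus0 + 1), seq[locus0], seq[locus0] + ins)
    roll = rng.random()
    anchor = seq[locus0]
    if roll < 0.7 or signature != "none":
        return VariantCall(GenomicLocus(chrom, locus0 + 1), anchor, _other_base(anchor))
    if roll < 0.85:
        ins = _other_base(anchor, seq[locus0 + 1])
        return VariantCall(GenomicLocus(chrom, locus0 + 1), anchor, anchor + ins)
    if seq[locus0 + 1] == anchor:
        seq[locus0 + 1] = _other_base(anchor)
    if seq[locus0 + 2] == seq[locus0 + 1]:
        seq[locus0 + 2] = _other_base(seq[locus0 + 1], anchor)
    return VariantCall(GenomicLocus(chrom, locus0 + 1), anchor + seq[locus0 + 1], anchor)


# ---------------------------------------------------------------------------
# whole-dataset generation


@dataclass
class SimulatedDataset:
    reference_fasta: str
    tumor_bam: str
    vcf: str
    truth_tsv: str
    normal_bam: Optional[str] = None
    variants: list = field(default_factory=list)
    truth: dict = field(default_factory=dict)  # key -> (label, signature)


DEFAULT_MIX = {
    "none": 0.4,
    "near_head": 0.05, "near_end": 0.05, "strand_bias": 0.05,
    "same_start_end": 0.05, "low_mapq": 0.05, "adjacent_insertion": 0.05,
    "adjacent_deletion": 0.05, "linked_mismatch": 0.05, "multi_mismatch": 0.05,
    "multi_allele": 0.05, "low_vaf": 0.05, "low_coverage": 0.05,
}


def generate_dataset(
    out_dir: str,
    n_variants: int,
    signature_mix: Optional[dict[str, float]] = None,
    somatic: bool = False,
    seed: int = 0,
    cfg: Optional[ThresholdConfig] = None,
    spacing: int = 400,
    chrom: str = "chr1",
) -> SimulatedDataset:
    """Write a mutually consistent FASTA / sorted-indexed BAM(s) / VCF /
    truth TSV under ``out_dir``. Deterministic for a seed."""
    mix = dict(signature_mix or DEFAULT_MIX)
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"signature mix sums to {total}, expected 1")
    for sig in mix:
        if sig not in SIGNATURE_TO_TAG:
            raise ValueError(f"unknown signature {sig!r} in mix")
        if not somatic and sig in SOMATIC_SIGNATURES:
            raise ValueError(f"signature {sig!r} requires somatic mode")
    cfg = cfg or ThresholdConfig()
    rng = np.random.default_rng(seed)
    os.makedirs(out_dir, exist_ok=True)

    margin = 400
    length = 2 * margin + max(n_variants, 1) * spacing
    seq_str, _ = make_reference(length, seed=int(rng.integers(2 ** 31)))
    seq = list(seq_str)

    signatures = _allocate(mix, n_variants)
    rng.shuffle(signatures)

    tumor_reads: list[SimRead] = []
    normal_reads: list[SimRead] = []
    variants: list[VariantCall] = []
    truth: dict = {}
    sig_of: list[str] = []
    for i in range(n_variants):
        locus0 = margin + i * spacing
        sig = signatures[i]
        variant = prepare_site(seq, locus0, sig, chrom, cfg, rng)
        spec = ArtifactSpec.for_signature(sig, strong=True)
        tumor_reads += simulate_variant_pileup(
            "".join(seq), variant, spec, rng, name_prefix=f"v{i:05d}t")
        if somatic:
            nspec = ArtifactSpec(signature="none", depth=spec.normal_depth,
                                 vaf=spec.normal_vaf)
            if nspec.depth > 0:
                normal_reads += simulate_variant_pileup(
                    "".join(seq), variant, nspec, rng, name_prefix=f"v{i:05d}n")
        variants.append(variant)
        sig_of.append(sig)
        truth[variant.key] = (1 if sig == "none" else 0, sig)

    ref_path = os.path.join(out_dir, "ref.fa")
    _write_fasta(ref_path, chrom, "".join(seq))
    tumor_bam = os.path.join(out_dir, "tumor.bam")
    write_bam(tumor_bam, chrom, length, tumor_reads)
    normal_bam = None
    if somatic:
        normal_bam = os.path.join(out_dir, "normal.bam")
        write_bam(normal_bam, chrom, length, normal_reads)
    vcf_path = os.path.join(out_dir, "calls.vcf")
    _write_vcf(vcf_path, chrom, length, variants)
    truth_path = os.path.join(out_dir, "truth.tsv")
    with open(truth_path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tlabel\tsignature\n")
        for v, sig in zip(variants, sig_of):
            label = 1 if sig == "none" else 0
            fh.write(f"{v.locus.chrom}\t{v.locus.pos}\t{v.ref}\t{v.alt}\t{label}\t{sig}\n")
    return SimulatedDataset(
        reference_fasta=ref_path, tumor_bam=tumor_bam, vcf=vcf_path,
        truth_tsv=truth_path, normal_bam=normal_bam,
        variants=variants, truth=truth,
    )


def _allocate(mix: dict[str, float], n: int) -> list[str]:
    """Largest-remainder allocation of n variants across signatures."""
    names = sorted(mix)
    exact = {s: mix[s] * n for s in names}
    counts = {s: int(exact[s]) for s in names}
    short = n - sum(counts.values())
    for s in sorted(names, key=lambda s: exact[s] - counts[s], reverse=True)[:short]:
        counts[s] += 1
    out: list[str] = []
    for s in names:
        out += [s] * counts[s]
    return out


def _write_fasta(path: str, chrom: str, seq: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")
    pysam.faidx(path)


def write_bam(path: str, chrom: str, length: int, reads: Sequence[SimRead]) -> None:
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": length}],
    })
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for r in sorted(reads, key=lambda r: (r.start0, r.name, not r.first_in_pair)):
            bam.write(r.to_segment(header))
    pysam.index(path)


def _write_vcf(path: str, chrom: str, length: int, variants: Sequence[VariantCall]) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.locus.chrom, v.locus.pos)):
            fh.write(f"{v.locus.chrom}\t{v.locus.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\n")
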