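import numpy as np
import pysam
import pytest

from varscreen.core import (
    GenomicLocus,
    MismatchRecord,
    NormalTrackSummary,
    PileupContext,
    ReadEvidence,
    ThresholdConfig,
    VariantCall,
)
from varscreen.alignment_io import catalog_mismatches

CHROM = "chr1"
POS = 1000  # 1-based candidate locus used by in-memory pileups
REF_BASE = "A"
ALT_BASE = "G"


@pytest.fixture
def cfg():
    return ThresholdConfig()


@pytest.fixture
def variant():
    return VariantCall(GenomicLocus(CHROM, POS), REF_BASE, ALT_BASE)


def make_read(
    read_id="r0",
    allele=ALT_BASE,
    covers=True,
    dist_head=40,
    dist_end=59,
    strand="+",
    mapq=60,
    aln_start=None,
    aln_end=None,
    has_adjacent_insertion=False,
    has_adjacent_deletion=False,
    paired=True,
    in_mate_overlap=False,
    linked=(),
    candidate=ALT_BASE,
):
    """A ReadEvidence with clean mid-read defaults; supports follows allele."""
    if aln_start is None:
        aln_start = POS - dist_head if strand == "+" else POS - dist_end
    if aln_end is None:
        aln_end = aln_start + 99
    return ReadEvidence(
        read_id=read_id,
        covers=covers,
        supports=covers and allele == candidate,
        allele=allele if covers else None,
        dist_head=dist_head,
        dist_end=dist_end,
        strand=strand,
        mapq=mapq,
        aln_start=aln_start,
        aln_end=aln_end,
        has_adjacent_insertion=has_adjacent_insertion,
        has_adjacent_deletion=has_adjacent_deletion,
        paired=paired,
        in_mate_overlap=in_mate_overlap and paired,
        linked_mismatch_ids=frozenset(linked),
    )


def make_context(reads, variant=None, window=None, window_start=None):
    """PileupContext over an in-memory read list; mismatch catalog derived."""
    if variant is None:
        variant = VariantCall(GenomicLocus(CHROM, POS), REF_BASE, ALT_BASE)
    if window is None:
        # fixed repeat-free window with the reference base (A) at the center
        window = "TGGTGTTAACCTTACTATACACCCGCTCCGGGGTTTGGCTC"
        window_start = variant.locus.pos - 20
    return PileupContext(
        variant=variant,
        reads=list(reads),
        mismatches=catalog_mismatches(reads),
        window_n=20,
        ref_window=window,
        ref_window_start=window_start,
    )


MISMATCH_POOL = [(POS - 7, "C"), (POS - 3, "T"), (POS + 2, "C"), (POS + 5, "T"), (POS + 9, "C")]


def random_pileup(rng, max_reads=30):
    """Randomized in-memory pileup exercising every count pathway."""
    n = int(rng.integers(0, max_reads + 1))
    alleles = [REF_BASE, REF_BASE, REF_BASE, ALT_BASE, ALT_BASE, "T", "*", "-1", "+C"]
    reads = []
    for i in range(n):
        covers = rng.random() < 0.9
        strand = "+" if rng.random() < 0.5 else "-"
        paired = rng.random() < 0.8
        n_linked = int(rng.integers(0, 3))
        linked = [MISMATCH_POOL[j] for j in rng.choice(5, size=n_linked, replace=False)]
        reads.append(
            make_read(
                read_id=f"r{i}",
                allele=alleles[int(rng.integers(len(alleles)))] if covers else None,
                covers=covers,
                dist_head=int(rng.integers(0, 100)),
                dist_end=int(rng.integers(0, 100)),
                strand=strand,
                mapq=int(rng.choice([0, 5, 9, 10, 11, 30, 60])),
                aln_start=int(rng.integers(POS - 99, POS + 1)),
                has_adjacent_insertion=rng.random() < 0.15,
                has_adjacent_deletion=rng.random() < 0.15,
                paired=paired,
                in_mate_overlap=paired and rng.random() < 0.3,
                linked=linked if covers else (),
            )
        )
    return make_context(reads)


def random_normal_summary(rng):
    d_normal = int(rng.integers(0, 61))
    d_n = int(rng.integers(0, d_normal + 1)) if d_normal else 0
    return NormalTrackSummary(d_normal=d_normal, d_n=d_n)


# ---------------------------------------------------------------------------
# raw BAM/FASTA builders for alignment_io tests


def write_fasta(path, chrom, seq):
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n{seq}\n")
    pysam.faidx(str(path))
    return str(path)


def bam_header(chrom, length):
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": chrom, "LN": length}]}
    )


def segment(
    header,
    name,
    start0,
    seq,
    cigar,
    flag=0,
    mapq=60,
    next_start0=None,
    tlen=0,
    mc=None,
):
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = seq
    a.flag = flag
    a.reference_id = 0 if not (flag & 0x4) else -1
    a.reference_start = start0 if not (flag & 0x4) else -1
    a.mapping_quality = mapq
    if not (flag & 0x4):
        a.cigarstring = cigar
    a.next_reference_id = 0 if next_start0 is not None else -1
    a.next_reference_start = next_start0 if next_start0 is not None else -1
    a.template_length = tlen
    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    if mc:
        a.set_tag("MC", mc)
    return a


def write_bam(path, header, segments):
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for seg in sorted(segments, key=lambda s: (s.reference_start if s.reference_start >= 0 else 1 << 30)):
            bam.write(seg)
    pysam.index(str(path))
    return str(path)
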