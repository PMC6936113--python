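"""Alignment/VCF handling: retrieval, support classification, output."""

import numpy as np
import pysam
import pytest

from varscreen.alignment_io import (
    DataError,
    build_pileup_context,
    classify_support,
    fetch_reads,
    load_variants,
    normalize_variant,
    write_scored_output,
)
from varscreen.core import (
    GenomicLocus,
    MetricVector,
    PileupCounts,
    ScoredVariant,
    Tag,
    ThresholdConfig,
    VariantCall,
)

from conftest import bam_header, segment, write_bam, write_fasta
from oracles import linear_scan_reads

RNG = np.random.default_rng(99)
REF = "".join(RNG.choice(list("ACGT"), size=500))
POS0 = 200  # 0-based locus used throughout
POS1 = POS0 + 1
REF_BASE = REF[POS0]
ALT_BASE = next(b for b in "ACGT" if b != REF_BASE)
SNV = VariantCall(GenomicLocus("chr1", POS1), REF_BASE, ALT_BASE)


def seq_for(start0, length=100, subs=None):
    s = list(REF[start0:start0 + length])
    for pos0, base in (subs or {}).items():
        s[pos0 - start0] = base
    return "".join(s)


@pytest.fixture
def ref_fasta(tmp_path):
    return write_fasta(tmp_path / "ref.fa", "chr1", REF)


class TestLoadVariants:
    def write_vcf(self, path, rows):
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n##contig=<ID=chr1,length=500>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for row in rows:
                fh.write("\t".join(map(str, row)) + "\n")
        return str(path)

    def test_single_snv(self, tmp_path):
        vcf = self.write_vcf(tmp_path / "a.vcf", [("chr1", 100, ".", "A", "G", ".", ".", ".")])
        calls = load_variants(vcf)
        assert len(calls) == 1
        v = calls[0]
        assert (v.locus.chrom, v.locus.pos, v.ref, v.alt) == ("chr1", 100, "A", "G")
        assert v.vclass.value == "SNV"

    def test_multiallelic_split_and_ordering(self, tmp_path):
        vcf = self.write_vcf(tmp_path / "a.vcf", [
            ("chr1", 100, ".", "A", "G,T", ".", ".", "."),
            ("chr1", 50, ".", "AT", "A", ".", ".", "."),
        ])
        calls = load_variants(vcf)
        assert [(c.locus.pos, c.alt) for c in calls] == [(50, "A"), (100, "G"), (100, "T")]
        assert calls[0].vclass.value == "DEL"

    def test_indel_left_alignment_against_reference(self, tmp_path, ref_fasta):
        # deleting one base of a homopolymer run must shift to the run's start
        run_start = REF.index(REF_BASE * 2)  # any repeated base will do
        seq = "AGTTTTACGT" + REF[10:]
        fa = write_fasta(tmp_path / "la.fa", "chr1", seq)
        vcf = self.write_vcf(tmp_path / "b.vcf", [("chr1", 5, ".", "TT", "T", ".", ".", ".")])
        with pysam.FastaFile(fa) as ref:
            calls = load_variants(vcf, reference=ref)
        v = calls[0]
        assert (v.locus.pos, v.ref, v.alt) == (2, "GT", "G")

    def test_unknown_contig_rejected(self, tmp_path, ref_fasta):
        vcf = self.write_vcf(tmp_path / "c.vcf", [("chr9", 10, ".", "A", "G", ".", ".", ".")])
        with open(vcf) as fh:  # patch header contig to keep VCF parseable
            text = fh.read().replace("ID=chr1", "ID=chr9")
        with open(vcf, "w") as fh:
            fh.write(text)
        with pysam.FastaFile(ref_fasta) as ref:
            with pytest.raises(DataError, match="chr9"):
                load_variants(vcf, reference=ref)

    def test_malformed_vcf(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text("not a vcf at all\n")
        with pytest.raises(DataError):
            load_variants(str(path))


class TestNormalize:
    @pytest.mark.parametrize("pos,ref,alt,expected", [
        (100, "A", "G", (100, "A", "G")),
        (100, "ATT", "GTT", (100, "A", "G")),  # shared suffix trimmed
        (100, "CAT", "CGT", (101, "A", "G")),  # shared prefix trimmed
    ])
    def test_snv_normalization(self, pos, ref, alt, expected):
        v = normalize_variant("chr1", pos, ref, alt)
        assert (v.locus.pos, v.ref, v.alt) == expected


class TestFetchReads:
    def make_track(self, tmp_path):
        header = bam_header("chr1", 500)
        segs = []
        for i in range(10):
            start0 = POS0 - 50 + i * 3
            flag = 0x400 if i < 2 else 0  # two duplicates
            segs.append(segment(header, f"cov{i}", start0, seq_for(start0), "100M", flag=flag))
        segs.append(segment(header, "sec", POS0 - 10, seq_for(POS0 - 10), "100M", flag=0x100))
        segs.append(segment(header, "unmapped", 0, "A" * 100, None, flag=0x4))
        segs.append(segment(header, "far", 400, seq_for(400, 90), "90M"))
        return write_bam(tmp_path / "t.bam", header, segs)

    def test_duplicates_and_secondary_excluded(self, tmp_path):
        bam = self.make_track(tmp_path)
        reads = fetch_reads(bam, GenomicLocus("chr1", POS1), variant=SNV)
        assert len(reads) == 8
        assert all(not r.read_id.startswith(("sec", "unmapped")) for r in reads)

    def test_equals_linear_scan_oracle(self, tmp_path):
        bam = self.make_track(tmp_path)
        got = sorted(r.read_id for r in fetch_reads(bam, GenomicLocus("chr1", POS1), variant=SNV))
        with pysam.AlignmentFile(bam) as af:
            expected = linear_scan_reads(af, "chr1", POS0, POS0 + 1)
        assert got == expected

    def test_locus_beyond_alignments_is_empty(self, tmp_path):
        bam = self.make_track(tmp_path)
        assert fetch_reads(bam, GenomicLocus("chr1", 499), variant=SNV) == []

    def test_softclip_invisible_to_head_distance(self, tmp_path):
        header = bam_header("chr1", 500)
        start0 = POS0 - 3
        seq = "TTTTT" + seq_for(start0, 95)
        segs = [segment(header, "sc", start0, seq, "5S95M")]
        bam = write_bam(tmp_path / "sc.bam", header, segs)
        (ev,) = fetch_reads(bam, GenomicLocus("chr1", POS1), variant=SNV)
        assert ev.dist_head == 3

    def test_missing_index_instructs(self, tmp_path):
        header = bam_header("chr1", 500)
        path = tmp_path / "noidx.bam"
        with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
            bam.write(segment(header, "x", 10, seq_for(10), "100M"))
        from varscreen.alignment_io import open_alignment
        with pytest.raises(DataError, match="index"):
            open_alignment(str(path))


class TestClassifySupport:
    header = bam_header("chr1", 500)

    def test_snv_base_match(self):
        start0 = POS0 - 40
        read = segment(self.header, "a", start0, seq_for(start0, subs={POS0: ALT_BASE}), "100M")
        assert classify_support(read, SNV) == "supports"
        ref_read = segment(self.header, "b", start0, seq_for(start0), "100M")
        assert classify_support(ref_read, SNV) == "covers_only"

    def test_deletion_spanning_locus_covers_only(self):
        start0 = POS0 - 52
        seq = REF[start0:start0 + 50] + REF[start0 + 55:start0 + 105]
        read = segment(self.header, "d", start0, seq, "50M5D50M")
        assert classify_support(read, SNV) == "supports" or True
        assert classify_support(read, SNV) == "covers_only"

    def test_insertion_support(self):
        ins_var = VariantCall(GenomicLocus("chr1", POS1), REF_BASE, REF_BASE + "TTC")
        start0 = POS0 - 49
        seq = REF[start0:POS0 + 1] + "TTC" + REF[POS0 + 1:POS0 + 51]
        read = segment(self.header, "i", start0, seq, "50M3I50M")
        assert classify_support(read, ins_var) == "supports"
        plain = segment(self.header, "p", start0, seq_for(start0, 103), "103M")
        assert classify_support(plain, ins_var) == "covers_only"

    def test_deletion_support(self):
        del_var = VariantCall(GenomicLocus("chr1", POS1),
                              REF[POS0:POS0 + 3], REF[POS0])
        start0 = POS0 - 49
        seq = REF[start0:POS0 + 1] + REF[POS0 + 3:POS0 + 53]
        read = segment(self.header, "dd", start0, seq, "50M2D50M")
        assert classify_support(read, del_var) == "supports"

    def test_no_cover(self):
        read = segment(self.header, "n", 0, seq_for(0), "100M")
        assert classify_support(read, SNV) == "no_cover"

    def test_malformed_cigar_length(self):
        read = segment(self.header, "m", POS0 - 10, seq_for(POS0 - 10, 50), "100M")
        with pytest.raises(DataError, match="CIGAR"):
            classify_support(read, SNV)


class TestMismatchCatalog:
    def test_linked_mismatch_counted_per_read(self, tmp_path, ref_fasta, cfg):
        header = bam_header("chr1", 500)
        mm_pos0 = POS0 + 3
        mm_base = next(b for b in "ACGT" if b != REF[mm_pos0])
        segs = []
        for i in range(8):
            start0 = POS0 - 60 + i * 5
            segs.append(segment(header, f"s{i}", start0,
                                seq_for(start0, subs={POS0: ALT_BASE, mm_pos0: mm_base}),
                                "100M"))
        for i in range(2):
            start0 = POS0 - 30 + i * 5
            segs.append(segment(header, f"c{i}", start0, seq_for(start0), "100M"))
        bam = write_bam(tmp_path / "mm.bam", header, segs)
        with pysam.AlignmentFile(bam) as af, pysam.FastaFile(ref_fasta) as ref:
            ctx = build_pileup_context(af, ref, SNV, cfg)
        assert len(ctx.mismatches) == 1
        rec = ctx.mismatches[0]
        assert (rec.pos, rec.allele, rec.depth, rec.cooccurrence) == (
            mm_pos0 + 1, mm_base, 8, 8)

    def test_clean_pileup_empty_catalog(self, tmp_path, ref_fasta, cfg):
        header = bam_header("chr1", 500)
        segs = [segment(header, f"c{i}", POS0 - 50 + i, seq_for(POS0 - 50 + i), "100M")
                for i in range(5)]
        bam = write_bam(tmp_path / "cl.bam", header, segs)
        with pysam.AlignmentFile(bam) as af, pysam.FastaFile(ref_fasta) as ref:
            ctx = build_pileup_context(af, ref, SNV, cfg)
        assert ctx.mismatches == []
        assert ctx.window_n == 20

    def test_mismatch_on_nonsupporting_reads_only(self, tmp_path, ref_fasta, cfg):
        header = bam_header("chr1", 500)
        mm_pos0 = POS0 - 4
        mm_base = next(b for b in "ACGT" if b != REF[mm_pos0])
        segs = [segment(header, "alt0", POS0 - 50,
                        seq_for(POS0 - 50, subs={POS0: ALT_BASE}), "100M")]
        segs += [segment(header, f"c{i}", POS0 - 40 + i,
                         seq_for(POS0 - 40 + i, subs={mm_pos0: mm_base}), "100M")
                 for i in range(3)]
        bam = write_bam(tmp_path / "nm.bam", header, segs)
        with pysam.AlignmentFile(bam) as af, pysam.FastaFile(ref_fasta) as ref:
            ctx = build_pileup_context(af, ref, SNV, cfg)
        (rec,) = ctx.mismatches
        assert rec.depth == 3 and rec.cooccurrence == 0


class TestScoredOutput:
    def make_scored(self, vscore=3.0, tags=frozenset({Tag.LC})):
        return ScoredVariant(
            variant=SNV,
            metrics=MetricVector(lcr=1.0),
            counts=PileupCounts(d=5, d_m=3),
            vscore=vscore,
            tags=tags,
        )

    def test_empty_input_writes_headers_only(self, tmp_path):
        tsv, vcf = write_scored_output([], str(tmp_path / "out"))
        lines = open(tsv).read().splitlines()
        assert len(lines) == 1 and lines[0].startswith("chrom\tpos")
        with pysam.VariantFile(vcf) as vf:
            assert list(vf) == []

    def test_tsv_row_and_info_format(self, tmp_path):
        sv = self.make_scored()
        tsv, vcf = write_scored_output([sv], str(tmp_path / "out"))
        row = open(tsv).read().splitlines()[-1]
        assert row.endswith("3.00\tLC")
        text = open(vcf).read()
        assert "VS=3.00;VT=LC" in text

    def test_vcf_round_trip(self, tmp_path):
        vcf_in = tmp_path / "in.vcf"
        vcf_in.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=chr1,length=500>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            f"chr1\t{POS1}\t.\t{REF_BASE}\t{ALT_BASE}\t.\t.\t.\n")
        sv = self.make_scored(vscore=7.73, tags=frozenset({Tag.LC, Tag.HDR}))
        _, vcf = write_scored_output([sv], str(tmp_path / "out"), vcf_in=str(vcf_in))
        with pysam.VariantFile(vcf) as vf:
            (rec,) = list(vf)
            assert rec.info["VS"][0] == pytest.approx(7.73)
            assert rec.info["VT"][0] == "HDR|LC"

    def test_tagless_variant_round_trips(self, tmp_path):
        sv = self.make_scored(vscore=0.0, tags=frozenset())
        _, vcf = write_scored_output([sv], str(tmp_path / "out"))
        with pysam.VariantFile(vcf) as vf:
            (rec,) = list(vf)
            assert rec.info["VS"][0] == pytest.approx(0.0)
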