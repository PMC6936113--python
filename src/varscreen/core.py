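"""Core domain types shared across the package.

Coordinates are 1-based inclusive for loci (VCF convention); internal window
arithmetic is half-open and 0-based where noted at each boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class VariantClass(str, Enum):
    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"


@dataclass(frozen=True, order=True)
class GenomicLocus:
    """A 1-based reference position."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"locus position must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class VariantCall:
    """One candidate variant in normalized (left-aligned, minimal) form.

    ``ref``/``alt`` follow VCF allele conventions: an SNV has single-base
    alleles; insertions/deletions carry one anchor base (``ref='A'``,
    ``alt='ATT'`` inserts TT after the anchor).
    """

    locus: GenomicLocus
    ref: str
    alt: str

    def __post_init__(self) -> None:
        for allele in (self.ref, self.alt):
            if not allele or set(allele) - set("ACGT"):
                raise ValueError(f"allele must be non-empty over ACGT: {allele!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")

    @property
    def vclass(self) -> VariantClass:
        if len(self.ref) == len(self.alt) == 1:
            return VariantClass.SNV
        if len(self.alt) > len(self.ref):
            return VariantClass.INS
        return VariantClass.DEL

    @property
    def inserted(self) -> str:
        """Inserted bases of an INS (alleles share the anchor prefix)."""
        return self.alt[len(self.ref):]

    @property
    def deleted_len(self) -> int:
        return len(self.ref) - len(self.alt)

    @property
    def allele_key(self) -> str:
        """Canonical key for the observed-allele space at the locus.

        SNV -> the alt base; INS -> ``+SEQ``; DEL -> ``-N`` (N deleted bases).
        The same key space is used for non-candidate alleles seen in reads.
        """
        vc = self.vclass
        if vc is VariantClass.SNV:
            return self.alt
        if vc is VariantClass.INS:
            return "+" + self.inserted
        return f"-{self.deleted_len}"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.locus.chrom, self.locus.pos, self.ref, self.alt)


@dataclass
class ReadEvidence:
    """Per-read observation at a candidate locus.

    ``allele`` is the observed allele key at the locus ('A'.. for a base,
    '+SEQ' insertion after the locus, '-N' deletion starting after the locus,
    '*' when an upstream deletion spans the locus, None when not covering).
    ``linked_mismatch_ids`` holds (ref_pos, base) identifiers of substitution
    mismatches this read carries inside the +/-10 bp catalog window.
    """

    read_id: str
    covers: bool
    supports: bool
    allele: Optional[str]
    dist_head: int
    dist_end: int
    strand: str  # '+' or '-'
    mapq: int
    aln_start: int  # 1-based first aligned reference base
    aln_end: int  # 1-based last aligned reference base (inclusive)
    has_adjacent_insertion: bool = False
    has_adjacent_deletion: bool = False
    paired: bool = False
    in_mate_overlap: bool = False
    linked_mismatch_ids: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.supports and not self.covers:
            raise ValueError("supports implies covers")
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")
        if self.covers and (self.dist_head < 0 or self.dist_end < 0):
            raise ValueError("covering read must have non-negative head/end distances")


@dataclass(frozen=True)
class MismatchRecord:
    """A (position, allele) substitution near the candidate locus.

    ``depth`` is v_i/d_i — reads carrying this mismatch; ``cooccurrence`` is
    h — reads carrying both the mismatch and the candidate allele.
    """

    pos: int  # 1-based reference position
    allele: str
    depth: int
    cooccurrence: int

    def __post_init__(self) -> None:
        if not (0 <= self.cooccurrence <= self.depth):
            raise ValueError("0 <= cooccurrence <= depth violated")


@dataclass
class PileupContext:
    """Everything needed to score one candidate variant on one track."""

    variant: VariantCall
    reads: list[ReadEvidence]
    mismatches: list[MismatchRecord]
    window_n: int  # reference positions within 10 bp up/downstream, locus excluded
    ref_window: str
    ref_window_start: int  # 1-based contig position of ref_window[0]

    def __post_init__(self) -> None:
        self.reads = sorted(self.reads, key=lambda r: (r.aln_start, r.aln_end, r.read_id))

    def ref_base_at(self, pos: int) -> str:
        idx = pos - self.ref_window_start
        if not 0 <= idx < len(self.ref_window):
            raise IndexError(f"position {pos} outside reference window")
        return self.ref_window[idx]


@dataclass
class PileupCounts:
    """Raw per-locus read tallies underlying the rate metrics."""

    d: int = 0
    d_m: int = 0
    d_h: int = 0
    d_e: int = 0
    d_insert: int = 0
    d_del: int = 0
    d_s_max: int = 0
    d_d_max: int = 0
    d_l: int = 0
    d_mv: int = 0
    d_si: int = 0
    d_p: int = 0
    n_other_alleles: int = 0  # distinct non-reference, non-candidate alleles (diagnostic)


GERMLINE_METRICS = (
    "lcr", "vafr", "nh", "ne", "ni", "nd", "sse", "dir",
    "lm", "mm", "mv", "hdr", "si", "r", "ri", "li",
)
SOMATIC_METRICS = GERMLINE_METRICS + ("nvaf", "lncr")


@dataclass
class MetricVector:
    """The named artifact metrics for one variant.

    All fields lie in [0, 1] except ``mm``, ``mv`` and ``hdr`` which may
    exceed 1; ``r``, ``ri``, ``li`` are binary flags. ``nvaf``/``lncr`` are
    populated in somatic mode only.
    """

    lcr: float = 0.0
    vafr: float = 0.0
    nh: float = 0.0
    ne: float = 0.0
    ni: float = 0.0
    nd: float = 0.0
    sse: float = 0.0
    dir: float = 0.0
    lm: float = 0.0
    mm: float = 0.0
    mv: float = 0.0
    hdr: float = 0.0
    si: float = 0.0
    r: int = 0
    ri: int = 0
    li: int = 0
    nvaf: Optional[float] = None
    lncr: Optional[float] = None

    def as_dict(self, somatic: bool = False) -> dict[str, float]:
        names = SOMATIC_METRICS if somatic else GERMLINE_METRICS
        out = {}
        for name in names:
            v = getattr(self, name)
            out[name] = 0.0 if v is None else float(v)
        return out

    @property
    def is_somatic(self) -> bool:
        return self.nvaf is not None


@dataclass
class ThresholdConfig:
    """Tunable thresholds for metric computation and tagging.

    Defaults follow the documented somatic exome settings (min depth 15,
    min normal depth 5, min VAF 0.15) and the stated metric defaults
    (near-distance 5 bp, MAPQ 10, mismatch frequency 0.05, concordance 0.9,
    large-insert length 20).
    """

    thr: int = 15
    thr_n: int = 5
    thr_vaf: float = 0.15
    near_dist: int = 5
    mapq_thr: int = 10
    mm_freq_thr: float = 0.05
    hr_thr: float = 0.9
    li_len: int = 20
    unit_len_max: int = 5
    min_copies: int = 4  # tandem units of length >= 2
    homopolymer_min: int = 5
    repeat_dist: int = 10  # bp around the locus scanned for repeat tracts
    window_pad: int = 10  # mismatch catalog half-window
    exclude_duplicates: bool = True
    vn_literal: bool = False  # use the literal VN reading (0.1*thr, d_normal>=2)
    germline_vscore_cutoff: float = 3.5
    germline_min_support: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.thr_vaf <= 1:
            raise ValueError("thr_vaf must be in (0, 1]")
        for name in ("thr", "thr_n", "near_dist", "mapq_thr", "li_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class NormalTrackSummary:
    """Normal-track evidence for a somatic candidate."""

    d_normal: int = 0
    d_n: int = 0
    germline_alleles: dict[str, float] = field(default_factory=dict)  # key -> v-score

    def __post_init__(self) -> None:
        if self.d_n > self.d_normal:
            raise ValueError("d_n cannot exceed d_normal")


class Tag(str, Enum):
    """Manual-review annotations; NCN/LCN/VN apply in somatic mode only."""

    LC = "LC"
    LVF = "LVF"
    LM = "LM"
    MM = "MM"
    HDR = "HDR"
    HE = "HE"
    EN = "EN"
    NI = "NI"
    ND = "ND"
    D = "D"
    SSE = "SSE"
    MV = "MV"
    RR = "RR"
    RI = "RI"
    AO = "AO"
    SI = "SI"
    NCN = "NCN"
    LCN = "LCN"
    VN = "VN"


SOMATIC_ONLY_TAGS = frozenset({Tag.NCN, Tag.LCN, Tag.VN})

DEFAULT_WEIGHTS: dict[str, float] = {
    # level 3
    "lcr": 3.0, "vafr": 3.0, "lm": 3.0, "ni": 3.0, "nd": 3.0,
    # level 2
    "lncr": 2.0, "mv": 2.0, "hdr": 2.0,
    # level 1
    "nh": 1.0, "ne": 1.0, "sse": 1.0, "dir": 1.0, "mm": 1.0,
    "si": 1.0, "r": 1.0, "ri": 1.0, "li": 1.0, "nvaf": 1.0,
}


@dataclass
class WeightConfig:
    """Per-metric weights of the weighted variant score."""

    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))

    def __post_init__(self) -> None:
        missing = set(SOMATIC_METRICS) - set(self.weights)
        if missing:
            raise ValueError(f"weights missing for metrics: {sorted(missing)}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")


@dataclass
class ScoredVariant:
    variant: VariantCall
    metrics: MetricVector
    counts: PileupCounts
    vscore: float
    tags: frozenset[Tag]
    normal: Optional[NormalTrackSummary] = None

    @property
    def tag_string(self) -> str:
        if not self.tags:
            return "."
        return ";".join(sorted(t.value for t in self.tags))


@dataclass
class EvaluationResult:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    f_beta: float
    accuracy: float
    mcc: float
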