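# varscreen

Automated screening of false-positive variant calls from read-level
evidence. `varscreen` replaces the most mechanical part of IGV-based manual
review: for every candidate variant in a VCF it inspects the BAM pileup,
computes 16 quantitative artifact metrics (18 in tumor/normal somatic mode),
marks categorical review tags, and summarizes everything into a single
weighted **v-score** — low score, likely true variant. It is aimed at
groups doing germline or somatic short-read variant calling who today spend
hours clicking through a visualizer to weed out artifacts.

## The model

For a candidate at locus *p*, let *d* be the covering reads and *d_m* the
reads supporting the alternate allele. The metrics are simple per-read
rates, each targeting one known artifact mode:

| metric | definition | artifact mode |
|---|---|---|
| `lcr` | 1 − min(thr, d)/thr | low coverage |
| `vafr` | 1 − d_m/d | low allele fraction |
| `nh`, `ne` | supporters within 5 bp of read head / end ÷ d_m | end-of-read errors |
| `ni`, `nd` | supporters with an insertion / deletion within 5 bp ÷ d_m | misalignment near indels |
| `sse` | largest identical-(start,end) supporter group ÷ d_m | duplicate stacks |
| `dir` | majority-strand supporters ÷ d_m | strand bias |
| `lm` | supporters with MAPQ < 10 ÷ d_m | ambiguous mapping |
| `mm` | (Σ depths of mismatches with frequency < 0.05 in ±10 bp) × 100 / n | noisy context |
| `mv` | reads carrying a third allele ÷ d_m | multi-allelic sites |
| `hdr` | Σ HR over linked mismatches, HR = 2h/(d_m + d_i) | recurrent co-occurring mismatches |
| `si` | supporters inside mate overlap ÷ paired supporters | short FFPE fragments |
| `r`, `ri`, `li` | binary repeat-context flags | tandem repeats, repeat-unit and duplicative insertions |
| `nvaf`, `lncr` | normal-track allele fraction, normal low-coverage risk | somatic mode only |

All metrics lie in [0, 1] except `mm`, `mv` and `hdr`, which may exceed 1.
Nineteen review tags (LC, LVF, LM, MM, HDR, HE, EN, NI, ND, D, SSE, MV, RR,
RI, AO, SI and — somatic only — NCN, LCN, VN) are thresholded directly on
these metrics. The v-score is the weighted sum v = Σ wᵢ·xᵢ with weight 3
for {lcr, vafr, lm, ni, nd}, weight 2 for {lncr, mv, hdr} and 1 elsewhere;
a v-score threshold is picked by sweeping cutoffs at 0.1 intervals and
maximizing F_β = (1+β²)·P·R / (β²·P + R) with β = 0.3 by default. An
optional XGBoost classifier (binary-logistic objective, 27-point grid over
learning rate / gamma / max depth with 10-fold CV) refines germline calls
from the same metric vectors.

A synthetic paired-end pileup generator plants each artifact signature into
otherwise clean pileups, so the full path — BAM in, tags and scores out —
is testable without any external data.

## Worked example

```bash
varscreen simulate --n 20 --seed 5 --out-dir sim
varscreen score --bam sim/tumor.bam --vcf sim/calls.vcf --ref sim/ref.fa --out scored
varscreen eval --scored scored.tsv --truth sim/truth.tsv --out sweep.tsv
```

The eval step prints the selected operating point:

```
best threshold: 2.10
P=1.0000 R=1.0000 F_beta=1.0000 accuracy=1.0000 MCC=1.0000
```

and `scored.tsv` holds one row per variant (abridged columns):

```
chrom  pos   ref  alt  vclass  d   d_m  vscore  tags
chr1   401   G    GA   INS     50  25   2.06    .
chr1   801   G    A    SNV     50  25   42.06   MM
chr1   1201  A    C    SNV     50  25   2.06    .
```

The clean heterozygous calls score ≈ 2 (mostly the vafr term at VAF 0.5)
and carry no tag; the variant planted with scattered low-frequency
mismatches is tagged MM and its v-score is dominated by the `mm` term, so
any threshold between the two groups separates them — here the sweep picks
2.10 and classifies every variant correctly. `scored.vcf` is a copy of the
input VCF with `VS` (v-score) and `VT` (tags) INFO fields added.

Somatic mode adds `--mode somatic --normal-bam normal.bam`: potential
germline alleles are first detected in the normal track by v-score,
excluded from the tumor-track `mv` tally, and `nvaf`/`lncr` plus the
NCN/LCN/VN tags are emitted.

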