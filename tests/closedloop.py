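"""Shared closed-loop harness: simulate one artifact signature, write real
files, score through the full alignment path, return the assigned tags."""

import numpy as np
import pysam

from varscreen.alignment_io import build_pileup_context
from varscreen.core import Tag, ThresholdConfig
from varscreen.metrics import compute_metric_vector
from varscreen.simulate import (
    SIGNATURE_TO_TAG,
    SOMATIC_SIGNATURES,
    ArtifactSpec,
    make_reference,
    prepare_site,
    simulate_variant_pileup,
    write_bam,
)
from varscreen.somatic import score_somatic_variant
from varscreen.tagscore import assign_tags, vscore

from conftest import write_fasta

# binary repeat-context flags have no intensity dial; their sub-threshold
# counterpart is a repeat-free site
_BINARY_SITE_SIGS = (
    "repeat_context", "repeat_unit_insertion", "large_duplicative_insertion")

# tags tolerated alongside the intended one (prerequisites)
ALLOWED_EXTRA = {Tag.RI: {Tag.RR}}


def score_signature(tmp_path, signature, strong=True, seed=0):
    """Returns (intended_tag, assigned_tags, vscore) for one simulated case."""
    cfg = ThresholdConfig()
    rng = np.random.default_rng(seed)
    length, locus0 = 3000, 1500
    seq, _ = make_reference(length, seed=seed + 1)
    seq = list(seq)
    site_sig = signature
    if not strong and signature in _BINARY_SITE_SIGS:
        site_sig = "none"
    variant = prepare_site(seq, locus0, site_sig, "chr1", cfg, rng)
    ref_str = "".join(seq)
    spec = ArtifactSpec.for_signature(signature, strong=strong)
    somatic = signature in SOMATIC_SIGNATURES

    tumor_reads = simulate_variant_pileup(ref_str, variant, spec, rng, "t")
    fasta = write_fasta(tmp_path / f"{signature}_{strong}.fa", "chr1", ref_str)
    tumor_bam = str(tmp_path / f"{signature}_{strong}_t.bam")
    write_bam(tumor_bam, "chr1", length, tumor_reads)
    normal_bam = None
    if somatic:
        nspec = ArtifactSpec(signature="none", depth=spec.normal_depth,
                             vaf=spec.normal_vaf)
        normal_reads = (simulate_variant_pileup(ref_str, variant, nspec, rng, "n")
                        if nspec.depth else [])
        normal_bam = str(tmp_path / f"{signature}_{strong}_n.bam")
        write_bam(normal_bam, "chr1", length, normal_reads)

    with pysam.AlignmentFile(tumor_bam) as bam, pysam.FastaFile(fasta) as ref:
        ctx = build_pileup_context(bam, ref, variant, cfg)
        if somatic:
            with pysam.AlignmentFile(normal_bam) as nbam:
                nctx = build_pileup_context(nbam, ref, variant, cfg)
            vec, counts, summary = score_somatic_variant(ctx, nctx, cfg)
            tags = assign_tags(vec, counts, cfg, normal=summary)
        else:
            vec, counts = compute_metric_vector(ctx, cfg)
            tags = assign_tags(vec, counts, cfg)
    return SIGNATURE_TO_TAG[signature], tags, vscore(vec)
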