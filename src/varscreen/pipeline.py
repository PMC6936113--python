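"""Run orchestration: configuration, per-variant scoring, parallel dispatch.

Scoring one variant is a pure function of the input files and thresholds,
so results are independent of worker count and processing order; output
rows are reassembled in variant order, making files bitwise identical for
any parallelism level. The worker count itself is therefore logged but
never echoed into output headers.
"""

from __future__ import annotations

import logging
import os
from concurrent.futures import ProcessPoolExecutor
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import pysam
import yaml

from . import __version__
from .alignment_io import (
    DataError,
    build_pileup_context,
    load_variants,
    open_alignment,
    write_scored_output,
)
from .core import (
    ScoredVariant,
    ThresholdConfig,
    VariantCall,
    WeightConfig,
)
from .metrics import compute_metric_vector
from .somatic import score_somatic_variant
from .tagscore import assign_tags, sweep_thresholds, vscore

logger = logging.getLogger(__name__)


class ConfigError(RuntimeError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    bam: str = ""
    vcf: str = ""
    ref: str = ""
    out: str = "varscreen_out"
    mode: str = "germline"  # or "somatic"
    normal_bam: Optional[str] = None
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    weights: WeightConfig = field(default_factory=WeightConfig)
    beta: float = 0.3
    step: float = 0.1
    workers: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("germline", "somatic"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "somatic" and not self.normal_bam:
            raise ConfigError("somatic mode requires a normal-track alignment (--normal-bam)")
        for label, path in (("bam", self.bam), ("vcf", self.vcf), ("ref", self.ref)):
            if not path or not os.path.exists(path):
                raise ConfigError(f"{label} file missing: {path!r}")
        if self.normal_bam and not os.path.exists(self.normal_bam):
            raise ConfigError(f"normal bam missing: {self.normal_bam!r}")

    def provenance(self) -> dict:
        """Config values echoed into output headers (reconstructible run)."""
        meta = {
            "version": __version__,
            "mode": self.mode,
            "bam": self.bam,
            "normal_bam": self.normal_bam or ".",
            "vcf": self.vcf,
            "ref": self.ref,
            "beta": self.beta,
            "step": self.step,
            "seed": self.seed,
        }
        meta.update({f"thr.{k}": v for k, v in asdict(self.thresholds).items()})
        meta.update({f"w.{k}": v for k, v in sorted(self.weights.weights.items())})
        return meta


def load_config_file(path: str) -> dict:
    """Flat key-value (YAML) config; unknown keys rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must hold a flat mapping")
    return data


def score_one(config: RunConfig, variant: VariantCall) -> ScoredVariant:
    """Score a single candidate variant (opens files per call; see
    ``score_variants`` for the batched path)."""
    with pysam.AlignmentFile(config.bam) as bam, pysam.FastaFile(config.ref) as ref:
        normal = pysam.AlignmentFile(config.normal_bam) if config.normal_bam else None
        try:
            return _score_variant(variant, bam, normal, ref, config)
        finally:
            if normal:
                normal.close()


def _score_variant(variant, bam, normal_bam, ref, config: RunConfig) -> ScoredVariant:
    cfg = config.thresholds
    ctx = build_pileup_context(bam, ref, variant, cfg)
    if config.mode == "somatic":
        normal_ctx = build_pileup_context(normal_bam, ref, variant, cfg)
        vec, counts, summary = score_somatic_variant(
            ctx, normal_ctx, cfg, weights=config.weights)
        tags = assign_tags(vec, counts, cfg, normal=summary)
    else:
        vec, counts = compute_metric_vector(ctx, cfg)
        summary = None
        tags = assign_tags(vec, counts, cfg)
    return ScoredVariant(
        variant=variant, metrics=vec, counts=counts,
        vscore=vscore(vec, config.weights), tags=tags, normal=summary,
    )


def _score_chunk(args) -> list[tuple[int, ScoredVariant]]:
    config, indexed = args
    out = []
    with pysam.AlignmentFile(config.bam) as bam, pysam.FastaFile(config.ref) as ref:
        normal = pysam.AlignmentFile(config.normal_bam) if config.normal_bam else None
        try:
            for idx, variant in indexed:
                out.append((idx, _score_variant(variant, bam, normal, ref, config)))
        finally:
            if normal:
                normal.close()
    return out


def score_variants(config: RunConfig,
                   variants: Optional[Sequence[VariantCall]] = None) -> list[ScoredVariant]:
    """Score all candidates in the run's VCF; result order follows the
    (sorted) variant list regardless of worker scheduling."""
    config.validate()
    if variants is None:
        with pysam.FastaFile(config.ref) as ref:
            variants = load_variants(config.vcf, reference=ref)
    indexed = list(enumerate(variants))
    workers = max(1, config.workers)
    logger.info("scoring %d variants with %d worker(s)", len(indexed), workers)
    if workers == 1 or len(indexed) < 2:
        results = _score_chunk((config, indexed))
    else:
        chunks = [indexed[i::workers] for i in range(workers)]
        results = []
        with ProcessPoolExecutor(max_workers=workers) as pool:
            for part in pool.map(_score_chunk, [(config, c) for c in chunks if c]):
                results.extend(part)
    results.sort(key=lambda pair: pair[0])
    return [sv for _, sv in results]


def cmd_score(config: RunConfig) -> tuple[str, str]:
    """Score + tag + v-score every variant; write TSV and annotated VCF."""
    scored = score_variants(config)
    return write_scored_output(
        scored, config.out, vcf_in=config.vcf,
        somatic=config.mode == "somatic", header_meta=config.provenance(),
    )


# ---------------------------------------------------------------------------
# evaluation glue


def read_truth(path: str) -> dict[tuple, int]:
    """TSV with columns chrom, pos, ref, alt, label (header optional)."""
    truth: dict[tuple, int] = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if not f or f[0] in ("chrom", "#chrom", ""):
                continue
            truth[(f[0], int(f[1]), f[2], f[3])] = int(f[4])
    return truth


def read_scored_tsv(path: str) -> tuple[list[tuple], list[float], "pd.DataFrame"]:
    """Keys, v-scores and full metric frame from a cmd_score TSV."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    keys = [
        (str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        for r in df.itertuples()
    ]
    return keys, [float(v) for v in df["vscore"]], df


def cmd_eval(scored_tsv: str, truth_tsv: str, beta: float = 0.3,
             step: float = 0.1, out: Optional[str] = None):
    """Threshold sweep of a scored TSV against truth labels."""
    keys, scores, _ = read_scored_tsv(scored_tsv)
    truth = read_truth(truth_tsv)
    pairs = [(s, truth[k]) for s, k in zip(scores, keys) if k in truth]
    missing = len(scores) - len(pairs)
    if missing:
        logger.warning("%d scored variants lack truth labels; excluded", missing)
    if not pairs:
        raise DataError("no scored variant matches the truth labels")
    table, best = sweep_thresholds(
        [p[0] for p in pairs], [p[1] for p in pairs], beta=beta, step=step)
    if out:
        with open(out, "w") as fh:
            fh.write("threshold\ttp\tfp\ttn\tfn\tprecision\trecall\tf_beta\taccuracy\tmcc\n")
            for r in table:
                fh.write(f"{r.threshold:.4g}\t{r.tp}\t{r.fp}\t{r.tn}\t{r.fn}\t"
                         f"{r.precision:.6f}\t{r.recall:.6f}\t{r.f_beta:.6f}\t"
                         f"{r.accuracy:.6f}\t{r.mcc:.6f}\n")
    return table, best
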