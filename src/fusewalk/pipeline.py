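"""End-to-end discovery and annotation pipelines.

``run_discover`` chains the single-end discovery stages: exon RPKM ->
trimmed-outlier z-scores -> candidate genes -> exon walking -> partial-read
extraction -> color-space consensus -> split alignment -> junction support.
``run_annotate`` chains the downstream stages: curation -> copy-number
mechanism -> chimeric structure -> cohort summary.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

from .annotation import AnnotationSet, GenomeRef
from .colorspace import ColorRead, build_consensus, extract_partial_reads
from .copynumber import (
    DEFAULT_AMP_LOG2,
    DEFAULT_DEL_DELTA,
    DEFAULT_WINDOW,
    MechanismCall,
    SegmentSet,
    classify_mechanism,
)
from .curation import CurationParams, CuratedFusion, apply_curation
from .expression import (
    DEFAULT_FOLD,
    DEFAULT_MIN_MAPQ,
    DEFAULT_QUANTILE,
    DEFAULT_RPKM_MIN,
    DEFAULT_TRIM_FRACTION,
    DEFAULT_Z_MIN,
    ExonExpressionMatrix,
    copa_z,
    select_candidate_genes,
    walk_breakpoints,
)
from .splitmap import (
    DEFAULT_MIN_MARGIN,
    DEFAULT_MIN_PART_LEN,
    FusionCandidate,
    GenomeIndex,
    count_junction_support,
    split_align,
)
from .structure import StructureCall, build_chimeric, classify_structure

log = logging.getLogger("fusewalk")


@dataclass
class RunConfig:
    """Flat pipeline configuration; every threshold at its documented default."""

    trim_fraction: float = DEFAULT_TRIM_FRACTION
    z_min: float = DEFAULT_Z_MIN
    rpkm_min: float = DEFAULT_RPKM_MIN
    walk_fold: float = DEFAULT_FOLD
    walk_quantile: float = DEFAULT_QUANTILE
    min_mapq: int = DEFAULT_MIN_MAPQ
    max_exon_match: int = 35
    min_anchor: int = 10
    min_support: int = 2
    max_mismatch_frac: float = 0.1
    min_part_len: int = DEFAULT_MIN_PART_LEN
    min_margin: int = DEFAULT_MIN_MARGIN
    cn_window: int = DEFAULT_WINDOW
    amp_log2: float = DEFAULT_AMP_LOG2
    del_delta: float = DEFAULT_DEL_DELTA
    uar_extension: int = 10_000
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a flat key=value config file; unknown keys are rejected."""
        kwargs = {}
        valid = cls().__dict__
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{ln}: expected key=value")
                key, _, value = line.partition("=")
                key = key.strip()
                if key not in valid:
                    raise ValueError(f"{path}:{ln}: unknown config key {key!r}")
                kind = type(valid[key])
                kwargs[key] = kind(value.strip())
        return cls(**kwargs)


def run_discover(
    genome: GenomeRef,
    annotation: AnnotationSet,
    matrix: ExonExpressionMatrix,
    color_reads: dict[str, list[ColorRead]],
    base_reads: Optional[dict[str, list[str]]] = None,
    config: Optional[RunConfig] = None,
    index: Optional[GenomeIndex] = None,
) -> list[FusionCandidate]:
    """Discover fusion candidates from expression outliers and junction reads."""
    cfg = config or RunConfig()
    copa = copa_z(matrix, cfg.trim_fraction, cfg.z_min)
    candidates = select_candidate_genes(copa, matrix, cfg.rpkm_min)
    log.info("candidate (gene, sample) pairs: %d", len(candidates))
    if index is None:
        index = GenomeIndex(genome)
    results: list[FusionCandidate] = []
    seen: set[tuple] = set()
    for gene_id, sample in candidates:
        model = annotation.get(gene_id)
        if model is None:
            continue
        breakpoints = walk_breakpoints(
            matrix, gene_id, sample, cfg.walk_fold, cfg.walk_quantile
        )
        for bp in breakpoints:
            if bp.direction != "drop":
                continue  # the 5' anchor gene shows the drop pattern
            rank = bp.boundary[0]
            exon = model.exons[rank - 1]
            boundary = exon.end if model.strand == "+" else exon.start + 1
            partial = extract_partial_reads(
                color_reads.get(sample, []),
                boundary,
                chrom=model.chrom,
                max_exon_match=cfg.max_exon_match,
                min_anchor=cfg.min_anchor,
            )
            consensuses = build_consensus(
                partial, cfg.min_support, cfg.max_mismatch_frac
            )
            for consensus in consensuses:
                candidate = split_align(
                    consensus,
                    genome,
                    annotation,
                    model,
                    index=index,
                    min_part_len=cfg.min_part_len,
                    min_margin=cfg.min_margin,
                    sample=sample,
                )
                if candidate is None:
                    continue
                key = (
                    sample,
                    candidate.five_chrom, candidate.five_pos,
                    candidate.three_chrom, candidate.three_pos,
                )
                if key in seen:
                    continue
                seen.add(key)
                pool: Iterable = (base_reads or {}).get(sample, [])
                jr, wt5, wt3 = count_junction_support(
                    pool, candidate, genome, annotation, cfg.min_anchor
                )
                candidate.junction_reads = max(jr, candidate.junction_reads)
                candidate.wt5, candidate.wt3 = wt5, wt3
                results.append(candidate)
    log.info("fusion candidates: %d", len(results))
    return results


@dataclass
class AnnotatedFusion:
    curated: CuratedFusion
    mechanism: Optional[MechanismCall] = None
    structure: Optional[StructureCall] = None


def run_annotate(
    curated_inputs: Sequence,
    annotation: AnnotationSet,
    genome: Optional[GenomeRef] = None,
    segsets: Optional[dict[str, SegmentSet]] = None,
    copa=None,
    params: Optional[CurationParams] = None,
    config: Optional[RunConfig] = None,
) -> list[AnnotatedFusion]:
    """Curate records, then attach mechanism and structure calls.

    Mechanism classification is skipped (with a warning) for samples without
    a segment profile; structure prediction is skipped when no genome is
    supplied or the 5' junction is not at an exon boundary.
    """
    cfg = config or RunConfig()
    audited = apply_curation(curated_inputs, annotation, copa, params=params)
    out = []
    for cf in audited:
        entry = AnnotatedFusion(curated=cf)
        if cf.retained:
            record = cf.record
            fusion_view = _RecordView(record)
            if segsets is not None and record.sample in segsets:
                entry.mechanism = classify_mechanism(
                    fusion_view,
                    segsets[record.sample],
                    cfg.cn_window,
                    cfg.amp_log2,
                    cfg.del_delta,
                )
            elif segsets is not None:
                log.warning("no segments for sample %s; mechanism skipped", record.sample)
            if genome is not None:
                try:
                    chimeric = build_chimeric(
                        fusion_view, annotation, genome, cfg.uar_extension
                    )
                    entry.structure = classify_structure(chimeric)
                except (KeyError, ValueError) as exc:
                    log.warning("structure prediction skipped: %s", exc)
        out.append(entry)
    return out


class _RecordView:
    """Adapter exposing a CallerRecord under the fusion attribute names."""

    def __init__(self, record):
        self.sample = record.sample
        self.five_gene = record.gene5
        self.five_chrom = record.chrom5
        self.five_strand = record.strand5
        self.five_pos = record.pos5
        self.three_gene = record.gene3
        self.three_chrom = record.chrom3
        self.three_strand = record.strand3
        self.three_pos = record.pos3


def write_candidates_tsv(path, candidates: Sequence[FusionCandidate]) -> None:
    cols = [
        "sample", "gene_5p", "gene_3p", "junction_reads", "wt5", "wt3",
        "chr_5p", "strand_5p", "pos_5p", "chr_3p", "strand_3p", "pos_3p",
        "partner_class", "source",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in candidates:
            fh.write(
                "\t".join(
                    str(x if x is not None else "NA")
                    for x in (
                        c.sample, c.five_gene, c.three_gene, c.junction_reads,
                        c.wt5, c.wt3, c.five_chrom, c.five_strand, c.five_pos,
                        c.three_chrom, c.three_strand, c.three_pos,
                        c.partner_class, c.source,
                    )
                )
                + "\n"
            )
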