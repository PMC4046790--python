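"""Deterministic synthetic cohorts with planted fusions and ground truth.

The generator writes a toy reference (random chromosomes carrying
non-overlapping multi-exon genes with clean open reading frames, plus
annotation-free gaps that stand in for unannotated regions), plants fusions
covering all six copy-number mechanisms and all eight transcript structure
classes, and emits everything the discovery pipeline consumes: 50 bp
single-end junction reads in color space, per-exon count matrices with the
planted 5'/3' expression imbalance, segmented copy-number profiles built to
embody each mechanism, and emulated external-caller files with labelled
decoys.  Every artifact is a pure function of (config, seed).

Coding transcripts are built codon-by-codon (ATG, non-stop codons with a
methionine planted every 25 codons, terminal TAA) so frame arithmetic on
planted fusions is exact; non-coding transcripts and unannotated gaps are
"ORF-poor": stop codons are planted in all three frames every ~100 bases so
no spurious open reading frame of consequence can arise.  Junction-adjacent
reference bases are adjusted so that a planted junction never has breakpoint
homology — split alignment can recover planted coordinates exactly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, Exon, GeneModel, GenomeRef, reverse_complement
from .colorspace import ColorRead, encode_colors
from .copynumber import CopySegment, SegmentSet
from .expression import ExonExpressionMatrix
from .structure import STRUCTURE_CLASSES

_STOP_BLOCK = "TAAATAAATAA"  # stop codons in all three frames
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
_BASES = np.array(list("ACGT"))


@dataclass
class FusionSpec:
    mechanism: str
    structure_class: str
    expression_fold: float = 8.0
    junction_depth: int = 30
    sample: Optional[str] = None


@dataclass
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 400_000
    n_genes: int = 20
    noncoding_fraction: float = 0.2
    n_samples: int = 8
    fusions: list[FusionSpec] = field(default_factory=list)
    read_length: int = 50
    error_rate: float = 0.0
    colorspace: bool = True
    baseline_rpkm: float = 30.0
    sigma_log: float = 0.2
    total_reads: int = 50_000_000
    wt_depth: int = 8
    uar_extension_emitted: int = 1_000


def default_fusion_specs() -> list[FusionSpec]:
    """Eight planted fusions covering all structure classes and mechanisms."""
    return [
        FusionSpec("focal_amplification", "in_frame"),
        FusionSpec("complex", "out_of_frame"),
        FusionSpec("deletion_based", "promoter_swap_full"),
        FusionSpec("interchromosomal", "promoter_swap_n_truncated"),
        FusionSpec("tandem_duplication", "noncoding_truncation"),
        FusionSpec("none", "truncated_gene"),
        FusionSpec("complex", "extended_3utr"),
        FusionSpec("interchromosomal", "no_protein"),
    ]


def recovery_fusion_specs(n: int, depth: int = 30) -> list[FusionSpec]:
    """n copy-neutral junction-recovery specs cycling structure classes.

    Junction recovery is a read-level statistic, so these specs keep the
    copy-number profile flat; mechanism coverage is exercised by
    :func:`default_fusion_specs`.
    """
    classes = ["in_frame", "out_of_frame", "truncated_gene", "noncoding_truncation"]
    return [
        FusionSpec("none", classes[i % len(classes)], junction_depth=depth)
        for i in range(n)
    ]


@dataclass
class TruthRecord:
    sample: str
    five_gene: str
    five_gene_id: str
    five_chrom: str
    five_strand: str
    five_pos: int  # 1-based last 5'-side base
    five_rank: int
    three_gene: str  # symbol or "UAR"
    three_gene_id: Optional[str]
    three_chrom: str
    three_strand: str
    three_pos: int  # 1-based first 3'-side base
    three_rank: Optional[int]
    mechanism: str
    structure_class: str
    junction_depth: int
    expression_fold: float
    fused_sequence: str
    junction_offset: int  # index of first 3' base in fused_sequence


@dataclass
class SimReference:
    genome: GenomeRef
    annotation: AnnotationSet
    gene_order: dict[str, list[str]]  # chrom -> gene ids in genomic order
    uar_regions: dict[str, tuple[int, int]]  # chrom -> 0-based half-open gap
    config: SimConfig

    def __iter__(self):
        return iter((self.genome, self.annotation))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, length)])


def _orf_poor_sequence(rng: np.random.Generator, length: int) -> str:
    parts = []
    total = 0
    while total < length:
        chunk = int(rng.integers(60, 100))
        parts.append(_random_seq(rng, chunk))
        parts.append(_STOP_BLOCK)
        total += chunk + len(_STOP_BLOCK)
    return "".join(parts)[:length]


def _make_coding_transcript(
    rng: np.random.Generator, exon_lengths: Sequence[int]
) -> tuple[str, tuple[int, int]]:
    tx_len = int(sum(exon_lengths))
    e1, e2, e_last = exon_lengths[0], exon_lengths[1], exon_lengths[-1]
    off = 3 * int(rng.integers(2, max(3, (e2 - 6) // 3)))
    cds_start = int(e1 + off)
    v = 3 * int(rng.integers(1, 5))
    n_codons = (tx_len - e_last - v - cds_start) // 3
    if n_codons < 40:
        raise ValueError("gene too short for a coding transcript")
    codons = ["ATG"]
    for j in range(1, n_codons - 1):
        if j % 25 == 0:
            codons.append("ATG")
        else:
            codons.append(_NONSTOP_CODONS[int(rng.integers(0, len(_NONSTOP_CODONS)))])
    codons.append("TAA")
    cds = "".join(codons)
    cds_end = cds_start + len(cds)
    tx = _random_seq(rng, cds_start) + cds + _random_seq(rng, tx_len - cds_end)
    return tx, (cds_start, cds_end)


def simulate_reference(config: SimConfig) -> SimReference:
    """Toy genome + annotation: multi-exon genes and >= 20 kb UAR gaps."""
    rng = np.random.default_rng(config.seed)
    L = config.chrom_length
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    sequences = {c: list(_random_seq(rng, L)) for c in chroms}

    gene_zone = (90_000, L - 90_000)
    uar = {c: (L - 80_000, L - 40_000) for c in chroms}
    for c in chroms:
        s, e = uar[c]
        sequences[c][s:e] = list(_orf_poor_sequence(rng, e - s))

    per_chrom = math.ceil(config.n_genes / config.n_chromosomes)
    if per_chrom < 1:
        raise ValueError("n_genes must cover every chromosome")
    stride = (gene_zone[1] - gene_zone[0]) // per_chrom
    models = []
    gene_order: dict[str, list[str]] = {c: [] for c in chroms}
    gidx = 0
    for c in chroms:
        cursor = gene_zone[0]
        for j in range(per_chrom):
            if gidx >= config.n_genes:
                break
            gidx += 1
            gene_id = f"G{gidx:03d}"
            symbol = f"GENE{gidx}"
            if config.noncoding_fraction > 0:
                period = max(2, round(1 / config.noncoding_fraction))
                coding = j % period != 2 % period
            else:
                coding = True
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(7, 10))
            exon_lengths = rng.integers(100, 220, n_exons)
            intron_lengths = rng.integers(400, 900, n_exons - 1)
            span_len = int(exon_lengths.sum() + intron_lengths.sum())
            start = gene_zone[0] + j * stride  # genes spread over the zone
            if span_len > stride - 1_000:
                raise ValueError("genes requested exceed packing capacity")
            if coding:
                tx, cds_span = _make_coding_transcript(rng, exon_lengths)
            else:
                tx, cds_span = _orf_poor_sequence(rng, int(exon_lengths.sum())), None
            # genomic exon intervals, ascending; exon_lengths is in
            # transcript order, so reverse it for minus-strand genes
            genomic_sizes = exon_lengths if strand == "+" else exon_lengths[::-1]
            ivs = []
            pos = start
            for i in range(n_exons):
                ivs.append((pos, pos + int(genomic_sizes[i])))
                pos += int(genomic_sizes[i])
                if i < n_exons - 1:
                    pos += int(intron_lengths[i])
            ordered = ivs if strand == "+" else ivs[::-1]
            exons = [Exon(c, s, e, r) for r, (s, e) in enumerate(ordered, 1)]
            # write transcript content into the genome
            offset = 0
            for (s, e) in ordered:
                chunk = tx[offset : offset + (e - s)]
                if strand == "-":
                    chunk = reverse_complement(chunk)
                sequences[c][s:e] = list(chunk)
                offset += e - s
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    symbol=symbol,
                    chrom=c,
                    strand=strand,
                    exons=exons,
                    cds_span=cds_span,
                    biotype="coding" if coding else "noncoding",
                    sources={"sim"},
                )
            )
            gene_order[c].append(gene_id)
            cursor = start + span_len + 2_000
    if gidx < config.n_genes:
        raise ValueError("genes requested exceed packing capacity")
    genome = GenomeRef({c: "".join(sequences[c]) for c in chroms})
    return SimReference(genome, AnnotationSet(models), gene_order, uar, config)


# ---------------------------------------------------------------------------
# Fusion planting

_MIN_PAIR_DISTANCE = {"complex": 150_000}
_DEFAULT_PAIR_DISTANCE = 70_000


def _tx_cumlen(model: GeneModel) -> list[int]:
    out = []
    acc = 0
    for exon in model.exons:
        acc += exon.length
        out.append(acc)
    return out


def _coding_break_ranks(model: GeneModel) -> list[int]:
    cds_start, cds_end = model.cds_span
    cum = _tx_cumlen(model)
    return [
        exon.rank
        for exon, t in zip(model.exons, cum)
        if cds_start < t < cds_end and exon.rank < len(model.exons)
    ]


def _boundary_pos_5p(model: GeneModel, rank: int) -> int:
    exon = model.exons[rank - 1]
    return exon.end if model.strand == "+" else exon.start + 1


def _entry_pos_3p(model: GeneModel, rank: int) -> int:
    exon = model.exons[rank - 1]
    return exon.start + 1 if model.strand == "+" else exon.end


def _plan_coding_junction(
    genome: GenomeRef,
    five: GeneModel,
    three: GeneModel,
    in_frame: bool,
) -> tuple[int, int]:
    """Choose (k, m) exon ranks realizing the requested frame relation."""
    cds5 = five.cds_span
    cds3 = three.cds_span
    cum5 = _tx_cumlen(five)
    cum3 = _tx_cumlen(three)
    tx5 = five.spliced_sequence(genome)
    tx3 = three.spliced_sequence(genome)
    k_ranks = _coding_break_ranks(five)
    k_ranks.sort(key=lambda r: abs(r - len(five.exons) // 2))
    for k in k_ranks:
        t_k = cum5[k - 1]
        L5 = t_k - cds5[0]
        for m in range(2, len(three.exons)):
            d3 = cum3[m - 2]
            if not (cds3[0] < d3 < cds3[1] - 30):
                continue
            frame_ok = (L5 - (d3 - cds3[0])) % 3 == 0
            if in_frame != frame_ok:
                continue
            if in_frame:
                fused = tx5[:t_k] + tx3[d3:]
                pep_nt = _translated_nt(fused[cds5[0] :])
                expected = (t_k - cds5[0]) + (cds3[1] - d3) - 3
                if pep_nt != expected:
                    continue  # premature stop in a hybrid codon; try next
            return k, m
    raise ValueError("no junction realizes the requested frame relation")


def _translated_nt(seq: str) -> int:
    n = 0
    for i in range(0, len(seq) - 2, 3):
        if seq[i : i + 3] in _STOPS:
            return n
        n += 3
    return n


def _plan_junction(
    genome: GenomeRef, spec: FusionSpec, five: GeneModel, three: Optional[GeneModel]
) -> tuple[int, Optional[int]]:
    cls = spec.structure_class
    if cls in ("in_frame", "out_of_frame"):
        assert three is not None
        return _plan_coding_junction(genome, five, three, cls == "in_frame")
    if cls == "promoter_swap_full":
        return 1, 2
    if cls == "promoter_swap_n_truncated":
        assert three is not None
        cds3 = three.cds_span
        cum3 = _tx_cumlen(three)
        for m in range(3, len(three.exons)):
            d3 = cum3[m - 2]
            if cds3[0] < d3 and (cds3[1] - d3) >= 3 * 80:
                return 1, m
        raise ValueError("partner too short for an N-truncated promoter swap")
    if cls == "noncoding_truncation":
        ranks = _coding_break_ranks(five)
        return ranks[len(ranks) // 2], 2
    if cls == "truncated_gene":
        ranks = _coding_break_ranks(five)
        return ranks[len(ranks) // 2], None
    if cls == "extended_3utr":
        # break at the last exon boundary downstream of the stop codon
        cum = _tx_cumlen(five)
        cds_end = five.cds_span[1]
        for exon, t in zip(five.exons, cum):
            if t >= cds_end and exon.rank < len(five.exons):
                return exon.rank, None
        raise ValueError("no 3' UTR exon boundary available")
    if cls == "no_protein":
        k = max(2, len(five.exons) // 2)
        return k, None
    raise ValueError(f"unknown structure class {cls!r}")


def _gene_mid(model: GeneModel) -> int:
    s, e = model.span
    return (s + e) // 2


def _choose_partners(
    ref: SimReference, spec: FusionSpec, used: set[str]
) -> tuple[GeneModel, Optional[GeneModel], Optional[tuple[str, int, str]]]:
    """Pick a 5' gene and either a partner gene or a UAR locus."""
    ann = ref.annotation
    cls = spec.structure_class
    want_coding_5p = cls != "no_protein"
    partner_kind = (
        "uar"
        if cls in ("truncated_gene", "extended_3utr", "no_protein")
        else ("noncoding" if cls == "noncoding_truncation" else "coding")
    )
    min_dist = _MIN_PAIR_DISTANCE.get(spec.mechanism, _DEFAULT_PAIR_DISTANCE)
    chroms = list(ref.gene_order)

    def _ok_five(gid: str) -> bool:
        m = ann.get(gid)
        if gid in used or m is None:
            return False
        if want_coding_5p:
            return m.cds_span is not None and len(_coding_break_ranks(m)) >= 2
        return m.biotype == "noncoding"

    def _ok_three(gid: str) -> bool:
        m = ann.get(gid)
        if gid in used or m is None:
            return False
        if partner_kind == "coding":
            return m.cds_span is not None and len(m.exons) >= 4
        return m.biotype == "noncoding"

    uar_count = getattr(_choose_partners, "_uar_count", {})

    for c5 in chroms:
        order = ref.gene_order[c5]
        for i5, gid5 in enumerate(order):
            if not _ok_five(gid5):
                continue
            five = ann.get(gid5)
            p5_approx = _gene_mid(five)
            if spec.mechanism == "focal_amplification" and not (
                81_000 < p5_approx < ref.config.chrom_length - 81_000
            ):
                continue
            if spec.mechanism == "none" and not (
                31_000 < p5_approx < ref.config.chrom_length - 31_000
            ):
                continue
            if partner_kind == "uar":
                c3 = c5
                if spec.mechanism == "interchromosomal":
                    c3 = next(c for c in chroms if c != c5)
                n_prev = uar_count.get(c3, 0)
                s, e = ref.uar_regions[c3]
                pos = s + 5_000 + 7_000 * n_prev
                if pos >= e - 2_000:
                    continue
                if c3 == c5:
                    dist = abs(pos - p5_approx)
                    if dist < min_dist and spec.mechanism in (
                        "complex", "tandem_duplication", "deletion_based",
                        "focal_amplification",
                    ):
                        continue
                    if spec.mechanism == "tandem_duplication" and pos > p5_approx:
                        continue
                strand3 = "+" if (n_prev % 2 == 0) else "-"
                uar_count[c3] = n_prev + 1
                _choose_partners._uar_count = uar_count
                used.add(gid5)
                return five, None, (c3, pos, strand3)
            # annotated partner
            partner_chroms = (
                [c for c in chroms if c != c5]
                if spec.mechanism == "interchromosomal"
                else [c5]
            )
            for c3 in partner_chroms:
                for i3, gid3 in enumerate(ref.gene_order[c3]):
                    if gid3 == gid5 or not _ok_three(gid3):
                        continue
                    three = ann.get(gid3)
                    if c3 == c5:
                        if abs(i3 - i5) < 2:
                            continue  # adjacency filter would discard it
                        dist = abs(_gene_mid(three) - p5_approx)
                        if spec.mechanism in (
                            "complex", "tandem_duplication",
                            "deletion_based", "focal_amplification",
                        ) and dist < min_dist:
                            continue
                        if spec.mechanism == "tandem_duplication" and _gene_mid(three) > p5_approx:
                            continue
                        if spec.mechanism == "deletion_based" and _gene_mid(three) < p5_approx:
                            continue
                        if spec.mechanism == "focal_amplification" and not (
                            81_000 < _gene_mid(three) < ref.config.chrom_length - 81_000
                        ):
                            continue
                        if spec.mechanism == "none" and not (
                            31_000 < _gene_mid(three) < ref.config.chrom_length - 31_000
                        ):
                            continue
                    used.add(gid5)
                    used.add(gid3)
                    return five, three, None
    raise ValueError(
        f"no gene layout satisfies spec ({spec.mechanism}, {spec.structure_class})"
    )


def _fused_parts(
    genome: GenomeRef,
    five: GeneModel,
    k: int,
    three: Optional[GeneModel],
    m: Optional[int],
    uar: Optional[tuple[str, int, str]],
    uar_len: int,
) -> tuple[str, str]:
    tx5 = five.spliced_sequence(genome)
    cum5 = _tx_cumlen(five)
    five_part = tx5[: cum5[k - 1]]
    if three is not None:
        cum3 = _tx_cumlen(three)
        d3 = cum3[m - 2] if m >= 2 else 0
        three_part = three.spliced_sequence(genome)[d3:]
    else:
        c3, pos, strand3 = uar
        n = genome.length(c3)
        if strand3 == "+":
            three_part = genome.fetch(c3, pos - 1, min(n, pos - 1 + uar_len))
        else:
            three_part = reverse_complement(
                genome.fetch(c3, max(0, pos - uar_len), pos)
            )
    return five_part, three_part


def _mechanism_segments(
    mech: str, chrom_len: int, c5: str, p5: int, c3: str, p3: int
) -> dict[str, list[tuple[int, int, float]]]:
    """Per-chromosome (start, end, seg_mean) lists embodying a mechanism."""
    L = chrom_len
    if mech == "interchromosomal":
        return {
            c5: [(1, p5, 0.5), (p5 + 1, L, 0.0)],
            c3: [(1, L, 0.0)],
        }
    lo, hi = min(p5, p3), max(p5, p3)
    if mech == "none":
        return {c5: [(1, L, 0.0)]}
    if mech == "focal_amplification":
        a, b = lo - 50_000, hi + 50_000
        return {c5: [(1, a - 1, 0.0), (a, b, 1.5), (b + 1, L, 0.0)]}
    if mech == "tandem_duplication":
        # 3' point at the amplified segment's start, 5' point at its end
        return {c5: [(1, p3 - 1, 0.0), (p3, p5, 1.5), (p5 + 1, L, 0.0)]}
    if mech == "deletion_based":
        return {c5: [(1, lo - 1, 0.0), (lo, hi, -1.0), (hi + 1, L, 0.0)]}
    if mech == "complex":
        third = (hi - lo) // 4
        a = lo + third
        b = a + third
        c = b + third
        return {
            c5: [
                (1, lo - 1, 0.0),
                (lo, a, 1.2),
                (a + 1, b, -0.5),
                (b + 1, c, 1.1),
                (c + 1, hi, -0.4),
                (hi + 1, L, 0.0),
            ]
        }
    raise ValueError(f"unknown mechanism {mech!r}")


def plant_fusions(
    config: SimConfig, ref: SimReference
) -> tuple[dict[str, SegmentSet], list[TruthRecord]]:
    """Realize the fusion specs on the reference.

    Mutates the reference genome in place where a junction would otherwise
    carry breakpoint homology (one intron/intergenic base per junction
    side).  Returns per-sample segment profiles and the truth records.
    """
    specs = config.fusions or default_fusion_specs()
    samples = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    if len(specs) > len(samples):
        raise ValueError("more fusion specs than samples")
    _choose_partners._uar_count = {}
    used: set[str] = set()
    genome = ref.genome
    muts: dict[tuple[str, int], str] = {}
    plans = []
    for i, spec in enumerate(specs):
        if spec.mechanism == "interchromosomal" and config.n_chromosomes < 2:
            raise ValueError("interchromosomal fusion needs >= 2 chromosomes")
        sample = spec.sample or samples[i]
        five, three, uar = _choose_partners(ref, spec, used)
        k, m = _plan_junction(genome, spec, five, three)
        plans.append((spec, sample, five, three, uar, k, m))
        _disambiguate_junction(genome, muts, five, k, three, m, uar, config)
    _apply_mutations(genome, muts)

    truths = []
    seg_plan: dict[str, dict[str, list[tuple[int, int, float]]]] = {
        s: {} for s in samples
    }
    for spec, sample, five, three, uar, k, m in plans:
        five_pos = _boundary_pos_5p(five, k)
        if three is not None:
            c3 = three.chrom
            p3 = _entry_pos_3p(three, m)
            strand3 = three.strand
            three_name, three_id = three.symbol, three.gene_id
        else:
            c3, p3, strand3 = uar
            three_name, three_id = "UAR", None
        five_part, three_part = _fused_parts(
            genome, five, k, three, m, uar, config.uar_extension_emitted
        )
        truths.append(
            TruthRecord(
                sample=sample,
                five_gene=five.symbol,
                five_gene_id=five.gene_id,
                five_chrom=five.chrom,
                five_strand=five.strand,
                five_pos=five_pos,
                five_rank=k,
                three_gene=three_name,
                three_gene_id=three_id,
                three_chrom=c3,
                three_strand=strand3,
                three_pos=p3,
                three_rank=m,
                mechanism=spec.mechanism,
                structure_class=spec.structure_class,
                junction_depth=spec.junction_depth,
                expression_fold=spec.expression_fold,
                fused_sequence=five_part + three_part,
                junction_offset=len(five_part),
            )
        )
        for chrom, segs in _mechanism_segments(
            spec.mechanism, config.chrom_length, five.chrom, five_pos, c3, p3
        ).items():
            if chrom in seg_plan[sample]:
                raise ValueError(
                    f"two fusions touch {chrom} in sample {sample}; unsupported"
                )
            seg_plan[sample][chrom] = segs

    chroms = list(ref.gene_order)
    segsets = {}
    for sample in samples:
        segments = []
        for chrom in chroms:
            plan = seg_plan[sample].get(chrom, [(1, config.chrom_length, 0.0)])
            for start, end, mean in plan:
                if start > end:
                    continue
                segments.append(
                    CopySegment(sample, chrom, start, end, mean, n_markers=50)
                )
        segsets[sample] = SegmentSet(sample, segments)
    return segsets, truths


def _apply_mutations(genome: GenomeRef, muts: dict[tuple[str, int], str]) -> None:
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for (chrom, pos), base in muts.items():
        by_chrom.setdefault(chrom, []).append((pos, base))
    for chrom, edits in by_chrom.items():
        seq = list(genome.sequences[chrom])
        for pos, base in edits:
            seq[pos] = base
        genome.sequences[chrom] = "".join(seq)


def _other_base(*avoid: str) -> str:
    for b in "ACGT":
        if b not in avoid:
            return b
    return "A"


def _disambiguate_junction(
    genome: GenomeRef,
    muts: dict[tuple[str, int], str],
    five: GeneModel,
    k: int,
    three: Optional[GeneModel],
    m: Optional[int],
    uar: Optional[tuple[str, int, str]],
    config: SimConfig,
) -> None:
    """Remove breakpoint homology around a planted junction."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    five_part, three_part = _fused_parts(
        genome, five, k, three, m, uar, config.uar_extension_emitted
    )
    first_distal = three_part[0]
    last_exonic = five_part[-1]
    exon5 = five.exons[k - 1]
    # anchor side: the base that would extend the exon alignment past the
    # boundary, read in transcript direction
    if five.strand == "+":
        pos = exon5.end  # 0-based base just past the exon
        if genome.sequences[five.chrom][pos] == first_distal:
            muts[(five.chrom, pos)] = _other_base(first_distal)
    else:
        pos = exon5.start - 1
        if comp[genome.sequences[five.chrom][pos]] == first_distal:
            muts[(five.chrom, pos)] = _other_base(comp[first_distal])
    # distal side: the base preceding the entry point in distal orientation
    if three is not None:
        exon3 = three.exons[m - 1]
        if three.strand == "+":
            pos = exon3.start - 1
            if genome.sequences[three.chrom][pos] == last_exonic:
                muts[(three.chrom, pos)] = _other_base(last_exonic)
        else:
            pos = exon3.end
            if comp[genome.sequences[three.chrom][pos]] == last_exonic:
                muts[(three.chrom, pos)] = _other_base(comp[last_exonic])
    else:
        c3, p3, strand3 = uar
        if strand3 == "+":
            pos = p3 - 2
            if pos >= 0 and genome.sequences[c3][pos] == last_exonic:
                muts[(c3, pos)] = _other_base(last_exonic)
        else:
            pos = p3  # 0-based base after the (1-based) entry
            if pos < genome.length(c3) and comp[genome.sequences[c3][pos]] == last_exonic:
                muts[(c3, pos)] = _other_base(comp[last_exonic])


# ---------------------------------------------------------------------------
# Reads and expression


@dataclass
class SimReads:
    color_reads: dict[str, list[ColorRead]]  # sample -> junction color reads
    base_reads: dict[str, list[str]]         # sample -> base-space read pool
    matrix: ExonExpressionMatrix


def _spliced_junction_window(
    model: GeneModel, genome: GenomeRef, rank: int
) -> tuple[str, int]:
    tx = model.spliced_sequence(genome)
    cum = _tx_cumlen(model)
    return tx, cum[rank - 1]


def simulate_reads_and_expression(
    config: SimConfig, ref: SimReference, truths: Sequence[TruthRecord]
) -> SimReads:
    """Junction reads, wild-type reads and the per-exon count matrix."""
    rng = np.random.default_rng(config.seed + 7)
    rl = config.read_length
    samples = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    color_reads: dict[str, list[ColorRead]] = {s: [] for s in samples}
    base_reads: dict[str, list[str]] = {s: [] for s in samples}
    for t in truths:
        color_reads.setdefault(t.sample, [])
        base_reads.setdefault(t.sample, [])

    for ti, truth in enumerate(truths):
        fused = truth.fused_sequence
        J = truth.junction_offset
        if J < rl or len(fused) - J < rl:
            raise ValueError("read_length exceeds junction context")
        n_reads = int(rng.poisson(truth.junction_depth))
        for r in range(n_reads):
            o = int(rng.integers(5, rl - 4))  # 5' side bases
            seq = fused[J - o : J - o + rl]
            colors = encode_colors("T", seq)
            if config.error_rate > 0:
                colors = _corrupt_colors(rng, colors, config.error_rate)
            read = ColorRead(
                read_id=f"f{ti}_{r}",
                primer="T",
                colors=colors,
                ref_start=truth.five_pos - o,
                matched_length=o,
                chrom=truth.five_chrom,
            )
            color_reads[truth.sample].append(read)
            base_reads[truth.sample].append(read.bases)
        # wild-type junction reads for both partners
        ann = ref.annotation
        five = ann.get(truth.five_gene_id)
        if truth.five_rank < len(five.exons):
            tx, j = _spliced_junction_window(five, ref.genome, truth.five_rank)
            _emit_wt_reads(rng, base_reads[truth.sample], tx, j, rl, config.wt_depth)
        if truth.three_gene_id is not None and truth.three_rank and truth.three_rank > 1:
            three = ann.get(truth.three_gene_id)
            tx, j = _spliced_junction_window(three, ref.genome, truth.three_rank - 1)
            _emit_wt_reads(rng, base_reads[truth.sample], tx, j, rl, config.wt_depth)

    matrix = _expression_matrix(config, ref, truths, rng)
    return SimReads(color_reads=color_reads, base_reads=base_reads, matrix=matrix)


def _emit_wt_reads(rng, pool: list[str], tx: str, junction: int, rl: int, depth: int) -> None:
    n = int(rng.poisson(depth))
    for _ in range(n):
        o = int(rng.integers(12, rl - 11))
        start = junction - o
        if start < 0 or start + rl > len(tx):
            continue
        pool.append(tx[start : start + rl])


def _corrupt_colors(rng, colors: str, rate: float) -> str:
    out = list(colors)
    hits = np.nonzero(rng.random(len(out)) < rate)[0]
    for i in hits:
        out[i] = str((int(out[i]) + int(rng.integers(1, 4))) % 4)
    return "".join(out)


def _expression_matrix(
    config: SimConfig,
    ref: SimReference,
    truths: Sequence[TruthRecord],
    rng: np.random.Generator,
) -> ExonExpressionMatrix:
    samples = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    rows = []
    keys = []
    meta_rows = []
    lengths = []
    fold_of: dict[tuple[str, str, int], float] = {}
    for truth in truths:
        for exon_rank in range(1, truth.five_rank + 1):
            fold_of[(truth.sample, truth.five_gene_id, exon_rank)] = truth.expression_fold
        if truth.three_gene_id is not None and truth.three_rank is not None:
            three = ref.annotation.get(truth.three_gene_id)
            for exon_rank in range(truth.three_rank, len(three.exons) + 1):
                fold_of[(truth.sample, truth.three_gene_id, exon_rank)] = truth.expression_fold

    tot_m = config.total_reads / 1e6
    for model in sorted(ref.annotation, key=lambda m: m.gene_id):
        base = float(np.exp(rng.normal(np.log(config.baseline_rpkm), 0.5)))
        for exon in model.exons:
            len_kb = exon.length / 1e3
            noise = np.exp(rng.normal(0.0, config.sigma_log, len(samples)))
            rpkm = base * noise
            for si, s in enumerate(samples):
                fold = fold_of.get((s, model.gene_id, exon.rank), 1.0)
                rpkm[si] *= fold
            counts = np.rint(rpkm * len_kb * tot_m).astype(int)
            rows.append(counts)
            keys.append((model.gene_id, exon.rank))
            lengths.append(exon.length)
            meta_rows.append((exon.chrom, exon.start + 1, exon.end))
    idx = pd.MultiIndex.from_tuples(keys, names=["gene_id", "rank"])
    counts_df = pd.DataFrame(np.vstack(rows), index=idx, columns=samples)
    totals = pd.Series(config.total_reads, index=samples, dtype=float)
    meta = pd.DataFrame(meta_rows, index=idx, columns=["chrom", "start", "end"])
    return ExonExpressionMatrix(counts_df, pd.Series(lengths, index=idx), totals, meta)


# ---------------------------------------------------------------------------
# Emulated caller files with decoys

_DECOY_KINDS = (
    "non_boundary", "below_ratio", "low_support", "candidate_only_low_z",
    "blacklist", "adjacent",
)


def emit_caller_files(
    truths: Sequence[TruthRecord],
    ref: SimReference,
    out_dir,
    dialect: str = "tophatfusion",
    decoy_count: int = 6,
    seed: int = 0,
) -> dict[str, str]:
    """Render truths plus rule-violating decoys in a caller dialect.

    Decoys cycle through the curation rules one violation each; a sidecar
    TSV labels every row with its truth/decoy status, the violated rule and
    the auxiliary evidence (wild-type counts and outlier z) the curation
    step consumes.  Byte-identical output for identical (truths, seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [_truth_row(t) for t in truths]
    rng = np.random.default_rng(seed)
    rows += [
        _decoy_row(ref, _DECOY_KINDS[i % len(_DECOY_KINDS)], i, rng)
        for i in range(decoy_count)
    ]
    paths = {}
    sidecar = out_dir / "caller_truth.tsv"
    with open(sidecar, "w") as fh:
        fh.write(
            "sample\tgene_5p\tchr_5p\tpos_5p\tstrand_5p\tgene_3p\tchr_3p\tpos_3p"
            "\tstrand_3p\tspan\twt5\twt3\tz\tcandidate_only\tis_decoy\tviolated_rule\n"
        )
        for row in rows:
            fh.write(
                "\t".join(
                    str(row[c])
                    for c in (
                        "sample", "gene5", "chrom5", "pos5", "strand5",
                        "gene3", "chrom3", "pos3", "strand3", "span",
                        "wt5", "wt3", "z", "candidate_only", "is_decoy", "rule",
                    )
                )
                + "\n"
            )
    paths["sidecar"] = str(sidecar)

    if dialect == "tophatfusion":
        pot = out_dir / "potential_fusion.txt"
        res = out_dir / "result.txt"
        orient = lambda r: ("f" if r["strand5"] == "+" else "r") + (
            "f" if r["strand3"] == "+" else "r"
        )
        with open(pot, "w") as fh:
            for row in rows:
                fh.write(
                    f"{row['sample']} {row['chrom5']}-{row['chrom3']} "
                    f"{row['pos5'] - 1} {row['pos3'] - 1} {orient(row)}\n"
                )
                fh.write(f"{row['span']} {max(0, row['span'] // 2)} {row['span']}\n")
                fh.write(f"{row['gene5']} {row['gene3']}\n\n")
        with open(res, "w") as fh:
            for row in rows:
                if row["candidate_only"]:
                    continue
                fh.write(
                    "\t".join(
                        str(x)
                        for x in (
                            row["sample"], row["gene5"], row["chrom5"],
                            row["pos5"] - 1, row["gene3"], row["chrom3"],
                            row["pos3"] - 1, row["span"],
                            max(0, row["span"] // 2), row["span"], orient(row),
                        )
                    )
                    + "\n"
                )
        paths["potential"] = str(pot)
        paths["result"] = str(res)
    elif dialect == "snowshoes":
        ss = out_dir / "final_fusion_report_RNA.txt"
        with open(ss, "w") as fh:
            fh.write(
                "sample\tgene_5p\tchr_5p\tpos_5p\tstrand_5p\tgene_3p\tchr_3p"
                "\tpos_3p\tstrand_3p\tspan_reads\tisoform\n"
            )
            for row in rows:
                if row["candidate_only"]:
                    continue
                fh.write(
                    "\t".join(
                        str(x)
                        for x in (
                            row["sample"], row["gene5"], row["chrom5"],
                            row["pos5"], row["strand5"], row["gene3"],
                            row["chrom3"], row["pos3"], row["strand3"],
                            row["span"], 1,
                        )
                    )
                    + "\n"
                )
        paths["snowshoes"] = str(ss)
    else:
        raise ValueError(f"unsupported dialect {dialect!r}")
    return paths


def _truth_row(truth: TruthRecord) -> dict:
    return dict(
        sample=truth.sample,
        gene5=truth.five_gene,
        chrom5=truth.five_chrom,
        pos5=truth.five_pos,
        strand5=truth.five_strand,
        gene3=truth.three_gene,
        chrom3=truth.three_chrom,
        pos3=truth.three_pos,
        strand3=truth.three_strand,
        span=max(120, truth.junction_depth * 4),
        wt5=10,
        wt3=5 if truth.three_gene != "UAR" else "NA",
        z=12.0,
        candidate_only=0,
        is_decoy=0,
        rule="",
    )


def _decoy_row(ref: SimReference, kind: str, i: int, rng: np.random.Generator) -> dict:
    ann = ref.annotation
    chrom = list(ref.gene_order)[0]
    order = ref.gene_order[chrom]
    # template: non-adjacent coding pair at exon boundaries, healthy evidence
    g5 = ann.get(order[0])
    g3 = ann.get(order[2])
    adj5, adj3 = ann.get(order[3]), ann.get(order[4])
    pos5 = _boundary_pos_5p(g5, 2)
    pos3 = _entry_pos_3p(g3, 2)
    row = dict(
        sample=f"S{(i % 4) + 1:02d}",
        gene5=g5.symbol, chrom5=g5.chrom, pos5=pos5, strand5=g5.strand,
        gene3=g3.symbol, chrom3=g3.chrom, pos3=pos3, strand3=g3.strand,
        span=150, wt5=10, wt3=10, z=12.0, candidate_only=0,
        is_decoy=1, rule=kind,
    )
    if kind == "non_boundary":
        row["pos5"] += 7
        row["pos3"] += 7
    elif kind == "below_ratio":
        row["wt5"] = row["wt3"] = 100
    elif kind == "low_support":
        row["span"] = 5
        row["z"] = 3.0
        row["wt5"] = row["wt3"] = 1  # ratio rule still passes
    elif kind == "candidate_only_low_z":
        row["candidate_only"] = 1
        row["span"] = 50
        row["z"] = 7.0
    elif kind == "blacklist":
        row["gene5"], row["gene3"] = "TFG", "GPR128"
    elif kind == "adjacent":
        row.update(
            gene5=adj5.symbol, chrom5=adj5.chrom, strand5=adj5.strand,
            pos5=_boundary_pos_5p(adj5, 2),
            gene3=adj3.symbol, chrom3=adj3.chrom, strand3=adj3.strand,
            pos3=_entry_pos_3p(adj3, 2),
        )
    return row


def read_caller_sidecar(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
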