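"""Chimeric transcript construction and protein-structure classification.

Given a curated fusion with its 5' breakpoint at an exon boundary, the
chimeric transcript is the 5' partner's exons through the breakpoint joined
to either the 3' partner's exons from its breakpoint onward or, for an
unannotated region (UAR) partner, raw genomic sequence.  The predicted
protein is read from the 5' partner's start codon to the first stop, and the
junction's effect is classified:

* ``in_frame`` — 5' coding bases retained preserve the 3' partner's reading
  frame with no intervening stop; the peptide carries residues of both genes;
* ``out_of_frame`` — frame broken or a stop intervenes: C-terminal
  truncation of the 5' protein;
* ``promoter_swap_full`` / ``promoter_swap_n_truncated`` — junction upstream
  of the 5' CDS: the 5' gene contributes only its promoter/5' UTR;
* ``noncoding_truncation`` — 3' partner is a non-coding gene;
* ``truncated_gene`` — UAR partner entering inside the 5' CDS;
* ``extended_3utr`` — junction downstream of the complete 5' CDS, so only
  the 3' UTR changes;
* ``no_protein`` — no open reading frame of at least ``min_orf`` codons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from Bio.Seq import Seq

from .annotation import AnnotationSet, GeneModel, GenomeRef, reverse_complement

DEFAULT_UAR_EXTENSION = 10_000
DEFAULT_MIN_ORF = 50  # codons

STRUCTURE_CLASSES = (
    "in_frame",
    "out_of_frame",
    "promoter_swap_full",
    "promoter_swap_n_truncated",
    "noncoding_truncation",
    "extended_3utr",
    "truncated_gene",
    "no_protein",
)


@dataclass
class ChimericTranscript:
    sequence: str
    junction_offset: int  # 0-based: sequence[:offset] is the 5' contribution
    five_model: GeneModel
    five_exons_retained: int
    five_coding_bases: int
    three_model: Optional[GeneModel]  # None for UAR
    three_entry_offset: Optional[int]  # transcript offset in the 3' partner
    three_class: str  # annotated_coding / annotated_noncoding / UAR


@dataclass
class StructureCall:
    structure_class: str
    peptide: str
    frame_shift: bool

    def __post_init__(self):
        if self.structure_class not in STRUCTURE_CLASSES:
            raise ValueError(f"unknown structure class {self.structure_class!r}")


class NonExonicJunctionError(ValueError):
    pass


def _exon_end_rank(model: GeneModel, pos_1based: int) -> Optional[int]:
    for exon in model.exons:
        last = exon.end if model.strand == "+" else exon.start + 1
        if last == pos_1based:
            return exon.rank
    return None


def _tx_offset_of_position(model: GeneModel, pos_1based: int) -> Optional[int]:
    """0-based transcript offset of a genomic position inside an exon."""
    acc = 0
    for exon in model.exons:
        if exon.start + 1 <= pos_1based <= exon.end:
            if model.strand == "+":
                return acc + (pos_1based - (exon.start + 1))
            return acc + (exon.end - pos_1based)
        acc += exon.length
    return None


def build_chimeric(
    fusion,
    annotation: AnnotationSet,
    genome: GenomeRef,
    uar_extension: int = DEFAULT_UAR_EXTENSION,
) -> ChimericTranscript:
    """Assemble the fused transcript sequence for a curated fusion.

    ``fusion`` needs five_gene/five_pos, three_gene/three_chrom/three_pos/
    three_strand attributes (1-based coordinates).  The 5' breakpoint must
    be a transcript-oriented exon end of the 5' gene.
    """
    five = annotation.representative_model(fusion.five_gene)
    if five is None:
        raise KeyError(f"5' gene {fusion.five_gene!r} not in annotation")
    rank = _exon_end_rank(five, fusion.five_pos)
    if rank is None:
        raise NonExonicJunctionError(
            f"non-exonic 5' junction at {five.chrom}:{fusion.five_pos}"
        )
    five_seq = "".join(
        _exon_seq(five, genome, e) for e in five.exons if e.rank <= rank
    )
    if five.cds_span is not None:
        cds_start, cds_end = five.cds_span
        five_coding = max(0, min(len(five_seq), cds_end) - cds_start)
    else:
        five_coding = 0

    three_gene = getattr(fusion, "three_gene", "UAR")
    if three_gene != "UAR":
        three = annotation.representative_model(three_gene)
        if three is None:
            raise KeyError(f"3' gene {three_gene!r} not in annotation")
        entry = _tx_offset_of_position(three, fusion.three_pos)
        if entry is None:
            raise NonExonicJunctionError(
                f"3' junction {three.chrom}:{fusion.three_pos} outside exons of {three_gene}"
            )
        three_seq = three.spliced_sequence(genome)[entry:]
        three_class = (
            "annotated_coding" if three.biotype == "coding" else "annotated_noncoding"
        )
        return ChimericTranscript(
            sequence=five_seq + three_seq,
            junction_offset=len(five_seq),
            five_model=five,
            five_exons_retained=rank,
            five_coding_bases=five_coding,
            three_model=three,
            three_entry_offset=entry,
            three_class=three_class,
        )
    # UAR partner: raw genomic continuation on the split-hit strand
    chrom = fusion.three_chrom
    pos = fusion.three_pos
    strand = getattr(fusion, "three_strand", "+")
    n = genome.length(chrom)
    if strand == "+":
        seq = genome.fetch(chrom, pos - 1, min(n, pos - 1 + uar_extension))
    else:
        seq = reverse_complement(genome.fetch(chrom, max(0, pos - uar_extension), pos))
    return ChimericTranscript(
        sequence=five_seq + seq,
        junction_offset=len(five_seq),
        five_model=five,
        five_exons_retained=rank,
        five_coding_bases=five_coding,
        three_model=None,
        three_entry_offset=None,
        three_class="UAR",
    )


def _exon_seq(model: GeneModel, genome: GenomeRef, exon) -> str:
    seq = genome.fetch(model.chrom, exon.start, exon.end)
    return reverse_complement(seq) if model.strand == "-" else seq


def _translate_to_stop(seq: str) -> str:
    coding = seq[: len(seq) - len(seq) % 3]
    return str(Seq(coding).translate(to_stop=True))


def _scan_orf(seq: str, min_orf: int) -> Optional[str]:
    """Longest ATG-initiated ORF of >= min_orf codons, scanning all frames."""
    best = None
    for frame in range(3):
        i = frame
        while i + 3 <= len(seq):
            if seq[i : i + 3] == "ATG":
                pep = _translate_to_stop(seq[i:])
                if len(pep) >= min_orf and (best is None or len(pep) > len(best)):
                    best = pep
                i += 3
            else:
                i += 3
    return best


def classify_structure(
    chimeric: ChimericTranscript, min_orf: int = DEFAULT_MIN_ORF
) -> StructureCall:
    """Classify the junction's predicted effect on the protein product."""
    five = chimeric.five_model
    seq = chimeric.sequence
    junction = chimeric.junction_offset

    if five.cds_span is None:
        pep = _scan_orf(seq, min_orf)
        if pep is None:
            return StructureCall("no_protein", "", False)
        return StructureCall("truncated_gene", pep, False)

    cds_start, cds_end = five.cds_span
    peptide = _translate_to_stop(seq[cds_start:])
    stop_nt = cds_start + 3 * len(peptide)

    # promoter-only contribution from the 5' gene
    if junction <= cds_start:
        if chimeric.three_class == "annotated_coding":
            assert chimeric.three_model is not None
            p_start, p_end = chimeric.three_model.cds_span or (0, 0)
            d3 = chimeric.three_entry_offset or 0
            if chimeric.three_model.cds_span is None:
                return StructureCall("no_protein", "", False)
            if d3 <= p_start:
                pep3 = _translate_to_stop(
                    seq[junction + (p_start - d3):]
                )
                return StructureCall("promoter_swap_full", pep3, False)
            if d3 < p_end:
                pep3 = _scan_orf(seq[junction:], min_orf) or ""
                cls = "promoter_swap_n_truncated" if pep3 else "no_protein"
                return StructureCall(cls, pep3, False)
        pep = _scan_orf(seq, min_orf)
        if pep is None:
            return StructureCall("no_protein", "", False)
        return StructureCall("truncated_gene", pep, False)

    # full 5' CDS retained: only the 3' UTR changes
    if junction >= cds_end:
        return StructureCall("extended_3utr", peptide, False)

    # junction inside the 5' CDS
    L5 = chimeric.five_coding_bases
    if chimeric.three_class == "annotated_noncoding":
        return StructureCall("noncoding_truncation", peptide, True)
    if chimeric.three_class == "UAR":
        return StructureCall("truncated_gene", peptide, True)

    assert chimeric.three_model is not None
    if chimeric.three_model.cds_span is None:
        return StructureCall("noncoding_truncation", peptide, True)
    p_start, p_end = chimeric.three_model.cds_span
    d3 = chimeric.three_entry_offset or 0
    frame_ok = (L5 - (d3 - p_start)) % 3 == 0
    # residues of the 3' partner appear only if translation passes the point
    # where the partner's CDS begins in the fused sequence
    partner_cds_entry = junction + max(0, p_start - d3)
    reaches_partner = stop_nt > partner_cds_entry
    if frame_ok and d3 < p_end and reaches_partner:
        return StructureCall("in_frame", peptide, False)
    return StructureCall("out_of_frame", peptide, True)


def wildtype_peptide(model: GeneModel, genome: GenomeRef) -> str:
    """Translate a gene model's annotated CDS."""
    if model.cds_span is None:
        return ""
    tx = model.spliced_sequence(genome)
    return _translate_to_stop(tx[model.cds_span[0] :])


def kinase_domain_retained(
    call: StructureCall,
    domains: dict[str, list[tuple[str, int, int]]],
    partner_peptides: dict[str, str],
) -> bool:
    """True iff the fusion peptide keeps a complete annotated domain.

    ``domains`` maps gene symbol -> [(domain name, aa_start, aa_end)] with
    1-based inclusive protein coordinates; ``partner_peptides`` maps symbol
    -> wild-type peptide.  The test is containment of the unbroken domain
    image in the predicted peptide.
    """
    annotated = [
        (symbol, iv)
        for symbol, ivs in domains.items()
        if symbol in partner_peptides
        for iv in ivs
    ]
    if not annotated:
        warnings.warn("no domain annotation for either partner")
        return False
    for symbol, (_name, aa_start, aa_end) in annotated:
        wt = partner_peptides[symbol]
        if aa_end > len(wt):
            continue
        image = wt[aa_start - 1 : aa_end]
        if image and image in call.peptide:
            return True
    return False


def read_domain_tsv(path) -> dict[str, list[tuple[str, int, int]]]:
    """Read domain intervals: gene symbol, domain name, aa_start, aa_end."""
    out: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{ln}: expected 4 columns")
            symbol, name, start, end = fields
            out.setdefault(symbol, []).append((name, int(start), int(end)))
    return out
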