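"""Split-align consensus sequences and count junction-spanning reads.

A fusion consensus decomposes into an exon-side part, which must align to
the anchor gene's flanking exon at high identity, and a distal part that
must map *uniquely* elsewhere in the genome.  The aligner is deterministic
seed-and-extend: exact 16-mer seeds, ungapped extension (match +1,
mismatch -2), and an acceptance rule on the best-versus-second-best score
margin at distinct loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .annotation import AnnotationSet, GeneModel, GenomeRef, reverse_complement
from .colorspace import ColorRead, ConsensusSeq

DEFAULT_SEED_K = 16
DEFAULT_MIN_PART_LEN = 20
DEFAULT_MIN_MARGIN = 8
MATCH_SCORE = 1
MISMATCH_SCORE = -2
ANCHOR_MIN_IDENTITY = 0.95


@dataclass(frozen=True)
class SplitHit:
    """One ungapped placement of a query interval on the genome."""

    q_start: int
    q_end: int
    chrom: str
    strand: str
    ref_start: int  # 0-based
    ref_end: int    # half-open
    score: int
    identity: float


@dataclass
class FusionCandidate:
    """A 5'->3' fusion junction with partner loci and read support."""

    sample: str
    five_gene: str
    five_chrom: str
    five_strand: str
    five_pos: int  # 1-based last 5'-side base
    three_gene: str
    three_chrom: str
    three_strand: str
    three_pos: int  # 1-based first 3'-side base
    partner_class: str = "annotated_coding"
    junction_reads: int = 0
    wt5: Optional[int] = None
    wt3: Optional[int] = None
    fusion_sequence: str = ""
    source: str = "internal"
    provenance: set = field(default_factory=set)
    candidate_only: bool = False
    reject_reason: Optional[str] = None

    @property
    def gene_pair(self) -> tuple[str, str]:
        return (self.five_gene, self.three_gene)


class GenomeIndex:
    """Exact k-mer index over the forward strand of every chromosome."""

    def __init__(self, genome: GenomeRef, k: int = DEFAULT_SEED_K):
        self.genome = genome
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom in genome.chrom_names:
            seq = genome.sequences[chrom]
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((chrom, i))

    def seed_positions(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])


def _extend_ungapped(
    query: str, seq: str, q_pos: int, r_pos: int, k: int, x_drop: int = 8
) -> tuple[int, int, int, int, int, float]:
    """Extend a seed in both directions; returns (qs, qe, rs, re, score, identity)."""
    # right extension
    qe, re_ = q_pos + k, r_pos + k
    score = k * MATCH_SCORE
    best_score, best_qe, best_re = score, qe, re_
    while qe < len(query) and re_ < len(seq):
        score += MATCH_SCORE if query[qe] == seq[re_] else MISMATCH_SCORE
        qe += 1
        re_ += 1
        if score > best_score:
            best_score, best_qe, best_re = score, qe, re_
        elif best_score - score > x_drop:
            break
    # left extension
    qs, rs = q_pos, r_pos
    score = best_score
    best_qs, best_rs = qs, rs
    best_total = score
    while qs > 0 and rs > 0:
        score += MATCH_SCORE if query[qs - 1] == seq[rs - 1] else MISMATCH_SCORE
        qs -= 1
        rs -= 1
        if score > best_total:
            best_total, best_qs, best_rs = score, qs, rs
        elif best_total - score > x_drop:
            break
    qs, rs, qe, re_, score = best_qs, best_rs, best_qe, best_re, best_total
    matches = sum(1 for a, b in zip(query[qs:qe], seq[rs:re_]) if a == b)
    identity = matches / (qe - qs) if qe > qs else 0.0
    return qs, qe, rs, re_, score, identity


def _forward_hits(
    query: str, index: GenomeIndex, chrom_filter: Optional[str] = None
) -> list[SplitHit]:
    """Best ungapped hit per (chrom, diagonal) for the forward query."""
    k = index.k
    best: dict[tuple[str, int], SplitHit] = {}
    for i in range(0, max(1, len(query) - k + 1)):
        kmer = query[i : i + k]
        if len(kmer) < k:
            break
        for chrom, pos in index.seed_positions(kmer):
            if chrom_filter is not None and chrom != chrom_filter:
                continue
            diag = pos - i
            key = (chrom, diag)
            if key in best:
                continue
            seq = index.genome.sequences[chrom]
            qs, qe, rs, re_, score, ident = _extend_ungapped(query, seq, i, pos, k)
            best[key] = SplitHit(qs, qe, chrom, "+", rs, re_, score, ident)
    return list(best.values())


def find_hits(
    query: str, index: GenomeIndex, chrom_filter: Optional[str] = None
) -> list[SplitHit]:
    """Ungapped hits of a query on both strands, best first.

    Minus-strand hits report the query interval in query coordinates and the
    reference interval on the forward reference; the query segment matches
    the reverse complement of that reference slice.
    """
    hits = _forward_hits(query, index, chrom_filter)
    rc = reverse_complement(query)
    n = len(query)
    for hit in _forward_hits(rc, index, chrom_filter):
        hits.append(
            SplitHit(
                q_start=n - hit.q_end,
                q_end=n - hit.q_start,
                chrom=hit.chrom,
                strand="-",
                ref_start=hit.ref_start,
                ref_end=hit.ref_end,
                score=hit.score,
                identity=hit.identity,
            )
        )
    hits.sort(key=lambda h: (-h.score, h.chrom, h.ref_start, h.strand))
    return hits


def _distinct_loci(hits: Sequence[SplitHit], slop: int = 50) -> list[SplitHit]:
    """Collapse hits whose reference placements overlap; keep the best."""
    kept: list[SplitHit] = []
    for hit in hits:
        clash = False
        for other in kept:
            if (
                hit.chrom == other.chrom
                and hit.ref_start < other.ref_end + slop
                and other.ref_start < hit.ref_end + slop
            ):
                clash = True
                break
        if not clash:
            kept.append(hit)
    return kept


def split_align(
    consensus: ConsensusSeq | str,
    genome: GenomeRef,
    annotation: AnnotationSet,
    anchor_gene: GeneModel,
    index: Optional[GenomeIndex] = None,
    min_part_len: int = DEFAULT_MIN_PART_LEN,
    min_margin: int = DEFAULT_MIN_MARGIN,
    sample: str = "",
) -> Optional[FusionCandidate]:
    """Split a consensus into anchor-exon and distal parts.

    The exon-side part must align to the anchor gene with identity >= 0.95
    reaching one end of the query; the remainder must map genome-wide to a
    single best locus with score margin >= ``min_margin`` over the runner-up
    and must fall outside the anchor gene (otherwise the call is rejected as
    "intragenic" or "non-unique").  Breakpoints are reported 1-based: last
    exon-side base and first distal base, and the candidate is written in
    fusion-transcript (5'->3') orientation.
    """
    query = consensus.sequence if isinstance(consensus, ConsensusSeq) else consensus
    if len(query) < 2 * min_part_len:
        return None
    if index is None:
        index = GenomeIndex(genome)
    span = anchor_gene.span
    anchor_hits = [
        h
        for h in find_hits(query, index, chrom_filter=anchor_gene.chrom)
        if h.ref_start < span[1] and h.ref_end > span[0]
        and h.identity >= ANCHOR_MIN_IDENTITY
        and (h.q_end - h.q_start) >= min_part_len
    ]
    # the exon part must reach one end of the query
    anchor_hits = [h for h in anchor_hits if h.q_start <= 2 or h.q_end >= len(query) - 2]
    if not anchor_hits:
        return None
    anchor_hit = anchor_hits[0]
    anchor_at_start = anchor_hit.q_start <= 2

    if anchor_at_start:
        remainder = query[anchor_hit.q_end :]
        rem_offset = anchor_hit.q_end
    else:
        remainder = query[: anchor_hit.q_start]
        rem_offset = 0
    if len(remainder) < min_part_len:
        return None

    rem_hits = _distinct_loci(
        [
            h
            for h in find_hits(remainder, index)
            if h.identity >= ANCHOR_MIN_IDENTITY
            and (h.q_end - h.q_start) >= min_part_len
        ]
    )
    if not rem_hits:
        return None
    best = rem_hits[0]
    if (
        best.chrom == anchor_gene.chrom
        and best.ref_start < span[1]
        and best.ref_end > span[0]
    ):
        return _rejected(sample, anchor_gene, "intragenic")
    if len(rem_hits) > 1 and best.score - rem_hits[1].score < min_margin:
        return _rejected(sample, anchor_gene, "non-unique")

    # refine the split point jointly on the two diagonals: seed extension can
    # overshoot a junction when flanking bases coincide by chance
    split = _refine_split(
        query, genome, anchor_hit, best, rem_offset, anchor_at_start, min_part_len
    )
    if split is None:
        return None

    if anchor_at_start:
        five_pos = _diag_ref_pos(anchor_hit, split - 1, 0) + 1
        five_strand = anchor_hit.strand
        three_pos = _diag_ref_pos(best, split, rem_offset) + 1
        three_strand = best.strand
        five = (anchor_gene.symbol, anchor_gene.chrom, five_strand, five_pos)
        partner_locus = (best.chrom, best.ref_start, best.ref_end)
        partner_class = classify_three_prime_partner(partner_locus, annotation)
        partner_name = _partner_name(partner_locus, annotation, partner_class)
        three = (partner_name, best.chrom, three_strand, three_pos)
    else:
        # anchor side is the 3' partner; distal part is 5'
        five_pos = _diag_ref_pos(best, split - 1, 0) + 1
        five_strand = best.strand
        partner_locus = (best.chrom, best.ref_start, best.ref_end)
        partner_class = classify_three_prime_partner(partner_locus, annotation)
        partner_name = _partner_name(partner_locus, annotation, partner_class)
        five = (partner_name, best.chrom, five_strand, five_pos)
        three_pos = _diag_ref_pos(anchor_hit, split, 0) + 1
        three_strand = anchor_hit.strand
        three = (anchor_gene.symbol, anchor_gene.chrom, three_strand, three_pos)
        partner_class = "annotated_coding" if anchor_gene.biotype == "coding" else "annotated_noncoding"

    return FusionCandidate(
        sample=sample,
        five_gene=five[0],
        five_chrom=five[1],
        five_strand=five[2],
        five_pos=five[3],
        three_gene=three[0],
        three_chrom=three[1],
        three_strand=three[2],
        three_pos=three[3],
        partner_class=partner_class,
        junction_reads=len(consensus.member_ids)
        if isinstance(consensus, ConsensusSeq)
        else 0,
        fusion_sequence=query,
        source="internal",
        provenance={"internal"},
    )


def _rejected(sample: str, anchor_gene: GeneModel, reason: str) -> None:
    # rejections return None; reason retained for logging by callers
    return None


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _diag_ref_pos(hit: SplitHit, q_index: int, q_offset: int) -> int:
    """0-based reference position for a query index along a hit's diagonal.

    ``q_offset`` converts full-query indexes to the coordinate system the hit
    was computed in (nonzero when the hit came from a query suffix).
    """
    q = q_index - q_offset
    if hit.strand == "+":
        return hit.ref_start + (q - hit.q_start)
    return hit.ref_end - 1 - (q - hit.q_start)


def _diag_base(genome: GenomeRef, hit: SplitHit, q_index: int, q_offset: int) -> Optional[str]:
    pos = _diag_ref_pos(hit, q_index, q_offset)
    seq = genome.sequences[hit.chrom]
    if not (0 <= pos < len(seq)):
        return None
    base = seq[pos]
    return base if hit.strand == "+" else _COMP.get(base, "N")


def _refine_split(
    query: str,
    genome: GenomeRef,
    anchor_hit: SplitHit,
    distal_hit: SplitHit,
    rem_offset: int,
    anchor_at_start: bool,
    min_part_len: int,
) -> Optional[int]:
    """Split point maximizing total matches over the two fixed diagonals.

    Ties break toward the split implied by the seed hits.  Returns the
    full-query index of the first distal-side base (anchor at query start)
    or the first anchor-side base (anchor at query end).
    """
    n = len(query)
    if anchor_at_start:
        left_hit, left_off = anchor_hit, 0
        right_hit, right_off = distal_hit, rem_offset
        initial = anchor_hit.q_end
    else:
        left_hit, left_off = distal_hit, 0
        right_hit, right_off = anchor_hit, 0
        initial = anchor_hit.q_start
    left = [0] * (n + 1)  # matches of query[:p] on the left diagonal
    for i in range(n):
        base = _diag_base(genome, left_hit, i, left_off)
        left[i + 1] = left[i] + (1 if base == query[i] else 0)
    right = [0] * (n + 1)  # matches of query[p:] on the right diagonal
    for i in range(n - 1, -1, -1):
        base = _diag_base(genome, right_hit, i, right_off)
        right[i] = right[i + 1] + (1 if base == query[i] else 0)
    best_p, best_score = None, -1
    for p in range(min_part_len, n - min_part_len + 1):
        score = left[p] + right[p]
        if score > best_score or (
            score == best_score and abs(p - initial) < abs(best_p - initial)
        ):
            best_p, best_score = p, score
    return best_p


def classify_three_prime_partner(
    locus: tuple[str, int, int], annotation: AnnotationSet
) -> str:
    """annotated_coding / annotated_noncoding / UAR for a reference locus."""
    chrom, start, end = locus
    models = annotation.overlapping(chrom, start, end)
    if any(m.biotype == "coding" for m in models):
        return "annotated_coding"
    if models:
        return "annotated_noncoding"
    return "UAR"


def _partner_name(
    locus: tuple[str, int, int], annotation: AnnotationSet, partner_class: str
) -> str:
    if partner_class == "UAR":
        return "UAR"
    chrom, start, end = locus
    models = annotation.overlapping(chrom, start, end)
    coding = [m for m in models if m.biotype == "coding"]
    pool = coding or models
    return sorted(pool, key=lambda m: m.gene_id)[0].symbol


# ---------------------------------------------------------------------------
# Junction support counting

DEFAULT_JUNCTION_FLANK = 45
DEFAULT_SUPPORT_MIN_ANCHOR = 10


def _read_sequences(reads: Iterable) -> list[str]:
    out = []
    for read in reads:
        if isinstance(read, ColorRead):
            out.append(read.bases)
        else:
            out.append(str(read))
    return out


def _spliced_prefix_window(model: GeneModel, genome: GenomeRef, rank: int, flank: int) -> str:
    """Last ``flank`` transcript bases through exon ``rank``."""
    seq = "".join(
        _exon_seq(model, genome, e) for e in model.exons if e.rank <= rank
    )
    return seq[-flank:]


def _spliced_suffix_window(model: GeneModel, genome: GenomeRef, rank: int, flank: int) -> str:
    """First ``flank`` transcript bases from exon ``rank`` onward."""
    seq = "".join(
        _exon_seq(model, genome, e) for e in model.exons if e.rank >= rank
    )
    return seq[:flank]


def _exon_seq(model: GeneModel, genome: GenomeRef, exon) -> str:
    seq = genome.fetch(model.chrom, exon.start, exon.end)
    return reverse_complement(seq) if model.strand == "-" else seq


def _boundary_rank_5p(model: GeneModel, pos_1based: int) -> Optional[int]:
    """Rank of the exon whose transcript-oriented end is at ``pos_1based``."""
    for exon in model.exons:
        last = exon.end if model.strand == "+" else exon.start + 1
        if last == pos_1based:
            return exon.rank
    return None


def _boundary_rank_3p(model: GeneModel, pos_1based: int) -> Optional[int]:
    """Rank of the exon whose transcript-oriented start is at ``pos_1based``."""
    for exon in model.exons:
        first = exon.start + 1 if model.strand == "+" else exon.end
        if first == pos_1based:
            return exon.rank
    return None


def _count_spanning(
    reads: list[str], window: str, junction_offset: int, min_anchor: int, max_mismatch: int
) -> int:
    import edlib

    count = 0
    for seq in reads:
        hit = False
        for cand in (seq, reverse_complement(seq)):
            res = edlib.align(cand, window, mode="HW", task="locations")
            if res["editDistance"] < 0 or res["editDistance"] > max_mismatch:
                continue
            for start, end in res["locations"]:
                # edlib locations are inclusive
                if start <= junction_offset - min_anchor and end + 1 >= junction_offset + min_anchor:
                    hit = True
                    break
            if hit:
                break
        if hit:
            count += 1
    return count


def count_junction_support(
    reads: Iterable,
    candidate: FusionCandidate,
    genome: GenomeRef,
    annotation: AnnotationSet,
    min_anchor: int = DEFAULT_SUPPORT_MIN_ANCHOR,
    flank: int = DEFAULT_JUNCTION_FLANK,
    max_mismatch: int = 2,
) -> tuple[int, Optional[int], Optional[int]]:
    """Count fusion-junction and wild-type-junction spanning reads.

    A read spans a junction when it aligns to the junction window (edit
    distance <= ``max_mismatch``) covering >= ``min_anchor`` bases on each
    side.  Wild-type counts are taken at the spliced exon-exon junction of
    each partner at the corresponding breakpoint; a UAR partner has no
    wild-type junction (None).
    """
    seqs = _read_sequences(reads)
    five_model = annotation.representative_model(candidate.five_gene)

    # fusion window: 5' side flank + 3' side flank, rebuilt from the genome
    five_flank = _genomic_side_window(genome, candidate, "5", flank, five_model)
    three_flank = _genomic_side_window(genome, candidate, "3", flank, None)
    window = five_flank + three_flank
    junction_reads = _count_spanning(
        seqs, window, len(five_flank), min_anchor, max_mismatch
    )

    wt5 = wt3 = None
    if five_model is not None:
        rank = _boundary_rank_5p(five_model, candidate.five_pos)
        if rank is not None and rank < len(five_model.exons):
            w5 = _spliced_prefix_window(five_model, genome, rank, flank)
            w5b = _spliced_suffix_window(five_model, genome, rank + 1, flank)
            wt5 = _count_spanning(
                seqs, w5 + w5b, len(w5), min_anchor, max_mismatch
            )
        else:
            wt5 = 0
    if candidate.three_gene != "UAR":
        three_model = annotation.representative_model(candidate.three_gene)
        if three_model is not None:
            rank = _boundary_rank_3p(three_model, candidate.three_pos)
            if rank is not None and rank > 1:
                w3a = _spliced_prefix_window(three_model, genome, rank - 1, flank)
                w3b = _spliced_suffix_window(three_model, genome, rank, flank)
                wt3 = _count_spanning(
                    seqs, w3a + w3b, len(w3a), min_anchor, max_mismatch
                )
            else:
                wt3 = 0
    return junction_reads, wt5, wt3


def _genomic_side_window(
    genome: GenomeRef,
    candidate: FusionCandidate,
    side: str,
    flank: int,
    model: Optional[GeneModel],
) -> str:
    """Fusion-transcript-oriented sequence flanking the junction on one side."""
    if side == "5":
        chrom, strand, pos = candidate.five_chrom, candidate.five_strand, candidate.five_pos
        if model is not None:
            rank = _boundary_rank_5p(model, pos)
            if rank is not None:
                return _spliced_prefix_window(model, genome, rank, flank)
        if strand == "+":
            start = max(0, pos - flank)
            return genome.fetch(chrom, start, pos)
        seq = genome.fetch(
            chrom, pos - 1, min(genome.length(chrom), pos - 1 + flank)
        )
        return reverse_complement(seq)
    chrom, strand, pos = candidate.three_chrom, candidate.three_strand, candidate.three_pos
    if strand == "+":
        return genome.fetch(chrom, pos - 1, min(genome.length(chrom), pos - 1 + flank))
    seq = genome.fetch(chrom, max(0, pos - flank), pos)
    return reverse_complement(seq)
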