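import numpy as np
import pytest

from fusewalk.annotation import AnnotationSet, Exon, GeneModel, GenomeRef
from fusewalk.colorspace import extract_partial_reads, build_consensus
from fusewalk.copynumber import SegmentSet
from fusewalk.splitmap import (
    FusionCandidate,
    GenomeIndex,
    classify_three_prime_partner,
    count_junction_support,
    split_align,
)


def _toy_world(seed=7, dup_remainder=False):
    """Two-chromosome toy genome with one anchor gene and a distal locus."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    chr1 = "".join(bases[rng.integers(0, 4, 30_000)])
    chr2 = "".join(bases[rng.integers(0, 4, 30_000)])
    exon1 = (1_000, 1_500)
    exon2 = (2_000, 2_500)
    gene = GeneModel(
        "anchor", "ANCHOR", "chr1", "+",
        [Exon("chr1", *exon1, 1), Exon("chr1", *exon2, 2)],
    )
    if dup_remainder:
        # plant the distal 25-mer twice
        seg = chr2[10_000:10_025]
        chr2 = chr2[:20_000] + seg + chr2[20_025:]
    genome = GenomeRef({"chr1": chr1, "chr2": chr2})
    ann = AnnotationSet([gene])
    return genome, ann, gene


class TestSplitAlign:
    def test_planted_split_recovers_breakpoints(self):
        genome, ann, gene = _toy_world()
        # 25 bp ending at exon 1's end + 25 bp from chr2:10001
        query = genome.fetch("chr1", 1_475, 1_500) + genome.fetch("chr2", 10_000, 10_025)
        cand = split_align(query, genome, ann, gene, min_part_len=20)
        assert cand is not None
        assert (cand.five_chrom, cand.five_pos) == ("chr1", 1_500)
        assert (cand.three_chrom, cand.three_pos) == ("chr2", 10_001)
        assert cand.partner_class == "UAR"

    def test_wholly_intragenic_consensus_rejected(self):
        genome, ann, gene = _toy_world()
        query = genome.fetch("chr1", 1_440, 1_500)
        assert split_align(query, genome, ann, gene) is None

    def test_non_unique_remainder_rejected(self):
        genome, ann, gene = _toy_world(dup_remainder=True)
        query = genome.fetch("chr1", 1_475, 1_500) + genome.fetch("chr2", 10_000, 10_025)
        assert split_align(query, genome, ann, gene) is None

    def test_minus_strand_distal_part(self):
        genome, ann, gene = _toy_world()
        from fusewalk.annotation import reverse_complement

        # remove chance micro-homology at the junction so the planted
        # breakpoints are the unique optimum
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        chr1 = list(genome.sequences["chr1"])
        chr2 = list(genome.sequences["chr2"])
        first_distal = comp[chr2[10_029]]
        if chr1[1_500] == first_distal:
            chr1[1_500] = next(b for b in "ACGT" if b != first_distal)
        if comp[chr2[10_030]] == chr1[1_499]:
            chr2[10_030] = next(b for b in "ACGT" if comp[b] != chr1[1_499])
        genome = GenomeRef({"chr1": "".join(chr1), "chr2": "".join(chr2)})

        distal = reverse_complement(genome.fetch("chr2", 10_000, 10_030))
        query = genome.fetch("chr1", 1_470, 1_500) + distal
        cand = split_align(query, genome, ann, gene)
        assert cand is not None
        assert cand.three_strand == "-"
        assert cand.three_pos == 10_030  # first distal base, 1-based

    def test_locality_under_unrelated_chromosome_reversal(self):
        genome, ann, gene = _toy_world()
        query = genome.fetch("chr1", 1_475, 1_500) + genome.fetch("chr2", 10_000, 10_025)
        cand1 = split_align(query, genome, ann, gene)
        flipped = GenomeRef(
            {
                "chr1": genome.sequences["chr1"],
                "chr2": genome.sequences["chr2"],
                "chr3": genome.sequences["chr1"][::-1],
            }
        )
        cand2 = split_align(query, flipped, ann, gene)
        assert (cand1.five_pos, cand1.three_pos) == (cand2.five_pos, cand2.three_pos)

    def test_recovers_planted_junctions_exactly_on_cohort(self, cohort):
        _, ref, _, truths, reads = cohort
        index = GenomeIndex(ref.genome)
        for truth in truths:
            anchor = ref.annotation.get(truth.five_gene_id)
            partial = extract_partial_reads(
                reads.color_reads[truth.sample], truth.five_pos, chrom=truth.five_chrom
            )
            consensuses = build_consensus(partial)
            assert consensuses, f"no consensus for {truth.five_gene}"
            cands = [
                split_align(c, ref.genome, ref.annotation, anchor, index=index)
                for c in consensuses
            ]
            hits = [
                c
                for c in cands
                if c is not None
                and (c.five_pos, c.three_pos) == (truth.five_pos, truth.three_pos)
            ]
            assert hits, f"junction missed for {truth.five_gene}->{truth.three_gene}"
            assert hits[0].junction_reads >= 2  # >= consensus min_support


class TestPartnerClass:
    def test_three_way_classification(self, reference):
        ann = reference.annotation
        coding = next(m for m in ann if m.biotype == "coding")
        noncoding = next(m for m in ann if m.biotype == "noncoding")
        s, e = coding.exons[0].start, coding.exons[0].end
        assert classify_three_prime_partner((coding.chrom, s, e), ann) == "annotated_coding"
        s, e = noncoding.exons[0].start, noncoding.exons[0].end
        assert (
            classify_three_prime_partner((noncoding.chrom, s, e), ann)
            == "annotated_noncoding"
        )
        uar = reference.uar_regions[coding.chrom]
        assert (
            classify_three_prime_partner((coding.chrom, uar[0] + 100, uar[0] + 200), ann)
            == "UAR"
        )


class TestJunctionSupport:
    def test_no_spanning_reads(self, cohort):
        _, ref, _, truths, _ = cohort
        truth = truths[0]
        cand = FusionCandidate(
            sample=truth.sample,
            five_gene=truth.five_gene,
            five_chrom=truth.five_chrom,
            five_strand=truth.five_strand,
            five_pos=truth.five_pos,
            three_gene=truth.three_gene,
            three_chrom=truth.three_chrom,
            three_strand=truth.three_strand,
            three_pos=truth.three_pos,
            junction_reads=1,
        )
        jr, wt5, wt3 = count_junction_support([], cand, ref.genome, ref.annotation)
        assert jr == 0

    def test_uar_partner_has_no_wildtype_junction(self, cohort):
        _, ref, _, truths, reads = cohort
        truth = next(t for t in truths if t.three_gene == "UAR")
        cand = FusionCandidate(
            sample=truth.sample,
            five_gene=truth.five_gene,
            five_chrom=truth.five_chrom,
            five_strand=truth.five_strand,
            five_pos=truth.five_pos,
            three_gene="UAR",
            three_chrom=truth.three_chrom,
            three_strand=truth.three_strand,
            three_pos=truth.three_pos,
            junction_reads=1,
        )
        jr, wt5, wt3 = count_junction_support(
            reads.base_reads[truth.sample], cand, ref.genome, ref.annotation
        )
        assert wt3 is None
        assert jr > 0 and wt5 is not None

    def test_counts_track_planted_depth(self):
        """At planted depth 30 the anchored junction count stays within
        3 sd of the Poisson expectation (reads must clear the per-side
        minimum anchor, which trims the expectation by the anchor fraction).
        """
        from fusewalk.simulate import (
            SimConfig,
            FusionSpec,
            plant_fusions,
            simulate_reads_and_expression,
            simulate_reference,
        )

        cfg = SimConfig(
            seed=5, fusions=[FusionSpec("none", "in_frame", junction_depth=30)]
        )
        ref = simulate_reference(cfg)
        _, truths = plant_fusions(cfg, ref)
        reads = simulate_reads_and_expression(cfg, ref, truths)
        truth = truths[0]
        cand = FusionCandidate(
            sample=truth.sample,
            five_gene=truth.five_gene,
            five_chrom=truth.five_chrom,
            five_strand=truth.five_strand,
            five_pos=truth.five_pos,
            three_gene=truth.three_gene,
            three_chrom=truth.three_chrom,
            three_strand=truth.three_strand,
            three_pos=truth.three_pos,
            junction_reads=1,
        )
        jr, _, _ = count_junction_support(
            reads.base_reads[truth.sample], cand, ref.genome, ref.annotation
        )
        # offsets are uniform over 41 positions; 31 clear the 10 bp anchor
        expect = 30 * 31 / 41
        assert abs(jr - expect) <= 3 * np.sqrt(30)
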