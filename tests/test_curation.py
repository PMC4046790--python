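import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from fusewalk.annotation import AnnotationSet, Exon, GeneModel
from fusewalk.curation import (
    CallerRecord,
    CurationParams,
    DialectError,
    apply_curation,
    merge_caller_records,
    read_caller_records,
)
from fusewalk.simulate import (
    SimConfig,
    emit_caller_files,
    plant_fusions,
    read_caller_sidecar,
    simulate_reference,
)

POTENTIAL = """\
S01 chr1-chr2 999 4999 ff
120 60 120
GENEA GENEB

S01 chr1-chr1 1999 7999 fr
30 15 30
GENEC GENED

S02 chr2-chr2 2999 8999 rr
45 20 45
GENEE GENEF
"""

RESULT = (
    "S01\tGENEA\tchr1\t999\tGENEB\tchr2\t4999\t120\t60\t120\tff\n"
)

SNOWSHOES = (
    "sample\tgene_5p\tchr_5p\tpos_5p\tstrand_5p\tgene_3p\tchr_3p\tpos_3p"
    "\tstrand_3p\tspan_reads\tisoform\n"
    "S03\tGENEG\tchr1\t1200\t+\tGENEH\tchr1\t5200\t+\t80\t1\n"
    "S03\tGENEG\tchr1\t1200\t+\tGENEH\tchr1\t6200\t+\t12\t2\n"
)


class TestDialects:
    def test_potential_records_are_candidate_only(self, tmp_path):
        p = tmp_path / "potential_fusion.txt"
        p.write_text(POTENTIAL)
        records = read_caller_records(p, "tophatfusion_potential")
        assert len(records) == 3
        assert all(r.candidate_only for r in records)
        # 0-based on disk -> 1-based in memory
        assert records[0].pos5 == 1000 and records[0].pos3 == 5000
        assert (records[1].strand5, records[1].strand3) == ("+", "-")

    def test_result_reconciliation_clears_candidate_only(self, tmp_path):
        p = tmp_path / "potential_fusion.txt"
        p.write_text(POTENTIAL)
        r = tmp_path / "result.txt"
        r.write_text(RESULT)
        merged = merge_caller_records(
            [
                read_caller_records(p, "tophatfusion_potential"),
                read_caller_records(r, "tophatfusion_result"),
            ]
        )
        by_pair = {m.pair: m for m in merged}
        assert not by_pair[("GENEA", "GENEB")].candidate_only
        assert by_pair[("GENEC", "GENED")].candidate_only
        assert len(by_pair[("GENEA", "GENEB")].provenance) == 2

    def test_snowshoes_isoforms_kept_distinct(self, tmp_path):
        p = tmp_path / "final_fusion_report_RNA.txt"
        p.write_text(SNOWSHOES)
        records = read_caller_records(p, "snowshoes")
        assert len(records) == 2
        assert {r.pos3 for r in records} == {5200, 6200}

    def test_unknown_layout_names_offender(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("sample\tnot\tthe\tright\theader\n")
        with pytest.raises(DialectError):
            read_caller_records(p, "snowshoes")
        with pytest.raises(DialectError):
            read_caller_records(p, "nonsense")


def _rec(**kw):
    base = dict(
        sample="S01", gene5="A", chrom5="chr1", pos5=1000, strand5="+",
        gene3="B", chrom3="chr1", pos3=5000, strand3="+",
        spanning_reads=150, caller="snowshoes",
    )
    base.update(kw)
    return CallerRecord(**base)


class TestMerge:
    def test_breakpoints_beyond_tolerance_kept_distinct(self):
        a = _rec(pos3=5000)
        b = _rec(pos3=5100)
        assert len(merge_caller_records([[a], [b]], tol=10)) == 2

    def test_identical_records_collapse_with_max_span(self):
        a = _rec(spanning_reads=100)
        b = _rec(spanning_reads=140, caller="tophatfusion")
        merged = merge_caller_records([[a], [b]], tol=10)
        assert len(merged) == 1
        assert merged[0].spanning_reads == 140
        assert merged[0].provenance == {"snowshoes", "tophatfusion"}

    def test_matches_bruteforce_pairwise_clustering(self):
        rng = np.random.default_rng(9)
        records = [
            _rec(
                sample=f"S{rng.integers(1, 3):02d}",
                gene5=rng.choice(["A", "B"]),
                gene3=rng.choice(["X", "Y"]),
                pos5=int(rng.integers(1000, 1040)),
                pos3=int(rng.integers(5000, 5040)),
                spanning_reads=int(rng.integers(1, 200)),
            )
            for _ in range(40)
        ]
        tol = 10
        merged = merge_caller_records([records], tol=tol)
        # brute-force greedy clustering in input order with the same key
        clusters = []
        for rec in records:
            for cl in clusters:
                ref = cl[0]
                if (
                    (ref.sample, ref.gene5, ref.gene3)
                    == (rec.sample, rec.gene5, rec.gene3)
                    and abs(ref.pos5 - rec.pos5) <= tol
                    and abs(ref.pos3 - rec.pos3) <= tol
                ):
                    cl.append(rec)
                    break
            else:
                clusters.append([rec])
        assert len(merged) == len(clusters)
        assert sorted(m.spanning_reads for m in merged) == sorted(
            max(r.spanning_reads for r in cl) for cl in clusters
        )


def _toy_annotation():
    def gene(gene_id, start, strand="+"):
        exons = [
            Exon("chr1", start, start + 200, 1),
            Exon("chr1", start + 500, start + 700, 2),
        ]
        if strand == "-":
            exons = [
                Exon("chr1", start + 500, start + 700, 1),
                Exon("chr1", start, start + 200, 2),
            ]
        return GeneModel(gene_id, gene_id, "chr1", strand, exons, cds_span=(50, 350))

    return AnnotationSet(
        [gene("A", 1_000), gene("B", 20_000), gene("C", 40_000, "-"), gene("MID", 10_000)]
    )


class TestCurationRules:
    @pytest.fixture
    def ann(self):
        return _toy_annotation()

    def _record(self, **kw):
        # breakpoints at A exon 1 end (1200) and B exon 2 start (20501)
        base = dict(
            sample="S01", gene5="A", chrom5="chr1", pos5=1200, strand5="+",
            gene3="B", chrom3="chr1", pos3=20_501, strand3="+",
            spanning_reads=150, wt5=10, wt3=10,
        )
        base.update(kw)
        return CallerRecord(**base)

    def test_printed_support_ratio_passes(self, ann):
        rec = self._record(spanning_reads=47, wt5=6, wt3=3)
        audited = apply_curation([rec], ann, {("S01", "A"): 12.0})
        assert audited[0].rule_ratio  # 47/6 > 2

    def test_wildtype_zero_passes_ratio(self, ann):
        rec = self._record(spanning_reads=31, wt5=31, wt3=0)
        audited = apply_curation([rec], ann, {("S01", "A"): 12.0})
        assert audited[0].rule_ratio

    def test_candidate_only_z_threshold(self, ann):
        low = self._record(candidate_only=True, spanning_reads=50)
        high = self._record(candidate_only=True, spanning_reads=50)
        a_low = apply_curation([low], ann, {("S01", "A"): 7.0})[0]
        a_high = apply_curation([high], ann, {("S01", "A"): 12.0})[0]
        assert not a_low.retained and not a_low.rule_candidate_z
        assert a_high.retained

    def test_blacklisted_pair_rejected(self, ann):
        rec = self._record(gene5="TFG", gene3="GPR128")
        audited = apply_curation([rec], ann, {("S01", "TFG"): 12.0})
        assert not audited[0].rule_blacklist and not audited[0].retained

    def test_non_boundary_rejected(self, ann):
        rec = self._record(pos5=1207, pos3=20_508)
        audited = apply_curation([rec], ann, {("S01", "A"): 12.0})
        assert not audited[0].rule_boundary

    def test_orientation_must_match_gene_strands(self, ann):
        rec = self._record(gene3="C", pos3=40_700, strand3="+")  # C is '-'
        audited = apply_curation([rec], ann, {("S01", "A"): 12.0})
        assert not audited[0].rule_orientation

    def test_adjacent_genes_discarded(self, ann):
        # A and MID have no gene between them
        rec = self._record(gene3="MID", pos3=10_501)
        audited = apply_curation([rec], ann, {("S01", "A"): 12.0})
        assert audited[0].adjacent and not audited[0].retained

    def test_audit_trail_conservation(self, ann):
        records = [self._record(pos5=1200 + i) for i in range(5)]
        audited = apply_curation(records, ann, None)
        assert [a.record for a in audited] == records

    def test_decoy_cohort_recovered_exactly(self, tmp_path):
        cfg = SimConfig(seed=1)
        ref = simulate_reference(cfg)
        _, truths = plant_fusions(cfg, ref)
        paths = emit_caller_files(
            truths, ref, tmp_path, dialect="tophatfusion", decoy_count=6, seed=3
        )
        merged = merge_caller_records(
            [
                read_caller_records(paths["potential"], "tophatfusion_potential"),
                read_caller_records(paths["result"], "tophatfusion_result"),
            ]
        )
        side = read_caller_sidecar(paths["sidecar"])
        zmap = {}
        wt = {}
        as_int = lambda v: None if pd.isna(v) else int(v)
        for row in side.itertuples():
            zmap[(row.sample, row.gene_5p)] = float(row.z)
            zmap[(row.sample, row.gene_3p)] = float(row.z)
            wt[(row.sample, row.gene_5p, row.gene_3p)] = (
                as_int(row.wt5), as_int(row.wt3),
            )
        wt_list = [wt[(m.sample, m.gene5, m.gene3)] for m in merged]
        audited = apply_curation(merged, ref.annotation, zmap, wt_counts=wt_list)
        truth_set = {(t.sample, t.five_gene, t.three_gene) for t in truths}
        for cf in audited:
            r = cf.record
            assert cf.retained == ((r.sample, r.gene5, r.gene3) in truth_set)


def brute_force_rules(record, wt, z, params, ann):
    """Independent re-statement of the curation conditions."""
    boundary = False
    for chrom, pos in ((record.chrom5, record.pos5), (record.chrom3, record.pos3)):
        try:
            if ann.is_known_exon_boundary(chrom, pos, params.boundary_tol):
                boundary = True
        except KeyError:
            pass
    observed = [w for w in wt if w is not None]
    ratio = (not observed) or any(
        w == 0 or record.spanning_reads / w > params.min_ratio for w in observed
    )
    support = record.spanning_reads >= params.min_span or z >= params.z_pass
    cand = (not record.candidate_only) or z >= params.z_candidate_only
    orient = True
    for sym, strand in ((record.gene5, record.strand5), (record.gene3, record.strand3)):
        models = ann.models_of_symbol(sym)
        if strand != "." and models and all(m.strand != strand for m in models):
            orient = False
    blk = (record.gene5, record.gene3) not in params.blacklist
    return boundary and ratio and support and cand and orient and blk


class TestCurationProperties:
    def _random_records(self, n, rng, ann):
        symbols = ["A", "B", "C", "MID", "GHOST"]
        records = []
        for i in range(n):
            records.append(
                CallerRecord(
                    sample="S01",
                    gene5=str(rng.choice(symbols)),
                    chrom5="chr1",
                    pos5=int(rng.choice([1200, 1501, 20_501, 777, 40_700])),
                    strand5=str(rng.choice(["+", "-", "."])),
                    gene3=str(rng.choice(symbols)),
                    chrom3="chr1",
                    pos3=int(rng.choice([1200, 20_501, 888, 40_001])),
                    strand3=str(rng.choice(["+", "-", "."])),
                    spanning_reads=int(rng.integers(0, 200)),
                    candidate_only=bool(rng.random() < 0.5),
                )
            )
        return records

    def test_matches_independent_evaluator(self):
        ann = _toy_annotation()
        rng = np.random.default_rng(13)
        params = CurationParams()
        records = self._random_records(300, rng, ann)
        zs = rng.uniform(0, 15, len(records))
        wts = [
            (
                None if rng.random() < 0.2 else int(rng.integers(0, 80)),
                None if rng.random() < 0.2 else int(rng.integers(0, 80)),
            )
            for _ in records
        ]
        zmap = {}
        for rec, z in zip(records, zs):
            zmap[(rec.sample, rec.gene5)] = max(
                zmap.get((rec.sample, rec.gene5), -math.inf), float(z)
            )
        audited = apply_curation(records, ann, zmap, wt_counts=wts, params=params)
        for cf, rec, wt in zip(audited, records, wts):
            z = max(
                zmap.get((rec.sample, rec.gene5), -math.inf),
                zmap.get((rec.sample, rec.gene3), -math.inf),
            )
            rules_pass = brute_force_rules(rec, wt, z, params, ann)
            adjacent = cf.adjacent
            assert cf.retained == (rules_pass and not adjacent)

    def test_monotone_under_threshold_tightening(self):
        ann = _toy_annotation()
        rng = np.random.default_rng(14)
        records = self._random_records(120, rng, ann)
        wts = [(int(rng.integers(0, 50)), int(rng.integers(0, 50))) for _ in records]
        zmap = {
            (r.sample, g): float(rng.uniform(0, 15))
            for r in records
            for g in (r.gene5, r.gene3)
        }
        loose = CurationParams()
        kept_loose = {
            id(cf.record)
            for cf in apply_curation(records, ann, zmap, wt_counts=wts, params=loose)
            if cf.retained
        }
        for tight in (
            CurationParams(min_ratio=4),
            CurationParams(min_span=180, z_pass=9),
            CurationParams(z_candidate_only=14),
        ):
            kept_tight = {
                id(cf.record)
                for cf in apply_curation(records, ann, zmap, wt_counts=wts, params=tight)
                if cf.retained
            }
            assert kept_tight <= kept_loose
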