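import gzip
import math
from types import SimpleNamespace

import numpy as np
import pytest
from scipy import stats

from fusewalk.copynumber import (
    CopySegment,
    SegmentSet,
    classify_mechanism,
    partner_copy_correlation,
    read_segments,
)

SEG_TEXT = (
    "sample\tchrom\tstart\tend\tn_markers\tseg_mean\n"
    "S1\tchr1\t1\t1000\t50\t0.1\n"
    "S1\tchr1\t1001\t5000\t80\t-0.4\n"
)


def _fusion(c5, p5, c3, p3):
    return SimpleNamespace(five_chrom=c5, five_pos=p5, three_chrom=c3, three_pos=p3)


def _segset(rows, sample="S"):
    return SegmentSet(
        sample, [CopySegment(sample, c, s, e, m) for c, s, e, m in rows]
    )


class TestSegIO:
    def test_two_segments_four_breakpoints(self, tmp_path):
        p = tmp_path / "a.seg"
        p.write_text(SEG_TEXT)
        segsets = read_segments(p)
        assert segsets["S1"].breakpoints("chr1") == [1, 1000, 1001, 5000]

    def test_gzip_identical(self, tmp_path):
        plain = tmp_path / "a.seg"
        plain.write_text(SEG_TEXT)
        gz = tmp_path / "a.seg.gz"
        with gzip.open(gz, "wt") as fh:
            fh.write(SEG_TEXT)
        a, b = read_segments(plain)["S1"], read_segments(gz)["S1"]
        assert a.breakpoints("chr1") == b.breakpoints("chr1")

    def test_unsorted_rows_sorted_silently(self, tmp_path):
        p = tmp_path / "a.seg"
        p.write_text(
            "sample\tchrom\tstart\tend\tn_markers\tseg_mean\n"
            "S1\tchr1\t1001\t5000\t80\t-0.4\n"
            "S1\tchr1\t1\t1000\t50\t0.1\n"
        )
        assert read_segments(p)["S1"].breakpoints("chr1") == [1, 1000, 1001, 5000]

    def test_overlap_is_hard_error(self, tmp_path):
        p = tmp_path / "a.seg"
        p.write_text(
            "sample\tchrom\tstart\tend\tn_markers\tseg_mean\n"
            "S1\tchr1\t1\t1000\t50\t0.1\n"
            "S1\tchr1\t900\t5000\t80\t-0.4\n"
        )
        with pytest.raises(ValueError, match="overlapping"):
            read_segments(p)

    def test_random_endpoints_match_scan(self, tmp_path):
        rng = np.random.default_rng(6)
        edges = np.cumsum(rng.integers(100, 2000, 50))
        lines = ["sample\tchrom\tstart\tend\tn_markers\tseg_mean"]
        expect = set()
        prev = 1
        for e in edges:
            lines.append(f"S1\tchr1\t{prev}\t{int(e)}\t10\t{rng.normal():.3f}")
            expect |= {prev, int(e)}
            prev = int(e) + 1
        p = tmp_path / "a.seg"
        p.write_text("\n".join(lines) + "\n")
        assert set(read_segments(p)["S1"].breakpoints("chr1")) == expect


class TestNearestBreakpoint:
    def test_exact_endpoint_zero(self):
        ss = _segset([("chr1", 1000, 2000, 0.0)])
        assert ss.nearest_breakpoint("chr1", 1000) == 0

    def test_midway(self):
        ss = _segset([("chr1", 1000, 2000, 0.0)])
        assert ss.nearest_breakpoint("chr1", 1500) == 500

    def test_absent_chromosome_is_infinite(self):
        ss = _segset([("chr1", 1000, 2000, 0.0)])
        assert math.isinf(ss.nearest_breakpoint("chrX", 1500))

    def test_random_positions_match_linear_scan(self):
        rng = np.random.default_rng(8)
        rows = []
        prev = 1
        for _ in range(20):
            end = prev + int(rng.integers(50, 400))
            rows.append(("chr1", prev, end, 0.0))
            prev = end + 1
        ss = _segset(rows)
        points = sorted({r[1] for r in rows} | {r[2] for r in rows})
        for pos in rng.integers(1, prev, 200):
            assert ss.nearest_breakpoint("chr1", int(pos)) == min(
                abs(p - pos) for p in points
            )


W = 30_000  # default matching window


class TestMechanismClassifier:
    def test_focal_amplification_interior_points(self):
        ss = _segset(
            [("chr1", 1, 99_999, 0.0), ("chr1", 100_000, 400_000, 1.5),
             ("chr1", 400_001, 600_000, 0.0)]
        )
        call = classify_mechanism(_fusion("chr1", 200_000, "chr1", 300_000), ss)
        assert call.label == "focal_amplification"

    def test_flat_profile_is_none(self):
        ss = _segset([("chr1", 1, 600_000, 0.0)])
        call = classify_mechanism(_fusion("chr1", 200_000, "chr1", 300_000), ss)
        assert call.label == "none"

    def test_tandem_duplication_points_at_segment_ends(self):
        ss = _segset(
            [("chr1", 1, 99_999, 0.0), ("chr1", 100_000, 300_000, 1.5),
             ("chr1", 300_001, 600_000, 0.0)]
        )
        # 3' point at the amplified segment start, 5' point at its end
        call = classify_mechanism(_fusion("chr1", 300_000, "chr1", 100_000), ss)
        assert call.label == "tandem_duplication"

    def test_deletion_between_higher_flanks(self):
        ss = _segset(
            [("chr1", 1, 99_999, 0.2), ("chr1", 100_000, 300_000, -0.9),
             ("chr1", 300_001, 600_000, 0.1)]
        )
        call = classify_mechanism(_fusion("chr1", 100_000, "chr1", 300_000), ss)
        assert call.label == "deletion_based"

    def test_complex_needs_multiple_segments_between(self):
        ss = _segset(
            [("chr1", 1, 99_999, 0.0), ("chr1", 100_000, 200_000, 1.2),
             ("chr1", 200_001, 300_000, -0.5), ("chr1", 300_001, 400_000, 1.1),
             ("chr1", 400_001, 500_000, -0.3), ("chr1", 500_001, 600_000, 0.0)]
        )
        call = classify_mechanism(_fusion("chr1", 100_000, "chr1", 500_000), ss)
        assert call.label == "complex"
        assert call.segments_between and call.segments_between > 1

    def test_interchromosomal_needs_one_nearby_breakpoint(self):
        ss = SegmentSet(
            "S",
            [
                CopySegment("S", "chr1", 1, 100_000, 0.5),
                CopySegment("S", "chr1", 100_001, 600_000, 0.0),
                CopySegment("S", "chr2", 1, 600_000, 0.0),
            ],
        )
        near = classify_mechanism(_fusion("chr1", 100_000, "chr2", 300_000), ss)
        assert near.label == "interchromosomal"
        far = classify_mechanism(_fusion("chr1", 300_000, "chr2", 300_000), ss)
        assert far.label == "none"

    def test_exactly_one_label_per_fusion(self, cohort):
        _, _, segsets, truths, _ = cohort
        from fusewalk.copynumber import MECHANISMS

        for t in truths:
            call = classify_mechanism(t, segsets[t.sample])
            assert call.label in MECHANISMS

    def test_recovers_all_planted_mechanisms(self, cohort):
        _, _, segsets, truths, _ = cohort
        assert {t.mechanism for t in truths} == set(
            ("none", "focal_amplification", "tandem_duplication",
             "deletion_based", "complex", "interchromosomal")
        )
        for t in truths:
            assert classify_mechanism(t, segsets[t.sample]).label == t.mechanism

    def test_shift_invariance(self, cohort):
        _, _, segsets, truths, _ = cohort
        shift = 12_345
        for t in truths:
            ss = segsets[t.sample]
            shifted = SegmentSet(
                t.sample,
                [
                    CopySegment(t.sample, s.chrom, s.start + shift, s.end + shift, s.seg_mean)
                    for segs in ss.by_chrom.values()
                    for s in segs
                ],
            )
            moved = _fusion(
                t.five_chrom, t.five_pos + shift, t.three_chrom, t.three_pos + shift
            )
            assert (
                classify_mechanism(moved, shifted).label
                == classify_mechanism(t, ss).label
            )


class TestCopyCorrelation:
    def _fusions_with_means(self, pairs):
        rows = []
        fusions = []
        for i, (m5, m3) in enumerate(pairs):
            start5, start3 = 1 + 2000 * i, 1_000_000 + 2000 * i
            rows.append(("chr1", start5, start5 + 999, m5))
            rows.append(("chr1", start3, start3 + 999, m3))
            f = _fusion("chr1", start5 + 500, "chr1", start3 + 500)
            f.sample = "S"
            fusions.append(f)
        return fusions, {"S": _segset(rows)}

    def test_identical_values_r_one(self):
        fusions, segsets = self._fusions_with_means([(0.5, 0.5), (1.2, 1.2), (2.0, 2.0)])
        assert partner_copy_correlation(fusions, segsets) == pytest.approx(1.0)

    def test_antisymmetric_r_minus_one(self):
        fusions, segsets = self._fusions_with_means([(1.0, -1.0), (2.0, -2.0), (3.0, -3.0)])
        assert partner_copy_correlation(fusions, segsets) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(10)
        pairs = [(float(a), float(b)) for a, b in rng.normal(0, 1, (20, 2))]
        fusions, segsets = self._fusions_with_means(pairs)
        xs, ys = zip(*pairs)
        assert partner_copy_correlation(fusions, segsets) == pytest.approx(
            float(stats.pearsonr(xs, ys).statistic)
        )

    def test_too_few_pairs(self):
        fusions, segsets = self._fusions_with_means([(0.5, 0.5), (1.0, 1.0)])
        with pytest.raises(ValueError):
            partner_copy_correlation(fusions, segsets)
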