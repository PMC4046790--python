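"""Segmented copy-number profiles and fusion-mechanism classification.

Segment endpoints from SNP-array segmentation are taken as genomic
breakpoints.  Each fusion is assigned one of six formation mechanisms by a
fixed decision sequence over the two fusion points and the segment profile:

1. none — no genomic breakpoints around either fusion point (and the points
   do not sit inside a high-level amplicon);
2. focal_amplification — both points interior to one amplified segment;
3. tandem_duplication — points at the end and start of one amplified
   segment (consistent with a head-to-tail duplication);
4. deletion_based — points at the start and end of a segment relatively
   deleted versus its flanks;
5. complex — both points at breakpoints with multiple whole segments
   between them (chromothripsis-like);
6. interchromosomal — partners on different chromosomes with at least one
   point near a breakpoint.

The matching window, amplification threshold and deletion contrast are
configuration, not recovered constants.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd
from scipy import stats

DEFAULT_WINDOW = 30_000
DEFAULT_AMP_LOG2 = 0.9
DEFAULT_DEL_DELTA = 0.3

MECHANISMS = (
    "none",
    "focal_amplification",
    "tandem_duplication",
    "deletion_based",
    "complex",
    "interchromosomal",
)


@dataclass(frozen=True)
class CopySegment:
    sample: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # inclusive
    seg_mean: float
    n_markers: Optional[int] = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")


class SegmentSet:
    """One sample's segments, indexed per chromosome, endpoints sorted."""

    def __init__(self, sample: str, segments: Iterable[CopySegment]):
        self.sample = sample
        self.by_chrom: dict[str, list[CopySegment]] = {}
        for seg in segments:
            if seg.sample != sample:
                raise ValueError("mixed samples in one SegmentSet")
            self.by_chrom.setdefault(seg.chrom, []).append(seg)
        self._endpoints: dict[str, list[int]] = {}
        for chrom, segs in self.by_chrom.items():
            segs.sort(key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if a.end >= b.start:
                    raise ValueError(
                        f"overlapping segments on {chrom}: "
                        f"({a.start}-{a.end}) and ({b.start}-{b.end})"
                    )
            pts = sorted({p for s in segs for p in (s.start, s.end)})
            self._endpoints[chrom] = pts

    def breakpoints(self, chrom: str) -> list[int]:
        return self._endpoints.get(chrom, [])

    def nearest_breakpoint(self, chrom: str, pos: int) -> float:
        """Minimum distance to any segment endpoint; +inf off-chromosome."""
        pts = self._endpoints.get(chrom)
        if not pts:
            return math.inf
        i = bisect_left(pts, pos)
        best = math.inf
        for j in (i - 1, i):
            if 0 <= j < len(pts):
                best = min(best, abs(pts[j] - pos))
        return best

    def segment_at(self, chrom: str, pos: int) -> Optional[CopySegment]:
        segs = self.by_chrom.get(chrom, [])
        for seg in segs:
            if seg.start <= pos <= seg.end:
                return seg
        return None

    def segment_index(self, chrom: str, seg: CopySegment) -> int:
        return self.by_chrom[chrom].index(seg)

    def seg_mean_at(self, chrom: str, pos: int) -> Optional[float]:
        seg = self.segment_at(chrom, pos)
        return None if seg is None else seg.seg_mean


def read_segments(path) -> dict[str, SegmentSet]:
    """Read a SEG file (sample, chrom, start, end, n_markers, seg_mean).

    Accepts gzip input and a header line; rows are sorted silently, but
    overlapping segments within a sample+chromosome are a hard error.
    Returns one SegmentSet per sample.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 6:
        raise ValueError(f"{path}: expected 6-column SEG layout")
    df.columns = ["sample", "chrom", "start", "end", "n_markers", "seg_mean"]
    out = {}
    for sample, sub in df.groupby("sample", sort=False):
        segs = [
            CopySegment(
                sample=str(sample),
                chrom=str(r.chrom),
                start=int(r.start),
                end=int(r.end),
                seg_mean=float(r.seg_mean),
                n_markers=None if pd.isna(r.n_markers) else int(r.n_markers),
            )
            for r in sub.itertuples()
        ]
        out[str(sample)] = SegmentSet(str(sample), segs)
    return out


def write_segments(path, segsets: dict[str, SegmentSet]) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tn_markers\tseg_mean\n")
        for sample, segset in segsets.items():
            for chrom in sorted(segset.by_chrom):
                for seg in segset.by_chrom[chrom]:
                    nm = seg.n_markers if seg.n_markers is not None else 0
                    fh.write(
                        f"{sample}\t{chrom}\t{seg.start}\t{seg.end}\t{nm}\t{seg.seg_mean:.4f}\n"
                    )


@dataclass
class MechanismCall:
    label: str
    dist5: float
    dist3: float
    seg_mean5: Optional[float]
    seg_mean3: Optional[float]
    segments_between: Optional[int] = None

    def __post_init__(self):
        if self.label not in MECHANISMS:
            raise ValueError(f"unknown mechanism label {self.label!r}")


def classify_mechanism(
    fusion,
    segset: SegmentSet,
    window: int = DEFAULT_WINDOW,
    amp_log2: float = DEFAULT_AMP_LOG2,
    del_delta: float = DEFAULT_DEL_DELTA,
) -> MechanismCall:
    """Assign one of the six mechanism labels to a fusion.

    ``fusion`` needs attributes five_chrom/five_pos/three_chrom/three_pos.
    The amplicon test runs before the no-breakpoint shortcut so that a
    fusion interior to a broad amplified segment is called
    focal_amplification rather than none.
    """
    c5, p5 = fusion.five_chrom, fusion.five_pos
    c3, p3 = fusion.three_chrom, fusion.three_pos
    d5 = segset.nearest_breakpoint(c5, p5)
    d3 = segset.nearest_breakpoint(c3, p3)
    m5 = segset.seg_mean_at(c5, p5)
    m3 = segset.seg_mean_at(c3, p3)
    evidence = dict(dist5=d5, dist3=d3, seg_mean5=m5, seg_mean3=m3)

    if c5 != c3:
        label = "interchromosomal" if min(d5, d3) <= window else "none"
        return MechanismCall(label=label, **evidence)

    seg5 = segset.segment_at(c5, p5)
    seg3 = segset.segment_at(c3, p3)

    # focal amplification: both points interior to one amplified segment
    if (
        seg5 is not None
        and seg5 is seg3
        and seg5.seg_mean >= amp_log2
        and min(abs(p5 - seg5.start), abs(p5 - seg5.end)) > window
        and min(abs(p3 - seg5.start), abs(p3 - seg5.end)) > window
    ):
        return MechanismCall(label="focal_amplification", **evidence)

    if d5 > window and d3 > window:
        return MechanismCall(label="none", **evidence)

    lo, hi = min(p5, p3), max(p5, p3)
    # tandem duplication: points at the end and start of one amplified segment
    for seg in segset.by_chrom.get(c5, []):
        if seg.seg_mean < amp_log2:
            continue
        if abs(p5 - seg.end) <= window and abs(p3 - seg.start) <= window:
            return MechanismCall(label="tandem_duplication", **evidence)

    # deletion: points at the start/end of a segment deleted vs its flanks
    segs = segset.by_chrom.get(c5, [])
    for i, seg in enumerate(segs):
        ends = sorted((seg.start, seg.end))
        if not (
            (abs(p5 - ends[0]) <= window and abs(p3 - ends[1]) <= window)
            or (abs(p5 - ends[1]) <= window and abs(p3 - ends[0]) <= window)
        ):
            continue
        flanks = []
        if i > 0:
            flanks.append(segs[i - 1].seg_mean)
        if i + 1 < len(segs):
            flanks.append(segs[i + 1].seg_mean)
        if flanks and seg.seg_mean <= min(flanks) - del_delta:
            return MechanismCall(label="deletion_based", **evidence)

    # complex: both points at breakpoints with > 1 whole segment between
    if d5 <= window and d3 <= window:
        between = sum(1 for seg in segs if lo < seg.start and seg.end < hi)
        if between > 1:
            return MechanismCall(
                label="complex", segments_between=between, **evidence
            )
        return MechanismCall(label="none", segments_between=between, **evidence)

    return MechanismCall(label="none", **evidence)


def partner_copy_correlation(
    fusions: Iterable, segsets: dict[str, SegmentSet]
) -> float:
    """Pearson r between 5'- and 3'-point segment means across fusions."""
    pairs = []
    for fusion in fusions:
        segset = segsets.get(fusion.sample)
        if segset is None:
            continue
        m5 = segset.seg_mean_at(fusion.five_chrom, fusion.five_pos)
        m3 = segset.seg_mean_at(fusion.three_chrom, fusion.three_pos)
        if m5 is not None and m3 is not None:
            pairs.append((m5, m3))
    if len(pairs) < 3:
        raise ValueError("need >= 3 fusions with both points covered")
    xs, ys = zip(*pairs)
    return float(stats.pearsonr(xs, ys).statistic)
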