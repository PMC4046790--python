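"""SOLiD dibase color-space codec, partial-read extraction, and consensus.

SOLiD reads encode transitions between adjacent bases rather than bases: a
color c in {0,1,2,3} encodes the dibase (prev, cur) under the standard code
(identical pair -> 0; AC/CA/GT/TG -> 1; AG/GA/CT/TC -> 2; AT/TA/CG/GC -> 3),
which is XOR over the 2-bit base alphabet.  Decoding therefore needs a known
starting base (the ligation primer) and a single color error corrupts every
downstream base — which is why consensus voting here happens per color
column, not on decoded bases.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

_BASE2BIT = {"A": 0, "C": 1, "G": 2, "T": 3}
_BIT2BASE = "ACGT"


class ColorspaceError(ValueError):
    pass


def encode_colors(primer: str, bases: str) -> str:
    """Encode a base string as SOLiD colors given the primer base."""
    if primer not in _BASE2BIT:
        raise ColorspaceError(f"invalid primer base {primer!r}")
    prev = _BASE2BIT[primer]
    out = []
    for base in bases:
        if base not in _BASE2BIT:
            raise ColorspaceError(f"cannot encode ambiguous base {base!r}")
        cur = _BASE2BIT[base]
        out.append(str(prev ^ cur))
        prev = cur
    return "".join(out)


def decode_colors(primer: str, colors: str, policy: str = "strict") -> str:
    """Decode colors back to bases; '.' stops decoding unless policy='truncate'."""
    if primer not in _BASE2BIT:
        raise ColorspaceError(f"invalid primer base {primer!r}")
    prev = _BASE2BIT[primer]
    out = []
    for color in colors:
        if color == ".":
            if policy == "truncate":
                break
            raise ColorspaceError("missing color '.' in read")
        if color not in "0123":
            raise ColorspaceError(f"invalid color {color!r}")
        prev ^= int(color)
        out.append(_BIT2BASE[prev])
    return "".join(out)


@dataclass
class ColorRead:
    """A color-space read partially anchored to a known exon.

    ``ref_start`` is the 0-based genomic position of the read's first base;
    ``matched_length`` counts the leading bases that match the anchor exon
    (the rest hangs past the candidate breakpoint).
    """

    read_id: str
    primer: str
    colors: str
    ref_start: int
    matched_length: int
    quals: Optional[Sequence[int]] = None
    chrom: str = ""

    def __post_init__(self):
        if self.matched_length > len(self.colors):
            raise ValueError("matched_length exceeds read length")

    def __len__(self) -> int:
        return len(self.colors)

    @property
    def bases(self) -> str:
        return decode_colors(self.primer, self.colors)


def read_csfasta(path) -> list[tuple[str, str, str]]:
    """Parse a csfasta file into (read_id, primer, colors) tuples."""
    out = []
    with open(path) as fh:
        rid = None
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                rid = line[1:]
            else:
                if rid is None:
                    raise ColorspaceError(f"{path}: colors before header")
                primer, colors = line[0], line[1:]
                out.append((rid, primer, colors))
                rid = None
    return out


def write_csfasta(path, reads: Iterable[ColorRead]) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f">{read.read_id}\n{read.primer}{read.colors}\n")


DEFAULT_MAX_EXON_MATCH = 35
DEFAULT_MIN_ANCHOR = 10


def extract_partial_reads(
    reads: Iterable[ColorRead],
    boundary: int,
    chrom: Optional[str] = None,
    max_exon_match: int = DEFAULT_MAX_EXON_MATCH,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
) -> list[ColorRead]:
    """Reads straddling a candidate breakpoint with a partial exon match.

    ``boundary`` is the 1-based genomic coordinate of the last exon base
    (``chrom``, when given, must match the read's anchor chromosome).  A
    read qualifies when its span covers the boundary and its exon-matched
    prefix is strictly shorter than ``max_exon_match`` but at least
    ``min_anchor`` bases.
    """
    out = []
    for read in reads:
        if chrom is not None and read.chrom and read.chrom != chrom:
            continue
        span_start = read.ref_start + 1  # 1-based first base
        span_end = read.ref_start + len(read)
        if not (span_start <= boundary < span_end):
            continue
        if min_anchor <= read.matched_length < max_exon_match:
            out.append(read)
    return out


@dataclass
class ConsensusSeq:
    """Plurality consensus over a cluster of junction-spanning reads."""

    sequence: str                 # decoded base-space consensus
    colors: str                   # color-space consensus (genomic transitions)
    support: list[int]            # per color column, votes for the winner
    member_ids: list[str]
    cluster_id: int
    anchor_offset: int            # bases of the consensus matching the exon side

    def __len__(self) -> int:
        return len(self.sequence)


DEFAULT_MIN_SUPPORT = 2
DEFAULT_MAX_MISMATCH_FRAC = 0.1


def _genomic_columns(read: ColorRead) -> dict[int, tuple[str, int]]:
    """Map genomic transition index -> (color, quality).

    Color i (i >= 1) of a read encodes the transition between genome
    positions ref_start+i-1 and ref_start+i.  Color 0 involves the ligation
    primer and is not a genomic transition, so it is excluded from voting.
    """
    cols = {}
    for i in range(1, len(read.colors)):
        q = read.quals[i] if read.quals is not None else 1
        cols[read.ref_start + i] = (read.colors[i], q)
    return cols


def _base_columns(read: ColorRead) -> dict[int, str]:
    bases = read.bases
    return {read.ref_start + i: b for i, b in enumerate(bases)}


def _mismatch_frac(a: dict[int, tuple[str, int]], b: dict[int, tuple[str, int]]) -> Optional[float]:
    shared = a.keys() & b.keys()
    if not shared:
        return None
    mism = sum(1 for t in shared if a[t][0] != b[t][0])
    return mism / len(shared)


def build_consensus(
    reads: Sequence[ColorRead],
    min_support: int = DEFAULT_MIN_SUPPORT,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> list[ConsensusSeq]:
    """Cluster junction reads and emit one consensus per adequate cluster.

    Reads sharing the anchored boundary are greedily clustered, longest seed
    first: a read joins the first cluster whose seed it matches with color
    mismatch fraction <= ``max_mismatch_frac`` over their shared columns.
    Each cluster with >= ``min_support`` members yields a consensus by
    per-column plurality vote in color space (ties broken by highest summed
    quality, then lowest color), decoded to base space from the plurality
    starting base.  Input order never changes the result.
    """
    if not reads:
        return []
    ordered = sorted(reads, key=lambda r: (-len(r), r.read_id))
    clusters: list[list[ColorRead]] = []
    seeds: list[dict[int, tuple[str, int]]] = []
    for read in ordered:
        cols = _genomic_columns(read)
        placed = False
        for seed, cluster in zip(seeds, clusters):
            frac = _mismatch_frac(seed, cols)
            if frac is not None and frac <= max_mismatch_frac:
                cluster.append(read)
                placed = True
                break
        if not placed:
            clusters.append([read])
            seeds.append(cols)

    out = []
    cluster_id = 0
    for cluster in clusters:
        if len(cluster) < min_support:
            continue
        consensus = _vote(cluster, cluster_id)
        if consensus is not None:
            out.append(consensus)
            cluster_id += 1
    return out


def _vote(cluster: list[ColorRead], cluster_id: int) -> Optional[ConsensusSeq]:
    votes: dict[int, Counter] = defaultdict(Counter)
    qual: dict[int, Counter] = defaultdict(Counter)
    for read in cluster:
        for t, (color, q) in _genomic_columns(read).items():
            votes[t][color] += 1
            qual[t][color] += q
    if not votes:
        return None
    t0, t1 = min(votes), max(votes)
    colors = []
    support = []
    for t in range(t0, t1 + 1):
        if t not in votes:
            return None  # gap in coverage; cluster unusable
        counter = votes[t]
        best = max(counter, key=lambda c: (counter[c], qual[t][c], -int(c)))
        colors.append(best)
        support.append(counter[best])
    # starting base: plurality of decoded bases at position t0 - 1
    base_votes = Counter()
    for read in cluster:
        bcols = _base_columns(read)
        if t0 - 1 in bcols:
            base_votes[bcols[t0 - 1]] += 1
    if not base_votes:
        return None
    start_base = min(base_votes, key=lambda b: (-base_votes[b], b))
    seq = start_base + decode_colors(start_base, "".join(colors))
    # consensus spans genome positions [t0-1, t1]; anchor offset = matched
    # exon bases inside that window (max over members)
    anchor = 0
    for read in cluster:
        matched_end = read.ref_start + read.matched_length  # exclusive, 0-based
        anchor = max(anchor, min(matched_end, t1 + 1) - (t0 - 1))
    return ConsensusSeq(
        sequence=seq,
        colors="".join(colors),
        support=support,
        member_ids=sorted(r.read_id for r in cluster),
        cluster_id=cluster_id,
        anchor_offset=max(anchor, 0),
    )
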