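"""External fusion-caller tables and the six-condition curation filter.

Paired-end callers emit large candidate lists with many false positives;
the curation filter keeps a fusion only when all of these hold:

1. at least one breakpoint is a known exon boundary (within a tolerance);
2. the fusion-spanning read count exceeds twice at least one corresponding
   wild-type exon-exon spanning count (a wild-type count of zero passes —
   the wild-type junction is simply not expressed);
3. spanning reads >= ``min_span`` OR the partner genes' best expression
   outlier z-score >= ``z_pass``;
4. records present only in a caller's unfiltered candidate list additionally
   need z >= ``z_candidate_only``;
5. the reported junction preserves each annotated partner's transcriptional
   (5'->3') direction;
6. the gene pair is not on the normal-tissue blacklist (default TFG->GPR128).

Fusions between immediately adjacent genes are additionally discarded as
likely read-through transcripts.  Every input record is returned with a full
per-rule audit trail, retained or not.

File dialects (documented layouts; coordinates on disk are 0-based for the
TopHat-style dialects and 1-based for the SnowShoes-style dialect, always
normalized to 1-based in memory):

* ``tophatfusion_potential`` — blank-line-separated blocks::

      sample chrA-chrB posA posB orient
      nspan npairs nboth
      geneA geneB

  ``orient`` is two characters from {f, r} (forward/reverse strand).
* ``tophatfusion_result`` — one tab-separated line per fusion:
  sample, geneA, chrA, posA, geneB, chrB, posB, nspan, npairs, nboth, orient.
* ``snowshoes`` — header + tab-separated columns: sample, gene_5p, chr_5p,
  pos_5p, strand_5p, gene_3p, chr_3p, pos_3p, strand_3p, span_reads, isoform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .annotation import AnnotationSet, are_adjacent_genes, _open_text
from .expression import CopaResult

DEFAULT_BLACKLIST = frozenset({("TFG", "GPR128")})


class DialectError(ValueError):
    pass


@dataclass
class CallerRecord:
    sample: str
    gene5: str
    chrom5: str
    pos5: int  # 1-based
    strand5: str  # '+', '-' or '.' when the caller does not report it
    gene3: str
    chrom3: str
    pos3: int
    strand3: str
    spanning_reads: int
    spanning_pairs: int = 0
    caller: str = "internal"
    candidate_only: bool = False
    wt5: Optional[int] = None
    wt3: Optional[int] = None
    provenance: set = field(default_factory=set)

    def __post_init__(self):
        if self.spanning_reads < 0:
            raise ValueError("spanning reads must be >= 0")
        if not self.provenance:
            self.provenance = {self.caller}

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene5, self.gene3)


@dataclass
class CurationParams:
    min_ratio: float = 2.0
    min_span: int = 100
    z_pass: float = 5.0
    z_candidate_only: float = 10.0
    blacklist: frozenset = DEFAULT_BLACKLIST
    boundary_tol: int = 0

    def __post_init__(self):
        for name in ("min_ratio", "min_span", "z_pass", "z_candidate_only"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class CuratedFusion:
    record: CallerRecord
    rule_boundary: bool
    rule_ratio: bool
    rule_support: bool
    rule_candidate_z: bool
    rule_orientation: bool
    rule_blacklist: bool
    adjacent: bool
    max_z: float

    @property
    def retained(self) -> bool:
        return (
            self.rule_boundary
            and self.rule_ratio
            and self.rule_support
            and self.rule_candidate_z
            and self.rule_orientation
            and self.rule_blacklist
            and not self.adjacent
        )


_STRAND = {"f": "+", "r": "-"}


def read_caller_records(path, dialect: str) -> list[CallerRecord]:
    if dialect == "tophatfusion_potential":
        return _read_tophat_potential(path)
    if dialect == "tophatfusion_result":
        return _read_tophat_result(path)
    if dialect == "snowshoes":
        return _read_snowshoes(path)
    raise DialectError(f"unknown dialect {dialect!r}")


def _orient_to_strands(orient: str, path, line: str) -> tuple[str, str]:
    if len(orient) != 2 or any(c not in _STRAND for c in orient):
        raise DialectError(f"{path}: bad orientation in line {line!r}")
    return _STRAND[orient[0]], _STRAND[orient[1]]


def _read_tophat_potential(path) -> list[CallerRecord]:
    records = []
    with _open_text(path) as fh:
        block: list[str] = []
        for raw in list(fh) + [""]:
            line = raw.rstrip("\n")
            if line.strip():
                block.append(line)
                continue
            if not block:
                continue
            if len(block) < 3:
                raise DialectError(f"{path}: truncated block starting {block[0]!r}")
            head = block[0].split()
            if len(head) != 5 or "-" not in head[1]:
                raise DialectError(f"{path}: bad header line {block[0]!r}")
            sample, chroms, pos_a, pos_b, orient = head
            chrom_a, _, chrom_b = chroms.partition("-")
            counts = block[1].split()
            if len(counts) != 3:
                raise DialectError(f"{path}: bad counts line {block[1]!r}")
            genes = block[2].split()
            if len(genes) != 2:
                raise DialectError(f"{path}: bad gene line {block[2]!r}")
            strand5, strand3 = _orient_to_strands(orient, path, block[0])
            records.append(
                CallerRecord(
                    sample=sample,
                    gene5=genes[0],
                    chrom5=chrom_a,
                    pos5=int(pos_a) + 1,
                    strand5=strand5,
                    gene3=genes[1],
                    chrom3=chrom_b,
                    pos3=int(pos_b) + 1,
                    strand3=strand3,
                    spanning_reads=int(counts[0]),
                    spanning_pairs=int(counts[1]),
                    caller="tophatfusion",
                    candidate_only=True,
                    provenance={"tophatfusion_potential"},
                )
            )
            block = []
    return records


def _read_tophat_result(path) -> list[CallerRecord]:
    records = []
    with _open_text(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 11:
                raise DialectError(f"{path}:{ln}: expected 11 columns, got {line!r}")
            (sample, gene5, chrom5, pos5, gene3, chrom3, pos3,
             nspan, npairs, _nboth, orient) = fields
            strand5, strand3 = _orient_to_strands(orient, path, line)
            records.append(
                CallerRecord(
                    sample=sample,
                    gene5=gene5,
                    chrom5=chrom5,
                    pos5=int(pos5) + 1,
                    strand5=strand5,
                    gene3=gene3,
                    chrom3=chrom3,
                    pos3=int(pos3) + 1,
                    strand3=strand3,
                    spanning_reads=int(nspan),
                    spanning_pairs=int(npairs),
                    caller="tophatfusion",
                    candidate_only=False,
                    provenance={"tophatfusion_result"},
                )
            )
    return records


_SNOWSHOES_COLS = [
    "sample", "gene_5p", "chr_5p", "pos_5p", "strand_5p",
    "gene_3p", "chr_3p", "pos_3p", "strand_3p", "span_reads", "isoform",
]


def _read_snowshoes(path) -> list[CallerRecord]:
    records = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _SNOWSHOES_COLS:
            raise DialectError(f"{path}: unexpected header {header!r}")
        for ln, raw in enumerate(fh, 2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_SNOWSHOES_COLS):
                raise DialectError(f"{path}:{ln}: bad column count in {line!r}")
            row = dict(zip(_SNOWSHOES_COLS, fields))
            records.append(
                CallerRecord(
                    sample=row["sample"],
                    gene5=row["gene_5p"],
                    chrom5=row["chr_5p"],
                    pos5=int(row["pos_5p"]),
                    strand5=row["strand_5p"],
                    gene3=row["gene_3p"],
                    chrom3=row["chr_3p"],
                    pos3=int(row["pos_3p"]),
                    strand3=row["strand_3p"],
                    spanning_reads=int(row["span_reads"]),
                    caller="snowshoes",
                    candidate_only=False,
                    provenance={"snowshoes"},
                )
            )
    return records


def merge_caller_records(
    lists: Sequence[Sequence[CallerRecord]], tol: int = 10
) -> list[CallerRecord]:
    """Collapse records agreeing on sample, gene pair and breakpoints.

    Breakpoints within ``tol`` bases collapse; the merged record keeps the
    union of provenance tags, the maximum spanning-read count, and is
    candidate-only only when *every* source appearance was candidate-only.
    """
    groups: dict[tuple, list[list[CallerRecord]]] = {}
    for records in lists:
        for record in records:
            key = (record.sample, record.gene5, record.gene3)
            clusters = groups.setdefault(key, [])
            for cluster in clusters:
                ref = cluster[0]
                if abs(ref.pos5 - record.pos5) <= tol and abs(ref.pos3 - record.pos3) <= tol:
                    cluster.append(record)
                    break
            else:
                clusters.append([record])
    merged = []
    for clusters in groups.values():
        for cluster in clusters:
            best = max(cluster, key=lambda r: r.spanning_reads)
            merged.append(
                replace(
                    best,
                    spanning_reads=max(r.spanning_reads for r in cluster),
                    candidate_only=all(r.candidate_only for r in cluster),
                    provenance=set().union(*(r.provenance for r in cluster)),
                    wt5=next((r.wt5 for r in cluster if r.wt5 is not None), None),
                    wt3=next((r.wt3 for r in cluster if r.wt3 is not None), None),
                )
            )
    merged.sort(key=lambda r: (r.sample, r.gene5, r.gene3, r.pos5, r.pos3))
    return merged


def _max_partner_z(record: CallerRecord, copa, annotation: Optional[AnnotationSet]) -> float:
    """Max outlier z over all exons of both partner genes in the sample."""
    if copa is None:
        return -math.inf
    if isinstance(copa, dict):
        return max(
            copa.get((record.sample, record.gene5), -math.inf),
            copa.get((record.sample, record.gene3), -math.inf),
        )
    assert isinstance(copa, CopaResult)
    best = -math.inf
    for symbol in (record.gene5, record.gene3):
        gene_ids = [symbol]
        if annotation is not None:
            models = annotation.models_of_symbol(symbol)
            if models:
                gene_ids = [m.gene_id for m in models]
        for gid in gene_ids:
            if record.sample in copa.z.columns:
                best = max(best, copa.max_gene_z(gid, record.sample))
    return best


def _ratio_rule(record: CallerRecord, wt: tuple[Optional[int], Optional[int]], min_ratio: float) -> bool:
    observed = [w for w in wt if w is not None]
    if not observed:
        return True  # no wild-type junction to compare against
    for w in observed:
        if w == 0 or record.spanning_reads / w > min_ratio:
            return True
    return False


def _orientation_rule(record: CallerRecord, annotation: Optional[AnnotationSet]) -> bool:
    if annotation is None:
        return True
    for symbol, strand in ((record.gene5, record.strand5), (record.gene3, record.strand3)):
        if strand == ".":
            continue
        models = annotation.models_of_symbol(symbol)
        if models and not any(m.strand == strand for m in models):
            return False
    return True


def _boundary_rule(record: CallerRecord, annotation: Optional[AnnotationSet], tol: int) -> bool:
    if annotation is None:
        return False
    for chrom, pos in ((record.chrom5, record.pos5), (record.chrom3, record.pos3)):
        try:
            if annotation.is_known_exon_boundary(chrom, pos, tol) is not None:
                return True
        except KeyError:
            continue
    return False


def _adjacency(record: CallerRecord, annotation: Optional[AnnotationSet]) -> bool:
    if annotation is None or record.gene5 == record.gene3:
        return False
    if "UAR" in (record.gene5, record.gene3):
        return False
    a = annotation.representative_model(record.gene5)
    b = annotation.representative_model(record.gene3)
    if a is None or b is None:
        return False
    return are_adjacent_genes(a, b, annotation)


def apply_curation(
    records: Sequence[CallerRecord],
    annotation: Optional[AnnotationSet],
    copa,
    wt_counts: Optional[Sequence[tuple[Optional[int], Optional[int]]]] = None,
    params: Optional[CurationParams] = None,
) -> list[CuratedFusion]:
    """Audit every record against the curation rules.

    ``copa`` may be a :class:`~fusewalk.expression.CopaResult` (z looked up
    per partner gene and sample), a dict {(sample, gene): z}, or None (no
    expression evidence; z treated as -inf).  ``wt_counts`` overrides the
    per-record wild-type junction counts when given.  Output preserves input
    order and length: one audited entry per input record.
    """
    params = params or CurationParams()
    out = []
    for i, record in enumerate(records):
        wt = (
            wt_counts[i]
            if wt_counts is not None
            else (record.wt5, record.wt3)
        )
        z = _max_partner_z(record, copa, annotation)
        rule1 = _boundary_rule(record, annotation, params.boundary_tol)
        rule2 = _ratio_rule(record, wt, params.min_ratio)
        rule3 = record.spanning_reads >= params.min_span or z >= params.z_pass
        rule4 = (not record.candidate_only) or z >= params.z_candidate_only
        rule5 = _orientation_rule(record, annotation)
        rule6 = record.pair not in params.blacklist
        adjacent = _adjacency(record, annotation)
        out.append(
            CuratedFusion(
                record=record,
                rule_boundary=rule1,
                rule_ratio=rule2,
                rule_support=rule3,
                rule_candidate_z=rule4,
                rule_orientation=rule5,
                rule_blacklist=rule6,
                adjacent=adjacent,
                max_z=z,
            )
        )
    return out


def write_curated_tsv(path, audited: Sequence[CuratedFusion]) -> None:
    cols = [
        "sample", "gene_5p", "chr_5p", "pos_5p", "strand_5p",
        "gene_3p", "chr_3p", "pos_3p", "strand_3p", "span_reads",
        "candidate_only", "max_z",
        "rule_boundary", "rule_ratio", "rule_support", "rule_candidate_z",
        "rule_orientation", "rule_blacklist", "adjacent", "retained",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for cf in audited:
            r = cf.record
            z = "" if cf.max_z == -math.inf else f"{cf.max_z:.3f}"
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.sample, r.gene5, r.chrom5, r.pos5, r.strand5,
                        r.gene3, r.chrom3, r.pos3, r.strand3, r.spanning_reads,
                        int(r.candidate_only), z,
                        int(cf.rule_boundary), int(cf.rule_ratio),
                        int(cf.rule_support), int(cf.rule_candidate_z),
                        int(cf.rule_orientation), int(cf.rule_blacklist),
                        int(cf.adjacent), int(cf.retained),
                    )
                )
                + "\n"
            )
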