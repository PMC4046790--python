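"""Genome sequences, merged gene models, and interval/boundary queries.

Gene annotation for fusion calling is assembled by merging several source
databases (e.g. Ensembl, UCSC, RefSeq dumps) into a single
:class:`AnnotationSet`.  Models that share chromosome, strand and exact exon
structure are collapsed into one record carrying every source tag, so the
merge is idempotent and order-independent.

Coordinate conventions: everything in memory is 0-based half-open; all file
I/O and every reported breakpoint is 1-based inclusive, matching GTF/SEG and
the coordinate style of published fusion tables.
"""

from __future__ import annotations

import gzip
import io
from bisect import bisect_left, bisect_right, insort
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

_VALID_BASES = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _open_text(path) -> io.TextIOBase:
    """Open a possibly gzip-compressed text file."""
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


class GenomeRef:
    """In-memory reference genome: ordered chromosome names -> sequences."""

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValueError("genome must contain at least one chromosome")
        self.chrom_names: list[str] = list(sequences)
        self.sequences: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            if not seq:
                raise ValueError(f"chromosome {name!r} has empty sequence")
            if set(seq) - _VALID_BASES:
                bad = sorted(set(seq) - _VALID_BASES)
                raise ValueError(f"chromosome {name!r} has invalid bases {bad}")
            self.sequences[name] = seq

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return sequence [start, end), 0-based half-open."""
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        n = len(self.sequences[chrom])
        if not (0 <= start < end <= n):
            raise ValueError(
                f"coordinates [{start}, {end}) outside [0, {n}) on {chrom}"
            )
        return self.sequences[chrom][start:end]

    @classmethod
    def from_fasta(cls, path) -> "GenomeRef":
        seqs: dict[str, list[str]] = {}
        order: list[str] = []
        name = None
        with _open_text(path) as fh:
            for line in fh:
                line = line.rstrip()
                if not line:
                    continue
                if line.startswith(">"):
                    name = line[1:].split()[0]
                    seqs[name] = []
                    order.append(name)
                else:
                    if name is None:
                        raise ValueError(f"{path}: sequence before header")
                    seqs[name].append(line)
        return cls({n: "".join(seqs[n]) for n in order})

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in self.chrom_names:
                fh.write(f">{name}\n")
                seq = self.sequences[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class Exon:
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    rank: int   # 1-based, transcript 5'->3'

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"exon start {self.start} >= end {self.end}")
        if self.rank < 1:
            raise ValueError("exon rank must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """One transcript model.

    ``cds_span`` is an optional (start, end) interval in transcript
    coordinates (0-based half-open over the spliced sequence).
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    exons: list[Exon]
    cds_span: Optional[tuple[int, int]] = None
    biotype: str = "coding"
    sources: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError("gene model needs at least one exon")
        ranks = [e.rank for e in self.exons]
        if ranks != sorted(ranks) or len(set(ranks)) != len(ranks):
            raise ValueError("exon ranks must be unique and ascending")
        starts = [e.start for e in self.exons]
        if self.strand == "+":
            if starts != sorted(starts):
                raise ValueError("plus-strand exons must ascend genomically")
        else:
            if starts != sorted(starts, reverse=True):
                raise ValueError("minus-strand exons must descend genomically")
        # non-overlap check
        ordered = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(ordered, ordered[1:]):
            if a.end > b.start:
                raise ValueError("exons overlap")
        if self.cds_span is not None:
            s, e = self.cds_span
            if not (0 <= s < e <= self.tx_length):
                raise ValueError("cds_span outside transcript")

    @property
    def span(self) -> tuple[int, int]:
        return (min(e.start for e in self.exons), max(e.end for e in self.exons))

    @property
    def tx_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def cds_length(self) -> int:
        if self.cds_span is None:
            return 0
        return self.cds_span[1] - self.cds_span[0]

    def structure_key(self) -> tuple:
        return (
            self.chrom,
            self.strand,
            tuple((e.start, e.end) for e in self.exons),
        )

    def spliced_sequence(self, genome: GenomeRef) -> str:
        parts = []
        for exon in self.exons:
            seq = genome.fetch(self.chrom, exon.start, exon.end)
            if self.strand == "-":
                seq = reverse_complement(seq)
            parts.append(seq)
        return "".join(parts)

    def tx_offset_of_boundary(self, genomic_pos_1based: int) -> Optional[int]:
        """Transcript offset (bases from tx start) of an exon boundary.

        For an exon boundary given as a 1-based genomic coordinate of the
        *last base* of exon k (in transcript orientation), returns the number
        of transcript bases through exon k.  None if the position is not a
        transcript-oriented exon end.
        """
        total = 0
        for exon in self.exons:
            total += exon.length
            last = exon.end if self.strand == "+" else exon.start + 1
            if last == genomic_pos_1based:
                return total
        return None


class ParseError(ValueError):
    pass


class AnnotationSet:
    """Merged gene models with interval and exon-boundary indexes."""

    def __init__(self, models: Iterable[GeneModel]):
        self.models: dict[str, GeneModel] = {}
        merged: dict[tuple, GeneModel] = {}
        for model in models:
            key = model.structure_key()
            if key in merged:
                merged[key].sources |= model.sources
            else:
                merged[key] = model
        for model in merged.values():
            self.models[model.gene_id] = model
        self._trees: dict[str, IntervalTree] = {}
        self._boundaries: dict[str, list[tuple[int, str, int]]] = {}
        for model in self.models.values():
            tree = self._trees.setdefault(model.chrom, IntervalTree())
            s, e = model.span
            tree[s:e] = model.gene_id
            blist = self._boundaries.setdefault(model.chrom, [])
            for exon in model.exons:
                # both boundaries as 1-based coordinates
                insort(blist, (exon.start + 1, model.gene_id, exon.rank))
                insort(blist, (exon.end, model.gene_id, exon.rank))

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models.values())

    def get(self, gene_id: str) -> Optional[GeneModel]:
        return self.models.get(gene_id)

    def models_of_symbol(self, symbol: str) -> list[GeneModel]:
        return [m for m in self.models.values() if m.symbol == symbol]

    def representative_model(self, symbol: str) -> Optional[GeneModel]:
        """Longest coding transcript of a symbol; ties broken by lowest id."""
        candidates = self.models_of_symbol(symbol)
        if not candidates:
            return None
        coding = [m for m in candidates if m.cds_span is not None]
        pool = coding or candidates
        return min(pool, key=lambda m: (-m.cds_length, -m.tx_length, m.gene_id))

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        """Models overlapping [start, end) (0-based)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = tree[start:end]
        return sorted(
            (self.models[iv.data] for iv in hits), key=lambda m: m.gene_id
        )

    def at(self, chrom: str, pos_1based: int) -> list[GeneModel]:
        return self.overlapping(chrom, pos_1based - 1, pos_1based)

    def is_known_exon_boundary(
        self, chrom: str, pos: int, tol: int = 0
    ) -> Optional[tuple[Exon, GeneModel]]:
        """Exon whose start or end (1-based) is within ``tol`` of ``pos``.

        Ties break on smallest distance, then lowest gene_id.  Returns
        (exon, model) or None.
        """
        if chrom not in self._boundaries:
            raise KeyError(f"unknown chromosome {chrom!r}")
        blist = self._boundaries[chrom]
        lo = bisect_left(blist, (pos - tol, "", 0))
        hi = bisect_right(blist, (pos + tol, "￿", 1 << 30))
        best = None
        for bpos, gene_id, rank in blist[lo:hi]:
            dist = abs(bpos - pos)
            if dist > tol:
                continue
            key = (dist, gene_id)
            if best is None or key < best[0]:
                best = (key, gene_id, rank)
        if best is None:
            return None
        model = self.models[best[1]]
        exon = next(e for e in model.exons if e.rank == best[2])
        return exon, model


def are_adjacent_genes(a: GeneModel, b: GeneModel, annotation: AnnotationSet) -> bool:
    """True iff same chromosome and no third gene lies wholly in the gap.

    Overlapping genes have an empty gap and are adjacent by definition.
    Symmetric in its arguments.
    """
    if a.chrom != b.chrom:
        return False
    if a.gene_id == b.gene_id:
        return True
    (a_s, a_e), (b_s, b_e) = a.span, b.span
    gap_start, gap_end = min(a_e, b_e), max(a_s, b_s)
    if gap_start >= gap_end:
        return True  # spans overlap or touch
    for third in annotation.overlapping(a.chrom, gap_start, gap_end):
        if third.gene_id in (a.gene_id, b.gene_id):
            continue
        t_s, t_e = third.span
        if t_s >= gap_start and t_e <= gap_end:
            return False
    return True


@dataclass(frozen=True)
class Cytoband:
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    band: str


class CytobandTable:
    def __init__(self, bands: Iterable[Cytoband]):
        self._by_chrom: dict[str, list[Cytoband]] = {}
        for band in bands:
            self._by_chrom.setdefault(band.chrom, []).append(band)
        for chrom, rows in self._by_chrom.items():
            rows.sort(key=lambda b: b.start)
            for x, y in zip(rows, rows[1:]):
                if x.end > y.start:
                    raise ValueError(f"overlapping bands on {chrom}")

    @classmethod
    def from_tsv(cls, path) -> "CytobandTable":
        bands = []
        with _open_text(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ParseError(f"{path}:{ln}: expected >=4 columns")
                chrom, start, end, band = fields[:4]
                bands.append(Cytoband(chrom, int(start), int(end), band))
        return cls(bands)

    def band_of(self, chrom: str, pos: int) -> str:
        """Label of the band containing 1-based position ``pos``.

        Bands are half-open in 0-based coordinates, so a 1-based position
        equal to ``start + 1`` (the band's first base) belongs to that band.
        The label is formatted as chromosome (without any 'chr' prefix) plus
        band, e.g. "7p11".
        """
        rows = self._by_chrom.get(chrom)
        if rows is None:
            raise KeyError(f"no cytobands for chromosome {chrom!r}")
        pos0 = pos - 1
        for band in rows:
            if band.start <= pos0 < band.end:
                name = chrom[3:] if chrom.startswith("chr") else chrom
                return f"{name}{band.band}"
        raise ValueError(f"position {pos} outside covered range on {chrom}")


# ---------------------------------------------------------------------------
# Annotation readers


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def _load_gtf(path, source_tag: str) -> list[GeneModel]:
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{ln}: expected 9 GTF columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: bad coordinates") from exc
            if end_i < start_i:
                continue  # rejected record; logged by caller policy
            a = _parse_gtf_attributes(attrs)
            tid = a.get("transcript_id") or a.get("gene_id")
            if tid is None:
                raise ParseError(f"{path}:{ln}: missing transcript_id/gene_id")
            meta.setdefault(
                tid,
                {
                    "gene_id": a.get("gene_id", tid),
                    "symbol": a.get("gene_name", a.get("gene_id", tid)),
                    "chrom": chrom,
                    "strand": strand,
                    "biotype": a.get("gene_biotype", a.get("biotype", "coding")),
                },
            )
            # GTF is 1-based inclusive -> 0-based half-open
            iv = (start_i - 1, end_i)
            if feature == "exon":
                exons.setdefault(tid, []).append(iv)
            else:
                cds.setdefault(tid, []).append(iv)
    models = []
    for tid, ivs in exons.items():
        m = meta[tid]
        genomic = sorted(ivs)
        ordered = genomic if m["strand"] == "+" else genomic[::-1]
        exon_objs = [
            Exon(m["chrom"], s, e, rank)
            for rank, (s, e) in enumerate(ordered, 1)
        ]
        cds_span = None
        if tid in cds:
            cds_span = _cds_to_tx_span(exon_objs, m["strand"], cds[tid])
        biotype = "noncoding" if cds_span is None and m["biotype"] not in (
            "coding",
            "protein_coding",
        ) else ("coding" if cds_span is not None else "noncoding")
        models.append(
            GeneModel(
                gene_id=tid,
                symbol=m["symbol"],
                chrom=m["chrom"],
                strand=m["strand"],
                exons=exon_objs,
                cds_span=cds_span,
                biotype=biotype,
                sources={source_tag},
            )
        )
    return models


def _cds_to_tx_span(
    exons: Sequence[Exon], strand: str, cds_ivs: list[tuple[int, int]]
) -> tuple[int, int]:
    """Project genomic CDS intervals onto transcript coordinates."""
    g_start = min(s for s, _ in cds_ivs)
    g_end = max(e for _, e in cds_ivs)
    offsets = []
    total = 0
    for exon in exons:
        for gpos in (g_start, g_end - 1):
            if exon.start <= gpos < exon.end:
                if strand == "+":
                    off = total + (gpos - exon.start)
                else:
                    off = total + (exon.end - 1 - gpos)
                offsets.append(off)
        total += exon.length
    if len(offsets) < 2:
        raise ParseError("CDS interval does not land in exons")
    lo, hi = min(offsets), max(offsets)
    return (lo, hi + 1)


def _load_bed12(path, source_tag: str) -> list[GeneModel]:
    models = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}:{ln}: expected 12 BED columns")
            chrom = fields[0]
            start = int(fields[1])
            name = fields[3]
            strand = fields[5]
            thick_start, thick_end = int(fields[6]), int(fields[7])
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ParseError(f"{path}:{ln}: block count mismatch")
            genomic = [
                (start + off, start + off + size)
                for off, size in zip(starts, sizes)
            ]
            if any(e <= s for s, e in genomic):
                continue  # rejected record
            ordered = genomic if strand == "+" else genomic[::-1]
            exon_objs = [
                Exon(chrom, s, e, rank) for rank, (s, e) in enumerate(ordered, 1)
            ]
            cds_span = None
            if thick_end > thick_start:
                cds_span = _cds_to_tx_span(
                    exon_objs, strand, [(thick_start, thick_end)]
                )
            models.append(
                GeneModel(
                    gene_id=name,
                    symbol=name,
                    chrom=chrom,
                    strand=strand,
                    exons=exon_objs,
                    cds_span=cds_span,
                    biotype="coding" if cds_span else "noncoding",
                    sources={source_tag},
                )
            )
    return models


def write_gtf(annotation: AnnotationSet, path, source: str = "fusewalk") -> None:
    """Write gene models as GTF (exon and CDS features, 1-based inclusive)."""
    with open(path, "w") as fh:
        for model in sorted(annotation, key=lambda m: (m.chrom, m.span[0])):
            attrs = (
                f'gene_id "{model.gene_id}"; transcript_id "{model.gene_id}"; '
                f'gene_name "{model.symbol}"; gene_biotype '
                f'"{"protein_coding" if model.cds_span else "noncoding"}";'
            )
            for exon in model.exons:
                fh.write(
                    f"{model.chrom}\t{source}\texon\t{exon.start + 1}\t{exon.end}"
                    f"\t.\t{model.strand}\t.\t{attrs}\n"
                )
            if model.cds_span is not None:
                for (g_start, g_end) in _tx_span_to_genomic(model, *model.cds_span):
                    fh.write(
                        f"{model.chrom}\t{source}\tCDS\t{g_start + 1}\t{g_end}"
                        f"\t.\t{model.strand}\t0\t{attrs}\n"
                    )


def _tx_span_to_genomic(
    model: GeneModel, tx_start: int, tx_end: int
) -> list[tuple[int, int]]:
    """Project a transcript-coordinate interval onto genomic intervals."""
    out = []
    acc = 0
    for exon in model.exons:
        lo = max(tx_start, acc)
        hi = min(tx_end, acc + exon.length)
        if lo < hi:
            if model.strand == "+":
                out.append((exon.start + (lo - acc), exon.start + (hi - acc)))
            else:
                out.append((exon.end - (hi - acc), exon.end - (lo - acc)))
        acc += exon.length
    return sorted(out)


def load_annotation(paths_with_dialects: Sequence[tuple[str, str]]) -> AnnotationSet:
    """Load and merge gene models from (path, dialect) pairs.

    Dialects: ``gtf`` and ``bed12``.  Models identical in (chrom, strand,
    exon structure) collapse into one record carrying all source tags.
    """
    models: list[GeneModel] = []
    for path, dialect in paths_with_dialects:
        tag = str(path)
        if dialect == "gtf":
            models.extend(_load_gtf(path, tag))
        elif dialect == "bed12":
            models.extend(_load_bed12(path, tag))
        else:
            raise ValueError(f"unknown annotation dialect {dialect!r}")
    return AnnotationSet(models)
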