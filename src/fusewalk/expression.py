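"""Exon-level RPKM, trimmed-outlier (COPA) z-scores, and exon walking.

The outlier statistic standardizes each sample's exon RPKM against a trimmed
mean and standard deviation computed from the lowest ``k = ceil(f * n)``
sorted values, so a strong outlier inflates its own z-score rather than the
baseline.  An exon is an expression outlier in a sample when its z-score
exceeds ``z_min`` (strictly).

Exon walking scans a gene's exons in transcript order for an abrupt
fold-change in RPKM normalized per exon by the cohort 70th-percentile value;
such a step marks a candidate internal breakpoint — the signature of a
fusion transcript that uses only part of the gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, GeneModel

DEFAULT_TRIM_FRACTION = 0.75
DEFAULT_Z_MIN = 4.0
DEFAULT_RPKM_MIN = 20.0
DEFAULT_FOLD = 2.0
DEFAULT_QUANTILE = 0.70
DEFAULT_MIN_MAPQ = 10
SIGMA_FLOOR = 1e-8


class ExonExpressionMatrix:
    """Per-exon, per-sample RPKM with the raw counts behind it.

    Rows are keyed by (gene_id, rank); ``meta`` carries chrom/start/end per
    exon.  The identity RPKM = count / (length_kb * total_reads_millions)
    holds for every cell by construction.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        lengths_bp: pd.Series,
        totals_reads: pd.Series,
        meta: Optional[pd.DataFrame] = None,
    ):
        if (counts.values < 0).any():
            raise ValueError("negative counts")
        if (lengths_bp <= 0).any():
            raise ValueError("exon of zero length")
        if (totals_reads <= 0).any():
            bad = totals_reads.index[totals_reads <= 0].tolist()
            raise ValueError(f"sample(s) with zero total reads: {bad}")
        self.counts = counts
        self.lengths_bp = lengths_bp.loc[counts.index]
        self.totals_reads = totals_reads.loc[counts.columns]
        self.meta = meta
        len_kb = self.lengths_bp / 1_000.0
        tot_m = self.totals_reads / 1_000_000.0
        self.rpkm = counts.div(len_kb, axis=0).div(tot_m, axis=1)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def exon_keys(self) -> pd.MultiIndex:
        return self.counts.index

    def gene_ids(self) -> list[str]:
        return list(dict.fromkeys(self.counts.index.get_level_values(0)))

    def gene_rpkm(self, gene_id: str) -> pd.DataFrame:
        """RPKM rows of one gene, ordered by rank."""
        sub = self.rpkm.loc[gene_id]
        return sub.sort_index()

    def to_tsv(self, path) -> None:
        out = self.rpkm.copy()
        out.index = [f"{g}\t{r}" for g, r in out.index]
        with open(path, "w") as fh:
            fh.write("gene_id\trank\t" + "\t".join(map(str, out.columns)) + "\n")
            for idx, row in out.iterrows():
                fh.write(idx + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def read_exon_counts_tsv(path) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Read a per-exon count table.

    Layout: gene_id, rank, chrom, start, end, then one column per sample
    (start/end 1-based inclusive).  Returns (counts, lengths_bp, meta).
    """
    df = pd.read_csv(path, sep="\t")
    fixed = ["gene_id", "rank", "chrom", "start", "end"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    samples = [c for c in df.columns if c not in fixed]
    idx = pd.MultiIndex.from_frame(df[["gene_id", "rank"]])
    counts = df[samples].copy()
    counts.index = idx
    lengths = pd.Series(df["end"].values - df["start"].values + 1, index=idx)
    meta = df[["chrom", "start", "end"]].copy()
    meta.index = idx
    return counts, lengths, meta


def compute_exon_rpkm(
    source,
    annotation: AnnotationSet,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    totals_reads: Optional[dict[str, int]] = None,
) -> ExonExpressionMatrix:
    """Build the exon expression matrix from counts or alignments.

    ``source`` is either a per-exon count TSV path (see
    :func:`read_exon_counts_tsv`) or a mapping sample -> SAM path.  For
    alignment input a read counts toward an exon when its mapping quality is
    >= ``min_mapq`` and it overlaps the exon by at least one base; the
    per-sample library size is the number of mapped reads passing the same
    quality cutoff.
    """
    if isinstance(source, dict):
        counts, lengths, meta, totals = _count_from_sam(source, annotation, min_mapq)
        totals_series = pd.Series(totals)
    else:
        counts, lengths, meta = read_exon_counts_tsv(source)
        if totals_reads is not None:
            totals_series = pd.Series(totals_reads)
        else:
            totals_series = counts.sum(axis=0)
    return ExonExpressionMatrix(counts, lengths, totals_series, meta)


def _count_from_sam(sam_paths: dict[str, str], annotation: AnnotationSet, min_mapq: int):
    import pysam
    from intervaltree import IntervalTree

    exon_rows = []
    trees: dict[str, IntervalTree] = {}
    for model in annotation:
        for exon in model.exons:
            key = (model.gene_id, exon.rank)
            exon_rows.append((key, exon))
            trees.setdefault(exon.chrom, IntervalTree())[exon.start:exon.end] = key
    idx = pd.MultiIndex.from_tuples([k for k, _ in exon_rows])
    lengths = pd.Series([e.length for _, e in exon_rows], index=idx)
    meta = pd.DataFrame(
        {
            "chrom": [e.chrom for _, e in exon_rows],
            "start": [e.start + 1 for _, e in exon_rows],
            "end": [e.end for _, e in exon_rows],
        },
        index=idx,
    )
    counts = pd.DataFrame(0, index=idx, columns=list(sam_paths))
    totals: dict[str, int] = {}
    for sample, path in sam_paths.items():
        total = 0
        with pysam.AlignmentFile(str(path), "r") as sam:
            for read in sam:
                if read.is_unmapped or read.mapping_quality < min_mapq:
                    continue
                total += 1
                tree = trees.get(read.reference_name)
                if tree is None:
                    continue
                for iv in tree[read.reference_start:read.reference_end]:
                    counts.loc[iv.data, sample] += 1
        if total == 0:
            raise ValueError(f"sample {sample!r} has zero mapped reads")
        totals[sample] = total
    return counts, lengths, meta, totals


@dataclass
class CopaResult:
    """Trimmed-estimator outlier z-scores per exon and sample."""

    mu: pd.Series
    sigma: pd.Series
    k: pd.Series
    n: int
    z: pd.DataFrame
    outlier: pd.DataFrame
    z_min: float

    def max_gene_z(self, gene_id: str, sample: str) -> float:
        """Max z over the exons of a gene in one sample; -inf if absent."""
        try:
            sub = self.z.loc[gene_id]
        except KeyError:
            return float("-inf")
        return float(sub[sample].max())


def copa_z(
    matrix: ExonExpressionMatrix,
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
    z_min: float = DEFAULT_Z_MIN,
    eps: float = SIGMA_FLOOR,
) -> CopaResult:
    """Outlier z-scores from trimmed per-exon estimators.

    Per exon the RPKM values are sorted ascending; mu and sigma (sample
    standard deviation, n-1 denominator) are computed over the lowest
    ``k = ceil(trim_fraction * n)`` values, and ``z = (x - mu) / sigma`` for
    every sample.  Exons with sigma below ``eps`` get all-zero z-scores.
    """
    n = len(matrix.samples)
    if n < 4:
        raise ValueError("insufficient samples: COPA needs n >= 4")
    if not (0 < trim_fraction <= 1):
        raise ValueError("trim_fraction must be in (0, 1]")
    k = math.ceil(trim_fraction * n)
    values = matrix.rpkm.values
    sorted_vals = np.sort(values, axis=1)
    low = sorted_vals[:, :k]
    mu = low.mean(axis=1)
    sigma = low.std(axis=1, ddof=1) if k > 1 else np.zeros(len(mu))
    safe = sigma >= eps
    z = np.zeros_like(values, dtype=float)
    z[safe] = (values[safe] - mu[safe, None]) / sigma[safe, None]
    z_df = pd.DataFrame(z, index=matrix.rpkm.index, columns=matrix.rpkm.columns)
    return CopaResult(
        mu=pd.Series(mu, index=matrix.rpkm.index),
        sigma=pd.Series(sigma, index=matrix.rpkm.index),
        k=pd.Series(k, index=matrix.rpkm.index),
        n=n,
        z=z_df,
        outlier=z_df > z_min,
        z_min=z_min,
    )


def select_candidate_genes(
    copa: CopaResult,
    matrix: ExonExpressionMatrix,
    rpkm_min: float = DEFAULT_RPKM_MIN,
) -> list[tuple[str, str]]:
    """(gene, sample) pairs with an outlier exon worth walking.

    A pair qualifies when some exon of the gene both has max-across-samples
    RPKM strictly above ``rpkm_min`` and is an outlier in that sample.
    """
    eligible = matrix.rpkm.max(axis=1) > rpkm_min
    flagged = copa.outlier.loc[eligible.values]
    out = []
    for (gene_id, _rank), row in flagged.iterrows():
        for sample in row.index[row]:
            out.append((gene_id, sample))
    return sorted(set(out))


@dataclass
class WalkProfile:
    gene_id: str
    sample: str
    ranks: list[int]
    normalized: list[float]


@dataclass(frozen=True)
class BreakpointCandidate:
    gene_id: str
    sample: str
    boundary: tuple[int, int]  # (rank j, rank j+1)
    direction: str             # 'drop' or 'rise'
    fold_change: float


def walk_profile(
    matrix: ExonExpressionMatrix,
    gene_id: str,
    sample: str,
    quantile: float = DEFAULT_QUANTILE,
) -> Optional[WalkProfile]:
    """Normalized exon profile: RPKM over the cohort ``quantile`` percentile.

    Exons whose cohort percentile is zero fall back to the gene's smallest
    positive percentile; a gene with no nonzero percentile at all yields None.
    """
    sub = matrix.gene_rpkm(gene_id)
    q = np.percentile(sub.values, quantile * 100.0, axis=1)
    positive = q[q > 0]
    if positive.size == 0:
        return None
    q = np.where(q > 0, q, positive.min())
    values = sub[sample].values / q
    return WalkProfile(gene_id, sample, list(sub.index), [float(v) for v in values])


def walk_breakpoints(
    matrix: ExonExpressionMatrix,
    gene: GeneModel | str,
    sample: str,
    fold: float = DEFAULT_FOLD,
    quantile: float = DEFAULT_QUANTILE,
) -> list[BreakpointCandidate]:
    """Candidate breakpoints where the normalized profile steps by >= fold.

    Walking 5'->3', the boundary between ranks j and j+1 is a candidate when
    the normalized value drops to <= r_j / fold or rises to >= fold * r_j
    (inclusive comparisons).  Single-exon genes yield no candidates.
    """
    gene_id = gene.gene_id if isinstance(gene, GeneModel) else gene
    profile = walk_profile(matrix, gene_id, sample, quantile)
    if profile is None or len(profile.ranks) < 2:
        return []
    out = []
    vals = profile.normalized
    for i in range(len(vals) - 1):
        a, b = vals[i], vals[i + 1]
        j = profile.ranks[i]
        j1 = profile.ranks[i + 1]
        if a == 0.0 and b == 0.0:
            continue
        if b <= a / fold:
            fc = math.inf if b == 0 else a / b
            out.append(BreakpointCandidate(gene_id, sample, (j, j1), "drop", fc))
        elif b >= fold * a:
            fc = math.inf if a == 0 else b / a
            out.append(BreakpointCandidate(gene_id, sample, (j, j1), "rise", fc))
    return out
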