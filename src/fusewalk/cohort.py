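"""Cohort-level recurrence, distance, distribution and association summaries.

Recurrence is counted per *patient*, not per sequencing aliquot: TCGA
barcodes collapse at the participant field (project-TSS-participant, e.g.
TCGA-06-0211-01A and -01B are one patient), and discovery-cohort samples
with a known TCGA alias map to that patient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .annotation import CytobandTable
from .tables import DISCOVERY_TCGA_ALIASES


class PatientMap:
    """Resolve sample / aliquot identifiers to patient identifiers."""

    def __init__(
        self,
        aliases: Optional[Mapping[str, str]] = None,
        strict: bool = False,
        known_samples: Optional[Iterable[str]] = None,
    ):
        self.aliases = dict(DISCOVERY_TCGA_ALIASES)
        if aliases is not None:
            self.aliases.update(aliases)
        self.strict = strict
        self.known = set(known_samples) if known_samples is not None else None

    def patient_of(self, sample: str) -> str:
        if self.known is not None and sample not in self.known:
            raise KeyError(f"unmapped sample {sample!r}")
        resolved = self.aliases.get(sample, sample)
        if resolved.startswith("TCGA-"):
            fields = resolved.split("-")
            if len(fields) < 3:
                raise KeyError(f"malformed TCGA barcode {sample!r}")
            return "-".join(fields[:3])
        if self.strict and sample not in self.aliases:
            raise KeyError(f"unmapped sample {sample!r}")
        return resolved


def recurrent_partner_genes(
    fusions: pd.DataFrame,
    pmap: PatientMap,
    min_patients: int = 2,
) -> pd.Series:
    """Genes partnering in fusions of >= ``min_patients`` distinct patients.

    Each gene counts once per patient no matter how many of that patient's
    fusions involve it; "UAR" is a placeholder for unannotated sequence, not
    a gene, and is never counted.  Output is independent of row order and of
    duplicated aliquots.
    """
    patients_per_gene: dict[str, set[str]] = {}
    for row in fusions.itertuples():
        patient = pmap.patient_of(row.sample)
        for gene in (row.gene_5p, row.gene_3p):
            if gene == "UAR" or (isinstance(gene, float) and math.isnan(gene)):
                continue
            patients_per_gene.setdefault(gene, set()).add(patient)
    counts = {
        gene: len(pats)
        for gene, pats in patients_per_gene.items()
        if len(pats) >= min_patients
    }
    return pd.Series(counts, dtype=int).sort_index()


def pair_patient_counts(
    fusions: pd.DataFrame, pmap: PatientMap, by_cohort: bool = False
) -> pd.Series:
    """Distinct patients per (5' gene, 3' gene) pair, optionally per cohort."""
    seen: dict[tuple, set[str]] = {}
    for row in fusions.itertuples():
        key = (row.gene_5p, row.gene_3p)
        if by_cohort:
            key = key + (row.cohort,)
        seen.setdefault(key, set()).add(pmap.patient_of(row.sample))
    return pd.Series({k: len(v) for k, v in seen.items()}, dtype=int)


def partner_distance_stats(
    fusions: pd.DataFrame,
) -> tuple[int, int, list[int]]:
    """(min, max, all) breakpoint distances of intra-chromosomal fusions."""
    chrom5 = fusions["chrom_5p"] if "chrom_5p" in fusions else fusions["chrom"]
    chrom3 = fusions["chrom_3p"] if "chrom_3p" in fusions else fusions["chrom"]
    if (chrom5 != chrom3).any():
        bad = fusions.index[(chrom5 != chrom3)].tolist()
        raise ValueError(f"inter-chromosomal record(s) in input: rows {bad}")
    distances = (fusions["pos_5p"] - fusions["pos_3p"]).abs().astype(int).tolist()
    return min(distances), max(distances), distances


def format_distance(bp: int) -> str:
    """Human-readable distance: Mb to 2 significant figures, else whole kb."""
    if bp >= 1_000_000:
        mb = float(f"{bp / 1e6:.2g}")
        return f"{mb:g} Mb"
    return f"{round(bp / 1e3)} kb"


@dataclass
class CohortSummary:
    n_patients: int
    n_fusions: int
    frac_with_fusion: float
    frac_with_multiple: float
    mechanism_fractions: dict[str, float] = field(default_factory=dict)
    structure_fractions: dict[str, float] = field(default_factory=dict)
    chromosome_counts: dict[str, int] = field(default_factory=dict)
    chromosome_counts_by_subtype: dict[str, dict[str, int]] = field(default_factory=dict)
    band_density: dict[str, int] = field(default_factory=dict)


def summarize_cohort(
    fusions: pd.DataFrame,
    pmap: PatientMap,
    n_patients: int,
    mechanisms: Optional[Sequence[str]] = None,
    structures: Optional[Sequence[str]] = None,
    subtypes: Optional[Mapping[str, str]] = None,
    cytobands: Optional[CytobandTable] = None,
) -> CohortSummary:
    """Cohort-wide fusion burden, mechanism/structure mix, and hotspots.

    ``mechanisms`` and ``structures`` are per-fusion labels aligned with the
    rows of ``fusions``; ``subtypes`` maps sample -> molecular subtype label
    (missing samples are grouped as "unlabeled").  Breakpoint histograms
    count both partners' breakpoints.
    """
    patients = [pmap.patient_of(s) for s in fusions["sample"]]
    per_patient = pd.Series(patients).value_counts()
    n_with = int((per_patient >= 1).sum())
    n_multi = int((per_patient > 1).sum())

    def _fractions(labels: Optional[Sequence[str]]) -> dict[str, float]:
        if labels is None:
            return {}
        ser = pd.Series([l for l in labels if l is not None])
        if ser.empty:
            return {}
        return (ser.value_counts() / len(ser)).to_dict()

    chrom_counts: dict[str, int] = {}
    by_subtype: dict[str, dict[str, int]] = {}
    band_density: dict[str, int] = {}
    for row in fusions.itertuples():
        subtype = "unlabeled"
        if subtypes is not None:
            subtype = subtypes.get(row.sample, "unlabeled")
        for chrom, pos in ((row.chrom_5p, row.pos_5p), (row.chrom_3p, row.pos_3p)):
            chrom_counts[chrom] = chrom_counts.get(chrom, 0) + 1
            by_subtype.setdefault(subtype, {})[chrom] = (
                by_subtype.setdefault(subtype, {}).get(chrom, 0) + 1
            )
            if cytobands is not None:
                try:
                    band = cytobands.band_of(chrom, int(pos))
                except (KeyError, ValueError):
                    continue
                band_density[band] = band_density.get(band, 0) + 1

    return CohortSummary(
        n_patients=n_patients,
        n_fusions=len(fusions),
        frac_with_fusion=n_with / n_patients,
        frac_with_multiple=n_multi / n_patients,
        mechanism_fractions=_fractions(mechanisms),
        structure_fractions=_fractions(structures),
        chromosome_counts=chrom_counts,
        chromosome_counts_by_subtype=by_subtype,
        band_density=band_density,
    )


def association_test(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher exact p for a 2x2 count table.

    The p-value is the sum of hypergeometric probabilities, conditional on
    the margins, of all tables at most as probable as the observed one.
    The odds ratio is the sample odds ratio ad/bc (inf when bc = 0 with
    ad > 0, nan for 0/0).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    if n == 0:
        return float("nan"), 1.0
    ad, bc = a * d, b * c
    if bc == 0:
        odds = float("nan") if ad == 0 else float("inf")
    else:
        odds = ad / bc
    rv = hypergeom(n, c1, r1)
    lo = max(0, r1 - (n - c1))
    hi = min(r1, c1)
    p_obs = rv.pmf(a)
    ks = np.arange(lo, hi + 1)
    probs = rv.pmf(ks)
    p = float(probs[probs <= p_obs * (1 + 1e-9)].sum())
    return odds, min(p, 1.0)
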