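"""Variant-set logic: pre-filters, V/TV/T categorization, summaries, TMB.

Antigen categories follow the vaccine/tumor/germline partition used for
allogeneic whole-tumor vaccines: with the patient's germline defining self,
a variant is V when found only in the vaccine cell lines, TV when shared by
vaccine and tumor, and T when private to the tumor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

from .models import ExpressionProfile, GenomicKey, ProteinVariant

#: Captured human exome size in megabases used for mutational-burden rates.
DEFAULT_EXOME_MB = 50.39

CATEGORIES = ("V", "TV", "T")


@dataclass
class CategoryTable:
    """Disjoint assignment of variant keys to the V / TV / T categories."""

    assignments: Dict[GenomicKey, str] = field(default_factory=dict)

    @property
    def counts(self) -> Dict[str, int]:
        tally = {c: 0 for c in CATEGORIES}
        for category in self.assignments.values():
            tally[category] += 1
        return tally

    def keys_in(self, category: str) -> List[GenomicKey]:
        return [k for k, c in self.assignments.items() if c == category]


def prefilter_variants(
    variants: Sequence[ProteinVariant],
    expr: ExpressionProfile,
    min_vaf: float = 0.10,
    min_tpm: float = 0.0,
) -> List[ProteinVariant]:
    """Keep variants that are plausibly antigenic in the vaccine context.

    A variant survives when its maximal per-cell-line VAF exceeds ``min_vaf``
    (strictly), its gene is expressed in the combined vaccine profile
    (TPM strictly above ``min_tpm``), and the caller marked it PASS in at
    least one cell line. Genes missing from the profile count as TPM 0.
    """
    kept = []
    for v in variants:
        if v.max_vaf <= min_vaf:
            continue
        if expr.tpm(v.gene) <= min_tpm:
            continue
        if v.filter_pass_count < 1:
            continue
        kept.append(v)
    return kept


def categorize_variants(
    vaccine: Iterable[ProteinVariant],
    germline: Iterable[ProteinVariant],
    tumor: Iterable[ProteinVariant],
) -> CategoryTable:
    """Partition variant keys into V / TV / T with germline keys as self.

    The vaccine cell lines are unioned upstream, so ``vaccine`` may contain
    the same genomic key repeatedly; identity is the genomic key alone.
    """
    vac = {v.genomic_key for v in vaccine}
    germ = {v.genomic_key for v in germline}
    tum = {t.genomic_key for t in tumor}
    vac_somatic = vac - germ
    tum_somatic = tum - germ
    table = CategoryTable()
    for key in vac_somatic - tum:
        table.assignments[key] = "V"
    for key in vac_somatic & tum_somatic:
        table.assignments[key] = "TV"
    for key in tum_somatic - vac:
        table.assignments[key] = "T"
    return table


@dataclass
class CategorySummary:
    """Per-patient vaccine-specific totals and their cross-patient spread."""

    per_patient_vaccine_specific: Dict[str, int]
    per_patient_shared_fraction: Dict[str, float]
    mean_vaccine_specific: float
    sd_vaccine_specific: Optional[float]


def summarize_categories(
    tables: Mapping[str, CategoryTable] | Mapping[str, Mapping[str, int]],
) -> CategorySummary:
    """Summarize category counts across patients.

    Accepts either :class:`CategoryTable` objects or plain ``{category:
    count}`` mappings per patient. The vaccine-specific total per patient is
    ``|V| + |TV|``; the shared fraction is ``|TV| / (|V| + |TV|)``. The
    cross-patient spread uses the sample standard deviation (n - 1); with a
    single patient the SD is reported as absent.
    """
    totals: Dict[str, int] = {}
    shared: Dict[str, float] = {}
    for patient, table in tables.items():
        counts = table.counts if isinstance(table, CategoryTable) else dict(table)
        specific = counts.get("V", 0) + counts.get("TV", 0)
        totals[patient] = specific
        shared[patient] = counts.get("TV", 0) / specific if specific else 0.0
    values = list(totals.values())
    mean = sum(values) / len(values)
    if len(values) >= 2:
        sd = math.sqrt(sum((x - mean) ** 2 for x in values) / (len(values) - 1))
    else:
        sd = None
    return CategorySummary(
        per_patient_vaccine_specific=totals,
        per_patient_shared_fraction=shared,
        mean_vaccine_specific=mean,
        sd_vaccine_specific=sd,
    )


def compute_tmb(variants: Sequence[ProteinVariant], exome_mb: float = DEFAULT_EXOME_MB) -> float:
    """Tumor mutational burden: non-synonymous coding mutations per megabase.

    ``variants`` are expected to already be somatic (tumor minus germline)
    and, by construction of the variant readers, coding non-synonymous.
    """
    if exome_mb <= 0:
        raise ValueError(f"exome_mb must be > 0, got {exome_mb}")
    return len(variants) / exome_mb
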