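"""Candidate-selection cascade and the deterministic curation surrogate.

The cascade applies the study's selection rules in a fixed order: variant
evidence first (VAF, expression, RNA coverage), then presentation (mutant
strong binder, wild-type non-binder), stability, the HLA-C exclusion (the
stability predictor is not trained on HLA-C data), and finally the class II
exclusion that keeps CD8-restricted candidates. Every candidate carries a
full per-filter trace so rejections are auditable.

Manual curation — picking a final panel spread across stability and
expression — is replaced by a deterministic farthest-point selection in the
rank-transformed (stability rank, log1p TPM) plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

from .models import PeptidePair, ValidationError


@dataclass
class CascadeThresholds:
    """Selection rules; defaults are the study's quoted cut-offs."""

    min_vaf: float = 0.10          # max per-line VAF must exceed this (strict)
    min_tpm: float = 0.0           # combined vaccine TPM must exceed this (strict)
    min_rna_coverage: int = 10     # reads at the mutated position (>=)
    max_mut_rank_el: float = 0.5   # mutant %Rank_EL strictly below
    min_wt_rank_el: float = 2.0    # wild-type %Rank_EL at or above
    max_rank_stab: float = 2.0     # %Rank_Stab strictly below
    exclude_locus: str = "C"       # peptides presented on this locus are dropped
    min_classII_rank: float = 1.0  # minimum class II %Rank_EL at or above


@dataclass
class PeptideCandidate:
    """A scored mutant peptide on one patient allele, ready for the cascade."""

    pair: PeptidePair
    allele: str
    locus: str
    category: str
    mut_rank_el: Optional[float]
    wt_rank_el: Optional[float]
    rank_stab: Optional[float]
    classII_min_rank: Optional[float]
    tpm: float
    rna_coverage: int
    max_vaf: float
    gene: Optional[str] = None
    filter_trace: List[Tuple[str, bool]] = field(default_factory=list)

    @property
    def peptide(self) -> str:
        return self.pair.mutant


#: Cascade filter names in application order.
FILTER_ORDER = (
    "vaf",
    "expression",
    "rna_coverage",
    "mut_binding",
    "wt_nonbinding",
    "stability",
    "hla_c_exclusion",
    "classII_exclusion",
)


def _check(candidate: PeptideCandidate, name: str, thresholds: CascadeThresholds) -> bool:
    if name == "vaf":
        return candidate.max_vaf > thresholds.min_vaf
    if name == "expression":
        return candidate.tpm > thresholds.min_tpm
    if name == "rna_coverage":
        return candidate.rna_coverage >= thresholds.min_rna_coverage
    if name == "mut_binding":
        if candidate.mut_rank_el is None:
            raise ValidationError(
                f"candidate {candidate.peptide}/{candidate.allele}: missing mutant %Rank_EL"
            )
        return candidate.mut_rank_el < thresholds.max_mut_rank_el
    if name == "wt_nonbinding":
        if candidate.pair.wildtype is None:
            return True  # novel sequence: no wild-type counterpart to exclude
        if candidate.wt_rank_el is None:
            raise ValidationError(
                f"candidate {candidate.peptide}/{candidate.allele}: missing wild-type %Rank_EL"
            )
        return candidate.wt_rank_el >= thresholds.min_wt_rank_el
    if name == "stability":
        if candidate.rank_stab is None:
            raise ValidationError(
                f"candidate {candidate.peptide}/{candidate.allele}: missing %Rank_Stab"
            )
        return candidate.rank_stab < thresholds.max_rank_stab
    if name == "hla_c_exclusion":
        return candidate.locus != thresholds.exclude_locus
    if name == "classII_exclusion":
        if candidate.classII_min_rank is None:
            raise ValidationError(
                f"candidate {candidate.peptide}/{candidate.allele}: missing class II rank"
            )
        return candidate.classII_min_rank >= thresholds.min_classII_rank
    raise ValueError(f"unknown filter {name!r}")


def apply_cascade(
    candidates: Sequence[PeptideCandidate],
    thresholds: CascadeThresholds | None = None,
) -> Tuple[List[PeptideCandidate], List[Dict[str, object]]]:
    """Run every filter on every candidate; survivors pass all of them.

    Returns the survivors (with complete filter traces attached) and a trace
    table with one row per candidate recording each filter verdict and, for
    rejected candidates, the first failing filter.
    """
    thresholds = thresholds or CascadeThresholds()
    survivors: List[PeptideCandidate] = []
    trace_table: List[Dict[str, object]] = []
    for candidate in candidates:
        trace = [(name, _check(candidate, name, thresholds)) for name in FILTER_ORDER]
        candidate = replace(candidate, filter_trace=trace)
        first_fail = next((name for name, ok in trace if not ok), None)
        row: Dict[str, object] = {
            "peptide": candidate.peptide,
            "allele": candidate.allele,
            "survivor": first_fail is None,
            "first_fail": first_fail,
        }
        row.update({name: ok for name, ok in trace})
        trace_table.append(row)
        if first_fail is None:
            survivors.append(candidate)
    return survivors, trace_table


CANDIDATE_TSV_COLUMNS = [
    "peptide",
    "wildtype",
    "chrom",
    "pos",
    "ref",
    "alt",
    "transcript",
    "mut_positions",
    "allele",
    "locus",
    "category",
    "mut_rank_el",
    "wt_rank_el",
    "rank_stab",
    "classII_min_rank",
    "tpm",
    "rna_coverage",
    "max_vaf",
    "gene",
]


def candidates_to_frame(candidates: Sequence[PeptideCandidate]):
    """Flatten candidates to the documented TSV layout."""
    import pandas as pd

    rows = []
    for c in candidates:
        key = c.pair.genomic_key
        rows.append(
            {
                "peptide": c.peptide,
                "wildtype": c.pair.wildtype or "",
                "chrom": key[0],
                "pos": key[1],
                "ref": key[2],
                "alt": key[3],
                "transcript": c.pair.transcript,
                "mut_positions": ";".join(str(i) for i in sorted(c.pair.mut_positions)),
                "allele": c.allele,
                "locus": c.locus,
                "category": c.category,
                "mut_rank_el": c.mut_rank_el,
                "wt_rank_el": "" if c.wt_rank_el is None else c.wt_rank_el,
                "rank_stab": "" if c.rank_stab is None else c.rank_stab,
                "classII_min_rank": "" if c.classII_min_rank is None else c.classII_min_rank,
                "tpm": c.tpm,
                "rna_coverage": c.rna_coverage,
                "max_vaf": c.max_vaf,
                "gene": c.gene or "",
            }
        )
    return pd.DataFrame(rows, columns=CANDIDATE_TSV_COLUMNS)


def candidates_from_frame(frame) -> List[PeptideCandidate]:
    """Rebuild candidates from the documented TSV layout."""
    out: List[PeptideCandidate] = []
    for row in frame.itertuples(index=False):
        wildtype = str(row.wildtype) if str(row.wildtype) else None
        pair = PeptidePair(
            mutant=row.peptide,
            wildtype=wildtype,
            genomic_key=(str(row.chrom), int(row.pos), str(row.ref), str(row.alt)),
            transcript=str(row.transcript),
            mut_positions=frozenset(
                int(i) for i in str(row.mut_positions).split(";") if i
            ),
        )

        def opt(value) -> Optional[float]:
            text = str(value)
            return float(text) if text not in ("", "nan") else None

        out.append(
            PeptideCandidate(
                pair=pair,
                allele=str(row.allele),
                locus=str(row.locus),
                category=str(row.category),
                mut_rank_el=opt(row.mut_rank_el),
                wt_rank_el=opt(row.wt_rank_el),
                rank_stab=opt(row.rank_stab),
                classII_min_rank=opt(row.classII_min_rank),
                tpm=float(row.tpm),
                rna_coverage=int(row.rna_coverage),
                max_vaf=float(row.max_vaf),
                gene=(str(row.gene) or None) if hasattr(row, "gene") else None,
            )
        )
    return out


def _rank_unit(values: Sequence[float]) -> np.ndarray:
    """Average-tie ranks rescaled to [0, 1] (constant input maps to 0.5)."""
    ranks = rankdata(values)
    if len(values) == 1 or ranks.max() == ranks.min():
        return np.full(len(values), 0.5)
    return (ranks - 1) / (len(values) - 1)


def curate_selection(
    survivors: Sequence[PeptideCandidate],
    k: int,
    per_variant_max: int = 1,
) -> List[PeptideCandidate]:
    """Deterministic surrogate for manual panel curation.

    First keeps at most ``per_variant_max`` peptides per source variant (best
    mutant %Rank_EL; ties broken lexicographically by peptide sequence), then
    greedily selects ``k`` candidates by farthest-point dispersion in the 2-D
    space of rank-transformed (%Rank_Stab, log1p TPM), seeded from the
    extreme-TPM candidate. Ties at every step break lexicographically.
    """
    by_variant: Dict[tuple, List[PeptideCandidate]] = {}
    for cand in survivors:
        by_variant.setdefault(cand.pair.genomic_key, []).append(cand)
    deduped: List[PeptideCandidate] = []
    for group in by_variant.values():
        group = sorted(group, key=lambda c: (c.mut_rank_el, c.peptide))
        deduped.extend(group[:per_variant_max])
    deduped.sort(key=lambda c: c.peptide)
    if k > len(deduped):
        raise ValidationError(
            f"requested {k} candidates but only {len(deduped)} remain after dedup"
        )
    if k == len(deduped):
        return deduped

    x = _rank_unit([c.rank_stab for c in deduped])
    y = _rank_unit([math.log1p(c.tpm) for c in deduped])
    points = np.column_stack([x, y])
    # seed: the candidate at the expression extreme (highest TPM rank);
    # ties break toward the lexicographically first peptide
    seed_idx = min(range(len(deduped)), key=lambda i: (-y[i], deduped[i].peptide))
    chosen = [seed_idx]
    dist = np.linalg.norm(points - points[seed_idx], axis=1)
    while len(chosen) < k:
        best = min(
            (i for i in range(len(deduped)) if i not in chosen),
            key=lambda i: (-dist[i], deduped[i].peptide),
        )
        chosen.append(best)
        dist = np.minimum(dist, np.linalg.norm(points - points[best], axis=1))
    return [deduped[i] for i in sorted(chosen)]
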