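"""Core domain types shared across the pipeline.

The pipeline works at the protein-consequence level: a variant is identified
across samples by its genomic key (chrom, pos, ref, alt) while carrying the
protein-level annotation needed for peptide extraction, and downstream stages
exchange small frozen records rather than raw caller output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
CLASS_I_LOCI = ("A", "B", "C")
CLASS_II_LOCI = ("DRB1", "DQB1", "DQA1", "DPB1", "DPA1")

CONSEQUENCE_KINDS = ("missense", "inframe_insertion", "inframe_deletion", "frameshift")

GenomicKey = Tuple[str, int, str, str]


class ValidationError(ValueError):
    """A record violates a domain invariant."""


@dataclass(frozen=True)
class ProteinVariant:
    """One coding non-synonymous variant with its protein consequence.

    Identity across samples is the genomic key alone; the protein annotation
    (transcript, consequence, amino-acid change) travels with the record but
    does not participate in set comparisons between genomes.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: str
    consequence_kind: str
    protein_pos: int
    ref_aa: str
    alt_aa: str
    filter_pass_count: int = 1
    vaf_by_line: Mapping[str, float] = field(default_factory=dict)
    rna_coverage: int = 0
    rna_vaf: float = 0.0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"genomic position must be >= 1, got {self.pos}")
        if self.protein_pos < 1:
            raise ValidationError(f"protein position must be >= 1, got {self.protein_pos}")
        if self.consequence_kind not in CONSEQUENCE_KINDS:
            raise ValidationError(f"unknown consequence kind {self.consequence_kind!r}")
        if self.consequence_kind == "missense" and not (
            len(self.ref_aa) == 1 and len(self.alt_aa) == 1
        ):
            raise ValidationError(
                f"missense requires single-residue change, got {self.ref_aa!r}>{self.alt_aa!r}"
            )
        for line, vaf in self.vaf_by_line.items():
            if not 0.0 <= vaf <= 1.0:
                raise ValidationError(f"VAF for {line} out of [0,1]: {vaf}")
        if not 0.0 <= self.rna_vaf <= 1.0:
            raise ValidationError(f"RNA VAF out of [0,1]: {self.rna_vaf}")
        if self.rna_coverage < 0:
            raise ValidationError(f"negative RNA coverage: {self.rna_coverage}")
        if self.filter_pass_count < 0:
            raise ValidationError(f"negative pass count: {self.filter_pass_count}")

    @property
    def genomic_key(self) -> GenomicKey:
        return (self.chrom, self.pos, self.ref.upper(), self.alt.upper())

    @property
    def max_vaf(self) -> float:
        return max(self.vaf_by_line.values(), default=0.0)


@dataclass
class ExpressionProfile:
    """Gene expression per vaccine cell line plus the combined vaccine profile.

    The combined profile is the per-gene sum over cell lines rescaled so that
    it totals one million, i.e. it stays on the TPM scale.
    """

    per_line_tpm: Mapping[Tuple[str, str], float]
    combined_tpm: Mapping[str, float]

    @classmethod
    def from_per_line(cls, per_line_tpm: Mapping[Tuple[str, str], float]) -> "ExpressionProfile":
        summed: dict[str, float] = {}
        for (_, gene), tpm in per_line_tpm.items():
            if tpm < 0:
                raise ValidationError(f"negative TPM for gene {gene}: {tpm}")
            summed[gene] = summed.get(gene, 0.0) + tpm
        total = sum(summed.values())
        if total > 0:
            combined = {g: v * 1e6 / total for g, v in summed.items()}
        else:
            combined = {g: 0.0 for g in summed}
        return cls(per_line_tpm=dict(per_line_tpm), combined_tpm=combined)

    def tpm(self, gene: str) -> float:
        """Combined vaccine TPM for a gene; genes absent from the profile are 0."""
        return self.combined_tpm.get(gene, 0.0)


@dataclass(frozen=True)
class HLAAllele:
    """One HLA allele in WHO nomenclature with its protein sequence."""

    name: str
    locus: str
    hla_class: str
    protein_seq: str

    def __post_init__(self) -> None:
        if self.locus in CLASS_I_LOCI:
            expected = "I"
        elif self.locus in CLASS_II_LOCI:
            expected = "II"
        else:
            raise ValidationError(f"unknown HLA locus {self.locus!r}")
        if self.hla_class != expected:
            raise ValidationError(
                f"locus {self.locus} is class {expected}, record says {self.hla_class}"
            )
        if not self.protein_seq:
            raise ValidationError(f"empty protein sequence for {self.name}")
        bad = set(self.protein_seq) - (AMINO_ACIDS | {"X"})
        if bad:
            raise ValidationError(f"invalid residues in {self.name}: {sorted(bad)}")


def parse_hla_name(name: str) -> Tuple[str, str]:
    """Parse WHO nomenclature like ``HLA-B*57:01`` to (locus, class)."""
    token = name.strip()
    if token.startswith("HLA-"):
        token = token[4:]
    locus = token.split("*")[0]
    if locus in CLASS_I_LOCI:
        return locus, "I"
    if locus in CLASS_II_LOCI:
        return locus, "II"
    raise ValidationError(f"cannot parse HLA allele name {name!r}")


@dataclass
class PatientHaplotype:
    """Patient HLA genotype: six class I slots (duplicates mark homozygosity)."""

    class_I: Sequence[str]
    class_II: Sequence[str] = ()

    def __post_init__(self) -> None:
        if len(self.class_I) != 6:
            raise ValidationError(
                f"class I haplotype needs exactly 6 allele slots, got {len(self.class_I)}"
            )


@dataclass(frozen=True)
class PredictionRecord:
    """Peptide-HLA scores on the percentile-rank scale (lower = better)."""

    peptide: str
    allele: str
    rank_el: float
    rank_stab: Optional[float] = None
    icore: Optional[str] = None

    def __post_init__(self) -> None:
        if self.rank_el < 0:
            raise ValidationError(f"rank_el must be >= 0, got {self.rank_el}")
        if self.rank_stab is not None and self.rank_stab < 0:
            raise ValidationError(f"rank_stab must be >= 0, got {self.rank_stab}")


@dataclass(frozen=True)
class ELISpotAssay:
    """Replicate IFN-gamma spot counts for one (patient, timepoint, peptide)."""

    patient: str
    timepoint: str
    peptide: str
    stim_counts: Tuple[int, ...]
    ctrl_counts: Tuple[int, ...]
    cells_per_well: int

    def __post_init__(self) -> None:
        if self.timepoint not in ("PRE", "Post1", "Post2", "Post3"):
            raise ValidationError(f"unknown timepoint {self.timepoint!r}")
        if not self.stim_counts or not self.ctrl_counts:
            raise ValidationError("replicate lists must be non-empty")
        if any(c < 0 for c in self.stim_counts + self.ctrl_counts):
            raise ValidationError("spot counts must be non-negative")
        if self.cells_per_well <= 0:
            raise ValidationError(f"cells_per_well must be > 0, got {self.cells_per_well}")


@dataclass(frozen=True)
class PeptidePair:
    """A mutant peptide with its wild-type counterpart (when one exists).

    ``wildtype`` is absent for frameshift and in-frame indel peptides, whose
    novel sequence has no positionally matched germline counterpart.
    ``mut_positions`` are 1-based positions within the peptide.
    """

    mutant: str
    wildtype: Optional[str]
    genomic_key: GenomicKey
    transcript: str
    mut_positions: frozenset[int]

    def __post_init__(self) -> None:
        if not 8 <= len(self.mutant) <= 15:
            raise ValidationError(f"peptide length out of range: {self.mutant!r}")
        if not self.mut_positions:
            raise ValidationError("mut_positions must be non-empty")
        if self.wildtype is not None and len(self.wildtype) != len(self.mutant):
            raise ValidationError("wildtype and mutant peptides must be the same length")


@dataclass
class ImmunogenicityRecord:
    """Positivity call for one ELISpot assay.

    ``magnitude`` is floored at zero for reporting; ``raw_magnitude`` keeps
    the signed background-subtracted value.
    """

    patient: str
    timepoint: str
    peptide: str
    category: Optional[str]
    magnitude: float
    raw_magnitude: float
    p_value: Optional[float]
    positive: bool
    method: str

    def __post_init__(self) -> None:
        if self.method not in ("DFR", "empirical"):
            raise ValidationError(f"unknown positivity method {self.method!r}")
        if self.method == "DFR" and self.p_value is None:
            raise ValidationError("DFR calls must carry a p-value")
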