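"""Synthetic inputs with the statistical structure the analysis assumes.

The study's sequencing data are protected, so every downstream stage is
exercised on generated stand-ins that reproduce the relevant structure: the
vaccine/germline/tumor overlap pattern (including a high-burden patient
whose tumor shares a large fraction of vaccine variants), log-normal TPM
expression, HLA genotypes with optional class I homozygosity, and ELISpot
replicate counts with a planted correlation between log-expression and
response magnitude. Set sizes are fixed by construction, not by sampling,
and every generator is a pure function of its config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .models import (
    ELISpotAssay,
    ExpressionProfile,
    HLAAllele,
    PatientHaplotype,
    ProteinVariant,
)

_BASES = "ACGT"
_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


class ConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass
class SimulationConfig:
    """Study-scale defaults for the synthetic cohort.

    ``n_vaccine_variants`` is the number of vaccine-specific (non-germline)
    variants; ``tv_fraction`` of them are also present in the tumor. The
    high-burden scenario corresponds to ``tv_fraction=0.195``. ELISpot
    parameters describe a typical PBMC assay: 200,000 cells per well,
    triplicates, ~10 background spots per well, negative-binomial
    overdispersion, and a latent response magnitude (spots per 100,000
    cells) whose correlation with log1p(TPM) is planted at
    ``elispot_effect_corr``.
    """

    seed: int = 0
    n_vaccine_lines: int = 4
    n_vaccine_variants: int = 9500
    tv_fraction: float = 0.001
    n_tumor_private: int = 200
    n_germline_background: int = 500
    tpm_log_mean: float = 1.5
    tpm_log_sd: float = 1.5
    elispot_ctrl_mean: float = 10.0
    elispot_dispersion: float = 20.0
    elispot_effect_corr: float = 0.2
    elispot_mag_mean: float = 20.0
    elispot_mag_sd: float = 30.0
    cells_per_well: int = 200_000
    n_replicates: int = 3
    homozygous_class_I: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.tv_fraction <= 1.0:
            raise ConfigError(f"tv_fraction out of [0,1]: {self.tv_fraction}")
        if not -1.0 <= self.elispot_effect_corr <= 1.0:
            raise ConfigError(f"effect correlation out of [-1,1]: {self.elispot_effect_corr}")
        for name in (
            "n_vaccine_lines",
            "n_vaccine_variants",
            "n_tumor_private",
            "n_germline_background",
            "n_replicates",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.elispot_ctrl_mean < 0:
            raise ConfigError("elispot_ctrl_mean must be >= 0")


def _make_variant(
    rng: np.random.Generator,
    index: int,
    sample_id: str,
    lines: Sequence[str],
) -> ProteinVariant:
    chrom = f"chr{rng.integers(1, 23)}"
    # unique position per index guarantees distinct genomic keys
    pos = int(index * 97 + rng.integers(1, 97))
    ref, alt = rng.choice(list(_BASES), size=2, replace=False)
    kind = rng.choice(
        ["missense", "missense", "missense", "missense", "inframe_deletion", "frameshift"]
    )
    protein_pos = int(rng.integers(12, 400))
    if kind == "missense":
        ref_aa, alt_aa = rng.choice(list(_RESIDUES), size=2, replace=False)
    elif kind == "inframe_deletion":
        ref_aa = "".join(rng.choice(list(_RESIDUES), size=3))
        alt_aa = ""
    else:
        ref_aa, alt_aa = rng.choice(list(_RESIDUES), size=2, replace=False)
    vafs = {line: float(np.round(rng.beta(2.0, 4.0), 4)) for line in lines}
    return ProteinVariant(
        sample_id=sample_id,
        chrom=chrom,
        pos=pos,
        ref=str(ref),
        alt=str(alt),
        gene=f"GENE{index:05d}",
        transcript=f"TX{index:05d}",
        consequence_kind=str(kind),
        protein_pos=protein_pos,
        ref_aa=str(ref_aa),
        alt_aa=str(alt_aa),
        filter_pass_count=int(rng.integers(1, len(lines) + 1)) if lines else 1,
        vaf_by_line=vafs,
        rna_coverage=int(rng.negative_binomial(10, 10 / 60)),
        rna_vaf=float(np.round(rng.beta(5.0, 5.0), 4)),
    )


def simulate_variant_sets(
    cfg: SimulationConfig,
) -> Tuple[List[ProteinVariant], List[ProteinVariant], List[ProteinVariant]]:
    """Vaccine, germline, and tumor variant lists with exact overlap counts.

    After removing germline keys, the vaccine set has exactly
    ``n_vaccine_variants`` keys of which ``round(tv_fraction * n)`` are
    shared with the tumor; the tumor has ``n_tumor_private`` private keys.
    A germline background present in all three lists exercises the self
    subtraction.
    """
    n_tv = round(cfg.tv_fraction * cfg.n_vaccine_variants)
    if n_tv > cfg.n_vaccine_variants:
        raise ConfigError("shared fraction exceeds the vaccine variant count")
    n_v_only = cfg.n_vaccine_variants - n_tv
    rng = np.random.default_rng(cfg.seed)
    lines = [f"line{i+1}" for i in range(cfg.n_vaccine_lines)]

    counter = 0

    def draw(n: int, sample_id: str, with_lines: bool) -> List[ProteinVariant]:
        nonlocal counter
        out = []
        for _ in range(n):
            counter += 1
            out.append(_make_variant(rng, counter, sample_id, lines if with_lines else []))
        return out

    germ_bg = draw(cfg.n_germline_background, "germline", False)
    v_only = draw(n_v_only, "vaccine", True)
    tv = draw(n_tv, "vaccine", True)
    t_private = draw(cfg.n_tumor_private, "tumor", False)

    def as_sample(variants: Sequence[ProteinVariant], sample_id: str) -> List[ProteinVariant]:
        return [replace(v, sample_id=sample_id) for v in variants]

    vaccine = v_only + tv + as_sample(germ_bg, "vaccine")
    germline = germ_bg
    tumor = as_sample(tv, "tumor") + t_private + as_sample(germ_bg, "tumor")
    return vaccine, germline, tumor


def simulate_expression(cfg: SimulationConfig, genes: Sequence[str]) -> ExpressionProfile:
    """Log-normal per-line TPM draws, combined and rescaled to one million."""
    if not genes:
        raise ConfigError("gene list must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    per_line: Dict[Tuple[str, str], float] = {}
    for i in range(cfg.n_vaccine_lines):
        line = f"line{i+1}"
        draws = rng.lognormal(cfg.tpm_log_mean, cfg.tpm_log_sd, size=len(genes))
        for gene, tpm in zip(genes, draws):
            per_line[(line, gene)] = float(tpm)
    return ExpressionProfile.from_per_line(per_line)


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size, dtype=int)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_elispot(
    cfg: SimulationConfig,
    peptides_with_tpm: Sequence[Tuple[str, float]],
    immunogenic: Optional[Sequence[bool]] = None,
    patient: str = "sim",
    timepoint: str = "Post3",
) -> List[ELISpotAssay]:
    """Replicate ELISpot counts with a planted expression-magnitude link.

    Control wells are overdispersed negative-binomial counts around the
    configured background. Immunogenic peptides (all, by default) receive a
    latent response magnitude whose correlation with standardized log1p(TPM)
    equals ``elispot_effect_corr``; the latent magnitude (clipped at zero)
    raises the stimulated-well mean accordingly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    n = len(peptides_with_tpm)
    if immunogenic is None:
        immunogenic = [True] * n
    tpms = np.array([tpm for _, tpm in peptides_with_tpm], dtype=float)
    log_tpm = np.log1p(tpms)
    sd = log_tpm.std()
    z = (log_tpm - log_tpm.mean()) / sd if sd > 0 else np.zeros(n)
    rho = cfg.elispot_effect_corr
    latent = rho * z + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(n)
    magnitudes = np.clip(cfg.elispot_mag_mean + cfg.elispot_mag_sd * latent, 0.0, None)

    assays: List[ELISpotAssay] = []
    per_well = cfg.cells_per_well / 100_000
    for i, (peptide, _) in enumerate(peptides_with_tpm):
        ctrl = _nb_draw(rng, cfg.elispot_ctrl_mean, cfg.elispot_dispersion, cfg.n_replicates)
        stim_mean = cfg.elispot_ctrl_mean
        if immunogenic[i]:
            stim_mean = cfg.elispot_ctrl_mean + magnitudes[i] * per_well
        stim = _nb_draw(rng, stim_mean, cfg.elispot_dispersion, cfg.n_replicates)
        assays.append(
            ELISpotAssay(
                patient=patient,
                timepoint=timepoint,
                peptide=peptide,
                stim_counts=tuple(int(c) for c in stim),
                ctrl_counts=tuple(int(c) for c in ctrl),
                cells_per_well=cfg.cells_per_well,
            )
        )
    return assays


def simulate_hla_alleles(
    cfg: SimulationConfig,
    n_donor_per_locus: int = 2,
    seq_length: int = 362,
) -> Tuple[List[HLAAllele], PatientHaplotype, List[HLAAllele]]:
    """Synthetic donor and patient class I alleles (not real IMGT sequences).

    Alleles at one locus share a common backbone with sparse substitutions,
    mimicking the point-polymorphism structure of HLA; the patient is
    homozygous at every class I locus when the config says so.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    donors: List[HLAAllele] = []
    patient_alleles: List[HLAAllele] = []
    patient_slots: List[str] = []
    for locus in ("A", "B", "C"):
        backbone = "".join(rng.choice(list(_RESIDUES), size=seq_length))
        variants_needed = n_donor_per_locus + 2

        def mutate(seq: str, n_subs: int) -> str:
            chars = list(seq)
            sites = rng.choice(seq_length, size=n_subs, replace=False)
            for site in sites:
                current = chars[site]
                options = [r for r in _RESIDUES if r != current]
                chars[site] = str(rng.choice(options))
            return "".join(chars)

        allele_seqs = [mutate(backbone, int(rng.integers(5, 15))) for _ in range(variants_needed)]
        names = [f"HLA-{locus}*{i+1:02d}:01" for i in range(variants_needed)]
        alleles = [
            HLAAllele(name=n, locus=locus, hla_class="I", protein_seq=s)
            for n, s in zip(names, allele_seqs)
        ]
        donors.extend(alleles[:n_donor_per_locus])
        if cfg.homozygous_class_I:
            patient_pair = [alleles[n_donor_per_locus]] * 2
        else:
            patient_pair = alleles[n_donor_per_locus : n_donor_per_locus + 2]
        patient_alleles.extend(patient_pair)
        patient_slots.extend(a.name for a in patient_pair)
    haplotype = PatientHaplotype(class_I=patient_slots)

    # class II (DRB1) pair for the patient, used by the class II exclusion
    backbone_ii = "".join(rng.choice(list(_RESIDUES), size=266))
    class_ii_names = ["HLA-DRB1*01:01", "HLA-DRB1*04:01"]
    for name in class_ii_names:
        chars = list(backbone_ii)
        for site in rng.choice(266, size=8, replace=False):
            options = [r for r in _RESIDUES if r != chars[site]]
            chars[site] = str(rng.choice(options))
        patient_alleles.append(
            HLAAllele(name=name, locus="DRB1", hla_class="II", protein_seq="".join(chars))
        )
    haplotype = PatientHaplotype(class_I=patient_slots, class_II=class_ii_names)
    return donors, haplotype, patient_alleles


def simulate_proteins(
    variants: Sequence[ProteinVariant],
    cfg: SimulationConfig,
    flank: int = 30,
) -> Dict[str, str]:
    """Random germline proteins consistent with each variant's annotation."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))
    proteins: Dict[str, str] = {}
    for v in variants:
        if v.transcript in proteins:
            continue
        length = v.protein_pos + len(v.ref_aa) + flank
        seq = list(rng.choice(list(_RESIDUES), size=length))
        if v.ref_aa:
            for offset, aa in enumerate(v.ref_aa):
                seq[v.protein_pos - 1 + offset] = aa
        proteins[v.transcript] = "".join(seq)
    return proteins


def write_fixture_bundle(cfg: SimulationConfig, outdir: str | Path) -> Dict[str, Path]:
    """Write the full synthetic input bundle for a pipeline run."""
    from . import io_formats

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vaccine, germline, tumor = simulate_variant_sets(cfg)
    genes = sorted({v.gene for v in vaccine})
    expression = simulate_expression(cfg, genes)
    donors, haplotype, patient_alleles = simulate_hla_alleles(cfg)
    proteins = simulate_proteins(vaccine, cfg)

    # an example assay table: one mutant 9-mer per early vaccine variant,
    # with the planted expression-response structure
    tested = []
    for v in vaccine[: min(50, len(vaccine))]:
        protein = proteins.get(v.transcript)
        if protein is None or v.protein_pos + 8 > len(protein):
            continue
        peptide = protein[v.protein_pos - 1 : v.protein_pos + 8]
        if len(peptide) == 9 and not any(p == peptide for p, _ in tested):
            tested.append((peptide, expression.tpm(v.gene)))
    assays = simulate_elispot(cfg, tested) if tested else []

    paths = {
        "vaccine_variants": outdir / "vaccine_variants.tsv",
        "germline_variants": outdir / "germline_variants.tsv",
        "tumor_variants": outdir / "tumor_variants.tsv",
        "expression": outdir / "expression.tsv",
        "donor_hla": outdir / "donor_hla.fasta",
        "patient_hla": outdir / "patient_hla.fasta",
        "proteins": outdir / "proteins.fasta",
        "elispot": outdir / "elispot.tsv",
    }
    io_formats.write_variant_tsv(vaccine, paths["vaccine_variants"])
    io_formats.write_variant_tsv(germline, paths["germline_variants"])
    io_formats.write_variant_tsv(tumor, paths["tumor_variants"])
    io_formats.write_expression_tsv(expression, paths["expression"])
    io_formats.write_hla_fasta(donors, paths["donor_hla"])
    io_formats.write_hla_fasta(patient_alleles, paths["patient_hla"])
    io_formats.write_protein_fasta(proteins, paths["proteins"])
    io_formats.write_elispot_table(assays, paths["elispot"])
    return paths
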