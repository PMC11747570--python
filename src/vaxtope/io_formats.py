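"""Readers and writers for every external table and sequence format.

All tabular formats are tab-delimited UTF-8 with a header row. Variants can
arrive either as a minimal VCF 4.2 (CHROM/POS/REF/ALT plus a CSQ-style
annotation and per-cell-line FORMAT fields) or as an equivalent protein-level
TSV; both dialects normalize to the same :class:`~vaxtope.models.ProteinVariant`
records.

Variant TSV columns::

    sample_id  chrom  pos  ref  alt  gene  transcript  consequence
    protein_pos  ref_aa  alt_aa  filter_pass_count  vafs  rna_coverage  rna_vaf

``vafs`` packs per-cell-line variant allele frequencies as
``line1=0.40;line2=0.10``. ``consequence`` accepts either the pipeline's
short kinds or Ensembl-style terms (``missense_variant`` etc.).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    ELISpotAssay,
    ExpressionProfile,
    HLAAllele,
    PredictionRecord,
    ProteinVariant,
    ValidationError,
    parse_hla_name,
)


class FormatError(ValueError):
    """An input file does not conform to the documented dialect."""


#: Ensembl-style consequence terms mapped to the pipeline's consequence kinds.
CONSEQUENCE_MAP = {
    "missense": "missense",
    "missense_variant": "missense",
    "inframe_insertion": "inframe_insertion",
    "conservative_inframe_insertion": "inframe_insertion",
    "disruptive_inframe_insertion": "inframe_insertion",
    "inframe_deletion": "inframe_deletion",
    "conservative_inframe_deletion": "inframe_deletion",
    "disruptive_inframe_deletion": "inframe_deletion",
    "frameshift": "frameshift",
    "frameshift_variant": "frameshift",
}

#: Valid annotations that are nevertheless not coding non-synonymous changes;
#: records carrying only these are excluded without a warning.
NON_CANDIDATE_CONSEQUENCES = {
    "synonymous_variant",
    "stop_retained_variant",
    "start_retained_variant",
    "intron_variant",
    "intergenic_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "non_coding_transcript_variant",
    "non_coding_transcript_exon_variant",
    "splice_region_variant",
    "stop_gained",
    "stop_lost",
    "start_lost",
}

VARIANT_TSV_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "transcript",
    "consequence",
    "protein_pos",
    "ref_aa",
    "alt_aa",
    "filter_pass_count",
    "vafs",
    "rna_coverage",
    "rna_vaf",
]

ELISPOT_TSV_COLUMNS = ["patient", "timepoint", "peptide", "stim_counts", "ctrl_counts", "cells_per_well"]

PREDICTION_TSV_COLUMNS = ["peptide", "allele", "rank_el", "rank_stab", "icore"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s) {missing}")


def _parse_vafs(cell: str) -> Dict[str, float]:
    vafs: Dict[str, float] = {}
    cell = cell.strip()
    if not cell:
        return vafs
    for item in cell.split(";"):
        line, _, value = item.partition("=")
        if not _:
            raise FormatError(f"cannot parse VAF entry {item!r} (expected line=value)")
        vafs[line.strip()] = float(value)
    return vafs


def _format_vafs(vafs: Dict[str, float]) -> str:
    return ";".join(f"{line}={vaf:.6g}" for line, vaf in sorted(vafs.items()))


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

def read_variant_table(path: str | Path, dialect: str = "tsv") -> List[ProteinVariant]:
    """Read coding non-synonymous variants from a TSV or minimal VCF.

    Records with valid but non-candidate consequences (synonymous, non-coding)
    are excluded silently; an unknown consequence string triggers a
    record-level warning and the record is skipped.
    """
    if dialect == "tsv":
        return _read_variant_tsv(Path(path))
    if dialect == "vcf":
        return _read_variant_vcf(Path(path))
    raise ValueError(f"unknown variant dialect {dialect!r}")


def _normalize_consequence(raw: str, where: str) -> Optional[str]:
    term = raw.strip()
    if term in CONSEQUENCE_MAP:
        return CONSEQUENCE_MAP[term]
    if term in NON_CANDIDATE_CONSEQUENCES:
        return None
    warnings.warn(f"{where}: unknown consequence {term!r}; record skipped")
    return None


def _read_variant_tsv(path: Path) -> List[ProteinVariant]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, VARIANT_TSV_COLUMNS, f"variant TSV {path}")
    variants: List[ProteinVariant] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        kind = _normalize_consequence(row.consequence, f"{path}:{i}")
        if kind is None:
            continue
        variants.append(
            ProteinVariant(
                sample_id=row.sample_id,
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref.upper(),
                alt=row.alt.upper(),
                gene=row.gene,
                transcript=row.transcript,
                consequence_kind=kind,
                protein_pos=int(row.protein_pos),
                ref_aa=row.ref_aa,
                alt_aa=row.alt_aa,
                filter_pass_count=int(row.filter_pass_count),
                vaf_by_line=_parse_vafs(row.vafs),
                rna_coverage=int(row.rna_coverage),
                rna_vaf=float(row.rna_vaf),
            )
        )
    return variants


def write_variant_tsv(variants: Iterable[ProteinVariant], path: str | Path) -> None:
    rows = []
    for v in variants:
        rows.append(
            {
                "sample_id": v.sample_id,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "transcript": v.transcript,
                "consequence": v.consequence_kind,
                "protein_pos": v.protein_pos,
                "ref_aa": v.ref_aa,
                "alt_aa": v.alt_aa,
                "filter_pass_count": v.filter_pass_count,
                "vafs": _format_vafs(dict(v.vaf_by_line)),
                "rna_coverage": v.rna_coverage,
                "rna_vaf": f"{v.rna_vaf:.6g}",
            }
        )
    pd.DataFrame(rows, columns=VARIANT_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


_CSQ_FIELDS = ["Allele", "Consequence", "SYMBOL", "Feature", "Protein_position", "Amino_acids"]
_CSQ_FORMAT = "|".join(_CSQ_FIELDS)


def _read_variant_vcf(path: Path) -> List[ProteinVariant]:
    import pysam

    variants: List[ProteinVariant] = []
    with pysam.VariantFile(str(path)) as vf:
        csq_header = vf.header.info.get("CSQ")
        if csq_header is None:
            raise FormatError(f"variant VCF {path}: missing required column(s) ['INFO/CSQ']")
        lines = list(vf.header.samples)
        for rec in vf:
            sample_id = rec.info.get("SAMPLE", "")
            csq_entries = rec.info.get("CSQ", ())
            if isinstance(csq_entries, str):
                csq_entries = (csq_entries,)
            for alt_idx, alt in enumerate(rec.alts or ()):
                vafs: Dict[str, float] = {}
                pass_count = 0
                for line in lines:
                    fmt = rec.samples[line]
                    af = fmt.get("AF")
                    if af is not None:
                        value = af[alt_idx] if isinstance(af, tuple) else af
                        if value is not None:
                            # VCF FORMAT floats are 32-bit; normalize to the
                            # 6-significant-digit precision of the TSV dialect
                            vafs[line] = float(f"{float(value):.6g}")
                    if fmt.get("FT") == "PASS":
                        pass_count += 1
                for entry in csq_entries:
                    fields = dict(zip(_CSQ_FIELDS, entry.split("|")))
                    if fields.get("Allele") != alt:
                        continue
                    kind = _normalize_consequence(
                        fields.get("Consequence", ""), f"{path}:{rec.chrom}:{rec.pos}"
                    )
                    if kind is None:
                        continue
                    aa = fields.get("Amino_acids", "")
                    ref_aa, _, alt_aa = aa.partition("/")
                    variants.append(
                        ProteinVariant(
                            sample_id=str(sample_id),
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref.upper(),
                            alt=alt.upper(),
                            gene=fields.get("SYMBOL", ""),
                            transcript=fields.get("Feature", ""),
                            consequence_kind=kind,
                            protein_pos=int(fields["Protein_position"]),
                            ref_aa=ref_aa,
                            alt_aa=alt_aa,
                            filter_pass_count=pass_count,
                            vaf_by_line=vafs,
                            rna_coverage=int(rec.info.get("RNAC", 0)),
                            rna_vaf=float(f"{float(rec.info.get('RNAVAF', 0.0)):.6g}"),
                        )
                    )
    return variants


def write_variant_vcf(variants: Iterable[ProteinVariant], path: str | Path) -> None:
    """Write variants as a minimal VCF 4.2 with a CSQ-style annotation."""
    import pysam

    variants = list(variants)
    lines = sorted({line for v in variants for line in v.vaf_by_line})
    header = pysam.VariantHeader()
    for chrom in sorted({v.chrom for v in variants}):
        header.contigs.add(chrom)
    header.info.add("CSQ", ".", "String", f"Consequence annotations. Format: {_CSQ_FORMAT}")
    header.info.add("SAMPLE", 1, "String", "Originating sample")
    header.info.add("RNAC", 1, "Integer", "RNA read coverage at the mutated position")
    header.info.add("RNAVAF", 1, "Float", "RNA variant allele frequency")
    header.formats.add("AF", "A", "Float", "Variant allele frequency")
    header.formats.add("FT", 1, "String", "Per-cell-line caller filter")
    header.filters.add("FAIL", None, None, "No cell line passed caller filters")
    for line in lines:
        header.add_sample(line)

    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for v in variants:
            rec = vf.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt), filter="PASS" if v.filter_pass_count else "FAIL"
            )
            aa = f"{v.ref_aa}/{v.alt_aa}"
            rec.info["CSQ"] = (
                f"{v.alt}|{v.consequence_kind}|{v.gene}|{v.transcript}|{v.protein_pos}|{aa}",
            )
            rec.info["SAMPLE"] = v.sample_id
            rec.info["RNAC"] = v.rna_coverage
            rec.info["RNAVAF"] = v.rna_vaf
            # FT carries PASS for the first filter_pass_count lines with a VAF;
            # per-line caller verdicts are not retained beyond the count.
            n_pass = 0
            for line in lines:
                if line in v.vaf_by_line:
                    rec.samples[line]["AF"] = (v.vaf_by_line[line],)
                    if n_pass < v.filter_pass_count:
                        rec.samples[line]["FT"] = "PASS"
                        n_pass += 1
            vf.write(rec)


# ---------------------------------------------------------------------------
# Protein and HLA FASTA
# ---------------------------------------------------------------------------

def read_protein_fasta(path: str | Path) -> Dict[str, str]:
    """Read a transcript-keyed protein FASTA (first header token = transcript)."""
    proteins: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        proteins[rec.id] = str(rec.seq).upper()
    return proteins


def write_protein_fasta(proteins: Dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in proteins.items()]
    SeqIO.write(records, str(path), "fasta")


def read_hla_fasta(path: str | Path) -> List[HLAAllele]:
    """Read HLA allele protein sequences; headers must use WHO nomenclature."""
    alleles: Dict[str, HLAAllele] = {}
    out: List[HLAAllele] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        try:
            locus, hla_class = parse_hla_name(name)
        except ValidationError as exc:
            raise FormatError(f"HLA FASTA {path}: {exc}") from exc
        allele = HLAAllele(
            name=name, locus=locus, hla_class=hla_class, protein_seq=str(rec.seq).upper()
        )
        previous = alleles.get(name)
        if previous is not None:
            if previous.protein_seq != allele.protein_seq:
                raise FormatError(
                    f"HLA FASTA {path}: duplicate allele {name} with differing sequences"
                )
            continue
        alleles[name] = allele
        out.append(allele)
    return out


def write_hla_fasta(alleles: Iterable[HLAAllele], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(a.protein_seq), id=a.name, description="") for a in alleles
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path) -> ExpressionProfile:
    """Read a gene x cell-line TPM table (column ``gene`` + one per line)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["gene"], f"expression TSV {path}")
    lines = [c for c in df.columns if c != "gene"]
    if not lines:
        raise FormatError(f"expression TSV {path}: missing required column(s) ['<cell line>']")
    per_line = {
        (line, row["gene"]): float(row[line]) for _, row in df.iterrows() for line in lines
    }
    return ExpressionProfile.from_per_line(per_line)


def write_expression_tsv(profile: ExpressionProfile, path: str | Path) -> None:
    lines = sorted({line for line, _ in profile.per_line_tpm})
    genes = sorted({gene for _, gene in profile.per_line_tpm})
    rows = [
        {"gene": g, **{line: profile.per_line_tpm.get((line, g), 0.0) for line in lines}}
        for g in genes
    ]
    pd.DataFrame(rows, columns=["gene", *lines]).to_csv(path, sep="\t", index=False)


def read_melanocyte_tsv(path: str | Path) -> Dict[str, float]:
    """Read a two-column gene -> TPM table (healthy-melanocyte reference)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["gene", "tpm"], f"melanocyte TSV {path}")
    return {row["gene"]: float(row["tpm"]) for _, row in df.iterrows()}


# ---------------------------------------------------------------------------
# Prediction tables
# ---------------------------------------------------------------------------

def read_prediction_tsv(path: str | Path) -> List[PredictionRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, PREDICTION_TSV_COLUMNS, f"prediction TSV {path}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            PredictionRecord(
                peptide=row.peptide,
                allele=row.allele,
                rank_el=float(row.rank_el),
                rank_stab=float(row.rank_stab) if row.rank_stab else None,
                icore=row.icore or None,
            )
        )
    return records


def write_prediction_tsv(records: Iterable[PredictionRecord], path: str | Path) -> None:
    rows = [
        {
            "peptide": r.peptide,
            "allele": r.allele,
            "rank_el": f"{r.rank_el:.17g}",
            "rank_stab": "" if r.rank_stab is None else f"{r.rank_stab:.17g}",
            "icore": r.icore or "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=PREDICTION_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ELISpot tables
# ---------------------------------------------------------------------------

def _parse_counts(cell: str, what: str) -> Tuple[int, ...]:
    cell = str(cell).strip()
    if not cell:
        raise ValidationError(f"{what}: empty replicate count list")
    counts = tuple(int(x) for x in cell.split(";"))
    if any(c < 0 for c in counts):
        raise ValidationError(f"{what}: negative spot count in {cell!r}")
    return counts


def read_elispot_table(path: str | Path) -> List[ELISpotAssay]:
    """Read replicate ELISpot counts, one row per (patient, timepoint, peptide)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ELISPOT_TSV_COLUMNS, f"ELISpot TSV {path}")
    seen: set[Tuple[str, str, str]] = set()
    assays: List[ELISpotAssay] = []
    for row in df.itertuples(index=False):
        key = (row.patient, row.timepoint, row.peptide)
        if key in seen:
            raise ValidationError(f"ELISpot TSV {path}: duplicate assay key {key}")
        seen.add(key)
        where = f"ELISpot TSV {path} {key}"
        assays.append(
            ELISpotAssay(
                patient=row.patient,
                timepoint=row.timepoint,
                peptide=row.peptide,
                stim_counts=_parse_counts(row.stim_counts, where),
                ctrl_counts=_parse_counts(row.ctrl_counts, where),
                cells_per_well=int(row.cells_per_well),
            )
        )
    return assays


def write_elispot_table(assays: Iterable[ELISpotAssay], path: str | Path) -> None:
    rows = [
        {
            "patient": a.patient,
            "timepoint": a.timepoint,
            "peptide": a.peptide,
            "stim_counts": ";".join(str(c) for c in a.stim_counts),
            "ctrl_counts": ";".join(str(c) for c in a.ctrl_counts),
            "cells_per_well": a.cells_per_well,
        }
        for a in assays
    ]
    pd.DataFrame(rows, columns=ELISPOT_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
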