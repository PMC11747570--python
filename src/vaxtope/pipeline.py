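"""End-to-end orchestration of the antigen-discovery pipeline.

A run takes a structured config (YAML), validates it up front, executes the
stages — simulate, categorize, extract peptides, allogeneic HLA, prioritize,
features, ELISpot, evaluate — into an append-only run directory, and writes
a manifest with the config snapshot, seed, and checksums of every input and
output, so identical configs reproduce byte-identical runs.

All randomness (simulator, mock predictor, resampling) flows from the one
root seed recorded in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Dict, List, Optional, Tuple

import pandas as pd
import yaml

from . import io_formats
from .allo_hla import derive_allo_candidates
from .categorize import (
    CategoryTable,
    categorize_variants,
    compute_tmb,
    prefilter_variants,
    summarize_categories,
)
from .elispot_stats import PositivityConfig, call_positivity
from .evaluate import compare_categories, feature_screen
from .features import build_feature_vector
from .models import ProteinVariant, ValidationError
from .peptides import extract_mutant_peptides
from .predictors import MockPredictor, PredictorInterface
from .prioritize import CascadeThresholds, PeptideCandidate, apply_cascade, curate_selection
from .synthetic_data import SimulationConfig, simulate_elispot, write_fixture_bundle

logger = logging.getLogger("vaxtope")

#: Demo-scale defaults: thresholds stay config-exposed; the relaxed
#: presentation cut-offs make a mock-scored synthetic run informative
#: (the mock ranks are uniform, so the study's strict cut-offs would leave
#: an empty panel at demo scale).
DEFAULT_CONFIG: Dict[str, Any] = {
    "seed": 0,
    "simulate": {
        "n_vaccine_variants": 150,
        "tv_fraction": 0.05,
        "n_tumor_private": 30,
        "n_germline_background": 50,
    },
    "thresholds": {
        "max_mut_rank_el": 5.0,
        "min_wt_rank_el": 2.0,
        "max_rank_stab": 10.0,
    },
    # per-peptide reading: with triplicates the DFR granularity (p >= 1/20)
    # cannot clear a family-wise correction over a whole screening batch
    "positivity": {"adjust": "none"},
    "curate_k": 12,
}


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def load_config(path: str | Path) -> Dict[str, Any]:
    with open(path) as fh:
        loaded = yaml.safe_load(fh) or {}
    return validate_config(loaded)


def validate_config(config: Dict[str, Any]) -> Dict[str, Any]:
    """Merge with defaults and validate before any stage runs."""
    known = set(DEFAULT_CONFIG)
    unknown = set(config) - known
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    merged = {k: v for k, v in DEFAULT_CONFIG.items()}
    for key, value in config.items():
        if isinstance(DEFAULT_CONFIG[key], dict):
            if not isinstance(value, dict):
                raise ValidationError(f"config section {key!r} must be a mapping")
            merged[key] = {**DEFAULT_CONFIG[key], **value}
        else:
            merged[key] = value
    for section, cls in (
        ("simulate", SimulationConfig),
        ("thresholds", CascadeThresholds),
        ("positivity", PositivityConfig),
    ):
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(merged[section]) - valid
        if bad:
            raise ValidationError(f"unknown key(s) in config section {section!r}: {sorted(bad)}")
    if not isinstance(merged["seed"], int):
        raise ValidationError("seed must be an integer")
    return merged


def _score_candidates(
    pairs_by_variant: Dict[Tuple, List],
    variants_by_key: Dict[Tuple, ProteinVariant],
    categories: CategoryTable,
    expression,
    predictor: PredictorInterface,
    class_i_slots: List[str],
    class_ii_alleles: List[str],
    locus_of: Dict[str, str],
) -> List[PeptideCandidate]:
    candidates = []
    for key, pairs in pairs_by_variant.items():
        variant = variants_by_key[key]
        category = categories.assignments.get(key)
        if category is None:
            continue
        for pair in pairs:
            class_ii = [predictor.score(pair.mutant, a).rank_el for a in class_ii_alleles]
            for allele in sorted(set(class_i_slots)):
                rec = predictor.score(pair.mutant, allele)
                wt_rank = (
                    predictor.score(pair.wildtype, allele).rank_el
                    if pair.wildtype is not None
                    else None
                )
                candidates.append(
                    PeptideCandidate(
                        pair=pair,
                        allele=allele,
                        locus=locus_of[allele],
                        category=category,
                        mut_rank_el=rec.rank_el,
                        wt_rank_el=wt_rank,
                        rank_stab=rec.rank_stab,
                        classII_min_rank=min(class_ii) if class_ii else float("inf"),
                        tpm=expression.tpm(variant.gene),
                        rna_coverage=variant.rna_coverage,
                        max_vaf=variant.max_vaf,
                        gene=variant.gene,
                    )
                )
    return candidates


def run_pipeline(config: Dict[str, Any], out_dir: str | Path) -> Path:
    """Run every stage on a seeded synthetic fixture; returns the run dir."""
    config = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config["seed"]
    logger.info("run starting: seed=%d out=%s", seed, out)

    # --- simulate ---------------------------------------------------------
    sim_cfg = SimulationConfig(seed=seed, **config["simulate"])
    input_dir = out / "inputs"
    input_paths = write_fixture_bundle(sim_cfg, input_dir)

    # --- categorize -------------------------------------------------------
    vaccine = io_formats.read_variant_table(input_paths["vaccine_variants"])
    germline = io_formats.read_variant_table(input_paths["germline_variants"])
    tumor = io_formats.read_variant_table(input_paths["tumor_variants"])
    expression = io_formats.read_expression_tsv(input_paths["expression"])

    filtered_vaccine = prefilter_variants(vaccine, expression)
    categories = categorize_variants(filtered_vaccine, germline, tumor)
    counts = categories.counts
    summary = summarize_categories({"sim": categories})
    germ_keys = {v.genomic_key for v in germline}
    tumor_somatic_keys = {v.genomic_key for v in tumor} - germ_keys
    tumor_somatic = [v for v in tumor if v.genomic_key in tumor_somatic_keys]
    tmb = compute_tmb(tumor_somatic)
    category_rows = [
        {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "category": c}
        for k, c in sorted(categories.assignments.items())
    ]
    pd.DataFrame(category_rows).to_csv(out / "categories.tsv", sep="\t", index=False)
    with open(out / "category_summary.json", "w") as fh:
        json.dump(
            {
                "counts": counts,
                "vaccine_specific": summary.per_patient_vaccine_specific["sim"],
                "shared_fraction": summary.per_patient_shared_fraction["sim"],
                "tumor_tmb_per_mb": tmb,
            },
            fh,
            indent=2,
        )

    # --- extract peptides -------------------------------------------------
    proteins = io_formats.read_protein_fasta(input_paths["proteins"])
    vaccine_by_key: Dict[Tuple, ProteinVariant] = {}
    for v in filtered_vaccine:
        vaccine_by_key.setdefault(v.genomic_key, v)
    pairs_by_variant: Dict[Tuple, List] = {}
    for key, variant in vaccine_by_key.items():
        if categories.assignments.get(key) not in ("V", "TV"):
            continue
        if variant.consequence_kind == "frameshift":
            continue  # the synthetic bundle does not carry mutant tails
        protein = proteins.get(variant.transcript)
        if protein is None:
            continue
        pairs = extract_mutant_peptides(variant, protein)
        if pairs:
            pairs_by_variant[key] = pairs
    peptide_rows = [
        {
            "mutant": p.mutant,
            "wildtype": p.wildtype or "",
            "chrom": key[0],
            "pos": key[1],
            "transcript": p.transcript,
            "mut_positions": ";".join(str(i) for i in sorted(p.mut_positions)),
        }
        for key, pairs in sorted(pairs_by_variant.items())
        for p in pairs
    ]
    pd.DataFrame(peptide_rows).to_csv(out / "peptides.tsv", sep="\t", index=False)

    # --- allogeneic HLA ---------------------------------------------------
    donor_alleles = io_formats.read_hla_fasta(input_paths["donor_hla"])
    patient_alleles = io_formats.read_hla_fasta(input_paths["patient_hla"])
    predictor = MockPredictor(seed=seed)
    allo = derive_allo_candidates(donor_alleles, patient_alleles)
    allo_rows = []
    for donor_name, windows in allo.items():
        for pep in windows:
            rank = predictor.score(pep, donor_name).rank_el
            allo_rows.append(
                {
                    "donor_allele": donor_name,
                    "peptide": pep,
                    "rank_el": rank,
                    "strong_binder": rank < 0.5,
                }
            )
    pd.DataFrame(allo_rows).to_csv(out / "allo_hla_candidates.tsv", sep="\t", index=False)

    # --- prioritize -------------------------------------------------------
    class_i_slots = sorted({a.name for a in patient_alleles if a.hla_class == "I"})
    class_ii = sorted({a.name for a in patient_alleles if a.hla_class == "II"})
    locus_of = {a.name: a.locus for a in patient_alleles}
    candidates = _score_candidates(
        pairs_by_variant,
        vaccine_by_key,
        categories,
        expression,
        predictor,
        class_i_slots,
        class_ii,
        locus_of,
    )
    thresholds = CascadeThresholds(**config["thresholds"])
    survivors, trace = apply_cascade(candidates, thresholds)
    pd.DataFrame(trace).to_csv(out / "cascade_trace.tsv", sep="\t", index=False)
    k = min(config["curate_k"], len({c.pair.genomic_key for c in survivors}))
    panel = curate_selection(survivors, k=k) if k else []
    pd.DataFrame(
        [
            {
                "peptide": c.peptide,
                "allele": c.allele,
                "category": c.category,
                "mut_rank_el": c.mut_rank_el,
                "rank_stab": c.rank_stab,
                "tpm": c.tpm,
            }
            for c in panel
        ]
    ).to_csv(out / "panel.tsv", sep="\t", index=False)

    # --- features ---------------------------------------------------------
    feature_rows = []
    for cand in survivors:
        variant = vaccine_by_key[cand.pair.genomic_key]
        records = [predictor.score(cand.peptide, a) for a in sorted(set(class_i_slots))]
        slot_ranks = [predictor.score(cand.peptide, a).rank_el for a in class_i_slots]
        vector = build_feature_vector(
            mutant=cand.peptide,
            wildtype=cand.pair.wildtype,
            mut_rank_el=cand.mut_rank_el,
            wt_rank_el=cand.wt_rank_el,
            rank_stab=cand.rank_stab,
            class_i_ranks=slot_ranks,
            records_per_allele=records,
            tpm=cand.tpm,
            rna_vaf=variant.rna_vaf,
            icore=predictor.score(cand.peptide, cand.allele).icore,
        )
        feature_rows.append(
            {"peptide": cand.peptide, "allele": cand.allele, "category": cand.category, **vector}
        )
    features_df = pd.DataFrame(feature_rows)
    features_df.to_csv(out / "features.tsv", sep="\t", index=False)

    # --- ELISpot ----------------------------------------------------------
    tested = []
    seen_peptides = set()
    for cand in survivors:
        if cand.peptide not in seen_peptides:
            seen_peptides.add(cand.peptide)
            tested.append((cand.peptide, cand.tpm, cand.category))
    assays = simulate_elispot(sim_cfg, [(p, tpm) for p, tpm, _ in tested])
    io_formats.write_elispot_table(assays, out / "elispot.tsv")
    cat_map = {("sim", p): c for p, _, c in tested}
    records = call_positivity(assays, PositivityConfig(**config["positivity"]), categories=cat_map)
    records_df = pd.DataFrame(
        [
            {
                "patient": r.patient,
                "timepoint": r.timepoint,
                "peptide": r.peptide,
                "category": r.category,
                "magnitude": r.magnitude,
                "raw_magnitude": r.raw_magnitude,
                "p_value": r.p_value,
                "positive": r.positive,
                "method": r.method,
            }
            for r in records
        ]
    )
    records_df.to_csv(out / "immunogenicity.tsv", sep="\t", index=False)

    # --- evaluate ---------------------------------------------------------
    evaluation: Dict[str, Any] = {}
    if not features_df.empty:
        call_by_peptide = {r.peptide: (r.positive, r.magnitude) for r in records}
        merged = features_df.drop_duplicates(subset="peptide").copy()
        merged["positive"] = [call_by_peptide[p][0] for p in merged["peptide"]]
        merged["magnitude"] = [call_by_peptide[p][1] for p in merged["peptide"]]
        # wild-type-dependent features are absent for indel peptides; the
        # screen compares only columns defined for every tested peptide
        numeric = [
            c
            for c in merged.columns
            if c not in ("peptide", "allele", "category", "positive", "magnitude")
            and not merged[c].isna().any()
        ]
        if merged["positive"].sum() >= 2 and (~merged["positive"]).sum() >= 2:
            screen = feature_screen(merged, numeric)
            screen.to_csv(out / "feature_screen.tsv", sep="\t", index=False)
            evaluation["top_feature"] = screen.iloc[0]["feature"]
        by_cat = {
            c: group["magnitude"].tolist()
            for c, group in records_df.groupby("category")
            if len(group)
        }
        if len([c for c, v in by_cat.items() if v]) >= 2:
            compare_categories(by_cat).to_csv(out / "category_contrasts.tsv", sep="\t", index=False)
        evaluation["n_tested"] = len(tested)
        evaluation["n_positive"] = int(records_df["positive"].sum())
    with open(out / "evaluation.json", "w") as fh:
        json.dump(evaluation, fh, indent=2, default=str)

    # --- manifest ---------------------------------------------------------
    outputs = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": seed,
        "config": config,
        "checksums": {str(p.relative_to(out)): _sha256(p) for p in outputs},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("run complete: %d output files", len(outputs))
    return out
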