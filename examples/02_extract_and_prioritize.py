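"""Extract mutant peptides for one variant and run the selection cascade.

A missense variant yields every 8-11-mer window covering the substituted
residue; each window is scored on the patient's alleles with the bundled
mock predictor and pushed through the study's filter cascade.
"""

from vaxtope.models import ProteinVariant
from vaxtope.peptides import extract_mutant_peptides
from vaxtope.predictors import MockPredictor
from vaxtope.prioritize import CascadeThresholds, PeptideCandidate, apply_cascade

protein = "MTEYKLVVVGAGGVGKSALTIQLIQNHFVDEYDPTIEDSYRKQVVIDGET"
variant = ProteinVariant(
    sample_id="vaccine", chrom="chr12", pos=25245350, ref="C", alt="T",
    gene="KRAS", transcript="ENST00000311936", consequence_kind="missense",
    protein_pos=12, ref_aa="G", alt_aa="D",
    vaf_by_line={"line1": 0.35}, rna_coverage=40, rna_vaf=0.5,
)

pairs = extract_mutant_peptides(variant, protein)
print(f"{len(pairs)} mutant windows (8+9+10+11 = 38 for an interior change)")

predictor = MockPredictor(seed=1)
candidates = []
for pair in pairs:
    record = predictor.score(pair.mutant, "HLA-B*57:01")
    wt = predictor.score(pair.wildtype, "HLA-B*57:01").rank_el
    candidates.append(
        PeptideCandidate(
            pair=pair, allele="HLA-B*57:01", locus="B", category="V",
            mut_rank_el=record.rank_el, wt_rank_el=wt, rank_stab=record.rank_stab,
            classII_min_rank=50.0, tpm=8.0, rna_coverage=40, max_vaf=0.35,
        )
    )

# mock ranks are uniform, so demo thresholds are looser than the study's
survivors, trace = apply_cascade(candidates, CascadeThresholds(max_mut_rank_el=20, max_rank_stab=50))
print(f"{len(survivors)} windows survive the cascade")
for row in [r for r in trace if not r["survivor"]][:3]:
    print(f"  rejected {row['peptide']}: first failing filter = {row['first_fail']}")
# each rejected window records the first filter it failed, so the whole
# selection is auditable
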