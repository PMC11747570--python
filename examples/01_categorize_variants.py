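"""Categorize vaccine/germline/tumor variants into V, TV, and T.

Builds a small synthetic cohort, runs the set logic with the patient's
germline as self, and reports the category counts, the shared fraction,
and the tumor mutational burden.
"""

from vaxtope.categorize import categorize_variants, compute_tmb, summarize_categories
from vaxtope.synthetic_data import SimulationConfig, simulate_variant_sets

cfg = SimulationConfig(seed=1, n_vaccine_variants=500, tv_fraction=0.1, n_tumor_private=80)
vaccine, germline, tumor = simulate_variant_sets(cfg)
table = categorize_variants(vaccine, germline, tumor)
summary = summarize_categories({"demo": table})

germ = {v.genomic_key for v in germline}
tumor_somatic = [v for v in tumor if v.genomic_key not in germ]

print("category counts:", table.counts)
print(f"vaccine-specific variants: {summary.per_patient_vaccine_specific['demo']}")
print(f"shared fraction: {100 * summary.per_patient_shared_fraction['demo']:.1f}%")
print(f"tumor TMB: {compute_tmb(tumor_somatic):.2f} mutations/Mb")
# V = antigens only the vaccine offers (alloantigens + vaccine-private
# mutations); TV = shared neoantigens also present in this tumor; the TMB
# uses the 50.39 Mb captured exome.
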