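"""Derive alloantigen candidate peptides from donor-recipient HLA mismatches.

Residues where a vaccine (donor) HLA allele differs from BOTH of the
patient's alleles at the same locus seed candidate windows; windows the
patient's own alleles already contain are removed.
"""

from vaxtope.allo_hla import derive_allo_candidates, find_mismatches
from vaxtope.synthetic_data import SimulationConfig, simulate_hla_alleles

cfg = SimulationConfig(seed=3)
donors, haplotype, patient_alleles = simulate_hla_alleles(cfg)
patient_class_i = [a for a in patient_alleles if a.hla_class == "I"]

donor = donors[0]
same_locus = [a for a in patient_class_i if a.locus == donor.locus]
mismatches = find_mismatches(donor, same_locus)
print(f"{donor.name}: {len(mismatches)} mismatch positions vs both patient alleles")

candidates = derive_allo_candidates(donors, patient_class_i)
for name, windows in candidates.items():
    print(f"  {name}: {len(windows)} candidate windows")
# each window is a donor-allele k-mer (8-11) covering at least one mismatch
# and absent from the patient's own HLA proteins - a potential alloantigen
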