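"""Re-derive the study's summary statistics from its printed tables.

The per-patient variant category counts, positivity tallies, and the
dual-patient epitope panel are shipped as constants; everything below is
recomputed from them.
"""

from vaxtope import studydata
from vaxtope.categorize import summarize_categories
from vaxtope.evaluate import concordance

summary = summarize_categories(studydata.VARIANT_COUNTS)
print(f"mean vaccine-specific variants: {summary.mean_vaccine_specific:.0f}")
print(f"sample SD across patients:      {summary.sd_vaccine_specific:.0f}")
print(f"#032 shared fraction: {100 * summary.per_patient_shared_fraction['#032']:.1f}%")
print(f"#005 shared fraction: {100 * summary.per_patient_shared_fraction['#005']:.2f}%")

pct = studydata.positivity_percentages()
print(f"#032 vaccine-only positivity: {pct['#032']['V']:.1f}%")
print(f"#045 vaccine-only positivity: {pct['#045']['V']:.1f}%")

calls = [(a, b) for _, _, _, a, b, _ in studydata.DUAL_PATIENT_PANEL]
result = concordance(calls)
print(
    f"dual-patient panel: {result.n_concordant} concordant / "
    f"{result.n_discordant} discordant of {len(calls)}"
)
# the high shared fraction of one patient reflects an exceptionally high
# tumor mutational burden; discordant responses despite shared HLA point
# to patient-specific immune stochasticity
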