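# vaxtope

Antigen discovery and T-cell immune-response analysis for allogeneic
whole-tumor cell vaccines.

Allogeneic cell vaccines such as the VACCIMEL melanoma vaccine expose the
patient's immune system to three kinds of antigens at once: **alloantigens**
(germline polymorphism differences between the vaccine donor lines and the
patient, including mismatched HLA molecules), **shared neoantigens** (somatic
mutations present in both the vaccine cells and the patient's tumor), and the
patient's **private neoantigens**. `vaxtope` implements the computational arm
of such a study, for immunologists and bioinformaticians who need to go from
annotated variant tables to tested, audited epitope panels:

- **Variant categorization** — with the patient's germline exome as self,
  partition variant keys into `V` (vaccine-only), `TV` (vaccine and tumor)
  and `T` (tumor-only): `V = (vac ∖ germ) ∖ tum`, `TV = (vac ∖ germ) ∩
  (tum ∖ germ)`, `T = (tum ∖ germ) ∖ vac`; plus pre-filters (VAF > 10%,
  TPM > 0, caller PASS) and TMB over the 50.39 Mb captured exome.
- **Peptide extraction** — every 8–11-mer window of the mutated protein
  covering an altered residue, paired with its wild-type counterpart where
  one exists; windows identical to germline substrings are never emitted.
- **Allogeneic-HLA epitopes** — donor-allele windows covering residues that
  differ from *both* patient alleles at the same locus.
- **Prioritization cascade** — the study's quoted rules (max VAF > 0.10,
  TPM > 0, RNA coverage ≥ 10, mutant %Rank_EL < 0.5, wild-type
  %Rank_EL ≥ 2, %Rank_Stab < 2, no HLA-C, class II %Rank_EL ≥ 1) with a
  complete per-filter audit trace, and a deterministic farthest-point
  surrogate for manual panel curation.
- **Feature battery** — DAI (`mut %Rank_EL / wt %Rank_EL`), PHBR (harmonic
  mean of the best rank over the six class I allele slots), HLA promiscuity,
  expression features (`TPM × RNA_VAF`, log2 fold change vs melanocytes),
  BLOSUM string-kernel self-similarity (whole peptide and non-anchor core),
  and physicochemical properties.
- **ELISpot positivity** — magnitude as background-subtracted spots per
  100,000 effector cells and a distribution-free resampling (DFR) test:
  `T = mean(stim) − m·mean(ctrl)` against all reassignments of the pooled
  wells (20 splits for triplicates), with Holm adjustment optional.
- **Evaluation** — ROC AUC and normalized partial AUC (FPR ≤ 0.1), Pearson
  correlations with `r(n−2)`-style degrees of freedom, Mann-Whitney category
  contrasts with star annotations, dual-patient concordance, and cohort
  overlap vs TMB.

External peptide–HLA predictors stay behind one interface: a deterministic
seeded **mock predictor** (uniform percentile ranks) makes the whole pipeline
runnable offline, and a **prediction-table adapter** ingests scores from any
real tool. A synthetic-data generator reproduces the statistical structure of
the study's protected sequencing data (variant-set overlaps, log-normal TPM,
overdispersed ELISpot counts with a planted expression–response correlation).

## Worked example

```bash
python examples/06_study_tables.py
```

```text
mean vaccine-specific variants: 9481
sample SD across patients:      270
#032 shared fraction: 19.5%
#005 shared fraction: 0.05%
#032 vaccine-only positivity: 37.2%
#045 vaccine-only positivity: 55.3%
dual-patient panel: 7 concordant / 10 discordant of 17
```

The first two lines are the cohort mean ± SD of vaccine-specific variants
(`|V| + |TV|` per patient) recomputed from the per-patient category counts.
The shared fractions show one high-TMB patient whose tumor shares 19.5% of
the vaccine's variants while another shares 0.05%. The positivity lines
recompute percent-responding from positives/tested tallies, and the last
line counts epitopes called positive in only one of two HLA-matched patients
— immune responses are largely not conserved across patients.

The other `examples/` scripts each demonstrate one capability (categorize,
extract + prioritize, allo-HLA, ELISpot calls, feature screen, full
pipeline). The same stages are exposed as a CLI:

```bash
vaxtope run --seed 7 --out runs/demo      # full synthetic pipeline
vaxtope simulate --seed 3 --out inputs/   # fixture bundle only
```

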