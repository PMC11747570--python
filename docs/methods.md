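# Methods

## Scope and data model

`vaxtope` analyzes antigens offered by an allogeneic whole-tumor cell
vaccine. It starts downstream of variant calling and annotation: inputs are
protein-level variant tables (or a minimal VCF with a CSQ-style annotation
plus a transcript-keyed protein FASTA), gene-level TPM per vaccine cell
line, HLA genotypes with allele protein sequences, peptide–HLA percentile
ranks from any predictor, and ELISpot replicate counts. Read alignment,
variant calling, annotation, expression quantification, and HLA typing are
out of scope, as are the external predictor models themselves.

Variant identity across genomes is the genomic key `(chrom, pos, ref,
alt)`; protein annotations travel with the record but do not participate in
set comparisons. The four vaccine cell lines are unioned into one vaccine
variant set; per-line provenance is kept for the VAF filter. One record is
kept per `(genomic key, transcript)`; downstream set logic keys on the
genomic key alone. Multi-allelic VCF records split into one record per alt
allele. Genomic and protein coordinates are 1-based; peptide windows are
1-based closed intervals.

## Category model

With the patient's germline defining self:

```
V  = (vaccine ∖ germline) ∖ tumor        vaccine-exclusive antigens
TV = (vaccine ∖ germline) ∩ (tumor ∖ germline)   shared neoantigens
T  = (tumor ∖ germline) ∖ vaccine        private neoantigens
```

Pre-filters retain variants with max per-line VAF strictly above 0.10,
combined vaccine TPM strictly above 0, and caller PASS in at least one cell
line. The combined expression profile sums the per-line TPM and rescales to
one million, so it remains on the TPM scale. TMB divides the count of
coding non-synonymous somatic variants by the captured exome size (default
50.39 Mb). Whether published per-patient category counts precede or follow
the expression/VAF filters is not fully documented; the tooling therefore
reports both raw and filtered counts. The vaccine "somatic fraction"
requires a population germline resource and is supported only as an
intersection with a user-supplied somatic key list.

## Peptide extraction

For a missense variant the mutated protein is built by substitution and
every 8–11-mer containing the substituted residue is emitted, each paired
with the positionally corresponding wild-type window. In-frame indels emit
windows overlapping any altered or junction residue, with no wild-type
counterpart; multi-residue in-frame substitutions are treated as the union
of per-residue changes. Frameshifts require the mutant tail (supplied
translated, or as a coding sequence translated with the standard code to
the first stop) and emit windows overlapping any novel residue. Windows
containing ambiguous residues (X) are dropped with a warning because
predictors cannot score them; windows identical to any same-length germline
substring are suppressed (a peptide the patient's proteome already contains
is not a neoantigen); duplicate mutant sequences from one variant keep the
first occurrence in N-to-C order. An interior missense therefore yields
exactly 8+9+10+11 = 38 windows.

The non-anchor core of a predictor-reported interaction core keeps the 4th
through penultimate residues, since anchor positions contact the HLA groove
rather than the T-cell receptor.

## Allogeneic HLA epitopes

A donor-allele position is a mismatch when its residue differs from *both*
patient alleles of the same locus ("corresponding HLA molecules";
cross-locus comparison is never performed). Equal-length sequences are
compared positionally. Unequal lengths are refused unless alignment is
requested, in which case a BLOSUM62 global pairwise alignment (gap open
−11, extend −1) maps donor positions onto each recipient allele and gap
columns are excluded from mismatch calling. Candidate windows are all donor
k-mers (8–11 for class I, 15 for class II) overlapping at least one
mismatch, minus windows identical to a recipient-allele substring, and are
deduplicated across all donor alleles with provenance kept on the first
emitting allele.

## Predictor interface

All peptide–HLA scoring flows through one deterministic interface. The
bundled mock predictor derives a 9×20 position–residue weight table per
allele from `(seed, allele)`; a peptide's pseudo-energy is the minimum
window sum and its percentile rank is taken within a seeded reference
distribution of 100,000 random 9-mers for that allele, so ranks are uniform
on (0, 100] over random peptides and all quoted thresholds (0.5 strong,
2 weak) are meaningful. Stability ranks use an independent table; the icore
is the minimal-energy window. The table adapter loads precomputed records
and raises on any missing pair — scores are never defaulted. Real external
tools are deliberately not wrapped; their output enters through the table
format.

## Prioritization cascade and curation surrogate

The cascade evaluates, in order: VAF, expression, RNA coverage (pooled
reads at the mutated position; a per-line reading is available in config),
mutant presentation (%Rank_EL < 0.5), wild-type non-binding (%Rank_EL ≥ 2,
skipped when no wild-type counterpart exists), stability (%Rank_Stab < 2),
HLA-C exclusion (the stability predictor is not trained on HLA-C), and the
class II exclusion (minimum class II %Rank_EL over the patient's alleles
≥ 1, keeping CD8-restricted candidates). All inequalities are strict or
inclusive exactly as listed. Every candidate records each filter verdict;
the order affects only trace attribution, never the survivor set, which is
also invariant to input permutation.

Manual curation — spreading a fixed-size panel across stability and
expression while avoiding near-duplicate peptides from one variant — is
replaced by a deterministic surrogate: at most one peptide per source
variant (best mutant rank, lexicographic tie-break), then greedy
farthest-point selection in the plane of rank-transformed `%Rank_Stab` and
rank-transformed `log1p(TPM)`, seeded from the expression extreme, ties
broken lexicographically. Greedy farthest-point is a 2-approximation of
max-min dispersion; determinism was valued over optimality.

## Feature battery

Formula-level features: DAI = mutant %Rank_EL / wild-type %Rank_EL (values
below 1 mean the mutation improved presentation); PHBR = harmonic mean of
the best rank over exactly six class I allele slots, homozygous loci
contributing their allele twice; promiscuity counts alleles bound strongly
(< 0.5) and weakly ([0.5, 2)); mutant-transcript expression TPM × RNA_VAF;
log2 fold change vs healthy melanocytes with pseudocount 0.01 on both sides
(expression tables contain exact zeros); string-kernel self-similarity
`K(a,b)/√(K(a,a)K(b,b))` where K sums substitution-matrix-weighted products
over all k-mer pairs, k = 1..3, BLOSUM62 shifted non-negative (kernel
order, matrix and shift are configurable since the canonical settings are
not fixed); GRAVY, average molecular weight and aromaticity via Biopython's
ProteinAnalysis; and pI by bisection of the Henderson–Hasselbalch net
charge over pH 0–14 with Biopython's pKa table (the full range matters for
short, very acidic or basic peptides). Features needing externally trained
models (processing, transport, foreignness, T-cell propensity, integrated
presentation scores) are accepted only as pass-through columns from a
prediction table, never computed internally.

## ELISpot magnitude and positivity

Magnitude = (mean stimulated − mean control) × 100,000 / cells-per-well,
floored at zero for reporting with the signed value retained. The DFR test
is instantiated concretely as a resampling test of H₀: mean(stim) ≤
m · mean(ctrl) with statistic `T = mean(stim) − m·mean(ctrl)`: the null
distribution re-assigns the pooled wells into arms of the observed sizes —
exhaustively up to 5 wells per arm (20 splits for 3+3), seeded Monte-Carlo
with 10,000 resamples beyond — and p is the fraction of resampled T at
least the observed value, the observed split included, so triplicate
p-values are multiples of 1/20 and never zero. The multiplier defaults to
2 (the conservative variant); 1 is exposed. Under an exchangeable null with
multiplier 1 the test is permutation-valid to enumeration granularity.

Positivity uses DFR wherever both arms have triplicates, with Holm
adjustment within each (patient, timepoint) batch by default; "none" gives
the per-peptide reading. Note an interplay: the triplicate p-value floor of
1/20 means Holm over a batch of more than one such test can never reject at
α = 0.05, so large single-batch screens should use the per-peptide reading
— the demo pipeline does. With fewer replicates an empirical rule applies
(these criteria are not standardized; the defaults — magnitude ≥ 20 per 1e5
cells and stimulated mean ≥ 2× control — are config-exposed and flagged in
output). Mixed-timepoint effector samples have no formal representation;
records carry a free-text note.

## Evaluation statistics

AUC is the Mann-Whitney probability (ties counted half); the partial AUC
integrates the ROC over FPR ∈ [0, 0.1] by trapezoid with interpolation at
the cap and divides by the cap, so a perfect classifier scores 1 and the
diagonal scores 0.05 (the normalization of a partial AUC is otherwise
convention-dependent). Feature screens restrict to predicted strong binders
when a rank column is supplied, since binding is a prerequisite for
recognition and confounds the comparison. Pearson correlations report
two-sided t-based p at n−2 degrees of freedom. Mann-Whitney contrasts are
exact for tie-free groups of at most 8, normal-approximated with tie
correction otherwise; stars at p < 0.05/0.01/0.001/0.0001. Concordance
compares per-peptide calls between two patients at a single timepoint;
cross-timepoint fluctuation is reported descriptively only. Cohort overlap
intersects exact peptide strings and correlates per-patient shared counts
with TMB.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical structure* the analysis assumes,
with set sizes fixed by construction rather than sampling, and every
generator a pure function of (config, seed):

- vaccine/germline/tumor overlap with exact requested counts, including a
  high-burden scenario (9,652 vaccine-specific variants, 19.5% shared) and
  a germline background present in all three lists;
- log-normal per-line TPM (log-mean 1.5, log-SD 1.5), combined and
  rescaled to one million;
- synthetic HLA alleles as sparse substitutions on a per-locus backbone,
  with optional class I homozygosity (these are labelled synthetic and are
  not IMGT sequences);
- ELISpot counts: negative-binomial wells (overdispersion size 20, control
  mean 10 spots, 200,000 cells/well, triplicates) — ELISpot replicates are
  overdispersed, which keeps the DFR null simulation honest — and a latent
  response magnitude (mean 20, SD 30 per 1e5 cells, clipped at zero, chosen
  to match published magnitude spreads and positivity rates of roughly
  4–55%) whose correlation with standardized log1p(TPM) is planted exactly
  at `elispot_effect_corr`.

It does not emulate raw reads, caller error profiles, real HLA polymorphism
structure, pool deconvolution, or inter-assay batch effects. Passing tests
therefore demonstrate the *logic and calibration* of the pipeline, not
recovery of any patient-level biological result.

One property deserves an explicit caveat. The planted correlation bounds
how well any binary positivity label can track expression: labels are a
function of the latent magnitude plus independent noise, so with planted
ρ = 0.2 the expression feature's AUC against the calls is capped near 0.59
(the point-biserial of a dichotomized ρ = 0.2 latent is at most ≈ 0.8ρ).
Consequently, in a 200-peptide screen with 10 pure-noise decoys the
expression feature lands in the top 3 of the partial-AUC ranking in roughly
75–85% of seeded runs — materially above chance (27%), but an informative
ceiling: a stronger guarantee would require planting label–expression
dependence beyond the stated correlation. The acceptance suite measures
this frequency as-is.

## Problem sizes and numerical choices

The test and acceptance runs use: 1,000 random category instances up to
10,000 keys; 1,000 random peptide-extraction instances; 2,000 simulated
null assays for DFR calibration; 100 seeded 200-peptide screens for the
planted-effect analysis; and a demo pipeline at 150 vaccine variants with
relaxed presentation cut-offs (uniform mock ranks would otherwise leave an
empty panel at that scale — the study-scale thresholds remain the library
defaults). Floating-point ranks round-trip through prediction TSVs at 17
significant digits; VCF FORMAT floats are normalized to the TSV dialect's
6-digit precision on read. Ties everywhere break lexicographically by
peptide sequence for determinism.
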