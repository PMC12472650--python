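# Methods

`allneo` implements a somatic-missense → class-I neoantigen analysis for a
pediatric acute lymphoblastic leukemia (ALL) style cohort, together with a
synthetic-cohort generator that stands in for protected patient exomes.  This
note documents the model, the parameters that matter, the numerical choices,
and what the synthetic data can and cannot certify.

## Pipeline model

**Peptide enumeration.**  A missense substitution at protein position *p*
(1-based, HGVS-style) can appear in any 9-mer window whose start lies in
`[max(1, p−8), min(p, L−8)]` for a protein of length *L*.  Internal mutations
(9 ≤ *p* ≤ *L*−8) therefore yield exactly nine tiling mutant/wild-type
nonamer pairs; near a terminus we emit the reduced window set rather than
padding, and proteins shorter than nine residues yield none (warned, not
fatal).  The register of the mutated residue within a peptide is 0-based.
Duplicate somatic events within a patient are collapsed before enumeration,
since the tumor mutational burden (TMB) counts distinct events.

**Binding and %Rank.**  Each distinct peptide is scored against each of the
patient's distinct HLA-A/-B/-C alleles (homozygous loci contribute one
allele).  The bundled predictor is a *surrogate*: a keyed hash of
(peptide, allele, model key) mapped so that log₁₀ IC50 is uniform on
[0, log₁₀ 50000] nM.  It is a deterministic, reproducible affinity oracle
with exactly the distributional properties the cohort statistics need — it is
not a biological binding model, and per-allele binding motifs, anchor
residues and affinity correlations between similar peptides are absent by
design.  External NetMHC-style score tables (TSV: peptide, allele, ic50_nm,
rank_pct) can be substituted for it at the pipeline level.

The %Rank of a query IC50 against one allele is the percentage of a
background of random natural 9-mers (distinct windows sampled from the
proteome) with *strictly* lower IC50; ties count as not-lower ("top x%"
semantics), making the rank monotone in IC50 and giving the definitional
property that ~2% of background peptides rank below 2%.  Backgrounds are
allele-specific (whether a shared background would be equivalent is
predictor-dependent; allele-specific is the safer contract).  Production
scale is 200,000 background peptides per allele; the bundled configuration
uses 5,000, which bounds the rank granularity at 0.02% — far below the 2%
threshold it feeds.

**Neoantigen definition.**  A (mutant peptide, allele) candidate is called
when the mutant record is a binder — IC50 < 500 nM *or* %Rank < 2%, both
strict, so boundary values fail — and the mutant affinity differs from the
wild-type counterpart's.  The differential agretopic index is
DAI = IC50(wt) − IC50(mut) (positive ⇒ mutant binds more strongly); "same
affinity" is operationalized as relative IC50 agreement within a configurable
tolerance (default 1e-6, i.e. equality at reported precision), applied per
(peptide, allele) since affinity is allele-specific.  Only the same-affinity
exclusion is applied; the wild type is *not* additionally required to be a
non-binder.  Per-patient load counts unique (peptide, allele) pairs — one
peptide presented by three alleles counts three — with a unique-peptide mode
available, since published load counts are ambiguous between the two units.
Identical (patient, peptide, allele) triples arising from different
mutations or registers are deduplicated.

**Mutant/wild-type coupling hook.**  By default the surrogate scores mutant
and wild-type peptides independently, so near-equal affinities (and hence
DAI exclusions) essentially never occur by chance.  A `mixing` parameter
blends the mutant log-affinity toward its wild-type partner's
(`mixing=1` ⇒ identical affinities, everything excluded), giving the DAI
filter non-trivial behavior when an analysis needs it.

## Cohort statistics

* **TMB–load correlation**: Pearson R from a linear regression plus Spearman
  rho, both with two-sided p-values.
* **Two-group comparisons** (sex; age <10 y vs ≥10 y, exact 120 months to the
  older group; WBC <50,000/µL vs ≥; blast % <50 vs ≥50; immunophenotype
  pre-B vs T; NCI risk; MMR status; median splits of TMB and load with ties
  to the low group): group means, a Wilcoxon–Mann–Whitney p (exact
  enumeration for combined n ≤ 10 without ties, normal approximation with
  tie correction otherwise), and a permutation p.
* **Permutation engine**: two-sided test on |difference of group means|
  (statistic pluggable), with the add-one-smoothed estimator
  p̂ = (1 + B)/(1 + m) so p̂ > 0 always, and adaptive stopping when m reaches
  5,000 or the binomial SE of p̂ falls below 10% of p̂ (checked every 250
  draws) — the defaults of the lmPerm permutation framework.  No
  multiple-testing correction is applied across variables, deliberately
  mirroring the single-table reporting convention of cohort studies of this
  size.
* **NCI risk**: high risk iff age < 12 months, age ≥ 120 months, or
  WBC ≥ 50,000/µL.  The canonical prose statement of this rule pairs its
  clauses inconsistently ("or" in the standard-risk sentence, "and/or" in
  the high-risk one); we implement the internally consistent rule that
  matches the high-risk clause, which partitions the (age, WBC) plane.
* **HLA frequencies** are reported in both *carrier* (patients with ≥1 copy
  / n) and *allelic* (copies / 2n) modes, because published allele
  percentages mix the two denominators; allelic mode sums to 1 per locus
  exactly.
* **MMR status**: MUT iff any missense mutation in MSH2, MSH6, MLH1 or PMS2
  (case-insensitive).

## Survival

EFS events are relapse or death (whichever first); OS events are deaths;
times are months.  Kaplan–Meier curves, the two-group log-rank test and the
Cox proportional-hazards fit are delegated to lifelines.  Ties in the Cox
partial likelihood are handled by Efron's approximation (lifelines'
estimator; the data-generating conventions here do not single out Breslow vs
Efron, and with continuous simulated times ties are null sets).  Monotone
likelihoods (perfect separation) are flagged as non-converged rather than
reported.  Burden dichotomization for curves uses the cohort median, ties to
the low group.

## Synthetic cohort generator

The generator's defaults are the study conditions of the analysis:

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 35 | matched tumor/normal cohort size |
| `mmr_mut_fraction` | 8/35 | probability a patient is MMR-mutant |
| `mmr_fold` | 3.4 | hypermutator burden fold (≈ ratio of reported group means 3532/1028) |
| `mu_wt` | 200 | mean missense count per MMR-wild-type patient (desk scale) |
| `dispersion` | 4.0 | negative-binomial size *k*; Var = µ + µ²/k |
| `mmr_planted_extra` | 2.6 | planted MMR-gene mutations per MUT patient = 1 + Poisson(2.6) |
| `n_proteins`, lengths | 200, U[100, 600] | random uniform-residue proteome |
| `burden_log_hazard` | 0 | log-hazard per SD of burden in survival times |

Counts are negative-binomial with mean `mu_wt` (WT) or `mu_wt × mmr_fold`
(MUT); positions uniform over proteome residues; alternate residues uniform
over the 19 non-reference amino acids.  Every MMR-mutant patient receives at
least one mutation planted in an MMR-labeled protein (mean ≈ 3.6, echoing 29
reported MMR-gene mutations across 8 carriers), and wild-type patients draw
positions only from non-MMR proteins, so the planted stratification is exact
by construction.  HLA genotypes draw two alleles per locus independently
with replacement (homozygosity allowed, no linkage structure) from a
frequency table whose defaults echo the reported leading alleles
(HLA-A*02:01 15.6%, HLA-A*24:02 14.8%, HLA-B*39:05 9.4%, HLA-C*07:01 26.6%,
…).  Clinical covariates use Bernoulli sex (58% male) and immunophenotype
(88% pre-B), uniform age over 6–203 months, log-normal WBC
(median ≈ 24,000/µL, P(≥50,000) ≈ 0.3) and uniform blast %.  Event times are
exponential with hazard `baseline × exp(β·z)` where z is the standardized
burden covariate (β = 0 by default — the reference analysis found no
burden–outcome association); censoring is uniform over a 60–84-month
follow-up window.

**Scale.**  `mu_wt = 200` is a deliberate desk-scale reduction of the
reported wild-type mean (~1028) so the full pipeline runs in seconds; the
group *ratio*, not the absolute burden, is what the stratified comparison
tests.  **Dispersion** is not identified by published group means; k = 4 was
fixed a priori by a design power calculation: with n = 35, a MUT fraction of
8/35 and fold 3.4, the normal-approximation power of the mean-difference
test at α = 0.05 is ≈ 0.97, comfortably delivering the clearly separated
hypermutator phenotype the analysis is built around, while keeping
per-patient counts visibly overdispersed (CV ≈ 0.5–0.7).  Real TMB
distributions are heavier-tailed than this (the reference cohort's maximum
was ~16× its mean); the generator does not attempt to reproduce that tail.

**Seeding.**  A single master seed spawns independent per-stage substreams
(proteome, mutations, genotypes, clinical) via `numpy` `SeedSequence`, so
identical (config, seed) gives byte-identical serialized cohorts and editing
one stage's parameters does not perturb the others.

## What passing tests do and do not show

Because the binding surrogate is distributionally flat (log-uniform IC50,
independent across peptides), the binder rate under the default thresholds
is ≈ 0.57 per (peptide, allele) — far above the rate of a real predictor —
so absolute neoantigen loads here exceed realistic loads by an order of
magnitude, while *structural* results (tight TMB–load correlation via
binomial thinning, MMR-group separation, permutation calibration, survival
machinery) are faithfully exercised.  Published absolute cohort numbers
(total mutations, total neoantigens, median load) are functions of protected
patient data and a neural-network predictor, and are not reproduction
targets at desk scale.

## Numerical choices and degenerate inputs

* Strict inequalities throughout the binder rule; `percent_rank` counts
  strictly-lower reference values via binary search on the sorted background.
* The surrogate hash is FNV-1a over residue bytes keyed by a BLAKE2b digest
  of (model key, allele), finalized with splitmix64; uniformity of the
  resulting log-affinities is verified by a Kolmogorov–Smirnov check at the
  1% critical value in the test suite.
* Permutation p-values use +1/+1 smoothing; `se_stop_frac = 0` disables
  early stopping for exhaustive-comparison tests.
* Reference-residue mismatches in a mutation table abort the run (corrupt
  table); mutations referencing proteins absent from the FASTA are skipped,
  warned about, and counted in the run report.
* Constant covariates, single-group comparisons, zero pooled events and
  non-positive times raise typed errors rather than producing numbers.

## Known limitations

* The surrogate predictor has no peptide–HLA biology; DAI behavior under
  default mixing is binary (almost never "same affinity").
* No DNA-level simulation: no codon structure, trinucleotide signatures or
  VCF emission; amino-acid background is uniform rather than human-like.
* HLA haplotypes carry no linkage disequilibrium.
* Frameshift/indel/fusion neoantigens and peptide lengths other than nine
  are out of scope; expression-based filtering is not implemented.
* The Cox model defaults to a univariate burden effect; adjustment is
  possible by passing additional covariate columns.
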