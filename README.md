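# allneo

Somatic-missense neoantigen calling and cohort statistics for pediatric
acute lymphoblastic leukemia (ALL) style cohorts, with a fully synthetic
cohort generator in place of protected patient exomes.

## The problem

Tumor-specific missense mutations can create *neoantigens*: mutant peptides
presented by a patient's HLA class-I molecules and potentially visible to
T cells.  Given a per-patient table of somatic missense mutations, the
patient's six HLA-A/-B/-C alleles and a peptide–HLA affinity predictor, the
pipeline

1. expands each mutation at protein position *p* into its tiling 9-mer
   windows (exactly nine for internal mutations), pairing every mutant
   nonamer with its wild-type counterpart;
2. scores every distinct (peptide, allele) pair, attaching an empirical
   %Rank against a background of random natural 9-mers;
3. calls a candidate a neoantigen when the mutant peptide binds —
   IC50 < 500 nM **or** %Rank < 2%, strict — and its affinity differs from
   the wild type's (the differential agretopic index,
   DAI = IC50(wt) − IC50(mut), must be non-zero at tolerance);
4. aggregates per-patient neoantigen load (unique peptide–allele pairs) next
   to tumor mutational burden (TMB = distinct missense events), and
5. runs the cohort statistics: TMB–load correlation (Pearson R, Spearman ρ),
   two-group comparisons across clinical strata with Wilcoxon–Mann–Whitney
   and adaptive permutation tests (5,000 iterations or SE < 10% of p̂),
   mismatch-repair (MSH2/MSH6/MLH1/PMS2) stratification, HLA carrier/allelic
   frequencies, NCI risk classification, and EFS/OS survival analysis
   (Kaplan–Meier, log-rank, Cox).

Real patient exomes for such cohorts are protected, so the package ships a
seeded synthetic generator: negative-binomial burdens with an MMR-mutant
hypermutator subgroup (fold 3.4), planted MMR-gene mutations, HLA genotypes
from a configurable allele-frequency table, and clinical/survival
covariates.  A deterministic hash-based surrogate stands in for the
neural-network affinity predictor; externally produced NetMHC-style score
tables can be supplied instead.  See `docs/methods.md` for the model in
full and for what the synthetic conditions do and do not certify.

## Worked example

The numbered drivers under `analysis/` run the whole study on the default
synthetic cohort (35 patients, master seed 1), writing bulk intermediates to
`scratch/` and result tables to `results/`:

```bash
python analysis/01_simulate_cohort.py 1
python analysis/02_enumerate_peptides.py
python analysis/03_predict_binding.py 1
python analysis/04_call_neoantigens.py
python analysis/05_cohort_statistics.py 1
python analysis/06_survival_analysis.py
```

prints

```
simulated 35 patients: 11359 missense mutations, 10 MMR-mutant patients carrying 178 MMR-gene mutations
11359 mutations -> 99823 nonamer pairs (10752 mutations with the full nine windows)
1057087 distinct (peptide, allele) records over 30 alleles; mean binder rate 0.574 at <500 nM or <2% rank
331164 neoantigen calls; per-patient load median 5765 (range 2084–28971); top shared peptide in 5.7% of patients
TMB–load correlation: Pearson R = 0.992, Spearman rho = 0.984
MMR stratification (TMB): MUT(10) vs WT(25), means 681.5 vs 181.8, Wilcoxon p = 0.0, permutation p = 0.0002
EFS: 14 events; median-load split log-rank p = 0.554; Cox HR per SD load = 1.0571
OS: 7 events; median-load split log-rank p = 0.586; Cox HR per SD load = 1.1324
```

Reading the output: neoantigen load tracks mutational burden almost
perfectly (R ≈ 0.99 — load is a thinned count of burden), the ten MMR-mutant
hypermutators carry ~3.7× the burden of wild-type patients with the
difference surviving the permutation test (p ≈ 2×10⁻⁴), and — as in the
cohort this emulates — the median-load split shows no survival difference.
Absolute counts are surrogate-predictor artifacts (the flat affinity
distribution passes ~57% of candidates); the structure, not the scale, is
the point.

The same pipeline is scriptable through a single entry point:

```bash
allneo simulate --out cohort/ --seed 1
allneo run --config run.yaml --seed 1     # enumerate → predict → call → stats
```

plus stage-wise subcommands (`enumerate`, `predict`, `call`, `stats`,
`survive`) over the on-disk TSV dialects.

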