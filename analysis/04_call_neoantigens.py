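#!/usr/bin/env python
"""Step 4 — apply the neoantigen definition and build the patient table.

Keeps mutant peptides that bind a patient allele (<500 nM or %Rank < 2%)
and whose affinity differs from the wild-type counterpart's (the
differential-agretopic-index exclusion), deduplicates per (patient, peptide,
allele), and aggregates per-patient neoantigen loads alongside TMB, MMR
status and clinical covariates.
"""

from pathlib import Path

import pandas as pd

from allneo import calling, io as aio
from allneo.binding import read_binding_table
from allneo.peptides import dedupe_mutations
from allneo.stats import summarize_patients

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort_dir = ROOT / "scratch" / "cohort"
    pipe_dir = ROOT / "scratch" / "pipeline"
    pairs = aio.read_pairs_tsv(pipe_dir / "pairs.tsv")
    records = read_binding_table(pipe_dir / "binding.tsv")
    genotypes = {g.patient_id: g for g in aio.read_hla_tsv(cohort_dir / "hla.tsv")}
    clinical = aio.read_clinical_tsv(cohort_dir / "clinical.tsv")
    mutations = dedupe_mutations(aio.read_mutations_tsv(cohort_dir / "mutations.tsv"))

    cfg = calling.FilterConfig()
    idx = {(r.peptide, r.allele): r for r in records}
    calls = []
    by_patient: dict[str, list] = {}
    for p in pairs:
        by_patient.setdefault(p.mutation.patient_id, []).append(p)
    loads = {}
    for pid, prs in sorted(by_patient.items()):
        # restrict the shared record table to this patient's alleles
        alleles = genotypes[pid].distinct_alleles
        sub = [idx[(pep, a)] for a in alleles
               for pep in {q for pr in prs for q in (pr.mut_peptide, pr.wt_peptide)}]
        pcalls = calling.call_neoantigens(prs, sub, cfg)
        loads[pid] = calling.neoantigen_load(pcalls)
        calls.extend(pcalls)

    aio.write_calls_tsv(calls, pipe_dir / "calls.tsv")
    shared = calling.shared_neoantigens(calls, len(clinical))
    shared.to_csv(pipe_dir / "shared_neoantigens.tsv", sep="\t", index=False)
    shared.head(50).to_csv(
        ROOT / "results" / "shared_neoantigens_top50.tsv", sep="\t", index=False
    )
    summaries = summarize_patients(mutations, loads, clinical)
    aio.write_summaries_tsv(summaries, ROOT / "results" / "summaries.tsv")

    load_series = pd.Series(loads)
    print(
        f"{len(calls)} neoantigen calls; per-patient load median "
        f"{load_series.median():.0f} (range {load_series.min()}–{load_series.max()}); "
        f"top shared peptide in {shared.carrier_fraction.max() * 100:.1f}% of patients"
    )


if __name__ == "__main__":
    main()
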