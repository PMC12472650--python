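"""End-to-end orchestration: mutations → peptides → binding → calls → stats.

``run_pipeline`` chains the stages deterministically for a fixed
(config, seed): read and validate inputs, deduplicate mutations, enumerate
tiling nonamer pairs, calibrate allele-specific %Rank backgrounds, score and
filter neoantigen candidates, aggregate per-patient summaries, and write the
cohort statistics and survival tables together with a machine-readable run
report.  Mutations referencing a protein absent from the FASTA are skipped
with a warning and counted in the report (imperfect annotation tables must
not kill a run); a reference-residue mismatch aborts, since it signals a
corrupt table rather than a missing record.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import binding, calling, io, peptides, stats, survival

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Counts, warnings and output manifest of one pipeline run."""

    patients: int = 0
    mutations_read: int = 0
    mutations_deduped: int = 0
    mutations_skipped: int = 0
    peptide_pairs: int = 0
    binding_records: int = 0
    neoantigen_calls: int = 0
    summaries: int = 0
    stats_tables: int = 0
    warnings: list[str] = field(default_factory=list)
    manifest: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def run_pipeline(config: io.RunConfig) -> RunReport:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()

    # --- inputs
    proteome = io.read_proteome_fasta(config.proteome_path)
    by_id = {p.protein_id: p for p in proteome}
    raw_mutations = io.read_mutations_tsv(config.mutations_path)
    genotypes = io.read_hla_tsv(config.hla_path)
    clinical = io.read_clinical_tsv(config.clinical_path)
    report.patients = len(clinical)
    report.mutations_read = len(raw_mutations)

    mutations = []
    for m in peptides.dedupe_mutations(raw_mutations):
        if m.protein_id not in by_id:
            report.mutations_skipped += 1
            msg = f"mutation {m.patient_id}/{m.protein_id}:{m.position} references unknown protein; skipped"
            logger.warning(msg)
            report.warnings.append(msg)
            continue
        mutations.append(m)
    report.mutations_deduped = len(mutations)

    # --- peptide pairs
    pairs_by_patient: dict[str, list[peptides.PeptidePair]] = {}
    all_pairs: list[peptides.PeptidePair] = []
    for m in mutations:
        prs = peptides.enumerate_nonamer_pairs(by_id[m.protein_id], m)
        pairs_by_patient.setdefault(m.patient_id, []).extend(prs)
        all_pairs.extend(prs)
    report.peptide_pairs = len(all_pairs)

    # --- binding
    seedseq = np.random.SeedSequence(config.seed).spawn(2)
    predictor = binding.SurrogatePredictor(config.model_key, config.mixing)
    geno_by_patient = {g.patient_id: g for g in genotypes}
    external_records = (
        binding.read_binding_table(config.binding_path)
        if config.binding_path
        else None
    )
    calibrations: dict[str, binding.RankCalibration] = {}
    if external_records is None:
        distinct_alleles = sorted(
            {a for g in genotypes for a in g.distinct_alleles}
        )
        background = binding.sample_background_peptides(
            proteome, config.n_random, np.random.default_rng(seedseq[0])
        )
        for allele in distinct_alleles:
            calibrations[allele] = binding.calibrate_rank(
                allele, background, predictor=predictor
            )
        io.write_calibrations_tsv(calibrations, out / "calibrations.tsv")

    # --- calls per patient
    calls_by_patient: dict[str, list[calling.NeoantigenCall]] = {}
    all_calls: list[calling.NeoantigenCall] = []
    for pid, prs in sorted(pairs_by_patient.items()):
        if external_records is not None:
            records = external_records
        else:
            geno = geno_by_patient.get(pid)
            if geno is None:
                msg = f"patient {pid} has mutations but no HLA genotype; skipped"
                logger.warning(msg)
                report.warnings.append(msg)
                continue
            records = binding.predict_pairs(prs, geno, predictor, calibrations)
        report.binding_records += len(records)
        pcalls = calling.call_neoantigens(prs, records, config.filter)
        calls_by_patient[pid] = pcalls
        all_calls.extend(pcalls)
    report.neoantigen_calls = len(all_calls)

    # --- summaries
    loads = {
        pid: calling.neoantigen_load(c, unit=config.load_unit)
        for pid, c in calls_by_patient.items()
    }
    summaries = stats.summarize_patients(mutations, loads, clinical)
    report.summaries = len(summaries)

    io.write_calls_tsv(all_calls, out / "calls.tsv")
    io.write_summaries_tsv(summaries, out / "summaries.tsv")
    shared = calling.shared_neoantigens(all_calls, len(clinical))
    shared.to_csv(out / "shared_neoantigens.tsv", sep="\t", index=False)

    # --- cohort statistics
    stats_rng = np.random.default_rng(seedseq[1])
    for mode in ("carrier", "allelic"):
        stats.hla_frequencies(genotypes, mode=mode).to_csv(
            out / f"hla_{mode}.tsv", sep="\t", index=False
        )
    results: dict = {}
    try:
        corr = stats.correlate_tmb_load(summaries)
        results["correlation"] = dataclasses.asdict(corr)
    except ValueError as exc:
        report.warnings.append(f"correlation not computable: {exc}")
    rows = []
    for var in stats.GROUP_VARIABLES:
        try:
            for gc in stats.compare_groups(summaries, var, rng=stats_rng):
                rows.append(
                    {
                        "variable": gc.variable,
                        "outcome": gc.outcome,
                        "group1": gc.labels[0],
                        "group2": gc.labels[1],
                        "n1": gc.n[0],
                        "n2": gc.n[1],
                        "mean1": gc.means[0],
                        "mean2": gc.means[1],
                        "wilcoxon_u": gc.wilcoxon_u,
                        "wilcoxon_p": gc.wilcoxon_p,
                        "permutation_p": gc.permutation_p,
                        "permutation_iterations": gc.permutation_iterations,
                    }
                )
        except ValueError as exc:
            report.warnings.append(f"{var}: not computable ({exc})")
    pd.DataFrame(rows).to_csv(out / "group_comparisons.tsv", sep="\t", index=False)
    report.stats_tables = 3  # hla carrier + hla allelic + group comparisons

    # --- survival
    surv_results = {}
    load_vec = np.array([s.load for s in summaries], dtype=float)
    for endpoint in ("EFS", "OS"):
        recs = survival.survival_records(clinical, endpoint)
        km = survival.km_estimate(recs)
        pd.DataFrame(
            {
                "time": km.times,
                "n_at_risk": km.at_risk,
                "n_events": km.n_events,
                "survival": km.survival,
            }
        ).to_csv(out / f"km_{endpoint.lower()}.tsv", sep="\t", index=False)
        labels = survival.median_split_labels(load_vec)
        ga = [r for r, lab in zip(recs, labels) if lab == "low"]
        gb = [r for r, lab in zip(recs, labels) if lab == "high"]
        entry: dict = {}
        try:
            chi2, p = survival.logrank_test(ga, gb)
            entry["logrank_chi2"], entry["logrank_p"] = chi2, p
        except ValueError as exc:
            report.warnings.append(f"{endpoint} log-rank not computable: {exc}")
        times = np.array(
            [r.efs_time if endpoint == "EFS" else r.os_time for r in clinical]
        )
        events = np.array(
            [r.efs_event if endpoint == "EFS" else r.os_event for r in clinical]
        )
        try:
            sd = load_vec.std()
            cov = pd.DataFrame({"load_sd": (load_vec - load_vec.mean()) / sd})
            fit = survival.cox_fit(times, events, cov)
            entry["cox"] = {
                "converged": fit.converged,
                "coefficients": fit.coefficients,
                "standard_errors": fit.standard_errors,
                "hazard_ratios": fit.hazard_ratios,
            }
        except ValueError as exc:
            report.warnings.append(f"{endpoint} Cox not computable: {exc}")
        surv_results[endpoint] = entry
    results["survival"] = surv_results

    with open(out / "stats.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)

    report.manifest = {
        "calls": str(out / "calls.tsv"),
        "summaries": str(out / "summaries.tsv"),
        "shared_neoantigens": str(out / "shared_neoantigens.tsv"),
        "group_comparisons": str(out / "group_comparisons.tsv"),
        "hla_carrier": str(out / "hla_carrier.tsv"),
        "hla_allelic": str(out / "hla_allelic.tsv"),
        "km_efs": str(out / "km_efs.tsv"),
        "km_os": str(out / "km_os.tsv"),
        "stats": str(out / "stats.json"),
        "report": str(out / "report.json"),
    }
    report.to_json(out / "report.json")
    return report
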