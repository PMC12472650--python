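"""File formats: proteome FASTA and the pipeline's TSV dialects.

All tables are UTF-8, tab-delimited, header-keyed (column order free, strict
header validation), with 1-based protein positions on disk.  FASTA goes
through Biopython's SeqIO; the gene symbol rides in the description as
``gene=SYMBOL``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .binding import HLAGenotype, RankCalibration
from .calling import FilterConfig, NeoantigenCall
from .peptides import MissenseMutation, PeptidePair, ProteinRecord
from .simulate import ClinicalRecord, SyntheticCohort
from .stats import PatientSummary


class FormatError(ValueError):
    """A table or FASTA file does not match the expected dialect."""


def _read_tsv(path, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    missing = set(columns) - set(df.columns)
    if missing:
        raise FormatError(
            f"{path}: missing columns {sorted(missing)}; "
            f"expected {columns}, found {list(df.columns)}"
        )
    return df


# --- proteome FASTA ----------------------------------------------------------


def write_proteome_fasta(proteome: list[ProteinRecord], path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.protein_id, description=f"gene={p.gene}")
        for p in proteome
    ]
    SeqIO.write(records, str(path), "fasta")


def read_proteome_fasta(path) -> list[ProteinRecord]:
    proteome = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = rec.id
        for token in rec.description.split():
            if token.startswith("gene="):
                gene = token[5:]
        proteome.append(
            ProteinRecord(protein_id=rec.id, gene=gene, sequence=str(rec.seq))
        )
    if not proteome:
        raise FormatError(f"{path}: no FASTA records")
    return proteome


# --- mutations ---------------------------------------------------------------

MUTATION_COLUMNS = ["patient_id", "gene", "protein_id", "pos_1based", "ref_aa", "alt_aa"]


def write_mutations_tsv(mutations: list[MissenseMutation], path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": m.patient_id,
                "gene": m.gene,
                "protein_id": m.protein_id,
                "pos_1based": m.position,
                "ref_aa": m.ref_aa,
                "alt_aa": m.alt_aa,
            }
            for m in mutations
        ],
        columns=MUTATION_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_mutations_tsv(path) -> list[MissenseMutation]:
    df = _read_tsv(path, MUTATION_COLUMNS)
    return [
        MissenseMutation(
            patient_id=str(r.patient_id),
            gene=str(r.gene),
            protein_id=str(r.protein_id),
            position=int(r.pos_1based),
            ref_aa=str(r.ref_aa),
            alt_aa=str(r.alt_aa),
        )
        for r in df.itertuples(index=False)
    ]


# --- HLA genotypes -----------------------------------------------------------

HLA_COLUMNS = ["patient_id", "A1", "A2", "B1", "B2", "C1", "C2"]


def write_hla_tsv(genotypes: list[HLAGenotype], path) -> None:
    rows = []
    for g in genotypes:
        by_locus: dict[str, list[str]] = {"A": [], "B": [], "C": []}
        for a in g.alleles:
            by_locus[a[4]].append(a)
        rows.append(
            {
                "patient_id": g.patient_id,
                "A1": by_locus["A"][0],
                "A2": by_locus["A"][1],
                "B1": by_locus["B"][0],
                "B2": by_locus["B"][1],
                "C1": by_locus["C"][0],
                "C2": by_locus["C"][1],
            }
        )
    pd.DataFrame(rows, columns=HLA_COLUMNS).to_csv(path, sep="\t", index=False)


def read_hla_tsv(path) -> list[HLAGenotype]:
    df = _read_tsv(path, HLA_COLUMNS)
    return [
        HLAGenotype(
            patient_id=str(r.patient_id),
            alleles=(str(r.A1), str(r.A2), str(r.B1), str(r.B2), str(r.C1), str(r.C2)),
        )
        for r in df.itertuples(index=False)
    ]


# --- clinical ----------------------------------------------------------------

CLINICAL_COLUMNS = [
    "patient_id",
    "sex",
    "age_months",
    "wbc",
    "immunophenotype",
    "blast_pct",
    "efs_time",
    "efs_event",
    "os_time",
    "os_event",
]


def write_clinical_tsv(clinical: list[ClinicalRecord], path) -> None:
    pd.DataFrame(
        [dataclasses.asdict(c) for c in clinical], columns=CLINICAL_COLUMNS
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_clinical_tsv(path) -> list[ClinicalRecord]:
    df = _read_tsv(path, CLINICAL_COLUMNS)
    return [
        ClinicalRecord(
            patient_id=str(r.patient_id),
            sex=str(r.sex),
            age_months=float(r.age_months),
            wbc=float(r.wbc),
            immunophenotype=str(r.immunophenotype),
            blast_pct=float(r.blast_pct),
            efs_time=float(r.efs_time),
            efs_event=int(r.efs_event),
            os_time=float(r.os_time),
            os_event=int(r.os_event),
        )
        for r in df.itertuples(index=False)
    ]


# --- peptide pairs and calls -------------------------------------------------

PAIR_COLUMNS = [
    "patient_id",
    "gene",
    "protein_id",
    "pos_1based",
    "ref_aa",
    "alt_aa",
    "start",
    "register",
    "mut_peptide",
    "wt_peptide",
]


def write_pairs_tsv(pairs: list[PeptidePair], path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": p.mutation.patient_id,
                "gene": p.mutation.gene,
                "protein_id": p.mutation.protein_id,
                "pos_1based": p.mutation.position,
                "ref_aa": p.mutation.ref_aa,
                "alt_aa": p.mutation.alt_aa,
                "start": p.start,
                "register": p.register,
                "mut_peptide": p.mut_peptide,
                "wt_peptide": p.wt_peptide,
            }
            for p in pairs
        ],
        columns=PAIR_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path) -> list[PeptidePair]:
    df = _read_tsv(path, PAIR_COLUMNS)
    return [
        PeptidePair(
            mutation=MissenseMutation(
                patient_id=str(r.patient_id),
                gene=str(r.gene),
                protein_id=str(r.protein_id),
                position=int(r.pos_1based),
                ref_aa=str(r.ref_aa),
                alt_aa=str(r.alt_aa),
            ),
            start=int(r.start),
            register=int(r.register),
            mut_peptide=str(r.mut_peptide),
            wt_peptide=str(r.wt_peptide),
        )
        for r in df.itertuples(index=False)
    ]


CALL_COLUMNS = [
    "patient_id",
    "gene",
    "protein_id",
    "pos_1based",
    "mut_peptide",
    "allele",
    "mut_ic50",
    "mut_rank",
    "wt_ic50",
    "dai",
]


def write_calls_tsv(calls: list[NeoantigenCall], path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": c.patient_id,
                "gene": c.mutation.gene,
                "protein_id": c.mutation.protein_id,
                "pos_1based": c.mutation.position,
                "mut_peptide": c.mut_peptide,
                "allele": c.allele,
                "mut_ic50": c.mut_ic50,
                "mut_rank": c.mut_rank,
                "wt_ic50": c.wt_ic50,
                "dai": c.dai,
            }
            for c in calls
        ],
        columns=CALL_COLUMNS,
    ).to_csv(path, sep="\t", index=False, float_format="%.4f")


# --- per-patient summaries ---------------------------------------------------

SUMMARY_COLUMNS = [
    "patient_id",
    "tmb",
    "load",
    "mmr_status",
    "sex",
    "age_months",
    "wbc",
    "immunophenotype",
    "blast_pct",
    "nci_risk",
    "efs_time",
    "efs_event",
    "os_time",
    "os_event",
]


def write_summaries_tsv(summaries: list[PatientSummary], path) -> None:
    pd.DataFrame(
        [dataclasses.asdict(s) for s in summaries], columns=SUMMARY_COLUMNS
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_summaries_tsv(path) -> list[PatientSummary]:
    df = _read_tsv(path, SUMMARY_COLUMNS)
    return [
        PatientSummary(
            patient_id=str(r.patient_id),
            tmb=int(r.tmb),
            load=int(r.load),
            mmr_status=str(r.mmr_status),
            sex=str(r.sex),
            age_months=float(r.age_months),
            wbc=float(r.wbc),
            immunophenotype=str(r.immunophenotype),
            blast_pct=float(r.blast_pct),
            nci_risk=str(r.nci_risk),
            efs_time=float(r.efs_time),
            efs_event=int(r.efs_event),
            os_time=float(r.os_time),
            os_event=int(r.os_event),
        )
        for r in df.itertuples(index=False)
    ]


# --- calibration cache (text) ------------------------------------------------


def write_calibrations_tsv(calibrations: dict[str, RankCalibration], path) -> None:
    """Long-format text cache: one (allele, ic50_nm) row per reference value."""
    frames = [
        pd.DataFrame({"allele": allele, "ic50_nm": cal.reference})
        for allele, cal in sorted(calibrations.items())
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_calibrations_tsv(path) -> dict[str, RankCalibration]:
    df = _read_tsv(path, ["allele", "ic50_nm"])
    out = {}
    for allele, grp in df.groupby("allele"):
        vals = np.sort(grp["ic50_nm"].to_numpy(dtype=float))
        out[str(allele)] = RankCalibration(
            allele=str(allele), reference=vals, n_random=len(vals)
        )
    return out


# --- cohort bundle -----------------------------------------------------------


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict[str, str]:
    """Serialize a synthetic cohort; returns the file manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "proteome": str(out / "proteome.fasta"),
        "mutations": str(out / "mutations.tsv"),
        "hla": str(out / "hla.tsv"),
        "clinical": str(out / "clinical.tsv"),
        "truth": str(out / "truth.json"),
    }
    write_proteome_fasta(cohort.proteome, manifest["proteome"])
    write_mutations_tsv(cohort.mutations, manifest["mutations"])
    write_hla_tsv(cohort.genotypes, manifest["hla"])
    write_clinical_tsv(cohort.clinical, manifest["clinical"])
    with open(manifest["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=2, sort_keys=True)
    return manifest


# --- run configuration -------------------------------------------------------


@dataclass
class RunConfig:
    """Paths and parameters of one end-to-end pipeline run."""

    proteome_path: str
    mutations_path: str
    hla_path: str
    clinical_path: str
    out_dir: str
    binding_path: str | None = None  # external NetMHC-style table, optional
    filter: FilterConfig = field(default_factory=FilterConfig)
    n_random: int = 5000  # %Rank background size (production scale: 200000)
    model_key: str = "surrogate-v1"
    mixing: float = 0.0
    load_unit: str = "peptide_allele"
    seed: int = 0

    def validate(self) -> None:
        for name in ("proteome_path", "mutations_path", "hla_path", "clinical_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FormatError(f"{name}: {p} does not exist")
        if self.binding_path and not Path(self.binding_path).exists():
            raise FormatError(f"binding_path: {self.binding_path} does not exist")


def load_run_config(path) -> RunConfig:
    """Read a RunConfig from a YAML file (nested ``filter`` section allowed)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    filt = FilterConfig(**raw.pop("filter", {}))
    return RunConfig(filter=filt, **raw)
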