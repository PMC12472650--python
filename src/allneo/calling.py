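"""Neoantigen calling: binder thresholds, wild-type exclusion, load counts.

A candidate mutant 9-mer is called a (potential) neoantigen for a patient when
it binds at least one of the patient's HLA class-I alleles — predicted IC50
strictly below 500 nM or %Rank strictly below 2% — and its binding differs
from that of its wild-type counterpart.  The difference in affinity between
wild type and mutant is the differential agretopic index, DAI = wt_ic50 −
mut_ic50 (positive when the mutant binds more strongly); candidates whose
mutant and wild-type affinities coincide (relative difference within a small
tolerance) are excluded, since such peptides give the immune system nothing
tumor-specific to see.

One mutation can yield several neoantigens — different registers, different
alleles — so the per-patient load counts unique (peptide, allele) pairs by
default (a unique-peptide mode is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .binding import BindingRecord
from .peptides import MissenseMutation, PeptidePair


class PairingError(ValueError):
    """A mutant record lacks its wild-type partner (or vice versa)."""


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the neoantigen definition.

    ``ic50_threshold`` (nM) and ``rank_threshold`` (%) are strict upper
    bounds; ``dai_tolerance`` is the relative IC50 difference below which
    mutant and wild type count as "same affinity" and the candidate is
    excluded (default 1e-6, i.e. equality at reported precision).
    """

    ic50_threshold: float = 500.0
    rank_threshold: float = 2.0
    dai_tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if self.ic50_threshold <= 0 or self.rank_threshold <= 0:
            raise ValueError("thresholds must be > 0")
        if self.dai_tolerance < 0:
            raise ValueError("dai_tolerance must be >= 0")


@dataclass(frozen=True)
class NeoantigenCall:
    patient_id: str
    mutation: MissenseMutation
    mut_peptide: str
    allele: str
    mut_ic50: float
    mut_rank: float
    wt_ic50: float
    dai: float


def is_binder(record: BindingRecord, cfg: FilterConfig) -> bool:
    """Binder rule: IC50 < threshold OR %Rank < threshold, both strict."""
    return record.ic50 < cfg.ic50_threshold or record.rank_pct < cfg.rank_threshold


def compute_dai(mut_ic50: float, wt_ic50: float) -> float:
    """DAI = wt_ic50 − mut_ic50 (nM); positive ⇒ mutant binds more strongly."""
    if mut_ic50 <= 0 or wt_ic50 <= 0:
        raise ValueError("affinities must be > 0 nM")
    return wt_ic50 - mut_ic50


def call_neoantigens(
    pairs: list[PeptidePair],
    records: list[BindingRecord],
    cfg: FilterConfig,
) -> list[NeoantigenCall]:
    """Apply the full neoantigen definition to scored peptide pairs.

    For every (pair, allele) with both mutant and wild-type records: keep it
    when the mutant record passes :func:`is_binder` and the mutant/wild-type
    affinities differ by more than ``dai_tolerance`` relative to the wild
    type.  Identical (patient, mut_peptide, allele) triples arising from
    different mutations or registers are deduplicated (first occurrence kept,
    pairs processed in input order).

    ``records`` must cover every peptide of every pair for every allele
    present in ``records``; a mutant without its wild-type partner raises
    :class:`PairingError`.
    """
    if not pairs:
        return []
    index: dict[tuple[str, str], BindingRecord] = {}
    alleles: set[str] = set()
    for r in records:
        index[(r.peptide, r.allele)] = r
        alleles.add(r.allele)
    calls: list[NeoantigenCall] = []
    seen: set[tuple[str, str, str]] = set()
    for pair in pairs:
        patient = pair.mutation.patient_id
        for allele in sorted(alleles):
            mut_rec = index.get((pair.mut_peptide, allele))
            if mut_rec is None:
                continue
            wt_rec = index.get((pair.wt_peptide, allele))
            if wt_rec is None:
                raise PairingError(
                    f"no wild-type record for {pair.wt_peptide}/{allele} "
                    f"(mutant {pair.mut_peptide})"
                )
            if not is_binder(mut_rec, cfg):
                continue
            if abs(mut_rec.ic50 - wt_rec.ic50) <= cfg.dai_tolerance * wt_rec.ic50:
                continue  # same affinity as wild type → excluded
            key = (patient, pair.mut_peptide, allele)
            if key in seen:
                continue
            seen.add(key)
            calls.append(
                NeoantigenCall(
                    patient_id=patient,
                    mutation=pair.mutation,
                    mut_peptide=pair.mut_peptide,
                    allele=allele,
                    mut_ic50=mut_rec.ic50,
                    mut_rank=mut_rec.rank_pct,
                    wt_ic50=wt_rec.ic50,
                    dai=compute_dai(mut_rec.ic50, wt_rec.ic50),
                )
            )
    return calls


def neoantigen_load(
    calls: list[NeoantigenCall], unit: str = "peptide_allele"
) -> int:
    """Per-patient neoantigen load.

    ``unit="peptide_allele"`` (default) counts unique (mut_peptide, allele)
    pairs — one peptide presented by three alleles counts three times;
    ``unit="peptide"`` counts unique peptides.  All calls must belong to one
    patient.
    """
    if not calls:
        return 0
    patients = {c.patient_id for c in calls}
    if len(patients) > 1:
        raise ValueError(f"calls span multiple patients: {sorted(patients)}")
    if unit == "peptide_allele":
        return len({(c.mut_peptide, c.allele) for c in calls})
    if unit == "peptide":
        return len({c.mut_peptide for c in calls})
    raise ValueError(f"unknown load unit {unit!r}")


def shared_neoantigens(
    calls: list[NeoantigenCall], n_patients: int
) -> pd.DataFrame:
    """Carrier fraction per neoantigen peptide across the cohort.

    Returns a DataFrame (mut_peptide, n_carriers, carrier_fraction) sorted by
    descending fraction then peptide; a patient contributing the same peptide
    through several alleles or mutations counts once.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    carriers: dict[str, set[str]] = {}
    for c in calls:
        carriers.setdefault(c.mut_peptide, set()).add(c.patient_id)
    df = pd.DataFrame(
        [
            {
                "mut_peptide": pep,
                "n_carriers": len(pats),
                "carrier_fraction": len(pats) / n_patients,
            }
            for pep, pats in carriers.items()
        ],
        columns=["mut_peptide", "n_carriers", "carrier_fraction"],
    )
    return df.sort_values(
        ["carrier_fraction", "mut_peptide"], ascending=[False, True]
    ).reset_index(drop=True)
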