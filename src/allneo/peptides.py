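"""Missense mutations on protein sequences and tiling nonamer extraction.

An HLA class-I epitope is canonically nine residues long, so a single amino-acid
substitution at protein position ``p`` can surface in up to nine distinct 9-mer
windows — every window whose 1-based start lies in ``[p-8, p]`` and that fits
inside the protein.  Each mutant window is paired with the corresponding
wild-type window from the reference sequence; downstream binding prediction
scores both members of the pair so that the wild-type affinity is always
available for the differential (DAI) exclusion filter.

Protein coordinates are 1-based inclusive (HGVS-style, as mutation tables are
written); the register of the mutated residue within a peptide is 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PEPTIDE_LENGTH = 9

_AA_SET = frozenset(AMINO_ACIDS)


class MutationError(ValueError):
    """A mutation is inconsistent with its reference protein."""


@dataclass(frozen=True)
class ProteinRecord:
    """A reference protein: identifier, gene symbol, amino-acid sequence."""

    protein_id: str
    gene: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise ValueError(
                f"{self.protein_id}: non-standard residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MissenseMutation:
    """One somatic protein-level substitution in one patient.

    ``position`` is 1-based.  The count of distinct objects of this type per
    patient is the tumor mutational burden (TMB) used throughout the cohort
    statistics.
    """

    patient_id: str
    protein_id: str
    gene: str
    position: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise MutationError(f"position must be >= 1, got {self.position}")
        if self.ref_aa == self.alt_aa:
            raise MutationError(
                f"{self.protein_id}:{self.position} ref == alt ({self.ref_aa}); "
                "not a missense change"
            )


@dataclass(frozen=True)
class PeptidePair:
    """A mutant 9-mer with its wild-type counterpart.

    ``start`` is the 1-based start of the window in the protein; ``register``
    is the 0-based offset of the mutated residue within the peptide, so
    ``register == mutation.position - start``.
    """

    mutation: MissenseMutation
    mut_peptide: str
    wt_peptide: str
    start: int
    register: int


def apply_missense(
    protein: ProteinRecord, position: int, ref_aa: str, alt_aa: str
) -> str:
    """Return the protein sequence with ``ref_aa`` at ``position`` replaced by
    ``alt_aa``.

    Raises ``MutationError`` if the position falls outside the sequence, if the
    reference residue disagrees with the sequence (a corrupt mutation table),
    or if ref equals alt.
    """
    if not 1 <= position <= len(protein):
        raise MutationError(
            f"{protein.protein_id}: position {position} outside 1..{len(protein)}"
        )
    if ref_aa == alt_aa:
        raise MutationError(f"ref_aa == alt_aa ({ref_aa}); not a missense change")
    found = protein.sequence[position - 1]
    if found != ref_aa:
        raise MutationError(
            f"{protein.protein_id}:{position} reference mismatch: "
            f"table says {ref_aa}, sequence has {found}"
        )
    return protein.sequence[: position - 1] + alt_aa + protein.sequence[position:]


def enumerate_nonamer_pairs(
    protein: ProteinRecord, mutation: MissenseMutation
) -> list[PeptidePair]:
    """Enumerate every mutant/wild-type nonamer pair overlapping a mutation.

    Window starts run over ``[max(1, p-8), min(p, L-8)]`` (1-based) for a
    mutation at position ``p`` in a protein of length ``L``: mutations at least
    eight residues from both termini yield exactly nine pairs; near a terminus
    the window set shrinks rather than being padded.  Proteins shorter than
    nine residues cannot host a nonamer and yield an empty list (with a logged
    warning).
    """
    L = len(protein)
    if L < PEPTIDE_LENGTH:
        logger.warning(
            "%s: length %d < %d, no nonamer windows",
            protein.protein_id,
            L,
            PEPTIDE_LENGTH,
        )
        return []
    mutant_seq = apply_missense(
        protein, mutation.position, mutation.ref_aa, mutation.alt_aa
    )
    p = mutation.position
    pairs = []
    for start in range(max(1, p - 8), min(p, L - PEPTIDE_LENGTH + 1) + 1):
        i = start - 1
        wt = protein.sequence[i : i + PEPTIDE_LENGTH]
        mut = mutant_seq[i : i + PEPTIDE_LENGTH]
        pairs.append(
            PeptidePair(
                mutation=mutation,
                mut_peptide=mut,
                wt_peptide=wt,
                start=start,
                register=p - start,
            )
        )
    return pairs


def dedupe_mutations(mutations: list[MissenseMutation]) -> list[MissenseMutation]:
    """Drop exact duplicate somatic events, preserving first-seen order.

    TMB counts distinct somatic events, so identical (patient, protein,
    position, alt) rows — common in concatenated annotation tables — collapse
    to one.
    """
    seen: set[tuple[str, str, int, str]] = set()
    out = []
    for m in mutations:
        key = (m.patient_id, m.protein_id, m.position, m.alt_aa)
        if key not in seen:
            seen.add(key)
            out.append(m)
    return out
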