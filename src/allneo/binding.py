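"""Peptide–HLA class-I binding: surrogate predictor, %Rank calibration, IO.

Real pipelines obtain IC50 affinities from a neural-network predictor
(NetMHC-family tools).  This module defines the binding *contract* the rest of
the pipeline consumes: a :class:`BindingRecord` per (peptide, allele), an
empirical %Rank computed against a background of random natural 9-mers, and a
reader for externally produced NetMHC-style score tables.

The built-in :class:`SurrogatePredictor` is a deterministic, reproducible
affinity oracle — a keyed hash of (peptide, allele) mapped to a log-uniform
IC50 on [1, 50000] nM — not a biological model.  It gives the pipeline exactly
the statistical properties the cohort analysis needs (stable values, a
controllable binder rate through the filter thresholds, and a definitionally
calibrated %Rank) without shipping or re-training a neural network.  A
``mixing`` parameter couples a mutant peptide's log-affinity to its wild-type
counterpart's, so the wild-type-exclusion (DAI) filter has non-trivial
behavior when desired; by default the two are independent.
"""

from __future__ import annotations

import hashlib
import math
import re
from dataclasses import dataclass, field

import numpy as np

from .peptides import PEPTIDE_LENGTH, PeptidePair, ProteinRecord

ALLELE_RE = re.compile(r"^HLA-[ABC]\*\d{2}:\d{2,3}$")

#: IC50 ceiling of the surrogate (nM); NetMHC-style tools report up to 50 µM.
IC50_MAX_NM = 50_000.0
_LOG10_IC50_MAX = math.log10(IC50_MAX_NM)

#: Background size used in production-scale %Rank calibration.
N_RANDOM_PRODUCTION = 200_000
#: Desk-scale default used by the bundled pipeline configuration.
N_RANDOM_DEFAULT = 5_000


class AlleleError(ValueError):
    """Malformed HLA allele name or genotype."""


class CalibrationError(ValueError):
    """%Rank calibration could not be built."""


class BindingTableError(ValueError):
    """A NetMHC-style binding table is malformed."""


@dataclass(frozen=True)
class HLAGenotype:
    """Six class-I alleles (two each at HLA-A, -B, -C) for one patient."""

    patient_id: str
    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.alleles) != 6:
            raise AlleleError(
                f"{self.patient_id}: expected 6 alleles, got {len(self.alleles)}"
            )
        per_locus: dict[str, int] = {"A": 0, "B": 0, "C": 0}
        for a in self.alleles:
            if not ALLELE_RE.match(a):
                raise AlleleError(f"{self.patient_id}: bad allele name {a!r}")
            per_locus[a[4]] += 1
        if any(n != 2 for n in per_locus.values()):
            raise AlleleError(
                f"{self.patient_id}: need exactly 2 alleles per locus, "
                f"got {per_locus}"
            )

    @property
    def distinct_alleles(self) -> tuple[str, ...]:
        """Distinct alleles, sorted; homozygous loci contribute one entry."""
        return tuple(sorted(set(self.alleles)))


@dataclass(frozen=True)
class BindingRecord:
    peptide: str
    allele: str
    ic50: float
    rank_pct: float

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise BindingTableError(f"ic50 must be > 0, got {self.ic50}")
        if not 0.0 <= self.rank_pct <= 100.0:
            raise BindingTableError(f"rank_pct outside [0,100]: {self.rank_pct}")


@dataclass(frozen=True)
class RankCalibration:
    """Sorted surrogate IC50s of ``n_random`` background 9-mers for one allele.

    A query peptide's %Rank is the percentage of background peptides with a
    strictly lower (stronger) IC50 — "top x%" semantics, allele-specific.
    """

    allele: str
    reference: np.ndarray = field(repr=False)
    n_random: int

    def __post_init__(self) -> None:
        if self.n_random < 100:
            raise CalibrationError("n_random must be >= 100")
        if len(self.reference) != self.n_random:
            raise CalibrationError("reference length != n_random")
        if np.any(np.diff(self.reference) < 0):
            raise CalibrationError("reference values must be sorted ascending")


# --- surrogate predictor -----------------------------------------------------

_FNV_OFFSET = np.uint64(0xCBF29CE484222325)
_FNV_PRIME = np.uint64(0x100000001B3)


def _splitmix64(h: np.ndarray) -> np.ndarray:
    h = (h ^ (h >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    h = (h ^ (h >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return h ^ (h >> np.uint64(31))


def _hash_units(peptides: np.ndarray, allele: str, model_key: str) -> np.ndarray:
    """Map an (N, 9) uint8 array of peptides to uniform variates in [0, 1).

    FNV-1a over the residue bytes, keyed by a digest of (model_key, allele),
    finalized with splitmix64 for equidistribution.  Pure and stable across
    runs and platforms.
    """
    key = hashlib.blake2b(
        f"{model_key}|{allele}".encode(), digest_size=8
    ).digest()
    seed = np.uint64(int.from_bytes(key, "big"))
    with np.errstate(over="ignore"):
        h = np.full(peptides.shape[0], _FNV_OFFSET, dtype=np.uint64)
        for j in range(peptides.shape[1]):
            h = (h ^ peptides[:, j].astype(np.uint64)) * _FNV_PRIME
        h = _splitmix64(h ^ seed)
    return h / np.float64(2**64)


def _encode(peptides: list[str]) -> np.ndarray:
    arr = np.frombuffer(
        "".join(peptides).encode("ascii"), dtype=np.uint8
    ).reshape(len(peptides), PEPTIDE_LENGTH)
    return arr


class SurrogatePredictor:
    """Deterministic stand-in affinity oracle.

    IC50 = 10**(u * log10(50000)) nM, with u a keyed-hash uniform variate of
    (peptide, allele) — log10(IC50) is uniform on [0, log10(50000)].  The same
    (peptide, allele, model_key) always yields the same value.

    Parameters
    ----------
    model_key:
        Namespaces the hash; different keys behave as independent predictors.
    mixing:
        In ``score_pair``, the mutant log-affinity is blended with the
        wild-type's: ``log_mut_eff = (1-mixing)*log_mut + mixing*log_wt``.
        0 (default) leaves mutant and wild type independent; 1 makes every
        mutant bind exactly like its wild-type counterpart, so the DAI filter
        removes everything.
    """

    def __init__(self, model_key: str = "surrogate-v1", mixing: float = 0.0):
        if not 0.0 <= mixing <= 1.0:
            raise ValueError(f"mixing must be in [0,1], got {mixing}")
        self.model_key = model_key
        self.mixing = mixing

    def ic50_batch(self, peptides: list[str], allele: str) -> np.ndarray:
        """Vectorized IC50 (nM) for many 9-mers against one allele."""
        if not peptides:
            return np.empty(0)
        for p in peptides:
            if len(p) != PEPTIDE_LENGTH:
                raise ValueError(f"peptide {p!r} is not a 9-mer")
        u = _hash_units(_encode(peptides), allele, self.model_key)
        return 10.0 ** (u * _LOG10_IC50_MAX)

    def ic50(self, peptide: str, allele: str) -> float:
        """IC50 (nM) of one 9-mer against one allele."""
        return float(self.ic50_batch([peptide], allele)[0])

    def score_pair(
        self, mut_peptide: str, wt_peptide: str, allele: str
    ) -> tuple[float, float]:
        """(mut_ic50, wt_ic50) with optional mutant→wild-type coupling."""
        wt = self.ic50(wt_peptide, allele)
        mut = self.ic50(mut_peptide, allele)
        if self.mixing > 0.0:
            log_mut = (1.0 - self.mixing) * math.log10(mut) + self.mixing * math.log10(wt)
            mut = 10.0**log_mut
        return mut, wt


def surrogate_ic50(
    peptide: str, allele: str, model_key: str = "surrogate-v1"
) -> float:
    """Functional shorthand for :meth:`SurrogatePredictor.ic50`."""
    return SurrogatePredictor(model_key).ic50(peptide, allele)


# --- %Rank calibration -------------------------------------------------------


def sample_background_peptides(
    proteome: list[ProteinRecord], n: int, rng: np.random.Generator
) -> list[str]:
    """Draw ``n`` distinct random natural 9-mers from a proteome.

    All distinct 9-residue windows of the proteome form the candidate pool; a
    uniform sample without replacement of size ``n`` is returned.  Raises
    ``CalibrationError`` if the proteome holds fewer than ``n`` distinct
    windows.
    """
    pool: set[str] = set()
    for prot in proteome:
        seq = prot.sequence
        for i in range(len(seq) - PEPTIDE_LENGTH + 1):
            pool.add(seq[i : i + PEPTIDE_LENGTH])
    if len(pool) < n:
        raise CalibrationError(
            f"proteome yields {len(pool)} distinct 9-mers < requested {n}"
        )
    ordered = sorted(pool)  # stable order before sampling → reproducible
    idx = rng.choice(len(ordered), size=n, replace=False)
    return [ordered[i] for i in idx]


def calibrate_rank(
    allele: str,
    background_peptides: list[str],
    n_random: int | None = None,
    predictor: SurrogatePredictor | None = None,
) -> RankCalibration:
    """Build the empirical %Rank reference for one allele.

    Scores ``n_random`` background 9-mers (defaults to all supplied) with the
    predictor and stores them sorted ascending.
    """
    predictor = predictor or SurrogatePredictor()
    n_random = n_random if n_random is not None else len(background_peptides)
    if len(background_peptides) < n_random:
        raise CalibrationError(
            f"{len(background_peptides)} background peptides < n_random={n_random}"
        )
    values = predictor.ic50_batch(background_peptides[:n_random], allele)
    return RankCalibration(
        allele=allele, reference=np.sort(values), n_random=n_random
    )


def percent_rank(ic50: float, calibration: RankCalibration) -> float:
    """%Rank of an IC50: 100 × (#reference strictly below) / n_random.

    Ties count as not-lower, so a peptide exactly at a reference value is not
    credited with outranking it; monotone non-decreasing in ic50.
    """
    below = int(np.searchsorted(calibration.reference, ic50, side="left"))
    return 100.0 * below / calibration.n_random


def percent_rank_batch(
    ic50s: np.ndarray, calibration: RankCalibration
) -> np.ndarray:
    below = np.searchsorted(calibration.reference, ic50s, side="left")
    return 100.0 * below / calibration.n_random


# --- scoring pair sets -------------------------------------------------------


def predict_pairs(
    pairs: list[PeptidePair],
    genotype: HLAGenotype,
    predictor: SurrogatePredictor,
    calibrations: dict[str, RankCalibration],
) -> list[BindingRecord]:
    """Score every distinct peptide of a pair set against every distinct
    allele of a genotype.

    Mutant and wild-type members of a pair are always scored against the same
    allele set.  Each distinct peptide is scored once per allele; with the
    generic disjoint mutant/wild-type sets the output holds
    (|distinct mut| + |distinct wt|) × |distinct alleles| records.  When the
    predictor couples mutant to wild-type affinities (mixing > 0) the mutant
    records carry the blended value of the pair in which the peptide first
    appears; in the pathological case of a peptide occurring both as a mutant
    and as a wild type, the mutant-role value is the one reported.
    """
    if not pairs:
        return []
    mut_set: dict[str, str] = {}
    wt_set: set[str] = set()
    for pr in pairs:
        mut_set.setdefault(pr.mut_peptide, pr.wt_peptide)
        wt_set.add(pr.wt_peptide)
    wt_only = sorted(wt_set - set(mut_set))
    muts = sorted(mut_set)
    records: list[BindingRecord] = []
    for allele in genotype.distinct_alleles:
        cal = calibrations[allele]
        wt_pepts = sorted(wt_set)
        wt_vals = dict(zip(wt_pepts, predictor.ic50_batch(wt_pepts, allele)))
        mut_vals = predictor.ic50_batch(muts, allele)
        if predictor.mixing > 0.0:
            partner = np.array([wt_vals[mut_set[m]] for m in muts])
            mut_vals = 10.0 ** (
                (1.0 - predictor.mixing) * np.log10(mut_vals)
                + predictor.mixing * np.log10(partner)
            )
        peptides = muts + wt_only
        values = np.concatenate(
            [mut_vals, np.array([wt_vals[p] for p in wt_only])]
        ) if wt_only else mut_vals
        ranks = percent_rank_batch(values, cal)
        records.extend(
            BindingRecord(peptide=p, allele=allele, ic50=float(v), rank_pct=float(r))
            for p, v, r in zip(peptides, values, ranks)
        )
    return records


# --- NetMHC-style table IO ---------------------------------------------------

BINDING_COLUMNS = ["peptide", "allele", "ic50_nm", "rank_pct"]


def read_binding_table(path) -> list[BindingRecord]:
    """Read a NetMHC-style TSV (peptide, allele, ic50_nm, rank_pct).

    Header-keyed (column order free).  Malformed rows are rejected together
    with their 1-based line numbers.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(BINDING_COLUMNS) - set(df.columns)
    if missing:
        raise BindingTableError(
            f"{path}: missing columns {sorted(missing)}; "
            f"expected {BINDING_COLUMNS}, found {list(df.columns)}"
        )
    records = []
    bad: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after header
        try:
            rec = BindingRecord(
                peptide=str(row.peptide),
                allele=str(row.allele),
                ic50=float(row.ic50_nm),
                rank_pct=float(row.rank_pct),
            )
        except (BindingTableError, ValueError, TypeError) as exc:
            bad.append((line, str(exc)))
            continue
        records.append(rec)
    if bad:
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in bad[:10])
        raise BindingTableError(f"{path}: {len(bad)} malformed row(s): {detail}")
    return records


def write_binding_table(records: list[BindingRecord], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "peptide": r.peptide,
                "allele": r.allele,
                "ic50_nm": r.ic50,
                "rank_pct": r.rank_pct,
            }
            for r in records
        ],
        columns=BINDING_COLUMNS,
    ).to_csv(path, sep="\t", index=False)
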