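"""Cohort-level statistics: TMB, HLA frequencies, correlations, group tests.

The analyses mirror a standard tumor-cohort workup: tumor mutational burden
(TMB, distinct somatic missense mutations per patient) against neoantigen
load; per-allele HLA frequencies on both carrier and allelic denominators
(cohort reports mix the two, hence the explicit mode); two-group comparisons
of burden and load across clinical strata with a rank test and a permutation
test with lmPerm-style adaptive stopping; the NCI age/WBC risk dichotomy; and
mismatch-repair (MMR) stratification by the presence of any missense mutation
in MSH2, MSH6, MLH1 or PMS2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .binding import HLAGenotype
from .peptides import MissenseMutation
from .simulate import MMR_GENES, ClinicalRecord


@dataclass(frozen=True)
class PatientSummary:
    """One row of the analysis table: burden, load, strata, outcomes."""

    patient_id: str
    tmb: int
    load: int
    mmr_status: str  # "MUT" | "WT"
    sex: str
    age_months: float
    wbc: float
    immunophenotype: str
    blast_pct: float
    nci_risk: str  # "standard" | "high"
    efs_time: float = float("nan")
    efs_event: int = 0
    os_time: float = float("nan")
    os_event: int = 0


@dataclass(frozen=True)
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    slope: float
    intercept: float


@dataclass(frozen=True)
class PermutationResult:
    p_value: float
    iterations: int
    observed: float
    se: float


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    outcome: str  # "tmb" | "load"
    labels: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    wilcoxon_u: float
    wilcoxon_p: float
    permutation_p: float
    permutation_iterations: int


def tmb(mutations: Sequence[MissenseMutation]) -> int:
    """Distinct somatic missense events (the TMB unit of this analysis)."""
    return len(
        {(m.patient_id, m.protein_id, m.position, m.alt_aa) for m in mutations}
    )


def mmr_status(mutations: Sequence[MissenseMutation]) -> str:
    """"MUT" iff any mutation hits MSH2/MSH6/MLH1/PMS2 (case-insensitive)."""
    genes = {g.upper() for g in MMR_GENES}
    for m in mutations:
        if m.gene.upper() in genes:
            return "MUT"
    return "WT"


def classify_nci_risk(age_months: float, wbc: float) -> str:
    """NCI risk dichotomy for pediatric ALL.

    High risk when any high-risk criterion holds — age under 1 year, age 10
    years or older, or WBC >= 50,000/µL — standard risk otherwise.  (The
    criteria are canonically stated with an inconsistent or/and pairing
    between the two arms; the implemented rule is the internally consistent
    one that matches the high-risk clause.)
    """
    if age_months < 0 or wbc < 0:
        raise ValueError("age and WBC must be non-negative")
    if age_months < 12 or age_months >= 120 or wbc >= 50_000:
        return "high"
    return "standard"


def hla_frequencies(
    genotypes: Sequence[HLAGenotype], mode: str = "carrier"
) -> pd.DataFrame:
    """Per-allele frequency table.

    ``carrier`` mode: fraction of patients carrying >= 1 copy (homozygotes
    count once).  ``allelic`` mode: copies / (2 × n_patients) per locus, so
    each locus sums to 1 exactly.  Returns columns (locus, allele, count,
    frequency) sorted by locus then descending frequency.
    """
    if not genotypes:
        raise ValueError("need at least one genotype")
    if mode not in ("carrier", "allelic"):
        raise ValueError(f"unknown mode {mode!r}")
    n = len(genotypes)
    rows = []
    if mode == "carrier":
        carriers: dict[str, set[str]] = {}
        for g in genotypes:
            for a in set(g.alleles):
                carriers.setdefault(a, set()).add(g.patient_id)
        for allele, pats in carriers.items():
            rows.append(
                {
                    "locus": allele[4],
                    "allele": allele,
                    "count": len(pats),
                    "frequency": len(pats) / n,
                }
            )
    else:
        copies: dict[str, int] = {}
        for g in genotypes:
            for a in g.alleles:
                copies[a] = copies.get(a, 0) + 1
        for allele, c in copies.items():
            rows.append(
                {
                    "locus": allele[4],
                    "allele": allele,
                    "count": c,
                    "frequency": c / (2 * n),
                }
            )
    df = pd.DataFrame(rows, columns=["locus", "allele", "count", "frequency"])
    return df.sort_values(
        ["locus", "frequency", "allele"], ascending=[True, False, True]
    ).reset_index(drop=True)


def correlate_tmb_load(summaries: Sequence[PatientSummary]) -> CorrelationResult:
    """Pearson R (via linear regression) and Spearman rho of load on TMB."""
    if len(summaries) < 3:
        raise ValueError("need at least 3 patients")
    x = np.array([s.tmb for s in summaries], dtype=float)
    y = np.array([s.load for s in summaries], dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    lin = sps.linregress(x, y)
    rho, rho_p = sps.spearmanr(x, y)
    return CorrelationResult(
        pearson_r=float(lin.rvalue),
        pearson_p=float(lin.pvalue),
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        slope=float(lin.slope),
        intercept=float(lin.intercept),
    )


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon–Mann–Whitney test.

    Exact null enumeration for combined n <= 10 without ties; normal
    approximation with tie correction otherwise.  Returns (U of group A, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (pooled.size <= 10 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _mean_difference(a: np.ndarray, b: np.ndarray) -> float:
    return float(a.mean() - b.mean())


def permutation_test(
    values: Sequence[float],
    labels: Sequence,
    statistic: Callable[[np.ndarray, np.ndarray], float] | None = None,
    max_iter: int = 5000,
    se_stop_frac: float = 0.1,
    rng: np.random.Generator | int | None = None,
    batch: int = 250,
) -> PermutationResult:
    """Two-group permutation test with adaptive stopping.

    The statistic (default: difference of group means) is evaluated on the
    observed labeling and on random relabelings; the two-sided p-value is the
    add-one-smoothed tail fraction ``(1 + #{|stat*| >= |stat|}) / (1 + m)``.
    Sampling stops when ``m`` reaches ``max_iter`` or when the binomial
    standard error of the smoothed estimate drops below
    ``se_stop_frac × p̂`` (checked every ``batch`` permutations) — the
    stopping rule of the lmPerm permutation framework with its defaults of
    5000 iterations and a 10%-of-p SE threshold.  Setting ``se_stop_frac=0``
    disables early stopping.
    """
    vals = np.asarray(values, dtype=float)
    labs = np.asarray(labels)
    uniq = np.unique(labs)
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(uniq)}")
    mask = labs == uniq[0]
    n_a = int(mask.sum())
    n = vals.size
    if n_a == 0 or n_a == n:
        raise ValueError("both groups must be non-empty")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    stat = statistic or _mean_difference
    observed = abs(stat(vals[mask], vals[~mask]))
    tol = 1e-12 * max(1.0, observed)
    fast = statistic is None
    total = float(vals.sum())
    exceed = 0
    m = 0
    while m < max_iter:
        size = min(batch, max_iter - m)
        if fast:
            order = np.argsort(rng.random((size, n)), axis=1)[:, :n_a]
            sum_a = vals[order].sum(axis=1)
            stats_abs = np.abs(sum_a / n_a - (total - sum_a) / (n - n_a))
        else:
            stats_abs = np.empty(size)
            for i in range(size):
                perm = rng.permutation(n)
                pa = perm[:n_a]
                pb = perm[n_a:]
                stats_abs[i] = abs(stat(vals[pa], vals[pb]))
        exceed += int(np.sum(stats_abs >= observed - tol))
        m += size
        p_hat = (1 + exceed) / (1 + m)
        se = float(np.sqrt(p_hat * (1 - p_hat) / m))
        if se_stop_frac > 0 and se < se_stop_frac * p_hat:
            break
    p_hat = (1 + exceed) / (1 + m)
    se = float(np.sqrt(p_hat * (1 - p_hat) / m))
    return PermutationResult(
        p_value=float(p_hat), iterations=m, observed=observed, se=se
    )


# --- grouping variables ------------------------------------------------------

#: variable name → (label function, (label_low, label_high)) over PatientSummary
_GROUPERS: dict[str, Callable[[PatientSummary], str]] = {
    "sex": lambda s: "male" if s.sex == "M" else "female",
    "age": lambda s: "ge10y" if s.age_months >= 120 else "lt10y",
    "wbc": lambda s: "ge50k" if s.wbc >= 50_000 else "lt50k",
    "blast": lambda s: "ge50pct" if s.blast_pct >= 50 else "lt50pct",
    "immunophenotype": lambda s: s.immunophenotype,
    "nci_risk": lambda s: s.nci_risk,
    "mmr_status": lambda s: s.mmr_status,
}

GROUP_VARIABLES = tuple(_GROUPERS) + ("tmb_median", "load_median")


def group_labels(
    summaries: Sequence[PatientSummary], variable: str
) -> np.ndarray:
    """Two-group labeling of the cohort for a named variable.

    Median-split variables (``tmb_median``, ``load_median``) assign values
    equal to the median to the low group (<= median).
    """
    if variable in _GROUPERS:
        f = _GROUPERS[variable]
        return np.array([f(s) for s in summaries])
    if variable in ("tmb_median", "load_median"):
        attr = variable.split("_")[0]
        vals = np.array([getattr(s, attr) for s in summaries], dtype=float)
        med = float(np.median(vals))
        return np.where(vals <= med, "low", "high")
    raise ValueError(f"unknown grouping variable {variable!r}")


def compare_groups(
    summaries: Sequence[PatientSummary],
    variable: str,
    max_iter: int = 5000,
    se_stop_frac: float = 0.1,
    rng: np.random.Generator | int | None = None,
) -> list[GroupComparison]:
    """Compare TMB and neoantigen load across one two-group variable.

    Returns one :class:`GroupComparison` per outcome, each holding group
    means, the Wilcoxon–Mann–Whitney p and the adaptive permutation p.
    Raises ``ValueError`` if the variable does not split the cohort into two
    non-empty groups (reported by the caller as not-computable).
    """
    labs = group_labels(summaries, variable)
    uniq = sorted(set(labs))
    if len(uniq) != 2:
        raise ValueError(
            f"variable {variable!r} yields {len(uniq)} group(s); need 2"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = []
    for outcome in ("tmb", "load"):
        vals = np.array([getattr(s, outcome) for s in summaries], dtype=float)
        a = vals[labs == uniq[0]]
        b = vals[labs == uniq[1]]
        u, wp = mann_whitney(a, b)
        perm = permutation_test(
            vals, labs, max_iter=max_iter, se_stop_frac=se_stop_frac, rng=rng
        )
        out.append(
            GroupComparison(
                variable=variable,
                outcome=outcome,
                labels=(uniq[0], uniq[1]),
                n=(a.size, b.size),
                means=(float(a.mean()), float(b.mean())),
                wilcoxon_u=u,
                wilcoxon_p=wp,
                permutation_p=perm.p_value,
                permutation_iterations=perm.iterations,
            )
        )
    return out


def summarize_patients(
    mutations: Sequence[MissenseMutation],
    loads: dict[str, int],
    clinical: Sequence[ClinicalRecord],
) -> list[PatientSummary]:
    """Assemble the per-patient analysis table.

    ``loads`` maps patient id → neoantigen load (0 for absent patients); the
    patient universe is the clinical table.
    """
    by_patient: dict[str, list[MissenseMutation]] = {}
    for m in mutations:
        by_patient.setdefault(m.patient_id, []).append(m)
    out = []
    for rec in clinical:
        muts = by_patient.get(rec.patient_id, [])
        out.append(
            PatientSummary(
                patient_id=rec.patient_id,
                tmb=tmb(muts),
                load=int(loads.get(rec.patient_id, 0)),
                mmr_status=mmr_status(muts),
                sex=rec.sex,
                age_months=rec.age_months,
                wbc=rec.wbc,
                immunophenotype=rec.immunophenotype,
                blast_pct=rec.blast_pct,
                nci_risk=classify_nci_risk(rec.age_months, rec.wbc),
                efs_time=rec.efs_time,
                efs_event=rec.efs_event,
                os_time=rec.os_time,
                os_event=rec.os_event,
            )
        )
    return out
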