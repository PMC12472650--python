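"""Cohort statistics: frequencies, correlations, rank and permutation tests."""

import itertools

import numpy as np
import pytest

from allneo.binding import HLAGenotype
from allneo.peptides import MissenseMutation
from allneo.stats import (
    PatientSummary,
    classify_nci_risk,
    compare_groups,
    correlate_tmb_load,
    group_labels,
    hla_frequencies,
    mann_whitney,
    mmr_status,
    permutation_test,
    tmb,
)


def _mut(patient="P1", gene="GENE0005", pos=10, alt="C"):
    return MissenseMutation(patient, "PR1", gene, pos, "A", alt)


def _summary(pid, tmb_=10, load=5, **kw):
    defaults = dict(
        mmr_status="WT",
        sex="M",
        age_months=60.0,
        wbc=10_000.0,
        immunophenotype="preB",
        blast_pct=80.0,
        nci_risk="standard",
    )
    defaults.update(kw)
    return PatientSummary(patient_id=pid, tmb=tmb_, load=load, **defaults)


class TestTmb:
    def test_empty(self):
        assert tmb([]) == 0

    def test_distinct(self):
        assert tmb([_mut(pos=1), _mut(pos=2), _mut(pos=3)]) == 3

    def test_duplicates_collapse(self):
        assert tmb([_mut(pos=1), _mut(pos=1)]) == 1


class TestMmrStatus:
    def test_single_mlh1_is_mut(self):
        assert mmr_status([_mut(gene="MLH1")]) == "MUT"

    def test_case_insensitive(self):
        assert mmr_status([_mut(gene="msh2")]) == "MUT"

    def test_other_genes_are_wt(self):
        assert mmr_status([_mut(gene="TP53"), _mut(gene="KRAS")]) == "WT"

    def test_empty_is_wt(self):
        assert mmr_status([]) == "WT"


class TestNciRisk:
    @pytest.mark.parametrize(
        "age,wbc,expected",
        [
            (60, 30_000, "standard"),
            (130, 10_000, "high"),   # >= 10 years
            (60, 50_000, "high"),    # WBC boundary inclusive
            (6, 1_000, "high"),      # infant
            (120, 1_000, "high"),    # exactly 10 years → older group
            (119.9, 49_999, "standard"),
        ],
    )
    def test_partition(self, age, wbc, expected):
        assert classify_nci_risk(age, wbc) == expected

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            classify_nci_risk(-1, 0)


def _genotypes_with_carriers(n_carriers, n_total, allele="HLA-A*02:01"):
    base = (
        "HLA-A*01:01",
        "HLA-A*03:01",
        "HLA-B*07:02",
        "HLA-B*39:05",
        "HLA-C*07:01",
        "HLA-C*04:01",
    )
    genos = []
    for i in range(n_total):
        alleles = list(base)
        if i < n_carriers:
            alleles[0] = allele
        genos.append(HLAGenotype(f"P{i:03d}", tuple(alleles)))
    return genos


class TestHlaFrequencies:
    def test_carrier_ten_of_sixtyfour(self):
        df = hla_frequencies(_genotypes_with_carriers(10, 64), mode="carrier")
        row = df[df.allele == "HLA-A*02:01"].iloc[0]
        assert round(100 * row.frequency, 1) == 15.6

    def test_homozygote_counts(self):
        g = HLAGenotype(
            "P1",
            (
                "HLA-A*02:01",
                "HLA-A*02:01",
                "HLA-B*07:02",
                "HLA-B*39:05",
                "HLA-C*07:01",
                "HLA-C*04:01",
            ),
        )
        carrier = hla_frequencies([g], mode="carrier")
        allelic = hla_frequencies([g], mode="allelic")
        assert carrier[carrier.allele == "HLA-A*02:01"].iloc[0]["count"] == 1
        assert allelic[allelic.allele == "HLA-A*02:01"].iloc[0]["count"] == 2

    def test_allelic_locus_sums_to_one(self):
        genos = _genotypes_with_carriers(20, 64)
        df = hla_frequencies(genos, mode="allelic")
        for _, grp in df.groupby("locus"):
            assert grp.frequency.sum() == pytest.approx(1.0)


class TestCorrelation:
    def test_identity_gives_unity(self):
        summ = [_summary(f"P{i}", tmb_=i + 1, load=i + 1) for i in range(10)]
        res = correlate_tmb_load(summ)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.spearman_rho == pytest.approx(1.0)

    def test_antimonotone_gives_minus_one(self):
        summ = [_summary(f"P{i}", tmb_=i + 1, load=100 - i**2) for i in range(8)]
        assert correlate_tmb_load(summ).spearman_rho == pytest.approx(-1.0)

    def test_constant_vector_raises(self):
        summ = [_summary(f"P{i}", tmb_=5, load=i) for i in range(5)]
        with pytest.raises(ValueError):
            correlate_tmb_load(summ)


class TestMannWhitney:
    def test_exact_small_sample(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(2 / 6)

    def test_identical_groups(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p >= 0.99

    def test_monotone_transform_invariance(self):
        a = [1.0, 3.0, 5.0, 11.0]
        b = [2.0, 4.0, 6.0, 7.0]
        _, p1 = mann_whitney(a, b)
        _, p2 = mann_whitney(np.exp(a), np.exp(b))
        assert p1 == pytest.approx(p2)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestPermutation:
    def test_invariant_statistic_gives_one(self):
        res = permutation_test([5.0] * 8, ["a"] * 4 + ["b"] * 4, rng=0)
        assert res.p_value == 1.0

    def test_matches_exhaustive_enumeration(self):
        """Combined n = 6: MC estimate matches the 20-split exhaustive p."""
        values = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        obs = abs(values[:3].mean() - values[3:].mean())
        count = 0
        total = 0
        for comb in itertools.combinations(range(6), 3):
            rest = [i for i in range(6) if i not in comb]
            stat = abs(values[list(comb)].mean() - values[rest].mean())
            count += stat >= obs - 1e-12
            total += 1
        exact = count / total  # = 2/20
        res = permutation_test(
            values, labels, max_iter=20_000, se_stop_frac=0.0, rng=1
        )
        se = np.sqrt(exact * (1 - exact) / res.iterations)
        assert abs(res.p_value - exact) < 3 * se + 1 / res.iterations

    def test_stopping_rule_respects_max_iter(self):
        rng = np.random.default_rng(2)
        values = np.concatenate([rng.normal(0, 1, 10), rng.normal(5, 1, 10)])
        labels = ["a"] * 10 + ["b"] * 10
        res = permutation_test(values, labels, max_iter=5000, rng=3)
        assert res.iterations <= 5000
        assert 0 < res.p_value <= 1

    def test_early_stop_on_large_p(self):
        rng = np.random.default_rng(4)
        values = rng.normal(0, 1, 30)
        labels = ["a"] * 15 + ["b"] * 15
        res = permutation_test(values, labels, max_iter=5000, rng=5)
        # a clearly null comparison should stop well before max_iter
        assert res.iterations < 5000

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            permutation_test([1.0, 2.0], ["a", "a"], rng=0)


class TestCompareGroups:
    def test_identical_groups_are_null(self):
        summ = [
            _summary(f"P{i}", tmb_=v, load=v, sex="M" if i % 2 else "F")
            for i, v in enumerate([10, 10, 20, 20, 30, 30, 40, 40])
        ]
        for gc in compare_groups(summ, "sex", rng=0):
            assert gc.means[0] == gc.means[1]
            assert gc.permutation_p > 0.9

    def test_separated_groups_reject(self):
        summ = [
            _summary(f"P{i}", tmb_=10 + i, load=5, mmr_status="WT")
            for i in range(10)
        ] + [
            _summary(f"Q{i}", tmb_=1000 + i, load=5, mmr_status="MUT")
            for i in range(10)
        ]
        gc_tmb = compare_groups(summ, "mmr_status", rng=1)[0]
        assert gc_tmb.outcome == "tmb"
        assert gc_tmb.permutation_p < 0.01
        assert gc_tmb.wilcoxon_p < 0.01

    def test_empty_group_not_computable(self):
        summ = [_summary(f"P{i}", sex="M") for i in range(6)]
        with pytest.raises(ValueError):
            compare_groups(summ, "sex", rng=0)

    def test_median_split_ties_to_low(self):
        summ = [_summary(f"P{i}", tmb_=v) for i, v in enumerate([1, 2, 2, 3])]
        labs = group_labels(summ, "tmb_median")
        assert list(labs) == ["low", "low", "low", "high"]
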