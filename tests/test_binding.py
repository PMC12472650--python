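"""Surrogate predictor distribution, %Rank calibration, binding-table IO."""

import numpy as np
import pytest
from scipy import stats as sps

from allneo.binding import (
    AlleleError,
    BindingTableError,
    CalibrationError,
    BindingRecord,
    HLAGenotype,
    RankCalibration,
    SurrogatePredictor,
    calibrate_rank,
    percent_rank,
    predict_pairs,
    read_binding_table,
    sample_background_peptides,
    surrogate_ic50,
    write_binding_table,
)
from allneo.peptides import MissenseMutation, ProteinRecord, enumerate_nonamer_pairs

ALLELE = "HLA-A*02:01"


def random_peptides(n, seed=0):
    rng = np.random.default_rng(seed)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    return ["".join(rng.choice(aa, size=9)) for _ in range(n)]


class TestGenotype:
    def test_valid_genotype(self):
        g = HLAGenotype(
            "P1",
            (
                "HLA-A*02:01",
                "HLA-A*24:02",
                "HLA-B*07:02",
                "HLA-B*39:05",
                "HLA-C*07:01",
                "HLA-C*04:01",
            ),
        )
        assert len(g.distinct_alleles) == 6

    def test_bad_allele_name(self):
        with pytest.raises(AlleleError):
            HLAGenotype("P1", ("A*02:01",) * 6)

    def test_locus_imbalance(self):
        with pytest.raises(AlleleError):
            HLAGenotype(
                "P1",
                (
                    "HLA-A*02:01",
                    "HLA-A*24:02",
                    "HLA-A*01:01",
                    "HLA-B*39:05",
                    "HLA-C*07:01",
                    "HLA-C*04:01",
                ),
            )


class TestSurrogate:
    def test_deterministic(self):
        v1 = surrogate_ic50("MKTAYIAKQ", ALLELE)
        v2 = surrogate_ic50("MKTAYIAKQ", ALLELE)
        assert v1 == v2

    def test_range_contract(self):
        pred = SurrogatePredictor()
        vals = pred.ic50_batch(random_peptides(2000, 3), ALLELE)
        assert np.all(vals >= 1.0) and np.all(vals <= 50_000.0)

    def test_model_key_namespaces(self):
        assert surrogate_ic50("MKTAYIAKQ", ALLELE, "a") != surrogate_ic50(
            "MKTAYIAKQ", ALLELE, "b"
        )

    def test_wrong_length_raises(self):
        with pytest.raises(ValueError):
            surrogate_ic50("MKTA", ALLELE)

    def test_log_ic50_uniform_by_ks(self):
        """log10(IC50)/log10(50000) should be U(0,1): KS below the 1% critical value."""
        pred = SurrogatePredictor()
        vals = pred.ic50_batch(random_peptides(10_000, 11), ALLELE)
        u = np.log10(vals) / np.log10(50_000.0)
        ks = sps.kstest(u, "uniform").statistic
        assert ks < 1.628 / np.sqrt(10_000)

    def test_mixing_one_copies_wild_type(self):
        pred = SurrogatePredictor(mixing=1.0)
        mut, wt = pred.score_pair("MKTAYIAKQ", "MKTAYIAKR", ALLELE)
        assert mut == pytest.approx(wt)

    def test_batch_matches_scalar(self):
        pred = SurrogatePredictor()
        peps = random_peptides(50, 5)
        batch = pred.ic50_batch(peps, ALLELE)
        assert batch == pytest.approx([pred.ic50(p, ALLELE) for p in peps])


class TestCalibration:
    def test_reference_sorted_and_reproducible(self, small_proteome):
        rng = np.random.default_rng(9)
        bg = sample_background_peptides(small_proteome, 200, rng)
        cal = calibrate_rank(ALLELE, bg)
        assert np.all(np.diff(cal.reference) >= 0)
        bg2 = sample_background_peptides(
            small_proteome, 200, np.random.default_rng(9)
        )
        cal2 = calibrate_rank(ALLELE, bg2)
        assert np.array_equal(cal.reference, cal2.reference)

    def test_insufficient_background_raises(self):
        tiny = [ProteinRecord("P", "G", "MKTAYIAKQ")]  # one distinct 9-mer
        with pytest.raises(CalibrationError):
            sample_background_peptides(tiny, 100, np.random.default_rng(0))

    def test_background_self_rank_fraction(self, small_proteome):
        """By construction, ~2% of background peptides rank below 2%."""
        bg = sample_background_peptides(
            small_proteome, 500, np.random.default_rng(2)
        )
        cal = calibrate_rank(ALLELE, bg)
        ranks = [percent_rank(v, cal) for v in cal.reference]
        frac = np.mean(np.array(ranks) < 2.0)
        assert abs(frac - 0.02) <= 1 / 500 + 1e-12

    def test_n_random_floor(self):
        with pytest.raises(CalibrationError):
            RankCalibration(ALLELE, np.arange(50.0), 50)


class TestPercentRank:
    CAL = RankCalibration(
        ALLELE, np.array([float(i) for i in range(100, 200)]), 100
    )

    def test_below_minimum_is_zero(self):
        assert percent_rank(5.0, self.CAL) == 0.0

    def test_above_maximum_is_hundred(self):
        assert percent_rank(1e6, self.CAL) == 100.0

    def test_strict_count(self):
        cal = RankCalibration(
            ALLELE, np.array([10.0, 100.0, 1000.0] + [2000.0] * 97), 100
        )
        # 1 of the first 3 reference values strictly below 100 nM
        assert percent_rank(100.0, cal) == pytest.approx(1.0)

    def test_reference_of_three_semantics(self):
        # direct count on {10, 100, 1000}: one value strictly below 100
        ref = np.array([10.0, 100.0, 1000.0])
        below = np.searchsorted(ref, 100.0, side="left")
        assert 100.0 * below / 3 == pytest.approx(33.33, abs=0.01)

    def test_monotone_in_ic50(self):
        rng = np.random.default_rng(4)
        qs = np.sort(rng.uniform(0, 300, size=50))
        ranks = [percent_rank(q, self.CAL) for q in qs]
        assert np.all(np.diff(ranks) >= 0)


class TestPredictPairs:
    def _pairs(self, protein100):
        m = MissenseMutation(
            "P1",
            protein100.protein_id,
            protein100.gene,
            50,
            protein100.sequence[49],
            "A" if protein100.sequence[49] != "A" else "C",
        )
        return enumerate_nonamer_pairs(protein100, m)

    def _geno(self, hom=False):
        if hom:
            return HLAGenotype(
                "P1",
                (
                    "HLA-A*02:01",
                    "HLA-A*02:01",
                    "HLA-B*07:02",
                    "HLA-B*07:02",
                    "HLA-C*07:01",
                    "HLA-C*07:01",
                ),
            )
        return HLAGenotype(
            "P1",
            (
                "HLA-A*02:01",
                "HLA-A*24:02",
                "HLA-B*07:02",
                "HLA-B*39:05",
                "HLA-C*07:01",
                "HLA-C*04:01",
            ),
        )

    def _cals(self, alleles, proteome):
        bg = sample_background_peptides(
            proteome, 200, np.random.default_rng(1)
        )
        return {a: calibrate_rank(a, bg) for a in alleles}

    def test_record_count(self, protein100, small_proteome):
        pairs = self._pairs(protein100)
        geno = self._geno()
        records = predict_pairs(
            pairs, geno, SurrogatePredictor(), self._cals(geno.distinct_alleles, small_proteome)
        )
        # 9 distinct mutant + 9 distinct wild-type peptides × 6 alleles
        assert len(records) == 108

    def test_homozygous_dedup(self, protein100, small_proteome):
        pairs = self._pairs(protein100)
        geno = self._geno(hom=True)
        assert len(geno.distinct_alleles) == 3
        records = predict_pairs(
            pairs, geno, SurrogatePredictor(), self._cals(geno.distinct_alleles, small_proteome)
        )
        assert len(records) == 54

    def test_empty_input(self, small_proteome):
        assert predict_pairs([], self._geno(), SurrogatePredictor(), {}) == []


class TestBindingTable:
    def test_round_trip(self, tmp_path):
        recs = [
            BindingRecord("MKTAYIAKQ", ALLELE, 123.4, 1.5),
            BindingRecord("AAAAAAAAA", "HLA-B*07:02", 4999.0, 55.0),
            BindingRecord("CCCCCCCCC", ALLELE, 1.0, 0.0),
        ]
        path = tmp_path / "binding.tsv"
        write_binding_table(recs, path)
        assert read_binding_table(path) == recs

    def test_missing_column_raises(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("peptide\tallele\tic50_nm\nMKTAYIAKQ\tHLA-A*02:01\t10\n")
        with pytest.raises(BindingTableError, match="rank_pct"):
            read_binding_table(path)

    def test_negative_ic50_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "peptide\tallele\tic50_nm\trank_pct\n"
            "MKTAYIAKQ\tHLA-A*02:01\t10\t1.0\n"
            "AAAAAAAAA\tHLA-A*02:01\t-1\t1.0\n"
        )
        with pytest.raises(BindingTableError, match="line 3"):
            read_binding_table(path)
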