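import numpy as np
import pandas as pd
import pytest

from targetmr.exceptions import ConfigurationError, InputError
from targetmr.sumstats import (LDMatrix, LocusDefinition, SummaryTable,
                               harmonize, read_sumstats, slice_locus)

from conftest import make_table

GLP1R = LocusDefinition("GLP1R", "6", 39_016_574, 39_055_519, 500)

TSV_HEADER = "SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"


def write_tsv(path, rows):
    path.write_text(TSV_HEADER + "".join(
        "\t".join(str(v) for v in r) + "\n" for r in rows))
    return path


class TestRead:
    def test_well_formed_file_round_trips(self, tmp_path):
        p = write_tsv(tmp_path / "x.tsv", [
            ("rs1", 6, 100, "A", "G", 0.3, 0.1, 0.02, 1e-9, 10000),
            ("rs2", 6, 200, "C", "T", 0.5, -0.05, 0.01, 1e-6, 10000),
            ("rs3", 6, 300, "G", "A", 0.1, 0.2, 0.04, 1e-7, 10000),
        ])
        tab = read_sumstats(p)
        assert len(tab) == 3 and tab.n_dropped == 0

    def test_invalid_rows_dropped_and_counted(self, tmp_path):
        p = write_tsv(tmp_path / "x.tsv", [
            ("rs1", 6, 100, "A", "G", 0.3, 0.1, 0.02, 1e-9, 10000),
            ("rs2", 6, 200, "C", "T", 0.5, 0.05, 0.0, 1e-6, 10000),   # se = 0
        ])
        tab = read_sumstats(p)
        assert len(tab) == 1 and tab.n_dropped == 1

    def test_lowercase_alleles_normalized(self, tmp_path):
        p = write_tsv(tmp_path / "x.tsv",
                      [("rs1", 6, 100, "a", "g", 0.3, 0.1, 0.02, 1e-9, 10000)])
        tab = read_sumstats(p)
        assert tab.df.loc[0, "effect_allele"] == "A"
        assert tab.df.loc[0, "other_allele"] == "G"

    def test_indels_rejected(self, tmp_path):
        p = write_tsv(tmp_path / "x.tsv", [
            ("rs1", 6, 100, "AT", "G", 0.3, 0.1, 0.02, 1e-9, 10000),
            ("rs2", 6, 200, "C", "T", 0.5, 0.05, 0.01, 1e-6, 10000),
        ])
        assert read_sumstats(p).snp_ids == ["rs2"]

    def test_missing_column_is_configuration_error(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("SNP\tBETA\nrs1\t0.1\n")
        with pytest.raises(ConfigurationError):
            read_sumstats(p)

    def test_empty_after_filtering_is_input_error(self, tmp_path):
        p = write_tsv(tmp_path / "x.tsv",
                      [("rs1", 6, 100, "A", "G", 0.3, 0.1, 0.0, 1e-9, 10000)])
        with pytest.raises(InputError):
            read_sumstats(p)


class TestSliceLocus:
    def test_printed_window_bounds(self):
        # +-500 kb around 6:39,016,574-39,055,519 keeps [38516574, 39555519]
        tab = make_table([
            {"snp_id": "below", "pos": 38_516_573},
            {"snp_id": "low_edge", "pos": 38_516_574},
            {"snp_id": "high_edge", "pos": 39_555_519},
            {"snp_id": "above", "pos": 39_555_520},
        ])
        kept = slice_locus(tab, GLP1R).snp_ids
        assert kept == ["low_edge", "high_edge"]

    def test_zero_window_keeps_gene_body_only(self):
        tab = make_table([
            {"snp_id": "inside", "pos": 39_020_000},
            {"snp_id": "outside", "pos": 39_010_000},
        ])
        locus = LocusDefinition("GLP1R", "6", 39_016_574, 39_055_519, 0)
        assert slice_locus(tab, locus).snp_ids == ["inside"]

    def test_other_chromosome_excluded_and_empty_ok(self):
        tab = make_table([{"snp_id": "chr19", "chrom": "19", "pos": 39_020_000}])
        assert len(slice_locus(tab, GLP1R)) == 0

    def test_output_invariant_to_row_order(self):
        rows = [{"snp_id": f"rs{i}", "pos": 39_016_574 + i * 37} for i in range(8)]
        fwd = slice_locus(make_table(rows), GLP1R).df
        rev = slice_locus(make_table(rows[::-1]), GLP1R).df
        pd.testing.assert_frame_equal(
            fwd.reset_index(drop=True), rev.reset_index(drop=True))


class TestHarmonize:
    def pair(self, xrows, yrows):
        return make_table(xrows), make_table(yrows)

    def test_swapped_alleles_flip_outcome_beta(self):
        x, y = self.pair(
            [{"effect_allele": "A", "other_allele": "G", "beta": 0.10}],
            [{"effect_allele": "G", "other_allele": "A", "beta": 0.30,
              "eaf": 0.7}])
        ht = harmonize(x, y)
        row = ht.df.iloc[0]
        assert row.beta_y == pytest.approx(-0.30)
        assert row.eaf_y == pytest.approx(0.3)
        assert row.action == "flipped"

    def test_identical_alleles_kept_unchanged(self):
        x, y = self.pair([{"beta": 0.1}], [{"beta": 0.3}])
        row = harmonize(x, y).df.iloc[0]
        assert row.action == "kept" and row.beta_y == pytest.approx(0.3)

    def test_strand_flip_resolved_via_complement(self):
        x, y = self.pair(
            [{"effect_allele": "A", "other_allele": "G", "beta": 0.1}],
            [{"effect_allele": "T", "other_allele": "C", "beta": 0.3}])
        row = harmonize(x, y).df.iloc[0]
        assert row.action == "strand_kept" and row.beta_y == pytest.approx(0.3)

    def test_palindromic_at_half_frequency_dropped(self):
        x, y = self.pair(
            [{"effect_allele": "A", "other_allele": "T", "eaf": 0.50}],
            [{"effect_allele": "A", "other_allele": "T", "eaf": 0.50}])
        ht = harmonize(x, y)
        assert len(ht) == 0
        assert ht.dropped.iloc[0]["reason"] == "palindromic_ambiguous"

    def test_palindromic_aligned_by_frequency(self):
        # informative frequencies on opposite sides: orientation flip implied
        x, y = self.pair(
            [{"effect_allele": "A", "other_allele": "T", "eaf": 0.10,
              "beta": 0.1}],
            [{"effect_allele": "A", "other_allele": "T", "eaf": 0.88,
              "beta": 0.3}])
        row = harmonize(x, y).df.iloc[0]
        assert row.action == "flipped"
        assert row.beta_y == pytest.approx(-0.3)

    def test_irreconcilable_alleles_dropped_with_reason(self):
        x, y = self.pair(
            [{"effect_allele": "A", "other_allele": "G"}],
            [{"effect_allele": "A", "other_allele": "C"}])
        ht = harmonize(x, y)
        assert len(ht) == 0
        assert ht.dropped.iloc[0]["reason"] == "allele_mismatch"

    def test_missing_outcome_eaf_drops_palindromic_keeps_others(self):
        x = make_table([
            {"snp_id": "pal", "effect_allele": "C", "other_allele": "G",
             "eaf": 0.1},
            {"snp_id": "solid", "effect_allele": "A", "other_allele": "G"},
        ])
        y = make_table([
            {"snp_id": "pal", "effect_allele": "C", "other_allele": "G",
             "eaf": np.nan},
            {"snp_id": "solid", "effect_allele": "A", "other_allele": "G",
             "eaf": np.nan},
        ])
        ht = harmonize(x, y)
        assert ht.df["snp_id"].tolist() == ["solid"]
        assert ht.dropped.iloc[0]["reason"] == "palindromic_no_eaf"

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        pairs = [("A", "G"), ("G", "A"), ("T", "C"), ("A", "T"), ("C", "G")]
        xrows, yrows = [], []
        for i in range(20):
            ea, oa = pairs[rng.integers(len(pairs))]
            f = float(rng.uniform(0.05, 0.95))
            xrows.append({"snp_id": f"s{i}", "effect_allele": ea,
                          "other_allele": oa, "eaf": f,
                          "beta": float(rng.normal())})
            swap = bool(rng.integers(2))
            yrows.append({"snp_id": f"s{i}",
                          "effect_allele": oa if swap else ea,
                          "other_allele": ea if swap else oa,
                          "eaf": 1 - f if swap else f,
                          "beta": float(rng.normal())})
        once = harmonize(make_table(xrows), make_table(yrows))
        twice = harmonize(*once.to_tables())
        num = once.df.drop(columns="action")
        pd.testing.assert_frame_equal(num, twice.df.drop(columns="action"))

    def test_wald_ratios_reciprocal_when_direction_swapped(self):
        x, y = self.pair(
            [{"snp_id": "s", "beta": 0.2, "se": 0.01}],
            [{"snp_id": "s", "beta": 0.05, "se": 0.01}])
        fwd = harmonize(x, y).df.iloc[0]
        rev = harmonize(y, x).df.iloc[0]
        assert (fwd.beta_y / fwd.beta_x) == pytest.approx(
            1.0 / (rev.beta_y / rev.beta_x))


class TestLDMatrix:
    def test_round_trip_and_validation(self, tmp_path):
        ld = LDMatrix(["a", "b"], np.array([[1.0, 0.3], [0.3, 1.0]]))
        ld.to_tsv(tmp_path / "ld.tsv")
        back = LDMatrix.from_tsv(tmp_path / "ld.tsv")
        assert back.ids == ["a", "b"]
        assert back.value("a", "b") == pytest.approx(0.3)

    def test_asymmetry_rejected(self):
        with pytest.raises(ConfigurationError):
            LDMatrix(["a", "b"], np.array([[1.0, 0.5], [0.1, 1.0]]))

    def test_bad_diagonal_rejected(self):
        with pytest.raises(ConfigurationError):
            LDMatrix(["a", "b"], np.array([[0.9, 0.1], [0.1, 1.0]]))
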