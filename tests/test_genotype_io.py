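"""Genotype parsing, TASSEL recoding, marker QC and mean imputation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmgp import genotype_io as gio


class TestReader:
    def test_single_marker_row_transcribes_directly(self, hapmap_file):
        path = hapmap_file(["m1\t1\t0.5\t0"])
        m = gio.read_hapmap_numeric(path)
        assert m.coding_tag == gio.TASSEL
        assert m.values.shape == (3, 1)
        np.testing.assert_array_equal(m.values[:, 0], [1.0, 0.5, 0.0])
        assert m.line_ids == ["L1", "L2", "L3"]

    def test_empty_file_is_a_parse_error(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("")
        with pytest.raises(gio.HapmapParseError, match="empty"):
            gio.read_hapmap_numeric(path)

    def test_missing_token_sets_mask(self, hapmap_file):
        path = hapmap_file(["m1\t1\tNA\t0", "m2\t0.5\t0.5\t1"])
        m = gio.read_hapmap_numeric(path)
        assert m.missing_mask[1, 0]  # line L2, marker m1
        assert m.missing_mask.sum() == 1

    def test_malformed_row_names_line_number(self, hapmap_file):
        path = hapmap_file(["m1\t1\t0.5\t0", "m2\t1\t0"])
        with pytest.raises(gio.HapmapParseError, match=":3:"):
            gio.read_hapmap_numeric(path)

    def test_unknown_token_rejected(self, hapmap_file):
        path = hapmap_file(["m1\t1\tAA\t0"])
        with pytest.raises(gio.HapmapParseError, match="AA"):
            gio.read_hapmap_numeric(path)

    def test_lines_as_rows_orientation(self, hapmap_file):
        path = hapmap_file(["r1\t1\t0\t0.5"], header="line\tm1\tm2\tm3")
        m = gio.read_hapmap_numeric(path, orientation="lines_as_rows")
        assert m.values.shape == (1, 3)
        assert m.marker_ids == ["m1", "m2", "m3"]


class TestRecode:
    def test_published_mapping(self):
        m = gio.MarkerMatrix(np.array([[1.0], [0.5], [0.0]]), ["a", "b", "c"], ["m1"])
        r = gio.recode_tassel(m)
        np.testing.assert_array_equal(r.values[:, 0], [-1.0, 0.0, 1.0])
        assert r.coding_tag == gio.RECODED

    def test_heterozygotes_map_to_zero(self):
        m = gio.MarkerMatrix(np.array([[0.5], [0.5]]), ["a", "b"], ["m1"])
        np.testing.assert_array_equal(gio.recode_tassel(m).values[:, 0], [0.0, 0.0])

    def test_missing_stays_missing(self):
        m = gio.MarkerMatrix(np.array([[1.0], [np.nan], [0.0]]), list("abc"), ["m1"])
        r = gio.recode_tassel(m)
        np.testing.assert_array_equal(r.values[:, 0], [-1.0, np.nan, 1.0])

    def test_out_of_coding_entry_rejected(self):
        m = gio.MarkerMatrix(np.array([[2.0]]), ["a"], ["m1"])
        with pytest.raises(ValueError, match="TASSEL"):
            gio.recode_tassel(m)

    @given(
        st.lists(st.sampled_from([1.0, 0.5, 0.0]), min_size=1, max_size=30)
    )
    @settings(deadline=None, max_examples=50)
    def test_recode_is_a_bijection(self, column):
        m = gio.MarkerMatrix(
            np.array(column)[:, None], [f"l{i}" for i in range(len(column))], ["m"]
        )
        r = gio.recode_tassel(m)
        inverse = {-1.0: 1.0, 0.0: 0.5, 1.0: 0.0}
        restored = np.vectorize(inverse.get)(r.values)
        np.testing.assert_array_equal(restored, m.values)


class TestFilter:
    def _mat(self, cols):
        cols = np.asarray(cols, dtype=float).T
        return gio.MarkerMatrix(
            cols,
            [f"l{i}" for i in range(cols.shape[0])],
            [f"m{k}" for k in range(cols.shape[1])],
            coding_tag=gio.RECODED,
        )

    def test_monomorphic_marker_removed(self):
        m = self._mat([[-1, -1, -1, -1]])
        kept, rep = gio.filter_markers(m)
        assert kept.n_markers == 0 and rep.n_removed_maf == 1

    def test_maf_quarter_marker_kept(self):
        # minor count 2 of 8 alleles -> MAF 0.25
        m = self._mat([[-1, -1, -1, 1]])
        kept, _ = gio.filter_markers(m)
        assert kept.n_markers == 1

    def test_rare_allele_removed_at_two_percent(self):
        col = [-1.0] * 49 + [1.0]  # MAF 2/100 = 0.02
        kept, rep = gio.filter_markers(self._mat([col]))
        assert kept.n_markers == 0 and rep.n_removed_maf == 1

    def test_all_missing_marker_removed_under_missingness(self):
        m = self._mat([[np.nan, np.nan, np.nan], [-1, 0, 1]])
        kept, rep = gio.filter_markers(m)
        assert rep.n_removed_missing == 1 and kept.n_markers == 1

    def test_marker_failing_both_rules_counts_once(self):
        # 2/3 missing (>= 0.5) and monomorphic on the remainder
        m = self._mat([[np.nan, np.nan, -1.0]])
        _, rep = gio.filter_markers(m)
        assert rep.n_removed_missing == 1 and rep.n_removed_maf == 0

    def test_filtering_is_idempotent(self):
        rng = np.random.default_rng(3)
        vals = rng.choice([-1.0, 0.0, 1.0, np.nan], size=(30, 50), p=[0.4, 0.2, 0.3, 0.1])
        m = gio.MarkerMatrix(vals, [f"l{i}" for i in range(30)],
                             [f"m{k}" for k in range(50)], coding_tag=gio.RECODED)
        once, _ = gio.filter_markers(m)
        twice, rep = gio.filter_markers(once)
        assert twice.n_markers == once.n_markers
        assert rep.n_removed_maf == 0 and rep.n_removed_missing == 0

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=100)
    def test_report_arithmetic_identity(self, seed):
        rng = np.random.default_rng(seed)
        n, p = rng.integers(2, 12), rng.integers(1, 20)
        vals = rng.choice([-1.0, 0.0, 1.0, np.nan], size=(n, p))
        m = gio.MarkerMatrix(vals, [f"l{i}" for i in range(n)],
                             [f"m{k}" for k in range(p)], coding_tag=gio.RECODED)
        kept, rep = gio.filter_markers(m)
        assert rep.n_markers_out == rep.n_markers_in - rep.n_removed_maf - rep.n_removed_missing
        assert rep.n_markers_out == kept.n_markers


class TestImpute:
    def _mat(self, col):
        col = np.asarray(col, dtype=float)[:, None]
        return gio.MarkerMatrix(col, [f"l{i}" for i in range(len(col))], ["m"],
                                coding_tag=gio.RECODED)

    def test_symmetric_column_imputes_zero(self):
        out = gio.impute_mean(self._mat([-1, 1, np.nan]))
        assert out.values[2, 0] == 0.0

    def test_constant_column_imputes_the_constant(self):
        out = gio.impute_mean(self._mat([1, 1, np.nan]))
        assert out.values[2, 0] == 1.0

    def test_complete_column_returned_unchanged(self):
        m = self._mat([-1, 0, 1])
        out = gio.impute_mean(m)
        np.testing.assert_array_equal(out.values, m.values)

    def test_all_missing_column_raises(self):
        with pytest.raises(ValueError, match="filter_markers"):
            gio.impute_mean(self._mat([np.nan, np.nan]))

    def test_column_means_preserved(self):
        rng = np.random.default_rng(9)
        vals = rng.choice([-1.0, 0.0, 1.0, np.nan], size=(40, 25), p=[0.3, 0.3, 0.3, 0.1])
        vals[0] = 1.0  # guarantee every column has data
        m = gio.MarkerMatrix(vals, [f"l{i}" for i in range(40)],
                             [f"m{k}" for k in range(25)], coding_tag=gio.RECODED)
        out = gio.impute_mean(m)
        assert not np.isnan(out.values).any()
        np.testing.assert_allclose(
            np.nanmean(m.values, axis=0), out.values.mean(axis=0), atol=1e-12
        )
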