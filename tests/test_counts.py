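import gzip

import numpy as np
import pytest
from scipy.stats import pearsonr

from cnatac.counts import (
    CountMatrix,
    FragmentRecord,
    GCCorrector,
    count_fragments,
    filter_cells,
    filter_zero_bins,
    gc_correct,
    read_fragments,
)
from cnatac.genome import BinSet, make_bins


class TestReadFragments:
    def test_five_column_line(self, tmp_path):
        p = tmp_path / "frags.tsv"
        p.write_text("chr1\t10\t110\tAAAC\t3\n")
        (rec,) = read_fragments(p)
        assert rec == FragmentRecord("chr1", 10, 110, "AAAC", 3)

    def test_whitelist_skips_other_barcodes(self, tmp_path):
        p = tmp_path / "frags.tsv"
        p.write_text("chr1\t10\t110\tAAAC\t3\nchr1\t10\t110\tTTTG\t1\n")
        recs = list(read_fragments(p, barcode_whitelist={"AAAC"}))
        assert [r.barcode for r in recs] == ["AAAC"]

    def test_four_columns_default_count(self, tmp_path):
        p = tmp_path / "frags.tsv"
        p.write_text("# comment\nchr1\t0\t100\tAAAC\n")
        (rec,) = read_fragments(p)
        assert rec.dup_count == 1

    def test_gzip_transparent(self, tmp_path):
        p = tmp_path / "frags.tsv.gz"
        with gzip.open(p, "wt") as fh:
            fh.write("chr1\t5\t95\tAAAC\t2\n")
        assert list(read_fragments(p))[0].start == 5

    def test_bad_coordinates_report_line(self, tmp_path):
        p = tmp_path / "frags.tsv"
        p.write_text("chr1\t0\t100\tAAAC\nchr1\tx\t100\tAAAC\n")
        with pytest.raises(ValueError, match=":2"):
            list(read_fragments(p))


class TestCountFragments:
    def _bins(self):
        return make_bins({"chr1": 1000}, 100)

    def test_midpoint_rule(self):
        # fragment [50,150) has midpoint 100 -> second bin
        m = count_fragments([FragmentRecord("chr1", 50, 150, "A")], self._bins())
        assert m.values[0].tolist() == [0, 1] + [0] * 8

    def test_accumulation_same_cell_same_bin(self):
        frags = [FragmentRecord("chr1", 0, 50, "A")] * 2
        m = count_fragments(frags, self._bins())
        assert m.values[0, 0] == 2

    def test_unknown_chromosome_tallied(self):
        frags = [
            FragmentRecord("chrUn", 0, 50, "A"),
            FragmentRecord("chr1", 0, 50, "A"),
        ]
        m = count_fragments(frags, self._bins())
        assert m.meta["skipped_fragments"] == 1
        assert m.values.sum() == 1

    def test_conservation(self):
        rng = np.random.default_rng(3)
        bins = self._bins()
        frags = [
            FragmentRecord("chr1", int(s), int(s) + 80, f"c{rng.integers(4)}")
            for s in rng.integers(0, 900, size=200)
        ]
        m = count_fragments(frags, bins)
        assert m.values.sum() + m.meta["skipped_fragments"] == 200

    def test_empty_input(self):
        m = count_fragments([], self._bins())
        assert m.values.shape == (0, 10)


class TestFilters:
    def _matrix(self, totals):
        values = np.array([[t] for t in totals])
        bins = make_bins({"c": 100}, 100)
        return CountMatrix(values, [f"c{i}" for i in range(len(totals))], bins)

    def test_cell_filter_threshold(self):
        m = filter_cells(self._matrix([100, 5000, 20000]), 20000)
        assert list(m.cell_ids) == ["c2"]

    def test_cell_filter_zero_is_identity(self):
        m = filter_cells(self._matrix([1, 2, 3]), 0)
        assert m.n_cells == 3

    def test_cell_filter_boundary_kept(self):
        m = filter_cells(self._matrix([50, 50]), 50)
        assert m.n_cells == 2

    def test_cell_filter_all_removed(self):
        with pytest.raises(ValueError, match="min_frags"):
            filter_cells(self._matrix([1, 2]), 10)

    def _bin_matrix(self, n_zero, n_cells=100):
        values = np.ones((n_cells, 2), dtype=int)
        values[:n_zero, 0] = 0
        bins = make_bins({"c": 200}, 100)
        return CountMatrix(values, [f"c{i}" for i in range(n_cells)], bins)

    def test_zero_bin_strict_inequality(self):
        # zero in 86/100 cells: removed; zero in 85/100: kept
        assert filter_zero_bins(self._bin_matrix(86)).n_bins == 1
        assert filter_zero_bins(self._bin_matrix(85)).n_bins == 2

    def test_dense_bin_kept(self):
        assert filter_zero_bins(self._bin_matrix(0)).n_bins == 2

    def test_all_bins_removed(self):
        m = self._bin_matrix(100)
        m.values[:, 1] = 0
        with pytest.raises(ValueError):
            filter_zero_bins(m, 0.5)


class TestGCCorrection:
    def test_flat_counts_nearly_unchanged(self):
        rng = np.random.default_rng(0)
        gc = rng.uniform(0.3, 0.6, 500)
        x = np.full((1, 500), 20.0)
        out = GCCorrector(gc=gc).fit_transform(x)
        np.testing.assert_allclose(out, x, rtol=1e-6)

    def test_linear_gc_trend_removed(self):
        rng = np.random.default_rng(6)
        gc = rng.uniform(0.3, 0.6, 1000)
        x = rng.poisson(50 * gc).astype(float)[None, :]
        out = GCCorrector(gc=gc).fit_transform(x)
        assert abs(pearsonr(x[0], gc).statistic) > 0.5
        assert abs(pearsonr(out[0], gc).statistic) < 0.1

    def test_mean_preserved_within_5pct(self):
        rng = np.random.default_rng(2)
        gc = rng.uniform(0.3, 0.6, 800)
        x = rng.poisson(30 * (0.5 + gc), size=(5, 800)).astype(float)
        out = GCCorrector(gc=gc).fit_transform(x)
        np.testing.assert_allclose(out.mean(axis=1), x.mean(axis=1), rtol=0.05)

    def test_too_few_gc_values_passthrough_with_warning(self):
        gc = np.tile([0.4, 0.5], 50)
        x = np.arange(100, dtype=float)[None, :]
        with pytest.warns(UserWarning, match="distinct GC"):
            out = GCCorrector(gc=gc).fit_transform(x)
        np.testing.assert_array_equal(out, x)

    def test_gc_correct_wrapper_flags_matrix(self):
        rng = np.random.default_rng(4)
        bins = make_bins({"c": 100 * 300}, 100)
        df = bins.df.copy()
        df["gc"] = rng.uniform(0.3, 0.6, 300)
        bins = BinSet(df, 100)
        m = CountMatrix(rng.poisson(15, (3, 300)), ["a", "b", "c"], bins)
        out = gc_correct(m)
        assert out.corrected
        with pytest.raises(ValueError):
            gc_correct(out)
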