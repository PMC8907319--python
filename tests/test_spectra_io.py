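import numpy as np
import pytest
from hypothesis import given, strategies as st

from nircal import (
    ReferenceTable,
    SpectraSet,
    align,
    read_reference_csv,
    read_spectra_csv,
    write_spectra_csv,
)
from nircal.spectra_io import SpectraValidationError


def _toy_csv(path, header, rows):
    lines = ["sample_id," + ",".join(str(h) for h in header)]
    for rid, vals in rows:
        lines.append(f"{rid}," + ",".join(str(v) for v in vals))
    path.write_text("\n".join(lines) + "\n")


class TestReadSpectra:
    def test_shape_preserved(self, tmp_path):
        p = tmp_path / "s.csv"
        _toy_csv(p, [9000, 8000, 7000, 6000, 5000],
                 [("A", [1, 2, 3, 4, 5]), ("B", [2, 3, 4, 5, 6]), ("C", [0, 0, 1, 1, 2])])
        s = read_spectra_csv(p)
        assert (s.n_rows, s.n_wavenumbers) == (3, 5)

    def test_ascending_file_normalized_to_descending(self, tmp_path):
        p = tmp_path / "asc.csv"
        _toy_csv(p, [4000, 6000, 8000, 10000], [("A", [1, 2, 3, 4])])
        s = read_spectra_csv(p)
        assert s.wavenumbers.tolist() == [10000, 8000, 6000, 4000]
        assert s.absorbance[0].tolist() == [4, 3, 2, 1]

    def test_duplicate_row_id_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        _toy_csv(p, [9000, 8000], [("A", [1, 2]), ("A", [3, 4])])
        with pytest.raises(SpectraValidationError, match="duplicate"):
            read_spectra_csv(p)

    def test_malformed_number_named(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("sample_id,9000,8000\nA,1.0,oops\n")
        with pytest.raises(SpectraValidationError):
            read_spectra_csv(p)

    def test_non_monotone_grid_rejected(self, tmp_path):
        p = tmp_path / "nm.csv"
        _toy_csv(p, [9000, 7000, 8000], [("A", [1, 2, 3])])
        with pytest.raises(SpectraValidationError, match="monotone"):
            read_spectra_csv(p)


class TestRoundTrip:
    def test_integer_matrix_exact(self, tmp_path):
        s = SpectraSet(np.array([9000.0, 8000.0, 7000.0]),
                       np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]), ["A", "B"])
        p = tmp_path / "rt.csv"
        write_spectra_csv(s, p)
        s2 = read_spectra_csv(p)
        assert np.array_equal(s.absorbance, s2.absorbance)
        assert s.row_ids == s2.row_ids

    def test_random_floats_bitstable(self, tmp_path, rng):
        wn = np.linspace(10000, 4000, 20)
        s = SpectraSet(wn, rng.normal(0, 1, (7, 20)), [f"r{i}" for i in range(7)])
        p = tmp_path / "rt.csv"
        write_spectra_csv(s, p)
        s2 = read_spectra_csv(p)
        assert np.max(np.abs(s.absorbance - s2.absorbance)) < 1e-12
        assert np.max(np.abs(s.wavenumbers - s2.wavenumbers)) < 1e-12

    def test_empty_spectra_roundtrip(self, tmp_path):
        s = SpectraSet(np.array([9000.0, 8000.0]), np.empty((0, 2)), [])
        p = tmp_path / "empty.csv"
        write_spectra_csv(s, p)
        s2 = read_spectra_csv(p)
        assert s2.n_rows == 0
        assert s2.n_wavenumbers == 2

    @given(st.integers(2, 8), st.integers(1, 6), st.integers(0, 2**31 - 1))
    def test_roundtrip_property(self, tmp_path_factory, n_wn, n_rows, seed):
        rng = np.random.default_rng(seed)
        wn = np.sort(rng.uniform(4000, 10000, n_wn))[::-1]
        s = SpectraSet(wn, rng.normal(0, 10, (n_rows, n_wn)),
                       [f"x{i}" for i in range(n_rows)])
        p = tmp_path_factory.mktemp("rt") / "p.csv"
        write_spectra_csv(s, p)
        s2 = read_spectra_csv(p)
        assert np.max(np.abs(s.absorbance - s2.absorbance)) < 1e-12


class TestReferenceTable:
    def test_component_column_selected(self, tmp_path):
        p = tmp_path / "ref.csv"
        p.write_text("sample_id,moisture,caffeine\nA,4.0,1.2\nB,5.1,0.8\n")
        t = read_reference_csv(p, "caffeine")
        assert t.values == {"A": 1.2, "B": 0.8}

    def test_unknown_component_names_available(self, tmp_path):
        p = tmp_path / "ref.csv"
        p.write_text("sample_id,moisture,caffeine\nA,4.0,1.2\n")
        with pytest.raises(SpectraValidationError, match="moisture"):
            read_reference_csv(p, "unknown")

    def test_extreme_values_preserved(self, tmp_path):
        # a file holding the published moisture extremes must load them intact
        p = tmp_path / "ref.csv"
        p.write_text("sample_id,moisture\nA,3.76\nB,6.29\nC,4.79\n")
        t = read_reference_csv(p, "moisture")
        vals = list(t.values.values())
        assert (min(vals), max(vals)) == (3.76, 6.29)

    def test_negative_value_rejected(self):
        with pytest.raises(SpectraValidationError, match="negative"):
            ReferenceTable("m", {"A": -1.0})


class TestAlign:
    def _spectra(self, ids):
        wn = np.array([9000.0, 8000.0])
        return SpectraSet(wn, np.arange(2 * len(ids), dtype=float).reshape(len(ids), 2), ids)

    def test_intersection_in_spectra_order(self):
        s = self._spectra(["A", "B", "C"])
        r = ReferenceTable("m", {"B": 1.0, "C": 2.0, "D": 3.0})
        s2, r2 = align(s, r)
        assert s2.row_ids == ["B", "C"]
        assert list(r2.values) == ["B", "C"]

    def test_identical_sets_passthrough(self):
        s = self._spectra(["A", "B"])
        r = ReferenceTable("m", {"A": 1.0, "B": 2.0})
        s2, r2 = align(s, r)
        assert s2.row_ids == ["A", "B"]
        assert np.array_equal(s2.absorbance, s.absorbance)

    def test_disjoint_sets_error(self):
        s = self._spectra(["A"])
        r = ReferenceTable("m", {"Z": 1.0})
        with pytest.raises(SpectraValidationError, match="common"):
            align(s, r)

    def test_idempotent(self):
        s = self._spectra(["A", "B", "C"])
        r = ReferenceTable("m", {"B": 1.0, "C": 2.0})
        s1, r1 = align(s, r)
        s2, r2 = align(s1, r1)
        assert s1.row_ids == s2.row_ids
        assert np.array_equal(s1.absorbance, s2.absorbance)
        assert r1.values == r2.values
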