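import io

import numpy as np
import pandas as pd
import pytest

from nmrcal.spectra_io import (KJELDAHL_FACTOR, ReferenceTable, Spectrum,
                               ValidationError, assemble_matrix,
                               load_reference_table, read_matrix_csv,
                               read_spectrum, write_matrix_csv,
                               write_spectrum)
from nmrcal.synthetic_data import GeneratorConfig, default_basis


class TestSpectrum:
    def test_ascending_input_is_reversed_to_descending(self):
        s = Spectrum("a", [10.0, 20.0, 30.0], [1.0, 2.0, 3.0])
        assert np.array_equal(s.ppm, [30.0, 20.0, 10.0])
        assert np.array_equal(s.intensity, [3.0, 2.0, 1.0])

    def test_descending_input_kept(self):
        s = Spectrum("a", [30.0, 20.0], [3.0, 2.0])
        assert np.array_equal(s.ppm, [30.0, 20.0])

    @pytest.mark.parametrize("ppm,intensity,msg", [
        ([10.0, 30.0, 20.0], [1, 2, 3], "monotone"),
        ([10.0, 20.0], [1.0, np.nan], "non-finite"),
        ([10.0], [1.0], "at least 2"),
        ([10.0, 20.0, 30.0], [1.0, 2.0], "mismatch"),
    ])
    def test_invalid_inputs_rejected(self, ppm, intensity, msg):
        with pytest.raises(ValidationError, match=msg):
            Spectrum("a", ppm, intensity)


class TestSpectrumIO:
    def test_two_column_text_parses(self):
        s = read_spectrum(io.StringIO("200.0 1.0\n100.0 2.0\n"), "xy")
        assert np.array_equal(s.ppm, [200.0, 100.0])
        assert np.array_equal(s.intensity, [1.0, 2.0])

    def test_ascending_file_gives_identical_spectrum(self):
        desc = read_spectrum(io.StringIO("200.0 1.0\n100.0 2.0\n"), "xy")
        asc = read_spectrum(io.StringIO("100.0 2.0\n200.0 1.0\n"), "xy")
        assert np.array_equal(desc.ppm, asc.ppm)
        assert np.array_equal(desc.intensity, asc.intensity)

    @pytest.mark.parametrize("dialect", ["xy", "jcamp"])
    def test_round_trip_is_lossless(self, dialect, rng):
        grid = np.linspace(220.0, 0.0, 3072)
        basis = default_basis()[0]
        s = Spectrum("synthetic", grid,
                     basis.evaluate(grid) + rng.normal(0, 0.01, grid.size))
        buf = io.StringIO()
        write_spectrum(s, buf, dialect)
        back = read_spectrum(io.StringIO(buf.getvalue()), dialect,
                             sample_id="synthetic")
        np.testing.assert_allclose(back.ppm, s.ppm, rtol=1e-9)
        np.testing.assert_allclose(back.intensity, s.intensity, rtol=1e-9)

    def test_jcamp_metadata_preserved(self):
        s = Spectrum("p1", [200.0, 100.0], [1.0, 2.0],
                     meta={"title": "pollen 1", "nucleus": "^13C"})
        buf = io.StringIO()
        write_spectrum(s, buf, "jcamp")
        back = read_spectrum(io.StringIO(buf.getvalue()), "jcamp")
        assert back.meta["title"] == "pollen 1"
        assert back.meta["nucleus"] == "^13C"

    def test_xy_write_emits_one_line_per_point(self):
        s = Spectrum("a", [30.0, 20.0, 10.0], [1.0, 2.0, 3.0])
        buf = io.StringIO()
        write_spectrum(s, buf, "xy")
        assert len(buf.getvalue().strip().splitlines()) == 3


class TestAssembleMatrix:
    def test_shared_grid_stacks_unchanged(self):
        grid = [200.0, 150.0, 100.0]
        specs = [Spectrum(f"s{i}", grid, [i, i + 1.0, i + 2.0])
                 for i in range(3)]
        m = assemble_matrix(specs, grid="intersection")
        assert m.X.shape == (3, 3)
        np.testing.assert_array_equal(m.X[1], [1.0, 2.0, 3.0])

    def test_linear_midpoint_interpolation(self):
        s1 = Spectrum("a", [200.0, 100.0], [0.0, 2.0])
        s2 = Spectrum("b", [200.0, 150.0, 100.0], [1.0, 1.0, 1.0])
        m = assemble_matrix([s1, s2], grid=[150.0, 120.0])
        assert m.row("a")[0] == pytest.approx(1.0)

    def test_refine_then_coarsen_round_trip(self):
        # smooth Lorentzian-sum signals survive 2x refine + return
        grid = np.linspace(220.0, 0.0, 512)
        fine = np.linspace(220.0, 0.0, 1023)
        basis = default_basis()[1]
        specs = [Spectrum("a", grid, basis.evaluate(grid)),
                 Spectrum("b", grid, 2 * basis.evaluate(grid))]
        up = assemble_matrix(specs, grid=fine)
        back = assemble_matrix(
            [Spectrum(sid, fine, row) for sid, row in zip(up.sample_ids, up.X)],
            grid=grid)
        np.testing.assert_allclose(back.X[:, 1:-1],
                                   np.stack([s.intensity for s in specs])[:, 1:-1],
                                   atol=1e-6)

    def test_disjoint_ranges_and_duplicate_ids_rejected(self):
        a = Spectrum("a", [220.0, 150.0], [1.0, 1.0])
        b = Spectrum("b", [100.0, 10.0], [1.0, 1.0])
        with pytest.raises(ValidationError, match="disjoint"):
            assemble_matrix([a, b])
        with pytest.raises(ValidationError, match="duplicate"):
            assemble_matrix([a, Spectrum("a", [220.0, 150.0], [2.0, 2.0])])

    def test_no_extrapolation(self):
        a = Spectrum("a", [200.0, 100.0], [1.0, 1.0])
        b = Spectrum("b", [200.0, 100.0], [1.0, 2.0])
        with pytest.raises(ValidationError, match="extrapolation"):
            assemble_matrix([a, b], grid=[210.0, 150.0])


class TestMatrixCSV:
    def test_round_trip(self, small_matrix, tmp_path):
        path = tmp_path / "m.csv"
        write_matrix_csv(small_matrix, path)
        back = read_matrix_csv(path)
        assert back.sample_ids == small_matrix.sample_ids
        np.testing.assert_allclose(back.X, small_matrix.X, rtol=1e-9)
        np.testing.assert_allclose(back.grid, small_matrix.grid, atol=1e-6)


class TestReferenceTable:
    def test_packaged_fixture_has_35_validated_rows(self):
        ref = load_reference_table()
        assert len(ref) == 35
        assert ref.sample_ids[0] == "1" and ref.sample_ids[-1] == "35"

    def test_known_fixture_rows(self):
        df = load_reference_table().frame
        r30 = df.loc["30"]
        assert (r30.tp, r30.abts, r30.protein, r30.n, r30.ph) == \
            (14.57, 264.8, 28.81, 4.61, 5.80)
        r10 = df.loc["10"]
        assert (r10.tp, r10.abts) == (4.16, 117.2)

    def test_kjeldahl_inconsistency_rejected(self):
        df = load_reference_table().frame.reset_index()
        df.loc[0, "protein"] = 20.0
        df.loc[0, "n"] = 4.0  # 6.25 * 4.0 = 25.0 != 20.0
        with pytest.raises(ValidationError, match="inconsistent"):
            ReferenceTable(df)

    def test_negative_hydrogen_share_rejected(self):
        df = load_reference_table().frame.reset_index()
        df.loc[0, "nhcs"] = 40.0  # below C + N + S
        with pytest.raises(ValidationError, match="NHCS"):
            ReferenceTable(df)

    def test_protein_matches_kjeldahl_on_every_row(self):
        df = load_reference_table().frame
        dev = (df.protein - KJELDAHL_FACTOR * df.n).abs()
        assert dev.max() <= 0.006

    def test_subset_preserves_order(self):
        ref = load_reference_table()
        sub = ref.subset(["3", "1"])
        assert sub.sample_ids == ("3", "1")
        assert sub.frame.loc["3", "tp"] == 12.54
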