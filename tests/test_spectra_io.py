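import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from naquant import (
    SimulationParams,
    Spectrum,
    align_spectra,
    bin_spectrum,
    make_design,
    read_spectrum,
    simulate_dataset,
)
from naquant.exceptions import (
    EmptyMatrixError,
    FormatError,
    ManifestError,
    UnsupportedModeError,
)
from naquant.spectra_io import AlignedMatrix, bin_index, read_manifest
from naquant.synthetic_data import noiseless

from conftest import write_mzml


class TestSpectrum:
    def test_sorts_and_merges(self):
        s = Spectrum("a", [200.0, 100.0, 200.0], [1.0, 2.0, 3.0])
        assert s.mz.tolist() == [100.0, 200.0]
        assert s.intensity.tolist() == [2.0, 4.0]

    def test_drops_zero_intensity(self):
        s = Spectrum("a", [100.0, 150.0], [0.0, 5.0])
        assert len(s) == 1

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="negative intensity"):
            Spectrum("a", [100.0], [-5.0])

    def test_nonpositive_mz_rejected(self):
        with pytest.raises(ValueError, match="nonpositive m/z"):
            Spectrum("a", [0.0], [5.0])


class TestReadSpectrumCsv:
    def test_direct_parse(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("121.0295,1000\n241.2173,500\n")
        s = read_spectrum(p)
        assert len(s) == 2
        assert s.mz.tolist() == [121.0295, 241.2173]
        assert s.intensity.tolist() == [1000.0, 500.0]

    def test_out_of_order_sorted(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("241.2173,500\n121.0295,1000\n")
        s = read_spectrum(p)
        assert s.mz.tolist() == [121.0295, 241.2173]

    def test_negative_intensity_error(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("121.0295,-5\n")
        with pytest.raises(FormatError):
            read_spectrum(p)

    def test_header_row_tolerated(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("mz,intensity\n121.0295,1000\n")
        s = read_spectrum(p)
        assert len(s) == 1

    def test_garbage_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("hello\nworld,not_a_number\n")
        with pytest.raises(FormatError):
            read_spectrum(p)


class TestReadSpectrumMzml:
    def test_single_scan(self, tmp_path):
        p = write_mzml(tmp_path / "s.mzML", [([121.0295, 241.2173], [1000.0, 500.0])])
        s = read_spectrum(p)
        assert np.allclose(s.mz, [121.0295, 241.2173])
        assert np.allclose(s.intensity, [1000.0, 500.0])

    def test_multi_scan_averaged(self, tmp_path):
        scans = [([100.0, 200.0], [10.0, 20.0]), ([100.0, 200.0], [30.0, 40.0])]
        s = read_spectrum(write_mzml(tmp_path / "s.mzML", scans))
        assert np.allclose(s.intensity, [20.0, 30.0])

    def test_zlib_float32(self, tmp_path):
        p = write_mzml(
            tmp_path / "s.mzML", [([150.5], [7.0])], compress=True, dtype="f"
        )
        s = read_spectrum(p)
        assert np.allclose(s.mz, [150.5], atol=1e-4)
        assert np.allclose(s.intensity, [7.0])

    def test_profile_mode_rejected(self, tmp_path):
        p = write_mzml(tmp_path / "s.mzML", [([100.0], [1.0])], mode="profile")
        with pytest.raises(UnsupportedModeError):
            read_spectrum(p)

    def test_unparseable_rejected(self, tmp_path):
        p = tmp_path / "s.mzML"
        p.write_text("<mzML><broken")
        with pytest.raises(FormatError):
            read_spectrum(p)


class TestBinSpectrum:
    def test_shared_bin_summed(self):
        s = Spectrum("a", [150.0004, 150.0006], [10.0, 20.0])
        out = bin_spectrum(s, 100.0, 400.0, 0.001)
        assert out == {50000: 30.0}

    def test_peak_at_mz_max_discarded(self):
        s = Spectrum("a", [400.0], [5.0])
        assert bin_spectrum(s, 100.0, 400.0, 0.001) == {}

    def test_empty_spectrum(self):
        s = Spectrum("a", [], [])
        assert bin_spectrum(s, 100.0, 400.0, 0.001) == {}

    def test_decimal_safe_edges(self):
        # (100.001 - 100)/0.001 is 0.999... in floats; must land in bin 1
        assert bin_index(100.001, 100.0, 0.001) == 1
        assert bin_index(150.0006, 100.0, 0.001) == 50000
        for k in range(1, 2000, 37):
            mz = 100.0 + k * 0.001
            assert bin_index(mz, 100.0, 0.001) == k

    @given(
        mz=st.floats(min_value=100.0, max_value=399.999),
        intensity=st.floats(min_value=0.01, max_value=1e6),
    )
    @settings(max_examples=100, deadline=None)
    def test_conservation_single_peak(self, mz, intensity):
        out = bin_spectrum(Spectrum("a", [mz], [intensity]), 100.0, 400.0, 0.001)
        assert math.isclose(sum(out.values()), intensity)
        (idx,) = out.keys()
        assert 0 <= idx <= math.floor(300.0 / 0.001)


class TestAlignSpectra:
    def test_disjoint_peaks(self):
        s1 = Spectrum("a", [150.0], [10.0])
        s2 = Spectrum("b", [250.0], [20.0])
        matrix, grid = align_spectra([s1, s2], 100.0, 400.0, 0.001)
        assert matrix.X.shape == (2, 2)
        assert np.allclose(matrix.X, [[10.0, 0.0], [0.0, 20.0]])
        assert np.all(np.diff(grid.occupied_bins) > 0)

    def test_identical_spectra(self):
        s = Spectrum("a", [150.0, 250.0], [10.0, 20.0])
        matrix, _ = align_spectra([s, s, s], 100.0, 400.0, 0.001)
        assert np.allclose(matrix.X, matrix.X[0])

    def test_zero_mass_error_gives_ten_bins(self):
        params = noiseless(SimulationParams(seed=5))
        spectra, _ = simulate_dataset(make_design(), params)
        matrix, _ = align_spectra(spectra, 100.0, 400.0, 0.001)
        assert matrix.n_samples == 36
        assert matrix.n_bins == 10

    def test_no_peaks_in_range(self):
        s = Spectrum("a", [50.0], [1.0])
        with pytest.raises(EmptyMatrixError):
            align_spectra([s], 100.0, 400.0, 0.001)

    def test_row_conserves_in_range_intensity(self, rng):
        mz = np.sort(rng.uniform(50.0, 450.0, size=200))
        inten = rng.uniform(0.1, 100.0, size=200)
        s = Spectrum("a", mz, inten)
        matrix, _ = align_spectra([s], 100.0, 400.0, 0.001)
        in_range = inten[(mz >= 100.0) & (mz < 400.0)].sum()
        assert np.isclose(matrix.X.sum(), in_range)

    def test_binning_idempotent_on_centers(self, rng):
        mz = np.sort(rng.choice(np.arange(100000, 400000), 50, replace=False))
        s = Spectrum("a", 100.0 + (mz - 100000 + 0.5) * 0.001, rng.uniform(1, 10, 50))
        m1, g1 = align_spectra([s], 100.0, 400.0, 0.001)
        s2 = Spectrum("a", g1.bin_centers, m1.X[0])
        m2, g2 = align_spectra([s2], 100.0, 400.0, 0.001)
        assert np.array_equal(g1.occupied_bins, g2.occupied_bins)
        assert np.allclose(m1.X, m2.X)

    def test_column_count_bound(self, rng):
        spectra = [
            Spectrum(f"s{i}", np.sort(rng.uniform(100, 400, 50)), np.ones(50))
            for i in range(4)
        ]
        matrix, _ = align_spectra(spectra, 100.0, 400.0, 0.001)
        assert matrix.n_bins <= math.floor(300.0 / 0.001) + 1


class TestAlignedMatrixCsv:
    def test_round_trip(self, tmp_path):
        m = AlignedMatrix(
            np.array([[1.0, 2.0], [3.0, 4.0]]), np.array([100.0005, 200.0005]), ["a", "b"]
        )
        path = tmp_path / "X.csv"
        m.to_csv(path)
        m2 = AlignedMatrix.from_csv(path)
        assert np.allclose(m.X, m2.X)
        assert np.allclose(m.bin_centers, m2.bin_centers)
        assert m2.sample_ids == ["a", "b"]


class TestManifest:
    def test_minimal(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("sample_id,path\na,a.csv\n")
        df = read_manifest(p)
        assert df.loc[0, "role"] == "unknown"
        assert df.loc[0, "dilution_factor"] == 1.0

    def test_missing_columns(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("sample,file\na,a.csv\n")
        with pytest.raises(ManifestError):
            read_manifest(p)

    def test_bad_role(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("sample_id,path,role\na,a.csv,training\n")
        with pytest.raises(ManifestError):
            read_manifest(p)
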