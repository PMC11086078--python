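"""Spectrum parsing, canonicalization, normalization and band extraction."""

import io

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cottonfir.spectra_io import (
    DegenerateSpectrumError,
    Spectrum,
    SpectrumParseError,
    band_intensity,
    extract_bands,
    normalize_region,
    read_spectrum,
    write_spectrum,
)


class TestSpectrumInvariants:
    def test_descending_input_is_canonicalized_ascending(self):
        s = read_spectrum("1032 0.40\n1028 0.20", "two_column")
        assert np.array_equal(s.wavenumbers, [1028.0, 1032.0])
        assert np.array_equal(s.absorbances, [0.20, 0.40])

    @pytest.mark.parametrize("w, a, match", [
        ([1032.0, 1032.0], [0.1, 0.2], "duplicate"),
        ([1000.0], [0.1], "at least 2"),
        ([600.0, 700.0], [0.1, 0.2], "step exceeds"),
        ([600.0, 604.0], [0.1, np.nan], "non-finite"),
        ([600.0, 604.0, 608.0], [0.1, 0.2], "length mismatch"),
    ])
    def test_invariant_violations_rejected(self, w, a, match):
        with pytest.raises(SpectrumParseError, match=match):
            Spectrum(np.array(w), np.array(a))


class TestDialects:
    def test_two_column_accepts_comments_and_commas(self):
        text = "# acquired 4 cm-1\n1028, 0.20\n1032 0.40\n"
        s = read_spectrum(text, "two_column")
        assert len(s) == 2

    @pytest.mark.parametrize("text, match", [
        ("1028 0.2\nbad line here\n", "line 2"),
        ("1028 abc\n1032 0.4\n", "line 1"),
        ("1032 0.1\n1032 0.2\n", "duplicate"),
    ])
    def test_two_column_parse_errors_name_the_line(self, text, match):
        with pytest.raises(SpectrumParseError, match=match):
            read_spectrum(text, "two_column")

    def test_csv_matrix_yields_replicates_on_shared_grid(self):
        text = "id,1028,1032,1036\nrep1,0.1,0.2,0.3\nrep2,0.4,0.5,0.6\n"
        specs = read_spectrum(io.StringIO(text), "csv_matrix")
        assert [s.replicate_id for s in specs] == ["rep1", "rep2"]
        assert np.array_equal(specs[0].wavenumbers, specs[1].wavenumbers)

    @pytest.mark.parametrize("dialect", ["two_column", "csv_matrix", "jcampdx"])
    def test_round_trip_reproduces_grid_and_values(self, dialect, flat_spectrum):
        s = flat_spectrum
        text = write_spectrum(s, dialect)
        back = read_spectrum(io.StringIO(text), dialect)
        if isinstance(back, list):
            back = back[0]
        assert np.allclose(back.wavenumbers, s.wavenumbers, atol=1e-9, rtol=0)
        assert np.allclose(back.absorbances, s.absorbances, atol=1e-9, rtol=0)

    def test_round_trip_idempotence(self, noiseless_spectrum):
        once = read_spectrum(write_spectrum(noiseless_spectrum), "two_column")
        twice = read_spectrum(write_spectrum(once), "two_column")
        assert np.array_equal(once.wavenumbers, twice.wavenumbers)
        assert np.array_equal(once.absorbances, twice.absorbances)

    def test_jcampdx_requires_xydata_block(self):
        with pytest.raises(SpectrumParseError, match="XYDATA"):
            read_spectrum("##TITLE=x\n##END=\n", "jcampdx")

    def test_unknown_dialect_rejected(self, flat_spectrum):
        with pytest.raises(ValueError, match="dialect"):
            read_spectrum("1 2", "spc")
        with pytest.raises(ValueError, match="dialect"):
            write_spectrum(flat_spectrum, "spc")


class TestNormalizeRegion:
    def test_constant_becomes_unity(self, flat_spectrum):
        n = normalize_region(flat_spectrum)
        assert np.allclose(n.absorbances, 1.0, atol=1e-12)

    def test_region_mean_is_one_and_restricted(self, noiseless_spectrum):
        n = normalize_region(noiseless_spectrum, 600.0, 1800.0)
        assert n.wavenumbers[0] >= 600.0 and n.wavenumbers[-1] <= 1800.0
        assert abs(n.absorbances.mean() - 1.0) < 1e-12

    def test_scaling_by_inverse_mean(self):
        w = np.arange(600.0, 1804.0, 4.0)
        s = Spectrum(w, np.full(w.size, 0.25))
        assert np.allclose(normalize_region(s).absorbances, 1.0)

    def test_empty_region_errors(self):
        w = np.arange(3500.0, 4004.0, 4.0)
        s = Spectrum(w, np.ones(w.size))
        with pytest.raises(DegenerateSpectrumError, match="no grid points"):
            normalize_region(s, 600.0, 1800.0)

    def test_preserves_band_ratios(self, noiseless_spectrum):
        from cottonfir.band_indices import compute_r1, compute_r2

        before = extract_bands(noiseless_spectrum)
        after = extract_bands(normalize_region(noiseless_spectrum, 600.0, 1800.0))
        assert compute_r1(after) == pytest.approx(compute_r1(before), abs=1e-9)
        assert compute_r2(after) == pytest.approx(compute_r2(before), abs=1e-9)


class TestBandIntensity:
    def test_flat_spectrum_any_center(self, flat_spectrum):
        assert band_intensity(flat_spectrum, 1032.0) == pytest.approx(0.5)

    def test_three_point_average(self):
        s = Spectrum(np.array([1028.0, 1032.0, 1036.0]),
                     np.array([0.2, 0.4, 0.3]))
        assert band_intensity(s, 1032.0, 3) == pytest.approx(0.3)

    def test_off_grid_center_snaps_to_nearest_with_high_tie_break(self):
        # brute-force oracle: nearest grid point, ties toward higher wavenumber
        w = np.arange(1000.0, 1041.0, 4.0)
        a = np.linspace(0.1, 1.0, w.size)
        s = Spectrum(w, a)
        for center in np.arange(1000.0, 1040.5, 0.5):
            d = np.abs(w - center)
            best = max(np.flatnonzero(d == d.min()))  # exhaustive scan, high tie
            assert band_intensity(s, center, 1) == pytest.approx(a[best])

    def test_window_one_equals_nearest_lookup(self, noiseless_spectrum):
        s = noiseless_spectrum
        for i in range(0, len(s), 97):
            assert band_intensity(s, s.wavenumbers[i], 1) == s.absorbances[i]

    @given(a=st.floats(0.1, 10.0), b=st.floats(-0.5, 0.5))
    def test_linearity_in_affine_maps(self, a, b):
        w = np.arange(600.0, 1804.0, 4.0)
        rng = np.random.default_rng(7)
        s = Spectrum(w, rng.uniform(0.0, 1.0, w.size))
        base = band_intensity(s, 1032.0)
        assert band_intensity(s.scaled(a, b), 1032.0) == pytest.approx(
            a * base + b, abs=1e-12, rel=1e-12)

    @pytest.mark.parametrize("center", [100.0, 5000.0])
    def test_center_outside_grid_errors(self, flat_spectrum, center):
        with pytest.raises(DegenerateSpectrumError, match="outside grid"):
            band_intensity(flat_spectrum, center)

    def test_window_past_edge_errors(self, flat_spectrum):
        with pytest.raises(DegenerateSpectrumError, match="past grid edge"):
            band_intensity(flat_spectrum, 600.0, 3)

    def test_even_window_rejected(self, flat_spectrum):
        with pytest.raises(ValueError, match="odd"):
            band_intensity(flat_spectrum, 1032.0, 2)


class TestExtractBands:
    def test_flat_spectrum_all_bands_equal(self, flat_spectrum):
        b = extract_bands(flat_spectrum)
        assert {b.i956, b.i1032, b.i1500, b.i708, b.i730, b.i800} == {0.5}
        assert b.window_points == 3

    def test_truncated_spectrum_names_missing_bands(self):
        w = np.arange(750.0, 1804.0, 4.0)
        s = Spectrum(w, np.ones(w.size))
        with pytest.raises(DegenerateSpectrumError) as err:
            extract_bands(s)
        assert "708" in str(err.value) and "730" in str(err.value)

    def test_designed_amplitudes_recovered_without_noise(self, noiseless_spectrum):
        from cottonfir.band_indices import MaturityIndices

        idx = MaturityIndices.from_bands(extract_bands(noiseless_spectrum))
        assert idx.m_ir == pytest.approx(0.8, abs=1e-6)
        assert idx.ci_ir == pytest.approx(80.0, abs=1e-6)
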