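"""Spectrum I/O, resampling, normalization, characteristics, codes."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ccspec.spectra import (
    Spectrum,
    UV_GRID,
    VIS_GRID,
    extract_characteristics,
    normalize_minmax,
    parse_concentration_code,
    read_spectrum,
    resample,
    to_uv_grid,
    write_spectrum,
)


def make_spectrum(values, start=360.0, step=10.0, **kw):
    return Spectrum(start, step, np.asarray(values, dtype=float), **kw)


class TestGrids:
    def test_uv_grid_is_58_points_from_230(self):
        assert UV_GRID.n == 58
        assert UV_GRID.wavelengths[0] == 230.0
        assert UV_GRID.step_nm == 3.0

    def test_vis_grid_is_43_points_360_to_780(self):
        assert VIS_GRID.n == 43
        assert VIS_GRID.wavelengths[0] == 360.0
        assert VIS_GRID.wavelengths[-1] == 780.0


class TestIO:
    def test_round_trip_lossless(self, tmp_path, rng):
        s = make_spectrum(rng.uniform(0, 5, 43))
        p = tmp_path / "s.csv"
        write_spectrum(s, p)
        s2 = read_spectrum(p)
        assert s2.same_grid(s)
        np.testing.assert_allclose(s2.absorbance, s.absorbance, atol=1e-9)

    def test_43_row_visible_file(self, tmp_path):
        p = tmp_path / "vis.csv"
        wl = 360 + 10 * np.arange(43)
        p.write_text(
            "wavelength_nm,absorbance\n"
            + "\n".join(f"{w},{0.1 * i}" for i, w in enumerate(wl))
        )
        s = read_spectrum(p)
        assert s.grid_step_nm == 10.0
        assert s.n_points == 43

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("wavelength_nm,absorbance\n")
        with pytest.raises(ValueError):
            read_spectrum(p)

    def test_non_uniform_grid_names_rows(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("wavelength_nm,absorbance\n360,1\n370,1\n385,1\n")
        with pytest.raises(ValueError, match="non-uniform"):
            read_spectrum(p)


class TestResample:
    def test_uv_resample_has_58_points(self):
        wl = np.arange(230, 401)  # 1-nm source
        s = Spectrum(230.0, 1.0, np.sin(wl / 40.0) + 1.5)
        out = to_uv_grid(s)
        assert out.n_points == 58

    def test_identity_on_same_grid(self, rng):
        s = make_spectrum(rng.uniform(0, 2, 43))
        out = resample(s, 360.0, 10.0, 43)
        np.testing.assert_allclose(out.absorbance, s.absorbance, atol=1e-12)

    def test_constant_stays_constant(self):
        s = make_spectrum(np.full(43, 1.3))
        out = resample(s, 365.0, 10.0, 40)
        np.testing.assert_allclose(out.absorbance, 1.3)

    def test_out_of_range_errors(self):
        s = make_spectrum(np.ones(43))
        with pytest.raises(ValueError, match="coverage"):
            resample(s, 300.0, 10.0, 43)

    def test_commutes_with_affine_scaling(self, rng):
        a = rng.uniform(0, 2, 43)
        s = make_spectrum(a)
        out1 = resample(s.with_absorbance(3 * a + 1), 365.0, 5.0, 50).absorbance
        out2 = 3 * resample(s, 365.0, 5.0, 50).absorbance + 1
        np.testing.assert_allclose(out1, out2, atol=1e-12)


class TestNormalize:
    def test_affine_map_example(self):
        s = make_spectrum([0.2, 0.7, 1.2])
        np.testing.assert_allclose(
            normalize_minmax(s).absorbance, [0.0, 0.5, 1.0], atol=1e-15
        )

    def test_idempotent(self, rng):
        s = normalize_minmax(make_spectrum(rng.uniform(0, 5, 43)))
        np.testing.assert_allclose(
            normalize_minmax(s).absorbance, s.absorbance, atol=1e-15
        )

    @given(st.integers(3, 60), st.integers(0, 10_000))
    def test_min_zero_max_one(self, n, seed):
        r = np.random.default_rng(seed)
        vals = r.uniform(-2, 5, n)
        if vals.max() - vals.min() < 1e-9:
            return
        out = normalize_minmax(make_spectrum(vals))
        assert out.absorbance.min() == 0.0
        assert out.absorbance.max() == 1.0
        assert out.normalized

    def test_constant_errors(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_minmax(make_spectrum(np.full(10, 2.0)))


class TestCharacteristics:
    def test_peak_wavelength(self):
        a = np.zeros(58)
        a[24] = 1.0  # 230 + 3*24 = 302 nm
        s = Spectrum(230.0, 3.0, a)
        assert extract_characteristics(s).lambda_peak_nm == 302.0

    def test_monotone_spectrum_height_at_250(self):
        a = np.linspace(1.0, 0.0, 58)
        s = Spectrum(230.0, 3.0, a)
        c = extract_characteristics(s)
        # nearest grid point to 250 nm is 251 nm (index 7)
        assert c.peak_height == a[7]

    def test_area_matches_direct_summation(self, rng):
        a = rng.uniform(0, 1, 58)
        s = Spectrum(230.0, 3.0, a)
        total = 0.0
        for v in a:  # independent summation oracle
            total += v
        assert np.isclose(extract_characteristics(s).area_sum, total)

    def test_tie_breaks_to_lowest_wavelength(self):
        a = np.zeros(58)
        a[10] = a[30] = 1.0
        s = Spectrum(230.0, 3.0, a)
        assert extract_characteristics(s).lambda_peak_nm == 230.0 + 3 * 10

    def test_lambda_invariant_under_normalization(self, rng):
        a = rng.uniform(0, 3, 58)
        s = Spectrum(230.0, 3.0, a)
        c_raw = extract_characteristics(s)
        c_norm = extract_characteristics(normalize_minmax(s))
        assert c_raw.lambda_peak_nm == c_norm.lambda_peak_nm
        # S and H are scale-dependent by design
        assert not np.isclose(c_raw.area_sum, c_norm.area_sum)


class TestConcentrationCodes:
    @pytest.mark.parametrize(
        "code, expected",
        [
            ("1.1", [(1, 0.75e-4)]),
            ("1.2", [(1, 1.0e-4)]),
            ("7", [(7, 1.0e-4)]),
            ("1.3", [(1, 1.25e-4)]),
            ("1.1 + 3.3", [(1, 0.75e-4), (3, 1.25e-4)]),
            ("2 + 4.1 + 9.2", [(2, 1.0e-4), (4, 0.75e-4), (9, 1.0e-4)]),
        ],
    )
    def test_mapping(self, code, expected):
        out = [(c.dye_id, c.concentration_mol_per_l) for c in parse_concentration_code(code)]
        assert out == expected

    @pytest.mark.parametrize("bad", ["", "1.4", "x.1", "1..2", "1 +", "+ 2"])
    def test_malformed_codes_error_with_position(self, bad):
        with pytest.raises(ValueError, match="position|empty"):
            parse_concentration_code(bad)

    def test_relative_concentration(self):
        (c,) = parse_concentration_code("5.3")
        assert np.isclose(c.relative_concentration, 1.25)
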