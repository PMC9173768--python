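"""Spectral data model, normalization, resampling and the generators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tscocryst import (
    CoefficientSet,
    LibraryConfig,
    RamanSpectrum,
    SpectralGrid,
    make_fingerprint_library,
    make_viscosity_table,
    normalize,
    resample,
    restrict_range,
    synthesize_mixture,
)
from tscocryst.errors import (
    ConfigError,
    CoverageError,
    DegenerateSpectrum,
    DomainError,
    EmptyRange,
    UnknownComponent,
)
from tscocryst.rheology import ArrheniusParams, CarreauParams, carreau_viscosity
from tscocryst.spectra import DEFAULT_SHEAR_RATES, DEFAULT_TEMPERATURES


def spec(intensities, wavenumbers=None, label="test"):
    w = wavenumbers if wavenumbers is not None else np.arange(len(intensities), dtype=float)
    return RamanSpectrum(w, np.asarray(intensities, float), label=label)


class TestNormalize:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ([2.0, 4.0, 6.0], [0.0, 0.5, 1.0]),
            ([0.0, 0.5, 1.0], [0.0, 0.5, 1.0]),  # idempotence on normalized input
            ([-1.0, 0.0, 3.0], [0.0, 0.25, 1.0]),
        ],
    )
    def test_min_max_map(self, raw, expected):
        assert np.allclose(normalize(spec(raw)).intensities, expected)

    def test_constant_spectrum_is_degenerate(self):
        with pytest.raises(DegenerateSpectrum):
            normalize(spec([5.0, 5.0, 5.0]))

    @given(
        values=st.lists(
            st.floats(min_value=-1e3, max_value=1e3), min_size=3, max_size=40
        ),
        scale=st.floats(min_value=1e-3, max_value=1e3),
        offset=st.floats(min_value=-100, max_value=100),
    )
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, values, scale, offset):
        """normalize(c*x + d) == normalize(x) for c > 0, and the result
        is exactly bounded in [0, 1] with endpoints attained."""
        arr = np.asarray(values)
        if arr.max() - arr.min() < 1e-6:
            return
        base = normalize(spec(arr))
        shifted = normalize(spec(scale * arr + offset))
        assert np.allclose(base.intensities, shifted.intensities, atol=1e-9)
        assert base.intensities.min() == 0.0
        assert base.intensities.max() == 1.0
        assert normalize(base).intensities == pytest.approx(base.intensities)


class TestResample:
    def test_default_grid_yields_1000_points(self):
        w = np.linspace(300, 4000, 500)
        out = resample(spec(np.sin(w / 100) + 2, w), SpectralGrid())
        assert len(out) == 1000
        assert out.wavenumbers[0] == 400.0 and out.wavenumbers[-1] == 3750.0

    def test_identity_on_matching_grid(self):
        grid = SpectralGrid(400, 3750, 200)
        s = spec(np.random.default_rng(0).uniform(size=200), grid.wavenumbers)
        assert np.allclose(resample(s, grid).intensities, s.intensities)

    def test_linear_ramp_interpolates_exactly(self):
        # intensity = wavenumber/1000 is reproduced exactly by linear interpolation
        w = np.linspace(350, 3800, 97)
        grid = SpectralGrid(400, 3750, 333)
        out = resample(spec(w / 1000.0, w), grid)
        assert np.allclose(out.intensities, grid.wavenumbers / 1000.0, atol=1e-12)

    def test_resample_twice_is_identity(self):
        grid = SpectralGrid(400, 3750, 150)
        s = spec(np.random.default_rng(1).uniform(size=300), np.linspace(400, 3750, 300))
        once = resample(s, grid)
        twice = resample(once, grid)
        assert np.allclose(once.intensities, twice.intensities)

    def test_no_extrapolation(self):
        s = spec([1.0, 2.0], np.array([500.0, 3000.0]))
        with pytest.raises(CoverageError):
            resample(s, SpectralGrid())


class TestRestrictRange:
    def test_window_filter(self, default_library):
        s = default_library.fingerprints["CO-1"]
        out = restrict_range(s, 700, 1200)
        assert np.all((out.wavenumbers >= 700) & (out.wavenumbers <= 1200))
        kept = (s.wavenumbers >= 700) & (s.wavenumbers <= 1200)
        assert len(out) == int(kept.sum())

    def test_full_range_is_identity(self, default_library):
        s = default_library.fingerprints["CO-1"]
        out = restrict_range(s, 400, 3750)
        assert np.array_equal(out.intensities, s.intensities)

    def test_empty_window(self, default_library):
        with pytest.raises(EmptyRange):
            restrict_range(default_library.fingerprints["CO-1"], 5000, 6000)


class TestFingerprintLibrary:
    def test_default_census(self, default_library):
        assert len(default_library.fingerprints) == 21
        names = default_library.fingerprint_names
        assert names[:9] == [f"CO-{k}" for k in range(1, 10)]
        assert "DI-3" in names and "DN-9" in names
        assert default_library.grid.n_points == 1000

    def test_determinism(self):
        a = make_fingerprint_library(seed=42)
        b = make_fingerprint_library(seed=42)
        for name in a.all_spectra():
            assert np.array_equal(
                a.all_spectra()[name].intensities, b.all_spectra()[name].intensities
            )

    def test_seed_changes_spectra(self):
        a = make_fingerprint_library(seed=1)
        b = make_fingerprint_library(seed=2)
        assert not np.allclose(
            a.fingerprints["CO-1"].intensities, b.fingerprints["CO-1"].intensities
        )

    @pytest.mark.parametrize("name, band", [("CO-5", (2000, 2500)), ("CO-2", (700, 1200))])
    def test_marker_bands(self, default_library, name, band):
        s = default_library.fingerprints[name]
        peak = s.wavenumbers[np.argmax(s.intensities)]
        assert band[0] <= peak <= band[1]

    def test_all_spectra_normalized(self, default_library):
        for s in default_library.all_spectra().values():
            assert s.is_normalized
            assert np.all((s.intensities >= 0) & (s.intensities <= 1))

    def test_bad_config(self):
        with pytest.raises(ConfigError):
            make_fingerprint_library(LibraryConfig(families={"C O": 3}))
        with pytest.raises(ConfigError):
            make_fingerprint_library(
                LibraryConfig(families={"CO": 2}, marker_overrides={"CO-9": 900.0})
            )
        with pytest.raises(ConfigError):
            make_fingerprint_library(
                LibraryConfig(families={"CO": 2}, marker_overrides={"CO-1": 9000.0})
            )


class TestSynthesizeMixture:
    def test_single_component_identity(self, small_library):
        cs = CoefficientSet(linear={"CO-1": 1.0})
        R = synthesize_mixture(small_library, cs, noise_sd=0.0)
        assert np.allclose(
            R.intensities, small_library.fingerprints["CO-1"].intensities, atol=1e-12
        )

    def test_all_zero_is_degenerate(self, small_library):
        with pytest.raises(DegenerateSpectrum):
            synthesize_mixture(small_library, CoefficientSet(), noise_sd=0.0)

    def test_unknown_key(self, small_library):
        with pytest.raises(UnknownComponent):
            synthesize_mixture(
                small_library, CoefficientSet(linear={"XX-1": 1.0}), noise_sd=0.0
            )

    def test_noise_is_seeded(self, small_library):
        cs = CoefficientSet(linear={"CO-1": 0.5, "DI-1": 0.5})
        a = synthesize_mixture(small_library, cs, noise_sd=0.01, seed=3)
        b = synthesize_mixture(small_library, cs, noise_sd=0.01, seed=3)
        c = synthesize_mixture(small_library, cs, noise_sd=0.01, seed=4)
        assert np.array_equal(a.intensities, b.intensities)
        assert not np.array_equal(a.intensities, c.intensities)


class TestViscosityTable:
    def test_exact_carreau_when_noiseless(self):
        p = CarreauParams(mu0=100.0, lam=1e4, n=-0.35)
        arr = ArrheniusParams(A=610.75, E_over_R=-736.64)
        table = make_viscosity_table(p, arr, noise_rel=0.0, seed=0)
        for _, row in table.iterrows():
            mu0_T = arr.mu0(row["T_K"])
            expected = carreau_viscosity(
                row["shear_s-1"], CarreauParams(mu0=mu0_T, lam=1e4, n=-0.35)
            )
            assert row["viscosity_cP"] == pytest.approx(expected, rel=1e-12)

    def test_default_conditions(self):
        table = make_viscosity_table(CarreauParams(mu0=50.0, lam=1e4, n=-0.35))
        assert sorted(table["T_K"].unique()) == sorted(DEFAULT_TEMPERATURES)
        for T, group in table.groupby("T_K"):
            assert sorted(group["shear_s-1"]) == sorted(DEFAULT_SHEAR_RATES)
            # pseudoplastic: viscosity strictly decreasing in shear
            ordered = group.sort_values("shear_s-1")["viscosity_cP"].to_numpy()
            assert np.all(np.diff(ordered) < 0)

    def test_nonpositive_shear_rejected(self):
        with pytest.raises(DomainError):
            make_viscosity_table(
                CarreauParams(mu0=50.0, lam=1.0, n=0.5), shear_rates=[0.0, 1.0]
            )
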