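"""Raman spectral data model and seeded synthetic generators.

The central object is :class:`RamanSpectrum`: a strictly increasing
wavenumber grid (cm^-1) with one intensity per point.  All downstream
analysis operates on min-max normalized intensities, so normalization,
resampling and band restriction live here, together with the synthetic
generators that emulate quantum-chemistry-derived fingerprint spectra
(sums of Lorentzian lines), polynomial mixture spectra, and
shear-thinning viscosity tables.

A *fingerprint* is the Raman signature of one molecular-interaction pair
in a binary drug/coformer system: CO-* for drug-coformer cocrystal
pairs, DI-* for drug dimers, DN-* for coformer dimers.  The isolated
molecules A (drug) and B (coformer) are carried alongside the
fingerprints and treated as spectral contamination ("noise") during
weight extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence, TYPE_CHECKING

import numpy as np

from .errors import (
    ConfigError,
    CoverageError,
    DegenerateSpectrum,
    DomainError,
    EmptyRange,
    UnknownComponent,
)

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .rheology import ArrheniusParams, CarreauParams
    from .unmix import CoefficientSet

__all__ = [
    "RamanSpectrum",
    "SpectralGrid",
    "PeakModel",
    "FingerprintLibrary",
    "LibraryConfig",
    "DEFAULT_GRID",
    "normalize",
    "resample",
    "restrict_range",
    "restrict_library",
    "make_fingerprint_library",
    "synthesize_mixture",
    "make_viscosity_table",
]


@dataclass(frozen=True)
class SpectralGrid:
    """Uniform wavenumber grid. Default: 1,000 points over 400-3750 cm^-1."""

    lo: float = 400.0
    hi: float = 3750.0
    n_points: int = 1000

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ConfigError(f"grid requires lo < hi, got [{self.lo}, {self.hi}]")
        if self.n_points < 2:
            raise ConfigError("grid requires at least 2 points")

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n_points)

    @property
    def spacing(self) -> float:
        return (self.hi - self.lo) / (self.n_points - 1)


DEFAULT_GRID = SpectralGrid()


@dataclass(frozen=True)
class RamanSpectrum:
    """One spectrum: strictly increasing wavenumbers (cm^-1) + intensities."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", i)
        if w.ndim != 1 or i.ndim != 1 or w.shape != i.shape:
            raise ConfigError("wavenumbers and intensities must be 1-D and equal length")
        if w.size < 2:
            raise ConfigError("a spectrum needs at least 2 points")
        if not np.all(np.diff(w) > 0):
            raise ConfigError("wavenumbers must be strictly increasing")

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    @property
    def is_normalized(self) -> bool:
        """True when min intensity is exactly 0 and max exactly 1."""
        return bool(self.intensities.min() == 0.0 and self.intensities.max() == 1.0)


@dataclass(frozen=True)
class PeakModel:
    """A single Lorentzian line: center (cm^-1), HWHM width, peak amplitude."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigError("peak width must be positive")
        if self.amplitude <= 0:
            raise ConfigError("peak amplitude must be positive")

    def evaluate(self, wavenumbers: np.ndarray) -> np.ndarray:
        w2 = self.width**2
        return self.amplitude * w2 / ((wavenumbers - self.center) ** 2 + w2)


def normalize(spectrum: RamanSpectrum) -> RamanSpectrum:
    """Min-max normalize: x_bar = (x - min) / (max - min).

    Idempotent and invariant under positive affine rescaling of the
    intensities.  Raises :class:`DegenerateSpectrum` for a constant
    spectrum, whose normalization is undefined.
    """
    x = spectrum.intensities
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise DegenerateSpectrum(
            f"cannot normalize constant spectrum {spectrum.label!r} (max == min)"
        )
    scaled = (x - lo) / (hi - lo)
    return replace(spectrum, intensities=scaled)


def resample(spectrum: RamanSpectrum, grid: SpectralGrid) -> RamanSpectrum:
    """Linearly interpolate a spectrum onto a uniform grid.

    The input span must cover the target grid; extrapolation is refused
    (:class:`CoverageError`) rather than fabricating intensities.
    """
    w = spectrum.wavenumbers
    tol = 1e-9 * max(abs(grid.lo), abs(grid.hi), 1.0)
    if w[0] > grid.lo + tol or w[-1] < grid.hi - tol:
        raise CoverageError(
            f"spectrum spans [{w[0]:g}, {w[-1]:g}] cm^-1, cannot cover "
            f"[{grid.lo:g}, {grid.hi:g}]"
        )
    target = grid.wavenumbers
    values = np.interp(target, w, spectrum.intensities)
    return RamanSpectrum(target, values, label=spectrum.label)


def restrict_range(spectrum: RamanSpectrum, lo: float, hi: float) -> RamanSpectrum:
    """Keep exactly the points with lo <= wavenumber <= hi (order preserved)."""
    if not lo < hi:
        raise EmptyRange(f"invalid range [{lo}, {hi}]")
    mask = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers <= hi)
    if int(mask.sum()) < 2:
        raise EmptyRange(
            f"fewer than 2 grid points fall inside [{lo:g}, {hi:g}] cm^-1"
        )
    return RamanSpectrum(
        spectrum.wavenumbers[mask], spectrum.intensities[mask], label=spectrum.label
    )


# ---------------------------------------------------------------------------
# Fingerprint library generator
# ---------------------------------------------------------------------------

#: Family -> number of fingerprints in the default binary drug/coformer system.
DEFAULT_FAMILIES: Mapping[str, int] = {"CO": 9, "DI": 3, "DN": 9}

#: Marker-band overrides guaranteeing the two headline fingerprints carry
#: their distinguishing peaks: CO-5 in 2000-2500 cm^-1, CO-2 in 700-1200 cm^-1.
DEFAULT_MARKERS: Mapping[str, float] = {"CO-5": 2250.0, "CO-2": 950.0}


@dataclass(frozen=True)
class LibraryConfig:
    """Peak rules for the synthetic fingerprint library.

    Each basis spectrum is a sum of one dominant *marker* Lorentzian
    (amplitude 1, guaranteeing an identifiable band per component) plus
    a seeded handful of minor lines, then min-max normalized.
    """

    grid: SpectralGrid = DEFAULT_GRID
    families: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_FAMILIES))
    molecules: Sequence[str] = ("A", "B")
    #: None applies DEFAULT_MARKERS to whichever of those names exist;
    #: an explicit mapping is validated strictly.
    marker_overrides: Mapping[str, float] | None = None
    marker_band: tuple[float, float] = (600.0, 3600.0)
    n_minor_peaks: tuple[int, int] = (3, 6)
    width_range: tuple[float, float] = (8.0, 30.0)
    minor_amplitude_max: float = 0.35

    def fingerprint_names(self) -> list[str]:
        names: list[str] = []
        for fam, count in self.families.items():
            if not fam or not str(fam).isalpha():
                raise ConfigError(f"unknown family name {fam!r}")
            if int(count) < 0:
                raise ConfigError(f"negative count for family {fam!r}")
            names.extend(f"{fam}-{k}" for k in range(1, int(count) + 1))
        if not names:
            raise ConfigError("config must define at least one fingerprint")
        if len(self.molecules) != 2:
            raise ConfigError("config must name exactly 2 isolated molecules")
        return names


@dataclass(frozen=True)
class FingerprintLibrary:
    """Named basis spectra (2 isolated molecules + N fingerprints) on one grid."""

    grid: SpectralGrid
    molecule_A: RamanSpectrum
    molecule_B: RamanSpectrum
    fingerprints: dict[str, RamanSpectrum]
    seed: int

    def __post_init__(self) -> None:
        ref = self.grid.wavenumbers
        for spec in self.all_spectra().values():
            if len(spec) != ref.size or not np.allclose(spec.wavenumbers, ref):
                raise ConfigError(f"spectrum {spec.label!r} not on the library grid")
            if not spec.is_normalized:
                raise ConfigError(f"spectrum {spec.label!r} is not normalized")

    @property
    def fingerprint_names(self) -> list[str]:
        return list(self.fingerprints)

    @property
    def basis_names(self) -> list[str]:
        """Molecules first ('A', 'B'), then the fingerprints in order."""
        return ["A", "B", *self.fingerprints]

    def all_spectra(self) -> dict[str, RamanSpectrum]:
        return {"A": self.molecule_A, "B": self.molecule_B, **self.fingerprints}

    def basis_matrix(self) -> np.ndarray:
        """Intensities stacked column-wise in ``basis_names`` order (n x P)."""
        return np.column_stack(
            [self.all_spectra()[name].intensities for name in self.basis_names]
        )


def _synth_spectrum(
    name: str, marker: float, cfg: LibraryConfig, rng: np.random.Generator
) -> RamanSpectrum:
    w = cfg.grid.wavenumbers
    peaks = [PeakModel(center=marker, width=float(rng.uniform(*cfg.width_range)), amplitude=1.0)]
    n_minor = int(rng.integers(cfg.n_minor_peaks[0], cfg.n_minor_peaks[1] + 1))
    for _ in range(n_minor):
        peaks.append(
            PeakModel(
                center=float(rng.uniform(cfg.grid.lo, cfg.grid.hi)),
                width=float(rng.uniform(*cfg.width_range)),
                amplitude=float(rng.uniform(0.05, cfg.minor_amplitude_max)),
            )
        )
    total = np.sum([p.evaluate(w) for p in peaks], axis=0)
    return normalize(RamanSpectrum(w, total, label=name))


def make_fingerprint_library(
    config: LibraryConfig | None = None, seed: int = 0
) -> FingerprintLibrary:
    """Build a deterministic synthetic fingerprint library.

    The default config produces molecules A and B plus 21 fingerprints
    (CO-1..CO-9, DI-1..DI-3, DN-1..DN-9) on the 1,000-point default grid.
    Marker bands are spread evenly over the grid so every component has
    a distinguishing line; the unmixing problem is then identifiable for
    generic mixtures.  Bit-identical output for identical (config, seed).
    """
    cfg = config or LibraryConfig()
    fp_names = cfg.fingerprint_names()
    basis_order = [*cfg.molecules, *fp_names]

    lo_m, hi_m = cfg.marker_band
    if lo_m < cfg.grid.lo or hi_m > cfg.grid.hi:
        raise ConfigError("marker band extends beyond the grid")
    markers = dict(zip(basis_order, np.linspace(lo_m, hi_m, len(basis_order))))
    if cfg.marker_overrides is None:
        overrides = {k: v for k, v in DEFAULT_MARKERS.items() if k in markers}
    else:
        overrides = dict(cfg.marker_overrides)
    for name, center in overrides.items():
        if name not in markers:
            raise ConfigError(f"marker override for unknown component {name!r}")
        if not cfg.grid.lo <= center <= cfg.grid.hi:
            raise ConfigError(f"marker for {name!r} at {center} cm^-1 is off-grid")
        markers[name] = float(center)

    rng = np.random.default_rng(seed)
    spectra = {name: _synth_spectrum(name, markers[name], cfg, rng) for name in basis_order}
    mol_a, mol_b = cfg.molecules
    return FingerprintLibrary(
        grid=cfg.grid,
        molecule_A=spectra[mol_a],
        molecule_B=spectra[mol_b],
        fingerprints={n: spectra[n] for n in fp_names},
        seed=seed,
    )


def restrict_library(
    library: FingerprintLibrary, lo: float, hi: float
) -> FingerprintLibrary:
    """Restrict every basis spectrum to [lo, hi] cm^-1 and re-normalize."""
    def cut(s: RamanSpectrum) -> RamanSpectrum:
        return normalize(restrict_range(s, lo, hi))

    a = cut(library.molecule_A)
    grid = SpectralGrid(float(a.wavenumbers[0]), float(a.wavenumbers[-1]), len(a))
    return FingerprintLibrary(
        grid=grid,
        molecule_A=a,
        molecule_B=cut(library.molecule_B),
        fingerprints={n: cut(s) for n, s in library.fingerprints.items()},
        seed=library.seed,
    )


# ---------------------------------------------------------------------------
# Mixture synthesis (forward polynomial model)
# ---------------------------------------------------------------------------

def synthesize_mixture(
    library: FingerprintLibrary,
    coefficients: "CoefficientSet",
    noise_sd: float = 0.0,
    seed: int = 0,
    fourth_order: Mapping[tuple[str, str, str, str], float] | None = None,
) -> RamanSpectrum:
    """Evaluate the truncated polynomial forward model and normalize.

    R = a + sum_i a_i r_i + sum_{ij} a_ij r_i r_j + sum_{ijk} a_ijk r_i r_j r_k
    with optional caller-supplied fourth-order cross terms (used to probe
    truncation error), plus additive Gaussian noise of ``noise_sd``.
    """
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    spectra = library.all_spectra()

    def vec(name: str) -> np.ndarray:
        try:
            return spectra[name].intensities
        except KeyError:
            raise UnknownComponent(f"unknown coefficient key {name!r}") from None

    total = np.full(library.grid.n_points, float(coefficients.constant))
    for name, a in coefficients.linear.items():
        total = total + a * vec(name)
    for pair, a in coefficients.pairwise.items():
        total = total + a * vec(pair[0]) * vec(pair[1])
    for trip, a in coefficients.triple.items():
        total = total + a * vec(trip[0]) * vec(trip[1]) * vec(trip[2])
    for quad, a in (fourth_order or {}).items():
        prod = np.ones_like(total)
        for name in quad:
            prod = prod * vec(name)
        total = total + a * prod

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        total = total + rng.normal(0.0, noise_sd, size=total.size)

    return normalize(
        RamanSpectrum(library.grid.wavenumbers, total, label="mixture")
    )


# ---------------------------------------------------------------------------
# Viscosity table generator
# ---------------------------------------------------------------------------

#: Operating temperatures of the twin-screw granulator (K), room temperature
#: up to just above the coformer melting point.
DEFAULT_TEMPERATURES: tuple[float, ...] = (298.0, 325.0, 350.0, 375.0, 400.0)

#: Applied shear rates (inverse time, unit carried by the caller's metadata).
DEFAULT_SHEAR_RATES: tuple[float, ...] = (1.0, 0.1, 0.01, 0.001, 0.0001, 0.00001)


def make_viscosity_table(
    carreau: "CarreauParams",
    arrhenius: "ArrheniusParams | None" = None,
    shear_rates: Sequence[float] = DEFAULT_SHEAR_RATES,
    temperatures: Sequence[float] = DEFAULT_TEMPERATURES,
    noise_rel: float = 0.0,
    seed: int = 0,
):
    """Synthesize a (T, shear, viscosity) table from the Carreau model.

    The time constant and power index are shared across temperatures;
    the zero-shear plateau is temperature-scaled through the Arrhenius
    law ``mu0(T) = A * exp(E_R / T)`` when ``arrhenius`` is given.
    Noise is multiplicative lognormal with relative scale ``noise_rel``
    so positivity is preserved.  Viscosity is strictly decreasing in
    shear (before noise) for a pseudoplastic index n < 1.
    """
    import pandas as pd

    from .rheology import carreau_viscosity

    rates = np.asarray(shear_rates, dtype=float)
    if np.any(rates <= 0):
        raise DomainError("shear rates must be strictly positive")
    if noise_rel < 0:
        raise DomainError("noise_rel must be >= 0")

    rng = np.random.default_rng(seed)
    rows = []
    for T in temperatures:
        mu0_T = arrhenius.mu0(T) if arrhenius is not None else carreau.mu0
        p_T = replace(carreau, mu0=float(mu0_T))
        for g in rates:
            mu = carreau_viscosity(float(g), p_T)
            if noise_rel > 0:
                mu *= float(np.exp(rng.normal(0.0, noise_rel)))
            rows.append((float(T), float(g), float(mu)))
    return pd.DataFrame(rows, columns=["T_K", "shear_s-1", "viscosity_cP"])
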