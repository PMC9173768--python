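"""Process design space {T, tau, t, a'_i} on the (T, M) plane.

Temperature T, shear rate tau and residence time t are the three
manipulable operating parameters of a twin-screw granulator.  Shear and
time collapse into the dimensionless gauge parameter

    M = psi * t * tau * f / L

where L is the granulator length, f the screw lead (forward transport
per rotation) and psi a correction factor, taken as 1 by default.  A
design space maps (T, M) cells to mean fingerprint fractions, and an
optimum-window search plus interpolating lookup make it usable as the
decision surface of a process controller.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import (
    BinningError,
    DomainError,
    EmptyInput,
    EmptySpace,
    OutOfBounds,
    UnknownFingerprint,
)
from .unmix import WeightSet

__all__ = [
    "GranulatorSpec",
    "ProcessCondition",
    "DesignSpace",
    "OperatingWindow",
    "LookupResult",
    "FractionField",
    "BLANK_THRESHOLD",
    "compute_M",
    "build_design_space",
    "find_optimum",
    "lookup",
    "screw_speed_for_M",
]

#: Fraction values below this are rendered blank ("nearly zero") in maps.
BLANK_THRESHOLD = 1e-5

#: Default axis ranges: granulator temperatures (K) and the unit M interval.
DEFAULT_T_RANGE = (298.0, 400.0)
DEFAULT_M_RANGE = (0.0, 1.0)


@dataclass(frozen=True)
class GranulatorSpec:
    """Twin-screw granulator geometry: length L (m), screw lead f
    (m per rotation), correction factor psi (dimensionless, default 1)."""

    L: float = 1.0
    f: float = 0.01
    psi: float = 1.0

    def __post_init__(self) -> None:
        if self.L <= 0 or self.f <= 0:
            raise DomainError("granulator L and f must be positive")
        if self.psi <= 0:
            raise DomainError("psi must be positive")


@dataclass(frozen=True)
class ProcessCondition:
    """One operating point: temperature T (K), shear rate tau (inverse
    time), residence/trajectory time t (same time base as tau)."""

    T: float
    tau: float
    t: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise DomainError("shear rate tau must be positive")
        if self.t < 0:
            raise DomainError("time t must be >= 0")


def compute_M(
    cond: ProcessCondition,
    spec: GranulatorSpec,
    clamp: bool = False,
) -> float:
    """Gauge parameter M = psi * t * tau * f / L (dimensionless).

    Linear and strictly increasing in t, tau and f; decreasing in L.
    With ``clamp`` the value is clipped to [0, 1] (with a warning) for
    design-space lookups.
    """
    M = spec.psi * cond.t * cond.tau * spec.f / spec.L
    if clamp and not 0.0 <= M <= 1.0:
        warnings.warn(f"M = {M:.4g} clamped to [0, 1]", stacklevel=2)
        M = float(np.clip(M, 0.0, 1.0))
    return float(M)


def screw_speed_for_M(
    M: float, spec: GranulatorSpec, t: float, tau_per_speed: float
) -> float:
    """Invert M for the screw rotation speed.

    tau = M * L / (psi * t * f), then speed = tau / tau_per_speed where
    ``tau_per_speed`` is the (machine-specific) proportionality between
    shear rate and rotation speed.
    """
    if M < 0:
        raise DomainError("M must be >= 0")
    if t <= 0:
        raise DomainError("residence time t must be positive to invert M")
    if tau_per_speed <= 0:
        raise DomainError("tau_per_speed must be positive")
    tau = M * spec.L / (spec.psi * t * spec.f)
    return tau / tau_per_speed


# ---------------------------------------------------------------------------
# Design space container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignSpace:
    """Binned map from (T, M) cells to mean fingerprint fractions.

    ``fractions[name]`` is an (n_T, n_M) array; NaN marks a cell with no
    contributing estimate ("not computed"), which is distinct from a
    stored near-zero value (< ``BLANK_THRESHOLD``, rendered blank).
    """

    T_edges: np.ndarray
    M_edges: np.ndarray
    fractions: dict[str, np.ndarray]
    counts: np.ndarray
    provenance: str = ""

    @property
    def T_axis(self) -> np.ndarray:
        """Cell centers along T."""
        return 0.5 * (self.T_edges[:-1] + self.T_edges[1:])

    @property
    def M_axis(self) -> np.ndarray:
        return 0.5 * (self.M_edges[:-1] + self.M_edges[1:])

    @property
    def fingerprint_names(self) -> list[str]:
        return list(self.fractions)

    def occupied(self) -> np.ndarray:
        return self.counts > 0

    def blank_mask(self, name: str) -> np.ndarray:
        """Cells whose stored fraction is nearly zero (below 1e-5)."""
        vals = self.fractions[name]
        return (self.counts > 0) & (np.nan_to_num(vals, nan=1.0) < BLANK_THRESHOLD)

    # -- serialization: axes.json + one CSV matrix per fingerprint ---------

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        axes = {
            "T_edges": self.T_edges.tolist(),
            "M_edges": self.M_edges.tolist(),
            "fingerprints": self.fingerprint_names,
            "provenance": self.provenance,
        }
        (d / "axes.json").write_text(json.dumps(axes, indent=1))
        np.savetxt(d / "counts.csv", self.counts, delimiter=",", fmt="%d")
        for name, mat in self.fractions.items():
            np.savetxt(d / f"{name}.csv", mat, delimiter=",")

    @classmethod
    def load(cls, directory: str | Path) -> "DesignSpace":
        d = Path(directory)
        axes = json.loads((d / "axes.json").read_text())
        counts = np.loadtxt(d / "counts.csv", delimiter=",", dtype=int, ndmin=2)
        fractions = {
            name: np.loadtxt(d / f"{name}.csv", delimiter=",", ndmin=2)
            for name in axes["fingerprints"]
        }
        return cls(
            T_edges=np.asarray(axes["T_edges"], float),
            M_edges=np.asarray(axes["M_edges"], float),
            fractions=fractions,
            counts=counts,
            provenance=axes.get("provenance", ""),
        )


def build_design_space(
    estimates: Sequence[tuple[ProcessCondition, WeightSet]],
    spec: GranulatorSpec,
    T_bins: int = 5,
    M_bins: int = 20,
    T_range: tuple[float, float] = DEFAULT_T_RANGE,
    M_range: tuple[float, float] = DEFAULT_M_RANGE,
    provenance: str = "",
) -> DesignSpace:
    """Bin (condition, weights) estimates into a (T, M) design space.

    Each condition maps to a cell via ``compute_M`` (clamped to the M
    range); a cell's fraction is the arithmetic mean of its contributing
    weight sets.  Cells without estimates stay NaN — missing, never
    imputed.
    """
    if not estimates:
        raise EmptyInput("no (condition, weights) estimates supplied")
    if T_bins < 2 or M_bins < 2:
        raise BinningError("need at least 2 bins per axis")

    T_edges = np.linspace(T_range[0], T_range[1], T_bins + 1)
    M_edges = np.linspace(M_range[0], M_range[1], M_bins + 1)

    names: list[str] = []
    for _, ws in estimates:
        for n in ws.weights:
            if n not in names:
                names.append(n)

    sums = {n: np.zeros((T_bins, M_bins)) for n in names}
    counts = np.zeros((T_bins, M_bins), dtype=int)

    def cell_index(value: float, edges: np.ndarray) -> int:
        idx = int(np.searchsorted(edges, value, side="right") - 1)
        return int(np.clip(idx, 0, edges.size - 2))

    for cond, ws in estimates:
        M = compute_M(cond, spec, clamp=True)
        i = cell_index(cond.T, T_edges)
        j = cell_index(M, M_edges)
        counts[i, j] += 1
        for n in names:
            sums[n][i, j] += ws.weights.get(n, 0.0)

    fractions = {}
    with np.errstate(invalid="ignore"):
        for n in names:
            fractions[n] = np.where(counts > 0, sums[n] / np.maximum(counts, 1), np.nan)
    return DesignSpace(
        T_edges=T_edges,
        M_edges=M_edges,
        fractions=fractions,
        counts=counts,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Optimum search and lookup
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OperatingWindow:
    """A rectangular operating window in axis units."""

    T_lo: float
    T_hi: float
    M_lo: float
    M_hi: float

    def contains(self, T: float, M: float) -> bool:
        return self.T_lo <= T <= self.T_hi and self.M_lo <= M <= self.M_hi

    @property
    def T_center(self) -> float:
        return 0.5 * (self.T_lo + self.T_hi)

    @property
    def M_center(self) -> float:
        return 0.5 * (self.M_lo + self.M_hi)


def find_optimum(space: DesignSpace, targets: Sequence[str]) -> OperatingWindow:
    """Locate the cell window maximizing the summed target fraction.

    Ties are broken toward the lowest temperature, then the lowest M
    (row-major scan), so a flat field deterministically returns the
    lowest-T, lowest-M cell.
    """
    for t in targets:
        if t not in space.fractions:
            raise UnknownFingerprint(f"target {t!r} not in design space")
    occ = space.occupied()
    if not occ.any():
        raise EmptySpace("design space has no occupied cell")

    score = np.zeros_like(space.counts, dtype=float)
    for t in targets:
        score += np.nan_to_num(space.fractions[t], nan=0.0)
    score[~occ] = -np.inf

    best = float(score.max())
    # first index pair achieving the max, scanning T ascending then M
    i, j = next(zip(*np.nonzero(score == best)))
    return OperatingWindow(
        T_lo=float(space.T_edges[i]),
        T_hi=float(space.T_edges[i + 1]),
        M_lo=float(space.M_edges[j]),
        M_hi=float(space.M_edges[j + 1]),
    )


@dataclass(frozen=True)
class LookupResult:
    fractions: dict[str, float]
    had_missing_neighbors: bool


def lookup(space: DesignSpace, T: float, M: float) -> LookupResult:
    """Bilinear interpolation of fractions at (T, M) over occupied cells.

    Queries must fall within the axis bounds (cell edges).  Neighbors
    with no estimate are excluded and the interpolation weights
    renormalized; the result flags that exclusion.  Queries between an
    outer edge and the first cell center use the nearest cell.
    """
    if not (space.T_edges[0] <= T <= space.T_edges[-1]):
        raise OutOfBounds(f"T = {T} outside [{space.T_edges[0]}, {space.T_edges[-1]}]")
    if not (space.M_edges[0] <= M <= space.M_edges[-1]):
        raise OutOfBounds(f"M = {M} outside [{space.M_edges[0]}, {space.M_edges[-1]}]")

    def bracket(value: float, centers: np.ndarray) -> tuple[int, int, float]:
        if value <= centers[0]:
            return 0, 0, 0.0
        if value >= centers[-1]:
            return centers.size - 1, centers.size - 1, 0.0
        hi = int(np.searchsorted(centers, value))
        lo = hi - 1
        frac = (value - centers[lo]) / (centers[hi] - centers[lo])
        return lo, hi, float(frac)

    i0, i1, fT = bracket(T, space.T_axis)
    j0, j1, fM = bracket(M, space.M_axis)
    corners = [
        ((i0, j0), (1 - fT) * (1 - fM)),
        ((i0, j1), (1 - fT) * fM),
        ((i1, j0), fT * (1 - fM)),
        ((i1, j1), fT * fM),
    ]
    occ = space.occupied()
    used = [(idx, w) for idx, w in corners if w > 0 or (i0 == i1 and j0 == j1)]
    # deduplicate corners collapsed by edge clamping
    seen: dict[tuple[int, int], float] = {}
    for idx, w in used:
        seen[idx] = seen.get(idx, 0.0) + w
    missing = any(not occ[idx] for idx in seen)
    alive = {idx: w for idx, w in seen.items() if occ[idx]}
    total = sum(alive.values())
    if total <= 0:
        return LookupResult(fractions={n: np.nan for n in space.fractions}, had_missing_neighbors=True)
    fractions = {}
    for name, mat in space.fractions.items():
        fractions[name] = float(
            sum(w * mat[idx] for idx, w in alive.items()) / total
        )
    return LookupResult(fractions=fractions, had_missing_neighbors=missing)


# ---------------------------------------------------------------------------
# Synthetic fraction field (ground-truth fixture for pipeline tests)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Surface:
    """Parametric fraction surface over (T, M).

    kinds: 'unimodal' — Gaussian bump at (T_center, M_center) with
    widths (T_width, M_width) and peak ``height``; 'monotone' —
    ``height * exp(M_slope * M)``; 'flat' — constant ``height``.
    """

    kind: str
    height: float
    T_center: float = 349.0
    M_center: float = 0.5
    T_width: float = 30.0
    M_width: float = 0.2
    M_slope: float = 0.0

    def raw(self, T: np.ndarray | float, M: np.ndarray | float) -> np.ndarray:
        T = np.asarray(T, float)
        M = np.asarray(M, float)
        if self.kind == "unimodal":
            return self.height * np.exp(
                -(((T - self.T_center) / self.T_width) ** 2)
                - ((M - self.M_center) / self.M_width) ** 2
            )
        if self.kind == "monotone":
            return self.height * np.exp(self.M_slope * M) * np.ones_like(T)
        if self.kind == "flat":
            return np.full(np.broadcast(T, M).shape, self.height)
        raise DomainError(f"unknown surface kind {self.kind!r}")


class FractionField:
    """Ground-truth fingerprint-fraction surfaces over the (T, M) plane.

    A synthetic stand-in for the molecular-simulation-derived fraction
    maps: each fingerprint carries a parametric surface, and fractions
    at any (T, M) are the surface values normalized to sum to one.  The
    field knows its own optimum window (computed from the cell-mean
    truth with the same argmax rule the design space uses), so pipeline
    tests can check end-to-end recovery against it.
    """

    def __init__(self, surfaces: Mapping[str, Surface]):
        self.surfaces = dict(surfaces)

    @property
    def fingerprint_names(self) -> list[str]:
        return list(self.surfaces)

    def fractions(self, T: float, M: float) -> dict[str, float]:
        raw = {n: float(s.raw(T, M)) for n, s in self.surfaces.items()}
        total = sum(raw.values())
        return {n: v / total for n, v in raw.items()}

    def weight_set(self, T: float, M: float) -> WeightSet:
        return WeightSet(weights=self.fractions(T, M))

    def true_design_space(
        self,
        T_bins: int = 5,
        M_bins: int = 20,
        T_range: tuple[float, float] = DEFAULT_T_RANGE,
        M_range: tuple[float, float] = DEFAULT_M_RANGE,
    ) -> DesignSpace:
        """Exact cell-center design space of the field (no unmixing)."""
        T_edges = np.linspace(T_range[0], T_range[1], T_bins + 1)
        M_edges = np.linspace(M_range[0], M_range[1], M_bins + 1)
        Tc = 0.5 * (T_edges[:-1] + T_edges[1:])
        Mc = 0.5 * (M_edges[:-1] + M_edges[1:])
        fractions = {n: np.zeros((T_bins, M_bins)) for n in self.surfaces}
        for i, T in enumerate(Tc):
            for j, M in enumerate(Mc):
                for n, v in self.fractions(float(T), float(M)).items():
                    fractions[n][i, j] = v
        return DesignSpace(
            T_edges=T_edges,
            M_edges=M_edges,
            fractions=fractions,
            counts=np.ones((T_bins, M_bins), dtype=int),
            provenance="synthetic-fraction-field",
        )

    def encoded_optimum(
        self, targets: Sequence[str], T_bins: int = 5, M_bins: int = 20
    ) -> OperatingWindow:
        return find_optimum(self.true_design_space(T_bins, M_bins), targets)

    @classmethod
    def default_cocrystal_field(cls) -> "FractionField":
        """Seven-fingerprint field whose target-cocrystal optimum sits
        near T = 345 K, M = 0.475: two cocrystal fingerprints (CO-5,
        CO-2) peak there, one cocrystal (CO-1) decays with M, two are
        near-zero, and the dimers form a mild background."""
        return cls(
            {
                "CO-1": Surface(kind="monotone", height=0.20, M_slope=-2.2),
                "CO-2": Surface(
                    kind="unimodal", height=0.35,
                    T_center=347.0, M_center=0.50, T_width=35.0, M_width=0.20,
                ),
                "CO-3": Surface(kind="flat", height=1e-3),
                "CO-4": Surface(kind="flat", height=5e-6),
                "CO-5": Surface(
                    kind="unimodal", height=0.50,
                    T_center=345.0, M_center=0.475, T_width=28.0, M_width=0.16,
                ),
                "DI-1": Surface(kind="monotone", height=0.12, M_slope=-0.5),
                "DN-1": Surface(kind="flat", height=0.10),
            }
        )
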