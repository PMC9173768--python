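"""Flory-Huggins miscibility screening of fingerprint pairs.

Before building a design space it is worth asking which molecular
interaction pairs can coexist in a mixed phase at all.  Lattice
solution theory condenses that question into the dimensionless
interaction parameter chi: small or negative chi favors mixing, large
positive chi favors demixing, with the critical value for a binary pair
of segment counts (m_i, m_j)

    chi_crit = 1/2 * (1/sqrt(m_i) + 1/sqrt(m_j))^2      (= 2 for 1, 1).

Two standard routes to chi are provided:

* solubility parameters (Hildebrand):  chi = V_ref (delta_i - delta_j)^2 / (R T)
  — always nonnegative, suitable when only cohesion densities are known;
* exchange energies:  chi = z (w_ij - (w_ii + w_jj)/2) / (R T)
  — signed, the route of choice when pairwise interaction energies are
  available (e.g. from electronic-structure calculations), since only
  it can express favorable (negative-chi) cross interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.constants import R as R_GAS  # J / (mol K)

from .errors import DomainError, MissingDescriptor

__all__ = [
    "FingerprintDescriptor",
    "ChiMatrix",
    "chi_from_solubility",
    "chi_from_energies",
    "classify_miscibility",
    "critical_chi",
]

#: Reference molar volume, m^3/mol — typical small-molecule magnitude.
DEFAULT_V_REF = 1.0e-4
#: Lattice coordination number.
DEFAULT_Z = 6


@dataclass(frozen=True)
class FingerprintDescriptor:
    """Thermodynamic descriptors of one fingerprint.

    ``delta``: Hildebrand solubility parameter, MPa^0.5 (optional).
    ``pair_energy``: partner name -> interaction energy w, kJ/mol;
    must include the self energy (partner == own name) for the
    energy route.  ``segments``: lattice segment count m (default 1).
    """

    name: str
    delta: float | None = None
    pair_energy: Mapping[str, float] = field(default_factory=dict)
    segments: int = 1

    def __post_init__(self) -> None:
        if self.delta is None and not self.pair_energy:
            raise MissingDescriptor(
                f"{self.name!r} needs a solubility parameter or pair energies"
            )
        if self.segments < 1:
            raise DomainError("segment count must be >= 1")


@dataclass(frozen=True)
class ChiMatrix:
    """Symmetric Flory-Huggins interaction matrix at temperature T (K)."""

    names: list[str]
    chi: np.ndarray
    T: float

    def __post_init__(self) -> None:
        c = np.asarray(self.chi, float)
        if c.shape != (len(self.names), len(self.names)):
            raise DomainError("chi matrix shape does not match names")
        if not np.allclose(c, c.T):
            raise DomainError("chi matrix must be symmetric")
        if not np.allclose(np.diag(c), 0.0):
            raise DomainError("chi diagonal must be zero")
        object.__setattr__(self, "chi", c)

    def value(self, a: str, b: str) -> float:
        i, j = self.names.index(a), self.names.index(b)
        return float(self.chi[i, j])


def chi_from_solubility(
    descriptors: Sequence[FingerprintDescriptor],
    T: float,
    V_ref: float = DEFAULT_V_REF,
) -> ChiMatrix:
    """chi_ij = V_ref * (delta_i - delta_j)^2 / (R T); delta in MPa^0.5."""
    if T <= 0 or V_ref <= 0:
        raise DomainError("T and V_ref must be positive")
    deltas = []
    for d in descriptors:
        if d.delta is None:
            raise MissingDescriptor(f"{d.name!r} lacks a solubility parameter")
        deltas.append(d.delta * 1e3)  # MPa^0.5 -> Pa^0.5
    delta = np.asarray(deltas)
    diff = delta[:, None] - delta[None, :]
    chi = V_ref * diff**2 / (R_GAS * T)
    return ChiMatrix(names=[d.name for d in descriptors], chi=chi, T=T)


def chi_from_energies(
    descriptors: Sequence[FingerprintDescriptor],
    T: float,
    z: int = DEFAULT_Z,
) -> ChiMatrix:
    """chi_ij = z * (w_ij - (w_ii + w_jj)/2) / (R T); w in kJ/mol.

    Negative chi (cross contact more favorable than the self average)
    signals a mixing tendency.
    """
    if T <= 0:
        raise DomainError("T must be positive")
    if z < 1:
        raise DomainError("coordination number z must be >= 1")
    names = [d.name for d in descriptors]
    by_name = {d.name: d for d in descriptors}

    def w(a: str, b: str) -> float:
        da = by_name[a]
        if b in da.pair_energy:
            return float(da.pair_energy[b])
        db = by_name[b]
        if a in db.pair_energy:
            return float(db.pair_energy[a])
        raise MissingDescriptor(f"missing pair energy for ({a!r}, {b!r})")

    n = len(names)
    chi = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            exchange = w(names[i], names[j]) - 0.5 * (
                w(names[i], names[i]) + w(names[j], names[j])
            )
            chi[i, j] = chi[j, i] = z * exchange * 1e3 / (R_GAS * T)
    return ChiMatrix(names=names, chi=chi, T=T)


def critical_chi(m_i: int, m_j: int) -> float:
    """Binary Flory-Huggins critical value: 1/2 (1/sqrt(m_i) + 1/sqrt(m_j))^2."""
    return 0.5 * (1.0 / np.sqrt(m_i) + 1.0 / np.sqrt(m_j)) ** 2


def classify_miscibility(
    chi: ChiMatrix, segments: Mapping[str, int] | None = None
) -> dict[tuple[str, str], str]:
    """Label each unordered pair 'miscible' (chi <= chi_crit) or 'demixing'."""
    segments = segments or {}
    out: dict[tuple[str, str], str] = {}
    for i, a in enumerate(chi.names):
        for j in range(i + 1, len(chi.names)):
            b = chi.names[j]
            crit = critical_chi(segments.get(a, 1), segments.get(b, 1))
            key = tuple(sorted((a, b)))
            out[key] = "miscible" if chi.chi[i, j] <= crit else "demixing"
    return out
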