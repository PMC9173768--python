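"""Polynomial (Volterra-kernel) spectral unmixing via pseudoinverse.

A probe-measured mixture spectrum R is modelled as a truncated
polynomial in the normalized basis spectra r_i (isolated molecules A, B
plus the N interaction fingerprints):

    R ~ a + sum_i a_i r_i + sum_{i<=j} a_ij r_i r_j
          + sum_{i<=j<=k} a_ijk r_i r_j r_k

evaluated pointwise over the wavenumber grid.  Writing the model as
R = rho @ A, the coefficient vector A is the minimum-norm least-squares
solution obtained from the Moore-Penrose pseudoinverse of the design
matrix rho — rho may be rank deficient (duplicated or overlapping
fingerprints) and the pseudoinverse handles that without failure.

Only the *linear* coefficients carry direct physical meaning: the
intuitive fingerprint weight is

    a'_i = a_i / sum_{fingerprints j} a_j

after discarding the isolated-molecule contributions a_A, a_B as
spectral contamination.  Higher-order terms absorb band overlap and are
kept purely to improve the reconstruction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import GridMismatch, ShapeError, ZeroDenominator
from .spectra import FingerprintLibrary, RamanSpectrum, normalize, restrict_library, restrict_range

__all__ = [
    "CoefficientSet",
    "WeightSet",
    "FitResult",
    "DEFAULT_RCOND",
    "MEASUREMENT_RCOND",
    "build_design_matrix",
    "solve_coefficients",
    "extract_weights",
    "unmix",
    "is_noise_dominated",
]

#: Relative cutoff for small singular values in the pseudoinverse.
#: The tight default preserves exact algebraic recovery on noiseless,
#: consistent systems.
DEFAULT_RCOND = 1e-10

#: Coarser cutoff for noisy (probe-measured) spectra.  The polynomial
#: design matrix is severely ill-conditioned, so with measurement noise
#: the small singular directions only amplify noise into the linear
#: coefficients; truncating them acts as regularization and stabilizes
#: the extracted weights at percent-level spectral noise.
MEASUREMENT_RCOND = 1e-3


def _canon(names: Sequence[str]) -> tuple[str, ...]:
    return tuple(sorted(names))


@dataclass
class CoefficientSet:
    """Polynomial coefficients a, a_i, a_ij, a_ijk.

    Pair and triple keys are stored canonically (sorted tuples), so the
    symmetric duplicates of the raw double/triple sums collapse to one
    coefficient each.
    """

    constant: float = 0.0
    linear: dict[str, float] = field(default_factory=dict)
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)
    triple: dict[tuple[str, str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pairwise = {_canon(k): v for k, v in self.pairwise.items()}
        self.triple = {_canon(k): v for k, v in self.triple.items()}

    def fingerprint_linear(self) -> dict[str, float]:
        """Linear coefficients with the isolated molecules removed."""
        return {k: v for k, v in self.linear.items() if k not in ("A", "B")}


@dataclass(frozen=True)
class WeightSet:
    """Intuitive fingerprint weights a'_i (sum to 1) plus the removed
    isolated-molecule contributions (a_A, a_B)."""

    weights: dict[str, float]
    noise_share: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class FitResult:
    coefficients: CoefficientSet
    weights: WeightSet
    reconstruction: RamanSpectrum
    relative_error: float  # percent, ||R - R_hat|| / ||R|| * 100
    rank: int
    condition_estimate: float


def build_design_matrix(
    library: FingerprintLibrary, order: int = 3
) -> tuple[np.ndarray, list[tuple[str, ...]]]:
    """Assemble the polynomial design matrix rho and its column index.

    Columns: one constant column of ones, the P = N + 2 basis spectra,
    then all unique elementwise products of 2 (order >= 2) and 3
    (order >= 3) basis spectra — multiset combinations, so P(P+1)/2
    pair columns and P(P+1)(P+2)/6 triple columns.
    """
    if order not in (1, 2, 3):
        raise ShapeError(f"order must be 1, 2 or 3, got {order}")
    names = library.basis_names
    ref = library.grid.wavenumbers
    for spec in library.all_spectra().values():
        if len(spec) != ref.size or not np.allclose(spec.wavenumbers, ref, rtol=0, atol=1e-6):
            raise GridMismatch(f"spectrum {spec.label!r} not on the shared grid")

    basis = library.basis_matrix()  # n x P
    cols: dict[str, np.ndarray] = {n: basis[:, i] for i, n in enumerate(names)}

    columns: list[np.ndarray] = [np.ones(ref.size)]
    index: list[tuple[str, ...]] = [()]
    for n in names:
        columns.append(cols[n])
        index.append((n,))
    if order >= 2:
        for i, j in itertools.combinations_with_replacement(names, 2):
            columns.append(cols[i] * cols[j])
            index.append(_canon((i, j)))
    if order >= 3:
        for i, j, k in itertools.combinations_with_replacement(names, 3):
            columns.append(cols[i] * cols[j] * cols[k])
            index.append(_canon((i, j, k)))
    return np.column_stack(columns), index


def _coeffs_from_vector(
    vector: np.ndarray, index: Sequence[tuple[str, ...]]
) -> CoefficientSet:
    cs = CoefficientSet()
    for value, key in zip(vector, index):
        if len(key) == 0:
            cs.constant = float(value)
        elif len(key) == 1:
            cs.linear[key[0]] = float(value)
        elif len(key) == 2:
            cs.pairwise[key] = float(value)
        else:
            cs.triple[key] = float(value)
    return cs


def solve_coefficients(
    rho: np.ndarray,
    R: RamanSpectrum | np.ndarray,
    index: Sequence[tuple[str, ...]],
    rcond: float = DEFAULT_RCOND,
) -> CoefficientSet:
    """Minimum-norm least-squares solve of R = rho @ A via pseudoinverse.

    Never fails on rank deficiency: singular values below ``rcond``
    times the largest are treated as zero.
    """
    y = R.intensities if isinstance(R, RamanSpectrum) else np.asarray(R, float)
    if y.shape[0] != rho.shape[0]:
        raise ShapeError(
            f"spectrum length {y.shape[0]} != design matrix rows {rho.shape[0]}"
        )
    if len(index) != rho.shape[1]:
        raise ShapeError("column index length does not match design matrix")
    solution = np.linalg.pinv(rho, rcond=rcond) @ y
    return _coeffs_from_vector(solution, index)


def extract_weights(
    coefficients: CoefficientSet, clip_negative: bool = False
) -> WeightSet:
    """Normalize fingerprint linear coefficients into weights a'_i.

    a'_i = a_i / sum_j a_j over fingerprints only; the isolated-molecule
    coefficients a_A, a_B are removed and reported as ``noise_share``.
    Negative weights are reported as-is unless ``clip_negative`` is set,
    in which case they are clipped to zero and the rest renormalized
    (useful for a controller that needs proper fractions).
    """
    fp = coefficients.fingerprint_linear()
    if not fp:
        raise ZeroDenominator("no fingerprint linear coefficients present")
    denom = sum(fp.values())
    if abs(denom) < 1e-12:
        raise ZeroDenominator(
            f"fingerprint coefficients sum to {denom:.3e}; weights undefined"
        )
    weights = {k: v / denom for k, v in fp.items()}
    if clip_negative:
        clipped = {k: max(v, 0.0) for k, v in weights.items()}
        total = sum(clipped.values())
        if total < 1e-12:
            raise ZeroDenominator("all weights clipped to zero")
        weights = {k: v / total for k, v in clipped.items()}
    noise = (coefficients.linear.get("A", 0.0), coefficients.linear.get("B", 0.0))
    return WeightSet(weights=weights, noise_share=noise)


def is_noise_dominated(coefficients: CoefficientSet, ratio: float = 100.0) -> bool:
    """True when isolated-molecule linear coefficients dwarf the
    fingerprint ones — the 'all-noise' case (e.g. a pure molecule-A
    spectrum), where extracted weights would be meaningless."""
    fp = sum(abs(v) for v in coefficients.fingerprint_linear().values())
    mol = abs(coefficients.linear.get("A", 0.0)) + abs(coefficients.linear.get("B", 0.0))
    return mol > ratio * fp


def unmix(
    library: FingerprintLibrary,
    R: RamanSpectrum,
    order: int = 3,
    band: tuple[float, float] | None = None,
    clip_negative: bool = False,
    rcond: float = DEFAULT_RCOND,
) -> FitResult:
    """Full unmixing pipeline: restrict -> design matrix -> solve -> weights.

    ``band`` restricts both the library and the measured spectrum to a
    wavenumber window (re-normalizing each) before fitting — e.g. the
    700-1200 cm^-1 window conventionally used to monitor one cocrystal
    band.  ``relative_error`` is the norm-relative reconstruction error
    in percent.

    With the full 21-fingerprint default library at order 3 the system
    is underdetermined (more columns than grid points); the minimum-norm
    solution is still returned, but weight identifiability then rests on
    the spectral distinctness of the basis — prefer a reduced library
    when quantitative weights matter.
    """
    if band is not None:
        lo, hi = band
        library = restrict_library(library, lo, hi)
        R = normalize(restrict_range(R, lo, hi))
    elif not R.is_normalized:
        R = normalize(R)

    rho, index = build_design_matrix(library, order=order)
    y = R.intensities

    # One SVD serves the solve, the rank and the conditioning report.
    u, s, vt = np.linalg.svd(rho, full_matrices=False)
    cutoff = rcond * s[0] if s.size else 0.0
    keep = s > cutoff
    rank = int(keep.sum())
    inv_s = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
    solution = vt.T @ (inv_s * (u.T @ y))
    coefficients = _coeffs_from_vector(solution, index)

    reconstruction = rho @ solution
    rel_err = 100.0 * float(
        np.linalg.norm(y - reconstruction) / np.linalg.norm(y)
    )
    weights = extract_weights(coefficients, clip_negative=clip_negative)
    return FitResult(
        coefficients=coefficients,
        weights=weights,
        reconstruction=RamanSpectrum(
            R.wavenumbers, reconstruction, label="reconstruction"
        ),
        relative_error=rel_err,
        rank=rank,
        condition_estimate=float(s[0] / s[keep][-1]) if rank else np.inf,
    )
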