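"""Closed-loop control sketch: probe spectrum -> fractions -> setpoint move.

The design space doubles as the decision surface of a simple process
controller: at each step the probe-measured Raman spectrum is unmixed
into fingerprint fractions, the current operating point (T, M) is
compared against the optimum window for the target fingerprints, and a
bounded step of temperature and/or screw speed toward that window is
recommended.  Speed is the preferred handle: once the temperature sits
inside its optimal band, only the screw speed is adjusted (barrel
temperature is slow and lossy to manipulate on an uninsulated machine).

The state-to-M mapping uses a fixed configured residence time t and a
machine proportionality tau = tau_per_speed * speed, giving
M = psi * t * f * tau_per_speed * speed / L — linear in speed, so speed
is an effective actuator for M.  Real installations can substitute
their own mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .design_space import (
    DesignSpace,
    FractionField,
    GranulatorSpec,
    OperatingWindow,
    ProcessCondition,
    compute_M,
    find_optimum,
)
from .errors import DomainError, ZeroDenominator
from .spectra import FingerprintLibrary, RamanSpectrum, resample, synthesize_mixture
from .unmix import MEASUREMENT_RCOND, CoefficientSet, WeightSet, unmix

__all__ = [
    "ControllerState",
    "ControllerConfig",
    "Recommendation",
    "estimate_fractions",
    "recommend",
    "run_closed_loop",
    "survey_design_space",
]


@dataclass(frozen=True)
class ControllerState:
    """Current operating point and actuator limits of the granulator."""

    T: float                       # K
    speed: float                   # rotations / s
    spec: GranulatorSpec
    target: tuple[str, ...]
    T_bounds: tuple[float, float] = (298.0, 400.0)
    speed_bounds: tuple[float, float] = (0.01, 100.0)
    tau_per_speed: float = 1.0     # shear rate per unit rotation speed
    residence_time: float = 50.0   # s, configured mean residence time

    def __post_init__(self) -> None:
        if not self.T_bounds[0] <= self.T <= self.T_bounds[1]:
            raise DomainError("T outside configured bounds")
        if not self.speed_bounds[0] <= self.speed <= self.speed_bounds[1]:
            raise DomainError("speed outside configured bounds")
        if self.tau_per_speed <= 0 or self.residence_time <= 0:
            raise DomainError("tau_per_speed and residence_time must be positive")

    @property
    def tau(self) -> float:
        return self.tau_per_speed * self.speed

    @property
    def M(self) -> float:
        cond = ProcessCondition(T=self.T, tau=self.tau, t=self.residence_time)
        return compute_M(cond, self.spec)

    def speed_for_M(self, M: float) -> float:
        c = (
            self.spec.psi * self.residence_time * self.spec.f * self.tau_per_speed
            / self.spec.L
        )
        return M / c


@dataclass(frozen=True)
class ControllerConfig:
    """Step limits of the (deliberately simple) control policy."""

    step_T: float = 5.0            # K per move
    step_speed_frac: float = 0.10  # relative speed change per move


@dataclass(frozen=True)
class Recommendation:
    action: str                    # 'hold' | 'adjust'
    delta_T: float
    delta_speed: float
    estimated_fractions: WeightSet
    rationale: str

    def __post_init__(self) -> None:
        if self.action == "hold" and (self.delta_T != 0 or self.delta_speed != 0):
            raise DomainError("hold implies zero deltas")


def estimate_fractions(
    R: RamanSpectrum,
    library: FingerprintLibrary,
    rcond: float = MEASUREMENT_RCOND,
) -> WeightSet:
    """Unmix a probe spectrum into fingerprint fractions (order 3,
    negatives clipped and renormalized, coarse singular-value cutoff —
    all for robustness against measurement noise).

    Resamples onto the library grid when needed.  A spectrum carrying
    only isolated-molecule signal raises :class:`ZeroDenominator` — the
    all-noise case a controller must treat as "no fingerprint present".
    """
    if len(R) != library.grid.n_points or not np.allclose(
        R.wavenumbers, library.grid.wavenumbers
    ):
        R = resample(R, library.grid)
    result = unmix(library, R, order=3, clip_negative=True, rcond=rcond)
    return result.weights


def recommend(
    state: ControllerState,
    fractions: WeightSet,
    space: DesignSpace,
    config: ControllerConfig | None = None,
) -> Recommendation:
    """Compare (T, M) against the optimum window and propose one move.

    Inside the window: hold.  Outside: step T toward the window's
    temperature band (only while T is outside it) and step speed toward
    the window's M band, both bounded by the config step sizes and the
    state's actuator limits.
    """
    cfg = config or ControllerConfig()
    window: OperatingWindow = find_optimum(space, list(state.target))
    T, M = state.T, state.M

    if window.contains(T, M):
        return Recommendation(
            action="hold", delta_T=0.0, delta_speed=0.0,
            estimated_fractions=fractions,
            rationale=f"(T={T:.1f} K, M={M:.3f}) inside optimum window",
        )

    delta_T = 0.0
    if not (window.T_lo <= T <= window.T_hi):
        raw = np.clip(window.T_center - T, -cfg.step_T, cfg.step_T)
        new_T = float(np.clip(T + raw, *state.T_bounds))
        delta_T = new_T - T

    delta_speed = 0.0
    if not (window.M_lo <= M <= window.M_hi):
        desired = state.speed_for_M(window.M_center)
        cap = cfg.step_speed_frac * state.speed
        raw = np.clip(desired - state.speed, -cap, cap)
        new_speed = float(np.clip(state.speed + raw, *state.speed_bounds))
        delta_speed = new_speed - state.speed

    return Recommendation(
        action="adjust", delta_T=delta_T, delta_speed=delta_speed,
        estimated_fractions=fractions,
        rationale=(
            f"(T={T:.1f} K, M={M:.3f}) outside window "
            f"[{window.T_lo:.1f}, {window.T_hi:.1f}] K x "
            f"[{window.M_lo:.3f}, {window.M_hi:.3f}]"
        ),
    )


def apply(state: ControllerState, rec: Recommendation) -> ControllerState:
    """Apply a recommendation; a hold leaves the state unchanged."""
    if rec.action == "hold":
        return state
    return replace(state, T=state.T + rec.delta_T, speed=state.speed + rec.delta_speed)


def survey_design_space(
    field: FractionField,
    library: FingerprintLibrary,
    spec: GranulatorSpec,
    T_bins: int = 5,
    M_bins: int = 20,
    noise_sd: float = 0.01,
    contamination: float = 0.05,
    seed: int = 0,
    rcond: float = MEASUREMENT_RCOND,
) -> DesignSpace:
    """Build a design space by surveying a synthetic plant.

    For every (T, M) cell center, a mixture spectrum is synthesized
    from the field's true fractions (plus isolated-molecule
    contamination and Gaussian noise), unmixed into weights, and the
    (condition, weights) estimates are binned into a design space —
    the full measure-then-map pipeline, exercised end to end.
    """
    from .design_space import build_design_space

    rng = np.random.default_rng(seed)
    T_edges = np.linspace(298.0, 400.0, T_bins + 1)
    M_edges = np.linspace(0.0, 1.0, M_bins + 1)
    T_centers = 0.5 * (T_edges[:-1] + T_edges[1:])
    M_centers = 0.5 * (M_edges[:-1] + M_edges[1:])

    estimates = []
    tau = 1.0
    for T in T_centers:
        for M in M_centers:
            t = float(M) * spec.L / (spec.psi * tau * spec.f)
            cond = ProcessCondition(T=float(T), tau=tau, t=t)
            truth = field.fractions(float(T), float(M))
            coeffs = CoefficientSet(
                linear={**truth, "A": contamination, "B": contamination}
            )
            mix_seed = int(rng.integers(0, 2**31 - 1))
            R = synthesize_mixture(library, coeffs, noise_sd=noise_sd, seed=mix_seed)
            weights = unmix(library, R, order=3, clip_negative=True, rcond=rcond).weights
            estimates.append((cond, weights))
    return build_design_space(
        estimates, spec, T_bins=T_bins, M_bins=M_bins,
        provenance="synthetic-plant-survey",
    )


def run_closed_loop(
    field: FractionField,
    library: FingerprintLibrary,
    space: DesignSpace,
    state: ControllerState,
    steps: int = 50,
    seed: int = 0,
    noise_sd: float = 0.01,
    contamination: float = 0.05,
    config: ControllerConfig | None = None,
) -> pd.DataFrame:
    """Simulate the full loop on a synthetic plant.

    The plant's true composition at the current (T, M) comes from the
    fraction field; a mixture spectrum is synthesized from it (plus
    isolated-molecule contamination and Gaussian noise), unmixed, and
    the recommendation applied.  Returns a per-step log with columns
    (step, T, speed, M, action, plus one fraction column per estimated
    fingerprint).  Deterministic given the seed.
    """
    if steps < 1:
        raise DomainError("steps must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(steps):
        M_plant = float(np.clip(state.M, 0.0, 1.0))
        truth = field.fractions(state.T, M_plant)
        coeffs = CoefficientSet(
            linear={**truth, "A": contamination, "B": contamination}
        )
        step_seed = int(rng.integers(0, 2**31 - 1))
        R = synthesize_mixture(library, coeffs, noise_sd=noise_sd, seed=step_seed)
        try:
            fractions = estimate_fractions(R, library)
        except ZeroDenominator:
            fractions = WeightSet(weights={n: 0.0 for n in field.fingerprint_names})
        rec = recommend(state, fractions, space, config=config)
        rows.append(
            {
                "step": k,
                "T": state.T,
                "speed": state.speed,
                "M": state.M,
                "action": rec.action,
                **{f"frac_{n}": v for n, v in fractions.weights.items()},
            }
        )
        state = apply(state, rec)
    return pd.DataFrame(rows)
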