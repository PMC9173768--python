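"""Gauge parameter M, design-space binning, optimum search and lookup."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tscocryst import (
    DesignSpace,
    GranulatorSpec,
    ProcessCondition,
    build_design_space,
    compute_M,
    find_optimum,
    lookup,
    screw_speed_for_M,
)
from tscocryst.design_space import FractionField, OperatingWindow, Surface
from tscocryst.errors import (
    DomainError,
    EmptyInput,
    OutOfBounds,
    UnknownFingerprint,
)
from tscocryst.unmix import WeightSet


class TestComputeM:
    def test_worked_example(self):
        spec = GranulatorSpec(L=1.0, f=0.01, psi=1.0)
        cond = ProcessCondition(T=350, tau=2.0, t=50.0)
        assert compute_M(cond, spec) == pytest.approx(1.0)

    def test_zero_time(self):
        spec = GranulatorSpec(L=1.0, f=0.01)
        assert compute_M(ProcessCondition(T=350, tau=1.0, t=0.0), spec) == 0.0

    def test_default_psi_is_one(self):
        assert GranulatorSpec().psi == 1.0

    @given(
        t=st.floats(min_value=0.1, max_value=1e3),
        tau=st.floats(min_value=0.1, max_value=1e2),
        f=st.floats(min_value=1e-3, max_value=1.0),
        L=st.floats(min_value=0.1, max_value=10.0),
        factor=st.floats(min_value=1.01, max_value=10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotonicity(self, t, tau, f, L, factor):
        """M increases with t, tau and f; decreases with L."""
        spec = GranulatorSpec(L=L, f=f)
        base = compute_M(ProcessCondition(T=300, tau=tau, t=t), spec)
        assert compute_M(ProcessCondition(T=300, tau=tau, t=t * factor), spec) > base
        assert compute_M(ProcessCondition(T=300, tau=tau * factor, t=t), spec) > base
        assert compute_M(
            ProcessCondition(T=300, tau=tau, t=t), GranulatorSpec(L=L, f=f * factor)
        ) > base
        assert compute_M(
            ProcessCondition(T=300, tau=tau, t=t), GranulatorSpec(L=L * factor, f=f)
        ) < base

    def test_invalid_geometry(self):
        with pytest.raises(DomainError):
            GranulatorSpec(L=0.0, f=0.01)
        with pytest.raises(DomainError):
            GranulatorSpec(L=1.0, f=-1.0)


class TestScrewSpeed:
    def test_inverts_compute_M(self):
        spec = GranulatorSpec(L=2.0, f=0.02)
        speed, t, tau_per_speed = 3.7, 40.0, 1.5
        tau = tau_per_speed * speed
        M = compute_M(ProcessCondition(T=300, tau=tau, t=t), spec)
        assert screw_speed_for_M(M, spec, t, tau_per_speed) == pytest.approx(
            speed, abs=1e-9
        )

    def test_zero_M_zero_speed(self):
        assert screw_speed_for_M(0.0, GranulatorSpec(), 10.0, 1.0) == 0.0

    def test_doubling_lead_halves_speed(self):
        spec = GranulatorSpec(L=1.0, f=0.01)
        spec2 = GranulatorSpec(L=1.0, f=0.02)
        s1 = screw_speed_for_M(0.5, spec, 50.0, 1.0)
        s2 = screw_speed_for_M(0.5, spec2, 50.0, 1.0)
        assert s2 == pytest.approx(s1 / 2)

    def test_zero_time_rejected(self):
        with pytest.raises(DomainError):
            screw_speed_for_M(0.5, GranulatorSpec(), 0.0, 1.0)


def ws(**weights):
    return WeightSet(weights=weights)


def cond_for_M(M, spec, T):
    tau = 1.0
    t = M * spec.L / (spec.psi * tau * spec.f)
    return ProcessCondition(T=T, tau=tau, t=t)


class TestBuildDesignSpace:
    def test_single_estimate_occupies_one_cell(self, granulator):
        cond = cond_for_M(0.475, granulator, 345.0)
        space = build_design_space([(cond, ws(F1=0.4, F2=0.6))], granulator)
        assert space.counts.sum() == 1
        i, j = np.argwhere(space.counts)[0]
        assert space.fractions["F1"][i, j] == pytest.approx(0.4)
        assert np.isnan(space.fractions["F1"][0, 0])

    def test_cell_mean(self, granulator):
        c = cond_for_M(0.3, granulator, 310.0)
        space = build_design_space(
            [(c, ws(F1=0.4)), (c, ws(F1=0.6))], granulator
        )
        i, j = np.argwhere(space.counts)[0]
        assert space.fractions["F1"][i, j] == pytest.approx(0.5)

    def test_mass_conservation(self, granulator):
        rng = np.random.default_rng(0)
        estimates = []
        for _ in range(40):
            w = rng.dirichlet(np.ones(3))
            estimates.append(
                (
                    cond_for_M(rng.uniform(0, 1), granulator, rng.uniform(298, 400)),
                    ws(F1=w[0], F2=w[1], F3=w[2]),
                )
            )
        space = build_design_space(estimates, granulator)
        total = sum(space.fractions[n] for n in ("F1", "F2", "F3"))
        occupied = space.counts > 0
        assert np.allclose(total[occupied], 1.0, atol=1e-9)

    def test_blank_marking_below_threshold(self, granulator):
        cond = cond_for_M(0.5, granulator, 350.0)
        space = build_design_space(
            [(cond, ws(F1=1e-6, F2=1.0))], granulator
        )
        assert space.blank_mask("F1").sum() == 1
        assert space.blank_mask("F2").sum() == 0

    def test_empty_input(self, granulator):
        with pytest.raises(EmptyInput):
            build_design_space([], granulator)


class TestFindOptimum:
    def test_flat_field_tie_break(self, granulator):
        estimates = [
            (cond_for_M(m, granulator, T), ws(F1=0.5))
            for T in (310.0, 330.0, 370.0)
            for m in (0.1, 0.5, 0.9)
        ]
        space = build_design_space(estimates, granulator)
        window = find_optimum(space, ["F1"])
        # lowest occupied T bin and lowest occupied M bin win the tie
        assert window.T_lo == space.T_edges[0]
        assert window.M_lo == pytest.approx(0.1, abs=0.05)

    def test_single_cell(self, granulator):
        cond = cond_for_M(0.72, granulator, 380.0)
        space = build_design_space([(cond, ws(F1=1.0))], granulator)
        window = find_optimum(space, ["F1"])
        assert window.contains(380.0, 0.72)

    def test_unknown_target(self, granulator):
        cond = cond_for_M(0.7, granulator, 380.0)
        space = build_design_space([(cond, ws(F1=1.0))], granulator)
        with pytest.raises(UnknownFingerprint):
            find_optimum(space, ["F9"])

    def test_encoded_field_optimum_in_paper_band(self, cocrystal_field):
        """The default synthetic field's cocrystal optimum overlaps the
        340-350 K, 0.4-0.55 M window it was designed to encode."""
        window = cocrystal_field.encoded_optimum(["CO-5", "CO-2"])
        assert window.T_lo < 350 and window.T_hi > 340
        assert window.M_lo < 0.55 and window.M_hi > 0.4


class TestLookup:
    def make_space(self, granulator):
        estimates = []
        for T in (308.2, 328.6, 349.0, 369.4, 389.8):  # cell centers
            for M in np.arange(0.025, 1.0, 0.05):
                estimates.append(
                    (cond_for_M(float(M), granulator, T), ws(F1=float(M)))
                )
        return build_design_space(estimates, granulator)

    def test_exact_center(self, granulator):
        space = self.make_space(granulator)
        result = lookup(space, 349.0, 0.475)
        assert result.fractions["F1"] == pytest.approx(0.475)
        assert not result.had_missing_neighbors

    def test_midpoint_interpolation(self, granulator):
        space = self.make_space(granulator)
        result = lookup(space, 349.0, 0.5)  # midway between 0.475 and 0.525 cells
        assert result.fractions["F1"] == pytest.approx(0.5)

    def test_out_of_bounds(self, granulator):
        space = self.make_space(granulator)
        with pytest.raises(OutOfBounds):
            lookup(space, 500.0, 0.5)
        with pytest.raises(OutOfBounds):
            lookup(space, 350.0, 1.5)

    def test_missing_neighbors_flagged(self, granulator):
        cond = cond_for_M(0.475, granulator, 345.0)
        space = build_design_space([(cond, ws(F1=0.8))], granulator)
        result = lookup(space, 345.0, 0.5)
        assert result.had_missing_neighbors
        assert result.fractions["F1"] == pytest.approx(0.8)


class TestSerialization:
    def test_roundtrip(self, granulator, tmp_path):
        estimates = [
            (cond_for_M(0.3, granulator, 320.0), ws(F1=0.4, F2=0.6)),
            (cond_for_M(0.8, granulator, 380.0), ws(F1=0.9, F2=0.1)),
        ]
        space = build_design_space(estimates, granulator, provenance="unit-test")
        space.save(tmp_path / "space")
        loaded = DesignSpace.load(tmp_path / "space")
        assert loaded.provenance == "unit-test"
        assert np.array_equal(loaded.counts, space.counts)
        for name in space.fractions:
            assert np.allclose(
                loaded.fractions[name], space.fractions[name], equal_nan=True
            )


class TestFractionField:
    def test_fractions_sum_to_one(self, cocrystal_field):
        for T, M in [(298, 0.0), (345, 0.475), (400, 1.0)]:
            total = sum(cocrystal_field.fractions(T, M).values())
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_surface_kinds(self):
        field = FractionField(
            {
                "X": Surface(kind="unimodal", height=1.0, T_center=350, M_center=0.5),
                "Y": Surface(kind="flat", height=0.5),
            }
        )
        peak = field.fractions(350, 0.5)["X"]
        off = field.fractions(298, 0.05)["X"]
        assert peak > off
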