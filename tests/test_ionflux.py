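"""Unit and property tests for the selectivity-filter hopping model."""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from poreblock.ionflux import (
    AmbiguousStationaryError,
    BathConditions,
    KineticScheme,
    MissingActivityError,
    SchemeValidationError,
    State,
    Transition,
    apply_block,
    build_rate_matrix,
    detailed_balance_residual,
    kcv_like_scheme,
    occupancy_vs_voltage,
    site_occupancy,
    stationary_flux,
    steady_state,
    symmetric_kcl_conditions,
)

from conftest import random_irreducible_scheme


# ---------------------------------------------------------------------------
# rate matrix construction
# ---------------------------------------------------------------------------

class TestBuildRateMatrix:
    def test_zero_voltage_rates_equal_k0_times_activity(self, kcv_scheme, symmetric_cond):
        Q = build_rate_matrix(kcv_scheme, symmetric_cond)
        idx = {lab: i for i, lab in enumerate(kcv_scheme.labels)}
        for tr in kcv_scheme.transitions:
            expected = tr.k0
            if tr.coupling:
                expected *= symmetric_cond.activities[tr.coupling]
            assert Q[idx[tr.source], idx[tr.target]] == pytest.approx(expected, rel=1e-12)

    def test_unit_delta_at_thermal_voltage_multiplies_rate_by_e(self):
        scheme = KineticScheme(
            states=(State("a"), State("b")),
            transitions=(Transition("a", "b", 100.0, delta=1.0),
                         Transition("b", "a", 100.0, delta=0.0)),
        )
        cond = BathConditions()
        v_therm = cond.thermal_voltage_mV
        assert v_therm == pytest.approx(25.693, abs=0.01)
        Q = build_rate_matrix(scheme, cond.at(v_therm))
        assert Q[0, 1] == pytest.approx(100.0 * math.e, rel=1e-12)
        assert Q[1, 0] == pytest.approx(100.0, rel=1e-12)

    def test_doubling_cytosolic_activity_scales_only_coupled_transitions(
        self, kcv_scheme, symmetric_cond
    ):
        Q1 = build_rate_matrix(kcv_scheme, symmetric_cond)
        doubled = dict(symmetric_cond.activities)
        doubled[("K", "cytosolic")] *= 2
        Q2 = build_rate_matrix(kcv_scheme, BathConditions(0.0, doubled))
        idx = {lab: i for i, lab in enumerate(kcv_scheme.labels)}
        for tr in kcv_scheme.transitions:
            i, j = idx[tr.source], idx[tr.target]
            factor = 2.0 if tr.coupling == ("K", "cytosolic") else 1.0
            assert Q2[i, j] == pytest.approx(factor * Q1[i, j], rel=1e-12)

    def test_missing_activity_is_a_configuration_error(self, kcv_scheme):
        with pytest.raises(MissingActivityError):
            build_rate_matrix(kcv_scheme, BathConditions(0.0, {}))

    def test_negative_rate_rejected_at_construction(self):
        with pytest.raises(SchemeValidationError):
            Transition("a", "b", -1.0)

    def test_rows_sum_to_zero(self, kcv_scheme, symmetric_cond):
        Q = build_rate_matrix(kcv_scheme, symmetric_cond.at(120.0))
        assert np.abs(Q.sum(axis=1)).max() < 1e-6 * np.abs(Q).max()


# ---------------------------------------------------------------------------
# stationary solve
# ---------------------------------------------------------------------------

class TestSteadyState:
    def test_symmetric_two_state_chain_is_half_half(self):
        Q = np.array([[-3.0, 3.0], [3.0, -3.0]])
        assert steady_state(Q) == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_blocked_scheme_leaves_state_2_empty(self, blocked_scheme, symmetric_cond):
        for v in (-160.0, -60.0, 0.0, 60.0, 160.0):
            P = steady_state(build_rate_matrix(blocked_scheme, symmetric_cond.at(v)))
            assert P[blocked_scheme.index("2")] < 1e-10

    def test_two_absorbing_classes_raise_with_classes_reported(self):
        Q = np.zeros((4, 4))
        Q[0, 1] = Q[1, 0] = 1.0
        Q[2, 3] = Q[3, 2] = 1.0
        np.fill_diagonal(Q, -Q.sum(axis=1))
        with pytest.raises(AmbiguousStationaryError) as err:
            steady_state(Q)
        assert len(err.value.classes) == 2

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_gillespie_occupancy_on_random_schemes(self, seed):
        """Stationary solve agrees with a long exact stochastic simulation."""
        from poreblock.simchan import markov_occupancy

        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(3, 7))
        Q = random_irreducible_scheme(rng, n)
        P = steady_state(Q)
        frac, se = markov_occupancy(Q, n_events=400_000, seed=2000 + seed)
        assert np.all(np.abs(frac - P) <= 3 * np.maximum(se, 1e-12))

    @given(st.integers(0, 10_000))
    def test_normalization_and_positivity(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        Q = random_irreducible_scheme(rng, n)
        P = steady_state(Q)
        assert abs(P.sum() - 1.0) < 1e-10
        assert np.all(P >= 0) and np.all(P <= 1)
        assert np.abs(P @ Q).max() < 1e-9 * np.abs(Q).max()


# ---------------------------------------------------------------------------
# blocking
# ---------------------------------------------------------------------------

class TestApplyBlock:
    def test_exactly_three_rates_zeroed_others_identical(self, kcv_scheme):
        blocked = apply_block(kcv_scheme)
        zeroed = {("1", "2"), ("2", "1"), ("3", "2")}
        for tr_old, tr_new in zip(kcv_scheme.transitions, blocked.transitions):
            if (tr_old.source, tr_old.target) in zeroed:
                assert tr_new.k0 == 0.0
            else:
                assert tr_new == tr_old

    def test_idempotent(self, kcv_scheme):
        once = apply_block(kcv_scheme)
        twice = apply_block(once)
        assert once.transitions == twice.transitions

    def test_input_not_modified(self, kcv_scheme):
        k0_before = [tr.k0 for tr in kcv_scheme.transitions]
        apply_block(kcv_scheme)
        assert [tr.k0 for tr in kcv_scheme.transitions] == k0_before

    def test_partial_preexisting_zero(self, kcv_scheme):
        from dataclasses import replace

        pre = replace(
            kcv_scheme,
            transitions=tuple(
                replace(tr, k0=0.0) if (tr.source, tr.target) == ("1", "2") else tr
                for tr in kcv_scheme.transitions
            ),
        )
        blocked = apply_block(pre)
        assert blocked.transition("2", "1").k0 == 0.0
        assert blocked.transition("3", "2").k0 == 0.0

    def test_missing_transition_raises(self):
        scheme = KineticScheme(
            states=(State("1"), State("2")),
            transitions=(Transition("1", "2", 1.0), Transition("2", "1", 1.0)),
        )
        with pytest.raises(SchemeValidationError):
            apply_block(scheme)


# ---------------------------------------------------------------------------
# site occupancy
# ---------------------------------------------------------------------------

class TestSiteOccupancy:
    @pytest.mark.parametrize(
        "P, expected",
        [((0.2, 0.1, 0.3, 0.2, 0.2), 0.7), ((1.0, 0.0, 0.0, 0.0, 0.0), 0.0)],
    )
    def test_s4_occupancy_sums_states_3_to_5(self, kcv_scheme, P, expected):
        assert site_occupancy(np.array(P), kcv_scheme, "S4") == pytest.approx(expected)

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=5, max_size=5)
    )
    def test_s2_equals_s4_under_reference_annotations(self, kcv_scheme, raw):
        P = np.array(raw) / np.sum(raw)
        assert site_occupancy(P, kcv_scheme, "S2") == pytest.approx(
            site_occupancy(P, kcv_scheme, "S4")
        )

    def test_unknown_site_raises(self, kcv_scheme):
        with pytest.raises(SchemeValidationError):
            site_occupancy(np.full(5, 0.2), kcv_scheme, "S9")


# ---------------------------------------------------------------------------
# occupancy vs voltage
# ---------------------------------------------------------------------------

class TestOccupancyProfile:
    def test_blocked_profile_p2_column_zero(self, blocked_scheme, symmetric_cond):
        prof = occupancy_vs_voltage(
            blocked_scheme, symmetric_cond, np.arange(-160.0, 161.0, 20.0)
        )
        assert prof.blocked
        assert np.abs(prof.state("2")).max() < 1e-10

    def test_rows_normalized(self, kcv_scheme, symmetric_cond):
        prof = occupancy_vs_voltage(kcv_scheme, symmetric_cond, [-100.0, 0.0, 100.0])
        assert np.abs(prof.P.sum(axis=1) - 1).max() < 1e-10

    def test_equilibrium_block_preserves_open_state_proportions(
        self, kcv_scheme, blocked_scheme, symmetric_cond
    ):
        """Cutting edges of a reversible chain at equilibrium cannot shift the
        relative weights of the remaining states; the removed P2 is absorbed
        by state 1, so each |change| is bounded by P2(open)."""
        P_open = steady_state(build_rate_matrix(kcv_scheme, symmetric_cond))
        P_blk = steady_state(build_rate_matrix(blocked_scheme, symmetric_cond))
        p2 = P_open[kcv_scheme.index("2")]
        for lab in ("3", "4", "5"):
            i = kcv_scheme.index(lab)
            assert abs(P_blk[i] - P_open[i]) <= p2 + 1e-12
        # exact invariance of proportions among the surviving cycle states
        keep = [kcv_scheme.index(lab) for lab in ("1", "3", "4", "5")]
        ratio_open = P_open[keep] / P_open[keep].sum()
        ratio_blk = P_blk[keep] / P_blk[keep].sum()
        assert ratio_blk == pytest.approx(ratio_open, abs=1e-9)

    def test_monotone_blocked_s4_occupancy_spans_stated_range(
        self, blocked_scheme, symmetric_cond
    ):
        prof = occupancy_vs_voltage(
            blocked_scheme, symmetric_cond, np.arange(-160.0, 161.0, 20.0)
        )
        p = prof.site("S4")
        assert np.all(np.diff(p) > 0)
        assert 0.25 < p[0] < 0.45 and 0.9 < p[-1] < 1.0

    def test_length_one_grid_matches_single_solve(self, kcv_scheme, symmetric_cond):
        prof = occupancy_vs_voltage(kcv_scheme, symmetric_cond, [37.0])
        P = steady_state(build_rate_matrix(kcv_scheme, symmetric_cond.at(37.0)))
        assert prof.P[0] == pytest.approx(P, abs=1e-12)


# ---------------------------------------------------------------------------
# flux and thermodynamics
# ---------------------------------------------------------------------------

class TestFlux:
    def test_no_driving_force_no_flux(self, kcv_scheme, symmetric_cond):
        res = stationary_flux(kcv_scheme, symmetric_cond)
        # normalize by the rate scale: the cycle carries ~1e8 s^-1 one-way rates
        k_scale = max(tr.k0 for tr in kcv_scheme.transitions)
        assert abs(res.flux_per_s) / k_scale < 1e-10
        assert not res.open_cycle

    def test_positive_voltage_drives_outward_current(self, kcv_scheme, symmetric_cond):
        up = stationary_flux(kcv_scheme, symmetric_cond.at(120.0))
        down = stationary_flux(kcv_scheme, symmetric_cond.at(-120.0))
        assert up.current_pA > 0 > down.current_pA

    def test_blocked_scheme_reports_zero_flux_with_flag(self, blocked_scheme, symmetric_cond):
        res = stationary_flux(blocked_scheme, symmetric_cond.at(80.0))
        assert res.flux_per_s == 0.0 and res.current_pA == 0.0
        assert res.open_cycle

    def test_three_state_cycle_matches_hand_computed_flux(self):
        """Brute-force arithmetic oracle on a small cycle with hand-set rates."""
        scheme = KineticScheme(
            states=(State("a"), State("b"), State("c")),
            transitions=(
                Transition("a", "b", 5.0), Transition("b", "a", 1.0),
                Transition("b", "c", 4.0), Transition("c", "b", 2.0),
                Transition("c", "a", 3.0), Transition("a", "c", 1.0),
            ),
        )
        cond = BathConditions()
        Q = build_rate_matrix(scheme, cond)
        P = steady_state(Q)
        J_hand = P[0] * 5.0 - P[1] * 1.0
        res = stationary_flux(scheme, cond)
        assert res.flux_per_s == pytest.approx(J_hand, rel=1e-9)
        # stationarity: same net flux on every edge
        assert res.flux_per_s == pytest.approx(P[1] * 4.0 - P[2] * 2.0, rel=1e-9)
        assert res.flux_per_s == pytest.approx(P[2] * 3.0 - P[0] * 1.0, rel=1e-9)


class TestDetailedBalance:
    def test_reference_set_is_microreversible_at_equilibrium(
        self, kcv_scheme, symmetric_cond
    ):
        assert abs(detailed_balance_residual(kcv_scheme, symmetric_cond)) < 1e-10

    def test_affinity_at_100mV_equals_reduced_voltage(self, kcv_scheme, symmetric_cond):
        # total translocated charge is 1, so the affinity is F*V/RT = 3.8922
        res = detailed_balance_residual(kcv_scheme, symmetric_cond.at(100.0))
        assert res == pytest.approx(3.8922, abs=2e-4)

    def test_scaling_one_forward_rate_by_e_adds_one(self, kcv_scheme, symmetric_cond):
        from dataclasses import replace

        bumped = replace(
            kcv_scheme,
            transitions=tuple(
                replace(tr, k0=tr.k0 * math.e)
                if (tr.source, tr.target) == ("3", "4")
                else tr
                for tr in kcv_scheme.transitions
            ),
        )
        base = detailed_balance_residual(kcv_scheme, symmetric_cond)
        assert detailed_balance_residual(bumped, symmetric_cond) == pytest.approx(
            base + 1.0, abs=1e-10
        )

    def test_open_cycle_reports_infinite_affinity(self, blocked_scheme, symmetric_cond):
        assert math.isinf(detailed_balance_residual(blocked_scheme, symmetric_cond))
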