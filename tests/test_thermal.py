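"""Gradient planning, tube assignment, and thermocycler programs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from assemblyline.design import PcrSpec
from assemblyline.thermal import (
    GradientGeometry,
    GradientInfeasible,
    LayoutError,
    assign_tubes,
    build_dpn1_program,
    build_goldengate_program,
    build_pcr_program,
    extension_time,
    plan_gradient,
    reaction_tolerance,
)


def _rxn(rid, ta, delta=None, length=1000):
    return PcrSpec(id=rid, template_name=f"t{rid}", fwd_oligo=f"f{rid}",
                   rev_oligo=f"r{rid}", product_length=length, ta_opt=ta, delta=delta)


def _rxns(tas, deltas=None):
    deltas = deltas or [None] * len(tas)
    return [_rxn(i + 1, ta, d) for i, (ta, d) in enumerate(zip(tas, deltas))]


# ---------------------------------------------------------------------------
# independent brute-force oracle (naive re-implementation, kept separate from
# the planner's own search code)
# ---------------------------------------------------------------------------

def _oracle_zone_temps(a, b, n):
    if n == 1 or a == b:
        return [a] * n
    return [a + k * (b - a) / (n - 1) for k in range(n)]


def _oracle_eval(tas, tols, a, b, n_zones):
    temps = _oracle_zone_temps(a, b, n_zones)
    devs = [min(abs(ta - t) for t in temps) for ta in tas]
    excess = max(max(d - tol, 0.0) for d, tol in zip(devs, tols))
    return excess, max(devs)


def _oracle_plan(tas, tols, n_zones, max_span=24.0):
    """Defaults if feasible, otherwise exhaustive grid optimum on the same
    0.1 °C deci-degree grid and tie-break order."""
    lo, hi = min(tas), max(tas)
    excess, maxdev = _oracle_eval(tas, tols, lo, hi, n_zones)
    if excess <= 1e-12:
        return lo, hi, 0.0
    lo_d, hi_d = round(lo * 10), round(hi * 10)
    candidates = []
    for a in range(lo_d - 20, lo_d + 21):
        for b in range(hi_d - 20, hi_d + 21):
            if b < a or (b - a) / 10.0 > max_span:
                continue
            ex, md = _oracle_eval(tas, tols, a / 10.0, b / 10.0, n_zones)
            candidates.append((ex, md, a, b - a))
    ex, md, a, span = min(candidates)
    return a / 10.0, (a + span) / 10.0, ex


class TestTolerance:
    @pytest.mark.parametrize(
        "delta,expected", [(0.2, 0.2), (1.0, 0.4), (None, 0.4), (0.4, 0.4), (0.0, 0.0)]
    )
    def test_min_of_delta_and_default(self, delta, expected):
        assert reaction_tolerance(delta) == pytest.approx(expected)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            reaction_tolerance(-0.1)


class TestPlanGradient:
    def test_flat_plan_when_all_equal(self):
        plan = plan_gradient(_rxns([60.0] * 5))
        assert plan.is_flat
        assert all(a.deviation == 0.0 for a in plan.assignments.values())
        assert plan.zone_temps == [60.0] * 12

    def test_mixed_optima_within_tolerance(self):
        plan = plan_gradient(_rxns([58.0, 58.4, 59.1, 60.2, 64.5]))
        for a in plan.assignments.values():
            assert a.deviation <= a.tolerance + 1e-12
        # the hottest reaction occupies the hottest occupied zone
        hottest = max(plan.assignments.values(), key=lambda a: a.zone)
        assert plan.assignments[5].zone == hottest.zone

    def test_zone_temps_equally_spaced_nondecreasing(self):
        plan = plan_gradient(_rxns([58.0, 61.3, 66.0]))
        diffs = np.diff(plan.zone_temps)
        assert np.all(diffs >= -1e-12)
        assert np.allclose(diffs, diffs[0], atol=1e-9)

    def test_span_limit(self):
        plan = plan_gradient(_rxns([55.0, 72.5]))
        zones = {a.zone for a in plan.assignments.values()}
        assert len(zones) == 2
        with pytest.raises(GradientInfeasible, match="split run"):
            plan_gradient(_rxns([55.0, 72.5]),
                          GradientGeometry(max_span=15.0))

    def test_rigid_delta_forces_endpoint_adjustment(self):
        # zone spacing with defaults is (66-58)/11 = 0.727; a 0.05 °C delta at
        # an off-grid optimum is only satisfiable after endpoint re-optimization
        rxns = _rxns([58.0, 62.33, 66.0], deltas=[None, 0.05, None])
        plan = plan_gradient(rxns)
        a = plan.assignments[2]
        assert a.deviation <= a.tolerance + 1e-12

    def test_tolerance_infeasible(self):
        # two rigid reactions 0.3 °C apart can never both sit on a zone of a
        # 1-zone block
        rxns = _rxns([60.0, 60.3], deltas=[0.0, 0.0])
        with pytest.raises(GradientInfeasible, match="tolerance"):
            plan_gradient(rxns, GradientGeometry(n_zones=1, rows_per_zone=8))

    def test_relabeling_ids_preserves_zone_temps(self):
        tas = [58.3, 59.9, 61.2, 63.0]
        p1 = plan_gradient(_rxns(tas))
        relabeled = [_rxn(rid, ta) for rid, ta in zip([40, 10, 30, 20], tas)]
        p2 = plan_gradient(relabeled)
        assert p1.zone_temps == p2.zone_temps
        assert (p1.t_low, p1.t_high) == (p2.t_low, p2.t_high)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        tas=st.lists(
            st.integers(550, 700).map(lambda d: d / 10.0), min_size=1, max_size=8
        ),
        rigid=st.lists(st.booleans(), min_size=8, max_size=8),
    )
    def test_matches_bruteforce_oracle(self, tas, rigid):
        """Planner endpoints and worst tolerance-excess equal an exhaustive
        search over the same endpoint grid."""
        deltas = [0.2 if r else None for r in rigid[: len(tas)]]
        rxns = _rxns(tas, deltas)
        tols = [reaction_tolerance(d) for d in deltas]
        try:
            plan = plan_gradient(rxns)
        except GradientInfeasible:
            a, b, ex = _oracle_plan(tas, tols, 12)
            assert ex > 1e-12
            return
        a, b, ex = _oracle_plan(tas, tols, 12)
        assert (plan.t_low, plan.t_high) == (pytest.approx(a), pytest.approx(b))
        plan_excess = max(
            max(asg.deviation - asg.tolerance, 0.0)
            for asg in plan.assignments.values()
        )
        assert plan_excess == pytest.approx(ex, abs=1e-9)

    def test_feasibility_guarantee_small_spread(self):
        """Any 12-zone design whose optima span <= 8 °C is served within
        0.4 °C by the default endpoints (half-spacing 8/22 < 0.4)."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            tas = np.round(rng.uniform(58.0, 66.0, rng.integers(2, 13)), 1)
            plan = plan_gradient(_rxns(list(tas)))
            assert plan.max_deviation < 0.4


class TestAssignTubes:
    def test_two_reactions_same_zone_fill_rows(self):
        plan = plan_gradient(_rxns([60.0, 60.0, 62.0]))
        zone = plan.assignments[1].zone
        assert plan.assignments[1].position == f"A{zone + 1}"
        assert plan.assignments[2].position == f"B{zone + 1}"

    def test_single_reaction_single_zone_is_a1(self):
        plan = plan_gradient(_rxns([60.0]))
        assert plan.assignments[1].position == "A1"

    def test_positions_unique(self):
        plan = plan_gradient(_rxns([58.0 + 0.3 * i for i in range(20)]))
        positions = [a.position for a in plan.assignments.values()]
        assert len(positions) == len(set(positions))

    def test_zone_overflow(self):
        # nine identical optima all land in one zone of an 8-row block
        with pytest.raises(LayoutError):
            plan_gradient(_rxns([60.0] * 9))


class TestExtensionTime:
    @pytest.mark.parametrize(
        "lengths,expected",
        [([1000], 30), ([800, 2400, 3200], 100), ([150], 10), ([1001], 35)],
    )
    def test_rounding_and_floor(self, lengths, expected):
        assert extension_time(lengths) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            extension_time([])


class TestPrograms:
    def test_pcr_program_shape(self):
        plan = plan_gradient(_rxns([58.0, 64.0]))
        prog = build_pcr_program(plan, ext_s=100.0)
        assert prog.steps[0].temperature_c == 98.0 and prog.steps[0].duration_s == 30.0
        assert prog.steps[-1].temperature_c == 72.0 and prog.steps[-1].duration_s == 300.0
        assert prog.cycled_block == (1, 3, 34)
        assert prog.steps[2].gradient == (plan.t_low, plan.t_high)

    def test_flat_plan_renders_single_temperature(self):
        plan = plan_gradient(_rxns([60.0, 60.0]))
        prog = build_pcr_program(plan, ext_s=30.0)
        assert prog.steps[2].gradient is None
        assert prog.steps[2].temperature_c == 60.0

    def test_pcr_total_duration(self):
        plan = plan_gradient(_rxns([60.0]))
        prog = build_pcr_program(plan, ext_s=60.0, n_cycles=34)
        assert prog.total_duration_s() == pytest.approx(30 + 34 * (10 + 30 + 60) + 300)

    def test_dpn1_program(self):
        prog = build_dpn1_program()
        assert [(s.temperature_c, s.duration_s) for s in prog.steps] == [
            (37.0, 1800.0), (65.0, 1200.0)
        ]
        assert prog.cycled_block is None

    def test_goldengate_program_defaults(self):
        prog = build_goldengate_program()
        assert prog.cycled_block == (0, 1, 30)
        assert prog.steps[-1].temperature_c == 80.0
        one = build_goldengate_program(n_cycles=1)
        assert one.cycled_block == (0, 1, 1)
        assert one.total_duration_s() == pytest.approx(300 + 300 + 300 + 600)
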