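"""Annealing-gradient planning and thermocycler program construction.

A gradient thermocycler block holds a linear temperature gradient across its
columns during the annealing step, so a single run can serve reactions with
different annealing optima.  The planner chooses gradient endpoints and a
column (zone) for every reaction so that each reaction anneals within its
tolerance of its optimum — 0.4 °C by default, tighter when the design file
carries a more rigid per-reaction delta.  When the default endpoints (the min
and max optima) leave some reaction outside its tolerance, the endpoints are
re-optimized by an exhaustive 0.1 °C grid search around the defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .design import PcrSpec

__all__ = [
    "GradientGeometry",
    "GradientPlan",
    "ThermoProgram",
    "ProgramStep",
    "GradientInfeasible",
    "LayoutError",
    "DEFAULT_TOLERANCE_C",
    "reaction_tolerance",
    "plan_gradient",
    "assign_tubes",
    "extension_time",
    "build_pcr_program",
    "build_dpn1_program",
    "build_goldengate_program",
]

#: accommodation bound for annealing temperatures (°C)
DEFAULT_TOLERANCE_C = 0.4

_ROWS = "ABCDEFGH"


class GradientInfeasible(Exception):
    """No single gradient run can satisfy the reactions' tolerances."""


class LayoutError(Exception):
    """Tube or labware capacity exceeded."""


@dataclass(frozen=True)
class GradientGeometry:
    """Thermocycler block geometry: the gradient runs across the columns,
    cold on the left, hot on the right; tubes fill rows top-down."""

    n_zones: int = 12
    rows_per_zone: int = 8
    orientation: str = "columns_cold_to_hot"
    max_span: float = 24.0

    def __post_init__(self) -> None:
        if self.n_zones < 1:
            raise ValueError("n_zones must be >= 1")
        if self.max_span <= 0:
            raise ValueError("max_span must be positive")


@dataclass(frozen=True)
class Assignment:
    """Where one reaction sits in the gradient and how well it is served."""

    zone: int
    position: str | None  # e.g. "A6"; set by assign_tubes
    deviation: float      # |ta_opt - zone temperature|, °C
    tolerance: float      # this reaction's accommodation bound, °C


@dataclass
class GradientPlan:
    """Endpoints, per-zone temperatures, and reaction placements."""

    t_low: float
    t_high: float
    zone_temps: list[float]
    assignments: dict[int, Assignment] = field(default_factory=dict)

    @property
    def is_flat(self) -> bool:
        return math.isclose(self.t_low, self.t_high, abs_tol=1e-12)

    @property
    def max_deviation(self) -> float:
        return max((a.deviation for a in self.assignments.values()), default=0.0)


@dataclass(frozen=True)
class ProgramStep:
    """One thermocycler step: a fixed temperature or a gradient span."""

    duration_s: float
    temperature_c: float | None = None
    gradient: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("step duration must be positive")
        if (self.temperature_c is None) == (self.gradient is None):
            raise ValueError("exactly one of temperature_c/gradient must be set")


@dataclass(frozen=True)
class ThermoProgram:
    """An ordered step list with at most one cycled block.

    ``cycled_block`` is (first step index, last step index, n_cycles),
    inclusive on both ends.
    """

    label: str
    steps: tuple[ProgramStep, ...]
    cycled_block: tuple[int, int, int] | None = None

    def total_duration_s(self) -> float:
        total = 0.0
        for i, step in enumerate(self.steps):
            if self.cycled_block and self.cycled_block[0] <= i <= self.cycled_block[1]:
                total += step.duration_s * self.cycled_block[2]
            else:
                total += step.duration_s
        return total

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "steps": [
                {
                    "duration_s": s.duration_s,
                    "temperature_c": s.temperature_c,
                    "gradient": list(s.gradient) if s.gradient else None,
                }
                for s in self.steps
            ],
            "cycled_block": list(self.cycled_block) if self.cycled_block else None,
        }


# ---------------------------------------------------------------------------
# gradient planning
# ---------------------------------------------------------------------------

def reaction_tolerance(delta: float | None, default_tol: float = DEFAULT_TOLERANCE_C) -> float:
    """Accommodation bound for one reaction: min(delta, default).

    A design-file delta below the default marks a reaction with a rigid
    annealing requirement; a delta at or above it never loosens the bound.
    Missing delta means the default applies.
    """
    if delta is None:
        return default_tol
    if delta < 0:
        raise ValueError(f"delta must be >= 0, got {delta}")
    return min(delta, default_tol)


def _zone_temps(t_low: float, t_high: float, n_zones: int) -> list[float]:
    if n_zones == 1 or math.isclose(t_low, t_high, abs_tol=1e-12):
        return [t_low] * n_zones
    return [t_low + k * (t_high - t_low) / (n_zones - 1) for k in range(n_zones)]


def _assign(tas: Sequence[float], temps: Sequence[float]) -> list[tuple[int, float]]:
    """Best zone per reaction: minimal |ta - temp|, ties to the lower zone."""
    out = []
    for ta in tas:
        best_zone, best_dev = 0, abs(ta - temps[0])
        for z in range(1, len(temps)):
            dev = abs(ta - temps[z])
            if dev < best_dev - 1e-12:
                best_zone, best_dev = z, dev
        out.append((best_zone, best_dev))
    return out


def _score(
    tas: Sequence[float], tols: Sequence[float], t_low: float, t_high: float, n_zones: int
) -> tuple[float, float]:
    """(max clamped excess over tolerance, max deviation) for given endpoints."""
    temps = _zone_temps(t_low, t_high, n_zones)
    devs = [dev for _, dev in _assign(tas, temps)]
    excess = max(max(d - t, 0.0) for d, t in zip(devs, tols))
    return excess, max(devs)


def plan_gradient(
    reactions: Sequence[PcrSpec],
    geometry: GradientGeometry = GradientGeometry(),
    default_tol: float = DEFAULT_TOLERANCE_C,
) -> GradientPlan:
    """Choose gradient endpoints and a zone for every reaction.

    Endpoints default to the min and max annealing optima.  If any reaction
    then deviates beyond its tolerance, both endpoints are re-optimized by
    exhaustive grid search (±2.0 °C around the defaults in 0.1 °C steps),
    minimizing first the worst tolerance excess, then the worst deviation;
    ties break to the lowest ``t_low``, then the smallest span.

    Raises
    ------
    GradientInfeasible
        With reason ``"split run"`` when the optima span more than the block
        can hold, or ``"tolerance"`` when no endpoint choice within the search
        window accommodates every reaction.
    """
    if not 1 <= len(reactions) <= geometry.n_zones * geometry.rows_per_zone:
        raise ValueError(
            f"need 1..{geometry.n_zones * geometry.rows_per_zone} reactions, "
            f"got {len(reactions)}"
        )
    tas = [r.ta_opt for r in reactions]
    tols = [reaction_tolerance(r.delta, default_tol) for r in reactions]
    lo, hi = min(tas), max(tas)
    if hi - lo > geometry.max_span + 1e-12:
        raise GradientInfeasible(
            f"split run: optima span {hi - lo:.1f} °C exceeds the "
            f"{geometry.max_span:.1f} °C block maximum"
        )

    best = (lo, hi)
    excess, _ = _score(tas, tols, lo, hi, geometry.n_zones)
    if excess > 1e-12:
        # grid search endpoints in 0.1 °C steps on an integer deci-degree grid
        lo_d, hi_d = round(lo * 10), round(hi * 10)
        best_key: tuple | None = None
        for a in range(lo_d - 20, lo_d + 21):
            for b in range(max(a, hi_d - 20), hi_d + 21):
                if (b - a) / 10.0 > geometry.max_span + 1e-12:
                    continue
                ex, maxdev = _score(tas, tols, a / 10.0, b / 10.0, geometry.n_zones)
                key = (ex, maxdev, a, b - a)
                if best_key is None or key < best_key:
                    best_key, best = key, (a / 10.0, b / 10.0)
        assert best_key is not None
        if best_key[0] > 1e-12:
            raise GradientInfeasible(
                "tolerance: no endpoint choice accommodates every reaction"
            )

    t_low, t_high = best
    temps = _zone_temps(t_low, t_high, geometry.n_zones)
    assignments = {
        r.id: Assignment(zone=z, position=None, deviation=dev, tolerance=tol)
        for r, (z, dev), tol in zip(reactions, _assign(tas, temps), tols)
    }
    plan = GradientPlan(t_low=t_low, t_high=t_high, zone_temps=temps, assignments=assignments)
    return assign_tubes(plan, geometry)


def assign_tubes(plan: GradientPlan, geometry: GradientGeometry = GradientGeometry()) -> GradientPlan:
    """Assign a tube position to every reaction.

    Within each zone (block column), tubes fill rows A→H in ascending reaction
    id; the position string is row letter + 1-based column number ("A6").
    """
    by_zone: dict[int, list[int]] = {}
    for rid in sorted(plan.assignments):
        by_zone.setdefault(plan.assignments[rid].zone, []).append(rid)
    new_assignments = dict(plan.assignments)
    for zone, rids in by_zone.items():
        if len(rids) > geometry.rows_per_zone:
            raise LayoutError(
                f"zone {zone}: {len(rids)} reactions exceed {geometry.rows_per_zone} rows"
            )
        for row, rid in enumerate(rids):
            new_assignments[rid] = replace(
                plan.assignments[rid], position=f"{_ROWS[row]}{zone + 1}"
            )
    return GradientPlan(
        t_low=plan.t_low,
        t_high=plan.t_high,
        zone_temps=list(plan.zone_temps),
        assignments=new_assignments,
    )


# ---------------------------------------------------------------------------
# extension time and programs
# ---------------------------------------------------------------------------

def extension_time(
    product_lengths: Iterable[int],
    rate_s_per_kb: float = 30.0,
    rounding: float = 5.0,
    floor: float = 10.0,
) -> float:
    """One extension time (s) covering every product in the run.

    Sized for the longest product at *rate_s_per_kb*, rounded up to the
    nearest *rounding* seconds, never below *floor*.
    """
    lengths = list(product_lengths)
    if not lengths:
        raise ValueError("need at least one product length")
    if any(l <= 0 for l in lengths):
        raise ValueError("product lengths must be positive")
    raw = max(lengths) / 1000.0 * rate_s_per_kb
    return max(floor, math.ceil(raw / rounding) * rounding)


def _anneal_step(plan: GradientPlan, duration_s: float = 30.0) -> ProgramStep:
    if plan.is_flat:
        return ProgramStep(duration_s=duration_s, temperature_c=plan.t_low)
    return ProgramStep(duration_s=duration_s, gradient=(plan.t_low, plan.t_high))


def build_pcr_program(
    plan: GradientPlan,
    ext_s: float,
    n_cycles: int = 34,
    denature_c: float = 98.0,
    extend_c: float = 72.0,
) -> ThermoProgram:
    """Gradient amplification: initial denaturation, cycled
    denature/anneal/extend, and a 5-minute final extension."""
    steps = (
        ProgramStep(duration_s=30.0, temperature_c=denature_c),
        ProgramStep(duration_s=10.0, temperature_c=denature_c),
        _anneal_step(plan),
        ProgramStep(duration_s=ext_s, temperature_c=extend_c),
        ProgramStep(duration_s=300.0, temperature_c=extend_c),
    )
    return ThermoProgram(label="amplification", steps=steps, cycled_block=(1, 3, n_cycles))


def build_dpn1_program() -> ThermoProgram:
    """Template digestion: 30 min at 37 °C, then 20 min inactivation at 65 °C."""
    return ThermoProgram(
        label="digestion",
        steps=(
            ProgramStep(duration_s=1800.0, temperature_c=37.0),
            ProgramStep(duration_s=1200.0, temperature_c=65.0),
        ),
    )


def build_goldengate_program(
    n_cycles: int = 30,
    digest_c: float = 37.0,
    ligate_c: float = 16.0,
    step_s: float = 300.0,
    final_digest_c: float = 50.0,
    final_digest_s: float = 300.0,
    inactivate_c: float = 80.0,
    inactivate_s: float = 600.0,
) -> ThermoProgram:
    """Cycled restriction–ligation, a final digestion, and heat inactivation."""
    steps = (
        ProgramStep(duration_s=step_s, temperature_c=digest_c),
        ProgramStep(duration_s=step_s, temperature_c=ligate_c),
        ProgramStep(duration_s=final_digest_s, temperature_c=final_digest_c),
        ProgramStep(duration_s=inactivate_s, temperature_c=inactivate_c),
    )
    return ThermoProgram(label="assembly", steps=steps, cycled_block=(0, 1, n_cycles))
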