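"""Virtual-deck execution of a run bundle with exact amount bookkeeping.

Every transfer moves liquid volume and a proportional share of each tracked
species (primers in pmol, template and fragment DNA in ng); an amplification
cycle seeds fragment species at the configured assumed yield, and a digestion
cycle destroys template species in its wells.  The simulator is the package's
principal verification surface: conservation, capacity, final compositions
and equimolarity are all asserted against the executed state, never against
the plan that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .deck import DeckLayout, Stage, TrackingRow
from .stoichiometry import Location, Stock, TransferStep
from .workflows import Message, Pause, RunBundle, SpeciesInfo, Thermocycle

__all__ = [
    "SimError",
    "Well",
    "SimState",
    "ConservationReport",
    "execute",
    "check_conservation",
    "well_composition",
    "fragment_pmol",
    "tracking_rows",
]

#: average molar mass of one double-stranded base pair, g/mol
BP_G_PER_MOL = 650.0


class SimError(Exception):
    """The bundle references a source the deck does not hold."""


def fragment_pmol(mass_ng: float, length_bp: int) -> float:
    """Convert a double-stranded DNA mass to picomoles via its length."""
    return mass_ng * 1e3 / (length_bp * BP_G_PER_MOL)


@dataclass
class Well:
    volume_ul: float = 0.0
    amounts: dict[str, float] = field(default_factory=dict)  # species -> native unit


@dataclass
class SimState:
    """Deck contents after (partial) execution of a run bundle."""

    wells: dict[Location, Well] = field(default_factory=dict)
    species: dict[str, SpeciesInfo] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)
    violations: list[tuple[str, str]] = field(default_factory=list)
    #: species destroyed by digestion / created by amplification (exempt from
    #: conservation against the initial state)
    digested: set[str] = field(default_factory=set)
    created: set[str] = field(default_factory=set)

    def violate(self, code: str, detail: str) -> None:
        self.violations.append((code, detail))


@dataclass
class ConservationReport:
    mismatches: list[tuple[str, float, float, list[Location]]] = field(default_factory=list)
    volume_initial_ul: float = 0.0
    volume_final_ul: float = 0.0

    @property
    def ok(self) -> bool:
        return not self.mismatches and self.volume_ok

    @property
    def volume_ok(self) -> bool:
        scale = max(abs(self.volume_initial_ul), 1.0)
        return abs(self.volume_final_ul - self.volume_initial_ul) <= 1e-9 * scale


def _initial_state(
    initial_stocks: Sequence[Stock], species: Mapping[str, SpeciesInfo]
) -> SimState:
    state = SimState(species=dict(species))
    for stock in initial_stocks:
        if stock.location is None:
            raise SimError(f"stock {stock.name!r} has no deck location")
        well = state.wells.setdefault(stock.location, Well())
        well.volume_ul += stock.volume_ul
        # a primer/template stock tube carries its species at the stock conc;
        # the species name is the stock name without the "_stock" suffix
        sp = stock.name.removesuffix("_stock")
        if sp in species and stock.conc_value > 0:
            well.amounts[sp] = well.amounts.get(sp, 0.0) + stock.conc_value * stock.volume_ul
    return state


def _apply_transfer(state: SimState, step: TransferStep, capacity_ul: float) -> None:
    if step.source not in state.wells:
        raise SimError(f"transfer {step.ordinal}: source {step.source} not placed")
    src = state.wells[step.source]
    vol = step.volume_ul
    if vol > src.volume_ul + 1e-9:
        state.violate(
            "overdraw",
            f"step {step.ordinal}: {vol:.3f} µL from {step.source} holding "
            f"{src.volume_ul:.3f} µL",
        )
        vol = src.volume_ul
    frac = vol / src.volume_ul if src.volume_ul > 0 else 0.0
    dest = state.wells.setdefault(step.dest, Well())
    for sp, amount in list(src.amounts.items()):
        moved = amount * frac
        src.amounts[sp] = amount - moved
        dest.amounts[sp] = dest.amounts.get(sp, 0.0) + moved
    src.volume_ul -= vol
    dest.volume_ul += vol
    if dest.volume_ul > capacity_ul + 1e-9:
        state.violate(
            "capacity",
            f"step {step.ordinal}: well {step.dest} at {dest.volume_ul:.1f} µL "
            f"exceeds {capacity_ul:.1f} µL",
        )
    state.log.append(
        f"transfer {step.ordinal}: {vol:g} µL {step.source} -> {step.dest}"
    )


def _apply_thermocycle(state: SimState, step: Thermocycle) -> None:
    if step.kind == "digestion":
        for loc in step.wells:
            well = state.wells.get(loc)
            if well is None:
                continue
            for sp in list(well.amounts):
                info = state.species.get(sp)
                if info is not None and info.kind == "template":
                    well.amounts[sp] = 0.0
                    state.digested.add(sp)
    elif step.kind == "amplification":
        for loc, sp, length, yield_ng_ul in step.products:
            well = state.wells.setdefault(loc, Well())
            well.amounts[sp] = well.amounts.get(sp, 0.0) + yield_ng_ul * well.volume_ul
            state.created.add(sp)
    state.log.append(f"thermocycle {step.ordinal}: {step.program.label} ({step.kind})")


def execute(
    bundle: RunBundle,
    layout: DeckLayout | None = None,
    initial_stocks: Sequence[Stock] | None = None,
    stop_after: int | None = None,
) -> SimState:
    """Run a bundle's steps in ordinal order on a fresh virtual deck.

    *layout* and *initial_stocks* default to the bundle's own; *stop_after*
    truncates execution after the step with that ordinal (for stage
    snapshots).  Overdraws and capacity overruns are recorded as violations,
    never silently dropped; pauses and messages are logged no-ops.
    """
    initial_stocks = bundle.initial_stocks if initial_stocks is None else initial_stocks
    capacity = float(bundle.config_snapshot.get("well_capacity_ul", 200.0))
    state = _initial_state(initial_stocks, bundle.species)
    last = -1
    for step in bundle.steps:
        if step.ordinal <= last:
            raise SimError(f"step ordinals not strictly increasing at {step.ordinal}")
        last = step.ordinal
        if stop_after is not None and step.ordinal > stop_after:
            break
        if isinstance(step, TransferStep):
            _apply_transfer(state, step, capacity)
        elif isinstance(step, Thermocycle):
            _apply_thermocycle(state, step)
        elif isinstance(step, (Pause, Message)):
            text = step.message if isinstance(step, Pause) else step.text
            state.log.append(f"{type(step).__name__.lower()} {step.ordinal}: {text}")
        else:  # pragma: no cover - exhaustive over the Step union
            raise SimError(f"unknown step type {type(step).__name__}")
    return state


def check_conservation(
    state: SimState, initial_stocks: Sequence[Stock], rel_tol: float = 1e-9
) -> ConservationReport:
    """Compare total species amounts and liquid volume against the initial
    stocks.  Species destroyed by a modeled digestion or created by a modeled
    amplification are exempt."""
    report = ConservationReport()
    initial: dict[str, float] = {}
    for stock in initial_stocks:
        sp = stock.name.removesuffix("_stock")
        if sp in state.species and stock.conc_value > 0:
            initial[sp] = initial.get(sp, 0.0) + stock.conc_value * stock.volume_ul
        report.volume_initial_ul += stock.volume_ul
    finals: dict[str, float] = {}
    where: dict[str, list[Location]] = {}
    for loc, well in state.wells.items():
        report.volume_final_ul += well.volume_ul
        for sp, amount in well.amounts.items():
            finals[sp] = finals.get(sp, 0.0) + amount
            if amount > 0:
                where.setdefault(sp, []).append(loc)
    for sp in sorted(set(initial) | set(finals)):
        if sp in state.digested or sp in state.created:
            continue
        a, b = initial.get(sp, 0.0), finals.get(sp, 0.0)
        scale = max(abs(a), abs(b), 1e-30)
        if abs(a - b) > rel_tol * scale:
            report.mismatches.append((sp, a, b, sorted(where.get(sp, []))))
    return report


def well_composition(
    state: SimState, well: Location
) -> tuple[float, dict[str, dict[str, float]]]:
    """Volume and per-species amount/concentration of one well.

    Concentrations are in each species' native unit per µL — µM for primers
    (pmol/µL), ng/µL for template and fragment DNA; fragments also report
    picomoles via their length.
    """
    if well not in state.wells:
        raise KeyError(f"unknown well {well}")
    w = state.wells[well]
    comp: dict[str, dict[str, float]] = {}
    for sp, amount in w.amounts.items():
        info = state.species.get(sp)
        entry = {
            "amount": amount,
            "unit_conc": amount / w.volume_ul if w.volume_ul > 0 else 0.0,
        }
        if info is not None and info.kind == "fragment" and info.length_bp:
            entry["pmol"] = fragment_pmol(amount, info.length_bp)
        comp[sp] = entry
    return w.volume_ul, comp


# ---------------------------------------------------------------------------
# tracking tables from simulated stage snapshots
# ---------------------------------------------------------------------------

_ITEM_KINDS = {"pcr": "reaction", "pool": "pool", "predil": "predilution"}


def _row_for(item: str, loc: Location, well: Well, state: SimState, stage: Stage) -> TrackingRow:
    info = state.species.get(item)
    if info is not None:
        amount = well.amounts.get(item, 0.0)
        conc = amount / well.volume_ul if well.volume_ul > 0 else 0.0
        unit = "uM" if info.unit == "pmol" else "ng/uL"
        kind = info.kind
    else:
        stock_species = item.removesuffix("_stock")
        sinfo = state.species.get(stock_species)
        if item.endswith("_stock") and sinfo is not None:
            amount = well.amounts.get(stock_species, 0.0)
            conc = amount / well.volume_ul if well.volume_ul > 0 else 0.0
            unit = "uM" if sinfo.unit == "pmol" else "ng/uL"
            kind = sinfo.kind
        else:
            conc, unit = 0.0, "none"
            kind = _ITEM_KINDS.get(item.split("_")[0], "reagent")
    return TrackingRow(
        item=item, kind=kind, slot=loc[0], well=loc[1],
        conc_value=round(conc, 9), conc_unit=unit,
        volume_ul=max(well.volume_ul, 0.0), stage=stage,
    )


def tracking_rows(bundle: RunBundle) -> list[TrackingRow]:
    """Location/concentration/volume rows for every placed item at every
    pipeline stage it survives, computed by replaying the bundle on the
    virtual deck up to each stage boundary."""
    rows: list[TrackingRow] = []
    placements = bundle.layout.placements
    # initial stage: declared stocks at their required volumes
    for stock in bundle.initial_stocks:
        assert stock.location is not None
        rows.append(
            TrackingRow(
                item=stock.name, kind=stock.kind.value, slot=stock.location[0],
                well=stock.location[1], conc_value=stock.conc_value,
                conc_unit=stock.conc_unit, volume_ul=stock.volume_ul,
                stage=Stage.INITIAL,
            )
        )
    for stage, boundary in sorted(bundle.stage_boundaries.items(), key=lambda kv: kv[1]):
        state = execute(bundle, stop_after=boundary)
        for item, loc in sorted(placements.items(), key=lambda kv: (kv[1][0], kv[1][1])):
            well = state.wells.get(loc)
            if well is None or well.volume_ul <= 1e-12:
                continue
            rows.append(_row_for(item, loc, well, state, stage))
    return rows
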