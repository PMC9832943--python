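"""Deck and labware model, deterministic placement, and rendered artifacts.

The working surface has numbered slots (1–11) each holding one labware item;
the thermocycler occupies its fixed slot.  Placement is fully deterministic —
stocks fill tube racks and the working plate column-major in bundle order,
reactions sit at their gradient tube positions — so rendered setup files and
tracking tables are byte-identical across runs on the same input.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

from .config import RunConfig
from .design import DesignBundle, Strategy
from .stoichiometry import Location, Stock
from .thermal import GradientPlan, LayoutError, ThermoProgram

__all__ = [
    "DeckLayout",
    "Labware",
    "Stage",
    "TrackingRow",
    "THERMOCYCLER_SLOT",
    "layout_deck",
    "render_reagent_setup",
    "render_reactions_setup",
    "write_tracking_tables",
]

THERMOCYCLER_SLOT = 7
MAX_SLOT = 11

_LABWARE_WELLS = {
    "tube_rack_24": (4, 6),     # rows A-D x 6 columns
    "plate_96": (8, 12),
    "thermocycler": (8, 12),
    "tip_rack": (8, 12),
}


def _wells_column_major(labware_type: str) -> Iterator[str]:
    rows, cols = _LABWARE_WELLS[labware_type]
    for c in range(1, cols + 1):
        for r in range(rows):
            yield f"{'ABCDEFGH'[r]}{c}"


class Stage(str, enum.Enum):
    INITIAL = "initial"
    POST_DILUTION = "post_dilution"
    POST_PCR = "post_pcr"
    POST_DIGEST = "post_digest"
    POST_ASSEMBLY = "post_assembly"


@dataclass(frozen=True)
class Labware:
    type: str
    label: str


@dataclass
class TrackingRow:
    """One item's location, concentration and volume at one pipeline stage."""

    item: str
    kind: str
    slot: int
    well: str
    conc_value: float
    conc_unit: str
    volume_ul: float
    stage: Stage

    def __post_init__(self) -> None:
        if self.volume_ul < 0:
            raise ValueError(f"{self.item}: negative volume")


@dataclass
class DeckLayout:
    """Slot → labware assignments plus item placements."""

    slots: dict[int, Labware] = field(default_factory=dict)
    placements: dict[str, Location] = field(default_factory=dict)

    def assign_slot(self, labware: Labware) -> int:
        """Claim the lowest free non-thermocycler slot."""
        for slot in range(1, MAX_SLOT + 1):
            if slot != THERMOCYCLER_SLOT and slot not in self.slots:
                self.slots[slot] = labware
                return slot
        raise LayoutError(f"no free slot for {labware.label}")

    def place(self, item: str, slot: int, well: str) -> None:
        loc = (slot, well)
        if any(existing == loc for existing in self.placements.values()):
            raise LayoutError(f"{item}: well {loc} already occupied")
        if item in self.placements:
            raise LayoutError(f"{item}: already placed")
        self.placements[item] = loc

    def occupied_wells(self, slot: int) -> set[str]:
        return {w for s, w in self.placements.values() if s == slot}


def _fill_racks(layout: DeckLayout, items: Sequence[str], label_prefix: str) -> None:
    """Place items into as many 24-tube racks as needed, column-major."""
    wells = list(_wells_column_major("tube_rack_24"))
    for rack_no, start in enumerate(range(0, len(items), len(wells)), start=1):
        chunk = items[start : start + len(wells)]
        slot = layout.assign_slot(Labware("tube_rack_24", f"{label_prefix}_{rack_no}"))
        for item, well in zip(chunk, wells):
            layout.place(item, slot, well)


def layout_deck(
    bundle: DesignBundle,
    config: RunConfig,
    plan: GradientPlan | None = None,
    reagent_names: Sequence[str] = (),
) -> DeckLayout:
    """Deterministic placement of every stock and reaction.

    Reagents fill one tube rack; primer then template stock tubes fill further
    racks (wells A1→D6 column-major, new racks allocated as needed); working
    dilutions fill the 96-well plate in the same order; reactions sit at their
    gradient tube positions on the thermocycler; pooled-assembly wells take
    the first free thermocycler wells column-major.  Only the labware actually
    needed is allocated.
    """
    layout = DeckLayout()
    layout.slots[THERMOCYCLER_SLOT] = Labware("thermocycler", "thermocycler")

    if reagent_names:
        slot = layout.assign_slot(Labware("tube_rack_24", "reagents"))
        wells = _wells_column_major("tube_rack_24")
        for name in reagent_names:
            try:
                layout.place(name, slot, next(wells))
            except StopIteration:
                raise LayoutError("more reagents than one rack holds") from None

    stock_items = [f"{o.name}_stock" for o in bundle.oligos] + [
        f"{t}_stock" for t in bundle.template_names
    ]
    _fill_racks(layout, stock_items, "stocks")

    working_items = [o.name for o in bundle.oligos] + list(bundle.template_names)
    if len(working_items) > 96:
        raise LayoutError("more working dilutions than one 96-well plate holds")
    slot = layout.assign_slot(Labware("plate_96", "working_plate"))
    for item, well in zip(working_items, _wells_column_major("plate_96")):
        layout.place(item, slot, well)

    if plan is not None:
        for rid in sorted(plan.assignments):
            pos = plan.assignments[rid].position
            if pos is None:
                raise LayoutError(f"reaction {rid}: no tube position assigned")
            layout.place(f"pcr_{rid}", THERMOCYCLER_SLOT, pos)

    if bundle.strategy in (Strategy.GOLDEN_GATE, Strategy.AQUA):
        occupied = layout.occupied_wells(THERMOCYCLER_SLOT)
        free = (w for w in _wells_column_major("thermocycler") if w not in occupied)
        for combo in bundle.combinations:
            try:
                layout.place(f"pool_{combo.construct_name}", THERMOCYCLER_SLOT, next(free))
            except StopIteration:
                raise LayoutError("thermocycler full: no well for assembly pool") from None
    return layout


# ---------------------------------------------------------------------------
# rendered artifacts
# ---------------------------------------------------------------------------

def _well_sort_key(loc: Location) -> tuple:
    slot, well = loc
    return (slot, int(well[1:]), well[0])


def render_reagent_setup(layout: DeckLayout, stocks: Sequence[Stock]) -> str:
    """Human-readable bench setup: one line per placed stock with the volume
    the run requires, ordered by slot then well (column-major)."""
    by_name = {s.name: s for s in stocks}
    lines = ["item | kind | slot | well | required_volume_ul"]
    placed = [
        (name, layout.placements[name]) for name in by_name if name in layout.placements
    ]
    placed.sort(key=lambda kv: _well_sort_key(kv[1]))
    for name, (slot, well) in placed:
        s = by_name[name]
        lines.append(f"{name} | {s.kind.value} | {slot} | {well} | {s.volume_ul:.2f}")
    return "\n".join(lines) + "\n"


def render_reactions_setup(plan: GradientPlan, program: ThermoProgram) -> str:
    """Tube-placement instructions plus the gradient program, mirroring the
    cold-to-hot column layout of the thermocycler block."""
    lines = ["Gradient PCR tube placement", "position | zone | zone_temp_C | reaction"]
    entries = sorted(
        plan.assignments.items(), key=lambda kv: (kv[1].zone, kv[1].position or "")
    )
    for rid, a in entries:
        lines.append(
            f"{a.position} | {a.zone + 1} | {plan.zone_temps[a.zone]:.1f} | pcr_{rid}"
        )
    lines.append("")
    lines.append(f"Program: {program.label}")
    if plan.is_flat:
        lines.append(f"annealing temperature: {plan.t_low:.1f} C (uniform)")
    else:
        lines.append(f"gradient: {plan.t_low:.1f} C to {plan.t_high:.1f} C")
    lines.append("step | temperature_C | duration_s")
    for i, step in enumerate(program.steps):
        if step.gradient is not None:
            temp = f"{step.gradient[0]:.1f}-{step.gradient[1]:.1f}"
        else:
            temp = f"{step.temperature_c:.1f}"
        cyc = ""
        if program.cycled_block and program.cycled_block[0] <= i <= program.cycled_block[1]:
            cyc = f" | x{program.cycled_block[2]}"
        lines.append(f"{i + 1} | {temp} | {step.duration_s:.0f}{cyc}")
    return "\n".join(lines) + "\n"


def write_tracking_tables(rows: Sequence[TrackingRow], out_dir: str | Path) -> list[Path]:
    """One ``tracking_<stage>.csv`` per stage present in *rows*; within a
    stage, rows keep their given order."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for stage in Stage:
        stage_rows = [r for r in rows if r.stage == stage]
        if not stage_rows:
            continue
        p = out / f"tracking_{stage.value}.csv"
        with p.open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["item", "kind", "slot", "well", "conc_value", "conc_unit",
                        "volume_ul", "stage"])
            for r in stage_rows:
                w.writerow([r.item, r.kind, r.slot, r.well, format(r.conc_value, "g"),
                            r.conc_unit, format(round(r.volume_ul, 9), "g"), r.stage.value])
        paths.append(p)
    return paths
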