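"""End-to-end run builders: one per assembly strategy.

Each builder composes the gradient planner, the stoichiometry bookkeeping and
the deck model into a :class:`RunBundle` — an ordered list of transfer, pause,
thermocycle and message steps plus everything needed to render instruction
files and to replay the run on the virtual deck.

Strategies
----------
``pcr_only``
    Dilutions → PCR mixes → pause → external gradient amplification →
    optional template digestion.
``golden_gate``
    The PCR workflow, then digestion, a clean-up pause, equimolar pooling of
    fragments per construct, enzyme/buffer additions, and cycled
    restriction–ligation (on the deck's thermocycler by default).
``iva_onepot``
    One reaction well per construct containing every primer and template, a
    single one-pot gradient PCR, digestion, and transformation of the mixture;
    constructs of more than two fragments are refused unless overridden.
``aqua``
    Separate PCRs per fragment as in the PCR workflow, digestion, then
    equimolar pooling with no enzymes and no assembly cycle — assembly happens
    in vivo after transformation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

from .config import RunConfig
from .design import Combination, DesignBundle, PcrSpec, Strategy, validate_design
from .deck import (
    DeckLayout,
    Stage,
    layout_deck,
    render_reactions_setup,
    render_reagent_setup,
)
from .stoichiometry import (
    Location,
    MixError,
    MixReport,
    Stock,
    StockKind,
    TransferStep,
    build_dpn1_mix,
    build_pcr_mix,
    equimolar_volumes,
    plan_primer_dilution,
    plan_template_dilution,
)
from .thermal import (
    GradientGeometry,
    GradientPlan,
    ThermoProgram,
    build_dpn1_program,
    build_goldengate_program,
    build_pcr_program,
    extension_time,
    plan_gradient,
)

__all__ = [
    "Pause",
    "Thermocycle",
    "Message",
    "SpeciesInfo",
    "RunBundle",
    "StrategyError",
    "build_pcr_workflow",
    "build_goldengate_workflow",
    "build_onepot_iva_workflow",
    "build_aqua_workflow",
    "build_workflow",
    "emit_artifacts",
]


class StrategyError(Exception):
    """The design is incompatible with the selected assembly strategy."""


@dataclass(frozen=True)
class Pause:
    """A manual intervention point; execution resumes on user confirmation."""

    ordinal: int
    message: str


@dataclass(frozen=True)
class Thermocycle:
    """Run a thermal program, on the deck module or on an external cycler.

    ``kind`` gives the virtual deck its semantics: ``amplification`` seeds the
    declared product species, ``digestion`` destroys template species in the
    affected wells, ``assembly`` is thermally real but chemically inert here.
    ``products`` lists (well, species name, length bp, assumed ng/µL).
    """

    ordinal: int
    program: ThermoProgram
    location: str  # "on_deck" | "external"
    kind: str      # "amplification" | "digestion" | "assembly"
    wells: tuple[Location, ...] = ()
    products: tuple[tuple[Location, str, int, float], ...] = ()


@dataclass(frozen=True)
class Message:
    """An instruction to the operator with no deck action."""

    ordinal: int
    text: str


Step = TransferStep | Pause | Thermocycle | Message


@dataclass(frozen=True)
class SpeciesInfo:
    """A tracked molecular species and its native amount unit."""

    name: str
    kind: str           # primer | template | fragment
    unit: str           # pmol | ng
    length_bp: int | None = None


@dataclass
class RunBundle:
    """A fully specified, simulatable liquid-handling run."""

    strategy: Strategy
    steps: list[Step]
    layout: DeckLayout
    initial_stocks: list[Stock]
    species: dict[str, SpeciesInfo]
    plan: GradientPlan
    pcr_program: ThermoProgram
    design: DesignBundle
    config_snapshot: dict[str, Any]
    mix_report: MixReport
    #: ordinal of the last step of each completed stage
    stage_boundaries: dict[Stage, int] = field(default_factory=dict)
    artifacts: dict[str, str] = field(default_factory=dict)

    @property
    def transfers(self) -> list[TransferStep]:
        return [s for s in self.steps if isinstance(s, TransferStep)]


# ---------------------------------------------------------------------------
# shared building blocks
# ---------------------------------------------------------------------------

class _Builder:
    """Accumulates steps with strictly increasing ordinals."""

    def __init__(self, config: RunConfig, layout: DeckLayout) -> None:
        self.config = config
        self.layout = layout
        self.steps: list[Step] = []
        self.mix_report = MixReport()
        self._drawn: dict[str, float] = {}  # stock/source item -> µL drawn

    @property
    def next_ordinal(self) -> int:
        return len(self.steps)

    def transfer(self, source_name: str, dest: Location, volume: float,
                 water_filler: bool = False) -> None:
        if volume <= 0:
            return
        src = self.layout.placements[source_name]
        if volume < self.config.min_pipette_ul and not water_filler:
            self.mix_report.record(f"{source_name} -> {dest}", volume)
        self.steps.append(
            TransferStep(
                ordinal=self.next_ordinal,
                source=src,
                dest=dest,
                volume_ul=volume,
                source_name=source_name,
                water_filler=water_filler,
            )
        )
        self._drawn[source_name] = self._drawn.get(source_name, 0.0) + volume

    def extend(self, steps: Sequence[TransferStep]) -> None:
        for s in steps:
            renumbered = dataclasses.replace(s, ordinal=self.next_ordinal)
            if s.volume_ul < self.config.min_pipette_ul and not s.water_filler:
                self.mix_report.record(f"{s.source_name} -> {s.dest}", s.volume_ul)
            self.steps.append(renumbered)
            if s.source_name:
                self._drawn[s.source_name] = (
                    self._drawn.get(s.source_name, 0.0) + s.volume_ul
                )

    def pause(self, message: str) -> None:
        self.steps.append(Pause(self.next_ordinal, message))

    def thermocycle(self, program: ThermoProgram, location: str, kind: str,
                    wells: Sequence[Location] = (),
                    products: Sequence[tuple[Location, str, int, float]] = ()) -> None:
        if location == "external" and not (
            self.steps and isinstance(self.steps[-1], Pause)
        ):
            self.pause(f"Move reactions to the external thermocycler for {program.label}.")
        self.steps.append(
            Thermocycle(self.next_ordinal, program, location, kind,
                        tuple(wells), tuple(products))
        )

    def message(self, text: str) -> None:
        self.steps.append(Message(self.next_ordinal, text))

    def drawn(self, name: str) -> float:
        return self._drawn.get(name, 0.0)


def _reagent_names(strategy: Strategy, config: RunConfig) -> list[str]:
    names = ["master_mix", "water"]
    if config.dpn1_enabled or strategy in (Strategy.GOLDEN_GATE, Strategy.AQUA,
                                           Strategy.IVA_ONEPOT):
        names += ["cutsmart_buffer", "dpn1"]
    if strategy == Strategy.GOLDEN_GATE:
        names += ["ligase_buffer", "typeIIs_enzyme", "ligase"]
        if config.destination_backbone_pieces:
            names.append("destination_plasmid")
    return names


def _species_registry(bundle: DesignBundle) -> dict[str, SpeciesInfo]:
    species = {
        o.name: SpeciesInfo(o.name, "primer", "pmol") for o in bundle.oligos
    }
    for t in bundle.template_names:
        species[t] = SpeciesInfo(t, "template", "ng")
    for p in bundle.pcrs:
        species[f"frag_{p.id}"] = SpeciesInfo(
            f"frag_{p.id}", "fragment", "ng", p.product_length
        )
    return species


def _geometry(config: RunConfig) -> GradientGeometry:
    return GradientGeometry(
        n_zones=config.n_zones,
        rows_per_zone=config.rows_per_zone,
        max_span=config.max_gradient_span_c,
    )


def _add_dilution_steps(b: _Builder, bundle: DesignBundle) -> None:
    """Working dilutions for every primer and distinct template."""
    cfg = b.config
    for o in bundle.oligos:
        d = plan_primer_dilution(
            primer_name=o.name,
            stock_conc=cfg.primer_stock_conc_um,
            final_conc=cfg.primer_final_conc_um,
            rxn_volume=cfg.rxn_volume_ul,
            add_volume=cfg.primer_add_volume_ul,
            working_volume=cfg.working_volume_ul,
        )
        dest = b.layout.placements[o.name]
        b.transfer(f"{o.name}_stock", dest, d.source_volume_ul)
        b.transfer("water", dest, d.diluent_volume_ul, water_filler=True)
    for t in bundle.template_names:
        d = plan_template_dilution(
            template_name=t,
            stock_conc=cfg.template_conc(t),
            target_mass=cfg.template_target_mass_ng,
            add_volume=cfg.template_add_volume_ul,
            working_volume=cfg.working_volume_ul,
            rxn_volume=cfg.rxn_volume_ul,
            min_pipette=cfg.min_pipette_ul,
        )
        dest = b.layout.placements[t]
        b.transfer(f"{t}_stock", dest, d.source_volume_ul)
        b.transfer("water", dest, d.diluent_volume_ul, water_filler=True)


def _add_pcr_mix_steps(b: _Builder, reactions: Sequence[PcrSpec]) -> list[Location]:
    wells = []
    for rxn in sorted(reactions, key=lambda r: r.id):
        dest = b.layout.placements[f"pcr_{rxn.id}"]
        b.extend(build_pcr_mix(rxn, b.config, b.layout.placements, dest))
        wells.append(dest)
    return wells


def _amplification(b: _Builder, plan: GradientPlan, reactions: Sequence[PcrSpec],
                   products_per_well: dict[int, Sequence[tuple[str, int]]]) -> ThermoProgram:
    """Pause, then the external gradient amplification with declared products.

    ``products_per_well`` maps reaction id to the (species, length) fragments
    amplified in that well.
    """
    cfg = b.config
    ext = extension_time(
        [length for prods in products_per_well.values() for _, length in prods],
        rate_s_per_kb=cfg.extension_rate_s_per_kb,
        rounding=cfg.extension_rounding_s,
        floor=cfg.extension_floor_s,
    )
    program = build_pcr_program(
        plan, ext, n_cycles=cfg.pcr_cycles,
        denature_c=cfg.denature_temp_c, extend_c=cfg.extend_temp_c,
    )
    wells = [b.layout.placements[f"pcr_{r.id}"] for r in reactions]
    products = tuple(
        (b.layout.placements[f"pcr_{rid}"], name, length, cfg.assumed_yield_ng_ul)
        for rid, prods in products_per_well.items()
        for name, length in prods
    )
    b.pause(
        "Transfer reaction tubes to the gradient thermocycler; "
        "arrange tubes as listed in reactions_setup.txt."
    )
    b.thermocycle(program, "external", "amplification", wells, products)
    return program


def _add_digestion(b: _Builder, reactions: Sequence[PcrSpec]) -> None:
    wells = []
    for rxn in sorted(reactions, key=lambda r: r.id):
        dest = b.layout.placements[f"pcr_{rxn.id}"]
        b.extend(build_dpn1_mix(b.layout.placements, dest,
                                rxn_volume=b.config.rxn_volume_ul))
        wells.append(dest)
    b.thermocycle(build_dpn1_program(), "on_deck", "digestion", wells)


def _initial_stocks(b: _Builder, bundle: DesignBundle, reagents: Sequence[str]) -> list[Stock]:
    """Stocks at their required volumes (what reagent_setup asks the user to
    provide), each tagged with the species it carries."""
    cfg = b.config
    stocks = []
    reagent_kinds = {
        "master_mix": StockKind.MASTER_MIX,
        "water": StockKind.WATER,
        "cutsmart_buffer": StockKind.BUFFER,
        "dpn1": StockKind.ENZYME,
        "ligase_buffer": StockKind.BUFFER,
        "typeIIs_enzyme": StockKind.ENZYME,
        "ligase": StockKind.ENZYME,
        "destination_plasmid": StockKind.TEMPLATE,
    }
    for name in reagents:
        conc, unit = (0.0, "none")
        if name == "destination_plasmid":
            conc, unit = cfg.destination_plasmid_conc_ng_ul, "ng/uL"
        stocks.append(Stock(name=name, kind=reagent_kinds[name], conc_value=conc,
                            conc_unit=unit,
                            volume_ul=b.drawn(name) + cfg.dead_volume_ul,
                            location=b.layout.placements.get(name)))
    for o in bundle.oligos:
        sname = f"{o.name}_stock"
        stocks.append(Stock(name=sname, kind=StockKind.PRIMER,
                            conc_value=cfg.primer_stock_conc_um, conc_unit="uM",
                            volume_ul=b.drawn(sname) + cfg.dead_volume_ul,
                            location=b.layout.placements.get(sname)))
    for t in bundle.template_names:
        sname = f"{t}_stock"
        stocks.append(Stock(name=sname, kind=StockKind.TEMPLATE,
                            conc_value=cfg.template_conc(t), conc_unit="ng/uL",
                            volume_ul=b.drawn(sname) + cfg.dead_volume_ul,
                            location=b.layout.placements.get(sname)))
    return stocks


def _require_valid(bundle: DesignBundle) -> None:
    report = validate_design(bundle)
    if not report.ok:
        raise StrategyError(f"design fails validation: {report.violations}")


# ---------------------------------------------------------------------------
# strategy builders
# ---------------------------------------------------------------------------

def build_pcr_workflow(bundle: DesignBundle, config: RunConfig = RunConfig()) -> RunBundle:
    """Gradient-optimized PCR setup: dilutions, mixes, external amplification,
    and (by default) DpnI template digestion."""
    _require_valid(bundle)
    reactions = bundle.pcrs
    plan = plan_gradient(reactions, _geometry(config), config.default_tolerance_c)
    reagents = _reagent_names(Strategy.PCR_ONLY, config)
    layout = layout_deck(bundle, config, plan, reagents)
    b = _Builder(config, layout)

    _add_dilution_steps(b, bundle)
    b.stage_boundaries = {Stage.POST_DILUTION: b.next_ordinal - 1}
    _add_pcr_mix_steps(b, reactions)
    program = _amplification(
        b, plan, reactions,
        {r.id: [(f"frag_{r.id}", r.product_length)] for r in reactions},
    )
    b.stage_boundaries[Stage.POST_PCR] = b.next_ordinal - 1
    if config.dpn1_enabled:
        _add_digestion(b, reactions)
        b.stage_boundaries[Stage.POST_DIGEST] = b.next_ordinal - 1

    return RunBundle(
        strategy=Strategy.PCR_ONLY,
        steps=b.steps,
        layout=layout,
        initial_stocks=_initial_stocks(b, bundle, reagents),
        species=_species_registry(bundle),
        plan=plan,
        pcr_program=program,
        design=bundle,
        config_snapshot=config.to_dict(),
        mix_report=b.mix_report,
        stage_boundaries=b.stage_boundaries,
    )


def _pool_combination(
    b: _Builder, bundle: DesignBundle, combo: Combination, dest: Location
) -> float:
    """Equimolar fragment additions for one construct; returns the pooled
    volume.  Sub-minimum proportional volumes are routed through a fresh
    predilution well so delivered moles are unchanged."""
    cfg = b.config
    pieces = [bundle.piece_by_id(pid) for pid in combo.piece_ids]
    skip = set(cfg.destination_backbone_pieces)
    pooled = [(p.id, p.length) for p in pieces if p.id not in skip]
    volumes, predilutions = equimolar_volumes(
        pooled, ref_volume=cfg.equimolar_ref_volume_ul, min_pipette=cfg.min_pipette_ul
    )
    total = 0.0
    for piece in pieces:
        if piece.id in skip:
            continue
        src_name = f"pcr_{piece.source_pcr}"
        v = volumes[piece.id]
        if piece.id in predilutions:
            f = predilutions[piece.id]
            predil_key = f"predil_{combo.construct_name}_{piece.id}"
            plate_slot = next(
                s for s, lw in b.layout.slots.items() if lw.label == "working_plate"
            )
            occupied = b.layout.occupied_wells(plate_slot)
            from .deck import _wells_column_major  # deterministic free-well scan

            free = next(w for w in _wells_column_major("plate_96") if w not in occupied)
            b.layout.place(predil_key, plate_slot, free)
            dil_dest = (plate_slot, free)
            b.transfer(src_name, dil_dest, cfg.min_pipette_ul)
            b.transfer("water", dil_dest, (f - 1.0) * cfg.min_pipette_ul,
                       water_filler=True)
            b.transfer(predil_key, dest, cfg.min_pipette_ul)
        else:
            b.transfer(src_name, dest, v)
        total += v if piece.id not in predilutions else cfg.min_pipette_ul
    return total


def build_goldengate_workflow(bundle: DesignBundle, config: RunConfig = RunConfig()) -> RunBundle:
    """Golden Gate: gradient PCR, digestion, clean-up pause, equimolar
    pooling, and cycled restriction–ligation assembly.

    With ``destination_backbone_pieces`` configured, those pieces are supplied
    as an intact destination plasmid (carrying internal type-IIS sites) added
    directly to each assembly instead of being amplified.
    """
    _require_valid(bundle)
    skip_pieces = set(config.destination_backbone_pieces)
    skip_pcrs = {bundle.piece_by_id(pid).source_pcr for pid in skip_pieces}
    reactions = [p for p in bundle.pcrs if p.id not in skip_pcrs]
    if not reactions:
        raise StrategyError("destination-plasmid mode left no PCRs to run")
    plan = plan_gradient(reactions, _geometry(config), config.default_tolerance_c)
    reagents = _reagent_names(Strategy.GOLDEN_GATE, config)
    layout = layout_deck(bundle, config, plan, reagents)
    b = _Builder(config, layout)

    _add_dilution_steps(b, bundle)
    b.stage_boundaries = {Stage.POST_DILUTION: b.next_ordinal - 1}
    _add_pcr_mix_steps(b, reactions)
    program = _amplification(
        b, plan, reactions,
        {r.id: [(f"frag_{r.id}", r.product_length)] for r in reactions},
    )
    b.stage_boundaries[Stage.POST_PCR] = b.next_ordinal - 1
    _add_digestion(b, reactions)
    b.stage_boundaries[Stage.POST_DIGEST] = b.next_ordinal - 1

    b.pause(
        "Remove fragment reactions, clean and concentrate them, and return "
        "each tube to its original thermocycler position."
    )
    pool_wells = []
    for combo in bundle.combinations:
        dest = layout.placements[f"pool_{combo.construct_name}"]
        pooled_volume = _pool_combination(b, bundle, combo, dest)
        if skip_pieces:
            b.transfer("destination_plasmid", dest, config.destination_plasmid_volume_ul)
            pooled_volume += config.destination_plasmid_volume_ul
        b.transfer("ligase_buffer", dest, config.gg_buffer_volume_ul)
        b.transfer("typeIIs_enzyme", dest, config.gg_enzyme_volume_ul)
        b.transfer("ligase", dest, config.gg_ligase_volume_ul)
        water = config.gg_total_volume_ul - pooled_volume - (
            config.gg_buffer_volume_ul + config.gg_enzyme_volume_ul
            + config.gg_ligase_volume_ul
        )
        if water < -1e-9:
            raise MixError(
                f"{combo.construct_name}: pooled fragments overflow the "
                f"{config.gg_total_volume_ul} µL assembly reaction"
            )
        b.transfer("water", dest, max(water, 0.0), water_filler=True)
        pool_wells.append(dest)

    gg_program = build_goldengate_program(
        n_cycles=config.gg_cycles,
        digest_c=config.gg_digest_temp_c,
        ligate_c=config.gg_ligate_temp_c,
        step_s=config.gg_step_duration_s,
        final_digest_c=config.gg_final_digest_temp_c,
        final_digest_s=config.gg_final_digest_s,
        inactivate_c=config.gg_inactivate_temp_c,
        inactivate_s=config.gg_inactivate_s,
    )
    location = "external" if config.gg_external_cycling else "on_deck"
    b.thermocycle(gg_program, location, "assembly", pool_wells)
    b.stage_boundaries[Stage.POST_ASSEMBLY] = b.next_ordinal - 1

    return RunBundle(
        strategy=Strategy.GOLDEN_GATE,
        steps=b.steps,
        layout=layout,
        initial_stocks=_initial_stocks(b, bundle, reagents),
        species=_species_registry(bundle),
        plan=plan,
        pcr_program=program,
        design=bundle,
        config_snapshot=config.to_dict(),
        mix_report=b.mix_report,
        stage_boundaries=b.stage_boundaries,
    )


def build_onepot_iva_workflow(bundle: DesignBundle, config: RunConfig = RunConfig()) -> RunBundle:
    """One-pot in vivo assembly: one PCR well per construct holding every
    primer and template, a single gradient amplification, digestion, and
    transformation of the raw mixture.

    Constructs with more than two fragments are refused (one-pot amplification
    of three or more fragments fails consistently) unless
    ``onepot_override`` is set, in which case a warning step is emitted.
    """
    _require_valid(bundle)
    oversize = [
        c.construct_name
        for c in bundle.combinations
        if len(c.piece_ids) > config.onepot_max_fragments
    ]
    if oversize and not config.onepot_override:
        raise StrategyError(
            f"one-pot IVA is limited to {config.onepot_max_fragments} fragments "
            f"per construct; offending: {oversize} (set onepot_override to force)"
        )

    # one pseudo-reaction per construct: annealing optimum is the mean of the
    # member reactions', tolerance the tightest member delta
    pseudo: list[PcrSpec] = []
    members: dict[int, list[PcrSpec]] = {}
    for i, combo in enumerate(bundle.combinations, start=1):
        rxns = [bundle.pcr_by_id(bundle.piece_by_id(pid).source_pcr)
                for pid in combo.piece_ids]
        deltas = [r.delta for r in rxns if r.delta is not None]
        pseudo.append(
            PcrSpec(
                id=i,
                template_name=rxns[0].template_name,
                fwd_oligo=rxns[0].fwd_oligo,
                rev_oligo=rxns[0].rev_oligo,
                product_length=max(r.product_length for r in rxns),
                ta_opt=sum(r.ta_opt for r in rxns) / len(rxns),
                delta=min(deltas) if deltas else None,
                note=combo.construct_name,
            )
        )
        members[i] = rxns

    plan = plan_gradient(pseudo, _geometry(config), config.default_tolerance_c)
    reagents = _reagent_names(Strategy.IVA_ONEPOT, config)
    layout = layout_deck(bundle, config, plan, reagents)
    b = _Builder(config, layout)

    if oversize:
        b.message(
            f"WARNING: constructs {oversize} exceed "
            f"{config.onepot_max_fragments} fragments; one-pot amplification "
            "of such designs fails consistently."
        )
    _add_dilution_steps(b, bundle)
    b.stage_boundaries = {Stage.POST_DILUTION: b.next_ordinal - 1}

    scale = config.rxn_volume_ul / 25.0
    for p in pseudo:
        dest = layout.placements[f"pcr_{p.id}"]
        rxns = members[p.id]
        b.transfer("master_mix", dest, config.rxn_volume_ul / 2.0)
        total = config.rxn_volume_ul / 2.0
        primers: list[str] = []
        for r in rxns:
            for name in (r.fwd_oligo, r.rev_oligo):
                if name not in primers:
                    primers.append(name)
        templates: list[str] = []
        for r in rxns:
            if r.template_name not in templates:
                templates.append(r.template_name)
        for name in primers:
            b.transfer(name, dest, config.primer_add_volume_ul * scale)
            total += config.primer_add_volume_ul * scale
        for name in templates:
            b.transfer(name, dest, config.template_add_volume_ul * scale)
            total += config.template_add_volume_ul * scale
        water = config.rxn_volume_ul - total
        if water < -1e-9:
            raise MixError(f"{p.note}: one-pot components exceed the reaction volume")
        b.transfer("water", dest, max(water, 0.0), water_filler=True)

    products = {
        p.id: [(f"frag_{r.id}", r.product_length) for r in members[p.id]]
        for p in pseudo
    }
    program = _amplification(b, plan, pseudo, products)
    b.stage_boundaries[Stage.POST_PCR] = b.next_ordinal - 1
    _add_digestion(b, pseudo)
    b.stage_boundaries[Stage.POST_DIGEST] = b.next_ordinal - 1
    b.message("Transform each fragment mixture into E. coli; assembly occurs in vivo.")

    return RunBundle(
        strategy=Strategy.IVA_ONEPOT,
        steps=b.steps,
        layout=layout,
        initial_stocks=_initial_stocks(b, bundle, reagents),
        species=_species_registry(bundle),
        plan=plan,
        pcr_program=program,
        design=bundle,
        config_snapshot=config.to_dict(),
        mix_report=b.mix_report,
        stage_boundaries=b.stage_boundaries,
    )


def build_aqua_workflow(bundle: DesignBundle, config: RunConfig = RunConfig()) -> RunBundle:
    """Separate-PCR homology assembly: the PCR workflow, digestion, equimolar
    pooling per construct, and transformation — no enzymes, no assembly
    cycle (native host machinery joins the fragments in vivo)."""
    _require_valid(bundle)
    reactions = bundle.pcrs
    plan = plan_gradient(reactions, _geometry(config), config.default_tolerance_c)
    reagents = _reagent_names(Strategy.AQUA, config)
    layout = layout_deck(bundle, config, plan, reagents)
    b = _Builder(config, layout)

    _add_dilution_steps(b, bundle)
    b.stage_boundaries = {Stage.POST_DILUTION: b.next_ordinal - 1}
    _add_pcr_mix_steps(b, reactions)
    program = _amplification(
        b, plan, reactions,
        {r.id: [(f"frag_{r.id}", r.product_length)] for r in reactions},
    )
    b.stage_boundaries[Stage.POST_PCR] = b.next_ordinal - 1
    _add_digestion(b, reactions)
    b.stage_boundaries[Stage.POST_DIGEST] = b.next_ordinal - 1

    for combo in bundle.combinations:
        dest = layout.placements[f"pool_{combo.construct_name}"]
        _pool_combination(b, bundle, combo, dest)
    b.stage_boundaries[Stage.POST_ASSEMBLY] = b.next_ordinal - 1
    b.message("Transform each fragment mixture into E. coli; assembly occurs in vivo.")

    return RunBundle(
        strategy=Strategy.AQUA,
        steps=b.steps,
        layout=layout,
        initial_stocks=_initial_stocks(b, bundle, reagents),
        species=_species_registry(bundle),
        plan=plan,
        pcr_program=program,
        design=bundle,
        config_snapshot=config.to_dict(),
        mix_report=b.mix_report,
        stage_boundaries=b.stage_boundaries,
    )


_BUILDERS = {
    Strategy.PCR_ONLY: build_pcr_workflow,
    Strategy.GOLDEN_GATE: build_goldengate_workflow,
    Strategy.IVA_ONEPOT: build_onepot_iva_workflow,
    Strategy.AQUA: build_aqua_workflow,
}


def build_workflow(bundle: DesignBundle, config: RunConfig = RunConfig()) -> RunBundle:
    """Dispatch to the builder for the bundle's strategy."""
    return _BUILDERS[bundle.strategy](bundle, config)


# ---------------------------------------------------------------------------
# artifact emission
# ---------------------------------------------------------------------------

def _step_to_json(step: Step) -> dict[str, Any]:
    if isinstance(step, TransferStep):
        return {
            "type": "transfer", "ordinal": step.ordinal,
            "source": list(step.source), "dest": list(step.dest),
            "volume_ul": step.volume_ul, "source_name": step.source_name,
            "water_filler": step.water_filler,
        }
    if isinstance(step, Pause):
        return {"type": "pause", "ordinal": step.ordinal, "message": step.message}
    if isinstance(step, Thermocycle):
        return {
            "type": "thermocycle", "ordinal": step.ordinal,
            "program": step.program.to_dict(), "location": step.location,
            "kind": step.kind, "wells": [list(w) for w in step.wells],
            "products": [[list(w), n, l, c] for w, n, l, c in step.products],
        }
    return {"type": "message", "ordinal": step.ordinal, "text": step.text}


def emit_artifacts(rb: RunBundle, out_dir: str | Path) -> dict[str, str]:
    """Render every run artifact into *out_dir*.

    Writes the four design section tables, ``reagent_setup.txt``,
    ``reactions_setup.txt``, per-stage tracking CSVs, ``runbundle.json`` and
    ``picklist.csv``; returns a name → path mapping (also stored on the
    bundle).  Output is byte-identical across runs on the same input.
    """
    from .deck import write_tracking_tables
    from .design import write_section_tables
    from .simulate import tracking_rows  # deferred: simulate imports this module

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    for p in write_section_tables(rb.design, out):
        artifacts[p.name] = str(p)

    reagent_path = out / "reagent_setup.txt"
    reagent_path.write_text(
        render_reagent_setup(rb.layout, rb.initial_stocks), encoding="utf-8"
    )
    artifacts["reagent_setup.txt"] = str(reagent_path)

    reactions_path = out / "reactions_setup.txt"
    reactions_path.write_text(
        render_reactions_setup(rb.plan, rb.pcr_program), encoding="utf-8"
    )
    artifacts["reactions_setup.txt"] = str(reactions_path)

    for p in write_tracking_tables(tracking_rows(rb), out):
        artifacts[p.name] = str(p)

    picklist_path = out / "picklist.csv"
    with picklist_path.open("w", newline="", encoding="utf-8") as fh:
        import csv

        w = csv.writer(fh)
        w.writerow(["ordinal", "source_slot", "source_well", "dest_slot",
                    "dest_well", "volume_ul", "mix_reps", "mix_vol_ul"])
        for s in rb.transfers:
            mix_reps, mix_vol = s.mix_after if s.mix_after else ("", "")
            w.writerow([s.ordinal, s.source[0], s.source[1], s.dest[0], s.dest[1],
                        format(round(s.volume_ul, 9), "g"), mix_reps, mix_vol])
    artifacts["picklist.csv"] = str(picklist_path)

    runbundle_path = out / "runbundle.json"
    payload = {
        "strategy": rb.strategy.value,
        "config": rb.config_snapshot,
        "steps": [_step_to_json(s) for s in rb.steps],
        "mix_report_below_min": [
            {"label": label, "volume_ul": v} for label, v in rb.mix_report.below_min
        ],
        "artifacts": sorted(artifacts),
    }
    runbundle_path.write_text(
        json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    artifacts["runbundle.json"] = str(runbundle_path)

    rb.artifacts = artifacts
    return artifacts
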