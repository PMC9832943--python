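"""Concentration and volume bookkeeping: dilutions, reaction mixes, pooling.

Every dilution obeys C1·V1 = C2·V2 exactly; every reaction mix reproduces the
printed final composition (0.1 µM of each primer and 0.5 ng template in a
25 µL PCR; 19/5/1 µL water/buffer/enzyme for template digestion) and scales
linearly with reaction volume.  Equimolar pooling adds a volume proportional
to each fragment's length, under the assumption that every PCR yields the
same mass concentration; fragments whose proportional volume would fall below
the pipettable minimum are prediluted so the delivered moles are unchanged.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .config import RunConfig
from .design import PcrSpec

__all__ = [
    "StockKind",
    "Stock",
    "Dilution",
    "TransferStep",
    "MixReport",
    "DilutionError",
    "MixError",
    "plan_primer_dilution",
    "plan_template_dilution",
    "build_pcr_mix",
    "build_dpn1_mix",
    "equimolar_volumes",
]

Location = tuple[object, str]  # (slot id, well name)


class DilutionError(Exception):
    """A requested dilution cannot be pipetted as specified."""


class MixError(Exception):
    """A reaction mix cannot be assembled (e.g. components exceed volume)."""


class StockKind(str, enum.Enum):
    PRIMER = "primer"
    TEMPLATE = "template"
    FRAGMENT = "fragment"
    ENZYME = "enzyme"
    BUFFER = "buffer"
    WATER = "water"
    MASTER_MIX = "master_mix"


#: concentration units understood by the bookkeeping
CONC_UNITS = ("uM", "ng/uL", "x", "none")


@dataclass
class Stock:
    """A named liquid with a concentration, a volume, and (once placed on the
    deck) a location."""

    name: str
    kind: StockKind
    conc_value: float = 0.0
    conc_unit: str = "none"
    volume_ul: float = 0.0
    location: Location | None = None

    def __post_init__(self) -> None:
        if self.volume_ul < 0 or self.conc_value < 0:
            raise ValueError(f"stock {self.name!r}: negative volume or concentration")
        if self.conc_unit not in CONC_UNITS:
            raise ValueError(f"stock {self.name!r}: unknown unit {self.conc_unit!r}")


@dataclass(frozen=True)
class Dilution:
    """One C1·V1 = C2·V2 dilution from a stock into a working solution.

    ``add_volume_ul`` is the per-reaction volume of the *result* that delivers
    the intended amount into a reaction.  A pass-through (``source_volume ==
    result volume``, no diluent) represents using the stock directly.
    """

    source: Stock
    source_volume_ul: float
    diluent_volume_ul: float
    result: Stock
    add_volume_ul: float

    @property
    def is_passthrough(self) -> bool:
        return self.diluent_volume_ul == 0.0


@dataclass(frozen=True)
class TransferStep:
    """One liquid transfer on the deck."""

    ordinal: int
    source: Location
    dest: Location
    volume_ul: float
    source_name: str = ""
    mix_after: tuple[int, float] | None = None
    water_filler: bool = False


@dataclass
class MixReport:
    """Pipetting-quality findings: transfers below the pipettable minimum."""

    below_min: list[tuple[str, float]] = field(default_factory=list)

    def record(self, label: str, volume_ul: float) -> None:
        self.below_min.append((label, volume_ul))

    @property
    def ok(self) -> bool:
        return not self.below_min


def _working_stock(name: str, kind: StockKind, conc: float, unit: str, vol: float) -> Stock:
    return Stock(name=name, kind=kind, conc_value=conc, conc_unit=unit, volume_ul=vol)


# ---------------------------------------------------------------------------
# dilution planning
# ---------------------------------------------------------------------------

def plan_primer_dilution(
    primer_name: str = "primer",
    stock_conc: float = 100.0,
    final_conc: float = 0.1,
    rxn_volume: float = 25.0,
    add_volume: float = 1.0,
    working_volume: float = 20.0,
) -> Dilution:
    """Dilute a primer stock to the working concentration that delivers
    *final_conc* when *add_volume* is added to a *rxn_volume* reaction.

    At defaults the working stock is 2.5 µM: 0.5 µL of 100 µM stock plus
    19.5 µL water.
    """
    working_conc = final_conc * rxn_volume / add_volume
    if stock_conc <= working_conc:
        raise DilutionError(
            f"{primer_name}: stock {stock_conc} µM at or below working target "
            f"{working_conc} µM; use the stock directly with an adjusted add volume"
        )
    source = Stock(f"{primer_name}_stock", StockKind.PRIMER, stock_conc, "uM", working_volume)
    v1 = working_conc * working_volume / stock_conc
    result = _working_stock(primer_name, StockKind.PRIMER, working_conc, "uM", working_volume)
    return Dilution(
        source=source,
        source_volume_ul=v1,
        diluent_volume_ul=working_volume - v1,
        result=result,
        add_volume_ul=add_volume,
    )


def plan_template_dilution(
    template_name: str = "template",
    stock_conc: float = 50.0,
    target_mass: float = 0.5,
    add_volume: float = 1.0,
    working_volume: float = 20.0,
    rxn_volume: float = 25.0,
    min_pipette: float = 1.0,
) -> Dilution:
    """Dilute a template stock so *add_volume* delivers *target_mass* ng.

    A stock already at or below the working concentration is passed through
    with the add volume raised to deliver the target mass; the raised volume
    must stay pipettable and within 10% of the reaction volume.
    """
    if stock_conc <= 0:
        raise DilutionError(f"{template_name}: stock concentration must be positive")
    working_conc = target_mass / add_volume
    source = Stock(f"{template_name}_stock", StockKind.TEMPLATE, stock_conc, "ng/uL", working_volume)
    if stock_conc > working_conc:
        v1 = working_conc * working_volume / stock_conc
        result = _working_stock(template_name, StockKind.TEMPLATE, working_conc, "ng/uL", working_volume)
        return Dilution(source, v1, working_volume - v1, result, add_volume)
    # pass-through: stock used directly at a larger add volume
    needed = target_mass / stock_conc
    cap = 0.1 * rxn_volume
    if needed > cap:
        raise DilutionError(
            f"{template_name}: template too dilute — delivering {target_mass} ng "
            f"needs {needed:.2f} µL, above the {cap:.2f} µL cap (10% of reaction)"
        )
    if needed < min_pipette:
        needed = min_pipette  # same conc, slightly more mass is never reachable here
    result = _working_stock(template_name, StockKind.TEMPLATE, stock_conc, "ng/uL", working_volume)
    return Dilution(source, working_volume, 0.0, result, needed)


# ---------------------------------------------------------------------------
# reaction mixes
# ---------------------------------------------------------------------------

def build_pcr_mix(
    rxn: PcrSpec,
    config: RunConfig,
    placements: Mapping[str, Location],
    dest: Location,
    start_ordinal: int = 0,
) -> list[TransferStep]:
    """Transfers assembling one PCR from working stocks.

    Per 25 µL reaction at defaults: 12.5 µL 2× polymerase master mix, 1 µL
    each working primer, 1 µL working template, and water to volume (9.5 µL).
    All component volumes scale linearly with the configured reaction volume,
    keeping the final composition fixed.

    *placements* maps stock names (``master_mix``, ``water``, each working
    primer and template) to deck locations.
    """
    scale = config.rxn_volume_ul / 25.0
    master = config.rxn_volume_ul / 2.0
    primer_add = config.primer_add_volume_ul * scale
    template_add = config.template_add_volume_ul * scale
    water = config.rxn_volume_ul - master - 2 * primer_add - template_add
    if water < -1e-12:
        raise MixError(
            f"PCR {rxn.id}: overfull — components exceed {config.rxn_volume_ul} µL"
        )
    water = max(water, 0.0)
    components = [
        ("master_mix", master, False),
        (rxn.fwd_oligo, primer_add, False),
        (rxn.rev_oligo, primer_add, False),
        (rxn.template_name, template_add, False),
        ("water", water, True),
    ]
    steps = []
    for i, (name, vol, filler) in enumerate(components):
        steps.append(
            TransferStep(
                ordinal=start_ordinal + i,
                source=placements[name],
                dest=dest,
                volume_ul=vol,
                source_name=name,
                water_filler=filler,
            )
        )
    return steps


def build_dpn1_mix(
    placements: Mapping[str, Location],
    dest: Location,
    rxn_volume: float = 25.0,
    start_ordinal: int = 0,
) -> list[TransferStep]:
    """Post-PCR template digestion additions: 19 µL water, 5 µL reaction
    buffer and 1 µL DpnI per default-volume reaction, scaled proportionally
    for other reaction volumes (final well volume 2× the PCR volume)."""
    scale = rxn_volume / 25.0
    additions = [
        ("water", 19.0 * scale, True),
        ("cutsmart_buffer", 5.0 * scale, False),
        ("dpn1", 1.0 * scale, False),
    ]
    return [
        TransferStep(
            ordinal=start_ordinal + i,
            source=placements[name],
            dest=dest,
            volume_ul=vol,
            source_name=name,
            water_filler=filler,
        )
        for i, (name, vol, filler) in enumerate(additions)
    ]


# ---------------------------------------------------------------------------
# equimolar pooling
# ---------------------------------------------------------------------------

def equimolar_volumes(
    fragments: Sequence[tuple[int, int]],
    ref_volume: float = 4.0,
    min_pipette: float = 1.0,
) -> tuple[dict[int, float], dict[int, float]]:
    """Per-fragment pooling volumes proportional to fragment length.

    With equal mass concentrations across PCRs (the equal-yield assumption),
    volume ∝ length delivers equal moles of every fragment.  The longest
    fragment gets *ref_volume*; any fragment whose proportional volume falls
    below *min_pipette* is prediluted by the smallest factor that brings its
    addition up to exactly *min_pipette*, leaving delivered moles unchanged.

    Returns ``(volumes, predilution factors)`` keyed by fragment id; the
    factor dict only lists prediluted fragments.
    """
    if not fragments:
        raise ValueError("need at least one fragment")
    if any(length <= 0 for _, length in fragments):
        raise ValueError("fragment lengths must be positive")
    if ref_volume < min_pipette:
        raise ValueError("ref_volume must be >= min_pipette")
    max_len = max(length for _, length in fragments)
    volumes: dict[int, float] = {}
    predilutions: dict[int, float] = {}
    for fid, length in fragments:
        v = ref_volume * length / max_len
        if v < min_pipette:
            predilutions[fid] = min_pipette / v
            v = min_pipette
        volumes[fid] = v
    return volumes, predilutions
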