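"""Run configuration: every tunable the planner consumes, with bench defaults.

All volumes are in µL, temperatures in °C, durations in seconds, molar
concentrations in µM and mass concentrations in ng/µL.  A configuration is an
immutable snapshot: workflows embed ``to_dict()`` output in every run bundle so
a run can be reproduced byte-for-byte from its own artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration for a planning run.

    Defaults reproduce the standard bench protocol: 25 µL PCRs with 0.1 µM of
    each primer and 0.5 ng linearized template, DpnI digestion by 19/5/1 µL
    additions, and a 12-zone annealing gradient that accommodates every
    reaction to within 0.4 °C.
    """

    # --- PCR composition -------------------------------------------------
    rxn_volume_ul: float = 25.0
    primer_stock_conc_um: float = 100.0
    primer_final_conc_um: float = 0.1
    primer_add_volume_ul: float = 1.0
    template_target_mass_ng: float = 0.5
    template_add_volume_ul: float = 1.0
    template_stock_conc_ng_ul: float = 50.0
    #: per-template stock concentration overrides, name -> ng/µL
    template_stock_overrides: Mapping[str, float] = field(default_factory=dict)
    working_volume_ul: float = 20.0
    min_pipette_ul: float = 1.0

    # --- gradient geometry and thermal programs --------------------------
    n_zones: int = 12
    rows_per_zone: int = 8
    max_gradient_span_c: float = 24.0
    default_tolerance_c: float = 0.4
    extension_rate_s_per_kb: float = 30.0
    extension_rounding_s: float = 5.0
    extension_floor_s: float = 10.0
    pcr_cycles: int = 34
    denature_temp_c: float = 98.0
    extend_temp_c: float = 72.0

    # --- DpnI digestion ---------------------------------------------------
    dpn1_enabled: bool = True

    # --- Golden Gate assembly --------------------------------------------
    gg_total_volume_ul: float = 20.0
    gg_buffer_volume_ul: float = 2.0
    gg_enzyme_volume_ul: float = 1.0
    gg_ligase_volume_ul: float = 1.0
    gg_cycles: int = 30
    gg_digest_temp_c: float = 37.0
    gg_ligate_temp_c: float = 16.0
    gg_step_duration_s: float = 300.0
    gg_final_digest_temp_c: float = 50.0
    gg_final_digest_s: float = 300.0
    gg_inactivate_temp_c: float = 80.0
    gg_inactivate_s: float = 600.0
    gg_external_cycling: bool = False
    #: piece ids supplied as an intact destination plasmid instead of PCRs
    destination_backbone_pieces: tuple[int, ...] = ()
    destination_plasmid_volume_ul: float = 1.0
    destination_plasmid_conc_ng_ul: float = 25.0

    # --- equimolar pooling ------------------------------------------------
    equimolar_ref_volume_ul: float = 4.0
    #: assumed post-PCR fragment yield, equal across reactions (ng/µL)
    assumed_yield_ng_ul: float = 20.0

    # --- one-pot IVA ------------------------------------------------------
    onepot_max_fragments: int = 2
    onepot_override: bool = False

    # --- simulator --------------------------------------------------------
    dead_volume_ul: float = 0.0
    well_capacity_ul: float = 200.0

    def template_conc(self, template_name: str) -> float:
        """Stock concentration (ng/µL) for a named template."""
        return float(self.template_stock_overrides.get(template_name, self.template_stock_conc_ng_ul))

    # working concentrations are derived, never stored, so the printed final
    # concentrations stay exact under any add volume
    @property
    def primer_working_conc_um(self) -> float:
        return self.primer_final_conc_um * self.rxn_volume_ul / self.primer_add_volume_ul

    @property
    def template_working_conc_ng_ul(self) -> float:
        return self.template_target_mass_ng / self.template_add_volume_ul

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["template_stock_overrides"] = dict(d["template_stock_overrides"])
        d["destination_backbone_pieces"] = list(d["destination_backbone_pieces"])
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs = dict(data)
        if "destination_backbone_pieces" in kwargs:
            kwargs["destination_backbone_pieces"] = tuple(kwargs["destination_backbone_pieces"])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a YAML or JSON configuration file."""
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
        return cls.from_dict(data or {})
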