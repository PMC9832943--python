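# assemblyline

Build planning for combinatorial DNA assembly on a liquid-handling robot.

Starting from a combinatorial design file — the CSV a DNA-assembly design
tool emits, listing synthesized primers, PCR reactions, assembly pieces, and
the ordered piece combinations that make up each construct — `assemblyline`
produces a fully specified, machine-checkable run plan for one of four
strategies: gradient-optimized PCR only, Golden Gate (cycled
restriction–ligation with a type-IIS enzyme), one-pot IVA, or separate-PCR
AQUA (both homology-dependent, assembled in vivo after transformation). The
plan covers working-stock dilution series, per-reaction mixes, thermocycler
programs, equimolar fragment pooling, deck placement and tube-arrangement
instructions, per-stage item tracking, and a transfer picklist — and every
plan is validated by replaying it on a virtual deck with exact volume and
molar bookkeeping.

It is written for synthetic-biology bench scientists and biofoundry
engineers who design combinatorially and want the error-prone arithmetic —
annealing-gradient optimization, C1·V1 = C2·V2 dilutions, equimolar ratios —
done by software rather than by hand.

## The core calculations

**Annealing gradient.** Each PCR *i* has an optimal annealing temperature
*Tₐ,ᵢ* and a tolerance τᵢ = min(δᵢ, 0.4 °C), where δᵢ is the design file's
per-reaction *delta*. The thermocycler block holds a linear gradient across
its 12 columns; zone *k* sits at *T_low + k·(T_high − T_low)/11*. Endpoints
default to (min Tₐ, max Tₐ) and each reaction is assigned the nearest zone;
if any |Tₐ,ᵢ − T_zone(i)| > τᵢ, the endpoints are re-optimized by exhaustive
0.1 °C grid search (±2 °C), minimizing the worst tolerance excess, then the
worst deviation. Every reaction in a run is accommodated within 0.4 °C or
the run is declared infeasible — never silently degraded.

**Composition.** Reactions are assembled to the printed protocol: 25 µL PCRs
with 0.1 µM of each primer and 0.5 ng template (working stocks derived, e.g.
2.5 µM primers so that a 1 µL addition lands exactly at 0.1 µM); DpnI
digestion by 19 µL water + 5 µL buffer + 1 µL enzyme, 30 min at 37 °C and
20 min at 65 °C; amplification with 34 cycles and a 5-minute final extension
at 72 °C.

**Equimolar pooling.** Under the equal-yield assumption (every fragment PCR
at the same mass concentration), adding volume *vᵢ = v_ref · Lᵢ / L_max*
delivers equal moles of every fragment; sub-µL additions are routed through
an exact predilution. The virtual deck verifies pairwise mole equality in
every pooled well.

## Worked example

Generate the bundled demonstration design — 7 PCRs wired into 4 four-piece
constructs that share 3 backbone pieces — and plan a Golden Gate run:

```
$ assemblyline fixture --chromoprotein --out fx
fx/design.csv
$ assemblyline setup fx/design.csv --strategy goldengate --out run
135 steps planned; 13 artifacts in run
```

`run/reactions_setup.txt` begins:

```
Gradient PCR tube placement
position | zone | zone_temp_C | reaction
A1 | 1 | 58.9 | pcr_6
A2 | 2 | 59.4 | pcr_2
A3 | 3 | 60.0 | pcr_1
A4 | 4 | 60.5 | pcr_4
A5 | 5 | 61.0 | pcr_3
B5 | 5 | 61.0 | pcr_7
A12 | 12 | 64.7 | pcr_5

Program: amplification
gradient: 58.9 C to 64.7 C
```

Reaction 5 anneals ~4 °C hotter than the rest, so the planner placed it
alone in the hottest column (A12) while the other six cluster in the cold
half of the gradient; one run serves all seven within 0.4 °C of their
optima. `run/reagent_setup.txt` lists what to put where, with required
volumes summed over the whole run:

```
item | kind | slot | well | required_volume_ul
master_mix | master_mix | 1 | A1 | 87.50
water | water | 1 | B1 | 636.28
cutsmart_buffer | buffer | 1 | C1 | 35.00
dpn1 | enzyme | 1 | D1 | 7.00
```

(87.5 µL master mix = 7 reactions × 12.5 µL; 35 µL buffer and 7 µL DpnI =
7 × 5 and 7 × 1 µL digestion additions.) The remaining artifacts are the
four split design tables (`oligo.csv`, `pcr.csv`, `assembly.csv`,
`combinations.csv`), per-stage tracking CSVs, `picklist.csv` (one row per
transfer: ordinal, source/destination slot and well, volume), and
`runbundle.json`, which embeds every step and the full effective
configuration so the run can be reproduced byte-for-byte.

The same plan is checkable in code:

```python
from assemblyline import (parse_design, Strategy, build_goldengate_workflow,
                          execute, check_conservation, well_composition)

bundle = parse_design("fx/design.csv", Strategy.GOLDEN_GATE)
rb = build_goldengate_workflow(bundle)
state = execute(rb)                       # virtual deck
assert state.violations == []
assert check_conservation(state, rb.initial_stocks).ok
vol, comp = well_composition(state, rb.layout.placements["pool_construct_1"])
print(vol, {k: round(v["pmol"], 4) for k, v in comp.items() if "pmol" in v})
# 20.0 {'frag_1': 0.028, 'frag_2': 0.028, 'frag_5': 0.028, 'frag_6': 0.028}
```

Each assembly well ends at exactly 20 µL with equal moles of its four
fragments.

## Configuration

Every default named above is a key in a YAML/JSON config file passed as
`--config run.yaml` (reaction volume, stock and final concentrations, zone
count and gradient orientation, tolerance, extension rate, cycle counts,
Golden Gate volumes and temperatures, pooling reference volume, pipettable
minimum, feature flags such as `dpn1_enabled`, `gg_external_cycling`,
`destination_backbone_pieces`, `onepot_override`). See `docs/methods.md` for
the reasoning behind each default and the model's assumptions and limits.
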