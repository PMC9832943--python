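# Methods

`assemblyline` converts a combinatorial DNA-assembly design — the tables a
design tool emits listing primers, PCR reactions, assembly pieces, and the
ordered piece sets making up each construct — into a fully specified
liquid-handling run, and verifies that run by exact bookkeeping on a virtual
deck. This note records the models, the defaults, and the choices made where
the procedure was genuinely open.

## Scope and model of the run

A run is an ordered list of steps: liquid transfers with (slot, well)
endpoints, pauses for manual interventions (moving tubes to an external
gradient thermocycler, cleaning up fragments), thermocycler programs, and
operator messages. The run is *planned*, not executed: the package's claim is
that if the plan is followed, the resulting reactions have the intended
composition. That claim is checked mechanically — every workflow is replayed
on a virtual deck that conserves volume and molecular amounts, and tests
assert final compositions there rather than on the arithmetic that produced
the plan.

A run is limited to 96 combined distinct primers and templates; validation
enforces the bound exactly (96 passes, 97 fails, for any mix of the two).

## Annealing-temperature gradient

Each PCR carries an optimal annealing temperature (the mean of its two
primers' annealing optima unless the design file states one) and optionally a
*delta*, the tolerable variance for that reaction. The effective tolerance is
`min(delta, 0.4 °C)`; 0.4 °C is the accommodation bound a single gradient run
must meet, and a looser delta never relaxes it.

The block is modeled as 8 rows × 12 columns with the gradient linear across
columns, cold left to hot right (configurable, since instruments differ in
orientation and zone count). Endpoints default to the min and max optima;
zone *k* sits at `t_low + k·(t_high−t_low)/(n_zones−1)`. Each reaction goes
to the zone minimizing its deviation (ties to the colder zone). If any
reaction then exceeds its tolerance — which happens exactly when a rigid
delta demands finer placement than the zone spacing offers — both endpoints
are re-optimized by exhaustive grid search ±2.0 °C around the defaults in
0.1 °C steps, minimizing first the worst clamped excess over tolerance, then
the worst deviation, with ties broken to the lowest `t_low` and then the
smallest span. The search is deterministic and small (41² candidate pairs);
a test holds it equal to an independently coded brute force on designs of up
to 8 reactions. For 12 zones, any design whose optima span ≤ 8 °C is served
within 0.4 °C by the default endpoints (zone spacing ≤ 8/11 °C, so the worst
half-spacing is ≈ 0.364 °C).

Within a zone, tubes fill rows A→H in ascending reaction id; a design
putting more than 8 reactions in one zone is a layout error. Designs whose
optima span more than the block maximum (24 °C default) are refused with a
split-run error rather than silently degraded.

Extension time is one value for the whole run: the longest product at
30 s/kb, rounded up to 5 s, floored at 10 s (all configurable; the rate is a
common polymerase spec, not a measured constant). The amplification program
is 30 s at 98 °C; then 34 cycles (configurable; 36 is the common alternative)
of 10 s at 98 °C, 30 s at the gradient (a single temperature when the plan is
flat), and the extension at 72 °C; then a 5-minute final extension at 72 °C.

## Composition bookkeeping

All dilutions obey C1·V1 = C2·V2 exactly. Working concentrations are derived
from the printed final composition, never stored: with 1 µL additions into a
25 µL reaction, the primer working stock is 0.1 µM × 25 / 1 = 2.5 µM (0.5 µL
of a 100 µM stock + 19.5 µL water in a 20 µL working volume) and the template
working stock is 0.5 ng/µL. A template stock already at or below its working
concentration is passed through with the add volume raised to deliver 0.5 ng,
capped at 10 % of the reaction volume — beyond that the template is reported
as too dilute rather than distorting the reaction.

A PCR is assembled as 2× polymerase master mix (half the reaction volume),
one add volume of each working primer and of the working template, and water
to volume — 12.5/1/1/1/9.5 µL at defaults, scaling linearly so the final
composition (0.1 µM each primer, 0.5 ng template) is invariant under the
reaction volume. The master mix abstracts polymerase, dNTPs and buffer as
one liquid: per-enzyme volumes are vendor-internal and irrelevant to the
final concentrations being checked. Template digestion adds 19 µL water,
5 µL reaction buffer, and 1 µL DpnI per 25 µL reaction (proportional
otherwise) and runs 30 min at 37 °C then 20 min at 65 °C.

Transfers below the pipettable minimum (1.0 µL default) are permitted but
always collected into a mix report — e.g. the 0.5 µL primer stock draw at
defaults — never silently emitted.

## Equimolar pooling and assembly strategies

Pooling assumes every fragment PCR yields the same mass concentration
(the equal-yield assumption); volumes proportional to fragment length then
deliver equal moles. The longest fragment in a pool receives the reference
volume (4.0 µL default); a fragment whose proportional volume falls below
the pipettable minimum is prediluted in a fresh well by the smallest factor
bringing its addition to exactly the minimum, leaving delivered moles
unchanged. The simulator verifies pairwise mole equality in every pooled
well.

*Golden Gate* appends to the PCR workflow: digestion, a pause to clean and
concentrate fragments (returned to their original positions; cleaned
concentrations are assumed unchanged unless overridden), equimolar pooling
per construct, then 2 µL 10× ligase buffer, 1 µL type-IIS enzyme, 1 µL
ligase, and water to a 20 µL reaction, cycled 30× between 37 °C and 16 °C
(5 min each) with a 50 °C final digestion and 80 °C heat inactivation — the
standard restriction–ligation cycle; all numbers are configuration keys.
A destination-plasmid mode supplies designated backbone pieces as an intact
plasmid with internal type-IIS sites: those PCRs are skipped and a fixed
volume of the plasmid is added to each assembly instead.

*One-pot IVA* puts all primers and templates of a construct in a single
reaction and relies on in vivo homologous recombination after
transformation. Constructs of more than two fragments are refused — one-pot
amplification of three or more fragments fails consistently — unless
explicitly overridden, in which case the plan carries a warning step. The
pooled well's annealing optimum is the mean of its member reactions',
with the tightest member delta as its tolerance.

*AQUA* (separate-PCR homology assembly) shares the PCR-plus-digestion prefix
with Golden Gate step-for-step, then pools equimolar volumes per construct
with no enzymes and no assembly cycle; the run ends with the instruction to
transform the mixture.

## Virtual deck

Wells track liquid volume and per-species amounts — primers in pmol (µM·µL),
template and fragment DNA in ng, with fragment moles derived from declared
lengths at 650 g·mol⁻¹·bp⁻¹; enzymes, buffers and master mix contribute
volume only. Transfers move amounts proportionally; overdraws and well-
capacity overruns are recorded as violations, never dropped. A digestion
cycle zeroes template species in its wells. Because equimolarity claims need
fragment moles to exist, an amplification cycle seeds each reaction well's
declared fragment at a configurable assumed yield (20 ng/µL), equal across
wells — this is the equal-yield assumption made executable, not a kinetic
model. Conservation checks compare totals against the initial stocks to
1e-9 relative, exempting exactly the species a modeled digestion destroyed
or an amplification created. Evaporation, dead volume and tip residue are
not modeled (a dead-volume key exists, default 0).

## Synthetic designs

The fixture generator emulates upstream design-tool output: reactions get
annealing optima drawn uniformly (58–66 °C default, rounded to 0.1 °C),
product lengths uniform on 500–5000 bp, random A/C/G/T filler sequences, and
names like `oligo_k` / `template_k` / `frag_k`; one template per reaction.
The mixed delta policy gives alternate reactions 0.2 °C and 1.0 °C deltas to
exercise the rigid-tolerance branch. Same seed, byte-identical file, with a
JSON manifest of every generated value serving as parser ground truth. A
fixed chromoprotein-panel-like fixture wires 7 PCRs into 4 four-piece
constructs sharing 3 backbone pieces, the structure used for end-to-end
Golden Gate and AQUA checks. The fixtures declare annealing optima rather
than computing them from sequence, and assume ideal stocks; passing tests
therefore validate planning arithmetic and bookkeeping, not primer design or
wet-lab yields.

## Numerical and determinism choices

Comparisons on the gradient grid use integer deci-degrees to avoid float
drift; zone temperatures are reported rounded to 0.1 °C but deviations are
computed unrounded. All placement is deterministic (column-major fill,
bundle order, 1-based columns), identifiers are case-sensitive and trimmed,
files are UTF-8 with comma delimiters only, and every rendered artifact is
byte-identical across runs on the same input; the full effective
configuration is embedded in `runbundle.json`, and rebuilding from that
snapshot reproduces the artifacts byte-for-byte.

## Problem sizes

Tests and the acceptance script run at desk scale: gradient properties over
100 seeded designs of 2–12 reactions, end-to-end runs on the 7-PCR /
4-construct fixture, and brute-force oracle comparisons on ≤ 8 reactions —
sizes chosen to match the structures the workflows are designed around while
keeping the whole suite interactive.

## Known limitations

No PCR-yield or kinetics modeling (the equal-yield assumption replaces
measurement); no primer design or melting-temperature computation from
sequence; no vendor robot driver — the emission target is the neutral JSON
run bundle and picklist CSV; no magnetic-bead cleanup or transformation
automation; the 34-vs-36 cycle choice and gradient orientation are exposed
as configuration because no selection rule is defined.
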