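"""Deterministic synthetic design files with ground-truth manifests.

Stands in for the output of an upstream combinatorial design tool in every
test: same seed, byte-identical file.  Sequences are random A/C/G/T filler and
annealing optima are declared, not computed from sequence — the fixtures
exercise the planner, not primer design.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np

from .design import (
    CAPACITY_LIMIT,
    AssemblyPiece,
    Combination,
    DesignBundle,
    Oligo,
    PcrSpec,
    PieceKind,
    Strategy,
    write_design,
)

__all__ = ["FixtureSpec", "FixtureError", "generate_design", "generate_bundle",
           "chromoprotein_like_fixture"]


class FixtureError(Exception):
    """Raised when a fixture spec cannot yield a valid design."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic combinatorial design.

    ``delta_policy``: ``all_default`` leaves every reaction's delta blank (the
    planner default tolerance applies); ``mixed`` gives half the reactions a
    rigid 0.2 °C delta and half a loose 1.0 °C one, exercising the
    tighter-than-default branch of the gradient planner.
    """

    n_assemblies: int = 4
    fragments_per_assembly: int = 4
    ta_range: tuple[float, float] = (58.0, 66.0)
    length_range: tuple[int, int] = (500, 5000)
    delta_policy: str = "all_default"
    seed: int = 0
    strategy: Strategy = Strategy.PCR_ONLY

    def __post_init__(self) -> None:
        if self.n_assemblies < 1 or self.fragments_per_assembly < 2:
            raise FixtureError("need >= 1 assembly of >= 2 fragments")
        lo, hi = self.ta_range
        if not (50.0 <= lo <= hi <= 75.0):
            raise FixtureError("ta_range must lie within [50, 75] °C")
        lmin, lmax = self.length_range
        if not (100 <= lmin <= lmax <= 10000):
            raise FixtureError("length_range must lie within [100, 10000] bp")
        if self.delta_policy not in ("all_default", "mixed"):
            raise FixtureError(f"unknown delta_policy {self.delta_policy!r}")


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def generate_bundle(spec: FixtureSpec) -> DesignBundle:
    """Build the in-memory bundle a :class:`FixtureSpec` describes."""
    rng = np.random.default_rng(spec.seed)
    n_pcr = spec.n_assemblies * spec.fragments_per_assembly
    n_templates = n_pcr  # one template per fragment PCR
    if 2 * n_pcr + n_templates > CAPACITY_LIMIT:
        raise FixtureError(
            f"{2 * n_pcr} primers + {n_templates} templates exceeds the "
            f"{CAPACITY_LIMIT}-item capacity"
        )
    kind = (
        PieceKind.GOLDEN_GATE
        if spec.strategy == Strategy.GOLDEN_GATE
        else PieceKind.HOMOLOGY
    )
    oligos: list[Oligo] = []
    pcrs: list[PcrSpec] = []
    pieces: list[AssemblyPiece] = []
    combinations: list[Combination] = []
    lmin, lmax = spec.length_range
    for a in range(spec.n_assemblies):
        ids = []
        for f in range(spec.fragments_per_assembly):
            k = a * spec.fragments_per_assembly + f + 1
            ta = round(float(rng.uniform(*spec.ta_range)), 1)
            length = int(rng.integers(lmin, lmax + 1))
            fwd = Oligo(f"oligo_{2 * k - 1}", _random_seq(rng, 20), ta)
            rev = Oligo(f"oligo_{2 * k}", _random_seq(rng, 20), ta)
            oligos += [fwd, rev]
            if spec.delta_policy == "mixed":
                delta = 0.2 if k % 2 == 1 else 1.0
            else:
                delta = None
            pcrs.append(
                PcrSpec(
                    id=k,
                    template_name=f"template_{k}",
                    fwd_oligo=fwd.name,
                    rev_oligo=rev.name,
                    product_length=length,
                    ta_opt=ta,
                    delta=delta,
                    note=f"frag_{k}",
                )
            )
            pieces.append(AssemblyPiece(id=k, source_pcr=k, length=length, piece_kind=kind))
            ids.append(k)
        combinations.append(Combination(f"construct_{a + 1}", tuple(ids)))
    return DesignBundle(oligos, pcrs, pieces, combinations, spec.strategy)


def _manifest(spec: FixtureSpec, bundle: DesignBundle) -> dict[str, Any]:
    return {
        "spec": {**dataclasses.asdict(spec), "strategy": spec.strategy.value},
        "seed": spec.seed,
        "oligos": [dataclasses.asdict(o) for o in bundle.oligos],
        "pcrs": [dataclasses.asdict(p) for p in bundle.pcrs],
        "pieces": [
            {**dataclasses.asdict(p), "piece_kind": p.piece_kind.value}
            for p in bundle.pieces
        ],
        "combinations": [
            {"construct_name": c.construct_name, "piece_ids": list(c.piece_ids)}
            for c in bundle.combinations
        ],
    }


def generate_design(spec: FixtureSpec, out_dir: str | Path) -> tuple[Path, dict[str, Any]]:
    """Write a parseable synthetic design file plus its ground-truth manifest.

    Returns the design-file path and a manifest dict recording every generated
    value (also written next to the design as ``design_manifest.json``).
    Identical specs produce byte-identical files.
    """
    bundle = generate_bundle(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design_path = write_design(bundle, out / "design.csv")
    manifest = _manifest(spec, bundle)
    (out / "design_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return design_path, manifest


# Chromoprotein-panel-style wiring: pieces 2, 5 and 6 are shared
# backbone/selection parts, pieces 1, 3, 4 and 7 are the color-specific parts;
# each of the four constructs = one color part + the three backbone parts.
_CHROMO_COLOR_PIECES = (1, 3, 4, 7)
_CHROMO_BACKBONE_PIECES = (2, 5, 6)


def chromoprotein_like_fixture(
    out_dir: str | Path, strategy: Strategy = Strategy.GOLDEN_GATE
) -> tuple[Path, dict[str, Any]]:
    """Four 4-piece constructs sharing three backbone pieces across 7 PCRs.

    Mirrors a four-plasmid chromoprotein panel: seven amplified fragments, of
    which three (backbone, marker, origin) are reused by every construct and
    four carry the construct-specific coding sequence.
    """
    rng = np.random.default_rng(20220907)
    kind = (
        PieceKind.GOLDEN_GATE
        if strategy == Strategy.GOLDEN_GATE
        else PieceKind.HOMOLOGY
    )
    tas = [60.1, 59.4, 61.0, 60.5, 64.7, 58.9, 60.8]  # piece 5 runs hot
    lengths = [720, 2200, 710, 695, 1450, 980, 705]
    oligos: list[Oligo] = []
    pcrs: list[PcrSpec] = []
    pieces: list[AssemblyPiece] = []
    for k in range(1, 8):
        ta, length = tas[k - 1], lengths[k - 1]
        fwd = Oligo(f"oligo_{2 * k - 1}", _random_seq(rng, 20), ta)
        rev = Oligo(f"oligo_{2 * k}", _random_seq(rng, 20), ta)
        oligos += [fwd, rev]
        pcrs.append(
            PcrSpec(
                id=k,
                template_name=f"template_{k}",
                fwd_oligo=fwd.name,
                rev_oligo=rev.name,
                product_length=length,
                ta_opt=ta,
                note=f"frag_{k}",
            )
        )
        pieces.append(AssemblyPiece(id=k, source_pcr=k, length=length, piece_kind=kind))
    combinations = [
        Combination(f"construct_{i + 1}", (color, *_CHROMO_BACKBONE_PIECES))
        for i, color in enumerate(_CHROMO_COLOR_PIECES)
    ]
    bundle = DesignBundle(oligos, pcrs, pieces, combinations, strategy)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design_path = write_design(bundle, out / "design.csv")
    spec = FixtureSpec(n_assemblies=4, fragments_per_assembly=4, seed=20220907,
                       strategy=strategy)
    manifest = _manifest(spec, bundle)
    (out / "design_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return design_path, manifest
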