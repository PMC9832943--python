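"""Data model and parser for combinatorial assembly design files.

The input dialect is a single UTF-8 CSV with four named sections — primer
synthesis, PCR reactions, assembly pieces, and piece combinations — the tables
a combinatorial design tool emits to specify how a set of constructs is built
from PCR-amplified fragments.  The parser splits the file into four typed
tables, validates cross-references and the 96-item primer+template capacity,
and can write the tables back out as per-stage CSVs.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Strategy",
    "Oligo",
    "PcrSpec",
    "AssemblyPiece",
    "Combination",
    "DesignBundle",
    "ValidationReport",
    "DesignError",
    "ParseError",
    "CrossReferenceError",
    "parse_design",
    "write_design",
    "write_section_tables",
    "read_section_tables",
    "validate_design",
    "CAPACITY_LIMIT",
]

#: maximum combined count of distinct primers and templates per run
CAPACITY_LIMIT = 96

SECTION_OLIGOS = "Oligo Synthesis"
SECTION_PCRS = "PCR Reactions"
SECTION_PIECES = "Assembly Pieces"
SECTION_COMBINATIONS = "Combinations of Assembly Pieces"
SECTIONS = (SECTION_OLIGOS, SECTION_PCRS, SECTION_PIECES, SECTION_COMBINATIONS)

OLIGO_COLUMNS = ["Name", "Sequence", "Anneal Tm (C)", "Cost"]
PCR_COLUMNS = [
    "ID", "Template", "Forward Oligo", "Reverse Oligo",
    "Product Length (bp)", "Mean Anneal Tm (C)", "Delta (C)", "Note",
]
PIECE_COLUMNS = ["ID", "Source PCR", "Length (bp)", "Kind"]
COMBINATION_COLUMNS = ["Construct", "Piece IDs"]


class DesignError(Exception):
    """Base class for design-file problems."""


class ParseError(DesignError):
    """Raised when a design file is structurally invalid."""


class CrossReferenceError(DesignError):
    """Raised when a record references an identifier that does not resolve."""


class Strategy(str, enum.Enum):
    """Assembly strategy the downstream workflow should implement."""

    PCR_ONLY = "pcr_only"
    GOLDEN_GATE = "golden_gate"
    IVA_ONEPOT = "iva_onepot"
    AQUA = "aqua"


class PieceKind(str, enum.Enum):
    GOLDEN_GATE = "golden_gate"
    HOMOLOGY = "homology"


@dataclass(frozen=True)
class Oligo:
    """A synthesized primer with the annealing optimum of its 3' portion."""

    name: str
    sequence: str
    anneal_tm: float
    cost: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("oligo name must be non-empty")
        if not self.sequence:
            raise ValueError(f"oligo {self.name!r}: sequence must be non-empty")
        if not (30.0 <= self.anneal_tm <= 80.0):
            raise ValueError(
                f"oligo {self.name!r}: anneal_tm {self.anneal_tm} outside [30, 80] °C"
            )


@dataclass(frozen=True)
class PcrSpec:
    """One PCR: a template amplified with a forward/reverse primer pair.

    ``ta_opt`` is the reaction's optimal annealing temperature (the mean of the
    two primers' annealing optima when not given explicitly).  ``delta`` is the
    tolerable variance from that optimum for this reaction; ``None`` means the
    planner's default tolerance applies.
    """

    id: int
    template_name: str
    fwd_oligo: str
    rev_oligo: str
    product_length: int
    ta_opt: float
    delta: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.product_length <= 0:
            raise ValueError(f"PCR {self.id}: product length must be positive")
        if self.delta is not None and self.delta < 0:
            raise ValueError(f"PCR {self.id}: delta must be >= 0")


@dataclass(frozen=True)
class AssemblyPiece:
    """An assembly fragment produced by one PCR."""

    id: int
    source_pcr: int
    length: int
    piece_kind: PieceKind


@dataclass(frozen=True)
class Combination:
    """An ordered set of pieces assembled into one construct."""

    construct_name: str
    piece_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.piece_ids) < 2:
            raise ValueError(
                f"construct {self.construct_name!r}: needs at least 2 pieces"
            )


@dataclass
class DesignBundle:
    """The four parsed design tables plus the selected assembly strategy."""

    oligos: list[Oligo]
    pcrs: list[PcrSpec]
    pieces: list[AssemblyPiece]
    combinations: list[Combination]
    strategy: Strategy = Strategy.PCR_ONLY

    def oligo_by_name(self, name: str) -> Oligo:
        for o in self.oligos:
            if o.name == name:
                return o
        raise CrossReferenceError(f"unknown oligo {name!r}")

    def pcr_by_id(self, pcr_id: int) -> PcrSpec:
        for p in self.pcrs:
            if p.id == pcr_id:
                return p
        raise CrossReferenceError(f"unknown PCR id {pcr_id}")

    def piece_by_id(self, piece_id: int) -> AssemblyPiece:
        for p in self.pieces:
            if p.id == piece_id:
                return p
        raise CrossReferenceError(f"unknown piece id {piece_id}")

    @property
    def template_names(self) -> list[str]:
        """Distinct template names in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.pcrs:
            seen.setdefault(p.template_name, None)
        return list(seen)

    @property
    def capacity_count(self) -> int:
        """Combined count of distinct primers and distinct templates."""
        return len({o.name for o in self.oligos}) + len(set(self.template_names))


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_design`: never raised, always reported."""

    violations: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, code: str, message: str) -> None:
        self.violations.append((code, message))

    def codes(self) -> set[str]:
        return {code for code, _ in self.violations}


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _split_sections(rows: list[list[str]]) -> dict[str, list[list[str]]]:
    sections: dict[str, list[list[str]]] = {}
    current: list[list[str]] | None = None
    for row in rows:
        stripped = [c.strip() for c in row]
        head = stripped[0] if stripped else ""
        if head in SECTIONS and all(not c for c in stripped[1:]):
            current = sections.setdefault(head, [])
            continue
        if current is not None and any(stripped):
            current.append(stripped)
    return sections


def _float_or_none(cell: str) -> float | None:
    return float(cell) if cell.strip() else None


def _section_records(
    sections: dict[str, list[list[str]]], name: str, columns: Sequence[str]
) -> list[dict[str, str]]:
    if name not in sections or not sections[name]:
        raise ParseError(name)
    header, *data = sections[name]
    if header[: len(columns)] != list(columns):
        raise ParseError(f"{name}: expected columns {list(columns)}, got {header}")
    if not data:
        raise ParseError(name)
    records = []
    for row in data:
        row = row + [""] * (len(columns) - len(row))
        records.append({col: row[i] for i, col in enumerate(columns)})
    return records


def parse_design(file_path: str | Path, strategy: Strategy | str = Strategy.PCR_ONLY) -> DesignBundle:
    """Parse a single-file combinatorial design into a :class:`DesignBundle`.

    The file must contain all four named sections, each with its column-header
    row and at least one data row.  Identifiers are case-sensitive and trimmed
    of surrounding whitespace; only comma delimiters are accepted.

    Raises
    ------
    ParseError
        If a section is missing or empty, or a header row is malformed.
    CrossReferenceError
        If a record references an unknown oligo, template, PCR or piece.
    """
    strategy = Strategy(strategy)
    path = Path(file_path)
    sample = path.read_text(encoding="utf-8")
    first = sample.splitlines()[0] if sample.splitlines() else ""
    if ";" in first and "," not in first:
        raise ParseError("semicolon-delimited files are not accepted; use commas")
    rows = list(csv.reader(sample.splitlines()))
    sections = _split_sections(rows)

    oligos = [
        Oligo(
            name=r["Name"],
            sequence=r["Sequence"],
            anneal_tm=float(r["Anneal Tm (C)"]),
            cost=_float_or_none(r["Cost"]),
        )
        for r in _section_records(sections, SECTION_OLIGOS, OLIGO_COLUMNS)
    ]
    names = [o.name for o in oligos]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ParseError(f"duplicate oligo names: {dupes}")
    oligo_tm = {o.name: o.anneal_tm for o in oligos}

    pcrs = []
    for r in _section_records(sections, SECTION_PCRS, PCR_COLUMNS):
        fwd, rev = r["Forward Oligo"], r["Reverse Oligo"]
        for ref in (fwd, rev):
            if ref not in oligo_tm:
                raise CrossReferenceError(f"PCR {r['ID']}: unknown oligo {ref!r}")
        ta = _float_or_none(r["Mean Anneal Tm (C)"])
        if ta is None:
            ta = (oligo_tm[fwd] + oligo_tm[rev]) / 2.0
        pcrs.append(
            PcrSpec(
                id=int(r["ID"]),
                template_name=r["Template"],
                fwd_oligo=fwd,
                rev_oligo=rev,
                product_length=int(r["Product Length (bp)"]),
                ta_opt=ta,
                delta=_float_or_none(r["Delta (C)"]),
                note=r["Note"],
            )
        )
    pcr_ids = {p.id for p in pcrs}

    pieces = []
    for r in _section_records(sections, SECTION_PIECES, PIECE_COLUMNS):
        src = int(r["Source PCR"])
        if src not in pcr_ids:
            raise CrossReferenceError(f"piece {r['ID']}: unknown source PCR {src}")
        pieces.append(
            AssemblyPiece(
                id=int(r["ID"]),
                source_pcr=src,
                length=int(r["Length (bp)"]),
                piece_kind=PieceKind(r["Kind"]),
            )
        )
    piece_ids = {p.id for p in pieces}

    combinations = []
    for r in _section_records(sections, SECTION_COMBINATIONS, COMBINATION_COLUMNS):
        ids = tuple(int(tok) for tok in r["Piece IDs"].split(";") if tok.strip())
        for pid in ids:
            if pid not in piece_ids:
                raise CrossReferenceError(
                    f"construct {r['Construct']!r}: unknown piece id {pid}"
                )
        combinations.append(Combination(construct_name=r["Construct"], piece_ids=ids))

    return DesignBundle(oligos, pcrs, pieces, combinations, strategy)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _fmt(value: object) -> str:
    # str() on floats is the shortest exact repr, so writes parse back bit-equal
    return "" if value is None else str(value)


def _oligo_rows(bundle: DesignBundle) -> Iterable[list[str]]:
    for o in bundle.oligos:
        yield [o.name, o.sequence, _fmt(o.anneal_tm), _fmt(o.cost)]


def _pcr_rows(bundle: DesignBundle) -> Iterable[list[str]]:
    for p in bundle.pcrs:
        yield [
            _fmt(p.id), p.template_name, p.fwd_oligo, p.rev_oligo,
            _fmt(p.product_length), _fmt(p.ta_opt), _fmt(p.delta), p.note,
        ]


def _piece_rows(bundle: DesignBundle) -> Iterable[list[str]]:
    for p in bundle.pieces:
        yield [_fmt(p.id), _fmt(p.source_pcr), _fmt(p.length), p.piece_kind.value]


def _combination_rows(bundle: DesignBundle) -> Iterable[list[str]]:
    for c in bundle.combinations:
        yield [c.construct_name, ";".join(str(i) for i in c.piece_ids)]


def write_design(bundle: DesignBundle, file_path: str | Path) -> Path:
    """Write a bundle back to the single-file design dialect."""
    path = Path(file_path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        for section, columns, rows in (
            (SECTION_OLIGOS, OLIGO_COLUMNS, _oligo_rows(bundle)),
            (SECTION_PCRS, PCR_COLUMNS, _pcr_rows(bundle)),
            (SECTION_PIECES, PIECE_COLUMNS, _piece_rows(bundle)),
            (SECTION_COMBINATIONS, COMBINATION_COLUMNS, _combination_rows(bundle)),
        ):
            w.writerow([section])
            w.writerow(columns)
            w.writerows(rows)
    return path


_SECTION_FILES = {
    "oligo.csv": (OLIGO_COLUMNS, _oligo_rows),
    "pcr.csv": (PCR_COLUMNS, _pcr_rows),
    "assembly.csv": (PIECE_COLUMNS, _piece_rows),
    "combinations.csv": (COMBINATION_COLUMNS, _combination_rows),
}


def write_section_tables(bundle: DesignBundle, out_dir: str | Path) -> list[Path]:
    """Split a bundle into the four per-stage CSVs.

    Writes ``oligo.csv``, ``pcr.csv``, ``assembly.csv`` and
    ``combinations.csv`` into *out_dir*, preserving file order.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for fname, (columns, rowgen) in _SECTION_FILES.items():
        p = out / fname
        with p.open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(columns)
            w.writerows(rowgen(bundle))
        paths.append(p)
    return paths


def read_section_tables(in_dir: str | Path, strategy: Strategy | str = Strategy.PCR_ONLY) -> DesignBundle:
    """Reassemble a bundle from the four per-stage CSVs (inverse of
    :func:`write_section_tables`)."""
    in_dir = Path(in_dir)
    lines: list[str] = []
    for fname, section in (
        ("oligo.csv", SECTION_OLIGOS),
        ("pcr.csv", SECTION_PCRS),
        ("assembly.csv", SECTION_PIECES),
        ("combinations.csv", SECTION_COMBINATIONS),
    ):
        path = in_dir / fname
        if not path.exists():
            raise ParseError(section)
        lines.append(section)
        lines.append(path.read_text(encoding="utf-8").rstrip("\n"))
    import tempfile

    with tempfile.NamedTemporaryFile(
        "w", suffix=".csv", delete=False, encoding="utf-8"
    ) as fh:
        fh.write("\n".join(lines) + "\n")
        tmp = fh.name
    try:
        return parse_design(tmp, strategy)
    finally:
        Path(tmp).unlink(missing_ok=True)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_design(bundle: DesignBundle) -> ValidationReport:
    """Check design integrity; reports violations rather than raising.

    Violation codes: ``capacity`` (more than 96 combined distinct primers and
    templates), ``reference`` (dangling cross-reference), ``length``
    (nonpositive product or piece length, or piece/PCR length mismatch),
    ``delta`` (negative tolerance), ``orphan`` (piece in no combination),
    ``ta_opt`` (optimum outside its primer pair's range).
    """
    report = ValidationReport()
    if bundle.capacity_count > CAPACITY_LIMIT:
        report.add(
            "capacity",
            f"{bundle.capacity_count} combined primers+templates exceeds {CAPACITY_LIMIT}",
        )
    oligo_names = {o.name for o in bundle.oligos}
    pcr_by_id = {p.id: p for p in bundle.pcrs}
    for p in bundle.pcrs:
        for ref in (p.fwd_oligo, p.rev_oligo):
            if ref not in oligo_names:
                report.add("reference", f"PCR {p.id}: unknown oligo {ref!r}")
        if p.product_length <= 0:
            report.add("length", f"PCR {p.id}: nonpositive product length")
        if p.delta is not None and p.delta < 0:
            report.add("delta", f"PCR {p.id}: negative delta")
        tms = [
            bundle.oligo_by_name(ref).anneal_tm
            for ref in (p.fwd_oligo, p.rev_oligo)
            if ref in oligo_names
        ]
        if len(tms) == 2 and not (min(tms) - 1e-9 <= p.ta_opt <= max(tms) + 1e-9):
            report.add("ta_opt", f"PCR {p.id}: ta_opt {p.ta_opt} outside primer range")
    piece_ids = set()
    for piece in bundle.pieces:
        piece_ids.add(piece.id)
        src = pcr_by_id.get(piece.source_pcr)
        if src is None:
            report.add("reference", f"piece {piece.id}: unknown source PCR {piece.source_pcr}")
        elif piece.length != src.product_length:
            report.add(
                "length",
                f"piece {piece.id}: length {piece.length} != PCR product {src.product_length}",
            )
        if piece.length <= 0:
            report.add("length", f"piece {piece.id}: nonpositive length")
    referenced: set[int] = set()
    for combo in bundle.combinations:
        for pid in combo.piece_ids:
            referenced.add(pid)
            if pid not in piece_ids:
                report.add(
                    "reference",
                    f"construct {combo.construct_name!r}: unknown piece id {pid}",
                )
    for pid in sorted(piece_ids - referenced):
        report.add("orphan", f"piece {pid} not used by any combination")
    return report
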