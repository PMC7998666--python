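"""Readers and writers for structures, IQA tables and thermochemistry.

The toolkit consumes post-processed quantum-chemistry output: Cartesian
structures (standard XYZ), per-atom QTAIM properties (net atomic charge
``Q(A)`` in e, optional atomic self-energy), unordered pairwise IQA
interaction energies (``Vcl``, ``VXC``), and per-structure thermochemistry
(E, E_ZPVE, H, G at a temperature T). Native carriers are comma-delimited
UTF-8 text with a required header; a simplified AIMAll-``.sum``-style dialect
(two fixed-header sections, energies in hartree) is also read. All energies
are converted to kcal/mol on input.

Atom labels are element symbol + 1-based serial ("Li27", "C28"); comparison
is case-sensitive on that canonical form. Pairs are stored once under a
canonical ordering (lexicographic by element symbol, then serial) so lookup
of (A, B) and (B, A) returns the identical record.
"""

from __future__ import annotations

import csv
import io
import math
import re
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Mapping

from .errors import IntegrityError, ParseError, ResolutionError, UsageError
from .units import canonical_unit, convert_units

__all__ = [
    "Atom",
    "Structure",
    "AtomRecord",
    "AtomTable",
    "PairTable",
    "ThermoRecord",
    "Snapshot",
    "parse_label",
    "canonical_pair",
    "read_xyz",
    "write_xyz",
    "read_pair_table",
    "write_pair_table",
    "read_atom_table",
    "write_atom_table",
    "read_aimall_sum",
    "read_energy_summary",
    "write_energy_summary",
]

# IUPAC element symbols, H..Og.
ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni "
    "Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I "
    "Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt "
    "Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No Lr "
    "Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og".split()
)

_LABEL_RE = re.compile(r"^([A-Z][a-z]?)([1-9][0-9]*)$")


def parse_label(label: str) -> tuple[str, int]:
    """Split an atom label like ``"Li27"`` into ``("Li", 27)``.

    Raises :class:`ParseError` for anything that is not an element symbol
    followed by a 1-based serial.
    """
    m = _LABEL_RE.match(label)
    if m is None or m.group(1) not in ELEMENTS:
        raise ParseError(f"invalid atom label {label!r} (expected e.g. 'Li27')")
    return m.group(1), int(m.group(2))


def make_label(element: str, serial: int) -> str:
    return f"{element}{serial}"


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical storage order of an unordered pair: by (element, serial)."""
    if a == b:
        raise UsageError(f"self-pair {a!r} is not a valid interaction pair")
    ka, kb = parse_label(a), parse_label(b)
    return (a, b) if ka <= kb else (b, a)


@dataclass(frozen=True)
class Atom:
    serial: int
    element: str
    x: float
    y: float
    z: float

    @property
    def label(self) -> str:
        return make_label(self.element, self.serial)

    @property
    def position(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class Structure:
    """An ordered Cartesian structure; serials are contiguous from 1."""

    label: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        for i, atom in enumerate(self.atoms, start=1):
            if atom.serial != i:
                raise IntegrityError(
                    f"structure {self.label!r}: atom serial {atom.serial} at "
                    f"position {i}; serials must be contiguous from 1"
                )
            if atom.element not in ELEMENTS:
                raise IntegrityError(f"unknown element symbol {atom.element!r}")
            if not all(math.isfinite(v) for v in atom.position):
                raise IntegrityError(f"non-finite coordinate on atom {atom.label}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def labels(self) -> list[str]:
        return [a.label for a in self.atoms]

    def atom(self, label: str) -> Atom:
        for a in self.atoms:
            if a.label == label:
                return a
        raise ResolutionError(f"structure {self.label!r} has no atom {label!r}")


@dataclass(frozen=True)
class AtomRecord:
    element: str
    charge: float  # net atomic charge Q(A), in e
    self_energy: float | None = None  # atomic self-energy, kcal/mol


class AtomTable:
    """Per-atom QTAIM properties keyed by canonical atom label."""

    def __init__(self, records: Mapping[str, AtomRecord] | None = None):
        self._records: dict[str, AtomRecord] = {}
        if records:
            for label, rec in records.items():
                self.add(label, rec)

    def add(self, label: str, record: AtomRecord) -> None:
        element, _ = parse_label(label)
        if element != record.element:
            raise IntegrityError(
                f"label {label!r} does not match element {record.element!r}"
            )
        if label in self._records:
            raise IntegrityError(f"duplicate atom label {label!r}")
        self._records[label] = record

    def charge(self, label: str) -> float:
        try:
            return self._records[label].charge
        except KeyError:
            raise ResolutionError(f"no atom {label!r} in atom table") from None

    def __getitem__(self, label: str) -> AtomRecord:
        try:
            return self._records[label]
        except KeyError:
            raise ResolutionError(f"no atom {label!r} in atom table") from None

    def __contains__(self, label: str) -> bool:
        return label in self._records

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[str]:
        return iter(self._records)

    @property
    def labels(self) -> set[str]:
        return set(self._records)

    def items(self) -> Iterable[tuple[str, AtomRecord]]:
        return self._records.items()


@dataclass(frozen=True)
class PairRecord:
    """One unordered pair's IQA interaction energy components, kcal/mol."""

    vcl: float  # classical (coulombic) component
    vxc: float  # exchange-correlation (covalent) component

    @property
    def total(self) -> float:
        return self.vcl + self.vxc


class PairTable:
    """Unordered atom-pair map to (Vcl, VXC); the raw IQA interaction matrix.

    Each unordered pair is stored exactly once under the canonical ordering;
    lookups with either argument order return the identical record.
    """

    def __init__(self) -> None:
        self._pairs: dict[tuple[str, str], PairRecord] = {}

    def add(self, a: str, b: str, vcl: float, vxc: float) -> None:
        key = canonical_pair(a, b)
        existing = self._pairs.get(key)
        rec = PairRecord(vcl, vxc)
        if existing is not None:
            if existing == rec:
                return  # exact duplicate, deduplicate silently
            raise IntegrityError(
                f"conflicting duplicate pair {key}: {existing} vs {rec}"
            )
        self._pairs[key] = rec

    def get(self, a: str, b: str) -> PairRecord:
        try:
            return self._pairs[canonical_pair(a, b)]
        except KeyError:
            raise ResolutionError(f"no pair ({a}, {b}) in pair table") from None

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return canonical_pair(a, b) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)

    def items(self) -> Iterable[tuple[tuple[str, str], PairRecord]]:
        return self._pairs.items()

    @property
    def labels(self) -> set[str]:
        out: set[str] = set()
        for a, b in self._pairs:
            out.add(a)
            out.add(b)
        return out

    def total_sum(self, term: str = "total") -> float:
        """Sum of one term over the whole table, each pair counted once."""
        if term == "cl":
            return sum(r.vcl for r in self._pairs.values())
        if term == "xc":
            return sum(r.vxc for r in self._pairs.values())
        if term == "total":
            return sum(r.total for r in self._pairs.values())
        raise UsageError(f"unknown term {term!r}; expected cl, xc or total")


#: Reaction-profile energy terms, in native reporting order.
THERMO_TERMS = ("E", "E_ZPVE", "H", "G")


@dataclass
class ThermoRecord:
    """One structure's thermochemistry: E, E_ZPVE, H, G in kcal/mol at T (K).

    A term may be None to mark it explicitly absent (e.g. electronic-only
    records), but a record must carry at least one term.
    """

    label: str
    E: float | None = None
    E_ZPVE: float | None = None
    H: float | None = None
    G: float | None = None
    T: float = 298.15

    def __post_init__(self) -> None:
        if all(getattr(self, t) is None for t in THERMO_TERMS):
            raise IntegrityError(f"thermo record {self.label!r} has no energy terms")
        if not self.T > 0:
            raise IntegrityError(f"thermo record {self.label!r}: T must be > 0 K")

    def term(self, name: str) -> float | None:
        if name not in THERMO_TERMS:
            raise UsageError(f"unknown thermo term {name!r}; expected {THERMO_TERMS}")
        return getattr(self, name)


@dataclass
class Snapshot:
    """One structure's complete record along a mechanism.

    Any component may be absent, but at least one must be present, and when
    both a pair table and an atom table are given every pair label must exist
    in the atom table.
    """

    label: str
    structure: Structure | None = None
    atom_table: AtomTable | None = None
    pair_table: PairTable | None = None
    thermo: ThermoRecord | None = None

    def __post_init__(self) -> None:
        if (
            self.structure is None
            and self.atom_table is None
            and self.pair_table is None
            and self.thermo is None
        ):
            raise IntegrityError(f"snapshot {self.label!r} has no components")
        if self.pair_table is not None and self.atom_table is not None:
            missing = self.pair_table.labels - self.atom_table.labels
            if missing:
                raise IntegrityError(
                    f"snapshot {self.label!r}: pair-table labels missing from "
                    f"atom table: {sorted(missing)}"
                )


# ---------------------------------------------------------------------------
# XYZ


def read_xyz(stream: IO[str] | str) -> Structure:
    """Read one standard XYZ block (count line, comment line, atom lines).

    The comment line becomes the structure label when non-empty.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = stream.read().splitlines()
    if not lines:
        raise ParseError("empty XYZ input")
    try:
        count = int(lines[0].strip())
    except ValueError:
        raise ParseError(f"line 1: expected atom count, got {lines[0]!r}") from None
    comment = lines[1].strip() if len(lines) > 1 else ""
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) != count:
        raise ParseError(
            f"XYZ count mismatch: header says {count} atoms, found {len(body)} "
            f"atom lines (starting line 3)"
        )
    atoms: list[Atom] = []
    for i, line in enumerate(body, start=1):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"line {i + 2}: expected 'element x y z', got {line!r}")
        element = parts[0]
        try:
            x, y, z = (float(v) for v in parts[1:4])
        except ValueError:
            raise ParseError(f"line {i + 2}: non-numeric coordinate in {line!r}") from None
        atoms.append(Atom(i, element, x, y, z))
    return Structure(label=comment or "structure", atoms=atoms)


def write_xyz(structure: Structure, stream: IO[str] | None = None) -> str:
    """Write a structure as standard XYZ; returns the text."""
    lines = [str(len(structure)), structure.label]
    for a in structure.atoms:
        lines.append(f"{a.element} {a.x:.10f} {a.y:.10f} {a.z:.10f}")
    text = "\n".join(lines) + "\n"
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# Native delimited tables


def _csv_rows(stream: IO[str] | str, required: tuple[str, ...], what: str):
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    reader = csv.DictReader(stream)
    if reader.fieldnames is None:
        return  # empty body -> no rows
    fields = [f.strip() for f in reader.fieldnames]
    missing = [c for c in required if c not in fields]
    if missing:
        raise ParseError(f"{what}: missing required column(s) {missing}; header {fields}")
    for lineno, row in enumerate(reader, start=2):
        yield lineno, {(k.strip() if k else k): (v.strip() if v else v) for k, v in row.items()}


def read_pair_table(stream: IO[str] | str, units: str = "kcal/mol") -> PairTable:
    """Read a native pairs table (columns A, B, Vcl, VXC) into kcal/mol.

    Rows listing both (A, B) and (B, A) with identical values are
    deduplicated; differing values raise :class:`IntegrityError`.
    """
    unit = canonical_unit(units)
    table = PairTable()
    for lineno, row in _csv_rows(stream, ("A", "B", "Vcl", "VXC"), "pairs table"):
        try:
            vcl = convert_units(float(row["Vcl"]), unit, "kcal/mol")
            vxc = convert_units(float(row["VXC"]), unit, "kcal/mol")
        except ValueError:
            raise ParseError(f"pairs table line {lineno}: non-numeric energy") from None
        table.add(row["A"], row["B"], vcl, vxc)
    return table


def write_pair_table(table: PairTable, stream: IO[str] | None = None) -> str:
    out = io.StringIO()
    writer = csv.writer(out)
    writer.writerow(["A", "B", "Vcl", "VXC"])
    for (a, b), rec in sorted(table.items(), key=lambda kv: (parse_label(kv[0][0]), parse_label(kv[0][1]))):
        writer.writerow([a, b, repr(rec.vcl), repr(rec.vxc)])
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def read_atom_table(stream: IO[str] | str) -> AtomTable:
    """Read a native atoms table (columns label, element, Q[, E_self])."""
    table = AtomTable()
    for lineno, row in _csv_rows(stream, ("label", "element", "Q"), "atoms table"):
        try:
            q = float(row["Q"])
        except ValueError:
            raise ParseError(f"atoms table line {lineno}: non-numeric charge") from None
        e_self = row.get("E_self")
        self_energy = float(e_self) if e_self not in (None, "") else None
        table.add(row["label"], AtomRecord(row["element"], q, self_energy))
    return table


def write_atom_table(table: AtomTable, stream: IO[str] | None = None) -> str:
    out = io.StringIO()
    writer = csv.writer(out)
    writer.writerow(["label", "element", "Q", "E_self"])
    for label, rec in sorted(table.items(), key=lambda kv: parse_label(kv[0])):
        writer.writerow(
            [label, rec.element, repr(rec.charge), "" if rec.self_energy is None else repr(rec.self_energy)]
        )
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# Simplified AIMAll-.sum-style dialect

_SUM_ATOM_HEADER = "[Atomic Properties]"
_SUM_PAIR_HEADER = "[IQA Pairwise]"


def read_aimall_sum(stream: IO[str] | str) -> tuple[AtomTable, PairTable]:
    """Read the simplified ``.sum`` dialect (energies in hartree).

    The dialect has two sections with fixed bracketed headers::

        [Atomic Properties]
        Atom  q(A)
        Li1   0.9000
        [IQA Pairwise]
        A    B    Vcl        VXC
        Li1  C2   -0.144857  -0.025497

    The pairwise section may be absent (atoms-only files yield an empty pair
    table); the atomic section is mandatory. All energies are converted to
    kcal/mol. This is a documented subset, not the full vendor format.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = stream.read().splitlines()
    atom_table = AtomTable()
    pair_table = PairTable()
    section: str | None = None
    saw_atoms = False
    expect_header = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == _SUM_ATOM_HEADER:
            section, saw_atoms, expect_header = "atoms", True, True
            continue
        if line == _SUM_PAIR_HEADER:
            section, expect_header = "pairs", True
            continue
        if section is None:
            raise ParseError(f"line {lineno}: content before any section header")
        if expect_header:
            expect_header = False  # column-name line, checked loosely
            cols = line.split()
            want = ["Atom", "q(A)"] if section == "atoms" else ["A", "B", "Vcl", "VXC"]
            if cols[: len(want)] != want:
                raise ParseError(
                    f"line {lineno}: bad column header for {section} section: {line!r}"
                )
            continue
        parts = line.split()
        if section == "atoms":
            if len(parts) < 2:
                raise ParseError(f"line {lineno}: malformed atomic record {line!r}")
            label = parts[0]
            element, _ = parse_label(label)
            try:
                q = float(parts[1])
            except ValueError:
                raise ParseError(f"line {lineno}: non-numeric charge {parts[1]!r}") from None
            self_energy = None
            if len(parts) >= 3:
                try:
                    self_energy = convert_units(float(parts[2]), "hartree", "kcal/mol")
                except ValueError:
                    raise ParseError(f"line {lineno}: non-numeric self-energy") from None
            atom_table.add(label, AtomRecord(element, q, self_energy))
        else:
            if len(parts) < 4:
                raise ParseError(f"line {lineno}: malformed pairwise record {line!r}")
            try:
                vcl = convert_units(float(parts[2]), "hartree", "kcal/mol")
                vxc = convert_units(float(parts[3]), "hartree", "kcal/mol")
            except ValueError:
                raise ParseError(f"line {lineno}: non-numeric pair energy") from None
            pair_table.add(parts[0], parts[1], vcl, vxc)
    if not saw_atoms:
        raise ParseError(f"missing mandatory section {_SUM_ATOM_HEADER!r}")
    return atom_table, pair_table


# ---------------------------------------------------------------------------
# Thermochemistry


def read_energy_summary(stream: IO[str] | str) -> list[ThermoRecord]:
    """Read a thermochemistry summary (label, E, E_ZPVE, H, G, T, units).

    Energies are converted to kcal/mol; empty cells mark a term absent.
    """
    records: list[ThermoRecord] = []
    for lineno, row in _csv_rows(
        stream, ("label", "E", "E_ZPVE", "H", "G", "T", "units"), "energy summary"
    ):
        unit = canonical_unit(row["units"])

        def grab(col: str) -> float | None:
            cell = row.get(col)
            if cell in (None, ""):
                return None
            try:
                return convert_units(float(cell), unit, "kcal/mol")
            except ValueError:
                raise ParseError(
                    f"energy summary line {lineno}: non-numeric {col} {cell!r}"
                ) from None

        try:
            temperature = float(row["T"])
        except ValueError:
            raise ParseError(f"energy summary line {lineno}: non-numeric T") from None
        records.append(
            ThermoRecord(
                label=row["label"],
                E=grab("E"),
                E_ZPVE=grab("E_ZPVE"),
                H=grab("H"),
                G=grab("G"),
                T=temperature,
            )
        )
    return records


def write_energy_summary(records: Iterable[ThermoRecord], stream: IO[str] | None = None) -> str:
    out = io.StringIO()
    writer = csv.writer(out)
    writer.writerow(["label", "E", "E_ZPVE", "H", "G", "T", "units"])
    for rec in records:
        writer.writerow(
            [rec.label]
            + ["" if rec.term(t) is None else repr(rec.term(t)) for t in THERMO_TERMS]
            + [repr(rec.T), "kcal/mol"]
        )
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text
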