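"""Named molecular fragments: parsing, validation, and the study library.

A fragment is a named set of atom labels within one snapshot's atom universe.
Fragment specs are comma-separated lists of labels and/or serial ranges
("N1-H15" means every atom with serial 1..15 regardless of element — ranges
run over serial numbers because chemically meaningful fragments such as a
quinoxaline moiety span mixed elements).

The bundled library covers the 2-phenylquinoxaline (molecule 1, serials
1-26) + lithium phenylacetylide (molecule 2, Li27-H40) nucleophilic-addition
study, with an optional water molecule (O41, H42, H43) for the hydrolysis
stage. Machine names are ASCII (Q, Ph1, Bn, P, N, C, L, A, R, Ph2, G1, G2,
F1-F4); the script-letter forms used in print are kept as display aliases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ResolutionError, UsageError
from .iqa_io import make_label, parse_label

__all__ = [
    "Fragment",
    "FragmentSet",
    "Universe",
    "parse_fragment_spec",
    "validate_fragments",
    "quinoxaline_universe",
    "quinoxaline_fragment_library",
    "DISPLAY_ALIASES",
]


class Universe:
    """The atom-label universe of a snapshot: an ordered label <-> serial map."""

    def __init__(self, labels: list[str]):
        self._by_serial: dict[int, str] = {}
        for label in labels:
            _, serial = parse_label(label)
            if serial in self._by_serial:
                raise UsageError(f"duplicate serial {serial} in universe")
            self._by_serial[serial] = label
        self._labels = set(labels)

    @classmethod
    def from_elements(cls, elements_by_serial: dict[int, str]) -> "Universe":
        return cls([make_label(el, s) for s, el in sorted(elements_by_serial.items())])

    def __contains__(self, label: str) -> bool:
        return label in self._labels

    def __len__(self) -> int:
        return len(self._labels)

    @property
    def labels(self) -> set[str]:
        return set(self._labels)

    def label_for_serial(self, serial: int) -> str:
        try:
            return self._by_serial[serial]
        except KeyError:
            raise ResolutionError(f"no atom with serial {serial} in universe") from None


@dataclass(frozen=True)
class Fragment:
    """A named set of atom labels."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        for label in self.members:
            parse_label(label)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, label: str) -> bool:
        return label in self.members

    def spec_string(self) -> str:
        """Explicit (range-free) spec string; stable serial order."""
        return ",".join(sorted(self.members, key=lambda lb: parse_label(lb)[1]))


@dataclass
class FragmentSet:
    """Uniquely named fragments, optionally tied to a declared universe."""

    fragments: dict[str, Fragment] = field(default_factory=dict)
    universe: Universe | None = None

    def add(self, fragment: Fragment) -> None:
        if fragment.name in self.fragments:
            raise UsageError(f"duplicate fragment name {fragment.name!r}")
        self.fragments[fragment.name] = fragment

    def __getitem__(self, name: str) -> Fragment:
        try:
            return self.fragments[name]
        except KeyError:
            raise ResolutionError(f"no fragment named {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.fragments

    def __iter__(self):
        return iter(self.fragments.values())

    def __len__(self) -> int:
        return len(self.fragments)

    @property
    def names(self) -> list[str]:
        return list(self.fragments)


def parse_fragment_spec(text: str, universe: Universe, name: str = "") -> Fragment:
    """Expand a fragment spec string over *universe* into an explicit Fragment.

    Spec grammar: comma-separated items; each item is either an atom label
    ("C2") or a serial range "Xi-Yj" covering every serial i..j inclusive
    regardless of element. Range endpoints must exist in the universe; a
    reversed range (i > j) is a usage error.
    """
    members: set[str] = set()
    for item in (part.strip() for part in text.split(",")):
        if not item:
            continue
        if "-" in item:
            start_s, end_s = (p.strip() for p in item.split("-", 1))
            _, i = parse_label(start_s)
            _, j = parse_label(end_s)
            for endpoint in (start_s, end_s):
                if endpoint not in universe:
                    raise ResolutionError(
                        f"range endpoint {endpoint!r} not in universe"
                    )
            if i > j:
                raise UsageError(f"reversed range {item!r} (serial {i} > {j})")
            for serial in range(i, j + 1):
                members.add(universe.label_for_serial(serial))
        else:
            if item not in universe:
                raise ResolutionError(f"unknown atom label {item!r}")
            members.add(item)
    return Fragment(name=name or text, members=frozenset(members))


@dataclass
class ValidationReport:
    """Result of a disjointness/partition check over a fragment set."""

    mode: str
    overlaps: list[tuple[str, str, frozenset[str]]]
    uncovered: frozenset[str]
    passed: bool

    def __bool__(self) -> bool:
        return self.passed


def validate_fragments(fset: FragmentSet, universe: Universe, mode: str = "disjoint") -> ValidationReport:
    """Check pairwise disjointness and (for partition mode) full coverage.

    mode: "disjoint" — no two fragments share an atom; "partition" —
    additionally every universe atom is covered; "none" — report only.
    """
    if mode not in ("disjoint", "partition", "none"):
        raise UsageError(f"unknown validation mode {mode!r}")
    frags = list(fset)
    overlaps: list[tuple[str, str, frozenset[str]]] = []
    for i, fa in enumerate(frags):
        for fb in frags[i + 1 :]:
            shared = fa.members & fb.members
            if shared:
                overlaps.append((fa.name, fb.name, frozenset(shared)))
    covered: set[str] = set()
    for f in frags:
        covered |= f.members
    uncovered = frozenset(universe.labels - covered)
    if mode == "disjoint":
        passed = not overlaps
    elif mode == "partition":
        passed = not overlaps and not uncovered
    else:
        passed = True
    return ValidationReport(mode=mode, overlaps=overlaps, uncovered=uncovered, passed=passed)


# ---------------------------------------------------------------------------
# Study system: 2-phenylquinoxaline (1) + lithium phenylacetylide (2) [+ H2O]

# Serial -> element for the two reactant molecules. Molecule 1 (serials 1-26):
# the quinoxaline core N1,C2,C3,N4,C5-C10 with ring hydrogens H11-H15 and the
# phenyl substituent at C2, C16-C21/H22-H26. Molecule 2 (27-40): Li27, the
# acetylide carbons C28/C29, and the phenyl ring C30-C35/H36-H40.
_STUDY_ELEMENTS: dict[int, str] = {
    1: "N", 2: "C", 3: "C", 4: "N",
    **{s: "C" for s in range(5, 11)},
    **{s: "H" for s in range(11, 16)},
    **{s: "C" for s in range(16, 22)},
    **{s: "H" for s in range(22, 27)},
    27: "Li", 28: "C", 29: "C",
    **{s: "C" for s in range(30, 36)},
    **{s: "H" for s in range(36, 41)},
}
_WATER_ELEMENTS = {41: "O", 42: "H", 43: "H"}

# name -> (spec string, display alias)
_LIBRARY_SPECS: dict[str, tuple[str, str]] = {
    "Q": ("N1-H15", "\U0001d4ac"),        # quinoxaline moiety of 1
    "Ph1": ("C16-H26", "\U0001d4ab\U0001d4bd1"),  # phenyl substituent at C2
    "Bn": ("C5-C10,H12-H15", "ℬ\U0001d4c3"),  # benzene ring of 1
    "P": ("N1-C5,C10,H11", "\U0001d4ab"),  # pyrazine ring of 1
    "N": ("N1,N4", "\U0001d4dd"),          # the two ring nitrogens
    "C": ("C2,C3,C5,C10", "\U0001d4d2"),   # electrophilic carbons
    "L": ("Li27,C28,C29", "\U0001d4db"),   # Li + acetylide carbons of 2
    "A": ("C28,C29", "\U0001d4d0"),        # acetylide carbons only
    "R": ("C28-H40", "\U0001d4e1"),        # all of 2 except Li
    "Ph2": ("C30-H40", "\U0001d4ab\U0001d4bd2"),  # phenyl ring of 2
    "G1": ("C2,N1,C10", "\U0001d4a21"),    # 3-atom environment around N1
    "G2": ("C3,N4,C5", "\U0001d4a22"),     # 3-atom environment around N4
    "F1": ("N1,C2,C3,C16", "ℱ₁"),
    "F2": ("C2,C3,N4,H11", "ℱ₂"),
    "F3": ("N4,C5,C6,C10", "ℱ₃"),
    "F4": ("C5,C10,C9,N1", "ℱ₄"),
}

#: ASCII machine name -> script-letter display alias.
DISPLAY_ALIASES = {name: alias for name, (_, alias) in _LIBRARY_SPECS.items()}


def quinoxaline_universe(with_water: bool = False) -> Universe:
    """The 40-atom two-reactant universe, optionally extended by water."""
    elements = dict(_STUDY_ELEMENTS)
    if with_water:
        elements.update(_WATER_ELEMENTS)
    return Universe.from_elements(elements)


def quinoxaline_fragment_library(with_water: bool = False) -> FragmentSet:
    """The 16 named fragments of the nucleophilic-addition study system.

    Ranges are expanded to explicit label sets at load time so downstream
    energetics never re-parses range notation.
    """
    universe = quinoxaline_universe(with_water=with_water)
    fset = FragmentSet(universe=universe)
    for name, (spec, _alias) in _LIBRARY_SPECS.items():
        fset.add(parse_fragment_spec(spec, universe, name=name))
    return fset
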