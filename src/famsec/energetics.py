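"""Fragment-attributed IQA energy computations.

The raw input is the unordered pairwise interaction matrix: for every atom
pair {A, B} a classical (coulombic) component Vcl(A,B) and an
exchange-correlation (covalent) component VXC(A,B), whose sum is the total
pair interaction energy. Fragment-level energetics are plain sums over these
pair records, with each unordered pair counted exactly once — no halving or
double counting — which makes interfragment additivity and whole-table
completeness exact identities.

Sign convention: attractive interactions are negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .errors import IntegrityError, ResolutionError, UsageError
from .iqa_io import AtomTable, PairRecord, PairTable, parse_label

__all__ = [
    "InteractionResult",
    "pair_total",
    "interfragment_energy",
    "intrafragment_sum",
    "percent_character",
    "fragment_charge",
    "rank_interactions",
]

TERMS = ("cl", "xc", "total")


def _members(fragment) -> frozenset[str]:
    """Accept a Fragment or any iterable of atom labels."""
    members = getattr(fragment, "members", fragment)
    return frozenset(members)


def _frag_name(fragment, default: str) -> str:
    return getattr(fragment, "name", default)


def pair_total(record: PairRecord | tuple[float, float]) -> float:
    """Total interaction energy of one pair: Vcl + VXC (kcal/mol)."""
    if isinstance(record, PairRecord):
        return record.total
    vcl, vxc = record
    return vcl + vxc


@dataclass(frozen=True)
class InteractionResult:
    """Summed interaction energies between two disjoint fragments (kcal/mol)."""

    fragment_a: str
    fragment_b: str
    vcl_sum: float
    vxc_sum: float
    n_pairs_counted: int

    @property
    def total(self) -> float:
        return self.vcl_sum + self.vxc_sum

    def value(self, term: str = "total") -> float:
        if term == "cl":
            return self.vcl_sum
        if term == "xc":
            return self.vxc_sum
        if term == "total":
            return self.total
        raise UsageError(f"unknown term {term!r}; expected one of {TERMS}")


def interfragment_energy(
    pair_table: PairTable,
    frag_a,
    frag_b,
    term: str = "total",
    strict: bool = False,
) -> InteractionResult:
    """Sum an interaction term over all pairs crossing two disjoint fragments.

    Pairs absent from the table contribute exactly 0 and are excluded from
    ``n_pairs_counted``; with ``strict=True`` an absent crossing pair is an
    integrity error instead (for dense tables where absence means data loss).
    """
    if term not in TERMS:
        raise UsageError(f"unknown term {term!r}; expected one of {TERMS}")
    a = _members(frag_a)
    b = _members(frag_b)
    shared = a & b
    if shared:
        raise UsageError(
            f"fragments {_frag_name(frag_a, 'A')!r} and {_frag_name(frag_b, 'B')!r} "
            f"overlap on {sorted(shared)}"
        )
    vcl = 0.0
    vxc = 0.0
    n = 0
    for (pa, pb), rec in pair_table.items():
        if (pa in a and pb in b) or (pa in b and pb in a):
            vcl += rec.vcl
            vxc += rec.vxc
            n += 1
    if strict and n < len(a) * len(b):
        raise IntegrityError(
            f"strict mode: {len(a) * len(b) - n} crossing pair(s) absent between "
            f"{_frag_name(frag_a, 'A')!r} and {_frag_name(frag_b, 'B')!r}"
        )
    return InteractionResult(
        fragment_a=_frag_name(frag_a, "A"),
        fragment_b=_frag_name(frag_b, "B"),
        vcl_sum=vcl,
        vxc_sum=vxc,
        n_pairs_counted=n,
    )


def intrafragment_sum(pair_table: PairTable, frag, term: str = "xc") -> float:
    """Sum a term over all unordered pairs internal to one fragment.

    The default term is the exchange-correlation component, the natural probe
    of how intact a ring's covalent framework remains along a pathway.
    """
    if term not in TERMS:
        raise UsageError(f"unknown term {term!r}; expected one of {TERMS}")
    members = _members(frag)
    if len(members) < 2:
        raise UsageError(
            f"fragment {_frag_name(frag, '?')!r} needs >= 2 members for an "
            f"intra-fragment sum (got {len(members)})"
        )
    out = 0.0
    for (pa, pb), rec in pair_table.items():
        if pa in members and pb in members:
            out += rec.vcl if term == "cl" else rec.vxc if term == "xc" else rec.total
    return out


def percent_character(record) -> tuple[float, float]:
    """Percent classical vs covalent character of an interaction.

    Accepts a PairRecord, an InteractionResult, or a (Vcl, VXC) tuple and
    returns (100*Vcl/total, 100*VXC/total); the two components sum to 100
    exactly up to rounding. Undefined when the total is zero.
    """
    if isinstance(record, InteractionResult):
        vcl, vxc = record.vcl_sum, record.vxc_sum
    elif isinstance(record, PairRecord):
        vcl, vxc = record.vcl, record.vxc
    else:
        vcl, vxc = record
    total = vcl + vxc
    if total == 0:
        raise UsageError("character undefined: total interaction energy is zero")
    return (100.0 * vcl / total, 100.0 * vxc / total)


def fragment_charge(atom_table: AtomTable, frag) -> float:
    """Net charge of a fragment: sum of Q(A) over its members (e)."""
    members = _members(frag)
    missing = [m for m in members if m not in atom_table]
    if missing:
        raise ResolutionError(
            f"fragment {_frag_name(frag, '?')!r}: member(s) missing from atom "
            f"table: {sorted(missing)}"
        )
    return sum(atom_table.charge(m) for m in members)


def rank_interactions(
    pair_table: PairTable,
    k: int,
    sense: str = "attractive",
    split: tuple | None = None,
) -> list[tuple[tuple[str, str], PairRecord]]:
    """Top-k atom pairs by total interaction energy.

    sense="attractive" ranks most negative first; "repulsive" most positive
    first. With ``split=(frag_a, frag_b)`` only pairs crossing that split are
    considered. Ties are broken by canonical pair ordering.
    """
    if k <= 0:
        raise UsageError(f"k must be positive (got {k})")
    if sense not in ("attractive", "repulsive"):
        raise UsageError(f"unknown sense {sense!r}; expected attractive or repulsive")
    entries: Iterable[tuple[tuple[str, str], PairRecord]] = pair_table.items()
    if split is not None:
        a = _members(split[0])
        b = _members(split[1])
        entries = [
            ((pa, pb), rec)
            for (pa, pb), rec in entries
            if (pa in a and pb in b) or (pa in b and pb in a)
        ]

    def sort_key(item):
        (pa, pb), rec = item
        energy = rec.total if sense == "attractive" else -rec.total
        return (energy, parse_label(pa), parse_label(pb))

    ranked = sorted(entries, key=sort_key)
    return ranked[:k]
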