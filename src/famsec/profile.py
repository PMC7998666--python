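"""Reaction-energy-profile (REP) assembly, barriers, and step-to-step deltas.

A pathway is an ordered sequence of role-annotated steps (reactant set,
adduct, transition state, intermediate, product), each pointing at a
thermochemistry record. The REP expresses every step's energy terms
(E, E_ZPVE, H, G) relative to a reference built from the isolated species the
step contains: a step of composition ["1", "2"] is referenced to
E(1) + E(2), and when a reagent joins mid-profile (e.g. water at the
hydrolysis stage) the reference for the later segment gains that species'
terms, keeping one continuous profile across the composition change.

Temperature is metadata: thermal corrections are never recomputed here, and
mixing records computed at different temperatures in one profile is an
error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .energetics import fragment_charge, interfragment_energy, intrafragment_sum
from .errors import IntegrityError, ResolutionError, UsageError
from .iqa_io import THERMO_TERMS, Snapshot, ThermoRecord

__all__ = [
    "ROLES",
    "ReactionStep",
    "REPTable",
    "BarrierResult",
    "build_profile",
    "barrier",
    "QuantitySpec",
    "evaluate_quantity",
    "step_delta",
    "pathway_compare",
]

ROLES = ("reactant_set", "adduct", "ts", "intermediate", "product")

#: Barriers smaller than this (kcal/mol) are flagged "negligible" in reports.
NEGLIGIBLE_BARRIER = 1.5
#: Pathways whose barriers differ by less than this are "comparable".
TIE_THRESHOLD = 0.1


@dataclass(frozen=True)
class ReactionStep:
    """One stationary point along a pathway.

    composition lists the isolated species the step contains (e.g.
    ["1", "2"] or ["1", "2", "H2O"]); the summed thermochemistry of those
    species defines the step's reference zero.
    """

    label: str
    role: str
    pathway: str = ""
    composition: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise UsageError(f"unknown step role {self.role!r}; expected one of {ROLES}")
        if not self.composition:
            raise UsageError(f"step {self.label!r}: composition must be non-empty")


def _check_ordering(steps: Sequence[ReactionStep]) -> None:
    for i, step in enumerate(steps):
        if step.role == "ts":
            if i == 0 or i == len(steps) - 1:
                raise UsageError(
                    f"ts step {step.label!r} must be flanked by non-ts steps"
                )
            if steps[i - 1].role == "ts" or steps[i + 1].role == "ts":
                raise UsageError(
                    f"consecutive ts steps around {step.label!r} are not a valid pathway"
                )


class REPTable:
    """Per-step relative energy terms versus the composition reference.

    ``frame`` is a pandas DataFrame indexed by step label with one column per
    available term plus role/pathway metadata columns.
    """

    def __init__(self, steps: Sequence[ReactionStep], relative: Mapping[str, dict[str, float]], terms: tuple[str, ...]):
        self.steps = list(steps)
        self.terms = terms
        self._by_label = {s.label: s for s in steps}
        rows = []
        for s in steps:
            row = {"role": s.role, "pathway": s.pathway, "composition": "+".join(s.composition)}
            row.update({t: relative[s.label][t] for t in terms})
            rows.append(row)
        self.frame = pd.DataFrame(rows, index=[s.label for s in steps])
        self.frame.index.name = "step"

    def relative(self, label: str, term: str) -> float:
        if label not in self._by_label:
            raise ResolutionError(f"no step {label!r} in profile")
        if term not in self.terms:
            raise ResolutionError(f"term {term!r} not available; have {self.terms}")
        return float(self.frame.at[label, term])

    def step(self, label: str) -> ReactionStep:
        try:
            return self._by_label[label]
        except KeyError:
            raise ResolutionError(f"no step {label!r} in profile") from None

    @property
    def pathway(self) -> str:
        return self.steps[0].pathway if self.steps else ""

    def ts_labels(self) -> list[str]:
        return [s.label for s in self.steps if s.role == "ts"]

    def __len__(self) -> int:
        return len(self.steps)


def build_profile(
    steps: Sequence[ReactionStep],
    thermo_records: Sequence[ThermoRecord] | Mapping[str, ThermoRecord],
) -> REPTable:
    """Assemble a REP table from steps and their thermochemistry records.

    ``thermo_records`` must contain one record per step label and one per
    isolated species named in any step composition. For each step and term,
    relative = value(step) - sum over the step's composition of the species
    values, summed in composition order. Terms present in every needed
    record are reported; a term present in some records but missing where
    needed is a completeness error, as is any mix of temperatures.
    """
    if not steps:
        raise UsageError("cannot build a profile from zero steps")
    _check_ordering(steps)
    if isinstance(thermo_records, Mapping):
        records = dict(thermo_records)
    else:
        records = {}
        for rec in thermo_records:
            if rec.label in records:
                raise IntegrityError(f"duplicate thermo record for {rec.label!r}")
            records[rec.label] = rec

    needed = [s.label for s in steps]
    species = []
    for s in steps:
        for sp in s.composition:
            if sp not in species:
                species.append(sp)
    for label in needed + species:
        if label not in records:
            raise IntegrityError(f"missing thermo record for {label!r}")

    used = [records[lb] for lb in needed + species]
    temperatures = sorted({rec.T for rec in used})
    if len(temperatures) > 1:
        offenders = [rec.label for rec in used]
        raise IntegrityError(
            f"mixed temperatures {temperatures} across records {offenders}; "
            f"a profile must be single-temperature"
        )

    # terms available everywhere they are needed
    terms = tuple(
        t for t in THERMO_TERMS if all(rec.term(t) is not None for rec in used)
    )
    partially = [
        t
        for t in THERMO_TERMS
        if t not in terms and any(rec.term(t) is not None for rec in used)
    ]
    if partially:
        raise IntegrityError(
            f"term(s) {partially} present in some records but missing in others; "
            f"mark them absent everywhere or supply them everywhere"
        )
    if not terms:
        raise IntegrityError("no energy term is present across all records")

    relative: dict[str, dict[str, float]] = {}
    for s in steps:
        row: dict[str, float] = {}
        for t in terms:
            ref = 0.0
            for sp in s.composition:  # summed in composition order (documented)
                ref += records[sp].term(t)  # type: ignore[operator]
            row[t] = records[s.label].term(t) - ref  # type: ignore[operator]
        relative[s.label] = row
    return REPTable(steps, relative, terms)


@dataclass(frozen=True)
class BarrierResult:
    """A forward barrier; ``flagged`` marks suspicious (negative) values and
    ``negligible`` barriers below the reporting threshold."""

    value: float
    ts_label: str
    from_label: str
    term: str
    flagged: bool
    negligible: bool

    def __float__(self) -> float:
        return self.value


def barrier(
    rep: REPTable,
    ts_label: str,
    from_label: str,
    term: str | None = None,
    negligible_threshold: float = NEGLIGIBLE_BARRIER,
) -> BarrierResult:
    """Forward barrier: relative(ts) - relative(from), kcal/mol.

    ``term`` defaults to the profile's first available term. A negative
    result is allowed but flagged: a transition state below its predecessor
    indicates inconsistent inputs.
    """
    if term is None:
        term = rep.terms[0]
    value = rep.relative(ts_label, term) - rep.relative(from_label, term)
    return BarrierResult(
        value=value,
        ts_label=ts_label,
        from_label=from_label,
        term=term,
        flagged=value < 0,
        negligible=abs(value) < negligible_threshold,
    )


# ---------------------------------------------------------------------------
# Step-to-step deltas over snapshot energetics


@dataclass(frozen=True)
class QuantitySpec:
    """Names an energetics quantity evaluable on one snapshot.

    op: "intrafragment_sum" (fragments=(F,), term), "interfragment_energy"
    (fragments=(F1, F2), term), "pair_total" (pair=(A, B)), or
    "fragment_charge" (fragments=(F,)).
    """

    op: str
    fragments: tuple = ()
    term: str = "total"
    pair: tuple[str, str] | None = None


def evaluate_quantity(snapshot: Snapshot, spec: QuantitySpec) -> float:
    if spec.op == "intrafragment_sum":
        if snapshot.pair_table is None:
            raise ResolutionError(f"snapshot {snapshot.label!r} has no pair table")
        (frag,) = spec.fragments
        return intrafragment_sum(snapshot.pair_table, frag, term=spec.term)
    if spec.op == "interfragment_energy":
        if snapshot.pair_table is None:
            raise ResolutionError(f"snapshot {snapshot.label!r} has no pair table")
        fa, fb = spec.fragments
        return interfragment_energy(snapshot.pair_table, fa, fb, term=spec.term).value(spec.term)
    if spec.op == "pair_total":
        if snapshot.pair_table is None:
            raise ResolutionError(f"snapshot {snapshot.label!r} has no pair table")
        if spec.pair is None:
            raise UsageError("pair_total spec requires pair=(A, B)")
        return snapshot.pair_table.get(*spec.pair).total
    if spec.op == "fragment_charge":
        if snapshot.atom_table is None:
            raise ResolutionError(f"snapshot {snapshot.label!r} has no atom table")
        (frag,) = spec.fragments
        return fragment_charge(snapshot.atom_table, frag)
    raise UsageError(f"unknown quantity op {spec.op!r}")


def step_delta(
    snap_1: Snapshot,
    snap_2: Snapshot,
    quantity_spec: QuantitySpec | Sequence[QuantitySpec],
) -> float | pd.DataFrame:
    """Change of a fragment quantity between two consecutive snapshots.

    delta = value(snap_2) - value(snap_1); atom labeling must be consistent
    across the snapshots. A sequence of specs returns a tidy table. The
    canonical use is the intra-fragment covalent (XC) sums of the benzene
    ring, pyrazine ring and full quinoxaline moiety between the adduct and
    transition-state stages — the delta that shows whether nucleophilic
    addition at a site disrupts each ring's covalent framework.
    """
    if isinstance(quantity_spec, QuantitySpec):
        return evaluate_quantity(snap_2, quantity_spec) - evaluate_quantity(snap_1, quantity_spec)
    rows = []
    for spec in quantity_spec:
        v1 = evaluate_quantity(snap_1, spec)
        v2 = evaluate_quantity(snap_2, spec)
        names = ",".join(getattr(f, "name", "?") for f in spec.fragments) or (
            "-".join(spec.pair) if spec.pair else ""
        )
        rows.append(
            {
                "quantity": spec.op,
                "fragments": names,
                "term": spec.term,
                snap_1.label: v1,
                snap_2.label: v2,
                "delta": v2 - v1,
            }
        )
    return pd.DataFrame(rows)


def pathway_compare(
    rep_tables: Mapping[str, REPTable] | Sequence[REPTable],
    term: str | None = None,
    tie_threshold: float = TIE_THRESHOLD,
) -> pd.DataFrame:
    """Rank pathways by their (first) forward barrier for one term.

    All pathways must share the same role structure. The result table has one
    row per pathway, sorted by barrier ascending, with the product (last
    step) stability and a ``comparable_with`` column listing pathways whose
    barrier lies within ``tie_threshold`` kcal/mol.
    """
    if isinstance(rep_tables, Mapping):
        tables = dict(rep_tables)
    else:
        tables = {t.pathway or f"pathway{i}": t for i, t in enumerate(rep_tables)}
    if len(tables) < 2:
        raise UsageError("pathway_compare needs at least two pathways")
    roles = None
    for name, rep in tables.items():
        r = tuple(s.role for s in rep.steps)
        if roles is None:
            roles = r
        elif r != roles:
            raise UsageError(
                f"pathway {name!r} role structure {r} differs from {roles}"
            )
    if term is None:
        term = next(iter(tables.values())).terms[0]
    rows = []
    for name, rep in tables.items():
        ts = rep.ts_labels()
        if not ts:
            raise UsageError(f"pathway {name!r} has no ts step")
        ts_label = ts[0]
        idx = next(i for i, s in enumerate(rep.steps) if s.label == ts_label)
        b = barrier(rep, ts_label, rep.steps[idx - 1].label, term=term)
        rows.append(
            {
                "pathway": name,
                "barrier": b.value,
                "ts": ts_label,
                "from": rep.steps[idx - 1].label,
                "product": rep.steps[-1].label,
                "product_rel": rep.relative(rep.steps[-1].label, term),
                "flagged": b.flagged,
            }
        )
    out = pd.DataFrame(rows).sort_values(["barrier", "pathway"]).reset_index(drop=True)
    comparable = []
    for i, row in out.iterrows():
        near = [
            other["pathway"]
            for j, other in out.iterrows()
            if j != i and abs(other["barrier"] - row["barrier"]) < tie_threshold
        ]
        comparable.append(",".join(near))
    out["comparable_with"] = comparable
    return out
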