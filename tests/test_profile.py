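"""Reaction-energy-profile assembly, barriers, deltas, pathway comparison."""

import numpy as np
import pytest

from famsec.errors import IntegrityError, ResolutionError, UsageError
from famsec.iqa_io import ThermoRecord
from famsec.profile import (
    QuantitySpec,
    ReactionStep,
    barrier,
    build_profile,
    pathway_compare,
    step_delta,
)
from famsec.synth import PlantedStep, generate_pathway


def simple_steps(pathway="RP", composition=("1", "2")):
    return [
        ReactionStep("ad", "adduct", pathway, composition),
        ReactionStep("ts1", "ts", pathway, composition),
        ReactionStep("int", "intermediate", pathway, composition),
    ]


def records_for(rel, refs=(-100.0, -50.0), composition=("1", "2"), T=195.15):
    """Absolute thermo records realizing given relative E values."""
    recs = [
        ThermoRecord(label=sp, E=refs[i], T=T) for i, sp in enumerate(composition)
    ]
    total_ref = sum(refs)
    for label, value in rel.items():
        recs.append(ThermoRecord(label=label, E=value + total_ref, T=T))
    return recs


class TestBuildProfile:
    def test_reference_composition_is_zero(self):
        steps = simple_steps()
        recs = records_for({"ad": 0.0, "ts1": 10.0, "int": -5.0})
        rep = build_profile(steps, recs)
        assert rep.relative("ad", "E") == pytest.approx(0.0)

    def test_intermediate_stabilities_and_their_gap(self):
        # 5a at +1.1 and 5b at -4.9 vs the reactants: gap 6.0 kcal/mol
        steps_a = [
            ReactionStep("3a", "adduct", "RP-C2", ("1", "2")),
            ReactionStep("4a", "ts", "RP-C2", ("1", "2")),
            ReactionStep("5a", "intermediate", "RP-C2", ("1", "2")),
        ]
        recs = records_for({"3a": -6.0, "4a": 12.0, "5a": 1.1, "5b": -4.9})
        rep = build_profile(steps_a, recs)
        assert rep.relative("5a", "E") == pytest.approx(1.1)
        steps_b = [
            ReactionStep("3a", "adduct", "RP-C3", ("1", "2")),
            ReactionStep("4a", "ts", "RP-C3", ("1", "2")),
            ReactionStep("5b", "intermediate", "RP-C3", ("1", "2")),
        ]
        rep_b = build_profile(steps_b, recs)
        diff = rep.relative("5a", "E") - rep_b.relative("5b", "E")
        assert diff == pytest.approx(6.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_hand_subtraction(self, seed):
        rng = np.random.default_rng(seed)
        rel = {lb: float(rng.normal(scale=20)) for lb in ("ad", "ts1", "int")}
        refs = tuple(float(v) for v in rng.normal(scale=200, size=2))
        recs = records_for(rel, refs=refs)
        rep = build_profile(simple_steps(), recs)
        by_label = {r.label: r for r in recs}
        for lb in rel:
            expected = by_label[lb].E - (by_label["1"].E + by_label["2"].E)
            assert rep.relative(lb, "E") == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_gauge_invariance(self, seed):
        rng = np.random.default_rng(seed + 500)
        rel = {lb: float(rng.normal(scale=20)) for lb in ("ad", "ts1", "int")}
        shift = float(rng.normal(scale=300))
        rep1 = build_profile(simple_steps(), records_for(rel, refs=(-100.0, -50.0)))
        # shift every absolute energy of the segment by moving one species
        rep2 = build_profile(simple_steps(), [
            ThermoRecord("1", E=-100.0 + shift, T=195.15),
            ThermoRecord("2", E=-50.0, T=195.15),
            *[
                ThermoRecord(lb, E=v + (-150.0 + shift), T=195.15)
                for lb, v in rel.items()
            ],
        ])
        for lb in rel:
            assert rep1.relative(lb, "E") == pytest.approx(rep2.relative(lb, "E"), abs=1e-9)

    def test_segmented_reference_across_reagent_addition(self, bundle):
        rep = build_profile(bundle["pathways"]["RP-C3"], bundle["thermo"])
        # rel(6b) - rel(5b) equals the water-adduct formation energy (-15.0)
        assert rep.relative("6b", "G") - rep.relative("5b", "G") == pytest.approx(-15.0)
        assert rep.frame.loc["6b", "composition"] == "1+2+H2O"

    def test_mixed_temperatures_rejected(self):
        recs = records_for({"ad": 0.0, "ts1": 5.0, "int": 1.0})
        recs[0] = ThermoRecord("1", E=-100.0, T=298.15)
        with pytest.raises(IntegrityError, match="temperatures"):
            build_profile(simple_steps(), recs)

    def test_missing_thermo_record(self):
        recs = records_for({"ad": 0.0, "ts1": 5.0})
        with pytest.raises(IntegrityError, match="int"):
            build_profile(simple_steps(), recs)

    def test_partially_present_term_rejected(self):
        recs = records_for({"ad": 0.0, "ts1": 5.0, "int": 1.0})
        recs[2] = ThermoRecord("ad", E=-150.0, H=-149.0, T=195.15)
        with pytest.raises(IntegrityError, match="H"):
            build_profile(simple_steps(), recs)

    def test_ts_must_be_flanked(self):
        steps = [
            ReactionStep("ts1", "ts", "RP", ("1",)),
            ReactionStep("int", "intermediate", "RP", ("1",)),
        ]
        with pytest.raises(UsageError, match="flanked"):
            build_profile(steps, [])


class TestBarrier:
    def test_flat_ts_is_flagged_negligible(self):
        recs = records_for({"ad": -2.0, "ts1": -2.0, "int": -5.0})
        rep = build_profile(simple_steps(), recs)
        b = barrier(rep, "ts1", "ad")
        assert b.value == 0.0
        assert b.negligible and not b.flagged

    def test_negative_barrier_flagged(self):
        recs = records_for({"ad": 0.0, "ts1": -3.0, "int": -5.0})
        rep = build_profile(simple_steps(), recs)
        assert barrier(rep, "ts1", "ad").flagged

    @pytest.mark.parametrize("seed", range(10))
    def test_forward_reverse_reconstruction(self, seed):
        rng = np.random.default_rng(seed)
        rel = {lb: float(rng.normal(scale=15)) for lb in ("ad", "ts1", "int")}
        rep = build_profile(simple_steps(), records_for(rel))
        forward = barrier(rep, "ts1", "ad").value
        reverse = barrier(rep, "ts1", "int").value
        assert forward - reverse == pytest.approx(rel["int"] - rel["ad"], abs=1e-9)

    def test_hydrolysis_barrier_magnitude(self):
        # 6a at -20.0 and 7a at -19.0 (G): a 1.0 kcal/mol, negligible barrier
        steps = [
            ReactionStep("6a", "adduct", "RP-C2", ("1", "2", "H2O")),
            ReactionStep("7a", "ts", "RP-C2", ("1", "2", "H2O")),
            ReactionStep("8a", "product", "RP-C2", ("1", "2", "H2O")),
        ]
        recs = [
            ThermoRecord("1", G=-100.0, T=195.15),
            ThermoRecord("2", G=-50.0, T=195.15),
            ThermoRecord("H2O", G=-25.0, T=195.15),
            ThermoRecord("6a", G=-195.0, T=195.15),
            ThermoRecord("7a", G=-194.0, T=195.15),
            ThermoRecord("8a", G=-205.0, T=195.15),
        ]
        rep = build_profile(steps, recs)
        b = barrier(rep, "7a", "6a", term="G")
        assert b.value == pytest.approx(1.0)
        assert b.negligible

    def test_unknown_label(self):
        rep = build_profile(simple_steps(), records_for({"ad": 0.0, "ts1": 1.0, "int": 0.5}))
        with pytest.raises(ResolutionError):
            barrier(rep, "nope", "ad")


class TestStepDelta:
    def test_identical_snapshots_give_zero(self, random_snapshot):
        snap = random_snapshot(4, n_atoms=6)
        labels = sorted(snap.pair_table.labels)
        spec = QuantitySpec("intrafragment_sum", fragments=(frozenset(labels[:3]),), term="xc")
        assert step_delta(snap, snap, spec) == 0.0

    def test_forming_bond_strengthens_by_printed_endpoints(self, bundle):
        # C3...C28 total goes from -20.8 (adduct) to -107.1 (TS): delta -86.3
        snap_3b, snap_4b = bundle["ts_bond_snapshots"]
        spec = QuantitySpec("pair_total", pair=("C3", "C28"))
        assert step_delta(snap_3b, snap_4b, spec) == pytest.approx(-86.3)

    @pytest.mark.parametrize("seed", range(10))
    def test_antisymmetry(self, seed, random_snapshot):
        s1 = random_snapshot(seed, n_atoms=7)
        s2 = random_snapshot(seed + 1000, n_atoms=7)
        labels = sorted(s1.pair_table.labels)
        spec = QuantitySpec("intrafragment_sum", fragments=(frozenset(labels[:4]),), term="xc")
        assert step_delta(s1, s2, spec) == -step_delta(s2, s1, spec)

    @pytest.mark.parametrize("seed", range(5))
    def test_recompute_and_subtract_oracle(self, seed, random_snapshot):
        from famsec.energetics import intrafragment_sum

        s1 = random_snapshot(seed, n_atoms=8)
        s2 = random_snapshot(seed + 77, n_atoms=8)
        labels = sorted(s1.pair_table.labels)
        frag = frozenset(labels[:5])
        spec = QuantitySpec("intrafragment_sum", fragments=(frag,), term="xc")
        expected = intrafragment_sum(s2.pair_table, frag, "xc") - intrafragment_sum(
            s1.pair_table, frag, "xc"
        )
        assert step_delta(s1, s2, spec) == pytest.approx(expected, abs=1e-12)

    def test_delta_table_over_multiple_specs(self):
        from famsec.synth import GeneratorSpec, generate_snapshot

        # single-element palette keeps labels identical across the snapshots
        s1 = generate_snapshot(GeneratorSpec(n_atoms=6, elements=("C",), seed=1))
        s2 = generate_snapshot(GeneratorSpec(n_atoms=6, elements=("C",), seed=2))
        labels = sorted(s1.pair_table.labels)
        specs = [
            QuantitySpec("intrafragment_sum", fragments=(frozenset(labels[:3]),), term="xc"),
            QuantitySpec("pair_total", pair=(labels[0], labels[1])),
        ]
        table = step_delta(s1, s2, specs)
        assert list(table["delta"]) == pytest.approx(
            [step_delta(s1, s2, sp) for sp in specs]
        )

    def test_invalid_fragment_resolves_error(self, random_snapshot):
        snap = random_snapshot(0, n_atoms=4)
        spec = QuantitySpec("fragment_charge", fragments=(frozenset({"Xe99"}),))
        with pytest.raises(ResolutionError):
            step_delta(snap, snap, spec)


class TestPathwayCompare:
    def test_planted_four_pathway_ordering(self, bundle):
        from famsec.profile import build_profile

        tables = {
            name: build_profile(steps, bundle["thermo"])
            for name, steps in bundle["pathways"].items()
            if name in ("RP-C2", "RP-C3", "RP-C5", "RP-C10")
        }
        out = pathway_compare(tables, term="E_ZPVE")
        assert list(out["pathway"]) == ["RP-C3", "RP-C2", "RP-C10", "RP-C5"]
        assert out.loc[2, "barrier"] == pytest.approx(36.7)
        assert out.loc[3, "barrier"] == pytest.approx(36.8)
        # 36.8 vs 36.7 differ by more than the 0.1 tie threshold; a looser
        # chemically sensible threshold reports them comparable
        loose = pathway_compare(tables, term="E_ZPVE", tie_threshold=0.2)
        assert "RP-C5" in loose.loc[2, "comparable_with"]

    def test_identical_pathways_tie(self):
        planted = [
            PlantedStep("ad", "adduct", {"E": -2.0}),
            PlantedStep("ts1", "ts", {"E": 10.0}),
            PlantedStep("int", "intermediate", {"E": -4.0}),
        ]
        reps = {}
        for name in ("a", "b"):
            pw = generate_pathway(planted, seed=3, pathway=name)
            reps[name] = build_profile(pw.steps, pw.thermo_records)
        out = pathway_compare(reps, term="E")
        assert out.loc[0, "comparable_with"] == out.loc[1, "pathway"]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        barriers = {f"p{i}": float(rng.uniform(1, 40)) for i in range(4)}
        reps = {}
        for name, b in barriers.items():
            planted = [
                PlantedStep("ad", "adduct", {"E": 0.0}),
                PlantedStep("ts1", "ts", {"E": b}),
                PlantedStep("int", "intermediate", {"E": -1.0}),
            ]
            pw = generate_pathway(planted, seed=seed, pathway=name)
            reps[name] = build_profile(pw.steps, pw.thermo_records)
        out = pathway_compare(reps, term="E")
        expected = [name for name, _ in sorted(barriers.items(), key=lambda kv: kv[1])]
        assert list(out["pathway"]) == expected

    def test_mismatched_roles_rejected(self):
        pw1 = generate_pathway(
            [
                PlantedStep("ad", "adduct", {"E": 0.0}),
                PlantedStep("ts1", "ts", {"E": 5.0}),
                PlantedStep("int", "intermediate", {"E": -1.0}),
            ],
            pathway="a",
        )
        pw2 = generate_pathway(
            [
                PlantedStep("r", "reactant_set", {"E": 0.0}),
                PlantedStep("ts1", "ts", {"E": 5.0}),
                PlantedStep("pr", "product", {"E": -1.0}),
            ],
            pathway="b",
        )
        reps = {
            "a": build_profile(pw1.steps, pw1.thermo_records),
            "b": build_profile(pw2.steps, pw2.thermo_records),
        }
        with pytest.raises(UsageError, match="role structure"):
            pathway_compare(reps, term="E")
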