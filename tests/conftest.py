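import numpy as np
import pytest

from famsec.iqa_io import PairTable
from famsec.synth import GeneratorSpec, generate_snapshot, worked_example_fixtures


@pytest.fixture(scope="session")
def bundle():
    """The worked-example fixture bundle of the case study."""
    return worked_example_fixtures()


@pytest.fixture()
def random_snapshot():
    """Factory for small random snapshots with complete pair tables."""

    def make(seed: int, n_atoms: int = 8, total_charge: float = 0.0):
        return generate_snapshot(
            GeneratorSpec(n_atoms=n_atoms, total_charge=total_charge, seed=seed)
        )

    return make


def brute_force_interfragment(table: PairTable, frag_a, frag_b, term: str = "total"):
    """Independent oracle: exhaustive double loop over the label sets."""
    members_a = sorted(getattr(frag_a, "members", frag_a))
    members_b = sorted(getattr(frag_b, "members", frag_b))
    total = 0.0
    n = 0
    for a in members_a:
        for b in members_b:
            if (a, b) in table:
                rec = table.get(a, b)
                total += {"cl": rec.vcl, "xc": rec.vxc, "total": rec.total}[term]
                n += 1
    return total, n


def brute_force_intrafragment(table: PairTable, frag, term: str = "xc"):
    members = sorted(getattr(frag, "members", frag))
    total = 0.0
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            if (a, b) in table:
                rec = table.get(a, b)
                total += {"cl": rec.vcl, "xc": rec.vxc, "total": rec.total}[term]
    return total


def random_disjoint_fragments(labels, rng: np.random.Generator, n_blocks: int = 2):
    """Partition a shuffled label list into n non-empty blocks."""
    labels = list(labels)
    rng.shuffle(labels)
    cuts = sorted(rng.choice(np.arange(1, len(labels)), size=n_blocks - 1, replace=False))
    blocks = []
    prev = 0
    for c in list(cuts) + [len(labels)]:
        blocks.append(frozenset(labels[prev:c]))
        prev = c
    return blocks
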