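import numpy as np
import pytest
from hypothesis import settings

import moveindex as mi

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[c] for c in rng.integers(0, 4, n))


def random_text(rng: np.random.Generator, n: int) -> str:
    """Random terminated DNA text (no separators)."""
    return random_dna(rng, n) + "$"


def iter_pointers(table: mi.MoveTable):
    """Every valid BiPointer of a table, in BWT offset order."""
    for run, row in enumerate(table.rows):
        for off in range(row.p, row.p + row.len):
            yield mi.BiPointer(run=run, off=off)


def exhaustive_max_fast_forwards(table: mi.MoveTable) -> int:
    """Max fast-forward steps over an LF query at every BWT offset."""
    worst = 0
    for ptr in iter_pointers(table):
        row = table.rows[ptr.run]
        off2 = row.pi + (ptr.off - row.p)
        _, steps = mi.fast_forward(table, row.xi, off2)
        if steps > worst:
            worst = steps
    return worst


@pytest.fixture(scope="session")
def acac_oracle():
    return mi.build_oracle("ACAC$")


@pytest.fixture(scope="session")
def acac_table(acac_oracle):
    return mi.build_move_table(acac_oracle)


@pytest.fixture(scope="session")
def small_pangenome():
    """A ~5 kb, 5-haplotype synthetic pangenome with its oracle and both
    move tables; shared across tests that only read from it."""
    spec = mi.PangenomeSpec(base_length=1000, n_haplotypes=5, seed=42)
    records = mi.generate_pangenome(spec)
    text = mi.build_text(records)
    oracle = mi.build_oracle(text)
    default = mi.build_move_table(oracle, mode="default")
    constant = mi.build_move_table(oracle, mode="constant", d=3)
    return text, oracle, default, constant
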