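"""Shared fixtures: planted clustering instances and the benchmark scenario."""

from __future__ import annotations

import random

import numpy as np
import pytest

from mixcat import run_benchmark

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AA) for _ in range(length))


def mutate_protein(rng: random.Random, seq: str, identity: float) -> str:
    """Point-substituted variant at approximately the given identity."""
    n_changes = round((1.0 - identity) * len(seq))
    positions = rng.sample(range(len(seq)), n_changes)
    out = list(seq)
    for pos in positions:
        out[pos] = rng.choice([a for a in AA if a != out[pos]])
    return "".join(out)


def planted_instance(
    seed: int,
    n_species: int = 8,
    variants_per_species: tuple[int, int] = (1, 4),
    identity_range: tuple[float, float] = (0.90, 0.99),
    n_singletons: int = 5,
    length_range: tuple[int, int] = (40, 150),
) -> dict[str, str]:
    """Planted clusters: species with near-identical variants plus unrelated
    singletons.  Variant identities straddle the 0.95 threshold, so the
    greedy rule has real decisions to make."""
    rng = random.Random(seed)
    proteins: dict[str, str] = {}
    for s in range(n_species):
        base = random_protein(rng, rng.randint(*length_range))
        proteins[f"sp{s}_v0"] = base
        for v in range(1, rng.randint(*variants_per_species)):
            ident = rng.uniform(*identity_range)
            seq = mutate_protein(rng, base, ident)
            if len(seq) >= 30 and rng.random() < 0.3:  # fragment variant
                cut = rng.randint(len(seq) // 2, len(seq) - 5)
                seq = seq[:cut] if rng.random() < 0.5 else seq[-cut:]
            proteins[f"sp{s}_v{v}"] = seq
    for i in range(n_singletons):
        proteins[f"single{i}"] = random_protein(rng, rng.randint(*length_range))
    return proteins


@pytest.fixture(scope="session")
def benchmark():
    """The shipped end-to-end benchmark scenario (simulation seed 0)."""
    return run_benchmark()


@pytest.fixture(scope="session")
def benchmark_rates(benchmark):
    return {
        name: np.array(benchmark.rates(name))
        for name in ("individual", "coassembly", "mix")
    }
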