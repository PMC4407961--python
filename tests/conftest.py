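import numpy as np
import pytest

from cavepairs.comparative import Phylogeny
from cavepairs.morphometry import CHANNEL_TRAITS, StandardizedProfile, TraitRecord


@pytest.fixture
def small_tree() -> Phylogeny:
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150423)


def make_records(rng: np.random.Generator, n: int = 8) -> list[TraitRecord]:
    """Random but valid trait table: allometric lines plus mild residual scatter."""
    lengths = rng.uniform(4.0, 16.0, size=n)
    records = []
    for i, L in enumerate(lengths):
        vals = {}
        for k, t in enumerate(CHANNEL_TRAITS):
            vals[t] = 0.3 + (0.12 - 0.01 * k) * L + rng.normal(0, 0.05)
        records.append(TraitRecord(f"sp{i+1}", float(L), **vals))
    return records


def random_profiles(rng: np.random.Generator, n: int) -> list[StandardizedProfile]:
    return [
        StandardizedProfile(
            f"sp{i+1}", float(rng.uniform(4, 16)), rng.uniform(-2, 2, size=4)
        )
        for i in range(n)
    ]
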