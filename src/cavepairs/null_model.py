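"""Virtual-species null model for filtering vs. competition tests.

Regional pools of real cave amphipods are small (four species around Movile,
seven around Frasassi), too small for a resampling test over real species pairs.
The null model therefore simulates *virtual* species: each trait of each virtual
species is drawn independently and uniformly between the minimum and maximum
observed in the real regional pool, yielding (by default) 100 virtual species
per region. 1000 random pairs of distinct virtual species give a null
distribution of Euclidean distances; an observed focal pair is then located in
that distribution with two one-sided empirical p-values.

Classification: a pair significantly *more different* than the null suggests
competition (limiting similarity / character displacement); significantly *more
similar* suggests environmental filtering; otherwise random.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import CavepairsError, InsufficientDataError
from .morphometry import CHANNEL_TRAITS, StandardizedProfile, euclidean_distance

PROCESSES = ("filtering", "competition", "random")


@dataclass(frozen=True)
class TraitRanges:
    """Per-trait (min, max) observed in a regional pool; the box the null resamples."""

    body_size: tuple[float, float]
    channel: np.ndarray  # shape (4, 2): per-coordinate (min, max)

    def __post_init__(self) -> None:
        channel = np.asarray(self.channel, dtype=float)
        if channel.shape != (len(CHANNEL_TRAITS), 2):
            raise CavepairsError(f"channel ranges must be (4, 2), got {channel.shape}")
        lo_le_hi = self.body_size[0] <= self.body_size[1] and np.all(
            channel[:, 0] <= channel[:, 1]
        )
        if not lo_le_hi:
            raise CavepairsError("trait range with min > max")
        object.__setattr__(self, "channel", channel)


@dataclass(frozen=True)
class VirtualPool:
    """Simulated regional pool: n virtual species x (body size + 4 channel coords)."""

    region_id: str
    body_size: np.ndarray  # (n,)
    channel: np.ndarray  # (n, 4)
    seed: int

    @property
    def n(self) -> int:
        return int(self.body_size.shape[0])

    def coordinates(self, trait_set: str) -> np.ndarray:
        if trait_set == "body_size":
            return self.body_size[:, None]
        if trait_set == "channel":
            return self.channel
        raise CavepairsError(f"unknown trait_set {trait_set!r}")


@dataclass(frozen=True)
class NullDistribution:
    """Euclidean distances of randomly drawn virtual-species pairs."""

    region_id: str
    trait_set: str
    distances: np.ndarray
    n_pairs: int
    seed: int


@dataclass(frozen=True)
class PairTest:
    """Location of an observed species-pair distance in the null distribution.

    ``p_similarity`` and ``p_difference`` are one-sided add-one empirical
    p-values sharing the ties mass (their sum is >= 1). ``process`` is the
    classification at level ``alpha``; ``p_label`` is the presentation string
    (``p < 1/n_pairs`` when the observed distance is beyond every null draw).
    """

    pair: tuple[str, str]
    trait_set: str
    observed: float
    p_similarity: float
    p_difference: float
    alpha: float
    process: str
    p_label: str

    @property
    def p_value(self) -> float:
        """The reported p: the winning (smaller) side."""
        return min(self.p_similarity, self.p_difference)


def trait_ranges(pool_members: Sequence[StandardizedProfile]) -> TraitRanges:
    """Coordinate-wise min/max over the real pool, for body size and channel."""
    if len(pool_members) < 2:
        raise InsufficientDataError("regional pool needs at least 2 member species")
    body = np.array([p.body_size for p in pool_members])
    chan = np.array([p.channel for p in pool_members])
    ranges = TraitRanges(
        body_size=(float(body.min()), float(body.max())),
        channel=np.column_stack([chan.min(axis=0), chan.max(axis=0)]),
    )
    if ranges.body_size[0] == ranges.body_size[1] or np.any(
        ranges.channel[:, 0] == ranges.channel[:, 1]
    ):
        warnings.warn("degenerate trait range (min == max); simulated trait will be constant")
    return ranges


def simulate_virtual_pool(
    ranges: TraitRanges, n: int = 100, seed: int = 0, region_id: str = "pool"
) -> VirtualPool:
    """Draw n virtual species, each trait independently uniform within its range."""
    if n < 2:
        raise CavepairsError(f"virtual pool needs n >= 2, got {n}")
    rng = np.random.default_rng(seed)
    body = rng.uniform(ranges.body_size[0], ranges.body_size[1], size=n)
    chan = rng.uniform(ranges.channel[:, 0], ranges.channel[:, 1], size=(n, len(CHANNEL_TRAITS)))
    return VirtualPool(region_id=region_id, body_size=body, channel=chan, seed=seed)


def sample_null_distances(
    pool: VirtualPool, trait_set: str, n_pairs: int = 1000, seed: int = 0
) -> NullDistribution:
    """Distances of ``n_pairs`` random pairs of *distinct* virtual species.

    Pairs are sampled with replacement across draws (one virtual species may
    recur in several pairs), never within a pair.
    """
    if pool.n < 2:
        raise CavepairsError("virtual pool too small to draw pairs")
    if n_pairs < 1:
        raise CavepairsError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    i = rng.integers(0, pool.n, size=n_pairs)
    j = rng.integers(0, pool.n - 1, size=n_pairs)
    j = np.where(j >= i, j + 1, j)  # shift: j uniform over indices != i
    coords = pool.coordinates(trait_set)
    distances = np.linalg.norm(coords[i] - coords[j], axis=1)
    return NullDistribution(pool.region_id, trait_set, distances, n_pairs, seed)


def empirical_p(observed: float, null: NullDistribution, side: str) -> float:
    """Add-one one-sided empirical p-value: (#{extreme or tied} + 1)/(n + 1)."""
    d = null.distances
    if d.size == 0:
        raise CavepairsError("empty null distribution")
    if side == "similarity":
        count = int(np.sum(d <= observed))
    elif side == "difference":
        count = int(np.sum(d >= observed))
    else:
        raise CavepairsError(f"unknown side {side!r}")
    return (count + 1) / (d.size + 1)


def classify_pair(p_similarity: float, p_difference: float, alpha: float = 0.05) -> str:
    """Label the process: competition (too different), filtering (too similar), random."""
    for p in (p_similarity, p_difference):
        if not (0.0 < p <= 1.0):
            raise CavepairsError(f"invalid p-value {p}")
    if alpha < 0.5 and p_similarity <= alpha and p_difference <= alpha:
        # the two one-sided p's share the ties mass, so they sum to >= 1
        raise CavepairsError(
            "both one-sided p-values significant: inconsistent null distribution"
        )
    if p_difference <= alpha:
        return "competition"
    if p_similarity <= alpha:
        return "filtering"
    return "random"


def format_p(p: float, n_pairs: int) -> str:
    """Presentation string; a p at the add-one floor is shown as a '<' bound."""
    floor = 1.0 / (n_pairs + 1)
    if p <= floor:
        return f"p < {1.0 / n_pairs:g}"
    return f"p = {p:.3g}"


def test_pair(
    a: StandardizedProfile,
    b: StandardizedProfile,
    null: NullDistribution,
    alpha: float = 0.05,
) -> PairTest:
    """Run the full two-sided-by-two-one-sided test for an observed species pair."""
    observed = euclidean_distance(a, b, null.trait_set)
    return test_distance((a.species_id, b.species_id), observed, null, alpha)


def test_distance(
    pair: tuple[str, str], observed: float, null: NullDistribution, alpha: float = 0.05
) -> PairTest:
    """Same as :func:`test_pair` for a precomputed distance (e.g. an ancestral pair)."""
    p_sim = empirical_p(observed, null, "similarity")
    p_diff = empirical_p(observed, null, "difference")
    process = classify_pair(p_sim, p_diff, alpha)
    return PairTest(
        pair=pair,
        trait_set=null.trait_set,
        observed=float(observed),
        p_similarity=p_sim,
        p_difference=p_diff,
        alpha=alpha,
        process=process,
        p_label=format_p(min(p_sim, p_diff), null.n_pairs),
    )
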