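"""Synthetic study systems: trees, trait evolution, regional pools and focal pairs.

The generator emulates the statistical structure the analysis assumes:

* ultrametric pure-birth trees (extinction adds nothing the pipeline uses);
* Gaussian trait evolution on the tree under BM or root-conditioned OU;
* regional pools whose species occupy a trait bounding box — body size uniform
  on 4–16 mm (the size span of European niphargid amphipods), standardized
  ventral-channel residuals uniform on [-2, 2];
* focal species pairs planted so that their trait distance sits at a chosen
  percentile of the exhaustive pool-pair distance distribution (low percentile:
  a filtered, over-similar pair; high percentile: an over-dispersed,
  competition-like pair; ``neutral``: the focal pair is exchangeable with the
  virtual species the null model draws).

``make_measurement_table`` inverts the allometric standardization so the whole
pipeline — including the regression step — can run on generated raw-mm tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .comparative import Phylogeny, bm_covariance, ou_covariance
from .errors import CavepairsError
from .morphometry import (
    CHANNEL_TRAITS,
    StandardizedProfile,
    TraitRecord,
    standardize,
    write_trait_table,
)

#: per-trait allometric intercepts (mm) used when inverting standardization
CHANNEL_INTERCEPTS = (0.30, 0.25, 0.20, 0.18)
#: per-trait multiplier on the common allometric slope
CHANNEL_SLOPE_FACTORS = (1.0, 0.9, 0.6, 0.55)


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of a synthetic study system.

    ``effect_percentile`` places the focal pair's distance within the exhaustive
    pool-pair distance distribution (ignored for ``process='neutral'``, where the
    focal pair is drawn like any virtual species). Trait ranges default to a
    4–16 mm body-size span and [-2, 2] standardized channel residuals.
    """

    process: str = "neutral"  # filtering | competition | neutral
    effect_percentile: float = 50.0
    n_pool: int = 100
    n_tips: int | None = None  # defaults to n_pool + 2
    model: str = "BM"
    alpha: float = 1.0
    sigma2: float = 0.5
    allometric_slope: float = 0.12
    noise_sd: float = 0.0
    seed: int = 0
    body_range: tuple[float, float] = (4.0, 16.0)
    channel_range: tuple[float, float] = (-2.0, 2.0)
    region_id: str = "synthetic"
    species_prefix: str = ""  # prepended to generated ids, for multi-region studies

    def __post_init__(self) -> None:
        if self.process not in ("filtering", "competition", "neutral"):
            raise CavepairsError(f"unknown process {self.process!r}")
        if not (0.0 <= self.effect_percentile <= 100.0):
            raise CavepairsError("effect_percentile must lie in [0, 100]")
        if self.n_pool < 2:
            raise CavepairsError("n_pool must be >= 2")
        if self.n_tips is not None and self.n_tips < 4:
            raise CavepairsError("n_tips must be >= 4")


@dataclass
class Scenario:
    """All artifacts of one synthetic study system, plus the planted truth."""

    spec: ScenarioSpec
    records: list[TraitRecord]
    profiles: list[StandardizedProfile]  # planted standardized-space positions
    pool_ids: list[str]
    focal_pair: tuple[str, str]
    tree: Phylogeny
    target_distance: dict = field(default_factory=dict)  # trait_set -> planted distance

    def pool_profiles(self) -> list[StandardizedProfile]:
        pool = set(self.pool_ids)
        return [p for p in self.profiles if p.species_id in pool]

    def focal_profiles(self) -> tuple[StandardizedProfile, StandardizedProfile]:
        by_id = {p.species_id: p for p in self.profiles}
        return by_id[self.focal_pair[0]], by_id[self.focal_pair[1]]

    def write(self, outdir) -> dict:
        """Emit trait CSV, pool list, pair CSV, newick tree and a manifest JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_trait_table(self.records, outdir / "traits.csv")
        (outdir / "pool.txt").write_text(
            "# regional pool membership (one species per line)\n"
            + "".join(f"{s}\n" for s in self.pool_ids)
        )
        (outdir / "pairs.csv").write_text(
            "pair_id,species_a,species_b,region_id\n"
            f"pair1,{self.focal_pair[0]},{self.focal_pair[1]},{self.spec.region_id}\n"
        )
        (outdir / "tree.nwk").write_text(self.tree.to_newick() + "\n")
        manifest = {
            "spec": asdict(self.spec),
            "focal_pair": list(self.focal_pair),
            "target_distance": self.target_distance,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return manifest


def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0,
                  labels: Sequence[str] | None = None) -> Phylogeny:
    """Ultrametric pure-birth tree: exponential waiting times, random lineage splits."""
    if n_tips < 2:
        raise CavepairsError("need at least 2 tips")
    if labels is not None and len(labels) != n_tips:
        raise CavepairsError("labels length must equal n_tips")
    rng = np.random.default_rng(seed)
    # the root splits at time 0 into two lineages; then, with k lineages alive,
    # wait Exp(k*birth_rate) and split a uniformly chosen lineage
    t = 0.0
    pending: list[dict] = [{"start": 0.0, "children": None} for _ in range(2)]
    nodes = pending[:]  # currently unresolved lineages
    while len(nodes) < n_tips:
        k = len(nodes)
        t += rng.exponential(1.0 / (birth_rate * k))
        idx = int(rng.integers(k))
        parent = nodes.pop(idx)
        parent["split"] = t
        kids = [{"start": t, "children": None}, {"start": t, "children": None}]
        parent["children"] = kids
        nodes.extend(kids)
    # one more waiting time so the last cherry has positive terminal branches
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    total = t

    tip_names = iter(labels if labels is not None else (f"t{i+1}" for i in range(n_tips)))

    def render(node: dict) -> str:
        if node["children"] is None:
            return f"{next(tip_names)}:{total - node['start']:.12g}"
        inner = ",".join(render(ch) for ch in node["children"])
        return f"({inner}):{node['split'] - node['start']:.12g}"

    root_children = ",".join(render(ch) for ch in pending)
    return Phylogeny.from_newick(f"({root_children});")


def simulate_traits(
    tree: Phylogeny,
    model: str,
    sigma2: float,
    seed: int = 0,
    alpha: float = 0.0,
    root_state: float = 0.0,
) -> dict[str, float]:
    """One multivariate-normal draw of tip trait values under BM or OU."""
    if sigma2 < 0:
        raise CavepairsError("sigma2 must be >= 0")
    if sigma2 == 0.0:
        return {l: float(root_state) for l in tree.tip_labels}
    if model == "BM":
        V = bm_covariance(tree, sigma2)
    elif model == "OU":
        V = ou_covariance(tree, alpha, sigma2)
    else:
        raise CavepairsError(f"unknown model {model!r}")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(V + 1e-12 * np.eye(tree.n_tips))
    y = root_state + L @ rng.standard_normal(tree.n_tips)
    return dict(zip(tree.tip_labels, map(float, y)))


def make_measurement_table(
    profiles: Sequence[StandardizedProfile],
    allometric_slope: float = 0.12,
    noise_sd: float = 0.0,
    seed: int = 0,
    resid_scale: float = 0.08,
) -> list[TraitRecord]:
    """Invert standardization: embed planted channel residuals in raw mm measurements.

    Body length equals the profile's body size. Each channel measurement is
    ``intercept + slope_t * length + resid_scale * r_perp + noise`` where
    ``r_perp`` is the planted residual vector made orthogonal to the allometric
    design ``[1, length]`` — that orthogonalization is what makes re-running the
    standardization an exact inverse (up to the common residual-SD scale) when
    ``noise_sd = 0``.
    """
    if len(profiles) < 3:
        raise CavepairsError("need >= 3 profiles to embed a regression design")
    rng = np.random.default_rng(seed)
    L = np.array([p.body_size for p in profiles])
    R = np.array([p.channel for p in profiles])  # (n, 4)
    X = np.column_stack([np.ones_like(L), L])
    beta, *_ = np.linalg.lstsq(X, R, rcond=None)
    R_perp = R - X @ beta
    records = []
    noise = rng.normal(0.0, noise_sd, size=R.shape) if noise_sd > 0 else np.zeros_like(R)
    for i, p in enumerate(profiles):
        values = {}
        for k, trait in enumerate(CHANNEL_TRAITS):
            slope_t = allometric_slope * CHANNEL_SLOPE_FACTORS[k]
            v = CHANNEL_INTERCEPTS[k] + slope_t * L[i] + resid_scale * R_perp[i, k] + noise[i, k]
            if v <= 0:
                raise CavepairsError(
                    f"generated non-positive measurement for {p.species_id}/{trait}; "
                    "reduce residual scale or noise, or raise the intercepts"
                )
            values[trait] = float(v)
        records.append(TraitRecord(species_id=p.species_id, body_length=float(L[i]), **values))
    return records


def _place_pair_at_distance(
    lo: np.ndarray, hi: np.ndarray, d: float
) -> tuple[np.ndarray, np.ndarray]:
    """Two points inside the box [lo, hi] at Euclidean distance d, on its diagonal."""
    span = hi - lo
    diag = float(np.linalg.norm(span))
    if d > diag + 1e-12:
        raise CavepairsError(f"target distance {d} exceeds the pool box diagonal {diag}")
    center = (lo + hi) / 2.0
    u = span / diag if diag > 0 else np.zeros_like(span)
    half = np.clip(d, 0.0, diag) / 2.0
    return center - half * u, center + half * u


def make_scenario(spec: ScenarioSpec) -> Scenario:
    """Build a complete synthetic study system from a :class:`ScenarioSpec`.

    Pool members are uniform in the fixed generator ranges. The focal pair is
    placed per-trait-set at ``effect_percentile`` of the exhaustive pool-pair
    distance distribution (computed inside the *observed* pool ranges, the same
    box the null model resamples); under ``neutral`` it is instead drawn
    uniformly from the observed pool ranges, making it exchangeable with the
    null model's virtual species.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pool
    body = rng.uniform(*spec.body_range, size=n)
    chan = rng.uniform(*spec.channel_range, size=(n, len(CHANNEL_TRAITS)))
    pool_ids = [f"{spec.species_prefix}pool{i+1}" for i in range(n)]

    body_lo, body_hi = body.min(), body.max()
    chan_lo, chan_hi = chan.min(axis=0), chan.max(axis=0)

    focal_ids = [f"{spec.species_prefix}focal_a", f"{spec.species_prefix}focal_b"]
    measurement_seed = int(rng.integers(2**31))

    def build(focal_body: np.ndarray, focal_chan: np.ndarray):
        profiles = [
            StandardizedProfile(pool_ids[i], float(body[i]), chan[i]) for i in range(n)
        ] + [
            StandardizedProfile(focal_ids[k], float(focal_body[k]), focal_chan[k])
            for k in range(2)
        ]
        records = make_measurement_table(
            profiles,
            allometric_slope=spec.allometric_slope,
            noise_sd=spec.noise_sd,
            seed=measurement_seed,
        )
        return profiles, records

    if spec.process == "neutral":
        focal_body = rng.uniform(body_lo, body_hi, size=2)
        focal_chan = rng.uniform(chan_lo, chan_hi, size=(2, len(CHANNEL_TRAITS)))
        profiles, records = build(focal_body, focal_chan)
        targets = {}
    else:
        # percentile targets from the exhaustive pool-pair distance distribution
        iu, ju = np.triu_indices(n, k=1)
        d_body = np.abs(body[iu] - body[ju])
        pct = spec.effect_percentile
        tb = 0.0 if pct == 0.0 else float(np.percentile(d_body, pct))
        a_b, b_b = _place_pair_at_distance(np.array([body_lo]), np.array([body_hi]), tb)
        focal_body = np.array([a_b[0], b_b[0]])

        # Channel placement is calibrated through the standardization round trip:
        # the allometric refit absorbs the part of a planted focal offset that is
        # collinear with body length, so the offset is rescaled until the
        # *re-standardized* focal distance sits at the requested percentile of the
        # re-standardized exhaustive pool-pair distances.
        chan_center = (chan_lo + chan_hi) / 2.0
        span = chan_hi - chan_lo
        diag = float(np.linalg.norm(span))
        u = span / diag if diag > 0 else np.zeros_like(span)
        scale = 0.0 if pct == 0.0 else 1.0
        d_chan0 = np.linalg.norm(chan[iu] - chan[ju], axis=1)
        tc0 = 0.0 if pct == 0.0 else float(np.percentile(d_chan0, pct))
        if tc0 > diag + 1e-12:
            raise CavepairsError(
                f"infeasible percentile: channel target {tc0} exceeds box diagonal {diag}"
            )
        tc_real = tc0
        for _ in range(6 if tc0 > 0 else 1):
            half = scale * tc0 / 2.0
            focal_chan = np.vstack([chan_center - half * u, chan_center + half * u])
            profiles, records = build(focal_body, focal_chan)
            std = {p.species_id: p for p in standardize(records)}
            pool_std = np.array([std[s].channel for s in pool_ids])
            d_std = np.linalg.norm(pool_std[iu] - pool_std[ju], axis=1)
            tc_real = 0.0 if pct == 0.0 else float(np.percentile(d_std, pct))
            d_real = float(
                np.linalg.norm(std[focal_ids[0]].channel - std[focal_ids[1]].channel)
            )
            if tc0 == 0.0 or d_real == 0.0:
                break
            if abs(d_real - tc_real) <= 1e-9 * max(tc_real, 1.0):
                break
            scale *= tc_real / d_real
        targets = {"body_size": tb, "channel": tc_real}

    n_tips = spec.n_tips if spec.n_tips is not None else n + 2
    if n_tips < n + 2:
        raise CavepairsError("n_tips must cover pool plus focal species")
    extra = [f"{spec.species_prefix}out{i+1}" for i in range(n_tips - n - 2)]
    tip_order = pool_ids + focal_ids + extra
    order = rng.permutation(len(tip_order))
    tree = simulate_tree(
        n_tips,
        seed=int(rng.integers(2**31)),
        labels=[tip_order[i] for i in order],
    )
    if extra:
        # outgroup tips get median-like measurements so loaders stay happy
        med = StandardizedProfile("tmp", float(np.median(body)), np.zeros(4))
        extras = [
            StandardizedProfile(e, med.body_size, np.zeros(4)) for e in extra
        ]
        records += make_measurement_table(
            profiles[:1] + profiles[1:3] + extras,
            allometric_slope=spec.allometric_slope,
            noise_sd=0.0,
            seed=0,
        )[3:]

    return Scenario(
        spec=spec,
        records=records,
        profiles=profiles,
        pool_ids=pool_ids,
        focal_pair=(focal_ids[0], focal_ids[1]),
        tree=tree,
        target_distance=targets,
    )


@dataclass
class Study:
    """A multi-region synthetic study: merged trait table, pools, pairs, one tree."""

    scenarios: dict
    records: list[TraitRecord]
    pools: dict  # region_id -> list of species ids
    pairs: list  # dicts with pair_id, species_a, species_b, region_id
    tree: Phylogeny

    def write(self, outdir) -> Path:
        """Emit all pipeline inputs plus a ready-to-run config.yaml; returns its path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_trait_table(self.records, outdir / "traits.csv")
        pool_files = {}
        for region, members in self.pools.items():
            name = f"pool_{region}.txt"
            (outdir / name).write_text("".join(f"{s}\n" for s in members))
            pool_files[region] = name
        lines = ["pair_id,species_a,species_b,region_id"]
        for p in self.pairs:
            lines.append(f"{p['pair_id']},{p['species_a']},{p['species_b']},{p['region_id']}")
        (outdir / "pairs.csv").write_text("\n".join(lines) + "\n")
        (outdir / "tree.nwk").write_text(self.tree.to_newick() + "\n")
        config = (
            "trait_table: traits.csv\n"
            "tree: tree.nwk\n"
            "pairs: pairs.csv\n"
            "pools:\n"
            + "".join(f"  {r}: {f}\n" for r, f in sorted(pool_files.items()))
        )
        (outdir / "config.yaml").write_text(config)
        manifest = {r: asdict(sc.spec) for r, sc in self.scenarios.items()}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return outdir / "config.yaml"


def make_study(specs: Mapping[str, "ScenarioSpec"]) -> Study:
    """Build one study from several per-region scenarios joined under a common root.

    Regions without an explicit ``species_prefix`` get ``<region>_`` so species
    ids stay unique; each region's ultrametric tree becomes one subtree of a
    shared root (the regional faunas are reciprocally monophyletic here, a
    simplification the tree-free null model never looks at).
    """
    scenarios = {}
    for region, spec in specs.items():
        if spec.species_prefix == "":
            spec = replace(spec, species_prefix=f"{region}_", region_id=region)
        scenarios[region] = make_scenario(spec)
    records = [r for sc in scenarios.values() for r in sc.records]
    ids = [r.species_id for r in records]
    if len(set(ids)) != len(ids):
        raise CavepairsError("species id collision across regions; use distinct prefixes")
    pools = {region: list(sc.pool_ids) for region, sc in scenarios.items()}
    pairs = [
        {
            "pair_id": f"{region}_pair",
            "species_a": sc.focal_pair[0],
            "species_b": sc.focal_pair[1],
            "region_id": region,
        }
        for region, sc in scenarios.items()
    ]
    subtrees = []
    for sc in scenarios.values():
        nwk = sc.tree.to_newick().rstrip().rstrip(";")
        subtrees.append(f"{nwk}:1.0")
    tree = Phylogeny.from_newick("(" + ",".join(subtrees) + ");")
    return Study(scenarios=scenarios, records=records, pools=pools, pairs=pairs, tree=tree)
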