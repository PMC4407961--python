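"""End-to-end analysis: standardize -> pair tests -> model fit -> ancestors -> divergence.

The pipeline reproduces the structure of the study's summary tables: for each
region x trait set, rows for the extant focal pair and for the ancestral pair
under the lower / mean / upper reconstruction variants, each with its Euclidean
distance, empirical p-value, process label, normalized distance and (for
ancestral rows) the extant/ancestral divergence factor. Extant and ancestral
pairs are located in the *same* regional null distribution.

Every stochastic stage draws its seed deterministically from the run seed and
the stage name, so e.g. changing ``n_pairs`` does not perturb the virtual pool.
"""

from __future__ import annotations

import json
import logging
import warnings
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparative import (
    ANCESTRAL_VARIANTS,
    AncestralEstimate,
    ModelFit,
    Phylogeny,
    ancestral_pair_distance,
    divergence_report,
    fit_model,
    reconstruct_ancestor,
    select_model,
    sister_species,
)
from .errors import CavepairsError
from .morphometry import (
    CHANNEL_TRAITS,
    TRAIT_SETS,
    StandardizedProfile,
    euclidean_distance,
    load_trait_table,
    normalize_distance,
    standardize,
    theoretical_extremes,
)
from .null_model import (
    NullDistribution,
    sample_null_distances,
    simulate_virtual_pool,
    test_distance,
    test_pair,
    trait_ranges,
)

log = logging.getLogger("cavepairs")

ROW_ORDER = ("extant", "ancestral-lower", "ancestral-mean", "ancestral-upper")


@dataclass
class AnalysisConfig:
    """Inputs and knobs of one full run (defaults mirror the published design)."""

    trait_table: str
    tree: str
    pairs: str
    pools: dict  # region_id -> pool membership file
    n_virtual: int = 100
    n_pairs: int = 1000
    alpha_level: float = 0.05
    model: str = "auto"  # BM | OU | auto (per-trait AIC selection)
    seed: int = 0
    standardization_scope: str = "per_region"  # or "global"
    holm_adjust: bool = False

    def __post_init__(self) -> None:
        if self.model not in ("BM", "OU", "auto"):
            raise CavepairsError(f"unknown model {self.model!r}")
        if self.standardization_scope not in ("per_region", "global"):
            raise CavepairsError(
                f"unknown standardization_scope {self.standardization_scope!r}"
            )

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise CavepairsError(f"config {path} is not a mapping")
        base = path.parent
        for key in ("trait_table", "tree", "pairs"):
            if key in raw:
                raw[key] = str(base / raw[key])
        if "pools" in raw:
            raw["pools"] = {k: str(base / v) for k, v in raw["pools"].items()}
        try:
            return cls(**raw)
        except TypeError as exc:
            raise CavepairsError(f"bad config field: {exc}") from exc


@dataclass
class RegionDetail:
    """Intermediate artifacts of one region, kept for audit and regeneration."""

    region_id: str
    pair: tuple[str, str]
    sisters: dict
    fits: dict  # trait coordinate -> ModelFit
    estimates: dict  # species -> trait_set -> list[AncestralEstimate]
    nulls: dict  # trait_set -> NullDistribution


@dataclass
class AnalysisReport:
    table: pd.DataFrame
    provenance: dict
    details: list = field(default_factory=list)

    def write(self, outdir, fmt: str = "tsv") -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        if fmt in ("tsv", "both"):
            p = outdir / "report.tsv"
            self.table.to_csv(p, sep="\t", index=False, float_format="%.6g")
            written.append(p)
        if fmt in ("json", "both"):
            p = outdir / "report.json"
            payload = {
                "provenance": self.provenance,
                "rows": json.loads(self.table.to_json(orient="records")),
            }
            p.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
            written.append(p)
        prov = outdir / "provenance.json"
        prov.write_text(json.dumps(self.provenance, indent=2, sort_keys=True) + "\n")
        written.append(prov)
        return written


def subseed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (stable across platforms, < 2**31)."""
    return zlib.crc32(f"{seed}:{stage}".encode()) % (2**31)


def load_pool_file(path) -> list[str]:
    """Pool membership: one species per line, '#' comments."""
    members = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                members.append(line)
    if len(members) < 2:
        raise CavepairsError(f"pool file {path} lists fewer than 2 species")
    if len(set(members)) != len(members):
        raise CavepairsError(f"pool file {path} has duplicate species")
    return members


def load_pairs(path) -> list[dict]:
    df = pd.read_csv(path)
    needed = {"pair_id", "species_a", "species_b", "region_id"}
    if not needed.issubset(df.columns):
        raise CavepairsError(f"pair file {path} must have columns {sorted(needed)}")
    return df.to_dict(orient="records")


def holm_adjust(pvalues: Sequence[float]) -> list[float]:
    """Holm step-down adjustment (monotone, capped at 1)."""
    m = len(pvalues)
    order = np.argsort(pvalues)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvalues[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()


def _coordinate_traits(profiles: Mapping[str, StandardizedProfile]) -> dict:
    """Per-coordinate trait maps over species: body_size + the 4 channel coords."""
    coords = {"body_size": {s: p.body_size for s, p in profiles.items()}}
    for k, name in enumerate(CHANNEL_TRAITS):
        coords[name] = {s: float(p.channel[k]) for s, p in profiles.items()}
    return coords


def _fit_coordinate(
    tree: Phylogeny, values: Mapping[str, float], model: str, name: str
) -> ModelFit:
    if model in ("BM", "OU"):
        return fit_model(tree, values, model, trait_name=name)
    fits = [fit_model(tree, values, m, trait_name=name) for m in ("BM", "OU")]
    return select_model(fits)


def run_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Execute the full stage order and assemble the report table."""
    log.info("stage 1/7: load inputs")
    records = load_trait_table(config.trait_table)
    by_id = {r.species_id: r for r in records}
    pairs = load_pairs(config.pairs)
    pools = {region: load_pool_file(path) for region, path in config.pools.items()}
    for region, members in pools.items():
        unknown = set(members) - set(by_id)
        if unknown:
            raise CavepairsError(
                f"pool {region!r} lists species missing from the trait table: {sorted(unknown)}"
            )
    for p in pairs:
        if p["region_id"] not in pools:
            raise CavepairsError(f"pair {p['pair_id']} references unknown region {p['region_id']!r}")
        for sp in (p["species_a"], p["species_b"]):
            if sp not in by_id:
                raise CavepairsError(f"focal species {sp!r} missing from the trait table")
            if sp in pools[p["region_id"]]:
                raise CavepairsError(
                    f"focal species {sp!r} must not be a member of pool {p['region_id']!r}"
                )

    tree = Phylogeny.from_file(config.tree)
    with_data = [l for l in tree.tip_labels if l in by_id]
    if len(with_data) < tree.n_tips:
        tree = tree.prune_to(with_data)
    for p in pairs:
        for sp in (p["species_a"], p["species_b"]):
            if sp not in tree.tip_labels:
                raise CavepairsError(f"focal species {sp!r} is not a tip of the tree")

    rows = []
    details = []
    stage_seeds = {}
    for p in pairs:
        region = p["region_id"]
        pair = (p["species_a"], p["species_b"])
        log.info("region %s: stage 2/7 standardize (%s)", region, config.standardization_scope)
        if config.standardization_scope == "per_region":
            fit_recs = [by_id[s] for s in pools[region] + list(pair)]
        else:
            fit_recs = records
        profiles = {pr.species_id: pr for pr in standardize(records, fit_records=fit_recs)}
        pool_profiles = [profiles[s] for s in pools[region]]
        focal_a, focal_b = profiles[pair[0]], profiles[pair[1]]

        log.info("region %s: stage 3/7 virtual pool + null distances", region)
        ranges = trait_ranges(pool_profiles)
        vseed = subseed(config.seed, f"{region}:virtual_pool")
        stage_seeds[f"{region}:virtual_pool"] = vseed
        virtual = simulate_virtual_pool(ranges, config.n_virtual, vseed, region_id=region)
        nulls: dict[str, NullDistribution] = {}
        for trait_set in TRAIT_SETS:
            nseed = subseed(config.seed, f"{region}:{trait_set}:null_pairs")
            stage_seeds[f"{region}:{trait_set}:null_pairs"] = nseed
            nulls[trait_set] = sample_null_distances(
                virtual, trait_set, config.n_pairs, nseed
            )

        log.info("region %s: stage 4/7 comparative model fits (%s)", region, config.model)
        coord_values = _coordinate_traits(profiles)
        tree_region = tree  # same tree either scope; values differ
        fits = {
            name: _fit_coordinate(tree_region, values, config.model, name)
            for name, values in coord_values.items()
        }

        log.info("region %s: stage 5/7 ancestral reconstruction", region)
        sisters = {sp: sister_species(tree_region, sp) for sp in pair}
        estimates: dict[str, dict[str, list[AncestralEstimate]]] = {}
        for sp in pair:
            sister_pair = (sp, sisters[sp])
            per_set: dict[str, list[AncestralEstimate]] = {
                "body_size": [
                    reconstruct_ancestor(
                        tree_region, coord_values["body_size"], fits["body_size"], sister_pair
                    )
                ],
                "channel": [
                    reconstruct_ancestor(
                        tree_region, coord_values[name], fits[name], sister_pair
                    )
                    for name in CHANNEL_TRAITS
                ],
            }
            estimates[sp] = per_set

        log.info("region %s: stage 6/7 pair tests + divergence factors", region)
        for trait_set in TRAIT_SETS:
            null = nulls[trait_set]
            dmin, dmax = theoretical_extremes(pool_profiles, trait_set)
            extant = test_pair(focal_a, focal_b, null, config.alpha_level)
            anc_dist = {
                v: ancestral_pair_distance(
                    estimates[pair[0]][trait_set], estimates[pair[1]][trait_set], v
                )
                for v in ANCESTRAL_VARIANTS
            }
            div = divergence_report(pair, trait_set, extant.observed, anc_dist)
            for row_label, ptest, factor in [
                ("extant", extant, None),
                *[
                    (
                        f"ancestral-{v}",
                        test_distance(pair, anc_dist[v], null, config.alpha_level),
                        div.factors[v],
                    )
                    for v in ANCESTRAL_VARIANTS
                ],
            ]:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    norm, exceeds = normalize_distance(ptest.observed, dmin, dmax)
                rows.append(
                    {
                        "region": region,
                        "pair_id": p["pair_id"],
                        "trait_set": trait_set,
                        "row": row_label,
                        "distance": ptest.observed,
                        "p_value": ptest.p_value,
                        "p_label": ptest.p_label,
                        "process": ptest.process,
                        "p_similarity": ptest.p_similarity,
                        "p_difference": ptest.p_difference,
                        "normalized": norm,
                        "exceeds_theoretical": exceeds,
                        "divergence_factor": factor,
                    }
                )
        details.append(
            RegionDetail(
                region_id=region,
                pair=pair,
                sisters=sisters,
                fits=fits,
                estimates=estimates,
                nulls=nulls,
            )
        )

    table = pd.DataFrame(rows)
    table["row"] = pd.Categorical(table["row"], categories=ROW_ORDER, ordered=True)
    table = table.sort_values(["region", "trait_set", "row"]).reset_index(drop=True)
    table["row"] = table["row"].astype(str)

    if config.holm_adjust:
        log.info("stage 7/7: Holm adjustment across %d rows", len(table))
        table["p_holm"] = holm_adjust(table["p_value"].tolist())
        table["process_holm"] = [
            proc if padj <= config.alpha_level else "random"
            for proc, padj in zip(table["process"], table["p_holm"])
        ]

    provenance = {
        "package": "cavepairs",
        "version": __version__,
        "config": asdict(config),
        "stage_seeds": stage_seeds,
        "selected_models": {
            d.region_id: {name: f.model for name, f in d.fits.items()} for d in details
        },
        "sisters": {d.region_id: d.sisters for d in details},
    }
    return AnalysisReport(table=table, provenance=provenance, details=details)
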