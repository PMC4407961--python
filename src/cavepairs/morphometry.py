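"""Allometric standardization of amphipod morphometric traits and trait-space distances.

Two functional trait sets are analyzed for each species:

* **body size** — the species mean adult body length, in mm, used raw. Body size
  is a resource-use (trophic) axis; standardizing it against itself would be
  meaningless, so distances on this axis stay in mm.
* **ventral channel** — four linear measurements describing the gill-ventilation
  channel formed by the coxal plates and pereopod bases: ventro-distal lengths of
  coxal plates II and III and the widths of the bases of pereopods V and VII.
  Each measurement is regressed on body length across species (ordinary least
  squares on species means) and expressed as a standardized residual
  (residual / residual SD), removing the allometric size dependence. The
  resulting 4-vector is dimensionless.

Distances between species are Euclidean: the absolute body-length difference in
mm, or the 4-D norm of standardized-residual differences. Normalized distances
rescale an observed distance by the theoretical extremes achievable inside a
regional pool's trait bounding box.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CavepairsError,
    DegenerateRangeError,
    DegenerateRegressionError,
    InsufficientDataError,
)

#: ventral-channel measurements, in fixed coordinate order
CHANNEL_TRAITS: tuple[str, ...] = ("coxa2", "coxa3", "basis5", "basis7")

#: recognized trait sets for distance computations
TRAIT_SETS: tuple[str, ...] = ("body_size", "channel")

#: CSV header expected by :func:`load_trait_table`
TRAIT_TABLE_COLUMNS = (
    "species",
    "body_length_mm",
    "coxa2_mm",
    "coxa3_mm",
    "basis5_mm",
    "basis7_mm",
)


@dataclass(frozen=True)
class TraitRecord:
    """Raw species-mean measurements, all in mm, all strictly positive."""

    species_id: str
    body_length: float
    coxa2: float
    coxa3: float
    basis5: float
    basis7: float

    def __post_init__(self) -> None:
        for name in ("body_length",) + CHANNEL_TRAITS:
            value = getattr(self, name)
            if not (value > 0) or not math.isfinite(value):
                raise CavepairsError(
                    f"measurement {name!r} of species {self.species_id!r} must be "
                    f"strictly positive and finite, got {value!r}"
                )

    def channel_values(self) -> np.ndarray:
        return np.array([getattr(self, t) for t in CHANNEL_TRAITS], dtype=float)


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of one channel measurement on body length, across species means.

    ``residual_sd`` uses the n-2 denominator (two regression parameters).
    """

    trait_name: str
    slope: float
    intercept: float
    residual_sd: float
    n: int

    def residual(self, body_length: float, value: float) -> float:
        return value - (self.intercept + self.slope * body_length)


@dataclass(frozen=True)
class StandardizedProfile:
    """Species position in trait space: raw body size (mm) + 4 standardized residuals."""

    species_id: str
    body_size: float
    channel: np.ndarray

    def __post_init__(self) -> None:
        channel = np.asarray(self.channel, dtype=float)
        if channel.shape != (len(CHANNEL_TRAITS),):
            raise CavepairsError(
                f"channel vector must have {len(CHANNEL_TRAITS)} coordinates, "
                f"got shape {channel.shape}"
            )
        object.__setattr__(self, "channel", channel)

    def coordinates(self, trait_set: str) -> np.ndarray:
        """Trait vector on the requested axis set (1-D for body size, 4-D for channel)."""
        if trait_set == "body_size":
            return np.array([self.body_size], dtype=float)
        if trait_set == "channel":
            return self.channel
        raise CavepairsError(f"unknown trait_set {trait_set!r}")


@dataclass(frozen=True)
class DistanceSummary:
    """A pairwise Euclidean distance, optionally normalized to the pool's extremes."""

    pair: tuple[str, str]
    trait_set: str
    distance: float
    normalized: float | None = None
    exceeds_bounds: bool = field(default=False)


def load_trait_table(path) -> list[TraitRecord]:
    """Read the trait CSV (one row per species; a per-specimen dialect is averaged).

    Expected header: ``species,body_length_mm,coxa2_mm,coxa3_mm,basis5_mm,basis7_mm``
    with an optional ``n_specimens`` column. Missing values are an error — damaged
    measurements are excluded upstream, never imputed.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRAIT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise CavepairsError(f"trait table {path} lacks columns {missing}")
    if df[list(TRAIT_TABLE_COLUMNS)].isna().any().any():
        bad = df.loc[df[list(TRAIT_TABLE_COLUMNS)].isna().any(axis=1), "species"].tolist()
        raise CavepairsError(f"missing measurements for species {bad}; imputation is not supported")
    if df["species"].duplicated().any():
        counts = df["species"].value_counts()
        dup = counts[counts > 1]
        warnings.warn(
            f"per-specimen rows detected; averaging {dict(dup)} rows per species",
            stacklevel=2,
        )
        df = df.groupby("species", as_index=False, sort=False).mean(numeric_only=True)
    return [
        TraitRecord(
            species_id=str(row.species),
            body_length=float(row.body_length_mm),
            coxa2=float(row.coxa2_mm),
            coxa3=float(row.coxa3_mm),
            basis5=float(row.basis5_mm),
            basis7=float(row.basis7_mm),
        )
        for row in df.itertuples(index=False)
    ]


def write_trait_table(records: Iterable[TraitRecord], path) -> None:
    rows = [
        {
            "species": r.species_id,
            "body_length_mm": r.body_length,
            "coxa2_mm": r.coxa2,
            "coxa3_mm": r.coxa3,
            "basis5_mm": r.basis5,
            "basis7_mm": r.basis7,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def fit_allometry(records: Sequence[TraitRecord], trait_name: str) -> RegressionFit:
    """OLS regression of one channel measurement on body length across species.

    Raises :class:`InsufficientDataError` below 3 species and
    :class:`DegenerateRegressionError` when body length has zero variance. A
    perfectly collinear trait yields ``residual_sd == 0`` with a warning.
    """
    if trait_name not in CHANNEL_TRAITS:
        raise CavepairsError(f"unknown channel trait {trait_name!r}")
    if len(records) < 3:
        raise InsufficientDataError(
            f"insufficient data: {len(records)} species for {trait_name} regression (need >= 3)"
        )
    ids = [r.species_id for r in records]
    if len(set(ids)) != len(ids):
        raise CavepairsError("duplicate species_id in regression input")
    x = np.array([r.body_length for r in records], dtype=float)
    y = np.array([getattr(r, trait_name) for r in records], dtype=float)
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise DegenerateRegressionError(
            "degenerate regression: zero variance in body length"
        )
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (len(records) - 2)))
    if residual_sd <= 1e-12 * max(1.0, float(np.abs(y).max())):
        residual_sd = 0.0
    if residual_sd == 0.0:
        warnings.warn(
            f"degenerate fit: {trait_name} is perfectly collinear with body length",
            stacklevel=2,
        )
    return RegressionFit(trait_name, slope, intercept, residual_sd, len(records))


def standardize(
    records: Sequence[TraitRecord],
    fit_records: Sequence[TraitRecord] | None = None,
) -> list[StandardizedProfile]:
    """Standardize the four channel measurements; pass body length through as body size.

    The regression for each channel trait is fitted on ``fit_records`` (defaults
    to ``records``), then applied to every record, so a regional standardization
    can be extended to species outside the fitting pool (e.g. the full phylogeny).
    Across the fitting set each channel coordinate has mean 0 and SD 1 by
    construction.
    """
    scope = records if fit_records is None else fit_records
    fits = {t: fit_allometry(scope, t) for t in CHANNEL_TRAITS}
    profiles = []
    for r in records:
        channel = np.empty(len(CHANNEL_TRAITS))
        for k, t in enumerate(CHANNEL_TRAITS):
            f = fits[t]
            resid = f.residual(r.body_length, getattr(r, t))
            if f.residual_sd == 0.0:
                channel[k] = 0.0
            else:
                channel[k] = resid / f.residual_sd
        profiles.append(StandardizedProfile(r.species_id, r.body_length, channel))
    return profiles


def standardization_fits(records: Sequence[TraitRecord]) -> dict[str, RegressionFit]:
    """The per-trait regression fits behind :func:`standardize` (for provenance output)."""
    return {t: fit_allometry(records, t) for t in CHANNEL_TRAITS}


def euclidean_distance(
    a: StandardizedProfile, b: StandardizedProfile, trait_set: str
) -> float:
    """Euclidean distance between two species on a trait set (mm for body size)."""
    return float(np.linalg.norm(a.coordinates(trait_set) - b.coordinates(trait_set)))


def normalize_distance(d: float, dmin: float, dmax: float) -> tuple[float, bool]:
    """Rescale a distance to the pool's theoretical extremes: (d - dmin)/(dmax - dmin).

    Returns ``(value, exceeds_bounds)``. Values outside [0, 1] are legitimate —
    ancestral pairs can fall outside the extant pool's bounding box — and are
    flagged rather than clamped.
    """
    if not (dmax > dmin >= 0):
        raise DegenerateRangeError(
            f"degenerate range: need dmax > dmin >= 0, got dmin={dmin}, dmax={dmax}"
        )
    value = (d - dmin) / (dmax - dmin)
    exceeds = not (0.0 <= value <= 1.0)
    if exceeds:
        warnings.warn(
            f"normalized distance {value:.4g} falls outside [0, 1] "
            "(pair lies outside the pool's theoretical range)",
            stacklevel=2,
        )
    return value, exceeds


def theoretical_extremes(
    pool_profiles: Sequence[StandardizedProfile], trait_set: str
) -> tuple[float, float]:
    """Theoretical (min, max) Euclidean distance inside the pool's bounding box.

    The minimum is 0 (any two species can coincide inside overlapping ranges);
    the maximum is the diagonal of the per-coordinate min–max box.
    """
    if len(pool_profiles) < 2:
        raise InsufficientDataError("need at least 2 pool species for theoretical extremes")
    coords = np.array([p.coordinates(trait_set) for p in pool_profiles])
    spans = coords.max(axis=0) - coords.min(axis=0)
    return 0.0, float(np.linalg.norm(spans))


def summarize_pair(
    a: StandardizedProfile,
    b: StandardizedProfile,
    trait_set: str,
    pool_profiles: Sequence[StandardizedProfile] | None = None,
) -> DistanceSummary:
    """Distance between two species, normalized against a pool when one is given."""
    d = euclidean_distance(a, b, trait_set)
    if pool_profiles is None:
        return DistanceSummary((a.species_id, b.species_id), trait_set, d)
    dmin, dmax = theoretical_extremes(pool_profiles, trait_set)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm, exceeds = normalize_distance(d, dmin, dmax)
    return DistanceSummary((a.species_id, b.species_id), trait_set, d, norm, exceeds)
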