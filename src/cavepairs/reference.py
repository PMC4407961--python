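"""Published Euclidean distances for the two sulfidic-cave species pairs.

These are the reported trait distances for the coexisting amphipod pairs of
Movile Cave (Romania) and the Frasassi cave system (Italy): the extant pair and
the three ancestral reconstruction variants (lower / mean / upper, i.e.
reconstructed value -/+ its standard error). Body-size distances are in mm;
ventral-channel distances are in standardized-residual units. They serve as
*inputs* to the divergence-factor arithmetic — the raw morphometric tables
behind them are not redistributed here, so the absolute values cannot be
recomputed from scratch within this package.
"""

from __future__ import annotations

#: (region, trait_set) -> row -> Euclidean distance
PUBLISHED_DISTANCES: dict[tuple[str, str], dict[str, float]] = {
    ("movile", "body_size"): {
        "extant": 6.805,
        "lower": 7.01,
        "mean": 7.8,
        "upper": 8.59,
    },
    ("movile", "channel"): {
        "extant": 2.8166,
        "lower": 0.9876,
        "mean": 0.5494,
        "upper": 0.4197,
    },
    ("frasassi", "body_size"): {
        "extant": 3.775,
        "lower": 0.18,
        "mean": 0.25,
        "upper": 0.32,
    },
    ("frasassi", "channel"): {
        "extant": 3.386,
        "lower": 2.63,
        "mean": 2.69,
        "upper": 2.704,
    },
}

#: reported process label per (region, trait_set, row) — for layout comparisons
PUBLISHED_PROCESSES: dict[tuple[str, str], dict[str, str]] = {
    ("movile", "body_size"): {
        "extant": "competition",
        "lower": "competition",
        "mean": "competition",
        "upper": "competition",
    },
    ("movile", "channel"): {
        "extant": "competition",
        "lower": "random",
        "mean": "filtering",
        "upper": "filtering",
    },
    ("frasassi", "body_size"): {
        "extant": "random",
        "lower": "filtering",
        "mean": "filtering",
        "upper": "filtering",
    },
    ("frasassi", "channel"): {
        "extant": "competition",
        "lower": "random",
        "mean": "random",
        "upper": "random",
    },
}

#: published regional pool sizes (species counts of real, non-sulfidic pools)
POOL_SIZES = {"movile": 4, "frasassi": 7}
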