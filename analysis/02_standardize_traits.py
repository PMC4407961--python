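#!/usr/bin/env python
"""Allometric standardization of the study's raw morphometric table.

For each region, the four ventral-channel measurements are regressed on body
length across the regional pool plus the focal pair, and expressed as
standardized residuals; body size stays in raw mm. Writes per-region
standardized profiles (TSV) and the regression fits (JSON) to
results/standardized/.
"""

import json
from pathlib import Path

import pandas as pd

from cavepairs.morphometry import load_trait_table, standardization_fits, standardize
from cavepairs.pipeline import load_pairs, load_pool_file

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "results" / "study"
OUT = ROOT / "results" / "standardized"


def main() -> None:
    records = load_trait_table(STUDY / "traits.csv")
    by_id = {r.species_id: r for r in records}
    pairs = load_pairs(STUDY / "pairs.csv")
    OUT.mkdir(parents=True, exist_ok=True)

    for pair in pairs:
        region = pair["region_id"]
        pool = load_pool_file(STUDY / f"pool_{region}.txt")
        fit_recs = [by_id[s] for s in pool + [pair["species_a"], pair["species_b"]]]
        profiles = standardize(records, fit_records=fit_recs)
        rows = [
            {
                "species": p.species_id,
                "body_size_mm": p.body_size,
                "coxa2_std": p.channel[0],
                "coxa3_std": p.channel[1],
                "basis5_std": p.channel[2],
                "basis7_std": p.channel[3],
                "role": (
                    "focal"
                    if p.species_id in (pair["species_a"], pair["species_b"])
                    else ("pool" if p.species_id in pool else "outgroup")
                ),
            }
            for p in profiles
        ]
        df = pd.DataFrame(rows)
        df.to_csv(OUT / f"profiles_{region}.tsv", sep="\t", index=False,
                  float_format="%.6g")
        fits = standardization_fits(fit_recs)
        (OUT / f"allometry_{region}.json").write_text(
            json.dumps(
                {t: vars(f) for t, f in fits.items()}, indent=2, sort_keys=True
            )
            + "\n"
        )
        print(f"{region}: standardized {len(df)} species "
              f"({(df.role == 'pool').sum()} pool, 2 focal)")
        for t, f in fits.items():
            print(f"  {t}: slope {f.slope:.4f} mm/mm, intercept {f.intercept:.4f} mm, "
                  f"residual SD {f.residual_sd:.4f} mm (n={f.n})")


if __name__ == "__main__":
    main()
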