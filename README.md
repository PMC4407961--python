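# cavepairs

Eco-evolutionary trait analysis for coexisting cave amphipod species pairs.

Amphipods of the genus *Niphargus* independently colonized two sulfidic cave
systems in Europe (Movile Cave, Romania; the Frasassi caves, Italy), and in
each cave two species coexist. Two opposing assembly processes could shape
their morphology: **environmental filtering** (the harsh sulfidic habitat
admits only species with suitable traits, making co-occurring species more
similar than chance) and **competition / character displacement** (limiting
similarity drives coexisting species apart). `cavepairs` implements the
quantitative machinery to tell these apart for two functional trait sets — the
species mean adult **body size** (a trophic, resource-use axis, in mm) and the
4-dimensional shape of the **ventral channel** (coxal plate II/III lengths and
pereopod V/VII basis widths, the groove that channels oxygenated water over
the gills) — for both the extant species pairs and their reconstructed
ancestors.

## The methods at its core

1. **Allometric standardization.** Each channel measurement is regressed on
   body length across species means (OLS); traits enter the analysis as
   standardized residuals `r_i / s`, with `s` the residual SD (n−2
   denominator). Body size stays in raw mm.
2. **Virtual-species null model.** Real regional pools are small (4 and 7
   species), so a null distribution is simulated: 100 virtual species with
   each trait drawn uniformly between the pool's observed min and max, 1000
   random pairs of distinct virtual species, and their Euclidean distances.
   An observed pair gets two one-sided add-one empirical p-values,
   `p = (#{d ≤ or ≥ obs} + 1)/(n + 1)`, and a label: *competition* when it is
   significantly more different than the null, *filtering* when significantly
   more similar, otherwise *random*.
3. **BM/OU comparative model.** Tip traits are modeled as a multivariate
   normal induced by the phylogeny: Brownian motion with
   `cov(i,j) = σ²·s_ij` (shared root-to-MRCA path), or a root-conditioned
   Ornstein–Uhlenbeck process with
   `cov(i,j) = σ²/(2α)·e^{−α(t_i+t_j−2s_ij)}(1−e^{−2αs_ij})`, which nests BM
   as `α → 0`. Models are fitted by ML (GLS root state, closed-form σ²,
   profile likelihood over log α) and compared by AIC.
4. **Ancestral reconstruction.** The trait value at the first-level MRCA of
   each focal species and its sister is the GLS conditional expectation of the
   node state given all tips; its SE includes root-estimation uncertainty.
   Three variants (mean, mean ± SE) yield ancestral pair distances, the same
   null-model test applied to ancestors, and **divergence factors**
   `extant distance / ancestral distance`.

## Worked example

Real raw morphometric tables are not redistributed here, so the worked example
runs on a synthetic study with a planted truth (see `analysis/01` to `05` for
the full narrative). Generate a study and run the pipeline:

```bash
python analysis/01_simulate_study.py
python analysis/05_divergence_report.py
```

which prints (abridged; both focal pairs were planted at the 99.9th percentile
of their pool's pairwise distances, i.e. a competition-like pattern):

```
  region trait_set             row  distance     p_label     process  normalized  divergence_factor
frasassi body_size          extant  7.385505   p < 0.001 competition    0.999507                NaN
frasassi body_size ancestral-lower  1.911165   p = 0.474      random    0.258645           3.864398
...
  movile   channel          extant  3.182427 p = 0.00599 competition    0.729535                NaN
  movile   channel ancestral-upper  0.533232 p = 0.00899   filtering    0.122237           5.968182
```

Reading it: each region × trait set block has one *extant* row and three
*ancestral* rows (lower/mean/upper reconstruction variants). The extant pairs
are correctly flagged as more different than the null (`competition`,
`p < 0.001` meaning the observed distance exceeded all 1000 null draws), the
reconstructed ancestors sit much closer together (distances shrink, labels
drift toward `random`/`filtering`), and the divergence factor says how many
times further apart the extant species are than their inferred ancestors.
`normalized` rescales each distance by the pool's theoretical extremes
(0 = coincident, 1 = the pool bounding-box diagonal; ancestral pairs may exceed
the box and are flagged rather than clamped).

The same script also recomputes the divergence factors of the real cave pairs
from their published Euclidean distances (e.g. Movile ventral channel:
2.8166/0.9876 ≈ 2.85 and 2.8166/0.4197 ≈ 6.71; Frasassi body size:
3.775/0.32 ≈ 11.8 and 3.775/0.18 ≈ 21.0) — pure arithmetic on published
values, no raw data needed.

There is also a CLI for the individual stages:

```bash
cavepairs simulate --process competition --seed 7 --out study/
cavepairs run --config study/config.yaml --out report/
cavepairs test-pair --traits study/traits.csv --pool study/pool.txt \
    --species-a focal_a --species-b focal_b
```

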