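# Methods

This note records the models, the numerical choices, and the places where the
design was genuinely open, in the order the pipeline runs them.

## Trait sets and standardization

Each species is a point in two trait spaces: raw mean adult body length (mm)
and a 4-vector of ventral-channel shape coordinates (ventro-distal lengths of
coxal plates II and III, basis widths of pereopods V and VII). Channel
measurements are regressed on body length by ordinary least squares across
species means — one row per species; a per-specimen table is accepted and
averaged with a logged count — and each residual is divided by the residual SD
(n−2 denominator), so across the fitting set every channel coordinate has mean
0 and SD 1. Pereopod VI is deliberately not a trait (frequently damaged in
real material); missing measurements are an error at load time, never imputed.

Open choices made here:

* **Body size is analyzed in raw mm.** Standardizing size against itself is
  undefined, and published body-size distances are of body-length magnitude.
* **Standardization scope.** By default the regression is fitted per region on
  the regional pool plus the focal pair, then *applied* to every loaded
  species. Fitting per region keeps residuals comparable within the pool the
  null model resamples; applying the fitted transform to all species puts the
  whole phylogeny on the same scale, which the comparative stage requires. A
  `standardization_scope: global` switch fits on all species instead.
* **Degenerate regressions.** Fewer than 3 species or zero body-length
  variance is an error. A perfectly collinear trait (residual SD 0) is
  reported with a warning and standardizes to 0.

Distances are Euclidean: |Δ body length| in mm, or the 4-D norm of channel
residual differences (dimensionless). Normalized distances are
`(d − d_min)/(d_max − d_min)` with `d_min = 0` (overlapping ranges always
admit coincident points) and `d_max` the diagonal of the pool's per-coordinate
min–max bounding box. Neither extreme is defined by the source design, so both
are stated package choices; values outside [0, 1] (possible for ancestral
pairs) are flagged, never clamped.

## Virtual-species null model

Real regional pools hold 4 (Movile) and 7 (Frasassi) species — too few for a
resampling test over real pairs — so the null is simulated: each of `n_virtual
= 100` virtual species draws every trait independently and uniformly between
the pool's observed minimum and maximum; `n_pairs = 1000` unordered pairs of
distinct virtual species (sampled with replacement across draws, never within
a pair) give the null distance distribution. Focal (sulfidic) species are
excluded from the range-defining pool by the loader.

Empirical p-values use the add-one rule `p = (r + 1)/(n + 1)` for each side
(similarity: `d ≤ obs`; difference: `d ≥ obs`; ties count in both tails, so
`p_sim + p_diff ≥ 1`). A p at the floor 1/(n+1) is presented as the bound
`p < 1/n` (with 1000 pairs: `p < 0.001`), matching how an observation beyond
every null draw is conventionally reported. Classification at level α
(default 0.05): difference side significant → *competition*; else similarity
side significant → *filtering*; else *random*; the reported p is the winning
side. Both sides significant simultaneously is impossible for α < 0.5 and is
asserted. No multiple-testing correction is applied by default (the published
tables report raw p's); `holm_adjust: true` adds Holm-adjusted columns.

## BM/OU model and ancestral reconstruction

Tip traits are one draw from a multivariate normal on the rooted tree
(branch lengths mandatory and taken as given; no ultrametricization):

* BM: `cov(i,j) = σ² s_ij`, `s_ij` the depth of the MRCA of tips i, j.
* OU, root-conditioned with the root at the process optimum:
  `cov(i,j) = σ²/(2α) · exp(−α(t_i + t_j − 2 s_ij)) · (1 − exp(−2α s_ij))`.

The root-conditioned (non-stationary) form was chosen because it makes BM the
exact α → 0 limit, so the AIC comparison (k = 2 vs k = 3) is between nested
models; it also needs no ultrametricity. For fixed α the root state is the GLS
estimate and σ² is closed-form ML; α is profiled on a deterministic log grid
(33 points on [1e−6, 1e2]) followed by bounded scalar refinement between the
bracketing grid points — profile likelihoods in α can be flat, and the grid
keeps the search reproducible. Exact AIC ties resolve toward fewer parameters.
Each trait coordinate is fitted and reconstructed independently (univariate
analysis per trait; α is per-trait). Numerics: covariance factorizations go
through Cholesky with an explicit pivot-ratio singularity check (LAPACK can
silently pass a zero pivot); duplicate zero-distance tips are named in the
error.

Ancestral states are estimated only at first-level MRCAs (each focal species
with its sister tip, found as the tip sharing the deepest MRCA), because
reconstruction accuracy decays toward the root; requesting a node at the root
logs a warning. The node is one more Gaussian coordinate of the fitted
process at its depth: the estimate is the conditional mean given all tips
(fitted root plugged in) and the SE is the square root of the GLS *prediction*
variance — conditional variance plus the propagated variance of the estimated
root state. The plug-in conditional variance alone would be exactly zero at
the root, which is an artifact of treating the estimated root as known; with
the prediction variance, SE grows toward the root as it should, and a
zero-length branch still pins the estimate to its tip with SE 0. Under BM the
estimate is a weighted average of tip values with weights summing to 1
(checked numerically). Three variants — mean, mean ± SE applied
coordinate-wise and species-wise — feed the ancestral pair distances;
divergence factors are extant/ancestral per variant, undefined (reported as
such) when the ancestral distance is 0.

Exact numerical reproduction of the published *ancestral-row* distances is not
claimed: they depend on the original software's internal OU parameterization
and SE definition, which are not published. The factor arithmetic on the
published distances, the table layout, and the classification logic are
reproduced exactly. (One published number does not follow from its own table:
the Frasassi ventral-channel factor range is printed as 1.21–1.29, but the
printed distances give 3.386/2.704 = 1.25 for the lower end; this package
reports the ratios computed from the distances.)

## Synthetic study systems

The generator emulates exactly the structure the analysis assumes, so every
stage is testable without the (undistributed) real tables. What it does:

* **Trees**: ultrametric pure-birth trees (Exp(kλ) waiting times, uniform
  lineage splits). Extinction is omitted — nothing downstream uses it.
  Multi-region studies join each region's tree under a shared root
  (reciprocally monophyletic regions; the joined tree is no longer globally
  ultrametric, which the root-conditioned OU handles).
* **Traits on trees**: one multivariate-normal draw from the BM/OU covariance
  (Cholesky with a 1e−12 jitter).
* **Pools**: body size uniform on 4–16 mm (the span of European niphargid
  amphipods), channel residuals uniform on [−2, 2] (the plausible range of
  standardized residuals). Pool sizes 4 and 7 — the real pool sizes — are
  supported without degeneracy; the default is 100 so the exhaustive pool-pair
  distance distribution that anchors planted effects is well resolved.
* **Focal pairs**: placed so their distance sits at `effect_percentile` of the
  exhaustive pool-pair distance distribution (0 → identical vectors;
  99.9 → an extreme competition-like pair). Placement manipulates only trait
  vectors, not the tree — the null model is tree-free. Under `neutral` the
  focal pair is drawn uniformly from the *observed* pool ranges, i.e.
  exchangeable with the null model's virtual species; that is the definition
  of neutrality with respect to this test (drawing from the generator's true
  ranges would bake the small-pool range-underestimation bias into the
  "neutral" condition).
* **Raw tables**: `make_measurement_table` inverts standardization — body
  length is the body size; each channel measurement is intercept + slope ×
  length + scaled residual. Planted residuals are first orthogonalized
  against the design [1, length], which makes re-standardization an exact
  inverse at zero noise. Because a planted focal offset that correlates with
  body length would otherwise be absorbed by the allometric refit, planted
  (non-neutral) channel offsets are calibrated through the actual
  standardization round trip (a short fixed-point rescaling, ≤ 6 iterations)
  so the *re-standardized* focal distance hits the requested percentile.

What the generator does **not** emulate: measurement error correlated across
traits, non-uniform (e.g. clumped) pool trait distributions, phylogenetic
signal in pool membership, unequal specimen counts. Passing tests therefore
show the machinery is correct under the stated assumptions, not that real
cave faunas satisfy them.

## Pipeline determinism and problem sizes

Every stochastic stage derives its seed as `crc32(f"{seed}:{stage}") mod 2³¹`,
so changing one knob (e.g. `n_pairs`) does not perturb other stages, and a
rerun with the same config is byte-identical. Extant and ancestral pairs of a
region × trait set are located in the *same* null distribution.

Verification problem sizes, chosen to give tight Monte-Carlo error at
interactive runtimes: null-model calibration uses 2000 neutral replicates
(binomial SE ≈ 0.7 percentage points on a 10% rate) and 500 planted-pair
power replicates; OU parameter recovery and BM-vs-OU AIC selection use 50
replicates on 200-tip trees (median σ̂² within 25% of truth, median α̂ within
a factor 2, at the simulated depths of ≈ 5 time units with α = σ² = 1);
model-oracle agreement is checked to 1e−8–1e−10 on trees of ≤ 10 tips.

## Known limitations

* The OU fit assumes a single optimum equal to the root state; no
  multi-optimum (Hansen-model) regimes.
* Univariate fits ignore trait covariance; a multivariate comparative model
  could borrow strength across channel coordinates.
* The virtual-species null ignores correlation structure among traits in the
  pool (uniform and independent per trait, the only reading consistent with a
  per-trait min–max resampling design).
* Pool ranges estimated from 4–7 species underestimate true ranges; the test
  is calibrated against the estimated box, not the unknown true one.
* Tests with >2 co-occurring species, abundance-weighted nulls, and
  phylogenetically constrained nulls are out of scope.
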