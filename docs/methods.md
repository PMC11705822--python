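# Methods

Statistical definitions, the synthetic-survey model, and the numerical
choices behind `ciliateco`. Everything here is implemented in
`src/ciliateco/` and exercised by `tests/`.

## Sampling frame and habitat zones

A sample is one (station, season, depth) water bottle. Habitat zones
follow the bottom and sampling depths with strict 200 m cutoffs:

- **neritic** — bottom depth < 200 m;
- **upper oceanic** — bottom ≥ 200 m and sample depth < 200 m;
- **deep oceanic** — bottom ≥ 200 m and sample depth ≥ 200 m.

A bottom depth of exactly 200 m is oceanic; a sample at exactly 200 m in
oceanic water is deep oceanic. Samples below the seafloor are rejected.

Environmental variables are grouped for variation partitioning as
**physical** (Sal, Tem, pH, DO), **chemical** (Nox, SRP, Si) and **food**
(the chlorophyll size fractions MChla, NChla, PChla plus the picoplankton
counts Syn, Peuk, Pro). Total chlorophyll (Chla) is the sum of its size
fractions; it participates in correlation screens and Mantel tests but is
excluded from the food predictor set to avoid double-counting its
fractions.

## Alpha diversity

Richness is the count of taxa with positive abundance; Shannon entropy is
computed on within-sample proportions in natural log (bits selectable).
All-zero samples get NaN entropy — undefined, not zero. Group contrasts
use Tukey's HSD (studentized range, `scipy.stats.tukey_hsd`); with two
groups this reduces exactly to the pooled two-sided t-test.
Diversity–environment screens use tie-corrected Spearman correlation
(Pearson selectable) with cells masked at p > 0.05 and no multiplicity
correction — a deliberate screening convention, stated in the output.

## Beta diversity

Bray–Curtis dissimilarity (optionally on sqrt- or log1p-transformed
abundances) feeds:

- **NMDS** — SMACOF with isotonic regression, best of `n_starts` random
  starts, quality reported as Kruskal stress-1 in [0, 1];
- **ANOSIM** — R = (mean between-group rank − mean within-group rank) /
  (n(n−1)/4) over all pairwise distances with average-rank ties, p by
  label permutation;
- **Mantel** — Pearson (or Spearman) correlation of upper-triangle
  vectors, one-sided (positive association), p by joint row/column
  permutation of the second matrix.

All permutation tests take an explicit seed
(`numpy.random.default_rng`) and use the add-one rule
p = (exceedances + 1) / (n_perm + 1). Tests cross-check both statistics
against scikit-bio and against exhaustive enumeration on small instances.

## Constrained ordination and variation partitioning

**RDA** centers the (typically Hellinger-transformed) community matrix
and projects it on an orthonormal basis of the predictor span (QR with
column pivoting drops collinear columns); R² is the projected fraction of
the total sum of squares and is adjusted by Ezekiel's formula.
**CCA** uses the chi-square standardized residual matrix with
row-mass-weighted predictors; because Ezekiel's formula is biased there,
the adjusted R² uses the permutation correction
1 − (1 − R²)/(1 − mean(R²_perm)). Both match R `vegan` to ~1e-9 on shared
inputs (tested via `Rscript`).

**PCNM** spatial eigenvectors: great-circle (haversine, R = 6371 km)
distances between samples, truncated at the longest minimum-spanning-tree
edge among *distinct* station coordinates (repeat visits to a station must
not shrink the threshold); distances above the threshold are replaced by
4× the threshold; Gower double-centering and eigendecomposition keep only
positive-eigenvalue axes, unit norm, with a deterministic sign convention
(largest-magnitude element positive). On an equidistant transect, axis k
oscillates with k sign changes — coarse to fine spatial scales.

**Forward selection** is greedy on added R² with three guards:

1. a **global pre-test** — selection is attempted only if the full
   candidate model passes a permutation test at alpha. Without it the
   best-of-m marginal test is selection-biased and the pure-noise
   family-wise error of selecting anything cannot sit near alpha;
2. a **marginal permutation test** on each entering candidate, computed
   on the candidate residualized against the already-selected set (the
   statistic is the sum of squares explained; permutation preserves the
   candidate's norm, so scale cancels);
3. a **cumulative adjusted-R² cap** at the full model's adjusted R²,
   active from the second step onward. The cap exists to stop noise
   accumulation in later steps; at the first step a lone strong driver
   legitimately exceeds the noise-deflated full-model adjusted R² about
   half the time, so a literal first-step cap would reject true drivers —
   the first entry is already protected by guards 1 and 2.

Measured on pure-noise data, the type-I rate (≥1 variable selected) sits
at ~4–5% for alpha = 0.05.

**Variation partitioning** fits every union of 2 or 3 predictor sets,
converts each to adjusted R², and solves the inclusion–exclusion system
for unique and shared fractions. Negative fractions are reported as-is
(standard semantics — shared adjusted-R² fractions are not variances).
Fractions plus residual sum to 1 exactly.

## Co-occurrence networks

Taxa enter the network if present in at least 2 samples **and** exceeding
0.5% relative abundance in some sample. Edges are pairwise Spearman
correlations with **strict** thresholds: |rho| > 0.2 and p < 0.05 (a
correlation of exactly 0.2 is excluded; Benjamini–Hochberg adjustment is
optional). Nodes without edges are dropped; constant features are
excluded and recorded.

Modules come from seeded Louvain modularity maximization on the
unweighted graph, numbered 1-based by decreasing size. Topology
(mean local clustering; mean shortest path within the largest component)
is calibrated against an ensemble of Erdős–Rényi G(n, m) graphs with the
observed node and edge counts; the small-world coefficient is
sigma = (C/C_null)/(L/L_null). Levins' niche breadth B = 1/Σp² summarizes
how evenly a taxon spreads over samples. In the integrated network
(ciliates + phytoplankton + environmental variables), edges are classified
by endpoint types and cross-tabulated by feeding habit × phylum and
trophic type × variable group.

## Synthetic survey generator

The generator emulates a two-season shelf-to-basin survey:

- **Design** — 12 shelf stations (bottoms 50–180 m) and 19 basin stations
  (bottoms 300–1,500 m) on a west-to-east grid; standard depths
  0–1,500 m; a sample exists where the depth does not exceed the bottom;
  both seasons reuse one fixed station layout (real campaigns revisit
  nearly but not exactly the same set), giving ~210 samples per season.
- **Environment** — depth-profile templates per variable (temperature
  declining as a power law with a +3 °C summer offset; oxygen and pH
  declining; nutrients increasing, log-scale; chlorophyll fractions and
  picoplankton decaying exponentially below the euphotic zone with
  coastal enrichment), plus seeded lognormal/additive noise.
- **Community** — each taxon is assigned a driver: an environmental
  variable (Gaussian niche on the z-scored variable), season (a
  multiplier), space (smooth function of longitude), or nothing, in
  proportions 0.5/0.2/0.1/0.2 by default. Abundances are lognormal around
  the niche expectation (noise sd 0.6 log-units) with 25% zero-inflation.
- **Phytoplankton** — 40 taxa with their own profiles; a subset is
  *coupled* to ciliate taxa by blending the ciliate's log-signal into the
  phytoplankton's with weight `coupling`, scaled to at least a one
  log-unit amplitude (bloom-scale variability) so the transferred signal
  is not drowned by generator noise by construction.
- **Ground truth** — every taxon's driver, niche parameters and coupled
  pairs are written to `ground_truth.json` for validation.

Coupled-pair recovery as network edges is tested under an explicitly
detectable condition (coupling 0.7, noise sd 0.35, zero-inflation 0.05:
≥90% of pairs recovered over 50 seeds); under default noise the links are
intentionally only partially detectable, as in real surveys.

All randomness flows through per-stage `numpy.random.default_rng`
children of a single seed, so every table is reproducible from
`SimConfig`.

## Numerical and reproducibility choices

- Permutation p-values use the add-one rule and never equal zero.
- Per-stage pipeline seeds ({beta, vpa, network, integrated}) derive from
  a single `--seed` and stay below 2³¹.
- Output CSVs carry the configuration hash in a `#` header comment;
  identical configurations reproduce outputs byte for byte.
- Eigenvector signs (PCNM) and module numbering are made deterministic.

## Limitations

- The generator is a caricature: taxa respond to a single driver each,
  noise is homoscedastic on the log scale, and stations sit on a regular
  grid. It validates the inference chain, not oceanography.
- The diversity–environment screen deliberately applies no multiplicity
  correction; treat it as exploratory.
- CCA's permutation-corrected adjusted R² is itself a Monte-Carlo
  estimate and varies slightly with the seed and permutation count.
- NMDS stress around 0.29 on the default synthetic survey indicates a
  weakly 2-D structure; interpret the embedding qualitatively.
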