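# Methods

This note documents the models and algorithms implemented in
`wetareas`, the parameters that matter, the synthetic-data generator's
assumptions, and the design choices made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Wet-areas mapping (module `hydrology`)

The depth-to-water (DTW) index approximates depth to the water table at
each raster cell as the least cumulative-slope path cost to the nearest
hydrological source:

DTW = [Σᵢ (dz/dx)ᵢ · aᵢ] · x_c  (meters),

over 8-connected paths with dx = x_c (cardinal) or √2·x_c (diagonal)
and path factor a. The computation pipeline is:

1. **Depression filling** — priority-flood with an ε gradient
   (default ε = 10⁻⁶·x_c). After filling, every cell has a strictly
   descending 8-neighbor path to the boundary (or to nodata, which is
   treated as off-grid), which is what D8 routing requires. Cells
   outside depressions and flats are untouched.
2. **D8 flow directions** — steepest positive drop per unit distance;
   ties broken in the fixed clockwise order E, NE, N, NW, W, SW, S, SE
   for determinism. Cells with no lower neighbor are outlets only when
   they touch the boundary/nodata; elsewhere they are an error telling
   the caller to fill first. Because flow always goes strictly
   downhill, the flow graph is acyclic by construction.
3. **Flow accumulation** — topological (Kahn) accumulation of cell
   areas in hectares; a cell counts its own area, so accumulation ≥
   one cell everywhere and outlet cells jointly account for the whole
   grid area.
4. **Sources** — cells with accumulation ≥ λ (the flow-initiation
   threshold, hectares). Larger λ gives a subset of the sources of a
   smaller λ, so DTW is elementwise non-decreasing in λ. A λ that
   yields no source is an error for a single-threshold call and a
   logged skip inside the multi-threshold suite.
5. **DTW** — exact multi-source Dijkstra with step weight
   cost(Δz)/dx · a · x_c. In the default `rise_only` mode
   cost(Δz) = max(Δz, 0) walking away from the source, which keeps
   DTW ≥ 0 and reads as height above the water surface; `absolute`
   mode (|Δz|) is available for sensitivity analysis. All weights are
   ≥ 0, so the shortest-path solution is exact, and with a = √2 each
   diagonal step contributes exactly its elevation rise, preserving
   the meters interpretation. On a uniformly tilted plane DTW
   therefore equals the elevation difference to the stream — the
   closed form the tests check. The path factor a = 2 is exposed as a
   configuration option; the geometric reading (√2) is the default.

Nodata cells are barriers for both flow routing and DTW paths; cells
walled off from every source come back NaN with a logged count. The
suite (`dtw_suite`) runs filling/D8/accumulation once, computes DTW per
λ, and reports the pairwise Pearson correlation matrix of the DTW
rasters — the quantitative sense in which neighboring thresholds are
functionally equivalent.

## 2. Raster I/O (module `raster`)

One raster format is supported: the ESRI ASCII grid, chosen because it
is plain text and diff-able in tests. Grids are ≥ 2×2, row 0 is north,
indices are 0-based, cell centers sit at origin + ((col+0.5)·x_c,
−(row+0.5)·x_c). Elevations are held at full float precision and
written with 6 significant digits by default (configurable). No
projections, datums or tiling — out of scope.

## 3. Synthetic landscapes and communities (module `synthetic`)

**Landscape.** A tilted plane (base slope 0.01 eastward) plus 2–8 m
Gaussian hills and one meandering channel incised 2 m, on a 180×180
grid of 10 m cells (324 ha). The 10 m resolution is a deliberate
scaling choice: λ = 16 ha needs 1,600 upslope cells at 10 m but
160,000 at 1 m, and the coarser grid lets the full seven-threshold
suite run in seconds while preserving the hydrological structure
(mild relief, elevated blocks, an incised valley with a wet floor).
Hills are suppressed inside the channel corridor so incision is not
dammed; consequently depression filling changes the surface by less
than the incision depth.

**Forest types.** Cells are classified by DTW position: conifer on the
wettest cells (DTW ≤ 1.2 m), mixed in (1.2, 2.5], broadleaf above —
the drier-to-wetter ordering of boreal cover types. The breaks were
chosen so the conifer stratum spans roughly 0–1.2 m DTW; with a much
narrower band the within-conifer DTW gradient is too short for any
cover–DTW slope to be statistically identifiable at realistic noise.

**Plot design.** Three east–west compartments per forest type, 8–14
plots each, 111 plots total (34/38/39 by type), replicating the field
layout this kind of study uses. Within a compartment, plots sit at
evenly spaced DTW quantiles (one plot → the median-DTW cell). Quantile
stratification is this package's choice; field studies describe only
"capturing the moisture gradient".

**Community generator.** Two modes:

* `glmm` (default) — plot-level responses are drawn from the
  generating models directly: richness R ~ Poisson(exp(a + b·DTW +
  u_j)) (optional lognormal overdispersion), total cover via
  √cover = a + b·DTW + u_j + ε truncated at 0, and an
  inverse-Simpson target D from its own linear predictor (identity or
  log scale per forest type). Species identities are then sampled
  without replacement with probability ∝ Gaussian moisture-niche
  weight × forest-type affinity, and abundances follow a geometric
  series whose decay is solved (Brent root find) so the realized
  inverse Simpson equals D exactly; the best-suited species gets the
  largest share, which is what produces wet/moist/dry indicator
  structure. The plot total is floored at 0.1% *before* allocation so
  proportions — hence richness and diversity — are never distorted by
  the floor. D is clamped to its mathematical range [1, R]; with the
  default recovery settings this binds in < 3% of plots and shifts
  the diversity slope by about −0.003, well inside Monte-Carlo error.
* `niche` — the classical species-level model: presence ~
  Bernoulli(baseline × niche weight), cover = max_cover × niche ×
  affinity × lognormal noise, capped at max_cover. Responses emerge
  bottom-up; the generating slopes are then *not* exactly controlled,
  which is why the recovery experiments use `glmm` mode.

Default generating coefficients are the per-forest-type field values
(e.g. richness slope 0.07 on the log link; conifer cover slope −0.54
on the √ scale; diversity slope 0.52 for broadleaf on the identity
scale). Compartment random-intercept SD defaults to 0.15 per response;
cover residual SD 1.5 (√ scale); diversity residual SD 0.7. What the
generator does **not** emulate: spatial autocorrelation of species
beyond the DTW covariate, substrate/microhabitat effects, and
species-level temporal dynamics — so passing tests demonstrate the
statistical machinery, not field realism of any particular community.

## 4. Community statistics (module `community`)

Per plot: total cover = Σ covers; richness = #{cover > 0}; diversity =
inverse Simpson 1/Σp² (Hill order 2, an effective species number). An
empty plot returns (0, 0, 0) — field data genuinely contain zero-cover
quadrats. Wetness classes partition [0, ∞): wet [0, 0.5], moist
(0.5, 2], dry (2, ∞); the half-open convention closes the 0.5–0.6 m
gap the verbal field definition leaves.

Indicator species analysis follows Dufrêne–Legendre: IV = 100·A·B with
A the species' relative mean abundance in a class and B its relative
frequency there; each species is reported for its maximizing class
(the standard one-row-per-species layout). The null preserves class
sizes by permuting plots; the randomized mean/SD columns summarize the
permuted max-IV distribution, and p = (exceedances + 1)/(n_perm + 1).
Defaults: n_perm = 999, seed mandatory. Species accumulation curves
are permutation means of cumulative distinct-species counts.

## 5. Inference (module `inference`)

**Mixed models.** Y_ij = μ + β·DTW_i + e_j(i) with a single random
intercept per compartment. Gaussian responses: statsmodels MixedLM
with the Powell optimizer (REML for the reported coefficients and
variance components; an ML refit supplies the log-likelihood so AICc
is well defined across thresholds — the fixed-effects structure is
constant across λ, so REML Δ would also be defensible; ML is the
default and documented here). When a variance component sits on the
boundary the profiled covariance can be singular; the coefficient SE
then falls back to the GLS expression at the estimated components.
Poisson (log link) responses: maximum likelihood with 30-node
Gauss–Hermite quadrature over the random intercept, numerical-Hessian
SEs, Nelder–Mead polish if BFGS stalls. k counts every estimated
parameter (Gaussian 4, Poisson 3). Marginal R² = var(Xβ̂)/(var(Xβ̂) +
σ²_α + σ²_ε) is "variance explained by the fixed effect alone";
conditional R² adds σ²_α to the numerator; the Poisson latent-scale
residual variance uses the trigamma approximation ψ₁(λ̄) at λ̄ =
exp(mean linear predictor + σ²_α/2). Zero-valued responses are
excluded from log-scale fits (with a logged count) rather than
offset-shifted.

**Threshold selection.** ΔAICc = AICc_i − AICc_min per λ; supported
set {Δ < 2}; Δ ∈ [3, 7] flagged "considerably less" support and
Δ > 10 "very unlikely". Fits being compared must share n, response and
transform. In the pipeline, the overall selected λ is the one
supported for the most (forest type × response) pairs, ties to the
smallest λ.

**Composition.** Bray–Curtis d(u,v) = Σ|x_u − x_v|/Σ(x_u + x_v);
zero-cover plots are excluded (distance undefined) with a logged
count — whether such plots belong in composition analyses is genuinely
open, and exclusion is this package's documented choice. PERMANOVA
with a continuous covariate: G = −½·J·D²·J, rank-1 hat matrix from the
centered covariate, pseudo-F = tr(HGH)/[tr((I−H)G(I−H))/(n−2)],
R² = tr(HGH)/tr(G), permutation p with the add-one rule. Because
tr(G) is permutation-invariant, F is monotone in tr(HGH), so the
permutation comparison uses the numerator — this avoids 0/0 noise
when a covariate explains (numerically) all of tr(G), in which case
F is reported as infinite and R² as 1. Exhaustive enumeration of all
n! permutations is available for n ≤ 8. NMDS minimizes Kruskal
stress-1 by SMACOF majorization with isotonic regression
(scikit-learn backend), best of n_restarts random starts, coordinates
centered and principal-axis rotated. One-way ANOVA across forest
types uses Tukey-adjusted pairwise comparisons rendered as a
shared-letter display.

## 6. Pipeline and reproducibility (module `pipeline`)

A run is one YAML file: terrain (DEM path XOR landscape parameters),
plots (CSV path XOR community parameters), the λ list, DTW options,
permutation counts and a mandatory master seed. Every stochastic stage
draws a named child seed derived from the master seed (recorded in the
report), every intermediate artifact is written (rasters as ESRI
ASCII, tables as CSV), and the JSON report contains no timestamps or
absolute paths, so identical configurations produce byte-identical
reports. Stage failures surface with the stage name.

## 7. Numerical choices and known limitations

* D8 tie-break order, the ε fill gradient, and seeded permutations
  make every raster and every test bit-reproducible.
* Problem sizes used by the test suite and the acceptance script —
  25×25 oracle grids, a 180×180 landscape, 200 recovery replicates,
  100 selection replicates, 2,000 null calibrations at 199
  permutations — were chosen as the smallest designs at which the
  checked properties are statistically meaningful.
* Single-direction (D8) routing only; no D∞/MFD, breaching, or road
  enforcement. No real groundwater physics: DTW is a topographic
  index.
* The Poisson GLMM assumes a single random intercept; no crossed or
  nested random effects.
* Permutation p-values are exact only in enumeration mode; Monte-Carlo
  p has resolution 1/(n_perm + 1).
* The ISA permutation count of the original field workflow (PC-ORD
  "default settings") is unknown; n_perm = 999 here, a divergence of
  unknown size.
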