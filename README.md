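# wetareas

Wet-areas mapping from bare-earth DEMs and analysis of bryophyte
communities along the resulting soil-moisture gradient.

The package is aimed at landscape ecohydrologists and community
ecologists who want to (i) compute the cartographic **depth-to-water
(DTW) index** from an elevation model at a range of flow-initiation
thresholds and (ii) relate plot-level vegetation attributes — percent
cover, species richness, inverse-Simpson diversity, and species
composition — to that moisture gradient with the statistical machinery
standard in this literature: random-intercept mixed models ranked by
AICc, indicator species analysis, PERMANOVA and NMDS. Because suitable
public field datasets are rare, a first-class synthetic-data module
generates boreal-style landscapes and communities with *known*
generating parameters, so every stage of the workflow can be validated
end to end.

## The model at the core

**DTW index.** Each cell's depth to water (meters) is the least
cumulative-slope path cost to the nearest hydrological source:

    DTW = [ Σᵢ (dz/dx)ᵢ · aᵢ ] · x_c

summed over the steps *i* of an 8-connected path, with dx = x_c for
cardinal and √2·x_c for diagonal steps, path factor *a* (1 cardinal;
√2 diagonal by default, so a diagonal step contributes exactly its
elevation rise and the index keeps its meters reading; 2 is available
as an option), and cell size x_c. Sources are the cells whose D8
upslope contributing area reaches the flow-initiation threshold λ
(hectares); they have DTW = 0. Low λ predicts a wetter landscape than
high λ, and the seven conventional settings λ = 0.5, 1, 2, 4, 8, 12,
16 ha are the default suite. The stack is: priority-flood depression
filling (ε-gradient) → D8 steepest descent → flow accumulation →
source extraction → exact multi-source Dijkstra.

**Plot models.** For each response Y (cover on the √ scale, richness as
Poisson counts on a log link, inverse-Simpson diversity raw or logged):

    Y_ij = μ + β·DTW_i + e_j(i),   e_j ~ N(0, σ²_α)

with the forest compartment *j* as a random blocking intercept.
Gaussian responses are fitted by REML (ML refit for the likelihood);
Poisson models by maximum likelihood with Gauss–Hermite quadrature.
Fits at different λ are ranked by AICc (AICc = −2ℓ + 2k +
2k(k+1)/(n−k−1)); thresholds with ΔAICc < 2 form the supported set.
Composition is analysed with Bray–Curtis dissimilarities: PERMANOVA
against DTW as a continuous predictor (Gower-centered G matrix, 1-df
pseudo-F, permutation p), NMDS (Kruskal stress-1), and
Dufrêne–Legendre indicator species analysis across wet (0–0.5 m),
moist (0.5–2 m) and dry (> 2 m) DTW classes.

## Worked example

Simulate a landscape plus community, then analyse it:

```sh
wetareas simulate --outdir sim --seed 3
wetareas dtw --dem sim/dem.asc --lambda 4 --out dtw4.asc
wetareas fit --plots sim/plots.csv --response diversity --out fit.csv
wetareas permanova --plots sim/plots.csv --n-perm 199 --seed 2
wetareas nmds --plots sim/plots.csv --seed 2 --out coords.csv
```

prints

```
coef=0.8832 se=0.1069 p=1.447e-16 AICc=434.17
F=24.664 R2=0.185 p=0.005 (n_perm=199, excluded=0)
stress=0.1878 converged=True
```

i.e. on this simulated landscape, plot diversity increases by 0.88
effective species per meter of depth-to-water (deeper water table →
drier site → more even bryophyte assemblage), DTW explains 18.5% of
the compositional variation among the 111 plots (pseudo-F = 24.7,
permutation p = 0.005), and the two-dimensional ordination represents
the Bray–Curtis structure with stress 0.19.

The full workflow — DTW suite across all seven thresholds, per-forest-
type fits, AICc threshold selection, then ISA/PERMANOVA/NMDS at the
selected threshold, with every intermediate artifact and seed written
to disk — runs from a single YAML configuration:

```sh
wetareas run --config examples/run.yaml
```

The same API is available from Python (`wetareas.hydrology.dtw_suite`,
`wetareas.inference.fit_dtw_model`, `wetareas.pipeline.run_pipeline`,
…); see `docs/methods.md` for the modelling details and design choices.

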