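# distdecay

Distance decay of community similarity, taxonomically and functionally.

Community ecologists and biogeographers routinely ask how fast the
similarity between pairs of communities declines with the spatial or the
environmental distance separating them, and whether trait (functional)
composition decays differently from species (taxonomic) composition —
turnover among functionally redundant species produces taxonomic decay with
no functional decay, while strong environmental filtering of traits can do
the opposite.  `distdecay` implements that analysis as a tested, reusable
pipeline over a four-table dataset bundle (sites × species abundances,
species × traits, sites × coordinates, sites × environment), and ships a
synthetic metacommunity generator so the entire pipeline runs, and can be
validated, with no external data.

## What it computes

For communities *j*, *k* with shared feature content *a* and unique content
*b*, *c*, similarity is the Sørensen form

    S_jk = 1 − (b + c) / (2a + b + c)

with the exact decomposition β_total = β_repl + β_rich into replacement
(turnover) and richness-difference parts.  Taxonomic features are species
(counts, or min/remainder sums for abundances).  Functional features are
volumes of a 3-axis trait space (balanced Gower distance → PCoA) in which
each community is a Gaussian-kernel hypervolume; shared and unique volumes
come from Monte-Carlo set operations.

Per dataset, the decay along great-circle spatial distance (km) and
standardized environmental distance (rescaled to [0, 1]) is summarised by

* **strength** — ranked (Spearman) Mantel *r*, permutation-tested, signed so
  that positive *r* means decay; and
* **rate** — the slope of a quasi-binomial log-link GLM,
  E[S] = exp(β0 + β1·d), with positive slopes truncated to zero,

giving four Mantel *r* values and four slopes (taxonomic/functional ×
spatial/environmental).  A trait-shuffling null model (999 iterations by
default) yields standardized effect sizes: SES > 1.96 means functional
similarity decays faster than expected given the taxonomic decay.  Across
datasets, paired *t*-tests compare taxonomic vs functional Mantel *r*, and
boosted regression trees under Laplace loss model the decay rates from nine
dataset descriptors (latitude, spatial extent, realm, body size, dispersal
mode, taxonomic and functional γ-diversity, site and variable counts), with
relative influence, partial dependence, interaction statistics and
subsampling sensitivity.

See `docs/methods.md` for the full model description and numerical choices.

## Worked example

```python
from distdecay import SimulationParams, simulate_dataset, decay_suite

ds = simulate_dataset(SimulationParams(seed=3))   # 20 sites, 40 species
metrics = decay_suite(ds, seed=1, n_perm=99, n_samples=500)
print(metrics.summary())
```

prints

```
Distance decay metrics (occurrence data, dataset 'sim_seed3')
  taxonomic  x spatial      : Mantel r =  0.175 (p = 0.070), slope = -0.0004015
  taxonomic  x environmental: Mantel r =  0.485 (p = 0.020), slope = -0.2018
  functional x spatial      : Mantel r =  0.012 (p = 0.400), slope =  0
  functional x environmental: Mantel r =  0.378 (p = 0.010), slope = -0.1283
```

This simulated dataset couples traits to the environment at strength 0.5,
so both similarity facets decay along the environmental gradient (taxonomic
Mantel r = 0.485, functional 0.378; rates 0.20 and 0.13 per unit
environmental distance), while the spatial signal is weak at the default
150 km dispersal range: the taxonomic spatial slope is −0.0004 per km and
the functional spatial slope was positive and therefore truncated to 0 (no
functional spatial decay).

The same pipeline is scriptable from the shell:

```bash
distdecay simulate --out bundle/ --seed 3
distdecay run bundle/ --out results/ --seed 1        # similarities, distances, metrics
distdecay null bundle/ --out results/ --null-iters 999 --seed 1
distdecay meta metrics/ --out synthesis/             # t-tests + BRT across datasets
```

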