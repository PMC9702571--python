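# ripdiv

Multifaceted diversity of riparian bird communities along river
elevational gradients.

Riparian zones — the ribbons of habitat where a river meets its banks —
concentrate biodiversity in mountain landscapes, and bird communities
there respond to both the terrestrial (forest cover, vegetation
structure) and the fluvial (channel width, sinuosity, gravel bars) sides
of the ecotone. A recurring observation in river ecology is the
*mid-peak pattern*: diversity is highest at intermediate positions along
the upstream–downstream gradient. Testing that pattern properly requires
more than counting species, because functional and phylogenetic
diversity carry their own information but also track species richness
mechanically.

`ripdiv` is a reusable pipeline for this class of study. Given a
site × species abundance matrix, a species trait table, a phylogeny, a
site table (elevation, river identity, environmental columns) and a
conservation-status map, it computes per site:

- **Taxonomic diversity** — species richness `S` and the Shannon index
  `H' = −Σ pᵢ log₂ pᵢ`;
- **Functional richness** `FRic` — the convex-hull volume of the
  community in a Gower/PCoA trait space, standardized by the pool hull;
- **Faith's phylogenetic diversity** `PD` — the branch-length sum of the
  minimal subtree spanning the community (root included);
- **Standardized effect sizes** `sesFD`, `sesPD` — observed FRic/PD
  against a richness-constrained null model
  (`ses = (obs − mean_null) / sd_null`, 1000 randomizations that
  preserve each site's richness and abundance multiset exactly);
- **Blomberg's K** per trait with a tip-permutation significance test
  (`K = 1` expected under Brownian-motion trait evolution);
- **Conservation value index** `CVI = Σ log₁₀(aᵢ + 1) · eᵢ` with weights
  `eᵢ ∈ {1, 4, 8}` for unprotected / class-II / class-I species;
- **Gradient smooths** — penalized-spline fits of each diversity facet
  on elevation with shrunken river and river-direction intercepts
  (REML), plus peak location and hump/monotone classification;
- **Driver inference** — stepwise VIF filtering (threshold 4),
  all-subsets Gaussian mixed models (river random intercept), AICc
  ranking, and full model averaging over the ΔAICc ≤ 2 set with
  unconditional SEs and per-predictor relative importance.

A first-class synthetic-data module generates complete studies with the
structure this analysis assumes (six rivers, 481–912 masl, 47 species
with Gaussian elevational niches peaking at 700 masl, a Yule phylogeny,
Brownian-motion traits, environment columns correlated with elevation),
so the entire pipeline is testable without any field data.

## Worked example

```python
import pandas as pd
from ripdiv import PipelineConfig, SimulationConfig, run_full_analysis

cfg = PipelineConfig(simulation=SimulationConfig(seed=11), seed=11,
                     n_null_reps=999, n_perm=999, out_dir="results_run")
paths = run_full_analysis(cfg)
print(pd.read_csv(paths["gradient_peaks"]).to_string(index=False))
```

```
response shape  peak_elevation      edf
       S  hump             698 3.000644
 shannon  hump             691 2.852411
    FRic  hump             682 2.470857
      PD  hump             694 2.931379
```

All four diversity facets are classified hump-shaped with interior
peaks near the 700 masl optimum built into the generator; `edf` is the
effective degrees of freedom of each elevation smooth (1 = straight
line, up to k − 1 = 4). The per-site profile holds the raw and
standardized metrics:

```
site_id   S  shannon   FRic  FRic_raw      PD  sesFD  sesPD    CVI
R1_s01    4    1.837  0.200     0.076   9.570 -0.005 -0.597  3.386
R1_s02    4    1.936  0.192     0.073  10.340 -0.055 -0.107  3.687
R1_s03   10    2.948  0.609     0.230  18.434  0.450 -0.371  6.982
```

and the decoupling report shows why the SES step matters — raw FRic and
PD correlate strongly with richness while their standardized versions
do not:

```
 metric      r     p  n  decoupled
shannon  0.921 0.000 60      False
   FRic  0.714 0.000 57      False
     PD  0.916 0.000 60      False
  sesFD -0.106 0.432 57      False
  sesPD  0.064 0.628 60       True
```

The driver table for richness (`drivers_S.csv`) has the shape of a
model-averaged coefficient table — estimate, unconditional SE, normal
p-value, and relative importance (summed Akaike weight of the top-set
models containing the term):

```
term         response  Estimate     SE      p  importance
(Intercept)         S     7.817  0.284  0.000       1.000
Shrub               S     0.516  0.336  0.125       0.863
Lnum                S     0.954  0.384  0.013       1.000
Bar                 S     0.267  0.326  0.413       0.530
Sinuosity           S     1.274  0.460  0.006       1.000
H_SD                S     0.310  0.489  0.526       0.406
Bared               S    -0.083  0.205  0.686       0.239
Herb                S    -0.016  0.097  0.873       0.060
```

Here the mid-peaked habitat-heterogeneity columns (Lnum, Sinuosity)
come out significant because, in this synthetic run, richness is driven
by elevation and those columns share its hump — the "shared
environmental response" signature the pipeline is designed to expose.

The same stages are available from the shell:

```sh
ripdiv simulate --seed 11 --out study/
ripdiv all --out-dir results/ --seed 11
ripdiv diversity --community study/community.csv --traits study/traits.csv \
    --tree study/tree.nwk --sites study/sites.csv --status study/status.csv \
    --out profile.csv
```

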