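# fireweek

Weekly cycles in regional fire counts: Bayesian negative-binomial
regression with intrinsic-CAR spatial effects, DIC model selection, and
posterior contrast testing.

## The problem

Vegetation burning in sub-Saharan Africa is overwhelmingly anthropogenic —
fire is a land-management tool — so fire activity can inherit the seven-day
rhythm of human life even though no natural forcing has a weekly period.
If the regionally dominant religion prescribes a weekly day of rest, fire
counts should dip on Sunday in predominantly Christian regions and on
Friday in predominantly Muslim ones, and the dip should be sharpest where
burning is most closely managed (croplands).

`fireweek` implements that analysis as a reusable, tested pipeline for
anyone working with regional event counts and a contiguity structure:

* classify regions by dominant religion (Christian / Muslim / mixed, with
  exclusion rules for regions dominated by other traditions or lacking
  data) and by dominant anthrome (cropland / natural / rangeland / settled
  / mixed land use);
* model yearly weekday counts with a negative-binomial GLMM;
* select among candidate fixed-effect structures by DIC;
* test religion × weekday contrasts via posterior contour probabilities
  with Benjamini–Hochberg multiplicity adjustment;
* generate synthetic region systems with the same statistical structure,
  so every stage is testable without the original satellite/administrative
  data.

## The model

For region *i* (area `area_i`, religion *R*, anthrome *A*) and weekday
*W* ∈ {1=Mon, …, 7=Sun}, the yearly fire count `Y_iW` is negative binomial
with shape θ and mean `μ_iW`,

```
ln μ_iW = ln(area_i) + α0 + α_A + α_R + α_W + α_RW + α_RA + α_WA + α_RWA + z_i
```

with corner-constrained factor coding, `ln(area_i)` as offset (so the model
describes fire *density*), and `z` an intrinsic conditional autoregressive
(ICAR) field on the region contiguity graph with precision τ — an improper
Gaussian Markov random field with log-density
`((n−k)/2)·ln τ − (τ/2)·Σ_{i~j}(z_i − z_j)²`, identified by sum-to-zero
constraints per graph component. Posteriors are sampled with an in-package
adaptive Metropolis-within-Gibbs sampler (preconditioned MALA for the fixed
effects, graph-coloured single-site updates for `z`, conjugate gamma update
for τ, and likelihood-invariant translation moves along the fixed-effect /
spatial-field confounding ridge). Models are compared by
`DIC = D̄ + p_D`, and contrasts between religion × weekday cell means are
summarised by posterior means, sds, 95% credible intervals, and the
posterior contour probability of zero (one minus the content of the HPD
interval just covering zero), BH-adjusted across the 15-contrast family.

## Worked example

Simulate a 10×10 cropland lattice with rest-day deficits of −0.21 on the
log scale (three annual replicates), let DIC choose between the model with
and without the religion × weekday interaction, and test the contrasts:

```python
import fireweek as fw

cfg = fw.SimulationConfig(rows=10, cols=10, n_years=3,
                          anthrome_weights={"Cropland": 1.0}, seed=1)
records, graph, labels, panel, truth = fw.simulate_dataset(cfg)

table, best, fits = fw.select_model(
    panel, labels, truth.log_areas, graph,
    ["R + W + R:W + ICAR", "R + W + ICAR"],
    config=fw.MCMCConfig(seed=1),
)
print(table.round(2))
contrasts = fw.run_contrast_suite(fits[best.to_string()].samples, best)
```

Output:

```
             model      dic    p_d     dbar
R + W + R:W + ICAR 22577.94 107.30 22470.63
      R + W + ICAR 22579.40  95.34 22484.05

       contrast    mean     sd  ci_low  ci_high       p  p_normal    p_bh
Chr:Sun-Chr:Mon -0.2779 0.0750 -0.4221  -0.1325 0.00000   0.00021 0.00000
Chr:Sun-Chr:Tue -0.2675 0.0758 -0.4180  -0.1177 0.00050   0.00041 0.00107
Chr:Sun-Chr:Wed -0.3079 0.0741 -0.4532  -0.1588 0.00000   0.00003 0.00000
...
```

Reading this: DIC prefers the interaction model (lowest DIC wins; the gap
widens with the nine-year replication the generator uses by default), all
Christian Sunday-versus-weekday contrasts are negative — Sunday fire
activity is lower — with small contour probabilities (`p`), and the
BH-adjusted column (`p_bh`) controls the false discovery rate across all 15
tests. The `p_normal` column is the normal-approximation variant
`2Φ(−|mean|/sd)`, always reported alongside the KDE-based estimate for
transparency.

The same workflow is scriptable from the shell:

```bash
fireweek simulate --seed 1 --out-dir data/
fireweek classify --regions data/regions.csv --counts data/counts.csv --out-dir out/
fireweek select --regions data/regions.csv --counts data/counts.csv \
    --adjacency data/adjacency.csv --out out/model_table.csv
fireweek report --seed 1 --out-dir out/full        # full pipeline
```

`fireweek report` runs classify → global model selection (twelve-model
space) → per-anthrome selection (four-model space) → contrast suite on the
best cropland model, writing `crosstab.csv`, `model_table_*.csv`,
`contrasts.csv`, `weekday_minima.csv`, and a run log with the seed and
config hash.

## Layout

```
src/fireweek/
  region_data.py     # region table, adjacency graph, fire-count panel, CSV I/O
  classification.py  # religion/anthrome labelling, exclusion rules, crosstab
  model.py           # NB pmf, design matrices, ICAR density, log-posterior
  inference.py       # MCMC sampler, DIC, model selection, summaries
  contrasts.py       # cell-mean contrasts, contour probabilities, BH
  synthetic.py       # lattice generator, ICAR field sampler, fixtures
  pipeline.py        # end-to-end orchestration
  cli.py             # `fireweek` command-line interface
docs/methods.md      # modelling and design notes
```
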