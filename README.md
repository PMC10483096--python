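# hoiscan

Detecting higher-order interactions (HOIs) in small experimental food
webs from abundance time series.

## The problem

In a community of more than two species, the per-capita effect of one
competitor on another need not be fixed: a third species can modify it.
Such interaction modifications — higher-order interactions — are
distinct from interaction chains (indirect effects propagating through
fixed pairwise links) and change how well pairwise models predict
community dynamics. `hoiscan` implements a regression pipeline that asks
whether HOIs are detectable in protist microcosm experiments: a focal
pair of ciliate consumers (*Colpidium*, code `C`, and *Dexiostoma*, `D`)
cultured alone or with a third competitor (*Paramecium* `P` or
*Spirostomum* `S`), each combination also run with a top predator
(*Spathidium* `Pd`) — six treatments, four replicate microcosms each,
sampled every second day for 53 days.

## The method

For a focal species *i* the per-capita growth-rate response between
consecutive samples is

    r_i(t) = ( N_{i,t+Δt} / N_{i,t} ) / Δt

and six candidate models describe how r depends on community densities:

| model | form | K (2 sp) | K (3 sp) |
|---|---|---|---|
| additive LV | r = λ_i − Σ_j α_ij N_j | 4 | 5 |
| interactive LV (intra HOI) | … − Σ_j β_ijj N_j² | 6 | 8 |
| interactive LV (inter HOI) | … − Σ_{j<k} β_ijk N_j N_k | 5 | 8 |
| interactive LV (full HOI) | … − both HOI sums | 7 | 11 |
| additive Ricker | r = λ_i e^(−Σ_j α_ij N_j) | 4 | 5 |
| interactive Ricker | r = λ_i e^(−Σ α_ij N_j − Σ β_ijk N_j N_k) | 5 | 8 |

LV models are Gaussian GLMs with identity link (least squares), Ricker
models Gaussian GLMs with log link; K counts the intercept, the slope
coefficients and the Gaussian dispersion. Models are ranked by
small-sample AICc, and among models within ΔAICc < 2 of the best the one
with fewest parameters is the most parsimonious. Quadratic terms
(β_ijj N_j²) capture intraspecific HOIs — species *j*'s density
modifying its own per-capita effect — and cross-products (β_ijk N_j N_k)
interspecific HOIs. Persistence is analysed separately: time to
extinction per microcosm (zeros sustained to the end of the series, else
right-censored at day 53), Kaplan–Meier curves, and (pairwise) log-rank
tests across community compositions. Mean abundances are compared with a
two-way linear model (third-species identity × predator presence) on
log10(mean + 1).

Because the pipeline needs data with known ground truth, the package
ships a synthetic microcosm generator: discrete-time LV/Ricker dynamics
with optional HOI terms, multiplicative lognormal process noise, an
absorbing extinction threshold, scheduled predator introductions, and a
Poisson subsample-counting observation layer (three 250 µL subsamples,
density = mean of the three counts, explicit zeros).

## Worked example

```python
import hoiscan as h

table = h.generate_study(h.default_study_params(), obs=h.ObservationParams(),
                         replicates=4, seed=42)

reg = h.growth_table(table, "C", "CDS")          # 104 growth observations
fits = h.fit_all_models(reg, focal="C", community="CDS")
sel = h.select_model(fits)
print(sel.rows[["model", "K", "AICc", "dAICc"]].to_string(index=False))
```

```
               model  K        AICc     dAICc
         additive_LV  5 -295.027599  0.000000
  interactive_Ricker  8 -293.305950  1.721649
interactive_LV_inter  8 -290.674807  4.352792
     additive_Ricker  5 -290.531197  4.496402
interactive_LV_intra  8 -290.313390  4.714209
 interactive_LV_full 11 -283.910565 11.117034
```

Both the additive LV (K=5) and the interactive Ricker (K=8) fall within
ΔAICc < 2, so the parsimony rule selects the additive LV — in this
seed's CDS community the interspecific HOI built into the generator is
too weak relative to process noise to be declared. The fitted
coefficients of the winner (positive α = suppression):

```python
best = {f.spec.name: f for f in fits}[sel.most_parsimonious_model]
print(best.summary())
```

```
Additive LV | focal C | community CDS
  link=identity  n=104  K=5  loglik=152.820  AICc=-295.028  converged=True
  lambda = 1.01564
  alpha[C] = 0.000588204
  alpha[D] = 0.000131332
  alpha[S] = -0.00064319
```

Persistence of *Colpidium* across the predator-free communities:

```python
groups = h.survival_by_treatment(table, "C", ["CD", "CDP", "CDS"])
lr = h.logrank_test(groups)        # stat=13.990, df=2, p=0.0009
km = h.km_estimate(groups["CD"])   # S(53) = 0.0: C excluded in all 4 CD runs
```

Community composition strongly affects *Colpidium* persistence in the
synthetic study: it is competitively excluded by *Dexiostoma* when the
two are alone, and rescued by a third competitor.

The same stages are available from the shell
(`hoiscan simulate / growth-rates / fit / select / survive / abundance`),
and `hoiscan run` executes the whole pipeline from a YAML config into a
directory of CSV/JSON artifacts with a reproducibility manifest.

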