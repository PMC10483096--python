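# Methods

## Growth-rate response

The regression response for focal species *i* over one sampling interval
is the density ratio scaled by the interval, r = (N_{t+Δt}/N_t)/Δt, in
units of day⁻¹. A population is stationary at r·Δt = 1 (r = 0.5/day on
the default two-day grid). Two conventions are implemented because the
literature uses both: the plain ratio (default — it is the quantity the
model equations describe, and it is non-negative, which the log-link
Ricker fit benefits from) and the log-ratio ln(N_{t+Δt}/N_t)/Δt. Under
the ratio convention a transition landing on zero is a valid response
(r = 0); a transition *starting* at zero is undefined and dropped under
both conventions. Covariate densities are taken at the interval start,
the standard discrete-map convention. Replicate microcosms of a
community are pooled with no random effects: the unit of inference is
the (focal species, community) pair. Predator treatments are excluded
from interaction-strength fitting by default because predators cause
early extinctions that leave too few informative transitions.

## Model suite and fitting

Six models are compared per (focal, community): additive
Lotka–Volterra, three interactive LV variants (intraspecific HOI terms
N_j², interspecific HOI terms N_jN_k, or both), additive Ricker, and
interactive Ricker (interspecific HOI only). LV models are linear in
densities and fitted by ordinary least squares (identical to a Gaussian
GLM with identity link). Ricker models are fitted as Gaussian GLMs with
log link via IRLS (statsmodels), started from least squares on the log
of the response clipped below at 10⁻³ times its smallest positive
value, with convergence tolerance 1e-10 and at most 200 iterations.
Gaussian errors with a log link accept zero responses as-is, so no
observations are discarded for the Ricker fits.

Reported coefficients follow the suppression sign convention: the model
subtracts α- and β-terms from λ, so raw regression slopes are negated
and a positive α_ij means species *j* depresses the growth of *i*. For
the log link, λ̂ = exp(intercept).

The interspecific-HOI sum runs over all unordered pairs of distinct
community members, including pairs containing the focal species. This
is what makes the inter-HOI model the same size (K = 8 in a
three-species community) for both focal species, and it is the reading
consistent with the published parameter counts for this model family; a
stricter variant that drops pairs whose second member is the focal
species is available via `inter_pairs="exclude_focal_k"`.

Both links maximise the same Gaussian likelihood, so their
log-likelihoods are comparable; the residual variance uses the MLE
denominator n (not n − p), matching likelihood-based information
criteria, and is floored at 1e-12 so a model that interpolates the data
exactly (noiseless fixtures) keeps a finite log-likelihood. K counts
the intercept, every slope, and the dispersion: K = 2 + #slopes. A
design whose columns are exactly collinear raises an error naming the
redundant columns; a design with more coefficients than observations
yields a non-converged result so the remaining five models can still be
compared.

## Model selection

AICc = −2ℓ + 2K + 2K(K+1)/(n−K−1), with n the number of pooled growth
observations (the studies this emulates do not report a per-fit n; the
pooled count is the natural choice since all six models are fitted on
the identical observation set, and n > K + 1 is enforced). Models
within ΔAICc < 2 of the best are treated as equivalently supported and
the one with fewest parameters wins; ties on K break by lower AICc,
then by a fixed model-name order, so selection is deterministic.
Non-converged fits are excluded from the ranking and listed, rather
than assigned infinite AICc, so a model can never win merely because a
competitor crashed silently.

## Survival analysis

Extinction is scored conservatively: the event time is the first
sampled day of the terminal all-zero run of the observed series. A
single zero followed by a positive count is treated as a detection
failure (a 250 µL subsample of a sparse culture can easily miss every
individual), not a rebound from extinction. Units still positive at the
last sample are right-censored at day 53. A species never detected at
all in a microcosm is assigned an event at the first sampling day after
time zero, the earliest resolvable time.

Kaplan–Meier estimates use the product-limit formula with 95% bands
from the Greenwood variance on the log-survival scale,
S·exp(±1.96·√var(log S)). The k-group comparison is the standard
log-rank chi-square with df = k − 1; pairwise comparisons default to
Benjamini–Hochberg adjustment (configurable to none, since practice
varies). The chi-square p-value is asymptotic: at four replicates per
group it approximates the exact permutation p to within about 0.1, so
survival p-values on this design are indicative rather than exact —
the test suite checks the approximation against full enumeration.

## Abundance effects

Each microcosm contributes one mean density per species (all sampling
days, zeros included). Effects of community composition are estimated
by a two-way linear model with interaction: third-competitor identity
(levels none / P / S, baseline none — the baseline level is needed so
"adding Paramecium" is expressed relative to the two-species community)
crossed with predator presence, on log10(mean + 1) by default. The
transform is configurable because reported effect sizes in this
literature are log-scale but the exact base and offset are rarely
stated; log10 with a +1 offset handles exact zeros. Coefficients come
with normal-theory 95% CIs and type-II F tests.

## Synthetic microcosm generator

The generator inverts the response convention: densities advance as
N_{t+Δt} = N_t · max(r(N_t), 0) · Δt · ε. The clamp at zero is needed
because the discrete LV map is unbounded below; ε is lognormal with
median 1 and scale σ_proc (multiplicative noise keeps densities
non-negative and mimics demographic stochasticity; default σ_proc =
0.05). Densities below the extinction threshold (default 0.01/mL, one
individual per assumed 100 mL culture) become exactly zero and stay
zero. The sampling grid is {0, Δt, 2Δt, …} up to the largest multiple
of Δt ≤ horizon — 27 sampling days for Δt = 2 and a 53-day horizon
(whether day 53 itself is sampled is ambiguous on a two-day grid; the
uniform-grid choice is configurable). Consumers start at 10% of their
carrying capacity; the predator starts at zero and is injected as
individuals/volume on scheduled days (default: ten individuals into
100 mL on days 4 and 8).

Observation mimics subsample counting: per record, `n_subsamples`
(default 3) Poisson counts with mean density × 0.25 mL, each converted
back to a density, averaged; all-zero counts give an exact zero.

Default study parameters are chosen to be realistic for ciliate
microcosms, not estimates of any real system: carrying capacities 1200
(C), 2500 (D), 120 (P), 40 (S) and 20 (Pd) individuals/mL — small-bodied
species reach thousands per mL, the large *Spirostomum* tens; intrinsic
responses 0.4–1.2/day; each species' self-limitation places its
monoculture equilibrium at its carrying capacity; cross-competition is
20–30% of self-limitation except that *Dexiostoma* suppresses
*Colpidium* at 90%, so C tends toward competitive exclusion in the
two-species community and persists longer with a third competitor. The
predator consumes all ciliates (prey density boosts its growth, its
density depresses prey growth) with an explicit self-limitation of 0.05
per (ind/mL) bounding it at a few tens per mL. The CD community carries
an intraspecific HOI (D modifies C's self-limitation) and the CDS
community an interspecific one, so the synthetic study exercises every
model family; CDP runs on pure additive Ricker dynamics. With process
and counting noise at their defaults, these built-in HOIs are weak
enough that selection does not always recover them — which is
realistic, and the reason the calibrated recovery-rate experiments
below exist.

What the generator deliberately does not emulate: bacterial resource
dynamics, predator functional responses beyond linear LV coupling
(no Holling saturation), species misclassification, volume loss from
repeated sampling, or temporal parameter drift. Passing tests therefore
show the inference machinery is correct under its own assumptions, not
that real microcosms satisfy them.

## Validation experiments

`hoiscan.validation` fixes a two-species benchmark (unequal competitors,
asymmetry keeps the design matrix full-rank in noiseless runs) used by
the test suite and the acceptance script alike: (1) noiseless data
refit by the generating model recovers every coefficient to round-off;
(2) under σ_proc = 0.05, coefficient RMSE over 200 simulated studies
falls when the pooled transition count doubles (2 vs 4 replicate
microcosms, ≈52 vs ≈104 transitions); (3) parsimony selection recovers
the generating model class — a no-HOI model for additive truth, an
HOI-containing model for full-HOI truth with HOI load about half the
self-limitation load — in at least 70% of 200 studies per scenario.
Problem sizes (200 replicates, 4 pooled microcosms, 27-day grid) keep
each experiment under a minute on one CPU while holding the Monte-Carlo
error on a 70%-gate to a few percent.

## Known limitations

- Process noise enters the regression multiplicatively
  (r_obs = r_true·ε) while the Gaussian GLM assumes additive errors;
  at σ_proc ≈ 0.05 the induced bias (E[ε] ≈ 1.001) is negligible but it
  grows with σ.
- Pooling replicates ignores between-microcosm heterogeneity; no
  random-effects variant is provided.
- Observation error in the covariates (densities measured with
  counting noise appear on the right-hand side) attenuates coefficient
  estimates; the state-space treatment that would correct this is out
  of scope.
- The log-link Ricker likelihood is not concave in general; IRLS from
  the log-least-squares start has converged in all tested scenarios,
  but a non-converged fit is reported rather than silently retried.
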