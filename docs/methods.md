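# Methods

## The model

For each gene *g* and de novo variant class *v* ∈ {LGD, Dmis}, the observed
count d<sub>gv</sub> in a cohort of *N* trios is modelled as a two-component
mixture over the latent risk status y<sub>g</sub>:

```
pi_g  = f_E(x_g)                      # prior risk probability from expression
y_g   ~ Bernoulli(pi_g)
y_g=0 : d_gv ~ Poisson(M_gv)                               M_gv = 2 N mu_gv
y_g=1 : gamma_gv ~ Gamma(mean gamma_bar_v, rate beta_bar_v)
        d_gv ~ Poisson(gamma_gv M_gv)
```

Marginalising the relative risk gives the closed-form negative-binomial
(Gamma-Poisson) alternative likelihood
NB(d; size = γ̄β̄, p = β̄/(β̄+M)).  Classes are conditionally independent
given y<sub>g</sub>, so their log-likelihoods add.  The posterior probability
of association is

PPA<sub>g</sub> = π<sub>g</sub>P<sub>alt</sub> /
(π<sub>g</sub>P<sub>alt</sub> + (1−π<sub>g</sub>)P<sub>null</sub>),

and the Bayesian FDR of the top-*k* list (genes ranked by decreasing PPA) is
the running mean of 1−PPA.  All likelihood arithmetic is in log space with
log-sum-exp mixtures.

The Gamma is parameterised by (mean relative risk γ̄, rate β̄), the
TADA/extTADA reporting convention, with shape γ̄β̄ and scale 1/β̄.  γ̄ is
restricted to > 1 under the alternative; the model is weakly identified as
γ̄ → 1 (alternative collapses onto the null), which the truncation avoids.

## Expression-informed priors

**Bulk (scalar covariate).**  With x the expression rank percentile in
[0, 1],

```
pi_g = pi_bar * Sigmoid(x | A, B, C)
Sigmoid(x) = C + L / (1 + exp(A (B - x)))
L = (1 - C) A / (log(e^A + e^{AB}) - log(e^{AB} + 1))
```

L is the exact constant making the sigmoid integrate to 1 on [0, 1], so
π̄ is the average prior across genes and the sigmoid doubles as a proper
density (used by the simulator through its analytic CDF).  A is the
steepness (numerically stable to A ~ 1e4 via log-sum-exp and `expit`), B the
inflection point on the rank scale, C the floor.  A variant of this formula
with the steepness multiplying the exponential instead of sitting in the
exponent circulates; only the form above is consistent with the normaliser
L, so that is what is implemented.

**Single cell (vector covariate).**  With x the per-(timepoint, cell-type)
fraction-of-cells-expressing vector, π<sub>g</sub> = f_E(x<sub>g</sub>) is a
small feed-forward network: Linear(C, 32) → ELU → LayerNorm (encoding
block), then Linear(32, 2) → ELU (sampler block), softmax over the two class
scores.  The sampler block deliberately carries no layer norm: layer
normalisation of a 2-vector equals the sign of the score difference
((a−mean)/std = ±1 for n = 2), which collapses the output to two constants
and kills the gradient — we verified that a sampler with layer norm trains
to the label base rate for every gene.  Bias terms everywhere; weights
initialised N(0, 1/fan_in) from the run seed.

## Inference

**Bulk: posterior sampling.**  The risk indicator is marginalised
analytically, leaving 8 free parameters (π̄, A, B, C, γ̄, β̄ per class) or 5
for the uniform-prior (expression-free) baseline, the extTADA-style
comparator.  Sampling uses an affine-invariant ensemble sampler (32 walkers,
2000 iterations, first half discarded as warm-up; walkers serve as chains
for the split-R̂/ESS diagnostics, computed with arviz).  Hyperpriors
(weakly informative, overridable in `BulkFitConfig.hyperpriors`):

| parameter | prior | note |
|---|---|---|
| π̄ | Beta(1, 9) | mean 0.1, mass at small proportions |
| γ̄ (each class) | Exponential(mean 20), truncated > 1 | matches plausible relative-risk magnitudes |
| β̄ (each class) | Gamma(2, 2) | mean 1; zero density at 0 (see below) |
| A | half-Normal(200) | |
| B, C | Uniform(0, 1) | |

The β̄ prior must vanish at 0: as β̄ → 0 the NB marginal puts probability
→ 1 on d = 0 for any M, so a half-normal (positive density at 0) lets
no-signal data be absorbed by an infinitely overdispersed "risk" component
with π̄ → 1.  Gamma(2, 2) removes that singularity; with all-zero counts the
fitted π̄ then stays near the lower range of its prior, as it should.

A fast MAP path (`method="map"`, Nelder-Mead on log/logit-transformed
parameters, 3 restarts) provides point estimates for replicate-heavy power
studies; PPA/FDR tables from a fit are always computed at the posterior
means (or the MAP point).

**Single cell: semi-supervised variational training.**  The loss is the
negative ELBO, Σ<sub>g</sub> KL[Bern(π<sub>g</sub>)‖Bern(π̄)] −
[π<sub>g</sub> log P<sub>alt</sub> + (1−π<sub>g</sub>) log P<sub>null</sub>],
with the expectation over the binary y taken exactly (two-term sum) rather
than by Monte-Carlo reparameterisation — same objective, zero estimator
variance.  The KL anchor π̄ is a required input, in practice the mixture
proportion estimated by the uniform-prior baseline; both a much larger or a
much smaller anchor degrades false-discovery calibration.  Training is
two-phase (defaults): 50 epochs of cross-entropy pretraining on labelled
genes (known risk genes positive, genes with LGD variants in controls
negative) at lr 1e-2, then 60 epochs of unsupervised ELBO on all genes at
lr 1e-3 decaying ×0.95 per epoch, full-batch Adam.  (γ̄, β̄) are learned
only in the unsupervised phase, on the log scale for positivity,
initialised from the baseline fit.  The learning rates, decay and optimizer
are not externally constrained; they were fixed once at conventional values
and are exposed in `TrainingConfig`.  Everything is plain numpy with
hand-written backpropagation, verified against central finite differences
in the test suite.

After training, PPA uses the learned π<sub>g</sub> and (γ̄, β̄); the FDR
table is produced both over all genes and with the training-label genes
removed (the labelled known-risk genes would otherwise occupy the top of
the ranking and distort discovery counts).

## Simulators

**Bulk scenario.**  3.7% of genes are risk genes; risk-gene covariates are
drawn from the sigmoid density by inverse-CDF on a 10,001-point grid using
the analytic CDF, non-risk covariates Uniform(0, 1); counts from the
generative model with truth γ̄ = 20 (LGD) / 12 (Dmis), β̄ = 0.84 / 0.90 and
sigmoid truth (A, B, C) = (104.15, 0.74, 0.28) — the posterior means of a
published congenital-heart-disease-scale fit, giving the characteristic
"high-expression genes ~3× more likely to be risk" enrichment.  Cohort
sizes 2,645–20,000 trios.

Per-gene per-class mutation rates come from a truncated log-normal:
log10 μ ~ N(−5.8, 0.6) on [−8, −3.5].  The mean was chosen to match
published class-specific (LGD / damaging-missense) background-rate tables
(median class rate ≈ 1.6e-6) and reproduces the realistic discovery regime:
at 2,645 trios recall at FDR ≤ 0.05 is ~10%, rising to ~35% at 10,000 —
the regime in which an expression-informed prior has room to add power.  A
synthesizer centred an order of magnitude higher (appropriate for a gene's
*total* de novo rate, not a class rate) drives recall above 80% at cohort
10,000 and saturates both models.  A real rate table can be supplied
instead (`rate_table` / `--rates`).

**Single-cell scenario.**  The risk prior is a non-linear function of a
fraction-expressing matrix, built exactly as in the study design: SVD of
the centred labelled-gene submatrix (59 positives / 86 negatives), project
all genes onto the components explaining ≥ 95% of labelled-gene variance,
elastic-net logistic regression on the labelled genes (mixing 0.5, penalty
by 5-fold CV), predicted probabilities squared then linearly scaled to mean
0.032 and clipped at 1 (order: square → scale → clip).  Risk genes are
drawn once from this prior (~600 at atlas scale) and held fixed across
replicates; counts are redrawn per replicate at 16,616 trios with the same
relative-risk truth as the bulk scenario (the class-specific values for the
original cohort are not published).  ~100 risk and ~300 non-risk genes are
emitted as semi-supervision labels and excluded from evaluation.

Because real single-cell data are not bundled, the package also synthesises
a fraction-expressing matrix (`synthesize_expression_matrix`): genes load
on a few latent co-expression programs, cell types mix the programs, and
loadings are squashed into [0, 1]; a risk-like gene subset shares elevated
loadings on two programs and supplies the 59/86 label lists.  This captures
the property the method exploits — labelled genes and co-expression
structure jointly predictive of risk — but not dropout noise, library-size
variation, batch structure, or realistic cell-type proportions; passing
tests therefore demonstrate correct inference under the model's
assumptions, not performance on any particular real atlas.

## Evaluation conventions

Realized FDP at a nominal cutoff is FP / max(1, discoveries) among genes
with estimated FDR ≤ cutoff, reported as 0 when nothing is discovered.
Precision-recall sweeps PPA descending; recall denominators count all true
risk genes after exclusions.  Recall-by-mutation-rate uses quintiles of the
summed class rates by default.  The frequentist baseline is the single-tail
Poisson test P(X ≥ d | M) per class, combined across classes by a
Bonferroni-corrected minimum (×2; Fisher combination available), with
Benjamini-Hochberg correction across genes.

## Problem sizes used in the shipped studies

Simulated studies run at 18,000 genes.  Parameter-recovery fits use one
cohort-20,000 dataset with the full 2000-iteration sampler; the power
comparison uses 10 replicates at cohort 10,000 with MAP fits per replicate
(point estimates are all that recall at a fixed FDR cutoff consumes; the
paper-scale version of this study used 100 replicates per cohort size).
Single-cell calibration runs one replicate at 18,000 genes × 60 synthetic
cell types.

## Known limitations

* The ensemble sampler's walkers mix more slowly than gradient-based
  samplers on the 8-parameter model; R̂ near 1.1 can require longer chains.
  The contract is on the posterior summaries, and the sampler backend is
  deliberately pluggable.
* γ̄ ≈ 1 (relative risk near null) is weakly identified; the truncation
  γ̄ > 1 is a modelling choice, not an inference result.
* The prior network is intentionally small; with very few cell types it can
  underfit sharply non-linear priors, and with correlated columns the
  per-cell-type Spearman readout attributes association to all correlated
  cell types, not a causal one.
* Exact reproduction of published real-data gene lists requires the
  original DNV tables, expression ranks and single-cell atlases, which are
  not redistributed here; the loaders accept them in the documented TSV/MTX
  dialects.
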