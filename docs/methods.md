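# Methods

## Model

Samples are grouped into *stages* related by a DAG (the partial order);
each stage carries one latent log-expression value per probe, and each DAG
edge a positive *development* distance `δ`. Three standard designs are
built in: grouped-ordered (one stage per stage label, labels chained, with
declared branches), individual-ordered (one stage per sample, each sample
preceded by all samples of the previous label), and individual-reference
(all non-reference samples directly after all reference samples).

Latent expression propagates along the DAG. For miR `i` at non-initial
stage `s` with parents `P(s)`:

    x_is ~ Normal( mean = Σ_p (1/δ_ps)(x_ip + τ_i δ_ps) / W_s ,
                   precision = λ_i W_s ),      W_s = Σ_p 1/δ_ps.

The weighted mean gives equally distant parents equal weight and lets a
distant parent's influence vanish; the precision grows when any incoming
development shrinks, and reduces to `λ_i / δ` for a single parent. The
trend `τ_i` has units of log-expression per unit development. mRNA latents
`y_gs` follow the identical form with `τ_i δ_ps` replaced by the
interaction effect `(r_g · v) δ'_ps`, where `r_g` holds the gene's
interaction coefficients over its candidate miRs and `v` is, by default,
the candidate-miR expression vector at the *child* stage (`interaction_stage
= "child"`); `"parent"` and `"difference"` variants are selectable, the
latter making the single-pair reduction below exact. Initial stages receive
a vague `Normal(0, 0.01)` prior.

Observations sit under a two-level technical hierarchy per platform:
set-level latents (one per physical array) around the stage latent with
precision `φ_set`, and replicate observations around the set latent with
precision `φ_rep`. Interaction coefficients have the score-informed prior
`r_jg ~ Normal(c_jg · β, 1/φ_r)` with `c_jg = [ind_1, ind_1·score_1,
ind_2, ind_2·score_2, …]` over the configured prediction algorithms; the
per-algorithm indicator doubles as the constant a score term needs, and a
zero score stays distinguishable from "not predicted". Coefficients `β`,
trends `τ`, and initial-stage latents carry `Normal(0, 0.01)` priors; every
precision a Gamma prior; the developments a Gamma(1, 1) prior, which pins
down their otherwise scale-free values (doubling all `δ` and `λ` together
would leave the likelihood unchanged).

### Precision-prior shape

The precision priors default to **shape 1, rate 0.001** (an exponential
with mean 1000 — effectively flat over the plausible range but bounded at
zero). A conventional `Gamma(0.001, 0.001)` prior has a density pole at
zero, and because only the ratio `λ/δ` is identified, that pole drives a
joint collapse `λ → 0, δ → 0` under the ELBO-maximizing development
updates: the stage precisions degenerate, and with them all trend
information (`precision(τ) ≈ λ Σ δ`). Shape 1 removes the pole and the
collapse; the variational gamma *posteriors* are unaffected in form.

## Fitting

Mean-field variational Bayes, fully factorized (one univariate normal
factor per latent expression, set latent, trend, interaction coefficient
and prediction coefficient; one gamma factor per precision). Conjugate
updates run in a fixed sweep: set latents → x (topological order) → y
(topological order) → τ → r → β → φ_r → λ → technical φ. Factors that
couple (probes within a stage through shared genes; a gene's coefficients
through its shared residual) are updated sequentially; independent blocks
are vectorized. Each sweep ends with a coordinate-wise bounded 1-D
optimization of every development on the exact δ-dependent part of the
ELBO, in log space over (1e-6, 1e6); a candidate is kept only if it does
not lower the objective. The first 10 sweeps skip the development step
(`delta_warmup`) so the conjugate factors settle before the point
estimates commit — this reliably reaches higher ELBO optima than
optimizing `δ` from the first sweep. The default run is 200 iterations
with the full ELBO recorded after each; an optional relative-change
tolerance allows early stopping.

ELBO monotonicity across every conjugate update and accepted development
step is the strongest global check on the update algebra, and the test
suite asserts it after each individual update group as well as across full
runs. Named precisions can be pinned at fixed values (point-mass factors,
excluded from updates, priors and entropies) — useful for empirical-Bayes
runs and essential for the analytic reduction below. Gamma rates and
normal precisions are floored at 1e-12; clamping events are counted.

## The single-pair reduction

For one miR and one mRNA on a fully ordered chain, two closed-form
estimators summarize the ordered-versus-unordered contrast (their original
derivation's displayed equations are not recoverable, so the forms here are
reconstructions validated against a brute-force iterative VB oracle): the
unordered fit regresses levels, `w = Σ t m / Σ t²`; the ordered fit
regresses first differences. Each reports a self-consistent precision
`E[λ]·Σ(regressor²)` with `E[λ] = (n−1)/RSS` from the zero-prior gamma
fixed point. At a *shared* noise level the comparison reduces to the design
sums, `Σ(Δt)² ≈ 2S(1−ρ₁)` versus `Σt² = S`, so the ordered model wins
approximately when the lag-1 autocorrelation `ρ₁ < 1/2` (boundary terms of
order 1/S excluded; the property is asserted well clear of the threshold).

Running the full engine with `interaction_stage="difference"`, unit fixed
developments, technical precisions pinned at 1e12, a vague pinned miR
stage precision, flat `φ_r`, and flat gamma priors reproduces the ordered
closed form to better than 1e-6 — an end-to-end validation of the engine's
interaction and precision updates.

## Preprocessing

Quantile normalization within each platform (across-column mean of order
statistics; ties take the average-rank interpolation, matching limma's
`normalizeQuantiles`, against which it is tested), then a probewise one-way
fixed-effects ANOVA across stage labels (set-averaged values by default,
replicate-level by flag; unadjusted F-test, α = 0.05, probes with
undefined F dropped, `α = 1` disables the filter), then removal of probes
in no predicted pair, then per-probe scaling to mean 0 and sample standard
deviation 1 (n−1 denominator). The order is fixed: normalize → filter →
restrict → scale.

## Synthetic data

The generator runs the model forward on a 5-stage DAG (4-chain plus one
branch off the initial stage, the shape of a staged-disease study with a
leukemic branch): developments from Gamma(1, 1) truncated to [0.05, 20]
(the truncation only avoids numerically degenerate propagation), trends of
magnitude 0.75 injected into 25% of miRs with random sign, stage
precisions λ = 10 (stage-transition noise sd ≈ 0.3 at δ = 1), technical
precisions 25 (sd 0.2) at both levels, initial latents `N(0, 1)`. The
default size mirrors a prediction-filtered staged microarray study — 28
miRs, 367 genes, 1754 candidate pairs, 2 expression sets per stage with 2
replicates; validation runs use a reduced profile (100 genes, 478 pairs,
same pairs-per-gene density) and unit tests a tiny one (4 miRs, 12 genes,
3 stages).

Prediction scores are drawn first (negative, mean −0.5), each candidate
pair assigned to one or both algorithms; truly active pairs then draw
`r ~ Normal(c·β_true, 1/16)` with `β_true = (−0.2, 0.6)` per algorithm, so
scores are informative about effect sign and size by construction.

By default **every predicted pair is active** (`frac_active = 1`): the
well-specified regime in which recovery measures the inference machinery
itself. This is a deliberate design grounded in a power analysis with an
oracle ridge estimator given the true latents, developments and prior:
with 4 stage transitions per gene against ~4.8 candidate pairs per gene,
part of each gene's coefficient vector is unidentified and filled in by
the score prior, so when a large fraction of predicted pairs is truly
inactive *no* estimator can exceed a truth-correlation of about 0.5–0.7
(oracle ceilings ≈ 0.52 at 50% active, 0.70 at 80%, 0.85 at 100%).
Lowering `frac_active` is therefore exposed as a misspecification dial: a
robustness test runs the 50%-active regime and asserts the graceful
degradation rather than a recovery floor.

What the simulation does *not* emulate: probe-level array artifacts, batch
effects, missing values, non-normal noise, transcription-factor
confounding, or prediction scores whose informativeness differs between
algorithms. Passing recovery tests therefore validate the estimator under
its own assumptions (plus mild score-prior misspecification), not
performance on any real cohort.

## Evaluation

Interactions are ranked by `|z|` of the variational posterior (posterior
mean magnitude by flag); an optional negative-only mode drops
positive-mean pairs. Trend tables list miRs with `|z| > 3` (threshold
configurable). The correlation baselines rank candidate pairs by Pearson
correlation of set-averaged profiles, by absolute value or most-negative.
The average relative rank statistic divides two ascending-sorted rank
lists elementwise and averages; it is scale-free and equals 1 for
identical lists. Reported statistics print at 2 decimals; files keep full
precision.

## Known limitations

- All mRNA stage-to-stage change is attributed to miR interactions (plus
  noise); unmodeled regulators bias coefficients.
- The fully factorized posterior understates uncertainty for strongly
  coupled coefficients (a gene's candidate miRs with similar stage
  profiles), and the joint λ–δ scale direction is nearly flat in the ELBO,
  so point developments should be read only relative to one another.
- Single-sample stages (individual-ordered / individual-reference designs)
  leave `φ_set` and `φ_rep` identifiable only through their sum; only the
  convolution enters the likelihood, so inference is unaffected.
- Per-gene candidate sets larger than the number of stage transitions are
  partially prior-determined by construction (see the power analysis
  above); more stages or fewer candidates per gene sharpen recovery.
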