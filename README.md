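# mirvb

Bayesian inference of microRNA–mRNA regulatory interactions from **partially
ordered** paired expression data, combined with sequence-based target
predictions, fitted by mean-field variational Bayes.

## The problem

MicroRNAs (miRs) repress mRNAs by binding complementary target sites.
Sequence-based predictors (TargetScan *context+*, miRanda *mirSVR*) propose
candidate miR–mRNA pairs with quantitative scores but have many false
positives; expression data can confirm which candidates behave like real
regulation. Most expression-based methods ignore any natural ordering of the
samples. When samples fall into ordered *stages* — a time course, disease
grades such as the Durie-Salmon stages of multiple myeloma, developmental
types — stage-to-stage changes carry information that level-wise correlation
discards: a miR and mRNA that change together *between adjacent stages* are
better interaction candidates than a merely correlated pair, and for
stage profiles with low lag-1 autocorrelation the ordered model provably
estimates interaction coefficients with higher precision.

`mirvb` implements a hierarchical model for this setting. Stages form a DAG
(a *partial order*); each stage holds replicate expression sets. For miR
`i` at non-initial stage `s` with parents `P(s)` and per-edge development
distances `δ_ps`:

    x_is ~ N( Σ_p (1/δ_ps)(x_ip + τ_i δ_ps) / W_s ,  precision λ_i W_s ),
    W_s = Σ_p 1/δ_ps

so a short development ties a child tightly to its parent, and the per-miR
trend `τ_i` drifts expression along the ordering. mRNA expression `y_gs`
follows the same form with the trend replaced by an interaction term
`r_g · x_s` over the gene's candidate miRs. Each interaction coefficient has
a score-informed prior

    r_jg ~ N( c_jg · β , 1/φ_r )

where `c_jg` stacks per-algorithm prediction indicators and scores and `β`
is learned jointly — so the data decide how much each predictor is worth.
Observations sit under two technical noise levels (between expression sets,
and between replicates within a set). Both positive and negative
interactions are allowed; in practice the score-informed prior drives the
top of the ranking negative, as expected for miR targeting.

Everything is fitted by coordinate-ascent variational Bayes (conjugate
normal/gamma factors; the developments `δ` are point-optimized on the
evidence lower bound once per sweep). Interactions are ranked by the
posterior z-score `z = mean · √precision`; trends with `|z| > 3` are
reported as stage-progression regulators.

## Worked example

```python
from mirvb import SyntheticConfig, generate, fit, rank_interactions, significant_trends
from mirvb.synthetic_data import recovery_report

dataset, predictions, order, truth = generate(SyntheticConfig.tiny(), seed=1)
posterior = fit(dataset, order, predictions, n_iter=100, seed=1)
print(rank_interactions(posterior, predictions=predictions).head(3))
print(recovery_report(truth, posterior))
```

prints (ELBO rises monotonically from −685.5 to −211.2 over the 100
iterations):

```
 rank     mir     gene      mean       sd          z                      predicted_by
    1 miR-004 GENE0012 -1.328967 0.028588 -46.487362                targetscan_context
    2 miR-004 GENE0011 -0.853042 0.026276 -32.464829                    miranda_mirsvr
    3 miR-004 GENE0008 -1.452580 0.049360 -29.428165 miranda_mirsvr,targetscan_context
{'r_correlation': 0.842, 'sign_agreement_top': 1.0,
 'active_in_top_quartile': 0.25, 'trend_recovery': 1.0}
```

The three strongest inferred interactions are negative (repression), their
fitted coefficients correlate with the generating truth at 0.84, and the one
miR simulated with an expression trend is recovered above `|z| = 3`.

## Command line

The same pipeline runs headless from one YAML config:

```bash
mirvb simulate   --config run.yaml   # synthetic data with ground truth
mirvb preprocess --config run.yaml   # quantile norm -> ANOVA filter -> z-scale
mirvb fit        --config run.yaml   # variational posterior + ELBO trace
mirvb rank       --config run.yaml   # ranked interactions, trend table
mirvb eval --ranks-a a.tsv --ranks-b b.tsv --validated v.tsv
```

`eval` computes the *average relative rank* statistic between two rankings
of the same validated pairs: sort both rank lists ascending, divide
position by position, and average. Values below 1 mean ranking A places the
validated pairs higher — an estimate of how many fewer candidates would
need testing to recover the same validations.

Real data enter as plain TSVs: an expression matrix per platform (probes ×
observations, log scale), an observation annotation (observation, sample,
stage, expression set, replicate), prediction tables in the TargetScan
context+ / miRanda mirSVR download dialects, and a declarative ordering
(grouped-ordered, individual-ordered, individual-reference, or a custom
DAG in JSON).

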