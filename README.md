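# starharvest

A grid-world intergroup-bias experiment as a fully tested, simulation-
validated pipeline. The package is for computational behavioural
scientists who study how people form social categories from markers of
group identity: it provides the *star-harvest* game (five players compete
for stars on a grid and can zap each other into a three-turn time-out), a
synthetic-participant generator whose players follow parameterized
social-categorization rules under three marker conditions — binary colour,
colour × shape, and a continuous colour gradient — and the complete
analysis chain for the resulting behaviour, validated end to end by rule
and parameter recovery.

## The model at the core

Whenever the participant shares a row or column with a bot, the nearest
such bot is a potential zap target. The participant zaps it with
probability

```
p(zap) = logistic( b_i + rule(target) + s·bin + d·dist + c·closest )
```

where `b_i ~ N(b, σ_b²)` is a participant-specific baseline, `rule(·)` the
categorization rule's log-odds offset for the target's similarity coding
(binary colour rule, shape rule, liberal/conservative threshold rules,
singling out one similarity rank, or a continuous similarity rule), `bin`
the 25-turn time bin, `dist` the Manhattan distance and `closest` whether
the participant is nearest to the star.

The analysis chain mirrors that model: a trial-level **mixed-effects
logistic regression** (random intercept per participant, estimated by
adaptive Gauss–Hermite marginal maximum likelihood) of zap decisions on
the condition's similarity coding; a **mixed linear model** of time-binned
zap rates (learning dynamics); **k-means rule discovery** on centred,
standardized per-participant zap-rate profiles with silhouette-based
peak/plateau selection of the number of clusters; and a **linear model**
of the post-game allocation of ten bonus stars.

## Worked example

Simulate a binary-condition cohort of 200 synthetic participants — 30%
follow a colour rule (+1.5 log-odds toward the outgroup), 70% are
indifferent — and run the full chain:

```python
import starharvest as sh

result = sh.run_pipeline(
    {"seed": 11,
     "design": {"marker_condition": "binary",
                "behaviour_condition": "all_avoiders"},
     "cohort": {"n_participants": 200,
                "rule_mixture": [
                    {"rule_kind": "colour_binary", "proportion": 0.3,
                     "effect_logit": -1.5, "baseline_logit": 0.0},
                    {"rule_kind": "indifferent", "proportion": 0.7,
                     "baseline_logit": -1.5}]}},
    "out/demo")

print(result.trial_models["all_avoiders"].summary())
c = result.clustering
print(f"selected k = {c.k_selected}, cluster sizes = {c.cluster_sizes}")
print(c.cluster_profiles.round(3))
```

prints

```
mixed logistic regression (adaptive Gauss-Hermite, random intercept)  (n_obs=11082, n_groups=200, converged=True, df=normal)
             term  estimate      se        z       p
            const   -1.0092  0.0877 -11.5085  0.0000
      same_colour   -0.4847  0.0535  -9.0560  0.0000
         distance   -0.1260  0.0200  -6.3140  0.0000
  closest_to_star   -0.5426  0.0717  -7.5668  0.0000
target_play_order    0.0055  0.0190   0.2920  0.7703
sigma_u: 0.6639797419377513

selected k = 2, cluster sizes = [110, 90]
         rate_1  rate_2  rate_3  rate_4
cluster
1         0.177   0.169   0.128   0.120
2         0.131   0.118   0.332   0.352
```

Read: pooled over the mixture, sharing the participant's colour lowers the
zap log-odds by ≈0.48; being far away or being closest to a star also
suppresses zapping. The silhouette curve selects two clusters, and their
*unscaled* profiles identify the planted structure — cluster 2 zaps the
two dissimilar targets (ranks 3–4, rates ≈0.33–0.35) far more than the
similar ones (≈0.12), while cluster 1 barely differentiates.

The same objects are available piecewise: `simulate_cohort` →
`cohort_opportunities` → `zap_profiles` / `time_binned_rates` →
`TrialZapModel`, `TimeBinModel`, `ExtremesContrastModel`,
`AllocationModel` (statsmodels-style: construct from a data frame,
`fit()`, inspect the results object) → `discover_rules`. Plots live in
`starharvest.plotting`; a `starharvest` CLI (`simulate`, `features`,
`fit`, `cluster`, `run-all`, `replicate`) wraps the pipeline, and
`replicate_from_deposit` runs the chain on externally deposited
trial-level data via a documented column schema.

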