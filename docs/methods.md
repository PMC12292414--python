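# Methods

## The task and what the package models

Five players share a rectangular grid. Each of 100 turns, every player in a
fixed order either moves one cell, stays, or fires a zap ray along its row
or column; players caught by a ray sit in a time-out zone for exactly three
of their own turn slots and then re-enter at their spawn cell (or the
nearest free cell). A single star is on the grid at most once at a time;
when absent it respawns each turn with probability `star_respawn_prob` on a
uniformly chosen unoccupied cell, and moving onto it collects it.

One player is the (synthetic) participant; the other four are bots running
one of two algorithms. *Avoiders* chase the star when they are the
(weakly) closest player and the row-then-column path is clear, retreat when
another player blocks that path, and never zap; when idle they take a
uniformly random legal step, so the arena stays in motion. *Zappers* chase
the star likewise but zap a blocker they can reach along their row or
column, and stay when idle. Bots are memoryless.

Before the game the participant picks a team colour (green or orange, a
minimal-group induction); afterwards it divides ten bonus stars between the
four bots. Three marker conditions control how the bots differ from the
participant: **binary** (two round green, two round orange avatars),
**multi** (colour crossed with shape: round/pentagon), and **gradient**
(round avatars at integer positions 0–3 of a green-orange colour axis).
Similarity of a target to the participant is coded per condition — a
same-colour indicator; colour, shape and their interaction; or linear
(0–3) and quadratic (0–9) colour distance — and every roster's four bots
are also ranked 1 (most similar) to 4 (least), ties broken by play order.

## The synthetic participant

Whenever at least one bot shares the participant's row or column, the
nearest such bot (ties by play order) is the decision's *candidate
target*. The participant zaps it with probability

    logistic( b_i + rule(target) + s·bin + d·distance + c·closest )

and otherwise steps toward the star (random legal step when no star is
present). Here `b_i` is the participant's baseline zap propensity, drawn
per participant as N(baseline, baseline_sd²); `rule(target)` is the
categorization rule's log-odds offset; `bin` is the 25-turn time bin;
`distance` the Manhattan distance to the target; `closest` whether the
participant is currently nearest to the star.

The rule library covers the categorization patterns the design can elicit:
`indifferent` (no offset), `colour_binary` / `shape_binary` (offset on
same-marker targets; negative values are ingroup suppression, and a rule
"targeting the outgroup" is written as a baseline shift plus a negative
same-marker offset), `conservative_threshold` (rank 1 only),
`liberal_threshold` (rank 4 only), `single_out(k)` (one chosen rank), and
`similarity_linear` (offset × distance/3). With a zero effect every rule
reduces to indifference.

Star allocation uses the same rule: weights are a softmax of the *favour*
term (the negative of the zap offset, divided by a temperature), and the
ten stars are drawn from a multinomial over those weights. A deterministic
largest-remainder rounding is available, but the stochastic default is
used throughout so that allocation regressions see realistic residual
variance.

### Why one candidate per decision

A turn permits one action, so at most one target can be zapped per
decision. If the generative model instead evaluated *every* shared-line
target per turn, decisions with two or more simultaneous targets would
under-realize zaps relative to independent Bernoulli draws (one ray per
turn), and the shortfall concentrates on high-probability targets —
measured as ≈0.13 attenuation of a planted same-colour log-odds. With a
single candidate per decision, every zap/no-zap outcome is an exact draw
from the stated logistic model, and the trial-level regression fitted to
those records is correctly specified. Feature extraction therefore
defaults to one record per decision (the candidate) for games played with
blocking rays; per-shared-target extraction (`targets="all_shared"` or
`"line_of_sight"`) remains available for data produced under pass-through
rays.

### Ray blocking

The engine supports both ray semantics: pass-through (everyone on the line
is hit — the default, and the convention for the bots' task) and blocking
(`ray_blocking=True`, the ray stops at the first player). Synthetic
cohorts use blocking so that a zap resolves against exactly the candidate
it was aimed at; with pass-through rays, bots standing behind the target
would be "zapped" without any behavioural decision about them, which
contaminates their opportunity records.

## Generator defaults (the simulated study conditions)

| parameter | default | why |
|---|---|---|
| turns | 100 | task length of the experimental block |
| timeout | 3 turns | time-out penalty of the task |
| cohort arena | 7×7 | compact arena so a 100-turn game yields a useful number of shared-line opportunities (~50–60 decisions, ~13 per similarity rank); analyses are dimension-agnostic |
| engine default grid | 11×11 | roomier default for raw engine use |
| star respawn | 1.0 (cohorts), 0.5 (engine default) | a star always in play keeps all players moving |
| baseline logit | −1.5 | ≈0.14–0.2 zap probability per opportunity, mid-range of plausible zap rates |
| baseline sd | 0.5 | between-participant heterogeneity matching the model's random intercept |
| distance coef | −0.1 /cell | far targets are zapped less |
| closest-star coef | −0.5 | collecting beats zapping when a star is in reach |
| rule effect | 1.5 log-odds | a strong, clearly expressed categorization rule |
| zappers time slope | +0.125 logit/bin | escalation toward zapper opponents over the block (≈0.02 rate units per bin) |
| play order | randomized per participant | varies spawn corners and makes play order a genuine covariate |
| mixture weights | ≈30/70 (binary), 15/25/60 (multi), 17/15/15/53 (gradient) | the relative cluster prevalences this design elicits |

Cohort simulation derives all randomness from one `SeedSequence`:
identical (spec, seed) reproduce the cohort byte for byte.

## Analysis chain

* **Opportunities** — one record per participant decision with a candidate
  target, with the condition's similarity coding, distance,
  closest-to-star flag, target play order and time bin.
* **Zap profiles** — per participant, opportunity-conditioned zap rates
  toward targets ordered by similarity rank (undefined, never imputed,
  when a rank had no opportunities).
* **Trial-level model** — mixed-effects logistic regression of zap/no-zap
  on the similarity coding + task covariates with a random intercept per
  participant. statsmodels has no frequentist GLMM, so the marginal
  likelihood is maximized directly: the scalar random-intercept integral
  per participant is evaluated by adaptive Gauss–Hermite quadrature (modes
  by Newton, 9 nodes — results are identical to 21 nodes to four
  decimals), optimized by L-BFGS-B (gradient tolerance 1e-8), standard
  errors from a finite-difference Hessian, Wald z inference. A
  single-participant dataset drops the random effect and reduces exactly
  to ordinary logistic regression.
* **Time-bin model** — mixed linear regression of per-bin rates on
  similarity (no quadratic term), time bin, their interaction, and an
  all-zappers indicator and its time interaction; random intercept and
  time-bin slope per participant (statsmodels MixedLM, REML). p-values use
  the normal approximation (flagged `df: normal`); no Satterthwaite
  degrees of freedom are available in the installed stack.
* **Extremes contrast** — mixed linear model of rank-1 vs rank-4 rates
  across marker conditions; the dissimilar × condition interactions
  measure how marker complexity attenuates the bias gap.
* **Allocation model** — OLS of stars on the similarity coding.
* **Rule discovery** — profiles are column-centred (each rank position's
  cohort mean removed) then row-standardized (each participant's 4-vector
  to mean 0, variance 1; zero-variance or incomplete profiles are excluded
  and reported; column standardization is available via
  `scaling="column"`). k-means (Euclidean, best of 50 restarts) is scored
  by mean silhouette for k = 2..8, and k is the smallest value within
  0.02 of the curve's maximum — the peak-or-plateau rule; 0 tolerance
  gives the strict peak. Clusters are renumbered by decreasing size and
  characterized by their mean *unscaled* rate profiles.

## What the validation shows — and what it cannot

`starharvest.validation` plants known rules and checks what the chain
recovers. Three results frame the interpretation:

* Cluster-count recovery is reliable: silhouette peak/plateau selection
  finds 2 clusters in binary, 3 in multi and 4 in gradient mixtures at a
  1.5 log-odds planted effect.
* Membership recovery is information-limited. A 100-turn game yields only
  ~13 opportunities per similarity rank, so a rate carries binomial noise
  of sd ≈ 0.1 while the logistic rate gap at effect 1.5 is at most ≈0.3.
  After row standardization the profiles of indifferent participants are
  noise-dominated, and adjusted Rand agreement with planted labels
  plateaus around 0.2–0.6 depending on condition. Simulations show
  near-perfect membership recovery would require either ≈3 log-odds
  effects or several hundred opportunities per target — more data than
  the task produces. The same ceiling applies to the real task, so
  cluster *memberships* (unlike cluster counts and cluster mean profiles)
  should be read as noisy estimates.
* The trial-level estimator is calibrated: a planted −1.0 same-colour
  log-odds at n = 150 participants is recovered without systematic bias
  and with close-to-nominal 95% CI coverage. A small residual (~0.02–0.05)
  arises because zap-prone participants remove their targets to time-out
  and thereby reduce their own opportunity counts (informative cluster
  sizes) — a property of the game, not of the estimator.

The generator emulates opportunity-conditioned decisions, baseline
heterogeneity, time trends and allocation bias. It does **not** emulate
learning within the game (the time trend is planted generatively, not
produced by a learning model), bot retaliation or memory, human movement
strategy beyond greedy star-seeking, or any perceptual nonlinearity of the
colour gradient (integer spacing is assumed). Passing recovery tests
therefore validates the analysis chain, not any claim about human
behaviour.

## Numerical and degenerate-input conventions

Coordinates are 0-based (row, col) with row 0 at the top; all distances
are Manhattan. Illegal moves are coerced to `stay` and flagged rather than
raised, so imperfect policies cannot crash a simulation. Constant
outcomes raise `DegenerateDataError`; all-identical profiles are excluded
from clustering with a report rather than silently scaled. Logistic
regression with a constant-column design raises from the underlying
optimizer. All stochastic components consume `numpy.random.Generator`
streams seeded from explicit integers; engine randomness (star spawning)
and policy randomness are separate streams so a logged game can be
replayed exactly from its recorded actions.

## Problem sizes

Validation experiments use cohorts of 300 (rule recovery), 150 (coverage
and bias attenuation) and 120 (pipeline demonstrations) synthetic
participants, with 5–100 seeded replications per experiment; these sizes
give stable recovery statistics while keeping a full validation run in the
minutes range on one core.
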