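"""Recovery experiments: the package's evidence that the analysis chain
finds what the generator planted.

Three experiment families validate the pipeline end to end:

* **rule recovery** — simulate a cohort with a planted rule mixture, run
  profiles -> scaling -> silhouette/k-means, and score the selected number
  of clusters and the adjusted Rand agreement with the planted labels;
* **coverage** — simulate cohorts whose participants all carry a known
  similarity effect, fit the trial-level mixed logistic regression, and
  check how often the 95% confidence interval covers the planted value;
* **bias attenuation** — compare the cohort-level gap in zap rates between
  the most and least similar targets when the same per-rule effect is
  spread over one rule (binary) versus several (gradient).

All experiments derive their randomness from a single base seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .agents import CohortSpec, RuleKind, RuleParams, simulate_cohort
from .clustering import cluster_profiles, select_k, silhouette_curve
from .design import DesignSpec, MarkerCondition
from .features import center_scale_profiles, cohort_opportunities, zap_profiles
from .models import fit_trial_logit

__all__ = [
    "criterion_mixture",
    "outgroup_colour_rule",
    "outgroup_shape_rule",
    "RecoveryOutcome",
    "rule_recovery_replication",
    "rule_recovery_experiment",
    "coverage_experiment",
    "bias_gap",
    "bias_attenuation_experiment",
]

#: default planted effect magnitude (log-odds) for recovery experiments
RECOVERY_EFFECT = 1.5
BASELINE = -1.5


def outgroup_colour_rule(effect: float, baseline: float = BASELINE) -> RuleParams:
    """A colour rule adding ``+effect`` log-odds toward different-colour
    targets (written as a baseline shift plus a same-colour offset)."""
    return RuleParams(
        RuleKind.COLOUR_BINARY, effect_logit=-effect, baseline_logit=baseline + effect
    )


def outgroup_shape_rule(effect: float, baseline: float = BASELINE) -> RuleParams:
    """A shape rule adding ``+effect`` log-odds toward different-shape targets."""
    return RuleParams(
        RuleKind.SHAPE_BINARY, effect_logit=-effect, baseline_logit=baseline + effect
    )


def criterion_mixture(
    condition: MarkerCondition, effect: float = RECOVERY_EFFECT
) -> tuple[tuple[RuleParams, float], ...]:
    """Planted mixtures for rule-recovery experiments.

    Binary: 30% colour rule / 70% indifferent (two clusters).  Multi:
    colour rule, shape rule, indifferent (three clusters).  Gradient:
    single-out rules for ranks 2, 3 and 4 plus indifferent (four
    clusters).  Every rule adds ``+effect`` log-odds toward the players it
    targets (the outgroup for colour/shape rules, one similarity rank for
    single-out rules).  Mixture weights follow the cluster prevalences the
    three-condition design is known to elicit.
    """
    condition = MarkerCondition(condition)
    if condition == MarkerCondition.BINARY:
        return (
            (outgroup_colour_rule(effect), 0.3),
            (RuleParams(baseline_logit=BASELINE), 0.7),
        )
    if condition == MarkerCondition.MULTI:
        return (
            (outgroup_colour_rule(effect), 0.15),
            (outgroup_shape_rule(effect), 0.25),
            (RuleParams(baseline_logit=BASELINE), 0.6),
        )
    return (
        (RuleParams(RuleKind.SINGLE_OUT, single_out_rank=2, effect_logit=effect, baseline_logit=BASELINE), 0.17),
        (RuleParams(RuleKind.SINGLE_OUT, single_out_rank=3, effect_logit=effect, baseline_logit=BASELINE), 0.15),
        (RuleParams(RuleKind.SINGLE_OUT, single_out_rank=4, effect_logit=effect, baseline_logit=BASELINE), 0.15),
        (RuleParams(baseline_logit=BASELINE), 0.53),
    )


@dataclass
class RecoveryOutcome:
    seed: int
    k_planted: int
    k_selected: int
    ari: float
    n_clustered: int

    @property
    def k_correct(self) -> bool:
        return self.k_selected == self.k_planted

    @property
    def success(self) -> bool:
        return self.k_correct and self.ari >= 0.9


def rule_recovery_replication(
    condition: MarkerCondition,
    seed: int,
    n_participants: int = 300,
    mixture=None,
    k_max: int = 8,
    n_restarts: int = 50,
    plateau_tol: float = 0.02,
) -> RecoveryOutcome:
    """One seeded cohort: simulate, cluster, and score against the planted
    rule labels (adjusted Rand index over the clustered participants)."""
    condition = MarkerCondition(condition)
    mixture = mixture or criterion_mixture(condition)
    cohort = simulate_cohort(
        CohortSpec(
            design=DesignSpec(condition),
            n_participants=n_participants,
            rule_mixture=mixture,
            seed=seed,
        )
    )
    records = cohort_opportunities(cohort)
    profiles = zap_profiles(records)
    matrix, _ = center_scale_profiles(profiles)
    curve = silhouette_curve(matrix, k_max=k_max, n_restarts=n_restarts, seed=seed)
    k = select_k(curve, plateau_tol=plateau_tol)
    result = cluster_profiles(matrix, k, profiles, seed=seed, n_restarts=n_restarts)
    planted = cohort.labels.set_index("participant_id").loc[matrix.index, "rule"]
    ari = float(adjusted_rand_score(planted, result.assignments))
    return RecoveryOutcome(
        seed=seed,
        k_planted=len(mixture),
        k_selected=k,
        ari=ari,
        n_clustered=len(matrix),
    )


def rule_recovery_experiment(
    condition: MarkerCondition,
    n_replications: int = 10,
    base_seed: int = 0,
    n_participants: int = 300,
    **kwargs,
) -> list[RecoveryOutcome]:
    seeds = _spawn_seeds(base_seed, n_replications)
    return [
        rule_recovery_replication(condition, seed, n_participants, **kwargs)
        for seed in seeds
    ]


def coverage_experiment(
    n_replications: int = 25,
    base_seed: int = 0,
    n_participants: int = 150,
    effect: float = -1.0,
) -> pd.DataFrame:
    """Confidence-interval coverage of a planted same-colour log-odds.

    Every participant of each replication carries the colour rule with the
    planted ``effect``; the trial-level mixed logistic regression is fitted
    and the 95% CI for ``same_colour`` is checked against the planted
    value.  Returns one row per replication (estimate, CI, covered).
    """
    rows = []
    mixture = ((RuleParams(RuleKind.COLOUR_BINARY, effect_logit=effect, baseline_logit=BASELINE), 1.0),)
    for seed in _spawn_seeds(base_seed, n_replications):
        cohort = simulate_cohort(
            CohortSpec(
                design=DesignSpec(MarkerCondition.BINARY),
                n_participants=n_participants,
                rule_mixture=mixture,
                seed=seed,
            )
        )
        res = fit_trial_logit(cohort_opportunities(cohort), MarkerCondition.BINARY)
        ci = res.conf_int().loc["same_colour"]
        rows.append(
            {
                "seed": seed,
                "estimate": res["same_colour"],
                "se": res.se("same_colour"),
                "lower": ci["lower"],
                "upper": ci["upper"],
                "covered": bool(ci["lower"] <= effect <= ci["upper"]),
                "converged": res.converged,
            }
        )
    return pd.DataFrame(rows)


def bias_gap(cohort) -> float:
    """Cohort-mean zap-rate gap between the least (rank 4) and most (rank 1)
    similar targets: the population-level intergroup-bias measure."""
    profiles = zap_profiles(cohort_opportunities(cohort))
    return float(profiles["rate_4"].mean() - profiles["rate_1"].mean())


def bias_attenuation_experiment(
    n_seeds: int = 20,
    base_seed: int = 0,
    n_participants: int = 150,
    effect: float = RECOVERY_EFFECT,
    rule_mass: float = 0.3,
) -> pd.DataFrame:
    """Bias gaps under one planted rule (binary) versus four (gradient).

    Both cohorts plant the same total rule mass and the same per-rule
    effect (+``effect`` log-odds toward the targeted players): the binary
    cohort concentrates it in a single colour rule targeting the outgroup,
    while the gradient cohort spreads it over single-out rules for ranks
    2, 3 and 4.  Diversity dilutes the population-level rank-4 - rank-1
    gap, so the gradient gap should be systematically smaller.
    """
    binary_mix = (
        (outgroup_colour_rule(effect), rule_mass),
        (RuleParams(baseline_logit=BASELINE), 1 - rule_mass),
    )
    third = rule_mass / 3
    gradient_mix = (
        (RuleParams(RuleKind.SINGLE_OUT, single_out_rank=2, effect_logit=effect, baseline_logit=BASELINE), third),
        (RuleParams(RuleKind.SINGLE_OUT, single_out_rank=3, effect_logit=effect, baseline_logit=BASELINE), third),
        (RuleParams(RuleKind.SINGLE_OUT, single_out_rank=4, effect_logit=effect, baseline_logit=BASELINE), third),
        (RuleParams(baseline_logit=BASELINE), 1 - rule_mass),
    )
    rows = []
    for seed in _spawn_seeds(base_seed, n_seeds):
        gaps = {}
        for cond, mix in (
            (MarkerCondition.BINARY, binary_mix),
            (MarkerCondition.GRADIENT, gradient_mix),
        ):
            cohort = simulate_cohort(
                CohortSpec(
                    design=DesignSpec(cond),
                    n_participants=n_participants,
                    rule_mixture=mix,
                    seed=seed,
                )
            )
            gaps[cond.value] = bias_gap(cohort)
        rows.append(
            {
                "seed": seed,
                "gap_binary": gaps["binary"],
                "gap_gradient": gaps["gradient"],
                "attenuated": gaps["gradient"] < gaps["binary"],
            }
        )
    return pd.DataFrame(rows)


def _spawn_seeds(base_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(base_seed)
    return [int(s % (2**31)) for s in ss.generate_state(n)]
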