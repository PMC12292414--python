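"""Player policies: rule-governed bots and synthetic participants.

Two bot algorithms populate the games:

* **avoider** — chases the star when it is the closest player and nothing is
  in its way, retreats from the star when another player blocks its path,
  and never zaps;
* **zapper** — chases the star likewise but zaps players that block its
  path to the star.

Synthetic participants realise parameterized social-categorization rules.
Whenever a bot shares the participant's row or column it is a potential zap
target; the participant zaps it with probability

    logistic(baseline + rule(target) + time_slope * bin
             + distance_coef * d + closest_star_coef * closest)

where ``rule(target)`` is the rule's log-odds offset for that target's
similarity coding.  The rule library covers the categorization patterns the
design can elicit: indifference, binary colour or shape rules, liberal and
conservative threshold rules, singling out one similarity rank, and a
continuous similarity-distance rule.  The same rule drives the post-game
allocation of ten bonus stars (favouring targets the rule zaps less).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .design import (
    BehaviourCondition,
    DesignSpec,
    MarkerCondition,
    Roster,
    SimilarityCovariates,
    make_roster,
)
from .engine import (
    DIRECTIONS,
    Action,
    EventLog,
    GameConfig,
    GameState,
    MOVE,
    STAY,
    ZAP,
    manhattan,
    run_game,
)

__all__ = [
    "RuleKind",
    "RuleParams",
    "CohortSpec",
    "CohortData",
    "avoider_policy",
    "zapper_policy",
    "make_participant_policy",
    "allocation_policy",
    "simulate_cohort",
    "rule_term",
]


class RuleKind(str, enum.Enum):
    INDIFFERENT = "indifferent"
    COLOUR_BINARY = "colour_binary"
    SHAPE_BINARY = "shape_binary"
    LIBERAL_THRESHOLD = "liberal_threshold"
    CONSERVATIVE_THRESHOLD = "conservative_threshold"
    SINGLE_OUT = "single_out"
    SIMILARITY_LINEAR = "similarity_linear"


@dataclass(frozen=True)
class RuleParams:
    """A synthetic participant's decision parameters (log-odds units).

    ``effect_logit`` is the offset the rule adds for the targets it singles
    out: ``colour_binary``/``shape_binary`` add it to same-colour /
    same-shape targets (negative values = ingroup suppression, the
    empirically typical direction), ``conservative_threshold`` to the most
    similar target (rank 1), ``liberal_threshold`` to the most dissimilar
    (rank 4), ``single_out(k)`` to rank ``k`` only, and
    ``similarity_linear`` adds ``effect_logit * linear_distance / 3``.
    With ``effect_logit = 0`` every rule collapses to ``indifferent``.
    """

    rule_kind: RuleKind = RuleKind.INDIFFERENT
    single_out_rank: Optional[int] = None
    baseline_logit: float = -1.0
    effect_logit: float = 0.0
    time_slope_logit: float = 0.0
    distance_coef: float = -0.1
    closest_star_coef: float = -0.5

    def __post_init__(self) -> None:
        if self.rule_kind == RuleKind.SINGLE_OUT:
            if self.single_out_rank not in (1, 2, 3, 4):
                raise ValueError("single_out requires single_out_rank in 1..4")

    @property
    def label(self) -> str:
        if self.rule_kind == RuleKind.SINGLE_OUT:
            return f"single_out_{self.single_out_rank}"
        return self.rule_kind.value


def rule_term(params: RuleParams, cov: SimilarityCovariates) -> float:
    """Log-odds offset the rule assigns to a target with covariates ``cov``."""
    kind, e = params.rule_kind, params.effect_logit
    if e == 0.0 or kind == RuleKind.INDIFFERENT:
        return 0.0
    if kind == RuleKind.COLOUR_BINARY:
        return e * cov.get("same_colour")
    if kind == RuleKind.SHAPE_BINARY:
        return e * cov.get("same_shape")
    if kind == RuleKind.CONSERVATIVE_THRESHOLD:
        return e if cov.similarity_rank == 1 else 0.0
    if kind == RuleKind.LIBERAL_THRESHOLD:
        return e if cov.similarity_rank == 4 else 0.0
    if kind == RuleKind.SINGLE_OUT:
        return e if cov.similarity_rank == params.single_out_rank else 0.0
    if kind == RuleKind.SIMILARITY_LINEAR:
        return e * cov.get("linear_distance") / 3.0
    raise ValueError(f"unknown rule kind {kind}")  # pragma: no cover


# ---------------------------------------------------------------------------
# geometry helpers shared by the policies

def _l_path_cells(start, goal) -> list:
    """Cells of the row-then-column shortest path from start to goal,
    excluding the start cell (the goal cell is included)."""
    (r0, c0), (r1, c1) = start, goal
    cells = []
    if c1 != c0:
        step = 1 if c1 > c0 else -1
        for c in range(c0 + step, c1 + step, step):
            cells.append((r0, c))
    if r1 != r0:
        step = 1 if r1 > r0 else -1
        for r in range(r0 + step, r1 + step, step):
            cells.append((r, c1))
    return cells


def _blockers_on_path(state: GameState, pid: int) -> list[int]:
    me = state.players[pid].position
    star = state.star
    if star is None:
        return []
    path = set(_l_path_cells(me, star))
    return [
        p.id
        for p in state.players.values()
        if p.id != pid and p.position is not None and p.position in path
    ]


def _weakly_closest(state: GameState, pid: int) -> bool:
    star = state.star
    if star is None:
        return False
    mine = manhattan(state.players[pid].position, star)
    for p in state.players.values():
        if p.id != pid and p.position is not None:
            if manhattan(p.position, star) < mine:
                return False
    return True


def _move_toward(state: GameState, pid: int) -> Action:
    """First step of the row-then-column path; falls back to the other axis
    or to stay when the step cell is occupied."""
    me = state.players[pid].position
    star = state.star
    if star is None:
        return Action(STAY)
    candidates = []
    if star[1] != me[1]:
        candidates.append("E" if star[1] > me[1] else "W")
    if star[0] != me[0]:
        candidates.append("S" if star[0] > me[0] else "N")
    occupied = state.occupied_cells()
    for d in candidates:
        dr, dc = DIRECTIONS[d]
        cell = (me[0] + dr, me[1] + dc)
        if state.in_grid(cell) and cell not in occupied:
            return Action(MOVE, d)
    return Action(STAY)


def _wander(state: GameState, pid: int, rng: np.random.Generator) -> Action:
    """A uniformly chosen legal move (used for idle roaming)."""
    me = state.players[pid].position
    occupied = state.occupied_cells()
    options = []
    for d, (dr, dc) in DIRECTIONS.items():
        cell = (me[0] + dr, me[1] + dc)
        if state.in_grid(cell) and cell not in occupied:
            options.append(d)
    if not options:
        return Action(STAY)
    return Action(MOVE, options[int(rng.integers(len(options)))])


def _move_away(state: GameState, pid: int, rng: np.random.Generator) -> Action:
    """A uniformly chosen legal move that increases distance to the star."""
    me = state.players[pid].position
    star = state.star
    if star is None:
        return Action(STAY)
    occupied = state.occupied_cells()
    options = []
    base = manhattan(me, star)
    for d, (dr, dc) in DIRECTIONS.items():
        cell = (me[0] + dr, me[1] + dc)
        if state.in_grid(cell) and cell not in occupied and manhattan(cell, star) > base:
            options.append(d)
    if not options:
        return Action(STAY)
    return Action(MOVE, options[int(rng.integers(len(options)))])


def avoider_policy(state: GameState, pid: int, rng: np.random.Generator) -> Action:
    """Chase the star when closest with a clear path; retreat when another
    player blocks the path; roam otherwise; never zap.

    The idle case (star present, not closest, path clear) is a uniformly
    random legal move: the bot keeps moving about the arena rather than
    freezing in place.
    """
    if state.star is None:
        return Action(STAY)
    if _blockers_on_path(state, pid):
        return _move_away(state, pid, rng)
    if _weakly_closest(state, pid):
        return _move_toward(state, pid)
    return _wander(state, pid, rng)


def zapper_policy(state: GameState, pid: int, rng: np.random.Generator) -> Action:
    """Zap a player blocking the path to the star (when the blocker shares
    the bot's row or column, so a ray can reach it); otherwise chase the
    star when closest."""
    if state.star is None:
        return Action(STAY)
    me = state.players[pid].position
    star = state.star
    blockers = _blockers_on_path(state, pid)
    zappable = []
    for bid in blockers:
        pos = state.players[bid].position
        if pos[0] == me[0]:
            zappable.append((abs(pos[1] - me[1]), bid, "E" if pos[1] > me[1] else "W"))
        elif pos[1] == me[1]:
            zappable.append((abs(pos[0] - me[0]), bid, "S" if pos[0] > me[0] else "N"))
    if zappable:
        zappable.sort()
        return Action(ZAP, zappable[0][2])
    if blockers:
        return Action(STAY)
    if _weakly_closest(state, pid):
        return _move_toward(state, pid)
    return Action(STAY)


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


def make_participant_policy(
    params: RuleParams,
    covariates: Mapping[int, SimilarityCovariates],
):
    """Build the synthetic participant's policy.

    At each decision, the *candidate target* is the nearest bot sharing the
    participant's row or column (Manhattan distance, ties broken by play
    order); the participant zaps it with the rule's logistic probability,
    and otherwise moves toward the star (or roams when none is present).
    One candidate per decision keeps every zap/no-zap outcome an exact
    Bernoulli draw from the stated logistic model — the same model the
    trial-level regression fits.  Under blocking rays
    (``GameConfig.ray_blocking``) only line-of-sight bots — the nearest in
    each direction — are candidates, so the candidate is always a target a
    ray can actually reach.
    """
    terms = {bid: rule_term(params, cov) for bid, cov in covariates.items()}

    def policy(state: GameState, pid: int, rng: np.random.Generator) -> Action:
        me = state.players[pid].position
        bin_size = max(1, state.config.n_turns // 4)
        time_bin = state.turn // bin_size
        closest = 1.0 if _weakly_closest(state, pid) else 0.0
        shared = []
        for bid in terms:
            p = state.players.get(bid)
            if p is None or p.position is None:
                continue
            if p.position[0] == me[0] or p.position[1] == me[1]:
                shared.append((manhattan(me, p.position), bid))
        if shared:
            dist, bid = min(shared)
            eta = (
                params.baseline_logit
                + terms[bid]
                + params.time_slope_logit * time_bin
                + params.distance_coef * dist
                + params.closest_star_coef * closest
            )
            if rng.random() < _sigmoid(eta):
                pos = state.players[bid].position
                if pos[0] == me[0]:
                    d = "E" if pos[1] > me[1] else "W"
                else:
                    d = "S" if pos[0] > me[0] else "N"
                return Action(ZAP, d)
        if state.star is not None:
            return _move_toward(state, pid)
        return _wander(state, pid, rng)

    return policy


def allocation_policy(
    params: RuleParams,
    roster: Roster,
    rng: np.random.Generator,
    temperature: float = 1.0,
    deterministic: bool = False,
) -> np.ndarray:
    """Divide ten bonus stars between the four bots.

    Target weights are a softmax of the rule's *favour* term (the negative
    of its zap offset, scaled by ``temperature``): targets the rule zaps
    less receive more stars.  By default the ten stars are drawn from a
    multinomial with those weights, so cohorts show realistic star-count
    variability; ``deterministic=True`` instead rounds the expected shares
    to integers by largest remainder.  The result always sums to 10, in bot
    id order.
    """
    covs = roster.covariates()
    favour = np.array([-rule_term(params, covs[bid]) for bid in roster.bot_ids])
    w = np.exp((favour - favour.max()) / max(temperature, 1e-12))
    p = w / w.sum()
    if not deterministic:
        return rng.multinomial(10, p)
    exact = 10 * p
    base = np.floor(exact).astype(int)
    short = 10 - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    base[order[:short]] += 1
    return base


def default_cohort_game() -> GameConfig:
    """Game configuration for synthetic cohorts: a compact 7x7 arena with a
    star always in play, so a 100-turn game yields a useful number of
    shared-line zap opportunities against every target.  Rays block (hit
    the nearest player) so each zap resolves against exactly the target it
    was aimed at."""
    return GameConfig(grid_rows=7, grid_cols=7, star_respawn_prob=1.0, ray_blocking=True)


@dataclass(frozen=True)
class CohortSpec:
    """A simulated study arm: design cell, size, and the planted rule mixture.

    ``baseline_sd`` is the between-participant standard deviation (log-odds)
    of baseline zap propensity: each participant's baseline is drawn from a
    normal around its rule's ``baseline_logit``, matching the random
    intercept of the trial-level model.  Play order (and with it the
    starting corner of every player) is randomized per participant unless
    ``randomize_play_order`` is off.
    """

    design: DesignSpec
    n_participants: int
    rule_mixture: tuple[tuple[RuleParams, float], ...]
    seed: int = 0
    game: GameConfig = field(default_factory=default_cohort_game)
    allocation_temperature: float = 1.0
    baseline_sd: float = 0.5
    randomize_play_order: bool = True

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.rule_mixture)
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"rule mixture proportions sum to {total}, expected 1")
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be >= 0")


@dataclass
class CohortData:
    """Output of :func:`simulate_cohort`: one game log and one allocation per
    synthetic participant, plus the planted rule labels for recovery tests."""

    spec: CohortSpec
    roster: Roster
    logs: list[EventLog]
    allocations: pd.DataFrame  # participant_id, player_id, stars + covariates
    labels: pd.DataFrame  # participant_id, rule label and parameters

    @property
    def participant_ids(self) -> list[int]:
        return list(self.labels["participant_id"])


def simulate_cohort(spec: CohortSpec) -> CohortData:
    """Simulate a cohort: each synthetic participant draws a rule from the
    mixture, plays one seeded game against the design's bots, and then
    allocates ten bonus stars.  Fixed ``spec.seed`` gives identical output."""
    roster = make_roster(spec.design)
    covs = roster.covariates()
    bot_policy = (
        avoider_policy
        if spec.design.behaviour_condition == BehaviourCondition.ALL_AVOIDERS
        else zapper_policy
    )
    ss = np.random.SeedSequence(spec.seed)
    master = np.random.default_rng(ss)
    rules = [r for r, _ in spec.rule_mixture]
    props = np.array([p for _, p in spec.rule_mixture])
    logs: list[EventLog] = []
    alloc_rows = []
    label_rows = []
    children = ss.spawn(max(spec.n_participants, 1))
    cov_table = roster.covariate_table()
    for i in range(spec.n_participants):
        rule = rules[int(master.choice(len(rules), p=props))]
        prng = np.random.default_rng(children[i])
        if spec.baseline_sd > 0:
            rule = replace(
                rule,
                baseline_logit=rule.baseline_logit
                + spec.baseline_sd * float(prng.standard_normal()),
            )
        game_seed = int(prng.integers(2**31))
        order = spec.game.play_order
        if spec.randomize_play_order:
            order = tuple(int(x) for x in prng.permutation(list(order)))
        config = replace(spec.game, seed=game_seed, play_order=order)
        policies = {bid: bot_policy for bid in roster.bot_ids}
        policies[roster.PARTICIPANT_ID] = make_participant_policy(rule, covs)
        logs.append(run_game(config, policies))
        stars = allocation_policy(
            rule, roster, prng, temperature=spec.allocation_temperature
        )
        for bid, s in zip(roster.bot_ids, stars):
            alloc_rows.append({"participant_id": i, "player_id": bid, "stars": int(s)})
        label_rows.append(
            {
                "participant_id": i,
                "rule": rule.label,
                "rule_kind": rule.rule_kind.value,
                "single_out_rank": rule.single_out_rank,
                "baseline_logit": rule.baseline_logit,
                "effect_logit": rule.effect_logit,
                "time_slope_logit": rule.time_slope_logit,
            }
        )
    allocations = pd.DataFrame(
        alloc_rows, columns=["participant_id", "player_id", "stars"]
    )
    if len(allocations):
        allocations = allocations.merge(cov_table, on="player_id", how="left")
    labels = pd.DataFrame(
        label_rows,
        columns=[
            "participant_id",
            "rule",
            "rule_kind",
            "single_out_rank",
            "baseline_logit",
            "effect_logit",
            "time_slope_logit",
        ],
    )
    return CohortData(
        spec=spec, roster=roster, logs=logs, allocations=allocations, labels=labels
    )
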