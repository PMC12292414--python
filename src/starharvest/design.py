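"""Experimental design: marker conditions, avatar rosters and similarity codings.

Three social-marker conditions manipulate how the four bot players differ
from the participant:

``binary``
    two round green and two round orange avatars; the only marker is team
    colour (a minimal-group manipulation).
``multi``
    colour is crossed with a second, team-irrelevant marker (shape):
    round/pentagon x green/orange.
``gradient``
    four round avatars whose colours sit at the integer positions 0..3 of a
    green-to-orange gradient; similarity is the linear colour distance.

Every downstream analysis (trial-level zap regressions, time-binned rates,
zap profiles, star-allocation models) encodes target similarity through the
condition-specific covariates produced here.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "Shape",
    "Team",
    "MarkerCondition",
    "BehaviourCondition",
    "Avatar",
    "DesignSpec",
    "SimilarityCovariates",
    "Roster",
    "DesignError",
    "make_roster",
    "similarity_covariates",
]


class DesignError(ValueError):
    """A covariate or roster was requested that the condition does not define."""


class Shape(str, enum.Enum):
    ROUND = "round"
    PENTAGON = "pentagon"


class Team(str, enum.Enum):
    GREEN = "green"
    ORANGE = "orange"


class MarkerCondition(str, enum.Enum):
    BINARY = "binary"
    MULTI = "multi"
    GRADIENT = "gradient"


class BehaviourCondition(str, enum.Enum):
    ALL_AVOIDERS = "all_avoiders"
    ALL_ZAPPERS = "all_zappers"


#: colour_index of the pure team colours on the green..orange axis
GREEN_INDEX = 0
ORANGE_INDEX = 3
N_BOTS = 4


@dataclass(frozen=True)
class Avatar:
    """A player's appearance: position on the colour gradient, shape, team.

    ``colour_index`` is the ordinal position on the green-orange axis
    (0 = pure green, 3 = pure orange).  Binary and multi rosters use only
    the endpoints {0, 3}; the gradient roster uses all of 0..3.
    """

    colour_index: int
    shape: Shape = Shape.ROUND
    team: Team = Team.GREEN

    def __post_init__(self) -> None:
        if not 0 <= self.colour_index <= 3:
            raise DesignError(f"colour_index must be in 0..3, got {self.colour_index}")


def _participant_avatar(team: Team) -> Avatar:
    idx = GREEN_INDEX if team == Team.GREEN else ORANGE_INDEX
    return Avatar(colour_index=idx, shape=Shape.ROUND, team=team)


@dataclass(frozen=True)
class DesignSpec:
    """One cell of the experimental design: marker x behaviour x team."""

    marker_condition: MarkerCondition
    behaviour_condition: BehaviourCondition = BehaviourCondition.ALL_AVOIDERS
    participant_team: Team = Team.GREEN

    @classmethod
    def from_dict(cls, d: Mapping[str, str]) -> "DesignSpec":
        return cls(
            marker_condition=MarkerCondition(d["marker_condition"]),
            behaviour_condition=BehaviourCondition(
                d.get("behaviour_condition", "all_avoiders")
            ),
            participant_team=Team(d.get("participant_team", "green")),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "DesignSpec":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls.from_dict(data)


@dataclass(frozen=True)
class SimilarityCovariates:
    """Condition-specific similarity coding of one target relative to the participant.

    Fields not defined by the condition are stored as ``None``; accessing
    them through :meth:`get` raises :class:`DesignError` so that a model for
    the wrong condition fails loudly rather than silently coding zeros.
    ``similarity_rank`` orders the roster's four bots from most (1) to least
    (4) similar and is defined in every condition.
    """

    condition: MarkerCondition
    similarity_rank: int
    same_colour: int | None = None
    same_shape: int | None = None
    colour_shape_interaction: int | None = None
    linear_distance: int | None = None
    quadratic_distance: int | None = None

    def get(self, name: str) -> int:
        value = getattr(self, name)
        if value is None:
            raise DesignError(
                f"covariate {name!r} is not defined in the {self.condition.value} condition"
            )
        return value

    def as_dict(self) -> dict[str, int | None]:
        return {
            "similarity_rank": self.similarity_rank,
            "same_colour": self.same_colour,
            "same_shape": self.same_shape,
            "colour_shape_interaction": self.colour_shape_interaction,
            "linear_distance": self.linear_distance,
            "quadratic_distance": self.quadratic_distance,
        }


def similarity_covariates(
    participant: Avatar,
    target: Avatar,
    condition: MarkerCondition,
    similarity_rank: int = 0,
) -> SimilarityCovariates:
    """Code the similarity of ``target`` to ``participant`` for one condition.

    ``similarity_rank`` is a roster-level quantity (ties are broken by play
    order); :meth:`Roster.covariate_table` fills it in.  When called directly
    a rank of 0 marks "not assigned".
    """
    condition = MarkerCondition(condition)
    same_colour = int(target.colour_index == participant.colour_index)
    if condition == MarkerCondition.BINARY:
        return SimilarityCovariates(
            condition=condition, similarity_rank=similarity_rank, same_colour=same_colour
        )
    if condition == MarkerCondition.MULTI:
        same_shape = int(target.shape == participant.shape)
        return SimilarityCovariates(
            condition=condition,
            similarity_rank=similarity_rank,
            same_colour=same_colour,
            same_shape=same_shape,
            colour_shape_interaction=same_colour * same_shape,
        )
    dist = abs(target.colour_index - participant.colour_index)
    return SimilarityCovariates(
        condition=condition,
        similarity_rank=similarity_rank,
        linear_distance=dist,
        quadratic_distance=dist * dist,
    )


@dataclass(frozen=True)
class Roster:
    """The five players of one game: one participant plus four bots.

    Player ids are integers in play order: 0 is the participant, 1..4 are
    the bots.  ``play_order`` is the (deterministic) order in which players
    act within a turn.
    """

    spec: DesignSpec
    participant: Avatar
    bots: tuple[Avatar, ...]
    play_order: tuple[int, ...] = field(default=(0, 1, 2, 3, 4))

    PARTICIPANT_ID = 0

    @property
    def bot_ids(self) -> tuple[int, ...]:
        return tuple(range(1, 1 + len(self.bots)))

    def avatar(self, player_id: int) -> Avatar:
        if player_id == self.PARTICIPANT_ID:
            return self.participant
        return self.bots[player_id - 1]

    def similarity_ranks(self) -> dict[int, int]:
        """Rank each bot id 1 (most similar) to 4 (least), ties by play order."""
        cond = self.spec.marker_condition
        keys: list[tuple[tuple, int]] = []
        for bid in self.bot_ids:
            bot = self.avatar(bid)
            if cond == MarkerCondition.GRADIENT:
                key: tuple = (abs(bot.colour_index - self.participant.colour_index),)
            else:
                same_col = int(bot.colour_index == self.participant.colour_index)
                same_shape = int(bot.shape == self.participant.shape)
                # same colour before different colour, then same shape first
                key = (1 - same_col, 1 - same_shape)
            keys.append((key, bid))
        keys.sort()  # lexicographic; bid (play order) breaks ties
        return {bid: rank for rank, (_, bid) in enumerate(keys, start=1)}

    def covariate_table(self) -> pd.DataFrame:
        """One row per bot with avatar descriptors and similarity covariates."""
        ranks = self.similarity_ranks()
        rows = []
        for bid in self.bot_ids:
            bot = self.avatar(bid)
            cov = similarity_covariates(
                self.participant, bot, self.spec.marker_condition, ranks[bid]
            )
            rows.append(
                {
                    "player_id": bid,
                    "colour_index": bot.colour_index,
                    "shape": bot.shape.value,
                    "team": bot.team.value,
                    **cov.as_dict(),
                }
            )
        return pd.DataFrame(rows)

    def covariates(self) -> dict[int, SimilarityCovariates]:
        ranks = self.similarity_ranks()
        return {
            bid: similarity_covariates(
                self.participant, self.avatar(bid), self.spec.marker_condition, ranks[bid]
            )
            for bid in self.bot_ids
        }

    def to_csv(self, path: str | Path) -> None:
        self.covariate_table().to_csv(path, index=False)


def make_roster(spec: DesignSpec) -> Roster:
    """Build the published bot roster for a design cell.

    Bots are listed in play order.  Binary: two round green, two round
    orange.  Multi: round/pentagon crossed with green/orange.  Gradient:
    round avatars at colour positions 0, 1, 2, 3.
    """
    participant = _participant_avatar(spec.participant_team)
    cond = spec.marker_condition
    if cond == MarkerCondition.BINARY:
        bots = (
            Avatar(GREEN_INDEX, Shape.ROUND, Team.GREEN),
            Avatar(GREEN_INDEX, Shape.ROUND, Team.GREEN),
            Avatar(ORANGE_INDEX, Shape.ROUND, Team.ORANGE),
            Avatar(ORANGE_INDEX, Shape.ROUND, Team.ORANGE),
        )
    elif cond == MarkerCondition.MULTI:
        bots = (
            Avatar(GREEN_INDEX, Shape.ROUND, Team.GREEN),
            Avatar(GREEN_INDEX, Shape.PENTAGON, Team.GREEN),
            Avatar(ORANGE_INDEX, Shape.ROUND, Team.ORANGE),
            Avatar(ORANGE_INDEX, Shape.PENTAGON, Team.ORANGE),
        )
    else:
        bots = tuple(
            Avatar(i, Shape.ROUND, Team.GREEN if i <= 1 else Team.ORANGE)
            for i in range(4)
        )
    return Roster(spec=spec, participant=participant, bots=bots)
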