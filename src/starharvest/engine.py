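"""Turn-based grid-world engine for the star-harvest game.

Five players (one participant, four bots) move on a rectangular grid,
collect a star that respawns stochastically, and may zap: a ray fired along
the actor's row or column that sends every player it catches to a time-out
zone off the grid for ``timeout_turns`` of their own turn slots.

The engine is deterministic given ``GameConfig.seed``: star spawning draws
from an engine-owned random stream that player policies never touch, so a
logged game can be replayed exactly from its recorded actions.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GameConfig",
    "PlayerState",
    "GameState",
    "Action",
    "EventRecord",
    "EventLog",
    "MOVE",
    "ZAP",
    "STAY",
    "DIRECTIONS",
    "spawn_star",
    "zap_targets",
    "apply_action",
    "run_game",
    "replay_log",
    "manhattan",
]

MOVE, ZAP, STAY = "move", "zap", "stay"
#: direction -> (d_row, d_col); row 0 is the top of the grid
DIRECTIONS: dict[str, tuple[int, int]] = {
    "N": (-1, 0),
    "S": (1, 0),
    "E": (0, 1),
    "W": (0, -1),
}

Cell = tuple[int, int]


def manhattan(a: Cell, b: Cell) -> int:
    return abs(a[0] - b[0]) + abs(a[1] - b[1])


@dataclass(frozen=True)
class Action:
    kind: str  # move | zap | stay
    direction: Optional[str] = None  # N | S | E | W for move/zap

    def __post_init__(self) -> None:
        if self.kind not in (MOVE, ZAP, STAY):
            raise ValueError(f"unknown action kind {self.kind!r}")
        if self.kind in (MOVE, ZAP) and self.direction not in DIRECTIONS:
            raise ValueError(f"{self.kind} requires a direction in NSEW")


@dataclass(frozen=True)
class GameConfig:
    """Task parameters.  The defaults reproduce the published task:
    100 turns, three-turn time-outs, five players acting in a fixed order."""

    grid_rows: int = 11
    grid_cols: int = 11
    n_turns: int = 100
    timeout_turns: int = 3
    star_respawn_prob: float = 0.5
    seed: int = 0
    play_order: tuple[int, ...] = (0, 1, 2, 3, 4)
    #: if True, a zap ray stops at the first player it reaches (line-of-sight
    #: targeting); if False it passes through and hits everyone on the line
    ray_blocking: bool = False

    def __post_init__(self) -> None:
        if self.grid_rows < 3 or self.grid_cols < 3:
            raise ValueError("grid must be at least 3x3")
        if not 0.0 <= self.star_respawn_prob <= 1.0:
            raise ValueError("star_respawn_prob must be a probability")
        if len(set(self.play_order)) != len(self.play_order):
            raise ValueError("play_order must be a permutation of player ids")

    def initial_positions(self) -> dict[int, Cell]:
        """Four corners plus the centre cell, assigned in play order."""
        r, c = self.grid_rows - 1, self.grid_cols - 1
        cells = [(0, 0), (0, c), (r, 0), (r, c), (self.grid_rows // 2, self.grid_cols // 2)]
        if len(self.play_order) > len(cells):
            raise ValueError("engine supports at most 5 players")
        return {pid: cells[i] for i, pid in enumerate(self.play_order)}

    def to_dict(self) -> dict:
        return {
            "grid_rows": self.grid_rows,
            "grid_cols": self.grid_cols,
            "n_turns": self.n_turns,
            "timeout_turns": self.timeout_turns,
            "star_respawn_prob": self.star_respawn_prob,
            "seed": self.seed,
            "play_order": list(self.play_order),
            "ray_blocking": self.ray_blocking,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GameConfig":
        d = dict(d)
        d["play_order"] = tuple(d.get("play_order", (0, 1, 2, 3, 4)))
        return cls(**d)


@dataclass
class PlayerState:
    id: int
    position: Optional[Cell]  # None while in the time-out zone
    spawn_cell: Cell
    timeout_remaining: int = 0
    stars_collected: int = 0

    @property
    def active(self) -> bool:
        return self.timeout_remaining == 0


@dataclass
class GameState:
    turn: int
    players: dict[int, PlayerState]
    star: Optional[Cell]
    config: GameConfig

    @classmethod
    def initial(cls, config: GameConfig) -> "GameState":
        pos = config.initial_positions()
        players = {
            pid: PlayerState(id=pid, position=pos[pid], spawn_cell=pos[pid])
            for pid in config.play_order
        }
        return cls(turn=0, players=players, star=None, config=config)

    def occupied_cells(self) -> set[Cell]:
        return {p.position for p in self.players.values() if p.position is not None}

    def in_grid(self, cell: Cell) -> bool:
        return 0 <= cell[0] < self.config.grid_rows and 0 <= cell[1] < self.config.grid_cols

    def snapshot_positions(self) -> tuple:
        return tuple(self.players[pid].position for pid in self.config.play_order)


@dataclass(frozen=True)
class EventRecord:
    """One decision by one active player, with the state it saw."""

    turn: int
    actor_id: int
    kind: str
    direction: Optional[str]
    zap_victims: tuple[int, ...]
    star_collected: int
    coerced: int  # 1 if the policy's action was illegal and replaced by stay
    positions: tuple  # per player in play order; None = time-out zone
    star: Optional[Cell]


@dataclass
class EventLog:
    config: GameConfig
    records: list[EventRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        order = self.config.play_order
        rows = []
        for r in self.records:
            row = {
                "turn": r.turn,
                "actor_id": r.actor_id,
                "kind": r.kind,
                "direction": r.direction or "",
                "zap_victims": ";".join(str(v) for v in r.zap_victims),
                "star_collected": r.star_collected,
                "coerced": r.coerced,
                "star_row": -1 if r.star is None else r.star[0],
                "star_col": -1 if r.star is None else r.star[1],
            }
            for pid, pos in zip(order, r.positions):
                row[f"row_{pid}"] = -1 if pos is None else pos[0]
                row[f"col_{pid}"] = -1 if pos is None else pos[1]
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, stem: str | Path) -> tuple[Path, Path]:
        """Write ``<stem>.csv`` (tidy, one row per decision) and ``<stem>.json``
        (the game configuration)."""
        stem = Path(stem)
        csv_path = stem.with_suffix(".csv")
        json_path = stem.with_suffix(".json")
        self.to_dataframe().to_csv(csv_path, index=False)
        json_path.write_text(json.dumps(self.config.to_dict(), indent=2))
        return csv_path, json_path

    @classmethod
    def read(cls, stem: str | Path) -> "EventLog":
        stem = Path(stem)
        config = GameConfig.from_dict(json.loads(stem.with_suffix(".json").read_text()))
        df = pd.read_csv(stem.with_suffix(".csv"), keep_default_na=False)
        order = config.play_order
        records = []
        for row in df.itertuples(index=False):
            d = row._asdict()
            positions = tuple(
                None if d[f"row_{pid}"] == -1 else (int(d[f"row_{pid}"]), int(d[f"col_{pid}"]))
                for pid in order
            )
            star = None if d["star_row"] == -1 else (int(d["star_row"]), int(d["star_col"]))
            victims = tuple(int(v) for v in str(d["zap_victims"]).split(";") if v != "")
            records.append(
                EventRecord(
                    turn=int(d["turn"]),
                    actor_id=int(d["actor_id"]),
                    kind=str(d["kind"]),
                    direction=str(d["direction"]) or None,
                    zap_victims=victims,
                    star_collected=int(d["star_collected"]),
                    coerced=int(d["coerced"]),
                    positions=positions,
                    star=star,
                )
            )
        return cls(config=config, records=records)


def spawn_star(state: GameState, config: GameConfig, rng: np.random.Generator) -> None:
    """With probability ``star_respawn_prob``, place a star on a uniformly
    chosen unoccupied cell — but only if no star is currently on the grid
    (at most one star at a time)."""
    if state.star is not None:
        return
    if rng.random() >= config.star_respawn_prob:
        return
    occupied = state.occupied_cells()
    n_cells = config.grid_rows * config.grid_cols
    if len(occupied) >= n_cells:
        warnings.warn("grid full: star spawn skipped", stacklevel=2)
        return
    while True:
        cell = (
            int(rng.integers(config.grid_rows)),
            int(rng.integers(config.grid_cols)),
        )
        if cell not in occupied:
            state.star = cell
            return


def zap_targets(state: GameState, actor_id: int, direction: str) -> list[int]:
    """All active players on the ray from the actor's cell to the grid edge.

    The ray passes through players: everyone on the line is hit, not just
    the nearest.
    """
    actor = state.players[actor_id]
    if not actor.active or actor.position is None:
        raise ValueError(f"player {actor_id} is in time-out and cannot zap")
    dr, dc = DIRECTIONS[direction]
    r, c = actor.position
    hits = []
    for p in state.players.values():
        if p.id == actor_id or p.position is None:
            continue
        pr, pc = p.position
        if dr == 0 and pr == r and (pc - c) * dc > 0:
            hits.append((abs(pc - c), p.id))
        elif dc == 0 and pc == c and (pr - r) * dr > 0:
            hits.append((abs(pr - r), p.id))
    return [pid for _, pid in sorted(hits)]


def _reentry_cell(state: GameState, player: PlayerState) -> Cell:
    """The player's spawn cell, or the nearest free star-less cell by
    Manhattan distance with a row-major tie-break."""
    occupied = state.occupied_cells()
    blocked = occupied | ({state.star} if state.star is not None else set())
    if player.spawn_cell not in blocked:
        return player.spawn_cell
    best = None
    for r in range(state.config.grid_rows):
        for c in range(state.config.grid_cols):
            cell = (r, c)
            if cell in blocked:
                continue
            key = (manhattan(cell, player.spawn_cell), r, c)
            if best is None or key < best[0]:
                best = (key, cell)
    if best is None:  # pragma: no cover - grid of >=9 cells with <=5 players
        raise RuntimeError("no free cell for re-entry")
    return best[1]


def apply_action(
    state: GameState, actor_id: int, action: Action, config: GameConfig
) -> tuple[Action, tuple[int, ...], int, int]:
    """Execute one action in place.

    Returns ``(executed_action, zap_victims, star_collected, coerced)``.
    An illegal move (off-grid or onto an occupied cell) is replaced by
    ``stay`` and flagged.
    """
    actor = state.players[actor_id]
    if not actor.active or actor.position is None:
        raise ValueError(f"player {actor_id} is in time-out and cannot act")
    if action.kind == STAY:
        return action, (), 0, 0
    if action.kind == ZAP:
        on_ray = zap_targets(state, actor_id, action.direction)
        if config.ray_blocking and on_ray:
            on_ray = on_ray[:1]  # nearest player blocks the ray
        victims = tuple(on_ray)
        for vid in victims:
            victim = state.players[vid]
            victim.timeout_remaining = config.timeout_turns
            victim.position = None
        return action, victims, 0, 0
    # move
    dr, dc = DIRECTIONS[action.direction]
    target = (actor.position[0] + dr, actor.position[1] + dc)
    if not state.in_grid(target) or target in state.occupied_cells():
        logger.debug("illegal move by %s to %s coerced to stay", actor_id, target)
        return Action(STAY), (), 0, 1
    actor.position = target
    collected = 0
    if state.star == target:
        actor.stars_collected += 1
        state.star = None
        collected = 1
    return action, (), collected, 0


Policy = Callable[[GameState, int, np.random.Generator], Action]


def run_game(config: GameConfig, policy_map: Mapping[int, Policy]) -> EventLog:
    """Run a full game and return its event log.

    Each turn, every player acts once in ``play_order``.  A player in
    time-out has its counter decremented at its own slot instead of acting
    (re-entering the grid when the counter reaches zero), so a zap victim
    misses exactly ``timeout_turns`` of its own slots.  Star spawning uses
    an engine-owned stream; policies draw from a separate stream, so
    identical (config, policies) give identical logs.
    """
    missing = set(config.play_order) - set(policy_map)
    if missing:
        raise ValueError(f"no policy for players {sorted(missing)}")
    engine_rng = np.random.default_rng([config.seed, 0])
    policy_rng = np.random.default_rng([config.seed, 1])
    state = GameState.initial(config)
    log = EventLog(config=config)
    for turn in range(config.n_turns):
        state.turn = turn
        spawn_star(state, config, engine_rng)
        for pid in config.play_order:
            player = state.players[pid]
            if player.timeout_remaining > 0:
                player.timeout_remaining -= 1
                if player.timeout_remaining == 0:
                    player.position = _reentry_cell(state, player)
                continue
            positions = state.snapshot_positions()
            star = state.star
            try:
                action = policy_map[pid](state, pid, policy_rng)
            except Exception:
                raise
            if not isinstance(action, Action):
                action, coerced0 = Action(STAY), 1
            else:
                coerced0 = 0
            executed, victims, collected, coerced = apply_action(state, pid, action, config)
            log.records.append(
                EventRecord(
                    turn=turn,
                    actor_id=pid,
                    kind=executed.kind,
                    direction=executed.direction,
                    zap_victims=victims,
                    star_collected=collected,
                    coerced=coerced | coerced0,
                    positions=positions,
                    star=star,
                )
            )
    return log


def replay_log(log: EventLog) -> bool:
    """Re-simulate a game from its logged actions and verify every recorded
    state snapshot.  Returns True on success; raises AssertionError on the
    first divergence."""
    config = log.config
    engine_rng = np.random.default_rng([config.seed, 0])
    state = GameState.initial(config)
    it = iter(log.records)
    rec: Optional[EventRecord] = next(it, None)
    for turn in range(config.n_turns):
        state.turn = turn
        spawn_star(state, config, engine_rng)
        for pid in config.play_order:
            player = state.players[pid]
            if player.timeout_remaining > 0:
                player.timeout_remaining -= 1
                if player.timeout_remaining == 0:
                    player.position = _reentry_cell(state, player)
                continue
            assert rec is not None, "log ended before the game did"
            assert (rec.turn, rec.actor_id) == (turn, pid), (
                f"log order mismatch at turn {turn}: expected actor {pid}, "
                f"log has turn {rec.turn} actor {rec.actor_id}"
            )
            assert rec.positions == state.snapshot_positions(), (
                f"position snapshot diverged at turn {turn}, actor {pid}"
            )
            assert rec.star == state.star, f"star snapshot diverged at turn {turn}"
            executed, victims, collected, _ = apply_action(
                state, pid, Action(rec.kind, rec.direction), config
            )
            assert victims == rec.zap_victims, f"zap victims diverged at turn {turn}"
            assert collected == rec.star_collected, f"star pickup diverged at turn {turn}"
            rec = next(it, None)
    assert rec is None, "log has records beyond the last turn"
    return True
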