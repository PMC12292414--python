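"""From event logs to analysis units.

Every analysis of zapping behaviour conditions on *opportunities*: decision
points at which the participant shared a row or column with another player.
This module extracts one opportunity record per (decision, shared-line
target), aggregates them into per-participant zap profiles (the
4-vector of opportunity-conditioned zap rates against targets ordered by
similarity), time-binned rates for the learning-dynamics analysis, and the
centred/scaled profile matrix used for rule clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd

from .agents import CohortData
from .design import Roster
from .engine import EventLog, manhattan

__all__ = [
    "OPPORTUNITY_COLUMNS",
    "extract_opportunities",
    "cohort_opportunities",
    "zap_profiles",
    "time_binned_rates",
    "center_scale_profiles",
]

OPPORTUNITY_COLUMNS = [
    "participant_id",
    "turn",
    "time_bin",
    "target_id",
    "zapped",
    "similarity_rank",
    "same_colour",
    "same_shape",
    "colour_shape_interaction",
    "linear_distance",
    "quadratic_distance",
    "distance",
    "closest_to_star",
    "target_play_order",
]


def extract_opportunities(
    log: EventLog,
    roster: Roster,
    participant_id: int = 0,
    targets: str | None = None,
) -> pd.DataFrame:
    """Opportunity records for one participant's decisions.

    ``targets`` selects the regression unit:

    ``"candidate"``
        one record per decision, for the nearest bot sharing the
        participant's row or column (ties broken by play order) — the
        target of the decision;
    ``"all_shared"``
        one record per (decision, bot sharing a row or column);
    ``"line_of_sight"``
        one record per (decision, shared-line bot a ray could reach, i.e.
        the nearest per direction).

    The default (None) is ``"candidate"`` for games played with blocking
    rays and ``"all_shared"`` otherwise.  ``zapped`` is 1 iff that target
    was hit by the participant's zap on that decision (under pass-through
    rays one ray can hit several targets).  Covariates are computed from
    the state the participant saw: Manhattan ``distance`` to the target,
    whether the participant was (weakly) the closest active player to the
    star, the target's play order, the similarity coding of the roster's
    condition, and the 25-turn ``time_bin``.
    """
    if targets is None:
        targets = "candidate" if log.config.ray_blocking else "all_shared"
    if targets not in ("candidate", "all_shared", "line_of_sight"):
        raise ValueError(f"unknown targets mode {targets!r}")
    order = list(log.config.play_order)
    idx = {pid: i for i, pid in enumerate(order)}
    pi = idx[roster.PARTICIPANT_ID]
    covs = roster.covariates()
    bin_size = max(1, log.config.n_turns // 4)
    rows = []
    for rec in log.records:
        if rec.actor_id != roster.PARTICIPANT_ID:
            continue
        me = rec.positions[pi]
        if me is None:
            raise ValueError(
                f"malformed log: participant acted from time-out at turn {rec.turn}"
            )
        star = rec.star
        if star is not None:
            my_d = manhattan(me, star)
            closest = int(
                all(
                    manhattan(pos, star) >= my_d
                    for j, pos in enumerate(rec.positions)
                    if j != pi and pos is not None
                )
            )
        else:
            closest = 0
        shared = []
        for bid in roster.bot_ids:
            pos = rec.positions[idx[bid]]
            if pos is None:
                continue
            if pos[0] != me[0] and pos[1] != me[1]:
                continue
            shared.append((manhattan(me, pos), bid, pos))
        shared.sort(key=lambda t: t[:2])
        if targets == "candidate" and shared:
            shared = shared[:1]
        elif targets == "line_of_sight" and shared:
            nearest_per_dir: dict[tuple, tuple] = {}
            for dist, bid, pos in shared:
                side = (
                    (pos[0] > me[0]) - (pos[0] < me[0]),
                    (pos[1] > me[1]) - (pos[1] < me[1]),
                )
                nearest_per_dir.setdefault(side, (dist, bid, pos))
            shared = sorted(nearest_per_dir.values(), key=lambda t: t[:2])
        for dist, bid, pos in shared:
            cov = covs[bid]
            rows.append(
                {
                    "participant_id": participant_id,
                    "turn": rec.turn,
                    "time_bin": rec.turn // bin_size,
                    "target_id": bid,
                    "zapped": int(bid in rec.zap_victims and rec.kind == "zap"),
                    **cov.as_dict(),
                    "distance": manhattan(me, pos),
                    "closest_to_star": closest,
                    "target_play_order": order.index(bid),
                }
            )
    return pd.DataFrame(rows, columns=OPPORTUNITY_COLUMNS)


def cohort_opportunities(cohort: CohortData) -> pd.DataFrame:
    """Stack opportunity records for every participant of a simulated cohort."""
    frames = [
        extract_opportunities(log, cohort.roster, participant_id=i)
        for i, log in enumerate(cohort.logs)
    ]
    if not frames:
        return pd.DataFrame(columns=OPPORTUNITY_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def zap_profiles(records: pd.DataFrame) -> pd.DataFrame:
    """Per-participant opportunity-conditioned zap rates by similarity rank.

    Returns a wide frame indexed by ``participant_id`` with columns
    ``rate_1..rate_4`` and opportunity counts ``n_1..n_4``; a rate is NaN
    (undefined, never imputed) when its opportunity count is zero.
    """
    if records.empty:
        raise ValueError("no opportunity records")
    g = records.groupby(["participant_id", "similarity_rank"])["zapped"]
    agg = g.agg(zaps="sum", opportunities="count").reset_index()
    rates = agg.pivot(index="participant_id", columns="similarity_rank", values="zaps")
    counts = agg.pivot(
        index="participant_id", columns="similarity_rank", values="opportunities"
    )
    out = pd.DataFrame(index=rates.index)
    for rank in (1, 2, 3, 4):
        n = counts[rank] if rank in counts else pd.Series(0, index=out.index)
        z = rates[rank] if rank in rates else pd.Series(0, index=out.index)
        n = n.fillna(0).astype(int)
        out[f"rate_{rank}"] = np.where(n > 0, z.fillna(0) / n.replace(0, 1), np.nan)
        out[f"n_{rank}"] = n
    return out


def time_binned_rates(records: pd.DataFrame) -> pd.DataFrame:
    """Opportunity-conditioned zap rate per (participant, target, time bin).

    The grid is completed over all four bins; cells with zero opportunities
    carry NaN rates (flagged, not imputed).  Target covariates are carried
    along for modelling.
    """
    if records.empty:
        raise ValueError("no opportunity records")
    cov_cols = [
        "similarity_rank",
        "same_colour",
        "same_shape",
        "colour_shape_interaction",
        "linear_distance",
        "quadratic_distance",
    ]
    target_covs = (
        records[["participant_id", "target_id"] + cov_cols]
        .drop_duplicates(subset=["participant_id", "target_id"])
    )
    g = (
        records.groupby(["participant_id", "target_id", "time_bin"])["zapped"]
        .agg(zaps="sum", opportunities="count")
        .reset_index()
    )
    full = (
        target_covs[["participant_id", "target_id"]]
        .merge(pd.DataFrame({"time_bin": [0, 1, 2, 3]}), how="cross")
        .merge(g, on=["participant_id", "target_id", "time_bin"], how="left")
    )
    full["opportunities"] = full["opportunities"].fillna(0).astype(int)
    full["rate"] = np.where(
        full["opportunities"] > 0, full["zaps"].fillna(0) / full["opportunities"].replace(0, 1), np.nan
    )
    full = full.drop(columns=["zaps"]).merge(
        target_covs, on=["participant_id", "target_id"], how="left"
    )
    return full


@dataclass
class ScalingReport:
    """Participants excluded from the clustering matrix and why."""

    missing_rates: list
    zero_variance: list

    @property
    def excluded(self) -> list:
        return list(self.missing_rates) + list(self.zero_variance)


def center_scale_profiles(
    profiles: pd.DataFrame,
    scaling: Literal["row", "column"] = "row",
) -> tuple[pd.DataFrame, ScalingReport]:
    """Centre and scale zap profiles for k-means clustering.

    Each similarity-rank column is first centred by its cohort mean
    (removing each target position's average zapping rate).  Then, under
    ``scaling='row'`` (default), each participant's 4-vector is standardized
    to mean 0 and variance 1; under ``scaling='column'`` each column is
    standardized instead.  Participants with an undefined rate (zero
    opportunities against some rank) or with zero post-centring variance
    cannot be standardized and are excluded, listed in the report.
    """
    rate_cols = [f"rate_{r}" for r in (1, 2, 3, 4)]
    rates = profiles[rate_cols].astype(float)
    missing = list(rates.index[rates.isna().any(axis=1)])
    rates = rates.drop(index=missing)
    if len(rates) < 2:
        raise ValueError("need at least 2 complete profiles to centre and scale")
    centred = rates - rates.mean(axis=0)
    zero_var: list = []
    if scaling == "row":
        rowc = centred.sub(centred.mean(axis=1), axis=0)
        sd = rowc.std(axis=1, ddof=0)
        zero_var = list(rowc.index[sd <= 1e-12])
        rowc = rowc.drop(index=zero_var)
        sd = sd.drop(index=zero_var)
        out = rowc.div(sd, axis=0)
    elif scaling == "column":
        sd = centred.std(axis=0, ddof=0)
        if (sd <= 1e-12).any():
            degenerate = [c for c in rate_cols if sd[c] <= 1e-12]
            raise ValueError(f"columns with zero variance: {degenerate}")
        out = centred / sd
    else:
        raise ValueError("scaling must be 'row' or 'column'")
    out.columns = [f"z_{r}" for r in (1, 2, 3, 4)]
    return out, ScalingReport(missing_rates=missing, zero_variance=zero_var)
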