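"""End-to-end orchestration: simulate -> features -> models -> clustering.

A run is driven by a single YAML/JSON configuration and one master seed;
per-stage substreams are spawned from it, so identical (config, seed) give
byte-identical outputs.  Every file a run writes is listed with a SHA-256
checksum in the run manifest.  The module also supports replication from a
deposited trial-level dataset through a documented column schema.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agents import (
    CohortData,
    CohortSpec,
    RuleKind,
    RuleParams,
    default_cohort_game,
    simulate_cohort,
)
from .clustering import ClusterResult, discover_rules
from .design import BehaviourCondition, DesignSpec, MarkerCondition, Team
from .engine import GameConfig
from .features import (
    OPPORTUNITY_COLUMNS,
    center_scale_profiles,
    cohort_opportunities,
    time_binned_rates,
    zap_profiles,
)
from .models import (
    ModelResult,
    fit_allocation_lm,
    fit_timebin_lm,
    fit_trial_logit,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "PipelineResult",
    "run_pipeline",
    "replicate_from_deposit",
    "export_deposit",
    "default_rule_mixture",
]

#: per-arm participant-id offset keeping ids globally unique when both
#: behaviour conditions are simulated
ARM_OFFSET = 1_000_000


def default_rule_mixture(condition: MarkerCondition) -> tuple[tuple[RuleParams, float], ...]:
    """The generator's default planted rule mixtures.

    Mixture weights follow the relative cluster prevalences the design is
    known to elicit: in the binary condition roughly a third of
    participants follow a colour rule and the rest are indifferent; in the
    multi condition colour-rule, shape-rule and indifferent participants
    coexist; in the gradient condition the liberal (most-dissimilar) rule
    and two intermediate single-out rules each attract a minority.  Effect
    magnitudes default to 1.5 log-odds — a strong, clearly expressed rule —
    with binary colour/shape rules expressed as ingroup suppression.
    """
    condition = MarkerCondition(condition)
    if condition == MarkerCondition.BINARY:
        return (
            (RuleParams(RuleKind.COLOUR_BINARY, effect_logit=-1.5), 0.31),
            (RuleParams(RuleKind.INDIFFERENT), 0.69),
        )
    if condition == MarkerCondition.MULTI:
        return (
            (RuleParams(RuleKind.COLOUR_BINARY, effect_logit=-1.5), 0.14),
            (RuleParams(RuleKind.SHAPE_BINARY, effect_logit=-1.5), 0.24),
            (RuleParams(RuleKind.INDIFFERENT), 0.62),
        )
    return (
        (RuleParams(RuleKind.SINGLE_OUT, single_out_rank=4, effect_logit=1.5), 0.15),
        (RuleParams(RuleKind.SINGLE_OUT, single_out_rank=2, effect_logit=1.5), 0.17),
        (RuleParams(RuleKind.SINGLE_OUT, single_out_rank=3, effect_logit=1.5), 0.15),
        (RuleParams(RuleKind.INDIFFERENT), 0.53),
    )


def _parse_mixture(items) -> tuple[tuple[RuleParams, float], ...]:
    mixture = []
    for item in items:
        item = dict(item)
        prop = float(item.pop("proportion"))
        kind = RuleKind(item.pop("rule_kind"))
        mixture.append((RuleParams(rule_kind=kind, **item), prop))
    total = sum(p for _, p in mixture)
    if abs(total - 1.0) > 1e-8:
        raise ValueError(f"rule mixture proportions sum to {total:.4g}, expected 1")
    return tuple(mixture)


@dataclass(frozen=True)
class PipelineConfig:
    """Validated run configuration."""

    marker_condition: MarkerCondition
    behaviour: str  # all_avoiders | all_zappers | both
    n_participants: int
    rule_mixture: tuple[tuple[RuleParams, float], ...]
    seed: int = 0
    participant_team: Team = Team.GREEN
    game: GameConfig = field(default_factory=default_cohort_game)
    allocation_temperature: float = 1.0
    baseline_sd: float = 0.5
    #: extra per-time-bin log-odds of zapping in the all-zappers arm: the
    #: learned escalation toward opponents who zap
    time_slope_zappers: float = 0.125
    k_max: int = 8
    n_restarts: int = 50
    plateau_tol: float = 0.02
    scaling: str = "row"

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        design = dict(d.get("design", {}))
        cohort = dict(d.get("cohort", {}))
        analysis = dict(d.get("analysis", {}))
        condition = MarkerCondition(design["marker_condition"])
        behaviour = design.get("behaviour_condition", "both")
        if behaviour != "both":
            behaviour = BehaviourCondition(behaviour).value
        mixture = (
            _parse_mixture(cohort["rule_mixture"])
            if "rule_mixture" in cohort
            else default_rule_mixture(condition)
        )
        return cls(
            marker_condition=condition,
            behaviour=behaviour,
            n_participants=int(cohort.get("n_participants", 50)),
            rule_mixture=mixture,
            seed=int(d.get("seed", 0)),
            participant_team=Team(design.get("participant_team", "green")),
            game=(
                GameConfig.from_dict(d["game"]) if "game" in d else default_cohort_game()
            ),
            allocation_temperature=float(cohort.get("allocation_temperature", 1.0)),
            baseline_sd=float(cohort.get("baseline_sd", 0.5)),
            time_slope_zappers=float(cohort.get("time_slope_zappers", 0.125)),
            k_max=int(analysis.get("k_max", 8)),
            n_restarts=int(analysis.get("n_restarts", 50)),
            plateau_tol=float(analysis.get("plateau_tol", 0.02)),
            scaling=str(analysis.get("scaling", "row")),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)

    @property
    def arms(self) -> list[BehaviourCondition]:
        if self.behaviour == "both":
            return [BehaviourCondition.ALL_AVOIDERS, BehaviourCondition.ALL_ZAPPERS]
        return [BehaviourCondition(self.behaviour)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    package_version: str
    status: str = "ok"
    failed_stage: Optional[str] = None
    stages: list[str] = field(default_factory=list)
    files: dict[str, dict] = field(default_factory=dict)
    created: float = 0.0

    def add_file(self, name: str, path: Path) -> None:
        self.files[name] = {"path": str(path), "sha256": _sha256(path)}

    def write(self, path: Path) -> None:
        path.write_text(
            json.dumps(
                {
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "package_version": self.package_version,
                    "status": self.status,
                    "failed_stage": self.failed_stage,
                    "stages": self.stages,
                    "files": self.files,
                    "created": self.created,
                },
                indent=2,
            )
        )


@dataclass
class PipelineResult:
    """In-memory results of a pipeline run (the manifest lists the files)."""

    manifest: RunManifest
    cohorts: dict[str, CohortData] = field(default_factory=dict)
    opportunities: Optional[pd.DataFrame] = None
    allocations: Optional[pd.DataFrame] = None
    labels: Optional[pd.DataFrame] = None
    profiles: Optional[pd.DataFrame] = None
    binned: Optional[pd.DataFrame] = None
    matrix: Optional[pd.DataFrame] = None
    scaling_report: object = None
    trial_models: dict[str, ModelResult] = field(default_factory=dict)
    timebin_model: Optional[ModelResult] = None
    allocation_models: dict[str, ModelResult] = field(default_factory=dict)
    clustering: Optional[ClusterResult] = None


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(repr(config).encode()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig | Mapping | str | Path,
    output_dir: str | Path,
    stages: tuple[str, ...] = ("simulate", "features", "fit", "cluster"),
) -> PipelineResult:
    """Run the pipeline stages, writing every stage output under
    ``output_dir`` and returning results plus a checksummed manifest.

    Identical (config, seed) produce identical output files.  If a stage
    fails, the manifest records it and the outputs of completed stages are
    retained.
    """
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_file(config)
    elif isinstance(config, Mapping):
        config = PipelineConfig.from_dict(config)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=_config_hash(config),
        seed=config.seed,
        package_version=__version__,
        created=time.time(),
    )
    result = PipelineResult(manifest=manifest)
    ss = np.random.SeedSequence(config.seed)
    arm_seeds = {
        arm.value: int(child.generate_state(1)[0] % (2**31))
        for arm, child in zip(config.arms, ss.spawn(len(config.arms)))
    }
    try:
        if "simulate" in stages:
            _stage_simulate(config, arm_seeds, out, manifest, result)
        if "features" in stages:
            _stage_features(config, out, manifest, result)
        if "fit" in stages:
            _stage_fit(config, out, manifest, result)
        if "cluster" in stages:
            _stage_cluster(config, out, manifest, result)
    except Exception as exc:
        manifest.status = f"failed: {exc}"
        manifest.failed_stage = manifest.stages[-1] if manifest.stages else stages[0]
        manifest.write(out / "manifest.json")
        raise
    manifest.write(out / "manifest.json")
    manifest.add_file("manifest", out / "manifest.json")
    return result


def _stage_simulate(config, arm_seeds, out, manifest, result) -> None:
    manifest.stages.append("simulate")
    opp_frames, alloc_frames, label_frames = [], [], []
    for arm_i, arm in enumerate(config.arms):
        mixture = config.rule_mixture
        if (
            arm == BehaviourCondition.ALL_ZAPPERS
            and config.time_slope_zappers != 0.0
        ):
            # zapping escalates over time only against zapper opponents
            mixture = tuple(
                (
                    replace(
                        rule,
                        time_slope_logit=rule.time_slope_logit
                        + config.time_slope_zappers,
                    ),
                    p,
                )
                for rule, p in mixture
            )
        spec = CohortSpec(
            design=DesignSpec(
                marker_condition=config.marker_condition,
                behaviour_condition=arm,
                participant_team=config.participant_team,
            ),
            n_participants=config.n_participants,
            rule_mixture=mixture,
            seed=arm_seeds[arm.value],
            game=config.game,
            allocation_temperature=config.allocation_temperature,
            baseline_sd=config.baseline_sd,
        )
        cohort = simulate_cohort(spec)
        result.cohorts[arm.value] = cohort
        offset = arm_i * ARM_OFFSET
        opp = cohort_opportunities(cohort)
        for df, frames in (
            (opp, opp_frames),
            (cohort.allocations.copy(), alloc_frames),
            (cohort.labels.copy(), label_frames),
        ):
            if len(df):
                df["participant_id"] = df["participant_id"] + offset
            df["behaviour_condition"] = arm.value
            frames.append(df)
    opportunities = pd.concat(opp_frames, ignore_index=True)
    allocations = pd.concat(alloc_frames, ignore_index=True)
    labels = pd.concat(label_frames, ignore_index=True)
    result.opportunities = opportunities
    result.allocations = allocations
    result.labels = labels
    for name, df in (
        ("opportunities", opportunities),
        ("allocations", allocations),
        ("labels", labels),
    ):
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        manifest.add_file(name, path)


def _require(result, attr, out, name):
    value = getattr(result, attr, None)
    if value is None:
        path = out / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(
                f"stage input {name!r} not found in memory or at {path}"
            )
        value = pd.read_csv(path)
        setattr(result, attr, value)
    return value


def _stage_features(config, out, manifest, result) -> None:
    manifest.stages.append("features")
    opportunities = _require(result, "opportunities", out, "opportunities")
    profiles = zap_profiles(opportunities)
    binned = time_binned_rates(
        opportunities.drop(columns=["behaviour_condition"], errors="ignore")
    )
    arm_of = opportunities.drop_duplicates("participant_id").set_index("participant_id")[
        "behaviour_condition"
    ]
    binned["behaviour_condition"] = binned["participant_id"].map(arm_of)
    matrix, report = center_scale_profiles(profiles, scaling=config.scaling)
    result.profiles = profiles
    result.binned = binned
    result.matrix = matrix
    result.scaling_report = report
    for name, df in (
        ("profiles", profiles.reset_index()),
        ("timebinned", binned),
        ("profile_matrix", matrix.reset_index()),
    ):
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        manifest.add_file(name, path)


def _stage_fit(config, out, manifest, result) -> None:
    manifest.stages.append("fit")
    opportunities = _require(result, "opportunities", out, "opportunities")
    allocations = _require(result, "allocations", out, "allocations")
    binned = getattr(result, "binned", None)
    for arm in config.arms:
        sub = opportunities[opportunities["behaviour_condition"] == arm.value]
        res = fit_trial_logit(sub, config.marker_condition)
        result.trial_models[arm.value] = res
        paths = res.write(out / f"trial_model_{arm.value}")
        for p in paths:
            manifest.add_file(p.name, p)
        alloc_res = fit_allocation_lm(allocations, config.marker_condition, behaviour=arm)
        result.allocation_models[arm.value] = alloc_res
        for p in alloc_res.write(out / f"allocation_model_{arm.value}"):
            manifest.add_file(p.name, p)
    if binned is not None:
        result.timebin_model = fit_timebin_lm(binned, config.marker_condition)
        for p in result.timebin_model.write(out / "timebin_model"):
            manifest.add_file(p.name, p)


def _stage_cluster(config, out, manifest, result) -> None:
    manifest.stages.append("cluster")
    profiles = getattr(result, "profiles", None)
    matrix = getattr(result, "matrix", None)
    if profiles is None or matrix is None:
        raise FileNotFoundError("cluster stage requires the features stage outputs")
    clustering = discover_rules(
        matrix,
        profiles,
        k_max=min(config.k_max, max(2, len(matrix) - 1)),
        n_restarts=config.n_restarts,
        plateau_tol=config.plateau_tol,
        seed=config.seed,
    )
    result.clustering = clustering
    for p in clustering.write(out / "clustering"):
        manifest.add_file(p.name, p)


# ---------------------------------------------------------------------------
# replication from a deposited dataset

#: logical schema of a deposited trial-level file
DEPOSIT_TRIAL_COLUMNS = OPPORTUNITY_COLUMNS
DEPOSIT_ALLOCATION_COLUMNS = ["participant_id", "player_id", "stars"]


@dataclass
class ReplicationResult:
    trial_model: ModelResult
    clustering: ClusterResult
    allocation_model: Optional[ModelResult]
    comparison: Optional[pd.DataFrame]


def export_deposit(opportunities: pd.DataFrame, allocations: pd.DataFrame, data_dir: str | Path) -> None:
    """Write simulated data in the deposit schema (round-trip helper)."""
    d = Path(data_dir)
    d.mkdir(parents=True, exist_ok=True)
    opportunities.to_csv(d / "trials.csv", index=False)
    allocations.to_csv(d / "allocations.csv", index=False)


def replicate_from_deposit(
    data_dir: str | Path,
    condition: MarkerCondition,
    column_map: Optional[Mapping[str, str]] = None,
    reference: Optional[str | Path | pd.DataFrame] = None,
    k_max: int = 8,
    n_restarts: int = 50,
    plateau_tol: float = 0.02,
    scaling: str = "row",
    seed: int = 0,
) -> ReplicationResult:
    """Run the analysis chain on a deposited trial-level dataset.

    ``data_dir`` must contain ``trials.csv`` with the columns of
    ``DEPOSIT_TRIAL_COLUMNS`` (or names mapped to them via ``column_map``,
    deposit name -> canonical name) and may contain ``allocations.csv``.
    If ``reference`` (a CSV or frame with columns ``term, estimate``) is
    given, a comparison table of fitted against reference estimates is
    attached.
    """
    d = Path(data_dir)
    if not d.is_dir():
        raise FileNotFoundError(f"deposit directory not found: {d}")
    trials_path = d / "trials.csv"
    if not trials_path.exists():
        raise FileNotFoundError(f"deposit is missing trials.csv (in {d})")
    trials = pd.read_csv(trials_path)
    if column_map:
        trials = trials.rename(columns=dict(column_map))
    condition = MarkerCondition(condition)
    from .models import similarity_terms  # local import to avoid cycle at module load

    needed = [
        "participant_id",
        "turn",
        "time_bin",
        "target_id",
        "zapped",
        "similarity_rank",
        "distance",
        "closest_to_star",
        "target_play_order",
    ] + similarity_terms(condition)
    missing = [c for c in needed if c not in trials.columns]
    if missing:
        raise ValueError(
            "deposit schema error: missing columns "
            f"{missing}; expected (possibly via column_map) {needed}"
        )
    trial_model = fit_trial_logit(trials, condition)
    profiles = zap_profiles(trials)
    matrix, _ = center_scale_profiles(profiles, scaling=scaling)
    clustering = discover_rules(
        matrix,
        profiles,
        k_max=min(k_max, max(2, len(matrix) - 1)),
        n_restarts=n_restarts,
        plateau_tol=plateau_tol,
        seed=seed,
    )
    allocation_model = None
    alloc_path = d / "allocations.csv"
    if alloc_path.exists():
        alloc = pd.read_csv(alloc_path)
        missing_a = [c for c in DEPOSIT_ALLOCATION_COLUMNS if c not in alloc.columns]
        if missing_a:
            raise ValueError(f"deposit allocations.csv missing columns {missing_a}")
        allocation_model = fit_allocation_lm(alloc, condition)
    comparison = None
    if reference is not None:
        ref = reference if isinstance(reference, pd.DataFrame) else pd.read_csv(reference)
        fitted = trial_model.to_frame()[["term", "estimate"]]
        comparison = fitted.merge(
            ref.rename(columns={"estimate": "reference"}), on="term", how="outer"
        )
        comparison["difference"] = comparison["estimate"] - comparison["reference"]
    return ReplicationResult(
        trial_model=trial_model,
        clustering=clustering,
        allocation_model=allocation_model,
        comparison=comparison,
    )
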