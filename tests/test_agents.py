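"""Bot algorithms, the participant rule library, allocations and cohorts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

import starharvest as sh
from starharvest.agents import (
    CohortSpec,
    RuleKind,
    RuleParams,
    allocation_policy,
    avoider_policy,
    make_participant_policy,
    rule_term,
    simulate_cohort,
    zapper_policy,
)
from starharvest.design import MarkerCondition
from starharvest.engine import (
    Action,
    GameConfig,
    GameState,
    MOVE,
    STAY,
    ZAP,
    manhattan,
    run_game,
)
from starharvest.features import cohort_opportunities


def _state(positions, star=None, rows=11, cols=11, **kw):
    cfg = GameConfig(grid_rows=rows, grid_cols=cols, play_order=tuple(positions), **kw)
    state = GameState.initial(cfg)
    for pid, pos in positions.items():
        state.players[pid].position = pos
        state.players[pid].spawn_cell = pos
    state.star = star
    return state


class TestAvoider:
    def test_closest_with_clear_path_approaches_the_star(self):
        state = _state({0: (5, 5), 1: (0, 0)}, star=(5, 8))
        rng = np.random.default_rng(0)
        a = avoider_policy(state, 0, rng)
        assert a.kind == MOVE and a.direction == "E"

    def test_blocked_path_triggers_retreat(self):
        state = _state({0: (5, 5), 1: (5, 7)}, star=(5, 8))
        rng = np.random.default_rng(0)
        a = avoider_policy(state, 0, rng)
        assert a.kind in (MOVE, STAY)
        if a.kind == MOVE:
            dr, dc = {"N": (-1, 0), "S": (1, 0), "E": (0, 1), "W": (0, -1)}[a.direction]
            new = (5 + dr, 5 + dc)
            assert manhattan(new, (5, 8)) > manhattan((5, 5), (5, 8))

    def test_no_star_means_stay(self):
        state = _state({0: (5, 5), 1: (0, 0)}, star=None)
        assert avoider_policy(state, 0, np.random.default_rng(0)).kind == STAY

    def test_never_zaps_across_many_states(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            cells = [tuple(x) for x in rng.integers(0, 11, size=(3, 2))]
            if len(set(cells)) < 3:
                continue
            state = _state(dict(enumerate(cells[:2])), star=cells[2])
            assert avoider_policy(state, 0, rng).kind != ZAP


class TestZapper:
    def test_zaps_blocker_on_shared_row_toward_the_star(self):
        state = _state({0: (5, 5), 1: (5, 7)}, star=(5, 9))
        a = zapper_policy(state, 0, np.random.default_rng(0))
        assert a.kind == ZAP and a.direction == "E"

    def test_clear_path_and_closest_moves_toward_star(self):
        state = _state({0: (5, 5), 1: (0, 0)}, star=(5, 8))
        a = zapper_policy(state, 0, np.random.default_rng(0))
        assert a.kind == MOVE and a.direction == "E"

    def test_no_star_means_stay(self):
        state = _state({0: (5, 5), 1: (0, 0)}, star=None)
        assert zapper_policy(state, 0, np.random.default_rng(0)).kind == STAY


class TestRuleTerms:
    COV = {"binary": MarkerCondition.BINARY, "gradient": MarkerCondition.GRADIENT}

    def _covs(self, cond="gradient"):
        roster = sh.make_roster(sh.DesignSpec(MarkerCondition(cond)))
        return roster.covariates()

    @pytest.mark.parametrize(
        "kind,kw",
        [
            (RuleKind.COLOUR_BINARY, {}),
            (RuleKind.LIBERAL_THRESHOLD, {}),
            (RuleKind.CONSERVATIVE_THRESHOLD, {}),
            (RuleKind.SINGLE_OUT, {"single_out_rank": 3}),
            (RuleKind.SIMILARITY_LINEAR, {}),
        ],
    )
    def test_zero_effect_collapses_every_rule_to_indifferent(self, kind, kw):
        cond = "binary" if kind == RuleKind.COLOUR_BINARY else "gradient"
        params = RuleParams(kind, effect_logit=0.0, **kw)
        for cov in self._covs(cond).values():
            assert rule_term(params, cov) == 0.0

    def test_single_out_targets_exactly_one_rank(self):
        params = RuleParams(RuleKind.SINGLE_OUT, single_out_rank=3, effect_logit=2.0)
        terms = {c.similarity_rank: rule_term(params, c) for c in self._covs().values()}
        assert terms == {1: 0.0, 2: 0.0, 3: 2.0, 4: 0.0}

    def test_liberal_and_conservative_target_the_extremes(self):
        lib = RuleParams(RuleKind.LIBERAL_THRESHOLD, effect_logit=1.0)
        con = RuleParams(RuleKind.CONSERVATIVE_THRESHOLD, effect_logit=1.0)
        for cov in self._covs().values():
            assert rule_term(lib, cov) == (1.0 if cov.similarity_rank == 4 else 0.0)
            assert rule_term(con, cov) == (1.0 if cov.similarity_rank == 1 else 0.0)

    def test_similarity_linear_scales_with_distance(self):
        params = RuleParams(RuleKind.SIMILARITY_LINEAR, effect_logit=3.0)
        for cov in self._covs().values():
            assert rule_term(params, cov) == pytest.approx(cov.linear_distance)

    def test_colour_rule_monotonicity_in_the_logit(self):
        # at equal covariates the zap logit is strictly higher for a
        # different-colour candidate under ingroup suppression
        params = RuleParams(RuleKind.COLOUR_BINARY, effect_logit=-2.0)
        covs = self._covs("binary")
        same = [rule_term(params, c) for c in covs.values() if c.same_colour == 1]
        diff = [rule_term(params, c) for c in covs.values() if c.same_colour == 0]
        assert max(same) < min(diff)

    def test_single_out_requires_a_rank(self):
        with pytest.raises(ValueError):
            RuleParams(RuleKind.SINGLE_OUT, effect_logit=1.0)


class TestParticipantPolicy:
    def test_minus_infinity_baseline_never_zaps(self):
        roster = sh.make_roster(sh.DesignSpec(MarkerCondition.BINARY))
        policy = make_participant_policy(
            RuleParams(baseline_logit=-1e9), roster.covariates()
        )
        cfg = GameConfig(seed=1)
        policies = {b: avoider_policy for b in roster.bot_ids}
        policies[0] = policy
        log = run_game(cfg, policies)
        assert all(r.kind != ZAP for r in log.records if r.actor_id == 0)

    def test_zap_aimed_at_nearest_shared_line_bot(self):
        roster = sh.make_roster(sh.DesignSpec(MarkerCondition.BINARY))
        policy = make_participant_policy(
            RuleParams(baseline_logit=1e9), roster.covariates()
        )
        state = _state({0: (5, 5), 1: (5, 8), 2: (5, 3), 3: (0, 0), 4: (10, 10)})
        state.star = (9, 9)
        a = policy(state, 0, np.random.default_rng(0))
        assert a.kind == ZAP and a.direction == "W"  # bot 2 at distance 2


class TestAllocation:
    def _roster(self, cond="binary"):
        return sh.make_roster(sh.DesignSpec(MarkerCondition(cond)))

    @pytest.mark.parametrize("kind,kw,cond", [
        (RuleKind.INDIFFERENT, {}, "binary"),
        (RuleKind.COLOUR_BINARY, {"effect_logit": -2.0}, "binary"),
        (RuleKind.SINGLE_OUT, {"single_out_rank": 4, "effect_logit": 1.5}, "gradient"),
    ])
    def test_allocations_always_sum_to_ten(self, kind, kw, cond):
        roster = self._roster(cond)
        rng = np.random.default_rng(0)
        for _ in range(50):
            stars = allocation_policy(RuleParams(kind, **kw), roster, rng)
            assert stars.sum() == 10 and (stars >= 0).all()

    def test_indifferent_rule_is_uniform_in_expectation(self):
        roster = self._roster()
        rng = np.random.default_rng(1)
        total = np.zeros(4)
        n = 400
        for _ in range(n):
            total += allocation_policy(RuleParams(), roster, rng)
        assert np.allclose(total / n, 2.5, atol=0.2)

    def test_ingroup_favouring_rule_gives_ingroup_more(self):
        # ingroup suppression in zapping implies ingroup favour in allocation
        roster = self._roster()
        params = RuleParams(RuleKind.COLOUR_BINARY, effect_logit=-2.0)
        rng = np.random.default_rng(2)
        total = np.zeros(4)
        for _ in range(300):
            total += allocation_policy(params, roster, rng)
        same = [
            i for i, b in enumerate(roster.bots)
            if b.colour_index == roster.participant.colour_index
        ]
        diff = [i for i in range(4) if i not in same]
        assert total[same].sum() > total[diff].sum()

    @settings(derandomize=True, max_examples=60)
    @given(
        effect=st.floats(-4, 4, allow_nan=False),
        temperature=st.floats(0.1, 5, allow_nan=False),
        rank=st.integers(1, 4),
        seed=st.integers(0, 2**31 - 1),
        deterministic=st.booleans(),
    )
    def test_allocation_totals_ten_for_arbitrary_rules(
        self, effect, temperature, rank, seed, deterministic
    ):
        roster = self._roster("gradient")
        params = RuleParams(RuleKind.SINGLE_OUT, single_out_rank=rank, effect_logit=effect)
        stars = allocation_policy(
            params,
            roster,
            np.random.default_rng(seed),
            temperature=temperature,
            deterministic=deterministic,
        )
        assert stars.sum() == 10 and (stars >= 0).all()

    def test_deterministic_rounding_preserves_the_sum(self):
        roster = self._roster("gradient")
        params = RuleParams(RuleKind.CONSERVATIVE_THRESHOLD, effect_logit=-2.0)
        stars = allocation_policy(
            params, roster, np.random.default_rng(0), deterministic=True
        )
        again = allocation_policy(
            params, roster, np.random.default_rng(99), deterministic=True
        )
        assert stars.sum() == 10
        assert (stars == again).all()


class TestSimulateCohort:
    def _mix(self):
        return (
            (RuleParams(RuleKind.COLOUR_BINARY, effect_logit=-1.5), 0.3),
            (RuleParams(), 0.7),
        )

    def test_empty_cohort_gives_empty_outputs(self):
        spec = CohortSpec(
            design=sh.DesignSpec(MarkerCondition.BINARY),
            n_participants=0,
            rule_mixture=self._mix(),
        )
        data = simulate_cohort(spec)
        assert data.logs == []
        assert data.allocations.empty and data.labels.empty

    def test_bad_mixture_is_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            CohortSpec(
                design=sh.DesignSpec(MarkerCondition.BINARY),
                n_participants=5,
                rule_mixture=((RuleParams(), 0.9),),
            )

    def test_fixed_seed_reproduces_the_cohort(self):
        spec = CohortSpec(
            design=sh.DesignSpec(MarkerCondition.BINARY),
            n_participants=8,
            rule_mixture=self._mix(),
            seed=77,
        )
        a, b = simulate_cohort(spec), simulate_cohort(spec)
        pd.testing.assert_frame_equal(a.labels, b.labels)
        pd.testing.assert_frame_equal(a.allocations, b.allocations)
        assert [l.records for l in a.logs] == [l.records for l in b.logs]

    def test_mixture_label_counts_match_binomial_expectation(self):
        spec = CohortSpec(
            design=sh.DesignSpec(MarkerCondition.BINARY),
            n_participants=300,
            rule_mixture=self._mix(),
            seed=5,
            game=GameConfig(n_turns=2, grid_rows=7, grid_cols=7),
        )
        data = simulate_cohort(spec)
        n_colour = (data.labels["rule_kind"] == "colour_binary").sum()
        # binomial(300, .3): mean 90, sd ~7.9; allow 4 sd
        assert abs(n_colour - 90) < 32

    def test_avoider_cohort_bots_never_zap(self, colour_cohort):
        for log in colour_cohort.logs:
            for r in log.records:
                if r.actor_id != 0:
                    assert r.kind != ZAP

    def test_realized_rates_match_the_logistic_prediction(self, colour_cohort):
        # closed-form check: average realized zap rate equals the mean of the
        # per-record logistic probabilities within Monte-Carlo error
        opp = cohort_opportunities(colour_cohort)
        labels = colour_cohort.labels.set_index("participant_id")
        opp = opp.join(labels[["baseline_logit", "effect_logit"]], on="participant_id")
        eta = (
            opp["baseline_logit"]
            + opp["effect_logit"] * opp["same_colour"]
            - 0.1 * opp["distance"]
            - 0.5 * opp["closest_to_star"]
        )
        p = expit(eta)
        se = np.sqrt((p * (1 - p)).sum()) / len(p)
        assert abs(opp["zapped"].mean() - p.mean()) < 4 * se
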