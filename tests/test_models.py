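"""Regression models: mixed logistic, time-bin and extremes linear mixed
models, allocation regression, and their oracle equivalences."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import statsmodels.api as sm

import starharvest as sh
from starharvest.agents import RuleKind, RuleParams, allocation_policy
from starharvest.design import MarkerCondition
from starharvest.features import cohort_opportunities, time_binned_rates, zap_profiles
from starharvest.models import (
    DegenerateDataError,
    MixedLogit,
    fit_allocation_lm,
    fit_extremes_lm,
    fit_timebin_lm,
    fit_trial_logit,
)


def _glmm_data(seed, G=80, m=30, beta=(-1.0, 0.8), sigma=0.6):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(G), m)
    X = np.column_stack([np.ones(G * m), rng.integers(0, 2, G * m).astype(float)])
    u = sigma * rng.standard_normal(G)
    y = (rng.random(G * m) < expit(X @ np.array(beta) + u[g])).astype(float)
    return y, X, g


class TestMixedLogit:
    def test_recovers_planted_parameters(self):
        y, X, g = _glmm_data(0, G=120, m=40)
        res = MixedLogit(y, X, g, exog_names=["const", "x"]).fit()
        assert res.converged
        assert abs(res["x"] - 0.8) < 3 * res.se("x")
        assert abs(res.extra["sigma_u"] - 0.6) < 0.2

    def test_constant_outcome_is_degenerate(self):
        y, X, g = _glmm_data(1)
        with pytest.raises(DegenerateDataError):
            MixedLogit(np.zeros_like(y), X, g)

    def test_near_zero_heterogeneity_matches_plain_logit(self):
        # sigma -> 0: the marginal model collapses to ordinary logistic
        y, X, g = _glmm_data(2, G=60, m=40, sigma=0.0)
        mixed = MixedLogit(y, X, g, exog_names=["const", "x"]).fit()
        plain = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(mixed.params, plain.params, atol=0.02)

    def test_summary_mentions_method_and_terms(self):
        y, X, g = _glmm_data(3, G=40, m=20)
        res = MixedLogit(y, X, g, exog_names=["const", "x"]).fit()
        text = res.summary()
        assert "Gauss-Hermite" in text and "x" in text


class TestTrialZapModel:
    def test_single_participant_equals_ordinary_logit(self, colour_records):
        one = colour_records[colour_records["participant_id"] == 0]
        res = fit_trial_logit(one, MarkerCondition.BINARY)
        X = np.column_stack(
            [
                np.ones(len(one)),
                one["same_colour"],
                one["distance"],
                one["closest_to_star"],
                one["target_play_order"],
            ]
        )
        oracle = sm.Logit(one["zapped"].to_numpy(float), X).fit(disp=0)
        assert np.allclose(res.params, oracle.params, atol=1e-6)
        assert np.allclose(res.bse, oracle.bse, atol=1e-6)

    def test_recovers_planted_ingroup_suppression(self, colour_records, colour_cohort):
        res = fit_trial_logit(colour_records, MarkerCondition.BINARY)
        assert res.converged
        # 30% of participants carry a -1.5 same-colour offset; the pooled
        # conditional estimate must be clearly negative
        assert res["same_colour"] < -0.2
        assert res.pvalues[res.terms.index("same_colour")] < 0.05

    def test_wrong_condition_coding_is_rejected(self, colour_records):
        with pytest.raises(ValueError):
            fit_trial_logit(colour_records, MarkerCondition.GRADIENT)

    def test_all_zero_outcomes_raise_degenerate_error(self, colour_records):
        silent = colour_records.copy()
        silent["zapped"] = 0
        with pytest.raises(DegenerateDataError):
            fit_trial_logit(silent, MarkerCondition.BINARY)


def _timebin_cohorts(time_slope_zappers=0.8, seed=11, n=40):
    """Both behaviour arms of a binary cohort; a time trend planted only in
    the all-zappers arm."""
    frames = []
    for arm, slope, offset in (
        (sh.BehaviourCondition.ALL_AVOIDERS, 0.0, 0),
        (sh.BehaviourCondition.ALL_ZAPPERS, time_slope_zappers, 10_000),
    ):
        mix = (
            (
                RuleParams(
                    RuleKind.COLOUR_BINARY,
                    effect_logit=-1.5,
                    time_slope_logit=slope,
                ),
                1.0,
            ),
        )
        cohort = sh.simulate_cohort(
            sh.CohortSpec(
                design=sh.DesignSpec(MarkerCondition.BINARY, behaviour_condition=arm),
                n_participants=n,
                rule_mixture=mix,
                seed=seed,
            )
        )
        opp = cohort_opportunities(cohort)
        binned = time_binned_rates(opp)
        binned["participant_id"] = binned["participant_id"] + offset
        binned["behaviour_condition"] = arm.value
        frames.append(binned)
    return pd.concat(frames, ignore_index=True)


class TestTimeBinModel:
    def test_recovers_zappers_only_time_trend_and_colour_effect(self):
        binned = _timebin_cohorts()
        res = fit_timebin_lm(binned, MarkerCondition.BINARY)
        assert res["zappers:time_bin"] > 0
        assert res["zappers:time_bin"] > 2 * res.se("zappers:time_bin")
        assert res["same_colour"] < 0

    def test_constant_rates_give_near_zero_slopes(self):
        rng = np.random.default_rng(0)
        rows = []
        for pid in range(30):
            for tid, sc in ((1, 1), (2, 1), (3, 0), (4, 0)):
                for tb in range(4):
                    rows.append(
                        {
                            "participant_id": pid,
                            "target_id": tid,
                            "time_bin": tb,
                            "same_colour": sc,
                            "rate": 0.2 + 0.01 * rng.standard_normal(),
                            "opportunities": 10,
                            "behaviour_condition": "all_avoiders"
                            if pid < 15
                            else "all_zappers",
                        }
                    )
        res = fit_timebin_lm(pd.DataFrame(rows), MarkerCondition.BINARY)
        for term in ("time_bin", "same_colour:time_bin", "zappers:time_bin"):
            assert abs(res[term]) < 0.01


def _extremes_table(gaps, n_per=60, noise=0.05, seed=0):
    """Synthetic rank-1/rank-4 rate pairs with a planted per-condition gap."""
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for cond, gap in gaps.items():
        for _ in range(n_per):
            base = 0.2 + 0.05 * rng.standard_normal()
            for rank, rate in ((1, base), (4, base + gap)):
                rows.append(
                    {
                        "participant_id": pid,
                        "marker_condition": cond,
                        "behaviour_condition": "all_avoiders",
                        "similarity_rank": rank,
                        "rate": rate + noise * rng.standard_normal(),
                    }
                )
            pid += 1
    return pd.DataFrame(rows)


class TestExtremesModel:
    def test_recovers_the_planted_gap(self):
        table = _extremes_table({"binary": 0.15, "multi": 0.15, "gradient": 0.15})
        res = fit_extremes_lm(table)
        assert abs(res["dissimilar"] - 0.15) < 0.03
        # equal bias in all conditions: interactions vanish
        assert abs(res["dissimilar:multi"]) < 0.03
        assert abs(res["dissimilar:gradient"]) < 0.03

    def test_bias_only_in_binary_yields_negative_interactions(self):
        table = _extremes_table({"binary": 0.2, "multi": 0.0, "gradient": 0.0})
        res = fit_extremes_lm(table)
        assert res["dissimilar:multi"] < -0.1
        assert res["dissimilar:gradient"] < -0.1

    def test_other_ranks_are_rejected(self):
        table = _extremes_table({"binary": 0.1})
        table.loc[0, "similarity_rank"] = 2
        with pytest.raises(ValueError, match="ranks 1 and 4"):
            fit_extremes_lm(table)


class TestAllocationModel:
    def _alloc_frame(self, params, cond, n=200, seed=0, **kw):
        roster = sh.make_roster(sh.DesignSpec(MarkerCondition(cond)))
        cov = roster.covariate_table()
        rng = np.random.default_rng(seed)
        rows = []
        for pid in range(n):
            stars = allocation_policy(params, roster, rng, **kw)
            for bid, s in zip(roster.bot_ids, stars):
                rows.append({"participant_id": pid, "player_id": bid, "stars": int(s)})
        return pd.DataFrame(rows).merge(cov, on="player_id")

    def test_uniform_allocations_have_zero_slope(self):
        df = self._alloc_frame(RuleParams(), "binary")
        res = fit_allocation_lm(df, MarkerCondition.BINARY)
        assert abs(res["same_colour"]) < 3 * res.se("same_colour") + 1e-9

    def test_ingroup_favouring_rule_recovers_positive_colour_effect(self):
        df = self._alloc_frame(
            RuleParams(RuleKind.COLOUR_BINARY, effect_logit=-2.0), "binary"
        )
        res = fit_allocation_lm(df, MarkerCondition.BINARY)
        assert res["same_colour"] > 0.5
        assert res.stat_name == "t" and res.df_resid is not None

    def test_gradient_conservative_rule_matches_the_sign_pattern(self):
        # favour concentrated on the most similar target: stars fall with
        # distance but level off - negative linear, positive quadratic
        df = self._alloc_frame(
            RuleParams(RuleKind.CONSERVATIVE_THRESHOLD, effect_logit=-2.5), "gradient"
        )
        res = fit_allocation_lm(df, MarkerCondition.GRADIENT)
        assert res["linear_distance"] < 0
        assert res["quadratic_distance"] > 0

    def test_allocations_not_summing_to_ten_are_rejected(self):
        df = self._alloc_frame(RuleParams(), "binary", n=5)
        df.loc[0, "stars"] += 1
        with pytest.raises(ValueError, match="sum to 10"):
            fit_allocation_lm(df, MarkerCondition.BINARY)

    def test_result_files_round_trip(self, tmp_path):
        df = self._alloc_frame(RuleParams(), "binary", n=20)
        res = fit_allocation_lm(df, MarkerCondition.BINARY)
        csv_path, json_path = res.write(tmp_path / "alloc")
        frame = pd.read_csv(csv_path)
        assert list(frame["term"]) == res.terms
        assert json_path.exists()
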