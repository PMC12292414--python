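"""Regression models for zapping and star-allocation behaviour.

The analysis chain comprises four models, exposed statsmodels-style as a
model class built from a data frame whose ``fit()`` returns a results
object with estimates, standard errors, test statistics and ``summary()``:

* :class:`TrialZapModel` — trial-level mixed-effects logistic regression of
  the zap / no-zap decision on the condition's similarity coding plus task
  covariates, with a random intercept (baseline zap propensity) per
  participant.  Estimated by maximum likelihood with an adaptive
  Gauss-Hermite approximation of the random-intercept integral
  (:class:`MixedLogit`).
* :class:`TimeBinModel` — mixed-effects linear regression of
  opportunity-conditioned zap rates on time bin, similarity, their
  interaction, and bot behaviour, with random intercept and time-bin slope
  per participant (via ``statsmodels`` MixedLM).
* :class:`ExtremesContrastModel` — linear mixed model contrasting zap rates
  toward the most and least similar targets across marker conditions.
* :class:`AllocationModel` — ordinary linear regression of post-game star
  allocations on the condition's similarity coding.

Functional wrappers (``fit_trial_logit`` etc.) cover the same surface.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats

import statsmodels.api as sm

from .design import BehaviourCondition, MarkerCondition

__all__ = [
    "DegenerateDataError",
    "ModelResult",
    "MixedLogit",
    "TrialZapModel",
    "TimeBinModel",
    "ExtremesContrastModel",
    "AllocationModel",
    "fit_trial_logit",
    "fit_timebin_lm",
    "fit_extremes_lm",
    "fit_allocation_lm",
    "similarity_terms",
]


class DegenerateDataError(ValueError):
    """The outcome carries no information (e.g. all zeros or all ones)."""


#: fixed-effect similarity codings per marker condition (trial-level models)
_SIMILARITY_TERMS = {
    MarkerCondition.BINARY: ["same_colour"],
    MarkerCondition.MULTI: ["same_colour", "same_shape", "colour_shape_interaction"],
    MarkerCondition.GRADIENT: ["linear_distance", "quadratic_distance"],
}


def similarity_terms(condition: MarkerCondition, quadratic: bool = True) -> list[str]:
    terms = list(_SIMILARITY_TERMS[MarkerCondition(condition)])
    if not quadratic and "quadratic_distance" in terms:
        terms.remove("quadratic_distance")
    return terms


@dataclass
class ModelResult:
    """Estimates and inference for one fitted model.

    ``stat`` holds z statistics for mixed models (normal approximation to
    the sampling distribution, flagged by ``df_method``) and t statistics
    for ordinary least squares.
    """

    terms: list[str]
    params: np.ndarray
    bse: np.ndarray
    stat: np.ndarray
    pvalues: np.ndarray
    stat_name: str
    n_obs: int
    n_groups: int
    converged: bool
    method: str
    df_method: str = "normal"
    df_resid: Optional[float] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = len(self.terms)
        for name in ("params", "bse", "stat", "pvalues"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (k,):
                raise ValueError(f"{name} must have one entry per term")
            setattr(self, name, arr)

    def __getitem__(self, term: str) -> float:
        return float(self.params[self.terms.index(term)])

    def se(self, term: str) -> float:
        return float(self.bse[self.terms.index(term)])

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        if self.stat_name == "t" and self.df_resid:
            q = stats.t.ppf(1 - alpha / 2, self.df_resid)
        else:
            q = stats.norm.ppf(1 - alpha / 2)
        lo = self.params - q * self.bse
        hi = self.params + q * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi}, index=self.terms)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.params,
                "se": self.bse,
                self.stat_name: self.stat,
                "p": self.pvalues,
            }
        )

    def summary(self) -> str:
        header = (
            f"{self.method}  (n_obs={self.n_obs}, n_groups={self.n_groups}, "
            f"converged={self.converged}, df={self.df_method})\n"
        )
        if not self.converged:
            header += "WARNING: fit did not converge; estimates unreliable\n"
        body = self.to_frame().to_string(index=False, float_format=lambda v: f"{v: .4f}")
        extra = ""
        if self.extra:
            extra = "\n" + "\n".join(f"{k}: {v}" for k, v in self.extra.items())
        return header + body + extra

    def write(self, stem: str | Path) -> tuple[Path, Path]:
        """CSV of the coefficient table plus a JSON model card."""
        stem = Path(stem)
        csv_path, json_path = stem.with_suffix(".csv"), stem.with_suffix(".json")
        self.to_frame().to_csv(csv_path, index=False)
        card = {
            "method": self.method,
            "terms": self.terms,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "converged": bool(self.converged),
            "df_method": self.df_method,
            "extra": {k: (float(v) if np.isscalar(v) else v) for k, v in self.extra.items()},
        }
        json_path.write_text(json.dumps(card, indent=2))
        return csv_path, json_path


# ---------------------------------------------------------------------------
# mixed-effects logistic regression (random intercept per group)


class MixedLogit:
    """Logistic regression with a Gaussian random intercept per group.

    The marginal likelihood integrates the random intercept out of each
    group's Bernoulli likelihood with adaptive Gauss-Hermite quadrature
    (nodes recentred at each group's conditional mode, a Laplace-class
    approximation).  With one scalar random effect per group the integrals
    are one-dimensional, so a modest number of nodes is accurate.

    Parameters are the fixed-effect vector and the log random-intercept
    standard deviation; both are estimated by maximizing the marginal
    likelihood (L-BFGS-B, gradient tolerance 1e-8).
    """

    def __init__(
        self,
        endog: np.ndarray,
        exog: np.ndarray,
        groups: np.ndarray,
        exog_names: Optional[Sequence[str]] = None,
    ) -> None:
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or len(self.exog) != len(self.endog):
            raise ValueError("exog must be 2-d and aligned with endog")
        codes, uniques = pd.factorize(np.asarray(groups))
        self.group_idx = codes
        self.group_labels = uniques
        self.n_groups = len(uniques)
        self.exog_names = list(exog_names or [f"x{j}" for j in range(self.exog.shape[1])])
        s = self.endog.sum()
        if s == 0 or s == len(self.endog):
            raise DegenerateDataError(
                "outcome is constant (all zeros or all ones); logistic fit is degenerate"
            )
        self._u = np.zeros(self.n_groups)

    # -- likelihood ---------------------------------------------------------

    def _modes(self, eta: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
        """Conditional modes and curvatures of each group's log integrand."""
        y, gidx, G = self.endog, self.group_idx, self.n_groups
        u = self._u.copy()
        inv_var = 1.0 / (sigma * sigma)
        hess = np.full(G, -inv_var)
        for _ in range(50):
            a = eta + u[gidx]
            mu = special.expit(a)
            grad = np.bincount(gidx, weights=y - mu, minlength=G) - u * inv_var
            hess = -np.bincount(gidx, weights=mu * (1 - mu), minlength=G) - inv_var
            step = grad / hess
            u = u - step
            if np.max(np.abs(step)) < 1e-10:
                break
        self._u = u
        return u, hess

    def loglike(self, params: np.ndarray, n_quad: int = 9) -> float:
        beta, log_sigma = params[:-1], params[-1]
        sigma = float(np.exp(np.clip(log_sigma, -10.0, 5.0)))
        eta = self.exog @ beta
        u_hat, hess = self._modes(eta, sigma)
        tau = 1.0 / np.sqrt(-hess)
        nodes, weights = hermgauss(n_quad)
        y, gidx, G = self.endog, self.group_idx, self.n_groups
        log_terms = np.empty((G, n_quad))
        for k, (x_k, w_k) in enumerate(zip(nodes, weights)):
            u_k = u_hat + np.sqrt(2.0) * tau * x_k
            a = eta + u_k[gidx]
            ll_rows = y * a - np.logaddexp(0.0, a)
            ll_g = np.bincount(gidx, weights=ll_rows, minlength=G)
            prior = -0.5 * (u_k / sigma) ** 2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)
            log_terms[:, k] = np.log(w_k) + x_k * x_k + ll_g + prior
        group_ll = np.log(np.sqrt(2.0) * tau) + special.logsumexp(log_terms, axis=1)
        return float(group_ll.sum())

    # -- estimation ---------------------------------------------------------

    def _start_params(self) -> np.ndarray:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                beta0 = sm.Logit(self.endog, self.exog).fit(disp=0, maxiter=100).params
            if not np.all(np.isfinite(beta0)):
                raise ValueError
        except Exception:
            beta0 = np.zeros(self.exog.shape[1])
        return np.concatenate([np.asarray(beta0), [np.log(0.5)]])

    def fit(self, n_quad: int = 9, gtol: float = 1e-8, maxiter: int = 300) -> ModelResult:
        start = self._start_params()

        def neg_ll(p: np.ndarray) -> float:
            return -self.loglike(p, n_quad=n_quad)

        res = optimize.minimize(
            neg_ll,
            start,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12},
        )
        params = res.x
        hess = _numerical_hessian(neg_ll, params)
        cov = _safe_inverse(hess)
        bse_all = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        k = self.exog.shape[1]
        beta, bse = params[:k], bse_all[:k]
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(bse > 0, beta / bse, np.nan)
        p = 2 * stats.norm.sf(np.abs(z))
        sigma_u = float(np.exp(params[-1]))
        return ModelResult(
            terms=self.exog_names,
            params=beta,
            bse=bse,
            stat=z,
            pvalues=p,
            stat_name="z",
            n_obs=len(self.endog),
            n_groups=self.n_groups,
            converged=bool(res.success),
            method="mixed logistic regression (adaptive Gauss-Hermite, random intercept)",
            df_method="normal",
            extra={"sigma_u": sigma_u, "loglike": -float(res.fun)},
        )


def _numerical_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                val = (f(x + ei) - 2 * f0 + f(x - ei)) / (h[i] * h[i])
            else:
                val = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h[i] * h[j])
            H[i, j] = H[j, i] = val
    return H


def _safe_inverse(H: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


# ---------------------------------------------------------------------------
# model classes


def _design_matrix(df: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    X = np.column_stack([np.ones(len(df))] + [df[t].to_numpy(dtype=float) for t in terms])
    return X


class TrialZapModel:
    """Trial-level mixed logistic regression of zap decisions.

    ``records`` are opportunity records from one marker condition and one
    behaviour condition.  Fixed effects: the condition's similarity coding,
    the Manhattan distance to the target, whether the participant was
    closest to the star, and the target's play order; random intercept per
    participant.  A dataset with a single participant is fitted as an
    ordinary logistic regression (the random effect is dropped).
    """

    COVARIATES = ["distance", "closest_to_star", "target_play_order"]

    def __init__(self, records: pd.DataFrame, condition: MarkerCondition) -> None:
        self.condition = MarkerCondition(condition)
        self.terms = ["const"] + similarity_terms(self.condition) + self.COVARIATES
        missing = [t for t in self.terms[1:] if t not in records.columns]
        if missing:
            raise ValueError(f"records lack required columns: {missing}")
        if records[self.terms[1:]].isna().any().any():
            raise ValueError(
                "NaN covariates: records do not match the requested condition coding"
            )
        self.records = records
        self.endog = records["zapped"].to_numpy(dtype=float)
        if self.endog.sum() in (0, len(self.endog)):
            raise DegenerateDataError("zap outcome is constant across all records")
        self.exog = _design_matrix(records, self.terms[1:])
        self.groups = records["participant_id"].to_numpy()

    def fit(self, n_quad: int = 9, **kwargs) -> ModelResult:
        if len(pd.unique(self.groups)) < 2:
            return _fit_plain_logit(self.endog, self.exog, self.terms)
        model = MixedLogit(self.endog, self.exog, self.groups, exog_names=self.terms)
        return model.fit(n_quad=n_quad, **kwargs)


def _fit_plain_logit(endog, exog, terms) -> ModelResult:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(endog, exog).fit(disp=0)
    return ModelResult(
        terms=list(terms),
        params=res.params,
        bse=res.bse,
        stat=res.tvalues,
        pvalues=res.pvalues,
        stat_name="z",
        n_obs=int(res.nobs),
        n_groups=1,
        converged=bool(res.mle_retvals.get("converged", True)),
        method="logistic regression (single participant; random effect dropped)",
    )


def _mixedlm_result(res, terms, n_groups, method, singular_ok=True) -> ModelResult:
    fe = res.fe_params
    bse = res.bse_fe
    z = np.asarray(fe) / np.asarray(bse)
    p = 2 * stats.norm.sf(np.abs(z))
    return ModelResult(
        terms=list(terms),
        params=np.asarray(fe),
        bse=np.asarray(bse),
        stat=z,
        pvalues=p,
        stat_name="z",
        n_obs=int(res.nobs),
        n_groups=n_groups,
        converged=bool(getattr(res, "converged", True)),
        method=method,
        df_method="normal",
        extra={"random_effects_cov": np.asarray(res.cov_re).tolist()},
    )


class TimeBinModel:
    """Mixed linear regression of time-binned zap rates.

    The table (from :func:`starharvest.features.time_binned_rates`, with a
    ``behaviour_condition`` column and globally unique participant ids when
    both behaviour arms are pooled) is modelled with fixed effects:
    similarity terms (no quadratic in the gradient condition), time bin,
    similarity x time bin, an all-zappers indicator and its interaction with
    time bin; random intercept and time-bin slope per participant.  Cells
    with undefined rates are dropped.
    """

    def __init__(self, binned: pd.DataFrame, condition: MarkerCondition) -> None:
        self.condition = MarkerCondition(condition)
        sim = similarity_terms(self.condition, quadratic=False)
        df = binned.dropna(subset=["rate"]).copy()
        if df.empty:
            raise DegenerateDataError("no defined rate cells")
        if "behaviour_condition" in df.columns:
            df["zappers"] = (
                df["behaviour_condition"].astype(str)
                == BehaviourCondition.ALL_ZAPPERS.value
            ).astype(float)
        else:
            df["zappers"] = 0.0
        terms = ["const"]
        for s in sim:
            terms.append(s)
        terms.append("time_bin")
        for s in sim:
            df[f"{s}:time_bin"] = df[s] * df["time_bin"]
            terms.append(f"{s}:time_bin")
        if df["zappers"].nunique() > 1:
            df["zappers:time_bin"] = df["zappers"] * df["time_bin"]
            terms += ["zappers", "zappers:time_bin"]
        self.df = df
        self.terms = terms
        self.sim_terms = sim

    def fit(self, **kwargs) -> ModelResult:
        df = self.df
        endog = df["rate"].to_numpy(dtype=float)
        exog = _design_matrix(df, self.terms[1:])
        groups = df["participant_id"].to_numpy()
        n_groups = len(pd.unique(groups))
        if n_groups < 2:
            res = sm.OLS(endog, exog).fit()
            return _ols_result(res, self.terms, "linear regression (single participant)")
        exog_re = np.column_stack([np.ones(len(df)), df["time_bin"].to_numpy(dtype=float)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(endog, exog, groups=groups, exog_re=exog_re).fit(
                reml=True, **kwargs
            )
        return _mixedlm_result(
            res,
            self.terms,
            n_groups,
            "mixed linear regression (random intercept + time-bin slope)",
        )


class ExtremesContrastModel:
    """Zap-rate contrast between the most and least similar targets.

    Input: one row per (participant, rank in {1, 4}) with columns
    ``participant_id`` (globally unique across conditions),
    ``marker_condition``, ``behaviour_condition``, ``similarity_rank`` and
    ``rate``.  Fixed effects: a dissimilar indicator (rank 4), marker
    condition dummies (binary as reference), their interactions with the
    indicator, and an all-zappers indicator; random intercept per
    participant.  The dissimilar x condition interactions measure how much
    marker complexity attenuates the intergroup-bias gap.
    """

    TERMS = [
        "const",
        "dissimilar",
        "multi",
        "gradient",
        "dissimilar:multi",
        "dissimilar:gradient",
        "zappers",
    ]

    def __init__(self, table: pd.DataFrame) -> None:
        df = table.dropna(subset=["rate"]).copy()
        ranks = set(df["similarity_rank"].unique())
        if not ranks <= {1, 4}:
            raise ValueError("extremes table must contain only similarity ranks 1 and 4")
        df["dissimilar"] = (df["similarity_rank"] == 4).astype(float)
        cond = df["marker_condition"].astype(str)
        df["multi"] = (cond == MarkerCondition.MULTI.value).astype(float)
        df["gradient"] = (cond == MarkerCondition.GRADIENT.value).astype(float)
        df["dissimilar:multi"] = df["dissimilar"] * df["multi"]
        df["dissimilar:gradient"] = df["dissimilar"] * df["gradient"]
        df["zappers"] = (
            df["behaviour_condition"].astype(str)
            == BehaviourCondition.ALL_ZAPPERS.value
        ).astype(float)
        self.df = df
        self.terms = [t for t in self.TERMS if t == "const" or df[t].nunique() > 1]

    def fit(self, **kwargs) -> ModelResult:
        df = self.df
        endog = df["rate"].to_numpy(dtype=float)
        exog = _design_matrix(df, self.terms[1:])
        groups = df["participant_id"].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(endog, exog, groups=groups).fit(reml=True, **kwargs)
        return _mixedlm_result(
            res,
            self.terms,
            len(pd.unique(groups)),
            "mixed linear regression (extremes contrast, random intercept)",
        )


def _ols_result(res, terms, method) -> ModelResult:
    return ModelResult(
        terms=list(terms),
        params=np.asarray(res.params),
        bse=np.asarray(res.bse),
        stat=np.asarray(res.tvalues),
        pvalues=np.asarray(res.pvalues),
        stat_name="t",
        n_obs=int(res.nobs),
        n_groups=int(res.nobs),
        converged=True,
        method=method,
        df_method="t",
        df_resid=float(res.df_resid),
    )


class AllocationModel:
    """Ordinary linear regression of the ten-star allocations.

    Four rows per participant (one per target), stars summing to 10;
    regressors are the condition's similarity coding.
    """

    def __init__(self, allocations: pd.DataFrame, condition: MarkerCondition) -> None:
        self.condition = MarkerCondition(condition)
        self.terms = ["const"] + similarity_terms(self.condition)
        sums = allocations.groupby("participant_id")["stars"].sum()
        bad = sums[sums != 10]
        if len(bad):
            raise ValueError(
                f"allocations must sum to 10 per participant; offenders: {list(bad.index[:5])}"
            )
        self.df = allocations

    def fit(self) -> ModelResult:
        endog = self.df["stars"].to_numpy(dtype=float)
        exog = _design_matrix(self.df, self.terms[1:])
        res = sm.OLS(endog, exog).fit()
        return _ols_result(res, self.terms, "linear regression (star allocation)")


# ---------------------------------------------------------------------------
# functional wrappers (the operation surface)


def fit_trial_logit(records: pd.DataFrame, condition: MarkerCondition, **kwargs) -> ModelResult:
    return TrialZapModel(records, condition).fit(**kwargs)


def fit_timebin_lm(binned: pd.DataFrame, condition: MarkerCondition, **kwargs) -> ModelResult:
    return TimeBinModel(binned, condition).fit(**kwargs)


def fit_extremes_lm(table: pd.DataFrame, **kwargs) -> ModelResult:
    return ExtremesContrastModel(table).fit(**kwargs)


def fit_allocation_lm(
    allocations: pd.DataFrame,
    condition: MarkerCondition,
    behaviour: Optional[BehaviourCondition] = None,
) -> ModelResult:
    df = allocations
    if behaviour is not None and "behaviour_condition" in df.columns:
        df = df[df["behaviour_condition"].astype(str) == BehaviourCondition(behaviour).value]
    return AllocationModel(df, condition).fit()
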