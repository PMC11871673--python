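"""Mixed-effects influence models for interval-level synchrony.

The response is dtw/second for one dyad in one sampling interval of a
scenario phase.  Fixed effects enter cumulatively in tiers:

====  ==================================================================
tier  fixed effects (cumulative)
====  ==================================================================
0     intercept only (random effects: team, dyad, interval index)
1     + proximity (mean dyad distance in metres)
2     + scenario type (street = reference)
3     + scenario order (first = reference)
4     + scenario type x scenario order interaction
====  ==================================================================

Random intercepts: the team is the top-level grouping factor; dyad identity
and sampling-interval index (time-bin identity shared across dyads) enter as
variance components within team.  Tiers are compared by sequential
likelihood-ratio tests on maximum-likelihood fits; the reported fit of the
chosen tier uses restricted maximum likelihood, with Wald-z confidence
intervals and p-values for the fixed effects.

The stability sweep refits the selected tier per metric for each sampling
interval length and records which fixed effects retain p <= 0.05.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import chi2

from .types import SCENARIO_PHASES, SessionAnnotation, ValidationError

logger = logging.getLogger("teamsync")

ALPHA_DEFAULT = 0.05
N_TIERS = 5

_TIER_TERMS = [
    "1",
    "mean_distance_m",
    "C(scenario, Treatment('street'))",
    "C(order, Treatment('first'))",
    "C(scenario, Treatment('street')):C(order, Treatment('first'))",
]

#: human-readable names for the patsy design columns
_EFFECT_NAMES = {
    "Intercept": "intercept",
    "mean_distance_m": "proximity",
    "C(scenario, Treatment('street'))[T.tunnel]": "scenario[tunnel]",
    "C(order, Treatment('first'))[T.second]": "order[second]",
    "C(scenario, Treatment('street'))[T.tunnel]:C(order, Treatment('first'))[T.second]": "scenario:order",
}

_VC_FULL = {"dyad": "0 + C(dyad)", "interval": "0 + C(interval_index)"}


def tier_formula(tier: int) -> str:
    if not 0 <= tier < N_TIERS:
        raise ValidationError(f"tier must be 0-4, got {tier}")
    rhs = " + ".join(_TIER_TERMS[: tier + 1]) if tier > 0 else "1"
    return f"dtw_per_second ~ {rhs}"


def build_design(
    sync_df: pd.DataFrame,
    prox_df: pd.DataFrame,
    annotations: dict[str, SessionAnnotation],
) -> pd.DataFrame:
    """Join synchrony and proximity tables into the model table (scenario phases only).

    One row per (dyad, metric, delta_s, interval): response ``dtw_per_second``,
    covariates ``mean_distance_m``, ``scenario`` (street/tunnel), ``order``
    (first/second) and ``interval_index``; grouping ids ``team_id`` and
    ``dyad``.  Rows with a missing response or missing proximity are dropped
    with a logged count (missing position data leaves its intervals absent).
    """
    keys = ["team_id", "member_a", "member_b", "phase", "delta_s", "interval_index"]
    if sync_df.empty or prox_df.empty:
        raise ValidationError("empty design: no synchrony or proximity records to join")
    s = sync_df[sync_df["phase"].isin(SCENARIO_PHASES)].copy()
    p = prox_df[prox_df["phase"].isin(SCENARIO_PHASES)][keys + ["mean_distance_m", "n_samples"]]
    merged = s.merge(p, on=keys, how="inner")
    n0 = len(merged)
    merged = merged.dropna(subset=["dtw_per_second", "mean_distance_m"])
    if len(merged) < n0:
        logger.info("build_design: dropped %d row(s) with missing synchrony or proximity", n0 - len(merged))
    if merged.empty:
        raise ValidationError("empty design: no scenario intervals with both synchrony and proximity")
    order_names = {1: "first", 2: "second"}
    merged["scenario"] = merged["phase"]
    merged["order"] = [
        order_names[annotations[t].scenario_order()[ph]]
        for t, ph in zip(merged["team_id"], merged["phase"])
    ]
    merged["dyad"] = merged["member_a"] + "--" + merged["member_b"]
    cols = ["team_id", "dyad", "metric", "delta_s", "interval_index", "interval_start_s",
            "scenario", "order", "mean_distance_m", "dtw_per_second"]
    return merged[cols].reset_index(drop=True)


@dataclass
class InfluenceResult:
    metric: str
    delta_s: int
    tier: int
    fixed_effects: dict[str, dict]          # name -> estimate, ci_low, ci_high, p
    random_variances: dict[str, float]      # team, dyad, interval -> variance
    n_obs: int
    converged: bool
    reml: bool
    llf: float
    simplifications: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric, "delta_s": self.delta_s, "tier": self.tier,
            "fixed_effects": self.fixed_effects,
            "random_variances": self.random_variances,
            "n_obs": self.n_obs, "converged": self.converged,
            "reml": self.reml, "llf": self.llf,
            "simplifications": self.simplifications,
        }


def _fit_once(table: pd.DataFrame, formula: str, vc: dict, reml: bool):
    model = smf.mixedlm(formula, table, groups=table["team_id"],
                        re_formula="1", vc_formula=vc or None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=reml, method="lbfgs", maxiter=200)
    return res


def fit_lme(
    table: pd.DataFrame,
    tier: int,
    *,
    reml: bool = True,
    allow_fallback: bool = True,
) -> InfluenceResult:
    """Fit the tiered linear mixed model on a single-metric, single-delta table.

    On non-convergence the random-effects structure is simplified stepwise
    (drop the interval-index component, then the dyad component); every
    simplification is recorded in the result.
    """
    for col, name in (("metric", "metric"), ("delta_s", "delta_s")):
        if table[col].nunique() != 1:
            raise ValidationError(f"fit_lme expects a single {name}; got {sorted(table[col].unique())}")
    formula = tier_formula(tier)
    ladders = [dict(_VC_FULL)]
    if allow_fallback:
        ladders += [{"dyad": _VC_FULL["dyad"]}, {}]
    simplifications: list[str] = []
    res = None
    for i, vc in enumerate(ladders):
        try:
            res = _fit_once(table, formula, vc, reml)
        except Exception as exc:  # singular fits raise LinAlgError etc.
            logger.warning("LME fit failed (%s); simplifying random effects", exc)
            res = None
        if res is not None and res.converged:
            break
        if i + 1 < len(ladders):
            dropped = set(ladders[i]) - set(ladders[i + 1])
            simplifications.append(f"dropped random intercept(s): {sorted(dropped)}")
    if res is None:
        raise ValidationError("mixed-model fit failed even after random-effect simplification")

    fe = {}
    ci = res.conf_int()
    for name in res.fe_params.index:
        fe[_EFFECT_NAMES.get(name, name)] = {
            "estimate": float(res.fe_params[name]),
            "ci_low": float(ci.loc[name, 0]),
            "ci_high": float(ci.loc[name, 1]),
            "p": float(res.pvalues[name]),
        }
    rv = {"team": float(np.asarray(res.cov_re)[0, 0]) if res.cov_re.size else 0.0}
    vcomp = dict(zip(res.model.exog_vc.names, np.asarray(res.vcomp))) if res.vcomp.size else {}
    rv["dyad"] = float(vcomp.get("dyad", 0.0))
    rv["interval"] = float(vcomp.get("interval", 0.0))
    return InfluenceResult(
        metric=str(table["metric"].iloc[0]),
        delta_s=int(table["delta_s"].iloc[0]),
        tier=tier,
        fixed_effects=fe,
        random_variances=rv,
        n_obs=int(len(table)),
        converged=bool(res.converged),
        reml=reml,
        llf=float(res.llf),
        simplifications=simplifications,
    )


@dataclass
class ModelSelection:
    best_tier: int
    comparison: pd.DataFrame    # tier, llf, lr_stat, p, converged
    truncated: bool = False

    def to_dict(self) -> dict:
        return {
            "best_tier": self.best_tier,
            "comparison": self.comparison.to_dict(orient="records"),
            "truncated": self.truncated,
        }


def select_model(table: pd.DataFrame, *, alpha: float = ALPHA_DEFAULT) -> ModelSelection:
    """Sequential likelihood-ratio model selection over tiers 0-4 (ML fits).

    The selected tier is the highest one whose added term is significant at
    ``alpha`` (parsimony on ties or non-improvement).  A non-convergent tier
    truncates the ladder at the last convergent one with a warning.
    """
    rows = []
    fits: list[InfluenceResult] = []
    truncated = False
    for tier in range(N_TIERS):
        try:
            res = fit_lme(table, tier, reml=False, allow_fallback=True)
        except ValidationError:
            res = None
        if res is None or not res.converged:
            logger.warning("tier %d did not converge; truncating model comparison", tier)
            truncated = True
            break
        lr = p = np.nan
        if fits:
            lr = max(0.0, 2.0 * (res.llf - fits[-1].llf))
            p = float(chi2.sf(lr, df=1))
        rows.append({"tier": tier, "llf": res.llf, "lr_stat": lr, "p": p, "converged": True})
        fits.append(res)
    comparison = pd.DataFrame(rows)
    sig = [r["tier"] for r in rows if np.isfinite(r.get("p", np.nan)) and r["p"] < alpha]
    best = max(sig) if sig else 0
    return ModelSelection(best_tier=best, comparison=comparison, truncated=truncated)


@dataclass
class StabilityRow:
    metric: str
    delta_s: int
    per_effect_significant: dict[str, bool]
    all_significant: bool
    n_obs: int

    def to_dict(self) -> dict:
        return {"metric": self.metric, "delta_s": self.delta_s,
                **{f"sig_{k}": v for k, v in self.per_effect_significant.items()},
                "all_significant": self.all_significant, "n_obs": self.n_obs}


def stability_sweep(
    design: pd.DataFrame,
    intervals: list[int],
    *,
    metrics: list[str] | None = None,
    tier: int = 4,
    alpha: float = ALPHA_DEFAULT,
) -> list[StabilityRow]:
    """Refit the selected model per metric per sampling-interval length.

    ``design`` must contain rows for every requested delta_s (a build_design
    output over multiple tilings).  Records which fixed effects retain
    p <= alpha; n_obs shrinks as delta_s grows because fewer tiles fit in a
    scenario.
    """
    metrics = metrics or sorted(design["metric"].unique())
    rows: list[StabilityRow] = []
    for metric in metrics:
        for delta in intervals:
            sub = design[(design["metric"] == metric) & (design["delta_s"] == delta)]
            if sub.empty:
                logger.warning("stability sweep: no rows for metric=%s delta_s=%s", metric, delta)
                continue
            res = fit_lme(sub, tier, reml=True)
            flags = {
                name: bool(eff["p"] <= alpha)
                for name, eff in res.fixed_effects.items()
                if name != "intercept"
            }
            rows.append(StabilityRow(metric, int(delta), flags, all(flags.values()), res.n_obs))
    return rows


def stability_frame(rows: list[StabilityRow]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in rows])
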