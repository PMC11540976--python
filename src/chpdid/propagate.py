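"""Uncertainty propagation, percent-change reporting, and events avoided.

The DiD analysis is repeated once per posterior draw of township log
incidence; the reported point estimate is the median of the per-draw
points and the reported 95% CI takes the medians of the per-draw lower
and upper bounds.  Log-scale effects convert to percent change via
(exp(coef) - 1) * 100, and a percent-change ATT converts to counts of
events avoided against the relevant counterfactual.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import did as did_mod
from .bym import PosteriorDraws
from .periods import PRE_PERIODS

logger = logging.getLogger(__name__)

TARGETS = ("overall", "e0", "e1")


def percent_change(coef):
    """Log-scale effect to percent change in incidence: (exp(c) - 1) * 100."""
    return (np.exp(coef) - 1.0) * 100.0


@dataclass
class PropagatedSummary:
    """Per-target draw distributions and their median summaries."""

    points: dict[str, np.ndarray]
    lowers: dict[str, np.ndarray]
    uppers: dict[str, np.ndarray]
    n_failed: int
    n_draws: int
    bound_shape: dict[str, dict] = field(default_factory=dict)

    def summary(self, target: str, as_percent: bool = True) -> dict:
        pt = float(np.median(self.points[target]))
        lo = float(np.median(self.lowers[target]))
        hi = float(np.median(self.uppers[target]))
        if as_percent:
            pt, lo, hi = (float(percent_change(x)) for x in (pt, lo, hi))
        return {"estimate": pt, "ci": (lo, hi)}

    def to_dict(self) -> dict:
        return {
            t: {
                "log": self.summary(t, as_percent=False),
                "percent": self.summary(t, as_percent=True),
                "bound_shape": self.bound_shape.get(t, {}),
            }
            for t in self.points
        } | {"n_draws": self.n_draws, "n_failed": self.n_failed}


def run_over_draws(
    draws: PosteriorDraws,
    exposure_panel: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    adjusted: bool = True,
    control_group: str = "never",
    covariate_names: list[str] | None = None,
    max_failure_rate: float = 0.01,
) -> PropagatedSummary:
    """Repeat the full DiD once per posterior draw and pool the results.

    Each draw supplies the outcome panel (log incidence); the group-time
    effects are estimated, aggregated to event-time and overall effects,
    and the per-draw point and CI bounds collected.  Draw-level failures
    are skipped and counted; more than ``max_failure_rate`` of them is an
    error.  Skew and excess kurtosis of the bound distributions are
    recorded so the normality of the CI distributions can be inspected.
    """
    points = {t: [] for t in TARGETS}
    lowers = {t: [] for t in TARGETS}
    uppers = {t: [] for t in TARGETS}
    n_failed = 0
    for d in range(draws.n_draws):
        frame = draws.draw_frame(d)
        try:
            panel = did_mod.build_panel(frame, exposure_panel, covariates)
            gts = did_mod.estimate_all_gt(
                panel,
                adjusted=adjusted,
                control_group=control_group,
                covariates=covariate_names,
            )
            agg = did_mod.aggregate_dynamic(gts)
        except (did_mod.EstimationError, ValueError) as exc:
            n_failed += 1
            logger.warning("draw %d failed: %s", d, exc)
            continue
        recs = {"overall": agg.overall}
        for e, rec in agg.dynamic.items():
            recs[f"e{e}"] = rec
        for t in TARGETS:
            if t in recs:
                points[t].append(recs[t]["estimate"])
                lowers[t].append(recs[t]["ci"][0])
                uppers[t].append(recs[t]["ci"][1])
    if n_failed > max_failure_rate * draws.n_draws:
        raise RuntimeError(
            f"{n_failed}/{draws.n_draws} draw-level analyses failed"
        )
    points = {t: np.array(v) for t, v in points.items() if len(v)}
    lowers = {t: np.array(v) for t, v in lowers.items() if len(v)}
    uppers = {t: np.array(v) for t, v in uppers.items() if len(v)}
    shape = {}
    for t in points:
        shape[t] = {}
        for name, arr in (("lower", lowers[t]), ("upper", uppers[t])):
            if len(arr) >= 8 and np.std(arr) > 0:
                shape[t][name] = {
                    "skew": float(stats.skew(arr)),
                    "excess_kurtosis": float(stats.kurtosis(arr)),
                }
    return PropagatedSummary(
        points=points,
        lowers=lowers,
        uppers=uppers,
        n_failed=n_failed,
        n_draws=draws.n_draws,
        bound_shape=shape,
    )


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass
class EventsAvoided:
    """Counterfactual events avoided implied by a percent-change ATT."""

    observed_events: float
    att_pct: float
    avoided: int
    ci: tuple[int, int]
    avoided_raw: float = 0.0


def _check_att(att_pct: float) -> float:
    a = att_pct / 100.0
    if a <= -1.0:
        raise ValueError("ATT of -100% or lower has no counterfactual")
    return a


def events_avoided_exposed(
    observed_events: float,
    att_pct: float,
    att_ci_pct: tuple[float, float],
) -> EventsAvoided:
    """Events avoided among townships actually exposed to the policy.

    The observed count already reflects the policy, so the counterfactual
    count divides it back out: avoided = E * (1 / (1 + a) - 1) with a the
    proportional ATT.  A negative ATT yields a positive avoided count.
    """
    a = _check_att(att_pct)
    avoided = observed_events * (1.0 / (1.0 + a) - 1.0)
    bounds = sorted(
        observed_events * (1.0 / (1.0 + _check_att(b)) - 1.0)
        for b in att_ci_pct
    )
    return EventsAvoided(
        observed_events=observed_events,
        att_pct=att_pct,
        avoided=_round_half_away(avoided),
        ci=(_round_half_away(bounds[0]), _round_half_away(bounds[1])),
        avoided_raw=avoided,
    )


def events_avoided_if_all_exposed(
    unexposed_events: float,
    att_pct: float,
    att_ci_pct: tuple[float, float],
) -> EventsAvoided:
    """Additional events avoided had unexposed townships also adopted.

    These counts were observed without the policy, so the effect applies
    forward: avoided = -E * a.
    """
    a = _check_att(att_pct)
    avoided = -unexposed_events * a
    bounds = sorted(-unexposed_events * _check_att(b) for b in att_ci_pct)
    return EventsAvoided(
        observed_events=unexposed_events,
        att_pct=att_pct,
        avoided=_round_half_away(avoided),
        ci=(_round_half_away(bounds[0]), _round_half_away(bounds[1])),
        avoided_raw=avoided,
    )


def pretrend_diagnostic(
    log_rate_table: pd.DataFrame,
    exposure_panel: pd.DataFrame,
    placebo_period: str = "P2011",
    base_period: str = "P2009",
) -> dict:
    """Pre-policy parallel-trends diagnostics.

    Computes per-cohort mean log incidence over the pre-policy windows,
    placebo DiD effects that pretend each eventual cohort adopted at
    ``placebo_period`` (change from ``base_period``, vs never-exposed
    townships), and a Wald test comparing per-township linear time trends
    between eventual cohorts and the never-exposed group.
    """
    panel = did_mod.build_panel(log_rate_table, exposure_panel)
    pre = panel[panel["period"].isin(PRE_PERIODS)]
    cohorts = [c for c in pre["cohort"].unique() if c != "never"]
    if not cohorts or "never" not in pre["cohort"].unique():
        raise ValueError("need at least one eventual cohort and never-exposed")
    if pre["period"].nunique() < 3:
        raise ValueError("need at least three pre-policy windows")

    cohort_means = (
        pre.groupby(["cohort", "period"])["y"].mean().unstack().to_dict("index")
    )

    wide = pre.pivot_table(index="township_id", columns="period", values="y")
    cohort = pre.groupby("township_id")["cohort"].first()
    placebo = {}
    eval_periods = [
        p for p in PRE_PERIODS
        if p > base_period
    ]
    for g in cohorts:
        for t in eval_periods:
            d = (cohort == g) | (cohort == "never")
            ids = cohort.index[d]
            dmask = (cohort.loc[ids] == g).to_numpy().astype(float)
            dy = (wide.loc[ids, t] - wide.loc[ids, base_period]).to_numpy()
            mu_t = (dmask * dy).sum() / dmask.sum()
            mu_c = ((1 - dmask) * dy).sum() / (1 - dmask).sum()
            att = mu_t - mu_c
            n_t, n_c = int(dmask.sum()), int((1 - dmask).sum())
            c_t = np.sqrt(n_t / (n_t - 1)) if n_t > 1 else 1.0
            c_c = np.sqrt(n_c / (n_c - 1)) if n_c > 1 else 1.0
            psi = c_t * dmask * (dy - mu_t) / dmask.mean() - c_c * (
                1 - dmask
            ) * (dy - mu_c) / (1 - dmask).mean()
            se = float(np.std(psi, ddof=1) / np.sqrt(len(ids)))
            placebo[f"{g}@{t}"] = {
                "estimate": float(att),
                "se": se,
                "ci": (att - 1.96 * se, att + 1.96 * se),
            }

    # per-township linear trend slopes over the pre windows
    order = {p: i for i, p in enumerate(PRE_PERIODS)}
    x = np.array([order[p] for p in wide.columns], dtype=float)
    xc = x - x.mean()
    slopes = (wide.to_numpy() @ xc) / (xc @ xc)
    slopes = pd.Series(slopes, index=wide.index)
    trend_tests = {}
    s_never = slopes[cohort == "never"]
    for g in cohorts:
        s_g = slopes[cohort == g]
        diff = s_g.mean() - s_never.mean()
        se = math.sqrt(
            s_g.var(ddof=1) / len(s_g) + s_never.var(ddof=1) / len(s_never)
        )
        z = diff / se
        trend_tests[g] = {
            "slope_diff": float(diff),
            "se": float(se),
            "z": float(z),
            "p": float(2 * stats.norm.sf(abs(z))),
        }
    return {
        "cohort_period_means": cohort_means,
        "placebo_att": placebo,
        "trend_tests": trend_tests,
    }
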