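"""Staggered-adoption difference-in-differences with doubly robust adjustment.

Group-time average treatment effects ATT(g, t) compare the outcome change
of the cohort first exposed in window g against never-exposed (or
not-yet-exposed) townships, from the common pre-policy base window.  The
adjusted estimator combines a logistic propensity score with a linear
outcome regression of the control outcome change on covariates, so it is
consistent when either model is right.  Per-township influence-function
values drive standard errors, event-time and overall aggregation, the
omnibus joint equality test, and subgroup heterogeneity tests.

Outcomes are log standardised incidence, so effects exponentiate to
multiplicative rate changes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .periods import ANALYSIS_PERIODS, COHORT_TO_PERIOD, period_index

logger = logging.getLogger(__name__)

BASE_PERIOD = "P2013"

PROPENSITY_TRIM = (0.001, 0.999)


class EstimationError(RuntimeError):
    """Raised when a group-time effect cannot be estimated."""


@dataclass
class GroupTimeATT:
    """One ATT(g, t) on the log scale with influence-function inference."""

    g: str
    t: str
    event_time: int
    estimate: float
    se: float
    psi: pd.Series  # per-township influence values over the (g, t) sample
    n_treated: int
    n_control: int
    adjusted: bool
    n_trimmed: int = 0
    propensity: pd.Series | None = None
    control_weights: pd.Series | None = None

    @property
    def ci(self) -> tuple[float, float]:
        return (self.estimate - 1.96 * self.se, self.estimate + 1.96 * self.se)


@dataclass
class AggregateResult:
    """Dynamic (by event time) and overall aggregates of group-time ATTs."""

    dynamic: dict[int, dict]          # e -> {estimate, se, ci, weights}
    overall: dict                     # {estimate, se, ci, weights}
    psi_dynamic: dict[int, pd.Series] = field(default_factory=dict)
    psi_overall: pd.Series | None = None

    def percent(self, which="overall") -> dict:
        """Effect and CI as percent change in incidence."""
        rec = self.overall if which == "overall" else self.dynamic[which]
        to_pct = lambda x: (np.exp(x) - 1.0) * 100.0
        lo, hi = rec["ci"]
        return {"estimate": to_pct(rec["estimate"]), "ci": (to_pct(lo), to_pct(hi))}


def build_panel(
    log_rate_table: pd.DataFrame,
    exposure_panel: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    subgroup: str | None = None,
) -> pd.DataFrame:
    """Merge outcomes, cohorts and covariates into one long panel.

    Returns rows (township_id, period, y, cohort, covariates...).  The
    panel must be balanced over the analysis windows; missing cells raise.
    """
    lr = log_rate_table
    if subgroup is not None and "subgroup" in lr.columns:
        lr = lr[lr["subgroup"] == subgroup]
    panel = lr[["township_id", "period", "log_rate"]].rename(columns={"log_rate": "y"})
    cohorts = exposure_panel[["township_id", "cohort"]].drop_duplicates()
    panel = panel.merge(cohorts, on="township_id", how="left")
    if panel["cohort"].isna().any():
        missing = panel[panel["cohort"].isna()]["township_id"].unique()
        raise ValueError(f"townships without cohort label: {missing[:5]}")
    if covariates is not None:
        panel = panel.merge(covariates, on="township_id", how="left")
    counts = panel.groupby("township_id")["period"].nunique()
    if counts.nunique() > 1:
        raise ValueError("unbalanced panel: townships observed in unequal periods")
    return panel


def _event_time(g: str, t: str) -> int:
    post = [p for p in ANALYSIS_PERIODS if period_index(p) >= period_index(COHORT_TO_PERIOD[g])]
    return post.index(t)


def _control_mask(cohort: pd.Series, g: str, t: str, control_group: str) -> pd.Series:
    if control_group == "never":
        return cohort == "never"
    if control_group == "not_yet":
        not_yet = cohort.map(
            lambda c: c == "never"
            or period_index(COHORT_TO_PERIOD[c]) > period_index(t)
        )
        return not_yet & (cohort != g)
    raise ValueError(f"unknown control_group {control_group!r}")


def _design(x: pd.DataFrame) -> np.ndarray | None:
    """Standardised covariate design with constant columns dropped.

    Centring/scaling is an affine reparameterisation (identical fitted
    propensities and regression predictions) that keeps the optimiser
    well conditioned at n ~ 150 with covariates on very different scales.
    """
    keep = [c for c in x.columns if np.nanstd(x[c].to_numpy()) > 1e-12]
    if not keep:
        return None
    arr = x[keep].to_numpy(dtype=float)
    arr = (arr - arr.mean(axis=0)) / arr.std(axis=0)
    return sm.add_constant(arr, has_constant="add")


def estimate_gt_att(
    panel: pd.DataFrame,
    g: str,
    t: str,
    adjusted: bool = True,
    control_group: str = "never",
    covariates: list[str] | None = None,
    covariates_or: list[str] | None = None,
    base_period: str = BASE_PERIOD,
) -> GroupTimeATT:
    """ATT(g, t): outcome change of cohort g at window t vs controls.

    Unadjusted mode is the difference in mean outcome changes.  Adjusted
    mode is the doubly robust combination: treated mean of the
    outcome-regression residual minus the odds-weighted control mean,
    with weights p(X)/(1-p(X)) normalised over controls.  ``covariates``
    feed the propensity model; ``covariates_or`` (defaulting to the same
    list) feed the outcome regression, allowing deliberate
    misspecification of one model in robustness experiments.
    """
    if period_index(t) < period_index(COHORT_TO_PERIOD[g]):
        raise ValueError(f"ATT({g}, {t}) undefined before adoption")
    wide = panel.pivot_table(index="township_id", columns="period", values="y")
    cohort = panel.groupby("township_id")["cohort"].first()
    treated = cohort == g
    control = _control_mask(cohort, g, t, control_group)
    if control.sum() == 0:
        raise EstimationError(f"empty control set for ATT({g}, {t})")
    if treated.sum() == 0:
        raise EstimationError(f"no townships in cohort {g}")

    sample = treated | control
    ids = cohort.index[sample]
    d = treated[sample].to_numpy().astype(float)
    dy = (wide.loc[ids, t] - wide.loc[ids, base_period]).to_numpy()
    if np.isnan(dy).any():
        raise ValueError("missing outcomes in the (g, t) sample")

    n = len(ids)
    n_trimmed = 0
    phat = None
    ctrl_w = None
    if not adjusted or not covariates:
        m_hat = np.zeros(n)
        w_ctrl = 1.0 - d
    else:
        cov_ps = covariates
        cov_or = covariates_or if covariates_or is not None else covariates
        x_all = panel.groupby("township_id").first().loc[ids]
        xd_ps = _design(x_all[cov_ps])
        xd_or = _design(x_all[cov_or])
        if xd_ps is None:
            m_hat = np.zeros(n) if xd_or is None else _fit_or(xd_or, dy, d)
            w_ctrl = 1.0 - d
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    logit = sm.Logit(d, xd_ps).fit(disp=0, maxiter=200)
                except Exception as exc:  # singular / separation
                    raise EstimationError(
                        f"propensity model failed for ATT({g}, {t}): {exc}"
                    ) from exc
            if np.max(np.abs(logit.params)) > 50:
                raise EstimationError(
                    f"complete separation in propensity model for ATT({g}, {t})"
                )
            p = logit.predict(xd_ps)
            out_of_range = (p < PROPENSITY_TRIM[0]) | (p > PROPENSITY_TRIM[1])
            n_trimmed = int(out_of_range.sum())
            if n_trimmed:
                logger.warning(
                    "ATT(%s, %s): trimmed %d propensity values to %s",
                    g, t, n_trimmed, PROPENSITY_TRIM,
                )
                p = np.clip(p, *PROPENSITY_TRIM)
            m_hat = _fit_or(xd_or, dy, d) if xd_or is not None else np.zeros(n)
            w_ctrl = (1.0 - d) * p / (1.0 - p)
            phat = pd.Series(p, index=ids, name="propensity")

    r = dy - m_hat
    pbar = d.mean()
    wbar = w_ctrl.mean()
    mu_t = (d * r).mean() / pbar
    mu_c = (w_ctrl * r).mean() / wbar
    att = mu_t - mu_c
    # HC2-style small-sample factors: each arm's squared-residual sum uses
    # 1/(m-1) rather than 1/m scaling, matching the unbiased (Welch)
    # variance of a difference in means in the unweighted case
    n_t = int(d.sum())
    n_c = int((1 - d).sum())
    c_t = np.sqrt(n_t / (n_t - 1)) if n_t > 1 else 1.0
    c_c = np.sqrt(n_c / (n_c - 1)) if n_c > 1 else 1.0
    psi = c_t * d * (r - mu_t) / pbar - c_c * w_ctrl * (r - mu_c) / wbar
    se = float(np.std(psi, ddof=1) / np.sqrt(n))
    if se == 0:
        logger.warning(
            "ATT(%s, %s): zero-variance influence function (noise-free data?)",
            g, t,
        )
    if w_ctrl.sum() > 0:
        ctrl_w = pd.Series(w_ctrl, index=ids, name="control_weight")
        ctrl_w = ctrl_w[ctrl_w > 0] / ctrl_w[ctrl_w > 0].sum()
    return GroupTimeATT(
        g=g,
        t=t,
        event_time=_event_time(g, t),
        estimate=float(att),
        se=se,
        psi=pd.Series(psi, index=ids, name="psi"),
        n_treated=int(d.sum()),
        n_control=int((1 - d).sum()),
        adjusted=bool(adjusted and covariates),
        n_trimmed=n_trimmed,
        propensity=phat,
        control_weights=ctrl_w,
    )


def _fit_or(xd: np.ndarray, dy: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Outcome regression of the change on covariates among controls."""
    ctrl = d == 0
    beta, *_ = np.linalg.lstsq(xd[ctrl], dy[ctrl], rcond=None)
    return xd @ beta


def estimate_all_gt(
    panel: pd.DataFrame,
    adjusted: bool = True,
    control_group: str = "never",
    covariates: list[str] | None = None,
    covariates_or: list[str] | None = None,
) -> list[GroupTimeATT]:
    """All defined ATT(g, t) over cohorts present in the panel."""
    cohorts = panel["cohort"].unique()
    out = []
    for g in ("g2016", "g2018"):
        if g not in cohorts:
            continue
        first = COHORT_TO_PERIOD[g]
        for t in ANALYSIS_PERIODS:
            if period_index(t) < period_index(first):
                continue
            out.append(
                estimate_gt_att(
                    panel, g, t,
                    adjusted=adjusted,
                    control_group=control_group,
                    covariates=covariates,
                    covariates_or=covariates_or,
                )
            )
    return out


def _combine_psi(
    parts: list[tuple[float, pd.Series]],
) -> tuple[pd.Series, float]:
    """Weighted sum of influence functions on the union township set.

    Each component's values are rescaled by n_union / n_component so that
    every estimator satisfies est - truth ~ mean of psi over the union
    sample; the combined SE is then sd(psi) / sqrt(n_union).
    """
    index = parts[0][1].index
    for _, p in parts[1:]:
        index = index.union(p.index)
    n = len(index)
    total = pd.Series(0.0, index=index)
    for w, p in parts:
        total = total.add(w * (n / len(p)) * p, fill_value=0.0)
    se = float(np.std(total.to_numpy(), ddof=1) / np.sqrt(n))
    return total, se


def aggregate_dynamic(gts: list[GroupTimeATT]) -> AggregateResult:
    """Event-time effects theta(e): cohort-size-weighted means of ATT(g, t).

    Weights are proportional to the number of treated townships in each
    contributing cohort and sum to one within each event time.
    """
    if not gts:
        raise ValueError("no group-time effects to aggregate")
    dynamic: dict[int, dict] = {}
    psi_dyn: dict[int, pd.Series] = {}
    for e in sorted({gt.event_time for gt in gts}):
        members = [gt for gt in gts if gt.event_time == e]
        sizes = np.array([gt.n_treated for gt in members], dtype=float)
        w = sizes / sizes.sum()
        est = float(np.sum(w * [gt.estimate for gt in members]))
        psi, se = _combine_psi(list(zip(w, [gt.psi for gt in members])))
        dynamic[e] = {
            "estimate": est,
            "se": se,
            "ci": (est - 1.96 * se, est + 1.96 * se),
            "weights": {f"ATT({gt.g},{gt.t})": wi for gt, wi in zip(members, w)},
            "n_treated": int(sizes.sum()),
        }
        psi_dyn[e] = psi
    overall = _aggregate_overall(dynamic, psi_dyn)
    return AggregateResult(
        dynamic=dynamic,
        overall=overall[0],
        psi_dynamic=psi_dyn,
        psi_overall=overall[1],
    )


def _aggregate_overall(dynamic, psi_dyn):
    es = sorted(dynamic)
    sizes = np.array([dynamic[e]["n_treated"] for e in es], dtype=float)
    w = sizes / sizes.sum()
    est = float(np.sum(w * [dynamic[e]["estimate"] for e in es]))
    psi, se = _combine_psi([(wi, psi_dyn[e]) for wi, e in zip(w, es)])
    rec = {
        "estimate": est,
        "se": se,
        "ci": (est - 1.96 * se, est + 1.96 * se),
        "weights": {f"e={e}": float(wi) for e, wi in zip(es, w)},
    }
    return rec, psi


def aggregate_overall(result: AggregateResult) -> dict:
    """Overall ATT (already computed during dynamic aggregation)."""
    return result.overall


def joint_equality_test(gts: list[GroupTimeATT]) -> dict:
    """Omnibus Wald test that all group-time ATTs are equal.

    Contrasts each effect against the first; the contrast covariance
    comes from the influence functions on the union township set.
    Reported as F with (k-1, n-k) reference degrees of freedom.
    """
    k = len(gts)
    if k < 2:
        raise ValueError("joint test needs at least two group-time effects")
    index = gts[0].psi.index
    for gt in gts[1:]:
        index = index.union(gt.psi.index)
    n = len(index)
    psi_mat = np.column_stack(
        [
            gt.psi.reindex(index, fill_value=0.0).to_numpy() * (n / len(gt.psi))
            for gt in gts
        ]
    )
    cov = (psi_mat.T @ psi_mat) / n**2
    ests = np.array([gt.estimate for gt in gts])
    contrast = np.zeros((k - 1, k))
    contrast[:, 0] = -1.0
    contrast[np.arange(k - 1), np.arange(1, k)] = 1.0
    c = contrast @ ests
    vc = contrast @ cov @ contrast.T
    if np.allclose(c, 0.0):
        return {"F": 0.0, "p": 1.0, "df": (k - 1, n - k)}
    try:
        solved = np.linalg.solve(vc, c)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(
            "singular contrast covariance; drop collinear effects"
        ) from exc
    wald = float(c @ solved)
    f_stat = wald / (k - 1)
    p = float(stats.f.sf(f_stat, k - 1, n - k))
    return {"F": f_stat, "p": p, "df": (k - 1, n - k)}


def heterogeneity_test(
    result_a: AggregateResult, result_b: AggregateResult
) -> dict:
    """Two-sided z test for a difference in overall ATTs between subgroups.

    The covariance between the two estimates is taken from the paired
    influence functions when both are available (the subgroups share the
    township panel); otherwise it is assumed zero with a logged caveat.
    """
    a, b = result_a.overall, result_b.overall
    if a.get("se") is None or b.get("se") is None:
        raise ValueError("both results need standard errors")
    cov = 0.0
    pa, pb = result_a.psi_overall, result_b.psi_overall
    if pa is not None and pb is not None:
        index = pa.index.union(pb.index)
        va = pa.reindex(index, fill_value=0.0).to_numpy()
        vb = pb.reindex(index, fill_value=0.0).to_numpy()
        cov = float(va @ vb) / len(index) ** 2
    else:
        logger.warning("no paired influence functions; assuming zero covariance")
    var = a["se"] ** 2 + b["se"] ** 2 - 2 * cov
    if var <= 0:
        raise EstimationError("non-positive variance for heterogeneity contrast")
    diff = a["estimate"] - b["estimate"]
    if diff == 0.0:
        return {"z": 0.0, "p": 1.0, "cov": cov}
    z = diff / np.sqrt(var)
    return {"z": float(z), "p": float(2 * stats.norm.sf(abs(z))), "cov": cov}


def covariate_balance(
    gt: GroupTimeATT, panel: pd.DataFrame, covariates: list[str]
) -> pd.Series:
    """Standardised mean differences after IPW reweighting of controls."""
    x = panel.groupby("township_id").first()
    treated_ids = gt.psi.index[gt.psi.index.isin(x.index)]
    cohort = x["cohort"]
    t_mask = cohort.loc[treated_ids] == gt.g
    xt = x.loc[treated_ids[t_mask], covariates]
    if gt.control_weights is None:
        raise ValueError("no control weights stored (unadjusted fit?)")
    w = gt.control_weights
    xc = x.loc[w.index, covariates]
    diffs = {}
    for c in covariates:
        mt = xt[c].mean()
        mc = float(np.sum(w.to_numpy() * xc[c].to_numpy()))
        sd = np.sqrt((xt[c].var(ddof=1) + xc[c].var(ddof=1)) / 2)
        diffs[c] = 0.0 if sd == 0 else (mt - mc) / sd
    return pd.Series(diffs, name="std_diff")
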