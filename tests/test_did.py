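"""Group-time ATT estimation, aggregation and tests."""

import numpy as np
import pandas as pd
import pytest

from chpdid import did
from chpdid.did import AggregateResult

from conftest import DID_COVS, run_single_did


def panel_from_wide(values, cohorts, covariates=None):
    """values: {township: {period: y}}; cohorts: {township: g}."""
    rows = []
    for tid, per in values.items():
        for p, y in per.items():
            rows.append({"township_id": tid, "period": p, "y": y,
                         "cohort": cohorts[tid]})
    panel = pd.DataFrame(rows)
    if covariates is not None:
        cov = pd.DataFrame(covariates).T.rename_axis("township_id").reset_index()
        panel = panel.merge(cov, on="township_id")
    return panel


def two_by_two(treated_pre, treated_post, control_pre, control_post, n_each=4):
    values, cohorts = {}, {}
    for i in range(n_each):
        values[f"T{i}"] = {"P2013": treated_pre, "P2016": treated_post}
        cohorts[f"T{i}"] = "g2016"
        values[f"C{i}"] = {"P2013": control_pre, "P2016": control_post}
        cohorts[f"C{i}"] = "never"
    return panel_from_wide(values, cohorts)


class TestGroupTimeATT:
    def test_matches_four_cell_closed_form(self):
        panel = two_by_two(10.0, 9.0, 8.0, 8.5)
        gt = did.estimate_gt_att(panel, "g2016", "P2016", adjusted=False)
        assert gt.estimate == pytest.approx((9 - 10) - (8.5 - 8), abs=1e-12)

    def test_unadjusted_equals_closed_form_on_random_panels(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            nt, nc = rng.integers(3, 10, size=2)
            yt0, yt1 = rng.normal(5, 1, nt), rng.normal(5, 1, nt)
            yc0, yc1 = rng.normal(5, 1, nc), rng.normal(5, 1, nc)
            values, cohorts = {}, {}
            for i in range(nt):
                values[f"T{i}"] = {"P2013": yt0[i], "P2016": yt1[i]}
                cohorts[f"T{i}"] = "g2016"
            for i in range(nc):
                values[f"C{i}"] = {"P2013": yc0[i], "P2016": yc1[i]}
                cohorts[f"C{i}"] = "never"
            gt = did.estimate_gt_att(
                panel_from_wide(values, cohorts), "g2016", "P2016", adjusted=False
            )
            oracle = (yt1.mean() - yt0.mean()) - (yc1.mean() - yc0.mean())
            assert gt.estimate == pytest.approx(oracle, abs=1e-10)

    def test_constant_covariates_reduce_to_unadjusted(self):
        panel = two_by_two(10.0, 9.0, 8.0, 8.5)
        cov = {t: {"x1": 3.0, "x2": 7.0} for t in panel["township_id"].unique()}
        panel = panel.merge(
            pd.DataFrame(cov).T.rename_axis("township_id").reset_index(),
            on="township_id",
        )
        adj = did.estimate_gt_att(
            panel, "g2016", "P2016", adjusted=True, covariates=["x1", "x2"]
        )
        una = did.estimate_gt_att(panel, "g2016", "P2016", adjusted=False)
        assert adj.estimate == pytest.approx(una.estimate, abs=1e-10)

    def test_outcome_shift_invariance(self, sim_default):
        """Adding a constant to every outcome leaves all ATTs unchanged."""
        from chpdid import exposure, rates

        panel_e = exposure.assign_exposure(
            exposure.compute_enrolled_fraction(sim_default.villages)
        )
        pooled = rates.pool_events(sim_default.events)
        lt = rates.log_rates(rates.direct_standardize(pooled, "all"))
        panel = did.build_panel(lt, panel_e, sim_default.covariates)
        shifted = panel.copy()
        shifted["y"] = shifted["y"] + 2.5
        for adjusted in (False, True):
            a = did.estimate_gt_att(panel, "g2016", "P2016",
                                    adjusted=adjusted, covariates=DID_COVS)
            b = did.estimate_gt_att(shifted, "g2016", "P2016",
                                    adjusted=adjusted, covariates=DID_COVS)
            assert a.estimate == pytest.approx(b.estimate, abs=1e-10)

    def test_influence_function_centred(self, sim_default):
        agg, gts = run_single_did(sim_default, adjusted=True, covariates=DID_COVS)
        for gt in gts:
            assert abs(gt.psi.mean()) < 1e-10
            assert gt.se > 0

    def test_pre_adoption_target_rejected(self):
        panel = two_by_two(1, 2, 3, 4)
        with pytest.raises(ValueError, match="before adoption"):
            did.estimate_gt_att(panel, "g2018", "P2016")

    def test_empty_control_set_rejected(self):
        values = {f"T{i}": {"P2013": 1.0, "P2016": 2.0} for i in range(4)}
        cohorts = {t: "g2016" for t in values}
        with pytest.raises(did.EstimationError, match="control"):
            did.estimate_gt_att(
                panel_from_wide(values, cohorts), "g2016", "P2016", adjusted=False
            )

    def test_ipw_balances_confounded_covariates(self):
        """After odds-of-exposure reweighting, control covariate means
        line up with treated means: the standardised difference is small
        on average across replicate studies (each replicate keeps some
        finite-sample residual imbalance)."""
        from chpdid import SimulationConfig, generate_dataset, exposure, rates

        raw_diffs, weighted_diffs = [], []
        for seed in range(15):
            cfg = SimulationConfig(
                cohort_fractions=(0.55, 0.0, 0.45),
                assignment_confounding=1.0,
                trend_confounding=0.05,
                seed=100 + seed,
            )
            d = generate_dataset(cfg)
            panel_e = exposure.assign_exposure(
                exposure.compute_enrolled_fraction(d.villages)
            )
            pooled = rates.pool_events(d.events)
            lt = rates.log_rates(rates.direct_standardize(pooled, "all"))
            panel = did.build_panel(lt, panel_e, d.covariates)
            gt = did.estimate_gt_att(
                panel, "g2016", "P2016", adjusted=True, covariates=["agri_pct"]
            )
            balance = did.covariate_balance(gt, panel, ["agri_pct"])
            raw = panel.groupby("township_id").first()
            raw_diffs.append(
                abs(
                    raw[raw["cohort"] == "g2016"]["agri_pct"].mean()
                    - raw[raw["cohort"] == "never"]["agri_pct"].mean()
                )
                / raw["agri_pct"].std()
            )
            weighted_diffs.append(abs(balance["agri_pct"]))
        assert np.mean(raw_diffs) > 0.2  # assignment really is confounded
        assert np.mean(weighted_diffs) < 0.1


class TestAggregation:
    def test_single_cohort_event_time_passes_through(self, sim_default):
        agg, gts = run_single_did(sim_default, adjusted=False)
        e1 = [g for g in gts if g.event_time == 1]
        assert len(e1) == 1
        assert agg.dynamic[1]["estimate"] == pytest.approx(e1[0].estimate, abs=1e-12)
        assert agg.dynamic[1]["se"] == pytest.approx(e1[0].se, rel=1e-10)

    def test_equal_cohort_sizes_average_evenly(self):
        values, cohorts = {}, {}
        for i in range(5):
            values[f"A{i}"] = {"P2013": 10.0 + i, "P2016": 9.0 + i, "P2018": 9.5 + i}
            cohorts[f"A{i}"] = "g2016"
            values[f"B{i}"] = {"P2013": 8.0 - i, "P2016": 8.0 - i, "P2018": 6.0 - i}
            cohorts[f"B{i}"] = "g2018"
            values[f"C{i}"] = {"P2013": 5.0, "P2016": 5.0 + i, "P2018": 5.5}
            cohorts[f"C{i}"] = "never"
        panel = panel_from_wide(values, cohorts)
        gts = did.estimate_all_gt(panel, adjusted=False)
        agg = did.aggregate_dynamic(gts)
        e0 = [g for g in gts if g.event_time == 0]
        assert agg.dynamic[0]["estimate"] == pytest.approx(
            np.mean([g.estimate for g in e0]), abs=1e-12
        )
        for rec in agg.dynamic.values():
            assert sum(rec["weights"].values()) == pytest.approx(1.0)
        assert sum(agg.overall["weights"].values()) == pytest.approx(1.0)

    def test_identical_dynamic_effects_pin_overall(self):
        psi = pd.Series(np.zeros(4), index=list("abcd"))
        psi.iloc[0] = 0.1
        psi.iloc[1] = -0.1
        agg = AggregateResult(
            dynamic={
                0: {"estimate": -0.07, "se": 0.01, "ci": (-0.09, -0.05),
                    "weights": {}, "n_treated": 10},
                1: {"estimate": -0.07, "se": 0.02, "ci": (-0.11, -0.03),
                    "weights": {}, "n_treated": 30},
            },
        overall={}, psi_dynamic={0: psi, 1: psi}, psi_overall=None)
        rec, _ = did._aggregate_overall(agg.dynamic, agg.psi_dynamic)
        assert rec["estimate"] == pytest.approx(-0.07, abs=1e-12)

    def test_ci_contains_estimate(self, sim_default):
        agg, _ = run_single_did(sim_default, adjusted=True, covariates=DID_COVS)
        for rec in [agg.overall, *agg.dynamic.values()]:
            assert rec["ci"][0] <= rec["estimate"] <= rec["ci"][1]


class TestJointEquality:
    def test_identical_estimates_give_zero_statistic(self):
        psi = pd.Series(np.r_[0.2, -0.2, np.zeros(6)], index=[f"t{i}" for i in range(8)])
        gts = [
            did.GroupTimeATT("g2016", t, e, -0.05, 0.01, psi, 4, 4, False)
            for e, t in enumerate(["P2016", "P2018"])
        ]
        res = did.joint_equality_test(gts)
        assert res["F"] == 0.0 and res["p"] == 1.0

    def test_two_effects_reduce_to_squared_z(self, sim_default):
        _, gts = run_single_did(sim_default, adjusted=False)
        pair = [g for g in gts if g.g == "g2016"]
        res = did.joint_equality_test(pair)
        index = pair[0].psi.index.union(pair[1].psi.index)
        n = len(index)
        p0 = pair[0].psi.reindex(index, fill_value=0.0) * (n / len(pair[0].psi))
        p1 = pair[1].psi.reindex(index, fill_value=0.0) * (n / len(pair[1].psi))
        var = ((p1 - p0) @ (p1 - p0)) / n**2
        z = (pair[1].estimate - pair[0].estimate) / np.sqrt(var)
        assert res["F"] == pytest.approx(z**2, rel=1e-10)

    def test_needs_at_least_two_effects(self):
        with pytest.raises(ValueError, match="two"):
            did.joint_equality_test([])


class TestHeterogeneity:
    def _agg(self, est, se, psi=None):
        return AggregateResult(
            dynamic={}, overall={"estimate": est, "se": se,
                                 "ci": (est - 1.96 * se, est + 1.96 * se)},
            psi_overall=psi,
        )

    def test_identical_results_give_null_z(self):
        a = self._agg(-0.08, 0.02)
        res = did.heterogeneity_test(a, self._agg(-0.08, 0.02))
        assert res["z"] == 0.0 and res["p"] == 1.0

    def test_hand_computed_z_without_covariance(self):
        res = did.heterogeneity_test(
            self._agg(-0.1, 0.02), self._agg(-0.05, 0.02)
        )
        assert res["z"] == pytest.approx(-1.7678, abs=5e-5)

    def test_shared_panel_covariance_used(self, sim_default):
        from chpdid import exposure, rates

        panel_e = exposure.assign_exposure(
            exposure.compute_enrolled_fraction(sim_default.villages)
        )
        pooled = rates.pool_events(sim_default.events)
        aggs = {}
        for sub in ("men", "women"):
            lt = rates.log_rates(rates.direct_standardize(pooled, sub))
            panel = did.build_panel(lt, panel_e, sim_default.covariates)
            aggs[sub] = did.aggregate_dynamic(
                did.estimate_all_gt(panel, adjusted=True, covariates=DID_COVS)
            )
        res = did.heterogeneity_test(aggs["men"], aggs["women"])
        assert res["cov"] != 0.0
        assert 0.0 <= res["p"] <= 1.0
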