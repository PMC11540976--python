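"""Synthetic-study generator: geography, rollout, effects and counts."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from chpdid import SimulationConfig, generate_dataset
from chpdid.simulate import (
    generate_geography,
    generate_spatial_effects,
    township_ids,
)


def adjacency_matrix(adjacency, ids):
    index = {t: i for i, t in enumerate(ids)}
    mat = np.zeros((len(ids), len(ids)))
    for a, b in adjacency.to_numpy():
        mat[index[a], index[b]] = 1
        mat[index[b], index[a]] = 1
    return mat


class TestGeography:
    def test_2x2_lattice_has_four_rook_edges(self):
        cfg = SimulationConfig(n_townships=4, grid_dims=(2, 2), seed=0)
        _, adjacency, _ = generate_geography(cfg, np.random.default_rng(0))
        assert len(adjacency) == 4

    def test_adjacency_symmetric_and_irreflexive(self, sim_default):
        ids = list(sim_default.townships["township_id"])
        mat = adjacency_matrix(sim_default.adjacency, ids)
        assert np.array_equal(mat, mat.T)
        assert np.all(np.diag(mat) == 0)

    def test_full_size_lattice_connected(self, sim_default):
        g = nx.Graph()
        ids = list(sim_default.townships["township_id"])
        g.add_nodes_from(ids)
        g.add_edges_from(map(tuple, sim_default.adjacency.to_numpy()))
        assert g.number_of_nodes() == 151
        assert nx.is_connected(g)

    def test_village_counts_within_range(self, sim_default):
        counts = sim_default.villages.groupby("township_id").size()
        lo, hi = sim_default.config.villages_range
        assert counts.between(lo, hi).all()
        assert set(counts.index) == set(township_ids(151))

    def test_impossible_grid_rejected(self):
        cfg = SimulationConfig(n_townships=10, grid_dims=(3, 3))
        with pytest.raises(ValueError, match="grid"):
            cfg.validate()


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,match",
        [
            ({"cohort_fractions": (0.5, 0.5, 0.5)}, "sum to 1"),
            ({"spatial_sd": -0.1}, "SDs"),
            ({"population_range": (0, 10)}, "population"),
            ({"villages_range": (0, 5)}, "villages_range"),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            SimulationConfig(**kwargs).validate()


class TestRollout:
    def test_planted_thresholds_by_cohort(self, sim_default):
        v = sim_default.villages
        cohorts = sim_default.cohorts
        for tid, grp in v.groupby("township_id"):
            m = len(grp)
            by17 = (grp["enroll_year"].dropna() <= 2017).sum()
            by19 = grp["enroll_year"].notna().sum()
            cohort = cohorts[tid]
            if cohort == "g2016":
                assert by17 > m / 2
            elif cohort == "g2018":
                assert by17 <= m / 2 and by19 > m / 2
            else:
                assert by19 <= m / 2

    def test_enrollment_years_in_policy_window(self, sim_default):
        years = sim_default.villages["enroll_year"].dropna()
        assert years.between(2015, 2019).all()

    def test_default_cohort_sizes(self, sim_default):
        counts = sim_default.cohorts.value_counts()
        assert counts["g2016"] == 75
        assert counts["g2018"] == 17
        assert counts["never"] == 59


class TestSpatialEffects:
    def test_icar_field_sums_to_zero(self, sim_default):
        cfg = sim_default.config
        u, v = generate_spatial_effects(
            cfg, sim_default.adjacency, np.random.default_rng(3)
        )
        assert abs(u.sum()) < 1e-8

    def test_spatial_field_smoother_than_iid(self, sim_default):
        """Neighbour differences of u are smaller relative to its scale
        than for an iid field of the same marginal spread."""
        cfg = sim_default.config
        rng = np.random.default_rng(12)
        u, _ = generate_spatial_effects(cfg, sim_default.adjacency, rng)
        edges = sim_default.adjacency.to_numpy()
        du = np.array([u[a] - u[b] for a, b in edges])
        iid = pd.Series(
            rng.normal(0, u.std(), size=len(u)), index=u.index
        )
        diid = np.array([iid[a] - iid[b] for a, b in edges])
        assert (du**2).mean() / u.var() < (diid**2).mean() / iid.var()


class TestEvents:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(
            n_townships=12, grid_dims=(3, 4), villages_range=(3, 6),
            cohort_fractions=(0.5, 0.25, 0.25), seed=77,
        )
        d1 = generate_dataset(cfg)
        d2 = generate_dataset(cfg)
        pd.testing.assert_frame_equal(d1.events, d2.events)
        pd.testing.assert_frame_equal(d1.villages, d2.villages)
        pd.testing.assert_frame_equal(d1.covariates, d2.covariates)

    def test_counts_match_intensities_over_replicates(self, sim_small):
        """Mean simulated count over 1000 redraws stays within 3 SE of
        the generating intensity at a sampled cell."""
        lam = sim_small._lam_yearly
        i, y, s = 3, 8, 2
        rng = np.random.default_rng(123)
        means = np.array(
            [rng.poisson(lam[i, y, s]) for _ in range(1000)], dtype=float
        )
        se = np.sqrt(lam[i, y, s] / 1000)
        assert abs(means.mean() - lam[i, y, s]) < 3 * se

    def test_redraw_preserves_structure(self, sim_small):
        ev = sim_small.redraw_events(np.random.default_rng(5))
        assert ev.shape == sim_small.events.shape
        assert (ev["population"] == sim_small.events["population"]).all()

    def test_null_effects_equalise_cohort_rates(self):
        """With tau = 0, no confounding and no random effects, the true
        standardised rates are identical across townships in a window."""
        cfg = SimulationConfig(
            n_townships=12, grid_dims=(3, 4), villages_range=(3, 6),
            cohort_fractions=(0.5, 0.25, 0.25), tau_dynamic=(0.0, 0.0),
            spatial_sd=0.0, unstructured_sd=0.0,
            covariate_effects={}, seed=4,
        )
        d = generate_dataset(cfg)
        for period in ("P2016", "P2018"):
            vals = [
                t["log_std_rate"][period] for t in d.truth["townships"].values()
            ]
            assert np.ptp(vals) < 1e-12

    def test_planted_effect_shifts_true_rates_multiplicatively(self):
        """Switching tau on changes exposed townships' true rates by
        exactly exp(tau) and leaves never-exposed townships untouched."""
        base = dict(
            n_townships=12, grid_dims=(3, 4), villages_range=(3, 6),
            cohort_fractions=(0.5, 0.25, 0.25), seed=9,
        )
        null = generate_dataset(SimulationConfig(**base, tau_dynamic=(0.0, 0.0)))
        hit = generate_dataset(
            SimulationConfig(**base, tau_dynamic=(np.log(0.934), np.log(0.90)))
        )
        for tid, rec in hit.truth["townships"].items():
            ref = null.truth["townships"][tid]
            for period in ("P2016", "P2018"):
                diff = rec["log_std_rate"][period] - ref["log_std_rate"][period]
                assert diff == pytest.approx(rec["tau_by_period"][period], abs=1e-12)


class TestOutputFiles:
    def test_written_csvs_round_trip(self, sim_small, tmp_path):
        sim_small.write(tmp_path)
        for name in ("villages", "events", "covariates", "adjacency"):
            assert (tmp_path / f"{name}.csv").exists()
        ev = pd.read_csv(tmp_path / "events.csv")
        assert len(ev) == len(sim_small.events)
        assert (tmp_path / "truth.json").exists()
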