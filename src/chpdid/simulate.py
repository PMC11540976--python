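"""Synthetic study generator for the clean-heating-policy evaluation.

Real Beijing surveillance data are restricted, so every analysis stage is
exercised on synthetic townships that reproduce the statistical structure
the estimators assume: ~151 townships on a rook-adjacency lattice, each
containing villages that enroll into the policy in a staggered fashion
over 2015-2019; Poisson event counts per age-sex stratum whose log means
carry stratum baselines, common period effects, covariate effects,
spatially structured (intrinsic CAR) and unstructured township effects,
and a dynamic multiplicative treatment effect switched on at each
township's adoption window.

The planted treatment effects and random effects are returned as a truth
record so recovery tests can compare estimates against known values.

All stochastic steps consume one numpy Generator seeded from
``SimulationConfig.seed`` in a fixed order (geography, covariates, cohort
assignment, village rollout, spatial effects, event counts), so a
configuration maps deterministically to a dataset.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .periods import (
    AGE_BANDS_FINE,
    PERIOD_YEARS,
    PERIODS,
    SEXES,
    COHORT_TO_PERIOD,
    period_index,
)
from .rates import STANDARD_POPULATION_2010

#: (sex, fine band) strata in a fixed order.
STRATA: tuple[tuple[str, str], ...] = tuple(
    (sex, band) for sex in SEXES for band in AGE_BANDS_FINE
)

#: Default baseline incidence per 100 000 per two-year window, by stratum.
#: Chosen to give township-level standardised incidence in the few-hundred
#: per 100 000 range typical of peri-urban myocardial-infarction surveillance,
#: with the usual steep age gradient and male excess.
DEFAULT_BASELINE_PER_1E5: dict[tuple[str, str], float] = {
    ("men", "35-49"): 40.0,
    ("men", "50-64"): 250.0,
    ("men", "65-79"): 900.0,
    ("men", "80+"): 2300.0,
    ("women", "35-49"): 15.0,
    ("women", "50-64"): 120.0,
    ("women", "65-79"): 650.0,
    ("women", "80+"): 1900.0,
}

#: Default common period effects on the log scale (secular drift, base
#: window P2013 = 0).
DEFAULT_PERIOD_EFFECTS: dict[str, float] = {
    "P2007": -0.20,
    "P2009": -0.12,
    "P2011": -0.05,
    "P2013": 0.0,
    "P2016": 0.06,
    "P2018": 0.12,
}

#: Township covariate distributions: name -> (mean, sd) for clipped
#: normals, or ("bernoulli", p).  Centres follow the pre-policy covariate
#: summaries of the study population (proportions as fractions).
DEFAULT_COVARIATES: dict[str, tuple] = {
    "agri_pct": (0.79, 0.08),
    "unemployment_pct": (0.04, 0.01),
    "secondary_ed_pct": (0.27, 0.07),
    "smoking_pct": (0.25, 0.05),
    "obesity_pct": (0.22, 0.03),
    "hypercholesterolaemia_pct": (0.07, 0.02),
    "temp_var_annual": (11.5, 0.15),
    "temp_var_heating": (3.2, 0.15),
    "hospital_beds_per_1000": (2.0, 1.0),
    "retired_plant": ("bernoulli", 0.3),
}

#: Default covariate effects on the log rate (level effects only; they
#: shift township baselines and cancel in first differences).
DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "agri_pct": 0.20,
    "unemployment_pct": 0.50,
    "secondary_ed_pct": -0.30,
    "smoking_pct": 0.80,
    "obesity_pct": 0.50,
    "temp_var_annual": 0.02,
    "hospital_beds_per_1000": -0.01,
    "retired_plant": 0.03,
}


@dataclass
class SimulationConfig:
    """Study-design parameters for one synthetic dataset.

    cohort_fractions are the shares of townships adopting in 2016-17, in
    2018-19, and never (defaults 75/151, 17/151, 59/151).  tau_dynamic
    holds the planted multiplicative treatment effects on the log-rate
    scale by event time (first and second post-adoption windows);
    defaults ln(0.934) and ln(0.90), i.e. -6.6% and -10% rate reductions.

    assignment_confounding tilts the probability of ever adopting by the
    standardised confounder (logit slope); trend_confounding makes the
    confounder shift a township's secular slope, so unadjusted contrasts
    are biased when both are nonzero.
    """

    n_townships: int = 151
    villages_range: tuple[int, int] = (5, 40)
    grid_dims: tuple[int, int] = (12, 13)
    cohort_fractions: tuple[float, float, float] = (75 / 151, 17 / 151, 59 / 151)
    baseline_per_1e5: dict = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_PER_1E5)
    )
    period_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_PERIOD_EFFECTS)
    )
    covariates: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    covariate_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    confounder: str = "agri_pct"
    assignment_confounding: float = 0.0
    trend_confounding: float = 0.0
    spatial_sd: float = 0.15
    unstructured_sd: float = 0.10
    tau_dynamic: tuple[float, ...] = (math.log(0.934), math.log(0.90))
    population_range: tuple[int, int] = (8_000, 30_000)
    monthly: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.grid_dims[0] * self.grid_dims[1] < self.n_townships:
            raise ValueError(
                f"grid {self.grid_dims} cannot hold {self.n_townships} townships"
            )
        if abs(sum(self.cohort_fractions) - 1.0) > 1e-9:
            raise ValueError("cohort_fractions must sum to 1")
        if min(self.cohort_fractions) < 0:
            raise ValueError("cohort_fractions must be non-negative")
        if self.spatial_sd < 0 or self.unstructured_sd < 0:
            raise ValueError("random-effect SDs must be >= 0")
        if self.population_range[0] <= 0:
            raise ValueError("populations must be > 0")
        if not 1 <= self.villages_range[0] <= self.villages_range[1]:
            raise ValueError("invalid villages_range")
        for p in PERIODS:
            if p not in self.period_effects:
                raise ValueError(f"period_effects missing {p}")


def township_ids(n: int) -> list[str]:
    return [f"T{i + 1:03d}" for i in range(n)]


def generate_geography(config: SimulationConfig, rng: np.random.Generator):
    """Lattice townships, rook adjacency, and a village roster.

    Townships occupy the first ``n_townships`` cells of the grid in
    row-major order; rook moves between occupied cells give a sparse,
    symmetric, connected neighbour graph.  Village counts per township
    are uniform over ``villages_range``.
    """
    config.validate()
    n = config.n_townships
    nrow, ncol = config.grid_dims
    ids = township_ids(n)
    pos = {i: divmod(i, ncol) for i in range(n)}
    townships = pd.DataFrame(
        {"township_id": ids,
         "row": [pos[i][0] for i in range(n)],
         "col": [pos[i][1] for i in range(n)]}
    )
    edges = []
    for i in range(n):
        r, c = pos[i]
        for dr, dc in ((0, 1), (1, 0)):
            rr, cc = r + dr, c + dc
            if rr < nrow and cc < ncol:
                j = rr * ncol + cc
                if j < n:
                    edges.append((ids[i], ids[j]))
    adjacency = pd.DataFrame(edges, columns=["township_id_1", "township_id_2"])

    g = nx.Graph()
    g.add_nodes_from(ids)
    g.add_edges_from(edges)
    if not nx.is_connected(g):
        raise ValueError("lattice adjacency is not connected")

    counts = rng.integers(
        config.villages_range[0], config.villages_range[1] + 1, size=n
    )
    vrows = []
    for tid, m in zip(ids, counts):
        for k in range(int(m)):
            vrows.append({"village_id": f"{tid}V{k + 1:03d}", "township_id": tid})
    villages = pd.DataFrame(vrows)
    return townships, adjacency, villages


def generate_covariates(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Time-invariant township covariates drawn once per township."""
    n = config.n_townships
    data = {"township_id": township_ids(n)}
    for name, spec in config.covariates.items():
        if spec[0] == "bernoulli":
            data[name] = rng.binomial(1, spec[1], size=n).astype(float)
        else:
            mean, sd = spec
            vals = rng.normal(mean, sd, size=n)
            data[name] = np.clip(vals, 1e-6, None)
    return pd.DataFrame(data)


def assign_cohorts(
    config: SimulationConfig,
    covariates: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.Series:
    """Adoption cohort per township.

    With ``assignment_confounding == 0`` the cohort counts are exact
    (rounded fractions, random permutation).  Otherwise townships adopt
    ever vs never by a Bernoulli draw with logit-linear probability in
    the standardised confounder, with the intercept solved so the mean
    adoption probability matches the configured ever-treated share; the
    2016-vs-2018 split among adopters is independent of the confounder,
    which keeps each treated-cohort-vs-never propensity exactly logistic.
    """
    n = config.n_townships
    f16, f18, fnever = config.cohort_fractions
    ids = township_ids(n)
    gamma = config.assignment_confounding
    if gamma == 0.0:
        n16 = round(f16 * n)
        n18 = round(f18 * n)
        labels = np.array(
            ["g2016"] * n16 + ["g2018"] * n18 + ["never"] * (n - n16 - n18)
        )
        rng.shuffle(labels)
        return pd.Series(labels, index=ids, name="cohort")

    z = covariates.set_index("township_id")[config.confounder].loc[ids].to_numpy()
    z = (z - z.mean()) / z.std()
    f_ever = f16 + f18

    def mean_p(a):
        return expit(a + gamma * z).mean() - f_ever

    a = brentq(mean_p, -30.0, 30.0)
    ever = rng.random(n) < expit(a + gamma * z)
    split16 = f16 / f_ever if f_ever > 0 else 0.0
    first = np.where(rng.random(n) < split16, "g2016", "g2018")
    labels = np.where(ever, first, "never")
    return pd.Series(labels, index=ids, name="cohort")


def generate_rollout(
    config: SimulationConfig,
    villages: pd.DataFrame,
    cohorts: pd.Series,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Village enrollment years consistent with each township's cohort.

    For a township with m villages, strictly more than half means at
    least floor(m/2)+1 enrolled.  g2016 townships cross that count with
    years <= 2017; g2018 townships stay at or below half through 2017 and
    cross with years <= 2019; never townships stay at or below half
    through 2019.  Within those constraints counts and years are uniform
    (the policy's within-township rollout law is not part of the design,
    so the least-informative choice is used).
    """
    out = villages.copy()
    out["enroll_year"] = pd.array([pd.NA] * len(out), dtype="Int64")
    early_years = np.array([2015, 2016, 2017])
    late_years = np.array([2018, 2019])
    for tid, grp in out.groupby("township_id"):
        m = len(grp)
        half = m // 2  # largest count with fraction <= 1/2
        cohort = cohorts[tid]
        if cohort == "g2016":
            k1 = int(rng.integers(half + 1, m + 1))
            rest = m - k1
            # later villages may still enroll (or not) after the crossing
            k2 = k1 + int(rng.integers(0, rest + 1))
        elif cohort == "g2018":
            k2 = int(rng.integers(half + 1, m + 1))
            k1 = int(rng.integers(0, min(k2, half) + 1))
        else:
            k2 = int(rng.integers(0, half + 1))
            k1 = int(rng.integers(0, k2 + 1))
        idx = rng.permutation(grp.index.to_numpy())
        years = np.concatenate(
            [
                rng.choice(early_years, size=k1),
                rng.choice(late_years, size=k2 - k1),
            ]
        )
        out.loc[idx[: k2], "enroll_year"] = years.astype("int64")
    return out


_LAPLACIAN_CACHE: dict = {}


def _icar_basis(adjacency: pd.DataFrame, ids: list[str]):
    """Eigenbasis of the graph Laplacian (cached) for ICAR sampling."""
    key = (tuple(ids), tuple(map(tuple, adjacency.to_numpy())))
    if key not in _LAPLACIAN_CACHE:
        index = {t: i for i, t in enumerate(ids)}
        n = len(ids)
        lap = np.zeros((n, n))
        for a, b in adjacency.to_numpy():
            i, j = index[a], index[b]
            lap[i, j] -= 1.0
            lap[j, i] -= 1.0
            lap[i, i] += 1.0
            lap[j, j] += 1.0
        vals, vecs = np.linalg.eigh(lap)
        _LAPLACIAN_CACHE[key] = (vals, vecs)
    return _LAPLACIAN_CACHE[key]


def generate_spatial_effects(
    config: SimulationConfig,
    adjacency: pd.DataFrame,
    rng: np.random.Generator,
):
    """Draw ICAR-structured u (sum-to-zero) and iid normal v."""
    ids = township_ids(config.n_townships)
    vals, vecs = _icar_basis(adjacency, ids)
    # skip the null (constant) eigenvector; covariance sigma^2 * L^+
    z = rng.normal(size=len(ids) - 1)
    u = config.spatial_sd * (vecs[:, 1:] @ (z / np.sqrt(vals[1:])))
    u -= u.mean()
    v = rng.normal(0.0, config.unstructured_sd, size=len(ids))
    return pd.Series(u, index=ids, name="u"), pd.Series(v, index=ids, name="v")


@dataclass
class SimulatedData:
    """One synthetic dataset plus its generating truth."""

    config: SimulationConfig
    townships: pd.DataFrame
    adjacency: pd.DataFrame
    villages: pd.DataFrame
    covariates: pd.DataFrame
    cohorts: pd.Series
    events: pd.DataFrame
    truth: dict
    _lam_yearly: np.ndarray | None = None
    _pop_strata: np.ndarray | None = None

    def redraw_events(self, rng: np.random.Generator) -> pd.DataFrame:
        """New Poisson counts from the same stored intensities."""
        counts = rng.poisson(self._lam_yearly)
        ev = self.events.copy()
        ev["events"] = counts.ravel()
        return ev

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.villages.to_csv(outdir / "villages.csv", index=False)
        self.events.to_csv(outdir / "events.csv", index=False)
        self.covariates.to_csv(outdir / "covariates.csv", index=False)
        self.adjacency.to_csv(outdir / "adjacency.csv", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1)


def _tau_at(config: SimulationConfig, cohort: str, period: str) -> float:
    """Planted treatment effect for a cohort at a window (0 pre-adoption)."""
    if cohort == "never" or period not in PERIODS:
        return 0.0
    first = COHORT_TO_PERIOD.get(cohort)
    if first is None:
        return 0.0
    e = period_index(period) - period_index(first)
    if e < 0:
        return 0.0
    taus = config.tau_dynamic
    return taus[min(e, len(taus) - 1)]


def generate_dataset(config: SimulationConfig) -> SimulatedData:
    """Full synthetic dataset: geography, rollout, covariates, events, truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    townships, adjacency, villages = generate_geography(config, rng)
    covariates = generate_covariates(config, rng)
    cohorts = assign_cohorts(config, covariates, rng)
    villages = generate_rollout(config, villages, cohorts, rng)
    u, v = generate_spatial_effects(config, adjacency, rng)

    ids = township_ids(config.n_townships)
    n = len(ids)
    s = len(STRATA)

    # linear predictor pieces
    # covariate effects centred at the configured means so the stratum
    # baselines stay the average township's rates
    beta_term = np.zeros(n)
    cov = covariates.set_index("township_id").loc[ids]
    for name, b in config.covariate_effects.items():
        if name in cov:
            spec = config.covariates.get(name)
            centre = spec[1] if spec and spec[0] == "bernoulli" else (
                spec[0] if spec else 0.0
            )
            beta_term += b * (cov[name].to_numpy() - centre)
    zconf = cov[config.confounder].to_numpy()
    zconf = (zconf - zconf.mean()) / zconf.std()

    pop_total = rng.integers(
        config.population_range[0], config.population_range[1] + 1, size=n
    )
    w_ref = np.array([STANDARD_POPULATION_2010[st] for st in STRATA])
    pop_strata = np.maximum(1, np.round(pop_total[:, None] * w_ref[None, :])).astype(
        int
    )  # (n, s)

    baseline = np.array(
        [math.log(config.baseline_per_1e5[st] / 1e5) for st in STRATA]
    )
    base_idx = period_index("P2013")

    years = np.arange(2007, 2020)
    year_period = {}
    for y in years:
        for p, (y0, y1) in PERIOD_YEARS.items():
            if y0 <= y <= y1:
                year_period[y] = p
    year_period[2015] = "P2016"  # rate level only; excluded from pooling

    lam = np.empty((n, len(years), s))
    tau_mat = np.zeros((n, len(PERIODS)))
    for ti, period in enumerate(PERIODS):
        for i, tid in enumerate(ids):
            tau_mat[i, ti] = _tau_at(config, cohorts[tid], period)

    log_std_rate = {}
    w_tilde = w_ref / w_ref.sum()
    for yi, y in enumerate(years):
        p = year_period[y]
        ti = period_index(p)
        tidx = ti - base_idx
        theta_common = (
            config.period_effects[p]
            + beta_term
            + config.trend_confounding * zconf * tidx
            + u.to_numpy()
            + v.to_numpy()
        )
        tau_y = tau_mat[:, ti] if y != 2015 else np.zeros(n)
        # per-person two-year rate; each calendar year carries half
        rate_pp = np.exp(
            baseline[None, :] + (theta_common + tau_y)[:, None]
        )  # (n, s)
        lam[:, yi, :] = pop_strata * rate_pp / 2.0

    # truth: per-township log standardised rate per window (per 100 000)
    for period in PERIODS:
        ti = period_index(period)
        tidx = ti - base_idx
        theta_common = (
            config.period_effects[period]
            + beta_term
            + config.trend_confounding * zconf * tidx
            + u.to_numpy()
            + v.to_numpy()
        )
        rate_pp = np.exp(
            baseline[None, :] + (theta_common + tau_mat[:, ti])[:, None]
        )
        std_rate = 1e5 * (rate_pp * w_tilde[None, :]).sum(axis=1)
        log_std_rate[period] = np.log(std_rate)

    counts = rng.poisson(lam)

    ev = pd.DataFrame(
        {
            "township_id": np.repeat(ids, len(years) * s),
            "year": np.tile(np.repeat(years, s), n),
            "sex": np.tile([st[0] for st in STRATA], n * len(years)),
            "age_band": np.tile([st[1] for st in STRATA], n * len(years)),
            "events": counts.ravel(),
            "population": np.tile(pop_strata[:, None, :], (1, len(years), 1)).ravel(),
        }
    )
    if config.monthly:
        ev = _to_monthly(ev, rng)

    truth = {
        "tau_dynamic": list(config.tau_dynamic),
        "townships": {
            tid: {
                "cohort": cohorts[tid],
                "u": float(u[tid]),
                "v": float(v[tid]),
                "tau_by_period": {
                    p: _tau_at(config, cohorts[tid], p) for p in PERIODS
                },
                "log_std_rate": {
                    p: float(log_std_rate[p][i]) for p in PERIODS
                },
            }
            for i, tid in enumerate(ids)
        },
    }
    return SimulatedData(
        config=config,
        townships=townships,
        adjacency=adjacency,
        villages=villages,
        covariates=covariates,
        cohorts=cohorts,
        events=ev,
        truth=truth,
        _lam_yearly=lam,
        _pop_strata=pop_strata,
    )


def _to_monthly(ev: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Split yearly counts uniformly over months (for november pooling)."""
    months = np.arange(1, 13)
    n = len(ev)
    counts = ev["events"].to_numpy()
    split = rng.multinomial(counts, np.full(12, 1 / 12))
    out = ev.loc[ev.index.repeat(12)].reset_index(drop=True)
    out["month"] = np.tile(months, n)
    out["events"] = split.ravel()
    return out
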