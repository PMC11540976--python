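import pandas as pd
import pytest

from chpdid import SimulationConfig, generate_dataset
from chpdid import exposure as exposure_mod
from chpdid import rates as rates_mod

#: Covariates entering the adjusted DiD in tests.
DID_COVS = [
    "agri_pct",
    "unemployment_pct",
    "secondary_ed_pct",
    "smoking_pct",
    "obesity_pct",
    "temp_var_annual",
    "hospital_beds_per_1000",
    "retired_plant",
]


@pytest.fixture(scope="session")
def sim_default():
    """Full-size synthetic study (151 townships, default design)."""
    return generate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def sim_small():
    """Small study for cheap tests: 24 townships on a 5x5 lattice."""
    cfg = SimulationConfig(
        n_townships=24,
        grid_dims=(5, 5),
        villages_range=(4, 12),
        cohort_fractions=(0.5, 0.125, 0.375),
        seed=5,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def analysis_default(sim_default):
    """Exposure panel and standardised log rates for the default study."""
    fractions = exposure_mod.compute_enrolled_fraction(sim_default.villages)
    panel = exposure_mod.assign_exposure(fractions)
    pooled = rates_mod.pool_events(sim_default.events)
    log_tab = rates_mod.log_rates(rates_mod.direct_standardize(pooled, "all"))
    return {
        "fractions": fractions,
        "exposure": panel,
        "pooled": pooled,
        "log_rates": log_tab,
    }


def run_single_did(data, adjusted=True, covariates=None, subgroup="all",
                   control_group="never"):
    """One full generator -> exposure -> rates -> DiD pass."""
    from chpdid import did as did_mod

    panel_e = exposure_mod.assign_exposure(
        exposure_mod.compute_enrolled_fraction(data.villages)
    )
    pooled = rates_mod.pool_events(data.events)
    log_tab = rates_mod.log_rates(rates_mod.direct_standardize(pooled, subgroup))
    panel = did_mod.build_panel(log_tab, panel_e, data.covariates)
    gts = did_mod.estimate_all_gt(
        panel, adjusted=adjusted, covariates=covariates,
        control_group=control_group,
    )
    return did_mod.aggregate_dynamic(gts), gts
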