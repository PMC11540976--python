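"""Event pooling and direct age-sex standardisation of incidence rates.

Townships report myocardial-infarction event counts and populations per
age-sex stratum and calendar year.  This module pools them into two-year
windows and computes directly standardised rates (events per 100 000) per
township, window and subgroup, using a fixed reference population.

The packaged reference weights are a synthetic stand-in for the 2010
Beijing census age-sex structure (the real reference table is not
published); they are plausible for an ageing peri-urban population and sum
to one over the eight fine strata.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .periods import AGE_BANDS_FINE, AGE_COLLAPSE, PERIOD_YEARS, year_to_period

logger = logging.getLogger(__name__)

#: Synthetic 2010 reference population shares per (sex, fine age band).
#: Ages 35+ only; men and women split evenly within bands.
STANDARD_POPULATION_2010: dict[tuple[str, str], float] = {
    ("men", "35-49"): 0.21,
    ("women", "35-49"): 0.21,
    ("men", "50-64"): 0.155,
    ("women", "50-64"): 0.155,
    ("men", "65-79"): 0.10,
    ("women", "65-79"): 0.10,
    ("men", "80+"): 0.035,
    ("women", "80+"): 0.035,
}

#: Subgroup -> (sexes included, fine age bands included).
SUBGROUPS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "all": (("men", "women"), AGE_BANDS_FINE),
    "men": (("men",), AGE_BANDS_FINE),
    "women": (("women",), AGE_BANDS_FINE),
    "ge65": (("men", "women"), ("65-79", "80+")),
    "men_ge65": (("men",), ("65-79", "80+")),
    "women_ge65": (("women",), ("65-79", "80+")),
    "age65_79": (("men", "women"), ("65-79",)),
    "age80plus": (("men", "women"), ("80+",)),
}


def standard_weights(
    subgroup: str,
    age_bands: str = "main",
    std: dict[tuple[str, str], float] | None = None,
) -> pd.Series:
    """Reference weights for a subgroup, renormalised to sum to one.

    Parameters
    ----------
    subgroup
        One of :data:`SUBGROUPS`.
    age_bands
        ``"main"`` collapses the fine bands to {35-64, 65+} (the default
        analysis), ``"fine"`` keeps all four bands (sensitivity analysis).
    std
        Alternative reference shares keyed by (sex, fine band).
    """
    if subgroup not in SUBGROUPS:
        raise ValueError(f"unknown subgroup {subgroup!r}")
    std = STANDARD_POPULATION_2010 if std is None else std
    sexes, bands = SUBGROUPS[subgroup]
    raw: dict[tuple[str, str], float] = {}
    for (sex, band), w in std.items():
        if sex not in sexes or band not in bands:
            continue
        key_band = AGE_COLLAPSE[band] if age_bands == "main" else band
        raw[(sex, key_band)] = raw.get((sex, key_band), 0.0) + w
    total = sum(raw.values())
    if total <= 0:
        raise ValueError(f"no reference mass for subgroup {subgroup!r}")
    idx = pd.MultiIndex.from_tuples(sorted(raw), names=["sex", "age_band"])
    return pd.Series([raw[k] / total for k in sorted(raw)], index=idx, name="weight")


def collapse_age_bands(events: pd.DataFrame) -> pd.DataFrame:
    """Collapse fine age bands to the main-analysis bands {35-64, 65+}."""
    out = events.copy()
    out["age_band"] = out["age_band"].map(AGE_COLLAPSE)
    if out["age_band"].isna().any():
        raise ValueError("events contain age bands outside the fine set")
    keys = [c for c in ("township_id", "period", "year", "sex", "age_band") if c in out]
    return out.groupby(keys, as_index=False)[["events", "population"]].sum()


def _november_period(year: int, month: int) -> str | None:
    # Window labelled Py covers Nov 1 (y-1) .. Oct 31 (y+1): each window is
    # led in by the heating season starting the preceding November.
    shifted = year if month >= 11 else year - 1
    for p, (y0, _) in PERIOD_YEARS.items():
        if shifted in (y0 - 1, y0):
            return p
    return None


def pool_events(
    events: pd.DataFrame,
    window_start: str = "calendar",
    pooling: str = "2year",
) -> pd.DataFrame:
    """Pool yearly (or monthly) stratum event counts into study windows.

    Parameters
    ----------
    events
        Long table with columns township_id, year, sex, age_band, events,
        population (and month for november pooling).  Population is the
        stratum population in that year.
    window_start
        ``"calendar"`` uses Jan 1 windows and drops the 2015 pilot year;
        ``"november"`` shifts windows to heating-season years (requires a
        ``month`` column).
    pooling
        ``"2year"`` for the study windows, ``"1year"`` for single calendar
        years (labels ``Y<year>``; used in the older-adult sensitivity).

    Events are summed over the window; populations are averaged over the
    window's years, so rates are events per person per window.
    """
    if "period" in events.columns:
        return events.copy()
    ev = events.copy()
    if pooling == "1year":
        ev = ev[ev["year"] != 2015]
        ev["period"] = "Y" + ev["year"].astype(str)
    elif window_start == "calendar":
        ev["period"] = ev["year"].map(year_to_period)
        ev = ev[ev["period"].notna()]
    elif window_start == "november":
        if "month" not in ev.columns:
            raise ValueError("november pooling requires a 'month' column")
        ev["period"] = [
            _november_period(y, m) for y, m in zip(ev["year"], ev["month"])
        ]
        ev = ev[ev["period"].notna()]
    else:
        raise ValueError(f"unknown window_start {window_start!r}")

    keys = ["township_id", "period", "sex", "age_band"]
    pooled = ev.groupby(keys, as_index=False).agg(
        events=("events", "sum"),
        population=("population", "sum"),
        n_years=("year", "nunique"),
    )
    # population column holds person-periods: mean yearly population.
    pooled["population"] = pooled["population"] / pooled["n_years"]
    return pooled.drop(columns="n_years")


def direct_standardize(
    pooled: pd.DataFrame,
    subgroup: str = "all",
    age_bands: str = "main",
    std: dict[tuple[str, str], float] | None = None,
) -> pd.DataFrame:
    """Directly standardised incidence per township and window.

    rate = 100000 * sum_s w_s * events_s / population_s with reference
    weights ``w_s`` renormalised over the subgroup's strata.  Raw events
    and populations are carried through for downstream counterfactuals.
    """
    weights = standard_weights(subgroup, age_bands=age_bands, std=std)
    ev = collapse_age_bands(pooled) if age_bands == "main" else pooled.copy()
    sexes, _ = SUBGROUPS[subgroup]
    bands = weights.index.get_level_values("age_band").unique()
    ev = ev[ev["sex"].isin(sexes) & ev["age_band"].isin(bands)]

    bad = ev[ev["population"] <= 0]
    if len(bad):
        r = bad.iloc[0]
        raise ValueError(
            f"zero population stratum: township {r['township_id']} "
            f"period {r['period']} {r['sex']} {r['age_band']}"
        )

    ev = ev.merge(
        weights.rename("w").reset_index(), on=["sex", "age_band"], how="left"
    )
    ev["contrib"] = 1e5 * ev["w"] * ev["events"] / ev["population"]
    out = ev.groupby(["township_id", "period"], as_index=False).agg(
        events=("events", "sum"),
        population=("population", "sum"),
        rate=("contrib", "sum"),
        n_strata=("w", "size"),
    )
    expected = len(weights)
    short = out[out["n_strata"] != expected]
    if len(short):
        raise ValueError(
            f"township {short.iloc[0]['township_id']} is missing strata for "
            f"subgroup {subgroup!r}"
        )
    out = out.drop(columns="n_strata")
    out.insert(2, "subgroup", subgroup)
    return out


def log_rates(
    rates: pd.DataFrame,
    floor_events: float | None = 0.5,
) -> pd.DataFrame:
    """Attach the natural-log rate, with a continuity floor for empty cells.

    Cells with zero pooled events have rate 0; a floor of ``floor_events``
    pseudo-events over the cell's total population keeps the log finite.
    Pass ``floor_events=None`` to make zero rates an error instead.
    """
    out = rates.copy()
    zero = out["rate"] <= 0
    if zero.any():
        if floor_events is None:
            raise ValueError(f"{int(zero.sum())} zero-rate cells and no floor")
        logger.warning(
            "applying continuity floor of %s events to %d zero-rate cells",
            floor_events,
            int(zero.sum()),
        )
        out.loc[zero, "rate"] = (
            1e5 * floor_events / out.loc[zero, "population"]
        )
    out["log_rate"] = np.log(out["rate"])
    return out


def expected_events(pooled: pd.DataFrame, subgroup: str = "all",
                    age_bands: str = "main") -> pd.DataFrame:
    """Internally standardised expected counts per township and window.

    Stratum reference rates are pooled over all townships within each
    window; E_i = sum_s population_is * rho_s.  Also returns the reference
    standardised rate (per 100 000) implied by those stratum rates, used to
    place smoothed relative risks back on the incidence scale.
    """
    weights = standard_weights(subgroup, age_bands=age_bands)
    ev = collapse_age_bands(pooled) if age_bands == "main" else pooled.copy()
    sexes, _ = SUBGROUPS[subgroup]
    bands = weights.index.get_level_values("age_band").unique()
    ev = ev[ev["sex"].isin(sexes) & ev["age_band"].isin(bands)].copy()

    strat = ev.groupby(["period", "sex", "age_band"]).agg(
        ev_tot=("events", "sum"), pop_tot=("population", "sum")
    )
    strat["rho"] = strat["ev_tot"] / strat["pop_tot"]
    ev = ev.merge(strat["rho"].reset_index(), on=["period", "sex", "age_band"])
    ev["e_contrib"] = ev["population"] * ev["rho"]
    out = ev.groupby(["township_id", "period"], as_index=False).agg(
        observed=("events", "sum"), expected=("e_contrib", "sum")
    )

    w = weights.rename("w").reset_index()
    ref = strat.reset_index().merge(w, on=["sex", "age_band"])
    ref["r_contrib"] = 1e5 * ref["w"] * ref["rho"]
    ref_rate = ref.groupby("period")["r_contrib"].sum().rename("reference_rate")
    out = out.merge(ref_rate.reset_index(), on="period")
    return out
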