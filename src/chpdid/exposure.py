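"""Township exposure to the clean-heating policy from village enrollment.

The policy enrolled whole villages; the outcome data resolve only to
townships.  A township counts as exposed in a window when strictly more
than half (by default) of its villages have enrolled by the window's last
year.  Enrollment is cumulative, so exposure is absorbing and each
township belongs to the cohort of its first exposed window (g2016, g2018)
or to the never-exposed cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import pandas as pd

from .periods import ANALYSIS_PERIODS, PERIOD_TO_COHORT, PERIOD_YEARS, PERIODS

ENROLL_YEARS = range(2015, 2020)


def compute_enrolled_fraction(
    villages: pd.DataFrame,
    periods: tuple[str, ...] = PERIODS,
) -> pd.DataFrame:
    """Cumulative enrolled-village fraction per township and window.

    A village with enrollment year y counts in every window whose last
    calendar year is >= y (2015 pilot enrollees therefore accrue from the
    2016-17 window on).  Fractions are exact rationals stored alongside
    integer numerators/denominators so threshold comparisons never suffer
    float round-off.
    """
    v = villages.copy()
    if v["township_id"].isna().any() or (v["township_id"] == "").any():
        raise ValueError("village without a township")
    years = v["enroll_year"].dropna()
    bad = years[(years < min(ENROLL_YEARS)) | (years > max(ENROLL_YEARS))]
    if len(bad):
        raise ValueError(
            f"enrollment years outside {min(ENROLL_YEARS)}-{max(ENROLL_YEARS)}: "
            f"{sorted(bad.unique())}"
        )

    totals = v.groupby("township_id").size()
    if (totals == 0).any():  # pragma: no cover - groupby cannot emit zeros
        raise ValueError("township with zero villages")

    parts = []
    for period in periods:
        end_year = PERIOD_YEARS[period][1]
        enrolled = (
            v[v["enroll_year"].notna() & (v["enroll_year"] <= end_year)]
            .groupby("township_id")
            .size()
            .reindex(totals.index, fill_value=0)
        )
        part = pd.DataFrame(
            {
                "township_id": totals.index,
                "period": period,
                "n_enrolled": enrolled.to_numpy(dtype=int),
                "n_villages": totals.to_numpy(dtype=int),
            }
        )
        parts.append(part)
    out = pd.concat(parts, ignore_index=True)
    out["fraction"] = out["n_enrolled"] / out["n_villages"]
    return out


def _exceeds(n_enrolled: int, n_villages: int, threshold: float, strict: bool) -> bool:
    frac = Fraction(n_enrolled, n_villages)
    thr = Fraction(str(threshold))
    return frac > thr if strict else frac >= thr


def assign_exposure(
    fractions: pd.DataFrame,
    threshold: float = 0.50,
    strict: bool = True,
    analysis_periods: tuple[str, ...] = ANALYSIS_PERIODS,
) -> pd.DataFrame:
    """Binary exposure panel and adoption cohort per township.

    Returns one row per township and window with columns fraction,
    exposed, cohort.  The cohort is the first window (among the
    post-policy analysis windows) in which the enrolled fraction strictly
    exceeds ``threshold``; the comparison uses exact rational arithmetic,
    so a township at exactly 50% is not exposed.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    panel = fractions.copy()
    panel["exposed"] = [
        _exceeds(ne, nv, threshold, strict)
        for ne, nv in zip(panel["n_enrolled"], panel["n_villages"])
    ]
    adoptable = panel[
        panel["exposed"]
        & panel["period"].isin(analysis_periods)
        & panel["period"].isin(PERIOD_TO_COHORT)
    ]
    first = (
        adoptable.sort_values("period")
        .groupby("township_id")["period"]
        .first()
        .map(PERIOD_TO_COHORT)
    )
    panel["cohort"] = (
        panel["township_id"].map(first).fillna("never").astype(str)
    )
    return panel


@dataclass
class SensitivityExposure:
    """70/30 exposure definition with the indeterminate middle excluded."""

    panel: pd.DataFrame
    excluded: list = field(default_factory=list)


def assign_exposure_sensitivity(
    fractions: pd.DataFrame,
    exposed_threshold: float = 0.70,
    unexposed_threshold: float = 0.30,
) -> SensitivityExposure:
    """More-distinct exposure contrast: >70% exposed, <30% unexposed.

    Townships whose final (2019) enrolled fraction lies in
    [unexposed_threshold, exposed_threshold] are neither clearly exposed
    nor clearly spared and are excluded from the analysis set.
    """
    panel = assign_exposure(fractions, threshold=exposed_threshold)
    final_period = PERIODS[-1]
    final = panel[panel["period"] == final_period]
    excluded = []
    for _, row in final.iterrows():
        frac = Fraction(int(row["n_enrolled"]), int(row["n_villages"]))
        lo = Fraction(str(unexposed_threshold))
        hi = Fraction(str(exposed_threshold))
        if lo <= frac <= hi:
            excluded.append(row["township_id"])
    keep = panel[~panel["township_id"].isin(excluded)].reset_index(drop=True)
    return SensitivityExposure(panel=keep, excluded=sorted(excluded))
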