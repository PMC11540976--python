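"""Study periods and age-sex strata shared across the pipeline.

The study pools events into two-year windows labelled by their first
calendar year.  Three windows form the estimation panel (one pre-policy,
two post-policy) and three earlier windows are kept for pre-trend
diagnostics.  2015, the policy pilot year, belongs to no calendar window.
"""

from __future__ import annotations

#: All two-year windows, oldest first.
PERIODS: tuple[str, ...] = ("P2007", "P2009", "P2011", "P2013", "P2016", "P2018")

#: Windows entering the difference-in-differences panel.
ANALYSIS_PERIODS: tuple[str, ...] = ("P2013", "P2016", "P2018")

#: Windows used only for pre-trend diagnostics.
PRE_PERIODS: tuple[str, ...] = ("P2007", "P2009", "P2011", "P2013")

#: First and last calendar year covered by each window (calendar pooling).
PERIOD_YEARS: dict[str, tuple[int, int]] = {
    "P2007": (2007, 2008),
    "P2009": (2009, 2010),
    "P2011": (2011, 2012),
    "P2013": (2013, 2014),
    "P2016": (2016, 2017),
    "P2018": (2018, 2019),
}

#: The pilot year excluded from calendar pooling.
PILOT_YEAR = 2015

#: Adoption cohorts: first window with >threshold village enrollment.
COHORTS: tuple[str, ...] = ("g2016", "g2018", "never")

#: Cohort label for each possible first-exposed window.
PERIOD_TO_COHORT: dict[str, str] = {"P2016": "g2016", "P2018": "g2018"}
COHORT_TO_PERIOD: dict[str, str] = {v: k for k, v in PERIOD_TO_COHORT.items()}

#: Fine age bands (the sensitivity-analysis standardisation strata).
AGE_BANDS_FINE: tuple[str, ...] = ("35-49", "50-64", "65-79", "80+")

#: Main-analysis bands, collapsed from the fine ones.
AGE_BANDS_MAIN: tuple[str, ...] = ("35-64", "65+")

#: Fine-band -> main-band collapse map.
AGE_COLLAPSE: dict[str, str] = {
    "35-49": "35-64",
    "50-64": "35-64",
    "65-79": "65+",
    "80+": "65+",
}

SEXES: tuple[str, ...] = ("men", "women")


def period_index(period: str) -> int:
    """Ordinal position of a window among all study windows."""
    return PERIODS.index(period)


def year_to_period(year: int) -> str | None:
    """Calendar window containing ``year``; None for the pilot year."""
    for p, (y0, y1) in PERIOD_YEARS.items():
        if y0 <= year <= y1:
            return p
    return None
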