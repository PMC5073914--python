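"""Stepped wedge rollout schedules and the derived design covariates.

A wedge schedule records, for each site, the first quarter in which the
site is in the implementation ("on") state; every site starts in the
control ("off") state at quarter 1 and, once on, stays on. The default
schedule is the nine-site, twelve-quarter rollout used throughout the
package's worked examples: three phase-1 sites starting in quarters 2-4,
three phase-2 sites in quarters 5, 5 and 8, and three phase-3 sites in
quarters 9, 11 and 12.

From a schedule the module derives, per site-quarter cell, the three
time-level predictors of the evaluation model: the calendar quarter QTR
(coded 1..n_quarters, uncentered), the on/off indicator TREAT, and their
product QTR*TREAT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

SIZES = ("small", "medium", "large")

#: Default first-on quarters for sites 1..9.
DEFAULT_START_QUARTERS = (2, 3, 4, 5, 5, 8, 9, 11, 12)

#: Default size labels for sites 1..9 (2 small, 2 medium, 5 large),
#: assigned deterministically by site_id and spread across the rollout
#: phases so that size does not proxy implementation timing (size is a
#: null covariate: it carries no simulated effect); configurable per
#: schedule.
DEFAULT_SIZES = ("medium", "large", "small", "large", "large", "large", "small", "large", "medium")

#: Default rollout phase (fiscal year of engagement) per site; carried as
#: metadata only — the evaluation model never uses phase.
DEFAULT_PHASES = (1, 1, 1, 2, 2, 2, 3, 3, 3)


@dataclass(frozen=True)
class SiteProfile:
    """One site's place in the rollout.

    ``size`` encodes the two site-level model indicators MED and LG
    (small is the reference level). ``start_quarter`` is the first
    quarter in the implementation state and must be >= 2: every site is
    in control at quarter 1.
    """

    site_id: int
    size: str
    phase: int
    start_quarter: int

    def __post_init__(self) -> None:
        if self.size not in SIZES:
            raise ValueError(f"size must be one of {SIZES}, got {self.size!r}")
        if self.start_quarter < 2:
            raise ValueError(f"start_quarter must be >= 2 (site {self.site_id}: all sites begin in control)")

    @property
    def med(self) -> int:
        return int(self.size == "medium")

    @property
    def lg(self) -> int:
        return int(self.size == "large")


@dataclass(frozen=True)
class WedgeSchedule:
    """An ordered collection of site profiles over a fixed horizon."""

    sites: tuple[SiteProfile, ...]
    n_quarters: int = 12

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", tuple(self.sites))
        ids = sorted(s.site_id for s in self.sites)
        if ids != list(range(1, len(self.sites) + 1)):
            raise ValueError(f"site_ids must be contiguous from 1, got {ids}")
        if self.n_quarters < 1:
            raise ValueError("n_quarters must be positive")
        for s in self.sites:
            if s.start_quarter > self.n_quarters:
                raise ValueError(
                    f"site {s.site_id} starts in quarter {s.start_quarter}, beyond horizon {self.n_quarters}"
                )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site(self, site_id: int) -> SiteProfile:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(f"unknown site_id {site_id}")

    def to_records(self) -> list[dict]:
        return [
            {"site_id": s.site_id, "size": s.size, "phase": s.phase, "start_quarter": s.start_quarter}
            for s in sorted(self.sites, key=lambda s: s.site_id)
        ]

    @classmethod
    def from_records(cls, records: Iterable[dict], n_quarters: int = 12) -> "WedgeSchedule":
        sites = tuple(
            SiteProfile(
                site_id=int(r["site_id"]),
                size=str(r["size"]),
                phase=int(r.get("phase", 0)),
                start_quarter=int(r["start_quarter"]),
            )
            for r in records
        )
        return cls(sites=sites, n_quarters=n_quarters)


@dataclass(frozen=True)
class DesignCell:
    """One site-quarter cell with its time-level model covariates."""

    site_id: int
    quarter: int
    qtr: float
    treat: int
    qtr_x_treat: float


def default_schedule() -> WedgeSchedule:
    """The nine-site, twelve-quarter rollout with the default size labels."""
    sites = tuple(
        SiteProfile(site_id=i + 1, size=DEFAULT_SIZES[i], phase=DEFAULT_PHASES[i], start_quarter=DEFAULT_START_QUARTERS[i])
        for i in range(9)
    )
    return WedgeSchedule(sites=sites, n_quarters=12)


def treat_indicator(schedule: WedgeSchedule, site_id: int, quarter: int) -> int:
    """On/off indicator: 1 iff ``quarter`` >= the site's start quarter."""
    if not 1 <= quarter <= schedule.n_quarters:
        raise ValueError(f"quarter {quarter} outside 1..{schedule.n_quarters}")
    site = schedule.site(site_id)
    return int(quarter >= site.start_quarter)


def expand_design(schedule: WedgeSchedule) -> list[DesignCell]:
    """One DesignCell per (site, quarter), ordered by (site_id, quarter).

    QTR is coded as the calendar quarter number (1..n_quarters,
    uncentered) and the interaction is QTR*TREAT on that calendar scale.
    Deterministic and independent of the order sites appear in the
    schedule.
    """
    cells = []
    for site in sorted(schedule.sites, key=lambda s: s.site_id):
        for quarter in range(1, schedule.n_quarters + 1):
            treat = int(quarter >= site.start_quarter)
            qtr = float(quarter)
            cells.append(
                DesignCell(site_id=site.site_id, quarter=quarter, qtr=qtr, treat=treat, qtr_x_treat=qtr * treat)
            )
    return cells


def design_frame(schedule: WedgeSchedule) -> pd.DataFrame:
    """The expanded design as a DataFrame (CSV-exportable)."""
    return pd.DataFrame([c.__dict__ for c in expand_design(schedule)])[
        ["site_id", "quarter", "qtr", "treat", "qtr_x_treat"]
    ]
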