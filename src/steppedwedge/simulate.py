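"""Respondent-level survey simulation for a stepped wedge rollout.

Each site-quarter cell surveys a fresh cross-section of respondents
(nobody is surveyed twice). The single outcome is a 4-category ordinal
access rating, stored as 1 = always, 2 = usually, 3 = sometimes,
4 = never ("how often did you receive care as soon as you needed it").

The generating mechanism, per site:

* control state: the four categories are uniform (0.25 each);
* first implementation quarter: the distribution jumps to a site-specific
  target with "always" in [0.30, 0.36] and "usually" in [0.29, 0.33]
  (the complementary mass split between "sometimes" and "never" inside
  their own printed ranges) — a 4-11 percentage-point improvement;
* each ensuing implementation quarter: "always" and "usually" each gain
  a site-specific 1-3 percentage points, taken from "sometimes" and
  "never" in proportion to their mass above the plateau floors, until
  the plateau caps (always <= 0.44, usually <= 0.42, sometimes >= 0.07,
  never >= 0.05) bind.

Gender and race/ethnicity are simulated as null covariates: independent
Bernoulli draws (10% female, 25% nonwhite by default) with no effect on
the outcome. Every source of randomness derives from one scenario seed
via independent per-site substreams, so adding a site leaves the other
sites' draws untouched.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .schedule import WedgeSchedule, default_schedule

CATEGORIES = ("always", "usually", "sometimes", "never")

_UNIFORM = (0.25, 0.25, 0.25, 0.25)


class ConfigurationError(ValueError):
    """Raised when simulation ranges cannot satisfy the probability simplex."""


@dataclass(frozen=True)
class OutcomeDistribution:
    """Category probabilities for one site-quarter cell."""

    p_always: float
    p_usually: float
    p_sometimes: float
    p_never: float

    def __post_init__(self) -> None:
        p = self.as_array()
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError(f"probabilities outside [0, 1]: {p}")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"probabilities must sum to 1, got {p.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_always, self.p_usually, self.p_sometimes, self.p_never])

    @property
    def mean_access(self) -> float:
        """Expected value of the 1..4 coding."""
        return float(np.dot(self.as_array(), [1, 2, 3, 4]))


@dataclass(frozen=True)
class EffectProfile:
    """Site-level treatment effect: first-quarter jump target and drift rates.

    ``first_quarter`` is the outcome distribution in the site's first
    implementation quarter. ``drift_always`` / ``drift_usually`` are the
    per-quarter probability gains of the two improving categories in
    every ensuing quarter, clamped at ``caps`` = (max always, max
    usually, min sometimes, min never).
    """

    site_id: int
    first_quarter: OutcomeDistribution
    drift_always: float
    drift_usually: float
    caps: tuple[float, float, float, float] = (0.44, 0.42, 0.07, 0.05)


@dataclass(frozen=True)
class RespondentRecord:
    """One surveyed patient (a Level-1 unit)."""

    respondent_id: int
    site_id: int
    quarter: int
    access: int  # 1 = always .. 4 = never
    female: int
    nonwhite: int


@dataclass(frozen=True)
class ScenarioConfig:
    """All simulation knobs for one scenario.

    Defaults reproduce the reference study conditions: 9 sites x 12
    quarters x 1000 respondents per cell, uniform control outcome,
    4-11 point first-quarter jump, 1-3 point per-quarter drift, 90%
    male and 75% white respondents.
    """

    schedule: WedgeSchedule = field(default_factory=default_schedule)
    n_per_cell: int = 1000
    p_female: float = 0.10
    p_nonwhite: float = 0.25
    jump_always: tuple[float, float] = (0.30, 0.36)
    jump_usually: tuple[float, float] = (0.29, 0.33)
    jump_sometimes: tuple[float, float] = (0.16, 0.23)
    jump_never: tuple[float, float] = (0.11, 0.20)
    drift_range: tuple[float, float] = (0.01, 0.03)
    caps: tuple[float, float, float, float] = (0.44, 0.42, 0.07, 0.05)
    null_effect: bool = False
    exact_covariate_quota: bool = False
    redraw_drift_each_quarter: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise ConfigurationError("n_per_cell must be >= 1")
        for name in ("p_female", "p_nonwhite"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        for name in ("jump_always", "jump_usually", "jump_sometimes", "jump_never", "drift_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ConfigurationError(f"{name} must be an ordered pair in [0, 1], got {(lo, hi)}")
        cap_a, cap_u, floor_s, floor_n = self.caps
        if self.jump_always[1] > cap_a or self.jump_usually[1] > cap_u:
            raise ConfigurationError("jump ranges must be nested inside caps")
        if self.jump_sometimes[0] < floor_s or self.jump_never[0] < floor_n:
            raise ConfigurationError("jump ranges must be nested inside caps")
        # Simplex feasibility at the extremes of the jump draw.
        for pa in self.jump_always:
            for pu in self.jump_usually:
                rest = 1.0 - pa - pu
                lo = max(self.jump_sometimes[0], rest - self.jump_never[1])
                hi = min(self.jump_sometimes[1], rest - self.jump_never[0])
                if lo > hi + 1e-12:
                    raise ConfigurationError(
                        f"jump ranges infeasible: with always={pa}, usually={pu} the remaining "
                        f"mass {rest:.3f} cannot satisfy the sometimes/never ranges"
                    )

    def replace(self, **changes) -> "ScenarioConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schedule"] = {"n_quarters": self.schedule.n_quarters, "sites": self.schedule.to_records()}
        for key in ("jump_always", "jump_usually", "jump_sometimes", "jump_never", "drift_range", "caps"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "schedule" in d and isinstance(d["schedule"], dict):
            sched = d["schedule"]
            d["schedule"] = WedgeSchedule.from_records(sched["sites"], n_quarters=int(sched.get("n_quarters", 12)))
        for key in ("jump_always", "jump_usually", "jump_sometimes", "jump_never", "drift_range", "caps"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _site_rng(config: ScenarioConfig, site_id: int) -> np.random.Generator:
    """Independent substream for one site, derived from the scenario seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(site_id,)))


def draw_effect_profile(rng: np.random.Generator, site_id: int, config: ScenarioConfig) -> EffectProfile:
    """Draw one site's jump target and drift rates (site-level heterogeneity).

    Under ``null_effect`` the profile is degenerate: uniform target and
    zero drift, so the cell distribution never leaves the control state.
    """
    if config.null_effect:
        return EffectProfile(
            site_id=site_id,
            first_quarter=OutcomeDistribution(*_UNIFORM),
            drift_always=0.0,
            drift_usually=0.0,
            caps=config.caps,
        )
    pa = rng.uniform(*config.jump_always)
    pu = rng.uniform(*config.jump_usually)
    rest = 1.0 - pa - pu
    lo = max(config.jump_sometimes[0], rest - config.jump_never[1])
    hi = min(config.jump_sometimes[1], rest - config.jump_never[0])
    if lo > hi + 1e-12:
        raise ConfigurationError(
            f"cannot place remaining mass {rest:.3f} inside the sometimes/never ranges for site {site_id}"
        )
    ps = rng.uniform(lo, hi) if hi > lo else 0.5 * (lo + hi)
    pn = rest - ps
    first = OutcomeDistribution(pa, pu, ps, pn)
    d_a, d_u = rng.uniform(*config.drift_range, size=2)
    return EffectProfile(site_id=site_id, first_quarter=first, drift_always=float(d_a), drift_usually=float(d_u), caps=config.caps)


def _drift_step(p: np.ndarray, d_always: float, d_usually: float, caps: tuple[float, float, float, float]) -> np.ndarray:
    """One quarter of improvement, conserving mass and honouring caps.

    Gains to always/usually are clamped at their caps; the mass removed
    is taken from sometimes/never in proportion to their current mass,
    clamped at the plateau floors (a clamped category's shortfall moves
    to the other), so the simplex is preserved exactly and the floors
    are never crossed.
    """
    cap_a, cap_u, floor_s, floor_n = caps
    add_a = max(0.0, min(d_always, cap_a - p[0]))
    add_u = max(0.0, min(d_usually, cap_u - p[1]))
    total = add_a + add_u
    avail_s = max(0.0, p[2] - floor_s)
    avail_n = max(0.0, p[3] - floor_n)
    available = avail_s + avail_n
    if total <= 0.0 or available <= 0.0:
        return p
    if total > available:
        scale = available / total
        add_a *= scale
        add_u *= scale
        total = available
    rem_s = total * p[2] / (p[2] + p[3])
    rem_n = total - rem_s
    if rem_s > avail_s:
        rem_s, rem_n = avail_s, total - avail_s
    elif rem_n > avail_n:
        rem_n, rem_s = avail_n, total - avail_n
    out = p + np.array([add_a, add_u, -rem_s, -rem_n])
    return np.clip(out, 0.0, 1.0)


def category_probs(
    state: str,
    quarters_since_start: Optional[int],
    profile: EffectProfile,
) -> OutcomeDistribution:
    """Outcome distribution for a cell in the given state.

    ``quarters_since_start`` counts implementation quarters (1 = the
    site's first on-quarter); it is ignored in the control state.
    """
    if state == "control":
        return OutcomeDistribution(*_UNIFORM)
    if state != "implementation":
        raise ValueError(f"state must be 'control' or 'implementation', got {state!r}")
    if quarters_since_start is None or quarters_since_start < 1:
        raise ValueError(f"quarters_since_start must be >= 1 in the implementation state, got {quarters_since_start}")
    p = profile.first_quarter.as_array()
    for _ in range(quarters_since_start - 1):
        p = _drift_step(p, profile.drift_always, profile.drift_usually, profile.caps)
    p = p / p.sum()  # guard float drift; exact to ~1e-16
    return OutcomeDistribution(*p)


def cell_distributions(config: ScenarioConfig) -> dict[tuple[int, int], OutcomeDistribution]:
    """The exact generating distribution of every (site, quarter) cell.

    This is the simulation's ground truth: downstream oracles use it to
    compute design-implied quantities without Monte-Carlo error.
    """
    out: dict[tuple[int, int], OutcomeDistribution] = {}
    for site in config.schedule.sites:
        rng = _site_rng(config, site.site_id)
        profile = draw_effect_profile(rng, site.site_id, config)
        for quarter in range(1, config.schedule.n_quarters + 1):
            if quarter < site.start_quarter:
                out[(site.site_id, quarter)] = category_probs("control", None, profile)
            else:
                q_since = quarter - site.start_quarter + 1
                out[(site.site_id, quarter)] = category_probs("implementation", q_since, profile)
    return out


def simulate_dataset(config: ScenarioConfig) -> pd.DataFrame:
    """Simulate one respondent-level dataset.

    Returns a DataFrame with columns ``respondent_id, site_id, quarter,
    access, female, nonwhite`` and exactly ``n_per_cell`` rows per
    (site, quarter) cell. Respondent ids run sequentially over
    (quarter, site) blocks: ids 1..n fall in quarter 1 at site 1, the
    final block in the last quarter at the last site. Fully reproducible
    from ``config.seed``.
    """
    n = config.n_per_cell
    frames = []
    for site in sorted(config.schedule.sites, key=lambda s: s.site_id):
        rng = _site_rng(config, site.site_id)
        profile = draw_effect_profile(rng, site.site_id, config)
        for quarter in range(1, config.schedule.n_quarters + 1):
            if quarter < site.start_quarter:
                dist = category_probs("control", None, profile)
            else:
                dist = category_probs("implementation", quarter - site.start_quarter + 1, profile)
            access = rng.choice([1, 2, 3, 4], size=n, p=dist.as_array())
            if config.exact_covariate_quota:
                female = _quota_draw(rng, n, config.p_female)
                nonwhite = _quota_draw(rng, n, config.p_nonwhite)
            else:
                female = (rng.random(n) < config.p_female).astype(np.int64)
                nonwhite = (rng.random(n) < config.p_nonwhite).astype(np.int64)
            frames.append(
                pd.DataFrame(
                    {
                        "site_id": site.site_id,
                        "quarter": quarter,
                        "access": access.astype(np.int64),
                        "female": female,
                        "nonwhite": nonwhite,
                    }
                )
            )
    data = pd.concat(frames, ignore_index=True)
    # Fresh cross-sections numbered over (quarter, site) blocks.
    data = data.sort_values(["quarter", "site_id"], kind="stable").reset_index(drop=True)
    data.insert(0, "respondent_id", np.arange(1, len(data) + 1, dtype=np.int64))
    return data


def _quota_draw(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """Exactly round(n*p) successes, in random positions."""
    k = int(round(n * p))
    out = np.zeros(n, dtype=np.int64)
    out[: min(k, n)] = 1
    rng.shuffle(out)
    return out


def summarize_mean_access(dataset: pd.DataFrame, schedule: Optional[WedgeSchedule] = None) -> pd.DataFrame:
    """Per-cell mean access score Y_.jk (sum of 1..4 codes / cell n).

    With a ``schedule``, cells absent from the data appear with a
    missing mean (never an imputed zero).
    """
    if dataset.empty:
        raise ValueError("dataset is empty")
    g = dataset.groupby(["site_id", "quarter"])["access"].agg(mean_access="mean", n="size").reset_index()
    if schedule is not None:
        full = pd.MultiIndex.from_product(
            [sorted(s.site_id for s in schedule.sites), range(1, schedule.n_quarters + 1)],
            names=["site_id", "quarter"],
        )
        g = g.set_index(["site_id", "quarter"]).reindex(full).reset_index()
        g["n"] = g["n"].fillna(0).astype(int)
    return g


def write_dataset(dataset: pd.DataFrame, path) -> None:
    dataset.to_csv(path, index=False)


def read_dataset(path) -> pd.DataFrame:
    data = pd.read_csv(path)
    expected = ["respondent_id", "site_id", "quarter", "access", "female", "nonwhite"]
    missing = [c for c in expected if c not in data.columns]
    if missing:
        raise ValueError(f"dataset file missing columns {missing}")
    return data[expected].astype(np.int64)
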