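"""End-to-end scenario runs: simulate, fit Models 1-4, render summaries.

A scenario run produces an :class:`EvaluationReport` holding the four
standard model fits on one simulated dataset, the per-cell mean-access
table (the trajectory summary), and the full resolved configuration so
the report can be regenerated bit-identically from its own provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import model as _model
from .model import FitOptions, FitResult, ModelSpec, fit, wald_summary
from .schedule import WedgeSchedule
from .simulate import ScenarioConfig, simulate_dataset, summarize_mean_access

#: Table row order and labels for the coefficient table.
TABLE_ROWS = [
    ("intercept", "Intercept, gamma_000"),
    ("delta2", "Threshold 2, delta_2"),
    ("delta3", "Threshold 3, delta_3"),
    ("qtr", "QTR, gamma_010"),
    ("treat", "TREAT, gamma_020"),
    ("qtr_x_treat", "QTR*TREAT, gamma_030"),
    ("female", "FEMALE, gamma_100 (ref: MALE)"),
    ("nonwhite", "NONWHITE, gamma_200 (ref: WHITE)"),
    ("med", "MED, gamma_001 (ref: SMALL)"),
    ("lg", "LG, gamma_002 (ref: SMALL)"),
]


@dataclass
class EvaluationReport:
    """One scenario evaluation: four model fits plus trajectory summary."""

    config: ScenarioConfig
    fits: dict[int, FitResult]
    mean_access: pd.DataFrame
    version: str = ""
    replicate_index: Optional[int] = None

    def to_dir(self, path) -> Path:
        """Write models_1..4.csv, table1.txt, mean_access.csv and the
        resolved config under ``path``."""
        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        for number, fit_result in self.fits.items():
            wald_summary(fit_result).to_csv(out / f"model_{number}.csv", index=False)
        (out / "table1.txt").write_text(render_table1(self))
        self.mean_access.to_csv(out / "mean_access.csv", index=False)
        (out / "config_resolved.yaml").write_text(
            yaml.safe_dump({"version": self.version, "config": self.config.to_dict()}, sort_keys=False)
        )
        return out

    @property
    def all_converged(self) -> bool:
        return all(f.converged for f in self.fits.values())


def run_scenario(
    config: ScenarioConfig,
    models: Sequence[int] = (1, 2, 3, 4),
    options: Optional[FitOptions] = None,
    dataset: Optional[pd.DataFrame] = None,
) -> EvaluationReport:
    """Simulate one dataset and fit the requested models on it.

    All fits use the same dataset. A model's non-convergence is recorded
    in its FitResult; it does not abort the run.
    """
    from . import __version__

    if dataset is None:
        dataset = simulate_dataset(config)
    fits: dict[int, FitResult] = {}
    for number in models:
        fits[number] = fit(dataset, config.schedule, ModelSpec.from_number(number), options)
    mean_access = summarize_mean_access(dataset, config.schedule)
    return EvaluationReport(config=config, fits=fits, mean_access=mean_access, version=__version__)


def render_table1(report: EvaluationReport) -> str:
    """Side-by-side coefficient table over the fitted models.

    Cells read "estimate (SE)/OR" with ``**`` marking p < 0.001 and
    ``a`` marking p < 0.05; a term absent from a model leaves a blank
    cell. Threshold rows are re-derived per model, never copied across
    columns.
    """
    frame = table1_frame(report)
    widths = {c: max(len(c), frame[c].astype(str).map(len).max()) for c in frame.columns}
    lines = ["  ".join(c.ljust(widths[c]) for c in frame.columns)]
    lines.append("  ".join("-" * widths[c] for c in frame.columns))
    for _, row in frame.iterrows():
        lines.append("  ".join(str(row[c]).ljust(widths[c]) for c in frame.columns))
    lines.append("")
    lines.append("** p < 0.001; a p < 0.05. Coeff (SE)/OR.")
    return "\n".join(lines) + "\n"


def table1_frame(report: EvaluationReport) -> pd.DataFrame:
    """The coefficient table as a DataFrame of formatted cells."""
    columns: dict[str, list[str]] = {"Parameter": [label for _, label in TABLE_ROWS]}
    for number in sorted(report.fits):
        summary = wald_summary(report.fits[number]).set_index("term")
        cells = []
        for term, _ in TABLE_ROWS:
            cells.append(summary.loc[term, "cell"] if term in summary.index else "")
        columns[f"Model {number}"] = cells
    return pd.DataFrame(columns)


@dataclass
class BatchResult:
    """Replicate-level estimates and aggregate summaries from a batch."""

    replicates: pd.DataFrame
    n_requested: int
    n_failed: int
    alpha: float

    def rejection_rate(self, term: str = "treat") -> float:
        return float(self.replicates[f"reject_{term}"].mean())

    def mean(self, column: str) -> float:
        return float(self.replicates[column].mean())

    def sd(self, column: str) -> float:
        return float(self.replicates[column].std(ddof=1))


def monte_carlo_batch(
    config: ScenarioConfig,
    n_replicates: int,
    base_seed: int,
    model_number: int = 1,
    alpha: float = 0.05,
    options: Optional[FitOptions] = None,
) -> BatchResult:
    """Independent seeded replicates of simulate-and-fit.

    Each replicate draws its own seed from a root seed sequence, so the
    batch is reproducible and replicates are mutually independent. A
    replicate whose fit errors out is excluded and counted.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    seeds = (np.random.SeedSequence(base_seed).generate_state(n_replicates) % (2**31)).tolist()
    spec = ModelSpec.from_number(model_number)
    rows = []
    n_failed = 0
    for i, seed in enumerate(seeds):
        rep_config = config.replace(seed=int(seed))
        try:
            dataset = simulate_dataset(rep_config)
            res = fit(dataset, rep_config.schedule, spec, options)
        except Exception:  # noqa: BLE001 - replicate failure is data, not fatal
            n_failed += 1
            continue
        row = {
            "replicate": i,
            "seed": int(seed),
            "converged": res.converged,
            "delta2": res.delta2,
            "delta3": res.delta3,
            "variance_time": res.variance_time,
            "variance_site": res.variance_site,
        }
        for term, c in res.coefficients.items():
            row[term] = c.estimate
            row[f"se_{term}"] = c.se
            row[f"p_{term}"] = c.p_value
            row[f"reject_{term}"] = bool(c.p_value < alpha)
        rows.append(row)
    return BatchResult(replicates=pd.DataFrame(rows), n_requested=n_replicates, n_failed=n_failed, alpha=alpha)


def plot_mean_access(mean_access: pd.DataFrame, schedule: WedgeSchedule, path=None):
    """Trajectory plot of per-site mean access over quarters.

    The y-axis is inverted (the 1..4 coding has 1 = "always"), so
    improvement reads upward; each site's implementation start quarter
    is marked.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    for site in sorted(schedule.sites, key=lambda s: s.site_id):
        sub = mean_access[mean_access["site_id"] == site.site_id]
        (line,) = ax.plot(sub["quarter"], sub["mean_access"], marker="o", ms=3, label=f"Site {site.site_id}")
        ax.axvline(site.start_quarter, color=line.get_color(), alpha=0.15, lw=1)
    ax.set_xlabel("Quarter")
    ax.set_ylabel("Mean access score (1 = always ... 4 = never)")
    ax.invert_yaxis()
    ax.set_title("Mean simulated patient-assessed access by site")
    ax.legend(fontsize=7, ncol=3)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


def load_config(path) -> ScenarioConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return ScenarioConfig.from_dict(raw)


def save_config(config: ScenarioConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
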