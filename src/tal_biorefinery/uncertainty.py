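"""Latin-hypercube Monte Carlo, Spearman screening, and scenario grids.

Latin hypercube sampling places exactly one draw in each of n
equal-probability strata per parameter, with independent stratum
permutations across parameters. Influential parameters are screened with
Spearman rank correlations against each sustainability indicator using
the dual threshold |rho| >= 0.10 and p < 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import config as _config

__all__ = [
    "ParameterDistribution",
    "SampleTable",
    "IndicatorSummary",
    "SensitivityResult",
    "MonteCarloResult",
    "lhs_sample",
    "monte_carlo",
    "spearman_screen",
    "grid_map",
    "scenario",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20250501
PERCENTILES = (5, 25, 50, 75, 95)
RHO_THRESHOLD = 0.10
P_THRESHOLD = 0.05


@dataclass
class ParameterDistribution:
    """One uncertain parameter bound to a config path."""

    name: str
    shape: str  # "uniform" | "triangular"
    lower: float
    upper: float
    mode: float | None
    baseline: float
    path: str

    def __post_init__(self) -> None:
        if self.shape not in ("uniform", "triangular"):
            raise ValueError(f"{self.name}: unknown shape {self.shape!r}")
        if not (self.lower < self.upper):
            raise ValueError(f"{self.name}: lower must be below upper")
        if self.shape == "triangular":
            if self.mode is None or not (self.lower <= self.mode <= self.upper):
                raise ValueError(f"{self.name}: mode must lie within [lower, upper]")
        if not (self.lower - 1e-12 <= self.baseline <= self.upper + 1e-12):
            raise ValueError(f"{self.name}: baseline outside the support")

    def ppf(self, q: np.ndarray) -> np.ndarray:
        if self.shape == "uniform":
            return self.lower + q * (self.upper - self.lower)
        c = (self.mode - self.lower) / (self.upper - self.lower)
        return stats.triang.ppf(q, c, loc=self.lower, scale=self.upper - self.lower)


@dataclass
class SampleTable:
    """n x p matrix of Monte Carlo draws."""

    samples: pd.DataFrame
    seed: int
    distributions: list[ParameterDistribution]

    @property
    def n(self) -> int:
        return len(self.samples)


def lhs_sample(
    dists: Sequence[ParameterDistribution], n: int, seed: int = DEFAULT_SEED
) -> SampleTable:
    """Latin hypercube sample: one draw per equal-probability stratum.

    For each parameter the unit interval is cut into n strata; one uniform
    draw is taken inside each stratum and the strata are independently
    permuted, then mapped through the distribution's inverse CDF.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    columns = {}
    for dist in dists:
        strata = rng.permutation(n)
        u = (strata + rng.uniform(size=n)) / n
        columns[dist.path] = dist.ppf(u)
    table = pd.DataFrame(columns)
    return SampleTable(samples=table, seed=seed, distributions=list(dists))


@dataclass
class IndicatorSummary:
    """Percentile summary (5/25/50/75/95) plus the baseline value."""

    percentiles: dict[int, float]
    baseline: float

    def __post_init__(self) -> None:
        values = [self.percentiles[p] for p in sorted(self.percentiles)]
        if any(b < a - 1e-12 for a, b in zip(values, values[1:])):
            raise ValueError("percentiles must be non-decreasing")


@dataclass
class MonteCarloResult:
    table: SampleTable
    indicators: pd.DataFrame  # one row per sample; NaN for failed runs
    summaries: dict[str, IndicatorSummary]
    n_failed: int
    flagged: bool


def monte_carlo(
    model: Callable[[dict[str, float]], dict[str, float]],
    table: SampleTable,
    failure_limit: float = 0.01,
) -> MonteCarloResult:
    """Evaluate ``model`` on every sampled row and summarize the indicators.

    ``model`` maps {config_path: value} to {indicator: value}. Failed
    evaluations are recorded as NaN rows (never silently dropped); the run
    is flagged when more than ``failure_limit`` of samples fail.
    """
    rows: list[dict[str, float]] = []
    n_failed = 0
    for _, sample in table.samples.iterrows():
        try:
            rows.append(dict(model(sample.to_dict())))
        except Exception:
            rows.append({})
            n_failed += 1
    indicators = pd.DataFrame(rows, index=table.samples.index)
    flagged = n_failed > failure_limit * max(1, table.n)
    if flagged:
        warnings.warn(
            f"{n_failed}/{table.n} Monte Carlo evaluations failed", RuntimeWarning
        )
    baseline_inputs = {d.path: d.baseline for d in table.distributions}
    baseline_out = model(baseline_inputs)
    summaries = {}
    for col in indicators.columns:
        vals = indicators[col].dropna().to_numpy()
        pct = {p: float(np.percentile(vals, p)) for p in PERCENTILES}
        summaries[col] = IndicatorSummary(percentiles=pct, baseline=float(baseline_out[col]))
    return MonteCarloResult(
        table=table,
        indicators=indicators,
        summaries=summaries,
        n_failed=n_failed,
        flagged=flagged,
    )


@dataclass
class SensitivityResult:
    """Spearman screen of every parameter against one indicator."""

    table: pd.DataFrame  # columns: parameter, rho, p_value, significant
    notes: list[str] = field(default_factory=list)


def spearman_screen(table: SampleTable, outputs: pd.Series | np.ndarray) -> SensitivityResult:
    """Rank-correlation screen with the |rho| >= 0.10 and p < 0.05 rule.

    Ties take midranks; p-values use the t approximation. A constant
    output has undefined rho, reported as 0 with the flag false and a note.
    """
    y = np.asarray(outputs, dtype=float)
    if len(y) < 10:
        raise ValueError("need at least 10 samples for the Spearman screen")
    mask = np.isfinite(y)
    rows = []
    notes: list[str] = []
    for path in table.samples.columns:
        x = table.samples[path].to_numpy()[mask]
        yv = y[mask]
        if np.ptp(yv) == 0 or np.ptp(x) == 0:
            rows.append({"parameter": path, "rho": 0.0, "p_value": 1.0, "significant": False})
            notes.append(f"{path}: constant input or output; rho undefined, reported as 0")
            continue
        rho, p = stats.spearmanr(x, yv)
        rows.append(
            {
                "parameter": path,
                "rho": float(rho),
                "p_value": float(p),
                "significant": bool(abs(rho) >= RHO_THRESHOLD and p < P_THRESHOLD),
            }
        )
    return SensitivityResult(table=pd.DataFrame(rows), notes=notes)


def _feasible(cfg: dict) -> bool:
    from .flowsheet import FermentationSpec  # deferred import
    from .config import build_specs

    try:
        ferm: FermentationSpec = build_specs(cfg)["fermentation"]
    except (ValueError, KeyError):
        return False
    return (
        ferm.required_substrate_concentration
        <= ferm.max_sugar_concentration_g_per_L
        and ferm.carbon_closure_ok()
    )


def grid_map(
    x_axis: tuple[str, Sequence[float]],
    y_axis: tuple[str, Sequence[float]],
    cfg: dict,
    evaluate: Callable[[dict], dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Full-factorial indicator surface over two config-path axes.

    Returns a long-format frame with columns x, y, feasible, and one
    column per indicator (NaN where the cell is infeasible, e.g. a titer
    unreachable at the given yield under the sugar-concentration cap).
    All other parameters stay at the values in ``cfg``.
    """
    from .pipeline import evaluate as _default_evaluate

    evaluate = evaluate or _default_evaluate
    x_path, x_values = x_axis
    y_path, y_values = y_axis
    if len(x_values) < 2 or len(y_values) < 2:
        raise ValueError("axis resolutions must be >= 2")
    rows = []
    for yv in y_values:
        for xv in x_values:
            trial = _config.apply_overrides(cfg, {x_path: float(xv), y_path: float(yv)})
            row: dict[str, Any] = {"x": float(xv), "y": float(yv)}
            if _feasible(trial):
                try:
                    out = evaluate(trial)
                    row.update(
                        {k: v for k, v in out.items() if isinstance(v, (int, float))}
                    )
                    row["feasible"] = True
                except Exception:
                    row["feasible"] = False
            else:
                row["feasible"] = False
            rows.append(row)
    return pd.DataFrame(rows)


def scenario(
    cfg: dict,
    overrides: dict[str, float],
    evaluate: Callable[[dict], dict[str, float]] | None = None,
) -> dict[str, Any]:
    """Deterministic evaluation of named overrides vs the un-overridden run.

    Returns indicators under the overrides plus ``delta_*`` entries
    relative to the baseline configuration.
    """
    from .pipeline import evaluate as _default_evaluate

    evaluate = evaluate or _default_evaluate
    trial = _config.apply_overrides(cfg, overrides)  # raises on unknown paths
    base = evaluate(cfg)
    out = evaluate(trial)
    result: dict[str, Any] = dict(out)
    for key, value in out.items():
        if isinstance(value, (int, float)) and key in base:
            result[f"delta_{key}"] = value - base[key]
    return result
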