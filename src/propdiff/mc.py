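"""Monte Carlo harness: replicate experiments and summarize estimator behavior.

Each experiment draws ``reps`` independent two-sample datasets from a
scenario, fits the requested models, and aggregates bias, empirical
variance, rejection rate and their Monte Carlo errors.  Replication
``r`` of an experiment is reproducible in isolation: its random stream
depends only on ``(seed, r)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import estimators
from .generators import (
    BETA_GRID,
    GROUP_SIZES,
    MULTINOMIAL_GRID,
    BetaScenario,
    MultinomialScenario,
    beta_scenario,
    draw_beta_two_sample,
    draw_multinomial_two_sample,
    multinomial_scenario,
)

__all__ = [
    "ExperimentConfig",
    "ReplicationRecord",
    "ModelSummary",
    "SummaryRow",
    "run_replication",
    "run_experiment",
    "mc_errors",
    "scenario_grid",
    "summary_frame",
]

MODEL_TAGS = estimators.MODEL_TAGS

_FITTERS: dict[str, Callable] = {
    "linear": estimators.fit_linear,
    "beta_const": estimators.fit_beta_const,
    "beta_vardisp": estimators.fit_beta_vardisp,
    "fraclogit": estimators.fit_fraclogit,
}


@dataclass(frozen=True)
class ExperimentConfig:
    """One simulation experiment: a scenario plus run controls."""

    scenario: BetaScenario | MultinomialScenario
    reps: int = 20000
    seed: int = 0
    models: tuple[str, ...] = MODEL_TAGS
    alpha: float = 0.05
    label: str = ""

    def __post_init__(self) -> None:
        if self.reps < 2:
            raise ValueError("reps must be at least 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0,1)")
        unknown = set(self.models) - set(MODEL_TAGS)
        if unknown:
            raise ValueError(f"unknown model tags: {sorted(unknown)}")


@dataclass
class ModelRep:
    """Per-model outcome of a single replication."""

    delta_hat: float = math.nan
    model_var: float = math.nan
    reject: bool = False
    converged: bool = False


@dataclass
class ReplicationRecord:
    index: int
    results: dict[str, ModelRep]


@dataclass
class ModelSummary:
    bias: float
    mc_error_bias: float
    variance: float
    mc_error_variance: float
    rejection_rate: float
    mc_error_rejection: float
    mean_model_variance: float
    n_excluded: int


@dataclass
class SummaryRow:
    """Aggregated experiment summary, one block per model."""

    label: str
    n0: int
    n1: int
    true_delta: float
    reps: int
    seed: int
    scenario_fields: dict[str, float]
    models: dict[str, ModelSummary]


def replication_rng(seed: int, index: int) -> np.random.Generator:
    """Independent substream for replication ``index`` of master ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def _draw(config: ExperimentConfig, rng: np.random.Generator):
    if isinstance(config.scenario, BetaScenario):
        return draw_beta_two_sample(config.scenario, rng)
    return draw_multinomial_two_sample(config.scenario, rng)


def run_replication(config: ExperimentConfig, index: int) -> ReplicationRecord:
    """Draw one dataset and fit every requested model.

    Deterministic given ``(config.seed, index)``.  Fit failures are
    recorded as non-converged entries rather than raised.
    """
    rng = replication_rng(config.seed, index)
    data = _draw(config, rng)
    results: dict[str, ModelRep] = {}
    for tag in config.models:
        rep = ModelRep()
        try:
            fit = _FITTERS[tag](data)
            if fit.converged:
                eff = estimators.effect_from_fit(fit, alpha=config.alpha)
                rep = ModelRep(
                    delta_hat=eff.delta_hat,
                    model_var=eff.se**2,
                    reject=eff.reject,
                    converged=True,
                )
        except (ValueError, np.linalg.LinAlgError, FloatingPointError):
            pass
        results[tag] = rep
    return ReplicationRecord(index=index, results=results)


def mc_errors(
    estimates: Sequence[float], rejections: Sequence[bool], reps: int
) -> tuple[float, float, float]:
    """Monte Carlo standard errors of bias, variance and rejection rate.

    * MCE(bias) = sd(estimates) / sqrt(reps)
    * MCE(variance) = s^2 * sqrt(2 / (reps - 1))
    * MCE(rejection) = sqrt(r*(1-r) / reps)
    """
    if reps < 2:
        raise ValueError("at least 2 replications are required")
    est = np.asarray(estimates, dtype=float)
    rej = np.asarray(rejections, dtype=float)
    s2 = float(np.var(est, ddof=1))
    mce_bias = math.sqrt(s2) / math.sqrt(reps)
    mce_variance = s2 * math.sqrt(2.0 / (reps - 1))
    r_hat = float(rej.mean()) if rej.size else math.nan
    mce_rejection = math.sqrt(r_hat * (1.0 - r_hat) / reps)
    return mce_bias, mce_variance, mce_rejection


def _scenario_fields(scenario) -> dict[str, float]:
    if isinstance(scenario, BetaScenario):
        return {
            "mu0": scenario.group0.mu,
            "phi0": scenario.group0.phi,
            "mu1": scenario.group1.mu,
            "phi1": scenario.group1.phi,
        }
    return {"ey0": scenario.mean0, "ey1": scenario.mean1}


def run_experiment(
    config: ExperimentConfig, progress: Callable[[int], None] | None = None
) -> SummaryRow:
    """Run all replications and aggregate per-model summaries.

    Non-converged replications are excluded from a model's aggregates
    and counted in ``n_excluded``.  A model with no converged
    replications gets an all-NaN summary block.
    """
    per_model: dict[str, dict[str, list]] = {
        tag: {"delta": [], "mvar": [], "reject": []} for tag in config.models
    }
    for r in range(config.reps):
        record = run_replication(config, r)
        for tag in config.models:
            rep = record.results[tag]
            if rep.converged:
                per_model[tag]["delta"].append(rep.delta_hat)
                per_model[tag]["mvar"].append(rep.model_var)
                per_model[tag]["reject"].append(rep.reject)
        if progress is not None:
            progress(r)

    true_delta = config.scenario.true_delta
    models: dict[str, ModelSummary] = {}
    for tag in config.models:
        deltas = np.asarray(per_model[tag]["delta"], dtype=float)
        n_ok = deltas.size
        n_excluded = config.reps - n_ok
        if n_ok < 2:
            models[tag] = ModelSummary(*([math.nan] * 7), n_excluded=n_excluded)
            continue
        rejects = np.asarray(per_model[tag]["reject"], dtype=bool)
        mce_bias, mce_var, mce_rej = mc_errors(deltas, rejects, n_ok)
        models[tag] = ModelSummary(
            bias=float(deltas.mean() - true_delta),
            mc_error_bias=mce_bias,
            variance=float(np.var(deltas, ddof=1)),
            mc_error_variance=mce_var,
            rejection_rate=float(rejects.mean()),
            mc_error_rejection=mce_rej,
            mean_model_variance=float(np.mean(per_model[tag]["mvar"])),
            n_excluded=n_excluded,
        )
    return SummaryRow(
        label=config.label,
        n0=config.scenario.n0,
        n1=config.scenario.n1,
        true_delta=true_delta,
        reps=config.reps,
        seed=config.seed,
        scenario_fields=_scenario_fields(config.scenario),
        models=models,
    )


def _derive_seed(master_seed: int, index: int) -> int:
    return int(np.random.SeedSequence(entropy=master_seed, spawn_key=(index,)).generate_state(1)[0])


def scenario_grid(
    table_id: int,
    reps: int = 20000,
    seed: int = 0,
    models: tuple[str, ...] = MODEL_TAGS,
    rows: Sequence[int] | None = None,
    n_values: Sequence[int] = GROUP_SIZES,
    alpha: float = 0.05,
) -> list[ExperimentConfig]:
    """All experiment configs of a shipped grid.

    Grid 1 has 24 beta rows, grid 2 has 4 discrete rows; each row is
    crossed with the shipped group sizes.  Each experiment receives its
    own seed derived from ``seed`` so configurations are independent but
    jointly reproducible.
    """
    if table_id == 1:
        all_rows = range(1, len(BETA_GRID) + 1)
        build = beta_scenario
    elif table_id == 2:
        all_rows = range(1, len(MULTINOMIAL_GRID) + 1)
        build = multinomial_scenario
    else:
        raise ValueError(f"unknown grid id: {table_id!r} (expected 1 or 2)")
    use_rows = list(all_rows) if rows is None else list(rows)
    for row in use_rows:
        if row not in all_rows:
            raise KeyError(f"row {row} not in grid {table_id}")
    configs = []
    idx = 0
    for row in use_rows:
        for n in n_values:
            configs.append(
                ExperimentConfig(
                    scenario=build(row, int(n)),
                    reps=reps,
                    seed=_derive_seed(seed, idx),
                    models=tuple(models),
                    alpha=alpha,
                    label=f"table{table_id}_row{row}_n{n}",
                )
            )
            idx += 1
    return configs


_MODEL_COLUMNS = (
    "bias",
    "mc_error_bias",
    "variance",
    "mc_error_variance",
    "rejection_rate",
    "mc_error_rejection",
    "mean_model_variance",
    "n_excluded",
)


def summary_frame(rows: Sequence[SummaryRow]) -> pd.DataFrame:
    """Flatten summary rows into a stable delimited-table schema.

    One row per experiment; scenario identifier columns first, then one
    column block per model
    (``<model>_bias`` ... ``<model>_n_excluded``).
    """
    records = []
    for row in rows:
        rec: dict = {
            "label": row.label,
            "n0": row.n0,
            "n1": row.n1,
            "true_delta": row.true_delta,
            "reps": row.reps,
            "seed": row.seed,
        }
        rec.update(row.scenario_fields)
        for tag, summ in row.models.items():
            for col in _MODEL_COLUMNS:
                rec[f"{tag}_{col}"] = getattr(summ, col)
        records.append(rec)
    return pd.DataFrame.from_records(records)
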