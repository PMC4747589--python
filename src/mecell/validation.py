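"""Population-level validation: resampling envelopes, fit-error metrics
and robustness experiments.

A fitted population model is validated by resampling virtual cells from
it, simulating them over the full experiment, and comparing the
time-wise median and 95% band against held-out data.  Unlike real
cells, all virtual cells span the whole horizon starting from
m = p = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._kernel import propagate
from .dynamics import ErrorModel
from .input_model import InputSignal, ShockSchedule, build_input
from .population import PopulationModel, sample_log
from .synthetic import CellTrajectory, StudyDataset

__all__ = ["PopulationEnvelope", "predict_population", "fit_error",
           "envelope_coverage", "robustness_experiment", "predict_cells"]


@dataclass(frozen=True)
class PopulationEnvelope:
    """Time-wise median and quantile band of simulated fluorescence."""

    times: np.ndarray
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_virtual: int
    q_lower: float = 2.5
    q_upper: float = 97.5

    def __post_init__(self) -> None:
        if np.any(self.lower > self.median + 1e-9) or np.any(self.median > self.upper + 1e-9):
            raise ValueError("envelope quantiles must satisfy lower <= median <= upper")


def simulate_virtual_population(
    pop: PopulationModel,
    schedule: ShockSchedule,
    n: int,
    rng: np.random.Generator,
    sample_period_min: float = 6.0,
    with_noise: bool = False,
    transport_delay_min: float = 2.0,
    lag_min: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample n parameter sets and simulate their fluorescence at the
    frame times (all cells from t = 0, m = p = 0).  Returns
    ``(frame_times, values)`` with values of shape (n, n_frames)."""
    input_signal = build_input(schedule, transport_delay_min, lag_min)
    frames = np.arange(0.0, schedule.duration_min + 1e-9, sample_period_min)
    eval_times = np.maximum(frames - pop.tau_min, 0.0)
    grid = np.unique(np.concatenate([input_signal.grid_times, eval_times]))
    Z = sample_log(pop, n, rng)
    theta = np.exp(Z)
    zeros = np.zeros(n)
    _, P = propagate(grid, input_signal.at(grid[:-1]),
                     np.zeros(n, dtype=np.int64), zeros, zeros,
                     theta[:, 0], theta[:, 1], theta[:, 2], theta[:, 3])
    vals = P[:, np.searchsorted(grid, eval_times)]
    if with_noise:
        e1 = rng.standard_normal(vals.shape)
        e2 = rng.standard_normal(vals.shape)
        vals = vals * (1.0 + pop.error.sigma_mult * e1) + pop.error.sigma_add * e2
    return frames, vals


def predict_population(
    pop: PopulationModel,
    schedule: ShockSchedule,
    n: int = 10000,
    rng: np.random.Generator | int | None = None,
    with_noise: bool = False,
    sample_period_min: float = 6.0,
    quantiles: tuple[float, float] = (2.5, 97.5),
    **input_kwargs,
) -> PopulationEnvelope:
    """Time-wise median and quantile band of n resampled virtual cells."""
    if n < 100:
        raise ValueError("need n >= 100 virtual cells")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    frames, vals = simulate_virtual_population(
        pop, schedule, n, rng, sample_period_min, with_noise, **input_kwargs)
    lo, med, hi = np.percentile(vals, [quantiles[0], 50.0, quantiles[1]], axis=0)
    return PopulationEnvelope(times=frames, median=med, lower=lo, upper=hi,
                              n_virtual=n, q_lower=quantiles[0], q_upper=quantiles[1])


def predict_cells(study: StudyDataset, params_log: np.ndarray, input: InputSignal,
                  tau_min: float) -> dict[str, np.ndarray]:
    """Noise-free per-cell predictions aligned with each trajectory's
    sample times; ``params_log`` rows follow study.trajectories order."""
    from .dynamics import StudySimulator

    sim = StudySimulator(study.trajectories, input, tau_min)
    pred = sim.predictions(np.asarray(params_log, dtype=float))
    out = {}
    for c, traj in enumerate(study.trajectories):
        out[traj.cell_id] = pred[sim.obs_cell == c]
    return out


def fit_error(study: StudyDataset, predictions: dict[str, np.ndarray],
              floor_fraction: float = 0.05) -> float:
    """Average relative absolute difference between single-cell
    predictions and data, in percent.

    Each residual is normalized by the cell's time-averaged fluorescence,
    floored at ``floor_fraction`` of the peak of the population median
    curve (avoids blow-up at low signal)."""
    frames = np.unique(np.concatenate([t.times for t in study.trajectories]))
    med = []
    for tt in frames:
        vals = []
        for t in study.trajectories:
            j = np.searchsorted(t.times, tt)
            if j < len(t.times) and abs(t.times[j] - tt) < 1e-9:
                vals.append(t.values[j])
        if vals:
            med.append(np.median(vals))
    floor = floor_fraction * max(float(np.max(med)), 1e-12)

    errs = []
    for traj in study.trajectories:
        if traj.cell_id not in predictions:
            continue
        pred = np.asarray(predictions[traj.cell_id], dtype=float)
        if pred.shape != traj.values.shape:
            raise ValueError(f"cell {traj.cell_id}: prediction length mismatch")
        y_ref = max(float(np.mean(traj.values)), floor)
        errs.append(np.abs(pred - traj.values) / y_ref)
    if not errs:
        raise ValueError("no overlapping cells between study and predictions")
    return float(100.0 * np.mean(np.concatenate(errs)))


def envelope_coverage(study: StudyDataset, env: PopulationEnvelope) -> float:
    """Fraction of data points lying inside [lower, upper] at their
    sample times (times matched to the nearest envelope frame)."""
    inside = total = 0
    for traj in study.trajectories:
        idx = np.clip(np.searchsorted(env.times, traj.times), 0, len(env.times) - 1)
        left = np.clip(idx - 1, 0, len(env.times) - 1)
        idx = np.where(np.abs(env.times[left] - traj.times) <
                       np.abs(env.times[idx] - traj.times), left, idx)
        inside += int(np.sum((traj.values >= env.lower[idx]) &
                             (traj.values <= env.upper[idx])))
        total += len(traj.values)
    return inside / total if total else 0.0


def truncate_study(study: StudyDataset, horizon_min: float) -> StudyDataset:
    """Drop samples after ``horizon_min`` (cells left empty are removed)."""
    kept = []
    for traj in study.trajectories:
        mask = traj.times <= horizon_min + 1e-9
        if mask.sum() >= 2:
            kept.append(CellTrajectory(cell_id=traj.cell_id, times=traj.times[mask],
                                       values=traj.values[mask],
                                       birth_time_min=traj.birth_time_min,
                                       end_time_min=min(traj.end_time_min, horizon_min)))
    ids = {t.cell_id for t in kept}
    lineage = study.lineage[study.lineage["daughter_id"].isin(ids) &
                            study.lineage["mother_id"].isin(ids)].reset_index(drop=True)
    truth = (study.truth_params.loc[study.truth_params.index.intersection(ids)]
             if study.truth_params is not None else None)
    return StudyDataset(trajectories=kept,
                        features=study.features.loc[study.features.index.intersection(ids)],
                        lineage=lineage, schedule=study.schedule,
                        truth_params=truth, truth_population=study.truth_population)


def subsample_study(study: StudyDataset, n_cells: int,
                    rng: np.random.Generator) -> StudyDataset:
    """Seeded random subset of cells (lineage/features subset to match)."""
    if n_cells >= len(study):
        return study
    pick = rng.choice(len(study), size=n_cells, replace=False)
    kept = [study.trajectories[i] for i in sorted(pick)]
    ids = {t.cell_id for t in kept}
    lineage = study.lineage[study.lineage["daughter_id"].isin(ids) &
                            study.lineage["mother_id"].isin(ids)].reset_index(drop=True)
    truth = (study.truth_params.loc[study.truth_params.index.intersection(ids)]
             if study.truth_params is not None else None)
    return StudyDataset(trajectories=kept,
                        features=study.features.loc[study.features.index.intersection(ids)],
                        lineage=lineage, schedule=study.schedule,
                        truth_params=truth, truth_population=study.truth_population)


def mu_recovery_error(fitted: PopulationModel, truth: PopulationModel,
                      free_components: tuple[int, ...] = (0, 1, 3)) -> float:
    """Max relative error of the free log-mean components (the mean of
    ln k_p is fixed during inference and excluded)."""
    idx = list(free_components)
    return float(np.max(np.abs((fitted.mu[idx] - truth.mu[idx]) / truth.mu[idx])))


def robustness_experiment(
    study: StudyDataset,
    input: InputSignal,
    saem_config,
    cell_counts: tuple[int, ...] = (32, 64, 128, None),
    horizons_h: tuple[float, ...] = (5.0, 7.0, 10.0),
    rng: np.random.Generator | int | None = None,
    n_envelope: int = 2000,
) -> pd.DataFrame:
    """Re-fit SAEM on subsampled / truncated data and score each
    condition: μ-recovery error against ground truth (when available)
    and envelope coverage on the full held-out study."""
    from .saem import fit_saem

    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rows = []
    for count in cell_counts:
        for horizon in horizons_h:
            sub = study if count is None else subsample_study(study, count, rng)
            sub = truncate_study(sub, horizon * 60.0)
            pop_fit, _ = fit_saem(sub, input, saem_config)
            env = predict_population(pop_fit, study.schedule, n=n_envelope,
                                     rng=rng, with_noise=True)
            cov = envelope_coverage(study, env)
            mu_err = (mu_recovery_error(pop_fit, study.truth_population)
                      if study.truth_population is not None else np.nan)
            rows.append({"n_cells": count or len(study), "horizon_h": horizon,
                         "mu_error": mu_err, "coverage": cov,
                         "tau_min": pop_fit.tau_min})
    return pd.DataFrame(rows)
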