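"""Naive population inference: independent per-cell maximum-likelihood
fits, pooled afterwards into an empirical parameter distribution.

This is the natural baseline: each cell is fitted on its own (with the
maturation delay τ and the noise strengths frozen to values estimated
once on the population's median trajectory), and the population
distribution is simply the sample mean/covariance of the per-cell
log-estimates.  Because a single trajectory constrains four rates only
weakly, per-cell estimates are noisy and the pooled covariance is
inflated by estimation error — the deficiency the mixed-effects (SAEM)
approach corrects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .dynamics import CellParameters, ErrorModel, StudySimulator, loglik
from .input_model import InputSignal
from .population import PopulationModel, fit_empirical
from .synthetic import CellTrajectory, StudyDataset

__all__ = ["NaiveFitResult", "fit_mean_cell", "fit_cell_ml", "pool_population",
           "fit_study_naive"]

logger = logging.getLogger(__name__)

LITERATURE_THETA = np.array([5.0, 0.12, 1.0, 0.008])
BOX_HALFWIDTH = 6.0  # log-units around the search center


class FitError(RuntimeError):
    pass


@dataclass
class CellFit:
    params: CellParameters
    loglik: float
    converged: bool
    n_restarts: int


@dataclass
class NaiveFitResult:
    per_cell: dict[str, CellFit]
    pooled: PopulationModel
    tau_min: float
    error: ErrorModel
    mean_cell: CellParameters


def median_trajectory(study: StudyDataset) -> CellTrajectory:
    """Time-wise median fluorescence across cells (frames observed by at
    least 20% of cells, so sparse late/early frames don't dominate)."""
    all_times = np.unique(np.concatenate([t.times for t in study.trajectories]))
    n = len(study.trajectories)
    med, keep = [], []
    for tt in all_times:
        vals = [t.values[np.searchsorted(t.times, tt)]
                for t in study.trajectories
                if np.any(np.isclose(t.times, tt, atol=1e-9))]
        if len(vals) >= max(3, 0.2 * n):
            med.append(float(np.median(vals)))
            keep.append(tt)
    return CellTrajectory(cell_id="<median>", times=np.array(keep),
                          values=np.array(med), birth_time_min=float(keep[0]),
                          end_time_min=float(keep[-1]))


def _box_penalty(z: np.ndarray, center: np.ndarray) -> float:
    excess = np.abs(z - center) - BOX_HALFWIDTH
    return float(1e6 * np.sum(np.clip(excess, 0.0, None) ** 2))


def fit_mean_cell(
    study: StudyDataset,
    input: InputSignal,
    init_from_literature: CellParameters | None = None,
    n_starts: int = 3,
    rng: np.random.Generator | int | None = None,
    tau_bounds: tuple[float, float] = (0.0, 30.0),
) -> tuple[CellParameters, float, ErrorModel]:
    """Fit the median trajectory jointly for (θ, τ, σ_add, σ_mult).

    A multi-start Nelder-Mead search (literature-centered starts with
    seeded log-space perturbations) maximizes the likelihood of the
    population median trajectory.  The returned delay and noise
    strengths are frozen for all subsequent per-cell fits.
    """
    if len(study.trajectories) == 0:
        raise FitError("empty study")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    med = median_trajectory(study)
    init = init_from_literature or CellParameters.from_array(LITERATURE_THETA)
    z0 = init.log_array()

    def objective(x: np.ndarray) -> float:
        z, tau, ln_sa, ln_sm = x[:4], x[4], x[5], x[6]
        if not (tau_bounds[0] <= tau <= tau_bounds[1]):
            return 1e12 + 1e6 * (tau - np.clip(tau, *tau_bounds)) ** 2
        pen = _box_penalty(z, z0)
        try:
            ll = loglik(med, CellParameters.from_log_array(np.clip(z, -30, 30)),
                        tau, ErrorModel(np.exp(ln_sa), np.exp(ln_sm)), input)
        except FloatingPointError:
            return 1e12
        return -ll + pen

    best = None
    x0_base = np.concatenate([z0, [5.0, np.log(5.0), np.log(0.1)]])
    for s in range(n_starts):
        x0 = x0_base.copy()
        if s > 0:
            x0[:4] += rng.normal(0, 0.5, 4)
            x0[4] = rng.uniform(*tau_bounds)
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"maxfev": 4000, "xatol": 1e-6, "fatol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise FitError("no finite-likelihood point found for the mean cell")
    z, tau = best.x[:4], float(np.clip(best.x[4], *tau_bounds))
    error = ErrorModel(float(np.exp(best.x[5])), float(np.exp(best.x[6])))
    return CellParameters.from_log_array(z), tau, error


def fit_cell_ml(
    traj: CellTrajectory,
    input: InputSignal,
    init: CellParameters,
    tau_min: float,
    error: ErrorModel,
    n_restarts: int = 3,
    rng: np.random.Generator | int | None = None,
    _sim: StudySimulator | None = None,
) -> CellFit:
    """Per-cell maximum-likelihood fit over (ln k_m, ln g_m, ln k_p,
    ln g_p) with τ and the noise strengths held fixed.

    Nelder-Mead from the supplied init plus seeded perturbed restarts;
    the search is confined to a ±6 log-unit box around the init.  A fit
    ending on the box boundary is reported with ``converged=False``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sim = _sim or StudySimulator([traj], input, tau_min)
    z0 = init.log_array()

    def objective(z: np.ndarray) -> float:
        return float(-sim.loglik_cells(z[None, :], error)[0] + _box_penalty(z, z0))

    best, best_z = None, None
    for s in range(n_restarts):
        start = z0 if s == 0 else z0 + rng.normal(0, 0.7, 4)
        res = optimize.minimize(objective, start, method="Nelder-Mead",
                                options={"maxfev": 2500, "xatol": 1e-7, "fatol": 1e-9})
        if np.isfinite(res.fun) and (best is None or res.fun < best):
            best, best_z = res.fun, res.x
    if best is None or best >= 1e11:
        return CellFit(params=init, loglik=-np.inf, converged=False,
                       n_restarts=n_restarts)
    at_bound = bool(np.any(np.abs(best_z - z0) >= BOX_HALFWIDTH - 1e-6))
    return CellFit(params=CellParameters.from_log_array(best_z),
                   loglik=float(-best), converged=not at_bound,
                   n_restarts=n_restarts)


def pool_population(per_cell: dict[str, CellFit], tau_min: float,
                    error: ErrorModel) -> PopulationModel:
    """Empirical mean/covariance of the per-cell log-estimates
    (successful fits only; unbiased covariance)."""
    Z = np.array([f.params.log_array() for f in per_cell.values()
                  if f.converged and np.isfinite(f.loglik)])
    if len(Z) < 5:
        raise FitError(f"need >= 5 successful fits to pool, got {len(Z)}")
    return fit_empirical(Z, tau_min, error, fixed_mean_lnkp=False)


def fit_study_naive(
    study: StudyDataset,
    input: InputSignal,
    rng: np.random.Generator | int | None = None,
    n_restarts: int = 3,
    mean_cell_starts: int = 3,
    tau_error: tuple[float, ErrorModel] | None = None,
) -> NaiveFitResult:
    """Full naive pipeline: mean-cell fit (shared τ and noise), per-cell
    ML fits, empirical pooling."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if tau_error is None:
        mean_params, tau_min, error = fit_mean_cell(
            study, input, n_starts=mean_cell_starts, rng=rng)
    else:
        tau_min, error = tau_error
        mean_params = CellParameters.from_array(LITERATURE_THETA)
    sim = StudySimulator(study.trajectories, input, tau_min)
    per_cell: dict[str, CellFit] = {}
    for c, traj in enumerate(study.trajectories):
        fit = fit_cell_ml(traj, input, mean_params, tau_min, error,
                          n_restarts=n_restarts, rng=rng, _sim=sim._single(c))
        if not np.isfinite(fit.loglik):
            logger.warning("cell %s: all restarts diverged; excluded from pooling",
                           traj.cell_id)
        per_cell[traj.cell_id] = fit
    pooled = pool_population(per_cell, tau_min, error)
    return NaiveFitResult(per_cell=per_cell, pooled=pooled, tau_min=tau_min,
                          error=error, mean_cell=mean_params)
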