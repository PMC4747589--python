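"""Two-state gene-expression dynamics and the observation model.

The reporter system is described per cell by linear ODEs driven by the
transcription-factor activity u(t):

    dm/dt = k_m · u(t) − g_m · m        (mRNA)
    dp/dt = k_p · m    − g_p · p        (protein)

with u piecewise-constant, so the system is propagated exactly segment
by segment (no generic ODE solver).  Fluorescence observations are the
protein level delayed by the maturation time τ and corrupted by combined
additive + multiplicative Gaussian noise:

    y_j = p(t_j − τ) · (1 + σ_mult · ε1_j) + σ_add · ε2_j.

Only the product k_mp = k_m·k_p is structurally identifiable from
fluorescence alone: rescaling (c·k_m, k_p/c) rescales m by c and leaves
p(t) unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernel import propagate
from .input_model import InputSignal

__all__ = [
    "CellParameters",
    "StateTrajectory",
    "ErrorModel",
    "simulate",
    "observe",
    "loglik",
    "StudySimulator",
]

PARAM_NAMES = ("k_m", "g_m", "k_p", "g_p")


@dataclass(frozen=True)
class CellParameters:
    """Kinetic rates of one cell.

    k_m : mRNA synthesis rate (a.u.·min⁻¹ per unit u)
    g_m : mRNA degradation rate (min⁻¹)
    k_p : protein synthesis rate per mRNA (min⁻¹)
    g_p : protein degradation/dilution rate (min⁻¹)
    """

    k_m: float
    g_m: float
    k_p: float
    g_p: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive and finite, got {v}")

    @property
    def k_mp(self) -> float:
        """Composite protein production rate k_m·k_p — the combination
        identifiable at the single-cell level."""
        return self.k_m * self.k_p

    def as_array(self) -> np.ndarray:
        return np.array([self.k_m, self.g_m, self.k_p, self.g_p])

    def log_array(self) -> np.ndarray:
        return np.log(self.as_array())

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "CellParameters":
        return cls(*(float(x) for x in theta))

    @classmethod
    def from_log_array(cls, z: np.ndarray) -> "CellParameters":
        return cls.from_array(np.exp(np.asarray(z, dtype=float)))


@dataclass(frozen=True)
class StateTrajectory:
    """Deterministic (mRNA, protein) trajectory on a time grid."""

    times: np.ndarray
    m_values: np.ndarray
    p_values: np.ndarray
    initial_state: tuple[float, float]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        m = np.asarray(self.m_values, dtype=float)
        p = np.asarray(self.p_values, dtype=float)
        if not (t.shape == m.shape == p.shape):
            raise ValueError("times, m_values, p_values must have matching shapes")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "m_values", m)
        object.__setattr__(self, "p_values", p)


@dataclass(frozen=True)
class ErrorModel:
    """Combined measurement-noise strengths, shared by all cells."""

    sigma_add: float
    sigma_mult: float

    def __post_init__(self) -> None:
        if self.sigma_add < 0 or self.sigma_mult < 0:
            raise ValueError("noise strengths must be non-negative")
        if self.sigma_add == 0 and self.sigma_mult == 0:
            raise ValueError("at least one noise strength must be positive")

    def variance(self, prediction: np.ndarray) -> np.ndarray:
        """Observation variance at a model prediction (the multiplicative
        term uses the prediction, not the datum, keeping the likelihood
        well-defined at low signal)."""
        p = np.asarray(prediction, dtype=float)
        return self.sigma_add**2 + (self.sigma_mult * p) ** 2


def _union_grid(input: InputSignal, t_lo: float, t_hi: float, extra: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Grid containing all input breakpoints in [t_lo, t_hi] plus the
    requested times, with the drive value per segment."""
    bp = input.grid_times
    inside = bp[(bp > t_lo) & (bp < t_hi)]
    grid = np.unique(np.concatenate([[t_lo, t_hi], inside, np.asarray(extra, dtype=float)]))
    u_seg = input.at(grid[:-1]) if len(grid) > 1 else np.empty(0)
    return grid, u_seg


def simulate(
    params: CellParameters,
    input: InputSignal,
    times: np.ndarray,
    init: tuple[float, float] = (0.0, 0.0),
) -> StateTrajectory:
    """Exact propagation of the linear ODE system at the requested times.

    ``times`` must be non-decreasing; integration starts at ``times[0]``
    from ``init = (m0, p0)``.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be non-decreasing")
    m0, p0 = float(init[0]), float(init[1])
    if m0 < 0 or p0 < 0:
        raise ValueError(f"initial state must be non-negative, got {init}")

    grid, u_seg = _union_grid(input, times[0], times[-1], times)
    M, P = propagate(
        grid, u_seg, np.zeros(1, dtype=np.int64),
        np.array([m0]), np.array([p0]),
        np.array([params.k_m]), np.array([params.g_m]),
        np.array([params.k_p]), np.array([params.g_p]),
    )
    idx = np.searchsorted(grid, times)
    return StateTrajectory(times=times, m_values=M[0, idx], p_values=P[0, idx],
                           initial_state=(m0, p0))


def predict_fluorescence(
    params: CellParameters,
    input: InputSignal,
    sample_times: np.ndarray,
    tau_min: float,
    init: tuple[float, float],
    start_time: float | None = None,
) -> np.ndarray:
    """Noise-free predicted fluorescence p(t_j − τ) at the sample times.

    The state clock starts at ``start_time`` (default: first sample);
    evaluation times falling before it return the initial protein level
    (the state is clipped to its initial value before the cell's window).
    """
    sample_times = np.asarray(sample_times, dtype=float)
    t0 = float(sample_times[0]) if start_time is None else float(start_time)
    eval_times = np.maximum(sample_times - tau_min, t0)
    order = np.argsort(eval_times)
    traj = simulate(params, input, np.concatenate([[t0], eval_times[order]]), init)
    out = np.empty_like(eval_times)
    out[order] = traj.p_values[1:]
    return out


def observe(
    traj: StateTrajectory,
    tau_min: float,
    sample_times: np.ndarray,
    error: ErrorModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply maturation delay and measurement noise to a state trajectory.

    Protein values at ``sample_times − tau_min`` are taken from ``traj``
    (times before the trajectory start clip to the initial state), then

        y_j = p(t_j − τ)·(1 + σ_mult·ε1_j) + σ_add·ε2_j

    with independent standard-normal draws from ``rng``.
    """
    sample_times = np.asarray(sample_times, dtype=float)
    eval_times = np.clip(sample_times - tau_min, traj.times[0], traj.times[-1])
    # trajectory times are a simulation grid; interpolate is exact only at
    # grid points, so require eval times to be on the grid
    idx = np.searchsorted(traj.times, eval_times)
    idx = np.clip(idx, 0, len(traj.times) - 1)
    on_grid = np.isclose(traj.times[idx], eval_times, rtol=0, atol=1e-9)
    if not np.all(on_grid):
        p = np.interp(eval_times, traj.times, traj.p_values)
    else:
        p = traj.p_values[idx]
    e1 = rng.standard_normal(len(sample_times))
    e2 = rng.standard_normal(len(sample_times))
    return p * (1.0 + error.sigma_mult * e1) + error.sigma_add * e2


def loglik(
    trajectory,
    params: CellParameters,
    tau_min: float,
    error: ErrorModel,
    input: InputSignal,
    init_policy: str = "birth_anchor",
) -> float:
    """Gaussian log-likelihood of one cell's fluorescence trajectory.

    ``trajectory`` needs ``times`` and ``values`` attributes (a
    :class:`~mecell.synthetic.CellTrajectory` or equivalent).  Initial
    conditions follow ``init_policy``:

    * ``"birth_anchor"`` (default): the state clock starts at the
      cell's birth time with m = 0 (newborns carry no shock-induced
      mRNA); the unobserved protein level at birth enters through its
      decaying contribution, anchored so the prediction matches the
      first retained observation.
    * ``"first_obs"``: the clock starts at the first observation with
      m = 0 and p0 equal to that observation (clipped at 0).
    * ``"zero"``: clock at first observation, m = p = 0.
    """
    sim = StudySimulator([trajectory], input, tau_min, init_policy=init_policy)
    ll = float(sim.loglik_cells(params.log_array()[None, :], error)[0])
    if ll <= -1e11:
        cell = getattr(trajectory, "cell_id", "<anonymous>")
        raise FloatingPointError(f"non-finite model prediction for cell {cell}")
    return ll


class StudySimulator:
    """Vectorized likelihood engine for a set of cells sharing one input.

    Precomputes, for a fixed maturation delay τ, a union time grid
    covering every cell's (delay-shifted) observation times plus all
    input breakpoints, so that the likelihood of all cells at arbitrary
    log-parameter matrices can be evaluated with a single propagation
    call.  This is the hot path of the naive, SAEM and MAP fits.
    """

    def __init__(self, trajectories, input: InputSignal, tau_min: float,
                 init_policy: str = "birth_anchor"):
        if init_policy not in ("birth_anchor", "first_obs", "zero"):
            raise ValueError(f"unknown init_policy {init_policy!r}")
        self.input = input
        self.tau_min = float(tau_min)
        self.init_policy = init_policy
        self.n_cells = len(trajectories)
        self.cell_ids = [t.cell_id for t in trajectories]
        first_obs = np.array([float(t.times[0]) for t in trajectories])
        first_vals = np.array([float(t.values[0]) for t in trajectories])
        if init_policy == "birth_anchor":
            starts = np.array([float(getattr(t, "birth_time_min", t.times[0]))
                               for t in trajectories])
            starts = np.minimum(starts, first_obs)
            self.p0 = np.zeros(self.n_cells)
        elif init_policy == "first_obs":
            starts = first_obs
            self.p0 = np.maximum(first_vals, 0.0)
        else:  # "zero"
            starts = first_obs
            self.p0 = np.zeros(self.n_cells)
        self.m0 = np.zeros(self.n_cells)
        self.y1 = first_vals

        obs_cell, obs_time, obs_y = [], [], []
        for c, t in enumerate(trajectories):
            tt = np.asarray(t.times, dtype=float)
            obs_cell.append(np.full(len(tt), c))
            obs_time.append(np.maximum(tt - self.tau_min, starts[c]))
            obs_y.append(np.asarray(t.values, dtype=float))
        self.obs_cell = np.concatenate(obs_cell).astype(np.int64)
        self.obs_eval = np.concatenate(obs_time)
        self.obs_y = np.concatenate(obs_y)
        self.n_obs = len(self.obs_y)
        self.obs_counts = np.bincount(self.obs_cell, minlength=self.n_cells)
        # index (into the flat arrays) of each cell's first observation
        self.first_ptr = np.concatenate([[0], np.cumsum(self.obs_counts)[:-1]]).astype(np.int64)
        self.e1 = self.obs_eval[self.first_ptr]

        t_lo = float(min(starts.min(), self.obs_eval.min()))
        t_hi = float(max(starts.max(), self.obs_eval.max()))
        self.grid, self.u_seg = _union_grid(
            input, t_lo, t_hi, np.concatenate([starts, self.obs_eval]))
        self.start_idx = np.searchsorted(self.grid, starts).astype(np.int64)
        self.obs_grid_idx = np.searchsorted(self.grid, self.obs_eval)

    def predictions(self, Z: np.ndarray) -> np.ndarray:
        """Flat array of noise-free predictions for every observation.

        Z : (n_cells, 4) matrix of log-parameters (ln k_m, ln g_m,
        ln k_p, ln g_p), one row per cell.
        """
        Z = np.asarray(Z, dtype=float)
        theta = np.exp(np.clip(Z, -40.0, 40.0))
        M, P = propagate(self.grid, self.u_seg, self.start_idx, self.m0, self.p0,
                         theta[:, 0], theta[:, 1], theta[:, 2], theta[:, 3])
        pred = P[self.obs_cell, self.obs_grid_idx]
        if self.init_policy == "birth_anchor":
            # the unobserved protein level at birth contributes
            # a·exp(−g_p·(t − t_first)); a >= 0 is anchored so the first
            # retained observation is matched exactly
            anchor = np.maximum(self.y1 - pred[self.first_ptr], 0.0)
            gp = theta[self.obs_cell, 3]
            pred = pred + anchor[self.obs_cell] * np.exp(
                -gp * (self.obs_eval - self.e1[self.obs_cell]))
        return pred

    def loglik_cells(self, Z: np.ndarray, error: ErrorModel) -> np.ndarray:
        """Per-cell log-likelihood at log-parameter matrix Z."""
        pred = self.predictions(Z)
        var = error.variance(pred)
        ll = -0.5 * (np.log(2 * np.pi * var) + (self.obs_y - pred) ** 2 / var)
        ll = np.where(np.isfinite(ll), ll, -1e12)
        return np.bincount(self.obs_cell, weights=ll, minlength=self.n_cells)

    def loglik_single(self, cell_index: int, z: np.ndarray, error: ErrorModel) -> float:
        Z = np.tile(z, (1, 1))
        sub = self._single(cell_index)
        return float(sub.loglik_cells(Z, error)[0])

    def _single(self, cell_index: int) -> "StudySimulator":
        """Cheap single-cell view (shares the grid)."""
        view = object.__new__(StudySimulator)
        view.__dict__.update(self.__dict__)
        mask = self.obs_cell == cell_index
        view.n_cells = 1
        view.cell_ids = [self.cell_ids[cell_index]]
        view.m0 = self.m0[cell_index:cell_index + 1]
        view.p0 = self.p0[cell_index:cell_index + 1]
        view.start_idx = self.start_idx[cell_index:cell_index + 1]
        view.obs_cell = np.zeros(mask.sum(), dtype=np.int64)
        view.obs_grid_idx = self.obs_grid_idx[mask]
        view.obs_eval = self.obs_eval[mask]
        view.obs_y = self.obs_y[mask]
        view.n_obs = len(view.obs_y)
        view.obs_counts = np.array([view.n_obs])
        view.first_ptr = np.zeros(1, dtype=np.int64)
        view.e1 = view.obs_eval[:1]
        view.y1 = self.y1[cell_index:cell_index + 1]
        return view
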