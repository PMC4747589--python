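"""Joint log-normal population distribution of the kinetic parameters.

Cell-to-cell (extrinsic) variability is represented by
ln(θ) ~ N(μ, Σ) over θ = (k_m, g_m, k_p, g_p), together with the shared
maturation delay τ and the shared measurement-noise strengths.  The
covariance Σ carries the cross-correlations between rates that make the
population distribution predictive; dropping them (``decorrelate``)
keeps every marginal but destroys the joint structure.

Because only k_mp = k_m·k_p is identifiable per cell, inference fixes
the mean of ln k_p (``fixed_mean_lnkp``) and reports the induced moments
of ln k_mp = ln k_m + ln k_p via :meth:`PopulationModel.kmp_view`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import stats

from .dynamics import ErrorModel, CellParameters

__all__ = ["PopulationModel", "sample", "decorrelate", "log_prior", "dispersion_metrics"]

LOG_PARAM_NAMES = ("ln_k_m", "ln_g_m", "ln_k_p", "ln_g_p")


class PopulationModelError(ValueError):
    pass


@dataclass(frozen=True)
class PopulationModel:
    """Log-normal population distribution plus shared observation model."""

    mu: np.ndarray
    sigma: np.ndarray
    tau_min: float
    error: ErrorModel
    fixed_mean_lnkp: bool = True

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if mu.shape != (4,):
            raise PopulationModelError(f"mu must be a 4-vector, got shape {mu.shape}")
        if sigma.shape != (4, 4):
            raise PopulationModelError(f"sigma must be 4x4, got shape {sigma.shape}")
        if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(sigma))):
            raise PopulationModelError("non-finite entries in mu or sigma")
        if not np.allclose(sigma, sigma.T, atol=1e-10):
            raise PopulationModelError("sigma must be symmetric")
        eigvals = np.linalg.eigvalsh(sigma)
        if eigvals.min() < -1e-10 * max(1.0, abs(eigvals.max())):
            raise PopulationModelError("sigma must be positive semi-definite")
        if self.tau_min < 0:
            raise PopulationModelError("tau_min must be non-negative")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", 0.5 * (sigma + sigma.T))

    # ---- identifiable view -------------------------------------------------
    def kmp_view(self) -> dict:
        """Induced moments of ln k_mp = ln k_m + ln k_p.

        Returns mean and variance of ln k_mp plus its covariance and
        correlation with ln g_m and ln g_p — the population-level
        quantities that remain identifiable under the (k_m, k_p)
        structural degeneracy.
        """
        S = self.sigma
        mean = float(self.mu[0] + self.mu[2])
        var = float(S[0, 0] + S[2, 2] + 2 * S[0, 2])
        out = {"mean_ln_kmp": mean, "var_ln_kmp": var}
        for j, name in ((1, "g_m"), (3, "g_p")):
            cov = float(S[0, j] + S[2, j])
            out[f"cov_ln_kmp_ln_{name}"] = cov
            denom = np.sqrt(max(var, 0.0) * max(S[j, j], 0.0))
            out[f"corr_ln_kmp_ln_{name}"] = float(cov / denom) if denom > 0 else np.nan
        return out

    # ---- serialization -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "tau_min": self.tau_min,
            "sigma_add": self.error.sigma_add,
            "sigma_mult": self.error.sigma_mult,
            "fixed_mean_lnkp": self.fixed_mean_lnkp,
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PopulationModel":
        d = json.loads(Path(path).read_text())
        return cls(
            mu=np.array(d["mu"]), sigma=np.array(d["sigma"]), tau_min=d["tau_min"],
            error=ErrorModel(d["sigma_add"], d["sigma_mult"]),
            fixed_mean_lnkp=d.get("fixed_mean_lnkp", True),
        )


def sample(pop: PopulationModel, n: int, rng: np.random.Generator) -> list[CellParameters]:
    """Draw n parameter sets θ = exp(z), z ~ N(μ, Σ)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    Z = sample_log(pop, n, rng)
    return [CellParameters.from_log_array(z) for z in Z]


def sample_log(pop: PopulationModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw (n, 4) log-parameter vectors z ~ N(μ, Σ)."""
    eigvals, eigvecs = np.linalg.eigh(pop.sigma)
    root = eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))
    return pop.mu + rng.standard_normal((n, 4)) @ root.T


def decorrelate(pop: PopulationModel) -> PopulationModel:
    """Copy of the model with off-diagonal covariance zeroed (marginals
    preserved, joint structure discarded)."""
    return replace(pop, sigma=np.diag(np.diag(pop.sigma)))


def log_prior(params: CellParameters, pop: PopulationModel,
              allow_singular: bool = False) -> float:
    """Log-density of θ under the log-normal population distribution.

    Includes the Jacobian of the log transform (−Σ ln θ_k), i.e. this is
    the density of θ itself, not of ln θ.
    """
    z = params.log_array()
    eigvals = np.linalg.eigvalsh(pop.sigma)
    if eigvals.min() <= 1e-300 and not allow_singular:
        raise PopulationModelError(
            "singular sigma in log_prior (pass allow_singular=True to use a pseudo-inverse)")
    mvn = stats.multivariate_normal(mean=pop.mu, cov=pop.sigma,
                                    allow_singular=allow_singular)
    return float(mvn.logpdf(z) - z.sum())


def log_prior_z(Z: np.ndarray, pop: PopulationModel) -> np.ndarray:
    """Vectorized N(μ, Σ) log-density of log-parameter rows (no Jacobian:
    density of z, used by samplers operating in log space)."""
    Z = np.atleast_2d(Z)
    diff = Z - pop.mu
    sign, logdet = np.linalg.slogdet(pop.sigma)
    if sign <= 0:
        raise PopulationModelError("sigma not positive definite in log_prior_z")
    sol = np.linalg.solve(pop.sigma, diff.T).T
    quad = np.sum(diff * sol, axis=1)
    return -0.5 * (4 * np.log(2 * np.pi) + logdet + quad)


def dispersion_metrics(pop: PopulationModel) -> tuple[float, float]:
    """Compactness/structure metrics of the parameter distribution.

    Returns
    -------
    mean_cv_offdiag
        Mean of |Σ_ij / (μ_i μ_j)| over i ≠ j, computed on the log-scale
        moments — the "amount of structure" in the distribution.
    ellipsoid_volume_95
        Volume of the 95% confidence ellipsoid of N(μ, Σ):
        V = (π²/2)·r⁴·√det Σ with r² the 0.95 quantile of χ²(4) — the
        typical parameter-space volume occupied by the population.
    """
    S = pop.sigma
    mu = pop.mu
    off = ~np.eye(4, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.abs(S / np.outer(mu, mu))
    mean_cv = float(np.mean(cv[off]))
    r2 = stats.chi2.ppf(0.95, df=4)
    det = max(float(np.linalg.det(S)), 0.0)
    unit_ball_4 = np.pi**2 / 2.0
    volume = unit_ball_4 * r2**2 * np.sqrt(det)
    return mean_cv, float(volume)


def fit_empirical(Z: np.ndarray, tau_min: float, error: ErrorModel,
                  fixed_mean_lnkp: bool = True) -> PopulationModel:
    """Empirical (mean, covariance) of log-parameter rows as a model
    (unbiased covariance)."""
    Z = np.asarray(Z, dtype=float)
    mu = Z.mean(axis=0)
    sigma = np.cov(Z, rowvar=False, ddof=1)
    return PopulationModel(mu=mu, sigma=sigma, tau_min=tau_min, error=error,
                           fixed_mean_lnkp=fixed_mean_lnkp)
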