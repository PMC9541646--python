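"""Multispecies Gompertz community simulation with Poisson sampling.

The latent process is the discrete-time version of Gompertz-regulated log
abundance dynamics: for species i with growth rate r_i ~ N(mu_r, sigma2_r)
drawn once (quenched heterogeneity),

    X_{i,t+1} = X_{i,t} + r_i - gamma * X_{i,t} + eta_{i,t} + eps_t,

with species-specific noise eta_{i,t} ~ N(0, sigma2_s) independent over
species and time, and a common environmental shock eps_t ~ N(0, sigma2_E)
shared by all species in a step.  This is an AR(1) in X with coefficient
(1 - gamma): the stationary mean is mu_r / gamma (the mean log carrying
capacity) and the stationary variance of the species-specific deviation is
sigma2_s / (1 - (1 - gamma)^2), which approaches the continuous-time value
sigma2_s / (2 gamma) for small gamma.  Observed counts are Poisson with
mean nu * exp(X), nu being the sampling intensity.

The simulator doubles as the synthetic-fixture generator for tests and as
the engine of the parametric bootstrap (via :func:`simulate_from_fitted`,
which draws from a *fitted* mixed model rather than from the process).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CommunityTable

__all__ = [
    "SimulationConfig",
    "SimulatedCommunity",
    "simulate",
    "simulate_from_fitted",
    "simulation_study_grid",
]

#: hard overflow guard for latent log abundance (exp(710) overflows float64)
_LOG_ABUNDANCE_MAX = 700.0


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one community simulation.

    Defaults follow the reference study conditions: 100 species run for
    370 steps with the first 320 discarded as burn-in, all species starting
    at the mean log carrying capacity ``mu_r / gamma``.
    """

    n_species: int = 100
    n_steps: int = 370
    burn_in: int = 320
    gamma: float = 0.1
    mu_r: float = 1.0
    sigma2_r: float = 0.0
    sigma2_s: float = 0.0
    sigma2_E: float = 0.0
    nu: float = 1.0
    x0: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species <= 0:
            raise ValueError("n_species must be > 0")
        if not (0 <= self.burn_in < self.n_steps):
            raise ValueError("require 0 <= burn_in < n_steps")
        if not (0 < self.gamma < 1):
            raise ValueError("gamma must be in (0, 1) for a stable discrete map")
        for name in ("sigma2_r", "sigma2_s", "sigma2_E"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.nu <= 1):
            raise ValueError("nu must be in (0, 1]")

    @property
    def initial_state(self) -> float:
        return self.mu_r / self.gamma if self.x0 is None else self.x0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulatedCommunity:
    """Latent log abundances (after burn-in), Poisson counts and growth rates."""

    latent_logN: np.ndarray  # S x T
    counts: np.ndarray  # S x T, nonnegative ints
    growth_rates: np.ndarray  # length S
    config: SimulationConfig

    @property
    def n_retained(self) -> int:
        return self.latent_logN.shape[1]

    def to_table(self, location="site-1") -> CommunityTable:
        """Long-format view: one row per (species, time step)."""
        S, T = self.counts.shape
        df = pd.DataFrame(
            {
                "species": np.repeat([f"sp{i:03d}" for i in range(S)], T),
                "time": np.tile(np.arange(T, dtype=float), S),
                "location": location,
                "replicate": 0,
                "count": self.counts.ravel(),
            }
        )
        return CommunityTable(df)

    def write(self, path: str | Path) -> None:
        """Write counts as long-format CSV plus a sidecar config (with seed)."""
        self.to_table().write_csv(path)
        sidecar = Path(path).with_suffix(".config.json")
        sidecar.write_text(json.dumps(self.config.to_dict(), indent=2))


def simulate(config: SimulationConfig) -> SimulatedCommunity:
    """Run the discrete Gompertz community dynamics and Poisson-sample counts."""
    rng = np.random.default_rng(config.seed)
    S, n, burn = config.n_species, config.n_steps, config.burn_in
    g = config.gamma

    r = rng.normal(config.mu_r, np.sqrt(config.sigma2_r), size=S)
    x = np.full(S, config.initial_state, dtype=float)
    keep = np.empty((S, n - burn), dtype=float)

    sd_s = np.sqrt(config.sigma2_s)
    sd_E = np.sqrt(config.sigma2_E)
    for t in range(n):
        eta = rng.normal(0.0, sd_s, size=S) if sd_s > 0 else 0.0
        eps = rng.normal(0.0, sd_E) if sd_E > 0 else 0.0
        x = x + r - g * x + eta + eps
        if np.any(np.abs(x) > _LOG_ABUNDANCE_MAX):
            raise FloatingPointError(
                f"latent log abundance exceeded {_LOG_ABUNDANCE_MAX} at step {t}"
            )
        if t >= burn:
            keep[:, t - burn] = x

    counts = rng.poisson(config.nu * np.exp(keep))
    return SimulatedCommunity(latent_logN=keep, counts=counts, growth_rates=r, config=config)


def simulate_from_fitted(results, seed: int) -> CommunityTable:
    """Parametric draw of a new data set from a fitted mixed model.

    Random effects are drawn from N(0, estimated covariance), the linear
    predictor is assembled on the same (species, unit, group, replicate)
    grid as the original data, and counts are Poisson(exp(eta)).  This is
    the generator behind the parametric bootstrap.
    """
    # implemented on the model side, where the random-effect design lives
    return results.model.simulate(results.params, seed=seed)


def simulation_study_grid(
    gammas=(0.05, 0.1, 0.5),
    use_text_gammas: bool = False,
    n_species: int = 100,
    n_steps: int = 370,
    burn_in: int = 320,
    seed: int = 0,
) -> list[SimulationConfig]:
    """Full factorial of the reference simulation-study design.

    Cells: within-species proportion sigma2_e in {0.2, 0.4, 0.6, 0.8} with
    sigma2_h = 1 - sigma2_e, common environmental variance sigma2_c in
    {0.01, 0.1}, sampling intensity nu in {0.01, 0.1, 0.5}, crossed with
    the density-regulation strengths ``gammas``.  Process-scale parameters
    follow from sigma2_s = 2 gamma sigma2_e, sigma2_r = gamma^2 sigma2_h,
    sigma2_E = 2 gamma sigma2_c and mu_r = 10 gamma (log carrying
    capacity 10).

    ``use_text_gammas`` switches to the alternative set {0.01, 0.1, 0.5}.
    """
    if use_text_gammas:
        gammas = (0.01, 0.1, 0.5)
    grid = []
    for g in gammas:
        for s2e in (0.2, 0.4, 0.6, 0.8):
            s2h = 1.0 - s2e
            for s2c in (0.01, 0.1):
                for nu in (0.01, 0.1, 0.5):
                    grid.append(
                        SimulationConfig(
                            n_species=n_species,
                            n_steps=n_steps,
                            burn_in=burn_in,
                            gamma=g,
                            mu_r=10.0 * g,
                            sigma2_r=g**2 * s2h,
                            sigma2_s=2 * g * s2e,
                            sigma2_E=2 * g * s2c,
                            nu=nu,
                            seed=seed,
                        )
                    )
    return grid
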