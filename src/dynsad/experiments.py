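"""Replicate-simulation experiments: estimator bias and bootstrap coverage.

These are the building blocks of the simulation study: simulate
communities from the Gompertz process at a design cell, fit the GLMM to
each replicate, and summarise estimator bias; or wrap each fit in a
parametric bootstrap and measure interval coverage of the generating
parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import DynamicSADModel, InnerNewtonError, ModelSpec
from .simulate import SimulationConfig, simulate

__all__ = ["design_cell", "recovery_experiment", "coverage_experiment"]

log = logging.getLogger(__name__)


def design_cell(
    gamma: float,
    sigma2_e: float = 0.2,
    sigma2_c: float = 0.1,
    nu: float = 0.5,
    logK: float = 10.0,
    n_species: int = 100,
    n_steps: int = 370,
    burn_in: int = 320,
    seed: int = 0,
) -> SimulationConfig:
    """One cell of the simulation-study design on the process scale.

    sigma2_e and sigma2_h = 1 - sigma2_e are the GLMM-scale variances the
    process parameters are derived from (sigma2_s = 2 gamma sigma2_e,
    sigma2_r = gamma^2 sigma2_h, sigma2_E = 2 gamma sigma2_c,
    mu_r = logK * gamma).
    """
    return SimulationConfig(
        n_species=n_species,
        n_steps=n_steps,
        burn_in=burn_in,
        gamma=gamma,
        mu_r=logK * gamma,
        sigma2_r=gamma**2 * (1.0 - sigma2_e),
        sigma2_s=2 * gamma * sigma2_e,
        sigma2_E=2 * gamma * sigma2_c,
        nu=nu,
        seed=seed,
    )


@dataclass
class RecoveryResult:
    """Replicate estimates and their bias relative to the generating cell."""

    estimates: pd.DataFrame
    truth: dict

    @property
    def bias(self) -> pd.Series:
        common = [k for k in self.truth if k in self.estimates.columns]
        return self.estimates[common].mean() - pd.Series(self.truth)[common]


def recovery_experiment(
    cell: SimulationConfig,
    n_reps: int,
    seed: int = 0,
    spec: ModelSpec | None = None,
    n_starts: int = 1,
) -> RecoveryResult:
    """Fit the GLMM to ``n_reps`` fresh process simulations of one cell."""
    spec = spec if spec is not None else ModelSpec(separate_common_rate=True)
    g = cell.gamma
    truth = {
        "sigma2_h": cell.sigma2_r / g**2,
        "sigma2_e": cell.sigma2_s / (2 * g),
        "sigma2_c": cell.sigma2_E / (2 * g),
        "gamma": g,
        "gamma_c": g,
        "beta0": np.log(cell.nu) + cell.mu_r / g,
    }
    rows = []
    for k in range(n_reps):
        cfg = SimulationConfig(**{**cell.to_dict(), "seed": (seed + 1) * 10007 + k})
        table = simulate(cfg).to_table()
        model = DynamicSADModel(table, spec)
        try:
            res = model.fit(seed=seed + k, n_starts=n_starts)
            rows.append(res.estimates)
        except (RuntimeError, InnerNewtonError, np.linalg.LinAlgError) as err:
            log.warning("replicate %d failed: %s", k, err)
    if not rows:
        raise RuntimeError("no replicate fit converged")
    return RecoveryResult(estimates=pd.DataFrame(rows), truth=truth)


def coverage_experiment(
    cell: SimulationConfig,
    n_outer: int,
    n_boot: int,
    parameter: str = "sigma2_h",
    level: float = 0.95,
    seed: int = 0,
    spec: ModelSpec | None = None,
) -> dict:
    """Interval coverage of a generating parameter under repeated sampling.

    For each outer replicate: simulate the process, fit, bootstrap the fit
    with ``n_boot`` replicates, and check whether the ``level`` percentile
    interval for ``parameter`` contains the generating value.
    """
    spec = spec if spec is not None else ModelSpec()
    g = cell.gamma
    truth = {
        "sigma2_h": cell.sigma2_r / g**2,
        "sigma2_e": cell.sigma2_s / (2 * g),
        "sigma2_c": cell.sigma2_E / (2 * g),
        "gamma": g,
    }[parameter]
    n_done, n_covered = 0, 0
    for outer in range(n_outer):
        cfg = SimulationConfig(**{**cell.to_dict(), "seed": (seed + 1) * 20011 + outer})
        table = simulate(cfg).to_table()
        model = DynamicSADModel(table, spec)
        try:
            res = model.fit(seed=seed + outer, n_starts=1)
            boot = res.bootstrap(n_reps=n_boot, level=level, seed=seed + outer)
        except (RuntimeError, InnerNewtonError, np.linalg.LinAlgError) as err:
            log.warning("outer replicate %d failed: %s", outer, err)
            continue
        lo, hi = boot.intervals.loc[parameter]
        n_done += 1
        n_covered += bool(lo <= truth <= hi)
    if n_done == 0:
        raise RuntimeError("no outer replicate completed")
    return {
        "parameter": parameter,
        "truth": truth,
        "n_outer": n_done,
        "n_covered": n_covered,
        "coverage": n_covered / n_done,
        "level": level,
    }
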