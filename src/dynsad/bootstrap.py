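"""Parametric-bootstrap uncertainty for fitted abundance-distribution GLMMs.

Each replicate simulates a new data set from the fitted model on the
original observation grid, refits the same model specification (warm
started at the original estimates, with one dispersed fallback start) and
records the parameter estimates together with derived quantities.
Percentile intervals are taken over converged replicates; non-converged
replicates are counted and excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import DynamicSADModel, DynamicSADResults, InnerNewtonError

__all__ = ["BootstrapResult", "parametric_bootstrap", "summarize_intervals"]


@dataclass
class BootstrapResult:
    """Replicate estimates and percentile intervals from a parametric bootstrap."""

    n_requested: int
    n_converged: int
    level: float
    seed: int
    replicates: pd.DataFrame  # one row per converged replicate
    intervals: pd.DataFrame = field(default=None)  # parameter x (lower, upper)
    replicate_seeds: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.intervals is None:
            self.intervals = percentile_intervals(self.replicates, self.level)

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.replicates.to_csv(prefix.with_suffix(".replicates.csv"), index=False)
        payload = {
            "n_requested": self.n_requested,
            "n_converged": self.n_converged,
            "level": self.level,
            "seed": self.seed,
            "replicate_seeds": self.replicate_seeds,
            "intervals": {
                p: [float(lo), float(hi)]
                for p, (lo, hi) in self.intervals.iterrows()
            },
        }
        prefix.with_suffix(".intervals.json").write_text(json.dumps(payload, indent=2))


def _empirical_quantile(values: np.ndarray, p: float) -> float:
    """Order-statistic (inverted-CDF) quantile of finite values."""
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return np.nan
    return float(np.quantile(finite, p, method="inverted_cdf"))


def percentile_intervals(replicates: pd.DataFrame, level: float) -> pd.DataFrame:
    """Equal-tailed percentile intervals column-wise over a replicate table.

    Quantiles are empirical order statistics (the classical percentile
    bootstrap), so strictly monotone transforms commute with the interval
    endpoints.
    """
    alpha = (1.0 - level) / 2.0
    lo, hi = {}, {}
    for col in replicates.columns:
        vals = pd.to_numeric(replicates[col], errors="coerce").to_numpy(dtype=float)
        lo[col] = _empirical_quantile(vals, alpha)
        hi[col] = _empirical_quantile(vals, 1.0 - alpha)
    return pd.DataFrame({"lower": pd.Series(lo), "upper": pd.Series(hi)})


def _replicate_seed(master: int, k: int) -> int:
    # counter scheme keeping derived seeds well below 2**31
    return int((master * 100003 + k) % (2**31 - 1))


def parametric_bootstrap(
    fit: DynamicSADResults,
    n_reps: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    similarity_lags: tuple = (),
    nu: float = 1.0,
    ftol: float = 1e-7,
    inner_tol: float = 1e-6,
    min_converged_frac: float = 0.5,
) -> BootstrapResult:
    """Parametric bootstrap of all estimates and derived quantities.

    Parameters
    ----------
    fit :
        A converged :class:`~dynsad.model.DynamicSADResults`.
    n_reps :
        Number of replicates (the reference analyses use 1000).
    level :
        Interval coverage level in (0, 1).
    similarity_lags :
        Lags/distances at which per-replicate similarity curves are
        recorded (columns ``rho_x(<lag>)`` and ``rho_xbar(<lag>)``).
    nu :
        Sampling intensity used for the population-parameter transform.

    Raises
    ------
    RuntimeError
        If fewer than ``min_converged_frac`` of replicates converge.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    if not fit.converged:
        raise ValueError("bootstrap requires a converged fit")

    model = fit.model
    params_hat = fit.params
    rows = []
    seeds = []
    n_failed = 0
    for k in range(n_reps):
        rep_seed = _replicate_seed(seed, k)
        seeds.append(rep_seed)
        counts = model.simulate_counts(params_hat, seed=rep_seed)
        rep_model = model.clone_with_counts(counts)
        try:
            rep = rep_model.fit(
                start_params=fit.theta, n_starts=1, seed=rep_seed,
                ftol=ftol, inner_tol=inner_tol,
            )
            if not rep.converged:
                raise RuntimeError("optimizer flagged non-convergence")
        except (RuntimeError, InnerNewtonError, np.linalg.LinAlgError):
            try:  # one dispersed fallback start
                rep = rep_model.fit(n_starts=1, seed=rep_seed + 1, ftol=ftol,
                                    inner_tol=inner_tol)
            except (RuntimeError, InnerNewtonError, np.linalg.LinAlgError):
                n_failed += 1
                continue
        row = dict(rep.estimates)
        try:
            pp = rep.to_population_params(nu=nu)
            row.update(
                {
                    "sigma2_r": pp.sigma2_r,
                    "sigma2_s": pp.sigma2_s,
                    "sigma2_E": pp.sigma2_E,
                    "logK": pp.logK,
                }
            )
            props = rep.variance_proportions()
            for kk, v in props["species_specific"].items():
                row[f"prop_{kk}"] = v
            for u in similarity_lags:
                row[f"rho_x({u})"] = float(rep.similarity_relative(u))
                if "general" in props:
                    row[f"rho_xbar({u})"] = float(rep.similarity_mean(u))
        except (ValueError, ZeroDivisionError):
            pass  # boundary replicate: derived quantities undefined
        rows.append(row)

    n_converged = len(rows)
    if n_converged < min_converged_frac * n_reps:
        raise RuntimeError(
            f"only {n_converged}/{n_reps} bootstrap replicates converged"
        )
    replicates = pd.DataFrame(rows)
    return BootstrapResult(
        n_requested=n_reps,
        n_converged=n_converged,
        level=level,
        seed=seed,
        replicates=replicates,
        replicate_seeds=seeds,
    )


def summarize_intervals(
    result: BootstrapResult, transforms: dict | None = None
) -> pd.DataFrame:
    """Percentile intervals after per-replicate transformation.

    ``transforms`` maps output names to callables applied row-wise to the
    replicate table before taking percentiles (e.g. return time
    ``1/gamma``).  Replicates where a transform is non-finite are dropped
    for that quantity, with the drop count reported.
    """
    if result.replicates.empty:
        raise ValueError("empty bootstrap result")
    frames = {c: result.replicates[c] for c in result.replicates.columns}
    if transforms:
        for name, fn in transforms.items():
            frames[name] = result.replicates.apply(fn, axis=1)
    alpha = (1.0 - result.level) / 2.0
    out = []
    for name, series in frames.items():
        vals = pd.to_numeric(series, errors="coerce").to_numpy(dtype=float)
        n_finite = int(np.isfinite(vals).sum())
        out.append(
            {
                "parameter": name,
                "lower": _empirical_quantile(vals, alpha),
                "upper": _empirical_quantile(vals, 1.0 - alpha),
                "n_dropped": int(len(vals) - n_finite),
            }
        )
    return pd.DataFrame(out).set_index("parameter")
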