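"""Parameter containers and the covariance algebra linking the two scales.

A fitted intercept-only Poisson GLMM is summarised by its variance
components on the linear-predictor (log abundance) scale
(:class:`VarianceComponents`); Gompertz population dynamics are summarised
on the process scale (:class:`PopulationParams`).  The two are connected by

    sigma2_h = sigma2_r / gamma**2      (species heterogeneity)
    sigma2_e = sigma2_s / (2 * gamma)   (species-specific environment)
    sigma2_c = sigma2_E / (2 * gamma_c) (common environment)

so that the covariance of log abundance of one species at lag u,

    cov(X_t, X_{t+u}) = sigma2_r/gamma^2
                        + (sigma2_s/(2 gamma)) exp(-gamma u)
                        + (sigma2_E/(2 gamma)) exp(-gamma u),

coincides with the covariance of linear predictors of the mixed model.
This module also provides variance partitioning and the community
similarity (correlation) curves derived from a fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "VarianceComponents",
    "PopulationParams",
    "linear_predictor_covariance",
    "stationary_relative_variance",
    "log_abundance_covariance",
    "to_population_params",
    "from_population_params",
    "variance_proportions",
    "similarity_relative",
    "similarity_mean",
]


@dataclass(frozen=True)
class VarianceComponents:
    """Variance components of the intercept-only Poisson GLMM.

    Attributes
    ----------
    beta0 :
        Intercept, the expected log count (confounded with sampling
        intensity: what is estimated from data is ``ln nu + log K``).
    sigma2_h :
        Among-species variance (species heterogeneity; variance of log
        carrying capacity).
    sigma2_e :
        Within-species (species x unit) environmental variance.
    sigma2_c :
        Common-environment (among-unit) variance, synchronising species.
    sigma2_o :
        Observation-level variance (overdispersion); 0 if not modelled.
    sigma2_u :
        Uncorrelated sampling-unit variance; 0 if not modelled.
    gamma :
        Decay rate of the species-specific correlation (per year for
        temporal models; per km -- conventionally called alpha -- for
        spatial models).
    gamma_c :
        Decay rate of the common-environment correlation; defaults to
        ``gamma`` when not estimated separately.
    dimension :
        ``"temporal"`` or ``"spatial"``; controls serialisation key names
        (gamma/gamma_c vs alpha/alpha_c).
    """

    beta0: float
    sigma2_h: float
    sigma2_e: float
    sigma2_c: float
    gamma: float
    gamma_c: float | None = None
    sigma2_o: float = 0.0
    sigma2_u: float = 0.0
    dimension: str = "temporal"

    def __post_init__(self) -> None:
        for name in ("sigma2_h", "sigma2_e", "sigma2_c", "sigma2_o", "sigma2_u"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.gamma_c is not None and self.gamma_c <= 0:
            raise ValueError("gamma_c must be > 0")
        if self.dimension not in ("temporal", "spatial"):
            raise ValueError("dimension must be 'temporal' or 'spatial'")

    @property
    def rate_c(self) -> float:
        """Common-environment decay rate, falling back to ``gamma``."""
        return self.gamma if self.gamma_c is None else self.gamma_c

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        rate_key, rate_c_key = (
            ("gamma", "gamma_c") if self.dimension == "temporal" else ("alpha", "alpha_c")
        )
        return {
            "beta0": self.beta0,
            "sigma2_h": self.sigma2_h,
            "sigma2_e": self.sigma2_e,
            "sigma2_c": self.sigma2_c,
            "sigma2_o": self.sigma2_o,
            "sigma2_u": self.sigma2_u,
            rate_key: self.gamma,
            rate_c_key: self.rate_c,
            "dimension": self.dimension,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VarianceComponents":
        d = dict(d)
        dimension = d.pop("dimension", "spatial" if "alpha" in d else "temporal")
        gamma = d.pop("gamma", d.pop("alpha", None))
        gamma_c = d.pop("gamma_c", d.pop("alpha_c", None))
        if gamma is None:
            raise ValueError("missing decay rate (gamma or alpha)")
        if gamma_c is not None and float(gamma_c) == float(gamma):
            gamma_c = None  # shared rate round-trips to the default
        d.pop("nu", None)
        return cls(
            beta0=float(d.pop("beta0")),
            sigma2_h=float(d.pop("sigma2_h", 0.0)),
            sigma2_e=float(d.pop("sigma2_e", 0.0)),
            sigma2_c=float(d.pop("sigma2_c", 0.0)),
            sigma2_o=float(d.pop("sigma2_o", 0.0)),
            sigma2_u=float(d.pop("sigma2_u", 0.0)),
            gamma=float(gamma),
            gamma_c=None if gamma_c is None else float(gamma_c),
            dimension=dimension,
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            yaml.safe_dump(self.to_dict(), sort_keys=False)
            if path.suffix in (".yml", ".yaml")
            else json.dumps(self.to_dict(), indent=2)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "VarianceComponents":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(d)


@dataclass(frozen=True)
class PopulationParams:
    """Gompertz population-dynamics parameters of the community.

    ``mean_growth`` is the mean density-independent growth rate among
    species (per year), ``sigma2_r`` its among-species variance,
    ``sigma2_s``/``sigma2_E`` the species-specific and general (shared)
    environmental variances per year, ``gamma`` the strength of density
    regulation (1/gamma is the mean return time to equilibrium), ``logK``
    the mean log carrying capacity (= mean_growth / gamma) and ``nu`` the
    sampling intensity (fraction of true abundance observed).
    """

    mean_growth: float
    sigma2_r: float
    sigma2_s: float
    sigma2_E: float
    gamma: float
    logK: float
    nu: float = 1.0
    gamma_c: float | None = None

    def __post_init__(self) -> None:
        for name in ("sigma2_r", "sigma2_s", "sigma2_E"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if not (0 < self.nu <= 1):
            raise ValueError("nu must be in (0, 1]")
        if not np.isclose(self.logK * self.gamma, self.mean_growth, rtol=1e-8, atol=1e-10):
            raise ValueError("logK * gamma must equal mean_growth")

    @property
    def rate_c(self) -> float:
        return self.gamma if self.gamma_c is None else self.gamma_c

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# covariance algebra


def stationary_relative_variance(p: PopulationParams) -> float:
    """Stationary variance of relative log abundance (width of the SAD).

    ``sigma2_s / (2 gamma) + sigma2_r / gamma**2`` -- the within-species
    environmental part plus the heterogeneity part.
    """
    return p.sigma2_s / (2.0 * p.gamma) + p.sigma2_r / p.gamma**2


def log_abundance_covariance(p: PopulationParams, u: float) -> float:
    """Covariance of one species' log abundance at lag ``u >= 0`` years."""
    if u < 0:
        raise ValueError("lag u must be >= 0")
    g = p.gamma
    return p.sigma2_r / g**2 + (p.sigma2_s / (2 * g)) * np.exp(-g * u) + (
        p.sigma2_E / (2 * p.rate_c)
    ) * np.exp(-p.rate_c * u)


def linear_predictor_covariance(
    vc: VarianceComponents,
    u: float,
    same_species: bool = True,
    same_replicate: bool = False,
) -> float:
    """Covariance between two linear predictors at lag ``u``.

    Same species, same replicate at lag 0 includes every component
    (sigma2_h + sigma2_e + sigma2_c + sigma2_o); same species otherwise
    decays as ``sigma2_h + sigma2_e e^{-gamma u} + sigma2_c e^{-gamma_c u}``;
    different species share only the common environment,
    ``sigma2_c e^{-gamma_c u}``.
    """
    if u < 0:
        raise ValueError("lag u must be >= 0")
    common = vc.sigma2_c * np.exp(-vc.rate_c * u)
    if not same_species:
        return common
    if same_replicate and u == 0:
        return vc.sigma2_h + vc.sigma2_e + vc.sigma2_c + vc.sigma2_o
    return vc.sigma2_h + vc.sigma2_e * np.exp(-vc.gamma * u) + common


def to_population_params(vc: VarianceComponents, nu: float = 1.0) -> PopulationParams:
    """Transform GLMM variance components to population-dynamic parameters.

    Uses sigma2_r = gamma^2 sigma2_h, sigma2_s = 2 gamma sigma2_e,
    sigma2_E = 2 gamma_c sigma2_c, log K = beta0 - ln(nu) and
    mean_growth = gamma * log K.
    """
    if not (0 < nu <= 1):
        raise ValueError("nu must be in (0, 1]")
    g = vc.gamma
    logK = vc.beta0 - np.log(nu)
    return PopulationParams(
        mean_growth=g * logK,
        sigma2_r=g**2 * vc.sigma2_h,
        sigma2_s=2 * g * vc.sigma2_e,
        sigma2_E=2 * vc.rate_c * vc.sigma2_c,
        gamma=g,
        gamma_c=vc.gamma_c,
        logK=logK,
        nu=nu,
    )


def from_population_params(
    p: PopulationParams,
    sigma2_o: float = 0.0,
    sigma2_u: float = 0.0,
    dimension: str = "temporal",
) -> VarianceComponents:
    """Inverse of :func:`to_population_params` (observation terms optional)."""
    g = p.gamma
    return VarianceComponents(
        beta0=p.logK + np.log(p.nu),
        sigma2_h=p.sigma2_r / g**2,
        sigma2_e=p.sigma2_s / (2 * g),
        sigma2_c=p.sigma2_E / (2 * p.rate_c),
        sigma2_o=sigma2_o,
        sigma2_u=sigma2_u,
        gamma=g,
        gamma_c=p.gamma_c,
        dimension=dimension,
    )


def variance_proportions(vc: VarianceComponents) -> dict[str, dict[str, float]]:
    """Partition the variance on each of the two scales of community dynamics.

    Returns proportions of the species-specific (relative log abundance)
    variance attributable to heterogeneity, within-species environment and
    observation noise, and of the general (mean log abundance) variance
    attributable to common environment and uncorrelated sampling noise.
    Each block sums to one.
    """
    species_total = vc.sigma2_h + vc.sigma2_e + vc.sigma2_o
    if species_total <= 0:
        raise ValueError("species-specific components are all zero")
    out = {
        "species_specific": {
            "sigma2_h": vc.sigma2_h / species_total,
            "sigma2_e": vc.sigma2_e / species_total,
            "sigma2_o": vc.sigma2_o / species_total,
        }
    }
    general_total = vc.sigma2_c + vc.sigma2_u
    if general_total > 0:
        out["general"] = {
            "sigma2_c": vc.sigma2_c / general_total,
            "sigma2_u": vc.sigma2_u / general_total,
        }
    return out


def similarity_relative(vc: VarianceComponents, u: float | np.ndarray) -> float | np.ndarray:
    """Correlation of relative log abundance at lag/distance ``u``.

    ``(sigma2_e e^{-gamma u} + sigma2_h) / (sigma2_e + sigma2_h + sigma2_o)``;
    observation-level variance dilutes the correlation without contributing
    signal at positive lags.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("lag must be >= 0")
    denom = vc.sigma2_e + vc.sigma2_h + vc.sigma2_o
    if denom <= 0:
        raise ValueError("zero species-specific variance")
    val = (vc.sigma2_e * np.exp(-vc.gamma * u) + vc.sigma2_h) / denom
    return float(val) if val.ndim == 0 else val


def similarity_mean(vc: VarianceComponents, v: float | np.ndarray) -> float | np.ndarray:
    """Correlation of mean log abundance at lag/distance ``v``.

    ``sigma2_c e^{-gamma_c v} / (sigma2_c + sigma2_u)``.
    """
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("lag must be >= 0")
    denom = vc.sigma2_c + vc.sigma2_u
    if denom <= 0:
        raise ValueError("zero general variance")
    val = vc.sigma2_c * np.exp(-vc.rate_c * v) / denom
    return float(val) if val.ndim == 0 else val


def replace_vc(vc: VarianceComponents, **kw) -> VarianceComponents:
    """Functional update of a frozen :class:`VarianceComponents`."""
    return replace(vc, **kw)
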