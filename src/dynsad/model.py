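"""Intercept-only Poisson GLMM for dynamic species abundance distributions.

The observed count of species i in sampling unit t (a time point for
temporal models, a location for spatial ones), group z and replicate j is
Poisson with log mean

    eta_ijtz = beta0 + h_i + e_itz + c_tz + eps_ijtz + u_jtz,

where the random effects are (all optional except that at least one must
be present):

* ``among_species``       h ~ N(0, sigma2_h I_S), shared across groups;
* ``species_by_unit_correlated``  e ~ N(0, sigma2_e I ⊗ rho), one
  exponentially correlated series per species nested in each group;
* ``common_unit_correlated``      c ~ N(0, sigma2_c rho_c) per group,
  synchronising all species;
* ``observation_level``   eps ~ N(0, sigma2_o I), one effect per row
  (overdispersion);
* ``sampling_unit_iid``   u ~ N(0, sigma2_u I), one effect per
  (group, unit, replicate) sampling event.

The correlation rho has elements exp(-gamma |t_l - t_k|) in time or
exp(-alpha d_kl) in space; the common-environment term may carry its own
rate (gamma_c / alpha_c).  The marginal likelihood integrates the random
effects out by a Laplace approximation: an inner Newton maximisation of
the joint log density over b, plus half the log determinant of the
negative joint Hessian.  The outer optimisation works on the unconstrained
scale (log variances, log rates) with analytic gradients on the dense
linear-algebra path and finite differences on the sparse path used for
large problems.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.linalg.lapack import dpotri
from scipy.optimize import minimize
from scipy.special import gammaln

from .data import CommunityTable, DistanceMatrix
from .kernels import ou_precision_equal_spacing, pairwise_lags
from .params import VarianceComponents

__all__ = ["ModelSpec", "DynamicSADModel", "DynamicSADResults", "InnerNewtonError"]

EFFECTS = (
    "among_species",
    "species_by_unit_correlated",
    "common_unit_correlated",
    "observation_level",
    "sampling_unit_iid",
)

_EFFECT_VAR = {
    "among_species": "sigma2_h",
    "species_by_unit_correlated": "sigma2_e",
    "common_unit_correlated": "sigma2_c",
    "observation_level": "sigma2_o",
    "sampling_unit_iid": "sigma2_u",
}


#: problems with at most this many random effects use dense linear algebra
#: (and analytic outer gradients); larger ones use sparse factorisations,
#: which win once the cubic dense factorisation cost dominates
DENSE_MAX_Q = 450

_BOUND_TOL = 1e-8  # variance below this is reported as a boundary estimate


def _splu_sym(H):
    """Sparse LU tuned for the symmetric positive definite Laplace Hessian."""
    return spla.splu(H, permc_spec="MMD_AT_PLUS_A", options=dict(SymmetricMode=True))


class InnerNewtonError(RuntimeError):
    """Inner mode search failed; carries the iteration trace."""

    def __init__(self, message: str, trace: list):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class ModelSpec:
    """Which random effects to fit, and how dimensions are separated.

    ``dimension`` selects the modelled axis: temporal models treat time
    points as correlated units and group observations by location; spatial
    models treat locations as units (requiring ``distances``) and group by
    time point.  ``separate_common_rate`` estimates a distinct decay rate
    for the common-environment term (gamma_c / alpha_c).
    """

    dimension: str = "temporal"
    effects: tuple = (
        "among_species",
        "species_by_unit_correlated",
        "common_unit_correlated",
    )
    separate_common_rate: bool = False
    distances: DistanceMatrix | None = None

    def __post_init__(self) -> None:
        if self.dimension not in ("temporal", "spatial"):
            raise ValueError("dimension must be 'temporal' or 'spatial'")
        unknown = [e for e in self.effects if e not in EFFECTS]
        if unknown:
            raise ValueError(f"unknown effect name(s) {unknown}; valid: {EFFECTS}")
        if not self.effects:
            raise ValueError("at least one random effect is required")
        if self.dimension == "spatial" and (
            "species_by_unit_correlated" in self.effects
            or "common_unit_correlated" in self.effects
        ) and self.distances is None:
            raise ValueError("spatial models with correlated effects need distances")


@dataclass
class _CorrBlock:
    """One group's correlated sub-structure: kron(I_reps, rho(D))."""

    offset: int  # global index of the first effect of the block
    reps: int  # number of identical rho-blocks (species in group, or 1)
    D: np.ndarray  # T_g x T_g pairwise lags/distances
    spacing: float | None = None  # grid step if the points are equally spaced

    @property
    def T(self) -> int:
        return self.D.shape[0]

    @property
    def size(self) -> int:
        return self.reps * self.T

    @property
    def idx(self) -> np.ndarray:
        """(reps, T) global indices of the block's effects."""
        if not hasattr(self, "_idx"):
            self._idx = (
                self.offset
                + np.arange(self.reps)[:, None] * self.T
                + np.arange(self.T)[None, :]
            )
        return self._idx


def _equal_spacing(D: np.ndarray) -> float | None:
    """Grid step if D is the lag matrix of an equally spaced 1-D grid."""
    T = D.shape[0]
    if T < 2:
        return None
    d = D[0, 1]
    if d <= 0:
        return None
    idx = np.arange(T, dtype=float)
    ref = np.abs(idx[:, None] - idx[None, :]) * d
    return d if np.allclose(D, ref, rtol=1e-9, atol=1e-12) else None


@dataclass
class _EffectDesign:
    name: str
    cols: np.ndarray  # observation -> global effect index
    offset: int
    size: int
    corr: list | None = None  # list of _CorrBlock, or None for iid
    var_param: int = -1  # index into theta
    rate_param: int | None = None


def _corr_matrices(block: _CorrBlock, rate: float):
    """R, R^{-1} and logdet R for one block at the given decay rate.

    Equally spaced grids take the AR(1) fast path: the inverse is exactly
    tridiagonal (coefficient phi = exp(-rate*spacing)) and the log
    determinant is (T-1) * log(1 - phi^2).  General point sets fall back
    to a Cholesky factorisation of the dense kernel matrix.
    """
    R = np.exp(-rate * block.D)
    if block.spacing is not None:
        phi = np.exp(-rate * block.spacing)
        Rinv = ou_precision_equal_spacing(block.T, rate, block.spacing)
        logdet = (block.T - 1) * np.log1p(-(phi**2))
        return R, Rinv, logdet
    try:
        c, lower = sla.cho_factor(R, lower=True)
    except sla.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"correlation matrix not positive definite at rate {rate}"
        ) from err
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    Rinv = sla.cho_solve((c, lower), np.eye(block.T))
    return R, Rinv, logdet


class DynamicSADModel:
    """Intercept-only Poisson mixed model for community count data.

    Parameters
    ----------
    table :
        Long-format community counts.  Zero-fill beforehand
        (:meth:`dynsad.data.CommunityTable.zero_fill`) so absences are
        explicit zeros; the model uses the rows as given.
    spec :
        Random-effect structure and dimension handling.

    Examples
    --------
    >>> model = DynamicSADModel(table, ModelSpec(dimension="temporal"))
    >>> res = model.fit(seed=1)
    >>> res.params.sigma2_h
    """

    def __init__(self, table: CommunityTable, spec: ModelSpec | None = None):
        self.spec = spec if spec is not None else ModelSpec()
        self.table = table
        self._build(table.data)
        self._b_cache: np.ndarray | None = None

    # ------------------------------------------------------------------
    # design construction
    def _build(self, df: pd.DataFrame) -> None:
        temporal = self.spec.dimension == "temporal"
        unit_col = "time" if temporal else "location"
        group_col = "location" if temporal else "time"

        key = df[["species", unit_col, group_col, "replicate"]]
        if key.duplicated().any():
            raise ValueError(
                "duplicate (species, unit, group, replicate) observation keys"
            )

        self.y = df["count"].to_numpy(dtype=np.int64)
        if np.any(self.y < 0):
            raise ValueError("counts must be nonnegative")
        self.nobs = len(df)

        self.species_levels, species_codes = np.unique(df["species"], return_inverse=True)
        self.group_levels, group_codes = np.unique(df[group_col], return_inverse=True)
        self.n_species = len(self.species_levels)
        self.n_groups = len(self.group_levels)

        # per-group sorted units and lag/distance matrices
        unit_vals = df[unit_col].to_numpy()
        self._group_units: list[np.ndarray] = []
        self._group_lags: list[np.ndarray] = []
        all_units = set()
        for g in range(self.n_groups):
            units = np.unique(unit_vals[group_codes == g])
            all_units.update(units.tolist())
            self._group_units.append(units)
            if temporal:
                D = pairwise_lags(units.astype(float))
            else:
                D = self.spec.distances.submatrix(list(units)) if self.spec.distances is not None else pairwise_lags(np.arange(len(units)))
            self._group_lags.append(D)
        self.n_units = len(all_units)

        # observation -> (group, unit index within group)
        unit_idx = np.empty(self.nobs, dtype=np.int64)
        for g in range(self.n_groups):
            mask = group_codes == g
            lookup = {u: k for k, u in enumerate(self._group_units[g])}
            unit_idx[mask] = np.array([lookup[u] for u in unit_vals[mask]])

        self._species_codes = species_codes
        self._group_codes = group_codes
        self._unit_idx = unit_idx

        # canonical effect order; theta = [beta0, log variances..., log rates...]
        effects_in = [e for e in EFFECTS if e in self.spec.effects]
        self.param_names = ["beta0"]
        self._var_param: dict[str, int] = {}
        for e in effects_in:
            self._var_param[e] = len(self.param_names)
            self.param_names.append("log_" + _EFFECT_VAR[e])

        sbu = "species_by_unit_correlated" in effects_in
        cu = "common_unit_correlated" in effects_in
        self._rate_param: dict[str, int] = {}
        if sbu:
            self._rate_param["species_by_unit_correlated"] = len(self.param_names)
            self.param_names.append("log_gamma")
        if cu:
            if self.spec.separate_common_rate or not sbu:
                self._rate_param["common_unit_correlated"] = len(self.param_names)
                self.param_names.append("log_gamma_c")
            else:
                self._rate_param["common_unit_correlated"] = self._rate_param[
                    "species_by_unit_correlated"
                ]
        self.n_params = len(self.param_names)

        # effect designs
        self.effects: list[_EffectDesign] = []
        offset = 0
        for name in effects_in:
            cols, size, corr = self._effect_columns(name, offset)
            self.effects.append(
                _EffectDesign(
                    name=name,
                    cols=cols,
                    offset=offset,
                    size=size,
                    corr=corr,
                    var_param=self._var_param[name],
                    rate_param=self._rate_param.get(name),
                )
            )
            offset += size
        self.q = offset

        # sparse indicator design Z (N x q)
        rows = np.tile(np.arange(self.nobs), len(self.effects))
        cols = np.concatenate([e.cols for e in self.effects])
        data = np.ones(len(rows))
        self.Z = sp.csr_matrix((data, (rows, cols)), shape=(self.nobs, self.q))
        self._dense = self.q <= DENSE_MAX_Q
        # indicator-structure shortcuts for the dense path: Z has exactly one
        # 1 per (row, effect), so Z^T W Z, Z^T v, Z b and diag(Z A Z^T) reduce
        # to bincounts/gathers over the per-effect column arrays
        self._cols_list = [e.cols for e in self.effects]
        n_eff = len(self.effects)
        if self._dense:
            pair = [
                ce.astype(np.int64) * self.q + cf
                for ce in self._cols_list
                for cf in self._cols_list
            ]
            self._pair_flat = np.concatenate(pair)
            self._n_pairs = n_eff * n_eff
        self._loggamma_y = float(np.sum(gammaln(self.y + 1.0)))

    # dense-path helpers built on the indicator structure of Z ------------
    def _Zb(self, b: np.ndarray) -> np.ndarray:
        out = b[self._cols_list[0]].copy()
        for cols in self._cols_list[1:]:
            out += b[cols]
        return out

    def _Zt(self, v: np.ndarray) -> np.ndarray:
        out = np.empty(self.q)
        for e in self.effects:
            out[e.offset : e.offset + e.size] = np.bincount(
                e.cols - e.offset, weights=v, minlength=e.size
            )
        return out

    def _ZtWZ(self, w: np.ndarray) -> np.ndarray:
        flat = np.bincount(
            self._pair_flat,
            weights=np.tile(w, self._n_pairs),
            minlength=self.q * self.q,
        )
        return flat.reshape(self.q, self.q)

    def _diag_ZAZt(self, A: np.ndarray) -> np.ndarray:
        gathered = A.ravel()[self._pair_flat].reshape(self._n_pairs, self.nobs)
        return gathered.sum(axis=0)

    def _effect_columns(self, name: str, offset: int):
        si, gi, ui = self._species_codes, self._group_codes, self._unit_idx
        if name == "among_species":
            return offset + si, self.n_species, None
        if name == "observation_level":
            return offset + np.arange(self.nobs), self.nobs, None
        if name == "sampling_unit_iid":
            key = gi.astype(np.int64) * (self._unit_idx.max() + 1)
            trip = pd.MultiIndex.from_arrays(
                [gi, ui, self.table.data["replicate"].to_numpy()]
            )
            codes, levels = pd.factorize(trip, sort=True)
            return offset + codes, len(levels), None
        if name == "common_unit_correlated":
            cols = np.empty(self.nobs, dtype=np.int64)
            corr, local = [], 0
            for g in range(self.n_groups):
                T = len(self._group_units[g])
                D = self._group_lags[g]
                corr.append(
                    _CorrBlock(offset=offset + local, reps=1, D=D, spacing=_equal_spacing(D))
                )
                cols[gi == g] = offset + local + ui[gi == g]
                local += T
            return cols, local, corr
        if name == "species_by_unit_correlated":
            cols = np.empty(self.nobs, dtype=np.int64)
            corr, local = [], 0
            for g in range(self.n_groups):
                mask = gi == g
                T = len(self._group_units[g])
                sp_in_g = np.unique(si[mask])
                rep_of = np.full(self.n_species, -1, dtype=np.int64)
                rep_of[sp_in_g] = np.arange(len(sp_in_g))
                corr.append(
                    _CorrBlock(
                        offset=offset + local,
                        reps=len(sp_in_g),
                        D=self._group_lags[g],
                        spacing=_equal_spacing(self._group_lags[g]),
                    )
                )
                cols[mask] = offset + local + rep_of[si[mask]] * T + ui[mask]
                local += len(sp_in_g) * T
            return cols, local, corr
        raise ValueError(f"unknown effect {name!r}")

    # ------------------------------------------------------------------
    # parameter packing
    def _unpack(self, theta: np.ndarray):
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError(f"theta must have length {self.n_params} ({self.param_names})")
        beta0 = theta[0]
        variances = {e.name: np.exp(theta[e.var_param]) for e in self.effects}
        rates = {
            e.name: np.exp(theta[e.rate_param])
            for e in self.effects
            if e.rate_param is not None
        }
        return beta0, variances, rates

    def start_params(self, jitter: float = 0.0, rng: np.random.Generator | None = None):
        """Data-driven starting values on the unconstrained scale.

        beta0 from the log grand mean count; the method-of-moments
        variance of log(count+1) split evenly across the included
        components; decay rates at 1/(median positive lag).
        """
        theta = np.empty(self.n_params)
        theta[0] = np.log(max(self.y.mean(), 1e-3))
        v = max(float(np.var(np.log(self.y + 1.0))), 0.05)
        for e in self.effects:
            theta[e.var_param] = np.log(v / len(self.effects))
        lags = np.concatenate([D[np.triu_indices(D.shape[0], 1)] for D in self._group_lags])
        med = np.median(lags[lags > 0]) if np.any(lags > 0) else 1.0
        for i in range(1 + len(self.effects), self.n_params):
            theta[i] = np.log(1.0 / med)
        if jitter > 0:
            rng = rng if rng is not None else np.random.default_rng()
            theta = theta + rng.uniform(-jitter, jitter, size=self.n_params)
            theta[0] = np.log(max(self.y.mean(), 1e-3))  # keep the intercept anchored
        return theta

    # ------------------------------------------------------------------
    # precision matrix of the random effects
    def _precision_parts(self, variances: dict, rates: dict):
        """Per-effect precision blocks and logdet of the covariance."""
        logdet_sigma = 0.0
        parts = []  # (effect, list of (block, Rinv) or None)
        for e in self.effects:
            s2 = variances[e.name]
            logdet_sigma += e.size * np.log(s2)
            if e.corr is None:
                parts.append((e, None))
                continue
            rate = rates[e.name]
            mats = []
            for block in e.corr:
                R, Rinv, logdetR = _corr_matrices(block, rate)
                logdet_sigma += block.reps * logdetR
                mats.append((block, R, Rinv))
            parts.append((e, mats))
        return parts, logdet_sigma

    def _precision_dense(self, parts, variances):
        Q = np.zeros((self.q, self.q))
        for e, mats in parts:
            inv_s2 = 1.0 / variances[e.name]
            if mats is None:
                idx = np.arange(e.offset, e.offset + e.size)
                Q[idx, idx] = inv_s2
                continue
            for block, _R, Rinv in mats:
                P = Rinv * inv_s2
                idx = block.idx
                Q[idx[:, :, None], idx[:, None, :]] = P[None, :, :]
        return Q

    def _precision_sparse(self, parts, variances):
        blocks = []
        for e, mats in parts:
            inv_s2 = 1.0 / variances[e.name]
            if mats is None:
                blocks.append(sp.identity(e.size, format="csr") * inv_s2)
                continue
            for block, _R, Rinv in mats:
                P = sp.csr_matrix(Rinv * inv_s2)
                P.eliminate_zeros()
                blocks.append(sp.kron(sp.identity(block.reps, format="csr"), P, format="csr"))
        return sp.block_diag(blocks, format="csc")

    # ------------------------------------------------------------------
    # inner Laplace mode search
    def _inner_newton(self, beta0, Q, b0, tol=None, max_iter=100):
        if tol is None:
            tol = getattr(self, "_inner_tol", 1e-8)
        y, Z = self.y, self.Z
        dense = self._dense
        Qd = Q if dense else None
        b = b0.copy()

        def joint(b):
            eta = beta0 + (self._Zb(b) if dense else Z @ b)
            eta = np.clip(eta, -700, 700)
            mu = np.exp(eta)
            quad = b @ (Qd @ b) if dense else b @ (Q @ b)
            return float(y @ eta - mu.sum() - 0.5 * quad), eta, mu

        f, eta, mu = joint(b)
        trace = []
        for it in range(max_iter):
            resid = y - mu
            grad = (self._Zt(resid) if dense else Z.T @ resid) - (Q @ b)
            gnorm = np.max(np.abs(grad))
            trace.append((it, f, gnorm))
            if gnorm < tol:
                break
            if dense:
                H = self._ZtWZ(mu) + Q
                try:
                    c = sla.cho_factor(H, lower=True, check_finite=False)
                    step = sla.cho_solve(c, grad, check_finite=False)
                except sla.LinAlgError:
                    step = np.linalg.solve(H + 1e-8 * np.eye(self.q), grad)
            else:
                W = sp.diags(mu)
                H = (Z.T @ W @ Z + Q).tocsc()
                step = _splu_sym(H).solve(grad)
            # backtracking line search guaranteeing monotone ascent
            # (up to floating-point noise in the joint objective)
            f_tol = 1e-9 * (1.0 + abs(f))
            alpha, ok = 1.0, False
            for _ in range(40):
                f_new, eta_new, mu_new = joint(b + alpha * step)
                if np.isfinite(f_new) and f_new >= f - f_tol:
                    ok = True
                    break
                alpha *= 0.5
            if not ok:
                raise InnerNewtonError("inner Newton line search failed", trace)
            b = b + alpha * step
            f, eta, mu = f_new, eta_new, mu_new
            if alpha * np.max(np.abs(step)) < 1e-11:
                break  # step at numerical resolution; gradient is noise-level
        else:
            raise InnerNewtonError(
                f"inner Newton did not reach gradient norm {tol} in {max_iter} iterations",
                trace,
            )
        return b, f, eta, mu

    def _hessian_logdet(self, mu, Q):
        if self._dense:
            H = self._ZtWZ(mu) + Q
            c = sla.cho_factor(H, lower=True, check_finite=False)
            return H, c, 2.0 * np.sum(np.log(np.diag(c[0])))
        W = sp.diags(mu)
        H = (self.Z.T @ W @ self.Z + Q).tocsc()
        lu = _splu_sym(H)
        return H, lu, float(np.sum(np.log(np.abs(lu.U.diagonal()))))

    # ------------------------------------------------------------------
    # marginal negative log likelihood (Laplace)
    def nll(self, theta: np.ndarray) -> float:
        """Laplace-approximated negative marginal log likelihood."""
        return self._nll_impl(theta, want_grad=False)[0]

    def nll_and_grad(self, theta: np.ndarray):
        """NLL with its analytic gradient (dense path only)."""
        if not self._dense:
            raise NotImplementedError("analytic gradient requires the dense path")
        return self._nll_impl(theta, want_grad=True)

    def _nll_impl(self, theta, want_grad: bool):
        beta0, variances, rates = self._unpack(theta)
        parts, logdet_sigma = self._precision_parts(variances, rates)
        Q = (
            self._precision_dense(parts, variances)
            if self._dense
            else self._precision_sparse(parts, variances)
        )
        b0 = (
            self._b_cache
            if self._b_cache is not None and self._b_cache.shape == (self.q,)
            else np.zeros(self.q)
        )
        b, f_joint, eta, mu = self._inner_newton(beta0, Q, b0)
        self._b_cache = b
        H, fac, logdet_H = self._hessian_logdet(mu, Q)

        quad = b @ (Q @ b)
        loglik_y = self.y @ eta - mu.sum() - self._loggamma_y
        nll = -(loglik_y) + 0.5 * quad + 0.5 * logdet_sigma + 0.5 * logdet_H
        if not want_grad:
            return float(nll), None

        # analytic gradient: envelope terms plus the movement of the mode
        # propagated through the log-determinant correction
        y = self.y
        Ainv, info = dpotri(fac[0], lower=True)
        if info != 0:
            raise np.linalg.LinAlgError("dpotri failed on the Laplace Hessian")
        A = np.tril(Ainv) + np.tril(Ainv, -1).T
        d = self._diag_ZAZt(A)
        s = d * mu
        gb = 0.5 * self._Zt(s)
        Agb = A @ gb

        grad = np.zeros(self.n_params)
        grad[0] = (mu.sum() - y.sum()) + 0.5 * s.sum() + Agb @ (-self._Zt(mu))

        for e, mats in parts:
            sl = slice(e.offset, e.offset + e.size)
            Qe_b = Q[sl, sl] @ b[sl]
            direct = (
                -0.5 * b[sl] @ Qe_b
                + 0.5 * e.size
                - 0.5 * np.sum(A[sl, sl] * Q[sl, sl])
            )
            dF = np.zeros(self.q)
            dF[sl] = Qe_b
            grad[e.var_param] += direct + Agb @ dF

            if mats is None or e.rate_param is None:
                continue
            rate = rates[e.name]
            inv_s2 = 1.0 / variances[e.name]
            acc = 0.0
            dF = np.zeros(self.q)
            for block, R, Rinv in mats:
                X = (rate * block.D) * R  # = -dR/dlog(rate)
                M = inv_s2 * (Rinv @ X @ Rinv)  # dQ_block/dlog(rate)
                acc += 0.5 * block.reps * np.sum(Rinv * (-X))  # d logdet Sigma
                idx = block.idx
                B = b[idx]  # (reps, T)
                MB = B @ M  # M symmetric
                acc += 0.5 * np.sum(B * MB)
                acc += 0.5 * np.sum(A[idx[:, :, None], idx[:, None, :]] * M[None, :, :])
                dF[idx] = dF[idx] - MB
            grad[e.rate_param] += acc + Agb @ dF
        return float(nll), grad

    # ------------------------------------------------------------------
    def fit(
        self,
        start_params: np.ndarray | None = None,
        n_starts: int = 3,
        seed: int | None = None,
        ftol: float = 1e-9,
        inner_tol: float = 1e-8,
        maxiter: int = 500,
    ) -> "DynamicSADResults":
        """Maximise the Laplace marginal likelihood.

        Runs ``n_starts`` quasi-Newton optimisations (the first from
        :meth:`start_params` or ``start_params`` if given, the rest
        jittered by up to +/-50% on the variance scale) and keeps the best
        converged fit.
        """
        rng = np.random.default_rng(seed)
        self._inner_tol = inner_tol
        bounds = [(-30.0, 30.0)]
        for name in self.param_names[1:]:
            bounds.append((-20.0, 6.0) if name.startswith("log_sigma2") else (np.log(1e-4), np.log(100.0)))

        use_grad = self._dense
        fun = self.nll_and_grad if use_grad else self.nll

        attempts = []
        for k in range(max(n_starts, 1)):
            if k == 0 and start_params is not None:
                theta0 = np.asarray(start_params, dtype=float)
            else:
                theta0 = self.start_params(jitter=0.0 if k == 0 else np.log(1.5), rng=rng)
            self._b_cache = None
            try:
                options = {"ftol": ftol, "maxiter": maxiter, "maxcor": 25}
                if not use_grad:
                    # finite-difference step must sit above the noise floor
                    # of the inner Newton (gradient tolerance 1e-8)
                    options["eps"] = 1e-5
                opt = minimize(
                    fun,
                    theta0,
                    jac=use_grad,
                    method="L-BFGS-B",
                    bounds=bounds,
                    options=options,
                )
                attempts.append(opt)
            except (InnerNewtonError, np.linalg.LinAlgError) as err:
                attempts.append(err)
        converged = [o for o in attempts if not isinstance(o, Exception) and np.isfinite(o.fun)]
        if not converged:
            raise RuntimeError(f"no start converged; traces: {attempts}")
        best = min(converged, key=lambda o: o.fun)

        # conditional modes at the optimum
        beta0, variances, rates = self._unpack(best.x)
        parts, _ = self._precision_parts(variances, rates)
        Q = (
            self._precision_dense(parts, variances)
            if self._dense
            else self._precision_sparse(parts, variances)
        )
        self._b_cache = None
        b, _, _, _ = self._inner_newton(beta0, Q, np.zeros(self.q))
        re_modes = {
            e.name: b[e.offset : e.offset + e.size].copy() for e in self.effects
        }
        return DynamicSADResults(
            model=self,
            theta=best.x.copy(),
            loglik=-float(best.fun),
            re_modes=re_modes,
            converged=bool(getattr(best, "success", False)),
            optimizer=dict(
                message=str(getattr(best, "message", "")),
                nit=int(getattr(best, "nit", -1)),
                n_starts=len(attempts),
                n_converged=len(converged),
            ),
        )

    # ------------------------------------------------------------------
    def simulate(self, params: VarianceComponents, seed: int) -> CommunityTable:
        """Draw a replicate data set from the model at the given parameters.

        Random effects are sampled from N(0, Sigma(params)), the linear
        predictor is assembled on the original observation grid and counts
        are Poisson(exp(eta)) -- the generator of the parametric bootstrap.
        """
        counts = self.simulate_counts(params, seed)
        df = self.table.data.copy()
        df["count"] = counts
        return CommunityTable(df, self.table.locations)

    def simulate_counts(self, params: VarianceComponents, seed: int) -> np.ndarray:
        """Counts of one parametric draw, aligned with the observation rows."""
        rng = np.random.default_rng(seed)
        theta = self.params_to_theta(params)
        beta0, variances, rates = self._unpack(theta)
        b = np.zeros(self.q)
        for e in self.effects:
            sd = np.sqrt(variances[e.name])
            if e.corr is None:
                b[e.offset : e.offset + e.size] = sd * rng.standard_normal(e.size)
                continue
            rate = rates[e.name]
            for block in e.corr:
                R = np.exp(-rate * block.D)
                try:
                    L = np.linalg.cholesky(R)
                except np.linalg.LinAlgError as err:
                    raise np.linalg.LinAlgError(
                        "estimated correlation matrix is not positive definite"
                    ) from err
                z = rng.standard_normal((block.reps, block.T))
                vals = sd * (z @ L.T)
                b[block.offset : block.offset + block.size] = vals.ravel()
        eta = beta0 + self.Z @ b
        return rng.poisson(np.exp(np.clip(eta, -700, 700)))

    def clone_with_counts(self, counts: np.ndarray) -> "DynamicSADModel":
        """Shallow copy sharing the design but carrying new counts.

        The observation grid, random-effect design and parameterisation
        are reused; only the response changes.  This is what the
        parametric bootstrap uses to avoid rebuilding the design for
        every replicate.
        """
        counts = np.asarray(counts)
        if counts.shape != self.y.shape or np.any(counts < 0):
            raise ValueError("counts must be nonnegative with the original shape")
        import copy

        new = copy.copy(self)
        new.y = counts.astype(np.int64)
        new._loggamma_y = float(np.sum(gammaln(new.y + 1.0)))
        new._b_cache = None
        df = self.table.data.copy()
        df["count"] = new.y
        new.table = CommunityTable(df, self.table.locations)
        return new

    def params_to_theta(self, params: VarianceComponents) -> np.ndarray:
        """Pack a :class:`VarianceComponents` into the model's theta vector."""
        theta = np.zeros(self.n_params)
        theta[0] = params.beta0
        values = {
            "among_species": params.sigma2_h,
            "species_by_unit_correlated": params.sigma2_e,
            "common_unit_correlated": params.sigma2_c,
            "observation_level": params.sigma2_o,
            "sampling_unit_iid": params.sigma2_u,
        }
        for e in self.effects:
            theta[e.var_param] = np.log(max(values[e.name], 1e-12))
            if e.rate_param is not None:
                rate = params.gamma if e.name == "species_by_unit_correlated" else params.rate_c
                theta[e.rate_param] = np.log(rate)
        return theta

    def design_info(self) -> dict:
        """Sizes of the random-effect blocks (diagnostic)."""
        return {e.name: e.size for e in self.effects}


class DynamicSADResults:
    """Fit results: estimates, likelihood, conditional modes, diagnostics."""

    def __init__(self, model, theta, loglik, re_modes, converged, optimizer):
        self.model = model
        self.theta = theta
        self.loglik = loglik
        self.re_modes = re_modes
        self.converged = converged
        self.optimizer = optimizer
        self.nobs = model.nobs

    # -- estimates on the natural scale --------------------------------
    @property
    def estimates(self) -> dict:
        beta0, variances, rates = self.model._unpack(self.theta)
        out = {"beta0": float(beta0)}
        for e in self.model.effects:
            out[_EFFECT_VAR[e.name]] = float(variances[e.name])
        if "species_by_unit_correlated" in rates:
            out["gamma"] = float(rates["species_by_unit_correlated"])
        if "common_unit_correlated" in rates:
            key = "gamma_c"
            out[key] = float(rates["common_unit_correlated"])
        return out

    @property
    def params(self) -> VarianceComponents:
        est = self.estimates
        gamma = est.get("gamma", est.get("gamma_c", 1.0))
        gamma_c = est.get("gamma_c")
        return VarianceComponents(
            beta0=est["beta0"],
            sigma2_h=est.get("sigma2_h", 0.0),
            sigma2_e=est.get("sigma2_e", 0.0),
            sigma2_c=est.get("sigma2_c", 0.0),
            sigma2_o=est.get("sigma2_o", 0.0),
            sigma2_u=est.get("sigma2_u", 0.0),
            gamma=gamma,
            gamma_c=gamma_c,
            dimension=self.model.spec.dimension,
        )

    # -- derived quantities ---------------------------------------------
    def to_population_params(self, nu: float = 1.0):
        from .params import to_population_params

        return to_population_params(self.params, nu=nu)

    def variance_proportions(self):
        from .params import variance_proportions

        return variance_proportions(self.params)

    def similarity_relative(self, u):
        from .params import similarity_relative

        return similarity_relative(self.params, u)

    def similarity_mean(self, v):
        from .params import similarity_mean

        return similarity_mean(self.params, v)

    def simulate(self, seed: int) -> CommunityTable:
        """Parametric draw from the fitted model on the original grid."""
        return self.model.simulate(self.params, seed=seed)

    def bootstrap(self, n_reps: int = 1000, level: float = 0.95, seed: int = 0, **kw):
        from .bootstrap import parametric_bootstrap

        return parametric_bootstrap(self, n_reps=n_reps, level=level, seed=seed, **kw)

    # -- diagnostics -----------------------------------------------------
    def diagnostics(self, rate_span: float = 10.0, flat_tol: float = 0.05) -> dict:
        """Boundary, identifiability and small-level-count warnings.

        Flags variance components within numerical distance of zero,
        decay rates whose likelihood is flat over a ``rate_span``-fold
        range, and correlated effects estimated from few units.
        """
        report: dict = {"boundary": [], "flat_rate": [], "few_levels": []}
        est = self.estimates
        for key, val in est.items():
            if key.startswith("sigma2") and val < _BOUND_TOL:
                report["boundary"].append(key)
        model = self.model
        for name in ("gamma", "gamma_c"):
            idx = None
            for e in model.effects:
                if e.rate_param is None:
                    continue
                pname = model.param_names[e.rate_param]
                if pname == "log_" + name:
                    idx = e.rate_param
            if idx is None:
                continue
            base = model.nll(self.theta)
            span = np.log(np.sqrt(rate_span))
            deltas = []
            for shift in (-span, span):
                th = self.theta.copy()
                th[idx] += shift
                try:
                    deltas.append(abs(model.nll(th) - base))
                except (InnerNewtonError, np.linalg.LinAlgError):
                    deltas.append(np.inf)
            if max(deltas) < flat_tol:
                report["flat_rate"].append(name)
        n_units_min = min(len(u) for u in model._group_units)
        if n_units_min <= 4:
            for e in model.effects:
                if e.corr is not None:
                    report["few_levels"].append(
                        f"{_EFFECT_VAR[e.name]} estimated from only {n_units_min} "
                        "units per group; decay-rate uncertainty will be large"
                    )
        return report

    # -- presentation ----------------------------------------------------
    def summary(self, nu: float = 1.0) -> str:
        est = self.estimates
        spec = self.model.spec
        lines = [
            "Dynamic species abundance distribution GLMM (Poisson, Laplace)",
            "=" * 64,
            f"dimension: {spec.dimension}    observations: {self.nobs}",
            f"species: {self.model.n_species}    units: {self.model.n_units}"
            f"    groups: {self.model.n_groups}",
            f"log-likelihood: {self.loglik:.3f}    converged: {self.converged}",
            "-" * 64,
            f"{'parameter':<14}{'estimate':>12}",
        ]
        for k, v in est.items():
            lines.append(f"{k:<14}{v:>12.4f}")
        rate_label = "years" if spec.dimension == "temporal" else "km"
        if "gamma" in est:
            lines.append(f"{'1/gamma':<14}{1.0 / est['gamma']:>12.2f}  ({rate_label})")
        if "gamma_c" in est:
            lines.append(f"{'1/gamma_c':<14}{1.0 / est['gamma_c']:>12.2f}  ({rate_label})")
        lines.append("-" * 64)
        props = self.variance_proportions()
        ss = props["species_specific"]
        lines.append(
            "relative log abundance variance split: "
            + ", ".join(f"{k} {100 * v:.0f}%" for k, v in ss.items() if v > 0 or k != "sigma2_o")
        )
        if "general" in props:
            lines.append(
                "mean log abundance variance split:     "
                + ", ".join(f"{k} {100 * v:.0f}%" for k, v in props["general"].items())
            )
        pp = self.to_population_params(nu=nu)
        lines.append(
            f"population scale (nu={nu}): logK={pp.logK:.2f}, "
            f"sigma2_r={pp.sigma2_r:.4f}, sigma2_s={pp.sigma2_s:.4f}, "
            f"sigma2_E={pp.sigma2_E:.4f}"
        )
        return "\n".join(lines)

    def save(self, path: str | Path, seed: int | None = None) -> None:
        payload = {
            "estimates": self.estimates,
            "loglik": self.loglik,
            "converged": self.converged,
            "optimizer": self.optimizer,
            "spec": {
                "dimension": self.model.spec.dimension,
                "effects": list(self.model.spec.effects),
                "separate_common_rate": self.model.spec.separate_common_rate,
            },
            "n_obs": self.nobs,
            "n_species": self.model.n_species,
            "n_units": self.model.n_units,
            "n_groups": self.model.n_groups,
            "seed": seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))
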