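"""Joint Gaussian model for a bivariate areal outcome and a misaligned areal covariate.

The model treats both data sources as aggregates of one spatially continuous,
zero-mean Gaussian process U(x) with exponential covariance
``Cov{U(x), U(x')} = tau^2 exp(-||x - x'||/delta)``.  With Y_ij the outcome for
group i in coarse unit j and Z_k the covariate in fine unit k,

    Y_ij = alpha_i + beta_i * Ubar_j + T_ij          (i = 1, 2)
    Z_k  = gamma + Ubar*_k + V_k

where Ubar_j and Ubar*_k are the polygon averages of U over the coarse and
fine units, V_k ~ N(0, nu^2) i.i.d., and (T_1j, T_2j) i.i.d. bivariate normal
with covariance Omega = [[omega1^2, omega12], [omega12, omega2^2]].

Everything observed is jointly Gaussian, so the exact likelihood is available;
it is evaluated through the factorisation
``[Y1, Y2, Z] = [Y1, Y2 | Z] [Z]`` and maximised numerically over an
unconstrained parameterisation (variances as logs, the cross-group correlation
through atanh).  The intercepts (alpha_1, alpha_2, gamma) are profiled out by
generalised least squares at each covariance-parameter evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .geometry import (
    AreaUnit,
    FactorTable,
    QuadratureGrid,
    add_jitter,
)

__all__ = [
    "ModelParams",
    "MisalignedData",
    "FittedModel",
    "LRTestResult",
    "exp_cov",
    "build_joint_covariance",
    "log_likelihood",
    "fit_mle",
    "variance_explained",
    "cross_group_correlation",
    "practical_range",
    "lr_test",
    "fit_report_table",
]

FULL = "full"
NO_COVARIATE = "no_covariate"

#: transformed-scale parameter names, Table-style reporting order
PARAM_NAMES_FULL = [
    "alpha_1",
    "alpha_2",
    "beta_1",
    "beta_2",
    "log_omega1_sq",
    "log_omega2_sq",
    "atanh_rho",
    "gamma",
    "log_tau2",
    "log_delta",
    "log_nu2",
]
PARAM_NAMES_REDUCED = [p for p in PARAM_NAMES_FULL if not p.startswith("beta")]


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ModelParams:
    """Full parameter vector of the joint model.

    alpha : (2,) intercepts of the outcome (outcome units, e.g. years)
    beta : (2,) regression coefficients on the latent spatial process
    gamma : covariate intercept
    tau2 : variance of the spatial process U (covariate-scale variance)
    delta : exponential-correlation scale parameter, metres
    nu2 : covariate nugget variance
    omega : (2, 2) covariance of the outcome noise pair (T_1j, T_2j)
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma: float
    tau2: float
    delta: float
    nu2: float
    omega: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float))
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "omega", np.asarray(self.omega, dtype=float))
        if self.alpha.shape != (2,) or self.beta.shape != (2,):
            raise ModelError("alpha and beta must each have two entries")
        if self.omega.shape != (2, 2) or not np.allclose(
            self.omega, self.omega.T
        ):
            raise ModelError("omega must be a symmetric 2x2 matrix")
        for name in ("tau2", "delta", "nu2"):
            if not getattr(self, name) > 0:
                raise ModelError(f"{name} must be positive")
        w1, w2 = self.omega[0, 0], self.omega[1, 1]
        if not (w1 > 0 and w2 > 0 and self.omega[0, 1] ** 2 < w1 * w2):
            raise ModelError("omega must be positive definite")

    @property
    def rho(self) -> float:
        """Cross-group noise correlation omega12 / (omega1 omega2)."""
        return float(self.omega[0, 1] / np.sqrt(self.omega[0, 0] * self.omega[1, 1]))

    # --- unconstrained transformed vector --------------------------------
    def to_vector(self, variant: str = FULL) -> np.ndarray:
        vals = {
            "alpha_1": self.alpha[0],
            "alpha_2": self.alpha[1],
            "beta_1": self.beta[0],
            "beta_2": self.beta[1],
            "log_omega1_sq": np.log(self.omega[0, 0]),
            "log_omega2_sq": np.log(self.omega[1, 1]),
            "atanh_rho": np.arctanh(np.clip(self.rho, -1 + 1e-12, 1 - 1e-12)),
            "gamma": self.gamma,
            "log_tau2": np.log(self.tau2),
            "log_delta": np.log(self.delta),
            "log_nu2": np.log(self.nu2),
        }
        names = PARAM_NAMES_FULL if variant == FULL else PARAM_NAMES_REDUCED
        return np.array([vals[k] for k in names])

    @staticmethod
    def from_vector(t: np.ndarray, variant: str = FULL) -> "ModelParams":
        names = PARAM_NAMES_FULL if variant == FULL else PARAM_NAMES_REDUCED
        d = dict(zip(names, np.asarray(t, dtype=float)))
        w1 = np.exp(d["log_omega1_sq"])
        w2 = np.exp(d["log_omega2_sq"])
        rho = np.tanh(d["atanh_rho"])
        w12 = rho * np.sqrt(w1 * w2)
        beta = np.array([d.get("beta_1", 0.0), d.get("beta_2", 0.0)])
        return ModelParams(
            alpha=np.array([d["alpha_1"], d["alpha_2"]]),
            beta=beta,
            gamma=d["gamma"],
            tau2=np.exp(d["log_tau2"]),
            delta=np.exp(d["log_delta"]),
            nu2=np.exp(d["log_nu2"]),
            omega=np.array([[w1, w12], [w12, w2]]),
        )


@dataclass
class MisalignedData:
    """Outcome over the coarse partition, covariate over the fine partition."""

    coarse_units: list[AreaUnit]
    fine_units: list[AreaUnit]
    outcome: np.ndarray  # (n, 2)
    covariate: np.ndarray  # (m,)

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome, dtype=float)
        self.covariate = np.asarray(self.covariate, dtype=float)
        n, m = len(self.coarse_units), len(self.fine_units)
        if self.outcome.shape != (n, 2):
            raise ModelError(
                f"outcome must be ({n}, 2) to match the coarse units, "
                f"got {self.outcome.shape}"
            )
        if self.covariate.shape != (m,):
            raise ModelError(
                f"covariate must have length {m} to match the fine units, "
                f"got {self.covariate.shape}"
            )
        if not np.all(np.isfinite(self.outcome)) or not np.all(
            np.isfinite(self.covariate)
        ):
            raise ModelError("missing or non-finite values are not supported")

    @property
    def n(self) -> int:
        return len(self.coarse_units)

    @property
    def m(self) -> int:
        return len(self.fine_units)

    def stacked(self) -> np.ndarray:
        """Observation vector (Y_1, Y_2, Z) of length 2n + m."""
        return np.concatenate(
            [self.outcome[:, 0], self.outcome[:, 1], self.covariate]
        )


def exp_cov(distance, tau2: float, delta: float):
    """Exponential covariance tau^2 exp(-distance/delta); vectorised."""
    distance = np.asarray(distance, dtype=float)
    if np.any(distance < 0):
        raise ModelError("distance must be non-negative")
    if not (tau2 > 0 and delta > 0):
        raise ModelError("tau2 and delta must be positive")
    out = tau2 * np.exp(-distance / delta)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# covariance assembly and likelihood
# ---------------------------------------------------------------------------


def _cov_blocks(params: ModelParams, factors: FactorTable):
    """Sigma_coarse, Sigma_fine and coarse-fine cross factors scaled by tau2."""
    S_cc = params.tau2 * factors.f_cc(params.delta)
    S_ff = params.tau2 * factors.f_ff(params.delta)
    S_cf = params.tau2 * factors.f_cf(params.delta)
    return S_cc, S_ff, S_cf


def _assemble_joint(params: ModelParams, factors: FactorTable) -> np.ndarray:
    """(2n + m) covariance of the stacked observations (Y1, Y2, Z)."""
    n, m = factors.n, factors.m
    S_cc, S_ff, S_cf = _cov_blocks(params, factors)
    b1, b2 = params.beta
    I_n = np.eye(n)
    top = [
        b1 * b1 * S_cc + params.omega[0, 0] * I_n,
        b1 * b2 * S_cc + params.omega[0, 1] * I_n,
        b1 * S_cf,
    ]
    mid = [
        top[1].T,
        b2 * b2 * S_cc + params.omega[1, 1] * I_n,
        b2 * S_cf,
    ]
    bot = [top[2].T, mid[2].T, S_ff + params.nu2 * np.eye(m)]
    return np.block([top, mid, bot])


def _mean_vector(params: ModelParams, n: int, m: int) -> np.ndarray:
    return np.concatenate(
        [
            np.full(n, params.alpha[0]),
            np.full(n, params.alpha[1]),
            np.full(m, params.gamma),
        ]
    )


def build_joint_covariance(
    params: ModelParams,
    data: MisalignedData,
    grid: QuadratureGrid,
    factors: FactorTable | None = None,
    jitter: bool = True,
) -> np.ndarray:
    """Joint covariance matrix of (Y_1, Y_2, Z), with stabilising jitter.

    Raises
    ------
    ModelError
        If the jittered matrix is not positive definite (reports the smallest
        eigenvalue).
    """
    if factors is None:
        factors = FactorTable(data.coarse_units, data.fine_units, grid)
    S = _assemble_joint(params, factors)
    if jitter:
        S = add_jitter(S)
        try:
            cho_factor(S, lower=True)
        except np.linalg.LinAlgError:
            ev = float(np.linalg.eigvalsh(S)[0])
            raise ModelError(
                f"joint covariance not positive definite after jitter "
                f"(smallest eigenvalue {ev:.3e})"
            )
    return S


def _gauss_logpdf(resid: np.ndarray, cov: np.ndarray) -> float:
    c, low = cho_factor(add_jitter(cov), lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    quad = float(resid @ cho_solve((c, low), resid))
    k = len(resid)
    return -0.5 * (k * np.log(2.0 * np.pi) + logdet + quad)


def log_likelihood(
    params: ModelParams,
    data: MisalignedData,
    grid: QuadratureGrid,
    factors: FactorTable | None = None,
) -> float:
    """Exact Gaussian log-likelihood via the [Y1, Y2 | Z] [Z] factorisation.

    Numerically equal (to ~1e-6 relative) to the log-density of the stacked
    joint Gaussian over (Y_1, Y_2, Z).
    """
    if factors is None:
        factors = FactorTable(data.coarse_units, data.fine_units, grid)
    n, m = factors.n, factors.m
    if data.n != n or data.m != m:
        raise ModelError("data dimensions do not match the factor table")
    S_cc, S_ff, S_cf = _cov_blocks(params, factors)
    b1, b2 = params.beta

    # marginal of the covariate
    Sz = add_jitter(S_ff + params.nu2 * np.eye(m))
    rz = data.covariate - params.gamma
    cz, lowz = cho_factor(Sz, lower=True)
    logdet_z = 2.0 * float(np.sum(np.log(np.diag(cz))))
    alpha_z = cho_solve((cz, lowz), rz)
    ll_z = -0.5 * (m * np.log(2 * np.pi) + logdet_z + float(rz @ alpha_z))

    # conditional of the outcome given the covariate
    C = np.vstack([b1 * S_cf, b2 * S_cf])  # (2n, m) cross-covariance
    I_n = np.eye(n)
    S_y = np.block(
        [
            [b1 * b1 * S_cc + params.omega[0, 0] * I_n,
             b1 * b2 * S_cc + params.omega[0, 1] * I_n],
            [b1 * b2 * S_cc + params.omega[0, 1] * I_n,
             b2 * b2 * S_cc + params.omega[1, 1] * I_n],
        ]
    )
    y = np.concatenate([data.outcome[:, 0], data.outcome[:, 1]])
    mu_y = np.concatenate([np.full(n, params.alpha[0]), np.full(n, params.alpha[1])])
    cond_mean = mu_y + C @ alpha_z
    cond_cov = S_y - C @ cho_solve((cz, lowz), C.T)
    ll_y = _gauss_logpdf(y - cond_mean, cond_cov)
    return ll_y + ll_z


# ---------------------------------------------------------------------------
# maximum likelihood
# ---------------------------------------------------------------------------

_MEAN_PARAMS = ("alpha_1", "alpha_2", "gamma")


def _design(n: int, m: int) -> np.ndarray:
    X = np.zeros((2 * n + m, 3))
    X[:n, 0] = 1.0
    X[n : 2 * n, 1] = 1.0
    X[2 * n :, 2] = 1.0
    return X


def _profile_nll_factory(data: MisalignedData, factors: FactorTable, variant: str):
    """Negative log-likelihood over covariance parameters, intercepts profiled.

    The intercepts (alpha_1, alpha_2, gamma) enter only the mean, so at each
    covariance evaluation their GLS estimate is exact and the profile value
    equals the fully maximised likelihood over the mean.
    """
    n, m = data.n, data.m
    z = data.stacked()
    X = _design(n, m)
    cov_names = [p for p in (PARAM_NAMES_FULL if variant == FULL else PARAM_NAMES_REDUCED)
                 if p not in _MEAN_PARAMS]

    def phi_to_params(phi: np.ndarray, mean: np.ndarray | None = None) -> ModelParams:
        d = dict(zip(cov_names, phi))
        full = {
            "alpha_1": 0.0 if mean is None else mean[0],
            "alpha_2": 0.0 if mean is None else mean[1],
            "gamma": 0.0 if mean is None else mean[2],
            **d,
        }
        names = PARAM_NAMES_FULL if variant == FULL else PARAM_NAMES_REDUCED
        return ModelParams.from_vector(np.array([full[k] for k in names]), variant)

    def nll(phi: np.ndarray) -> float:
        try:
            params = phi_to_params(phi)
            S = add_jitter(_assemble_joint(params, factors))
            c, low = cho_factor(S, lower=True)
        except (np.linalg.LinAlgError, FloatingPointError, ModelError):
            return 1e12
        logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
        Sinv_X = cho_solve((c, low), X)
        XtSX = X.T @ Sinv_X
        mu = np.linalg.solve(XtSX, Sinv_X.T @ z)
        r = z - X @ mu
        quad = float(r @ cho_solve((c, low), r))
        val = 0.5 * (len(z) * np.log(2 * np.pi) + logdet + quad)
        return val if np.isfinite(val) else 1e12

    def gls_mean(phi: np.ndarray) -> np.ndarray:
        params = phi_to_params(phi)
        S = add_jitter(_assemble_joint(params, factors))
        c, low = cho_factor(S, lower=True)
        Sinv_X = cho_solve((c, low), X)
        return np.linalg.solve(X.T @ Sinv_X, Sinv_X.T @ z)

    return nll, gls_mean, phi_to_params, cov_names


def _mom_init(data: MisalignedData, grid: QuadratureGrid, variant: str) -> ModelParams:
    """Method-of-moments starting values.

    gamma and alpha from sample means, an even variance split of the covariate
    between tau^2 and nu^2, delta at a quarter of the domain diameter, beta and
    the outcome-noise covariance from OLS of the outcome on the coarse-averaged
    covariate (averaged through the shared quadrature points).
    """
    cov = data.covariate
    if np.std(cov) == 0:
        raise ModelError("constant covariate: beta is unidentifiable")
    gamma0 = float(np.mean(cov))
    alpha0 = data.outcome.mean(axis=0)
    s2 = float(np.var(cov, ddof=1))
    bounds = grid.points.min(axis=0), grid.points.max(axis=0)
    diam = float(np.hypot(*(bounds[1] - bounds[0])))
    delta0 = max(diam / 4.0, grid.spacing)

    # coarse-averaged covariate via shared quadrature points
    lc = grid.labels(data.coarse_units)
    lf = grid.labels(data.fine_units)
    both = (lc >= 0) & (lf >= 0)
    x_coarse = np.full(data.n, gamma0)
    for j in range(data.n):
        sel = both & (lc == j)
        if sel.any():
            x_coarse[j] = float(np.mean(cov[lf[sel]]))
    xc = x_coarse - x_coarse.mean()
    denom = float(xc @ xc)
    resid = np.empty_like(data.outcome)
    beta0 = np.zeros(2)
    for i in range(2):
        yi = data.outcome[:, i]
        b = float(xc @ (yi - yi.mean()) / denom) if denom > 0 else 0.0
        if variant == NO_COVARIATE:
            b = 0.0
        beta0[i] = b
        resid[:, i] = yi - yi.mean() - b * xc
    om = np.cov(resid.T, ddof=1)
    w1 = max(float(om[0, 0]), 1e-3)
    w2 = max(float(om[1, 1]), 1e-3)
    rho = float(np.clip(om[0, 1] / np.sqrt(w1 * w2), -0.9, 0.9))
    return ModelParams(
        alpha=alpha0,
        beta=beta0,
        gamma=gamma0,
        tau2=max(s2 / 2, 1e-3),
        delta=delta0,
        nu2=max(s2 / 2, 1e-3),
        omega=np.array(
            [[w1, rho * np.sqrt(w1 * w2)], [rho * np.sqrt(w1 * w2), w2]]
        ),
    )


def _numerical_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian with per-coordinate relative steps."""
    k = len(x)
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        fpp = f(x + 2 * ei)
        fmm = f(x - 2 * ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / (4 * h[i] ** 2)
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            fp_p = f(x + ei + ej)
            fp_m = f(x + ei - ej)
            fm_p = f(x - ei + ej)
            fm_m = f(x - ei - ej)
            H[i, j] = H[j, i] = (fp_p - fp_m - fm_p + fm_m) / (4 * h[i] * h[j])
    return H


@dataclass
class FittedModel:
    """Maximum-likelihood fit with Wald intervals on the reporting scale."""

    params_hat: ModelParams
    loglik: float
    vcov: np.ndarray
    confint: pd.DataFrame
    convergence: dict
    model_variant: str
    param_names: list[str] = field(default_factory=list)

    def se(self, name: str) -> float:
        """Standard error of a transformed-scale parameter by name."""
        i = self.param_names.index(name)
        return float(np.sqrt(max(self.vcov[i, i], 0.0)))


def fit_mle(
    data: MisalignedData,
    grid: QuadratureGrid,
    variant: Literal["full", "no_covariate"] = FULL,
    init: ModelParams | None = None,
    options: dict | None = None,
) -> FittedModel:
    """Fit the joint model by maximum likelihood.

    Parameters are optimised on an unconstrained scale (variances as logs,
    cross-group correlation through atanh); intercepts are profiled out by
    GLS.  Wald 95% intervals come from the inverse observed information
    (finite-difference Hessian) on the transformed scale.

    Options (dict): ``n_starts`` (default 5) random multi-starts around the
    method-of-moments initialisation, ``seed`` for the start perturbations,
    ``ftol``/``maxiter`` passed to the optimiser, ``compute_ci`` (default
    True) to skip the Hessian, ``factors`` to reuse a prebuilt FactorTable.
    """
    opts = dict(options or {})
    if variant not in (FULL, NO_COVARIATE):
        raise ModelError(f"unknown variant {variant!r}")
    if data.n < 3 or data.m < 3:
        raise ModelError("at least 3 coarse and 3 fine units are required")
    if float(np.std(data.covariate)) == 0.0:
        raise ModelError("constant covariate: beta is unidentifiable")
    factors = opts.pop("factors", None) or FactorTable(
        data.coarse_units, data.fine_units, grid
    )
    nll, gls_mean, phi_to_params, cov_names = _profile_nll_factory(
        data, factors, variant
    )
    init_params = init if init is not None else _mom_init(data, grid, variant)
    t0 = init_params.to_vector(variant)
    names = PARAM_NAMES_FULL if variant == FULL else PARAM_NAMES_REDUCED
    cov_idx = [i for i, p in enumerate(names) if p not in _MEAN_PARAMS]
    phi0 = t0[cov_idx]

    # generous box constraints keep the optimiser off degenerate ridges
    diam = float(np.hypot(*(grid.points.max(axis=0) - grid.points.min(axis=0))))
    lb, ub = [], []
    for nm in cov_names:
        if nm == "log_delta":
            # ranges below the quadrature resolution are not identifiable
            lb.append(np.log(grid.spacing / 2))
            ub.append(np.log(diam * 20))
        elif nm.startswith("log_"):
            lb.append(-20.0)
            ub.append(30.0)
        elif nm == "atanh_rho":
            lb.append(-6.0)
            ub.append(6.0)
        else:  # beta
            lb.append(-1e4)
            ub.append(1e4)
    bounds = list(zip(lb, ub))

    n_starts = int(opts.pop("n_starts", 5))
    seed = opts.pop("seed", 0)
    ftol = float(opts.pop("ftol", 1e-9))
    maxiter = int(opts.pop("maxiter", 400))
    rng = np.random.default_rng(seed)
    starts = [phi0]
    for _ in range(max(0, n_starts - 1)):
        starts.append(np.clip(phi0 + rng.normal(0, 0.4, len(phi0)), lb, ub))

    best = None
    n_failed = 0
    for s in starts:
        res = optimize.minimize(
            nll,
            np.clip(s, lb, ub),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": ftol, "maxiter": maxiter},
        )
        if not np.isfinite(res.fun) or res.fun >= 1e12:
            n_failed += 1
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise ModelError(
            f"optimiser failed to converge from all {len(starts)} starts"
        )

    phi_hat = best.x
    mean_hat = gls_mean(phi_hat)
    params_hat = phi_to_params(phi_hat, mean_hat)
    loglik = float(log_likelihood(params_hat, data, grid, factors))
    t_hat = params_hat.to_vector(variant)

    vcov = np.full((len(names), len(names)), np.nan)
    ci = None
    if opts.pop("compute_ci", True):
        def full_nll(t):
            try:
                p = ModelParams.from_vector(t, variant)
                return -log_likelihood(p, data, grid, factors)
            except (ModelError, np.linalg.LinAlgError):
                return 1e12

        H = _numerical_hessian(full_nll, t_hat)
        try:
            vcov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            vcov = np.linalg.pinv(H)
        se = np.sqrt(np.clip(np.diag(vcov), 0.0, np.inf))
        zq = stats.norm.ppf(0.975)
        ci = pd.DataFrame(
            {
                "parameter": names,
                "estimate": t_hat,
                "ci_low": t_hat - zq * se,
                "ci_high": t_hat + zq * se,
            }
        )
        ci = _append_log_omega12(ci, params_hat, vcov, names, zq)
    else:
        ci = pd.DataFrame(
            {
                "parameter": names,
                "estimate": t_hat,
                "ci_low": np.nan,
                "ci_high": np.nan,
            }
        )

    convergence = {
        "success": bool(best.success),
        "nll": float(best.fun),
        "n_starts": len(starts),
        "n_failed_starts": n_failed,
        "message": str(best.message),
        "n_iter": int(best.nit),
    }
    return FittedModel(
        params_hat=params_hat,
        loglik=loglik,
        vcov=vcov,
        confint=ci,
        convergence=convergence,
        model_variant=variant,
        param_names=list(names),
    )


def _append_log_omega12(ci, params, vcov, names, zq):
    """Delta-method row for log(omega12), the conventional reporting scale.

    log omega12 = 0.5 log omega1^2 + 0.5 log omega2^2 + log tanh(z), defined
    only when the estimated cross-correlation is positive.
    """
    rho = params.rho
    if rho <= 0:
        return ci
    z = float(np.arctanh(np.clip(rho, -1 + 1e-12, 1 - 1e-12)))
    est = float(np.log(params.omega[0, 1]))
    grad = np.zeros(len(names))
    grad[names.index("log_omega1_sq")] = 0.5
    grad[names.index("log_omega2_sq")] = 0.5
    grad[names.index("atanh_rho")] = (1 - rho**2) / rho
    var = float(grad @ vcov @ grad)
    se = np.sqrt(max(var, 0.0)) if np.isfinite(var) else np.nan
    row = pd.DataFrame(
        {
            "parameter": ["log_omega12"],
            "estimate": [est],
            "ci_low": [est - zq * se],
            "ci_high": [est + zq * se],
        }
    )
    return pd.concat([ci, row], ignore_index=True)


# ---------------------------------------------------------------------------
# derived summaries
# ---------------------------------------------------------------------------


def variance_explained(beta_i: float, tau2: float, omega_i2: float) -> float:
    """Fraction of the outcome's total variance carried by the spatial term.

    ``beta_i^2 tau^2 / (beta_i^2 tau^2 + omega_i^2)``; zero iff beta_i is 0.
    """
    if not (tau2 > 0 and omega_i2 > 0):
        raise ModelError("tau2 and omega_i2 must be positive")
    s = beta_i**2 * tau2
    return float(s / (s + omega_i2))


def cross_group_correlation(omega: np.ndarray) -> float:
    """Residual correlation between the two outcome groups, omega12/(omega1 omega2)."""
    omega = np.asarray(omega, dtype=float)
    w1, w2, w12 = omega[0, 0], omega[1, 1], omega[0, 1]
    if not (w1 > 0 and w2 > 0 and w12**2 < w1 * w2):
        raise ModelError("omega must be positive definite")
    return float(w12 / np.sqrt(w1 * w2))


def practical_range(delta: float, threshold: float = 0.05) -> float:
    """Distance beyond which the spatial correlation drops below ``threshold``."""
    if not delta > 0:
        raise ModelError("delta must be positive")
    if not 0 < threshold <= 1:
        raise ModelError("threshold must be in (0, 1]")
    return float(-delta * np.log(threshold))


@dataclass(frozen=True)
class LRTestResult:
    statistic: float
    df: int
    pvalue: float


def lr_test(full: FittedModel, reduced: FittedModel) -> LRTestResult:
    """Likelihood-ratio test of beta_1 = beta_2 = 0 (chi-squared, 2 df)."""
    if full.model_variant != FULL or reduced.model_variant != NO_COVARIATE:
        raise ModelError(
            "lr_test expects the full fit first and the no-covariate fit second"
        )
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = float(stats.chi2.sf(stat, df=2))
    return LRTestResult(statistic=float(stat), df=2, pvalue=p)


def fit_report_table(fitted: FittedModel) -> pd.DataFrame:
    """Table-style fit report: parameter, estimate, 95% CI, plus the loglik."""
    df = fitted.confint.copy()
    extra = pd.DataFrame(
        {
            "parameter": ["log_likelihood"],
            "estimate": [fitted.loglik],
            "ci_low": [np.nan],
            "ci_high": [np.nan],
        }
    )
    return pd.concat([df, extra], ignore_index=True)
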