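"""Spatially continuous prediction, joint sampling, and non-exceedance maps.

The target surface for group i is ``Y_i(x) = alpha_i + beta_i U(x)``: the
de-noised outcome implied by the latent spatial process.  Because the data
and the target are jointly Gaussian under the fitted model, prediction is the
standard Gaussian conditional computed at the plug-in maximum-likelihood
estimates.  All cross-covariances between the target and the observations are
derived from the single joint model, e.g.

    Cov{Y_i(x), Y_{i'j}} = beta_i beta_{i'} tau^2 * kbar(x, coarse unit j)
    Cov{Y_i(x), Z_k}     = beta_i tau^2 * kbar(x, fine unit k)

with ``kbar`` the area-normalised point-to-polygon kernel average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import shapely
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import pdist, squareform
from shapely.ops import unary_union

from .geometry import (
    AreaUnit,
    QuadratureGrid,
    FactorTable,
    add_jitter,
    points_to_units_factor,
)
from .model import FittedModel, MisalignedData, ModelError, _assemble_joint, _mean_vector

__all__ = [
    "PredictionLattice",
    "PredictiveField",
    "make_prediction_lattice",
    "predictive_distribution",
    "sample_predictive",
    "nep",
    "classify_nep",
    "areal_prediction",
    "ArealPrediction",
]

LIKELY_BELOW = "likely_below"
LIKELY_ABOVE = "likely_above"
UNCERTAIN = "uncertain"


@dataclass
class PredictionLattice:
    """Regular grid of prediction points restricted to the study region."""

    spacing: float
    points: np.ndarray  # (q, 2)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 1:
            raise ModelError("prediction lattice must contain at least one point")

    @property
    def q(self) -> int:
        return len(self.points)


def make_prediction_lattice(
    units: list[AreaUnit], spacing: float = 250.0
) -> PredictionLattice:
    """Regular lattice at ``spacing`` metres clipped to the union of ``units``."""
    if not spacing > 0:
        raise ModelError("spacing must be positive")
    region = unary_union([u.polygon for u in units])
    xmin, ymin, xmax, ymax = region.bounds
    xs = np.arange(xmin + spacing / 2, xmax, spacing)
    ys = np.arange(ymin + spacing / 2, ymax, spacing)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    shapely.prepare(region)
    keep = shapely.intersects_xy(region, pts[:, 0], pts[:, 1])
    if not keep.any():
        raise ModelError("no lattice point falls inside the study region")
    return PredictionLattice(spacing=float(spacing), points=pts[keep])


@dataclass
class PredictiveField:
    """Gaussian predictive distribution of the two surfaces on a lattice.

    ``mean`` stacks group 1 then group 2 (length 2q); ``sd`` the marginal
    predictive standard deviations; ``cov`` the full predictive covariance
    when it was requested (needed for joint sampling).
    """

    lattice: PredictionLattice
    mean: np.ndarray
    sd: np.ndarray
    cov: np.ndarray | None = None

    @property
    def q(self) -> int:
        return self.lattice.q

    def group(self, group: int) -> slice:
        if group not in (1, 2):
            raise ModelError("group must be 1 or 2")
        q = self.q
        return slice((group - 1) * q, group * q)


def _cross_cov_to_data(
    points: np.ndarray,
    fitted_params,
    data: MisalignedData,
    grid: QuadratureGrid,
) -> tuple[np.ndarray, np.ndarray]:
    """Point-to-coarse and point-to-fine kernel factors scaled by tau2."""
    p = fitted_params
    kc = p.tau2 * points_to_units_factor(points, data.coarse_units, grid, p.delta)
    kf = p.tau2 * points_to_units_factor(points, data.fine_units, grid, p.delta)
    return kc, kf


def predictive_distribution(
    fitted: FittedModel,
    data: MisalignedData,
    grid: QuadratureGrid,
    lattice: PredictionLattice,
    conditioning: Literal["all_data", "leb_only"] = "all_data",
    factors: FactorTable | None = None,
    full_cov: bool = True,
) -> PredictiveField:
    """Predictive distribution of the two outcome surfaces on a lattice.

    ``conditioning="all_data"`` (default) conditions on outcome and covariate
    jointly; ``"leb_only"`` conditions on the outcome alone.  With
    ``full_cov=False`` only marginal variances are computed, which keeps
    memory linear in the lattice size (but disables joint sampling).
    """
    p = fitted.params_hat
    n, m, q = data.n, data.m, lattice.q
    if factors is None:
        factors = FactorTable(data.coarse_units, data.fine_units, grid)
    S = add_jitter(_assemble_joint(p, factors))
    z = data.stacked()
    mu = _mean_vector(p, n, m)

    kc, kf = _cross_cov_to_data(lattice.points, p, data, grid)
    b = p.beta
    # rows: group-1 surface then group-2 surface; columns: (Y1, Y2, Z)
    Srow = np.block(
        [
            [b[0] * b[0] * kc, b[0] * b[1] * kc, b[0] * kf],
            [b[1] * b[0] * kc, b[1] * b[1] * kc, b[1] * kf],
        ]
    )
    if conditioning == "leb_only":
        keep = np.arange(2 * n)
    elif conditioning == "all_data":
        keep = np.arange(2 * n + m)
    else:
        raise ModelError(f"unknown conditioning {conditioning!r}")
    S_dd = S[np.ix_(keep, keep)]
    S_td = Srow[:, keep]
    c, low = cho_factor(S_dd, lower=True)
    w = cho_solve((c, low), (z - mu)[keep])
    mean = np.concatenate([np.full(q, p.alpha[0]), np.full(q, p.alpha[1])])
    mean = mean + S_td @ w

    # prior covariance of the stacked surfaces
    A = cho_solve((c, low), S_td.T)  # (n_data, 2q)
    if full_cov:
        Kxx = p.tau2 * np.exp(
            -squareform(pdist(lattice.points)) / p.delta
        )
        prior = np.block(
            [
                [b[0] * b[0] * Kxx, b[0] * b[1] * Kxx],
                [b[1] * b[0] * Kxx, b[1] * b[1] * Kxx],
            ]
        )
        cov = prior - S_td @ A
        cov = 0.5 * (cov + cov.T)
        var = np.clip(np.diag(cov), 0.0, np.inf)
        return PredictiveField(
            lattice=lattice, mean=mean, sd=np.sqrt(var), cov=cov
        )
    prior_var = np.concatenate(
        [np.full(q, b[0] ** 2 * p.tau2), np.full(q, b[1] ** 2 * p.tau2)]
    )
    var = np.clip(prior_var - np.einsum("ij,ji->i", S_td, A), 0.0, np.inf)
    return PredictiveField(lattice=lattice, mean=mean, sd=np.sqrt(var), cov=None)


def sample_predictive(
    field: PredictiveField, n_draws: int, seed: int | None = None
) -> np.ndarray:
    """Joint draws from the predictive field; (n_draws, 2q), seeded."""
    if field.cov is None:
        raise ModelError(
            "field has no covariance factor; recompute with full_cov=True"
        )
    if n_draws < 1:
        raise ModelError("n_draws must be >= 1")
    cov = field.cov
    # eigen factor tolerates the exactly-singular case (e.g. zero variance)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, np.inf)
    L = evecs * np.sqrt(evals)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, len(field.mean)))
    return field.mean + z @ L.T


def nep(field: PredictiveField, group: int, threshold: float) -> np.ndarray:
    """Non-exceedance probability Pr(Y_group(x) < threshold | data) per point.

    Closed form from the Gaussian marginals.  At points with zero predictive
    variance the probability degenerates to {0, 1} (0.5 exactly at the mean).
    """
    if not np.isfinite(threshold):
        raise ModelError("threshold must be finite")
    s = field.group(group)
    mean, sd = field.mean[s], field.sd[s]
    out = np.empty_like(mean)
    pos = sd > 0
    out[pos] = stats.norm.cdf((threshold - mean[pos]) / sd[pos])
    zero = ~pos
    out[zero] = np.where(
        mean[zero] < threshold, 1.0, np.where(mean[zero] > threshold, 0.0, 0.5)
    )
    return out


def classify_nep(
    nep_values: np.ndarray, low: float = 0.2, high: float = 0.8
) -> np.ndarray:
    """Label points by their non-exceedance probability.

    NEP >= high: the surface is likely below the threshold; NEP <= low:
    likely above; in between the classification is uncertain.
    """
    if not 0 < low < high < 1:
        raise ModelError("thresholds must satisfy 0 < low < high < 1")
    v = np.asarray(nep_values, dtype=float)
    out = np.full(v.shape, UNCERTAIN, dtype=object)
    out[v >= high] = LIKELY_BELOW
    out[v <= low] = LIKELY_ABOVE
    return out


@dataclass
class ArealPrediction:
    """Per-unit predictive distribution of the aggregated de-noised outcome."""

    unit_ids: list[str]
    mean: np.ndarray  # (n, 2)
    sd: np.ndarray  # (n, 2)

    def interval(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        zq = stats.norm.ppf(0.5 + level / 2)
        return self.mean - zq * self.sd, self.mean + zq * self.sd


def areal_prediction(
    fitted: FittedModel,
    data: MisalignedData,
    grid: QuadratureGrid,
    units: list[AreaUnit] | None = None,
    factors: FactorTable | None = None,
    include_noise: bool = False,
) -> ArealPrediction:
    """Conditional distribution of the aggregated outcome given the data.

    By default the target is ``alpha_i + beta_i Ubar_j`` — the de-noised
    areal surface (the quantity mapped as the model-based unit-level
    estimate).  With ``include_noise=True`` the target is the observable
    unit-level outcome itself (the de-noised value plus its unit-level noise
    T_ij): the predictive sd then adds the estimated noise variance
    omega_i^2, which is the relevant interval when asking where a published
    unit-level figure would fall.
    """
    if units is not None and units is not data.coarse_units:
        raise ModelError(
            "areal_prediction currently targets the data's coarse units"
        )
    p = fitted.params_hat
    n, m = data.n, data.m
    if factors is None:
        factors = FactorTable(data.coarse_units, data.fine_units, grid)
    S = add_jitter(_assemble_joint(p, factors))
    S_cc = p.tau2 * factors.f_cc(p.delta)
    S_cf = p.tau2 * factors.f_cf(p.delta)
    b = p.beta
    z = data.stacked()
    mu = _mean_vector(p, n, m)
    c, low = cho_factor(S, lower=True)
    w = cho_solve((c, low), z - mu)

    mean = np.empty((n, 2))
    sd = np.empty((n, 2))
    for i in range(2):
        # Cov(beta_i Ubar, (Y1, Y2, Z))
        cross = np.hstack([b[i] * b[0] * S_cc, b[i] * b[1] * S_cc, b[i] * S_cf])
        mean[:, i] = p.alpha[i] + cross @ w
        A = cho_solve((c, low), cross.T)
        prior = b[i] ** 2 * np.diag(S_cc)
        var = np.clip(prior - np.einsum("ij,ji->i", cross, A), 0, None)
        if include_noise:
            var = var + p.omega[i, i]
        sd[:, i] = np.sqrt(var)
    return ArealPrediction(
        unit_ids=[u.id for u in data.coarse_units], mean=mean, sd=sd
    )


def latent_areal_mean(
    fitted: FittedModel,
    data: MisalignedData,
    grid: QuadratureGrid,
    factors: FactorTable | None = None,
) -> np.ndarray:
    """Predictive mean of the latent areal averages Ubar_j given all data."""
    p = fitted.params_hat
    if factors is None:
        factors = FactorTable(data.coarse_units, data.fine_units, grid)
    S = add_jitter(_assemble_joint(p, factors))
    S_cc = p.tau2 * factors.f_cc(p.delta)
    S_cf = p.tau2 * factors.f_cf(p.delta)
    b = p.beta
    cross = np.hstack([b[0] * S_cc, b[1] * S_cc, S_cf])
    z = data.stacked()
    mu = _mean_vector(p, data.n, data.m)
    c, low = cho_factor(S, lower=True)
    return cross @ cho_solve((c, low), z - mu)
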