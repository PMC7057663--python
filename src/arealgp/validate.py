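"""Residual diagnostics: empirical variograms with Monte-Carlo tolerance envelopes.

The fitted model assumes that, once the latent spatial process is accounted
for, the per-unit outcome residuals ``T_ij = Y_ij - alpha_i - beta_i Ubar_j``
are spatially unstructured.  The check: compute the empirical semivariogram of
the estimated residuals against the coarse-unit centroids, then compare it
bin-by-bin with a pointwise tolerance envelope built by repeatedly permuting
the residual-to-centroid assignment (which is exact under exchangeability,
i.e. no residual spatial correlation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .geometry import FactorTable, QuadratureGrid
from .model import FittedModel, MisalignedData, ModelError
from .predict import latent_areal_mean

__all__ = [
    "ResidualSet",
    "VariogramEnvelope",
    "extract_residuals",
    "empirical_variogram",
    "permutation_envelope",
    "default_bins",
]


@dataclass
class ResidualSet:
    """Estimated unstructured residuals with coarse-unit centroids."""

    centroids: np.ndarray  # (n, 2)
    residuals: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.residuals = np.asarray(self.residuals, dtype=float)
        if self.centroids.shape[0] != self.residuals.shape[0]:
            raise ModelError("centroids and residuals must align row-wise")
        if not np.all(np.isfinite(self.residuals)):
            raise ModelError("residuals must be finite")


def extract_residuals(
    fitted: FittedModel,
    data: MisalignedData,
    grid: QuadratureGrid,
    factors: FactorTable | None = None,
) -> ResidualSet:
    """Residuals ``Y_ij - alpha_hat_i - beta_hat_i Uhat_j`` per coarse unit.

    ``Uhat_j`` is the predictive mean of the latent areal average given all
    data under the plug-in estimates; centroids are area-weighted polygon
    centroids (for multi-part units, the centroid of the union).
    """
    p = fitted.params_hat
    u_hat = latent_areal_mean(fitted, data, grid, factors)
    resid = data.outcome - p.alpha[None, :] - np.outer(u_hat, p.beta)
    cents = np.array([u.centroid for u in data.coarse_units])
    return ResidualSet(centroids=cents, residuals=resid)


def default_bins(
    centroids: np.ndarray | None = None, n_bins: int = 12
) -> np.ndarray:
    """Default distance-bin edges: 12 equal bins on [0, 10] km.

    When the supplied centroids span a smaller domain, the upper edge falls
    back to half the centroid-cloud diameter so bins are not all empty.
    """
    upper = 10_000.0
    if centroids is not None:
        diam = float(pdist(np.asarray(centroids, dtype=float)).max())
        if diam / 2 < upper:
            upper = diam / 2
    return np.linspace(0.0, upper, n_bins + 1)


def empirical_variogram(
    residuals: ResidualSet, group: int, bins: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Binned empirical semivariogram of one group's residuals.

    Per bin: half the mean squared difference over all centroid pairs whose
    separation falls in the bin (each unordered pair counted once).  Empty
    bins are reported as NaN, not zero.

    Returns (semivariance per bin, pair count per bin).
    """
    if group not in (1, 2):
        raise ModelError("group must be 1 or 2")
    if bins is None:
        bins = default_bins(residuals.centroids)
    bins = np.asarray(bins, dtype=float)
    d = pdist(residuals.centroids)
    r = residuals.residuals[:, group - 1]
    n = len(r)
    ii, jj = np.triu_indices(n, k=1)
    sq = (r[ii] - r[jj]) ** 2
    which = np.digitize(d, bins) - 1  # bin index; outside range -> -1 or nb
    nb = len(bins) - 1
    gamma = np.full(nb, np.nan)
    counts = np.zeros(nb, dtype=int)
    for b in range(nb):
        sel = which == b
        counts[b] = int(sel.sum())
        if counts[b] > 0:
            gamma[b] = 0.5 * float(np.mean(sq[sel]))
    return gamma, counts


@dataclass
class VariogramEnvelope:
    """Empirical variogram with pointwise permutation tolerance bands."""

    bin_edges: np.ndarray
    empirical: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    counts: np.ndarray
    n_permutations: int
    seed: int | None
    level: float
    inside: bool

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin_mid": self.midpoints,
                "empirical": self.empirical,
                "lower": self.lower,
                "upper": self.upper,
                "n_pairs": self.counts,
            }
        )


def permutation_envelope(
    residuals: ResidualSet,
    group: int,
    bins: np.ndarray | None = None,
    B: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> VariogramEnvelope:
    """Monte-Carlo tolerance envelope for the empirical variogram.

    Permutes the residual-to-centroid assignment B times (centroids held
    fixed), recomputes the variogram each time, and takes pointwise
    ``(1-level)/2`` and ``(1+level)/2`` quantiles per distance bin.  The
    verdict is ``inside`` iff the observed variogram lies within the band in
    every non-empty bin; an excursion is evidence of residual spatial
    structure the model has not captured.
    """
    if B < 100:
        raise ModelError(f"B must be at least 100, got {B}")
    if not 0 < level < 1:
        raise ModelError("level must be in (0, 1)")
    if bins is None:
        bins = default_bins(residuals.centroids)
    bins = np.asarray(bins, dtype=float)
    emp, counts = empirical_variogram(residuals, group, bins)

    # permutation null: recompute variogram on shuffled residuals
    d = pdist(residuals.centroids)
    n = residuals.residuals.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    which = np.digitize(d, bins) - 1
    nb = len(bins) - 1
    members = [np.flatnonzero(which == b) for b in range(nb)]
    r = residuals.residuals[:, group - 1]
    rng = np.random.default_rng(seed)
    sims = np.full((B, nb), np.nan)
    for b_rep in range(B):
        perm = rng.permutation(n)
        rp = r[perm]
        sq = (rp[ii] - rp[jj]) ** 2
        for b in range(nb):
            if members[b].size:
                sims[b_rep, b] = 0.5 * float(np.mean(sq[members[b]]))
    alpha = (1.0 - level) / 2.0
    lower = np.full(nb, np.nan)
    upper = np.full(nb, np.nan)
    nonempty = counts > 0
    lower[nonempty] = np.quantile(sims[:, nonempty], alpha, axis=0)
    upper[nonempty] = np.quantile(sims[:, nonempty], 1 - alpha, axis=0)
    inside = bool(
        np.all(
            (emp[nonempty] >= lower[nonempty]) & (emp[nonempty] <= upper[nonempty])
        )
    )
    return VariogramEnvelope(
        bin_edges=bins,
        empirical=emp,
        lower=lower,
        upper=upper,
        counts=counts,
        n_permutations=B,
        seed=seed,
        level=level,
        inside=inside,
    )
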