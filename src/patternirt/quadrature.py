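"""Quadrature rules for integrating over the latent-severity prior.

Marginal likelihoods and posterior (EAP) moments require integrals against a
multivariate normal prior N(0, R) with unit variances and free correlations.
Two rules are provided:

* a tensor-product Gauss-Hermite rule (deterministic, the package default),
* a scrambled-Sobol quasi-Monte-Carlo rule with equal weights, mirroring the
  QMC-EM flavour of estimation used by full-information item factor analysis
  software.

Both rules are built on the independent standard-normal scale and mapped
through the Cholesky factor of the prior correlation, so the stored weights
are exact prior masses and need no density reweighting when the correlation
is updated during estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["QuadratureRule", "gauss_hermite_rule", "qmc_rule"]


@dataclass(frozen=True)
class QuadratureRule:
    """Nodes (on the correlated theta scale) and prior weights."""

    kind: str  # "gauss_hermite_tensor" | "quasi_monte_carlo"
    z_nodes: np.ndarray  # K x D, independent standard-normal scale
    weights: np.ndarray  # K, non-negative, sums to 1
    latent_corr: np.ndarray  # D x D correlation used to place theta nodes
    n_points: int  # per-dimension count (tensor) or total (QMC)
    seed: int | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("negative quadrature weights")
        object.__setattr__(self, "weights", w / w.sum())
        object.__setattr__(self, "z_nodes", np.asarray(self.z_nodes, dtype=float))
        object.__setattr__(self, "latent_corr", np.asarray(self.latent_corr, dtype=float))

    @property
    def n_nodes(self) -> int:
        return self.z_nodes.shape[0]

    @property
    def n_dim(self) -> int:
        return self.z_nodes.shape[1]

    @property
    def theta_nodes(self) -> np.ndarray:
        """Nodes on the correlated-prior scale: theta = L z, L = chol(R)."""
        L = np.linalg.cholesky(self.latent_corr)
        return self.z_nodes @ L.T

    def with_correlation(self, latent_corr: np.ndarray) -> "QuadratureRule":
        return QuadratureRule(
            kind=self.kind,
            z_nodes=self.z_nodes,
            weights=self.weights,
            latent_corr=np.asarray(latent_corr, dtype=float),
            n_points=self.n_points,
            seed=self.seed,
        )


def _check_corr(latent_corr: np.ndarray | None, n_dim: int) -> np.ndarray:
    if latent_corr is None:
        return np.eye(n_dim)
    R = np.asarray(latent_corr, dtype=float)
    if R.shape != (n_dim, n_dim):
        raise ValueError("latent correlation has wrong shape")
    if not np.allclose(np.diag(R), 1.0):
        raise ValueError("latent correlation must have unit diagonal")
    np.linalg.cholesky(R)  # raises if not positive definite
    return R


def gauss_hermite_rule(
    n_dim: int, n_points: int = 21, latent_corr: np.ndarray | None = None
) -> QuadratureRule:
    """Tensor-product Gauss-Hermite rule with ``n_points`` nodes per dimension."""
    if n_points < 2:
        raise ValueError("need at least 2 nodes per dimension")
    x, w = np.polynomial.hermite.hermgauss(n_points)
    # rescale from weight exp(-x^2) to the standard normal density
    z1 = x * np.sqrt(2.0)
    w1 = w / np.sqrt(np.pi)
    grids = np.meshgrid(*([z1] * n_dim), indexing="ij")
    z = np.column_stack([g.ravel() for g in grids])
    wgrids = np.meshgrid(*([w1] * n_dim), indexing="ij")
    weights = np.prod(np.column_stack([g.ravel() for g in wgrids]), axis=1)
    return QuadratureRule(
        kind="gauss_hermite_tensor",
        z_nodes=z,
        weights=weights,
        latent_corr=_check_corr(latent_corr, n_dim),
        n_points=n_points,
    )


def qmc_rule(
    n_dim: int,
    n_points: int = 2000,
    seed: int = 0,
    latent_corr: np.ndarray | None = None,
) -> QuadratureRule:
    """Scrambled-Sobol quasi-Monte-Carlo rule with equal weights."""
    if n_points < 2:
        raise ValueError("need at least 2 points")
    sampler = stats.qmc.Sobol(d=n_dim, scramble=True, seed=seed)
    u = sampler.random(n_points)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    z = stats.norm.ppf(u)
    weights = np.full(n_points, 1.0 / n_points)
    return QuadratureRule(
        kind="quasi_monte_carlo",
        z_nodes=z,
        weights=weights,
        latent_corr=_check_corr(latent_corr, n_dim),
        n_points=n_points,
        seed=seed,
    )
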