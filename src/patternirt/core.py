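"""The multidimensional graded response model (MGRM).

For an item with discrimination vector ``a``, boundary intercepts
``d_1 > ... > d_m`` and a latent severity vector ``theta``, the cumulative
("category t or above") probabilities are

    P*_t(theta) = F(a . theta + d_t),    t = 1..m,

with the conventions ``P*_0 = 1`` and ``P*_{m+1} = 0``, where ``F`` is the
standard normal CDF (probit link) or the standard logistic CDF.  The exact
category probabilities are successive differences ``P_t = P*_t - P*_{t+1}``.

This module evaluates those probabilities, Reckase's multidimensional
discrimination index (MDISC), directional Fisher information for single
items and the whole test, item character curves along an item's own factor,
and expected-a-posteriori (EAP) severity scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bank import ItemBank, ItemParameters
from .links import link_cdf, link_pdf
from .quadrature import QuadratureRule, gauss_hermite_rule

__all__ = [
    "cumulative_prob",
    "category_prob",
    "category_prob_table",
    "mdisc",
    "mdisc_quality",
    "item_information",
    "test_information_grid",
    "icc_curves",
    "eap_score",
    "InformationGrid",
    "EapScore",
]

_PROB_FLOOR = 1e-300


def _check_theta(item: ItemParameters, theta: np.ndarray) -> np.ndarray:
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if theta.shape[1] != item.n_dim:
        raise ValueError(f"theta must have {item.n_dim} coordinates")
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite theta")
    return theta


def cumulative_prob(item: ItemParameters, theta, t: int):
    """P*_t(theta): probability of responding in category ``t`` or above.

    ``t = 0`` returns 1 and ``t = m + 1`` returns 0 by convention.
    Accepts a single theta vector or an array of them; returns a scalar or
    an array accordingly.
    """
    theta2 = _check_theta(item, theta)
    m = item.n_boundaries
    if not 0 <= t <= m + 1:
        raise IndexError(f"boundary index {t} outside 0..{m + 1}")
    if t == 0:
        out = np.ones(theta2.shape[0])
    elif t == m + 1:
        out = np.zeros(theta2.shape[0])
    else:
        out = link_cdf(theta2 @ item.a + item.d[t - 1], item.link)
    return float(out[0]) if np.ndim(theta) == 1 else out


def category_prob(item: ItemParameters, theta, t: int):
    """P_t(theta) = P*_t - P*_{t+1}: probability of the exact category ``t``."""
    m = item.n_boundaries
    if not 0 <= t <= m:
        raise IndexError(f"category index {t} outside 0..{m}")
    return cumulative_prob(item, theta, t) - cumulative_prob(item, theta, t + 1)


def category_prob_table(item: ItemParameters, theta: np.ndarray) -> np.ndarray:
    """All category probabilities at once: K x (m + 1) for K theta rows."""
    theta = _check_theta(item, theta)
    z = theta @ item.a
    cum = link_cdf(z[:, None] + item.d[None, :], item.link)  # K x m
    ones = np.ones((theta.shape[0], 1))
    zeros = np.zeros((theta.shape[0], 1))
    star = np.concatenate([ones, cum, zeros], axis=1)  # K x (m + 2)
    return -np.diff(star, axis=1)


def mdisc(item: ItemParameters) -> float:
    """Reckase's multidimensional discrimination index: ||a||_2.

    Under simple structure this equals the item's single nonzero slope.
    """
    if not np.any(item.a != 0):
        raise ValueError(f"{item.item_id}: MDISC undefined for an all-zero discrimination vector")
    return float(np.linalg.norm(item.a))


def mdisc_quality(value: float) -> str:
    """Item-quality class: >1 high, 0.5..1 medium, otherwise low."""
    if value > 1.0:
        return "high"
    if value >= 0.5:
        return "medium"
    return "low"


def _information_terms(item: ItemParameters, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-category probabilities and boundary-density differences.

    The gradient of P_t with respect to theta is (f(z_t) - f(z_{t+1})) a,
    with f the link density and f(z_0) = f(z_{m+1}) = 0.
    """
    z = theta @ item.a
    zb = z[:, None] + item.d[None, :]
    dens = link_pdf(zb, item.link)  # K x m
    zerocol = np.zeros((theta.shape[0], 1))
    padded = np.concatenate([zerocol, dens, zerocol], axis=1)  # K x (m + 2)
    diff = padded[:, :-1] - padded[:, 1:]  # K x (m + 1): f(z_t) - f(z_{t+1})
    probs = category_prob_table(item, theta)
    return probs, diff


def item_information(item: ItemParameters, theta, direction: np.ndarray | None = None) -> float:
    """Directional Fisher information of a graded item at ``theta``.

    I(theta; u) = sum_t (u . grad P_t)^2 / P_t.  ``direction`` defaults to
    the item's own loading direction (the unit vector along ``a``); it must
    have unit norm.
    """
    theta2 = _check_theta(item, theta)
    if direction is None:
        norm = np.linalg.norm(item.a)
        if norm == 0:
            return 0.0  # flat surfaces carry no information in any direction
        direction = item.a / norm
    else:
        direction = np.asarray(direction, dtype=float)
        norm = np.linalg.norm(direction)
        if norm == 0:
            raise ValueError("direction must have nonzero norm")
        if not np.isclose(norm, 1.0):
            raise ValueError("direction must be a unit vector")
    probs, diff = _information_terms(item, theta2)
    proj = float(item.a @ direction)
    info = np.sum((proj * diff) ** 2 / np.maximum(probs, _PROB_FLOOR), axis=1)
    return float(info[0]) if np.ndim(theta) == 1 else info


@dataclass(frozen=True)
class InformationGrid:
    """Information values over a tensor grid of latent severities."""

    axis_points: tuple[np.ndarray, ...]
    values: np.ndarray  # shape = tuple(len(ax) for ax in axis_points)
    kind: str  # "item" | "test"

    def __post_init__(self) -> None:
        for ax in self.axis_points:
            if ax.size > 1 and not np.all(np.diff(ax) > 0):
                raise ValueError("grid axes must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("information must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        """Long-format records: one row per grid node."""
        mesh = np.meshgrid(*self.axis_points, indexing="ij")
        data = {f"theta{k + 1}": m.ravel() for k, m in enumerate(mesh)}
        data["information"] = self.values.ravel()
        return pd.DataFrame(data)

    def argmax_theta(self) -> np.ndarray:
        idx = np.unravel_index(np.argmax(self.values), self.values.shape)
        return np.array([ax[i] for ax, i in zip(self.axis_points, idx)])


def test_information_grid(
    bank: ItemBank,
    axis_range: tuple[float, float] = (-4.0, 4.0),
    step: float = 0.1,
) -> InformationGrid:
    """Test information (sum of item informations, each along its own
    loading direction) over a tensor grid of theta values."""
    if step <= 0:
        raise ValueError("step must be positive")
    lo, hi = axis_range
    axis = np.arange(lo, hi + step / 2, step)
    axes = tuple(axis.copy() for _ in range(bank.n_dim))
    mesh = np.meshgrid(*axes, indexing="ij")
    theta = np.column_stack([m.ravel() for m in mesh])
    total = np.zeros(theta.shape[0])
    for item in bank.items:
        total += item_information_array(item, theta)
    return InformationGrid(axis_points=axes, values=total.reshape(mesh[0].shape), kind="test")


def item_information_array(item: ItemParameters, theta: np.ndarray) -> np.ndarray:
    """Vectorized information along the item's own loading direction."""
    norm = np.linalg.norm(item.a)
    if norm == 0:
        return np.zeros(np.atleast_2d(theta).shape[0])
    return item_information(item, np.atleast_2d(theta))


def icc_curves(
    item: ItemParameters,
    own_dimension: int,
    theta_range: tuple[float, float] = (-4.0, 4.0),
    step: float = 0.1,
) -> pd.DataFrame:
    """Item character curves: category probabilities along the item's own
    factor with all other coordinates fixed at 0 (the prior mean).

    Returns long-format records with columns theta, category, probability.
    """
    if item.a[own_dimension] == 0:
        raise ValueError(f"{item.item_id}: no loading on dimension {own_dimension}")
    lo, hi = theta_range
    grid = np.arange(lo, hi + step / 2, step)
    theta = np.zeros((grid.size, item.n_dim))
    theta[:, own_dimension] = grid
    probs = category_prob_table(item, theta)
    records = []
    for t in range(item.n_categories):
        records.append(
            pd.DataFrame(
                {
                    "item_id": item.item_id,
                    "theta": grid,
                    "category": t,
                    "probability": probs[:, t],
                }
            )
        )
    return pd.concat(records, ignore_index=True)


@dataclass(frozen=True)
class EapScore:
    """Posterior mean and SD of the latent severity vector."""

    theta: np.ndarray
    sd: np.ndarray
    all_missing: bool = False


def eap_score(
    bank: ItemBank,
    responses: np.ndarray,
    latent_cov: np.ndarray | None = None,
    rule: QuadratureRule | None = None,
) -> EapScore:
    """Expected-a-posteriori severity score for one respondent.

    The posterior is proportional to the N(0, latent_cov) prior density times
    the MGRM likelihood of the observed responses; missing items contribute
    no likelihood term.  A fully missing response row returns the prior mean
    and SD, flagged.
    """
    responses = np.asarray(responses, dtype=float).ravel()
    if responses.size != bank.n_items:
        raise ValueError("response row length must match the bank")
    if latent_cov is None:
        latent_cov = np.eye(bank.n_dim)
    latent_cov = np.asarray(latent_cov, dtype=float)
    if not np.allclose(np.diag(latent_cov), 1.0):
        raise ValueError("latent covariance must have unit diagonal")
    if rule is None:
        rule = gauss_hermite_rule(bank.n_dim, 21, latent_corr=latent_cov)
    elif not np.allclose(rule.latent_corr, latent_cov):
        rule = rule.with_correlation(latent_cov)
    theta = rule.theta_nodes
    observed = ~np.isnan(responses)
    if not observed.any():
        return EapScore(theta=np.zeros(bank.n_dim), sd=np.ones(bank.n_dim), all_missing=True)
    log_post = np.log(rule.weights)
    for j in np.flatnonzero(observed):
        probs = category_prob_table(bank.items[j], theta)
        log_post = log_post + np.log(np.maximum(probs[:, int(responses[j])], _PROB_FLOOR))
    log_post -= log_post.max()
    w = np.exp(log_post)
    w /= w.sum()
    mean = w @ theta
    var = w @ (theta - mean) ** 2
    return EapScore(theta=mean, sd=np.sqrt(var), all_missing=False)
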