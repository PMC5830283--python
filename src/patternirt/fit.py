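"""Marginal maximum-likelihood estimation of the MGRM by EM.

Full-information item factor analysis: the marginal likelihood integrates
the graded-response likelihood over a multivariate-normal prior on the
latent severities.  The E-step evaluates each respondent's posterior over a
fixed quadrature rule (tensor Gauss-Hermite by default, scrambled-Sobol QMC
as an option); the M-step maximizes each item's expected complete-data
log-likelihood over its free slopes and all boundary intercepts, and the
latent correlation is re-estimated from pooled posterior second moments.

Confirmatory constraints (discriminations fixed to zero off an item's
factor) are enforced exactly in every iterate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .bank import ItemBank, ItemParameters, starting_bank
from .core import category_prob_table, mdisc
from .links import link_cdf, link_pdf
from .quadrature import QuadratureRule, gauss_hermite_rule
from .responses import ResponseMatrix

__all__ = [
    "EStepResult",
    "MgrmFitResult",
    "e_step",
    "m_step_item",
    "update_latent_corr",
    "fit_mgrm",
    "collapse_empty_categories",
]

logger = logging.getLogger(__name__)

_PROB_FLOOR = 1e-300
_D_BOUND = 15.0
_A_BOUND = 25.0


@dataclass(frozen=True)
class EStepResult:
    """Posterior node weights per respondent and the marginal log-likelihood."""

    posterior: np.ndarray  # n x K, rows sum to 1
    loglik: float
    theta_nodes: np.ndarray  # K x D


@dataclass
class MgrmFitResult:
    bank: ItemBank
    latent_corr: np.ndarray
    loglik_path: list[float]
    n_iterations: int
    converged: bool
    tolerance: float
    rule: QuadratureRule
    item_flags: dict[str, list[str]] = field(default_factory=dict)
    collapse_maps: dict[str, dict[int, int]] = field(default_factory=dict)
    standard_errors: pd.DataFrame | None = None

    @property
    def loglik(self) -> float:
        return self.loglik_path[-1] if self.loglik_path else float("nan")

    def parameter_table(self) -> pd.DataFrame:
        """Item table: slopes, boundary intercepts and MDISC, one row per item."""
        rows = []
        for it in self.bank.items:
            row = {"item_id": it.item_id}
            for k in range(it.n_dim):
                row[f"a{k + 1}"] = it.a[k]
            for t in range(it.n_boundaries):
                row[f"d{t + 1}"] = it.d[t]
            row["MDISC"] = mdisc(it) if np.any(it.a != 0) else 0.0
            rows.append(row)
        return pd.DataFrame(rows)


def _loglik_nodes(
    values: np.ndarray, bank: ItemBank, theta_nodes: np.ndarray
) -> np.ndarray:
    """n x K matrix of per-respondent log-likelihoods at each node."""
    n = values.shape[0]
    L = np.zeros((n, theta_nodes.shape[0]))
    for j, item in enumerate(bank.items):
        col = values[:, j]
        observed = ~np.isnan(col)
        if not observed.any():
            continue
        logp = np.log(np.maximum(category_prob_table(item, theta_nodes), _PROB_FLOOR))
        L[observed] += logp[:, col[observed].astype(int)].T
    return L


def e_step(
    responses: ResponseMatrix,
    bank: ItemBank,
    latent_corr: np.ndarray,
    rule: QuadratureRule,
) -> EStepResult:
    """Posterior node weights proportional to prior mass times likelihood.

    Respondents with all items missing get the prior as posterior and
    contribute zero to the marginal log-likelihood.
    """
    rule = rule.with_correlation(latent_corr)
    theta = rule.theta_nodes
    L = _loglik_nodes(responses.values, bank, theta)
    A = L + np.log(rule.weights)[None, :]
    amax = A.max(axis=1, keepdims=True)
    lse = amax[:, 0] + np.log(np.exp(A - amax).sum(axis=1))
    post = np.exp(A - lse[:, None])
    return EStepResult(posterior=post, loglik=float(lse.sum()), theta_nodes=theta)


def _item_objective(
    params: np.ndarray,
    item: ItemParameters,
    free_idx: np.ndarray,
    counts: np.ndarray,
    theta: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Negative expected complete-data log-likelihood and its gradient.

    ``params`` packs the free slope entries followed by all boundary
    intercepts; ``counts`` is the K x (m + 1) matrix of expected response
    counts at each quadrature node.
    """
    n_free = free_idx.size
    a = np.zeros(item.n_dim)
    a[free_idx] = params[:n_free]
    d = params[n_free:]
    z = theta @ a
    zb = z[:, None] + d[None, :]
    cum = link_cdf(zb, item.link)
    dens = link_pdf(zb, item.link)
    K = theta.shape[0]
    star = np.concatenate([np.ones((K, 1)), cum, np.zeros((K, 1))], axis=1)
    # floor well above the underflow threshold: count/prob ratios in the
    # gradient must stay finite at line-search trial points where a cell
    # probability collapses to zero
    probs = np.maximum(-np.diff(star, axis=1), 1e-12)
    nll = -float(np.sum(counts * np.log(probs)))

    ratio = counts / probs  # K x (m + 1)
    # dP_t/dd_s = dens_s * (1[s == t] - 1[s == t + 1]), so
    # dl/dd_s = dens_s * (ratio_s - ratio_{s-1})
    grad_d = np.einsum("ks,ks->s", dens, ratio[:, 1:] - ratio[:, :-1])
    # dP_t/da_q = theta_q * (dens_t - dens_{t+1}), with dens_0 = dens_{m+1} = 0
    zerocol = np.zeros((K, 1))
    padded = np.concatenate([zerocol, dens, zerocol], axis=1)
    ddiff = padded[:, :-1] - padded[:, 1:]  # K x (m + 1)
    per_node = np.sum(ratio * ddiff, axis=1)  # K
    grad_a = theta[:, free_idx].T @ per_node
    return nll, -np.concatenate([grad_a, grad_d])


_GAP_LOG_LO = np.log(1e-5)
_GAP_LOG_HI = np.log(12.0)


def _ordered_objective(
    u: np.ndarray,
    item: ItemParameters,
    free_idx: np.ndarray,
    counts: np.ndarray,
    theta: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Objective in the ordered parameterization d_t = d_{t-1} - exp(g_t).

    The log-gap transform keeps the boundary intercepts strictly descending
    at every point the line search visits, so category probabilities stay
    positive and the objective smooth.
    """
    n_free = free_idx.size
    m = item.n_boundaries
    d1 = u[n_free]
    gaps = np.exp(u[n_free + 1 :]) if m > 1 else np.empty(0)
    d = d1 - np.concatenate([[0.0], np.cumsum(gaps)])
    x = np.concatenate([u[:n_free], d])
    nll, grad = _item_objective(x, item, free_idx, counts, theta)
    gd = grad[n_free:]
    # d_t depends on d1 with coefficient 1 and on gap_s (s <= t) with -1
    tail = np.cumsum(gd[::-1])[::-1]  # tail[s] = sum_{t >= s} dnll/dd_t
    gu = np.concatenate([grad[:n_free], [tail[0]], -gaps * tail[1:]]) if m > 1 else grad
    return nll, gu


def m_step_item(
    counts: np.ndarray,
    theta_nodes: np.ndarray,
    item: ItemParameters,
    free_mask: np.ndarray,
) -> tuple[ItemParameters, list[str]]:
    """Maximize one item's expected complete-data log-likelihood.

    Free slope entries (per ``free_mask``) and all boundary intercepts are
    updated by bounded quasi-Newton search in an order-preserving
    parameterization; fixed-zero slopes stay exactly zero.  Intercepts that
    run into the search bounds (as happens when a category is nearly or
    never observed) are flagged as boundary estimates; a failed search
    leaves the item at its previous values, flagged.
    """
    free_idx = np.flatnonzero(np.asarray(free_mask, dtype=bool))
    if np.any(counts < -1e-9):
        raise ValueError("negative expected counts")
    flags: list[str] = []
    empty = np.flatnonzero(counts.sum(axis=0) < 1e-8)
    if empty.size:
        flags.append(
            "category with (near-)zero expected count: boundary estimate driven "
            f"to the limit for categories {empty.tolist()}"
        )
    m = item.n_boundaries
    gaps0 = np.maximum(-np.diff(item.d), 2e-5) if m > 1 else np.empty(0)
    u0 = np.concatenate([item.a[free_idx], [item.d[0]], np.log(gaps0)])
    bounds = (
        [(-_A_BOUND, _A_BOUND)] * free_idx.size
        + [(-_D_BOUND, _D_BOUND)]
        + [(_GAP_LOG_LO, _GAP_LOG_HI)] * (m - 1)
    )
    res = optimize.minimize(
        _ordered_objective,
        u0,
        args=(item, free_idx, counts, theta_nodes),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not np.all(np.isfinite(res.x)):
        flags.append(f"optimizer did not converge: {res.message}")
        return item, flags
    n_free = free_idx.size
    a = np.array(item.a)
    a[free_idx] = res.x[:n_free]
    d1 = res.x[n_free]
    gaps = np.exp(res.x[n_free + 1 :]) if m > 1 else np.empty(0)
    d = d1 - np.concatenate([[0.0], np.cumsum(gaps)])
    at_bound = abs(d1) >= _D_BOUND - 1e-6 or (
        m > 1 and np.any(res.x[n_free + 1 :] >= _GAP_LOG_HI - 1e-6)
    )
    if at_bound:
        flags.append("boundary intercept at search bound (category nearly unobserved)")
    if free_idx.size and np.any(np.abs(a[free_idx]) >= _A_BOUND - 1e-6):
        flags.append("slope at search bound")
    return replace(item, a=a, d=d), flags


def update_latent_corr(theta_nodes: np.ndarray, posterior: np.ndarray) -> np.ndarray:
    """Latent correlation maximizing the expected complete-data prior term.

    The prior is N(0, R) with the variances pinned at 1, so the M-step
    maximizes -log|R|/2 - tr(R^-1 M)/2 over correlation matrices R, where
    M is the posterior second moment about the origin pooled over
    respondents.  For two dimensions this is an exact one-parameter search
    (keeping EM monotone); for more dimensions the pooled moment is
    rescaled to unit diagonal, which is a close but inexact surrogate.  A
    degenerate pooled moment is repaired by eigenvalue clipping, with a
    warning.
    """
    mean_w = posterior.mean(axis=0)  # K
    M = (theta_nodes.T * mean_w) @ theta_nodes
    M = (M + M.T) / 2.0
    D = M.shape[0]
    if D == 2:
        m11, m22, m12 = M[0, 0], M[1, 1], M[0, 1]

        def neg_expected(r: float) -> float:
            det = 1.0 - r * r
            return 0.5 * np.log(det) + (m11 + m22 - 2.0 * r * m12) / (2.0 * det)

        res = optimize.minimize_scalar(neg_expected, bounds=(-0.999, 0.999), method="bounded",
                                       options={"xatol": 1e-10})
        r = float(res.x)
        return np.array([[1.0, r], [r, 1.0]])
    scale = 1.0 / np.sqrt(np.diag(M))
    R = M * scale[:, None] * scale[None, :]
    R = (R + R.T) / 2.0
    eigvals = np.linalg.eigvalsh(R)
    if eigvals.min() <= 1e-10:
        warnings.warn("pooled posterior moment not positive definite; repaired by eigenvalue clipping")
        vals, vecs = np.linalg.eigh(R)
        vals = np.maximum(vals, 1e-6)
        R = vecs @ np.diag(vals) @ vecs.T
        scale = 1.0 / np.sqrt(np.diag(R))
        R = R * scale[:, None] * scale[None, :]
        R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return R


def collapse_empty_categories(
    responses: ResponseMatrix, bank: ItemBank
) -> tuple[ResponseMatrix, ItemBank, dict[str, dict[int, int]]]:
    """Remap observed categories to a contiguous 0..m' range per item.

    The graded model is undefined for unobserved categories, so empty ones
    are collapsed away and the remapping is logged and returned.  An item
    with fewer than two observed categories is an error.
    """
    values = np.array(responses.values)
    new_items = []
    maps: dict[str, dict[int, int]] = {}
    for j, item in enumerate(bank.items):
        col = values[:, j]
        observed = np.unique(col[~np.isnan(col)]).astype(int)
        if observed.size < 2:
            raise ValueError(f"{item.item_id}: fewer than 2 observed categories")
        full = np.arange(item.n_categories)
        if observed.size == item.n_categories and np.array_equal(observed, full):
            new_items.append(item)
            continue
        mapping = {int(old): rank for rank, old in enumerate(observed)}
        maps[item.item_id] = mapping
        logger.warning("%s: collapsing empty categories, remap %s", item.item_id, mapping)
        remapped = np.array(col)
        mask = ~np.isnan(col)
        remapped[mask] = [mapping[int(v)] for v in col[mask]]
        values[:, j] = remapped
        # keep the boundary above each surviving non-lowest category
        keep_idx = sorted({int(observed[r]) - 1 for r in range(1, observed.size)})
        d = item.d[keep_idx]
        if d.size > 1 and not np.all(np.diff(d) < 0):
            d = np.sort(d)[::-1]
        new_items.append(replace(item, d=d, category_labels=None))
    new_bank = ItemBank(
        items=tuple(new_items),
        loading_pattern=bank.loading_pattern,
        dimension_labels=bank.dimension_labels,
        category_labels=None if maps else bank.category_labels,
    )
    new_rm = ResponseMatrix(values=values, item_ids=responses.item_ids, respondent_ids=responses.respondent_ids)
    return new_rm, new_bank, maps


def fit_mgrm(
    responses: ResponseMatrix,
    bank: ItemBank | None = None,
    rule: QuadratureRule | None = None,
    tol: float = 1e-4,
    max_iter: int = 500,
    estimate_corr: bool = True,
    latent_corr: np.ndarray | None = None,
    compute_se: bool = False,
    start_bank: ItemBank | None = None,
) -> MgrmFitResult:
    """Fit the MGRM by EM until the largest parameter change drops below ``tol``.

    Parameters
    ----------
    responses
        Integer category matrix; blank cells are missing.
    bank
        Bank carrying the loading pattern, link and category counts; the
        confirmatory constraints come from here.  Estimation always starts
        from neutral values (free slopes 1, equally spaced intercepts), not
        from the bank's parameter values.
    rule
        Quadrature rule; default tensor Gauss-Hermite with 21 nodes per
        dimension.
    estimate_corr
        Re-estimate the latent correlation each iteration (default); when
        False, ``latent_corr`` (identity by default) is held fixed.
    start_bank
        Override the neutral starting values with explicit ones (e.g. a
        known truth in self-consistency simulations); must match the
        (possibly collapsed) category layout.
    """
    if bank is None:
        raise ValueError("an initial ItemBank (loading pattern + link) is required")
    if responses.n_respondents < 2:
        raise ValueError("need at least 2 respondents")
    responses.validate_against(bank)
    responses, work_bank, maps = collapse_empty_categories(responses, bank)
    # neutral starting values on the (possibly collapsed) category layout
    if start_bank is not None:
        if [it.n_categories for it in start_bank.items] != [
            it.n_categories for it in work_bank.items
        ]:
            raise ValueError("start_bank does not match the (collapsed) category layout")
        start = start_bank.with_link(work_bank.link)
    else:
        start = starting_bank(
            work_bank.loading_pattern,
            [it.n_categories for it in work_bank.items],
            link=work_bank.link,
            item_ids=work_bank.item_ids,
        )
        start = ItemBank(
            items=tuple(
                replace(s, label=w.label) for s, w in zip(start.items, work_bank.items)
            ),
            loading_pattern=work_bank.loading_pattern,
            dimension_labels=work_bank.dimension_labels,
        )
    if rule is None:
        rule = gauss_hermite_rule(work_bank.n_dim, 21)
    R = np.eye(work_bank.n_dim) if latent_corr is None else np.asarray(latent_corr, dtype=float)

    current = start
    loglik_path: list[float] = []
    item_flags: dict[str, list[str]] = {}
    converged = False
    n_iter = 0
    values = responses.values
    for n_iter in range(1, max_iter + 1):
        es = e_step(responses, current, R, rule)
        loglik_path.append(es.loglik)
        new_items = []
        max_change = 0.0
        for j, item in enumerate(current.items):
            col = values[:, j]
            observed = ~np.isnan(col)
            counts = np.zeros((es.theta_nodes.shape[0], item.n_categories))
            cats = col[observed].astype(int)
            post_obs = es.posterior[observed]
            for t in range(item.n_categories):
                sel = cats == t
                if sel.any():
                    counts[:, t] = post_obs[sel].sum(axis=0)
            new_item, flags = m_step_item(counts, es.theta_nodes, item, current.loading_pattern[j])
            if flags:
                item_flags.setdefault(item.item_id, []).extend(
                    f for f in flags if f not in item_flags.get(item.item_id, [])
                )
            max_change = max(
                max_change,
                float(np.max(np.abs(new_item.a - item.a), initial=0.0)),
                float(np.max(np.abs(new_item.d - item.d), initial=0.0)),
            )
            new_items.append(new_item)
        current = ItemBank(
            items=tuple(new_items),
            loading_pattern=current.loading_pattern,
            dimension_labels=current.dimension_labels,
        )
        if estimate_corr and work_bank.n_dim > 1:
            R_new = update_latent_corr(es.theta_nodes, es.posterior)
            max_change = max(max_change, float(np.max(np.abs(R_new - R))))
            R = R_new
        if max_change < tol:
            converged = True
            break
    if max_iter == 0:
        current = start

    result = MgrmFitResult(
        bank=current,
        latent_corr=R,
        loglik_path=loglik_path,
        n_iterations=n_iter if max_iter > 0 else 0,
        converged=converged,
        tolerance=tol,
        rule=rule.with_correlation(R),
        item_flags=item_flags,
        collapse_maps=maps,
    )
    if compute_se:
        result.standard_errors = _observed_information_se(responses, result)
    return result


def _pack_free(bank: ItemBank) -> tuple[np.ndarray, list[tuple[str, str]]]:
    params, names = [], []
    for j, it in enumerate(bank.items):
        for k in np.flatnonzero(bank.loading_pattern[j]):
            params.append(it.a[k])
            names.append((it.item_id, f"a{k + 1}"))
        for t in range(it.n_boundaries):
            params.append(it.d[t])
            names.append((it.item_id, f"d{t + 1}"))
    return np.array(params), names


def _unpack_free(bank: ItemBank, params: np.ndarray) -> ItemBank:
    items = []
    pos = 0
    for j, it in enumerate(bank.items):
        a = np.array(it.a)
        free = np.flatnonzero(bank.loading_pattern[j])
        a[free] = params[pos : pos + free.size]
        pos += free.size
        d = params[pos : pos + it.n_boundaries]
        pos += it.n_boundaries
        items.append(replace(it, a=a, d=np.array(d)))
    return ItemBank(
        items=tuple(items),
        loading_pattern=bank.loading_pattern,
        dimension_labels=bank.dimension_labels,
    )


def _observed_information_se(responses: ResponseMatrix, result: MgrmFitResult) -> pd.DataFrame:
    """Standard errors from a central-difference Hessian of the marginal
    log-likelihood at the EM solution (item parameters only; the latent
    correlation is held at its estimate)."""
    bank = result.bank
    x0, names = _pack_free(bank)
    rule = result.rule
    R = result.latent_corr

    def negll(x: np.ndarray) -> float:
        try:
            b = _unpack_free(bank, x)
        except ValueError:  # ordering violated by the perturbation
            return np.inf
        return -e_step(responses, b, R, rule).loglik

    h = 1e-4
    p = x0.size
    H = np.zeros((p, p))
    f0 = negll(x0)
    fp = np.zeros(p)
    fm = np.zeros(p)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h
        fp[i] = negll(x0 + ei)
        fm[i] = negll(x0 - ei)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h**2
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h
            ej[j] = h
            fpp = negll(x0 + ei + ej)
            fmm = negll(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm) / (
                2 * h**2
            )
    with np.errstate(invalid="ignore"):
        try:
            cov = np.linalg.inv(H)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
    return pd.DataFrame(
        {"item_id": [n[0] for n in names], "parameter": [n[1] for n in names], "se": se}
    )
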