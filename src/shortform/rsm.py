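"""Rating Scale Model (polytomous Rasch family) with missing-by-design data.

The RSM gives an item one difficulty ``beta_i`` and shares a single set of
ordered category thresholds ``tau_1..tau_{m-1}`` across all items:

    P(X_ij = x | theta) = exp( x*theta - x*beta_i - sum_{k<=x} tau_k ) / Z,

for categories x = 0..m-1 (sum over an empty index set is 0).  Estimation
is marginal maximum likelihood by EM: the latent trait is standard normal
(mean fixed at 0), integrated over a fixed grid of quadrature nodes; in
the E-step each respondent's posterior over nodes is computed from their
observed items only, so structurally missing cells ("does not apply")
simply contribute nothing to the likelihood.  Identification fixes the
latent mean at 0 and constrains the thresholds to sum to zero (a constant
can otherwise be traded between the threshold mean and all difficulties).

Standard errors come from the observed information matrix of the item
parameters (numerical Hessian of the marginal log-likelihood); person
scores are EAP (posterior mean), with ML scoring available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess

__all__ = ["RsmFit", "fit_rsm", "rsm_category_probs", "difficulty_comparison"]

QUAD_LO, QUAD_HI, QUAD_N = -6.0, 6.0, 41
EM_TOL = 1e-5
EM_MAX_ITER = 500


def _thresholds_full(tau_free: np.ndarray, m: int) -> np.ndarray:
    """Expand m-2 free thresholds into m-1 summing to zero."""
    if m == 2:
        return np.zeros(1)
    return np.concatenate([tau_free, [-tau_free.sum()]])


def rsm_category_probs(theta, difficulties, thresholds) -> np.ndarray:
    """Category probabilities, shape (n_theta, n_items, m).

    ``thresholds`` are the m-1 shared step parameters (tau_1..tau_{m-1});
    the cumulative sums enter the category logits.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    beta = np.atleast_1d(np.asarray(difficulties, dtype=float))
    tau = np.asarray(thresholds, dtype=float)
    m = tau.size + 1
    x = np.arange(m)
    cum_tau = np.concatenate([[0.0], np.cumsum(tau)])  # sum_{k<=x} tau_k
    # logits[q, i, x] = x*theta_q - x*beta_i - cum_tau[x]
    logits = (
        x[None, None, :] * theta[:, None, None]
        - x[None, None, :] * beta[None, :, None]
        - cum_tau[None, None, :]
    )
    logits -= logits.max(axis=2, keepdims=True)
    ex = np.exp(logits)
    return ex / ex.sum(axis=2, keepdims=True)


@dataclass(frozen=True)
class RsmFit:
    item_ids: list[str]
    item_difficulties: pd.Series
    category_thresholds: np.ndarray  # shared, sum to zero
    difficulty_se: pd.Series
    person_scores: pd.Series  # EAP estimates
    loglik: float
    n_iterations: int
    converged: bool
    excluded_items: list[str]
    loglik_trace: np.ndarray


def fit_rsm(
    responses,
    n_categories: int | None = None,
    item_ids=None,
    respondent_ids=None,
    max_iter: int = EM_MAX_ITER,
    tol: float = EM_TOL,
) -> RsmFit:
    """Fit the RSM by MML/EM on an ordinal matrix with NaN = missing.

    Responses must be coded 0..m-1 (or 1..m, which is shifted down).  Items
    with all observed responses in a single category are inestimable; they
    are excluded with a warning and listed in ``excluded_items``.
    """
    if isinstance(responses, pd.DataFrame):
        item_ids = list(responses.columns) if item_ids is None else list(item_ids)
        respondent_ids = list(responses.index) if respondent_ids is None else list(respondent_ids)
        X = responses.to_numpy(dtype=float)
    else:
        X = np.asarray(responses, dtype=float)
        if item_ids is None:
            item_ids = [f"item{j + 1}" for j in range(X.shape[1])]
        if respondent_ids is None:
            respondent_ids = list(range(X.shape[0]))
    obs = ~np.isnan(X)
    if not obs.any(axis=0).all():
        bad = [item_ids[j] for j in np.flatnonzero(~obs.any(axis=0))]
        raise ValueError(f"item(s) with no observed responses: {bad}")
    if not obs.any(axis=1).all():
        bad = [respondent_ids[r] for r in np.flatnonzero(~obs.any(axis=1))]
        raise ValueError(f"respondent(s) with no observed responses: {bad}")
    lo = np.nanmin(X)
    if lo > 0:  # accept 1-based codes
        X = X - lo
    if n_categories is None:
        n_categories = int(np.nanmax(X)) + 1
    m = int(n_categories)
    if m < 2:
        raise ValueError("need at least 2 categories")

    # drop inestimable items (all observed responses in one category)
    excluded = []
    keep = []
    for j, iid in enumerate(item_ids):
        vals = X[obs[:, j], j]
        if np.unique(vals).size < 2:
            excluded.append(iid)
            warnings.warn(f"item {iid!r} has a single observed category; excluded")
        else:
            keep.append(j)
    if len(keep) < 1:
        raise ValueError("no estimable items")
    X = X[:, keep]
    obs = obs[:, keep]
    kept_ids = [item_ids[j] for j in keep]
    n_persons, n_items = X.shape

    nodes = np.linspace(QUAD_LO, QUAD_HI, QUAD_N)
    wq = stats.norm.pdf(nodes)
    wq = wq / wq.sum()
    log_wq = np.log(wq)
    Xc = np.where(obs, X, 0).astype(int)

    beta = np.zeros(n_items)
    tau_free = np.zeros(max(m - 2, 0))
    n_free = n_items + tau_free.size

    def person_loglik_by_node(beta, tau_full):
        P = rsm_category_probs(nodes, beta, tau_full)  # (Q, items, m)
        logP = np.log(np.clip(P, 1e-300, None))
        # L[q, p] = sum_i obs[p,i] * logP[q, i, Xc[p, i]]
        L = logP[:, np.arange(n_items)[None, :], Xc]  # (Q, n_persons, n_items)
        return np.where(obs[None, :, :], L, 0.0).sum(axis=2)  # (Q, n_persons)

    def marginal_ll(params):
        b = params[:n_items]
        t = _thresholds_full(params[n_items:], m)
        L = person_loglik_by_node(b, t)
        a = L + log_wq[:, None]
        amax = a.max(axis=0)
        return float(np.sum(amax + np.log(np.exp(a - amax).sum(axis=0))))

    trace = []
    ll_old = -np.inf
    converged = False
    it = 0
    post = None
    for it in range(1, max_iter + 1):
        tau_full = _thresholds_full(tau_free, m)
        # E-step
        L = person_loglik_by_node(beta, tau_full)  # (Q, n_persons)
        a = L + log_wq[:, None]
        amax = a.max(axis=0)
        lse = amax + np.log(np.exp(a - amax).sum(axis=0))
        ll = float(lse.sum())
        trace.append(ll)
        post = np.exp(a - lse[None, :])  # (Q, n_persons), columns sum to 1
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
        # expected counts r[q, i, x]
        onehot = np.zeros((n_persons, n_items, m))
        onehot[np.arange(n_persons)[:, None], np.arange(n_items)[None, :], Xc] = 1.0
        onehot *= obs[:, :, None]
        r = np.einsum("qp,pix->qix", post, onehot)

        def neg_q(params):
            b = params[:n_items]
            t = _thresholds_full(params[n_items:], m)
            P = rsm_category_probs(nodes, b, t)
            return -float(np.sum(r * np.log(np.clip(P, 1e-300, None))))

        x0 = np.concatenate([beta, tau_free])
        res = optimize.minimize(neg_q, x0, method="L-BFGS-B")
        beta = res.x[:n_items]
        tau_free = res.x[n_items:]

    tau_full = _thresholds_full(tau_free, m)
    # standard errors from the observed information of the item parameters
    theta_hat = np.concatenate([beta, tau_free])
    H = approx_hess(theta_hat, lambda p: -marginal_ll(p))
    try:
        cov = np.linalg.inv(H)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se_all = np.full(n_free, np.nan)
    se = se_all[:n_items]

    # EAP person scores from the final posterior
    L = person_loglik_by_node(beta, tau_full)
    a = L + log_wq[:, None]
    amax = a.max(axis=0)
    lse = amax + np.log(np.exp(a - amax).sum(axis=0))
    post = np.exp(a - lse[None, :])
    eap = post.T @ nodes

    return RsmFit(
        item_ids=kept_ids,
        item_difficulties=pd.Series(beta, index=kept_ids, name="difficulty"),
        category_thresholds=tau_full,
        difficulty_se=pd.Series(se, index=kept_ids, name="se"),
        person_scores=pd.Series(eap, index=respondent_ids, name="eap"),
        loglik=float(lse.sum()),
        n_iterations=it,
        converged=converged,
        excluded_items=excluded,
        loglik_trace=np.asarray(trace),
    )


def difficulty_comparison(
    fit_a: RsmFit,
    fit_b: RsmFit,
    labels: tuple[str, str] = ("a", "b"),
    sort_by: str | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Aligned per-item difficulty table for two fits (e.g. caregiver vs
    child), with standard errors, sorted by the first fit's difficulty.

    Returns ``(table, dropped)`` where ``dropped`` lists items present in
    only one fit (excluded from the table).
    """
    ids_a, ids_b = set(fit_a.item_ids), set(fit_b.item_ids)
    shared = [i for i in fit_a.item_ids if i in ids_b]
    if not shared:
        raise ValueError("no overlapping items between the two fits")
    dropped = sorted((ids_a | ids_b) - set(shared))
    la, lb = labels
    table = pd.DataFrame(
        {
            f"difficulty_{la}": fit_a.item_difficulties[shared],
            f"se_{la}": fit_a.difficulty_se[shared],
            f"difficulty_{lb}": fit_b.item_difficulties[shared],
            f"se_{lb}": fit_b.difficulty_se[shared],
        }
    )
    table["difference"] = table[f"difficulty_{lb}"] - table[f"difficulty_{la}"]
    key = sort_by or f"difficulty_{la}"
    return table.sort_values(key), dropped
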