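"""Phylogenetic signal statistics for continuous traits.

Four estimators are provided, mirroring the usual comparative toolbox:

- Blomberg's K: ratio of observed to Brownian-expected trait variance
  partitioning; K near 1 under Brownian motion, below 1 for weaker signal.
  Significance by permuting tip labels and ranking the variance of
  phylogenetically independent contrasts.
- Abouheif's C (test for serial independence): Moran-type autocorrelation
  with topology-derived proximities, permutation p-value.
- Pagel's lambda: maximum likelihood over the lambda-scaled covariance,
  likelihood-ratio test against lambda = 0 with the boundary-corrected
  50:50 chi-square mixture.
- Phylogenetic eigenvector regression (PVR): trait regressed on principal
  coordinates of the patristic distance matrix, eigenvectors chosen by the
  broken-stick rule or stepwise AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .phylo import TimeTree, gls_mean, vcv_with_lambda

__all__ = [
    "SignalResult",
    "blomberg_k",
    "abouheif_cmean",
    "abouheif_proximity",
    "pagel_lambda_ml",
    "pvr",
    "broken_stick",
    "independent_contrasts",
    "signal_report",
]


@dataclass
class SignalResult:
    method: str
    statistic: float
    p_value: float
    n_perm: int | None = None
    extras: dict = field(default_factory=dict)


def _aligned(trait: pd.Series, tt: TimeTree) -> tuple[np.ndarray, list[str]]:
    labels = tt.tip_labels
    x = trait.reindex(labels)
    if x.isna().any():
        missing = list(x.index[x.isna()])
        raise ValueError(f"trait missing for tips: {missing}")
    return x.to_numpy(dtype=float), labels


# ---------------------------------------------------------------------------
# Independent contrasts (used by the K permutation test)


def contrast_matrix(tt: TimeTree) -> tuple[np.ndarray, list[str]]:
    """Linear map M with M @ x = Felsenstein's standardized contrasts.

    Contrasts are linear in the tip values, so the whole pruning pass can be
    frozen into an (n-1) x n matrix once per tree; polytomies are resolved
    pairwise in child order.
    """
    tree = tt.tree
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    n = len(leaves)
    index = {id(lf): i for i, lf in enumerate(leaves)}
    from .phylo import BRANCH_FLOOR

    rows: list[np.ndarray] = []
    node_coef: dict[int, np.ndarray] = {}
    node_bl: dict[int, float] = {}
    for nd in tree.postorder_node_iter():
        bl = max(nd.edge.length or 0.0, BRANCH_FLOOR) if nd.parent_node is not None else 0.0
        if nd.is_leaf():
            e = np.zeros(n)
            e[index[id(nd)]] = 1.0
            node_coef[id(nd)] = e
            node_bl[id(nd)] = bl
            continue
        kids = nd.child_nodes()
        v, b = node_coef[id(kids[0])], node_bl[id(kids[0])]
        for k in kids[1:]:
            v2, b2 = node_coef[id(k)], node_bl[id(k)]
            denom = b + b2
            if denom <= 0:
                denom = 1e-12
            rows.append((v - v2) / np.sqrt(denom))
            v = (v * b2 + v2 * b) / denom
            b = b * b2 / denom
        node_coef[id(nd)] = v
        node_bl[id(nd)] = bl + b
    return np.vstack(rows), labels


def independent_contrasts(tt: TimeTree, trait: pd.Series) -> np.ndarray:
    """Felsenstein's standardized contrasts for one trait."""
    M, labels = contrast_matrix(tt)
    return M @ trait.reindex(labels).to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Blomberg's K


def blomberg_k(
    trait: pd.Series, tt: TimeTree, n_perm: int = 999, seed: int | None = None
) -> SignalResult:
    """Blomberg's K with a PIC-variance permutation test.

    K = (MSE0/MSE)_observed / (MSE0/MSE)_expected, with the GLS root
    estimate, MSE0 the trait variance about that root and MSE the
    phylogenetically corrected variance; the expectation depends only on the
    tree.  The permutation p-value ranks the observed variance of
    independent contrasts among tip-shuffled datasets (small variance =
    signal).
    """
    x, labels = _aligned(trait, tt)
    n = len(x)
    if n < 4:
        raise ValueError("need >= 4 tips")
    V = vcv_with_lambda(tt, 1.0).V
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular phylogenetic covariance; consider flooring zero branches"
        ) from exc
    one = np.ones(n)
    a = gls_mean(x, Vinv)
    r = x - a
    mse0 = float(r @ r) / (n - 1)
    mse = float(r @ Vinv @ r) / (n - 1)
    expected = (np.trace(V) - n / float(one @ Vinv @ one)) / (n - 1)
    k = (mse0 / mse) / expected if mse > 0 else np.inf

    if seed is None:
        raise ValueError("seed required for the permutation test")
    rng = np.random.default_rng(seed)
    M, m_labels = contrast_matrix(tt)
    xm = pd.Series(x, index=labels).reindex(m_labels).to_numpy()
    obs_var = float(np.var(M @ xm, ddof=1))
    perms = np.array([rng.permutation(xm) for _ in range(n_perm)])
    if n_perm:
        pv = np.var(M @ perms.T, axis=0, ddof=1)
        count = int(np.sum(pv <= obs_var))
    else:
        count = 0
    p = (count + 1) / (n_perm + 1)
    return SignalResult("K", k, p, n_perm, {"pic_variance": obs_var})


# ---------------------------------------------------------------------------
# Abouheif's C


def abouheif_proximity(tt: TimeTree, row_normalize: bool = True) -> pd.DataFrame:
    """Abouheif proximity: 1 / product of direct-descendant counts of the
    internal nodes along the path between each pair of tips."""
    tree = tt.tree
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    n = len(leaves)
    # path to root for each leaf: list of internal nodes with their dd counts
    anc: list[list[tuple[int, int]]] = []
    for lf in leaves:
        chain = []
        nd = lf.parent_node
        while nd is not None:
            chain.append((id(nd), len(nd.child_nodes())))
            nd = nd.parent_node
        anc.append(chain)
    A = np.zeros((n, n))
    for i in range(n):
        anc_i = dict(anc[i])
        order_i = [nid for nid, _ in anc[i]]
        rank_i = {nid: r for r, nid in enumerate(order_i)}
        for j in range(i + 1, n):
            # MRCA = first ancestor of j that is also an ancestor of i
            mrca = None
            below_j = []
            for nid, dd in anc[j]:
                if nid in anc_i:
                    mrca = nid
                    break
                below_j.append(dd)
            prod = np.prod(below_j) if below_j else 1.0
            prod *= anc_i[mrca]
            for nid, dd in anc[i]:
                if nid == mrca:
                    break
                prod *= dd
            A[i, j] = A[j, i] = 1.0 / prod
    if row_normalize:
        rs = A.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        A = A / rs
    return pd.DataFrame(A, index=labels, columns=labels)


def abouheif_cmean(
    trait: pd.Series, tt: TimeTree, n_perm: int = 999, seed: int | None = None
) -> SignalResult:
    """Abouheif's Cmean: Moran-style autocorrelation with Abouheif proximities.

    Permutation test, greater tail (positive autocorrelation = signal).
    """
    x, labels = _aligned(trait, tt)
    if np.var(x) == 0:
        raise ValueError("zero-variance trait: statistic undefined")
    if seed is None:
        raise ValueError("seed required for the permutation test")
    W = abouheif_proximity(tt).to_numpy()
    rng = np.random.default_rng(seed)

    def moran(v: np.ndarray) -> float:
        vc = v - v.mean()
        return float(vc @ W @ vc / (vc @ vc))

    obs = moran(x)
    count = sum(moran(rng.permutation(x)) >= obs for _ in range(n_perm))
    p = (count + 1) / (n_perm + 1)
    return SignalResult("abouheif_C", obs, p, n_perm)


# ---------------------------------------------------------------------------
# Pagel's lambda


def _lambda_loglik(x: np.ndarray, tt: TimeTree, lam: float) -> float:
    V = vcv_with_lambda(tt, lam).V
    n = len(x)
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vinv = np.linalg.inv(V)
    a = gls_mean(x, Vinv)
    r = x - a
    s2 = float(r @ Vinv @ r) / n
    if s2 <= 0:
        return -np.inf
    return -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)


def pagel_lambda_ml(trait: pd.Series, tt: TimeTree) -> SignalResult:
    """ML estimate of Pagel's lambda in [0, 1] with a boundary-corrected LRT.

    The likelihood profiles sigma2 and the root state out analytically; the
    p-value tests lambda = 0 with the 50:50 chi0:chi1 mixture.  A flat
    profile (star tree) sets the ``unidentifiable`` flag.
    """
    x, _ = _aligned(trait, tt)
    if len(x) < 4:
        raise ValueError("need >= 4 tips")

    def nll(lam: float) -> float:
        return -_lambda_loglik(x, tt, lam)

    grid = np.linspace(0.0, 1.0, 21)
    lls = np.array([-nll(g) for g in grid])
    unident = bool(np.max(lls) - np.min(lls) < 1e-7)
    g0 = grid[int(np.argmax(lls))]
    lo, hi = max(0.0, g0 - 0.05), min(1.0, g0 + 0.05)
    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded")
    lam_hat, ll_hat = float(res.x), -float(res.fun)
    # snap to the better of the boundaries when they dominate
    for b in (0.0, 1.0):
        if -nll(b) >= ll_hat - 1e-10:
            cand = -nll(b)
            if cand > ll_hat:
                lam_hat, ll_hat = b, cand
    ll0 = -nll(0.0)
    lr = max(0.0, 2 * (ll_hat - ll0))
    p = 1.0 if lr == 0 else 0.5 * stats.chi2.sf(lr, df=1)
    return SignalResult(
        "pagel_lambda",
        lam_hat,
        float(p),
        None,
        {"logL": ll_hat, "logL0": ll0, "unidentifiable": unident},
    )


# ---------------------------------------------------------------------------
# Phylogenetic eigenvector regression


def broken_stick(n: int) -> np.ndarray:
    """Broken-stick expected fractions b_k = (1/n) * sum_{i=k..n} 1/i."""
    inv = 1.0 / np.arange(1, n + 1)
    return np.array([inv[k - 1 :].sum() / n for k in range(1, n + 1)])


def _phylo_eigenvectors(tt: TimeTree) -> tuple[np.ndarray, np.ndarray, list[str]]:
    from .phylo import patristic_distances

    D = patristic_distances(tt)
    labels = list(D.index)
    M = D.to_numpy()
    n = len(M)
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ M @ J
    w, U = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    pos = w > max(w.max(), 1e-300) * 1e-10
    return w[pos], U[:, pos], labels


def pvr(
    trait: pd.Series, tt: TimeTree, selection: str = "broken_stick"
) -> SignalResult:
    """Phylogenetic eigenvector regression.

    Principal coordinates of the double-centred patristic distance matrix
    serve as predictors; the broken-stick rule (or stepwise AIC) picks which
    to keep.  Reports R-squared, the overall F-test p, the retained
    eigenvector ids and the cumulative eigenvalue fraction they explain.
    """
    import statsmodels.api as sm

    x, labels = _aligned(trait, tt)
    if len(x) < 5:
        raise ValueError("need >= 5 tips")
    w, U, vec_labels = _phylo_eigenvectors(tt)
    frac = w / w.sum()
    if selection == "broken_stick":
        bs = broken_stick(len(w))
        keep = [i for i in range(len(w)) if frac[i] > bs[i]]
    elif selection == "aic_step":
        keep = []
        remaining = list(range(len(w)))
        cur_aic = sm.OLS(x, np.ones((len(x), 1))).fit().aic
        improved = True
        while improved and remaining:
            improved = False
            best = (cur_aic, None)
            for i in remaining:
                cols = np.column_stack([np.ones(len(x)), U[:, keep + [i]]])
                aic = sm.OLS(x, cols).fit().aic
                if aic < best[0] - 1e-9:
                    best = (aic, i)
            if best[1] is not None:
                keep.append(best[1])
                remaining.remove(best[1])
                cur_aic = best[0]
                improved = True
        keep = sorted(keep)
    else:
        raise ValueError(f"unknown selection {selection!r}")
    if not keep:
        return SignalResult(
            "PVR", 0.0, 1.0, None, {"retained": [], "note": "no eigenvector retained"}
        )
    Xd = np.column_stack([np.ones(len(x)), U[:, keep]])
    fit = sm.OLS(x, Xd).fit()
    extras = {
        "retained": [f"V{i + 1}" for i in keep],
        "cumulative_eigenvalue_fraction": float(frac[keep].sum()),
        "adj_r2": float(fit.rsquared_adj),
        "aic": float(fit.aic),
    }
    p = float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else 1.0
    return SignalResult("PVR", float(fit.rsquared), p, None, extras)


# ---------------------------------------------------------------------------
# Reporting


def signal_report(
    traits: pd.DataFrame, tt: TimeTree, n_perm: int = 999, seed: int = 0
) -> pd.DataFrame:
    """Per-trait summary table of all four signal tests."""
    rows = []
    for j, col in enumerate(traits.columns):
        tr = traits[col]
        for res in (
            blomberg_k(tr, tt, n_perm=n_perm, seed=seed + j),
            abouheif_cmean(tr, tt, n_perm=n_perm, seed=seed + 1000 + j),
            pagel_lambda_ml(tr, tt),
            pvr(tr, tt),
        ):
            rows.append(
                {
                    "trait": col,
                    "method": res.method,
                    "statistic": res.statistic,
                    "p": res.p_value,
                    "n_perm": res.n_perm,
                    **{f"extra_{k}": v for k, v in res.extras.items()},
                }
            )
    return pd.DataFrame(rows)
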