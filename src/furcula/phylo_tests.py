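"""Group tests and model fits that respect phylogenetic covariance.

Classical ANOVA/MANOVA statistics are computed on the raw trait values, but
their null distributions come from Brownian-motion simulation on the tree
(rate estimated from the observed data by GLS), following the
simulation-null approach of Garland et al.  The phylogenetic p-value is the
rank of the observed statistic among the simulated ones.  The same
machinery supplies the null for a phylogenetic Tukey HSD based on the
studentized range.

``fit_evo_models`` ranks Brownian motion, Ornstein-Uhlenbeck, early-burst
and white-noise models of a single trait by AICc; ``phyl_rma`` performs a
reduced major axis regression on GLS (co)variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .phylo import TimeTree, cholesky_psd, gls_mean, vcv_with_lambda

__all__ = [
    "GroupTestResult",
    "phyl_anova",
    "phyl_tukey_hsd",
    "fit_evo_models",
    "phyl_rma",
    "normality_diagnostics",
]


@dataclass
class GroupTestResult:
    statistic_name: str  # "F" or "Wilks"
    statistic: float
    p_ahistorical: float
    p_phylogenetic: float
    n_sim: int
    seed: int
    extras: dict = field(default_factory=dict)


def _group_matrix(groups: pd.Series, labels: list[str]) -> tuple[np.ndarray, list[str]]:
    g = groups.reindex(labels)
    if g.isna().any():
        raise ValueError(f"groups missing for tips: {list(g.index[g.isna()])}")
    levels = sorted(g.unique())
    counts = g.value_counts()
    small = [lv for lv in levels if counts[lv] < 2]
    if small:
        raise ValueError(f"groups with < 2 members: {small}")
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    G = np.zeros((len(levels), len(labels)))
    for i, lv in enumerate(levels):
        G[i] = (g.to_numpy() == lv).astype(float)
    return G, levels


def _f_stats_batch(X: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Univariate one-way F for each row of X (rows = replicates)."""
    n = X.shape[1]
    counts = G.sum(axis=1)
    g = len(counts)
    means = (X @ G.T) / counts  # (reps, g)
    grand = X.mean(axis=1, keepdims=True)
    ssb = (counts * (means - grand) ** 2).sum(axis=1)
    fitted = means @ G  # (reps, n)
    ssw = ((X - fitted) ** 2).sum(axis=1)
    dfb, dfw = g - 1, n - g
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    return np.where(np.isfinite(F), F, 0.0)


def _wilks_f(X: np.ndarray, G: np.ndarray) -> tuple[float, float, float, float]:
    """Wilks' lambda and its Rao F approximation: (lambda, F, df1, df2)."""
    n, p = X.shape
    counts = G.sum(axis=1)
    g = len(counts)
    means = (G @ X) / counts[:, None]
    grand = X.mean(axis=0)
    fitted = G.T @ means
    W = (X - fitted).T @ (X - fitted)
    B = ((means - grand).T * counts) @ (means - grand)
    dfh, dfe = g - 1, n - g
    sign_w, ld_w = np.linalg.slogdet(W)
    sign_t, ld_t = np.linalg.slogdet(W + B)
    if sign_w <= 0 or sign_t <= 0:
        lam = 0.0
    else:
        lam = float(np.exp(ld_w - ld_t))
    denom = p**2 + dfh**2 - 5
    t = np.sqrt((p**2 * dfh**2 - 4) / denom) if denom > 0 else 1.0
    df1 = p * dfh
    df2 = (dfe + dfh - (p + dfh + 1) / 2) * t - (p * dfh - 2) / 2
    lam_t = lam ** (1 / t) if lam > 0 else 0.0
    F = ((1 - lam_t) / lam_t) * (df2 / df1) if lam_t > 0 else np.inf
    return lam, float(F), float(df1), float(df2)


def _gls_rate(X: np.ndarray, Vinv: np.ndarray) -> np.ndarray:
    """GLS evolutionary rate (matrix) of traits X given inverse covariance."""
    n = X.shape[0]
    one = np.ones(n)
    denom = one @ Vinv @ one
    a = (one @ Vinv @ X) / denom
    R = (X - a).T @ Vinv @ (X - a) / (n - 1)
    return np.atleast_2d(R)


def _simulate_null(
    V: np.ndarray, R: np.ndarray, n_sim: int, rng: np.random.Generator
) -> np.ndarray:
    """BM replicate datasets: (n_sim, n_tips, n_traits) with cov V (tips) x R (traits)."""
    n = V.shape[0]
    p = R.shape[0]
    Lv = cholesky_psd(V)
    Lr = cholesky_psd(R + 1e-12 * np.trace(R) / p * np.eye(p))
    Z = rng.standard_normal((n_sim, n, p))
    return Lv @ Z @ Lr.T


def phyl_anova(
    traits: pd.Series | pd.DataFrame,
    groups: pd.Series,
    tt: TimeTree,
    n_sim: int = 999,
    seed: int = 0,
) -> GroupTestResult:
    """Phylogenetic ANOVA (univariate F) or MANOVA (Wilks' lambda -> F).

    The statistic is the classical one; the phylogenetic p-value is its rank
    among ``n_sim`` Brownian-motion simulations on the tree, with the
    evolutionary rate (matrix) estimated from the observed traits by GLS.
    The ahistorical p-value from the F distribution is reported alongside.
    """
    import warnings

    if n_sim < 99:
        warnings.warn("n_sim < 99 gives a very coarse phylogenetic p-value")
    labels = tt.tip_labels
    multi = isinstance(traits, pd.DataFrame) and traits.shape[1] > 1
    Xdf = pd.DataFrame(traits).reindex(labels)
    if Xdf.isna().any().any():
        raise ValueError("traits missing for some tips")
    X = Xdf.to_numpy(dtype=float)
    G, levels = _group_matrix(groups, labels)
    n = len(labels)
    g = len(levels)
    V = vcv_with_lambda(tt, 1.0).V
    Vinv = np.linalg.inv(V)
    R = _gls_rate(X, Vinv)
    rng = np.random.default_rng(seed)
    sims = _simulate_null(V, R, n_sim, rng)

    if multi:
        lam, F_obs, df1, df2 = _wilks_f(X, G)
        p_ahist = float(stats.f.sf(F_obs, df1, df2)) if np.isfinite(F_obs) else 0.0
        count = 0
        for b in range(n_sim):
            _, F_b, _, _ = _wilks_f(sims[b], G)
            if F_b >= F_obs:
                count += 1
        p_phylo = (count + 1) / (n_sim + 1)
        return GroupTestResult(
            "Wilks", lam, p_ahist, p_phylo, n_sim, seed,
            {"F": F_obs, "df1": df1, "df2": df2, "groups": levels},
        )

    x = X[:, 0]
    F_obs = float(_f_stats_batch(x[None, :], G)[0])
    p_ahist = float(stats.f.sf(F_obs, g - 1, n - g))
    F_null = _f_stats_batch(sims[:, :, 0], G)
    p_phylo = (int(np.sum(F_null >= F_obs)) + 1) / (n_sim + 1)
    return GroupTestResult("F", F_obs, p_ahist, p_phylo, n_sim, seed, {"groups": levels})


def phyl_tukey_hsd(
    trait: pd.Series,
    groups: pd.Series,
    tt: TimeTree,
    n_sim: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Phylogenetic Tukey HSD on a single trait.

    The studentized range q (Tukey-Kramer form for unequal group sizes) is
    computed for every group pair; the null distribution of the *maximum* q
    comes from BM simulation, so flagged pairs control the familywise error
    rate at ``alpha``.
    """
    labels = tt.tip_labels
    x = trait.reindex(labels).to_numpy(dtype=float)
    G, levels = _group_matrix(groups, labels)
    counts = G.sum(axis=1)
    n, g = len(x), len(levels)
    V = vcv_with_lambda(tt, 1.0).V
    Vinv = np.linalg.inv(V)
    R = _gls_rate(x[:, None], Vinv)
    rng = np.random.default_rng(seed)
    sims = _simulate_null(V, R, n_sim, rng)[:, :, 0]

    def pair_q(v: np.ndarray) -> np.ndarray:
        means = (G @ v) / counts
        fitted = G.T @ means
        msw = ((v - fitted) ** 2).sum() / (n - g)
        qs = []
        for i, j in combinations(range(g), 2):
            se = np.sqrt(msw / 2 * (1 / counts[i] + 1 / counts[j]))
            qs.append(abs(means[i] - means[j]) / se if se > 0 else 0.0)
        return np.array(qs)

    q_obs = pair_q(x)
    q_null_max = np.array([pair_q(sims[b]).max() for b in range(n_sim)])
    crit = float(np.quantile(q_null_max, 1 - alpha))
    rows = []
    for idx, (i, j) in enumerate(combinations(range(g), 2)):
        p = (int(np.sum(q_null_max >= q_obs[idx])) + 1) / (n_sim + 1)
        rows.append(
            {
                "group1": levels[i],
                "group2": levels[j],
                "q": q_obs[idx],
                "p": p,
                "significant": bool(q_obs[idx] > crit),
            }
        )
    return pd.DataFrame(rows)


def pairwise_grid(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-trait HSD tables into an X/- grid (rows trait x pair)."""
    out = {}
    for trait, tbl in tables.items():
        out[trait] = {
            (r.group1, r.group2): ("X" if r.significant else "-")
            for r in tbl.itertuples()
        }
    pairs = sorted({p for d in out.values() for p in d})
    grid = pd.DataFrame(
        {f"{a}|{b}": [out[t].get((a, b), "-") for t in out] for a, b in pairs},
        index=list(out),
    )
    return grid


# ---------------------------------------------------------------------------
# Evolutionary model selection


def _profile_loglik(x: np.ndarray, C: np.ndarray) -> tuple[float, float, float]:
    """(logL, sigma2_hat, root_hat) for x ~ N(root * 1, sigma2 * C)."""
    n = len(x)
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0:
        return -np.inf, np.nan, np.nan
    Cinv = np.linalg.inv(C)
    a = gls_mean(x, Cinv)
    r = x - a
    s2 = float(r @ Cinv @ r) / n
    if s2 <= 0:
        return -np.inf, s2, a
    ll = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    return ll, s2, a


def _ou_structure(V: np.ndarray, alpha: float) -> np.ndarray:
    d = np.diag(V)
    D = d[:, None] + d[None, :] - 2 * V  # patristic distances
    with np.errstate(over="ignore"):
        C = np.exp(-alpha * D) * (1 - np.exp(-2 * alpha * V)) / (2 * alpha)
    return C


def _eb_structure(V: np.ndarray, a: float) -> np.ndarray:
    return (np.exp(a * V) - 1.0) / a


def aicc(logL: float, k: int, n: int) -> float:
    return -2 * logL + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_evo_models(trait: pd.Series, tt: TimeTree) -> pd.DataFrame:
    """ML fits of BM, OU, EB and white-noise models, ranked by AICc.

    Each model profiles the rate and root state analytically and optimizes
    any remaining shape parameter (OU's alpha, EB's decay) numerically.
    Rows that fail to converge are flagged rather than dropped.
    """
    labels = tt.tip_labels
    x = trait.reindex(labels).to_numpy(dtype=float)
    n = len(x)
    if n < 6:
        raise ValueError("need >= 6 tips")
    V = vcv_with_lambda(tt, 1.0).V
    T = float(np.max(np.diag(V)))
    rows = []

    def add(model: str, ll: float, k: int, params: dict, converged: bool = True) -> None:
        rows.append(
            {
                "model": model,
                "logL": ll,
                "k": k,
                "AICc": aicc(ll, k, n) if np.isfinite(ll) else np.inf,
                "converged": converged,
                **params,
            }
        )

    ll, s2, a0 = _profile_loglik(x, V)
    add("BM", ll, 2, {"sigma2": s2, "root": a0})

    # OU: optimize alpha on log scale
    def ou_nll(log_alpha: float) -> float:
        return -_profile_loglik(x, _ou_structure(V, np.exp(log_alpha)))[0]

    try:
        res = optimize.minimize_scalar(
            ou_nll, bounds=(np.log(1e-6 / T), np.log(50.0 / T)), method="bounded"
        )
        alpha = float(np.exp(res.x))
        ll, s2, a0 = _profile_loglik(x, _ou_structure(V, alpha))
        add("OU", ll, 3, {"sigma2": s2, "root": a0, "alpha": alpha}, res.success)
    except Exception:
        add("OU", -np.inf, 3, {}, False)

    # EB: exponential rate decay, a < 0
    def eb_nll(a: float) -> float:
        return -_profile_loglik(x, _eb_structure(V, a))[0]

    try:
        res = optimize.minimize_scalar(
            eb_nll, bounds=(np.log(1e-5) / T, -1e-8), method="bounded"
        )
        a_hat = float(res.x)
        ll, s2, a0 = _profile_loglik(x, _eb_structure(V, a_hat))
        add("EB", ll, 3, {"sigma2": s2, "root": a0, "a": a_hat}, res.success)
    except Exception:
        add("EB", -np.inf, 3, {}, False)

    ll, s2, a0 = _profile_loglik(x, np.eye(n))
    add("white_noise", ll, 2, {"sigma2": s2, "root": a0})

    df = pd.DataFrame(rows)
    df["dAICc"] = df["AICc"] - df["AICc"].min()
    return df.sort_values("AICc").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Phylogenetic reduced major axis regression


def phyl_rma(x: pd.Series, y: pd.Series, tt: TimeTree) -> dict:
    """Phylogenetic RMA: slope from the ratio of GLS variances, sign from the
    GLS covariance; R^2 and a t-test p-value from the GLS correlation."""
    labels = tt.tip_labels
    xv = x.reindex(labels).to_numpy(dtype=float)
    yv = y.reindex(labels).to_numpy(dtype=float)
    if np.isnan(xv).any() or np.isnan(yv).any():
        raise ValueError("incomplete x/y pairs over the tree tips")
    n = len(xv)
    V = vcv_with_lambda(tt, 1.0).V
    Vinv = np.linalg.inv(V)
    ax, ay = gls_mean(xv, Vinv), gls_mean(yv, Vinv)
    rx, ry = xv - ax, yv - ay
    sxx = float(rx @ Vinv @ rx) / (n - 1)
    syy = float(ry @ Vinv @ ry) / (n - 1)
    sxy = float(rx @ Vinv @ ry) / (n - 1)
    if sxx <= 0:
        raise ValueError("zero GLS variance in x")
    slope = float(np.sign(sxy) if sxy != 0 else 1.0) * np.sqrt(syy / sxx)
    intercept = ay - slope * ax
    r = sxy / np.sqrt(sxx * syy) if syy > 0 else 0.0
    r2 = r**2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        tstat = r * np.sqrt((n - 2) / (1 - r2))
        p = float(2 * stats.t.sf(abs(tstat), n - 2))
    return {"slope": slope, "intercept": intercept, "r2": float(r2), "p": p, "n": n}


# ---------------------------------------------------------------------------
# Distributional diagnostics (report, not a gate)


def normality_diagnostics(traits: pd.DataFrame, groups: pd.Series | None = None) -> dict:
    """Mardia's multivariate skewness/kurtosis tests plus Box's M (if groups).

    Returned as a plain dict of statistics and p-values; the group tests do
    not gate on these.
    """
    X = traits.to_numpy(dtype=float)
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / n
    Sinv = np.linalg.inv(S + 1e-12 * np.eye(p))
    Dm = Xc @ Sinv @ Xc.T
    b1 = float(np.sum(Dm**3)) / n**2
    b2 = float(np.mean(np.diag(Dm) ** 2))
    skew_stat = n * b1 / 6
    skew_df = p * (p + 1) * (p + 2) / 6
    kurt_z = (b2 - p * (p + 2)) / np.sqrt(8 * p * (p + 2) / n)
    out = {
        "mardia_skew": skew_stat,
        "mardia_skew_p": float(stats.chi2.sf(skew_stat, skew_df)),
        "mardia_kurtosis_z": float(kurt_z),
        "mardia_kurtosis_p": float(2 * stats.norm.sf(abs(kurt_z))),
    }
    if groups is not None:
        g = groups.reindex(traits.index)
        levels = sorted(g.unique())
        pooled = np.zeros((p, p))
        dfs = []
        dets = []
        ok = True
        for lv in levels:
            Xi = X[(g == lv).to_numpy()]
            ni = len(Xi)
            if ni < p + 2:
                ok = False
                break
            Si = np.cov(Xi, rowvar=False)
            pooled += (ni - 1) * Si
            dfs.append(ni - 1)
            dets.append(np.linalg.slogdet(Si)[1])
        if ok:
            df_tot = sum(dfs)
            pooled /= df_tot
            M = df_tot * np.linalg.slogdet(pooled)[1] - sum(
                d * ld for d, ld in zip(dfs, dets)
            )
            kg = len(levels)
            c1 = (2 * p**2 + 3 * p - 1) / (6 * (p + 1) * (kg - 1)) * (
                sum(1 / d for d in dfs) - 1 / df_tot
            )
            chi = M * (1 - c1)
            dfm = (kg - 1) * p * (p + 1) / 2
            out["box_m"] = float(M)
            out["box_m_p"] = float(stats.chi2.sf(chi, dfm))
        else:
            out["box_m"] = np.nan
            out["box_m_p"] = np.nan
    return out
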