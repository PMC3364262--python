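"""Phylogenetic flexible discriminant analysis (pFDA).

Trait values of related species are correlated under Brownian motion, which
biases ordinary discriminant analysis.  pFDA removes that bias by whitening
both the predictor matrix and the class-indicator matrix with
C(lambda)^(-1/2), where C is the phylogenetic covariance of the tips and
Pagel's lambda scales its off-diagonals (lambda = 0 recovers ordinary LDA
up to a harmless rescaling on a star tree).  The working lambda is chosen
by maximizing the log-likelihood of the multivariate linear regression of
the whitened indicators on the whitened predictors; discrimination itself
is a linear discriminant fit in the whitened space.

Unknown-class tips are whitened jointly with the training tips under
C(lambda*) over the combined tip set, then classified by the discriminant
refitted on the (jointly) whitened training rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .phylo import TimeTree, vcv_with_lambda

logger = logging.getLogger(__name__)

__all__ = [
    "PFDAModel",
    "ConfusionMatrix",
    "whitening_matrix",
    "optimize_lambda",
    "pfda_train",
    "pfda_predict",
    "lambda_sweep",
    "confusion_summary",
    "loo_accuracy",
]


@dataclass
class PFDAModel:
    lambda_opt: float
    logL_profile: pd.DataFrame  # columns: lambda, logL
    whitener: np.ndarray
    classes: list[str]
    training_ids: list[str]
    training_scores: pd.DataFrame
    training_labels: pd.Series
    lda: LinearDiscriminantAnalysis
    priors: np.ndarray
    flat_profile: bool = False

    def discriminant_coordinates(self) -> pd.DataFrame:
        Xw = self.whitener @ self.training_scores.reindex(self.training_ids).to_numpy()
        Z = self.lda.transform(Xw)
        cols = [f"dv{i + 1}" for i in range(Z.shape[1])]
        return pd.DataFrame(Z, index=self.training_ids, columns=cols)


@dataclass
class ConfusionMatrix:
    counts: pd.DataFrame  # rows = predicted, columns = true
    percent_correct: pd.Series  # per true class, rounded to integer percent
    error_rate: float


def whitening_matrix(C: np.ndarray, jitter: float = 1e-13) -> np.ndarray:
    """Symmetric inverse square root of C via eigendecomposition.

    Eigenvalues are floored only at the level of double-precision roundoff
    (relative ``jitter``), guarding against slightly negative values from
    numerically singular covariances without distorting genuinely small ones.
    """
    w, U = np.linalg.eigh(C)
    floor = max(w.max(), 1e-300) * jitter
    if np.any(w < floor):
        w = np.maximum(w, floor)
    return U @ np.diag(1.0 / np.sqrt(w)) @ U.T


def _indicator(labels: pd.Series, classes: list[str]) -> np.ndarray:
    Y = np.zeros((len(labels), len(classes)))
    for j, c in enumerate(classes):
        Y[:, j] = (labels.to_numpy() == c).astype(float)
    return Y


def _fit_loglik(Xw: np.ndarray, onew: np.ndarray, Yw: np.ndarray, logdet_C: float = 0.0) -> float:
    """Log-likelihood of the multivariate regression of whitened traits on
    whitened class indicators.

    Whitening by C(lambda)^(-1/2) makes this the PGLS likelihood of the
    traits given the classes, so the profile over lambda estimates the
    residual (within-class) phylogenetic signal of the traits.  The last
    indicator column is dropped (linearly dependent on the others plus the
    intercept), keeping the design full rank.
    """
    D = np.column_stack([onew, Yw[:, :-1]])
    n, q = Xw.shape
    beta, *_ = np.linalg.lstsq(D, Xw, rcond=None)
    E = Xw - D @ beta
    S = E.T @ E / n
    sign, logdet = np.linalg.slogdet(S + 1e-300 * np.eye(q))
    if sign <= 0:
        return -np.inf
    # logdet_C is the Jacobian of the whitening transform: without it the
    # likelihoods at different lambda are not on a common scale
    return -0.5 * (n * (q * np.log(2 * np.pi) + logdet + q) + q * logdet_C)


def _aligned_scores(scores: pd.DataFrame, labels_index) -> pd.DataFrame:
    out = scores.reindex(labels_index)
    if out.isna().any().any():
        missing = list(out.index[out.isna().any(axis=1)])
        raise ValueError(f"scores missing for tips: {missing}")
    return out


def optimize_lambda(
    scores: pd.DataFrame,
    labels: pd.Series,
    tt: TimeTree,
    grid: np.ndarray | None = None,
    refine: bool = True,
) -> tuple[float, pd.DataFrame, bool]:
    """Profile log-likelihood over lambda; returns (lambda*, profile, flat_flag).

    ``grid`` defaults to 0..1 in steps of 0.01; the argmax is refined by
    bounded scalar optimization within one grid step.  A profile flat to
    1e-6 (star tree) is flagged and lambda* falls back to the grid argmax.
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0001, 0.01), 10)
    grid = np.asarray(grid, dtype=float)
    if np.any((grid < 0) | (grid > 1)):
        raise ValueError("lambda grid must lie in [0, 1]")
    ids = list(labels.index)
    X = _aligned_scores(scores, ids).to_numpy(dtype=float)
    classes = sorted(labels.unique())
    Y = _indicator(labels, classes)
    sub = _subtree(tt, ids)
    order = sub.tip_labels
    perm = [ids.index(t) for t in order]
    X, Y = X[perm], Y[perm]

    def loglik(lam: float) -> float:
        C = vcv_with_lambda(sub, float(lam)).V
        W = whitening_matrix(C)
        sign, logdet_C = np.linalg.slogdet(C)
        return _fit_loglik(W @ X, W @ np.ones(len(order)), W @ Y, logdet_C)

    lls = np.array([loglik(g) for g in grid])
    profile = pd.DataFrame({"lambda": grid, "logL": lls})
    flat = bool(np.max(lls) - np.min(lls) < 1e-6)
    lam_star = float(grid[int(np.argmax(lls))])
    if refine and not flat and len(grid) > 1:
        step = np.max(np.diff(np.sort(grid)))
        lo, hi = max(0.0, lam_star - step), min(1.0, lam_star + step)
        res = optimize.minimize_scalar(
            lambda v: -loglik(v), bounds=(lo, hi), method="bounded"
        )
        if -res.fun >= lls.max():
            lam_star = float(res.x)
    return lam_star, profile, flat


def _subtree(tt: TimeTree, tips: list[str]) -> TimeTree:
    if set(tips) == set(tt.tip_labels):
        return tt
    sub = tt.copy()
    sub.tree.retain_taxa_with_labels(tips)
    return TimeTree(sub.tree)


def pfda_train(
    scores: pd.DataFrame,
    labels: pd.Series,
    tt: TimeTree,
    lam: float | None = None,
    priors: str = "uniform",
) -> PFDAModel:
    """Train a pFDA model at a given lambda (optimized over a grid if None).

    Class priors default to uniform: the training classes are balanced by
    survey design, not population frequency.  Each class needs >= 2 members.
    """
    ids = list(labels.index)
    counts = labels.value_counts()
    small = sorted(counts.index[counts < 2])
    if small:
        raise ValueError(f"classes with < 2 training tips: {small}")
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    sub = _subtree(tt, ids)
    order = sub.tip_labels
    X = _aligned_scores(scores, order).to_numpy(dtype=float)
    y = labels.reindex(order)
    flat = False
    if lam is None:
        lam, profile, flat = optimize_lambda(scores, labels, tt)
    else:
        _, profile, _ = optimize_lambda(
            scores, labels, tt, grid=np.array([lam]), refine=False
        )
    C = vcv_with_lambda(sub, lam).V
    W = whitening_matrix(C)
    Xw = W @ X
    if np.linalg.matrix_rank(Xw - Xw.mean(axis=0)) < Xw.shape[1]:
        logger.info("collinear whitened predictors; LDA falls back to pseudo-inverse")
    pr = (
        np.full(len(classes), 1.0 / len(classes))
        if priors == "uniform"
        else counts.reindex(classes).to_numpy() / len(y)
    )
    lda = LinearDiscriminantAnalysis(priors=pr)
    lda.fit(Xw, y.to_numpy())
    return PFDAModel(
        lambda_opt=lam,
        logL_profile=profile,
        whitener=W,
        classes=classes,
        training_ids=order,
        training_scores=pd.DataFrame(X, index=order, columns=scores.columns),
        training_labels=y,
        lda=lda,
        priors=pr,
        flat_profile=flat,
    )


def pfda_predict(
    model: PFDAModel,
    scores_unknown: pd.DataFrame,
    tree_full: TimeTree,
    low_posterior: float = 0.5,
) -> pd.DataFrame:
    """Predict classes for unknown tips.

    Training and unknown rows are whitened together under C(lambda*) over
    the combined tip set, the discriminant is refitted on the whitened
    training rows, and unknowns receive the class with the highest
    posterior.  Predictions whose maximum posterior falls below
    ``low_posterior`` are flagged — typically shapes far outside the
    training morphospace.
    """
    unknown_ids = list(scores_unknown.index)
    tips = set(tree_full.tip_labels)
    absent = [t for t in unknown_ids if t not in tips]
    if absent:
        raise ValueError(f"unknown tips missing from tree: {absent}")
    new_ids = [u for u in unknown_ids if u not in set(model.training_ids)]
    all_ids = model.training_ids + new_ids
    sub = _subtree(tree_full, all_ids)
    order = sub.tip_labels
    Xall = pd.concat([model.training_scores, scores_unknown.loc[new_ids]]).reindex(order)
    if Xall.isna().any().any():
        raise ValueError("scores missing for some tips")
    C = vcv_with_lambda(sub, model.lambda_opt).V
    W = whitening_matrix(C)
    Xw = pd.DataFrame(W @ Xall.to_numpy(dtype=float), index=order, columns=Xall.columns)
    train_mask = [t in set(model.training_ids) for t in order]
    lda = LinearDiscriminantAnalysis(priors=model.priors)
    lda.fit(
        Xw.loc[train_mask].to_numpy(),
        model.training_labels.reindex([t for t, m in zip(order, train_mask) if m]).to_numpy(),
    )
    Xu = Xw.loc[unknown_ids].to_numpy()
    post = lda.predict_proba(Xu)
    pred = lda.predict(Xu)
    Z = lda.transform(Xu)
    out = pd.DataFrame(
        {
            "predicted": pred,
            "max_posterior": post.max(axis=1),
            "low_posterior_flag": post.max(axis=1) < low_posterior,
        },
        index=unknown_ids,
    )
    for j, c in enumerate(lda.classes_):
        out[f"posterior_{c}"] = post[:, j]
    for j in range(Z.shape[1]):
        out[f"dv{j + 1}"] = Z[:, j]
    return out


def lambda_sweep(
    scores: pd.DataFrame,
    labels: pd.Series,
    scores_unknown: pd.DataFrame,
    tt: TimeTree,
    grid: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Predicted class of each unknown across a lambda grid.

    Returns the unknown-by-lambda table and a per-unknown stability score
    (fraction of grid values voting for the modal class).
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0001, 0.1), 10)
    grid = np.asarray(grid, dtype=float)
    if np.any((grid < 0) | (grid > 1)):
        raise ValueError("grid must lie in [0, 1]")
    cols = {}
    for lam in grid:
        model = pfda_train(scores, labels, tt, lam=float(lam))
        pred = pfda_predict(model, scores_unknown, tt)
        cols[float(lam)] = pred["predicted"]
    table = pd.DataFrame(cols)
    stability = table.apply(
        lambda row: row.value_counts().iloc[0] / len(row), axis=1
    )
    return table, stability


def confusion_summary(
    true_labels, predicted_labels, classes: list[str] | None = None
) -> ConfusionMatrix:
    """Confusion matrix with columns = true and rows = predicted classes.

    ``percent_correct`` per true class is 100 * diagonal / column sum,
    rounded to the nearest integer percent; ``error_rate`` is
    1 - trace / total.
    """
    t = pd.Series(list(true_labels))
    p = pd.Series(list(predicted_labels))
    if len(t) != len(p):
        raise ValueError("label vectors differ in length")
    if classes is None:
        classes = sorted(set(t) | set(p))
    else:
        stray = sorted((set(t) | set(p)) - set(classes))
        if stray:
            raise ValueError(f"labels outside class set: {stray}")
    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for ti, pi in zip(t, p):
        counts.loc[pi, ti] += 1
    colsum = counts.sum(axis=0)
    diag = pd.Series(np.diag(counts), index=classes)
    with np.errstate(invalid="ignore"):
        # round half up (62.5 -> 63), matching conventional display rounding
        pct = np.floor(100 * diag / colsum.replace(0, np.nan) + 0.5).fillna(0).astype(int)
    total = int(counts.to_numpy().sum())
    err = 1.0 - float(np.trace(counts)) / total if total else 0.0
    return ConfusionMatrix(counts=counts, percent_correct=pct, error_rate=err)


def loo_accuracy(
    scores: pd.DataFrame, labels: pd.Series, tt: TimeTree, lam: float | None = None
) -> float:
    """Leave-one-out classification accuracy of pFDA on the training set."""
    if lam is None:
        lam, _, _ = optimize_lambda(scores, labels, tt)
    hits = 0
    for tip in labels.index:
        tr = labels.drop(tip)
        model = pfda_train(scores.drop(index=tip), tr, tt, lam=lam)
        pred = pfda_predict(model, scores.loc[[tip]], tt)
        hits += int(pred["predicted"].iloc[0] == labels[tip])
    return hits / len(labels)
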