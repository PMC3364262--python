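"""Time-scaled trees, phylogenetic covariance and Brownian-motion simulation.

A :class:`TimeTree` wraps a rooted dendropy tree whose branch lengths are in
millions of years (Ma).  Composite trees assembled from the literature lack
branch lengths, so :func:`scale_to_dates` assigns them from a table of node
and tip ages, sharing undated spans equally.  The phylogenetic covariance of
a Brownian-motion trait is the matrix of shared root-to-ancestor path
lengths; Pagel's lambda scales its off-diagonals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

BRANCH_FLOOR = 1e-8  # Ma; zero-length branches are floored before covariance work


class TreeError(ValueError):
    pass


@dataclass
class TimeTree:
    """Rooted tree with branch lengths in Ma."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            dupes = sorted({t for t in labels if labels.count(t) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def copy(self) -> "TimeTree":
        return TimeTree(self.tree.clone(depth=1))

    # -- depths -----------------------------------------------------------
    def node_depths(self) -> dict[dendropy.Node, float]:
        """Distance from the root to each node (root = 0)."""
        depths: dict[dendropy.Node, float] = {}
        for nd in self.tree.preorder_node_iter():
            if nd.parent_node is None:
                depths[nd] = 0.0
            else:
                depths[nd] = depths[nd.parent_node] + (nd.edge.length or 0.0)
        return depths

    def max_depth(self) -> float:
        d = self.node_depths()
        return max(d[lf] for lf in self.tree.leaf_node_iter())


def parse_newick(text: str) -> TimeTree:
    if text.count("(") != text.count(")"):
        raise TreeError("unbalanced parentheses in newick string")
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True, rooting="force-rooted"
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise TreeError(f"duplicate tip labels: {exc}") from exc
    return TimeTree(tree)


def read_newick(path) -> TimeTree:
    with open(path, encoding="utf-8") as fh:
        return parse_newick(fh.read())


def write_newick(tt: TimeTree) -> str:
    return (
        tt.tree.as_string(
            schema="newick",
            unquoted_underscores=True,
            suppress_rooting=True,
            real_value_format_specifier=".10g",
        ).strip()
    )


# ---------------------------------------------------------------------------
# Time scaling


def scale_to_dates(tt: TimeTree, ages: dict[str, float] | pd.DataFrame) -> TimeTree:
    """Assign branch lengths from node/tip ages (Ma before present, 0 = extant).

    Every tip and the root must be dated (directly or via a labelled internal
    node).  Undated internal nodes are interpolated so that the branches
    between consecutive dated nodes on a path are equal: a node with dated
    parent takes, over its dated descendants, the oldest age consistent with
    even spacing, which keeps parent >= child everywhere.
    """
    if isinstance(ages, pd.DataFrame):
        ages = dict(zip(ages.iloc[:, 0].astype(str), ages.iloc[:, 1].astype(float)))
    out = tt.copy()
    tree = out.tree

    def label_of(nd) -> str | None:
        if nd.taxon is not None:
            return nd.taxon.label
        return nd.label

    age: dict[dendropy.Node, float | None] = {}
    for nd in tree.preorder_node_iter():
        lab = label_of(nd)
        age[nd] = float(ages[lab]) if lab is not None and lab in ages else None
    root = tree.seed_node
    if age[root] is None:
        raise TreeError("root must be dated")
    for lf in tree.leaf_node_iter():
        if age[lf] is None:
            raise TreeError(f"tip {label_of(lf)!r} is undated")
    # consistency among the directly dated
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None or age[nd] is None:
            continue
        anc = nd.parent_node
        while anc is not None and age[anc] is None:
            anc = anc.parent_node
        if anc is not None and age[anc] is not None and age[nd] > age[anc] + 1e-12:
            raise TreeError(
                f"node {label_of(nd) or '<internal>'} (age {age[nd]}) older than "
                f"dated ancestor {label_of(anc) or '<root>'} (age {age[anc]})"
            )

    # Even spacing: if the nearest dated descendant d lies `edges` edges below
    # the dated node nd, each branch on that chain gets (age[nd]-age[d])/edges;
    # taking the max over dated descendants keeps parent >= child on all paths.
    def interpolate(nd: dendropy.Node) -> None:
        for child in nd.child_nodes():
            if age[child] is None:
                best = -np.inf
                stack = [(child, 1)]
                while stack:
                    cur, edges = stack.pop()
                    if age[cur] is not None:
                        cand = age[nd] - (age[nd] - age[cur]) / edges
                        best = max(best, cand)
                    else:
                        for g in cur.child_nodes():
                            stack.append((g, edges + 1))
                age[child] = best
            interpolate(child)

    interpolate(root)
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            ln = age[nd.parent_node] - age[nd]
            nd.edge.length = max(ln, 0.0)
    return TimeTree(tree)


# ---------------------------------------------------------------------------
# Branch-length transforms


def transform_branches(tt: TimeTree, mode: str, param: float = 1.0) -> TimeTree:
    """Standard branch-length transforms.

    - ``grafen``: node height = (descendant tip count - 1), normalized to root
      height 1 and raised to ``param`` (Grafen's rho).
    - ``pagel_equal``: every branch set to 1.
    - ``ou``: Ornstein-Uhlenbeck depth transform with alpha = ``param``; as
      alpha -> 0 it approaches the original lengths.
    - ``power``: each length raised to ``param``.
    """
    out = tt.copy()
    tree = out.tree
    if mode == "pagel_equal":
        for e in tree.preorder_edge_iter():
            if e.head_node.parent_node is not None:
                e.length = 1.0
        return TimeTree(tree)
    if mode == "grafen":
        rho = param
        if rho <= 0:
            raise ValueError("grafen rho must be > 0")
        heights: dict[dendropy.Node, float] = {}
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                heights[nd] = 0.0
            else:
                heights[nd] = len(nd.leaf_nodes()) - 1
        root_h = heights[tree.seed_node]
        if root_h <= 0:
            raise TreeError("grafen transform needs >= 2 tips")
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None:
                hp = (heights[nd.parent_node] / root_h) ** rho
                hc = (heights[nd] / root_h) ** rho
                nd.edge.length = hp - hc
        return TimeTree(tree)
    if mode == "power":
        if param <= 0:
            raise ValueError("power exponent must be > 0")
        for e in tree.preorder_edge_iter():
            if e.head_node.parent_node is not None:
                e.length = (e.length or 0.0) ** param
        return TimeTree(tree)
    if mode == "ou":
        alpha = param
        if alpha <= 0:
            raise ValueError("ou alpha must be > 0")
        depths = out.node_depths()
        T = out.max_depth()
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            d1 = depths[nd.parent_node]
            d2 = depths[nd]
            nd.edge.length = (
                (1.0 / (2 * alpha))
                * np.exp(-2 * alpha * (T - d2))
                * (1.0 - np.exp(-2 * alpha * (d2 - d1)))
            )
        return TimeTree(tree)
    raise ValueError(f"unknown transform mode {mode!r}")


def power_transform_to_bm(tt: TimeTree, trait: pd.Series, grid=None) -> tuple[TimeTree, float]:
    """Pick the branch-length power that maximizes the BM likelihood of a trait.

    The exponent is searched on a grid (default 0.1..3.0 step 0.05); the
    transformed tree and the chosen exponent are returned.
    """
    if grid is None:
        grid = np.arange(0.1, 3.0001, 0.05)
    best = (-np.inf, 1.0)
    for p in grid:
        cand = transform_branches(tt, "power", float(p))
        V = vcv_with_lambda(cand, 1.0)
        ll = _bm_loglik(trait, V)
        if ll > best[0]:
            best = (ll, float(p))
    return transform_branches(tt, "power", best[1]), best[1]


# ---------------------------------------------------------------------------
# Covariance


@dataclass
class PhyloCovariance:
    labels: list[str]
    V: np.ndarray
    lam: float = 1.0

    def matrix(self) -> pd.DataFrame:
        return pd.DataFrame(self.V, index=self.labels, columns=self.labels)


def vcv_with_lambda(tt: TimeTree, lam: float = 1.0) -> PhyloCovariance:
    """Shared root-to-ancestor path-length matrix, off-diagonals scaled by lambda.

    The diagonal holds root-to-tip path lengths and is untouched by lambda.
    Zero-length branches are floored at ``BRANCH_FLOOR`` Ma.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    tree = tt.tree
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    n = len(leaves)
    index = {id(lf): i for i, lf in enumerate(leaves)}
    V = np.zeros((n, n))
    # postorder accumulation: for each node, tips below it share that node's depth
    depths = {}
    below: dict[int, list[int]] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            depths[id(nd)] = 0.0
        else:
            ln = nd.edge.length or 0.0
            depths[id(nd)] = depths[id(nd.parent_node)] + max(ln, BRANCH_FLOOR)
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            i = index[id(nd)]
            below[id(nd)] = [i]
            V[i, i] = depths[id(nd)]
        else:
            kids = [below[id(c)] for c in nd.child_nodes()]
            d = depths[id(nd)]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        V[i, kids[b]] = d
                        V[kids[b], i] = d
            below[id(nd)] = [i for k in kids for i in k]
    if lam != 1.0:
        off = ~np.eye(n, dtype=bool)
        V = V.copy()
        V[off] *= lam
    return PhyloCovariance(labels, V, lam)


def cholesky_psd(V: np.ndarray, jitter: float = 1e-10) -> np.ndarray:
    """Cholesky factor, adding a tiny diagonal jitter if V is numerically singular."""
    try:
        return np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        scale = np.mean(np.diag(V)) or 1.0
        return np.linalg.cholesky(V + jitter * scale * np.eye(len(V)))


def simulate_bm(
    tt: TimeTree,
    sigma2: float = 1.0,
    root_value: float = 0.0,
    n_traits: int = 1,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate Brownian-motion tip values: MVN with covariance sigma2 * V."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if rng is None:
        if seed is None:
            raise ValueError("seed (or rng) required")
        rng = np.random.default_rng(seed)
    pc = vcv_with_lambda(tt, 1.0)
    n = len(pc.labels)
    if sigma2 == 0.0:
        X = np.full((n, n_traits), root_value)
    else:
        L = cholesky_psd(sigma2 * pc.V)
        X = root_value + L @ rng.standard_normal((n, n_traits))
    return pd.DataFrame(X, index=pc.labels, columns=[f"t{i + 1}" for i in range(n_traits)])


# ---------------------------------------------------------------------------
# GLS helpers shared by the statistics modules


def gls_mean(x: np.ndarray, Vinv: np.ndarray) -> float:
    one = np.ones(len(x))
    return float(one @ Vinv @ x / (one @ Vinv @ one))


def _bm_loglik(trait: pd.Series, pc: PhyloCovariance) -> float:
    """Profile BM log-likelihood of a trait (sigma2 and root maximized out)."""
    x = trait.reindex(pc.labels).to_numpy(dtype=float)
    n = len(x)
    Vinv = np.linalg.inv(pc.V)
    a = gls_mean(x, Vinv)
    r = x - a
    s2 = float(r @ Vinv @ r) / n
    sign, logdet = np.linalg.slogdet(pc.V)
    if sign <= 0:
        return -np.inf
    return -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)


def patristic_distances(tt: TimeTree) -> pd.DataFrame:
    """Tip-to-tip path-length matrix."""
    pc = vcv_with_lambda(tt, 1.0)
    d = np.diag(pc.V)
    D = d[:, None] + d[None, :] - 2 * pc.V
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=pc.labels, columns=pc.labels)
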