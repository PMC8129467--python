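"""Phylogenetic signal and ancestral niche estimation under Brownian motion.

Trees are :class:`dendropy.Tree` objects: rooted, strictly bifurcating, with
positive branch lengths. Under Brownian motion (BM) a trait accrues variance
proportionally to elapsed branch length, so the tip values are jointly normal
with covariance ``V[i, j]`` equal to the shared root-to-MRCA path length of
tips i and j.

Blomberg's K compares the observed ratio of among-tip variance to
phylogenetically corrected variance against its BM expectation on the same
tree. K near 1 means the trait diverged roughly as BM predicts (phylogenetic
signal / niche conservatism); K near 0 means relatives are no more similar
than chance; K above 1 means stronger-than-BM conservatism. Significance
comes from a permutation null that shuffles trait values across tips.

Ancestral states are estimated two ways and compared for robustness:
PIC (Felsenstein's independent-contrasts pruning, each node using only its
descendants) and REML (BM rate fitted by residual maximum likelihood, node
states by the conditional normal expectation given all tips).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .grids import GridSpec
from .rasters import RasterLayer

__all__ = [
    "load_tree", "validate_tree", "resolve_polytomies", "label_nodes",
    "phylo_vcv", "node_tip_cov", "blomberg_k", "blomberg_k_test",
    "ace_pic", "ace_reml", "species_niche_values", "summarize_signal",
    "AncestralEstimate",
]


# ---------------------------------------------------------------- tree plumbing

def load_tree(source: str, schema: str = "newick") -> dendropy.Tree:
    """Read and validate a rooted tree from a file path or newick string."""
    if schema == "newick" and source.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=source, schema=schema,
                                 preserve_underscores=True)
    else:
        tree = dendropy.Tree.get(path=source, schema=schema,
                                 preserve_underscores=True)
    validate_tree(tree)
    return tree


def validate_tree(tree: dendropy.Tree) -> None:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("tree has duplicate tip labels")
    if len(labels) < 2:
        raise ValueError("tree needs at least 2 tips")
    for node in tree.preorder_node_iter():
        kids = node.child_nodes()
        if kids and len(kids) != 2:
            raise ValueError(
                "tree is not strictly bifurcating; resolve polytomies first "
                "(see resolve_polytomies)"
            )
        if node.parent_node is not None and (
            node.edge.length is None or node.edge.length <= 0
        ):
            raise ValueError("tree has a missing or non-positive branch length")


def resolve_polytomies(tree: dendropy.Tree, epsilon: float) -> dendropy.Tree:
    """Arbitrarily bifurcate polytomies, giving new edges length ``epsilon``.

    PIC weights diverge at zero branch lengths, so a strictly positive
    epsilon must be supplied deliberately by the caller.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be strictly positive")
    tree = tree.clone(depth=1)
    tree.resolve_polytomies()
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and not node.edge.length:
            node.edge.length = epsilon
    validate_tree(tree)
    return tree


def label_nodes(tree: dendropy.Tree) -> None:
    """Give unlabeled internal nodes stable preorder ids nd1, nd2, ..."""
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        i += 1
        if not node.label:
            node.label = f"nd{i}"


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def _node_depths(tree: dendropy.Tree) -> dict:
    depths = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            depths[node] = depths[node.parent_node] + node.edge.length
    return depths


def phylo_vcv(tree: dendropy.Tree) -> pd.DataFrame:
    """Tip x tip BM covariance matrix V (shared root-to-MRCA path lengths)."""
    validate_tree(tree)
    depths = _node_depths(tree)
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    n = len(leaves)
    index = {lf: i for i, lf in enumerate(leaves)}
    V = np.zeros((n, n))
    # postorder: each internal node is the MRCA of tip pairs drawn from
    # different child subtrees
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = [index[node]]
            V[index[node], index[node]] = depths[node]
            continue
        kids = node.child_nodes()
        left, right = below[kids[0]], below[kids[1]]
        for i in left:
            for j in right:
                V[i, j] = V[j, i] = depths[node]
        below[node] = left + right
    return pd.DataFrame(V, index=labels, columns=labels)


def node_tip_cov(tree: dendropy.Tree) -> pd.DataFrame:
    """Internal-node x tip BM covariances: depth of MRCA(node, tip)."""
    label_nodes(tree)
    depths = _node_depths(tree)
    leaves = list(tree.leaf_node_iter())
    tips = [lf.taxon.label for lf in leaves]
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    # tip sets per node, to find the lowest ancestor of `node` containing a tip
    tipset: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tipset[node] = {node.taxon.label}
        else:
            tipset[node] = set().union(*(tipset[k] for k in node.child_nodes()))
    C = np.zeros((len(internals), len(tips)))
    for r, node in enumerate(internals):
        for c, tip in enumerate(tips):
            anc = node
            while tip not in tipset[anc]:
                anc = anc.parent_node
            C[r, c] = depths[anc]
    return pd.DataFrame(C, index=[nd.label for nd in internals], columns=tips)


def _align_trait(tree: dendropy.Tree, trait: pd.Series):
    """Prune tips lacking a finite trait value; return (tree, ordered values)."""
    trait = pd.Series(trait).astype(float)
    trait = trait[np.isfinite(trait)]
    tips = tip_labels(tree)
    missing_in_tree = set(trait.index) - set(tips)
    if missing_in_tree:
        raise ValueError(f"trait names species not in the tree: {sorted(missing_in_tree)[:5]}")
    keep = [t for t in tips if t in trait.index]
    if len(keep) < len(tips):
        tree = tree.extract_tree_with_taxa_labels(keep)
        tree.purge_taxon_namespace()
        validate_tree(tree)
    x = trait.reindex(tip_labels(tree))
    return tree, x


# ---------------------------------------------------------------- Blomberg's K

def _k_statistics(V: np.ndarray, x: np.ndarray):
    """(K, MSE) for a trait on a BM covariance matrix."""
    n = len(x)
    cf = cho_factor(V)
    Vi1 = cho_solve(cf, np.ones(n))
    denom1 = Vi1.sum()                      # 1' V^-1 1
    a_hat = x @ Vi1 / denom1                # GLS/phylogenetic mean
    r = x - a_hat
    mse0 = r @ r / (n - 1)
    mse = r @ cho_solve(cf, r) / (n - 1)
    if mse <= 0:
        raise ValueError("constant trait: Blomberg's K is undefined")
    expected = (np.trace(V) - n / denom1) / (n - 1)
    return (mse0 / mse) / expected, mse


def blomberg_k(tree: dendropy.Tree, trait: pd.Series) -> float:
    """Blomberg's K of one trait on the tree (tips missing the trait pruned)."""
    tree, x = _align_trait(tree, trait)
    if len(x) < 4:
        raise ValueError("Blomberg's K needs at least 4 tips with data")
    V = phylo_vcv(tree).to_numpy()
    K, _ = _k_statistics(V, x.to_numpy())
    return float(K)


def blomberg_k_test(tree: dendropy.Tree, trait: pd.Series, n_perm: int = 999,
                    seed: int | None = None):
    """(K, p) with a tip-shuffling permutation null.

    The test statistic is the phylogenetically corrected mean squared error:
    traits with signal sit closer to the BM expectation, giving a *low* MSE,
    so p is the (continuity-corrected) fraction of permutations at least as
    low as observed.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    tree, x = _align_trait(tree, trait)
    if len(x) < 4:
        raise ValueError("Blomberg's K needs at least 4 tips with data")
    V = phylo_vcv(tree).to_numpy()
    xv = x.to_numpy()
    K, mse_obs = _k_statistics(V, xv)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        _, mse_p = _k_statistics(V, rng.permutation(xv))
        hits += mse_p <= mse_obs
    p = (1 + hits) / (n_perm + 1)
    return float(K), float(p)


# ------------------------------------------------------- ancestral estimation

@dataclass
class AncestralEstimate:
    """Internal-node states from one method, root first in ``states``."""

    method: str                       # "PIC" | "REML"
    states: pd.Series                 # index = internal node labels (preorder)
    root_state: float
    sigma2: float | None = None       # BM rate (REML only)

    def table(self, tree: dendropy.Tree) -> pd.DataFrame:
        """node_id, parent, age (height above the deepest tip), state, method."""
        label_nodes(tree)
        depths = _node_depths(tree)
        height = max(d for nd, d in depths.items() if nd.is_leaf())
        rows = []
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            rows.append({
                "node_id": node.label,
                "parent": node.parent_node.label if node.parent_node else "",
                "age": height - depths[node],
                "state": self.states[node.label],
                "method": self.method,
            })
        return pd.DataFrame(rows)


def ace_pic(tree: dendropy.Tree, trait: pd.Series) -> AncestralEstimate:
    """Ancestral states by Felsenstein's independent-contrasts pruning.

    Postorder: a node's state is the branch-length-weighted mean of its two
    children's working values, and its own working branch is lengthened by
    b1*b2/(b1+b2) to carry the added uncertainty upward. Each node's estimate
    therefore depends only on its descendants.
    """
    tree, x = _align_trait(tree, trait)
    label_nodes(tree)
    val: dict = {}
    blen: dict = {}
    states = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            val[node] = float(x[node.taxon.label])
            blen[node] = node.edge.length
            continue
        c1, c2 = node.child_nodes()
        b1, b2 = blen[c1], blen[c2]
        v = (val[c1] / b1 + val[c2] / b2) / (1.0 / b1 + 1.0 / b2)
        val[node] = v
        states[node.label] = v
        extra = b1 * b2 / (b1 + b2)
        blen[node] = (node.edge.length or 0.0) + extra
    order = [nd.label for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    states = pd.Series(states).reindex(order)
    return AncestralEstimate("PIC", states, float(states.iloc[0]))


def _reml_sigma2(V: np.ndarray, resid: np.ndarray, denom1: float) -> tuple[float, float]:
    """Maximize the BM restricted log-likelihood in sigma^2 numerically."""
    n = len(resid)
    sign, logdetV = np.linalg.slogdet(V)
    if sign <= 0:
        raise ValueError("phylogenetic covariance matrix is singular")
    cf = cho_factor(V)
    Q = resid @ cho_solve(cf, resid)  # (x - a1)' V^-1 (x - a1)

    def neg_restricted_ll(log_s2: float) -> float:
        s2 = np.exp(log_s2)
        return 0.5 * ((n - 1) * (np.log(2 * np.pi) + log_s2) + logdetV
                      + np.log(denom1) + Q / s2)

    # closed-form optimum is Q/(n-1); bracket it generously so the optimizer
    # cannot silently pin at a bound
    center = np.log(max(Q / (n - 1), 1e-300))
    res = minimize_scalar(neg_restricted_ll, bounds=(center - 20, center + 20),
                          method="bounded", options={"xatol": 1e-12})
    if not res.success:
        raise RuntimeError(f"REML optimizer failed: {res.message}")
    return float(np.exp(res.x)), float(-res.fun)


def ace_reml(tree: dendropy.Tree, trait: pd.Series) -> AncestralEstimate:
    """Ancestral states under BM with the rate fitted by REML.

    Root state is the GLS (phylogenetic) mean of the tips; every internal
    node k is the conditional normal expectation
    ``a + C_k V^-1 (x - a 1)`` with C_k the BM covariances between node k
    and the tips. A constant trait returns the constant with sigma2 = 0.
    """
    tree, x = _align_trait(tree, trait)
    if len(x) < 3:
        raise ValueError("REML ancestral estimation needs at least 3 tips")
    label_nodes(tree)
    Vdf = phylo_vcv(tree)
    V = Vdf.to_numpy()
    xv = x.reindex(Vdf.index).to_numpy()
    n = len(xv)
    cf = cho_factor(V)
    Vi1 = cho_solve(cf, np.ones(n))
    denom1 = Vi1.sum()
    a_hat = xv @ Vi1 / denom1
    resid = xv - a_hat
    order = [nd.label for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    if np.allclose(resid, 0.0):
        states = pd.Series(a_hat, index=order)
        return AncestralEstimate("REML", states, float(a_hat), sigma2=0.0)
    sigma2, _ = _reml_sigma2(V, resid, denom1)
    C = node_tip_cov(tree).reindex(index=order, columns=Vdf.index).to_numpy()
    node_states = a_hat + C @ cho_solve(cf, resid)
    states = pd.Series(node_states, index=order)
    return AncestralEstimate("REML", states, float(a_hat), sigma2=sigma2)


# ------------------------------------------------------------- niche values

def species_niche_values(records: pd.DataFrame, layers: dict[str, RasterLayer],
                         subgrid: GridSpec | None = None) -> pd.DataFrame:
    """Per-species environmental niche values, species x variables.

    Each record is dropped into its fine-grid cell (0.25 degree by default);
    each occupied cell gets the mean of the layer's pixels; the species value
    is the unweighted mean over its occupied cells, so a cell visited by many
    records counts once.
    """
    from .env_layers import cell_summary  # local import to avoid a cycle
    from .occurrences import assign_cells

    subgrid = subgrid or GridSpec(0.25)
    rec = assign_cells(records.drop(columns=["cell_id"], errors="ignore"), subgrid)
    occupied = rec[["species", "cell_id"]].drop_duplicates()
    out = {}
    for name, layer in layers.items():
        per_cell = cell_summary(layer, subgrid, "mean")
        vals = occupied["cell_id"].map(per_cell)
        out[name] = vals.groupby(occupied["species"].to_numpy()).mean()
    table = pd.DataFrame(out)
    dead = table.index[table.isna().any(axis=1)]
    if len(dead):
        warnings.warn(f"{len(dead)} species had no on-raster records and were dropped",
                      stacklevel=2)
        table = table.drop(index=dead)
    table.index.name = "species"
    return table


def summarize_signal(tree: dendropy.Tree, traits: pd.DataFrame, n_perm: int = 999,
                     seed: int | None = None) -> pd.DataFrame:
    """Blomberg's K and permutation p for every trait column."""
    ss = np.random.SeedSequence(seed)
    rows = []
    for child, col in zip(ss.spawn(traits.shape[1]), traits.columns):
        K, p = blomberg_k_test(tree, traits[col], n_perm=n_perm,
                               seed=child.generate_state(1)[0])
        rows.append({"variable": col, "K": K, "p": p, "n_perm": n_perm})
    return pd.DataFrame(rows)
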