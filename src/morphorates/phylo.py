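"""Phylogenetic covariance machinery under Brownian motion (BM).

All comparative statistics in this package share the same linear-model
view of trait evolution: for a rooted tree with branch lengths, tip
values of a BM trait have covariance proportional to the matrix ``C`` of
shared root-to-MRCA path lengths.  This module provides

* :class:`Phylogeny` -- a thin, validated wrapper around a dendropy tree;
* :class:`PhyloCovariance` -- ``C``, its inverse, the inverse symmetric
  square root ``P`` (so ``P C P^T = I``) and the GLS weights for the
  phylogenetic mean;
* multivariate BM simulation along the tree;
* maximum-likelihood (GLS) ancestral states for a univariate trait, with
  per-node variances, and traitgram (time, value) segments built from
  them.

The inverse square root is computed by symmetric eigendecomposition
rather than Cholesky so the transformed residuals are rotation-consistent
across trait blocks.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .errors import DataError, NumericalError

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "phylo_covariance",
    "phylo_gls_mean",
    "transformed_residuals",
    "simulate_bm",
    "ancestral_states",
    "AncestralStateResult",
    "traitgram_coordinates",
]

_ULTRAMETRIC_RTOL = 1e-6
_DEPTH_RATIO_WARN = 1.001


class Phylogeny:
    """A rooted phylogeny with strictly positive branch lengths.

    Wraps a :class:`dendropy.Tree`; validation enforces distinct tip
    labels and a branch length on every non-root edge.  Tip order is the
    order in which tips appear in the newick string and is used as the
    default row order for all comparative statistics.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = []
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise DataError("tree contains an unlabeled tip")
            labels.append(str(leaf.taxon.label))
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise DataError(f"duplicate tip labels: {', '.join(dupes)}")
        if len(labels) < 2:
            raise DataError("tree must have at least 2 tips")
        root = tree.seed_node
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                raise DataError(
                    f"missing branch length on edge above "
                    f"{node.taxon.label if node.taxon else 'an internal node'}"
                )
            if node.edge.length <= 0:
                raise DataError("branch lengths must be strictly positive")
        self.tip_labels: tuple[str, ...] = tuple(labels)
        self._depths: dict[dendropy.Node, float] = {root: 0.0}
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            self._depths[node] = self._depths[node.parent_node] + node.edge.length

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_newick(cls, source: str) -> "Phylogeny":
        """Parse a newick string."""
        try:
            tree = dendropy.Tree.get(
                data=source,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:
            raise DataError(f"could not parse newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_newick(fh.read())

    def newick(self) -> str:
        out = io.StringIO()
        self._tree.write(
            file=out,
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        return out.getvalue().strip()

    # -- basic geometry -----------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def tip_depths(self) -> dict[str, float]:
        return {
            str(leaf.taxon.label): self._depths[leaf]
            for leaf in self._tree.leaf_node_iter()
        }

    @property
    def depth(self) -> float:
        return max(self.tip_depths.values())

    @property
    def is_ultrametric(self) -> bool:
        d = list(self.tip_depths.values())
        return (max(d) - min(d)) <= _ULTRAMETRIC_RTOL * max(d)

    def covariance(self, tip_order=None) -> "PhyloCovariance":
        return phylo_covariance(self, tip_order)

    # -- internal node bookkeeping -----------------------------------------

    def _node_table(self):
        """Postorder nodes with stable ids, depths and tip index sets.

        Tips get their taxon label as id; internal nodes get ``node{k}``
        with ``k`` the postorder index.
        """
        index = {lbl: i for i, lbl in enumerate(self.tip_labels)}
        info = []
        tipsets: dict[dendropy.Node, frozenset[int]] = {}
        for k, node in enumerate(self._tree.postorder_node_iter()):
            if node.is_leaf():
                name = str(node.taxon.label)
                tipsets[node] = frozenset([index[name]])
            else:
                name = f"node{k}"
                tipsets[node] = frozenset().union(
                    *(tipsets[ch] for ch in node.child_nodes())
                )
            info.append((name, node, self._depths[node], tipsets[node]))
        return info, tipsets


@dataclass(frozen=True)
class PhyloCovariance:
    """BM tip covariance ``C`` and derived operators for one tip order."""

    tip_order: tuple[str, ...]
    C: np.ndarray
    C_inv: np.ndarray
    P: np.ndarray  # inverse symmetric square root of C
    gls_weights: np.ndarray  # length-N weights of the phylogenetic mean

    @property
    def n(self) -> int:
        return len(self.tip_order)

    @property
    def trace(self) -> float:
        return float(np.trace(self.C))

    @property
    def one_Cinv_one(self) -> float:
        return float(self.C_inv.sum())


def phylo_covariance(tree: Phylogeny, tip_order=None) -> PhyloCovariance:
    """Shared-path-length covariance matrix and its transforms.

    ``C[i, j]`` is the root-to-MRCA path length of tips i and j; the
    diagonal holds tip depths.  ``P = V diag(w^-1/2) V^T`` from the
    eigendecomposition ``C = V diag(w) V^T``.
    """
    if tree.n_tips < 3:
        raise DataError("comparative statistics need at least 3 tips")
    order = tuple(tip_order) if tip_order is not None else tree.tip_labels
    if sorted(order) != sorted(tree.tip_labels):
        raise DataError("tip_order must be a permutation of the tree's tip labels")
    depths = tree.tip_depths
    if max(depths.values()) / min(depths.values()) > _DEPTH_RATIO_WARN:
        warnings.warn(
            "tree is not ultrametric; rate and signal statistics assume "
            "time-proportional covariance",
            stacklevel=2,
        )
    n = len(order)
    pos = {lbl: i for i, lbl in enumerate(order)}
    C = np.zeros((n, n))
    for lbl, d in depths.items():
        C[pos[lbl], pos[lbl]] = d
    info, tipsets = tree._node_table()
    tip_to_pos = np.array([pos[lbl] for lbl in tree.tip_labels])
    for _, node, depth, _ in info:
        children = node.child_nodes()
        if not children:
            continue
        child_sets = [np.array(sorted(tipsets[ch])) for ch in children]
        for i in range(len(child_sets)):
            for j in range(i + 1, len(child_sets)):
                rows = tip_to_pos[child_sets[i]]
                cols = tip_to_pos[child_sets[j]]
                C[np.ix_(rows, cols)] = depth
                C[np.ix_(cols, rows)] = depth

    w, V = np.linalg.eigh(C)
    if w.min() < 1e-12 * w.max():
        raise NumericalError(
            "phylogenetic covariance is numerically singular "
            f"(condition number {w.max() / max(w.min(), 1e-300):.3e})"
        )
    C_inv = (V / w) @ V.T
    P = (V / np.sqrt(w)) @ V.T
    weights = C_inv.sum(axis=1) / C_inv.sum()
    return PhyloCovariance(order, C, C_inv, P, weights)


def _as_matrix(Y, cov: PhyloCovariance) -> np.ndarray:
    """Align a ShapeMatrix (by labels) or a bare array (assumed aligned)."""
    if hasattr(Y, "reorder"):
        return Y.reorder(list(cov.tip_order)).values
    arr = np.asarray(Y, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] != cov.n:
        raise DataError(
            f"data has {arr.shape[0]} rows but the tree has {cov.n} tips"
        )
    return arr


def phylo_gls_mean(Y, cov: PhyloCovariance) -> np.ndarray:
    """Generalized least squares (phylogenetic) mean of each column."""
    return cov.gls_weights @ _as_matrix(Y, cov)


def transformed_residuals(Y, cov: PhyloCovariance) -> np.ndarray:
    """``U = P (Y - 1 E(Y)^T)``: residuals whitened by the phylogeny."""
    arr = _as_matrix(Y, cov)
    return cov.P @ (arr - cov.gls_weights @ arr)


# ---------------------------------------------------------------------------
# Brownian-motion simulation


def _rate_cholesky(rate_matrix, p: int | None) -> np.ndarray:
    r = np.asarray(rate_matrix, dtype=float)
    if r.ndim == 0:
        if r <= 0 and r != 0:
            raise NumericalError("scalar rate must be non-negative")
        if p is None:
            p = 1
        return np.sqrt(float(r)) * np.eye(p)
    if r.ndim == 1:
        if np.any(r < 0):
            raise NumericalError("per-dimension rates must be non-negative")
        return np.diag(np.sqrt(r))
    if r.shape[0] != r.shape[1]:
        raise NumericalError("rate matrix must be square")
    try:
        return np.linalg.cholesky(r)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("rate matrix is not symmetric positive definite") from exc


def simulate_bm(
    tree: Phylogeny,
    rate_matrix,
    seed=None,
    n_reps: int = 1,
    rng: np.random.Generator | None = None,
    root_state=0.0,
):
    """Simulate multivariate Brownian motion along the tree.

    Increments along each edge are multivariate normal with covariance
    ``branch_length * rate_matrix``; ``rate_matrix`` may be a scalar, a
    vector of per-dimension rates, or a full SPD matrix.  Returns an
    ``(N, p)`` matrix of tip states in ``tree.tip_labels`` order, or
    ``(n_reps, N, p)`` when ``n_reps > 1``.  A fixed ``seed`` makes the
    result reproducible; passing an existing ``rng`` continues its stream.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    r = np.asarray(rate_matrix, dtype=float)
    p = 1 if r.ndim == 0 else r.shape[0]
    L = _rate_cholesky(rate_matrix, p)
    root = tree._tree.seed_node
    states: dict[dendropy.Node, np.ndarray] = {
        root: np.broadcast_to(
            np.asarray(root_state, dtype=float), (n_reps, p)
        ).copy()
    }
    tip_states: dict[str, np.ndarray] = {}
    for node in tree._tree.preorder_node_iter():
        if node is root:
            pass
        else:
            z = rng.standard_normal((n_reps, p))
            states[node] = states[node.parent_node] + np.sqrt(node.edge.length) * (
                z @ L.T
            )
        if node.is_leaf():
            tip_states[str(node.taxon.label)] = states[node]
    out = np.stack([tip_states[lbl] for lbl in tree.tip_labels], axis=1)
    return out[0] if n_reps == 1 else out


# ---------------------------------------------------------------------------
# Ancestral states and traitgrams


@dataclass(frozen=True)
class AncestralStateResult:
    """ML (GLS) ancestral state estimates under BM for a univariate trait.

    ``frame`` has one row per node (tips included) with columns
    ``node``, ``time``, ``estimate``, ``variance``, ``is_tip``; tips carry
    the observed value and zero variance.  The root row equals the
    phylogenetic GLS mean.
    """

    frame: pd.DataFrame
    sigma2: float  # GLS estimate of the BM rate used for the variances

    @property
    def root_estimate(self) -> float:
        root_row = self.frame.loc[self.frame["time"] == 0.0]
        return float(root_row["estimate"].iloc[0])


def ancestral_states(tree: Phylogeny, y, tip_order=None) -> AncestralStateResult:
    """Maximum-likelihood ancestral states of a continuous trait under BM.

    For internal node v with depth ``t_v`` and vector ``c_v`` of shared
    path lengths with the tips, the GLS estimate is
    ``a_v = mu + c_v^T C^{-1} (y - mu)`` with ``mu`` the phylogenetic
    mean, and its variance is
    ``sigma^2 (t_v - c_v^T C^{-1} c_v + (1 - 1^T C^{-1} c_v)^2 / (1^T C^{-1} 1))``
    with ``sigma^2`` estimated by GLS from the tip data.
    """
    cov = tree.covariance(tip_order)
    yv = _as_matrix(y, cov)[:, 0]
    mu = float(cov.gls_weights @ yv)
    resid = yv - mu
    alpha = cov.C_inv @ resid
    n = cov.n
    sigma2 = float(resid @ alpha / (n - 1))

    info, tipsets = tree._node_table()
    pos = {lbl: i for i, lbl in enumerate(cov.tip_order)}
    tree_tip_pos = np.array([pos[lbl] for lbl in tree.tip_labels])

    rows = []
    node_names: dict[dendropy.Node, str] = {}
    for name, node, depth, tipset in info:
        node_names[node] = name
        if node.is_leaf():
            i = pos[name]
            rows.append((name, depth, float(yv[i]), 0.0, True))
            continue
        c_v = np.zeros(n)
        # tips below v share its full depth; tips elsewhere share the depth
        # of the lowest ancestor of v that contains them
        c_v[tree_tip_pos[sorted(tipset)]] = depth
        prev = tipset
        anc = node.parent_node
        while anc is not None:
            newly = tipsets[anc] - prev
            if newly:
                c_v[tree_tip_pos[sorted(newly)]] = tree._depths[anc]
            prev = tipsets[anc]
            anc = anc.parent_node
        est = mu + float(c_v @ alpha)
        h = cov.C_inv @ c_v
        var = sigma2 * (
            depth - float(c_v @ h) + (1.0 - float(h.sum())) ** 2 / cov.one_Cinv_one
        )
        rows.append((name, depth, est, max(var, 0.0), False))

    frame = pd.DataFrame(
        rows, columns=["node", "time", "estimate", "variance", "is_tip"]
    )
    result = AncestralStateResult(frame, sigma2)
    result.frame.attrs["node_names"] = {
        id(node): name for node, name in node_names.items()
    }
    return result


def traitgram_coordinates(tree: Phylogeny, y, tip_order=None) -> pd.DataFrame:
    """Edge segments projecting the tree into (time, trait) space.

    One row per edge, from ``(parent_time, parent_state)`` to
    ``(child_time, child_state)``; tip endpoints carry observed values.
    """
    anc = ancestral_states(tree, y, tip_order)
    values = dict(zip(anc.frame["node"], anc.frame["estimate"]))
    times = dict(zip(anc.frame["node"], anc.frame["time"]))
    info, _ = tree._node_table()
    name_of = {id(node): name for name, node, _, _ in info}
    rows = []
    for name, node, _, _ in info:
        parent = node.parent_node
        if parent is None:
            continue
        pname = name_of[id(parent)]
        rows.append(
            (
                pname,
                name,
                times[pname],
                values[pname],
                times[name],
                values[name],
            )
        )
    return pd.DataFrame(
        rows,
        columns=["parent", "child", "time_parent", "value_parent", "time_child", "value_child"],
    )
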