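"""Branch-specific selection test on region alignments.

A region alignment is scored under a substitution model (JC69 by
default) on a fixed topology whose branch lengths come from a neutral
fit on putatively nonfunctional regions. Two nested models are
compared per region:

* null: all branch lengths scaled by a free region-wide rate r
  (divergence due to drift plus region-level constraint);
* alternative: additionally, the named foreground branch is scaled by a
  free factor zeta.

zeta > 1 indicates acceleration on the foreground branch (candidate
positive selection), zeta < 1 branch-specific constraint. The LRT
statistic 2*(l_alt - l_null) is referred to chi-square with 1 df;
directional p-values are obtained by halving the two-sided p according
to the sign of zeta_hat - 1 (the null value zeta = 1 is interior, so no
boundary mixture applies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


class PhyloTree:
    """Rooted topology with branch lengths and one named foreground branch.

    Nodes are stored in postorder (children before parents); the
    foreground branch is the edge above the node carrying the foreground
    leaf name.
    """

    def __init__(self, newick: str, foreground: str | None = None):
        tree = dendropy.Tree.get(data=newick, schema="newick")
        nodes = list(tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.edge_len = np.zeros(self.n_nodes)
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        self.leaf_index: dict[str, int] = {}
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                self.parent[i] = index[id(nd.parent_node)]
                self.children[self.parent[i]].append(i)
                self.edge_len[i] = nd.edge.length or 0.0
            if nd.is_leaf():
                self.leaf_index[nd.taxon.label] = i
        if np.any(self.edge_len < 0):
            raise ValueError("negative branch length")
        self.root = self.n_nodes - 1
        self.foreground_node: int | None = None
        if foreground is not None:
            self.set_foreground(foreground)

    @property
    def leaves(self) -> list[str]:
        return list(self.leaf_index)

    def set_foreground(self, name: str) -> None:
        if name not in self.leaf_index:
            raise ValueError(f"foreground branch {name!r} not in topology")
        self.foreground_node = self.leaf_index[name]

    def with_edge_lengths(self, edge_len: np.ndarray) -> "PhyloTree":
        out = object.__new__(PhyloTree)
        out.__dict__ = {**self.__dict__}
        out.edge_len = np.asarray(edge_len, dtype=float)
        return out

    def to_newick(self) -> str:
        def fmt(i: int) -> str:
            if not self.children[i]:
                name = next(n for n, j in self.leaf_index.items() if j == i)
                return f"{name}:{self.edge_len[i]:.6f}"
            inner = ",".join(fmt(c) for c in self.children[i])
            if i == self.root:
                return f"({inner});"
            return f"({inner}):{self.edge_len[i]:.6f}"

        return fmt(self.root)


def jc69_transition(t: float) -> np.ndarray:
    """JC69 transition probability matrix for branch length t
    (expected substitutions per site)."""
    e = np.exp(-4.0 * t / 3.0)
    same = 0.25 + 0.75 * e
    diff = 0.25 * (1.0 - e)
    p = np.full((4, 4), diff)
    np.fill_diagonal(p, same)
    return p


def encode_alignment(
    alignment: Mapping[str, str], leaf_names: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse an alignment to unique site patterns with counts.

    Columns containing any gap or ambiguity code are dropped
    (complete-case). Returns (patterns, counts): patterns is
    (n_patterns, n_leaves) with base codes 0..3.
    """
    missing = [n for n in leaf_names if n not in alignment]
    if missing:
        raise ValueError(f"alignment missing rows for leaves: {missing}")
    seqs = [alignment[n].upper() for n in leaf_names]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("alignment rows differ in length")
    mat = np.array([[_BASE_INDEX.get(b, -1) for b in s] for s in seqs], dtype=np.int8)
    ok = (mat >= 0).all(axis=0)
    mat = mat[:, ok]
    if mat.shape[1] == 0:
        return np.empty((0, len(seqs)), dtype=np.int8), np.empty(0, dtype=int)
    patterns, counts = np.unique(mat.T, axis=0, return_counts=True)
    return patterns, counts


def _pattern_loglik(
    patterns: np.ndarray,
    counts: np.ndarray,
    tree: PhyloTree,
    edge_scale: np.ndarray,
) -> float:
    """Felsenstein pruning over collapsed site patterns, JC69.

    edge_scale gives the effective length multiplier of every edge."""
    n_pat = patterns.shape[0]
    if n_pat == 0:
        return 0.0
    partial = np.zeros((tree.n_nodes, n_pat, 4))
    leaf_col = {idx: k for k, name in enumerate(tree.leaf_index) for idx in [tree.leaf_index[name]]}
    for i in range(tree.n_nodes):
        kids = tree.children[i]
        if not kids:
            obs = patterns[:, leaf_col[i]]
            partial[i][np.arange(n_pat), obs] = 1.0
        else:
            acc = np.ones((n_pat, 4))
            for c in kids:
                p = jc69_transition(tree.edge_len[c] * edge_scale[c])
                acc *= partial[c] @ p.T
            partial[i] = acc
    site_lik = partial[tree.root].mean(axis=1)  # stationary frequencies 1/4
    # floor protects the optimizer's line search from -inf at zero-length
    # branches; the floor is far below any attainable site likelihood
    return float(np.sum(counts * np.log(np.maximum(site_lik, 1e-300))))


def region_log_likelihood(
    alignment: Mapping[str, str],
    tree: PhyloTree,
    r: float = 1.0,
    zeta: float = 1.0,
) -> float:
    """Log likelihood of a region alignment with region rate r and
    foreground multiplier zeta (requires a foreground branch when
    zeta != 1)."""
    if r < 0 or zeta < 0:
        raise ValueError("r and zeta must be nonnegative")
    patterns, counts = encode_alignment(alignment, tree.leaves)
    return _loglik_from_patterns(patterns, counts, tree, r, zeta)


def _loglik_from_patterns(patterns, counts, tree: PhyloTree, r: float, zeta: float) -> float:
    scale = np.full(tree.n_nodes, r)
    if tree.foreground_node is not None:
        scale[tree.foreground_node] = r * zeta
    elif zeta != 1.0:
        raise ValueError("zeta != 1 requires a foreground branch")
    return _pattern_loglik(patterns, counts, tree, scale)


def jc_distance(p: float) -> float:
    """JC69 distance for an observed mismatch fraction p (capped just
    below saturation)."""
    p = min(p, 0.74)
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def _jc_start(patterns, counts, topology: PhyloTree, free: np.ndarray) -> np.ndarray:
    """Starting branch lengths: terminal edges get half the smallest JC
    pairwise distance touching the leaf; internal edges a small value."""
    names = topology.leaves
    total = counts.sum()
    dist = {}
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            mism = counts[patterns[:, a] != patterns[:, b]].sum() / total
            dist[(a, b)] = dist[(b, a)] = jc_distance(mism)
    col = {topology.leaf_index[n]: k for k, n in enumerate(names)}
    out = np.full(len(free), 0.01)
    for j, node in enumerate(free):
        if node in col:
            a = col[node]
            out[j] = 0.5 * min(dist[(a, b)] for b in range(len(names)) if b != a)
    return out


def fit_neutral_tree(
    neutral_alignment: Mapping[str, str],
    topology: PhyloTree,
    min_columns: int = 100,
) -> PhyloTree:
    """Maximum-likelihood branch lengths on a fixed topology from a
    (putatively neutral) alignment, JC69, gapped columns excluded.

    For a rooted tree the two edges meeting at the root are not
    separately identifiable under a reversible model; only their sum is.
    The optimizer returns one point on that ridge, which is sufficient
    for all downstream likelihoods.
    """
    if len(topology.leaves) < 3:
        raise ValueError("need at least 3 leaves to fit a tree")
    patterns, counts = encode_alignment(neutral_alignment, topology.leaves)
    if counts.sum() < min_columns:
        raise ValueError(
            f"only {counts.sum()} ungapped columns; need >= {min_columns}"
        )
    free = np.array([i for i in range(topology.n_nodes) if i != topology.root])

    # optimize log branch lengths: keeps the line search away from the
    # -inf wall at zero length and equalizes parameter scales
    lo, hi = np.log(1e-7), np.log(5.0)

    def neg_ll(x):
        lengths = np.zeros(topology.n_nodes)
        lengths[free] = np.exp(x)
        t = topology.with_edge_lengths(lengths)
        return -_pattern_loglik(patterns, counts, t, np.ones(topology.n_nodes))

    # start from per-leaf JC distances (half the smallest pairwise
    # distance touching each leaf; internal edges start small)
    x0 = np.log(np.maximum(_jc_start(patterns, counts, topology, free), 1e-4))
    res = optimize.minimize(
        neg_ll, x0, method="L-BFGS-B", bounds=[(lo, hi)] * len(free),
        options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
    )
    lengths = np.zeros(topology.n_nodes)
    lengths[free] = np.exp(res.x)
    # snap numerically-zero branches to exact zero
    lengths[lengths <= 2e-7] = 0.0
    fitted = topology.with_edge_lengths(lengths)
    logger.info("neutral tree fit: ll = %.2f", -res.fun)
    return fitted


@dataclass
class SelectionResult:
    ocr_id: str
    zeta_hat: float
    r_hat: float
    ll_null: float
    ll_alt: float
    lrt: float
    p: float
    p_accel: float
    p_cons: float
    n_columns: int
    converged: bool = True


def zeta_lrt(
    alignment: Mapping[str, str],
    tree: PhyloTree,
    ocr_id: str = "",
    min_columns: int = 50,
) -> SelectionResult:
    """Likelihood-ratio test for a foreground rate multiplier.

    Null: zeta fixed at 1, region rate r free. Alternative: (r, zeta)
    both free. Two-sided p from chi-square(1); p_accel = p/2 when
    zeta_hat > 1 (else 1 - p/2), and symmetrically for p_cons.
    """
    if tree.foreground_node is None:
        raise ValueError("tree has no foreground branch")
    patterns, counts = encode_alignment(alignment, tree.leaves)
    n_cols = int(counts.sum())
    if n_cols < min_columns:
        raise ValueError(f"only {n_cols} ungapped columns; need >= {min_columns}")

    def nll_null(log_r):
        return -_loglik_from_patterns(patterns, counts, tree, np.exp(log_r), 1.0)

    res0 = optimize.minimize_scalar(
        nll_null, bounds=(np.log(1e-4), np.log(100.0)), method="bounded",
        options={"xatol": 1e-10},
    )
    r_null = float(np.exp(res0.x))
    ll_null = -float(res0.fun)

    def nll_alt(x):
        return -_loglik_from_patterns(
            patterns, counts, tree, np.exp(x[0]), np.exp(x[1])
        )

    starts = [(r_null, 1.0)] + [(a, b) for a in (0.5, 1.0, 2.0) for b in (0.5, 1.0, 2.0)]
    best = None
    bounds = [(np.log(1e-4), np.log(100.0)), (np.log(1e-4), np.log(100.0))]
    converged = False
    for r0, z0 in starts:
        res = optimize.minimize(
            nll_alt,
            np.log([r0, z0]),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-10},
        )
        converged = converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    r_hat, zeta_hat = np.exp(best.x)
    ll_alt = -float(best.fun)
    lrt = max(2.0 * (ll_alt - ll_null), 0.0)
    p = float(stats.chi2.sf(lrt, df=1))
    if zeta_hat > 1:
        p_accel, p_cons = p / 2.0, 1.0 - p / 2.0
    else:
        p_accel, p_cons = 1.0 - p / 2.0, p / 2.0
    if not converged:
        logger.warning("zeta LRT optimizer did not converge for %s", ocr_id)
        return SelectionResult(
            ocr_id, float(zeta_hat), float(r_hat), ll_null, ll_alt, lrt,
            np.nan, np.nan, np.nan, n_cols, converged=False,
        )
    return SelectionResult(
        ocr_id, float(zeta_hat), float(r_hat), ll_null, ll_alt, lrt,
        p, p_accel, p_cons, n_cols,
    )
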