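"""Genomic relationship matrix and population-structure views.

The relationship matrix averages per-locus outer products of
frequency-centred genotype columns scaled by ``4 p (1 - p)``::

    G = (1 / L) * sum_l  Z_l Z_l' / (4 p_l (1 - p_l)),   Z_l = g_l - 2 p_l

On this scale the expected self-relationship of a non-inbred individual
is about one half. ``scale='standard'`` divides by ``2 p (1 - p)``
instead (exactly twice the default), giving the conventional unit
diagonal. Structure views derive from the distance ``1 - G``: a classical
multidimensional scaling embedding of samples and a neighbour-joining
tree of cross-level mean kinships.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .matrix import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class KinshipMatrix:
    """Symmetric relationship matrix with its allele-frequency vector."""

    ids: np.ndarray
    matrix: np.ndarray
    freqs: np.ndarray
    scope: str = "pooled"

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("kinship matrix shape does not match ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("kinship matrix not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)


def compute_grm(
    g: GenotypeMatrix,
    p: Optional[np.ndarray] = None,
    scale: str = "astle",
    scope: str = "pooled",
) -> KinshipMatrix:
    """Build the genomic relationship matrix from complete genotypes.

    Parameters
    ----------
    g
        Complete genotype matrix (no missing entries).
    p
        Allele frequencies per locus; estimated from ``g`` when omitted.
        Every locus must satisfy ``0 < p < 1``.
    scale
        ``'astle'`` (default): per-locus denominator ``4 p (1 - p)``,
        self-relationship about 0.5. ``'standard'``: ``2 p (1 - p)``,
        self-relationship about 1 (exactly twice the default).
    """
    if not g.is_complete:
        raise ValueError("genotypes contain missing entries; impute first")
    codes = g.codes.astype(float)
    if p is None:
        p = codes.mean(axis=0) / 2.0
    else:
        p = np.asarray(p, dtype=float)
        if len(p) != g.n_snps:
            raise ValueError("frequency vector length must match SNP count")
    fixed = (p <= 0.0) | (p >= 1.0)
    if fixed.any():
        bad = list(g.snp_ids[fixed][:5])
        raise ValueError(
            f"{int(fixed.sum())} loci have allele frequency 0 or 1 "
            f"(e.g. {bad}); apply MAF filtering before building G"
        )
    if scale == "astle":
        denom = 4.0 * p * (1.0 - p)
    elif scale == "standard":
        denom = 2.0 * p * (1.0 - p)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    Z = codes - 2.0 * p
    G = (Z / denom) @ Z.T / g.n_snps
    G = (G + G.T) / 2.0
    return KinshipMatrix(ids=g.plant_ids, matrix=G, freqs=p, scope=scope)


def kinship_distance(K: KinshipMatrix) -> np.ndarray:
    """Distance matrix ``1 - G`` with the diagonal forced to zero."""
    D = 1.0 - K.matrix
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


@dataclass
class StructureEmbedding:
    """Principal coordinates of a classical (Torgerson) scaling."""

    coords: np.ndarray       # samples x dims
    eigenvalues: np.ndarray  # all eigenvalues, descending
    shares: np.ndarray       # variance share per retained dim

    @property
    def cumulative_shares(self) -> np.ndarray:
        return np.cumsum(self.shares)


def mds(D: np.ndarray, dims: int = 2) -> StructureEmbedding:
    """Classical multidimensional scaling of a symmetric distance matrix.

    Double-centres ``-0.5 * D**2``, eigendecomposes, and scales
    eigenvectors by the square roots of the positive eigenvalues.
    Variance shares are taken over positive eigenvalues only. Requesting
    more dimensions than there are positive eigenvalues truncates with a
    warning.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    positive = evals > max(1e-12, 1e-12 * abs(evals[0]))
    n_pos = int(positive.sum())
    if dims > n_pos:
        warnings.warn(
            f"requested {dims} dimensions but only {n_pos} positive "
            f"eigenvalues; truncating", stacklevel=2
        )
        dims = n_pos
    lam = evals[:dims]
    coords = evecs[:, :dims] * np.sqrt(lam)
    total = evals[positive].sum()
    shares = lam / total if total > 0 else np.zeros(dims)
    return StructureEmbedding(coords=coords, eigenvalues=evals, shares=shares)


def cross_level_distance(
    K: KinshipMatrix,
    labels: Sequence,
    zero_diagonal: bool = False,
) -> Tuple[List, np.ndarray]:
    """Mean-kinship distances between crosses.

    Between-cross kinship is the mean of ``G[i, j]`` over cross pairs;
    within-cross means use off-diagonal pairs only. Distance is
    ``1 - mean kinship``. Single-sample crosses have no off-diagonal
    pair, so their self term falls back to the diagonal entry (flagged).
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != K.n:
        raise ValueError("labels must match kinship dimension")
    uniq: List = []
    for lab in labels:
        if lab not in uniq:
            uniq.append(lab)
    if len(uniq) < 2:
        raise ValueError("need at least two crosses")
    G = K.matrix
    D = np.zeros((len(uniq), len(uniq)))
    for a, la in enumerate(uniq):
        ia = np.flatnonzero(labels == la)
        for b, lb in enumerate(uniq[: a + 1]):
            ib = np.flatnonzero(labels == lb)
            block = G[np.ix_(ia, ib)]
            if a == b:
                if len(ia) == 1:
                    logger.warning(
                        "cross %s has a single sample; self term uses the "
                        "diagonal", la
                    )
                    mean_k = float(block[0, 0])
                else:
                    off = ~np.eye(len(ia), dtype=bool)
                    mean_k = float(block[off].mean())
            else:
                mean_k = float(block.mean())
            D[a, b] = D[b, a] = 1.0 - mean_k
    if zero_diagonal:
        np.fill_diagonal(D, 0.0)
    return uniq, D


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------


@dataclass
class _Node:
    label: Optional[str]
    children: List[Tuple["_Node", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class NJTree:
    """Unrooted neighbour-joining tree with a Newick serialization."""

    root: _Node
    leaf_names: List[str]

    @property
    def newick(self) -> str:
        return _newick(self.root) + ";"

    def leaf_distances(self) -> Tuple[List[str], np.ndarray]:
        """Path-length distances between every pair of leaves."""
        leaves: List[Tuple[str, float]] = []

        dists = {}

        def walk(node: _Node, acc: float, path: list) -> None:
            if node.is_leaf():
                dists[node.label] = list(path) + [(node, acc)]
            for child, length in node.children:
                walk(child, acc + length, path + [(node, acc)])

        walk(self.root, 0.0, [])
        names = self.leaf_names
        n = len(names)
        D = np.zeros((n, n))
        for i in range(n):
            pi = dists[names[i]]
            nodes_i = {id(nd): d for nd, d in pi}
            for j in range(i + 1, n):
                pj = dists[names[j]]
                # deepest common node
                common = [d for nd, d in pj if id(nd) in nodes_i]
                lca = max(common)
                di = pi[-1][1]
                dj = pj[-1][1]
                D[i, j] = D[j, i] = di + dj - 2 * lca
        return names, D


def _newick(node: _Node) -> str:
    if node.is_leaf():
        return str(node.label)
    parts = [f"{_newick(child)}:{length:.10g}" for child, length in node.children]
    return "(" + ",".join(parts) + ")"


def neighbor_joining(D: np.ndarray, labels: Sequence[str]) -> NJTree:
    """Saitou-Nei agglomeration with the standard Q criterion.

    Ties on Q are broken toward the smallest taxon-index pair; negative
    branch lengths are clamped to zero with a warning. Exact on additive
    distance matrices.
    """
    D = np.asarray(D, dtype=float).copy()
    labels = [str(x) for x in labels]
    n = D.shape[0]
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be square and symmetric")
    if (D < -1e-12).any():
        raise ValueError("distances must be non-negative")
    if not np.allclose(np.diag(D), 0.0, atol=1e-9):
        raise ValueError("distance matrix must have a zero diagonal")
    if len(labels) != n:
        raise ValueError("labels must match distance dimension")

    nodes: List[_Node] = [_Node(lab) for lab in labels]
    active = list(range(n))
    clamped = False

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # first minimum in row-major order = smallest index pair on ties
        flat = int(np.argmin(Q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0 or lj < 0:
            clamped = True
            li, lj = max(li, 0.0), max(lj, 0.0)
        new = _Node(None, [(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to the remaining taxa
        new_row = np.zeros(D.shape[0] + 1)
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (D[i, ak] + D[j, ak] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(new_row) - 1] = new_row[:-1]
        D[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(new)
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]

    i, j = active
    d = D[i, j]
    if d < 0:
        clamped = True
        d = 0.0
    if nodes[i].is_leaf():
        i, j = j, i  # with >= 3 taxa the last merged node is internal
    root = _Node(None, list(nodes[i].children) + [(nodes[j], d)])
    if clamped:
        warnings.warn("negative NJ branch lengths clamped to zero",
                      stacklevel=2)
    return NJTree(root=root, leaf_names=labels)
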