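"""Phylogenies, phylogenetic covariance and Brownian-motion simulation.

The phylogenetic covariance matrix ``C`` has ``C[i, j]`` equal to the shared
root-to-MRCA path length of tips *i* and *j* (and the root-to-tip distance
on the diagonal).  Under Brownian motion with rate ``sigma^2`` a trait's
covariance across tips is ``sigma^2 * C``; Pagel's λ rescales the
off-diagonal entries to interpolate between the star phylogeny (λ = 0) and
the Brownian expectation (λ = 1).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Zero-length terminal branches are replaced by this fraction of tree height
#: so that C stays invertible.
_ZERO_BRANCH_FRACTION = 1e-8


def normalize_tip(name: str) -> str:
    """Canonical tip-name form: stripped, internal whitespace -> underscore."""
    return "_".join(str(name).strip().split())


class TipMismatchError(KeyError):
    """Raised when requested species are absent from the tree."""


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths, wrapping a dendropy tree."""

    tree: dendropy.Tree

    @classmethod
    def from_newick(cls, source: str | Path) -> "Phylogeny":
        """Read a Newick (or NEXUS-embedded) tree from a path or string."""
        text = None
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                        and "(" not in source and Path(str(source)).exists()):
            text = Path(source).read_text()
        else:
            text = str(source)
        schema = "nexus" if text.lstrip().lower().startswith("#nexus") else "newick"
        tree = dendropy.Tree.get(data=text, schema=schema,
                                 preserve_underscores=True)
        return cls(tree=tree)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    @property
    def tip_labels(self) -> list[str]:
        return [normalize_tip(leaf.taxon.label) for leaf in self.tree.leaf_node_iter()]

    def __len__(self) -> int:
        return len(self.tree.leaf_nodes())

    @property
    def height(self) -> float:
        """Maximum root-to-tip path length."""
        depths = self.tree.calc_node_root_distances(return_leaf_distances_only=True)
        return float(max(depths))

    def pruned_to(self, tips) -> "Phylogeny":
        """Copy of the tree retaining only the named tips."""
        wanted = {normalize_tip(t) for t in tips}
        have = set(self.tip_labels)
        missing = sorted(wanted - have)
        if missing:
            raise TipMismatchError(
                f"{len(missing)} species absent from tree: {', '.join(missing)}")
        clone = self.tree.clone(depth=1)
        keep = [leaf.taxon for leaf in clone.leaf_node_iter()
                if normalize_tip(leaf.taxon.label) in wanted]
        clone.retain_taxa(keep)
        return Phylogeny(tree=clone)


@dataclass(frozen=True)
class PhyloCovariance:
    """n x n matrix of shared path lengths with its tip ordering."""

    matrix: np.ndarray
    tips: tuple[str, ...]

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.tips):
            raise ValueError("covariance must be square and match tip count")
        if not np.allclose(m, m.T):
            raise ValueError("covariance must be symmetric")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "tips", tuple(self.tips))

    def reordered(self, tips) -> "PhyloCovariance":
        order = [self.tips.index(normalize_tip(t)) for t in tips]
        return PhyloCovariance(self.matrix[np.ix_(order, order)],
                               tuple(self.tips[i] for i in order))


def phylo_covariance(tree: Phylogeny, tips=None) -> PhyloCovariance:
    """Shared root-to-MRCA path lengths, optionally pruned to a tip subset.

    Zero-length terminal branches are replaced by ``1e-8 x tree height``
    (with a warning) so the matrix stays invertible.
    """
    if tips is not None:
        tree = tree.pruned_to(tips)
    t = tree.tree
    height = tree.height
    bumped = 0
    for leaf in t.leaf_node_iter():
        if not leaf.edge.length:
            leaf.edge.length = _ZERO_BRANCH_FRACTION * max(height, 1.0)
            bumped += 1
    if bumped:
        logger.warning("replaced %d zero-length terminal branches", bumped)

    leaves = list(t.leaf_node_iter())
    labels = [normalize_tip(leaf.taxon.label) for leaf in leaves]
    if len(set(labels)) != len(labels):
        raise ValueError("tip labels are not unique after normalization")
    index = {id(leaf): i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))

    # Postorder sweep: at each internal node of depth d, every pair of tips
    # drawn from two different child subtrees has MRCA depth d.
    depth = {}
    below = {}
    for node in t.preorder_node_iter():
        parent_depth = depth.get(id(node.parent_node), 0.0)
        edge = node.edge.length or 0.0
        depth[id(node)] = parent_depth + edge
    for node in t.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            below[id(node)] = [i]
            C[i, i] = depth[id(node)]
            continue
        groups = [below.pop(id(child)) for child in node.child_nodes()]
        d = depth[id(node)]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    C[a, groups[gj]] = d
                    C[groups[gj], a] = d
        below[id(node)] = [i for g in groups for i in g]

    if tips is not None:
        order = [labels.index(normalize_tip(s)) for s in tips]
        C = C[np.ix_(order, order)]
        labels = [labels[i] for i in order]
    return PhyloCovariance(C, tuple(labels))


def lambda_transform(C: PhyloCovariance | np.ndarray, lam: float):
    """Multiply off-diagonal entries of C by λ, leaving the diagonal fixed."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    if isinstance(C, PhyloCovariance):
        return PhyloCovariance(lambda_transform(C.matrix, lam), C.tips)
    C = np.asarray(C, dtype=float)
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


def simulate_bm(tree: Phylogeny, n_traits: int = 1, rate: float | np.ndarray = 1.0,
                lam: float = 1.0, seed: int | None = None,
                tips=None) -> pd.DataFrame:
    """Simulate traits under λ-transformed Brownian motion on a tree.

    Each trait is an independent multivariate-normal draw across tips with
    covariance ``rate * lambda_transform(C, lam)``.  Reproducible under a
    fixed seed.
    """
    rates = np.broadcast_to(np.asarray(rate, dtype=float), (n_traits,))
    if np.any(rates <= 0):
        raise ValueError("rate must be positive")
    C = phylo_covariance(tree, tips)
    V = lambda_transform(C.matrix, lam)
    # Cholesky with a tiny jitter fallback for semi-definite V (λ = 0 on a
    # star tree is exactly diagonal, so this rarely triggers).
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(V + 1e-12 * np.trace(V) / len(C.tips) * np.eye(len(C.tips)))
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((len(C.tips), n_traits))
    X = L @ Z * np.sqrt(rates)
    return pd.DataFrame(X, index=list(C.tips),
                        columns=[f"trait{i + 1}" for i in range(n_traits)])
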