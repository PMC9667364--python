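"""Multivariate phylogenetic signal: Blomberg's K generalized to K_mult.

K_mult compares the observed dispersion of multivariate trait data around
the phylogenetic (GLS) mean with its phylogenetically corrected dispersion,
scaled by the Brownian-motion expectation of that ratio:

    K = [ tr(E'E) / tr(E' C^-1 E) ] / [ (tr(C) - n / (1' C^-1 1)) / (n - 1) ]

with ``E = X - 1 a'`` where ``a`` is the GLS estimate of the ancestral mean.
K ≈ 1 for data evolved under Brownian motion on the given tree, < 1 when
relatives resemble each other less than Brownian motion predicts, > 1 when
they resemble each other more.  Significance comes from permuting the rows
of the data matrix across the tips of the tree.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo import Phylogeny, PhyloCovariance, normalize_tip, phylo_covariance


class ConstantDataError(ValueError):
    """Raised when the trait matrix has no variation (K undefined)."""


@dataclass(frozen=True)
class KmultResult:
    K: float
    p: float
    n_perm: int
    seed: int
    n: int
    n_traits: int

    def summary(self) -> dict:
        return {"K_mult": self.K, "p": self.p, "n_perm": self.n_perm,
                "seed": self.seed, "n": self.n, "n_traits": self.n_traits}


def _kstat(X: np.ndarray, Cinv: np.ndarray, ones_Cinv: np.ndarray,
           denom_mean: float, expectation: float) -> float:
    a = (ones_Cinv @ X) / denom_mean  # GLS phylogenetic mean, per trait
    E = X - a[None, :]
    num = float(np.einsum("ij,ij->", E, E))
    den = float(np.einsum("ik,ij,jk->", E, Cinv, E))
    if den <= 0 or num <= 0:
        raise ConstantDataError("trait matrix has no usable variation")
    return (num / den) / expectation


def kmult(data: pd.DataFrame, tree: Phylogeny | PhyloCovariance,
          n_perm: int = 999, seed: int | None = None) -> KmultResult:
    """K_mult with a permutation test.

    Parameters
    ----------
    data
        Species-indexed trait matrix (>= 4 species, >= 1 trait column).
    tree
        Phylogeny (pruned to the data) or precomputed covariance.
    n_perm
        Number of row permutations (>= 99); the observed statistic is
        included in the null set, so the smallest attainable p is
        ``1 / (n_perm + 1)``.
    seed
        Seed for the permutation stream (mandatory in pipeline runs).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    data = data.rename(index=normalize_tip).astype(float)
    if data.isna().any().any():
        raise ValueError("trait matrix contains missing values")
    species = list(data.index)
    n, t = data.shape
    if n < 4:
        raise ValueError(f"need >= 4 species, have {n}")
    if isinstance(tree, PhyloCovariance):
        C = tree.reordered(species)
    else:
        C = phylo_covariance(tree, species)
    X = data.to_numpy(dtype=float)
    if np.allclose(X.std(axis=0), 0.0):
        raise ConstantDataError("all trait columns are constant")

    Cm = C.matrix
    Cinv = np.linalg.inv(Cm)
    ones = np.ones(n)
    ones_Cinv = ones @ Cinv
    denom_mean = float(ones_Cinv @ ones)
    expectation = (float(np.trace(Cm)) - n / denom_mean) / (n - 1)

    observed = _kstat(X, Cinv, ones_Cinv, denom_mean, expectation)
    rng = np.random.default_rng(seed)
    hits = 1  # observed statistic counts as a member of the null set
    for _ in range(n_perm):
        perm = rng.permutation(n)
        k = _kstat(X[perm], Cinv, ones_Cinv, denom_mean, expectation)
        if k >= observed:
            hits += 1
    p = hits / (n_perm + 1)
    return KmultResult(K=float(observed), p=float(p), n_perm=n_perm,
                       seed=-1 if seed is None else int(seed),
                       n=n, n_traits=t)
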