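"""Phylogenetic two-block partial least squares (pPLS).

Tests whether two multivariate trait blocks have evolved in a correlated
fashion.  Both blocks are whitened by the phylogeny
(``U = P (Y - 1 E(Y)^T)``), the cross-block covariance
``R12 = U1^T U2 / (N - 1)`` is decomposed by SVD, and the statistic is
the absolute correlation between the first pair of latent scores
(``U1 u1`` and ``U2 v1``).  Significance comes from phylogenetic
permutations in which the whitened rows of one block (the second
argument, by convention) are shuffled across tips and the statistic is
recomputed; whitened rows are exchangeable under the Brownian-motion
null, which keeps the test's size correct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, DegenerateShapeError
from .phylo import PhyloCovariance, Phylogeny, _as_matrix

__all__ = ["PLSResult", "phylo_pls"]


@dataclass(frozen=True)
class PLSResult:
    """First-pair pPLS correlation with its permutation test."""

    pls_corr: float
    p_value: float
    left_vector: np.ndarray  # length p1, unit norm
    right_vector: np.ndarray  # length p2, unit norm
    left_scores: np.ndarray  # length N
    right_scores: np.ndarray  # length N
    n_permutations: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pls_corr": [self.pls_corr],
                "p_value": [self.p_value],
                "n_permutations": [self.n_permutations],
                "seed": [self.seed],
            }
        )


def _abs_corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx <= 0 or sy <= 0:
        raise DegenerateShapeError("constant latent scores; pPLS undefined")
    return float(abs(np.corrcoef(x, y)[0, 1]))


def _first_pair(U1: np.ndarray, U2: np.ndarray):
    """Leading singular pair of the cross-block covariance."""
    r12 = U1.T @ U2 / (U1.shape[0] - 1)
    u, s, vt = np.linalg.svd(r12, full_matrices=False)
    return u[:, 0], vt[0]


def phylo_pls(
    block1,
    block2,
    tree: Phylogeny,
    n_permutations: int = 10000,
    seed: int | None = None,
) -> PLSResult:
    """Phylogenetic two-block PLS with permutation test.

    The left singular vector's largest-magnitude element is made
    positive (the right vector and both score vectors follow), so
    results are sign-deterministic.
    """
    if n_permutations < 1:
        raise DataError("n_permutations must be >= 1")
    cov = tree.covariance()
    if cov.n < 4:
        raise DataError("pPLS needs at least 4 species")
    Y1 = _as_matrix(block1, cov)
    Y2 = _as_matrix(block2, cov)
    for name, arr in (("block1", Y1), ("block2", Y2)):
        if np.allclose(arr, arr[0]):
            raise DegenerateShapeError(f"{name} is constant; pPLS undefined")

    def whiten(arr: np.ndarray) -> np.ndarray:
        return cov.P @ (arr - cov.gls_weights @ arr)

    U1 = whiten(Y1)
    U2 = whiten(Y2)
    u, v = _first_pair(U1, U2)
    i = int(np.argmax(np.abs(u)))
    if u[i] < 0:
        u, v = -u, -v
    s1, s2 = U1 @ u, U2 @ v
    observed = _abs_corr(s1, s2)

    # Permute rows of the *whitened* second block: under the BM null the
    # whitened rows are exchangeable, so the test holds its size.  Shuffling
    # raw rows instead would destroy the phylogenetic structure only in the
    # permuted block while the other keeps it, inflating the type-I error.
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        idx = rng.permutation(cov.n)
        U2p = U2[idx]
        up, vp = _first_pair(U1, U2p)
        if _abs_corr(U1 @ up, U2p @ vp) >= observed:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return PLSResult(
        pls_corr=observed,
        p_value=p,
        left_vector=u,
        right_vector=v,
        left_scores=s1,
        right_scores=s2,
        n_permutations=n_permutations,
        seed=seed,
    )
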