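"""Multivariate phylogenetic signal: the K_mult statistic.

K_mult generalizes Blomberg's K to multivariate traits by replacing
variances with squared Euclidean distances in trait space.  With Y the
(N, p) species matrix, E(Y) the phylogenetic (GLS) mean and
U = P (Y - 1 E(Y)^T) the phylogenetically whitened residuals,

    K_mult = [ sum_i ||Y_i - E(Y)||^2 / sum_i ||U_i||^2 ]
             / [ (tr(C) - N / (1^T C^-1 1)) / (N - 1) ]

The denominator of the second factor is the value the first ratio takes
in expectation under Brownian motion, so K_mult = 1 for BM-evolved data,
smaller values indicate less phylogenetic structure than BM, and larger
values more.  With p = 1 the statistic reduces exactly to univariate
Blomberg's K.  Significance is assessed by permuting species vectors
(whole rows) across the tips of the phylogeny.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .phylo import PhyloCovariance, Phylogeny, _as_matrix

__all__ = ["SignalResult", "kmult", "kmult_test"]


@dataclass(frozen=True)
class SignalResult:
    """K_mult with its permutation null distribution."""

    k_mult: float
    p_value: float
    n_permutations: int
    permuted_values: np.ndarray
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k_mult": [self.k_mult],
                "p_value": [self.p_value],
                "n_permutations": [self.n_permutations],
                "seed": [self.seed],
            }
        )


def _kmult_from_aligned(Yv: np.ndarray, cov: PhyloCovariance) -> float:
    n = cov.n
    mean = cov.gls_weights @ Yv
    resid = Yv - mean
    num = float(np.sum(resid**2))
    U = cov.P @ resid
    den = float(np.sum(U**2))
    tol = 1e-12 * (float(np.sum(Yv**2)) + 1.0)
    if num <= tol or den <= tol:
        raise DataError("trait matrix has zero variance; K_mult undefined")
    expected = (cov.trace - n / cov.one_Cinv_one) / (n - 1)
    return (num / den) / expected


def kmult(Y, tree: Phylogeny, cov: PhyloCovariance | None = None) -> float:
    """Observed K_mult for a species-by-coefficient matrix on a tree."""
    if cov is None:
        cov = tree.covariance()
    if cov.n < 4:
        raise DataError("K_mult needs at least 4 species")
    return _kmult_from_aligned(_as_matrix(Y, cov), cov)


def kmult_test(
    Y,
    tree: Phylogeny,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> SignalResult:
    """Permutation test of phylogenetic signal.

    Each permutation shuffles whole rows of Y across tips, preserving the
    covariance among coefficients within a species, and recomputes
    K_mult.  The p-value uses the (b + 1) / (m + 1) convention, so its
    floor at 1000 permutations is 0.001.
    """
    if n_permutations < 1:
        raise DataError("n_permutations must be >= 1")
    cov = tree.covariance()
    if cov.n < 4:
        raise DataError("K_mult needs at least 4 species")
    Yv = _as_matrix(Y, cov)
    observed = _kmult_from_aligned(Yv, cov)
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_permutations)
    for m in range(n_permutations):
        idx = rng.permutation(cov.n)
        permuted[m] = _kmult_from_aligned(Yv[idx], cov)
    p = (int(np.sum(permuted >= observed)) + 1) / (n_permutations + 1)
    return SignalResult(observed, p, n_permutations, permuted, seed)
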