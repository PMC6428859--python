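"""Multivariate evolutionary rates and rate-ratio tests.

For one trait block the Brownian-motion rate is estimated from the
phylogenetically whitened residuals ``U = P (Y - 1 E(Y)^T)``: writing
``d_i`` for the Euclidean norm of row i of U,

    sigma^2 = sum_i d_i^2 / (N * p)

i.e. the mean squared morphospace distance of species from the
phylogenetic mean, per species and per trait dimension.  Dividing by the
dimension p makes blocks of unequal dimensionality comparable and makes
sigma^2 estimate the per-dimension BM rate directly; when all blocks
share one p (as with 80 Fourier coefficients per trait) every rate ratio
is unaffected by this choice.  ``dim_normalize=False`` restores division
by N alone.

The rate ratio R = max(sigma^2) / min(sigma^2) across blocks is tested
against a simulation null in which all blocks evolve jointly under BM
with a single common (pooled) rate matrix; pairwise block contrasts are
evaluated from the same simulations.  Confidence intervals for each
block's sigma^2 come from bootstrapping the individuals used to compute
species mean shapes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .efa import ShapeMatrix
from .errors import DataError
from .phylo import PhyloCovariance, Phylogeny, _as_matrix, simulate_bm

__all__ = [
    "RateComparisonResult",
    "RateCI",
    "sigma2_mult",
    "compare_rates",
    "bootstrap_sigma2_ci",
]


def _sigma2_from_aligned(
    Yv: np.ndarray, cov: PhyloCovariance, dim_normalize: bool
) -> float:
    resid = Yv - cov.gls_weights @ Yv
    U = cov.P @ resid
    d2 = float(np.sum(U**2))
    denom = cov.n * Yv.shape[1] if dim_normalize else cov.n
    return d2 / denom


def sigma2_mult(
    Y,
    tree: Phylogeny,
    cov: PhyloCovariance | None = None,
    dim_normalize: bool = True,
) -> float:
    """Multivariate evolutionary rate of one block on a tree."""
    if cov is None:
        cov = tree.covariance()
    Yv = _as_matrix(Y, cov)
    if Yv.size == 0:
        raise DataError("empty trait block")
    return _sigma2_from_aligned(Yv, cov, dim_normalize)


@dataclass(frozen=True)
class RateComparisonResult:
    """Per-block rates, global rate ratio and simulation p-values."""

    sigma2: dict
    rate_ratio: float
    p_value: float
    pairwise_p: dict  # keys: (block_a, block_b) tuples, both orders resolvable
    null_ratios: np.ndarray
    n_simulations: int
    seed: int | None
    dim_normalize: bool = True

    def pairwise(self, a: str, b: str) -> float:
        if (a, b) in self.pairwise_p:
            return self.pairwise_p[(a, b)]
        return self.pairwise_p[(b, a)]

    def to_frame(self) -> pd.DataFrame:
        rows = [("sigma2", name, value) for name, value in self.sigma2.items()]
        rows.append(("rate_ratio", "all", self.rate_ratio))
        rows.append(("p_value", "all", self.p_value))
        for (a, b), p in self.pairwise_p.items():
            rows.append(("pairwise_p", f"{a}|{b}", p))
        return pd.DataFrame(rows, columns=["quantity", "block", "value"])


@dataclass(frozen=True)
class RateCI:
    """Percentile bootstrap confidence interval for one block's sigma^2."""

    block: str
    point: float
    lower: float
    upper: float
    level: float
    n_boot: int


def _collect_blocks(blocks) -> list[ShapeMatrix]:
    if isinstance(blocks, Mapping):
        items = list(blocks.values())
    else:
        items = list(blocks)
    if len(items) < 2:
        raise DataError("compare_rates needs at least 2 blocks")
    names = [b.block for b in items]
    if len(set(names)) != len(names):
        raise DataError("blocks must have distinct names")
    tip_sets = {frozenset(b.row_labels) for b in items}
    if len(tip_sets) != 1:
        raise DataError("all blocks must cover the same set of species")
    return items


def compare_rates(
    blocks,
    tree: Phylogeny,
    n_simulations: int = 1000,
    seed: int | None = None,
    dim_normalize: bool = True,
) -> RateComparisonResult:
    """Compare multivariate evolutionary rates across trait blocks.

    ``blocks`` is a sequence (or mapping name -> block) of species-level
    :class:`ShapeMatrix` objects sharing one species set.  The null
    distribution of the rate ratio is generated by simulating all blocks
    jointly under BM with a single pooled per-dimension rate (rate
    equality is precisely the null hypothesis being tested); p-values use
    the (b + 1) / (m + 1) convention.
    """
    if n_simulations < 1:
        raise DataError("n_simulations must be >= 1")
    items = _collect_blocks(blocks)
    cov = tree.covariance()
    aligned = [_as_matrix(b, cov) for b in items]
    names = [b.block for b in items]
    dims = [a.shape[1] for a in aligned]
    n = cov.n

    d2 = []
    for arr in aligned:
        resid = arr - cov.gls_weights @ arr
        d2.append(float(np.sum((cov.P @ resid) ** 2)))
    sigma2 = {
        name: (val / (n * p) if dim_normalize else val / n)
        for name, val, p in zip(names, d2, dims)
    }
    values = np.array(list(sigma2.values()))
    observed_ratio = float(values.max() / values.min())

    # pooled per-dimension rate for the common-rate null
    p_total = sum(dims)
    pooled = sum(d2) / (n * p_total)

    sims = simulate_bm(tree, pooled * np.ones(p_total), seed=seed, n_reps=n_simulations)
    # whiten every replicate: U_r = P (X_r - 1 w X_r)
    means = np.einsum("j,rjk->rk", cov.gls_weights, sims)
    U = np.einsum("ij,rjk->rik", cov.P, sims - means[:, None, :])
    null_sigma2 = np.empty((n_simulations, len(items)))
    offset = 0
    for b, p in enumerate(dims):
        block_d2 = np.sum(U[:, :, offset : offset + p] ** 2, axis=(1, 2))
        null_sigma2[:, b] = block_d2 / (n * p if dim_normalize else n)
        offset += p
    null_ratios = null_sigma2.max(axis=1) / null_sigma2.min(axis=1)
    p_global = (int(np.sum(null_ratios >= observed_ratio)) + 1) / (n_simulations + 1)

    pairwise = {}
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            pair = np.array([values[i], values[j]])
            obs = pair.max() / pair.min()
            null_pair = np.maximum(
                null_sigma2[:, i] / null_sigma2[:, j],
                null_sigma2[:, j] / null_sigma2[:, i],
            )
            pairwise[(names[i], names[j])] = (
                int(np.sum(null_pair >= obs)) + 1
            ) / (n_simulations + 1)

    return RateComparisonResult(
        sigma2=sigma2,
        rate_ratio=observed_ratio,
        p_value=p_global,
        pairwise_p=pairwise,
        null_ratios=null_ratios,
        n_simulations=n_simulations,
        seed=seed,
        dim_normalize=dim_normalize,
    )


def bootstrap_sigma2_ci(
    specimen_blocks,
    tree: Phylogeny,
    species_of: Mapping[str, str],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    dim_normalize: bool = True,
) -> list[RateCI]:
    """Bootstrap confidence intervals for sigma^2 over individuals.

    Each iteration resamples specimens within species with replacement,
    recomputes species mean shapes and sigma^2; the interval is the
    percentile interval of the bootstrap distribution.

    Parameters
    ----------
    specimen_blocks:
        Mapping or sequence of specimen-level :class:`ShapeMatrix`
        objects (row labels are specimen ids).
    species_of:
        Mapping specimen id -> species label.
    """
    if not 0 < level < 1:
        raise DataError("level must be in (0, 1)")
    if isinstance(specimen_blocks, Mapping):
        items = list(specimen_blocks.values())
    else:
        items = list(specimen_blocks)
    cov = tree.covariance()
    rng = np.random.default_rng(seed)
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    out = []
    for block in items:
        groups: dict[str, list[int]] = {}
        for i, sid in enumerate(block.row_labels):
            if sid not in species_of:
                raise DataError(
                    f"specimen {sid!r} in block {block.block!r} has no species"
                )
            groups.setdefault(str(species_of[sid]), []).append(i)
        missing = [t for t in cov.tip_order if t not in groups]
        if missing:
            raise DataError(
                f"block {block.block!r}: no specimens for species: "
                + ", ".join(missing)
            )
        group_idx = [np.array(groups[t]) for t in cov.tip_order]
        vals = block.values
        point_means = np.vstack([vals[g].mean(axis=0) for g in group_idx])
        point = _sigma2_from_aligned(point_means, cov, dim_normalize)
        boots = np.empty(n_boot)
        means = np.empty_like(point_means)
        for b in range(n_boot):
            for s, g in enumerate(group_idx):
                take = g[rng.integers(0, len(g), size=len(g))]
                means[s] = vals[take].mean(axis=0)
            boots[b] = _sigma2_from_aligned(means, cov, dim_normalize)
        out.append(
            RateCI(
                block=block.block,
                point=point,
                lower=float(np.quantile(boots, lo_q)),
                upper=float(np.quantile(boots, hi_q)),
                level=level,
                n_boot=n_boot,
            )
        )
    return out
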