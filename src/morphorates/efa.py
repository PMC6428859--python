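"""Elliptic Fourier analysis (EFA) of closed 2D outlines.

A closed outline traced around a structure (a genital sclerite, a tibia)
is decomposed into a sum of harmonic ellipses.  With the outline treated
as a closed polygon parameterized by cumulative chord length ``t`` with
perimeter ``T``, the coordinate functions are expanded as

    x(t) = A0 + sum_n a_n cos(2 pi n t / T) + b_n sin(2 pi n t / T)
    y(t) = C0 + sum_n c_n cos(2 pi n t / T) + d_n sin(2 pi n t / T)

so each harmonic ``n`` contributes one quadruple ``(a_n, b_n, c_n, d_n)``
and twenty harmonics give an 80-dimensional shape descriptor.  For a
piecewise-linear contour the Fourier integrals have an exact closed form
(the classical chord-length formulation), which is what this module
implements; no resampling is required for polygonal input.

Size normalization divides every harmonic by the magnitude of the
first-harmonic semi-major axis, making coefficients invariant to scale
(and, with the DC terms dropped, to translation).  Full normalization
additionally removes rotation and starting-point phase using the
first-harmonic orientation angles.

The module also provides outline reconstruction from coefficients,
polygon (shoelace) area, assembly of per-specimen coefficient matrices,
species mean shapes, and a centered PCA of coefficient matrices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DataError, DegenerateShapeError, InvalidOutlineError

logger = logging.getLogger(__name__)

__all__ = [
    "Outline",
    "HarmonicCoefficientSet",
    "ShapeMatrix",
    "ShapePCAResult",
    "compute_efa",
    "normalize_coefficients",
    "reconstruct_outline",
    "outline_area",
    "flatten",
    "assemble_block",
    "species_mean_shapes",
    "shape_pca",
    "coefficient_column_labels",
]


# ---------------------------------------------------------------------------
# Outline container


@dataclass(frozen=True)
class Outline:
    """A closed polygonal outline: ordered (x, y) vertices, implicitly closed.

    On construction the vertex list is cleaned: an explicit closing
    duplicate of the first vertex is dropped and consecutive identical
    points are merged.  At least 3 distinct vertices and a positive
    perimeter are required.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidOutlineError(
                f"outline points must be a (K, 2) array, got shape {pts.shape}"
            )
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) > 1:
            keep = np.ones(len(pts), dtype=bool)
            keep[1:] = ~np.all(np.isclose(pts[1:], pts[:-1]), axis=1)
            pts = pts[keep]
        if len(pts) < 3:
            raise InvalidOutlineError(
                f"outline needs at least 3 distinct points, got {len(pts)}"
            )
        pts = np.ascontiguousarray(pts)
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)
        if self.perimeter <= 0:
            raise InvalidOutlineError("outline has zero perimeter")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def _chords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-edge (dx, dy, dt) including the closing edge."""
        closed = np.vstack([self.points, self.points[:1]])
        d = np.diff(closed, axis=0)
        dt = np.hypot(d[:, 0], d[:, 1])
        return d[:, 0], d[:, 1], dt

    @property
    def perimeter(self) -> float:
        return float(self._chords[2].sum())

    @property
    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        x1, y1 = np.roll(x, -1), np.roll(y, -1)
        return float(0.5 * np.sum(x * y1 - x1 * y))

    @property
    def is_counterclockwise(self) -> bool:
        return self.signed_area > 0

    def reversed(self) -> "Outline":
        return Outline(self.points[::-1].copy())

    def cycled(self, start: int) -> "Outline":
        """Same polygon traversed from a different starting vertex."""
        return Outline(np.roll(self.points, -start, axis=0))


def outline_area(outline: Outline) -> float:
    """Absolute shoelace area of the outline polygon.

    Self-intersecting polygons still return the (absolute) shoelace value,
    with a warning, since digitization slips occasionally produce small
    bow-ties that are harmless for shape description.
    """
    area = abs(outline.signed_area)
    try:  # pragma: no cover - availability guard
        from shapely.geometry import LinearRing

        if not LinearRing(outline.points).is_simple:
            logger.warning(
                "outline is self-intersecting; shoelace area may not equal "
                "the enclosed area"
            )
    except ImportError:
        pass
    return area


# ---------------------------------------------------------------------------
# Harmonic coefficients


@dataclass(frozen=True)
class HarmonicCoefficientSet:
    """DC terms plus per-harmonic quadruples (a_n, b_n, c_n, d_n).

    ``normalization`` is one of ``"raw"``, ``"size"`` or ``"full"``.
    """

    a0: float
    c0: float
    harmonics: np.ndarray  # (n_harmonics, 4) columns a, b, c, d
    normalization: str = "raw"

    def __post_init__(self) -> None:
        h = np.asarray(self.harmonics, dtype=float)
        if h.ndim != 2 or h.shape[1] != 4 or h.shape[0] < 1:
            raise DataError(f"harmonics must be (N_h, 4), got {h.shape}")
        if self.normalization not in ("raw", "size", "full"):
            raise DataError(f"unknown normalization {self.normalization!r}")
        h = np.ascontiguousarray(h)
        h.setflags(write=False)
        object.__setattr__(self, "harmonics", h)

    @property
    def n_harmonics(self) -> int:
        return self.harmonics.shape[0]

    def flatten(self) -> np.ndarray:
        """Coefficient vector in column order a1,b1,c1,d1,a2,... (length 4*N_h)."""
        return self.harmonics.ravel().copy()

    def first_harmonic_ellipse(self) -> tuple[float, float, float]:
        """Return (magnitude E, start-point phase theta, rotation psi).

        E is the semi-major axis length of the first-harmonic ellipse;
        theta is the parametric phase at which the first harmonic passes
        through the semi-major axis; psi is the spatial orientation of
        that axis.
        """
        a, b, c, d = self.harmonics[0]
        theta = 0.5 * np.arctan2(2.0 * (a * b + c * d), a * a + c * c - b * b - d * d)
        ct, st = np.cos(theta), np.sin(theta)
        a_star, c_star = a * ct + b * st, c * ct + d * st
        b_star, d_star = -a * st + b * ct, -c * st + d * ct
        if np.hypot(b_star, d_star) > np.hypot(a_star, c_star):
            # arctan2 branch picked the semi-minor axis; rotate a quarter turn
            theta += 0.5 * np.pi
            a_star, c_star = b_star, d_star
        magnitude = float(np.hypot(a_star, c_star))
        psi = float(np.arctan2(c_star, a_star))
        return magnitude, float(theta), psi


def flatten(coeffs: HarmonicCoefficientSet) -> np.ndarray:
    """Module-level alias for :meth:`HarmonicCoefficientSet.flatten`."""
    return coeffs.flatten()


def coefficient_column_labels(n_harmonics: int) -> list[str]:
    return [f"{letter}{n}" for n in range(1, n_harmonics + 1) for letter in "abcd"]


def compute_efa(
    outline: Outline, n_harmonics: int, ensure_ccw: bool = True
) -> HarmonicCoefficientSet:
    """Raw elliptic Fourier coefficients of a closed polygonal outline.

    The chord-length Fourier integrals are evaluated exactly for the
    piecewise-linear contour.  By default the outline is standardized to
    counterclockwise traversal first so handedness is consistent across
    specimens.

    Parameters
    ----------
    outline:
        Closed outline with K >= 3 vertices.
    n_harmonics:
        Number of harmonics N_h >= 1.  Values above K/2 are allowed but
        exceed the information content of the polygon; a warning is
        emitted.
    """
    if n_harmonics < 1:
        raise DataError("n_harmonics must be >= 1")
    if ensure_ccw and not outline.is_counterclockwise:
        outline = outline.reversed()
    if n_harmonics > outline.n_points // 2:
        warnings.warn(
            f"n_harmonics={n_harmonics} exceeds half the vertex count "
            f"({outline.n_points}); higher harmonics are unreliable",
            stacklevel=2,
        )
    dx, dy, dt = outline._chords
    if np.any(dt <= 0):  # cleaned outlines cannot hit this
        raise InvalidOutlineError("zero-length chord in outline")
    t = np.cumsum(dt)
    T = t[-1]
    t_prev = t - dt

    n = np.arange(1, n_harmonics + 1)
    # phase matrices: (K, N_h)
    omega = 2.0 * np.pi * np.outer(1.0 / T, n)  # (1, N_h)
    cos1, cos0 = np.cos(t[:, None] * omega), np.cos(t_prev[:, None] * omega)
    sin1, sin0 = np.sin(t[:, None] * omega), np.sin(t_prev[:, None] * omega)
    scale = T / (2.0 * np.pi**2 * n**2)
    vx = dx / dt
    vy = dy / dt
    a = scale * (vx @ (cos1 - cos0))
    b = scale * (vx @ (sin1 - sin0))
    c = scale * (vy @ (cos1 - cos0))
    d = scale * (vy @ (sin1 - sin0))

    # DC terms: exact means of the piecewise-linear x(t), y(t)
    closed = np.vstack([outline.points, outline.points[:1]])
    mids = 0.5 * (closed[1:] + closed[:-1])
    a0 = float(np.dot(dt, mids[:, 0]) / T)
    c0 = float(np.dot(dt, mids[:, 1]) / T)

    return HarmonicCoefficientSet(a0, c0, np.column_stack([a, b, c, d]))


def normalize_coefficients(
    coeffs: HarmonicCoefficientSet, mode: str = "size"
) -> HarmonicCoefficientSet:
    """Normalize raw EFA coefficients.

    ``mode="size"`` divides every harmonic quadruple by the magnitude of
    the first-harmonic semi-major axis and zeroes the DC terms, yielding
    scale- and translation-invariant coefficients.  ``mode="full"``
    additionally removes rotation and starting-point phase via the
    first-harmonic angles, with the sign convention that the normalized
    first-harmonic ``a_1`` is positive.
    """
    if mode not in ("size", "full"):
        raise DataError(f"normalization mode must be 'size' or 'full', got {mode!r}")
    magnitude, theta, psi = coeffs.first_harmonic_ellipse()
    if magnitude < 1e-12:
        raise DegenerateShapeError(
            "first-harmonic ellipse is degenerate; cannot normalize"
        )
    if mode == "size":
        return HarmonicCoefficientSet(
            0.0, 0.0, coeffs.harmonics / magnitude, normalization="size"
        )

    def _transform(theta_: float) -> np.ndarray:
        ct, st = np.cos(theta_), np.sin(theta_)
        a_star = coeffs.harmonics[0, 0] * ct + coeffs.harmonics[0, 1] * st
        c_star = coeffs.harmonics[0, 2] * ct + coeffs.harmonics[0, 3] * st
        psi_ = np.arctan2(c_star, a_star)
        cp, sp = np.cos(psi_), np.sin(psi_)
        rot = np.array([[cp, sp], [-sp, cp]])
        out = np.empty_like(coeffs.harmonics)
        for i, nh in enumerate(range(1, coeffs.n_harmonics + 1)):
            m = coeffs.harmonics[i].reshape(2, 2)
            cn, sn = np.cos(nh * theta_), np.sin(nh * theta_)
            phase = np.array([[cn, -sn], [sn, cn]])
            out[i] = (rot @ m @ phase).ravel() / magnitude
        return out

    normalized = _transform(theta)
    if normalized[0, 0] < 0:  # resolve the half-turn ambiguity of theta
        normalized = _transform(theta + np.pi)
    return HarmonicCoefficientSet(0.0, 0.0, normalized, normalization="full")


def reconstruct_outline(coeffs: HarmonicCoefficientSet, n_points: int) -> Outline:
    """Evaluate the Fourier series at ``n_points`` equally spaced parameters.

    The parameter runs over one full period starting at the contour's
    starting point, so reconstruction followed by re-extraction keeps the
    starting point aligned.
    """
    if n_points < 3:
        raise DataError("n_points must be >= 3 to form an outline")
    tau = np.arange(n_points) / n_points  # one period, endpoint excluded
    n = np.arange(1, coeffs.n_harmonics + 1)
    ang = 2.0 * np.pi * np.outer(tau, n)
    cos, sin = np.cos(ang), np.sin(ang)
    a, b, c, d = coeffs.harmonics.T
    x = coeffs.a0 + cos @ a + sin @ b
    y = coeffs.c0 + cos @ c + sin @ d
    return Outline(np.column_stack([x, y]))


# ---------------------------------------------------------------------------
# Coefficient matrices


@dataclass(frozen=True)
class ShapeMatrix:
    """Rows of flattened coefficients for one trait block.

    ``values`` is an (N, p) matrix with no missing entries; ``row_labels``
    are specimen or species identifiers; ``block`` is the trait name.
    """

    values: np.ndarray
    row_labels: tuple[str, ...]
    block: str
    column_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise DataError("ShapeMatrix values must be 2-D")
        if np.isnan(v).any():
            raise DataError(f"block {self.block!r} contains missing values")
        labels = tuple(str(r) for r in self.row_labels)
        if len(labels) != v.shape[0]:
            raise DataError("row_labels length must match the number of rows")
        if len(set(labels)) != len(labels):
            raise DataError(f"duplicate row labels in block {self.block!r}")
        cols = tuple(self.column_labels) or tuple(
            coefficient_column_labels(v.shape[1] // 4)
            if v.shape[1] % 4 == 0
            else (f"v{i+1}" for i in range(v.shape[1]))
        )
        if len(cols) != v.shape[1]:
            raise DataError("column_labels length must match the number of columns")
        v = np.ascontiguousarray(v)
        v.setflags(write=False)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "row_labels", labels)
        object.__setattr__(self, "column_labels", cols)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.values, index=list(self.row_labels), columns=list(self.column_labels)
        )

    def reorder(self, labels) -> "ShapeMatrix":
        """Return a copy with rows in the given label order."""
        index = {lbl: i for i, lbl in enumerate(self.row_labels)}
        missing = [lbl for lbl in labels if lbl not in index]
        if missing:
            raise DataError(
                f"block {self.block!r} is missing rows for: {', '.join(map(str, missing))}"
            )
        idx = [index[lbl] for lbl in labels]
        return ShapeMatrix(
            self.values[idx], tuple(labels), self.block, self.column_labels
        )


def assemble_block(coeff_sets, block: str) -> ShapeMatrix:
    """Stack per-specimen coefficient sets into a ShapeMatrix.

    ``coeff_sets`` is a mapping label -> HarmonicCoefficientSet or an
    iterable of (label, coefficients) pairs.  All members must share the
    same harmonic count and normalization.
    """
    if hasattr(coeff_sets, "items"):
        pairs = list(coeff_sets.items())
    else:
        pairs = list(coeff_sets)
    if not pairs:
        raise DataError(f"no coefficient sets supplied for block {block!r}")
    n_h = {c.n_harmonics for _, c in pairs}
    if len(n_h) != 1:
        raise DataError(
            f"mixed harmonic counts in block {block!r}: {sorted(n_h)}"
        )
    norms = {c.normalization for _, c in pairs}
    if len(norms) != 1:
        raise DataError(f"mixed normalizations in block {block!r}: {sorted(norms)}")
    labels = [str(lbl) for lbl, _ in pairs]
    values = np.vstack([c.flatten() for _, c in pairs])
    return ShapeMatrix(values, tuple(labels), block)


def species_mean_shapes(matrix: ShapeMatrix, species, tree=None) -> ShapeMatrix:
    """Arithmetic per-species column means of a specimen-level matrix.

    ``species`` gives the species label of each row.  When a phylogeny is
    supplied the output rows follow its tip order and every tip must be
    represented in the data; species present in the data but absent from
    the tree are dropped with a log message.
    """
    species = [str(s) for s in species]
    if len(species) != matrix.n_rows:
        raise DataError("species labels must align with matrix rows")
    order: list[str] = []
    seen = set()
    for s in species:
        if s not in seen:
            seen.add(s)
            order.append(s)
    if tree is not None:
        tips = list(tree.tip_labels)
        missing = [t for t in tips if t not in seen]
        if missing:
            raise DataError(
                "species present in tree but absent from data: "
                + ", ".join(missing)
            )
        extra = [s for s in order if s not in set(tips)]
        if extra:
            logger.info(
                "dropping %d species not in the tree: %s", len(extra), ", ".join(extra)
            )
        order = tips
    arr = np.empty((len(order), matrix.p))
    species_arr = np.asarray(species)
    for i, s in enumerate(order):
        arr[i] = matrix.values[species_arr == s].mean(axis=0)
    return ShapeMatrix(arr, tuple(order), matrix.block, matrix.column_labels)


# ---------------------------------------------------------------------------
# Shape PCA


@dataclass(frozen=True)
class ShapePCAResult:
    """Centered (not scaled) PCA of a coefficient matrix."""

    scores: np.ndarray  # (N, k)
    loadings: np.ndarray  # (p, k)
    variance_explained: np.ndarray  # (k,) proportions of total variance
    mean_vector: np.ndarray  # (p,)
    row_labels: tuple[str, ...]


def shape_pca(matrix: ShapeMatrix, k: int | None = None) -> ShapePCAResult:
    """Principal components of a coefficient block.

    The decomposition is by SVD of the column-centered matrix.  The sign
    of each component is fixed so that its largest-magnitude loading is
    positive, making results reproducible across platforms.
    """
    if matrix.n_rows < 2:
        raise DataError("PCA needs at least 2 rows")
    max_k = min(matrix.n_rows - 1, matrix.p)
    if k is None:
        k = max_k
    if not 1 <= k <= max_k:
        raise DataError(f"k must be in [1, {max_k}], got {k}")
    mean = matrix.values.mean(axis=0)
    centered = matrix.values - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total = float(np.sum(s**2))
    if total <= 0:
        raise DataError("matrix has zero variance; PCA undefined")
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    var = (s[:k] ** 2) / total
    return ShapePCAResult(scores, loadings, var, mean, matrix.row_labels)
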