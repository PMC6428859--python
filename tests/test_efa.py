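"""Elliptic Fourier analysis: extraction, normalization, reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from morphorates import (
    DataError,
    DegenerateShapeError,
    InvalidOutlineError,
    Outline,
    assemble_block,
    compute_efa,
    normalize_coefficients,
    outline_area,
    reconstruct_outline,
    shape_pca,
    species_mean_shapes,
)
from morphorates.efa import ShapeMatrix

from conftest import circle_points


def quadrature_efa(points: np.ndarray, n_harmonics: int):
    """Independent oracle: Kuhl-Giardina integrals by dense numerical quadrature.

    Integrates x(t) cos(2 pi n t / T) dt (and the sine/y analogues) along
    each polygon edge with a fine trapezoid rule in the chord-length
    parameter, never reusing the closed-form implementation.
    """
    pts = np.vstack([points, points[:1]])
    seg = np.diff(pts, axis=0)
    dt = np.hypot(seg[:, 0], seg[:, 1])
    t1 = np.cumsum(dt)
    t0 = t1 - dt
    T = t1[-1]
    m = 4096  # quadrature nodes per edge
    a = np.zeros(n_harmonics)
    b = np.zeros(n_harmonics)
    c = np.zeros(n_harmonics)
    d = np.zeros(n_harmonics)
    for k in range(len(seg)):
        u = np.linspace(0.0, 1.0, m)
        t = t0[k] + u * dt[k]
        x = pts[k, 0] + u * seg[k, 0]
        y = pts[k, 1] + u * seg[k, 1]
        for n in range(1, n_harmonics + 1):
            cosn = np.cos(2 * np.pi * n * t / T)
            sinn = np.sin(2 * np.pi * n * t / T)
            a[n - 1] += np.trapezoid(x * cosn, t)
            b[n - 1] += np.trapezoid(x * sinn, t)
            c[n - 1] += np.trapezoid(y * cosn, t)
            d[n - 1] += np.trapezoid(y * sinn, t)
    return np.column_stack([a, b, c, d]) * (2.0 / T)


class TestOutline:
    def test_cleaning_drops_closing_duplicate_and_repeats(self):
        pts = [[0, 0], [0, 0], [1, 0], [1, 1], [1, 1], [0, 1], [0, 0]]
        o = Outline(np.asarray(pts, float))
        assert o.n_points == 4

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidOutlineError):
            Outline(np.array([[0, 0], [1, 1]], float))

    def test_degenerate_after_cleaning_rejected(self):
        with pytest.raises(InvalidOutlineError):
            Outline(np.array([[0, 0], [0, 0], [0, 0], [1, 1]], float))


class TestComputeEFA:
    def test_circle_first_harmonic_is_the_circle(self):
        o = Outline(circle_points(radius=2.0, n=256))
        coeffs = compute_efa(o, 1)
        assert np.allclose(coeffs.harmonics[0], [2, 0, 0, 2], atol=1e-3)

    def test_ellipse_axis_aligned_and_even_harmonics_vanish(self):
        # 2-fold symmetry of the ellipse kills every even harmonic; the
        # arc-length first harmonic stays axis-aligned with a > d > 0.
        t = np.linspace(0, 2 * np.pi, 512, endpoint=False)
        o = Outline(np.column_stack([3 * np.cos(t), np.sin(t)]))
        coeffs = compute_efa(o, 4)
        a1, b1, c1, d1 = coeffs.harmonics[0]
        assert abs(b1) < 1e-10 and abs(c1) < 1e-10
        assert a1 > d1 > 0
        assert np.sum(coeffs.harmonics[1] ** 2) < 1e-6  # harmonic 2
        assert np.sum(coeffs.harmonics[3] ** 2) < 1e-6  # harmonic 4

    @pytest.mark.filterwarnings("ignore:n_harmonics")
    def test_square_matches_quadrature_oracle(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        coeffs = compute_efa(Outline(square), 5)
        oracle = quadrature_efa(square, 5)
        assert np.allclose(coeffs.harmonics, oracle, atol=1e-8)

    def test_translation_changes_only_dc_terms(self, rng):
        pts = circle_points(n=64) + 0.1 * rng.normal(size=(64, 2))
        base = compute_efa(Outline(pts), 6)
        moved = compute_efa(Outline(pts + [3.0, -2.0]), 6)
        assert np.allclose(base.harmonics, moved.harmonics, atol=1e-10)
        assert moved.a0 == pytest.approx(base.a0 + 3.0, abs=1e-9)
        assert moved.c0 == pytest.approx(base.c0 - 2.0, abs=1e-9)

    def test_invalid_harmonic_count(self):
        o = Outline(circle_points(n=16))
        with pytest.raises(DataError):
            compute_efa(o, 0)


class TestNormalization:
    def test_size_mode_unit_semi_major(self, rng):
        pts = circle_points(n=128) * 3.7 + rng.normal(scale=0.05, size=(128, 2))
        normalized = normalize_coefficients(compute_efa(Outline(pts), 8), "size")
        magnitude, _, _ = normalized.first_harmonic_ellipse()
        assert magnitude == pytest.approx(1.0, abs=1e-12)
        assert normalized.a0 == 0.0 and normalized.c0 == 0.0

    def test_scale_and_translation_invariance(self, rng):
        pts = circle_points(n=128) + 0.2 * rng.normal(size=(128, 2))
        a = normalize_coefficients(compute_efa(Outline(pts), 8), "size")
        b = normalize_coefficients(
            compute_efa(Outline(pts * 5.0 + [11.0, -4.0]), 8), "size"
        )
        assert np.allclose(a.harmonics, b.harmonics, atol=1e-10)

    def test_full_mode_rotation_and_start_invariance(self):
        t = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        pts = np.column_stack([2.0 * np.cos(t), np.sin(t)])
        theta = np.deg2rad(37.0)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = np.roll(pts @ rot.T, -10, axis=0)
        a = normalize_coefficients(compute_efa(Outline(pts), 6), "full")
        b = normalize_coefficients(compute_efa(Outline(moved), 6), "full")
        assert np.allclose(a.harmonics, b.harmonics, atol=1e-6)

    def test_degenerate_first_harmonic_rejected(self):
        # a shape whose first harmonic vanishes: two-lobed figure traversed
        # so the fundamental frequency cancels
        t = np.linspace(0, 2 * np.pi, 512, endpoint=False)
        pts = np.column_stack(
            [np.cos(2 * t) * (1 + 0.01 * np.cos(4 * t)), np.sin(2 * t)]
        )
        coeffs = compute_efa(Outline(pts), 4)
        with pytest.raises(DegenerateShapeError):
            normalize_coefficients(coeffs, "size")


class TestReconstruction:
    def test_circle_roundtrip_deviation(self):
        o = Outline(circle_points(radius=2.0, n=256))
        coeffs = compute_efa(o, 10)
        back = reconstruct_outline(coeffs, 256)
        radii = np.hypot(back.points[:, 0], back.points[:, 1])
        assert np.max(np.abs(radii - 2.0)) < 1e-3 * 2.0

    def test_error_non_increasing_in_harmonics(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 2 * np.pi, 512, endpoint=False)
        r = 1.0 + 0.2 * np.cos(3 * t) + 0.1 * np.sin(5 * t)
        pts = np.column_stack([r * np.cos(t), r * np.sin(t)])
        o = Outline(pts)
        errors = []
        for nh in (2, 5, 10, 20):
            back = reconstruct_outline(compute_efa(o, nh), 512)
            errors.append(np.mean(np.linalg.norm(back.points - pts, axis=1)))
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errors, errors[1:]))

    def test_too_few_points_rejected(self):
        coeffs = compute_efa(Outline(circle_points(n=32)), 2)
        with pytest.raises(DataError):
            reconstruct_outline(coeffs, 2)


class TestArea:
    @pytest.mark.parametrize(
        "points, expected",
        [
            (np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float), 1.0),
            (np.array([[0, 0], [2, 0], [0, 2]], float), 2.0),
        ],
    )
    def test_polygon_areas(self, points, expected):
        assert outline_area(Outline(points)) == pytest.approx(expected)

    def test_circle_area_converges(self):
        o = Outline(circle_points(radius=2.0, n=4096))
        assert outline_area(o) == pytest.approx(np.pi * 4.0, abs=1e-3)

    @given(shift=st.integers(min_value=0, max_value=63), reverse=st.booleans())
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_invariant_to_relabeling_and_direction(self, shift, reverse):
        pts = circle_points(n=64) * [1.3, 0.8]
        o = Outline(pts).cycled(shift)
        if reverse:
            o = o.reversed()
        assert outline_area(o) == pytest.approx(
            outline_area(Outline(pts)), rel=1e-12
        )


class TestFlattenAssemble:
    @pytest.mark.parametrize("nh, length", [(20, 80), (10, 40)])
    def test_vector_length(self, nh, length):
        coeffs = compute_efa(Outline(circle_points(n=128)), nh)
        assert coeffs.flatten().shape == (length,)

    def test_column_order_is_per_harmonic_quadruples(self):
        coeffs = compute_efa(Outline(circle_points(n=64)), 2)
        flat = coeffs.flatten()
        assert np.allclose(flat[:4], coeffs.harmonics[0])
        assert np.allclose(flat[4:], coeffs.harmonics[1])

    def test_mixed_harmonic_counts_rejected(self):
        o = Outline(circle_points(n=128))
        with pytest.raises(DataError):
            assemble_block(
                [("s1", compute_efa(o, 20)), ("s2", compute_efa(o, 10))], "pygidium"
            )


class TestSpeciesMeans:
    def test_single_specimen_identity_and_two_specimen_mean(self):
        values = np.array([[1.0, 2.0], [3.0, 6.0], [5.0, 5.0]])
        m = ShapeMatrix(values, ("x1", "x2", "y1"), "b", ("v1", "v2"))
        out = species_mean_shapes(m, ["X", "X", "Y"])
        assert list(out.row_labels) == ["X", "Y"]
        assert np.allclose(out.values[0], [2.0, 4.0])
        assert np.allclose(out.values[1], [5.0, 5.0])

    def test_missing_tree_species_reported(self, three_tip_tree):
        m = ShapeMatrix(np.ones((2, 2)), ("s1", "s2"), "b", ("v1", "v2"))
        with pytest.raises(DataError, match="C"):
            species_mean_shapes(m, ["A", "B"], tree=three_tip_tree)


class TestShapePCA:
    def test_rank_one_data(self):
        base = np.outer(np.arange(5.0), [1.0, 2.0, -1.0])
        m = ShapeMatrix(base, tuple("abcde"), "b", ("v1", "v2", "v3"))
        res = shape_pca(m, k=1)
        assert res.variance_explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_gaussian_splits_variance(self):
        rng = np.random.default_rng(11)
        values = rng.normal(size=(10000, 2))
        m = ShapeMatrix(
            values, tuple(f"s{i}" for i in range(10000)), "b", ("v1", "v2")
        )
        res = shape_pca(m, k=2)
        assert np.allclose(res.variance_explained, [0.5, 0.5], atol=0.02)

    def test_scores_orthogonal_and_reconstruct(self, rng):
        values = rng.normal(size=(12, 6))
        m = ShapeMatrix(values, tuple(f"s{i}" for i in range(12)), "b")
        res = shape_pca(m)
        gram = res.scores.T @ res.scores
        assert np.allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)
        approx = res.mean_vector + res.scores @ res.loadings.T
        assert np.allclose(approx, values, atol=1e-8)

    def test_sign_convention_deterministic(self, rng):
        values = rng.normal(size=(8, 4))
        m = ShapeMatrix(values, tuple(f"s{i}" for i in range(8)), "b")
        res = shape_pca(m, k=2)
        for j in range(2):
            i = np.argmax(np.abs(res.loadings[:, j]))
            assert res.loadings[i, j] > 0

    def test_k_out_of_range(self, rng):
        m = ShapeMatrix(rng.normal(size=(4, 3)), tuple("abcd"), "b")
        with pytest.raises(DataError):
            shape_pca(m, k=4)
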