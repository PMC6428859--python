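"""Synthetic study generation: trees, planted rates, outline synthesis."""

import dataclasses

import numpy as np
import pytest

from morphorates import (
    DataError,
    StudyDesign,
    compute_efa,
    embed_shape_deviations,
    generate_dataset,
    normalize_coefficients,
    phylo_pls,
    compare_rates,
    recover_shape_deviations,
    synthesize_outlines,
)
from morphorates.synthetic import BlockSpec


def small_design(**overrides) -> StudyDesign:
    defaults = dict(
        n_species=12,
        specimens_per_species=3,
        blocks=(
            BlockSpec("pygidium", 8, 1.99, "female"),
            BlockSpec("aedeagus", 8, 0.73, "male"),
        ),
        cross_block_correlation={("pygidium", "aedeagus"): 0.67},
        within_species_sd=0.2,
        tree_seed=1,
        trait_seed=2,
    )
    defaults.update(overrides)
    return StudyDesign(**defaults)


class TestStudyDesign:
    def test_default_design_mirrors_the_study(self):
        d = StudyDesign()
        assert d.n_species == 33
        assert [b.p for b in d.blocks] == [80, 80, 80, 80]
        assert [b.rate for b in d.blocks] == [1.99, 0.73, 0.36, 0.24]
        assert d.cross_block_correlation[("pygidium", "aedeagus")] == 0.67
        np.linalg.cholesky(d.rate_matrix())  # implied joint matrix is SPD

    def test_invalid_correlation_rejected(self):
        with pytest.raises(DataError):
            small_design(cross_block_correlation={("pygidium", "aedeagus"): 1.0})

    def test_unknown_block_in_correlation_rejected(self):
        with pytest.raises(DataError):
            small_design(cross_block_correlation={("pygidium", "elytra"): 0.5})


class TestGenerateDataset:
    def test_zero_noise_makes_conspecifics_identical(self):
        data = generate_dataset(small_design(within_species_sd=0.0))
        block = data.specimens["pygidium"]
        species = data.metadata.set_index("specimen_id").loc[
            list(block.row_labels), "species"
        ]
        for sp in data.tree.tip_labels:
            rows = block.values[np.asarray(species == sp)]
            assert np.allclose(rows, rows[0])

    def test_determinism_under_fixed_seeds(self):
        a = generate_dataset(small_design())
        b = generate_dataset(small_design())
        assert a.tree.newick() == b.tree.newick()
        assert np.array_equal(
            a.species_means["pygidium"].values, b.species_means["pygidium"].values
        )

    def test_rate_ordering_recovered(self):
        # planted pygidium rate > aedeagus rate should show in the estimates
        hits = 0
        for rep in range(20):
            design = small_design(
                n_species=20,
                blocks=(
                    BlockSpec("pygidium", 20, 1.99, "female"),
                    BlockSpec("aedeagus", 20, 0.73, "male"),
                ),
                tree_seed=100 + rep,
                trait_seed=200 + rep,
            )
            data = generate_dataset(design)
            res = compare_rates(
                list(data.species_means.values()), data.tree,
                n_simulations=9, seed=rep,
            )
            hits += res.sigma2["pygidium"] > res.sigma2["aedeagus"]
        assert hits >= 19

    def test_uncorrelated_genital_blocks_give_null_pls(self):
        # type-I behaviour at rho=0: detection rate near alpha
        rejections = 0
        for rep in range(40):
            design = small_design(
                n_species=16,
                cross_block_correlation={},
                tree_seed=300 + rep,
                trait_seed=400 + rep,
            )
            data = generate_dataset(design)
            res = phylo_pls(
                data.species_means["pygidium"],
                data.species_means["aedeagus"],
                data.tree,
                n_permutations=99,
                seed=rep,
            )
            rejections += res.p_value <= 0.05
        assert rejections / 40 < 0.2

    def test_metadata_covers_all_specimens(self):
        data = generate_dataset(small_design())
        assert len(data.metadata) == 12 * 3 * 2
        assert set(data.metadata["trait"]) == {"pygidium", "aedeagus"}
        assert set(data.metadata.columns) >= {
            "specimen_id", "species", "sex", "trait", "trait_size",
        }


class TestOutlineSynthesis:
    def test_round_trip_on_embedded_vectors(self, rng):
        deviations = rng.normal(0, 1.4, size=(4, 80))
        vectors = embed_shape_deviations(deviations)
        outlines = synthesize_outlines(vectors, n_points=1024)
        for vec, outline in zip(vectors, outlines):
            extracted = normalize_coefficients(
                compute_efa(outline, len(vec) // 4), mode="size"
            )
            assert np.max(np.abs(extracted.flatten() - vec)) < 1e-6

    def test_first_harmonic_only_vector_is_an_ellipse(self):
        vec = np.zeros(8)
        vec[0], vec[3] = 1.0, 0.6
        (outline,) = synthesize_outlines(vec[None, :], n_points=256)
        # an ellipse-like closed curve: radius oscillates once between the
        # two semi-axes (the emitted geometry compensates the chord-length
        # parameterization, so the axes are near, not equal to, 1 and 0.6)
        r = np.hypot(outline.points[:, 0], outline.points[:, 1])
        assert 0.4 < r.min() < 0.7
        assert 0.9 < r.max() < 1.1
        # two-fold symmetry: radii repeat half a period later
        assert np.allclose(r, np.roll(r, 128), atol=1e-6)

    def test_too_few_points_rejected(self, rng):
        vec = embed_shape_deviations(rng.normal(size=(1, 8)))
        with pytest.raises(DataError):
            synthesize_outlines(vec, n_points=2)

    def test_degenerate_first_harmonic_rejected(self):
        vec = np.zeros((1, 8))
        vec[0, 4] = 1.0  # only harmonic-2 content
        from morphorates.errors import DegenerateShapeError

        with pytest.raises(DegenerateShapeError):
            synthesize_outlines(vec, n_points=128)

    def test_deviation_recovery_preserves_block_variance_ratio(self, rng):
        # the embedding applies (approximately) the same linear map to every
        # row, so at study-realistic amplitudes a planted variance contrast
        # between row groups survives the trip through outlines and back
        strong = rng.normal(0, np.sqrt(1.99), size=(8, 40))
        weak = rng.normal(0, np.sqrt(0.73), size=(8, 40))
        vectors = embed_shape_deviations(np.vstack([strong, weak]))
        outlines = synthesize_outlines(vectors, n_points=512)
        extracted = np.vstack([
            normalize_coefficients(compute_efa(o, 11), mode="size").flatten()
            for o in outlines
        ])
        recovered = recover_shape_deviations(extracted)
        ratio = recovered[:8].var() / recovered[8:].var()
        planted = strong.var() / weak.var()
        assert ratio == pytest.approx(planted, rel=0.15)
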