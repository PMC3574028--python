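import numpy as np
import pytest

from ssbond.core import AnnotationTrack, Protein
from ssbond.features import (
    CSP_GRID,
    HLOC_GRID,
    LW_GRID,
    ConfigurationError,
    FeatureFunction,
    FeatureFunctionSet,
    csp_window,
    encode_cysteine,
    encode_pair,
    encode_protein,
    global_histogram,
    interval_histogram,
    local_histogram,
    local_window,
    scalar_features,
)


@pytest.fixture
def ss3_protein():
    """4-residue protein with a one-hot SS3 track: H H E E."""
    protein = Protein(id="s", sequence="ACCA")
    values = np.array([[1, 0, 0], [1, 0, 0], [0, 1, 0], [0, 1, 0]], dtype=float)
    protein.attach(AnnotationTrack("SS3", ["H", "E", "C"], values))
    return protein


class TestScalarFeatures:
    def test_relative_positions_and_difference(self, four_cys_protein):
        # cysteines at 0-based 9? -> fixture uses 4,19,29,49; build ad hoc
        seq = ["A"] * 100
        seq[9] = seq[29] = "C"
        protein = Protein(id="p", sequence="".join(seq))
        np.testing.assert_allclose(
            scalar_features(protein, (0, 1), "RelPos"), [0.10, 0.30]
        )
        np.testing.assert_allclose(
            scalar_features(protein, (0, 1), "PosDiff"), [0.20]
        )

    def test_position_difference_strictly_positive(self, four_cys_protein):
        for a in range(4):
            for b in range(a + 1, 4):
                assert scalar_features(four_cys_protein, (a, b), "PosDiff")[0] > 0

    def test_relative_indices(self, four_cys_protein):
        np.testing.assert_allclose(
            scalar_features(four_cys_protein, (0, 3), "RelIdx"), [0.25, 1.0]
        )
        np.testing.assert_allclose(
            scalar_features(four_cys_protein, (0, 3), "IdxDiff"), [0.75]
        )

    def test_parity(self):
        seq5 = "C" * 5
        seq4 = "C" * 4
        assert scalar_features(Protein(id="o", sequence=seq5), None, "Par")[0] == 1
        assert scalar_features(Protein(id="e", sequence=seq4), None, "Par")[0] == 0

    def test_pair_symbol_without_pair_raises(self, four_cys_protein):
        with pytest.raises(ValueError):
            scalar_features(four_cys_protein, None, "RelPos")


class TestCspWindow:
    def test_interior_cysteine(self, four_cys_protein):
        # positions [4, 19, 29, 49], L=100, k=1, w=3
        np.testing.assert_allclose(
            csp_window(four_cys_protein, 1, 3), [-0.15, 0.0, 0.10]
        )

    def test_boundary_slots_are_zero(self, four_cys_protein):
        np.testing.assert_allclose(
            csp_window(four_cys_protein, 0, 3), [0.0, 0.0, 0.15]
        )

    def test_degenerate_window(self, four_cys_protein):
        for k in range(4):
            np.testing.assert_array_equal(csp_window(four_cys_protein, k, 1), [0.0])

    def test_even_window_rejected(self, four_cys_protein):
        with pytest.raises(ConfigurationError):
            csp_window(four_cys_protein, 0, 4)


class TestHistograms:
    def test_global_histogram_counts_one_hot_labels(self, ss3_protein):
        np.testing.assert_allclose(
            global_histogram(ss3_protein, "SS3"), [0.5, 0.5, 0.0]
        )

    def test_global_histogram_uniform_track(self):
        protein = Protein(id="u", sequence="ACCA")
        protein.attach(
            AnnotationTrack("SS3", ["H", "E", "C"], np.full((4, 3), 1 / 3))
        )
        np.testing.assert_allclose(global_histogram(protein, "SS3"), [1 / 3] * 3)

    def test_interval_histogram_two_residue_case(self, ss3_protein):
        # cysteines at positions 1, 2: rows H then E
        np.testing.assert_allclose(
            interval_histogram(ss3_protein, (0, 1), "SS3"), [0.5, 0.5, 0.0]
        )

    def test_interval_covering_chain_equals_global(self):
        protein = Protein(id="c", sequence="CAAC")
        rng = np.random.default_rng(1)
        protein.attach(
            AnnotationTrack("SS3", ["H", "E", "C"], rng.dirichlet(np.ones(3), 4))
        )
        np.testing.assert_allclose(
            interval_histogram(protein, (0, 1), "SS3"),
            global_histogram(protein, "SS3"),
        )

    def test_adjacent_cysteines_buried_interval(self):
        protein = Protein(id="b", sequence="CC")
        protein.attach(
            AnnotationTrack("SA", ["buried", "exposed"], np.array([[1, 0], [1, 0.0]]))
        )
        np.testing.assert_allclose(
            interval_histogram(protein, (0, 1), "SA"), [1.0, 0.0]
        )

    def test_missing_track_raises(self, ss3_protein):
        with pytest.raises(KeyError, match="SS8"):
            global_histogram(ss3_protein, "SS8")


class TestLocalHistogram:
    def test_fully_in_bounds_window_has_zero_oob(self, protein_with_tracks):
        vec = local_histogram(protein_with_tracks, 2, "SS3", 10)
        assert vec[-1] == 0.0
        assert vec.shape == (4,)

    def test_out_of_bounds_fraction_at_chain_start(self):
        seq = "C" + "A" * 20
        protein = Protein(id="edge", sequence=seq)
        protein.attach(
            AnnotationTrack("SS3", ["H", "E", "C"], np.full((21, 3), 1 / 3))
        )
        vec = local_histogram(protein, 0, "SS3", 10)
        # offsets -5..4: five positions fall before the chain
        assert vec[-1] == pytest.approx(0.5)

    def test_pure_label_window(self, ss3_protein):
        # cysteine at position 1, w=2 covers rows 0..1 (both H)
        vec = local_histogram(ss3_protein, 0, "SS3", 2)
        np.testing.assert_allclose(vec, [1.0, 0.0, 0.0, 0.0])


class TestLocalWindow:
    def test_w1_returns_own_row(self, protein_with_tracks):
        pos = protein_with_tracks.cysteine_positions[1]
        np.testing.assert_array_equal(
            local_window(protein_with_tracks, 1, "PSSM", 1),
            protein_with_tracks.track("PSSM").values[pos],
        )

    def test_out_of_bounds_entries_zero(self):
        protein = Protein(id="edge", sequence="CAAAA")
        protein.attach(
            AnnotationTrack("SS3", ["H", "E", "C"], np.full((5, 3), 1 / 3))
        )
        vec = local_window(protein, 0, "SS3", 5)
        np.testing.assert_array_equal(vec[: 2 * 3], 0.0)
        assert vec[2 * 3:].sum() > 0

    def test_pssm_window_dimensionality(self, protein_with_tracks):
        assert local_window(protein_with_tracks, 0, "PSSM", 15).shape == (300,)

    def test_even_window_rejected(self, protein_with_tracks):
        with pytest.raises(ConfigurationError):
            local_window(protein_with_tracks, 0, "PSSM", 4)


class TestDimensionalities:
    @pytest.mark.parametrize("w", CSP_GRID)
    def test_csp_dimension_equals_window(self, four_cys_protein, w):
        assert csp_window(four_cys_protein, 1, w).shape == (w,)

    @pytest.mark.parametrize("w", HLOC_GRID)
    def test_hloc_dimension(self, protein_with_tracks, w):
        assert local_histogram(protein_with_tracks, 1, "SS3", w).shape == (4,)
        assert FeatureFunction("Hloc", "SS3", w).d_single == 4

    @pytest.mark.parametrize("w", LW_GRID)
    def test_lw_dimension(self, protein_with_tracks, w):
        assert local_window(protein_with_tracks, 1, "SS3", w).shape == (3 * w,)
        assert FeatureFunction("LW", "SS3", w).d_single == 3 * w

    def test_production_default_total_dimensionality(self):
        feature_set = FeatureFunctionSet.from_spec("LW:PSSM:15,CSP:17")
        assert feature_set.total_d == 2 * 15 * 20 + 2 * 17  # 634


class TestEncoders:
    def test_encode_pair_concatenates_in_member_order(self, protein_with_tracks):
        feature_set = FeatureFunctionSet.from_spec("Nr,CSP:3")
        vec = encode_pair(protein_with_tracks, (0, 2), feature_set)
        assert vec.shape == (1 + 2 * 3,)
        assert vec[0] == protein_with_tracks.length
        np.testing.assert_allclose(vec[1:4], csp_window(protein_with_tracks, 0, 3))
        np.testing.assert_allclose(vec[4:7], csp_window(protein_with_tracks, 2, 3))

    def test_empty_set_gives_empty_vector(self, protein_with_tracks):
        assert encode_pair(protein_with_tracks, (0, 1), FeatureFunctionSet([])).size == 0

    def test_protein_arity_set_constant_over_pairs(self, protein_with_tracks):
        feature_set = FeatureFunctionSet.from_spec("Nr,Nc,Par,Hglob:SS3")
        reference = encode_pair(protein_with_tracks, (0, 1), feature_set)
        for pair in [(0, 2), (1, 3), (2, 3)]:
            np.testing.assert_array_equal(
                encode_pair(protein_with_tracks, pair, feature_set), reference
            )

    def test_encode_cysteine_rejects_pair_arity(self, protein_with_tracks):
        with pytest.raises(ConfigurationError):
            encode_cysteine(
                protein_with_tracks, 0, FeatureFunctionSet.from_spec("PosDiff")
            )

    def test_encode_cysteine_shapes(self, protein_with_tracks):
        assert encode_cysteine(
            protein_with_tracks, 0, FeatureFunctionSet.from_spec("Hloc:SS3:10")
        ).shape == (4,)
        np.testing.assert_array_equal(
            encode_cysteine(
                protein_with_tracks, 0, FeatureFunctionSet.from_spec("Nc,Par")
            ),
            [4.0, 0.0],
        )

    def test_lonely_cysteine_csp_all_zero(self):
        protein = Protein(id="solo", sequence="ACA")
        np.testing.assert_array_equal(
            encode_cysteine(protein, 0, FeatureFunctionSet.from_spec("CSP:3")),
            [0.0, 0.0, 0.0],
        )

    def test_encode_protein(self, ss3_protein):
        np.testing.assert_array_equal(
            encode_protein(ss3_protein, FeatureFunctionSet.from_spec("Nc")), [2.0]
        )
        vec = encode_protein(ss3_protein, FeatureFunctionSet.from_spec("Hglob:AA"))
        assert vec.shape == (21,)
        assert vec.sum() == pytest.approx(1.0)
        with pytest.raises(ConfigurationError):
            encode_protein(ss3_protein, FeatureFunctionSet.from_spec("CSP:3"))

    def test_label_order_permutation_permutes_features(self):
        protein = Protein(id="perm", sequence="CAAC")
        rng = np.random.default_rng(3)
        values = rng.dirichlet(np.ones(3), 4)
        protein.attach(AnnotationTrack("SS3", ["H", "E", "C"], values))
        forward = local_window(protein, 0, "SS3", 3)
        permuted_protein = Protein(id="perm2", sequence="CAAC")
        order = [2, 0, 1]
        permuted_protein.attach(
            AnnotationTrack("SS3", ["C", "H", "E"], values[:, order])
        )
        backward = local_window(permuted_protein, 0, "SS3", 3)
        np.testing.assert_allclose(
            backward.reshape(3, 3)[:, [1, 2, 0]], forward.reshape(3, 3)
        )

    def test_one_member_per_family(self):
        with pytest.raises(ConfigurationError):
            FeatureFunctionSet.from_spec("LW:PSSM:15,LW:PSSM:5")
        # same symbol on different annotations is a different family
        FeatureFunctionSet.from_spec("LW:PSSM:15,LW:SS3:5")
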