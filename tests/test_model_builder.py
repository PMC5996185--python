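import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from decost.model_builder import (
    FILTERED,
    EmptyModelError,
    InteractionRecord,
    SystemModel,
    build_adjacency,
    normalize_dynamics,
    quantify_interaction,
)


class TestQuantifyInteraction:
    def test_activation_high_confidence(self):
        assert quantify_interaction("activation", 900, 500) == 1

    def test_catalysis_is_neutral(self):
        assert quantify_interaction("catalysis", 900, 500) == 0

    def test_low_confidence_is_filtered(self):
        assert quantify_interaction("inhibition", 400, 500) is FILTERED

    def test_inhibition(self):
        assert quantify_interaction("inhibition", 900, 500) == -1

    def test_case_insensitive(self):
        assert quantify_interaction("  ACTIVATION ", None, 500) == 1

    def test_missing_confidence_passes_filter(self):
        assert quantify_interaction("inhibition", None, 500) == -1

    def test_unknown_label_maps_to_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert quantify_interaction("frobnication", None, 500) == 0
        assert "frobnication" in caplog.text

    @pytest.mark.parametrize(
        "mechanism", ["expression", "catalysis", "ptmod", "binding", "reaction", "other"]
    )
    def test_neutral_mechanisms(self, mechanism):
        assert quantify_interaction(mechanism, None, 500) == 0

    def test_pure_function(self):
        results = {quantify_interaction("activation", 700, 500) for _ in range(10)}
        assert results == {1}


class TestBuildAdjacency:
    def test_single_activation_edge(self):
        model = build_adjacency([InteractionRecord("A", "B", "activation")])
        assert model.genes == ["a", "b"]
        assert np.count_nonzero(model.raw_adjacency) == 1
        # incoming layout: effect of a (source) lands on row of b (target)
        assert model.raw_adjacency[1, 0] == 1

    def test_opposing_parallel_edges_cancel(self):
        records = [
            InteractionRecord("A", "B", "activation"),
            InteractionRecord("A", "B", "inhibition"),
        ]
        model = build_adjacency(records)
        assert np.count_nonzero(model.raw_adjacency) == 0

    def test_filter_then_sum_then_clip(self):
        records = [
            InteractionRecord("A", "B", "activation", 900),
            InteractionRecord("A", "B", "activation", 100),
        ]
        model = build_adjacency(records, min_confidence=500)
        assert model.raw_adjacency[1, 0] == 1

    def test_parallel_activations_clip_to_one(self):
        records = [InteractionRecord("A", "B", "activation") for _ in range(3)]
        model = build_adjacency(records)
        assert model.raw_adjacency[1, 0] == 1

    def test_paper_literal_layout_is_transpose(self):
        records = [
            InteractionRecord("A", "B", "activation"),
            InteractionRecord("B", "C", "inhibition"),
        ]
        incoming = build_adjacency(records, layout="incoming")
        literal = build_adjacency(records, layout="paper-literal")
        np.testing.assert_array_equal(incoming.raw_adjacency, literal.raw_adjacency.T)

    def test_empty_after_filtering_raises(self):
        with pytest.raises(EmptyModelError):
            build_adjacency([InteractionRecord("A", "B", "activation", 100)], 500)

    def test_self_loop_permitted(self):
        model = build_adjacency([InteractionRecord("A", "A", "inhibition")])
        assert model.raw_adjacency[0, 0] == -1

    def test_permutation_equivariance(self, rng):
        records = [
            InteractionRecord(f"g{i}", f"g{j}", mech)
            for i, j, mech in [
                (0, 1, "activation"), (1, 2, "inhibition"), (2, 0, "activation"),
                (0, 2, "binding"), (2, 1, "inhibition"),
            ]
        ]
        reference = build_adjacency(records).raw_adjacency
        for _ in range(5):
            shuffled = [records[i] for i in rng.permutation(len(records))]
            np.testing.assert_array_equal(build_adjacency(shuffled).raw_adjacency, reference)

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 5),
                st.integers(0, 5),
                st.sampled_from(["activation", "inhibition", "binding"]),
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_entries_always_in_unit_interval(self, edges):
        records = [InteractionRecord(f"g{i}", f"g{j}", m) for i, j, m in edges]
        model = build_adjacency(records)
        assert np.all(model.raw_adjacency >= -1) and np.all(model.raw_adjacency <= 1)


class TestNormalizeDynamics:
    def _model(self, raw):
        raw = np.asarray(raw, dtype=float)
        genes = [f"g{i}" for i in range(raw.shape[0])]
        return SystemModel(genes=genes, raw_adjacency=raw)

    def test_nilpotent_left_unchanged(self):
        model = normalize_dynamics(self._model([[0, 1], [0, 0]]))
        assert model.normalization == 0
        np.testing.assert_array_equal(model.dynamics, model.raw_adjacency)

    def test_real_unit_eigenvalues(self):
        model = normalize_dynamics(self._model([[0, 1], [1, 0]]))
        assert model.normalization == pytest.approx(1.0)
        np.testing.assert_allclose(model.dynamics, model.raw_adjacency)

    def test_complex_unit_magnitude_eigenvalues(self):
        # eigenvalues +/- i: characteristic polynomial x^2 + 1
        model = normalize_dynamics(self._model([[0, 1], [-1, 0]]))
        assert model.normalization == pytest.approx(1.0)
        np.testing.assert_allclose(model.dynamics, model.raw_adjacency)

    def test_normalization_times_dynamics_recovers_raw(self, rng):
        raw = rng.choice([-1.0, 0.0, 1.0], size=(8, 8))
        model = normalize_dynamics(self._model(raw))
        if model.normalization > 0:
            np.testing.assert_allclose(
                model.dynamics * model.normalization, model.raw_adjacency, atol=1e-12
            )

    def test_spectral_radius_at_most_one(self, rng):
        for _ in range(20):
            raw = rng.choice([-1.0, 0.0, 1.0], size=(10, 10), p=[0.1, 0.8, 0.1])
            model = normalize_dynamics(self._model(raw))
            radius = np.max(np.abs(np.linalg.eigvals(model.dynamics)))
            assert radius <= 1 + 1e-9

    def test_stability_margin_shrinks_radius(self):
        model = normalize_dynamics(self._model([[0, 1], [1, 0]]), stability_margin=0.05)
        radius = np.max(np.abs(np.linalg.eigvals(model.dynamics)))
        assert radius == pytest.approx(1 / 1.05)
        np.testing.assert_allclose(
            model.dynamics * model.normalization, model.raw_adjacency, atol=1e-12
        )

    def test_non_finite_entries_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            normalize_dynamics(self._model([[np.inf, 0], [0, 0]]))


class TestSystemModel:
    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError, match="duplicates"):
            SystemModel(genes=["a", "a"], raw_adjacency=np.zeros((2, 2)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            SystemModel(genes=["a", "b"], raw_adjacency=np.zeros((3, 3)))

    def test_save_load_round_trip(self, two_gene_model, tmp_path):
        two_gene_model.save(tmp_path / "model")
        loaded = type(two_gene_model).load(tmp_path / "model")
        assert loaded.genes == two_gene_model.genes
        np.testing.assert_allclose(loaded.raw_adjacency, two_gene_model.raw_adjacency)
        np.testing.assert_allclose(loaded.dynamics, two_gene_model.dynamics)
        assert loaded.normalization == pytest.approx(two_gene_model.normalization)
        assert loaded.layout == two_gene_model.layout
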