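"""SVM trait models: training, prediction, ranking, serialization."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cogtrait.genotype_io import GenotypeProfile, Label, PhenotypeTable
from cogtrait.trait_model import (
    FeatureDirection,
    ModelFormatError,
    RankingUnsupportedError,
    SingleClassError,
    TraitModel,
    load_model,
    predict,
    rank_features,
    save_model,
    train,
)


def _planted_dataset(n_per_class=10, n_background=30, seed=0):
    """Positives carry marker 'T1'; background COGs are random per genome."""
    rng = np.random.default_rng(seed)
    profiles, labels = [], {}
    for i in range(2 * n_per_class):
        positive = i < n_per_class
        cogs = {f"B{j:03d}" for j in rng.choice(n_background, 8, replace=False)}
        if positive:
            cogs.add("T1")
        profiles.append(GenotypeProfile(f"g{i:02d}", frozenset(cogs)))
        labels[f"g{i:02d}"] = Label.POSITIVE if positive else Label.NEGATIVE
    return profiles, PhenotypeTable("planted", labels)


@pytest.fixture(scope="module")
def planted():
    profiles, labels = _planted_dataset()
    return profiles, labels, train(profiles, labels)


class TestTrain:
    def test_planted_marker_gets_largest_weight_magnitude(self, planted):
        _, _, model = planted
        idx = model.vocabulary.index("T1")
        others = np.abs(np.delete(model.weights, idx))
        assert abs(model.weights[idx]) > others.max()
        assert model.weights[idx] > 0

    def test_new_genome_with_marker_predicted_positive(self, planted):
        _, _, model = planted
        (pred,) = predict(model, [GenotypeProfile("new", frozenset({"T1"}))])
        assert pred.label is Label.POSITIVE

    def test_vocabulary_is_sorted_union_of_training_cogs(self, planted):
        profiles, _, model = planted
        union = sorted(set().union(*(p.cogs for p in profiles)))
        assert list(model.vocabulary) == union
        assert len(model.weights) == len(model.vocabulary)

    def test_single_class_training_set_is_an_error(self):
        profiles, labels = _planted_dataset()
        all_pos = PhenotypeTable(
            "t", {g: Label.POSITIVE for g in labels.labels}
        )
        with pytest.raises(SingleClassError, match="no negative examples"):
            train(profiles, all_pos)

    def test_unknown_labels_are_excluded_from_counts(self):
        profiles, labels = _planted_dataset()
        labels.labels["g00"] = Label.UNKNOWN
        labels.labels["g19"] = Label.UNKNOWN
        model = train(profiles, labels)
        assert model.n_train_pos == 9
        assert model.n_train_neg == 9

    def test_labelled_genome_without_profile_is_excluded_with_warning(
        self, caplog
    ):
        profiles, labels = _planted_dataset()
        labels.labels["ghost"] = Label.POSITIVE
        with caplog.at_level("WARNING"):
            model = train(profiles, labels)
        assert model.n_train_pos == 10
        assert "1 labelled genome(s) lack genotype profiles" in caplog.text

    def test_training_is_invariant_to_genome_order(self, planted):
        profiles, labels, model = planted
        shuffled = train(list(reversed(profiles)), labels)
        probes = profiles + [GenotypeProfile("probe", frozenset({"T1", "B001"}))]
        a = [p.decision_value for p in predict(model, probes)]
        b = [p.decision_value for p in predict(shuffled, probes)]
        assert a == b  # bit-identical, not merely close

    def test_invalid_cost_rejected(self, planted):
        profiles, labels, _ = planted
        with pytest.raises(ValueError, match="cost_C"):
            train(profiles, labels, cost_C=0)


class TestPredict:
    def test_unseen_cogs_fall_back_to_bias(self, planted):
        _, _, model = planted
        (pred,) = predict(
            model, [GenotypeProfile("novel", frozenset({"ZZZ1", "ZZZ2"}))]
        )
        assert pred.decision_value == model.bias
        # tie (or negative bias) conservatively predicts NEGATIVE
        expected = Label.POSITIVE if model.bias > 0 else Label.NEGATIVE
        assert pred.label is expected

    def test_empty_profile_is_valid_input(self, planted):
        _, _, model = planted
        (pred,) = predict(model, [GenotypeProfile("empty", frozenset())])
        assert pred.decision_value == model.bias

    def test_training_set_is_perfectly_classified(self, planted):
        profiles, labels, model = planted
        for pred in predict(model, profiles):
            assert pred.label is labels.labels[pred.genome_id]

    def test_decision_value_is_sum_of_present_weights_plus_bias(self, planted):
        _, _, model = planted
        cogs = frozenset({"T1", "B001", "unseen"})
        expected = model.bias + sum(
            model.weights[model.vocabulary.index(c)]
            for c in cogs
            if c in model.vocabulary
        )
        (pred,) = predict(model, [GenotypeProfile("probe", cogs)])
        assert pred.decision_value == pytest.approx(expected, abs=1e-12)


class TestRankFeatures:
    def test_planted_marker_ranks_first_as_presence_predictor(self, planted):
        _, _, model = planted
        top = rank_features(model, top_n=1)[0]
        assert top.cog == "T1"
        assert top.rank == 1
        assert top.direction is FeatureDirection.PRESENCE_PREDICTS_POSITIVE

    def test_absence_driven_trait_yields_negative_predictors(self, absence_data):
        profiles, labels, truth = absence_data
        model = train(profiles, labels)
        top = rank_features(model, top_n=len(truth.marker_cogs))
        assert all(
            f.direction is FeatureDirection.ABSENCE_PREDICTS_POSITIVE
            for f in top
        )
        assert {f.cog for f in top} == set(truth.marker_cogs)

    def test_zero_weights_rank_lexicographically_as_absence(self):
        model = TraitModel(
            trait_name="t",
            vocabulary=("A", "B", "C"),
            weights=np.zeros(3),
            bias=0.0,
            n_train_pos=1,
            n_train_neg=1,
        )
        ranked = rank_features(model)
        assert [f.cog for f in ranked] == ["A", "B", "C"]
        assert all(
            f.direction is FeatureDirection.ABSENCE_PREDICTS_POSITIVE
            for f in ranked
        )

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=30))
    def test_ranking_invariants(self, weights):
        vocab = tuple(f"C{i:03d}" for i in range(len(weights)))
        model = TraitModel(
            trait_name="t",
            vocabulary=vocab,
            weights=np.asarray(weights),
            bias=0.0,
            n_train_pos=1,
            n_train_neg=1,
        )
        ranked = rank_features(model)
        mags = [abs(f.weight) for f in ranked]
        assert mags == sorted(mags, reverse=True)
        assert [f.rank for f in ranked] == list(range(1, len(vocab) + 1))
        assert {f.cog for f in ranked} == set(vocab)

    def test_nonlinear_kernel_cannot_be_ranked(self):
        profiles, labels = _planted_dataset()
        model = train(profiles, labels, kernel="rbf")
        with pytest.raises(RankingUnsupportedError, match="linear kernel"):
            rank_features(model)


class TestNonLinearKernels:
    def test_rbf_model_predicts_training_data(self):
        profiles, labels = _planted_dataset()
        model = train(profiles, labels, kernel="rbf")
        assert model.weights is None
        assert not model.supports_ranking
        for pred in predict(model, profiles):
            assert pred.label is labels.labels[pred.genome_id]

    def test_polynomial_alias_accepted(self):
        profiles, labels = _planted_dataset()
        model = train(profiles, labels, kernel="polynomial")
        assert model.kernel == "poly"

    def test_unknown_kernel_rejected(self):
        profiles, labels = _planted_dataset()
        with pytest.raises(ValueError, match="unknown kernel"):
            train(profiles, labels, kernel="quadratic")

    def test_nonlinear_model_cannot_be_serialized(self, tmp_path):
        profiles, labels = _planted_dataset()
        model = train(profiles, labels, kernel="rbf")
        with pytest.raises(ValueError, match="linear-kernel"):
            save_model(model, tmp_path / "m.txt")


class TestSerialization:
    def test_round_trip_preserves_all_fields(self, planted, tmp_path):
        _, _, model = planted
        path = tmp_path / "m.txt"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.trait_name == model.trait_name
        assert loaded.vocabulary == model.vocabulary
        assert np.array_equal(loaded.weights, model.weights)
        assert loaded.bias == model.bias
        assert loaded.cost_C == model.cost_C
        assert (loaded.n_train_pos, loaded.n_train_neg) == (
            model.n_train_pos,
            model.n_train_neg,
        )

    def test_save_load_save_is_byte_identical(self, planted, tmp_path):
        _, _, model = planted
        p1, p2 = tmp_path / "m1.txt", tmp_path / "m2.txt"
        save_model(model, p1)
        save_model(load_model(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_decision_values_survive_round_trip_exactly(self, planted, tmp_path):
        profiles, _, model = planted
        path = tmp_path / "m.txt"
        save_model(model, path)
        loaded = load_model(path)
        before = [p.decision_value for p in predict(model, profiles)]
        after = [p.decision_value for p in predict(loaded, profiles)]
        assert before == after

    def test_truncated_file_is_a_parse_error(self, planted, tmp_path):
        _, _, model = planted
        path = tmp_path / "m.txt"
        save_model(model, path)
        text = path.read_text().splitlines()
        path.write_text("\n".join(text[: len(text) // 2]) + "\n")
        with pytest.raises(ModelFormatError):
            load_model(path)

    def test_unknown_version_header_rejected(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text("# cogtrait model format v99\n[meta]\n")
        with pytest.raises(ModelFormatError, match="v1"):
            load_model(path)

    def test_garbage_file_rejected(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text("not a model\n")
        with pytest.raises(ModelFormatError):
            load_model(path)
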