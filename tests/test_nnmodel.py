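import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palnn.nnmodel import (
    GENOME_WIDE_PRESET,
    SMALL_PRESET,
    ModelConfig,
    TrainedModel,
    balance_dataset,
    build_model,
    default_hidden_sizes,
    parameter_count,
    train,
    train_ensemble,
)


def toy_config(**over):
    base = dict(
        input_size=10, hidden1=6, hidden2=4, input_mask_p=0.0,
        hidden_dropout_p=0.0, learning_rate=5e-3, weight_decay=0.0,
        epochs=5, batch_size=32, label_noise_sd=0.0, input_noise_sd=0.0,
        n_val_cases=10, n_val_controls=10, seed=8, dtype="float64",
    )
    base.update(over)
    return ModelConfig(**base)


def toy_data(seed=42, n=120, L=10):
    rng = np.random.default_rng(seed)
    x = rng.choice([-1.0, 0.0, 1.0], size=(n, L))
    y = (x[:, 2] + 0.5 * x[:, 7] > 0).astype(int)
    return x, y


class TestArchitecture:
    def test_genome_wide_parameter_count(self):
        model = build_model(ModelConfig(**GENOME_WIDE_PRESET))
        assert model.n_parameters == 84_260_139

    def test_small_preset_parameter_count(self):
        # closed-form affine count: 20714*82+82 + 82*8+8 + 8+1
        assert parameter_count(**{k: SMALL_PRESET[k] for k in
                                  ("input_size", "hidden1", "hidden2")}) == 1_699_303

    @given(
        L=st.integers(1, 300),
        h1=st.integers(1, 40),
        h2=st.integers(1, 20),
    )
    @settings(max_examples=25, deadline=None)
    def test_count_formula_matches_introspection(self, L, h1, h2):
        model = build_model(ModelConfig(input_size=L, hidden1=h1, hidden2=h2,
                                        input_mask_p=0.0, hidden_dropout_p=0.0))
        assert model.n_parameters == parameter_count(L, h1, h2)

    def test_output_in_open_unit_interval(self):
        model = build_model(toy_config())
        out = model.predict(np.random.default_rng(0).normal(size=(50, 10)))
        assert np.all((out > 0) & (out < 1))

    def test_default_hidden_size_rule(self):
        assert default_hidden_sizes(290_522) == (291, 29)
        assert default_hidden_sizes(5000) == (8, 4)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            ModelConfig(input_size=10, input_mask_p=1.0)
        with pytest.raises(ValueError):
            ModelConfig(input_size=10, learning_rate=0.0)


class TestBalance:
    def test_paper_scale_counts(self):
        cases = [f"c{i}" for i in range(1814)]
        controls = [f"k{i}" for i in range(7325)]
        out = balance_dataset(cases, controls, seed=1)
        assert sum(1 for s in out if s.startswith("c")) == 3628
        assert sum(1 for s in out if s.startswith("k")) == 3662

    def test_small_counts(self):
        out = balance_dataset(list(range(10)), list(range(100, 120)), seed=2)
        assert sum(1 for s in out if s < 100) == 20
        assert sum(1 for s in out if s >= 100) == 10

    def test_each_case_exactly_twice(self):
        out = balance_dataset(["a", "b", "c"], list(range(10)), seed=3)
        assert sorted(s for s in out if isinstance(s, str)) == list("aabbcc")

    def test_controls_subset_without_replacement(self):
        controls = list(range(21))
        out = [s for s in balance_dataset(["a"], controls, seed=4) if s != "a"]
        assert len(out) == 10 and len(set(out)) == 10

    @pytest.mark.parametrize("n_controls", [37, 40, 43])
    def test_resulting_ratio_near_one(self, n_controls):
        # with controls ~ 4x cases the balanced ratio 4*cases/controls stays
        # within [0.9, 1.1] (up to the halving floor)
        out = balance_dataset(list(range(1000, 1010)), list(range(n_controls)),
                              seed=5)
        n_case = sum(1 for s in out if s >= 1000)
        n_ctrl = len(out) - n_case
        assert 0.9 <= n_case / n_ctrl <= 1.12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            balance_dataset([], [1], seed=0)


class TestTraining:
    def test_deterministic_history(self):
        x, y = toy_data()
        h1 = train(TrainedModel(toy_config()), x, y).history
        h2 = train(TrainedModel(toy_config()), x, y).history
        assert h1 == h2  # bitwise-identical loss history

    def test_frozen_loss_trajectory(self):
        # regression: plain deterministic fit with all stochastic layers off
        x, y = toy_data()
        model = train(TrainedModel(toy_config()), x, y)
        expected_train = [0.727693674346, 0.716094426785, 0.703454149267,
                          0.691598673922, 0.679132727162]
        expected_val = [0.702953417363, 0.701440421916, 0.700392344989,
                        0.700026253884, 0.699989494906]
        assert model.history["train_loss"] == pytest.approx(expected_train, abs=1e-10)
        assert model.history["val_loss"] == pytest.approx(expected_val, abs=1e-10)

    def test_history_lengths(self):
        x, y = toy_data()
        model = train(TrainedModel(toy_config(epochs=7)), x, y)
        assert len(model.history["train_loss"]) == 7
        assert len(model.history["val_loss"]) == 7

    def test_separable_data_improves(self, tiny_trained_model):
        model, _, _ = tiny_trained_model
        assert model.history["val_loss"][-1] < model.history["val_loss"][0]

    def test_validation_split_too_large(self):
        x, y = toy_data()
        with pytest.raises(ValueError, match="validation"):
            train(TrainedModel(toy_config(n_val_cases=1000)), x, y)

    def test_non_binary_labels_rejected(self):
        x, _ = toy_data()
        with pytest.raises(ValueError, match="binary"):
            train(TrainedModel(toy_config()), x, np.full(len(x), 2))

    def test_persistence_round_trip(self, tmp_path, tiny_trained_model):
        model, x, _ = tiny_trained_model
        model.save(tmp_path / "ckpt")
        back = TrainedModel.load(tmp_path / "ckpt")
        probe = x[:16]
        assert np.array_equal(back.predict(probe), model.predict(probe))
        assert back.history == model.history
        for k, v in model.params.items():
            assert np.array_equal(back.params[k], v)  # bit-identical reload


class TestEnsemble:
    def test_distinct_initializations(self):
        x, y = toy_data()
        models = train_ensemble(x, y, toy_config(epochs=1), seeds=[1, 2, 3])
        assert len(models) == 3
        w = [m.params["W1"] for m in models]
        assert not np.array_equal(w[0], w[1])
        assert [m.config.seed for m in models] == [1, 2, 3]

    def test_single_seed_reduces_to_train(self):
        x, y = toy_data()
        solo = train_ensemble(x, y, toy_config(), seeds=[8])[0]
        direct = train(TrainedModel(toy_config(seed=8)), x, y)
        assert solo.history == direct.history

    def test_duplicate_seeds_warn(self):
        x, y = toy_data()
        with pytest.warns(UserWarning, match="duplicate"):
            train_ensemble(x, y, toy_config(epochs=1), seeds=[1, 1])

    def test_permuted_labels_recorded_and_independent(self):
        x, y = toy_data()
        models = train_ensemble(x, y, toy_config(epochs=1), seeds=[1, 2],
                                permute_labels=True, permutation_seed=50)
        assert [m.label_permutation_seed for m in models] == [50, 51]

    def test_shared_permutation(self):
        x, y = toy_data()
        models = train_ensemble(x, y, toy_config(epochs=1), seeds=[1, 2],
                                permute_labels=True, permutation_seed=50,
                                shared_permutation=True)
        assert [m.label_permutation_seed for m in models] == [50, 50]

    def test_permuted_labels_do_not_learn_signal(self):
        # strong-signal fixture: true-label training improves validation loss,
        # permuted-label training does not
        rng = np.random.default_rng(9)
        x = rng.choice([-1.0, 0.0, 1.0], size=(400, 12))
        y = (x[:, 5] > 0).astype(int)
        cfg = toy_config(input_size=12, epochs=30, learning_rate=1e-2,
                         n_val_cases=20, n_val_controls=20)
        true_model = train_ensemble(x, y, cfg, seeds=[4])[0]
        null_model = train_ensemble(x, y, cfg, seeds=[4], permute_labels=True,
                                    permutation_seed=77)[0]
        true_gain = true_model.history["val_loss"][0] - true_model.history["val_loss"][-1]
        null_gain = null_model.history["val_loss"][0] - null_model.history["val_loss"][-1]
        assert true_gain > 0.1
        assert null_gain < 0.05
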