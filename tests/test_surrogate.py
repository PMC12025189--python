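"""MLP surrogate: activations, losses, training protocol, field prediction."""

import numpy as np
import pytest

from stemlattice import surrogate as sg
from stemlattice.dataset import build_corpus
from stemlattice.remodeling import RemodelParams


@pytest.fixture(scope="module")
def tiny_corpus():
    return build_corpus(6, seed=5, elem_size=4.0,
                        params=RemodelParams(max_iters=12))


class TestActivations:
    def test_values(self):
        assert sg.activation("sigmoid", 0.0) == pytest.approx(0.5)
        assert sg.activation("relu", -3.0) == 0.0
        assert sg.activation("tanh", 1.0) == pytest.approx(
            (np.e ** 2 - 1) / (np.e ** 2 + 1))

    def test_unknown_name(self):
        with pytest.raises(ValueError):
            sg.activation("swish", 1.0)


class TestLosses:
    def test_values(self):
        assert sg.losses([1.0, 0.0], [0.0, 0.0]) == (0.5, 0.5)
        assert sg.losses([0.3, 0.7], [0.3, 0.7]) == (0.0, 0.0)

    def test_mse_dominates_squared_mae(self):
        rng = np.random.default_rng(0)
        p, t = rng.normal(size=50), rng.normal(size=50)
        mse, mae = sg.losses(p, t)
        assert mse >= mae ** 2 - 1e-12     # Jensen

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sg.losses([], [])


class TestSpec:
    @pytest.mark.parametrize("kwargs", [
        dict(n_hidden_layers=0), dict(n_hidden_layers=6),
        dict(neurons_per_layer=16), dict(activation="linear"),
        dict(batch_size=16),
    ])
    def test_out_of_range_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sg.MlpSpec(**kwargs)


class TestTrainingProtocol:
    def test_early_stop_after_patience(self):
        """Anti-correlated validation targets: validation loss rises while
        training converges, so the patience counter ends training exactly 5
        non-improving epochs past the best one, whose weights are restored."""
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(128, 3))
        y = X[:, 0]
        Xv = rng.uniform(size=(64, 3))
        yv = 1.0 - Xv[:, 0]
        est = sg.DensityMLP(n_hidden_layers=1, neurons_per_layer=32,
                            batch_size=32, max_epochs=100, patience=5,
                            random_state=0)
        est.fit(X, y, Xv, yv)
        assert est.n_epochs_ < 100
        assert est.n_epochs_ - est.best_epoch_ == 6   # best + 5 stalls + stop
        # restored weights reproduce the recorded minimum validation loss
        mse, _ = sg.losses(est.predict(Xv), yv)
        assert mse == pytest.approx(est.history_["val_loss"].min(), rel=1e-9)

    def test_learns_smooth_function(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(size=(500, 2))
        y = 0.3 + 0.4 * np.sin(2 * X[:, 0]) * X[:, 1]
        est = sg.DensityMLP(n_hidden_layers=2, neurons_per_layer=64,
                            batch_size=64, max_epochs=60, patience=None,
                            random_state=2)
        est.fit(X, y)
        assert est.history_["train_loss"].iloc[-1] < est.history_["train_loss"].iloc[0]
        mse, _ = sg.losses(est.predict(X), y)
        assert mse < 1e-3

    def test_overfit_capacity_tiny_set(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(size=(50, 11))
        y = rng.uniform(size=50)
        est = sg.DensityMLP(n_hidden_layers=3, neurons_per_layer=128,
                            batch_size=50, max_epochs=200, patience=None,
                            learning_rate=3e-3, random_state=4)
        est.fit(X, y)
        mse, _ = sg.losses(est.predict(X), y)
        assert mse < 1e-4

    def test_reproducible_with_seed(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(size=(128, 4))
        y = X.sum(axis=1) / 4
        preds = []
        for _ in range(2):
            est = sg.DensityMLP(n_hidden_layers=1, neurons_per_layer=32,
                                batch_size=32, max_epochs=10, patience=None,
                                random_state=11)
            est.fit(X, y)
            preds.append(est.predict(X))
        np.testing.assert_array_equal(preds[0], preds[1])


class TestTune:
    def test_budget_one_returns_single_spec(self, tiny_corpus):
        spec, trials = sg.tune(tiny_corpus, 1, seed=0, epochs=2)
        assert len(trials) == 1
        assert spec == sg.MlpSpec(**trials.iloc[0][
            ["n_hidden_layers", "neurons_per_layer", "activation", "batch_size"]
        ].to_dict())

    def test_specs_within_ranges_and_best_selected(self, tiny_corpus):
        spec, trials = sg.tune(tiny_corpus, 5, seed=1, epochs=2)
        assert 1 <= spec.n_hidden_layers <= 5
        assert 32 <= spec.neurons_per_layer <= 256
        assert trials["val_mae"].min() == pytest.approx(
            trials.loc[trials["val_mae"].idxmin(), "val_mae"])
        assert len(trials) == 5

    def test_zero_budget_rejected(self, tiny_corpus):
        with pytest.raises(ValueError):
            sg.tune(tiny_corpus, 0)


class TestPredictField:
    def test_field_clamped_and_solid_forced(self, tiny_corpus, midrange_dv,
                                            midrange_mesh):
        model = sg.train_final(tiny_corpus, sg.MlpSpec(n_hidden_layers=1,
                                                       neurons_per_layer=32),
                               seed=0, max_epochs=3)
        field = sg.predict_field(model, midrange_dv, midrange_mesh)
        band = field.remodel_mask
        assert np.all(field.vf[~band] == 1.0)
        assert field.vf[band].min() >= field.vf_min
        assert field.vf[band].max() <= 1.0

    def test_missing_scalers_rejected(self, midrange_dv, midrange_mesh):
        est = sg.DensityMLP(n_hidden_layers=1, neurons_per_layer=32,
                            max_epochs=1, random_state=0)
        est.fit(np.zeros((8, 11)), np.zeros(8))
        with pytest.raises(ValueError):
            sg.predict_field(est, midrange_dv, midrange_mesh)


class TestPersistence:
    def test_save_load_round_trip(self, tiny_corpus, tmp_path):
        model = sg.train_final(tiny_corpus, sg.MlpSpec(n_hidden_layers=1,
                                                       neurons_per_layer=32),
                               seed=0, max_epochs=3)
        sg.save_model(model, tmp_path / "m")
        back = sg.load_model(tmp_path / "m")
        X, _ = tiny_corpus.xy("val")
        np.testing.assert_allclose(back.predict(X), model.predict(X), rtol=1e-12)
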