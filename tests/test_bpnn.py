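"""Network building blocks against independent oracles.

The forward pass is checked against a naively coded per-neuron loop, the
analytic gradient against central finite differences, and the trainers
against a representable target and the analytic toy surface.
"""

import math

import numpy as np
import pytest

from leukotransit.bpnn import (
    Network,
    NetworkSpec,
    SurrogateModel,
    activation,
    activation_derivative,
    forward,
    init_network,
    jacobian,
    loss_and_gradient,
    min_hidden_nodes,
    train,
    train_surrogate,
)
from leukotransit.evaluation import r_squared
from leukotransit.sweep_dataset import toy_surface_table


class TestActivations:
    @pytest.mark.parametrize(
        "tag,x,expected",
        [
            ("logsig", 0.0, 0.5),
            ("tansig", 0.0, 0.0),
            ("purelin", 3.7, 3.7),
            ("logsig", 100.0, 1.0),
        ],
    )
    def test_values(self, tag, x, expected):
        assert activation(x, tag) == pytest.approx(expected)

    def test_tansig_is_odd_and_matches_definition(self):
        x = np.linspace(-5, 5, 101)
        assert np.allclose(activation(x, "tansig"), -activation(-x, "tansig"))
        assert np.allclose(activation(x, "tansig"), 2.0 / (1.0 + np.exp(-2 * x)) - 1.0)

    def test_derivative_consistency(self):
        x = np.linspace(-3, 3, 61)
        for tag in ("logsig", "tansig", "purelin"):
            a = activation(x, tag)
            num = (activation(x + 1e-6, tag) - activation(x - 1e-6, tag)) / 2e-6
            assert np.allclose(activation_derivative(a, tag), num, atol=1e-8)

    def test_unknown_tag(self):
        with pytest.raises(ValueError, match="unknown activation"):
            activation(0.0, "relu")


def naive_forward(net, x):
    """Independent matrix-free re-evaluation: explicit per-neuron loops."""
    a = list(map(float, x))
    for li, (w, b) in enumerate(zip(net.weights, net.biases)):
        out = []
        for k in range(w.shape[1]):
            s = b[k] + sum(a[i] * w[i, k] for i in range(w.shape[0]))
            out.append(float(activation(s, net.layer_activation(li))))
        a = out
    return np.array(a)


class TestForward:
    def test_zero_network_outputs_zero(self):
        spec = NetworkSpec(layer_sizes=[3, 4, 1])
        net = Network(
            [np.zeros((3, 4)), np.zeros((4, 1))], [np.zeros(4), np.zeros(1)], spec
        )
        out, _ = forward(net, [1.0, -2.0, 0.5])
        assert out == pytest.approx(0.0)

    def test_minimal_identity_chain(self):
        spec = NetworkSpec(layer_sizes=[1, 1, 1])
        net = Network(
            [np.ones((1, 1)), np.ones((1, 1))], [np.zeros(1), np.zeros(1)], spec
        )
        out, _ = forward(net, [0.0])
        assert out == pytest.approx(0.0)  # tansig(0) = 0, then purelin

    def test_matches_naive_loop_oracle(self):
        spec = NetworkSpec(layer_sizes=[2, 5, 10, 1], seed=7)
        net = init_network(spec)
        rng = np.random.default_rng(0)
        for x in rng.uniform(-2, 2, size=(5, 2)):
            out, _ = forward(net, x)
            assert out[0, 0] == pytest.approx(naive_forward(net, x)[0], abs=1e-12)

    def test_shape_mismatch(self):
        net = init_network(NetworkSpec(layer_sizes=[2, 3, 1], seed=0))
        with pytest.raises(ValueError, match="features"):
            forward(net, [1.0, 2.0, 3.0])


def relative_gradient_error(net, X, Y):
    """Max relative deviation of analytic vs central-difference gradient."""
    _, grads = loss_and_gradient(net, X, Y)
    flat_analytic = np.concatenate(
        [np.concatenate([dw.ravel(), db.ravel()]) for dw, db in grads]
    )
    eps = 1e-5  # balances truncation against roundoff in the oracle
    num = np.empty_like(flat_analytic)
    k = 0
    for li in range(net.n_layers):
        for arr in (net.weights[li], net.biases[li]):
            flat = arr.ravel()
            for i in range(flat.size):
                orig = flat[i]
                flat[i] = orig + eps
                up, _ = loss_and_gradient(net, X, Y)
                flat[i] = orig - eps
                dn, _ = loss_and_gradient(net, X, Y)
                flat[i] = orig
                num[k] = (up - dn) / (2 * eps)
                k += 1
    scale = np.maximum(np.abs(num), 1e-4)
    return np.max(np.abs(flat_analytic - num) / scale)


class TestGradient:
    def test_perfect_predictions_zero_gradient(self):
        spec = NetworkSpec(layer_sizes=[1, 1])
        net = Network([np.array([[2.0]])], [np.array([0.5])], spec)
        X = np.array([[1.0], [2.0]])
        Y = 2.0 * X + 0.5
        mse, grads = loss_and_gradient(net, X, Y)
        assert mse == pytest.approx(0.0)
        for dw, db in grads:
            assert np.allclose(dw, 0) and np.allclose(db, 0)

    def test_single_layer_reduces_to_delta_rule(self):
        # purelin single layer: gradient of MSE is 2/n * x^T (o - y)
        spec = NetworkSpec(layer_sizes=[2, 1])
        net = Network([np.array([[0.3], [-0.2]])], [np.array([0.1])], spec)
        X = np.array([[1.0, 2.0]])
        Y = np.array([[1.5]])
        o, _ = forward(net, X)
        _, grads = loss_and_gradient(net, X, Y)
        expected = 2.0 * (o - Y)[0, 0] * X[0]
        assert np.allclose(grads[0][0].ravel(), expected)
        assert np.allclose(grads[0][1], 2.0 * (o - Y)[0, 0])

    def test_finite_difference_agreement_on_study_shape(self):
        spec = NetworkSpec(layer_sizes=[2, 5, 10, 1], seed=42)
        net = init_network(spec)
        rng = np.random.default_rng(42)
        X = rng.uniform(-1, 1, (8, 2))
        Y = rng.uniform(-1, 1, (8, 1))
        assert relative_gradient_error(net, X, Y) < 1e-6

    def test_finite_difference_agreement_many_configs(self):
        # 100 seeded small architectures
        rng = np.random.default_rng(2024)
        for trial in range(100):
            sizes = [int(rng.integers(1, 4)), int(rng.integers(2, 5)),
                     int(rng.integers(2, 5)), 1]
            net = init_network(NetworkSpec(layer_sizes=sizes, seed=trial))
            X = rng.uniform(-1, 1, (4, sizes[0]))
            Y = rng.uniform(-1, 1, (4, 1))
            assert relative_gradient_error(net, X, Y) < 1e-6

    def test_jacobian_matches_gradient(self):
        # J^T r recovers the backprop gradient of the SSE/2
        spec = NetworkSpec(layer_sizes=[2, 4, 1], seed=3)
        net = init_network(spec)
        rng = np.random.default_rng(3)
        X = rng.uniform(-1, 1, (6, 2))
        Y = rng.uniform(-1, 1, (6, 1))
        J, out = jacobian(net, X)
        r = (out - Y).ravel()
        _, grads = loss_and_gradient(net, X, Y)
        flat = np.concatenate([np.concatenate([dw.ravel(), db.ravel()]) for dw, db in grads])
        assert np.allclose(J.T @ r * 2.0 / r.size, flat, atol=1e-12)


class TestInit:
    def test_seed_determinism(self):
        spec = NetworkSpec(layer_sizes=[2, 5, 1], seed=9)
        a, b = init_network(spec), init_network(spec)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)
        c = init_network(spec, seed=10)
        assert any(not np.array_equal(wa, wc) for wa, wc in zip(a.weights, c.weights))

    def test_all_zero_init_rejected_in_training(self):
        spec = NetworkSpec(layer_sizes=[2, 3, 1])
        net = Network([np.zeros((2, 3)), np.zeros((3, 1))], [np.zeros(3), np.zeros(1)], spec)
        with pytest.raises(ValueError, match="symmetric"):
            train(net, toy_surface_table(4, 4))


class TestTraining:
    def test_representable_linear_target(self):
        # y = x with a 1-3-1 net reaches MSE below 1e-6
        import pandas as pd

        from leukotransit.sweep_dataset import SampleTable

        x = np.linspace(-2, 2, 50)
        df = pd.DataFrame({"x": x, "y": x})
        table = SampleTable.from_frame(df, ["x"], "y", fractions=(0.8, 0.1, 0.1), seed=0)
        spec = NetworkSpec(layer_sizes=[1, 3, 1], goal=1e-7, max_epochs=300, seed=1)
        net, report = train(init_network(spec), table, spec)
        assert min(report.train_mse) < 1e-6

    def test_toy_surface_heldout_r2(self):
        table = toy_surface_table(8, 8, seed=3)
        spec = NetworkSpec(layer_sizes=[2, 5, 10, 1], goal=1e-10, max_epochs=400,
                           max_fail=25, seed=5)
        model, _ = train_surrogate(table, spec, seed=5)
        test = table.df[table.df.split == "test"]
        r2 = r_squared(model.predict(test[["Re", "AR"]]), test["transit_time"])
        assert r2 > 0.999

    def test_end_to_end_determinism(self):
        table = toy_surface_table(6, 6, seed=2)
        spec = NetworkSpec(layer_sizes=[2, 4, 1], goal=1e-9, max_epochs=50, seed=8)
        _, rep1 = train(init_network(spec), table, spec)
        _, rep2 = train(init_network(spec), table, spec)
        assert rep1.train_mse == rep2.train_mse
        assert rep1.best_epoch == rep2.best_epoch
        assert rep1.stop_reason == rep2.stop_reason

    def test_best_validation_weights_returned(self):
        table = toy_surface_table(8, 8, seed=4)
        spec = NetworkSpec(layer_sizes=[2, 5, 10, 1], goal=1e-12, max_epochs=200,
                           max_fail=10, seed=4)
        net, report = train(init_network(spec), table, spec)
        # report invariant: best-val MSE is the minimum of the recorded curve
        assert report.best_val_mse == pytest.approx(min(report.val_mse))
        X_va, Y_va = table.normalized_arrays("val")
        out, _ = forward(net, X_va)
        assert float(np.mean((out - Y_va) ** 2)) == pytest.approx(report.best_val_mse, rel=1e-9)

    def test_gd_monotone_on_convex_problem(self):
        # single purelin layer, full batch, small rate: convex least squares
        import pandas as pd

        from leukotransit.sweep_dataset import SampleTable

        rng = np.random.default_rng(0)
        x = rng.uniform(-1, 1, 60)
        df = pd.DataFrame({"x": x, "y": 0.7 * x + 0.2})
        table = SampleTable.from_frame(df, ["x"], "y", fractions=(1.0, 0.0, 0.0), seed=0)
        spec = NetworkSpec(layer_sizes=[1, 1], hidden_activation="purelin",
                           trainer="gd", learning_rate=0.05, goal=1e-14, max_epochs=200, seed=0)
        _, report = train(init_network(spec), table, spec)
        diffs = np.diff(report.train_mse)
        assert np.all(diffs <= 1e-15)

    def test_gd_and_lm_agree_on_toy_surface(self):
        table = toy_surface_table(8, 8, seed=3)
        test = table.df[table.df.split == "test"]
        lm_spec = NetworkSpec(layer_sizes=[2, 5, 10, 1], goal=1e-12, max_epochs=400,
                              max_fail=25, seed=5)
        lm, _ = train_surrogate(table, lm_spec, seed=5)
        r2_lm = r_squared(lm.predict(test[["Re", "AR"]]), test["transit_time"])
        gd_spec = NetworkSpec(layer_sizes=[2, 5, 10, 1], trainer="gd", learning_rate=0.05,
                              goal=1e-12, max_epochs=30000, max_fail=10**6, seed=5)
        gd, _ = train_surrogate(table, gd_spec, seed=5)
        r2_gd = r_squared(gd.predict(test[["Re", "AR"]]), test["transit_time"])
        assert abs(r2_lm - r2_gd) < 1e-3


class TestHiddenNodeRule:
    @pytest.mark.parametrize("M,h,expected", [(2, 115, 15), (1, 1, 1), (2, 10, 4)])
    def test_values(self, M, h, expected):
        assert min_hidden_nodes(M, h) == expected

    def test_brute_force_oracle(self):
        # independent scan with explicit binomial sums
        def oracle(M, h):
            I = 1
            while sum(math.comb(I, n) for n in range(M + 1)) <= h:
                I += 1
            return I

        for M in (1, 2, 3):
            for h in (1, 5, 50, 115, 500):
                assert min_hidden_nodes(M, h) == oracle(M, h)

    def test_invalid(self):
        with pytest.raises(ValueError):
            min_hidden_nodes(0, 10)


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path):
        table = toy_surface_table(6, 6, seed=1)
        spec = NetworkSpec(layer_sizes=[2, 4, 1], goal=1e-8, max_epochs=40, seed=2)
        model, _ = train_surrogate(table, spec, seed=2)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = SurrogateModel.load(path)
        X = table.df[["Re", "AR"]]
        assert np.allclose(loaded.predict(X), model.predict(X))
        assert loaded.norm == model.norm

    def test_bad_format_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"format": "something-else"}')
        with pytest.raises(ValueError, match="format"):
            SurrogateModel.load(path)
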