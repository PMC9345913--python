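"""Sugeno ANFIS: membership functions, forward pass, hybrid learning."""

import copy
import itertools

import numpy as np
import pytest

import dryanfis as da
from dryanfis.anfis import (
    _consequent_outputs,
    _firing_from_degrees,
    _premise_gradient,
)

MF = da.MembershipFunction


def random_mf(family, rng):
    """A valid random membership function whose support covers [-0.5, 1.5],
    so that random models leave no dead zones for sampled inputs."""
    c = rng.uniform(0, 1)
    if family == "trimf":
        w = rng.uniform(1.6, 2.5)
        return MF("trimf", [c - w, c, c + w])
    if family == "gaussmf":
        return MF("gaussmf", [rng.uniform(0.05, 0.6), c])
    if family == "gbellmf":
        return MF("gbellmf", [rng.uniform(0.1, 0.8), rng.uniform(0.6, 3.0), c])
    w = rng.uniform(1.6, 2.5)
    inner = rng.uniform(0.05, 0.3)
    return MF("pimf", [c - w, c - inner, c + inner, c + w])


def random_model(rng, n_inputs=2, n_mf=2, family=None):
    """A random grid-shaped model on [0, 1]^k with random consequents."""
    inputs = []
    for j in range(n_inputs):
        fam = family or rng.choice(da.MF_FAMILIES)
        mfs = [random_mf(fam, rng) for _ in range(n_mf)]
        lo = min(-0.5, min(m.center for m in mfs) - 0.1)
        hi = max(1.5, max(m.center for m in mfs) + 0.1)
        inputs.append(da.FuzzyInput(f"x{j}", lo, hi, mfs))
    rule_index = np.array(list(itertools.product(*(range(n_mf),) * n_inputs)))
    consequents = rng.normal(size=(rule_index.shape[0], n_inputs + 1))
    return da.ANFISModel(inputs=inputs,
                         rulebase=da.RuleBase(rule_index, consequents))


def forward_oracle(model, x):
    """Layer-by-layer brute-force forward pass (loops, no vectorization)."""
    degrees = [[float(mf(x[j])) for mf in fi.mfs]
               for j, fi in enumerate(model.inputs)]
    w = []
    for rule in model.rulebase.rule_index:
        prod = 1.0
        for j, m in enumerate(rule):
            prod *= degrees[j][m]
        w.append(prod)
    total = sum(w)
    out = 0.0
    for wi, coeffs in zip(w, model.rulebase.consequents):
        f = sum(c * xj for c, xj in zip(coeffs[:-1], x)) + coeffs[-1]
        out += (wi / total) * f
    return out


class TestMembershipFunctions:
    def test_gbell_center_is_one(self):
        assert MF("gbellmf", [2, 1, 5])(5.0) == 1.0

    def test_gauss_limits(self):
        mf = MF("gaussmf", [1.0, 0.0])
        assert mf(0.0) == 1.0
        assert mf(50.0) == pytest.approx(0.0, abs=1e-300)

    def test_triangle_linear_interpolation(self):
        mf = MF("trimf", [0, 1, 2])
        assert mf(0.5) == pytest.approx(0.5)
        assert mf(1.0) == 1.0
        assert mf(1.75) == pytest.approx(0.25)
        assert mf(-0.1) == 0.0 and mf(2.1) == 0.0

    def test_pi_curve_shape(self):
        mf = MF("pimf", [0, 1, 2, 3])
        assert mf(1.5) == 1.0            # plateau
        assert mf(0.5) == pytest.approx(0.5)   # S-ramp midpoint
        assert mf(2.5) == pytest.approx(0.5)   # Z-ramp midpoint
        assert mf(-0.5) == 0.0 and mf(3.5) == 0.0

    @pytest.mark.parametrize("family, params", [
        ("trimf", [1, 0, 2]),
        ("gaussmf", [0.0, 1]),
        ("gbellmf", [-1, 1, 0]),
        ("gbellmf", [1, 0, 0]),
        ("pimf", [0, 2, 1, 3]),
        ("nosuch", [1, 2]),
    ])
    def test_invalid_parameters_rejected_at_construction(self, family, params):
        with pytest.raises(da.InvalidInputError):
            MF(family, params)

    @pytest.mark.parametrize("family", da.MF_FAMILIES)
    def test_degrees_stay_in_unit_interval(self, family, rng):
        mf = random_mf(family, rng)
        x = rng.uniform(-5, 5, 500)
        y = mf(x)
        assert np.all(y >= 0) and np.all(y <= 1)


class TestGridPartition:
    @pytest.mark.parametrize("family", da.MF_FAMILIES)
    def test_adjacent_mfs_cross_near_half(self, family):
        fi = da.grid_partition("x", 0.0, 10.0, 3, family)
        centers = [mf.center for mf in fi.mfs]
        assert centers == pytest.approx([0.0, 5.0, 10.0])
        for left, right in zip(fi.mfs, fi.mfs[1:]):
            mid = 0.5 * (left.center + right.center)
            assert left(mid) == pytest.approx(0.5, abs=1e-9)
            assert right(mid) == pytest.approx(0.5, abs=1e-9)

    def test_rule_explosion(self):
        for n_mf, expected in [(2, 8), (3, 27), (5, 125)]:
            model = da.ANFISModel.from_grid(
                ["a", "b", "c"], [(0, 1)] * 3, n_mf, "gaussmf")
            assert model.n_rules == expected


class TestForwardPass:
    def test_hand_set_degrees_product(self):
        degrees = [np.array([[0.8, 0.2]]), np.array([[0.5, 0.5]])]
        ridx = np.array(list(itertools.product(range(2), range(2))))
        w = _firing_from_degrees(degrees, ridx)[0]
        assert w == pytest.approx([0.40, 0.40, 0.10, 0.10])

    def test_zero_degree_kills_rule(self, rng):
        model = random_model(rng, family="trimf")
        a = model.inputs[0].mfs[0].params[0]
        x = np.array([a - 10.0, 0.5])  # far left of every triangle of input 0
        w = da.firing_strengths(model, x)
        assert np.all(w[model.rulebase.rule_index[:, 0] == 0] == 0)

    def test_normalize_examples(self):
        assert da.normalize(np.array([0.4, 0.4, 0.1, 0.1])) == pytest.approx(
            [0.4, 0.4, 0.1, 0.1])
        assert da.normalize(np.array([2.0, 2.0])) == pytest.approx([0.5, 0.5])

    def test_normalize_conservation(self, rng):
        w = rng.uniform(0.0, 1.0, size=(200, 27)) + 1e-9
        assert da.normalize(w).sum(axis=1) == pytest.approx(np.ones(200))

    def test_normalize_scale_invariance(self, rng):
        w = rng.uniform(0.1, 1.0, 27)
        np.testing.assert_allclose(da.normalize(3.7 * w), da.normalize(w))

    def test_all_zero_firing_raises(self):
        with pytest.raises(da.DegenerateInputError):
            da.normalize(np.zeros(4))

    def test_constant_consequents_give_constant_output(self, rng):
        model = random_model(rng, n_inputs=2, n_mf=3, family="gaussmf")
        model.rulebase.consequents[:] = 0.0
        model.rulebase.consequents[:, -1] = 4.2
        x = rng.uniform(0, 1, size=(50, 2))
        assert model.predict(x) == pytest.approx(np.full(50, 4.2))

    def test_single_rule_model_is_its_linear_function(self, rng):
        model = random_model(rng, n_inputs=1, n_mf=2, family="gaussmf")
        model.rulebase = da.RuleBase(np.array([[0]]),
                                     np.array([[2.0, -1.0]]))
        x = rng.uniform(0, 1, size=(20, 1))
        assert model.predict(x) == pytest.approx(2.0 * x[:, 0] - 1.0)

    @pytest.mark.parametrize("family", da.MF_FAMILIES)
    def test_matches_brute_force_oracle(self, family, rng):
        for n_inputs, n_mf in [(1, 2), (2, 3), (3, 2), (3, 3)]:
            model = random_model(rng, n_inputs=n_inputs, n_mf=n_mf, family=family)
            for _ in range(10):
                x = rng.uniform(-0.2, 1.2, n_inputs)
                if da.firing_strengths(model, x).sum() < 1e-9:
                    continue  # underflow floor regime, oracle not comparable
                assert da.predict(model, x) == pytest.approx(
                    forward_oracle(model, x), abs=1e-12, rel=1e-12)

    def test_wrong_input_arity_rejected(self, rng):
        model = random_model(rng, n_inputs=2)
        with pytest.raises(da.InvalidInputError):
            model.predict(np.zeros((5, 3)))


class TestLSEConsequents:
    def test_recovers_generating_consequents(self, rng):
        model = random_model(rng, n_inputs=2, n_mf=2, family="gaussmf")
        truth = model.rulebase.consequents.copy()
        x = rng.uniform(0, 1, size=(60, 2))
        y = model.predict(x)
        model.rulebase.consequents[:] = 0.0
        est = da.lse_consequents(model, x, y)
        np.testing.assert_allclose(est, truth, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(model.predict(x), y, atol=1e-9)

    def test_zero_target_gives_zero_consequents(self, rng):
        model = random_model(rng, n_inputs=2, n_mf=2, family="gaussmf")
        x = rng.uniform(0, 1, size=(40, 2))
        est = da.lse_consequents(model, x, np.zeros(40))
        np.testing.assert_allclose(est, 0.0, atol=1e-10)

    def test_single_rule_reduces_to_simple_regression(self, rng):
        model = random_model(rng, n_inputs=1, n_mf=2, family="gaussmf")
        model.rulebase = da.RuleBase(np.array([[0]]), np.zeros((1, 2)))
        x = rng.uniform(0, 1, size=(30, 1))
        y = 3.0 * x[:, 0] + rng.normal(0, 0.1, 30)
        est = da.lse_consequents(model, x, y)
        slope, intercept = np.polyfit(x[:, 0], y, 1)
        assert est[0] == pytest.approx([slope, intercept], rel=1e-8)

    def test_pass_never_increases_training_sse(self, rng):
        for _ in range(5):
            model = random_model(rng, n_inputs=2, n_mf=2)
            x = rng.uniform(0, 1, size=(50, 2))
            y = rng.normal(size=50)
            before = np.sum((y - model.predict(x)) ** 2)
            da.lse_consequents(model, x, y)
            after = np.sum((y - model.predict(x)) ** 2)
            assert after <= before + 1e-9

    def test_rank_deficiency_warns_and_solves(self, rng):
        model = random_model(rng, n_inputs=2, n_mf=3, family="gaussmf")
        x = rng.uniform(0, 1, size=(8, 2))  # 8 samples, 27 coefficients
        y = rng.normal(size=8)
        with pytest.warns(UserWarning, match="minimum-norm"):
            da.lse_consequents(model, x, y)
        np.testing.assert_allclose(model.predict(x), y, atol=1e-6)


class TestPremiseGradient:
    @pytest.mark.parametrize("family", da.MF_FAMILIES)
    def test_matches_finite_differences(self, family, rng):
        model = random_model(rng, n_inputs=2, n_mf=2, family=family)
        x = rng.uniform(-0.1, 1.1, size=(25, 2))
        y = rng.normal(size=25)

        def sse():
            return float(np.sum((y - model.predict(x)) ** 2))

        analytic = _premise_gradient(model, x, y)
        h = 1e-6
        for j, fi in enumerate(model.inputs):
            for m, mf in enumerate(fi.mfs):
                for p in range(mf.params.size):
                    orig = mf.params[p]
                    mf.params[p] = orig + h
                    up = sse()
                    mf.params[p] = orig - h
                    down = sse()
                    mf.params[p] = orig
                    numeric = (up - down) / (2 * h)
                    assert analytic[j][m][p] == pytest.approx(
                        numeric, rel=1e-5, abs=1e-6), (family, j, m, p)

    def test_zero_error_means_zero_step(self, rng):
        model = random_model(rng, n_inputs=2, n_mf=2, family="gaussmf")
        x = rng.uniform(0, 1, size=(30, 2))
        y = model.predict(x)  # already exact
        before = [mf.params.copy() for fi in model.inputs for mf in fi.mfs]
        da.backprop_premise(model, x, y, step=0.1)
        after = [mf.params for fi in model.inputs for mf in fi.mfs]
        for b, a in zip(before, after):
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_zero_step_is_identity(self, rng):
        model = random_model(rng, n_inputs=2, n_mf=2)
        x = rng.uniform(0, 1, size=(30, 2))
        y = rng.normal(size=30)
        before = [mf.params.copy() for fi in model.inputs for mf in fi.mfs]
        da.backprop_premise(model, x, y, step=0.0)
        for b, mf in zip(before, (m for fi in model.inputs for m in fi.mfs)):
            np.testing.assert_array_equal(mf.params, b)

    def test_step_reduces_error_on_descent_direction(self, rng):
        model = random_model(rng, n_inputs=2, n_mf=2, family="gaussmf")
        x = rng.uniform(0, 1, size=(40, 2))
        y = np.sin(3 * x[:, 0]) + x[:, 1]
        da.lse_consequents(model, x, y)
        before = np.sum((y - model.predict(x)) ** 2)
        da.backprop_premise(model, x, y, step=1e-4)
        after = np.sum((y - model.predict(x)) ** 2)
        assert after < before


class TestTraining:
    def test_noiseless_realizable_target_converges(self, rng):
        teacher = random_model(rng, n_inputs=2, n_mf=2, family="gaussmf")
        x = rng.uniform(0, 1, size=(80, 2))
        y = teacher.predict(x)
        student = da.ANFISModel(
            inputs=copy.deepcopy(teacher.inputs),
            rulebase=da.RuleBase(teacher.rulebase.rule_index.copy(),
                                 np.zeros_like(teacher.rulebase.consequents)))
        cfg = da.TrainConfig(max_epochs=10, seed=3, ridge=0.0)
        res = da.train(student, x, y, cfg)
        assert res.train_rmse_per_epoch[-1] < 1e-8
        assert np.all(np.diff(res.train_rmse_per_epoch) <= 1e-10)
        assert res.test_rmse < 1e-8

    def test_same_seed_reproduces_trajectories_bit_identically(self, rng):
        x = rng.uniform(0, 1, size=(60, 2))
        y = np.exp(-2 * x[:, 0]) + 0.1 * x[:, 1]
        cfg = da.TrainConfig(max_epochs=15, seed=11)
        runs = []
        for _ in range(2):
            model = da.ANFISModel.from_data(x, ["a", "b"], 2, "gbellmf")
            runs.append(da.train(model, x, y, cfg))
        np.testing.assert_array_equal(runs[0].train_rmse_per_epoch,
                                      runs[1].train_rmse_per_epoch)
        np.testing.assert_array_equal(runs[0].check_rmse_per_epoch,
                                      runs[1].check_rmse_per_epoch)
        assert runs[0].best_epoch == runs[1].best_epoch

    def test_best_epoch_is_first_argmin_and_snapshot_reproduces_it(self, rng):
        x = rng.uniform(0, 1, size=(80, 2))
        y = np.exp(-3 * x[:, 0]) * (1 + 0.2 * x[:, 1]) + rng.normal(0, 0.02, 80)
        cfg = da.TrainConfig(max_epochs=20, seed=5)
        model = da.ANFISModel.from_data(x, ["a", "b"], 2, "gaussmf")
        res = da.train(model, x, y, cfg)
        hist = res.check_rmse_per_epoch
        assert res.best_epoch == int(np.argmin(hist)) + 1
        ic = res.split_indices["check"]
        re_eval = da.rmse(y[ic], res.model_at_best.predict(x[ic]))
        assert re_eval == pytest.approx(hist[res.best_epoch - 1], rel=1e-12)

    def test_invalid_config_rejected(self):
        with pytest.raises(da.InvalidConfigError):
            da.TrainConfig(max_epochs=0)
        with pytest.raises(da.InvalidConfigError):
            da.TrainConfig(split=(0.5, 0.2, 0.2))

    def test_split_is_a_partition(self):
        tr, ck, te = da.split_dataset(100, (0.6, 0.15, 0.25), seed=2)
        assert sorted(np.concatenate([tr, ck, te])) == list(range(100))
        assert tr.size == 60 and ck.size == 15 and te.size == 25


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert da.rmse(y, y) == 0.0
        assert da.r_squared(y, y) == 1.0

    def test_mean_prediction_has_zero_r2(self):
        y = np.array([0.0, 1.0, 2.0])
        assert da.r_squared(y, np.full(3, y.mean())) == pytest.approx(0.0)

    def test_rmse_arithmetic(self):
        assert da.rmse([0, 1, 2], [0, 1, 1]) == pytest.approx(np.sqrt(1 / 3))

    def test_constant_target_r2_undefined(self):
        with pytest.raises(da.InvalidInputError):
            da.r_squared([1.0, 1.0, 1.0], [1.0, 2.0, 1.0])


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, rng):
        model = random_model(rng, n_inputs=3, n_mf=2)
        clone = da.ANFISModel.from_json(model.to_json())
        x = rng.uniform(0, 1, size=(40, 3))
        np.testing.assert_array_equal(model.predict(x), clone.predict(x))

    def test_trained_model_round_trips_through_file(self, rng, tmp_path):
        x = rng.uniform(0, 1, size=(60, 2))
        y = np.exp(-x[:, 0]) + x[:, 1]
        model = da.ANFISModel.from_data(x, ["a", "b"], 2, "pimf")
        res = da.train(model, x, y, da.TrainConfig(max_epochs=5, seed=1))
        path = tmp_path / "model.json"
        res.model_at_best.save(path)
        loaded = da.ANFISModel.load(path)
        assert loaded.trained
        np.testing.assert_array_equal(res.model_at_best.predict(x),
                                      loaded.predict(x))
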