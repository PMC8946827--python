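"""Network, loss and training-loop tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ipgbp.ssrnet import (
    SSRNetConfig,
    LossSpec,
    ParameterBudgetError,
    ConvergenceUndefinedError,
    compute_quartiles,
    penalty_loss,
    penalty_weights,
    build_ssrnet,
    train_personalized,
    predict_bp,
    convergence_epoch,
    SSRNet,
)


def _quartile_oracle(values):
    """Sorted linear-interpolation quantiles, written from the definition."""
    v = sorted(values)
    n = len(v)
    out = []
    for q in (0.25, 0.5, 0.75):
        pos = q * (n - 1)
        lo = int(np.floor(pos))
        frac = pos - lo
        out.append(v[lo] + frac * (v[min(lo + 1, n - 1)] - v[lo]))
    return tuple(out)


class TestQuartiles:
    def test_constant_sequence(self):
        assert compute_quartiles([5.0] * 30) == (5.0, 5.0, 5.0)

    def test_one_to_eight_matches_definition_oracle(self):
        values = list(range(1, 9))
        assert compute_quartiles(values) == pytest.approx(_quartile_oracle(values), abs=1e-12)

    def test_permutation_invariance(self):
        values = [3.0, 9.0, 1.0, 7.0, 5.0, 2.0]
        assert compute_quartiles(values) == compute_quartiles(sorted(values, reverse=True))

    def test_random_vectors_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            v = rng.normal(120, 5, size=rng.integers(4, 60))
            assert compute_quartiles(v) == pytest.approx(_quartile_oracle(v), abs=1e-12)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            compute_quartiles([1.0, 2.0, 3.0])


class TestPenaltyLoss:
    SPEC = LossSpec(alpha=3.0, Q1=115.0, Q3=124.0)

    def test_zero_error_gives_zero_loss(self):
        assert penalty_loss(130.0, 130.0, self.SPEC) == 0.0  # outside band too

    def test_inside_band_plain_absolute_error(self):
        assert penalty_loss(125.0, 120.0, self.SPEC) == pytest.approx(5.0)

    def test_above_q3_weighted_by_alpha(self):
        assert penalty_loss(125.0, 130.0, self.SPEC) == pytest.approx(15.0)

    def test_below_q1_weighted_by_alpha(self):
        assert penalty_loss(110.0, 100.0, self.SPEC) == pytest.approx(30.0)

    def test_boundary_reference_uses_unweighted_branch(self):
        assert penalty_loss(120.0, 115.0, self.SPEC) == pytest.approx(5.0)
        assert penalty_loss(120.0, 124.0, self.SPEC) == pytest.approx(4.0)

    def test_alpha_one_collapses_to_plain_mae(self):
        spec1 = LossSpec(alpha=1.0, Q1=115.0, Q3=124.0)
        rng = np.random.default_rng(2)
        pred = rng.normal(120, 6, 50)
        cuff = rng.normal(120, 6, 50)
        assert penalty_loss(pred, cuff, spec1) == pytest.approx(np.mean(np.abs(pred - cuff)))

    def test_batch_averages_per_sample_losses(self):
        pred = np.array([125.0, 125.0])
        cuff = np.array([120.0, 130.0])  # inside, outside
        assert penalty_loss(pred, cuff, self.SPEC) == pytest.approx((5.0 + 15.0) / 2)

    @settings(derandomize=True, max_examples=40)
    @given(pred=st.floats(80, 180), cuff=st.floats(80, 180))
    def test_never_below_plain_absolute_error(self, pred, cuff):
        loss = penalty_loss(pred, cuff, self.SPEC)
        assert loss >= abs(pred - cuff) - 1e-9
        if 115.0 <= cuff <= 124.0:
            assert loss == pytest.approx(abs(pred - cuff))

    def test_finite_difference_gradient_is_alpha_or_one(self):
        eps = 1e-6
        for cuff, expected in ((120.0, 1.0), (130.0, 3.0), (100.0, 3.0)):
            for pred in (cuff + 4.0, cuff - 4.0):
                g = (penalty_loss(pred + eps, cuff, self.SPEC)
                     - penalty_loss(pred - eps, cuff, self.SPEC)) / (2 * eps)
                assert abs(g) == pytest.approx(expected, rel=1e-5)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            LossSpec(alpha=0.5)
        with pytest.raises(ValueError):
            LossSpec(alpha=2.0, Q1=10.0, Q3=5.0)
        with pytest.raises(ValueError):
            penalty_weights(np.array([1.0]), LossSpec(alpha=2.0))


class TestBuild:
    def test_default_within_parameter_budget(self):
        model = build_ssrnet()
        assert model.n_parameters <= 40_000

    def test_budget_error_names_the_count(self):
        cfg = SSRNetConfig(max_params=100)
        with pytest.raises(ParameterBudgetError, match=r"\d+ trainable"):
            build_ssrnet(cfg)

    def test_predictions_bounded_by_bp_range(self):
        model = build_ssrnet(seed=1)
        rng = np.random.default_rng(0)
        preds = model.forward(rng.random((8, 32, 32)) * 100)
        assert np.all(preds >= 80.0) and np.all(preds <= 180.0)

    def test_batch_shape_contract(self):
        model = build_ssrnet(seed=2)
        preds = model.forward(np.random.default_rng(1).random((5, 32, 32)))
        assert preds.shape == (5,)

    def test_inference_deterministic(self):
        model = build_ssrnet(seed=3)
        img = np.random.default_rng(2).random((32, 32))
        assert predict_bp(model, img) == predict_bp(model, img)

    def test_zero_image_yields_stagewise_center_prediction(self):
        """Zero input + zero-initialized biases: uniform bins, no shifts.

        Hand computation for 3 stages of 3 bins: each stage's soft
        expectation is (K-1)/2 = 1, divided by cumulative bin products
        3, 9, 27, so y_norm = 1/3 + 1/9 + 1/27 = 13/27.
        """
        cfg = SSRNetConfig(dtype="float64")
        model = build_ssrnet(cfg, seed=4)
        y = predict_bp(model, np.zeros((32, 32)))
        expected = 80.0 + (180.0 - 80.0) * (13.0 / 27.0)
        assert y == pytest.approx(expected, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        model = build_ssrnet()
        with pytest.raises(ValueError):
            predict_bp(model, np.zeros((16, 16)))

    def test_save_load_round_trip(self, tmp_path):
        model = build_ssrnet(seed=6)
        img = np.random.default_rng(3).random((32, 32))
        model.save(tmp_path / "model")
        again = SSRNet.load(tmp_path / "model")
        assert predict_bp(again, img) == pytest.approx(predict_bp(model, img), rel=1e-6)


class TestBackprop:
    def test_analytic_gradients_match_finite_differences(self):
        model = build_ssrnet(SSRNetConfig(dtype="float64"), seed=5)
        rng = np.random.default_rng(3)
        x = rng.random((3, 32, 32))
        y = np.array([120.0, 115.0, 130.0])

        pred = model.forward(x)
        model.zero_grad()
        model.backward(np.sign(pred - y) / y.size)
        eps = 1e-6
        rs = np.random.default_rng(0)
        for w, g in model.parameters():
            flat, gf = w.ravel(), g.ravel()
            for idx in rs.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = np.mean(np.abs(model.forward(x) - y))
                flat[idx] = orig - eps
                lm = np.mean(np.abs(model.forward(x) - y))
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert gf[idx] == pytest.approx(num, abs=1e-4 * (1 + abs(num)))


def _convergence_oracle(history, rel_tol=0.02, patience=10):
    """Brute-force scan of the convergence definition (loops, no vectorizing)."""
    T = len(history)
    for e in range(1, T - patience + 1):  # 1-indexed epochs
        ok = True
        for j in range(e + 1, e + patience + 1):  # 1-indexed epochs to inspect
            prev_best = min(history[: j - 1])
            imp = (prev_best - history[j - 1]) / prev_best if prev_best > 0 else 0.0
            if imp >= rel_tol:
                ok = False
                break
        if ok:
            return e
    return None


class TestConvergenceEpoch:
    def test_flat_history_converges_at_epoch_one(self):
        assert convergence_epoch([5.0] * 50) == 1

    def test_always_halving_never_converges(self):
        h = [100.0 * 0.5**k for k in range(50)]
        assert convergence_epoch(h) is None

    def test_short_history_raises(self):
        with pytest.raises(ConvergenceUndefinedError):
            convergence_epoch([1.0] * 5, patience=10)

    def test_random_histories_match_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            h = list(np.abs(rng.normal(5, 2, size=40)).cumsum()[::-1] / 40 + rng.random(40))
            assert convergence_epoch(h) == _convergence_oracle(h)


@pytest.fixture(scope="module")
def toy_data():
    # images whose mean brightness encodes the target: learnable quickly
    rng = np.random.default_rng(0)
    y = rng.uniform(100, 140, 40)
    x = np.stack([np.full((32, 32), (v - 100) / 40) + 0.05 * rng.standard_normal((32, 32))
                  for v in y])
    return x, y


class TestTraining:
    def test_same_seed_identical_history(self, toy_data):
        x, y = toy_data
        _, r1 = train_personalized((x, y), epochs=4, seed=9)
        _, r2 = train_personalized((x, y), epochs=4, seed=9)
        assert r1.loss_history == r2.loss_history

    def test_loss_decreases_from_first_epoch(self, toy_data):
        x, y = toy_data
        _, rep = train_personalized((x, y), epochs=30, seed=1)
        assert rep.loss_history[-1] <= rep.loss_history[0]

    def test_alpha_one_training_equals_plain_mae_loss_values(self, toy_data):
        x, y = toy_data
        _, rep = train_personalized((x, y), loss=LossSpec(alpha=1.0), epochs=3, seed=2)
        assert rep.alpha_used == 1.0

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_personalized((np.empty((0, 32, 32)), np.empty(0)))

    def test_report_records_test_mae(self, toy_data):
        x, y = toy_data
        _, rep = train_personalized((x[:30], y[:30]), epochs=3, seed=3,
                                    test_pairs=(x[30:], y[30:]))
        assert rep.final_test_MAE is not None and np.isfinite(rep.final_test_MAE)
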