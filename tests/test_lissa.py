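import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lissarbf as lr
from lissarbf.lissa import (
    LGEBoundInputs,
    TrainingDivergedError,
    init_params,
    lissa_gradient,
)


class TestSigmoid:
    def test_zero_maps_to_half(self):
        assert lr.sigmoid(0.0) == 0.5

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(-50, 50))
    def test_symmetry_identity(self, x):
        assert lr.sigmoid(x) == pytest.approx(1.0 - lr.sigmoid(-x), abs=1e-12)

    @pytest.mark.parametrize("x", [500.0, -500.0, 1e8, -1e8])
    def test_stable_for_extreme_arguments(self, x):
        v = lr.sigmoid(x)
        assert np.isfinite(v) and 0.0 <= v <= 1.0


class TestAutoencoderForward:
    def test_all_zero_weights_give_half_everywhere(self):
        params = lr.AutoencoderParams(
            W=np.zeros((3, 4)), b1=np.zeros(4), V=np.zeros((4, 3)), b2=np.zeros(3)
        )
        C, Y = lr.ae_forward(np.array([[1.0, 0.0, 1.0]]), params)
        assert (C == 0.5).all() and (Y == 0.5).all()

    def test_scalar_chain_hand_check(self):
        # d=2, h=1: c = s(0.3*1 + (-0.2)*0 + 0.1), y_m = s(c*v_m + b2_m)
        params = lr.AutoencoderParams(
            W=np.array([[0.3], [-0.2]]),
            b1=np.array([0.1]),
            V=np.array([[0.5, -0.4]]),
            b2=np.array([0.2, -0.1]),
        )
        x = np.array([[1.0, 0.0]])
        c = 1.0 / (1.0 + np.exp(-(0.3 + 0.1)))
        y0 = 1.0 / (1.0 + np.exp(-(c * 0.5 + 0.2)))
        y1 = 1.0 / (1.0 + np.exp(-(c * -0.4 - 0.1)))
        C, Y = lr.ae_forward(x, params)
        assert C[0, 0] == pytest.approx(c, rel=1e-12)
        np.testing.assert_allclose(Y[0], [y0, y1], rtol=1e-12)

    def test_encode_matches_forward_codes(self, tiny_ae):
        X = np.array([[1.0, 0.0, 1.0, 1.0], [0.0, 0.0, 1.0, 0.0]])
        C, Y = lr.ae_forward(X, tiny_ae)
        np.testing.assert_array_equal(lr.encode(X, tiny_ae), C)
        assert ((C > 0) & (C < 1)).all() and ((Y > 0) & (Y < 1)).all()

    def test_shape_mismatch_rejected(self, tiny_ae):
        with pytest.raises(ValueError, match="features"):
            lr.ae_forward(np.ones((2, 3)), tiny_ae)


class TestReconstructionMSE:
    def test_perfect_reconstruction_is_zero(self):
        X = np.random.default_rng(0).random((4, 3))
        assert lr.reconstruction_mse(X, X) == 0.0

    def test_single_instance_sum_of_squares(self):
        assert lr.reconstruction_mse(np.array([[1.0, 1.0]]), np.array([[0.0, 0.0]])) == 2.0

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(1)
        X, Y = rng.random((5, 3)), rng.random((5, 3))
        expected = sum(
            sum((Y[i, j] - X[i, j]) ** 2 for j in range(3)) for i in range(5)
        ) / 5
        assert lr.reconstruction_mse(Y, X) == pytest.approx(expected, rel=1e-12)


class TestHaltonAndPerturbations:
    def test_base2_prefix_is_van_der_corput(self):
        np.testing.assert_allclose(lr.halton_points(3, 1).ravel(), [0.5, 0.25, 0.75])

    def test_first_point_in_two_dimensions(self):
        np.testing.assert_allclose(lr.halton_points(1, 2).ravel(), [0.5, 1.0 / 3.0])

    def test_low_discrepancy_mean_near_center(self):
        pts = lr.halton_points(50, 1)
        assert abs(pts.mean() - 0.5) < 0.05

    def test_zero_radius_gives_zero_offsets(self):
        perts = lr.perturbation_set(0.0, 10, 3)
        assert (perts.offsets == 0.0).all()

    def test_first_offset_in_one_dimension(self):
        assert lr.perturbation_set(1.0, 1, 1).offsets[0, 0] == pytest.approx(0.0)

    def test_offsets_bounded_by_radius(self):
        perts = lr.perturbation_set(0.3, 50, 10)
        assert np.abs(perts.offsets).max() <= 0.3

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            lr.perturbation_set(-0.1, 5, 2)


class TestSTSM:
    def test_zero_radius_gives_zero_sensitivity(self, tiny_ae):
        X = np.array([[1.0, 0.0, 1.0, 0.0]])
        perts = lr.perturbation_set(0.0, 50, 4)
        assert lr.stsm(tiny_ae, X, perts) == 0.0

    def test_duplicate_rows_do_not_change_the_average(self, tiny_ae):
        X = np.array([[1.0, 0.0, 1.0, 0.0]])
        perts = lr.perturbation_set(0.2, 20, 4)
        single = lr.stsm(tiny_ae, X, perts)
        stacked = lr.stsm(tiny_ae, np.vstack([X, X, X]), perts)
        assert stacked == pytest.approx(single, rel=1e-12)

    def test_quasi_mc_agrees_with_monte_carlo_oracle(self, tiny_ae):
        # oracle: plain uniform Monte Carlo with 10^4 offsets
        rng = np.random.default_rng(11)
        X = rng.integers(0, 2, size=(8, 4)).astype(float)
        Q = 0.4
        qmc_val = lr.stsm(tiny_ae, X, lr.perturbation_set(Q, 50, 4))
        offsets = rng.uniform(-Q, Q, size=(10_000, 4))
        _, Y = lr.ae_forward(X, tiny_ae)
        total = 0.0
        for off in offsets:
            _, Yp = lr.ae_forward(X + off, tiny_ae)
            total += float(np.sum((Y - Yp) ** 2))
        mc_val = total / (X.shape[0] * offsets.shape[0])
        assert qmc_val == pytest.approx(mc_val, rel=0.10)

    def test_raw_sum_variant_scales_by_point_count(self, tiny_ae):
        X = np.array([[1.0, 0.0, 0.0, 1.0], [0.0, 1.0, 1.0, 0.0]])
        perts = lr.perturbation_set(0.2, 25, 4)
        assert lr.stsm(tiny_ae, X, perts, normalize=False) == pytest.approx(
            25 * lr.stsm(tiny_ae, X, perts), rel=1e-12
        )

    def test_larger_neighborhood_usually_more_sensitive(self):
        # statistical property: local nonmonotonicity possible, >= 90% must hold
        rng = np.random.default_rng(5)
        hold = 0
        for trial in range(20):
            params = init_params(d=3, h=4, seed=trial)
            X = rng.integers(0, 2, size=(5, 3)).astype(float)
            lo = lr.stsm(params, X, lr.perturbation_set(0.1, 50, 3))
            hi = lr.stsm(params, X, lr.perturbation_set(0.2, 50, 3))
            hold += hi >= lo
        assert hold >= 18


class TestObjectiveAndGradient:
    def test_weight_zero_reduces_to_reconstruction_error(self, tiny_ae):
        X = np.array([[1.0, 0.0, 1.0, 1.0], [0.0, 1.0, 0.0, 0.0]])
        perts = lr.perturbation_set(0.3, 10, 4)
        _, Y = lr.ae_forward(X, tiny_ae)
        assert lr.lissa_objective(tiny_ae, X, perts, stsm_weight=0.0) == pytest.approx(
            lr.reconstruction_mse(Y, X)
        )

    def test_objective_is_sum_of_terms(self, tiny_ae):
        X = np.array([[1.0, 0.0, 1.0, 1.0], [0.0, 1.0, 0.0, 0.0]])
        perts = lr.perturbation_set(0.3, 10, 4)
        _, Y = lr.ae_forward(X, tiny_ae)
        expected = lr.reconstruction_mse(Y, X) + 2.5 * lr.stsm(tiny_ae, X, perts)
        assert lr.lissa_objective(tiny_ae, X, perts, stsm_weight=2.5) == pytest.approx(
            expected, rel=1e-12
        )

    @pytest.mark.parametrize("stsm_weight", [0.0, 1.0])
    def test_analytic_gradient_matches_central_differences(self, stsm_weight):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 2, size=(6, 3)).astype(float)
        params = init_params(d=3, h=4, seed=8)
        perts = lr.perturbation_set(0.25, 12, 3)
        _, grad = lissa_gradient(params, X, perts, stsm_weight)
        eps = 1e-6
        fields = {k: getattr(params, k).copy() for k in ("W", "b1", "V", "b2")}
        for name, arr in fields.items():
            for idx in np.ndindex(arr.shape):
                orig = arr[idx]
                for sign in (+1, -1):
                    arr[idx] = orig + sign * eps
                    perturbed = lr.AutoencoderParams(**{**fields, name: arr.copy()})
                    val = lr.lissa_objective(perturbed, X, perts, stsm_weight)
                    if sign > 0:
                        up = val
                    else:
                        down = val
                arr[idx] = orig
                fd = (up - down) / (2 * eps)
                an = getattr(grad, name)[idx]
                assert an == pytest.approx(fd, rel=1e-5, abs=1e-10)


class TestTraining:
    def test_objective_decreases_on_synthetic_data(self):
        cfg = lr.GeneratorConfig(d=8, p=5, n_per_class=10, flip_prob=0.05, seed=1)
        X = lr.generate_dataset(cfg).features.astype(float)
        _, hist = lr.train_autoencoder(X, lr.LiSSATrainConfig(hidden_units=10, epochs=150, seed=0))
        assert hist.objective[-1] < hist.objective[0]
        assert len(hist.objective) == 151

    def test_plain_autoencoder_mode_reduces_reconstruction_error(self):
        cfg = lr.GeneratorConfig(d=8, p=5, n_per_class=10, flip_prob=0.05, seed=1)
        X = lr.generate_dataset(cfg).features.astype(float)
        _, hist = lr.train_autoencoder(
            X, lr.LiSSATrainConfig(hidden_units=10, epochs=150, seed=0, stsm_weight=0.0)
        )
        assert hist.R[-1] < hist.R[0]
        assert (hist.stsm == 0.0).all()

    def test_same_seed_gives_bit_identical_parameters(self, noisy_dataset):
        cfg = lr.LiSSATrainConfig(hidden_units=8, epochs=40, seed=13)
        X = noisy_dataset.features.astype(float)
        a, hist_a = lr.train_autoencoder(X, cfg)
        b, hist_b = lr.train_autoencoder(X, cfg)
        for name in ("W", "b1", "V", "b2"):
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))
        np.testing.assert_array_equal(hist_a.objective, hist_b.objective)

    def test_divergence_is_reported_with_epoch(self):
        # saturating sigmoids keep finite learning rates stable, so force the
        # overflow that the guard exists for
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        cfg = lr.LiSSATrainConfig(
            hidden_units=4, epochs=50, learning_rate=float("inf"), seed=0
        )
        with pytest.raises(TrainingDivergedError, match="epoch"):
            lr.train_autoencoder(X, cfg)

    def test_params_json_round_trip(self, tiny_ae):
        back = lr.AutoencoderParams.from_json(tiny_ae.to_json())
        for name in ("W", "b1", "V", "b2"):
            np.testing.assert_array_equal(getattr(back, name), getattr(tiny_ae, name))


class TestLGEBound:
    def test_degenerate_constants(self):
        inputs = LGEBoundInputs(A=0.0, B=0.0, eta=0.05, N=100)
        assert lr.lge_bound(0.04, 0.09, inputs) == pytest.approx((0.2 + 0.3) ** 2)

    def test_confidence_term_alone(self):
        inputs = LGEBoundInputs(A=0.0, B=2.0, eta=0.05, N=50)
        expected = 2.0 * np.sqrt(np.log(0.05) / (-2 * 50))
        assert lr.lge_bound(0.0, 0.0, inputs) == pytest.approx(expected)

    def test_monotone_in_training_error(self):
        inputs = LGEBoundInputs(A=0.5, B=1.0, eta=0.1, N=30)
        values = [lr.lge_bound(r, 0.2, inputs) for r in np.linspace(0, 2, 9)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("eta", [0.0, 1.0, -0.5, 2.0])
    def test_invalid_confidence_rejected(self, eta):
        with pytest.raises(ValueError):
            LGEBoundInputs(A=0.0, B=0.0, eta=eta, N=10)
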