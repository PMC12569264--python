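"""Model mapping, simulation and identification of the two-timescale system."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from causalfp import (
    CausalSignature,
    ContinuousTwoTimescaleSystem,
    ParcellatedTimeSeries,
    PartitionSpec,
    continuous_from_signature,
    identify_signature,
    imex_discretize,
    one_step_residual,
    simulate_trajectory,
    to_state_evolution_form,
)

from conftest import full_partition, make_stable_signature, simulate_from


class TestImexDiscretize:
    def test_zero_dynamics_gives_identity_update(self):
        sys = ContinuousTwoTimescaleSystem(
            F_s=np.zeros((3, 3)), G_s=np.zeros((3, 2)),
            F_f=np.zeros((3, 3)), G_f=np.zeros((3, 2)),
            epsilon=0.2, dt=0.72,
        )
        sig = imex_discretize(sys)
        assert np.array_equal(sig.Q, np.zeros((3, 3)))
        assert np.array_equal(sig.A, np.eye(3))
        assert np.array_equal(sig.B1, np.zeros((3, 2)))
        assert np.array_equal(sig.B2, np.zeros((3, 2)))

    def test_scalar_arithmetic(self):
        # dt=0.72 with epsilon = 0.25 gives tau = 0.144; choose epsilon so
        # tau = 0.12: tau = dt*eps/(1+eps) -> eps = tau/(dt-tau) = 0.2
        eps = 0.12 / (0.72 - 0.12)
        sys = ContinuousTwoTimescaleSystem(
            F_s=np.array([[-1.0]]), G_s=np.zeros((1, 0)),
            F_f=np.array([[0.0]]), G_f=np.zeros((1, 0)),
            epsilon=eps, dt=0.72,
        )
        assert sys.tau == pytest.approx(0.12)
        sig = imex_discretize(sys)
        assert sig.A[0, 0] == pytest.approx(1 + 0.60 * (-1.0))
        assert sig.Q[0, 0] == 0.0

    @pytest.mark.parametrize("epsilon", [0.05, 0.2, 0.5, 0.9])
    def test_block_inversion_round_trip(self, rng, epsilon):
        F_f = rng.normal(size=(4, 4))
        np.fill_diagonal(F_f, 0.0)
        sys = ContinuousTwoTimescaleSystem(
            F_s=rng.normal(size=(4, 4)), G_s=rng.normal(size=(4, 2)),
            F_f=F_f, G_f=rng.normal(size=(4, 2)),
            epsilon=epsilon, dt=0.72,
        )
        back = continuous_from_signature(imex_discretize(sys), epsilon)
        for name in ("F_s", "G_s", "F_f", "G_f"):
            np.testing.assert_allclose(
                getattr(back, name), getattr(sys, name), atol=1e-12
            )

    def test_tau_within_sampling_interval(self):
        sys = ContinuousTwoTimescaleSystem(
            F_s=np.zeros((2, 2)), G_s=np.zeros((2, 0)),
            F_f=np.zeros((2, 2)), G_f=np.zeros((2, 0)),
            epsilon=0.999, dt=0.72,
        )
        assert 0 < sys.tau < sys.dt

    def test_epsilon_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="epsilon"):
            ContinuousTwoTimescaleSystem(
                F_s=np.zeros((2, 2)), G_s=np.zeros((2, 0)),
                F_f=np.zeros((2, 2)), G_f=np.zeros((2, 0)),
                epsilon=1.5, dt=0.72,
            )

    def test_nonzero_fast_diagonal_warns(self):
        sys = ContinuousTwoTimescaleSystem(
            F_s=np.zeros((2, 2)), G_s=np.zeros((2, 0)),
            F_f=np.eye(2), G_f=np.zeros((2, 0)),
            epsilon=0.2, dt=0.72,
        )
        with pytest.warns(UserWarning, match="diagonal"):
            imex_discretize(sys)


class TestSimulateTrajectory:
    def test_zero_input_zero_state_stays_zero(self, stable_signature):
        ts = simulate_trajectory(
            stable_signature, np.zeros((2, 11)), np.zeros(5), noise_sd=0.0, seed=0
        )
        np.testing.assert_array_equal(ts.values, np.zeros_like(ts.values))

    def test_geometric_series_closed_form(self):
        a, b, c = 0.8, 0.5, 2.0
        sig = CausalSignature(
            Q=np.array([[0.0]]), A=np.array([[a]]),
            B1=np.zeros((1, 1)), B2=np.array([[b]]), dt=0.72,
        )
        T = 30
        ts = simulate_trajectory(sig, np.full((1, T + 1), c), np.zeros(1), 0.0, seed=0)
        k = np.arange(T + 1)
        expected = b * c * (1 - a**k) / (1 - a)
        np.testing.assert_allclose(ts.values[0], expected, atol=1e-12)

    def test_singular_implicit_matrix_raises_with_condition(self):
        sig = CausalSignature(
            Q=np.array([[0.0, 1.0], [1.0, 0.0]]), A=np.eye(2) * 0.5,
            B1=np.zeros((2, 0)), B2=np.zeros((2, 0)), dt=0.72,
        )
        with pytest.raises(np.linalg.LinAlgError, match="condition number"):
            simulate_trajectory(sig, np.zeros((0, 5)), np.zeros(2), 0.0, seed=0)

    def test_seed_reproducibility(self, stable_signature, rng):
        U = rng.normal(size=(2, 21))
        a = simulate_trajectory(stable_signature, U, np.zeros(5), 0.3, seed=7)
        b = simulate_trajectory(stable_signature, U, np.zeros(5), 0.3, seed=7)
        np.testing.assert_array_equal(a.values, b.values)


class TestIdentifySignature:
    def test_zero_series_yields_zero_blocks(self):
        ts = ParcellatedTimeSeries(np.zeros((4, 50)) , dt=0.72)
        part = PartitionSpec([0, 1, 2], [3])
        sig = identify_signature(ts, part, lambda_reg=0.1)
        assert sig.residual_norm == pytest.approx(0.0, abs=1e-12)
        for name in ("Q", "A", "B1", "B2"):
            np.testing.assert_allclose(getattr(sig, name), 0.0, atol=1e-12)

    def test_scalar_state_recovers_structural_blocks(self, rng):
        # with a single state there is no concurrent coupling and the
        # structural parameters are identifiable from one noise-free run
        sig = CausalSignature(
            Q=np.zeros((1, 1)), A=np.array([[0.7]]),
            B1=np.array([[1.3, -0.4]]), B2=np.array([[0.2, 0.9]]), dt=0.72,
        )
        ts = simulate_from(sig, rng, T=300)
        est = identify_signature(ts, full_partition(sig), lambda_reg=1e-10)
        np.testing.assert_allclose(est.A, sig.A, atol=1e-6)
        np.testing.assert_allclose(est.B1, sig.B1, atol=1e-6)
        np.testing.assert_allclose(est.B2, sig.B2, atol=1e-6)

    def test_noise_free_fit_is_exact_and_reduced_form_recovered(self, rng):
        # the structural split (Q vs A) is not identifiable from a single
        # noise-free run, but the fit interpolates the data exactly and the
        # state-evolution (reduced) form is recovered to machine precision
        sig = make_stable_signature(rng, m=5, n=2)
        ts = simulate_from(sig, rng, T=400)
        est = identify_signature(ts, full_partition(sig), lambda_reg=1e-8)
        assert est.residual_norm < 1e-8
        ft, fe = to_state_evolution_form(sig), to_state_evolution_form(est)
        np.testing.assert_allclose(fe.A_hat, ft.A_hat, atol=1e-8)
        np.testing.assert_allclose(fe.B1_hat, ft.B1_hat, atol=1e-8)
        np.testing.assert_allclose(fe.B2_hat, ft.B2_hat, atol=1e-8)

    def test_identified_diag_q_is_exactly_zero(self, rng):
        sig = make_stable_signature(rng, m=6, n=2)
        ts = simulate_from(sig, rng, T=200, noise_sd=0.2)
        est = identify_signature(ts, full_partition(sig), lambda_reg=0.5)
        assert np.all(np.diag(est.Q) == 0.0)

    def test_hcp_shaped_signature_dimensions(self, rng):
        # 100 parcels split 90 states / 10 inputs gives R of shape 90 x 200
        values = rng.normal(size=(100, 251))
        ts = ParcellatedTimeSeries(values, dt=0.72)
        part = PartitionSpec(list(range(90)), list(range(90, 100)))
        sig = identify_signature(ts, part, lambda_reg=1e-3)
        assert sig.R.shape == (90, 200)

    def test_short_series_warns(self, rng):
        sig = make_stable_signature(rng, m=6, n=2)
        ts = simulate_from(sig, rng, T=10)
        with pytest.warns(UserWarning, match="under-determined"):
            identify_signature(ts, full_partition(sig), lambda_reg=1e-3)

    def test_stated_mode_matches_ridge_at_small_lambda(self, rng):
        sig = make_stable_signature(rng, m=4, n=1)
        ts = simulate_from(sig, rng, T=150, noise_sd=0.1)
        ridge = identify_signature(ts, full_partition(sig), lambda_reg=1e-8, mode="ridge")
        stated = identify_signature(ts, full_partition(sig), lambda_reg=1e-8, mode="stated")
        np.testing.assert_allclose(stated.R, ridge.R, atol=1e-4)

    def test_stated_objective_below_zero_solution(self, rng):
        # the returned minimizer never does worse than the all-zero blocks
        sig = make_stable_signature(rng, m=4, n=1)
        ts = simulate_from(sig, rng, T=150, noise_sd=0.3)
        lam = 0.7
        est = identify_signature(ts, full_partition(sig), lambda_reg=lam, mode="stated")
        X, _ = full_partition(sig).split(ts)
        zero_obj = np.linalg.norm(X[:, 1:], "fro")
        blocks = sum(np.linalg.norm(getattr(est, n), "fro") for n in ("Q", "A", "B1", "B2"))
        assert lam * blocks + est.residual_norm <= zero_obj + 1e-9

    def test_single_timescale_forces_fast_blocks_to_zero(self, rng):
        sig = make_stable_signature(rng, m=4, n=2)
        ts = simulate_from(sig, rng, T=200, noise_sd=0.1)
        est = identify_signature(ts, full_partition(sig), single_timescale=True)
        assert np.all(est.Q == 0.0)
        assert np.all(est.B1 == 0.0)
        assert np.linalg.norm(est.A) > 0

    def test_autonomous_system_without_inputs(self, rng):
        sig = make_stable_signature(rng, m=4, n=0)
        U = np.zeros((0, 101))
        ts = simulate_trajectory(sig, U, rng.normal(size=4), 0.05, seed=3)
        est = identify_signature(ts, full_partition(sig), lambda_reg=1e-6)
        assert est.B1.shape == (4, 0)
        assert est.R.shape == (4, 8)


class TestOneStepResidual:
    def test_zero_on_self_simulated_data(self, rng, stable_signature):
        sig = stable_signature
        sig.partition = full_partition(sig)
        ts = simulate_from(sig, rng, T=100)
        assert one_step_residual(sig, ts) <= 1e-9

    def test_matches_training_residual(self, rng):
        sig = make_stable_signature(rng, m=4, n=2)
        ts = simulate_from(sig, rng, T=150, noise_sd=0.2)
        est = identify_signature(ts, full_partition(sig), lambda_reg=1e-4)
        assert one_step_residual(est, ts) == pytest.approx(est.residual_norm, rel=1e-12)

    def test_identified_beats_zero_model(self, rng):
        sig = make_stable_signature(rng, m=4, n=2)
        ts = simulate_from(sig, rng, T=150, noise_sd=0.2)
        part = full_partition(sig)
        est = identify_signature(ts, part, lambda_reg=0.0)
        zero = CausalSignature(
            Q=np.zeros((4, 4)), A=np.zeros((4, 4)),
            B1=np.zeros((4, 2)), B2=np.zeros((4, 2)), dt=0.72, partition=part,
        )
        assert one_step_residual(est, ts) <= one_step_residual(zero, ts)

    def test_residual_grows_with_noise(self, rng):
        # Spearman correlation of residual vs injected noise over 20 seeds
        sig = make_stable_signature(rng, m=4, n=2)
        part = full_partition(sig)
        levels = np.linspace(0.0, 0.5, 20)
        residuals = []
        for i, sd in enumerate(levels):
            ts = simulate_from(sig, rng, T=150, noise_sd=sd, seed=1000 + i)
            est = identify_signature(ts, part, lambda_reg=1e-6)
            residuals.append(est.residual_norm)
        rho, _ = spearmanr(levels, residuals)
        assert rho > 0

    def test_shape_mismatch_rejected(self, rng):
        sig = make_stable_signature(rng, m=4, n=2)
        sig.partition = full_partition(sig)
        other = ParcellatedTimeSeries(rng.normal(size=(5, 30)), dt=0.72)
        with pytest.raises(ValueError):
            one_step_residual(sig, other)
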