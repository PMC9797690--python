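"""Forward model: neuronal SDE, Balloon hemodynamics, analytic spectra."""

import numpy as np
import pytest
from scipy.linalg import solve_lyapunov

from ecdcm.exceptions import ArgumentError, StabilityError
from ecdcm.forward import (bold_timeseries, hemodynamic_forward,
                           hemodynamic_transfer, predict_csd,
                           sample_powerlaw_noise, simulate_neural)
from ecdcm.model import (CouplingModel, CrossSpectra, HemodynamicParams,
                         NeuronalNoiseSpec, save_trajectories)


class TestSimulateNeural:
    def test_deterministic_decay_matches_closed_form(self):
        model = CouplingModel(A=np.diag([-0.5, -0.5]))
        x = simulate_neural(model, None, duration=4.0, dt=0.01, x0=[1.0, 0.0])
        # x(t) = (e^{-0.5 t}, 0); at t = 2 the first node is e^{-1}
        k = int(round(2.0 / 0.01))
        assert x[k, 0] == pytest.approx(np.exp(-1.0), rel=1e-9)
        assert x[k, 1] == 0.0

    def test_stationary_covariance_solves_lyapunov_equation(self, stable3):
        # white state noise of intensity alpha: A S + S A' + alpha I = 0
        alpha = 0.02
        noise = NeuronalNoiseSpec(amplitude_alpha=alpha, exponent_beta=0.0)
        dt = 0.05
        x = simulate_neural(stable3, noise, duration=1e5 * dt, dt=dt, seed=1)
        emp = np.cov(x.T)
        # independent oracle: Kronecker-product linear solve
        A = stable3.A
        n = A.shape[0]
        K = np.kron(A, np.eye(n)) + np.kron(np.eye(n), A)
        sigma = np.linalg.solve(K, (-alpha * np.eye(n)).ravel()).reshape(n, n)
        assert np.allclose(sigma, solve_lyapunov(A, -alpha * np.eye(n)))
        rel = np.linalg.norm(emp - sigma) / np.linalg.norm(sigma)
        assert rel < 0.08

    @pytest.mark.parametrize("seed", range(5))
    def test_lyapunov_consistency_random_stable_systems(self, seed):
        g = np.random.default_rng(seed + 100)
        A = -np.eye(3) * (0.5 + 0.3 * g.random()) + 0.1 * g.standard_normal((3, 3))
        model = CouplingModel(A=A)
        if not model.is_stable():
            pytest.skip("random draw unstable")
        alpha = 0.01
        noise = NeuronalNoiseSpec(amplitude_alpha=alpha)
        x = simulate_neural(model, noise, duration=4000.0, dt=0.05, seed=seed)
        sigma = solve_lyapunov(A, -alpha * np.eye(3))
        rel = np.linalg.norm(np.cov(x.T) - sigma) / np.linalg.norm(sigma)
        assert rel < 0.15

    def test_noise_free_simulation_is_linear_in_x0(self, stable3):
        kw = dict(duration=20.0, dt=0.05)
        x1 = simulate_neural(stable3, None, x0=[1.0, 0.0, 0.0], **kw)
        x2 = simulate_neural(stable3, None, x0=[0.0, 2.0, -1.0], **kw)
        x12 = simulate_neural(stable3, None, x0=[1.0, 2.0, -1.0], **kw)
        assert np.allclose(x1 + x2, x12, atol=1e-12)

    def test_seven_node_run_downsamples_to_130_volumes(self, white_noise, hemo):
        from ecdcm.cohort import BASE_A
        model = CouplingModel(A=BASE_A)
        y = bold_timeseries(model, white_noise, hemo, n_volumes=130, tr=3.0,
                            dt=0.1, seed=0)
        assert y.shape == (130, 7)
        assert model.node_labels[0] == "L-PCC"

    def test_unstable_matrix_raises(self):
        model = CouplingModel(A=np.array([[0.1]]))
        with pytest.raises(StabilityError):
            simulate_neural(model, None, duration=1.0, dt=0.01)

    def test_nonpositive_dt_raises(self, stable3):
        with pytest.raises(ArgumentError):
            simulate_neural(stable3, None, duration=1.0, dt=0.0)


class TestPowerlawNoise:
    def test_white_noise_per_sample_variance(self, rng):
        v = sample_powerlaw_noise(200000, 2, 0.1, alpha=0.5, beta=0.0, rng=rng)
        assert v.var(axis=0) == pytest.approx(0.5 / 0.1, rel=0.05)

    def test_powerlaw_slope_of_periodogram(self, rng):
        from scipy import signal
        v = sample_powerlaw_noise(2 ** 16, 1, 1.0, alpha=1.0, beta=1.0,
                                  rng=rng)[:, 0]
        f, p = signal.welch(v, fs=1.0, nperseg=4096, return_onesided=False)
        keep = (f > 0.01) & (f < 0.4)
        slope = np.polyfit(np.log(f[keep]), np.log(p[keep]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.15)


class TestHemodynamics:
    def test_zero_input_stays_at_resting_readout(self, hemo):
        y = hemodynamic_forward(np.zeros((200, 3)), hemo, dt=0.1)
        assert np.allclose(y, 0.0, atol=1e-12)

    def test_readout_identity_at_rest(self):
        for p in (HemodynamicParams(),
                  HemodynamicParams(k1=2.0, k2=0.5, k3=0.9)):
            assert p.readout(np.array(1.0), np.array(1.0)) == 0.0

    def test_response_matches_fine_step_integration(self, hemo):
        # a brief smooth activation; reference run at 1/10 the step size
        dt = 0.1
        t = np.arange(400) * dt
        x = np.exp(-0.5 * ((t - 2.0) / 0.5) ** 2)[:, None]
        y = hemodynamic_forward(x, hemo, dt)
        fine = 10
        tf = np.arange(400 * fine) * (dt / fine)
        xf = np.exp(-0.5 * ((tf - 2.0) / 0.5) ** 2)[:, None]
        yf = hemodynamic_forward(xf, hemo, dt / fine)[::fine]
        assert np.max(np.abs(y - yf)) < 1e-3 * np.max(np.abs(yf))

    def test_invalid_params_raise(self):
        with pytest.raises(ArgumentError):
            HemodynamicParams(transit_tau=-1.0)
        with pytest.raises(ArgumentError):
            HemodynamicParams(o2_extraction_E0=1.5)


class TestPredictCsd:
    def test_decoupled_nodes_have_zero_cross_spectra(self, white_noise, hemo):
        model = CouplingModel(A=np.diag([-0.4, -0.6]))
        csd = predict_csd(model, white_noise, hemo, np.linspace(0.01, 0.15, 12))
        offdiag = csd.S[:, 0, 1]
        assert np.allclose(offdiag, 0.0, atol=1e-20)

    def test_hermitian_with_nonnegative_diagonal(self, stable3, white_noise, hemo):
        csd = predict_csd(stable3, white_noise, hemo,
                          np.linspace(0.005, 0.16, 20))
        assert csd.is_hermitian()
        assert np.all(csd.S[:, range(3), range(3)].real >= 0)

    def test_identity_hemodynamics_reduces_to_neuronal_spectrum(
            self, stable3, white_noise):
        freqs = np.linspace(0.01, 0.1, 8)
        csd = predict_csd(stable3, white_noise, None, freqs)
        w = 2j * np.pi * freqs
        for k, wk in enumerate(w):
            H = np.linalg.inv(wk * np.eye(3) - stable3.A)
            S = white_noise.amplitude_alpha * H @ H.conj().T \
                + white_noise.observation_alpha * np.eye(3)
            assert np.allclose(csd.S[k], S, rtol=1e-10)

    def test_matches_welch_spectrum_of_long_simulation(self, stable3, hemo):
        from ecdcm.spectra import SpectralConfig, estimate_csd
        noise = NeuronalNoiseSpec(amplitude_alpha=2e-3,
                                  observation_alpha=1e-12)
        y = bold_timeseries(stable3, noise, hemo, n_volumes=6000, tr=3.0,
                            dt=0.05, seed=2, observation_noise=False)
        csd = estimate_csd(y, tr=3.0, config=SpectralConfig(
            nperseg=128, noverlap=96, smooth=7, fmin=0.01, fmax=0.1))
        pred = predict_csd(stable3, noise, hemo, csd.freqs)
        rel = np.linalg.norm(csd.S - pred.S) / np.linalg.norm(pred.S)
        assert rel < 0.12

    def test_unstable_model_raises(self, white_noise, hemo):
        with pytest.raises(StabilityError):
            predict_csd(CouplingModel(A=np.array([[0.2]])), white_noise,
                        hemo, np.array([0.05]))

    def test_hemodynamic_transfer_is_low_pass(self, hemo):
        h = np.abs(hemodynamic_transfer(np.array([0.01, 0.05, 0.15]), hemo))
        assert h[0] > h[1] > h[2]


class TestSerialisation:
    def test_trajectories_roundtrip_hdf5(self, tmp_path, stable3, white_noise):
        import h5py
        x = simulate_neural(stable3, white_noise, duration=30.0, dt=0.1,
                            seed=0)
        csd = predict_csd(stable3, white_noise, None,
                          np.linspace(0.01, 0.1, 5))
        path = tmp_path / "run.h5"
        save_trajectories(path, x=x, csd=csd, dt=0.1, tr=3.0,
                          labels=stable3.node_labels)
        with h5py.File(path) as h:
            assert np.allclose(h["x"][:], x)
            assert np.allclose(h["S"][:], csd.S)
            assert h.attrs["dt"] == 0.1

    def test_cross_spectra_roundtrip(self, tmp_path, stable3, white_noise):
        csd = predict_csd(stable3, white_noise, None,
                          np.linspace(0.01, 0.1, 5))
        path = tmp_path / "csd.h5"
        csd.to_hdf5(path, TR=3.0)
        back = CrossSpectra.from_hdf5(path)
        assert np.allclose(back.S, csd.S)
        assert np.allclose(back.freqs, csd.freqs)
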