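"""Generative forward model: neuronal SDE, Balloon hemodynamics, spectra.

Three layers map a coupling matrix to data features:

1. ``simulate_neural`` integrates dx/dt = A x + v (Euler-Maruyama for
   stochastic runs, matrix-exponential stepping for deterministic ones).
2. ``hemodynamic_forward`` drives one Balloon model per node (RK4) and
   applies the static BOLD readout.
3. ``predict_csd`` gives the model-implied BOLD cross-spectral density
   analytically from the transfer function of the linearised system:

       S_y(f) = h(f) H(f) G_v(f) H(f)^H conj(h(f)) + G_e(f) I,

   with H(f) = (2*pi*i*f*I - A)^-1 the neuronal transfer matrix and h(f)
   the scalar hemodynamic transfer obtained by linearising the Balloon
   model about its resting fixed point.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ArgumentError, IntegrationError, StabilityError
from .model import CouplingModel, CrossSpectra, HemodynamicParams, NeuronalNoiseSpec

try:
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:          # pragma: no cover - numba is an optional speedup
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap


@_njit(fastmath=False)
def _em_loop(x, Adt, v, dt):
    n_steps = x.shape[0]
    for k in range(1, n_steps):
        x[k] = x[k - 1] + Adt @ x[k - 1] + dt * v[k - 1]


@_njit(fastmath=False)
def _balloon_step(state, x, kappa, gamma, tau, ialpha, E0, eps):
    n = state.shape[1]
    out = np.empty_like(state)
    for i in range(n):
        s, f, v, q = state[0, i], state[1, i], state[2, i], state[3, i]
        if f < 1e-6:
            f = 1e-6
        if v < 1e-6:
            v = 1e-6
        E = 1.0 - (1.0 - E0) ** (1.0 / f)
        fout = v ** ialpha
        out[0, i] = eps * x[i] - kappa * s - gamma * (f - 1.0)
        out[1, i] = s
        out[2, i] = (f - fout) / tau
        out[3, i] = (f * E / E0 - fout * q / v) / tau
    return out


@_njit(fastmath=False)
def _balloon_loop(x, dt, kappa, gamma, tau, ialpha, E0, eps):
    n_steps, n = x.shape
    vq = np.empty((n_steps, 2, n))
    state = np.empty((4, n))
    state[0] = 0.0
    state[1] = 1.0
    state[2] = 1.0
    state[3] = 1.0
    vq[0, 0] = state[2]
    vq[0, 1] = state[3]
    for k in range(n_steps - 1):
        xk = x[k]
        xk1 = x[k + 1]
        xmid = 0.5 * (xk + xk1)
        k1 = _balloon_step(state, xk, kappa, gamma, tau, ialpha, E0, eps)
        k2 = _balloon_step(state + 0.5 * dt * k1, xmid, kappa, gamma, tau,
                           ialpha, E0, eps)
        k3 = _balloon_step(state + 0.5 * dt * k2, xmid, kappa, gamma, tau,
                           ialpha, E0, eps)
        k4 = _balloon_step(state + dt * k3, xk1, kappa, gamma, tau,
                           ialpha, E0, eps)
        state = state + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        vq[k + 1, 0] = state[2]
        vq[k + 1, 1] = state[3]
    return vq

__all__ = [
    "simulate_neural",
    "hemodynamic_forward",
    "predict_csd",
    "sample_powerlaw_noise",
    "bold_timeseries",
    "hemodynamic_transfer",
]


def _check_stable(model: CouplingModel) -> None:
    if not model.is_stable():
        ev = model.eigenvalues()
        raise StabilityError(
            f"A is unstable: max Re(eig) = {ev.real.max():.4g} >= 0")


def sample_powerlaw_noise(n_steps: int, n_series: int, dt: float,
                          alpha: float, beta: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Sample series with two-sided spectral density alpha * f**(-beta).

    Spectral synthesis: independent Gaussian Fourier coefficients scaled
    so the expected periodogram equals the target density.  The DC bin is
    zeroed (zero-mean process; also regularises the f -> 0 divergence for
    beta > 0).  For beta = 0 this is exact band-limited white noise with
    per-sample variance alpha / dt.
    """
    if n_steps < 2:
        raise ArgumentError("need at least 2 steps")
    freqs = np.fft.rfftfreq(n_steps, d=dt)
    dens = np.zeros_like(freqs)
    dens[1:] = alpha * freqs[1:] ** (-beta)
    # E|Z_k|^2 = S(f_k) * n / dt reproduces the two-sided density.
    scale = np.sqrt(dens * n_steps / dt)
    z = np.empty((freqs.size, n_series), dtype=complex)
    z[1:-1] = (rng.standard_normal((freqs.size - 2, n_series))
               + 1j * rng.standard_normal((freqs.size - 2, n_series))) / np.sqrt(2)
    z[0] = 0.0
    # Nyquist bin (present for even n) must be real-valued.
    z[-1] = rng.standard_normal(n_series) if n_steps % 2 == 0 else (
        (rng.standard_normal(n_series) + 1j * rng.standard_normal(n_series))
        / np.sqrt(2))
    return np.fft.irfft(scale[:, None] * z, n=n_steps, axis=0)


def simulate_neural(model: CouplingModel, noise: NeuronalNoiseSpec | None,
                    duration: float, dt: float, seed: int | None = None,
                    x0: np.ndarray | None = None) -> np.ndarray:
    """Integrate the neuronal state equation; returns (n_steps, n) array.

    With ``noise=None`` the deterministic relaxation from ``x0`` is
    propagated exactly with the matrix exponential e^{A dt}; otherwise
    endogenous fluctuations are synthesised from their power-law spectrum
    and the SDE is integrated by Euler-Maruyama.
    """
    if dt <= 0:
        raise ArgumentError("dt must be positive")
    if duration <= dt:
        raise ArgumentError("duration must exceed dt")
    _check_stable(model)
    n = model.n_nodes
    n_steps = int(round(duration / dt))
    x = np.zeros((n_steps, n))
    x[0] = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float)

    if noise is None:
        from scipy.linalg import expm
        P = expm(model.A * dt)
        for k in range(1, n_steps):
            x[k] = P @ x[k - 1]
        return x

    rng = np.random.default_rng(seed)
    v = sample_powerlaw_noise(n_steps, n, dt, noise.amplitude_alpha,
                              noise.exponent_beta, rng)
    Adt = np.ascontiguousarray(model.A * dt)
    _em_loop(x, Adt, v, dt)
    if not np.all(np.isfinite(x)):
        raise IntegrationError("neuronal trajectory diverged")
    return x


def _balloon_rhs(state: np.ndarray, x: np.ndarray,
                 p: HemodynamicParams) -> np.ndarray:
    """Balloon-model time derivatives; state rows (s, f, v, q) per node."""
    s, f, v, q = state
    f = np.maximum(f, 1e-6)
    v = np.maximum(v, 1e-6)
    ia = 1.0 / p.stiffness_alpha
    E = 1.0 - (1.0 - p.o2_extraction_E0) ** (1.0 / f)
    fout = v ** ia
    ds = p.epsilon * x - p.signal_decay_kappa * s - p.feedback_gamma * (f - 1.0)
    df = s
    dv = (f - fout) / p.transit_tau
    dq = (f * E / p.o2_extraction_E0 - fout * q / v) / p.transit_tau
    return np.array([ds, df, dv, dq])


def hemodynamic_forward(x: np.ndarray, params: HemodynamicParams,
                        dt: float) -> np.ndarray:
    """BOLD trajectory from neural activity via RK4 Balloon integration.

    ``x`` is (n_steps, n); hemodynamics are independent across nodes and
    the readout is applied to the instantaneous volume and dHb states.
    Neural drive is held piecewise linear between samples.
    """
    if dt <= 0:
        raise ArgumentError("dt must be positive")
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if not np.all(np.isfinite(x)):
        raise ArgumentError("x must be finite")
    n_steps, n = x.shape
    vq = _balloon_loop(np.ascontiguousarray(x), dt,
                       params.signal_decay_kappa, params.feedback_gamma,
                       params.transit_tau, 1.0 / params.stiffness_alpha,
                       params.o2_extraction_E0, params.epsilon)
    if not np.all(np.isfinite(vq)):
        raise IntegrationError("Balloon integration diverged")
    return params.readout(vq[:, 0, :], vq[:, 1, :])


def _balloon_jacobian(p: HemodynamicParams):
    """Linearisation (M, b, c) of the Balloon model at its fixed point.

    Returns the state Jacobian M (4x4), input gain b (dstate/dx) and
    readout gradient c so that h(f) = c (2*pi*i*f I - M)^-1 b.
    Computed by central finite differences of the exact right-hand side.
    """
    s0 = np.array([0.0, 1.0, 1.0, 1.0])
    eps = 1e-6
    M = np.empty((4, 4))
    for j in range(4):
        dp = np.zeros(4)
        dp[j] = eps
        hi = _balloon_rhs((s0 + dp)[:, None], np.zeros(1), p)[:, 0]
        lo = _balloon_rhs((s0 - dp)[:, None], np.zeros(1), p)[:, 0]
        M[:, j] = (hi - lo) / (2 * eps)
    b = np.array([p.epsilon, 0.0, 0.0, 0.0])
    # y = V0[k1(1-q) + k2(1-q/v) + k3(1-v)]; gradient at v = q = 1.
    c = np.array([0.0, 0.0,
                  p.V0 * (p.k2 - p.k3),
                  -p.V0 * (p.k1 + p.k2)])
    return M, b, c


def hemodynamic_transfer(freqs: np.ndarray, params: HemodynamicParams) -> np.ndarray:
    """Scalar BOLD transfer function h(f) of the linearised Balloon model."""
    M, b, c = _balloon_jacobian(params)
    w = 2j * np.pi * np.asarray(freqs, dtype=float)
    eye = np.eye(4)
    sys = w[:, None, None] * eye - M
    return np.linalg.solve(sys, np.broadcast_to(b, (w.size, 4))[..., None])[
        :, :, 0] @ c


def predict_csd(model: CouplingModel, noise: NeuronalNoiseSpec,
                hemo: HemodynamicParams | None, freqs: np.ndarray,
                nyquist: float | None = None) -> CrossSpectra:
    """Model-implied BOLD cross-spectral density on ``freqs``.

    ``hemo=None`` bypasses the hemodynamic transfer (identity readout of
    the neuronal states), which exposes the pure neuronal spectrum.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0):
        raise ArgumentError("frequencies must be strictly positive")
    if nyquist is not None and np.any(freqs > nyquist + 1e-12):
        raise ArgumentError("frequencies exceed the Nyquist bound")
    _check_stable(model)
    n = model.n_nodes
    w = 2j * np.pi * freqs
    eye = np.eye(n)
    H = np.linalg.inv(w[:, None, None] * eye - model.A)      # (F, n, n)
    Gv = noise.state_density(freqs)                          # shared per node
    S = Gv[:, None, None] * (H @ np.conj(np.swapaxes(H, 1, 2)))
    if hemo is not None:
        h2 = np.abs(hemodynamic_transfer(freqs, hemo)) ** 2
        S = S * h2[:, None, None]
    S = S + noise.observation_density(freqs)[:, None, None] * eye
    # enforce exact Hermitian symmetry against round-off
    S = 0.5 * (S + np.conj(np.swapaxes(S, 1, 2)))
    return CrossSpectra(freqs=freqs, S=S, node_labels=model.node_labels)


def bold_timeseries(model: CouplingModel, noise: NeuronalNoiseSpec,
                    hemo: HemodynamicParams, n_volumes: int, tr: float,
                    dt: float = 0.1, seed: int | None = None,
                    burn_in: float = 60.0,
                    observation_noise: bool = True) -> np.ndarray:
    """Simulate a BOLD run sampled every TR; returns (n_volumes, n).

    The neuronal SDE and Balloon model are integrated at ``dt`` with a
    stationarisation burn-in, downsampled to the repetition time, and
    measurement noise with the spec's power-law spectrum is added at the
    sampled rate.
    """
    if tr <= 0 or n_volumes < 1:
        raise ArgumentError("tr must be positive and n_volumes >= 1")
    stride = int(round(tr / dt))
    if abs(stride * dt - tr) > 1e-9:
        raise ArgumentError("dt must divide TR")
    rng = np.random.default_rng(seed)
    n_burn = int(round(burn_in / dt))
    duration = n_volumes * tr + burn_in
    x = simulate_neural(model, noise, duration, dt,
                        seed=int(rng.integers(2 ** 31)))
    y = hemodynamic_forward(x, hemo, dt)
    y = y[n_burn::stride][:n_volumes]
    if observation_noise:
        e = sample_powerlaw_noise(max(n_volumes, 2), model.n_nodes, tr,
                                  noise.observation_alpha,
                                  noise.observation_beta, rng)[:n_volumes]
        y = y + e
    return y
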