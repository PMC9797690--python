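"""Domain types for the generative effective-connectivity model.

The neuronal level is a linear stochastic differential equation

    dx/dt = A x + C u + v,

where ``A`` (units Hz) holds the intrinsic coupling: ``A[i, j]`` is the
influence of node ``j`` on node ``i`` (directions run from columns to
rows).  ``v`` is endogenous neuronal fluctuation with a power-law
spectrum.  In resting state the exogenous input ``u`` and all modulatory
matrices ``B`` are identically zero; they are carried in the types so the
same machinery extends to task designs.

The observation level is the Balloon hemodynamic model: neural activity
drives a vasodilatory signal, blood inflow, venous volume ``v`` and
deoxyhemoglobin content ``q``, and the BOLD readout is

    y = V0 [ k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v) ].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .exceptions import ArgumentError

#: Node order used throughout: bilateral posterior cingulate, bilateral
#: anterior cingulate, bilateral dorsolateral prefrontal, medial prefrontal.
DEFAULT_NODE_LABELS = (
    "L-PCC", "R-PCC", "L-ACC", "R-ACC", "L-dlPFC", "R-dlPFC", "mPFC",
)


def _as_matrix(x, n: int, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.shape != (n, n):
        raise ArgumentError(f"{name} must be {n}x{n}, got {a.shape}")
    return a


@dataclass
class CouplingModel:
    """Coupling parameters (A, B, C) of the neuronal state equation."""

    A: np.ndarray
    B: list[np.ndarray] = field(default_factory=list)
    C: np.ndarray | None = None
    node_labels: tuple[str, ...] | None = None

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ArgumentError(f"A must be square, got shape {self.A.shape}")
        n = self.A.shape[0]
        self.B = [_as_matrix(b, n, "B") for b in self.B]
        if self.C is None:
            self.C = np.zeros((n, 1))
        self.C = np.asarray(self.C, dtype=float)
        if self.C.shape[0] != n:
            raise ArgumentError("C must have one row per node")
        if self.node_labels is None:
            if n == len(DEFAULT_NODE_LABELS):
                self.node_labels = DEFAULT_NODE_LABELS
            else:
                self.node_labels = tuple(f"node{i}" for i in range(n))
        self.node_labels = tuple(self.node_labels)
        if len(self.node_labels) != n:
            raise ArgumentError("node_labels length must equal n_nodes")

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvals(self.A)

    def is_stable(self) -> bool:
        """True when every eigenvalue of A has negative real part."""
        return bool(np.all(self.eigenvalues().real < 0))

    def max_time_constant(self) -> float:
        """Slowest relaxation time 1/|Re lambda|_min of a stable A, in s."""
        re = self.eigenvalues().real
        return float(1.0 / np.min(-re)) if np.all(re < 0) else np.inf


@dataclass
class NeuronalNoiseSpec:
    """Power-law spectra of neuronal fluctuations and measurement noise.

    Both the endogenous fluctuation ``v`` and the observation noise ``e``
    are given two-sided spectral densities g(f) = alpha * f**(-beta)
    (units: signal^2 / Hz), evaluated on strictly positive frequencies.
    beta = 0 recovers white noise of intensity alpha.
    """

    amplitude_alpha: float = 1e-3
    exponent_beta: float = 0.0
    observation_alpha: float = 1e-8
    observation_beta: float = 0.0

    def __post_init__(self):
        if self.amplitude_alpha <= 0 or self.observation_alpha <= 0:
            raise ArgumentError("noise amplitudes must be strictly positive")

    def state_density(self, freqs: np.ndarray) -> np.ndarray:
        return _powerlaw(freqs, self.amplitude_alpha, self.exponent_beta)

    def observation_density(self, freqs: np.ndarray) -> np.ndarray:
        return _powerlaw(freqs, self.observation_alpha, self.observation_beta)


def _powerlaw(freqs: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    f = np.asarray(freqs, dtype=float)
    if np.any(f <= 0):
        raise ArgumentError("power-law spectra require strictly positive frequencies")
    return alpha * f ** (-beta)


# 3 T constants for the BOLD readout coefficients: frequency offset at the
# outer surface of magnetised vessels theta0 (s^-1), slope of the
# intravascular relaxation rate r0 (s^-1), intra-/extravascular signal
# ratio at rest.
_THETA0_3T = 80.6
_R0_3T = 110.0
_EPS_RATIO_3T = 0.47


@dataclass
class HemodynamicParams:
    """Balloon-model rate constants and BOLD readout coefficients.

    Defaults are the published values of the generalised BOLD signal
    model: signal decay kappa = 0.64 / s, flow feedback gamma = 0.32 / s,
    venous transit time tau = 2 s, vessel stiffness alpha = 0.32, resting
    oxygen extraction E0 = 0.4 and resting venous volume fraction
    V0 = 0.04; k1-k3 are computed for a 3 T scanner at 30 ms echo time.
    """

    signal_decay_kappa: float = 0.64
    feedback_gamma: float = 0.32
    transit_tau: float = 2.0
    stiffness_alpha: float = 0.32
    o2_extraction_E0: float = 0.4
    V0: float = 0.04
    k1: float = _THETA0_3T * 4.3 * 0.4 * 0.03
    k2: float = _EPS_RATIO_3T * _R0_3T * 0.4 * 0.03
    k3: float = 1.0 - _EPS_RATIO_3T
    epsilon: float = 1.0

    def __post_init__(self):
        for name in ("signal_decay_kappa", "feedback_gamma", "transit_tau",
                     "stiffness_alpha", "o2_extraction_E0", "V0", "k1", "k2",
                     "k3", "epsilon"):
            if getattr(self, name) <= 0:
                raise ArgumentError(f"{name} must be strictly positive")
        if not 0 < self.o2_extraction_E0 < 1:
            raise ArgumentError("o2_extraction_E0 must lie in (0, 1)")
        if not 0 < self.V0 < 1:
            raise ArgumentError("V0 must lie in (0, 1)")

    @classmethod
    def for_echo_time(cls, te: float = 0.03, **kwargs) -> "HemodynamicParams":
        """Readout coefficients recomputed for echo time ``te`` (s) at 3 T."""
        E0 = kwargs.get("o2_extraction_E0", 0.4)
        return cls(
            k1=4.3 * _THETA0_3T * E0 * te,
            k2=_EPS_RATIO_3T * _R0_3T * E0 * te,
            k3=1.0 - _EPS_RATIO_3T,
            **kwargs,
        )

    def readout(self, v: np.ndarray, q: np.ndarray) -> np.ndarray:
        """Static BOLD readout from venous volume v and dHb content q."""
        return self.V0 * (self.k1 * (1.0 - q)
                          + self.k2 * (1.0 - q / v)
                          + self.k3 * (1.0 - v))


@dataclass
class CrossSpectra:
    """Hermitian cross-spectral density on a positive frequency grid.

    ``S[k]`` is the n x n two-sided cross-spectral density matrix at
    ``freqs[k]`` (Hz); for a real-valued signal the density at -f is the
    complex conjugate, so positive frequencies carry all information.
    """

    freqs: np.ndarray
    S: np.ndarray
    node_labels: tuple[str, ...] | None = None

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.S = np.asarray(self.S, dtype=complex)
        if self.freqs.ndim != 1 or np.any(self.freqs <= 0):
            raise ArgumentError("freqs must be a 1-D strictly positive array")
        if np.any(np.diff(self.freqs) <= 0):
            raise ArgumentError("freqs must be strictly increasing")
        if self.S.ndim != 3 or self.S.shape[0] != self.freqs.size \
                or self.S.shape[1] != self.S.shape[2]:
            raise ArgumentError("S must have shape (n_freqs, n, n)")
        if self.node_labels is not None:
            self.node_labels = tuple(self.node_labels)
            if len(self.node_labels) != self.S.shape[1]:
                raise ArgumentError("node_labels length must equal n nodes")

    @property
    def n_nodes(self) -> int:
        return self.S.shape[1]

    def is_hermitian(self, tol: float = 1e-8) -> bool:
        return bool(np.allclose(self.S, np.conj(np.swapaxes(self.S, 1, 2)),
                                atol=tol * (1 + np.abs(self.S).max())))

    def to_hdf5(self, path, **attrs) -> None:
        with h5py.File(path, "w") as h:
            h.create_dataset("freqs", data=self.freqs)
            h.create_dataset("S", data=self.S)
            if self.node_labels:
                h.attrs["labels"] = list(self.node_labels)
            for k, v in attrs.items():
                h.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path) -> "CrossSpectra":
        with h5py.File(path, "r") as h:
            labels = tuple(h.attrs["labels"]) if "labels" in h.attrs else None
            return cls(freqs=h["freqs"][:], S=h["S"][:], node_labels=labels)


def save_trajectories(path, *, x=None, y=None, csd: CrossSpectra | None = None,
                      dt: float | None = None, tr: float | None = None,
                      labels=None) -> None:
    """Write latent/BOLD trajectories and spectra to one HDF5 container."""
    with h5py.File(path, "w") as h:
        if x is not None:
            h.create_dataset("x", data=np.asarray(x, dtype=float))
        if y is not None:
            h.create_dataset("y", data=np.asarray(y, dtype=float))
        if csd is not None:
            h.create_dataset("freqs", data=csd.freqs)
            h.create_dataset("S", data=csd.S)
        if dt is not None:
            h.attrs["dt"] = dt
        if tr is not None:
            h.attrs["TR"] = tr
        if labels is not None:
            h.attrs["labels"] = list(labels)
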