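"""Reduced-scale validation experiments used by the test-suite and the
reproduction script.

Each experiment fixes its own study conditions once (sample sizes, signal
strengths, spectral-estimation settings) and reports summary quantities:

* ``lyapunov_experiment`` — stationary covariance of the neuronal SDE
  against the Lyapunov-equation solution.
* ``csd_match_experiment`` — analytic BOLD cross-spectra against the
  Welch estimate of a long simulation.
* ``recovery_experiment`` — per-subject posterior recovery of known
  couplings at high SNR (long runs, negligible measurement noise).
* ``progression_experiment`` — the four-group attenuation design:
  thresholded group networks across CN/EMCI/LMCI/AD-like cohorts with a
  strong-signal ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_lyapunov
from scipy.stats import spearmanr

from .cohort import BASE_A, CohortConfig, generate_cohort
from .forward import bold_timeseries, predict_csd, simulate_neural
from .inversion import fit_cohort
from .model import CouplingModel, HemodynamicParams, NeuronalNoiseSpec
from .peb import PEB, threshold_network
from .spectra import SpectralConfig, estimate_csd

__all__ = [
    "subnetwork_base", "strong_signal_base",
    "lyapunov_experiment", "csd_match_experiment",
    "recovery_experiment", "progression_experiment",
    "RECOVERY_SPECTRAL", "PROGRESSION_SPECTRAL",
]

#: node subset used for 4-node reduced experiments
SUBNET_NODES = (0, 1, 4, 6)        # L-PCC, R-PCC, L-dlPFC, mPFC
SUBNET_LABELS = ("L-PCC", "R-PCC", "L-dlPFC", "mPFC")

RECOVERY_SPECTRAL = SpectralConfig(nperseg=128, smooth=5, fmin=0.005,
                                   fmax=0.1, n_freq=8)
PROGRESSION_SPECTRAL = RECOVERY_SPECTRAL

#: strong-signal off-diagonal coupling (Hz) for the progression analogue
STRONG_COUPLING = 0.08


def subnetwork_base() -> np.ndarray:
    """4-node submatrix of the reference coupling matrix."""
    idx = list(SUBNET_NODES)
    return BASE_A[np.ix_(idx, idx)].copy()


def strong_signal_base() -> np.ndarray:
    """Strong-signal analogue: uniform off-diagonal couplings."""
    A = subnetwork_base()
    off = ~np.eye(A.shape[0], dtype=bool)
    A[off] = STRONG_COUPLING
    return A


def lyapunov_experiment(seed: int, n_steps: int = 100_000, dt: float = 0.05):
    """Relative Frobenius error of the empirical stationary covariance.

    Fixed well-conditioned 3-node system (the seed varies only the noise
    realisation), white state noise of intensity alpha; the oracle is the
    continuous Lyapunov solution A S + S A' + alpha I = 0.
    """
    A = np.array([[-1.0, 0.2, 0.0],
                  [0.15, -0.9, 0.2],
                  [0.0, 0.1, -1.1]])
    model = CouplingModel(A=A)
    alpha = 0.02
    noise = NeuronalNoiseSpec(amplitude_alpha=alpha)
    x = simulate_neural(model, noise, duration=n_steps * dt, dt=dt, seed=seed)
    sigma = solve_lyapunov(A, -alpha * np.eye(3))
    rel = np.linalg.norm(np.cov(x.T) - sigma) / np.linalg.norm(sigma)
    return float(rel), n_steps


def csd_match_experiment(seed: int, n_volumes: int = 10_000):
    """Relative error between analytic and Welch-estimated BOLD CSD."""
    g = np.random.default_rng(seed)
    A = -np.eye(3) * 0.6 + 0.15 * g.standard_normal((3, 3))
    model = CouplingModel(A=A)
    noise = NeuronalNoiseSpec(amplitude_alpha=2e-3, observation_alpha=1e-12)
    hemo = HemodynamicParams()
    y = bold_timeseries(model, noise, hemo, n_volumes=n_volumes, tr=3.0,
                        dt=0.05, seed=seed, observation_noise=False)
    csd = estimate_csd(y, tr=3.0, config=SpectralConfig(
        nperseg=128, noverlap=96, smooth=7, fmin=0.01, fmax=0.1))
    pred = predict_csd(model, noise, hemo, csd.freqs)
    rel = np.linalg.norm(csd.S - pred.S) / np.linalg.norm(pred.S)
    return float(rel), n_volumes


@dataclass
class RecoveryResult:
    frac_within_2sd: float
    rank_correlation: float
    n_subjects: int


def recovery_experiment(seed: int, n_subjects: int = 20,
                        n_volumes: int = 1510) -> RecoveryResult:
    """Parameter recovery on one high-SNR synthetic group (4 nodes).

    High SNR means long resting-state runs and negligible measurement
    noise; every subject is inverted and compared against their own
    ground-truth coupling matrix.
    """
    cfg = CohortConfig(
        base_A=subnetwork_base(), node_labels=SUBNET_LABELS,
        group_sizes={"CN": n_subjects, "EMCI": 1, "LMCI": 1, "AD": 1},
        n_volumes=n_volumes, dt=0.05, seed=seed)
    records = [r for r in generate_cohort(cfg) if r.group == "CN"]
    posts = fit_cohort(records, spectral_config=RECOVERY_SPECTRAL)
    n = cfg.n_nodes
    off = ~np.eye(n, dtype=bool)
    z_all, est_all, truth_all = [], [], []
    for rec, post in zip(records, posts):
        err = (post.A_mean - rec.ground_truth_A)[off]
        z_all.append(err / post.A_sd[off])
        est_all.append(post.A_mean[off])
        truth_all.append(rec.ground_truth_A[off])
    z = np.concatenate(z_all)
    rho = spearmanr(np.concatenate(est_all), np.concatenate(truth_all))
    return RecoveryResult(
        frac_within_2sd=float(np.mean(np.abs(z) < 2)),
        rank_correlation=float(rho.statistic),
        n_subjects=n_subjects)


@dataclass
class ProgressionResult:
    cn_full_at_05: int           # replicates with a full CN network at 0.5
    monotone_at_099: int         # replicates with non-increasing edge counts
    n_replicates: int
    edge_counts: list            # per replicate: {group: edges@0.99}


def progression_experiment(seed: int, n_replicates: int = 10,
                           n_subjects: int = 16,
                           n_volumes: int = 1010) -> ProgressionResult:
    """Four-group attenuation design at reduced scale.

    Ground truth is the strong-signal base; off-diagonal couplings are
    attenuated by (1.0, 0.6, 0.3, 0.05) along CN -> EMCI -> LMCI -> AD.
    Reports how often the CN-like network is full at the 0.5 threshold
    and the 0.99-threshold edge count is non-increasing across groups.
    """
    base = strong_signal_base()
    n = base.shape[0]
    full = n * n
    cn_full = 0
    mono = 0
    counts = []
    for rep in range(n_replicates):
        cfg = CohortConfig(
            base_A=base, node_labels=SUBNET_LABELS,
            group_sizes={g: n_subjects for g in
                         ("CN", "EMCI", "LMCI", "AD")},
            attenuation={"CN": 1.0, "EMCI": 0.6, "LMCI": 0.3, "AD": 0.05},
            n_volumes=n_volumes, dt=0.05, seed=seed + rep)
        records = generate_cohort(cfg)
        posts = fit_cohort(records, spectral_config=PROGRESSION_SPECTRAL)
        at05 = {}
        at99 = {}
        for g in ("CN", "EMCI", "LMCI", "AD"):
            ps = [p for p, r in zip(posts, records) if r.group == g]
            cp = PEB(ps).fit().search()
            at05[g] = int(threshold_network(cp, 0.5)[0].sum())
            at99[g] = int(threshold_network(cp, 0.99)[0].sum())
        seq = [at99[g] for g in ("CN", "EMCI", "LMCI", "AD")]
        cn_full += at05["CN"] == full
        mono += all(a >= b for a, b in zip(seq, seq[1:]))
        counts.append(at99)
    return ProgressionResult(cn_full_at_05=cn_full, monotone_at_099=mono,
                             n_replicates=n_replicates, edge_counts=counts)
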