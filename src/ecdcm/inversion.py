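"""Subject-level Bayesian inversion of the spectral generative model.

``SpectralDCM`` fits the coupling matrix A (plus fluctuation-spectrum and
selected hemodynamic parameters) to an observed cross-spectral density by
variational Laplace: the posterior is assumed Gaussian, and a free-energy
bound on the log model evidence,

    F = <log p(data | theta)>_q - KL(q || prior),

is ascended by Gauss-Newton steps with Levenberg-Marquardt damping and
step rejection.  The likelihood is an independent Gaussian on the stacked
real and imaginary cross-spectral entries, with a single log-precision
hyperparameter updated by EM between parameter steps.

Parameterisation (the "latent" vector):
  * off-diagonal A entries, direct scale, prior N(0, 1/64);
  * self-connections a_ii = -0.5 exp(theta_ii), prior theta ~ N(0, 1/64)
    (guarantees a negative diagonal);
  * log-scaling of fluctuation/observation noise amplitudes and additive
    offsets of their spectral exponents, prior N(0, 1/64);
  * optional tight log-scalings of hemodynamic kappa and tau, N(0, 1/256).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import forward
from .exceptions import ArgumentError, ConfigError, NumericalError
from .model import CouplingModel, CrossSpectra, HemodynamicParams, NeuronalNoiseSpec
from .spectra import SpectralConfig, estimate_csd

__all__ = [
    "ParamSpace", "PriorSpec", "InversionConfig",
    "SpectralDCM", "SpectralDCMResults", "fit_cohort",
]

SELF_SCALE = -0.5  # a_ii = SELF_SCALE * exp(latent)


@dataclass
class InversionConfig:
    """Variational-Laplace settings."""

    max_iter: int = 128
    tol: float = 1e-4           # free-energy change counted as converged
    n_tol: int = 3              # consecutive small changes required
    fd_step: float = 1e-4       # central-difference step on the latent scale
    init_damping: float = 1.0
    max_damping: float = 1e8
    fixed_log_precision: float | None = None   # None -> EM-updated
    fit_hemo: bool = True
    hemo: HemodynamicParams = field(default_factory=HemodynamicParams)
    base_state_alpha: float = 1e-3
    base_state_beta: float = 0.0
    base_obs_alpha: float = 1e-6
    base_obs_beta: float = 0.0


class ParamSpace:
    """Mapping between the latent vector and generative-model objects."""

    def __init__(self, n_nodes: int, config: InversionConfig,
                 node_labels=None):
        self.n = n_nodes
        self.config = config
        self.node_labels = tuple(node_labels) if node_labels else None
        n = n_nodes
        self.off_idx = [(i, j) for i in range(n) for j in range(n) if i != j]
        self.n_off = len(self.off_idx)
        self.n_self = n
        self.n_noise = 4
        self.n_hemo = 2 if config.fit_hemo else 0
        self.n_params = self.n_off + self.n_self + self.n_noise + self.n_hemo

    @property
    def labels(self) -> list[str]:
        nl = self.node_labels or tuple(f"node{i}" for i in range(self.n))
        out = [f"A[{nl[i]}<-{nl[j]}]" for i, j in self.off_idx]
        out += [f"self[{nl[i]}]" for i in range(self.n)]
        out += ["log_state_alpha", "state_beta", "log_obs_alpha", "obs_beta"]
        if self.n_hemo:
            out += ["log_kappa", "log_tau"]
        return out

    def a_slice(self) -> slice:
        """Slice of the latent vector holding all A parameters."""
        return slice(0, self.n_off + self.n_self)

    def is_self(self) -> np.ndarray:
        m = np.zeros(self.n_params, dtype=bool)
        m[self.n_off:self.n_off + self.n_self] = True
        return m

    def unpack(self, theta: np.ndarray):
        """Latent vector -> (CouplingModel, NeuronalNoiseSpec, HemodynamicParams)."""
        cfg = self.config
        A = np.zeros((self.n, self.n))
        for k, (i, j) in enumerate(self.off_idx):
            A[i, j] = theta[k]
        lat_self = theta[self.n_off:self.n_off + self.n_self]
        np.fill_diagonal(A, SELF_SCALE * np.exp(lat_self))
        ln = theta[self.n_off + self.n_self:]
        noise = NeuronalNoiseSpec(
            amplitude_alpha=cfg.base_state_alpha * np.exp(ln[0]),
            exponent_beta=cfg.base_state_beta + ln[1],
            observation_alpha=cfg.base_obs_alpha * np.exp(ln[2]),
            observation_beta=cfg.base_obs_beta + ln[3],
        )
        hemo = cfg.hemo
        if self.n_hemo:
            hemo = replace(hemo,
                           signal_decay_kappa=hemo.signal_decay_kappa * np.exp(ln[4]),
                           transit_tau=hemo.transit_tau * np.exp(ln[5]))
        model = CouplingModel(A=A, node_labels=self.node_labels)
        return model, noise, hemo

    def pack_A(self, A: np.ndarray, theta: np.ndarray | None = None) -> np.ndarray:
        """Write a real-valued A matrix into (a copy of) a latent vector."""
        theta = np.zeros(self.n_params) if theta is None else theta.copy()
        for k, (i, j) in enumerate(self.off_idx):
            theta[k] = A[i, j]
        d = np.diag(A)
        if np.any(d >= 0):
            raise ArgumentError("self-connections must be negative")
        theta[self.n_off:self.n_off + self.n_self] = np.log(d / SELF_SCALE)
        return theta

    def a_matrix(self, theta: np.ndarray) -> np.ndarray:
        """Real-valued A (self-connections back-transformed)."""
        return self.unpack(theta)[0].A

    def default_priors(self) -> "PriorSpec":
        mean = np.zeros(self.n_params)
        var = np.full(self.n_params, 1.0 / 64.0)
        if self.n_hemo:
            var[-self.n_hemo:] = 1.0 / 256.0
        return PriorSpec(mean=mean, covariance_diag=var)


@dataclass
class PriorSpec:
    """Diagonal Gaussian prior over the latent parameter vector."""

    mean: np.ndarray
    covariance_diag: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance_diag = np.asarray(self.covariance_diag, dtype=float)
        if self.mean.shape != self.covariance_diag.shape or self.mean.ndim != 1:
            raise ArgumentError("prior mean and covariance diagonal must be "
                                "1-D arrays of equal length")
        if np.any(self.covariance_diag <= 0):
            raise ArgumentError("prior covariance diagonal must be positive")

    @property
    def n_params(self) -> int:
        return self.mean.size

    @property
    def covariance(self) -> np.ndarray:
        return np.diag(self.covariance_diag)


def _csd_features(S: np.ndarray) -> np.ndarray:
    """Stack Hermitian CSD matrices into a real feature vector."""
    nf, n, _ = S.shape
    iu_r, ju_r = np.triu_indices(n)
    iu_i, ju_i = np.triu_indices(n, k=1)
    re = S[:, iu_r, ju_r].real
    im = S[:, iu_i, ju_i].imag
    return np.concatenate([re.reshape(nf, -1), im.reshape(nf, -1)],
                          axis=1).ravel()


class SpectralDCM:
    """Model object: one subject's CSD plus priors and settings.

    Parameters
    ----------
    csd : CrossSpectra
        Observed cross-spectral density (the data feature).
    priors : PriorSpec, optional
        Defaults to the shrinkage priors of ``ParamSpace.default_priors``.
    config : InversionConfig, optional
    """

    def __init__(self, csd: CrossSpectra, priors: PriorSpec | None = None,
                 config: InversionConfig | None = None):
        self.csd = csd
        self.config = config or InversionConfig()
        self.space = ParamSpace(csd.n_nodes, self.config,
                                node_labels=csd.node_labels)
        self.priors = priors or self.space.default_priors()
        if self.priors.n_params != self.space.n_params:
            raise ArgumentError(
                f"prior dimension {self.priors.n_params} does not match "
                f"parameter count {self.space.n_params}")
        y = _csd_features(csd.S)
        # normalise features so the noise log-precision is O(1)
        self.scale_ = float(np.sqrt(np.mean(y ** 2))) or 1.0
        self.data_ = y / self.scale_

    @classmethod
    def from_timeseries(cls, y: np.ndarray, tr: float,
                        spectral_config: SpectralConfig | None = None,
                        node_labels=None, **kwargs) -> "SpectralDCM":
        spectral_config = spectral_config or SpectralConfig(
            nperseg=64, smooth=3, fmin=0.008, fmax=0.1)
        csd = estimate_csd(y, tr, config=spectral_config,
                           node_labels=node_labels)
        return cls(csd, **kwargs)

    # -- generative prediction ------------------------------------------

    def _hemo_transfer_sq(self, lk: float, lt: float) -> np.ndarray:
        """|h(f)|^2 for given hemodynamic log-scalings, cached."""
        if not hasattr(self, "_h2_cache"):
            self._h2_cache = {}
        key = (round(float(lk), 12), round(float(lt), 12))
        if key not in self._h2_cache:
            hemo = self.config.hemo
            if lk or lt:
                hemo = replace(hemo,
                               signal_decay_kappa=hemo.signal_decay_kappa * np.exp(lk),
                               transit_tau=hemo.transit_tau * np.exp(lt))
            h = forward.hemodynamic_transfer(self.csd.freqs, hemo)
            self._h2_cache[key] = np.abs(h) ** 2
        return self._h2_cache[key]

    def _predict_batch(self, thetas: np.ndarray) -> np.ndarray:
        """Feature predictions for a (m, p) batch; NaN rows where A is
        unstable."""
        cfg = self.config
        sp = self.space
        thetas = np.atleast_2d(thetas)
        m = thetas.shape[0]
        n = sp.n
        freqs = self.csd.freqs
        F = freqs.size
        A = np.zeros((m, n, n))
        if sp.n_off:
            oi = np.array([i for i, _ in sp.off_idx])
            oj = np.array([j for _, j in sp.off_idx])
            A[:, oi, oj] = thetas[:, :sp.n_off]
        d = np.arange(n)
        A[:, d, d] = SELF_SCALE * np.exp(
            thetas[:, sp.n_off:sp.n_off + n])
        stable = np.linalg.eigvals(A).real.max(axis=1) < 0

        ln = thetas[:, sp.n_off + sp.n_self:]
        alpha_v = cfg.base_state_alpha * np.exp(ln[:, 0])
        beta_v = cfg.base_state_beta + ln[:, 1]
        alpha_e = cfg.base_obs_alpha * np.exp(ln[:, 2])
        beta_e = cfg.base_obs_beta + ln[:, 3]

        w = 2j * np.pi * freqs
        Mat = w[None, :, None, None] * np.eye(n) - A[:, None, :, :]
        Mat[~stable] = np.eye(n)    # placeholder to keep inv defined
        H = np.linalg.inv(Mat)
        Gv = alpha_v[:, None] * freqs[None, :] ** (-beta_v[:, None])
        S = Gv[:, :, None, None] * (H @ np.conj(np.swapaxes(H, -1, -2)))

        if sp.n_hemo:
            h2 = np.empty((m, F))
            for r in range(m):
                h2[r] = self._hemo_transfer_sq(ln[r, 4], ln[r, 5])
        else:
            h2 = np.broadcast_to(self._hemo_transfer_sq(0.0, 0.0), (m, F))
        S = S * h2[:, :, None, None]
        Ge = alpha_e[:, None] * freqs[None, :] ** (-beta_e[:, None])
        S[:, :, d, d] += Ge[:, :, None]

        iu_r, ju_r = np.triu_indices(n)
        iu_i, ju_i = np.triu_indices(n, k=1)
        re = S[:, :, iu_r, ju_r].real
        im = S[:, :, iu_i, ju_i].imag
        feats = np.concatenate([re, im], axis=2).reshape(m, -1) / self.scale_
        feats[~stable] = np.nan
        return feats

    def _predict(self, theta: np.ndarray) -> np.ndarray | None:
        """Feature prediction, or None if A is unstable at theta."""
        g = self._predict_batch(theta[None, :])[0]
        return None if np.any(np.isnan(g)) else g

    def _jacobian(self, theta: np.ndarray, g0: np.ndarray) -> np.ndarray:
        h = self.config.fd_step
        p = theta.size
        pert = np.concatenate([theta + h * np.eye(p),
                               theta - h * np.eye(p)], axis=0)
        G = self._predict_batch(pert)
        gp, gm = G[:p], G[p:]
        J = np.zeros((g0.size, p))
        for j in range(p):
            ok_p = not np.any(np.isnan(gp[j]))
            ok_m = not np.any(np.isnan(gm[j]))
            if ok_p and ok_m:
                J[:, j] = (gp[j] - gm[j]) / (2 * h)
            elif ok_p:
                J[:, j] = (gp[j] - g0) / h
            elif ok_m:
                J[:, j] = (g0 - gm[j]) / h
        return J

    # -- free energy ----------------------------------------------------

    def _free_energy(self, ey, J, Sigma, mu, lam):
        """Variational free energy for Gaussian q at (mu, Sigma)."""
        N = ey.size
        P0d = 1.0 / self.priors.covariance_diag
        emu = mu - self.priors.mean
        if np.isneginf(lam):
            accuracy = 0.0
        else:
            pi = np.exp(lam)
            accuracy = (-0.5 * pi * (ey @ ey + np.einsum("ij,jk,ik->", J, Sigma, J))
                        + 0.5 * N * (lam - np.log(2 * np.pi)))
        sign, logdet_S = np.linalg.slogdet(Sigma)
        if sign <= 0:
            raise NumericalError("posterior covariance not positive definite")
        kl = 0.5 * (np.sum(P0d * np.diag(Sigma)) + np.sum(P0d * emu ** 2)
                    - mu.size + np.sum(np.log(self.priors.covariance_diag))
                    - logdet_S)
        return accuracy - kl, accuracy, kl

    def _posterior_cov(self, J, lam):
        P0 = np.diag(1.0 / self.priors.covariance_diag)
        if np.isneginf(lam):
            H = P0
        else:
            H = np.exp(lam) * (J.T @ J) + P0
        Sigma = np.linalg.inv(H)
        return 0.5 * (Sigma + Sigma.T)

    def _update_lambda(self, ey, J, lam):
        if self.config.fixed_log_precision is not None:
            return self.config.fixed_log_precision
        # EM fixed point: precision = N / (residual power + curvature term)
        for _ in range(2):
            Sigma = self._posterior_cov(J, lam)
            r = ey @ ey + np.einsum("ij,jk,ik->", J, Sigma, J)
            lam = float(np.clip(np.log(ey.size / max(r, 1e-300)), -40.0, 40.0))
        return lam

    # -- fitting --------------------------------------------------------

    def fit(self) -> "SpectralDCMResults":
        cfg = self.config
        mu = self.priors.mean.copy()
        g = self._predict(mu)
        if g is None:
            raise NumericalError("prior mean implies an unstable A")
        ey = self.data_ - g
        lam = cfg.fixed_log_precision
        if lam is None:
            lam = float(np.clip(np.log(ey.size / max(ey @ ey, 1e-300)),
                                -40.0, 40.0))
        J = self._jacobian(mu, g)
        lam = self._update_lambda(ey, J, lam)
        Sigma = self._posterior_cov(J, lam)
        F, _, _ = self._free_energy(ey, J, Sigma, mu, lam)
        trace = [F]
        nu = cfg.init_damping
        small = 0
        converged = False
        n_iter = 0

        if np.isneginf(lam):
            # likelihood switched off: the posterior is the prior
            return self._results(mu, Sigma, trace, 0, True, lam, ey, J)

        for n_iter in range(1, cfg.max_iter + 1):
            P0d = 1.0 / self.priors.covariance_diag
            grad = np.exp(lam) * (J.T @ ey) - P0d * (mu - self.priors.mean)
            H = np.exp(lam) * (J.T @ J) + np.diag(P0d)
            accepted = False
            while nu <= cfg.max_damping:
                try:
                    step = np.linalg.solve(H + nu * np.diag(np.diag(H)), grad)
                except np.linalg.LinAlgError:
                    raise NumericalError("singular curvature matrix")
                mu_c = mu + step
                g_c = self._predict(mu_c)
                if g_c is not None and np.all(np.isfinite(g_c)):
                    ey_c = self.data_ - g_c
                    J_c = self._jacobian(mu_c, g_c)
                    lam_c = self._update_lambda(ey_c, J_c, lam)
                    Sigma_c = self._posterior_cov(J_c, lam_c)
                    F_c, _, _ = self._free_energy(ey_c, J_c, Sigma_c, mu_c, lam_c)
                    if np.isfinite(F_c) and F_c >= F - 1e-8:
                        accepted = True
                        break
                nu *= 8.0
            if not accepted:
                break
            dF = F_c - F
            mu, ey, J, lam, Sigma, F = mu_c, ey_c, J_c, lam_c, Sigma_c, F_c
            trace.append(F)
            nu = max(nu / 8.0, 1e-8)
            small = small + 1 if abs(dF) < cfg.tol else 0
            if small >= cfg.n_tol:
                converged = True
                break

        return self._results(mu, Sigma, trace, n_iter, converged, lam, ey, J)

    def _results(self, mu, Sigma, trace, n_iter, converged, lam, ey, J):
        F, accuracy, kl = self._free_energy(ey, J, Sigma, mu, lam)
        return SpectralDCMResults(
            model=self, mean=mu, covariance=Sigma, free_energy=float(F),
            accuracy=float(accuracy), complexity=float(kl),
            f_trace=np.asarray(trace), n_iterations=n_iter,
            converged=converged, log_precision=float(lam))


@dataclass
class SpectralDCMResults:
    """Gaussian posterior over latent parameters plus the free energy."""

    model: SpectralDCM
    mean: np.ndarray
    covariance: np.ndarray
    free_energy: float
    accuracy: float
    complexity: float
    f_trace: np.ndarray
    n_iterations: int
    converged: bool
    log_precision: float

    @property
    def space(self) -> ParamSpace:
        return self.model.space

    @property
    def A_mean(self) -> np.ndarray:
        """Posterior-mean coupling matrix on the real (Hz) scale."""
        return self.space.a_matrix(self.mean)

    @property
    def A_sd(self) -> np.ndarray:
        """Posterior SD of each A entry (delta method on the diagonal)."""
        sd = np.sqrt(np.diag(self.covariance))
        n = self.space.n
        out = np.zeros((n, n))
        for k, (i, j) in enumerate(self.space.off_idx):
            out[i, j] = sd[k]
        lat = self.mean[self.space.n_off:self.space.n_off + n]
        lat_sd = sd[self.space.n_off:self.space.n_off + n]
        np.fill_diagonal(out, np.abs(SELF_SCALE) * np.exp(lat) * lat_sd)
        return out

    def summary(self) -> pd.DataFrame:
        """Per-parameter posterior table (latent scale)."""
        sd = np.sqrt(np.diag(self.covariance))
        return pd.DataFrame({
            "parameter": self.space.labels,
            "mean": self.mean,
            "sd": sd,
        })

    def to_hdf5(self, path, **attrs) -> None:
        import h5py
        with h5py.File(path, "w") as h:
            h.create_dataset("mu", data=self.mean)
            h.create_dataset("Sigma", data=self.covariance)
            h.create_dataset("F", data=self.free_energy)
            h.create_dataset("prior_mean", data=self.model.priors.mean)
            h.create_dataset("prior_var", data=self.model.priors.covariance_diag)
            h.attrs["labels"] = self.space.labels
            h.attrs["n_nodes"] = self.space.n
            h.attrs["fit_hemo"] = self.space.config.fit_hemo
            if self.space.node_labels:
                h.attrs["node_labels"] = list(self.space.node_labels)
            h.attrs["converged"] = self.converged
            h.attrs["n_iterations"] = self.n_iterations
            for k, v in attrs.items():
                h.attrs[k] = v


def fit_cohort(records, priors: PriorSpec | None = None,
               config: InversionConfig | None = None,
               spectral_config: SpectralConfig | None = None,
               verbose: bool = False) -> list[SpectralDCMResults]:
    """Invert every subject of a cohort; order is preserved.

    ``records`` is a sequence of objects with ``roi_series`` (time x nodes),
    ``tr`` and optionally ``labels``/``node_labels`` attributes (see
    ``ecdcm.cohort.SubjectRecord``), or plain (series, tr) tuples.
    """
    results = []
    n_nodes = None
    for k, rec in enumerate(records):
        if isinstance(rec, tuple):
            series, tr, labels = rec[0], rec[1], None
        else:
            series, tr = rec.roi_series, rec.tr
            labels = getattr(rec, "node_labels", None)
        series = np.asarray(series, dtype=float)
        if n_nodes is None:
            n_nodes = series.shape[1]
        elif series.shape[1] != n_nodes:
            raise ConfigError(
                f"subject {k} has {series.shape[1]} nodes, expected {n_nodes}")
        dcm = SpectralDCM.from_timeseries(series, tr,
                                          spectral_config=spectral_config,
                                          priors=priors, config=config,
                                          node_labels=labels)
        res = dcm.fit()
        results.append(res)
        if verbose:
            print(f"subject {k}: F={res.free_energy:.2f} "
                  f"iters={res.n_iterations} converged={res.converged}")
    return results
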