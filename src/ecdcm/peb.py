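"""Group-level parametric empirical Bayes and Bayesian model reduction.

``PEB`` pools subject posteriors in a two-level linear-Gaussian model:
each subject's parameter vector is a design-matrix combination of group
effects plus an i.i.d. Gaussian random effect,

    theta_i = (x_i' (x) I) beta + eps_i,   eps_i ~ N(0, exp(-gamma) I),

and the group effects carry a Gaussian shrinkage prior.  The single
between-subject log-precision gamma is optimised by maximising the
marginal likelihood (empirical Bayes); beta then has a closed-form
Gaussian posterior.

``bmr_reduce`` gives the change in log evidence and the posterior under
any modified (reduced) prior, analytically, without re-fitting data.
``PEBResults.search`` uses it over on/off patterns of each connection
(greedy pruning followed by exhaustive scoring of the remaining
candidate set) and Bayesian-model-averages the surviving models into
per-connection posterior probabilities and strengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .exceptions import ArgumentError, ConfigError, NumericalError
from .inversion import SELF_SCALE, SpectralDCMResults

__all__ = [
    "GaussianDensity", "PEB", "PEBModel", "PEBResults",
    "ConnectionProbabilities", "bmr_reduce", "threshold_network",
]


@dataclass
class GaussianDensity:
    """A multivariate Gaussian given by mean and covariance."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ArgumentError("covariance shape does not match mean")


def bmr_reduce(full_prior: GaussianDensity, full_posterior: GaussianDensity,
               reduced_prior: GaussianDensity):
    """Evidence change and posterior under a reduced prior.

    Returns ``(delta_free_energy, reduced_posterior)`` where
    delta_free_energy = log p(y | reduced) - log p(y | full), computed
    from Gaussian algebra alone (no re-inversion of the data).
    """
    if not (full_prior.mean.size == full_posterior.mean.size
            == reduced_prior.mean.size):
        raise ArgumentError("dimension mismatch between densities")
    P0 = _inv_psd(full_prior.cov, "full prior")
    P = _inv_psd(full_posterior.cov, "full posterior")
    Pr0 = _inv_psd(reduced_prior.cov, "reduced prior")
    Pr = P + Pr0 - P0
    sign, _ = np.linalg.slogdet(Pr)
    if sign <= 0:
        raise NumericalError("reduced posterior precision not positive "
                             "definite; the prior reduction is inadmissible")
    b = (P @ full_posterior.mean + Pr0 @ reduced_prior.mean
         - P0 @ full_prior.mean)
    mu_r = np.linalg.solve(Pr, b)
    c = (full_posterior.mean @ P @ full_posterior.mean
         + reduced_prior.mean @ Pr0 @ reduced_prior.mean
         - full_prior.mean @ P0 @ full_prior.mean)
    dF = 0.5 * (_slogdet(P) + _slogdet(Pr0) - _slogdet(P0) - _slogdet(Pr))
    dF -= 0.5 * (c - b @ mu_r)
    cov_r = np.linalg.inv(Pr)
    return float(dF), GaussianDensity(mean=mu_r, cov=0.5 * (cov_r + cov_r.T))


def _deshrink(mu, cov, prior_mean, prior_var_diag):
    """Recover the per-subject likelihood kernel from posterior and prior.

    Dividing the Gaussian posterior by the Gaussian prior yields the data
    evidence about the parameters unbiased by first-level shrinkage:
    precision P - P0 and mean (P - P0)^-1 (P mu - P0 m0).  Directions the
    data did not inform get a floor precision (huge variance), which the
    second level then down-weights naturally.
    """
    P = np.linalg.inv(cov)
    Lam = P - np.diag(1.0 / prior_var_diag)
    w, V = np.linalg.eigh(0.5 * (Lam + Lam.T))
    floor = max(1e-8, 1e-10 * max(w.max(), 1.0))
    w = np.maximum(w, floor)
    Lam = V @ np.diag(w) @ V.T
    C = V @ np.diag(1.0 / w) @ V.T
    eta = C @ (P @ mu - prior_mean / prior_var_diag)
    return eta, 0.5 * (C + C.T)


def _inv_psd(M, name):
    try:
        return np.linalg.inv(M)
    except np.linalg.LinAlgError as e:
        raise NumericalError(f"singular covariance in {name}") from e


def _slogdet(M):
    sign, ld = np.linalg.slogdet(M)
    if sign <= 0:
        raise NumericalError("non-positive-definite matrix in evidence "
                             "computation")
    return ld


@dataclass
class PEBConfig:
    """Second-level settings.

    gamma_bounds: search interval for the between-subject log precision.
    gamma_prior_mean / gamma_prior_var: weak Gaussian hyperprior on gamma.
    beta_prior_var: shrinkage-prior variance of each group effect
        (None disables shrinkage: flat prior on beta).
    reduced_var: prior variance representing a switched-off connection.
    max_exhaustive: model-space size scored exhaustively after pruning.
    """

    gamma_bounds: tuple = (-5.0, 25.0)
    gamma_prior_mean: float = 4.0
    gamma_prior_var: float = 16.0
    beta_prior_var: float | None = 1.0 / 64.0
    reduced_var: float = 1e-8
    max_exhaustive: int = 8
    use_subject_priors: bool = True


class PEB:
    """Model object for the between-subject (second) level.

    Parameters
    ----------
    posteriors : sequence of SpectralDCMResults or (mean, cov) pairs
        Subject-level Gaussian posteriors.
    design_matrix : (n_subjects, n_covariates) array, optional
        First column should be the group mean (all ones); defaults to a
        single all-ones column.
    param_indices : sequence of int, optional
        Which latent parameters enter the second level; defaults to all
        coupling (A) parameters when posteriors are SpectralDCMResults,
        else all parameters.
    param_labels, self_mask : optional metadata used for reporting.
    """

    def __init__(self, posteriors, design_matrix=None, param_indices=None,
                 config: PEBConfig | None = None, param_labels=None,
                 self_mask=None, node_labels=None, space=None,
                 subject_priors=None):
        if len(posteriors) == 0:
            raise ConfigError("PEB requires at least one subject")
        self.config = config or PEBConfig()
        mus, covs = [], []
        first = posteriors[0]
        if isinstance(first, SpectralDCMResults) or space is not None:
            space = space if space is not None else first.space
            if param_indices is None:
                param_indices = np.arange(space.n_params)[space.a_slice()]
            if param_labels is None:
                param_labels = [space.labels[i] for i in param_indices]
            if self_mask is None:
                self_mask = space.is_self()[param_indices]
            if node_labels is None:
                node_labels = (first.model.csd.node_labels
                               if isinstance(first, SpectralDCMResults)
                               else space.node_labels)
            self.space = space
            for r in posteriors:
                m = r.mean if isinstance(r, SpectralDCMResults) else np.asarray(r[0], float)
                c = r.covariance if isinstance(r, SpectralDCMResults) else np.atleast_2d(np.asarray(r[1], float))
                m = m[param_indices]
                c = c[np.ix_(param_indices, param_indices)]
                if self.config.use_subject_priors:
                    if isinstance(r, SpectralDCMResults):
                        pm = r.model.priors.mean
                        pv = r.model.priors.covariance_diag
                    elif subject_priors is not None:
                        pm, pv = (np.asarray(a, float) for a in subject_priors)
                    else:
                        pm = pv = None
                    if pm is not None:
                        m, c = _deshrink(m, c, pm[param_indices],
                                         pv[param_indices])
                mus.append(m)
                covs.append(c)
        else:
            self.space = None
            for m, c in posteriors:
                m = np.asarray(m, dtype=float)
                idx = (np.arange(m.size) if param_indices is None
                       else np.asarray(param_indices))
                mus.append(m[idx])
                covs.append(np.atleast_2d(np.asarray(c, float))[np.ix_(idx, idx)])
        self.mus = np.asarray(mus)                  # (n_sub, p)
        self.covs = np.asarray(covs)                # (n_sub, p, p)
        self.n_subjects, self.n_params = self.mus.shape
        self.param_labels = (list(param_labels) if param_labels is not None
                             else [f"p{i}" for i in range(self.n_params)])
        self.self_mask = (np.asarray(self_mask, dtype=bool)
                          if self_mask is not None
                          else np.zeros(self.n_params, dtype=bool))
        self.node_labels = tuple(node_labels) if node_labels else None
        if design_matrix is None:
            design_matrix = np.ones((self.n_subjects, 1))
        self.X = np.atleast_2d(np.asarray(design_matrix, dtype=float))
        if self.X.shape[0] != self.n_subjects:
            raise ConfigError("design matrix rows must match subject count")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ConfigError("design matrix is rank deficient")
        self.n_cov = self.X.shape[1]

    # -- marginal likelihood over gamma ---------------------------------

    def _evidence(self, gamma: float):
        """Log evidence (beta integrated out) at fixed gamma, plus the
        posterior precision/mean ingredients."""
        p, k = self.n_params, self.n_cov
        sig_b = np.exp(-gamma)
        dim = k * p
        Pb = np.zeros((dim, dim))
        r = np.zeros(dim)
        quad = 0.0
        logdet = 0.0
        for i in range(self.n_subjects):
            C = self.covs[i] + sig_b * np.eye(p)
            Ci = np.linalg.inv(C)
            logdet += _slogdet(2 * np.pi * C)
            Cimu = Ci @ self.mus[i]
            quad += self.mus[i] @ Cimu
            Pb += np.kron(np.outer(self.X[i], self.X[i]), Ci)
            r += np.kron(self.X[i], Cimu)
        if self.config.beta_prior_var is not None:
            P0 = np.eye(dim) / self.config.beta_prior_var
            Ppost = Pb + P0
            m = np.linalg.solve(Ppost, r)
            lz = (-0.5 * logdet - 0.5 * quad + 0.5 * (r @ m)
                  - 0.5 * dim * np.log(self.config.beta_prior_var)
                  - 0.5 * _slogdet(Ppost))
        else:
            # flat (improper) prior on beta: profile marginal likelihood
            Ppost = Pb
            m = np.linalg.solve(Ppost, r)
            lz = (-0.5 * logdet - 0.5 * quad + 0.5 * (r @ m)
                  + 0.5 * dim * np.log(2 * np.pi) - 0.5 * _slogdet(Ppost))
        lz += -0.5 * (gamma - self.config.gamma_prior_mean) ** 2 \
            / self.config.gamma_prior_var
        return lz, m, Ppost

    def fit(self) -> "PEBResults":
        res = minimize_scalar(lambda g: -self._evidence(g)[0],
                              bounds=self.config.gamma_bounds,
                              method="bounded",
                              options={"xatol": 1e-4})
        gamma = float(res.x)
        lz, m, Ppost = self._evidence(gamma)
        cov = np.linalg.inv(Ppost)
        cov = 0.5 * (cov + cov.T)
        return PEBResults(
            model=self,
            beta_mean=m.reshape(self.n_cov, self.n_params),
            beta_cov=cov,
            gamma=gamma,
            free_energy=float(lz),
        )


#: Backwards-compatible alias: the fitted second-level model object.
PEBModel = PEB


@dataclass
class ConnectionProbabilities:
    """Per-connection presence probabilities and model-averaged strengths.

    Matrices are indexed [to, from] (columns are source nodes); strengths
    are on the real scale, self-connections back-transformed from their
    log-latent representation.
    """

    prob: np.ndarray
    strength_mean: np.ndarray
    strength_var: np.ndarray
    node_labels: tuple | None = None
    param_prob: np.ndarray | None = None
    param_mean: np.ndarray | None = None
    param_var: np.ndarray | None = None

    def edge_list(self) -> pd.DataFrame:
        n = self.prob.shape[0]
        labels = self.node_labels or tuple(f"node{i}" for i in range(n))
        rows = [
            {"from_label": labels[j], "to_label": labels[i],
             "strength": self.strength_mean[i, j],
             "variance": self.strength_var[i, j],
             "probability": self.prob[i, j]}
            for j in range(n) for i in range(n)
        ]
        return pd.DataFrame(rows)


@dataclass
class PEBResults:
    """Posterior over group effects plus empirical-Bayes hyperparameters."""

    model: PEB
    beta_mean: np.ndarray       # (n_cov, n_params)
    beta_cov: np.ndarray        # (n_cov*n_params, n_cov*n_params)
    gamma: float
    free_energy: float

    @property
    def random_effect_sd(self) -> float:
        return float(np.exp(-self.gamma / 2.0))

    def group_prior(self) -> GaussianDensity:
        dim = self.model.n_cov * self.model.n_params
        v = self.model.config.beta_prior_var
        if v is None:
            raise ConfigError("model search requires a proper shrinkage prior")
        return GaussianDensity(mean=np.zeros(dim), cov=np.eye(dim) * v)

    def group_posterior(self) -> GaussianDensity:
        return GaussianDensity(mean=self.beta_mean.ravel(), cov=self.beta_cov)

    def summary(self) -> pd.DataFrame:
        sd = np.sqrt(np.diag(self.beta_cov)).reshape(self.beta_mean.shape)
        rows = []
        for c in range(self.model.n_cov):
            for p, lbl in enumerate(self.model.param_labels):
                rows.append({"covariate": c, "parameter": lbl,
                             "mean": self.beta_mean[c, p],
                             "sd": sd[c, p]})
        return pd.DataFrame(rows)

    # -- Bayesian model reduction over on/off patterns ------------------

    def _reduced_prior(self, off: np.ndarray) -> GaussianDensity:
        """Prior with the given group-mean parameters switched off."""
        prior = self.group_prior()
        cov = prior.cov.copy()
        # only covariate 0 (the group mean) participates in the search
        for p in np.flatnonzero(off):
            cov[p, p] = self.model.config.reduced_var
        return GaussianDensity(mean=prior.mean, cov=cov)

    def _delta_f(self, off: np.ndarray):
        return bmr_reduce(self.group_prior(), self.group_posterior(),
                          self._reduced_prior(off))

    def search(self, max_exhaustive: int | None = None) -> ConnectionProbabilities:
        """BMR over on/off patterns of the group-mean connections.

        Connections are greedily pruned while switching them off improves
        the evidence; the last ``max_exhaustive`` uncertain candidates are
        then scored exhaustively (2^m models) and Bayesian-model-averaged
        with softmax(evidence) weights.
        """
        cfg = self.model.config
        m_ex = max_exhaustive or cfg.max_exhaustive
        p = self.model.n_params
        off = np.zeros(p, dtype=bool)

        if p > m_ex:
            # greedy pruning: switch off the connection whose removal
            # increases the evidence the most, while any does
            improved = True
            while improved and (~off).sum() > m_ex:
                improved = False
                base = self._delta_f(off)[0]
                gains = np.full(p, -np.inf)
                for j in np.flatnonzero(~off):
                    trial = off.copy()
                    trial[j] = True
                    gains[j] = self._delta_f(trial)[0] - base
                best = int(np.argmax(gains))
                if gains[best] > 0:
                    off[best] = True
                    improved = True
            # uncertain set: smallest |evidence change| among current states
            margins = np.empty(p)
            base_dF = self._delta_f(off)[0]
            for j in range(p):
                trial = off.copy()
                trial[j] = ~trial[j]
                margins[j] = abs(self._delta_f(trial)[0] - base_dF)
            candidates = np.argsort(margins)[:m_ex]
        else:
            candidates = np.arange(p)

        fixed_off = off.copy()
        fixed_off[candidates] = False
        n_c = candidates.size
        n_models = 2 ** n_c
        dFs = np.empty(n_models)
        posts = []
        for m in range(n_models):
            trial = fixed_off.copy()
            for b in range(n_c):
                if (m >> b) & 1:
                    trial[candidates[b]] = True
            dF, post = self._delta_f(trial)
            dFs[m] = dF
            posts.append((trial, post))
        w = np.exp(dFs - dFs.max())
        w /= w.sum()

        # per-parameter probability of being "on", and BMA moments
        prob = np.zeros(p)
        mean = np.zeros(p)
        second = np.zeros(p)
        for wt, (trial, post) in zip(w, posts):
            prob += wt * (~trial)
            mu = post.mean[:p]          # covariate 0 block
            var = np.diag(post.cov)[:p]
            mean += wt * mu
            second += wt * (var + mu ** 2)
        var = np.maximum(second - mean ** 2, 0.0)
        prob = np.clip(prob, 0.0, 1.0)
        return self._to_matrices(prob, mean, var)

    def _to_matrices(self, prob, mean, var) -> ConnectionProbabilities:
        """Arrange parameter vectors as [to, from] matrices on the real scale."""
        sm = self.model.self_mask
        mean_t = mean.copy()
        var_t = var.copy()
        # self-connections: a = -0.5 exp(latent); delta-method variance
        mean_t[sm] = SELF_SCALE * np.exp(mean[sm])
        var_t[sm] = (np.abs(SELF_SCALE) * np.exp(mean[sm])) ** 2 * var[sm]
        if self.model.space is not None:
            n = self.model.space.n
            P = np.zeros((n, n))
            M = np.zeros((n, n))
            V = np.zeros((n, n))
            k = 0
            for idx, (i, j) in enumerate(self.model.space.off_idx):
                P[i, j], M[i, j], V[i, j] = prob[idx], mean_t[idx], var_t[idx]
                k += 1
            for s in range(n):
                P[s, s] = prob[k + s]
                M[s, s] = mean_t[k + s]
                V[s, s] = var_t[k + s]
            labels = self.model.node_labels
        else:
            # no node structure available: report flat 1 x p "matrices"
            p = prob.size
            P, M, V = (x.reshape(1, p) for x in (prob, mean_t, var_t))
            labels = None
        return ConnectionProbabilities(
            prob=P, strength_mean=M, strength_var=V, node_labels=labels,
            param_prob=prob, param_mean=mean_t, param_var=var_t)


def threshold_network(cp: ConnectionProbabilities, level: float):
    """Adjacency and strengths of connections with probability > level.

    ``level`` must lie in [0, 1); 0 keeps every connection with nonzero
    probability (the no-threshold condition).
    """
    if not 0 <= level < 1:
        raise ArgumentError("threshold level must lie in [0, 1)")
    adjacency = cp.prob > level if level > 0 else cp.prob > 0
    strengths = np.where(adjacency, cp.strength_mean, 0.0)
    return adjacency, strengths
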