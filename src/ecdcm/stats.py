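"""Frequentist group analyses on subject-level connection strengths.

Two operations mirror the downstream statistics of the study design:

* ``anova_connections`` — one-way ANOVA per connection across the four
  groups, followed by all pairwise group contrasts with pooled-error
  standard errors and Bonferroni-adjusted significance (family = the
  number of pairwise comparisons within a connection).
* ``stepwise_regression`` — forward stepwise linear regression of a
  cognitive score on connection strengths (SPSS-style entry/removal
  p-value criteria), reporting standardized coefficients and the final
  model's R^2 and F.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ArgumentError, DataError

__all__ = ["AnovaTable", "StepwiseResult", "anova_connections",
           "stepwise_regression"]


@dataclass
class AnovaTable:
    """Per-connection F tests plus pairwise Bonferroni contrasts."""

    connections: list
    f_statistic: np.ndarray
    p_value: np.ndarray
    pairwise: pd.DataFrame
    alpha: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "connection": self.connections,
            "F": self.f_statistic,
            "p": self.p_value,
        })

    def significant(self) -> list:
        return [c for c, p in zip(self.connections, self.p_value)
                if p < self.alpha]


def anova_connections(strengths, groups, alpha: float = 0.05,
                      connection_labels=None) -> AnovaTable:
    """One-way ANOVA per connection with Bonferroni pairwise contrasts.

    Parameters
    ----------
    strengths : (n_subjects, n_connections) array or DataFrame
    groups : length-n_subjects sequence of group labels
    alpha : family-wise significance level for ``significant()``

    The pairwise table follows the reporting layout
    (connection, (I) group, (J) group, mean difference (I-J), std. error,
    adjusted significance); the adjustment multiplies each two-sided
    pooled-t p-value by the number of pairwise comparisons, capped at 1.
    """
    if isinstance(strengths, pd.DataFrame):
        if connection_labels is None:
            connection_labels = list(strengths.columns)
        strengths = strengths.to_numpy(dtype=float)
    strengths = np.asarray(strengths, dtype=float)
    if strengths.ndim == 1:
        strengths = strengths[:, None]
    n_sub, n_conn = strengths.shape
    groups = np.asarray(groups)
    if groups.size != n_sub:
        raise ArgumentError("groups length must match subject count")
    labels = list(dict.fromkeys(groups))
    if len(labels) < 2:
        raise DataError("ANOVA requires at least 2 groups")
    sizes = {g: int(np.sum(groups == g)) for g in labels}
    for g, n in sizes.items():
        if n < 2:
            raise DataError(f"group {g!r} has fewer than 2 subjects")
    if connection_labels is None:
        connection_labels = [f"c{k}" for k in range(n_conn)]

    n_pairs = len(labels) * (len(labels) - 1) // 2
    df_within = n_sub - len(labels)
    f_stats = np.empty(n_conn)
    p_vals = np.empty(n_conn)
    rows = []
    for k in range(n_conn):
        y = strengths[:, k]
        means = {g: y[groups == g].mean() for g in labels}
        grand = y.mean()
        ss_between = sum(sizes[g] * (means[g] - grand) ** 2 for g in labels)
        ss_within = sum(((y[groups == g] - means[g]) ** 2).sum()
                        for g in labels)
        df_between = len(labels) - 1
        mse = ss_within / df_within
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss_between / df_between) / mse if mse > 0 else (
                0.0 if ss_between == 0 else np.inf)
        f_stats[k] = f
        p_vals[k] = sps.f.sf(f, df_between, df_within) if np.isfinite(f) else 0.0
        for gi, gj in combinations(labels, 2):
            diff = means[gi] - means[gj]
            se = np.sqrt(mse * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
            if se > 0:
                t = diff / se
                p = 2 * sps.t.sf(abs(t), df_within)
            else:
                p = 1.0 if diff == 0 else 0.0
            sig = min(p * n_pairs, 1.0)
            lab = connection_labels[k]
            rows.append({"connection": lab, "(I) group": gi, "(J) group": gj,
                         "mean difference (I-J)": diff, "std. error": se,
                         "sig.": sig})
            rows.append({"connection": lab, "(I) group": gj, "(J) group": gi,
                         "mean difference (I-J)": -diff, "std. error": se,
                         "sig.": sig})
    return AnovaTable(connections=list(connection_labels),
                      f_statistic=f_stats, p_value=p_vals,
                      pairwise=pd.DataFrame(rows), alpha=alpha)


@dataclass
class StepwiseResult:
    """Forward-selection outcome for one cognitive score."""

    entered: list
    standardized_beta: np.ndarray
    beta_p_values: np.ndarray
    r_squared: float
    f_statistic: float
    model_p_value: float
    n_subjects: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "predictor": self.entered,
            "beta": self.standardized_beta,
            "p": self.beta_p_values,
        })


def _ols(y, X):
    """Least squares with intercept; returns (coef, residual SS, df_resid)."""
    n = y.size
    Xd = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    coef, _, rank, _ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ coef
    return coef, float(resid @ resid), n - rank


def stepwise_regression(score, strengths, p_enter: float = 0.05,
                        p_remove: float = 0.10,
                        connection_labels=None) -> StepwiseResult:
    """Forward stepwise regression with backward removal.

    At each step the candidate with the smallest partial-F p-value enters
    if that p-value is below ``p_enter``; entered predictors whose partial
    p-value rises above ``p_remove`` are dropped again.  Reported
    coefficients are standardized (z-scored response and predictors).
    """
    if isinstance(strengths, pd.DataFrame):
        if connection_labels is None:
            connection_labels = list(strengths.columns)
        strengths = strengths.to_numpy(dtype=float)
    y = np.asarray(score, dtype=float)
    X = np.asarray(strengths, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n_sub, n_cand = X.shape
    if y.size != n_sub:
        raise ArgumentError("score length must match subject count")
    if np.ptp(y) == 0:
        raise DataError("response is constant")
    if not 0 <= p_enter <= 1 or not 0 <= p_remove <= 1:
        raise ArgumentError("p_enter and p_remove must lie in [0, 1]")
    if connection_labels is None:
        connection_labels = [f"c{k}" for k in range(n_cand)]

    selected: list[int] = []

    def partial_p(cols):
        """p-value of each coefficient in the model with the given columns."""
        coef, rss, dfr = _ols(y, X[:, cols])
        if dfr <= 0:
            return None
        ps = []
        Xd = np.column_stack([np.ones(n_sub), X[:, cols]])
        xtx_inv = np.linalg.pinv(Xd.T @ Xd)
        mse = rss / dfr if dfr > 0 else np.inf
        for j in range(1, len(cols) + 1):
            se = np.sqrt(max(mse * xtx_inv[j, j], 1e-300))
            t = coef[j] / se
            ps.append(2 * sps.t.sf(abs(t), dfr))
        return ps

    tss0 = float(((y - y.mean()) ** 2).sum())
    seen = {tuple(selected)}
    for _ in range(2 * n_cand + 4):      # hard cap against cycling
        remaining = [k for k in range(n_cand) if k not in selected]
        if not remaining or n_sub - len(selected) - 2 <= 0:
            break
        if selected:
            _, rss_cur, _ = _ols(y, X[:, selected])
            if rss_cur <= 1e-12 * tss0:  # numerically perfect fit
                break
        best_p, best_k = np.inf, None
        for k in remaining:
            ps = partial_p(selected + [k])
            if ps is None:
                continue
            if ps[-1] < best_p:
                best_p, best_k = ps[-1], k
        if best_k is None or not best_p < p_enter:
            break
        selected.append(best_k)
        # backward removal
        while len(selected) > 1:
            ps = partial_p(selected)
            worst = int(np.argmax(ps))
            if ps[worst] > p_remove and selected[worst] != best_k:
                selected.pop(worst)
            else:
                break
        key = tuple(sorted(selected))
        if key in seen:                   # revisited a model: stop
            break
        seen.add(key)

    if selected:
        zy = (y - y.mean()) / y.std(ddof=1)
        Zx = X[:, selected]
        Zx = (Zx - Zx.mean(axis=0)) / Zx.std(axis=0, ddof=1)
        coef, rss, dfr = _ols(zy, Zx)
        betas = coef[1:]
        ps = np.asarray(partial_p(selected))
        tss = float(zy @ zy)
        r2 = 1.0 - rss / tss
        k = len(selected)
        if 1.0 - r2 > 1e-14:
            f = (r2 / k) / ((1 - r2) / (n_sub - k - 1))
            model_p = float(sps.f.sf(f, k, n_sub - k - 1))
        else:                       # numerically perfect fit
            r2, f, model_p = 1.0, np.inf, 0.0
    else:
        betas = np.array([])
        ps = np.array([])
        r2, f, model_p = 0.0, np.nan, np.nan
    return StepwiseResult(
        entered=[connection_labels[k] for k in selected],
        standardized_beta=betas, beta_p_values=ps,
        r_squared=float(r2), f_statistic=float(f) if selected else np.nan,
        model_p_value=model_p, n_subjects=n_sub)
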