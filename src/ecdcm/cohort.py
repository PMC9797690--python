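"""Synthetic four-group cohort emulating an AD-progression study.

The generator produces a cohort of CN / EMCI / LMCI / AD subjects with

* a shared ground-truth coupling matrix (default: the CN group matrix
  reported by the reference analysis, ``BASE_A``),
* group-wise multiplicative attenuation of the off-diagonal couplings
  (disease progressively weakens between-region influence),
* per-subject Gaussian random effects on every coupling entry, with
  stability-rejected resampling,
* BOLD time series simulated through the full neuronal + hemodynamic
  forward model at the study's acquisition parameters (TR = 3 s, 140
  volumes of which the first 10 are discarded), and
* cognitive scores (MMSE-like and CDR-like) that are linear functions of
  the subject's coupling strengths plus Gaussian noise, anchored so the
  CN and AD group means match the reference demographics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import forward
from .exceptions import ArgumentError, ConfigError
from .model import (DEFAULT_NODE_LABELS, CouplingModel, HemodynamicParams,
                    NeuronalNoiseSpec)

__all__ = [
    "BASE_A", "GROUPS", "CohortConfig", "ScoreModel", "SubjectRecord",
    "generate_cohort", "generate_coupling_matrices", "generate_scores",
    "default_score_models", "write_manifest", "render_nifti",
]

GROUPS = ("CN", "EMCI", "LMCI", "AD")

# Ground-truth coupling (Hz), indexed [to, from], node order
# L-PCC, R-PCC, L-ACC, R-ACC, L-dlPFC, R-dlPFC, mPFC: the CN group
# posterior means of the reference analysis.
BASE_A = np.array([
    [-3.409e-01, 6.810e-02, 5.377e-02, 4.640e-02, 3.484e-02, 4.900e-02, 5.165e-02],
    [6.963e-02, -3.764e-01, 6.388e-02, 6.570e-02, 3.612e-02, 3.800e-02, 4.584e-02],
    [5.544e-02, 7.408e-02, -3.631e-01, 1.055e-01, 4.268e-02, 7.492e-02, 4.635e-02],
    [4.120e-02, 8.136e-02, 1.026e-01, -3.787e-01, 7.986e-03, 4.455e-02, 5.455e-02],
    [5.228e-02, 5.234e-02, 6.959e-02, 9.842e-03, -3.802e-01, 9.445e-02, 2.421e-02],
    [6.599e-02, 3.964e-02, 8.255e-02, 5.221e-02, 8.666e-02, -3.612e-01, 1.884e-02],
    [7.884e-02, 6.622e-02, 6.039e-02, 8.409e-02, 2.884e-02, 9.391e-03, -4.345e-01],
])

#: Group-mean targets of the emulated demographics.
MMSE_TARGETS = {"CN": 29.32, "EMCI": 27.91, "LMCI": 27.54, "AD": 19.80}
CDR_TARGETS = {"CN": 0.00, "EMCI": 0.47, "LMCI": 0.48, "AD": 1.02}


@dataclass
class ScoreModel:
    """score = intercept + coefficients . vec(A_subject) + N(0, noise_sd^2)."""

    intercept: float
    coefficients: np.ndarray      # length n_nodes**2, vec in C order
    noise_sd: float

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)


def default_score_models(base_A: np.ndarray = BASE_A,
                         attenuation_ad: float = 0.05) -> dict[str, ScoreModel]:
    """MMSE-like and CDR-like score models anchored at the CN and AD means.

    Coefficients load uniformly on the off-diagonal couplings; the weight
    is solved so that full attenuation of the off-diagonals moves the
    group mean from the CN target to the AD target, which ties the score
    scale to the connectivity scale without per-group intercepts.
    """
    n = base_A.shape[0]
    off = ~np.eye(n, dtype=bool)
    total = base_A[off].sum()
    drop = total * (1.0 - attenuation_ad)
    out = {}
    for name, targets, noise in (("mmse", MMSE_TARGETS, 0.9),
                                 ("cdr", CDR_TARGETS, 0.1)):
        # no attenuation contrast -> flat score model at the CN target
        w = (targets["CN"] - targets["AD"]) / drop if abs(drop) > 1e-12 else 0.0
        coef = np.where(off, w, 0.0).ravel()
        intercept = targets["CN"] - coef @ base_A.ravel()
        out[name] = ScoreModel(intercept=intercept, coefficients=coef,
                               noise_sd=noise)
    return out


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort."""

    group_sizes: dict = field(default_factory=lambda: {
        "CN": 31, "EMCI": 34, "LMCI": 31, "AD": 34})
    base_A: np.ndarray = field(default_factory=lambda: BASE_A.copy())
    attenuation: dict = field(default_factory=lambda: {
        "CN": 1.0, "EMCI": 0.6, "LMCI": 0.3, "AD": 0.05})
    self_shift: dict = field(default_factory=lambda: {g: 0.0 for g in GROUPS})
    random_effect_sd: float = 0.03
    score_models: dict = None
    noise: NeuronalNoiseSpec = field(default_factory=lambda: NeuronalNoiseSpec(
        amplitude_alpha=1e-3, exponent_beta=0.0,
        observation_alpha=1e-7, observation_beta=0.0))
    hemo: HemodynamicParams = field(default_factory=HemodynamicParams)
    tr: float = 3.0
    n_volumes: int = 140
    discard_initial: int = 10
    dt: float = 0.05
    node_labels: tuple = None
    seed: int = 0

    def __post_init__(self):
        self.base_A = np.asarray(self.base_A, dtype=float)
        n = self.base_A.shape[0]
        if self.base_A.shape != (n, n):
            raise ConfigError("base_A must be square")
        if self.node_labels is None:
            self.node_labels = (DEFAULT_NODE_LABELS if n == 7 else
                                tuple(f"node{i}" for i in range(n)))
        att = [self.attenuation[g] for g in GROUPS]
        if any(not 0 <= a <= 1 for a in att):
            raise ConfigError("attenuation multipliers must lie in [0, 1]")
        if any(a < b for a, b in zip(att, att[1:])):
            raise ConfigError(
                "attenuation must be non-increasing along CN->EMCI->LMCI->AD")
        if any(s < 1 for s in self.group_sizes.values()):
            raise ConfigError("group sizes must be >= 1")
        if self.score_models is None:
            self.score_models = default_score_models(
                self.base_A, self.attenuation["AD"])

    @property
    def n_nodes(self) -> int:
        return self.base_A.shape[0]

    @property
    def n_retained(self) -> int:
        return self.n_volumes - self.discard_initial


@dataclass
class SubjectRecord:
    """One subject: identity, ground truth, data and scores."""

    subject_id: str
    group: str
    ground_truth_A: np.ndarray
    roi_series: np.ndarray        # (n_retained, n_nodes)
    tr: float
    scores: dict
    node_labels: tuple = DEFAULT_NODE_LABELS


def _draw_subject_A(cfg: CohortConfig, group: str,
                    rng: np.random.Generator) -> np.ndarray:
    """Attenuated base coupling plus random effect, resampled for stability."""
    n = cfg.n_nodes
    off = ~np.eye(n, dtype=bool)
    A_g = cfg.base_A.copy()
    A_g[off] *= cfg.attenuation[group]
    A_g[~off] += cfg.self_shift.get(group, 0.0)
    for _ in range(100):
        A = A_g + cfg.random_effect_sd * rng.standard_normal((n, n))
        if np.all(np.diag(A) < 0) and np.all(np.linalg.eigvals(A).real < 0):
            return A
    raise ConfigError(
        f"could not draw a stable coupling matrix for group {group} "
        f"after 100 attempts")


def generate_coupling_matrices(config: CohortConfig,
                               rng: np.random.Generator | None = None):
    """Ground-truth A matrices for every subject, grouped as in the cohort."""
    rng = rng or np.random.default_rng(config.seed)
    out = []
    for g in GROUPS:
        for k in range(config.group_sizes[g]):
            out.append((g, _draw_subject_A(config, g, rng)))
    return out


def generate_scores(records, score_models: dict, seed: int | None = None):
    """Cognitive scores for existing records; returns a list of dicts.

    Each score is a linear readout of the subject's ground-truth coupling
    plus Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    out = []
    for rec in records:
        A = rec.ground_truth_A if hasattr(rec, "ground_truth_A") else rec
        vec = np.asarray(A, dtype=float).ravel()
        scores = {}
        for name, sm in score_models.items():
            if sm.coefficients.size != vec.size:
                raise ArgumentError(
                    f"score model {name!r} expects {sm.coefficients.size} "
                    f"coefficients, coupling has {vec.size} entries")
            scores[name] = float(sm.intercept + sm.coefficients @ vec
                                 + sm.noise_sd * rng.standard_normal())
        out.append(scores)
    return out


def generate_cohort(config: CohortConfig | None = None,
                    include_series: bool = True) -> list[SubjectRecord]:
    """Generate the full synthetic cohort, reproducibly from config.seed."""
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    truths = generate_coupling_matrices(cfg, rng)
    records = []
    for k, (group, A) in enumerate(truths):
        if include_series:
            model = CouplingModel(A=A, node_labels=cfg.node_labels)
            y = forward.bold_timeseries(
                model, cfg.noise, cfg.hemo, n_volumes=cfg.n_volumes,
                tr=cfg.tr, dt=cfg.dt, seed=int(rng.integers(2 ** 31)))
            series = y[cfg.discard_initial:]
        else:
            series = np.zeros((cfg.n_retained, cfg.n_nodes))
        records.append(SubjectRecord(
            subject_id=f"sub-{k:04d}", group=group, ground_truth_A=A,
            roi_series=series, tr=cfg.tr, scores={},
            node_labels=cfg.node_labels))
    all_scores = generate_scores(records, cfg.score_models,
                                 seed=int(rng.integers(2 ** 31)))
    for rec, sc in zip(records, all_scores):
        rec.scores = sc
    return records


def write_manifest(records, path, series_dir=None) -> pd.DataFrame:
    """Write the cohort manifest TSV (and per-subject series TSVs).

    Columns: subject_id, group, mmse, cdr, series (path, stored relative
    to the manifest so runs are relocatable), tr.  When ``series_dir`` is
    given each subject's ROI series is written there as a TSV with
    ROI-label header.
    """
    import os

    base = os.path.dirname(os.path.abspath(str(path)))
    rows = []
    for rec in records:
        series_path = ""
        if series_dir is not None:
            os.makedirs(series_dir, exist_ok=True)
            abs_path = os.path.join(str(series_dir), f"{rec.subject_id}.tsv")
            pd.DataFrame(rec.roi_series, columns=list(rec.node_labels)) \
                .to_csv(abs_path, sep="\t", index=False,
                        float_format="%.10g")
            series_path = os.path.relpath(abs_path, base)
        rows.append({
            "subject_id": rec.subject_id,
            "group": rec.group,
            "mmse": rec.scores.get("mmse", np.nan),
            "cdr": rec.scores.get("cdr", np.nan),
            "series": series_path,
            "tr": rec.tr,
        })
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return df


def render_nifti(record: SubjectRecord, rois, voxel_mm: float = 4.0,
                 margin_mm: float = 12.0):
    """Paint a subject's ROI series into a synthetic 4-D NIfTI image.

    Spheres of each ROI's radius are painted on an otherwise-zero volume
    whose affine covers the ROI coordinates with ``margin_mm`` headroom;
    every voxel in a sphere carries that ROI's time course.  Intended for
    end-to-end testing of ROI extraction.
    """
    import nibabel as nib

    coords = np.asarray(rois.coordinates, dtype=float)
    lo = coords.min(axis=0) - margin_mm
    hi = coords.max(axis=0) + margin_mm
    shape = np.ceil((hi - lo) / voxel_mm).astype(int) + 1
    affine = np.diag([voxel_mm] * 3 + [1.0])
    affine[:3, 3] = lo
    n_t = record.roi_series.shape[0]
    data = np.zeros((*shape, n_t), dtype=np.float32)
    grid = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                                indexing="ij"), axis=-1)
    mm = grid * voxel_mm + lo
    for k, (c, r) in enumerate(zip(coords, np.broadcast_to(
            rois.radius_mm, (coords.shape[0],)))):
        mask = np.sum((mm - c) ** 2, axis=-1) <= r ** 2
        data[mask] = record.roi_series[:, k].astype(np.float32)
    return nib.Nifti1Image(data, affine)
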