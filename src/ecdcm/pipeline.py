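"""End-to-end pipeline: cohort -> inversion -> PEB/BMR -> group statistics.

``run_pipeline`` executes the full analysis from a ``RunConfig`` and
writes every report surface as plain-text tables: the cohort manifest,
per-subject posteriors (HDF5 + a flat TSV of connection strengths),
per-group PEB matrices in From/To/M/Var layout with posterior
probabilities, thresholded networks at each confidence level, the ANOVA
table and stepwise-regression results, plus a JSON provenance record.
Outputs contain no timestamps, so identical config + seed reproduces
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (GROUPS, CohortConfig, generate_cohort,
                     write_manifest)
from .exceptions import ConfigError, DataError, EcdcmError
from .inversion import InversionConfig, fit_cohort
from .peb import PEB, PEBConfig, threshold_network
from .roi import read_cohort_manifest
from .spectra import SpectralConfig
from .stats import anova_connections, stepwise_regression

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline", "render_reports"]

DEFAULT_THRESHOLDS = (0.0, 0.5, 0.75, 0.95, 0.99)


class PipelineStageError(EcdcmError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"stage {stage!r} failed: {original}")


@dataclass
class RunConfig:
    """Fully describes one pipeline run."""

    out_dir: str = "ecdcm-run"
    seed: int = 0
    manifest: str | None = None          # None -> synthetic cohort
    cohort: dict = field(default_factory=dict)      # CohortConfig overrides
    spectral: dict = field(default_factory=dict)    # SpectralConfig overrides
    inversion: dict = field(default_factory=dict)   # InversionConfig overrides
    peb: dict = field(default_factory=dict)         # PEBConfig overrides
    thresholds: tuple = DEFAULT_THRESHOLDS
    scores: tuple = ("mmse", "cdr")
    p_enter: float = 0.05
    p_remove: float = 0.10
    alpha: float = 0.05
    log_level: str = "INFO"

    def __post_init__(self):
        self.thresholds = tuple(float(t) for t in self.thresholds)
        if any(not 0 <= t < 1 for t in self.thresholds):
            raise ConfigError("thresholds must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        try:
            return cls(**raw)
        except TypeError as e:
            raise ConfigError(str(e)) from e

    def canonical_json(self) -> str:
        """Canonical description of the analysis (output location and
        logging excluded, so relocated runs hash identically)."""
        d = asdict(self)
        d.pop("out_dir", None)
        d.pop("log_level", None)
        return json.dumps(d, sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _build_cohort_config(cfg: RunConfig) -> CohortConfig:
    kw = dict(cfg.cohort)
    if "base_A" in kw:
        kw["base_A"] = np.asarray(kw["base_A"], dtype=float)
    kw.setdefault("seed", cfg.seed)
    return CohortConfig(**kw)


def _connection_label(labels, i, j) -> str:
    return f"{labels[j]} -> {labels[i]}"


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a run report dict (also written as JSON)."""
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    report: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                    "version": __version__}

    # ---- stage: cohort -------------------------------------------------
    try:
        if config.manifest:
            records = read_cohort_manifest(config.manifest, require_series=True)
        else:
            ccfg = _build_cohort_config(config)
            records = generate_cohort(ccfg)
            write_manifest(records, os.path.join(out, "manifest.tsv"),
                           series_dir=os.path.join(out, "series"))
        if not records:
            raise DataError("cohort is empty")
        n_nodes = records[0].roi_series.shape[1]
        labels = records[0].node_labels or tuple(
            f"node{i}" for i in range(n_nodes))
        report["n_subjects"] = len(records)
        report["groups"] = {g: sum(r.group == g for r in records)
                            for g in GROUPS}
    except Exception as e:
        raise PipelineStageError("cohort", e) from e

    # ---- stage: invert -------------------------------------------------
    try:
        inv_cfg = InversionConfig(**config.inversion)
        spec_kw = dict(config.spectral)
        spec_cfg = (SpectralConfig(**spec_kw) if spec_kw else
                    SpectralConfig(nperseg=64, smooth=3, fmin=0.008, fmax=0.1,
                                   n_freq=6))
        posteriors = fit_cohort(records, config=inv_cfg,
                                spectral_config=spec_cfg)
        os.makedirs(os.path.join(out, "posteriors"), exist_ok=True)
        conn_rows = []
        for rec, post in zip(records, posteriors):
            post.to_hdf5(os.path.join(out, "posteriors",
                                      f"{rec.subject_id}.h5"),
                         subject_id=rec.subject_id, group=rec.group)
            A = post.A_mean
            row = {"subject_id": rec.subject_id, "group": rec.group,
                   **{s: rec.scores.get(s, np.nan) for s in config.scores}}
            for i in range(n_nodes):
                for j in range(n_nodes):
                    row[_connection_label(labels, i, j)] = A[i, j]
            conn_rows.append(row)
        conn_df = pd.DataFrame(conn_rows)
        conn_df.to_csv(os.path.join(out, "subject_connections.tsv"),
                       sep="\t", index=False, float_format="%.8g")
        report["n_converged"] = int(sum(p.converged for p in posteriors))
    except PipelineStageError:
        raise
    except Exception as e:
        raise PipelineStageError("invert", e) from e

    # ---- stage: peb ----------------------------------------------------
    try:
        peb_cfg = PEBConfig(**config.peb)
        group_edges = {}
        for g in GROUPS:
            idx = [k for k, r in enumerate(records) if r.group == g]
            if not idx:
                continue
            peb = PEB([posteriors[k] for k in idx], config=peb_cfg)
            fitted = peb.fit()
            cp = fitted.search()
            rows = []
            for j in range(n_nodes):
                for i in range(n_nodes):
                    rows.append({
                        "From": labels[j], "To": labels[i],
                        "M": cp.strength_mean[i, j],
                        "Var": cp.strength_var[i, j],
                        "Pp": cp.prob[i, j]})
            pd.DataFrame(rows).to_csv(
                os.path.join(out, f"peb_{g}.tsv"), sep="\t", index=False,
                float_format="%.8g")
            edges = {}
            for level in config.thresholds:
                adj, _ = threshold_network(cp, level)
                edges[level] = int(adj.sum())
            group_edges[g] = edges
        report["edges_per_threshold"] = {
            g: {str(k): v for k, v in e.items()}
            for g, e in group_edges.items()}
    except PipelineStageError:
        raise
    except Exception as e:
        raise PipelineStageError("peb", e) from e

    # ---- stage: stats --------------------------------------------------
    try:
        conn_cols = [c for c in conn_df.columns
                     if c not in ("subject_id", "group", *config.scores)]
        strengths = conn_df[conn_cols]
        groups_arr = conn_df["group"].to_numpy()
        anova = anova_connections(strengths, groups_arr, alpha=config.alpha)
        anova.pairwise.to_csv(os.path.join(out, "anova_pairwise.tsv"),
                              sep="\t", index=False, float_format="%.6g")
        anova.summary().to_csv(os.path.join(out, "anova_f.tsv"),
                               sep="\t", index=False, float_format="%.6g")
        report["anova_significant"] = anova.significant()
        for score in config.scores:
            if score not in conn_df.columns:
                continue
            y = conn_df[score].to_numpy(dtype=float)
            sw = stepwise_regression(y, strengths, p_enter=config.p_enter,
                                     p_remove=config.p_remove)
            sw.summary().to_csv(
                os.path.join(out, f"stepwise_{score}.tsv"), sep="\t",
                index=False, float_format="%.6g")
            report[f"stepwise_{score}"] = {
                "entered": sw.entered, "r_squared": sw.r_squared,
                "f": sw.f_statistic, "p": sw.model_p_value}
            # scatter data for entered connections
            if sw.entered:
                sc = conn_df[["subject_id", score, *sw.entered]]
                sc.to_csv(os.path.join(out, f"scatter_{score}.csv"),
                          index=False, float_format="%.8g")
    except PipelineStageError:
        raise
    except Exception as e:
        raise PipelineStageError("stats", e) from e

    with open(os.path.join(out, "provenance.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    render_reports(out)
    return report


def render_reports(run_dir: str) -> None:
    """Assemble figure/table analogues from a completed run directory."""
    peb_files = {g: os.path.join(run_dir, f"peb_{g}.tsv") for g in GROUPS}
    present = {g: p for g, p in peb_files.items() if os.path.exists(p)}
    if not present:
        raise DataError(f"no PEB outputs found in {run_dir!r}")

    frames = []
    grid_rows = []
    with open(os.path.join(run_dir, "provenance.json")) as fh:
        report = json.load(fh)
    thresholds = None
    for g, path in present.items():
        df = pd.read_csv(path, sep="\t")
        df.insert(0, "group", g)
        frames.append(df)
        edges = report.get("edges_per_threshold", {}).get(g, {})
        if thresholds is None:
            thresholds = sorted(float(t) for t in edges)
        for t in sorted(edges, key=float):
            grid_rows.append({"group": g, "threshold": float(t),
                              "n_edges": edges[t]})
    all_groups = pd.concat(frames, ignore_index=True)
    all_groups[["group", "From", "To", "M", "Var"]].to_csv(
        os.path.join(run_dir, "report_group_matrices.csv"), index=False,
        float_format="%.8g")
    pd.DataFrame(grid_rows).to_csv(
        os.path.join(run_dir, "report_threshold_grid.tsv"), sep="\t",
        index=False)
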