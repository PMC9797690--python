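"""ROI time-series extraction from 4-D NIfTI volumes and cohort tables.

Regions are spheres in MNI millimetre space; a voxel belongs to a sphere
when its centre lies within the radius (inclusive).  The default ROI set
covers the seven regions of the study: bilateral PCC, ACC and dlPFC plus
mPFC, with 8 mm radii.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import GROUPS, SubjectRecord
from .exceptions import ArgumentError, DataError, ManifestError, ROIError

__all__ = ["ROISet", "DEFAULT_ROIS", "extract_roi_timeseries",
           "read_cohort_manifest"]


@dataclass
class ROISet:
    """Labelled sphere ROIs in MNI mm coordinates."""

    labels: tuple
    coordinates: np.ndarray       # (n, 3) in mm
    radius_mm: float = 8.0

    def __post_init__(self):
        self.labels = tuple(self.labels)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.labels), 3):
            raise ArgumentError("coordinates must be (n_labels, 3)")
        if self.radius_mm <= 0:
            raise ArgumentError("radius must be positive")

    @classmethod
    def from_tsv(cls, path) -> "ROISet":
        df = pd.read_csv(path, sep="\t")
        required = {"label", "x", "y", "z"}
        if not required.issubset(df.columns):
            raise DataError(f"ROI table needs columns {sorted(required)}")
        radius = float(df["radius"].iloc[0]) if "radius" in df.columns else 8.0
        return cls(labels=tuple(df["label"]),
                   coordinates=df[["x", "y", "z"]].to_numpy(float),
                   radius_mm=radius)

    @classmethod
    def from_yaml(cls, path) -> "ROISet":
        import yaml
        with open(path) as fh:
            spec = yaml.safe_load(fh)
        rois = spec["rois"] if isinstance(spec, dict) else spec
        labels = [r["label"] for r in rois]
        coords = [(r["x"], r["y"], r["z"]) for r in rois]
        radius = (spec.get("radius", 8.0) if isinstance(spec, dict) else 8.0)
        return cls(labels=tuple(labels), coordinates=np.asarray(coords),
                   radius_mm=float(radius))

    def to_tsv(self, path) -> None:
        pd.DataFrame({
            "label": self.labels,
            "x": self.coordinates[:, 0],
            "y": self.coordinates[:, 1],
            "z": self.coordinates[:, 2],
            "radius": self.radius_mm,
        }).to_csv(path, sep="\t", index=False)


#: The study's seven regions (MNI mm).
DEFAULT_ROIS = ROISet(
    labels=("L-PCC", "R-PCC", "L-ACC", "R-ACC", "L-dlPFC", "R-dlPFC", "mPFC"),
    coordinates=np.array([
        [-8.0, -49.0, 38.0],
        [8.0, -48.0, 39.0],
        [-5.0, 39.0, 20.0],
        [6.0, 33.0, 16.0],
        [-39.0, 34.0, 37.0],
        [35.0, 39.0, 31.0],
        [0.0, 53.0, -14.0],
    ]),
    radius_mm=8.0,
)


def extract_roi_timeseries(volume_4d, rois: ROISet, discard_initial: int = 0,
                           summary: str = "mean") -> np.ndarray:
    """ROI-summarised time series (time x rois) from a 4-D image.

    ``summary`` is 'mean' (voxel average) or 'eigenvariate' (first
    principal component, scaled to the average voxel variance and
    sign-aligned with the mean series).
    """
    img = volume_4d if hasattr(volume_4d, "affine") else nib.load(str(volume_4d))
    if img.affine is None:
        raise DataError("image has no affine; voxel->mm mapping unknown")
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise DataError(f"expected a 4-D image, got {data.ndim}-D")
    n_t = data.shape[3]
    if discard_initial < 0 or discard_initial >= n_t:
        raise ArgumentError("discard_initial must lie in [0, n_volumes)")
    shape = data.shape[:3]
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    mm = nib.affines.apply_affine(img.affine, vox)
    out = np.empty((n_t - discard_initial, len(rois.labels)))
    flat = data.reshape(-1, n_t)
    for k, (label, c) in enumerate(zip(rois.labels, rois.coordinates)):
        inside = np.sum((mm - c) ** 2, axis=1) <= rois.radius_mm ** 2
        if not inside.any():
            raise ROIError(f"ROI {label!r}: no voxel centre falls inside "
                           f"the {rois.radius_mm} mm sphere at {tuple(c)}")
        series = flat[inside, discard_initial:]
        if summary == "mean":
            out[:, k] = series.mean(axis=0)
        elif summary == "eigenvariate":
            centered = series - series.mean(axis=1, keepdims=True)
            _, s, vt = np.linalg.svd(centered, full_matrices=False)
            pc = vt[0] * s[0] / np.sqrt(series.shape[0])
            mean_series = series.mean(axis=0)
            if np.dot(pc, mean_series - mean_series.mean()) < 0:
                pc = -pc
            out[:, k] = pc + mean_series.mean()
        else:
            raise ArgumentError(f"unknown summary {summary!r}")
    return out


REQUIRED_COLUMNS = ("subject_id", "group", "mmse", "cdr", "series")


def read_cohort_manifest(path, require_series: bool = False):
    """Validated subject stubs from a manifest TSV.

    Raises ``ManifestError`` naming the offending line for unknown group
    labels, missing columns or unreadable series paths.
    """
    import os

    try:
        df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    except Exception as e:
        raise ManifestError(f"cannot parse manifest: {e}") from e
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"missing required column(s): {', '.join(missing)}")
    records = []
    for idx, row in df.iterrows():
        line = idx + 2  # 1-based, after the header
        group = str(row["group"])
        if group not in GROUPS:
            raise ManifestError(
                f"unknown group label {group!r} (expected one of "
                f"{', '.join(GROUPS)})", line=line)
        series_path = str(row["series"]) if pd.notna(row["series"]) else ""
        series = np.zeros((0, 0))
        tr = float(row["tr"]) if "tr" in df.columns else np.nan
        if series_path and not os.path.isabs(series_path):
            series_path = os.path.join(os.path.dirname(os.path.abspath(
                str(path))), series_path)
        if series_path:
            if not os.path.exists(series_path):
                raise ManifestError(
                    f"series file not found: {series_path}", line=line)
            sdf = pd.read_csv(series_path, sep="\t")
            series = sdf.to_numpy(dtype=float)
            labels = tuple(sdf.columns)
        elif require_series:
            raise ManifestError("series path is required but empty", line=line)
        else:
            labels = None
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]), group=group,
            ground_truth_A=None, roi_series=series, tr=tr,
            scores={"mmse": float(row["mmse"]), "cdr": float(row["cdr"])},
            node_labels=labels))
    return records
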