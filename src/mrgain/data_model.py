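"""Domain types and delimited-text I/O for regional activity tables.

The central container is :class:`ROIDataset`: one subject's activity matrix
(timepoints x regions of interest, in percent signal change) together with
parcel metadata (label, hemisphere, centroid, size) and subject metadata
(age, head motion).  All downstream modeling operates on contiguous
train / validation / test segments of the time axis, produced by
:func:`split_segments`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Hemisphere",
    "ParcelInfo",
    "SubjectMeta",
    "ROIDataset",
    "SegmentSplit",
    "to_percent_signal_change",
    "split_segments",
    "load_roi_dataset",
    "write_roi_dataset",
    "homotopic_partner",
]

#: minimum series length that still yields three non-empty segments
MIN_TIMEPOINTS = 8

#: tolerance (relative to column scale) for the zero-mean invariant of
#: percent-signal-change columns
_MEAN_TOL = 1e-5


class Hemisphere(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    NONE = "none"


@dataclass(frozen=True)
class ParcelInfo:
    """Metadata for a single region of interest (ROI).

    ``centroid`` is the parcel's center of mass in scanner millimeters and is
    used for edge-length classification in the group analysis.  ``label`` is
    shared between homotopic parcels; the hemisphere field disambiguates.
    """

    roi_id: int
    label: str
    hemisphere: Hemisphere
    centroid: tuple[float, float, float]
    voxel_count: int

    def __post_init__(self) -> None:
        if self.voxel_count <= 0:
            raise ValueError(f"voxel_count must be positive for ROI {self.label!r}")
        if len(self.centroid) != 3:
            raise ValueError(f"centroid must be a 3-vector for ROI {self.label!r}")

    @property
    def display_name(self) -> str:
        if self.hemisphere is Hemisphere.NONE:
            return self.label
        return f"{'lh' if self.hemisphere is Hemisphere.LEFT else 'rh'}_{self.label}"


@dataclass(frozen=True)
class SubjectMeta:
    """Per-subject covariates: age in years and mean inter-volume head
    displacement in millimeters (as estimated by motion correction)."""

    subject_id: str
    age: float
    head_motion: float

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError("age must be positive")
        if self.head_motion < 0:
            raise ValueError("head_motion must be non-negative")


@dataclass(frozen=True)
class SegmentSplit:
    """Contiguous half-open [start, stop) index ranges over the time axis."""

    train: tuple[int, int]
    validation: tuple[int, int]
    test: tuple[int, int]

    def __post_init__(self) -> None:
        t, v, s = self.train, self.validation, self.test
        if not (t[0] == 0 and t[1] == v[0] and v[1] == s[0] and t[0] < t[1] < v[1] < s[1]):
            raise ValueError("segments must be contiguous, ordered and non-empty")

    @property
    def n_timepoints(self) -> int:
        return self.test[1]

    @property
    def train_slice(self) -> slice:
        return slice(*self.train)

    @property
    def validation_slice(self) -> slice:
        return slice(*self.validation)

    @property
    def test_slice(self) -> slice:
        return slice(*self.test)


def split_segments(n_timepoints: int) -> SegmentSplit:
    """Partition ``[0, T)`` into training (first half), validation (third
    quarter) and test (last quarter) ranges.

    Boundaries use the floor rule: train ends at ``floor(T/2)`` and
    validation ends at ``floor(3T/4)``, so any remainder samples accrue to
    the later segments.
    """
    T = int(n_timepoints)
    if T < MIN_TIMEPOINTS:
        raise ValueError(
            f"too few timepoints to segment: T={T} < {MIN_TIMEPOINTS}"
        )
    half = T // 2
    three_q = (3 * T) // 4
    return SegmentSplit(train=(0, half), validation=(half, three_q), test=(three_q, T))


def to_percent_signal_change(raw_activity: np.ndarray) -> np.ndarray:
    """Convert raw-unit activity to percent signal change per column.

    Each column is expressed relative to its own full-series mean:
    ``100 * (x - mean) / mean``.  Output columns therefore have exactly zero
    mean.  Columns whose mean is zero (including all-zero columns and
    already zero-mean converted data) are rejected rather than re-scaled.
    """
    raw = np.asarray(raw_activity, dtype=float)
    if raw.ndim != 2:
        raise ValueError("raw_activity must be a 2-D timepoints x ROIs array")
    means = raw.mean(axis=0)
    scale = np.maximum(np.abs(raw).max(axis=0), 1.0)
    bad = np.flatnonzero(np.abs(means) <= 1e-12 * scale)
    if bad.size:
        raise ValueError(
            f"cannot convert to percent signal change: ROI column(s) {bad.tolist()} "
            "have zero mean (raw scanner units are expected to be positive)"
        )
    return 100.0 * (raw - means) / means


@dataclass
class ROIDataset:
    """One subject's activity table plus parcel and subject metadata.

    ``activity`` is timepoints x ROIs in percent signal change (zero-mean
    columns); ``tr`` is the sampling interval in seconds.
    """

    activity: np.ndarray
    parcels: list[ParcelInfo]
    meta: SubjectMeta
    tr: float = 1.94

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if self.activity.ndim != 2:
            raise ValueError("activity must be 2-D (timepoints x ROIs)")
        T, R = self.activity.shape
        if T < MIN_TIMEPOINTS:
            raise ValueError(f"too few timepoints: T={T} < {MIN_TIMEPOINTS}")
        if len(self.parcels) != R:
            raise ValueError(
                f"parcel metadata has {len(self.parcels)} rows but activity has {R} columns"
            )
        if not np.isfinite(self.activity).all():
            t, r = np.argwhere(~np.isfinite(self.activity))[0]
            raise ValueError(f"non-finite activity value at timepoint {t}, ROI column {r}")
        ids = [p.roi_id for p in self.parcels]
        if ids != list(range(R)):
            raise ValueError("parcel roi_id values must be 0..R-1 in column order")
        seen: set[tuple[str, Hemisphere]] = set()
        for p in self.parcels:
            key = (p.label, p.hemisphere)
            if key in seen:
                raise ValueError(
                    f"duplicate ROI label {p.label!r} within hemisphere {p.hemisphere.value}"
                )
            seen.add(key)
        means = self.activity.mean(axis=0)
        tol = _MEAN_TOL * np.maximum(np.abs(self.activity).max(axis=0), 1.0)
        off = np.flatnonzero(np.abs(means) > tol)
        if off.size:
            raise ValueError(
                f"activity columns {off.tolist()} are not zero-mean percent signal "
                "change; load raw data with units='raw' to convert"
            )
        if not self.tr > 0:
            raise ValueError("tr must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.activity.shape[0]

    @property
    def n_rois(self) -> int:
        return self.activity.shape[1]

    @property
    def labels(self) -> list[str]:
        return [p.display_name for p in self.parcels]

    def roi_index(self, name: str) -> int:
        """Resolve a display name ('lh_precuneus') or bare unique label."""
        names = self.labels
        if name in names:
            return names.index(name)
        bare = [i for i, p in enumerate(self.parcels) if p.label == name]
        if len(bare) == 1:
            return bare[0]
        raise KeyError(f"ROI {name!r} not found or ambiguous")

    def default_split(self) -> SegmentSplit:
        return split_segments(self.n_timepoints)


def homotopic_partner(parcels: list[ParcelInfo], roi_id: int) -> int | None:
    """Return the roi_id of the same-labeled parcel in the opposite
    hemisphere, or None when no such partner exists."""
    p = parcels[roi_id]
    if p.hemisphere is Hemisphere.NONE:
        return None
    other = Hemisphere.RIGHT if p.hemisphere is Hemisphere.LEFT else Hemisphere.LEFT
    matches = [q.roi_id for q in parcels if q.label == p.label and q.hemisphere is other]
    if not matches:
        return None
    if len(matches) > 1:
        raise ValueError(f"multiple homotopic partners for ROI {p.label!r}")
    return matches[0]


# ---------------------------------------------------------------------------
# delimited-text I/O


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def _read_table(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path))
    return df


def load_roi_dataset(
    activity_path: str | Path,
    parcel_path: str | Path,
    meta_path: str | Path,
    units: str = "raw",
    tr: float = 1.94,
) -> ROIDataset:
    """Load a subject's activity table and metadata from delimited text.

    Parameters
    ----------
    activity_path : CSV/TSV with one header row naming ROIs and one time
        sample per row; columns must match the parcel file row order.
    parcel_path : CSV with columns label, hemisphere, x_mm, y_mm, z_mm,
        voxel_count.
    meta_path : CSV with columns subject_id, age_years, head_motion_mm.
    units : 'raw' (scanner units, converted to percent signal change) or
        'percent' (already converted; columns must be zero-mean).
    """
    activity_path = Path(activity_path)
    parcel_path = Path(parcel_path)
    meta_path = Path(meta_path)
    if units not in {"raw", "percent"}:
        raise ValueError("units must be 'raw' or 'percent'")

    act = _read_table(activity_path)
    for col in act.columns:
        if not pd.api.types.is_numeric_dtype(act[col]):
            bad = act[col].map(lambda v: not isinstance(v, (int, float, np.number)))
            row = int(np.flatnonzero(bad.to_numpy())[0]) if bad.any() else 0
            raise ValueError(
                f"non-numeric activity cell at row {row}, column {col!r} in {activity_path.name}"
            )
    values = act.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        t, r = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"missing/non-finite activity value at row {int(t)}, column "
            f"{act.columns[int(r)]!r} in {activity_path.name}"
        )

    pdf = _read_table(parcel_path)
    required = ["label", "hemisphere", "x_mm", "y_mm", "z_mm", "voxel_count"]
    missing = [c for c in required if c not in pdf.columns]
    if missing:
        raise ValueError(f"parcel file {parcel_path.name} lacks columns {missing}")
    if len(pdf) != values.shape[1]:
        raise ValueError(
            f"activity table has {values.shape[1]} ROI columns but parcel file "
            f"has {len(pdf)} rows"
        )
    parcels = [
        ParcelInfo(
            roi_id=i,
            label=str(row.label),
            hemisphere=Hemisphere(str(row.hemisphere)),
            centroid=(float(row.x_mm), float(row.y_mm), float(row.z_mm)),
            voxel_count=int(row.voxel_count),
        )
        for i, row in enumerate(pdf.itertuples(index=False))
    ]

    mdf = _read_table(meta_path)
    for c in ("subject_id", "age_years", "head_motion_mm"):
        if c not in mdf.columns:
            raise ValueError(f"subject metadata file lacks column {c!r}")
    first = mdf.iloc[0]
    meta = SubjectMeta(
        subject_id=str(first["subject_id"]),
        age=float(first["age_years"]),
        head_motion=float(first["head_motion_mm"]),
    )

    if units == "raw":
        values = to_percent_signal_change(values)
    return ROIDataset(activity=values, parcels=parcels, meta=meta, tr=tr)


def write_roi_dataset(
    dataset: ROIDataset,
    out_dir: str | Path,
    activity_name: str = "activity.csv",
    parcel_name: str = "parcels.csv",
    meta_name: str = "meta.csv",
) -> dict[str, Path]:
    """Write activity (percent signal change, 6 significant digits), parcel
    and subject metadata tables to ``out_dir``; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "activity": out / activity_name,
        "parcels": out / parcel_name,
        "meta": out / meta_name,
    }
    adf = pd.DataFrame(dataset.activity, columns=dataset.labels)
    adf.to_csv(paths["activity"], index=False, float_format="%.6g", sep=_sep_for(paths["activity"]))
    pdf = pd.DataFrame(
        {
            "label": [p.label for p in dataset.parcels],
            "hemisphere": [p.hemisphere.value for p in dataset.parcels],
            "x_mm": [p.centroid[0] for p in dataset.parcels],
            "y_mm": [p.centroid[1] for p in dataset.parcels],
            "z_mm": [p.centroid[2] for p in dataset.parcels],
            "voxel_count": [p.voxel_count for p in dataset.parcels],
        }
    )
    pdf.to_csv(paths["parcels"], index=False)
    mdf = pd.DataFrame(
        {
            "subject_id": [dataset.meta.subject_id],
            "age_years": [dataset.meta.age],
            "head_motion_mm": [dataset.meta.head_motion],
        }
    )
    mdf.to_csv(paths["meta"], index=False)
    return paths
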