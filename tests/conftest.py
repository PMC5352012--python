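"""Shared fixtures: small deterministic datasets built in memory."""

import numpy as np
import pytest

from mrgain.data_model import Hemisphere, ParcelInfo, ROIDataset, SubjectMeta, split_segments


def build_dataset(activity: np.ndarray, tr: float = 1.94) -> ROIDataset:
    """Wrap an arbitrary matrix (centered per column) in an ROIDataset with
    generic parcel metadata."""
    A = np.asarray(activity, dtype=float)
    A = A - A.mean(axis=0)
    R = A.shape[1]
    half = R // 2
    parcels = []
    for i in range(R):
        if i < half:
            hemi, h = Hemisphere.LEFT, i
        elif i < 2 * half:
            hemi, h = Hemisphere.RIGHT, i - half
        else:
            hemi, h = Hemisphere.NONE, i
        parcels.append(
            ParcelInfo(
                roi_id=i,
                label=f"p{h:03d}",
                hemisphere=hemi,
                centroid=(float(10 * i), 0.0, 0.0),
                voxel_count=100,
            )
        )
    meta = SubjectMeta(subject_id="test", age=40.0, head_motion=0.1)
    return ROIDataset(activity=A, parcels=parcels, meta=meta, tr=tr)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_dataset(rng):
    """T=100, R=5 dataset where column 0 depends on columns 1 and 2."""
    T = 100
    X = rng.standard_normal((T, 5))
    X[:, 0] = 2.0 * X[:, 1] - 1.0 * X[:, 2] + 0.3 * rng.standard_normal(T)
    return build_dataset(X)


@pytest.fixture
def small_split(small_dataset):
    return split_segments(small_dataset.n_timepoints)
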