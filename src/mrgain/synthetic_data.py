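"""Ground-truth synthetic multiregional activity.

The generator emulates the statistical structure of parcellated
resting-state BOLD tables so that every pipeline stage can be tested
against a known answer: temporally autocorrelated signals (AR(1) drivers,
coefficient 0.5, roughly matching BOLD autocorrelation at a ~2 s sampling
interval), "integrator" regions formed as sparse weighted sums of several
drivers plus observation noise, one strongly coupled region pair emulating
redundant homotopic regions, and one high-amplitude-noise region emulating
low temporal signal-to-noise parcels.

Drivers are exogenous and mixed in a single shot (not a recurrent system):
this keeps the ground-truth weights identifiable and matches the
instantaneous weighted-sum model class the fitting modules assume.  It is a
deliberate simplification relative to real hemodynamics — there is no
hemodynamic convolution, physiological noise, or scanner artifact model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .data_model import Hemisphere, ParcelInfo, ROIDataset, SubjectMeta

__all__ = ["GroundTruth", "make_scenario", "simulate_dataset", "evaluate_recovery"]

#: AR(1) coefficient of driver signals
AR_COEF = 0.5
#: burn-in samples discarded before each simulated series
_BURN_IN = 100


@dataclass
class GroundTruth:
    """The dependency structure a scenario is generated from.

    ``weight_matrix[j, i]`` is the true weight of region ``j`` in the
    weighted sum that forms region ``i`` (diagonal zero).  ``driver_rois``
    are exogenous autocorrelated-noise regions; ``integrator_rois`` are the
    sparse mixtures; ``coupled_pairs`` lists (source, partner, correlation)
    triples; ``low_tsnr_rois`` are drivers rendered at larger amplitude so
    their temporal signal-to-noise ratio is poor.
    """

    n_rois: int
    weight_matrix: np.ndarray
    driver_rois: tuple[int, ...]
    integrator_rois: tuple[int, ...]
    coupled_pairs: list[tuple[int, int, float]]
    low_tsnr_rois: tuple[int, ...]
    noise_sd: np.ndarray
    seed: int
    tr: float = 1.94

    def __post_init__(self) -> None:
        W = np.asarray(self.weight_matrix, dtype=float)
        if W.shape != (self.n_rois, self.n_rois):
            raise ValueError("weight_matrix must be R x R")
        if np.any(np.diag(W) != 0.0):
            raise ValueError("weight_matrix diagonal must be zero")
        if np.any(np.asarray(self.noise_sd) < 0):
            raise ValueError("noise_sd must be non-negative")
        for a, b, r in self.coupled_pairs:
            if b in self.driver_rois:
                raise ValueError("coupled partner cannot itself be a driver")
        self.weight_matrix = W

    def true_predictors(self, target: int) -> np.ndarray:
        return np.flatnonzero(self.weight_matrix[:, target])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_rois": self.n_rois,
            "weight_matrix": self.weight_matrix.tolist(),
            "driver_rois": list(self.driver_rois),
            "integrator_rois": list(self.integrator_rois),
            "coupled_pairs": [[a, b, r] for a, b, r in self.coupled_pairs],
            "low_tsnr_rois": list(self.low_tsnr_rois),
            "noise_sd": np.asarray(self.noise_sd).tolist(),
            "seed": self.seed,
            "tr": self.tr,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            n_rois=int(d["n_rois"]),
            weight_matrix=np.asarray(d["weight_matrix"], dtype=float),
            driver_rois=tuple(d["driver_rois"]),
            integrator_rois=tuple(d["integrator_rois"]),
            coupled_pairs=[(int(a), int(b), float(r)) for a, b, r in d["coupled_pairs"]],
            low_tsnr_rois=tuple(d["low_tsnr_rois"]),
            noise_sd=np.asarray(d["noise_sd"], dtype=float),
            seed=int(d["seed"]),
            tr=float(d["tr"]),
        )


def make_scenario(
    n_rois: int = 32,
    k_predictors: int = 5,
    true_weight: float = 0.2,
    noise_sd: float | None = None,
    residual_fraction: float = 0.2,
    n_integrators: int = 6,
    coupled_r: float = 0.85,
    include_coupled_pair: bool = True,
    include_low_tsnr_roi: bool = True,
    seed: int = 0,
) -> GroundTruth:
    """Build a ground-truth dependency structure.

    Region roles (for the default 32 regions): indices 0..24 are exogenous
    drivers (24 rendered with low temporal SNR when enabled), index 25 is
    the coupled partner of driver 0 (activity correlation ``coupled_r``),
    and the last ``n_integrators`` indices are integrators, each a weighted
    sum of ``k_predictors`` distinct ordinary drivers with weight
    ``true_weight`` plus white observation noise.  When ``noise_sd`` is not
    given it is derived so the noise contributes ``residual_fraction`` of
    each integrator's variance (the irreducible model error, ~20% by
    default).  The structure (which drivers feed which integrator) is drawn
    from ``seed``; a different noise seed at simulation time changes the
    activity but not the sparsity pattern.
    """
    if k_predictors >= n_rois - 1:
        raise ValueError("k_predictors must be smaller than n_rois - 1")
    n_special = (1 if include_coupled_pair else 0)
    n_drivers = n_rois - n_integrators - n_special
    if n_drivers <= k_predictors:
        raise ValueError("infeasible configuration: not enough driver regions")
    if not 0.0 < residual_fraction < 1.0:
        raise ValueError("residual_fraction must lie in (0, 1)")

    rng = np.random.default_rng(seed)
    drivers = tuple(range(n_drivers))
    low_tsnr = (n_drivers - 1,) if include_low_tsnr_roi else ()
    # predictors are drawn from the ordinary drivers only
    pool = [d for d in drivers if d not in low_tsnr]
    coupled: list[tuple[int, int, float]] = []
    next_id = n_drivers
    if include_coupled_pair:
        coupled = [(0, next_id, float(coupled_r))]
        next_id += 1
    integrators = tuple(range(next_id, n_rois))

    if noise_sd is None:
        # white noise making up residual_fraction of the integrator variance
        signal_var = k_predictors * true_weight**2
        noise_sd = float(np.sqrt(signal_var * residual_fraction / (1.0 - residual_fraction)))

    W = np.zeros((n_rois, n_rois))
    sd = np.zeros(n_rois)
    for i in integrators:
        chosen = rng.choice(pool, size=k_predictors, replace=False)
        W[np.sort(chosen), i] = true_weight
        sd[i] = noise_sd
    for a, b, r in coupled:
        W[a, b] = r
        sd[b] = float(np.sqrt(1.0 - r**2))
    return GroundTruth(
        n_rois=n_rois,
        weight_matrix=W,
        driver_rois=drivers,
        integrator_rois=integrators,
        coupled_pairs=coupled,
        low_tsnr_rois=low_tsnr,
        noise_sd=sd,
        seed=int(seed),
    )


def _ar1(rng: np.random.Generator, T: int) -> np.ndarray:
    """Unit-variance, zero-mean AR(1) series (empirically standardized)."""
    e = rng.standard_normal(T + _BURN_IN)
    x = lfilter([1.0], [1.0, -AR_COEF], e)[_BURN_IN:]
    x = x - x.mean()
    return x / x.std()


def _fabricated_parcels(n_rois: int) -> list[ParcelInfo]:
    """Deterministic parcel metadata with homotopic pairs and centroids on
    a lattice spanning both short (< 50 mm) and long (> 50 mm) distances."""
    half = n_rois // 2
    parcels = []
    for i in range(n_rois):
        if i < half:
            hemi, h = Hemisphere.LEFT, i
        elif i < 2 * half:
            hemi, h = Hemisphere.RIGHT, i - half
        else:  # odd count: a final midline parcel
            hemi, h = Hemisphere.NONE, i
        label = f"roi_{h:03d}"
        x = {Hemisphere.LEFT: -30.0, Hemisphere.RIGHT: 30.0, Hemisphere.NONE: 0.0}[hemi]
        y = (h % 4) * 18.0 - 27.0
        z = (h // 4) * 18.0 - 27.0
        parcels.append(
            ParcelInfo(
                roi_id=i,
                label=label,
                hemisphere=hemi,
                centroid=(x, y, z),
                voxel_count=60 + 7 * (i % 13),
            )
        )
    return parcels


def simulate_dataset(
    gt: GroundTruth,
    T: int = 660,
    noise_seed: int | None = None,
    subject_id: str | None = None,
) -> ROIDataset:
    """Render one subject's activity table from a ground truth.

    Driver columns are unit-variance AR(1) series (low-tSNR drivers are
    scaled up so their variance dominates their mean magnitude); integrator
    columns are the ground-truth weighted sums of driver columns plus white
    noise; coupled partners mix their source with independent AR(1) noise
    to hit the requested correlation in expectation.  Columns are exactly
    zero-mean, in the percent-signal-change convention (amplitudes of order
    0.5-1%).  Deterministic given ``(gt.seed, noise_seed)``.
    """
    if T < 8:
        raise ValueError("too few timepoints to segment")
    seed = gt.seed if noise_seed is None else int(noise_seed)
    rng = np.random.default_rng(seed)
    R = gt.n_rois
    A = np.zeros((T, R))
    low_scale = 2.5  # amplitude factor rendering low-tSNR drivers noisy
    for d in gt.driver_rois:
        A[:, d] = _ar1(rng, T)
        if d in gt.low_tsnr_rois:
            A[:, d] *= low_scale
    for a, b, r in gt.coupled_pairs:
        A[:, b] = r * A[:, a] + np.sqrt(1.0 - r**2) * _ar1(rng, T)
    for i in gt.integrator_rois:
        A[:, i] = A @ gt.weight_matrix[:, i] + gt.noise_sd[i] * rng.standard_normal(T)
    A -= A.mean(axis=0)

    meta_rng = np.random.default_rng(seed + 10_007)
    meta = SubjectMeta(
        subject_id=subject_id or f"sim-{seed:06d}",
        age=float(np.round(meta_rng.uniform(18.0, 77.0), 1)),
        head_motion=float(np.round(meta_rng.uniform(0.03, 0.30), 3)),
    )
    return ROIDataset(activity=A, parcels=_fabricated_parcels(R), meta=meta, tr=gt.tr)


def evaluate_recovery(selected, gt: GroundTruth, target: int) -> tuple[float, float, float]:
    """Set-overlap of a selected predictor set against the ground truth.

    Returns (precision, recall, Jaccard index) of ``selected`` versus the
    nonzero entries of the target's true weight column.
    """
    truth = set(int(j) for j in gt.true_predictors(target))
    if not truth:
        raise ValueError(f"target ROI {target} has no true predictors")
    sel = set(int(j) for j in selected)
    inter = len(truth & sel)
    precision = inter / len(sel) if sel else 0.0
    recall = inter / len(truth)
    union = len(truth | sel)
    jaccard = inter / union if union else 0.0
    return float(precision), float(recall), float(jaccard)
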