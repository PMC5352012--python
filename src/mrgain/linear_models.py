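"""Linear models of one ROI's activity as a weighted sum of other ROIs.

The model class is intercept-free: ``y_i[t] = sum_j w_{j,i} x_j[t]`` where
the sum runs over predictor ROIs (never the modeled ROI itself).  Fitting
always happens on the training segment; model selection (regularization
level, predictor subset) is by prediction error on the validation segment.

Numerical conventions
---------------------
Before fitting, every column is centered by its *training-segment* mean and
predictors are scaled to unit training-segment standard deviation.  The
returned weights are rescaled back to the percent-signal-change scale, and
the centering offsets are stored on the model so that predictions on the
validation/test segments apply the same offsets.  Standardization makes the
"smallest weight" elimination criterion of the backward-selection loop
scale-invariant; centering guards against slow drift between segments.

Lasso and elastic-net paths are solved by cyclic coordinate descent
(scikit-learn's path solvers), which is deterministic for fixed input.
The penalty is parameterized as ``mean((y - x)^2) + c * P(w)`` with
``P(w) = |w|_1`` for the Lasso and
``P(w) = mix * |w|_1 + (1 - mix)/2 * |w|_2^2`` for the elastic net; this
maps exactly onto the solver's ``alpha = c / 2`` and ``l1_ratio = mix``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import enet_path, lasso_path

from .data_model import ROIDataset, SegmentSplit
from .metrics import prediction_error

__all__ = [
    "LinearROIModel",
    "FitConfig",
    "fit_ols",
    "fit_single_best_predictor",
    "fit_lasso_path",
    "fit_elastic_net_grid",
    "lasso_candidates",
    "elastic_net_candidates",
    "predict",
    "validation_error",
]


@dataclass
class LinearROIModel:
    """A fitted intercept-free linear model for one target ROI.

    ``weights`` are on the percent-signal-change scale, aligned with
    ``predictors`` (roi_id indices).  ``predictor_offsets`` /
    ``target_offset`` hold the training-segment means subtracted during
    fitting (zero for hand-constructed models).  ``weights_std`` are the
    weights on the standardized scale used for elimination decisions.
    """

    target_roi: int
    predictors: np.ndarray
    weights: np.ndarray
    fit_method: str
    fit_segment: str = "train"
    predictor_offsets: np.ndarray | None = None
    target_offset: float = 0.0
    weights_std: np.ndarray | None = None
    validation_error: float | None = None
    penalty: float | None = None
    l1_mix: float | None = None

    def __post_init__(self) -> None:
        self.predictors = np.asarray(self.predictors, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.predictors.size < 1:
            raise ValueError("a model needs at least one predictor")
        if self.predictors.size != self.weights.size:
            raise ValueError("weights must align with predictors")
        if self.target_roi in self.predictors:
            raise ValueError("the modeled ROI may not predict itself")
        if np.unique(self.predictors).size != self.predictors.size:
            raise ValueError("duplicate predictor roi_id")

    @property
    def n_predictors(self) -> int:
        return int(self.predictors.size)

    def nonzero(self) -> "LinearROIModel":
        """Drop zero-weight predictors (keeps at least the model valid)."""
        keep = np.flatnonzero(self.weights != 0.0)
        if keep.size == 0:
            raise ValueError("all weights are zero; no informative predictor")
        return LinearROIModel(
            target_roi=self.target_roi,
            predictors=self.predictors[keep],
            weights=self.weights[keep],
            fit_method=self.fit_method,
            fit_segment=self.fit_segment,
            predictor_offsets=None
            if self.predictor_offsets is None
            else self.predictor_offsets[keep],
            target_offset=self.target_offset,
            weights_std=None if self.weights_std is None else self.weights_std[keep],
            validation_error=self.validation_error,
            penalty=self.penalty,
            l1_mix=self.l1_mix,
        )


@dataclass
class FitConfig:
    """Grids and solver settings for regularized fits.

    The Lasso path uses ``n_lasso_lambdas`` log-spaced penalty magnitudes
    from the smallest all-zero penalty ``c_max`` down to
    ``c_max * lambda_min_ratio``; the elastic net evaluates
    ``n_enet_lambdas`` magnitudes for each L1/L2 mixing value in
    ``enet_mixes`` (250 candidates with the defaults).
    """

    n_lasso_lambdas: int = 200
    n_enet_lambdas: int = 50
    enet_mixes: tuple[float, ...] = (0.01, 0.05, 0.1, 0.5, 1.0)
    lambda_min_ratio: float = 1e-4
    tol: float = 1e-9
    max_iter: int = 100_000

    def __post_init__(self) -> None:
        if self.n_lasso_lambdas < 1 or self.n_enet_lambdas < 1:
            raise ValueError("regularization grids must be non-empty")
        if not all(0.0 < m <= 1.0 for m in self.enet_mixes):
            raise ValueError("enet_mixes must lie in (0, 1]")
        if not 0.0 < self.lambda_min_ratio < 1.0:
            raise ValueError("lambda_min_ratio must lie in (0, 1)")


def _as_slice(segment) -> slice:
    if isinstance(segment, slice):
        return segment
    start, stop = segment
    return slice(int(start), int(stop))


def predict(model: LinearROIModel, dataset: ROIDataset, segment) -> np.ndarray:
    """Evaluate the weighted sum over the segment's rows.

    ``segment`` is a half-open (start, stop) pair or slice over time
    indices.  Centering offsets stored on the model are applied; for models
    without offsets this is the plain weighted sum of predictor columns.
    """
    sl = _as_slice(segment)
    if np.any(model.predictors >= dataset.n_rois) or np.any(model.predictors < 0):
        raise KeyError("model predictor roi_id absent from dataset")
    X = dataset.activity[sl][:, model.predictors]
    if model.predictor_offsets is not None:
        X = X - model.predictor_offsets
    return X @ model.weights + model.target_offset


def validation_error(model: LinearROIModel, dataset: ROIDataset, split: SegmentSplit) -> float:
    """Prediction error (% of activity variance) on the validation segment."""
    obs = dataset.activity[split.validation_slice, model.target_roi]
    return prediction_error(obs, predict(model, dataset, split.validation))


def _training_design(
    dataset: ROIDataset,
    split: SegmentSplit,
    target: int,
    predictors,
):
    """Centered / standardized training design and the scaling bookkeeping."""
    preds = np.asarray(predictors, dtype=int)
    if preds.size == 0:
        raise ValueError("empty predictor list")
    if target in preds:
        raise ValueError("target ROI cannot be its own predictor")
    tr = split.train_slice
    X = dataset.activity[tr][:, preds]
    y = dataset.activity[tr, target]
    mu_x = X.mean(axis=0)
    mu_y = float(y.mean())
    sd_x = X.std(axis=0)
    const = np.flatnonzero(sd_x == 0.0)
    if const.size:
        raise ValueError(
            f"constant training-segment column(s) for predictor ROI(s) "
            f"{preds[const].tolist()}"
        )
    Xs = (X - mu_x) / sd_x
    yc = y - mu_y
    return preds, Xs, yc, mu_x, mu_y, sd_x


def _assemble(
    target: int,
    preds: np.ndarray,
    w_std: np.ndarray,
    mu_x: np.ndarray,
    mu_y: float,
    sd_x: np.ndarray,
    fit_method: str,
    **extra,
) -> LinearROIModel:
    return LinearROIModel(
        target_roi=target,
        predictors=preds,
        weights=w_std / sd_x,
        fit_method=fit_method,
        predictor_offsets=mu_x.copy(),
        target_offset=mu_y,
        weights_std=np.asarray(w_std, dtype=float),
        **extra,
    )


def fit_ols(
    dataset: ROIDataset,
    split: SegmentSplit,
    target: int,
    predictors,
) -> LinearROIModel:
    """Ordinary least squares on the training segment.

    Minimizes the training sum of squared residuals of the intercept-free
    model (after centering).  When there are more predictors than training
    rows the minimum-norm solution is returned with a warning.
    """
    preds, Xs, yc, mu_x, mu_y, sd_x = _training_design(dataset, split, target, predictors)
    if Xs.shape[0] < Xs.shape[1]:
        warnings.warn(
            f"underdetermined OLS for target ROI {target}: {Xs.shape[1]} predictors, "
            f"{Xs.shape[0]} training rows; returning the minimum-norm solution",
            stacklevel=2,
        )
    w_std, *_ = np.linalg.lstsq(Xs, yc, rcond=None)
    return _assemble(target, preds, w_std, mu_x, mu_y, sd_x, "ols")


def fit_single_best_predictor(
    dataset: ROIDataset,
    split: SegmentSplit,
    target: int,
) -> LinearROIModel:
    """OLS model using only the predictor ROI most correlated (in absolute
    Pearson correlation, on the training segment) with the target.

    Exact correlation ties break toward the lowest roi_id.
    """
    if dataset.n_rois < 2:
        raise ValueError("need at least two ROIs")
    tr = split.train_slice
    A = dataset.activity[tr]
    y = A[:, target]
    sy = y.std()
    candidates = np.array([j for j in range(dataset.n_rois) if j != target])
    sx = A[:, candidates].std(axis=0)
    ok = sx > 0
    if sy == 0 or not ok.any():
        raise ValueError("all candidate training correlations are undefined")
    yc = y - y.mean()
    Xc = A[:, candidates] - A[:, candidates].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (Xc.T @ yc) / (len(y) * sx * sy)
    corr[~ok] = 0.0
    corr[~np.isfinite(corr)] = 0.0
    best = candidates[int(np.argmax(np.abs(corr)))]
    model = fit_ols(dataset, split, target, [best])
    model.fit_method = "single_predictor"
    return model


def _lambda_grid(Xs: np.ndarray, yc: np.ndarray, n: int, min_ratio: float, mix: float = 1.0):
    """Log-spaced penalty magnitudes from the smallest all-zero penalty down.

    ``c_max = 2 * max|X'y| / (n_train * mix)`` is the smallest c at which the
    L1 part alone forces every weight to zero.
    """
    c_max = 2.0 * np.max(np.abs(Xs.T @ yc)) / (Xs.shape[0] * mix)
    if c_max <= 0:
        raise ValueError("target is uncorrelated with every predictor on training data")
    return np.geomspace(c_max, c_max * min_ratio, n)


def lasso_candidates(
    dataset: ROIDataset,
    split: SegmentSplit,
    target: int,
    config: FitConfig | None = None,
    predictors=None,
) -> list[LinearROIModel]:
    """All Lasso-path candidate models over the penalty grid, each with its
    validation error attached.  Zero weights are retained so candidates stay
    aligned with the full predictor set (useful for optimality checks)."""
    config = config or FitConfig()
    if predictors is None:
        predictors = [j for j in range(dataset.n_rois) if j != target]
    preds, Xs, yc, mu_x, mu_y, sd_x = _training_design(dataset, split, target, predictors)
    cs = _lambda_grid(Xs, yc, config.n_lasso_lambdas, config.lambda_min_ratio)
    alphas, coefs, _ = lasso_path(
        Xs, yc, alphas=cs / 2.0, tol=config.tol, max_iter=config.max_iter
    )
    out = []
    for k in range(len(alphas)):
        m = _assemble(
            target, preds, coefs[:, k], mu_x, mu_y, sd_x, "lasso",
            penalty=float(2.0 * alphas[k]),
        )
        m.validation_error = validation_error(m, dataset, split)
        out.append(m)
    return out


def elastic_net_candidates(
    dataset: ROIDataset,
    split: SegmentSplit,
    target: int,
    config: FitConfig | None = None,
    predictors=None,
) -> list[LinearROIModel]:
    """All elastic-net candidates over the (penalty magnitude, L1/L2 mix)
    grid, with validation errors attached."""
    config = config or FitConfig()
    if predictors is None:
        predictors = [j for j in range(dataset.n_rois) if j != target]
    preds, Xs, yc, mu_x, mu_y, sd_x = _training_design(dataset, split, target, predictors)
    out = []
    for mix in config.enet_mixes:
        cs = _lambda_grid(Xs, yc, config.n_enet_lambdas, config.lambda_min_ratio, mix=mix)
        alphas, coefs, _ = enet_path(
            Xs,
            yc,
            l1_ratio=mix,
            alphas=cs / 2.0,
            tol=config.tol,
            max_iter=config.max_iter,
        )
        for k in range(len(alphas)):
            m = _assemble(
                target, preds, coefs[:, k], mu_x, mu_y, sd_x, "elastic_net",
                penalty=float(2.0 * alphas[k]), l1_mix=float(mix),
            )
            m.validation_error = validation_error(m, dataset, split)
            out.append(m)
    return out


def _select_by_validation(candidates: list[LinearROIModel]) -> LinearROIModel:
    """Minimal validation error; ties prefer fewer nonzero predictors, then
    a larger penalty (parsimony first)."""
    def key(m: LinearROIModel):
        nnz = int(np.count_nonzero(m.weights))
        return (m.validation_error, nnz, -(m.penalty or 0.0))

    best = min(candidates, key=key)
    if not np.count_nonzero(best.weights):
        raise ValueError(
            "model selection returned the empty model: no informative predictor "
            "at any regularization level"
        )
    return best.nonzero()


def fit_lasso_path(
    dataset: ROIDataset,
    split: SegmentSplit,
    target: int,
    config: FitConfig | None = None,
    predictors=None,
) -> LinearROIModel:
    """L1-regularized fit over the penalty grid; the candidate with the
    smallest validation error is returned with its zero-weight predictors
    dropped."""
    return _select_by_validation(lasso_candidates(dataset, split, target, config, predictors))


def fit_elastic_net_grid(
    dataset: ROIDataset,
    split: SegmentSplit,
    target: int,
    config: FitConfig | None = None,
    predictors=None,
) -> LinearROIModel:
    """L1+L2-regularized fit over the two-parameter grid; selection as for
    the Lasso path."""
    return _select_by_validation(
        elastic_net_candidates(dataset, split, target, config, predictors)
    )
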