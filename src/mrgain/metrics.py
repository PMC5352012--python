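"""Prediction error, permutation null models, multiregional prediction gain
and temporal signal-to-noise ratio.

Prediction error is always reported in percent of the observed activity
variance: the mean squared difference between predicted and observed series,
divided by the mean squared deviation of the observed series from its own
segment mean.  Predicting the segment mean therefore scores exactly 100%
("chance level"); a perfect prediction scores 0%.  Averages use the
population convention (divide by n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "prediction_error",
    "tsnr",
    "NullDistribution",
    "null_model_errors",
    "GainResult",
    "multiregional_prediction_gain",
]


def prediction_error(observed, predicted) -> float:
    """Normalized prediction error in % of activity variance.

    ``100 * mean((y - x)^2) / mean((x - mean(x))^2)`` where ``x`` is the
    observed and ``y`` the predicted series over the same segment.
    """
    x = np.asarray(observed, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("observed and predicted must be 1-D series of equal length")
    if x.size < 2:
        raise ValueError("need at least two timepoints")
    power = np.mean((x - x.mean()) ** 2)
    if power == 0.0:
        raise ValueError("observed series is constant; prediction error undefined")
    return float(100.0 * np.mean((y - x) ** 2) / power)


def tsnr(series) -> float:
    """Temporal signal-to-noise ratio: mean absolute percent signal change
    divided by the (population) variance of the series."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("series must be 1-D with at least two timepoints")
    var = np.mean((x - x.mean()) ** 2)
    if var == 0.0:
        raise ValueError("constant series has undefined tSNR")
    return float(np.mean(np.abs(x)) / var)


@dataclass
class NullDistribution:
    """Test-segment errors of weight-reordered null models.

    Each permutation reassigns the fitted weights to the model's own
    predictors uniformly at random; the p-value uses the add-one estimator
    ``(1 + #{permuted <= observed}) / (n_perm + 1)``, so that a well-fitting
    model (observed error below every null error) scores the smallest
    attainable p rather than zero.
    """

    permuted_errors: np.ndarray
    observed_error: float
    p_value: float
    n_perm: int
    seed: int


def null_model_errors(
    model,
    dataset,
    split,
    n_perm: int = 500,
    seed: int = 0,
) -> NullDistribution:
    """Test-segment error distribution under random weight reordering."""
    from .linear_models import predict

    if model.n_predictors < 1:
        raise ValueError("model has no predictors")
    sl = split.test_slice
    obs = dataset.activity[sl, model.target_roi]
    observed_error = prediction_error(obs, predict(model, dataset, split.test))

    X = dataset.activity[sl][:, model.predictors]
    if model.predictor_offsets is not None:
        X = X - model.predictor_offsets
    power = np.mean((obs - obs.mean()) ** 2)
    rng = np.random.default_rng(seed)
    errs = np.empty(n_perm)
    for k in range(n_perm):
        w = model.weights[rng.permutation(model.n_predictors)]
        pred = X @ w + model.target_offset
        errs[k] = 100.0 * np.mean((pred - obs) ** 2) / power
    p = (1.0 + np.count_nonzero(errs <= observed_error)) / (n_perm + 1.0)
    return NullDistribution(
        permuted_errors=errs,
        observed_error=float(observed_error),
        p_value=float(p),
        n_perm=int(n_perm),
        seed=int(seed),
    )


@dataclass
class GainResult:
    """Multiregional prediction gain for one target ROI.

    ``gain = error_single - error_multi`` on the test segment: how much the
    multi-predictor model improves on the best single correlated predictor.
    A large gain marks a region whose activity is uniquely explained only by
    combining several regions; a small gain marks redundancy with one
    strongly coupled partner.
    """

    target_roi: int
    error_multi: float
    error_single: float
    gain: float
    p_value: float
    single_predictor: int


def multiregional_prediction_gain(
    dataset,
    split,
    target: int,
    multi_model,
    single_model,
) -> GainResult:
    """Gain of the multi-predictor model over the single-predictor model.

    Both errors are evaluated on the held-out test segment.  Significance is
    a paired t-test over the per-timepoint squared errors of the two models
    (the two error series share timepoints).
    """
    from .linear_models import predict

    if multi_model.target_roi != target or single_model.target_roi != target:
        raise ValueError("both models must target the same ROI")
    obs = dataset.activity[split.test_slice, target]
    pred_multi = predict(multi_model, dataset, split.test)
    pred_single = predict(single_model, dataset, split.test)
    err_multi = prediction_error(obs, pred_multi)
    err_single = prediction_error(obs, pred_single)
    se_multi = (pred_multi - obs) ** 2
    se_single = (pred_single - obs) ** 2
    diff = se_single - se_multi
    if np.allclose(diff, 0.0, atol=1e-15 * max(1.0, np.abs(se_multi).max())):
        p = 1.0
    else:
        p = float(stats.ttest_rel(se_single, se_multi).pvalue)
    return GainResult(
        target_roi=int(target),
        error_multi=float(err_multi),
        error_single=float(err_single),
        gain=float(err_single - err_multi),
        p_value=p,
        single_predictor=int(single_model.predictors[0]),
    )
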