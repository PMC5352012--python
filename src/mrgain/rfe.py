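"""Recursive feature elimination over whole-brain predictor sets.

Starting from all candidate predictors, the loop repeatedly fits the target
ROI by ordinary least squares, records the validation-segment error, and
removes the predictor with the smallest absolute standardized weight, until
a single predictor remains.  Two rules turn the resulting trace into a
final model:

* ``select_final_rfe`` (the primary, most parsimonious rule) keeps only the
  predictors whose elimination *raised the smallest validation error seen in
  all later iterations* — i.e. step ``t``'s eliminated predictor is kept iff
  ``v_t < min_{s > t} v_s`` — plus the final surviving predictor, and refits
  that set on the training segment.
* ``select_final_rfe2`` returns the already-fitted model at the minimum of
  the validation-error curve.

The kept set of the first rule is always a subset of the second rule's
predictor set: a kept elimination can only occur at or after the global
minimum of the curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import ROIDataset, SegmentSplit
from .linear_models import LinearROIModel, fit_ols, validation_error

__all__ = [
    "RFEStep",
    "RFETrace",
    "run_rfe",
    "select_final_rfe",
    "select_final_rfe2",
    "fit_simple_regression",
    "kept_elimination_steps",
    "min_error_step",
]


@dataclass(frozen=True)
class RFEStep:
    model: LinearROIModel
    validation_error: float

    @property
    def predictors(self) -> np.ndarray:
        return self.model.predictors


@dataclass
class RFETrace:
    """The ordered sequence of models produced by the elimination loop.

    ``steps[t]`` holds the model with ``(R - 1) - t`` predictors and its
    validation error; ``eliminated[t]`` is the predictor removed *after*
    step ``t`` (the final one-predictor step removes nothing).
    """

    target_roi: int
    steps: list[RFEStep]
    eliminated: list[int]

    def __post_init__(self) -> None:
        if len(self.eliminated) != len(self.steps) - 1:
            raise ValueError("need exactly one elimination between consecutive steps")

    @property
    def validation_errors(self) -> np.ndarray:
        return np.array([s.validation_error for s in self.steps])

    @property
    def survivor(self) -> int:
        return int(self.steps[-1].model.predictors[0])


def run_rfe(
    dataset: ROIDataset,
    split: SegmentSplit,
    target: int,
    predictors=None,
) -> RFETrace:
    """Backward elimination from the full predictor set down to one.

    At each step the predictor with the smallest absolute weight on the
    standardized scale is removed (ties break toward the lowest roi_id,
    which the ascending predictor ordering guarantees).
    """
    if predictors is None:
        predictors = [j for j in range(dataset.n_rois) if j != target]
    current = sorted(int(p) for p in predictors)
    if len(current) < 2:
        raise ValueError("recursive elimination needs at least two initial predictors")

    steps: list[RFEStep] = []
    eliminated: list[int] = []
    while True:
        model = fit_ols(dataset, split, target, current)
        steps.append(RFEStep(model=model, validation_error=validation_error(model, dataset, split)))
        if len(current) == 1:
            break
        drop = int(np.argmin(np.abs(model.weights_std)))
        eliminated.append(current[drop])
        current = current[:drop] + current[drop + 1 :]
    return RFETrace(target_roi=int(target), steps=steps, eliminated=eliminated)


def kept_elimination_steps(validation_errors) -> list[int]:
    """Steps whose elimination strictly raised the suffix minimum.

    Step ``t`` (which eliminated one predictor) is kept iff
    ``v_t < min(v_{t+1}, ..., v_last)``.  The final step performs no
    elimination and is never indexed here.
    """
    v = np.asarray(validation_errors, dtype=float)
    if v.ndim != 1 or v.size < 1:
        raise ValueError("validation_errors must be a non-empty 1-D sequence")
    kept = []
    suffix_min = np.inf
    for t in range(v.size - 2, -1, -1):
        suffix_min = min(suffix_min, v[t + 1])
        if v[t] < suffix_min:
            kept.append(t)
    kept.reverse()
    return kept


def min_error_step(validation_errors) -> int:
    """Index of the minimal validation error; ties break toward the latest
    step, i.e. the model with fewest predictors."""
    v = np.asarray(validation_errors, dtype=float)
    return int(v.size - 1 - np.argmin(v[::-1]))


def select_final_rfe(
    trace: RFETrace,
    dataset: ROIDataset,
    split: SegmentSplit,
) -> LinearROIModel:
    """Primary final-model rule: keep the predictors whose elimination
    raised the smallest later validation error, plus the survivor, and refit
    that set by OLS on the training segment."""
    v = trace.validation_errors
    kept = {trace.eliminated[t] for t in kept_elimination_steps(v)}
    kept.add(trace.survivor)
    model = fit_ols(dataset, split, trace.target_roi, sorted(kept))
    model.fit_method = "rfe"
    model.validation_error = validation_error(model, dataset, split)
    return model


def select_final_rfe2(trace: RFETrace) -> LinearROIModel:
    """Alternative rule: the stored model at the minimum of the
    validation-error curve, without refitting."""
    model = trace.steps[min_error_step(trace.validation_errors)].model
    model.fit_method = "rfe2"
    model.validation_error = float(trace.validation_errors[min_error_step(trace.validation_errors)])
    return model


def fit_simple_regression(
    dataset: ROIDataset,
    split: SegmentSplit,
    target: int,
) -> LinearROIModel:
    """Baseline with no selection: OLS on every other ROI as predictor."""
    if dataset.n_rois < 2:
        raise ValueError("need at least two ROIs")
    predictors = [j for j in range(dataset.n_rois) if j != target]
    model = fit_ols(dataset, split, target, predictors)
    model.fit_method = "simple"
    model.validation_error = validation_error(model, dataset, split)
    return model
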