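"""Group-level aggregation across subjects.

Covers bootstrap means with percentile confidence intervals, the
identification of key predictor ROIs from normalized weights, the
classification of integration-network edges by centroid distance and
hemisphere, a weight-versus-correlation sanity check, and partial
correlations of per-subject measures with age while controlling for head
motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import Hemisphere, ParcelInfo

__all__ = [
    "normalize_weights",
    "bootstrap_mean_ci",
    "KeyPredictorResult",
    "identify_key_predictors",
    "IntegrationEdge",
    "classify_dependencies",
    "weight_correlation_check",
    "partial_correlation_controlling_motion",
]

#: centroid distance (mm) separating short- from long-range dependencies
LONG_RANGE_MM = 50.0

#: bootstrap-mean gain (% of activity variance) above which a target ROI is
#: treated as an integrator when assembling group networks
INTEGRATOR_GAIN_PCT = 13.0


def normalize_weights(model) -> np.ndarray:
    """Express a model's weights as % of the total absolute weight onto the
    modeled ROI: ``100 * |w_j| / sum_k |w_k|``.  Entries sum to 100."""
    w = np.abs(np.asarray(model.weights, dtype=float))
    total = w.sum()
    if total == 0.0:
        raise ValueError("all-zero weight vector cannot be normalized")
    return 100.0 * w / total


def bootstrap_mean_ci(
    values,
    n_boot: int = 500,
    seed: int = 0,
    ci: float = 95.0,
) -> tuple[float, tuple[float, float]]:
    """Bootstrap estimate of the mean with a percentile confidence interval.

    Resamples the values with replacement ``n_boot`` times; returns the mean
    of the bootstrap means and the (2.5, 97.5) percentile interval (for the
    default 95% level).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("values must be a non-empty 1-D vector")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    means = x[idx].mean(axis=1)
    lo, hi = np.percentile(means, [(100 - ci) / 2, 100 - (100 - ci) / 2])
    return float(means.mean()), (float(lo), float(hi))


@dataclass
class KeyPredictorResult:
    """Group-level evidence that one predictor carries significantly more
    normalized weight onto a target than weight-reordered null models do."""

    target_roi: int
    predictor_roi: int
    mean_weight_pct: float
    null_mean_weight_pct: float
    ci95: tuple[float, float]
    p_raw: float
    p_corrected: float
    is_key: bool


def identify_key_predictors(
    models,
    pool_size: int | None = None,
    candidates=None,
    n_comparisons: int | None = None,
    alpha: float = 0.05,
    n_boot: int = 500,
    seed: int = 0,
) -> list[KeyPredictorResult]:
    """Across-subject test for key predictor ROIs of one target.

    For every candidate predictor (by default the union of predictors over
    the subjects' models; a predictor absent from a subject's model
    contributes weight 0 for that subject), the per-subject normalized
    weight is compared against its value under null models that reassign
    the model's weight multiset uniformly across the ``pool_size`` candidate
    predictor slots (every ROI that could have predicted the target —
    normally R - 1; defaults to the number of candidates considered).  The
    null preserves how much total weight a model carries but randomizes
    which regions receive it, so averaged over reassignments every slot's
    null normalized weight is exactly ``100 / pool_size``.  The test is a
    paired t-test of observed versus null weights across subjects.  Raw
    p-values are Bonferroni-corrected by ``n_comparisons`` (default: the
    number of candidates) and capped at 1; a predictor is key when its
    corrected p falls below ``alpha`` and its mean observed weight exceeds
    the null mean.
    """
    models = list(models)
    if len(models) < 2:
        raise ValueError("need at least two subjects")
    target = models[0].target_roi
    if any(m.target_roi != target for m in models):
        raise ValueError("all models must share the same target ROI")

    if candidates is None:
        cand = sorted({int(p) for m in models for p in m.predictors})
    else:
        cand = sorted(int(c) for c in candidates)
    if not cand:
        raise ValueError("no candidate predictors")
    if pool_size is None:
        pool_size = len(cand)
    if pool_size < max(m.n_predictors for m in models):
        raise ValueError("pool_size smaller than a model's predictor count")
    col = {c: j for j, c in enumerate(cand)}

    S, C = len(models), len(cand)
    obs = np.zeros((S, C))
    null = np.full((S, C), 100.0 / pool_size)
    for s, m in enumerate(models):
        nw = normalize_weights(m)
        for p, w in zip(m.predictors, nw):
            j = col.get(int(p))
            if j is not None:
                obs[s, j] = w

    n_comp = n_comparisons if n_comparisons is not None else C
    results = []
    for j, c in enumerate(cand):
        # sorted values make the paired test (whose null side is constant
        # per candidate) exactly invariant to subject ordering
        o = np.sort(obs[:, j])
        d = o - null[:, j]
        if np.allclose(d, 0.0, atol=1e-12):
            p_raw = 1.0
        elif np.ptp(d) == 0.0:
            # constant nonzero difference: degenerate, maximally significant
            p_raw = 0.0
        else:
            p_raw = float(stats.ttest_rel(o, null[:, j]).pvalue)
        p_corr = min(1.0, p_raw * n_comp)
        # sorted values keep the bootstrap invariant to subject ordering
        mean, ci95 = bootstrap_mean_ci(np.sort(obs[:, j]), n_boot=n_boot, seed=seed + j)
        results.append(
            KeyPredictorResult(
                target_roi=int(target),
                predictor_roi=int(c),
                mean_weight_pct=mean,
                null_mean_weight_pct=float(null[:, j].mean()),
                ci95=ci95,
                p_raw=p_raw,
                p_corrected=p_corr,
                is_key=bool(p_corr < alpha and obs[:, j].mean() > null[:, j].mean()),
            )
        )
    return results


@dataclass(frozen=True)
class IntegrationEdge:
    """One dependency of a target ROI on a predictor ROI, classified by
    centroid distance (short <= 50 mm < long) and hemisphere relation."""

    target_roi: int
    predictor_roi: int
    distance_mm: float
    kind: str  # "short" | "long"
    homotopic: bool
    interhemispheric: bool


def classify_dependencies(
    edges,
    parcels: list[ParcelInfo],
) -> list[IntegrationEdge]:
    """Classify (target, predictor) pairs into the integration-network edge
    taxonomy: Euclidean centroid distance with the 50 mm short/long
    threshold, homotopy (same label, opposite hemisphere) and
    inter-hemisphericity."""
    by_id = {p.roi_id: p for p in parcels}
    out = []
    for t, p in edges:
        pt, pp = by_id[int(t)], by_id[int(p)]
        ct = np.asarray(pt.centroid, dtype=float)
        cp = np.asarray(pp.centroid, dtype=float)
        if not (np.isfinite(ct).all() and np.isfinite(cp).all()):
            raise ValueError(f"missing centroid for edge ({t}, {p})")
        d = float(np.linalg.norm(ct - cp))
        inter = (
            pt.hemisphere is not Hemisphere.NONE
            and pp.hemisphere is not Hemisphere.NONE
            and pt.hemisphere is not pp.hemisphere
        )
        out.append(
            IntegrationEdge(
                target_roi=int(t),
                predictor_roi=int(p),
                distance_mm=d,
                kind="long" if d > LONG_RANGE_MM else "short",
                homotopic=bool(pt.label == pp.label and inter),
                interhemispheric=bool(inter),
            )
        )
    return out


def weight_correlation_check(
    models,
    datasets,
    splits,
    n_shuffle: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Pearson correlation between normalized predictor weights and the
    absolute training-segment activity correlation of each predictor with
    its target, pooled over models.

    Significance comes from shuffling the correlation values against the
    weights (add-one permutation p, two-sided on |r|).  Requires at least
    10 pooled pairs.
    """
    weights, corrs = [], []
    for model, ds, split in zip(models, datasets, splits):
        nw = normalize_weights(model)
        tr = split.train_slice
        y = ds.activity[tr, model.target_roi]
        for p, w in zip(model.predictors, nw):
            x = ds.activity[tr, int(p)]
            r = np.corrcoef(x, y)[0, 1]
            if not np.isfinite(r):
                raise ValueError(f"undefined training correlation for ROI {int(p)}")
            weights.append(w)
            corrs.append(abs(r))
    if len(weights) < 10:
        raise ValueError(f"need at least 10 (weight, correlation) pairs, got {len(weights)}")
    w = np.asarray(weights)
    c = np.asarray(corrs)
    if w.std() == 0 or c.std() == 0:
        raise ValueError("degenerate (constant) weight or correlation vector")
    r_obs = float(stats.pearsonr(w, c).statistic)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_shuffle):
        r_perm = float(stats.pearsonr(w, rng.permutation(c)).statistic)
        if abs(r_perm) >= abs(r_obs):
            hits += 1
    p = (1.0 + hits) / (n_shuffle + 1.0)
    return r_obs, float(p)


def partial_correlation_controlling_motion(measure, age, motion) -> tuple[float, float]:
    """Partial Pearson correlation of a per-subject measure with age,
    controlling for head motion.

    Both variables are residualized on motion (with an intercept) and the
    residuals correlated; the two-sided p-value uses ``n - 3`` degrees of
    freedom, as one covariate is partialled out.
    """
    m = np.asarray(measure, dtype=float)
    a = np.asarray(age, dtype=float)
    h = np.asarray(motion, dtype=float)
    if not (m.shape == a.shape == h.shape) or m.ndim != 1:
        raise ValueError("measure, age and motion must be 1-D vectors of equal length")
    n = m.size
    if n < 4:
        raise ValueError("need at least 4 subjects for a partial correlation")
    if m.std() == 0 or a.std() == 0:
        raise ValueError("constant measure or age vector")
    design = np.column_stack([np.ones(n), h])
    res_m = m - design @ np.linalg.lstsq(design, m, rcond=None)[0]
    res_a = a - design @ np.linalg.lstsq(design, a, rcond=None)[0]
    if res_m.std() == 0 or res_a.std() == 0:
        raise ValueError("a variable is fully explained by motion; partial correlation undefined")
    r = float(np.corrcoef(res_m, res_a)[0, 1])
    df = n - 3
    r_clipped = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clipped * np.sqrt(df / (1.0 - r_clipped**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p
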