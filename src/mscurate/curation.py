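"""Corrector/Filter/Pipeline machinery and the default QC-driven curation.

A curation pipeline is an ordered list of processing steps, each either a
*corrector* (changes area values: blank correction, LOESS drift correction,
normalisation) or a *filter* (removes feature columns: retention-time range,
QC presence, variation, prevalence, D-ratio).  Every step logs what it
removed or changed, so the run produces the feature "funnel" alongside the
curated matrix.

The default pipeline order is the reference-material curation workflow:

    rt_range -> qc_presence -> blank_correction -> batch_correction
      -> variation (robust RSD) -> prevalence -> d_ratio -> normalization

Inequality conventions (documented per flag): the variation filter removes
features with estimator strictly greater than ``max_value``; the D-ratio
filter keeps features strictly below ``max_ratio``; the retention-time window
is closed.  Undefined (NaN) metric values always fail their filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .datamodel import (
    DataMatrix,
    SampleMapping,
    ValidationError,
    cv as _cv,
    d_ratio as _d_ratio,
    detection_rate,
    robust_rsd as _robust_rsd,
)

__all__ = [
    "ProcessorStep",
    "Pipeline",
    "PipelineError",
    "LoessParams",
    "rt_range_filter",
    "qc_presence_filter",
    "blank_correction",
    "loess_batch_correction",
    "variation_filter",
    "prevalence_filter",
    "dratio_filter",
    "total_area_normalization",
    "run_pipeline",
    "default_pipeline",
]


class PipelineError(RuntimeError):
    """A step failed; carries the step name and the partial report."""

    def __init__(self, step: str, report: list[dict], cause: Exception):
        super().__init__(f"pipeline step {step!r} failed: {cause}")
        self.step = step
        self.report = report
        self.cause = cause


@dataclass(frozen=True)
class ProcessorStep:
    """One correction-or-filter with its parameters."""

    name: str
    params: dict = field(default_factory=dict)

    @property
    def kind(self) -> str:
        return "corrector" if STEP_REGISTRY[self.name][1] == "corrector" else "filter"


@dataclass(frozen=True)
class LoessParams:
    """LOESS drift-correction parameters.

    frac: span (fraction of QC points per local fit) or ``"auto"`` for
    per-feature LOOCV selection over ``frac_grid``; interpolator: how drift
    estimated at QC run orders is carried to every other injection.
    """

    frac: float | str = "auto"
    frac_grid: tuple[float, ...] = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    interpolator: str = "linear"
    min_qc_detections: int = 4

    def __post_init__(self) -> None:
        if self.frac == "auto":
            if not self.frac_grid:
                raise ValueError("frac_grid must be non-empty when frac='auto'")
            bad = [f for f in self.frac_grid if not 0 < f <= 1]
        else:
            bad = [] if 0 < float(self.frac) <= 1 else [self.frac]
        if bad:
            raise ValueError(f"LOESS fractions must lie in (0, 1]: {bad}")
        if self.interpolator not in ("linear", "cubic"):
            raise ValueError(f"unknown interpolator {self.interpolator!r}")


# ---------------------------------------------------------------------------
# individual steps; each returns (new matrix, log record)
# ---------------------------------------------------------------------------

def rt_range_filter(
    matrix: DataMatrix, min_rt: float = 0.0, max_rt: float = math.inf
) -> tuple[DataMatrix, dict]:
    """Keep features whose retention time lies in the closed [min_rt, max_rt]."""
    if min_rt > max_rt:
        raise ValidationError("min_rt must not exceed max_rt")
    rt = matrix.feature_meta["rt"]
    removed = list(rt.index[(rt < min_rt) | (rt > max_rt)])
    out = matrix.drop_features(removed) if removed else matrix.copy()
    return out, _record("rt_range", matrix, removed)


def qc_presence_filter(
    matrix: DataMatrix,
    min_qc_dr: float = 1.0,
    require_bracket: bool = True,
    threshold: float = 0.0,
) -> tuple[DataMatrix, dict]:
    """Keep features sufficiently detected in pooled-QC injections.

    A feature passes when its detection rate over QC samples (area strictly
    above ``threshold``) is at least ``min_qc_dr``; with ``require_bracket``
    it must also be detected in the first and last QC of each batch, so a
    subsequent LOESS correction never extrapolates.
    """
    qc_samples = matrix.samples_of_type("qc")
    if len(qc_samples) == 0:
        raise ValidationError("qc_presence_filter requires qc samples")
    qc_areas = matrix.areas.loc[qc_samples]
    dr = (qc_areas > threshold).mean(axis=0)
    keep = dr >= min_qc_dr
    if require_bracket:
        meta = matrix.sample_meta.loc[qc_samples]
        for _, grp in meta.groupby("batch"):
            first = grp["order"].idxmin()
            last = grp["order"].idxmax()
            keep &= (matrix.areas.loc[first] > threshold) & (matrix.areas.loc[last] > threshold)
    removed = list(keep.index[~keep])
    out = matrix.drop_features(removed) if removed else matrix.copy()
    return out, _record("qc_presence", matrix, removed)


def blank_correction(
    matrix: DataMatrix,
    mode: str = "threshold_subtract",
    fold_threshold: float = 10.0,
    applies_to: Iterable[str] = ("study", "qc"),
) -> tuple[DataMatrix, dict]:
    """Remove the blank contribution from each feature.

    ``threshold_subtract`` (default): per feature, sample areas at or below
    ``fold_threshold`` times the maximum blank area are set to 0; remaining
    areas have the mean blank area subtracted (clipped at 0).
    ``subtract_mean`` / ``subtract_max`` subtract unconditionally.
    """
    if mode not in ("threshold_subtract", "subtract_mean", "subtract_max"):
        raise ValueError(f"unknown blank-correction mode {mode!r}")
    blanks = matrix.samples_of_type("blank")
    if len(blanks) == 0:
        raise ValidationError("blank_correction requires blank samples")
    target = matrix.sample_meta.index[matrix.sample_meta["type"].isin(set(applies_to))]
    out = matrix.copy()
    bmax = matrix.areas.loc[blanks].max(axis=0).to_numpy()
    bmean = matrix.areas.loc[blanks].mean(axis=0).to_numpy()
    block = out.areas.loc[target].to_numpy()
    if mode == "threshold_subtract":
        zero = block <= fold_threshold * bmax[None, :]
        block = np.where(zero, 0.0, np.maximum(block - bmean[None, :], 0.0))
    elif mode == "subtract_mean":
        block = np.maximum(block - bmean[None, :], 0.0)
    else:
        block = np.maximum(block - bmax[None, :], 0.0)
    out.areas.loc[target] = block
    return out, _record("blank_correction", matrix, [], corrected_samples=list(target))


def loess_batch_correction(
    matrix: DataMatrix,
    params: LoessParams | None = None,
    applies_to: Iterable[str] = ("study", "qc"),
) -> tuple[DataMatrix, dict]:
    """QC-based LOESS signal-drift correction, per feature and per batch.

    For each feature the (run order, area) points of the pooled-QC injections
    are smoothed with LOESS; the span is either fixed or chosen per feature by
    leave-one-out cross-validation over ``params.frac_grid``.  The smoothed
    drift at QC orders is interpolated to every injection's order and each
    area is multiplied by ``median(QC areas) / drift(order)``, restoring the
    feature to its QC-median level.  Features whose drift estimate is zero,
    negative or non-finite anywhere are removed (logged).
    """
    params = params or LoessParams()
    out = matrix.copy()
    sm = out.sample_meta
    target_ids = sm.index[sm["type"].isin(set(applies_to))]
    removed: list[str] = []
    chosen: dict[str, float] = {}
    for batch, batch_meta in sm.groupby("batch"):
        qc_ids = batch_meta.index[batch_meta["type"] == "qc"]
        if len(qc_ids) < params.min_qc_detections:
            raise ValidationError(
                f"batch {batch} has {len(qc_ids)} QC samples; "
                f"at least {params.min_qc_detections} are required"
            )
        qc_sorted = batch_meta.loc[qc_ids].sort_values("order").index
        x_qc = batch_meta.loc[qc_sorted, "order"].to_numpy(dtype=float)
        targets = [s for s in target_ids if s in batch_meta.index]
        x_all = batch_meta.loc[targets, "order"].to_numpy(dtype=float)
        if x_all.size and (x_all.min() < x_qc.min() or x_all.max() > x_qc.max()):
            raise ValidationError(
                f"batch {batch} has samples outside the QC bracket; "
                "apply qc_presence_filter(require_bracket=True) first"
            )
        for feat in out.areas.columns:
            y_qc = out.areas.loc[qc_sorted, feat].to_numpy(dtype=float)
            frac = (
                _loocv_frac(x_qc, y_qc, params.frac_grid)
                if params.frac == "auto"
                else float(params.frac)
            )
            fit = lowess(y_qc, x_qc, frac=frac, return_sorted=True)
            drift = _interpolate(fit[:, 0], fit[:, 1], x_all, params.interpolator)
            if not np.all(np.isfinite(drift)) or np.any(drift <= 0.0):
                removed.append(feat)
                continue
            ref = float(np.median(y_qc))
            factors = ref / drift
            col = out.areas.loc[targets, feat].to_numpy(dtype=float)
            out.areas.loc[targets, feat] = col * factors
            chosen[feat] = frac
    if removed:
        removed = sorted(set(removed))
        out = out.drop_features(removed)
    return out, _record("batch_correction", matrix, removed, loess_frac=chosen)


def _loocv_frac(x: np.ndarray, y: np.ndarray, grid: Sequence[float]) -> float:
    """Span minimising the leave-one-out squared prediction error (first
    minimiser wins, so ties pick the smallest span)."""
    best_frac, best_err = None, math.inf
    for fr in grid:
        err = 0.0
        for i in range(x.size):
            xr = np.delete(x, i)
            yr = np.delete(y, i)
            fit = lowess(yr, xr, frac=fr, return_sorted=True)
            pred = float(np.interp(x[i], fit[:, 0], fit[:, 1]))
            err += (y[i] - pred) ** 2
        if err < best_err:
            best_frac, best_err = fr, err
    return float(best_frac)


def _interpolate(x: np.ndarray, y: np.ndarray, xnew: np.ndarray, kind: str) -> np.ndarray:
    if kind == "linear":
        return np.interp(xnew, x, y)
    from scipy.interpolate import CubicSpline

    return CubicSpline(x, y)(xnew)


def variation_filter(
    matrix: DataMatrix,
    max_value: float = 0.20,
    estimator: str = "robust_rsd",
    classes: Iterable[str] | None = None,
) -> tuple[DataMatrix, dict]:
    """Remove features whose dispersion over the selected classes (default:
    the QC classes) exceeds ``max_value`` (strictly), or is undefined."""
    if estimator not in ("cv", "robust_rsd"):
        raise ValueError(f"unknown estimator {estimator!r}")
    func = _robust_rsd if estimator == "robust_rsd" else _cv
    samples = (
        matrix.samples_of_classes(classes)
        if classes is not None
        else matrix.samples_of_type("qc")
    )
    if len(samples) == 0:
        raise ValidationError("variation_filter has no samples to evaluate")
    values = matrix.areas.loc[samples].apply(lambda c: func(c.to_numpy()), axis=0)
    removed = list(values.index[~(values <= max_value)])  # NaN fails too
    out = matrix.drop_features(removed) if removed else matrix.copy()
    return out, _record("variation", matrix, removed)


def prevalence_filter(
    matrix: DataMatrix,
    lower: float = 1.0,
    upper: float = 1.0,
    threshold: float = 5.0,
    mode: str = "intraclass",
) -> tuple[DataMatrix, dict]:
    """Threshold-zeroing followed by a detection-rate window over study classes.

    First, every area strictly below ``threshold`` is set to 0 matrix-wide
    (the zeroing is part of the step).  Then features are kept iff
    ``lower <= DR <= upper`` where DR uses the same threshold (area strictly
    greater) over the study classes, in ``intraclass`` (minimum per-class
    rate), ``intraclass_max`` or ``global`` mode.
    """
    if not (0.0 <= lower <= upper <= 1.0):
        raise ValidationError("prevalence bounds must satisfy 0 <= lower <= upper <= 1")
    out = matrix.copy()
    vals = out.areas.to_numpy()
    vals[vals < threshold] = 0.0
    out.areas = pd.DataFrame(vals, index=out.areas.index, columns=out.areas.columns)
    dr = detection_rate(out, out.mapping.study, threshold, mode)
    keep = (dr >= lower) & (dr <= upper)
    removed = list(keep.index[~keep])
    result = out.drop_features(removed) if removed else out
    return result, _record("prevalence", matrix, removed)


def dratio_filter(matrix: DataMatrix, max_ratio: float = 0.10) -> tuple[DataMatrix, dict]:
    """Keep features with D-ratio strictly below ``max_ratio``; undefined
    D-ratios (zero study dispersion) are removed."""
    ratio = _d_ratio(matrix)
    keep = ratio < max_ratio
    removed = list(keep.index[~keep])
    out = matrix.drop_features(removed) if removed else matrix.copy()
    return out, _record("d_ratio", matrix, removed)


def total_area_normalization(
    matrix: DataMatrix, applies_to: Iterable[str] | None = None
) -> tuple[DataMatrix, dict]:
    """Divide each sample's areas by the sample's total area.

    With ``applies_to`` given (e.g. ``("study", "qc")`` in the default
    pipeline) only those sample types are normalised; otherwise every row is.
    A zero-total sample is an error naming the sample.
    """
    out = matrix.copy()
    if applies_to is None:
        target = out.areas.index
    else:
        target = out.sample_meta.index[out.sample_meta["type"].isin(set(applies_to))]
    totals = out.areas.loc[target].sum(axis=1)
    zero = totals.index[totals <= 0.0]
    if len(zero):
        raise ValidationError(f"zero total area for sample(s): {list(zero)}")
    out.areas.loc[target] = out.areas.loc[target].div(totals, axis=0)
    return out, _record("normalization", matrix, [], corrected_samples=list(target))


def _record(name: str, before: DataMatrix, removed: list[str], **extra) -> dict:
    rec = {
        "step": name,
        "features_before": before.n_features,
        "features_after": before.n_features - len(removed),
        "removed": sorted(removed),
    }
    rec.update(extra)
    return rec


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

STEP_REGISTRY: dict[str, tuple[Callable, str]] = {
    "rt_range": (rt_range_filter, "filter"),
    "qc_presence": (qc_presence_filter, "filter"),
    "blank_correction": (blank_correction, "corrector"),
    "batch_correction": (loess_batch_correction, "corrector"),
    "variation": (variation_filter, "filter"),
    "prevalence": (prevalence_filter, "filter"),
    "d_ratio": (dratio_filter, "filter"),
    "normalization": (total_area_normalization, "corrector"),
}


class Pipeline:
    """Ordered list of processing steps with a per-step removal log."""

    def __init__(self, steps: Sequence[ProcessorStep] = ()):
        for step in steps:
            if step.name not in STEP_REGISTRY:
                raise ValueError(f"unknown pipeline step {step.name!r}")
        self.steps = list(steps)
        self.log: list[dict] = []

    def apply(self, matrix: DataMatrix) -> DataMatrix:
        self.log = []
        current = matrix
        for step in self.steps:
            func, _ = STEP_REGISTRY[step.name]
            params = dict(step.params)
            if step.name == "batch_correction" and "params" not in params:
                loess_keys = {"frac", "frac_grid", "interpolator", "min_qc_detections"}
                lp = {k: params.pop(k) for k in list(params) if k in loess_keys}
                if lp:
                    if "frac_grid" in lp:
                        lp["frac_grid"] = tuple(lp["frac_grid"])
                    params["params"] = LoessParams(**lp)
            try:
                current, record = func(current, **params)
            except Exception as exc:  # noqa: BLE001 - wrap with context
                raise PipelineError(step.name, self.log, exc) from exc
            record["kind"] = step.kind
            record["params"] = dict(step.params)
            self.log.append(record)
        return current

    def funnel(self) -> list[tuple[str, int]]:
        """Feature count surviving after each step (the funnel plot data)."""
        return [(rec["step"], rec["features_after"]) for rec in self.log]


def default_pipeline(
    min_rt: float = 90.0,
    max_rt: float = math.inf,
    fold_threshold: float = 10.0,
    use_loess: bool = True,
    loess: LoessParams | None = None,
    max_rsd: float = 0.20,
    prevalence_threshold: float = 5.0,
    min_prevalence: float = 1.0,
    max_d_ratio: float = 0.10,
) -> Pipeline:
    """The reference-material curation pipeline with its default thresholds.

    Rt >= 90 s, full QC presence with bracketing, 10-fold blank
    threshold-subtraction, LOOCV-LOESS drift correction (switchable), robust
    RSD <= 20 % in QCs, 100 % intraclass prevalence at area threshold 5,
    D-ratio < 10 %, total-area normalisation.
    """
    steps = [
        ProcessorStep("rt_range", {"min_rt": min_rt, "max_rt": max_rt}),
        ProcessorStep("qc_presence", {"min_qc_dr": 1.0, "require_bracket": True}),
        ProcessorStep("blank_correction", {"fold_threshold": fold_threshold}),
    ]
    if use_loess:
        steps.append(ProcessorStep("batch_correction", {"params": loess or LoessParams()}))
    steps += [
        ProcessorStep("variation", {"max_value": max_rsd, "estimator": "robust_rsd"}),
        ProcessorStep(
            "prevalence",
            {"lower": min_prevalence, "upper": 1.0, "threshold": prevalence_threshold},
        ),
        ProcessorStep("d_ratio", {"max_ratio": max_d_ratio}),
        ProcessorStep("normalization", {"applies_to": ("study", "qc")}),
    ]
    return Pipeline(steps)


def run_pipeline(matrix: DataMatrix, pipeline: Pipeline | Sequence[ProcessorStep]) -> tuple[DataMatrix, list[dict]]:
    """Apply a pipeline and return (curated matrix, per-step report)."""
    if not isinstance(pipeline, Pipeline):
        pipeline = Pipeline(pipeline)
    curated = pipeline.apply(matrix)
    return curated, pipeline.log


def pipeline_from_config(config: dict) -> Pipeline:
    """Build a pipeline from a YAML/JSON-style dict: ``{"steps": [{"name": ..., "params": {...}}, ...]}``."""
    steps = [ProcessorStep(s["name"], dict(s.get("params", {}))) for s in config["steps"]]
    return Pipeline(steps)
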