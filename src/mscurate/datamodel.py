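"""Data matrix container, sample/feature metadata and QC metrics.

An untargeted LC-MS study is summarised by an N x K matrix of chromatographic
peak areas (N samples, K features).  Each feature is an (m/z, retention time)
pair; each sample carries a class label, a run order, a batch and a sample
type.  The metrics defined here (detection rate, CV, robust RSD, D-ratio) are
the quantities every curation filter consumes.

Undefined metric values (zero median, zero study dispersion, ...) are
represented as NaN; downstream filters treat NaN as a failing value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("mscurate")

#: multiplies the MAD so that, for normal data, it estimates the standard
#: deviation (1 / Phi^-1(3/4)).
MAD_SCALE = 1.4826

SAMPLE_TYPES = ("study", "qc", "blank", "other")


class ValidationError(ValueError):
    """Raised when a container or its inputs violate an invariant."""


@dataclass(frozen=True)
class SampleMapping:
    """Assignment of sample classes to sample types.

    The mapping gives every processing step its default behaviour: filters
    compute their metric on the ``qc`` (or ``study``) classes and act on the
    ``study`` classes without the user repeating class lists per step.
    """

    study: frozenset[str]
    qc: frozenset[str]
    blank: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        sets = {"study": self.study, "qc": self.qc, "blank": self.blank}
        for name, classes in sets.items():
            object.__setattr__(self, name, frozenset(classes))
        for a in sets:
            for b in sets:
                if a < b and set(getattr(self, a)) & set(getattr(self, b)):
                    raise ValidationError(
                        f"classes assigned to both {a!r} and {b!r}: "
                        f"{sorted(set(getattr(self, a)) & set(getattr(self, b)))}"
                    )

    def type_of(self, class_label: str) -> str:
        for name in ("study", "qc", "blank"):
            if class_label in getattr(self, name):
                return name
        return "other"

    @classmethod
    def from_dict(cls, d: Mapping[str, Iterable[str]]) -> "SampleMapping":
        return cls(
            study=frozenset(d.get("study", ())),
            qc=frozenset(d.get("qc", ())),
            blank=frozenset(d.get("blank", ())),
        )


@dataclass
class DataMatrix:
    """N x K peak-area matrix with sample and feature metadata.

    Parameters
    ----------
    areas:
        DataFrame of non-negative peak areas, samples on rows (index = sample
        ids), features on columns (columns = feature ids).
    sample_meta:
        DataFrame indexed by sample id with columns ``class`` (str),
        ``order`` (positive int, unique within a batch), ``batch`` (int) and,
        optionally, ``type``; when absent the type is derived from ``mapping``.
    feature_meta:
        DataFrame indexed by feature id with columns ``mz`` (Th, > 0) and
        ``rt`` (s, >= 0).
    mapping:
        class -> sample-type assignment used by default by every QC step.
    """

    areas: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame
    mapping: SampleMapping

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        a = self.areas
        if a.shape[0] < 1:
            raise ValidationError("data matrix needs at least one sample")
        if a.shape[1] == 0:
            # filters may legitimately empty the matrix
            logger.warning("data matrix has no features left")
        if a.index.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if a.columns.has_duplicates:
            raise ValidationError("duplicate feature ids")
        vals = a.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValidationError("non-finite peak areas")
        if (vals < 0).any():
            raise ValidationError("negative peak areas")
        missing = set(a.index) - set(self.sample_meta.index)
        if missing:
            raise ValidationError(f"samples missing from metadata: {sorted(missing)}")
        extra = set(self.sample_meta.index) - set(a.index)
        if extra:
            raise ValidationError(f"metadata samples absent from areas: {sorted(extra)}")
        if set(a.columns) != set(self.feature_meta.index):
            raise ValidationError("feature ids of areas and feature metadata differ")
        self.sample_meta = self.sample_meta.loc[a.index]
        self.feature_meta = self.feature_meta.loc[a.columns]
        fm = self.feature_meta
        if (fm["mz"] <= 0).any():
            raise ValidationError("feature m/z must be positive")
        if (fm["rt"] < 0).any():
            raise ValidationError("feature rt must be non-negative")
        sm = self.sample_meta
        if "type" not in sm.columns:
            sm = sm.assign(type=[self.mapping.type_of(c) for c in sm["class"]])
            self.sample_meta = sm
        bad = set(sm["type"]) - set(SAMPLE_TYPES)
        if bad:
            raise ValidationError(f"unknown sample types: {sorted(bad)}")
        for batch, grp in sm.groupby("batch"):
            if grp["order"].duplicated().any():
                raise ValidationError(f"duplicate run orders in batch {batch}")

    # -- convenience --------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.areas.shape[0]

    @property
    def n_features(self) -> int:
        return self.areas.shape[1]

    def samples_of_type(self, sample_type: str) -> pd.Index:
        return self.sample_meta.index[self.sample_meta["type"] == sample_type]

    def samples_of_classes(self, classes: Iterable[str]) -> pd.Index:
        classes = set(classes)
        unknown = classes - set(self.sample_meta["class"])
        if unknown:
            raise ValidationError(f"unknown class labels: {sorted(unknown)}")
        return self.sample_meta.index[self.sample_meta["class"].isin(classes)]

    def copy(self) -> "DataMatrix":
        return DataMatrix(
            self.areas.copy(), self.sample_meta.copy(), self.feature_meta.copy(), self.mapping
        )

    def drop_features(self, feature_ids: Iterable[str]) -> "DataMatrix":
        ids = [f for f in feature_ids]
        return DataMatrix(
            self.areas.drop(columns=ids),
            self.sample_meta.copy(),
            self.feature_meta.drop(index=ids),
            self.mapping,
        )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def mad(values: np.ndarray) -> float:
    """Median absolute deviation from the median (unscaled)."""
    v = np.asarray(values, dtype=float)
    return float(np.median(np.abs(v - np.median(v))))


def robust_rsd(values) -> float:
    """Robust relative standard deviation, ``1.4826 * MAD / median``.

    The MAD times the normal-consistency factor estimates the standard
    deviation without being distorted by outlying injections; dividing by the
    median gives a robust analogue of the CV.  Returns NaN when the median is
    zero (the ratio is undefined).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("robust_rsd requires at least 2 values")
    med = float(np.median(v))
    if med == 0.0:
        return float("nan")
    return MAD_SCALE * mad(v) / med


def cv(values) -> float:
    """Coefficient of variation: sample standard deviation over the mean.

    Returns NaN when the mean is zero.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("cv requires at least 2 values")
    m = float(np.mean(v))
    if m == 0.0:
        return float("nan")
    return float(np.std(v, ddof=1)) / m


def detection_rate(
    matrix: DataMatrix,
    classes: Iterable[str],
    threshold: float = 0.0,
    mode: str = "intraclass",
) -> pd.Series:
    """Per-feature detection rate over the given sample classes.

    A sample *detects* a feature iff its area is strictly greater than
    ``threshold``.  In ``global`` mode the rate is the fraction of all samples
    of the given classes; in ``intraclass`` mode the rate is computed per
    class and the minimum over classes is returned (``intraclass_max`` takes
    the maximum instead, for the looser at-least-one-class reading).
    """
    classes = list(classes)
    if not classes:
        raise ValidationError("classes must be non-empty")
    if mode not in ("intraclass", "global", "intraclass_max"):
        raise ValueError(f"unknown detection-rate mode: {mode!r}")
    samples = matrix.samples_of_classes(classes)
    detected = matrix.areas.loc[samples] > threshold
    if mode == "global":
        return detected.mean(axis=0)
    labels = matrix.sample_meta.loc[samples, "class"]
    per_class = detected.groupby(labels, observed=True).mean()
    if mode == "intraclass":
        return per_class.min(axis=0)
    return per_class.max(axis=0)


def d_ratio(matrix: DataMatrix, mapping: SampleMapping | None = None) -> pd.Series:
    """Per-feature dispersion ratio: MAD over QC samples / MAD over study samples.

    Low values mean the technical (QC) variation is small relative to the
    biological (study) variation.  Returns NaN where the study MAD is zero.
    """
    mapping = mapping or matrix.mapping
    qc_samples = matrix.samples_of_classes(mapping.qc) if mapping.qc else pd.Index([])
    study_samples = matrix.samples_of_classes(mapping.study) if mapping.study else pd.Index([])
    if len(qc_samples) == 0 or len(study_samples) == 0:
        raise ValidationError("d_ratio requires both qc and study samples")
    qc_mad = matrix.areas.loc[qc_samples].apply(lambda c: mad(c.to_numpy()), axis=0)
    study_mad = matrix.areas.loc[study_samples].apply(lambda c: mad(c.to_numpy()), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = qc_mad / study_mad
    out[study_mad == 0.0] = np.nan
    return out


def feature_metrics(matrix: DataMatrix, threshold: float = 0.0) -> pd.DataFrame:
    """Summary table of per-feature QC metrics (DR, CV, robust RSD, D-ratio)."""
    mapping = matrix.mapping
    qc_samples = matrix.samples_of_classes(mapping.qc)
    qc = matrix.areas.loc[qc_samples]
    out = pd.DataFrame(index=matrix.areas.columns)
    out["detection_rate"] = detection_rate(matrix, mapping.study, threshold, "intraclass")
    out["cv"] = qc.apply(lambda c: cv(c.to_numpy()), axis=0)
    out["robust_rsd"] = qc.apply(lambda c: robust_rsd(c.to_numpy()), axis=0)
    out["d_ratio"] = d_ratio(matrix)
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_matrix(
    areas_path: str | Path,
    sample_meta_path: str | Path,
    feature_meta_path: str | Path,
    mapping: SampleMapping | Mapping[str, Iterable[str]] | None = None,
) -> DataMatrix:
    """Assemble a :class:`DataMatrix` from three CSV files.

    ``areas_path``: samples x features, first column the sample id.
    ``sample_meta_path``: columns ``id,class,order,batch[,type]``.
    ``feature_meta_path``: columns ``id,mz,rt``.

    Missing area cells become 0 (logged); negative areas are rejected.  When
    ``mapping`` is omitted it is derived from an explicit ``type`` column of
    the sample metadata.
    """
    try:
        areas = pd.read_csv(areas_path, index_col=0)
        sample_meta = pd.read_csv(sample_meta_path, index_col="id")
        feature_meta = pd.read_csv(feature_meta_path, index_col="id")
    except (OSError, pd.errors.ParserError) as exc:
        raise IOError(f"cannot read input table: {exc}") from exc
    try:
        areas = areas.astype(float)
    except ValueError as exc:
        raise ValidationError(f"malformed numeric field in {areas_path}: {exc}") from exc
    n_missing = int(areas.isna().sum().sum())
    if n_missing:
        logger.warning("%d missing area cells set to 0", n_missing)
        areas = areas.fillna(0.0)
    if mapping is None:
        if "type" not in sample_meta.columns:
            raise ValidationError(
                "no sample mapping given and no 'type' column in sample metadata"
            )
        by_type: dict[str, set[str]] = {t: set() for t in ("study", "qc", "blank")}
        for cls, typ in zip(sample_meta["class"], sample_meta["type"]):
            if typ in by_type:
                by_type[typ].add(cls)
        mapping = SampleMapping.from_dict(by_type)
    elif not isinstance(mapping, SampleMapping):
        mapping = SampleMapping.from_dict(mapping)
    return DataMatrix(areas, sample_meta, feature_meta, mapping)


def save_matrix(matrix: DataMatrix, areas_path, sample_meta_path=None, feature_meta_path=None) -> None:
    """Write the container back to the three-CSV layout used by load_matrix."""
    matrix.areas.to_csv(areas_path, index_label="sample")
    if sample_meta_path is not None:
        matrix.sample_meta.to_csv(sample_meta_path, index_label="id")
    if feature_meta_path is not None:
        matrix.feature_meta.to_csv(feature_meta_path, index_label="id")
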