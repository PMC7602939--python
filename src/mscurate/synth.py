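"""Synthetic data generators with ground truth, plus a brute-force reference
implementation of the default curation rules.

Two generators cover the two kinds of input the toolkit consumes:

* :func:`generate_raw_run` plants Gaussian elution profiles as centroid MS1
  scans (optionally serialised to a minimal mzML document) and returns the
  analytic ground truth (apex, area = height * sd * sqrt(2*pi)).
* :func:`generate_study` emulates an analytical batch: a handful of plasma
  materials measured in process replicates, pooled-QC injections following a
  leading block / bracketing / trailing template, multiplicative signal drift
  over run order, proportional noise, blank contamination and per-class
  detection dropout.  Ground truth (drift-free areas, the drift curve,
  contaminated/low-prevalence feature ids) is returned alongside.

:func:`naive_default_curation` re-applies every default curation rule with
plain Python loops; it is the independent oracle the pipeline is validated
against.
"""

from __future__ import annotations

import base64
import math
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

from .datamodel import DataMatrix, SampleMapping
from .rawdata import MSSpectrum

__all__ = [
    "GaussianFeature",
    "RawRunSpec",
    "generate_raw_run",
    "write_mzml",
    "StudySpec",
    "StudyTruth",
    "generate_study",
    "naive_default_curation",
]


# ---------------------------------------------------------------------------
# raw runs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianFeature:
    """One planted chromatographic feature: a Gaussian elution profile at a
    (nearly) fixed m/z."""

    mz: float
    rt: float          # apex, s
    width: float       # Gaussian sd, s
    height: float      # apex intensity
    mz_jitter: float = 0.0   # sd of per-scan m/z scatter, Th

    @property
    def area(self) -> float:
        return self.height * self.width * math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class RawRunSpec:
    """Specification of a synthetic centroid MS1 run."""

    n_scans: int = 100
    scan_interval: float = 0.5   # s
    features: tuple[GaussianFeature, ...] = ()
    noise_points: int = 0        # random centroid points per scan
    noise_level: float = 0.0     # exponential intensity scale of noise points
    mz_range: tuple[float, float] = (100.0, 1000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scans < 1 or self.scan_interval <= 0:
            raise ValueError("n_scans and scan_interval must be positive")
        duration = self.n_scans * self.scan_interval
        for f in self.features:
            if not (0.0 <= f.rt <= duration):
                raise ValueError(f"feature apex {f.rt} s outside run (0..{duration} s)")


def generate_raw_run(spec: RawRunSpec) -> tuple[list[MSSpectrum], pd.DataFrame]:
    """Generate the spectra of a synthetic run and its ground-truth table.

    Each feature contributes one centroid point per scan where its Gaussian
    profile exceeds a small floor; noise points have uniform m/z and
    exponential intensity.  The truth table columns are
    ``mz, rt, width, height, area``.
    """
    rng = np.random.default_rng(spec.seed)
    intensity_floor = 1.0
    spectra: list[MSSpectrum] = []
    for i in range(spec.n_scans):
        t = i * spec.scan_interval
        mzs: list[float] = []
        ints: list[float] = []
        for f in spec.features:
            y = f.height * math.exp(-((t - f.rt) ** 2) / (2.0 * f.width**2))
            if y >= intensity_floor:
                m = f.mz + (rng.normal(0.0, f.mz_jitter) if f.mz_jitter > 0 else 0.0)
                mzs.append(m)
                ints.append(y)
        for _ in range(spec.noise_points):
            mzs.append(float(rng.uniform(*spec.mz_range)))
            ints.append(float(rng.exponential(spec.noise_level)) if spec.noise_level > 0 else 0.0)
        mz = np.asarray(mzs)
        inten = np.asarray(ints)
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        # nudge exact duplicates apart to keep the strictly-increasing invariant
        if mz.size > 1:
            dup = np.flatnonzero(np.diff(mz) <= 0)
            for d in dup:
                mz[d + 1] = np.nextafter(mz[d], np.inf)
        spectra.append(MSSpectrum(mz, inten, time=t, ms_level=1, is_centroid=True))
    truth = pd.DataFrame(
        [
            {"mz": f.mz, "rt": f.rt, "width": f.width, "height": f.height, "area": f.area}
            for f in spec.features
        ],
        columns=["mz", "rt", "width", "height", "area"],
    )
    return spectra, truth


# ---------------------------------------------------------------------------
# minimal mzML serialisation
# ---------------------------------------------------------------------------

def _b64(values: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{values.size}d", *values)).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0" id="{run_id}">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo"/>
  </cvList>
  <run id="{run_id}">
    <spectrumList count="{count}">
"""

_MZML_SPECTRUM = """      <spectrum index="{index}" id="scan={scan}" defaultArrayLength="{npts}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{level}"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{time}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_mzml(spectra: Sequence[MSSpectrum], path: str | Path, run_id: str = "synthetic_run") -> None:
    """Serialise spectra as a minimal centroid MS1 mzML document.

    The document carries only what downstream reading needs: ms level,
    centroid flag, scan start time in seconds and uncompressed 64-bit float
    m/z / intensity arrays.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_MZML_HEADER.format(run_id=escape(run_id), count=len(spectra)))
        for i, s in enumerate(spectra):
            mz_b64 = _b64(s.mz)
            int_b64 = _b64(s.intensity)
            fh.write(
                _MZML_SPECTRUM.format(
                    index=i,
                    scan=i + 1,
                    npts=s.mz.size,
                    level=s.ms_level,
                    time=repr(float(s.time)),
                    mz_len=len(mz_b64),
                    mz_b64=mz_b64,
                    int_len=len(int_b64),
                    int_b64=int_b64,
                )
            )
        fh.write(_MZML_FOOTER)


# ---------------------------------------------------------------------------
# study matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudySpec:
    """Specification of a synthetic analytical batch.

    Defaults emulate a reference-material study: four plasma materials in six
    process replicates, three process blanks at the start of the batch, and a
    pooled-QC template of a leading block, a bracketing QC after every block
    of ``block_size`` study injections, and a trailing block.  Drift is
    multiplicative over run order; noise is proportional.
    """

    classes: tuple[tuple[str, int], ...] = (
        ("plasma_srm", 6),
        ("plasma_diabetic", 6),
        ("plasma_hyperlip", 6),
        ("plasma_afram", 6),
    )
    n_features: int = 50
    n_blanks: int = 3
    n_leading_qc: int = 3
    n_trailing_qc: int = 3
    block_size: int = 4
    drift: str = "linear"              # linear | exponential | random_walk | none
    drift_magnitude: float = 0.4       # g spans 1.0 .. 1 + magnitude over the batch
    noise_sd: float = 0.02             # proportional (multiplicative) noise sd
    feature_scale_mu: float = math.log(1000.0)
    feature_scale_sigma: float = 1.0
    class_effect_sigma: float = 0.3    # log-scale between-material effect
    replicate_sigma: float = 0.1       # log-scale within-material variation
    contaminated_fraction: float = 0.1
    contamination_level: tuple[float, float] = (50.0, 500.0)
    low_prevalence_fraction: float = 0.15
    low_prevalence_dropout: float = 0.5
    dropout: float = 0.0               # baseline per-entry dropout in study samples
    rt_range: tuple[float, float] = (30.0, 1080.0)
    mz_range: tuple[float, float] = (100.0, 1000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        if not self.classes:
            raise ValueError("at least one study class is required")
        if self.drift not in ("linear", "exponential", "random_walk", "none"):
            raise ValueError(f"unknown drift family {self.drift!r}")
        if self.n_leading_qc < 1 or self.n_trailing_qc < 1:
            raise ValueError("QC template needs leading and trailing QCs")


@dataclass
class StudyTruth:
    """Ground truth accompanying a generated study."""

    base_areas: pd.DataFrame          # drift- and noise-free areas, N x K
    drift: pd.Series                  # g(order), indexed by sample id
    qc_orders: np.ndarray
    contaminated: list[str]
    low_prevalence: list[str]
    dropped: pd.DataFrame             # boolean N x K dropout mask

    def reference_level(self) -> float:
        """Median of the drift curve over QC orders: the level a QC-median
        referenced multiplicative correction restores areas to."""
        qc_ids = self.drift.index[np.isin(self.drift.index.map(self._order_of), self.qc_orders)]
        return float(np.median(self.drift.loc[qc_ids]))

    def _order_of(self, sid):  # pragma: no cover - helper for index mapping
        return self._orders[sid]

    _orders: dict = field(default_factory=dict)


def _drift_curve(spec: StudySpec, orders: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if spec.drift == "none" or spec.drift_magnitude == 0:
        return np.ones(orders.size)
    span = orders.max() - orders.min()
    u = (orders - orders.min()) / (span if span > 0 else 1)
    if spec.drift == "linear":
        return 1.0 + spec.drift_magnitude * u
    if spec.drift == "exponential":
        return np.exp(math.log1p(spec.drift_magnitude) * u)
    # smooth random walk: cumulative Gaussian steps smoothed by a cubic fit
    steps = rng.normal(0.0, 1.0, orders.size).cumsum()
    steps = (steps - steps.min()) / max(np.ptp(steps), 1e-12)
    coef = np.polyfit(u, steps, 3)
    smooth = np.polyval(coef, u)
    smooth = (smooth - smooth.min()) / max(np.ptp(smooth), 1e-12)
    return 1.0 + spec.drift_magnitude * smooth


def generate_study(spec: StudySpec) -> tuple[DataMatrix, StudyTruth]:
    """Generate a synthetic study matrix with its ground truth.

    True (drift-free) area of sample n, feature k:
    ``x = scale_k * class_effect_{class(n),k} * replicate_noise``; QC rows use
    the pooled profile (mean of class means).  Observed area is
    ``x * g(order) * (1 + eps)`` with proportional noise eps.  Contaminated
    features additionally carry a blank-level baseline present in every
    injection including the blanks.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.n_features
    feature_ids = [f"F{i:04d}" for i in range(k)]

    # --- injection sequence -------------------------------------------------
    sample_rows: list[tuple[str, str, str]] = []  # (id, class, type)
    for b in range(spec.n_blanks):
        sample_rows.append((f"blank{b + 1}", "blank", "blank"))
    qc_count = 0
    for _ in range(spec.n_leading_qc):
        qc_count += 1
        sample_rows.append((f"qc{qc_count:02d}", "pooled_qc", "qc"))
    study_units: list[tuple[str, str]] = []
    for cls, n in spec.classes:
        for r in range(n):
            study_units.append((f"{cls}_{r + 1}", cls))
    perm = rng.permutation(len(study_units))
    placed = 0
    for idx in perm:
        sid, cls = study_units[idx]
        sample_rows.append((sid, cls, "study"))
        placed += 1
        if placed % spec.block_size == 0 and placed < len(study_units):
            qc_count += 1
            sample_rows.append((f"qc{qc_count:02d}", "pooled_qc", "qc"))
    for _ in range(spec.n_trailing_qc):
        qc_count += 1
        sample_rows.append((f"qc{qc_count:02d}", "pooled_qc", "qc"))

    ids = [r[0] for r in sample_rows]
    classes = [r[1] for r in sample_rows]
    types = [r[2] for r in sample_rows]
    orders = np.arange(1, len(ids) + 1)
    sample_meta = pd.DataFrame(
        {"class": classes, "order": orders, "batch": 1, "type": types}, index=pd.Index(ids, name="id")
    )

    # --- true areas ---------------------------------------------------------
    scale = np.exp(rng.normal(spec.feature_scale_mu, spec.feature_scale_sigma, k))
    class_names = [c for c, _ in spec.classes]
    class_effect = {
        c: np.exp(rng.normal(0.0, spec.class_effect_sigma, k)) for c in class_names
    }
    pooled = np.mean([class_effect[c] for c in class_names], axis=0)
    contaminated_idx = np.flatnonzero(rng.random(k) < spec.contaminated_fraction)
    blank_level = np.zeros(k)
    blank_level[contaminated_idx] = rng.uniform(*spec.contamination_level, contaminated_idx.size)
    low_idx = np.flatnonzero(rng.random(k) < spec.low_prevalence_fraction)
    low_class = {i: class_names[rng.integers(len(class_names))] for i in low_idx}

    base = np.zeros((len(ids), k))
    for i, (sid, cls, typ) in enumerate(sample_rows):
        if typ == "blank":
            base[i] = blank_level
        elif typ == "qc":
            base[i] = scale * pooled + blank_level
        else:
            rep = np.exp(rng.normal(0.0, spec.replicate_sigma, k))
            base[i] = scale * class_effect[cls] * rep + blank_level

    g = _drift_curve(spec, orders.astype(float), rng)
    eps = rng.normal(0.0, spec.noise_sd, base.shape) if spec.noise_sd > 0 else np.zeros_like(base)
    observed = base * g[:, None] * np.clip(1.0 + eps, 0.05, None)

    # --- dropout ------------------------------------------------------------
    dropped = np.zeros(base.shape, dtype=bool)
    for i, (sid, cls, typ) in enumerate(sample_rows):
        if typ != "study":
            continue
        if spec.dropout > 0:
            dropped[i] |= rng.random(k) < spec.dropout
        for fi, c in low_class.items():
            if cls == c and rng.random() < spec.low_prevalence_dropout:
                dropped[i, fi] = True
    observed[dropped] = 0.0

    areas = pd.DataFrame(observed, index=sample_meta.index, columns=feature_ids)
    feature_meta = pd.DataFrame(
        {
            "mz": rng.uniform(*spec.mz_range, k),
            "rt": rng.uniform(*spec.rt_range, k),
        },
        index=pd.Index(feature_ids, name="id"),
    )
    mapping = SampleMapping(
        study=frozenset(class_names), qc=frozenset({"pooled_qc"}), blank=frozenset({"blank"})
    )
    matrix = DataMatrix(areas, sample_meta, feature_meta, mapping)

    truth = StudyTruth(
        base_areas=pd.DataFrame(base, index=sample_meta.index, columns=feature_ids),
        drift=pd.Series(g, index=sample_meta.index),
        qc_orders=orders[np.asarray(types) == "qc"],
        contaminated=[feature_ids[i] for i in contaminated_idx],
        low_prevalence=[feature_ids[i] for i in low_idx],
        dropped=pd.DataFrame(dropped, index=sample_meta.index, columns=feature_ids),
    )
    truth._orders = dict(zip(ids, orders))
    return matrix, truth


# ---------------------------------------------------------------------------
# brute-force reference curation (the oracle)
# ---------------------------------------------------------------------------

def _naive_median(vals: list[float]) -> float:
    return float(np.median(np.asarray(vals, dtype=float)))


def _naive_mad(vals: list[float]) -> float:
    med = _naive_median(vals)
    return _naive_median([abs(v - med) for v in vals])


def _naive_rsd(vals: list[float]) -> float:
    med = _naive_median(vals)
    if med == 0.0:
        return float("nan")
    return 1.4826 * _naive_mad(vals) / med


def naive_default_curation(
    matrix: DataMatrix,
    min_rt: float = 90.0,
    max_rt: float = float("inf"),
    min_qc_dr: float = 1.0,
    fold_threshold: float = 10.0,
    use_loess: bool = True,
    loess_frac: float | str = "auto",
    frac_grid: Sequence[float] = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    max_rsd: float = 0.20,
    prevalence_threshold: float = 5.0,
    min_prevalence: float = 1.0,
    max_d_ratio: float = 0.10,
) -> dict:
    """Plain-loop re-application of every default curation rule.

    Returns ``{"surviving": {step_name: [feature ids]}, "areas": dict}`` where
    ``areas`` maps (sample id, feature id) to the final normalised area.  The
    implementation deliberately avoids the pipeline code paths: all metrics
    are computed with explicit loops.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    sm = matrix.sample_meta
    ids = list(matrix.areas.index)
    feats = list(matrix.areas.columns)
    A = {(s, f): float(matrix.areas.at[s, f]) for s in ids for f in feats}
    cls = {s: sm.at[s, "class"] for s in ids}
    typ = {s: sm.at[s, "type"] for s in ids}
    order = {s: int(sm.at[s, "order"]) for s in ids}
    qc_ids = [s for s in ids if typ[s] == "qc"]
    study_ids = [s for s in ids if typ[s] == "study"]
    blank_ids = [s for s in ids if typ[s] == "blank"]
    surviving: dict[str, list[str]] = {}

    # 1. retention-time range
    feats = [
        f
        for f in feats
        if min_rt <= float(matrix.feature_meta.at[f, "rt"]) <= max_rt
    ]
    surviving["rt_range"] = list(feats)

    # 2. QC presence with bracketing
    qc_sorted = sorted(qc_ids, key=lambda s: order[s])
    kept = []
    for f in feats:
        n_det = sum(1 for s in qc_ids if A[(s, f)] > 0.0)
        dr = n_det / len(qc_ids)
        bracket = A[(qc_sorted[0], f)] > 0.0 and A[(qc_sorted[-1], f)] > 0.0
        if dr >= min_qc_dr and bracket:
            kept.append(f)
    feats = kept
    surviving["qc_presence"] = list(feats)

    # 3. blank threshold-subtract
    for f in feats:
        bvals = [A[(s, f)] for s in blank_ids]
        bmax = max(bvals) if bvals else 0.0
        bmean = sum(bvals) / len(bvals) if bvals else 0.0
        for s in study_ids + qc_ids:
            a = A[(s, f)]
            if a <= fold_threshold * bmax:
                A[(s, f)] = 0.0
            else:
                A[(s, f)] = max(a - bmean, 0.0)
    surviving["blank_correction"] = list(feats)

    # 4. LOESS drift correction (QC-median referenced, per feature)
    if use_loess:
        x_qc = np.array([float(order[s]) for s in qc_sorted])
        kept = []
        for f in feats:
            y_qc = np.array([A[(s, f)] for s in qc_sorted])
            if loess_frac == "auto":
                best_frac, best_err = None, math.inf
                for fr in frac_grid:
                    err = 0.0
                    for i in range(x_qc.size):
                        xr = np.delete(x_qc, i)
                        yr = np.delete(y_qc, i)
                        fit = lowess(yr, xr, frac=fr, return_sorted=True)
                        pred = float(np.interp(x_qc[i], fit[:, 0], fit[:, 1]))
                        err += (y_qc[i] - pred) ** 2
                    if err < best_err:
                        best_frac, best_err = fr, err
                fr = best_frac
            else:
                fr = loess_frac
            fit = lowess(y_qc, x_qc, frac=fr, return_sorted=True)
            ref = _naive_median(list(y_qc))
            ok = True
            factors = {}
            for s in study_ids + qc_ids:
                d = float(np.interp(order[s], fit[:, 0], fit[:, 1]))
                if not math.isfinite(d) or d <= 0.0:
                    ok = False
                    break
                factors[s] = ref / d
            if not ok:
                continue
            for s, fac in factors.items():
                A[(s, f)] *= fac
            kept.append(f)
        feats = kept
    surviving["batch_correction"] = list(feats)

    # 5. robust-RSD variation filter on QCs
    kept = []
    for f in feats:
        rsd = _naive_rsd([A[(s, f)] for s in qc_ids])
        if not math.isnan(rsd) and rsd <= max_rsd:
            kept.append(f)
    feats = kept
    surviving["variation"] = list(feats)

    # 6. prevalence: threshold-zeroing then 100 % intraclass DR
    for f in feats:
        for s in ids:
            if A[(s, f)] < prevalence_threshold:
                A[(s, f)] = 0.0
    kept = []
    study_classes = sorted({cls[s] for s in study_ids})
    for f in feats:
        per_class = []
        for c in study_classes:
            members = [s for s in study_ids if cls[s] == c]
            per_class.append(
                sum(1 for s in members if A[(s, f)] > prevalence_threshold) / len(members)
            )
        if min(per_class) >= min_prevalence:
            kept.append(f)
    feats = kept
    surviving["prevalence"] = list(feats)

    # 7. D-ratio
    kept = []
    for f in feats:
        mq = _naive_mad([A[(s, f)] for s in qc_ids])
        ms = _naive_mad([A[(s, f)] for s in study_ids])
        if ms > 0.0 and mq / ms < max_d_ratio:
            kept.append(f)
    feats = kept
    surviving["d_ratio"] = list(feats)

    # 8. total-area normalisation over study + QC rows
    final: dict[tuple[str, str], float] = {}
    if feats:
        for s in study_ids + qc_ids:
            tot = sum(A[(s, f)] for f in feats)
            if tot <= 0.0:
                raise ValueError(f"zero total area for sample {s}")
            for f in feats:
                final[(s, f)] = A[(s, f)] / tot
    surviving["normalization"] = list(feats)
    return {"surviving": surviving, "areas": final}
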