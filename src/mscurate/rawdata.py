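"""Raw-data tools: mzML reading, chromatograms, spectrum accumulation and
wavelet-based peak/feature detection.

Peak picking follows the continuous-wavelet-transform scheme standard in
chromatography: the signal is convolved with Mexican-hat (Ricker) wavelets on
a grid of widths, local CWT maxima are linked into ridge lines across scales,
and ridges that persist and stand above the noise become peaks.  Feature
detection chains a centWave-style region-of-interest (ROI) builder with the
same CWT picker applied to each ROI trace.

All retention times are seconds; m/z tolerances are absolute Thomson by
default with a ppm mode where noted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import base64
import zlib
import xml.etree.ElementTree as ET

import numpy as np
import pandas as pd
from scipy.signal import argrelmax, fftconvolve

__all__ = [
    "MSSpectrum",
    "Chromatogram",
    "Roi",
    "PeakDescriptor",
    "read_mzml",
    "make_chromatogram",
    "accumulate_spectra",
    "detect_peaks_cwt",
    "make_rois",
    "detect_features",
    "targeted_feature_detection",
    "chromatogram_widths",
    "spectrum_widths",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MSSpectrum:
    """One mass spectrum: paired m/z / intensity arrays at an acquisition time."""

    mz: np.ndarray
    intensity: np.ndarray
    time: float = 0.0
    ms_level: int = 1
    is_centroid: bool = True

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.ms_level < 1:
            raise ValueError("ms_level must be a positive integer")


@dataclass
class Chromatogram:
    """Intensity versus retention time (seconds)."""

    time: np.ndarray
    intensity: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity must have equal length")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class Roi:
    """A contiguous m/z-stable trace across scans (centWave stage one).

    Gap scans carry intensity 0 and a NaN m/z entry in ``mz_trace``.
    """

    scan_times: np.ndarray
    mz_trace: np.ndarray
    intensity_trace: np.ndarray
    mean_mz: float

    def __post_init__(self) -> None:
        self.scan_times = np.asarray(self.scan_times, dtype=float)
        self.mz_trace = np.asarray(self.mz_trace, dtype=float)
        self.intensity_trace = np.asarray(self.intensity_trace, dtype=float)
        n = self.scan_times.size
        if self.mz_trace.size != n or self.intensity_trace.size != n:
            raise ValueError("ROI traces must have equal length")

    @property
    def n_points(self) -> int:
        return int(np.sum(~np.isnan(self.mz_trace)))


@dataclass
class PeakDescriptor:
    """One detected peak on a 1-D signal.

    For chromatographic peaks the coordinates are retention times in seconds;
    for spectral peaks they are m/z values.  ``mz`` is filled only when the
    peak comes from feature detection on an ROI.
    """

    apex_time: float
    start_time: float
    end_time: float
    area: float
    height: float
    snr: float
    mz: float | None = None

    def __post_init__(self) -> None:
        if not (self.start_time <= self.apex_time <= self.end_time):
            raise ValueError("peak bounds must satisfy start <= apex <= end")
        if self.area < 0 or self.snr < 0:
            raise ValueError("area and snr must be non-negative")


# ---------------------------------------------------------------------------
# mzML input
# ---------------------------------------------------------------------------

# mzML controlled-vocabulary accessions used while parsing
_ACC_MS_LEVEL = "MS:1000511"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def read_mzml(path: str | Path) -> list[MSSpectrum]:
    """Read an mzML file into a time-ordered list of :class:`MSSpectrum`.

    Handles uncompressed or zlib-compressed 32/64-bit float binary arrays.
    Profile spectra are accepted (flagged ``is_centroid=False``); scan start
    times are converted to seconds whatever unit the file declares.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"mzML file not found: {path}")
    spectra: list[MSSpectrum] = []
    try:
        for _, elem in ET.iterparse(str(path), events=("end",)):
            if _localname(elem.tag) == "spectrum":
                spectra.append(_parse_spectrum(elem))
                elem.clear()
    except ET.ParseError as exc:
        raise IOError(f"cannot parse mzML file {path}: {exc}") from exc
    if not spectra:
        raise IOError(f"no spectra found in {path}")
    spectra.sort(key=lambda s: s.time)
    return spectra


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(elem: ET.Element) -> dict[str, ET.Element]:
    return {
        child.get("accession", ""): child
        for child in elem
        if _localname(child.tag) == "cvParam"
    }


def _parse_spectrum(elem: ET.Element) -> MSSpectrum:
    params = _cv_params(elem)
    level = int(params[_ACC_MS_LEVEL].get("value", 1)) if _ACC_MS_LEVEL in params else 1
    centroid = _ACC_CENTROID in params or _ACC_PROFILE not in params
    time_s = 0.0
    mz = intensity = None
    for child in elem.iter():
        name = _localname(child.tag)
        if name == "scan":
            scan_params = _cv_params(child)
            if _ACC_SCAN_START in scan_params:
                p = scan_params[_ACC_SCAN_START]
                value = float(p.get("value", 0.0))
                unit = (p.get("unitName") or "minute").lower()
                time_s = value * 60.0 if unit.startswith("min") else value
        elif name == "binaryDataArray":
            kind, values = _parse_binary_array(child)
            if kind == "mz":
                mz = values
            elif kind == "intensity":
                intensity = values
    if mz is None or intensity is None:
        raise IOError("spectrum lacks m/z or intensity binary array")
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    # collapse exact duplicates so the strictly-increasing invariant holds
    if mz.size > 1 and np.any(np.diff(mz) <= 0):
        uniq, inv = np.unique(mz, return_inverse=True)
        summed = np.zeros_like(uniq)
        np.add.at(summed, inv, intensity)
        mz, intensity = uniq, summed
    return MSSpectrum(mz, intensity, time=time_s, ms_level=level, is_centroid=centroid)


def _parse_binary_array(elem: ET.Element) -> tuple[str | None, np.ndarray]:
    params = _cv_params(elem)
    dtype = np.float32 if _ACC_F32 in params else np.float64
    kind = "mz" if _ACC_MZ_ARRAY in params else "intensity" if _ACC_INT_ARRAY in params else None
    raw = b""
    for child in elem:
        if _localname(child.tag) == "binary" and child.text:
            raw = base64.b64decode(child.text.strip())
    if _ACC_ZLIB in params:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _ms1(spectra: Iterable[MSSpectrum]) -> list[MSSpectrum]:
    out = [s for s in spectra if s.ms_level == 1]
    if not out:
        raise ValueError("no MS1 spectra in input")
    return out


# ---------------------------------------------------------------------------
# chromatogram creation and spectrum accumulation
# ---------------------------------------------------------------------------

def make_chromatogram(
    spectra: Sequence[MSSpectrum],
    target_mz: float,
    tolerance: float | None = 0.005,
    aggregation: str = "sum",
    tolerance_ppm: float | None = None,
) -> Chromatogram:
    """Extracted ion chromatogram for ``target_mz`` +/- ``tolerance``.

    The window is absolute Th by default; pass ``tolerance_ppm`` instead for
    a relative window.  Each MS1 scan contributes the sum (or max) of
    intensities whose m/z falls in the closed window; scans with no matching
    point contribute 0.
    """
    if tolerance_ppm is not None:
        tolerance = target_mz * tolerance_ppm * 1e-6
    if tolerance is None or tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if aggregation not in ("sum", "max"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    ms1 = _ms1(spectra)
    lo, hi = target_mz - tolerance, target_mz + tolerance
    times = np.empty(len(ms1))
    vals = np.zeros(len(ms1))
    for i, s in enumerate(ms1):
        times[i] = s.time
        a = np.searchsorted(s.mz, lo, side="left")
        b = np.searchsorted(s.mz, hi, side="right")
        if b > a:
            window = s.intensity[a:b]
            vals[i] = window.sum() if aggregation == "sum" else window.max()
    order = np.argsort(times, kind="stable")
    return Chromatogram(times[order], vals[order], label=f"EIC {target_mz:.4f}")


def accumulate_spectra(
    spectra: Sequence[MSSpectrum],
    time_window: tuple[float, float],
    mz_merge_tolerance: float = 0.0,
) -> MSSpectrum:
    """Merge all MS1 spectra inside ``time_window`` into one spectrum.

    Points closer than ``mz_merge_tolerance`` (strict) are combined: summed
    intensity, intensity-weighted mean m/z.
    """
    lo, hi = time_window
    in_window = [s for s in _ms1(spectra) if lo <= s.time <= hi]
    if not in_window:
        raise ValueError(f"no MS1 spectra in time window [{lo}, {hi}]")
    mz = np.concatenate([s.mz for s in in_window])
    intensity = np.concatenate([s.intensity for s in in_window])
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    out_mz: list[float] = []
    out_int: list[float] = []
    i = 0
    while i < mz.size:
        j = i + 1
        m, w = mz[i], intensity[i]
        centroid = m
        while j < mz.size and mz[j] - centroid < mz_merge_tolerance:
            w_new = w + intensity[j]
            centroid = (centroid * w + mz[j] * intensity[j]) / w_new if w_new > 0 else (
                (centroid + mz[j]) / 2.0
            )
            w = w_new
            j += 1
        out_mz.append(centroid)
        out_int.append(w)
        i = j
    t = float(np.mean([s.time for s in in_window]))
    return MSSpectrum(np.asarray(out_mz), np.asarray(out_int), time=t, ms_level=1)


# ---------------------------------------------------------------------------
# CWT peak picking
# ---------------------------------------------------------------------------

def _ricker(points: int, a: float) -> np.ndarray:
    """Mexican-hat wavelet, unit-energy normalisation."""
    amp = 2.0 / (math.sqrt(3.0 * a) * math.pi**0.25)
    x = np.arange(points) - (points - 1) / 2.0
    return amp * (1.0 - (x / a) ** 2) * np.exp(-(x**2) / (2.0 * a**2))


def _cwt(y: np.ndarray, widths: np.ndarray) -> np.ndarray:
    n = y.size
    out = np.empty((widths.size, n))
    for k, w in enumerate(widths):
        m = min(10 * int(math.ceil(w)) + 1, n)
        out[k] = fftconvolve(y, _ricker(m, w), mode="same")
    return out


def chromatogram_widths(max_peak_width: float = 60.0, n: int = 10) -> np.ndarray:
    """Geometric width grid (samples) for chromatographic peak picking."""
    return np.geomspace(1.0, max(2.0, 0.5 * max_peak_width), n)


def spectrum_widths(max_peak_width: float = 10.0, n: int = 8) -> np.ndarray:
    """Geometric width grid (samples) for spectral (m/z-domain) peak picking."""
    return np.geomspace(1.0, max(1.5, 0.5 * max_peak_width), n)


def _ridge_lines(
    cwt: np.ndarray, widths: np.ndarray, gap_thresh: int = 2
) -> list[list[tuple[int, int]]]:
    """Link per-scale local maxima into ridge lines (largest scale down)."""
    n_scales = cwt.shape[0]
    maxima: list[np.ndarray] = []
    for k in range(n_scales):
        order = max(1, int(widths[k] / 4.0))
        idx = argrelmax(cwt[k], order=order)[0]
        maxima.append(idx[cwt[k][idx] > 0])
    ridges: list[dict] = []
    active: list[dict] = []
    for k in range(n_scales - 1, -1, -1):
        cols = list(maxima[k])
        used = [False] * len(cols)
        for ridge in active:
            last_col = ridge["points"][-1][1]
            tol = max(1.0, widths[k] / 2.0)
            best, best_d = -1, tol + 1
            for ci, c in enumerate(cols):
                d = abs(c - last_col)
                if not used[ci] and d <= tol and d < best_d:
                    best, best_d = ci, d
            if best >= 0:
                used[best] = True
                ridge["points"].append((k, cols[best]))
                ridge["gap"] = 0
            else:
                ridge["gap"] += 1
        for ridge in [r for r in active if r["gap"] > gap_thresh]:
            active.remove(ridge)
            ridges.append(ridge)
        for ci, c in enumerate(cols):
            if not used[ci]:
                active.append({"points": [(k, c)], "gap": 0})
    ridges.extend(active)
    return [r["points"] for r in ridges]


def _noise_level(y: np.ndarray, left: int, right: int, width: float) -> float:
    """Robust noise estimate from detrended flanks of the peak."""
    from scipy.signal import detrend

    pad = max(20, int(5 * width))
    pieces = []
    lo = max(0, left - pad)
    if left - lo >= 4:
        pieces.append(detrend(y[lo:left]))
    hi = min(y.size, right + pad)
    if hi - right >= 4:
        pieces.append(detrend(y[right:hi]))
    if not pieces or sum(p.size for p in pieces) < 8:
        # no usable flank (peak spans the signal): fall back to the robust
        # dispersion of the whole detrended signal, a conservative estimate
        flank = detrend(y)
    else:
        flank = np.concatenate(pieces)
    return 1.4826 * float(np.median(np.abs(flank - np.median(flank))))


def detect_peaks_cwt(
    signal: Chromatogram | MSSpectrum | np.ndarray,
    widths: Sequence[float] | None = None,
    min_snr: float = 3.0,
    min_length: int = 3,
) -> list[PeakDescriptor]:
    """Ridge-line CWT peak detection on a chromatogram or spectrum.

    Parameters
    ----------
    signal:
        A :class:`Chromatogram`, an :class:`MSSpectrum` (the m/z axis plays
        the role of time) or a bare intensity array (unit sample spacing).
    widths:
        Wavelet width grid in samples; defaults to :func:`chromatogram_widths`.
    min_snr:
        Minimum peak height over the robust noise level of the detrended
        flanking signal.  Noiseless signals get infinite SNR.
    min_length:
        Minimum ridge length in scales.

    Returns peaks sorted by apex coordinate.  Peak bounds are the raw-signal
    minima flanking the apex within a window set by the best-responding scale;
    the area is the trapezoidal integral above a straight baseline joining
    the boundary intensities.
    """
    if isinstance(signal, Chromatogram):
        x, y = signal.time, signal.intensity
    elif isinstance(signal, MSSpectrum):
        x, y = signal.mz, signal.intensity
    else:
        y = np.asarray(signal, dtype=float)
        x = np.arange(y.size, dtype=float)
    widths = np.asarray(
        chromatogram_widths() if widths is None else widths, dtype=float
    )
    widths = np.sort(widths)
    if y.size < widths.max():
        raise ValueError("signal shorter than the largest wavelet width")
    if np.ptp(y) == 0:
        return []
    cwt = _cwt(y, widths)
    peaks: list[PeakDescriptor] = []
    taken: list[tuple[int, int]] = []
    for ridge in _ridge_lines(cwt, widths):
        if len(ridge) < min_length:
            continue
        coefs = np.array([cwt[k, c] for k, c in ridge])
        best = int(np.argmax(coefs))
        best_scale = widths[ridge[best][0]]
        # apex: position of the ridge at its smallest scale, refined on raw y
        k_min = min(r[0] for r in ridge)
        col = [c for k, c in ridge if k == k_min][0]
        r0 = max(0, col - int(math.ceil(widths[k_min])))
        r1 = min(y.size, col + int(math.ceil(widths[k_min])) + 1)
        apex = r0 + int(np.argmax(y[r0:r1]))
        left, right = _peak_bounds(y, apex, best_scale)
        if right - left < 2:
            continue
        if any(lo <= apex <= hi for lo, hi in taken):
            continue
        baseline = np.linspace(y[left], y[right], right - left + 1)
        seg = y[left : right + 1] - baseline
        area = float(np.trapezoid(np.clip(seg, 0.0, None), x[left : right + 1]))
        height = float(y[apex] - np.interp(apex, [left, right], [y[left], y[right]]))
        if height <= 0:
            continue
        noise = _noise_level(y, left, right, best_scale)
        snr = float("inf") if noise == 0 else height / noise
        if snr < min_snr:
            continue
        taken.append((left, right))
        peaks.append(
            PeakDescriptor(
                apex_time=float(x[apex]),
                start_time=float(x[left]),
                end_time=float(x[right]),
                area=area,
                height=height,
                snr=snr,
            )
        )
    peaks.sort(key=lambda p: p.apex_time)
    return peaks


def _peak_bounds(y: np.ndarray, apex: int, scale: float) -> tuple[int, int]:
    """Boundaries: raw-signal minima within +/- 4 x best scale of the apex,
    extended outward while the signal keeps descending (so a peak wider than
    the scale window is never truncated mid-slope)."""
    w = max(2, int(math.ceil(4.0 * scale)))
    lo = max(0, apex - w)
    hi = min(y.size - 1, apex + w)
    left = lo + int(np.argmin(y[lo : apex + 1])) if apex > lo else lo
    right = apex + int(np.argmin(y[apex : hi + 1])) if hi > apex else hi
    if left == lo:
        while left > 0 and y[left - 1] < y[left]:
            left -= 1
    if right == hi:
        while right < y.size - 1 and y[right + 1] < y[right]:
            right += 1
    return left, right


# ---------------------------------------------------------------------------
# centWave-style feature detection
# ---------------------------------------------------------------------------

def make_rois(
    spectra: Sequence[MSSpectrum],
    mz_tolerance: float = 0.005,
    min_length: int = 5,
    min_intensity: float = 500.0,
    max_gap: int = 1,
    mz_tolerance_ppm: float | None = None,
) -> list[Roi]:
    """Build regions of interest by greedy scan-to-scan m/z trace extension.

    A centroid extends an open ROI when its m/z is within ``mz_tolerance`` of
    the ROI's running mean m/z (``mz_tolerance_ppm`` switches to a relative
    window); each ROI accepts at most one point per scan (the closest).  A scan without a matching point counts as a gap
    (intensity 0); more than ``max_gap`` consecutive gaps closes the ROI.
    ROIs with fewer than ``min_length`` real points, or whose maximum
    intensity never reaches ``min_intensity``, are discarded.
    """
    ms1 = _ms1(spectra)
    for s in ms1:
        if not s.is_centroid:
            raise ValueError("make_rois requires centroid spectra")
    open_rois: list[dict] = []
    finished: list[Roi] = []

    def close(roi: dict) -> None:
        # trim trailing gaps
        while roi["intensity"] and np.isnan(roi["mz"][-1]):
            for key in ("times", "mz", "intensity"):
                roi[key].pop()
        n_real = sum(0 if np.isnan(v) else 1 for v in roi["mz"])
        if n_real >= min_length and max(roi["intensity"]) >= min_intensity:
            finished.append(
                Roi(
                    np.asarray(roi["times"]),
                    np.asarray(roi["mz"]),
                    np.asarray(roi["intensity"]),
                    mean_mz=roi["sum_mz"] / n_real,
                )
            )

    for s in ms1:
        candidates: list[tuple[float, int, int]] = []
        for ri, roi in enumerate(open_rois):
            mean = roi["sum_mz"] / roi["n"]
            tol = mean * mz_tolerance_ppm * 1e-6 if mz_tolerance_ppm else mz_tolerance
            a = np.searchsorted(s.mz, mean - tol, side="left")
            b = np.searchsorted(s.mz, mean + tol, side="right")
            for pi in range(a, b):
                candidates.append((abs(s.mz[pi] - mean), ri, pi))
        candidates.sort()
        roi_used: set[int] = set()
        point_used: set[int] = set()
        for _, ri, pi in candidates:
            if ri in roi_used or pi in point_used:
                continue
            roi_used.add(ri)
            point_used.add(pi)
            roi = open_rois[ri]
            roi["times"].append(s.time)
            roi["mz"].append(float(s.mz[pi]))
            roi["intensity"].append(float(s.intensity[pi]))
            roi["sum_mz"] += float(s.mz[pi])
            roi["n"] += 1
            roi["gap"] = 0
        still_open: list[dict] = []
        for ri, roi in enumerate(open_rois):
            if ri in roi_used:
                still_open.append(roi)
                continue
            roi["gap"] += 1
            if roi["gap"] > max_gap:
                close(roi)
            else:
                roi["times"].append(s.time)
                roi["mz"].append(float("nan"))
                roi["intensity"].append(0.0)
                still_open.append(roi)
        open_rois = still_open
        for pi in range(s.mz.size):
            if pi not in point_used:
                open_rois.append(
                    {
                        "times": [s.time],
                        "mz": [float(s.mz[pi])],
                        "intensity": [float(s.intensity[pi])],
                        "sum_mz": float(s.mz[pi]),
                        "n": 1,
                        "gap": 0,
                    }
                )
    for roi in open_rois:
        close(roi)
    finished.sort(key=lambda r: (r.mean_mz, r.scan_times[0]))
    return finished


_FEATURE_COLUMNS = ["mz", "rt", "area", "height", "snr"]


def detect_features(
    spectra: Sequence[MSSpectrum],
    roi_params: dict | None = None,
    cwt_params: dict | None = None,
) -> pd.DataFrame:
    """centWave-style untargeted feature detection.

    ROIs are built with :func:`make_rois`, the CWT picker runs on each ROI's
    intensity trace (zero-padded at both ends so edge peaks see a baseline),
    and each retained peak becomes a feature row with intensity-weighted mean
    m/z within the peak bounds.
    """
    roi_params = dict(roi_params or {})
    cwt_params = dict(cwt_params or {})
    rois = make_rois(spectra, **roi_params)
    rows = []
    for roi in rois:
        rows.extend(_roi_peaks(roi, cwt_params))
    out = pd.DataFrame(rows, columns=_FEATURE_COLUMNS)
    return out.sort_values(["mz", "rt"]).reset_index(drop=True)


def _roi_peaks(roi: Roi, cwt_params: dict) -> list[dict]:
    y = roi.intensity_trace
    t = roi.scan_times
    if t.size < 2:
        return []
    dt = float(np.median(np.diff(t)))
    pad = 5
    t_pad = np.concatenate(
        [t[0] - dt * np.arange(pad, 0, -1), t, t[-1] + dt * np.arange(1, pad + 1)]
    )
    y_pad = np.concatenate([np.zeros(pad), y, np.zeros(pad)])
    params = dict(cwt_params)
    widths = params.pop("widths", None)
    if widths is None:
        widths = chromatogram_widths(max_peak_width=max(4.0, y.size))
    widths = np.asarray(widths, dtype=float)
    widths = widths[widths <= y_pad.size]
    if widths.size == 0:
        return []
    chrom = Chromatogram(t_pad, y_pad, label=f"ROI {roi.mean_mz:.4f}")
    rows = []
    for peak in detect_peaks_cwt(chrom, widths=widths, **params):
        sel = (t >= peak.start_time) & (t <= peak.end_time) & ~np.isnan(roi.mz_trace)
        if not sel.any():
            continue
        w = roi.intensity_trace[sel]
        mz = float(np.average(roi.mz_trace[sel], weights=w)) if w.sum() > 0 else roi.mean_mz
        rows.append(
            {
                "mz": mz,
                "rt": peak.apex_time,
                "area": peak.area,
                "height": peak.height,
                "snr": peak.snr,
            }
        )
    return rows


def targeted_feature_detection(
    spectra: Sequence[MSSpectrum],
    targets: Sequence[dict],
    mz_tolerance: float = 0.005,
    cwt_params: dict | None = None,
) -> pd.DataFrame:
    """Extract the best chromatographic peak for each known target.

    ``targets`` is a sequence of dicts with keys ``name``, ``mz`` and optional
    ``rt_min`` / ``rt_max``.  For each target an EIC is built and picked; the
    highest-area peak inside the retention-time window (or overall when no
    window is given) is reported.  Targets with no acceptable peak yield an
    explicit row with ``detected = False``.
    """
    if not targets:
        raise ValueError("targets must be non-empty")
    cwt_params = dict(cwt_params or {})
    rows = []
    for tgt in targets:
        name = tgt.get("name", f"mz{tgt['mz']:.4f}")
        eic = make_chromatogram(spectra, tgt["mz"], mz_tolerance)
        widths = cwt_params.get("widths")
        usable = eic.intensity.size >= np.max(
            np.asarray(widths if widths is not None else chromatogram_widths())
        )
        peaks = detect_peaks_cwt(eic, **cwt_params) if usable else []
        lo = tgt.get("rt_min", -math.inf)
        hi = tgt.get("rt_max", math.inf)
        in_window = [p for p in peaks if lo <= p.apex_time <= hi]
        if in_window:
            best = max(in_window, key=lambda p: p.area)
            sel = (eic.time >= best.start_time) & (eic.time <= best.end_time)
            w = eic.intensity[sel]
            rows.append(
                {
                    "name": name,
                    "detected": True,
                    "mz": _eic_weighted_mz(spectra, tgt["mz"], mz_tolerance, best),
                    "rt": best.apex_time,
                    "area": best.area,
                    "height": best.height,
                    "snr": best.snr,
                }
            )
        else:
            rows.append(
                {
                    "name": name,
                    "detected": False,
                    "mz": float("nan"),
                    "rt": float("nan"),
                    "area": float("nan"),
                    "height": float("nan"),
                    "snr": float("nan"),
                }
            )
    return pd.DataFrame(rows).set_index("name")


def _eic_weighted_mz(
    spectra: Sequence[MSSpectrum], target_mz: float, tol: float, peak: PeakDescriptor
) -> float:
    """Intensity-weighted mean observed m/z across the peak's scans."""
    num = den = 0.0
    for s in _ms1(spectra):
        if not (peak.start_time <= s.time <= peak.end_time):
            continue
        a = np.searchsorted(s.mz, target_mz - tol, side="left")
        b = np.searchsorted(s.mz, target_mz + tol, side="right")
        if b > a:
            num += float(np.dot(s.mz[a:b], s.intensity[a:b]))
            den += float(np.sum(s.intensity[a:b]))
    return num / den if den > 0 else target_mz
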