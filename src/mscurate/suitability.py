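"""System-suitability references and PCA-based quality assessment.

A system-suitability sample (SSS) is a mixture of known chemical standards
injected repeatedly; the replicate injections define, per analyte, the mean
and dispersion of m/z, retention time and peak area.  Later injections are
checked against closed acceptance intervals: mean +/- k*SD for m/z and area
(default k = 2) and mean +/- a fixed tolerance for retention time (default
3 s).  PCA score computation supports run-order colouring to make signal
drift visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datamodel import DataMatrix

__all__ = [
    "SuitabilityReference",
    "build_reference",
    "check_injection",
    "pca_scores",
]


@dataclass
class SuitabilityReference:
    """Per-analyte acceptance intervals from replicate SSS injections.

    ``table`` is indexed by analyte name with columns ``mean_mz, sd_mz,
    mean_rt, rt_tolerance, mean_area, sd_area``; ``k_sd`` scales the SD
    intervals for m/z and area.
    """

    table: pd.DataFrame
    k_sd: float = 2.0
    n_replicates: int = 0

    def interval(self, analyte: str, quantity: str) -> tuple[float, float]:
        row = self.table.loc[analyte]
        if quantity == "rt":
            return row["mean_rt"] - row["rt_tolerance"], row["mean_rt"] + row["rt_tolerance"]
        mean, sd = row[f"mean_{quantity}"], row[f"sd_{quantity}"]
        return mean - self.k_sd * sd, mean + self.k_sd * sd

    def to_csv(self, path) -> None:
        self.table.assign(k_sd=self.k_sd, n_replicates=self.n_replicates).to_csv(
            path, index_label="analyte"
        )

    @classmethod
    def from_csv(cls, path) -> "SuitabilityReference":
        t = pd.read_csv(path, index_col="analyte")
        k_sd = float(t.pop("k_sd").iloc[0]) if "k_sd" in t else 2.0
        n = int(t.pop("n_replicates").iloc[0]) if "n_replicates" in t else 0
        return cls(t, k_sd=k_sd, n_replicates=n)


def build_reference(
    replicate_features: Sequence[pd.DataFrame],
    k_sd: float = 2.0,
    rt_tol: float = 3.0,
) -> SuitabilityReference:
    """Build acceptance intervals from replicate SSS feature tables.

    Each table is indexed by analyte name with columns ``mz, rt, area`` (the
    shape produced by targeted feature detection).  Every analyte must be
    detected in every replicate; the reference stores the means, the standard
    deviations of m/z and area, and the fixed rt tolerance.
    """
    if len(replicate_features) < 2:
        raise ValueError("at least 2 replicate injections are required")
    analytes = list(replicate_features[0].index)
    for i, rep in enumerate(replicate_features):
        missing = [a for a in analytes if a not in rep.index]
        if "detected" in rep.columns:
            missing += [a for a in analytes if a in rep.index and not rep.at[a, "detected"]]
        if set(rep.index) != set(analytes) or missing:
            raise ValueError(
                f"replicate {i} does not cover all analytes (missing: {sorted(set(missing))})"
            )
    rows = []
    for a in analytes:
        mz = np.array([float(rep.at[a, "mz"]) for rep in replicate_features])
        rt = np.array([float(rep.at[a, "rt"]) for rep in replicate_features])
        area = np.array([float(rep.at[a, "area"]) for rep in replicate_features])
        rows.append(
            {
                "mean_mz": mz.mean(),
                "sd_mz": mz.std(ddof=1),
                "mean_rt": rt.mean(),
                "rt_tolerance": rt_tol,
                "mean_area": area.mean(),
                "sd_area": area.std(ddof=1),
            }
        )
    table = pd.DataFrame(rows, index=pd.Index(analytes, name="analyte"))
    return SuitabilityReference(table, k_sd=k_sd, n_replicates=len(replicate_features))


def check_injection(features: pd.DataFrame, reference: SuitabilityReference) -> pd.DataFrame:
    """Check one injection's analyte measurements against the reference.

    ``features`` is indexed by analyte with columns ``mz, rt, area`` and an
    optional ``detected`` flag.  Returns a table with the measured values,
    one closed-interval pass flag per quantity and the overall conjunction;
    analytes missing or flagged undetected fail all three checks.
    """
    rows = []
    for a in reference.table.index:
        present = a in features.index and (
            "detected" not in features.columns or bool(features.at[a, "detected"])
        )
        row = {"analyte": a}
        if not present:
            row.update(
                {q: float("nan") for q in ("mz", "rt", "area")},
                mz_pass=False,
                rt_pass=False,
                area_pass=False,
            )
        else:
            for q in ("mz", "rt", "area"):
                val = float(features.at[a, q])
                lo, hi = reference.interval(a, q)
                row[q] = val
                row[f"{q}_pass"] = bool(lo <= val <= hi)
        row["overall_pass"] = row["mz_pass"] and row["rt_pass"] and row["area_pass"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("analyte")


def pca_scores(
    matrix: DataMatrix | pd.DataFrame,
    n_components: int = 2,
    scaling: str = "none",
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA scores for drift assessment and sample-cluster inspection.

    The matrix is column-mean-centred, optionally autoscaled (unit variance)
    or Pareto-scaled (sqrt of the SD), and decomposed by SVD.  Component signs
    are fixed so that the largest-magnitude loading of each component is
    positive, making score plots reproducible.  Returns (scores, explained
    variance fractions); when called on a :class:`DataMatrix` the scores
    carry the run order for drift colouring.
    """
    if isinstance(matrix, DataMatrix):
        data = matrix.areas
        order = matrix.sample_meta["order"]
    else:
        data = matrix
        order = None
    X = data.to_numpy(dtype=float)
    if X.shape[0] <= n_components:
        raise ValueError("n_components must be smaller than the number of samples")
    sd = X.std(axis=0, ddof=1)
    if np.all(sd == 0):
        raise ValueError("constant matrix has no variance to decompose")
    Xc = X - X.mean(axis=0)
    if scaling == "autoscale":
        Xc = Xc / np.where(sd == 0, 1.0, sd)
    elif scaling == "pareto":
        Xc = Xc / np.where(sd == 0, 1.0, np.sqrt(sd))
    elif scaling != "none":
        raise ValueError(f"unknown scaling {scaling!r}")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(Xc)
    # deterministic sign: largest-|loading| positive per component
    for j in range(scores.shape[1]):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    cols = [f"PC{j + 1}" for j in range(scores.shape[1])]
    out = pd.DataFrame(scores, index=data.index, columns=cols)
    if order is not None:
        out["order"] = order
    return out, pca.explained_variance_ratio_.copy()
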