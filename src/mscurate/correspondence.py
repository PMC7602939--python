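"""Cluster-based feature correspondence across samples.

Feature observations (sample, m/z, rt, area) from several injections are
matched into data-matrix columns by density-based clustering in tolerance-
standardised (m/z, rt) coordinates.  The cited description of the original
correspondence procedure is limited to "cluster-based", so the scheme here is
a documented standard choice: DBSCAN with eps = 1 in standardised space and a
two-point neighbourhood, per-sample duplicate resolution by maximum area, and
a minimum sample-coverage fraction.  Like any untested correspondence step it
should be validated on known standards before untargeted use.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .datamodel import DataMatrix, SampleMapping

__all__ = ["match_features"]

_REQUIRED = ("sample_id", "mz", "rt", "area")


def match_features(
    observations: pd.DataFrame,
    mz_tolerance: float = 0.01,
    rt_tolerance: float = 5.0,
    min_fraction: float = 0.5,
    mapping: SampleMapping | None = None,
    sample_meta: pd.DataFrame | None = None,
) -> tuple[DataMatrix, pd.DataFrame]:
    """Match per-sample feature observations into an N x K data matrix.

    Parameters
    ----------
    observations:
        DataFrame with columns ``sample_id, mz, rt, area`` (one row per
        detected feature per sample).
    mz_tolerance, rt_tolerance:
        Scale of one standardised unit per coordinate; two observations closer
        than roughly one tolerance in both coordinates cluster together.
    min_fraction:
        Clusters detected in fewer than this fraction of samples are dropped.
    mapping, sample_meta:
        Optional sample metadata for the resulting container; defaults to a
        single study class in observation order.

    Returns (matrix, duplicates) where ``duplicates`` logs same-sample
    observations resolved by keeping the higher area (ties: earlier rt).
    """
    for col in _REQUIRED:
        if col not in observations.columns:
            raise ValueError(f"observations lack required column {col!r}")
    if len(observations) == 0:
        raise ValueError("no observations given")
    samples = sorted(set(observations["sample_id"]))
    if len(samples) < 2:
        raise ValueError("feature correspondence requires observations from >= 2 samples")
    if mz_tolerance <= 0 or rt_tolerance <= 0:
        raise ValueError("tolerances must be positive")

    obs = observations.reset_index(drop=True).copy()
    coords = np.column_stack(
        [obs["mz"].to_numpy() / mz_tolerance, obs["rt"].to_numpy() / rt_tolerance]
    )
    labels = DBSCAN(eps=1.0, min_samples=2).fit_predict(coords)
    obs["cluster"] = labels
    obs = obs[obs["cluster"] >= 0]

    dup_rows = []
    kept_idx = []
    for (label, sid), grp in obs.groupby(["cluster", "sample_id"], sort=True):
        if len(grp) == 1:
            kept_idx.append(grp.index[0])
            continue
        best = grp.sort_values(["area", "rt"], ascending=[False, True]).index[0]
        kept_idx.append(best)
        for i in grp.index:
            if i != best:
                dup_rows.append(obs.loc[i, ["sample_id", "mz", "rt", "area"]].to_dict() | {"cluster": label})
    obs = obs.loc[sorted(kept_idx)]

    n_samples = len(samples)
    clusters = []
    for label, grp in obs.groupby("cluster", sort=True):
        if len(grp) / n_samples < min_fraction:
            continue
        clusters.append(
            {
                "label": label,
                "mz": float(grp["mz"].median()),
                "rt": float(grp["rt"].median()),
                "members": grp,
            }
        )
    clusters.sort(key=lambda c: (c["mz"], c["rt"]))
    if not clusters:
        raise ValueError("no feature cluster passed the min_fraction requirement")

    feature_ids = [f"FT{i + 1:04d}" for i in range(len(clusters))]
    areas = pd.DataFrame(0.0, index=pd.Index(samples, name="id"), columns=feature_ids)
    for fid, c in zip(feature_ids, clusters):
        for _, row in c["members"].iterrows():
            areas.at[row["sample_id"], fid] = float(row["area"])
    feature_meta = pd.DataFrame(
        {"mz": [c["mz"] for c in clusters], "rt": [c["rt"] for c in clusters]},
        index=pd.Index(feature_ids, name="id"),
    )
    if sample_meta is None:
        sample_meta = pd.DataFrame(
            {
                "class": "study",
                "order": np.arange(1, n_samples + 1),
                "batch": 1,
                "type": "study",
            },
            index=areas.index,
        )
    if mapping is None:
        mapping = SampleMapping(
            study=frozenset(sample_meta.loc[sample_meta["type"] == "study", "class"]),
            qc=frozenset(sample_meta.loc[sample_meta["type"] == "qc", "class"]),
            blank=frozenset(sample_meta.loc[sample_meta["type"] == "blank", "class"]),
        )
    matrix = DataMatrix(areas, sample_meta, feature_meta, mapping)
    duplicates = pd.DataFrame(dup_rows, columns=["sample_id", "mz", "rt", "area", "cluster"])
    return matrix, duplicates
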