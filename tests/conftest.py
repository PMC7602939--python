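import numpy as np
import pandas as pd
import pytest

from mscurate import DataMatrix, SampleMapping


def build_matrix(
    values,
    classes,
    types=None,
    orders=None,
    batch=1,
    mz=None,
    rt=None,
    mapping=None,
    sample_ids=None,
    feature_ids=None,
):
    """Assemble a DataMatrix from plain arrays for tests."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    sample_ids = sample_ids or [f"S{i + 1}" for i in range(n)]
    feature_ids = feature_ids or [f"F{j + 1}" for j in range(k)]
    if mapping is None:
        by_type = {"study": set(), "qc": set(), "blank": set()}
        types = types or ["study"] * n
        for c, t in zip(classes, types):
            if t in by_type:
                by_type[t].add(c)
        mapping = SampleMapping.from_dict(by_type)
    areas = pd.DataFrame(values, index=sample_ids, columns=feature_ids)
    sample_meta = pd.DataFrame(
        {
            "class": classes,
            "order": orders if orders is not None else np.arange(1, n + 1),
            "batch": batch,
        },
        index=areas.index,
    )
    if types is not None:
        sample_meta["type"] = types
    feature_meta = pd.DataFrame(
        {
            "mz": mz if mz is not None else np.linspace(100, 900, k),
            "rt": rt if rt is not None else np.linspace(100, 900, k),
        },
        index=areas.columns,
    )
    return DataMatrix(areas, sample_meta, feature_meta, mapping)


def drift_batch(seed, noise_sd, n_injections=40, qc_every=5, n_features=10, drift_span=0.4):
    """A single analytical batch with planted multiplicative linear drift.

    QCs sit at every ``qc_every``-th injection plus the final one (so the QC
    template brackets every study sample).  Returns (matrix, drift-free true
    areas, drift curve g, QC-median reference level of g).
    """
    rng = np.random.default_rng(seed)
    ids, classes, types = [], [], []
    for i in range(1, n_injections + 1):
        if (i - 1) % qc_every == 0 or i == n_injections:
            ids.append(f"qc{i}")
            classes.append("pooled_qc")
            types.append("qc")
        else:
            ids.append(f"s{i}")
            classes.append("study")
            types.append("study")
    orders = np.arange(1, n_injections + 1)
    g = 1.0 + drift_span * (orders - 1) / (n_injections - 1)
    scale = np.exp(rng.normal(np.log(1000), 0.5, n_features))
    x = np.outer(np.ones(n_injections), scale)
    study_mask = np.array(types) == "study"
    x[study_mask] *= np.exp(rng.normal(0, 0.2, (study_mask.sum(), n_features)))
    eps = rng.normal(0, noise_sd, x.shape) if noise_sd > 0 else np.zeros_like(x)
    observed = x * g[:, None] * (1 + eps)
    matrix = build_matrix(
        observed, classes, types, orders=orders, sample_ids=ids,
        mapping=SampleMapping(frozenset({"study"}), frozenset({"pooled_qc"})),
    )
    ref_level = float(np.median(g[np.array(types) == "qc"]))
    return matrix, x, g, ref_level


@pytest.fixture
def worked_qc_study_matrix():
    """QC areas {100,101,102}, study areas {50,100,150,200} for one feature."""
    values = np.array([[100.0], [101.0], [102.0], [50.0], [100.0], [150.0], [200.0]])
    classes = ["qc"] * 3 + ["study"] * 4
    types = ["qc"] * 3 + ["study"] * 4
    return build_matrix(values, classes, types)
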