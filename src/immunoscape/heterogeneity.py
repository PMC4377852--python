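"""Intratumoral heterogeneity from cancer-cell-fraction (CCF) tables.

Each mutation in a tumor carries a CCF in (0, 1] — the fraction of
cancer cells harboring it.  A fully clonal tumor piles all mass at 1;
subclonal structure spreads mass to lower fractions.  The heterogeneity
statistic is the exact area under the empirical CDF of the tumor's CCFs
over [0, 1]: 0 for a fully clonal tumor, growing as mass moves away
from 1.  Tumors are compared by the Kolmogorov-Smirnov D statistic
between their CCF distributions and clustered into clonal groups.

CCF estimation (purity/ploidy-aware callers) is upstream of this
module; the importer only validates ranges.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering

__all__ = [
    "heterogeneity_score",
    "pairwise_ks",
    "cluster_clonal_groups",
    "read_ccf_tables",
    "write_ccf_tables",
]


def _validate_ccf(ccfs) -> np.ndarray:
    x = np.asarray(ccfs, dtype=float)
    if x.size == 0:
        raise ValueError("CCF table is empty")
    if (x <= 0).any() or (x > 1).any():
        raise ValueError("CCF values must lie in (0, 1]")
    return x


def heterogeneity_score(ccfs) -> float:
    """Exact area under the empirical CDF of the CCFs over [0, 1].

    The empirical CDF is a right-continuous step function; the integral
    is the sum of rectangle areas between consecutive sorted values
    (no numerical quadrature).  All CCFs equal to 1 give 0; a point
    mass at c gives 1 - c.
    """
    x = np.sort(_validate_ccf(ccfs))
    n = x.size
    # F = i/n on [x_i, x_{i+1}); F = 1 on [x_n, 1]
    steps = np.arange(1, n) / n
    area = float(np.sum(steps * np.diff(x))) + (1.0 - float(x[-1]))
    return area


def ks_d(a, b) -> float:
    """Two-sample Kolmogorov-Smirnov D: sup_x |F_a(x) - F_b(x)|."""
    a = np.sort(_validate_ccf(a))
    b = np.sort(_validate_ccf(b))
    pooled = np.concatenate((a, b))
    fa = np.searchsorted(a, pooled, side="right") / a.size
    fb = np.searchsorted(b, pooled, side="right") / b.size
    return float(np.max(np.abs(fa - fb)))


def pairwise_ks(tables: dict[str, np.ndarray] | pd.Series) -> pd.DataFrame:
    """Symmetric KS-D matrix across tumors."""
    if isinstance(tables, pd.Series):
        tables = tables.to_dict()
    ids = list(tables)
    if len(ids) < 2:
        raise ValueError("need at least 2 tumors")
    sorted_vals = {t: np.sort(_validate_ccf(v)) for t, v in tables.items()}
    d = pd.DataFrame(0.0, index=ids, columns=ids)
    for i, ti in enumerate(ids):
        for tj in ids[i + 1 :]:
            val = ks_d(sorted_vals[ti], sorted_vals[tj])
            d.loc[ti, tj] = d.loc[tj, ti] = val
    return d


def cluster_clonal_groups(
    d_matrix: pd.DataFrame, k: int = 4, method: str = "ward_rows"
) -> pd.Series:
    """Group tumors by clonal architecture from the KS-D matrix.

    Default (``ward_rows``): each tumor's row of the D matrix is its
    feature vector; agglomerative clustering with Ward linkage and
    Euclidean metric, cut at ``k`` groups.  Alternative (``average_d``):
    the D matrix itself is the precomputed distance, average linkage.
    """
    n = len(d_matrix)
    if k < 1 or k > n:
        raise ValueError(f"k={k} outside [1, {n}]")
    if method == "ward_rows":
        model = AgglomerativeClustering(n_clusters=k, linkage="ward")
        import warnings

        with warnings.catch_warnings():
            # rows of the D matrix are deliberately used as feature vectors
            warnings.simplefilter("ignore")
            labels = model.fit_predict(d_matrix.to_numpy())
    elif method == "average_d":
        model = AgglomerativeClustering(
            n_clusters=k, linkage="average", metric="precomputed"
        )
        labels = model.fit_predict(d_matrix.to_numpy())
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.Series(labels, index=d_matrix.index, name="clonal_group")


def read_ccf_tables(path) -> dict[str, np.ndarray]:
    """Read a CCF TSV (tumor_id, mutation_id, ccf) into per-tumor arrays."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for tumor, sub in df.groupby("tumor_id"):
        out[str(tumor)] = _validate_ccf(sub["ccf"].to_numpy())
    return out


def write_ccf_tables(tables: dict[str, np.ndarray], path) -> None:
    rows = []
    for tumor, vals in tables.items():
        for i, c in enumerate(np.asarray(vals, dtype=float)):
            rows.append((tumor, f"{tumor}_m{i}", c))
    pd.DataFrame(rows, columns=["tumor_id", "mutation_id", "ccf"]).to_csv(
        path, sep="\t", index=False
    )
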