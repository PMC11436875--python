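"""Cluster-labeling agreement metrics: homogeneity, completeness, V-measure,
per-cluster purity, and replicate-membership correlation.

Let ``a_ck`` be the number of cells with ground-truth class ``c`` (e.g.
dissection/FACS label) assigned to cluster ``k``, and ``N`` the total cell
count. With Shannon entropies in nats and the convention ``0 log 0 = 0``:

    h = 1                       if H(C|K) = 0
      = 1 - H(C|K) / H(C)       otherwise
    c = 1                       if H(K|C) = 0
      = 1 - H(K|C) / H(K)       otherwise
    V_beta = (1 + beta) h c / (beta h + c)

``V_beta`` is the beta-weighted harmonic mean of homogeneity and
completeness (beta = 1 gives the standard V-measure). The ratios are
invariant to the entropy log base; the stored raw entropies are in nats.

Per-cluster purity is the largest class fraction within the cluster,
bounded in [1/|C|, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClusterLabeling",
    "VMeasureResult",
    "PurityResult",
    "contingency",
    "v_measure",
    "purity",
    "replicate_membership_correlation",
]


@dataclass
class ClusterLabeling:
    """Class x cluster contingency table ``a_ck``."""

    table: pd.DataFrame  # rows: classes c, columns: clusters k

    def __post_init__(self) -> None:
        if (self.table.to_numpy() < 0).any():
            raise ValueError("negative contingency counts")

    @property
    def n(self) -> int:
        return int(self.table.to_numpy().sum())


@dataclass(frozen=True)
class VMeasureResult:
    h: float
    c: float
    v_beta: float
    beta: float
    entropy_c: float
    entropy_k: float
    entropy_c_given_k: float
    entropy_k_given_c: float


@dataclass(frozen=True)
class PurityResult:
    p_k: dict[str, float]


def contingency(classes: Sequence, clusters: Sequence) -> ClusterLabeling:
    """Cross-tabulate class labels against cluster labels."""
    if len(classes) != len(clusters):
        raise ValueError("label vectors differ in length")
    if len(classes) == 0:
        raise ValueError("empty labeling")
    table = pd.crosstab(pd.Series(classes, name="class"),
                        pd.Series(clusters, name="cluster"))
    return ClusterLabeling(table)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _conditional_entropy(a: np.ndarray, axis: int) -> float:
    """H(rows|cols) for axis=0: -sum_ck (a_ck/N) log(a_ck / colsum_k)."""
    n = a.sum()
    marg = np.broadcast_to(a.sum(axis=axis, keepdims=True), a.shape)
    mask = a > 0  # 0 log 0 := 0
    terms = np.zeros_like(a)
    terms[mask] = (a[mask] / n) * np.log(a[mask] / marg[mask])
    return float(-terms.sum())


def v_measure(cl: ClusterLabeling, beta: float = 1.0) -> VMeasureResult:
    """Homogeneity, completeness, and their beta-weighted harmonic mean."""
    a = cl.table.to_numpy(dtype=float)
    if a.sum() < 1:
        raise ValueError("empty contingency table")
    h_c = _entropy(a.sum(axis=1) / a.sum())
    h_k = _entropy(a.sum(axis=0) / a.sum())
    h_c_given_k = _conditional_entropy(a, axis=0)
    h_k_given_c = _conditional_entropy(a, axis=1)
    tol = 1e-12
    h = 1.0 if h_c_given_k <= tol else 1.0 - h_c_given_k / h_c
    c = 1.0 if h_k_given_c <= tol else 1.0 - h_k_given_c / h_k
    if h + c == 0:
        v = 0.0
    else:
        v = (1 + beta) * h * c / (beta * h + c)
    return VMeasureResult(h, c, v, beta, h_c, h_k, h_c_given_k, h_k_given_c)


def purity(cl: ClusterLabeling) -> PurityResult:
    """Per-cluster maximum class fraction.

    The denominator is the cluster's size (sum of ``a_ck`` over classes) —
    the only reading bounded in [1/|C|, 1].
    """
    a = cl.table
    sizes = a.sum(axis=0)
    if (sizes == 0).any():
        raise ValueError("empty cluster in contingency table")
    return PurityResult({str(k): float(a[k].max() / sizes[k]) for k in a.columns})


def replicate_membership_correlation(proportions: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of cluster-membership proportions.

    ``proportions`` rows are replicates, columns clusters (shared universe).
    A zero-variance replicate vector is an error.
    """
    arr = proportions.to_numpy(dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least two replicates")
    if np.any(arr.std(axis=1) == 0):
        raise ValueError("zero-variance membership vector")
    corr = np.corrcoef(arr)
    return pd.DataFrame(corr, index=proportions.index, columns=proportions.index)
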