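"""Weighted coexpression submodule detection across venom-type treatments.

The stages mirror standard weighted-network practice: a variance-stabilising
log transform and dispersion-based transcript filter, Pearson correlation, a
soft-threshold adjacency (``|cor|^beta``, beta = 10 by default), the
topological overlap measure (TOM), and average-linkage clustering of
``1 - TOM`` with the cut height chosen by mean silhouette.  Minimum module
size 1 keeps even single-transcript modules, matching a deliberately
permissive screen on small designs.  Module 0 is the unassigned background.

Correlations estimated from very few samples are noise; the stage refuses to
run below 4 samples and warns below 8.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score
from statsmodels.nonparametric.smoothers_lowess import lowess

from .exceptions import ValidationError

__all__ = [
    "NetworkConfig",
    "transform_and_filter",
    "adjacency",
    "topological_overlap",
    "detect_modules",
    "module_profiles",
]


@dataclass
class NetworkConfig:
    correlation: str = "pearson"
    beta: float = 10.0
    signed: bool = False
    min_module_size: int = 1
    filter_quantile: float = 0.5  # fraction of transcripts retained

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValidationError("beta must be >= 1")
        if self.min_module_size < 1:
            raise ValidationError("min_module_size must be >= 1")
        if not 0 < self.filter_quantile <= 1:
            raise ValidationError("filter_quantile must be in (0, 1]")
        if self.correlation != "pearson":
            raise ValidationError("only pearson correlation is supported")


def transform_and_filter(
    expr: pd.DataFrame, config: NetworkConfig | None = None
) -> pd.DataFrame:
    """log2(TPM + 1) transform, then keep the most over-dispersed transcripts.

    Per transcript the variance of the transformed values is regressed on
    the mean (lowess trend); transcripts are ranked by the residual, which
    decouples dispersion from expression level, and the top
    ``filter_quantile`` fraction is retained.  Zero-variance transcripts are
    always dropped.
    """
    config = config or NetworkConfig()
    if expr.shape[1] < 4:
        raise ValidationError("coexpression needs at least 4 samples")
    if expr.shape[1] < 8:
        warnings.warn(
            f"only {expr.shape[1]} samples: correlations will be noisy", stacklevel=2
        )
    t = np.log2(expr.astype(float) + 1.0)
    mean = t.mean(axis=1)
    var = t.var(axis=1, ddof=1)
    keep = var > 0
    t, mean, var = t[keep], mean[keep], var[keep]
    if t.empty:
        return t
    if mean.nunique() > 2:
        trend = lowess(var.to_numpy(), mean.to_numpy(), frac=0.5,
                       return_sorted=False)
    else:
        trend = np.full(len(var), var.mean())
    residual = var.to_numpy() - trend
    n_keep = max(1, int(round(config.filter_quantile * len(t))))
    order = np.argsort(-residual, kind="stable")
    retained = t.index[np.sort(order[:n_keep])]
    return t.loc[retained]


def adjacency(expr_t: pd.DataFrame, config: NetworkConfig | None = None) -> pd.DataFrame:
    """Soft-threshold adjacency from Pearson correlations.

    Unsigned (default): ``|cor|^beta``; signed: ``((1 + cor)/2)^beta``.
    The diagonal is zeroed (no self-adjacency).
    """
    config = config or NetworkConfig()
    if expr_t.shape[1] < 3:
        raise ValidationError("correlation needs at least 3 samples")
    values = expr_t.to_numpy(float)
    if (values.std(axis=1) == 0).any():
        raise ValidationError("zero-variance transcript: run transform_and_filter first")
    cor = np.corrcoef(values)
    a = np.abs(cor) ** config.beta if not config.signed else ((1 + cor) / 2) ** config.beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=expr_t.index, columns=expr_t.index)


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap similarity.

    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``k`` the adjacency row sums; diagonal 1.  High TOM means two nodes are
    both directly linked and share neighbours.
    """
    a = adj.to_numpy(float)
    if not np.allclose(a, a.T):
        raise ValidationError("adjacency must be symmetric")
    if (a < 0).any() or (a > 1).any():
        raise ValidationError("adjacency must lie in [0, 1]")
    if not np.allclose(np.diag(a), 0):
        raise ValidationError("adjacency diagonal must be zero")
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


_CUT_HEIGHTS = np.arange(0.05, 0.951, 0.05)


def detect_modules(
    tom: pd.DataFrame, config: NetworkConfig | None = None
) -> pd.Series:
    """Cluster ``1 - TOM`` by average linkage; cut height by mean silhouette.

    Candidate cut heights 0.05..0.95 (step 0.05) are scored by the mean
    silhouette of the induced partition on the ``1 - TOM`` distance; the
    best-scoring partition wins.  Clusters smaller than ``min_module_size``
    are relabelled 0 (background); surviving modules are renumbered 1..K by
    decreasing size.  Returns transcript -> module id.
    """
    config = config or NetworkConfig()
    ids = tom.index
    n = len(ids)
    if n == 1:
        return pd.Series([1 if config.min_module_size <= 1 else 0], index=ids,
                         name="module")
    d = 1.0 - tom.to_numpy(float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, None)
    z = linkage(squareform(d, checks=False), method="average")
    best_labels, best_score = None, -np.inf
    for h in _CUT_HEIGHTS:
        labels = fcluster(z, t=h, criterion="distance")
        k = len(np.unique(labels))
        if k < 2 or k >= n:
            continue
        score = silhouette_score(d, labels, metric="precomputed")
        if score > best_score:
            best_labels, best_score = labels, score
    if best_labels is None:
        # every cut is trivial: all transcripts cohere as a single module
        best_labels = np.ones(n, dtype=int)
    modules = pd.Series(best_labels, index=ids, name="module")
    sizes = modules.value_counts()
    keep = sizes[sizes >= config.min_module_size].index
    renumber = {old: i + 1 for i, old in enumerate(sizes.loc[keep].index)}
    return modules.map(lambda m: renumber.get(m, 0)).rename("module")


def module_profiles(
    assignment: pd.Series,
    expr_t: pd.DataFrame,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """Mean transformed expression per module per treatment.

    ``samples`` needs ``sample_id`` and ``venom_type`` columns covering every
    expression column.  Module 0, when present, is the unassigned background
    and is reported like any other row; callers should flag it as such.
    """
    meta = samples.set_index("sample_id") if "sample_id" in samples.columns else samples
    missing = [c for c in expr_t.columns if c not in meta.index]
    if missing or meta.loc[list(expr_t.columns), "venom_type"].isna().any():
        raise ValidationError(f"samples without treatment: {missing}")
    treatment = meta.loc[list(expr_t.columns), "venom_type"]
    by_treatment = expr_t.T.groupby(treatment.values).mean().T
    return by_treatment.groupby(assignment).mean().rename_axis("module")
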