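"""Simplified negative-binomial Wald differential expression.

A deliberately transparent "deseq2-like (simplified)" stage: median-of-ratios
size factors, method-of-moments NB dispersion, a delta-method Wald test on
the log2 fold change, and Benjamini-Hochberg adjustment.  Dispersion
shrinkage, outlier (Cook's) filtering and independent filtering are NOT
implemented; the stage is meant for planted-truth simulations and for
operating on already-published DE tables, not for matching any external
tool's numbers.

Model: counts ~ NB(mu, alpha) with Var = mu + alpha*mu^2.  For group means
``m_g`` estimated from ``n_g`` samples of normalised counts,

    Var(m_g)        = (m_g + alpha*m_g^2) / n_g
    LFC             = log2(m_2 / m_1)
    Var(LFC)        = [Var(m_1)/m_1^2 + Var(m_2)/m_2^2] / ln(2)^2    (delta method)
    stat            = LFC / SE,  p = two-sided normal tail.

Group means of zero are replaced by half the smallest nonzero group mean in
the matrix so the fold change stays finite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import FormatError, ValidationError

__all__ = [
    "size_factors",
    "nb_wald_test",
    "bh_adjust",
    "wald_stat_from_table",
    "count_significant",
    "parse_printed_p",
]

METHOD_LABEL = "deseq2-like (simplified)"

_DISPERSION_FLOOR = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalisation factors.

    For each transcript with all-positive counts, the ratio of each sample's
    count to the transcript's geometric mean; the factor is the per-sample
    median of those ratios.
    """
    if (counts.values < 0).any():
        raise ValidationError("counts must be non-negative")
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValidationError("no transcript with all-positive counts")
    log_geo = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_geo, axis=0)
    return np.exp(ratios.median(axis=0)).rename("size_factor")


def _dispersion_mom(norm: np.ndarray, group_idx: list[np.ndarray]) -> np.ndarray:
    """Pooled within-group method-of-moments NB dispersion per transcript.

    Solves Var = mu + alpha*mu^2 from within-group sample moments,
    truncated below at a small floor.  Groups of one sample contribute
    nothing (dispersion then rests on the floor, i.e. near-Poisson).
    """
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    for idx in group_idx:
        n = idx.size
        if n < 2:
            continue
        sub = norm[:, idx]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        num += (n - 1) * (var - mu)
        den += (n - 1) * mu**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, 0.0)
    return np.maximum(alpha, _DISPERSION_FLOOR)


def nb_wald_test(counts: pd.DataFrame, groups: pd.Series | dict) -> pd.DataFrame:
    """Two-group NB Wald test on a transcript x sample count matrix.

    ``groups`` maps sample -> level; exactly two levels are required and the
    fold change is level2 over level1 in sorted-level order.  Returns a
    table with baseMean, log2FoldChange, lfcSE, stat, p_value, p_adj and a
    method label column.
    """
    groups = pd.Series(groups)
    groups = groups.loc[counts.columns]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValidationError(f"exactly two group levels required, got {levels}")
    sf = size_factors(counts)
    norm = (counts / sf).to_numpy(float)
    idx1 = np.flatnonzero((groups == levels[0]).to_numpy())
    idx2 = np.flatnonzero((groups == levels[1]).to_numpy())

    mu1 = norm[:, idx1].mean(axis=1)
    mu2 = norm[:, idx2].mean(axis=1)
    if (mu1 == 0).all() or (mu2 == 0).all():
        raise ValidationError("one group is all-zero for every transcript")
    alpha = _dispersion_mom(norm, [idx1, idx2])

    nonzero = np.concatenate([mu1[mu1 > 0], mu2[mu2 > 0]])
    pseudo = nonzero.min() / 2.0
    m1 = np.where(mu1 > 0, mu1, pseudo)
    m2 = np.where(mu2 > 0, mu2, pseudo)

    lfc = np.log2(m2 / m1)
    var1 = (m1 + alpha * m1**2) / idx1.size
    var2 = (m2 + alpha * m2**2) / idx2.size
    se = np.sqrt(var1 / m1**2 + var2 / m2**2) / np.log(2)
    stat = lfc / se
    p = 2 * stats.norm.sf(np.abs(stat))
    return pd.DataFrame(
        {
            "baseMean": norm.mean(axis=1),
            "log2FoldChange": lfc,
            "lfcSE": se,
            "stat": stat,
            "p_value": p,
            "p_adj": bh_adjust(pd.Series(p, index=counts.index)).to_numpy(),
            "method": METHOD_LABEL,
        },
        index=counts.index,
    )


def bh_adjust(p) -> pd.Series:
    """Benjamini-Hochberg step-up with missing-value propagation.

    Missing p-values stay missing and are excluded from the number of tests.
    """
    p = pd.Series(p, dtype=float)
    valid = p.notna()
    vals = p[valid].to_numpy()
    if ((vals < 0) | (vals > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    out = pd.Series(np.nan, index=p.index)
    if valid.any():
        out[valid] = multipletests(vals, method="fdr_bh")[1]
    return out


def wald_stat_from_table(log2fc: float, lfcse: float) -> float:
    """Recompute a Wald statistic from printed LFC and SE columns."""
    if lfcse <= 0:
        raise ValidationError(f"lfcSE must be positive, got {lfcse}")
    return log2fc / lfcse


def parse_printed_p(cell) -> float:
    """Parse a printed p-value cell; ``<0.001`` counts as 0.0005, NA as missing."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return np.nan
    text = str(cell).strip().rstrip("*")
    if text in {"NA", "na", ""}:
        return np.nan
    if text.startswith("<"):
        return float(text[1:]) / 2.0
    try:
        return float(text)
    except ValueError as exc:
        raise FormatError(f"unparseable p-value cell {cell!r}") from exc


def count_significant(table: pd.DataFrame, alpha: float = 0.05,
                      column: str = "p_adj") -> int:
    """Count rows with adjusted p strictly below ``alpha``; missing never counts."""
    if column not in table.columns:
        raise FormatError(f"table lacks column {column!r}")
    parsed = table[column].map(parse_printed_p)
    return int((parsed < alpha).sum())
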