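"""Compositional expression-divergence analysis.

Relative transcript abundances (TPM) are compositional: each sample's values
are constrained to a fixed total, so raw between-sample comparisons confound
a transcript's change with everyone else's.  The divergence statistic used
here works in centered log-ratio (CLR) coordinates instead:

1. multiplicative zero replacement (zeros cannot be log-transformed),
2. CLR transform per sample: ``clr(x)_i = ln x_i - mean(ln x)``,
3. a total-least-squares (orthogonal) line fit through the nontoxin cloud
   of one sample pair,
4. an empirical two-sided null band from the nontoxin signed orthogonal
   residuals (99% of the background mass by default, 0.5% per tail),
5. a toxin is called a divergence outlier when its signed residual falls
   strictly outside the band; the direction names the sample with the
   higher CLR value relative to the fitted line.

The null band asks "how far apart can two biological replicates of the same
animal's housekeeping transcriptome drift?" and flags toxins that exceed
that drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import FitError, ValidationError

__all__ = [
    "replace_zeros",
    "clr_transform",
    "TlsFit",
    "fit_orthogonal_line",
    "NullBand",
    "build_null_band",
    "call_outliers",
    "divergence_analysis",
    "family_composition",
]


def replace_zeros(matrix: pd.DataFrame, delta_fraction: float = 0.5) -> pd.DataFrame:
    """Multiplicative simple zero replacement.

    Each zero becomes ``delta_fraction`` times the smallest nonzero value in
    its sample; nonzero values are multiplicatively rescaled so the sample
    total is preserved.  Strictly positive columns are returned unchanged.
    """
    if (matrix.values < 0).any():
        raise ValidationError("expression matrix must be non-negative")
    out = matrix.astype(float).copy()
    for col in out.columns:
        x = out[col].to_numpy()
        zeros = x == 0
        if not zeros.any():
            continue
        if zeros.all():
            raise ValidationError(f"sample {col!r} is all zero")
        delta = delta_fraction * x[~zeros].min()
        total = x.sum()
        replaced = delta * zeros.sum()
        x = np.where(zeros, delta, x * (total - replaced) / total)
        out[col] = x
    return out


def clr_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Centered log-ratio transform, column-wise (per sample).

    Requires strictly positive input (run :func:`replace_zeros` first).
    Every output column sums to zero; the transform is invariant to
    rescaling a sample by any positive constant.
    """
    if (matrix.values <= 0).any():
        raise ValidationError(
            "CLR needs strictly positive values; replace zeros first"
        )
    logged = np.log(matrix.astype(float))
    return logged - logged.mean(axis=0)


@dataclass
class TlsFit:
    """Total-least-squares line with signed orthogonal residuals.

    The signed residual of a point is its perpendicular distance to the
    line, positive above it: ``(y - slope*x - intercept) / sqrt(1+slope^2)``.
    """

    slope: float
    intercept: float
    residuals: pd.Series

    def residual(self, x, y):
        return (y - self.slope * x - self.intercept) / np.sqrt(1 + self.slope**2)


def fit_orthogonal_line(x: pd.Series, y: pd.Series) -> TlsFit:
    """Fit the line minimising the summed squared perpendicular distances.

    Equivalent to the principal axis of the 2x2 covariance matrix of
    ``(x, y)`` (total least squares with error-variance ratio 1).
    """
    x = pd.Series(x)
    y = pd.Series(y, index=x.index)
    if len(x) < 3:
        raise FitError("orthogonal fit needs at least 3 points")
    xv, yv = x.to_numpy(float), y.to_numpy(float)
    xc, yc = xv - xv.mean(), yv - yv.mean()
    cov = np.cov(np.vstack([xc, yc]))
    if np.allclose(cov, 0):
        raise FitError("degenerate input: all points identical")
    if np.isclose(cov[0, 0], 0):
        raise FitError("x values all equal: orthogonal line is vertical")
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]  # principal axis
    slope = v[1] / v[0]
    intercept = yv.mean() - slope * xv.mean()
    resid = (yv - slope * xv - intercept) / np.sqrt(1 + slope**2)
    return TlsFit(slope=float(slope), intercept=float(intercept),
                  residuals=pd.Series(resid, index=x.index))


@dataclass
class NullBand:
    """Empirical residual band holding ``level`` of the background mass."""

    lower: float
    upper: float
    level: float
    n_background: int

    def contains(self, residual) -> np.ndarray:
        """Boundary points count as inside (conservative tie rule)."""
        r = np.asarray(residual, float)
        return (r >= self.lower) & (r <= self.upper)


def build_null_band(fit: TlsFit, level: float = 0.99) -> NullBand:
    """Two-sided empirical quantile band of the background residuals.

    ``fit`` must have been computed on the background (nontoxin) points
    only.  The band spans the ``(1-level)/2`` and ``1-(1-level)/2``
    empirical quantiles, i.e. the central ``level`` of the background mass
    with equal tails.
    """
    if not 0.5 < level < 1:
        raise ValidationError(f"level must be in (0.5, 1), got {level}")
    resid = fit.residuals.to_numpy(float)
    n = resid.size
    if n < 100 and level >= 0.99:
        import warnings

        warnings.warn(
            f"only {n} background points: {level:.0%} quantiles are unstable",
            stacklevel=2,
        )
    tail = (1 - level) / 2
    lower, upper = np.quantile(resid, [tail, 1 - tail])
    return NullBand(lower=float(lower), upper=float(upper), level=level, n_background=n)


def call_outliers(
    toxin_ids,
    clr: pd.DataFrame,
    fit: TlsFit,
    band: NullBand,
    pair: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Flag toxins whose signed residual lies strictly outside the null band.

    ``pair`` selects the (x, y) sample columns; defaults to the first two
    columns of ``clr``.  Direction is the sample on whose side of the fitted
    line the point falls: the y sample for positive residuals, the x sample
    for negative ones.  Points exactly on a band boundary are inside.
    """
    if pair is None:
        pair = (clr.columns[0], clr.columns[1])
    sx, sy = pair
    missing = [t for t in toxin_ids if t not in clr.index]
    if missing:
        raise KeyError(f"toxins absent from CLR matrix: {missing}")
    x = clr.loc[list(toxin_ids), sx]
    y = clr.loc[list(toxin_ids), sy]
    resid = fit.residual(x.to_numpy(), y.to_numpy())
    flag = ~band.contains(resid)
    direction = np.where(flag, np.where(resid > 0, sy, sx), "")
    return pd.DataFrame(
        {
            "transcript_id": list(toxin_ids),
            "residual": resid,
            "flag": flag,
            "direction": direction,
        }
    ).set_index("transcript_id")


def divergence_analysis(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    pair: tuple[str, str] | None = None,
    level: float = 0.99,
    delta_fraction: float = 0.5,
) -> tuple[pd.DataFrame, TlsFit, NullBand]:
    """End-to-end intra-pair divergence outlier screen.

    Zero-replaces and CLR-transforms ``matrix`` (all transcripts, so toxins
    and nontoxins share the geometric-mean reference), fits the orthogonal
    line and the null band on nontoxins only, and calls toxin outliers.
    """
    if pair is None:
        pair = (matrix.columns[0], matrix.columns[1])
    clr = clr_transform(replace_zeros(matrix, delta_fraction))
    classes = annotation.loc[clr.index, "class"]
    nontoxins = clr.index[classes == "nontoxin"]
    toxins = clr.index[classes == "toxin"]
    fit = fit_orthogonal_line(clr.loc[nontoxins, pair[0]], clr.loc[nontoxins, pair[1]])
    band = build_null_band(fit, level=level)
    calls = call_outliers(toxins, clr, fit, band, pair=pair)
    return calls, fit, band


def family_composition(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    scope: str = "per_sample",
) -> pd.DataFrame:
    """Toxin-family share of total toxin expression, in percent.

    ``per_sample`` returns a family x sample table of
    ``100 * family TPM / total toxin TPM``; ``species_average`` returns the
    arithmetic mean of the per-sample percentages as a single column.
    """
    classes = annotation.loc[matrix.index, "class"]
    toxins = matrix.loc[classes == "toxin"]
    totals = toxins.sum(axis=0)
    if (totals == 0).any():
        zero = totals.index[totals == 0].tolist()
        raise ValidationError(f"zero total toxin TPM in samples {zero}")
    fam = annotation.loc[toxins.index, "family"]
    pct = toxins.groupby(fam).sum() / totals * 100.0
    if scope == "per_sample":
        return pct
    if scope == "species_average":
        return pct.mean(axis=1).to_frame("average_percent")
    raise ValueError(f"unknown scope {scope!r}")
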