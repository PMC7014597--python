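"""Pairwise codon-level divergence by Nei-Gojobori counting.

For each codon the number of synonymous sites is the expected fraction of
single-base changes that preserve the amino acid; changes producing stop
codons are excluded from both numerator and denominator, so a fully counted
codon contributes N + S = 3 sites scaled by the kept (non-stop) fraction.
Observed differences between two aligned codons are resolved by averaging
synonymous/nonsynonymous step counts over all minimal mutational pathways
that avoid stop codons, each pathway weighted equally.  Proportions are
Jukes-Cantor corrected, ``d = -(3/4) ln(1 - 4p/3)``, and
``omega = dN / dS`` whenever ``dS > 0``.

These are counting estimates: deterministic and desk-verifiable, suitable
for rank comparisons of toxins against a nontoxin background, but not
numerically comparable to maximum-likelihood codon-model estimates beyond
rank order.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

__all__ = [
    "count_sites",
    "PairwiseSubstStats",
    "pairwise_dnds",
    "apply_ds_filters",
    "GroupComparison",
    "compare_groups",
    "percentile_flags",
    "flag_overlap",
]

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}

_CODON_TABLE = {}


def _codon_table() -> dict[str, str]:
    global _CODON_TABLE
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE = dict(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


def translate(codon: str) -> str:
    return _codon_table()[codon]


def _split_codons(seq: str) -> list[str]:
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0 or len(seq) < 3:
        raise ValidationError("sequence length must be a positive multiple of 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for c in codons:
        if any(b not in BASES for b in c):
            raise ValidationError(f"invalid codon {c!r}")
        if c in STOPS:
            raise ValidationError(f"internal stop codon {c!r}")
    return codons


def _nonstop_changes(codon: str, pos: int) -> int:
    n = 0
    for base in BASES:
        if base == codon[pos]:
            continue
        if codon[:pos] + base + codon[pos + 1 :] not in STOPS:
            n += 1
    return n


def _codon_s(codon: str) -> float:
    """Synonymous site count: per position, syn fraction of non-stop changes."""
    aa = translate(codon)
    s = 0.0
    for pos in range(3):
        kept, syn = 0, 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOPS:
                continue
            kept += 1
            if translate(mutant) == aa:
                syn += 1
        if kept:
            s += syn / kept
    return s


def count_sites(seq: str) -> tuple[float, float]:
    """Expected (N, S) site counts for a codon sequence.

    Per codon position, the synonymous fraction is the share of non-stop
    single-base changes that preserve the amino acid; ``S`` sums those
    fractions and ``N`` is the kept-change complement, so ``N + S = 3`` for
    every codon from which no stop is reachable.
    """
    n_total, s_total = 0.0, 0.0
    for codon in _split_codons(seq):
        s = _codon_s(codon)
        kept = sum(_nonstop_changes(codon, pos) for pos in range(3))
        n = 3.0 * kept / 9.0 - s
        n_total += n
        s_total += s
    return n_total, s_total


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(nonsyn, syn) step counts averaged over minimal stop-free pathways."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    for order in permutations(diff_pos):
        current = c1
        nd, sd = 0.0, 0.0
        blocked = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if nxt in STOPS:
                blocked = True
                break
            if translate(nxt) == translate(current):
                sd += 1
            else:
                nd += 1
            current = nxt
        if not blocked:
            results.append((nd, sd))
    if not results:
        # every ordering passes through a stop; fall back to counting through
        # them so the comparison is still defined (rare corner, documented)
        for order in permutations(diff_pos):
            current = c1
            nd, sd = 0.0, 0.0
            for pos in order:
                nxt = current[:pos] + c2[pos] + current[pos + 1 :]
                if nxt in STOPS or translate(nxt) != translate(current):
                    nd += 1
                else:
                    sd += 1
                current = nxt
            results.append((nd, sd))
    arr = np.array(results, dtype=float)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean())


def jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return float("nan")
    return float(-0.75 * np.log(1 - 4.0 * p / 3.0)) + 0.0  # normalise -0.0


@dataclass
class PairwiseSubstStats:
    """Site/difference counts and corrected distances for one ortholog pair."""

    pair_id: str
    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    dN: float
    dS: float
    omega: float | None
    n_codons: int
    n_gapped_codons: int = 0
    filter_status: str = "kept"


def pairwise_dnds(seq1: str, seq2: str, pair_id: str = "") -> PairwiseSubstStats:
    """NG86 pairwise dN/dS for two codon-aligned coding sequences.

    Gapped codon columns (any ``-`` in either codon) are dropped pairwise
    and counted.  Site totals are averaged over the two sequences;
    differences are pathway-averaged per codon.  ``omega`` is defined only
    when ``dS > 0``; a proportion >= 3/4 leaves the distance (and the
    record's filter status) undefined.
    """
    s1, s2 = seq1.upper().replace("U", "T"), seq2.upper().replace("U", "T")
    if len(s1) != len(s2):
        raise ValidationError("aligned sequences must have equal length")
    if len(s1) % 3 != 0 or len(s1) < 3:
        raise ValidationError("alignment length must be a positive multiple of 3")
    codons1, codons2, gapped = [], [], 0
    for i in range(0, len(s1), 3):
        c1, c2 = s1[i : i + 3], s2[i : i + 3]
        if "-" in c1 or "-" in c2:
            gapped += 1
            continue
        codons1.append(c1)
        codons2.append(c2)
    if not codons1:
        raise ValidationError("no ungapped codon columns")
    n1, s_1 = count_sites("".join(codons1))
    n2, s_2 = count_sites("".join(codons2))
    n_sites, s_sites = (n1 + n2) / 2.0, (s_1 + s_2) / 2.0
    nd = sd = 0.0
    for c1, c2 in zip(codons1, codons2):
        d_n, d_s = _pathway_counts(c1, c2)
        nd += d_n
        sd += d_s
    p_n = nd / n_sites if n_sites > 0 else 0.0
    p_s = sd / s_sites if s_sites > 0 else 0.0
    d_n, d_s = jukes_cantor(p_n), jukes_cantor(p_s)
    undefined = np.isnan(d_n) or np.isnan(d_s)
    omega = None
    if not undefined and d_s > 0:
        omega = d_n / d_s
    return PairwiseSubstStats(
        pair_id=pair_id,
        N=n_sites,
        S=s_sites,
        Nd=nd,
        Sd=sd,
        pN=p_n,
        pS=p_s,
        dN=d_n,
        dS=d_s,
        omega=omega,
        n_codons=len(codons1),
        n_gapped_codons=gapped,
        filter_status="undefined" if undefined else "kept",
    )


def apply_ds_filters(
    stats_list: list[PairwiseSubstStats],
    min_ds: float = 0.001,
    max_ds: float = 0.10,
) -> tuple[list[PairwiseSubstStats], pd.DataFrame]:
    """dS exclusion windows.

    ``dS < min_ds`` risks wildly inflated omega (division by a near-zero
    synonymous distance); ``dS > max_ds`` risks misidentified orthologs.
    Kept iff ``min_ds <= dS <= max_ds`` and both distances are defined.
    The operation is idempotent: statuses are recomputed from dS each call.
    """
    kept = []
    rows = []
    for st in stats_list:
        if np.isnan(st.dN) or np.isnan(st.dS):
            st.filter_status = "undefined"
        elif st.dS < min_ds:
            st.filter_status = "excluded_low_dS"
        elif st.dS > max_ds:
            st.filter_status = "excluded_high_dS"
        else:
            st.filter_status = "kept"
            kept.append(st)
        rows.append({"pair_id": st.pair_id, "dS": st.dS, "filter_status": st.filter_status})
    return kept, pd.DataFrame(rows, columns=["pair_id", "dS", "filter_status"])


@dataclass
class GroupComparison:
    quantity: str
    statistic: float
    p_value: float
    n_toxin: int
    n_nontoxin: int


def compare_groups(
    toxin_values, nontoxin_values, quantity: str = "omega"
) -> GroupComparison:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) toxin vs nontoxin contrast.

    Two-sided, normal approximation with tie correction.  The groups are
    independent and of unequal size, so the unpaired rank-sum form applies;
    a paired signed-rank variant is available via ``paired_signed_rank``.
    """
    x = np.asarray(list(toxin_values), float)
    y = np.asarray(list(nontoxin_values), float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups need at least one member")
    if np.all(np.concatenate([x, y]) == np.concatenate([x, y])[0]):
        return GroupComparison(quantity, float("nan"), 1.0, x.size, y.size)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return GroupComparison(quantity, float(res.statistic), float(res.pvalue),
                           x.size, y.size)


def paired_signed_rank(x, y, quantity: str = "omega") -> GroupComparison:
    x, y = np.asarray(list(x), float), np.asarray(list(y), float)
    if x.size != y.size:
        raise ValidationError("paired test needs equal-length samples")
    if np.all(x == y):
        return GroupComparison(quantity, float("nan"), 1.0, x.size, y.size)
    res = stats.wilcoxon(x, y)
    return GroupComparison(quantity, float(res.statistic), float(res.pvalue),
                           x.size, y.size)


def percentile_flags(
    values: pd.Series,
    is_toxin: pd.Series,
    level: float = 0.95,
) -> tuple[pd.Index, float]:
    """Toxins strictly above the nontoxin empirical percentile.

    Returns (flagged toxin index, threshold).  A toxin exactly at the
    percentile is not flagged.  Fewer than 20 nontoxins triggers a warning.
    """
    values = pd.Series(values, dtype=float)
    is_toxin = pd.Series(is_toxin).astype(bool).loc[values.index]
    nontoxin = values[~is_toxin].dropna()
    if len(nontoxin) < 20:
        import warnings

        warnings.warn(
            f"only {len(nontoxin)} nontoxins: percentile threshold unstable",
            stacklevel=2,
        )
    threshold = float(np.quantile(nontoxin.to_numpy(), level))
    toxin = values[is_toxin]
    return toxin.index[toxin > threshold], threshold


def flag_overlap(flags: dict[str, pd.Index]) -> pd.Index:
    """Intersection of per-quantity flag sets (e.g. high-dN AND high-dS toxins)."""
    sets = list(flags.values())
    if not sets:
        return pd.Index([])
    out = sets[0]
    for s in sets[1:]:
        out = out.intersection(s)
    return out
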