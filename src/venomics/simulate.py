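"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here with a known truth
record, so each stage is testable without sequencing data.  The generators
are deterministic given their seed, and at zero noise each planted feature
is exactly recoverable by the corresponding analysis stage.

Default scales: a venom-gland-like composition has two samples per species,
tens of toxins in ~14 families against ~1500 nontoxins; divergence outliers
are planted with a 5 CLR-unit shift over a 0.5 CLR-unit replicate noise
(an over-expression an order of magnitude beyond replicate drift); coverage
is tiled uniformly at 20x with 100-base reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "ExpressionTruth",
    "simulate_expression",
    "CoverageTruth",
    "simulate_coverage",
    "CodonPairTruth",
    "simulate_codon_pair",
    "OrthogroupTruth",
    "simulate_orthogroups",
    "CoexpressionTruth",
    "simulate_coexpression",
]

TOXIN_FAMILIES = (
    "PLA2", "SVMPII", "SVMPIII", "SVSP", "CTL", "BPP", "VEGF",
    "LAAO", "CRISP", "HYAL", "NUC", "PDE", "NGF", "Waprin",
)


# ---------------------------------------------------------------------------
# compositional expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionTruth:
    """Planted outliers: toxin id -> sample that over-expresses it."""

    outliers: dict[str, str] = field(default_factory=dict)
    toxin_ids: list[str] = field(default_factory=list)
    nontoxin_ids: list[str] = field(default_factory=list)


def simulate_expression(
    n_toxins: int = 40,
    n_nontoxins: int = 1500,
    n_outliers: int = 5,
    outlier_shift: float = 5.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    sample_ids: tuple[str, str] = ("S1", "S2"),
    toxin_log_mean: float = 6.0,
    nontoxin_log_mean: float = 3.0,
    log_sd: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame, ExpressionTruth]:
    """Two-replicate compositional expression with planted divergence outliers.

    Log-abundances of all transcripts are drawn about a shared per-transcript
    level with independent N(0, noise_sd) replicate noise, so nontoxins sit
    on the identity line in CLR space up to that noise.  ``n_outliers``
    toxins get ``outlier_shift`` added to one sample's log-abundance
    (direction random per toxin).  Columns are closed to the TPM total 1e6.
    Toxins sit higher in base abundance than nontoxins by default; setting
    ``toxin_log_mean = nontoxin_log_mean`` yields null toxins drawn from the
    background distribution (the calibration condition for the null band).

    Returns (expression matrix, annotation table, truth).
    """
    if n_toxins <= 0 or n_nontoxins <= 0:
        raise ValidationError("transcript counts must be positive")
    if n_outliers > n_toxins:
        raise ValidationError("n_outliers cannot exceed n_toxins")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    toxin_ids = [f"TOX{i + 1:04d}" for i in range(n_toxins)]
    nontoxin_ids = [f"NTX{i + 1:04d}" for i in range(n_nontoxins)]
    ids = toxin_ids + nontoxin_ids
    n = len(ids)

    base = np.concatenate(
        [
            rng.normal(toxin_log_mean, log_sd, n_toxins),
            rng.normal(nontoxin_log_mean, log_sd, n_nontoxins),
        ]
    )
    log1 = base + rng.normal(0.0, noise_sd, n)
    log2 = base + rng.normal(0.0, noise_sd, n)

    truth = ExpressionTruth(toxin_ids=toxin_ids, nontoxin_ids=nontoxin_ids)
    chosen = rng.choice(n_toxins, size=n_outliers, replace=False)
    for idx in sorted(chosen):
        which = rng.integers(2)
        if which == 0:
            log1[idx] += outlier_shift
        else:
            log2[idx] += outlier_shift
        truth.outliers[toxin_ids[idx]] = sample_ids[which]

    raw = np.exp(np.column_stack([log1, log2]))
    tpm = raw / raw.sum(axis=0) * 1e6
    expr = pd.DataFrame(tpm, index=pd.Index(ids, name="transcript_id"),
                        columns=list(sample_ids))
    families = [TOXIN_FAMILIES[i % len(TOXIN_FAMILIES)] for i in range(n_toxins)]
    annot = pd.DataFrame(
        {
            "class": ["toxin"] * n_toxins + ["nontoxin"] * n_nontoxins,
            "family": families + [""] * n_nontoxins,
            "orthology_label": ["unassigned"] * n,
        },
        index=expr.index,
    )
    return expr, annot, truth


# ---------------------------------------------------------------------------
# read coverage
# ---------------------------------------------------------------------------


@dataclass
class CoverageTruth:
    junction_at: int | None
    low_region: tuple[int, int] | None
    read_length: int


def _tile(start: int, stop: int, read_length: int, depth: float,
          offset: int = 0) -> np.ndarray:
    """Uniformly tiled read starts over [start, stop) at target fold depth."""
    span = stop - start
    if span < read_length:
        return np.empty(0, dtype=int)
    n_reads = max(1, int(round(depth * span / read_length)))
    return (start + np.floor(np.linspace(0, span - read_length, n_reads))).astype(int)


def simulate_coverage(
    transcript_length: int,
    read_length: int = 100,
    depth: float = 20.0,
    junction_at: int | None = None,
    low_region: tuple[int, int] | None = None,
    seed: int = 0,
    transcript_id: str = "T1",
) -> tuple[pd.DataFrame, CoverageTruth]:
    """Uniformly tiled read alignments with optional planted defects.

    A chimeric junction is planted by tiling the two flanks independently so
    no read spans the joint; it must lie at least one read length from both
    ends or the overhang screen could not see it.  A low-coverage region is
    planted by dropping every read overlapping it (depth 0 inside).
    """
    if read_length >= transcript_length:
        raise ValidationError("read_length must be smaller than transcript_length")
    if junction_at is not None and not (
        read_length <= junction_at <= transcript_length - read_length
    ):
        raise ValidationError(
            "junction within one read length of an end is undetectable by construction"
        )
    if junction_at is None:
        starts = _tile(0, transcript_length, read_length, depth)
    else:
        starts = np.concatenate(
            [
                _tile(0, junction_at, read_length, depth),
                _tile(junction_at, transcript_length, read_length, depth),
            ]
        )
    ends = starts + read_length
    if low_region is not None:
        lo, hi = low_region
        keep = (ends <= lo) | (starts >= hi)
        starts, ends = starts[keep], ends[keep]
    table = pd.DataFrame(
        {
            "read_id": [f"r{i + 1}" for i in range(len(starts))],
            "transcript_id": transcript_id,
            "start": starts,
            "end": ends,
        }
    )
    return table, CoverageTruth(junction_at=junction_at, low_region=low_region,
                                read_length=read_length)


# ---------------------------------------------------------------------------
# codon pairs
# ---------------------------------------------------------------------------

# fourfold-degenerate codons ending in T: third-position T->C is always
# synonymous and second-position ->A is always nonsynonymous, with no stop
# reachable by either edit.
_SAFE_CODONS = ("GGT", "GCT", "GTT", "CCT", "CGT", "ACT", "TCT", "CTT")


@dataclass
class CodonPairTruth:
    syn_positions: list[int]
    nonsyn_positions: list[int]


def simulate_codon_pair(
    n_codons: int,
    target_syn_diffs: int,
    target_nonsyn_diffs: int,
    seed: int = 0,
) -> tuple[str, str, CodonPairTruth]:
    """Two coding sequences differing by exact planted substitution counts.

    Each difference is a single-base change in its own codon (so pathway
    counting is unambiguous): synonymous edits flip a fourfold third
    position, nonsynonymous edits flip the second position.  Neither
    sequence ever contains a stop codon.
    """
    if n_codons < 1:
        raise ValidationError("n_codons must be >= 1")
    if target_syn_diffs < 0 or target_nonsyn_diffs < 0:
        raise ValidationError("difference targets must be >= 0")
    if target_syn_diffs + target_nonsyn_diffs > n_codons:
        raise ValidationError(
            "at most one planted difference per codon: targets exceed n_codons"
        )
    rng = np.random.default_rng(seed)
    codons = [str(rng.choice(_SAFE_CODONS)) for _ in range(n_codons)]
    positions = rng.permutation(n_codons)
    syn_pos = sorted(int(i) for i in positions[:target_syn_diffs])
    nonsyn_pos = sorted(
        int(i)
        for i in positions[target_syn_diffs : target_syn_diffs + target_nonsyn_diffs]
    )
    mutated = list(codons)
    for i in syn_pos:
        mutated[i] = mutated[i][:2] + "C"
    for i in nonsyn_pos:
        mutated[i] = mutated[i][0] + "A" + mutated[i][2]
    return "".join(codons), "".join(mutated), CodonPairTruth(syn_pos, nonsyn_pos)


# ---------------------------------------------------------------------------
# orthogroups
# ---------------------------------------------------------------------------


@dataclass
class OrthogroupTruth:
    n_one_to_one: int
    n_dup_a: int
    n_dup_b: int
    n_loss_a: int
    n_loss_b: int


def simulate_orthogroups(
    n_one_to_one: int = 10,
    n_dup_a: int = 0,
    n_dup_b: int = 0,
    n_loss_a: int = 0,
    n_loss_b: int = 0,
    seed: int = 0,
    species: tuple[str, str] = ("A", "B"),
):
    """Orthogroup table with planted one-to-one/duplication/loss structure.

    Each duplication group has two members in the duplicated species and one
    in the other (one duplication event); each loss group has one member on
    the surviving side only.  The turnover classifier recovers the planted
    counts exactly.
    """
    from .io import Orthogroups

    counts = (n_one_to_one, n_dup_a, n_dup_b, n_loss_a, n_loss_b)
    if any(c < 0 for c in counts):
        raise ValidationError("orthogroup counts must be >= 0")
    rng = np.random.default_rng(seed)
    sp_a, sp_b = species
    table = Orthogroups(species=[sp_a, sp_b])
    serial = iter(range(1, sum(counts) * 4 + 1))

    def new_id(sp: str) -> str:
        return f"{sp.lower()}{next(serial)}"

    specs = (
        [("one_to_one", 1, 1)] * n_one_to_one
        + [("dup_a", 2, 1)] * n_dup_a
        + [("dup_b", 1, 2)] * n_dup_b
        + [("loss_a", 0, 1)] * n_loss_a
        + [("loss_b", 1, 0)] * n_loss_b
    )
    order = rng.permutation(len(specs))
    for og_i, spec_i in enumerate(order, start=1):
        _, m_a, m_b = specs[spec_i]
        table.groups[f"OG{og_i:04d}"] = {
            sp_a: [new_id(sp_a) for _ in range(m_a)],
            sp_b: [new_id(sp_b) for _ in range(m_b)],
        }
    return table, OrthogroupTruth(*counts)


# ---------------------------------------------------------------------------
# coexpression blocks
# ---------------------------------------------------------------------------


@dataclass
class CoexpressionTruth:
    modules: dict[str, int]  # transcript -> module (0 = background)
    patterns: np.ndarray  # module x treatment mean profile


def simulate_coexpression(
    n_modules: int = 2,
    transcripts_per_module: int = 10,
    n_background: int = 20,
    within_cor: float = 0.9,
    n_samples_per_treatment: int = 4,
    seed: int = 0,
    treatments: tuple[str, ...] = ("A", "A+B", "B"),
    patterns: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, CoexpressionTruth]:
    """Treatment-structured coexpression blocks on a TPM-like scale.

    Transcripts in a module share a standardised per-sample factor built
    from a module-specific treatment profile; each transcript mixes the
    factor and private noise as ``sqrt(r)*f + sqrt(1-r)*eps`` so pairwise
    within-module correlation is ``within_cor`` in expectation.  Background
    transcripts are independent noise.  Values are returned as
    ``TPM = 2^v - 1`` with ``v`` the simulated log2 expression, so the
    network stage's ``log2(x+1)`` recovers ``v`` exactly.

    Returns (expression matrix, sample metadata, truth).
    """
    if not 0 <= within_cor < 1:
        raise ValidationError("within_cor must lie in [0, 1)")
    if len(treatments) < 2:
        raise ValidationError("at least two treatments required")
    if n_modules < 0 or n_background < 0 or n_samples_per_treatment < 1:
        raise ValidationError("counts must be non-negative (samples >= 1)")
    rng = np.random.default_rng(seed)
    n_samples = len(treatments) * n_samples_per_treatment
    sample_ids = []
    sample_treatment = []
    for t_i, treatment in enumerate(treatments):
        for r in range(n_samples_per_treatment):
            sample_ids.append(f"{treatment}_{r + 1}")
            sample_treatment.append(treatment)
    treat_index = np.repeat(np.arange(len(treatments)), n_samples_per_treatment)

    if patterns is None:
        patterns = np.empty((n_modules, len(treatments)))
        for m in range(n_modules):
            while True:
                p = rng.choice([-1.5, 1.5], size=len(treatments))
                if len(set(p)) > 1 and not any(
                    np.array_equal(p, patterns[j]) for j in range(m)
                ):
                    patterns[m] = p
                    break
    else:
        patterns = np.asarray(patterns, float)
        if patterns.shape != (n_modules, len(treatments)):
            raise ValidationError("patterns must be n_modules x n_treatments")

    rows, ids, modules = [], [], {}
    for m in range(n_modules):
        f = patterns[m][treat_index] + rng.normal(0.0, 0.5, n_samples)
        f = (f - f.mean()) / f.std()  # unit-variance shared factor
        for t in range(transcripts_per_module):
            tid = f"M{m + 1}_T{t + 1}"
            eps = rng.normal(0.0, 1.0, n_samples)
            v = 8.0 + 2.0 * (np.sqrt(within_cor) * f + np.sqrt(1 - within_cor) * eps)
            rows.append(v)
            ids.append(tid)
            modules[tid] = m + 1
    for b in range(n_background):
        tid = f"BG_T{b + 1}"
        rows.append(8.0 + 2.0 * rng.normal(0.0, 1.0, n_samples))
        ids.append(tid)
        modules[tid] = 0
    values = np.maximum(np.array(rows), 0.0)
    expr = pd.DataFrame(2.0**values - 1.0,
                        index=pd.Index(ids, name="transcript_id"),
                        columns=sample_ids)
    samples = pd.DataFrame({"sample_id": sample_ids, "venom_type": sample_treatment})
    return expr, samples, CoexpressionTruth(modules=modules, patterns=patterns)
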