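"""Assembly and expression quality-control callers.

Four bespoke screens over transcript-level read evidence:

* :func:`depth_profile` / :func:`call_presence` — per-base coverage and the
  low-coverage absence rule (a transcript is absent when more than 10% of
  its length has depth below 5x, by default).
* :func:`screen_chimeras` — mis-joined (chimeric) contigs betray themselves
  by asymmetric read overhangs: at a true junction no read spans the joint,
  so reads covering a site near it pile up on one side.  A site is flagged
  when the mean left and mean right overhang of its covering reads differ by
  more than half the mean read length.
* :func:`kmer_crosstalk_filter` — index-hopping between samples multiplexed
  on one lane leaves k-mers wildly more abundant in the source sample;
  reads carrying such k-mers are removed from the low-count (recipient)
  sample.
* :func:`cluster_transcripts` — greedy centroid clustering of assembled
  coding sequences at a global-alignment identity threshold (98% default)
  to collapse alleles and very recent paralogs.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .exceptions import ValidationError

__all__ = [
    "CoverageProfile",
    "depth_profile",
    "PresenceCall",
    "call_presence",
    "ChimeraFlag",
    "screen_chimeras",
    "kmer_crosstalk_filter",
    "Cluster",
    "cluster_transcripts",
]


@dataclass
class CoverageProfile:
    transcript_id: str
    depth: np.ndarray  # reads covering each base
    length: int


def depth_profile(alignments: pd.DataFrame, transcript_length: int,
                  transcript_id: str | None = None) -> CoverageProfile:
    """Per-base read depth from an alignment table via interval stabbing."""
    if transcript_length <= 0:
        raise ValidationError("transcript length must be positive")
    starts = alignments["start"].to_numpy(int)
    ends = alignments["end"].to_numpy(int)
    if len(starts) and (starts.min() < 0 or ends.max() > transcript_length
                        or (starts >= ends).any()):
        raise ValidationError("alignment interval out of transcript bounds")
    diff = np.zeros(transcript_length + 1, dtype=np.int64)
    np.add.at(diff, starts, 1)
    np.add.at(diff, ends, -1)
    tid = transcript_id
    if tid is None:
        ids = alignments["transcript_id"].unique()
        tid = ids[0] if len(ids) else ""
    return CoverageProfile(transcript_id=str(tid),
                           depth=np.cumsum(diff[:-1]),
                           length=transcript_length)


@dataclass
class PresenceCall:
    transcript_id: str
    sample_id: str
    verdict: str  # "present" | "absent"
    low_coverage_fraction: float


def call_presence(
    profile: CoverageProfile,
    sample_id: str = "",
    min_depth: int = 5,
    max_low_fraction: float = 0.10,
) -> PresenceCall:
    """Absent iff the fraction of bases below ``min_depth`` strictly exceeds
    ``max_low_fraction``."""
    if profile.length <= 0:
        raise ValidationError("zero-length transcript")
    low = float((profile.depth < min_depth).sum()) / profile.length
    verdict = "absent" if low > max_low_fraction else "present"
    return PresenceCall(profile.transcript_id, sample_id, verdict, low)


@dataclass
class ChimeraFlag:
    transcript_id: str
    sites: np.ndarray          # flagged site positions
    left_overhang: np.ndarray  # mean bases left of each flagged site
    right_overhang: np.ndarray
    mean_read_length: float

    @property
    def flagged(self) -> bool:
        return self.sites.size > 0


def screen_chimeras(
    alignments: pd.DataFrame,
    transcript_length: int,
    asym_fraction: float = 0.50,
    min_reads_at_site: int = 3,
    transcript_id: str | None = None,
) -> ChimeraFlag:
    """Flag sites with asymmetric read overhangs.

    For each site ``i`` at least one mean read length from both transcript
    ends and covered by at least ``min_reads_at_site`` reads, the mean
    left overhang is ``mean(i - start)`` and the mean right overhang
    ``mean(end - i - 1)`` over covering reads.  The site is flagged when
    ``|left - right| > asym_fraction * mean read length``.  Overhang means
    are ill-defined near termini, so those sites are never eligible.
    """
    if alignments.empty:
        raise ValidationError("no reads: chimera screen undefined")
    starts = alignments["start"].to_numpy(np.int64)
    ends = alignments["end"].to_numpy(np.int64)
    lengths = ends - starts
    mrl = float(lengths.mean())

    # vectorised per-site sums over covering reads via difference arrays
    L = transcript_length
    diff_n = np.zeros(L + 1)
    diff_s = np.zeros(L + 1)
    diff_e = np.zeros(L + 1)
    np.add.at(diff_n, starts, 1)
    np.add.at(diff_n, ends, -1)
    np.add.at(diff_s, starts, starts)
    np.add.at(diff_s, ends, -starts)
    np.add.at(diff_e, starts, ends)
    np.add.at(diff_e, ends, -ends)
    n = np.cumsum(diff_n[:-1])
    sum_start = np.cumsum(diff_s[:-1])
    sum_end = np.cumsum(diff_e[:-1])

    i = np.arange(L)
    eligible = (i >= mrl) & (L - 1 - i >= mrl) & (n >= min_reads_at_site)
    with np.errstate(divide="ignore", invalid="ignore"):
        left = i - sum_start / n
        right = sum_end / n - i - 1
    asym = np.abs(left - right) > asym_fraction * mrl
    flagged = eligible & asym
    sites = i[flagged]
    return ChimeraFlag(
        transcript_id=str(transcript_id or alignments["transcript_id"].iloc[0]),
        sites=sites,
        left_overhang=left[flagged],
        right_overhang=right[flagged],
        mean_read_length=mrl,
    )


# ---------------------------------------------------------------------------
# k-mer cross-talk filter
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGT", "TGCA")


def _canonical_kmers(seq: str, k: int):
    seq = seq.upper()
    for j in range(len(seq) - k + 1):
        kmer = seq[j : j + k]
        rc = kmer.translate(_COMP)[::-1]
        yield min(kmer, rc)


def kmer_crosstalk_filter(
    reads_by_sample: dict[str, dict[str, str]],
    k: int = 21,
    fold: float = 500.0,
) -> tuple[dict[str, dict[str, str]], pd.DataFrame]:
    """Remove reads carrying k-mers with extreme between-sample imbalance.

    Canonical k-mer counts are normalised per million k-mers within each
    sample.  For every sample pair a k-mer is flagged for the lower-count
    sample when ``(higher + 0.5) / (lower + 0.5)`` strictly exceeds
    ``fold`` (0.5 is a pseudo-count so absent k-mers are comparable); reads
    in that sample containing a flagged k-mer are removed, on the premise
    that the low-count side received bleed-through.  Returns the filtered
    read sets and a removed-read report (sample, read_id).
    """
    if len(reads_by_sample) < 2:
        raise ValidationError("k-mer cross-talk filter needs >= 2 samples")
    counts: dict[str, dict[str, int]] = {}
    for sample, reads in reads_by_sample.items():
        c: dict[str, int] = {}
        for read in reads.values():
            if len(read) < k:
                raise ValidationError(f"k={k} exceeds a read length in {sample!r}")
            for kmer in _canonical_kmers(read, k):
                c[kmer] = c.get(kmer, 0) + 1
        counts[sample] = c
    ppm = {
        s: {kmer: n * 1e6 / max(sum(c.values()), 1) for kmer, n in c.items()}
        for s, c in counts.items()
    }
    samples = sorted(reads_by_sample)
    flagged: dict[str, set[str]] = {s: set() for s in samples}
    for a_i in range(len(samples)):
        for b_i in range(a_i + 1, len(samples)):
            a, b = samples[a_i], samples[b_i]
            for kmer in set(ppm[a]) | set(ppm[b]):
                va, vb = ppm[a].get(kmer, 0.0), ppm[b].get(kmer, 0.0)
                hi, lo = max(va, vb), min(va, vb)
                if (hi + 0.5) / (lo + 0.5) > fold:
                    flagged[a if va < vb else b].add(kmer)
    filtered: dict[str, dict[str, str]] = {}
    removed_rows = []
    for sample in samples:
        bad = flagged[sample]
        kept = {}
        for read_id, read in reads_by_sample[sample].items():
            if bad and any(kmer in bad for kmer in _canonical_kmers(read, k)):
                removed_rows.append({"sample": sample, "read_id": read_id})
            else:
                kept[read_id] = read
        filtered[sample] = kept
    report = pd.DataFrame(removed_rows, columns=["sample", "read_id"])
    return filtered, report


# ---------------------------------------------------------------------------
# identity clustering
# ---------------------------------------------------------------------------


@dataclass
class Cluster:
    cluster_id: int
    representative: str
    members: list[str] = field(default_factory=list)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    return aligner


def alignment_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Global-alignment identity: matches / alignment columns."""
    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(a, b)[0]
    identities = aln.counts().identities
    return identities / aln.length


def cluster_transcripts(
    sequences: dict[str, str], identity: float = 0.98
) -> list[Cluster]:
    """Greedy centroid clustering at a global-identity threshold.

    Sequences are processed longest-first (ties broken lexicographically by
    sequence then id, so the result is independent of input order).  Each
    sequence joins the first existing centroid with identity >= the
    threshold, else it seeds a new cluster.  The representative is the
    longest member, which by the processing order is the seed.
    """
    if not sequences:
        raise ValidationError("empty sequence set")
    for name, seq in sequences.items():
        if not seq:
            raise ValidationError(f"empty sequence {name!r}")
    aligner = _make_aligner()
    order = sorted(sequences, key=lambda n: (-len(sequences[n]), sequences[n], n))
    clusters: list[Cluster] = []
    for name in order:
        seq = sequences[name]
        for cluster in clusters:
            if alignment_identity(sequences[cluster.representative], seq, aligner) >= identity:
                cluster.members.append(name)
                break
        else:
            clusters.append(
                Cluster(cluster_id=len(clusters) + 1, representative=name, members=[name])
            )
    return clusters
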