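"""Readers and writers for the external formats the pipeline consumes.

All tabular formats are plain TSV.  Transcript coordinates are 0-based,
half-open everywhere inside the package; the SAM reader converts at ingress.

Formats owned by this module
----------------------------
wide expression   transcript_id + one numeric column per sample (TPM scale)
RSEM results      header-driven; needs transcript_id (or gene_id),
                  expected_count and TPM columns, any superset accepted
orthogroups       Orthogroup + one column per species of comma-separated ids
annotation        transcript_id, class, family, orthology_label
alignment table   read_id, transcript_id, start, end (0-based half-open)
SAM subset        minimal reader using POS and the reference-consumed CIGAR
FASTA             via Biopython
newick            via dendropy
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import FormatError, ValidationError

VENOM_TYPES = ("A", "A+B", "B")


@dataclass
class SampleMeta:
    """Metadata for one sequenced venom-gland sample."""

    sample_id: str
    species: str
    venom_type: str
    locality_label: str | None = None

    def __post_init__(self) -> None:
        if self.venom_type not in VENOM_TYPES:
            raise ValidationError(
                f"venom_type must be one of {VENOM_TYPES}, got {self.venom_type!r}"
            )


@dataclass
class Orthogroups:
    """Orthogroup membership per species.

    ``groups`` maps orthogroup id to a ``{species: [member ids]}`` dict.
    Every member id appears in exactly one orthogroup.
    """

    species: list[str]
    groups: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def members(self, orthogroup: str, species: str) -> list[str]:
        return self.groups[orthogroup].get(species, [])

    def all_members(self) -> list[str]:
        return [
            m
            for g in self.groups.values()
            for members in g.values()
            for m in members
        ]


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

_RSEM_REQUIRED = {"expected_count", "TPM"}


def read_expression_table(
    path,
    dialect: str = "wide_tsv",
    sample_id: str | None = None,
    value: str = "TPM",
) -> pd.DataFrame:
    """Read an expression table into a transcript x sample DataFrame.

    ``wide_tsv`` expects a ``transcript_id`` column followed by one numeric
    column per sample.  ``rsem_results`` reads a single-sample RSEM results
    file (any column superset; columns selected by header name) and returns a
    one-column matrix named ``sample_id`` holding the ``value`` column
    (``TPM`` by default, ``expected_count`` for count-based stages).
    """
    if dialect == "wide_tsv":
        try:
            df = pd.read_csv(path, sep="\t")
        except pd.errors.EmptyDataError as exc:
            raise FormatError(f"{path}: empty expression table") from exc
        if "transcript_id" not in df.columns:
            raise FormatError(f"{path}: wide TSV must have a transcript_id column")
        df = df.set_index("transcript_id")
        if df.shape[1] == 0:
            raise FormatError(f"{path}: no sample columns")
    elif dialect == "rsem_results":
        try:
            df = pd.read_csv(path, sep="\t")
        except pd.errors.EmptyDataError as exc:
            raise FormatError(f"{path}: empty expression table") from exc
        cols = set(df.columns)
        id_col = "transcript_id" if "transcript_id" in cols else "gene_id"
        if id_col not in cols or not _RSEM_REQUIRED <= cols:
            raise FormatError(
                f"{path}: RSEM results need transcript_id/gene_id, "
                f"expected_count and TPM columns; found {sorted(cols)}"
            )
        name = sample_id or "sample"
        df = df.set_index(id_col)[[value]].rename(columns={value: name})
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate transcript ids {dupes}")
    if (df.values < 0).any():
        raise ValidationError(f"{path}: negative expression values")
    return df


def write_expression_table(matrix: pd.DataFrame, path) -> None:
    matrix.rename_axis("transcript_id").to_csv(path, sep="\t")


def combine_rsem_samples(frames: list[pd.DataFrame], fill_missing: bool = False) -> pd.DataFrame:
    """Join single-sample RSEM matrices on transcript id.

    A transcript missing from one sample is an error unless
    ``fill_missing`` requests explicit zero-filling.
    """
    joined = pd.concat(frames, axis=1)
    if joined.isna().any().any():
        if not fill_missing:
            missing = joined.index[joined.isna().any(axis=1)].tolist()
            raise ValidationError(
                f"transcripts missing from some samples: {missing[:5]}..."
                if len(missing) > 5
                else f"transcripts missing from some samples: {missing}"
            )
        joined = joined.fillna(0.0)
    return joined


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_ANNOT_COLS = ["transcript_id", "class", "family", "orthology_label"]


def read_annotation(path) -> pd.DataFrame:
    """Read a transcript annotation table indexed by transcript id.

    Invariants: ids unique; family must be non-empty for toxins.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _ANNOT_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: annotation lacks columns {missing}")
    df = df.set_index("transcript_id")
    if df.index.has_duplicates:
        raise ValidationError(f"{path}: duplicate transcript ids in annotation")
    bad = df[(df["class"] == "toxin") & (df["family"] == "")]
    if len(bad):
        raise ValidationError(f"{path}: toxins without family: {bad.index.tolist()}")
    return df


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.rename_axis("transcript_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# orthogroups
# ---------------------------------------------------------------------------


def read_orthogroups(path) -> Orthogroups:
    """Read an OrthoFinder-style orthogroups TSV.

    First column is the orthogroup id, remaining columns are species, cells
    hold comma-separated member ids (empty cells allowed).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: orthogroups need an id column plus species columns")
    species = list(df.columns[1:])
    table = Orthogroups(species=species)
    seen: dict[str, str] = {}
    for _, row in df.iterrows():
        og = row.iloc[0]
        members = {}
        for sp in species:
            ids = [m.strip() for m in row[sp].split(",") if m.strip()]
            for m in ids:
                if m in seen:
                    raise ValidationError(
                        f"{path}: member {m!r} appears in both {seen[m]} and {og}"
                    )
                seen[m] = og
            members[sp] = ids
        table.groups[og] = members
    return table


def write_orthogroups(table: Orthogroups, path) -> None:
    rows = [
        {"Orthogroup": og, **{sp: ",".join(members.get(sp, [])) for sp in table.species}}
        for og, members in table.groups.items()
    ]
    pd.DataFrame(rows, columns=["Orthogroup", *table.species]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def read_tree(path) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"{path}: unparseable newick ({exc})") from exc


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------------
# read alignments
# ---------------------------------------------------------------------------

_ALN_COLS = ["read_id", "transcript_id", "start", "end"]


def read_alignment_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _ALN_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: alignment table lacks columns {missing}")
    df = df[_ALN_COLS].astype({"start": int, "end": int})
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        raise ValidationError(f"{path}: intervals must satisfy 0 <= start < end")
    return df


def write_alignment_table(alignments: pd.DataFrame, path) -> None:
    alignments[_ALN_COLS].to_csv(path, sep="\t", index=False)


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = set("MDN=X")


def cigar_reference_length(cigar: str) -> int:
    """Reference-consumed length of a CIGAR string."""
    ops = _CIGAR_RE.findall(cigar)
    if not ops or "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise FormatError(f"malformed CIGAR {cigar!r}")
    return sum(int(n) for n, op in ops if op in _REF_CONSUMING)


def read_sam_alignments(path) -> pd.DataFrame:
    """Minimal SAM subset reader: mapped reads to (read_id, transcript_id, start, end).

    Only QNAME/FLAG/RNAME/POS/CIGAR are used.  POS is 1-based in SAM and is
    converted to the package's 0-based half-open convention.  Unmapped records
    (flag 0x4 or RNAME ``*``) are skipped.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("@"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}: SAM record with <6 fields")
            qname, flag, rname, pos, _, cigar = fields[:6]
            if rname == "*" or int(flag) & 0x4:
                continue
            start = int(pos) - 1
            rows.append(
                {
                    "read_id": qname,
                    "transcript_id": rname,
                    "start": start,
                    "end": start + cigar_reference_length(cigar),
                }
            )
    return pd.DataFrame(rows, columns=_ALN_COLS)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValidationError(f"{path}: duplicate sequence id {record.id!r}")
        seqs[record.id] = str(record.seq).upper()
    return seqs


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
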