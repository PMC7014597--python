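"""Bundled reference tables for the two-species palm-pitviper dataset.

The package ships the published per-toxin summary tables for the venom-gland
transcriptomes of *Bothriechis nigroviridis* (samples CLP1856, CLP1864) and
*B. nubestris* (CLP1859, CLP1865): transcripts-per-million expression,
ortholog/paralog label, the over-expression call against the nontoxin null,
the coverage-based presence/absence verdicts, and the two interspecific
differential-expression result tables (Type A vs *B. nubestris* and
Type A+B vs *B. nubestris*).  These ship as plain TSV so every derivable
count and statistic can be recomputed without any download.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_toxin_table",
    "load_de_table",
    "toxin_expression",
    "summarize_toxin_table",
    "SAMPLES",
]

SAMPLES = {
    "nigroviridis": ("CLP1856", "CLP1864"),
    "nubestris": ("CLP1859", "CLP1865"),
}

_DE_FILES = {
    "A": "de_typeA_vs_nubestris.tsv",
    "A+B": "de_typeAB_vs_nubestris.tsv",
}


def _read(name: str, **kwargs) -> pd.DataFrame:
    ref = resources.files("venomics") / "data" / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", **kwargs)


def load_toxin_table(species: str) -> pd.DataFrame:
    """Per-toxin summary table for ``nigroviridis`` or ``nubestris``."""
    if species not in SAMPLES:
        raise KeyError(f"species must be one of {sorted(SAMPLES)}, got {species!r}")
    return _read(f"toxins_{species}.tsv")


def load_de_table(comparison: str) -> pd.DataFrame:
    """Interspecific DE table; ``comparison`` is ``"A"`` or ``"A+B"``.

    p-value columns are kept as printed strings (``<0.001``, ``NA``); use
    :func:`venomics.de.parse_printed_p` / :func:`venomics.de.count_significant`.
    """
    if comparison not in _DE_FILES:
        raise KeyError(f"comparison must be one of {sorted(_DE_FILES)}")
    return _read(_DE_FILES[comparison], dtype={"p_value": str, "p_adj": str})


def toxin_expression(species: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression matrix + annotation derived from a bundled toxin table."""
    table = load_toxin_table(species)
    s1, s2 = SAMPLES[species]
    expr = (
        table.set_index("transcript_id")[[f"tpm_{s1}", f"tpm_{s2}"]]
        .rename(columns={f"tpm_{s1}": s1, f"tpm_{s2}": s2})
    )
    annot = table.set_index("transcript_id")[["family", "orthology_label"]].assign(
        **{"class": "toxin"}
    )[["class", "family", "orthology_label"]]
    return expr, annot


def summarize_toxin_table(species: str) -> dict[str, int]:
    """Counts derivable from one bundled toxin table.

    Keys: n_toxins, n_orthologs, n_overexpression_flags, and per-sample
    absence counts ``n_absent_<sample>`` plus the discordant-presence total.
    """
    table = load_toxin_table(species)
    s1, s2 = SAMPLES[species]
    p1, p2 = table[f"presence_{s1}"], table[f"presence_{s2}"]
    return {
        "n_toxins": len(table),
        "n_orthologs": int((table["orthology_label"] == "Ortholog").sum()),
        "n_overexpression_flags": int((table["over_expression"] != "-").sum()),
        f"n_absent_{s1}": int((p1 == "-").sum()),
        f"n_absent_{s2}": int((p2 == "-").sum()),
        "n_presence_discordant": int((p1 != p2).sum()),
    }
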