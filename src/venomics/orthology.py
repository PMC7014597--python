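"""Orthogroup classification, gene-family turnover, and cross-species merging.

For a two-species comparison each orthogroup is classified from its member
counts ``(mA, mB)``:

* ``1:1``  -> both members are one-to-one orthologs,
* ``m:1`` or ``1:m`` (m > 1) -> the family duplicated; ``m - 1`` duplication
  events are charged to the multi-member species and every member of the
  group is a ``duplication_member``,
* ``m:0`` -> one loss event in the empty species; surviving members are
  ``lost_in_other``.

With only two species an empty side could equally be a gain in the other
lineage; following parsimony on a two-taxon comparison the event is recorded
as a loss in the empty species and the ambiguity noted in the event record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .exceptions import ValidationError
from .io import Orthogroups

__all__ = [
    "TurnoverEvent",
    "classify_orthogroups",
    "MergedExpression",
    "merge_cross_species_expression",
    "map_events_on_tree",
    "ortholog_paralog_factorial",
]

ONE_TO_ONE = "one_to_one"
DUPLICATION_MEMBER = "duplication_member"
LOST_IN_OTHER = "lost_in_other"


@dataclass
class TurnoverEvent:
    orthogroup: str
    event: str  # "duplication" | "loss"
    species: str
    count: int = 1
    note: str = ""


def classify_orthogroups(
    table: Orthogroups,
) -> tuple[pd.DataFrame, list[TurnoverEvent]]:
    """Classify every member transcript and enumerate turnover events.

    Returns a classes table (transcript_id index; species, orthogroup,
    cls columns) and the event list.  Duplication events per group number
    ``max(mA, mB) - 1``; each group with an empty side yields one loss
    event in the empty species.
    """
    if len(table.species) != 2:
        raise ValidationError(
            f"two-species table required, got {len(table.species)} species"
        )
    sp_a, sp_b = table.species
    rows = []
    events: list[TurnoverEvent] = []
    for og, members in table.groups.items():
        a = members.get(sp_a, [])
        b = members.get(sp_b, [])
        if not a and not b:
            continue
        if a and b:
            if len(a) == 1 and len(b) == 1:
                cls = ONE_TO_ONE
            else:
                cls = DUPLICATION_MEMBER
                bigger = sp_a if len(a) >= len(b) else sp_b
                events.append(
                    TurnoverEvent(
                        orthogroup=og,
                        event="duplication",
                        species=bigger,
                        count=max(len(a), len(b)) - 1,
                    )
                )
        else:
            cls = LOST_IN_OTHER
            empty = sp_a if not a else sp_b
            events.append(
                TurnoverEvent(
                    orthogroup=og,
                    event="loss",
                    species=empty,
                    count=1,
                    note="two-species parsimony: loss here and gain in the "
                    "other lineage are equally parsimonious",
                )
            )
        for sp, ids in ((sp_a, a), (sp_b, b)):
            for tid in ids:
                rows.append(
                    {"transcript_id": tid, "species": sp, "orthogroup": og, "cls": cls}
                )
    classes = pd.DataFrame(rows, columns=["transcript_id", "species", "orthogroup", "cls"])
    return classes.set_index("transcript_id"), events


def turnover_counts(events: list[TurnoverEvent]) -> dict[str, dict[str, int]]:
    """Total duplication/loss event counts per species."""
    out: dict[str, dict[str, int]] = {}
    for ev in events:
        out.setdefault(ev.event, {}).setdefault(ev.species, 0)
        out[ev.event][ev.species] += ev.count
    return out


@dataclass
class MergedExpression:
    """Cross-species expression with structural zeros for missing paralogs.

    One-to-one ortholog pairs collapse to a single row (named by the
    orthogroup) drawing each species' columns from its own transcript, so
    they carry no structural zeros.  Every other member keeps its own row,
    zero-filled (and masked as structural) in the species that lacks it.
    """

    values: pd.DataFrame
    structural_zeros: pd.DataFrame  # same shape, True where the zero is structural
    row_meta: pd.DataFrame  # orthogroup, cls, source transcript per species


def merge_cross_species_expression(
    classes: pd.DataFrame,
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    species: tuple[str, str] | None = None,
) -> MergedExpression:
    if species is None:
        species = tuple(dict.fromkeys(classes["species"]))  # first-seen order
    sp_a, sp_b = species
    cols = list(expr_a.columns) + list(expr_b.columns)
    values, struct, meta = [], [], []

    def expr_for(sp: str) -> pd.DataFrame:
        return expr_a if sp == sp_a else expr_b

    for og, group in classes.groupby("orthogroup", sort=True):
        cls = group["cls"].iloc[0]
        if cls == ONE_TO_ONE:
            tid_a = group.index[group["species"] == sp_a][0]
            tid_b = group.index[group["species"] == sp_b][0]
            for tid, expr in ((tid_a, expr_a), (tid_b, expr_b)):
                if tid not in expr.index:
                    raise KeyError(f"expression missing for transcript {tid!r}")
            row = pd.concat([expr_a.loc[tid_a], expr_b.loc[tid_b]])
            values.append(row.rename(og))
            struct.append(pd.Series(False, index=cols, name=og))
            meta.append({"row": og, "orthogroup": og, "cls": cls,
                         sp_a: tid_a, sp_b: tid_b})
        else:
            for tid, sp in group["species"].items():
                expr = expr_for(sp)
                if tid not in expr.index:
                    raise KeyError(f"expression missing for transcript {tid!r}")
                own = expr.loc[tid]
                other_cols = [c for c in cols if c not in expr.columns]
                row = pd.concat([own, pd.Series(0.0, index=other_cols)])[cols]
                values.append(row.rename(tid))
                mask = pd.Series(False, index=cols, name=tid)
                mask[other_cols] = True
                struct.append(mask)
                meta.append({"row": tid, "orthogroup": og, "cls": cls,
                             sp_a: tid if sp == sp_a else "",
                             sp_b: tid if sp == sp_b else ""})
    values_df = pd.DataFrame(values, columns=cols)
    struct_df = pd.DataFrame(struct, columns=cols)
    meta_df = pd.DataFrame(meta).set_index("row")
    return MergedExpression(values=values_df, structural_zeros=struct_df, row_meta=meta_df)


def map_events_on_tree(
    tree: dendropy.Tree,
    events: list[TurnoverEvent],
    classes: pd.DataFrame,
) -> tuple[dendropy.Tree, list[dict]]:
    """Attach turnover events to a gene-family tree.

    Each event yields exactly one annotation record.  A duplication whose
    same-species members form a monophyletic group is attached to their
    MRCA's parent edge; otherwise the single annotation lists all member
    tips.  A loss is attached at the surviving members' position (their tip,
    or MRCA for several survivors), marking the missing sister lineage.
    Tips absent from the classes table produce a warning, not an error.
    """
    tree.is_rooted = True  # MRCA queries need an explicit root
    tips = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter() if leaf.taxon}
    for label in tips:
        if label not in classes.index:
            warnings.warn(f"tree tip {label!r} not in orthology table", stacklevel=2)
    annotations: list[dict] = []
    for ev in events:
        group = classes[classes["orthogroup"] == ev.orthogroup]
        if ev.event == "duplication":
            target_ids = group.index[group["species"] == ev.species]
        else:  # loss: annotate the survivors' position
            target_ids = group.index
        nodes = [tips[t] for t in target_ids if t in tips]
        if not nodes:
            warnings.warn(
                f"no tree tips for {ev.event} in {ev.orthogroup}; unannotated",
                stacklevel=2,
            )
            continue
        if len(nodes) == 1:
            attach, where = nodes[0], "tip"
        else:
            mrca = tree.mrca(taxa=[n.taxon for n in nodes])
            clade_tips = {leaf.taxon.label for leaf in mrca.leaf_iter()}
            if clade_tips == set(t for t in target_ids if t in tips):
                attach, where = mrca, "edge"
            else:
                attach, where = None, "tips"
        record = {
            "orthogroup": ev.orthogroup,
            "event": ev.event,
            "species": ev.species,
            "count": ev.count,
            "where": where,
            "tips": list(target_ids),
        }
        annotations.append(record)
        label = f"{ev.event}:{ev.species}:{ev.orthogroup}"
        targets = [attach] if attach is not None else nodes
        for node in targets:
            existing = node.annotations.get_value("turnover", "")
            node.annotations.drop(name="turnover")
            node.annotations.add_new(
                "turnover", f"{existing}|{label}" if existing else label
            )
    return tree, annotations


def ortholog_paralog_factorial(
    merged_clr: pd.DataFrame,
    classes: pd.DataFrame,
    species_of_sample: dict[str, str],
) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA of CLR expression.

    Factors: toxin type (one-to-one ortholog vs duplicated/conserved other)
    and species, with interaction; type II sums of squares because the
    design is unbalanced (unequal member counts per class).  ``merged_clr``
    is a merged matrix (see :func:`merge_cross_species_expression`) already
    in CLR units; rows are mapped to type via ``classes``.
    """
    long_rows = []
    cls_by_og = classes.reset_index().drop_duplicates("orthogroup").set_index("orthogroup")["cls"]
    for row_id, row in merged_clr.iterrows():
        if row_id in classes.index:
            cls = classes.loc[row_id, "cls"]
        elif row_id in cls_by_og.index:
            cls = cls_by_og.loc[row_id]
        else:
            raise KeyError(f"row {row_id!r} not resolvable to an orthology class")
        toxin_type = "one_to_one" if cls == ONE_TO_ONE else "other"
        for sample, value in row.items():
            long_rows.append(
                {
                    "value": float(value),
                    "toxin_type": toxin_type,
                    "species": species_of_sample[sample],
                }
            )
    data = pd.DataFrame(long_rows)
    cell_sizes = data.groupby(["toxin_type", "species"]).size()
    if (cell_sizes < 2).any() or len(cell_sizes) < 4:
        empty = cell_sizes[cell_sizes < 2] if len(cell_sizes) == 4 else cell_sizes
        raise ValidationError(f"factorial needs >=2 observations per cell, got:\n{empty}")
    model = smf.ols("value ~ C(toxin_type) * C(species)", data=data).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    anova = anova.rename(
        index={
            "C(toxin_type)": "toxin_type",
            "C(species)": "species",
            "C(toxin_type):C(species)": "toxin_type:species",
            "Residual": "residual",
        }
    )
    return anova.rename(columns={"PR(>F)": "p_value"})
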