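"""Orthogroup classification, turnover events, merging, tree mapping, ANOVA."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from venomics import composition, orthology, simulate
from venomics.exceptions import ValidationError
from venomics.io import Orthogroups


def _table(groups):
    return Orthogroups(species=["A", "B"], groups=groups)


def test_basic_classification_and_events():
    table = _table(
        {
            "OG1": {"A": ["a1"], "B": ["b1"]},
            "OG2": {"A": ["a2", "a3"], "B": ["b2"]},
            "OG3": {"A": [], "B": ["b3"]},
        }
    )
    classes, events = orthology.classify_orthogroups(table)
    assert classes.loc["a1", "cls"] == orthology.ONE_TO_ONE
    assert classes.loc["a2", "cls"] == orthology.DUPLICATION_MEMBER
    assert classes.loc["b2", "cls"] == orthology.DUPLICATION_MEMBER
    assert classes.loc["b3", "cls"] == orthology.LOST_IN_OTHER
    by_kind = orthology.turnover_counts(events)
    assert by_kind["duplication"] == {"A": 1}
    assert by_kind["loss"] == {"A": 1}


def test_planted_scenario_recovered():
    table, truth = simulate.simulate_orthogroups(3, 2, 1, 1, 2, seed=5)
    classes, events = orthology.classify_orthogroups(table)
    counts = orthology.turnover_counts(events)
    assert counts.get("duplication", {}).get("A", 0) == truth.n_dup_a
    assert counts.get("duplication", {}).get("B", 0) == truth.n_dup_b
    assert counts.get("loss", {}).get("A", 0) == truth.n_loss_a
    assert counts.get("loss", {}).get("B", 0) == truth.n_loss_b
    n_one = (classes["cls"] == orthology.ONE_TO_ONE).sum() // 2
    assert n_one == truth.n_one_to_one


def test_event_conservation_identities(rng):
    groups = {}
    for i in range(50):
        m_a, m_b = int(rng.integers(0, 4)), int(rng.integers(0, 4))
        if m_a == 0 and m_b == 0:
            m_b = 1
        groups[f"OG{i}"] = {
            "A": [f"a{i}_{j}" for j in range(m_a)],
            "B": [f"b{i}_{j}" for j in range(m_b)],
        }
    _, events = orthology.classify_orthogroups(_table(groups))
    dup_total = sum(e.count for e in events if e.event == "duplication")
    loss_total = sum(e.count for e in events if e.event == "loss")
    expected_dup = sum(
        max(len(g["A"]), len(g["B"])) - 1
        for g in groups.values()
        if g["A"] and g["B"] and max(len(g["A"]), len(g["B"])) > 1
    )
    expected_loss = sum(1 for g in groups.values() if not g["A"] or not g["B"])
    assert dup_total == expected_dup
    assert loss_total == expected_loss


def test_merge_structural_zeros():
    table = _table(
        {
            "OG1": {"A": ["a1"], "B": ["b1"]},
            "OG2": {"A": ["a2", "a3"], "B": ["b2"]},
            "OG3": {"A": [], "B": ["b3"]},
        }
    )
    classes, _ = orthology.classify_orthogroups(table)
    expr_a = pd.DataFrame(
        {"A1": [10.0, 5.0, 2.0], "A2": [20.0, 6.0, 3.0]}, index=["a1", "a2", "a3"]
    )
    expr_b = pd.DataFrame({"B1": [7.0, 4.0, 9.0], "B2": [8.0, 5.0, 10.0]},
                          index=["b1", "b2", "b3"])
    merged = orthology.merge_cross_species_expression(classes, expr_a, expr_b)
    # one-to-one pair collapses to one row without structural zeros
    assert not merged.structural_zeros.loc["OG1"].any()
    assert merged.values.loc["OG1", "A1"] == 10.0 and merged.values.loc["OG1", "B1"] == 7.0
    # a B-only member is structurally zero in both A samples
    assert merged.structural_zeros.loc["b3", ["A1", "A2"]].all()
    assert (merged.values.loc["b3", ["A1", "A2"]] == 0).all()
    # row count: one per 1:1 group, one per other member
    assert len(merged.values) == 1 + 3 + 1


def test_merge_missing_expression_raises():
    table = _table({"OG1": {"A": ["a1"], "B": ["b1"]}})
    classes, _ = orthology.classify_orthogroups(table)
    expr_a = pd.DataFrame({"A1": [1.0]}, index=["a1"])
    expr_b = pd.DataFrame({"B1": [1.0]}, index=["other"])
    with pytest.raises(KeyError):
        orthology.merge_cross_species_expression(classes, expr_a, expr_b)


def test_map_events_duplication_on_monophyletic_edge():
    table = _table({"OG1": {"A": ["a1", "a2"], "B": ["b1"]}})
    classes, events = orthology.classify_orthogroups(table)
    tree = dendropy.Tree.get(data="((a1,a2),b1);", schema="newick")
    annotated, records = orthology.map_events_on_tree(tree, events, classes)
    assert len(records) == len(events) == 1
    assert records[0]["where"] == "edge"
    mrca = annotated.mrca(taxon_labels=["a1", "a2"])
    assert "duplication:A:OG1" in mrca.annotations.get_value("turnover")


def test_map_events_no_events_no_annotations():
    table = _table({"OG1": {"A": ["a1"], "B": ["b1"]}})
    classes, events = orthology.classify_orthogroups(table)
    tree = dendropy.Tree.get(data="(a1,b1);", schema="newick")
    _, records = orthology.map_events_on_tree(tree, events, classes)
    assert records == []


def test_map_events_annotation_count_equals_event_count(rng):
    # random planted scenarios: one annotation record per event
    for rep in range(5):
        table, _ = simulate.simulate_orthogroups(
            2, int(rng.integers(0, 3)), int(rng.integers(0, 3)),
            int(rng.integers(0, 3)), int(rng.integers(0, 3)), seed=rep
        )
        classes, events = orthology.classify_orthogroups(table)
        tips = list(classes.index)
        newick = "(" + ",".join(tips) + ");"
        tree = dendropy.Tree.get(data=newick, schema="newick")
        _, records = orthology.map_events_on_tree(tree, events, classes)
        assert len(records) == len(events)


def _factorial_data(rng, interaction=0.0, n_per_cell=20):
    rows = {}
    classes_rows = []
    for t_i, cls in enumerate([orthology.ONE_TO_ONE, orthology.DUPLICATION_MEMBER]):
        for g in range(n_per_cell):
            rid = f"{cls}_{g}"
            a = rng.normal(0, 1, 2)
            b = rng.normal(0, 1, 2)
            if t_i == 1:
                b = b + interaction  # species x type interaction
            rows[rid] = np.concatenate([a, b])
            classes_rows.append({"transcript_id": rid, "species": "A",
                                 "orthogroup": rid, "cls": cls})
    merged = pd.DataFrame.from_dict(
        rows, orient="index", columns=["A1", "A2", "B1", "B2"]
    )
    classes = pd.DataFrame(classes_rows).set_index("transcript_id")
    species = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
    return merged, classes, species


def test_factorial_null_p_is_calibrated(rng):
    pvals = []
    for _ in range(100):
        merged, classes, species = _factorial_data(rng)
        anova = orthology.ortholog_paralog_factorial(merged, classes, species)
        pvals.append(anova.loc["toxin_type:species", "p_value"])
    assert 0.01 <= np.mean(np.array(pvals) < 0.05) <= 0.12


def test_factorial_detects_planted_interaction(rng):
    hits = 0
    for _ in range(20):
        merged, classes, species = _factorial_data(rng, interaction=2.0)
        anova = orthology.ortholog_paralog_factorial(merged, classes, species)
        hits += anova.loc["toxin_type:species", "p_value"] < 0.01
    assert hits >= 19


def test_factorial_empty_cell_errors(rng):
    merged, classes, species = _factorial_data(rng, n_per_cell=1)
    # one observation per (type, species) cell in the one_to_one row set
    merged = merged.iloc[:1]
    classes = classes.iloc[:1]
    with pytest.raises(ValidationError):
        orthology.ortholog_paralog_factorial(merged, classes, species)


def test_factorial_is_invariant_to_pre_clr_scaling(rng):
    # doubling raw TPM before CLR leaves CLR values, hence F, unchanged
    raw = pd.DataFrame(
        rng.lognormal(3, 1, (40, 4)), columns=["A1", "A2", "B1", "B2"],
        index=[f"t{i}" for i in range(40)],
    )
    clr1 = composition.clr_transform(raw)
    clr2 = composition.clr_transform(raw * 2.0)
    classes = pd.DataFrame(
        {
            "species": ["A"] * 40,
            "orthogroup": [f"t{i}" for i in range(40)],
            "cls": [orthology.ONE_TO_ONE] * 20 + [orthology.DUPLICATION_MEMBER] * 20,
        },
        index=raw.index,
    )
    species = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
    a1 = orthology.ortholog_paralog_factorial(clr1, classes, species)
    a2 = orthology.ortholog_paralog_factorial(clr2, classes, species)
    np.testing.assert_allclose(a1["F"].dropna(), a2["F"].dropna(),
                               rtol=1e-6, atol=1e-10)


def test_three_species_table_rejected():
    table = Orthogroups(species=["A", "B", "C"],
                        groups={"OG1": {"A": ["a"], "B": ["b"], "C": ["c"]}})
    with pytest.raises(ValidationError):
        orthology.classify_orthogroups(table)
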