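"""Epistasis scores, classification, experimental comparison and PR curves."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from fluxcost.epistasis import (classify_experimental, classify_prediction,
                                compare_with_experiment, epistasis_score,
                                filter_deletion_fitness,
                                precision_recall_curve, predict_pairwise)
from fluxcost.fba import Medium
from fluxcost.fixtures import make_scenario_model, scenario_medium
from fluxcost.gpr import parse_gpr
from fluxcost.model import MetabolicModel, Reaction


@pytest.mark.parametrize("wi, wj, wij, eps", [
    (1.0, 1.0, 0.0, -1.0),    # synthetic lethal
    (0.5, 0.5, 0.25, 0.0),    # multiplicative: no interaction
    (0.5, 0.5, 0.5, 0.25),    # antagonistic
])
def test_epistasis_formula(wi, wj, wij, eps):
    assert epistasis_score(wi, wj, wij) == pytest.approx(eps)


@pytest.mark.parametrize("eps, cls", [
    (-0.5, "synergistic"), (0.0, "none"), (5e-5, "none"),
    (0.002, "antagonistic"), (-0.00011, "synergistic"),
])
def test_prediction_classification(eps, cls):
    assert classify_prediction(eps) == cls


@pytest.mark.parametrize("eps, p, cls", [
    (-0.2, 0.001, "synergistic"),
    (-0.2, 0.2, "none"),       # fails the p cutoff
    (0.05, 0.001, "none"),     # fails the magnitude cutoff
    (0.2, 0.01, "antagonistic"),
])
def test_experimental_classification(eps, p, cls):
    assert classify_experimental(eps, p) == cls


def test_fitness_filter_keeps_boundary():
    table = pd.DataFrame({
        "gene_i": list("abc"), "gene_j": list("xyz"),
        "epsilon": [0.0] * 3, "p_value": [1.0] * 3,
        "fitness_i": [1.0, 1.0 + 3 * 0.05, 1.0 + 2 * 0.05],
        "fitness_j": [1.0, 1.0, 1.0],
    })
    kept = filter_deletion_fitness(table, wt_fitness=1.0, wt_sd=0.05)
    # wt+3sd removed; exact wt+2sd boundary kept ("no greater than")
    assert list(kept["gene_i"]) == ["a", "c"]


# -- prediction on fixture models -----------------------------------------

def test_isoenzyme_pair_semantics_transition():
    """The canonical isoenzyme pair: masked synthetic lethality under
    redundancy (eps = -1), no interaction once singles are already lethal
    under non-redundancy (eps = 0)."""
    model = make_scenario_model("isoenzyme")
    medium = scenario_medium()
    (red,) = predict_pairwise(model, [("g1", "g2")], medium, "redundant")
    assert (red.w_i, red.w_j, red.w_ij) == pytest.approx((1.0, 1.0, 0.0))
    assert red.epsilon == pytest.approx(-1.0)
    assert red.predicted_class == "synergistic"
    (non,) = predict_pairwise(model, [("g1", "g2")], medium, "nonredundant")
    assert (non.w_i, non.w_j, non.w_ij) == pytest.approx((0.0, 0.0, 0.0))
    assert non.epsilon == pytest.approx(0.0)
    assert non.predicted_class == "none"


def test_independent_bypassable_branches_show_no_epistasis():
    inf = np.inf
    model = MetabolicModel(
        reactions=[
            Reaction("EX_A", {"A": -1.0}, 0.0, inf, is_exchange=True),
            Reaction("P1", {"A": -1.0, "B": 1.0}, 0.0, inf),
            Reaction("P2", {"A": -1.0, "B": 1.0}, 0.0, inf),
            Reaction("Q1", {"B": -1.0, "C": 1.0}, 0.0, inf),
            Reaction("Q2", {"B": -1.0, "C": 1.0}, 0.0, inf),
            Reaction("GROWTH", {"C": -1.0}, 0.0, inf),
        ],
        objective_reaction="GROWTH",
        gpr={"P1": parse_gpr("g1"), "P2": parse_gpr("g2"),
             "Q1": parse_gpr("g3"), "Q2": parse_gpr("g4")},
    )
    medium = Medium("min", {"EX_A": 10.0})
    # g1 and g3 sit on different steps, each with a full-capacity bypass
    (rec,) = predict_pairwise(model, [("g1", "g3")], medium, "redundant")
    assert rec.epsilon == pytest.approx(0.0, abs=1e-9)
    # but the parallel pair on the same step is synthetically lethal
    (rec,) = predict_pairwise(model, [("g1", "g2")], medium, "redundant")
    assert rec.epsilon == pytest.approx(-1.0)


def test_epsilon_symmetric(toy_bundle):
    model = toy_bundle["model"]
    medium = toy_bundle["media"][0]
    genes = sorted(toy_bundle["catalog"].analysis_genes)[:6]
    pairs = [(genes[0], genes[1]), (genes[2], genes[3])]
    fwd = predict_pairwise(model, pairs, medium, "nonredundant")
    rev = predict_pairwise(model, [(j, i) for i, j in pairs], medium,
                           "nonredundant")
    for a, b in zip(fwd, rev):
        assert a.epsilon == pytest.approx(b.epsilon, abs=1e-9)


def test_nonredundant_interactions_superset(toy_bundle):
    """Rewriting OR to AND only adds knocked-out reactions, so every pair
    interacting under redundancy still interacts under non-redundancy
    (checked on pairs whose single knockouts stay viable both ways)."""
    model = toy_bundle["model"]
    medium = toy_bundle["media"][0]
    genes = sorted(toy_bundle["catalog"].analysis_genes)[:16]
    pairs = [(genes[i], genes[j]) for i in range(len(genes))
             for j in range(i + 1, len(genes))]
    red = predict_pairwise(model, pairs, medium, "redundant")
    non = predict_pairwise(model, pairs, medium, "nonredundant")
    red_hits = {(r.gene_i, r.gene_j) for r in red
                if r.predicted_class != "none"}
    non_viable = {(r.gene_i, r.gene_j): r for r in non}
    for key in red_hits:
        r = non_viable[key]
        # interaction persists unless a single became lethal (masking w=0)
        if r.w_i > 0 and r.w_j > 0:
            assert r.predicted_class != "none"


def test_unknown_gene_and_dead_medium_raise():
    model = make_scenario_model("isoenzyme")
    with pytest.raises(KeyError):
        predict_pairwise(model, [("g1", "nope")], scenario_medium())
    with pytest.raises(ValueError, match="does not grow"):
        predict_pairwise(model, [("g1", "g2")], Medium("starve", {}))


# -- comparison machinery --------------------------------------------------

def fisher_oracle_greater(a, b, c, d):
    """One-sided (enrichment) Fisher p by hypergeometric enumeration."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(k):
        return (math.comb(col1, k) * math.comb(n - col1, row1 - k)
                / math.comb(n, row1))

    return sum(prob(k) for k in range(a, min(row1, col1) + 1))


def records_from(eps_map):
    from fluxcost.epistasis import EpistasisRecord, classify_prediction

    return [EpistasisRecord(i, j, 1.0, 1.0, 1.0 + e, e,
                            classify_prediction(e))
            for (i, j), e in eps_map.items()]


def exp_table(class_map):
    rows = []
    for (i, j), cls in class_map.items():
        eps = {"synergistic": -0.5, "antagonistic": 0.5, "none": 0.0}[cls]
        rows.append((i, j, eps, 0.001, 1.0, 1.0))
    return pd.DataFrame(rows, columns=["gene_i", "gene_j", "epsilon",
                                       "p_value", "fitness_i", "fitness_j"])


def test_perfect_predictions_score_one():
    classes = {("a", "b"): "synergistic", ("c", "d"): "antagonistic",
               ("e", "f"): "none", ("g", "h"): "synergistic"}
    eps = {k: {"synergistic": -0.5, "antagonistic": 0.5, "none": 0.0}[v]
           for k, v in classes.items()}
    cmp = compare_with_experiment(records_from(eps), exp_table(classes))
    assert cmp.n_pairs == 4
    for cls in ("synergistic", "antagonistic", "none"):
        assert cmp.precision[cls] == 1.0 and cmp.recall[cls] == 1.0


def test_all_none_predictions_have_zero_recall():
    classes = {("a", "b"): "synergistic", ("c", "d"): "antagonistic",
               ("e", "f"): "none"}
    eps = {k: 0.0 for k in classes}
    cmp = compare_with_experiment(records_from(eps), exp_table(classes))
    assert cmp.recall["synergistic"] == 0.0
    assert cmp.recall["antagonistic"] == 0.0
    assert cmp.recall["none"] == 1.0


def test_fisher_p_matches_hypergeometric_oracle():
    rng = np.random.default_rng(0)
    for _ in range(5):
        n = 30
        keys = [(f"a{i}", f"b{i}") for i in range(n)]
        exp_cls = {k: rng.choice(["synergistic", "none"], p=[0.3, 0.7])
                   for k in keys}
        eps = {k: float(rng.choice([-0.5, 0.0], p=[0.4, 0.6])) for k in keys}
        cmp = compare_with_experiment(records_from(eps), exp_table(exp_cls))
        a = int(cmp.confusion.loc["synergistic", "synergistic"])
        b = int(cmp.confusion.loc[["antagonistic", "none"],
                                  "synergistic"].sum())
        c = int(cmp.confusion.loc["synergistic",
                                  ["antagonistic", "none"]].sum())
        d = n - a - b - c
        assert cmp.fisher_p["synergistic"] == pytest.approx(
            fisher_oracle_greater(a, b, c, d), rel=1e-9)


def test_pr_curve_monotone_recall():
    rng = np.random.default_rng(1)
    keys = [(f"a{i}", f"b{i}") for i in range(40)]
    eps = {k: float(rng.normal(0, 0.05)) for k in keys}
    exp_cls = {k: ("synergistic" if e < -0.02 and rng.random() < 0.8
                   else "none") for k, e in eps.items()}
    curve = precision_recall_curve(records_from(eps), exp_table(exp_cls),
                                   cutoffs=np.logspace(-4, -1, 12))
    syn = curve[curve["class"] == "synergistic"].sort_values("cutoff")
    rec = syn["recall"].to_numpy()
    assert np.all(np.diff(rec) <= 1e-12)  # recall never rises with the cutoff
    # extreme cutoffs: everything / nothing recalled
    assert precision_recall_curve(
        records_from(eps), exp_table(exp_cls),
        cutoffs=np.array([10.0]))["recall"].fillna(0).eq(0).all()
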