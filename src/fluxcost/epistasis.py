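"""Pairwise epistasis prediction and comparison with experimental data.

Epistasis between genes i and j is the deviation of the double-mutant
relative fitness from the multiplicative expectation:

    epsilon_ij = w_ij - w_i * w_j,

with relative fitness w = 1 - c derived from the FBA loss cost (wild type
w = 1).  Negative epsilon is synergistic (the double knockout hurts more than
expected, e.g. synthetic lethality); positive is antagonistic.

Predictions are made under either GPR semantics: "redundant" (standard FBA —
isoenzyme partners provide full backup, so a lone isoenzyme deletion is free)
or "nonredundant" (every OR rewritten to AND, so any isoenzyme deletion
disables its reaction).  Joint deletions evaluate the GPR with both genes
absent, which captures isoenzyme pairs that jointly disable a reaction
neither disables alone.

Predicted interactions are classified by a magnitude cutoff on epsilon alone
(FBA is deterministic); experimental interactions additionally require a
p-value cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fba import FbaProblem, Medium, knockout_reactions
from .model import MetabolicModel

__all__ = [
    "EpistasisRecord", "InteractionComparison",
    "epistasis_score", "predict_pairwise",
    "classify_prediction", "classify_experimental",
    "filter_deletion_fitness", "compare_with_experiment",
    "precision_recall_curve", "experimental_from_tsv",
    "PREDICTION_CUTOFF", "EXPERIMENTAL_EPS_CUTOFF", "EXPERIMENTAL_P_CUTOFF",
    "CLASSES",
]

#: |epsilon| cutoff for calling a predicted interaction
PREDICTION_CUTOFF = 1e-4
#: intermediate criteria for experimental interaction calls
EXPERIMENTAL_EPS_CUTOFF = 0.08
EXPERIMENTAL_P_CUTOFF = 0.05

CLASSES = ("synergistic", "antagonistic", "none")


@dataclass(frozen=True)
class EpistasisRecord:
    gene_i: str
    gene_j: str
    w_i: float
    w_j: float
    w_ij: float
    epsilon: float
    predicted_class: str


def epistasis_score(w_i: float, w_j: float, w_ij: float) -> float:
    """epsilon = w_ij - w_i * w_j."""
    return w_ij - w_i * w_j


def classify_prediction(epsilon: float,
                        cutoff: float = PREDICTION_CUTOFF) -> str:
    """synergistic if epsilon < -cutoff, antagonistic if > +cutoff, else none."""
    if epsilon < -cutoff:
        return "synergistic"
    if epsilon > cutoff:
        return "antagonistic"
    return "none"


def classify_experimental(epsilon: float, p_value: float,
                          eps_cutoff: float = EXPERIMENTAL_EPS_CUTOFF,
                          p_cutoff: float = EXPERIMENTAL_P_CUTOFF) -> str:
    """Interacting only if |epsilon| > eps_cutoff and p < p_cutoff; the sign
    of epsilon gives the class."""
    if abs(epsilon) > eps_cutoff and p_value < p_cutoff:
        return "synergistic" if epsilon < 0 else "antagonistic"
    return "none"


def predict_pairwise(model: MetabolicModel,
                     pairs: list[tuple[str, str]],
                     medium: Medium,
                     semantics: str = "redundant",
                     blocked: frozenset[str] = frozenset(),
                     cutoff: float = PREDICTION_CUTOFF
                     ) -> list[EpistasisRecord]:
    """Predict epistasis for each gene pair in one medium.

    Single- and double-knockout fitnesses come from FBA with the reactions
    disabled by the corresponding (joint) gene deletion blocked; fitness is
    normalised by the wild type and clipped to [0, 1] (FBA cannot predict
    fitness gains).  Unknown genes raise; a non-growing wild type raises.
    """
    genes = model.genes
    for i, j in pairs:
        unknown = {i, j} - genes
        if unknown:
            raise KeyError(f"genes not in model: {sorted(unknown)}")
    problem = FbaProblem(model, medium)
    wt = problem.solve(blocked)
    if not wt.grows:
        raise ValueError(f"wild type does not grow in medium {medium.name!r}")
    w_wt = wt.objective_value

    fitness_cache: dict[frozenset[str], float] = {}

    def fitness(deleted: frozenset[str]) -> float:
        if deleted not in fitness_cache:
            targets = knockout_reactions(model, deleted, semantics) - blocked
            if all(abs(wt.fluxes[r]) <= 1e-9 for r in targets):
                w = 1.0  # wild-type optimum unaffected
            else:
                sol = problem.solve(blocked | targets)
                w = (sol.objective_value / w_wt) if sol.status == "optimal" else 0.0
            fitness_cache[deleted] = min(1.0, max(0.0, w))
        return fitness_cache[deleted]

    records = []
    for i, j in pairs:
        w_i = fitness(frozenset({i}))
        w_j = fitness(frozenset({j}))
        w_ij = fitness(frozenset({i, j}))
        eps = epistasis_score(w_i, w_j, w_ij)
        records.append(EpistasisRecord(i, j, w_i, w_j, w_ij, eps,
                                       classify_prediction(eps, cutoff)))
    return records


# -- experimental comparison ----------------------------------------------


def experimental_from_tsv(path) -> pd.DataFrame:
    """Read an experimental genetic-interaction table.

    Columns: gene_i, gene_j, epsilon, p_value, fitness_i, fitness_j.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_i", "gene_j", "epsilon", "p_value",
                "fitness_i", "fitness_j"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"interaction table missing columns: {sorted(missing)}")
    return df


def filter_deletion_fitness(table: pd.DataFrame, wt_fitness: float,
                            wt_sd: float) -> pd.DataFrame:
    """Drop pairs where either single-mutant fitness exceeds the wild type by
    more than two standard deviations (FBA cannot predict fitness gains).
    The boundary value wt + 2*sd is kept."""
    ceiling = wt_fitness + 2.0 * wt_sd
    keep = (table["fitness_i"] <= ceiling) & (table["fitness_j"] <= ceiling)
    return table[keep].reset_index(drop=True)


@dataclass
class InteractionComparison:
    """Confusion matrix (experimental rows x predicted columns) with per-class
    precision/recall and a per-class 2x2 Fisher enrichment p-value."""

    confusion: pd.DataFrame
    precision: dict[str, float]
    recall: dict[str, float]
    fisher_p: dict[str, float]
    n_pairs: int


def _pair_key(i: str, j: str) -> tuple[str, str]:
    return (i, j) if i <= j else (j, i)


def compare_with_experiment(predictions: list[EpistasisRecord],
                            experimental: pd.DataFrame
                            ) -> InteractionComparison:
    """Score predicted classes against experimental classes pair by pair.

    ``experimental`` needs columns gene_i, gene_j and either a precomputed
    ``class`` column or epsilon/p_value (classified with the standard
    cutoffs).  Pairs present in both tables are compared; per interacting
    class, enrichment of predicted-in-class among experimental-in-class is
    tested with Fisher's exact test on the collapsed 2x2 table.
    """
    exp = experimental.copy()
    if "class" not in exp.columns:
        exp["class"] = [
            classify_experimental(e, p)
            for e, p in zip(exp["epsilon"], exp["p_value"])
        ]
    exp_class = {_pair_key(i, j): c for i, j, c in
                 zip(exp["gene_i"], exp["gene_j"], exp["class"])}
    pred_class = {_pair_key(r.gene_i, r.gene_j): r.predicted_class
                  for r in predictions}
    common = sorted(set(exp_class) & set(pred_class))
    confusion = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES))
    for key in common:
        confusion.loc[exp_class[key], pred_class[key]] += 1
    precision, recall, fisher_p = {}, {}, {}
    for cls in CLASSES:
        tp = int(confusion.loc[cls, cls])
        pred_pos = int(confusion[cls].sum())
        actual_pos = int(confusion.loc[cls].sum())
        precision[cls] = tp / pred_pos if pred_pos else float("nan")
        recall[cls] = tp / actual_pos if actual_pos else float("nan")
        n = int(confusion.values.sum())
        table = np.array([
            [tp, pred_pos - tp],
            [actual_pos - tp, n - pred_pos - actual_pos + tp],
        ])
        fisher_p[cls] = float(stats.fisher_exact(table,
                                                 alternative="greater")[1])
    return InteractionComparison(confusion, precision, recall, fisher_p,
                                 len(common))


def precision_recall_curve(predictions: list[EpistasisRecord],
                           experimental: pd.DataFrame,
                           cutoffs: np.ndarray | None = None
                           ) -> pd.DataFrame:
    """Precision/recall per interacting class as the prediction |epsilon|
    cutoff varies; the experimental classification stays fixed.

    Returns a long DataFrame with columns cutoff, class, precision, recall.
    """
    if cutoffs is None:
        cutoffs = np.logspace(-4, -2, 25)
    exp = experimental.copy()
    if "class" not in exp.columns:
        exp["class"] = [
            classify_experimental(e, p)
            for e, p in zip(exp["epsilon"], exp["p_value"])
        ]
    exp_class = {_pair_key(i, j): c for i, j, c in
                 zip(exp["gene_i"], exp["gene_j"], exp["class"])}
    eps = {_pair_key(r.gene_i, r.gene_j): r.epsilon for r in predictions}
    common = sorted(set(exp_class) & set(eps))
    rows = []
    for cutoff in np.asarray(cutoffs, dtype=float):
        for cls in ("synergistic", "antagonistic"):
            pred_pos = [k for k in common
                        if classify_prediction(eps[k], cutoff) == cls]
            actual_pos = [k for k in common if exp_class[k] == cls]
            tp = len(set(pred_pos) & set(actual_pos))
            precision = tp / len(pred_pos) if pred_pos else float("nan")
            recall = tp / len(actual_pos) if actual_pos else float("nan")
            rows.append((cutoff, cls, precision, recall))
    return pd.DataFrame(rows,
                        columns=["cutoff", "class", "precision", "recall"])
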