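"""Genome-scale metabolic model container and gene classification.

The model is the standard constraint-based object: a stoichiometric matrix S
over metabolites x reactions, per-reaction flux bounds (mmol gDW^-1 h^-1), a
biomass pseudo-reaction as objective, and a GPR expression per
enzyme-catalysed reaction.  Models are read either from SBML Level 3 / FBC
(delegated to cobrapy) or from a compact JSON dialect used for fixtures.

Sign convention for exchange reactions: positive flux exports the metabolite
out of the system, negative flux imports it.  A medium therefore acts by
relaxing exchange lower bounds (see :mod:`fluxcost.fba`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import gpr as gpr_mod
from .gpr import GprExpression, parse_gpr, serialize_gpr

__all__ = ["Reaction", "MetabolicModel", "GeneCatalog", "classify_genes",
           "load_json_model", "save_json_model", "load_sbml_model"]


@dataclass
class Reaction:
    """A reaction: id, stoichiometry {metabolite: coefficient}, flux bounds.

    Negative coefficients are substrates, positive products.  ``is_exchange``
    marks reactions connecting the network to the environment (single
    metabolite, by convention consumed on export).
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    is_exchange: bool = False

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )


@dataclass
class MetabolicModel:
    """Stoichiometric network with bounds, objective and GPR map."""

    reactions: list[Reaction]
    objective_reaction: str
    gpr: dict[str, GprExpression] = field(default_factory=dict)
    name: str = "model"

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reactions]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate reaction ids: {dupes}")
        self._index = {r.id: i for i, r in enumerate(self.reactions)}
        if self.objective_reaction not in self._index:
            raise ValueError(
                f"objective reaction {self.objective_reaction!r} not in model"
            )
        unknown = set(self.gpr) - set(self._index)
        if unknown:
            raise ValueError(f"GPR entries for unknown reactions: {sorted(unknown)}")

    # -- look-ups ---------------------------------------------------------

    @property
    def metabolites(self) -> set[str]:
        mets: set[str] = set()
        for r in self.reactions:
            mets.update(r.stoichiometry)
        return mets

    @property
    def genes(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for expr in self.gpr.values():
            out |= expr.genes()
        return out

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self._index[rid]]

    def reaction_index(self, rid: str) -> int:
        return self._index[rid]

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def gene_association_map(self) -> dict[str, set[str]]:
        """gene -> reactions in whose GPR it appears (cached; association,
        not necessity)."""
        cached = getattr(self, "_assoc_map", None)
        if cached is None:
            cached = {g: set() for g in self.genes}
            for rid, expr in self.gpr.items():
                for g in expr.genes():
                    cached[g].add(rid)
            self._assoc_map = cached
        return cached

    def reactions_for_gene(self, gene: str) -> set[str]:
        """Reactions in whose GPR the gene appears anywhere (association,
        not necessity)."""
        return set(self.gene_association_map().get(gene, set()))


@dataclass
class GeneCatalog:
    """Per-gene structural classification relative to a blocked-reaction set.

    ``isoenzymes``: genes belonging to the isoenzyme set of at least one
    unblocked reaction.  ``multifunctional``: genes associated with >= 2
    unblocked reactions.  ``blocked_only``: genes all of whose associated
    reactions are blocked; these are purged from downstream analyses.
    """

    associated_reactions: dict[str, set[str]]
    isoenzymes: set[str]
    multifunctional: set[str]
    blocked_only: set[str]

    def is_isoenzyme(self, gene: str) -> bool:
        return gene in self.isoenzymes

    def is_multifunctional(self, gene: str) -> bool:
        return gene in self.multifunctional

    def is_blocked_only(self, gene: str) -> bool:
        return gene in self.blocked_only

    @property
    def analysis_genes(self) -> set[str]:
        """Genes retained after purging blocked-only genes."""
        return set(self.associated_reactions) - self.blocked_only


def classify_genes(model: MetabolicModel,
                   blocked: set[str] | frozenset[str] = frozenset()) -> GeneCatalog:
    """Classify every model gene as isoenzyme / multifunctional / blocked-only.

    Classification only counts unblocked reactions: a gene whose isoenzyme
    partnership exists solely on a blocked reaction is not an isoenzyme for
    analysis purposes, and a gene is multifunctional iff it is associated
    with at least two unblocked reactions.
    """
    associated: dict[str, set[str]] = {g: set() for g in model.genes}
    iso: set[str] = set()
    multi: set[str] = set()
    for rid, expr in model.gpr.items():
        for g in expr.genes():
            associated[g].add(rid)
        if rid not in blocked:
            iso.update(gpr_mod.isoenzyme_set(expr))
    blocked_only = {
        g for g, rids in associated.items() if rids and rids <= set(blocked)
    }
    for g, rids in associated.items():
        if len(rids - set(blocked)) >= 2:
            multi.add(g)
    return GeneCatalog(
        associated_reactions=associated,
        isoenzymes=iso,
        multifunctional=multi,
        blocked_only=blocked_only,
    )


# -- JSON dialect ----------------------------------------------------------
#
# {"name": ..., "objective": "GROWTH",
#  "reactions": [{"id": "R1", "stoichiometry": {"A": -1, "B": 1},
#                 "lower_bound": 0, "upper_bound": 1000,
#                 "exchange": false, "gpr": "g1 or g2"}, ...]}
#
# "inf"/-"inf" and the JSON literals Infinity/-Infinity are accepted as
# bounds; a missing gpr key marks a spontaneous or unmapped reaction.

_INF = float("inf")


def _parse_bound(value, default: float) -> float:
    if value is None:
        return default
    if isinstance(value, str):
        s = value.strip().lower()
        if s in ("inf", "+inf", "infinity", "unbounded"):
            return _INF
        if s in ("-inf", "-infinity"):
            return -_INF
        return float(value)
    return float(value)


def model_to_dict(model: MetabolicModel) -> dict:
    def bound(x: float):
        if x == _INF:
            return "inf"
        if x == -_INF:
            return "-inf"
        return x

    reactions = []
    for r in model.reactions:
        entry: dict = {
            "id": r.id,
            "stoichiometry": dict(sorted(r.stoichiometry.items())),
            "lower_bound": bound(r.lower_bound),
            "upper_bound": bound(r.upper_bound),
        }
        if r.is_exchange:
            entry["exchange"] = True
        if r.id in model.gpr:
            entry["gpr"] = serialize_gpr(model.gpr[r.id])
        reactions.append(entry)
    return {"name": model.name, "objective": model.objective_reaction,
            "reactions": reactions}


def model_from_dict(data: dict) -> MetabolicModel:
    reactions = []
    gpr: dict[str, GprExpression] = {}
    for entry in data["reactions"]:
        rid = entry["id"]
        reactions.append(Reaction(
            id=rid,
            stoichiometry={m: float(c) for m, c in entry["stoichiometry"].items()},
            lower_bound=_parse_bound(entry.get("lower_bound"), 0.0),
            upper_bound=_parse_bound(entry.get("upper_bound"), _INF),
            is_exchange=bool(entry.get("exchange", False)),
        ))
        text = entry.get("gpr")
        if text:
            gpr[rid] = parse_gpr(text, reaction=rid)
    return MetabolicModel(
        reactions=reactions,
        objective_reaction=data["objective"],
        gpr=gpr,
        name=data.get("name", "model"),
    )


def load_json_model(path) -> MetabolicModel:
    import json

    with open(path) as fh:
        return model_from_dict(json.load(fh))


def save_json_model(model: MetabolicModel, path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1, sort_keys=False)
        fh.write("\n")


def load_sbml_model(path) -> MetabolicModel:
    """Read an SBML Level 3 / FBC model via cobrapy and convert.

    Only the information this package uses is retained: stoichiometry,
    bounds, exchange flags, the (first) objective reaction and the FBC gene
    association strings.
    """
    import cobra.io

    cb = cobra.io.read_sbml_model(str(path))
    objective_ids = [r.id for r in cb.reactions
                     if cb.objective.expression.as_coefficients_dict().get(
                         r.forward_variable, 0) != 0]
    if not objective_ids:
        raise ValueError("SBML model has no objective reaction")
    exchange_ids = {r.id for r in cb.exchanges}
    reactions = []
    gpr: dict[str, GprExpression] = {}
    for r in cb.reactions:
        reactions.append(Reaction(
            id=r.id,
            stoichiometry={m.id: coef for m, coef in r.metabolites.items()},
            lower_bound=float(r.lower_bound),
            upper_bound=float(r.upper_bound),
            is_exchange=r.id in exchange_ids,
        ))
        text = r.gene_reaction_rule
        if text:
            gpr[r.id] = parse_gpr(text, reaction=r.id)
    return MetabolicModel(
        reactions=reactions,
        objective_reaction=objective_ids[0],
        gpr=gpr,
        name=cb.id or "sbml-model",
    )
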