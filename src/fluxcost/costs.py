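"""Gene dispensability metrics: gene-loss, function-loss and hybrid costs.

All costs are relative fitness losses against the wild-type growth w_wt in a
given medium:

* reaction-loss cost of r:      (w_wt - w_{delta r}) / w_wt, clipped to [0, 1]
* gene-loss cost (GLC) of g:    cost of simultaneously blocking every reaction
  for which g is a necessary prerequisite per the GPR (standard FBA knockout);
  isoenzyme deletions cost nothing because the partner provides full backup.
* function-loss cost (FLC) of g: the sum over every reaction g is associated
  with (appears anywhere in the GPR) of that reaction's individual
  reaction-loss cost — isoenzymes are assumed completely non-redundant, and a
  multifunctional gene accumulates the cost of each of its functions.  FLC can
  exceed 1.
* hybrid 1: FLC for multifunctional genes, GLC otherwise.
* hybrid 2: FLC for isoenzyme-associated genes, GLC otherwise.

For genes that are neither isoenzymes nor multifunctional the two metrics
coincide exactly.  Costs are clipped at zero per reaction: FBA cannot predict
fitness gains from deletions, and tiny negative values are solver noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .fba import FbaProblem, GROWTH_TOL, Medium, knockout_map
from .model import GeneCatalog, MetabolicModel, classify_genes

__all__ = ["CostCalculator", "compute_cost_table", "essentiality_call",
           "COST_COLUMNS"]

COST_COLUMNS = ("glc", "flc", "hybrid1", "hybrid2", "wt_growth")


class MediumInvalidError(ValueError):
    """The wild type cannot grow in this medium; costs are undefined."""


@dataclass
class CostCalculator:
    """Caches the LP and per-reaction costs for one (model, medium) pair.

    Reaction costs are memoised because FLC revisits the same single-reaction
    knockouts for every associated gene.  A reaction carrying (numerically)
    zero flux in the wild-type optimum is skipped: the wild-type solution
    remains feasible after blocking it, so its removal cost is exactly 0.
    """

    model: MetabolicModel
    medium: Medium
    blocked: frozenset[str] = frozenset()
    semantics: str = "redundant"
    flc_aggregation: str = "sum"  # "sum" | "max" (alternative for multifunctional genes)
    _problem: FbaProblem = field(init=False, repr=False)
    _reaction_cost: dict[str, float] = field(init=False, default_factory=dict)

    def __post_init__(self) -> None:
        self._problem = FbaProblem(self.model, self.medium)
        wt = self._problem.solve(self.blocked)
        if not wt.grows:
            raise MediumInvalidError(
                f"wild type does not grow in medium {self.medium.name!r}"
            )
        self.wt_growth = wt.objective_value
        self._wt_fluxes = wt.fluxes
        self._knockout_maps: dict[str, dict[str, frozenset[str]]] = {}
        self._loss_cache: dict[frozenset[str], float] = {}

    def _relative_loss(self, extra_blocked: frozenset[str]) -> float:
        # the cache is shared between reaction- and gene-level knockouts:
        # a single-function gene and its reaction hit the same entry
        if all(abs(self._wt_fluxes[r]) <= 1e-9 for r in extra_blocked):
            return 0.0
        if extra_blocked not in self._loss_cache:
            sol = self._problem.solve(self.blocked | extra_blocked)
            w = sol.objective_value if sol.status == "optimal" else 0.0
            cost = (self.wt_growth - w) / self.wt_growth
            self._loss_cache[extra_blocked] = min(1.0, max(0.0, cost))
        return self._loss_cache[extra_blocked]

    def reaction_loss_cost(self, rid: str) -> float:
        """Fitness loss of the single-reaction knockout, in [0, 1]."""
        if rid not in self._reaction_cost:
            if rid in self.blocked:
                self._reaction_cost[rid] = 0.0
            else:
                self._reaction_cost[rid] = self._relative_loss(frozenset({rid}))
        return self._reaction_cost[rid]

    def gene_loss_cost(self, gene: str, semantics: str | None = None) -> float:
        """Fitness loss of the gene knockout under the chosen GPR semantics."""
        semantics = semantics or self.semantics
        if semantics not in self._knockout_maps:
            self._knockout_maps[semantics] = knockout_map(self.model, semantics)
        try:
            targets = self._knockout_maps[semantics][gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in model") from None
        return self._relative_loss(targets - self.blocked)

    def function_loss_cost(self, gene: str) -> float:
        """Summed individual removal costs of every associated reaction."""
        rids = self.model.reactions_for_gene(gene) - self.blocked
        costs = [self.reaction_loss_cost(r) for r in sorted(rids)]
        if not costs:
            return 0.0
        return max(costs) if self.flc_aggregation == "max" else sum(costs)

    def hybrid_loss_costs(self, gene: str,
                          catalog: GeneCatalog) -> tuple[float, float]:
        glc = self.gene_loss_cost(gene)
        flc = self.function_loss_cost(gene)
        hybrid1 = flc if catalog.is_multifunctional(gene) else glc
        hybrid2 = flc if catalog.is_isoenzyme(gene) else glc
        return hybrid1, hybrid2


def compute_cost_table(model: MetabolicModel,
                       media: list[Medium],
                       blocked: frozenset[str] = frozenset(),
                       catalog: GeneCatalog | None = None,
                       genes: list[str] | None = None,
                       semantics: str = "redundant",
                       flc_aggregation: str = "sum") -> pd.DataFrame:
    """Long-format cost table: one row per (gene, medium).

    Columns: glc, flc, hybrid1, hybrid2, wt_growth.  Blocked-only genes are
    purged; media in which the wild type cannot grow raise
    :class:`MediumInvalidError` (media enumeration only emits
    growth-supporting media, so this is a defensive check).
    """
    if catalog is None:
        catalog = classify_genes(model, set(blocked))
    if genes is None:
        genes = sorted(catalog.analysis_genes)
    rows = []
    for medium in media:
        calc = CostCalculator(model, medium, blocked=blocked,
                              semantics=semantics,
                              flc_aggregation=flc_aggregation)
        for gene in genes:
            glc = calc.gene_loss_cost(gene)
            flc = calc.function_loss_cost(gene)
            hybrid1 = flc if catalog.is_multifunctional(gene) else glc
            hybrid2 = flc if catalog.is_isoenzyme(gene) else glc
            rows.append((gene, medium.name, glc, flc, hybrid1, hybrid2,
                         calc.wt_growth))
    return pd.DataFrame(
        rows, columns=["gene", "medium", *COST_COLUMNS]
    )


def essentiality_call(cost: float, threshold: float = 0.99) -> bool:
    """Binary essentiality from a normalized cost: essential iff
    cost >= threshold."""
    return cost >= threshold
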