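"""Deterministic synthetic fixtures: toy models, rate tables, interactions.

Everything here exists so the full analysis pipeline is testable without any
external model or dataset.  Three kinds of fixtures are generated:

* **Scenario models** — the three canonical gene-to-reaction configurations
  in their simplest form (enzyme complex, isoenzyme pair, multifunctional
  enzyme), plus a branch model with a partial-capacity bypass that produces
  fractional costs.  Each ships with analytically known wild-type growth and
  per-reaction removal costs.

* **Random toy models** — a linear biomass backbone fed by several
  alternative carbon and nitrogen sources (so minimal-media enumeration
  yields a carbon x nitrogen grid), with configurable fractions of isoenzyme
  (OR) and complex (AND) GPRs, multifunctional gene reuse, partial-capacity
  bypass reactions, and dead-end (blocked) reactions carrying their own
  genes.  Same seed, same spec => bit-identical model.

* **Synthetic evolutionary rates** — per-species d_N/d_S values generated as
  a log-linear decreasing function of each gene's functional burden (mean
  function-loss cost across media) plus Gaussian noise on the log scale, with
  a configurable fraction of missing orthologs.  The decreasing construction
  makes the cost/rate anticorrelation recoverable by the pipeline; the noise
  level controls how strongly.

* **Synthetic interaction tables** — experimental-style epistasis records
  derived from model predictions with additive noise, for exercising the
  comparison machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fba import Medium
from .gpr import parse_gpr
from .model import MetabolicModel, Reaction

__all__ = ["FixtureSpec", "ToyFixture", "SCENARIOS", "SCENARIO_EXPECTATIONS",
           "make_scenario_model", "scenario_medium", "make_random_toy_model",
           "random_fixture", "make_synthetic_rates",
           "make_synthetic_interactions", "SPECIES"]

SCENARIOS = ("complex", "isoenzyme", "multifunctional", "branch")

#: stand-in species names for synthetic rate tables (five related taxa)
SPECIES = ("sp1", "sp2", "sp3", "sp4", "sp5")

INF = float("inf")


def _rxn(rid: str, stoich: dict[str, float], lb: float = 0.0,
         ub: float = INF, exchange: bool = False) -> Reaction:
    return Reaction(rid, stoich, lb, ub, is_exchange=exchange)


def scenario_medium() -> Medium:
    """Default minimal medium for the scenario models: substrate A at 10."""
    return Medium("minimal", {"EX_A": 10.0})


def make_scenario_model(scenario: str) -> MetabolicModel:
    """One of the canonical GPR configurations on a hand-solvable backbone.

    All scenarios import substrate A (capped at 10 by :func:`scenario_medium`)
    and drain the final metabolite through the GROWTH pseudo-reaction:

    * ``complex``:         A -R1-> B, GPR ``g1 and g2``; wt growth 10.
    * ``isoenzyme``:       A -R1-> B, GPR ``g1 or g2``; wt growth 10.
    * ``multifunctional``: A -R1-> B -R2-> C, both reactions mapped to g1;
      wt growth 10.
    * ``branch``:          A -R1-> B, A -R2-> C, B -R3-> C with R3 capped at
      4; R2 (GPR ``g1 or g2``) is the full-capacity main branch, R1/R3 a
      partial bypass; wt growth 10, removing R2 leaves 4.
    """
    if scenario == "complex":
        reactions = [
            _rxn("EX_A", {"A": -1.0}, exchange=True),
            _rxn("R1", {"A": -1.0, "B": 1.0}),
            _rxn("GROWTH", {"B": -1.0}),
        ]
        gpr = {"R1": "g1 and g2"}
    elif scenario == "isoenzyme":
        reactions = [
            _rxn("EX_A", {"A": -1.0}, exchange=True),
            _rxn("R1", {"A": -1.0, "B": 1.0}),
            _rxn("GROWTH", {"B": -1.0}),
        ]
        gpr = {"R1": "g1 or g2"}
    elif scenario == "multifunctional":
        reactions = [
            _rxn("EX_A", {"A": -1.0}, exchange=True),
            _rxn("R1", {"A": -1.0, "B": 1.0}),
            _rxn("R2", {"B": -1.0, "C": 1.0}),
            _rxn("GROWTH", {"C": -1.0}),
        ]
        gpr = {"R1": "g1", "R2": "g1"}
    elif scenario == "branch":
        reactions = [
            _rxn("EX_A", {"A": -1.0}, exchange=True),
            _rxn("R1", {"A": -1.0, "B": 1.0}, ub=INF),
            _rxn("R2", {"A": -1.0, "C": 1.0}),
            _rxn("R3", {"B": -1.0, "C": 1.0}, ub=4.0),
            _rxn("GROWTH", {"C": -1.0}),
        ]
        gpr = {"R2": "g1 or g2", "R1": "g3", "R3": "g4"}
    else:
        raise ValueError(f"unknown scenario {scenario!r}; one of {SCENARIOS}")
    return MetabolicModel(
        reactions=reactions,
        objective_reaction="GROWTH",
        gpr={rid: parse_gpr(text, reaction=rid) for rid, text in gpr.items()},
        name=f"scenario-{scenario}",
    )


#: analytically derived wild-type growth and single-reaction removal costs
#: on :func:`scenario_medium` (uptake cap 10); asserted in the test suite.
SCENARIO_EXPECTATIONS: dict[str, dict] = {
    "complex": {"wt_growth": 10.0, "reaction_costs": {"R1": 1.0}},
    "isoenzyme": {"wt_growth": 10.0, "reaction_costs": {"R1": 1.0}},
    "multifunctional": {"wt_growth": 10.0,
                        "reaction_costs": {"R1": 1.0, "R2": 1.0}},
    # blocking the main branch R2 reroutes through R1+R3 capped at 4:
    # cost (10 - 4)/10; blocking R1 or R3 leaves the full-capacity R2.
    "branch": {"wt_growth": 10.0,
               "reaction_costs": {"R1": 0.0, "R2": 0.6, "R3": 0.0}},
}


# -- random toy models -----------------------------------------------------


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the random toy-model generator.

    The defaults describe the simulation conditions used throughout the test
    suite and the reproduction script: a 200-gene network whose minimal-media
    enumeration yields a 10 x 5 carbon/nitrogen grid (50 media), with 30% of
    enzymatic reaction slots carrying isoenzyme (OR) rules.
    """

    seed: int = 0
    n_genes: int = 200
    n_carbon_sources: int = 10
    n_nitrogen_sources: int = 5
    iso_fraction: float = 0.3
    complex_fraction: float = 0.15
    multifunctional_fraction: float = 0.15
    bypass_fraction: float = 0.4
    blocked_gene_fraction: float = 0.05
    uptake_cap: float = 10.0


@dataclass
class ToyFixture:
    """A generated model bundled with its reference medium and source ids."""

    spec: FixtureSpec
    model: MetabolicModel
    reference: Medium
    carbon_exchange: str
    nitrogen_exchange: str
    carbon_exchanges: list[str] = field(default_factory=list)
    nitrogen_exchanges: list[str] = field(default_factory=list)


def random_fixture(spec: FixtureSpec) -> ToyFixture:
    """Generate a random toy model plus its reference minimal medium.

    Topology: each carbon source C_i enters through its own uptake reaction
    (C_i -> yield_i * M0, yields in [0.6, 1]) into a linear backbone
    M0 -> M1 -> ... that, together with assimilated nitrogen, feeds the
    GROWTH drain.  Backbone steps may carry a partial-capacity, independently
    mapped bypass, so single-reaction removal costs take fractional values.
    GPR slots are drawn as isoenzyme pairs/triples (OR), complexes (AND) or
    single genes, with occasional reuse of an existing single gene
    (multifunctionality).  A final set of dead-end reactions carries genes
    associated only with blocked reactions.

    The wild type grows on every carbon x nitrogen pairing by construction;
    this is asserted and a failure raises (no silent regeneration).
    """
    rng = np.random.default_rng(spec.seed)
    gene_counter = 0
    used_single_genes: list[str] = []

    def new_gene() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"g{gene_counter:04d}"

    n_blocked_genes = int(round(spec.blocked_gene_fraction * spec.n_genes))
    budget = spec.n_genes - n_blocked_genes

    reactions: list[Reaction] = []
    gpr_text: dict[str, str] = {}

    def draw_gpr(rid: str) -> None:
        """Assign a GPR to reaction ``rid`` according to the slot mix."""
        u = rng.random()
        if u < spec.iso_fraction:
            arity = 3 if rng.random() < 0.2 else 2
            members = [new_gene() for _ in range(arity)]
            # occasionally one member is an existing singly-mapped gene, so
            # some isoenzymes are also multifunctional (their gene-loss cost
            # is then nonzero, as for real multifunctional isoenzymes)
            if (used_single_genes
                    and rng.random() < spec.multifunctional_fraction):
                members[-1] = used_single_genes[
                    int(rng.integers(len(used_single_genes)))]
            gpr_text[rid] = " or ".join(members)
        elif u < spec.iso_fraction + spec.complex_fraction:
            members = [new_gene(), new_gene()]
            gpr_text[rid] = " and ".join(members)
        else:
            if (used_single_genes
                    and rng.random() < spec.multifunctional_fraction):
                g = used_single_genes[int(rng.integers(len(used_single_genes)))]
            else:
                g = new_gene()
                used_single_genes.append(g)
            gpr_text[rid] = g

    # carbon entry points
    carbon_exchanges = []
    for i in range(1, spec.n_carbon_sources + 1):
        met = f"C{i}"
        ex = f"EX_C{i}"
        upt = f"UPT_C{i}"
        yield_i = 1.0 if i == 1 else float(rng.uniform(0.6, 1.0))
        reactions.append(_rxn(ex, {met: -1.0}, exchange=True))
        reactions.append(_rxn(upt, {met: -1.0, "M0": yield_i}))
        draw_gpr(upt)
        carbon_exchanges.append(ex)

    # nitrogen entry points
    nitrogen_exchanges = []
    for i in range(1, spec.n_nitrogen_sources + 1):
        met = f"N{i}"
        ex = f"EX_N{i}"
        upt = f"UPT_N{i}"
        reactions.append(_rxn(ex, {met: -1.0}, exchange=True))
        reactions.append(_rxn(upt, {met: -1.0, "NH": 1.0}))
        draw_gpr(upt)
        nitrogen_exchanges.append(ex)

    # backbone: extend until the gene budget is spent (at least 3 steps)
    step = 0
    while gene_counter < budget or step < 3:
        step += 1
        prev, cur = f"M{step - 1}", f"M{step}"
        rid = f"BB{step}"
        reactions.append(_rxn(rid, {prev: -1.0, cur: 1.0}))
        draw_gpr(rid)
        if rng.random() < spec.bypass_fraction:
            cap = float(rng.uniform(1.0, 9.0))
            bid = f"BYP{step}"
            reactions.append(_rxn(bid, {prev: -1.0, cur: 1.0}, ub=cap))
            if rng.random() < 0.5:
                draw_gpr(bid)
        if gene_counter >= budget and step >= 3:
            break

    reactions.append(_rxn("GROWTH", {f"M{step}": -1.0, "NH": -1.0}))

    # dead-end reactions: no consumer for X_k, so they can never carry flux
    for k in range(1, n_blocked_genes + 1):
        src = f"M{int(rng.integers(0, step))}"
        rid = f"DEAD{k}"
        reactions.append(_rxn(rid, {src: -1.0, f"X{k}": 1.0}))
        gpr_text[rid] = new_gene()

    model = MetabolicModel(
        reactions=reactions,
        objective_reaction="GROWTH",
        gpr={rid: parse_gpr(t, reaction=rid) for rid, t in gpr_text.items()},
        name=f"toy-seed{spec.seed}",
    )
    reference = Medium("EX_C1|EX_N1", {"EX_C1": spec.uptake_cap,
                                       "EX_N1": spec.uptake_cap})

    from .fba import FbaProblem  # deferred: avoids import cycle at module load

    if not FbaProblem(model, reference).solve().grows:
        raise RuntimeError(
            f"generated fixture (seed {spec.seed}) does not grow on its "
            "reference medium; the spec parameters are degenerate"
        )
    return ToyFixture(
        spec=spec, model=model, reference=reference,
        carbon_exchange="EX_C1", nitrogen_exchange="EX_N1",
        carbon_exchanges=carbon_exchanges,
        nitrogen_exchanges=nitrogen_exchanges,
    )


def make_random_toy_model(spec: FixtureSpec) -> MetabolicModel:
    """The model component of :func:`random_fixture`."""
    return random_fixture(spec).model


# -- synthetic rate tables -------------------------------------------------


def make_synthetic_rates(burden: pd.Series | dict[str, float],
                         noise_sd: float = 0.5,
                         seed: int = 0,
                         decay: float = 3.0,
                         missing_fraction: float = 0.1,
                         species: tuple[str, ...] = SPECIES
                         ) -> dict[str, dict[str, float]]:
    """Per-species d_N/d_S values decreasing in functional burden.

    ``burden`` is typically each gene's mean function-loss cost across media.
    For gene g and species s:  k_{g,s} = exp(-decay * burden_g + eta) with
    eta ~ Normal(0, noise_sd) drawn independently per (gene, species).
    High-burden genes therefore evolve slowly (low d_N/d_S), making the
    anticorrelation with loss costs recoverable; ``noise_sd`` sets how
    cleanly.  Each (gene, species) entry is dropped with probability
    ``missing_fraction`` (missing ortholog); genes losing all species are
    excluded downstream, exercising that code path.
    """
    rng = np.random.default_rng(seed)
    burden = pd.Series(dict(burden), dtype=float).sort_index()
    out: dict[str, dict[str, float]] = {}
    for gene, b in burden.items():
        entry = {}
        for sp in species:
            if rng.random() < missing_fraction:
                continue
            entry[sp] = float(np.exp(-decay * b + rng.normal(0.0, noise_sd)))
        if entry:
            out[gene] = entry
        else:
            out[gene] = {}
    return out


def make_synthetic_interactions(records,
                                seed: int = 0,
                                epsilon_noise_sd: float = 0.0,
                                wt_fitness: float = 1.0,
                                wt_sd: float = 0.05,
                                fast_grower_fraction: float = 0.0
                                ) -> pd.DataFrame:
    """Experimental-style interaction table derived from predicted records.

    Starts from a list of :class:`~fluxcost.epistasis.EpistasisRecord` (the
    "ground truth"), adds Gaussian noise to epsilon, sets small p-values for
    pairs with |epsilon| above the experimental cutoff and large ones
    otherwise, and copies the single-mutant fitnesses.  A configurable
    fraction of pairs is given an inflated single-mutant fitness (wild type
    + 3 sd) to exercise the deletion-fitness filter.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for r in records:
        eps = r.epsilon + (rng.normal(0.0, epsilon_noise_sd)
                           if epsilon_noise_sd > 0 else 0.0)
        interacting = abs(eps) > 0.08
        p = float(rng.uniform(0.0, 0.01)) if interacting \
            else float(rng.uniform(0.2, 1.0))
        f_i, f_j = r.w_i, r.w_j
        if fast_grower_fraction > 0 and rng.random() < fast_grower_fraction:
            f_i = wt_fitness + 3.0 * wt_sd
        rows.append((r.gene_i, r.gene_j, eps, p, f_i, f_j))
    return pd.DataFrame(rows, columns=["gene_i", "gene_j", "epsilon",
                                       "p_value", "fitness_i", "fitness_j"])
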