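"""FBA core: LP correctness against enumeration oracles, blocked reactions,
knockout semantics, backend agreement and a cobrapy cross-check."""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from fluxcost.fba import (FbaProblem, Medium, find_blocked_reactions,
                          knockout_map, knockout_reactions,
                          knockout_reactions_for_gene, solve_fba)
from fluxcost.fixtures import make_scenario_model, scenario_medium
from fluxcost.gpr import parse_gpr
from fluxcost.model import MetabolicModel, Reaction

BIG = 1000.0


def chain_model() -> MetabolicModel:
    return MetabolicModel(
        reactions=[
            Reaction("EX_A", {"A": -1.0}, 0.0, np.inf, is_exchange=True),
            Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, np.inf),
            Reaction("GROWTH", {"B": -1.0}, 0.0, np.inf),
        ],
        objective_reaction="GROWTH",
    )


def brute_force_optimum(model: MetabolicModel, medium: Medium,
                        blocked=frozenset(), big: float = BIG):
    """Vertex-enumeration oracle for tiny LPs.

    Replaces infinite bounds by +/-big (making the polytope a box-bounded
    polytope whose optimum sits at a basic solution), then enumerates every
    assignment of each variable to {lower bound, upper bound, free}, solves
    the mass-balance system for the free block when it is uniquely
    determined, and keeps the best feasible candidate.
    """
    n = len(model.reactions)
    mets = sorted(model.metabolites)
    S = np.zeros((len(mets), n))
    midx = {m: i for i, m in enumerate(mets)}
    for j, r in enumerate(model.reactions):
        for m, coef in r.stoichiometry.items():
            S[midx[m], j] = coef
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    for r in model.reactions:
        if r.is_exchange:
            j = model.reaction_index(r.id)
            cap = medium.uptake_limits.get(r.id)
            lb[j] = -cap if cap is not None else max(lb[j], 0.0)
    for rid in blocked:
        j = model.reaction_index(rid)
        lb[j] = ub[j] = 0.0
    lb = np.clip(lb, -big, big)
    ub = np.clip(ub, -big, big)
    obj = model.reaction_index(model.objective_reaction)
    best = None
    for assign in product((0, 1, 2), repeat=n):
        v = np.zeros(n)
        free = [j for j, a in enumerate(assign) if a == 2]
        for j, a in enumerate(assign):
            if a == 0:
                v[j] = lb[j]
            elif a == 1:
                v[j] = ub[j]
        rhs = -S[:, [j for j in range(n) if j not in free]] @ \
            v[[j for j in range(n) if j not in free]]
        if free:
            A = S[:, free]
            if np.linalg.matrix_rank(A) < len(free):
                continue  # not uniquely determined: not a basic solution
            sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            v[free] = sol
        if np.linalg.norm(S @ v) > 1e-7:
            continue
        if np.any(v < lb - 1e-7) or np.any(v > ub + 1e-7):
            continue
        if best is None or v[obj] > best:
            best = v[obj]
    return best  # None => infeasible


def random_tiny_model(rng: np.random.Generator) -> MetabolicModel:
    """Random stoichiometric network with <= 6 reactions; v = 0 is always
    feasible so the LP is never infeasible, only possibly zero.  Bounds are
    finite: random cyclic topologies with open bounds can make the
    objective unbounded, which is not the regime under test here."""
    n_mets = int(rng.integers(2, 5))
    n_rxns = int(rng.integers(3, 7))
    reactions = []
    for j in range(n_rxns):
        stoich = {}
        for i in range(n_mets):
            if rng.random() < 0.5:
                stoich[f"m{i}"] = float(rng.choice([-2, -1, 1, 2]))
        if not stoich:
            stoich[f"m{int(rng.integers(n_mets))}"] = 1.0
        lb = float(rng.choice([0.0, -10.0, -50.0]))
        ub = float(rng.choice([5.0, 10.0, 50.0]))
        reactions.append(Reaction(f"r{j}", stoich, lb, ub))
    return MetabolicModel(reactions=reactions, objective_reaction="r0")


# -- objective correctness -------------------------------------------------

def test_linear_chain_objective():
    m = chain_model()
    medium = Medium("min", {"EX_A": 10.0})
    assert solve_fba(m, medium).objective_value == pytest.approx(10.0)
    assert solve_fba(m, medium, {"R1"}).objective_value == pytest.approx(0.0)


def test_branch_bottleneck():
    m = make_scenario_model("branch")
    medium = scenario_medium()
    assert solve_fba(m, medium).objective_value == pytest.approx(10.0)
    # main branch R2 knocked out: reroute via R1 + R3 capped at 4
    assert solve_fba(m, medium, {"R2"}).objective_value == pytest.approx(4.0)


def test_mass_balance_and_bounds_of_solution(toy_bundle):
    model = toy_bundle["model"]
    medium = toy_bundle["media"][0]
    problem = FbaProblem(model, medium)
    sol = problem.solve()
    v = np.array([sol.fluxes[r.id] for r in model.reactions])
    assert np.abs(problem.S @ v).max() < 1e-6
    assert np.all(v >= problem.lb - 1e-6) and np.all(v <= problem.ub + 1e-6)


@pytest.mark.parametrize("seed", range(25))
def test_lp_matches_vertex_enumeration(seed):
    rng = np.random.default_rng(seed)
    model = random_tiny_model(rng)
    medium = Medium("none", {})
    expected = brute_force_optimum(model, medium)
    sol = solve_fba(model, medium)
    assert expected is not None and sol.status == "optimal"
    assert sol.objective_value == pytest.approx(max(0.0, expected), abs=1e-6)


def test_backends_agree(toy_bundle):
    model = toy_bundle["model"]
    for medium in toy_bundle["media"][:3]:
        a = FbaProblem(model, medium, backend="glpk").solve()
        b = FbaProblem(model, medium, backend="highs").solve()
        assert a.objective_value == pytest.approx(b.objective_value, abs=1e-6)


def test_cobra_cross_check():
    """Independent oracle: the same branch network built in cobrapy."""
    cobra = pytest.importorskip("cobra")
    m = make_scenario_model("branch")
    medium = scenario_medium()
    cb = cobra.Model("branch")
    mets = {x: cobra.Metabolite(x, compartment="c") for x in ("A", "B", "C")}
    for r in m.reactions:
        lb = -medium.uptake_limits.get(r.id, 0.0) if r.is_exchange \
            else r.lower_bound
        rx = cobra.Reaction(r.id, lower_bound=lb,
                            upper_bound=min(r.upper_bound, 1000.0))
        rx.add_metabolites({mets[x]: c for x, c in r.stoichiometry.items()})
        cb.add_reactions([rx])
    cb.objective = "GROWTH"
    assert cb.optimize().objective_value == pytest.approx(
        solve_fba(m, medium).objective_value, abs=1e-6)
    with cb:
        cb.reactions.R2.knock_out()
        ko = cb.optimize().objective_value
    assert ko == pytest.approx(
        solve_fba(m, medium, {"R2"}).objective_value, abs=1e-6)


# -- monotonicity and errors ----------------------------------------------

@pytest.mark.parametrize("seed", range(5))
def test_blocking_more_never_helps(seed):
    rng = np.random.default_rng(100 + seed)
    model = random_tiny_model(rng)
    medium = Medium("none", {})
    rids = [r.id for r in model.reactions if r.id != "r0"]
    sub = set(rng.choice(rids, size=1))
    sup = sub | set(rng.choice(rids, size=1))
    assert solve_fba(model, medium, sup).objective_value <= \
        solve_fba(model, medium, sub).objective_value + 1e-9


def test_unknown_blocked_reaction_raises():
    with pytest.raises(ValueError, match="unknown"):
        solve_fba(chain_model(), Medium("m", {"EX_A": 10.0}), {"nope"})


def test_medium_validation():
    with pytest.raises(ValueError, match="negative"):
        Medium("bad", {"EX_A": -1.0})
    with pytest.raises(ValueError, match="unknown exchange"):
        solve_fba(chain_model(), Medium("bad", {"R1": 10.0}))


# -- blocked reactions -----------------------------------------------------

def test_find_blocked_reactions():
    m = MetabolicModel(
        reactions=[
            Reaction("EX_A", {"A": -1.0}, 0.0, np.inf, is_exchange=True),
            Reaction("EX_B", {"B": -1.0}, 0.0, np.inf, is_exchange=True),
            Reaction("R1", {"A": -1.0, "C": 1.0}, 0.0, np.inf),
            Reaction("R2", {"B": -1.0, "C": 1.0}, 0.0, np.inf),
            Reaction("DEAD", {"A": -1.0, "X": 1.0}, 0.0, np.inf),
            Reaction("GROWTH", {"C": -1.0}, 0.0, np.inf),
        ],
        objective_reaction="GROWTH",
    )
    medium1 = Medium("m1", {"EX_A": 10.0})
    medium2 = Medium("m2", {"EX_B": 10.0})
    # dead-end product: blocked everywhere; R2 only usable in medium 2
    assert find_blocked_reactions(m, [medium1]) == {"DEAD", "EX_B", "R2"}
    assert find_blocked_reactions(m, [medium1, medium2]) == {"DEAD"}
    with pytest.raises(ValueError, match="at least one medium"):
        find_blocked_reactions(m, [])


# -- knockout translation --------------------------------------------------

def gpr_model(rules: dict[str, str]) -> MetabolicModel:
    reactions = [Reaction("EX_A", {"A": -1.0}, 0.0, np.inf, is_exchange=True)]
    prev = "A"
    for i, rid in enumerate(rules, start=1):
        reactions.append(Reaction(rid, {prev: -1.0, f"B{i}": 1.0}, 0.0, np.inf))
        prev = f"B{i}"
    reactions.append(Reaction("GROWTH", {prev: -1.0}, 0.0, np.inf))
    return MetabolicModel(
        reactions=reactions, objective_reaction="GROWTH",
        gpr={rid: parse_gpr(t) for rid, t in rules.items()})


def test_knockout_semantics():
    m = gpr_model({"R1": "g1 or g2", "R2": "g1 and g3"})
    assert knockout_reactions_for_gene(m, "g1", "redundant") == {"R2"}
    assert knockout_reactions_for_gene(m, "g1", "nonredundant") == {"R1", "R2"}
    assert knockout_reactions_for_gene(m, "g3", "redundant") == {"R2"}
    with pytest.raises(KeyError):
        knockout_reactions_for_gene(m, "nope")
    with pytest.raises(ValueError, match="semantics"):
        knockout_reactions(m, {"g1"}, "bogus")


def test_joint_deletion_evaluates_gpr_jointly():
    m = gpr_model({"R1": "g1 or g2"})
    # neither gene alone disables R1, deleting both does
    assert knockout_reactions(m, {"g1"}) == frozenset()
    assert knockout_reactions(m, {"g1", "g2"}) == {"R1"}


def test_knockout_map_matches_per_gene(toy_bundle):
    model = toy_bundle["model"]
    for semantics in ("redundant", "nonredundant"):
        km = knockout_map(model, semantics)
        for gene in sorted(model.genes)[:20]:
            assert km[gene] == knockout_reactions_for_gene(model, gene,
                                                           semantics)


def test_no_necessary_reactions_means_wild_type_growth():
    m = gpr_model({"R1": "g1 or g2"})
    medium = Medium("min", {"EX_A": 10.0})
    wt = solve_fba(m, medium).objective_value
    ko = solve_fba(m, medium,
                   knockout_reactions_for_gene(m, "g1")).objective_value
    assert ko == pytest.approx(wt)
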