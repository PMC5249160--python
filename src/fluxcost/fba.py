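"""Flux balance analysis: growth optimisation, variability, gene knockouts.

FBA finds a steady-state flux vector v maximising the biomass pseudo-reaction
flux w = v_biomass subject to mass balance S v = 0 and per-reaction bounds
alpha_i <= v_i <= beta_i.  Three constraint classes are applied on top of the
model's intrinsic bounds: irreversibility (alpha_i >= 0 where the model says
so), environmental nutrient availability (a :class:`Medium` caps import flux
through exchange reactions), and knockouts (alpha_i = beta_i = 0 for reactions
disabled by a gene deletion through the GPR).

The LP is solved with scipy's HiGHS backend.  Only the objective value is
contractual; at degenerate optima the returned flux vector is one of many.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .gpr import evaluate_gpr, or_to_and
from .model import MetabolicModel

__all__ = [
    "Medium", "FbaSolution", "FbaProblem", "solve_fba",
    "find_blocked_reactions", "knockout_reactions", "knockout_reactions_for_gene",
    "FLUX_ZERO_TOL", "GROWTH_TOL", "UNBOUNDED",
]

#: fluxes with magnitude below this are treated as zero
FLUX_ZERO_TOL = 1e-9
#: growth below this counts as "no growth"
GROWTH_TOL = 1e-6
#: sentinel for an uncapped import
UNBOUNDED = float("inf")


@dataclass(frozen=True)
class Medium:
    """An environment: per-exchange maximum import fluxes.

    ``uptake_limits`` maps exchange-reaction ids to the maximum import rate
    (mmol gDW^-1 h^-1); :data:`UNBOUNDED` leaves the import uncapped.
    Exchange reactions absent from the map are restricted to export only
    (v_i >= 0).  Non-exchange bounds are never touched.
    """

    name: str
    uptake_limits: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.uptake_limits.items() if v < 0}
        if bad:
            raise ValueError(f"medium {self.name}: negative uptake limits {bad}")

    def validate(self, model: MetabolicModel) -> None:
        known = {r.id for r in model.exchanges()}
        unknown = sorted(set(self.uptake_limits) - known)
        if unknown:
            raise ValueError(
                f"medium {self.name}: unknown exchange reactions {unknown}"
            )

    def replace_source(self, old: str, new: str, name: str | None = None) -> "Medium":
        """A copy with exchange ``old`` removed and ``new`` capped at the
        same uptake limit (used when enumerating alternative nutrients)."""
        limits = dict(self.uptake_limits)
        cap = limits.pop(old)
        limits[new] = cap
        return Medium(name or f"{self.name}[{old}->{new}]", limits)


@dataclass
class FbaSolution:
    """Outcome of one LP solve: status, objective value, flux vector."""

    status: str  # "optimal" | "infeasible"
    objective_value: float
    fluxes: dict[str, float]

    @property
    def grows(self) -> bool:
        return self.status == "optimal" and self.objective_value > GROWTH_TOL


try:  # GLPK (via cobrapy's swiglpk binding): warm-started re-solves
    import swiglpk as _glp
except ImportError:  # pragma: no cover - environment without GLPK
    _glp = None


class FbaProblem:
    """A model + medium bound to a reusable LP.

    Precomputes the sparse stoichiometric matrix and medium-adjusted bounds so
    repeated knockout solves (thousands per cost table) only swap bounds.  The
    default backend is GLPK through swiglpk, which keeps the factorised basis
    between solves; scipy's HiGHS is the fallback and serves as an internal
    cross-check.
    """

    def __init__(self, model: MetabolicModel, medium: Medium,
                 backend: str | None = None):
        medium.validate(model)
        self.model = model
        self.medium = medium
        if backend is None:
            backend = "glpk" if _glp is not None else "highs"
        if backend not in ("glpk", "highs"):
            raise ValueError(f"unknown LP backend {backend!r}")
        self.backend = backend
        n = len(model.reactions)
        mets = sorted(model.metabolites)
        met_index = {m: i for i, m in enumerate(mets)}
        rows, cols, vals = [], [], []
        for j, r in enumerate(model.reactions):
            for m, coef in r.stoichiometry.items():
                rows.append(met_index[m])
                cols.append(j)
                vals.append(coef)
        self.S = sparse.csc_matrix(
            (vals, (rows, cols)), shape=(len(mets), n)
        )
        lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
        for r in model.reactions:
            if r.is_exchange:
                j = model.reaction_index(r.id)
                cap = medium.uptake_limits.get(r.id)
                if cap is None:
                    lb[j] = max(lb[j], 0.0)  # export only
                else:
                    lb[j] = -cap
        self.lb, self.ub = lb, ub
        self.c = np.zeros(n)
        self.c[model.reaction_index(model.objective_reaction)] = 1.0
        self._lp = None
        if self.backend == "glpk":
            self._build_glpk(rows, cols, vals, len(mets), n)

    # -- GLPK backend ------------------------------------------------------

    def _build_glpk(self, rows, cols, vals, n_mets, n_rxns) -> None:
        glp = _glp
        lp = glp.glp_create_prob()
        glp.glp_add_rows(lp, n_mets)
        for i in range(n_mets):
            glp.glp_set_row_bnds(lp, i + 1, glp.GLP_FX, 0.0, 0.0)
        glp.glp_add_cols(lp, n_rxns)
        for j in range(n_rxns):
            self._glpk_set_col(lp, j, self.lb[j], self.ub[j])
        nnz = len(vals)
        ia = glp.intArray(nnz + 1)
        ja = glp.intArray(nnz + 1)
        ar = glp.doubleArray(nnz + 1)
        for k, (i, j, v) in enumerate(zip(rows, cols, vals), start=1):
            ia[k] = i + 1
            ja[k] = j + 1
            ar[k] = v
        glp.glp_load_matrix(lp, nnz, ia, ja, ar)
        glp.glp_set_obj_dir(lp, glp.GLP_MAX)
        self._smcp = glp.glp_smcp()
        glp.glp_init_smcp(self._smcp)
        self._smcp.msg_lev = glp.GLP_MSG_OFF
        self._lp = lp

    @staticmethod
    def _glpk_set_col(lp, j: int, lb: float, ub: float) -> None:
        glp = _glp
        lb_inf, ub_inf = lb == -np.inf, ub == np.inf
        if lb_inf and ub_inf:
            glp.glp_set_col_bnds(lp, j + 1, glp.GLP_FR, 0.0, 0.0)
        elif lb_inf:
            glp.glp_set_col_bnds(lp, j + 1, glp.GLP_UP, 0.0, ub)
        elif ub_inf:
            glp.glp_set_col_bnds(lp, j + 1, glp.GLP_LO, lb, 0.0)
        elif lb == ub:
            glp.glp_set_col_bnds(lp, j + 1, glp.GLP_FX, lb, ub)
        else:
            glp.glp_set_col_bnds(lp, j + 1, glp.GLP_DB, lb, ub)

    def __del__(self):  # free the GLPK problem object
        if getattr(self, "_lp", None) is not None and _glp is not None:
            _glp.glp_delete_prob(self._lp)
            self._lp = None

    def _glpk_optimize(self, c: np.ndarray,
                       blocked: frozenset[str]) -> tuple[str, float, np.ndarray]:
        glp = _glp
        lp = self._lp
        n = len(self.model.reactions)
        for j in range(n):
            glp.glp_set_obj_coef(lp, j + 1, float(c[j]))
        idx = [self.model.reaction_index(rid) for rid in blocked]
        for j in idx:
            glp.glp_set_col_bnds(lp, j + 1, glp.GLP_FX, 0.0, 0.0)
        try:
            ret = glp.glp_simplex(lp, self._smcp)
            if ret != 0:  # basis gone stale: rebuild and retry cold
                glp.glp_adv_basis(lp, 0)
                ret = glp.glp_simplex(lp, self._smcp)
            status = glp.glp_get_status(lp)
            if status == glp.GLP_OPT:
                obj = glp.glp_get_obj_val(lp)
                x = np.fromiter(
                    (glp.glp_get_col_prim(lp, j + 1) for j in range(n)),
                    dtype=float, count=n)
                return "optimal", obj, x
            if status == glp.GLP_UNBND:
                return "unbounded", np.inf, np.zeros(n)
            return "infeasible", 0.0, np.zeros(n)
        finally:
            for j in idx:
                self._glpk_set_col(lp, j, self.lb[j], self.ub[j])

    # -- HiGHS backend -----------------------------------------------------

    def _highs_optimize(self, c: np.ndarray,
                        blocked: frozenset[str]) -> tuple[str, float, np.ndarray]:
        lb, ub = self.lb.copy(), self.ub.copy()
        for rid in blocked:
            j = self.model.reaction_index(rid)
            lb[j] = ub[j] = 0.0
        res = linprog(-c, A_eq=self.S, b_eq=np.zeros(self.S.shape[0]),
                      bounds=np.column_stack([lb, ub]), method="highs")
        if res.status == 3:
            return "unbounded", np.inf, np.zeros(len(c))
        if not res.success:
            return "infeasible", 0.0, np.zeros(len(c))
        return "optimal", float(-res.fun), np.asarray(res.x, dtype=float)

    def _optimize(self, c: np.ndarray, blocked: frozenset[str]):
        if self.backend == "glpk":
            return self._glpk_optimize(c, blocked)
        return self._highs_optimize(c, blocked)

    # -- public interface --------------------------------------------------

    def solve(self, blocked: set[str] | frozenset[str] = frozenset()
              ) -> FbaSolution:
        """Maximise biomass flux with the given reactions forced to zero."""
        status, obj, x = self._optimize(self.c, frozenset(blocked))
        if status == "unbounded":
            raise ValueError(
                f"growth objective unbounded in medium {self.medium.name!r}; "
                "cap the uptake limits"
            )
        if status != "optimal":
            # infeasible (or numerically hopeless) mutants cannot grow
            return FbaSolution("infeasible", 0.0,
                               {r.id: 0.0 for r in self.model.reactions})
        fluxes = {r.id: float(v) for r, v in zip(self.model.reactions, x)}
        return FbaSolution("optimal", max(0.0, float(obj)), fluxes)

    def flux_range(self, rid: str,
                   blocked: set[str] | frozenset[str] = frozenset()
                   ) -> tuple[float, float]:
        """Minimum and maximum achievable flux through one reaction (no
        growth requirement — pure feasibility range).  An unbounded
        direction reports +/-inf."""
        n = len(self.model.reactions)
        j = self.model.reaction_index(rid)
        blocked = frozenset(blocked)
        c = np.zeros(n)
        c[j] = -1.0
        lo_status, lo_obj, lo_x = self._optimize(c, blocked)
        c[j] = 1.0
        hi_status, hi_obj, hi_x = self._optimize(c, blocked)
        vmin = (-np.inf if lo_status == "unbounded"
                else float(lo_x[j]) if lo_status == "optimal" else 0.0)
        vmax = (np.inf if hi_status == "unbounded"
                else float(hi_x[j]) if hi_status == "optimal" else 0.0)
        return vmin, vmax


def solve_fba(model: MetabolicModel, medium: Medium,
              blocked_reactions: set[str] | frozenset[str] = frozenset()
              ) -> FbaSolution:
    """One-shot FBA solve; see :class:`FbaProblem` for the batched interface."""
    unknown = set(blocked_reactions) - {r.id for r in model.reactions}
    if unknown:
        raise ValueError(f"unknown reactions to block: {sorted(unknown)}")
    return FbaProblem(model, medium).solve(frozenset(blocked_reactions))


def find_blocked_reactions(model: MetabolicModel,
                           media: list[Medium],
                           tol: float = GROWTH_TOL) -> set[str]:
    """Reactions incapable of carrying flux under every tested medium.

    A reaction is blocked iff in every medium its feasible flux range is
    {0} (both the maximum and minimum achievable flux are zero within
    ``tol``) — a flux-variability-style test.  Media should include the most
    permissive environments of interest; a reaction usable in any of them is
    not blocked.
    """
    if not media:
        raise ValueError("find_blocked_reactions requires at least one medium")
    candidates = {r.id for r in model.reactions}
    for medium in media:
        problem = FbaProblem(model, medium)
        # any flux-carrying reaction in the growth optimum is unblocked
        wt = problem.solve()
        if wt.status == "optimal":
            candidates -= {rid for rid, v in wt.fluxes.items() if abs(v) > tol}
        for rid in sorted(candidates):
            vmin, vmax = problem.flux_range(rid)
            if abs(vmin) > tol or abs(vmax) > tol:
                candidates.discard(rid)
    return candidates


def knockout_map(model: MetabolicModel,
                 semantics: str = "redundant") -> dict[str, frozenset[str]]:
    """gene -> reactions disabled by deleting that gene alone.

    Medium-independent, so computed once per (model, semantics) and reused
    across the thousands of knockout solves in a cost table.
    """
    if semantics not in ("redundant", "nonredundant"):
        raise ValueError(f"unknown GPR semantics {semantics!r}")
    out: dict[str, set[str]] = {g: set() for g in model.genes}
    for rid, expr in model.gpr.items():
        if semantics == "nonredundant":
            expr = or_to_and(expr)
        genes = expr.genes()
        for g in genes:
            if not evaluate_gpr(expr, genes - {g}):
                out[g].add(rid)
    return {g: frozenset(rids) for g, rids in out.items()}


def knockout_reactions(model: MetabolicModel,
                       deleted: set[str] | frozenset[str],
                       semantics: str = "redundant") -> frozenset[str]:
    """Reactions disabled when the genes in ``deleted`` are removed together.

    Each reaction's GPR is evaluated with the deleted genes absent and all
    other genes present; reactions whose GPR evaluates false are disabled.
    Under ``nonredundant`` semantics every OR in the GPR is first rewritten
    to AND, so deleting any single member of an isoenzyme set disables the
    reaction.  Joint deletions are evaluated directly on the GPR (not as the
    union of single-gene effects), which captures pairs that jointly falsify
    a rule neither falsifies alone — e.g. an isoenzyme pair.
    """
    if semantics not in ("redundant", "nonredundant"):
        raise ValueError(f"unknown GPR semantics {semantics!r}")
    assoc = model.gene_association_map()
    candidates: set[str] = set()
    for g in deleted:
        candidates |= assoc.get(g, set())
    out = set()
    for rid in candidates:
        expr = model.gpr[rid]
        if semantics == "nonredundant":
            expr = or_to_and(expr)
        if not evaluate_gpr(expr, expr.genes() - set(deleted)):
            out.add(rid)
    return frozenset(out)


def knockout_reactions_for_gene(model: MetabolicModel, gene: str,
                                semantics: str = "redundant") -> frozenset[str]:
    """Reactions disabled by deleting one gene under the chosen semantics."""
    if gene not in model.genes:
        raise KeyError(f"gene {gene!r} not in model")
    return knockout_reactions(model, {gene}, semantics)
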