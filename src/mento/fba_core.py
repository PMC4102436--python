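"""Flux balance analysis core: apply a medium, maximize biomass, knock out genes.

Flux balance analysis (FBA) treats the metabolic network at steady state:
S.V = 0 with flux bounds on every reaction, maximizing the biomass reaction
flux.  A medium is just a set of exchange metabolites whose uptake is
permitted: allowed exchanges get lower bound -|uptake_magnitude|, all other
exchanges get lower bound 0.  Secretion (positive exchange flux) stays open
for every exchange regardless of the medium — only uptake is restricted.

LPs are solved with HiGHS via scipy.optimize.linprog.  Growth tests compare
the biomass optimum against a cutoff with a small slack (1e-6) to absorb LP
round-off at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .errors import PreconditionError, SolverError, UnknownIdentifierError
from .model_io import MetabolicModel

__all__ = [
    "Medium",
    "FluxSolution",
    "DEFAULT_UPTAKE_MAGNITUDE",
    "DEFAULT_CUTOFF",
    "GROWTH_SLACK",
    "all_open_medium",
    "maximize_biomass",
    "grows",
    "fraction_of_max_cutoff",
    "delete_gene",
    "delete_genes",
]

#: conventional unconstrained uptake bound; doubles as the big-M coupling
#: constant in the minimal-environment MILP, so the two must stay equal.
DEFAULT_UPTAKE_MAGNITUDE = 1000.0

#: nominal "nonzero biomass" threshold, in absolute flux units
DEFAULT_CUTOFF = 0.1

#: slack subtracted from the cutoff in growth comparisons (LP round-off)
GROWTH_SLACK = 1e-6


@dataclass(frozen=True)
class Medium:
    """Exchange metabolites whose uptake is permitted.

    ``uptake_magnitude`` is the positive bound applied as lower bound
    ``-uptake_magnitude`` on each allowed exchange flux.
    """

    allowed_uptake: frozenset[str]
    uptake_magnitude: float = DEFAULT_UPTAKE_MAGNITUDE

    def __init__(self, allowed_uptake, uptake_magnitude=DEFAULT_UPTAKE_MAGNITUDE):
        object.__setattr__(self, "allowed_uptake", frozenset(allowed_uptake))
        if uptake_magnitude <= 0:
            raise PreconditionError("uptake_magnitude must be positive")
        object.__setattr__(self, "uptake_magnitude", float(uptake_magnitude))

    def without(self, met_id: str) -> "Medium":
        return Medium(self.allowed_uptake - {met_id}, self.uptake_magnitude)

    def with_(self, met_id: str) -> "Medium":
        return Medium(self.allowed_uptake | {met_id}, self.uptake_magnitude)


@dataclass(frozen=True)
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective: float
    fluxes: dict[str, float]


def all_open_medium(
    model: MetabolicModel, uptake_magnitude: float = DEFAULT_UPTAKE_MAGNITUDE
) -> Medium:
    """The permissive medium: every exchange metabolite may be taken up."""
    return Medium(model.exchange_metabolite_ids, uptake_magnitude)


def flux_bounds(model: MetabolicModel, medium: Medium) -> tuple[np.ndarray, np.ndarray]:
    """Per-reaction (lower, upper) bound arrays after applying the medium."""
    allowed = medium.allowed_uptake
    exch_mets = set(model.exchange_metabolite_ids)
    unknown = allowed - exch_mets
    if unknown:
        raise PreconditionError(
            f"medium allows uptake of non-exchangeable metabolites: {sorted(unknown)}"
        )
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    for j, r in enumerate(model.reactions):
        if not r.is_exchange:
            continue
        met = model.exchange_metabolite(r)
        lb[j] = -medium.uptake_magnitude if met in allowed else 0.0
    return lb, ub


_LP_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def maximize_biomass(model: MetabolicModel, medium: Medium) -> FluxSolution:
    """Maximize biomass flux subject to S.V = 0 and the medium's bounds."""
    lb, ub = flux_bounds(model, medium)
    n = len(model.reactions)
    c = np.zeros(n)
    c[model.reaction_index[model.biomass_reaction_id]] = -1.0
    S = model.stoichiometric_matrix()
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    status = _LP_STATUS.get(res.status)
    if status is None:
        raise SolverError(res.status, f"LP failed: {res.message}")
    if status == "unbounded":
        return FluxSolution(status="unbounded", objective=float("inf"), fluxes={})
    if status == "infeasible":
        # S.V=0 with V=0 is always feasible unless stored bounds exclude 0;
        # that is a malformed model, not a biological outcome.
        raise SolverError(
            "infeasible",
            "LP infeasible: some reaction bounds exclude zero flux",
        )
    fluxes = {r.id: float(x) for r, x in zip(model.reactions, res.x)}
    return FluxSolution(status="optimal", objective=-float(res.fun), fluxes=fluxes)


def grows(
    model: MetabolicModel, medium: Medium, cutoff: float = DEFAULT_CUTOFF
) -> bool:
    """True iff the biomass optimum reaches the cutoff (inclusive)."""
    if cutoff < 0:
        raise PreconditionError("cutoff must be >= 0")
    sol = maximize_biomass(model, medium)
    if sol.status == "unbounded":
        return True
    return sol.objective >= cutoff - GROWTH_SLACK


def fraction_of_max_cutoff(
    model: MetabolicModel,
    fraction: float,
    uptake_magnitude: float = DEFAULT_UPTAKE_MAGNITUDE,
) -> float:
    """A relative biomass cutoff: fraction of the optimum on the all-open medium.

    Offered as an alternative to the absolute nonzero-biomass threshold for
    models whose biomass scale differs wildly.
    """
    if not 0 < fraction <= 1:
        raise PreconditionError("fraction must be in (0, 1]")
    sol = maximize_biomass(model, all_open_medium(model, uptake_magnitude))
    if sol.status == "unbounded":
        raise SolverError("unbounded", "biomass unbounded on the open medium")
    return fraction * sol.objective


# ---------------------------------------------------------------------------
# gene deletions through GPR rules


def _gpr_active(gpr: str, knockouts: set[str]) -> bool:
    from cobra.core.gene import GPR

    return GPR.from_string(gpr).eval(knockouts=knockouts)


def delete_genes(model: MetabolicModel, genes) -> MetabolicModel:
    """Knock out a set of genes.

    Every reaction whose GPR evaluates false without these genes gets
    bounds [0, 0] (AND = enzyme complex, all subunits required; OR =
    isozymes, any one suffices).  Reactions with no GPR are untouched.
    """
    knockouts = set(genes)
    unknown = knockouts - model.genes
    if unknown:
        raise UnknownIdentifierError(f"unknown genes: {sorted(unknown)}")
    out = model.copy()
    for r in out.reactions:
        if r.gpr and not _gpr_active(r.gpr, knockouts):
            r.lower_bound = 0.0
            r.upper_bound = 0.0
    return out


def delete_gene(model: MetabolicModel, gene: str) -> MetabolicModel:
    """Single-gene knockout; see :func:`delete_genes`."""
    return delete_genes(model, {gene})
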