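"""Two-stage MILP prediction of minimal growth environments (MINENVs).

Stage 1 finds the least number of exchange metabolites whose uptake
suffices for biomass production above a cutoff.  For each exchange flux
``f_i`` a binary indicator ``theta_i`` is introduced with the coupling
constraint ``f_i >= -M * (1 - theta_i)`` (M = the uptake-bound magnitude):
``theta_i = 1`` forces ``f_i >= 0`` (the metabolite is not consumed),
``theta_i = 0`` leaves uptake open.  Maximizing ``sum(theta)`` subject to
steady state, reaction bounds, and ``f_biomass >= cutoff`` yields the
minimal number of consumed metabolites.  The support of this optimum is a
*non-unique* minimal environment: many equally small nutrient sets may
exist.

Stage 2 disambiguates.  With the cardinality capped at the stage-1 optimum,
the objective switches to minimizing the summed molar-weight *rank* of the
consumed metabolites (ranks from ascending molar mass, ties broken by
metabolite id).  Preferring light compounds yields a single canonical
MINENV per model — the simplest basic nutrient set of minimal size.  A
further refinement pass resolves the rare exact tie in summed rank by
preferring the set whose sorted rank vector is lexicographically smallest,
so the result is a deterministic function of the model alone.

Critical metabolites are the irreplaceable core: members of the MINENV
whose single closure kills growth even with every other exchange open.

MILPs are solved with HiGHS through scipy.optimize.milp.  After every
solve the extracted metabolite set is re-verified by plain FBA and pruned
to inclusion-minimality, so integrality tolerances can never leak into the
reported sets.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .errors import (
    InfeasibleTargetError,
    MilpTimeoutError,
    PreconditionError,
    SolverError,
)
from .fba_core import (
    DEFAULT_CUTOFF,
    DEFAULT_UPTAKE_MAGNITUDE,
    Medium,
    all_open_medium,
    delete_gene,
    grows,
)
from .model_io import MetabolicModel, MolarOrdering, molar_ordering

__all__ = [
    "MentoResult",
    "StabilityReport",
    "minimal_medium_size",
    "unique_minenv",
    "preferred_minenv",
    "swap_degeneracy_check",
    "critical_metabolites",
    "minenv_stability_under_deletions",
    "results_table",
    "write_results_table",
]

logger = logging.getLogger(__name__)

#: time limit per MILP solve, seconds
DEFAULT_TIME_LIMIT = 300.0

#: exchange count above which the lexicographic tie-refinement pass is
#: skipped (its 2**(E-rank) weights must stay exactly representable)
_REFINE_MAX_EXCHANGES = 45


@dataclass
class MentoResult:
    """Outcome of the two-stage minimal-environment computation."""

    minimal_size: int
    minenv: frozenset[str]
    molar_rank_sum: int
    cutoff_used: float
    solver_status: str
    theta: dict[str, int]
    critical: frozenset[str] | None = None
    uptake_magnitude: float = DEFAULT_UPTAKE_MAGNITUDE
    exempt: frozenset[str] = field(default_factory=frozenset)

    def medium(self) -> Medium:
        """The MINENV as an applicable medium (exempt compounds included)."""
        return Medium(self.minenv | self.exempt, self.uptake_magnitude)


# ---------------------------------------------------------------------------
# MILP assembly


class _MilpProblem:
    """Shared scaffolding for both MILP stages.

    Variable layout: all reaction fluxes first, then one binary theta per
    counted exchange.  Exempt metabolites keep uptake open without a theta
    (they are never counted).
    """

    def __init__(
        self,
        model: MetabolicModel,
        cutoff: float,
        uptake_magnitude: float,
        exempt: frozenset[str],
    ):
        self.model = model
        self.cutoff = cutoff
        self.M = float(uptake_magnitude)
        exchanges = model.exchanges
        met_of = {r.id: model.exchange_metabolite(r) for r in exchanges}
        self.counted = [r for r in exchanges if met_of[r.id] not in exempt]
        self.counted_mets = [met_of[r.id] for r in self.counted]
        self.n_rxn = len(model.reactions)
        self.n_theta = len(self.counted)
        ridx = model.reaction_index

        lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
        for r in exchanges:
            lb[ridx[r.id]] = -self.M  # uptake decided by theta / exemption
        lb = np.concatenate([lb, np.zeros(self.n_theta)])
        ub = np.concatenate([ub, np.ones(self.n_theta)])
        self.bounds = Bounds(lb, ub)
        self.integrality = np.concatenate(
            [np.zeros(self.n_rxn), np.ones(self.n_theta)]
        )

        S = model.stoichiometric_matrix()
        zero = sparse.csr_matrix((S.shape[0], self.n_theta))
        steady = LinearConstraint(sparse.hstack([S, zero], format="csr"), 0.0, 0.0)

        bm = np.zeros(self.n_rxn + self.n_theta)
        bm[ridx[model.biomass_reaction_id]] = 1.0
        growth = LinearConstraint(bm, cutoff, np.inf)

        # f_i - M*theta_i >= -M  (theta_i = 1 forces f_i >= 0)
        rows, cols, vals = [], [], []
        for k, r in enumerate(self.counted):
            rows += [k, k]
            cols += [ridx[r.id], self.n_rxn + k]
            vals += [1.0, -self.M]
        couple = LinearConstraint(
            sparse.csr_matrix(
                (vals, (rows, cols)), shape=(self.n_theta, self.n_rxn + self.n_theta)
            ),
            -self.M,
            np.inf,
        )
        self.base_constraints = [steady, growth, couple]

    def theta_objective(self, weights: np.ndarray, sense: str) -> np.ndarray:
        """Objective over theta variables; sense 'max' flips the sign."""
        c = np.zeros(self.n_rxn + self.n_theta)
        c[self.n_rxn :] = weights if sense == "min" else -weights
        return c

    def cardinality_constraint(self, max_consumed: int) -> LinearConstraint:
        """sum(1 - theta) <= max_consumed, i.e. sum(theta) >= E - max."""
        row = np.zeros(self.n_rxn + self.n_theta)
        row[self.n_rxn :] = 1.0
        return LinearConstraint(row, self.n_theta - max_consumed, np.inf)

    def solve(self, c, extra_constraints=(), time_limit=DEFAULT_TIME_LIMIT):
        t0 = time.perf_counter()
        res = milp(
            c=c,
            constraints=self.base_constraints + list(extra_constraints),
            integrality=self.integrality,
            bounds=self.bounds,
            options={"time_limit": time_limit, "mip_rel_gap": 0.0},
        )
        wall = time.perf_counter() - t0
        logger.info(
            "milp model=%s status=%s objective=%s gap=%s wall=%.3fs",
            self.model.id,
            res.status,
            getattr(res, "fun", None),
            getattr(res, "mip_gap", None),
            wall,
        )
        if res.status == 1:  # iteration/time limit
            raise MilpTimeoutError(
                incumbent=getattr(res, "fun", None),
                bound=getattr(res, "mip_dual_bound", None),
            )
        if res.status != 0:
            raise SolverError(res.status, f"MILP failed: {res.message}")
        return res

    def consumed_set(self, res) -> frozenset[str]:
        theta = np.round(res.x[self.n_rxn :]).astype(int)
        return frozenset(
            m for m, t in zip(self.counted_mets, theta) if t == 0
        )


def _check_cutoff_attainable(model, cutoff, uptake_magnitude):
    if cutoff < 0:
        raise PreconditionError("cutoff must be >= 0")
    if not grows(model, all_open_medium(model, uptake_magnitude), cutoff):
        raise InfeasibleTargetError(
            f"model {model.id!r}: biomass cutoff {cutoff} is unattainable "
            "even with every exchange open"
        )


def _prune_to_minimal(model, members, cutoff, uptake_magnitude, exempt, ordering=None):
    """Drop members whose removal keeps growth above the cutoff.

    The MILP bounds the support; FBA verifies necessity.  Heaviest-rank
    members are tried first so the survivors stay biased toward light
    compounds, matching the stage-2 objective.
    """
    keep = set(members)
    order = sorted(
        keep,
        key=(lambda m: (-ordering.rank_of[m], m)) if ordering else (lambda m: m),
    )
    for m in order:
        trial = Medium((keep - {m}) | set(exempt), uptake_magnitude)
        if grows(model, trial, cutoff):
            keep.discard(m)
    return frozenset(keep)


# ---------------------------------------------------------------------------
# stage 1


def minimal_medium_size(
    model: MetabolicModel,
    cutoff: float = DEFAULT_CUTOFF,
    uptake_magnitude: float = DEFAULT_UPTAKE_MAGNITUDE,
    exempt=(),
    time_limit: float = DEFAULT_TIME_LIMIT,
) -> tuple[int, frozenset[str]]:
    """Minimal number of uptaken exchange metabolites supporting growth.

    Returns ``(size, witness)``: the provably minimal count and one optimal
    nutrient set attaining it.  The witness is *a* minimal environment, not
    the canonical one — use :func:`unique_minenv` for that.
    """
    exempt = frozenset(exempt)
    _check_cutoff_attainable(model, cutoff, uptake_magnitude)
    prob = _MilpProblem(model, cutoff, uptake_magnitude, exempt)
    if prob.n_theta == 0:
        return 0, frozenset()
    res = prob.solve(
        prob.theta_objective(np.ones(prob.n_theta), "max"), time_limit=time_limit
    )
    witness = _prune_to_minimal(
        model, prob.consumed_set(res), cutoff, uptake_magnitude, exempt
    )
    return len(witness), witness


# ---------------------------------------------------------------------------
# stage 2


def unique_minenv(
    model: MetabolicModel,
    cutoff: float = DEFAULT_CUTOFF,
    uptake_magnitude: float = DEFAULT_UPTAKE_MAGNITUDE,
    exempt=(),
    time_limit: float = DEFAULT_TIME_LIMIT,
) -> MentoResult:
    """The canonical MINENV: minimal size, then minimal summed molar rank.

    Among all nutrient sets of stage-1 cardinality that reach the biomass
    cutoff, returns the one with the smallest sum of molar-mass ranks;
    exact rank-sum ties are broken by preferring the lexicographically
    smallest sorted rank vector.  Deterministic given the model.
    """
    ordering = molar_ordering(model)
    return _stage2(
        model,
        ordering,
        rank_weights=None,
        cutoff=cutoff,
        uptake_magnitude=uptake_magnitude,
        exempt=frozenset(exempt),
        time_limit=time_limit,
    )


def preferred_minenv(
    model: MetabolicModel,
    preferred,
    cutoff: float = DEFAULT_CUTOFF,
    uptake_magnitude: float = DEFAULT_UPTAKE_MAGNITUDE,
    exempt=(),
    time_limit: float = DEFAULT_TIME_LIMIT,
) -> MentoResult:
    """MINENV biased toward a preferred compound catalogue.

    Stage-1 cardinality is unchanged; the stage-2 objective becomes a
    two-tier preference — first minimize the number of consumed compounds
    *outside* ``preferred``, then the molar-rank sum.  Implemented as a
    single weighted objective with the tier-1 weight exceeding any
    attainable rank sum, so tier 1 strictly dominates.  With ``preferred``
    empty or all-inclusive this reduces exactly to :func:`unique_minenv`.
    """
    preferred = frozenset(preferred)
    ordering = molar_ordering(model)
    E = len(ordering.ranked_ids)
    big = float(E * E + 1)  # > any possible rank sum
    weights = {
        m: ordering.rank_of[m] + (0.0 if m in preferred else big)
        for m in ordering.ranked_ids
    }
    return _stage2(
        model,
        ordering,
        rank_weights=weights,
        cutoff=cutoff,
        uptake_magnitude=uptake_magnitude,
        exempt=frozenset(exempt),
        time_limit=time_limit,
    )


def _stage2(
    model: MetabolicModel,
    ordering: MolarOrdering,
    rank_weights: dict[str, float] | None,
    cutoff: float,
    uptake_magnitude: float,
    exempt: frozenset[str],
    time_limit: float,
) -> MentoResult:
    min_size, _witness = minimal_medium_size(
        model, cutoff, uptake_magnitude, exempt, time_limit
    )
    prob = _MilpProblem(model, cutoff, uptake_magnitude, exempt)
    if prob.n_theta == 0 or min_size == 0:
        minenv: frozenset[str] = frozenset()
        theta = {m: 1 for m in prob.counted_mets}
        return MentoResult(
            minimal_size=0,
            minenv=minenv,
            molar_rank_sum=0,
            cutoff_used=cutoff,
            solver_status="optimal",
            theta=theta,
            uptake_magnitude=uptake_magnitude,
            exempt=exempt,
        )

    weights = rank_weights or {m: float(ordering.rank_of[m]) for m in ordering.ranked_ids}
    w = np.array([weights[m] for m in prob.counted_mets])
    card = prob.cardinality_constraint(min_size)
    # min sum w_i (1-theta_i)  ==  max sum w_i theta_i  (constant offset)
    res = prob.solve(
        prob.theta_objective(w, "max"), extra_constraints=[card], time_limit=time_limit
    )
    consumed = prob.consumed_set(res)
    obj_star = float(np.sum([weights[m] for m in consumed]))

    # Lexicographic refinement: among sets tied on the weighted sum, prefer
    # the one whose sorted rank vector is smallest — i.e. greedily favour
    # inclusion of the lowest-ranked compounds via power-of-two bonuses.
    E = len(ordering.ranked_ids)
    if E <= _REFINE_MAX_EXCHANGES:
        # pin the weighted sum at its optimum: sum w*(1-theta) <= obj_star,
        # i.e. sum(w*theta) >= sum(w) - obj_star (it cannot go lower)
        tie = LinearConstraint(
            prob.theta_objective(w, "min"), float(np.sum(w)) - obj_star, np.inf
        )
        bonus = np.array(
            [float(2 ** (E - ordering.rank_of[m])) for m in prob.counted_mets]
        )
        res = prob.solve(
            prob.theta_objective(bonus, "min"),  # min bonus*theta = max bonus*(1-theta)
            extra_constraints=[card, tie],
            time_limit=time_limit,
        )
        consumed = prob.consumed_set(res)

    minenv = _prune_to_minimal(
        model, consumed, cutoff, uptake_magnitude, exempt, ordering
    )
    if len(minenv) > min_size:  # pragma: no cover - guarded by construction
        raise SolverError(
            "inconsistent", "stage-2 optimum violates the cardinality cap"
        )
    if not grows(model, Medium(minenv | exempt, uptake_magnitude), cutoff):
        raise SolverError(
            "inconsistent", "extracted MINENV fails the FBA growth re-check"
        )
    theta = {m: (0 if m in minenv else 1) for m in prob.counted_mets}
    return MentoResult(
        minimal_size=len(minenv),
        minenv=minenv,
        molar_rank_sum=int(sum(ordering.rank_of[m] for m in minenv)),
        cutoff_used=cutoff,
        solver_status="optimal",
        theta=theta,
        uptake_magnitude=uptake_magnitude,
        exempt=exempt,
    )


# ---------------------------------------------------------------------------
# degeneracy and criticality


def swap_degeneracy_check(
    model: MetabolicModel, result: MentoResult, mass_decimals: int = 6
) -> list[tuple[str, str]]:
    """Equal-mass single-compound swaps that preserve growth.

    For every MINENV member and every non-member of identical molar mass
    (equal after rounding to ``mass_decimals``), tests whether swapping the
    pair still grows at the result's cutoff.  An empty list certifies that
    the weight-ranked choice is non-degenerate for this model.
    """
    ordering = molar_ordering(model)
    swaps: list[tuple[str, str]] = []
    outside = [m for m in ordering.ranked_ids if m not in result.minenv]
    for member in sorted(result.minenv):
        mass = round(ordering.mass_of[member], mass_decimals)
        for candidate in outside:
            if round(ordering.mass_of[candidate], mass_decimals) != mass:
                continue
            trial = Medium(
                (result.minenv - {member}) | {candidate} | set(result.exempt),
                result.uptake_magnitude,
            )
            if grows(model, trial, result.cutoff_used):
                swaps.append((member, candidate))
    return swaps


def critical_metabolites(
    model: MetabolicModel, result: MentoResult
) -> frozenset[str]:
    """MINENV members that no other compound can replace.

    A member is critical when closing its uptake alone — with every other
    exchange open — drops the biomass optimum below the cutoff.
    """
    full = all_open_medium(model, result.uptake_magnitude)
    critical = frozenset(
        m
        for m in result.minenv
        if not grows(model, full.without(m), result.cutoff_used)
    )
    result.critical = critical
    return critical


# ---------------------------------------------------------------------------
# robustness to single-gene deletions


@dataclass
class StabilityReport:
    """How single-gene knockouts perturb the MINENV."""

    fraction_composition_changed: float
    fraction_size_changed: float
    per_gene: dict[str, dict]
    lethal: frozenset[str]
    baseline: MentoResult


def minenv_stability_under_deletions(
    model: MetabolicModel,
    cutoff: float = DEFAULT_CUTOFF,
    uptake_magnitude: float = DEFAULT_UPTAKE_MAGNITUDE,
    exempt=(),
    time_limit: float = DEFAULT_TIME_LIMIT,
) -> StabilityReport:
    """Recompute the MINENV under every single-gene knockout.

    Genes whose deletion abolishes growth on the all-open medium are
    recorded as lethal and excluded from the change ratios; for the rest,
    composition change means any set difference from the baseline MINENV
    and size change means different cardinality.
    """
    if not model.genes:
        raise PreconditionError(
            f"model {model.id!r} has no GPR-linked genes to delete"
        )
    exempt = frozenset(exempt)
    baseline = unique_minenv(model, cutoff, uptake_magnitude, exempt, time_limit)
    per_gene: dict[str, dict] = {}
    lethal: set[str] = set()
    n_comp = n_size = n_viable = 0
    for gene in sorted(model.genes):
        mutant = delete_gene(model, gene)
        if not grows(mutant, all_open_medium(mutant, uptake_magnitude), cutoff):
            lethal.add(gene)
            per_gene[gene] = {"lethal": True}
            continue
        res = unique_minenv(mutant, cutoff, uptake_magnitude, exempt, time_limit)
        comp_changed = res.minenv != baseline.minenv
        size_changed = res.minimal_size != baseline.minimal_size
        n_viable += 1
        n_comp += comp_changed
        n_size += size_changed
        per_gene[gene] = {
            "lethal": False,
            "composition_changed": comp_changed,
            "size_changed": size_changed,
            "minimal_size": res.minimal_size,
            "minenv": res.minenv,
        }
    return StabilityReport(
        fraction_composition_changed=(n_comp / n_viable) if n_viable else float("nan"),
        fraction_size_changed=(n_size / n_viable) if n_viable else float("nan"),
        per_gene=per_gene,
        lethal=frozenset(lethal),
        baseline=baseline,
    )


# ---------------------------------------------------------------------------
# tabular serialization


def results_table(results: dict[str, MentoResult]):
    """One row per organism: id, minimal size, MINENV ids, critical ids."""
    import pandas as pd

    rows = []
    for org in sorted(results):
        r = results[org]
        rows.append(
            {
                "organism": org,
                "minimal_size": r.minimal_size,
                "minenv": ",".join(sorted(r.minenv)),
                "critical": ",".join(sorted(r.critical)) if r.critical is not None else "",
            }
        )
    return pd.DataFrame(rows, columns=["organism", "minimal_size", "minenv", "critical"])


def write_results_table(results: dict[str, MentoResult], path) -> None:
    results_table(results).to_csv(path, sep="\t", index=False)
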