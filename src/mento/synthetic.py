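"""Seedable toy metabolic models, a brute-force oracle, and synthetic communities.

The toy generator builds tiny networks whose minimal media are exactly
enumerable: a biomass reaction consumes a handful of precursor compounds,
each precursor can be fed by one or more alternative external source
nutrients, and optional "hub" compounds convert into several precursors at
once — packing multiple nutritional needs into a single complex nutrient,
the way real minimal-environment predictions sometimes pick one compound
as a simultaneous carbon/nitrogen/phosphorus source.  With at most 12
exchange reactions the full uptake-subset lattice (<= 4096 FBA solves,
cut down further by feasibility monotonicity) is tractable, so the MILP
answers can be verified against exhaustive enumeration.

The community generator couples nutrition to co-occurrence: each
environment owns a core nutrient pool, and each organism draws its
precursor sources from its environments' cores with a tunable probability
(``coupling``) or uniformly from the global pool otherwise.  At coupling 1
co-habiting organisms eat alike by construction; at coupling 0 nutrition
is independent of the presence matrix, giving a null model for the
ecology analyses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import PreconditionError
from .fba_core import (
    DEFAULT_CUTOFF,
    DEFAULT_UPTAKE_MAGNITUDE,
    Medium,
    all_open_medium,
    grows,
)
from .model_io import MetabolicModel, Metabolite, Reaction, detect_exchanges

__all__ = [
    "ToyModelSpec",
    "CommunitySpec",
    "BruteForceResult",
    "generate_toy_model",
    "sample_toy_spec",
    "brute_force_minimal_media",
    "generate_community",
    "MAX_ORACLE_EXCHANGES",
]

#: lattice-enumeration guard: 2**12 = 4096 subsets
MAX_ORACLE_EXCHANGES = 12

#: molar masses of a small palette of plausible nutrients (g/mol scale);
#: values are distinct so default rank orderings are unambiguous
_MASS_PALETTE = [
    18.015, 26.98, 35.45, 39.10, 44.01, 58.44, 60.05, 75.07, 89.09, 105.09,
    117.15, 132.12, 146.14, 155.15, 174.20, 180.16, 204.23, 244.20, 323.20,
    363.22, 507.18,
]


@dataclass(frozen=True)
class ToyModelSpec:
    """Blueprint for a toy model with an enumerable minimal medium.

    ``n_biomass_precursors`` compounds are consumed by biomass; each has
    ``sources_per_precursor`` alternative external nutrients feeding it;
    ``n_convertible_hubs`` extra nutrients each convert into several
    precursors at once; ``n_distractors`` adds importable nutrients that
    feed nothing.  ``mass_assignment`` pins molar masses for chosen
    external nutrients (ids ``src_<p>_<s>``, ``hub_<h>``, ``dis_<d>``);
    unpinned masses come from a fixed palette, deterministically in
    ``seed``.  ``gpr_density`` is the probability that an internal
    reaction gets a gene rule.
    """

    n_biomass_precursors: int = 3
    sources_per_precursor: int = 2
    n_convertible_hubs: int = 0
    n_distractors: int = 0
    mass_assignment: dict = field(default_factory=dict)
    gpr_density: float = 0.0
    seed: int = 0

    @property
    def n_exchanges(self) -> int:
        return (
            self.n_biomass_precursors * self.sources_per_precursor
            + self.n_convertible_hubs
            + self.n_distractors
        )


@dataclass(frozen=True)
class CommunitySpec:
    """Blueprint for a synthetic community with tunable nutrient coupling.

    ``coupling`` is the probability that an organism's precursor source is
    drawn from its environments' core nutrient pools rather than uniformly
    from the global pool; 1.0 ties nutrition tightly to co-occurrence,
    0.0 makes them independent.
    """

    n_organisms: int = 50
    n_environments: int = 10
    core_nutrients_per_environment: int = 6
    coupling: float = 1.0
    n_precursors_per_organism: int = 3
    n_pool_nutrients: int = 60
    max_environments_per_organism: int = 3
    seed: int = 0


# ---------------------------------------------------------------------------
# toy model generation


def _toy_masses(spec: ToyModelSpec, ext_ids: list[str], rng) -> dict[str, float]:
    masses = {}
    palette = list(_MASS_PALETTE)
    for mid in ext_ids:
        if mid in spec.mass_assignment:
            masses[mid] = float(spec.mass_assignment[mid])
        else:
            k = int(rng.integers(len(palette)))
            # nudge repeated palette picks apart so unplanted ties are rare
            masses[mid] = round(palette[k] + 0.001 * len(masses), 3)
    return masses


def generate_toy_model(spec: ToyModelSpec) -> MetabolicModel:
    """Build the toy model a spec describes; deterministic in ``spec.seed``.

    The returned model always grows on the all-open medium (every
    precursor has at least one source).  Ground truth about the wiring is
    attached as ``model.ground_truth`` — a dict with per-precursor source
    nutrients and per-hub coverage — for use in tests.
    """
    if spec.n_biomass_precursors < 1 or spec.sources_per_precursor < 1:
        raise PreconditionError(
            "need at least one precursor with at least one source"
        )
    if spec.n_exchanges > MAX_ORACLE_EXCHANGES:
        raise PreconditionError(
            f"spec yields {spec.n_exchanges} exchanges; the oracle guard "
            f"caps toy models at {MAX_ORACLE_EXCHANGES}"
        )
    rng = np.random.default_rng(spec.seed)
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    genes: set[str] = set()
    sources_of: dict[str, list[str]] = {}
    hub_covers: dict[str, list[str]] = {}

    precursors = [f"pre_{p}" for p in range(spec.n_biomass_precursors)]
    for pid in precursors:
        mets.append(Metabolite(pid, compartment="c", formula="C4H8O4"))

    ext_ids = []
    for p in range(spec.n_biomass_precursors):
        sources_of[precursors[p]] = []
        for s in range(spec.sources_per_precursor):
            ext_ids.append(f"src_{p}_{s}")
    hubs = [f"hub_{h}" for h in range(spec.n_convertible_hubs)]
    ext_ids += hubs
    distractors = [f"dis_{d}" for d in range(spec.n_distractors)]
    ext_ids += distractors
    masses = _toy_masses(spec, ext_ids, rng)

    def add_external(mid: str) -> str:
        """Exchange + transport for one external nutrient; returns the
        cytosolic id."""
        e_id, c_id = f"{mid}_e", f"{mid}_c"
        mets.append(Metabolite(e_id, compartment="e", molar_mass=masses[mid]))
        mets.append(Metabolite(c_id, compartment="c", molar_mass=masses[mid]))
        rxns.append(Reaction(f"EX_{mid}", {e_id: -1.0}, is_exchange=True))
        rxns.append(Reaction(f"T_{mid}", {e_id: -1.0, c_id: 1.0}, lower_bound=0.0))
        return c_id

    def maybe_gpr(rxn: Reaction):
        if spec.gpr_density > 0 and rng.random() < spec.gpr_density:
            g = f"g_{rxn.id}"
            genes.add(g)
            rxn.gpr = g

    for p in range(spec.n_biomass_precursors):
        for s in range(spec.sources_per_precursor):
            mid = f"src_{p}_{s}"
            c_id = add_external(mid)
            conv = Reaction(
                f"C_{mid}", {c_id: -1.0, precursors[p]: 1.0}, lower_bound=0.0
            )
            maybe_gpr(conv)
            rxns.append(conv)
            sources_of[precursors[p]].append(f"{mid}_e")

    for h, hid in enumerate(hubs):
        c_id = add_external(hid)
        n_cover = int(rng.integers(2, spec.n_biomass_precursors + 1))
        cover = sorted(
            rng.choice(spec.n_biomass_precursors, size=n_cover, replace=False)
        )
        stoich = {c_id: -1.0}
        for p in cover:
            stoich[precursors[p]] = 1.0
        conv = Reaction(f"C_{hid}", stoich, lower_bound=0.0)
        maybe_gpr(conv)
        rxns.append(conv)
        hub_covers[f"{hid}_e"] = [precursors[p] for p in cover]

    for did in distractors:
        add_external(did)  # importable, feeds nothing

    biomass = Reaction(
        "biomass",
        {pid: -1.0 for pid in precursors},
        lower_bound=0.0,
        upper_bound=DEFAULT_UPTAKE_MAGNITUDE,
    )
    rxns.append(biomass)

    model = MetabolicModel(
        id=f"toy_seed{spec.seed}",
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id="biomass",
        genes=genes,
    )
    detect_exchanges(model)
    model.validate()
    if not grows(model, all_open_medium(model), DEFAULT_CUTOFF):
        raise PreconditionError(  # pragma: no cover - impossible by wiring
            "generated toy model fails to grow on the open medium"
        )
    model.ground_truth = {
        "sources_of": sources_of,
        "hub_covers": hub_covers,
        "distractors": [f"{d}_e" for d in distractors],
        "masses": {f"{m}_e": masses[m] for m in ext_ids},
    }
    return model


def sample_toy_spec(
    rng,
    min_exchanges: int = 3,
    max_exchanges: int = 10,
    gpr_density: float = 0.0,
) -> ToyModelSpec:
    """Draw a random toy spec with an exchange count in the given range.

    Precursor count, sources per precursor, hub count and distractor count
    are sampled until the implied exchange count lands inside
    ``[min_exchanges, max_exchanges]``; the model seed is drawn from the
    same generator, so a seeded ``rng`` yields a reproducible stream of
    specs.
    """
    if not 1 <= min_exchanges <= max_exchanges <= MAX_ORACLE_EXCHANGES:
        raise PreconditionError("invalid exchange-count range")
    while True:
        k = int(rng.integers(1, 4))
        s = int(rng.integers(1, 4))
        h = int(rng.integers(0, 3)) if k >= 2 else 0
        d = int(rng.integers(0, 3))
        if min_exchanges <= k * s + h + d <= max_exchanges:
            return ToyModelSpec(
                n_biomass_precursors=k,
                sources_per_precursor=s,
                n_convertible_hubs=h,
                n_distractors=d,
                gpr_density=gpr_density,
                seed=int(rng.integers(2**31)),
            )


# ---------------------------------------------------------------------------
# brute-force oracle


@dataclass(frozen=True)
class BruteForceResult:
    min_size: int
    minimal_sets: tuple[frozenset, ...]
    critical: frozenset


def brute_force_minimal_media(
    model: MetabolicModel,
    cutoff: float = DEFAULT_CUTOFF,
    uptake_magnitude: float = DEFAULT_UPTAKE_MAGNITUDE,
) -> BruteForceResult:
    """Exhaustive ground truth over every uptake subset.

    Scans the full subset lattice of exchange metabolites in ascending
    cardinality, FBA-testing growth (a superset of a known-feasible set is
    feasible by monotonicity and is not re-solved).  Returns the minimal
    feasible cardinality, every feasible set at that cardinality, and the
    intersection of ALL feasible sets — the ground-truth critical
    metabolites, i.e. compounds present in every medium that grows.
    """
    mets = sorted(model.exchange_metabolite_ids)
    if len(mets) > MAX_ORACLE_EXCHANGES:
        raise PreconditionError(
            f"{len(mets)} exchanges exceed the enumeration guard "
            f"({MAX_ORACLE_EXCHANGES})"
        )
    min_size = None
    minimal_sets: list[frozenset] = []
    inclusion_minimal: list[frozenset] = []
    critical: set | None = None
    for k in range(len(mets) + 1):
        for combo in itertools.combinations(mets, k):
            s = frozenset(combo)
            if any(f <= s for f in inclusion_minimal):
                feasible = True
            else:
                feasible = grows(model, Medium(s, uptake_magnitude), cutoff)
                if feasible:
                    inclusion_minimal.append(s)
            if feasible:
                if min_size is None:
                    min_size = k
                if k == min_size:
                    minimal_sets.append(s)
                critical = s if critical is None else (critical & s)
    if min_size is None:
        raise PreconditionError(
            f"model {model.id!r}: no uptake subset reaches cutoff {cutoff}"
        )
    return BruteForceResult(
        min_size=min_size,
        minimal_sets=tuple(minimal_sets),
        critical=frozenset(critical),
    )


# ---------------------------------------------------------------------------
# synthetic communities


def generate_community(spec: CommunitySpec):
    """Organism models + presence matrix + per-environment nutrient cores.

    Returns ``(models, profile, ground_truth)`` where ``models`` maps
    organism id to a toy :class:`MetabolicModel` whose external nutrients
    are drawn from a global pool shared across organisms (so MINENV sets
    are comparable), ``profile`` is the binary presence matrix, and
    ``ground_truth`` maps environment id to its core nutrient set.
    Deterministic in ``spec.seed``.
    """
    from .ecology import EcologicalProfile

    if spec.n_organisms < 2 or spec.n_environments < 1:
        raise PreconditionError("need >= 2 organisms and >= 1 environment")
    if spec.core_nutrients_per_environment > spec.n_pool_nutrients:
        raise PreconditionError("environment core larger than the nutrient pool")
    if not 0.0 <= spec.coupling <= 1.0:
        raise PreconditionError("coupling must be in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    pool = [f"nut_{i:03d}" for i in range(spec.n_pool_nutrients)]
    # distinct masses so molar ranks are unambiguous across the community
    pool_mass = {n: round(20.0 + 7.13 * i, 3) for i, n in enumerate(pool)}
    envs = [f"env_{j:02d}" for j in range(spec.n_environments)]
    cores = {
        e: frozenset(
            pool[i]
            for i in rng.choice(
                spec.n_pool_nutrients,
                size=spec.core_nutrients_per_environment,
                replace=False,
            )
        )
        for e in envs
    }
    orgs = [f"org_{i:03d}" for i in range(spec.n_organisms)]
    presence = np.zeros((spec.n_organisms, spec.n_environments), dtype=bool)
    models: dict[str, MetabolicModel] = {}
    for i, org in enumerate(orgs):
        max_memb = min(spec.max_environments_per_organism, spec.n_environments)
        n_memb = int(rng.integers(1, max_memb + 1))
        memb = rng.choice(spec.n_environments, size=n_memb, replace=False)
        presence[i, memb] = True
        local_core = sorted(set().union(*(cores[envs[j]] for j in memb)))
        chosen: list[str] = []
        for _p in range(spec.n_precursors_per_organism):
            if rng.random() < spec.coupling:
                nut = local_core[int(rng.integers(len(local_core)))]
            else:
                nut = pool[int(rng.integers(len(pool)))]
            chosen.append(nut)
        models[org] = _organism_model(org, chosen, pool_mass)
    profile = EcologicalProfile(organisms=orgs, environments=envs, presence=presence)
    return models, profile, dict(cores)


def _organism_model(
    org: str, precursor_sources: list[str], pool_mass: dict[str, float]
) -> MetabolicModel:
    """One-source-per-precursor toy model over globally named nutrients.

    The same nutrient may serve several precursors (one conversion each),
    in which case the organism's minimal medium is smaller than its
    precursor count.
    """
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    seen: set[str] = set()
    for nut in precursor_sources:
        if nut in seen:
            continue
        seen.add(nut)
        mets.append(Metabolite(f"{nut}_e", compartment="e", molar_mass=pool_mass[nut]))
        mets.append(Metabolite(f"{nut}_c", compartment="c", molar_mass=pool_mass[nut]))
        rxns.append(Reaction(f"EX_{nut}", {f"{nut}_e": -1.0}, is_exchange=True))
        rxns.append(
            Reaction(f"T_{nut}", {f"{nut}_e": -1.0, f"{nut}_c": 1.0}, lower_bound=0.0)
        )
    biomass_stoich: dict[str, float] = {}
    for p, nut in enumerate(precursor_sources):
        pre = f"pre_{p}"
        mets.append(Metabolite(pre, compartment="c", formula="C4H8O4"))
        rxns.append(
            Reaction(f"C_{p}_{nut}", {f"{nut}_c": -1.0, pre: 1.0}, lower_bound=0.0)
        )
        biomass_stoich[pre] = -1.0
    rxns.append(
        Reaction(
            "biomass",
            biomass_stoich,
            lower_bound=0.0,
            upper_bound=DEFAULT_UPTAKE_MAGNITUDE,
        )
    )
    model = MetabolicModel(
        id=org,
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id="biomass",
        genes=set(),
    )
    detect_exchanges(model)
    model.validate()
    return model
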