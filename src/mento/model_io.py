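"""Metabolic model containers, readers/writers, and molar-weight ordering.

The in-memory representation is deliberately small: a model is a list of
metabolites, a list of reactions with signed stoichiometry and flux bounds,
a designated biomass reaction, and an optional set of genes wired to
reactions through boolean gene-protein-reaction (GPR) rules.  Two on-disk
dialects are supported: the COBRA community JSON schema and SBML Level 3
(with the FBC package, delegated to cobrapy/libsbml).

Exchange reactions — boundary reactions moving exactly one metabolite in or
out of the system — are the objects the minimal-environment MILP reasons
about, so they are detected at load time and validated: an exchange that
touches more than one metabolite is a hard error.  The sign convention
throughout the package is negative flux = uptake, positive = secretion.

The molar ordering ranks every exchangeable metabolite by ascending molar
mass (ties broken by lexicographic metabolite id), producing the 1-based
rank vector used by the weight-minimizing second MILP stage.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

from .errors import (
    MassUnavailableError,
    ModelFormatError,
    ModelValidationError,
    UnknownIdentifierError,
)

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "MolarOrdering",
    "read_model",
    "write_model",
    "compound_mass",
    "molar_ordering",
    "to_cobra",
    "from_cobra",
]

#: conventional unconstrained flux bound (mmol/gDW/h in COBRA practice)
DEFAULT_BOUND = 1000.0


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``molar_mass`` (g/mol), when given, takes precedence over the mass
    derived from ``formula``; at least one of the two must be resolvable
    for every metabolite that has an exchange reaction.
    """

    id: str
    name: str = ""
    formula: str | None = None
    molar_mass: float | None = None
    compartment: str = ""


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds.

    ``stoichiometry`` maps metabolite id to its signed coefficient
    (negative = consumed).  ``gpr`` is a boolean expression over gene ids
    ("" means no gene association).  ``is_exchange`` marks boundary
    reactions; an exchange must touch exactly one metabolite.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: str = ""
    is_exchange: bool = False

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class MetabolicModel:
    """A stoichiometric network with a designated biomass reaction."""

    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_reaction_id: str
    genes: set[str] = field(default_factory=set)

    # -- indexing helpers ------------------------------------------------
    @property
    def metabolite_index(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    @property
    def reaction_index(self) -> dict[str, int]:
        return {r.id: j for j, r in enumerate(self.reactions)}

    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self.metabolites[self.metabolite_index[met_id]]
        except KeyError:
            raise UnknownIdentifierError(f"no metabolite {met_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self.reactions[self.reaction_index[rxn_id]]
        except KeyError:
            raise UnknownIdentifierError(f"no reaction {rxn_id!r}") from None

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def exchange_metabolite(self, rxn: Reaction) -> str:
        """The single metabolite an exchange reaction moves."""
        (met_id,) = rxn.stoichiometry.keys()
        return met_id

    @property
    def exchange_metabolite_ids(self) -> list[str]:
        """Exchangeable metabolites, in exchange-reaction order."""
        return [self.exchange_metabolite(r) for r in self.exchanges]

    def exchange_for(self, met_id: str) -> Reaction:
        for r in self.exchanges:
            if self.exchange_metabolite(r) == met_id:
                return r
        raise UnknownIdentifierError(f"no exchange reaction for {met_id!r}")

    def stoichiometric_matrix(self):
        """Sparse S (metabolites x reactions), CSR."""
        from scipy import sparse

        midx = self.metabolite_index
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(self.reactions):
            for met_id, coef in rxn.stoichiometry.items():
                rows.append(midx[met_id])
                cols.append(j)
                vals.append(float(coef))
        return sparse.csr_matrix(
            (vals, (rows, cols)),
            shape=(len(self.metabolites), len(self.reactions)),
        )

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            biomass_reaction_id=self.biomass_reaction_id,
            genes=set(self.genes),
        )

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        if self.biomass_reaction_id not in set(rxn_ids):
            raise ModelValidationError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )
        known = set(met_ids)
        for r in self.reactions:
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(
                    f"reaction {r.id!r}: lower bound {r.lower_bound} exceeds "
                    f"upper bound {r.upper_bound}"
                )
            missing = set(r.stoichiometry) - known
            if missing:
                raise ModelValidationError(
                    f"reaction {r.id!r} references unknown metabolites "
                    f"{sorted(missing)}"
                )
            n_touched = sum(1 for c in r.stoichiometry.values() if c != 0)
            if r.is_exchange and n_touched != 1:
                raise ModelValidationError(
                    f"exchange reaction {r.id!r} touches {n_touched} "
                    "metabolites; exchanges must move exactly one"
                )


@dataclass(frozen=True)
class MolarOrdering:
    """Exchange metabolites ranked by ascending molar mass.

    ``rank_of`` is 1-based; ties in mass are broken by lexicographic
    metabolite id so the ordering is identical across runs and machines.
    """

    ranked_ids: tuple[str, ...]
    rank_of: dict[str, int]
    mass_of: dict[str, float]


# ---------------------------------------------------------------------------
# exchange detection


def detect_exchanges(model: MetabolicModel) -> None:
    """Flag exchange reactions in place.

    A reaction is an exchange if it has exactly one nonzero stoichiometric
    entry; reactions already flagged (dialect markers such as an ``EX_``
    prefix or an SBML boundary species) are kept but re-validated.  The
    biomass reaction is never an exchange.
    """
    for r in model.reactions:
        if r.id == model.biomass_reaction_id:
            r.is_exchange = False
            continue
        nonzero = [m for m, c in r.stoichiometry.items() if c != 0]
        if len(nonzero) == 1:
            r.is_exchange = True


# ---------------------------------------------------------------------------
# molar masses


def compound_mass(met: Metabolite) -> float:
    """Molar mass in g/mol.

    An explicit ``molar_mass`` annotation wins; otherwise the mass is
    computed from the chemical formula using standard atomic masses
    (cobrapy's periodic table).  Formulas containing generic residues
    (``R``/``X`` groups) or no atoms at all are unresolvable and raise
    :class:`MassUnavailableError` — silently guessing a mass would corrupt
    the weight-ranked medium selection downstream.
    """
    if met.molar_mass is not None:
        if met.molar_mass <= 0:
            raise MassUnavailableError(
                [met.id], f"{met.id}: non-positive molar_mass {met.molar_mass}"
            )
        return float(met.molar_mass)
    if not met.formula:
        raise MassUnavailableError([met.id])
    from cobra.core.metabolite import Metabolite as _CobraMet

    with warnings.catch_warnings():
        # cobra warns (rather than raises) on elements outside its periodic
        # table; promote that to the hard error the callers rely on.
        warnings.simplefilter("error", UserWarning)
        try:
            weight = _CobraMet(met.id, formula=met.formula).formula_weight
        except UserWarning:
            raise MassUnavailableError(
                [met.id], f"{met.id}: formula {met.formula!r} has non-standard elements"
            ) from None
        except Exception:
            raise MassUnavailableError(
                [met.id], f"{met.id}: formula {met.formula!r} unparsable"
            ) from None
    if not weight:
        raise MassUnavailableError(
            [met.id], f"{met.id}: formula {met.formula!r} yields no mass"
        )
    return float(weight)


def molar_ordering(model: MetabolicModel) -> MolarOrdering:
    """Rank all exchangeable metabolites by ascending molar mass.

    Raises :class:`MassUnavailableError` listing every offender if any
    exchange metabolite lacks a resolvable mass.
    """
    masses: dict[str, float] = {}
    missing: list[str] = []
    for met_id in model.exchange_metabolite_ids:
        try:
            masses[met_id] = compound_mass(model.metabolite(met_id))
        except MassUnavailableError:
            missing.append(met_id)
    if missing:
        raise MassUnavailableError(sorted(missing))
    ranked = tuple(sorted(masses, key=lambda m: (masses[m], m)))
    return MolarOrdering(
        ranked_ids=ranked,
        rank_of={m: i + 1 for i, m in enumerate(ranked)},
        mass_of=masses,
    )


# ---------------------------------------------------------------------------
# JSON dialect (COBRA community schema)


def _json_to_model(doc: dict, model_id: str) -> MetabolicModel:
    try:
        mets = []
        for m in doc["metabolites"]:
            mets.append(
                Metabolite(
                    id=m["id"],
                    name=m.get("name", ""),
                    formula=m.get("formula"),
                    molar_mass=m.get("molar_mass"),
                    compartment=m.get("compartment", ""),
                )
            )
        rxns = []
        biomass_id = None
        for r in doc["reactions"]:
            rxn = Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["metabolites"].items()},
                lower_bound=float(r.get("lower_bound", -DEFAULT_BOUND)),
                upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
                gpr=r.get("gene_reaction_rule", "") or "",
                is_exchange=bool(r.get("is_exchange", False))
                or r["id"].startswith("EX_"),
            )
            rxns.append(rxn)
            if float(r.get("objective_coefficient", 0.0)) != 0.0:
                biomass_id = r["id"]
        genes = {g["id"] for g in doc.get("genes", [])}
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"malformed JSON model: {exc!r}") from exc
    if biomass_id is None:
        # fall back to the conventional naming
        for r in rxns:
            if "biomass" in r.id.lower():
                biomass_id = r.id
                break
    if biomass_id is None:
        raise ModelValidationError(
            "no biomass reaction: no reaction has a nonzero "
            "objective_coefficient and none is named like 'biomass'"
        )
    model = MetabolicModel(
        id=doc.get("id", model_id),
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id=biomass_id,
        genes=genes,
    )
    detect_exchanges(model)
    model.validate()
    return model


def _model_to_json(model: MetabolicModel) -> dict:
    def _bound(x: float) -> float:
        return x if math.isfinite(x) else math.copysign(1e6, x)

    mets = []
    for m in model.metabolites:
        entry: dict = {"id": m.id, "name": m.name, "compartment": m.compartment}
        if m.formula is not None:
            entry["formula"] = m.formula
        if m.molar_mass is not None:
            entry["molar_mass"] = m.molar_mass
        mets.append(entry)
    rxns = []
    for r in model.reactions:
        rxns.append(
            {
                "id": r.id,
                "name": r.id,
                "metabolites": dict(sorted(r.stoichiometry.items())),
                "lower_bound": _bound(r.lower_bound),
                "upper_bound": _bound(r.upper_bound),
                "gene_reaction_rule": r.gpr,
                "is_exchange": r.is_exchange,
                "objective_coefficient": (
                    1.0 if r.id == model.biomass_reaction_id else 0.0
                ),
            }
        )
    return {
        "id": model.id,
        "metabolites": mets,
        "reactions": rxns,
        "genes": [{"id": g, "name": g} for g in sorted(model.genes)],
        "compartments": {},
        "version": "1",
    }


# ---------------------------------------------------------------------------
# cobrapy conversion (SBML path + cross-validation in tests)


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy Model (biomass set as the objective)."""
    import cobra

    cb = cobra.Model(model.id)
    cmets = {}
    for m in model.metabolites:
        cm = cobra.Metabolite(
            m.id, formula=m.formula, name=m.name, compartment=m.compartment or "c"
        )
        cmets[m.id] = cm
    cb.add_metabolites(list(cmets.values()))
    crxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        crxns.append(cr)
    cb.add_reactions(crxns)
    for r in model.reactions:
        cr = cb.reactions.get_by_id(r.id)
        cr.add_metabolites({cmets[k]: v for k, v in r.stoichiometry.items()})
        if r.gpr:
            cr.gene_reaction_rule = r.gpr
    cb.objective = model.biomass_reaction_id
    return cb


def from_cobra(cb) -> MetabolicModel:
    """Convert a cobrapy Model; the objective reaction becomes biomass."""
    from cobra.util.solver import linear_reaction_coefficients

    mets = [
        Metabolite(
            id=m.id,
            name=m.name or "",
            formula=m.formula or None,
            compartment=m.compartment or "",
        )
        for m in cb.metabolites
    ]
    boundary_ids = {r.id for r in cb.boundary}
    rxns = [
        Reaction(
            id=r.id,
            stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
            lower_bound=float(r.lower_bound),
            upper_bound=float(r.upper_bound),
            gpr=r.gene_reaction_rule or "",
            is_exchange=r.id in boundary_ids,
        )
        for r in cb.reactions
    ]
    coeffs = linear_reaction_coefficients(cb)
    biomass_id = None
    if coeffs:
        biomass_id = max(coeffs, key=lambda r: abs(coeffs[r])).id
    else:
        for r in cb.reactions:
            if "biomass" in r.id.lower():
                biomass_id = r.id
                break
    if biomass_id is None:
        raise ModelValidationError("model has no objective/biomass reaction")
    model = MetabolicModel(
        id=cb.id or "model",
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id=biomass_id,
        genes={g.id for g in cb.genes},
    )
    detect_exchanges(model)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# public I/O


def _infer_dialect(path: str) -> str:
    lower = str(path).lower()
    if lower.endswith(".json"):
        return "json"
    if lower.endswith((".xml", ".sbml")):
        return "sbml"
    raise ModelFormatError(f"cannot infer dialect from path {path!r}")


def read_model(path, dialect: str | None = None) -> MetabolicModel:
    """Read a metabolic model from JSON (COBRA schema) or SBML L3/FBC.

    Returns a validated :class:`MetabolicModel` with exchange reactions
    flagged.  Parse problems raise :class:`ModelFormatError`; structural
    problems (missing biomass reaction, multi-metabolite exchange) raise
    :class:`ModelValidationError`.
    """
    dialect = dialect or _infer_dialect(path)
    if dialect == "json":
        try:
            with open(path) as fh:
                doc = json.load(fh)
        except (OSError, json.JSONDecodeError) as exc:
            raise ModelFormatError(f"cannot parse JSON model {path}: {exc}") from exc
        if not isinstance(doc, dict):
            raise ModelFormatError(f"{path}: JSON model must be an object")
        import os

        return _json_to_model(doc, os.path.splitext(os.path.basename(path))[0])
    if dialect == "sbml":
        import cobra.io

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cb = cobra.io.read_sbml_model(str(path))
        except ModelValidationError:
            raise
        except Exception as exc:
            raise ModelFormatError(f"cannot parse SBML model {path}: {exc}") from exc
        return from_cobra(cb)
    raise ModelFormatError(f"unknown dialect {dialect!r}")


def write_model(model: MetabolicModel, path, dialect: str | None = None) -> None:
    """Write a model to disk; the inverse of :func:`read_model`.

    The JSON round trip preserves stoichiometry, bounds, GPR strings,
    exchange flags, and molar-mass annotations field for field.
    """
    dialect = dialect or _infer_dialect(path)
    if dialect == "json":
        with open(path, "w") as fh:
            json.dump(_model_to_json(model), fh, indent=1, sort_keys=False)
            fh.write("\n")
        return
    if dialect == "sbml":
        import cobra.io

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cobra.io.write_sbml_model(to_cobra(model), str(path))
        return
    raise ModelFormatError(f"unknown dialect {dialect!r}")
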