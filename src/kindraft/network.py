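"""Metabolic-network container, stoichiometric matrix, and SBML I/O.

The in-memory model is deliberately small: ordered species, reactions with
signed stoichiometry (negative = consumed), compartments, and optional
per-reaction :class:`~kindraft.rate_laws.RateLaw` objects.  SBML Level 2
and Level 3 documents are read; Level 3 Version 2 is written.  Species
flagged ``boundaryCondition`` or ``constant`` are treated as boundary
(externally buffered) and excluded from steady-state balances.
"""
from __future__ import annotations

import copy
import math
import os
import re
from dataclasses import dataclass, field

import libsbml
import numpy as np

from ._sbmlmath import ast_to_sympy, sympy_to_ast
from .errors import MatchError, NetworkValidationError, SBMLReadError
from .rate_laws import LAW_TYPES, RateLaw
from .tables import FluxSet

_LAW_NS = "http://kindraft.readthedocs.io/ratelaw"


@dataclass
class Species:
    id: str
    name: str = ""
    compartment: str = "default"
    boundary: bool = False
    initial_concentration: float | None = None
    annotations: list[tuple[str, str]] = field(default_factory=list)

    def validate(self) -> list[str]:
        problems = []
        if not self.id:
            problems.append("species with empty id")
        if self.initial_concentration is not None and not (
            self.initial_concentration >= 0
        ):
            problems.append(
                f"species {self.id}: negative initial concentration "
                f"{self.initial_concentration}"
            )
        return problems


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    reversible: bool = False
    rate_law: RateLaw | None = None

    @property
    def substrates(self) -> dict[str, float]:
        """Consumed species id -> positive multiplicity."""
        return {s: -n for s, n in self.stoichiometry.items() if n < 0}

    @property
    def products(self) -> dict[str, float]:
        return {s: n for s, n in self.stoichiometry.items() if n > 0}

    def validate(self) -> list[str]:
        problems = []
        if not self.id:
            problems.append("reaction with empty id")
        if not self.stoichiometry:
            problems.append(f"reaction {self.id}: empty stoichiometry")
        for sid, n in self.stoichiometry.items():
            if n == 0:
                problems.append(f"reaction {self.id}: zero coefficient for {sid}")
        return problems


@dataclass
class Compartment:
    id: str
    size: float = 1.0

    def validate(self) -> list[str]:
        if not self.size > 0:
            return [f"compartment {self.id}: non-positive size {self.size}"]
        return []


@dataclass
class StoichMatrix:
    """Dense stoichiometric matrix over internal (non-boundary) species."""

    row_ids: list[str]
    col_ids: list[str]
    entries: np.ndarray

    def dot(self, fluxes: FluxSet | dict[str, float]) -> np.ndarray:
        """S.v with v assembled in column order (missing reactions -> 0)."""
        values = fluxes.values if isinstance(fluxes, FluxSet) else fluxes
        v = np.array([float(values.get(rid, 0.0)) for rid in self.col_ids])
        return self.entries @ v


@dataclass
class MetabolicNetwork:
    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    compartments: list[Compartment] = field(default_factory=list)
    global_parameters: dict[str, float] = field(default_factory=dict)

    # -- lookup ----------------------------------------------------------
    def get_species(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise MatchError(f"no species with id {sid!r}")

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise MatchError(f"no reaction with id {rid!r}")

    def _resolve(self, items, key: str, what: str) -> str:
        by_id = [x for x in items if x.id == key]
        if by_id:
            return by_id[0].id
        by_name = [x for x in items if x.name == key]
        if len(by_name) == 1:
            return by_name[0].id
        if len(by_name) > 1:
            raise MatchError(
                f"{what} name {key!r} is ambiguous: matches ids "
                + ", ".join(x.id for x in by_name)
            )
        raise MatchError(f"no {what} with id or name {key!r}")

    def resolve_species(self, key: str) -> str:
        """Map a table identifier to a species id (id first, then name)."""
        return self._resolve(self.species, key, "species")

    def resolve_reaction(self, key: str) -> str:
        return self._resolve(self.reactions, key, "reaction")

    def internal_species(self) -> list[Species]:
        return [s for s in self.species if not s.boundary]

    # -- validation ------------------------------------------------------
    def validate(self) -> list[str]:
        problems: list[str] = []
        seen: set[str] = set()
        for s in self.species:
            problems += s.validate()
            if s.id in seen:
                problems.append(f"duplicate species id {s.id}")
            seen.add(s.id)
        compartment_ids = {c.id for c in self.compartments}
        for c in self.compartments:
            problems += c.validate()
        if len(compartment_ids) != len(self.compartments):
            problems.append("duplicate compartment ids")
        for s in self.species:
            if self.compartments and s.compartment not in compartment_ids:
                problems.append(
                    f"species {s.id}: unknown compartment {s.compartment!r}"
                )
        species_ids = {s.id for s in self.species}
        rseen: set[str] = set()
        for r in self.reactions:
            problems += r.validate()
            if r.id in rseen:
                problems.append(f"duplicate reaction id {r.id}")
            rseen.add(r.id)
            for sid in r.stoichiometry:
                if sid not in species_ids:
                    problems.append(f"reaction {r.id}: unknown species {sid!r}")
        return problems

    def check_valid(self) -> None:
        problems = self.validate()
        if problems:
            raise NetworkValidationError("; ".join(problems))

    def copy(self) -> "MetabolicNetwork":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# stoichiometric matrix


def stoichiometric_matrix(network: MetabolicNetwork) -> StoichMatrix:
    """S over internal species (rows, document order) x reactions (columns)."""
    rows = [s.id for s in network.internal_species()]
    cols = [r.id for r in network.reactions]
    index = {sid: i for i, sid in enumerate(rows)}
    S = np.zeros((len(rows), len(cols)))
    for j, reaction in enumerate(network.reactions):
        for sid, n in reaction.stoichiometry.items():
            i = index.get(sid)
            if i is not None:
                S[i, j] = n
    return StoichMatrix(rows, cols, S)


def normalize_directionality(
    network: MetabolicNetwork, fluxes: FluxSet
) -> tuple[MetabolicNetwork, FluxSet]:
    """Flip every reaction carrying a negative reference flux.

    Negated stoichiometry with the absolute flux leaves S.v unchanged
    entry-wise; zero-flux reactions keep their stated direction.  The
    returned flux set is keyed by resolved reaction ids.
    """
    out = network.copy()
    new_values: dict[str, float] = {}
    for key, value in fluxes.values.items():
        rid = out.resolve_reaction(key)
        if rid in new_values:
            raise MatchError(f"flux table names reaction {rid} more than once")
        if value < 0:
            reaction = out.get_reaction(rid)
            reaction.stoichiometry = {
                sid: -n for sid, n in reaction.stoichiometry.items()
            }
            new_values[rid] = -value
        else:
            new_values[rid] = value
    return out, FluxSet(new_values, unit=fluxes.unit)


# ---------------------------------------------------------------------------
# SBML reading


def _annotations_from_cvterms(sbase) -> list[tuple[str, str]]:
    result = []
    for i in range(sbase.getNumCVTerms()):
        term = sbase.getCVTerm(i)
        for j in range(term.getNumResources()):
            uri = term.getResourceURI(j)
            parts = uri.rstrip("/").split("/")
            if len(parts) >= 2:
                result.append((parts[-2], parts[-1]))
    return result


def _law_type_from_annotation(kl) -> str | None:
    text = kl.getAnnotationString() or ""
    m = re.search(r'lawType="([a-z_]+)"', text)
    if m and m.group(1) in LAW_TYPES:
        return m.group(1)
    return None


def _read_kinetic_law(kl) -> RateLaw | None:
    if kl is None or kl.getMath() is None:
        return None
    params: dict[str, float] = {}
    for i in range(kl.getNumLocalParameters()):
        p = kl.getLocalParameter(i)
        params[p.getId()] = p.getValue()
    for i in range(kl.getNumParameters()):  # L2 stores them as Parameter
        p = kl.getParameter(i)
        if p.getId() not in params:
            params[p.getId()] = p.getValue()
    expr = ast_to_sympy(kl.getMath())
    law_type = _law_type_from_annotation(kl)
    if law_type is None:
        # fall back on the deterministic parameter-name conventions
        if any(k.startswith("Jref__") for k in params):
            law_type = "linlog"
        elif any(k.startswith("kcatf__") for k in params):
            law_type = "convenience"
        else:
            law_type = "mass_action"
    return RateLaw(law_type, expr, params)


def read_sbml(path: str | os.PathLike) -> MetabolicNetwork:
    """Read an SBML (L2/L3) document into a :class:`MetabolicNetwork`."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        messages = [
            doc.getError(i).getMessage().strip()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise SBMLReadError(f"malformed SBML in {path}: " + " | ".join(messages[:3]))
    model = doc.getModel()
    if model is None:
        raise SBMLReadError(f"{path}: document contains no model")
    for construct, count in (
        ("rules", model.getNumRules()),
        ("events", model.getNumEvents()),
        ("constraints", model.getNumConstraints()),
    ):
        if count:
            raise SBMLReadError(
                f"{path}: unsupported SBML construct: {count} {construct}"
            )

    net = MetabolicNetwork()
    for i in range(model.getNumCompartments()):
        c = model.getCompartment(i)
        size = c.getSize() if c.isSetSize() else 1.0
        if math.isnan(size):
            size = 1.0
        net.compartments.append(Compartment(c.getId(), size))
    for i in range(model.getNumSpecies()):
        s = model.getSpecies(i)
        conc: float | None = None
        if s.isSetInitialConcentration():
            conc = s.getInitialConcentration()
        elif s.isSetInitialAmount():
            size = 1.0
            comp = model.getCompartment(s.getCompartment())
            if comp is not None and comp.isSetSize() and not math.isnan(comp.getSize()):
                size = comp.getSize()
            conc = s.getInitialAmount() / size
        net.species.append(
            Species(
                id=s.getId(),
                name=s.getName() or "",
                compartment=s.getCompartment() or "default",
                boundary=bool(s.getBoundaryCondition() or s.getConstant()),
                initial_concentration=conc,
                annotations=_annotations_from_cvterms(s),
            )
        )
    for i in range(model.getNumReactions()):
        r = model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - (
                ref.getStoichiometry() if not math.isnan(ref.getStoichiometry()) else 1.0
            )
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + (
                ref.getStoichiometry() if not math.isnan(ref.getStoichiometry()) else 1.0
            )
        stoich = {sid: n for sid, n in stoich.items() if n != 0}
        net.reactions.append(
            Reaction(
                id=r.getId(),
                name=r.getName() or "",
                reversible=bool(r.getReversible()),
                stoichiometry=stoich,
                rate_law=_read_kinetic_law(r.getKineticLaw()),
            )
        )
    for i in range(model.getNumParameters()):
        p = model.getParameter(i)
        net.global_parameters[p.getId()] = p.getValue()
    net.check_valid()
    return net


# ---------------------------------------------------------------------------
# SBML writing (Level 3 Version 2)


def write_sbml(network: MetabolicNetwork, path: str | os.PathLike) -> None:
    """Write the network as SBML L3V2; kinetic laws (if any) included."""
    network.check_valid()
    doc = libsbml.SBMLDocument(3, 2)
    model = doc.createModel()
    model.setId("kindraft_model")

    compartments = network.compartments or [Compartment("default", 1.0)]
    for c in compartments:
        sc = model.createCompartment()
        sc.setId(c.id)
        sc.setSize(c.size)
        sc.setConstant(True)
        sc.setSpatialDimensions(3)
    compartment_ids = {c.id for c in compartments}

    meta_counter = 0
    for s in network.species:
        ss = model.createSpecies()
        ss.setId(s.id)
        if s.name:
            ss.setName(s.name)
        ss.setCompartment(s.compartment if s.compartment in compartment_ids
                          else compartments[0].id)
        ss.setBoundaryCondition(bool(s.boundary))
        ss.setConstant(False)
        ss.setHasOnlySubstanceUnits(False)
        if s.initial_concentration is not None:
            ss.setInitialConcentration(float(s.initial_concentration))
        if s.annotations:
            meta_counter += 1
            ss.setMetaId(f"meta_s{meta_counter}")
            for db, acc in s.annotations:
                term = libsbml.CVTerm()
                term.setQualifierType(libsbml.BIOLOGICAL_QUALIFIER)
                term.setBiologicalQualifierType(libsbml.BQB_IS)
                term.addResource(f"http://identifiers.org/{db}/{acc}")
                ss.addCVTerm(term)

    for r in network.reactions:
        sr = model.createReaction()
        sr.setId(r.id)
        if r.name:
            sr.setName(r.name)
        sr.setReversible(bool(r.reversible))
        for sid, n in r.stoichiometry.items():
            ref = sr.createReactant() if n < 0 else sr.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(abs(float(n)))
            ref.setConstant(True)
        if r.rate_law is not None:
            kl = sr.createKineticLaw()
            kl.setMath(sympy_to_ast(r.rate_law.expression))
            for pname, pvalue in r.rate_law.parameters.items():
                lp = kl.createLocalParameter()
                lp.setId(pname)
                lp.setValue(float(pvalue))
            kl.setAnnotation(
                f'<annotation><rateLaw xmlns="{_LAW_NS}" '
                f'lawType="{r.rate_law.law_type}"/></annotation>'
            )

    for pname, pvalue in network.global_parameters.items():
        p = model.createParameter()
        p.setId(pname)
        p.setValue(float(pvalue))
        p.setConstant(True)

    if not libsbml.writeSBMLToFile(doc, os.fspath(path)):
        raise IOError(f"could not write SBML to {path}")


# ---------------------------------------------------------------------------
# structural comparison (round-trip checks, validation reports)


def structural_diff(
    a: MetabolicNetwork, b: MetabolicNetwork, rel_tol: float = 1e-12
) -> list[str]:
    """Human-readable list of structural differences (empty = equal).

    Rate-law expressions are compared numerically at deterministic sample
    points rather than symbolically, so algebraically equivalent trees
    compare equal.
    """

    def close(x: float, y: float) -> bool:
        return math.isclose(x, y, rel_tol=rel_tol, abs_tol=rel_tol)

    diffs: list[str] = []
    if [s.id for s in a.species] != [s.id for s in b.species]:
        diffs.append("species id lists differ")
        return diffs
    for sa, sb in zip(a.species, b.species):
        for attr in ("name", "compartment", "boundary"):
            if getattr(sa, attr) != getattr(sb, attr):
                diffs.append(f"species {sa.id}: {attr} differs")
        ca, cb = sa.initial_concentration, sb.initial_concentration
        if (ca is None) != (cb is None) or (ca is not None and not close(ca, cb)):
            diffs.append(f"species {sa.id}: initial concentration differs")
        if sorted(sa.annotations) != sorted(sb.annotations):
            diffs.append(f"species {sa.id}: annotations differ")
    if [r.id for r in a.reactions] != [r.id for r in b.reactions]:
        diffs.append("reaction id lists differ")
        return diffs
    for ra, rb in zip(a.reactions, b.reactions):
        if ra.reversible != rb.reversible:
            diffs.append(f"reaction {ra.id}: reversibility differs")
        if set(ra.stoichiometry) != set(rb.stoichiometry) or any(
            not close(ra.stoichiometry[k], rb.stoichiometry[k])
            for k in ra.stoichiometry
        ):
            diffs.append(f"reaction {ra.id}: stoichiometry differs")
        la, lb = ra.rate_law, rb.rate_law
        if (la is None) != (lb is None):
            diffs.append(f"reaction {ra.id}: kinetic law presence differs")
        elif la is not None and lb is not None:
            if la.law_type != lb.law_type:
                diffs.append(f"reaction {ra.id}: law type differs")
            if set(la.parameters) != set(lb.parameters) or any(
                not close(la.parameters[k], lb.parameters[k]) for k in la.parameters
            ):
                diffs.append(f"reaction {ra.id}: law parameters differ")
            else:
                symbols = sorted(
                    {str(s) for s in la.expression.free_symbols}
                    | {str(s) for s in lb.expression.free_symbols}
                )
                for k in range(3):
                    point = {
                        name: 0.5 + ((7 * i + 3 * k) % 11) / 7.0
                        for i, name in enumerate(symbols)
                    }
                    va = float(la.expression.subs(point))
                    vb = float(lb.expression.subs(point))
                    if not math.isclose(va, vb, rel_tol=1e-9, abs_tol=1e-9):
                        diffs.append(
                            f"reaction {ra.id}: law expressions disagree numerically"
                        )
                        break
    ca = {c.id: c.size for c in a.compartments}
    cb = {c.id: c.size for c in b.compartments}
    if set(ca) != set(cb) or any(not close(ca[k], cb[k]) for k in ca):
        diffs.append("compartments differ")
    ga, gb = a.global_parameters, b.global_parameters
    if set(ga) != set(gb) or any(not close(ga[k], gb[k]) for k in ga):
        diffs.append("global parameters differ")
    return diffs
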