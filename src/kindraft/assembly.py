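"""Draft-model assembly: inject concentrations and reference fluxes, then
validate the reference steady state.

A draft kinetic model is complete once every species has an initial
concentration, every reaction a rate law, and (for lin-log laws) every
law's ``J_ref``/``c_ref`` anchors match a steady-state flux distribution.
By construction the assembled lin-log model then satisfies
``v(c_0) = J_ref`` exactly, and hence ``S.v(c_0) = 0`` to rounding error —
:func:`validate_reference_state` checks precisely that before the model is
handed to a parameter-estimation tool.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import AssemblyError, MatchError
from .network import MetabolicNetwork, stoichiometric_matrix
from .tables import ConcentrationSet, FluxSet

DEFAULT_CONCENTRATION = 0.0221  # mM; median metabolome fill-in value
RESIDUAL_TOL = 1e-9


@dataclass
class AddMetabolitesReport:
    """Which species received the default value, and which table entries
    matched nothing in the model."""

    defaulted: list[str] = field(default_factory=list)
    assigned: list[str] = field(default_factory=list)
    unmatched: list[str] = field(default_factory=list)


def add_metabolites(
    network: MetabolicNetwork,
    known: ConcentrationSet,
    default_value: float = DEFAULT_CONCENTRATION,
) -> tuple[MetabolicNetwork, AddMetabolitesReport]:
    """Set every species' initial concentration: the known value where the
    table provides one, the default elsewhere.

    Table entries matching no species are reported, not fatal: data files
    routinely list more metabolites than a reduced model retains.
    """
    if default_value < 0:
        raise AssemblyError(f"default concentration must be >= 0, got {default_value}")
    out = network.copy()
    report = AddMetabolitesReport()
    resolved: dict[str, float] = {}
    for key, value in known.items():
        try:
            sid = out.resolve_species(key)
        except MatchError:
            report.unmatched.append(key)
            continue
        resolved[sid] = float(value)
    for species in out.species:
        if species.id in resolved:
            species.initial_concentration = resolved[species.id]
            report.assigned.append(species.id)
        else:
            species.initial_concentration = float(default_value)
            report.defaulted.append(species.id)
    return out, report


def set_fluxes(network: MetabolicNetwork, fluxes: FluxSet) -> MetabolicNetwork:
    """Anchor every lin-log law at the reference state: ``J_ref`` becomes the
    reaction's reference flux and each ``c_ref`` the species' current
    initial concentration.  Non-lin-log laws are skipped with a warning."""
    out = network.copy()
    resolved: dict[str, float] = {}
    for key, value in fluxes.items():
        try:
            resolved[out.resolve_reaction(key)] = float(value)
        except MatchError:
            continue  # extra table entries are harmless
    conc = {
        s.id: s.initial_concentration
        for s in out.species
        if s.initial_concentration is not None
    }
    skipped = []
    for reaction in out.reactions:
        law = reaction.rate_law
        if law is None:
            raise AssemblyError(
                f"reaction {reaction.id} carries no kinetic law; run "
                "translate_kinetics first"
            )
        if law.law_type != "linlog":
            skipped.append(reaction.id)
            continue
        if reaction.id not in resolved:
            raise AssemblyError(
                f"flux set provides no reference flux for lin-log reaction "
                f"{reaction.id}"
            )
        law.parameters[f"Jref__{reaction.id}"] = resolved[reaction.id]
        for sid in reaction.stoichiometry:
            cref_name = f"cref__{reaction.id}__{sid}"
            if cref_name in law.parameters and sid in conc and conc[sid] > 0:
                law.parameters[cref_name] = conc[sid]
    if skipped:
        warnings.warn(
            "set_fluxes skipped non-lin-log reactions: " + ", ".join(skipped)
        )
    return out


def evaluate_rates(
    network: MetabolicNetwork, concentrations: ConcentrationSet | None = None
) -> FluxSet:
    """Evaluate every reaction's rate law at the given (or the stored
    initial) concentrations."""
    if concentrations is not None:
        conc = dict(concentrations.items())
    else:
        conc = {
            s.id: s.initial_concentration
            for s in network.species
            if s.initial_concentration is not None
        }
    rates: dict[str, float] = {}
    for reaction in network.reactions:
        if reaction.rate_law is None:
            raise AssemblyError(f"reaction {reaction.id} carries no kinetic law")
        rates[reaction.id] = reaction.rate_law.evaluate(conc, reaction.id)
    return FluxSet(rates)


@dataclass
class ValidationReport:
    per_reaction: dict[str, tuple[float, float | None, float | None]]
    steady_state_residual: dict[str, float]
    max_residual: float
    tolerance: float
    passed: bool

    def summary(self) -> str:
        lines = [
            f"reference-state validation: {'PASSED' if self.passed else 'FAILED'}",
            f"max |S.v(c0)| residual: {self.max_residual:.3e} "
            f"(tolerance {self.tolerance:.1e})",
        ]
        worst = sorted(
            self.steady_state_residual.items(), key=lambda kv: -kv[1]
        )[:5]
        for sid, r in worst:
            lines.append(f"  |d{sid}/dt| = {r:.3e}")
        return "\n".join(lines)


def validate_reference_state(
    network: MetabolicNetwork,
    tolerance: float = RESIDUAL_TOL,
    reference_fluxes: FluxSet | None = None,
) -> ValidationReport:
    """Evaluate all rates at the initial concentrations and check that the
    internal species balances close (max |S.v| <= tolerance).

    When ``reference_fluxes`` is given, the report also lists each
    reaction's deviation from its reference flux.
    """
    gaps = [
        s.id for s in network.species if s.initial_concentration is None
    ]
    if gaps:
        raise AssemblyError(
            "species without initial concentrations: " + ", ".join(gaps)
        )
    lawless = [r.id for r in network.reactions if r.rate_law is None]
    if lawless:
        raise AssemblyError("reactions without kinetic laws: " + ", ".join(lawless))
    rates = evaluate_rates(network)
    per_reaction: dict[str, tuple[float, float | None, float | None]] = {}
    for rid, rate in rates.items():
        ref = None
        if reference_fluxes is not None and rid in reference_fluxes:
            ref = float(reference_fluxes[rid])
        per_reaction[rid] = (rate, ref, abs(rate - ref) if ref is not None else None)
    S = stoichiometric_matrix(network)
    residual = np.abs(S.dot(rates))
    residual_map = {sid: float(r) for sid, r in zip(S.row_ids, residual)}
    max_residual = float(residual.max()) if residual.size else 0.0
    return ValidationReport(
        per_reaction=per_reaction,
        steady_state_residual=residual_map,
        max_residual=max_residual,
        tolerance=tolerance,
        passed=max_residual <= tolerance,
    )
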