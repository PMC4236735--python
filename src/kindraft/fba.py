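"""Flux balance analysis: reference flux distributions by linear programming.

The LP maximizes (or minimizes) the flux through one objective reaction
subject to steady state (S.v = 0 over internal species), per-reaction
bounds, and equality ("fixed rate") constraints such as a measured glucose
uptake.  Fixed fluxes are encoded as equal lower and upper bounds.  The
solver is scipy's deterministic HiGHS backend, and every optimal solution
is independently re-checked for feasibility before it is returned.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .errors import FBAError
from .network import MetabolicNetwork, normalize_directionality, stoichiometric_matrix
from .tables import FluxSet

FEASIBILITY_TOL = 1e-8


@dataclass
class FBAProblem:
    objective_reaction: str
    sense: str = "maximize"
    fixed_fluxes: dict[str, float] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    default_bound: float = 1000.0

    def validate(self, network: MetabolicNetwork) -> None:
        if self.sense not in ("maximize", "minimize"):
            raise FBAError(f"sense must be maximize or minimize, got {self.sense!r}")
        network.get_reaction(network.resolve_reaction(self.objective_reaction))
        for rid, (lo, hi) in self.bounds.items():
            network.resolve_reaction(rid)
            if lo > hi:
                raise FBAError(f"bounds for {rid}: lower {lo} > upper {hi}")
        for rid, value in self.fixed_fluxes.items():
            network.resolve_reaction(rid)
            if rid in self.bounds:
                lo, hi = self.bounds[rid]
                if not (lo <= value <= hi):
                    raise FBAError(
                        f"fixed flux {value} for {rid} outside bounds ({lo}, {hi})"
                    )


@dataclass
class FBASolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float | None = None
    fluxes: FluxSet | None = None


def _assemble_bounds(
    network: MetabolicNetwork, problem: FBAProblem
) -> list[tuple[float, float]]:
    M = problem.default_bound
    explicit = {network.resolve_reaction(k): v for k, v in problem.bounds.items()}
    fixed = {network.resolve_reaction(k): v for k, v in problem.fixed_fluxes.items()}
    out = []
    for reaction in network.reactions:
        lo, hi = explicit.get(
            reaction.id, (-M, M) if reaction.reversible else (0.0, M)
        )
        if reaction.id in fixed:
            lo = hi = fixed[reaction.id]
        out.append((lo, hi))
    return out


def check_feasibility(
    network: MetabolicNetwork,
    fluxes: FluxSet,
    problem: FBAProblem | None = None,
    tol: float = FEASIBILITY_TOL,
) -> float:
    """Return max |S.v| over internal species; raise if constraints break.

    Used both to re-check solver output and to vet fixture flux sets.
    """
    S = stoichiometric_matrix(network)
    residual = S.dot(fluxes)
    worst = float(np.max(np.abs(residual))) if residual.size else 0.0
    if worst > tol:
        raise FBAError(f"steady-state violation: max |S.v| = {worst:g} > {tol:g}")
    if problem is not None:
        for (lo, hi), reaction in zip(_assemble_bounds(network, problem),
                                      network.reactions):
            v = fluxes.values.get(reaction.id, 0.0)
            if v < lo - tol or v > hi + tol:
                raise FBAError(
                    f"flux {v} for {reaction.id} violates bounds ({lo}, {hi})"
                )
    return worst


def solve_fba(network: MetabolicNetwork, problem: FBAProblem) -> FBASolution:
    """Solve the FBA linear program; deterministic for fixed inputs."""
    problem.validate(network)
    S = stoichiometric_matrix(network)
    n = len(S.col_ids)
    obj_id = network.resolve_reaction(problem.objective_reaction)
    c = np.zeros(n)
    j = S.col_ids.index(obj_id)
    c[j] = -1.0 if problem.sense == "maximize" else 1.0
    bounds = _assemble_bounds(network, problem)
    res = linprog(
        c,
        A_eq=S.entries if S.entries.size else None,
        b_eq=np.zeros(len(S.row_ids)) if S.entries.size else None,
        bounds=bounds,
        method="highs",
    )
    if res.status == 2:
        return FBASolution(status="infeasible")
    if res.status == 3:
        return FBASolution(status="unbounded")
    if res.status != 0:
        raise FBAError(f"LP solver failure: {res.message}")
    fluxes = FluxSet({rid: float(v) for rid, v in zip(S.col_ids, res.x)})
    check_feasibility(network, fluxes, problem)
    objective = float(res.x[j])
    return FBASolution(status="optimal", objective_value=objective, fluxes=fluxes)


def reference_flux_workflow(
    network: MetabolicNetwork, problem: FBAProblem
) -> tuple[MetabolicNetwork, FluxSet]:
    """Solve FBA, then flip negative-flux reactions so all fluxes are >= 0."""
    solution = solve_fba(network, problem)
    if solution.status != "optimal":
        raise FBAError(f"FBA did not reach an optimum: status={solution.status}")
    return normalize_directionality(network, solution.fluxes)
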