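"""Synthetic networks with guaranteed steady-state flux distributions.

Every generator returns a ``(network, fluxes, concentrations)`` triple in
which ``S.v = 0`` holds over internal species *by construction*: random
networks are built flux-first (sample a backbone route plus shortcut
routes, then emit the reactions those routes use), so no rejection
sampling is needed and every fixture is FBA-feasible.  Concentrations are
drawn log-uniformly over 0.001–10 mM, mimicking the heavy-tailed spread of
measured metabolomes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FixtureError
from .network import Compartment, MetabolicNetwork, Reaction, Species
from .tables import ConcentrationSet, FluxSet

_CONC_RANGE = (0.001, 10.0)  # mM


@dataclass
class FixtureSpec:
    """Parameters of a random consistent network."""

    n_species: int = 8
    n_reactions: int = 12
    seed: int = 0
    flux_scale: float = 1.0
    kind: str = "random"

    def validate(self) -> None:
        if self.n_species < 2:
            raise FixtureError(f"need at least 2 species, got {self.n_species}")
        if self.n_reactions < self.n_species + 1:
            raise FixtureError(
                f"{self.n_reactions} reactions cannot connect "
                f"{self.n_species} species (need at least "
                f"{self.n_species + 1})"
            )
        if not self.flux_scale > 0:
            raise FixtureError("flux_scale must be positive")


def _network(species_ids, stoich_by_reaction, compartment="cell"):
    net = MetabolicNetwork(compartments=[Compartment(compartment, 1.0)])
    for sid in species_ids:
        net.species.append(Species(id=sid, compartment=compartment))
    for rid, stoich in stoich_by_reaction:
        net.reactions.append(Reaction(id=rid, stoichiometry=dict(stoich)))
    net.check_valid()
    return net


def toy_linear_chain(
    n: int = 3, flux: float = 1.0
) -> tuple[MetabolicNetwork, FluxSet, ConcentrationSet]:
    """Linear pathway X1 -> ... -> Xn with uptake and excretion, all
    reactions carrying the same flux; concentrations all 1.0 mM."""
    if n < 2:
        raise FixtureError(f"chain needs n >= 2 species, got {n}")
    if not flux > 0:
        raise FixtureError("flux must be positive")
    species = [f"X{i}" for i in range(1, n + 1)]
    reactions = [("R_in", {"X1": 1.0})]
    for i in range(1, n):
        reactions.append((f"R{i}", {f"X{i}": -1.0, f"X{i+1}": 1.0}))
    reactions.append(("R_out", {f"X{n}": -1.0}))
    net = _network(species, reactions)
    fluxes = FluxSet({rid: float(flux) for rid, _ in reactions})
    conc = ConcentrationSet({sid: 1.0 for sid in species})
    return net, fluxes, conc


def toy_branched() -> tuple[MetabolicNetwork, FluxSet, ConcentrationSet]:
    """Five-species network with one branch point: uptake 2 into M splits
    1/1 towards X and Y, each continuing to a product that is excreted."""
    species = ["M", "X", "Y", "P", "Q"]
    reactions = [
        ("R1", {"M": 1.0}),                 # uptake, flux 2
        ("R2", {"M": -1.0, "X": 1.0}),      # branch 1, flux 1
        ("R3", {"M": -1.0, "Y": 1.0}),      # branch 2, flux 1
        ("R4", {"X": -1.0, "P": 1.0}),
        ("R5", {"Y": -1.0, "Q": 1.0}),
        ("R6", {"P": -1.0}),
        ("R7", {"Q": -1.0}),
    ]
    net = _network(species, reactions)
    fluxes = FluxSet(
        {"R1": 2.0, "R2": 1.0, "R3": 1.0, "R4": 1.0, "R5": 1.0,
         "R6": 1.0, "R7": 1.0}
    )
    conc = ConcentrationSet({sid: 1.0 for sid in species})
    return net, fluxes, conc


def random_consistent_network(
    spec: FixtureSpec,
) -> tuple[MetabolicNetwork, FluxSet, ConcentrationSet]:
    """Random unimolecular network admitting a strictly positive steady
    state, deterministic for a given seed.

    A backbone route (uptake -> a random permutation of all species ->
    excretion) guarantees connectivity; extra reactions are shortcuts
    between backbone positions, and each shortcut adds its flux to the
    backbone segments upstream and downstream so that every species stays
    balanced.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_species
    order = rng.permutation(n)
    species = [f"S{i+1}" for i in range(n)]
    chain = [species[i] for i in order]

    # backbone: R_in -> chain[0] -> ... -> chain[-1] -> R_out
    backbone_edges: list[tuple[str | None, str | None]] = [(None, chain[0])]
    backbone_edges += [(chain[i], chain[i + 1]) for i in range(n - 1)]
    backbone_edges.append((chain[-1], None))
    base_flux = spec.flux_scale * float(rng.uniform(0.5, 2.0))
    edge_flux: dict[tuple[str | None, str | None], float] = {
        e: base_flux for e in backbone_edges
    }

    n_extra = spec.n_reactions - len(backbone_edges)
    existing = set(backbone_edges)
    attempts = 0
    while n_extra > 0 and attempts < 50 * spec.n_reactions:
        attempts += 1
        i, j = sorted(rng.choice(n, size=2, replace=False))
        edge = (chain[i], chain[j])
        if edge in existing:
            continue
        shortcut_flux = spec.flux_scale * float(rng.uniform(0.1, 1.0))
        # reroute: extra inflow up to chain[i], shortcut, extra outflow
        # from chain[j] on — every intermediate balance is untouched
        for k in range(i + 1):
            edge_flux[backbone_edges[k]] += shortcut_flux
        for k in range(j + 1, n + 1):
            edge_flux[backbone_edges[k]] += shortcut_flux
        edge_flux[edge] = shortcut_flux
        existing.add(edge)
        n_extra -= 1
    if n_extra > 0:
        raise FixtureError(
            f"could not place {spec.n_reactions} distinct reactions on "
            f"{n} species"
        )

    reactions = []
    k = 0
    for edge in backbone_edges + [e for e in edge_flux if e not in backbone_edges]:
        src, dst = edge
        k += 1
        if src is None:
            rid, stoich = "R_in", {dst: 1.0}
        elif dst is None:
            rid, stoich = "R_out", {src: -1.0}
        else:
            rid, stoich = f"R{k}", {src: -1.0, dst: 1.0}
        reactions.append((rid, stoich))
    net = _network(species, reactions)
    fluxes = FluxSet(
        {rid: edge_flux[edge]
         for (rid, _), edge in zip(
             reactions,
             backbone_edges + [e for e in edge_flux if e not in backbone_edges])}
    )
    lo, hi = np.log(_CONC_RANGE[0]), np.log(_CONC_RANGE[1])
    conc = ConcentrationSet(
        {sid: float(np.exp(rng.uniform(lo, hi))) for sid in species}
    )
    return net, fluxes, conc
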