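"""Network reduction by flux-proportional metabolite elimination.

Reducing a stoichiometric network before kinetic modeling means removing
selected internal metabolites while keeping the remaining species' mass
balances — and a consistent flux distribution — intact.  Metabolites are
eliminated one at a time, in the order given.  For a species *m* with
producers *p* (coefficient ``n_pm > 0``, flux ``v_p``) and consumers *c*
(``n_cm < 0``, flux ``v_c``) and total throughput ``T = sum_p n_pm v_p``,
each producer/consumer pair is replaced by a lumped reaction

    L_pc = (1/n_pm) R_p + (1/|n_cm|) R_c       (m cancels exactly)

carrying flux ``v(L_pc) = n_pm v_p |n_cm| v_c / T``.  Provided *m* was at
steady state, the lumps reproduce every retained species' net production
exactly, so ``S_red . v_red = 0`` is preserved to rounding error.  Which
metabolites to remove is the modeler's choice; the algorithm only refuses
degenerate cases (zero throughput with active reactions, hub metabolites
whose elimination would explode the reaction count).
"""
from __future__ import annotations

import os
import tempfile
import zipfile
from dataclasses import dataclass, field

import numpy as np

from .errors import ReductionError
from .network import (
    MetabolicNetwork,
    Reaction,
    read_sbml,
    stoichiometric_matrix,
    write_sbml,
)
from .tables import FluxSet, read_value_table, write_value_table

_ZERO = 1e-12
RESIDUAL_TOL = 1e-9
MODEL_MEMBER = "reduced_model.xml"
FLUX_MEMBER = "reduced_fluxes.tsv"


@dataclass
class ReductionResult:
    reduced_network: MetabolicNetwork
    reduced_fluxes: FluxSet
    lump_map: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    def max_residual(self) -> float:
        S = stoichiometric_matrix(self.reduced_network)
        r = S.dot(self.reduced_fluxes)
        return float(np.max(np.abs(r))) if r.size else 0.0

    def check_valid(self) -> None:
        worst = self.max_residual()
        if worst > RESIDUAL_TOL:
            raise ReductionError(
                f"reduced network violates steady state: max |S.v| = {worst:g}"
            )
        for rid, v in self.reduced_fluxes.items():
            if v < 0:
                raise ReductionError(f"negative reduced flux for {rid}: {v}")


def _combine(
    stoich_p: dict[str, float], wp: float, stoich_c: dict[str, float], wc: float,
    drop: str,
) -> dict[str, float]:
    out: dict[str, float] = {}
    for sid, n in stoich_p.items():
        out[sid] = out.get(sid, 0.0) + n * wp
    for sid, n in stoich_c.items():
        out[sid] = out.get(sid, 0.0) + n * wc
    out.pop(drop, None)
    return {sid: n for sid, n in out.items() if abs(n) > _ZERO}


def reduce_network(
    network: MetabolicNetwork,
    fluxes: FluxSet,
    remove: list[str],
    pair_cap: int = 200,
) -> ReductionResult:
    """Eliminate the given internal species, in order, by flux-proportional
    lumping; returns the reduced network, its flux distribution, and a
    provenance map for every lumped reaction.

    Requires a direction-normalized flux set (all values >= 0) covering
    every reaction, with S.v = 0 on the internal species.
    """
    flux: dict[str, float] = {}
    for key, value in fluxes.values.items():
        rid = network.resolve_reaction(key)
        flux[rid] = float(value)
    missing = [r.id for r in network.reactions if r.id not in flux]
    if missing:
        raise ReductionError(
            "flux set does not cover reaction(s): " + ", ".join(missing)
        )
    negative = [rid for rid, v in flux.items() if v < 0]
    if negative:
        raise ReductionError(
            "negative reference fluxes for "
            + ", ".join(negative)
            + "; run normalize_directionality first"
        )
    removal_ids = []
    internal = {s.id for s in network.internal_species()}
    for key in remove:
        sid = network.resolve_species(key)
        if sid not in internal:
            raise ReductionError(f"species {sid!r} is a boundary species")
        removal_ids.append(sid)

    net = network.copy()
    # provenance: current reaction id -> [(original id, weight)]
    provenance: dict[str, list[tuple[str, float]]] = {
        r.id: [(r.id, 1.0)] for r in net.reactions
    }
    reactions: dict[str, dict[str, float]] = {
        r.id: dict(r.stoichiometry) for r in net.reactions
    }
    order: list[str] = [r.id for r in net.reactions]
    originals = {r.id for r in net.reactions}

    for m in removal_ids:
        if not any(m == s.id for s in net.species):
            raise ReductionError(f"species {m!r} already removed")
        incident = [rid for rid in order if m in reactions[rid]]
        producers = [(rid, reactions[rid][m]) for rid in incident
                     if reactions[rid][m] > 0]
        consumers = [(rid, -reactions[rid][m]) for rid in incident
                     if reactions[rid][m] < 0]
        T_p = sum(n * flux[rid] for rid, n in producers)
        T_c = sum(n * flux[rid] for rid, n in consumers)
        if T_p <= _ZERO or T_c <= _ZERO:
            if all(flux[rid] <= _ZERO for rid in incident):
                # dead branch: drop the species and its zero-flux reactions
                for rid in incident:
                    order.remove(rid)
                    del reactions[rid], flux[rid], provenance[rid]
                net.species = [s for s in net.species if s.id != m]
                continue
            raise ReductionError(
                f"species {m!r} has zero reference throughput but active "
                "reactions; lumping weights are undefined"
            )
        T = T_p
        if abs(T_p - T_c) > max(1.0, T) * 1e-6:
            raise ReductionError(
                f"species {m!r} is not at steady state "
                f"(production {T_p:g} vs consumption {T_c:g})"
            )
        active_p = [(rid, n) for rid, n in producers if flux[rid] > _ZERO]
        active_c = [(rid, n) for rid, n in consumers if flux[rid] > _ZERO]
        if len(active_p) * len(active_c) > pair_cap:
            raise ReductionError(
                f"eliminating {m!r} would create "
                f"{len(active_p) * len(active_c)} lumped reactions "
                f"(cap {pair_cap}); removing this hub metabolite is inadvisable"
            )
        new_lumps: dict[tuple, tuple[str, dict[str, float], float,
                                     dict[str, float]]] = {}
        for p, n_p in active_p:
            for c, n_c in active_c:
                wp, wc = 1.0 / n_p, 1.0 / n_c
                stoich = _combine(reactions[p], wp, reactions[c], wc, drop=m)
                v_l = n_p * flux[p] * n_c * flux[c] / T
                if v_l <= _ZERO:
                    continue
                prov: dict[str, float] = {}
                for orig, w in provenance[p]:
                    prov[orig] = prov.get(orig, 0.0) + w * wp
                for orig, w in provenance[c]:
                    prov[orig] = prov.get(orig, 0.0) + w * wc
                key = tuple(sorted((sid, round(n, 12)) for sid, n in stoich.items()))
                if key in new_lumps:
                    # identical stoichiometry: merge by flux addition, with
                    # flux-weighted provenance so weight sums stay exact
                    lid, lstoich, lflux, lprov = new_lumps[key]
                    total = lflux + v_l
                    merged = {
                        o: (lprov.get(o, 0.0) * lflux + prov.get(o, 0.0) * v_l)
                        / total
                        for o in set(lprov) | set(prov)
                    }
                    new_lumps[key] = (lid, lstoich, total, merged)
                else:
                    new_lumps[key] = (f"lump__{p}__{c}", stoich, v_l, prov)
        if not new_lumps:
            raise ReductionError(
                f"eliminating {m!r} leaves no lumped reactions; its producers "
                "or consumers all carry zero flux"
            )
        for rid in incident:
            order.remove(rid)
            del reactions[rid], flux[rid], provenance[rid]
        for lid, stoich, v_l, prov in new_lumps.values():
            if lid in reactions:
                raise ReductionError(f"lump id collision: {lid}")
            if stoich:
                order.append(lid)
                reactions[lid] = stoich
                flux[lid] = v_l
                provenance[lid] = sorted(prov.items())
            # an empty lump (pure pass-through, e.g. source->sink) vanishes
        net.species = [s for s in net.species if s.id != m]

    net.reactions = [
        Reaction(
            id=rid,
            stoichiometry=reactions[rid],
            name=net.get_reaction(rid).name if rid in originals else "",
            reversible=net.get_reaction(rid).reversible if rid in originals
            else False,
        )
        if rid in originals
        else Reaction(id=rid, stoichiometry=reactions[rid], reversible=False)
        for rid in order
    ]
    lump_map = {
        rid: list(provenance[rid])
        for rid in order
        if provenance[rid] != [(rid, 1.0)]
    }
    result = ReductionResult(net, FluxSet({rid: flux[rid] for rid in order}),
                             lump_map)
    result.reduced_network.check_valid()
    result.check_valid()
    return result


def write_reduction_archive(result: ReductionResult, path: str | os.PathLike) -> None:
    """Write the reduction output as a zip archive with exactly two members:
    the reduced SBML model and the reduced flux table."""
    result.check_valid()
    with tempfile.TemporaryDirectory() as tmp:
        model_path = os.path.join(tmp, MODEL_MEMBER)
        flux_path = os.path.join(tmp, FLUX_MEMBER)
        write_sbml(result.reduced_network, model_path)
        write_value_table(result.reduced_fluxes, flux_path)
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            for member, src in ((MODEL_MEMBER, model_path), (FLUX_MEMBER, flux_path)):
                # fixed timestamp so identical inputs give identical archives
                info = zipfile.ZipInfo(member, date_time=(1980, 1, 1, 0, 0, 0))
                info.compress_type = zipfile.ZIP_DEFLATED
                with open(src, "rb") as fh:
                    zf.writestr(info, fh.read())


def read_reduction_archive(
    path: str | os.PathLike,
) -> tuple[MetabolicNetwork, FluxSet]:
    """Read back the two members of a reduction archive."""
    with zipfile.ZipFile(path) as zf, tempfile.TemporaryDirectory() as tmp:
        names = zf.namelist()
        if sorted(names) != sorted([MODEL_MEMBER, FLUX_MEMBER]):
            raise ReductionError(
                f"archive must contain exactly {MODEL_MEMBER} and {FLUX_MEMBER}, "
                f"found: {names}"
            )
        zf.extractall(tmp)
        net = read_sbml(os.path.join(tmp, MODEL_MEMBER))
        fluxes = read_value_table(os.path.join(tmp, FLUX_MEMBER), kind="flux")
    return net, fluxes
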