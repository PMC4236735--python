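"""Approximate kinetic rate laws: mass action, lin-log, convenience.

Turning a stoichiometric network into an ODE model requires a rate
expression for every reaction.  Before any parameter has been estimated,
three canonical approximate families are the standard scaffold choices:

* **mass action** — ``v = k_f * prod_s c_s^{|n_s|}``, minus the analogous
  reverse term for reversible reactions.  An irreversible source reaction
  (no substrates) degenerates to the zeroth-order rate ``v = k_f``.
* **lin-log** — ``v = J_ref * (1 + sum_j eps_j * ln(c_j / c_ref_j))`` over
  every species *j* participating in the reaction.  At the reference state
  (``c = c_ref``) the rate is exactly ``J_ref``, which is what makes this
  family convenient for anchoring a draft model to a flux distribution.
* **convenience kinetics** — a saturable, generalized reversible law with a
  half-saturation constant per participating species; it reduces to
  Michaelis-Menten for a unimolecular irreversible reaction.

Initialization follows the scaffolding convention: every kinetic parameter
and compartment size starts at 1.0, except the lin-log elasticities, which
start at the negative of the corresponding stoichiometric coefficient
(``eps = -n``), giving substrates positive and products negative control of
the rate around the reference state.

Parameters are named deterministically (``eps__<reaction>__<species>`` and
the like) and stored as reaction-local SBML parameters on export.
"""
from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping

import sympy

from .errors import AssemblyError, LogDomainError, RateLawError

if TYPE_CHECKING:  # pragma: no cover
    from .network import MetabolicNetwork, Reaction

LAW_TYPES = ("mass_action", "linlog", "convenience")

MASS_ACTION = "mass_action"
LINLOG = "linlog"
CONVENIENCE = "convenience"


@dataclass
class RateLaw:
    """A symbolic rate expression plus its (named) parameter values.

    ``expression`` is a sympy expression over species symbols (by species
    id) and parameter symbols; ``parameters`` maps every parameter symbol
    name to its current numeric value.
    """

    law_type: str
    expression: sympy.Expr
    parameters: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.law_type not in LAW_TYPES:
            raise RateLawError(
                f"unknown law type {self.law_type!r}; supported: "
                + ", ".join(LAW_TYPES)
            )
        free = {str(s) for s in self.expression.free_symbols}
        undeclared_ok = free - set(self.parameters)  # species symbols
        for name, value in self.parameters.items():
            if not math.isfinite(value):
                raise RateLawError(f"parameter {name} has non-finite value {value}")
        self.species_symbols = sorted(undeclared_ok)

    def evaluate(
        self, concentrations: Mapping[str, float], reaction_id: str = ""
    ) -> float:
        """Numerically evaluate the rate at the given concentrations.

        Raises :class:`LogDomainError` if a logarithm argument is not
        strictly positive, and :class:`AssemblyError` if a species symbol
        has no concentration.
        """
        # one single-pass substitution: partial substitution would let
        # sympy distribute numeric factors over sums, spoiling the exact
        # cancellation of log terms at the reference state
        subs = {
            sympy.Symbol(k): sympy.Float(v, precision=53)
            for k, v in self.parameters.items()
        }
        for sym in self.expression.free_symbols:
            if sym in subs:
                continue
            name = str(sym)
            if name not in concentrations:
                where = f" in reaction {reaction_id}" if reaction_id else ""
                raise AssemblyError(f"no concentration for species {name!r}{where}")
            subs[sym] = sympy.Float(float(concentrations[name]), precision=53)
        for lognode in self.expression.atoms(sympy.log):
            arg = float(lognode.args[0].xreplace(subs))
            if arg <= 0.0:
                bad = ", ".join(
                    sorted(
                        str(s)
                        for s in lognode.args[0].free_symbols
                        if str(s) not in self.parameters
                    )
                )
                where = f" in reaction {reaction_id}" if reaction_id else ""
                raise LogDomainError(
                    f"logarithm of non-positive quantity (species {bad}){where}"
                )
        value = float(self.expression.xreplace(subs))
        if not math.isfinite(value):
            where = f" in reaction {reaction_id}" if reaction_id else ""
            raise AssemblyError(f"rate evaluated to non-finite value{where}")
        return value


def _split(reaction: "Reaction"):
    substrates = {s: -n for s, n in reaction.stoichiometry.items() if n < 0}
    products = {s: n for s, n in reaction.stoichiometry.items() if n > 0}
    return substrates, products


def make_mass_action(reaction: "Reaction") -> RateLaw:
    """Elementary mass-action law; all rate constants start at 1.0."""
    substrates, products = _split(reaction)
    rid = reaction.id
    kf = sympy.Symbol(f"kf__{rid}")
    params = {f"kf__{rid}": 1.0}
    fwd = kf * sympy.Mul(
        *(sympy.Symbol(s) ** n for s, n in sorted(substrates.items()))
    )
    expr = fwd
    if reaction.reversible:
        kr = sympy.Symbol(f"kr__{rid}")
        params[f"kr__{rid}"] = 1.0
        expr = fwd - kr * sympy.Mul(
            *(sympy.Symbol(p) ** n for p, n in sorted(products.items()))
        )
    return RateLaw(MASS_ACTION, expr, params)


def make_linlog(reaction: "Reaction") -> RateLaw:
    """Lin-log law with elasticities set to ``-n`` and J_ref, c_ref at 1.0.

    J_ref and the per-species reference concentrations are placeholders
    until the flux- and concentration-injection steps overwrite them.
    """
    rid = reaction.id
    if not reaction.stoichiometry:
        raise RateLawError(f"reaction {rid} has no participants")
    jref_name = f"Jref__{rid}"
    params: dict[str, float] = {jref_name: 1.0}
    terms = []
    for sid, n in sorted(reaction.stoichiometry.items()):
        eps_name = f"eps__{rid}__{sid}"
        cref_name = f"cref__{rid}__{sid}"
        params[eps_name] = -float(n)
        params[cref_name] = 1.0
        # ln(c) - ln(c_ref) rather than ln(c/c_ref): the two log terms
        # cancel exactly in floating point at the reference state, so the
        # assembled draft reproduces J_ref bit-for-bit
        terms.append(
            sympy.Symbol(eps_name)
            * (sympy.log(sympy.Symbol(sid)) - sympy.log(sympy.Symbol(cref_name)))
        )
    expr = sympy.Symbol(jref_name) * (1 + sympy.Add(*terms))
    return RateLaw(LINLOG, expr, params)


def make_convenience(reaction: "Reaction") -> RateLaw:
    """Convenience-kinetics law with all parameters initialized to 1.0."""
    substrates, products = _split(reaction)
    rid = reaction.id
    E = sympy.Symbol(f"E__{rid}")
    kcatf = sympy.Symbol(f"kcatf__{rid}")
    params = {f"E__{rid}": 1.0, f"kcatf__{rid}": 1.0}

    def saturation(side: dict[str, float]):
        num_factors, den_factors = [], []
        for sid, n in sorted(side.items()):
            km_name = f"Km__{rid}__{sid}"
            params[km_name] = 1.0
            ratio = sympy.Symbol(sid) / sympy.Symbol(km_name)
            num_factors.append(ratio ** n)
            den_factors.append(
                sympy.Add(*(ratio ** m for m in range(int(round(n)) + 1)))
            )
        return sympy.Mul(*num_factors), sympy.Mul(*den_factors)

    num_s, den_s = saturation(substrates)
    numerator = kcatf * num_s
    denominator = den_s
    if reaction.reversible:
        kcatr = sympy.Symbol(f"kcatr__{rid}")
        params[f"kcatr__{rid}"] = 1.0
        num_p, den_p = saturation(products)
        numerator = numerator - kcatr * num_p
        denominator = den_s + den_p - 1
    expr = E * numerator / denominator
    return RateLaw(CONVENIENCE, expr, params)


_MAKERS = {
    MASS_ACTION: make_mass_action,
    LINLOG: make_linlog,
    CONVENIENCE: make_convenience,
}


def make_rate_law(reaction: "Reaction", law_type: str) -> RateLaw:
    try:
        maker = _MAKERS[law_type]
    except KeyError:
        raise RateLawError(
            f"unknown law type {law_type!r}; supported: " + ", ".join(LAW_TYPES)
        ) from None
    return maker(reaction)


def translate_kinetics(
    network: "MetabolicNetwork", law_type: str, force: bool = False
) -> "MetabolicNetwork":
    """Assign a rate law of one family to every reaction of a copy of the
    network, and set every compartment size to 1.0.

    Refuses to overwrite existing kinetic laws unless ``force`` is set.
    """
    if law_type not in _MAKERS:
        raise RateLawError(
            f"unknown law type {law_type!r}; supported: " + ", ".join(LAW_TYPES)
        )
    existing = [r.id for r in network.reactions if r.rate_law is not None]
    if existing and not force:
        raise RateLawError(
            "network already carries kinetic laws on: "
            + ", ".join(existing)
            + " (pass force=True to overwrite)"
        )
    out = copy.deepcopy(network)
    for compartment in out.compartments:
        compartment.size = 1.0
    for reaction in out.reactions:
        reaction.rate_law = make_rate_law(reaction, law_type)
    return out
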