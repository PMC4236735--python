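# Methods

## Scope and model

kindraft scaffolds draft kinetic models of metabolic networks. The input
is a stoichiometric model: species `i` (internal or boundary), reactions
`j` with signed coefficients `n_ij` (negative = consumed), compartments.
The stoichiometric matrix `S` spans internal species only; boundary
species (SBML `boundaryCondition` or `constant`) are treated as
externally buffered and excluded from all balances, the standard SBML
semantics. A flux vector `v` is a steady state when `S·v = 0`.

Units are by convention mM for concentrations and mM s⁻¹ for fluxes; unit
strings are carried through tables but no unit algebra is performed.
SBML Levels 2 and 3 are read; Level 3 Version 2 is written. SBML rules,
events, and constraints are out of scope and rejected with an error
naming the construct, since silently dropping them would change model
semantics.

## Reference fluxes (FBA)

`solve_fba` maximizes (or minimizes) one reaction's flux subject to
`S·v = 0`, per-reaction bounds, and fixed-rate equality constraints,
implemented as equal lower/upper bounds — the simplest faithful encoding
of "rate fixed at a measured value". Default bounds are `(0, M)` for
irreversible and `(−M, M)` for reversible reactions with `M = 1000`
(configurable); the magnitude is conventional in constraint-based
modeling and only matters as an "effectively unbounded" sentinel. The LP
is solved with scipy's HiGHS backend, which is deterministic, so repeated
runs return identical flux vectors even when the optimum is degenerate.
FBA optima are generally non-unique; the contract guarantees the
objective value and feasibility, not a particular vertex. Every optimal
solution is independently re-checked (`‖S·v‖∞ ≤ 10⁻⁸`, bounds, fixed
rates) before being returned; a violation raises rather than returning a
silently wrong answer.

`normalize_directionality` then flips every reaction carrying a negative
reference flux (negating its coefficients and taking the absolute flux),
which leaves `S·v` unchanged entry-wise and makes all reference fluxes
non-negative, as the lumping and lin-log anchoring steps require.
Zero-flux reactions keep their stated direction: there is no information
in a zero to justify flipping.

## Network reduction

Which metabolites to eliminate is the modeler's decision (typically fast,
highly connected intermediates); the algorithm only executes the
elimination. Species are removed one at a time in list order. For
species `m` with producers `p` (`n_pm > 0`, flux `v_p`) and consumers `c`
(`n_cm < 0`, flux `v_c`), with throughput `T = Σ_p n_pm·v_p`, each
producer/consumer pair becomes a lumped reaction

    L_pc = (1/n_pm)·R_p + (1/|n_cm|)·R_c,   v(L_pc) = n_pm·v_p·|n_cm|·v_c / T.

`m` cancels exactly in `L_pc`; summing the lump fluxes weighted by their
composition reproduces each original reaction's flux (this requires `m`
to be balanced under the input fluxes, which is checked). Consequently
`S_red·v_red` restricted to retained species equals the original `S·v`
entry-wise, and steady state is preserved to rounding error (asserted at
`10⁻⁹`).

Degenerate cases: zero throughput with an active incident reaction is an
error (the lumping weights would be undefined); a species whose incident
reactions all carry zero flux is deleted together with those reactions
(they contribute nothing to any balance); zero-flux producers or
consumers of an otherwise active species simply generate no lumps.
Eliminating a hub with more than a configurable number of
producer×consumer pairs (default 200) is refused with advice, since the
lump count grows multiplicatively. Lump ids are deterministic
(`lump__<p>__<c>`), and lumps with identical stoichiometry within one
elimination are merged by flux addition; their provenance weights are
combined as flux-weighted averages so that the weight-sum identity stays
exact. A lump whose stoichiometry cancels completely (a pure
source-to-sink pass-through) is dropped. In the dict-of-signed-
coefficients representation a species cannot appear on both sides of a
reaction; autocatalytic stoichiometries collapse to their net coefficient
on reading, which is the supported interpretation.

Removal order can matter on general networks (different lump sets of
equal aggregate behavior); on linear chains it does not, which is tested.
The reduction output is a zip archive with exactly two members — the
reduced SBML model and the reduced flux table — written with fixed
timestamps so identical inputs give byte-identical archives.

## Rate-law families and initialization

The three families are generated symbolically (sympy) per reaction, with
deterministic local parameter names (`kf__R`, `Jref__R`, `eps__R__S`,
`cref__R__S`, `Km__R__S`, …) stored as reaction-local SBML parameters to
avoid global name collisions:

* **Mass action** — irreversible `v = k_f·Π_s c_s^{|n_s|}`, reversible
  minus `k_r·Π_p c_p^{n_p}`. An irreversible source reaction (no
  substrates) takes the natural degenerate form `v = k_f` (zeroth order,
  the empty product being 1), so exchange reactions are first-class.
* **Lin-log** — `v = J_ref·(1 + Σ_j ε_j·(ln c_j − ln c_ref_j))` over all
  participating species. The elasticities are initialized to `ε_j =
  −n_ij`, giving substrates positive and products negative control at the
  reference; `J_ref` and `c_ref` start at 1.0 and are overwritten during
  assembly. The initialization rule "negative of the stoichiometric
  coefficients" applies to the elasticities only — they are the only
  per-species lin-log parameters. The difference-of-logs form is
  algebraically identical to `ln(c/c_ref)` but cancels *exactly* in
  floating point when `c = c_ref`, so the assembled draft reproduces
  `J_ref` bit-for-bit rather than to 1 ulp.
* **Convenience kinetics** —
  `v = E·(k_cat⁺·Π_s (c_s/K_s)^{|n_s|} − k_cat⁻·Π_p (c_p/K_p)^{n_p}) / D`
  with `D = Π_s Σ_{m=0..|n_s|}(c_s/K_s)^m` for irreversible reactions and
  `D = Π_s(…) + Π_p(…) − 1` for reversible ones. All parameters start at
  1.0. Integer stoichiometric multiplicities are assumed for the
  saturation sums.

`translate_kinetics` assigns one family to every reaction of a copy of
the network and sets every compartment size to 1.0 (the convention for a
not-yet-parameterized scaffold). Existing laws are only overwritten with
an explicit force flag. Rate-law evaluation substitutes all parameters
and concentrations in a single pass at 53-bit precision; partial
substitution is avoided deliberately because sympy would distribute
numeric factors over sums and spoil the exact reference-state
cancellation. Logarithms of non-positive concentrations raise a domain
error naming the species and reaction.

## Assembly and validation

`add_metabolites` gives every species an initial concentration: the table
value where present (matched by id first, then by display name;
ambiguous names are errors), otherwise a default (0.0221 mM — a typical
median metabolome concentration for exponentially growing bacteria at low
dilution rates). Table entries matching no species are reported, not
fatal, because curated data files routinely cover more metabolites than a
reduced model retains. `set_fluxes` anchors each lin-log law: `J_ref`
from the flux table, `c_ref` from the species' current initial
concentration — i.e. the reference state is identified with the initial
state, matching the situation where one steady-state dataset provides
both. Non-lin-log laws are skipped with a warning (they have no
reference-flux parameter).

`validate_reference_state` evaluates all rates at the initial
concentrations and checks `‖S·v(c₀)‖∞ ≤ 10⁻⁹` (default). The tolerance
is tight because the pipeline is pure arithmetic: with lin-log laws the
rates equal the reference fluxes exactly, and the residual is that of the
flux data themselves.

## Synthetic fixtures

The generators return `(network, fluxes, concentrations)` triples in
which `S·v = 0` holds by construction, so every pipeline stage is
testable without external data:

* `toy_linear_chain(n, flux)` — uptake → X1 → … → Xn → excretion, uniform
  flux, unit concentrations.
* `toy_branched()` — a five-species network whose branch point receives
  2 mM/s and splits 1/1; its reduction and FBA behavior are known in
  closed form.
* `random_consistent_network(spec)` — flux-first construction: a backbone
  route through a random permutation of all species guarantees
  connectivity and strict flux positivity; additional reactions are
  shortcut routes whose flux is added to the upstream and downstream
  backbone segments, so every species stays balanced without rejection
  sampling. Unimolecular stoichiometry, seeded `numpy` RNG,
  reproducible byte-for-byte. Concentrations are log-uniform on
  0.001–10 mM, mimicking the heavy-tailed spread of measured metabolomes.

What these fixtures do *not* emulate: bimolecular and cofactor-coupled
stoichiometry, thermodynamic constraints, realistic genome-scale
topology, measurement noise. Passing tests therefore demonstrate the
correctness of the algorithms' contracts (steady-state preservation,
reference-state identity, LP optimality), not biological realism of any
particular fixture.

## Numerical choices

* Steady-state residual tolerances: `10⁻⁸` for LP feasibility re-checks
  (solver-limited), `10⁻⁹` for reduction and draft validation
  (arithmetic-limited).
* Fluxes below `10⁻¹²` are treated as zero during reduction; lump
  stoichiometry entries below `10⁻¹²` are dropped as cancellation noise.
* Identifier matching is case-sensitive, id before name; ambiguity is an
  error rather than a silent first match.
* Value tables auto-detect tab vs comma on file content (tab preferred)
  and reject non-numeric values (including NaN/inf) with line numbers;
  nothing is silently coerced.
* SBML numeric round-trips rely on libsbml's double formatting; kinetic
  laws are compared numerically (not structurally) after round trips,
  since algebraically equivalent expression trees may differ.

## Problem sizes

The test suite and the acceptance script use networks of 5–15 species
(100 random instances per property) and toy problems with closed-form
answers, sizes at which the brute-force LP oracle (exhaustive
basic-feasible-solution enumeration) and hand derivations are exact and
the whole suite runs in seconds. The algorithms themselves have no
size-specific code paths; the hub cap is the only scale guard.

## Known limitations

* The flux-proportional elimination is one defensible reduction scheme;
  time-scale-based reduction methods can produce different (also valid)
  reduced networks. The contract here is steady-state and throughput
  preservation, not equivalence with any other scheme.
* Lumped reactions are emitted irreversible in the reference direction;
  reversibility information of the parents is not propagated.
* No thermodynamic consistency checks on generated laws.
* SBtab support is the small dialect the workflow needs, not the full
  specification; unknown columns are preserved as text.
* Unit strings are metadata only; mixed-unit inputs are the user's
  responsibility.
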