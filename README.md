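# kindraft

**kindraft** turns a stoichiometric metabolic network (SBML) into a *draft
kinetic model*: a structurally complete ODE model with approximate rate
laws, initial metabolite concentrations, and reference fluxes installed —
ready for parameter estimation in tools like COPASI, but not yet fitted.
It is aimed at systems biologists who have a reconstructed network plus a
handful of measured rates and concentrations and want to skip the tedious,
error-prone manual steps between "stoichiometric model" and "first
simulatable kinetic model".

The workflow chains five steps, each available as a library function, a
CLI subcommand, and a stage of the `pipeline` command:

1. **Reference fluxes** — FBA: maximize an objective reaction `v_obj`
   subject to `S·v = 0`, bounds, and measured equality constraints
   (e.g. a glucose uptake fixed at 0.2004 mM s⁻¹). Reactions solved with
   negative flux are flipped so all reference fluxes are ≥ 0.
2. **Network reduction** — eliminate user-selected metabolites by
   flux-proportional lumping: for species *m* with producers *p* and
   consumers *c*, each pair is replaced by the lump
   `L_pc = (1/n_pm)·R_p + (1/|n_cm|)·R_c` carrying flux
   `n_pm·v_p·|n_cm|·v_c / T` with `T = Σ_p n_pm·v_p`, which preserves
   every retained metabolite's balance exactly. Output is a zip archive
   with the reduced SBML model and the new flux table.
3. **Rate laws** — assign one of three approximate families to every
   reaction, with all parameters and compartment sizes initialized to 1.0:
   - mass action: `v = k_f·Π_s c_s^{|n_s|} (− k_r·Π_p c_p^{n_p})`
   - lin-log: `v = J_ref·(1 + Σ_j ε_j·ln(c_j/c_ref_j))`, with
     elasticities initialized to the negated stoichiometric coefficients
     (`ε_j = −n_ij`)
   - convenience kinetics: saturable generalized reversible law with one
     `K_m` per participating species
4. **Concentrations** — inject measured initial concentrations; unknown
   metabolites get a default fill-in (0.0221 mM, a typical metabolome
   median).
5. **Reference fluxes into laws** — set each lin-log `J_ref` to the
   reaction's reference flux and each `c_ref` to the species' initial
   concentration, then **validate**: at the reference state the model must
   satisfy `v(c₀) = J_ref` and `‖S·v(c₀)‖∞ ≤ 10⁻⁹`.

Tabular inputs are two-column (name, value) text tables; annotated
experimental-data tables in a minimal SBtab dialect (declaration line,
`!`-prefixed columns, ChEBI/KEGG identifier columns) are also supported,
including single-sheet `.xlsx` workbooks. A synthetic-fixture module
generates linear-chain, branched, and random steady-state-consistent
networks, so the whole pipeline is testable without any external data.

## Worked example

```python
import kindraft as kd

net, fluxes, conc = kd.toy_linear_chain(3, flux=1.0)
draft = kd.translate_kinetics(net, "linlog")
draft, _ = kd.add_metabolites(draft, conc, default_value=0.0221)
draft = kd.set_fluxes(draft, fluxes)
print(kd.evaluate_rates(draft).values)
print(kd.validate_reference_state(draft).summary())
```

prints

```
{'R_in': 1.0, 'R1': 1.0, 'R2': 1.0, 'R_out': 1.0}
reference-state validation: PASSED
max |S.v(c0)| residual: 0.000e+00 (tolerance 1.0e-09)
```

Every reaction's lin-log rate at the initial concentrations equals its
reference flux, so the draft model starts exactly at the steady state the
flux data describe — the property that makes it a sound starting point
for parameter fitting. The `examples/` directory has one short script per
capability (FBA, reduction, rate laws, SBtab tables), and the same
workflow is available from the shell:

```bash
kindraft pipeline --config config.yaml     # or stage-by-stage:
kindraft fba --model m.xml --objective R_out --fix R_in=0.2004 --out-fluxes v.tsv
kindraft reduce --model m.xml --fluxes v.tsv --remove hubs.txt --out reduced.zip
kindraft translate-kinetics --model reduced.xml --law linlog --out kin.xml
kindraft add-metabolites --model kin.xml --concentrations c.tsv --out kin2.xml
kindraft set-fluxes --model kin2.xml --fluxes v.tsv --out draft.xml
kindraft validate --model draft.xml
```

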