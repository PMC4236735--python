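"""Estimate a reference flux distribution by FBA with a measured uptake.

A 3-reaction chain is solved twice: once limited only by an uptake bound,
and once with the uptake pinned to a measured rate of 0.2004 mM/s (an
equality constraint), the usual way experimental uptake or maintenance
rates enter an FBA problem.
"""
import kindraft as kd

net = kd.MetabolicNetwork(
    compartments=[kd.Compartment("c")],
    species=[kd.Species("A", compartment="c"), kd.Species("B", compartment="c")],
    reactions=[
        kd.Reaction("R1", {"A": 1.0}),            # uptake
        kd.Reaction("R2", {"A": -1.0, "B": 1.0}),
        kd.Reaction("R3", {"B": -1.0}),           # excretion (objective)
    ],
)

bounded = kd.solve_fba(net, kd.FBAProblem("R3", bounds={"R1": (0.0, 10.0)}))
print(f"objective with uptake bound 10: {bounded.objective_value:g}")

fixed = kd.solve_fba(net, kd.FBAProblem("R3", fixed_fluxes={"R1": 0.2004}))
print(f"objective with uptake fixed at 0.2004: {fixed.objective_value:g}")
print("fluxes:", {rid: f"{v:g}" for rid, v in fixed.fluxes.items()})
# The whole chain is forced to the measured uptake rate: at steady state
# every step of an unbranched pathway carries the same flux.
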