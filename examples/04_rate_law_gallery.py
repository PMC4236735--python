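"""The three approximate rate-law families on a single reaction A -> B.

Prints each generated symbolic expression with its initialized parameters
and evaluates it at a test state, reproducing the closed-form values:
mass action 2A -> B at c_A = 2 gives 4; lin-log A -> B at c_A = 2 with
J_ref = 2 gives 2(1 + ln 2) ~ 3.3863; convenience kinetics at the all-ones
state gives 0.5 (half of V_max, since c_A = K_m).
"""
import kindraft as kd

bimolecular = kd.Reaction("R1", {"A": -2.0, "B": 1.0})
mass_action = kd.make_mass_action(bimolecular)
print("mass action, 2A -> B:")
print("  v =", mass_action.expression)
print("  v(c_A=2) =", mass_action.evaluate({"A": 2.0, "B": 1.0}))

unimolecular = kd.Reaction("R1", {"A": -1.0, "B": 1.0})
linlog = kd.make_linlog(unimolecular)
linlog.parameters["Jref__R1"] = 2.0
print("lin-log, A -> B (J_ref = 2):")
print("  v =", linlog.expression)
print("  elasticities:", {k: v for k, v in linlog.parameters.items()
                          if k.startswith("eps")})
print("  v(c_A=2, c_B=1) =", linlog.evaluate({"A": 2.0, "B": 1.0}))

convenience = kd.make_convenience(unimolecular)
print("convenience, A -> B:")
print("  v =", convenience.expression)
print("  v(all ones) =", convenience.evaluate({"A": 1.0, "B": 1.0}))
# Substrates get positive and products negative lin-log elasticities
# (eps = -n); the convenience law saturates at E * k_cat = 1.
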