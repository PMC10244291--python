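"""Closed-form local analysis of the unforced calcifier-alkalinity model.

Computes the equilibrium, the Hopf threshold of the weathering feedback,
and the linearized oscillation period — no simulation required.
"""

import calcalk as ck

p = ck.TABLE_DEFAULTS
eq = ck.equilibrium(p, gamma=0.0)
print(f"equilibrium: A* = {eq.A} mol eq m^-3, C* = {eq.C:.2e} mol eq m^-3")

gamma_h = ck.hopf_threshold(p)
print(f"Hopf threshold: gamma_H = {gamma_h:.4f}")
print("  -> below this feedback strength oscillations decay;"
      " above it a stable sawtooth limit cycle exists")

T_lin = ck.linear_internal_period(p, gamma=0.0)
print(f"linearized internal period: {T_lin:.0f} yr (~{T_lin/1e3:.0f} kyr)")
print("  -> the period of the damped spiral below the bifurcation")
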