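"""Bifurcation structure of the fast subsystem under frozen [K+]_out.

With extracellular potassium treated as a parameter, the spike-generating
(V, h, n) subsystem has a fold of equilibria (SN), a homoclinic orbit
bifurcation (HOM) destroying the spiking limit cycle, and a Hopf point on
the depolarized branch.  The strip between SN and HOM is bistable — the
substrate of the hysteresis-loop burster.
"""
import numpy as np

import pumpburst as pb

p = pb.ModelParameters(I_app=0.5, I_max=1.0)

sn = pb.locate_fold(0.5, p)
hopf = pb.locate_hopf(0.5, p)
death = pb.classify_cycle_death(0.5, p, K_window=(8.0, 14.0), tol=1e-4)

print(f"SN fold:        K_out = {sn.K_out:.4f} mM  "
      f"(zero eigenvalue {sn.diagnostics['zero_eigenvalue']:.1e})")
print(f"cycle death:    {death.type} at K_out = {death.K_out:.4f} mM")
print(f"Hopf:           K_out = {hopf.K_out:.4f} mM")
print(f"bistable window: {death.K_out - sn.K_out:.3f} mM wide")

print("\nequilibria across the window:")
for K in (10.3, 10.5, 10.6):
    eqs = pb.find_equilibria(K, 0.5, p)
    desc = ", ".join(f"{e.stability} (V={e.V:.1f})" for e in eqs)
    print(f"  K_out = {K:5.2f}: {desc}")

cyc = pb.find_limit_cycle(9.0, 0.5, p)
mults = np.sort(np.abs(cyc.floquet))[::-1]
print(f"\nspiking cycle at K_out = 9: period {cyc.period:.2f} ms, "
      f"|Floquet| = {np.round(mults, 5)}")
# One multiplier equals 1 (autonomous system); the others inside the unit
# circle confirm the orbit is stable.
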