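"""Reduced slow subsystem: averaged d[K+]_out/dt and the hysteresis loop.

Averaging the potassium flux over one fast limit-cycle period collapses
the model onto a single slow equation for [K+]_out.  At the reference
bursting parameters the spiking branch is positive (K+ accumulates) up to
the homoclinic, and the resting branch negative (the pump wins) down to
the fold: the slow flow must cycle — bursting.
"""
import numpy as np

import pumpburst as pb

p = pb.ModelParameters(I_max=1.0)
diagram = pb.assemble_hysteresis(0.5, p, K_window=(9.0, 12.0))

for m in diagram.markers:
    print(f"marker {m.type:5s} at K_out = {m.K_out:.4f} mM")

spk = diagram.branch("spiking")
ok = spk.valid & np.isfinite(spk.dKdt)
print(f"spiking branch:  dK/dt in [{spk.dKdt[ok].min():.2e}, "
      f"{spk.dKdt[ok].max():.2e}] mM/ms (all positive)")

rest = diagram.branch("resting_low")
ok = rest.valid & np.isfinite(rest.dKdt)
print(f"resting branch:  dK/dt in [{rest.dKdt[ok].min():.2e}, "
      f"{rest.dKdt[ok].max():.2e}] mM/ms (all negative)")

print(f"reduced fixed points on spiking branch: "
      f"{[f.K_out for f in diagram.fixed_points if f.branch == 'spiking']}")
print(f"predicted complete-system regime: "
      f"{pb.predict_complete_dynamics(diagram)}")

# A stable zero of the averaged derivative on the spiking branch would trap
# the slow variable (tonic firing).  Here there is none before the HOM, so
# the hysteresis loop closes and the prediction is bursting.
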