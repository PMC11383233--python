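# pumpburst

Slow, deterministic bursting from nothing but fast spiking currents, an
electrogenic Na⁺/K⁺-ATPase, and the potassium it moves.

`pumpburst` implements a minimal conductance-based neuron in which the
Wang–Buzsáki fast-spiking interneuron model (millisecond Na⁺/K⁺ channel
kinetics, activation *m* slaved to *m*∞(V)) is coupled to the
extracellular potassium concentration [K⁺]ₒ through two fluxes: the
voltage-gated K⁺ current that exports potassium with every spike, and a
K⁺-activated, electrogenic pump current that imports it again,

- I_Na = g_Na · h · m∞(V)³ · (V − E_Na),  I_K = g_K · n⁴ · (V − E_K),
  I_L = g_L · (V − E_L)
- C dV/dt = I_app − I_Na − I_K − I_L − I_P
- I_P = I_max / (1 + exp((K_half − [K⁺]ₒ)/1.1))
- d[K⁺]ₒ/dt = (I_K − 2 I_P) · A_cell/(r_v · F · V_cell)
- E_K = 26.71 · ln([K⁺]ₒ/140)  (mV, Nernst)

No slow ion channel exists anywhere in the model, yet the complete system
bursts on a timescale of seconds.  The package contains both the simulator
and the slow–fast machinery that explains the rhythm: bifurcation analysis
of the 3-D fast subsystem with [K⁺]ₒ as parameter (fold/SN, Hopf,
homoclinic, SNIC, fold-of-limit-cycles detection; saddle-node-loop and
homoclinic-turning-point localization), averaging of the potassium flux
over the fast limit cycle (the reduced slow subsystem), hysteresis-loop
assembly, and classification of the complete dynamics into rest, tonic
spiking, bursting, and depolarization block.

An extended variant makes intracellular sodium dynamic (Nernst-derived
E_Na, Na⁺-dependent pump); the burst mechanism survives it.

**Who it is for:** computational neuroscientists studying ion-concentration
dynamics, bursting mechanisms, class I (SNIC) excitability and its
saddle-node-loop unfolding, or pathologies of potassium homeostasis
(seizure-like bursting, spreading-depolarization-like block).

Note on the pump midpoint: the package default is `K_half = 11.0` mM, the
operating value of the published dynamics (it is what produces the 11-spike
reference burst and the spike-adding transition near I_max ≈ 0.9945);
`K_half = 10.0`, the constant printed inside the pump equation, is
available as an ordinary parameter. See `docs/methods.md`.

## Worked example

```python
import pumpburst as pb

p = pb.ModelParameters(I_app=0.5, I_max=1.0)   # reference bursting point
traj, spikes, s = pb.run_and_summarize(p, t_end=20000, transient_discard=8000)
print(s.regime, s.modal_spikes_per_burst)
print(round(s.interburst_interval), round(s.intra_burst_isi_mean, 1))
```

prints

```
bursting 11
1154 38.0
```

Every burst carries exactly 11 spikes; the quiescent interval between
bursts is ≈ 1.15 s, about 30 times the duration of one spiking cycle
(mean intra-burst inter-spike interval 38 ms), and [K⁺]ₒ shuttles between
≈ 10.38 and 10.76 mM.  The slow–fast view of the same point:

```python
d = pb.assemble_hysteresis(0.5, p, K_window=(9.0, 12.0))
print([(m.type, round(m.K_out, 3)) for m in d.markers])
print(pb.predict_complete_dynamics(d))
```

```
[('SN', 10.447), ('HOPF', 14.723), ('HOM', 10.746)]
bursting
```

The burst's [K⁺]ₒ window is exactly the bistable strip of the fast
subsystem between the fold (SN) and the homoclinic (HOM), with the
overshoot below the SN caused by the slow passage near its ghost.

The `examples/` directory holds one short narrative script per capability
(burst trace, fast-subsystem bifurcations, hysteresis loop, regime map,
dynamic-sodium variant).  A thin CLI mirrors the library:

```bash
pumpburst simulate --iapp 0.5 --imax 1.0 --out traj.csv
pumpburst bifurcate-fast --iapp 0.5 --kout 9:13:0.05 --out branch.csv
pumpburst reduce-slow --iapp 0.5 --kwin 9:12 --out hyst.csv
pumpburst regime-map --imax 1:2:1 --iapp 0.25:1:0.25 --out map.csv
pumpburst params dump
```

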