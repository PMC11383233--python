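# Methods

## Model

The fast subsystem is the Wang–Buzsáki fast-spiking interneuron reduced to
three dimensions: transient-sodium activation is slaved to its steady
state m∞(V) = α_m/(α_m+β_m), and the inactivation h and delayed-rectifier
activation n follow first-order kinetics accelerated by a temperature
factor φ = 5 applied at the right-hand-side level,

    dh/dt = φ (α_h(V)(1−h) − β_h(V) h),   dn/dt = φ (α_n(V)(1−n) − β_n(V) n),

with the standard rate functions (α_h = 0.07 e^{−(V+58)/20},
β_h = 1/(1+e^{−(V+28)/10}), α_n = −0.01(V+34)/(e^{−0.1(V+34)}−1),
β_n = 0.125 e^{−(V+44)/80}, α_m = −0.1(V+35)/(e^{−0.1(V+35)}−1),
β_m = 4 e^{−(V+60)/18}).  The removable singularities of α_n (V = −34 mV)
and α_m (V = −35 mV) are evaluated by their analytic limits on a symmetric
branch |V − V_sing| < 10⁻⁷ mV, avoiding 0/0 at exactly representable
voltages.

The membrane equation is C dV/dt = I_app − I_Na − I_K − I_L − I_P; the
pump current I_P enters it only in the electrogenic variant
(`electrogenic=True`, the default).  The electroneutral control — the pump
still moves K⁺ but carries no net charge — is the switch the shear
analysis rests on.

The slow variable is extracellular potassium,

    d[K⁺]ₒ/dt = (I_K − 2 I_P) · γ_out,   γ_out = A_cell/(r_v F V_cell) · 10⁻³,

where the factor 2 is the two K⁺ ions imported per pump cycle.  Unit
bookkeeping behind γ_out: a current density of 1 μA/cm² over A_cell cm²
is 10⁻⁶ C/s; dividing by Faraday's constant gives mol/s, dividing by the
extracellular volume r_v·V_cell cm³ = r_v·V_cell·10⁻³ L gives mol/L/s, and
1 M/s is numerically 1 mM/ms.  With the default geometry
γ_out ≈ 4.132·10⁻⁴ mM·cm²/(μA·ms); a unit test re-derives it from SI
quantities independently.  The averaged slow equation uses the same
effective extracellular volume (the volume written V_ex in the averaged
form is identified with r_v·V_cell; nothing else is dimensionally
consistent with the instantaneous continuity equation).

E_K is dynamic via the Nernst relation 26.71·ln([K⁺]ₒ/140); E_Na is the
constant 55 mV unless sodium is dynamic, in which case
E_Na = 26.71·ln(144/[Na⁺]ᵢ), d[Na⁺]ᵢ/dt = (−I_Na − 3 I_P)·γ_in with
γ_in = γ_out·r_v (intracellular volume), and the pump gains the standard
sodium sigmoid 1/(1+e^{(25−[Na⁺]ᵢ)/3}).  At [Na⁺]ᵢ = 18.4 mM that factor
is ≈ 1/10, so I_max ≈ 10 μA/cm² in the extended model corresponds to an
effective capacity of 1 in the base model, and E_Na(18.4) ≈ 55 mV.

### The pump midpoint: 11 mM, not 10

The printed form of the pump sigmoid carries a midpoint constant of 10 mM
while the surrounding text gives half activation at 11 mM.  These are not
interchangeable: with K_half = 11 the complete system at I_app = 0.5,
I_max = 1 produces the reference burster (11 spikes per burst; 11↔12
spike-adding transition at I_max ≈ 0.99450852625), whereas with
K_half = 10 the very same drive yields slow tonic spiking and no bursting
anywhere near those parameters.  The package therefore defaults to
`K_half = 11.0` — the value the published dynamics operate at — and keeps
10 available as an ordinary parameter; the analytic half-activation
property of the printed sigmoid (I_P = I_max/2 at 10 mM when K_half = 10)
is tested against that explicit parameterization.

## Numerics

**Integration.**  Classical fixed-step RK4 at dt = 0.005 ms (compiled with
numba), recording every 4th step (0.02 ms) by default; spike times are
interpolated linearly at the upward crossing of 0 mV with a 2 ms
refractory guard, so the recording stride does not limit their precision.
Halving dt moves spike times by < 0.1 ms (tested).  An adaptive RK45 mode
(scipy) exists solely as a cross-check oracle and agrees with the fixed
step on spike times.  The integrator is deterministic: identical
configurations produce bit-identical trajectories; there is no randomness
anywhere in the core.

**Default initial state** (the model's own study conditions, configurable):
V = −65 mV, gates at steady state, [K⁺]ₒ = 4.8 mM (E_K ≈ −90 mV, the
classic resting value for this neuron class), [Na⁺]ᵢ = 18.4 mM when
dynamic.  Regime classification simulates 12 s and discards 2 s; burst
*statistics* quoted for the reference attractor use 20 s with 8 s
discarded, because the approach to the burst attractor from low [K⁺]ₒ
still biases inter-spike statistics at 2 s.  Both the inter-burst interval
(last spike of a burst to first spike of the next) and the full cycle
period (first spike to first spike) are reported; the "about one second,
about 30 spiking cycles" characterisation of the reference rhythm refers
to the inter-burst interval (≈ 1.15 s against a 38 ms mean intra-burst
inter-spike interval; the full cycle is ≈ 1.54 s).

**Burst segmentation and regimes.**  Inter-spike intervals are split into
intra- and inter-burst classes at the largest adjacent ratio of the sorted
ISI sequence; the distribution counts as bimodal (bursting) when that
ratio exceeds 3 with at least two members per class.  Tonic = unimodal
ISIs; rest = no tail spikes with V settled below −60 mV; depolarization
block = no tail spikes with V above −50 mV and [K⁺]ₒ settled high or
rising; anything ambiguous is labelled `undetermined` rather than guessed.
Period-doubled trains are flagged when the ISI sequence alternates between
two values (sub-2% spread within each class, > 5% apart).  The 11↔12
spike-adding transition is located by bisection on I_max with a fresh
transient-discarded simulation per evaluation and the modal
spikes-per-burst as the count; the default tolerance 10⁻⁴ μA/cm² is what a
12 s simulation supports — the printed 11-digit transition value is
matched only to that tolerance.

**Equilibria and codimension-1 points.**  At an equilibrium the gates sit
on their steady-state curves, so the 3-D root problem reduces to a scalar
condition G(V; K, I_app) = 0, bracketed on a deterministic V grid,
solved by Brent's method and polished in 3-D (residual < 10⁻¹⁰).
Stability comes from the eigenvalues of a central finite-difference
Jacobian.  The fold (SN) solves {G = 0, ∂G/∂V = 0} with a 2-D Newton
iteration seeded from a coarse change in equilibrium count — equivalent
to, and more robust than, arclength continuation for a branch that is
scalar under the hood; the zero eigenvalue at the solution is ~10⁻¹⁰.
Hopf points are found by bisection on the real part of the complex pair of
the depolarized equilibrium.

**Limit cycles.**  The stable spiking orbit is settled by direct
integration (a continuation-style fallback drags a spiking state up from
lower [K⁺]ₒ when the generic start falls into the bistable fixed point),
its period estimated from returns to the Poincaré section V = −20 mV
(upward), then polished by single shooting — Newton on (h, n, τ) with V
fixed on the section, closure residual < 10⁻⁶.  Floquet multipliers come
from a central finite-difference monodromy matrix (steps 10⁻⁵ in V, 10⁻⁷
in the gates); the trivial multiplier reproduces 1 to ~10⁻⁵ and is tested
at 10⁻⁴.

**Cycle death and its classification.**  The upper [K⁺]ₒ boundary of the
spiking orbit is located by marching the orbit state upward in [K⁺]ₒ with
a step that shrinks on persistence failure (spikes still occurring in the
final stretch of a frozen-[K⁺]ₒ run).  The state is never jumped far in
the parameter: inside the bistable strip a long jump can land in the
fixed point's basin and fake an orbit death, while a failed short step is
self-correcting because the refined march re-probes from a closer seed.
The destroying bifurcation is SNIC when the
boundary sits at (or, because the persistence window cannot resolve
periods beyond ~2 s, slightly below) the fold, HOM when a saddle
exists there and the orbit approaches it (period ratio between probes at
0.02 and 0.004 mM below the boundary > 1.15, or a normalized
cycle-to-saddle distance < 0.05 with V scaled by 100 mV), and FLC
otherwise.  Periods above 1000 ms are treated as numerically homoclinic,
with the logarithmic law τ ≈ a − b·ln(K_hom − K) fitted for diagnostics.
The saddle-node-loop point (SNIC→HOM transition in I_app) and the turning
point of the HOM curve (HOM→FLC) are located by bisection on this
classification; a quadratic-fit refinement is available when a traced
two-parameter curve is supplied.  At the default pump capacity these sit
at I_app ≈ 0.30 and ≈ 0.62, bracketing the reference drive 0.5 as the
bursting wedge requires.

**Averaging and the hysteresis diagram.**  On the spiking branch the
reduced slow derivative is the trapezoidal average of I_K over one cycle
(≥ 2000 samples per period; the pump term is constant at frozen [K⁺]ₒ)
minus 2 I_P, times γ_out.  Resting branches evaluate the continuity
equation at the fixed point (low-voltage rest state, or the depolarized
upstate above the Hopf).  Averaging validity is flagged per point — invalid
within 0.05 mM of the branch end or at periods above 500 ms, where
timescale separation degrades — and the sign-consistency checks against
full simulations honour those flags.

Near a homoclinic the averaged derivative behaves as C₂ + C₁/τ(K) with C₂
(the saddle-dwell flux) negative, so every HOM-terminated spiking branch
crosses zero at some small distance below the boundary.  How much of that
structure to resolve is a scientific choice, not a numerical one: at
distances below ~10⁻³ mM the slow variable traverses the remaining gap
within a fraction of one spike cycle, the frozen-[K⁺]ₒ average no longer
describes the complete system's motion (at the strong-pump tonic case the
complete orbit even sweeps past the frozen-subsystem homoclinic every
cycle and returns), and a crossing found there carries no predictive
content.  The branch tail is therefore sampled geometrically down to
10⁻³ mM below the boundary.  At the reference bursting point the crossing
lies below that resolution (~10⁻⁴ mM), so the branch terminates positive
— the "reaches the homoclinic before the derivative turns negative"
picture — while at the strong-pump tonic case the crossing appears at
~5·10⁻³ mM and is resolved as a stable reduced fixed point.

**Prediction rule.**  No spiking branch → rest.  Orbit death on the fold
itself (SNIC, below the saddle-node loop) → tonic: with no bistable strip
the hysteresis loop cannot form.  A stable averaged crossing in the valid
region → tonic.  Homoclinic death with the branch positive throughout and
the resting branch negative down to the fold → bursting.  Fold-of-limit-
cycles death with no valid crossing → depolarization block.  A crossing
that exists only inside the averaging-breakdown zone (within 0.05 mM of
the branch end or at periods above 500 ms) leaves the reduced diagram
honestly inconclusive; the predictor then performs the validation step the
averaging method always requires near fast-subsystem bifurcations — one
direct simulation of the complete system — or returns the label
`requires_simulation` when that fallback is disabled.  The strong-pump
tonic case sits in this near-boundary regime, which is exactly where the
tonic/bursting transition of the complete system lives — the
period-doubling route that the reduced description cannot represent.

## What the tests do and do not show

All quantitative checks run against the model's own synthetic dynamics —
the model *is* the study object, there is no external data.  Passing tests
demonstrate internal consistency (continuation vs. brute force, shooting
vs. simulation, averaging vs. full per-spike increments, prediction vs.
direct classification) and reproduction of the published phenomenology at
the printed parameter points.  They do not validate the model against
physiological recordings, and the single-compartment, fixed-volume,
glia/diffusion/oxygen-free setting means quantitative [K⁺]ₒ excursions
should not be read as tissue predictions.

## Problem sizes

Default analyses are desk-scale by design: 12–20 s simulated per regime
cell at dt = 0.005 ms; hysteresis diagrams with ~40 spiking-branch
averages plus the geometric tail; organizing-center localization by
bisection to 2·10⁻³ μA/cm² (tests use 0.02).  Tighter tolerances only
lengthen the bisections; nothing in the method depends on the grid sizes.

## Known limitations

- Complete-system limit cycles are not continued; the period-doubling
  route at the bursting boundary is detected only as alternating-ISI
  patterns in simulation, and the spike-adding canard structure is located
  numerically (the transition parameter), not analysed.
- The reduced slow subsystem is built for the base model only; the
  dynamic-sodium variant is studied by simulation.
- The existence test for spiking orbits assumes the stable cycle is
  reachable by forward integration; unstable cycles are never computed
  explicitly (the FLC is detected through the stable orbit's
  disappearance at finite period).
- `classify_cycle_death` assumes the cycle exists at the low end of the
  supplied [K⁺]ₒ window; windows must be chosen to bracket one death.
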