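# Methods

This note records the model equations, parameter conventions, numerical
choices, and the design decisions taken where more than one reasonable
implementation existed.  Nothing here states an empirical number that the
test suite or `scripts/acceptance.py` does not itself compute.

## 1. Reduced interneuron phase model

An interneuron driven by a constant depolarizing current is treated as a
limit-cycle oscillator of intrinsic angular frequency ω; the septal pacemaker
is a weak periodic perturbation Q(t) = Q₀·cos(ω_θ t).  With an infinitesimal
phase response curve (PRC) z(φ) the phase obeys dφ/dt = ω + z(φ)Q(t).  For
the sinusoidal family z(φ) = z₀ − z₁·sin φ, averaging over single pacemaker
cycles (assuming the phase lag Δφ = φ − θ moves slowly on that timescale)
gives the Adler equation

    dΔφ/dt = Δω − A·sin Δφ,   Δω = ω − ω_θ,   A = Q₀z₁/2.

Phase locking (|Δω| < A) has the stable fixed point arcsin(Δω/A) and the
unstable point π − arcsin(Δω/A); frequency pulling (|Δω| > A) drifts at
f = √(Δω² − A²)/2π.  The closed-form trajectory is evaluated per branch of
its inner tangent and stitched into a continuous unwrapped function; in the
locking regime the tangent becomes a hyperbolic tangent.  Because the
printed tanh branch only covers initial phases between the two fixed points,
`adler_solution_from_initial` uses the equivalent Riccati form in
u = tan(Δφ/2), which is valid from any initial phase (including above the
unstable point, where the trajectory completes a forward cycle before
locking).

Both phase models are integrated with classical fixed-step RK4, default
dt = 10⁻⁴ s, with a guard dt·(|Δω|+A) ≤ 0.1.  The regime classifier uses a
relative tolerance of 10⁻⁹ on |Δω| − A so floating-point ties are reported
as the saddle-node boundary rather than as either regime.

Amplitude dynamics of the oscillator and non-sinusoidal PRCs are outside the
model; the averaging derivation assumes the z₀/z₁ family.  The relation
between the Gaussian drive width σ and the field radius R in the speed
constraint (Δω)² = A² + (πv/R)² is left to the user: R is an independent
input, because the spiking field width is an emergent quantity (see §5).

## 2. Spiking circuit

Leaky integrate-and-fire neurons with conductance synapses:

    dVm/dt = −(Vm − E₀)/τm − g(t)(Vm − E_rev)/Cm + I_ext/Cm + noise,

spike at V_θ, reset to V_r, no refractory period.  Synaptic conductances
decay exponentially and jump by the synaptic weight at each presynaptic
spike.  Fixed parameters (independent of running speed):

| parameter | interneuron | pyramidal |
|---|---|---|
| τm | 40 ms | 20 ms |
| Cm | 200 pF | 155 pF |
| E₀ | −65 mV | −65 mV |
| V_θ / V_r | −50 / −70 mV | −50 / −70 mV |
| synaptic τ (onto cell) | τ_E = 2 ms | τ_I = 10 ms |
| reversal (onto cell) | E_E = 0 mV | E_I = −70 mV |

w_E = 0.5 nS (pyramidal→interneuron), w_I = 25 nS (interneuron→pyramidal),
f_θ = 8 Hz, σ = 40 cm, dt = 0.1 ms.  Each pyramidal cell connects to exactly
one interneuron; each interneuron reciprocally inhibits exactly its own
pyramidal cells (the inhibitory incidence is the transpose of the excitatory
one); no same-type connections.  The interneuron count must divide the
pyramidal count so loads are equal.

Drives: interneurons get I0_I − I_θ·cos(ω_θ t) (minimal at t = 0; the
pacemaker phase convention is θ(0) = 0 at the cosine peak of the forcing
term).  Place cells get I_E·exp(−|x(t) − x_c|²/2σ²) along a straight
trajectory x(t) = x₀ + v·t, optionally offset laterally (14 cm for the
edge-pass protocol).  The running-speed laws (v in cm/s, currents pA,
noise mV) are

    I0_I = 79.5 + 0.027·v    I_θ = 0.065·v
    I_E  = 110 + 0.5·v       σn_E = 1.75 − 0.025·v  (valid to v = 70)

Dorsoventral parameter sets (both at v = 30 cm/s): dorsal σ = 45 cm,
σn = 0.7 mV, I0_I = 80.455 pA, I_θ = 1.95 pA, w_E = 0.53 nS; ventral
σ = 600 cm, σn = 3 mV, I0_I = 79.525 pA, I_θ = 0.12 pA, w_E = 0.081 nS.

### Numerical conventions

- **Integration**: forward Euler at dt = 0.1 ms; threshold tested after the
  update; membrane recorded at the start of each step; spikes stamped at the
  end of the step in which the crossing is detected.  Against the closed-form
  constant-current ISI, τm·ln((V∞−V_r)/(V∞−V_θ)), this scheme is accurate to
  about two Euler steps per interval (worst near rheobase, where the
  threshold approach is shallow) — the test suite asserts 2.5 steps.
- **Synapses**: conductances decay by exactly exp(−dt/τ) each step; a spike
  at step k increments the target conductance after that step's decay, so it
  first acts on step k+1.  The synaptic driving force uses the previous-step
  membrane potential (explicit Euler throughout).
- **Noise**: the membrane noise is a Langevin term — a per-step increment
  σn·η·√(dt/τm) with η ~ N(0,1) drawn independently per cell per step —
  giving a stationary subthreshold fluctuation of σn/√2 irrespective of dt.
  This scale is what makes the published σn values functionally meaningful:
  it reproduces a ~0.3 m dorsal and ~10 m ventral place field from the same
  drive geometry, and the speed-law noise then actually stabilizes field
  width across speeds.  A step-bound variant (increment σn·η·dt/τm, noise
  tied to the 0.1 ms step) is available via `noise_dt_bound=True` for
  sensitivity analyses.  Interneuron noise defaults to zero; it is a
  protocol parameter only in the noise-robustness sweep.
- **Initial conditions**: Vm(0) = E₀, conductances 0, pacemaker phase 0.
- **Determinism**: the per-step RNG is seeded inside the compiled kernel;
  identical configuration + seed ⇒ bit-identical spikes and traces.
- **Units**: SI internally; constructors and experiment configs accept
  pA/mV/ms/cm/nS.

### Lap geometry and the winding measure

A lap places the field center 3σ + margin into the run and extends margin
meters beyond the far 3σ edge (default margin 2.5 m, enlarged for the
ventral pole).  The interneuron's **cycles precessed** is the winding number
between its locked plateaus: the mean unwrapped spike phase over ~1.5 s just
before the first pyramidal spike minus the mean over the final ~1.5 s of the
lap, divided by 2π.  The window matters: because the pair sits near the
saddle-node by design, a large part of each cycle is traversed as a slow
creep *after* the last pyramidal spike, so a window clipped at the last
place-cell spike systematically undercounts the advance.  Plateau-to-plateau
the advance is integral and matches the one-cycle behavior of the circuit.
The raw `metrics.cycles_precessed(phases)` operation (unwrap within an
arbitrary window, round the drop) is also provided.

Spike phases are pacemaker phases 2π·f_θ·(t − t_reset) mod 2π, so a
precessing neuron's spike phase *decreases* across a traversal, and the
LIF locking phase decreases with depolarizing current; advances are counted
positive in that direction.

## 3. Analysis metrics

- **Instantaneous theta frequency**: membrane trace clipped at V_θ,
  zero-phase 2nd-order Butterworth band-pass 6.25–10 Hz (second-order
  sections), Hilbert phase, unwrap, 250 ms moving average, time derivative;
  0.75 s trimmed per edge.  Per-lap precession frequency is the mean within
  15 cm of the field center; a lap is excluded when its in-window standard
  deviation exceeds 1.75× the mean standard deviation over all laps at that
  speed (with a tiny absolute floor so identical laps never self-exclude).
- **Single-cell / population precession**: Pearson correlation between
  position (or signed distance from each spike's own field center) and
  phases rotated by a global offset, the offset chosen by exhaustive 1°
  grid search to minimize the correlation; phases are wrapped to [0, 2π)
  after rotation and then treated linearly.  This is deliberately a rotated
  linear correlation, not a circular–linear coefficient.
- **Theta-sequence score**: per pacemaker cycle, the Pearson correlation of
  within-cycle spike times against the field centers of the spiking cells.
  Windows have width 1/f_θ and are anchored where the rotated phase
  (Φ + φ̃_pop) mod 2π crosses zero — i.e. shifted by (1 − φ̃_pop/2π) periods —
  so each window brackets one full precession ramp; anchoring windows at
  +φ̃_pop/2π instead cuts sequences in half and empirically nulls the metric.
  Cycles with fewer than 3 spikes or 2 distinct cells are skipped, not
  zero-filled.
- **Binned circular comparison**: 5 equal spatial bins across the field;
  circular mean ± circular SE per bin and condition; shift = circular
  difference wrapped to (−π, π].  Near-uniform phase distributions (as
  produced inside a silencing window) make per-bin circular means unstable;
  conclusions from this analysis need the published lap counts (~10³).

## 4. Map capacity

The track is circular with N_bins = L/x_res bins; same-interneuron field
centers must sit ≥ N_d = D/x_res bins apart (`verify_map` uses the symmetric
circular-distance reading, distance < N_d ⇒ violation).  The sequential
count multiplies the choices N_p·N_bins − (i−1)·(N_p/N_I)·N_d for fields
i = 1…F·N_p and divides by (F·N_p)! for choice order; it is evaluated
exactly (big-integer/Fraction) and in log space (log-gamma), with the
Stirling form F·N_p(1 + ln L − ln x_res − ln F) + Σ ln(1 − (i−1)D/(L·N_I)).
The sequential argument assumes each placed field removes N_d *new* bins; a
brute-force enumerator over unordered field sets shows this is exact for
N_d = 1 and an over-count when exclusion zones can overlap (N_d ≥ 2) — the
tests measure the gap rather than hide it.  F·N_p is rounded to the nearest
integer.

Cell assemblies of n coactive cells use n distinct interneurons, one cell
each: N_CA = C(N_I, n)·(N_p/N_I)^n.  Phase sequences of m disjoint
assemblies deplete the interneuron pool: N_PS = Π C(N_I−(i−1)n, n)·(N_p/N_I)^n.
Both are evaluated via log-gamma, with the printed Stirling expansions as
variants.  Note: for the headline population (N_p = 10⁴, N_I = 10³, n = 100)
the assembly formula evaluates to ≈10²⁴⁰; the accompanying prose figure of
10⁵⁰⁰ is not reproducible from the formula, and this package reports the
formula's value.

## 5. What the synthetic protocols emulate — and what they do not

The simulator is its own data generator; all experiments are simulations of
idealized protocols: constant-speed straight runs, a perfectly sinusoidal
common pacemaker, one place field per cell with a Gaussian drive, and
stationary parameters within a lap.  Real recordings differ in ways these
tests deliberately do not capture: variable running speed and head
direction, theta harmonics and cycle-length variability, inhomogeneous
interneuron classes, plasticity, and measurement noise in position and LFP.
Passing tests therefore validate the *mechanism* (entrainment, saddle-node
escape, inheritance of precession, density-dependent sequence degradation)
and the analysis pipeline, not a fit to any particular animal's data.

Emergent field widths come from the interplay of drive, inhibition and
noise: with the defaults, the place cell fires over ~0.3–0.45 m (drive
σ = 40–45 cm) and ~12 m at the ventral pole (σ = 6 m), consistent with the
field sizes the model is meant to produce; the ventral pole's one-cycle
precession is stochastic (roughly three laps in four at the printed
parameters), which is why pole protocols use a majority vote over ≥5 laps.

Default protocol scales follow the published ones where stated (1050
silencing laps, 30 pooled laps, N_p = 1000 for the density sweep, 100 trials
per envelope amplitude); where unstated, defaults are 20 laps per condition
and 10 map repeats.  The test suite and acceptance checks run some network
protocols at N_p = 100–200 with 2–3 repeats — enough to resolve the
qualitative orderings they assert — purely as a configuration choice; the
experiment functions keep the published scales as defaults.

## 6. Known limitations

- Forward Euler with post-update thresholding has O(dt) spike-time bias;
  all published-parameter behavior is defined at dt = 0.1 ms.
- The envelope-sweep amplitude grid (110–250 pA in 15 steps) brackets the
  weak-to-strong drive range; the reported one-cycle upper bound is the mean
  spike count at the last grid point whose modal winding is one, so its
  resolution is set by the grid spacing (~10 pA ≈ 3–4 spikes).
- The silencing-protocol phase-shift analysis is reported but fragile at
  small lap counts (see §3).
- Capacity counting treats fields as distinguishable labeled choices and a
  circular track; non-uniform field sizes and 2-D environments are out of
  scope.
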