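# thetacomp

A spiking-circuit model of hippocampal **theta phase precession** and
**theta-sequence compression**, built around the idea that precession
originates in CA1 *interneurons* entrained by the medial-septum pacemaker and
is inherited by the place cells they inhibit.

The package is for computational neuroscientists who want to simulate,
analyze, and extend this circuit: it contains a deterministic-given-seed
leaky integrate-and-fire (LIF) simulator with conductance synapses, the
reduced phase-oscillator analytics that explain the circuit's dynamics, the
standard spike-phase and sequence metrics, and the combinatorics of
place-field maps under a same-interneuron exclusion constraint.

## The model in brief

An interneuron firing tonically at intrinsic frequency ω(I) and weakly forced
by an 8 Hz pacemaker current reduces, after cycle averaging, to the Adler
equation for its phase lag Δφ = φ − θ:

```
dΔφ/dt = Δω − A·sin(Δφ),      A = Q₀·z₁/2
```

with detuning Δω = ω − ω_θ and synchronization factor A set by the pacemaker
amplitude Q₀ and the sinusoidal PRC component z₁.  For |Δω| < A the
interneuron **locks** at Δφ = arcsin(Δω/A) — so the family of stable locking
phases spans exactly 180° — and for |Δω| > A it **precesses** at frequency
f = √(Δω² − A²)/2π.  Outside a place field the interneuron sits in the
locking regime; when its partner place cell fires, the extra excitatory
drive pushes it through the saddle-node into precession, and the place cell
(gated by the interneuron's inhibition) precesses with it.  Requiring
f = v/(2R) ties the detuning to running speed v and field radius R via
(Δω)² = A² + (πv/R)².

On a track, place cells that couple to the same interneuron must keep their
field centers at least an exclusion distance D apart or sequences are
disrupted; the number of admissible spatial maps, cell assemblies, and phase
sequences under that constraint is counted exactly and by Stirling
approximation in `thetacomp.capacity`.

## Worked example

```python
import math
from thetacomp import phase_reduction as pr
from thetacomp import experiments as xp

p = pr.PhaseReductionParams(detuning=2*math.pi*1.25, sync_factor=2*math.pi*0.75)
print(pr.classify_regime(p), pr.precession_frequency(p))

result = xp.run_minimal_pair(seed=0, n_laps=20)
print(result.summary["modal_advance_deg"], result.summary["out_rate_hz_mean"])
```

prints

```
pulling 1.0
360.0 8.059791385068552
```

The reduced oscillator with Δω = 2π·1.25 rad/s and A = 2π·0.75 rad/s is in
the frequency-pulling regime and precesses at exactly 1 Hz (a 3–4–5
triangle in angular units).  In the full spiking circuit at 40 cm/s, the
interneuron fires at ~8 Hz, fully entrained to the pacemaker outside the
place field, and advances through one full cycle — 360° — of pacemaker phase
across the field, the modal outcome over 20 noisy laps.

The same experiment layer reproduces the circuit's other signatures:
`run_speed_sweep` (precession frequency grows ~linearly with running speed),
`run_dorsoventral` (a 180° locking-phase gradient from a common pacemaker),
`run_envelope_sweep` (one-cycle precession is modal while the place cell
fires ~10–25 spikes per crossing), `run_network_density` and
`run_noise_sweep` (sequence compression degrades with field density and
interneuron noise while single-cell precession survives), and the
perturbation protocols.  Each is also a `thetacomp` CLI subcommand:

```bash
thetacomp reduced --detuning 7.85 --sync-factor 4.7
thetacomp simulate-pair --laps 20 --out out/pair
thetacomp capacity --n-pyr 10000 --n-int 1000 --fields-per-cell 0.2
```

## Layout

- `thetacomp.phase_reduction` — reduced phase model: regimes, closed-form
  trajectories, PRC averaging, speed constraint.
- `thetacomp.lif_network` — LIF populations, conductance synapses,
  pacemaker/place drives, speed laws, dorsoventral parameter sets,
  perturbation protocols (numba-accelerated kernel).
- `thetacomp.metrics` — instantaneous theta frequency, spike phases,
  phase–position correlations, per-cycle sequence scores, cycles precessed,
  binned circular statistics.
- `thetacomp.capacity` — constrained map generation/verification and the
  counting formulas with a brute-force enumeration oracle.
- `thetacomp.experiments` / `thetacomp.cli` — config-driven experiment
  protocols and the command-line interface.

See `docs/methods.md` for modeling assumptions, parameter tables, numerical
conventions, and known limitations.
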