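# Methods

This note documents the models, numerical choices and known limitations of
`itokit`: what is simulated, what is fitted, and what passing tests do and
do not establish.

## Ito model

Ito is modelled with two independent Hodgkin–Huxley gates,

    I_to = g_to · a · i · (V − E_rev)   [pA/pF],

activation `a` and inactivation `i` relaxing first-order toward
voltage-dependent steady states:

    a∞(V) = 1 / (1 + exp((act_vhalf − V) / act_k))
    i∞(V) = 1 / (1 + exp((V − inact_vhalf) / inact_k))

Both slope factors are reported positive; each curve's orientation is
fixed by its equation (activation increasing, availability decreasing), so
a single positive-k convention serves both genotypes.

Parameters per genotype (from the whole-cell characterization of
Kv4.3+KChIP2 in HEK293 cells at 22 °C):

| parameter | units | WT | T361S |
|---|---|---|---|
| act_vhalf | mV | −13.69 | −22.98 |
| act_k | mV | 11.35 | 9.67 |
| inact_vhalf | mV | −41.16 | −54.30 |
| inact_k | mV | 5.37 | 8.56 |
| tau_rec (at −80 mV) | ms | 27.33 | 81.17 |
| g_to | nS/pF | 3.998 (calibrated) | 1.5 × WT |

**Reversal potential.** E_rev is the potassium Nernst potential of the
recording solutions (5 mM external K⁺; 120 mM K-gluconate + 24 mM KCl
internal) at 22 °C: −85.5 mV. Configurable.

**Time constants.** Only the recovery time constant at the holding
potential is measured; the remaining kinetics are model choices, exposed
in the parameter set:

* `tau_act = 0.5 ms`, voltage-independent. Kv4.3+KChIP2 activation is
  fast; the specific value is chosen well below both the inactivation time
  constants and the analysis windows so that the peak of `a(t)·i(t)` under
  a voltage step occurs while `i` has barely moved. This is what makes
  peak-based Boltzmann analysis recover the generating parameters without
  protocol bias: with slower activation (e.g. 1.5 ms) the peak gating
  factor varies with voltage through `tau_i(V)` and `i∞(V)`, and the
  fitted activation V½ acquires a bias of order 0.1 mV. At 0.5 ms the
  residual worst-case round-trip bias is 0.04 mV (WT activation V½), with
  all other parameters at or below 0.01 units.
* `tau_i(V) = tau_dep + (tau_rec − tau_dep) · w(V)`, with
  `w(V) = σ(V)/σ(−80)` and `σ(V) = 1/(1+exp((V+50)/8))`. The
  normalization pins `tau_i(−80) = tau_rec` exactly — the recovery
  protocol measures recovery at the −80 mV holding potential, so the model
  must reproduce the measured constant there. `tau_dep = 80 ms` governs
  decay during depolarizing steps (essentially complete within the 500 ms
  activation step) and is shared by both genotypes; genotype differences
  in depolarized inactivation rate are not resolved by the recovery data
  and are not modelled.

**Conductance calibration.** The wild-type g_to is calibrated once so the
noise-free simulated WT peak density at +60 mV, measured exactly as the
analysis stage measures it, equals the reported group mean (557.9 pA/pF);
the value is frozen in `G_TO_WT_DEFAULT` and re-derivable via
`calibrate_g_to()`. The mutant conductance is 1.5 × WT, mirroring the
mutation's increased surface expression. With that single scale factor the
mutant's simulated density at +60 mV comes out at ≈799 pA/pF (+43%) purely
from the kinetic shifts — close to, but not tuned to, the reported
807.79 pA/pF (+45%).

**Voltage-clamp integration.** Under a piecewise-constant command the gate
ODEs are linear, so each segment is advanced with the exact exponential
update; the only discretization is the 10 kHz sampling grid. This removes
solver tolerance as a noise source in the synthetic-data path.

## Synthetic cohorts

The generator emulates the study's three protocols from a −80 mV holding
potential, each sweep preceded by 50 ms at holding (the analysis baseline
window):

* activation: 500 ms steps, −40…+60 mV in 10 mV increments (11 sweeps);
* inactivation: 1000 ms prepulses −100…0 mV, then 300 ms test at +60 mV;
* recovery: 500 ms P1 at +60 mV, gap at −80 mV of
  {2, 5, 10, 20, 50, 100, 200, 350, 500} ms, 200 ms P2 at +60 mV.

Step ranges bracket both genotypes' midpoints with at least three points
per Boltzmann shoulder. The inter-sweep interval is 5 s (≫ both recovery
constants), so each sweep starts from holding steady state.

Cell-to-cell dispersion targets the reported group SEMs at the reported
n: each kinetic parameter is drawn Normal with sd = SEM·√n (e.g. WT
activation V½: 1.48·√15 ≈ 5.7 mV), conductance Normal with CV matched to
the reported density SEM, capacitance lognormal (median 12 pF, geometric
sd 1.3). Recording noise is additive white Gaussian with sd = 1% of the
cell's peak activation current (floor 5 pA). Draws use per-cell substreams
spawned from the master seed, so cohorts are bit-reproducible and prefix-
stable in n.

What the generator does *not* emulate: leak and capacitive transients,
series-resistance error (85% compensated in the recordings), endogenous
HEK293 backgrounds, liquid-junction potentials, correlated (1/f) noise,
or correlations between kinetic parameters across cells. Passing tests
therefore show that the analysis chain is unbiased and well-calibrated for
data with this idealized error structure — not that it is robust to every
artifact of real recordings.

## Analysis stage

* **Peaks** are maxima after baseline subtraction (mean of the 10 ms of
  holding preceding the depolarizing step). For the inactivation family
  the baseline is taken before the *prepulse*, not immediately before the
  test pulse: at depolarized prepulses a genuine steady window current
  flows, and subtracting it would dent the availability curve near its
  foot by several percent. Recovery sweeps use a single pre-P1 baseline
  for both pulses (short gaps are shorter than a baseline window).
* **Smoothing.** Before peak detection the cohort analysis applies a 1 ms
  centered moving average. A raw maximum over thousands of noisy samples
  is an order statistic inflated by ~3 noise sd, which measurably biases
  the fitted activation curve (≈ +0.65 mV in V½ at the default noise);
  the smoother suppresses the inflation while attenuating the true peak
  by <0.2% (its width is far below the decay constants). This mirrors the
  low-pass filtering applied to real recordings.
* **Activation curves** are built from normalized chord conductance
  G(V) = density/(V − EK), the standard for A-type currents without tail
  protocols. Fitting normalized *current* instead moves the apparent V½
  ~15 mV depolarized (the driving-force gradient); a test documents this
  magnitude.
* **Fits** are unweighted nonlinear least squares (lmfit/Levenberg–
  Marquardt, xtol 1e−8). Boltzmann fits estimate a free amplitude and
  additive offset alongside V½ and k, which makes the fitted parameters
  exactly invariant to uniform offsets and positive rescalings of the raw
  currents. Initialization: V½ at the half-range crossing, k = 8 mV
  (activation) / 6 mV (inactivation); recovery τ at the first interval
  exceeding 1 − 1/e of the range. Flat data and sub-4-point curves are
  rejected as degenerate; non-convergence and non-positive slope/τ raise
  structured errors.
* **Statistics**: mean ± SEM (sd/√n, ddof 1); unpaired two-tailed
  Student's t with pooled variance (a paired mode exists but is unused);
  percent difference 100·(mean_B − mean_A)/mean_A. Zero pooled variance
  with unequal means reports p = 0 with a warning flag.

## Atrial action-potential model

The baseline cell is a deliberately compact human-atrial-like myocyte in
HH form — fast Na⁺ (m³hj), L-type Ca²⁺ (d·f, fixed Ca-dependent
inactivation factor, effective reversal +65 mV), rapid and slow delayed
rectifiers, ultrarapid atrial K⁺ (ua³ui), inward rectifier, Na⁺ background
leak, and the package's Ito — with fixed intracellular concentrations (no
calcium cycling). Gate kinetics follow standard human-atrial
formulations; conductances are calibrated once and frozen to an atrial
phenotype: resting Vm ≈ −78 mV, overshoot ≈ +21 mV, APD90 ≈ 226 ms at
BCL 1000 ms, monotone APD90 shortening toward BCL 500 ms (rate adaptation
carried chiefly by incomplete recovery of L-type inactivation at short
diastolic intervals). The module defines a minimal baseline-cell
interface (`state_names`, `initial_state`, `rhs`), so a full published
atrial model can be plugged in without touching the pacing or APD code.

Mutant arm: T361S steady-state curves and recovery τ, conductance
1.5 × WT (`ito_scale`), with an additional `density_scale` knob (default
1.0) for scaling current density independently of gating. Clamp-measured
kinetics are used in the 37 °C cell without temperature correction, and
the Ito reversal is the myocyte EK (−86.8 mV); both arms are treated
identically, so the WT−mutant contrast is unaffected by these conventions.

Numerics: LSODA (stiff-capable) at rtol 1e−6 / atol 1e−8; each beat is
integrated in two smooth segments (1 ms, −40 pA/pF stimulus on/off) so
the solver never steps across a discontinuity; 10 s unpaced equilibration
from the algebraic resting point precedes pacing; output sampled at
0.25 ms. APD90 of beat 40 moves by ~1e−4 ms when tolerances are tightened
10×, and by <1e−4 ms between beats 39 and 40 (quasi-steady state).

APD90 per beat: amplitude = peak − pre-stimulus Vm; onset at maximum
upstroke velocity; end at the first interpolated downward crossing of
peak − 0.9·amplitude. Beats with no upstroke past −40 mV or no
repolarization before the next stimulus are flagged, never dropped
silently.

Because no APD values are printed for the original simulation, the AP
stage's claims are property-based: mutant APD90 < WT APD90 at all six
BCLs (1000…500 ms, beat 40), APD90 non-increasing with faster pacing,
monotone in Ito conductance, solver-tolerance invariant. The calibrated
model gives a large mutant shortening (≈120 ms at BCL 1000); its
magnitude is a property of this baseline cell, not a measured quantity.

## Problem sizes

Defaults throughout are the study's own: cohorts of 15 (WT) and 17
(T361S) cells with all three protocols per cell; 25 seeded replicates for
the calibration checks; 40 paced beats per BCL at six BCLs. The
stochastic-realism check pools the 2-SEM coverage criterion over
parameters and replicates (per-parameter coverage of a mean of n draws
with sd = SEM·√n is ~95% by construction; the pooled rate is the stable
statistic at 25 replicates).

## Known limitations

* The two-gate Ito has a single inactivation time constant per voltage;
  fast/slow inactivation components and closed-state inactivation of
  Kv4.3 are not represented.
* KChIP2 is folded into the parameter values, not modelled as an entity.
* `tau_dep` is shared across genotypes (unmeasured); genotype differences
  in depolarized decay are absorbed into the conductance calibration.
* The baseline myocyte has no calcium handling, Na⁺/K⁺ pump or NCX, so
  long-timescale rate dependence (minutes) and Ca²⁺-mediated effects are
  out of reach; only beat-scale restitution is represented.
* Markov channel models, tissue-level propagation and re-entry are out of
  scope.
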