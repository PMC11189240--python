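# Methods

This note documents the models, the synthetic input stage, the numerical
choices and the known limitations of `lsoif`.

## Membrane models

All six variants are single-compartment IF models sharing
`C dV/dt = I_all` with C = 24 pF. The internal unit system is
mV / ms / nS / pF / pA, under which the equation closes without conversion
factors (pA/pF = mV/ms, nS·mV = pA). Spike-current amplitudes quoted in nA
are stored ×1000 in pA.

Shipped parameter presets:

| parameter | PLk/PSp | PEx | ALk/ASp | AEx |
|---|---|---|---|---|
| g_L (nS) | 26.4 | 26.4 | 14.4 | 14.4 |
| E_L (mV) | −60 | −60 | −56 | −56 |
| g_K (nS) | — | — | 21.6 | 21.6 |
| E_K (mV) | — | — | −75 | −75 |
| g_T (nS) | — | 26.4 | — | 26.4 |
| V_T (mV) | — | −46.6 | — | −47.3 |
| K_T (mV) | — | 1.8 | — | 1.8 |
| V_th (mV) | −45.1 | −10 | −45.8 | −10 |
| V_ref (mV) | −60 | −60 | −60 | −60 |
| T_ref (ms) | 2.0 | 2.0 | 2.0 | 2.0 |

Spike-mimicking current (PSp/ASp):
`I_spike = A_1 e^{−(t−s)/τ_1} − A_2 e^{−(t−s)/τ_2}` with A_1 = 24 nA,
A_2 = 12 nA and τ_1/τ_2 = 0.17/0.37 ms (passive) or 0.15/0.30 ms (active).

KLVA gating: `d' = α_d (1 − d) − β_d d` with the symmetric exponential
rates given in the README; the steady state is logistic in V with midpoint
−50 mV and slope scale 8 mV, about 22% open at −60 mV. The active resting
potential (leak/KLVA balance) is −60.56 mV.

### Spike and refractory semantics

* A spike is recorded at the first integration sample whose voltage
  reaches V_th outside the refractory window. The exponential variants'
  crossings are therefore quantized to the step and occur slightly
  (~0.1 ms) after the soft spike initiation at V_T; this is emergent and
  not corrected for.
* Resetting variants (PLk/PEx/ALk/AEx) clamp V at V_ref for T_ref = 2 ms.
  The KLVA gate keeps integrating at the clamped potential — this is what
  produces the elevated hazard at 3–4 ms intervals in the active models
  (the gate partially closes during the clamp, transiently raising
  excitability on release).
* Spike-current variants (PSp/ASp) never reset the voltage; only spike
  detection is disabled for T_ref. Their recovery is governed by the
  biphasic spike current, whose hyperpolarizing phase outlasts the
  refractory period — hence their insensitivity to T_ref in the
  refractory sweep and the modest ISI-histogram peak at exactly 2 ms.
* Initial conditions are the variant's resting state (root of the
  steady-state current, gate at d_inf). This removes onset transients, so
  rates are counted over the full record including onset.

### Integration

Forward Euler with dt = 0.002 ms by default (dt ≤ 0.01 ms accepted, and
enforced). The state update uses the conductance samples and state at the
left endpoint of each step. The exponential current's argument is clipped
at +20 before exponentiation so a diverging upswing cannot overflow before
the detection threshold is reached. The spike-mimicking current is carried
as two exponentially decayed state variables updated multiplicatively per
step, which equals the exact kernel sum over all past grid-aligned onsets;
the scalar reference stepper (`step`) instead prunes onsets older than
10 τ_2 (relative residual < 5e−5). Halving dt from 0.002 ms changes 40-s
spike counts by well under 2% (tested).

## Synthetic input stage

20 excitatory and 8 inhibitory afferents, each an independent Poisson
process with its own named RNG substream derived from
(seed, experiment, condition, fiber); input realizations therefore depend
on the stimulus condition but never on the model variant, so all six
models can be driven by bit-identical inputs.

Phase-locked fibers use the intensity
`λ(t) = rate · e^{κ(cos(2π f_m t − φ) − 1)} / (e^{−κ} I_0(κ))`, i.e. a von
Mises profile normalized so the cycle-averaged rate equals `rate`, with κ
solved from I_1(κ)/I_0(κ) = VS to 1e−10. Sampling is by thinning against
the intensity maximum — exact and reproducible. Empirical vector strength
of generated trains matches the prescribed VS within ±0.01 at 40 s
(tested).

Phase-difference convention: excitation is locked at phase 0; a phase
difference Δφ places the inhibitory intensity peak at −Δφ within the
cycle, i.e. negative Δφ delays inhibition. At 300 Hz the response is then
maximal near Δφ = −135° (inhibition arriving long after excitation within
the cycle) and minimal near +45°, where the inhibitory volley arrives just
before the excitatory one so that the slower IPSG (0.32 ms) peaks together
with the EPSG (0.16 ms). The mirrored convention is a detectable sign
error: it flips the tuning curve around 0°.

Conductance traces quantize spike times to the integration grid (round to
nearest sample) and truncate the unitary alpha kernel at 12 τ_syn
(relative residual < 1e−4).

Experiment-specific drives:

* binaural AM (phase tuning): both fiber groups at `λ(f_m)` and `VS(f_m)`,
  level-independent;
* binaural ILD: both groups homogeneous, excitation at the ipsilateral
  level's sigmoid rate, inhibition at the (ipsilateral + ILD) rate —
  ILD = contralateral − ipsilateral level;
* monaural AM: excitation AM-locked, inhibition homogeneous at the
  30 spikes/s spontaneous floor;
* ISI statistics: excitation homogeneous at the stimulus level's rate,
  inhibition at the spontaneous floor.

## Experiments, grids and problem sizes

Default 40 s of simulated time per stimulus condition (40-s rates at
~120 spikes/s have a sampling SE of ~1.7 spikes/s). Grids: phase −180° to
+180° in 22.5° steps; ILD −45 to +50 dB in 5 dB steps; monaural modulation
frequency {50, 100, 150, 200, 250, 300, 350, 450, 600, 800, 1000, 1200} Hz
— the 100–400 Hz region is sampled at 50 Hz resolution because the
physiological (and simulated) tuning peak lies there, typically near
250 Hz, and a sparser grid clips the measured peak rate. Peak/trough are
grid extrema. Tests and short demonstrations use 1–10 s per condition;
the acceptance script uses the full 40 s.

The nine response criteria (targeted, with accepted in parentheses where
loosened): monaural peak 120–160, trough 0–30, depth >110; phase peak
110–140 (90–140), trough 10–30, depth >90 (>70); ILD peak 110–140
(110–160), trough 10–30, depth >90. Range checks are inclusive at the
bounds. Several of the reference measures sit within 1–2 spikes/s of
these bounds (e.g. passive phase peaks just above 90), so single-
realization scores can flip at the knife edge; the comparison band of
±5 spikes/s used in the end-to-end tests reflects roughly 3× the sampling
SE plus cross-implementation integration differences.

## ISI statistics

Histograms use 0.2-ms bins from 0; density is normalized by bin width (s)
times total interval count. The hazard is N_i/(T_bin S_i) with S_i the
survivor count; computation stops at the first bin whose survivor count
falls strictly below 2% of the total (that bin excluded). Conditional
means of ISI_{n+1} are reported for ISI_n bins holding strictly more than
0.5% of all intervals. Simulated trains are renewal-like: conditional-mean
curves are flat (no AHP or other slow process is modelled; reproducing
negatively correlated successive intervals would require adding a ~10-ms
slow current, which is out of scope).

## Subthreshold characterization

The impedance is defined by quasi-active linearization about the operating
point: Y(f) = g_L + iωC + g_K [d_inf + (V_op − E_K) d_inf′ / (1 + iωτ_d)],
validated against a small-amplitude (10 pA) sinusoidal-current probe
simulation; the two agree within 2% over 10–2000 Hz (tested, typically
<0.2%). At −60 mV the passive low-frequency resistance is 1/g_L =
37.9 MΩ and the active linearized resistance 38.1 MΩ; the KLVA gating
relaxation makes the active |Z| exceed the passive one between roughly
40 and 400 Hz. The probe holds active membranes at the operating point
with a constant bias current.

## Calibration utilities

The exponential variants' free parameters are searched on the grid
V_T ∈ [−50, −40] mV (0.5 mV coarse, 0.1 mV fine around coarse passers —
the coarse/fine staging is read as mV), K_T ∈ [1.2, 4.0] mV (0.2 mV),
V_th ∈ [−30, 0] mV (5 mV), with g_T fixed at 26.4 nS, judged on the six
binaural measures (targeted level for active, accepted for passive). All
passers are returned unranked; no best-fit ordering is defined. A full
search at 40 s per condition is expensive (~2 h/grid point-set on one
CPU); a reduced-duration screening pass with 40-s confirmation is the
intended workflow (`duration` argument).

## What the synthetic inputs do and do not emulate

The input stage reproduces the firing rates and envelope phase locking of
spherical-bushy-cell and MNTB afferents as summary statistics; it contains
no cochlear filtering, no auditory-nerve refractoriness or adaptation, no
across-fiber correlation, and no level dependence of AM-driven rates.
Passing tests therefore demonstrate fidelity to this statistical input
model, not to arbitrary real sound input. Model outputs are sensitive to
the near-threshold fluctuation statistics: in low-rate regimes the output
rate varies by tens of percent for ~2% changes in membrane noise, so
small implementation details (RNG, kernel discretization) shift absolute
rates by a few spikes/s even between faithful implementations of the same
equations.

## Known limitations

* Tonic-firing LSO neurons only; no phasic/principal-cell, multi-
  compartment or Hodgkin–Huxley variants, and no coincidence-counting
  reference model.
* Forward Euler only, by design; no adaptive or implicit integrators.
* No serial ISI correlations (no slow adaptation current).
* Computation-time benchmarking is not an output; relative costs are
  hardware-dependent.
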