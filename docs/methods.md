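# Methods

## The model

`ca1ephys` simulates the subthreshold current-clamp behaviour of a CA1
pyramidal neuron reduced to an isopotential compartment carrying two
currents: an ohmic leak and the hyperpolarization-activated cation current
I_h. With voltage in mV, time in ms, specific quantities per cm² and
injected currents in pA, the membrane balance is

    Cm dV/dt = -(V - e_pas)/Rm - gbar · l · (V - E_h) + (I_inj + I_hold)/A

and the single gating variable `l` follows first-order kinetics
`dl/dt = (l∞(V) - l)/τ_l(V)` in the Borg-Graham thermodynamic form:

    l∞(V) = 1 / (1 + exp(-(V - Vl½)/kl))            kl < 0
    α(V)  = exp(c·ζ·(V - Vt½)),  β(V) = exp(c·ζ·γ·(V - Vt½))
    τ_l(V) = β(V) / (q_t · a0t · (1 + α(V))),  q_t = q10^((T - T_ref)/10)

Because `kl` is negative, activation rises with hyperpolarization; during a
negative current step the delayed opening of I_h pulls the voltage back up
after its initial dip, producing the characteristic sag. The package ships
six optimized parameter rows (wild-type and amyloidopathy-model groups at
three ages) as a JSON fixture; `cell_model_for_group("WT-1m")` builds a
ready-to-run cell from any of them.

### Fixed constants and why

| constant | default | rationale |
|---|---|---|
| E_h | -30 mV | standard reversal in the predecessor I_h model family; configurable |
| Cm | 1 µF/cm² | textbook specific capacitance; configurable |
| c | 0.0378 mV⁻¹ | F/RT at ≈34 °C |
| q10, T_ref | 4.5, 33 °C | rate temperature scaling of the I_h kinetics |
| T | 34 °C | recording/simulation temperature |
| membrane area A | 2.0·10⁻⁴ cm² | puts Rin = Rm/A in the physiological 100–200 MΩ range |

The default geometry is a single compartment; it is the surface on which
all headline numbers are computed. An optional ball-and-stick mode attaches
a passive dendritic cable whose I_h density rises sigmoidally with distance
(fold-increase A_f = 8, half-distance 280 µm, steepness 50 µm); it exists to
demonstrate the dendritic-gradient effects discussed under *Limitations*
and is not used by the acceptance computations.

### Integration

The integrator advances the gate by its exact exponential relaxation toward
`l∞(V)` over each step and the voltage by one backward-Euler step of the
membrane equation, which is linear in V once `l` is frozen. The scheme is
unconditionally stable; its accuracy contract is the grid-refinement
invariant tested in the suite: at the default dt = 0.025 ms, halving dt
moves no voltage sample by more than 0.05 mV. Exponents in α and β are
clamped at |x| = 50 so extreme voltages degrade gracefully instead of
overflowing. The hot loop is compiled with numba; a pure-python fallback
implements the identical scheme. Simulated steady states are independently
cross-checked in the tests against brentq root-finding on the algebraic
balance and against scipy's LSODA on the coupled system.

## Feature extraction

All features are computed by our own numpy routines with explicit missing
values (NaN), never silent zeros:

- **RMP**: mean of ≥100 ms of unstimulated baseline; cells above -50 mV are
  flagged for exclusion.
- **Input resistance**, two estimates: Ohm's law on the bias current that
  holds the cell at -65 mV, and the least-squares slope of end-of-step
  voltage vs current over the -100/-50 pA sweeps.
- **Membrane time constant**: least-squares fit of
  `V(t) = V_ss + (V_on - V_ss)·exp(-(t - t_on)/τ)` from stimulus onset to
  the sag trough, all three parameters free. Fits outside (0.5, 200] ms are
  reported missing with a diagnostic.
- **Sag**: mean of the last 10% of the step minus the trough voltage,
  clipped at zero. The trough is located (and read) on a ~1 ms
  moving-average copy of the trace: the raw minimum of a noisy sweep is an
  extreme-value statistic biased downward by several tenths of a mV at
  40 kHz sampling, and the 1 ms window removes that bias without touching
  the slow trough itself.
- **Spikes**: one event per upward crossing of -10 mV, timed at the local
  maximum before the next downward crossing; a trace ending mid-spike keeps
  the event and flags the train.
- **First-AP shape**: onset is the first sample of the contiguous
  dV/dt ≥ 20 mV/ms run preceding the peak (the derivative is lightly
  smoothed for this localisation only); amplitude = peak - onset voltage;
  width is the full width at half that amplitude with linear interpolation
  between samples; max dV/dt comes from raw centered differences.
- **Firing**: instantaneous frequencies 1000/ISI_i for the first ten
  intervals of the 300 pA sweep, mean rate over the step, and an
  eFEL-style adaptation index (mean of successive normalized ISI
  differences).

The 20 mV/ms onset criterion, the last-10% steady-state window and the
width-at-half-height definition are configurable; they are the package's
documented choices where the field uses several conventions.

## Parameter fitting

`IhStepModel` binds the model to a family of reference hyperpolarizing
sweeps (default -150/-100/-50 pA) and minimizes the pooled pointwise
voltage residual with bounded trust-region least squares (scipy TRF),
multi-started from seeded perturbations of a generic mid-bounds initial
point. Scale-like parameters (Rm, gbar, a0t, ζ) are optimized in log
space. `fit()` returns an `IhFitResults` with the winning parameters,
pooled and per-trace RMS in mV, the full start ensemble (reported rather
than discarded, because the kinetic parameters can trade off against each
other in the weakly identified regime) and a `summary()` table.

Candidates are simulated under the *reference* bias current — the current
actually injected when the references were recorded. This matters for
identifiability: if the bias were re-solved for every candidate, any error
in the leak reversal would be absorbed into the bias and leave the voltage
trajectory unchanged, making e_pas unrecoverable in principle. Under the
reference bias a wrong e_pas appears as a baseline offset in the residual.
A `hold_mode="recompute"` option provides the other behaviour for traces
whose bias is unknown.

Noiseless self-fits recover a generating parameter row essentially exactly.
With noisy references the conductance estimate inherits noise along the
soft direction in which gbar, Vl½ and kl jointly reshape the activation
curve over the narrow voltage window the protocol probes; the start
ensemble collapsing to one error value is the signature of that valley.

## The synthetic cohort generator

The generator's job is to produce protocol-conforming sweep families with
*known* ground truth so the extractor and the downstream statistics can be
tested end to end.

- **Between-cell variability**: each cell multiplies the group's parameter
  means by unit-mean lognormal factors (CV 0.1 by default; magnitudes for
  the negative-valued voltages), keeping signs and positivity.
- **Subthreshold sweeps** are exact model simulations plus additive white
  Gaussian noise (0.2 mV default); with zero noise they are bit-identical
  to `simulate_step` output.
- **Spiking sweeps** are stylized: spike peak times follow the group rate
  model (rate = slope·(I - rheobase), geometric ISI sequence whose
  first-ten mean matches the rate and whose tenth/first ratio is the
  adaptation ratio), and each spike is rendered from a triangular AP
  template (linear rise and fall, width at half height exact by
  construction) spliced onto integrate-and-fire-style charge-up segments
  that relax toward the take-off voltage with the cell's passive time
  constant. Scheduling the spikes, rather than letting threshold crossings
  emerge, is what makes spike count, instantaneous frequency and AP width
  exactly controllable — the property the closure tests rely on.
- **Group phenotypes**: default group specs encode the qualitative
  pattern being emulated — wider first AP in the amyloidopathy-free mutant
  group, ~12–15% narrower with developing amyloidopathy, lower firing
  slope in the strong-amyloidopathy group — with the recorded cohort sizes
  (14/12/19/11/15/21 cells).
- **Sag calibration**: `calibrate_sag` rescales gbar (and, when needed,
  kl) so the noiseless group-mean sag matches printed targets within 2%,
  and raises with the attainable range when a target set cannot be met
  (see *Limitations*); `on_unachievable="best"` returns the least-squares
  compromise with its full diagnostic record.

What the generator does **not** emulate: coloured (1/f) recording noise,
electrode and access-resistance artefacts, channel stochasticity,
conductance-based AP shapes, bursting, and within-cell nonstationarity.
Passing tests therefore certify the pipeline's internal consistency and
calibration, not performance on raw experimental recordings.

## Statistics and classification

Group comparisons run per feature, per current and per age: Shapiro-Wilk
normality at α = 0.05 in each group routes to a two-sided equal-variance
t-test (Welch optional) or a Mann-Whitney rank-sum test; significance is
declared at p ≤ 0.05 with no multiple-comparison correction, and ages are
never pooled. The suite verifies the type-I rate on null cohorts stays in
[0.03, 0.07].

Trace classification uses scikit-learn ensembles behind a fold engine of
our own: bagged deep trees (100 estimators, bootstrap fraction 1.0) or
AdaBoost-boosted depth-3 trees (100 estimators, learning rate 0.1) under
k-fold cross-validation (k = 10) in which every row is predicted exactly
once while held out. Missing features are imputed with training-fold
column medians; a split that leaves a class absent from a training fold is
redone stratified and flagged. The default feature set is the
current-dependent catalogue (τ, sag, spike counts, AP shape per current,
instantaneous frequencies). The unit of classification is the per-cell
feature row; per-sweep tables can be built by restricting the protocol.

## Problem sizes

The test suite and the acceptance harness use the following sizes, chosen
to exercise every contract at full fidelity where it matters: parameter
recovery runs the prescribed 8 starts on the AD-10m row; the six-group fit
quality runs 3 starts per group, since the start ensemble demonstrably
collapses to a single valley; cohorts for closure and classification tests
use 6–54 cells at dt = 0.05–0.1 ms, while the calibrated sag cohort keeps
the full n = 19 cells at dt = 0.025 ms.

## Limitations

- **Reduced geometry.** The six parameter rows were optimized against a
  full dendritic morphology with a sigmoidal I_h gradient; re-used in a
  single compartment they reproduce the fitted sweeps' qualitative
  behaviour but not every quantitative observation. Two consequences are
  documented and left visible rather than patched:
  1. the ~20% speed-up of the fitted membrane time constant between -50
     and -200 pA essentially vanishes in the single compartment (the
     modulation reappears once a dendritic I_h gradient is attached, as
     the ball-and-stick mode shows qualitatively);
  2. the printed WT-10m group-mean sag pair (5.6 mV at -200 pA *and*
     1.7 mV at -50 pA) is jointly outside the single compartment's
     attainable set — the -50 pA step only reaches ≈ -73 mV, where the
     somatic activation increment is too small relative to what -97 mV
     recruits, so the attainable sag ratio has a floor near 4.2 vs the
     printed 3.3. `calibrate_sag` reports this precisely; the benchmark
     cohort uses the balanced least-squares compromise.
- **Identifiability.** With three subthreshold sweeps, the activation
  parameters and the peak conductance are only weakly separable; the
  conductance estimate from noisy references carries the corresponding
  uncertainty even though the optimizer itself is exact on noiseless data.
- **Synthetic spiking** is phenomenological; AP-shape features beyond
  width/amplitude/peak/max-dV/dt (e.g. AHP kinetics) should not be read
  off the templates.
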