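# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of the package. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Voltage-clamp model and analysis

**Gating model.** The drug-sensitive current is
`I_Kr = g_max · m · h∞(V) · (V − E_K)`. Activation `m` relaxes exponentially
toward `m∞(V) = 1/(1+exp((V½ₐ − V)/kₐ))` with a tabulated, linearly
interpolated τ_act(V). Steady-state inactivation is the falling Boltzmann
`h∞(V) = 1 − 1/(1+exp((V½ᵢ − V)/kᵢ))` applied instantaneously — hERG
inactivation is one to two orders of magnitude faster than activation, so on
the seconds scale of a 4 s step protocol it is effectively at equilibrium.
The activation variable is carried by two components (fractions `frac_fast`
and `1 − frac_fast`) that share τ_act while opening but close with their own
τ_f and τ_s, which makes the tail current on return to holding exactly the
empirical biexponential the analysis stage fits. This construction is
deliberately phenomenological: the study's analysis fits mono- and
biexponential forms, and a generator whose truth *is* those forms makes
parameter recovery well posed. A three-state Markov chain (C ↔ O ↔ I, rates
`r₀·e^(zV)`) provides a second, mechanistic tier in which biexponential
tails *emerge* from the two nonzero eigenvalues of the rate matrix; the
suite checks the biexponential fitter against those eigenvalues (3%
tolerance) including the characteristic tail "hook" from inactivation
recovery.

**Fixed constants.** E_K = −88 mV from the recording solutions (5.4 mM
K⁺ out / 145 mM in, Nernst at 36 °C). Activation Boltzmann V½ₐ = −25 mV,
kₐ = 7 mV; inactivation V½ᵢ = −60 mV, kᵢ = 20 mV — values in the range
reported for hERG in hiPSC-CMs, selected once so that the steady-state I–V
over the −50…+40 mV protocol peaks at −20 mV, as observed. The WT τ_act
table spans 1.4 s at −50 mV to 90 ms at +40 mV. Cell capacitance defaults
to 20 pF, typical for single hiPSC-CMs.

**Calibration to printed values.** Each packaged genotype's `g_max` is
obtained in closed form from the target maximal tail density
(`gmax_for_tail_density`): the tail measurement reports the instantaneous
jump `g·(m_end − m∞(Vh))·h∞(Vh)·(Vh − E_K)` normalized by capacitance, so g
follows by inversion. The per-genotype τ_act tables are the WT table scaled
so the −30 mV ratios between cis and trans lines equal the reported 21%
(A561T) and 33% (N996I) accelerations; the deactivation constants place
τ_slow of each cis line below its trans counterpart. Tail densities within
each cis/trans pair are set equal (the study found no density difference by
phase).

**Step protocol.** 4 s steps from −40 mV holding, −50 to +40 mV in 10 mV
increments, 10 s cycle; each simulated sweep records 1 s of holding, the
step, and a 5 s tail. The exact step range is an assumption (it brackets the
−30/−20 mV analysis points and the −20 mV steady-state peak) and is
configurable.

**Measurement windows.** Steady state: mean over the final 200 ms of the
step minus the pre-step holding level (100 ms). Tail: largest-magnitude
excursion in the 500 ms after return, referenced to the mean of the final
500 ms of the tail epoch (the fully deactivated level). All windows are
module constants. With the slowest packaged τ_slow (1.2 s) the residual
un-deactivated current at the baseline window is < 3% of the slow component
and the recovered densities land within 0.5% of their calibration targets.

**Fitting.** Activation: `A(1 − e^(−t/τ)) + C`; deactivation:
`A_f e^(−t/τ_f) + A_s e^(−t/τ_s) + C` with components reordered to
τ_f ≤ τ_s. Both use multi-start nonlinear least squares over log-spaced τ
starts (deterministic), bounded τ ∈ [0.01 ms, 100 s], with an extra
opposite-sign amplitude start when the tail peaks after its first sample
(the Markov hook). Windows longer than 4000 samples are stride-decimated
before fitting — lossless in practice since every time constant of interest
exceeds the decimated sampling interval by orders of magnitude. Fits whose
residual reaches machine precision stop the multistart early. A fit is
flagged `degenerate` when τ_slow/τ_fast < 1.5 or one component carries < 1%
of the amplitude, the signature of an effectively monoexponential decay;
non-convergence is reported in the record, never raised. Fits are checked
against brute-force grid-search oracles (dense 1-D τ grid; 2-D grid plus
refinement with linear amplitude solves) at 1–2% on noise-free traces.
Whether kinetics should be fitted on the difference trace or the raw
pre-drug trace is not fully determined by the source description; the
difference trace is the default (consistent with defining I_Kr as the
drug-sensitive current), and the fitters accept any trace.

## Action potentials

The generator builds each beat from morphological targets rather than a
biophysical membrane model: a linear upstroke whose slope is exactly the
requested Vmax, a monotone PCHIP repolarization pinned to the requested
20/50/90% levels at the requested durations, and a diastole that either
ramps from MDP to the takeoff potential at the diastolic slope (spontaneous
mode — cycle length is therefore set by the slope, and a shallower slope
lengthens it) or rests at MDP until the stimulus (paced mode, takeoff from
MDP with 2 ms latency). A pacing period too short for the full AP raises a
capture-infeasibility error, or, on request, answers every second stimulus
to emulate loss of 1:1 following. No O'Hara-Rudy-class ionic model is
attempted: AP traces are parametric waveforms, which is exactly what makes
±1-sample recovery of the generating parameters a meaningful contract.

Detection is two-stage: prominent voltage peaks (≥ 20 mV prominence,
refractory 100 ms) mark candidate beats, and each takeoff is the end of the
last sub-threshold run of the lightly smoothed (0.3 ms) forward slope before
the peak, with the dV/dt threshold at 5 V/s. The takeoff-potential reading
of mDP (potential at the threshold crossing) is one of several possible
operationalizations of "minimum diastolic potential"; it is the default and
config-exposed. APDs are upstroke-referenced (takeoff to repolarization at
`peak − x%·APA`); peak-referencing can be derived from the reported peak
time. Vmax uses a Savitzky–Golay first derivative (quadratic, ~1.5 ms
window capped at half the upstroke) — exact on a linear ramp, noise-immune
otherwise. MDP and the repolarization crossings are read from a 1 ms
smoothed copy; the peak and takeoff samples are read raw because they are
sharp. Train summaries require ≥ 10 consecutive beats and report mean ±
SEM. Capture requires ≥ 95% of stimuli answered by exactly one AP within
150 ms and no ectopy. Recovery over 100 seeded noisy trains: median
absolute error ≤ 1% for APDs and ≤ 2% for Vmax (asserted in the suite).

## MEA field potentials

Each synthetic beat is a narrow biphasic spike (σ = 1.5 ms) plus a broad
repolarization wave (σ = 25 ms) whose peak sits one FPD after the spike
extremum, matching the spike-extremum-to-repolarization-peak definition of
FPD; the spike-onset reference is an alternative convention, not the
default. Injected events quantify the study's qualitative definitions:
abnormal repolarization adds an EAD-like wave at half the
repolarization-wave amplitude between the repolarization peak and the next
beat; fibrillation scales amplitudes to 18% of baseline and draws inter-beat
intervals with a realized CV of 0.35 (standardized jitter, clipped at 30% of
the period); quiescence is noise only.

The classifier applies precedence quiescence > fibrillation > abnormal
repolarization > none with thresholds: no detectable beats; median spike
amplitude < 30% of baseline *and* interval CV > 0.25; a post-repolarization
deflection ≥ 25% of the repolarization-wave amplitude on at least two beats
(on a ~12 ms smoothed trace, so broadband noise cannot mimic a deflection).
These thresholds quantify qualitative definitions and are keyword
arguments; a ±20% sweep changes ≤ 5% of calls on the 200-well synthetic
cohort, and accuracy on that labeled cohort is ≥ 95% (both asserted). A
well observed across a concentration ladder contributes its most severe
category — severity is described as progressive (quiescence preceded by
fibrillation and abnormal repolarization), and a duration-weighted
alternative is not implemented. Scores are the fixed weights
{0, 2, 3, 4}; the group score is their mean ± SEM. ΔΔFPD subtracts the mean
vehicle ΔFPD (percent change from each well's own baseline) per
concentration; no beat-rate correction of FPD is applied. Wells are single
aggregate signals — no spatial conduction analysis.

## ddPCR

λ = −ln(1 − n⁺/N) is the Poisson MLE for copies per partition (verified
against exhaustive likelihood maximization at small N). The 95% CI is a
Wilson score interval on the positive fraction mapped through the same
transform; the droplet-reader vendor's exact construction is undocumented,
so Wilson is an explicit stand-in (method switchable), not a claim of
bit-equivalence — its coverage is verified at ≈95% by simulation. FA CI
bounds take the extreme cross-channel combinations (λ_T low with λ_K high
and vice versa). The balance call uses the point estimate against the
inclusive band [0.4, 0.6]; the CI is reported alongside but does not drive
the call. Saturated channels (all partitions positive) are flagged, not
extrapolated.

## Statistics

The bespoke content is the decision tree and family definitions, not the
test statistics, which are delegated to scipy/statsmodels: two groups get
an unpaired two-sided t-test (two-sided throughout; sidedness was not
stated, and zero-variance identical groups return p = 1 by convention);
three groups get a one-way ANOVA gate at α = 0.05 with Tukey HSD post hoc
and pairwise t-tests run only when the gate opens; factorial designs get a
two-way ANOVA (type-II) with the Sidak family defined as the per-level
two-group comparisons, adjusted as 1 − (1 − p)^k. Null-simulation
calibration (type-I error 5% ± 1.5 points; Sidak FWER ≤ 5% plus Monte-Carlo
margin) is asserted in the suite. Repeated differentiations are pooled, as
in the source design; no mixed-effects modeling.

## What the synthetic data does and does not show

The generators reproduce the morphology, noise level (Gaussian white noise
only — no drift, line interference, or electrode artifacts), sampling rates
(20 kHz currents, 40 kHz APs, 12.5 kHz FP by default; tests and the
acceptance script use 4–10 kHz where the measured features are hundreds of
ms wide, keeping runtimes small without affecting recovery) and calibrated
group-level values of the study's recordings. Passing tests therefore
demonstrate that the analysis stages are correct and self-consistent — that
they recover known truth under realistic morphology and noise — not that
they would be robust to every artifact of real recordings (seal
instability, baseline wander, multi-unit MEA signals, rain in ddPCR droplet
calling). Liquid-junction and series-resistance corrections are assumed
applied upstream by the acquisition hardware.

## Known limitations

* The phenomenological current model has no activation delay (sigmoidicity)
  and treats inactivation as instantaneous; envelope-of-tails or
  fully-activated I–V protocols are out of scope, as is inactivation-
  kinetics fitting.
* The exact voltage-step range of the source protocol is an assumption
  (flagged in the protocol config).
* Event categories are per-recording; sub-minute event timing is not
  modeled.
* The reported low-pass setting of the source acquisition ("0.9 Hz") is
  almost certainly a kHz typo; the package neither applies nor guesses it —
  filtering is left to the user via the config.
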