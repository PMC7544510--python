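# Methods

This note documents the models, estimators and numerical choices behind
`vrnav`, what the synthetic-session generator does and does not emulate,
and the design decisions taken where the analysis was genuinely open.

## Coordinates and behavior

All spatial analyses live on the 200-cm circular "main track"
coordinate; the two identical semicircular corridors are pooled except
in the corridor-identity test, which works on the 400-cm loop. Signed
distances are circular, in `(−L/2, L/2]`, positive in the running
direction. The gain couples wheel displacement to virtual displacement
(`dx_virtual = g · dx_wheel`), so one lap costs `L/g` cm of running.

Trials are segmented at forward crossings of position 0, with a
hysteresis rule (a crossing opens a new trial only after ≥ 50 cm of
forward progress) so backward jitter across the line is not double
counted. Licks within 20 cm (circular, same trial) of the previous lick
share a bout; a bout is correct iff it overlaps the reward zone
(0 ± 12 cm) and triggered reward. Rewarded trials with < 5 incorrect
licks are `correct`; trials with > 5 incorrect licks are `early` if the
previous trial was correct, else `late`; exactly five incorrect licks
with reward is classified correct (the stated rules leave that count
open). Run speed comes from wheel displacement smoothed with a 250-ms
boxcar; all rate and decoding analyses use only samples with speed
> 5 cm/s, lick-position analyses use all samples. Units with waveform
trough-to-peak width < 600 µs are putative interneurons; V1 layers are
assigned from depth as L2–4 [250, 500), L5 [500, 700), L6 [700, 950) µm.

## Synthetic sessions

The generator emulates the study conditions: 200-cm corridor, landmarks
at 0/83/117 cm, gains {0.8, 1.0, 1.2} in blocks of 5–10 trials
(alternating with medium-gain blocks, ≈ 1/2 medium trials), 60-Hz
sampling, 6–9 Hz theta, and 60 trials per default session. Free
parameters the source data do not constrain were fixed once:

- **Locomotion**: Ornstein–Uhlenbeck speed (mean 25 cm/s, s.d. 7,
  τ = 2 s, clipped at 0) with brief pause epochs (rate 0.02 /s,
  ≈ 1.5 s), giving realistic occupancy non-uniformity and sub-5-cm/s
  stretches that exercise the speed gate.
- **Licking**: a lick zone around the reward whose center moves by
  `12.5 (g − 1)` cm, reproducing behavioral shifts of ∓2.5 cm at gains
  0.8/1.2; stray licks and occasional deliberate error bouts produce
  early/late trials.
- **Theta**: instantaneous frequency wanders inside 6–9 Hz (clipped OU
  around 8 Hz); the LFP is the cosine of the phase plus white noise, so
  band-passed LFP peaks mark phase 0.
- **Spiking**: each neuron is an inhomogeneous Poisson process (exact
  thinning) with intensity
  `λ(t) = [b + p · G(x_app − A sin(θ − θ0) − c_g)] · (1 + m cos(θ − θ_pref))`,
  where `G` is a wrapped Gaussian bump and the gain-g field center is
  `c_g = anchor + D (w g + 1 − w)` — the visual shift is `w (g − 1) D`.
  Positive drift amplitude `A` moves the field maximally ahead at
  `θ0 + 90°` and crosses behind→ahead at `θ0`. Optional per-neuron
  response latency (position read `Δ` seconds in the past), speed
  coupling, and session-level shared/per-region slow position-error
  processes (OU, for the coupling experiments) complete the model.
- **Covariates**: pupil size/azimuth/elevation are low-pass Gaussian
  noise, pupil size weakly speed-coupled — enough structure to exercise
  the GLM, with no claim of realism.

What the generator does **not** emulate: spike waveforms beyond a
scalar width, raw broadband LFP, visual rendering, eye movements driven
by the scene, non-Poisson spike-train structure (bursting,
refractoriness), and remapping or learning across the session. Passing
recovery tests therefore demonstrate estimator correctness under the
generative model, not robustness to every property of real recordings.

Sessions are deterministic given the config seed and round-trip
losslessly through a TSV-directory container (17-significant-digit
floats).

## Estimators

**Profiles.** Spike counts (spikes resampled onto the 60-Hz grid) and
occupancy are binned at 2 cm, each circularly smoothed with an 8-cm
s.d. Gaussian, then divided. Spatial-tuning significance uses a
circular time-shift null (spike train rotated by a random period > 5 s,
500 shuffles by default) with statistic max(rate) − mean(rate).

**Permutation criterion.** All permutation tests declare significance
by the exact p-value `p = (1 + #{null ≥ obs}) / (B + 1) ≤ α`, which
holds the nominal level at any shuffle count B (it coincides with the
(1−α)-percentile rule at B = 500). Empirical type-I rates of all five
tests fall inside the 95 % binomial band of nominal over 200 null
neurons (see `vrnav.validation`).

**Gain shift.** All circular 2-cm offsets of the medium profile are
scanned against the low/high profile (z-scored, FFT cross-correlation);
the argmax is refined below the bin width by parabolic interpolation of
the correlation peak. The refinement matters twice: it sharpens
recovery, and it removes the heavy ties a bin-quantized statistic
produces, which would otherwise make the trial-label permutation test
conservative. Ties break toward the smaller absolute, then negative,
shift. Amplitude-scaled explained variance is reported as
1 − Σ(Rg − αRm)²/Σ(Rg − ⟨Rg⟩)² (the raw ratio is a residual fraction),
with α fitted by least squares, both with and without the measured
shift applied.

**Theta phase.** Peaks of the 6–9 Hz band-passed LFP (3rd-order
Butterworth, zero-phase; prominence 0.5 s.d.) define phase 0; peaks
closer than 60 ms to the previous one are discarded; phase is linear in
time between retained peaks, and one per-session offset centers the CA1
pyramidal population rate at 180°. Because theta sweeps 40–60° per
60-Hz sample, all phase binning is done in continuous time: spike
phases are interpolated at exact spike times and occupancy is
integrated within samples (8× phase upsampling); whole-sample binning
would alias badly against 20° bins.

**Modulation index and PPC.** The phase profile uses 20° bins; the
displayed curve is smoothed with a 40° s.d. circular Gaussian, but the
index `(F_max − F_min)/F_mean` is computed from unsmoothed bins —
smoothing attenuates the first harmonic by ×0.78 and would break the
analytic identities (index → 2m for a sinusoidally modulated rate,
PPC ≈ (index/4)²). The extreme bins are selected by split-half
cross-validation (argmax/argmin located on the interleaved half of the
spikes, rates read from the other half, symmetrized), removing the
upward selection bias (≈ +0.09 at 5000 spikes) of a plain max−min.
PPC is computed via the resultant identity, which equals the pairwise
definition to machine precision.

**Precession.** The phase × position profile (20° × 2 cm bins) is
smoothed 40° × 8 cm for display; the drift curve — the cross-correlogram
argmax of each phase row against the phase-averaged profile, with
sub-bin refinement — is computed from maps smoothed along position
only, for the same attenuation reason. A closed-form quadrature fit
`a sin(θ − φ) + c` gives the amplitude and the behind→ahead
zero-crossing offset φ, which equals the generator's injected θ0.
Significance uses a spike-phase permutation on phase-unsmoothed maps.

**Decoding.** Encoding models are the medium-gain correct-trial
profiles floored at 0.01 Hz; the prior is training occupancy (uniform
optional). Posteriors are computed in the log domain and normalized;
medium-gain windows are decoded with models trained on the other 19 of
20 contiguous trial blocks, low/high-gain windows with the full
medium-gain model. Windows are non-overlapping 250-ms bins keeping
≥ 50 % speed-gated samples; a session must contribute > 10 spatially
tuned neurons. Error summaries bin errors per position, smooth the
distribution (2-cm s.d.), and report the weighted circular mean and the
argmax (bias), low/high corrected by the medium curve, with 20-fold
jackknife SEs.

**Phase-resolved decoding** (50-ms windows) required three choices to
be well calibrated: window phases are interpolated at exact window
centers; errors are residualized against 8-cm position bins before the
phase curve, because theta phase and position are deterministically
locked at the ≈ 3-cm theta wavelength of running, so position-dependent
bias otherwise masquerades as phase modulation; and the randomization
is a circular shift of the window-phase sequence, preserving the strong
autocorrelation of consecutive 50-ms windows that a per-window
permutation ignores. When the window grid aliases against theta and
leaves phase bins structurally empty, the sinusoid is fitted on the
populated bins.

**Error coupling.** Joint V1 × CA1 error histograms (2-cm bins, 4-cm
s.d. smoothing, correct trials) are compared to shuffles permuting
simultaneous windows within identical (2-cm position × per-session
speed-quintile) cells — singleton cells stay fixed and are counted;
100 shuffle repetitions are averaged by default (the repetition count
is a free parameter). The summary statistic is the difference-map mass
within 10 cm of the identity diagonal. The split-thirds control trains
the V1 decoder on the first third of usable trials, CA1 on the second,
and evaluates coupling on the third.

**GLM.** Spike counts per 250-ms window, mean-centered on the training
(medium-gain) windows. Step 1: ridge on 100 position indicators;
step 2: ridge of the residual on 549 behavioral columns (6 variables ×
10 medium-gain quantile bins × 9 lags from −1 to +1 s, plus 9 reward
lags); quantile edges are global (medium-gain), degenerate covariates
merge bins. The penalty is shared across steps; `lam="auto"` selects it
by nested 5-fold CV. Cross-validated predictions for medium windows use
contiguous trial folds so no window is predicted by a model that saw
it. Predicted profiles are built from predicted counts exactly as spike
profiles are. The latency scan refits step 1 with position indicators
read `delay` seconds in the past (0–1000 ms, 100-ms steps); the optimal
delay maximizes the correlation between the model-predicted and the
spike-measured low/high-gain profiles — only at the true latency does a
medium-gain-trained model transfer across gains, because the apparent
shift a latency produces scales with visual speed and hence with gain.
(Correlating predictions against the predicted medium profile instead
is degenerate: the predicted cross-gain shift is `d (g − 1) v` for any
true latency, so that criterion always peaks at zero delay.) Since
adjacent delays differ by sub-centimeter misalignments, the validation
measurement averages the score over 12 latency cells and snaps the
parabolic vertex of the score curve to the grid.

## Validation suite

`vrnav.validation` fixes the problem sizes used by the acceptance
script and tests: 200 null neurons × 200 shuffles per calibration
(40-trial sessions; 25 trials and 12-neuron populations for the
phase-decoding replicates); a (w ∈ {0, ½, 1}) × (D ∈ {30, 80}) grid at
≈ 30 trials per manipulated gain for shift recovery; 130-trial
(≈ 20-min) sessions with 5 cells per case for precession recovery
(offsets 200° and the V1-like 315°); 9 replicate estimates at 5000
spikes each for the index; nested 10/40/160-neuron populations for
decoder consistency; and 22 + 22-neuron sessions with a 6-cm shared
error process for the coupling experiment. The bias-direction twin uses
populations of distance cells anchored to the last landmark passed,
with anchor distances capped inside each landmark segment (a distance
estimate resets at a landmark; without the cap, high-gain fields
overshoot into the next segment) and 10-cm fields (wide fields smear
the distance ramp and flatten the near/at-landmark contrast).

## Known limitations

Estimates are validated under the generator's assumptions (Poisson
spiking, stationary fields, sinusoidal theta coupling). The drift
estimator reports the first harmonic of the drift curve only; the
equal-circular-medians statistic relies on its permutation null, not on
an asymptotic distribution; the look-up-table decoding variant and
state-space decoders are out of scope; and the pipeline's population
fractions on synthetic sessions depend on the chosen ground-truth
population and are reported as descriptive numbers, never as checks.
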