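# Methods

## The instrument and its digital twin

`optowell` models a 96-well optogenetic plate reader: each well of a
black-walled, clear-bottom plate sits between a top board carrying a blue
stimulation LED (470 nm) and a red OD LED (600 nm), and a bottom board
carrying a photodiode and a near-UV excitation LED (395 nm) for a
long-Stokes-shift reporter (mAmetrine-like; a Lucifer-Yellow-type dye serves
as the calibration standard). LED brightness is set by 12-bit PWM (integer
settings 0–4095, linear in time-averaged output), and each measurement is
the mean of many single ADC readings (default 100).

The twin (`optowell.twin.PlateTwin`) reproduces the parts of the physics the
software stack interacts with:

- **Per-well component gains.** Each of the four component classes carries
  96 multiplicative gains drawn lognormally with mean 1 and a configurable
  CV (lognormal guarantees positivity up to the ~20 % spreads seen on
  assembled devices). Defaults are the uncalibrated variability levels of
  the assembled instrument: photodiodes 5.1 %, blue LEDs 15.9 %, UV LEDs
  9.8 %, and OD LEDs 11.8 % gain CV combined with an 11.7 % per-well optical
  scatter (meniscus, alignment), jointly ≈16.6 % on the OD light path.
- **Readout.** A single reading is
  `clip(round(g_pd · incident + ε), 0, adc_max)` with ε ~ N(0, noise_sd);
  the default ADC ceiling is 1023 (10-bit) and the default single-reading
  noise is 4.2 counts. Averaging n readings shrinks the standard error as
  1/√n.
- **Channels.** Blue reads through an empty plate; the OD channel is
  attenuated decadically, `10^(−p·turbidity)` with path-length factor
  p = 0.5 (the short vertical light path reads about half the OD of a
  cuvette-geometry reference instrument); the fluorescence channel is
  `drive_uv · (fluor_gain · conc + bleed)` plus any sample blank, where the
  bleed term (15 % of the UV channel scale) models excitation light passing
  the emission filter and sets the channel's blank level (~120 counts).
- **Well insulation.** Crosstalk defaults to zero (the physical device's
  light insulation is confirmed); a 96×96 coupling matrix is retained for
  robustness experiments.
- All randomness flows from one seed; simulated experiments are
  bit-reproducible.

Two calibrated constants tie the twin to the published operating regime and
deserve explanation:

- `fluor_gain = 18.2` counts/(µg/mL) per unit excitation drive. Min-rule
  calibration pins the UV drives — and, through the software correction, the
  effective photodiode gain — to the dimmest member of each 96-component
  class. The expected product of those two minimum statistics at the default
  CVs is ≈0.686, so a calibrated instrument reads ≈12.5 counts/µg/mL, the
  published sensitivity. The per-seed spread of that product (SD ≈ 0.55
  counts/µg/mL) is real sampling variability of a 96-well build.
- `noise_sd = 4.2` counts. With the 3σ-blank convention below this puts the
  single-reading detection limit at 3·4.2/12.5 ≈ 1.0 µg/mL, the published
  LOD.

## Calibration

The workflow order is fixed: photodiodes first (they are the reference for
everything else), then LEDs.

1. **Photodiodes** are exposed to a uniform external field at four
   irradiances (31, 67, 74, 230 µW/cm²). Per irradiance, min-rule factors
   `c_i = min(r)/r_i` are computed from 100-reading means; the final factor
   is their arithmetic average (for a linear detector the four sets agree —
   an explicit test). Factors multiply all later readings in software.
2. **LEDs** are calibrated iteratively in their operating context (blue:
   empty plate; OD: liquid-filled plate, re-run at the start of every
   experiment on the actual T=0 cultures to capture liquid scatter and
   define the per-well blank; UV: uniform dye plate at 40 µg/mL). Each
   round: read (averaged, photodiode-corrected) → CV → factors (mean-rule
   `c_i = mean(r)/r_i` for blue/OD, min-rule for UV, which starts at full
   scale and can only dim) → `setting_i ← round(setting_i · c_i)` clipped to
   0–4095 (clipped wells are flagged). Iteration stops when CV < 1 % or
   after 3 rounds.

CV is sample SD (n−1) over mean × 100 %. Because counts and settings are
integers, a noise-free calibration bottoms out at a quantisation floor of
~0.05–0.1 % rather than exactly zero; the idempotence of converged settings
(further rounds move nothing by more than one PWM count) holds exactly in
the fine-resolution limit.

A deliberately physical detail: during the first UV round at full scale the
brightest wells can saturate the ADC, so the first factor set is distorted
and a second round is needed — matching the two rounds the physical
instrument needed.

## Spectroscopy

- **OD** is decadic absorbance against the per-experiment blank,
  `OD = −log10(counts/blank)`. The formula is the instrument-standard
  convention (the source material defers it to methods without printing
  it).
- **Cross-instrument harmonisation.** Per well, ordinary least squares of
  `ln(od_instrument + 1)` on the reference OD (natural log, matching the R
  `lm(log(...))` specification). The inverse `c = (ln(r+1) − b)/m` converts
  later readings to the reference scale, including in real time for
  OD-triggered feedback. Note the model family absorbs the mild concavity
  of `ln(0.5·ref + 1)` in ref, which is why the log fit outperforms a plain
  line at low OD.
- **Dilution-series characterisation.** The linear range grows from the
  three lowest concentrations while the per-well fit keeps R² ≥ 0.99 (an
  explicit rule; the published 40 µg/mL endpoint is reported without one).
  Sensitivity and R² come from the fit over that range; LOD =
  3·SD(blank)/sensitivity with the blank SD taken over single, unaveraged
  readings (the published LOD is only consistent with the instrument's
  noise floor if quoted per single acquisition; averaged blanks would give
  ~0.1 µg/mL); dynamic range = linear_upper/LOD. A noise-free blank has no
  defined LOD (reported as NaN rather than zero).

## Culture model

Each well holds a logistic-with-lag culture
(`dN/dt = r_eff·N·(1 − N/K)` after `lag`, with `r_eff` doubled while the
plate shakes; defaults r = 0.5 /h, K = 1 OD, lag = 1 h, shaking ×2) and a
reporter controlled by one of: arabinose (on iff inducer present), pDawn
(Hill activation by blue light), pDusk (Hill repression). Activation state
relaxes first-order toward the drive evaluated `switch_delay` (0.5 h) in the
past; reporter accumulates at `k_prod · induced_fraction · N` with no
degradation (the reporter is photostable under the excitation used).
Reporter is expressed in µg/mL-equivalents of the calibration dye so the
twin's fluorescence channel reads it directly.

Integration is explicit Euler (2-min substeps between measurement epochs).
The circuit response is evaluated at the **duty-averaged intensity** of the
pulse train rather than pulse-by-pulse: the photoreceptor integrates light
over timescales much longer than the 10-s pulse period, and this choice is
what makes 30 %-duty pulsed light fully repress a pDusk culture (averaging
the response instead of the intensity would leave 70 % residual drive —
qualitatively wrong).

Parameter defaults were set for the published regimes and then left alone:
`k_prod = 8` µg/mL/(OD·h) keeps 10-h full-induction trajectories within the
10-bit ADC; `half_max_light = 30` PWM-equivalents places the
0.5–10 %-of-maximum intensity ladder (duty-averaged 6–123) across the
graded region of the Hill curve (n = 2).

## Experiment engine

Stimulation is a per-well looping waveform (intensity, t_on, t_off; duty
cycle = 100·t_on/(t_on+t_off), e.g. 3 s/7 s → 30 %). At every measurement
epoch the engine pauses the shaker, forces every stimulation LED dark,
measures OD then fluorescence for all 96 wells (100-reading averages),
restores stimulation and resumes shaking — stimulation and measurement
intervals are disjoint by construction. Records are appended to per-signal
CSVs (rows = epochs, columns = wells A1..H12) as they are taken.

Feedback is evaluated once per epoch, immediately after records are
written. Three built-in policy classes: constant (open loop),
stop-on-fluorescence (intensity latched to 0 once the group-mean
fluorescence reaches the threshold), start-on-OD (protocol inactive until
the group-mean reference-adjusted OD reaches the threshold, then latched
on). Threshold policies are latched one-shot switches — inferred from the
published trajectories, which show no re-activation; a non-latched
hysteresis variant exists behind `latched=False`. A policy may group
replicate wells, receiving their arithmetic-mean record as input. Custom
policies are pure functions `(state, group records, protocol) → (state,
protocol)`.

Time is event-stepped; the sub-minute wall-clock duration of a real plate
read is not modelled (a nominal duration only guards against impossible
cadences).

## What the simulation does and does not show

The twin reproduces the *structure* of the measurement problem — per-well
gain dispersion, quantisation, averaged read noise, saturation, the ~½
OD-scale offset — so passing tests demonstrate that the calibration rules,
statistics and feedback logic are correct and self-consistent at the
published noise levels. It does not reproduce the physical origins of the
residual post-calibration CVs (the 2.8 % blue residual on hardware is
unexplained there; here residuals are quantisation + read noise, typically
≤1 %), spectral filter/fluorophore curves, temperature drift, evaporation,
or the diauxic second OD rise; calibration-CV comparisons are therefore
upper bounds, not equalities. Growth and induction parameters are
plausible for shaken E. coli in rich medium, not fits to any dataset.

## Problem sizes

All simulations operate on the full 96-well plate. The acceptance script
runs four calibration workflows, a 6-point dye series, and two 5-point bead
series (~10 s total); the test suite adds three closed-loop plate runs of
1–10 simulated hours at 20–30-min cadence (~3 s total).
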