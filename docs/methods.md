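# Methods

This note records the models, parameter choices and numerical decisions
behind `ventrack`, in the spirit of a methods appendix: what is computed,
what is assumed, and what the synthetic data can and cannot show.

## Measurement model and analysis chain

The measured quantity is the ventilatory signal: a weak bioelectric
oscillation generated by opercular (gill) movement, picked up by an array of
L = 126 bottom electrodes (14 × 9 grid, 15 mm pitch, 210 × 140 mm arena)
sampled at f_s = 1000 Hz.  Its instantaneous frequency tracks respiration;
its amplitude at an electrode decays with the fish–electrode distance.  The
chain exploits both facts:

* **Band-pass.** 4th-order Butterworth, 1–10 Hz, applied forward–backward
  (zero phase).  Butterworth order is a free choice (flat passband); the
  band is the physiological ventilation range.
* **Per-tick AR spectra.** Analysis ticks sit on an exact 33 Hz grid
  (sample index `round(k·f_s/f_m)`), one tick per grid point.  Each tick
  takes a 1 s window centred on the tick (shifted inward at the recording
  edges so it keeps full length), decimates it to 200 Hz — legitimate
  because the signal is band-limited to 10 Hz — and fits an AR(10) model by
  Burg's method, batched over all channels.  Peak frequency is the in-band
  argmax of the AR PSD on a 0.02 Hz grid.
* **Power weights.** The localisation weight of an electrode is the
  Hann-tapered band power of its window, not the raw AR-PSD maximum height:
  for noiseless near-sinusoidal segments the AR poles approach the unit
  circle and the peak height diverges, which made the centre of gravity
  jitter; band power is the stable measure of the ventilatory component's
  strength, and the taper suppresses partial-cycle sensitivity while the
  fish moves.
* **Localisation.** The 14 × 9 power map is refined by a bicubic spline
  (each electrode gap divided into five; negative interpolants clamped to
  zero) and the position estimate is the power-weighted centre of gravity,
  then zero-phase low-passed at 2 Hz.  Ticks with an all-zero power map hold
  the previous estimate and are flagged.  A full-2-D spline was chosen over
  per-axis 1-D interpolation: it is the standard smooth interpolant on a
  regular grid.
* **Velocity.** Central differences of the smoothed track, then a 2 Hz
  zero-phase low-pass.

### Numerical choices worth knowing

* A deterministic dither at 1e-2 of each window's RMS is added before the
  Burg fit.  On exactly noiseless signals the eight surplus AR poles are
  pure round-off and can outgrow the true spectral line; a −40 dB floor
  pins them without influencing any realistic (noisy) recording.  Burg's
  short-window frequency bias also motivated the 200 Hz decimated rate:
  at 50 Hz the worst-case phase-dependent bias of a pure tone reached
  0.5 Hz, at 200 Hz it is 0.04 Hz.
* The zero-phase filter's 1 Hz band edge rings for roughly 2 s at the
  recording boundaries.  The transient scales every channel identically, so
  localisation is unaffected, but the per-electrode peak-frequency readout
  near the edges is not trustworthy.  Analyses therefore simulate/record
  with settling padding and evaluate the analysed interior; the index stage
  trims 0.5 s per side before windowing (the cohort generator simulates
  301 s for 300 analysed seconds, keeping 60 windows per session exactly).

## Evaluation indices

Per 5 s window at 33 Hz: mean speed, stopping probability
(P_stop = 100 · time below v_stop / window), mean ventilatory frequency F_v
(peak frequency of the electrode nearest the estimated position), and the
SDs of speed and F_v over ticks.  The SD of P_stop is taken over five 1 s
sub-windows — the smallest sub-window still holding ≥ 33 ticks; a single
P_stop value per window has no SD.  v_stop defaults to 3 mm/s (≈ 1/10 body
length per second: below cruising speeds, above tracker jitter).  Indices
are standardised per fish: the baseline (normal) session's mean and SD map
to 0 and 1.  Standardisation is idempotent and refuses silently-degenerate
baselines (zero SD) by naming the offending index.

## Statistics

Welch's *t* (Welch–Satterthwaite df, two-sided), one-way fixed-effects ANOVA
(perfect separation returned as an infinite F with a degenerate flag rather
than an exception), Cohen's *d* with the pooled SD, and Tukey–Kramer
(studentised range with unequal-n standard errors, via `scipy.stats.tukey_hsd`).
PCA is an eigendecomposition of the correlation matrix of the pooled
standardised indices — correlation rather than covariance because the six
indices live on different scales; each loading column is flipped so its
largest-magnitude entry is positive, making loadings and scores reproducible.

## Classifiers

* **LDA.** One linear discriminant function per class,
  y_k(x) = w_kᵀ[1, x], with w_k = Σ⁻¹μ_k and bias −½μ_kᵀΣ⁻¹μ_k + log π_k
  from the pooled within-class covariance (ridge-regularised with a warning
  if near-singular).  Decision is the largest y_k; ties break to the lowest
  class index (normal < fear < appetitive).  For two classes the implied
  projection w₁ − w₂ is exactly the Fisher-ratio maximiser, which the tests
  verify against a 3600-angle grid search.
* **LLGMN.** Input x ∈ R^N is expanded to (1, x_i, x_i·x_j for i ≤ j),
  H = 1 + N + N(N+1)/2 terms, mapped linearly to K × M component units
  (last unit's weights pinned to zero for identifiability), pooled by a
  normalised exponential; a class posterior is the sum of its component
  units.  This realises a Gaussian-mixture posterior in feed-forward form.
  Training maximises the mean log posterior of the true class by full-batch
  gradient ascent with backtracking (the step is halved until the
  log-likelihood does not decrease), so the training trace is monotone by
  construction; initial rate 0.01, up to 2000 epochs, relative tolerance
  1e-6, near-zero seeded initialisation.  M defaults to 2 components per
  class because the appetitive state is deliberately bimodal.
* **Cross-validation.** Leave-one-fish-out: PCA and classifier are refitted
  on the other fish's windows for every fold, so nothing of the held-out
  animal — including the PC basis — leaks into training.  Per-fold macro-F
  averages over the classes present in that fold's truth (each fish only
  experiences two of the three states; a structural zero for the absent
  class would swamp between-fold comparisons).  Pooled confusion counts
  give the reported per-class precision/recall/F and macro F.

## The virtual aquarium

No recordings of this measurement type are public, so the generator defines
the study conditions: 15 fish with a fear (alarm-pheromone-style) session
and 8 fish with an appetitive (ethanol-place-preference-style) session, each
session 300 analysed seconds → 60 windows, 2760 windows in total.

A fish is a correlated random walk: heading diffusion set by a persistence
parameter, Ornstein–Uhlenbeck speed, alternating-renewal freezing bouts,
Poisson darts, reflective walls with a soft avoidance field (speed-scaled
steering torque plus braking within a 50 mm margin — open-field cruising
rather than wall-hugging, which also keeps centre-of-gravity localisation in
its well-conditioned interior regime).  Ventilation frequency is an OU
process (τ = 2 s) clipped to 1.2–9.5 Hz.  Rendering places a Gaussian
amplitude kernel (length-scale = one pitch) at the fish and runs a sinusoid
at the integrated instantaneous frequency; optional white channel noise is
scaled to a requested peak-channel SNR.  Real signals' amplitude units and
SNR are unknown, so SNR stays a free parameter.

Calibrated state programmes (speeds mm/s, rates 1/s, durations s, Hz):

| parameter            | normal | fear | appetitive |
|----------------------|--------|------|------------|
| mean speed           | 22     | 9    | 32         |
| speed SD / τ         | 8 / 5  | 2 / 3| 8 / 5      |
| freeze rate / mean dur | 0.05 / 0.7 | 0.15 / 2.5 | 0.06 / 8 |
| dart rate            | 0      | 0.02 | 0.03       |
| ventilation base / SD | 2.6 / 0.45 | 3.0 / 0.22 | 2.6 / 0.14 |
| heading persistence  | 0.88   | 0.6  | 0.8        |

Individual variability is a per-fish trait profile (lognormal multipliers,
CV 0.08, on speeds/bout parameters/rhythm variability; a ±0.06 Hz offset on
the ventilation base rate) shared across the fish's sessions, so per-fish
baseline standardisation cancels traits as intended.  Index-level cohort
generation samples ground truth on the 33 Hz grid with small
measurement-emulation noise (position σ 1.5 mm, frequency σ 0.05 Hz) and
runs it through the same smoothing/differentiation/windowing code as
electrode-derived tracks.

The calibration targets the qualitative structure reported for live fish:
fear lowers speed and its variability, raises stopping, its variability and
the ventilation rate, and stabilises the rhythm; the appetitive state raises
speed/stopping variability and stabilises the rhythm strongly while leaving
the rate itself unchanged; the respiratory-stability axis ranks fourth in
the PC decomposition, so discrimination of the appetitive state improves
sharply when the fourth PC is added; the appetitive state is a bimodal
cruise/station-hold mixture, which is why the Gaussian-mixture network beats
the linear discriminant.  Class-wise difficulty orders normal > fear >
appetitive.

**What passing tests do and do not show.**  The simulator has a literal
point-source amplitude model, white noise, a single fish, 2-D motion and
stationary state programmes.  Real recordings add electrode drift, mains
interference, body-geometry effects, 3-D excursions and slow emotional-state
dynamics (e.g. fear intensity decaying over minutes).  Tests passing on the
simulator validate the correctness and internal consistency of the analysis
chain and its statistical machinery — not field performance on live fish.
Session-level rhythm drift is real in the generator; with only 8 appetitive
fish, a window-level Welch test on F̄_v can reach significance at some
cohort seeds purely from that drift, which is why the "rate unchanged"
property is asserted at fixed seeds.

## Problem sizes used in tests and the acceptance script

Tracker accuracy uses 5 fish × 60 analysed seconds (noiseless); frequency
recovery uses stationary fish at {2, 3, 5, 8} Hz for 20 analysed seconds,
noiseless and at SNR 5; classifier toys use n = 4000 (LLGMN/Bayes) and
n = 1000 (Fisher grid search); the cohort battery runs the full 2760-window
design with leave-one-fish-out CV for N = 1…6 PCs.  These sizes keep a full
run in minutes on a single CPU while leaving the measured margins far from
the acceptance thresholds.

## Known limitations

* Localisation degrades near walls and corners (kernel truncation biases
  the centre of gravity inward); the wall-avoidance field keeps the default
  behaviour mostly interior, but p95 position errors near walls reach ~1
  electrode pitch.
* The peak-frequency readout is unreliable within ~2 s of recording
  boundaries (filter settling), and below ~1.2 Hz (detrending/edge effects).
* The LLGMN's backtracking ascent guarantees monotonicity, not global
  optimality; different seeds can land in different (similar-quality)
  optima.
* `compare_pc_counts`' Tukey–Kramer table across all folds mixes the two
  sub-cohorts, whose macro-F gap at small N inflates the pooled variance;
  per-class per-fold F-scores are exposed for sharper class-specific
  comparisons.
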