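# Methods

This note documents the models, conventions and numerical choices behind
`kneeprop`, and what the synthetic cohort does and does not establish about
real data.

## Sensor model and calibration

Each IMU reports orientation as a unit quaternion `q = (w, x, y, z)`
(scalar first, Hamilton products) at a nominal 74 Hz. Because `q` and `−q`
encode the same rotation, every rotation-level operation is sign-invariant,
and buffers are hemisphere-aligned (flipped to a non-negative dot product
with the first sample) before any component-wise averaging; a naive
component-wise mean would otherwise be sign-ambiguous.

Calibration has two stages:

1. **Flat-surface baseline.** With both knee sensors parallel on a flat
   surface, ~14 s of samples are recorded; the last 1000 samples
   (`buffer_len`, configurable) are averaged and normalized into a single
   baseline `q0`. Since the two sensors are physically parallel here, their
   buffer means are averaged into one shared baseline.
2. **Upright reference and offset.** With the sensors attached and the
   participant standing still, each sensor's mean orientation `q_ref` is
   recorded and the offset computed as `q_T = conj(q_ref) ⊗ q0`. Live
   samples are calibrated as `q_R ⊗ q_T`.

The defining contract of these conventions is: *a sensor read at the
upright pose is mapped to the baseline*, so both calibrated sensors
coincide at stance and the knee reads exactly 180° included (zero flexion)
there, regardless of mounting offsets. Any (left/right, pre/post)
multiplication convention satisfying this contract yields identical knee
angles; the one above is fixed throughout and tested.

**Angle extraction.** The knee rotation is
`q_knee = conj(q_shank_cal) ⊗ q_thigh_cal`; its intrinsic Y-X-Z Euler
decomposition's Y component (absolute value) is the flexion angle. The
knee's hinge axis is the sensors' Y axis, so in-plane squatting and
stretching are pure Y rotations, for which this extraction is exact; it is
only contract-tested on (near-)pure-Y motion. Near the gimbal degeneracy
(second angle → ±90°) the code falls back, deterministically and without
raising, to the axis-angle magnitude projected on Y. Two angle conventions
are supported and converted explicitly — *flexion* (0° = straight) and
*included* (180° = straight, the internal canonical form) — because squat
targets are naturally stated in flexion (90°/130°) and stretch targets in
included angle (135°/180°).

**Stream pairing.** Thigh and shank streams are paired
nearest-neighbour on the thigh clock within half the nominal sample
period; unmatched samples are dropped, and no resampling or interpolation
is performed (live systems pair whole sensor frames).

## Protocol and sonification

Schedules encode the study protocol as defaults: squat game rounds of 12
carrot groups (9 carrots each, 2.5 s hold, 20 s standing rest), stretch
game rounds of 12 fish on four trails mapped affinely from the included
angles {90, 120, 150, 180}° to screen positions {0, ⅓, ⅔, 1}, and pre/post
test blocks of 10 prompted movements (~5 s holds, class order randomized
per seed). Fish spawns are spaced so capture windows never overlap (the
source protocol does not state spawn timing; the spacing is configurable).
Trail quantization takes the nearest anchor, ties to the lower trail.

Sonification maps the vertical position `p ∈ [0, 1]` to amplitude `p`
(linear, silent at the bottom, maximum non-clipping at the top) and to a
pitch index `floor(p·(n_steps − 1))` on a monotone semitone ladder
(25 chromatic steps ≈ two octaves by default; only monotonicity is
specified, so the ladder length is configurable), with a fixed 0.15 s
stimulus duration inside the stated 0.1–0.2 s band. Both pitch and
loudness are modulated. Disabled feedback (the control arm) returns a
silence marker. No audio is synthesized — only the numeric mapping is
implemented.

## Synthetic cohort

The generator emulates the study conditions so that every downstream stage
has a ground-truth oracle.

- **Proprioceptive error.** Each participant has a signed systematic bias
  (magnitude ~ N(7.5°, 2°), clipped below at 1°, random sign) plus
  per-movement noise N(0, 3°). These defaults put pre-test AME on the
  5–10° scale typical of knee angle-reproduction testing. A movement's
  held angle is `target + bias + noise`, reached by a 1 s minimum-jerk
  transition, held with 0.3° motor tremor, and clipped at the anatomical
  limit of full extension. The recorded ground-truth AKA is the realized
  central-window mean — the same summary the analysis recovers.
- **Training effect.** Post-test errors of the experimental group are
  multiplied by `1 − learning_gain` (default gain 0.8, control group 0) —
  the simplest mechanism consistent with a positive improvement score
  IE = AME_pre − AME_post. With the default bias scale this yields a
  median IE separation of roughly 5–6° between arms.
- **IMU encoding.** The world frame is the flat calibration surface, so
  the flat buffers read (noisy) identity; each sensor carries a fixed
  random mounting offset (rotation up to 30° about a random axis) and
  per-sample orientation noise (default SD 0.25°); the thigh segment
  rotates about Y by the ground-truth flexion while the shank stays fixed
  (only the relative rotation carries information).
- **EMG.** Mixtures `E = W_true·H + ε` clipped at zero, with `W_true`
  having unit-norm columns and block-separated muscle supports, and `H`
  made of Gaussian bursts (SD 0.15 s) locked to catch/collection events
  with per-synergy lags of 0.5 s — staggered well beyond the burst width
  so the activation rows are near-orthogonal and a k-synergy mixture
  genuinely requires k components. The default sampling rate is 1111 Hz
  (typical for wearable EMG of this class; not dictated by the protocol).
  These are envelope-level signals, not interference-pattern EMG with a
  high-frequency carrier.
- **Reproducibility.** One master seed fans out through
  `numpy.random.SeedSequence` spawning, one child per participant, so a
  cohort regenerates byte-identically (CSV floats are written with 17
  significant digits and re-read with round-trip parsing).

What passing tests on this cohort do **not** show: robustness to
out-of-plane knee motion, soft-tissue artifact, sensor drift or dropped
frames; EMG crosstalk, motion artifact or non-stationary noise; or
non-Gaussian error distributions (the generator's errors are Gaussian with
an anatomical truncation at full extension; reproduction errors in real
cohorts are often heavier-tailed, which is why the analysis uses rank
tests and a z-score outlier screen in the first place).

## Metrics and inference

- `Error = AKA − TKA`, signed, both angles in the same convention. AKA for
  a hold is the mean over the central 60% of the window, excluding
  transitions (video-assisted segmentation is replaced by
  schedule-timestamp segmentation).
- `AME` defaults to |mean(errors)| ("absolute mean"); the mean-of-absolutes
  variant is available behind a flag because the two differ whenever
  errors cancel (e.g. [5, −5] → 0 vs 5).
- Outliers: one pass of `|z| > 2.5` using the sample (n−1) SD, applied by
  default to the IE values pooled per movement group across both arms;
  per-arm scope and population SD are flags. The screen is deliberately
  not iterated.
- Rank test: U from midranks; with tie-free samples and n1+n2 ≤ 25 the
  p-value is exact, from the counting recurrence
  `c(n1, n2, u) = c(n1−1, n2, u−n2) + c(n1, n2−1, u)` (verified against
  full enumeration for all n1, n2 ≤ 8); otherwise a tie-corrected normal
  approximation with continuity correction. One-sided means "first sample
  stochastically greater"; the two-sided p is twice the smaller tail,
  capped at 1. Reports always carry both sidedness variants, because at
  n = 7 + 7 the exact two-sided values for U = 41 and 42 (.038, .026)
  round to the familiar .04/.03 while the one-sided values are .019/.013 —
  output labels make explicit which is which. Quartiles use inclusive
  linear interpolation (the convention is otherwise unstated).
- Power: the a-priori sample-size search uses the between-factors
  repeated-measures ANOVA noncentral-F model,
  `λ = f²·N·m / (1 + (m−1)ρ)` with `df = (groups−1, N−groups)`, ρ exposed
  as a parameter (default 0.5). With f = 0.78, α = .05, power 80%, m = 2,
  ρ = 0.5 the search returns N = 12; published calculators' results depend
  on their exact input panel (effect metric, assumed ρ), so no specific N
  is claimed beyond the model stated here.
- Questionnaires: IMI subscales (7-point items, reverse items mapped
  x → 8−x) aggregate as raw sums by default, with mean and
  midpoint-centered-sum modes available — published subscale tables are
  not always consistent with a single transform (a raw-sum
  interest/enjoyment of 35 next to a negative pressure/tension value
  implies mixed conventions), so the mode is explicit. UEQ dimensions are
  item means on −3..+3; pragmatic quality = mean(perspicuity, efficiency,
  dependability), hedonic quality = mean(stimulation, novelty).

## Synergy analysis

Preprocessing per channel, in order: 5th-order Butterworth low-pass at
30 Hz, then high-pass at 4 Hz (sequential application equals a 4–30 Hz
band-pass for LTI filters), mean subtraction, rectification, division by
the channel maximum, then by the SD of the result (unit variance,
per-channel normalizers). Filtering is zero-phase (forward–backward) by
default — appropriate offline and it preserves burst timing — with a
single-pass causal mode behind a flag. All-zero or constant channels raise
a degenerate-input error naming the muscle.

NMF uses multiplicative updates (Frobenius loss), 10 random restarts
(seeded; best reconstruction kept), relative tolerance 1e-6, and a
1000-iteration cap (500 in the bundled pipeline configuration). Fitted `W`
columns are normalized to unit Euclidean norm with the scale pushed into
`H`. VAF is uncentered, `1 − ‖E − WH‖²_F / ‖E‖²_F` — the standard choice
in the synergy literature. The VAF curve over k = 1..7 is computed with
nested warm starts (the best k-solution, padded with a small random
column, seeds one candidate at k+1), which makes the curve non-decreasing
up to solver tolerance; the selected count is the smallest k whose VAF
*reaches* the threshold (the wording "dropped below" in protocol
descriptions of this rule is self-contradictory for a minimum count; VAF ≥
threshold is the only monotone reading, and it reproduces the observed
threshold ordering: relaxing 90 → 85 → 80% never raises the count). VAF
averaging scope is per-segment, configurable. Cross-arm weight comparison
matches columns by exhaustive optimal assignment on cosine similarity
(k ≤ 7 keeps this trivial).

## Pipeline and problem sizes

`run_pipeline` goes config → (simulate | load) → calibrate → angles →
segment → AME/IE → outlier screen → exact rank tests, plus EMG
segmentation → preprocessing → per-segment synergy-count selection →
per-class pooled weight fits → cross-arm matching → questionnaire scoring,
and emits a JSON report plus CSV tables that regenerate byte-identically
from config + inputs. Every protocol constant is a named config key, so
the default run is the study protocol.

Bundled verification runs are sized to finish quickly on one CPU: angle
recovery uses 20 seeded participants; synergy recovery uses 4-event
mixtures at 1111 Hz over 20 seeds; the power/calibration study uses 100
simulated cohorts with the training effect and 200–300 without, running
the full IMU encode → calibrate → decode path but skipping the EMG layer
(the kinematic outcome does not consume EMG, whose recovery is verified
separately); the bundled full-study run uses EMG at 250 Hz with 3 NMF
restarts. All of these sizes are configuration, not limits of the
implementation.

## Known limitations

- The Euler-based angle is only validated for hinge-like (pure-Y) motion;
  substantial out-of-plane rotation would need a different joint model.
- Included angles are clipped to [0°, 180°]; hyperextension folds onto
  flexion and is not represented.
- The exact test is limited to n1+n2 ≤ 25 (beyond that the normal
  approximation engages automatically).
- The synthetic EMG is an envelope-level model; preprocessing of real
  interference-pattern EMG would see different filter interactions.
- Synergy counts selected on real data depend on the VAF averaging scope
  and threshold; both are exposed rather than fixed.
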