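# kneeprop

Analysis toolkit for IMU-based knee-proprioception exergame studies.

Joint position sense — the ability to reproduce a target knee angle without
looking — is trained in rehabilitation with open-kinetic-chain (seated
stretches) and closed-kinetic-chain (squats) exercise. `kneeprop`
implements the full analysis stack for a two-arm exergame trial of this
kind, where wearable IMUs drive two games (a squatting game and a
trail-based stretching game), the experimental arm additionally hears the
joint position sonified (pitch and loudness follow the on-screen
position), and the outcome is how much each participant's
angle-reproduction error improves from a pre-test to a post-test.

The package covers:

- **Quaternion sensor calibration and knee-angle estimation.** Two IMUs
  (thigh/biceps femoris and midshank) stream unit quaternions at 74 Hz.
  A flat-surface recording gives a baseline `q0` (the normalized
  component-wise mean of a 1000-sample buffer, hemisphere-aligned because
  `q ≡ −q`); an upright-stance recording gives per-sensor references
  `q_ref`; the mounting offset is `q_T = q_ref* ⊗ q0`, and each live sample
  is calibrated as `q_R ⊗ q_T`. The knee angle is the Y Euler component of
  the rotation between the calibrated shank and thigh frames, reported as
  flexion (0° = straight) or the included angle (180° = straight).
- **Protocol schedules and sonification** for the two games (12 carrot
  groups × 9 carrots with 2.5 s holds; 12 fish on trails at
  90/120/150/180° included, 2 s catch hold, 10 s escape) and the pre/post
  tests (10 squats at 90/130° flexion, 10 stretches at 135/180° included).
- **Joint-position-error metrics.** Per movement, `Error = AKA − TKA`
  (actual minus target angle); per test and movement group, the average
  mean error `AME = |mean(Error)|`; per participant, the improvement
  `IE = AME_pre − AME_post`. Outliers are screened once at `|z| > 2.5`.
- **Exact small-sample inference.** The Mann-Whitney U null distribution is
  enumerated exactly (counting recurrence over all C(n1+n2, n1) rank
  assignments), giving exact one- and two-sided p-values at n = 7 + 7.
- **EMG muscle synergies.** Event-locked segments (the 2 s before each fish
  catch; first-to-ninth carrot of complete groups) are band-limited
  (5th-order Butterworth, 30 Hz low-pass then 4 Hz high-pass), detrended,
  rectified and max/SD-normalized, then factorized with non-negative
  matrix factorization `E ≈ W·H`; the synergy count is the smallest k whose
  variance accounted for (`1 − ‖E − WH‖²/‖E‖²`) reaches a 90/85/80%
  threshold, and weights are compared across arms by optimal cosine
  matching.
- **A synthetic cohort generator** producing ground-truth-annotated
  trajectories, IMU streams, event logs, synergy-mixture EMG and
  questionnaire tables, so the entire pipeline is testable without any
  recorded data.

Signal-path stages follow scikit-learn conventions
(`KneeAngleEstimator().fit(calibration).transform(streams)`,
`EMGPreprocessor`, `SynergyNMF`) and compose with sklearn tooling.

## Worked example

```python
import numpy as np
from kneeprop.pipeline import StudyConfig, run_pipeline

report = run_pipeline(StudyConfig(seed=3, with_emg=False))
for mg, r in report["inference"].items():
    print(f"{mg}: U={r['U']:.0f} one-sided p={r['p_one_sided']:.4f} "
          f"median IE EG={r['median_ie_eg']:.2f} CG={r['median_ie_cg']:.2f}")
```

prints

```
squat: U=48 one-sided p=0.0006 median IE EG=5.66 CG=0.44
stretch: U=43 one-sided p=0.0087 median IE EG=2.89 CG=-0.68
```

i.e. in this simulated 7 + 7 cohort the feedback arm improved its squat
reproduction error by a median 5.7° versus 0.4° in the control arm; with
U = 48 of a possible 49 the exact one-sided p-value is 0.0006, so the
training effect built into the generator is detected in both movement
groups. The same analysis is available from the shell:

```bash
kneeprop run-all --seed 3 --out results/
kneeprop simulate --out cohort/ && kneeprop metrics cohort/ --out metrics.csv
```

For the exact-test machinery directly:

```python
from kneeprop.stats import exact_p_from_u
exact_p_from_u(41, 7, 7, "two_sided")   # 0.0379  -> prints as .04
exact_p_from_u(42, 7, 7, "two_sided")   # 0.0262  -> prints as .03
```

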