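"""Synthetic study-cohort generator.

Produces complete, ground-truth-annotated data with the statistical
structure the analysis assumes: knee-angle trajectories with
participant-specific proprioceptive error (a signed bias plus Gaussian
noise around each target), a training effect that attenuates the error in
the auditory-feedback (experimental) group only, two-sensor IMU quaternion
streams with random mounting offsets and orientation noise, event logs
following the game schedules, EMG built as non-negative synergy mixtures
``E = W·H + ε`` time-locked to game events, and questionnaire item tables.

Every stochastic choice flows from one master seed through per-participant
spawned generators, so a cohort regenerates byte-identically from its
manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import quaternions as qt
from .protocol import (
    GameEvent,
    ProtocolSchedule,
    bunny_schedule,
    fish_schedule,
    test_schedule,
    schedule_to_events,
    write_events,
    write_schedules,
)
from .streams import (
    EMGStream,
    KneeAngleSeries,
    MUSCLES,
    SensorStream,
    write_angle_csv,
    write_emg_csv,
    write_sensor_csv,
)

# Cohort-level defaults: the study conditions the generator emulates.
# Proprioceptive biases are sized so pre-test AME lands on the 5-10 degree
# scale seen in angle-reproduction testing; the training effect is a
# fractional attenuation of that error for the experimental group.
DEFAULT_ERROR_SD = 3.0          # deg, within-movement reproduction noise
DEFAULT_BIAS_MEAN = 7.5         # deg, mean magnitude of per-participant bias
DEFAULT_BIAS_SD = 2.0           # deg, spread of the bias magnitude
DEFAULT_MOTOR_NOISE_SD = 0.3    # deg, within-hold tremor
DEFAULT_EFFECT = 0.8            # EG learning gain (fractional error reduction)
DEFAULT_IMU_RATE = 74.0         # Hz
DEFAULT_EMG_FS = 1111.0         # Hz (typical for the wearable EMG family used)
CALIB_DURATION = 14.0           # s per calibration recording


@dataclass
class ParticipantProfile:
    id: str
    group: str                     # "EG" | "CG"
    error_bias: float              # deg, signed systematic reproduction bias
    error_sd: float = DEFAULT_ERROR_SD
    learning_gain: float = 0.0     # fractional |error| reduction post-training
    motor_noise_sd: float = DEFAULT_MOTOR_NOISE_SD
    seed: int = 0

    def __post_init__(self):
        if self.group not in ("EG", "CG"):
            raise ValueError(f"group must be EG or CG, got {self.group!r}")
        if self.error_sd <= 0:
            raise ValueError("error_sd must be positive")
        if not 0.0 <= self.learning_gain <= 1.0:
            raise ValueError("learning_gain must lie in [0, 1]")


@dataclass
class SynergyGroundTruth:
    """Generative counterpart of the synergy model: non-negative muscle
    weights with unit-norm columns and task-locked activation bursts."""

    W_true: np.ndarray                     # (7, k), unit column norms
    burst_width: float = 0.15              # s, SD of each activation burst
    burst_delays: tuple = ()               # s, per-synergy lag after an event
    noise_sd: float = 0.02

    def __post_init__(self):
        self.W_true = np.asarray(self.W_true, dtype=float)
        if self.W_true.ndim != 2 or self.W_true.shape[0] != len(MUSCLES):
            raise ValueError("W_true must be (7, k)")
        k = self.W_true.shape[1]
        if not 1 <= k <= 7:
            raise ValueError("synergy count must lie in [1, 7]")
        if np.any(self.W_true < 0):
            raise ValueError("W_true must be non-negative")
        norms = np.linalg.norm(self.W_true, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("W_true columns must have unit norm")
        # stagger the per-synergy bursts well beyond their width so the
        # activation rows are close to temporally orthogonal: a k-synergy
        # mixture then genuinely needs k components
        if not self.burst_delays:
            self.burst_delays = tuple(-0.5 * j for j in range(k))

    @property
    def k(self) -> int:
        return self.W_true.shape[1]


def default_synergy_truth(k: int = 3, noise_sd: float = 0.02) -> SynergyGroundTruth:
    """Ground truth with well-separated muscle supports (block structure)."""
    blocks = np.array_split(np.arange(len(MUSCLES)), k)
    W = np.zeros((len(MUSCLES), k))
    for j, idx in enumerate(blocks):
        W[idx, j] = 1.0 + 0.3 * np.arange(len(idx))
    W /= np.linalg.norm(W, axis=0, keepdims=True)
    return SynergyGroundTruth(W_true=W, noise_sd=noise_sd)


# ---------------------------------------------------------------------------
# Knee-angle trajectories


def _min_jerk(u: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on [0, 1]."""
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def _rest_included(game: str) -> float:
    # standing rest for squats (straight leg); seated mid-range for stretches
    return 180.0 if game in ("bunny", "pretest_squat") else 90.0


def gen_trajectory(
    schedule: ProtocolSchedule,
    profile: ParticipantProfile,
    phase: str = "pre",
    rate: float = DEFAULT_IMU_RATE,
    rng: np.random.Generator | None = None,
    transition: float = 1.0,
    tail: float = 1.0,
) -> tuple[KneeAngleSeries, list[dict]]:
    """Ground-truth knee trajectory executing a schedule.

    Each entry is approached with a minimum-jerk transition, held with motor
    noise at the target plus a proprioceptive error draw
    ``bias + N(0, error_sd)`` (attenuated by ``learning_gain`` post-training
    in the experimental group), then released back to rest.  Returns the
    series and one ground-truth record per entry (target, attempted angle,
    error, window) in the entry's own angle convention.
    """
    if phase not in ("pre", "post"):
        raise ValueError("phase must be 'pre' or 'post'")
    rng = np.random.default_rng(profile.seed) if rng is None else rng
    attenuation = 1.0
    if phase == "post":
        attenuation = 1.0 - (profile.learning_gain if profile.group == "EG" else 0.0)

    rest = _rest_included(schedule.game)
    t_end = schedule.span[1] + tail
    n = int(np.floor(t_end * rate)) + 1
    times = np.arange(n) / rate
    angle = np.full(n, rest)

    truth: list[dict] = []
    for entry in schedule.entries:
        err = attenuation * (profile.error_bias + rng.normal(0.0, profile.error_sd))
        target_conv = entry.target_deg
        held_conv = target_conv + err
        held_inc = held_conv if entry.convention == "included" else 180.0 - held_conv
        held_inc = float(np.clip(held_inc, 0.0, 180.0))

        t_in0 = entry.start - transition
        mask_in = (times >= t_in0) & (times < entry.start)
        u = (times[mask_in] - t_in0) / transition
        angle[mask_in] = rest + (held_inc - rest) * _min_jerk(u)
        mask_hold = (times >= entry.start) & (times <= entry.end)
        angle[mask_hold] = held_inc
        t_out1 = entry.end + transition
        mask_out = (times > entry.end) & (times <= t_out1)
        u = (times[mask_out] - entry.end) / transition
        angle[mask_out] = held_inc + (rest - held_inc) * _min_jerk(u)
        angle[times > t_out1] = rest

        truth.append(
            {
                "label": entry.label,
                "movement_class": entry.movement_class,
                "window": (entry.start, entry.end),
                "convention": entry.convention,
                "TKA": target_conv,
                "error_drawn": err,
            }
        )

    hold_mask = np.zeros(n, dtype=bool)
    for entry in schedule.entries:
        hold_mask |= (times >= entry.start) & (times <= entry.end)
    angle[hold_mask] += rng.normal(0.0, profile.motor_noise_sd, hold_mask.sum())
    angle = np.clip(angle, 0.0, 180.0)

    # ground-truth AKA is the realized angle (after motor noise and the
    # anatomical clip at full extension), averaged over the central 60% of
    # the hold -- the same summary the analysis recovers
    for entry, rec in zip(schedule.entries, truth):
        margin = (entry.end - entry.start) * 0.2
        mask = (times >= entry.start + margin) & (times <= entry.end - margin)
        aka_inc = float(angle[mask].mean())
        aka = aka_inc if entry.convention == "included" else 180.0 - aka_inc
        rec["AKA"] = aka
        rec["error"] = aka - rec["TKA"]
    return KneeAngleSeries(times=times, included_deg=angle), truth


# ---------------------------------------------------------------------------
# IMU quaternion synthesis


def _noise_quats(rng: np.random.Generator, n: int, sd_deg: float) -> np.ndarray:
    if sd_deg <= 0:
        return np.tile([1.0, 0.0, 0.0, 0.0], (n, 1))
    axes = rng.normal(size=(n, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    angles = rng.normal(0.0, sd_deg, n)
    return qt.quat_from_axis_angle(axes, angles)


def random_mounting_offset(rng: np.random.Generator, max_angle_deg: float = 30.0) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    return qt.quat_from_axis_angle(axis, rng.uniform(0.0, max_angle_deg))


def angles_to_imu(
    truth: KneeAngleSeries,
    mounting_offsets: dict[str, np.ndarray] | None = None,
    orientation_noise_sd: float = 0.25,
    rate: float = DEFAULT_IMU_RATE,
    rng: np.random.Generator | None = None,
    calib_duration: float = CALIB_DURATION,
) -> dict[str, dict[str, SensorStream]]:
    """Encode a ground-truth angle series as raw two-sensor IMU streams plus
    the two calibration recordings the pipeline consumes.

    The world frame is the flat calibration desk, so both sensors read
    (noisy) identity during the flat recording.  At upright stance each
    sensor reads its mounting offset; during the task the thigh segment
    rotates about the knee's Y axis by the ground-truth flexion while the
    shank stays fixed — only the relative rotation matters for the angle.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    if mounting_offsets is None:
        mounting_offsets = {s: random_mounting_offset(rng) for s in ("thigh_BF", "midshank")}

    n_cal = int(np.floor(calib_duration * rate)) + 1
    t_cal = np.arange(n_cal) / rate

    def make_stream(sensor_id, times, segment_quats):
        mount = mounting_offsets[sensor_id]
        raw = qt.qmul(segment_quats, mount)
        raw = qt.qmul(raw, _noise_quats(rng, len(times), orientation_noise_sd))
        return SensorStream(sensor_id=sensor_id, times=times,
                            quats=qt.normalize(raw), nominal_rate=rate)

    identity = np.tile([1.0, 0.0, 0.0, 0.0], (n_cal, 1))
    flat = {
        s: SensorStream(
            sensor_id=s,
            times=t_cal,
            quats=qt.normalize(qt.qmul(identity, _noise_quats(rng, n_cal, orientation_noise_sd))),
            nominal_rate=rate,
        )
        for s in ("thigh_BF", "midshank")
    }
    upright = {s: make_stream(s, t_cal, identity) for s in ("thigh_BF", "midshank")}

    flexion = 180.0 - truth.included_deg
    thigh_segment = qt.quat_from_axis_angle(np.array([0.0, 1.0, 0.0]), flexion)
    shank_segment = np.tile([1.0, 0.0, 0.0, 0.0], (len(truth), 1))
    task = {
        "thigh_BF": make_stream("thigh_BF", truth.times, thigh_segment),
        "midshank": make_stream("midshank", truth.times, shank_segment),
    }
    return {"flat": flat, "upright": upright, "task": task}


# ---------------------------------------------------------------------------
# Game events and EMG


def simulate_game_events(
    schedule: ProtocolSchedule,
    rng: np.random.Generator,
    success_prob: float = 0.9,
    catch_hold: float = 2.0,
) -> list[GameEvent]:
    """Realize a game schedule as an event log.

    Each carrot group or fish succeeds independently with ``success_prob``;
    a successful group yields its 9 carrot events spread over the hold, a
    successful fish a catch ``catch_hold`` s after its spawn, a failed fish
    a miss at its escape time.  Failed carrot groups collect a random strict
    subset of carrots (an incomplete group, which the synergy segmentation
    must reject).
    """
    events: list[GameEvent] = []
    for i, entry in enumerate(schedule.entries):
        ok = rng.random() < success_prob
        if schedule.game == "bunny":
            n_collect = 9 if ok else int(rng.integers(0, 9))
            t_carrots = np.linspace(entry.start, entry.end, 9)
            for ordinal in range(1, n_collect + 1):
                events.append(
                    GameEvent(t=float(t_carrots[ordinal - 1]), kind="carrot_collected",
                              group=i, ordinal=ordinal)
                )
        elif schedule.game == "fish":
            trail = int(entry.movement_class.split("_")[1])
            if ok:
                events.append(GameEvent(t=entry.start + catch_hold, kind="fish_caught", trail=trail))
            else:
                events.append(GameEvent(t=entry.end, kind="fish_missed", trail=trail))
        else:
            raise ValueError(f"not a game schedule: {schedule.game}")
    events.sort(key=lambda e: e.t)
    return events


def gen_emg(
    events: list[GameEvent],
    truth: SynergyGroundTruth,
    fs: float = DEFAULT_EMG_FS,
    duration: float | None = None,
    rng: np.random.Generator | None = None,
) -> EMGStream:
    """Non-negative synergy-mixture EMG aligned to game events.

    Activations are Gaussian bursts centred (with per-synergy lags) on each
    catch/collection event; the mixture ``W_true·H`` is perturbed with
    zero-mean Gaussian noise and clipped at zero.
    """
    if fs < 100:
        raise ValueError("EMG sampling rate must be >= 100 Hz")
    rng = np.random.default_rng(0) if rng is None else rng
    anchor = [e for e in events if e.kind in ("carrot_collected", "fish_caught")]
    if duration is None:
        duration = (max(e.t for e in events) if events else 0.0) + 2.0
    n = int(np.floor(duration * fs)) + 1
    t = np.arange(n) / fs
    k = truth.k
    H = np.zeros((k, n))
    for ev in anchor:
        for j in range(k):
            c = ev.t + truth.burst_delays[j]
            amp = rng.uniform(0.5, 1.5)
            H[j] += amp * np.exp(-0.5 * ((t - c) / truth.burst_width) ** 2)
    E = truth.W_true @ H
    if truth.noise_sd > 0:
        E = E + rng.normal(0.0, truth.noise_sd, E.shape)
    E = np.clip(E, 0.0, None)
    return EMGStream(times=t, data=E.T, fs=fs)


def noise_sd_for_snr(truth: SynergyGroundTruth, events, fs, snr_db: float,
                     rng: np.random.Generator | None = None) -> float:
    """Noise SD giving a target SNR (dB) for this event layout, computed
    from the RMS of the clean mixture."""
    clean = gen_emg(events, SynergyGroundTruth(truth.W_true, truth.burst_width,
                                               truth.burst_delays, 0.0),
                    fs=fs, rng=np.random.default_rng(0) if rng is None else rng)
    rms = float(np.sqrt(np.mean(clean.data**2)))
    return rms / (10.0 ** (snr_db / 20.0))


# ---------------------------------------------------------------------------
# Questionnaires

IMI_ITEMS = {
    "interest_enjoyment": 7,
    "perceived_competence": 6,
    "perceived_choice": 7,
    "pressure_tension": 5,
}
UEQ_ITEMS = {
    "attractiveness": 6,
    "perspicuity": 4,
    "efficiency": 4,
    "dependability": 4,
    "stimulation": 4,
    "novelty": 4,
}


def gen_questionnaires(
    profiles: list[ParticipantProfile],
    rng: np.random.Generator | None = None,
    imi_group_means: dict[str, dict[str, float]] | None = None,
    ueq_group_means: dict[str, dict[str, float]] | None = None,
    all_max: bool = False,
):
    """Item-level IMI (1..7) and UEQ (-3..+3) tables with group-dependent
    means; ``all_max=True`` pins every item at its ceiling (for exercising
    the scoring bounds)."""
    import pandas as pd

    rng = np.random.default_rng(0) if rng is None else rng
    imi_means = imi_group_means or {
        "EG": {"interest_enjoyment": 5.0, "perceived_competence": 4.8,
               "perceived_choice": 4.5, "pressure_tension": 2.5},
        "CG": {"interest_enjoyment": 5.0, "perceived_competence": 4.8,
               "perceived_choice": 4.5, "pressure_tension": 2.6},
    }
    ueq_means = ueq_group_means or {
        "EG": {"attractiveness": 2.7, "perspicuity": 2.8, "efficiency": 2.1,
               "dependability": 2.5, "stimulation": 2.5, "novelty": 2.0},
        "CG": {"attractiveness": 2.4, "perspicuity": 2.7, "efficiency": 2.3,
               "dependability": 2.3, "stimulation": 1.9, "novelty": 1.7},
    }
    imi_rows, ueq_rows = [], []
    for p in profiles:
        for subscale, n_items in IMI_ITEMS.items():
            mu = 7.0 if all_max else imi_means[p.group][subscale]
            vals = np.clip(np.rint(rng.normal(mu, 1.0, n_items)), 1, 7).astype(int)
            if all_max:
                vals[:] = 7
            for i, v in enumerate(vals, 1):
                imi_rows.append({"participant": p.id, "group": p.group,
                                 "subscale": subscale, "item": i, "value": int(v)})
        for dim, n_items in UEQ_ITEMS.items():
            mu = 3.0 if all_max else ueq_means[p.group][dim]
            vals = np.clip(np.rint(rng.normal(mu, 0.8, n_items)), -3, 3).astype(int)
            if all_max:
                vals[:] = 3
            for i, v in enumerate(vals, 1):
                ueq_rows.append({"participant": p.id, "group": p.group,
                                 "dimension": dim, "item": i, "value": int(v)})
    return pd.DataFrame(imi_rows), pd.DataFrame(ueq_rows)


# ---------------------------------------------------------------------------
# Full cohort


@dataclass
class ParticipantData:
    profile: ParticipantProfile
    schedules: dict            # {"pre_squat": ProtocolSchedule, ...}
    trajectories: dict         # schedule key -> KneeAngleSeries
    truths: dict               # schedule key -> list of ground-truth records
    imu: dict                  # schedule key -> {"flat":…, "upright":…, "task":…}
    game_schedules: dict       # {"bunny": …, "fish": …}
    events: dict               # game -> list[GameEvent]
    emg: dict                  # game -> EMGStream
    synergy_truth: SynergyGroundTruth


@dataclass
class CohortDataset:
    participants: list[ParticipantData]
    imi: object                # pandas DataFrame of IMI items
    ueq: object                # pandas DataFrame of UEQ items
    manifest: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for pd_ in self.participants:
            pdir = out / pd_.profile.id
            pdir.mkdir(exist_ok=True)
            for key, streams in pd_.imu.items():
                for stage, recs in streams.items():
                    write_sensor_csv(pdir / f"imu_{key}_{stage}.csv", recs)
            for key, series in pd_.trajectories.items():
                write_angle_csv(pdir / f"truth_{key}.csv", series)
            for game, evs in pd_.events.items():
                write_events(pdir / f"events_{game}.jsonl", evs)
            for game, emg in pd_.emg.items():
                write_emg_csv(pdir / f"emg_{game}.csv", emg)
            write_schedules(pdir / "schedules.json",
                            {**pd_.schedules, **pd_.game_schedules})
        self.imi.to_csv(out / "imi_items.csv", index=False)
        self.ueq.to_csv(out / "ueq_items.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1, default=str)


def make_profiles(
    n_eg: int,
    n_cg: int,
    effect: float,
    seed_seq: np.random.SeedSequence,
    error_sd: float = DEFAULT_ERROR_SD,
    bias_mean: float = DEFAULT_BIAS_MEAN,
    bias_sd: float = DEFAULT_BIAS_SD,
) -> list[ParticipantProfile]:
    """Participant profiles; the training effect enters as the EG learning
    gain, control participants get gain 0."""
    children = seed_seq.spawn(n_eg + n_cg)
    rng = np.random.default_rng(seed_seq.spawn(1)[0])
    profiles = []
    for i in range(n_eg + n_cg):
        group = "EG" if i < n_eg else "CG"
        magnitude = max(1.0, rng.normal(bias_mean, bias_sd))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        profiles.append(
            ParticipantProfile(
                id=f"P{i + 1:02d}",
                group=group,
                error_bias=sign * magnitude,
                error_sd=error_sd,
                learning_gain=effect if group == "EG" else 0.0,
                seed=int(children[i].generate_state(1)[0] % (2**31)),
            )
        )
    return profiles


def gen_cohort(
    n_eg: int = 7,
    n_cg: int = 7,
    effect: float = DEFAULT_EFFECT,
    seed: int = 0,
    *,
    with_imu: bool = True,
    with_emg: bool = True,
    emg_fs: float = DEFAULT_EMG_FS,
    synergy_k: int = 3,
    emg_noise_sd: float = 0.02,
    orientation_noise_sd: float = 0.25,
    max_mounting_offset: float = 30.0,
    error_sd: float = DEFAULT_ERROR_SD,
    bias_mean: float = DEFAULT_BIAS_MEAN,
    bias_sd: float = DEFAULT_BIAS_SD,
    imu_rate: float = DEFAULT_IMU_RATE,
) -> CohortDataset:
    """Generate a full synthetic cohort (default: the study's 7 + 7).

    ``with_imu``/``with_emg`` toggle the expensive raw-signal layers; the
    ground-truth trajectories, schedules and events are always produced.
    """
    if n_eg < 1 or n_cg < 1:
        raise ValueError("group sizes must be >= 1")
    root = np.random.SeedSequence(seed)
    profile_seq, data_seq = root.spawn(2)
    profiles = make_profiles(n_eg, n_cg, effect, profile_seq,
                             error_sd=error_sd, bias_mean=bias_mean, bias_sd=bias_sd)
    participants = []
    data_children = data_seq.spawn(len(profiles) + 1)
    for p, child in zip(profiles, data_children):
        rng = np.random.default_rng(child)
        schedules = {
            "pre_squat": test_schedule("pretest_squat", rng_seed=rng),
            "pre_stretch": test_schedule("pretest_stretch", rng_seed=rng),
            "post_squat": test_schedule("pretest_squat", rng_seed=rng),
            "post_stretch": test_schedule("pretest_stretch", rng_seed=rng),
        }
        trajectories, truths, imu = {}, {}, {}
        for key, sched in schedules.items():
            phase = "pre" if key.startswith("pre_") else "post"
            series, truth = gen_trajectory(sched, p, phase=phase, rate=imu_rate, rng=rng)
            trajectories[key] = series
            truths[key] = truth
            if with_imu:
                offsets = {s: random_mounting_offset(rng, max_mounting_offset)
                           for s in ("thigh_BF", "midshank")}
                imu[key] = angles_to_imu(series, offsets, orientation_noise_sd,
                                         rate=imu_rate, rng=rng)
        game_schedules = {
            "bunny": bunny_schedule(rng_seed=rng),
            "fish": fish_schedule(rng_seed=rng),
        }
        events = {g: simulate_game_events(s, rng) for g, s in game_schedules.items()}
        syn_truth = default_synergy_truth(k=synergy_k, noise_sd=emg_noise_sd)
        emg = {}
        if with_emg:
            for game, evs in events.items():
                duration = game_schedules[game].span[1] + 2.0
                emg[game] = gen_emg(evs, syn_truth, fs=emg_fs, duration=duration, rng=rng)
        participants.append(
            ParticipantData(
                profile=p, schedules=schedules, trajectories=trajectories,
                truths=truths, imu=imu, game_schedules=game_schedules,
                events=events, emg=emg, synergy_truth=syn_truth,
            )
        )
    q_rng = np.random.default_rng(data_children[-1])
    imi, ueq = gen_questionnaires(profiles, rng=q_rng)
    manifest = {
        "seed": seed,
        "n_eg": n_eg,
        "n_cg": n_cg,
        "effect": effect,
        "error_sd": error_sd,
        "bias_mean": bias_mean,
        "bias_sd": bias_sd,
        "emg_fs": emg_fs,
        "imu_rate": imu_rate,
        "profiles": [asdict(p) for p in profiles],
    }
    return CohortDataset(participants=participants, imi=imi, ueq=ueq, manifest=manifest)
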