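"""Study orchestration: configuration, cohort loading, and the full
analysis from raw (or simulated) files to a report.

The default configuration encodes the study protocol: 74 Hz IMU streams
with 14 s / 1000-sample calibration buffers; a squat game of 12 carrot
groups (2.5 s holds, 20 s gaps) and a stretch game of 12 fish (2 s catch
hold, 10 s escape) on trails at 90/120/150/180°; pre/post tests of 10
squats (TKA 90/130° flexion) and 10 stretches (TKA 135/180° included);
z-score outlier screening at |z| > 2.5; α = .05; and an 85% VAF threshold
for the synergy count.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import KneeAngleEstimator
from .metrics import participant_metrics, remove_outliers, segment_tests
from .protocol import read_events, read_schedules
from .simulate import CohortDataset, ParticipantData, ParticipantProfile, gen_cohort
from .stats import describe, mann_whitney, qq_normality_corr, score_imi, score_ueq
from .streams import read_angle_csv, read_emg_csv, read_sensor_csv
from .synergy import (
    EMGPreprocessor,
    fit_nmf,
    k_from_vaf_curve,
    match_synergies,
    segment_emg,
    vaf_curve,
)

log = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """All knobs of one analysis run; fully serializable to YAML."""

    seed: int = 0
    simulate: bool = True
    cohort_dir: str | None = None          # read inputs from here when not simulating

    # cohort / generator conditions
    n_eg: int = 7
    n_cg: int = 7
    effect: float = 0.8
    error_sd: float = 3.0
    bias_mean: float = 7.5
    bias_sd: float = 2.0

    # sensing
    imu_rate: float = 74.0
    calib_duration: float = 14.0
    buffer_len: int = 1000
    orientation_noise_sd: float = 0.25
    max_mounting_offset: float = 30.0
    emg_fs: float = 1111.0

    # protocol constants
    bunny_groups: int = 12
    carrots_per_group: int = 9
    bunny_hold: float = 2.5
    bunny_gap: float = 20.0
    n_fish: int = 12
    fish_hold: float = 2.0
    fish_escape: float = 10.0
    test_movements: int = 10
    test_hold: float = 5.0

    # analysis conventions
    ame_mode: str = "abs_of_mean"          # abs_of_mean | mean_of_abs
    z_threshold: float = 2.5
    outlier_scope: str = "pooled"          # pooled | per_group | none
    alpha: float = 0.05
    causal_filter: bool = False
    vaf_threshold: float = 85.0
    vaf_thresholds: tuple = (90.0, 85.0, 80.0)
    nmf_restarts: int = 10
    nmf_max_iter: int = 500
    synergy_k: int = 3

    # stage toggles (IMU encoding/decoding and EMG synthesis are the
    # expensive layers; the kinematic outcome needs only the IMU path)
    with_imu: bool = True
    with_emg: bool = True

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "vaf_thresholds" in raw:
            raw["vaf_thresholds"] = tuple(raw["vaf_thresholds"])
        return cls(**raw)


def load_cohort(cohort_dir) -> CohortDataset:
    """Read a written cohort directory back into memory."""
    root = Path(cohort_dir)
    with open(root / "manifest.json") as fh:
        manifest = json.load(fh)
    participants = []
    for prof_dict in manifest["profiles"]:
        profile = ParticipantProfile(**prof_dict)
        pdir = root / profile.id
        schedules = read_schedules(pdir / "schedules.json")
        test_keys = [k for k in schedules if k not in ("bunny", "fish")]
        game_keys = [k for k in schedules if k in ("bunny", "fish")]
        imu = {}
        trajectories = {}
        for key in test_keys:
            traj_path = pdir / f"truth_{key}.csv"
            if traj_path.exists():
                trajectories[key] = read_angle_csv(traj_path)
            stages = {}
            for stage in ("flat", "upright", "task"):
                p = pdir / f"imu_{key}_{stage}.csv"
                if p.exists():
                    stages[stage] = read_sensor_csv(p, nominal_rate=manifest["imu_rate"])
            if stages:
                imu[key] = stages
        events = {}
        emg = {}
        for game in game_keys:
            ev_path = pdir / f"events_{game}.jsonl"
            if ev_path.exists():
                events[game] = read_events(ev_path)
            emg_path = pdir / f"emg_{game}.csv"
            if emg_path.exists():
                emg[game] = read_emg_csv(emg_path, fs=manifest["emg_fs"])
        participants.append(
            ParticipantData(
                profile=profile,
                schedules={k: schedules[k] for k in test_keys},
                trajectories=trajectories,
                truths={},
                imu=imu,
                game_schedules={k: schedules[k] for k in game_keys},
                events=events,
                emg=emg,
                synergy_truth=None,
            )
        )
    imi = pd.read_csv(root / "imi_items.csv")
    ueq = pd.read_csv(root / "ueq_items.csv")
    return CohortDataset(participants=participants, imi=imi, ueq=ueq, manifest=manifest)


# ---------------------------------------------------------------------------
# Analysis stages


def participant_angle_series(p: ParticipantData, config: StudyConfig) -> dict:
    """Knee-angle series per test, via the calibrated IMU path when raw
    streams exist, else the recorded ground-truth trajectories."""
    out = {}
    for key, sched in p.schedules.items():
        if config.with_imu and key in p.imu:
            est = KneeAngleEstimator(buffer_len=config.buffer_len)
            est.fit({"flat": p.imu[key]["flat"], "upright": p.imu[key]["upright"]})
            out[key] = est.transform(p.imu[key]["task"])
        else:
            out[key] = p.trajectories[key]
    return out


def kinematic_metrics(cohort: CohortDataset, config: StudyConfig) -> pd.DataFrame:
    """Per-participant AME pre/post and IE per movement group."""
    rows = []
    for p in cohort.participants:
        series = participant_angle_series(p, config)
        seg = {key: segment_tests(series[key], p.schedules[key]) for key in series}
        for mg_key in ("squat", "stretch"):
            pre = seg.get(f"pre_{mg_key}", [])
            post = seg.get(f"post_{mg_key}", [])
            for m in participant_metrics(p.profile.id, p.profile.group, pre, post,
                                         ame_mode=config.ame_mode):
                rows.append(
                    {
                        "participant": m.participant,
                        "group": m.group,
                        "movement_group": m.movement_group,
                        "ame_pre": m.ame_pre,
                        "ame_post": m.ame_post,
                        "ie": m.ie,
                        "n_pre": m.n_pre,
                        "n_post": m.n_post,
                        "outlier_flag": False,
                    }
                )
    return pd.DataFrame(rows)


def group_inference(metrics: pd.DataFrame, config: StudyConfig) -> dict:
    """Outlier screening and the EG-vs-CG rank tests per movement group."""
    results = {}
    for mg, sub in metrics.groupby("movement_group"):
        sub = sub.copy()
        if config.outlier_scope == "pooled":
            kept, removed = remove_outliers(sub["ie"].to_numpy(), config.z_threshold)
            sub["outlier_flag"] = ~np.isin(sub["ie"].to_numpy(), kept)
        elif config.outlier_scope == "per_group":
            flags = np.zeros(len(sub), dtype=bool)
            for grp in ("EG", "CG"):
                mask = (sub["group"] == grp).to_numpy()
                kept, _ = remove_outliers(sub.loc[mask, "ie"].to_numpy(), config.z_threshold)
                flags[mask] = ~np.isin(sub.loc[mask, "ie"].to_numpy(), kept)
            sub["outlier_flag"] = flags
        else:
            sub["outlier_flag"] = False
        metrics.loc[sub.index, "outlier_flag"] = sub["outlier_flag"]
        eg = sub.loc[(sub["group"] == "EG") & ~sub["outlier_flag"], "ie"].to_numpy()
        cg = sub.loc[(sub["group"] == "CG") & ~sub["outlier_flag"], "ie"].to_numpy()
        one = mann_whitney(eg, cg, "one_sided_greater")
        two = mann_whitney(eg, cg, "two_sided")
        med_eg, q1_eg, q3_eg = describe(eg)
        med_cg, q1_cg, q3_cg = describe(cg)
        results[mg] = {
            "U": one.U,
            "p_one_sided": one.p,
            "p_two_sided": two.p,
            "method": one.method,
            "significant_one_sided": bool(one.p < config.alpha),
            "n_eg": int(eg.size),
            "n_cg": int(cg.size),
            "median_ie_eg": med_eg,
            "iqr_ie_eg": [q1_eg, q3_eg],
            "median_ie_cg": med_cg,
            "iqr_ie_cg": [q1_cg, q3_cg],
            "outliers_removed": int(sub["outlier_flag"].sum()),
            "qq_normality_corr_pooled": qq_normality_corr(np.concatenate([eg, cg])),
        }
    return results


def _bunny_class(event_id: str, schedule) -> str:
    g = int(event_id.split("_")[1])
    return schedule.entries[g].movement_class


def synergy_analysis(cohort: CohortDataset, config: StudyConfig) -> dict:
    """Per-segment synergy-count selection and cross-group weight matching.

    Selects k per preprocessed segment from its VAF curve at each
    threshold, tallies the counts (per-threshold histograms over
    movements), then fits one model per movement class and study group at
    the modal k of the configured threshold and matches EG vs CG weights.
    """
    prep = EMGPreprocessor(causal=config.causal_filter)
    seg_records = []
    class_pools: dict[tuple[str, str], list[np.ndarray]] = {}
    rng = np.random.default_rng(config.seed + 1)
    for p in cohort.participants:
        for game, emg in p.emg.items():
            events = p.events.get(game, [])
            for seg in segment_emg(emg, events):
                try:
                    clean = prep.transform(seg)
                except ValueError as exc:
                    log.warning("participant %s %s %s: %s",
                                p.profile.id, game, seg.event_id, exc)
                    continue
                cls = (seg.movement_class if game == "fish"
                       else _bunny_class(seg.event_id, p.game_schedules["bunny"]))
                vafs, _ = vaf_curve(clean.matrix, restarts=config.nmf_restarts,
                                    seed=int(rng.integers(0, 2**31 - 1)),
                                    max_iter=config.nmf_max_iter)
                rec = {"participant": p.profile.id, "group": p.profile.group,
                       "game": game, "movement_class": cls,
                       "vaf": vafs.tolist()}
                for thr in config.vaf_thresholds:
                    rec[f"k_at_{thr:g}"] = k_from_vaf_curve(vafs, thr)
                seg_records.append(rec)
                class_pools.setdefault((cls, p.profile.group), []).append(clean.matrix)

    if not seg_records:
        return {"segments": [], "k_counts": {}, "classes": {}}

    seg_df = pd.DataFrame(seg_records)
    k_counts = {
        f"{thr:g}": seg_df[f"k_at_{thr:g}"].value_counts().sort_index().to_dict()
        for thr in config.vaf_thresholds
    }

    classes = {}
    key_thr = f"k_at_{config.vaf_threshold:g}"
    for cls in sorted({c for c, _ in class_pools}):
        entry = {"n_segments": {}}
        W_by_group = {}
        for grp in ("EG", "CG"):
            pool = class_pools.get((cls, grp))
            if not pool:
                continue
            sub = seg_df[(seg_df["movement_class"] == cls) & (seg_df["group"] == grp)]
            k_mode = int(sub[key_thr].mode().iloc[0])
            E = np.hstack(pool)
            model = fit_nmf(E, k=k_mode, restarts=config.nmf_restarts,
                            seed=int(rng.integers(0, 2**31 - 1)),
                            max_iter=config.nmf_max_iter)
            W_by_group[grp] = model.W
            entry["n_segments"][grp] = len(pool)
            entry[grp] = {"k": k_mode, "vaf": model.vaf, "W": model.W.tolist()}
        if set(W_by_group) == {"EG", "CG"}:
            _, sims = match_synergies(W_by_group["EG"], W_by_group["CG"])
            entry["cross_group_cosine"] = sims.tolist()
            entry["mean_cross_group_cosine"] = float(sims.mean())
        classes[cls] = entry
    return {
        "segments": seg_records,
        "k_counts": k_counts,
        "classes": classes,
        "n_movements": len(seg_records),
    }


def questionnaire_summary(cohort: CohortDataset) -> dict:
    """Group-level IMI subscale and UEQ dimension scores."""
    out: dict = {"imi": {}, "ueq": {}}
    imi, ueq = cohort.imi, cohort.ueq
    for grp, sub in imi.groupby("group"):
        per_participant = []
        for pid, psub in sub.groupby("participant"):
            items = {s: g["value"].tolist() for s, g in psub.groupby("subscale")}
            per_participant.append(score_imi(items, mode="sum"))
        df = pd.DataFrame(per_participant)
        out["imi"][grp] = {
            "mean": df.mean().round(6).to_dict(),
            "sd": df.std(ddof=1).round(6).to_dict(),
        }
    for grp, sub in ueq.groupby("group"):
        per_participant = []
        for pid, psub in sub.groupby("participant"):
            items = {d: g["value"].tolist() for d, g in psub.groupby("dimension")}
            per_participant.append(score_ueq(items))
        df = pd.DataFrame(per_participant)
        out["ueq"][grp] = {
            "mean": df.mean().round(6).to_dict(),
            "sd": df.std(ddof=1).round(6).to_dict(),
        }
    return out


def run_pipeline(config: StudyConfig, out_dir=None,
                 cohort: CohortDataset | None = None) -> dict:
    """Execute the full analysis and (optionally) write the report.

    Stages: simulate/load → calibrate → knee angles → test segmentation →
    AME/IE metrics → outlier screen → exact rank tests, plus EMG
    segmentation → preprocessing → NMF/VAF synergy analysis and
    questionnaire scoring.
    """
    t_start = time.time()
    if cohort is None:
        if config.simulate:
            cohort = gen_cohort(
                n_eg=config.n_eg, n_cg=config.n_cg, effect=config.effect,
                seed=config.seed, with_imu=config.with_imu,
                with_emg=config.with_emg, emg_fs=config.emg_fs,
                synergy_k=config.synergy_k, error_sd=config.error_sd,
                bias_mean=config.bias_mean, bias_sd=config.bias_sd,
                orientation_noise_sd=config.orientation_noise_sd,
                max_mounting_offset=config.max_mounting_offset,
                imu_rate=config.imu_rate,
            )
        else:
            if not config.cohort_dir:
                raise ValueError("config.simulate is false and no cohort_dir given")
            cohort = load_cohort(config.cohort_dir)

    metrics = kinematic_metrics(cohort, config)
    inference = group_inference(metrics, config)
    synergy = (synergy_analysis(cohort, config)
               if config.with_emg and any(p.emg for p in cohort.participants)
               else {"segments": [], "k_counts": {}, "classes": {}})
    questionnaires = questionnaire_summary(cohort)

    report = {
        "provenance": {
            "software": f"kneeprop {__version__}",
            "config": asdict(config),
            "n_participants": len(cohort.participants),
        },
        "participant_metrics": metrics.to_dict(orient="records"),
        "inference": inference,
        "synergy": synergy,
        "questionnaires": questionnaires,
        "runtime_s": round(time.time() - t_start, 3),
    }
    if out_dir is not None:
        write_report(report, metrics, out_dir)
    return report


def write_report(report: dict, metrics: pd.DataFrame, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # runtime is wall-clock noise; keep the serialized report reproducible
    stable = {k: v for k, v in report.items() if k != "runtime_s"}
    with open(out / "report.json", "w") as fh:
        json.dump(stable, fh, indent=1, sort_keys=True)
    metrics.to_csv(out / "participant_metrics.csv", index=False)
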