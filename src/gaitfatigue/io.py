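"""CSV/JSON readers and writers for cohorts and stage outputs.

A cohort on disk is a directory of per-(participant, bout, sensor) CSV
files — ``time_s`` plus one column per channel — alongside ``labels.csv``,
per-bout ground-truth heel-strike CSVs, and a ``manifest.json`` tying
everything together.  The same layout accommodates identically-shaped real
sensor exports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import MUSCLES, Channel, RawRecording
from .synthetic import CohortDataset, GroundTruth, ParticipantProfile, SimulationConfig
from .labels import borg_to_class

__all__ = ["write_cohort", "read_cohort", "write_json"]

_AXES = ("x", "y", "z")


def write_json(obj, path: Path | str) -> None:
    """Deterministic JSON dump (sorted keys, stable float formatting)."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _bout_frames(rec: RawRecording) -> dict[str, pd.DataFrame]:
    frames: dict[str, pd.DataFrame] = {}
    for site in ("foot", "l5s1"):
        cols = {"time_s": rec.channel(site, "accel", "x").times}
        for mod in ("accel", "gyro"):
            for ax in _AXES:
                cols[f"{mod}_{ax}"] = rec.channel(site, mod, ax).data
        frames[f"{site}_imu"] = pd.DataFrame(cols)
    emg_cols = {}
    for muscle in MUSCLES:
        ch = rec.select(modality="emg_envelope", axis=muscle)[0]
        emg_cols.setdefault("time_s", ch.times)
        emg_cols[muscle] = ch.data
    frames["emg"] = pd.DataFrame(emg_cols)
    hr = rec.select(modality="hr")[0]
    frames["hr"] = pd.DataFrame({"time_s": hr.times, "bpm": hr.data})
    return frames


def write_cohort(ds: CohortDataset, outdir: Path | str) -> Path:
    """Write a cohort as CSV files plus a manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": ds.config.to_dict(),
        "participants": {},
        "files": {},
    }
    for prof in ds.profiles:
        manifest["participants"][prof.id] = {
            "age": prof.age,
            "walking_speed": prof.walking_speed,
            "baseline_cycle_time": prof.baseline_cycle_time,
            "emg_baseline_rms": prof.emg_baseline_rms,
        }
    for pid, bout, rec in ds.bouts():
        for sensor, frame in _bout_frames(rec).items():
            name = f"{pid}_bout{bout}_{sensor}.csv"
            frame.to_csv(outdir / name, index=False)
            manifest["files"].setdefault(pid, {}).setdefault(str(bout), {})[sensor] = name
        truth = ds.ground_truth[pid]
        name = f"{pid}_bout{bout}_heel_strikes.csv"
        pd.DataFrame({"time_s": truth.heel_strike_times[bout]}).to_csv(
            outdir / name, index=False)
        manifest["files"][pid][str(bout)]["heel_strikes"] = name
    ds.labels.to_csv(outdir / "labels.csv", index=False)
    manifest["labels"] = "labels.csv"
    path = outdir / "manifest.json"
    write_json(manifest, path)
    return path


def read_cohort(indir: Path | str) -> CohortDataset:
    """Reconstruct a CohortDataset from a directory written by write_cohort."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    config = SimulationConfig.from_dict(manifest["config"])
    labels = pd.read_csv(indir / manifest["labels"])

    profiles: list[ParticipantProfile] = []
    recordings: dict[str, list[RawRecording]] = {}
    truths: dict[str, GroundTruth] = {}
    for pid, meta in manifest["participants"].items():
        profiles.append(ParticipantProfile(
            id=pid, age=meta["age"], walking_speed=meta["walking_speed"],
            baseline_cycle_time=meta["baseline_cycle_time"],
            emg_baseline_rms=meta["emg_baseline_rms"]))
        plabels = labels[labels["participant"] == pid].sort_values("bout")
        bouts = sorted(manifest["files"][pid], key=int)
        recs, hs_all, hr_all = [], [], []
        for bout in bouts:
            files = manifest["files"][pid][bout]
            channels: list[Channel] = []
            for site in ("foot", "l5s1"):
                frame = pd.read_csv(indir / files[f"{site}_imu"])
                for mod in ("accel", "gyro"):
                    for ax in _AXES:
                        channels.append(Channel(site, mod, ax, config.fs_imu,
                                                frame[f"{mod}_{ax}"].to_numpy()))
            emg = pd.read_csv(indir / files["emg"])
            emg_site = {"gastrocnemius": "shank", "tibialis_anterior": "shank",
                        "rectus_femoris": "thigh", "biceps_femoris": "thigh"}
            for muscle in MUSCLES:
                channels.append(Channel(emg_site[muscle], "emg_envelope", muscle,
                                        config.fs_emg, emg[muscle].to_numpy()))
            hr = pd.read_csv(indir / files["hr"])
            channels.append(Channel("chest", "hr", "bpm", config.fs_hr,
                                    hr["bpm"].to_numpy()))
            recs.append(RawRecording(channels=channels, t0=0.0,
                                     participant=pid, bout=int(bout)))
            hs = pd.read_csv(indir / files["heel_strikes"])["time_s"].to_numpy()
            hs_all.append(hs)
            hr_all.append(hr["bpm"].to_numpy())
        truths[pid] = GroundTruth(
            heel_strike_times=hs_all,
            fatigue_class=[borg_to_class(int(b)) for b in plabels["borg"]],
            borg=[int(b) for b in plabels["borg"]],
            lactate_surrogate=[float(v) for v in plabels["lactate_surrogate"]],
            hr_series=hr_all)
        recordings[pid] = recs
    return CohortDataset(config=config, profiles=profiles, recordings=recordings,
                         ground_truth=truths, labels=labels)
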