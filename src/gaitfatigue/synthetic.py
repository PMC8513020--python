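"""Synthetic treadmill-walking cohorts with known gait events and labels.

The generator emulates the structure of a fatigue-inducement protocol:
each participant walks a baseline bout (bout 0, non-fatigued) followed by
four progressively more fatiguing rounds, for five bouts of at least 120 s
of treadmill walking.  Each bout is recorded by a foot-instep IMU and an
L5-S1 IMU at 128 Hz, four sEMG envelope channels at 512 Hz, and a 1 Hz
heart-rate stream.  Fatigue acts on the signals through a configurable
effect ladder indexed by the bout's fatigue stage (0 = baseline):

* cycle-time lengthening — gait cycles stretch by ``effect_cycle_time``
  per stage (slower cadence under fatigue);
* foot-acceleration amplitude change — heel-strike shock transients and
  push-off bumps scale by ``effect_foot_accel`` per stage (reduced shock
  attenuation; the sign is configurable because slower walking can also
  lower peak accelerations);
* torso-motion drift — L5-S1 oscillation amplitudes scale by
  ``effect_torso`` per stage;
* EMG-RMS drift — each muscle's envelope scales by ``effect_emg_rms`` per
  stage (declining envelope amplitude signals muscular fatigue).

The foot sagittal gyro carries one fixed waveform template per gait cycle:
a toe-off minimum, a mid-swing maximum and a heel-strike minimum (the
second minimum of the cycle), time-warped to the cycle duration.  Ground
truth (heel-strike times, per-bout Borg value, fatigue class, a monotone
lactate surrogate and the heart-rate trace) is returned alongside the
signals, so segmentation and classification can be scored exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .labels import FatigueClass, borg_to_class
from .recording import MUSCLES, Channel, RawRecording

__all__ = [
    "SimulationConfig",
    "ParticipantProfile",
    "GroundTruth",
    "CohortDataset",
    "simulate_participant",
    "simulate_cohort",
]

# Foot sagittal-gyro cycle template (gait-phase units).  The stance phase sits near zero, a broad positive half-sine lobe spans
# the swing with its mid-swing maximum, and sharp negative notches mark
# toe-off (swing onset) and heel strike (cycle boundary).  The heel strike
# is the second of the two minima of each cycle in time order, and the
# broad lobe puts the dominant spectral line at the stride frequency.
_SWING_START = 0.45        # swing-lobe onset, cycle fraction
_SWING_AMP = 5.0           # mid-swing peak, rad/s
_TO_NOTCH = (-2.0, 0.47, 0.05)   # amplitude rad/s, phase, width (cycle fraction)
_HS_NOTCH = (-3.5, 1.00, 0.04)

# Gravity along the vertical accelerometer axis, m/s^2.
_G = 9.81

# EMG activation burst centres as gait-cycle phases, per muscle.
_EMG_PHASE = {
    "gastrocnemius": 0.45,       # push-off
    "tibialis_anterior": 0.05,   # loading response after heel strike
    "rectus_femoris": 0.15,      # early stance
    "biceps_femoris": 0.88,      # late swing
}


@dataclass
class SimulationConfig:
    """Study-level generator settings.

    Defaults reproduce the emulated protocol: 24 participants, five bouts
    (baseline + four fatigue rounds) of 120 s walking, IMUs at 128 Hz, EMG
    envelopes at 512 Hz, heart rate at 1 Hz.  Effect sizes are fractional
    changes per fatigue stage (= bout index).
    """

    n_participants: int = 24
    bouts_per_participant: int = 5
    bout_duration: float = 120.0      # seconds
    fs_imu: float = 128.0             # Hz
    fs_emg: float = 512.0             # Hz
    fs_hr: float = 1.0                # Hz
    baseline_cycle_time: float = 1.10   # cohort mean, seconds
    cycle_time_spread: float = 0.08     # between-participant SD, seconds
    cycle_cv: float = 0.03              # within-bout cycle-duration CV
    effect_cycle_time: float = 0.05     # fractional lengthening per stage
    effect_foot_accel: float = 0.05     # fractional amplitude change per stage
    effect_emg_rms: float = -0.10       # fractional RMS drift per stage
    effect_torso: float = 0.05          # fractional torso drift per stage
    noise_sd: dict[str, float] = field(default_factory=lambda: {
        "accel": 0.05,          # m/s^2
        "gyro": 0.05,           # rad/s
        "emg_envelope": 0.005,  # mV
        "hr": 1.0,              # bpm
    })
    borg_schedule: tuple[int, ...] = (0, 2, 4, 7, 9)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_participants", "bouts_per_participant"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("bout_duration", "fs_imu", "fs_emg", "fs_hr",
                     "baseline_cycle_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.cycle_time_spread < 0 or self.cycle_cv < 0:
            raise ValueError("spread and CV must be non-negative")
        if len(self.borg_schedule) != self.bouts_per_participant:
            raise ValueError("borg_schedule must have one value per bout")
        for b in self.borg_schedule:
            if int(b) != b or not 0 <= int(b) <= 10:
                raise ValueError("borg_schedule values must be integers in [0, 10]")
        if borg_to_class(int(self.borg_schedule[0])) is not FatigueClass.Low:
            raise ValueError("bout 0 must map to the Low fatigue class")
        for key, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise_sd[{key!r}] must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["borg_schedule"] = list(self.borg_schedule)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "borg_schedule" in d:
            d["borg_schedule"] = tuple(d["borg_schedule"])
        return cls(**d)


@dataclass
class ParticipantProfile:
    """Per-participant anthropometrics and baselines."""

    id: str
    age: float                     # years
    walking_speed: float           # m/s, self-selected
    baseline_cycle_time: float     # seconds
    emg_baseline_rms: dict[str, float]  # arbitrary units (mV), per muscle

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if not 0.7 <= self.baseline_cycle_time <= 1.6:
            raise ValueError("baseline_cycle_time outside physiological range (0.7-1.6 s)")


@dataclass
class GroundTruth:
    """Per-bout truth for one participant: events, labels, surrogates."""

    heel_strike_times: list[np.ndarray]     # seconds, per bout
    fatigue_class: list[FatigueClass]       # per bout
    borg: list[int]                         # per bout
    lactate_surrogate: list[float]          # mmol/L-like, per bout
    hr_series: list[np.ndarray]             # bpm at fs_hr, per bout

    def mean_cycle_time(self, bout: int) -> float:
        hs = self.heel_strike_times[bout]
        if hs.size < 2:
            raise ValueError("need at least two heel strikes")
        return float(np.mean(np.diff(hs)))


@dataclass
class CohortDataset:
    """All recordings, ground truth and labels for one simulated cohort."""

    config: SimulationConfig
    profiles: list[ParticipantProfile]
    recordings: dict[str, list[RawRecording]]   # participant id -> per-bout
    ground_truth: dict[str, GroundTruth]
    labels: pd.DataFrame                        # participant, bout, borg, class, lactate

    def bouts(self):
        """Iterate (participant_id, bout_index, recording)."""
        for pid, recs in self.recordings.items():
            for b, rec in enumerate(recs):
                yield pid, b, rec


def _participant_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))


def _draw_profile(index: int, config: SimulationConfig,
                  rng: np.random.Generator) -> ParticipantProfile:
    age = float(np.clip(rng.normal(21.75, 1.16), 18.0, 35.0))
    speed = float(np.clip(rng.normal(1.2, 0.15), 0.6, 2.0))
    t0 = float(np.clip(rng.normal(config.baseline_cycle_time,
                                  config.cycle_time_spread), 0.8, 1.5))
    emg = {m: float(0.15 * np.exp(rng.normal(0.0, 0.2))) for m in MUSCLES}
    return ParticipantProfile(id=f"P{index:02d}", age=age, walking_speed=speed,
                              baseline_cycle_time=t0, emg_baseline_rms=emg)


def _cycle_schedule(rng: np.random.Generator, duration: float, nominal: float,
                    cv: float) -> tuple[np.ndarray, np.ndarray]:
    """Draw cycle start times and durations covering one bout.

    The bout opens mid-cycle (a partial lead-in stride) so the first
    ground-truth heel strike is preceded by a toe-off and a mid-swing peak,
    mirroring a recording that starts while the subject is already walking.
    Returns (starts, durations) for every complete cycle; cycle k's heel
    strike falls at ``starts[k] + durations[k]``.
    """
    jitter = lambda: float(np.clip(rng.normal(0.0, cv), -3 * cv, 3 * cv))
    starts, durs = [], []
    d0 = nominal * (1.0 + jitter())
    t = -0.25 * d0
    d = d0
    while t + d <= duration:
        starts.append(t)
        durs.append(d)
        t += d
        d = nominal * (1.0 + jitter())
    return np.asarray(starts), np.asarray(durs)


def _add_gaussian(sig: np.ndarray, t: np.ndarray, center: float, amp: float,
                  sigma: float) -> None:
    """Add a Gaussian pulse in place, touching only a +-5 sigma slice."""
    fs = 1.0 / (t[1] - t[0])
    lo = max(0, int((center - 5 * sigma) * fs))
    hi = min(t.size, int(np.ceil((center + 5 * sigma) * fs)) + 1)
    if lo >= hi:
        return
    sl = t[lo:hi]
    sig[lo:hi] += amp * np.exp(-0.5 * ((sl - center) / sigma) ** 2)


def _phase_array(t: np.ndarray, starts: np.ndarray, durs: np.ndarray) -> np.ndarray:
    """Continuous gait phase (cycles elapsed) at each time sample.

    Linear within each cycle; past the final heel strike the phase is
    extrapolated a quarter cycle into a phantom stance and then frozen, so
    the tail of the bout carries quiet stance-level signal and no phantom
    gait events.
    """
    bounds = np.concatenate([starts, [starts[-1] + durs[-1]]])
    idx = np.arange(bounds.size, dtype=float)
    phase = np.interp(t, bounds, idx)
    tail = t > bounds[-1]
    if np.any(tail):
        phase[tail] = np.minimum(
            idx[-1] + (t[tail] - bounds[-1]) / durs[-1], idx[-1] + 0.25)
    return phase


def _wrapped_notch(frac: np.ndarray, amp: float, center: float,
                   width: float) -> np.ndarray:
    d = np.abs(frac - center)
    d = np.minimum(d, 1.0 - d)
    return amp * np.exp(-0.5 * (d / width) ** 2)


def _foot_gyro(frac: np.ndarray) -> np.ndarray:
    """Foot sagittal angular velocity as a function of wrapped gait phase."""
    frac = np.mod(frac, 1.0)
    sig = np.zeros_like(frac)
    swing = frac >= _SWING_START
    sig[swing] = _SWING_AMP * np.sin(
        np.pi * (frac[swing] - _SWING_START) / (1.0 - _SWING_START))
    sig += _wrapped_notch(frac, *_TO_NOTCH)
    sig += _wrapped_notch(frac, *_HS_NOTCH)
    return sig


def _foot_accel_vertical(t: np.ndarray, starts: np.ndarray, durs: np.ndarray,
                         amp_scale: float) -> np.ndarray:
    """Vertical foot acceleration: gravity, push-off bump, heel-strike shock.

    Each heel strike adds a decaying 15 Hz oscillation (the impact shock
    wave); its amplitude carries the fatigue effect.
    """
    sig = np.full_like(t, _G)
    fs = 1.0 / (t[1] - t[0])
    for s, d in zip(starts, durs):
        _add_gaussian(sig, t, s + 0.55 * d, 2.0 * amp_scale, 0.06 * d)
        hs = s + d
        lo = max(0, int(hs * fs))
        hi = min(t.size, int((hs + 0.20) * fs))
        if lo < hi:
            dt = t[lo:hi] - hs
            sig[lo:hi] += (1.5 * amp_scale * np.exp(-dt / 0.04)
                           * np.sin(2 * np.pi * 15.0 * dt))
    return sig


def _simulate_bout(profile: ParticipantProfile, config: SimulationConfig,
                   stage: int, rng: np.random.Generator
                   ) -> tuple[RawRecording, np.ndarray, np.ndarray]:
    """One bout at the given fatigue stage; returns (recording, hs_times, hr)."""
    nominal = profile.baseline_cycle_time * (1.0 + config.effect_cycle_time * stage)
    if config.bout_duration < 3 * nominal:
        raise ValueError("bout too short: duration must cover at least 3 nominal cycles")

    duration = config.bout_duration
    n_imu = int(round(duration * config.fs_imu))
    n_emg = int(round(duration * config.fs_emg))
    n_hr = max(1, int(round(duration * config.fs_hr)))
    t_imu = np.arange(n_imu) / config.fs_imu
    t_emg = np.arange(n_emg) / config.fs_emg

    starts, durs = _cycle_schedule(rng, duration, nominal, config.cycle_cv)
    heel_strikes = starts + durs            # one per complete cycle
    heel_strikes = heel_strikes[heel_strikes <= duration]

    phase_imu = _phase_array(t_imu, starts, durs)
    phase_emg = _phase_array(t_emg, starts, durs)
    frac_imu = np.mod(phase_imu, 1.0)

    accel_amp = 1.0 + config.effect_foot_accel * stage
    torso_amp = 1.0 + config.effect_torso * stage
    n_accel = config.noise_sd.get("accel", 0.0)
    n_gyro = config.noise_sd.get("gyro", 0.0)
    n_emgsd = config.noise_sd.get("emg_envelope", 0.0)
    n_hrsd = config.noise_sd.get("hr", 0.0)

    channels: list[Channel] = []

    # --- foot IMU ---
    gyro_sag = _foot_gyro(phase_imu)
    for axis, scale in (("x", 0.15), ("y", 0.10), ("z", 1.0)):
        data = scale * gyro_sag + n_gyro * rng.standard_normal(n_imu)
        channels.append(Channel("foot", "gyro", axis, config.fs_imu, data))
    acc_v = _foot_accel_vertical(t_imu, starts, durs, accel_amp)
    acc_ml = 0.3 * (acc_v - _G)
    acc_ap = 0.2 * (acc_v - _G)
    for axis, base in (("x", acc_v), ("y", acc_ml), ("z", acc_ap)):
        data = base + n_accel * rng.standard_normal(n_imu)
        channels.append(Channel("foot", "accel", axis, config.fs_imu, data))

    # --- L5-S1 IMU: smooth torso oscillations at step (2/cycle) and stride
    # frequency, amplitude carrying the torso effect ---
    tor_v = _G + 0.8 * torso_amp * np.sin(4 * np.pi * frac_imu)
    tor_ml = 0.4 * torso_amp * np.sin(2 * np.pi * frac_imu)
    tor_ap = 0.3 * torso_amp * np.cos(2 * np.pi * frac_imu)
    for axis, base in (("x", tor_v), ("y", tor_ml), ("z", tor_ap)):
        data = base + n_accel * rng.standard_normal(n_imu)
        channels.append(Channel("l5s1", "accel", axis, config.fs_imu, data))
    for axis, amp in (("x", 0.25), ("y", 0.20), ("z", 0.15)):
        base = amp * torso_amp * np.sin(2 * np.pi * frac_imu + 0.5)
        data = base + n_gyro * rng.standard_normal(n_imu)
        channels.append(Channel("l5s1", "gyro", axis, config.fs_imu, data))

    # --- sEMG envelopes: positive low-frequency activation bursts, one per
    # cycle at a muscle-specific phase, scaled by the per-stage RMS drift ---
    frac_emg = np.mod(phase_emg, 1.0)
    emg_site = {"gastrocnemius": "shank", "tibialis_anterior": "shank",
                "rectus_femoris": "thigh", "biceps_femoris": "thigh"}
    for muscle in MUSCLES:
        amp = profile.emg_baseline_rms[muscle] * (1.0 + config.effect_emg_rms * stage)
        dist = np.abs(frac_emg - _EMG_PHASE[muscle])
        dist = np.minimum(dist, 1.0 - dist)          # wrapped phase distance
        env = amp * (0.4 + np.exp(-0.5 * (dist / 0.08) ** 2))
        data = env + n_emgsd * rng.standard_normal(n_emg)
        channels.append(Channel(emg_site[muscle], "emg_envelope", muscle,
                                config.fs_emg, data))

    # --- heart rate: stage-dependent plateau with an on-bout rise ---
    t_hr = np.arange(n_hr) / config.fs_hr
    hr = (85.0 + 12.0 * stage + 5.0 * (1.0 - np.exp(-t_hr / 30.0))
          + n_hrsd * rng.standard_normal(n_hr))
    channels.append(Channel("chest", "hr", "bpm", config.fs_hr, hr))

    rec = RawRecording(channels=channels, t0=0.0, participant=profile.id)
    return rec, heel_strikes, hr


def simulate_participant(profile: ParticipantProfile, config: SimulationConfig,
                         seed: int | np.random.SeedSequence
                         ) -> tuple[list[RawRecording], GroundTruth]:
    """Simulate every bout for one participant.

    The fatigue stage equals the bout index (0 = non-fatigued baseline),
    and each configured effect scales linearly with the stage.  Identical
    (profile, config, seed) inputs give bit-identical output.
    """
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(int(seed))
    bout_seeds = ss.spawn(config.bouts_per_participant + 1)
    lact_rng = np.random.Generator(np.random.PCG64(bout_seeds[-1]))

    recordings: list[RawRecording] = []
    hs_all, classes, borgs, lactate, hr_all = [], [], [], [], []
    level = 1.2  # resting lactate surrogate
    for bout in range(config.bouts_per_participant):
        rng = np.random.Generator(np.random.PCG64(bout_seeds[bout]))
        rec, hs, hr = _simulate_bout(profile, config, bout, rng)
        rec.bout = bout
        borg = int(config.borg_schedule[bout])
        if bout > 0:
            # monotone by construction: a non-negative increment per stage
            level = level + 1.0 + 0.1 * abs(lact_rng.standard_normal())
        recordings.append(rec)
        hs_all.append(hs)
        borgs.append(borg)
        classes.append(borg_to_class(borg))
        lactate.append(round(level, 2))
        hr_all.append(hr)

    truth = GroundTruth(heel_strike_times=hs_all, fatigue_class=classes,
                        borg=borgs, lactate_surrogate=lactate, hr_series=hr_all)
    return recordings, truth


def simulate_cohort(config: SimulationConfig) -> CohortDataset:
    """Simulate the full cohort with participant-indexed sub-seeds."""
    profiles: list[ParticipantProfile] = []
    recordings: dict[str, list[RawRecording]] = {}
    truths: dict[str, GroundTruth] = {}
    rows = []
    for i in range(config.n_participants):
        ss = _participant_seed(config.seed, i)
        prof_rng = np.random.Generator(np.random.PCG64(ss.spawn(1)[0]))
        profile = _draw_profile(i, config, prof_rng)
        recs, truth = simulate_participant(profile, config, ss)
        profiles.append(profile)
        recordings[profile.id] = recs
        truths[profile.id] = truth
        for b in range(config.bouts_per_participant):
            rows.append({
                "participant": profile.id,
                "bout": b,
                "borg": truth.borg[b],
                "fatigue_class": truth.fatigue_class[b].label,
                "lactate_surrogate": truth.lactate_surrogate[b],
            })
    labels = pd.DataFrame(rows)
    return CohortDataset(config=config, profiles=profiles, recordings=recordings,
                         ground_truth=truths, labels=labels)
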