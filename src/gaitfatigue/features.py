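"""Per-gait-cycle feature engineering and baseline normalization.

Every retained gait cycle yields 43 features: ten time/frequency-domain
statistics of the foot acceleration magnitude, nine of the foot angular
velocity magnitude, ten each of the L5-S1 (torso) acceleration and angular
velocity magnitudes, and the RMS of the four sEMG envelopes.  Tri-axial
IMU channels are collapsed to their Euclidean magnitude before statistics,
and EMG windows cover the same time interval as the IMU window on the EMG
clock.

Because absolute feature scales differ strongly between participants,
features are normalized to each participant's non-fatigued baseline: for
every feature, the reference value is the mean over the first ten gait
cycles of bout 0, and every value is divided by that reference.  After
normalization the per-participant mean of the first ten bout-0 cycles of
every feature is exactly 1.

The statistic definitions are fixed conventions of this package:

* ``std``/``var``: population (divide by n);
* ``energy``: mean of squared samples (rate-independent);
* ``entropy``: Shannon entropy (natural log) of a 16-bin histogram of the
  window normalized to probabilities, with 0*log(0) := 0;
* ``kurtosis``: Fisher (excess), 0 for zero-variance windows;
* ``maxfreq``: frequency of the largest FFT magnitude excluding DC;
* ``stdfreq``: standard deviation of the normalized (DC-excluded) power
  spectral distribution;
* ``rms``: root of the mean of squared envelope samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import CycleWindow
from .recording import MUSCLES, RawRecording

__all__ = [
    "FEATURE_NAMES",
    "SENSOR_FEATURES",
    "NormalizationReference",
    "stat_features",
    "extract_window_features",
    "compute_reference",
    "normalize",
    "assemble_dataset",
    "normalize_dataset",
]

_STATS_10 = ("mean", "std", "max", "var", "median", "energy", "entropy",
             "kurtosis", "maxfreq", "stdfreq")

#: The 43 feature names, index 0-42.  Spelling quirks ("curtosis",
#: "Kurtosis", "tibilis") are kept verbatim so exported tables match the
#: published naming.
FEATURE_NAMES: tuple[str, ...] = (
    "gait_mean_acce", "gait_std_acce", "gait_max_acce", "gait_var_acce",
    "gait_median_acce", "gait_energy_acce", "gait_entropy_acce",
    "gait_kurtosis_acce", "gait_maxfreq_acce", "gait_stdfreq_acce",
    "gait_mean_gyro", "gait_std_gyro", "gait_max_gyro", "gait_var_gyro",
    "gait_median_gyro", "gait_energy_gyro", "gait_entropy_gyro",
    "gait_curtosis_gyro", "gait_maxfreq_gyro",
    "l2_mean_acce", "l2_std_acce", "l2_max_acce", "l2_var_acce",
    "l2_median_acce", "l2_energy_acce", "l2_entropy_acce",
    "l2_kurtosis_acce", "l2_maxfreq_acce", "l2_stdfreq_acce",
    "l2_mean_gyro", "l2_std_gyro", "l2_max_gyro", "l2_var_gyro",
    "l2_median_gyro", "l2_energy_gyro", "l2_entropy_gyro",
    "l2_Kurtosis_gyro", "l2_maxfreq_gyro", "l2_stdfreq_gyro",
    "rms_gastro", "rms_tibilisAnterior", "rms_rectusFemoris",
    "rms_bicepsFemoris",
)

#: Feature indices induced by each sensor, used by the ablation stage.
SENSOR_FEATURES: dict[str, tuple[int, ...]] = {
    "foot": tuple(range(0, 19)),
    "l5s1": tuple(range(19, 39)),
    "emg": tuple(range(39, 43)),
}

_ENTROPY_BINS = 16
_MIN_WINDOW = 8
_BASELINE_WINDOWS = 10

#: Identifier columns carried alongside the 43 features.
PROVENANCE_COLUMNS = ("participant", "bout", "cycle")
LABEL_COLUMNS = ("borg", "fatigue_class", "lactate_surrogate")


def stat_features(window: np.ndarray, fs: float) -> dict[str, float]:
    """The ten time/frequency statistics of one windowed signal.

    Returns a dict keyed by the short statistic names (``mean`` ...
    ``stdfreq``) under the conventions documented in the module docstring.
    """
    x = np.asarray(window, dtype=float)
    if x.size < _MIN_WINDOW:
        raise ValueError(f"window too short: need >= {_MIN_WINDOW} samples")
    n = x.size
    mean = float(np.mean(x))
    var = float(np.var(x))          # population
    std = float(np.sqrt(var))
    energy = float(np.mean(x ** 2))

    # windows whose range is below float resolution cannot be binned and
    # follow the constant-window convention (entropy 0)
    if not x.max() - x.min() > _ENTROPY_BINS * np.spacing(np.abs(x).max()):
        entropy = 0.0
    else:
        counts, _ = np.histogram(x, bins=_ENTROPY_BINS)
        p = counts / n
        nz = p[p > 0]
        entropy = float(-np.sum(nz * np.log(nz)))

    if var == 0.0:
        kurtosis = 0.0
    else:
        kurtosis = float(np.mean((x - mean) ** 4) / var ** 2 - 3.0)

    spectrum = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mags = spectrum[1:]             # exclude DC
    if mags.size == 0 or not np.any(mags > 0):
        maxfreq = 0.0
        stdfreq = 0.0
    else:
        maxfreq = float(freqs[1:][np.argmax(mags)])
        power = mags ** 2
        if power.sum() > 0:
            p = power / power.sum()
            mu = float(np.sum(p * freqs[1:]))
            stdfreq = float(np.sqrt(np.sum(p * (freqs[1:] - mu) ** 2)))
        else:
            # magnitudes so small their squares underflow: spectral
            # distribution is unresolvable, follow the degenerate convention
            stdfreq = 0.0

    return {
        "mean": mean,
        "std": std,
        "max": float(np.max(x)),
        "var": var,
        "median": float(np.median(x)),
        "energy": energy,
        "entropy": entropy,
        "kurtosis": kurtosis,
        "maxfreq": maxfreq,
        "stdfreq": stdfreq,
    }


def _rms(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("window too short: empty EMG slice")
    return float(np.sqrt(np.mean(x ** 2)))


# feature index -> (signal key, statistic); signal keys are resolved
# against the recording in _window_signals
_IMU_FAMILIES = (
    ("foot", "accel", _STATS_10),                  # indices 0-9
    ("foot", "gyro", _STATS_10[:9]),               # indices 10-18 (no stdfreq)
    ("l5s1", "accel", _STATS_10),                  # indices 19-28
    ("l5s1", "gyro", _STATS_10),                   # indices 29-38
)


def extract_window_features(window: CycleWindow, rec: RawRecording,
                            magnitudes: dict[tuple[str, str], np.ndarray] | None = None,
                            ) -> dict[str, float]:
    """Compute the 43 named features for one gait-cycle window.

    ``magnitudes`` may carry precomputed Euclidean-magnitude signals keyed
    by (site, modality) to avoid recomputing them per window.
    """
    values: dict[str, float] = {}
    idx = 0
    for site, modality, stats in _IMU_FAMILIES:
        try:
            fs = rec.sampling_rate(site, modality)
        except KeyError as exc:
            raise ValueError(f"missing channel: {site}/{modality}") from exc
        if magnitudes is not None and (site, modality) in magnitudes:
            mag = magnitudes[(site, modality)]
        else:
            mag = rec.magnitude(site, modality)
        lo, hi = window.sample_slice(fs)
        stats_values = stat_features(mag[lo:hi], fs)
        for stat in stats:
            values[FEATURE_NAMES[idx]] = stats_values[stat]
            idx += 1
    for muscle, name in zip(MUSCLES, FEATURE_NAMES[39:]):
        hits = rec.select(modality="emg_envelope", axis=muscle)
        if not hits:
            raise ValueError(f"missing channel: emg_envelope/{muscle}")
        ch = hits[0]
        lo, hi = window.sample_slice(ch.fs)
        values[name] = _rms(ch.data[lo:hi])
    return values


@dataclass
class NormalizationReference:
    """Per-participant baseline: the mean of the first ten bout-0 cycles."""

    participant: str
    values: pd.Series          # indexed by the 43 feature names
    n_windows: int = _BASELINE_WINDOWS

    def __post_init__(self) -> None:
        missing = [f for f in FEATURE_NAMES if f not in self.values.index]
        if missing:
            raise ValueError(f"reference missing features: {missing[:3]}...")
        bad = self.values.index[(self.values == 0) | ~np.isfinite(self.values)]
        if len(bad):
            raise ValueError(f"degenerate reference: feature {bad[0]!r} "
                             "has a zero or non-finite baseline value")


def compute_reference(baseline: pd.DataFrame, participant: str | None = None
                      ) -> NormalizationReference:
    """Baseline reference from a participant's bout-0 feature rows.

    Uses the first ten windows in cycle order; raises if fewer are present
    or if any feature's reference value is zero (which would make the
    normalized feature undefined).
    """
    df = baseline
    if participant is not None:
        df = df[df["participant"] == participant]
    if "bout" in df.columns:
        df = df[df["bout"] == 0]
    if "cycle" in df.columns:
        df = df.sort_values("cycle")
    if len(df) < _BASELINE_WINDOWS:
        raise ValueError("insufficient baseline: need >= "
                         f"{_BASELINE_WINDOWS} bout-0 windows, got {len(df)}")
    first = df.iloc[:_BASELINE_WINDOWS]
    ref = first[list(FEATURE_NAMES)].mean(axis=0)
    pid = participant if participant is not None else (
        str(df["participant"].iloc[0]) if "participant" in df.columns else "")
    return NormalizationReference(participant=pid, values=ref)


def normalize(matrix: pd.DataFrame,
              references: dict[str, NormalizationReference] | NormalizationReference,
              ) -> pd.DataFrame:
    """Divide every feature value by its participant's baseline reference."""
    out = matrix.copy()
    feats = list(FEATURE_NAMES)
    if isinstance(references, NormalizationReference):
        references = {references.participant: references}
    for pid, group in matrix.groupby("participant"):
        if pid not in references:
            raise ValueError(f"participant {pid!r} missing from references")
        ref = references[pid].values[feats]
        out.loc[group.index, feats] = group[feats] / ref.to_numpy()
    return out


def assemble_dataset(segmented, labels: pd.DataFrame) -> pd.DataFrame:
    """Build the labeled feature matrix for a whole cohort.

    ``segmented`` iterates (participant_id, bout, recording, windows);
    ``labels`` has one row per (participant, bout) with the Borg reading,
    fatigue class and lactate surrogate.  Returns one row per retained
    gait cycle with the 43 features, provenance and label columns, sorted
    by (participant, bout, cycle).
    """
    label_key = labels.set_index(["participant", "bout"])
    rows = []
    for pid, bout, rec, windows in segmented:
        try:
            lab = label_key.loc[(pid, bout)]
        except KeyError:
            raise ValueError(f"label missing for participant {pid!r} bout {bout}")
        magnitudes = {(site, mod): rec.magnitude(site, mod)
                      for site, mod, _ in _IMU_FAMILIES}
        for w in windows:
            row = {"participant": pid, "bout": bout, "cycle": w.cycle}
            row.update(extract_window_features(w, rec, magnitudes))
            for col in LABEL_COLUMNS:
                if col in lab.index:
                    row[col] = lab[col]
            rows.append(row)
    if not rows:
        raise ValueError("no windows to assemble")
    df = pd.DataFrame(rows).sort_values(["participant", "bout", "cycle"])
    df = df.reset_index(drop=True)
    cols = list(FEATURE_NAMES) + [c for c in PROVENANCE_COLUMNS + LABEL_COLUMNS
                                  if c in df.columns]
    df = df[cols]
    if df[list(FEATURE_NAMES)].isna().any().any():
        raise ValueError("feature matrix contains missing values")
    return df


def class_distribution(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-class row counts and proportions of the assembled matrix."""
    counts = matrix["fatigue_class"].value_counts()
    return pd.DataFrame({
        "n": counts,
        "fraction": counts / counts.sum(),
    })


def normalize_dataset(matrix: pd.DataFrame) -> tuple[pd.DataFrame,
                                                     dict[str, NormalizationReference]]:
    """Compute per-participant baseline references and normalize in one step."""
    refs = {
        str(pid): compute_reference(matrix, participant=pid)
        for pid in matrix["participant"].unique()
    }
    return normalize(matrix, refs), refs
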