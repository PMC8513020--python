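"""Signal cleaning, synchronization and gait-cycle segmentation.

The segmentation strategy follows the standard inertial gait-event
morphology: on the foot sagittal angular-velocity signal each stride shows
a toe-off trough, a large mid-swing peak, and a heel-strike trough.  Within
one gait cycle the heel strike is therefore the *second* minimum (toe-off
being the first).  Detection anchors strides on the prominent mid-swing
maxima, splits the signal at the midpoints between consecutive maxima, and
emits the second sub-threshold minimum of each stride window as the heel
strike.  The detection threshold is not fixed a priori: candidate
thresholds spanning 10-60% of the signal's negative range are scanned and
the one producing the most regular event train (minimum coefficient of
variation of inter-event intervals) is kept, so detection is invariant to
uniform signal scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .recording import Channel, RawRecording

__all__ = [
    "FilterSpec",
    "GaitEventSeries",
    "CycleWindow",
    "CleanLog",
    "lowpass_filter",
    "filter_recording",
    "clean_and_synchronize",
    "detect_heel_strikes",
    "partition_cycles",
    "segment_bout",
]

#: Physical plausibility bounds per modality; samples outside are treated
#: as faulty sensor values and replaced by linear interpolation.
PHYSICAL_BOUNDS: dict[str, tuple[float, float]] = {
    "accel": (-160.0, 160.0),        # m/s^2 (~16 g)
    "gyro": (-35.0, 35.0),           # rad/s (~2000 deg/s)
    "emg_envelope": (-0.5, 10.0),    # mV envelope
    "hr": (25.0, 250.0),             # bpm
}


@dataclass
class FilterSpec:
    """Low-pass Butterworth specification (applied zero-phase)."""

    order: int = 2
    cutoff: float = 6.0  # Hz

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class GaitEventSeries:
    """Detected heel strikes as sample indices on the foot-gyro clock."""

    heel_strike_indices: np.ndarray
    fs: float
    threshold: float
    channel: str = "foot/gyro"

    def __post_init__(self) -> None:
        idx = np.asarray(self.heel_strike_indices, dtype=int)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("heel-strike indices must be strictly increasing")
        self.heel_strike_indices = idx

    @property
    def times(self) -> np.ndarray:
        return self.heel_strike_indices / self.fs


@dataclass
class CycleWindow:
    """One gait cycle as a half-open time interval [start_s, end_s)."""

    cycle: int
    start_s: float
    end_s: float

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s

    def sample_slice(self, fs: float) -> tuple[int, int]:
        """Map the window onto a channel clock (0-based, half-open)."""
        return int(round(self.start_s * fs)), int(round(self.end_s * fs))


@dataclass
class CleanLog:
    """Counts of samples and cycles discarded or repaired during cleaning."""

    interpolated: dict[str, int] = field(default_factory=dict)
    cropped: dict[str, int] = field(default_factory=dict)
    discarded_cycles: int = 0


def lowpass_filter(signal: np.ndarray, fs: float, spec: FilterSpec | None = None
                   ) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter.

    Forward-backward application (``filtfilt``) preserves event timing at
    the cost of squaring the magnitude response, so a cutoff-frequency
    sinusoid is attenuated to 1/2 rather than 1/sqrt(2).  DC gain is 1.
    """
    spec = spec or FilterSpec()
    x = np.asarray(signal, dtype=float)
    if spec.cutoff >= fs / 2:
        raise ValueError("invalid cutoff: must be below the Nyquist frequency")
    if x.size <= 3 * spec.order:
        raise ValueError("signal too short for the requested filter order")
    sos = scipy.signal.butter(spec.order, spec.cutoff, btype="low", fs=fs,
                              output="sos")
    return scipy.signal.sosfiltfilt(sos, x)


def filter_recording(rec: RawRecording, spec: FilterSpec | None = None,
                     modalities: tuple[str, ...] = ("accel", "gyro")
                     ) -> RawRecording:
    """Return a copy of the recording with IMU channels low-pass filtered.

    EMG envelopes are already smoothed amplitude signals and heart rate is
    sampled far below the cutoff, so only accelerometer and gyroscope
    channels are filtered by default.
    """
    channels = []
    for ch in rec.channels:
        data = ch.data
        if ch.modality in modalities:
            data = lowpass_filter(data, ch.fs, spec)
        channels.append(Channel(ch.site, ch.modality, ch.axis, ch.fs, data))
    return RawRecording(channels=channels, t0=rec.t0,
                        participant=rec.participant, bout=rec.bout)


def _repair_out_of_range(data: np.ndarray, bounds: tuple[float, float]
                         ) -> tuple[np.ndarray, int]:
    lo, hi = bounds
    bad = ~np.isfinite(data) | (data < lo) | (data > hi)
    n_bad = int(bad.sum())
    if n_bad == 0:
        return data, 0
    if bad.all():
        raise ValueError("all samples out of physical bounds")
    idx = np.arange(data.size)
    repaired = data.copy()
    repaired[bad] = np.interp(idx[bad], idx[~bad], data[~bad])
    return repaired, n_bad


def clean_and_synchronize(recordings: list[RawRecording],
                          window: tuple[float, float],
                          bounds: dict[str, tuple[float, float]] | None = None,
                          ) -> tuple[RawRecording, CleanLog]:
    """Crop all channels to a common experiment window and repair outliers.

    Each input recording carries its own time origin; channels are cropped
    to the absolute interval ``window`` and re-referenced so the window
    start is time zero.  Samples outside the modality's physical bounds
    are replaced by linear interpolation and counted in the log.
    """
    t_start, t_end = window
    if t_end <= t_start:
        raise ValueError("experiment window must have positive length")
    bounds = {**PHYSICAL_BOUNDS, **(bounds or {})}
    log = CleanLog()
    channels: list[Channel] = []
    participant = recordings[0].participant if recordings else ""
    bout = recordings[0].bout if recordings else 0
    for rec in recordings:
        for ch in rec.channels:
            times = rec.t0 + np.arange(ch.data.size) / ch.fs
            keep = (times >= t_start) & (times < t_end)
            if not keep.any():
                raise ValueError(
                    f"no common window: channel {ch.site}/{ch.modality}/{ch.axis}"
                    " lies entirely outside the experiment window")
            key = f"{ch.site}/{ch.modality}/{ch.axis}"
            log.cropped[key] = int((~keep).sum())
            data = ch.data[keep]
            data, n_bad = _repair_out_of_range(data, bounds[ch.modality])
            if n_bad:
                log.interpolated[key] = n_bad
            channels.append(Channel(ch.site, ch.modality, ch.axis, ch.fs, data))
    return RawRecording(channels=channels, t0=0.0, participant=participant,
                        bout=bout), log


def _local_minima(x: np.ndarray) -> np.ndarray:
    """Indices of strict-or-plateau local minima."""
    minima, _ = scipy.signal.find_peaks(-x)
    return minima


def detect_heel_strikes(signal: np.ndarray, fs: float,
                        threshold_range: tuple[float, float] = (0.10, 0.60),
                        n_thresholds: int = 25,
                        refractory_fraction: float = 0.5,
                        ) -> GaitEventSeries:
    """Detect heel strikes on a filtered foot sagittal gyro signal.

    Strides are anchored on the mid-swing maxima (prominent positive
    peaks); the signal is split at midpoints between consecutive maxima so
    each stride window holds, in order, the toe-off trough, the mid-swing
    peak and the heel-strike trough.  For each candidate threshold —
    ``n_thresholds`` values spanning ``threshold_range`` of the signal's
    negative range — the second sub-threshold minimum of every stride is
    taken as the heel strike, and the threshold giving the minimum
    coefficient of variation of inter-event intervals wins.  A refractory
    rule (``refractory_fraction`` of the running median cycle time)
    suppresses double detections.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 8:
        raise ValueError("no gait detected: signal too short")
    x_min = float(x.min())
    x_max = float(x.max())
    if x_max <= 0 or x_min >= 0 or x_max == x_min:
        raise ValueError("no gait detected: signal has no stride morphology")

    # mid-swing anchors: prominent positive peaks
    peaks, _ = scipy.signal.find_peaks(x, height=0.3 * x_max,
                                       distance=max(1, int(0.3 * fs)))
    if peaks.size < 2:
        raise ValueError("no gait detected: too few mid-swing peaks")
    med_stride = float(np.median(np.diff(peaks)))
    refractory = refractory_fraction * med_stride
    # re-anchor with the stride-informed spacing constraint
    peaks, _ = scipy.signal.find_peaks(x, height=0.3 * x_max,
                                       distance=max(1, int(refractory)))
    if peaks.size < 2:
        raise ValueError("no gait detected: too few mid-swing peaks")

    # stride windows: midpoints between consecutive mid-swing peaks,
    # extended by half a stride at both ends
    mids = (peaks[:-1] + peaks[1:]) // 2
    half = int(round(med_stride / 2))
    edges = np.concatenate([[max(0, peaks[0] - half)], mids,
                            [min(x.size, peaks[-1] + half)]])

    minima = _local_minima(x)
    candidates: list[tuple[float, float, np.ndarray]] = []  # (cv, thr, events)
    for frac in np.linspace(*threshold_range, n_thresholds):
        thr = frac * x_min  # negative threshold value
        sub = minima[x[minima] < thr]
        events = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            stride_minima = sub[(sub >= lo) & (sub < hi)]
            if stride_minima.size >= 2:
                events.append(stride_minima[1])
        events = np.asarray(events, dtype=int)
        if events.size < 3:
            continue
        # refractory rule against residual double detections
        keep = [0]
        for i in range(1, events.size):
            if events[i] - events[keep[-1]] >= refractory:
                keep.append(i)
        events = events[keep]
        if events.size < 3:
            continue
        intervals = np.diff(events)
        cv = float(np.std(intervals) / np.mean(intervals))
        candidates.append((cv, thr, events))
    if not candidates:
        raise ValueError("no gait detected: no threshold yields a regular event train")
    # a threshold that misses strides outright can have a spuriously low CV;
    # regularity is only compared among near-complete event trains
    max_events = max(ev.size for _, _, ev in candidates)
    viable = [c for c in candidates if c[2].size >= 0.9 * max_events]
    cv, thr, events = min(viable, key=lambda c: c[0])
    return GaitEventSeries(heel_strike_indices=events, fs=fs, threshold=thr)


def partition_cycles(events: GaitEventSeries,
                     outlier_fraction: float = 0.5,
                     log: CleanLog | None = None) -> list[CycleWindow]:
    """Partition the bout into non-overlapping heel-strike-to-heel-strike
    windows.

    Cycles whose duration deviates from the bout median by more than
    ``outlier_fraction`` (default +-50%) are discarded and counted in the
    log; the remaining windows keep their original cycle indices.
    """
    times = events.times
    if times.size < 2:
        raise ValueError("insufficient events: need at least 2 heel strikes")
    durations = np.diff(times)
    med = float(np.median(durations))
    windows: list[CycleWindow] = []
    discarded = 0
    for k, (t0, t1) in enumerate(zip(times[:-1], times[1:])):
        d = t1 - t0
        if abs(d - med) > outlier_fraction * med:
            discarded += 1
            continue
        windows.append(CycleWindow(cycle=k, start_s=float(t0), end_s=float(t1)))
    if log is not None:
        log.discarded_cycles += discarded
    elif discarded:
        warnings.warn(f"discarded {discarded} outlier gait cycles", stacklevel=2)
    return windows


def segment_bout(rec: RawRecording, filter_spec: FilterSpec | None = None,
                 sagittal_axis: str = "z",
                 ) -> tuple[GaitEventSeries, list[CycleWindow], RawRecording]:
    """Filter a bout, detect heel strikes, and partition it into cycles.

    Returns the detected events, the retained cycle windows, and the
    filtered recording (whose channels the feature stage consumes).
    """
    filtered = filter_recording(rec, filter_spec)
    gyro = filtered.channel("foot", "gyro", sagittal_axis)
    events = detect_heel_strikes(gyro.data, gyro.fs)
    windows = partition_cycles(events, log=CleanLog())
    return events, windows, filtered
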