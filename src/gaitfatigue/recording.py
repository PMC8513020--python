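"""Multi-channel wearable recordings.

A :class:`RawRecording` bundles the synchronized channels of one walking
bout: a foot-instep IMU and an L5-S1 (lower-back) IMU sampled at 128 Hz,
four surface-EMG envelope channels sampled at 512 Hz, and a 1 Hz heart-rate
stream.  Channels of the same site share one sampling rate; time is
referenced to a common origin in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sensor sites recognised across the package.
SITES = ("foot", "l5s1", "thigh", "shank", "chest")

#: Channel modalities.
MODALITIES = ("accel", "gyro", "emg_envelope", "hr")

#: The four monitored muscles, in feature order (gastrocnemius first).
MUSCLES = ("gastrocnemius", "tibialis_anterior", "rectus_femoris", "biceps_femoris")


@dataclass
class Channel:
    """One sampled signal: a site/modality/axis triple with its data."""

    site: str
    modality: str
    axis: str
    fs: float
    data: np.ndarray

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.data = np.asarray(self.data, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.size) / self.fs

    @property
    def duration(self) -> float:
        return self.data.size / self.fs


@dataclass
class RawRecording:
    """Synchronized multi-channel time series for one participant bout."""

    channels: list[Channel] = field(default_factory=list)
    t0: float = 0.0
    participant: str = ""
    bout: int = 0

    def select(self, site: str | None = None, modality: str | None = None,
               axis: str | None = None) -> list[Channel]:
        out = []
        for ch in self.channels:
            if site is not None and ch.site != site:
                continue
            if modality is not None and ch.modality != modality:
                continue
            if axis is not None and ch.axis != axis:
                continue
            out.append(ch)
        return out

    def channel(self, site: str, modality: str, axis: str) -> Channel:
        hits = self.select(site, modality, axis)
        if not hits:
            raise KeyError(f"no channel {site}/{modality}/{axis}")
        return hits[0]

    def sampling_rate(self, site: str, modality: str) -> float:
        hits = self.select(site, modality)
        if not hits:
            raise KeyError(f"no channel {site}/{modality}")
        rates = {ch.fs for ch in hits}
        if len(rates) > 1:
            raise ValueError(f"inconsistent sampling rates for {site}/{modality}")
        return hits[0].fs

    def magnitude(self, site: str, modality: str) -> np.ndarray:
        """Euclidean magnitude across the axes of a tri-axial channel."""
        hits = self.select(site, modality)
        if not hits:
            raise KeyError(f"no channel {site}/{modality}")
        stacked = np.vstack([ch.data for ch in hits])
        return np.sqrt(np.sum(stacked ** 2, axis=0))
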