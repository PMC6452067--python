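"""Shared data containers for the controlled-exposure analysis pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SoundAnnotation:
    """A manually-ascribed sound interval on the tag audio channel.

    kind is one of {"clicks", "buzz", "other-whale"}.
    """

    start: float
    stop: float
    kind: str


@dataclass
class TagRecord:
    """Uniform-rate multichannel biologging record from an archival tag.

    Channels are sampled on one common grid at ``fs`` Hz (default 5 Hz):
    depth (m, positive down), triaxial accelerometer specific force
    (units of g, tag frame: x longitudinal forward, y lateral left,
    z dorso-ventral), triaxial magnetic field (µT, tag frame), and the
    flow-noise band level (dB, 66-94 Hz band) used for speed estimation.
    """

    fs: float
    depth: np.ndarray
    acc: np.ndarray  # (n, 3)
    mag: np.ndarray  # (n, 3)
    flow_db: np.ndarray
    annotations: list[SoundAnnotation] = field(default_factory=list)
    t0: float = 0.0

    def __post_init__(self):
        n = len(self.depth)
        if self.acc.shape != (n, 3) or self.mag.shape != (n, 3):
            raise ValueError("acceleration/magnetic channels must be (n, 3)")
        if len(self.flow_db) != n:
            raise ValueError("all channels must have equal length")
        if np.nanmin(self.depth) < -1.0:
            raise ValueError("depth below -1 m violates surface allowance")

    @property
    def n(self) -> int:
        return len(self.depth)

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "depth_m": self.depth,
                "acc_x_g": self.acc[:, 0],
                "acc_y_g": self.acc[:, 1],
                "acc_z_g": self.acc[:, 2],
                "mag_x_ut": self.mag[:, 0],
                "mag_y_ut": self.mag[:, 1],
                "mag_z_ut": self.mag[:, 2],
                "flow_db": self.flow_db,
            }
        )


@dataclass
class ExposureSchedule:
    """Per-pulse transmission parameters of one controlled sonar exposure."""

    treatment: str
    band_hz: tuple[float, float]
    pulse_times: np.ndarray  # s, relative to start_time_s
    source_levels: np.ndarray  # dB re 1 uPa^2 m^2 per pulse
    pulse_duration_s: float
    pulse_interval_s: float
    ramp_up_min: float
    full_power_min: float
    source_depth_m: float
    start_time_s: float = 0.0
    source_lat: float = 71.0
    source_lon: float = -7.0

    def __post_init__(self):
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        self.source_levels = np.asarray(self.source_levels, dtype=float)
        if np.any(np.diff(self.pulse_times) <= 0):
            raise ValueError("pulse times must be strictly increasing")
        if len(self.source_levels) != len(self.pulse_times):
            raise ValueError("one source level per pulse required")

    @property
    def n_pulses(self) -> int:
        return len(self.pulse_times)

    @property
    def duty_cycle_percent(self) -> float:
        """Duty cycle = 100 x pulse duration / pulse interval."""
        return 100.0 * self.pulse_duration_s / self.pulse_interval_s


@dataclass
class PsdSpectrogram:
    """Framed one-sided power spectral densities of a PAM recording.

    psd has shape (n_frames, n_freqs); frame spacing is half the frame
    length (50% overlap, Hann window).
    """

    times: np.ndarray  # frame centre times, s
    freqs: np.ndarray  # Hz, increasing
    psd: np.ndarray  # (n_frames, n_freqs), >= 0
    fs: float
    frame_len: int
    overlap: float = 0.5
    window: str = "hann"

    def __post_init__(self):
        if self.psd.shape != (len(self.times), len(self.freqs)):
            raise ValueError("psd shape must be (n_frames, n_freqs)")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency axis must be increasing")
        if np.nanmin(self.psd) < 0:
            raise ValueError("PSD must be non-negative")


@dataclass
class GroundTruth:
    """Known simulation truth recorded alongside generated datasets."""

    response_onset_time: float | None = None
    states: np.ndarray | None = None  # movement states in {1,2,3}
    click_times: np.ndarray | None = None
    pulse_spl: np.ndarray | None = None  # true received SPL per pulse, dB re 1 uPa
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.states is not None:
            s = np.asarray(self.states)
            if s.size and not np.isin(s, (1, 2, 3)).all():
                raise ValueError("state labels must be in {1, 2, 3}")
            self.states = s
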