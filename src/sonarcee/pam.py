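"""Guard-band energy detection of echolocation clicks and click-absence tests.

Passive-acoustic audio is framed into Hann-windowed, 50%-overlap power
spectral densities; PSDs are normalized by a noise floor (time average of the
frames with the lowest 5% of mean 5-50 kHz spectral level). Per 2.5-min
segment, band levels are the time average over the loudest 1% of frames in
the echolocation band (20-40 kHz) and a guard band (4-8 kHz); a click
detection is scored when echolocation level minus guard level passes a
threshold. The guard band rejects broadband transients, which raise both
bands. Runs of consecutive non-detected segments form click-absent periods;
the duration of the last absent period that starts during a sonar exposure is
tested against the 95th percentile of the baseline absent-period durations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .containers import PsdSpectrogram
from .simulate import ECHO_BAND, GUARD_BAND

SEGMENT_S = 150.0  # 2.5 min scoring segments
MIN_ABSENT_EXCLUDE_S = 600.0  # absent runs <= 10 min stay out of the baseline
FRAME_DURATION_S = 0.0569  # nominal frame length; 8192 samples at 144 kHz


def default_frame_len(fs: float) -> int:
    """Frame length in samples tying the nominal 56.9 ms frame to fs."""
    return 8192 if abs(fs - 144_000.0) < 1e-6 else int(round(FRAME_DURATION_S * fs))


def psd_spectrogram(
    audio: np.ndarray,
    fs: float,
    frame_len: int | None = None,
    overlap: float = 0.5,
) -> PsdSpectrogram:
    """One-sided Hann-window PSD frames (density scaling, so the integral of
    the PSD over frequency reproduces the frame signal power)."""
    x = np.asarray(audio, dtype=float)
    if frame_len is None:
        frame_len = default_frame_len(fs)
    if len(x) < frame_len:
        raise ValueError("audio shorter than one analysis frame")
    noverlap = int(round(frame_len * overlap))
    freqs, times, sxx = signal.spectrogram(
        x, fs=fs, window="hann", nperseg=frame_len, noverlap=noverlap,
        detrend=False, scaling="density", mode="psd",
    )
    return PsdSpectrogram(times=times, freqs=freqs, psd=sxx.T, fs=fs,
                          frame_len=frame_len, overlap=overlap)


@dataclass
class NormalizedPsd:
    """PSD in dB relative to the estimated noise-floor spectrum."""

    times: np.ndarray
    freqs: np.ndarray
    level_db: np.ndarray  # (n_frames, n_freqs)
    floor: np.ndarray  # linear PSD floor per bin
    flagged: bool = False


def normalize_psd(
    spec: PsdSpectrogram,
    ref_band: tuple[float, float] = (5_000.0, 50_000.0),
    quantile: float = 0.05,
) -> NormalizedPsd:
    """Normalize PSD frames by the noise-floor spectrum.

    The floor is the time average of the frames whose mean spectral level in
    ``ref_band`` lies in the lowest ``quantile``; rare loud transients fall
    outside that set and leave the floor unaffected.
    """
    in_ref = (spec.freqs >= ref_band[0]) & (spec.freqs <= ref_band[1])
    if not in_ref.any():
        raise ValueError("reference band outside the frequency axis")
    frame_level = spec.psd[:, in_ref].mean(axis=1)
    n = len(frame_level)
    flagged = False
    if n < 20:
        warnings.warn("fewer than 20 frames; noise floor from all frames", stacklevel=2)
        sel = np.ones(n, dtype=bool)
        flagged = True
    else:
        cutoff = np.quantile(frame_level, quantile)
        sel = frame_level <= cutoff
    floor = spec.psd[sel].mean(axis=0)
    floor = np.maximum(floor, np.finfo(float).tiny)
    with np.errstate(divide="ignore"):
        level_db = 10.0 * np.log10(np.maximum(spec.psd, np.finfo(float).tiny) / floor)
    return NormalizedPsd(spec.times, spec.freqs, level_db, floor, flagged)


def segment_level_difference(
    norm: NormalizedPsd,
    segment_s: float = SEGMENT_S,
    echo_band: tuple[float, float] = ECHO_BAND,
    guard_band: tuple[float, float] = GUARD_BAND,
    top_fraction: float = 0.01,
    min_frames: int = 100,
) -> pd.DataFrame:
    """Echo-band minus guard-band level (dB) per scoring segment.

    Per frame, the band level is the dB mean of the normalized PSD over the
    band; per segment and band, the statistic is the time average of the
    loudest ``top_fraction`` of frames. The segment grid is anchored at the
    recording start; a partial trailing segment is dropped.
    """
    in_echo = (norm.freqs >= echo_band[0]) & (norm.freqs <= echo_band[1])
    in_guard = (norm.freqs >= guard_band[0]) & (norm.freqs <= guard_band[1])
    echo_frame = 10.0 * np.log10(
        np.mean(10.0 ** (norm.level_db[:, in_echo] / 10.0), axis=1))
    guard_frame = 10.0 * np.log10(
        np.mean(10.0 ** (norm.level_db[:, in_guard] / 10.0), axis=1))
    seg_idx = np.floor(norm.times / segment_s).astype(int)
    n_seg = int(np.floor((norm.times[-1] + 1e-12) / segment_s))  # full segments only
    rows = []
    for k in range(n_seg):
        sel = seg_idx == k
        nf = int(sel.sum())
        if nf == 0:
            rows.append((k, k * segment_s, np.nan, 0))
            continue
        if nf < min_frames:
            warnings.warn(f"segment {k} has only {nf} frames", stacklevel=2)
        top = max(1, int(np.ceil(top_fraction * nf)))
        e = np.sort(echo_frame[sel])[-top:].mean()
        g = np.sort(guard_frame[sel])[-top:].mean()
        rows.append((k, k * segment_s, e - g, nf))
    return pd.DataFrame(rows, columns=["segment", "t_start_s", "level_diff_db", "n_frames"])


def detect(segments: pd.DataFrame, threshold_db: float) -> pd.DataFrame:
    """Score a click detection where the level difference passes the
    threshold (detected <=> level_diff_db >= threshold)."""
    out = segments.copy()
    out["detected"] = out["level_diff_db"] >= threshold_db
    return out


def segments_truth(
    click_times: np.ndarray, n_segments: int, segment_s: float = SEGMENT_S
) -> np.ndarray:
    """Truth labels: a segment is positive if it contains a truth click."""
    labels = np.zeros(n_segments, dtype=bool)
    idx = np.floor(np.asarray(click_times) / segment_s).astype(int)
    idx = idx[(idx >= 0) & (idx < n_segments)]
    labels[idx] = True
    return labels


def roc_tune(
    segments: pd.DataFrame,
    truth: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Precision and recall over a threshold grid against audited truth."""
    if thresholds is None:
        thresholds = np.arange(0.0, 15.5, 0.5)
    score = segments["level_diff_db"].to_numpy()
    truth = np.asarray(truth, dtype=bool)
    if len(truth) != len(score):
        raise ValueError("one truth label per segment required")
    if not truth.any():
        warnings.warn("no positive segments in truth; recall undefined", stacklevel=2)
    rows = []
    for thr in thresholds:
        det = score >= thr
        tp = int(np.sum(det & truth))
        fp = int(np.sum(det & ~truth))
        fn = int(np.sum(~det & truth))
        prec = tp / (tp + fp) if tp + fp else np.nan
        rec = tp / (tp + fn) if tp + fn else np.nan
        rows.append((thr, tp, fp, fn, prec, rec))
    return pd.DataFrame(rows, columns=["threshold_db", "tp", "fp", "fn",
                                       "precision", "recall"])


# -----------------------------------------------------------------------------
# click-absent periods


@dataclass
class ClickAbsentPeriods:
    """Maximal runs of consecutive non-detected segments."""

    periods: pd.DataFrame  # start_s, duration_h, n_segments
    segment_s: float = SEGMENT_S
    min_exclude_s: float = MIN_ABSENT_EXCLUDE_S

    @property
    def baseline_durations_h(self) -> np.ndarray:
        """Absent-period durations entering the baseline distribution
        (runs <= 10 min excluded: such gaps occur normally while foraging)."""
        d = self.periods["duration_h"].to_numpy()
        return d[d * 3600.0 > self.min_exclude_s]

    def response_threshold_h(self, q: float = 0.95) -> float:
        base = self.baseline_durations_h
        if base.size == 0:
            raise ValueError("empty baseline of click-absent periods")
        return float(np.quantile(base, q))  # type-7 interpolation

    def last_starting_in(self, t0_s: float, t1_s: float) -> pd.Series | None:
        sel = self.periods[(self.periods["start_s"] >= t0_s) & (self.periods["start_s"] < t1_s)]
        return None if sel.empty else sel.iloc[-1]


def click_absent_periods(
    detected: np.ndarray | pd.DataFrame, segment_s: float = SEGMENT_S
) -> ClickAbsentPeriods:
    """Run-length decomposition of the detection series into absent periods."""
    if isinstance(detected, pd.DataFrame):
        detected = detected["detected"].to_numpy()
    det = np.asarray(detected, dtype=bool)
    rows = []
    i = 0
    n = len(det)
    while i < n:
        if not det[i]:
            j = i
            while j < n and not det[j]:
                j += 1
            rows.append((i * segment_s, (j - i) * segment_s / 3600.0, j - i))
            i = j
        else:
            i += 1
    periods = pd.DataFrame(rows, columns=["start_s", "duration_h", "n_segments"])
    return ClickAbsentPeriods(periods=periods, segment_s=segment_s)


@dataclass
class AbsenceTestResult:
    response: bool
    duration_h: float
    threshold_h: float
    percentile: float
    n_baseline: int
    low_power: bool


def absence_outlier_test(
    duration_h: float,
    baseline: ClickAbsentPeriods | np.ndarray,
    q: float = 0.95,
) -> AbsenceTestResult:
    """Is an exposure-period click-absent duration an outlier against the
    baseline empirical distribution? Response <=> duration exceeds the
    ``q`` quantile of baseline durations."""
    base = (baseline.baseline_durations_h if isinstance(baseline, ClickAbsentPeriods)
            else np.asarray(baseline, dtype=float))
    if base.size == 0:
        raise ValueError("empty baseline of click-absent periods")
    low_power = base.size < 20
    if low_power:
        warnings.warn("fewer than 20 baseline periods; test has low power", stacklevel=2)
    thr = float(np.quantile(base, q))
    pct = float(np.mean(base <= duration_h))
    return AbsenceTestResult(
        response=bool(duration_h > thr), duration_h=float(duration_h),
        threshold_h=thr, percentile=pct, n_baseline=int(base.size),
        low_power=low_power,
    )
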