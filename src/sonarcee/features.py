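"""Behavioural time-series variables derived from a biologging tag record.

Seven 5 Hz / windowed variables: body orientation (pitch, roll, heading),
temperature-corrected depth, speed-through-water from flow noise (depth > 5 m
only), depth inflections (30 s window), circular variance of heading and pitch
(1 min window), pitching movement, and overall dynamic body acceleration
(5 s window, depth > 5 m only). Per-pulse received sound pressure levels are
computed from calibrated tag audio.

All sliding windows are centred and require full support: samples whose
window extends past the record edge (or contains masked input) are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from ._geo import wrap_angle
from .containers import TagRecord
from .simulate import FlowNoiseCalibration, flow_noise_calibration

SPEED_DEPTH_LIMIT_M = 5.0
P_REF_UPA = 1e-6  # Pa, reference pressure (1 µPa)


def _odd_window(window_s: float, fs: float) -> int:
    w = int(round(window_s * fs))
    return w + 1 if w % 2 == 0 else w


def _rolling_mean(x: np.ndarray, w: int) -> np.ndarray:
    """Centred rolling mean with full support (NaN at edges and around NaNs)."""
    return pd.Series(x).rolling(w, center=True, min_periods=w).mean().to_numpy()


# -----------------------------------------------------------------------------
# orientation


def orientation(acc: np.ndarray, mag: np.ndarray, declination_deg: float = 0.0):
    """Pitch, roll and heading (rad) from triaxial accelerometer and
    magnetometer samples in the tag frame.

    Pitch is the angle of the longitudinal axis above horizontal (from the
    gravity estimate), roll the rotation about that axis, and heading the
    tilt-corrected magnetic bearing, clockwise from geographic north in
    (-pi, pi]. Samples with zero-norm acceleration are masked.
    """
    acc = np.asarray(acc, dtype=float)
    mag = np.asarray(mag, dtype=float)
    norm = np.linalg.norm(acc, axis=-1)
    bad = norm == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        ax, ay, az = (acc[..., i] / norm for i in range(3))
    pitch = np.arcsin(np.clip(ax, -1.0, 1.0))
    roll = np.arctan2(-ay, -az)
    # tilt-correct the magnetic vector, then take the horizontal bearing
    mx, my, mz = mag[..., 0], mag[..., 1], mag[..., 2]
    cth, sth = np.cos(pitch), np.sin(pitch)
    cph, sph = np.cos(roll), np.sin(roll)
    mh_x = cth * mx + sth * sph * my + sth * cph * mz
    mh_y = cph * my - sph * mz
    heading = wrap_angle(np.arctan2(-mh_y, mh_x) + np.radians(declination_deg))
    for a in (pitch, roll, heading):
        a[bad] = np.nan
    return pitch, roll, heading


# -----------------------------------------------------------------------------
# depth


@dataclass
class DepthCalibration:
    offset: float = 0.0
    gain: float = 1.0
    temp_coeff: float = 0.0  # pressure units per degree of temperature change


def depth_from_pressure(
    pressure: np.ndarray,
    temperature: np.ndarray | float = 0.0,
    cal: DepthCalibration | None = None,
    ref_temperature: float = 0.0,
) -> np.ndarray:
    """Affine pressure-to-depth conversion with a linear temperature term:
    depth = gain * (pressure - offset - c_T * (T - T_ref))."""
    if cal is None:
        import warnings

        warnings.warn("no depth calibration supplied; using identity", stacklevel=2)
        cal = DepthCalibration()
    dT = np.asarray(temperature, dtype=float) - ref_temperature
    return cal.gain * (np.asarray(pressure, dtype=float) - cal.offset - cal.temp_coeff * dT)


# -----------------------------------------------------------------------------
# speed from flow noise


def speed_from_flow_noise(
    flow_db: np.ndarray,
    depth: np.ndarray,
    cal: FlowNoiseCalibration | None = None,
) -> np.ndarray:
    """Invert the monotone flow-noise-level calibration to speed (m/s).

    Levels outside the calibrated range are clamped to its ends; samples at
    depth <= 5 m are masked (surface splash noise corrupts the band level).
    """
    if cal is None:
        cal = flow_noise_calibration()
    speed = cal.invert(np.asarray(flow_db, dtype=float))
    speed = np.where(np.asarray(depth) > SPEED_DEPTH_LIMIT_M, speed, np.nan)
    return speed


# -----------------------------------------------------------------------------
# windowed variables


def depth_inflections(depth: np.ndarray, fs: float, window_s: float = 30.0) -> np.ndarray:
    """Proportion of zero crossings in the first difference of depth within a
    centred sliding window (values in [0, 1])."""
    depth = np.asarray(depth, dtype=float)
    w = _odd_window(window_s, fs)
    if len(depth) < w:
        raise ValueError("record shorter than one window")
    d = np.diff(depth)
    sc = (np.sign(d[:-1]) * np.sign(d[1:]) < 0).astype(float)  # n-2 pair flags
    npairs = w - 2
    conv = np.convolve(sc, np.ones(npairs) / npairs, mode="valid")
    out = np.full(len(depth), np.nan)
    h = (w - 1) // 2
    out[h : h + len(conv)] = conv
    return out


def circular_variance(angles: np.ndarray, fs: float, window_s: float = 60.0) -> np.ndarray:
    """1 minus the mean resultant length over a centred sliding window."""
    a = np.asarray(angles, dtype=float)
    w = _odd_window(window_s, fs)
    c = _rolling_mean(np.cos(a), w)
    s = _rolling_mean(np.sin(a), w)
    return 1.0 - np.sqrt(c**2 + s**2)


def odba(
    acc: np.ndarray, depth: np.ndarray, fs: float, window_s: float = 5.0
) -> np.ndarray:
    """Average overall dynamic body acceleration over a centred window.

    Gravity is separated with a running mean of the same window length; the
    result is masked at depth <= 5 m.
    """
    acc = np.asarray(acc, dtype=float)
    w = _odd_window(window_s, fs)
    dyn_sum = np.zeros(acc.shape[0])
    for i in range(3):
        grav = _rolling_mean(acc[:, i], w)
        dyn_sum = dyn_sum + np.abs(acc[:, i] - grav)
    out = _rolling_mean(dyn_sum, w)
    return np.where(np.asarray(depth) > SPEED_DEPTH_LIMIT_M, out, np.nan)


def pitching_movement(
    pitch: np.ndarray, depth: np.ndarray, fs: float, cutoff_hz: float = 0.125
) -> np.ndarray:
    """Magnitude of the high-pass-filtered pitch rate (rad/s), masked at
    depth <= 5 m.

    The operator is deliberately configurable: pitch rate is differentiated at
    the sample rate and high-passed with a zero-phase 2nd-order Butterworth
    filter (default cutoff half the nominal fluke-stroke frequency), isolating
    body-axis pitching from orientation changes of the dive trajectory.
    """
    p = np.asarray(pitch, dtype=float).copy()
    nan = ~np.isfinite(p)
    if nan.all():
        return np.full_like(p, np.nan)
    if nan.any():
        idx = np.arange(len(p))
        p[nan] = np.interp(idx[nan], idx[~nan], p[~nan])
    rate = np.gradient(p) * fs
    sos = signal.butter(2, cutoff_hz, btype="highpass", fs=fs, output="sos")
    hp = signal.sosfiltfilt(sos, rate)
    out = np.abs(hp)
    out[nan] = np.nan
    return np.where(np.asarray(depth) > SPEED_DEPTH_LIMIT_M, out, np.nan)


# -----------------------------------------------------------------------------
# received SPL from tag audio


def received_spl(
    waveform: np.ndarray,
    fs: float,
    pulse_times: np.ndarray,
    pulse_duration_s: float,
    window_s: float = 0.2,
) -> pd.DataFrame:
    """Per-pulse received SPL (dB re 1 µPa) from a calibrated pressure
    waveform (Pa).

    For each pulse, returns the maximum of the sliding ``window_s`` RMS level
    over the pulse, the whole-pulse RMS level, and their difference (the
    averaging-time correction). Pulses outside the recording, or silent
    pulses, yield NaN.
    """
    x = np.asarray(waveform, dtype=float)
    n = len(x)
    wlen = max(1, int(round(window_s * fs)))
    rows = []
    for t0 in np.atleast_1d(pulse_times):
        i0 = int(round(t0 * fs))
        i1 = int(round((t0 + pulse_duration_s) * fs))
        if i0 < 0 or i1 > n or i1 <= i0:
            rows.append((np.nan, np.nan, np.nan))
            continue
        seg = x[i0:i1] ** 2
        ms_pulse = seg.mean()
        if len(seg) >= wlen:
            csum = np.concatenate(([0.0], np.cumsum(seg)))
            ms_win = (csum[wlen:] - csum[:-wlen]) / wlen
            ms_best = ms_win.max()
        else:
            ms_best = ms_pulse
        if ms_pulse <= 0 or ms_best <= 0:
            rows.append((np.nan, np.nan, np.nan))
            continue
        spl_win = 10.0 * np.log10(ms_best) - 20.0 * np.log10(P_REF_UPA)
        spl_pulse = 10.0 * np.log10(ms_pulse) - 20.0 * np.log10(P_REF_UPA)
        rows.append((spl_win, spl_pulse, spl_win - spl_pulse))
    return pd.DataFrame(rows, columns=["spl_200ms", "spl_pulse", "correction_db"])


# -----------------------------------------------------------------------------
# full feature extraction


def extract_features(
    record: TagRecord,
    flow_cal: FlowNoiseCalibration | None = None,
    declination_deg: float = 0.0,
    pitching_cutoff_hz: float = 0.125,
) -> pd.DataFrame:
    """Derive the full behavioural feature set from a tag record.

    Returns a DataFrame indexed by time (s) with NaN marking masked samples.
    """
    fs = record.fs
    pitch, roll, heading = orientation(record.acc, record.mag, declination_deg)
    depth = record.depth
    feats = pd.DataFrame(
        {
            "depth": depth,
            "pitch": pitch,
            "roll": roll,
            "heading": heading,
            "speed": speed_from_flow_noise(record.flow_db, depth, flow_cal),
            "depth_inflections": depth_inflections(depth, fs),
            "circ_var_heading": circular_variance(heading, fs),
            "circ_var_pitch": circular_variance(pitch, fs),
            "pitching_movement": pitching_movement(pitch, depth, fs, pitching_cutoff_hz),
            "odba": odba(record.acc, depth, fs),
        },
        index=pd.Index(record.time, name="time_s"),
    )
    return feats
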