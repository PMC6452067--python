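"""Synthetic-data generators for every pipeline input, with known ground truth.

Field data from controlled exposure experiments on deep-diving odontocetes are
not publicly deposited, so every downstream analysis stage is exercised on
simulated inputs: a phase-machine dive-cycle biologging record with an
exposure-triggered avoidance change, a 3-state movement track with
exposure-dependent transition probabilities, a passive-acoustic scene with
click transients in band-limited noise, and the sonar transmission schedules
of the close and distant treatments.

All randomness flows from one seeded ``numpy.random.Generator`` per call; a
fixed seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _geo
from .containers import ExposureSchedule, GroundTruth, PsdSpectrogram, SoundAnnotation, TagRecord

G_STANDARD = 9.80665

# -----------------------------------------------------------------------------
# configuration


@dataclass
class DiveCycleParams:
    """Baseline dive-cycle phase machine (descent / bottom / ascent / surface /
    shallow bout). Defaults are plausible for a deep-foraging beaked whale but
    are artifact choices, configurable and not asserted as species-typical."""

    deep_depth_m: float = 800.0
    descent_rate_ms: float = 1.6
    bottom_duration_s: float = 900.0
    ascent_rate_ms: float = 1.5
    surface_duration_s: float = 480.0
    shallow_depth_m: float = 80.0
    n_shallow_dives: int = 2
    shallow_bottom_s: float = 180.0
    shallow_rate_ms: float = 1.2

    def cycle_duration_s(self) -> float:
        deep = self.deep_depth_m / self.descent_rate_ms + self.bottom_duration_s
        deep += self.deep_depth_m / self.ascent_rate_ms
        shallow = self.n_shallow_dives * (
            2 * self.shallow_depth_m / self.shallow_rate_ms
            + self.shallow_bottom_s
            + 60.0
        )
        return deep + self.surface_duration_s + shallow + self.surface_duration_s


@dataclass
class HmmTruth:
    """True 3-state movement process: gamma step lengths (km/h), von Mises
    turns, and multinomial-logit transition coefficients. The diagonal of the
    intercept-logit matrix is the reference category (logit 0 = stay);
    ``recovery_coef``/``recovery_spl_coef`` act on transitions out of state 1
    towards states 2 and 3, multiplying the time-to-recovery covariate
    (and its product with standardized SPLmax)."""

    step_mean_km: np.ndarray = field(default_factory=lambda: np.array([0.5, 1.8, 4.5]))
    step_sd_km: np.ndarray = field(default_factory=lambda: np.array([0.35, 0.9, 1.5]))
    turn_mean: np.ndarray = field(default_factory=lambda: np.zeros(3))
    turn_kappa: np.ndarray = field(default_factory=lambda: np.array([0.4, 4.0, 12.0]))
    tpm_logits: np.ndarray = field(
        default_factory=lambda: np.array(
            [[0.0, -2.2, -2.2], [-2.2, 0.0, -2.2], [-2.2, -2.2, 0.0]]
        )
    )
    recovery_coef: np.ndarray = field(default_factory=lambda: np.zeros(2))
    recovery_spl_coef: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        for name in ("step_mean_km", "step_sd_km", "turn_mean", "turn_kappa",
                     "tpm_logits", "recovery_coef", "recovery_spl_coef"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.step_mean_km <= 0):
            raise ValueError("step-length means must be positive")


@dataclass
class PamParams:
    """Passive-acoustic scene parameters."""

    fs: float = 144_000.0  # Hz; 8192-point frame is then 56.9 ms
    frame_len: int = 8192
    click_rate_hz: float = 0.4  # mean click rate while whales are clicking
    click_snr_db: float = 15.0  # in-band per-frame PSD excess over noise
    segment_s: float = 150.0  # 2.5 min scoring segments
    duration_s: float = 3600.0
    noise_psd: float = 1e-9  # flat background PSD (arbitrary pressure^2/Hz)
    freq_decimate: int = 32  # PSD-mode frequency-axis decimation factor
    clicking_intervals: list[tuple[float, float]] | None = None
    guard_interferer_times: tuple[float, ...] = ()
    broadband_interferer_times: tuple[float, ...] = ()


@dataclass
class SimConfig:
    """Master configuration for the synthetic generators.

    A fixed seed makes every generator bit-reproducible. ``treatment`` selects
    the exposure scenario: "close", "distant" or "none".
    """

    seed: int = 0
    duration_h: float = 10.0
    sample_rate: float = 5.0  # biologging Hz
    treatment: str = "none"
    exposure_start_h: float = 6.0
    response_onset_delay_s: float = 0.0
    avoidance_speed_gain: float = 1.7
    acc_noise_g: float = 0.02
    mag_noise_ut: float = 0.3
    flow_noise_db: float = 0.5
    depth_noise_m: float = 0.15
    dive: DiveCycleParams = field(default_factory=DiveCycleParams)
    hmm_truth: HmmTruth = field(default_factory=HmmTruth)
    pam: PamParams = field(default_factory=PamParams)

    def __post_init__(self):
        if self.duration_h <= 0:
            raise ValueError("duration must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be positive")
        if self.treatment not in ("close", "distant", "none"):
            raise ValueError(f"unknown treatment {self.treatment!r}")


# -----------------------------------------------------------------------------
# exposure schedules (transmission protocols of the close/distant treatments)

# Protocol table: frequency band, source level span (dB re 1 uPa^2 m^2), pulse
# duration/interval (s), ramp-up and full-power phases (min), source depth (m).
PROTOCOLS = {
    # close treatment, full source level
    "close": dict(band_hz=(1000.0, 2000.0), sl_min=185.0, sl_max=185.0,
                  pulse_s=1.0, interval_s=20.0, ramp_min=0.0, full_min=15.0,
                  depth_m=8.0),
    # close treatment at reduced output (amplifier-limited variant)
    "close-low": dict(band_hz=(1000.0, 2000.0), sl_min=122.0, sl_max=122.0,
                      pulse_s=1.0, interval_s=20.0, ramp_min=0.0, full_min=15.0,
                      depth_m=8.0),
    # distant treatment: compound tonal (500 ms linear upsweep 3350-3450 Hz
    # then 500 ms tones at 3600 and 3900 Hz), 20 min ramp-up to full power
    "distant": dict(band_hz=(3400.0, 3900.0), sl_min=154.0, sl_max=214.0,
                    pulse_s=1.5, interval_s=25.0, ramp_min=20.0, full_min=15.0,
                    depth_m=17.0),
}


def make_exposure(
    protocol: str,
    start_time_s: float = 0.0,
    source_lat: float = 71.0,
    source_lon: float = -7.0,
    source_level: float | None = None,
) -> ExposureSchedule:
    """Build the per-pulse transmission schedule for a named protocol.

    During ramp-up the source level rises linearly in dB from the protocol
    minimum to its maximum; the full-power phase transmits at the maximum.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown transmission protocol {protocol!r}")
    p = PROTOCOLS[protocol]
    ramp_s = p["ramp_min"] * 60.0
    total_s = ramp_s + p["full_min"] * 60.0
    times = np.arange(0.0, total_s - 1e-9, p["interval_s"])
    sl_max = source_level if source_level is not None else p["sl_max"]
    sl_min = p["sl_min"] if source_level is None else sl_max - (p["sl_max"] - p["sl_min"])
    levels = np.full(times.shape, sl_max)
    if ramp_s > 0:
        in_ramp = times < ramp_s
        levels[in_ramp] = sl_min + (sl_max - sl_min) * times[in_ramp] / ramp_s
    return ExposureSchedule(
        treatment="close" if protocol.startswith("close") else "distant",
        band_hz=p["band_hz"],
        pulse_times=times,
        source_levels=levels,
        pulse_duration_s=p["pulse_s"],
        pulse_interval_s=p["interval_s"],
        ramp_up_min=p["ramp_min"],
        full_power_min=p["full_min"],
        source_depth_m=p["depth_m"],
        start_time_s=start_time_s,
        source_lat=source_lat,
        source_lon=source_lon,
    )


# -----------------------------------------------------------------------------
# biologging record


def _phase_plan(cfg: SimConfig) -> list[tuple[str, float]]:
    """Sequence of (phase name, duration s) covering the record."""
    d = cfg.dive
    total = cfg.duration_h * 3600.0
    if total < d.cycle_duration_s():
        raise ValueError("record shorter than one dive cycle")
    plan: list[tuple[str, float]] = []
    t = 0.0
    while t < total:
        cycle = [
            ("descent", d.deep_depth_m / d.descent_rate_ms),
            ("bottom", d.bottom_duration_s),
            ("ascent", d.deep_depth_m / d.ascent_rate_ms),
            ("surface", d.surface_duration_s),
        ]
        for _ in range(d.n_shallow_dives):
            cycle += [
                ("shallow_descent", d.shallow_depth_m / d.shallow_rate_ms),
                ("shallow_bottom", d.shallow_bottom_s),
                ("shallow_ascent", d.shallow_depth_m / d.shallow_rate_ms),
                ("surface_short", 60.0),
            ]
        cycle.append(("surface", d.surface_duration_s))
        for name, dur in cycle:
            plan.append((name, dur))
            t += dur
            if t >= total:
                break
    return plan


_PHASE_SPEED = {
    "descent": 1.8, "bottom": 1.2, "ascent": 1.7, "surface": 0.4,
    "shallow_descent": 1.4, "shallow_bottom": 1.0, "shallow_ascent": 1.4,
    "surface_short": 0.4,
}
_PHASE_HEAD_SD = {  # per-sample heading random-walk sd (rad) at 5 Hz
    "descent": 0.004, "bottom": 0.030, "ascent": 0.004, "surface": 0.010,
    "shallow_descent": 0.008, "shallow_bottom": 0.020, "shallow_ascent": 0.008,
    "surface_short": 0.010,
}


def make_tag_record(cfg: SimConfig) -> tuple[TagRecord, GroundTruth]:
    """Simulate a high-resolution biologging record with optional avoidance.

    Baseline behaviour alternates deep foraging dives (with annotated click
    trains and buzzes during the bottom phase) and shallow-diving bouts. If an
    exposure is scheduled, from ``exposure_start + response_onset_delay``
    onwards the whale switches to sustained avoidance: directed heading with
    low circular variance, elevated speed, shallow travel, and no foraging
    sounds.
    """
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sample_rate
    n = int(round(cfg.duration_h * 3600.0 * fs))
    t = np.arange(n) / fs
    plan = _phase_plan(cfg)

    depth = np.zeros(n)
    speed = np.zeros(n)
    head_sd = np.zeros(n)
    phase_id = np.empty(n, dtype=object)

    # lay out phases sample-by-sample
    i = 0
    cur_depth = 0.0
    for name, dur in plan:
        m = min(n - i, int(round(dur * fs)))
        if m <= 0:
            break
        sl = slice(i, i + m)
        tt = np.arange(m) / fs
        if name in ("descent", "shallow_descent"):
            rate = cfg.dive.descent_rate_ms if name == "descent" else cfg.dive.shallow_rate_ms
            target = cfg.dive.deep_depth_m if name == "descent" else cfg.dive.shallow_depth_m
            depth[sl] = np.minimum(cur_depth + rate * tt, target)
        elif name in ("ascent", "shallow_ascent"):
            rate = cfg.dive.ascent_rate_ms if name == "ascent" else cfg.dive.shallow_rate_ms
            depth[sl] = np.maximum(cur_depth - rate * tt, 0.3)
        elif name in ("bottom", "shallow_bottom"):
            base = cur_depth
            wig = 15.0 if name == "bottom" else 6.0
            depth[sl] = base + wig * np.sin(2 * np.pi * 0.01 * tt + rng.uniform(0, 2 * np.pi))
        else:  # surface
            depth[sl] = 0.3
        cur_depth = depth[i + m - 1]
        speed[sl] = _PHASE_SPEED[name]
        head_sd[sl] = _PHASE_HEAD_SD[name]
        phase_id[sl] = name
        i += m
    if i < n:
        depth[i:] = 0.3
        speed[i:] = _PHASE_SPEED["surface"]
        head_sd[i:] = _PHASE_HEAD_SD["surface"]
        phase_id[i:] = "surface"

    # response onset
    onset: float | None = None
    if cfg.treatment != "none" and cfg.exposure_start_h * 3600.0 < t[-1]:
        onset = cfg.exposure_start_h * 3600.0 + cfg.response_onset_delay_s
        k = int(round(onset * fs))
        if k < n:
            m = n - k
            tt = np.arange(m) / fs
            # avoidance: leave current depth towards shallow directed travel
            travel_depth = 40.0
            d0 = depth[k]
            tau = 240.0  # s, transition constant
            depth[k:] = travel_depth + (d0 - travel_depth) * np.exp(-tt / tau) \
                + 8.0 * np.sin(2 * np.pi * 0.004 * tt)
            speed[k:] = _PHASE_SPEED["bottom"] * cfg.avoidance_speed_gain
            head_sd[k:] = 0.002
            phase_id[k:] = "response"

    depth = np.maximum(depth + rng.normal(0.0, cfg.depth_noise_m, n), -0.5)

    # pitch follows the vertical rate; fluking adds an oscillation
    vrate = np.gradient(depth) * fs
    with np.errstate(invalid="ignore"):
        pitch = -np.arcsin(np.clip(vrate / np.maximum(speed, 0.3), -0.98, 0.98))
    fluke_hz = 0.25
    fluke = 0.06 * np.sin(2 * np.pi * fluke_hz * t) * (speed > 0.6)
    pitch = pitch + fluke
    roll = rng.normal(0.0, 0.03, n)
    heading = np.cumsum(rng.normal(0.0, 1.0, n) * head_sd)
    heading = _geo.wrap_angle(heading + rng.uniform(-np.pi, np.pi))

    acc = _orientation_to_acc(pitch, roll) + rng.normal(0.0, cfg.acc_noise_g, (n, 3))
    # dynamic fluking acceleration on the dorso-ventral axis
    acc[:, 2] += 0.04 * speed * np.sin(2 * np.pi * fluke_hz * t) * (speed > 0.6)
    mag = _orientation_to_mag(pitch, roll, heading) + rng.normal(0.0, cfg.mag_noise_ut, (n, 3))

    flow = flow_noise_calibration()(speed) + rng.normal(0.0, cfg.flow_noise_db, n)

    # foraging-sound annotations: clicks span each baseline bottom phase
    annotations: list[SoundAnnotation] = []
    j = 0
    while j < n:
        if phase_id[j] == "bottom":
            k2 = j
            while k2 < n and phase_id[k2] == "bottom":
                k2 += 1
            start, stop = t[j], t[k2 - 1]
            if onset is not None:
                stop = min(stop, onset)
            if stop > start:
                annotations.append(SoundAnnotation(start, stop, "clicks"))
                for _ in range(rng.integers(2, 5)):
                    b0 = rng.uniform(start, max(start, stop - 15.0))
                    annotations.append(SoundAnnotation(b0, min(b0 + rng.uniform(5, 15), stop), "buzz"))
            j = k2
        else:
            j += 1

    record = TagRecord(fs=fs, depth=depth, acc=acc, mag=mag, flow_db=flow,
                       annotations=annotations)
    truth = GroundTruth(
        response_onset_time=onset,
        extras={"speed": speed, "heading": heading, "pitch_true": pitch,
                "phase": phase_id},
    )
    return record, truth


def flow_noise_calibration() -> "FlowNoiseCalibration":
    """Default monotone flow-noise-level <-> speed calibration curve."""
    speeds = np.linspace(0.0, 4.0, 41)
    levels = 60.0 + 12.0 * speeds
    return FlowNoiseCalibration(levels_db=levels, speeds_ms=speeds)


@dataclass
class FlowNoiseCalibration:
    """Monotone mapping between flow-noise band level (dB) and speed (m/s)."""

    levels_db: np.ndarray
    speeds_ms: np.ndarray

    def __post_init__(self):
        self.levels_db = np.asarray(self.levels_db, dtype=float)
        self.speeds_ms = np.asarray(self.speeds_ms, dtype=float)
        if np.any(np.diff(self.levels_db) <= 0):
            raise ValueError("calibration curve must be strictly monotone")

    def __call__(self, speed):
        """Forward map: speed -> level (used by the generator)."""
        return np.interp(speed, self.speeds_ms, self.levels_db)

    def invert(self, level):
        """Inverse map: level -> speed, clamped to the calibrated range."""
        return np.interp(level, self.levels_db, self.speeds_ms)


def _orientation_to_acc(pitch, roll):
    """Static specific force (units of g) in the tag frame for given attitude."""
    return np.stack(
        [np.sin(pitch), -np.cos(pitch) * np.sin(roll), -np.cos(pitch) * np.cos(roll)],
        axis=-1,
    )


# Earth magnetic field in NED coordinates at a high-latitude site (µT).
MAG_FIELD_NED = np.array([13.0, 0.0, 50.0])


def _orientation_to_mag(pitch, roll, heading, field_ned: np.ndarray = MAG_FIELD_NED):
    """Rotate the Earth field into the tag frame for attitude (yaw=heading)."""
    cps, sps = np.cos(heading), np.sin(heading)
    cth, sth = np.cos(pitch), np.sin(pitch)
    cph, sph = np.cos(roll), np.sin(roll)
    bn, be, bd = field_ned
    # body = Rx(roll)^T Ry(pitch)^T Rz(yaw)^T * ned
    x1 = cps * bn + sps * be
    y1 = -sps * bn + cps * be
    z1 = bd
    x2 = cth * x1 - sth * z1
    z2 = sth * x1 + cth * z1
    y3 = cph * y1 + sph * z2
    z3 = -sph * y1 + cph * z2
    return np.stack([x2, y3, z3], axis=-1)


# -----------------------------------------------------------------------------
# satellite track


def transition_matrix(truth: HmmTruth, ttr: float = 0.0, spl_z: float = 0.0) -> np.ndarray:
    """Row-stochastic transition matrix at given covariate values.

    Covariates act on transitions out of state 1 only (towards 2 and 3).
    """
    eta = truth.tpm_logits.copy()
    eta[0, 1:] += truth.recovery_coef * ttr + truth.recovery_spl_coef * ttr * spl_z
    ex = np.exp(eta - eta.max(axis=1, keepdims=True))
    return ex / ex.sum(axis=1, keepdims=True)


def simulate_step_turn(
    truth: HmmTruth,
    n_steps: int,
    rng: np.random.Generator,
    ttr: np.ndarray | None = None,
    spl_z: float = 0.0,
    initial_state: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate (states, step lengths km, turn angles rad) from the 3-state
    process. ``ttr`` is the per-step time-to-recovery covariate (h)."""
    if ttr is None:
        ttr = np.zeros(n_steps)
    states = np.empty(n_steps, dtype=int)
    p0 = _stationary(transition_matrix(truth, 0.0, 0.0))
    s = (rng.choice(3, p=p0) if initial_state is None else initial_state - 1)
    shapes = (truth.step_mean_km / truth.step_sd_km) ** 2
    scales = truth.step_sd_km**2 / truth.step_mean_km
    steps = np.empty(n_steps)
    turns = np.empty(n_steps)
    for k in range(n_steps):
        if k > 0:
            P = transition_matrix(truth, float(ttr[k]), spl_z)
            s = rng.choice(3, p=P[s])
        states[k] = s + 1
        steps[k] = rng.gamma(shapes[s], scales[s])
        turns[k] = rng.vonmises(truth.turn_mean[s], truth.turn_kappa[s])
    return states, steps, turns


def _stationary(P: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eig(P.T)
    i = np.argmin(np.abs(w - 1.0))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def make_sat_track(
    cfg: SimConfig,
    n_steps: int | None = None,
    start_lat: float = 71.0,
    start_lon: float = -7.0,
    start_time: str = "2016-06-01T00:00:00Z",
    obs_noise_km: float = 0.5,
    missing_fraction: float = 0.0,
    outlier_count: int = 0,
    spl_z: float = 0.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate an hourly satellite-tag track from the 3-state movement truth.

    Positions follow gamma step lengths and von Mises turns; transition
    probabilities out of state 1 respond to the time-to-recovery covariate
    when an exposure is scheduled. Isotropic Gaussian observation noise, a
    configurable fraction of missing fixes, and planted outlier fixes
    (implying speed > 8 m/s) support filter testing.
    """
    rng = np.random.default_rng(cfg.seed)
    if n_steps is None:
        n_steps = int(cfg.duration_h)
    if n_steps < 2:
        raise ValueError("need at least two hourly steps")
    hours = np.arange(n_steps + 1)
    if cfg.treatment != "none":
        ttr_pos = np.maximum(0.0, 8.0 - (hours[1:] - cfg.exposure_start_h))
        ttr = np.where(hours[1:] >= cfg.exposure_start_h, ttr_pos, 0.0)
    else:
        ttr = np.zeros(n_steps)
    states, steps, turns = simulate_step_turn(cfg.hmm_truth, n_steps, rng, ttr, spl_z)

    lat = np.empty(n_steps + 1)
    lon = np.empty(n_steps + 1)
    lat[0], lon[0] = start_lat, start_lon
    bearing = rng.uniform(-np.pi, np.pi)
    for k in range(n_steps):
        bearing = _geo.wrap_angle(bearing + turns[k])
        lat[k + 1], lon[k + 1] = _geo.destination(lat[k], lon[k], bearing, steps[k])

    # observation noise (isotropic, km)
    dlat = rng.normal(0.0, obs_noise_km, n_steps + 1) / 111.195
    dlon = rng.normal(0.0, obs_noise_km, n_steps + 1) / (111.195 * np.cos(np.radians(lat)))
    obs_lat, obs_lon = lat + dlat, lon + dlon

    missing = rng.random(n_steps + 1) < missing_fraction
    missing[0] = missing[-1] = False
    obs_lat[missing] = np.nan
    obs_lon[missing] = np.nan

    idx = np.array([], dtype=int)
    if outlier_count > 0:
        # plant outliers only at fixes with clean hourly neighbours, pairwise
        # non-adjacent, so each implies > 8 m/s to both neighbours by
        # construction (40 km displacement over 1 h >> 28.8 km/h)
        chosen: list[int] = []
        candidates = [k for k in range(1, n_steps)
                      if not (missing[k - 1] or missing[k] or missing[k + 1])]
        rng.shuffle(candidates)
        for k in candidates:
            if all(abs(k - c) > 1 for c in chosen):
                chosen.append(k)
            if len(chosen) == outlier_count:
                break
        if len(chosen) < outlier_count:
            raise ValueError("too many outliers requested for this track")
        idx = np.sort(np.array(chosen))
        for k in idx:
            obs_lat[k], obs_lon[k] = _geo.destination(
                obs_lat[k], obs_lon[k], rng.uniform(-np.pi, np.pi), 40.0
            )

    times = pd.to_datetime(start_time) + pd.to_timedelta(hours, unit="h")
    track = pd.DataFrame(
        {"time": times, "lon": obs_lon, "lat": obs_lat,
         "quality": "B", "error_sd_m": obs_noise_km * 1000.0}
    )
    truth = GroundTruth(
        response_onset_time=(cfg.exposure_start_h * 3600.0 if cfg.treatment != "none" else None),
        states=states,
        extras={"true_lat": lat, "true_lon": lon, "steps_km": steps,
                "turns_rad": turns, "ttr_h": ttr, "outlier_idx": idx},
    )
    return track, truth


# -----------------------------------------------------------------------------
# passive-acoustic scene

ECHO_BAND = (20_000.0, 40_000.0)
GUARD_BAND = (4_000.0, 8_000.0)


def make_pam_scene(cfg: SimConfig, mode: str = "psd"):
    """Simulate a PAM scene: background noise plus band-limited click
    transients (20-40 kHz) at truth times, with optional guard-band (4-8 kHz)
    or broadband interferers.

    mode="psd" emits framed power spectral densities directly (frame-level
    statistical emulation, cheap at scale); mode="audio" emits a pressure
    waveform for spectral-analysis tests.
    """
    p = cfg.pam
    if p.fs < 2 * ECHO_BAND[1]:
        raise ValueError("audio sample rate below twice the upper band edge")
    rng = np.random.default_rng(cfg.seed)
    intervals = p.clicking_intervals
    if intervals is None:
        intervals = [(0.0, p.duration_s)]
    click_times = []
    for a, b in intervals:
        n_clicks = rng.poisson(p.click_rate_hz * (b - a))
        click_times.append(np.sort(rng.uniform(a, b, n_clicks)))
    click_times = np.concatenate(click_times) if click_times else np.array([])
    truth = GroundTruth(click_times=click_times)

    if mode == "audio":
        return _pam_audio(p, click_times, rng), truth
    if mode != "psd":
        raise ValueError("mode must be 'psd' or 'audio'")

    hop = p.frame_len // 2
    n_frames = max(0, int((p.duration_s * p.fs - p.frame_len) // hop) + 1)
    # coarse frequency axis: the detector integrates over bands, so PSD-mode
    # scenes carry every freq_decimate-th bin to stay memory-light at scale
    freqs = np.fft.rfftfreq(p.frame_len, 1.0 / p.fs)[:: max(1, p.freq_decimate)]
    times = (np.arange(n_frames) * hop + p.frame_len / 2) / p.fs
    # single-frame periodogram of Gaussian noise: exponential per bin
    psd = rng.exponential(p.noise_psd, size=(n_frames, len(freqs)))

    snr = 10.0 ** (p.click_snr_db / 10.0)
    in_echo = (freqs >= ECHO_BAND[0]) & (freqs <= ECHO_BAND[1])
    for tc in click_times:
        f = int((tc * p.fs - p.frame_len / 2) // hop)
        for fi in (f, f + 1):
            if 0 <= fi < n_frames:
                psd[fi, in_echo] += snr * p.noise_psd
    in_guard = (freqs >= GUARD_BAND[0]) & (freqs <= GUARD_BAND[1])
    for tg in p.guard_interferer_times:
        f = int((tg * p.fs - p.frame_len / 2) // hop)
        if 0 <= f < n_frames:
            psd[f, in_guard] += snr * p.noise_psd
    in_broad = (freqs >= 2000.0) & (freqs <= 50_000.0)
    for tb in p.broadband_interferer_times:
        f = int((tb * p.fs - p.frame_len / 2) // hop)
        if 0 <= f < n_frames:
            psd[f, in_broad] += snr * p.noise_psd
    spec = PsdSpectrogram(times=times, freqs=freqs, psd=psd, fs=p.fs,
                          frame_len=p.frame_len)
    return spec, truth


def _pam_audio(p: PamParams, click_times: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = int(round(p.duration_s * p.fs))
    noise_sigma = np.sqrt(p.noise_psd * p.fs / 2.0)  # flat PSD -> white noise
    x = rng.normal(0.0, noise_sigma, n)
    # click: 0.4 ms Hann-windowed 30 kHz tone burst
    dur = int(round(4e-4 * p.fs))
    tt = np.arange(dur) / p.fs
    band_w = ECHO_BAND[1] - ECHO_BAND[0]
    snr = 10.0 ** (p.click_snr_db / 10.0)
    # amplitude so the in-band frame PSD excess is roughly the configured SNR
    amp = np.sqrt(snr * p.noise_psd * band_w * (p.frame_len / p.fs) / (dur / p.fs))
    burst = amp * np.hanning(dur) * np.sin(2 * np.pi * 30_000.0 * tt)
    for tc in click_times:
        i = int(round(tc * p.fs))
        if 0 <= i < n - dur:
            x[i : i + dur] += burst
    return x


# -----------------------------------------------------------------------------
# response-intensity dataset


def simulate_ri_dataset(
    beta0: float = 1.0,
    omega: float = 4.0,
    beta1: float = 0.12,
    beta2: float = 0.0,
    beta3: float = 0.0,
    gamma_: float | None = None,
    n_exposed: int = 4,
    n_baseline: int = 10,
    bins_per_whale: int = 10,
    tau: int = 4,
    L_values: tuple[float, ...] = (20.0, 35.0, 45.0, 55.0),
    R_values: tuple[float, ...] = (17.0, 0.8, 28.0, 5.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a per-whale, per-bin Mahalanobis-distance dataset from the
    piecewise dose-response-intensity mean with gamma observation noise.

    ``L`` is received SPLmax already offset by the 79 dB hearing-threshold
    reference; ``R`` the minimum source distance (km); ``tau`` the exposure
    bin. If ``gamma_`` is given it replaces the level term ``beta1 * L``.

    The default exposure design spans a wide range of received levels with
    source distances deliberately decorrelated from them — the contrast the
    close/distant treatments were built to create — so that level and
    distance effects are separately identifiable.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_exposed):
        L = L_values[i % len(L_values)]
        R = R_values[i % len(R_values)]
        for k in range(bins_per_whale):
            if k >= tau:
                level_term = gamma_ if gamma_ is not None else beta1 * L
                mu = beta0 + level_term * np.exp(beta2 * (tau - k)) * (1.0 + beta3 * R)
            else:
                mu = beta0
            rows.append(dict(whale=f"exp{i}", bin=k, md=rng.gamma(omega, mu / omega),
                             exposed=True, L=L, R=R, tau=tau))
    for i in range(n_baseline):
        for k in range(bins_per_whale):
            rows.append(dict(whale=f"base{i}", bin=k, md=rng.gamma(omega, beta0 / omega),
                             exposed=False, L=np.nan, R=np.nan, tau=np.nan))
    return pd.DataFrame(rows)


# -----------------------------------------------------------------------------
# feature-window streams for null-calibration studies


def make_feature_minutes(
    n_minutes: int,
    dim: int = 4,
    ar: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Per-minute Gaussian feature summaries (optionally AR(1)-correlated)
    used to exercise the change-point machinery at the analysis-unit scale."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.normal(0.0, 1.0, (n_minutes, dim))
    if ar == 0.0:
        return eps
    x = np.empty_like(eps)
    x[0] = eps[0]
    c = np.sqrt(1.0 - ar**2)
    for k in range(1, n_minutes):
        x[k] = ar * x[k - 1] + c * eps[k]
    return x
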