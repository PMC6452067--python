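"""Monte-Carlo received-sound-level estimation for animals with uncertain
position and depth.

Satellite tags and bottom-moored recorders do not measure the received
acoustic dose directly, so the per-pulse received SPL is modelled from the
transmission schedule and propagated geometry. The propagation model here is
spherical spreading plus linear frequency-dependent seawater absorption — a
deliberately simple, pluggable stand-in for a full ray-trace model; the
Monte-Carlo uncertainty machinery around it (positional and depth
uncertainty, per-pulse quantiles, SPLmax confidence intervals, averaging-time
correction) is the substantive part.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _geo
from .containers import ExposureSchedule


def thorp_absorption_db_km(f_khz: float) -> float:
    """Seawater absorption coefficient (dB/km), Thorp's empirical formula."""
    f2 = f_khz**2
    return 0.11 * f2 / (1.0 + f2) + 44.0 * f2 / (4100.0 + f2) + 2.75e-4 * f2 + 0.003


def propagate_spl(
    source_level: np.ndarray | float,
    range_m: np.ndarray | float,
    absorption_db_km: float,
) -> np.ndarray:
    """Received SPL (dB re 1 µPa) by spherical spreading plus absorption:
    SPL = SL - 20 log10(r / 1 m) - alpha * r_km. Ranges below the 1 m
    reference are clamped."""
    r = np.maximum(np.asarray(range_m, dtype=float), 1.0)
    return np.asarray(source_level, dtype=float) - 20.0 * np.log10(r) \
        - absorption_db_km * r / 1000.0


# -----------------------------------------------------------------------------
# depth uncertainty


@dataclass
class DepthUncertainty:
    """Normal depth-uncertainty distributions for surface and diving states."""

    surface_mean: float
    surface_sd: float
    diving_mean: float
    diving_sd: float
    flags: list = field(default_factory=list)

    def __post_init__(self):
        if self.surface_sd <= 0 or self.diving_sd <= 0:
            raise ValueError("depth-uncertainty s.d. must be positive")


def fit_depth_uncertainty(
    summary_times: np.ndarray,
    summary_depths: np.ndarray,
    coarse_times: np.ndarray,
    coarse_depths: np.ndarray,
    surface_threshold_m: float = 10.0,
    default_sd_m: float = 50.0,
) -> DepthUncertainty:
    """Fit the two depth-uncertainty normals by moment matching.

    Residuals are the coarse (2.5-min duty-cycle) depths minus the linear
    interpolation of the dive-summary profile at the same times, split into a
    surface state (interpolated depth <= threshold) and a diving state.
    States with fewer than 10 residuals get a wide default s.d. and a flag.
    """
    interp = np.interp(coarse_times, summary_times, summary_depths)
    resid = np.asarray(coarse_depths, dtype=float) - interp
    at_surface = interp <= surface_threshold_m
    flags = []
    out = {}
    for name, sel in (("surface", at_surface), ("diving", ~at_surface)):
        r = resid[sel]
        if len(r) < 10:
            warnings.warn(f"<10 {name} residuals; default s.d. used", stacklevel=2)
            flags.append(f"{name}_default_sd")
            out[name] = (0.0, default_sd_m)
        else:
            sd = float(r.std())
            if sd == 0.0:
                flags.append(f"{name}_degenerate")
                sd = 1e-6
            out[name] = (float(r.mean()), sd)
    return DepthUncertainty(out["surface"][0], out["surface"][1],
                            out["diving"][0], out["diving"][1], flags)


# -----------------------------------------------------------------------------
# dose estimates


@dataclass
class DoseEstimate:
    """Per-pulse received-SPL distributions and the SPLmax summary."""

    pulse_times: np.ndarray
    median: np.ndarray
    lo: np.ndarray  # 5th percentile per pulse
    hi: np.ndarray  # 95th percentile per pulse
    splmax_median: float
    splmax_ci: tuple[float, float]  # 90% interval of the per-draw maximum
    correction_db: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.lo > self.hi):
            raise ValueError("interval bounds out of order")


def _summarize(samples: np.ndarray, pulse_times: np.ndarray,
               correction_db: float, meta: dict) -> DoseEstimate:
    """samples: (n_draws, n_pulses) received SPLs (correction included)."""
    med = np.median(samples, axis=0)
    lo = np.quantile(samples, 0.05, axis=0)
    hi = np.quantile(samples, 0.95, axis=0)
    per_draw_max = samples.max(axis=1)
    return DoseEstimate(
        pulse_times=np.asarray(pulse_times, dtype=float),
        median=med, lo=lo, hi=hi,
        splmax_median=float(np.median(per_draw_max)),
        splmax_ci=(float(np.quantile(per_draw_max, 0.05)),
                   float(np.quantile(per_draw_max, 0.95))),
        correction_db=correction_db, meta=meta,
    )


def monte_carlo_dose(
    schedule: ExposureSchedule,
    whale_lat: float,
    whale_lon: float,
    position_sd_km: float,
    depth_mean_m: float,
    depth_sd_m: float,
    n_draws: int = 1000,
    seed: int = 0,
    correction_db: float = 0.0,
    absorption_db_km: float | None = None,
) -> DoseEstimate:
    """Propagate positional and depth uncertainty into received levels.

    Each draw displaces the whale isotropically (Gaussian, ``position_sd_km``)
    and draws a depth; per pulse, the slant range to the source gives the SPL
    through the propagation model, plus the averaging-time correction.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be at least 100")
    rng = np.random.default_rng(seed)
    if absorption_db_km is None:
        absorption_db_km = thorp_absorption_db_km(np.mean(schedule.band_hz) / 1000.0)
    dx = rng.normal(0.0, position_sd_km, n_draws)
    dy = rng.normal(0.0, position_sd_km, n_draws)
    depths = rng.normal(depth_mean_m, max(depth_sd_m, 1e-12), n_draws)
    h0 = _geo.haversine_km(whale_lat, whale_lon, schedule.source_lat, schedule.source_lon)
    # local-plane offset of the whale around its nominal position
    horiz_km = np.hypot(h0 + dx, dy)
    slant_m = np.sqrt((horiz_km * 1000.0) ** 2 + (depths - schedule.source_depth_m) ** 2)
    if np.any(slant_m < 1.0):
        warnings.warn("degenerate geometry: ranges clamped to 1 m", stacklevel=2)
    samples = propagate_spl(schedule.source_levels[None, :], slant_m[:, None],
                            absorption_db_km) + correction_db
    meta = dict(n_draws=n_draws, seed=seed, position_sd_km=position_sd_km,
                depth_sd_m=depth_sd_m, absorption_db_km=absorption_db_km)
    return _summarize(samples, schedule.pulse_times, correction_db, meta)


def mooring_dose(
    schedule: ExposureSchedule,
    mooring_lat: float,
    mooring_lon: float,
    depth_draws_m: np.ndarray,
    detection_range_km: tuple[float, float] = (1.0, 4.0),
    n_draws: int = 1000,
    seed: int = 0,
    correction_db: float = 0.0,
    absorption_db_km: float | None = None,
) -> DoseEstimate:
    """Dose for unlocalized animals near a moored recorder.

    Simulated animals are placed uniformly within the detection annulus
    around the mooring, at depths resampled from pre-exposure tag data.
    """
    rng = np.random.default_rng(seed)
    if absorption_db_km is None:
        absorption_db_km = thorp_absorption_db_km(np.mean(schedule.band_hz) / 1000.0)
    r1, r2 = detection_range_km
    u = rng.random(n_draws)
    radius = np.sqrt(u * (r2**2 - r1**2) + r1**2)  # uniform over the annulus area
    theta = rng.uniform(0.0, 2.0 * np.pi, n_draws)
    depths = rng.choice(np.asarray(depth_draws_m, dtype=float), n_draws, replace=True)
    h0 = _geo.haversine_km(mooring_lat, mooring_lon, schedule.source_lat, schedule.source_lon)
    horiz_km = np.hypot(h0 + radius * np.cos(theta), radius * np.sin(theta))
    slant_m = np.sqrt((horiz_km * 1000.0) ** 2 + (depths - schedule.source_depth_m) ** 2)
    samples = propagate_spl(schedule.source_levels[None, :], slant_m[:, None],
                            absorption_db_km) + correction_db
    meta = dict(n_draws=n_draws, seed=seed, detection_range_km=detection_range_km,
                absorption_db_km=absorption_db_km)
    return _summarize(samples, schedule.pulse_times, correction_db, meta)


def averaging_correction(
    spl_200ms: np.ndarray, spl_pulse: np.ndarray
) -> tuple[float, bool]:
    """Mean (200 ms - whole-pulse) SPL difference from paired measurements,
    applied additively to modelled whole-pulse SPLs. Returns (dB, flagged)."""
    a = np.asarray(spl_200ms, dtype=float)
    b = np.asarray(spl_pulse, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if not ok.any():
        warnings.warn("no paired SPL measurements; correction 0 dB", stacklevel=2)
        return 0.0, True
    return float(np.mean(a[ok] - b[ok])), False
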