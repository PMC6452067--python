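"""End-to-end orchestration: simulate -> features -> change-point -> dose ->
response-intensity -> movement HMM -> PAM, aligned on one exposure timeline.

``run_experiment`` executes every stage from a single master seed (fanned out
to per-stage seeds by fixed offsets, recorded in the report for exact replay)
and emits a study-style report: per-whale change-point time, SPL and source
distance at response onset with a censoring flag, AIC tables for the
response-intensity and movement models, the PAM click-absence verdict, and
Monte-Carlo dose summaries.
"""

from __future__ import annotations

import json
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import changepoint as cp
from . import dose as dose_mod
from . import features as feat
from . import hmm as hmm_mod
from . import pam as pam_mod
from . import response_intensity as ri_mod
from . import simulate as sim

SEED_OFFSETS = dict(tag=0, pam=1_000, sat=2_000, baseline=3_000, threshold=4_000,
                    dose=5_000, ri=6_000)


def onset_dose(
    changepoint_time_s: float | None,
    pulse_times_s: np.ndarray,
    pulse_spl_db: np.ndarray,
    pulse_distance_km: np.ndarray,
    pulse_interval_s: float,
    onset_resolution_s: float,
    ramp_up_min: float = 0.0,
    window_half_s: float = 450.0,
) -> dict | None:
    """SPL and source distance at response onset.

    SPL at onset is the maximum pulse SPL received up to and including the
    change-point window; the censored flag marks onsets whose time resolution
    cannot resolve individual pulses (coarse tags) or exposures without
    ramp-up (the first pulse already arrives at full power), in which case
    the value is an upper bound of the true threshold.
    """
    if changepoint_time_s is None:
        return None
    upto = pulse_times_s <= changepoint_time_s + window_half_s
    if not upto.any():
        raise ValueError("no dose overlap: change-point precedes the first pulse")
    spl = float(np.nanmax(pulse_spl_db[upto]))
    i_cp = int(np.argmin(np.abs(pulse_times_s - changepoint_time_s)))
    censored = (onset_resolution_s > pulse_interval_s) or (ramp_up_min == 0.0)
    return dict(
        spl_at_onset_db=spl,
        distance_at_onset_km=float(pulse_distance_km[i_cp]),
        censored=bool(censored),
    )


def run_experiment(
    cfg: sim.SimConfig,
    out_dir: str | Path | None = None,
    threshold_reps: int = 20_000,
    n_sat_tracks: int = 3,
    n_baseline_records: int = 4,
    detector_threshold_db: float = 5.0,
    fit_movement: bool = True,
    fit_ri: bool = True,
    make_figures: bool = False,
) -> dict:
    """Run the full multi-scale analysis on one simulated experiment.

    Returns the report dict; if ``out_dir`` is given, writes report.json plus
    CSVs (MD series, detections, decoded tracks) and optional figures there.
    """
    t_wall = time.time()
    report: dict = {"config": dict(seed=cfg.seed, treatment=cfg.treatment,
                                   duration_h=cfg.duration_h,
                                   exposure_start_h=cfg.exposure_start_h),
                    "seed_offsets": SEED_OFFSETS, "stages": {}}
    exposure_s = cfg.exposure_start_h * 3600.0

    # --- exposure schedule -------------------------------------------------
    schedule = None
    if cfg.treatment != "none":
        schedule = sim.make_exposure(cfg.treatment, start_time_s=exposure_s)
        report["exposure"] = dict(
            treatment=schedule.treatment, n_pulses=schedule.n_pulses,
            duty_cycle_percent=schedule.duty_cycle_percent,
            ramp_up_min=schedule.ramp_up_min,
        )

    # --- focal whale: tag record, features, change-point -------------------
    record, truth = sim.make_tag_record(replace(cfg, seed=cfg.seed + SEED_OFFSETS["tag"]))
    features = feat.extract_features(record)
    md_av = cp.analyze_record(
        features, exposure_s, "avoidance", reps=threshold_reps,
        seed=cfg.seed + SEED_OFFSETS["threshold"],
    )
    md_loc = cp.analyze_record(
        features, exposure_s, "locomotion", reps=threshold_reps,
        seed=cfg.seed + SEED_OFFSETS["threshold"] + 1,
    )
    report["changepoint"] = {
        "avoidance": dict(time_s=md_av.changepoint_time, threshold=md_av.threshold,
                          **md_av.meta),
        "locomotion": dict(time_s=md_loc.changepoint_time, threshold=md_loc.threshold,
                           **md_loc.meta),
        "truth_onset_s": truth.response_onset_time,
    }

    # --- truth received levels and onset dose ------------------------------
    onset = None
    if schedule is not None:
        pulse_abs = schedule.start_time_s + schedule.pulse_times
        d0_km = 1.0 if cfg.treatment == "close" else 17.0
        onset_t = truth.response_onset_time
        speed = truth.extras["speed"]
        rec_dist = np.full(schedule.n_pulses, d0_km)
        if onset_t is not None:
            dt = np.maximum(pulse_abs - onset_t, 0.0)
            rec_dist = d0_km + truth.extras["speed"].max() * dt / 1000.0
        i_sample = np.clip((pulse_abs * record.fs).astype(int), 0, record.n - 1)
        slant_m = np.sqrt((rec_dist * 1000.0) ** 2
                          + (record.depth[i_sample] - schedule.source_depth_m) ** 2)
        alpha = dose_mod.thorp_absorption_db_km(np.mean(schedule.band_hz) / 1000.0)
        pulse_spl = dose_mod.propagate_spl(schedule.source_levels, slant_m, alpha)
        truth.pulse_spl = pulse_spl
        onset = onset_dose(
            md_av.changepoint_time, pulse_abs, pulse_spl, rec_dist,
            schedule.pulse_interval_s, onset_resolution_s=md_av.step_s
            if hasattr(md_av, "step_s") else 60.0,
            ramp_up_min=schedule.ramp_up_min,
        )
        report["onset"] = onset

        # Monte-Carlo dose for a satellite-tagged whale at the same range
        mc = dose_mod.monte_carlo_dose(
            schedule, *sim._geo.destination(schedule.source_lat, schedule.source_lon,
                                            0.0, d0_km),
            position_sd_km=1.0, depth_mean_m=200.0, depth_sd_m=150.0,
            n_draws=500, seed=cfg.seed + SEED_OFFSETS["dose"],
        )
        report["dose"] = dict(splmax_median=mc.splmax_median, splmax_ci=mc.splmax_ci,
                              n_pulses=len(mc.median), meta=mc.meta)

    # --- response-intensity model comparison -------------------------------
    if fit_ri:
        ri_rows = _build_ri_dataset(cfg, record, features, exposure_s,
                                    n_baseline_records, onset)
        if ri_rows is not None:
            tab = ri_mod.compare_models(ri_rows, n_starts=8)
            report["ri_aic_table"] = tab.drop(columns=["results"]).to_dict("records")

    # --- satellite tracks and movement HMM ---------------------------------
    if fit_movement and n_sat_tracks >= 1:
        tracks, spls = [], []
        for i in range(n_sat_tracks):
            tr, tr_truth = sim.make_sat_track(
                replace(cfg, seed=cfg.seed + SEED_OFFSETS["sat"] + i),
                n_steps=max(48, int(cfg.duration_h)),
            )
            filt, _ = hmm_mod.speed_filter(tr)
            hourly = hmm_mod.interpolate_hourly(filt)
            st = hmm_mod.steps_turns(hourly)
            hrs = np.arange(len(st), dtype=float)
            st["ttr_h"] = (hmm_mod.time_to_recovery(hrs, cfg.exposure_start_h)
                           if cfg.treatment != "none" else 0.0)
            tracks.append(st)
            spls.append(130.0 - 2.0 * i)
        models = ("none", "recovery") if cfg.treatment == "none" else (
            "none", "recovery", "recovery-spl")
        fits = hmm_mod.fit_candidates(tracks, spl_max_db=spls, models=models,
                                      n_starts=4, seed=cfg.seed)
        selected, tab = hmm_mod.select_model(fits)
        report["hmm"] = dict(selected=selected, aic_table=tab.to_dict("records"),
                             occupancy=fits[selected].occupancy().tolist())
        decoded = fits[selected].viterbi()
    else:
        decoded = None

    # --- PAM: detections and click-absence test ----------------------------
    # The mooring scene runs on its own clock: intermittent baseline clicking
    # bouts (20 min on / 15 min off), then — under exposure — silence from
    # 60% of the scene onwards (whales near the mooring stop echolocating
    # and/or leave the area).
    pam_cfg = replace(cfg, seed=cfg.seed + SEED_OFFSETS["pam"])
    scene_s = pam_cfg.pam.duration_s
    pam_exposure_s = 0.6 * scene_s
    bouts = []
    t0 = 0.0
    while t0 < scene_s:
        bouts.append((t0, min(t0 + 1200.0, scene_s)))
        t0 += 2100.0
    if cfg.treatment != "none":
        bouts = [(a, min(b, pam_exposure_s)) for a, b in bouts if a < pam_exposure_s]
    pam_cfg.pam.clicking_intervals = bouts
    spec, pam_truth = sim.make_pam_scene(pam_cfg, mode="psd")
    norm = pam_mod.normalize_psd(spec)
    segs = pam_mod.segment_level_difference(norm)
    det = pam_mod.detect(segs, detector_threshold_db)
    pam_report = dict(n_segments=int(len(det)),
                      n_detected=int(det["detected"].sum()),
                      threshold_db=detector_threshold_db)
    if cfg.treatment != "none":
        runs = pam_mod.click_absent_periods(det)
        last = runs.last_starting_in(pam_exposure_s - pam_mod.SEGMENT_S, scene_s)
        base = pam_mod.click_absent_periods(
            det.iloc[: int(pam_exposure_s // pam_mod.SEGMENT_S)])
        if last is not None and base.baseline_durations_h.size:
            res = pam_mod.absence_outlier_test(last["duration_h"], base)
            pam_report["absence_test"] = dict(
                response=res.response, duration_h=res.duration_h,
                threshold_h=res.threshold_h, percentile=res.percentile,
                low_power=res.low_power)
    report["pam"] = pam_report

    report["elapsed_s"] = time.time() - t_wall
    _check_consistency(report)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
        pd.DataFrame({"time_s": md_av.center_times, "md": md_av.md}).to_csv(
            out / "md_avoidance.csv", index=False)
        det.to_csv(out / "pam_detections.csv", index=False)
        if decoded is not None:
            pd.DataFrame({f"track_{i}": pd.Series(d) for i, d in
                          enumerate(decoded)}).to_csv(out / "decoded_states.csv",
                                                      index=False)
        if make_figures:
            _figure_md(md_av, exposure_s, out / "md_avoidance.png")
    return report


def _build_ri_dataset(cfg, record, features, exposure_s, n_baseline, onset):
    """Bin the focal whale and synthetic baseline whales into the per-bin MD
    dataset against the pooled baseline average of all whales."""
    base_cfgs = [replace(cfg, seed=cfg.seed + SEED_OFFSETS["baseline"] + i,
                         treatment="none") for i in range(n_baseline)]
    base_feats = [feat.extract_features(sim.make_tag_record(c)[0]) for c in base_cfgs]
    variables = cp.AVOIDANCE_VARS
    span = ri_mod.BIN_SPAN_S
    pooled = []
    for f in [features] + base_feats:
        win = cp.window_means(f, variables, span, span)
        end = exposure_s if f is features else np.inf
        sel = win.center_times + span / 2.0 <= end
        pooled.append(win.vectors[sel])
    pooled = np.vstack(pooled)
    if pooled.shape[0] < len(variables) + 2:
        return None
    base_sum = cp.baseline_summary(pooled)
    rows = []
    focal_bins = ri_mod.md_bins(features, base_sum, variables, span, align_s=exposure_s)
    spl_max = onset["spl_at_onset_db"] if onset else 120.0
    for _, r in focal_bins.iterrows():
        rows.append(dict(whale="focal", bin=r["bin"], md=r["md"], exposed=True,
                         L=spl_max - ri_mod.SPL_OFFSET_DB,
                         R=1.0 if cfg.treatment == "close" else 17.0, tau=0))
    for i, f in enumerate(base_feats):
        for _, r in ri_mod.md_bins(f, base_sum, variables, span).iterrows():
            rows.append(dict(whale=f"base{i}", bin=r["bin"], md=r["md"],
                             exposed=False, L=np.nan, R=np.nan, tau=np.nan))
    return pd.DataFrame(rows)


def _check_consistency(report: dict) -> None:
    cp_time = report["changepoint"]["avoidance"]["time_s"]
    if "onset" in report and report["onset"] is not None:
        assert cp_time is not None, "onset SPL reported without a change-point"


def _figure_md(series, exposure_s, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(series.center_times / 3600.0, series.md, lw=0.8)
    ax.axhline(series.threshold, color="r", ls="--", label="threshold")
    ax.axvline(exposure_s / 3600.0, color="k", ls=":", label="exposure start")
    if series.changepoint_time is not None:
        ax.axvline(series.changepoint_time / 3600.0, color="g", label="change-point")
    ax.set(xlabel="time (h)", ylabel="Mahalanobis distance")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
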