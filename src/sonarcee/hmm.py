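"""Hidden Markov models of hourly movement with exposure-recovery covariates.

Satellite-tag tracks are speed-filtered, regularized to hourly positions and
converted to step lengths (gamma-distributed, km) and turn angles (von Mises,
positive = left). A 3-state HMM — tortuous (state 1), low-speed directional
(state 2) and high-speed directional (state 3) movement — is fitted by direct
numerical maximization of the joint forward log-likelihood over all tracks,
with a shared transition matrix. Covariates (a linearly decaying
time-to-recovery term, optionally interacting with standardized received
SPLmax or source distance) act on the multinomial-logit transition
probabilities out of state 1 only. Candidate covariate models are compared by
AIC with a "simplest within delta-AIC < 2" selection rule; states are decoded
with the Viterbi algorithm.

State identifiability: state-dependent step means are parameterized as ordered
increments, so state 1 always has the shortest steps and no post-hoc
relabelling is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import optimize
from scipy.special import gammaln, i0e

from . import _geo

N_STATES = 3
COVARIATE_MODELS = ("none", "recovery", "recovery-spl", "recovery-dist")
VMAX_MS = 8.0  # speed-filter threshold
MAX_RECOVERY_H = 8.0


# -----------------------------------------------------------------------------
# track preparation


def speed_filter(track: pd.DataFrame, vmax_ms: float = VMAX_MS) -> tuple[pd.DataFrame, list]:
    """Iteratively remove fixes whose implied great-circle speeds to both
    neighbours exceed ``vmax_ms``.

    Returns the filtered track and the index labels of removed fixes.
    """
    df = track.dropna(subset=["lon", "lat"]).copy()
    if len(df) < 2:
        raise ValueError("need at least two fixes")
    removed = []
    while True:
        t = df["time"]
        if pd.api.types.is_datetime64_any_dtype(t):
            dt_s = t.diff().dt.total_seconds().to_numpy()[1:]
        else:
            dt_s = np.diff(t.to_numpy(dtype=float)) * 3600.0  # hours assumed
        d_km = _geo.haversine_km(df["lat"].to_numpy()[:-1], df["lon"].to_numpy()[:-1],
                                 df["lat"].to_numpy()[1:], df["lon"].to_numpy()[1:])
        v = d_km * 1000.0 / dt_s
        # fix i has neighbours through segments i-1 and i
        bad = np.zeros(len(df), dtype=bool)
        bad[1:-1] = (v[:-1] > vmax_ms) & (v[1:] > vmax_ms)
        bad[0] = v[0] > vmax_ms and len(v) == 1
        if not bad.any():
            break
        worst = np.argmax(np.where(bad, np.concatenate([[0], v]), -np.inf))
        removed.append(df.index[worst])
        df = df.drop(df.index[worst])
        if len(df) < 2:
            raise ValueError("speed filter removed all usable fixes")
    return df, removed


def interpolate_hourly(track: pd.DataFrame, max_gap_h: float = 3.0) -> pd.DataFrame:
    """Linear interpolation of filtered fixes onto the hourly grid.

    Hours whose nearest bracketing fixes are more than ``max_gap_h`` apart
    are left missing. (A state-space track filter is deliberately out of
    scope; this is plumbing for the simulator-driven pipeline.)
    """
    t = pd.to_datetime(track["time"])
    t0 = t.iloc[0].ceil("h")
    grid = pd.date_range(t0, t.iloc[-1], freq="h")
    ts = (t - t.iloc[0]).dt.total_seconds().to_numpy()
    gs = (grid - t.iloc[0]).total_seconds().to_numpy()
    lon = np.interp(gs, ts, track["lon"].to_numpy())
    lat = np.interp(gs, ts, track["lat"].to_numpy())
    # mask grid hours inside long observation gaps
    gap_idx = np.searchsorted(ts, gs)
    lo = np.clip(gap_idx - 1, 0, len(ts) - 1)
    hi = np.clip(gap_idx, 0, len(ts) - 1)
    gap_h = (ts[hi] - ts[lo]) / 3600.0
    bad = gap_h > max_gap_h
    lon[bad] = np.nan
    lat[bad] = np.nan
    return pd.DataFrame({"time": grid, "lon": lon, "lat": lat})


def steps_turns(hourly: pd.DataFrame) -> pd.DataFrame:
    """Hourly step lengths (km) and turn angles (rad) from regular positions.

    Step k joins positions k and k+1 (great circle); turn k is the signed
    change of bearing into step k relative to step k-1, positive for a left
    turn. Intervals adjacent to missing positions are missing.
    """
    lat = hourly["lat"].to_numpy(dtype=float)
    lon = hourly["lon"].to_numpy(dtype=float)
    n = len(lat) - 1
    step = np.full(n, np.nan)
    brg = np.full(n, np.nan)
    ok = np.isfinite(lat[:-1]) & np.isfinite(lat[1:]) & np.isfinite(lon[:-1]) & np.isfinite(lon[1:])
    step[ok] = _geo.haversine_km(lat[:-1][ok], lon[:-1][ok], lat[1:][ok], lon[1:][ok])
    brg[ok] = _geo.initial_bearing_rad(lat[:-1][ok], lon[:-1][ok], lat[1:][ok], lon[1:][ok])
    turn = np.full(n, np.nan)
    both = np.isfinite(brg[1:]) & np.isfinite(brg[:-1])
    turn[1:][both] = -_geo.wrap_angle(brg[1:][both] - brg[:-1][both])
    out = pd.DataFrame({"step_km": step, "turn_rad": turn})
    if "time" in hourly:
        out.index = pd.Index(hourly["time"].to_numpy()[:-1], name="time")
    return out


def time_to_recovery(times_h, exposure_time_h: float, max_h: float = MAX_RECOVERY_H):
    """Linearly decaying exposure covariate: ``max(0, max_h - dt)`` for
    dt hours since exposure (0 before exposure)."""
    times_h = np.asarray(times_h, dtype=float)
    dt = times_h - exposure_time_h
    return np.where(dt >= 0.0, np.maximum(0.0, max_h - dt), 0.0)


# -----------------------------------------------------------------------------
# parameters


@dataclass
class HmmParams:
    """Natural parameters of the 3-state model.

    ``tpm_logits`` is a 3x3 matrix of multinomial-logit intercepts with the
    diagonal (stay) as reference category; ``coefs`` has one row per
    covariate, acting on transitions 1->2 and 1->3.
    """

    step_mean: np.ndarray
    step_sd: np.ndarray
    turn_mean: np.ndarray
    turn_kappa: np.ndarray
    tpm_logits: np.ndarray
    coefs: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))

    def transition_matrices(self, X: np.ndarray) -> np.ndarray:
        """(T, 3, 3) row-stochastic matrices at covariate values X (T, n_cov)."""
        T = X.shape[0]
        eta = np.broadcast_to(self.tpm_logits, (T, 3, 3)).copy()
        if self.coefs.shape[0]:
            eta[:, 0, 1] += X @ self.coefs[:, 0]
            eta[:, 0, 2] += X @ self.coefs[:, 1]
        eta -= eta.max(axis=2, keepdims=True)
        P = np.exp(eta)
        P /= P.sum(axis=2, keepdims=True)
        return P

    def stationary(self) -> np.ndarray:
        P = self.transition_matrices(np.zeros((1, self.coefs.shape[0])))[0]
        w, v = np.linalg.eig(P.T)
        pi = np.abs(np.real(v[:, np.argmin(np.abs(w - 1.0))]))
        return pi / pi.sum()


# -----------------------------------------------------------------------------
# numba kernels


@njit
def _forward(logb, P, pi):
    """Scaled forward log-likelihood of one track.

    logb: (T, S) observation log-densities (0 for missing obs);
    P: (T, S, S), P[t] governs the transition into step t; pi: (S,).
    """
    T, S = logb.shape
    ll = 0.0
    phi = np.empty(S)
    m = logb[0].max()
    tot = 0.0
    for s in range(S):
        phi[s] = pi[s] * np.exp(logb[0, s] - m)
        tot += phi[s]
    ll += m + np.log(tot)
    for s in range(S):
        phi[s] /= tot
    for t in range(1, T):
        m = logb[t].max()
        tot = 0.0
        nxt = np.zeros(S)
        for j in range(S):
            acc = 0.0
            for i in range(S):
                acc += phi[i] * P[t, i, j]
            nxt[j] = acc * np.exp(logb[t, j] - m)
            tot += nxt[j]
        ll += m + np.log(tot)
        for s in range(S):
            phi[s] = nxt[s] / tot
    return ll


@njit
def _viterbi(logb, logP, logpi):
    """Most probable state path; ties broken toward the lower state index."""
    T, S = logb.shape
    delta = np.empty((T, S))
    back = np.zeros((T, S), dtype=np.int64)
    for s in range(S):
        delta[0, s] = logpi[s] + logb[0, s]
    for t in range(1, T):
        for j in range(S):
            best = -np.inf
            arg = 0
            for i in range(S):
                v = delta[t - 1, i] + logP[t, i, j]
                if v > best:  # strict: first (lowest) index wins ties
                    best = v
                    arg = i
            delta[t, j] = best + logb[t, j]
            back[t, j] = arg
    path = np.zeros(T, dtype=np.int64)
    best = -np.inf
    for s in range(S):
        if delta[T - 1, s] > best:
            best = delta[T - 1, s]
            path[T - 1] = s
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


# -----------------------------------------------------------------------------
# observation densities


def _gamma_logpdf(x, mean, sd):
    a = (mean / sd) ** 2
    s = sd**2 / mean
    return (a - 1.0) * np.log(x) - x / s - a * np.log(s) - gammaln(a)


def _vonmises_logpdf(x, mu, kappa):
    return kappa * np.cos(x - mu) - np.log(2.0 * np.pi * i0e(kappa)) - kappa


def obs_logdensities(steps: np.ndarray, turns: np.ndarray, p: HmmParams) -> np.ndarray:
    """(T, 3) per-state observation log-densities; missing values contribute
    unit likelihood (log-density 0) while transitions still advance."""
    T = len(steps)
    logb = np.zeros((T, N_STATES))
    ok_s = np.isfinite(steps)
    ok_t = np.isfinite(turns)
    xs = np.where(ok_s, np.maximum(steps, 1e-10), 1.0)
    xt = np.where(ok_t, turns, 0.0)
    for s in range(N_STATES):
        ls = _gamma_logpdf(xs, p.step_mean[s], p.step_sd[s])
        lt = _vonmises_logpdf(xt, p.turn_mean[s], p.turn_kappa[s])
        logb[:, s] = np.where(ok_s, ls, 0.0) + np.where(ok_t, lt, 0.0)
    return logb


# -----------------------------------------------------------------------------
# model


class MovementHMM:
    """3-state step-and-turn HMM pooled over tracks with shared parameters.

    ``tracks`` is a list of DataFrames with columns ``step_km`` and
    ``turn_rad`` (NaN = missing) and, for covariate models, ``ttr_h``.
    Per-track received SPLmax (dB) and source distance (km) scalars are
    supplied through ``spl_max_db`` / ``distance_km`` and standardized
    (z-scored) across tracks before entering the logit.
    """

    def __init__(
        self,
        tracks: list[pd.DataFrame],
        covariate: str = "none",
        spl_max_db: list[float] | None = None,
        distance_km: list[float] | None = None,
        fix_turn_mean: bool = False,
    ):
        if covariate not in COVARIATE_MODELS:
            raise ValueError(f"covariate model must be one of {COVARIATE_MODELS}")
        self.covariate = covariate
        self.fix_turn_mean = fix_turn_mean
        self.tracks = tracks
        self._steps = [t["step_km"].to_numpy(dtype=float) for t in tracks]
        self._turns = [t["turn_rad"].to_numpy(dtype=float) for t in tracks]

        def _ttr(t):
            return t["ttr_h"].to_numpy(dtype=float) if "ttr_h" in t else np.zeros(len(t))

        if covariate == "none":
            self._X = [np.zeros((len(t), 0)) for t in tracks]
        elif covariate == "recovery":
            self._X = [_ttr(t)[:, None] for t in tracks]
        else:
            vals = spl_max_db if covariate == "recovery-spl" else distance_km
            if vals is None:
                raise ValueError(f"{covariate} requires per-track scalars")
            vals = np.asarray(vals, dtype=float)
            sd = vals.std()
            self.covariate_scale = (float(vals.mean()), float(sd if sd > 0 else 1.0))
            z = (vals - self.covariate_scale[0]) / self.covariate_scale[1]
            self._X = [np.column_stack([_ttr(t), _ttr(t) * z[i]])
                       for i, t in enumerate(tracks)]
        self.n_cov = self._X[0].shape[1]

    # -- parameter packing (ordered step means for identifiability) ------

    @property
    def param_names(self) -> list[str]:
        names = [f"step_mean_{i+1}" for i in range(3)]
        names += [f"step_sd_{i+1}" for i in range(3)]
        if not self.fix_turn_mean:
            names += [f"turn_mean_{i+1}" for i in range(3)]
        names += [f"turn_kappa_{i+1}" for i in range(3)]
        names += ["a_12", "a_13", "a_21", "a_23", "a_31", "a_32"]
        for c in range(self.n_cov):
            names += [f"c{c+1}_12", f"c{c+1}_13"]
        return names

    @property
    def k_params(self) -> int:
        return len(self.param_names)

    def _unpack(self, z: np.ndarray) -> HmmParams:
        i = 0
        incr = np.exp(z[i : i + 3]); i += 3
        step_mean = np.cumsum(incr)
        step_sd = np.exp(z[i : i + 3]); i += 3
        if self.fix_turn_mean:
            turn_mean = np.zeros(3)
        else:
            turn_mean = _geo.wrap_angle(z[i : i + 3]); i += 3
        turn_kappa = np.exp(z[i : i + 3]); i += 3
        A = np.zeros((3, 3))
        A[0, 1], A[0, 2], A[1, 0], A[1, 2], A[2, 0], A[2, 1] = z[i : i + 6]; i += 6
        coefs = z[i:].reshape(self.n_cov, 2) if self.n_cov else np.zeros((0, 2))
        return HmmParams(step_mean, step_sd, turn_mean, turn_kappa, A, coefs)

    def _pack(self, p: HmmParams) -> np.ndarray:
        incr = np.diff(np.concatenate([[0.0], p.step_mean]))
        z = [np.log(incr), np.log(p.step_sd)]
        if not self.fix_turn_mean:
            z.append(p.turn_mean)
        z.append(np.log(p.turn_kappa))
        A = p.tpm_logits
        z.append(np.array([A[0, 1], A[0, 2], A[1, 0], A[1, 2], A[2, 0], A[2, 1]]))
        if self.n_cov:
            z.append(p.coefs.ravel())
        return np.concatenate(z)

    # -- likelihood ------------------------------------------------------

    def loglike(self, params: HmmParams) -> float:
        """Joint forward log-likelihood over all tracks (shared parameters)."""
        if np.any(params.step_mean <= 0) or np.any(params.step_sd <= 0) or np.any(
            params.turn_kappa <= 0
        ):
            return -np.inf
        pi = params.stationary()
        ll = 0.0
        for steps, turns, X in zip(self._steps, self._turns, self._X):
            logb = obs_logdensities(steps, turns, params)
            P = params.transition_matrices(X)
            ll += _forward(logb, P, pi)
        return float(ll)

    def _nll_z(self, z: np.ndarray) -> float:
        with np.errstate(over="ignore"):
            ll = self.loglike(self._unpack(z))
        return 1e10 if not np.isfinite(ll) else -ll

    def fit(self, n_starts: int = 10, seed: int = 0, tol: float = 1e-7,
            start: HmmParams | None = None) -> "MovementHMMResults":
        """Direct numerical maximization of the forward log-likelihood from
        deterministic multi-starts (the first start is moment-based, the rest
        seeded jitters of it)."""
        rng = np.random.default_rng(seed)
        z0 = self._pack(start) if start is not None else self._moment_start()
        best = None
        for k in range(n_starts):
            zk = z0 if k == 0 else z0 + rng.normal(0.0, 0.4, z0.shape)
            res = optimize.minimize(self._nll_z, zk, method="L-BFGS-B", tol=tol)
            if best is None or res.fun < best.fun:
                best = res
        if best is None or best.fun >= 1e9:
            raise RuntimeError(f"HMM fit failed to converge: {best}")
        return MovementHMMResults(self, self._unpack(best.x), -best.fun, best)

    def _moment_start(self) -> np.ndarray:
        steps = np.concatenate(self._steps)
        steps = steps[np.isfinite(steps) & (steps > 0)]
        qs = np.quantile(steps, [1 / 6, 3 / 6, 5 / 6])
        means = np.maximum(qs, 1e-3)
        means = np.maximum.accumulate(means + np.arange(3) * 1e-3)
        sds = np.full(3, max(steps.std() / 2.0, 1e-3))
        p = HmmParams(
            step_mean=means,
            step_sd=sds,
            turn_mean=np.zeros(3),
            turn_kappa=np.array([0.5, 2.0, 8.0]),
            tpm_logits=np.where(np.eye(3, dtype=bool), 0.0, -2.2),
            coefs=np.zeros((self.n_cov, 2)),
        )
        return self._pack(p)


class MovementHMMResults:
    """Fitted HMM: parameter estimates, AIC, decoding, diagnostics."""

    def __init__(self, model: MovementHMM, params: HmmParams, llf: float, optres):
        self.model = model
        self.params = params
        self.llf = float(llf)
        self.optres = optres
        self.converged = bool(optres.success)

    @property
    def k_params(self) -> int:
        return self.model.k_params

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.llf

    def viterbi(self) -> list[np.ndarray]:
        """Jointly most probable state sequence per track (labels 1..3)."""
        p = self.params
        logpi = np.log(p.stationary())
        out = []
        for steps, turns, X in zip(self.model._steps, self.model._turns, self.model._X):
            logb = obs_logdensities(steps, turns, p)
            with np.errstate(divide="ignore"):
                logP = np.log(p.transition_matrices(X))
            out.append(_viterbi(logb, logP, logpi) + 1)
        return out

    def occupancy(self) -> np.ndarray:
        states = np.concatenate(self.viterbi())
        return np.array([(states == s).mean() for s in (1, 2, 3)])

    @property
    def degenerate_states(self) -> list[int]:
        return [s + 1 for s, f in enumerate(self.occupancy()) if f <= 0.01]

    def bse(self) -> pd.Series:
        """Delta-free standard errors: inverse numerical Hessian of the
        negative log-likelihood in the natural step/turn parameter space."""
        from .response_intensity import _num_hessian

        p = self.params
        x0 = np.concatenate([p.step_mean, p.step_sd, p.turn_mean, p.turn_kappa])

        def nll(v):
            q = HmmParams(v[0:3], v[3:6], v[6:9], v[9:12], p.tpm_logits, p.coefs)
            ll = self.model.loglike(q)
            return -ll if np.isfinite(ll) else 1e10

        H = _num_hessian(nll, x0)
        cov = np.linalg.pinv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        names = ([f"step_mean_{i}" for i in (1, 2, 3)] + [f"step_sd_{i}" for i in (1, 2, 3)]
                 + [f"turn_mean_{i}" for i in (1, 2, 3)] + [f"turn_kappa_{i}" for i in (1, 2, 3)])
        return pd.Series(se, index=names)

    def summary(self) -> str:
        p = self.params
        lines = [
            f"Movement HMM ({self.model.covariate} covariate model)",
            f"  logLik={self.llf:.3f}  AIC={self.aic:.3f}  k={self.k_params}"
            f"  converged={self.converged}",
            f"  step mean (km/h): {np.round(p.step_mean, 3)}",
            f"  step sd   (km/h): {np.round(p.step_sd, 3)}",
            f"  turn mean (rad):  {np.round(p.turn_mean, 3)}",
            f"  turn kappa:       {np.round(p.turn_kappa, 3)}",
            f"  transition logits:\n{np.round(p.tpm_logits, 3)}",
        ]
        if p.coefs.size:
            lines.append(f"  covariate coefs (1->2, 1->3):\n{np.round(p.coefs, 3)}")
        if self.degenerate_states:
            lines.append(f"  WARNING: degenerate states {self.degenerate_states}")
        return "\n".join(lines)


# -----------------------------------------------------------------------------
# model selection


def select_model(fits: dict[str, MovementHMMResults]) -> tuple[str, pd.DataFrame]:
    """Return the simplest model (fewest parameters) within delta-AIC < 2 of
    the minimum, plus the full AIC table."""
    tab = pd.DataFrame(
        [dict(model=name, k=r.k_params, llf=r.llf, aic=r.aic) for name, r in fits.items()]
    ).sort_values("aic").reset_index(drop=True)
    tab["delta_aic"] = tab["aic"] - tab["aic"].min()
    cand = tab[tab["delta_aic"] < 2.0].sort_values(["k", "aic"])
    return str(cand.iloc[0]["model"]), tab


def fit_candidates(
    tracks: list[pd.DataFrame],
    spl_max_db: list[float] | None = None,
    distance_km: list[float] | None = None,
    models: tuple[str, ...] = COVARIATE_MODELS,
    n_starts: int = 10,
    seed: int = 0,
    tol: float = 1e-7,
    **kw,
) -> dict[str, MovementHMMResults]:
    """Fit all candidate covariate models; later models warm-start from the
    no-covariate fit."""
    fits: dict[str, MovementHMMResults] = {}
    base_params = None
    for name in models:
        if (name == "recovery-spl" and spl_max_db is None) or (
            name == "recovery-dist" and distance_km is None
        ):
            import warnings

            warnings.warn(f"skipping {name}: per-track scalars missing", stacklevel=2)
            continue
        m = MovementHMM(tracks, name, spl_max_db, distance_km, **kw)
        start = None
        if base_params is not None and name != "none":
            start = HmmParams(
                base_params.step_mean.copy(), base_params.step_sd.copy(),
                base_params.turn_mean.copy(), base_params.turn_kappa.copy(),
                base_params.tpm_logits.copy(), np.zeros((m.n_cov, 2)),
            )
        fits[name] = m.fit(n_starts=n_starts if start is None else max(2, n_starts // 3),
                           seed=seed, tol=tol, start=start)
        if name == "none":
            base_params = fits[name].params
    return fits


def leave_out_sensitivity(
    tracks: list[pd.DataFrame],
    spl_max_db: list[float] | None = None,
    distance_km: list[float] | None = None,
    max_omit: int = 2,
    models: tuple[str, ...] = COVARIATE_MODELS,
    n_starts: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeat model selection after omitting combinations of one or two
    tracks; reports whether the selected model changes."""
    import itertools as it

    if len(tracks) < 3:
        raise ValueError("need at least three tracks")
    rows = []
    full_sel, _ = select_model(fit_candidates(tracks, spl_max_db, distance_km,
                                              models, n_starts, seed))
    rows.append(dict(omitted=(), selected=full_sel, changed=False))
    idx = range(len(tracks))
    for r in range(1, max_omit + 1):
        for omit in it.combinations(idx, r):
            keep = [i for i in idx if i not in omit]
            sub = [tracks[i] for i in keep]
            spl = [spl_max_db[i] for i in keep] if spl_max_db is not None else None
            dist = [distance_km[i] for i in keep] if distance_km is not None else None
            sel, _ = select_model(fit_candidates(sub, spl, dist, models, n_starts, seed))
            rows.append(dict(omitted=omit, selected=sel, changed=sel != full_sel))
    return pd.DataFrame(rows)
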