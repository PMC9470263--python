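"""Two-state hidden Markov model for movement classification and null tracks.

Regularized 5-min tracks are classified into 'foraging' (short steps, wide
turning-angle distribution) and 'transiting' (long, directed steps) states.
Emissions are gamma step lengths (parameterized by mean and SD) and von Mises
turning angles; the likelihood is the forward algorithm pooled over tracks and
maximized numerically with random restarts.  The fitted kernel also drives the
null model: tracks simulated step-by-step from the Markov chain, with per-fix
rejection of proposals that land on shore, form the random-movement ensemble
against which real prey encounter is scored.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.optimize import minimize
from scipy.special import gammaln, i0e, logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "HMMParams",
    "StateSequence",
    "fit_hmm",
    "decode",
    "fit_on_subset",
    "simulate_hmm_track",
    "simulate_ensemble",
    "filter_in_domain",
    "forward_loglik",
]

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class HMMParams:
    """Per-state gamma step and von Mises turn parameters plus Markov chain.

    State labels attach by step-length mean: 'foraging' is the state with the
    smaller mean step.  ``delta`` is the initial distribution (the stationary
    distribution of ``tmat`` when fitted here).
    """

    step_mean: tuple[float, float]
    step_sd: tuple[float, float]
    turn_mean: tuple[float, float]
    turn_kappa: tuple[float, float]
    tmat: tuple[tuple[float, float], tuple[float, float]]
    delta: tuple[float, float]

    def __post_init__(self) -> None:
        if min(self.step_mean) <= 0 or min(self.step_sd) <= 0:
            raise ValueError("step mean/SD must be positive")
        if min(self.turn_kappa) < 0:
            raise ValueError("kappa must be >= 0")
        G = np.asarray(self.tmat)
        if G.shape != (2, 2) or np.any(G < 0) or not np.allclose(G.sum(axis=1), 1):
            raise ValueError("tmat rows must be probability vectors")
        d = np.asarray(self.delta)
        if np.any(d < 0) or not math.isclose(d.sum(), 1.0, abs_tol=1e-8):
            raise ValueError("delta must sum to 1")

    @property
    def foraging_state(self) -> int:
        return int(np.argmin(self.step_mean))

    @property
    def transiting_state(self) -> int:
        return 1 - self.foraging_state

    @property
    def state_labels(self) -> tuple[str, str]:
        lab = ["", ""]
        lab[self.foraging_state] = "foraging"
        lab[self.transiting_state] = "transiting"
        return tuple(lab)

    def relabelled(self) -> "HMMParams":
        """Canonical ordering: state 0 = foraging (smaller step mean)."""
        k = self.foraging_state
        if k == 0:
            return self
        sw = [1, 0]
        G = np.asarray(self.tmat)[np.ix_(sw, sw)]
        return HMMParams(
            step_mean=(self.step_mean[1], self.step_mean[0]),
            step_sd=(self.step_sd[1], self.step_sd[0]),
            turn_mean=(self.turn_mean[1], self.turn_mean[0]),
            turn_kappa=(self.turn_kappa[1], self.turn_kappa[0]),
            tmat=tuple(tuple(row) for row in G),
            delta=(self.delta[1], self.delta[0]),
        )

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({
                "step_mean": list(self.step_mean), "step_sd": list(self.step_sd),
                "turn_mean": list(self.turn_mean), "turn_kappa": list(self.turn_kappa),
                "tmat": [list(r) for r in self.tmat], "delta": list(self.delta),
            }, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "HMMParams":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            step_mean=tuple(d["step_mean"]), step_sd=tuple(d["step_sd"]),
            turn_mean=tuple(d["turn_mean"]), turn_kappa=tuple(d["turn_kappa"]),
            tmat=tuple(tuple(r) for r in d["tmat"]), delta=tuple(d["delta"]),
        )


@dataclass
class StateSequence:
    """Viterbi path (per step) and forward-backward posteriors."""

    states: np.ndarray          # (L,) most-likely state per step
    posteriors: np.ndarray      # (L, 2), rows sum to 1
    labels: tuple[str, str]


# --------------------------------------------------------------------------
# emissions & likelihood
# --------------------------------------------------------------------------

def _gamma_logpdf(s: np.ndarray, mean: float, sd: float) -> np.ndarray:
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return (shape - 1) * np.log(s) - s / scale - shape * math.log(scale) - gammaln(shape)


def _vonmises_logpdf(a: np.ndarray, mu: float, kappa: float) -> np.ndarray:
    # log I0(k) = log(i0e(k)) + k keeps large kappa stable
    return kappa * np.cos(a - mu) - math.log(_TWO_PI) - (np.log(i0e(kappa)) + kappa)


def _track_arrays(tracks: list[pd.DataFrame]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pack per-track steps/turns into padded (n_tracks, Lmax) arrays + mask.

    Tracks may carry precomputed ``step_m``/``turn_rad`` columns (rows 0 is
    NaN-step); otherwise they are derived from x/y.
    """
    from .track_processing import steps_and_turns

    steps_l, turns_l = [], []
    for df in tracks:
        if "step_m" in df.columns:
            s = df["step_m"].to_numpy(dtype=float)
            a = df["turn_rad"].to_numpy(dtype=float)
        else:
            s, a = steps_and_turns(df["x"].to_numpy(float), df["y"].to_numpy(float))
        ok = ~np.isnan(s)
        steps_l.append(np.maximum(s[ok], 1e-6))
        turns_l.append(a[ok])
    if not steps_l or max(len(s) for s in steps_l) < 2:
        raise ValueError("need at least one track with >= 3 fixes")
    Lmax = max(len(s) for s in steps_l)
    n = len(steps_l)
    S = np.ones((n, Lmax))
    A = np.full((n, Lmax), np.nan)
    M = np.zeros((n, Lmax), dtype=bool)
    for i, (s, a) in enumerate(zip(steps_l, turns_l)):
        S[i, :len(s)] = s
        A[i, :len(a)] = a
        M[i, :len(s)] = True
    return S, A, M


def _log_emissions(S: np.ndarray, A: np.ndarray, p: HMMParams) -> np.ndarray:
    """(n, L, 2) log emission densities; missing turns contribute 0."""
    out = np.empty(S.shape + (2,))
    for k in range(2):
        out[..., k] = _gamma_logpdf(S, p.step_mean[k], p.step_sd[k])
        turn = np.where(np.isnan(A), 0.0,
                        _vonmises_logpdf(np.nan_to_num(A), p.turn_mean[k],
                                         p.turn_kappa[k]))
        out[..., k] += turn
    return out


def _pooled_loglik(S: np.ndarray, A: np.ndarray, M: np.ndarray,
                   p: HMMParams) -> float:
    """Forward algorithm (scaled) pooled over independent tracks."""
    logB = _log_emissions(S, A, p)
    G = np.asarray(p.tmat)
    la = np.log(np.asarray(p.delta))[None, :] + logB[:, 0, :]
    for t in range(1, S.shape[1]):
        m = la.max(axis=1, keepdims=True)
        a = np.exp(la - m)
        la_new = m + np.log(np.clip(a @ G, 1e-300, None)) + logB[:, t, :]
        la = np.where(M[:, t, None], la_new, la)
    return float(logsumexp(la, axis=1).sum())


def forward_loglik(tracks: list[pd.DataFrame], params: HMMParams) -> float:
    """Pooled forward-algorithm log-likelihood of tracks under ``params``."""
    S, A, M = _track_arrays(tracks)
    return _pooled_loglik(S, A, M, params)


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def _theta_to_params(theta: np.ndarray) -> HMMParams:
    mu = np.exp(theta[0:2])
    sd = np.exp(theta[2:4])
    tm = np.arctan2(np.sin(theta[4:6]), np.cos(theta[4:6]))
    kp = np.exp(theta[6:8])
    stay = 1.0 / (1.0 + np.exp(-theta[8:10]))
    G = np.array([[stay[0], 1 - stay[0]], [1 - stay[1], stay[1]]])
    # stationary distribution of the 2-state chain
    d1 = (1 - stay[1]) / max((1 - stay[0]) + (1 - stay[1]), 1e-12)
    delta = np.array([d1, 1 - d1])
    return HMMParams(step_mean=tuple(mu), step_sd=tuple(sd),
                     turn_mean=tuple(tm), turn_kappa=tuple(kp),
                     tmat=tuple(tuple(r) for r in G), delta=tuple(delta))


def _moment_init(S: np.ndarray, M: np.ndarray) -> np.ndarray:
    s = S[M]
    med = np.median(s)
    lo, hi = s[s <= med], s[s > med]
    mu = [max(lo.mean(), 1e-3), max(hi.mean(), 1e-3)]
    sd = [max(lo.std(), 1e-3 * mu[0]), max(hi.std(), 1e-3 * mu[1])]
    return np.array([math.log(mu[0]), math.log(mu[1]),
                     math.log(sd[0]), math.log(sd[1]),
                     0.0, 0.0, math.log(1.0), math.log(1.0),
                     2.0, 2.0])


def fit_hmm(tracks: list[pd.DataFrame], n_states: int = 2,
            n_restarts: int = 10, seed: int | None = None,
            ) -> tuple[HMMParams, float]:
    """Maximum-likelihood two-state fit, best of ``n_restarts`` starts.

    Gamma step emissions are parameterized by (mean, SD); the initial state
    distribution is tied to the stationary distribution of the transition
    matrix.  Returned parameters are relabelled so state 0 is 'foraging'.
    """
    if n_states != 2:
        raise NotImplementedError("only the two-state model is supported")
    S, A, M = _track_arrays(tracks)
    if np.std(S[M]) < 1e-12:
        logger.warning("all step lengths identical: states unidentifiable")
    rng = np.random.default_rng(seed)

    def nll(theta: np.ndarray) -> float:
        if np.any(np.abs(theta) > 30):
            return 1e12
        try:
            ll = _pooled_loglik(S, A, M, _theta_to_params(theta))
        except (ValueError, FloatingPointError):
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll

    base = _moment_init(S, M)
    best = None
    for r in range(max(n_restarts, 1)):
        x0 = base if r == 0 else base + rng.normal(0, 0.5, size=base.size) * np.array(
            [1, 1, 1, 1, 2, 2, 1.5, 1.5, 1, 1])
        res = minimize(nll, x0=x0, method="L-BFGS-B",
                       options={"maxiter": 300})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e12 or not np.isfinite(best.fun):
        raise RuntimeError("HMM likelihood is NaN at every restart")
    params = _theta_to_params(best.x).relabelled()
    return params, -float(best.fun)


def fit_on_subset(tracks_by_year: dict, n_per_year: int = 10,
                  seed: int | None = None, n_restarts: int = 10,
                  ) -> tuple[HMMParams, float, dict]:
    """Fit the HMM to a reproducible random subset of tracks per year.

    Years with fewer than ``n_per_year`` tracks contribute all their tracks
    (logged).  Returns (params, loglik, chosen-index map).
    """
    rng = np.random.default_rng(seed)
    chosen: dict = {}
    pool: list[pd.DataFrame] = []
    for year in sorted(tracks_by_year):
        tr = tracks_by_year[year]
        if len(tr) <= n_per_year:
            if len(tr) < n_per_year:
                logger.warning("year %s has %d < %d tracks: taking all",
                               year, len(tr), n_per_year)
            idx = np.arange(len(tr))
        else:
            idx = rng.choice(len(tr), size=n_per_year, replace=False)
        chosen[year] = sorted(int(i) for i in idx)
        pool.extend(tr[i] for i in chosen[year])
    params, ll = fit_hmm(pool, seed=seed, n_restarts=n_restarts)
    return params, ll, chosen


# --------------------------------------------------------------------------
# decoding
# --------------------------------------------------------------------------

def decode(track: pd.DataFrame, params: HMMParams) -> StateSequence:
    """Viterbi most-likely path plus forward-backward posteriors (per step)."""
    S, A, M = _track_arrays([track])
    L = int(M[0].sum())
    logB = _log_emissions(S[:, :L], A[:, :L], params)[0]  # (L, 2)
    logG = np.log(np.asarray(params.tmat))
    logd = np.log(np.asarray(params.delta))

    # Viterbi
    v = logd + logB[0]
    back = np.zeros((L, 2), dtype=int)
    for t in range(1, L):
        cand = v[:, None] + logG
        back[t] = cand.argmax(axis=0)
        v = cand.max(axis=0) + logB[t]
    states = np.zeros(L, dtype=int)
    states[-1] = int(v.argmax())
    for t in range(L - 1, 0, -1):
        states[t - 1] = back[t, states[t]]

    # forward-backward
    la = np.zeros((L, 2))
    la[0] = logd + logB[0]
    for t in range(1, L):
        la[t] = logsumexp(la[t - 1][:, None] + logG, axis=0) + logB[t]
    lb = np.zeros((L, 2))
    for t in range(L - 2, -1, -1):
        lb[t] = logsumexp(logG + (logB[t + 1] + lb[t + 1])[None, :], axis=1)
    lp = la + lb
    lp -= logsumexp(lp, axis=1, keepdims=True)
    return StateSequence(states=states, posteriors=np.exp(lp),
                         labels=params.state_labels)


# --------------------------------------------------------------------------
# null-model simulation
# --------------------------------------------------------------------------

def simulate_hmm_track(params: HMMParams, n_fixes: int,
                       start: tuple[float, float],
                       land_polygon=None, interval_s: float = 300.0,
                       seed: int | None = None, max_attempts: int = 1000,
                       min_step_m: float = 1.0) -> pd.DataFrame:
    """Simulate one track from the fitted movement kernel, avoiding land.

    States follow the Markov chain; per fix the step is gamma and the turn von
    Mises for the current state.  The initial heading is uniform on (-pi, pi].
    A proposed fix falling on land triggers a redraw of step AND turn, up to
    ``max_attempts`` (then an error naming the fix index).  After 200 failed
    redraws the turn proposal broadens to uniform so a track pressed against
    the shore with a concentrated turn kernel still terminates; this distorts
    the kernel only in those rare stuck configurations.  Step lengths are
    floored at ``min_step_m`` so headings stay defined.
    """
    if n_fixes < 2:
        raise ValueError("need at least 2 fixes")
    if land_polygon is not None and bool(shapely.contains_xy(
            land_polygon, start[0], start[1])):
        raise ValueError("start position is on land")
    rng = np.random.default_rng(seed)
    shape = tuple((m / s) ** 2 for m, s in zip(params.step_mean, params.step_sd))
    scale = tuple(s * s / m for m, s in zip(params.step_mean, params.step_sd))
    G = np.asarray(params.tmat)
    x = np.empty(n_fixes)
    y = np.empty(n_fixes)
    states = np.zeros(n_fixes, dtype=int)
    x[0], y[0] = start
    heading = rng.uniform(-math.pi, math.pi)
    s = int(rng.choice(2, p=np.asarray(params.delta)))
    for i in range(1, n_fixes):
        if i > 1:
            s = int(rng.choice(2, p=G[s]))
        for attempt in range(max_attempts):
            step = max(float(rng.gamma(shape[s], scale[s])), min_step_m)
            if i == 1 or attempt >= 200:
                h_prop = rng.uniform(-math.pi, math.pi)
            else:
                turn = float(rng.vonmises(params.turn_mean[s], params.turn_kappa[s]))
                h_prop = heading + turn
            nx = x[i - 1] + step * math.cos(h_prop)
            ny = y[i - 1] + step * math.sin(h_prop)
            if land_polygon is None or not bool(
                    shapely.contains_xy(land_polygon, nx, ny)):
                break
        else:
            raise RuntimeError(f"land rejection exhausted at fix {i}")
        heading = h_prop
        x[i], y[i] = nx, ny
        states[i] = s
    states[0] = states[1]
    from .track_processing import steps_and_turns
    step_arr, turn_arr = steps_and_turns(x, y)
    return pd.DataFrame({
        "t": interval_s * np.arange(n_fixes), "x": x, "y": y,
        "state": states, "step_m": step_arr, "turn_rad": turn_arr,
        "simulated": True,
    })


def simulate_ensemble(params: HMMParams, n_tracks: int,
                      n_fixes_per_track, starts, land_polygon=None,
                      interval_s: float = 300.0, seed: int | None = None,
                      ) -> list[pd.DataFrame]:
    """Simulate an ensemble of null tracks.

    ``n_fixes_per_track`` may be an int or a pool of real-track lengths
    (sampled with replacement so the ensemble matches the empirical length
    distribution).  ``starts`` is one (x, y) or a pool of start points sampled
    the same way.  Per-track seeds derive from ``seed`` and are recorded in
    ``attrs['seed']``.
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = np.atleast_1d(np.asarray(n_fixes_per_track, dtype=int))
    starts_arr = np.atleast_2d(np.asarray(starts, dtype=float))
    out = []
    for i in range(n_tracks):
        L = int(lengths[rng.integers(0, lengths.size)])
        st = starts_arr[rng.integers(0, starts_arr.shape[0])]
        sub = int(rng.integers(0, 2**31 - 1))
        tr = simulate_hmm_track(params, L, (st[0], st[1]), land_polygon,
                                interval_s, seed=sub)
        tr.attrs["seed"] = sub
        tr.insert(0, "id", f"sim{i:05d}")
        out.append(tr)
    return out


def filter_in_domain(tracks: list[pd.DataFrame], survey_polygon,
                     max_outside_fraction: float = 0.20) -> list[pd.DataFrame]:
    """Keep tracks with at most ``max_outside_fraction`` of fixes outside the
    survey polygon (strictly-more-than removal)."""
    kept = []
    for tr in tracks:
        inside = shapely.contains_xy(survey_polygon,
                                     tr["x"].to_numpy(), tr["y"].to_numpy())
        if (1.0 - inside.mean()) <= max_outside_fraction + 1e-12:
            kept.append(tr)
    return kept
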