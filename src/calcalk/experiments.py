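"""End-to-end drivers for the feedback-shift and forcing-comparison runs.

These reproduce the headline numerical experiments: step and ramp changes
of the feedback strength gamma under a fixed periodic forcing, with the
resulting delayed re-locking quantified (transition delay, envelope time
constants), and staircase comparisons across forcing periods including a
two-component obliquity/precession mixture.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cycles import (CycleSeries, StaircaseResult, asymptotic_periodicity,
                     detect_cycles, staircase)
from .integrate import SolverSettings, Trajectory, simulate
from .model import GammaSchedule, ModelParameters, TABLE_DEFAULTS
from .stability import EnvelopeFit, envelope_time_constant

__all__ = [
    "StepExperimentResult",
    "step_experiment",
    "ramp_experiment",
    "forcing_comparison",
    "sustained_lock_start",
    "write_outputs",
]

log = logging.getLogger(__name__)

#: cycles that must consecutively sit within the lock tolerance to call a
#: lock "sustained" (operationalizes the visual settling criterion)
SUSTAINED_CYCLES = 20
LOCK_TOL_FRAC = 0.02


def sustained_lock_start(cycle_times: np.ndarray, periodicities: np.ndarray,
                         target: float, tol_frac: float = LOCK_TOL_FRAC,
                         run_length: int = SUSTAINED_CYCLES) -> float | None:
    """Time of the first cycle opening ``run_length`` consecutive cycles
    within ``tol_frac`` of ``target``; None if no such run exists."""
    ok = np.abs(periodicities - target) <= tol_frac * target
    if len(ok) < run_length:
        return None
    run = 0
    for i, flag in enumerate(ok):
        run = run + 1 if flag else 0
        if run == run_length:
            return float(cycle_times[i - run_length + 1])
    return None


@dataclass
class StepExperimentResult:
    """Outcome of a feedback-strength step or ramp experiment."""

    trajectory: Trajectory = field(repr=False)
    cycles: CycleSeries = field(repr=False)
    schedule: GammaSchedule
    alpha: float
    D_pre: float
    D_post: float
    pre_lock_n: int
    post_lock_n: int
    pre_locked: bool
    post_locked: bool
    transition_delay: float | None     # yr from t_c to sustained new lock
    censored: bool                     # no sustained post lock within horizon
    pre_decay_fit: EnvelopeFit | None
    post_growth_fit: EnvelopeFit | None
    post_decay_fit: EnvelopeFit | None
    intermediate_multiples: list = field(default_factory=list)

    def summary(self) -> dict:
        def fit_dict(f):
            return None if f is None else {
                "tau": f.tau, "asymptote": f.asymptote,
                "r_squared": f.r_squared, "ok": f.ok}

        return {
            "schedule": self.schedule.to_dict(),
            "alpha": self.alpha,
            "D_pre": self.D_pre, "D_post": self.D_post,
            "pre_lock_n": self.pre_lock_n, "post_lock_n": self.post_lock_n,
            "pre_locked": self.pre_locked, "post_locked": self.post_locked,
            "transition_delay": self.transition_delay, "censored": self.censored,
            "pre_decay_fit": fit_dict(self.pre_decay_fit),
            "post_growth_fit": fit_dict(self.post_growth_fit),
            "post_decay_fit": fit_dict(self.post_decay_fit),
            "intermediate_multiples": self.intermediate_multiples,
        }


def _tail_mean(x: np.ndarray, n: int = 50) -> float:
    return float(np.mean(x[-n:])) if len(x) else np.nan


def _try_envelope(cycles_t, cycles_p, asymptote, direction, **kw):
    try:
        return envelope_time_constant((cycles_t, cycles_p), asymptote, direction, **kw)
    except ValueError as exc:
        log.info("envelope fit skipped (%s %s): %s", direction, asymptote, exc)
        return None


def _analyze_transition(traj: Trajectory, schedule: GammaSchedule, alpha: float,
                        T_force: float, n_last: int = 50) -> StepExperimentResult:
    t_c = schedule.t_c
    t_end = t_c + (schedule.delta_t or 0.0) if schedule.kind == "ramp" else t_c
    cyc = detect_cycles(traj)
    tm = cyc.max_times[:-1]
    per = cyc.periodicities
    pre = tm < t_c
    post = ~pre
    D_pre = _tail_mean(per[pre], n_last)
    D_post = _tail_mean(per[post], n_last)
    n_pre = int(round(D_pre / T_force)) if np.isfinite(D_pre) else 0
    n_post = int(round(D_post / T_force)) if np.isfinite(D_post) else 0
    pre_locked = bool(np.isfinite(D_pre)
                      and abs(D_pre - n_pre * T_force) <= LOCK_TOL_FRAC * T_force)
    post_locked = bool(np.isfinite(D_post)
                       and abs(D_post - n_post * T_force) <= LOCK_TOL_FRAC * T_force)

    delay = None
    censored = True
    if n_post > 0:
        start = sustained_lock_start(tm[post], per[post], n_post * T_force)
        # the new lock must postdate the (end of the) gamma change
        if start is not None:
            delay = max(0.0, float(start) - t_c)
            censored = False

    pre_fit = None
    if pre.sum() >= 10 and n_pre > 0:
        pre_fit = _try_envelope(tm[pre], per[pre], n_pre * T_force, "decay")
    growth_fit = None
    if post.sum() >= 10 and n_pre > 0 and n_post != n_pre:
        growth_fit = _try_envelope(tm[post], per[post], n_pre * T_force, "growth",
                                   cap_deviation=T_force / 2.0)
    decay_fit = None
    if n_post > 0 and not censored:
        # fit from where the periodicity first comes within half a gap of
        # the new multiple (past the intermittent phase)
        close = np.abs(per - n_post * T_force) < T_force / 2.0
        cand = np.flatnonzero(post & close)
        if cand.size:
            w0 = tm[cand[0]]
            decay_fit = _try_envelope(tm[post & (tm >= w0)], per[post & (tm >= w0)],
                                      n_post * T_force, "decay")

    inter = []
    for n_mid in range(min(n_pre, n_post) + 1, max(n_pre, n_post)):
        s = sustained_lock_start(tm[post], per[post], n_mid * T_force)
        if s is not None:
            inter.append({"n": n_mid, "t_start": s})

    return StepExperimentResult(traj, cyc, schedule, alpha, D_pre, D_post,
                                n_pre, n_post, pre_locked, post_locked,
                                delay, censored, pre_fit, growth_fit, decay_fit,
                                inter)


def step_experiment(gamma1: float, gamma2: float, alpha: float = 0.003,
                    t_c: float = 5e7, horizon: float = 1.5e8,
                    params: ModelParameters = TABLE_DEFAULTS,
                    settings: SolverSettings | None = None,
                    init=None, n_last: int = 50) -> StepExperimentResult:
    """Instantaneous feedback-strength step under fixed periodic forcing.

    Simulates with gamma = gamma1 before ``t_c`` and gamma2 after, detects
    the locked multiples before and after, and measures the transition
    delay: the time from ``t_c`` until the first run of 20 consecutive
    cycles within 2% of the new locked periodicity.
    """
    p = params.with_(alpha=alpha)
    sched = GammaSchedule.step(gamma1, gamma2, t_c)
    traj = simulate(p, sched, (0.0, horizon), init=init, settings=settings)
    return _analyze_transition(traj, sched, alpha, p.T_force, n_last)


def ramp_experiment(gamma1: float, gamma2: float, alpha: float = 0.003,
                    t_c: float = 5e7, delta_t: float = 1e5,
                    horizon: float = 1.5e8,
                    params: ModelParameters = TABLE_DEFAULTS,
                    settings: SolverSettings | None = None,
                    init=None, n_last: int = 50) -> StepExperimentResult:
    """Linear feedback-strength ramp over [t_c, t_c + delta_t].

    Same analysis as :func:`step_experiment`; additionally reports whether
    any intermediate forcing multiple hosts a sustained lock on the way.
    """
    p = params.with_(alpha=alpha)
    sched = GammaSchedule.ramp(gamma1, gamma2, t_c, delta_t)
    traj = simulate(p, sched, (0.0, horizon), init=init, settings=settings)
    return _analyze_transition(traj, sched, alpha, p.T_force, n_last)


def forcing_comparison(params: ModelParameters, gamma_grid, alpha: float,
                       periods, mixture_weights=None, horizon: float = 1e8,
                       n_last: int = 50,
                       settings: SolverSettings | None = None) -> dict:
    """Average-duration staircases under different forcing periods.

    One staircase per entry of ``periods`` (single cosine of amplitude
    ``alpha``) plus, when ``mixture_weights`` is given, one for the
    weighted multi-component forcing k = k0 (1 + sum_i w_i alpha
    cos(2 pi t / T_i)).  Keys are ``"T=<period>"`` and ``"mixture"``.
    """
    results: dict[str, StaircaseResult] = {}
    for T in periods:
        p = params.with_(T_force=float(T))
        results[f"T={T:g}"] = staircase(p, gamma_grid, alpha, horizon=horizon,
                                        n_last=n_last, settings=settings)
    if mixture_weights is not None:
        w = list(mixture_weights)
        if len(w) != len(periods) or any(x < 0 for x in w):
            raise ValueError("mixture_weights must be non-negative, one per period")
        # the mixture lives entirely in extra_forcing (primary alpha = 0);
        # lock metadata is reported against the first period
        T1 = float(periods[0])
        p_mix = params.with_(T_force=T1, alpha=0.0,
                             extra_forcing=tuple((alpha * wi, float(Ti), 0.0)
                                                 for wi, Ti in zip(w, periods)))
        p_free = params.with_(alpha=0.0, extra_forcing=())
        grid = np.asarray(gamma_grid, float)
        m = grid.size
        T0 = np.full(m, np.nan)
        D = np.full(m, np.nan)
        conv0 = np.zeros(m, bool)
        convD = np.zeros(m, bool)
        below = np.zeros(m, bool)
        failures: list[tuple[float, str]] = []
        for i, g in enumerate(grid):
            try:
                est0 = asymptotic_periodicity(p_free, g, 0.0, horizon, n_last, settings)
                T0[i], conv0[i], below[i] = est0.value, est0.converged, est0.below_bifurcation
                estD = asymptotic_periodicity(p_mix, g, 0.0, horizon, n_last, settings)
                D[i], convD[i] = estD.value, estD.converged
            except Exception as exc:
                failures.append((float(g), repr(exc)))
        with np.errstate(invalid="ignore"):
            lock_n = np.where(np.isfinite(D), np.round(D / T1), 0).astype(int)
        lock_res = D - lock_n * T1
        locked = (np.abs(lock_res) <= LOCK_TOL_FRAC * T1) & np.isfinite(D)
        results["mixture"] = StaircaseResult(grid, T0, D, alpha, T1, lock_n,
                                             lock_res, locked, conv0, convD,
                                             below, failures)
    return results


def write_outputs(result: StepExperimentResult, outdir) -> None:
    """Write trajectory CSV, cycle CSV, and summary JSON for one experiment."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.trajectory.save_csv(outdir / "trajectory.csv")
    result.cycles.to_dataframe().to_csv(outdir / "cycles.csv", index=False,
                                        float_format="%.10g")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary(), fh, indent=2)
    log.info("experiment outputs written to %s", outdir)
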