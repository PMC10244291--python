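"""Sawtooth cycle metrics: periodicity, amplitude, and the Devil's staircase.

Periodicity is the time between successive local maxima of alkalinity and
amplitude the drop from a maximum to the following minimum.  Two headline
observables are built on these: the internal period T0 (asymptotic
periodicity of the unforced system) and the average duration D (asymptotic
periodicity under periodic forcing), both computed by running the model to
its long-term behaviour and averaging the final cycles.  Plotting D
against T0 over a grid of feedback strengths yields the frequency-locking
staircase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import linregress

from .integrate import SolverSettings, Trajectory, simulate
from .model import GammaSchedule, ModelParameters, hopf_threshold

__all__ = [
    "CycleSeries",
    "PeriodicityEstimate",
    "StaircaseResult",
    "detect_cycles",
    "asymptotic_periodicity",
    "staircase",
    "lock_multiple",
    "length_amplitude_fit",
    "LengthAmplitudeFit",
]


@dataclass
class CycleSeries:
    """Per-cycle metrics from the alkalinity extrema of one trajectory."""

    max_times: np.ndarray
    min_times: np.ndarray
    periodicities: np.ndarray
    amplitudes: np.ndarray

    @property
    def n_cycles(self) -> int:
        return len(self.periodicities)

    def to_dataframe(self):
        import pandas as pd

        n = self.n_cycles
        return pd.DataFrame({
            "max_time": self.max_times[:n],
            "periodicity": self.periodicities,
            "amplitude": self.amplitudes[:n],
        })


def _empty_cycles() -> CycleSeries:
    z = np.empty(0)
    return CycleSeries(z, z.copy(), z.copy(), z.copy())


def _alternate(idx_max: np.ndarray, idx_min: np.ndarray, A: np.ndarray):
    """Merge extrema indices enforcing strict max/min alternation.

    Where two extrema of the same kind are adjacent, the more extreme one
    is kept (higher for maxima, lower for minima).
    """
    events = [(i, 1) for i in idx_max] + [(i, -1) for i in idx_min]
    events.sort()
    kept: list[tuple[int, int]] = []
    for i, kind in events:
        if kept and kept[-1][1] == kind:
            j = kept[-1][0]
            better = (A[i] > A[j]) if kind == 1 else (A[i] < A[j])
            if better:
                kept[-1] = (i, kind)
        else:
            kept.append((i, kind))
    maxima = np.array([i for i, k in kept if k == 1], dtype=int)
    minima = np.array([i for i, k in kept if k == -1], dtype=int)
    return maxima, minima


def _refine_times(idx: np.ndarray, t: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Sub-grid extremum times by parabolic interpolation through 3 samples."""
    times = t[idx].astype(float)
    dt = t[1] - t[0]
    interior = (idx > 0) & (idx < len(A) - 1)
    ii = idx[interior]
    denom = A[ii - 1] - 2.0 * A[ii] + A[ii + 1]
    ok = denom != 0.0
    off = np.zeros(len(ii))
    off[ok] = 0.5 * (A[ii - 1] - A[ii + 1])[ok] / denom[ok]
    off = np.clip(off, -0.5, 0.5)
    times[interior] = t[ii] + off * dt
    return times


def detect_cycles(traj: Trajectory, prominence_frac: float = 0.01,
                  refine: bool = True) -> CycleSeries:
    """Locate alkalinity maxima/minima and derive per-cycle metrics.

    Extrema must have prominence >= ``prominence_frac`` times the overall
    alkalinity range, which rejects sub-percent ripple without touching
    sawtooth cycles.  Max/min alternation is enforced; each maximum is
    paired with the following minimum for the amplitude, and the trailing
    unmatched maximum is dropped.  With ``refine`` the extremum *times*
    are interpolated to sub-grid precision (amplitudes stay on-sample).
    """
    A, t = traj.A, traj.t
    rng = float(A.max() - A.min())
    if rng == 0.0:
        warnings.warn("constant trajectory: no cycles")
        return _empty_cycles()
    prom = prominence_frac * rng
    idx_max, _ = find_peaks(A, prominence=prom)
    idx_min, _ = find_peaks(-A, prominence=prom)
    if len(idx_max) < 2:
        warnings.warn(f"fewer than 2 alkalinity maxima found ({len(idx_max)})")
        return _empty_cycles()
    idx_max, idx_min = _alternate(idx_max, idx_min, A)

    max_times = _refine_times(idx_max, t, A) if refine else t[idx_max].astype(float)
    min_times = _refine_times(idx_min, t, A) if refine else t[idx_min].astype(float)
    periodicities = np.diff(max_times)

    # amplitude: each maximum minus the first following minimum
    amps = []
    j = 0
    for i, im in enumerate(idx_max):
        while j < len(idx_min) and idx_min[j] < im:
            j += 1
        if j >= len(idx_min):
            break
        amps.append(A[im] - A[idx_min[j]])
    return CycleSeries(max_times, min_times, periodicities, np.array(amps))


@dataclass
class PeriodicityEstimate:
    """Mean of the trailing cycle periodicities of a long run."""

    value: float
    spread: float            # max-min of the trailing periodicities (yr)
    n_cycles_used: int
    converged: bool          # trailing spread <= 5% of the mean
    below_bifurcation: bool  # gamma below the Hopf threshold: damped spiral
    gamma: float
    alpha: float
    cycles: CycleSeries = field(repr=False, default=None)


def asymptotic_periodicity(params: ModelParameters, gamma: float,
                           alpha: float = 0.0, horizon: float = 1e8,
                           n_last: int = 50,
                           settings: SolverSettings | None = None,
                           init=None, prominence_frac: float = 0.01,
                           traj: Trajectory | None = None) -> PeriodicityEstimate:
    """Run the model for ``horizon`` years and average the final cycles.

    With ``alpha = 0`` the result is the internal period T0; with
    ``alpha > 0`` it is the average duration D.  Convergence is diagnosed
    from the spread of the trailing periodicities (flagged, never hidden).
    An already computed trajectory may be passed via ``traj``.
    """
    p = params.with_(alpha=alpha)
    if traj is None:
        traj = simulate(p, GammaSchedule.constant(gamma), (0.0, horizon),
                        init=init, settings=settings)
    cyc = detect_cycles(traj, prominence_frac=prominence_frac)
    below = gamma < hopf_threshold(params)
    if cyc.n_cycles == 0:
        return PeriodicityEstimate(np.nan, np.nan, 0, False, below, gamma, alpha, cyc)
    tail = cyc.periodicities[-n_last:]
    value = float(tail.mean())
    spread = float(tail.max() - tail.min())
    converged = bool(spread <= 0.05 * value)
    return PeriodicityEstimate(value, spread, len(tail), converged, below, gamma, alpha, cyc)


def lock_multiple(D: float, T_force: float, tol_frac: float = 0.02) -> tuple[int, bool]:
    """Nearest forcing multiple of an average duration and whether it locks.

    ``n = round(D / T_force)``; locked iff |D - n T_force| <= tol_frac * T_force.
    """
    if not (D > 0 and T_force > 0):
        raise ValueError("D and T_force must be positive")
    n = int(round(D / T_force))
    locked = abs(D - n * T_force) <= tol_frac * T_force
    return n, locked


@dataclass
class StaircaseResult:
    """Internal period and average duration over a feedback-strength grid."""

    gamma_grid: np.ndarray
    T0: np.ndarray
    D: np.ndarray
    alpha: float
    T_force: float
    lock_n: np.ndarray            # nearest forcing multiple of D
    lock_residual: np.ndarray     # D - lock_n * T_force (yr)
    locked: np.ndarray            # within 2% of the multiple
    converged_T0: np.ndarray
    converged_D: np.ndarray
    below_bifurcation: np.ndarray
    failures: list = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "gamma": self.gamma_grid, "T0": self.T0, "D": self.D,
            "lock_n": self.lock_n, "lock_residual": self.lock_residual,
            "locked": self.locked, "converged_T0": self.converged_T0,
            "converged_D": self.converged_D,
            "below_bifurcation": self.below_bifurcation,
        })


def staircase(params: ModelParameters, gamma_grid, alpha: float,
              horizon: float = 1e8, n_last: int = 50,
              settings: SolverSettings | None = None,
              lock_tol_frac: float = 0.02) -> StaircaseResult:
    """T0 (alpha = 0) and D (given alpha) per grid point, with lock metadata.

    Per-point failures are recorded and the scan continues.  With
    ``alpha = 0`` the staircase degenerates to the diagonal D = T0.
    """
    gamma_grid = np.asarray(gamma_grid, float)
    m = gamma_grid.size
    T0 = np.full(m, np.nan)
    D = np.full(m, np.nan)
    conv0 = np.zeros(m, bool)
    convD = np.zeros(m, bool)
    below = np.zeros(m, bool)
    failures: list[tuple[float, str]] = []
    for i, g in enumerate(gamma_grid):
        try:
            est0 = asymptotic_periodicity(params, g, 0.0, horizon, n_last, settings)
            T0[i], conv0[i], below[i] = est0.value, est0.converged, est0.below_bifurcation
            if alpha == 0.0:
                D[i], convD[i] = est0.value, est0.converged
            else:
                estD = asymptotic_periodicity(params, g, alpha, horizon, n_last, settings)
                D[i], convD[i] = estD.value, estD.converged
        except Exception as exc:  # per-point failure: record, keep scanning
            failures.append((float(g), repr(exc)))
    with np.errstate(invalid="ignore"):
        lock_n = np.where(np.isfinite(D), np.round(D / params.T_force), 0).astype(int)
    lock_res = D - lock_n * params.T_force
    locked = np.abs(lock_res) <= lock_tol_frac * params.T_force
    locked &= np.isfinite(D)
    return StaircaseResult(gamma_grid, T0, D, alpha, params.T_force, lock_n,
                           lock_res, locked, conv0, convD, below, failures)


@dataclass
class LengthAmplitudeFit:
    slope: float
    intercept: float
    r_squared: float
    degenerate: bool
    n_points: int


def length_amplitude_fit(cycles) -> LengthAmplitudeFit:
    """Least-squares line of cycle amplitude versus cycle length.

    ``cycles`` is one :class:`CycleSeries` or a list of them (pooled over
    runs).  A locked single-gamma run has essentially constant coordinates
    and is flagged degenerate (coefficient of variation < 1e-3 in either
    coordinate) rather than fitted.
    """
    if isinstance(cycles, CycleSeries):
        cycles = [cycles]
    per = np.concatenate([c.periodicities[:len(c.amplitudes)] for c in cycles])
    amp = np.concatenate([c.amplitudes[:len(c.periodicities)] for c in cycles])
    n = min(len(per), len(amp))
    per, amp = per[:n], amp[:n]
    if n < 5:
        raise ValueError(f"need at least 5 complete cycles, got {n}")
    degen = (np.std(per) < 1e-3 * abs(np.mean(per))
             or np.std(amp) < 1e-3 * abs(np.mean(amp)))
    if degen:
        return LengthAmplitudeFit(np.nan, np.nan, np.nan, True, n)
    fit = linregress(per, amp)
    return LengthAmplitudeFit(float(fit.slope), float(fit.intercept),
                              float(fit.rvalue ** 2), False, n)
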