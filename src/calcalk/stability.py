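"""Locked periodic orbits, Floquet multipliers, envelope fits, chaos indicator.

A frequency-locked state of the forced system is a fixed point of the
n-period stroboscopic map.  Newton iteration on that map (with the
monodromy matrix of the variational flow as the map Jacobian) locates
stable and unstable orbits alike; the monodromy eigenvalues (Floquet
multipliers) convert to e-folding time constants that can be compared
with exponential fits to the envelope of the per-cycle periodicity during
transients.  A Benettin-style tangent-vector iteration provides the
largest Lyapunov exponent as a chaos indicator.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import linregress

from .cycles import CycleSeries
from .integrate import SolverSettings, propagate_variational, _augmented_rhs, _solve_segment
from .model import ModelParameters, SystemState

__all__ = [
    "PeriodicOrbit",
    "FloquetResult",
    "EnvelopeFit",
    "find_periodic_orbit",
    "floquet_multipliers",
    "envelope_time_constant",
    "largest_lyapunov",
]

#: Tight default tolerances: locked-orbit multipliers sit within ~1% of the
#: unit circle, so the monodromy must be accurate to much better than that.
ORBIT_SETTINGS = SolverSettings(rel_tol=1e-12, abs_tol=1e-13)


@dataclass
class PeriodicOrbit:
    """A locked orbit of the forced system, anchored at forcing phase 0."""

    state0: SystemState
    n: int
    period: float           # n * T_force (yr)
    residual: float         # closure error of the stroboscopic map (state units)
    stable: bool

    def to_json(self) -> str:
        d = {"A": self.state0.A, "P": self.state0.P, "n": self.n,
             "period": self.period, "residual": self.residual, "stable": self.stable}
        return json.dumps(d)


@dataclass
class FloquetResult:
    """Monodromy eigenvalues of a locked orbit and derived time constants."""

    multipliers: np.ndarray      # pair of (possibly complex) eigenvalues
    exponents: np.ndarray        # ln|mu| / period (yr^-1)
    time_constant: float         # e-folding time |period / ln|mu_dominant|| (yr)
    direction: str               # "decay" | "growth"
    period: float
    liouville_rel_err: float     # |det Phi - exp(int tr J)| / |det Phi|
    degenerate: bool             # near-defective eigenpair flagged

    def to_json(self) -> str:
        d = {"multipliers_re": list(self.multipliers.real),
             "multipliers_im": list(self.multipliers.imag),
             "exponents": list(self.exponents),
             "time_constant": self.time_constant, "direction": self.direction,
             "period": self.period, "liouville_rel_err": self.liouville_rel_err}
        return json.dumps(d)


class OrbitSearchError(RuntimeError):
    """Newton iteration on the stroboscopic map failed to close an orbit."""

    def __init__(self, message: str, last_residual: float):
        super().__init__(message)
        self.last_residual = last_residual


def _strobe_with_jacobian(x: np.ndarray, params: ModelParameters, gamma: float,
                          n: int, settings: SolverSettings):
    Phi, final, _ = propagate_variational(
        SystemState(float(x[0]), float(x[1])), params, gamma,
        n * params.T_force, settings=settings, return_details=True)
    return final.as_array(), Phi


def find_periodic_orbit(params: ModelParameters, gamma: float, n: int,
                        seed_state: SystemState,
                        settings: SolverSettings | None = None,
                        tol: float = 1e-10, max_iter: int = 30) -> PeriodicOrbit:
    """Newton search for a fixed point of the n-period stroboscopic map.

    Converges to stable and unstable orbits alike given a seed reasonably
    close to one (a state from a converged long run, or a previously found
    orbit when continuing in gamma).  The forcing phase is 0 at the orbit
    anchor.  Raises :class:`OrbitSearchError` on divergence.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    settings = settings or ORBIT_SETTINGS
    x = seed_state.as_array()
    res = np.inf
    for _ in range(max_iter):
        Fx, Phi = _strobe_with_jacobian(x, params, gamma, n, settings)
        r = Fx - x
        res = float(np.max(np.abs(r)))
        if res < tol:
            mu = np.linalg.eigvals(Phi)
            return PeriodicOrbit(SystemState(float(x[0]), float(x[1])), n,
                                 n * params.T_force, res,
                                 bool(np.all(np.abs(mu) < 1.0)))
        try:
            dx = np.linalg.solve(Phi - np.eye(2), -r)
        except np.linalg.LinAlgError as exc:
            raise OrbitSearchError(f"singular map Jacobian: {exc}", res) from exc
        if not np.all(np.isfinite(dx)):
            raise OrbitSearchError("non-finite Newton step", res)
        x = x + dx
    raise OrbitSearchError(
        f"no convergence after {max_iter} Newton iterations (residual {res:.3e})", res)


def floquet_multipliers(orbit: PeriodicOrbit, params: ModelParameters, gamma: float,
                        settings: SolverSettings | None = None,
                        residual_tol: float = 1e-8) -> FloquetResult:
    """Floquet multipliers and e-folding time constant of a locked orbit.

    The monodromy matrix is the variational flow over one orbit period;
    its determinant is cross-checked against the Liouville identity
    ``det Phi = exp(integral of tr J)``.
    """
    if orbit.residual > residual_tol:
        raise ValueError(
            f"orbit residual {orbit.residual:.3e} exceeds tolerance {residual_tol:g}")
    settings = settings or ORBIT_SETTINGS
    Phi, _, tr_int = propagate_variational(orbit.state0, params, gamma,
                                           orbit.period, settings=settings,
                                           return_details=True)
    mu = np.linalg.eigvals(Phi)
    det = float(np.linalg.det(Phi))
    liouville = abs(det - math.exp(tr_int)) / abs(det)
    mods = np.abs(mu)
    dominant = float(np.max(mods))
    if math.isclose(dominant, 1.0, rel_tol=0.0, abs_tol=1e-14):
        raise ValueError("dominant multiplier is exactly on the unit circle")
    exponents = np.log(mods) / orbit.period
    time_constant = abs(orbit.period / math.log(dominant))
    direction = "decay" if dominant < 1.0 else "growth"
    # a real pair with nearly equal moduli and non-orthogonal eigenvectors
    # signals a near-defective monodromy
    degenerate = bool(np.all(mu.imag == 0.0)
                      and abs(mods[0] - mods[1]) < 1e-10 * dominant)
    if degenerate:
        warnings.warn("near-degenerate Floquet multipliers")
    return FloquetResult(mu, exponents, time_constant, direction,
                         orbit.period, liouville, degenerate)


@dataclass
class EnvelopeFit:
    """Exponential fit to the envelope of periodicity deviations."""

    tau: float               # e-folding time (yr)
    asymptote: float         # target periodicity (yr)
    r_squared: float
    window: tuple            # time range of the envelope points used (yr)
    direction: str
    n_points: int
    ok: bool                 # exponential regime found (sign and fit quality)

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def envelope_time_constant(cycles: CycleSeries, asymptote: float,
                           direction: str = "decay",
                           window: tuple[float, float] | None = None,
                           cap_deviation: float | None = None,
                           floor_frac: float = 0.1,
                           min_points: int = 5) -> EnvelopeFit:
    """Fit an exponential to the envelope of |periodicity - asymptote|.

    The envelope is taken as the local maxima of the absolute deviation of
    the per-cycle periodicity versus time, and log-deviation is fitted
    linearly in time; tau is the e-folding time (positive for both
    directions).  For a decay the window defaults to [envelope maximum,
    point where 10% of the initial deviation remains]; for a growth the
    fit is capped where the deviation exceeds ``cap_deviation`` (half the
    inter-multiple gap is a sensible cap).  A non-exponential envelope is
    flagged via ``ok=False``, never silently fitted away.
    """
    if direction not in ("decay", "growth"):
        raise ValueError("direction must be 'decay' or 'growth'")
    if isinstance(cycles, CycleSeries):
        per = cycles.periodicities
        t = cycles.max_times[:len(per)]
    else:  # bare (times, periodicities) arrays
        t, per = (np.asarray(a, float) for a in cycles)
    dev = np.abs(per - asymptote)
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        t, dev = t[sel], dev[sel]
    idx, _ = find_peaks(dev)
    te, de = t[idx], dev[idx]
    pos = de > 0
    te, de = te[pos], de[pos]
    if direction == "decay" and window is None and len(de):
        i0 = int(np.argmax(de))
        te, de = te[i0:], de[i0:]
        keep = de >= floor_frac * de[0]
        # keep the contiguous leading stretch above the floor
        stop = np.argmin(keep) if not keep.all() else len(keep)
        te, de = te[:stop], de[:stop]
    if direction == "growth" and cap_deviation is not None and len(de):
        over = de > cap_deviation
        stop = np.argmax(over) if over.any() else len(de)
        te, de = te[:stop], de[:stop]
    if len(de) < min_points:
        raise ValueError(
            f"need >= {min_points} envelope points in the window, got {len(de)}")
    fit = linregress(te, np.log(de))
    slope = float(fit.slope)
    r2 = float(fit.rvalue ** 2)
    wanted_sign = -1.0 if direction == "decay" else 1.0
    ok = (slope * wanted_sign > 0.0) and r2 >= 0.5
    if not ok:
        warnings.warn(
            f"envelope not in an exponential {direction} regime "
            f"(slope {slope:.3e}, r^2 {r2:.3f})")
    tau = abs(1.0 / slope) if slope != 0.0 else np.inf
    return EnvelopeFit(tau, asymptote, r2, (float(te[0]), float(te[-1])),
                       direction, len(de), bool(ok))


def largest_lyapunov(params: ModelParameters, gamma: float, alpha: float,
                     horizon: float, settings: SolverSettings | None = None,
                     init: SystemState | None = None,
                     renorm_period: float | None = None,
                     transient_frac: float = 0.2) -> float:
    """Largest Lyapunov exponent (yr^-1) by tangent-vector renormalization.

    Propagates a tangent vector along the forced trajectory, renormalizing
    once per forcing period (Benettin's method) and discarding the first
    ``transient_frac`` of the horizon.  Negative in locked or damped
    regimes, positive in the chaotic regime of strong forcing.
    """
    from .integrate import default_initial_state

    settings = settings or SolverSettings(rel_tol=1e-10, abs_tol=1e-12)
    if init is None:
        init = default_initial_state(params, gamma)
    p = params.with_(alpha=alpha)
    T = renorm_period or p.T_force
    n_seg = int(np.ceil(horizon / T))
    if n_seg < 5:
        raise ValueError("horizon must cover several forcing periods")
    f = _augmented_rhs(p, gamma)
    y = np.array([init.A, init.P, 1.0, 0.0, 0.0, 0.0, 0.0])
    n_trans = int(transient_frac * n_seg)
    total = 0.0
    history = []
    for i in range(n_seg):
        sol = _solve_segment(f, i * T, (i + 1) * T, y, None, settings)
        y = sol.y[:, -1]
        v = y[2:4]
        norm = float(np.hypot(v[0], v[1]))
        y[2:4] = v / norm
        y[4:] = 0.0
        if i >= n_trans:
            total += math.log(norm)
            history.append(total / ((i - n_trans + 1) * T))
    est = history[-1]
    if len(history) >= 10:
        tail = np.array(history[len(history) // 2:])
        scale = max(abs(est), 1e-12)
        if np.max(np.abs(tail - est)) > 0.5 * scale + 1e-7:
            warnings.warn(
                f"Lyapunov running estimate not settled (last {est:.3e} yr^-1)")
    return float(est)
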