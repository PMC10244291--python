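"""Synthetic waveform builders used as ground-truth fixtures."""

import numpy as np

from calcalk import Trajectory


def make_trajectory(t: np.ndarray, A: np.ndarray) -> Trajectory:
    return Trajectory(t, A, np.zeros_like(A), np.zeros_like(A), {"synthetic": True})


def sawtooth(period: float = 4e4, amplitude: float = 0.4, n_cycles: int = 12,
             dt: float = 100.0, rise_frac: float = 0.8) -> Trajectory:
    """Asymmetric sawtooth with grid-aligned maxima: slow rise, fast fall."""
    t = np.arange(0.0, n_cycles * period + dt, dt)
    phase = (t % period) / period
    A = np.where(phase <= rise_frac,
                 amplitude * phase / rise_frac,
                 amplitude * (1.0 - phase) / (1.0 - rise_frac))
    # shift so maxima (phase == rise_frac) sit exactly on grid points
    shift = int(round(rise_frac * period / dt)) * dt - rise_frac * period
    assert abs(shift) < 1e-9, "choose rise_frac so the peak is grid-aligned"
    return make_trajectory(t, A + 2.0)


def sinusoid(period: float = 4e4, half_amplitude: float = 0.2,
             n_cycles: int = 10, dt: float = 100.0) -> Trajectory:
    t = np.arange(0.0, n_cycles * period + dt, dt)
    return make_trajectory(t, 2.0 + half_amplitude * np.cos(2 * np.pi * t / period))
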