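"""Direction-selective complex-cell responses via opponent motion energy.

The front end is the classical quadrature construction: oriented Gabor pairs
(even/odd phase) define the spatial profile, two multi-stage low-pass kernels
with different stage counts (fast n=6, slow n=9) define the temporal profile,
and the four separable space-time filters per orientation combine into two
energies selective for opposite directions.  Opponent subtraction and
rectification yield one non-negative map per direction; responses are
normalised against the peak response to a full-contrast calibration bar
drifting at the configured reference speed, so complex-cell activity is a
bounded quantity in [0, 1] suitable as input to the rate dynamics downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage, signal

from .config import DirectionSet, ModelConfig
from .stimuli import BarSpec, StimulusMovie, render_crossing_bars

__all__ = ["temporal_kernel", "SpatioTemporalBank", "build_bank", "motion_energy"]


def temporal_kernel(n: int, tau_g: float, t_grid: np.ndarray) -> np.ndarray:
    """Multi-stage low-pass temporal filter g_n(t) sampled on ``t_grid``.

    g_n(t) = (t/tau)^n exp(-t/tau) [1/n! - (t/tau)^2/(n+2)!]

    The kernel vanishes at t=0, is biphasic (its sign flips where the bracket
    crosses zero, at t = tau*sqrt((n+2)!/n!)), and decays to zero for large t.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if tau_g <= 0:
        raise ValueError("tau_g must be positive")
    t = np.asarray(t_grid, dtype=float)
    if (t < 0).any():
        raise ValueError("temporal kernel is causal: t_grid must be >= 0")
    s = t / tau_g
    return s**n * np.exp(-s) * (1.0 / math.factorial(n)
                                - s**2 / math.factorial(n + 2))


def gabor_pair(orientation_deg: float, f_pix: float, sigma_x: float,
               sigma_y: float, support: Optional[int] = None
               ) -> Tuple[np.ndarray, np.ndarray]:
    """Quadrature Gabor pair with carrier varying along ``orientation_deg``.

    ``orientation_deg`` here is the axis of carrier modulation, i.e. the
    direction of preferred motion; the envelope's sigma_x lies along it.
    Returns (even, odd) kernels on a square support.
    """
    if support is None:
        support = int(math.ceil(3.0 * max(sigma_x, sigma_y)))
    ax = np.arange(-support, support + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)  # xx: columns (x), yy: rows (y)
    th = np.deg2rad(orientation_deg)
    u = xx * np.cos(th) + yy * np.sin(th)    # along motion
    v = -xx * np.sin(th) + yy * np.cos(th)   # along the contour
    env = np.exp(-(u**2 / (2 * sigma_x**2) + v**2 / (2 * sigma_y**2)))
    even = env * np.cos(2 * np.pi * f_pix * u)
    odd = env * np.sin(2 * np.pi * f_pix * u)
    even -= even.mean()  # zero-mean: no response to uniform luminance
    return even, odd


@dataclass
class SpatioTemporalBank:
    """Spatial Gabor pairs per carrier axis plus the two temporal kernels.

    Opposite directions share spatial kernels (orientation has period 180);
    they are told apart by the temporal phase of the quadrature combination.
    """

    directions: DirectionSet
    gabor_even: Dict[int, np.ndarray]   # keyed by axis index (direction mod 180)
    gabor_odd: Dict[int, np.ndarray]
    g_fast: np.ndarray
    g_slow: np.ndarray
    dt_frame: float
    calib_speed: float = 15.0
    _calibration: Optional[float] = None

    @property
    def n_taps(self) -> int:
        return len(self.g_fast)

    def calibration(self, shape=(48, 48)) -> float:
        """Peak raw opponent energy for a drifting full-contrast calibration bar.

        Computed once per bank and cached; every movie is normalised by this
        constant so responses are comparable across stimuli and contrasts.
        """
        if self._calibration is None:
            bar = BarSpec(orientation=135.0, direction=0.0, speed=self.calib_speed,
                          length=60.0, width=3.0, contrast=1.0,
                          center=(shape[0] / 2.0, shape[1] / 2.0 - 6.0))
            ghost = BarSpec(orientation=45.0, direction=180.0, speed=self.calib_speed,
                            length=60.0, width=3.0, contrast=0.0,
                            center=(shape[0] / 2.0, shape[1] / 2.0))
            n_frames = self.n_taps + 8
            movie = render_crossing_bars(bar, ghost, shape, n_frames, self.dt_frame)
            raw = _raw_opponent_energy(movie, self)
            peak = float(raw.max())
            if peak <= 0:
                raise RuntimeError("calibration stimulus evoked no energy")
            self._calibration = peak
        return self._calibration


def build_bank(config: ModelConfig, dt_frame: float,
               n_taps: Optional[int] = None) -> SpatioTemporalBank:
    """Assemble the spatiotemporal filter bank for all model directions.

    The temporal kernels are sampled at the frame interval over a support long
    enough to include both biphasic lobes of the slow (n=9) kernel.
    """
    dirs = config.directions()
    f_pix = config.f_pix
    sx = config.sigma_pix("sigma_x")
    sy = config.sigma_pix("sigma_y")
    even, odd = {}, {}
    n_axes = dirs.n_dir // 2
    for a in range(n_axes):
        even[a], odd[a] = gabor_pair(dirs.angles[a], f_pix, sx, sy)
    if n_taps is None:
        # cover ~2.3x the slow kernel's zero-crossing time
        t_max = 2.3 * config.tau_g * math.sqrt(
            math.factorial(config.n_slow + 2) / math.factorial(config.n_slow))
        n_taps = int(math.ceil(t_max / dt_frame)) + 1
    if n_taps < 3:
        raise ValueError("temporal kernel support shorter than 3 frames; "
                         "decrease dt_frame")
    t_grid = np.arange(n_taps) * dt_frame
    g_fast = temporal_kernel(config.n_fast, config.tau_g, t_grid)
    g_slow = temporal_kernel(config.n_slow, config.tau_g, t_grid)
    return SpatioTemporalBank(dirs, even, odd, g_fast, g_slow, dt_frame)


def _causal_filter(kernel: np.ndarray, x: np.ndarray) -> np.ndarray:
    """FIR filtering along axis 0 with zero initial history."""
    return signal.lfilter(kernel, [1.0], x, axis=0)


def _raw_opponent_energy(movie: StimulusMovie, bank: SpatioTemporalBank
                         ) -> np.ndarray:
    """Unnormalised opponent energy, shape (time, y, x, n_dir)."""
    I = movie.reversed_intensity()
    dirs = bank.directions
    n_axes = dirs.n_dir // 2
    T, H, W = I.shape
    out = np.zeros((T, H, W, dirs.n_dir))
    for a in range(n_axes):
        Se = np.empty_like(I)
        So = np.empty_like(I)
        for k in range(T):
            Se[k] = ndimage.convolve(I[k], bank.gabor_even[a], mode="nearest")
            So[k] = ndimage.convolve(I[k], bank.gabor_odd[a], mode="nearest")
        ef = _causal_filter(bank.g_fast, Se)
        of = _causal_filter(bank.g_fast, So)
        es = _causal_filter(bank.g_slow, Se)
        os_ = _causal_filter(bank.g_slow, So)
        # quadrature pairs for the two opposed directions along this axis
        e_pos = (ef + os_) ** 2 + (of - es) ** 2
        e_neg = (ef - os_) ** 2 + (of + es) ** 2
        # sign convention fixed so that direction index a prefers motion
        # toward angle dirs.angles[a] (verified on drifting-bar fixtures)
        out[..., a] = np.maximum(e_pos - e_neg, 0.0)
        out[..., dirs.opposite(a)] = np.maximum(e_neg - e_pos, 0.0)
    return out


def motion_energy(movie: StimulusMovie, bank: SpatioTemporalBank) -> np.ndarray:
    """Complex-cell activity v_cx, shape (time, y, x, n_dir), values in [0, 1].

    Opponent energy divided by the bank's calibration peak and clipped to the
    activity range.  A static movie yields zero everywhere (opponent
    subtraction cancels the temporally unmodulated response).
    """
    if movie.n_frames < 3:
        raise ValueError("movie too short for temporal filtering")
    if movie.dt_frame != bank.dt_frame:
        raise ValueError("movie and bank disagree on the frame interval")
    raw = _raw_opponent_energy(movie, bank)
    return np.clip(raw / bank.calibration(), 0.0, 1.0)
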