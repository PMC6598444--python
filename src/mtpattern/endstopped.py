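"""End-stopped V1 cells: complex-cell drive minus thresholded lateral inhibition.

An end-stopped unit is driven by the complex cell at its own location and
direction through a shunting excitation, and inhibited by the Gaussian-weighted
activity of same-direction complex cells across a surrounding patch — but only
where the local neighbourhood is active above a threshold.  Along an extended
moving edge, many neighbours are active, the inhibition is strong, and the unit
is silenced; at a line ending (terminator), the patch is half empty and
activity survives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .config import ModelConfig

__all__ = ["inhibition_kernel", "lateral_inhibition", "endstopped_step",
           "run_endstopped", "EndStoppedDynamics"]


def inhibition_kernel(radius: int = 8, hole: int = 3) -> np.ndarray:
    """Discretised Gaussian inhibition weights over a (2r+1)^2 patch.

    sigma = radius / 2, peak weight 1/sigma, and the inner +-``hole`` square
    (the gate neighbourhood) carries no weight: inhibition is recruited from
    the patch *around* the immediate neighbourhood.  A compact terminator
    blob, no wider than the hole, therefore barely inhibits itself, while an
    extended contour reaches far into the patch and accumulates inhibition
    several times the direct excitatory drive — the contrast end-stopping
    lives on.  The 1/sigma peak keeps the summed weight growing linearly
    (~2 pi sigma) rather than quadratically with patch size.
    """
    if hole >= radius:
        raise ValueError("hole must be smaller than the patch radius")
    sigma = radius / 2.0
    ax = np.arange(-radius, radius + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    mu = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2)) / sigma
    mu[(np.abs(xx) <= hole) & (np.abs(yy) <= hole)] = 0.0
    return mu


def lateral_inhibition(v_cx: np.ndarray, mu: np.ndarray, rho_cx: float,
                       gate_radius: int = 3) -> np.ndarray:
    """Gated inhibition field Gamma for one time point.

    v_cx : (y, x, n_dir) complex-cell activity in [0, 1].
    At each location and direction, Gamma is the mu-weighted sum of
    same-direction complex activity over the patch, switched on only where
    the maximum same-direction complex activity within the inner
    +-gate_radius neighbourhood exceeds rho_cx, and zero otherwise.
    """
    if v_cx.ndim != 3:
        raise ValueError("v_cx must be (y, x, n_dir)")
    out = np.empty_like(v_cx)
    size = 2 * gate_radius + 1
    for d in range(v_cx.shape[-1]):
        sl = v_cx[..., d]
        gate = ndimage.maximum_filter(sl, size=size, mode="nearest") > rho_cx
        out[..., d] = gate * ndimage.convolve(sl, mu, mode="nearest")
    return out


def endstopped_step(v_es: np.ndarray, v_cx: np.ndarray, gamma: np.ndarray,
                    config: ModelConfig, dt: Optional[float] = None) -> np.ndarray:
    """One forward-Euler step of the end-stopped shunting dynamics.

    dv/dt = (1 - v) * G_escx1 * v_cx  -  v * (tau_es + G_escx2 * Gamma)

    The shunting form keeps v in [0, 1] for bounded inputs; the state is
    clipped after the step as a numerical safeguard.
    """
    dt = config.dt if dt is None else dt
    if dt <= 0:
        raise ValueError("dt must be positive")
    dv = (1.0 - v_es) * (config.G_escx1 * v_cx) \
        - v_es * (config.tau_es + config.G_escx2 * gamma)
    return np.clip(v_es + dt * dv, 0.0, 1.0)


@dataclass
class EndStoppedDynamics:
    """Stateful stepping of the end-stopped population for a simulation run."""

    config: ModelConfig

    def __post_init__(self) -> None:
        self.mu = inhibition_kernel(self.config.es_inhib_radius,
                                    hole=self.config.es_gate_radius)
        self.v_es: Optional[np.ndarray] = None

    def step(self, v_cx: np.ndarray, gamma: Optional[np.ndarray] = None
             ) -> np.ndarray:
        if self.v_es is None:
            self.v_es = np.zeros_like(v_cx)
        if gamma is None:
            gamma = lateral_inhibition(v_cx, self.mu, self.config.c_cx,
                                       self.config.es_gate_radius)
        self.v_es = endstopped_step(self.v_es, v_cx, gamma, self.config)
        return self.v_es


def run_endstopped(v_cx_traj: np.ndarray, config: ModelConfig,
                   n_settle: int = 0,
                   mask: Optional[np.ndarray] = None) -> np.ndarray:
    """End-stopped trajectory for a complex-cell trajectory (time, y, x, dir).

    One Euler step per frame; if ``n_settle`` > 0 the final complex frame is
    held while the dynamics run an additional ``n_settle`` steps (the lateral
    inhibition field is then computed once and reused).  ``mask`` is an
    occlusion mask (y, x): the excitatory drive is zeroed outside it, while
    the lateral inhibition still pools the unmasked complex field, so a mask
    boundary never looks like a line ending.  Returns the trajectory
    including settle steps.
    """
    dyn = EndStoppedDynamics(config)
    T = v_cx_traj.shape[0]
    m = None if mask is None else mask[..., None]
    out = np.empty((T + n_settle,) + v_cx_traj.shape[1:], dtype=float)
    for k in range(T):
        gamma = lateral_inhibition(v_cx_traj[k], dyn.mu, config.c_cx,
                                   config.es_gate_radius)
        drive = v_cx_traj[k] if m is None else v_cx_traj[k] * m
        out[k] = dyn.step(drive, gamma)
    if n_settle > 0:
        last = v_cx_traj[-1]
        gamma = lateral_inhibition(last, dyn.mu, config.c_cx,
                                   config.es_gate_radius)
        drive = last if m is None else last * m
        for k in range(n_settle):
            out[T + k] = dyn.step(drive, gamma)
    return out
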