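"""The recurrent MT stage: integration and segmentation populations.

Integration units propagate unambiguous terminator motion across the network
through facilitatory same-direction surrounds; segmentation units, with
antagonistic surrounds, flag motion discontinuities and keep the propagation
from crossing object borders.  Both populations are rate units stepped with
forward Euler; the growth rate passes through the saturating nonlinearity h,
so activity rises toward a gain-dependent equilibrium and inhibition acts by
stalling growth.

Lateral interaction terms (all Gaussian-weighted, thresholded sums):

==========  =================================================================
lambda      same-direction excitation from the MT centre neighbourhood
gamma       inter-directional inhibition at the same location (delayed)
zeta        long-range same-direction inhibition from the surround annulus
            (delayed)
eta         direction-pooled integration drive onto segmentation units
chi_e/chi_i surround segmentation activity in the same / opposite direction
==========  =================================================================

Centre kernels span the MT classical receptive field (seven V1 lattice steps
across); annulus kernels span the surround (ten across).  Each kernel is
normalised to unit mass so every lateral term lives on the same [0, 1] scale
as the direct V1 drives and the printed gain table applies unchanged.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .config import DirectionSet, ModelConfig, saturate
from .ecrf import dog_kernel, ecrf_response, gate_motion
from .endstopped import EndStoppedDynamics, lateral_inhibition
from .motion_energy import build_bank, motion_energy
from .stimuli import StimulusMovie

__all__ = ["mt_kernels", "lateral_terms", "MTState", "mt_step",
           "simulate", "SimulationResult"]


def _gaussian_disc(radius: float, exclude_center: bool = False) -> np.ndarray:
    """Unit-mass Gaussian kernel truncated to a disc, sigma = radius / 2."""
    r = int(np.ceil(radius))
    ax = np.arange(-r, r + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    rr = np.hypot(xx, yy)
    k = np.exp(-(rr**2) / (2.0 * (radius / 2.0) ** 2))
    k[rr > radius] = 0.0
    if exclude_center:
        k[r, r] = 0.0
    return k / k.sum()


def _gaussian_annulus(r_in: float, r_out: float) -> np.ndarray:
    """Unit-mass Gaussian annulus between r_in and r_out."""
    r = int(np.ceil(r_out))
    ax = np.arange(-r, r + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    rr = np.hypot(xx, yy)
    mid = 0.5 * (r_in + r_out)
    k = np.exp(-((rr - mid) ** 2) / (2.0 * ((r_out - r_in) / 2.0) ** 2))
    k[(rr < r_in) | (rr > r_out)] = 0.0
    return k / k.sum()


def mt_kernels(config: ModelConfig) -> Dict[str, np.ndarray]:
    """Centre and surround kernels from the MT RF geometry.

    The MT centre spans ``mt_rf_scale`` V1 lattice steps in diameter and the
    surround annulus extends to ``mt_surround_scale`` steps.
    """
    r_center = config.mt_rf_scale / 2.0
    r_out = config.mt_surround_scale / 2.0
    annulus = _gaussian_annulus(r_center, r_out)
    return {
        "center": _gaussian_disc(r_center, exclude_center=True)
        * config.lambda_mass,
        "center_pool": _gaussian_disc(r_center, exclude_center=False),
        "annulus": annulus,
        # long-range inhibition is spatially diffuse: same annular footprint,
        # but only a fraction of the centre kernel's mass, so it biases the
        # competition without freezing the propagation wave the integration
        # population exists to carry
        "annulus_zeta": annulus * config.zeta_mass,
    }


def pool_inputs(field: np.ndarray, kernels: Dict[str, np.ndarray]
                ) -> np.ndarray:
    """Pool a V1 activity field (y, x, n_dir) over the MT centre RF.

    MT receptive fields span several V1 columns, so the feedforward drive of
    an MT unit is the Gaussian-weighted average of the V1 population within
    its centre, not the single co-located V1 cell.  This is what lets
    terminator signals reach MT units whose centres sit a few lattice steps
    away.
    """
    out = np.empty_like(field)
    for d in range(field.shape[-1]):
        out[..., d] = ndimage.convolve(field[..., d], kernels["center_pool"],
                                       mode="nearest")
    return out


def _direction_weights(dirs: DirectionSet, weighting: str) -> np.ndarray:
    """Inter-directional inhibition weights W[d, d'] (zero diagonal, rows sum 1)."""
    n = dirs.n_dir
    W = np.zeros((n, n))
    for d in range(n):
        for dp in range(n):
            if dp == d:
                continue
            if weighting == "uniform":
                W[d, dp] = 1.0
            else:  # cosine: opposite directions inhibit hardest
                ang = np.deg2rad(dirs.angles[d] - dirs.angles[dp])
                W[d, dp] = 1.0 - np.cos(ang)
        W[d] /= W[d].sum()
    return W


def lateral_terms(v_ig: np.ndarray, v_ig_delayed: np.ndarray,
                  v_sg: np.ndarray, kernels: Dict[str, np.ndarray],
                  dirs: DirectionSet, config: ModelConfig,
                  dir_weights: Optional[np.ndarray] = None
                  ) -> Tuple[np.ndarray, ...]:
    """All six lateral interaction fields for one time step.

    Inputs are (y, x, n_dir) activity arrays; ``v_ig_delayed`` is the
    integration field one inhibition delay in the past.  Contributions come
    only from units above the respective activity thresholds (c_ig, c_sg).
    Returns (lam, gamma, zeta, eta, chi_e, chi_i).
    """
    if v_ig_delayed is None:
        raise ValueError("delay history is empty")
    c_ig, c_sg = config.c_ig, config.c_sg
    ig_thr = np.where(v_ig > c_ig, v_ig, 0.0)
    igd_thr = np.where(v_ig_delayed > c_ig, v_ig_delayed, 0.0)
    sg_thr = np.where(v_sg > c_sg, v_sg, 0.0)
    if dir_weights is None:
        dir_weights = _direction_weights(dirs, config.gamma_weighting)

    n_dir = dirs.n_dir
    lam = np.empty_like(v_ig)
    zeta = np.empty_like(v_ig)
    chi_e = np.empty_like(v_ig)
    for d in range(n_dir):
        lam[..., d] = ndimage.convolve(ig_thr[..., d], kernels["center"],
                                       mode="nearest")
        zeta[..., d] = ndimage.convolve(igd_thr[..., d],
                                        kernels["annulus_zeta"],
                                        mode="nearest")
        chi_e[..., d] = ndimage.convolve(sg_thr[..., d], kernels["annulus"],
                                         mode="nearest")
    gamma = np.einsum("yxd,ed->yxe", igd_thr, dir_weights)
    eta = ndimage.convolve(ig_thr.mean(axis=-1), kernels["center_pool"],
                           mode="nearest")
    chi_i = chi_e[..., [dirs.opposite(d) for d in range(n_dir)]]
    return lam, gamma, zeta, eta, chi_e, chi_i


@dataclass
class MTState:
    """Joint state of the two MT populations plus the inhibition delay buffer."""

    v_ig: np.ndarray
    v_sg: np.ndarray
    history: deque  # past v_ig fields, maxlen = delay steps

    @classmethod
    def zeros(cls, shape: Tuple[int, int], n_dir: int, delay_steps: int
              ) -> "MTState":
        z = np.zeros(shape + (n_dir,))
        hist = deque([z.copy() for _ in range(delay_steps)],
                     maxlen=delay_steps)
        return cls(z.copy(), z.copy(), hist)


def mt_step(state: MTState, v_cx: np.ndarray, v_es: np.ndarray,
            kappa: np.ndarray, config: ModelConfig,
            kernels: Optional[Dict[str, np.ndarray]] = None,
            dir_weights: Optional[np.ndarray] = None,
            dirs: Optional[DirectionSet] = None) -> MTState:
    """One forward-Euler step of the coupled integration/segmentation dynamics.

    dv_ig/dt = h(G_igcx v_cx + G_iges v_es + G_igig2 lam + G_igcs kappa
                 - G_igig1 gamma(t-T) - G_igig3 zeta(t-T) - G_igsg v_sg
                 - tau_ig v_ig)
    dv_sg/dt = h(G_sgcx v_cx - G_sges v_es + G_sgig eta + G_sgsg1 chi_e
                 - G_sgsg2 chi_i - tau_sg v_sg)

    The V1 fields passed in are expected to be pooled over the MT centre RF
    (:func:`pool_inputs`); :func:`simulate` does this.
    """
    c = config
    if dirs is None:
        dirs = c.directions()
    if kernels is None:
        kernels = mt_kernels(c)
    delayed = state.history[0]
    lam, gamma, zeta, eta, chi_e, chi_i = lateral_terms(
        state.v_ig, delayed, state.v_sg, kernels, dirs, c, dir_weights)

    arg_ig = (c.G_igcx * c.mt_cx_gain * v_cx + c.G_iges * v_es
              + c.G_igig2 * lam
              + c.G_igcs * kappa - c.G_igig1 * gamma - c.G_igig3 * zeta
              - c.G_igsg * state.v_sg - c.tau_ig * state.v_ig)
    arg_sg = (c.G_sgcx * v_cx - c.G_sges * v_es
              + c.G_sgig * eta[..., None] + c.G_sgsg1 * chi_e
              - c.G_sgsg2 * chi_i - c.tau_sg * state.v_sg)
    for name, term in (("integration", arg_ig), ("segmentation", arg_sg)):
        if not np.all(np.isfinite(term)):
            raise FloatingPointError(f"non-finite {name} drive at MT step")
    v_ig = np.clip(state.v_ig + c.dt * saturate(arg_ig), 0.0, 1.0)
    v_sg = np.clip(state.v_sg + c.dt * saturate(arg_sg), 0.0, 1.0)
    state.history.append(state.v_ig.copy())
    return MTState(v_ig, v_sg, state.history)


@dataclass
class SimulationResult:
    """Full output of one network run."""

    config: ModelConfig
    movie: StimulusMovie
    n_settle: int
    v_cx_final: np.ndarray
    v_es_final: np.ndarray
    v_cs_final: np.ndarray
    kappa_final: np.ndarray
    v_ig_final: np.ndarray          # mean over the final evaluation window
    v_sg_final: np.ndarray
    v_ig_history: Optional[np.ndarray]   # (time, y, x, dir) if recorded
    probe_traces: Dict[Tuple[int, int], np.ndarray]  # (y, x) -> (time, dir)

    @property
    def n_steps(self) -> int:
        return self.movie.n_frames + self.n_settle


def simulate(movie: StimulusMovie, config: ModelConfig,
             n_settle: int = 800, record_history: bool = False,
             probes: Sequence[Tuple[int, int]] = (),
             final_window: float = 0.1) -> SimulationResult:
    """Run the full V1 -> MT cascade on a stimulus movie.

    The V1 front end (complex, end-stopped, form, and gated populations) is
    computed per frame and drives one MT Euler step per frame; after the movie
    ends the final V1 fields are held fixed for ``n_settle`` further steps so
    the slower recurrent MT dynamics (propagation from terminators, the
    pattern/component race) can play out.  ``v_ig_final`` averages the last
    ``final_window`` fraction of all steps.  Deterministic given (movie,
    config).
    """
    dirs = config.directions()
    bank = build_bank(config, movie.dt_frame)
    v_cx_raw = motion_energy(movie, bank)
    # responses inside an occluded border margin are hidden from every stage
    # downstream; lateral inhibition still pools the raw field (see
    # run_endstopped) so the margin boundary is not a line ending
    interior = movie.interior_mask()[..., None]
    v_cx_traj = v_cx_raw * interior
    ecrf_kernels = [dog_kernel(config, o) for o in dirs.orientations]
    kernels = mt_kernels(config)
    dir_weights = _direction_weights(dirs, config.gamma_weighting)

    T = movie.n_frames
    n_total = T + n_settle
    shape = movie.shape
    state = MTState.zeros(shape, dirs.n_dir, config.delay_steps)
    es = EndStoppedDynamics(config)

    n_final = max(1, int(round(final_window * n_total)))
    ig_sum = np.zeros(shape + (dirs.n_dir,))
    sg_sum = np.zeros_like(ig_sum)
    history = np.empty((n_total,) + shape + (dirs.n_dir,), dtype=np.float32) \
        if record_history else None
    traces = {tuple(p): np.empty((n_total, dirs.n_dir)) for p in probes}
    for y, x in traces:
        if not (0 <= y < shape[0] and 0 <= x < shape[1]):
            raise ValueError(f"probe ({y}, {x}) off the lattice")

    v_cs = kappa = v_es = None
    es_gamma = None
    for k in range(n_total):
        if k < T:
            v_cx = v_cx_traj[k]
            frame = movie.frames[k]
            v_cs = ecrf_response(frame, config, ecrf_kernels)
            kappa = gate_motion(v_cx, v_cs, dirs)
            es_gamma_k = lateral_inhibition(v_cx_raw[k], es.mu, config.c_cx,
                                            config.es_gate_radius)
            v_es = es.step(v_cx, es_gamma_k)
            v_cx_mt = pool_inputs(v_cx, kernels)
            kappa_mt = pool_inputs(kappa, kernels)
        else:
            v_cx = v_cx_traj[-1]
            if es_gamma is None:
                es_gamma = lateral_inhibition(v_cx_raw[-1], es.mu,
                                              config.c_cx,
                                              config.es_gate_radius)
            v_es = es.step(v_cx, es_gamma)
        v_es_mt = pool_inputs(v_es, kernels)
        state = mt_step(state, v_cx_mt, v_es_mt, kappa_mt, config, kernels,
                        dir_weights, dirs)
        if history is not None:
            history[k] = state.v_ig
        for p in traces:
            traces[p][k] = state.v_ig[p[0], p[1]]
        if k >= n_total - n_final:
            ig_sum += state.v_ig
            sg_sum += state.v_sg

    return SimulationResult(
        config=config, movie=movie, n_settle=n_settle,
        v_cx_final=v_cx_traj[-1], v_es_final=v_es, v_cs_final=v_cs,
        kappa_final=kappa, v_ig_final=ig_sum / n_final,
        v_sg_final=sg_sum / n_final, v_ig_history=history,
        probe_traces=traces)
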