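"""Orientation-selective V1 cells with suppressive extra-classical surrounds.

These form-signalling cells convolve the reversed stimulus intensity with an
oriented difference-of-Gaussians (centre minus a wider surround, both
elongated along the preferred contour) and saturate the result.  Because the
surround pools dark luminance over a wide area, the response collapses where
two bars cross (the extrinsic terminator) while staying high along isolated
edges and at true line endings — exactly the form cue the MT stage uses to
discount or favour the crossing.

The population is memoryless: it is recomputed frame by frame.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy import ndimage

from .config import DirectionSet, ModelConfig, saturate

__all__ = ["dog_kernel", "ecrf_response", "gate_motion", "GATE_EPS"]

#: strict-positivity gate tolerance; avoids gating on float noise
GATE_EPS = 1e-6


def dog_kernel(config: ModelConfig, orientation_deg: float,
               support: Optional[int] = None) -> np.ndarray:
    """Oriented centre-surround (Mexican-hat) kernel sampled on the lattice.

    R(u, v) = A_C exp(-(u^2/sxc^2 + v^2/syc^2)) - A_S exp(-(u^2/sxs^2 + v^2/sys^2))

    with (u, v) coordinates rotated so v runs along the preferred contour
    (the wider sigma_y* of the table lies along the orientation).  The support
    must hold at least 4 surround sigmas in both axes.
    """
    sxc = config.sigma_pix("sigma_xc")
    syc = config.sigma_pix("sigma_yc")
    sxs = config.sigma_pix("sigma_xs")
    sys_ = config.sigma_pix("sigma_ys")
    min_support = int(math.ceil(4.0 * max(sxs, sys_)))
    if support is None:
        support = min_support
    elif support < min_support:
        raise ValueError(f"support {support} too small; need >= {min_support} "
                         "(4 surround sigmas)")
    ax = np.arange(-support, support + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    th = np.deg2rad(orientation_deg)
    v = xx * np.cos(th) + yy * np.sin(th)   # along the contour
    u = -xx * np.sin(th) + yy * np.cos(th)  # across the contour
    return (config.A_C * np.exp(-(u**2 / sxc**2 + v**2 / syc**2))
            - config.A_S * np.exp(-(u**2 / sxs**2 + v**2 / sys_**2)))


def ecrf_response(frame: np.ndarray, config: ModelConfig,
                  kernels: Optional[list] = None) -> np.ndarray:
    """Form-cell activity v_cs for one frame, shape (y, x, n_orientations).

    ``frame`` is luminance in [0, 1]; it is reversed (I = background - frame,
    white background assumed at 1) so dark bars drive the filter, convolved
    with each oriented kernel, and saturated to [0, 1].
    """
    if frame.min() < -1e-12 or frame.max() > 1 + 1e-12:
        raise ValueError("frame luminance must lie in [0, 1]")
    dirs = config.directions()
    orientations = dirs.orientations
    if kernels is None:
        kernels = [dog_kernel(config, o) for o in orientations]
    I = np.clip(1.0 - frame, 0.0, 1.0)
    out = np.empty(frame.shape + (len(orientations),))
    for i, K in enumerate(kernels):
        out[..., i] = saturate(ndimage.convolve(I, K, mode="nearest"))
    return out


def gate_motion(v_cx: np.ndarray, v_cs: np.ndarray,
                direction_set: DirectionSet) -> np.ndarray:
    """Form-gated motion signal kappa, shape (y, x, n_dir).

    kappa(x, y, theta) equals the complex-cell activity wherever the form cell
    of the orientation orthogonal to theta is active, and zero elsewhere.  The
    gate suppresses the motion signal at extrinsic terminators, where surround
    suppression silences the form cells.
    """
    n_dir = direction_set.n_dir
    if v_cx.shape[-1] != n_dir:
        raise ValueError("v_cx last axis must index the model directions")
    if v_cs.shape[-1] != n_dir // 2:
        raise ValueError("v_cs is missing orientation slices")
    kappa = np.zeros_like(v_cx)
    for d in range(n_dir):
        o = direction_set.orthogonal_orientation(d)
        kappa[..., d] = np.where(v_cs[..., o] > GATE_EPS, v_cx[..., d], 0.0)
    return kappa
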