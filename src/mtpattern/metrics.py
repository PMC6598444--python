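"""Pattern-index analysis: desired-activity templates, S_P, S_C, and P_I.

The selectivity of a run is scored against two idealised outcomes.  The
pattern template puts unit activity over the whole stimulus footprint in the
pattern direction (upward for the canonical crossing-bar stimuli); each
component template puts unit activity over one bar's footprint in that bar's
aperture direction (up-left / up-right).  The summed absolute deviation
between the final integration-MT field and a template, normalised across the
ensemble of runs in a sweep, gives the selectivity levels

    S_P = 1 - N(sum |v_ig - v_dp|),   S_C = 1 - N(sum of both component
                                                  deviations)

and the pattern index P_I = S_P - S_C in [-1, 1]: positive means
pattern-selective, negative component-selective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .config import DirectionSet
from .stimuli import BarSpec, StimulusMovie, render_bar_frame

logger = logging.getLogger(__name__)

__all__ = ["ActivityTemplates", "build_templates", "deviations",
           "selectivity_levels", "pattern_index", "PatternIndexResult",
           "probe_timecourse", "normalize_ensemble"]


@dataclass
class ActivityTemplates:
    """Desired activity maps for the pattern and the two component readings."""

    pattern: np.ndarray            # (y, x), unit on the full footprint
    pattern_direction: int         # direction index (upward)
    components: List[np.ndarray]   # per bar, unit on that bar's footprint
    component_directions: List[int]


def _aperture_direction(bar: BarSpec, dirs: DirectionSet) -> int:
    """Direction index of the motion component orthogonal to the bar.

    Through a small aperture only the normal component of a bar's motion is
    visible; the template direction is the normal with positive projection on
    the true motion.
    """
    n1 = bar.orientation + 90.0
    th = np.deg2rad(bar.direction)
    motion = np.array([np.cos(th), np.sin(th)])
    nvec = np.array([np.cos(np.deg2rad(n1)), np.sin(np.deg2rad(n1))])
    angle = n1 if motion @ nvec > 0 else (n1 + 180.0)
    return dirs.index_of(angle % 360.0)


def build_templates(movie: StimulusMovie, dirs: DirectionSet,
                    bars: Sequence[BarSpec],
                    window: Optional[Tuple[int, int, int, int]] = None,
                    pattern_direction: float = 90.0,
                    at_frame: int = -1,
                    rf_radius: int = 0) -> ActivityTemplates:
    """Templates from the generating bar specs of an annotated movie.

    ``window`` is the crop (y0, y1, x0, x1) applied to the movie, if any; bar
    footprints are rendered at ``at_frame`` (default: the final frame, the
    evaluation time).  ``rf_radius`` dilates each footprint by the MT
    centre-RF radius: the desired-activity maps describe the MT population,
    whose units respond whenever their RF overlaps the bar, so the idealised
    map is the stimulus footprint smeared by the RF — without the dilation
    the narrow wedges at the bar crossing would count legitimate junction
    responses as off-stimulus.  A movie without terminator annotations is
    rejected — templates are only meaningful for the annotated bar stimuli.
    """
    if not movie.annotations:
        raise ValueError("movie carries no terminator annotations")
    t = (movie.n_frames + at_frame if at_frame < 0 else at_frame) \
        * movie.dt_frame
    comps, comp_dirs = [], []
    for bar in bars:
        if bar.contrast == 0.0:
            continue
        if window is None:
            fp = render_bar_frame(movie.shape, bar, t).astype(float)
        else:
            y0, y1, x0, x1 = window
            big = render_bar_frame((y1, x1), bar, t)
            fp = big[y0:y1, x0:x1].astype(float)
        if rf_radius > 0:
            ax = np.arange(-rf_radius, rf_radius + 1)
            disc = (ax[:, None] ** 2 + ax[None, :] ** 2) <= rf_radius**2
            fp = ndimage.binary_dilation(fp > 0, disc).astype(float)
        comps.append(fp)
        comp_dirs.append(_aperture_direction(bar, dirs))
    if not comps:
        raise ValueError("no visible bars to build templates from")
    pattern = np.clip(np.sum(comps, axis=0), 0.0, 1.0)
    return ActivityTemplates(
        pattern=pattern, pattern_direction=dirs.index_of(pattern_direction),
        components=comps, component_directions=comp_dirs)


def deviations(v_ig_final: np.ndarray, templates: ActivityTemplates
               ) -> Tuple[float, float]:
    """Summed absolute deviations (pattern, component) for one run.

    The sums run over the whole lattice: activity off the stimulus footprint
    counts against the run (the templates are zero there).
    """
    dp = float(np.abs(v_ig_final[..., templates.pattern_direction]
                      - templates.pattern).sum())
    dc = 0.0
    for fp, d in zip(templates.components, templates.component_directions):
        dc += float(np.abs(v_ig_final[..., d] - fp).sum())
    return dp, dc


def normalize_ensemble(values: np.ndarray) -> np.ndarray:
    """Min-max normalisation N(v) over a sweep ensemble.

    A degenerate ensemble (all deviations equal) carries no ranking
    information; by convention N = 0 then (selectivity 1), and the case is
    logged.
    """
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi - lo < 1e-12:
        logger.warning("degenerate normalisation ensemble (max == min); "
                       "defining N = 0 for all runs")
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def selectivity_levels(dev_p: np.ndarray, dev_c: np.ndarray
                       ) -> Tuple[np.ndarray, np.ndarray]:
    """S_P and S_C for a sweep ensemble of deviation values."""
    return 1.0 - normalize_ensemble(dev_p), 1.0 - normalize_ensemble(dev_c)


def pattern_index(S_P, S_C):
    """P_I = S_P - S_C: positive = pattern-selective, negative = component."""
    return np.asarray(S_P) - np.asarray(S_C)


@dataclass
class PatternIndexResult:
    """Selectivity scores for one (G_igcs, G_sges) gain pair."""

    G_igcs: float
    G_sges: float
    S_P: float
    S_C: float

    @property
    def P_I(self) -> float:
        return self.S_P - self.S_C


def probe_timecourse(v_ig_trace: np.ndarray, dirs: DirectionSet,
                     pattern_direction: int, component_direction: int,
                     dt: float) -> Dict[str, object]:
    """Pattern- vs component-direction activity traces at one probe.

    ``v_ig_trace`` is (time, n_dir) at the probe.  Returns both traces and the
    crossing time: the first time at which the pattern-direction activity
    exceeds the component-direction activity and stays above it for the rest
    of the run (None if it never dominates).
    """
    pat = v_ig_trace[:, pattern_direction]
    comp = v_ig_trace[:, component_direction]
    above = np.where(pat > comp)[0]
    crossing = float(above[0] * dt) if len(above) else None
    return {"pattern": pat, "component": comp, "crossing_time": crossing,
            "dt": dt}
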