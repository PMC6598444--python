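"""Stimulus movies: translating crossing bars and their occluded/contrast variants.

Conventions
-----------
Frames are arrays ``(time, y, x)`` of luminance in [0, 1] on a white
(luminance 1) background; bars are dark.  The y axis is the row index and the
"upward" pattern direction is +y (90 degrees); x is the column index (0
degrees is rightward).  Bar orientation is measured from the +x axis, so the
135-degree bar moves rightward, the 45-degree bar moves leftward, and their
intersection — the extrinsic terminator — translates straight up.

Bars are rendered with hard edges on the lattice (no sub-pixel smoothing);
fractional displacement accumulates and is rounded per frame.  Where bars of
equal contrast overlap, the overlap takes the darker value (min), mimicking a
saturated plaid whose crossing points are no darker than the bars; with
unequal contrasts the lower-contrast bar is drawn in front.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = [
    "BarSpec",
    "StimulusMovie",
    "render_bar_frame",
    "render_crossing_bars",
    "occlude_intrinsic_terminators",
    "contrast_variant",
    "preset_movie",
]


@dataclass
class BarSpec:
    """A rigidly translating dark bar.

    orientation : degrees from the +x axis, in [0, 180)
    direction   : degrees of true motion (0 = rightward, 180 = leftward)
    speed       : lattice steps per time unit
    length, width : lattice steps
    contrast    : darkness in [0, 1]; luminance of the bar is 1 - contrast
    center      : (y, x) position of the bar centre at frame 0
    """

    orientation: float = 135.0
    direction: float = 0.0
    speed: float = 15.0
    length: float = 40.0
    width: float = 3.0
    contrast: float = 1.0
    center: Tuple[float, float] = (32.0, 32.0)

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("bar speed must be positive")
        if not (0.0 <= self.contrast <= 1.0):
            raise ValueError("contrast must lie in [0, 1]")
        if not (0.0 <= self.orientation < 180.0):
            raise ValueError("orientation must lie in [0, 180)")

    def center_at(self, t: float) -> Tuple[float, float]:
        th = np.deg2rad(self.direction)
        cy, cx = self.center
        return (cy + self.speed * t * np.sin(th), cx + self.speed * t * np.cos(th))

    def endpoints_at(self, t: float) -> List[Tuple[float, float]]:
        """The two intrinsic terminators (y, x) at time t."""
        cy, cx = self.center_at(t)
        oy = np.sin(np.deg2rad(self.orientation)) * self.length / 2.0
        ox = np.cos(np.deg2rad(self.orientation)) * self.length / 2.0
        return [(cy + oy, cx + ox), (cy - oy, cx - ox)]


@dataclass
class StimulusMovie:
    """A calibrated stack of grayscale frames plus terminator annotations.

    ``annotations`` maps labels ("intrinsic" / "extrinsic") to arrays of shape
    (n_frames, n_points, 2) holding (y, x) trajectories; they exist purely so
    downstream analyses and tests can locate terminators without re-deriving
    the stimulus geometry.
    """

    frames: np.ndarray
    dt_frame: float = 0.01
    background: float = 1.0
    annotations: Dict[str, np.ndarray] = field(default_factory=dict)
    #: border width (lattice steps) treated as occluded: for cropped
    #: pattern stimuli the frame edge cuts the bars, and responses within
    #: this margin are masked so the cut ends do not act as terminators
    occluded_margin: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be (time, y, x) with at least 2 frames")
        if self.frames.min() < -1e-12 or self.frames.max() > 1 + 1e-12:
            raise ValueError("luminance must lie in [0, 1]")
        if self.dt_frame <= 0:
            raise ValueError("dt_frame must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def interior_mask(self) -> np.ndarray:
        """Boolean (y, x) map, False inside the occluded border margin."""
        m = np.zeros(self.shape, dtype=bool)
        k = self.occluded_margin
        if k == 0:
            m[:] = True
        else:
            m[k:-k, k:-k] = True
        return m

    @property
    def shape(self) -> Tuple[int, int]:
        return self.frames.shape[1:]

    def reversed_intensity(self) -> np.ndarray:
        """I = background - luminance, clipped to [0, 1]: dark bars become high."""
        return np.clip(self.background - self.frames, 0.0, 1.0)

    def mirrored(self) -> "StimulusMovie":
        """Left-right mirror of the movie (annotations mirrored too)."""
        w = self.shape[1]
        ann = {
            k: np.stack([v[..., 0], (w - 1) - v[..., 1]], axis=-1)
            for k, v in self.annotations.items()
        }
        return StimulusMovie(self.frames[:, :, ::-1].copy(), self.dt_frame,
                             self.background, ann)


def render_bar_frame(shape: Tuple[int, int], bar: BarSpec, t: float) -> np.ndarray:
    """Binary footprint (True where the bar covers the pixel) at time t."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = bar.center_at(t)
    # hard-edge rendering: displacement rounded to the lattice
    cy, cx = round(cy), round(cx)
    th = np.deg2rad(bar.orientation)
    # coordinates along/across the bar axis
    u = (xx - cx) * np.cos(th) + (yy - cy) * np.sin(th)
    v = -(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
    return (np.abs(u) <= bar.length / 2.0) & (np.abs(v) <= bar.width / 2.0)


def _intersection_point(bar1: BarSpec, bar2: BarSpec, t: float):
    """Intersection (y, x) of the two bar axes at time t, or None if parallel."""
    th1, th2 = np.deg2rad(bar1.orientation), np.deg2rad(bar2.orientation)
    d1 = np.array([np.sin(th1), np.cos(th1)])  # (dy, dx) along bar 1
    d2 = np.array([np.sin(th2), np.cos(th2)])
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(denom) < 1e-9:
        return None
    c1 = np.array(bar1.center_at(t))
    c2 = np.array(bar2.center_at(t))
    rhs = c2 - c1
    u = (rhs[0] * d2[1] - rhs[1] * d2[0]) / denom
    return tuple(c1 + u * d1)


def render_crossing_bars(
    bar1: BarSpec,
    bar2: BarSpec,
    shape: Tuple[int, int] = (64, 64),
    n_frames: int = 30,
    dt_frame: float = 0.01,
) -> StimulusMovie:
    """Two rigidly translating bars on a white background.

    Overlapping pixels take the darker (minimum-luminance) value so equal
    contrast bars form a saturated plaid; the intersection of the bar axes is
    annotated as the extrinsic terminator and the four bar endpoints as
    intrinsic terminators.  Raises if the bars never intersect on screen (the
    stimulus would carry no extrinsic terminator).
    """
    frames = np.ones((n_frames,) + tuple(shape))
    intr = np.zeros((n_frames, 4, 2))
    extr = np.zeros((n_frames, 1, 2))
    single = bar2.contrast == 0.0 or bar1.contrast == 0.0
    any_crossing = False
    for k in range(n_frames):
        t = k * dt_frame
        f1 = render_bar_frame(shape, bar1, t)
        f2 = render_bar_frame(shape, bar2, t)
        frame = frames[k]
        lum1, lum2 = 1.0 - bar1.contrast, 1.0 - bar2.contrast
        frame[f1] = np.minimum(frame[f1], lum1)
        frame[f2] = np.minimum(frame[f2], lum2)
        intr[k, :2] = bar1.endpoints_at(t)
        intr[k, 2:] = bar2.endpoints_at(t)
        pt = None if single else _intersection_point(bar1, bar2, t)
        if pt is not None:
            y, x = int(round(pt[0])), int(round(pt[1]))
            if 0 <= y < shape[0] and 0 <= x < shape[1] and (f1 & f2).any():
                any_crossing = True
            extr[k, 0] = pt
        else:
            extr[k, 0] = np.nan
    ann = {"intrinsic": intr}
    if single:
        pass  # degenerate single-bar movie: no extrinsic terminator
    elif not any_crossing:
        raise ValueError("bars never intersect within the frame: "
                         "no extrinsic terminator exists")
    else:
        ann["extrinsic"] = extr
    return StimulusMovie(frames, dt_frame=dt_frame, annotations=ann)


def occlude_intrinsic_terminators(
    movie: StimulusMovie, window: Tuple[int, int, int, int],
    margin: int = 6,
) -> StimulusMovie:
    """Crop to ``window`` = (y0, y1, x0, x1) so bars terminate at the frame edge.

    The crop must contain the extrinsic terminator in every frame and exclude
    every intrinsic terminator in every frame (otherwise the result would not
    be a pure pattern stimulus).  Intrinsic annotations are dropped; the
    extrinsic annotation is shifted into the cropped coordinates.  ``margin``
    is stored as the movie's occluded border width: the frame edge cuts the
    bars, and downstream stages mask their responses within the margin so the
    cut ends are hidden rather than seen as new terminators.
    """
    y0, y1, x0, x1 = window
    if not (0 <= y0 < y1 <= movie.shape[0] and 0 <= x0 < x1 <= movie.shape[1]):
        raise ValueError("window out of bounds")
    if "extrinsic" in movie.annotations:
        ex = movie.annotations["extrinsic"]
        inside = ((ex[..., 0] >= y0) & (ex[..., 0] < y1)
                  & (ex[..., 1] >= x0) & (ex[..., 1] < x1))
        if not inside.all():
            raise ValueError("window must contain the extrinsic terminator "
                             "in every frame")
    if "intrinsic" in movie.annotations:
        it = movie.annotations["intrinsic"]
        inside = ((it[..., 0] >= y0) & (it[..., 0] < y1)
                  & (it[..., 1] >= x0) & (it[..., 1] < x1))
        if inside.any():
            raise ValueError("window contains an intrinsic terminator: "
                             "the cropped stimulus would not be a pattern "
                             "stimulus")
    ann = {}
    if "extrinsic" in movie.annotations:
        ex = movie.annotations["extrinsic"].copy()
        ex[..., 0] -= y0
        ex[..., 1] -= x0
        ann["extrinsic"] = ex
    return StimulusMovie(movie.frames[:, y0:y1, x0:x1].copy(), movie.dt_frame,
                         movie.background, ann, occluded_margin=margin)


def contrast_variant(
    bar1: BarSpec,
    bar2: BarSpec,
    contrast1: float,
    contrast2: float,
    shape: Tuple[int, int] = (64, 64),
    n_frames: int = 30,
    dt_frame: float = 0.01,
) -> StimulusMovie:
    """Crossing bars with per-bar contrasts.

    With unequal contrasts the low-contrast bar is drawn in front (its
    luminance wins at the overlap), matching the percept of the lighter bar
    sliding over the darker one; equal contrasts reduce to
    :func:`render_crossing_bars`.
    """
    if contrast1 == 0.0 and contrast2 == 0.0:
        raise ValueError("at least one bar must have nonzero contrast")
    b1 = replace(bar1, contrast=contrast1)
    b2 = replace(bar2, contrast=contrast2)
    movie = render_crossing_bars(b1, b2, shape, n_frames, dt_frame)
    if contrast1 == contrast2 or contrast1 == 0.0 or contrast2 == 0.0:
        return movie
    front, back = (b1, b2) if contrast1 < contrast2 else (b2, b1)
    frames = movie.frames
    for k in range(movie.n_frames):
        t = k * dt_frame
        ffront = render_bar_frame(movie.shape, front, t)
        frames[k][ffront] = 1.0 - front.contrast
    return StimulusMovie(frames, dt_frame, movie.background, movie.annotations)


# ---------------------------------------------------------------------------
# presets used throughout the experiments

def default_bars(speed: float = 15.0, length: float = 40.0,
                 center: Tuple[float, float] = (32.0, 32.0),
                 offset: float = 8.0) -> Tuple[BarSpec, BarSpec]:
    """The canonical crossing pair: 135-deg bar moving right, 45-deg moving left.

    The bars start horizontally offset by ``offset`` lattice steps in opposite
    senses so the intersection starts below centre and sweeps upward through
    the movie.
    """
    cy, cx = center
    bar1 = BarSpec(orientation=135.0, direction=0.0, speed=speed, length=length,
                   center=(cy, cx - offset))
    bar2 = BarSpec(orientation=45.0, direction=180.0, speed=speed, length=length,
                   center=(cy, cx + offset))
    return bar1, bar2


def preset_movie(name: str, n_frames: int = 30, dt_frame: float = 0.01,
                 contrasts: Optional[Tuple[float, float]] = None) -> StimulusMovie:
    """Named stimulus presets.

    - ``crossing``: equal-contrast crossing bars, intrinsic terminators visible.
    - ``pattern``: the same bars, longer, cropped so only the extrinsic
      terminator remains in frame (the plaid-like pattern stimulus).
    - ``contrast``: the pattern stimulus with unequal bar contrasts.
    - ``blank``: a uniform white movie.
    """
    if name == "blank":
        return StimulusMovie(np.ones((max(2, n_frames), 64, 64)), dt_frame)
    if name == "crossing":
        b1, b2 = default_bars()
        return render_crossing_bars(b1, b2, (64, 64), n_frames, dt_frame)
    if name in ("pattern", "contrast"):
        b1, b2 = default_bars(length=60.0)
        c1, c2 = contrasts if contrasts is not None else (1.0, 1.0)
        full = contrast_variant(b1, b2, c1, c2, (64, 64), n_frames, dt_frame)
        return occlude_intrinsic_terminators(full, (14, 50, 14, 50))
    raise ValueError(f"unknown preset {name!r}")
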