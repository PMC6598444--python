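"""Run configuration, direction geometry, and the shared saturating nonlinearity.

Every constant of the model lives in :class:`ModelConfig`; a default-constructed
config reproduces the published parameter table exactly.  Time is expressed in a
single abstract unit (the printed "ms" labels are taken at face value as that
unit); space is expressed in lattice steps, with ``pixels_per_degree`` fixing
the conversion for the parameters printed in degrees.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import yaml

__all__ = ["ModelConfig", "DirectionSet", "saturate", "default_config"]


def saturate(x):
    """Piecewise-linear saturation h(x): 0 below 0, identity on [0, 1), 1 above.

    Accepts scalars or arrays; raises ``ValueError`` on non-finite input, which
    always signals a defect upstream (activities must stay finite).
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("saturate: non-finite input activity")
    out = np.clip(arr, 0.0, 1.0)
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out


@dataclass
class DirectionSet:
    """The N uniformly spaced motion directions and their index maps."""

    n_dir: int = 8

    def __post_init__(self) -> None:
        if self.n_dir < 2 or self.n_dir % 2 != 0:
            raise ValueError("n_dir must be even and >= 2 (opposites must exist)")
        self.angles = np.arange(self.n_dir) * (360.0 / self.n_dir)

    def index_of(self, angle_deg: float) -> int:
        step = 360.0 / self.n_dir
        idx = int(round((angle_deg % 360.0) / step)) % self.n_dir
        if not np.isclose((angle_deg % 360.0) % step, 0.0) and not np.isclose(
            (angle_deg % 360.0) % step, step
        ):
            raise ValueError(f"{angle_deg} is not one of the model directions")
        return idx

    def opposite(self, d: int) -> int:
        """Index of the direction 180 degrees from direction ``d``."""
        return (d + self.n_dir // 2) % self.n_dir

    @property
    def orientations(self) -> np.ndarray:
        """The distinct contour orientations (directions modulo 180)."""
        return self.angles[: self.n_dir // 2]

    def orthogonal_orientation(self, d: int) -> int:
        """Orientation index (into :attr:`orientations`) orthogonal to direction ``d``.

        Motion-selective cells pair with form cells whose preferred contour is
        orthogonal to the motion direction (a drifting edge modulates luminance
        along its normal).
        """
        angle = (self.angles[d] + 90.0) % 180.0
        step = 360.0 / self.n_dir
        return int(round(angle / step)) % (self.n_dir // 2)


# Published parameter table, one entry per symbol.  Units: gains and thresholds
# dimensionless; decay rates per time unit; dt, tau_g, T_ig in time units;
# f in cycles/degree; Gaussian widths in degrees.
@dataclass
class ModelConfig:
    # V1 end-stopped stage
    G_escx1: float = 2.0
    G_escx2: float = 3.0
    tau_es: float = 0.01
    # MT integration stage
    G_igcx: float = 0.5
    G_iges: float = 0.7
    G_igig1: float = 1.0
    G_igig2: float = 0.2
    G_igig3: float = 1.0
    G_igsg: float = 0.1
    G_igcs: float = 0.5  # sweepable: excitation from ECRF-gated V1 input
    tau_ig: float = 0.2
    T_ig: float = 0.1
    # MT segmentation stage
    G_sgcx: float = 1.0
    G_sges: float = 0.5  # sweepable: inhibition from end-stopped V1 cells
    G_sgig: float = 0.5
    G_sgsg1: float = 0.1
    G_sgsg2: float = 0.2
    tau_sg: float = 0.2
    # activity thresholds
    c_cx: float = 0.12
    c_sg: float = 0.02
    c_ig: float = 0.05
    # temporal filters
    tau_g: float = 0.01
    n_fast: int = 6
    n_slow: int = 9
    # numerics
    dt: float = 0.01
    # spatial filters (degrees / cycles per degree)
    f: float = 1.1
    sigma_x: float = 0.5
    sigma_y: float = 0.5
    A_C: float = 1.0
    A_S: float = 0.72
    sigma_xc: float = 0.35
    sigma_yc: float = 0.4
    sigma_xs: float = 0.4
    sigma_ys: float = 0.5
    # geometry
    N_dir: int = 8
    grid_shape: tuple = (64, 64)
    pixels_per_degree: float = 4.0
    mt_rf_scale: float = 7.0
    mt_surround_scale: float = 10.0
    # end-stopped lateral-inhibition patch radii (see methods note)
    es_inhib_radius: int = 12
    es_gate_radius: int = 4
    # inter-directional inhibition weighting: "uniform" or "cosine"
    gamma_weighting: str = "uniform"
    # kernel masses of the recurrent MT interactions, relative to the
    # unit-mass centre pooling kernel: lambda_mass scales same-direction
    # centre excitation (the propagation drive), zeta_mass the long-range
    # same-direction inhibition that contains it
    lambda_mass: float = 1.0
    zeta_mass: float = 0.1
    # coupling scale of the raw complex-cell drive into the integration
    # population (Eq. of dv_ig): the broadly tuned, aperture-ambiguous
    # complex input is weighted down relative to the terminator-selective
    # end-stopped input and the form-gated kappa pathway, implementing the
    # premise that unambiguous terminator signals win the integration race
    mt_cx_gain: float = 0.25
    seed: int = 0

    # names of the gains the published sweeps vary
    SWEEPABLE = ("G_igcs", "G_sges")

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        self.validate()

    def validate(self) -> None:
        for fld in dataclasses.fields(self):
            name = fld.name
            val = getattr(self, name)
            if name.startswith(("G_", "tau_", "c_")) and val < 0:
                raise ValueError(f"{name} must be >= 0, got {val}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.N_dir != 8:
            raise ValueError("the published configuration uses N_dir = 8")
        if self.mt_surround_scale <= self.mt_rf_scale:
            raise ValueError("MT surround must be larger than MT centre")
        if len(self.grid_shape) != 2 or min(self.grid_shape) < 8:
            raise ValueError("grid_shape must be 2-D and at least 8x8")
        if self.gamma_weighting not in ("uniform", "cosine"):
            raise ValueError("gamma_weighting must be 'uniform' or 'cosine'")

    # -- derived geometry -------------------------------------------------
    def directions(self) -> DirectionSet:
        return DirectionSet(self.N_dir)

    @property
    def f_pix(self) -> float:
        """Gabor carrier frequency in cycles per lattice step."""
        return self.f / self.pixels_per_degree

    def sigma_pix(self, name: str) -> float:
        """A Table sigma (degrees) converted to lattice steps."""
        return getattr(self, name) * self.pixels_per_degree

    @property
    def delay_steps(self) -> int:
        return max(1, int(round(self.T_ig / self.dt)))

    # -- (de)serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "ModelConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "grid_shape" in data:
            data["grid_shape"] = tuple(data["grid_shape"])
        return cls.from_dict(data)

    def replace(self, **kwargs) -> "ModelConfig":
        return dataclasses.replace(self, **kwargs)


def default_config(**overrides) -> ModelConfig:
    """The published parameter table as a ready-to-run configuration."""
    return ModelConfig(**overrides)
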