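"""HDF5 persistence for stimulus movies and population activity fields."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional, Union

import h5py
import numpy as np

from .stimuli import StimulusMovie

__all__ = ["save_movie", "load_movie", "save_fields", "load_fields"]


def save_movie(movie: StimulusMovie, path: Union[str, Path]) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("frames", data=movie.frames)
        d.attrs["dt_frame"] = movie.dt_frame
        d.attrs["background"] = movie.background
        d.attrs["axes"] = "t,y,x"
        ann = f.create_group("annotations")
        for key, val in movie.annotations.items():
            ann.create_dataset(key, data=val)


def load_movie(path: Union[str, Path]) -> StimulusMovie:
    with h5py.File(path, "r") as f:
        d = f["frames"]
        ann = {k: v[...] for k, v in f.get("annotations", {}).items()}
        return StimulusMovie(d[...], float(d.attrs["dt_frame"]),
                             float(d.attrs["background"]), ann)


def save_fields(fields: Dict[str, np.ndarray], path: Union[str, Path],
                attrs: Optional[dict] = None) -> None:
    """Write named activity arrays (one dataset per population)."""
    with h5py.File(path, "w") as f:
        for name, arr in fields.items():
            if arr is not None:
                f.create_dataset(name, data=np.asarray(arr))
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def load_fields(path: Union[str, Path]) -> Dict[str, np.ndarray]:
    with h5py.File(path, "r") as f:
        return {k: f[k][...] for k in f.keys()}
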