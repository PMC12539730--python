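"""Kymograph persistence (HDF5, CSV) and figure-style rendering."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np

from .core import Kymograph
from .params import ModelSpec

__all__ = ["save_kymograph", "load_kymograph", "kymograph_to_csv",
           "render_kymograph", "render_rgb"]

PathLike = Union[str, Path]


def save_kymograph(kymo: Kymograph, path: PathLike) -> None:
    """Write all species to an HDF5 file with full provenance."""
    with h5py.File(path, "w") as f:
        for sp, arr in kymo.data.items():
            f.create_dataset(sp, data=arr, compression="gzip")
        f.attrs["dx"] = kymo.dx
        f.attrs["record_interval"] = kymo.record_interval
        f.attrs["seed"] = kymo.seed
        f.attrs["model_spec"] = json.dumps(kymo.model.to_dict())


def load_kymograph(path: PathLike) -> Kymograph:
    with h5py.File(path, "r") as f:
        data = {sp: f[sp][...] for sp in f.keys()}
        model = ModelSpec.from_dict(json.loads(f.attrs["model_spec"]))
        return Kymograph(data=data, dx=float(f.attrs["dx"]),
                         record_interval=float(f.attrs["record_interval"]),
                         seed=int(f.attrs["seed"]), model=model)


def kymograph_to_csv(kymo: Kymograph, species: str, path: PathLike) -> None:
    """One species as a plain CSV matrix (rows = sites, columns = times)."""
    np.savetxt(path, kymo[species], delimiter=",")


def _norm(arr: np.ndarray) -> np.ndarray:
    lo, hi = arr.min(), arr.max()
    return (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)


def render_rgb(kymo: Kymograph) -> np.ndarray:
    """Three-channel composite: Ras = red, PKB = blue, PIP2 = green."""
    r = _norm(kymo["ras"])
    g = _norm(kymo["pip2"]) if "pip2" in kymo.data else np.zeros_like(r)
    b = _norm(kymo["pkb"]) if "pkb" in kymo.data else np.zeros_like(r)
    return np.stack([r, g, b], axis=-1)


def render_kymograph(kymo: Kymograph, path: PathLike,
                     species: Optional[str] = None,
                     cmap: str = "hot") -> None:
    """PNG rendering: single species with a colormap, or the RGB composite."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    extent = (0, kymo.n_times * kymo.record_interval, 0, 360)
    if species is None:
        ax.imshow(render_rgb(kymo), aspect="auto", origin="lower",
                  extent=extent)
    else:
        ax.imshow(kymo[species], aspect="auto", origin="lower", cmap=cmap,
                  extent=extent)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("membrane position (deg)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
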