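"""HDF5 storage for clip batches and delimited tables for ratings."""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .stimgen import StimulusSpec

__all__ = ["save_clips", "load_clips", "save_ratings", "load_ratings"]

_KEY_COLS = ("scene_class", "viscosity_step", "scene_variation", "optical_variation")


def save_clips(path: str, specs: "list[StimulusSpec]", clips: np.ndarray) -> None:
    """Clips plus design metadata in one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("clips", data=clips.astype(np.float32), compression="gzip")
        meta = np.array([[s.scene_class, s.viscosity_step, s.scene_variation,
                          s.optical_variation, s.seed] for s in specs], dtype=np.int64)
        f.create_dataset("design", data=meta)
        f["design"].attrs["columns"] = list(_KEY_COLS) + ["seed"]


def load_clips(path: str) -> tuple["list[StimulusSpec]", np.ndarray]:
    with h5py.File(path, "r") as f:
        clips = f["clips"][...]
        meta = f["design"][...]
    specs = [StimulusSpec(int(r[0]), int(r[1]), int(r[2]), int(r[3]), int(r[4]))
             for r in meta]
    return specs, clips


def save_ratings(path: str, records: pd.DataFrame) -> None:
    records.to_csv(path, sep="\t", index=False)


def load_ratings(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
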