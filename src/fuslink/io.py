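"""File formats for the pipeline.

Ultrafast stacks and power-Doppler movies travel as HDF5 (or NPZ for the
stacks); histology sections as 8-bit grayscale TIFF plus a labelled-mask
TIFF; cohort tables as CSV; generator parameters as a single YAML mapping.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .activation import ActivationMap
from .doppler import PowerDopplerMovie, UltrafastStack

__all__ = [
    "save_stack", "load_stack",
    "save_movie", "load_movie",
    "save_activation_map", "load_activation_map",
    "save_section", "load_section",
    "save_cohort", "load_cohort",
    "load_config",
]


def save_stack(path: str | Path, stack: UltrafastStack) -> None:
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, frames=stack.frames.astype(np.complex64),
                 ultrafast_rate_hz=stack.ultrafast_rate_hz,
                 pixel_size_mm=np.asarray(stack.pixel_size_mm))
        return
    with h5py.File(path, "w") as f:
        d = f.create_dataset("frames", data=stack.frames.astype(np.complex64))
        d.attrs["ultrafast_rate_hz"] = stack.ultrafast_rate_hz
        d.attrs["pixel_size_mm"] = np.asarray(stack.pixel_size_mm)


def load_stack(path: str | Path) -> UltrafastStack:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            return UltrafastStack(z["frames"], float(z["ultrafast_rate_hz"]),
                                  tuple(z["pixel_size_mm"]))
    with h5py.File(path, "r") as f:
        d = f["frames"]
        return UltrafastStack(d[()], float(d.attrs["ultrafast_rate_hz"]),
                              tuple(d.attrs["pixel_size_mm"]))


def save_movie(path: str | Path, movie: PowerDopplerMovie) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("power", data=movie.power)
        d.attrs["frame_rate_hz"] = movie.frame_rate_hz
        d.attrs["block_size"] = movie.block_size


def load_movie(path: str | Path) -> PowerDopplerMovie:
    with h5py.File(path, "r") as f:
        d = f["power"]
        return PowerDopplerMovie(d[()], float(d.attrs["frame_rate_hz"]),
                                 int(d.attrs["block_size"]))


def save_activation_map(path: str | Path, amap: ActivationMap) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("z", data=amap.z)
        f.create_dataset("p", data=amap.p)
        f.create_dataset("active", data=amap.active.astype(np.uint8))
        f.create_dataset("brain_mask", data=amap.brain_mask.astype(np.uint8))
        f.attrs["alpha_family"] = amap.alpha_family
        f.attrs["n_tests"] = amap.n_tests


def load_activation_map(path: str | Path) -> ActivationMap:
    with h5py.File(path, "r") as f:
        return ActivationMap(
            z=f["z"][()], p=f["p"][()], active=f["active"][()].astype(bool),
            alpha_family=float(f.attrs["alpha_family"]), n_tests=int(f.attrs["n_tests"]),
            brain_mask=f["brain_mask"][()].astype(bool),
        )


def save_section(image_path: str | Path, image: np.ndarray,
                 mask_path: str | Path | None = None,
                 region_masks: np.ndarray | None = None,
                 region_labels: dict[str, int] | None = None) -> None:
    """Write a section image (and optionally its labelled masks) as TIFF.

    The label map travels as a JSON sidecar next to the mask TIFF.
    """
    tifffile.imwrite(str(image_path), np.asarray(image, dtype=np.uint8))
    if mask_path is not None and region_masks is not None:
        tifffile.imwrite(str(mask_path), np.asarray(region_masks, dtype=np.uint8))
        if region_labels is not None:
            Path(mask_path).with_suffix(".labels.json").write_text(json.dumps(region_labels))


def load_section(image_path: str | Path, mask_path: str | Path | None = None):
    image = tifffile.imread(str(image_path))
    if mask_path is None:
        return image
    masks = tifffile.imread(str(mask_path))
    labels_file = Path(mask_path).with_suffix(".labels.json")
    labels = json.loads(labels_file.read_text()) if labels_file.exists() else None
    return image, masks, labels


def save_cohort(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def load_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path: str | Path) -> dict:
    """One YAML mapping holding all generator parameters."""
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a YAML mapping at top level")
    return cfg
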