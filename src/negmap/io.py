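"""File round-trips for the package's tabular, image and volume data.

Plain-text CSV for trial and PSC tables and contour polylines, 16-bit TIFF
for GLI images (values in [0, 1] scaled to the full integer range), NIfTI-1
for volumes.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import tifffile

from .cytoarch import ContourPair, GLIImage
from .roi import VolumeGrid

TRIAL_COLUMNS = ["subject", "polarity", "probe_type", "proportion", "token",
                 "rt_ms", "correct", "ratio"]
PSC_COLUMNS = ["subject", "polarity", "probe_type", "phase", "psc"]


def write_trials_csv(trials: pd.DataFrame, path) -> None:
    cols = [c for c in TRIAL_COLUMNS if c in trials.columns]
    trials[cols].to_csv(path, index=False)


def read_trials_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["correct"] = df["correct"].astype(bool)
    return df


def write_psc_csv(psc: pd.DataFrame, path) -> None:
    psc[PSC_COLUMNS].to_csv(path, index=False)


def read_psc_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_gli_tiff(image: GLIImage, path) -> None:
    scaled = np.round(np.clip(image.values, 0, 1) * 65535).astype(np.uint16)
    tifffile.imwrite(str(path), scaled,
                     resolution=(1e4 / image.pixel_size_um,) * 2)


def read_gli_tiff(path, pixel_size_um: float) -> GLIImage:
    raw = tifffile.imread(str(path)).astype(float)
    return GLIImage(raw / 65535.0, pixel_size_um)


def write_contour_csv(poly: np.ndarray, path) -> None:
    pd.DataFrame(np.asarray(poly), columns=["x", "y"]).to_csv(path, index=False)


def read_contour_pair(outer_path, inner_path) -> ContourPair:
    outer = pd.read_csv(outer_path)[["x", "y"]].to_numpy(float)
    inner = pd.read_csv(inner_path)[["x", "y"]].to_numpy(float)
    return ContourPair(outer, inner)


def write_volume(grid: VolumeGrid, path) -> None:
    grid.save(path)


def read_volume(path) -> VolumeGrid:
    return VolumeGrid.from_nifti(path)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating, np.bool_)):
            return o.item()
        return vars(o)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
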