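"""File-format helpers for the command-line workflow.

CSV layouts:

* checker spectra: columns ``wavelength_nm, patch_01 ... patch_24`` with
  401 data rows (380-780 nm at 1 nm).
* captured RGB: columns ``patch_id, R, G, B`` with 8-bit integer values.
* illuminant: columns ``wavelength_nm, spd``.
* labels: columns ``subject_id, label`` with labels in
  {Normal, BDR, PPDR, PDR}.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from PIL import Image

from .colorimetry import Illuminant
from .grid import VISIBLE_GRID

__all__ = [
    "read_checker_spectra_csv",
    "read_captured_rgb_csv",
    "read_illuminant_csv",
    "read_labels_csv",
    "read_image",
    "write_mask_png",
    "read_mask_png",
]


def read_checker_spectra_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns:
        raise ValueError(f"{path}: missing 'wavelength_nm' column")
    patches = [c for c in df.columns if c != "wavelength_nm"]
    if len(df) != VISIBLE_GRID.count:
        raise ValueError(
            f"{path}: expected {VISIBLE_GRID.count} wavelength rows, got {len(df)}"
        )
    return df[patches].to_numpy(dtype=float)


def read_captured_rgb_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    for col in ("R", "G", "B"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing '{col}' column")
    rgb = df[["R", "G", "B"]].to_numpy(dtype=float)
    if rgb.max() > 1.0:  # 8-bit convention
        rgb = rgb / 255.0
    if rgb.min() < 0 or rgb.max() > 1:
        raise ValueError(f"{path}: RGB values outside [0, 255]")
    return rgb


def read_illuminant_csv(path) -> Illuminant:
    df = pd.read_csv(path)
    if len(df) != VISIBLE_GRID.count:
        raise ValueError(
            f"{path}: expected {VISIBLE_GRID.count} wavelength rows, got {len(df)}"
        )
    col = "spd" if "spd" in df.columns else df.columns[1]
    return Illuminant(df[col].to_numpy(dtype=float))


def read_labels_csv(path) -> pd.Series:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty label file")
    if "subject_id" not in df.columns or "label" not in df.columns:
        raise ValueError(f"{path}: need 'subject_id' and 'label' columns")
    return df.set_index("subject_id")["label"]


def read_image(path) -> np.ndarray:
    img = np.asarray(Image.open(path).convert("RGB"))
    return img


def write_mask_png(path, mask: np.ndarray) -> None:
    Image.fromarray((np.asarray(mask, dtype=bool) * 255).astype(np.uint8)).save(path)


def read_mask_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) > 127
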