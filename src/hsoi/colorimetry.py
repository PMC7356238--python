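"""CIE colorimetry primitives: sRGB transfer, tristimulus integration, CMCCAT2000.

These are the building blocks of the checker-based spectral calibration:

* the sRGB encoding/decoding nonlinearity and the 3x3 sRGB<->XYZ matrix,
* tristimulus integration X = k * sum S(l) R(l) xbar(l) over the 380-780 nm
  grid with k = 100 / sum S(l) ybar(l) (a perfect reflector has Y = 100),
* the CMCCAT2000 chromatic-adaptation transform between the measurement
  illuminant of the spectrophotometer and the D65 white of sRGB.

XYZ scale convention: spectrum-derived tristimulus values live on the
Y in [0, 100] scale; the sRGB matrix path natively produces Y in [0, 1] and
is multiplied by 100 wherever the two meet.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .grid import VISIBLE_GRID, WavelengthGrid

__all__ = [
    "SRGB_TO_XYZ",
    "XYZ_TO_SRGB",
    "SRGB_THRESHOLD",
    "Illuminant",
    "ColorMatchingFunctions",
    "load_cmf",
    "load_d65",
    "linearize_srgb",
    "encode_srgb",
    "srgb_to_xyz",
    "xyz_to_srgb",
    "spectrum_to_xyz",
    "cmccat2000_adapt",
    "D65_WHITE",
]

#: IEC 61966-2-1 linear-RGB -> XYZ matrix (the 4-decimal printed form).
SRGB_TO_XYZ = np.array(
    [
        [0.4124, 0.3576, 0.1805],
        [0.2126, 0.7152, 0.0722],
        [0.0193, 0.1192, 0.9505],
    ]
)
XYZ_TO_SRGB = np.linalg.inv(SRGB_TO_XYZ)

#: Encoded-domain branch point of the sRGB transfer function. The standard
#: value 0.04045 is used; it is the point where the two branches meet.
SRGB_THRESHOLD = 0.04045

#: White point of sRGB (row sums of the matrix, Y = 100 scale).
D65_WHITE = 100.0 * SRGB_TO_XYZ.sum(axis=1)

# CMCCAT2000 sharpened cone-response matrix (Li, Luo, Rigg & Hunt 2002).
_CAT_M = np.array(
    [
        [0.7982, 0.3389, -0.1371],
        [-0.5918, 1.5512, 0.0406],
        [0.0008, 0.0239, 0.9753],
    ]
)
_CAT_M_INV = np.linalg.inv(_CAT_M)


@dataclass(frozen=True)
class Illuminant:
    """Relative spectral power distribution on the visible grid."""

    spd: np.ndarray
    grid: WavelengthGrid = VISIBLE_GRID

    def __post_init__(self) -> None:
        spd = self.grid.check(self.spd, "illuminant SPD")
        if np.any(spd < 0):
            raise ValueError("illuminant SPD must be non-negative")
        object.__setattr__(self, "spd", spd)

    def white_point(self, cmf: "ColorMatchingFunctions") -> np.ndarray:
        """XYZ of the perfect reflector under this illuminant (Y = 100)."""
        return spectrum_to_xyz(np.ones(self.grid.count), self, cmf)


@dataclass(frozen=True)
class ColorMatchingFunctions:
    """CIE standard-observer weighting functions xbar, ybar, zbar."""

    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray
    grid: WavelengthGrid = VISIBLE_GRID

    def __post_init__(self) -> None:
        for name in ("xbar", "ybar", "zbar"):
            vals = self.grid.check(getattr(self, name), name)
            if np.any(vals < 0):
                raise ValueError(f"{name} must be non-negative")
            object.__setattr__(self, name, vals)

    @property
    def matrix(self) -> np.ndarray:
        """401x3 stack of the three functions."""
        return np.column_stack([self.xbar, self.ybar, self.zbar])


def _data_csv(name: str) -> np.ndarray:
    with resources.files("hsoi.data").joinpath(name).open("rb") as fh:
        return np.loadtxt(fh, delimiter=",", skiprows=1)


def load_cmf() -> ColorMatchingFunctions:
    """Packaged CIE 1931 2-degree observer table (analytic-fit, synthetic)."""
    tab = _data_csv("cmf_cie1931_2deg_synthetic.csv")
    return ColorMatchingFunctions(tab[:, 1], tab[:, 2], tab[:, 3])


def load_d65() -> Illuminant:
    """Packaged D65-like daylight SPD (Planckian 6504 K, synthetic)."""
    tab = _data_csv("illuminant_d65_synthetic.csv")
    return Illuminant(tab[:, 1])


def linearize_srgb(v):
    """Decode sRGB-encoded channel values in [0, 1] to linear light."""
    v = np.asarray(v, dtype=float)
    if np.any(v < 0) or np.any(v > 1):
        raise ValueError("encoded sRGB values must lie in [0, 1]")
    out = np.where(
        v > SRGB_THRESHOLD,
        ((v + 0.055) / 1.055) ** 2.4,
        v / 12.92,
    )
    return out if out.ndim else float(out)


def encode_srgb(v):
    """Inverse of :func:`linearize_srgb` (linear light -> encoded)."""
    v = np.asarray(v, dtype=float)
    lin_thresh = SRGB_THRESHOLD / 12.92
    with np.errstate(invalid="ignore"):
        out = np.where(
            v > lin_thresh,
            1.055 * np.clip(v, 0.0, None) ** (1.0 / 2.4) - 0.055,
            v * 12.92,
        )
    return out if out.ndim else float(out)


def srgb_to_xyz(rgb) -> np.ndarray:
    """Encoded sRGB triplet(s) -> XYZ on the matrix's native Y in [0,1] scale.

    Accepts shape (..., 3); returns the same shape.
    """
    rgb = np.asarray(rgb, dtype=float)
    lin = linearize_srgb(rgb)
    return lin @ SRGB_TO_XYZ.T


def xyz_to_srgb(xyz, return_flag: bool = False):
    """XYZ (Y in [0,1] scale) -> encoded sRGB, clipping out-of-gamut values.

    Returns the encoded triplet(s); with ``return_flag=True`` also returns a
    boolean (or boolean array over the leading axes) marking where clipping
    occurred.
    """
    xyz = np.asarray(xyz, dtype=float)
    lin = xyz @ XYZ_TO_SRGB.T
    clipped_low = lin < 0.0
    lin = np.clip(lin, 0.0, None)
    enc = encode_srgb(lin)
    clipped_high = enc > 1.0
    enc = np.clip(enc, 0.0, 1.0)
    if return_flag:
        flag = np.any(clipped_low | clipped_high, axis=-1)
        return enc, (bool(flag) if flag.ndim == 0 else flag)
    return enc


def spectrum_to_xyz(
    reflectance, ill: Illuminant, cmf: ColorMatchingFunctions | None = None
) -> np.ndarray:
    """Tristimulus values of reflectance spectra under an illuminant.

    ``reflectance`` has shape (..., 401); the integral is the 1 nm rectangle
    sum, normalized so the perfect reflector has Y = 100.
    """
    if cmf is None:
        cmf = load_cmf()
    if ill.grid != cmf.grid:
        raise ValueError("illuminant and CMF grids differ")
    r = ill.grid.check(reflectance, "reflectance")
    k = 100.0 / float(ill.spd @ cmf.ybar)
    weights = ill.spd[:, None] * cmf.matrix  # 401x3
    return k * (r @ weights)


def cmccat2000_adapt(
    xyz, white_src, white_dst, degree: float = 1.0
) -> np.ndarray:
    """CMCCAT2000 chromatic adaptation from one white point to another.

    ``xyz`` has shape (..., 3) on the Y in [0, 100] scale; ``degree`` is the
    degree of adaptation D in [0, 1] (1 = complete). With D = 0 or equal
    whites the transform is the identity; the reverse adaptation (whites
    swapped) is its exact inverse.
    """
    if not 0.0 <= degree <= 1.0:
        raise ValueError("degree of adaptation must lie in [0, 1]")
    white_src = np.asarray(white_src, dtype=float)
    white_dst = np.asarray(white_dst, dtype=float)
    if white_src[1] <= 0 or white_dst[1] <= 0:
        raise ValueError("white points must have positive luminance Y")
    xyz = np.asarray(xyz, dtype=float)
    rgb = xyz @ _CAT_M.T
    rgb_ws = _CAT_M @ white_src
    rgb_wd = _CAT_M @ white_dst
    lum_ratio = white_src[1] / white_dst[1]
    scale = degree * lum_ratio * (rgb_wd / rgb_ws) + (1.0 - degree)
    return (rgb * scale) @ _CAT_M_INV.T
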