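"""Checker-based spectral calibration and per-pixel spectrum reconstruction.

The method relates a camera's sRGB output to full 380-780 nm reflectance
spectra using a 24-patch color checker measured with a spectrophotometer:

1.  The 401x24 checker spectra matrix ``D`` is reduced to a 6-row
    orthonormal eigenvector basis ``E`` (uncentered principal components of
    ``D D^T``), with coefficients ``alpha^T = D^T pinv(E)``.
2.  Target sRGB values ``A`` for each patch are computed from the measured
    spectra (tristimulus integration under the measurement illuminant,
    CMCCAT2000 adaptation to the D65 white of sRGB, inverse sRGB matrix).
3.  A 3x20 color-correction matrix ``C = A pinv(F)`` maps third-order
    polynomial features ``F`` of the captured RGB onto the targets.
4.  A transformation matrix ``M = alpha pinv(beta)`` links the corrected
    captures (as XYZ, adapted back to the measurement illuminant) to the
    spectral coefficients.

A new pixel is then reconstructed as ``spectrum = E^T M XYZ``. Because XYZ
has only three degrees of freedom, the reconstruction spans at most a
3-dimensional family of spectra; the basis restricts it to plausible smooth
reflectances but metameric detail beyond rank 3 is irrecoverable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import colorimetry as cm
from .grid import VISIBLE_GRID, WavelengthGrid

__all__ = [
    "CalibrationError",
    "CalibrationModel",
    "fit_basis",
    "spectral_coefficients",
    "polynomial_expand",
    "fit_color_correction",
    "correct_rgb",
    "fit_transformation",
    "reconstruct_spectrum",
    "calibrate",
    "image_to_cube",
]

#: Relative singular-value cutoff used by every pseudoinverse in the fit.
PINV_RCOND = 1e-10

#: Reconstructed reflectance is clipped to this range (slight overshoot
#: above 1 is physical for a regression-based estimate).
REFLECTANCE_CLIP = (0.0, 1.5)

MODEL_SCHEMA_VERSION = 1


class CalibrationError(RuntimeError):
    """Raised when a calibration stage cannot be fitted."""


def fit_basis(d: np.ndarray, n_basis: int = 6) -> np.ndarray:
    """Leading eigenvectors of the checker spectra's second-moment structure.

    ``d`` is the 401 x n_patches spectra matrix. The basis is fitted
    *uncentered* (left singular vectors of ``d``, equivalently eigenvectors
    of ``d d^T``) so that spectra are reconstructed as ``E^T alpha`` with no
    mean term. Rows are ordered by decreasing eigenvalue; each row's
    largest-magnitude entry is made positive.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != VISIBLE_GRID.count:
        raise ValueError(f"spectra matrix must be {VISIBLE_GRID.count} x n_patches")
    if not np.all(np.isfinite(d)):
        raise ValueError("spectra matrix contains non-finite values")
    u, s, _ = np.linalg.svd(d, full_matrices=False)
    rank = int(np.sum(s > s[0] * PINV_RCOND)) if s[0] > 0 else 0
    if rank < n_basis:
        raise CalibrationError(
            f"checker spectra have rank {rank}, need at least {n_basis} "
            "for the requested basis"
        )
    e = u[:, :n_basis].T  # n_basis x 401
    signs = np.sign(e[np.arange(n_basis), np.argmax(np.abs(e), axis=1)])
    return e * signs[:, None]


def spectral_coefficients(d: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Coordinates alpha of each checker spectrum in the basis.

    Computed literally as ``alpha^T = d^T pinv(e)``; for an orthonormal
    basis this equals the least-squares projection coefficients.
    """
    d = np.asarray(d, dtype=float)
    e = np.asarray(e, dtype=float)
    if d.shape[0] != e.shape[1]:
        raise ValueError("spectra and basis wavelength axes differ")
    return (d.T @ np.linalg.pinv(e, rcond=PINV_RCOND)).T


def polynomial_expand(rgb: np.ndarray) -> np.ndarray:
    """Third-order polynomial feature vector of an RGB triplet.

    Shape (..., 3) -> (..., 20), monomials in the fixed order
    [1, R, G, B, RG, GB, BR, R2, G2, B2, RGB, R3, G3, B3,
    RG2, RB2, GR2, GB2, BR2, BG2].
    """
    rgb = np.asarray(rgb, dtype=float)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    return np.stack(
        [
            np.ones_like(r),
            r, g, b,
            r * g, g * b, b * r,
            r**2, g**2, b**2,
            r * g * b,
            r**3, g**3, b**3,
            r * g**2, r * b**2, g * r**2, g * b**2, b * r**2, b * g**2,
        ],
        axis=-1,
    )


def fit_color_correction(a: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Least-squares color-correction matrix ``C = A pinv(F)``.

    ``a`` is 3 x n (target RGB per patch), ``f`` is 20 x n (polynomial
    features of the captured RGB).
    """
    a = np.asarray(a, dtype=float)
    f = np.asarray(f, dtype=float)
    if a.shape[1] != f.shape[1]:
        raise ValueError("target and feature sample counts differ")
    if np.linalg.matrix_rank(f) < min(f.shape):
        warnings.warn(
            "polynomial feature matrix is rank-deficient; the color "
            "correction uses the minimum-norm least-squares solution",
            stacklevel=2,
        )
    return a @ np.linalg.pinv(f, rcond=PINV_RCOND)


def correct_rgb(c: np.ndarray, rgb: np.ndarray, return_flag: bool = False):
    """Apply the color correction to encoded RGB value(s) in [0, 1]."""
    feats = polynomial_expand(rgb)
    out = feats @ np.asarray(c, dtype=float).T
    clipped = np.any((out < 0.0) | (out > 1.0), axis=-1)
    out = np.clip(out, 0.0, 1.0)
    if return_flag:
        return out, (bool(clipped) if clipped.ndim == 0 else clipped)
    return out


def fit_transformation(alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Camera-to-spectrophotometer transformation ``M = alpha pinv(beta)``."""
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if alpha.shape[1] != beta.shape[1]:
        raise ValueError("alpha and beta sample counts differ")
    if np.linalg.matrix_rank(beta) < min(beta.shape[0], 3):
        raise CalibrationError("corrected-capture matrix beta has rank < 3")
    return alpha @ np.linalg.pinv(beta, rcond=PINV_RCOND)


@dataclass
class CalibrationModel:
    """Fitted calibration: basis, coefficients, color correction, transform.

    ``beta_mode`` selects the regressor behind ``M``: ``"xyz"`` (default)
    uses the 3-vector of adapted tristimulus values (``M`` is 6x3, matching
    spectrum = E^T M XYZ); ``"poly"`` uses the 20-vector of polynomial
    features of the corrected RGB (``M`` is 6x20).
    """

    basis: np.ndarray             # n_basis x 401
    alpha: np.ndarray             # n_basis x 24
    color_correction: np.ndarray  # 3 x 20
    transformation: np.ndarray    # n_basis x 3 (or n_basis x 20)
    illuminant_spd: np.ndarray    # 401
    white_src: np.ndarray         # illuminant white, Y in [0,100]
    white_dst: np.ndarray         # sRGB/D65 white, Y in [0,100]
    beta_mode: str = "xyz"
    adapt_degree: float = 1.0
    adapt_at_inference: bool = True
    grid: WavelengthGrid = field(default_factory=lambda: VISIBLE_GRID)

    def __post_init__(self) -> None:
        n_basis = self.basis.shape[0]
        if self.basis.shape[1] != self.grid.count:
            raise ValueError("basis does not match the wavelength grid")
        if self.alpha.shape[0] != n_basis:
            raise ValueError("alpha and basis disagree on n_basis")
        expected_cols = 3 if self.beta_mode == "xyz" else 20
        if self.transformation.shape != (n_basis, expected_cols):
            raise ValueError(
                f"transformation must be {n_basis}x{expected_cols} "
                f"for beta_mode={self.beta_mode!r}"
            )

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        """Serialize with matrices as decimal strings (bit-exact round trip)."""
        def enc(a: np.ndarray):
            return np.vectorize(lambda x: repr(float(x)))(np.asarray(a)).tolist()

        doc = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "grid": {"start": self.grid.start, "stop": self.grid.stop,
                     "step": self.grid.step},
            "beta_mode": self.beta_mode,
            "adapt_degree": self.adapt_degree,
            "adapt_at_inference": self.adapt_at_inference,
            "basis": enc(self.basis),
            "alpha": enc(self.alpha),
            "color_correction": enc(self.color_correction),
            "transformation": enc(self.transformation),
            "illuminant_spd": enc(self.illuminant_spd),
            "white_src": enc(self.white_src),
            "white_dst": enc(self.white_dst),
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        doc = json.loads(text)
        if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ValueError("unsupported model schema version")

        def dec(x):
            return np.asarray(x, dtype=float)

        g = doc["grid"]
        return cls(
            basis=dec(doc["basis"]),
            alpha=dec(doc["alpha"]),
            color_correction=dec(doc["color_correction"]),
            transformation=dec(doc["transformation"]),
            illuminant_spd=dec(doc["illuminant_spd"]),
            white_src=dec(doc["white_src"]),
            white_dst=dec(doc["white_dst"]),
            beta_mode=doc["beta_mode"],
            adapt_degree=doc["adapt_degree"],
            adapt_at_inference=doc["adapt_at_inference"],
            grid=WavelengthGrid(g["start"], g["stop"], g["step"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            return cls.from_json(fh.read())

    # -- inference helpers ------------------------------------------------
    def regressor_from_rgb(self, rgb: np.ndarray) -> np.ndarray:
        """Corrected capture -> the regressor fed to ``M`` (XYZ or features)."""
        corrected = correct_rgb(self.color_correction, rgb)
        if self.beta_mode == "poly":
            return polynomial_expand(corrected)
        xyz = 100.0 * cm.srgb_to_xyz(corrected)
        if self.adapt_at_inference:
            xyz = cm.cmccat2000_adapt(
                xyz, self.white_dst, self.white_src, self.adapt_degree
            )
        return xyz


def reconstruct_spectrum(
    model: CalibrationModel, xyz: np.ndarray, return_flag: bool = False
):
    """Reconstruct reflectance spectra as ``E^T M XYZ`` (shape (..., 401)).

    ``xyz`` is the regressor on the model's native scale (tristimulus with
    Y in [0, 100] for ``beta_mode="xyz"``; 20 polynomial features for
    ``"poly"``). Values are clipped to [0, 1.5].
    """
    xyz = np.asarray(xyz, dtype=float)
    spectra = xyz @ (model.basis.T @ model.transformation).T
    lo, hi = REFLECTANCE_CLIP
    clipped = np.any((spectra < lo) | (spectra > hi), axis=-1)
    spectra = np.clip(spectra, lo, hi)
    if return_flag:
        return spectra, (bool(clipped) if clipped.ndim == 0 else clipped)
    return spectra


def calibrate(
    checker_spectra: np.ndarray,
    captured_rgb: np.ndarray,
    ill: cm.Illuminant,
    cmf: cm.ColorMatchingFunctions | None = None,
    n_basis: int = 6,
    beta_mode: str = "xyz",
    adapt_degree: float = 1.0,
) -> CalibrationModel:
    """Fit the full checker calibration.

    Parameters
    ----------
    checker_spectra
        401 x 24 reflectance matrix ``D`` measured by the spectrophotometer.
    captured_rgb
        24 x 3 encoded sRGB values of the same patches as captured by the
        camera, in [0, 1].
    ill
        Spectral power distribution of the light the checker was measured
        under (also the light the camera saw).
    """
    if cmf is None:
        cmf = cm.load_cmf()
    d = np.asarray(checker_spectra, dtype=float)
    captured = np.asarray(captured_rgb, dtype=float)
    if captured.ndim != 2 or captured.shape[1] != 3:
        raise ValueError("captured_rgb must be n_patches x 3")
    if captured.shape[0] != d.shape[1]:
        raise ValueError("spectra and captured RGB patch counts differ")

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except (ValueError, CalibrationError) as err:
            raise CalibrationError(f"calibration stage '{name}': {err}") from err

    e = stage("fit_basis", fit_basis, d, n_basis)
    alpha = stage("spectral_coefficients", spectral_coefficients, d, e)

    # Standard matrix A: measured spectra -> XYZ under the measurement
    # illuminant -> adapt to the D65 white of sRGB -> encoded sRGB targets.
    white_src = ill.white_point(cmf)
    white_dst = cm.D65_WHITE
    xyz_meas = stage("spectrum_to_xyz", cm.spectrum_to_xyz, d.T, ill, cmf)
    xyz_d65 = cm.cmccat2000_adapt(xyz_meas, white_src, white_dst, adapt_degree)
    a = cm.xyz_to_srgb(xyz_d65 / 100.0).T  # 3 x 24

    f = polynomial_expand(captured).T  # 20 x 24
    c = stage("fit_color_correction", fit_color_correction, a, f)
    corrected = correct_rgb(c, captured)  # 24 x 3

    if beta_mode == "poly":
        beta = polynomial_expand(corrected).T  # 20 x 24
    elif beta_mode == "xyz":
        xyz_corr = 100.0 * cm.srgb_to_xyz(corrected)
        xyz_corr = cm.cmccat2000_adapt(xyz_corr, white_dst, white_src, adapt_degree)
        beta = xyz_corr.T  # 3 x 24
    else:
        raise ValueError("beta_mode must be 'xyz' or 'poly'")
    m = stage("fit_transformation", fit_transformation, alpha, beta)

    return CalibrationModel(
        basis=e,
        alpha=alpha,
        color_correction=c,
        transformation=m,
        illuminant_spd=ill.spd,
        white_src=white_src,
        white_dst=white_dst,
        beta_mode=beta_mode,
        adapt_degree=adapt_degree,
    )


def image_to_cube(image: np.ndarray, model: CalibrationModel) -> np.ndarray:
    """Reconstruct the H x W x 401 reflectance cube of an 8-bit RGB image."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be H x W x 3 RGB")
    rgb = img.astype(float) / 255.0 if img.dtype == np.uint8 else img.astype(float)
    h, w = rgb.shape[:2]
    regressor = model.regressor_from_rgb(rgb.reshape(-1, 3))
    spectra = reconstruct_spectrum(model, regressor)
    return spectra.reshape(h, w, model.grid.count).astype(np.float32)
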