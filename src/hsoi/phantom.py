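"""Seeded synthetic data: checker spectra, camera captures, fundus phantoms.

Everything the pipeline consumes can be generated here with known ground
truth, so calibration, segmentation, oximetry and staging are testable
end-to-end without any external data:

* :func:`generate_checker_spectra` - smooth random reflectances of known
  spectral rank, standing in for a measured 24-patch color checker.
* :func:`simulate_capture` - the exact forward camera model of the
  calibration chain (spectrum -> XYZ -> chromatic adaptation -> sRGB), plus
  optional Gaussian sensor noise.
* :func:`generate_fundus_phantom` - a circular-field fundus image with
  curvilinear vessels whose per-pixel spectra follow the two-chromophore
  Beer-Lambert forward model at a prescribed oxygen saturation, rendered to
  RGB through :func:`simulate_capture`. The returned ground truth (vessel
  mask, artery/vein labels, SO2 map, reflectance cube) uses exactly the
  same hemoglobin extinction table the oximetry module consumes.

Every generator is a pure function of its seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from . import colorimetry as cm
from .grid import VISIBLE_GRID
from .oximetry import VesselGeometry, load_extinction

__all__ = [
    "PhantomSpec",
    "PhantomOutput",
    "generate_checker_spectra",
    "simulate_capture",
    "generate_fundus_phantom",
]


def generate_checker_spectra(
    seed: int, n_patches: int = 24, basis_dim: int = 6
) -> np.ndarray:
    """Random smooth reflectance spectra of exact rank ``basis_dim``.

    Returns the 401 x ``n_patches`` matrix D. Each column is a non-negative
    combination of ``basis_dim`` Gaussian bumps spanning 380-780 nm, scaled
    into [0.02, 0.95].
    """
    if basis_dim > n_patches:
        raise ValueError("basis_dim cannot exceed n_patches")
    rng = np.random.default_rng(seed)
    lam = VISIBLE_GRID.wavelengths
    centers = np.linspace(360.0, 800.0, basis_dim)
    sigma = 0.8 * (centers[-1] - centers[0]) / max(basis_dim - 1, 1)
    bumps = np.exp(-0.5 * ((lam[:, None] - centers[None, :]) / sigma) ** 2)
    coeffs = rng.uniform(0.3, 1.0, size=(basis_dim, n_patches))
    raw = bumps @ coeffs  # 401 x n_patches
    scale = 0.95 * rng.uniform(0.5, 1.0, size=n_patches) / raw.max(axis=0)
    return raw * scale


def simulate_capture(
    spectra: np.ndarray,
    ill: cm.Illuminant,
    noise_sigma: float = 0.0,
    seed: int = 0,
    cmf: cm.ColorMatchingFunctions | None = None,
) -> np.ndarray:
    """Forward camera model: reflectance spectra -> encoded sRGB captures.

    ``spectra`` is 401 x N (columns are patches/pixels); returns N x 3
    encoded sRGB in [0, 1]. Gaussian noise of standard deviation
    ``noise_sigma`` is added in the encoded domain and the result clipped.
    """
    if cmf is None:
        cmf = cm.load_cmf()
    xyz = cm.spectrum_to_xyz(np.asarray(spectra, dtype=float).T, ill, cmf)
    white_src = ill.white_point(cmf)
    xyz_d65 = cm.cmccat2000_adapt(xyz, white_src, cm.D65_WHITE)
    rgb = cm.xyz_to_srgb(xyz_d65 / 100.0)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        rgb = rgb + rng.normal(0.0, noise_sigma, size=rgb.shape)
    return np.clip(rgb, 0.0, 1.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic fundus phantom."""

    shape: tuple[int, int] = (192, 192)
    n_vessels: int = 6
    width_range: tuple[float, float] = (3.0, 7.0)
    artery_so2: float = 0.95
    vein_so2: float = 0.60
    #: Total hemoglobin concentration (molar) inside vessels; the default
    #: puts the 570 nm vessel absorbance around 0.6-0.7, i.e. mid-range
    #: vessel darkness and a well-conditioned oximetry system.
    total_hb_molar: float = 1.2e-3
    background_variation: float = 0.03
    disc_radius_frac: float = 0.11
    with_disc: bool = True
    noise_sigma: float = 0.0
    fov_margin_px: int = 4
    #: Vessels are drawn with this clearance from the FOV boundary: the
    #: peripheral rim of real fundus photographs is dominated by vignetting
    #: and is excluded from vessel annotation, so the phantom's ground truth
    #: covers only the annotatable interior.
    vessel_clearance_px: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.artery_so2 <= 1 and 0 <= self.vein_so2 <= 1):
            raise ValueError("SO2 values must lie in [0, 1]")
        if self.width_range[0] < 2:
            raise ValueError("vessel widths below 2 px are not resolvable")
        if min(self.shape) < 64:
            raise ValueError("phantom must be at least 64 x 64")


@dataclass
class PhantomOutput:
    """Rendered phantom plus every ground-truth layer."""

    image: np.ndarray          # H x W x 3 uint8
    mask: np.ndarray           # H x W bool vessel mask
    labels: np.ndarray         # H x W int (0 bg, 1 artery, 2 vein)
    so2: np.ndarray            # H x W float, NaN off-vessel
    cube: np.ndarray           # H x W x 401 float32 true reflectance
    fov_center: tuple[float, float]
    fov_radius: float
    spec: PhantomSpec = field(repr=False)


def _background_reflectance(lam: np.ndarray) -> np.ndarray:
    """Smooth reddish fundus spectrum: dark blue-green, bright red."""
    return 0.08 + 0.55 / (1.0 + np.exp(-(lam - 585.0) / 18.0))


def _disc_reflectance(lam: np.ndarray) -> np.ndarray:
    """Bright yellowish optic-disc spectrum."""
    return 0.35 + 0.45 / (1.0 + np.exp(-(lam - 500.0) / 25.0))


def _vessel_paths(spec: PhantomSpec, rng: np.random.Generator):
    """Random smooth curvilinear vessel centrelines through the FOV."""
    h, w = spec.shape
    paths = []
    for _ in range(spec.n_vessels):
        # endpoints on opposite image sides, interior control points jittered
        horizontal = rng.random() < 0.5
        n_ctrl = 5
        t = np.linspace(0.0, 1.0, n_ctrl)
        along = t * (w - 1) if horizontal else t * (h - 1)
        across0 = rng.uniform(0.15, 0.85) * (h - 1 if horizontal else w - 1)
        across = across0 + np.concatenate(
            [[0.0], rng.uniform(-0.18, 0.18, n_ctrl - 2) * min(h, w), [0.0]]
        ).cumsum()
        across = np.clip(across, 0, (h - 1 if horizontal else w - 1))
        cs = CubicSpline(t, np.column_stack([along, across]))
        dense = cs(np.linspace(0.0, 1.0, 40 * max(h, w) // 64))
        if horizontal:
            cols, rows = dense[:, 0], dense[:, 1]
        else:
            rows, cols = dense[:, 0], dense[:, 1]
        width = rng.uniform(*spec.width_range)
        paths.append((rows, cols, width))
    return paths


def generate_fundus_phantom(spec: PhantomSpec | None = None) -> PhantomOutput:
    """Render a fundus phantom with full ground truth (see module docs)."""
    if spec is None:
        spec = PhantomSpec()
    if spec.n_vessels > 20:
        raise ValueError("cannot place more than 20 vessels without overlap saturation")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    lam = VISIBLE_GRID.wavelengths
    ext = load_extinction()
    geom = VesselGeometry()
    ill = cm.load_d65()
    cmf = cm.load_cmf()

    yy, xx = np.mgrid[0:h, 0:w]
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    radius = min(h, w) / 2.0 - spec.fov_margin_px
    fov = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2

    # background with mild smooth multiplicative variation
    variation = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=12)
    variation /= max(np.abs(variation).max(), 1e-12)
    mult = 1.0 + spec.background_variation * variation
    r_bg = _background_reflectance(lam)

    # vessel mask / labels (pre-anti-aliasing stroke is the ground truth)
    mask = np.zeros((h, w), dtype=bool)
    labels = np.zeros((h, w), dtype=np.int8)
    so2_of_label = {1: spec.artery_so2, 2: spec.vein_so2}
    for i, (rows, cols, width) in enumerate(_vessel_paths(spec, rng)):
        lab = 1 if i % 2 == 0 else 2
        stroke = np.zeros((h, w), dtype=bool)
        rr = np.clip(np.round(rows).astype(int), 0, h - 1)
        cc = np.clip(np.round(cols).astype(int), 0, w - 1)
        stroke[rr, cc] = True
        n_dil = max(int(round((width - 1) / 2)), 0)
        if n_dil:
            stroke = ndimage.binary_dilation(
                stroke, structure=ndimage.generate_binary_structure(2, 2),
                iterations=n_dil,
            )
        r_inner = radius - spec.vessel_clearance_px
        stroke &= (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= r_inner**2
        labels[stroke & ~mask] = lab
        mask |= stroke

    # true reflectance cube
    cube = np.empty((h, w, lam.size), dtype=np.float32)
    cube[:] = (mult[:, :, None] * r_bg[None, None, :]).astype(np.float32)

    if spec.with_disc:
        disc_r = spec.disc_radius_frac * min(h, w)
        disc_c = (center[0] - 0.25 * radius, center[1] + 0.45 * radius)
        disc = (yy - disc_c[0]) ** 2 + (xx - disc_c[1]) ** 2 <= disc_r**2
        disc &= fov & ~mask
        cube[disc] = _disc_reflectance(lam).astype(np.float32)

    eps_hbo2, eps_hb = ext.on_grid(VISIBLE_GRID)
    so2_map = np.full((h, w), np.nan)
    for lab in (1, 2):
        sel = labels == lab
        if not sel.any():
            continue
        s = so2_of_label[lab]
        d = geom.path_cm("artery" if lab == 1 else "vein")
        c1 = s * spec.total_hb_molar
        c2 = (1.0 - s) * spec.total_hb_molar
        atten = 10.0 ** (-(d * (c1 * eps_hbo2 + c2 * eps_hb)))
        cube[sel] = (cube[sel] * atten[None, :].astype(np.float32))
        so2_map[sel] = s

    cube[~fov] = 0.0

    # render to RGB through the forward camera model
    flat = cube.reshape(-1, lam.size).T.astype(float)
    rgb = simulate_capture(flat, ill, spec.noise_sigma, spec.seed + 1, cmf)
    image = np.round(rgb.reshape(h, w, 3) * 255.0).astype(np.uint8)
    image[~fov] = 0

    return PhantomOutput(
        image=image,
        mask=mask,
        labels=labels.astype(int),
        so2=so2_map,
        cube=cube,
        fov_center=center,
        fov_radius=radius,
        spec=spec,
    )
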