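"""Regenerate the packaged spectral data tables under src/hsoi/data/.

All three tables are synthetic analytic stand-ins for measured reference
data (see each file's header comment); they are committed so the package is
fully self-contained and deterministic.
"""

from __future__ import annotations

import pathlib

import numpy as np

DATA = pathlib.Path(__file__).resolve().parents[1] / "src" / "hsoi" / "data"

LAM = 380.0 + np.arange(401)


def _lobe(lam: np.ndarray, mu: float, s_lo: float, s_hi: float) -> np.ndarray:
    """Piecewise Gaussian lobe with different widths below/above the peak."""
    s = np.where(lam < mu, s_lo, s_hi)
    return np.exp(-0.5 * ((lam - mu) / s) ** 2)


def cmf_table(lam: np.ndarray) -> np.ndarray:
    """CIE 1931 2-degree observer via a multi-lobe piecewise-Gaussian fit."""
    xbar = (
        1.056 * _lobe(lam, 599.8, 37.9, 31.0)
        + 0.362 * _lobe(lam, 442.0, 16.0, 26.7)
        - 0.065 * _lobe(lam, 501.1, 20.4, 26.2)
    )
    ybar = 0.821 * _lobe(lam, 568.8, 46.9, 40.5) + 0.286 * _lobe(lam, 530.9, 16.3, 31.1)
    zbar = 1.217 * _lobe(lam, 437.0, 11.8, 36.0) + 0.681 * _lobe(lam, 459.0, 26.0, 13.8)
    return np.clip(np.column_stack([xbar, ybar, zbar]), 0.0, None)


def d65_spd(lam: np.ndarray) -> np.ndarray:
    """Planckian 6504 K relative SPD, normalized to 100 at 560 nm."""
    h, c, kb = 6.62607015e-34, 2.99792458e8, 1.380649e-23
    T = 6504.0
    lm = lam * 1e-9
    planck = (1.0 / lm**5) / (np.exp(h * c / (lm * kb * T)) - 1.0)
    ref = np.interp(560.0, lam, planck)
    return 100.0 * planck / ref


def hemoglobin_tables(lam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic molar extinction spectra (cm^-1 M^-1) for HbO2 and Hb.

    Gaussian Soret and Q bands plus red/NIR tails, shaped to match the
    qualitative features of the measured hemoglobin spectra: oxyhemoglobin
    with a ~415 nm Soret peak and 542/577 nm Q-band doublet, deoxyhemoglobin
    with a ~432 nm Soret peak and a single broad ~556 nm band, near-equal
    values around 570 nm and a large deoxy/oxy contrast at 600-700 nm.
    """

    def g(mu: float, s: float) -> np.ndarray:
        return np.exp(-0.5 * ((lam - mu) / s) ** 2)

    eps_hbo2 = (
        480000.0 * g(415.0, 9.0)
        + 30000.0 * g(390.0, 16.0)
        + 52000.0 * g(542.0, 13.0)
        + 54000.0 * g(577.0, 10.0)
        + 1200.0 * g(480.0, 45.0)
        + 300.0
        + 600.0 / (1.0 + np.exp(-(lam - 700.0) / 30.0))
    )
    eps_hb = (
        520000.0 * g(432.0, 11.0)
        + 35000.0 * g(390.0, 18.0)
        + 54000.0 * g(556.0, 22.0)
        + 2500.0 * g(480.0, 45.0)
        + 900.0
        + 5500.0 * np.exp(-np.clip(lam - 590.0, 0.0, None) / 80.0)
        * 1.0 / (1.0 + np.exp(-(lam - 590.0) / 8.0))
        + 1400.0 * g(758.0, 30.0)
    )
    return eps_hbo2, eps_hb


def write_csv(path: pathlib.Path, header: str, cols: list[np.ndarray]) -> None:
    rows = np.column_stack([LAM] + cols)
    fmt = ["%.1f"] + ["%.6e"] * len(cols)
    np.savetxt(path, rows, fmt=fmt, delimiter=",", header=header, comments="")
    print("wrote", path)


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    cmf = cmf_table(LAM)
    write_csv(
        DATA / "cmf_cie1931_2deg_synthetic.csv",
        "wavelength_nm,xbar,ybar,zbar",
        [cmf[:, 0], cmf[:, 1], cmf[:, 2]],
    )
    write_csv(
        DATA / "illuminant_d65_synthetic.csv",
        "wavelength_nm,spd",
        [d65_spd(LAM)],
    )
    hbo2, hb = hemoglobin_tables(LAM)
    write_csv(
        DATA / "hemoglobin_extinction_synthetic.csv",
        "wavelength_nm,eps_hbo2_cm1M1,eps_hb_cm1M1",
        [hbo2, hb],
    )


if __name__ == "__main__":
    main()
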