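"""Wavelength sampling grid for all spectral quantities.

Every spectrum in this package — checker reflectances, illuminant power
distributions, color-matching functions, reconstructed per-pixel spectra and
hemoglobin extinction coefficients — lives on a single common grid covering
the visible range 380–780 nm sampled at 1 nm (401 points).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WavelengthGrid", "VISIBLE_GRID"]


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid in nanometres."""

    start: float = 380.0
    stop: float = 780.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if self.stop <= self.start or self.step <= 0:
            raise ValueError("grid must be strictly increasing")
        n = (self.stop - self.start) / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("step must divide the span exactly")

    @property
    def count(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.count)

    def check(self, values: np.ndarray, name: str = "spectrum") -> np.ndarray:
        """Validate that ``values``' last axis matches this grid."""
        arr = np.asarray(values, dtype=float)
        if arr.shape[-1] != self.count:
            raise ValueError(
                f"{name} has {arr.shape[-1]} samples, expected {self.count} "
                f"on the {self.start}-{self.stop} nm grid"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} contains non-finite values")
        return arr


#: The 380–780 nm, 1 nm grid (401 samples) used throughout.
VISIBLE_GRID = WavelengthGrid()
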