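"""Core record types: spectra and laboratory phenolic measurements.

A :class:`Spectrum` is one sample's reflectance trace over an ordered
wavelength grid together with its identity metadata (cultivar code and
harvest cut).  A :class:`PhenolicRecord` is the wet-lab total phenolic
content (TPC) of the same sample in mg gallic-acid equivalents per gram
dry weight (mg GAE/gDW).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


@dataclass
class Spectrum:
    """Reflectance of one sample over a strictly increasing wavelength grid.

    Parameters
    ----------
    sample_id
        Unique sample identifier.
    cultivar
        Cultivar code (e.g. ``"OC063"``).
    cut
        Harvest round, 1-based; proxies plant age.
    wavelengths_nm
        Strictly increasing wavelength grid in nanometres.
    reflectance
        Non-negative reflectance, one value per wavelength.
    meta
        Free-form annotations (e.g. ``{"injected_outlier": True}``).
    """

    sample_id: str
    cultivar: str
    cut: int
    wavelengths_nm: np.ndarray
    reflectance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths_nm.ndim != 1 or self.reflectance.ndim != 1:
            raise ValidationError(f"{self.sample_id}: wavelengths and reflectance must be 1-D")
        if len(self.wavelengths_nm) != len(self.reflectance):
            raise ValidationError(
                f"{self.sample_id}: {len(self.wavelengths_nm)} wavelengths "
                f"but {len(self.reflectance)} reflectance values"
            )
        if len(self.wavelengths_nm) >= 2 and not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValidationError(f"{self.sample_id}: wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValidationError(f"{self.sample_id}: non-finite reflectance values")

    @property
    def n_bands(self) -> int:
        return len(self.wavelengths_nm)

    def with_reflectance(self, reflectance: np.ndarray, **meta) -> "Spectrum":
        """Copy of this spectrum with new reflectance (and extra meta tags)."""
        return Spectrum(
            sample_id=self.sample_id,
            cultivar=self.cultivar,
            cut=self.cut,
            wavelengths_nm=self.wavelengths_nm.copy(),
            reflectance=np.asarray(reflectance, dtype=float),
            meta={**self.meta, **meta},
        )


@dataclass(frozen=True)
class PhenolicRecord:
    """Laboratory total phenolic content of one sample, mg GAE/gDW (> 0)."""

    sample_id: str
    tpc: float

    def __post_init__(self) -> None:
        if not (self.tpc > 0 and np.isfinite(self.tpc)):
            raise ValidationError(f"{self.sample_id}: tpc must be positive and finite, got {self.tpc}")
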